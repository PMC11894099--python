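"""Fluorescence quantification arithmetic: rim intensities, normalization,
Lamin stoichiometry, 3D nuclear means, phagosomes, instability rates."""

import math

import numpy as np
import pandas as pd
import pytest

from nucleodyn.intensity import (
    IntensityRecord,
    auto_rim_lines,
    instability_rate,
    lamin_stoichiometry,
    normalize_to_reference,
    nuclear_mean_3d,
    quantify_phagosomes,
    rim_intensity,
)
from nucleodyn.synth import make_lamina_fixture


def fixture_records(ratio, noise=0.0, seed=0, n=6):
    stack, table = make_lamina_fixture(ratio, n, n, 10.0, noise, seed)
    records = []
    bg_lines = [((1.0, 1.0), (1.0, 8.0)), ((3.0, 1.0), (3.0, 8.0)),
                ((5.0, 1.0), (5.0, 8.0))]
    for _, r in table.iterrows():
        records.append(
            rim_intensity(
                stack,
                auto_rim_lines((r.x_px, r.y_px), r.radius_px),
                bg_lines,
                nucleus_id=int(r.nucleus_id),
                cell_class=str(r.cell_class),
                age_group=str(r.age_group),
            )
        )
    return records


class TestRimIntensity:
    def test_hand_arithmetic(self):
        # raw 100 everywhere on the rim line; background lines 10, 12, 14
        stack = np.zeros((3, 10, 30))
        stack[:, 5, 0:10] = 100.0
        stack[:, 0, 0:10] = 10.0
        stack[:, 1, 0:10] = 12.0
        stack[:, 2, 0:10] = 14.0
        rec = rim_intensity(
            stack,
            [((0.0, 5.0), (9.0, 5.0))],
            [((0.0, 0.0), (9.0, 0.0)), ((0.0, 1.0), (9.0, 1.0)),
             ((0.0, 2.0), (9.0, 2.0))],
        )
        assert rec.raw == pytest.approx(100.0)
        assert rec.background == pytest.approx(12.0)
        assert rec.corrected == pytest.approx(88.0)
        assert not rec.negative_flag

    def test_uniform_image_corrects_to_zero(self):
        stack = np.full((3, 10, 10), 37.0)
        rec = rim_intensity(stack, [((1, 1), (8, 8))], [((1, 8), (8, 1))])
        assert rec.corrected == pytest.approx(0.0)

    def test_negative_corrected_flagged_not_clamped(self):
        stack = np.zeros((1, 5, 10))
        stack[0, 0] = 50.0  # background line brighter than rim line
        rec = rim_intensity(stack, [((0, 3), (9, 3))], [((0, 0), (9, 0))],
                            z_indices=[0])
        assert rec.corrected == pytest.approx(-50.0)
        assert rec.negative_flag

    def test_line_outside_image_rejected(self):
        stack = np.zeros((1, 5, 5))
        with pytest.raises(ValueError, match="outside"):
            rim_intensity(stack, [((0, 0), (99, 0))], [((0, 1), (4, 1))])

    def test_requires_lines(self):
        with pytest.raises(ValueError):
            rim_intensity(np.zeros((1, 5, 5)), [], [((0, 0), (4, 0))])

    def test_fixture_ratio_recovered_exactly(self):
        records = fixture_records(0.25, noise=0.0)
        hemo = np.mean([r.corrected for r in records if r.cell_class == "hemocyte"])
        epi = np.mean([r.corrected for r in records if r.cell_class == "epithelial"])
        assert hemo / epi == pytest.approx(0.25, abs=1e-12)


class TestNormalization:
    def make_records(self):
        recs = []
        for i, c in enumerate([20.0, 30.0]):
            recs.append(IntensityRecord(i, "hemocyte", "40h", c + 5, 5, c, False))
        for i, c in enumerate([90.0, 110.0]):
            recs.append(IntensityRecord(10 + i, "epithelial", "40h", c + 5, 5, c, False))
        return recs

    def test_division_by_reference_mean(self):
        recs = normalize_to_reference(self.make_records(), "epithelial")
        hemo = [r.normalized for r in recs if r.cell_class == "hemocyte"]
        assert hemo == pytest.approx([0.2, 0.3])

    def test_reference_self_normalizes_to_mean_one(self):
        recs = normalize_to_reference(self.make_records(), "epithelial")
        epi = [r.normalized for r in recs if r.cell_class == "epithelial"]
        assert np.mean(epi) == pytest.approx(1.0)

    def test_global_rescaling_invariance(self):
        recs1 = normalize_to_reference(self.make_records(), "epithelial")
        recs2 = self.make_records()
        for r in recs2:
            r.raw *= 3.7
            r.background *= 3.7
            r.corrected *= 3.7
        recs2 = normalize_to_reference(recs2, "epithelial")
        for a, b in zip(recs1, recs2):
            assert b.normalized == pytest.approx(a.normalized, rel=1e-12)

    def test_missing_reference_group_warns(self):
        recs = [IntensityRecord(0, "hemocyte", "75h", 10, 2, 8, False)]
        with pytest.warns(UserWarning, match="no epithelial"):
            normalize_to_reference(recs, "epithelial")
        assert math.isnan(recs[0].normalized)

    def test_uniform_offset_invariance_via_fixture(self):
        """Adding a constant b to every pixel leaves corrected values as-is."""
        from nucleodyn.synth import make_lamina_fixture
        from nucleodyn.intensity import auto_rim_lines, rim_intensity

        stack, table = make_lamina_fixture(0.5, 3, 3, 10.0, 0.0, 0)
        bg_lines = [((1.0, 1.0), (1.0, 8.0))]
        r = table.iloc[0]
        lines = auto_rim_lines((r.x_px, r.y_px), r.radius_px)
        c1 = rim_intensity(stack, lines, bg_lines).corrected
        c2 = rim_intensity(stack + 123.0, lines, bg_lines).corrected
        assert c2 == pytest.approx(c1, abs=1e-9)


class TestLaminStoichiometry:
    def table(self, med_a, med_b):
        rows = []
        for age, vals in med_a.items():
            rows += [dict(age_group=age, channel="dLamC", corrected=v) for v in vals]
        for age, vals in med_b.items():
            rows += [dict(age_group=age, channel="dLamB", corrected=v) for v in vals]
        return pd.DataFrame(rows)

    def test_hand_arithmetic_declining_ratio(self):
        # A-type flat, B-type doubling -> relative ratio halves
        df = self.table({"18h": [10.0], "75h": [10.0]},
                        {"18h": [10.0], "75h": [20.0]})
        out = lamin_stoichiometry(df, "18h").set_index("age_group")
        assert out.loc["18h", "ratio"] == pytest.approx(1.0)
        assert out.loc["75h", "ratio"] == pytest.approx(0.5)

    def test_identical_channels_give_unit_ratio(self):
        df = self.table({"18h": [3.0, 5.0], "40h": [7.0]},
                        {"18h": [3.0, 5.0], "40h": [7.0]})
        out = lamin_stoichiometry(df, "18h")
        assert np.allclose(out["ratio"], 1.0)

    def test_uniform_scaling_of_one_channel_cancels(self):
        base = self.table({"18h": [10.0], "75h": [14.0]},
                          {"18h": [8.0], "75h": [16.0]})
        scaled = base.copy()
        scaled.loc[scaled.channel == "dLamC", "corrected"] *= 5.0
        r1 = lamin_stoichiometry(base, "18h")["ratio"]
        r2 = lamin_stoichiometry(scaled, "18h")["ratio"]
        assert np.allclose(r1, r2)

    def test_channel_relabel_reciprocity(self):
        df = self.table({"18h": [10.0], "75h": [14.0]},
                        {"18h": [8.0], "75h": [16.0]})
        fwd = lamin_stoichiometry(df, "18h", "dLamC", "dLamB")["ratio"]
        rev = lamin_stoichiometry(df, "18h", "dLamB", "dLamC")["ratio"]
        assert np.allclose(fwd, 1.0 / rev)

    def test_missing_reference_channel_rejected(self):
        df = self.table({"18h": [10.0]}, {"40h": [8.0]})
        with pytest.raises(ValueError, match="missing at reference"):
            lamin_stoichiometry(df, "18h")


class TestNuclearMean3D:
    def test_constant_field(self):
        labels = np.zeros((3, 6, 6), dtype=int)
        labels[1, 2:4, 2:4] = 1
        vol = np.where(labels == 1, 50.0, 5.0)
        (rec,) = nuclear_mean_3d(labels, vol, 10.0)
        assert rec.corrected == pytest.approx(40.0)

    def test_background_volume_corrects_to_zero(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(20.0, 1.0, (3, 10, 10))
        labels = np.zeros_like(vol, dtype=int)
        labels[1, 2:8, 2:8] = 1
        control = vol.mean()
        (rec,) = nuclear_mean_3d(labels, vol, control)
        assert rec.corrected == pytest.approx(0.0, abs=1.0)

    def test_two_nuclei_generated_means(self):
        labels = np.zeros((2, 8, 16), dtype=int)
        labels[:, 2:6, 2:6] = 1
        labels[:, 2:6, 10:14] = 2
        vol = np.full(labels.shape, 10.0)
        vol[labels == 1] = 50.0
        vol[labels == 2] = 80.0
        recs = nuclear_mean_3d(labels, vol, 10.0)
        assert [r.corrected for r in recs] == pytest.approx([40.0, 70.0])

    def test_empty_labels(self):
        assert nuclear_mean_3d(np.zeros((2, 3, 3), int), np.zeros((2, 3, 3)), 1.0) == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nuclear_mean_3d(np.zeros((2, 3, 3), int), np.zeros((2, 3, 4)), 1.0)


class TestPhagosomes:
    def test_counting_and_area(self):
        cell = np.ones((10, 10), dtype=bool)
        lab = np.zeros((10, 10), dtype=int)
        lab[0, 0:2] = 1  # 2 px
        lab[2, 0:3] = 2  # 3 px
        lab[4, 0:5] = 3  # 5 px
        count, area = quantify_phagosomes(cell, lab, 2.0)
        assert count == 3
        assert area == pytest.approx(10 * 4.0)

    def test_empty(self):
        count, area = quantify_phagosomes(np.ones((5, 5), bool),
                                          np.zeros((5, 5), int), 1.0)
        assert count == 0 and area == 0.0

    def test_partial_overlap_clipped_to_cell(self):
        cell = np.zeros((6, 6), dtype=bool)
        cell[:, :3] = True
        lab = np.zeros((6, 6), dtype=int)
        lab[2, 1:5] = 1  # 4 px, 2 inside the cell
        count, area = quantify_phagosomes(cell, lab, 1.0)
        assert count == 1 and area == pytest.approx(2.0)


class TestInstabilityRate:
    def test_percentage(self):
        assert instability_rate(2, 50) == pytest.approx(4.0)
        assert instability_rate(0, 50) == 0.0
        assert instability_rate(50, 50) == pytest.approx(100.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            instability_rate(1, 0)


def test_full_ratio_recovery_with_noise():
    """Generating ratio recovered within 10% at 20% noise, several seeds."""
    vals = []
    for seed in range(5):
        records = fixture_records(0.25, noise=20.0, seed=seed, n=15)
        records = normalize_to_reference(records, "epithelial")
        hemo = np.mean([r.normalized for r in records if r.cell_class == "hemocyte"])
        vals.append(hemo)
    assert np.mean(vals) == pytest.approx(0.25, rel=0.10)
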