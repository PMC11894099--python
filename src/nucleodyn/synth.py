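"""Seeded synthetic movies and fixtures with known ground truth.

No primary imaging data accompany the study this pipeline quantifies, so
every downstream stage is exercised against generated data whose generative
parameters are known exactly.  The generator emulates migrating fluorescent
nuclei (uniform-intensity ellipsoids, ~2-8 um across) inside channel-like
regions, undergoing stochastic reversible elongation ("squeezing")
episodes.  The squeeze state follows a two-state Markov chain with
per-frame entry/exit probabilities, so the stationary squeezing occupancy
is ``p_enter / (p_enter + p_exit)`` and the mean event length ``1/p_exit``
frames -- closed forms that downstream statistics are validated against.

Two stock regimes encode the study's qualitative contrast: nuclei confined
in narrow "vessel" channels squeeze more often and for longer than nuclei
in an "open" tissue environment.

Determinism contract: identical seed + config give bit-identical output.
Each nucleus draws from its own random stream derived from the master seed
and the nucleus id, so adding a nucleus never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .movie import Movie

__all__ = [
    "SynthRegime",
    "SynthMovieConfig",
    "GroundTruth",
    "OPEN_REGIME",
    "VESSEL_REGIME",
    "simulate_sf_series",
    "render_movie",
    "make_lamina_fixture",
    "make_vessel_transit_movie",
    "TransitFixture",
]

_SQUEEZE_THRESHOLD = 0.4  # boundary between baseline and squeeze SF bands

NUCLEUS_INTENSITY = 200.0
BACKGROUND_INTENSITY = 20.0


@dataclass(frozen=True)
class SynthRegime:
    """Generative parameters of one migration environment."""

    name: str
    nucleus_diameter_um: float = 4.0
    speed_um_per_min: float = 2.0
    p_enter_squeeze: float = 0.1
    p_exit_squeeze: float = 0.3
    sf_baseline: float = 0.15
    sf_squeeze: float = 0.55
    channel_width_um: float | None = None
    sf_jitter_sd: float = 0.03
    turn_sd_rad: float = 0.3

    def __post_init__(self) -> None:
        for p in (self.p_enter_squeeze, self.p_exit_squeeze):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"transition probabilities must be in [0,1]; got {p}")
        if not 0.0 <= self.sf_baseline < _SQUEEZE_THRESHOLD:
            raise ValueError("sf_baseline must lie in [0, 0.4)")
        if not _SQUEEZE_THRESHOLD <= self.sf_squeeze < 1.0:
            raise ValueError("sf_squeeze must lie in [0.4, 1)")
        if self.nucleus_diameter_um <= 0 or self.speed_um_per_min <= 0:
            raise ValueError("diameters and speeds must be positive")
        if self.channel_width_um is not None and self.channel_width_um <= 0:
            raise ValueError("channel_width_um must be positive or None")

    @property
    def stationary_squeeze_fraction(self) -> float:
        """Markov stationary occupancy p_enter / (p_enter + p_exit)."""
        s = self.p_enter_squeeze + self.p_exit_squeeze
        return self.p_enter_squeeze / s if s > 0 else 0.0


#: Unconfined early-stage tissue: rare, short squeezing episodes.
OPEN_REGIME = SynthRegime(
    name="open",
    nucleus_diameter_um=4.0,
    speed_um_per_min=3.0,
    p_enter_squeeze=0.05,
    p_exit_squeeze=0.5,
    sf_baseline=0.10,
    sf_squeeze=0.50,
    channel_width_um=None,
)

#: Narrow vessel-like channel: frequent, longer squeezing episodes.
VESSEL_REGIME = SynthRegime(
    name="vessel",
    nucleus_diameter_um=4.0,
    speed_um_per_min=2.0,
    p_enter_squeeze=0.30,
    p_exit_squeeze=0.30,
    sf_baseline=0.18,
    sf_squeeze=0.55,
    channel_width_um=6.0,
)


@dataclass(frozen=True)
class SynthMovieConfig:
    regime: SynthRegime = VESSEL_REGIME
    n_nuclei: int = 3
    n_frames: int = 40
    frame_interval_s: float = 30.0
    pixel_size_um: float = 0.3
    z_slices: int = 7
    field_shape_px: tuple[int, int] = (64, 256)  # (y, x)
    noise_gaussian_sd: float = 5.0
    noise_poisson: bool = True
    seed: int = 0
    allow_collisions: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.z_slices < 1:
            raise ValueError("z_slices must be >= 1")


@dataclass
class GroundTruth:
    """Per-nucleus-per-frame truth plus the vessel mask and event intervals.

    ``table`` columns: frame, nucleus_id, x_px, y_px, z_px, semi_major_px,
    semi_minor_px, sf_true, squeezing.
    """

    table: pd.DataFrame
    vessel_mask: np.ndarray | None  # (y, x) uint8, 1 inside channel
    events: dict[int, list[tuple[int, int]]]  # nucleus id -> [(start, end)]
    config: SynthMovieConfig | None = field(default=None, repr=False)


def _nucleus_rng(seed: int, nucleus_id: int) -> np.random.Generator:
    """Stable per-nucleus stream: hashing the id into the seed sequence."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(nucleus_id,)))


def simulate_sf_series(
    regime: SynthRegime,
    n_frames: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one nucleus's SF time series.

    Two-state Markov chain (round/squeeze) with the regime's per-frame
    transition probabilities; the initial state is drawn from the stationary
    distribution.  Emitted SF is the state's level plus truncated Gaussian
    jitter, clipped so that the squeeze flag and ``SF >= 0.4`` agree frame
    by frame.

    Returns ``(sf, squeezing)``, both of length ``n_frames``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_in, p_out = regime.p_enter_squeeze, regime.p_exit_squeeze
    state = np.empty(n_frames, dtype=bool)
    state[0] = rng.random() < regime.stationary_squeeze_fraction
    u = rng.random(n_frames - 1)
    for i in range(1, n_frames):
        state[i] = (u[i - 1] < p_in) if not state[i - 1] else (u[i - 1] >= p_out)
    jitter = rng.normal(0.0, regime.sf_jitter_sd, n_frames)
    sf = np.where(state, regime.sf_squeeze, regime.sf_baseline) + jitter
    eps = 1e-6
    sf = np.where(
        state,
        np.clip(sf, _SQUEEZE_THRESHOLD, 1.0 - eps),
        np.clip(sf, 0.0, _SQUEEZE_THRESHOLD - eps),
    )
    return sf, state


def _state_events(state: np.ndarray) -> list[tuple[int, int]]:
    events = []
    start = None
    for i, s in enumerate(state):
        if s and start is None:
            start = i
        elif not s and start is not None:
            events.append((start, i - 1))
            start = None
    if start is not None:
        events.append((start, len(state) - 1))
    return events


def _fill_ellipsoid(volume, cz, cy, cx, a, b, c, theta, value):
    """Set voxels of the in-plane-rotated ellipsoid (a along theta) to value."""
    nz, ny, nx = volume.shape
    r_xy = max(a, b)
    z0, z1 = max(0, int(cz - c) - 1), min(nz, int(cz + c) + 2)
    y0, y1 = max(0, int(cy - r_xy) - 1), min(ny, int(cy + r_xy) + 2)
    x0, x1 = max(0, int(cx - r_xy) - 1), min(nx, int(cx + r_xy) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    dx = xx - cx
    dy = yy - cy
    dz = zz - cz
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 + (dz / c) ** 2 <= 1.0
    volume[z0:z1, y0:y1, x0:x1][inside] = value


def render_movie(config: SynthMovieConfig) -> tuple[Movie, GroundTruth]:
    """Render a seeded synthetic nuclear-channel movie with ground truth.

    Each nucleus is a filled uniform-intensity ellipsoid whose in-plane
    semi-axes realise the frame's true SF under the (a-b)/(a+b) formula
    while conserving projected area (a*b = r^2); the major axis aligns with
    the instantaneous velocity.  Nuclei are confined to the channel when the
    regime defines one, and each keeps to its own stretch of the field so
    centroids never approach closer than twice the nucleus diameter (unless
    ``allow_collisions``).  Imaging noise (Poisson then additive Gaussian)
    is applied last.
    """
    reg = config.regime
    ny, nx = config.field_shape_px
    ps = config.pixel_size_um
    r_px = reg.nucleus_diameter_um / 2.0 / ps
    d_px = 2.0 * r_px

    if d_px >= min(ny, nx):
        raise ValueError("nucleus larger than field")
    if reg.channel_width_um is not None:
        half_w = reg.channel_width_um / 2.0 / ps
        if 2 * half_w >= ny:
            raise ValueError("channel wider than field")
        if d_px > 2 * half_w:
            raise ValueError("nucleus larger than channel")
        y_lo, y_hi = ny / 2.0 - half_w, ny / 2.0 + half_w
        vessel_mask = np.zeros((ny, nx), dtype=np.uint8)
        vessel_mask[int(math.ceil(y_lo)) : int(math.floor(y_hi)) + 1, :] = 1
    else:
        y_lo, y_hi = 0.0, float(ny)
        vessel_mask = None

    # one disjoint territory per nucleus along x, margins of one diameter,
    # guaranteeing pairwise centroid spacing >= 2 * diameter
    seg = nx / config.n_nuclei
    if not config.allow_collisions and seg < 4 * d_px:
        raise ValueError(
            "field too small for collision-free placement; "
            "enlarge field_shape_px or set allow_collisions"
        )
    step_px = reg.speed_um_per_min * (config.frame_interval_s / 60.0) / ps

    nz = config.z_slices
    c_ax = min(r_px, max(1.0, (nz - 1) / 2.0)) if nz > 1 else 0.6
    movie_data = np.full(
        (config.n_frames, nz, ny, nx), BACKGROUND_INTENSITY, dtype=np.float64
    )
    rows = []
    events: dict[int, list[tuple[int, int]]] = {}

    for nid in range(config.n_nuclei):
        rng = _nucleus_rng(config.seed, nid)
        sf, state = simulate_sf_series(reg, config.n_frames, rng)
        events[nid] = _state_events(state)
        x_lo, x_hi = nid * seg + d_px, (nid + 1) * seg - d_px
        cx = float(rng.uniform(x_lo, x_hi))
        margin_y = min(r_px, (y_hi - y_lo) / 2.0 - 1.0)
        yc_lo, yc_hi = y_lo + margin_y, y_hi - margin_y
        cy = float(rng.uniform(yc_lo, yc_hi)) if yc_hi > yc_lo else (y_lo + y_hi) / 2.0
        cz = (nz - 1) / 2.0
        theta = float(rng.uniform(0.0, 2.0 * math.pi))
        for t in range(config.n_frames):
            s = sf[t]
            a = r_px * math.sqrt((1.0 + s) / (1.0 - s))
            b = r_px * math.sqrt((1.0 - s) / (1.0 + s))
            _fill_ellipsoid(
                movie_data[t], cz, cy, cx, a, b, c_ax, theta, NUCLEUS_INTENSITY
            )
            rows.append(
                dict(
                    frame=t,
                    nucleus_id=nid,
                    x_px=cx,
                    y_px=cy,
                    z_px=cz,
                    semi_major_px=a,
                    semi_minor_px=b,
                    sf_true=float(s),
                    squeezing=bool(state[t]),
                )
            )
            # advance: persistent random walk, reflected at territory bounds
            theta += float(rng.normal(0.0, reg.turn_sd_rad))
            step = step_px * float(rng.uniform(0.8, 1.2))
            cx += step * math.cos(theta)
            cy += step * math.sin(theta)
            if cx < x_lo:
                cx = 2 * x_lo - cx
                theta = math.pi - theta
            elif cx > x_hi:
                cx = 2 * x_hi - cx
                theta = math.pi - theta
            if yc_hi > yc_lo:
                if cy < yc_lo:
                    cy = 2 * yc_lo - cy
                    theta = -theta
                elif cy > yc_hi:
                    cy = 2 * yc_hi - cy
                    theta = -theta
            else:
                cy = (y_lo + y_hi) / 2.0

    noise_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xFFFF,))
    )
    if config.noise_poisson:
        movie_data = noise_rng.poisson(movie_data).astype(np.float64)
    if config.noise_gaussian_sd > 0:
        movie_data = movie_data + noise_rng.normal(
            0.0, config.noise_gaussian_sd, movie_data.shape
        )
    movie = Movie(
        data=movie_data.astype(np.float32),
        pixel_size_um=ps,
        frame_interval_s=config.frame_interval_s,
        name=f"synth-{reg.name}-seed{config.seed}",
    )
    truth = GroundTruth(
        table=pd.DataFrame(rows),
        vessel_mask=vessel_mask,
        events=events,
        config=config,
    )
    return movie, truth


def make_lamina_fixture(
    ratio: float,
    n_hemocyte: int = 10,
    n_epithelial: int = 10,
    background_level: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    rim_radius_px: float = 8.0,
    rim_thickness_px: float = 2.0,
    rim_signal: float = 100.0,
    z_slices: int = 5,
    age_group: str = "18h",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Immunostaining fixture: annular lamina rims of two cell classes.

    Epithelial nuclei get rim intensity ``rim_signal`` above background;
    hemocyte rims carry ``ratio * rim_signal``.  Returns the (z, y, x)
    stack and a table with columns ``nucleus_id, cell_class, age_group,
    x_px, y_px, radius_px``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n_total = n_hemocyte + n_epithelial
    pitch = int(4 * (rim_radius_px + rim_thickness_px))
    n_cols = int(math.ceil(math.sqrt(n_total)))
    n_rows = int(math.ceil(n_total / n_cols))
    ny, nx = n_rows * pitch, n_cols * pitch
    stack = np.full((z_slices, ny, nx), float(background_level))
    yy, xx = np.mgrid[0:ny, 0:nx]
    rows = []
    for i in range(n_total):
        cls = "hemocyte" if i < n_hemocyte else "epithelial"
        level = rim_signal * ratio if cls == "hemocyte" else rim_signal
        r0, c0 = divmod(i, n_cols)
        cy = r0 * pitch + pitch / 2.0
        cx = c0 * pitch + pitch / 2.0
        dist = np.hypot(xx - cx, yy - cy)
        annulus = (dist >= rim_radius_px - rim_thickness_px / 2.0) & (
            dist <= rim_radius_px + rim_thickness_px / 2.0
        )
        stack[:, annulus] += level
        rows.append(
            dict(
                nucleus_id=i,
                cell_class=cls,
                age_group=age_group,
                x_px=cx,
                y_px=cy,
                radius_px=rim_radius_px,
            )
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, stack.shape)
    return stack, pd.DataFrame(rows)


@dataclass
class TransitFixture:
    """Two-channel vessel-transit movie plus its generating truth."""

    walls: Movie
    nuclei: Movie
    measurement_x_px: int
    ground_truth: dict


def make_vessel_transit_movie(
    pre_diameter_um: float,
    dilation_factor: float,
    nucleus_diameter_um: float,
    seed: int = 0,
    *,
    pixel_size_um: float = 0.3,
    frame_interval_s: float = 30.0,
    n_frames: int = 30,
    noise_sd: float = 2.0,
    wall_amplitude: float = 150.0,
    wall_sigma_px: float = 1.2,
) -> TransitFixture:
    """Fixture for vessel-dilation analysis during nuclear transit.

    Two parallel bright wall lines (Gaussian cross-section, centre-to-centre
    separation ``pre_diameter_um``) widen to ``dilation_factor *
    pre_diameter_um`` while the nucleus centroid lies within one nuclear
    radius of the measurement line, then relax.  The nuclear channel carries
    a bright disk-shaped nucleus traversing the channel left to right.
    """
    if dilation_factor < 1.0:
        raise ValueError("dilation_factor must be >= 1")
    if nucleus_diameter_um > dilation_factor * pre_diameter_um:
        raise ValueError("nucleus wider than dilated vessel")
    ps = pixel_size_um
    d_pre_px = pre_diameter_um / ps
    d_nuc_px = nucleus_diameter_um / ps
    ny = int(math.ceil(d_pre_px * dilation_factor)) + 40
    nx = 120
    y_c = ny / 2.0
    x_meas = nx // 2
    bg = 10.0
    r_nuc = d_nuc_px / 2.0

    walls = np.full((n_frames, 1, ny, nx), bg)
    nuclei = np.full((n_frames, 1, ny, nx), bg)
    yy = np.arange(ny, dtype=float)[:, None]
    xx = np.arange(nx, dtype=float)[None, :]
    # nucleus path: enters at the left, exits at the right
    x_path = np.linspace(r_nuc + 2, nx - r_nuc - 2, n_frames)
    transit = np.abs(x_path - x_meas) <= r_nuc
    frames_in = np.nonzero(transit)[0]
    for t in range(n_frames):
        d = d_pre_px * (dilation_factor if transit[t] else 1.0)
        for y_wall in (y_c - d / 2.0, y_c + d / 2.0):
            walls[t, 0] += wall_amplitude * np.exp(
                -((yy - y_wall) ** 2) / (2.0 * wall_sigma_px**2)
            ) * np.ones_like(xx)
        disk = np.hypot(xx - x_path[t], yy - y_c) <= r_nuc
        nuclei[t, 0][disk] = NUCLEUS_INTENSITY
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        walls = walls + rng.normal(0.0, noise_sd, walls.shape)
        nuclei = nuclei + rng.normal(0.0, noise_sd, nuclei.shape)
    truth = dict(
        d_pre_um=pre_diameter_um,
        d_during_um=pre_diameter_um * dilation_factor,
        d_post_um=pre_diameter_um,
        d_nucleus_um=nucleus_diameter_um,
        residual_um=pre_diameter_um * dilation_factor - nucleus_diameter_um,
        transit_frames=(int(frames_in[0]), int(frames_in[-1])) if frames_in.size else None,
        dilation_factor=dilation_factor,
    )
    mk = lambda arr, nm: Movie(  # noqa: E731
        data=arr.astype(np.float32),
        pixel_size_um=ps,
        frame_interval_s=frame_interval_s,
        name=nm,
    )
    return TransitFixture(
        walls=mk(walls, f"transit-walls-seed{seed}"),
        nuclei=mk(nuclei, f"transit-nuclei-seed{seed}"),
        measurement_x_px=x_meas,
        ground_truth=truth,
    )
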