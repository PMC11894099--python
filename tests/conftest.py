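import numpy as np
import pytest


def rasterize_ellipse(semi_a, semi_b, theta=0.0, pad=4):
    """Binary mask of an axis-rotated ellipse, analytic oracle geometry."""
    r = int(np.ceil(max(semi_a, semi_b))) + pad
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = np.cos(theta), np.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    return (u / semi_a) ** 2 + (v / semi_b) ** 2 <= 1.0


def rasterize_disk(radius, pad=4):
    return rasterize_ellipse(radius, radius, pad=pad)


def random_blob_mask(rng, size=48):
    """Connected random blob: thresholded smoothed noise, largest component."""
    from scipy import ndimage

    img = ndimage.gaussian_filter(rng.normal(size=(size, size)), 4.0)
    mask = img > np.quantile(img, 0.8)
    lab, n = ndimage.label(mask)
    if n == 0:
        return random_blob_mask(rng, size)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


@pytest.fixture(scope="session")
def noise_free_movie():
    """One noise-free rendered vessel-regime movie with its ground truth."""
    from nucleodyn.synth import SynthMovieConfig, render_movie

    cfg = SynthMovieConfig(
        seed=11, n_nuclei=3, n_frames=20, noise_gaussian_sd=0.0, noise_poisson=False
    )
    movie, truth = render_movie(cfg)
    return movie, truth


@pytest.fixture(scope="session")
def default_movie():
    """One noisy rendered vessel-regime movie (default imaging noise)."""
    from nucleodyn.synth import SynthMovieConfig, render_movie

    cfg = SynthMovieConfig(seed=7, n_nuclei=3, n_frames=40)
    movie, truth = render_movie(cfg)
    return movie, truth
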