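import numpy as np
import pytest

from fibrarch.images import CalibratedImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_ridge():
    """Horizontal Gaussian ridge, FWHM 10 px, on a 90x90 field at 1 um/px."""
    sigma = 10.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rows = np.arange(90, dtype=float)[:, None]
    img = 200.0 * np.exp(-((rows - 45.0) ** 2) / (2 * sigma ** 2)) * np.ones((1, 90))
    return CalibratedImage(img, 1.0)


def brute_force_haralick(image, offset, levels):
    """Independent pair-enumeration evaluation of Haralick correlation.

    Enumerates every ordered pixel pair at the offset, builds the joint
    probability table explicitly and applies the correlation formula
    term by term.
    """
    img = np.asarray(image)
    h, w = img.shape
    dr, dc = offset
    pairs = []
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                pairs.append((int(img[r, c]), int(img[r2, c2])))
    if not pairs:
        raise ValueError("no valid pairs")
    p = {}
    for ij in pairs:
        p[ij] = p.get(ij, 0) + 1.0 / len(pairs)
    mu_i = sum(i * v for (i, _), v in p.items())
    mu_j = sum(j * v for (_, j), v in p.items())
    var_i = sum((i - mu_i) ** 2 * v for (i, _), v in p.items())
    var_j = sum((j - mu_j) ** 2 * v for (_, j), v in p.items())
    denom = (var_i * var_j) ** 0.5
    if denom == 0:
        return float("nan")
    return sum((i - mu_i) * (j - mu_j) * v for (i, j), v in p.items()) / denom
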