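"""Independent brute-force references used by the tests.

These deliberately do not share code with the package: the frame
modification is checked against an exhaustive search over a coordinate
grid, and the whole-signal SNR against the uniform-shift closed form
evaluated directly from Parseval.
"""

import numpy as np

_GRID_CACHE = {}


def _grid_points(n: int, axis: tuple) -> np.ndarray:
    key = (n, axis)
    if key not in _GRID_CACHE:
        arrs = np.meshgrid(*([np.asarray(axis)] * n), indexing="ij")
        _GRID_CACHE[key] = np.stack(arrs, axis=-1).reshape(-1, n)
    return _GRID_CACHE[key]


def grid_search_modification(mags, bit, eps, delta=0.0, step=0.5, reach=None):
    """Cheapest grid point satisfying the embedding rule, or (None, inf).

    The grid spans [0, max(mags) + reach] per coordinate with the given
    step; ``reach`` defaults to 2*eps + step so the uniform-shift optimum
    is always inside.
    """
    mags = np.asarray(mags, dtype=float)
    if reach is None:
        reach = 2.0 * eps + 2.0 * delta + step
    hi = mags.max() + reach
    axis = tuple(np.arange(0.0, hi + step / 2.0, step))
    pts = _grid_points(mags.size, axis)
    means = pts.mean(axis=1)
    m = mags.mean()
    if bit == 1:
        feasible = means >= m + eps
    else:
        feasible = means <= m - eps - delta
    if not np.any(feasible):
        return None, np.inf
    cand = pts[feasible]
    costs = ((cand - mags) ** 2).sum(axis=1)
    i = int(np.argmin(costs))
    return cand[i], float(costs[i])


def uniform_shift_snr_db(samples, bits, eps, delta, block_size):
    """Whole-signal SNR predicted by Parseval for the no-clamping oracle."""
    bits = np.asarray(bits)
    shift = np.where(bits == 1, eps, eps + delta)
    err = float((block_size * shift ** 2).sum())
    energy = float((np.asarray(samples, dtype=float) ** 2).sum())
    return -10.0 * np.log10(err / energy)
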