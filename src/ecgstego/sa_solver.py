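"""Simulated annealing for the constrained frame-modification problem.

The frame modification is a least-squares problem over magnitude vectors:
push the frame's mean magnitude above m + eps (bit 1) or below m - eps -
delta (bit 0) while staying non-negative and changing the coefficients as
little as possible.  Energy is defined as -(frame SNR), so lower energy is
better and the Metropolis rule "accept when dE <= 0" performs maximization.

Proposals are Gaussian perturbations of the current magnitudes followed by
an exact projection back onto the feasible set, so every visited point is
feasible and every iteration is productive.  The feasible sets are a
half-space intersected with the non-negative orthant; their Euclidean
projections (a uniform lift, and water-filling with clamping at zero) are
cheap and exact, and are exposed here because the closed-form optimum of the
frame problem is precisely the projection of the original magnitudes.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np


@dataclasses.dataclass
class SAParams:
    """Cooling schedule and proposal parameters.

    ``proposal_sd=None`` means 0.25x the embedding strength, resolved where
    the strength is known.  Energies are on the dB (SNR) scale, so the
    default temperatures are scale-free.
    """

    initial_temperature: float = 1.0
    final_temperature: float = 1e-3
    cooling_rate: float = 0.95
    iterations_per_temperature: int = 50
    proposal_sd: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not (self.initial_temperature > self.final_temperature > 0):
            raise ValueError("need initial_temperature > final_temperature > 0")
        if not 0 < self.cooling_rate < 1:
            raise ValueError("cooling_rate must lie in (0, 1)")
        if self.iterations_per_temperature < 1:
            raise ValueError("iterations_per_temperature must be >= 1")

    @property
    def n_temperatures(self) -> int:
        n = 0
        t = self.initial_temperature
        while t > self.final_temperature:
            n += 1
            t *= self.cooling_rate
        return n

    @property
    def total_iterations(self) -> int:
        return self.n_temperatures * self.iterations_per_temperature


def acceptance_probability(delta_e: float, temperature: float) -> float:
    """Metropolis rule: 1 if dE <= 0, else exp(-dE / T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return 1.0
    return math.exp(-delta_e / temperature)


# ---------------------------------------------------------------------------
# Exact projections onto the two feasible sets (batched over frames).


def project_mean_floor(x: np.ndarray, floor: np.ndarray) -> np.ndarray:
    """Euclidean projection of rows of ``x`` onto {y >= 0, mean(y) >= floor}.

    Clamp negatives, then lift uniformly; the returned rows satisfy the mean
    constraint under exact floating-point comparison.
    """
    y = np.maximum(np.atleast_2d(np.asarray(x, float)), 0.0)
    floor = np.atleast_1d(np.asarray(floor, float))
    for _ in range(64):
        gap = floor - y.mean(axis=1)
        if not np.any(gap > 0):
            break
        y = y + np.maximum(gap, 0.0)[:, None]
    bad = floor - y.mean(axis=1) > 0
    while np.any(bad):  # one-ulp insurance against rounding in the mean
        y[bad] += np.spacing(np.maximum(np.abs(floor[bad]), 1.0))[:, None]
        bad = floor - y.mean(axis=1) > 0
    return y


def project_sum_cap(x: np.ndarray, cap: np.ndarray) -> np.ndarray:
    """Euclidean projection of rows of ``x`` onto {y >= 0, sum(y) <= cap}.

    KKT water-filling: subtract a uniform level, clamping entries at zero
    (y_i = max(x_i - lam, 0) with lam chosen so the cap binds).  Rows whose
    clamped sum is already under the cap are returned unchanged.
    """
    y = np.maximum(np.atleast_2d(np.asarray(x, float)), 0.0)
    cap = np.atleast_1d(np.asarray(cap, float))
    if np.any(cap < 0):
        raise ValueError("sum cap must be non-negative")
    rows = np.nonzero(y.sum(axis=1) > cap)[0]
    if rows.size:
        sub = y[rows]
        s = cap[rows]
        u = -np.sort(-sub, axis=1)
        css = np.cumsum(u, axis=1)
        j = np.arange(1, sub.shape[1] + 1)
        active = u * j > css - s[:, None]
        has_active = active.any(axis=1)
        # rho: index of the last active coordinate in sorted order
        rho = sub.shape[1] - 1 - np.argmax(active[:, ::-1], axis=1)
        lam = (np.take_along_axis(css, rho[:, None], axis=1)[:, 0] - s) / (rho + 1)
        out = np.maximum(sub - lam[:, None], 0.0)
        out[~has_active] = 0.0  # cap of zero removes all mass
        y[rows] = out
        # exact-feasibility cleanup against rounding in lam
        over = y[rows].sum(axis=1) - s
        bad = np.nonzero(over > 0)[0]
        while bad.size:
            r = rows[bad]
            top = y[r].argmax(axis=1)
            y[r, top] = np.maximum(y[r, top] - over[bad], 0.0)
            over = y[rows].sum(axis=1) - s
            bad = np.nonzero(over > 0)[0]
    return y


# ---------------------------------------------------------------------------
# Generic single-problem annealer.


def anneal(initial, energy, project, params: SAParams, return_trace: bool = False):
    """Anneal from ``initial`` under ``energy``, keeping iterates feasible.

    ``project`` maps any magnitude vector onto the feasible set; it is
    applied to the initial point and to every proposal.  Returns the best
    feasible point seen.  Identical seeds give identical trajectories.  One
    uniform draw is consumed per iteration regardless of the dE branch so
    the random stream is branch-independent.
    """
    rng = np.random.default_rng(params.seed)
    sd = params.proposal_sd if params.proposal_sd is not None else 1.0
    cur = project(np.asarray(initial, dtype=float))
    e_cur = float(energy(cur))
    if not math.isfinite(e_cur):
        raise ValueError("energy is not finite at the projected initial point")
    best, e_best = cur.copy(), e_cur
    trace = [e_best]
    t = params.initial_temperature
    while t > params.final_temperature:
        for _ in range(params.iterations_per_temperature):
            cand = project(cur + rng.normal(0.0, sd, size=cur.shape))
            e_cand = float(energy(cand))
            u = rng.uniform()
            de = e_cand - e_cur
            if de <= 0 or u < math.exp(-de / t):
                cur, e_cur = cand, e_cand
                if e_cur < e_best:
                    best, e_best = cand.copy(), e_cur
            trace.append(e_best)
        t *= params.cooling_rate
    if return_trace:
        return best, trace
    return best


# ---------------------------------------------------------------------------
# Batched annealer over the frames of one embedding call.

_COST_FLOOR = 1e-300  # keeps log10 defined; cancels in energy differences


def _frame_energy(y: np.ndarray, orig: np.ndarray) -> np.ndarray:
    """-(frame SNR) up to an additive constant: 10*log10 of squared cost."""
    cost = ((y - orig) ** 2).sum(axis=1)
    return 10.0 * np.log10(cost + _COST_FLOOR)


def anneal_frames(
    magnitudes: np.ndarray,
    bits: np.ndarray,
    strength: float,
    delta: float,
    params: SAParams,
    initial: np.ndarray,
    chunk_size: int = 256,
) -> np.ndarray:
    """Anneal all bit-carrying frames of one embed call.

    ``magnitudes`` is (frames, n) of original magnitudes, ``bits`` the bit
    per frame, ``initial`` a feasible starting point per frame (the
    closed-form optimum; it is perturbed by one proposal step before the
    run).  One seeded generator per embed call, split per frame by frame
    index, so results do not depend on evaluation order.  Frames are
    processed in chunks to bound the memory of the precomputed random
    streams.
    """
    F = np.asarray(magnitudes, dtype=float)
    bits = np.asarray(bits).astype(np.uint8)
    B, n = F.shape
    out = np.empty_like(F)
    children = np.random.SeedSequence(params.seed).spawn(B)
    sd = params.proposal_sd if params.proposal_sd is not None else 0.25 * strength
    for start in range(0, B, chunk_size):
        stop = min(start + chunk_size, B)
        out[start:stop] = _anneal_chunk(
            F[start:stop],
            bits[start:stop],
            strength,
            delta,
            params,
            np.asarray(initial, float)[start:stop],
            children[start:stop],
            sd,
        )
    return out


def _anneal_chunk(F, bits, strength, delta, params, init, seeds, sd):
    B, n = F.shape
    total = params.total_iterations
    normals = np.empty((B, total, n))
    unifs = np.empty((B, total))
    init_noise = np.empty((B, n))
    for f in range(B):
        g = np.random.default_rng(seeds[f])
        init_noise[f] = g.normal(0.0, sd, n)
        normals[f] = g.normal(0.0, 1.0, (total, n))
        unifs[f] = g.uniform(size=total)
    normals *= sd

    out = np.empty_like(F)
    m = F.mean(axis=1)
    idx1 = np.nonzero(bits == 1)[0]
    idx0 = np.nonzero(bits != 1)[0]
    if idx1.size:
        out[idx1] = _anneal_sub(
            F[idx1], init[idx1] + init_noise[idx1], normals[idx1], unifs[idx1],
            params, _make_floor_projector(m[idx1] + strength),
            lambda y: project_mean_floor(y, m[idx1] + strength),
        )
    if idx0.size:
        cap = np.maximum((m[idx0] - strength - delta) * n, 0.0)
        out[idx0] = _anneal_sub(
            F[idx0], init[idx0] + init_noise[idx0], normals[idx0], unifs[idx0],
            params, _make_cap_projector(cap),
            lambda y: project_sum_cap(y, cap),
        )
    return out


def _make_floor_projector(floor):
    """Fast in-loop projector onto {y >= 0, mean(y) >= floor} (rowwise)."""
    col = floor[:, None]

    def project(y):
        np.maximum(y, 0.0, out=y)
        gap = col - y.mean(axis=1, keepdims=True)
        np.maximum(gap, 0.0, out=gap)
        y += gap
        return y

    return project


def _make_cap_projector(cap):
    """Fast in-loop projector onto {y >= 0, sum(y) <= cap} (rowwise)."""
    n = None
    j = None

    def project(y):
        nonlocal n, j
        if j is None:
            n = y.shape[1]
            j = np.arange(1, n + 1)
        np.maximum(y, 0.0, out=y)
        viol = y.sum(axis=1) > cap
        if np.any(viol):
            u = -np.sort(-y, axis=1)
            css = np.cumsum(u, axis=1)
            active = u * j > css - cap[:, None]
            has_active = active.any(axis=1)
            rho = n - 1 - np.argmax(active[:, ::-1], axis=1)
            lam = (np.take_along_axis(css, rho[:, None], axis=1)[:, 0] - cap) / (rho + 1)
            lam = np.where(viol & has_active, lam, 0.0)
            y -= lam[:, None]
            np.maximum(y, 0.0, out=y)
            y[viol & ~has_active] = 0.0
        return y

    return project


def _anneal_sub(F, init, normals, unifs, params, project, exact_project):
    """Metropolis chain for one constraint family; the returned best point
    goes through the exact projection so its constraint holds under exact
    floating-point comparison."""
    cur = exact_project(np.array(init, dtype=float))
    e_cur = _frame_energy(cur, F)
    best, e_best = cur.copy(), e_cur.copy()
    D = params.iterations_per_temperature
    t0, r = params.initial_temperature, params.cooling_rate
    total = normals.shape[1]
    temperature = t0
    for t_idx in range(total):
        if t_idx and t_idx % D == 0:
            temperature *= r
        cand = project(cur + normals[:, t_idx, :])
        e_cand = _frame_energy(cand, F)
        de = e_cand - e_cur
        accept = (de <= 0) | (unifs[:, t_idx] < np.exp(-np.maximum(de, 0.0) / temperature))
        cur = np.where(accept[:, None], cand, cur)
        e_cur = np.where(accept, e_cand, e_cur)
        improved = e_cur < e_best
        best = np.where(improved[:, None], cur, best)
        e_best = np.where(improved, e_cur, e_best)
    return exact_project(best)
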