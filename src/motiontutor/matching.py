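"""Pattern–signal matching: the invariant distance g/h and its minimizer.

The similarity between a one-period pattern P = (p¹..p^w) and the trailing
window of a signal S = (s¹..s^m) is judged after an explicit linear
transform of the pattern in both time (scale a, shift b) and value
(scale c, offset d):

    g(P, S, a, b, c, d) = (1/n) · Σ_{k=0}^{n−1} (p^{wrap(round(b − a·k))}·c + d − s^{m−k})²

with the pattern indexed cyclically (indices wrapped into [1, w]).  The
distance proper is h = min g over a discrete grid of the four parameters,
found by a two-stage coarse-to-fine "trial and error" search: a full
coarse-grid sweep, then local re-search around the few lowest coarse
minima with the grid step divided by ``refine_factor``.

Before the search both windows are linearly normalized so their extrema sit
at ±0.6, which shrinks the useful (c, d) ranges and keeps the evaluation
budget small.  ``h_oracle`` performs the exhaustive search over the fully
refined grid and exists purely as an independent check of the two-stage
minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .errors import InvalidInputError

NORM_LEVEL = 0.6  # normalized windows span [-0.6, +0.6]


# ---------------------------------------------------------------------------
# grid specification


@dataclass(frozen=True)
class GridAxis:
    """Discrete candidate set for one parameter: `count` evenly spaced
    values on [lo, hi]."""

    lo: float
    hi: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise InvalidInputError("axis count must be >= 1")
        if self.lo > self.hi:
            raise InvalidInputError("axis lo must not exceed hi")

    @property
    def step(self) -> float:
        return (self.hi - self.lo) / (self.count - 1) if self.count > 1 else 0.0

    def values(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.count)


@dataclass(frozen=True)
class MatchGrid:
    """Candidate sets Z′ for (a, b, c, d) plus refinement policy.

    ``b`` may be ``None``, meaning the full pattern period [1, w] with
    ``b_count`` candidates (the period is only known per pattern).
    """

    a: GridAxis = GridAxis(0.7, 1.3, 7)
    b: GridAxis | None = None
    c: GridAxis = GridAxis(0.8, 1.2, 5)
    d: GridAxis = GridAxis(-0.1, 0.1, 3)
    b_count: int = 20
    refine_factor: int = 5
    n_refine_regions: int = 3

    def b_axis(self, w: int) -> GridAxis:
        return self.b if self.b is not None else GridAxis(1.0, float(w), self.b_count)

    def stage1_count(self, w: int) -> int:
        return self.a.count * self.b_axis(w).count * self.c.count * self.d.count

    @classmethod
    def default(cls) -> "MatchGrid":
        """Reduced grid used on normalized windows; contains the identity
        transform (a=1, c=1, d=0) exactly."""
        return cls()

    @classmethod
    def unreduced(cls) -> "MatchGrid":
        """Unreduced coarse grid with cardinalities 30·20·15·25 (the
        quarter-million-evaluation configuration)."""
        return cls(
            a=GridAxis(0.7, 1.3, 30),
            b=None,
            c=GridAxis(0.7, 1.3, 15),
            d=GridAxis(-0.3, 0.3, 25),
            b_count=20,
        )


@dataclass
class MatchResult:
    """Fitted transform and achieved distance of one h evaluation."""

    a: float
    b: float
    c: float
    d: float
    g_value: float
    n: int
    stage1_min: float = float("nan")
    stage1_evals: int = 0
    total_evals: int = 0
    degenerate: bool = False


@dataclass
class NormalizationResult:
    zeta: float
    eta: float
    normalized: np.ndarray
    degenerate: bool = False


# ---------------------------------------------------------------------------
# elementary operations


def wrap_probe(j, w: int):
    """Wrap 1-based probe indices cyclically into [1, w]."""
    return (np.asarray(j, dtype=int) - 1) % w + 1


def normalize_window(values: Sequence[float]) -> NormalizationResult:
    """Linear map sending the window extrema to (−0.6, +0.6).

    A constant window cannot be normalized; it maps to all zeros with
    ζ = 0 and the degenerate flag set.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidInputError("normalization needs at least 2 samples")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return NormalizationResult(0.0, 0.0, np.zeros_like(x), degenerate=True)
    zeta = 2.0 * NORM_LEVEL / (hi - lo)
    eta = -NORM_LEVEL - zeta * lo
    return NormalizationResult(zeta, eta, zeta * x + eta)


def _pattern_array(P) -> np.ndarray:
    probes = getattr(P, "probes", P)
    return np.asarray(probes, dtype=float)


def _signal_array(S) -> np.ndarray:
    values = getattr(S, "values", S)
    return np.asarray(values, dtype=float)


def g_distance(P, S, a: float, b: float, c: float, d: float, n: int) -> float:
    """Mean-squared distance between the transformed pattern and the
    trailing n samples of the signal (direct, unnormalized evaluation)."""
    p = _pattern_array(P)
    s = _signal_array(S)
    w, m = p.size, s.size
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if n > m:
        raise InvalidInputError("n exceeds the signal length")
    k = np.arange(n)
    idx = wrap_probe(np.rint(b - a * k), w)
    resid = p[idx - 1] * c + d - s[m - 1 - k]
    return float(np.mean(resid**2))


# ---------------------------------------------------------------------------
# grid evaluation (all four parameters at once)
#
# For fixed (a, b) the transformed pattern samples pv_k are fixed, so g is a
# quadratic polynomial in (c, d) whose coefficients are three moments of pv
# against the reversed signal window.  This evaluates the whole grid exactly
# (same arithmetic as g at every grid point) without a four-deep loop.


def _moments(
    p: np.ndarray, s_rev: np.ndarray, a_vals: np.ndarray, b_vals: np.ndarray
):
    """Per-(a, b) moments of the transformed pattern against the reversed
    signal window: mean, square mean and cross moment."""
    w = p.size
    n = s_rev.size
    k = np.arange(n)
    idx = wrap_probe(
        np.rint(b_vals[None, :, None] - a_vals[:, None, None] * k), w
    )
    pv = p[idx - 1]  # (na, nb, n)
    m1 = pv.mean(axis=2)
    m2 = (pv * pv).mean(axis=2)
    mx = (pv * s_rev).mean(axis=2)
    return m1, m2, mx, float(s_rev.mean()), float((s_rev * s_rev).mean())


def _quad_g(m1, m2, mx, ms, s2, c, d):
    """g as a quadratic in (c, d) given the (a, b) moments (broadcasts)."""
    G = c * c * m2 - 2.0 * c * mx + 2.0 * c * d * m1 + d * d - 2.0 * d * ms + s2
    return np.maximum(G, 0.0)  # clip the tiny negative round-off


def _eval_grid(
    p: np.ndarray,
    s_rev: np.ndarray,
    a_vals: np.ndarray,
    b_vals: np.ndarray,
    c_vals: np.ndarray,
    d_vals: np.ndarray,
) -> np.ndarray:
    m1, m2, mx, ms, s2 = _moments(p, s_rev, a_vals, b_vals)
    c = c_vals[None, None, :, None]
    d = d_vals[None, None, None, :]
    return _quad_g(m1[..., None, None], m2[..., None, None], mx[..., None, None], ms, s2, c, d)


def _prepare(P, S, n: int | None, normalize: bool):
    p = _pattern_array(P)
    s = _signal_array(S)
    w, m = p.size, s.size
    if n is None:
        n = min(m, w)
    if n < 1 or n > m:
        raise InvalidInputError("matched length n out of range")
    s_win = s[m - n :]
    degenerate = False
    if normalize:
        np_res = normalize_window(p)
        ns_res = normalize_window(s_win)
        degenerate = np_res.degenerate or ns_res.degenerate
        p, s_win = np_res.normalized, ns_res.normalized
    return p, s_win[::-1].copy(), w, n, degenerate


def _refined_axis(axis: GridAxis, refine: int) -> np.ndarray:
    """Full-range lattice with the coarse step divided by ``refine``."""
    if axis.count == 1 or axis.step == 0.0:
        return np.array([axis.lo])
    total = (axis.count - 1) * refine + 1
    return np.linspace(axis.lo, axis.hi, total)


def _local_axis(
    axis: GridAxis, center: float, refine: int, span: int | None = None
) -> np.ndarray:
    """Refined lattice around a stage-1 seed: offsets in integer multiples
    of step/refine (so stage 2 stays on the oracle's refined lattice).

    ``span`` refined steps on each side; default keeps the coarse-axis
    cardinality (count points centred on the seed).
    """
    if axis.count == 1 or axis.step == 0.0:
        return np.array([center])
    fine = axis.step / refine
    if span is None:
        offs = (np.arange(axis.count) - axis.count // 2) * fine
    else:
        offs = np.arange(-span, span + 1) * fine
    vals = center + offs
    keep = (vals >= axis.lo - 1e-12) & (vals <= axis.hi + 1e-12)
    return vals[keep]


def h_distance(
    P,
    S,
    grid: MatchGrid | None = None,
    n: int | None = None,
    normalize: bool = True,
) -> Tuple[float, MatchResult]:
    """Two-stage coarse-to-fine minimization of g over the grid.

    Returns the minimum g and the fitted :class:`MatchResult`; the result is
    never above the stage-1 (coarse) minimum.  When ``normalize`` is on,
    both windows are mapped onto [−0.6, 0.6] first, so the fitted c and d
    are expressed in normalized units.
    """
    grid = grid or MatchGrid.default()
    p, s_rev, w, n, degenerate = _prepare(P, S, n, normalize)

    axes = (grid.a, grid.b_axis(w), grid.c, grid.d)
    vals = [ax.values() for ax in axes]
    G1 = _eval_grid(p, s_rev, *vals)
    stage1_evals = G1.size
    flat_order = np.argsort(G1, axis=None, kind="stable")
    i0 = np.unravel_index(flat_order[0], G1.shape)
    best_g = float(G1[i0])
    best = [vals[q][i0[q]] for q in range(4)]
    stage1_min = best_g

    # stage-2 seeds: lowest coarse points, deduplicated by (a, b) adjacency
    seeds: list[tuple] = []
    for flat in flat_order:
        ia, ib, ic, id_ = np.unravel_index(flat, G1.shape)
        if any(max(abs(ia - ja), abs(ib - jb)) < 2 for ja, jb in seeds):
            continue
        seeds.append((ia, ib))
        if len(seeds) >= grid.n_refine_regions:
            break

    total = stage1_evals
    ax_c, ax_d = axes[2], axes[3]
    rc = _refined_axis(ax_c, grid.refine_factor)
    rd = _refined_axis(ax_d, grid.refine_factor)

    # stage 2: (a, b) windows span the full coarse cell around each seed (g
    # is rugged in time scale/shift).  In (c, d) g is an exact
    # positive-definite quadratic, so the unconstrained continuous minimum
    # is a free lower bound per refined (a, b); only (a, b) candidates whose
    # bound beats the incumbent get the full refined (c, d) lattice sweep
    # (branch and bound — exact over the visited windows).
    cand: dict = {}
    span = 2 * grid.refine_factor  # ±2 coarse cells: tiles of adjacent seeds overlap
    for ia, ib in seeds:
        la = _local_axis(axes[0], vals[0][ia], grid.refine_factor, span=span)
        lb = _local_axis(axes[1], vals[1][ib], grid.refine_factor, span=span)
        if la.size == 0 or lb.size == 0:
            continue
        m1, m2, mx, ms, s2 = _moments(p, s_rev, la, lb)
        det = np.maximum(m2 - m1 * m1, 1e-15)
        c_star = (mx - m1 * ms) / det
        d_star = ms - m1 * c_star
        g_lower = _quad_g(m1, m2, mx, ms, s2, c_star, d_star)
        for iaa in range(la.size):
            for ibb in range(lb.size):
                key = (round(float(la[iaa]), 12), round(float(lb[ibb]), 12))
                if key not in cand:
                    total += 1  # the bound is itself one g evaluation
                    cand[key] = (
                        float(g_lower[iaa, ibb]),
                        float(m1[iaa, ibb]),
                        float(m2[iaa, ibb]),
                        float(mx[iaa, ibb]),
                        ms,
                        s2,
                    )

    max_expand = 30  # caps the per-call budget; rarely binding
    expanded = 0
    for (av, bv), (g_lower, m1v, m2v, mxv, msv, s2v) in sorted(
        cand.items(), key=lambda kv: kv[1][0]
    ):
        if g_lower >= best_g or expanded >= max_expand:
            break
        G2 = _quad_g(m1v, m2v, mxv, msv, s2v, rc[:, None], rd[None, :])
        total += G2.size
        expanded += 1
        j = np.unravel_index(np.argmin(G2), G2.shape)
        if float(G2[j]) < best_g:
            best_g = float(G2[j])
            best = [av, bv, rc[j[0]], rd[j[1]]]

    a, b, c, d = (float(v) for v in best)
    res = MatchResult(
        a=a,
        b=b,
        c=c,
        d=d,
        g_value=best_g,
        n=n,
        stage1_min=stage1_min,
        stage1_evals=stage1_evals,
        total_evals=total,
        degenerate=degenerate,
    )
    return best_g, res


def h_oracle(
    P,
    S,
    grid: MatchGrid | None = None,
    n: int | None = None,
    normalize: bool = True,
    max_evals: int = 20_000_000,
) -> Tuple[float, MatchResult]:
    """Exhaustive minimum of g over the fully refined grid (test oracle).

    Every axis is densified to step/refine_factor across its whole range,
    which is the superset of every grid stage 2 can visit; only feasible
    for small grids.
    """
    grid = grid or MatchGrid.default()
    p, s_rev, w, n, degenerate = _prepare(P, S, n, normalize)

    vals = [
        _refined_axis(ax, grid.refine_factor)
        for ax in (grid.a, grid.b_axis(w), grid.c, grid.d)
    ]
    size = int(np.prod([v.size for v in vals]))
    if size > max_evals:
        raise InvalidInputError(f"oracle grid too large ({size} evaluations)")
    G = _eval_grid(p, s_rev, *vals)
    j = np.unravel_index(np.argmin(G), G.shape)
    best = [float(vals[q][j[q]]) for q in range(4)]
    res = MatchResult(
        a=best[0],
        b=best[1],
        c=best[2],
        d=best[3],
        g_value=float(G[j]),
        n=n,
        stage1_evals=size,
        total_evals=size,
        degenerate=degenerate,
    )
    return float(G[j]), res
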