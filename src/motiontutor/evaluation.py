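"""Learning-efficiency parameters (E1–E3) and the statistical battery.

Motion accuracy is judged per position signal as the RMSE between the
signal and its phase-aligned shape pattern,

    RMSE_i = sqrt( (1/n) · Σ_k (s_i^k − p_i^{ind(k)})² ),

with ind(k) obtained from the time-point synchronization.  Three scalar
efficiency parameters summarize a session (all in millimetres):

* **E1** — mean RMSE over a fixed central fraction (0.3–0.9) of the test
  recording;
* **E2** — the same mean RMSE over a 30 s window starting at the longest
  interval the classifier spent uninterruptedly in the correct-execution
  class, making the measure robust to isolated mistakes;
* **E3** — learning progress, E2_test − β·E2_pre with β = 0.25.

Group comparisons follow the classical chain: Shapiro–Wilk normality per
group (critical value by seeded Monte Carlo, since small-sample W tables
are convention-dependent), mean-centered Levene homogeneity, then a
pooled two-sample one-sided Student t.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedStatisticError
from .matching import MatchGrid
from .patterns import Pattern1D
from .signals import MultiSignal, OneDSignal
from .synchronization import aggregate_time_point, time_point_1d

BETA = 0.25  # weight of the pre-learning phase in E3
E1_RANGE = (0.3, 0.9)  # fraction of the test signal entering E1
E2_WINDOW_S = 30.0  # s, fixed E2 evaluation window
MM_PER_M = 1000.0


# ---------------------------------------------------------------------------
# phase alignment over a whole recording


def estimate_tau_series(
    time_patterns: Dict[int, Pattern1D],
    S: MultiSignal,
    grid: MatchGrid | None = None,
    stride: int = 20,
    n_best: int = 3,
) -> np.ndarray:
    """Per-sample circular time point for a whole recording.

    The time point is estimated every ``stride`` samples on the trailing
    window ending there, unwrapped across period boundaries, and linearly
    interpolated in between (slope extrapolation before the first anchor).
    """
    w = next(iter(time_patterns.values())).w
    anchors = list(range(w, S.m + 1, stride))
    if not anchors:
        raise InvalidInputError("recording shorter than one pattern period")
    taus = []
    for stop in anchors:
        win = MultiSignal(
            {
                i: OneDSignal(
                    index=i,
                    values=S[i].values[:stop][-w:],
                    kind=S[i].kind,
                    axis=S[i].axis,
                    sample_rate=S[i].sample_rate,
                )
                for i in time_patterns
                if i in S.signals
            }
        )
        cands = [
            time_point_1d(pat, win[i], grid=grid)
            for i, pat in time_patterns.items()
            if i in win.signals
        ]
        taus.append(aggregate_time_point(cands, w=w, n_best=n_best).tau)

    # unwrap: τ advances ~1 probe per sample, dropping by w at period ends
    taus = np.asarray(taus)
    unwrapped = taus.copy()
    for j in range(1, taus.size):
        while unwrapped[j] < unwrapped[j - 1] - w / 2:
            unwrapped[j] += w * (1 + (unwrapped[j - 1] - unwrapped[j]) // w)
    k = np.arange(S.m)
    tau_full = np.interp(k, np.array(anchors) - 1, unwrapped)
    # back-extrapolate the pre-anchor head at one probe per sample
    head = k < anchors[0] - 1
    tau_full[head] = unwrapped[0] - ((anchors[0] - 1) - k[head])
    return tau_full


# ---------------------------------------------------------------------------
# RMSE and the efficiency parameters


def rmse(
    s: OneDSignal,
    P_shape: Pattern1D,
    tau_series: np.ndarray,
    sample_range: Tuple[int, int] | None = None,
    unit_scale: float = MM_PER_M,
) -> float:
    """Phase-aligned RMSE (mm) of one position signal over a sample range."""
    lo, hi = sample_range if sample_range is not None else (0, s.m)
    if hi <= lo:
        raise InvalidInputError("empty RMSE range")
    k = np.arange(lo, hi)
    w = P_shape.w
    idx = ((np.rint(tau_series[k]).astype(int) - 1) % w) + 1
    resid = s.values[k] - P_shape.probes[idx - 1]
    return float(np.sqrt(np.mean(resid**2)) * unit_scale)


def e1(
    S: MultiSignal,
    shape_patterns: Dict[int, Pattern1D],
    tau_series: np.ndarray,
    frac_range: Tuple[float, float] = E1_RANGE,
) -> Tuple[float, Dict[int, float]]:
    """Mean per-signal RMSE (mm) over the central fraction of the signal."""
    if not shape_patterns:
        raise InvalidInputError("at least one shape pattern required")
    m = S.m
    lo, hi = int(frac_range[0] * m), int(frac_range[1] * m)
    per = {
        i: rmse(S[i], pat, tau_series, sample_range=(lo, hi))
        for i, pat in shape_patterns.items()
    }
    return float(np.mean(list(per.values()))), per


@dataclass
class E2Result:
    value_mm: float
    start_sample: int
    window_samples: int
    truncated: bool
    per_signal: Dict[int, float]


def e2(
    S: MultiSignal,
    shape_patterns: Dict[int, Pattern1D],
    tau_series: np.ndarray,
    labels: Sequence[str],
    alpha_label: str = "c_alpha",
    window_s: float = E2_WINDOW_S,
) -> E2Result:
    """Mean RMSE on the fixed window anchored at the longest correct run.

    ``labels`` assigns a class label to every sample; the window (30 s by
    default) starts where the longest contiguous ``alpha_label`` run
    begins (earliest run wins ties) and is truncated, flagged, at the end
    of the recording.
    """
    labels = np.asarray(labels)
    if labels.size != S.m:
        raise InvalidInputError("labels must cover every sample")
    is_alpha = labels == alpha_label
    if not is_alpha.any():
        raise UndefinedStatisticError(f"no {alpha_label!r} interval in the timeline")
    # longest run of True; earliest on ties
    best_start, best_len, run_start = 0, 0, None
    for k, flag in enumerate(np.append(is_alpha, False)):
        if flag and run_start is None:
            run_start = k
        elif not flag and run_start is not None:
            if k - run_start > best_len:
                best_start, best_len = run_start, k - run_start
            run_start = None
    win = int(round(window_s * S.sample_rate))
    stop = min(best_start + win, S.m)
    per = {
        i: rmse(S[i], pat, tau_series, sample_range=(best_start, stop))
        for i, pat in shape_patterns.items()
    }
    return E2Result(
        value_mm=float(np.mean(list(per.values()))),
        start_sample=best_start,
        window_samples=stop - best_start,
        truncated=stop - best_start < win,
        per_signal=per,
    )


def e3(e2_test: float, e2_pre: float, beta: float = BETA) -> float:
    """Learning progress E3 = E2_test − β·E2_pre (mm)."""
    return float(e2_test - beta * e2_pre)


@dataclass
class EfficiencyReport:
    rmse_per_signal: Dict[int, float]
    e1_mm: float
    e2_mm: Optional[float] = None
    e3_mm: Optional[float] = None
    e1_range: Tuple[int, int] = (0, 0)
    e2_start_sample: Optional[int] = None
    e2_truncated: bool = False


# ---------------------------------------------------------------------------
# group statistics


def group_stats(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and sample (n−1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidInputError("group statistics need n >= 2")
    return float(x.mean()), float(x.std(ddof=1))


@functools.lru_cache(maxsize=32)
def shapiro_critical(
    n: int, alpha: float = 0.05, n_draws: int = 100_000, seed: int = 12345
) -> float:
    """Monte-Carlo lower critical value of the Shapiro–Wilk W statistic.

    Empirical ``alpha`` quantile of W over ``n_draws`` standard-normal
    samples of size n; seeded and cached.  Published small-n tables vary
    by approximation, hence the simulation.
    """
    rng = np.random.default_rng(seed)
    ws = np.empty(n_draws)
    draws = rng.standard_normal((n_draws, n))
    for j in range(n_draws):
        ws[j] = stats.shapiro(draws[j]).statistic
    return float(np.quantile(ws, alpha))


@dataclass
class StatReport:
    """One parameter row of the statistical battery."""

    mean: Dict[int, float]  # method → mean (mm)
    sd: Dict[int, float]
    n: Dict[int, int]
    shapiro_w: Dict[int, float]
    shapiro_crit: float
    levene_stat: float
    levene_crit: float
    t_stat: float
    t_crit: float
    p_one_sided: float
    df: int


def test_battery(
    group1: Sequence[float],
    group2: Sequence[float],
    alpha: float = 0.05,
    sw_draws: int = 20_000,
    sw_seed: int = 12345,
) -> StatReport:
    """Shapiro–Wilk, mean-centered Levene, and one-sided pooled t.

    The t statistic is oriented so that a *positive* value supports
    "group 1 (classification-assisted method) has the smaller mean":
    t = (mean₂ − mean₁)/SE with the pooled variance and df = n₁+n₂−2.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 3 or g2.size < 3:
        raise InvalidInputError("each group needs n >= 3")
    if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
        raise UndefinedStatisticError("both groups have zero variance")

    n1, n2 = g1.size, g2.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t_stat = float((g2.mean() - g1.mean()) / se)
    p = float(stats.t.sf(t_stat, df))

    lev = stats.levene(g1, g2, center="mean")
    # Monte-Carlo S-W critical value needs equal group sizes per call
    sw_crit = shapiro_critical(n1, alpha, sw_draws, sw_seed)

    m1, s1 = group_stats(g1)
    m2, s2 = group_stats(g2)
    return StatReport(
        mean={1: m1, 2: m2},
        sd={1: s1, 2: s2},
        n={1: n1, 2: n2},
        shapiro_w={1: float(stats.shapiro(g1).statistic), 2: float(stats.shapiro(g2).statistic)},
        shapiro_crit=sw_crit,
        levene_stat=float(lev.statistic),
        levene_crit=float(stats.f.ppf(1.0 - alpha, 1, df)),
        t_stat=t_stat,
        t_crit=float(stats.t.ppf(1.0 - alpha, df)),
        p_one_sided=p,
        df=df,
    )


# ---------------------------------------------------------------------------
# bundled participant table


def load_participant_table() -> pd.DataFrame:
    """Per-participant efficiency values of the two taught groups
    (columns: parameter, method, participant, value_mm)."""
    with resources.files("motiontutor.data").joinpath("table3.csv").open() as fh:
        return pd.read_csv(fh)


def battery_report(
    df: pd.DataFrame | None = None,
    alpha: float = 0.05,
    sw_draws: int = 20_000,
    sw_seed: int = 12345,
) -> Dict[str, StatReport]:
    """Run the full battery for every efficiency parameter in a table."""
    if df is None:
        df = load_participant_table()
    out: Dict[str, StatReport] = {}
    for param in sorted(df["parameter"].unique()):
        sub = df[df["parameter"] == param]
        g1 = sub[sub["method"] == 1].sort_values("participant")["value_mm"].to_numpy()
        g2 = sub[sub["method"] == 2].sort_values("participant")["value_mm"].to_numpy()
        out[param] = test_battery(g1, g2, alpha=alpha, sw_draws=sw_draws, sw_seed=sw_seed)
    return out
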