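"""Univariate comparison battery with automatic test routing.

Routing for continuous comparisons follows the study protocol: normality is
assessed per sample with Shapiro-Wilk (on the paired differences for paired
designs) and variance homogeneity with Levene's test; normal data use
Student's or Welch's t-test (paired t for paired designs), non-normal data
use Mann-Whitney U (Wilcoxon signed-rank when paired).  Parametric effects
are mean differences with t-based 95% CIs; non-parametric effects are
median differences with percentile bootstrap CIs (10,000 resamples, paired
resampling by subject or stratified resampling within groups).  Categorical
tables use the exact Freeman-Halton generalization of Fisher's test;
generation-wise entropy comparisons use Kruskal-Wallis with Dunn's post hoc
test and Bonferroni adjustment.  All p-values are two-sided and no
multiplicity correction is applied across morphological comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import lgamma
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from ._rng import substream

ALPHA_ROUTING = 0.05


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class RoutingTrace:
    """The pre-test p-values that determined the routed test."""

    shapiro_p: tuple[float, ...]
    levene_p: float | None
    normal: bool
    equal_variance: bool | None
    note: str = ""


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    effect: float
    ci95: tuple[float, float]
    ci_method: str               # "t_based" | "percentile_bootstrap"
    routing_trace: RoutingTrace

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")
        if self.ci95[0] > self.ci95[1] + 1e-12:
            raise StatsError(f"confidence interval reversed: {self.ci95}")


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def bootstrap_ci(x: np.ndarray, statistic: Callable, y: np.ndarray | None = None,
                 n_resamples: int = 10_000, mode: str = "simple",
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap confidence interval.

    ``statistic`` receives resampled arrays with an ``axis`` keyword
    (``statistic(x, axis=...)`` or ``statistic(x, y, axis=...)`` for
    two-sample modes).  Modes: ``simple`` (one sample), ``paired``
    (subjects resampled jointly, pairs intact), ``stratified`` (each group
    resampled independently).  Deterministic for a fixed seed.
    """
    rng = substream(seed, "bootstrap")
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise StatsError("bootstrap needs at least two observations")
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    if mode == "simple":
        idx = rng.integers(0, x.size, size=(n_resamples, x.size))
        reps = statistic(x[idx], axis=-1)
    elif mode == "paired":
        if y is None or len(y) != x.size:
            raise StatsError("paired mode needs equal-length x and y")
        y = np.asarray(y, dtype=float)
        idx = rng.integers(0, x.size, size=(n_resamples, x.size))
        reps = statistic(x[idx], y[idx], axis=-1)
    elif mode == "stratified":
        if y is None:
            raise StatsError("stratified mode needs two groups")
        y = np.asarray(y, dtype=float)
        if x.size == 0 or y.size == 0:
            raise StatsError("empty stratum")
        ix = rng.integers(0, x.size, size=(n_resamples, x.size))
        iy = rng.integers(0, y.size, size=(n_resamples, y.size))
        reps = statistic(x[ix], y[iy], axis=-1)
    else:
        raise StatsError(f"unknown bootstrap mode {mode!r}")
    lo, hi = np.percentile(reps, [lo_q, hi_q])
    return float(lo), float(hi)


def _median_diff(x, y, axis=-1):
    return np.median(x, axis=axis) - np.median(y, axis=axis)


# --------------------------------------------------------------------------
# routed two-sample comparison
# --------------------------------------------------------------------------

def route_and_compare(x: Sequence[float], y: Sequence[float], paired: bool,
                      alpha: float = ALPHA_ROUTING, n_resamples: int = 10_000,
                      seed: int = 0) -> ComparisonResult:
    """Two-sided comparison of two samples with protocol-faithful routing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise StatsError("each sample needs at least three observations")
    if paired and x.size != y.size:
        raise StatsError("paired samples must have equal length")

    if paired:
        d = x - y
        if np.ptp(d) == 0:  # Shapiro is undefined for constant input
            sh_p, normal = (1.0,), True
        else:
            sh_p = (float(stats.shapiro(d).pvalue),)
            normal = sh_p[0] > alpha
        if normal:
            trace = RoutingTrace(sh_p, None, True, None,
                                 note="paired normality assessed on differences")
            if np.ptp(d) == 0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_rel(x, y)
            n = d.size
            se = d.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.975, n - 1)
            return ComparisonResult("paired_t", float(t_stat), float(p),
                                    float(d.mean()),
                                    (float(d.mean() - tcrit * se), float(d.mean() + tcrit * se)),
                                    "t_based", trace)
        trace = RoutingTrace(sh_p, None, False, None,
                             note="paired non-normal: Wilcoxon signed-rank "
                                  "(protocol names only Mann-Whitney, which does not apply to pairs)")
        w_stat, p = stats.wilcoxon(x, y)
        ci = bootstrap_ci(x, lambda a, b, axis=-1: np.median(a - b, axis=axis),
                          y=y, n_resamples=n_resamples, mode="paired", seed=seed)
        return ComparisonResult("wilcoxon_signed_rank", float(w_stat), float(p),
                                float(np.median(d)), ci, "percentile_bootstrap", trace)

    sh_p = tuple(1.0 if np.ptp(s) == 0 else float(stats.shapiro(s).pvalue)
                 for s in (x, y))
    normal = all(p > alpha for p in sh_p)
    if normal:
        lev_p = float(stats.levene(x, y).pvalue) if (np.ptp(x) or np.ptp(y)) else 1.0
        equal_var = lev_p > alpha
        trace = RoutingTrace(sh_p, lev_p, True, equal_var)
        t_stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
        diff = float(x.mean() - y.mean())
        nx, ny = x.size, y.size
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if equal_var:
            sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
            se = np.sqrt(sp2 * (1 / nx + 1 / ny))
            df = nx + ny - 2
            name = "student_t"
        else:
            se = np.sqrt(vx / nx + vy / ny)
            df = (vx / nx + vy / ny) ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
            name = "welch_t"
        tcrit = stats.t.ppf(0.975, df)
        if se == 0:
            t_stat, p, ci = 0.0, 1.0, (diff, diff)
        else:
            ci = (diff - tcrit * se, diff + tcrit * se)
        return ComparisonResult(name, float(t_stat), float(p), diff,
                                (float(ci[0]), float(ci[1])), "t_based", trace)
    trace = RoutingTrace(sh_p, None, False, None)
    u_stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    ci = bootstrap_ci(x, _median_diff, y=y, n_resamples=n_resamples,
                      mode="stratified", seed=seed)
    return ComparisonResult("mann_whitney_u", float(u_stat), float(p),
                            float(np.median(x) - np.median(y)), ci,
                            "percentile_bootstrap", trace)


# --------------------------------------------------------------------------
# exact r x c categorical test (Freeman-Halton)
# --------------------------------------------------------------------------

def _log_table_prob(flat: Sequence[int], log_const: float, lf: np.ndarray) -> float:
    return log_const - sum(lf[v] for v in flat)


def fisher_exact_rxc(table: Sequence[Sequence[int]], max_tables: float = 2e7,
                     monte_carlo: bool = False, n_draws: int = 1_000_000,
                     seed: int = 0) -> float:
    """Exact Freeman-Halton p-value for an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of tables no more probable than the
    observed one (within a 1e-12 log slack).  For tables whose enumeration
    would exceed ``max_tables`` candidates, a seeded Monte Carlo
    approximation over random tables with fixed margins is available via
    ``monte_carlo=True``; otherwise an error is raised.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise StatsError("table must be a 2-D array of nonnegative integers")
    n = int(t.sum())
    if n == 0:
        raise StatsError("empty table")
    if n > 10_000:
        raise StatsError("table total exceeds 10,000; use a chi-square approximation")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    lf = np.array([lgamma(i + 1) for i in range(n + 1)])
    log_const = float(lf[rows].sum() + lf[cols].sum() - lf[n])
    logp_obs = _log_table_prob(t.ravel(), log_const, lf)

    # crude enumeration bound: product over cells of (min(row, col) + 1)
    bound = 1.0
    for r in rows[:-1]:
        for c in cols[:-1]:
            bound *= min(r, c) + 1
    if bound > max_tables:
        if not monte_carlo:
            raise StatsError(
                f"~{bound:.2g} candidate tables exceed the enumeration limit; "
                "call with monte_carlo=True for a seeded approximation")
        return _fisher_monte_carlo(t, logp_obs, log_const, lf, n_draws, seed)

    r_list = rows.tolist()
    total = 0.0
    slack = 1e-12

    def recurse(row_idx: int, col_rem: np.ndarray, acc: float) -> None:
        nonlocal total
        if row_idx == len(r_list) - 1:
            # last row forced by the column margins
            lp = acc - lf[col_rem].sum()
            if lp <= logp_obs + slack:
                total += np.exp(lp)
            return
        target = r_list[row_idx]
        suffix_rows = sum(r_list[row_idx + 1:])
        for cells in _row_compositions(target, col_rem, suffix_rows):
            recurse(row_idx + 1, col_rem - cells, acc - lf[cells].sum())

    recurse(0, cols.copy(), log_const)
    return float(min(total, 1.0))


def _row_compositions(target: int, col_rem: np.ndarray, suffix_rows: int):
    """All nonnegative integer rows summing to ``target`` within column margins."""
    c = len(col_rem)

    def rec(j: int, remaining: int, prefix: list[int]):
        if j == c - 1:
            if 0 <= remaining <= col_rem[j]:
                yield np.array(prefix + [remaining], dtype=np.int64)
            return
        tail_cap = int(col_rem[j + 1:].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(int(col_rem[j]), remaining)
        for v in range(lo, hi + 1):
            yield from rec(j + 1, remaining - v, prefix + [v])

    yield from rec(0, target, [])


def _fisher_monte_carlo(t: np.ndarray, logp_obs: float, log_const: float,
                        lf: np.ndarray, n_draws: int, seed: int) -> float:
    rng = substream(seed, "fisher_mc")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    row_labels = np.repeat(np.arange(len(rows)), rows)
    col_labels = np.repeat(np.arange(len(cols)), cols)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(col_labels)
        sim = np.zeros_like(t)
        np.add.at(sim, (row_labels, perm), 1)
        if _log_table_prob(sim.ravel(), log_const, lf) <= logp_obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_draws + 1)


# --------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# --------------------------------------------------------------------------

def kruskal_dunn(groups: Sequence[Sequence[float]]) -> tuple[float, dict[tuple[int, int], float]]:
    """Kruskal-Wallis across >= 3 groups plus Bonferroni-adjusted Dunn pairs.

    Returns the KW p-value and a map (i, j) -> adjusted two-sided p for every
    group pair, using pooled-rank z statistics with tie correction.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise StatsError("kruskal_dunn needs >= 3 groups; use route_and_compare for two")
    if any(g.size < 2 for g in groups):
        raise StatsError("every group needs at least two observations")
    kw_p = float(stats.kruskal(*groups).pvalue)

    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    n = pooled.size
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n - 1))
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    adjusted: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        adjusted[(i, j)] = float(min(1.0, p * n_pairs))
    return kw_p, adjusted


# --------------------------------------------------------------------------
# mouth-opening correlation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    method: str
    coefficient: float
    p_value: float
    ci95: tuple[float, float]
    undefined: bool = False


def delta_d_correlation(delta_d: Sequence[float], metric: Sequence[float],
                        alpha: float = ALPHA_ROUTING, n_resamples: int = 10_000,
                        seed: int = 0) -> CorrelationResult:
    """Correlation between mouth-opening extent and an airway metric.

    Pearson (with Fisher-z CI) when both variables pass Shapiro-Wilk,
    otherwise Spearman (with a percentile-bootstrap CI over subjects).
    Constant inputs are flagged as an undefined correlation.
    """
    x = np.asarray(delta_d, dtype=float)
    y = np.asarray(metric, dtype=float)
    if x.size != y.size:
        raise StatsError("delta_d and metric must have equal length")
    if x.size < 4:
        raise StatsError("correlation needs at least four observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult("undefined", float("nan"), float("nan"),
                                 (float("nan"), float("nan")), undefined=True)
    normal = (stats.shapiro(x).pvalue > alpha) and (stats.shapiro(y).pvalue > alpha)
    n = x.size
    if normal:
        r, p = stats.pearsonr(x, y)
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
        return CorrelationResult("pearson", float(r), float(p), ci)
    rho, p = stats.spearmanr(x, y)
    rng = substream(seed, "spearman_ci")
    idx = rng.integers(0, n, size=(n_resamples, n))
    reps = np.empty(n_resamples)
    for b in range(n_resamples):
        reps[b] = stats.spearmanr(x[idx[b]], y[idx[b]]).statistic
    lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    return CorrelationResult("spearman", float(rho), float(p), (float(lo), float(hi)))


# --------------------------------------------------------------------------
# cohort comparison tables
# --------------------------------------------------------------------------

def comparison_tables(metrics_df, n_resamples: int = 10_000, seed: int = 0):
    """The full univariate battery on a morphometry summary table.

    For each metric (means and CVs): paired closed-vs-open over all analyzed
    participants, and unpaired male-vs-female and symptomatic-vs-asymptomatic
    contrasts within each mouth position.  Returns one tidy DataFrame.
    """
    import pandas as pd
    from .morphometry import FRAME_METRIC_NAMES

    df = metrics_df[~metrics_df["osa_excluded"]].copy()
    cv_names = [f"{m}_cv" for m in FRAME_METRIC_NAMES
                if m not in ("total_length_cm", "epiglottic_length_cm")]
    metric_names = list(FRAME_METRIC_NAMES) + cv_names
    closed = df[df["position"] == "closed"].set_index("participant").sort_index()
    open_ = df[df["position"] == "open"].set_index("participant").sort_index()
    rows = []
    for im, metric in enumerate(metric_names):
        res = route_and_compare(open_[metric].to_numpy(), closed[metric].to_numpy(),
                                paired=True, n_resamples=n_resamples,
                                seed=seed + im)
        rows.append({"metric": metric, "contrast": "open_vs_closed",
                     "position": "both", **_result_row(res)})
        for position, sub in (("closed", closed), ("open", open_)):
            for contrast, mask_col, level in (("male_vs_female", "sex", "male"),
                                              ("symptomatic_vs_asymptomatic",
                                               "symptomatic", True)):
                a = sub.loc[sub[mask_col] == level, metric].to_numpy()
                b = sub.loc[sub[mask_col] != level, metric].to_numpy()
                res = route_and_compare(a, b, paired=False,
                                        n_resamples=n_resamples, seed=seed + im)
                rows.append({"metric": metric, "contrast": contrast,
                             "position": position, **_result_row(res)})
    return pd.DataFrame(rows)


def _result_row(res: ComparisonResult) -> dict:
    return {"test": res.test_name, "statistic": res.statistic,
            "p_value": res.p_value, "effect": res.effect,
            "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
            "ci_method": res.ci_method,
            "shapiro_p": ";".join(f"{p:.4g}" for p in res.routing_trace.shapiro_p),
            "levene_p": res.routing_trace.levene_p}
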