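"""Screening statistics: plate QC (Z'), hit calling, dose-response EC50
fits, kinetic summaries, and group comparisons.

The assay's primary readout is per-well percent NETotic. A screen is
judged by the Z' factor

    Z' = 1 - 3 (sigma_p + sigma_n) / |mu_p - mu_n|

between stimulated positive controls and vehicle negatives (sample
standard deviations). Compounds are *active* when they keep the NETotic
percentage below 50 (the induction plateau of ~70% minus a 30%-reduction
margin) and *strong* below 10. Dose-response curves use the four-parameter
logistic R(c) = bottom + (top - bottom) / (1 + (c/EC50)^h). Kinetic traces
(cytosolic ROS fold-change, TMRM accumulation) are summarized by an
exponential-approach fit: plateau, peak fold, and the first sampled time
reaching 95% of the plateau. Group comparisons follow one-way ANOVA with
Dunnett-vs-control post-hoc decisions whose critical values come from a
seeded Monte Carlo of the multivariate-t null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from nethcs.synthetic_imaging import KineticTrace

ACTIVE_THRESHOLD_PCT = 50.0   # ~70% induction minus a 30% reduction margin
STRONG_THRESHOLD_PCT = 10.0
STEADY_STATE_FRACTION = 0.95  # "steady state" = first time at 95% of plateau
DUNNETT_MC_DRAWS = 100_000


# ---------------------------------------------------------------------------
# Z' factor


@dataclass
class ZPrimeResult:
    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    z_prime: float | None   # None when the arms do not separate
    failed: bool = False


def zprime(pos: Sequence[float], neg: Sequence[float]) -> ZPrimeResult:
    """Z' screening-window statistic from control well readouts.

    Uses sample (n-1) standard deviations. When the arm means coincide the
    statistic is undefined and the result is flagged failed rather than
    returning a number.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 wells per control arm")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    sd_p = float(pos.std(ddof=1))
    sd_n = float(neg.std(ddof=1))
    if mu_p == mu_n:
        return ZPrimeResult(mu_p, sd_p, mu_n, sd_n, None, failed=True)
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return ZPrimeResult(mu_p, sd_p, mu_n, sd_n, float(z))


# ---------------------------------------------------------------------------
# Hit calling


@dataclass
class HitCall:
    compound_id: str
    pct_netotic: float
    active: bool
    strong: bool


def call_hits(
    compound_pct: Mapping[str, float] | Sequence[tuple[str, float]],
    active_threshold: float = ACTIVE_THRESHOLD_PCT,
    strong_threshold: float = STRONG_THRESHOLD_PCT,
) -> list[HitCall]:
    """Flag compounds by their (replicate-averaged) percent NETotic.

    ``active`` means strictly below ``active_threshold``; ``strong`` means
    strictly below ``strong_threshold`` (strong implies active for the
    default thresholds). Thresholds are configurable; the defaults encode
    an induction plateau of ~70% and a 30%-reduction activity margin.
    """
    items = compound_pct.items() if isinstance(compound_pct, Mapping) else compound_pct
    calls = []
    for cid, pct in items:
        pct = float(pct)
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"{cid}: pct_netotic {pct} outside [0, 100]")
        calls.append(HitCall(
            compound_id=str(cid), pct_netotic=pct,
            active=pct < active_threshold, strong=pct < strong_threshold,
        ))
    return calls


def aggregate_replicates(wells: Sequence[Mapping], by: str = "compound_id") -> dict[str, float]:
    """Arithmetic mean of pct_netotic per compound across replicate wells."""
    acc: dict[str, list[float]] = {}
    for w in wells:
        acc.setdefault(str(w[by]), []).append(float(w["pct_netotic"]))
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# Four-parameter logistic dose-response


@dataclass
class DoseResponseFit:
    """4PL fit; ``ec50_um`` is None for degenerate or failed fits."""

    bottom: float | None
    top: float | None
    ec50_um: float | None
    hill_coef: float | None
    residuals: np.ndarray | None
    converged: bool
    degenerate: bool = False
    extrapolated: bool = False
    covariance: np.ndarray | None = None


def four_pl(c, bottom, top, ec50, hill):
    """R(c) = bottom + (top - bottom) / (1 + (c/ec50)^hill); R(0) = top."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        log_ratio = np.where(c > 0, hill * (np.log(c) - math.log(ec50)), -np.inf)
    ratio = np.exp(np.clip(log_ratio, -700.0, 700.0))
    ratio = np.where(c > 0, ratio, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_dose_response(
    concentrations: Sequence[float],
    responses: Sequence[float],
    weights: Sequence[float] | None = None,
    degenerate_span: float = 1e-6,
) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start initialization.

    Requires >= 4 distinct concentrations (zero allowed: it anchors the
    top). EC50 is fitted on a log scale from a grid of starts spanning the
    tested range; the best converged start wins, and an EC50 outside
    [0.1 x min positive c, 10 x max c] is flagged extrapolated. Flat data
    (response span below ``degenerate_span`` x |mean|, or a fitted
    top ~ bottom) yields a degenerate fit with EC50 absent.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and responses must align")
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    w = np.ones_like(r) if weights is None else np.asarray(weights, dtype=float)

    span = float(r.max() - r.min())
    if span <= degenerate_span * max(1.0, abs(float(r.mean()))):
        return DoseResponseFit(float(r.mean()), float(r.mean()), None, None,
                               r - r.mean(), converged=True, degenerate=True)

    cpos = c[c > 0]
    log_starts = np.linspace(math.log(cpos.min() / 3), math.log(cpos.max() * 3), 7)
    hill_starts = (0.5, 1.0, 2.0, 4.0)

    def residual(p):
        bottom, top, log_ec50, log_hill = p
        pred = four_pl(c, bottom, top, math.exp(log_ec50), math.exp(log_hill))
        return (pred - r) * np.sqrt(w)

    best = None
    for ls in log_starts:
        for hs in hill_starts:
            p0 = (float(r.min()), float(r.max()), ls, math.log(hs))
            try:
                sol = optimize.least_squares(residual, p0, method="lm", max_nfev=2000)
            except Exception:  # noqa: BLE001 - a failed start is just skipped
                continue
            if not sol.success:
                continue
            cost = float(sol.cost)
            if best is None or cost < best.cost:
                best = sol
    if best is None:
        return DoseResponseFit(None, None, None, None, None, converged=False)

    bottom, top, log_ec50, log_hill = best.x
    ec50 = math.exp(log_ec50)
    hill = math.exp(log_hill)
    if abs(top - bottom) <= max(1e-8, 1e-6 * max(abs(top), abs(bottom), 1.0)):
        return DoseResponseFit(float(bottom), float(top), None, None,
                               best.fun, converged=True, degenerate=True)
    extrapolated = not (0.1 * cpos.min() <= ec50 <= 10.0 * cpos.max())
    # parameter covariance from the Jacobian at the optimum
    try:
        jtj = best.jac.T @ best.jac
        dof = max(1, len(r) - 4)
        cov = np.linalg.inv(jtj) * 2 * best.cost / dof
    except np.linalg.LinAlgError:
        cov = None
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), ec50_um=float(ec50),
        hill_coef=float(hill), residuals=best.fun, converged=True,
        extrapolated=extrapolated, covariance=cov,
    )


# ---------------------------------------------------------------------------
# Kinetic summaries


@dataclass
class KineticSummary:
    peak_fold: float
    plateau: float
    t_steady_min: float | None   # None = never reached within the trace
    initial_slope: float | None
    final_ratio_vs_baseline: float | None
    fit_converged: bool


def _fit_exponential_approach(t: np.ndarray, v: np.ndarray):
    """Fit v(t) = v0 + (plateau - v0)(1 - exp(-t/tau)); None on failure."""
    v0_guess = float(v[0])
    plateau_guess = float(np.mean(v[-3:]))
    tau_guess = max(1.0, float(t[-1]) / 4)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda tt, v0, plateau, tau: v0 + (plateau - v0) * (1 - np.exp(-tt / tau)),
                t, v, p0=(v0_guess, plateau_guess, tau_guess), maxfev=5000,
            )
        if popt[2] <= 0:
            return None
        return popt
    except (RuntimeError, optimize.OptimizeWarning):
        return None


def summarize_kinetics(
    trace: KineticTrace,
    baseline: KineticTrace | None = None,
) -> KineticSummary:
    """Summarize a kinetic time course.

    The plateau comes from an exponential-approach fit (mean of the last
    three samples when the fit fails). ``peak_fold`` is the maximum trace
    value divided by the value at t0, or by the baseline trace's mean when
    one is given. ``t_steady_min`` is the first *sampled* time at which
    the trace reaches 95% of the plateau. For accumulation traces the
    initial slope (plateau - v0)/tau and the final-value ratio against the
    baseline trace are also reported.
    """
    t, v = trace.times, trace.values
    if t.size < 5:
        raise ValueError("need at least 5 timepoints")
    if t[0] != 0:
        raise ValueError("trace must include t = 0")

    popt = _fit_exponential_approach(t, v)
    if popt is not None:
        v0, plateau, tau = (float(x) for x in popt)
        slope = (plateau - v0) / tau
        converged = True
    else:
        plateau = float(np.mean(v[-3:]))
        slope = None
        converged = False

    denom = float(np.mean(baseline.values)) if baseline is not None else float(v[0])
    if denom == 0:
        raise ValueError("zero reference value for fold-change")
    peak_fold = float(v.max()) / denom

    reached = np.nonzero(v >= STEADY_STATE_FRACTION * plateau)[0]
    t_steady = float(t[reached[0]]) if reached.size else None

    final_ratio = None
    if baseline is not None:
        if baseline.values[-1] == 0:
            raise ValueError("zero final baseline value")
        final_ratio = float(v[-1] / baseline.values[-1])
    return KineticSummary(
        peak_fold=peak_fold, plateau=plateau, t_steady_min=t_steady,
        initial_slope=slope, final_ratio_vs_baseline=final_ratio,
        fit_converged=converged,
    )


# ---------------------------------------------------------------------------
# ANOVA + Dunnett-vs-control


@dataclass
class GroupComparison:
    group: str
    mean_diff: float
    t_statistic: float
    p_adjusted: float
    reject: bool


@dataclass
class GroupStatsResult:
    anova_f: float
    anova_p: float
    dunnett_critical: float
    comparisons: list[GroupComparison]
    normality_warnings: dict[str, float] = field(default_factory=dict)


@lru_cache(maxsize=64)
def _dunnett_critical(
    sizes: tuple[int, ...], n_control: int, alpha: float,
    n_draws: int, seed: int,
) -> tuple[float, tuple[float, ...]]:
    """Monte Carlo (1-alpha) quantile of max |t_i| under the multivariate-t
    null for comparisons of k groups against a shared control.

    Returns the critical value plus the sorted null sample of max |t| (as
    a tuple) for adjusted-p evaluation.
    """
    rng = np.random.default_rng(seed)
    k = len(sizes)
    df = n_control + sum(sizes) - (k + 1)
    z0 = rng.standard_normal(n_draws) / math.sqrt(n_control)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    tmax = np.zeros(n_draws)
    for n_i in sizes:
        zi = rng.standard_normal(n_draws) / math.sqrt(n_i)
        ti = np.abs(zi - z0) / (s * math.sqrt(1 / n_i + 1 / n_control))
        tmax = np.maximum(tmax, ti)
    tmax.sort()
    crit = float(np.quantile(tmax, 1 - alpha))
    return crit, tuple(tmax[:: max(1, n_draws // 20000)])


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    control: str,
    alpha: float = 0.05,
    mc_draws: int = DUNNETT_MC_DRAWS,
    mc_seed: int = 12345,
) -> GroupStatsResult:
    """One-way ANOVA plus Dunnett-vs-control decisions.

    Critical values come from a seeded Monte Carlo of the multivariate-t
    null (``mc_draws`` draws, cached per design), so decisions are exactly
    reproducible. A Kolmogorov-Smirnov normality check per group (against
    a normal with the group's moments) is reported as a warning-level
    p-value map, never used as a gate.
    """
    if control not in values_by_group:
        raise KeyError(f"control group {control!r} absent")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")

    anova_f, anova_p = stats.f_oneway(*groups.values())
    if math.isnan(anova_f):  # identical constant groups
        anova_f, anova_p = 0.0, 1.0

    others = [k for k in groups if k != control]
    ctrl = groups[control]
    n0 = ctrl.size
    sizes = tuple(groups[k].size for k in others)
    df = n0 + sum(sizes) - (len(others) + 1)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups.values())
    s2 = ss_within / df if df > 0 else 0.0

    crit, null_sample = _dunnett_critical(sizes, n0, alpha, mc_draws, mc_seed)
    null_arr = np.asarray(null_sample)

    comparisons = []
    for k in others:
        g = groups[k]
        diff = float(g.mean() - ctrl.mean())
        se = math.sqrt(s2 * (1 / g.size + 1 / n0)) if s2 > 0 else 0.0
        tstat = diff / se if se > 0 else 0.0
        p_adj = float((null_arr >= abs(tstat)).mean()) if null_arr.size else 1.0
        comparisons.append(GroupComparison(
            group=k, mean_diff=diff, t_statistic=float(tstat),
            p_adjusted=p_adj, reject=abs(tstat) > crit,
        ))

    normality = {}
    for k, g in groups.items():
        sd = g.std(ddof=1)
        if sd > 0:
            normality[k] = float(stats.kstest((g - g.mean()) / sd, "norm").pvalue)
        else:
            normality[k] = 1.0
    return GroupStatsResult(
        anova_f=float(anova_f), anova_p=float(anova_p),
        dunnett_critical=crit, comparisons=comparisons,
        normality_warnings=normality,
    )
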