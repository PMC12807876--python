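"""Gated hypothesis testing, normalization schemes and rate estimation.

The testing decision tree mirrors the source analysis exactly: Shapiro-Wilk
normality on every group at alpha = 0.05; if all pass, Levene's test routes
two-group comparisons to Student's t (equal variance) or Welch's t, and
multi-group comparisons to Welch's ANOVA with a Games-Howell post hoc;
otherwise Mann-Whitney U (two groups) or Kruskal-Wallis with Dunn's post
hoc.  All tests are two-tailed; significance stars at 0.05 / 0.01 / 0.001 /
0.0001.  Adsorption rates come from pooled OLS over the linear window
(t = 4-5 min), re-estimated with HC3 robust standard errors when a
Breusch-Pagan or residual Shapiro-Wilk diagnostic fires at p < 0.05; the
Durbin-Watson statistic is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson

from .errors import ValidationError

__all__ = [
    "StatResult",
    "RateFit",
    "normalize_measure",
    "gated_two_group",
    "gated_multi_group",
    "dunn_test",
    "ols_rate",
    "pearson_fit",
    "area_to_radius",
    "significance_stars",
]

NORMALIZATION_SCHEMES = ("to_t0", "to_iso_control", "to_reference_signal", "to_ca0_pvp_control")


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: List[int]
    gate_trace: Dict[str, float]     # Shapiro-Wilk / Levene p-values that led here
    posthoc: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


@dataclass
class RateFit:
    slope: float                     # adsorption rate per unit time
    intercept: float
    stderr: float
    ci_low: float
    ci_high: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    robust_se_used: bool
    diagnostics: Dict[str, float]    # breusch_pagan_p, shapiro_resid_p, durbin_watson
    n: int

    def __post_init__(self) -> None:
        assert self.ci_low <= self.slope <= self.ci_high


def significance_stars(p: float) -> str:
    """Star annotation at the 0.05 / 0.01 / 0.001 / 0.0001 thresholds."""
    for thr, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p <= thr:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_measure(
    values: Sequence[float] | np.ndarray,
    scheme: str,
    reference: Optional[float] = None,
) -> Tuple[np.ndarray, Dict[str, str]]:
    """Element-wise normalization under one of the named schemes.

    ``to_t0`` divides by the first element (time-lapse baseline);
    ``to_iso_control``, ``to_reference_signal`` and ``to_ca0_pvp_control``
    divide by the supplied reference (isosmotic control mean, 1 uM protein
    solution signal, and the 0 uM Ca2+ / 2.5% PVP balanced control mean
    respectively).  The scheme is recorded in the returned metadata:
    values normalized under different schemes are not directly comparable.
    """
    if scheme not in NORMALIZATION_SCHEMES:
        raise ValidationError(f"unknown normalization scheme {scheme!r}")
    x = np.asarray(values, dtype=float)
    if scheme == "to_t0":
        if x.size == 0:
            raise ValidationError("cannot normalize an empty series")
        ref = x.flat[0]
    else:
        if reference is None:
            raise ValidationError(f"scheme {scheme!r} requires a reference value")
        ref = float(reference)
    if not np.isfinite(ref) or ref <= 0:
        raise ValidationError(f"normalization reference must be positive, got {ref}")
    return x / ref, {"scheme": scheme}


# ---------------------------------------------------------------------------
# gated hypothesis tests
# ---------------------------------------------------------------------------

def _gate_normality(groups: Sequence[np.ndarray], alpha: float) -> Tuple[bool, Dict[str, float]]:
    trace: Dict[str, float] = {}
    all_normal = True
    for i, g in enumerate(groups):
        p = float(sps.shapiro(g).pvalue)
        trace[f"shapiro_p_group{i}"] = p
        if p < alpha:
            all_normal = False
    return all_normal, trace


def gated_two_group(a, b, alpha: float = 0.05) -> StatResult:
    """Two-group comparison routed by the normality/variance gate.

    Both groups normal (Shapiro-Wilk p >= alpha) -> Levene: equal variance
    gives Student's t, unequal gives Welch's t; any non-normal group gives
    Mann-Whitney U.  All two-tailed.  The gate trace records every p-value
    that determined the route.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError(f"each group needs n >= 3, got {len(a)} and {len(b)}")
    normal, trace = _gate_normality([a, b], alpha)
    if normal:
        lev_p = float(sps.levene(a, b).pvalue)
        trace["levene_p"] = lev_p
        if lev_p >= alpha:
            res = sps.ttest_ind(a, b, equal_var=True)
            name = "student_t"
        else:
            res = sps.ttest_ind(a, b, equal_var=False)
            name = "welch_t"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        # identical samples give a degenerate U; report p = 1 (no evidence)
        if np.array_equal(np.sort(a), np.sort(b)) and len(a) == len(b):
            stat, p, name = float(len(a) * len(b) / 2.0), 1.0, "mann_whitney_u"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            stat, p, name = float(res.statistic), float(res.pvalue), "mann_whitney_u"
    return StatResult(test_name=name, statistic=stat, p_value=min(p, 1.0),
                      n_per_group=[len(a), len(b)], gate_trace=trace)


def dunn_test(groups: Sequence[np.ndarray], adjust: Optional[str] = None) -> pd.DataFrame:
    """Dunn's rank-based post hoc test after Kruskal-Wallis.

    Pairwise z statistics on mean ranks with the tie correction
    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t)/(12(N-1)) over tie groups.  ``adjust`` selects an
    optional multiplicity correction ('bonferroni' or 'holm'); none by
    default.
    """
    groups = [np.asarray(g, float) for g in groups]
    ns = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, start = [], 0
    for n in ns:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / ns[i] + 1.0 / ns[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": i, "group_b": j, "z": float(z), "p_unadjusted": float(p)})
    df = pd.DataFrame(rows)
    m = len(df)
    if adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(df["p_unadjusted"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(df["p_unadjusted"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_unadjusted"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adjusted"] = adj
    else:
        df["p_adjusted"] = df["p_unadjusted"]
    df["stars"] = df["p_adjusted"].map(significance_stars)
    return df


def gated_multi_group(groups: Sequence, alpha: float = 0.05,
                      dunn_adjust: Optional[str] = None) -> StatResult:
    """>= 3 group comparison routed by the normality gate.

    All groups normal -> Welch's ANOVA + Games-Howell post hoc (the
    equal-variance assumption is not relied on); otherwise Kruskal-Wallis
    + Dunn's post hoc.  The post hoc table carries significance stars.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 3:
        raise ValidationError(f"need >= 3 groups, got {len(groups)}")
    for i, g in enumerate(groups):
        if len(g) < 3:
            raise ValidationError(f"group {i} needs n >= 3, got {len(g)}")
        if np.ptp(g) == 0:
            raise ValidationError(f"group {i} has zero variance; omnibus tests are undefined")
    normal, trace = _gate_normality(groups, alpha)
    trace["levene_p"] = float(sps.levene(*groups).pvalue)
    long = pd.DataFrame({
        "value": np.concatenate(groups),
        "group": np.concatenate([[str(i)] * len(g) for i, g in enumerate(groups)]),
    })
    if normal:
        aov = pg.welch_anova(data=long, dv="value", between="group")
        stat, p = float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])
        ph = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        ph = ph.rename(columns={"A": "group_a", "B": "group_b", "pval": "p_adjusted"})
        ph["stars"] = ph["p_adjusted"].map(significance_stars)
        name = "welch_anova+games_howell"
    else:
        res = sps.kruskal(*groups)
        stat, p = float(res.statistic), float(res.pvalue)
        ph = dunn_test(groups, adjust=dunn_adjust)
        name = "kruskal_wallis+dunn"
    return StatResult(test_name=name, statistic=stat, p_value=min(p, 1.0),
                      n_per_group=[len(g) for g in groups], gate_trace=trace,
                      posthoc=ph)


# ---------------------------------------------------------------------------
# adsorption-rate OLS with diagnostics
# ---------------------------------------------------------------------------

def ols_rate(
    series: pd.DataFrame,
    window: Tuple[float, float] = (4.0, 5.0),
    time_col: str = "time_min",
    value_col: str = "S",
) -> RateFit:
    """Pooled OLS of adsorption signal on time within the linear window.

    All cells' points inside [window[0], window[1]] are pooled and S is
    regressed on time.  Breusch-Pagan (heteroscedasticity) and Shapiro-Wilk
    (residual normality) diagnostics gate an HC3 robust-SE re-estimate;
    with exactly two distinct time points the linearity checks do not
    apply but the diagnostics are still computed on residuals.  The
    Durbin-Watson statistic is reported.
    """
    t = series[time_col].to_numpy(float)
    y = series[value_col].to_numpy(float)
    sel = (t >= window[0]) & (t <= window[1]) & np.isfinite(y)
    t, y = t[sel], y[sel]
    if len(np.unique(t)) < 2:
        raise ValidationError("need >= 2 distinct time points inside the window")
    if np.ptp(y) == 0:
        raise ValidationError("response has zero variance inside the window")
    X = sm.add_constant(t)
    model = sm.OLS(y, X).fit()
    resid = model.resid
    bp_p = float(het_breuschpagan(resid, X)[1])
    if np.ptp(resid) == 0:
        sw_p = 1.0
    else:
        sw_p = float(sps.shapiro(resid).pvalue)
    dw = float(durbin_watson(resid))
    robust = bp_p < 0.05 or sw_p < 0.05
    if robust:
        model = sm.OLS(y, X).fit(cov_type="HC3")
    ci = model.conf_int()
    return RateFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        stderr=float(model.bse[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        p_value=float(model.pvalues[1]),
        robust_se_used=robust,
        diagnostics={"breusch_pagan_p": bp_p, "shapiro_resid_p": sw_p, "durbin_watson": dw},
        n=len(y),
    )


# ---------------------------------------------------------------------------
# correlation and small derived quantities
# ---------------------------------------------------------------------------

def pearson_fit(x, y) -> Dict[str, float]:
    """Pearson r with two-tailed p plus the OLS line and its 95% CI band.

    Returns slope/intercept of the least-squares line and the band
    half-width parameters (slope and intercept CIs).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3 or len(x) != len(y):
        raise ValidationError(f"need >= 3 paired values, got {len(x)} and {len(y)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    X = sm.add_constant(x)
    model = sm.OLS(y, X).fit()
    ci = model.conf_int(alpha=0.05)
    return {
        "r": float(r), "p": float(p), "n": len(x),
        "slope": float(model.params[1]), "intercept": float(model.params[0]),
        "slope_ci_low": float(ci[1][0]), "slope_ci_high": float(ci[1][1]),
        "intercept_ci_low": float(ci[0][0]), "intercept_ci_high": float(ci[0][1]),
    }


def area_to_radius(polygon_area: float) -> float:
    """Equivalent circular radius r = sqrt(A / pi) of a polygon area (um^2)."""
    if polygon_area < 0:
        raise ValidationError(f"area must be non-negative, got {polygon_area}")
    return float(np.sqrt(polygon_area / np.pi))
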