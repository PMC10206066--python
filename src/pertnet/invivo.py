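"""Summary-statistics analysis of the in-vivo biochemistry panel.

Works entirely from published per-group summaries (mean, SEM, n) of the
rat study — fasting serum glucose, lipid panel, HbA1c, insulin, TBARS —
rather than per-animal raw data:

* Friedewald's formula estimates LDL cholesterol from the lipid panel,
  LDL = TC - (HDL + TG/5), all in mg/dl.
* Percent change between group means (positive = reduction vs reference).
* One-way ANOVA reconstructed exactly from (mean, SEM, n): the group SD
  is sqrt(n)*SEM, so the within- and between-group sums of squares — and
  hence F — are algebraically identical to the raw-data ANOVA.
* Dunnett's multiple-comparison test of each treatment against one
  control, using the equicorrelated multivariate-t critical value
  (correlation 1/2 at equal n), computed by numerical integration over
  the shared control variate and the pooled-SD chi variable.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


@dataclass(frozen=True)
class GroupSummary:
    """One treatment group's published summary for one parameter."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)


@dataclass(frozen=True)
class AnovaSummaryResult:
    f_stat: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    p_value: float


@dataclass(frozen=True)
class DunnettComparison:
    treatment: str
    control: str
    difference: float
    ci_low: float
    ci_high: float
    adjusted_p: float
    critical_value: float


def friedewald_ldl(tc: float, tg: float, hdl: float) -> float:
    """LDL = TC - (HDL + TG/5), mg/dl.

    The formula is unreliable above TG = 400 mg/dl; that regime is
    warned about, not rejected, since published panels may still use it.
    """
    if min(tc, tg, hdl) < 0:
        raise ValueError("lipid panel values must be nonnegative")
    if tg > 400:
        import warnings

        warnings.warn("Friedewald formula is unreliable for TG > 400 mg/dl")
    return tc - (hdl + tg / 5.0)


def percent_change(treated_mean: float, reference_mean: float) -> float:
    """100 * (reference - treated) / reference; positive = reduction."""
    if reference_mean == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (reference_mean - treated_mean) / reference_mean


def anova_from_summary(groups: list[GroupSummary]) -> AnovaSummaryResult:
    """One-way ANOVA reconstructed from per-group (mean, SEM, n).

    SS_within = sum (n_i - 1) * sd_i^2 with sd_i = sqrt(n_i) * sem_i;
    SS_between uses the n-weighted grand mean.  Identical to the
    raw-data ANOVA when summaries come from raw data.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    df_between = len(groups) - 1
    df_within = int(n.sum()) - len(groups)
    grand = float((n * means).sum() / n.sum())
    ms_between = float((n * (means - grand) ** 2).sum() / df_between)
    ms_within = float(((n - 1) * sds**2).sum() / df_within)
    if ms_within == 0:
        if ms_between == 0:
            return AnovaSummaryResult(0.0, df_between, df_within, 0.0, 0.0, 1.0)
        raise ZeroDivisionError(
            "all SEMs are zero with unequal means: F is undefined"
        )
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaSummaryResult(f, df_between, df_within, ms_between, ms_within, p)


# ---------------------------------------------------------------------------
# Dunnett single-step machinery
#
# With control group 0 and treatments i = 1..k sharing a pooled variance
# estimate on df degrees of freedom, the test statistics can be written
# T_i = (a_i Z_i - b_i Z_0) / U with independent standard normals Z and
# U = s/sigma ~ chi_df/sqrt(df), where a_i = sqrt(n0/(n0+n_i)) and
# b_i = sqrt(n_i/(n0+n_i)) (a_i^2 + b_i^2 = 1).  Conditioning on Z_0 and
# U factorizes the joint two-sided probability into a product, leaving a
# smooth double integral evaluated by Gauss quadrature.


def _joint_prob(c: float, b: np.ndarray, df: int, n_z: int = 64, n_u: int = 96) -> float:
    """P(max_i |T_i| <= c) for the equicorrelated multivariate t."""
    if c <= 0:
        return 0.0
    a = np.sqrt(1.0 - b**2)
    # Gauss-Hermite for the control variate z ~ N(0,1)
    x, wx = special.roots_hermitenorm(n_z)
    # Gauss-Legendre for u on (0, u_max), u^2 ~ chi2_df / df
    u_max = math.sqrt(stats.chi2.isf(1e-12, df) / df)
    t, wt = special.roots_legendre(n_u)
    u = 0.5 * u_max * (t + 1.0)
    wu = 0.5 * u_max * wt
    log_norm = (df / 2.0) * math.log(df / 2.0) - special.gammaln(df / 2.0)
    chi_pdf = np.exp(log_norm + np.log(2.0) + (df - 1) * np.log(u) - df * u**2 / 2.0)

    zz = x[:, None]                       # (n_z, 1)
    cu = c * u[None, :]                   # (1, n_u)
    prod = np.ones((n_z, n_u))
    for ai, bi in zip(a, b):
        upper = (cu + bi * zz) / ai
        lower = (-cu + bi * zz) / ai
        prod *= special.ndtr(upper) - special.ndtr(lower)
    inner = (wx[:, None] / math.sqrt(2 * math.pi) * prod).sum(axis=0)
    return float((wu * chi_pdf * inner).sum())


def dunnett_critical_value(
    k: int, df: int, alpha: float = 0.05, n_treat: np.ndarray | None = None,
    n_control: float | None = None,
) -> float:
    """Two-sided Dunnett quantile: P(max_i |T_i| <= c) = 1 - alpha.

    Equal group sizes give the classical equicorrelated case (rho = 1/2);
    unequal sizes enter through b_i = sqrt(n_i / (n_i + n0)).  For k = 1
    this reduces to the ordinary two-sided Student t quantile.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_treat is None or n_control is None:
        b = np.full(k, math.sqrt(0.5))
    else:
        n_treat = np.asarray(n_treat, dtype=float)
        b = np.sqrt(n_treat / (n_treat + float(n_control)))
    lo = float(stats.t.isf(alpha / 2, df))          # Bonferroni brackets:
    hi = float(stats.t.isf(alpha / (2 * k), df))    # t_{a/2} <= c <= t_{a/2k}
    if k == 1:
        return lo
    return float(
        optimize.brentq(
            lambda c: _joint_prob(c, b, df) - (1.0 - alpha),
            lo - 1e-9, hi + 1e-9, xtol=1e-8,
        )
    )


def dunnett_from_summary(
    groups: list[GroupSummary], control: str, alpha: float = 0.05
) -> list[DunnettComparison]:
    """Single-step Dunnett comparisons of every treatment vs the control.

    Uses the pooled MS_within of all supplied groups; CI half-width is
    critical_value * sqrt(MS_within * (1/n_t + 1/n_c)); adjusted p is
    P(max_i |T_i| >= |t_obs|) under the joint null.
    """
    labels = [g.label for g in groups]
    if control not in labels:
        raise ValueError(f"control group {control!r} not among {labels}")
    if len(groups) < 2:
        raise ValueError("need at least one treatment group")
    anova = anova_from_summary(groups)
    ctrl = next(g for g in groups if g.label == control)
    treatments = [g for g in groups if g.label != control]
    k = len(treatments)
    n_treat = np.array([g.n for g in treatments], dtype=float)
    b = np.sqrt(n_treat / (n_treat + ctrl.n))
    crit = dunnett_critical_value(
        k, anova.df_within, alpha, n_treat=n_treat, n_control=ctrl.n
    )
    out = []
    for g in treatments:
        diff = g.mean - ctrl.mean
        se = math.sqrt(anova.ms_within * (1.0 / g.n + 1.0 / ctrl.n))
        t_obs = abs(diff) / se if se > 0 else math.inf
        adj_p = 1.0 - _joint_prob(t_obs, b, anova.df_within)
        out.append(
            DunnettComparison(
                treatment=g.label,
                control=control,
                difference=diff,
                ci_low=diff - crit * se,
                ci_high=diff + crit * se,
                adjusted_p=float(min(max(adj_p, 0.0), 1.0)),
                critical_value=crit,
            )
        )
    return out


# ---------------------------------------------------------------------------
# published reference panel

REFERENCE_RESOURCE = "invivo_set2_summary.tsv"


def load_invivo_reference() -> pd.DataFrame:
    """Published group summaries of the rat study (Set II panel).

    Columns: parameter, unit, group, mean, sem, n — one row per
    (parameter, group).  Groups: normal and diabetic controls, metformin
    and probucol monotherapies, and three metformin+probucol dose
    combinations; n = 3 animals per group.
    """
    ref = importlib.resources.files("pertnet.data").joinpath(REFERENCE_RESOURCE)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def groups_from_frame(frame: pd.DataFrame, parameter: str) -> list[GroupSummary]:
    """GroupSummary list for one parameter of a (parameter, group) table."""
    sub = frame[frame["parameter"] == parameter]
    if sub.empty:
        raise KeyError(f"parameter {parameter!r} not in table")
    return [
        GroupSummary(row.group, float(row.mean), float(row.sem), int(row.n))
        for row in sub.itertuples()
    ]


def anova_table(frame: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA per parameter of a (parameter, group, mean, sem, n) table."""
    rows = []
    for parameter in frame["parameter"].unique():
        res = anova_from_summary(groups_from_frame(frame, parameter))
        rows.append(
            (parameter, res.f_stat, res.df_between, res.df_within, res.p_value)
        )
    return pd.DataFrame(
        rows, columns=["parameter", "f_stat", "df_between", "df_within", "p_value"]
    )


def dunnett_table(
    frame: pd.DataFrame, control: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Dunnett comparisons vs one control, per parameter, as a flat table."""
    rows = []
    for parameter in frame["parameter"].unique():
        groups = groups_from_frame(frame, parameter)
        for cmp_ in dunnett_from_summary(groups, control, alpha):
            rows.append(
                (parameter, cmp_.treatment, cmp_.control, cmp_.difference,
                 cmp_.ci_low, cmp_.ci_high, cmp_.adjusted_p, cmp_.critical_value)
            )
    return pd.DataFrame(
        rows,
        columns=["parameter", "treatment", "control", "difference",
                 "ci_low", "ci_high", "adjusted_p", "critical_value"],
    )
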