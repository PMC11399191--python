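"""Cohort statistics: Mann-Whitney comparisons with Bonferroni family
correction, chi-squared characteristic tests, linear regression of BPE on
clinical factors, and 1:1 nearest-neighbour propensity-score matching.

Conventions
-----------
* Mann-Whitney U uses midranks for ties.  The two-sided p-value comes
  from full enumeration of the rank-sum null distribution when the
  product of the sample sizes is at most 400, and otherwise from the
  normal approximation with tie-corrected variance and continuity
  correction.
* Bonferroni adjustment multiplies the unadjusted p by the family size m
  and caps at 1; a result is significant when the adjusted p is below
  the family-wise error rate (0.1 over the m = 6 BPE measures by
  default).  This is decision-equivalent to comparing the unadjusted p
  against fwer/m.
* Chi-squared tests are Pearson's, with Yates continuity correction on
  2x2 tables only.
* Propensity scores are fitted by logistic regression of group
  membership on the confounders; matching is greedy nearest-neighbour on
  the logit scale, without replacement, processing treated subjects in
  descending propensity order.  Balance is reported as standardized mean
  differences (SMD) before and after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    DegenerateTableError,
    EmptyGroupError,
    InvalidSpecError,
    MatchPreconditionError,
)
from .io import GROUPS, MEASURE_COLUMNS

logger = logging.getLogger("bpequant")

#: Confounders used for propensity matching.
PSM_COVARIATES: tuple[str, ...] = ("age", "bmi", "menopausal", "hormone_tx", "fgt_level")

#: product of sample sizes at or below which the exact Mann-Whitney
#: null distribution is enumerated
EXACT_LIMIT = 400


# --------------------------------------------------------------------------
# Mann-Whitney U
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float  # two-sided
    method: str  # "exact" or "asymptotic"


def _exact_mw_p(ranks: np.ndarray, nx: int, u_obs: float) -> float:
    """Two-sided exact p by dynamic programming over the rank multiset.

    Enumerates the null distribution of the size-``nx`` subset rank sum
    (midranks doubled to integers), equivalent to enumerating all
    C(n, nx) group labelings.
    """
    w = np.rint(2 * ranks).astype(np.int64)  # doubled midranks are integers
    total = int(w.sum())
    n = len(w)
    # f[k, s] = number of size-k subsets with doubled-rank sum s
    f = np.zeros((nx + 1, total + 1))
    f[0, 0] = 1.0
    for wi in w:
        f[1:, wi:] += f[:-1, : total + 1 - wi]
    ny = n - nx
    mu = nx * ny / 2.0
    # U for doubled rank sum s: s/2 - nx(nx+1)/2
    s = np.arange(total + 1)
    u_vals = s / 2.0 - nx * (nx + 1) / 2.0
    extreme = np.abs(u_vals - mu) >= abs(u_obs - mu) - 1e-9
    from math import comb

    return float(f[nx, extreme].sum() / comb(n, nx))


def mann_whitney(xs: Sequence[float], ys: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U-test of two independent samples.

    U is the first sample's statistic from midrank summation.  The exact
    enumerated p is used for small samples (n_x * n_y <= 400); larger
    samples use the tie-corrected normal approximation with continuity
    correction.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    nx, ny = len(xs), len(ys)
    if nx == 0 or ny == 0:
        raise EmptyGroupError("both samples must be non-empty")
    pooled = np.concatenate([xs, ys])
    ranks = sps.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    if nx * ny <= EXACT_LIMIT:
        p = _exact_mw_p(ranks, nx, u_x)
        return MannWhitneyResult(u_x, min(1.0, p), "exact")
    res = sps.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "asymptotic")


# --------------------------------------------------------------------------
# Chi-squared
# --------------------------------------------------------------------------


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a contingency table.

    All-zero rows and columns are dropped first; Yates continuity
    correction is applied to 2x2 tables only.  Returns
    ``(statistic, df, p)``.
    """
    t = np.asarray(table)
    if t.ndim != 2:
        raise InvalidSpecError("contingency table must be 2-D")
    if (t < 0).any() or not np.allclose(t, np.rint(t)):
        raise InvalidSpecError("table cells must be non-negative integers")
    t = t.astype(np.int64)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateTableError(
            f"table collapses to shape {t.shape} after dropping empty margins"
        )
    correction = t.shape == (2, 2)
    stat, p, df, _ = sps.chi2_contingency(t, correction=correction)
    return float(stat), int(df), float(p)


# --------------------------------------------------------------------------
# Bonferroni family
# --------------------------------------------------------------------------


def bonferroni_family(
    ps: Sequence[float], m: int | None = None, fwer: float = 0.1
) -> list[tuple[float, bool]]:
    """Bonferroni adjustment over a family of m tests.

    adjusted p = min(1, m * p); significant iff adjusted p < fwer —
    equivalent to comparing the unadjusted p against fwer / m.
    """
    ps = [float(p) for p in ps]
    if m is None:
        m = len(ps)
    if m < 1:
        raise InvalidSpecError("family size m must be >= 1")
    if m < len(ps):
        raise InvalidSpecError(f"family size m={m} smaller than {len(ps)} tests")
    if any(not 0 < p <= 1 for p in ps):
        raise InvalidSpecError("p-values must lie in (0, 1]")
    return [(min(1.0, m * p), min(1.0, m * p) < fwer) for p in ps]


# --------------------------------------------------------------------------
# Linear regression
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    response: str
    model_type: str  # "univariate" | "multivariable"
    covariate: str
    coefficient: float
    ci_low: float
    ci_high: float
    p: float


def _check_design(x: pd.DataFrame) -> None:
    constant = [c for c in x.columns if x[c].nunique() <= 1]
    if constant:
        raise CollinearityError(constant)
    design = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        offending = [
            c
            for c in x.columns
            if np.linalg.matrix_rank(
                np.column_stack([np.ones(len(x)), x.drop(columns=c).to_numpy(float)])
            )
            == design.shape[1] - 1
        ]
        raise CollinearityError(offending or list(x.columns))


def fit_linear(
    cohort: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
    mode: str = "multivariable",
) -> list[RegressionResult]:
    """OLS of one BPE measure on clinical covariates, with 95% CIs.

    ``mode="univariate"`` fits each covariate alone (one simple
    regression per covariate); ``"multivariable"`` fits them jointly.
    The ``group`` column, when listed, enters as BRCA carrier status
    (0/1).  FGT level enters as its ordinal 1-4 value.
    """
    if mode not in ("univariate", "multivariable"):
        raise InvalidSpecError("mode must be 'univariate' or 'multivariable'")
    covariates = list(covariates)
    x = pd.DataFrame(index=cohort.index)
    for c in covariates:
        if c in ("group", "brca"):
            x["brca"] = (cohort["group"] == "brca").astype(float)
        else:
            x[c] = cohort[c].astype(float)
    y = cohort[response].astype(float)
    if len(cohort) <= len(x.columns) + 1:
        raise InvalidSpecError("need n > number of covariates + 1")

    def _fit(xsub: pd.DataFrame, model_type: str) -> list[RegressionResult]:
        _check_design(xsub)
        design = sm.add_constant(xsub, has_constant="add")
        res = sm.OLS(y, design).fit()
        ci = res.conf_int(alpha=0.05)
        return [
            RegressionResult(
                response, model_type,
                "intercept" if c == "const" else c,
                float(res.params[c]), float(ci.loc[c, 0]), float(ci.loc[c, 1]),
                float(res.pvalues[c]),
            )
            for c in design.columns
        ]

    if mode == "multivariable":
        return _fit(x, "multivariable")
    out: list[RegressionResult] = []
    for c in x.columns:
        out.extend(_fit(x[[c]], "univariate"))
    return out


def regression_to_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# --------------------------------------------------------------------------
# Propensity-score matching
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchResult:
    """1:1 matched pairs with propensity scores and balance diagnostics."""

    pairs: list[tuple[str, str]]  # (treated id, control id)
    propensity: pd.Series  # indexed by subject id
    smd_before: dict[str, float]
    smd_after: dict[str, float]
    treated_group: str
    control_group: str
    seed: int = 0

    @property
    def matched_ids(self) -> list[str]:
        return [i for pair in self.pairs for i in pair]


def _smd(t: pd.Series, c: pd.Series) -> float:
    """Standardized mean difference; binary covariates use the
    proportion-based pooled variance."""
    vals = set(pd.concat([t, c]).unique())
    if vals <= {0, 1}:
        p1, p2 = t.mean(), c.mean()
        denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    else:
        denom = np.sqrt((t.var(ddof=1) + c.var(ddof=1)) / 2.0)
    if denom == 0:
        return 0.0
    return float((t.mean() - c.mean()) / denom)


def propensity_match(
    cohort: pd.DataFrame,
    treated_group: str,
    control_group: str,
    covariates: Sequence[str] = PSM_COVARIATES,
    seed: int = 0,
    caliper: float | None = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour propensity-score matching.

    The propensity is a logistic regression of membership in
    ``treated_group`` on the covariates; matching runs on the logit
    scale without replacement, treated subjects in descending propensity
    order, ties broken by subject id.  The treated group must be the
    smaller (or equal) one.  An optional caliper (logit-scale SDs)
    discards matches beyond it.
    """
    for g in (treated_group, control_group):
        if g not in GROUPS:
            raise InvalidSpecError(f"unknown group {g!r}")
    sub = cohort[cohort["group"].isin([treated_group, control_group])].copy()
    treated = sub[sub["group"] == treated_group]
    control = sub[sub["group"] == control_group]
    if treated.empty or control.empty:
        raise EmptyGroupError("both groups must be non-empty")
    if len(treated) > len(control):
        raise MatchPreconditionError(
            f"treated group {treated_group!r} ({len(treated)}) larger than "
            f"control {control_group!r} ({len(control)}); swap the roles"
        )
    covariates = list(covariates)
    x = sub[covariates].astype(float)
    z = (sub["group"] == treated_group).astype(float)
    glm = sm.GLM(z, sm.add_constant(x, has_constant="add"),
                 family=sm.families.Binomial())
    ps = pd.Series(glm.fit().fittedvalues, index=sub.index)
    eps = 1e-12
    logit = np.log(np.clip(ps, eps, 1 - eps) / np.clip(1 - ps, eps, 1 - eps))

    t_idx = treated.index
    c_idx = control.index
    if (logit.loc[t_idx].min() > logit.loc[c_idx].max()
            or logit.loc[t_idx].max() < logit.loc[c_idx].min()):
        logger.warning("non-overlapping propensity supports between %s and %s",
                       treated_group, control_group)
    # descending propensity, ties by subject id
    t_ids_all = sub.loc[t_idx, "id"].astype(str).to_numpy()
    c_ids_all = sub.loc[c_idx, "id"].astype(str).to_numpy()
    logit_t = logit.loc[t_idx].to_numpy()
    logit_c = logit.loc[c_idx].to_numpy()
    order = np.lexsort((t_ids_all, -ps.loc[t_idx].to_numpy()))
    max_dist = (caliper * float(np.std(logit_c, ddof=1))) if caliper is not None else np.inf
    taken = np.zeros(len(c_idx), dtype=bool)
    pairs: list[tuple[str, str]] = []
    for k in order:
        if taken.all():
            break
        dist = np.abs(logit_c - logit_t[k])
        dist[taken] = np.inf
        dmin = dist.min()
        if dmin > max_dist:
            continue
        tied = np.flatnonzero(dist == dmin)
        best = tied[np.argsort(c_ids_all[tied])[0]]  # tie -> smallest id
        taken[best] = True
        pairs.append((str(t_ids_all[k]), str(c_ids_all[best])))

    smd_before = {c: _smd(treated[c].astype(float), control[c].astype(float))
                  for c in covariates}
    t_ids = [p[0] for p in pairs]
    c_ids = [p[1] for p in pairs]
    mt = sub.set_index("id").loc[t_ids]
    mc = sub.set_index("id").loc[c_ids]
    smd_after = {c: _smd(mt[c].astype(float), mc[c].astype(float))
                 for c in covariates}
    return MatchResult(
        pairs=pairs,
        propensity=pd.Series(ps.values, index=sub["id"].values),
        smd_before=smd_before,
        smd_after=smd_after,
        treated_group=treated_group,
        control_group=control_group,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------

STRATA = ("all", "dense", "nondense", "premenopausal", "postmenopausal")


@dataclass(frozen=True)
class ComparisonResult:
    measure: str
    group_a: str
    group_b: str
    median_a: float
    iqr_a: float
    median_b: float
    iqr_b: float
    n_a: int
    n_b: int
    u: float
    p_unadjusted: float
    p_adjusted: float
    m: int
    fwer: float
    significant: bool
    stratum: str = "all"


def _apply_stratum(cohort: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return cohort
    if stratum == "dense":  # heterogeneous or extreme FGT
        return cohort[cohort["fgt_level"].isin([3, 4])]
    if stratum == "nondense":
        return cohort[cohort["fgt_level"].isin([1, 2])]
    if stratum == "premenopausal":
        return cohort[cohort["menopausal"] == 0]
    if stratum == "postmenopausal":
        return cohort[cohort["menopausal"] == 1]
    raise InvalidSpecError(f"unknown stratum {stratum!r}; choose from {STRATA}")


def compare_groups(
    cohort: pd.DataFrame,
    group_pair: tuple[str, str],
    measures: Sequence[str] = MEASURE_COLUMNS,
    m: int | None = None,
    fwer: float = 0.1,
    stratum: str = "all",
    pairs: MatchResult | Sequence[tuple[str, str]] | None = None,
) -> list[ComparisonResult]:
    """Mann-Whitney comparison of two groups over a family of BPE
    measures, with Bonferroni adjustment (m defaults to the number of
    measures, i.e. 6 for the full battery).

    ``stratum`` restricts the cohort first ("dense" = heterogeneous or
    extreme FGT, "nondense" = the rest; pre/postmenopausal by status).
    ``pairs`` restricts to the subjects of a prior matching result so the
    matched-cohort comparison reuses exactly the matched subjects.
    """
    ga, gb = group_pair
    df = _apply_stratum(cohort, stratum)
    if pairs is not None:
        if isinstance(pairs, MatchResult):
            pairs = pairs.pairs
        ids = {i for pair in pairs for i in pair}
        df = df[df["id"].astype(str).isin(ids)]
    xa_all = df[df["group"] == ga]
    xb_all = df[df["group"] == gb]
    if xa_all.empty or xb_all.empty:
        raise EmptyGroupError(
            f"empty group in stratum {stratum!r}: "
            f"{ga}={len(xa_all)}, {gb}={len(xb_all)}"
        )
    measures = list(measures)
    family = m if m is not None else len(measures)
    raw = []
    for meas in measures:
        xa = xa_all[meas].to_numpy(float)
        xb = xb_all[meas].to_numpy(float)
        raw.append((meas, xa, xb, mann_whitney(xa, xb)))
    adjusted = bonferroni_family([r[3].p for r in raw], m=family, fwer=fwer)
    out = []
    for (meas, xa, xb, mw), (p_adj, sig) in zip(raw, adjusted):
        out.append(
            ComparisonResult(
                measure=meas, group_a=ga, group_b=gb,
                median_a=float(np.median(xa)), iqr_a=float(np.subtract(*np.percentile(xa, [75, 25]))),
                median_b=float(np.median(xb)), iqr_b=float(np.subtract(*np.percentile(xb, [75, 25]))),
                n_a=len(xa), n_b=len(xb),
                u=mw.u, p_unadjusted=mw.p, p_adjusted=p_adj,
                m=family, fwer=fwer, significant=sig, stratum=stratum,
            )
        )
    return out


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
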