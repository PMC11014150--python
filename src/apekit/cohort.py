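"""Cohort-level statistics on participant summary tables.

The workflow mirrors a population accelerometry analysis: participants are
grouped into sex-specific cardiorespiratory-fitness (VO2max) tertiles and
into BMI categories cut at 25 and 30 kg/m^2; age-sex weights equalize the
shares of the ten sex x age-decade cells; associations between per-bin daily
minutes and fitness/BMI are quantified with partial Spearman correlations
controlled for age, age^2 and sex; and group differences are tested with the
Kruskal-Wallis omnibus test followed by Dunn's pairwise test with Bonferroni
adjustment.

The partial Spearman statistic is computed as rank-transform, residualize on
the covariate design by (weighted) least squares, then correlate the
residuals; sex enters as a single indicator and age is centered before
squaring to curb collinearity. Weights act as frequency-style weights in
means and cross-products. Group tests run unweighted (weights are reported
alongside).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

AGE_GROUP_EDGES = (20, 30, 40, 50, 60, 70)  # decades 20-29 ... 60-70 (70 inclusive)
BMI_CUTS = (25.0, 30.0)


def age_group(age) -> np.ndarray:
    """Age-decade label; the last group 60-70 includes age 70 exactly."""
    age = np.asarray(age, dtype=float)
    if np.any(age < AGE_GROUP_EDGES[0]) or np.any(age > AGE_GROUP_EDGES[-1]):
        raise DataError(
            f"ages must lie within [{AGE_GROUP_EDGES[0]}, {AGE_GROUP_EDGES[-1]}]"
        )
    idx = np.clip(np.digitize(age, AGE_GROUP_EDGES[1:-1]), 0, 4)
    labels = np.array(["20_29", "30_39", "40_49", "50_59", "60_70"])
    return labels[idx]


def crf_tertile_cuts(vo2max) -> tuple[float, float]:
    """First and second tertile boundaries of a VO2max sample."""
    v = np.asarray(vo2max, dtype=float)
    q1, q2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
    return float(q1), float(q2)


def assign_groups(cohort: pd.DataFrame, bmi_cuts: tuple[float, float] = BMI_CUTS) -> pd.DataFrame:
    """Attach ``crf_third`` (sex-specific VO2max tertiles) and ``bmi_category``.

    BMI below the first cut is low, between the cuts (inclusive) mid, above
    the second cut high. Subjects missing a covariate are flagged <NA> for
    that scheme and excluded from it.
    """
    out = cohort.copy()
    lo, hi = bmi_cuts
    bmi = out["bmi"]
    out["bmi_category"] = pd.array(
        np.select([bmi < lo, bmi <= hi], ["low", "mid"], default="high"), dtype="string"
    )
    out.loc[bmi.isna(), "bmi_category"] = pd.NA

    out["crf_third"] = pd.array([pd.NA] * len(out), dtype="string")
    if "vo2max" in out.columns:
        for sex, grp in out.groupby("sex"):
            v = grp["vo2max"].dropna()
            if len(v) < 3:
                continue
            labels = pd.qcut(v, 3, labels=["low", "mid", "high"]).astype("string")
            out.loc[labels.index, "crf_third"] = labels
    return out


def compute_weights(cohort: pd.DataFrame) -> pd.Series:
    """Per-subject age-sex cell weights.

    Cells are the sex x age-decade combinations; target shares are equal
    across the observed (non-empty) cells, so the weighted cell shares come
    out equal. An empty canonical cell triggers a warning (its weight is
    undefined because no subject carries it).
    """
    cells = pd.Series(
        [f"{s}|{g}" for s, g in zip(cohort["sex"], age_group(cohort["age"]))],
        index=cohort.index,
    )
    counts = cells.value_counts()
    sexes = cohort["sex"].unique()
    canonical = {f"{s}|{g}" for s in sexes for g in ("20_29", "30_39", "40_49", "50_59", "60_70")}
    empty = canonical - set(counts.index)
    if empty:
        warnings.warn(f"empty age-sex cell(s): {sorted(empty)}; their weight is undefined")
    n = len(cohort)
    target = 1.0 / len(counts)
    w = cells.map(lambda c: target / (counts[c] / n))
    w.name = "weight"
    return w


def _weighted_corr(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    wa = a - np.average(a, weights=w)
    wb = b - np.average(b, weights=w)
    cov = np.average(wa * wb, weights=w)
    va = np.average(wa * wa, weights=w)
    vb = np.average(wb * wb, weights=w)
    if va <= 0 or vb <= 0:
        return float("nan")
    return float(cov / np.sqrt(va * vb))


@dataclass
class PartialCorrResult:
    r: float
    p: float
    n: int


def partial_spearman(x, y, age, sex, weights=None) -> PartialCorrResult:
    """Partial Spearman correlation of x and y controlled for age, age^2, sex.

    Both variables are rank-transformed (average ranks for ties), each rank
    vector is residualized on the covariate design (intercept, sex indicator,
    centered age, centered age squared) by weighted least squares, and the
    weighted product-moment correlation of the residuals is returned with a
    t-approximation p-value on n - 5 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    sex_arr = np.asarray(sex)
    n = len(x)
    if not (len(y) == len(age) == len(sex_arr) == n):
        raise DataError("x, y, age, sex must have equal length")
    if n < 6:
        raise DataError(f"need at least 6 observations, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("constant input: partial Spearman undefined")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise DataError("weights must be positive")

    if sex_arr.dtype.kind in "OUS":
        levels = pd.unique(sex_arr)
        if len(levels) > 2:
            raise DataError("sex must be a two-level label")
        sex_ind = (sex_arr == levels[-1]).astype(float)
    else:
        sex_ind = sex_arr.astype(float)

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    age_c = age - np.average(age, weights=w)
    design = np.column_stack([np.ones(n), sex_ind, age_c, age_c**2])

    sw = np.sqrt(w)
    xw = design * sw[:, None]

    def resid(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(xw, v * sw, rcond=None)
        return v - design @ beta

    ex = resid(rx)
    ey = resid(ry)
    r = _weighted_corr(ex, ey, w)
    df = n - design.shape[1] - 1
    if np.isnan(r) or df <= 0 or abs(r) >= 1:
        p = float("nan") if np.isnan(r) else 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p=p, n=n)


@dataclass
class GroupComparison:
    h: float
    p: float
    pairwise: pd.DataFrame  # group1, group2, z, p_unadj, p_adj


def group_compare(values, groups) -> GroupComparison:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise test (Bonferroni).

    Dunn's z statistic uses the rank-sum formulation with the standard tie
    correction; pairwise p-values are two-sided normal tail probabilities
    multiplied by the number of pairs (clipped at 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ConfigError("group_compare needs at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ConfigError("every group needs at least two subjects")

    try:
        h, p = stats.kruskal(*samples)
    except ValueError:  # all values identical
        h, p = 0.0, 1.0

    n = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(var_factor * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if se == 0 else (mean_ranks[g1] - mean_ranks[g2]) / se
        p_un = float(2 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "z": float(z),
                "p_unadj": p_un,
                "p_adj": min(1.0, p_un * len(pairs)),
            }
        )
    return GroupComparison(h=float(h), p=float(p), pairwise=pd.DataFrame(rows))
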