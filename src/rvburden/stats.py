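"""Burden counting and group statistics.

The burden of a gene-set in a subject is the number of qualifying (rare,
high-quality, diploid-region, deleterious) variants whose gene belongs to
the set. Group comparisons use one-sided unequal-variance (Welch) t-tests
with Satterthwaite degrees of freedom; a tie-aware exact Wilcoxon rank-sum
test serves as a non-parametric check, and Benjamini-Hochberg step-up
adjustment controls the false discovery rate across the tested family.

Direction semantics
-------------------
``"cases_greater"`` and ``"controls_greater"`` are fixed one-sided tails.
``"observed"`` takes the tail of the observed mean difference, i.e. half
the two-sided p-value; it is the appropriate choice for exploratory
burden scans where the direction is read off the data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import (
    ClassifierThresholds,
    DEFAULT_THRESHOLDS,
    classify_effect,
    is_damaging_missense,
)
from .types import (
    GeneSet,
    ImpactClass,
    Subject,
    VariantAnnotation,
    VariantCall,
    Zygosity,
)

DIRECTIONS = ("cases_greater", "controls_greater", "observed")

VARIANT_CLASSES = ("LOF", "damaging_missense")


class DegenerateStatisticsError(ValueError):
    """Raised when a test statistic is undefined (zero pooled variability)."""


@dataclass
class BurdenTestResult:
    set_name: str
    variant_class: str
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    t: float
    df: float
    p_one_sided: float
    direction: str
    n_case: int
    n_control: int
    q_bh: Optional[float] = None
    method: str = "welch"


# ---------------------------------------------------------------------------
# Burden counting
# ---------------------------------------------------------------------------

def qualifies_for_class(
    annotation: VariantAnnotation,
    variant_class: str,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    missing_policy: str = "unmet",
) -> bool:
    impact = classify_effect(annotation)
    if variant_class == "LOF":
        return impact is ImpactClass.LOF
    if variant_class == "damaging_missense":
        return impact is ImpactClass.MISSENSE and is_damaging_missense(
            annotation, thresholds, missing_policy
        )
    raise ValueError(f"unknown variant class {variant_class!r}")


def burden_counts(
    records: Sequence[tuple[VariantCall, VariantAnnotation]],
    gene_set: GeneSet,
    variant_class: str,
    subjects: Optional[Sequence[Subject]] = None,
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    missing_policy: str = "unmet",
    include_homozygous: bool = False,
    include_hemizygous: bool = True,
) -> dict[str, int]:
    """Per-subject count of qualifying variants whose gene is in the set.

    ``records`` must already have passed quality/rarity/region filtering.
    A variant counts once per subject even if annotated on several
    transcripts. Homozygous variants are tabulated separately from the
    (heterozygous + hemizygous) burden unless ``include_homozygous``;
    deletion-region hemizygous calls default to counting in every set that
    holds their gene (genome-wide totals included) and can be excluded
    with ``include_hemizygous=False``.
    """
    counts: dict[str, int] = {}
    if subjects is not None:
        counts = {s.subject_id: 0 for s in subjects}
    seen: set[tuple] = set()
    for call, annotation in records:
        if annotation.gene not in gene_set:
            continue
        if not include_homozygous and call.zygosity is Zygosity.HOMOZYGOUS:
            continue
        if not include_hemizygous and call.zygosity is Zygosity.HEMIZYGOUS:
            continue
        if not qualifies_for_class(annotation, variant_class, thresholds, missing_policy):
            continue
        key = (call.subject_id, *call.site_key)
        if key in seen:
            continue
        seen.add(key)
        counts[call.subject_id] = counts.get(call.subject_id, 0) + 1
    return counts


def gene_count_table(
    records: Sequence[tuple[VariantCall, VariantAnnotation]],
    subjects: Sequence[Subject],
    variant_class: str = "damaging_missense",
    thresholds: ClassifierThresholds = DEFAULT_THRESHOLDS,
    missing_policy: str = "unmet",
    include_homozygous: bool = False,
) -> pd.DataFrame:
    """Subjects x genes matrix of qualifying variant counts.

    Summing columns over a gene-set gives that set's per-subject burden;
    this is the fast path for the random-set empirical null.
    """
    ids = [s.subject_id for s in subjects]
    cells: dict[tuple[str, str], int] = {}
    seen: set[tuple] = set()
    for call, annotation in records:
        if not include_homozygous and call.zygosity is Zygosity.HOMOZYGOUS:
            continue
        if not qualifies_for_class(annotation, variant_class, thresholds, missing_policy):
            continue
        key = (call.subject_id, *call.site_key)
        if key in seen:
            continue
        seen.add(key)
        cells[(call.subject_id, annotation.gene)] = (
            cells.get((call.subject_id, annotation.gene), 0) + 1
        )
    genes = sorted({g for _, g in cells})
    table = pd.DataFrame(0, index=ids, columns=genes, dtype=int)
    for (sid, gene), n in cells.items():
        table.loc[sid, gene] = n
    return table


def set_burden_from_table(table: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    cols = [g for g in table.columns if g in gene_set]
    return table[cols].sum(axis=1) if cols else pd.Series(0, index=table.index)


# ---------------------------------------------------------------------------
# Welch one-sided t-test
# ---------------------------------------------------------------------------

def _welch_core(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        raise DegenerateStatisticsError("zero pooled variability in both groups")
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(t), float(df)


def _tail_p(t: float, df: float, direction: str) -> float:
    if direction == "cases_greater":
        return float(sps.t.sf(t, df))
    if direction == "controls_greater":
        return float(sps.t.cdf(t, df))
    if direction == "observed":
        return float(sps.t.sf(abs(t), df))
    raise ValueError(f"unknown direction {direction!r}; expected one of {DIRECTIONS}")


def welch_one_sided(
    x: Sequence[float],
    y: Sequence[float],
    direction: str = "observed",
    set_name: str = "",
    variant_class: str = "",
    method: str = "welch",
) -> BurdenTestResult:
    """One-sided Welch t-test of case counts ``x`` vs control counts ``y``.

    Uses the unequal-variance statistic with Welch-Satterthwaite degrees of
    freedom. ``direction="observed"`` reports the tail of the observed mean
    difference (half the two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, df = _welch_core(x, y)
    p = _tail_p(t, df, direction)
    return BurdenTestResult(
        set_name=set_name,
        variant_class=variant_class,
        mean_case=float(x.mean()),
        sd_case=float(x.std(ddof=1)),
        mean_control=float(y.mean()),
        sd_control=float(y.std(ddof=1)),
        t=t,
        df=df,
        p_one_sided=p,
        direction=direction,
        n_case=len(x),
        n_control=len(y),
        method=method,
    )


def welch_one_sided_matrix(
    X: np.ndarray,
    Y: np.ndarray,
    direction: str = "observed",
) -> np.ndarray:
    """Row-wise Welch one-sided p-values for many tests at once.

    ``X`` is (m, nx) case counts and ``Y`` (m, ny) control counts; rows with
    zero pooled variability yield NaN rather than raising.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    nx, ny = X.shape[1], Y.shape[1]
    vx, vy = X.var(axis=1, ddof=1), Y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (X.mean(axis=1) - Y.mean(axis=1)) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        if direction == "cases_greater":
            p = sps.t.sf(t, df)
        elif direction == "controls_greater":
            p = sps.t.cdf(t, df)
        elif direction == "observed":
            p = sps.t.sf(np.abs(t), df)
        else:
            raise ValueError(f"unknown direction {direction!r}")
    p = np.asarray(p, dtype=float)
    p[se2 == 0] = np.nan
    return p


# ---------------------------------------------------------------------------
# Exact Wilcoxon rank-sum (tie-aware), BH-FDR
# ---------------------------------------------------------------------------

def wilcoxon_one_sided(
    x: Sequence[float],
    y: Sequence[float],
    direction: str = "cases_greater",
    exact_limit: int = 12,
) -> float:
    """One-sided rank-sum p-value; exact tie-aware enumeration for small n.

    The statistic is the midrank sum of the case group. When
    nx + ny <= exact_limit every C(nx+ny, nx) assignment of the pooled
    midranks is enumerated, so average-rank ties are handled exactly.
    Larger samples fall back to the normal approximation. If every pooled
    value is identical the test is maximally uninformative and 0.5 is
    returned by symmetry convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.5
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:nx].sum()
    n = nx + ny
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if n <= exact_limit:
        eps = 1e-9
        total = ge = le = 0
        for combo in itertools.combinations(range(n), nx):
            w = ranks[list(combo)].sum()
            total += 1
            if w >= w_obs - eps:
                ge += 1
            if w <= w_obs + eps:
                le += 1
        p_upper = ge / total
        p_lower = le / total
    else:
        res_upper = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        res_lower = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic")
        p_upper, p_lower = float(res_upper.pvalue), float(res_lower.pvalue)
    if direction == "cases_greater":
        return p_upper
    if direction == "controls_greater":
        return p_lower
    expected = nx * (n + 1) / 2
    return p_upper if w_obs >= expected else p_lower


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_bh(results: Sequence[BurdenTestResult]) -> None:
    """Attach BH q-values across one family of results, in place."""
    qs = bh_fdr([r.p_one_sided for r in results])
    for r, q in zip(results, qs):
        r.q_bh = float(q)


# ---------------------------------------------------------------------------
# Total-burden adjustment, empirical specificity, rank comparison
# ---------------------------------------------------------------------------

def total_adjusted_test(
    x_set: Sequence[float],
    y_set: Sequence[float],
    x_total: Sequence[float],
    y_total: Sequence[float],
    direction: str = "observed",
    set_name: str = "",
    variant_class: str = "",
) -> BurdenTestResult:
    """Burden test adjusted for each subject's total qualifying-variant load.

    Default method: convert each subject's set count into the proportion
    count/total of that subject's genome-wide qualifying variants, then
    Welch-test the proportions. Scale-invariant by construction; the method
    is recorded in the result metadata.
    """
    x_total = np.asarray(x_total, dtype=float)
    y_total = np.asarray(y_total, dtype=float)
    if np.any(x_total <= 0) or np.any(y_total <= 0):
        raise ValueError("per-subject totals must be positive")
    px = np.asarray(x_set, dtype=float) / x_total
    py = np.asarray(y_set, dtype=float) / y_total
    return welch_one_sided(
        px,
        py,
        direction=direction,
        set_name=set_name,
        variant_class=variant_class,
        method="total_adjusted_proportion_welch",
    )


def null_p_distribution(
    table: pd.DataFrame,
    random_sets: Sequence[GeneSet],
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    direction: str = "observed",
) -> np.ndarray:
    """Burden-test p-value for each random gene-set (the empirical null)."""
    X = np.empty((len(random_sets), len(case_ids)))
    Y = np.empty((len(random_sets), len(control_ids)))
    for i, gs in enumerate(random_sets):
        counts = set_burden_from_table(table, gs)
        X[i] = counts.loc[list(case_ids)].to_numpy()
        Y[i] = counts.loc[list(control_ids)].to_numpy()
    return welch_one_sided_matrix(X, Y, direction=direction)


def empirical_specificity(
    observed_p: float,
    null_ps: Sequence[float],
) -> tuple[float, np.ndarray]:
    """Fraction of random-set p-values strictly below the observed p.

    Degenerate (NaN) null entries are dropped. Returns the fraction and the
    full null distribution used.
    """
    null_ps = np.asarray(null_ps, dtype=float)
    null_ps = null_ps[~np.isnan(null_ps)]
    if null_ps.size == 0:
        raise ValueError("need at least one random-set p-value")
    return float(np.mean(null_ps < observed_p)), null_ps


def rank_comparison(
    ranks_cases: Sequence[int],
    ranks_controls: Sequence[int],
) -> tuple[float, float, float]:
    """Compare the priority ranks of variant genes between groups.

    Lower rank = higher priority, so the one-sided alternative is that the
    case group's mean rank is *smaller*. Returns (mean_case, mean_control,
    one-sided Welch p).
    """
    rc = np.asarray(ranks_cases, dtype=float)
    rn = np.asarray(ranks_controls, dtype=float)
    if rc.size == 0 or rn.size == 0:
        raise ValueError("both rank lists must be non-empty")
    if np.any(rc <= 0) or np.any(rn <= 0):
        raise ValueError("ranks must be positive")
    result = welch_one_sided(rc, rn, direction="controls_greater")
    return float(rc.mean()), float(rn.mean()), result.p_one_sided
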