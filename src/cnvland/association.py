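"""Association tests between CNV regions, burden, and clinical phenotypes.

Region-by-phenotype tables use Pearson's chi-square with NO continuity
correction (this exactly reproduces published contingency results that a
Yates-corrected test would not), rows being the CNV statuses actually
observed for the region (loss / no change / gain, all-zero rows dropped)
and columns the phenotype levels.  Burden comparisons use the two-sided
Wilcoxon rank-sum test: exact null enumeration when both groups have at
most 20 observations and there are no ties, otherwise the tie-corrected
normal approximation with continuity correction.

Raw p-values are reported (significance at p <= 0.01 for region tests);
an optional Benjamini-Hochberg column can be added across regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import ValidationError

__all__ = [
    "ContingencyResult",
    "GroupComparison",
    "pearson_chi2",
    "cnv_phenotype_scan",
    "wilcoxon_rank_sum",
    "burden_by_group",
    "PHENOTYPES",
]

logger = logging.getLogger(__name__)

# clinical fields usable as categorical phenotypes, with display level order
PHENOTYPES = {
    "gender": ["female", "male"],
    "who_grade": ["I", "II", "III"],
    "history": ["primary", "recurrent"],
    "location": ["skull-base", "non-skull-base"],
    "edema": ["no", "yes"],
    "bone_invasion": ["no", "yes"],
    "multiple": ["no", "yes"],
    "size_group": ["small", "large"],
}

_STATUS_ORDER = ["loss", "none", "gain"]
_STATUS_LABEL = {"loss": "loss", "none": "no change", "gain": "gain"}


@dataclass
class ContingencyResult:
    """One region-by-phenotype chi-square test."""

    region: str
    phenotype: str
    table: pd.DataFrame  # rows: observed CNV statuses; columns: phenotype levels
    chi2: float
    df: int
    p: float
    significant: bool


@dataclass
class GroupComparison:
    """Burden comparison between phenotype groups (rank-sum tests)."""

    feature: str
    groups: list[str]
    statistic: float
    p: float
    size_bin_results: dict[str, tuple[float, float] | None] = field(default_factory=dict)
    pairwise: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Pearson chi-square
# ---------------------------------------------------------------------------


def pearson_chi2(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a counts table, no continuity correction.

    All-zero rows and columns are dropped first; at least a 2x2 table must
    remain.  Returns (chi2, df, p) with df = (rows-1)(cols-1) and p from
    the chi-square upper tail.
    """
    O = np.asarray(counts, dtype=float)
    if O.ndim != 2:
        raise ValidationError("counts must be a 2-D table")
    if np.any(O < 0):
        raise ValidationError("counts must be nonnegative")
    if not np.allclose(O, np.round(O)):
        raise ValidationError("counts must be integers")
    O = O[O.sum(axis=1) > 0][:, O.sum(axis=0) > 0]
    r, c = O.shape
    if r < 2 or c < 2:
        raise ValidationError(
            f"need at least 2 non-empty rows and columns (got {r}x{c})"
        )
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    total = O.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValidationError("zero margin after dropping empty rows/columns")
    E = row @ col / total
    chi2 = float(np.sum((O - E) ** 2 / E))
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def cnv_phenotype_scan(
    carrier_status: pd.DataFrame,
    clinical: pd.DataFrame,
    phenotype: str,
    alpha: float = 0.01,
    add_bh: bool = False,
) -> list[ContingencyResult]:
    """Chi-square test of every region's carrier status against a phenotype.

    ``carrier_status``: samples x regions with values in {'loss','none','gain'}
    (the carrier matrix).  ``clinical``: frame indexed by patient id with the
    phenotype column.  Rows of each table are restricted to statuses observed
    for that region; regions with a single observed status are skipped with
    a log message.  Raises if any phenotype level has zero patients.
    """
    if phenotype not in PHENOTYPES:
        raise ValidationError(
            f"unknown phenotype {phenotype!r}; choose one of {sorted(PHENOTYPES)}"
        )
    levels = PHENOTYPES[phenotype]
    pheno = clinical.loc[carrier_status.index, phenotype]
    if pheno.dtype == bool:
        pheno = pheno.map({False: "no", True: "yes"})
    pheno = pheno.astype(str)
    observed_levels = [lv for lv in levels if (pheno == lv).any()]
    if len(observed_levels) < len(levels):
        missing = sorted(set(levels) - set(observed_levels))
        raise ValidationError(f"phenotype {phenotype!r}: no patients at level(s) {missing}")

    results = []
    for region in carrier_status.columns:
        status = carrier_status[region]
        tab = np.array(
            [
                [int(((status == st) & (pheno == lv)).sum()) for lv in levels]
                for st in _STATUS_ORDER
            ]
        )
        keep = tab.sum(axis=1) > 0
        if keep.sum() < 2:
            logger.info("region %s: single CNV status observed; test skipped", region)
            continue
        tab = tab[keep]
        chi2, df, p = pearson_chi2(tab)
        table = pd.DataFrame(
            tab,
            index=[_STATUS_LABEL[s] for s, k in zip(_STATUS_ORDER, keep) if k],
            columns=levels,
        )
        results.append(
            ContingencyResult(
                region=str(region),
                phenotype=phenotype,
                table=table,
                chi2=chi2,
                df=df,
                p=p,
                significant=p <= alpha,
            )
        )
    if add_bh and results:
        q = stats.false_discovery_control([r.p for r in results], method="bh")
        for r, qv in zip(results, q):
            r.q = float(qv)  # supplementary attribute
    return results


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _exact_ranksum_p(w: int, n: int, m: int) -> float:
    """Two-sided exact p for rank-sum W of the first group (no ties).

    Enumerates the null distribution of W over all C(n+m, n) equally likely
    rank assignments by dynamic programming; p is the probability of a W at
    least as far from the null mean as observed (the distribution is
    symmetric about n(n+m+1)/2).
    """
    N = n + m
    max_w = n * N - n * (n - 1) // 2
    # ways[k][w] = number of k-subsets of ranks processed so far with sum w
    ways = np.zeros((n + 1, max_w + 1), dtype=float)
    ways[0, 0] = 1.0
    for rank in range(1, N + 1):
        upper = min(n, rank)
        for k in range(upper, 0, -1):
            ways[k, rank:] += ways[k - 1, : max_w + 1 - rank]
    dist = ways[n]
    total = dist.sum()
    mu = n * (N + 1) / 2.0
    dev = abs(w - mu)
    wvals = np.arange(max_w + 1)
    p = dist[np.abs(wvals - mu) >= dev - 1e-9].sum() / total
    return float(min(p, 1.0))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (W, p) where W is the rank sum of ``x`` (midranks under ties).
    Exact when both groups have <= 20 observations and there are no ties;
    otherwise the normal approximation with tie-corrected variance and a
    0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    n, m = len(x), len(y)
    N = n + m
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[:n].sum())
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if n <= 20 and m <= 20 and not has_ties:
        return w, _exact_ranksum_p(int(round(w)), n, m)

    mu = n * (N + 1) / 2.0
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return w, 1.0  # all values identical
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return w, float(min(2.0 * stats.norm.sf(z), 1.0))


def burden_by_group(
    burden: pd.DataFrame,
    clinical: pd.DataFrame,
    feature: str,
    size_bins: Sequence[str] | None = None,
) -> GroupComparison:
    """Rank-sum comparison of CNV burden between phenotype groups.

    Compares overall CNV counts between the feature's levels, plus one
    comparison per size bin (reported as None when a bin is empty in every
    group).  With three levels (WHO grade) all pairwise comparisons are
    added; the overall statistic then refers to grade I versus the pooled
    high-grade (II+III) group.
    """
    from .burden import SIZE_BINS

    size_bins = list(size_bins) if size_bins is not None else list(SIZE_BINS)
    if feature not in PHENOTYPES:
        raise ValidationError(f"unknown feature {feature!r}")
    levels = PHENOTYPES[feature]
    pheno = clinical.loc[burden.index, feature]
    if pheno.dtype == bool:
        pheno = pheno.map({False: "no", True: "yes"})
    pheno = pheno.astype(str)
    groups = {lv: burden[pheno == lv] for lv in levels if (pheno == lv).any()}
    if len(groups) < 2:
        raise ValidationError(f"feature {feature!r} has fewer than 2 observed levels")

    def compare(col: str, a: pd.DataFrame, b: pd.DataFrame):
        xa, xb = a[col].to_numpy(), b[col].to_numpy()
        if np.all(xa == 0) and np.all(xb == 0):
            return None
        return wilcoxon_rank_sum(xa, xb)

    names = list(groups)
    if len(names) == 2:
        a, b = groups[names[0]], groups[names[1]]
    else:
        # 3 levels: overall test is first level vs the pooled remainder
        a = groups[names[0]]
        b = pd.concat([groups[n] for n in names[1:]])
    stat, p = compare("n_cnvs", a, b)

    result = GroupComparison(feature=feature, groups=names, statistic=stat, p=p)
    for bin_name in size_bins:
        result.size_bin_results[bin_name] = compare(f"n_{bin_name}", a, b)
    if len(names) >= 3:
        for ga, gb in combinations(names, 2):
            result.pairwise[(ga, gb)] = compare("n_cnvs", groups[ga], groups[gb])
    return result
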