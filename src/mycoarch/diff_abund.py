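"""Per-taxon differential abundance between sample cohorts.

Each retained taxon is tested with the Kruskal–Wallis rank test on its CLR
abundance between two sample groups (in the two-group case this is the
Wilcoxon rank-sum test).  Effect size is the base-2 log ratio of group mean
relative abundances.  P-values are Bonferroni-corrected within the cohort
comparison, and a taxon is called significantly dysregulated when the
adjusted p-value is below 0.05 and |logFC| exceeds 1 (at least a two-fold
difference).

The statistic is computed from its rank definition with mid-ranks and tie
correction; the p-value is the chi-square tail with k-1 degrees of freedom,
the large-sample reference every standard implementation reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountTable
from .transform import AbundanceTable

logger = logging.getLogger(__name__)

DA_COLUMNS = ["domain", "H", "p_raw", "p_adj", "logFC", "direction", "significant"]


class CohortError(ValueError):
    """A cohort specification resolves to an unusable sample split."""


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def _tie_correction(values: np.ndarray) -> float:
    """1 - sum(t^3 - t) / (N^3 - N) over tied groups; 0 if all values tie."""
    n = values.size
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Kruskal–Wallis H and chi-square p for one variable across k groups.

    Mid-ranks with tie correction; requires >= 2 groups, each non-empty, and
    N >= 3.  All-identical values give (H, p) = (0, 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels, inverse = np.unique(groups, return_inverse=True)
    k = labels.size
    n = values.size
    if k < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    if n < 3:
        raise ValueError("kruskal_wallis requires N >= 3")

    correction = _tie_correction(values)
    if correction == 0.0:  # every observation identical
        return 0.0, 1.0
    ranks = stats.rankdata(values)
    rank_sums = np.bincount(inverse, weights=ranks, minlength=k)
    sizes = np.bincount(inverse, minlength=k)
    h = 12.0 / (n * (n + 1)) * (rank_sums ** 2 / sizes).sum() - 3.0 * (n + 1)
    h /= correction
    p = float(stats.chi2.sf(h, k - 1))
    return float(h), p


def kruskal_wallis_matrix(
    matrix: np.ndarray, groups: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Kruskal–Wallis over a variables x samples matrix."""
    matrix = np.asarray(matrix, dtype=float)
    groups = np.asarray(groups)
    labels, inverse = np.unique(groups, return_inverse=True)
    k = labels.size
    n = matrix.shape[1]
    if k < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    if n < 3:
        raise ValueError("kruskal_wallis requires N >= 3")
    sizes = np.bincount(inverse, minlength=k)

    ranks = stats.rankdata(matrix, axis=1)
    onehot = np.eye(k)[inverse]  # samples x groups
    rank_sums = ranks @ onehot  # rows x groups
    h = 12.0 / (n * (n + 1)) * (rank_sums ** 2 / sizes).sum(axis=1) - 3.0 * (n + 1)
    corrections = np.array([_tie_correction(row) for row in matrix])
    degenerate = corrections == 0.0
    h = np.where(degenerate, 0.0, h / np.where(degenerate, 1.0, corrections))
    p = np.where(degenerate, 1.0, stats.chi2.sf(h, k - 1))
    return h, p


# ---------------------------------------------------------------------------
# Effect size and multiplicity
# ---------------------------------------------------------------------------


def log_fold_change(
    counts: CountTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudo: float = 1e-6,
) -> pd.Series:
    """Per-taxon base-2 log ratio of group mean relative abundances (a over b)."""
    if not len(group_a) or not len(group_b):
        raise CohortError("both groups must be non-empty")
    mat = counts.counts
    rel = mat / mat.sum(axis=0).replace(0, np.nan)
    mean_a = rel[list(group_a)].mean(axis=1).fillna(0.0)
    mean_b = rel[list(group_b)].mean(axis=1).fillna(0.0)
    return np.log2((mean_a + pseudo) / (mean_b + pseudo))


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """p_adj = min(1, m * p); rejects p outside (0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, p * p.size)


# ---------------------------------------------------------------------------
# Cohort comparisons
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Two disjoint sample groups defined by field == value conjunctions.

    Predicates are mappings over sample-metadata columns, e.g.
    ``{"tissue": "tumor", "subtype": "CPTC"}`` vs ``{"tissue": "normal"}``.
    Gender comparisons pair each tumor group with its gender-matched
    normals; the BRAF comparison is tumor-vs-tumor by mutation status.
    """

    name: str
    group_a: Mapping[str, str]
    group_b: Mapping[str, str]

    def _select(self, meta: pd.DataFrame, predicate: Mapping[str, str]) -> list[str]:
        mask = pd.Series(True, index=meta.index)
        for column, value in predicate.items():
            if column not in meta.columns:
                raise CohortError(f"{self.name}: unknown metadata field {column!r}")
            mask &= meta[column] == value
        return list(meta.index[mask])

    def resolve(self, meta: pd.DataFrame) -> tuple[list[str], list[str]]:
        a = self._select(meta, self.group_a)
        b = self._select(meta, self.group_b)
        if not a:
            raise CohortError(f"{self.name}: group_a predicate {dict(self.group_a)} "
                              "matched no samples")
        if not b:
            raise CohortError(f"{self.name}: group_b predicate {dict(self.group_b)} "
                              "matched no samples")
        overlap = set(a) & set(b)
        if overlap:
            raise CohortError(f"{self.name}: groups overlap in {len(overlap)} samples")
        return a, b


def default_cohorts() -> list[CohortSpec]:
    """The seven standard comparisons: all tumors, three histologic subtypes
    and both genders against (gender-matched) adjacent normals, plus BRAF
    V600E-positive vs -negative tumors."""
    return [
        CohortSpec("tumor_vs_normal", {"tissue": "tumor"}, {"tissue": "normal"}),
        CohortSpec("cptc_vs_normal",
                   {"tissue": "tumor", "subtype": "CPTC"}, {"tissue": "normal"}),
        CohortSpec("fvptc_vs_normal",
                   {"tissue": "tumor", "subtype": "FVPTC"}, {"tissue": "normal"}),
        CohortSpec("tcptc_vs_normal",
                   {"tissue": "tumor", "subtype": "TCPTC"}, {"tissue": "normal"}),
        CohortSpec("male_tumor_vs_normal",
                   {"tissue": "tumor", "gender": "male"},
                   {"tissue": "normal", "gender": "male"}),
        CohortSpec("female_tumor_vs_normal",
                   {"tissue": "tumor", "gender": "female"},
                   {"tissue": "normal", "gender": "female"}),
        CohortSpec("braf_pos_vs_braf_neg",
                   {"tissue": "tumor", "braf_v600e": "positive"},
                   {"tissue": "tumor", "braf_v600e": "negative"}),
    ]


def run_cohort_comparison(
    counts: CountTable,
    abund: AbundanceTable,
    meta: pd.DataFrame,
    spec: CohortSpec,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    bonferroni: bool = True,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Differential-abundance table for one cohort comparison.

    One row per retained taxon: H, raw and Bonferroni-adjusted p, base-2
    logFC (group_a over group_b), direction, and the significance call
    (p < alpha on the adjusted scale by default, and |logFC| > threshold).
    """
    group_a, group_b = spec.resolve(meta)
    if len(group_a) < 2 or len(group_b) < 2:
        raise CohortError(f"{spec.name}: each group needs >= 2 samples")
    samples = group_a + group_b
    labels = np.array([0] * len(group_a) + [1] * len(group_b))
    values = abund.values.loc[counts.taxon_ids, samples].to_numpy()

    h, p_raw = kruskal_wallis_matrix(values, labels)
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
    p_adj = bonferroni_adjust(p_raw) if bonferroni else p_raw.copy()
    lfc = log_fold_change(counts, group_a, group_b).to_numpy()
    direction = np.where(lfc > 0, "over_in_a", "over_in_b")
    p_for_call = p_adj if use_adjusted else p_raw
    significant = (p_for_call < alpha) & (np.abs(lfc) > lfc_threshold)

    table = pd.DataFrame(
        {
            "domain": counts.taxa["domain"].to_numpy(),
            "H": h,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "logFC": lfc,
            "direction": direction,
            "significant": significant,
        },
        index=counts.counts.index,
    )
    logger.info("%s: %d/%d taxa significant (n=%d vs %d)",
                spec.name, int(significant.sum()), len(table),
                len(group_a), len(group_b))
    return table
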