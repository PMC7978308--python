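"""Pairwise gene co-occurrence / mutual-exclusivity tests and group comparisons.

For every unordered gene pair a 2x2 table (mutated/wild-type for each gene)
is tested with the two-sided Fisher exact test (the "probability mass at or
below the observed table" convention — two-sided conventions differ between
tools, so the choice is pinned here).  P-values are Benjamini-Hochberg
adjusted across pairs; a pair is called co-occurrent when the odds ratio
exceeds 1 and q < 0.05, mutually exclusive when the odds ratio is below 1
and q < 0.05.

Group TMB comparisons use the two-sided Welch (unequal-variance) t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fisher_exact_2x2(
    table, haldane_correction: bool = False
) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns ``(odds_ratio, p_value)``.  The odds ratio is the sample
    ``ad / bc``; zero-cell tables yield 0, ``inf`` or (for doubly degenerate
    tables) ``nan`` unless ``haldane_correction`` adds 0.5 to every cell.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    t = np.round(t).astype(int)
    p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    a, b, c, d = (float(x) for x in t.ravel())
    if haldane_correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf
    else:
        odds = (a * d) / (b * c)
    return odds, min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    Invariant to input order; every input must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class PairwiseTest:
    gene_a: str
    gene_b: str
    table: tuple[int, int, int, int]  # (both, a_only, b_only, neither)
    odds_ratio: float
    p_value: float
    q_value: float
    direction: str  # co_occurrent | exclusive | none


def pairwise_gene_tests(
    binary_matrix: pd.DataFrame, genes: list[str] | None = None, fdr: float = 0.05
) -> pd.DataFrame:
    """Fisher co-occurrence/exclusivity test for every unordered gene pair.

    ``binary_matrix`` is genes x samples (bool/0-1).  Returns one row per
    pair with the 2x2 table, odds ratio, p, BH q and called direction.
    """
    if genes is None:
        genes = list(binary_matrix.index)
    missing = [g for g in genes if g not in binary_matrix.index]
    if missing:
        raise KeyError(f"gene(s) absent from mutation matrix: {missing}")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for pairwise testing")
    M = binary_matrix.loc[genes].astype(bool)
    rows = []
    for ga, gb in combinations(genes, 2):
        a_vec, b_vec = M.loc[ga].to_numpy(), M.loc[gb].to_numpy()
        both = int((a_vec & b_vec).sum())
        a_only = int((a_vec & ~b_vec).sum())
        b_only = int((~a_vec & b_vec).sum())
        neither = int((~a_vec & ~b_vec).sum())
        odds, p = fisher_exact_2x2([[both, a_only], [b_only, neither]])
        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "n_both": both,
                "n_a_only": a_only,
                "n_b_only": b_only,
                "n_neither": neither,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    significant = df["q_value"] < fdr
    df["direction"] = "none"
    df.loc[significant & (df["odds_ratio"] > 1), "direction"] = "co_occurrent"
    df.loc[significant & (df["odds_ratio"] < 1), "direction"] = "exclusive"
    return df


def group_tmb_test(values, group_labels) -> tuple[float, float, dict[str, float]]:
    """Welch two-sided t-test between two groups of TMB values.

    Returns ``(t_statistic, p_value, group_means)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    x = values[labels == groups[0]]
    y = values[labels == groups[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=False)
    means = {str(groups[0]): float(x.mean()), str(groups[1]): float(y.mean())}
    return float(res.statistic), float(res.pvalue), means


def mutation_indicator_matrix(
    variants: pd.DataFrame, sample_ids: list[str], genes: list[str] | None = None,
    classes: frozenset | None = None,
) -> pd.DataFrame:
    """Genes x samples boolean matrix: sample carries >= 1 qualifying variant."""
    df = variants
    if classes is not None:
        df = df[df["variant_class"].isin(classes)]
    if genes is None:
        genes = sorted(df["gene"].unique())
    mat = pd.DataFrame(False, index=genes, columns=sample_ids)
    hit = df[df["gene"].isin(genes) & df["sample_id"].isin(sample_ids)]
    for g, s in zip(hit["gene"], hit["sample_id"]):
        mat.at[g, s] = True
    return mat
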