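"""Transcriptomic and methylation phenotype scores.

TPM normalization, single-sample gene-set enrichment (rank-weighted ECDF
difference between in-set and out-of-set genes), a composite
epithelial-mesenchymal transition (EMT) score defined as the mesenchymal
minus epithelial enrichment, and the promoter beta-value methylation classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and gene lengths (bp).

    ``tpm_g = 1e6 * (count_g / len_g) / sum_g'(count_g' / len_g')`` per
    sample; columns sum to one million.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing gene lengths")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    lib = rate.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return rate.div(lib, axis=1) * 1e6


@dataclass
class GeneSet:
    name: str
    genes: tuple

    def __post_init__(self):
        genes = tuple(dict.fromkeys(self.genes))  # dedupe, keep order
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", genes)


def read_gmt(path: str) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.append(GeneSet(parts[0], tuple(g for g in parts[2:] if g)))
    return sets


def ssgsea_score(expression: pd.Series, gene_set: GeneSet,
                 alpha: float = 0.75) -> float:
    """Single-sample enrichment of a gene set in one expression profile.

    Genes are ordered by decreasing expression; walking down the list, the
    in-set empirical CDF (steps weighted by rank^alpha, ranks averaged over
    ties) is accumulated against the uniform out-of-set ECDF, and the score is
    the sum of their running difference. Rank-based, hence invariant under
    monotone transforms of the expression values.
    """
    genes_in = [g for g in gene_set.genes if g in expression.index]
    if not genes_in:
        raise ValueError(f"no gene of set {gene_set.name!r} in the matrix")
    ranks = expression.rank(method="average")          # 1 = lowest
    order = expression.sort_values(ascending=False, kind="stable").index
    in_set = order.isin(genes_in)
    w = ranks.loc[order].to_numpy() ** alpha
    n = len(order)
    n_in = in_set.sum()
    step_in = np.where(in_set, w / w[in_set].sum(), 0.0)
    step_out = np.where(~in_set, 1.0 / (n - n_in), 0.0) if n > n_in else 0.0
    return float(np.sum(np.cumsum(step_in) - np.cumsum(step_out)))


def ssgsea_matrix(expression: pd.DataFrame, gene_sets: list,
                  alpha: float = 0.75, scale: str | None = None) -> pd.DataFrame:
    """Score every sample against every gene set; optional cohort z-scaling."""
    out = pd.DataFrame(
        {s: {gs.name: ssgsea_score(expression[s], gs, alpha) for gs in gene_sets}
         for s in expression.columns})
    if scale == "zscore":
        out = out.sub(out.mean(axis=1), axis=0).div(
            out.std(axis=1).replace(0, 1), axis=0)
    return out


def emt_score(expression: pd.DataFrame, epithelial: GeneSet,
              mesenchymal: GeneSet, alpha: float = 0.75) -> pd.Series:
    """Composite EMT score: mesenchymal minus epithelial enrichment.

    Rescaled by the cohort's maximum absolute value into [-1, 1]; positive
    values lean mesenchymal (sarcomatous), negative epithelial (carcinomatous).
    """
    raw = pd.Series({
        s: ssgsea_score(expression[s], mesenchymal, alpha)
        - ssgsea_score(expression[s], epithelial, alpha)
        for s in expression.columns})
    top = raw.abs().max()
    return raw / top if top > 0 else raw


def classify_promoter(beta: float) -> str:
    """Promoter methylation class: hypo (< 0.3), hyper (> 0.7), intermediate."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta value outside [0, 1]")
    if beta < 0.3:
        return "hypo"
    if beta > 0.7:
        return "hyper"
    return "intermediate"


def classify_promoters(betas: pd.Series) -> pd.Series:
    return betas.map(classify_promoter)


def paired_rank_compare(values_a: pd.DataFrame, values_b: pd.DataFrame
                        ) -> pd.DataFrame:
    """Rank-based paired comparison of two matched sample groups.

    A synthetic-demo utility (Wilcoxon signed-rank per gene across pairs); it
    does not reimplement the count-model differential tests used on real
    cohorts.
    """
    common = values_a.index.intersection(values_b.index)
    rows = []
    for g in common:
        a = values_a.loc[g].to_numpy(dtype=float)
        b = values_b.loc[g].to_numpy(dtype=float)
        if np.allclose(a, b):
            rows.append((g, float(np.median(b - a)), 1.0))
            continue
        stat = wilcoxon(a, b)
        rows.append((g, float(np.median(b - a)), float(stat.pvalue)))
    return pd.DataFrame(rows, columns=["gene", "median_diff", "p_value"]
                        ).set_index("gene")
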