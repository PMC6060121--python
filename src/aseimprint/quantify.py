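"""Read-count-ratio quantification of allelic bias.

The central statistic is the read count ratio

    S_ig = H_ig / T_ig = (sum_s H_s) / (sum_s T_s),

where the sum runs over the SNPs *s* at which individual *i* is usably
heterozygous in gene *g*, ``T_s`` is the total RNA-seq read count at the
SNP and ``H_s`` the count of the allele with more reads.  S ranges from
0.5 (balanced biallelic expression) to 1 (strictly monoallelic
expression, the hallmark of genomic imprinting).

Two variance-motivated transforms of S are provided for regression
modelling: a quasi-log transform Q and a within-gene rank transform R
scaled to (0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatioMatrix",
    "TransformParams",
    "read_count_ratio",
    "quality_filter",
    "quasi_log",
    "rank_transform",
    "prob_higher_is_biased",
]


@dataclass
class TransformParams:
    """Parameters of the S -> Q and S -> R transforms.

    ``pseudo_count`` (c) keeps the argument of the logarithm positive:
    Q = -log(1 - S*T/(T+c)).  ``rank_scale`` is the upper end of the
    rank transform's range.
    """

    pseudo_count: float = 1.0
    rank_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be > 0")


@dataclass
class RatioMatrix:
    """Per (individual, gene) allelic-bias statistics in long format.

    ``cells`` has one row per (individual, gene) with at least columns
    ``individual, gene, H, T, S``; transform columns ``Q`` and ``R`` are
    added by :func:`quasi_log` / :func:`rank_transform`.  ``snp_detail``
    keeps the per-SNP contributions (H_s, T_s, identity of the higher
    allele) that the reference/nonreference test consumes.
    """

    cells: pd.DataFrame
    snp_detail: pd.DataFrame = field(default_factory=pd.DataFrame)

    def pivot(self, value: str = "S") -> pd.DataFrame:
        """Individuals x genes matrix of one statistic (NaN = no data)."""
        return self.cells.pivot(index="individual", columns="gene", values=value)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def read_count_ratio(counts: pd.DataFrame, usable: pd.DataFrame) -> RatioMatrix:
    """Aggregate per-SNP allele counts into the read count ratio S_ig.

    Parameters
    ----------
    counts
        Allele-count table with columns
        ``individual, snp_id, gene, ref_count, alt_count``.
    usable
        Usable heterozygous calls, columns ``individual, snp_id``; only
        these (individual, SNP) pairs enter the summation.

    Returns
    -------
    RatioMatrix
        Cells with H = sum of per-SNP higher counts, T = sum of totals,
        S = H/T.  A (individual, gene) pair with no usable SNP is absent
        from the table (missing data, never zero-filled).  Per-SNP ties
        (ref == alt) contribute H_s = T_s/2, which is why H is carried
        as a float.
    """
    if (counts[["ref_count", "alt_count"]] < 0).to_numpy().any():
        raise ValueError("negative allele counts")
    used = counts.merge(usable[["individual", "snp_id"]], on=["individual", "snp_id"])
    used = used[(used.ref_count + used.alt_count) > 0].copy()
    ref = used.ref_count.to_numpy()
    alt = used.alt_count.to_numpy()
    used["T_s"] = ref + alt
    used["H_s"] = np.maximum(ref, alt)
    used["higher_allele"] = np.where(ref > alt, "ref", np.where(alt > ref, "alt", "tie"))

    cells = (
        used.groupby(["individual", "gene"], observed=True)[["H_s", "T_s"]]
        .sum()
        .reset_index()
        .rename(columns={"H_s": "H", "T_s": "T"})
    )
    cells["S"] = cells["H"] / cells["T"]
    detail = used[["individual", "snp_id", "gene", "ref_count", "alt_count",
                   "H_s", "T_s", "higher_allele"]]
    return RatioMatrix(cells=cells, snp_detail=detail)


def quality_filter(ratios: RatioMatrix, t_rc: int = 15, t_ind: int = 25) -> RatioMatrix:
    """Sequential read-count and individual-count filters.

    First removes cells with T < ``t_rc`` (strict, so T == t_rc is
    kept), then drops genes left with data on fewer than ``t_ind``
    individuals.  The order matters and is fixed.
    """
    kept = ratios.cells[ratios.cells["T"] >= t_rc]
    per_gene = kept.groupby("gene", observed=True)["individual"].size()
    genes = per_gene[per_gene >= t_ind].index
    kept = kept[kept.gene.isin(genes)].reset_index(drop=True)
    detail = ratios.snp_detail
    if len(detail):
        key = pd.MultiIndex.from_frame(kept[["individual", "gene"]])
        mask = pd.MultiIndex.from_frame(detail[["individual", "gene"]]).isin(key)
        detail = detail[mask].reset_index(drop=True)
    return RatioMatrix(cells=kept, snp_detail=detail)


def quasi_log(ratios: RatioMatrix, params: TransformParams | None = None) -> RatioMatrix:
    """Add the quasi-log transform Q = -log(1 - S*T/(T+c)) to the cells.

    Natural logarithm; c > 0 guarantees a positive argument, so Q lies
    in (0, log(T + c)] with the upper bound attained at S = 1.
    """
    params = params or TransformParams()
    c = params.pseudo_count
    cells = ratios.cells.copy()
    T = cells["T"].to_numpy(dtype=float)
    cells["Q"] = -np.log(1.0 - cells.S.to_numpy() * T / (T + c))
    return RatioMatrix(cells=cells, snp_detail=ratios.snp_detail)


def rank_transform(ratios: RatioMatrix, params: TransformParams | None = None) -> RatioMatrix:
    """Add the within-gene rank transform R to the cells.

    R_ig = #{j : S_jg <= S_ig} / #j * rank_scale, computed across the
    individuals with data for gene g.  Ties share the maximal rank (the
    count includes every j with an equal S), so a full tie gives
    R = rank_scale for everyone.
    """
    params = params or TransformParams()
    cells = ratios.cells.copy()
    grp = cells.groupby("gene", observed=True)["S"]
    cells["R"] = grp.rank(method="max") / grp.transform("size") * params.rank_scale
    return RatioMatrix(cells=cells, snp_detail=ratios.snp_detail)


def prob_higher_is_biased(p: float, t: int) -> float:
    """Probability that the higher-count allele is the biased allele.

    Under B ~ Binom(t, p) with p >= 0.5 the statistic H = max(B, t - B)
    equals B whenever 2B >= t.  This probability is monotone in p and
    tends to 1 as p -> 1, which is what justifies restricting inference
    to genes with high observed S.
    """
    if not 0.5 <= p < 1 + 1e-12:
        raise ValueError("p must be in [0.5, 1]")
    k = int(np.ceil(t / 2))
    return float(stats.binom.sf(k - 1, t, p))
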