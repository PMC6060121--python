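"""Gene scoring, ranking and imprinted-gene calling.

A gene's score is the right tail of the across-individuals empirical
distribution of its read count ratio: score = 1 - F_g(0.9), the
fraction of individuals with S > 0.9.  Genes are ranked by score and
the top of the ranking is screened with two tests that separate true
imprinting from look-alikes:

- the reference/nonreference allele test: under imprinting the parental
  origin of the higher-expressed allele is random, so at each SNP the
  number of individuals whose *reference* allele carries the higher
  count is Binom(n, 0.5); systematic deviation indicates reference
  mapping bias or a cis-eQTL ("X" flag);
- the nearly-unbiased-expression test: an (individual, gene) cell is
  certified nearly unbiased when S <= 0.6 and its binomial 95% upper
  confidence limit UCL = S + z_0.975 * sqrt(S(1-S)/T) <= 0.7.

Final calls combine rank with prior status: a top-ranked gene is called
imprinted when it is already known to be imprinted or lies within 1 Mb
of a known imprinted gene; a manual-include list mirrors the judgment
call of keeping a well-established imprinted gene that ranks just below
the cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["gene_score", "rank_genes", "ref_nonref_test", "nearly_unbiased_test",
           "classify_prior_status", "call_imprinted", "survival_curves",
           "Z_0975", "score_and_call"]

Z_0975 = 1.959963984540054  # 97.5% standard-normal quantile, double precision

PRIOR_LEVELS = ("known_imprinted", "nearby_candidate", "distant_candidate")


def gene_score(ratios, threshold: float = 0.9) -> pd.DataFrame:
    """Per-gene fraction of individuals with S strictly above ``threshold``."""
    cells = ratios.cells
    grp = cells.assign(above=cells.S > threshold).groupby("gene", observed=True)
    out = grp.agg(score=("above", "mean"), n_individuals=("above", "size"))
    return out.reset_index()


def rank_genes(ratios, threshold: float = 0.9,
               alt_threshold: float = 0.7) -> pd.DataFrame:
    """Rank genes by score, descending; deterministic tie-breaks.

    Ties on the primary score (1 - F_g(threshold)) are broken by the
    alternative score at ``alt_threshold`` (descending) and then by
    gene identifier, so the ranking is a stable permutation 1..n.
    """
    main = gene_score(ratios, threshold)
    alt = gene_score(ratios, alt_threshold).rename(columns={"score": "alt_score"})
    table = main.merge(alt[["gene", "alt_score"]], on="gene")
    table = table.sort_values(["score", "alt_score", "gene"],
                              ascending=[False, False, True],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def _exact_binom_p(k: int, n: int) -> float:
    """Exact two-sided binomial p-value at p0 = 0.5."""
    return stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue


def ref_nonref_test(snp_detail: pd.DataFrame, alpha: float = 0.05,
                    min_informative: int = 10
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP exact binomial test of reference-allele dominance.

    For each SNP, individuals with a strict higher allele (ties
    excluded) are informative; ``n_ref_higher`` of them having the
    reference allele on top is tested against Binom(n, 0.5),
    two-sided.  SNPs with fewer than ``min_informative`` informative
    individuals do not enter the gene-level decision.

    Gene-level compound decision: "X" (rejected) when the number of
    rejected SNPs exceeds the 95% quantile of Binom(#informative SNPs,
    alpha) — i.e. more per-SNP rejections than chance allows; "0" when
    no SNP is informative; "pass" otherwise.

    Returns ``(per_snp, per_gene)`` tables.
    """
    info = snp_detail[snp_detail.higher_allele != "tie"]
    grp = info.assign(ref_hi=info.higher_allele == "ref").groupby(
        ["gene", "snp_id"], observed=True)
    per_snp = grp.agg(n_informative=("ref_hi", "size"),
                      n_ref_higher=("ref_hi", "sum")).reset_index()
    per_snp["p_value"] = [
        _exact_binom_p(int(k), int(n))
        for k, n in zip(per_snp.n_ref_higher, per_snp.n_informative)]
    per_snp["informative"] = per_snp.n_informative >= min_informative
    per_snp["rejected"] = per_snp.informative & (per_snp.p_value < alpha)

    rows = []
    for gene, sub in per_snp.groupby("gene", observed=True):
        m = int(sub.informative.sum())
        r = int(sub.rejected.sum())
        if m == 0:
            decision, frac = "0", np.nan
        else:
            crit = stats.binom.ppf(0.95, m, alpha)
            decision = "X" if r > crit else "pass"
            frac = r / m
        rows.append({"gene": gene, "n_informative_snps": m,
                     "n_rejected_snps": r, "fraction_rejected": frac,
                     "refnonref_flag": decision})
    per_gene = pd.DataFrame(rows, columns=["gene", "n_informative_snps",
                                           "n_rejected_snps", "fraction_rejected",
                                           "refnonref_flag"])
    return per_snp, per_gene


def nearly_unbiased_test(ratios, s_max: float = 0.6,
                         ucl_max: float = 0.7) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Certify nearly unbiased expression per (individual, gene).

    UCL = S + z_0.975 * sqrt(S(1-S)/T); a cell passes when S <= s_max
    and UCL <= ucl_max.  Returns the per-cell table and the per-gene
    fraction of passing individuals.
    """
    cells = ratios.cells.copy()
    S = cells.S.to_numpy()
    T = cells["T"].to_numpy(dtype=float)
    cells["UCL"] = S + Z_0975 * np.sqrt(S * (1.0 - S) / T)
    cells["passes"] = (cells.S <= s_max) & (cells.UCL <= ucl_max)
    per_gene = (cells.groupby("gene", observed=True)["passes"].mean()
                .rename("unbiased_fraction").reset_index())
    return cells[["individual", "gene", "S", "T", "UCL", "passes"]], per_gene


def classify_prior_status(annotation: pd.DataFrame, known: list[str],
                          max_distance: int = 1_000_000) -> pd.DataFrame:
    """known_imprinted / nearby_candidate / distant_candidate per gene.

    A gene not on the known list is a nearby candidate when the minimal
    interval distance to any known imprinted gene on the same
    chromosome is below ``max_distance`` (overlap counts as distance
    0); otherwise it is a distant candidate.
    """
    required = {"gene", "chromosome", "start", "end"}
    if annotation[list(required)].isna().any().any():
        bad = annotation.loc[annotation[list(required)].isna().any(axis=1), "gene"]
        raise ValueError(f"missing coordinates for genes: {list(bad)}")
    known_set = set(known)
    ann = annotation.reset_index(drop=True)
    kn = ann[ann.gene.isin(known_set)]
    status = []
    for _, row in ann.iterrows():
        if row.gene in known_set:
            status.append("known_imprinted")
            continue
        same = kn[kn.chromosome == row.chromosome]
        if len(same):
            dist = np.maximum.reduce([
                same.start.to_numpy() - row.end,
                row.start - same.end.to_numpy(),
                np.zeros(len(same), dtype=np.int64)])
            if dist.min() < max_distance:
                status.append("nearby_candidate")
                continue
        status.append("distant_candidate")
    return ann.assign(prior_status=status)[["gene", "prior_status"]]


def call_imprinted(table: pd.DataFrame, top_n: int = 50,
                   manual_includes: list[str] | None = None) -> pd.DataFrame:
    """Final imprinted-gene calls from the ranked, annotated score table.

    A gene is called when it ranks within ``top_n`` and its prior
    status is known_imprinted or nearby_candidate, or when it is on the
    manual-include list (a curated rescue for established imprinted
    genes ranking just below the cutoff).
    """
    manual = set(manual_includes or [])
    absent = manual - set(table.gene)
    if absent:
        warnings.warn(f"manual includes not in score table, skipped: {sorted(absent)}")
    eligible = table.prior_status.isin(["known_imprinted", "nearby_candidate"])
    called = ((table["rank"] <= top_n) & eligible) | table.gene.isin(manual)
    return table.assign(called_imprinted=called)


def survival_curves(ratios, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene 1 - ECDF of S evaluated on a grid of cutoffs.

    Rows are genes, columns the grid points; each entry is the fraction
    of individuals with S strictly above the cutoff, so rows are
    monotone non-increasing along the grid.
    """
    grid = np.asarray(grid if grid is not None else np.linspace(0.5, 1.0, 51))
    if grid.min() < 0.5 - 1e-12 or grid.max() > 1.0 + 1e-12:
        raise ValueError("grid must lie within [0.5, 1]")
    cells = ratios.cells
    rows = {}
    for gene, sub in cells.groupby("gene", observed=True):
        s = np.sort(sub.S.to_numpy())
        rows[gene] = 1.0 - np.searchsorted(s, grid, side="right") / len(s)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"{g:.3f}" for g in grid])
    out.index.name = "gene"
    return out


def score_and_call(ratios, annotation: pd.DataFrame, known: list[str],
                   threshold: float = 0.9, alt_threshold: float = 0.7,
                   alpha: float = 0.05, min_informative: int = 10,
                   s_max: float = 0.6, ucl_max: float = 0.7, top_n: int = 50,
                   max_distance: int = 1_000_000,
                   manual_includes: list[str] | None = None) -> dict:
    """Run the whole calling stage; returns all tables keyed by name."""
    ranked = rank_genes(ratios, threshold, alt_threshold)
    per_snp, per_gene_rnr = ref_nonref_test(ratios.snp_detail, alpha, min_informative)
    per_cell, per_gene_unb = nearly_unbiased_test(ratios, s_max, ucl_max)
    prior = classify_prior_status(annotation, known, max_distance)
    table = (ranked.merge(per_gene_rnr, on="gene", how="left")
             .merge(per_gene_unb, on="gene", how="left")
             .merge(prior, on="gene", how="left"))
    table["refnonref_flag"] = table.refnonref_flag.fillna("0")
    table["prior_status"] = table.prior_status.fillna("distant_candidate")
    table = call_imprinted(table, top_n, manual_includes)
    return {"gene_table": table, "ref_nonref_snps": per_snp,
            "unbiased_cells": per_cell}
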