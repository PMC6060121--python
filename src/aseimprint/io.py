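"""Input readers, SNP-level filters and genotype-calibration checks.

Reads the four inputs of the pipeline — a genotype VCF (with per-call
heterozygosity confidence and an array/imputed source flag), a
tab-separated allele-count table, a sample-metadata table and a gene
annotation table — and applies the SNP quality filters and the
imputed-genotype calibration rules before any allelic-bias statistic is
computed.

Tables are plain pandas DataFrames with fixed column names; see the
module-level ``*_COLUMNS`` constants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["individual", "snp_id", "gene", "ref_count", "alt_count"]
GENOTYPE_COLUMNS = ["individual", "snp_id", "genotype", "l_het", "source"]
SNP_COLUMNS = ["snp_id", "chromosome", "position", "ref_allele", "alt_alleles",
               "known_in_dbsnp", "phred_quality", "gene"]
METADATA_COLUMNS = ["individual", "Dx", "Age", "Ancestry.1", "Ancestry.2",
                    "Ancestry.3", "Ancestry.4", "Ancestry.5", "Gender", "RIN",
                    "Institution", "RNA_batch"]
ANNOTATION_COLUMNS = ["gene", "chromosome", "start", "end", "prior_known"]

DX_LEVELS = ("Control", "SCZ", "AFF")

EXCLUSION_POLICIES = ("contradiction", "global", "off")


class ValidationError(ValueError):
    """Input fails a structural or semantic contract."""


@dataclass
class FilterTally:
    """Per-filter removal counts, in application order."""

    steps: list[tuple[str, int]]

    def as_dict(self) -> dict[str, int]:
        return dict(self.steps)


def read_genotype_vcf(path: str, lhet_field: str = "LH",
                      source_field: str = "SRC") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF 4.x genotype file.

    Returns ``(snps, genotypes)``: the SNP attribute table (one row per
    record; gene assignment from INFO/GENE, dbSNP status from INFO/DB,
    Phred quality from QUAL) and the genotype table with one row per
    (individual, record).  Heterozygosity confidence is taken from the
    per-sample ``lhet_field`` and the array/imputed flag from
    ``source_field``; array-sourced het calls must carry L_het == 1.

    Multiallelic records are preserved with all their alternative
    alleles; any genotype containing two distinct alleles is a het call.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    snp_rows = []
    geno_chunks = []
    for line_no, var in enumerate(vcf, start=1):
        info = dict(var.INFO)
        snp_rows.append({
            "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
            "chromosome": var.CHROM,
            "position": var.POS,
            "ref_allele": var.REF,
            "alt_alleles": ",".join(var.ALT),
            "known_in_dbsnp": bool(info.get("DB", False)),
            "phred_quality": float(var.QUAL) if var.QUAL is not None else 0.0,
            "gene": info.get("GENE", ""),
        })
        gts = var.genotype.array()[:, :2]
        het = gts[:, 0] != gts[:, 1]
        hom_alt = (gts[:, 0] > 0) & (gts[:, 1] > 0)
        genotype = np.where(het, "het", np.where(hom_alt, "hom_alt", "hom_ref"))
        try:
            lhet = np.asarray(var.format(lhet_field), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            lhet = None
        try:
            src_raw = var.format(source_field)
            source = np.asarray(src_raw).astype(str).ravel()
        except (KeyError, TypeError, ValueError):
            source = np.full(len(samples), "array")
        if lhet is None:
            if np.any((source == "imputed") & het):
                raise ValidationError(
                    f"VCF record {line_no} ({var.CHROM}:{var.POS}): imputed het "
                    f"call without FORMAT/{lhet_field}")
            lhet = np.ones(len(samples))
        lhet = np.where(source == "array", 1.0, lhet)
        geno_chunks.append(pd.DataFrame({
            "individual": samples,
            "snp_id": snp_rows[-1]["snp_id"],
            "genotype": genotype,
            "l_het": lhet,
            "source": source,
        }))
    snps = pd.DataFrame(snp_rows, columns=SNP_COLUMNS)
    genotypes = (pd.concat(geno_chunks, ignore_index=True)
                 if geno_chunks else pd.DataFrame(columns=GENOTYPE_COLUMNS))
    return snps, genotypes


def read_counts_table(path: str) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValidationError(f"counts table lacks columns {sorted(missing)}")
    dup = counts.duplicated(["individual", "snp_id"])
    if dup.any():
        raise ValidationError(
            "duplicated (individual, snp_id) rows; SNPs spanning several genes "
            "must be resolved upstream")
    if (counts[["ref_count", "alt_count"]] < 0).to_numpy().any():
        raise ValidationError("negative read counts")
    return counts[COUNT_COLUMNS]


def read_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata lacks columns {sorted(missing)}")
    if meta.Dx.isna().any() or not set(meta.Dx) <= set(DX_LEVELS):
        raise ValidationError(f"Dx must be one of {DX_LEVELS} with no missing values")
    if (meta.Age <= 0).any():
        raise ValidationError("ages must be positive")
    return meta


def read_annotation(path: str) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValidationError(f"annotation lacks columns {sorted(missing)}")
    if (ann.start > ann.end).any():
        raise ValidationError("gene intervals must satisfy start <= end")
    return ann


def filter_snps(snps: pd.DataFrame, counts: pd.DataFrame, min_phred: float = 20.0,
                require_known: bool = True, max_alleles: int = 2,
                min_reads_any_sample: int = 10) -> tuple[pd.DataFrame, FilterTally]:
    """SNP-level quality filters, applied sequentially.

    Keeps SNPs with Phred quality strictly above ``min_phred``, known in
    dbSNP (when required), at most ``max_alleles`` total alleles, and at
    least ``min_reads_any_sample`` mapped reads in at least one sample.
    SNPs absent from the count table count as zero reads everywhere.
    Returns the kept SNP table and per-filter removal tallies.
    """
    tally = []
    kept = snps
    n0 = len(kept)
    kept = kept[kept.phred_quality > min_phred]
    tally.append(("phred", n0 - len(kept)))
    if require_known:
        n0 = len(kept)
        kept = kept[kept.known_in_dbsnp.astype(bool)]
        tally.append(("novel", n0 - len(kept)))
    n0 = len(kept)
    n_alleles = kept.alt_alleles.str.split(",").str.len().fillna(0) + 1
    kept = kept[n_alleles <= max_alleles]
    tally.append(("multiallelic", n0 - len(kept)))
    n0 = len(kept)
    totals = counts.assign(T_s=counts.ref_count + counts.alt_count)
    max_cov = totals.groupby("snp_id", observed=True)["T_s"].max()
    cov = kept.snp_id.map(max_cov).fillna(0)
    kept = kept[cov >= min_reads_any_sample].reset_index(drop=True)
    tally.append(("low_coverage", n0 - len(kept)))
    return kept, FilterTally(tally)


def select_usable_het_calls(genotypes: pd.DataFrame, counts: pd.DataFrame,
                            l_het_cutoff: float = 0.95,
                            min_cov: int = 7) -> pd.DataFrame:
    """Heterozygous calls confident and covered enough to feed S.

    A call is usable when genotype == het, L_het >= ``l_het_cutoff``
    (inclusive; array calls have L_het == 1) and the RNA coverage at the
    SNP in that individual is >= ``min_cov`` (inclusive).
    """
    het = genotypes[(genotypes.genotype == "het") &
                    (genotypes.l_het >= l_het_cutoff)]
    totals = counts.assign(T_s=counts.ref_count + counts.alt_count)
    merged = het.merge(totals[["individual", "snp_id", "T_s"]],
                       on=["individual", "snp_id"], how="inner")
    usable = merged[merged.T_s >= min_cov]
    return usable[["individual", "snp_id", "source", "l_het"]].reset_index(drop=True)


def discordance_rate(counts: pd.DataFrame, usable: pd.DataFrame,
                     monoallelic_max_minor: int = 0) -> dict[str, float | None]:
    """DNA/RNA discordance per genotype source.

    A usable het call is discordant when its RNA counts are monoallelic:
    the minor allele has at most ``monoallelic_max_minor`` reads
    (default 0, the strictest reading).  Returns, per source, the
    fraction of discordant calls; ``None`` when a source has no usable
    calls (undefined, not zero).
    """
    merged = usable.merge(counts[["individual", "snp_id", "ref_count", "alt_count"]],
                          on=["individual", "snp_id"], how="inner")
    minor = np.minimum(merged.ref_count, merged.alt_count)
    merged = merged.assign(discordant=minor <= monoallelic_max_minor)
    rates: dict[str, float | None] = {}
    for source in ("array", "imputed"):
        sub = merged[merged.source == source]
        rates[source] = float(sub.discordant.mean()) if len(sub) else None
    return rates


def exclude_inconsistent_individuals(counts: pd.DataFrame, usable: pd.DataFrame,
                                     policy: str = "contradiction",
                                     min_cov: int = 7,
                                     monoallelic_max_minor: int = 0) -> pd.DataFrame:
    """Drop het calls of individuals whose imputed SNPs contradict each other.

    Imputation errors make a truly homozygous SNP look perfectly
    monoallelic; when two such errors (or an error plus genuine
    monoallelic expression) point at *opposite* alleles within one gene
    the individual's data for that gene cannot be trusted.

    Policies:

    - ``contradiction`` (default): within each (individual, gene), if
      the imputed het SNPs with coverage >= ``min_cov`` include at least
      one purely-reference and one purely-alternative monoallelic SNP,
      drop that individual's calls for that gene.
    - ``global``: same trigger, but the individual is dropped from every
      gene.
    - ``off``: return the usable set unchanged.
    """
    if policy not in EXCLUSION_POLICIES:
        raise ValidationError(
            f"unknown exclusion policy {policy!r}; choose from {EXCLUSION_POLICIES}")
    if policy == "off" or usable.empty:
        return usable
    merged = usable.merge(
        counts[["individual", "snp_id", "gene", "ref_count", "alt_count"]],
        on=["individual", "snp_id"], how="inner")
    imputed = merged[(merged.source == "imputed") &
                     (merged.ref_count + merged.alt_count >= min_cov)]
    mono_ref = imputed.alt_count <= monoallelic_max_minor
    mono_alt = imputed.ref_count <= monoallelic_max_minor
    flagged = imputed.assign(mono_ref=mono_ref & ~mono_alt,
                             mono_alt=mono_alt & ~mono_ref)
    per_block = flagged.groupby(["individual", "gene"], observed=True)[
        ["mono_ref", "mono_alt"]].any()
    bad_blocks = per_block[per_block.mono_ref & per_block.mono_alt].index
    if not len(bad_blocks):
        return usable
    if policy == "global":
        bad_ind = bad_blocks.get_level_values("individual").unique()
        return usable[~usable.individual.isin(bad_ind)].reset_index(drop=True)
    with_gene = usable.merge(counts[["individual", "snp_id", "gene"]],
                             on=["individual", "snp_id"], how="left")
    key = pd.MultiIndex.from_frame(with_gene[["individual", "gene"]])
    keep = ~key.isin(bad_blocks)
    return usable[keep].reset_index(drop=True)


def dx_margins(meta: pd.DataFrame) -> Counter:
    """Diagnosis-group sizes, e.g. Counter({'Control': 267, ...})."""
    return Counter(meta.Dx)
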