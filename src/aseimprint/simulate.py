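"""Synthetic cohort, genotype and allele-count generator.

Emulates the statistical structure of a large postmortem-brain ASE
study: a cohort of 579 individuals (267 controls, 258 with
schizophrenia, 54 with affective-spectrum disorder), thousands of
biallelically expressed genes among which a few dozen are imprinted,
SNP-array plus imputed DNA genotypes with imputation errors governed by
the heterozygosity confidence L_het, and RNA-seq allele counts drawn
from a (beta-)binomial read model whose success probability p_ig lies
in [0.5, 1) and is driven by gene-specific covariate effects on a
logistic link:

    p_ig = 0.5 + 0.5 * expit(eta_ig),
    eta_ig = mu_g + z(Age_i) * alpha_g + Ancestry.1_i * gamma1_g
             + Ancestry.3_i * gamma3_g + gender/dx offsets.

Reference-mapping-bias contaminants are genes whose higher-expressed
allele is *always* the reference allele; everything else assigns the
biased allele to ref or alt uniformly per (individual, SNP).  A ground
truth manifest accompanies every dataset so detection performance can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import COUNT_COLUMNS, GENOTYPE_COLUMNS

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort",
           "simulate_allelic_bias", "simulate_counts", "simulate_dataset",
           "write_dataset", "write_vcf"]

# Fixed standardisation of age inside the link; ages themselves stay in years.
AGE_CENTER = 55.0
AGE_SCALE = 20.0


class ConfigurationError(ValueError):
    pass


def default_error_curve(l_het: np.ndarray) -> np.ndarray:
    """Probability that an imputed het call is wrong, given L_het.

    Linear in the residual uncertainty: 0.6 * (1 - L_het), i.e. 3% at
    the L_het = 0.95 cutoff and 0 at full confidence.
    """
    return 0.6 * (1.0 - np.asarray(l_het, dtype=float))


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_individuals: int = 579
    dx_counts: dict = field(default_factory=lambda: {
        "Control": 267, "SCZ": 258, "AFF": 54})
    n_genes: int = 2000
    n_imprinted: int = 30
    mapping_bias_genes: int = 10
    n_unknown_imprinted: int = 4       # imprinted genes absent from the known list
    snps_per_gene_mean: float = 2.0    # SNPs per gene = 1 + Poisson(mean)
    mean_coverage: float = 20.0        # negative-binomial read depth per SNP
    coverage_dispersion: float = 5.0   # NB size parameter k
    rho: float = 0.0                   # beta-binomial overdispersion, 0 = binomial
    imprinted_p_range: tuple = (0.90, 0.99)
    contaminant_p_range: tuple = (0.85, 0.95)
    biallelic_mu: float = -6.0         # expit(-6) ~ 0.0025 -> p ~ 0.501
    age_slope_sd: float = 0.3          # on standardised age, imprinted genes
    ancestry_slope_sd: float = 0.3     # Ancestry.1 and Ancestry.3 slopes
    gender_offset_sd: float = 0.1
    dx_offset: float = 0.0             # no diagnosis effect by default
    array_fraction: float = 0.5        # fraction of SNPs on the DNA array
    novel_fraction: float = 0.05
    multiallelic_fraction: float = 0.02
    low_phred_fraction: float = 0.05
    imputation_error_curve: Callable[[np.ndarray], np.ndarray] = default_error_curve
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.dx_counts.values()) != self.n_individuals:
            raise ConfigurationError(
                f"dx_counts sum to {sum(self.dx_counts.values())}, "
                f"expected n_individuals = {self.n_individuals}")
        if not (self.n_imprinted + self.mapping_bias_genes <= self.n_genes):
            raise ConfigurationError("n_imprinted + contaminants exceeds n_genes")
        if not 0 <= self.rho < 1:
            raise ConfigurationError("rho must lie in [0, 1)")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What was actually simulated, for scoring the pipeline against."""

    genes: pd.DataFrame        # gene, status, known, p_baseline, coefficients
    p_matrix: pd.DataFrame     # individuals x genes true p_ig
    errors: pd.DataFrame       # erroneous imputed het calls, with true genotype


def simulate_cohort(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample metadata table: diagnosis, age, ancestry PCs, technical covariates."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_individuals
    dx = np.repeat(list(config.dx_counts), list(config.dx_counts.values()))
    meta = pd.DataFrame({
        "individual": [f"ind{i:04d}" for i in range(n)],
        "Dx": dx,
        "Age": np.round(rng.uniform(20, 95, n), 1),
        "Gender": rng.choice(["male", "female"], n, p=[0.6, 0.4]),
        "RIN": np.clip(np.round(rng.normal(7.8, 0.7, n), 2), 5.0, 10.0),
        "Institution": rng.choice(["Inst_A", "Inst_B", "Inst_C"], n,
                                  p=[0.45, 0.35, 0.20]),
        "RNA_batch": rng.choice([f"batch{b}" for b in range(1, 9)], n),
    })
    for j in range(1, 6):
        meta[f"Ancestry.{j}"] = np.round(rng.normal(0.0, 1.0, n), 4)
    return meta


def _simulate_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene catalogue with coordinates, true status and link coefficients.

    Imprinted genes are laid out in clusters (100 kb spacing) so the
    <1 Mb proximity rule is exercised; each cluster also gets one
    biallelic neighbour inside 1 Mb.  Contaminants and the remaining
    biallelic genes are placed far apart (3 Mb spacing) on a rotating
    set of chromosomes.
    """
    n = config.n_genes
    status = np.array(["biallelic"] * n, dtype=object)
    status[:config.n_imprinted] = "imprinted"
    status[config.n_imprinted:config.n_imprinted + config.mapping_bias_genes] = \
        "mapping_bias_contaminant"

    genes = pd.DataFrame({
        "gene": [f"GENE{i:05d}" for i in range(n)],
        "status": status,
    })
    mu = np.full(n, config.biallelic_mu)
    p_base = np.full(n, np.nan)
    imp = status == "imprinted"
    con = status == "mapping_bias_contaminant"
    p_base[imp] = rng.uniform(*config.imprinted_p_range, imp.sum())
    p_base[con] = rng.uniform(*config.contaminant_p_range, con.sum())
    # p = 1 is a valid degenerate case: mu = +inf, expit(inf) = 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_biased = np.log((p_base - 0.5) / (1.0 - p_base))  # logit((p-.5)/.5)
    mu[imp | con] = mu_biased[imp | con]
    genes["p_baseline"] = np.where(np.isnan(p_base), 0.5 + 0.5 * expit(mu), p_base)
    genes["mu"] = mu
    genes["alpha_age"] = np.where(imp, rng.normal(0, config.age_slope_sd, n), 0.0)
    genes["gamma1"] = np.where(imp, rng.normal(0, config.ancestry_slope_sd, n), 0.0)
    genes["gamma3"] = np.where(imp, rng.normal(0, config.ancestry_slope_sd, n), 0.0)
    genes["beta_gender"] = np.where(imp, rng.normal(0, config.gender_offset_sd, n), 0.0)
    genes["beta_dx"] = np.where(imp, config.dx_offset, 0.0)
    known = imp.copy()
    if config.n_unknown_imprinted and imp.sum():
        hide = rng.choice(np.flatnonzero(imp),
                          min(config.n_unknown_imprinted, imp.sum()), replace=False)
        known[hide] = False
    genes["known"] = known

    # Coordinates: imprinted clusters of ~4 genes + one biallelic neighbour.
    chrom = np.empty(n, dtype=object)
    start = np.zeros(n, dtype=np.int64)
    imp_idx = np.flatnonzero(imp)
    cluster_size = 4
    clusters = [imp_idx[i:i + cluster_size]
                for i in range(0, len(imp_idx), cluster_size)]
    bial_idx = list(np.flatnonzero(status == "biallelic"))
    neighbour_pool = bial_idx[:len(clusters)]
    far_pool = bial_idx[len(clusters):] + \
        list(np.flatnonzero(con))
    for c, members in enumerate(clusters):
        base = 10_000_000 + c * 20_000_000
        for j, gi in enumerate(members):
            chrom[gi] = f"chr{(c % 8) + 1}"
            start[gi] = base + j * 100_000
        if c < len(neighbour_pool):
            gi = neighbour_pool[c]
            chrom[gi] = f"chr{(c % 8) + 1}"
            start[gi] = base + cluster_size * 100_000 + 400_000  # < 1 Mb away
    for j, gi in enumerate(far_pool):
        chrom[gi] = f"chr{(j % 20) + 1}"
        start[gi] = 120_000_000 + (j // 20) * 3_000_000
    genes["chromosome"] = chrom
    genes["start"] = start
    genes["end"] = start + 20_000
    return genes


def _simulate_snps(config: SimulationConfig, genes: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    per_gene = 1 + rng.poisson(config.snps_per_gene_mean, len(genes))
    rows = genes.loc[genes.index.repeat(per_gene),
                     ["gene", "chromosome", "start"]].reset_index(drop=True)
    offset = rows.groupby("gene", observed=True).cumcount()
    n = len(rows)
    bases = np.array(["A", "C", "G", "T"])
    ref = rng.choice(bases, n)
    alt = rng.choice(bases, n)
    clash = alt == ref
    while clash.any():
        alt[clash] = rng.choice(bases, clash.sum())
        clash = alt == ref
    multi = rng.random(n) < config.multiallelic_fraction
    third = np.where(rng.random(n) < 0.5, "A", "G")
    third = np.where((third == ref) | (third == alt), "T", third)
    third = np.where((third == ref) | (third == alt), "C", third)
    alt_field = np.where(multi, np.char.add(np.char.add(alt.astype(str), ","),
                                            third.astype(str)), alt)
    phred = np.round(np.clip(rng.normal(45, 12, n), 1, 99), 1)
    low = rng.random(n) < config.low_phred_fraction
    phred[low] = np.round(rng.uniform(2, 20, low.sum()), 1)
    snps = pd.DataFrame({
        "snp_id": [f"rs{900000 + i}" for i in range(n)],
        "gene": rows.gene,
        "chromosome": rows.chromosome,
        "position": rows.start + 500 + offset * 700,
        "ref_allele": ref,
        "alt_alleles": alt_field,
        "known_in_dbsnp": rng.random(n) >= config.novel_fraction,
        "phred_quality": phred,
        "maf": rng.uniform(0.1, 0.5, n),
        "on_array": rng.random(n) < config.array_fraction,
    })
    return snps


def simulate_allelic_bias(config: SimulationConfig, metadata: pd.DataFrame,
                          genes: pd.DataFrame) -> pd.DataFrame:
    """True p_ig matrix (individuals x genes) from the logistic link."""
    z_age = (metadata.Age.to_numpy() - AGE_CENTER) / AGE_SCALE
    male = (metadata.Gender == "male").to_numpy(dtype=float)
    dx_case = (metadata.Dx != "Control").to_numpy(dtype=float)
    pc1 = metadata["Ancestry.1"].to_numpy()
    pc3 = metadata["Ancestry.3"].to_numpy()
    eta = (genes.mu.to_numpy()[None, :]
           + z_age[:, None] * genes.alpha_age.to_numpy()[None, :]
           + pc1[:, None] * genes.gamma1.to_numpy()[None, :]
           + pc3[:, None] * genes.gamma3.to_numpy()[None, :]
           + male[:, None] * genes.beta_gender.to_numpy()[None, :]
           + dx_case[:, None] * genes.beta_dx.to_numpy()[None, :])
    p = 0.5 + 0.5 * expit(eta)
    return pd.DataFrame(p, index=metadata.individual.to_numpy(),
                        columns=genes.gene.to_numpy())


def simulate_counts(config: SimulationConfig, p_matrix: pd.DataFrame,
                    genes: pd.DataFrame, snps: pd.DataFrame,
                    metadata: pd.DataFrame, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genotype calls, RNA-seq allele counts and the error manifest.

    Returns ``(counts, genotypes, errors)``.  Genotypes are Hardy-
    Weinberg draws per SNP MAF; imputed heterozygous calls flip to a
    truly homozygous underlying genotype with probability
    ``imputation_error_curve(l_het)``, which makes the RNA reads at
    those SNPs monoallelic.  Allele counts are emitted for called-het
    pairs only (homozygous calls are uninformative for S).
    """
    n_ind = len(metadata)
    n_snp = len(snps)
    maf = snps.maf.to_numpy()[:, None]
    u = rng.random((n_snp, n_ind))
    # 0 = hom_ref, 1 = het, 2 = hom_alt under HWE
    geno = np.where(u < (1 - maf) ** 2, 0,
                    np.where(u < (1 - maf) ** 2 + 2 * maf * (1 - maf), 1, 2))
    imputed = ~snps.on_array.to_numpy()
    l_het = np.ones((n_snp, n_ind))
    l_het[imputed] = rng.beta(30.0, 1.5, (imputed.sum(), n_ind))
    l_het = np.round(l_het, 4)

    het = geno == 1
    err_p = np.zeros((n_snp, n_ind))
    err_p[imputed] = config.imputation_error_curve(l_het[imputed])
    flipped = het & (rng.random((n_snp, n_ind)) < err_p)
    true_hom_alt = flipped & (rng.random((n_snp, n_ind)) < 0.5)

    # --- counts for called-het pairs ---
    si, ii = np.nonzero(het)
    T = rng.negative_binomial(
        config.coverage_dispersion,
        config.coverage_dispersion / (config.coverage_dispersion + config.mean_coverage),
        size=len(si))
    gene_of_snp = snps.gene.to_numpy()
    gene_pos = {g: j for j, g in enumerate(p_matrix.columns)}
    gj = np.fromiter((gene_pos[g] for g in gene_of_snp[si]), dtype=np.int64,
                     count=len(si))
    p_pair = p_matrix.to_numpy()[ii, gj]
    if config.rho > 0:
        nu = (1.0 - config.rho) / config.rho
        p_draw = rng.beta(p_pair * nu, (1.0 - p_pair) * nu)
    else:
        p_draw = p_pair
    B = rng.binomial(T, p_draw)
    contaminant = set(genes.gene[genes.status == "mapping_bias_contaminant"])
    is_con = np.isin(gene_of_snp[si], list(contaminant))
    to_ref = np.where(is_con, True, rng.random(len(si)) < 0.5)
    ref_count = np.where(to_ref, B, T - B)
    # erroneous het calls: all reads carry the single true allele
    fl = flipped[si, ii]
    ref_count = np.where(fl, np.where(true_hom_alt[si, ii], 0, T), ref_count)
    alt_count = T - ref_count

    snp_ids = snps.snp_id.to_numpy()
    ind_ids = metadata.individual.to_numpy()
    counts = pd.DataFrame({
        "individual": ind_ids[ii],
        "snp_id": snp_ids[si],
        "gene": gene_of_snp[si],
        "ref_count": ref_count.astype(np.int64),
        "alt_count": alt_count.astype(np.int64),
    })[COUNT_COLUMNS]

    # --- full genotype-call table ---
    call = np.where(het, "het", np.where(geno == 2, "hom_alt", "hom_ref"))
    genotypes = pd.DataFrame({
        "individual": np.tile(ind_ids, n_snp),
        "snp_id": np.repeat(snp_ids, n_ind),
        "genotype": call.ravel(),
        "l_het": np.where(imputed[:, None], l_het, 1.0).ravel(),
        "source": np.where(imputed, "imputed", "array").repeat(n_ind),
    })[GENOTYPE_COLUMNS]

    esi, eii = np.nonzero(flipped)
    errors = pd.DataFrame({
        "individual": ind_ids[eii],
        "snp_id": snp_ids[esi],
        "true_genotype": np.where(true_hom_alt[esi, eii], "hom_alt", "hom_ref"),
    })
    counts.attrs["geno_matrix"] = geno  # kept for the VCF writer
    return counts, genotypes, errors


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Full in-memory dataset: (metadata, genes, snps, counts, genotypes, truth)."""
    rng = np.random.default_rng(config.seed)
    metadata = simulate_cohort(config, rng)
    genes = _simulate_genes(config, rng)
    snps = _simulate_snps(config, genes, rng)
    p_matrix = simulate_allelic_bias(config, metadata, genes)
    counts, genotypes, errors = simulate_counts(
        config, p_matrix, genes, snps, metadata, rng)
    truth = GroundTruth(genes=genes.copy(), p_matrix=p_matrix, errors=errors)
    return metadata, genes, snps, counts, genotypes, truth


def write_vcf(path: Path, snps: pd.DataFrame, genotypes: pd.DataFrame,
              metadata: pd.DataFrame) -> None:
    """Write genotype calls as an uncompressed VCF 4.2 text file.

    FORMAT carries GT, the heterozygosity confidence LH and the
    array/imputed source flag SRC; INFO carries the gene assignment and
    the dbSNP-known flag; QUAL carries the SNP's Phred quality.
    """
    samples = metadata.individual.to_numpy()
    sample_pos = {s: j for j, s in enumerate(samples)}
    order = np.fromiter((sample_pos[s] for s in genotypes.individual),
                        dtype=np.int64, count=len(genotypes))
    snp_pos = {s: j for j, s in enumerate(snps.snp_id)}
    row = np.fromiter((snp_pos[s] for s in genotypes.snp_id),
                      dtype=np.int64, count=len(genotypes))
    gt_code = genotypes.genotype.map({"hom_ref": "0/0", "het": "0/1",
                                      "hom_alt": "1/1"}).to_numpy()
    gt_mat = np.empty((len(snps), len(samples)), dtype=object)
    gt_mat[row, order] = gt_code
    lh_mat = np.empty((len(snps), len(samples)), dtype=object)
    lh_mat[row, order] = np.char.mod("%.4f", genotypes.l_het.to_numpy())
    src = snps.on_array.map({True: "array", False: "imputed"}).to_numpy() \
        if "on_array" in snps else np.full(len(snps), "array")

    snps_sorted = snps.sort_values(["chromosome", "position"]).reset_index()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(snps_sorted.chromosome.unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene assignment">\n')
        fh.write('##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=LH,Number=1,Type=Float,Description='
                 '"Heterozygosity confidence L_het">\n')
        fh.write('##FORMAT=<ID=SRC,Number=1,Type=String,Description='
                 '"Genotype source: array or imputed">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for _, rec in snps_sorted.iterrows():
            i = rec["index"]
            info = f"GENE={rec.gene}" + (";DB" if rec.known_in_dbsnp else "")
            fields = [rec.chromosome, str(rec.position), rec.snp_id,
                      rec.ref_allele, rec.alt_alleles, f"{rec.phred_quality:g}",
                      "PASS", info, "GT:LH:SRC"]
            cells = [f"{gt_mat[i, j]}:{lh_mat[i, j]}:{src[i]}"
                     for j in range(len(samples))]
            fh.write("\t".join(fields + cells) + "\n")


def write_dataset(outdir: str | Path, config: SimulationConfig) -> GroundTruth:
    """Simulate and write the full input set of the analysis pipeline.

    Emits counts.tsv, genotypes.vcf, metadata.tsv, annotation.tsv,
    known_imprinted.txt plus the ground-truth manifest
    (truth_genes.tsv, truth_errors.tsv).  Returns the in-memory truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata, genes, snps, counts, genotypes, truth = simulate_dataset(config)
    counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    meta_cols = ["individual", "Dx", "Age", "Ancestry.1", "Ancestry.2",
                 "Ancestry.3", "Ancestry.4", "Ancestry.5", "Gender", "RIN",
                 "Institution", "RNA_batch"]
    metadata[meta_cols].to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    ann = genes[["gene", "chromosome", "start", "end", "known"]].rename(
        columns={"known": "prior_known"})
    ann.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    with open(outdir / "known_imprinted.txt", "w") as fh:
        for g in genes.gene[genes.known]:
            fh.write(g + "\n")
    write_vcf(outdir / "genotypes.vcf", snps, genotypes, metadata)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False,
                       float_format="%.6g")
    truth.errors.to_csv(outdir / "truth_errors.tsv", sep="\t", index=False)
    return truth
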