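"""End-to-end orchestration: simulate -> quantify -> call -> model.

`RunConfig` gathers every stage threshold (defaults are the analysis's
canonical values), the model formula and the seed; `run_pipeline`
executes the stages in order, writes fixed-column TSV outputs (floats
at 6 significant digits, missing values as "NA") and a machine-readable
run manifest, and is a pure function of (inputs, config, seed): two
runs with identical inputs produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calls, io, models, quantify, simulate

FLOAT_FORMAT = "%.6g"
NA_TOKEN = "NA"


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the canonical thresholds."""

    counts: str = ""
    genotypes: str = ""
    metadata: str = ""
    annotation: str = ""
    known_imprinted: str = ""
    out: str = "results"
    seed: int = 0
    # SNP / genotype filters
    min_phred: float = 20.0
    require_known: bool = True
    max_alleles: int = 2
    min_reads_any_sample: int = 10
    l_het_cutoff: float = 0.95
    min_cov: int = 7
    exclusion_policy: str = "contradiction"
    monoallelic_max_minor: int = 0
    # quantification
    t_rc: int = 15
    t_ind: int = 25
    pseudo_count: float = 1.0
    # calling
    score_threshold: float = 0.9
    alt_threshold: float = 0.7
    top_n: int = 50
    nearby_distance: int = 1_000_000
    alpha: float = 0.05
    min_informative: int = 10
    s_max: float = 0.6
    ucl_max: float = 0.7
    manual_includes: list = field(default_factory=list)
    # modelling
    model_spec: str = "Q ~ RIN + (1|RNA_batch) + (Age + Ancestry.1 | Gene)"
    test_terms: list = field(default_factory=lambda: ["(1|Dx)"])
    fit_models: bool = True

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise io.ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    PATH_FIELDS = ("counts", "genotypes", "metadata", "annotation",
                   "known_imprinted", "out")

    def digest(self) -> str:
        """Hash of the analytic parameters (file locations excluded)."""
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k not in self.PATH_FIELDS}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
              na_rep=NA_TOKEN)


def _log(fh, **kv) -> None:
    line = " ".join(f"{k}={v}" for k, v in kv.items())
    print(line, file=fh)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, log=sys.stderr) -> dict:
    """Execute all stages; returns the result tables keyed by name.

    Writes per-stage TSVs plus ``manifest.json`` under ``config.out``.
    A stage error aborts with the failing stage named; an empty result
    (e.g. no gene survives filtering) is reported, not raised.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    tallies: dict = {}

    stage = "load"
    try:
        snps, genotypes = io.read_genotype_vcf(config.genotypes)
        counts = io.read_counts_table(config.counts)
        metadata = io.read_metadata(config.metadata)
        annotation = io.read_annotation(config.annotation)
        known = [line.strip() for line in open(config.known_imprinted)
                 if line.strip()] if config.known_imprinted else []

        stage = "ase_data"
        kept_snps, tally = io.filter_snps(
            snps, counts, config.min_phred, config.require_known,
            config.max_alleles, config.min_reads_any_sample)
        tallies["snp_filters"] = tally.as_dict()
        counts = counts[counts.snp_id.isin(set(kept_snps.snp_id))]
        genotypes = genotypes[genotypes.snp_id.isin(set(kept_snps.snp_id))]
        usable = io.select_usable_het_calls(
            genotypes, counts, config.l_het_cutoff, config.min_cov)
        known_set = set(known)
        calib_counts = counts[~counts.gene.isin(known_set)]
        disc = io.discordance_rate(calib_counts, usable,
                                   config.monoallelic_max_minor)
        n_before = len(usable)
        usable = io.exclude_inconsistent_individuals(
            counts, usable, config.exclusion_policy, config.min_cov,
            config.monoallelic_max_minor)
        tallies["usable_het_calls"] = {"before_exclusion": n_before,
                                       "after_exclusion": len(usable)}
        results["discordance"] = disc
        _log(log, stage=stage, usable_calls=len(usable),
             array_discordance=disc["array"], imputed_discordance=disc["imputed"])

        stage = "quantify"
        ratios = quantify.read_count_ratio(counts, usable)
        n_genes_raw = ratios.cells.gene.nunique()
        ratios = quantify.quality_filter(ratios, config.t_rc, config.t_ind)
        params = quantify.TransformParams(pseudo_count=config.pseudo_count)
        ratios = quantify.quasi_log(ratios, params)
        ratios = quantify.rank_transform(ratios, params)
        results["ratios"] = ratios
        tallies["quality_filter"] = {
            "genes_before": int(n_genes_raw),
            "genes_after": int(ratios.cells.gene.nunique())}
        _write(ratios.cells, outdir / "ratios.tsv")
        _log(log, stage=stage, genes_before=n_genes_raw,
             genes_after=ratios.cells.gene.nunique(), cells=ratios.n_cells)
        if not ratios.n_cells:
            _log(log, stage=stage, note="no cells survive filtering; stopping")
            _write_manifest(outdir, config, tallies, results)
            return results

        stage = "call"
        called = calls.score_and_call(
            ratios, annotation, known, config.score_threshold,
            config.alt_threshold, config.alpha, config.min_informative,
            config.s_max, config.ucl_max, config.top_n,
            config.nearby_distance, config.manual_includes)
        results.update(called)
        grid = np.round(np.linspace(0.5, 1.0, 51), 3)
        surv = calls.survival_curves(ratios, grid)
        results["survival"] = surv
        _write(called["gene_table"], outdir / "gene_scores.tsv")
        _write(called["ref_nonref_snps"], outdir / "ref_nonref_snps.tsv")
        _write(called["unbiased_cells"], outdir / "unbiased_cells.tsv")
        _write(surv, outdir / "survival_curves.tsv", index=True)
        n_called = int(called["gene_table"].called_imprinted.sum())
        _log(log, stage=stage, called_imprinted=n_called)

        stage = "model"
        if config.fit_models and n_called:
            gt = called["gene_table"]
            called_genes = set(gt.gene[gt.called_imprinted])
            sub = quantify.RatioMatrix(
                cells=ratios.cells[ratios.cells.gene.isin(called_genes)],
                snp_detail=ratios.snp_detail)
            frame = models.assemble_model_frame(sub, metadata)
            spec = models.parse_model_spec(config.model_spec)
            fit = models.fit_mixed(models.build_design(frame, spec))
            results["mixed_fit"] = fit
            beta = pd.DataFrame({"term": fit.beta.index,
                                 "estimate": fit.beta.to_numpy()})
            _write(beta, outdir / "fixed_coefficients.tsv")
            _write(models.predict_random_coefficients(fit),
                   outdir / "random_coefficients.tsv")
            diag = models.residual_diagnostics(fit.residuals, fit.fitted)
            results["diagnostics"] = diag
            tests = []
            for term in config.test_terms:
                try:
                    tr = models.test_term(frame, spec, term)
                except models.ModelError as exc:
                    _log(log, stage=stage, term=term, skipped=str(exc))
                    continue
                tests.append(dataclasses.asdict(tr))
            term_table = pd.DataFrame(
                tests, columns=["term", "delta_aic", "chi2", "df", "p_value",
                                "aic_without", "aic_with"])
            results["term_tests"] = term_table
            _write(term_table, outdir / "term_tests.tsv")
            _log(log, stage=stage, aic=f"{fit.aic:.4f}",
                 loglik=f"{fit.loglik:.4f}", converged=fit.converged)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    _write_manifest(outdir, config, tallies, results)
    return results


def _write_manifest(outdir: Path, config: RunConfig, tallies: dict,
                    results: dict) -> None:
    import aseimprint

    table_hashes = {}
    for f in sorted(outdir.glob("*.tsv")):
        table_hashes[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {
        "package_version": aseimprint.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "filter_tallies": tallies,
        "table_hashes": table_hashes,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def simulate_inputs(outdir: str | Path, sim_config: simulate.SimulationConfig
                    ) -> simulate.GroundTruth:
    """Write a synthetic input set (stage `simulate` of run-all)."""
    return simulate.write_dataset(outdir, sim_config)


def input_config_for(directory: str | Path, out: str | Path,
                     seed: int = 0, **overrides) -> RunConfig:
    """RunConfig pointing at a directory written by `simulate_inputs`."""
    d = Path(directory)
    return RunConfig(counts=str(d / "counts.tsv"),
                     genotypes=str(d / "genotypes.vcf"),
                     metadata=str(d / "metadata.tsv"),
                     annotation=str(d / "annotation.tsv"),
                     known_imprinted=str(d / "known_imprinted.txt"),
                     out=str(out), seed=seed, **overrides)
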