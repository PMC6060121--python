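import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from aseimprint import pipeline
from aseimprint.simulate import SimulationConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


SMALL_CONFIG = SimulationConfig(
    n_individuals=60, dx_counts={"Control": 30, "SCZ": 20, "AFF": 10},
    n_genes=80, n_imprinted=8, mapping_bias_genes=3, n_unknown_imprinted=2,
    seed=42)


@pytest.fixture(scope="session")
def small_dataset():
    """In-memory synthetic dataset small enough for fast unit tests."""
    from aseimprint.simulate import simulate_dataset
    meta, genes, snps, counts, genotypes, truth = simulate_dataset(SMALL_CONFIG)
    return {"metadata": meta, "genes": genes, "snps": snps, "counts": counts,
            "genotypes": genotypes, "truth": truth}


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Small dataset written to disk and run through the full pipeline."""
    indir = tmp_path_factory.mktemp("inputs")
    outdir = tmp_path_factory.mktemp("outputs")
    truth = pipeline.simulate_inputs(indir, SMALL_CONFIG)
    cfg = pipeline.input_config_for(indir, outdir, seed=42, t_ind=10)
    results = pipeline.run_pipeline(cfg)
    return {"config": cfg, "results": results, "truth": truth,
            "indir": indir, "outdir": outdir}


def toy_counts(rows):
    """Counts table from (individual, snp, gene, ref, alt) tuples."""
    return pd.DataFrame(rows, columns=["individual", "snp_id", "gene",
                                       "ref_count", "alt_count"])


def usable_of(counts):
    return counts[["individual", "snp_id"]].drop_duplicates()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
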