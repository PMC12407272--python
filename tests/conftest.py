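import pandas as pd
import pytest

from subdom.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Small but complete synthetic bundle shared across tests."""
    cfg = SimConfig(n_chrom_per_subgenome=2, genes_per_chrom=150, seed=11)
    outdir = tmp_path_factory.mktemp("bundle_small")
    return generate_dataset(cfg, outdir=outdir)


@pytest.fixture(scope="session")
def medium_bundle():
    """Medium in-memory bundle for recovery/scoring tests."""
    cfg = SimConfig(n_chrom_per_subgenome=2, genes_per_chrom=600, seed=23)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def medium_peaks(medium_bundle):
    """Called CTL/WL peaks for the medium bundle (cached, expensive)."""
    from subdom.m6a import call_peaks

    return {cond: call_peaks(medium_bundle.m6a_windows, cond)
            for cond in ("CTL", "WL")}


@pytest.fixture(scope="session")
def diff_m6a_sim():
    """Simulation with ~500 differential-level m6A peaks planted."""
    from subdom.synthetic import (
        simulate_expression,
        simulate_genome_and_genes,
        simulate_m6a,
    )

    cfg = SimConfig(n_chrom_per_subgenome=2, genes_per_chrom=1200,
                    m6a_diff_fraction=0.2, seed=31)
    _, genes, anc, models = simulate_genome_and_genes(cfg)
    counts, samples, truth_bias, truth_deg = simulate_expression(genes, anc,
                                                                 cfg)
    windows, truth_peaks = simulate_m6a(models, anc, truth_deg, cfg)
    return {"config": cfg, "genes": genes, "counts": counts,
            "samples": samples, "truth_deg": truth_deg,
            "windows": windows, "truth_peaks": truth_peaks}


@pytest.fixture()
def toy_genes():
    """Two chromosomes, two genes each, deterministic layout."""
    return pd.DataFrame(
        {
            "gene_id": ["a1", "a2", "b1", "b2"],
            "chrom": ["chr01A", "chr01A", "chr01B", "chr01B"],
            "subgenome": ["A", "A", "B", "B"],
            "strand": ["+", "-", "+", "-"],
            "start": [10_000, 50_000, 10_000, 50_000],
            "end": [12_000, 52_000, 12_000, 52_000],
        }
    )
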