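import numpy as np
import pytest

from seedmod import (
    SimConfig,
    apply_lof_filter,
    compute_coexpression,
    harmonize,
    score_genes,
    simulate_networks,
)


@pytest.fixture()
def tiny_expression_tsv(tmp_path):
    """3 genes x 4 samples, plain well-formed TSV."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tS1\tS2\tS3\tS4\n"
        "GENE1\t1.0\t2.0\t3.0\t4.0\n"
        "GENE2\t4.0\t3.0\t2.0\t1.0\n"
        "GENE3\t1.5\t1.5\t2.5\t0.5\n"
    )
    return path


@pytest.fixture(scope="session")
def small_instance():
    """One modest planted instance shared by read-only tests.

    120 genes, 12-gene planted set; harmonized networks plus LOF-filtered
    seed scores, with the ground truth attached.
    """
    cfg = SimConfig(
        n_genes=120,
        planted_size=12,
        n_cases=200,
        n_controls=200,
        n_high_lof=8,
        rng_seed=42,
    )
    expr, graph, counts, truth = simulate_networks(cfg)
    corr = compute_coexpression(expr)
    universe, corr, graph = harmonize(corr, graph, counts)
    scores = apply_lof_filter(score_genes(corr, truth.seed), counts)
    return {
        "cfg": cfg,
        "universe": universe,
        "corr": corr,
        "graph": graph,
        "counts": counts,
        "scores": scores,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
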