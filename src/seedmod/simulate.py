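"""Synthetic inputs with a planted seed-centred module and known truth.

The generator emulates the statistical structure the discovery pipeline
assumes: a planted gene set whose expression shares a single latent
factor (so every planted pair has expected Pearson correlation
``rho_in``), an Erdos-Renyi-style PPI layer that is denser inside the
planted set (``density_in``) than outside (``density_bg``, with a
spanning path guaranteeing planted connectivity), low-mean control LOF
counts with optional inflated "constraint-violating" genes, case/control
de novo variant tables in which case non-synonymous mutations hit
planted genes ``enrichment_factor`` times more often, and a CNV table
with a configurable case bias toward planted genes.

Each sub-generator derives its random stream from (rng_seed, stage
index) so the three outputs are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from seedmod.errors import InputError
from seedmod.network_io import ControlVariantCounts, ExpressionMatrix

#: Concrete functional-class labels emitted per coarse class.
CLASS_LABELS = {
    "LOF": ("frameshift", "stop-gained", "splice-donor", "splice-acceptor"),
    "missense": ("missense", "missense-near-splice"),
    "synonymous": ("synonymous",),
    "other": ("intron", "intergenic"),
}

#: Coarse mutation-class mix per de novo event (roughly a coding de novo
#: spectrum: missense most common, ~2:1 missense:synonymous, LOF rarer).
CLASS_MIX = {"missense": 0.42, "LOF": 0.15, "synonymous": 0.28, "other": 0.15}

CASE_COHORTS = ("ASD", "ID", "DD", "EPI")
CASE_COHORT_PROBS = (0.5, 0.2, 0.2, 0.1)


@dataclass
class SimConfig:
    """Study conditions for one synthetic instance.

    Defaults describe the planted-module benchmark: 500 genes x 50
    samples, a 30-gene planted set with within-set correlation 0.9 and
    PPI density 0.5 over a 0.02 background, and cohorts of 1000 cases
    and 1000 controls averaging one de novo mutation per individual
    with a 5x case enrichment on planted genes (non-synonymous only).
    """

    n_genes: int = 500
    n_samples: int = 50
    planted_size: int = 30
    rho_in: float = 0.9
    rho_bg: float = 0.0
    density_in: float = 0.5
    density_bg: float = 0.02
    lof_mean: float = 0.5
    n_high_lof: int = 25
    high_lof_count: int = 20
    n_cases: int = 1000
    n_controls: int = 1000
    mutation_rate_per_individual: float = 1.0
    enrichment_factor: float = 5.0
    cnv_rate: float = 0.5
    cnv_case_bias: float = 4.0
    cnv_mean_genes: float = 3.0
    gene_length: int = 10_000
    gene_gap: int = 2_000
    gene_weights: np.ndarray | None = None  # length proxy for mutation placement
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.planted_size < self.n_genes):
            raise InputError("planted_size must be in (0, n_genes)")
        if not (0.0 <= self.rho_bg < self.rho_in <= 1.0):
            raise InputError("need 0 <= rho_bg < rho_in <= 1")
        if not (0.0 <= self.density_bg < self.density_in <= 1.0):
            raise InputError("need 0 <= density_bg < density_in <= 1")
        if self.enrichment_factor < 1.0:
            raise InputError("enrichment_factor must be >= 1")
        if self.n_samples < 2:
            raise InputError("need at least 2 expression samples")
        if self.gene_weights is not None and len(self.gene_weights) != self.n_genes:
            raise InputError("gene_weights length must equal n_genes")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["gene_weights"] is not None:
            d["gene_weights"] = list(map(float, d["gene_weights"]))
        return d


@dataclass
class TruthSet:
    """Ground truth for one instance: planted genes, seed, case gene weights."""

    planted: list[str]
    seed: str
    case_gene_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed not in self.planted:
            raise InputError("seed must be a planted gene")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            fh.write("gene\tcase_weight\n")
            for g in self.planted:
                fh.write(f"{g}\t{self.case_gene_weights.get(g, 1.0):.10g}\n")


def benchmark_grid(cfg: SimConfig):
    """Constraint grid for the planted-recovery benchmark on this config.

    One cell: a size band around the planted size, a minimum mean seed
    co-expression one sampling-noise band below the planted pairwise
    correlation, and a PPI-density floor between the background and
    planted densities.
    """
    from seedmod.module_assembly import Constraints

    lo = max(2, cfg.planted_size - 10)
    hi = cfg.planted_size + 10
    return [Constraints(lo, hi, max(0.0, cfg.rho_in - 0.05), 0.10)]


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.rng_seed, stage])


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_networks(cfg: SimConfig):
    """Expression, PPI graph, control LOF counts, and the truth set.

    Planted genes share one latent factor: expression = sqrt(rho_in) * z
    + sqrt(1 - rho_in) * noise per sample, giving expected pairwise
    Pearson correlation rho_in within the planted set.  Background genes
    optionally share their own factor at rho_bg (pure noise when 0).
    """
    rng = _rng(cfg, 0)
    genes = gene_names(cfg.n_genes)
    planted_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.planted_size, replace=False))
    planted = [genes[i] for i in planted_idx]
    seed = planted[int(rng.integers(len(planted)))]

    z = rng.standard_normal(cfg.n_samples)
    values = np.empty((cfg.n_genes, cfg.n_samples))
    is_planted = np.zeros(cfg.n_genes, dtype=bool)
    is_planted[planted_idx] = True
    noise = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    a_in = math.sqrt(cfg.rho_in)
    b_in = math.sqrt(1.0 - cfg.rho_in)
    values[is_planted] = a_in * z[None, :] + b_in * noise[is_planted]
    if cfg.rho_bg > 0:
        z_bg = rng.standard_normal(cfg.n_samples)
        a_bg, b_bg = math.sqrt(cfg.rho_bg), math.sqrt(1.0 - cfg.rho_bg)
        values[~is_planted] = a_bg * z_bg[None, :] + b_bg * noise[~is_planted]
    else:
        values[~is_planted] = noise[~is_planted]
    expr = ExpressionMatrix(genes, [f"S{j:03d}" for j in range(cfg.n_samples)], values)

    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    p_edge = np.where(
        is_planted[iu] & is_planted[ju], cfg.density_in, cfg.density_bg
    )
    drawn = rng.random(len(iu)) < p_edge
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from(
        (genes[i], genes[j]) for i, j in zip(iu[drawn], ju[drawn])
    )
    # guarantee the planted induced subgraph is connected
    order = rng.permutation(cfg.planted_size)
    for k in range(len(order) - 1):
        graph.add_edge(planted[order[k]], planted[order[k + 1]])

    lof = rng.poisson(cfg.lof_mean, cfg.n_genes)
    background_idx = np.flatnonzero(~is_planted)
    n_high = min(cfg.n_high_lof, len(background_idx))
    if n_high > 0:
        violators = rng.choice(background_idx, size=n_high, replace=False)
        lof[violators] += cfg.high_lof_count
    counts = ControlVariantCounts({g: int(c) for g, c in zip(genes, lof)})

    base = cfg.gene_weights if cfg.gene_weights is not None else np.ones(cfg.n_genes)
    case_w = np.asarray(base, dtype=float).copy()
    case_w[is_planted] *= cfg.enrichment_factor
    truth = TruthSet(
        planted=planted,
        seed=seed,
        case_gene_weights={g: float(w) for g, w in zip(genes, case_w)},
    )
    return expr, graph, counts, truth


def simulate_variants(cfg: SimConfig, truth: TruthSet) -> pd.DataFrame:
    """Case/control de novo variant records.

    Per-individual mutation counts are Poisson with the configured mean;
    each mutation gets a coarse class from CLASS_MIX, a concrete
    functional-class label, a gene (uniform by default, planted genes
    up-weighted by enrichment_factor for case non-synonymous mutations
    only), and a CADD score from a class-specific normal distribution.
    """
    rng = _rng(cfg, 1)
    genes = gene_names(cfg.n_genes)
    base_w = (
        np.asarray(cfg.gene_weights, dtype=float)
        if cfg.gene_weights is not None
        else np.ones(cfg.n_genes)
    )
    case_w = np.array([truth.case_gene_weights[g] for g in genes])

    coarse_names = list(CLASS_MIX)
    coarse_probs = np.array([CLASS_MIX[c] for c in coarse_names])
    gene_arr = np.array(genes, dtype=object)
    base_p = base_w / base_w.sum()
    case_p = case_w / case_w.sum()
    cadd_loc = {"LOF": 35.0, "missense": 15.0, "synonymous": 4.0, "other": 2.0}
    cadd_scale = {"LOF": 4.0, "missense": 8.0, "synonymous": 3.0, "other": 2.0}

    frames = []
    for arm, n_ind, prefix in (("case", cfg.n_cases, "P"), ("control", cfg.n_controls, "C")):
        n_muts = rng.poisson(cfg.mutation_rate_per_individual, n_ind)
        if arm == "case":
            cohorts = rng.choice(CASE_COHORTS, size=n_ind, p=CASE_COHORT_PROBS)
        else:
            cohorts = np.array(["control"] * n_ind)
        total = int(n_muts.sum())
        owner = np.repeat(np.arange(n_ind), n_muts)
        coarse_idx = rng.choice(len(coarse_names), size=total, p=coarse_probs)
        coarse = np.array(coarse_names, dtype=object)[coarse_idx]
        enriched = (arm == "case") & np.isin(coarse, ("LOF", "missense"))
        gene_col = np.empty(total, dtype=object)
        n_enr = int(enriched.sum())
        if n_enr:
            gene_col[enriched] = gene_arr[rng.choice(cfg.n_genes, size=n_enr, p=case_p)]
        if total - n_enr:
            gene_col[~enriched] = gene_arr[
                rng.choice(cfg.n_genes, size=total - n_enr, p=base_p)
            ]
        label_col = np.empty(total, dtype=object)
        cadd_col = np.empty(total)
        for cname in coarse_names:
            mask = coarse == cname
            k = int(mask.sum())
            if not k:
                continue
            labels = CLASS_LABELS[cname]
            label_col[mask] = np.array(labels, dtype=object)[rng.integers(len(labels), size=k)]
            cadd_col[mask] = np.clip(
                rng.normal(cadd_loc[cname], cadd_scale[cname], size=k), 0.0, None
            )
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [f"{prefix}{i:05d}" for i in owner],
                    "group": arm,
                    "cohort": cohorts[owner].astype(str) if total else np.array([], dtype=str),
                    "gene": gene_col,
                    "functional_class": label_col,
                    "cadd": np.round(cadd_col, 2),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[
        ["sample_id", "group", "cohort", "gene", "functional_class", "cadd"]
    ]


def gene_intervals(cfg: SimConfig) -> pd.DataFrame:
    """Tile genes along one synthetic chromosome (0-based half-open)."""
    genes = gene_names(cfg.n_genes)
    pitch = cfg.gene_length + cfg.gene_gap
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [i * pitch for i in range(cfg.n_genes)],
            "end": [i * pitch + cfg.gene_length for i in range(cfg.n_genes)],
            "gene": genes,
        }
    )


def simulate_cnvs(cfg: SimConfig, truth: TruthSet):
    """CNV table plus gene intervals; case CNVs prefer planted genes.

    Each individual carries Poisson(cnv_rate) CNVs; a CNV anchors at a
    gene (planted genes up-weighted by cnv_case_bias for cases) and
    spans 1 + Poisson(cnv_mean_genes - 1) consecutive genes.
    """
    rng = _rng(cfg, 2)
    genes = gene_names(cfg.n_genes)
    intervals = gene_intervals(cfg)
    starts = intervals["start"].to_numpy()
    ends = intervals["end"].to_numpy()
    planted_mask = np.isin(np.array(genes), np.array(truth.planted))

    records: list[dict] = []
    for arm, n_ind, prefix in (("case", cfg.n_cases, "P"), ("control", cfg.n_controls, "C")):
        w = np.ones(cfg.n_genes)
        if arm == "case":
            w[planted_mask] *= cfg.cnv_case_bias
        p = w / w.sum()
        n_cnvs = rng.poisson(cfg.cnv_rate, n_ind)
        for i in range(n_ind):
            for _ in range(n_cnvs[i]):
                anchor = int(rng.choice(cfg.n_genes, p=p))
                span = 1 + int(rng.poisson(max(cfg.cnv_mean_genes - 1.0, 0.0)))
                last = min(anchor + span - 1, cfg.n_genes - 1)
                start = int(max(starts[anchor] - rng.integers(0, cfg.gene_gap + 1), 0))
                end = int(ends[last] + rng.integers(0, cfg.gene_gap + 1))
                records.append(
                    {
                        "chrom": "chr1",
                        "start": start,
                        "end": end,
                        "sample_id": f"{prefix}{i:05d}",
                        "group": arm,
                        "type": "del" if rng.random() < 0.5 else "dup",
                    }
                )
    cnvs = pd.DataFrame(
        records, columns=["chrom", "start", "end", "sample_id", "group", "type"]
    )
    return cnvs, intervals


def write_bundle(cfg: SimConfig, outdir, header_lines: list[str] | None = None) -> dict:
    """Write a full synthetic input bundle as TSV files; returns the paths.

    Emits: expression.tsv, ppi.tsv, control_lof.tsv, variants.tsv,
    cnvs.tsv, gene_intervals.tsv, phenotype.tsv (planted genes annotated
    as 'planted_phenotype'), and truth.tsv.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    expr, graph, counts, truth = simulate_networks(cfg)
    variants = simulate_variants(cfg, truth)
    cnvs, intervals = simulate_cnvs(cfg, truth)

    def _write(df: pd.DataFrame, name: str, header=True, index=False, index_label=None):
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(line + "\n")
            df.to_csv(fh, sep="\t", header=header, index=index,
                      index_label=index_label, float_format="%.10g")
        return path

    paths = {}
    expr_df = pd.DataFrame(expr.values, index=expr.genes, columns=expr.samples)
    paths["expression"] = _write(expr_df, "expression.tsv", index=True, index_label="gene")
    edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in graph.edges()))
    paths["ppi"] = _write(edges, "ppi.tsv", header=False)
    lof_df = pd.DataFrame(sorted(counts.items()), columns=["gene", "lof_count"])
    paths["control_lof"] = _write(lof_df, "control_lof.tsv", header=False)
    paths["variants"] = _write(variants, "variants.tsv")
    paths["cnvs"] = _write(cnvs, "cnvs.tsv")
    paths["gene_intervals"] = _write(intervals, "gene_intervals.tsv")
    pheno = pd.DataFrame({"phenotype": "planted_phenotype", "gene": truth.planted})
    paths["phenotype"] = _write(pheno, "phenotype.tsv", header=False)
    truth_path = os.path.join(outdir, "truth.tsv")
    truth.to_tsv(truth_path)
    paths["truth"] = truth_path
    return paths
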