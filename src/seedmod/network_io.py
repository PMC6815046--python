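"""Reading, validation, and harmonization of the three network inputs.

The module discovery pipeline consumes three data layers over gene
symbols: a genes x samples expression matrix (from which a pairwise
Pearson co-expression matrix is derived), one or more undirected PPI
edge lists which are merged by union, and per-gene counts of
loss-of-function variants seen in control individuals.  ``harmonize``
restricts the co-expression matrix and interaction graph to their
common gene universe; control counts default to 0 for unseen genes.

Gene identifiers are matched as case-sensitive symbols; no alias
resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from seedmod.errors import InputError, ParseError

logger = logging.getLogger(__name__)

#: Number of protein-coding genes used as the genome-wide denominator in
#: phenotype enrichment scores (Gencode GRCh38.p12 protein-coding count).
GENOME_TOTAL_DEFAULT = 19_986


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (assumed normalised, e.g. log-scale) expression.

    Attributes
    ----------
    genes : list of str
        Ordered, unique gene symbols (rows).
    samples : list of str
        Ordered, unique sample labels (columns).
    values : ndarray of shape (n_genes, n_samples)
        Finite expression levels.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise InputError("duplicate gene identifiers in expression matrix")
        if len(set(self.samples)) != len(self.samples):
            raise InputError("duplicate sample identifiers in expression matrix")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise InputError(
                f"expression value shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.samples) < 2:
            raise InputError("expression matrix needs at least 2 samples")
        finite_per_row = np.isfinite(self.values).sum(axis=1)
        if (finite_per_row < 2).any():
            bad = self.genes[int(np.argmin(finite_per_row))]
            raise InputError(f"gene {bad!r} has fewer than 2 finite expression values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class CoexpressionMatrix:
    """Symmetric gene x gene Pearson correlation matrix with unit diagonal.

    Correlations that are undefined because one gene has zero variance
    are imputed to 0 so that the gene universe stays stable.
    """

    genes: list[str]
    corr: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        n = len(self.genes)
        if self.corr.shape != (n, n):
            raise InputError("correlation matrix shape inconsistent with gene list")
        if not np.all(np.isfinite(self.corr)):
            raise InputError("correlation matrix contains non-finite entries")
        if np.abs(self.corr).max(initial=0.0) > 1 + 1e-9:
            raise InputError("correlation entries outside [-1, 1]")
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise InputError("correlation matrix is not symmetric")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def loc(self, gene_a: str, gene_b: str) -> float:
        return float(self.corr[self._index[gene_a], self._index[gene_b]])

    def corr_with(self, gene: str) -> pd.Series:
        """Correlation of every gene with ``gene``, as a Series indexed by symbol."""
        if gene not in self._index:
            raise KeyError(gene)
        return pd.Series(self.corr[self._index[gene]], index=self.genes)

    def restrict(self, genes: list[str]) -> "CoexpressionMatrix":
        idx = [self._index[g] for g in genes]
        return CoexpressionMatrix(list(genes), self.corr[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.corr, index=self.genes, columns=self.genes).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path) -> "CoexpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


class ControlVariantCounts:
    """Per-gene counts of LOF variants observed in control samples.

    Genes absent from the table are treated as having 0 observed
    control LOF variants.
    """

    def __init__(self, counts: dict[str, int]):
        for gene, c in counts.items():
            if c < 0:
                raise InputError(f"negative control LOF count for gene {gene!r}")
        self._counts = {g: int(c) for g, c in counts.items()}

    def __getitem__(self, gene: str) -> int:
        return self._counts.get(gene, 0)

    def get(self, gene: str, default: int = 0) -> int:
        return self._counts.get(gene, default)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, gene: str) -> bool:
        return gene in self._counts

    def items(self):
        return self._counts.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, ControlVariantCounts) and self._counts == other._counts


@dataclass
class GeneUniverse:
    """Ordered gene symbols shared by the co-expression matrix and PPI graph.

    ``genome_total`` is the genome-wide protein-coding gene count used
    as the denominator in phenotype enrichment scores; it deliberately
    exceeds the analysed universe, which only covers genes present in
    both networks.
    """

    genes: list[str]
    genome_total: int = GENOME_TOTAL_DEFAULT

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError("gene universe is empty")
        if len(set(self.genes)) != len(self.genes):
            raise InputError("duplicate genes in universe")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene symbols, header samples).

    Duplicate gene rows are collapsed by their mean with a logged warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed structure
        raise ParseError(f"could not parse expression matrix {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise InputError(f"expression matrix {path} has fewer than 2 samples")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else "?"
            raise ParseError(
                f"malformed numeric cell in {path} at row {row!r}, column {col!r}"
            )
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene rows by mean: %s", len(dups), ", ".join(dups)
        )
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(list(df.index), list(df.columns.astype(str)), df.to_numpy(dtype=float))


def compute_coexpression(expr: ExpressionMatrix) -> CoexpressionMatrix:
    """Pairwise Pearson correlation across samples.

    Any pair where either gene has zero variance across samples is
    imputed to correlation 0; the diagonal is set to exactly 1.
    """
    values = expr.values
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    zero_var = sd == 0
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CoexpressionMatrix(list(expr.genes), corr)


def read_interaction_graph(paths) -> nx.Graph:
    """Read and union one or more two-column TSV edge lists into a simple graph.

    Edges are deduplicated regardless of orientation; self-loops are
    dropped with a warning; a third (weight/confidence) column, if
    present, is ignored.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    graph = nx.Graph()
    n_self = 0
    for path in paths:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ParseError(f"edge list {path} has fewer than 2 columns")
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
            if a == b:
                n_self += 1
                continue
            graph.add_edge(str(a), str(b))
    if n_self:
        logger.warning("dropped %d self-loop edge(s)", n_self)
    if graph.number_of_edges() == 0:
        raise InputError("interaction graph union contains no edges")
    return graph


def write_interaction_graph(graph: nx.Graph, path) -> None:
    """Serialize a graph as a two-column TSV edge list (sorted, deterministic)."""
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    pd.DataFrame(edges).to_csv(path, sep="\t", header=False, index=False)


def read_control_lof(path) -> ControlVariantCounts:
    """Read a two-column TSV of gene, control LOF count.

    A header row is tolerated; duplicate gene rows are summed with a
    warning; negative counts are rejected.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"control LOF table {path} has fewer than 2 columns")
    counts_col = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if counts_col.isna().iloc[0] and len(df) > 1:
        # header row
        df = df.iloc[1:]
        counts_col = counts_col.iloc[1:]
    if counts_col.isna().any():
        row = df.iloc[int(np.argmax(counts_col.isna().to_numpy())), 0]
        raise ParseError(f"malformed count in {path} at gene row {row!r}")
    genes = df.iloc[:, 0].astype(str)
    if (counts_col < 0).any():
        bad = genes[counts_col.lt(0)].iloc[0]
        raise InputError(f"negative control LOF count for gene {bad!r}")
    if genes.duplicated().any():
        dups = sorted(set(genes[genes.duplicated()]))
        logger.warning("summing duplicated control LOF rows: %s", ", ".join(dups))
    summed = counts_col.groupby(genes.values).sum()
    return ControlVariantCounts({str(g): int(c) for g, c in summed.items()})


def harmonize(
    corr: CoexpressionMatrix,
    graph: nx.Graph,
    counts: ControlVariantCounts | None = None,
) -> tuple[GeneUniverse, CoexpressionMatrix, nx.Graph]:
    """Restrict the co-expression matrix and PPI graph to their shared genes.

    The universe is the intersection of the two gene sets, ordered as in
    the co-expression matrix.  Control counts need no restriction since
    lookups default to 0.
    """
    graph_nodes = set(graph.nodes())
    shared = [g for g in corr.genes if g in graph_nodes]
    if not shared:
        raise InputError("co-expression matrix and PPI graph share no genes")
    universe = GeneUniverse(shared)
    corr_r = corr.restrict(shared)
    graph_r = nx.Graph(graph.subgraph(shared))
    return universe, corr_r, graph_r
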