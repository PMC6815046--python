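"""Per-gene scoring by relative ranking of co-expression with the seed.

Every non-seed gene i receives a score

    s_i = rank(|corr(i, seed)|) / m

where the ascending rank (ties averaged) is taken among the m non-seed
genes, so s_i lies in (0, 1] and is invariant under any strictly
monotone transform of the absolute seed co-expression.  The seed's own
score is fixed at 1 so it is never disadvantaged in the module score.

A hard eligibility filter excludes genes carrying more than ``max_lof``
loss-of-function variants in control individuals from path and module
construction; filtered genes keep their scores and remain in the
universe for enrichment denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from seedmod.errors import SeedNotInUniverseError
from seedmod.network_io import CoexpressionMatrix, ControlVariantCounts

logger = logging.getLogger(__name__)

#: Default cap on control LOF variants for a gene to stay module-eligible.
DEFAULT_MAX_LOF = 5


@dataclass
class SeedScoreVector:
    """Scores s_i in [0, 1] and eligibility flags for one seed gene."""

    seed: str
    scores: dict[str, float]
    eligible: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed not in self.scores:
            raise ValueError("seed gene must itself be scored")
        if not self.eligible:
            self.eligible = {g: True for g in self.scores}

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]

    def is_eligible(self, gene: str) -> bool:
        return self.eligible.get(gene, False)

    @property
    def genes(self) -> list[str]:
        return list(self.scores)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "gene": list(self.scores),
                "score": [self.scores[g] for g in self.scores],
                "eligible": [int(self.eligible.get(g, False)) for g in self.scores],
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def score_genes(corr: CoexpressionMatrix, seed: str) -> SeedScoreVector:
    """Score every gene by the rank of its absolute co-expression with ``seed``.

    Raises
    ------
    SeedNotInUniverseError
        If the seed is absent from the co-expression matrix.
    """
    if seed not in corr.genes:
        raise SeedNotInUniverseError(f"seed gene {seed!r} not in co-expression universe")
    series = corr.corr_with(seed)
    non_seed = [g for g in corr.genes if g != seed]
    scores: dict[str, float] = {seed: 1.0}
    if non_seed:
        r = np.abs(series.loc[non_seed].to_numpy())
        ranks = rankdata(r, method="average")
        m = len(non_seed)
        for gene, rank in zip(non_seed, ranks):
            scores[gene] = float(rank) / m
    return SeedScoreVector(seed=seed, scores=scores)


def apply_lof_filter(
    scores: SeedScoreVector,
    counts: ControlVariantCounts,
    max_lof: int = DEFAULT_MAX_LOF,
) -> SeedScoreVector:
    """Flag genes with more than ``max_lof`` control LOF variants as ineligible.

    Score values are never changed.  The seed is always eligible; if its
    own control count exceeds the cap a warning is logged.
    """
    if max_lof < 0:
        raise ValueError("max_lof must be >= 0")
    eligible = {g: counts[g] <= max_lof for g in scores.scores}
    if not eligible[scores.seed]:
        logger.warning(
            "seed gene %s has %d control LOF variants (> max_lof=%d); kept eligible",
            scores.seed,
            counts[scores.seed],
            max_lof,
        )
    eligible[scores.seed] = True
    return SeedScoreVector(seed=scores.seed, scores=dict(scores.scores), eligible=eligible)
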