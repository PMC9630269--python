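"""Comprehensive (RefFinder-style) consensus ranking.

Each of the four stability methods produces its own ordering of the
candidate genes.  The consensus score of a gene is the geometric mean of
its four integer ranks; genes are then ordered ascending by that score.
Ranks use competition ("min") ranking by default: tied scores — notably
geNorm's final pair, which share one M value — both receive the smaller
rank and the next gene skips a position.  The score is bounded by the
smallest and largest of the four ranks, so full agreement at rank r
yields exactly r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bestkeeper import BestKeeperResult
from .deltact import DeltaCtResult
from .genorm import GeNormTrace
from .normfinder import NormFinderResult

__all__ = ["ConsensusResult", "rank_methods", "geometric_mean_rank"]

METHODS = ("genorm", "normfinder", "bestkeeper", "deltact")


@dataclass
class ConsensusResult:
    """Per-method ranks, geometric-mean scores, and the final ordering."""

    method_ranks: pd.DataFrame  # genes x methods, integer ranks
    geomean_score: pd.Series
    ranking: list[str]

    def to_frame(self) -> pd.DataFrame:
        out = self.method_ranks.copy()
        out.columns = [f"rank_{m}" for m in out.columns]
        out["geomean_score"] = self.geomean_score
        out["final_rank"] = np.arange(1, len(out) + 1)[
            np.argsort(np.argsort(self.geomean_score.to_numpy(), kind="stable"),
                       kind="stable")
        ]
        out.index.name = "gene"
        return out.loc[self.ranking].reset_index()


def _ranks(scores: pd.Series, tie_policy: str) -> pd.Series:
    method = {"min": "min", "average": "average"}.get(tie_policy)
    if method is None:
        raise ValueError(f"tie_policy must be 'min' or 'average', got {tie_policy!r}")
    return pd.Series(rankdata(scores.to_numpy(), method=method), index=scores.index)


def rank_methods(
    genorm: GeNormTrace,
    normfinder: NormFinderResult,
    bestkeeper: BestKeeperResult,
    deltact: DeltaCtResult,
    tie_policy: str = "min",
) -> pd.DataFrame:
    """Integer rank of every gene under each of the four methods.

    geNorm ranks by the M value at exclusion (its tied final pair share
    rank 1), NormFinder by stability value, BestKeeper by the CP
    dispersion SD, and the delta-Ct method by mean pairwise-difference
    SD — all ascending (lower = more stable).
    """
    scores = {
        "genorm": genorm.m_at_exclusion,
        "normfinder": normfinder.stability,
        "bestkeeper": bestkeeper.sd_cp,
        "deltact": deltact.mean_sd,
    }
    gene_sets = {m: frozenset(s.index) for m, s in scores.items()}
    if len(set(gene_sets.values())) != 1:
        raise ValueError(f"methods cover different gene sets: {gene_sets}")
    genes = list(genorm.m_at_exclusion.index)
    ranks = pd.DataFrame(
        {m: _ranks(s.reindex(genes), tie_policy) for m, s in scores.items()}
    )
    ranks.index.name = "gene"
    return ranks


def geometric_mean_rank(method_ranks: pd.DataFrame) -> ConsensusResult:
    """Aggregate per-method ranks into the consensus ordering."""
    missing = [m for m in METHODS if m not in method_ranks.columns]
    if missing:
        raise ValueError(f"method ranks missing columns: {missing}")
    score = pd.Series(
        np.prod(method_ranks[list(METHODS)].to_numpy(), axis=1)
        ** (1.0 / len(METHODS)),
        index=method_ranks.index,
        name="geomean_score",
    )
    ranking = list(score.sort_values(kind="stable").index)
    return ConsensusResult(
        method_ranks=method_ranks, geomean_score=score, ranking=ranking
    )
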