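"""Comparative delta-Ct stability ranking.

The simplest of the four methods: for every gene j, take the Ct
difference against each other candidate k and compute its sample SD
across samples; the gene's score is the mean of those SDs.  A gene whose
pairwise differences are all nearly constant tracks the panel and is
stable.  The method operates on raw Ct by definition, which makes it
algebraically identical to the full-panel geNorm M when the
amplification factor is exactly 2 (log2 q differences equal negated Ct
differences up to a constant, and SD ignores constants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SpeciesPanel

__all__ = ["DeltaCtResult", "delta_ct_stability"]


@dataclass
class DeltaCtResult:
    """Per-gene mean pairwise-difference SD (cycles) and ranking."""

    mean_sd: pd.Series
    ranking: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "gene": self.ranking,
                "mean_sd": self.mean_sd.reindex(self.ranking).to_numpy(),
            }
        )


def delta_ct_stability(panel: SpeciesPanel) -> DeltaCtResult:
    """Mean SD of pairwise Ct differences for each gene."""
    ct = panel.values
    if ct.shape[0] < 3:
        raise ValueError("delta-Ct ranking requires at least 3 genes")
    if ct.shape[1] < 2:
        raise ValueError("delta-Ct ranking requires at least 2 samples")
    y = ct.to_numpy()
    diff = y[:, None, :] - y[None, :, :]
    sd = diff.std(axis=2, ddof=1)
    mean_sd = pd.Series(sd.sum(axis=1) / (len(ct.index) - 1), index=ct.index,
                        name="mean_sd")
    ranking = list(mean_sd.sort_values(kind="stable").index)
    return DeltaCtResult(mean_sd=mean_sd, ranking=ranking)
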