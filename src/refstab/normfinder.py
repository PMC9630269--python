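"""NormFinder model-based stability estimation (single-group form).

NormFinder fits the additive model

    y_ij = alpha_i + beta_j + eps_ij,    Var(eps_ij) = sigma_i^2

to the log quantities y of gene i in sample j: alpha_i is the gene's
expression level, beta_j the sample's loading/amount effect, and
sigma_i^2 the gene-specific variance left after both are removed — the
quantity of interest.  Double-centering the matrix removes the two main
effects; the residual

    z_ij = y_ij - mean_i - mean_j + grand mean

has expectation E[sum_j z_ij^2 / (n-1)] = sigma_i^2 (g-2)/g + S/g^2
with S the sum of all sigma^2 over the g genes, so a moment correction
recovers an unbiased estimate:

    sigma_i^2 = max(0, (u_i - U / (g (g-1))) * g / (g-2))

where u_i is gene i's raw residual variance and U their sum.  The
stability value is the square root; negative corrected variances (which
can occur at small g or when a gene tracks the panel almost exactly)
truncate to zero before the root.  Lower is more stable.

This is the single-condition form: each species panel here is one
experimental group, so the inter/intra-group decomposition of the
grouped estimator does not apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transform import QuantityMatrix

__all__ = ["NormFinderResult", "normfinder_stability"]


@dataclass
class NormFinderResult:
    """Per-gene stability values (log2 scale, >= 0) and ranking."""

    stability: pd.Series
    ranking: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "gene": self.ranking,
                "stability": self.stability.reindex(self.ranking).to_numpy(),
            }
        )


def normfinder_stability(qm: QuantityMatrix) -> NormFinderResult:
    """Model-based stability value for every gene of one panel."""
    g, n = qm.n_genes, qm.n_samples
    if g <= 2:
        raise ValueError("NormFinder requires >= 3 genes")
    if n < 2:
        raise ValueError("NormFinder requires >= 2 samples")
    y = qm.log2q.to_numpy()
    z = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    u = (z**2).sum(axis=1) / (n - 1)
    total = u.sum()
    var = np.maximum(0.0, (u - total / (g * (g - 1))) * g / (g - 2))
    stability = pd.Series(np.sqrt(var), index=qm.q.index, name="stability")
    ranking = list(stability.sort_values(kind="stable").index)
    return NormFinderResult(stability=stability, ranking=ranking)
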