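"""geNorm expression-stability analysis.

For each candidate gene j the geNorm stability measure M_j is the
arithmetic mean, over all other candidates k, of the sample standard
deviation (denominator n - 1) of the pairwise log-ratio
log2(q_j / q_k).  A perfectly co-regulated pair has a constant ratio and
contributes 0; the less a gene co-varies with the rest of the panel, the
larger its M.  The full procedure ranks genes by stepwise exclusion:
recompute M on the remaining subset, drop the gene with the largest M,
repeat until two genes remain (which are tied at rank 1 — a pairwise
ratio cannot separate them).

The per-gene value reported for the exclusion trace is the *average* M
of the panel from which the gene was excluded (the quantity geNorm's
stability chart plots), which yields a series decreasing toward the most
stable pair; the final pair's common value is their mutual pairwise SD.

The pairwise-variation statistic V(n/n+1) decides how many reference
genes are enough: NF_n is the per-sample geometric mean of the top-n
genes' quantities, and V(n/n+1) is the sample SD across samples of
log2(NF_n / NF_{n+1}).  V below 0.15 is the conventional indication that
the (n+1)-th gene adds nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transform import QuantityMatrix

__all__ = [
    "GeNormTrace",
    "pairwise_sd",
    "m_values",
    "stepwise_ranking",
    "pairwise_v",
    "recommend_n",
    "DEFAULT_V_THRESHOLD",
]

DEFAULT_V_THRESHOLD = 0.15


@dataclass
class GeNormTrace:
    """Outcome of geNorm stepwise exclusion on one panel.

    ranking
        Genes from most to least stable; the first two are tied.
    m_at_exclusion
        Per gene, the average panel M at the step where it was excluded
        (final pair: their shared pairwise M).
    v_series
        n -> V(n/n+1) for n = 2 .. g-1; filled by :func:`pairwise_v`.
    """

    ranking: list[str]
    m_at_exclusion: pd.Series
    v_series: pd.Series | None = None

    @property
    def final_pair(self) -> tuple[str, str]:
        return self.ranking[0], self.ranking[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "gene": self.ranking,
                "M": self.m_at_exclusion.reindex(self.ranking).to_numpy(),
            }
        )


def pairwise_sd(qm: QuantityMatrix, gene_j: str, gene_k: str) -> float:
    """Sample SD across samples of log2(q_j / q_k)."""
    if gene_j == gene_k:
        raise ValueError(f"pairwise SD requires two distinct genes, got {gene_j!r} twice")
    if qm.n_samples < 2:
        raise ValueError("pairwise SD requires at least 2 samples")
    ratio = qm.log2q.loc[gene_j] - qm.log2q.loc[gene_k]
    return float(ratio.std(ddof=1))


def m_values(qm: QuantityMatrix, gene_subset: list[str] | None = None) -> pd.Series:
    """geNorm M for every gene in ``gene_subset`` (default: all genes)."""
    subset = list(gene_subset) if gene_subset is not None else qm.genes
    if len(subset) < 2:
        raise ValueError("geNorm M requires at least 2 genes")
    y = qm.log2q.loc[subset].to_numpy()
    # SD matrix of all pairwise log-ratios; mean over the off-diagonal row
    diff = y[:, None, :] - y[None, :, :]
    sd = diff.std(axis=2, ddof=1)
    m = sd.sum(axis=1) / (len(subset) - 1)
    return pd.Series(m, index=subset, name="M")


def stepwise_ranking(qm: QuantityMatrix) -> GeNormTrace:
    """Rank genes by repeatedly excluding the least stable one.

    Ties in the largest M are broken by excluding the gene later in
    input order; the paper of record for this procedure never reports a
    mid-run tie, so the break only matters for degenerate input.
    """
    if qm.n_genes < 3:
        raise ValueError("geNorm stepwise ranking requires at least 3 genes")
    remaining = list(qm.genes)
    excluded: list[str] = []
    m_at: dict[str, float] = {}
    while len(remaining) > 2:
        m = m_values(qm, remaining)
        worst_m = m.max()
        # latest-in-input-order among ties
        worst = [g for g in remaining if m[g] == worst_m][-1]
        m_at[worst] = float(m.mean())
        remaining.remove(worst)
        excluded.append(worst)
    m = m_values(qm, remaining)
    shared = float(m.mean())
    for g in remaining:
        m_at[g] = shared
    ranking = remaining + excluded[::-1]
    return GeNormTrace(
        ranking=ranking,
        m_at_exclusion=pd.Series(m_at).reindex(ranking),
    )


def pairwise_v(qm: QuantityMatrix, trace: GeNormTrace) -> pd.Series:
    """V(n/n+1) for n = 2 .. g-1, stored on the trace and returned."""
    ranking = trace.ranking
    g = len(ranking)
    if g < 3:
        raise ValueError("pairwise variation requires at least 3 genes")
    log2q = qm.log2q.loc[ranking].to_numpy()
    v: dict[int, float] = {}
    for n in range(2, g):
        log_nf_n = log2q[:n].mean(axis=0)  # log2 geometric mean of top n
        log_nf_n1 = log2q[: n + 1].mean(axis=0)
        v[n] = float(np.std(log_nf_n - log_nf_n1, ddof=1))
    series = pd.Series(v, name="V")
    series.index.name = "n"
    trace.v_series = series
    return series


def recommend_n(
    v_series: pd.Series, threshold: float = DEFAULT_V_THRESHOLD
) -> tuple[int, bool]:
    """Smallest n with V(n/n+1) below threshold.

    Returns ``(n, ok)``.  If no V clears the threshold, returns the
    total gene count with ``ok=False`` — use all candidates, flagged.
    """
    if v_series is None or len(v_series) == 0:
        raise ValueError("empty V series")
    for n, v in v_series.items():
        if v < threshold:
            return int(n), True
    return int(v_series.index.max()) + 1, False
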