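"""BestKeeper descriptive statistics, SD filter, correlations and index.

BestKeeper works on raw crossing-point (CP/Ct) values, never on relative
quantities.  Per gene it reports the geometric and arithmetic mean CP,
the extreme CPs, a dispersion measure SD defined as the *mean absolute
deviation about the geometric mean* (not the root-mean-square SD), the
coefficient of variation CV% = 100 * SD / arithmetic mean, and the same
quantities re-expressed as x-fold changes: deviations of d cycles map to
2**d-fold expression changes (signed negative for CPs below the mean,
i.e. over-expression).  Genes with SD > 1 cycle are considered too
variable to normalise with and are excluded.

The retained genes are combined into the BestKeeper index — the
per-sample geometric mean of their CPs — and each candidate is judged by
its Pearson correlation with that index (and with every other
candidate), with two-sided p-values from the exact t transform
``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import SpeciesPanel

__all__ = [
    "BestKeeperGeneStats",
    "BestKeeperCorrelations",
    "BestKeeperResult",
    "gene_stats",
    "exclude_unstable",
    "pairwise_correlations",
    "bestkeeper_index",
    "bestkeeper_analysis",
    "DEFAULT_SD_THRESHOLD",
]

DEFAULT_SD_THRESHOLD = 1.0


@dataclass
class BestKeeperGeneStats:
    """Descriptive CP statistics for one gene."""

    n: int
    geo_mean: float
    ar_mean: float
    min_cp: float
    max_cp: float
    sd_cp: float
    cv_pct: float
    min_xfold: float
    max_xfold: float
    sd_xfold: float


@dataclass
class BestKeeperCorrelations:
    """Pairwise gene correlations and gene-vs-index correlations.

    ``gene_pair_r``/``gene_pair_p`` are symmetric DataFrames with NaN
    diagonal; ``index`` is the per-sample geometric-mean CP over the
    retained genes; ``index_r``/``index_p`` give each gene against it.
    """

    gene_pair_r: pd.DataFrame
    gene_pair_p: pd.DataFrame
    index: pd.Series
    index_r: pd.Series
    index_p: pd.Series
    retained: list[str]


@dataclass
class BestKeeperResult:
    """Full BestKeeper output for one panel."""

    stats: dict[str, BestKeeperGeneStats]
    retained: list[str]
    excluded: list[str]
    correlations: BestKeeperCorrelations

    @property
    def sd_cp(self) -> pd.Series:
        return pd.Series({g: s.sd_cp for g, s in self.stats.items()}, name="sd_cp")

    @property
    def ranking(self) -> list[str]:
        return list(self.sd_cp.sort_values(kind="stable").index)

    def stats_frame(self) -> pd.DataFrame:
        rows = ["n", "geo_mean", "ar_mean", "min_cp", "max_cp", "sd_cp",
                "cv_pct", "min_xfold", "max_xfold", "sd_xfold"]
        return pd.DataFrame(
            {g: [getattr(s, r) for r in rows] for g, s in self.stats.items()},
            index=rows,
        )


def gene_stats(
    panel: SpeciesPanel, xfold_base: float = 2.0
) -> dict[str, BestKeeperGeneStats]:
    """Descriptive CP statistics for every gene of a panel."""
    ct = panel.values
    if ct.shape[1] < 2:
        raise ValueError("BestKeeper statistics require at least 2 samples")
    if (ct.to_numpy() <= 0).any():
        raise ValueError("CP values must be positive")
    out: dict[str, BestKeeperGeneStats] = {}
    for gene in ct.index:
        cp = ct.loc[gene].to_numpy()
        geo = float(np.exp(np.log(cp).mean()))
        ar = float(cp.mean())
        sd = float(np.abs(cp - geo).mean())
        out[gene] = BestKeeperGeneStats(
            n=cp.size,
            geo_mean=geo,
            ar_mean=ar,
            min_cp=float(cp.min()),
            max_cp=float(cp.max()),
            sd_cp=sd,
            cv_pct=100.0 * sd / ar,
            min_xfold=-float(xfold_base ** (geo - cp.min())),
            max_xfold=float(xfold_base ** (cp.max() - geo)),
            sd_xfold=float(xfold_base**sd),
        )
    return out


def exclude_unstable(
    stats: dict[str, BestKeeperGeneStats],
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Split genes into (retained, excluded) by the SD <= threshold rule."""
    retained = [g for g, s in stats.items() if s.sd_cp <= sd_threshold]
    excluded = [g for g, s in stats.items() if s.sd_cp > sd_threshold]
    if not retained:
        raise ValueError(
            f"all genes exceed the BestKeeper SD threshold of {sd_threshold}"
        )
    return retained, excluded


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn(
            "zero-variance CP vector: correlation undefined, reported as NaN",
            stacklevel=2,
        )
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def pairwise_correlations(
    panel: SpeciesPanel, genes: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for every unordered gene pair (raw CP)."""
    ct = panel.values
    genes = list(genes) if genes is not None else list(ct.index)
    if ct.shape[1] < 3:
        raise ValueError("pairwise correlation requires at least 3 samples")
    r = pd.DataFrame(np.nan, index=genes, columns=genes)
    p = pd.DataFrame(np.nan, index=genes, columns=genes)
    for i, gj in enumerate(genes):
        for gk in genes[i + 1 :]:
            rv, pv = _pearson(ct.loc[gj].to_numpy(), ct.loc[gk].to_numpy())
            r.loc[gj, gk] = r.loc[gk, gj] = rv
            p.loc[gj, gk] = p.loc[gk, gj] = pv
    return r, p


def bestkeeper_index(
    panel: SpeciesPanel, retained: list[str]
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Geometric-mean CP index over retained genes, plus per-gene r and p.

    Correlations against the index are computed for *all* genes of the
    panel, retained or not, mirroring how BestKeeper reports candidates.
    """
    if not retained:
        raise ValueError("BestKeeper index requires at least one retained gene")
    ct = panel.values
    index = pd.Series(
        np.exp(np.log(ct.loc[retained].to_numpy()).mean(axis=0)),
        index=ct.columns,
        name="bestkeeper_index",
    )
    r: dict[str, float] = {}
    p: dict[str, float] = {}
    for gene in ct.index:
        if len(retained) == 1 and gene == retained[0]:
            r[gene], p[gene] = 1.0, 0.0
            continue
        r[gene], p[gene] = _pearson(ct.loc[gene].to_numpy(), index.to_numpy())
    return index, pd.Series(r, name="index_r"), pd.Series(p, name="index_p")


def bestkeeper_analysis(
    panel: SpeciesPanel,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    xfold_base: float = 2.0,
    force_all: bool = False,
) -> BestKeeperResult:
    """Run the complete BestKeeper pipeline on one panel.

    ``force_all`` builds the index from every gene regardless of the SD
    filter (the filter outcome is still reported).
    """
    stats = gene_stats(panel, xfold_base=xfold_base)
    retained, excluded = exclude_unstable(stats, sd_threshold)
    index_genes = list(stats) if force_all else retained
    pair_r, pair_p = pairwise_correlations(panel)
    index, index_r, index_p = bestkeeper_index(panel, index_genes)
    corr = BestKeeperCorrelations(
        gene_pair_r=pair_r,
        gene_pair_p=pair_p,
        index=index,
        index_r=index_r,
        index_p=index_p,
        retained=index_genes,
    )
    return BestKeeperResult(
        stats=stats, retained=retained, excluded=excluded, correlations=corr
    )
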