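"""Ct -> relative-quantity transforms and slope -> efficiency conversion.

geNorm and NormFinder operate on relative quantities rather than raw Ct:
each gene's Ct vector is rescaled with the comparative-Ct transform

    q[g, s] = E_g ** (min_s' Ct[g, s'] - Ct[g, s])

so the sample with the highest expression (lowest Ct) is set to 1 and
every other sample is a fraction of it.  ``E_g`` is the gene's per-cycle
amplification factor; E = 2 is perfect doubling (100 % efficiency) and is
the default throughout.  With E = 2 the log2 quantity is simply
``minCt - Ct``, which makes several cross-method identities exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data import SpeciesPanel

__all__ = [
    "EfficiencySpec",
    "QuantityMatrix",
    "relative_quantity",
    "efficiency_from_slope",
]


@dataclass(frozen=True)
class EfficiencySpec:
    """Per-gene amplification factors (dimensionless, 2.0 = 100 %).

    ``source`` records provenance: 'fixed_two' (the default, all genes at
    perfect doubling), 'from_slope' (converted from standard-curve
    slopes) or 'user'.
    """

    factors: Mapping[str, float] = field(default_factory=dict)
    default: float = 2.0
    source: str = "fixed_two"

    def __post_init__(self) -> None:
        for gene, e in {**dict(self.factors), "<default>": self.default}.items():
            if not 1.0 < float(e) <= 3.0:
                raise ValueError(
                    f"amplification factor for {gene} must be in (1, 3], got {e}"
                )

    def factor(self, gene: str) -> float:
        return float(self.factors.get(gene, self.default))

    def vector(self, genes: Iterable[str]) -> pd.Series:
        return pd.Series({g: self.factor(g) for g in genes})

    @classmethod
    def from_file(cls, path: str | Path) -> "EfficiencySpec":
        """Read a two-column gene,amplification_factor delimited file."""
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
        tab = pd.read_csv(path, sep=sep)
        tab.columns = [c.lower() for c in tab.columns]
        gene_col, eff_col = tab.columns[0], tab.columns[1]
        return cls(
            factors=dict(zip(tab[gene_col].astype(str), tab[eff_col].astype(float))),
            source="user",
        )

    @classmethod
    def from_slopes(cls, slopes: Mapping[str, float]) -> "EfficiencySpec":
        return cls(
            factors={g: efficiency_from_slope(s) for g, s in slopes.items()},
            source="from_slope",
        )


@dataclass
class QuantityMatrix:
    """Relative quantities and their base-2 logs for one panel.

    Invariants: per gene, max(q) == 1 (attained at the minimum-Ct sample)
    and q in (0, 1]; ``log2q`` is the elementwise base-2 log of ``q``.
    """

    q: pd.DataFrame
    log2q: pd.DataFrame
    efficiency: EfficiencySpec

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q.columns)

    @property
    def n_genes(self) -> int:
        return len(self.q.index)

    @property
    def n_samples(self) -> int:
        return len(self.q.columns)


def relative_quantity(
    panel: SpeciesPanel, eff: EfficiencySpec | None = None
) -> QuantityMatrix:
    """Comparative-Ct transform of a panel to relative quantities."""
    eff = eff or EfficiencySpec()
    ct = panel.values
    delta = ct.min(axis=1).to_numpy()[:, None] - ct.to_numpy()  # minCt - Ct, <= 0
    log2e = np.log2(eff.vector(panel.genes).to_numpy())[:, None]
    log2q = pd.DataFrame(delta * log2e, index=ct.index, columns=ct.columns)
    return QuantityMatrix(q=2.0**log2q, log2q=log2q, efficiency=eff)


def efficiency_from_slope(slope: float, as_percent: bool = False) -> float:
    """Convert a standard-curve slope to an amplification factor.

    The dilution-series slope of Ct against log10 input relates to the
    per-cycle amplification factor as ``E = 10 ** (-1 / slope)``; a slope
    of -3.3219 gives exactly E = 2 (100 %).  With ``as_percent`` the
    conventional percentage ``(E - 1) * 100`` is returned.
    """
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    e = 10.0 ** (-1.0 / slope)
    return (e - 1.0) * 100.0 if as_percent else e
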