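"""Model/Results interface tying the four stability methods together.

:class:`ReferenceGeneStability` is constructed from a Ct matrix (or a
pandas DataFrame plus group labels); ``fit()`` runs the requested
stability algorithms on every group's panel and returns a
:class:`StabilityResults` holding per-group :class:`PanelStability`
bundles — geNorm trace with V series and the recommended gene count,
delta-Ct, NormFinder and BestKeeper results, and the consensus ranking —
plus a ``summary()`` table and CSV writers.

Typical use::

    from refstab import ReferenceGeneStability
    res = ReferenceGeneStability.builtin().fit()
    print(res.summary())
    res.save_tables("out/")
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bestkeeper as bk
from . import consensus as cns
from . import deltact as dct
from . import genorm as gn
from . import normfinder as nf
from .data import CtMatrix, SpeciesPanel, builtin_dataset, load_ct_table, subset_by_group
from .transform import EfficiencySpec, relative_quantity

__all__ = ["ReferenceGeneStability", "StabilityResults", "PanelStability",
           "ALL_METHODS"]

logger = logging.getLogger("refstab")

ALL_METHODS = ("genorm", "normfinder", "bestkeeper", "deltact", "consensus")


@dataclass
class PanelStability:
    """All fitted results for one group's panel."""

    group: str
    panel: SpeciesPanel
    genorm: gn.GeNormTrace | None = None
    recommended_n: int | None = None
    recommended_ok: bool | None = None
    deltact: dct.DeltaCtResult | None = None
    normfinder: nf.NormFinderResult | None = None
    bestkeeper: bk.BestKeeperResult | None = None
    consensus: cns.ConsensusResult | None = None

    def top_genes(self, k: int = 3) -> list[str]:
        """Top-k genes by consensus, else by the first fitted method."""
        for res in (self.consensus, self.genorm, self.normfinder,
                    self.deltact):
            if res is not None:
                return res.ranking[:k]
        if self.bestkeeper is not None:
            return self.bestkeeper.ranking[:k]
        raise ValueError(f"no fitted method for group {self.group!r}")

    def method_tables(self) -> dict[str, pd.DataFrame]:
        tables: dict[str, pd.DataFrame] = {}
        if self.genorm is not None:
            tables["genorm_m"] = self.genorm.to_frame()
            if self.genorm.v_series is not None:
                tables["genorm_v"] = self.genorm.v_series.reset_index()
        if self.deltact is not None:
            tables["deltact"] = self.deltact.to_frame()
        if self.normfinder is not None:
            tables["normfinder"] = self.normfinder.to_frame()
        if self.bestkeeper is not None:
            tables["bestkeeper_stats"] = (
                self.bestkeeper.stats_frame().T.rename_axis("gene").reset_index()
            )
            r = self.bestkeeper.correlations.gene_pair_r
            p = self.bestkeeper.correlations.gene_pair_p
            rows = []
            genes = list(r.index)
            for i, gj in enumerate(genes):
                for gk in genes[i + 1 :]:
                    rows.append((gj, gk, r.loc[gj, gk], p.loc[gj, gk]))
            tables["bestkeeper_corr"] = pd.DataFrame(
                rows, columns=["gene_a", "gene_b", "r", "p"]
            )
            tables["bestkeeper_index"] = pd.DataFrame(
                {
                    "gene": self.bestkeeper.correlations.index_r.index,
                    "r": self.bestkeeper.correlations.index_r.to_numpy(),
                    "p": self.bestkeeper.correlations.index_p.to_numpy(),
                }
            )
        if self.consensus is not None:
            tables["consensus"] = self.consensus.to_frame()
        return tables


class ReferenceGeneStability:
    """Reference-gene stability model over one or more sample groups.

    Parameters
    ----------
    ct : CtMatrix
        Complete genes x samples quantification-cycle matrix with group
        labels.
    efficiency : EfficiencySpec, optional
        Per-gene amplification factors for the comparative-Ct transform;
        defaults to E = 2 for every gene.
    """

    def __init__(self, ct: CtMatrix, efficiency: EfficiencySpec | None = None):
        self.ct = ct
        self.efficiency = efficiency or EfficiencySpec()

    # -- constructors --------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        groups: pd.Series | dict | None = None,
        efficiency: EfficiencySpec | None = None,
    ) -> "ReferenceGeneStability":
        """Build from a genes x samples DataFrame and sample->group map."""
        if groups is None:
            groups = pd.Series("all", index=values.columns)
        elif isinstance(groups, dict):
            groups = pd.Series(groups)
        return cls(CtMatrix(values=values.copy(), group_of=groups),
                   efficiency=efficiency)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        layout: str = "wide",
        annotation: str | Path | None = None,
        efficiency: EfficiencySpec | None = None,
    ) -> "ReferenceGeneStability":
        return cls(load_ct_table(path, layout=layout, annotation=annotation),
                   efficiency=efficiency)

    @classmethod
    def builtin(cls, efficiency: EfficiencySpec | None = None) -> "ReferenceGeneStability":
        """The packaged six-species Leh-Ladakh PBMC dataset."""
        return cls(builtin_dataset(), efficiency=efficiency)

    # -- fitting -------------------------------------------------------

    def fit(
        self,
        methods: tuple[str, ...] | list[str] = ALL_METHODS,
        groups: list[str] | None = None,
        v_threshold: float = gn.DEFAULT_V_THRESHOLD,
        sd_threshold: float = bk.DEFAULT_SD_THRESHOLD,
        tie_policy: str = "min",
    ) -> "StabilityResults":
        """Run the requested methods on every (or the named) groups.

        ``consensus`` requires all four base methods; requesting it with
        a subset is a configuration error.
        """
        methods = tuple(methods)
        unknown = set(methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if not methods:
            raise ValueError("at least one method must be requested")
        if "consensus" in methods:
            base = {"genorm", "normfinder", "bestkeeper", "deltact"}
            if not base.issubset(methods):
                raise ValueError(
                    "consensus requires genorm, normfinder, bestkeeper and deltact"
                )
        groups = list(groups) if groups is not None else self.ct.groups
        for g in groups:
            if g not in self.ct.groups:
                raise KeyError(f"unknown group {g!r}; available: {self.ct.groups}")

        panels: dict[str, PanelStability] = {}
        for group in groups:
            t0 = time.perf_counter()
            panel = subset_by_group(self.ct, group)
            ps = PanelStability(group=group, panel=panel)
            qm = relative_quantity(panel, self.efficiency)
            if "genorm" in methods:
                ps.genorm = gn.stepwise_ranking(qm)
                gn.pairwise_v(qm, ps.genorm)
                ps.recommended_n, ps.recommended_ok = gn.recommend_n(
                    ps.genorm.v_series, v_threshold
                )
            if "deltact" in methods:
                ps.deltact = dct.delta_ct_stability(panel)
            if "normfinder" in methods:
                ps.normfinder = nf.normfinder_stability(qm)
            if "bestkeeper" in methods:
                ps.bestkeeper = bk.bestkeeper_analysis(panel, sd_threshold)
            if "consensus" in methods:
                ranks = cns.rank_methods(
                    ps.genorm, ps.normfinder, ps.bestkeeper, ps.deltact,
                    tie_policy=tie_policy,
                )
                ps.consensus = cns.geometric_mean_rank(ranks)
            panels[group] = ps
            logger.info(
                "group %s: %d genes x %d samples fitted in %.3fs",
                group, panel.ct.n_genes, panel.ct.n_samples,
                time.perf_counter() - t0,
            )
        return StabilityResults(model=self, panels=panels, methods=methods)

    def input_checksum(self) -> str:
        payload = self.ct.to_wide().to_csv().encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class StabilityResults:
    """Fitted stability results across groups."""

    model: ReferenceGeneStability
    panels: dict[str, PanelStability]
    methods: tuple[str, ...] = field(default_factory=tuple)

    def __getitem__(self, group: str) -> PanelStability:
        return self.panels[group]

    @property
    def groups(self) -> list[str]:
        return list(self.panels)

    # -- reporting -----------------------------------------------------

    def summary(self, top_k: int = 3, digits: int = 3) -> str:
        """Human-readable per-group summary (display-rounded)."""
        lines = ["Reference-gene stability summary",
                 "=" * 48]
        for group, ps in self.panels.items():
            parts = [f"{group}:"]
            try:
                tops = ps.top_genes(top_k)
                parts.append(", ".join(tops))
            except ValueError:
                pass
            if ps.recommended_n is not None:
                flag = "" if ps.recommended_ok else " (no V below threshold)"
                parts.append(f"; use {ps.recommended_n} genes{flag}")
            if ps.genorm is not None:
                pair = ps.genorm.final_pair
                m = ps.genorm.m_at_exclusion.iloc[0]
                parts.append(
                    f"; geNorm best pair {pair[0]}/{pair[1]} (M={m:.{digits}f})"
                )
            lines.append(" ".join(parts))
        return "\n".join(lines)

    def panel_summary(self) -> pd.DataFrame:
        """Machine-readable: top-2 genes per method per group."""
        rows = []
        for group, ps in self.panels.items():
            entry: dict[str, object] = {"group": group}
            if ps.genorm is not None:
                entry["genorm_top2"] = "|".join(ps.genorm.ranking[:2])
                entry["recommended_n"] = ps.recommended_n
            if ps.normfinder is not None:
                entry["normfinder_top2"] = "|".join(ps.normfinder.ranking[:2])
            if ps.bestkeeper is not None:
                entry["bestkeeper_top2"] = "|".join(ps.bestkeeper.ranking[:2])
            if ps.deltact is not None:
                entry["deltact_top2"] = "|".join(ps.deltact.ranking[:2])
            if ps.consensus is not None:
                entry["consensus_top2"] = "|".join(ps.consensus.ranking[:2])
            rows.append(entry)
        return pd.DataFrame(rows)

    def save_tables(self, outdir: str | Path) -> list[Path]:
        """Write every fitted table as CSV; returns the written paths.

        Numbers are written at full precision; use ``summary()`` for the
        display-rounded view.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for group, ps in self.panels.items():
            for name, table in ps.method_tables().items():
                path = outdir / f"{group}_{name}.csv"
                table.to_csv(path, index=False, encoding="utf-8")
                written.append(path)
        spath = outdir / "panel_summary.csv"
        self.panel_summary().to_csv(spath, index=False, encoding="utf-8")
        written.append(spath)
        return written

    # -- optional plotting hook (requires matplotlib) ------------------

    def plot_m(self, group: str, ax=None):
        """Bar chart of the geNorm M series for one group."""
        import matplotlib.pyplot as plt

        ps = self.panels[group]
        if ps.genorm is None:
            raise ValueError("geNorm was not fitted")
        if ax is None:
            _, ax = plt.subplots()
        frame = ps.genorm.to_frame()
        ax.bar(frame["gene"], frame["M"])
        ax.set_ylabel("average expression stability M")
        ax.set_title(f"geNorm stability — {group}")
        ax.tick_params(axis="x", rotation=60)
        return ax
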