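"""Ct matrices, species panels and delimited-text IO.

The central container is :class:`CtMatrix`: a genes x samples table of
quantification-cycle (Ct/Cq/CP) values together with a sample -> group
mapping (the group is typically a species code).  All downstream stability
algorithms require a complete matrix — missing Ct values are a hard error,
never imputed, because every statistic here (pairwise SDs, model-based
variances, geometric-mean indices) silently changes under imputation.

The packaged dataset (:func:`builtin_dataset`) is a 32-sample x 10-gene
panel of average raw Ct values measured in peripheral blood mononuclear
cells of six livestock species native to the trans-Himalayan Leh-Ladakh
region: Ladakhi cattle (LAC, 6), Ladakhi yak (LAY, 6), Ladakhi donkey
(LAD, 5), Changthangi goat (CHG, 5), double-hump camel (DHC, 5) and
Zanskar pony (ZAP, 5), over the candidate reference genes GAPDH, ACTB,
RPS9, EEF1A1, RPS15, RPS23, UXT, RPL4, B2M and HPRT1.  Values are stored
at the 3-decimal precision of the source measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "SpeciesPanel",
    "load_ct_table",
    "write_ct_table",
    "builtin_dataset",
    "subset_by_group",
    "BUILTIN_SPECIES",
]

BUILTIN_SPECIES = ("LAC", "LAY", "LAD", "CHG", "DHC", "ZAP")

#: Minimum samples per group accepted without error.
MIN_SAMPLES = 3
#: Minimum genes required by the stability algorithms (geNorm needs >= 3
#: candidates to do stepwise exclusion; NormFinder's variance correction
#: divides by g - 2).
MIN_GENES = 3


class CtMatrixError(ValueError):
    """Raised for structurally invalid Ct input."""


@dataclass
class CtMatrix:
    """Genes x samples matrix of quantification-cycle values.

    Parameters
    ----------
    values : pandas.DataFrame
        Real-valued frame indexed by gene (rows) with one column per
        sample.  Units are PCR cycles.
    group_of : pandas.Series
        Maps each sample identifier to its group label (species code).
    """

    values: pd.DataFrame
    group_of: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "gene"
        self.values.columns.name = None
        self.group_of = self.group_of.reindex(self.values.columns)
        self.validate()

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        v = self.values
        if v.empty:
            raise CtMatrixError("no data rows")
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise CtMatrixError(f"duplicate gene identifiers: {dup}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise CtMatrixError(f"duplicate sample identifiers: {dup}")
        if v.isna().any().any():
            g, s = next(
                (g, s) for g in v.index for s in v.columns if pd.isna(v.at[g, s])
            )
            raise CtMatrixError(f"missing Ct value for gene {g!r}, sample {s!r}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise CtMatrixError("Ct values must be finite and > 0")
        if self.group_of.isna().any():
            missing = self.group_of.index[self.group_of.isna()].tolist()
            raise CtMatrixError(f"samples without a group label: {missing}")

    # -- accessors -----------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group_of:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    # -- serialization -------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Return a (gene, sample, ct) long-format frame."""
        long = self.values.stack().rename("ct").reset_index()
        long.columns = ["gene", "sample", "ct"]
        return long

    def to_wide(self) -> pd.DataFrame:
        wide = self.values.copy()
        wide.index.name = "gene"
        return wide

    def annotation(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.group_of.index, "group": self.group_of.to_numpy()}
        )


@dataclass
class SpeciesPanel:
    """A single group's slice of a :class:`CtMatrix`.

    ``code`` is the group label (e.g. one of the six builtin species
    codes, or any user label); ``ct`` holds only that group's samples
    with the gene order of the parent matrix preserved.
    """

    code: str
    ct: CtMatrix
    min_samples: int = field(default=MIN_SAMPLES, repr=False)

    def __post_init__(self) -> None:
        if self.ct.n_samples < self.min_samples:
            raise CtMatrixError(
                f"group {self.code!r} has {self.ct.n_samples} samples; "
                f"at least {self.min_samples} required"
            )
        if self.ct.n_genes < MIN_GENES:
            raise CtMatrixError(
                f"group {self.code!r} has {self.ct.n_genes} genes; "
                f"at least {MIN_GENES} required"
            )

    @property
    def genes(self) -> list[str]:
        return self.ct.genes

    @property
    def samples(self) -> list[str]:
        return self.ct.samples

    @property
    def values(self) -> pd.DataFrame:
        return self.ct.values


# ---------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _read_annotation(path: Path) -> pd.Series:
    ann = pd.read_csv(path, sep=_sep_for(path))
    cols = [c.lower() for c in ann.columns]
    if "sample" not in cols or "group" not in cols:
        raise CtMatrixError(
            f"annotation file {path} must have columns 'sample' and 'group'"
        )
    ann.columns = cols
    return pd.Series(ann["group"].to_numpy(), index=ann["sample"].astype(str))


def load_ct_table(
    path: str | Path,
    layout: str = "wide",
    annotation: str | Path | None = None,
) -> CtMatrix:
    """Read a delimited Ct table into a :class:`CtMatrix`.

    ``wide`` layout: first column gene identifier, one column per sample.
    ``long`` layout: columns (gene, sample, ct) in any row order.
    The delimiter is inferred from the extension (.tsv/.tab/.txt tab,
    otherwise comma); decimals use '.'.  ``annotation`` is a two-column
    sample,group file; without it every sample is assigned group "all".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    if layout == "wide":
        raw = pd.read_csv(path, sep=sep, index_col=0)
        if raw.empty:
            raise CtMatrixError(f"{path}: no data rows")
        raw.index = raw.index.astype(str)
        raw.columns = raw.columns.astype(str)
        for col in raw.columns:
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()]
            if len(bad) and not raw[col].isna().any():
                raise CtMatrixError(
                    f"{path}: non-numeric Ct for gene {bad[0]!r}, sample {col!r}"
                )
        na = raw.isna()
        if na.any().any():
            g = raw.index[na.any(axis=1)][0]
            s = raw.columns[na.loc[g]][0]
            raise CtMatrixError(f"{path}: missing cell for gene {g!r}, sample {s!r}")
        values = raw.astype(float)
    elif layout == "long":
        raw = pd.read_csv(path, sep=sep)
        if raw.empty:
            raise CtMatrixError(f"{path}: no data rows")
        raw.columns = [c.lower() for c in raw.columns]
        needed = {"gene", "sample", "ct"}
        if not needed.issubset(raw.columns):
            raise CtMatrixError(
                f"{path}: long layout needs columns gene,sample,ct "
                f"(found {list(raw.columns)})"
            )
        dup = raw.duplicated(subset=["gene", "sample"])
        if dup.any():
            row = raw[dup].iloc[0]
            raise CtMatrixError(
                f"{path}: duplicate entry for gene {row['gene']!r}, "
                f"sample {row['sample']!r}"
            )
        ct = pd.to_numeric(raw["ct"], errors="coerce")
        if ct.isna().any():
            line = int(raw.index[ct.isna()][0]) + 2  # header + 1-based
            raise CtMatrixError(f"{path}: non-numeric Ct on line {line}")
        raw["ct"] = ct
        values = raw.pivot(index="gene", columns="sample", values="ct")
        # preserve first-appearance order rather than pivot's lexical sort
        values = values.loc[
            raw["gene"].astype(str).drop_duplicates().tolist(),
            raw["sample"].astype(str).drop_duplicates().tolist(),
        ]
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")

    if annotation is not None:
        group_of = _read_annotation(Path(annotation))
        unknown = set(group_of.index) - set(values.columns)
        if unknown:
            raise CtMatrixError(
                f"annotation lists unknown samples: {sorted(unknown)}"
            )
    else:
        group_of = pd.Series("all", index=values.columns)
    return CtMatrix(values=values, group_of=group_of)


def write_ct_table(
    ct: CtMatrix,
    path: str | Path,
    layout: str = "wide",
    annotation: str | Path | None = None,
) -> None:
    """Write a CtMatrix back to delimited text (UTF-8, '.' decimal)."""
    path = Path(path)
    sep = _sep_for(path)
    if layout == "wide":
        ct.to_wide().to_csv(path, sep=sep, encoding="utf-8")
    elif layout == "long":
        ct.to_long().to_csv(path, sep=sep, index=False, encoding="utf-8")
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    if annotation is not None:
        apath = Path(annotation)
        ct.annotation().to_csv(apath, sep=_sep_for(apath), index=False,
                               encoding="utf-8")


def builtin_dataset() -> CtMatrix:
    """The packaged six-species PBMC Ct dataset (32 samples x 10 genes)."""
    base = resources.files("refstab") / "datasets"
    with resources.as_file(base / "leh_ladakh_pbmc_ct.csv") as p:
        values = pd.read_csv(p, index_col=0)
    with resources.as_file(base / "leh_ladakh_pbmc_groups.csv") as p:
        ann = pd.read_csv(p)
    group_of = pd.Series(ann["group"].to_numpy(), index=ann["sample"])
    return CtMatrix(values=values, group_of=group_of)


def subset_by_group(ct: CtMatrix, group: str, min_samples: int = MIN_SAMPLES) -> SpeciesPanel:
    """Restrict a CtMatrix to one group's samples, gene order preserved."""
    mask = ct.group_of == group
    if not mask.any():
        raise KeyError(
            f"unknown group {group!r}; available: {ct.groups}"
        )
    samples = [s for s in ct.samples if mask[s]]
    sub = CtMatrix(
        values=ct.values[samples].copy(),
        group_of=ct.group_of[samples].copy(),
    )
    return SpeciesPanel(code=group, ct=sub, min_samples=min_samples)
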