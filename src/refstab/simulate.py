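"""Synthetic Ct-matrix generation and parameter-recovery experiments.

The generator draws from the additive model the stability algorithms
assume on the Ct scale:

    Ct[g, s] = baseline_ct[g] + b_s + e_gs
    b_s  ~ Normal(0, tau)       shared per-sample loading shift
    e_gs ~ Normal(0, sigma_g)   gene-specific technical/biological noise

A per-sample shift on the Ct scale is multiplicative on the quantity
scale, which is exactly what geometric-mean normalisation factors
remove; ``sigma_g`` is the injected "instability" each method should
recover.  Defaults mirror a typical candidate panel: 10 genes by 6
samples, baselines spread uniformly over 14-30 cycles (the span of real
PBMC reference-gene panels), a loading SD of 0.5 cycles, and noise SDs
graded from 0.1 to 1.0 cycles so the panel contains both stable and
unstable candidates.  No outlier or dropout model is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .bestkeeper import bestkeeper_analysis
from .data import CtMatrix, SpeciesPanel, subset_by_group
from .deltact import delta_ct_stability
from .genorm import stepwise_ranking
from .normfinder import normfinder_stability
from .transform import EfficiencySpec, relative_quantity

__all__ = ["SyntheticSpec", "generate", "recovery_experiment"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic Ct generator.

    baseline_ct and gene_noise_sd may be given per gene; left as None
    they are filled from the defaults described in the module docstring.
    ``efficiency`` only matters when downstream analyses are run with a
    non-default amplification factor; generation itself is on the Ct
    scale.
    """

    n_genes: int = 10
    n_samples: int = 6
    baseline_ct: np.ndarray | list[float] | None = None
    sample_effect_sd: float = 0.5
    gene_noise_sd: np.ndarray | list[float] | None = None
    efficiency: float = 2.0
    seed: int = 0
    group: str = "SIM"

    def __post_init__(self) -> None:
        if self.sample_effect_sd < 0:
            raise ValueError("sample_effect_sd must be >= 0")
        if self.gene_noise_sd is not None:
            sig = np.asarray(self.gene_noise_sd, dtype=float)
            if sig.size != self.n_genes:
                raise ValueError(
                    f"gene_noise_sd has {sig.size} entries for {self.n_genes} genes"
                )
            if (sig < 0).any():
                raise ValueError("gene noise SDs must be >= 0")
        if self.baseline_ct is not None:
            base = np.asarray(self.baseline_ct, dtype=float)
            if base.size != self.n_genes:
                raise ValueError(
                    f"baseline_ct has {base.size} entries for {self.n_genes} genes"
                )

    def resolved(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Baseline and noise-SD vectors, drawing defaults where unset."""
        if self.baseline_ct is None:
            base = rng.uniform(14.0, 30.0, size=self.n_genes)
        else:
            base = np.asarray(self.baseline_ct, dtype=float)
        if self.gene_noise_sd is None:
            sig = np.linspace(0.1, 1.0, self.n_genes)
        else:
            sig = np.asarray(self.gene_noise_sd, dtype=float)
        return base, sig

    def to_dict(self) -> dict:
        d = {
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "sample_effect_sd": self.sample_effect_sd,
            "efficiency": self.efficiency,
            "seed": self.seed,
            "group": self.group,
        }
        if self.baseline_ct is not None:
            d["baseline_ct"] = [float(x) for x in np.asarray(self.baseline_ct)]
        if self.gene_noise_sd is not None:
            d["gene_noise_sd"] = [float(x) for x in np.asarray(self.gene_noise_sd)]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


def generate(spec: SyntheticSpec) -> CtMatrix:
    """Draw one Ct matrix from the spec; deterministic under its seed."""
    rng = np.random.default_rng(spec.seed)
    base, sig = spec.resolved(rng)
    b = rng.normal(0.0, spec.sample_effect_sd, size=spec.n_samples)
    e = rng.normal(0.0, 1.0, size=(spec.n_genes, spec.n_samples)) * sig[:, None]
    ct = base[:, None] + b[None, :] + e
    genes = [f"G{i + 1:02d}" for i in range(spec.n_genes)]
    samples = [f"S{j + 1:02d}" for j in range(spec.n_samples)]
    values = pd.DataFrame(ct, index=genes, columns=samples)
    group_of = pd.Series(spec.group, index=values.columns)
    return CtMatrix(values=values, group_of=group_of)


def _panel(ct: CtMatrix, group: str) -> SpeciesPanel:
    return subset_by_group(ct, group)


def recovery_experiment(spec: SyntheticSpec, n_reps: int = 20) -> dict:
    """Run all four methods on replicate draws and score recovery.

    Per replicate the generator is reseeded as ``spec.seed + rep`` and
    each method's score vector is compared to the injected noise SDs by
    Spearman correlation.  Returns a dict with:

    ``spearman``
        DataFrame (replicate x method) of correlations.
    ``mean_rank``
        DataFrame (gene x method) of each gene's rank averaged over
        replicates (1 = judged most stable).
    ``sigma``
        The injected per-gene noise SDs.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    eff = EfficiencySpec(default=spec.efficiency)
    methods = ("genorm", "normfinder", "bestkeeper", "deltact")
    rho = {m: [] for m in methods}
    rank_sum = {m: np.zeros(spec.n_genes) for m in methods}
    sigma = None
    genes = None
    for rep in range(n_reps):
        rep_spec = SyntheticSpec(**{**spec.to_dict(), "seed": spec.seed + rep})
        rng = np.random.default_rng(rep_spec.seed)
        _, sigma = rep_spec.resolved(rng)
        ct = generate(rep_spec)
        panel = _panel(ct, spec.group)
        genes = panel.genes
        qm = relative_quantity(panel, eff)
        trace = stepwise_ranking(qm)
        scores = {
            "genorm": trace.m_at_exclusion.reindex(genes),
            "normfinder": normfinder_stability(qm).stability,
            "bestkeeper": bestkeeper_analysis(panel).sd_cp.reindex(genes),
            "deltact": delta_ct_stability(panel).mean_sd,
        }
        for m, s in scores.items():
            rho[m].append(float(spearmanr(sigma, s.to_numpy()).statistic))
            order = s.to_numpy().argsort(kind="stable").argsort() + 1
            rank_sum[m] += order
    spearman = pd.DataFrame(rho)
    spearman.index.name = "replicate"
    mean_rank = pd.DataFrame(
        {m: rank_sum[m] / n_reps for m in methods}, index=genes
    )
    mean_rank.index.name = "gene"
    return {"spearman": spearman, "mean_rank": mean_rank,
            "sigma": pd.Series(sigma, index=genes, name="sigma")}
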