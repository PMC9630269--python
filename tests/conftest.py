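import numpy as np
import pandas as pd
import pytest

from refstab import (
    EfficiencySpec,
    ReferenceGeneStability,
    builtin_dataset,
    relative_quantity,
    subset_by_group,
)

SPECIES = ("LAC", "LAY", "LAD", "CHG", "DHC", "ZAP")


@pytest.fixture(scope="session")
def ct():
    return builtin_dataset()


@pytest.fixture(scope="session")
def panels(ct):
    return {sp: subset_by_group(ct, sp) for sp in SPECIES}


@pytest.fixture(scope="session")
def quantities(panels):
    eff = EfficiencySpec()
    return {sp: relative_quantity(p, eff) for sp, p in panels.items()}


@pytest.fixture(scope="session")
def fitted():
    """Full six-species fit, shared across tests (read-only)."""
    return ReferenceGeneStability.builtin().fit()


def make_panel(values: np.ndarray, genes=None, samples=None, group="T"):
    """Small helper: build a SpeciesPanel from a raw array."""
    from refstab import CtMatrix, subset_by_group

    values = np.asarray(values, dtype=float)
    g, n = values.shape
    genes = genes or [f"g{i}" for i in range(g)]
    samples = samples or [f"s{j}" for j in range(n)]
    frame = pd.DataFrame(values, index=genes, columns=samples)
    ct = CtMatrix(values=frame, group_of=pd.Series(group, index=frame.columns))
    return subset_by_group(ct, group)
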