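import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from gmhi import AbundanceTable, CohortSpec, generate_cohort
from gmhi.profiles import HEALTHY, NONHEALTHY


def make_table(rows: dict, groups: dict | None = None,
               phenotypes: dict | None = None,
               bmi: dict | None = None,
               lineages: dict | None = None,
               normalize: bool = False) -> AbundanceTable:
    """Build an AbundanceTable from {sample: {species: abundance}}."""
    data = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    meta = pd.DataFrame(index=data.index)
    if groups:
        meta["group"] = pd.Series(groups)
    if phenotypes:
        meta["phenotype"] = pd.Series(phenotypes)
    if bmi:
        meta["bmi"] = pd.Series(bmi)
    table = AbundanceTable(data, meta if len(meta.columns) else None, lineages)
    return table.normalized() if normalize else table


def random_group_table(rng: np.random.Generator, n_h: int = 20, n_n: int = 15,
                       n_species: int = 12, sparsity: float = 0.5,
                       ) -> AbundanceTable:
    """Random sparse compositional table with healthy/nonhealthy labels."""
    n = n_h + n_n
    present = rng.random((n, n_species)) > sparsity
    empty = ~present.any(axis=1)
    present[empty, 0] = True
    vals = np.where(present, rng.lognormal(-3, 1, (n, n_species)), 0.0)
    vals /= vals.sum(axis=1, keepdims=True)
    ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"group": [HEALTHY] * n_h + [NONHEALTHY] * n_n},
        index=ids)
    return AbundanceTable(
        pd.DataFrame(vals, index=ids,
                     columns=[f"sp{j}" for j in range(n_species)]),
        meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared across tests (read-only)."""
    return generate_cohort(
        CohortSpec(n_h=120, n_n=120, n_species=50, n_planted_h=6,
                   n_planted_n=6, seed=11))
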