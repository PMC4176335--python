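"""Shared fixtures: the synthetic study dataset is generated once per
session (deterministic seed) and reused by unit and acceptance tests."""

from __future__ import annotations

import pytest

from rmscape.core_model import Gene, Replicon
from rmscape.homology import RoleCall
from rmscape.pipeline import analyze_dataset
from rmscape.synthetic_data import (CladeSimConfig, build_reference_library,
                                    simulate_clade, standard_dataset)

DATASET_SEED = 11


@pytest.fixture(scope="session")
def library():
    lib, founders = build_reference_library(DATASET_SEED)
    return lib, founders


@pytest.fixture(scope="session")
def dataset():
    return standard_dataset(DATASET_SEED)


@pytest.fixture(scope="session")
def analysis(dataset):
    return analyze_dataset(dataset, run_dnds=False)


@pytest.fixture(scope="session")
def clade_full():
    """A 7-strain clade with indels and one inversion per strain."""
    return simulate_clade(CladeSimConfig(clade_id="cl", sequences=True),
                          DATASET_SEED)


def make_replicon(role_plan: dict[int, tuple[str, str]], n_genes: int = 40,
                  circular: bool = True,
                  replicon_id: str = "rep") -> tuple[Replicon, dict]:
    """A bare replicon plus RoleCalls: role_plan maps rank -> (role, rm_type
    or flags tuple)."""
    genes = [Gene(f"{replicon_id}_g{i:03d}", replicon_id, i, 10 * i + 1,
                  10 * i + 9, "+", "M") for i in range(n_genes)]
    rep = Replicon(replicon_id, "chromosome", 10 * n_genes + 10, circular,
                   genes)
    roles = {}
    for rank, spec in role_plan.items():
        role, rm_type = spec[0], spec[1]
        flags = spec[2] if len(spec) > 2 else frozenset({(role if role not in
                                                          ("IIC", "TypeIV_REase")
                                                          else "REase",
                                                          rm_type or "IIC")})
        roles[genes[rank].gene_id] = RoleCall(genes[rank].gene_id, role,
                                              rm_type or "none", None,
                                              frozenset(flags))
    return rep, roles
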