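import numpy as np
import pytest

from vegftrap.config import (
    default_normal_mouse_config,
    default_xenograft_config,
    kinetics_from_config,
    network_spec_from_config,
    trafficking_from_config,
)
from vegftrap.engine import CompiledModel
from vegftrap.network import build_network


@pytest.fixture(scope="session")
def xenograft_config():
    return default_xenograft_config()


@pytest.fixture(scope="session")
def xenograft_network(xenograft_config):
    spec = network_spec_from_config(xenograft_config)
    return build_network(
        spec,
        kinetics_from_config(xenograft_config),
        trafficking_from_config(xenograft_config),
    )


@pytest.fixture(scope="session")
def xenograft_model(xenograft_config):
    return CompiledModel.from_config(xenograft_config)


@pytest.fixture(scope="session")
def xenograft_steady_state(xenograft_model):
    return xenograft_model.steady_state()


@pytest.fixture(scope="session")
def normal_mouse_config():
    return default_normal_mouse_config()


def make_inert_config(tumor_volume_cm3=0.01):
    """Xenograft config with all reactions, transport, secretion and
    trafficking switched off: only tumor-growth dilution remains active."""
    cfg = default_xenograft_config()
    for tab in cfg["kinetics"].values():
        tab["kon_per_M_s"] = 0.0
        tab["koff_per_s"] = 0.0
    for k in cfg["transport"]["clearance_per_s"]:
        cfg["transport"]["clearance_per_s"][k] = 0.0
    for side in ("normal", "tumor"):
        for k in cfg["transport"]["permeability_cm_per_s"][side]:
            cfg["transport"]["permeability_cm_per_s"][side][k] = 0.0
        cfg["transport"]["lymph_flow_cm3_per_s_per_cm3"][side] = 0.0
    cfg["transport"]["k_deg_per_s"] = 0.0
    for k in (
        "q_muscle_molecules_per_cell_s",
        "q_ec_molecules_per_cell_s",
        "q_tumor_molecules_per_cell_s",
        "q_svegfr1_ec_molecules_per_cell_s",
    ):
        cfg["secretion"][k] = 0.0
    for k in cfg["trafficking"]:
        cfg["trafficking"][k] = 0.0
    cfg["growth"]["initial_volume_cm3"] = tumor_volume_cm3
    return cfg
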