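"""Model configuration: schema, defaults, validation, YAML I/O.

The configuration is a nested mapping whose keys carry their units in their
names (``kon_per_M_s``, ``volume_cm3``, ...). A single declared schema is used
both to validate user files (unknown keys and out-of-range values are rejected
with the offending key path) and to document what each block means.

``default_xenograft_config()`` is the shipped three-compartment mouse bearing
a human tumor xenograft; ``default_normal_mouse_config()`` is the
two-compartment special case (no tumor) used for Table-1-style fits.

Kinetic rates, receptor densities and normal-compartment geometry are
prior-model defaults (the quantities this package derives and tests are the
tumor geometry chain, the network census, and the printed transport/bounds
values); every number here is overridable from YAML.
"""

from __future__ import annotations

import copy
import math

import yaml

from .geometry import derive_tumor_geometry
from .network import (
    Isoform,
    MatrixRegionSpec,
    NetworkSpec,
    SurfaceSpec,
)

__all__ = [
    "default_xenograft_config",
    "default_normal_mouse_config",
    "load_config",
    "save_config",
    "validate_config",
    "network_spec_from_config",
    "kinetics_from_config",
    "trafficking_from_config",
    "get_param",
    "set_param",
]

GROWTH_RATE_AVERAGE_PER_DAY = math.log(1e5) / 14.0  # 1e-6 -> 0.1 cm^3 in 14 days
GROWTH_RATE_FAST_PER_DAY = math.log(1e5) / 10.0

#: interaction-class kinetic table: kon (M^-1 s^-1), koff (s^-1).
#: One table keyed by interaction class — mouse/human pairings share rates.
DEFAULT_KINETICS = {
    "V:R1": {"kon_per_M_s": 3.0e7, "koff_per_s": 1.0e-3},
    "V:R2": {"kon_per_M_s": 1.0e7, "koff_per_s": 1.0e-3},
    "V:NRP": {"kon_per_M_s": 3.2e6, "koff_per_s": 1.0e-3},
    "coupling:R2_VN": {"kon_per_M_s": 1.0e7, "koff_per_s": 1.0e-3},
    "coupling:VR2_N": {"kon_per_M_s": 3.2e6, "koff_per_s": 1.0e-3},
    "coupling:VR1_N": {"kon_per_M_s": 3.2e6, "koff_per_s": 1.0e-3},
    "coupling:VN_R1": {"kon_per_M_s": 3.0e7, "koff_per_s": 1.0e-3},
    "coupling:R1_N": {"kon_per_M_s": 1.0e6, "koff_per_s": 1.0e-3},
    "sR1:V": {"kon_per_M_s": 3.3e7, "koff_per_s": 1.65e-3},  # Kd 50 pM
    "sR1:NRP": {"kon_per_M_s": 1.0e4, "koff_per_s": 1.0e-3},
    "V:GAG": {"kon_per_M_s": 4.2e5, "koff_per_s": 1.0e-2},
    "V:HSPG": {"kon_per_M_s": 4.2e5, "koff_per_s": 1.0e-2},
    # VEGF Trap: kon from SPR-scale measurements; Kd = 0.5 pM default
    # (fitted two-compartment value 0.29 pM; in-vitro 0.6 pM).
    "Trap:V": {"kon_per_M_s": 1.0e7, "koff_per_s": 5.0e-6},
    # weak, high-capacity plasma buffering: at 1.4 uM native / 14 nM activated,
    # each alpha2M form holds ~10% of the amount of free circulating VEGF
    "a2Mn:V": {"kon_per_M_s": 1.0e2, "koff_per_s": 1.4e-3},
    "a2Mf:V": {"kon_per_M_s": 1.0e4, "koff_per_s": 1.4e-3},
}

_SURFACE_FEATURES = (
    "vr1n_ternary",
    "r1n_coupling",
    "sr1_nrp",
    "hspg",
    "track_internalized",
    "receptor_pools",
)


def default_xenograft_config() -> dict:
    """Three-compartment tumor-bearing mouse (human xenograft) configuration."""
    tumor_geom = derive_tumor_geometry()
    gd = tumor_geom.as_flat_dict()
    ec_area_per_cell_cm2 = 1.0e-5  # ~1000 um^2 endothelial cell
    cfg = {
        "seed": 0,
        "geometry": {
            "normal": {
                # mouse skeletal muscle stands in for all normal tissue
                "volume_cm3": 9.0,
                "available_fluid_fraction": 0.10,
                "s_ec_cm2_per_cm3": 70.0,
                "ec_cells_per_cm3": 70.0 / ec_area_per_cell_cm2,  # 7.0e6
                "parenchymal_cells_per_cm3": 2.0e5,  # myocytes (large fibers)
            },
            "blood": {"plasma_volume_cm3": 1.0},
            "tumor": {
                "cell_diameter_um": 12.0,
                "lumen_diameter_um": 13.94,
                "wall_thickness_um": 0.5,
                "perimeter_correction": 0.23,
                "f_extracellular_fluid": 0.45,
                "f_intravascular": 0.10,
                "ebm_thickness_nm": 50.0,
                "pbm_thickness_nm": 30.0,
                "bm_fluid_fraction": 0.7,
                "ecm_fluid_fraction": 0.9318,
                "partition_coefficient": 0.9,
                # published available-fluid volumes carried as overrides of the
                # product formula (see geometry module notes)
                "available_fluid_overrides": {
                    "ECM": 0.2916,
                    "EBM": 9.720e-4,
                    "PBM": 5.082e-3,
                },
                "ec_cells_per_cm3": gd["s_ec_cm2_per_cm3"] / ec_area_per_cell_cm2,
            },
        },
        "growth": {
            "enabled": True,
            "initial_volume_cm3": 1e-6,
            "profile": "average",  # average | fast
            "rate_average_per_day": GROWTH_RATE_AVERAGE_PER_DAY,
            "rate_fast_per_day": GROWTH_RATE_FAST_PER_DAY,
            "trigger_volume_cm3": 0.1,  # ~100 mm^3 at first injection
        },
        "network": {
            "tumor_enabled": True,
            "isoforms": ["V120", "V164", "V121", "V165"],
            "svegfr1": True,
            "a2m": True,
            "trap": True,
            "surfaces": {
                "muscle_fiber": {
                    "compartment": "normal",
                    "tissue": "normal",
                    "cells": "parenchymal",
                    "receptors_per_cell": {"R1": 24000, "R2": 9600, "N1": 40000},
                },
                "EC_abluminal_normal": {
                    "compartment": "normal",
                    "tissue": "normal",
                    "cells": "ec",
                    "receptors_per_cell": {"R1": 10000, "R2": 10000, "N1": 20000},
                },
                "EC_luminal_normal": {
                    "compartment": "blood",
                    "tissue": "normal",
                    "cells": "ec",
                    "receptors_per_cell": {"R1": 10000, "R2": 10000, "N1": 20000},
                    "vr1n_ternary": True,
                    "r1n_coupling": True,
                    "sr1_nrp": True,
                    "hspg": True,
                    "hspg_sites_per_cell": 1.0e5,
                    "track_internalized": True,
                    "receptor_pools": True,
                },
                "EC_luminal_tumor": {
                    "compartment": "blood",
                    "tissue": "tumor",
                    "cells": "ec",
                    "receptors_per_cell": {"R1": 10000, "R2": 10000, "N1": 20000},
                    "vr1n_ternary": True,
                    "r1n_coupling": True,
                    "sr1_nrp": True,
                    "hspg": True,
                    "hspg_sites_per_cell": 1.0e5,
                    "track_internalized": True,
                    "receptor_pools": True,
                },
                "EC_abluminal_tumor": {
                    "compartment": "tumor",
                    "tissue": "tumor",
                    "cells": "ec",
                    "receptors_per_cell": {"R1": 10000, "R2": 10000, "N1": 20000},
                },
                "tumor_cell": {
                    "compartment": "tumor",
                    "tissue": "tumor",
                    "cells": "parenchymal",
                    # NRP2 at the same surface level as NRP1
                    "receptors_per_cell": {"R1": 1100, "R2": 550, "N1": 20000, "N2": 20000},
                    "vr1n_ternary": True,
                    "sr1_nrp": True,
                    "hspg": True,
                    "hspg_sites_per_cell": 1.0e5,
                    "receptor_pools": True,
                },
            },
            "matrix_site_density_uM": {
                "normal": {"ECM": 0.75, "EBM": 13.0, "PBM": 13.0},
                "tumor": {"ECM": 0.75, "EBM": 13.0, "PBM": 13.0},
            },
        },
        "kinetics": copy.deepcopy(DEFAULT_KINETICS),
        "trafficking": {
            "k_int_complex_per_s": 2.8e-4,
            "k_int_receptor_per_s": 2.8e-4,
            "k_insert_per_s": 2.8e-3,
            "k_deg_internal_per_s": 1.0e-4,
        },
        "transport": {
            # microvascular permeability, cm/s; tumor endothelium 10x leakier
            "permeability_cm_per_s": {
                "normal": {
                    "V": 4.0e-8,
                    "sR1": 1.5e-8,
                    "sR1_V": 1.5e-8,
                    "Trap": 3.0e-8,
                    "Trap_V": 3.0e-8,
                },
                "tumor": {
                    "V": 4.0e-7,
                    "sR1": 1.5e-7,
                    "sR1_V": 1.5e-7,
                    "Trap": 3.0e-7,
                    "Trap_V": 3.0e-7,
                },
            },
            # lymphatic drainage per cm^3 tissue; tumors lack functional lymphatics
            "lymph_flow_cm3_per_s_per_cm3": {"normal": 1.3e-6, "tumor": 0.0},
            "clearance_per_s": {
                "V": 3.4e-4,
                "sR1": 3.0e-4,
                "Trap": 1.3e-5,  # fitted two-compartment c_A
                "Trap_V": 2.5e-6,  # fitted two-compartment c_VA
                "a2M": 2.62e-3 / 60.0,  # ln2 / measured half-life
            },
            # soluble-factor complexes cleared at the slower partner's rate
            "complex_clearance_rule": "slower_partner",
            "k_deg_per_s": 1.28e-4,  # proteolysis of free VEGF in tissue
        },
        "secretion": {
            # Table-2 A673 baseline means (molecules/cell/s)
            "q_muscle_molecules_per_cell_s": 0.011,
            "q_ec_molecules_per_cell_s": 0.009,
            "q_tumor_molecules_per_cell_s": 0.009,
            "muscle_isoform_split": {"V120": 0.08, "V164": 0.92},
            "ec_isoform_split": {"V120": 0.10, "V164": 0.90},
            "tumor_isoform_split": {"V121": 0.50, "V165": 0.50},
            "q_svegfr1_ec_molecules_per_cell_s": 6.0e-3,
            "ec_luminal_fraction": 0.5,  # luminal/abluminal split of EC secretion
        },
        "concentrations": {
            "a2m_native_uM": 1.4,
            "a2m_fast_nM": 14.0,
        },
        "dosing": {
            "body_weight_g": 25.0,
            "mw_trap_kda": 115.0,
            "infusion_duration_s": 60.0,
        },
        "solver": {
            "rtol": 1.0e-8,
            "atol_pM": 1.0e-6,
            "method": "BDF",
            "steady_state_time_s": 2.0e7,
        },
    }
    return cfg


def default_normal_mouse_config() -> dict:
    """Two-compartment (non-tumor-bearing) mouse: tumor compartment disabled."""
    cfg = default_xenograft_config()
    cfg["network"]["tumor_enabled"] = False
    cfg["growth"]["enabled"] = False
    # Table-1 optimum for the normal mouse
    cfg["secretion"]["q_muscle_molecules_per_cell_s"] = 0.002
    cfg["secretion"]["q_ec_molecules_per_cell_s"] = 0.057
    return cfg


# --------------------------------------------------------------------------
# validation


def _fail(path: str, msg: str) -> None:
    raise ValueError(f"config key '{path}': {msg}")


def _require_keys(d: dict, allowed: set, path: str, required: set | None = None) -> None:
    unknown = set(d) - allowed
    if unknown:
        _fail(f"{path}.{sorted(unknown)[0]}", "unknown key")
    for k in required or allowed:
        if k not in d:
            _fail(f"{path}.{k}", "missing key")


def _check_nonneg(d: dict, keys: list, path: str) -> None:
    for k in keys:
        v = d[k]
        if not isinstance(v, (int, float)) or v < 0:
            _fail(f"{path}.{k}", f"must be a non-negative number (units in key name), got {v!r}")


def validate_config(cfg: dict) -> dict:
    """Validate structure, units and ranges; returns the config unchanged."""
    _require_keys(
        cfg,
        {
            "seed", "geometry", "growth", "network", "kinetics", "trafficking",
            "transport", "secretion", "concentrations", "dosing", "solver",
        },
        "config",
    )
    for side in ("normal", "tumor"):
        perm = cfg["transport"]["permeability_cm_per_s"][side]
        _check_nonneg(perm, list(perm), f"transport.permeability_cm_per_s.{side}")
    for cls in cfg["transport"]["permeability_cm_per_s"]["normal"]:
        kp_n = cfg["transport"]["permeability_cm_per_s"]["normal"][cls]
        kp_t = cfg["transport"]["permeability_cm_per_s"]["tumor"][cls]
        if kp_t < kp_n:
            _fail(
                f"transport.permeability_cm_per_s.tumor.{cls}",
                "tumor vasculature must be at least as permeable as normal",
            )
    _check_nonneg(
        cfg["transport"]["clearance_per_s"],
        list(cfg["transport"]["clearance_per_s"]),
        "transport.clearance_per_s",
    )
    _check_nonneg(cfg["transport"]["lymph_flow_cm3_per_s_per_cm3"], ["normal", "tumor"],
                  "transport.lymph_flow_cm3_per_s_per_cm3")
    if cfg["transport"]["k_deg_per_s"] < 0:
        _fail("transport.k_deg_per_s", "must be >= 0")
    for key, tab in cfg["kinetics"].items():
        _require_keys(tab, {"kon_per_M_s", "koff_per_s"}, f"kinetics.{key}")
        _check_nonneg(tab, ["kon_per_M_s", "koff_per_s"], f"kinetics.{key}")
    for name, split_key in (
        ("muscle_isoform_split", None),
        ("ec_isoform_split", None),
        ("tumor_isoform_split", None),
    ):
        split = cfg["secretion"][name]
        if abs(sum(split.values()) - 1.0) > 1e-9:
            _fail(f"secretion.{name}", "isoform fractions must sum to 1")
    _check_nonneg(
        cfg["secretion"],
        [
            "q_muscle_molecules_per_cell_s",
            "q_ec_molecules_per_cell_s",
            "q_tumor_molecules_per_cell_s",
            "q_svegfr1_ec_molecules_per_cell_s",
        ],
        "secretion",
    )
    for surf_id, s in cfg["network"]["surfaces"].items():
        for r, v in s["receptors_per_cell"].items():
            if v < 0:
                _fail(f"network.surfaces.{surf_id}.receptors_per_cell.{r}", "must be >= 0")
    g = cfg["growth"]
    if g["initial_volume_cm3"] < 0 or g["trigger_volume_cm3"] <= 0:
        _fail("growth", "volumes must be positive (cm^3)")
    if g["profile"] not in ("average", "fast"):
        _fail("growth.profile", "must be 'average' or 'fast'")
    if cfg["dosing"]["infusion_duration_s"] <= 0:
        _fail("dosing.infusion_duration_s", "must be > 0 (seconds)")
    return cfg


def load_config(path: str) -> dict:
    """Load and validate a YAML (or JSON — a YAML subset) configuration.

    The file may be partial: it is deep-merged over the xenograft defaults.
    """
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_xenograft_config()
    _deep_merge(cfg, user, "config")
    return validate_config(cfg)


def save_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _deep_merge(base: dict, user: dict, path: str) -> None:
    for k, v in user.items():
        if k not in base:
            _fail(f"{path}.{k}", "unknown key")
        if isinstance(base[k], dict) and isinstance(v, dict):
            _deep_merge(base[k], v, f"{path}.{k}")
        else:
            base[k] = v


# --------------------------------------------------------------------------
# structural spec from config


def network_spec_from_config(cfg: dict) -> NetworkSpec:
    net = cfg["network"]
    tumor = net["tumor_enabled"]
    compartments = ("normal", "blood", "tumor") if tumor else ("normal", "blood")
    isoforms = tuple(
        Isoform(n, "mouse" if n in ("V120", "V164") else "human") for n in net["isoforms"]
    )
    surfaces = []
    for sid, s in net["surfaces"].items():
        if not tumor and (s["compartment"] == "tumor" or s["tissue"] == "tumor"):
            continue
        features = {f: bool(s.get(f, False)) for f in _SURFACE_FEATURES}
        surfaces.append(
            SurfaceSpec(
                id=sid,
                compartment=s["compartment"],
                tissue=s["tissue"],
                receptors=tuple(s["receptors_per_cell"]),
                **features,
            )
        )
    regions = []
    for comp in ("normal", "tumor"):
        if comp == "tumor" and not tumor:
            continue
        for name in net["matrix_site_density_uM"][comp]:
            regions.append(MatrixRegionSpec(name, comp))
    return NetworkSpec(
        isoforms=isoforms,
        surfaces=tuple(surfaces),
        matrix_regions=tuple(regions),
        compartments=compartments,
        svegfr1=net["svegfr1"],
        a2m=net["a2m"],
        trap=net["trap"],
    )


def kinetics_from_config(cfg: dict) -> dict:
    return {
        k: {"kon": v["kon_per_M_s"], "koff": v["koff_per_s"]}
        for k, v in cfg["kinetics"].items()
    }


def trafficking_from_config(cfg: dict) -> dict:
    t = cfg["trafficking"]
    return {
        "k_int_complex": t["k_int_complex_per_s"],
        "k_int_receptor": t["k_int_receptor_per_s"],
        "k_insert": t["k_insert_per_s"],
        "k_deg_internal": t["k_deg_internal_per_s"],
    }


# --------------------------------------------------------------------------
# dotted-path parameter access (used by fitting, sweeps and eFAST)


def get_param(cfg: dict, path: str):
    node = cfg
    for part in path.split("."):
        node = node[part]
    return node


def set_param(cfg: dict, path: str, value) -> None:
    parts = path.split(".")
    node = cfg
    for part in parts[:-1]:
        node = node[part]
    if parts[-1] not in node:
        raise KeyError(f"unknown parameter path: {path}")
    node[parts[-1]] = value
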