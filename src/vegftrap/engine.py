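"""ODE assembly and integration for the three-compartment VEGF model.

State layout
------------
One concentration per enumerated species, in pM relative to the fluid phase
of its compartment (plasma for blood species, available interstitial fluid
for tissue species; surface and matrix species use the adjacent fluid as
reference volume so all mass-action terms are dimensionally uniform), plus
one bookkeeping state: the cumulative amount of VEGF Trap removed by plasma
clearance (pmol), used for drug-mass audits.

The right-hand side combines

* mass-action reaction fluxes (sparse stoichiometry x rate vector),
* secretion sources (myocytes, endothelium, tumor cells; sVEGFR1; alpha2M
  synthesis balancing its clearance),
* receptor insertion/synthesis maintaining ligand-free surface totals,
* transendothelial permeability exchange k_p * S * (C_blood - C_tissue),
* one-way lymphatic drainage from tissue to blood,
* plasma clearance (blood) and proteolytic degradation of free VEGF (tissue),
* an exponential tumor-volume dilution term, -(dV/dt / V) * C, applied to all
  tumor-compartment species so that amounts, not concentrations, are
  conserved under pure growth.

Tumor volume follows the prescribed exponential growth profile analytically
(drug exposure does not feed back on growth), so V(t) is not a state. All
blood-side couplings to the tumor scale linearly with V(t): the operator is
assembled once as L0 + V(t) * L1 and sources as b0 + V(t) * b1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from . import units
from .config import (
    kinetics_from_config,
    network_spec_from_config,
    trafficking_from_config,
    validate_config,
)
from .geometry import derive_tumor_geometry
from .network import Network, build_network

__all__ = [
    "DoseSchedule",
    "ModelState",
    "SimResult",
    "CompiledModel",
    "SteadyStateError",
    "assemble_rhs",
    "steady_state",
    "simulate",
    "dose_to_input",
]

MOUSE = ("V120", "V164")
HUMAN = ("V121", "V165")


class SteadyStateError(RuntimeError):
    """Raised when pre-equilibration does not converge; carries the residual."""

    def __init__(self, residual: float, worst_species: str):
        super().__init__(
            f"steady state not reached: residual {residual:.3e} (worst: {worst_species})"
        )
        self.residual = residual
        self.worst_species = worst_species


@dataclass(frozen=True)
class DoseSchedule:
    """Intravenous VEGF Trap dosing: amount, times, and infusion contract."""

    dose_mg_per_kg: float
    times_days: tuple[float, ...] = (0.0,)  # relative to the first injection
    infusion_duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg < 0:
            raise ValueError("dose must be >= 0")
        if self.infusion_duration_s <= 0:
            raise ValueError("infusion duration must be positive")
        if tuple(sorted(self.times_days)) != tuple(self.times_days):
            raise ValueError("dose times must be sorted")

    @staticmethod
    def twice_weekly(dose_mg_per_kg: float, weeks: int = 2,
                     infusion_duration_s: float = 60.0) -> "DoseSchedule":
        times = tuple(3.5 * i for i in range(2 * weeks))
        return DoseSchedule(dose_mg_per_kg, times, infusion_duration_s)


@dataclass
class ModelState:
    time_s: float
    concentrations_pM: np.ndarray  # one per species (audit state excluded)
    tumor_volume_cm3: float

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_pM, dtype=float)
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite concentration in model state")
        if c.min() < -1e-9:
            raise ValueError(f"negative concentration {c.min():.3e} pM in model state")


def _perm_class(name: str) -> str | None:
    """Permeability/clearance class of a fluid species, or None (no transport)."""
    if name.startswith("a2M"):
        return None
    if name == "Trap":
        return "Trap"
    if name.startswith("Trap_"):
        return "Trap_V"
    if name == "sR1":
        return "sR1"
    if name.startswith("sR1_"):
        return "sR1_V"
    return "V"


class CompiledModel:
    """A configuration compiled to fast array form.

    Build with :meth:`from_config`; derive variants with :meth:`with_params`
    (dotted config paths), which re-compiles from the updated configuration.
    """

    def __init__(self, cfg: dict, network: Network):
        self.cfg = cfg
        self.network = network
        self._compile()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_config(cls, cfg: dict) -> "CompiledModel":
        validate_config(cfg)
        spec = network_spec_from_config(cfg)
        net = build_network(spec, kinetics_from_config(cfg), trafficking_from_config(cfg))
        return cls(cfg, net)

    def with_params(self, updates: dict) -> "CompiledModel":
        import copy

        from .config import set_param

        cfg = copy.deepcopy(self.cfg)
        for path, value in updates.items():
            set_param(cfg, path, value)
        return CompiledModel.from_config(cfg)

    # -- compilation -------------------------------------------------------

    def _compile(self) -> None:  # noqa: C901  (long but linear assembly)
        cfg = self.cfg
        net = self.network
        species = net.species
        self.species_ids = [s.id for s in species]
        self.index = {sid: i for i, sid in enumerate(self.species_ids)}
        self.n_species = len(species)
        self.i_audit = self.n_species  # cumulative cleared Trap, pmol
        n = self.n_species + 1
        self.n_state = n

        geom = cfg["geometry"]
        self.tumor_enabled = cfg["network"]["tumor_enabled"]
        self.tumor_geom = derive_tumor_geometry(
            cell_diameter_um=geom["tumor"]["cell_diameter_um"],
            lumen_diameter_um=geom["tumor"]["lumen_diameter_um"],
            wall_thickness_um=geom["tumor"]["wall_thickness_um"],
            perimeter_correction=geom["tumor"]["perimeter_correction"],
            f_extracellular_fluid=geom["tumor"]["f_extracellular_fluid"],
            f_intravascular=geom["tumor"]["f_intravascular"],
            ebm_thickness_nm=geom["tumor"]["ebm_thickness_nm"],
            pbm_thickness_nm=geom["tumor"]["pbm_thickness_nm"],
            bm_fluid_fraction=geom["tumor"]["bm_fluid_fraction"],
            ecm_fluid_fraction=geom["tumor"]["ecm_fluid_fraction"],
            partition_coefficient=geom["tumor"]["partition_coefficient"],
            available_fluid_overrides=geom["tumor"].get("available_fluid_overrides"),
        )
        self.k_av = {
            "normal": geom["normal"]["available_fluid_fraction"],
            "blood": 1.0,
            "tumor": self.tumor_geom.available_fluid_fraction,
        }
        self.v_normal = geom["normal"]["volume_cm3"]
        self.v_plasma = geom["blood"]["plasma_volume_cm3"]
        self.vf_blood_l = self.v_plasma * 1e-3
        self.vf_normal_l = self.k_av["normal"] * self.v_normal * 1e-3

        growth = cfg["growth"]
        self.growth_enabled = bool(growth["enabled"]) and self.tumor_enabled
        self.v_tumor0 = growth["initial_volume_cm3"] if self.tumor_enabled else 0.0
        rate_key = f"rate_{growth['profile']}_per_day"
        self.growth_rate_per_s = growth[rate_key] / units.SECONDS_PER_DAY
        self.trigger_volume = growth["trigger_volume_cm3"]

        cells = {
            ("normal", "parenchymal"): geom["normal"]["parenchymal_cells_per_cm3"],
            ("normal", "ec"): geom["normal"]["ec_cells_per_cm3"],
            ("tumor", "parenchymal"): self.tumor_geom.cells_per_cm3,
            ("tumor", "ec"): geom["tumor"]["ec_cells_per_cm3"],
        }

        # reaction arrays ---------------------------------------------------
        a2, b2, c2, kon2, koff2 = [], [], [], [], []
        a1, c1, k1 = [], [], []
        for rx in net.reactions:
            if rx.koff is not None:  # reversible bimolecular binding/coupling
                ra, rb = rx.reactants
                a2.append(self.index[ra])
                b2.append(self.index[rb])
                c2.append(self.index[rx.products[0]])
                kon2.append(rx.kon * units.KON_M_TO_PM)
                koff2.append(rx.koff)
            else:  # unimolecular with 0 or 1 product
                a1.append(self.index[rx.reactants[0]])
                c1.append(self.index[rx.products[0]] if rx.products else -1)
                k1.append(rx.kon)
        self.a2 = np.array(a2, dtype=np.intp)
        self.b2 = np.array(b2, dtype=np.intp)
        self.c2 = np.array(c2, dtype=np.intp)
        self.kon2 = np.array(kon2)
        self.koff2 = np.array(koff2)
        self.a1 = np.array(a1, dtype=np.intp)
        self.c1 = np.array(c1, dtype=np.intp)
        self.k1 = np.array(k1)
        m2, m1 = len(a2), len(a1)

        rows, cols, vals = [], [], []
        for j in range(m2):
            rows += [self.a2[j], self.b2[j], self.c2[j]]
            cols += [j, j, j]
            vals += [-1.0, -1.0, 1.0]
        self.S2 = sparse.csr_matrix((vals, (rows, cols)), shape=(n, m2))
        rows, cols, vals = [], [], []
        for j in range(m1):
            rows.append(self.a1[j]); cols.append(j); vals.append(-1.0)
            if self.c1[j] >= 0:
                rows.append(self.c1[j]); cols.append(j); vals.append(1.0)
        self.S1 = sparse.csr_matrix((vals, (rows, cols)), shape=(n, m1))

        # jacobian pattern of the rate vectors
        self._d2_rows = np.repeat(np.arange(m2), 3)
        self._d2_cols = np.column_stack([self.a2, self.b2, self.c2]).ravel()
        self._d1_rows = np.arange(m1)
        self._d1_cols = self.a1
        self._d2_shape = (m2, n)
        self._d1_shape = (m1, n)

        # linear operator and sources ---------------------------------------
        L0 = sparse.lil_matrix((n, n))
        L1 = sparse.lil_matrix((n, n))
        b0 = np.zeros(n)
        b1 = np.zeros(n)
        tr = cfg["transport"]
        NA = units.AVOGADRO

        def fluid_idx(comp: str, name: str) -> int | None:
            return self.index.get(f"{comp}:fluid:{name}")

        fluid_names = sorted(
            {s.name for s in species if s.locale == "fluid" and s.compartment == "blood"}
        )
        active_tissues = [c for c in ("normal", "tumor") if c in net.spec.compartments]

        # permeability + lymph
        s_tot_normal = geom["normal"]["s_ec_cm2_per_cm3"] * self.v_normal
        s_ec_tumor = self.tumor_geom.composition.s_ec_cm2_per_cm3
        for tissue in active_tissues:
            kl = tr["lymph_flow_cm3_per_s_per_cm3"][tissue]
            for name in fluid_names:
                it = fluid_idx(tissue, name)
                ib = fluid_idx("blood", name)
                if it is None or ib is None:
                    continue
                cls = _perm_class(name)
                if cls is not None:
                    kp = tr["permeability_cm_per_s"][tissue][cls]
                    if tissue == "normal":
                        ct = kp * s_tot_normal * 1e-3 / self.vf_normal_l
                        cb = kp * s_tot_normal * 1e-3 / self.vf_blood_l
                        L0[it, it] -= ct; L0[it, ib] += ct
                        L0[ib, ib] -= cb; L0[ib, it] += cb
                    else:
                        ct = kp * s_ec_tumor * 1e-3 / (self.k_av["tumor"] * 1e-3)
                        cb1 = kp * s_ec_tumor * 1e-3 / self.vf_blood_l  # x V_T(t)
                        L0[it, it] -= ct; L0[it, ib] += ct
                        L1[ib, ib] -= cb1; L1[ib, it] += cb1
                if kl > 0:
                    if tissue == "normal":
                        lt = kl / self.k_av["normal"]
                        lb = kl * self.v_normal * 1e-3 / self.vf_blood_l
                        L0[it, it] -= lt
                        L0[ib, it] += lb
                    else:
                        L0[it, it] -= kl / self.k_av["tumor"]
                        L1[ib, it] += kl * 1e-3 / self.vf_blood_l

        # plasma clearance + Trap audit
        cl = tr["clearance_per_s"]
        slower = tr["complex_clearance_rule"] == "slower_partner"
        for name in fluid_names:
            ib = fluid_idx("blood", name)
            if ib is None:
                continue
            if name in MOUSE + HUMAN:
                c = cl["V"]
            elif name == "Trap":
                c = cl["Trap"]
            elif name.startswith("Trap_"):
                c = cl["Trap_V"]
            elif name == "sR1":
                c = cl["sR1"]
            elif name.startswith("sR1_"):
                c = min(cl["sR1"], cl["V"]) if slower else cl["sR1"]
            elif name in ("a2Mn", "a2Mf"):
                c = cl["a2M"]
            elif name.startswith("a2M"):
                c = min(cl["a2M"], cl["V"]) if slower else cl["a2M"]
            else:
                c = 0.0
            if c > 0:
                L0[ib, ib] -= c
                if name == "Trap" or name.startswith("Trap_"):
                    L0[self.i_audit, ib] += c * self.vf_blood_l

        # proteolytic degradation of free VEGF in tissue interstitium
        for tissue in active_tissues:
            for name in MOUSE + HUMAN:
                it = fluid_idx(tissue, name)
                if it is not None:
                    L0[it, it] -= tr["k_deg_per_s"]

        # secretion sources --------------------------------------------------
        sec = cfg["secretion"]
        f_lum = sec["ec_luminal_fraction"]

        def tissue_src(q: float, cells_per_cm3: float, tissue: str) -> float:
            # pM/s in the tissue's interstitial fluid; tumor volume cancels
            return q * cells_per_cm3 * 1e15 / (NA * self.k_av[tissue])

        def plasma_src(q: float, cells_per_cm3: float, v_tissue_cm3: float) -> float:
            return q * cells_per_cm3 * v_tissue_cm3 * 1e15 / (NA * self.v_plasma)

        for surf in net.spec.surfaces:
            scfg = cfg["network"]["surfaces"][surf.id]
            n_cells = cells[(surf.tissue, scfg["cells"])]
            if surf.id == "muscle_fiber":
                for iso, frac in sec["muscle_isoform_split"].items():
                    i = fluid_idx("normal", iso)
                    if i is not None:
                        b0[i] += tissue_src(
                            sec["q_muscle_molecules_per_cell_s"] * frac, n_cells, "normal"
                        )
            elif surf.id == "tumor_cell":
                for iso, frac in sec["tumor_isoform_split"].items():
                    i = fluid_idx("tumor", iso)
                    if i is not None:
                        b0[i] += tissue_src(
                            sec["q_tumor_molecules_per_cell_s"] * frac, n_cells, "tumor"
                        )
            elif scfg["cells"] == "ec":
                luminal = surf.compartment == "blood"
                q_v = sec["q_ec_molecules_per_cell_s"] * (f_lum if luminal else 1.0 - f_lum)
                q_s = sec["q_svegfr1_ec_molecules_per_cell_s"] * (
                    f_lum if luminal else 1.0 - f_lum
                )
                targets = {iso: q_v * frac for iso, frac in sec["ec_isoform_split"].items()}
                if net.spec.svegfr1:
                    targets["sR1"] = q_s
                for name, q in targets.items():
                    if luminal:
                        i = fluid_idx("blood", name)
                        if i is None:
                            continue
                        if surf.tissue == "normal":
                            b0[i] += plasma_src(q, n_cells, self.v_normal)
                        else:
                            b1[i] += plasma_src(q, n_cells, 1.0)  # x V_T(t)
                    else:
                        i = fluid_idx(surf.tissue, name)
                        if i is not None:
                            b0[i] += tissue_src(q, n_cells, surf.tissue)

        # alpha-2-macroglobulin synthesis balances its clearance at the
        # measured plasma levels (native 1.4 uM, activated 14 nM)
        conc = cfg["concentrations"]
        if net.spec.a2m and "blood" in net.spec.compartments:
            for name, target_pM in (
                ("a2Mn", conc["a2m_native_uM"] * 1e6),
                ("a2Mf", conc["a2m_fast_nM"] * 1e3),
            ):
                i = fluid_idx("blood", name)
                if i is not None:
                    b0[i] += cl["a2M"] * target_pM

        # receptor/site densities, insertion and synthesis sources -----------
        tk = trafficking_from_config(cfg)
        self.site_totals: dict[str, float] = {}  # species id -> ligand-free density (pM)
        self._b1_sites: dict[str, float] = {}  # luminal-tumor densities per cm^3 V_T
        for surf in net.spec.surfaces:
            scfg = cfg["network"]["surfaces"][surf.id]
            n_cells = cells[(surf.tissue, scfg["cells"])]
            luminal = surf.compartment == "blood"
            site_names = dict(scfg["receptors_per_cell"])
            if surf.hspg:
                site_names["HSPG"] = scfg["hspg_sites_per_cell"]
            for name, per_cell in site_names.items():
                sid = f"{surf.compartment}:{surf.id}:{name}"
                if luminal:
                    dens_per_vt = per_cell * n_cells * 1e15 / (NA * self.v_plasma)
                    if surf.tissue == "normal":
                        r0 = dens_per_vt * self.v_normal
                    else:
                        r0 = dens_per_vt * self.v_tumor0
                        self._b1_sites[sid] = dens_per_vt
                else:
                    r0 = per_cell * n_cells * 1e15 / (NA * self.k_av[surf.tissue])
                self.site_totals[sid] = r0
                is_receptor = name in surf.receptors
                pooled = surf.receptor_pools and is_receptor
                k_int = tk["k_int_receptor"]
                if k_int <= 0:
                    continue
                if pooled:
                    pool0 = r0 * k_int / tk["k_insert"] if tk["k_insert"] > 0 else 0.0
                    psid = f"{surf.compartment}:{surf.id}:{name}_pool"
                    self.site_totals[psid] = pool0
                    synth = tk["k_deg_internal"] * pool0
                    j = self.index[psid]
                    if sid in self._b1_sites:
                        self._b1_sites[psid] = self._b1_sites[sid] * k_int / tk["k_insert"]
                        b1[j] += tk["k_deg_internal"] * self._b1_sites[psid]
                    else:
                        b0[j] += synth
                else:
                    j = self.index[sid]
                    if sid in self._b1_sites:
                        b1[j] += k_int * self._b1_sites[sid]
                    else:
                        b0[j] += k_int * r0
        # matrix GAG totals (conserved; no turnover)
        for region in net.spec.matrix_regions:
            dens_uM = cfg["network"]["matrix_site_density_uM"][region.compartment][region.name]
            sid = f"{region.compartment}:{region.name}:GAG"
            self.site_totals[sid] = dens_uM * 1e6

        self.L0 = L0.tocsr()
        self.L1 = L1.tocsr()
        self.b0 = b0
        self.b1 = b1

        # dilution mask: all tumor-compartment species
        self.dilution_mask = np.zeros(n)
        for i, s in enumerate(species):
            if s.compartment == "tumor":
                self.dilution_mask[i] = 1.0

        # infusion target
        self.i_blood_trap = self.index.get("blood:fluid:Trap")

        # observable index groups
        self._obs: dict[str, list[int]] = {}
        comps = list(net.spec.compartments)
        for comp in comps:
            for label, names in (
                ("vegf_mouse", MOUSE),
                ("vegf_human", HUMAN),
                ("vegf_free", MOUSE + HUMAN),
            ):
                idxs = [self.index[f"{comp}:fluid:{v}"] for v in names
                        if f"{comp}:fluid:{v}" in self.index]
                self._obs[f"{label}_{comp}"] = idxs
            if net.spec.svegfr1:
                self._obs[f"svegfr1_{comp}"] = [self.index[f"{comp}:fluid:sR1"]]
        if net.spec.trap:
            self._obs["trap_free"] = [self.index["blood:fluid:Trap"]]
            self._obs["trap_mVEGF"] = [
                self.index[f"blood:fluid:Trap_{v}"] for v in MOUSE
                if f"blood:fluid:Trap_{v}" in self.index
            ]
            self._obs["trap_hVEGF"] = [
                self.index[f"blood:fluid:Trap_{v}"] for v in HUMAN
                if f"blood:fluid:Trap_{v}" in self.index
            ]

    # -- time-dependent pieces ---------------------------------------------

    def tumor_volume(self, t_s: float) -> float:
        if not self.tumor_enabled or self.v_tumor0 == 0.0:
            return self.v_tumor0
        if not self.growth_enabled:
            return self.v_tumor0
        return self.v_tumor0 * math.exp(self.growth_rate_per_s * t_s)

    def vf_tumor_l(self, t_s: float) -> float:
        return self.k_av["tumor"] * self.tumor_volume(t_s) * 1e-3

    def trigger_time_s(self) -> float:
        """Time for the tumor to grow from V0 to the treatment trigger volume."""
        if not self.growth_enabled or self.v_tumor0 <= 0:
            return 0.0
        return math.log(self.trigger_volume / self.v_tumor0) / self.growth_rate_per_s

    # -- RHS / Jacobian -------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, infusion_pM_s: float = 0.0,
            growth_on: bool | None = None) -> np.ndarray:
        growth_on = self.growth_enabled if growth_on is None else growth_on
        # plain polynomial mass action: small negative excursions self-correct
        # (the binding flux changes sign), which keeps the solver stable
        r2 = self.kon2 * y[self.a2] * y[self.b2] - self.koff2 * y[self.c2]
        r1 = self.k1 * y[self.a1]
        dy = self.S2 @ r2 + self.S1 @ r1
        vt = self.tumor_volume(t) if growth_on else self.v_tumor0
        dy += self.L0 @ y + self.b0
        if self.tumor_enabled:
            dy += vt * (self.L1 @ y) + vt * self.b1
            if growth_on:
                dy -= self.growth_rate_per_s * self.dilution_mask * y
        if infusion_pM_s and self.i_blood_trap is not None:
            dy[self.i_blood_trap] += infusion_pM_s
        return dy

    def jac(self, t: float, y: np.ndarray, infusion_pM_s: float = 0.0,
            growth_on: bool | None = None) -> sparse.csr_matrix:
        growth_on = self.growth_enabled if growth_on is None else growth_on
        d2 = np.column_stack(
            [self.kon2 * y[self.b2], self.kon2 * y[self.a2], -self.koff2]
        ).ravel()
        D2 = sparse.csr_matrix(
            (d2, (self._d2_rows, self._d2_cols)), shape=self._d2_shape
        )
        D1 = sparse.csr_matrix(
            (self.k1, (self._d1_rows, self._d1_cols)), shape=self._d1_shape
        )
        J = self.S2 @ D2 + self.S1 @ D1 + self.L0
        if self.tumor_enabled:
            vt = self.tumor_volume(t) if growth_on else self.v_tumor0
            J = J + vt * self.L1
            if growth_on:
                J = J - self.growth_rate_per_s * sparse.diags(self.dilution_mask)
        return J

    # -- initial guess / steady state ---------------------------------------

    def initial_guess(self) -> np.ndarray:
        """Ligand-free state: receptors/sites at nominal density, rest zero."""
        y = np.zeros(self.n_state)
        for sid, value in self.site_totals.items():
            y[self.index[sid]] = value
        conc = self.cfg["concentrations"]
        for name, val in (("a2Mn", conc["a2m_native_uM"] * 1e6),
                          ("a2Mf", conc["a2m_fast_nM"] * 1e3)):
            i = self.index.get(f"blood:fluid:{name}")
            if i is not None:
                y[i] = val
        return y

    def steady_state(self, y0: np.ndarray | None = None,
                     residual_tol: float = 1e-7) -> np.ndarray:
        """Drug-free steady state at fixed tumor volume V0 (growth frozen)."""
        if y0 is None:
            y0 = self.initial_guess()
        t_end = self.cfg["solver"]["steady_state_time_s"]
        sol = solve_ivp(
            lambda t, y: self.rhs(t, y, 0.0, growth_on=False),
            (0.0, t_end),
            y0,
            method=self.cfg["solver"]["method"],
            jac=lambda t, y: self.jac(t, y, 0.0, growth_on=False),
            rtol=self.cfg["solver"]["rtol"],
            atol=self.cfg["solver"]["atol_pM"],
        )
        if not sol.success:
            raise SteadyStateError(np.inf, sol.message)
        y = sol.y[:, -1]
        f = self.rhs(t_end, y, 0.0, growth_on=False)
        f[self.i_audit] = 0.0
        rel = np.abs(f) / (1.0 + np.abs(y))
        worst = int(np.argmax(rel))
        if rel[worst] > residual_tol:
            raise SteadyStateError(float(rel[worst]), self.species_ids[worst])
        return np.maximum(y, 0.0)

    # -- simulation ----------------------------------------------------------

    def state_at_trigger(self, y0: np.ndarray | None = None,
                         rtol: float | None = None) -> np.ndarray:
        """State after growing the tumor from V0 to the treatment trigger volume.

        Drug-free; reusable across dose levels for a fixed parameter set.
        """
        if y0 is None:
            y0 = self.steady_state()
        t_trig = self.trigger_time_s()
        if t_trig <= 0.0:
            return y0.copy()
        rtol = self.cfg["solver"]["rtol"] if rtol is None else rtol
        sol = solve_ivp(
            lambda t, y: self.rhs(t, y, 0.0),
            (0.0, t_trig),
            y0,
            method=self.cfg["solver"]["method"],
            jac=lambda t, y: self.jac(t, y, 0.0),
            rtol=rtol,
            atol=self.cfg["solver"]["atol_pM"],
        )
        if not sol.success:
            raise RuntimeError(f"growth-phase integration failed: {sol.message}")
        return sol.y[:, -1]

    def infusion_rate_pM_s(self, dose_mg_per_kg: float, duration_s: float) -> float:
        dosing = self.cfg["dosing"]
        return units.infusion_rate_pM_per_s(
            dose_mg_per_kg,
            dosing["body_weight_g"],
            dosing["mw_trap_kda"] * 1e3,
            self.v_plasma,
            duration_s,
        )

    def simulate(
        self,
        schedule: DoseSchedule | None = None,
        t_out_days: np.ndarray | None = None,
        horizon_days: float = 14.0,
        pre_equilibrate: bool = True,
        y0: np.ndarray | None = None,
        y_at_trigger: np.ndarray | None = None,
        rtol: float | None = None,
    ) -> "SimResult":
        """Integrate the model through growth-to-trigger and a dosing schedule.

        Output times are measured in days from the first injection (or from
        the start of integration when no schedule is given).
        """
        cfg_solver = self.cfg["solver"]
        rtol = cfg_solver["rtol"] if rtol is None else rtol
        atol = cfg_solver["atol_pM"]
        method = cfg_solver["method"]

        t_trig = self.trigger_time_s() if schedule is not None else 0.0
        t_start = 0.0
        if y_at_trigger is not None:
            y0 = y_at_trigger
            t_start = t_trig
        elif y0 is None:
            y0 = self.steady_state() if pre_equilibrate else self.initial_guess()
        if t_out_days is None:
            t_out_days = np.linspace(0.0, horizon_days, 141)
        t_out_days = np.asarray(t_out_days, dtype=float)
        t_out_abs = t_trig + t_out_days * units.SECONDS_PER_DAY
        horizon_abs = max(
            t_trig + horizon_days * units.SECONDS_PER_DAY, float(t_out_abs.max())
        )

        # piecewise-constant infusion segments
        events: list[tuple[float, float]] = []  # (start_abs, rate)
        boundaries = {t_start, horizon_abs}
        rate = 0.0
        if schedule is not None and schedule.dose_mg_per_kg > 0:
            rate = self.infusion_rate_pM_s(
                schedule.dose_mg_per_kg, schedule.infusion_duration_s
            )
            for td in schedule.times_days:
                start = t_trig + td * units.SECONDS_PER_DAY
                stop = start + schedule.infusion_duration_s
                if start < horizon_abs:
                    events.append((start, stop))
                    boundaries.update((start, min(stop, horizon_abs)))
        cuts = sorted(b for b in boundaries if t_start <= b <= horizon_abs)

        ts: list[float] = []
        ys: list[np.ndarray] = []
        y = y0.copy()
        t_prev = t_start
        if math.isclose(t_out_abs.min(), t_start, abs_tol=1e-9):
            ts.append(t_start)
            ys.append(y.copy())
        for t_next in cuts:
            if t_next <= t_prev:
                continue
            active = any(s <= t_prev < e for s, e in events)
            inf = rate if active else 0.0
            t_eval = t_out_abs[(t_out_abs > t_prev + 1e-9) & (t_out_abs <= t_next + 1e-9)]
            sol = solve_ivp(
                lambda t, yy: self.rhs(t, yy, inf),
                (t_prev, t_next),
                y,
                method=method,
                jac=lambda t, yy: self.jac(t, yy, inf),
                rtol=rtol,
                atol=atol,
                t_eval=np.sort(t_eval) if len(t_eval) else None,
                dense_output=False,
            )
            if not sol.success:
                raise RuntimeError(
                    f"integration failed at t={t_prev / 86400.0:.3f} d: {sol.message}; "
                    f"last state min {y.min():.3e} pM"
                )
            if len(t_eval):
                ts.extend(sol.t.tolist())
                ys.extend(list(sol.y.T))
                y = sol.y[:, -1].copy() if math.isclose(sol.t[-1], t_next) else None
                if y is None:
                    # finish the segment beyond the last output point
                    sol2 = solve_ivp(
                        lambda t, yy: self.rhs(t, yy, inf),
                        (sol.t[-1], t_next),
                        ys[-1],
                        method=method,
                        jac=lambda t, yy: self.jac(t, yy, inf),
                        rtol=rtol,
                        atol=atol,
                    )
                    if not sol2.success:
                        raise RuntimeError(f"integration failed: {sol2.message}")
                    y = sol2.y[:, -1].copy()
            else:
                y = sol.y[:, -1].copy()
            t_prev = t_next
        t_arr = np.array(ts)
        y_arr = np.array(ys)
        order = np.argsort(t_arr)
        return SimResult(
            model=self,
            t_days=(t_arr[order] - t_trig) / units.SECONDS_PER_DAY,
            t_abs_s=t_arr[order],
            states=y_arr[order],
        )

    # -- bookkeeping helpers ---------------------------------------------------

    def fluid_volume_l(self, compartment: str, t_abs_s: float) -> float:
        if compartment == "blood":
            return self.vf_blood_l
        if compartment == "normal":
            return self.vf_normal_l
        return self.vf_tumor_l(t_abs_s)

    def trap_amount_pmol(self, y: np.ndarray, t_abs_s: float) -> float:
        """Total VEGF Trap mass: free + complexed everywhere + cleared integral."""
        total = y[self.i_audit]
        for i, s in enumerate(self.network.species):
            n_trap = s.composition.get("Trap", 0)
            if n_trap:
                total += n_trap * y[i] * self.fluid_volume_l(s.compartment, t_abs_s)
        return total

    def surface_receptor_total(self, y: np.ndarray, surface_id: str, receptor: str) -> float:
        """Free + complexed + internalized receptor density on one surface (pM)."""
        total = 0.0
        for i, s in enumerate(self.network.species):
            if s.locale == surface_id:
                total += s.composition.get(receptor, 0) * y[i]
        return total


@dataclass
class SimResult:
    """Trajectories on the requested output grid (days from first dose)."""

    model: CompiledModel
    t_days: np.ndarray
    t_abs_s: np.ndarray
    states: np.ndarray  # (n_times, n_state)

    def observable(self, name: str) -> np.ndarray:
        idxs = self.model._obs.get(name)
        if idxs is None:
            raise KeyError(f"unknown observable {name!r}; have {sorted(self.model._obs)}")
        return self.states[:, idxs].sum(axis=1)

    def species(self, species_id: str) -> np.ndarray:
        return self.states[:, self.model.index[species_id]]

    def circulating_vegf_composition(self, t_index: int = -1) -> dict[str, float]:
        """Fractions of circulating VEGF: free / sVEGFR1- / a2M- / Trap-bound."""
        y = self.states[t_index]
        ix = self.model.index
        groups = {"free": [], "sVEGFR1": [], "a2M": [], "Trap": []}
        for v in MOUSE + HUMAN:
            for prefix, key in (
                ("", "free"), ("sR1_", "sVEGFR1"), ("a2Mn_", "a2M"),
                ("a2Mf_", "a2M"), ("Trap_", "Trap"),
            ):
                sid = f"blood:fluid:{prefix}{v}"
                if sid in ix:
                    groups[key].append(y[ix[sid]])
        totals = {k: float(np.sum(v)) for k, v in groups.items()}
        s = sum(totals.values())
        return {k: (v / s if s > 0 else float("nan")) for k, v in totals.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long-format trajectory table (time, compartment, species, pM)."""
        rows = []
        for j, s in enumerate(self.model.network.species):
            for i, td in enumerate(self.t_days):
                rows.append((td, s.compartment, s.locale, s.name, self.states[i, j]))
        return pd.DataFrame(
            rows, columns=["time_days", "compartment", "locale", "species",
                           "concentration_pM"]
        )

    def min_concentration(self) -> float:
        return float(self.states[:, : self.model.n_species].min())


# ---------------------------------------------------------------------------
# functional wrappers


def assemble_rhs(model: CompiledModel):
    """The model's derivative function f(t, y) (drug-free, growth per config)."""
    return lambda t, y: model.rhs(t, y)


def steady_state(model: CompiledModel, **kw) -> ModelState:
    y = model.steady_state(**kw)
    return ModelState(0.0, y[: model.n_species], model.v_tumor0)


def simulate(model: CompiledModel, schedule: DoseSchedule | None = None,
             t_out_days: np.ndarray | None = None, **kw) -> SimResult:
    return model.simulate(schedule=schedule, t_out_days=t_out_days, **kw)


def dose_to_input(dose_mg_per_kg: float, body_weight_g: float, mw_da: float,
                  plasma_volume_cm3: float, duration_s: float) -> float:
    """Constant infusion rate (pM/s) delivering the full dose to plasma."""
    return units.infusion_rate_pM_per_s(
        dose_mg_per_kg, body_weight_g, mw_da, plasma_volume_cm3, duration_s
    )
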