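"""Rule-based enumeration of molecular species and mass-action reactions.

The model tracks four VEGF isoforms — mouse VEGF120/VEGF164 (host) and human
VEGF121/VEGF165 (xenograft) — across three compartments (normal tissue, blood,
tumor). The long isoforms (164/165) carry the heparin-binding exon and are the
only ones that bind glycosaminoglycan (GAG) sites and neuropilins; this is the
single structural difference between short and long isoforms.

Species live in *locales*: a fluid phase per compartment (interstitial fluid
or plasma), three matrix sub-regions per tissue (ECM, EBM, PBM), and cell
surfaces (muscle fibers, abluminal/luminal endothelium of each tissue, tumor
cells). Which optional species classes a surface carries (VEGFR1-NRP ternary
complexes, sVEGFR1 captured on neuropilins, glycocalyx heparan-sulfate sites,
explicitly tracked internalized complexes, intracellular receptor pools) is
configurable per surface; the default xenograft configuration is defined in
:mod:`vegftrap.config` and its census is printed by the manifest so the
bookkeeping is auditable species-by-species.

Enumeration is a pure function of the configuration: species are ordered
compartment -> locale -> alphabetical identifier, and the manifest carries a
content hash so identical configurations are bit-identical.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "Isoform",
    "SurfaceSpec",
    "MatrixRegionSpec",
    "NetworkSpec",
    "Species",
    "Reaction",
    "NetworkManifest",
    "Network",
    "enumerate_species",
    "build_reactions",
    "build_network",
    "validate_network",
    "COMPARTMENTS",
]

COMPARTMENTS = ("normal", "blood", "tumor")
HEPARIN_ISOFORMS = {"V164", "V165"}
MOUSE_ISOFORMS = ("V120", "V164")
HUMAN_ISOFORMS = ("V121", "V165")
NRPS = ("N1", "N2")
RECEPTORS = ("R1", "R2", "N1", "N2")


@dataclass(frozen=True)
class Isoform:
    name: str  # V120 | V164 | V121 | V165
    origin: str  # mouse | human

    def __post_init__(self) -> None:
        if self.name not in MOUSE_ISOFORMS + HUMAN_ISOFORMS:
            raise ValueError(f"unknown isoform {self.name}")
        expected = "mouse" if self.name in MOUSE_ISOFORMS else "human"
        if self.origin != expected:
            raise ValueError(f"isoform {self.name} must have origin {expected}")

    @property
    def heparin_binding(self) -> bool:
        return self.name in HEPARIN_ISOFORMS


@dataclass(frozen=True)
class SurfaceSpec:
    """A cell surface, its receptor complement, and its optional species classes."""

    id: str  # muscle_fiber | EC_abluminal_normal | EC_luminal_normal | ...
    compartment: str  # compartment whose fluid the surface faces
    tissue: str  # parent tissue whose volume scales this surface (normal|tumor)
    receptors: tuple[str, ...]  # subset of R1, R2, N1, N2
    vr1n_ternary: bool = False  # VEGF-VEGFR1-NRP ternary complexes
    r1n_coupling: bool = False  # unliganded VEGFR1-NRP1 complex (implies ternaries)
    sr1_nrp: bool = False  # sVEGFR1 captured on neuropilins
    hspg: bool = False  # cell-surface / glycocalyx heparan-sulfate sites
    track_internalized: bool = False  # internalized complexes as explicit species
    receptor_pools: bool = False  # intracellular free-receptor pools

    def __post_init__(self) -> None:
        for r in self.receptors:
            if r not in RECEPTORS:
                raise ValueError(f"unknown receptor {r} on surface {self.id}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment}")
        if self.r1n_coupling and not self.vr1n_ternary:
            raise ValueError("r1n_coupling requires vr1n_ternary")

    @property
    def nrps(self) -> tuple[str, ...]:
        return tuple(r for r in self.receptors if r in NRPS)


@dataclass(frozen=True)
class MatrixRegionSpec:
    """An interstitial sub-region holding GAG binding sites."""

    name: str  # ECM | EBM | PBM
    compartment: str  # normal | tumor


@dataclass(frozen=True)
class NetworkSpec:
    """Everything the enumerator needs to know about model structure."""

    isoforms: tuple[Isoform, ...]
    surfaces: tuple[SurfaceSpec, ...]
    matrix_regions: tuple[MatrixRegionSpec, ...]
    compartments: tuple[str, ...] = COMPARTMENTS
    svegfr1: bool = True  # sVEGFR1 present in every fluid phase
    a2m: bool = True  # alpha-2-macroglobulin (native + fast), blood only
    trap: bool = True  # VEGF Trap and its 1:1 complexes, all compartments

    def __post_init__(self) -> None:
        for c in self.compartments:
            if c not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {c}")
        for s in self.surfaces:
            if s.compartment not in self.compartments:
                raise ValueError(f"surface {s.id} placed in disabled compartment")
        for m in self.matrix_regions:
            if m.compartment not in self.compartments:
                raise ValueError(f"matrix region in disabled compartment {m.compartment}")

    @property
    def hep_isoforms(self) -> tuple[str, ...]:
        return tuple(i.name for i in self.isoforms if i.heparin_binding)

    @property
    def isoform_names(self) -> tuple[str, ...]:
        return tuple(i.name for i in self.isoforms)


@dataclass(frozen=True)
class Species:
    """A state variable: identity, location, and molecular composition."""

    name: str  # e.g. "V164_R2_N1" or "int_V164_R2"
    compartment: str
    locale: str  # "fluid", matrix-region name, or surface id

    @property
    def id(self) -> str:
        return f"{self.compartment}:{self.locale}:{self.name}"

    @property
    def composition(self) -> Counter:
        """Multiset of elementary components, used for mass-balance audits."""
        name = self.name
        if name.startswith("int_"):
            name = name[4:]
        if name.endswith("_pool"):
            name = name[: -len("_pool")]
        return Counter(name.split("_"))


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction. Reversible if koff is not None.

    kon units: M^-1 s^-1 for bimolecular, s^-1 for unimolecular; source
    reactions (no reactants) carry their rate in the engine, not here.
    """

    reactants: tuple[str, ...]  # species ids
    products: tuple[str, ...]
    kind: str  # binding | coupling | internalization | insertion | secretion | degradation
    rate_class: str  # key into the kinetic table
    kon: float | None = None
    koff: float | None = None

    @property
    def kd(self) -> float | None:
        if self.kon and self.koff is not None and self.kon > 0:
            return self.koff / self.kon
        return None


@dataclass(frozen=True)
class NetworkManifest:
    counts: dict  # compartment -> species count
    locale_counts: dict  # (compartment, locale) -> count
    n_reactions: int
    sha256: str

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def audit_lines(self) -> list[str]:
        lines = [f"total species (state equations): {self.total}"]
        for c, n in self.counts.items():
            lines.append(f"  {c}: {n}")
            for (cc, loc), m in self.locale_counts.items():
                if cc == c:
                    lines.append(f"    {loc}: {m}")
        lines.append(f"reactions: {self.n_reactions}")
        lines.append(f"sha256: {self.sha256}")
        return lines


def _fluid_species(spec: NetworkSpec, compartment: str) -> list[str]:
    names = [i.name for i in spec.isoforms]
    if spec.svegfr1:
        names.append("sR1")
        names += [f"sR1_{i.name}" for i in spec.isoforms]
    if spec.trap:
        names.append("Trap")
        names += [f"Trap_{i.name}" for i in spec.isoforms]
    if spec.a2m and compartment == "blood":
        for form in ("a2Mn", "a2Mf"):
            names.append(form)
            names += [f"{form}_{i.name}" for i in spec.isoforms]
    return names


def _surface_species(spec: NetworkSpec, surf: SurfaceSpec) -> list[str]:
    iso = spec.isoform_names
    hep = spec.hep_isoforms
    names: list[str] = []
    complexes: list[str] = []
    for r in surf.receptors:
        names.append(r)
    if "R1" in surf.receptors:
        complexes += [f"{v}_R1" for v in iso]
    if "R2" in surf.receptors:
        complexes += [f"{v}_R2" for v in iso]
    for n in surf.nrps:
        complexes += [f"{v}_{n}" for v in hep]
        if "R2" in surf.receptors:
            complexes += [f"{v}_R2_{n}" for v in hep]
    if surf.vr1n_ternary and "R1" in surf.receptors:
        for n in surf.nrps:
            complexes += [f"{v}_R1_{n}" for v in iso]
    if surf.r1n_coupling and "R1" in surf.receptors:
        complexes += [f"R1_{n}" for n in surf.nrps]
    if surf.sr1_nrp and spec.svegfr1:
        for n in surf.nrps:
            complexes.append(f"sR1_{n}")
            complexes += [f"{v}_sR1_{n}" for v in hep]
    if surf.hspg:
        names.append("HSPG")
        complexes += [f"HSPG_{v}" for v in hep]
    names += complexes
    if surf.track_internalized:
        names += [f"int_{c}" for c in complexes]
    if surf.receptor_pools:
        names += [f"{r}_pool" for r in surf.receptors]
    return names


def enumerate_species(spec: NetworkSpec) -> list[Species]:
    """Deterministic, ordered species list (compartment -> locale -> name)."""
    out: list[Species] = []
    for comp in (c for c in COMPARTMENTS if c in spec.compartments):
        locales: list[tuple[str, list[str]]] = [("fluid", _fluid_species(spec, comp))]
        for region in spec.matrix_regions:
            if region.compartment == comp:
                names = ["GAG"] + [f"GAG_{v}" for v in spec.hep_isoforms]
                locales.append((region.name, names))
        for surf in spec.surfaces:
            if surf.compartment == comp:
                locales.append((surf.id, _surface_species(spec, surf)))
        for locale, names in locales:
            for name in sorted(names):
                out.append(Species(name, comp, locale))
    return out


def _manifest(spec: NetworkSpec, species: list[Species], n_reactions: int) -> NetworkManifest:
    counts: dict = {}
    locale_counts: dict = {}
    for s in species:
        counts[s.compartment] = counts.get(s.compartment, 0) + 1
        key = (s.compartment, s.locale)
        locale_counts[key] = locale_counts.get(key, 0) + 1
    digest = hashlib.sha256("\n".join(s.id for s in species).encode()).hexdigest()
    return NetworkManifest(counts, locale_counts, n_reactions, digest)


class _ReactionBuilder:
    def __init__(self, spec: NetworkSpec, species_ids: set[str]):
        self.spec = spec
        self.ids = species_ids
        self.reactions: list[Reaction] = []

    def rev(self, rate_class: str, reactants: tuple[str, ...], products: tuple[str, ...],
            kind: str, kinetics: dict) -> None:
        for sid in reactants + products:
            if sid not in self.ids:
                raise ValueError(f"reaction references unknown species {sid}")
        k = kinetics[rate_class]
        self.reactions.append(
            Reaction(reactants, products, kind, rate_class, kon=k["kon"], koff=k["koff"])
        )

    def uni(self, rate_class: str, reactant: str, products: tuple[str, ...],
            kind: str, rate: float) -> None:
        if reactant not in self.ids:
            raise ValueError(f"reaction references unknown species {reactant}")
        for sid in products:
            if sid not in self.ids:
                raise ValueError(f"reaction references unknown species {sid}")
        self.reactions.append(
            Reaction((reactant,), products, kind, rate_class, kon=rate, koff=None)
        )


def build_reactions(spec: NetworkSpec, species: list[Species], kinetics: dict,
                    trafficking: dict | None = None) -> list[Reaction]:
    """Generate the mass-action reaction list from the structural rules.

    ``kinetics`` maps rate-class keys to {"kon": M^-1 s^-1, "koff": s^-1}:
    V:R1, V:R2, V:NRP, coupling:R2_VN, coupling:VR2_N, coupling:VR1_N,
    coupling:VN_R1, coupling:R1_N, sR1:V, sR1:NRP, V:GAG, V:HSPG, Trap:V,
    a2Mn:V, a2Mf:V. ``trafficking`` supplies first-order rates (s^-1):
    k_int_complex, k_int_receptor, k_insert, k_deg_internal.
    """
    trafficking = trafficking or {}
    ids = {s.id for s in species}
    b = _ReactionBuilder(spec, ids)
    iso = spec.isoform_names
    hep = spec.hep_isoforms

    # --- fluid-phase binding ---------------------------------------------
    for comp in (c for c in COMPARTMENTS if c in spec.compartments):
        f = f"{comp}:fluid"
        for v in iso:
            if spec.trap:
                b.rev("Trap:V", (f"{f}:Trap", f"{f}:{v}"), (f"{f}:Trap_{v}",),
                      "binding", kinetics)
            if spec.svegfr1:
                b.rev("sR1:V", (f"{f}:sR1", f"{f}:{v}"), (f"{f}:sR1_{v}",),
                      "binding", kinetics)
            if spec.a2m and comp == "blood":
                for form in ("a2Mn", "a2Mf"):
                    b.rev(f"{form}:V", (f"{f}:{form}", f"{f}:{v}"),
                          (f"{f}:{form}_{v}",), "binding", kinetics)

    # --- matrix GAG sites (heparin-binding isoforms only) ----------------
    for region in spec.matrix_regions:
        f = f"{region.compartment}:fluid"
        m = f"{region.compartment}:{region.name}"
        for v in hep:
            b.rev("V:GAG", (f"{m}:GAG", f"{f}:{v}"), (f"{m}:GAG_{v}",),
                  "binding", kinetics)

    # --- surfaces ---------------------------------------------------------
    for surf in spec.surfaces:
        s = f"{surf.compartment}:{surf.id}"
        f = f"{surf.compartment}:fluid"
        complexes = [n for n in _surface_species(spec, surf)
                     if n not in surf.receptors and n != "HSPG"
                     and not n.startswith("int_") and not n.endswith("_pool")]
        if "R1" in surf.receptors:
            for v in iso:
                b.rev("V:R1", (f"{s}:R1", f"{f}:{v}"), (f"{s}:{v}_R1",),
                      "binding", kinetics)
        if "R2" in surf.receptors:
            for v in iso:
                b.rev("V:R2", (f"{s}:R2", f"{f}:{v}"), (f"{s}:{v}_R2",),
                      "binding", kinetics)
        for n in surf.nrps:
            for v in hep:
                b.rev("V:NRP", (f"{s}:{n}", f"{f}:{v}"), (f"{s}:{v}_{n}",),
                      "binding", kinetics)
                if "R2" in surf.receptors:
                    b.rev("coupling:R2_VN", (f"{s}:{v}_{n}", f"{s}:R2"),
                          (f"{s}:{v}_R2_{n}",), "coupling", kinetics)
                    b.rev("coupling:VR2_N", (f"{s}:{v}_R2", f"{s}:{n}"),
                          (f"{s}:{v}_R2_{n}",), "coupling", kinetics)
        if surf.vr1n_ternary and "R1" in surf.receptors:
            for n in surf.nrps:
                for v in iso:
                    b.rev("coupling:VR1_N", (f"{s}:{v}_R1", f"{s}:{n}"),
                          (f"{s}:{v}_R1_{n}",), "coupling", kinetics)
                for v in hep:
                    b.rev("coupling:VN_R1", (f"{s}:{v}_{n}", f"{s}:R1"),
                          (f"{s}:{v}_R1_{n}",), "coupling", kinetics)
        if surf.r1n_coupling and "R1" in surf.receptors:
            for n in surf.nrps:
                b.rev("coupling:R1_N", (f"{s}:R1", f"{s}:{n}"), (f"{s}:R1_{n}",),
                      "coupling", kinetics)
                for v in iso:
                    b.rev("V:R1", (f"{s}:R1_{n}", f"{f}:{v}"),
                          (f"{s}:{v}_R1_{n}",), "binding", kinetics)
        if surf.sr1_nrp and spec.svegfr1:
            for n in surf.nrps:
                b.rev("sR1:NRP", (f"{s}:{n}", f"{f}:sR1"), (f"{s}:sR1_{n}",),
                      "binding", kinetics)
                for v in hep:
                    b.rev("sR1:NRP", (f"{s}:{n}", f"{f}:sR1_{v}"),
                          (f"{s}:{v}_sR1_{n}",), "binding", kinetics)
                    b.rev("sR1:V", (f"{s}:sR1_{n}", f"{f}:{v}"),
                          (f"{s}:{v}_sR1_{n}",), "binding", kinetics)
        if surf.hspg:
            for v in hep:
                b.rev("V:HSPG", (f"{s}:HSPG", f"{f}:{v}"), (f"{s}:HSPG_{v}",),
                      "binding", kinetics)

        # trafficking: internalization of complexes and receptors; insertion
        k_int_c = trafficking.get("k_int_complex", 0.0)
        k_int_r = trafficking.get("k_int_receptor", 0.0)
        k_ins = trafficking.get("k_insert", 0.0)
        k_deg_i = trafficking.get("k_deg_internal", 0.0)
        if k_int_c > 0:
            # ligand in an internalized complex is degraded; receptor components
            # recycle to the intracellular pools (when the surface tracks them),
            # so internalization of complexes does not bleed receptor mass
            def _recycled(c: str) -> tuple[str, ...]:
                if not surf.receptor_pools:
                    return ()
                parts = c.split("_")
                return tuple(
                    f"{s}:{p}_pool" for p in parts if p in surf.receptors
                )

            for c in complexes:
                if surf.track_internalized:
                    b.uni("internalization", f"{s}:{c}", (f"{s}:int_{c}",),
                          "internalization", k_int_c)
                    if k_deg_i > 0:
                        b.uni("degradation", f"{s}:int_{c}", _recycled(c),
                              "degradation", k_deg_i)
                else:
                    b.uni("internalization", f"{s}:{c}", _recycled(c),
                          "internalization", k_int_c)
        if k_int_r > 0 and surf.hspg:
            # glycocalyx/heparan-sulfate turnover; the engine supplies the
            # matching constant insertion source so the site total is stable
            b.uni("internalization", f"{s}:HSPG", (), "internalization", k_int_r)
        if k_int_r > 0:
            for r in surf.receptors:
                if surf.receptor_pools:
                    b.uni("internalization", f"{s}:{r}", (f"{s}:{r}_pool",),
                          "internalization", k_int_r)
                    if k_ins > 0:
                        b.uni("insertion", f"{s}:{r}_pool", (f"{s}:{r}",),
                              "insertion", k_ins)
                    if k_deg_i > 0:
                        b.uni("degradation", f"{s}:{r}_pool", (), "degradation", k_deg_i)
                else:
                    b.uni("internalization", f"{s}:{r}", (), "internalization", k_int_r)
    return b.reactions


@dataclass(frozen=True)
class Network:
    spec: NetworkSpec
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    manifest: NetworkManifest

    def index(self) -> dict:
        return {s.id: i for i, s in enumerate(self.species)}


def build_network(spec: NetworkSpec, kinetics: dict, trafficking: dict | None = None) -> Network:
    species = enumerate_species(spec)
    reactions = build_reactions(spec, species, kinetics, trafficking)
    manifest = _manifest(spec, species, len(reactions))
    return Network(spec, tuple(species), tuple(reactions), manifest)


def validate_network(network: Network, kinetics: dict | None = None,
                     kd_expected: dict | None = None) -> dict:
    """Structural audit: per-reaction mass balance, orphan species, Kd consistency.

    Returns {"ok": bool, "violations": [str, ...]}.
    """
    violations: list[str] = []
    by_id = {s.id: s for s in network.species}
    touched: set[str] = set()
    for rx in network.reactions:
        lhs: Counter = Counter()
        rhs: Counter = Counter()
        for sid in rx.reactants:
            lhs.update(by_id[sid].composition)
            touched.add(sid)
        for sid in rx.products:
            rhs.update(by_id[sid].composition)
            touched.add(sid)
        if rx.kind in ("binding", "coupling"):
            if lhs != rhs:
                violations.append(f"mass imbalance in {rx.kind} {rx.reactants}->{rx.products}")
        elif rx.kind in ("internalization", "degradation") and rx.products:
            # recycling may drop the ligand but must not create components
            if rhs - lhs:
                violations.append(
                    f"component creation in {rx.kind} {rx.reactants}->{rx.products}"
                )
        elif rx.kind == "insertion" and rx.reactants and rx.products:
            if lhs != rhs:
                violations.append(f"mass imbalance in {rx.kind} {rx.reactants}->{rx.products}")
    # free (monomeric) species are never orphans; complexes must appear in a reaction
    for s in network.species:
        if sum(s.composition.values()) > 1 and s.id not in touched:
            violations.append(f"orphan complex species {s.id}")
    if kinetics and kd_expected:
        for rate_class, kd in kd_expected.items():
            k = kinetics.get(rate_class)
            if k and k["kon"] > 0:
                got = k["koff"] / k["kon"]
                if abs(got - kd) > 1e-6 * max(abs(kd), 1e-30):
                    violations.append(
                        f"Kd mismatch for {rate_class}: koff/kon={got:.6g}, declared {kd:.6g}"
                    )
    return {"ok": not violations, "violations": violations}
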