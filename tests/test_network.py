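"""Species enumeration and reaction generation: census, determinism, rules."""

import pytest

from vegftrap.config import (
    default_xenograft_config,
    kinetics_from_config,
    network_spec_from_config,
    trafficking_from_config,
)
from vegftrap.network import (
    Isoform,
    MatrixRegionSpec,
    NetworkSpec,
    Reaction,
    SurfaceSpec,
    build_network,
    build_reactions,
    enumerate_species,
    validate_network,
)

KIN = kinetics_from_config(default_xenograft_config())


def toy_spec(**kw):
    """One isoform pair, one surface with R1/R2/N1, one matrix region."""
    defaults = dict(
        isoforms=(Isoform("V120", "mouse"), Isoform("V164", "mouse")),
        surfaces=(
            SurfaceSpec("muscle_fiber", "normal", "normal", ("R1", "R2", "N1")),
        ),
        matrix_regions=(MatrixRegionSpec("ECM", "normal"),),
        compartments=("normal", "blood"),
        svegfr1=False,
        a2m=False,
        trap=True,
    )
    defaults.update(kw)
    return NetworkSpec(**defaults)


class TestEnumeration:
    def test_full_xenograft_census(self, xenograft_network):
        m = xenograft_network.manifest
        assert m.counts == {"normal": 53, "blood": 126, "tumor": 79}
        assert m.total == 258

    def test_enumeration_is_deterministic(self, xenograft_config):
        spec = network_spec_from_config(xenograft_config)
        n1 = build_network(spec, KIN, trafficking_from_config(xenograft_config))
        n2 = build_network(spec, KIN, trafficking_from_config(xenograft_config))
        assert [s.id for s in n1.species] == [s.id for s in n2.species]
        assert n1.manifest.sha256 == n2.manifest.sha256

    def test_species_ordered_compartment_locale_alphabetical(self, xenograft_network):
        order = {"normal": 0, "blood": 1, "tumor": 2}
        species = xenograft_network.species
        keys = []
        for s in species:
            keys.append(order[s.compartment])
        assert keys == sorted(keys)
        # alphabetical within each (compartment, locale)
        by_loc = {}
        for s in species:
            by_loc.setdefault((s.compartment, s.locale), []).append(s.name)
        for names in by_loc.values():
            assert names == sorted(names)

    def test_disabling_factors_never_increases_counts(self, xenograft_config):
        base = build_network(
            network_spec_from_config(xenograft_config), KIN
        ).manifest
        for field in ("svegfr1", "a2m", "trap"):
            spec = network_spec_from_config(xenograft_config)
            smaller = NetworkSpec(
                isoforms=spec.isoforms, surfaces=spec.surfaces,
                matrix_regions=spec.matrix_regions, compartments=spec.compartments,
                **{**{"svegfr1": spec.svegfr1, "a2m": spec.a2m, "trap": spec.trap},
                   field: False},
            )
            m = build_network(smaller, KIN).manifest
            for comp in m.counts:
                assert m.counts[comp] <= base.counts[comp]

    def test_tumor_disabled_is_strictly_smaller(self, xenograft_config):
        import copy

        cfg = copy.deepcopy(xenograft_config)
        cfg["network"]["tumor_enabled"] = False
        m = build_network(network_spec_from_config(cfg), KIN).manifest
        assert "tumor" not in m.counts
        assert m.counts["normal"] == 53
        assert m.counts["blood"] < 126  # no tumor endothelium in blood

    def test_toy_config_counted_by_hand(self):
        species = enumerate_species(toy_spec())
        # normal fluid: V120, V164, Trap, Trap_V120, Trap_V164           = 5
        # ECM: GAG, GAG_V164                                             = 2
        # surface: R1, R2, N1; V_R1 x2, V_R2 x2, V164_N1, V164_R2_N1     = 9
        # blood fluid: same 5 as normal fluid
        by_comp = {}
        for s in species:
            by_comp[s.compartment] = by_comp.get(s.compartment, 0) + 1
        assert by_comp == {"normal": 16, "blood": 5}

    def test_unknown_surface_receptor_rejected(self):
        with pytest.raises(ValueError):
            SurfaceSpec("muscle_fiber", "normal", "normal", ("R9",))


class TestReactions:
    def test_short_isoforms_get_no_gag_or_nrp_reactions(self, xenograft_network):
        for rx in xenograft_network.reactions:
            names = " ".join(rx.reactants + rx.products)
            if "GAG" in names or "HSPG" in names:
                assert "V120" not in names and "V121" not in names
            for prod in rx.products:
                tail = prod.split(":")[-1]
                if tail in ("V120_N1", "V121_N1", "V120_N2", "V121_N2"):
                    raise AssertionError(f"short-isoform NRP complex generated: {prod}")

    def test_trap_binds_each_isoform_once_per_compartment(self, xenograft_network):
        per_comp = {}
        for rx in xenograft_network.reactions:
            if rx.rate_class == "Trap:V":
                comp = rx.reactants[0].split(":")[0]
                per_comp[comp] = per_comp.get(comp, 0) + 1
        assert per_comp == {"normal": 4, "blood": 4, "tumor": 4}

    def test_toy_reaction_list_matches_hand_enumeration(self):
        spec = toy_spec()
        species = enumerate_species(spec)
        rxs = build_reactions(spec, species, KIN)
        by_kind = {}
        for rx in rxs:
            by_kind[rx.kind] = by_kind.get(rx.kind, 0) + 1
        # binding: Trap+V x2 per compartment (4), GAG+V164 (1),
        #          V+R1 x2, V+R2 x2, V164+N1 (5)
        # coupling: V164_N1+R2 and V164_R2+N1 (2)
        assert by_kind["binding"] == 10
        assert by_kind["coupling"] == 2

    def test_reaction_references_unknown_species_rejected(self):
        spec = toy_spec()
        species = enumerate_species(spec)[:-1]  # drop one species
        with pytest.raises(ValueError):
            build_reactions(spec, species, KIN)


class TestValidation:
    def test_default_network_has_no_violations(self, xenograft_network):
        report = validate_network(xenograft_network)
        assert report["ok"], report["violations"]

    def test_mass_imbalance_flagged(self, xenograft_network):
        bad = Reaction(
            reactants=("normal:fluid:V120", "normal:fluid:Trap"),
            products=("normal:fluid:Trap_V164",),  # wrong isoform in product
            kind="binding", rate_class="Trap:V", kon=1e7, koff=1e-5,
        )
        import dataclasses

        net = dataclasses.replace(
            xenograft_network, reactions=xenograft_network.reactions + (bad,)
        )
        report = validate_network(net)
        assert not report["ok"]
        assert any("mass imbalance" in v for v in report["violations"])

    def test_kd_consistency_check(self, xenograft_network):
        kin = {"Trap:V": {"kon": 1e7, "koff": 5e-6}}
        ok = validate_network(xenograft_network, kin, {"Trap:V": 5e-13})
        assert ok["ok"]
        bad = validate_network(xenograft_network, kin, {"Trap:V": 6e-13})
        assert not bad["ok"]

    def test_trap_kd_within_reported_scale(self, xenograft_config):
        k = xenograft_config["kinetics"]["Trap:V"]
        kd_pM = k["koff_per_s"] / k["kon_per_M_s"] * 1e12
        assert 0.25 <= kd_pM <= 5.0  # fitted 0.29 pM, in vitro 0.6 pM

    def test_receptor_totals_invariant_under_binding_reactions(self, xenograft_network):
        # structural check: every binding/coupling reaction conserves each
        # receptor component (free + complexed)
        by_id = {s.id: s for s in xenograft_network.species}
        for rx in xenograft_network.reactions:
            if rx.kind in ("binding", "coupling"):
                for receptor in ("R1", "R2", "N1", "N2"):
                    lhs = sum(by_id[r].composition.get(receptor, 0) for r in rx.reactants)
                    rhs = sum(by_id[p].composition.get(receptor, 0) for p in rx.products)
                    assert lhs == rhs, rx

    def test_every_complex_is_reachable(self, xenograft_network):
        report = validate_network(xenograft_network)
        assert not any("orphan" in v for v in report["violations"])
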