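"""Structural invariants of the network model and its serializations."""

import numpy as np
import pytest

from warburg.network import (
    Metabolite,
    MetabolicNetwork,
    NetworkParseError,
    NetworkValidationError,
    Reaction,
    format_equation,
    parse_equation,
    read_network,
    write_network,
)
from warburg.synth import make_toy_network

from conftest import random_toy_network


class TestDomainTypes:
    def test_metabolite_suffix_must_match_compartment(self):
        with pytest.raises(NetworkValidationError):
            Metabolite(id="glc[e]", compartment="c")
        with pytest.raises(NetworkValidationError):
            Metabolite(id="glc", compartment="c")

    def test_reaction_bound_order_and_empty_stoich(self):
        with pytest.raises(NetworkValidationError):
            Reaction(id="R", stoich={"a[c]": -1.0}, lower_bound=1, upper_bound=0)
        with pytest.raises(NetworkValidationError):
            Reaction(id="R", stoich={})

    def test_internal_reactions_need_both_sides(self):
        with pytest.raises(NetworkValidationError):
            Reaction(id="R", stoich={"a[c]": -1.0}, kind="internal")
        # boundary kinds may be one-sided by design
        Reaction(id="EX", stoich={"a[c]": -1.0}, kind="exchange")

    def test_duplicate_ids_rejected(self):
        m = Metabolite(id="a[c]", compartment="c")
        r = Reaction(id="R", stoich={"a[c]": -1.0}, kind="sink")
        with pytest.raises(NetworkValidationError):
            MetabolicNetwork([m, m], [r])
        with pytest.raises(NetworkValidationError):
            MetabolicNetwork([m], [r, r])

    def test_undeclared_metabolite_rejected(self):
        m = Metabolite(id="a[c]", compartment="c")
        r = Reaction(id="R", stoich={"ghost[c]": -1.0}, kind="sink")
        with pytest.raises(NetworkValidationError, match="undeclared"):
            MetabolicNetwork([m], [r])


class TestStoichiometricMatrix:
    def test_columns_reproduce_reaction_stoich(self, core_net):
        S = core_net.S
        midx = core_net.metabolite_index()
        for j, rxn in enumerate(core_net.reactions):
            col = np.zeros(len(core_net.metabolites))
            for mid, coeff in rxn.stoich.items():
                col[midx[mid]] = coeff
            np.testing.assert_array_equal(S[:, j], col)

    def test_no_all_zero_columns(self, core_net):
        assert np.all(np.abs(core_net.S).sum(axis=0) > 0)

    def test_toy_tsv_matrix_shape(self, tmp_path):
        # 2 metabolites, 3 reactions built from a hand-written table
        text = (
            "#!metabolite\ta[c]\tA\tc\n"
            "#!metabolite\tb[c]\tB\tc\n"
            "reaction_id\tequation\tlower\tupper\tkind\tnote\n"
            "SRC\t → a[c]\t0\t10\tdemand\t\n"
            "R1\ta[c] → b[c]\t0\t100\tinternal\t\n"
            "SNK\tb[c] → \t0\t100\tdemand\t\n"
        )
        p = tmp_path / "toy.tsv"
        p.write_text(text, encoding="utf-8")
        net = read_network(str(p), "tsv")
        assert net.S.shape == (2, 3)


class TestCancerCoreFixture:
    def test_bounds_are_ordered(self, core_net):
        lb, ub = core_net.bounds
        assert np.all(lb <= ub)

    def test_boundary_enumeration(self, core_net):
        kinds = {}
        for r in core_net.reactions:
            kinds.setdefault(r.kind, []).append(r.id)
        sink_species = {r.split("_")[1] for r in kinds["sink"]}
        assert {"nadh", "nad", "co2", "pi", "h", "h2o", "coa", "fad", "fadh2"} <= sink_species
        assert {"DM_accoa_m", "DM_adp_c", "DM_o2_c", "DM_glc_e", "DM_akg_m"} <= set(kinds["demand"])

    def test_hypoxic_oxygen_default_is_low(self, core_net):
        assert core_net.reaction("DM_o2_c").upper_bound == pytest.approx(0.5)

    def test_provenance_notes_present(self, core_net):
        assert all(r.note in {"pathway", "biochem", "boundary"} for r in core_net.reactions)


class TestEquationDialect:
    @pytest.mark.parametrize("eq,expected", [
        ("a[c] → b[c]", {"a[c]": -1.0, "b[c]": 1.0}),
        ("2 a[c] + b[c] ↔ 3 c[m]", {"a[c]": -2.0, "b[c]": -1.0, "c[m]": 3.0}),
        (" → a[e]", {"a[e]": 1.0}),
        ("a[e] → ", {"a[e]": -1.0}),
    ])
    def test_parse(self, eq, expected):
        assert parse_equation(eq) == expected

    def test_parse_rejects_missing_arrow(self):
        with pytest.raises(NetworkParseError):
            parse_equation("a[c] = b[c]")

    def test_format_parse_inverse(self, core_net):
        for rxn in core_net.reactions:
            assert parse_equation(format_equation(rxn)) == rxn.stoich


class TestRoundTrips:
    @pytest.mark.parametrize("fmt", ["tsv", "sbml"])
    def test_cancer_core_round_trip(self, core_net, tmp_path, fmt):
        p = tmp_path / f"core.{fmt}"
        write_network(core_net, str(p), fmt)
        back = read_network(str(p), fmt)
        assert len(back.reactions) == 80
        assert len(back.metabolites) == 66
        _assert_networks_equal(back, core_net)

    @pytest.mark.parametrize("fmt", ["tsv", "sbml"])
    def test_random_networks_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(42)
        for i in range(100):
            net = random_toy_network(rng)
            p = tmp_path / f"net_{fmt}_{i}"
            write_network(net, str(p), fmt)
            _assert_networks_equal(read_network(str(p), fmt), net)

    def test_chain_tsv_has_four_data_rows(self, tmp_path):
        p = tmp_path / "chain.tsv"
        write_network(make_toy_network("chain"), str(p), "tsv")
        rows = [
            line for line in p.read_text(encoding="utf-8").splitlines()
            if line and not line.startswith("#") and not line.startswith("reaction_id")
        ]
        assert len(rows) == 4

    def test_empty_network_refused(self, tmp_path):
        net = MetabolicNetwork([Metabolite(id="a[c]", compartment="c")], [
            Reaction(id="SK", stoich={"a[c]": -1.0}, kind="sink")])
        net.reactions = []
        with pytest.raises(NetworkValidationError):
            write_network(net, str(tmp_path / "x.tsv"), "tsv")

    def test_tsv_undeclared_metabolite_is_validation_error(self, tmp_path):
        text = (
            "#!metabolite\ta[c]\tA\tc\n"
            "reaction_id\tequation\tlower\tupper\tkind\tnote\n"
            "R1\ta[c] → ghost[c]\t0\t10\tinternal\t\n"
        )
        p = tmp_path / "bad.tsv"
        p.write_text(text, encoding="utf-8")
        with pytest.raises(NetworkValidationError, match="undeclared"):
            read_network(str(p), "tsv")

    def test_malformed_tsv_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "reaction_id\tequation\tlower\tupper\tkind\tnote\n"
            "R1\tnot an equation\t0\t10\tinternal\t\n",
            encoding="utf-8",
        )
        with pytest.raises(NetworkParseError, match=":2"):
            read_network(str(p), "tsv")


def _assert_networks_equal(a, b):
    assert a.metabolite_ids == b.metabolite_ids
    assert a.reaction_ids == b.reaction_ids
    for ra, rb in zip(a.reactions, b.reactions):
        assert ra.stoich == rb.stoich
        assert ra.kind == rb.kind
        assert ra.lower_bound == pytest.approx(rb.lower_bound)
        assert ra.upper_bound == pytest.approx(rb.upper_bound)
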