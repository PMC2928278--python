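"""FBA core: objectives, LP solves against a brute-force oracle, deletions."""

import itertools

import numpy as np
import pytest

from warburg.fba import (
    FIG_PHASE_WEIGHTS,
    GROWTH_COMPONENTS,
    ObjectiveError,
    ObjectiveSpec,
    delete_reaction,
    equimolar_objective,
    solve_fba,
    weighted_objective,
)
from warburg.synth import make_toy_network


def enumerate_vertices_optimum(S, lb, ub, c):
    """Independent LP oracle: enumerate basic feasible solutions.

    For max c·v s.t. S v = 0, lb <= v <= ub, every vertex fixes at least
    n - rank(S) variables at a bound; enumerate all such fixings, solve the
    reduced equality system, keep feasible points, and return the best
    objective (None if infeasible).
    """
    S = np.asarray(S, float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    k = n - r  # number of variables to pin at bounds
    best = None
    for free_idx in itertools.combinations(range(n), r):
        fixed_idx = [j for j in range(n) if j not in free_idx]
        A = S[:, list(free_idx)]
        if np.linalg.matrix_rank(A) < r:
            continue
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed_idx]):
            b = -S[:, fixed_idx] @ np.array(bounds_choice)
            v_free, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            v = np.empty(n)
            v[list(free_idx)] = v_free
            v[fixed_idx] = bounds_choice
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best


def random_lp_instance(rng):
    n_m = int(rng.integers(2, 5))
    n_r = int(rng.integers(n_m + 1, 8))
    S = np.zeros((n_m, n_r))
    S[rng.integers(n_m), 0] = 1.0  # source
    S[rng.integers(n_m), n_r - 1] = -1.0  # drain
    for j in range(1, n_r - 1):
        a, b = rng.choice(n_m, size=2, replace=False)
        S[a, j] = -float(rng.integers(1, 3))
        S[b, j] = float(rng.integers(1, 3))
    lb = np.where(rng.random(n_r) < 0.3, -float(rng.integers(1, 10)), 0.0)
    ub = lb + rng.integers(1, 10, size=n_r).astype(float)
    c = np.abs(rng.normal(size=n_r))  # objective weights are >= 0
    return S, lb, ub, c


class TestObjectives:
    def test_equimolar_has_eight_unit_components(self, core_net):
        obj = equimolar_objective(core_net)
        assert len(obj.components) == 8
        assert all(w == 1.0 for w in obj.components.values())
        assert sum(obj.components.values()) == len(obj.components)

    def test_missing_component_reaction_is_named(self, core_net):
        broken = delete_reaction(core_net, "DM_cit_c")  # still present, just closed
        # removal (not closure) must raise: build a net without the demand
        from warburg.network import MetabolicNetwork
        reduced = MetabolicNetwork(
            list(core_net.metabolites),
            [r for r in core_net.reactions if r.id != "DM_cit_c"],
        )
        with pytest.raises(ObjectiveError, match="DM_cit_c"):
            equimolar_objective(reduced)
        # closure keeps the reaction id present, so the spec still builds
        equimolar_objective(broken)

    def test_tuned_weight_set_values(self):
        obj = weighted_objective()
        assert obj.components["DM_atp_m"] == pytest.approx(17.09)
        assert obj.components["DM_r5p_c"] == pytest.approx(0.6)
        assert obj.components["DM_atp_c"] == pytest.approx(12.47)
        assert obj.components["DM_lac_e"] == pytest.approx(0.13)
        assert len(obj.components) == 8
        assert set(obj.components) == set(GROWTH_COMPONENTS)
        assert set(FIG_PHASE_WEIGHTS) == set(GROWTH_COMPONENTS)

    def test_objective_rejects_degenerate_weights(self):
        with pytest.raises(ObjectiveError):
            ObjectiveSpec({})
        with pytest.raises(ObjectiveError):
            ObjectiveSpec({"R": 0.0})
        with pytest.raises(ObjectiveError):
            ObjectiveSpec({"R": -1.0})


class TestSolveFba:
    def test_capacity_limited_chain(self):
        net = make_toy_network("chain")
        sol = solve_fba(net, ObjectiveSpec({"SNK": 1.0}))
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0)
        for rid in ("SRC", "R1", "R2", "SNK"):
            assert sol.fluxes[rid] == pytest.approx(10.0)

    def test_closed_source_gives_zero(self):
        net = make_toy_network("chain").with_bounds({"SRC": (0.0, 0.0)})
        sol = solve_fba(net, ObjectiveSpec({"SNK": 1.0}))
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0)

    def test_infeasible_and_unbounded_are_statuses(self):
        net = make_toy_network("chain").with_bounds({"SRC": (0.0, 0.0), "SNK": (5.0, 10.0)})
        assert solve_fba(net, ObjectiveSpec({"SNK": 1.0})).status == "infeasible"
        loop = make_toy_network("parallel").with_bounds(
            {"B1": (-1e30, 1e30), "B2": (-1e30, 1e30)}
        )
        assert solve_fba(loop, ObjectiveSpec({"B1": 1.0})).status == "unbounded"

    def test_matches_vertex_enumeration_oracle_on_random_lps(self):
        from warburg.network import MetabolicNetwork, Metabolite, Reaction

        rng = np.random.default_rng(7)
        checked = 0
        while checked < 50:
            S, lb, ub, c = random_lp_instance(rng)
            oracle = enumerate_vertices_optimum(S, lb, ub, c)
            if oracle is None:
                continue
            mets = [Metabolite(id=f"m{i}[c]", compartment="c") for i in range(S.shape[0])]
            rxns = []
            weights = {}
            for j in range(S.shape[1]):
                stoich = {f"m{i}[c]": S[i, j] for i in range(S.shape[0]) if S[i, j] != 0}
                has_both = any(v < 0 for v in stoich.values()) and any(
                    v > 0 for v in stoich.values()
                )
                rxns.append(Reaction(
                    id=f"R{j}", stoich=stoich, lower_bound=lb[j], upper_bound=ub[j],
                    kind="internal" if has_both else "sink",
                ))
                if c[j] > 0:
                    weights[f"R{j}"] = c[j]
            net = MetabolicNetwork(mets, rxns)
            sol = solve_fba(net, ObjectiveSpec(weights))
            assert sol.status == "optimal"
            assert sol.objective_value == pytest.approx(oracle, abs=1e-6)
            checked += 1

    def test_core_solution_satisfies_mass_balance_and_bounds(self, core_net, core_objective):
        sol = solve_fba(core_net, core_objective)
        v = sol.flux_vector(core_net)
        lb, ub = core_net.bounds
        scale = max(1.0, np.max(np.abs(v)))
        assert np.max(np.abs(core_net.S @ v)) <= 1e-9 * scale
        assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)
        assert sol.objective_value == pytest.approx(
            sum(core_objective.components[r] * sol.fluxes[r] for r in core_objective.components)
        )

    def test_objective_scaling(self, core_net, core_objective):
        base = solve_fba(core_net, core_objective).objective_value
        scaled = solve_fba(core_net, core_objective.scaled(3.5)).objective_value
        assert scaled == pytest.approx(3.5 * base, rel=1e-8)

    def test_agrees_with_cobra_oracle(self, core_net, core_objective, tmp_path):
        cobra = pytest.importorskip("cobra")
        from warburg.network import write_network
        p = tmp_path / "core.xml"
        write_network(core_net, str(p), "sbml")
        model = cobra.io.read_sbml_model(str(p))
        model.objective = {
            model.reactions.get_by_id(r): w
            for r, w in core_objective.components.items()
        }
        ref = model.optimize().objective_value
        mine = solve_fba(core_net, core_objective).objective_value
        assert mine == pytest.approx(ref, rel=1e-6)


class TestDeleteReaction:
    def test_broken_chain_gives_zero(self):
        net = make_toy_network("chain")
        sol = solve_fba(delete_reaction(net, "R1"), ObjectiveSpec({"SNK": 1.0}))
        assert sol.objective_value == pytest.approx(0.0)

    def test_original_is_unchanged(self):
        net = make_toy_network("chain")
        delete_reaction(net, "R1")
        assert net.reaction("R1").upper_bound == 1000.0

    def test_parallel_path_deletion_is_neutral(self):
        net = make_toy_network("parallel")
        obj = ObjectiveSpec({"SNK": 1.0})
        assert solve_fba(delete_reaction(net, "B1"), obj).objective_value == pytest.approx(10.0)

    def test_unknown_id_raises_key_error(self, core_net):
        with pytest.raises(KeyError):
            delete_reaction(core_net, "NOPE")

    def test_deleting_a_flux_restriction_never_increases_objective(
        self, core_net, core_objective
    ):
        # holds for every reaction whose bounds straddle zero (closing it is
        # a pure restriction); demands with maintenance lower bounds are the
        # deliberate exception, since deleting one also drops its minimum
        wt = solve_fba(core_net, core_objective).objective_value
        restrictions = [r.id for r in core_net.reactions if r.lower_bound <= 0]
        rng = np.random.default_rng(0)
        for rid in rng.choice(restrictions, size=20, replace=False):
            sol = solve_fba(delete_reaction(core_net, str(rid)), core_objective)
            if sol.status == "optimal":
                assert sol.objective_value <= wt + 1e-6
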