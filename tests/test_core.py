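import numpy as np
import pytest

from cafba import (
    CafbaWeights,
    build_cafba_lp,
    solve_cafba,
    verify_solution,
    wc_from_sugar_level,
)
from cafba.core import CafbaSolution
from cafba.toys import chain_lambda, make_linear_chain, make_two_pathway


@pytest.mark.parametrize("seed", range(8))
def test_chain_closed_form(seed):
    """A single pathway's optimum is phi_max*y / (w_C + sum w_i + y*w_R)."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 5))
    y = float(rng.uniform(0.3, 2.0))
    w_path = rng.uniform(0.01, 0.3, size=k).tolist()
    w_C = float(rng.uniform(0.0, 0.3))
    w_R = float(rng.uniform(0.05, 0.4))
    phi = float(rng.uniform(0.2, 0.9))
    model, weights, lam = make_linear_chain(
        k=k, y=y, w_path=w_path, w_C=w_C, w_R=w_R, phi_max=phi
    )
    sol = solve_cafba(model, weights)
    assert sol.optimal
    assert sol.growth_rate == pytest.approx(lam, abs=1e-8)
    assert sol.constraint_slack == pytest.approx(0.0, abs=1e-6)


def test_growth_is_hyperbolic_in_carbon_cost():
    """1/lambda is exactly affine in w_C (Monod-like lambda vs 1/w_C)."""
    model, weights, _ = make_linear_chain()
    inv_lams = []
    grid = [0.05, 0.1, 0.2, 0.4]
    for w_C in grid:
        sol = solve_cafba(model, weights.replace(w_C=w_C))
        inv_lams.append(1.0 / sol.growth_rate)
    slopes = np.diff(inv_lams) / np.diff(grid)
    np.testing.assert_allclose(slopes, slopes[0], atol=1e-8)


class TestBuildLP:
    def test_reversible_weighted_reaction_is_split(self):
        model, _ = _reversible_toy()
        weights = CafbaWeights(
            w_C=0.0, w_R=0.1, phi_max=0.5, w={"R1": 0.1}
        )
        lp = build_cafba_lp(model, weights)
        j = model.index("R1")
        assert j in lp.split
        pos = model.n_reactions + lp.split.index(j)
        assert lp.lower[j] == 0.0 and lp.upper[j] == 10.0
        assert lp.lower[pos] == 0.0 and lp.upper[pos] == 10.0
        assert lp.allocation_row[j] == pytest.approx(0.1)
        assert lp.allocation_row[pos] == pytest.approx(0.1)

    def test_unweighted_irreversible_reaction_not_split(self):
        model, weights, _ = make_linear_chain()
        lp = build_cafba_lp(model, weights)
        j = model.index("UPT")
        assert j not in lp.split
        assert lp.allocation_row[j] == 0.0

    def test_allocation_row_support(self):
        # chain with k weighted steps: k enzymatic coefficients plus the
        # biomass (w_R) and carbon-uptake (w_C backward) entries
        model, weights, _ = make_linear_chain(k=2, w_path=[0.1, 0.2])
        lp = build_cafba_lp(model, weights)
        assert int(np.count_nonzero(lp.allocation_row)) == 2 + 2

    def test_missing_enzymatic_weight_rejected(self):
        model, _, _ = make_linear_chain()
        with pytest.raises(ValueError, match="cover"):
            build_cafba_lp(
                model, CafbaWeights(w_C=0.1, w_R=0.1, phi_max=0.5, w={})
            )

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            CafbaWeights(w_C=0.0, w_R=0.1, phi_max=0.5, w={"E1": -1.0})


class TestSolve:
    def test_zero_budget_forces_zero_growth(self):
        model, weights, _ = make_linear_chain()
        sol = solve_cafba(model, weights.replace(phi_max=0.0))
        assert sol.optimal
        assert sol.growth_rate == pytest.approx(0.0, abs=1e-9)
        assert all(abs(v) < 1e-9 for v in sol.fluxes.values())

    def test_infeasible_when_budget_cannot_cover_forced_flux(self):
        model, weights, _ = make_linear_chain()
        j = model.index("BIOMASS")
        forced = model.copy()
        forced.lower_bounds[j] = 0.5  # demand growth with no budget
        sol = solve_cafba(forced, weights.replace(phi_max=0.0))
        assert sol.status == "infeasible"

    @pytest.mark.parametrize(
        "param,grid",
        [
            ("w_C", [0.0, 0.1, 0.3, 0.6]),
            ("w_R", [0.1, 0.2, 0.5, 1.0]),
        ],
    )
    def test_growth_nonincreasing_in_costs(self, param, grid):
        model, weights, _ = make_linear_chain()
        lams = [
            solve_cafba(model, weights.replace(**{param: g})).growth_rate
            for g in grid
        ]
        assert all(a >= b - 1e-10 for a, b in zip(lams, lams[1:]))

    def test_growth_nondecreasing_in_budget(self):
        model, weights, _ = make_linear_chain()
        lams = [
            solve_cafba(model, weights.replace(phi_max=p)).growth_rate
            for p in [0.1, 0.3, 0.6, 0.9]
        ]
        assert all(b >= a - 1e-10 for a, b in zip(lams, lams[1:]))

    def test_allocation_binds_at_growth_limited_optimum(self, core_model):
        from cafba import homogeneous_weights

        sol = solve_cafba(core_model, homogeneous_weights(core_model, 8.3e-4))
        assert sol.growth_rate > 0
        assert abs(sol.constraint_slack) <= 1e-6

    def test_sector_fractions_sum_to_budget(self):
        model, weights, _ = make_linear_chain()
        sol = solve_cafba(model, weights)
        total = sum(sol.sector_fractions.values())
        assert total == pytest.approx(weights.phi_max, abs=1e-8)


class TestVerify:
    def test_clean_solution_has_tiny_residuals(self):
        model, weights, _ = make_linear_chain()
        sol = solve_cafba(model, weights)
        report = verify_solution(model, weights, sol)
        assert max(report.values()) <= 1e-6

    def test_corrupted_fluxes_flagged(self):
        model, weights, _ = make_linear_chain()
        sol = solve_cafba(model, weights)
        sol.fluxes["UPT"] += 5000.0  # violates its upper bound
        report = verify_solution(model, weights, sol)
        assert report["bounds"] > 1.0
        assert report["mass_balance"] > 1.0

    def test_simultaneous_forward_backward_flagged(self):
        model, weights, _ = make_linear_chain()
        sol = solve_cafba(model, weights)
        sol.forward["E1"] = 1.0
        sol.backward["E1"] = 1.0
        report = verify_solution(model, weights, sol)
        assert report["split_property"] == pytest.approx(1.0)


class TestSugarLevel:
    def test_saturating_limit(self):
        assert wc_from_sugar_level(2e-4, K_M=0.1, g_level=1e9) == pytest.approx(
            2e-4, rel=1e-6
        )

    def test_half_saturation_doubles_cost(self):
        assert wc_from_sugar_level(2e-4, 0.1, 0.1) == pytest.approx(4e-4)

    def test_zero_base_cost(self):
        assert wc_from_sugar_level(0.0, 0.1, 0.5) == 0.0

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            wc_from_sugar_level(1e-4, 0.1, 0.0)


def test_two_pathway_switch_around_crossover():
    toy = make_two_pathway()
    for factor, active, idle in [(0.9, "PF", "PH"), (1.1, "PH", "PF")]:
        sol = solve_cafba(toy.model, toy.weights(toy.w_c_star * factor))
        assert sol.fluxes[active] > 1e-6
        assert sol.fluxes[idle] == pytest.approx(0.0, abs=1e-8)
        assert sol.growth_rate == pytest.approx(
            toy.lambda_star(toy.w_c_star * factor), abs=1e-8
        )


def _reversible_toy():
    """Two-metabolite toy with one reversible weighted interconversion."""
    import scipy.sparse as sp

    from cafba.model import MetabolicModel, SectorConfig, classify_reactions

    model = MetabolicModel(
        metabolite_ids=["a_c", "b_c"],
        reaction_ids=["EX_a", "R1", "BIOMASS"],
        S=sp.csc_matrix(
            np.array([[-1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        ),
        lower_bounds=np.array([-10.0, -10.0, 0.0]),
        upper_bounds=np.array([10.0, 10.0, 10.0]),
        biomass_reaction="BIOMASS",
        metabolite_compartments={"a_c": "c", "b_c": "c"},
    )
    model = classify_reactions(
        model, SectorConfig(carbon_source="EX_a")
    )
    return model, None
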