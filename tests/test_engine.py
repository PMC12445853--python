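import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafgx import EnvironmentState, ValidationError
from leafgx.engine import (
    STEP_LABELS,
    ScenarioError,
    TRAIT_COLUMNS,
    gsmax_from_operational,
    initial_state,
    normalize_timelapse,
    percent_changes,
    run_scenario,
    timelapse_frame,
)


@pytest.fixture(scope="module")
def co2_lapse(ref_env, constants):
    return run_scenario(ref_env, ref_env.replace(ca_ppm=800.0), constants,
                        scenario="co2_doubling")


@pytest.fixture(scope="module")
def vpd_lapse(ref_env, constants):
    return run_scenario(ref_env, ref_env.replace(vpd=2000.0), constants,
                        scenario="vpd_doubling")


class TestInitialState:
    def test_optimum_ratios_by_construction(self, ref_env, constants):
        leaf = initial_state(ref_env, constants)
        assert leaf.ratio_ci(ref_env) == pytest.approx(1.0, abs=1e-12)
        assert leaf.ratio_gs() == pytest.approx(constants.gamma_ratio,
                                                abs=1e-12)

    def test_reference_chi_and_assimilation(self, ref_env, constants):
        leaf = initial_state(ref_env, constants)
        assert round(leaf.chi_opt, 2) == 0.75
        assert round(leaf.a_leaf, 1) == 13.9


class TestGsmaxFromOperational:
    @pytest.mark.parametrize("gs,gamma,expected", [
        (0.25, 0.25, 1.0), (0.22, 0.25, 0.88)])
    def test_values(self, gs, gamma, expected):
        assert gsmax_from_operational(gs, gamma) == pytest.approx(expected)

    def test_round_trip(self):
        for gs in (0.05, 0.22, 1.3):
            assert gsmax_from_operational(gs, 0.25) * 0.25 == pytest.approx(gs)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            gsmax_from_operational(-0.1, 0.25)
        with pytest.raises(ValidationError):
            gsmax_from_operational(0.2, 1.2)


class TestScenarioStructure:
    def test_labels_once_in_order(self, co2_lapse):
        assert tuple(s.label for s in co2_lapse.steps) == STEP_LABELS
        assert [s.index for s in co2_lapse.steps] == [0, 1, 2, 3, 4]

    def test_gs_never_exceeds_gsmax(self, co2_lapse, vpd_lapse):
        for lapse in (co2_lapse, vpd_lapse):
            for step in lapse.steps:
                assert step.leaf.gs <= step.leaf.gsmax + 1e-12

    def test_ratio_gs_returns_to_gamma(self, co2_lapse, vpd_lapse, constants):
        for lapse in (co2_lapse, vpd_lapse):
            assert lapse.steps[4].leaf.ratio_gs() == pytest.approx(
                constants.gamma_ratio, abs=1e-12)

    def test_rejects_temperature_or_light_perturbation(self, ref_env,
                                                       constants):
        with pytest.raises(ScenarioError):
            run_scenario(ref_env, ref_env.replace(temp_c=30.0), constants)
        with pytest.raises(ScenarioError):
            run_scenario(ref_env, ref_env.replace(ppfd=400.0), constants)

    def test_null_perturbation_is_fixed_point(self, ref_env, constants):
        """env1 = env0: all five steps identical to step 0 within tolerance."""
        lapse = run_scenario(ref_env, ref_env, constants)
        leaf0 = lapse.steps[0].leaf
        for step in lapse.steps[1:]:
            for attr in ("ci", "gs", "vcmax", "jmax", "gsmax", "a_leaf"):
                assert getattr(step.leaf, attr) == pytest.approx(
                    getattr(leaf0, attr), rel=2e-4), (step.label, attr)


class TestScenarioPhysics:
    def test_co2_ratio_overshoots_then_relaxes_to_one(self, co2_lapse):
        """CO2 step: ci:ca/chi jumps above 1, then decreases monotonically
        back to 1 as stomata and biochemistry adjust."""
        ratios = [s.leaf.ratio_ci(s.env) for s in co2_lapse.steps]
        assert ratios[1] > 1.05
        assert ratios[1] > ratios[2] > ratios[3]
        assert ratios[3] == pytest.approx(1.0, abs=1e-6)
        assert ratios[4] == pytest.approx(1.0, abs=1e-6)

    def test_co2_instantaneous_fertilization(self, co2_lapse):
        a = [s.leaf.a_leaf for s in co2_lapse.steps]
        assert a[1] > a[0] * 1.2  # strong CO2 fertilization at fixed traits

    def test_vpd_step_leaves_assimilation_unchanged(self, vpd_lapse):
        """VPD does not enter the demand curve or the supply line: with all
        traits frozen, the instantaneous step changes nothing."""
        leaf0, leaf1 = vpd_lapse.steps[0].leaf, vpd_lapse.steps[1].leaf
        assert leaf1.a_leaf == pytest.approx(leaf0.a_leaf, rel=1e-9)
        assert leaf1.ci == pytest.approx(leaf0.ci, rel=1e-9)

    def test_stomata_close_in_both_scenarios(self, co2_lapse, vpd_lapse):
        for lapse in (co2_lapse, vpd_lapse):
            gs = [s.leaf.gs for s in lapse.steps]
            assert gs[2] < gs[1]          # minute-scale closure
            assert gs[3] < gs[0]          # acclimated state drier/more closed

    def test_vcmax_downregulates_under_co2_upregulates_under_vpd(
            self, co2_lapse, vpd_lapse):
        assert co2_lapse.steps[3].leaf.vcmax < co2_lapse.steps[0].leaf.vcmax
        assert vpd_lapse.steps[3].leaf.vcmax > vpd_lapse.steps[0].leaf.vcmax

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(ca_factor=st.floats(1 / 3, 3.0), vpd_factor=st.floats(1 / 3, 3.0))
    def test_step4_equals_fresh_optimum(self, ref_env, constants,
                                        ca_factor, vpd_factor):
        """Step-4 convergence: after anatomical adjustment the leaf equals a
        freshly coordinated leaf at the perturbed environment (rel 1e-4)."""
        env1 = ref_env.replace(ca_ppm=ref_env.ca_ppm * ca_factor,
                               vpd=ref_env.vpd * vpd_factor)
        lapse = run_scenario(ref_env, env1, constants)
        fresh = initial_state(env1, constants)
        leaf4 = lapse.steps[4].leaf
        for attr in ("ci", "gs", "vcmax", "jmax", "gsmax", "chi_opt",
                     "a_leaf"):
            assert getattr(leaf4, attr) == pytest.approx(
                getattr(fresh, attr), rel=1e-4), attr


class TestNormalizationAndReporting:
    def test_normalized_series_bounded_with_unit_max(self, co2_lapse,
                                                     vpd_lapse):
        for lapse in (co2_lapse, vpd_lapse):
            for trait, series in lapse.normalized.items():
                assert max(series) == 1.0, trait
                assert all(0.0 <= v <= 1.0 for v in series), trait

    def test_co2_assimilation_normalized_shape(self, co2_lapse):
        """A_leaf jumps at the instantaneous step, dips while stomata close
        at fixed biochemistry, and recovers to its peak once capacities and
        g_s are re-coordinated; step 0 is the scenario minimum."""
        series = co2_lapse.normalized["a_leaf"]
        assert series[3] == 1.0 and series[4] == 1.0
        assert series[0] < series[2] < series[1] < 1.0

    def test_percent_changes_identities(self, vpd_lapse):
        pc = percent_changes(vpd_lapse)
        gsmax = pc[(pc.trait == "gsmax")]["percent_change"].to_numpy()
        assert gsmax[0] == gsmax[1] == gsmax[2] == 0.0  # anatomy frozen 0-3
        a01 = pc[(pc.trait == "a_leaf")
                 & (pc.transition == "0-1")].percent_change.iloc[0]
        assert a01 == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_normalizes_to_ones(self, ref_env, constants):
        lapse = run_scenario(ref_env, ref_env, constants)
        assert np.allclose(lapse.normalized["gsmax"], 1.0)

    def test_frame_layout_and_determinism(self, ref_env, constants):
        """Identical configuration produces bit-identical exported tables."""
        env1 = ref_env.replace(ca_ppm=800.0)
        f1 = timelapse_frame(run_scenario(ref_env, env1, constants))
        f2 = timelapse_frame(run_scenario(ref_env, env1, constants))
        assert f1.to_csv(index=False) == f2.to_csv(index=False)
        assert set(f1.columns) == {"scenario", "step_index", "step_label",
                                   "timescale", "trait", "value",
                                   "normalized_value"}
        assert len(f1) == 5 * len(TRAIT_COLUMNS)
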