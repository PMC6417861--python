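import numpy as np
import pytest

from parpolar import GeometrySpec, Scenario, Trigger, make_scenario
from parpolar.scenarios import DEFAULT_CORNER_WEIGHTS


class TestScenarioBuild:
    def test_wt_trigger_sits_at_posterior_pole(self, params):
        sc = make_scenario("wt", "ellipse")
        prob = sc.build(params, 128)
        L = prob.curvature.circumference
        assert sc.trigger.center == pytest.approx(L / 2)
        # stress-reduction patch peaks at the trigger centre
        i = np.argmax(prob.trigger_patch)
        assert prob.x[i] == pytest.approx(L / 2, abs=2 * prob.dx)

    def test_no_trigger_has_no_patch(self, params):
        prob = make_scenario("no-trigger", "ellipse").build(params, 128)
        assert prob.trigger_patch is None

    def test_weak_anterior_depth_fraction(self):
        sc = make_scenario("weak-anterior")
        wt = make_scenario("wt", "ellipse")
        assert sc.trigger.center == 0.0
        assert sc.trigger.depth == pytest.approx(0.25 * wt.trigger.depth)

    def test_attachment_profile_peaks_at_curvature_peaks(self, params):
        sc = make_scenario("no-trigger", "ellipse")
        prob = sc.build(params, 256)
        konP = prob.kon_P_profile
        # enhancement only: never below the base rate, and the lateral
        # minimum stays close to it (the ellipse's excess vanishes there)
        assert np.all(konP >= params.kon_P - 1e-12)
        assert konP.min() == pytest.approx(params.kon_P, rel=0.05)
        i = int(np.argmax(konP))
        peaks = prob.curvature.peaks
        d = min(abs(prob.x[i] - c) for c in peaks)
        assert d < 3 * prob.dx

    def test_triangle_corner_weights_order_attachment(self, params):
        sc = make_scenario("no-trigger", "triangle")
        prob = sc.build(params, 256)
        curv = prob.curvature
        vals = [
            prob.kon_P_profile[int(round(c / curv.spacing)) % 256] for c in curv.peaks
        ]
        assert vals[0] > vals[1] > vals[2]
        assert sc.geometry.corner_weights == DEFAULT_CORNER_WEIGHTS

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            make_scenario("nonsense")
        with pytest.raises(ValueError):
            make_scenario("lateral", "triangle")


class TestInitialState:
    def test_uniform_start_is_mass_consistent(self, params):
        prob = make_scenario("no-trigger", "ellipse").build(params, 128)
        st = prob.initial_state(params)
        totA, totP = st.total_mass(params)
        assert totA == pytest.approx(params.A_total, rel=1e-12)
        assert totP == pytest.approx(params.P_total, rel=1e-12)

    def test_bias_bump_raises_P_locally(self, params):
        prob = make_scenario("no-trigger", "ellipse").build(params, 128)
        st = prob.initial_state(params, bias=(0.0, 8.0, 0.5))
        assert st.P[0] > st.P[64]
        totP = st.total_mass(params)[1]
        assert totP == pytest.approx(params.P_total, rel=1e-12)

    def test_noise_is_seeded_and_reproducible(self, params):
        sc = Scenario(
            "noisy", GeometrySpec(shape="ellipse"), None, noise_amp=0.05, noise_seed=7
        )
        st1 = sc.build(params, 64).initial_state(params)
        st2 = sc.build(params, 64).initial_state(params)
        assert np.array_equal(st1.P, st2.P)
        assert np.ptp(st1.P) > 0
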