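import numpy as np
import pytest

from conftest import make_stride
from gaitlen import GaitScenario, SubjectProfile, generate_trace, make_profiles
from gaitlen.calibration import RankDeficientError, fit, fit_polygon_style
from gaitlen.models import estimate_many

SUBJECT = SubjectProfile("S01", height=1.75)


def _strides_with_refs(seed=0, n=500, k1=0.35, k2=0.20, sigma=0.02):
    scenario = GaitScenario(seed=seed, n_strides=n, true_k1=k1, true_k2=k2,
                            length_noise_sd=sigma)
    _, strides = generate_trace(scenario)
    return strides


class TestFit:
    def test_base_noiseless_proportional_data(self):
        # (a_r^0.1, d_ref) = (1, 2) and (2, 4): K = 2 exactly
        strides = [make_stride(a_max=9, a_min=8, d_ref=2.0)] * 3 + [
            make_stride(a_max=1026, a_min=2, d_ref=4.0)
        ] * 3
        params = fit("base", strides)
        assert params.constants["K"] == pytest.approx(2.0)
        assert params.diagnostics["rss"] == pytest.approx(0.0, abs=1e-20)

    def test_proposed_parameter_recovery(self):
        params = fit("proposed", _strides_with_refs(seed=101))
        assert params.constants["K1"] == pytest.approx(0.35, abs=0.02)
        assert params.constants["K2"] == pytest.approx(0.20, abs=0.02)

    def test_recovery_error_vanishes_with_noise(self):
        errs = []
        for sigma in (0.02, 0.01, 0.0):
            p = fit("proposed", _strides_with_refs(seed=55, sigma=sigma))
            errs.append(abs(p.constants["K1"] - 0.35) + abs(p.constants["K2"] - 0.20))
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[-1] < 1e-10

    @pytest.mark.parametrize("model_id", ["base", "mikov", "bylemans"])
    def test_single_constant_fit_beats_grid(self, model_id, rng):
        strides = _strides_with_refs(seed=7, n=60)
        params = fit(model_id, strides, SUBJECT)
        d = np.array([s.d_ref for s in strides])

        def rss(c):
            p = type(params)(model_id, {"K": c})
            return np.sum((np.array(estimate_many(strides, p, SUBJECT)) - d) ** 2)

        K = params.constants["K"]
        grid = np.linspace(0.5 * K, 1.5 * K, 101)
        assert params.diagnostics["rss"] <= min(rss(c) for c in grid) + 1e-9

    def test_shin_park_collinear_frequency_rejected(self):
        strides = [make_stride(F=1.0, a_v=2.0, d_ref=1.2) for _ in range(10)]
        with pytest.raises(RankDeficientError, match="collinear"):
            fit("shin_park", strides)

    def test_sharp_yu_log_space_fit_recovers_power_law(self):
        rng = np.random.default_rng(3)
        strides = []
        for _ in range(200):
            F = rng.uniform(0.8, 1.2)
            a_r = rng.uniform(3.0, 8.0)
            d = 0.7 * 1.75 * a_r**0.3 * F**0.5
            strides.append(make_stride(F=F, a_max=8 + a_r, a_min=8, d_ref=d))
        p = fit("sharp_yu", strides, SUBJECT)
        assert p.constants["K2"] == 1.0
        assert p.constants["K1"] == pytest.approx(0.7, rel=1e-6)
        assert p.constants["K3"] == pytest.approx(0.3, abs=1e-6)
        assert p.constants["K4"] == pytest.approx(0.5, abs=1e-6)

    def test_sharp_yu_requires_positive_inputs(self):
        strides = [make_stride(a_max=8, a_min=8, d_ref=1.0)] * 10
        with pytest.raises(ValueError):
            fit("sharp_yu", strides, SUBJECT)

    def test_fit_invariant_to_stride_order(self):
        strides = _strides_with_refs(seed=9, n=50)
        p1 = fit("proposed", strides)
        p2 = fit("proposed", list(reversed(strides)))
        for k in p1.constants:
            assert p1.constants[k] == pytest.approx(p2.constants[k], rel=1e-10)

    def test_too_few_strides_rejected(self):
        with pytest.raises(ValueError, match="strides"):
            fit("proposed", _strides_with_refs(n=20)[:3])


class TestProfilesAndPolygonStyle:
    def test_three_speeds_give_increasing_mean_frequency(self):
        trials = {
            lab: generate_trace(GaitScenario(seed=20 + i, n_strides=60, speed_label=lab))[1]
            for i, lab in enumerate(("slow", "normal", "fast"))
        }
        profiles = make_profiles(trials, SUBJECT)
        freqs = [p.mean_F for p in profiles]
        assert freqs == sorted(freqs)
        assert len(profiles) == 3

    def test_duplicate_trials_give_identical_profiles(self):
        strides = _strides_with_refs(seed=31, n=60)
        p1 = make_profiles({"normal": strides}, SUBJECT)[0]
        p2 = make_profiles({"normal": list(strides)}, SUBJECT)[0]
        assert p1.params.constants == p2.params.constants
        assert (p1.mean_F, p1.mean_a_r) == (p2.mean_F, p2.mean_a_r)

    def test_joining_identical_windows_preserves_constants(self):
        strides = _strides_with_refs(seed=32, n=60)
        single = fit("proposed", strides)
        joined = fit_polygon_style("proposed", [strides, strides, strides])
        for k in single.constants:
            assert joined.constants[k] == pytest.approx(single.constants[k], rel=1e-9)

    def test_joined_fit_rss_at_least_sum_of_per_window(self):
        w1 = _strides_with_refs(seed=33, n=60, k1=0.5, k2=0.15)
        w2 = _strides_with_refs(seed=34, n=60, k1=0.25, k2=0.30)
        joined = fit_polygon_style("proposed", [w1, w2])
        separate = fit("proposed", w1).diagnostics["rss"] + fit("proposed", w2).diagnostics["rss"]
        assert joined.diagnostics["rss"] >= separate - 1e-9
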