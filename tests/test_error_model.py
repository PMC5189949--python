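"""Background-model calibration: smoothing, germline masking, thresholds, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bper.error_model import (
    BackgroundErrorModel,
    BackgroundErrorModelResults,
    ErrorModelConfig,
    NoiseStats,
    calibrate,
)
from bper.exceptions import (
    CalibrationError,
    ConsistencyError,
    MaskedPositionError,
    ModelLookupError,
    ModelVersionError,
)
from bper.panel import Alteration, PanelPosition, PileupMatrix
from conftest import clean_controls

SUB_T = Alteration("sub", "T")
DEL_3 = Alteration("del", "", 3)


class TestCalibration:
    def test_zero_count_pair_hand_value(self):
        """20 clean controls at depth 10,000: mu = c0/(d + 4 c0), sigma = 0, tau = floor."""
        model = calibrate(clean_controls(20))
        st_ = model.noise((("chr1", 100)), SUB_T)
        assert st_.mu == pytest.approx(0.5 / 10002, rel=1e-12)
        assert st_.sigma == 0.0
        assert model.threshold_for(("chr1", 100), SUB_T) == pytest.approx(0.003)

    def test_too_few_controls_raises(self):
        with pytest.raises(CalibrationError):
            calibrate(clean_controls(9))

    def test_controls_on_different_panels_raise(self):
        controls = clean_controls(10)
        other = PileupMatrix("odd", [PanelPosition("chrX", 1, "A")], [10_000])
        with pytest.raises(ConsistencyError):
            calibrate(controls[:-1] + [other])

    def test_germline_like_control_dropped_from_estimate(self):
        # one control carries a heterozygous-like 50% signal at position 0
        counts = [{} for _ in range(20)]
        counts[0] = {0: {"sub:T": 5000}}
        model = calibrate(clean_controls(20, counts=counts))
        st_ = model.noise(("chr1", 100), SUB_T)
        assert st_.n_controls == 19
        assert st_.mu == pytest.approx(0.5 / 10002, rel=1e-12)
        assert not model.is_masked(("chr1", 100))

    def test_position_masked_when_majority_germline(self):
        counts = [{0: {"sub:T": 5000}} if c < 11 else {} for c in range(20)]
        model = calibrate(clean_controls(20, counts=counts))
        assert model.is_masked(("chr1", 100))
        with pytest.raises(MaskedPositionError):
            model.threshold_for(("chr1", 100), SUB_T)

    def test_binomial_rate_recovery(self):
        """Controls with binomial errors at rate 1e-3: mu recovers the estimator's
        expectation within 3 SE and the raw rate within 10%."""
        rng = np.random.default_rng(11)
        rate, depth, n = 1e-3, 10_000, 20
        counts = [{0: {"sub:T": int(rng.binomial(depth, rate))}} for _ in range(n)]
        model = calibrate(clean_controls(n, counts=counts))
        mu = model.noise(("chr1", 100), SUB_T).mu
        expected = (rate * depth + 0.5) / (depth + 2.0)
        se = np.sqrt(rate * (1 - rate) / depth / n)
        assert abs(mu - expected) < 3 * se
        assert abs(mu - rate) / rate < 0.10

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        counts = [{i: {"sub:T": int(rng.poisson(3))} for i in range(5)} for _ in range(12)]
        controls = clean_controls(12, counts=counts)
        assert calibrate(controls) == calibrate(list(reversed(controls)))

    def test_shallow_controls_excluded(self):
        controls = clean_controls(20)
        shallow = PileupMatrix("sh", controls[0].positions, [500] * 5)
        model = calibrate(controls + [shallow])
        assert model.noise(("chr1", 100), SUB_T).n_controls == 20

    def test_recovery_improves_with_more_controls(self):
        """Mean absolute relative error of mu shrinks from 10 to 40 controls."""
        rng = np.random.default_rng(2)
        n_pos, depth = 100, 10_000
        rates = np.exp(rng.uniform(np.log(1e-5), np.log(1e-3), n_pos))
        panel = [PanelPosition("chr1", i + 1, "C") for i in range(n_pos)]

        def build(n):
            out = []
            for c in range(n):
                cnt = rng.binomial(depth, rates)
                out.append(
                    PileupMatrix(f"c{c}", panel, [depth] * n_pos,
                                 [{"sub:T": int(x)} if x else {} for x in cnt])
                )
            return out

        controls = build(40)
        expected = (rates * depth + 0.5) / (depth + 2.0)

        def mare(model):
            mus = np.array([model.noise(i, SUB_T).mu for i in range(n_pos)])
            return np.mean(np.abs(mus - expected) / expected)

        assert mare(calibrate(controls)) < mare(calibrate(controls[:10]))


class TestThresholds:
    def test_kind_specific_floors_on_clean_positions(self):
        model = calibrate(clean_controls(20))
        assert model.threshold_for(("chr1", 101), SUB_T) == pytest.approx(0.003)
        assert model.threshold_for(("chr1", 101), DEL_3) == pytest.approx(0.001)
        # 2 bp and 1 bp indels share the substitution floor
        assert model.threshold_for(("chr1", 101), Alteration("del", "", 2)) == pytest.approx(0.003)
        assert model.threshold_for(("chr1", 101), Alteration("ins", "AT", 0)) == pytest.approx(0.003)

    def test_noisy_position_uses_gaussian_bound(self):
        model = calibrate(clean_controls(20))
        model._pairs[(0, "sub:T")] = NoiseStats(20, 0.004, 0.001)
        assert model.threshold_for(("chr1", 100), SUB_T) == pytest.approx(0.007)

    def test_unknown_position_raises_lookup_error(self):
        model = calibrate(clean_controls(20))
        with pytest.raises(ModelLookupError):
            model.threshold_for(("chrZ", 1), SUB_T)

    @settings(max_examples=50, deadline=None)
    @given(
        mu=st.floats(0, 0.01), sigma=st.floats(0, 0.01),
        d_mu=st.floats(0, 0.01), d_sigma=st.floats(0, 0.01),
    )
    def test_tau_monotone_and_floored(self, mu, sigma, d_mu, d_sigma):
        model = calibrate(clean_controls(10, n_positions=1))
        def tau(m, s, alt=SUB_T):
            model._pairs[(0, alt.key)] = NoiseStats(10, m, s)
            return model.tau(0, alt)
        base = tau(mu, sigma)
        assert base >= 0.003
        assert tau(mu + d_mu, sigma) >= base
        assert tau(mu, sigma + d_sigma) >= base

    def test_noise_free_controls_hit_floor_everywhere(self, sim_setup):
        """With clean controls tau equals the kind floor at every position."""
        _, profile, _ = sim_setup
        clean = [
            PileupMatrix(f"z{c}", list(profile.panel), [10_000] * len(profile.panel))
            for c in range(20)
        ]
        model = calibrate(clean)
        taus = [model.tau(i, SUB_T) for i in range(len(profile.panel))]
        assert taus == pytest.approx([0.003] * len(taus))
        assert [model.tau(i, DEL_3) for i in range(5)] == pytest.approx([0.001] * 5)


class TestPersistence:
    def test_save_load_round_trip_and_reuse(self, sim_setup, tmp_path):
        config, profile, model = sim_setup
        path = tmp_path / "model.json"
        model.save(path)
        back = BackgroundErrorModelResults.load(path)
        assert back == model
        # reloaded model produces identical calls on a fixed sample
        from bper.simulate import simulate_plasma

        rng = np.random.default_rng(99)
        plasma = simulate_plasma(profile, config, rng, [(7, Alteration("sub", "T"), 0.02)])
        assert model.call_sample(plasma).passing == back.call_sample(plasma).passing

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "trunc.json"
        path.write_text('{"schema_version": 1, "config": {')
        with pytest.raises(ModelVersionError):
            BackgroundErrorModelResults.load(path)

    def test_version_mismatch_raises(self, tmp_path, sim_setup):
        _, _, model = sim_setup
        path = tmp_path / "model.json"
        model.save(path)
        import json

        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelVersionError):
            BackgroundErrorModelResults.load(path)
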