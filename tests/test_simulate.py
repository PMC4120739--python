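import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mixboost.simulate import (
    CONTAMINANTS,
    PCB_BLOCK,
    SimulationConfig,
    calibrate_noise,
    s_transform,
    simulate_panel,
    simulate_study,
    target_f,
    target_f_from_s,
)


class TestPanel:
    def test_shape_and_domains(self):
        panel = simulate_panel(SimulationConfig(seed=4))
        assert panel.shape == (1000, 28)
        assert list(panel.columns) == CONTAMINANTS + ["sex"]
        assert (panel[CONTAMINANTS] > 0).all().all()
        assert set(panel["sex"].unique()) <= {0.0, 1.0}
        assert not panel.isna().any().any()

    def test_seeded_determinism(self):
        a = simulate_panel(SimulationConfig(seed=9))
        b = simulate_panel(SimulationConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_pcb_copula_correlation(self):
        # Monte-Carlo check of the Gaussian copula against the configured
        # log-scale correlation
        R = np.eye(4)
        R[PCB_BLOCK.index("PCB 118"), PCB_BLOCK.index("PCB 153")] = 0.5
        R[PCB_BLOCK.index("PCB 153"), PCB_BLOCK.index("PCB 118")] = 0.5
        cfg = SimulationConfig(n_subjects=100_000, pcb_correlation=R, seed=12)
        panel = simulate_panel(cfg)
        got = np.corrcoef(np.log(panel["PCB 118"]), np.log(panel["PCB 153"]))[0, 1]
        assert abs(got - 0.5) < 0.02
        # uncorrelated pair of the block stays near zero
        other = np.corrcoef(np.log(panel["PCB 170"]), np.log(panel["PCB 209"]))[0, 1]
        assert abs(other) < 0.02

    def test_non_positive_definite_correlation_rejected(self):
        R = np.full((4, 4), 0.99)
        np.fill_diagonal(R, 1.0)
        R[0, 1] = R[1, 0] = -0.99  # inconsistent -> not PD
        with pytest.raises(ValueError, match="positive definite"):
            SimulationConfig(pcb_correlation=R)


class TestSTransform:
    def test_rank_transform_values(self):
        out = s_transform([10.0, 1.0, 5.0, 7.0], method="rank")
        assert np.allclose(np.sort(out), [0.125, 0.375, 0.625, 0.875])
        # monotone in the input
        assert np.array_equal(np.argsort(out), np.argsort([10.0, 1.0, 5.0, 7.0]))

    def test_constant_vector_maps_to_half(self):
        for method in ("rank", "range"):
            assert np.allclose(s_transform(np.ones(5), method), 0.5)

    def test_rank_is_spearman_perfect(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=101)
        s = s_transform(x, method="rank")
        rho = stats.spearmanr(x, s).statistic
        assert rho == pytest.approx(1.0)
        assert s.mean() == pytest.approx(0.5)  # forced by (rank - 1/2)/n
        assert np.all((s > 0) & (s < 1))

    def test_range_transform_spans_unit_interval(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=50)
        s = s_transform(x, method="range")
        assert s.min() == 0.0 and s.max() == 1.0
        assert np.array_equal(np.argsort(s), np.argsort(x))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            s_transform([])


class TestTargetFunction:
    def test_closed_form_values(self):
        # peak of the four-way bump, trough of the sine, male BPA at 1
        f = target_f_from_s(1, 1, 1, 1, 0, 1, 1)
        assert f == pytest.approx(12.0)
        # bump at peak, sine at its maximum, female BPA at 0
        f = target_f_from_s(1, 1, 1, 1, 0.25, 0, 0)
        assert f == pytest.approx(11.0 - 1.6)
        # all bump variables at 0: product term collapses to 11 e^-10
        f = target_f_from_s(0, 0, 0, 0, 0, 0, 0)
        assert f == pytest.approx(11.0 * np.exp(-10.0), rel=1e-12)

    def test_depends_only_on_named_columns(self):
        cfg = SimulationConfig(n_subjects=300, seed=5)
        panel = simulate_panel(cfg)
        f0 = target_f(panel)
        shuffled = panel.copy()
        rng = np.random.default_rng(0)
        for col in ["Hg", "PCB 126", "MEP"]:
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
        assert np.array_equal(f0, target_f(shuffled))

    def test_missing_column_named_in_error(self):
        panel = simulate_panel(SimulationConfig(n_subjects=50, seed=5))
        with pytest.raises(ValueError, match="OCDD"):
            target_f(panel.drop(columns=["OCDD"]))

    def test_sex_modifies_bpa_effect(self):
        # same concentrations, flipped sex: F differs through BPA exponent
        panel = simulate_panel(SimulationConfig(n_subjects=200, seed=6))
        flipped = panel.copy()
        flipped["sex"] = 1.0 - flipped["sex"]
        assert not np.allclose(target_f(panel), target_f(flipped))


class TestNoiseCalibration:
    def test_sigma_definition(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=2000)
        out1 = calibrate_noise(f, snr=1.0, rng=np.random.default_rng(0))
        out2 = calibrate_noise(f, snr=2.0, rng=np.random.default_rng(0))
        assert out1.sigma == pytest.approx(np.std(f))
        assert out2.sigma == pytest.approx(np.std(f) / np.sqrt(2.0))

    def test_realized_snr_within_tolerance(self):
        for snr in (2.0, 1.0, 0.5, 0.1):
            _, out = simulate_study(SimulationConfig(snr=snr, seed=17))
            assert abs(out.realized_snr - snr) / snr <= 0.10

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError, match="SNR undefined"):
            calibrate_noise(np.ones(100), snr=1.0)

    def test_mean_realized_snr_converges(self):
        # across seeds the realized SNR is centred on the target
        vals = [
            simulate_study(SimulationConfig(n_subjects=500, snr=1.0, seed=s))[1].realized_snr
            for s in range(30)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.02)

    def test_outcome_is_signal_plus_noise(self, snr2_study):
        data, out = snr2_study
        assert np.allclose(data["y"].to_numpy(), out.f_values + out.noise)
        assert len(out.y) == 1000
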