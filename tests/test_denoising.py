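import math

import numpy as np
import pytest

from xrfdwt import (DenoiseConfig, Spectrum, approximation_at, compute_metrics,
                    denoise, estimate_threshold, select_basis, select_level,
                    soft_threshold)
from xrfdwt import synthdata as sd
from xrfdwt.denoising import (DEFAULT_BASIS_CANDIDATES, DenoiseMetrics,
                              alpha_from, hard_threshold, metrics_table,
                              rank_by_alpha)

# Printed rows of the published basis-comparison study: (SNR, MSE, H).
TABLE2_ROWS = {
    "coif2": (103.85, 528.59, 0.1120), "coif3": (110.57, 519.53, 0.1241),
    "coif4": (110.09, 519.36, 0.1207), "coif5": (98.66, 516.30, 0.1170),
    "db5": (99.46, 531.07, 0.1185), "db6": (100.62, 524.08, 0.1232),
    "db7": (99.65, 517.64, 0.1140), "db8": (111.44, 518.96, 0.1218),
    "db9": (104.54, 516.39, 0.1076), "db10": (103.59, 520.54, 0.1172),
    "sym5": (105.45, 520.84, 0.1136), "sym6": (107.66, 519.21, 0.1099),
    "sym7": (95.79, 517.49, 0.1183), "sym8": (97.53, 519.33, 0.1121),
}
TABLE3_ROWS = {
    3: (110.57, 519.53, 0.1241), 4: (107.46, 603.68, 0.1044),
    5: (104.98, 686.08, 0.0584), 6: (97.52, 743.46, 0.0487),
    7: (113.44, 779.65, 0.0237), 8: (98.06, 798.07, 0.0280),
    9: (141.54, 807.36, 0.0313), 10: (92.70, 815.65, 0.0349),
}


class TestThresholding:
    @pytest.mark.parametrize("coeffs,t,expected", [
        ([5, -1, 2], 2.0, [3, 0, 0]),
        ([-5], 2.0, [-3]),
        ([1.5, -2.5, 0.0], 0.0, [1.5, -2.5, 0.0]),
    ])
    def test_soft_threshold_definition(self, coeffs, t, expected):
        np.testing.assert_allclose(soft_threshold(coeffs, t), expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold([1.0], -0.1)
        with pytest.raises(ValueError):
            hard_threshold([1.0], -0.1)

    def test_hard_threshold_keeps_survivors_unshrunk(self):
        np.testing.assert_allclose(hard_threshold([5, -1, 2], 2.0), [5, 0, 0])

    def test_universal_threshold_zero_for_zero_details(self):
        assert estimate_threshold(np.zeros(16), 1024) == 0.0

    def test_universal_threshold_closed_form(self):
        d = np.array([0.6745, -0.6745, 0.6745, -0.6745])
        assert estimate_threshold(d, 1024) == pytest.approx(
            math.sqrt(2 * math.log(1024)), rel=1e-12)

    def test_mad_consistency_monte_carlo(self):
        """For N(0,1) details the estimate concentrates near √(2 ln n)."""
        target = math.sqrt(2 * math.log(1024))
        vals = [estimate_threshold(np.random.default_rng(s).normal(size=512), 1024)
                for s in range(100)]
        assert np.mean(vals) == pytest.approx(target, rel=0.10)

    def test_empty_detail_rejected(self):
        with pytest.raises(ValueError):
            estimate_threshold(np.array([]), 1024)


class TestDenoise:
    def test_noiseless_smooth_spectrum_passes_through(self, sim_cfg, rms_fn):
        clean = sd.continuum(sim_cfg)
        s = Spectrum(clean)
        out = denoise(s)
        assert rms_fn(out.counts - clean) / rms_fn(clean) < 1e-6

    def test_fixed_zero_threshold_is_identity(self, cr_spectrum):
        s, _ = cr_spectrum
        cfg = DenoiseConfig(threshold_rule="fixed", threshold_value=0.0)
        out = denoise(s, cfg)
        np.testing.assert_allclose(out.counts, s.counts, atol=1e-8)

    def test_length_preserved(self, cr_spectrum):
        s, _ = cr_spectrum
        assert denoise(s).n_channels == s.n_channels

    def test_huge_threshold_leaves_only_approximation(self, cr_spectrum):
        """The approximation block must pass through shrinkage untouched."""
        s, _ = cr_spectrum
        cfg = DenoiseConfig(threshold_rule="fixed", threshold_value=1e12)
        out = denoise(s, cfg)
        np.testing.assert_allclose(
            out.counts, approximation_at(s.counts, "coif3", 3), atol=1e-6)

    def test_truth_referenced_snr_improves(self, sim_cfg):
        s, truth = sd.simulate_spectrum({"Cr": 300.0}, sim_cfg, seed=1)
        den = denoise(s)
        snr_raw = compute_metrics(truth.clean_spectrum, s.counts).snr
        snr_den = compute_metrics(truth.clean_spectrum, den.counts).snr
        assert snr_den > snr_raw

    def test_truth_referenced_mse_improves_in_most_seeds(self, sim_cfg):
        wins = 0
        for seed in range(100):
            s, truth = sd.simulate_spectrum({"Cr": 200.0}, sim_cfg, seed=seed)
            den = denoise(s)
            mse_raw = np.mean((s.counts - truth.clean_spectrum) ** 2)
            mse_den = np.mean((den.counts - truth.clean_spectrum) ** 2)
            wins += mse_den < mse_raw
        assert wins >= 95

    def test_peak_position_stable(self, sim_cfg, cal):
        s, truth = sd.simulate_spectrum({el: 400.0 for el in sim_cfg.lines.elements},
                                        sim_cfg, seed=4)
        den = denoise(s)
        for line in sim_cfg.lines:
            mu = cal.channel_index(line.energy)
            window = slice(mu - 25, mu + 26)
            shift = abs(int(np.argmax(den.counts[window]))
                        - int(np.argmax(truth.clean_spectrum[window])))
            assert shift <= 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DenoiseConfig(level=0)
        with pytest.raises(ValueError):
            DenoiseConfig(threshold_rule="fixed")
        with pytest.raises(ValueError):
            DenoiseConfig(mode="fuzzy")


class TestMetrics:
    def test_snr_mse_worked_example(self):
        m = compute_metrics(np.array([3.0, 4.0]), np.array([3.0, 0.0]))
        assert m.mse == pytest.approx(8.0)
        assert m.snr == pytest.approx(10 * math.log10(25 / 16), abs=1e-3)

    def test_uniform_entropy(self):
        n = 256
        m = compute_metrics(np.ones(n), np.ones(n) * 2.0)
        assert m.entropy == pytest.approx(math.log2(n), rel=1e-12)

    def test_identical_inputs_sentinel(self):
        x = np.arange(1.0, 9.0)
        m = compute_metrics(x, x)
        assert math.isinf(m.snr) and m.mse == 0.0 and m.alpha == 0.0

    def test_mse_properties(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=64) + 5, rng.normal(size=64) + 5
        assert compute_metrics(x, x).mse == 0.0
        assert compute_metrics(x, y).mse == pytest.approx(
            compute_metrics(y, x).mse)

    def test_snr_decreases_with_noise_level(self):
        """Adding white noise of growing variance strictly degrades SNR."""
        rng = np.random.default_rng(3)
        x = sd.continuum(sd.SimConfig())
        for seed in range(20):
            rng = np.random.default_rng(seed)
            snrs = [compute_metrics(x, x + rng.normal(0, s, x.size)).snr
                    for s in (1.0, 4.0, 16.0)]
            assert snrs[0] > snrs[1] > snrs[2]

    def test_alpha_conventions_are_reciprocal(self):
        for snr, mse, h in TABLE2_ROWS.values():
            assert alpha_from(snr, mse, h, "table") * \
                alpha_from(snr, mse, h, "eq10") == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("key,table,expected", [
        ("coif3", TABLE2_ROWS, 37.85),
        ("sym8", TABLE2_ROWS, 47.49),
        (4, TABLE3_ROWS, 53.81),
    ])
    def test_alpha_reproduces_printed_values(self, key, table, expected):
        snr, mse, h = table[key]
        assert alpha_from(snr, mse, h) == pytest.approx(expected, abs=0.05)


class TestSelection:
    @staticmethod
    def _injected(rows):
        return [(k, DenoiseMetrics(snr, mse, h, alpha_from(snr, mse, h)))
                for k, (snr, mse, h) in rows.items()]

    def test_printed_basis_table_ranks_coif3_first(self):
        ranked = rank_by_alpha(self._injected(TABLE2_ROWS))
        assert ranked[0][0] == "coif3"

    def test_printed_level_table_ranks_level3_first(self):
        ranked = rank_by_alpha(self._injected(TABLE3_ROWS))
        assert ranked[0][0] == 3

    def test_tie_broken_by_candidate_order(self):
        m = DenoiseMetrics(100.0, 500.0, 0.1, alpha_from(100.0, 500.0, 0.1))
        ranked = rank_by_alpha([("b", m), ("a", m)])
        assert [r[0] for r in ranked] == ["b", "a"]

    def test_single_candidate_selected(self, blank_spectrum):
        s, _ = blank_spectrum
        ranked = select_basis(s, ["db5"], level=4)
        assert len(ranked) == 1 and ranked[0][0] == "db5"

    def test_level_scan_cardinality(self, blank_spectrum):
        s, _ = blank_spectrum
        ranked = select_level(s, "coif3", range(3, 11))
        assert len(ranked) == 8
        assert {lv for lv, _ in ranked} == set(range(3, 11))

    def test_metrics_table_layout(self, blank_spectrum):
        s, _ = blank_spectrum
        df = metrics_table(select_basis(s, ["haar", "db5"], level=3), label="name")
        assert list(df.columns) == ["name", "snr", "mse", "entropy", "alpha"]
        assert df.alpha.is_monotonic_increasing

    def test_default_candidate_set_cardinality(self):
        assert len(DEFAULT_BASIS_CANDIDATES) == 14
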