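import numpy as np
import pytest
from scipy import integrate, stats

from sstrkit import editquant, synthgen, traceio
from sstrkit.editquant import (
    AnchorError,
    ControlError,
    ControlSet,
    SNPSpec,
    editing_fraction,
    filliben_correlation,
    fit_noise_model,
    quality_metrics,
    snp_detection_p,
)
from sstrkit.traceio import AnalysisWindow, Trace


def _flat_trace(seq, amplitude=1000.0):
    n = len(seq)
    heights = np.zeros((n, 4))
    for i, b in enumerate(seq):
        heights[i, traceio.BASE_INDEX[b]] = amplitude
    return Trace("flat", seq, heights)


class TestNoiseModel:
    def test_constant_background_gives_point_mass_mu(self, rng):
        seq = "".join(rng.choice(list("CGT"), 120))  # no called 'A'
        t = _flat_trace(seq)
        c = 0.02  # constant 'A' background proportion of the total
        t.peak_heights[:, 0] = c / (1 - c) * 1000.0
        model = fit_noise_model(t, AnalysisWindow(1, 120))
        assert model.per_base["A"].model_mu == pytest.approx(c)
        assert model.per_base["A"].degenerate

    def test_all_zero_background_flagged_degenerate(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 100))
        model = fit_noise_model(_flat_trace(seq), AnalysisWindow(1, 100))
        for b in "ACGT":
            assert model.per_base[b].degenerate
            assert model.per_base[b].model_mu == 0.0
            assert model.per_base[b].sf(0.01) == 0.0

    def test_window_too_small_rejected(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 100))
        with pytest.raises(ValueError, match="50"):
            fit_noise_model(_flat_trace(seq), AnalysisWindow(1, 30))

    def test_gamma_noise_parameters_recovered(self):
        """Fitting traces simulated from the model's own family recovers the
        generator's shape/scale within bootstrap uncertainty."""
        spec = synthgen.SynthTraceSpec(
            noise_zero_prob=0.2, noise_shape=2.0, noise_scale=0.005,
            context_multiplier_sd=0.0,
            true_editing={}, seed=21,
        )
        b = synthgen.gen_trace_set(spec)
        model = fit_noise_model(b.negative, AnalysisWindow(1, len(b.negative)))
        shapes = [model.per_base[x].shape for x in "ACGT"]
        zeros = [model.per_base[x].zero_prob for x in "ACGT"]
        # proportions are ~ gamma draws scaled by ~1/amplitude-sum; shape is
        # scale-free so it is recovered directly
        assert np.mean(shapes) == pytest.approx(2.0, rel=0.25)
        assert np.mean(zeros) == pytest.approx(0.2, abs=0.06)

    def test_filliben_matches_order_statistic_oracle(self, rng):
        values = rng.gamma(2.0, 0.01, size=40)
        dist = stats.gamma(2.0, scale=0.01)
        n = len(values)
        m = np.empty(n)
        m[0] = 1 - 0.5 ** (1 / n)
        m[-1] = 0.5 ** (1 / n)
        m[1:-1] = (np.arange(2, n) - 0.3175) / (n + 0.365)
        oracle = np.corrcoef(np.sort(values), dist.ppf(m))[0, 1]
        assert filliben_correlation(values, dist) == pytest.approx(oracle)

    def test_quality_metric_triplet(self, noisy_bundle):
        model = fit_noise_model(noisy_bundle.sample)
        qm = quality_metrics(noisy_bundle.sample, model)
        assert 0 < qm.average_percent_signal < 0.05
        assert set(qm.model_mu) == set("ACGT")
        for b in "ACGT":
            assert -1 <= qm.filliben[b] <= 1
        # on a signal-free control the correctly specified family fits well
        neg_model = fit_noise_model(noisy_bundle.negative)
        assert all(v > 0.9 for v in neg_model.filliben.values())

    def test_noiseless_trace_has_zero_average_noise(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        t = _flat_trace(seq)
        model = fit_noise_model(t, AnalysisWindow(50, 250))
        qm = quality_metrics(t, model, AnalysisWindow(50, 250))
        assert qm.average_percent_signal == 0.0


@pytest.fixture(scope="module")
def fitted(noisy_bundle):
    return fit_noise_model(noisy_bundle.sample)


class TestDetectionP:

    def test_zero_observed_signal_gives_p_one(self, fitted, noisy_bundle):
        t = noisy_bundle.sample
        pos = next(
            p for p in range(200, 400)
            if t.peak_heights[p - 1, traceio.BASE_INDEX["A"]] == 0
            and t.called_base(p) != "A"
        )
        assert snp_detection_p(fitted, t, pos, "A") == 1.0

    def test_consensus_channel_rejected(self, fitted, noisy_bundle):
        t = noisy_bundle.sample
        with pytest.raises(ValueError, match="consensus"):
            snp_detection_p(fitted, t, 250, t.called_base(250))

    def test_p_matches_quadrature_of_fitted_density(self, fitted):
        null = fitted.per_base["T"]
        assert not null.degenerate
        dist = null.continuous()
        for obs in (0.002, 0.01, 0.05):
            tail, _ = integrate.quad(dist.pdf, obs, np.inf)
            expected = (1 - null.zero_prob) * tail
            assert null.sf(obs) == pytest.approx(expected, rel=1e-6)

    def test_real_snps_detected_below_alpha(self, noisy_bundle, fitted):
        tmap = traceio.locate_target(noisy_bundle.sample, synthgen.FKB12_TARGET)
        for snp in noisy_bundle.spec.snp_panel:
            pos = tmap.rel_to_trace(snp.rel_position)
            p = snp_detection_p(fitted, noisy_bundle.sample, pos, snp.snp_base)
            assert p < editquant.DEFAULT_ALPHA


class TestEditingFraction:
    def test_hand_computed_normalization_chain(self):
        """Anchor 1000; sample wt 800 / snp 200; r_neg(wt)=1.0, r_pos(snp)=0.8
        -> norm_wt 0.8, norm_snp 0.25, editing 0.25/1.05."""
        template = synthgen.default_template()
        spec = synthgen.SynthTraceSpec(noise_zero_prob=1.0,
                                       context_multiplier_sd=0.0, seed=0)
        b = synthgen.gen_trace_set(spec)
        tmap = traceio.locate_target(b.sample, synthgen.FKB12_TARGET)
        snp = spec.snp_panel[0]
        pos = tmap.rel_to_trace(snp.rel_position)
        anchor = tmap.anchor_position()

        def set_heights(trace, anchor_h, wt_h, snp_h):
            trace.peak_heights[anchor - 1, :] = 0
            trace.peak_heights[anchor - 1, traceio.BASE_INDEX["A"]] = anchor_h
            trace.peak_heights[pos - 1, :] = 0
            trace.peak_heights[pos - 1, traceio.BASE_INDEX[snp.wt_base]] = wt_h
            trace.peak_heights[pos - 1, traceio.BASE_INDEX[snp.snp_base]] = snp_h

        set_heights(b.sample, 1000, 800, 200)
        set_heights(b.negative, 1000, 1000, 0)
        set_heights(b.positives[snp], 1000, 0, 800)
        est = editing_fraction(b.sample, ControlSet(b.negative, b.positives),
                               snp, tmap)
        assert est.norm_wt == pytest.approx(0.8)
        assert est.norm_snp == pytest.approx(0.25)
        assert est.editing_fraction == pytest.approx(0.25 / 1.05)
        assert est.naive_fraction == pytest.approx(0.2)

    def test_sample_equal_to_negative_gives_zero(self, noiseless_bundle, controls,
                                                 target_map):
        for snp in noiseless_bundle.spec.snp_panel:
            est = editing_fraction(
                noiseless_bundle.negative, controls, snp, target_map
            )
            assert est.editing_fraction == 0.0

    def test_sample_equal_to_positive_gives_one(self, noiseless_bundle, controls,
                                                target_map):
        for snp in noiseless_bundle.spec.snp_panel:
            est = editing_fraction(
                noiseless_bundle.positives[snp], controls, snp, target_map
            )
            assert est.editing_fraction == 1.0

    def test_normalization_recovers_truth_exactly_at_zero_noise(
        self, noiseless_bundle, controls, target_map
    ):
        truth = noiseless_bundle.spec.true_editing
        for snp in noiseless_bundle.spec.snp_panel:
            est = editing_fraction(noiseless_bundle.sample, controls, snp,
                                   target_map)
            assert est.editing_fraction == pytest.approx(
                truth[snp.rel_position], abs=1e-12
            )

    def test_naive_ratio_biased_by_planted_multiplier(
        self, noiseless_bundle, controls, target_map
    ):
        tab = noiseless_bundle.truth.table.set_index("rel_position")
        for snp in noiseless_bundle.spec.snp_panel:
            f = tab.loc[snp.rel_position, "true_editing"]
            if f in (0.0, 1.0):
                continue
            m_wt = tab.loc[snp.rel_position, "multiplier_wt"]
            m_snp = tab.loc[snp.rel_position, "multiplier_snp"]
            expected_naive = f * m_snp / (f * m_snp + (1 - f) * m_wt)
            est = editing_fraction(noiseless_bundle.sample, controls, snp,
                                   target_map)
            assert est.naive_fraction == pytest.approx(expected_naive, abs=1e-12)
            assert est.naive_fraction != pytest.approx(f, abs=1e-6)

    def test_scale_invariance_per_trace(self, noiseless_bundle, controls,
                                        target_map):
        """Multiplying all heights of any one chromatogram by a constant
        leaves every editing fraction unchanged (anchor normalization)."""
        snp = noiseless_bundle.spec.snp_panel[3]
        base = editing_fraction(noiseless_bundle.sample, controls, snp,
                                target_map).editing_fraction
        scaled = Trace(
            "scaled", noiseless_bundle.sample.called_sequence,
            noiseless_bundle.sample.peak_heights * 7.3,
        )
        est = editing_fraction(scaled, controls, snp, target_map)
        assert est.editing_fraction == pytest.approx(base, abs=1e-12)

    def test_estimates_always_in_unit_interval(self, noisy_bundle):
        tmap = traceio.locate_target(noisy_bundle.sample, synthgen.FKB12_TARGET)
        controls = ControlSet(noisy_bundle.negative, noisy_bundle.positives)
        model = fit_noise_model(noisy_bundle.sample)
        for snp in noisy_bundle.spec.snp_panel:
            est = editing_fraction(noisy_bundle.sample, controls, snp, tmap,
                                   model=model)
            assert 0.0 <= est.editing_fraction <= 1.0
            # invariant: fraction == norm_snp / (norm_snp + norm_wt) exactly
            assert est.editing_fraction == est.norm_snp / (
                est.norm_snp + est.norm_wt
            )

    def test_zero_anchor_errors(self, noiseless_bundle, controls, target_map):
        snp = noiseless_bundle.spec.snp_panel[0]
        broken = Trace(
            "broken", noiseless_bundle.sample.called_sequence,
            noiseless_bundle.sample.peak_heights.copy(),
        )
        broken.peak_heights[target_map.anchor_position() - 1, :] = 0
        broken.peak_heights[
            target_map.anchor_position() - 1, traceio.BASE_INDEX["C"]
        ] = 1.0
        with pytest.raises(AnchorError):
            editing_fraction(broken, controls, snp, target_map)

    def test_uninformative_control_errors(self, noiseless_bundle, target_map):
        snp = noiseless_bundle.spec.snp_panel[0]
        dead_pos = Trace(
            "dead", noiseless_bundle.negative.called_sequence,
            noiseless_bundle.negative.peak_heights.copy(),
        )
        with pytest.raises(ControlError, match="positive"):
            editing_fraction(
                noiseless_bundle.sample,
                ControlSet(noiseless_bundle.negative, {snp: dead_pos}),
                snp, target_map,
            )

    def test_output_row_uses_spreadsheet_columns(self, noiseless_bundle, controls,
                                                 target_map):
        snp = noiseless_bundle.spec.snp_panel[1]
        row = editing_fraction(noiseless_bundle.sample, controls, snp,
                               target_map).to_row()
        for col in ("WT base (norm_neg)", "SNP base (norm_pos)",
                    "Editing (norm)", "Editing (EditR)"):
            assert col in row
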