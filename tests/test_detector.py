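"""Peak detector: enhancement, moving averages, block generation, P/T
gating, evaluation metrics, end-to-end invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgfusion.detector import (BlockOfInterest, DetectorConfig,
                                blank_qrs, classify_pt, detect_all, detect_r,
                                enhance, evaluate, moving_average, pt_blocks,
                                r_blocks, rereference)
from ecgfusion.filtering import denoise, qrs_emphasis
from ecgfusion.io import ECGRecord, PeakAnnotations
from ecgfusion.synthetic import NoiseSpec, generate_record

FS = 360.0


def kuhn_max_matching(det, ref, tol):
    """Independent oracle: maximum bipartite matching via Kuhn's algorithm."""
    adj = [[j for j, r in enumerate(ref) if abs(d - r) <= tol] for d in det]
    match_ref = {}

    def try_assign(i, seen):
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if j not in match_ref or try_assign(match_ref[j], seen):
                match_ref[j] = i
                return True
        return False

    return sum(try_assign(i, set()) for i in range(len(det)))


class TestEnhance:
    def test_zero_signal(self):
        assert np.allclose(enhance(np.zeros(100)), 0)

    def test_identity_branch_squares(self):
        assert np.allclose(enhance(np.array([1.0, -2.0, 3.0]), alpha=0.0),
                           [1.0, 4.0, 9.0])

    def test_nonnegative(self, rng):
        assert np.all(enhance(rng.standard_normal(256), 0.01) >= 0)


class TestMovingAverage:
    def test_constant_interior(self):
        x = np.full(50, 3.0)
        out = moving_average(x, 5)
        assert np.allclose(out[2:-2], 3.0)

    def test_window_one_is_identity(self, rng):
        x = rng.standard_normal(30)
        assert np.array_equal(moving_average(x, 1), x)

    def test_matches_bruteforce(self, rng):
        x = rng.standard_normal(64)
        w = 5
        out = moving_average(x, w)
        for n in range(2, 62):
            assert out[n] == pytest.approx(np.mean(x[n - 2: n + 3]))

    @given(st.lists(st.floats(-100, 100), min_size=9, max_size=40),
           st.sampled_from([1, 3, 5, 7, 9]))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bruteforce_property(self, values, w):
        x = np.asarray(values)
        out = moving_average(x, w)
        half = w // 2
        for n in range(half, len(x) - half):
            assert out[n] == pytest.approx(np.mean(x[n - half: n + half + 1]),
                                           abs=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(10), 4)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(3), 5)


class TestRBlocks:
    def test_zero_signal_gives_no_blocks(self):
        assert r_blocks(np.zeros(1000), DetectorConfig(), FS) == []

    def test_negative_enhanced_rejected(self):
        with pytest.raises(ValueError):
            r_blocks(np.array([-1.0, 1.0]), DetectorConfig(), FS)

    def test_single_beat_one_block_contains_r(self):
        syn = generate_record(1, FS, 0.8, 0.0)
        blocks = r_blocks(enhance(syn.clean, 0.01), DetectorConfig(), FS)
        assert len(blocks) == 1
        r = syn.annotations.r_indices[0]
        assert blocks[0].start <= r < blocks[0].stop

    def test_sixty_beats_sixty_blocks(self, clean60):
        emphasized = qrs_emphasis(denoise(clean60.record),
                                  include_approx=False)
        blocks = r_blocks(enhance(emphasized.samples, 0.01),
                          DetectorConfig(), FS)
        assert len(blocks) == 60


class TestDetectR:
    def test_clean_record_perfect(self, clean60):
        r = detect_r(denoise(clean60.record))
        rep = evaluate(r, clean60.annotations.r_indices, FS)
        assert rep.se == 100.0 and rep.ppr == 100.0

    def test_amplitude_scale_invariance(self, noisy60):
        den = denoise(noisy60.record)
        r1 = detect_r(den)
        r2 = detect_r(den.with_samples(den.samples * 10))
        assert np.array_equal(r1, r2)

    def test_noisy_sensitivity(self, noisy60):
        r = detect_r(denoise(noisy60.record))
        rep = evaluate(r, noisy60.annotations.r_indices, FS)
        assert rep.se >= 99.0

    def test_beta_sweep_keeps_perfect_detection(self, clean60):
        den = denoise(clean60.record)
        for beta in (0.01, 0.05, 0.08, 0.15, 0.2):
            r = detect_r(den, DetectorConfig(beta=beta))
            rep = evaluate(r, clean60.annotations.r_indices, FS)
            assert rep.se == 100.0 and rep.ppr == 100.0, f"beta={beta}"


class TestBlankQRS:
    def test_interior_window_size_at_360(self):
        x = np.ones(1000)
        out = blank_qrs(x, [500], DetectorConfig(), FS)
        assert int(np.sum(out == 0)) == 91  # 30 + 1 + 60 samples

    def test_boundary_clipped(self):
        x = np.ones(100)
        out = blank_qrs(x, [5], DetectorConfig(), FS)
        assert np.all(out[:66] == 0) and np.all(out[66:] == 1)

    def test_samples_outside_blanks_untouched(self, rng):
        x = rng.standard_normal(2000)
        out = blank_qrs(x, [500, 1500], DetectorConfig(), FS)
        mask = np.ones(2000, bool)
        mask[470:561] = False
        mask[1470:1561] = False
        assert np.array_equal(out[mask], x[mask])


class TestPTBlocks:
    def test_zero_input_no_blocks(self):
        assert pt_blocks(np.zeros(2000), DetectorConfig(), FS) == []

    def test_constant_signal_tie_gives_no_blocks(self):
        assert pt_blocks(np.full(2000, 2.5), DetectorConfig(), FS) == []

    def test_single_beat_blocks_cover_p_and_t(self):
        # generous lead-in/out so the beat sits clear of the edge-guard zone
        syn = generate_record(1, FS, 1.6, 0.0)
        ann = syn.annotations
        blanked = blank_qrs(syn.clean, ann.r_indices, DetectorConfig(), FS)
        blocks = pt_blocks(enhance(blanked, 0.01), DetectorConfig(), FS)
        assert len(blocks) >= 2
        assert any(b.start <= ann.p_indices[0] < b.stop for b in blocks)
        assert any(b.start <= ann.t_indices[0] < b.stop for b in blocks)


class TestClassifyPT:
    def test_requires_r_peaks(self):
        with pytest.raises(ValueError):
            classify_pt([], np.array([]), DetectorConfig(), FS)

    def test_mid_rr_block_outside_gates_discarded(self):
        cfg = DetectorConfig()
        # peak 150 samples (0.416 s) before the only R: outside both gates
        block = BlockOfInterest(340, 360, 350, "PT-candidate")
        p, t = classify_pt([block], np.array([500]), cfg, FS)
        assert p.size == 0 and t.size == 0

    def test_single_r_with_trailing_t_bump(self):
        cfg = DetectorConfig()
        fs = FS
        x = np.zeros(720)
        r = 200
        t_true = r + 90  # 0.25 s after R
        x[t_true - 20: t_true + 21] += np.exp(
            -((np.arange(-20, 21)) ** 2) / (2 * 7.2 ** 2)) * 0.3
        blanked = blank_qrs(x, [r], cfg, fs)
        blocks = pt_blocks(enhance(blanked, cfg.alpha), cfg, fs)
        p, t = classify_pt(blocks, np.array([r]), cfg, fs, blanked=blanked)
        assert p.size == 0
        assert t.size == 1 and abs(int(t[0]) - t_true) <= 3

    def test_detected_p_precedes_and_t_follows_gated_r(self, clean60):
        ann = detect_all(clean60.record)
        r = ann.r_indices
        for p in ann.p_indices:
            nxt = r[r > p]
            assert nxt.size and 0.10 <= (nxt[0] - p) / FS <= 0.30
        for t in ann.t_indices:
            prv = r[r < t]
            assert prv.size and 0.18 <= (t - prv[-1]) / FS <= 0.48


class TestEvaluate:
    def test_identical_sequences(self):
        rep = evaluate([10, 20, 30], [10, 20, 30], FS)
        assert rep.se == 100.0 and rep.ppr == 100.0 and rep.err == 0.0

    def test_formula_arithmetic(self):
        # TP=9, FN=1, FP=0
        ref = np.arange(10) * 300
        det = ref[:9]
        rep = evaluate(det, ref, FS)
        assert (rep.tp, rep.fp, rep.fn) == (9, 0, 1)
        assert rep.se == pytest.approx(90.0)
        assert rep.ppr == pytest.approx(100.0)
        assert rep.err == pytest.approx(1 / 9)

    def test_no_matches_reports_infinite_err(self):
        rep = evaluate([0], [1000], FS)
        assert rep.err_infinite and np.isinf(rep.err)

    def test_perturbation_within_tolerance_keeps_full_sensitivity(self, rng):
        ref = np.sort(rng.choice(100000, size=50, replace=False))
        det = ref + rng.integers(-10, 11, size=50)  # tol = 0.030*360 = 10.8
        rep = evaluate(np.sort(det), ref, FS)
        assert rep.se == 100.0

    def test_greedy_equals_kuhn_oracle(self, rng):
        tol_s = 0.030
        for _ in range(200):
            nd = int(rng.integers(0, 21))
            nr = int(rng.integers(0, 21))
            det = np.sort(rng.integers(0, 400, size=nd))
            ref = np.sort(rng.integers(0, 400, size=nr))
            rep = evaluate(det, ref, FS, tol_s)
            assert rep.tp == kuhn_max_matching(det, ref, tol_s * FS)


class TestDetectAll:
    def test_clean_end_to_end(self, clean60):
        ann = detect_all(clean60.record)
        assert evaluate(ann.r_indices, clean60.annotations.r_indices,
                        FS).se >= 99.0
        # the edge guard deliberately forfeits the final T of a record
        assert evaluate(ann.p_indices, clean60.annotations.p_indices,
                        FS).se >= 95.0
        assert evaluate(ann.t_indices, clean60.annotations.t_indices,
                        FS).se >= 95.0

    def test_record_shorter_than_beat_returns_empty_with_warning(self):
        rec = ECGRecord(np.zeros(100), FS)
        with pytest.warns(UserWarning, match="shorter"):
            ann = detect_all(rec)
        assert ann.r_indices.size == 0

    def test_scale_invariance_exact(self, noisy60):
        a1 = detect_all(noisy60.record)
        a2 = detect_all(noisy60.record.with_samples(noisy60.record.samples * 7))
        for wave in ("r_indices", "p_indices", "t_indices"):
            assert np.array_equal(getattr(a1, wave), getattr(a2, wave))

    @pytest.mark.parametrize("shift", [512, 1024])
    def test_shift_covariance_on_transform_lattice(self, shift):
        """Zero-padding by a multiple of 2**a* shifts interior detections
        exactly (the decimated wavelet transform is translation-covariant
        only on its decimation lattice)."""
        syn = generate_record(20, FS, 0.8, 0.0)
        a1 = detect_all(syn.record)
        padded = np.concatenate([np.zeros(shift), syn.record.samples])
        a2 = detect_all(syn.record.with_samples(padded))
        n = len(syn.record)
        margin = int(2 * FS)
        for wave in ("r_indices", "p_indices", "t_indices"):
            x = getattr(a1, wave)
            y = getattr(a2, wave)
            interior = x[(x > margin) & (x < n - margin)]
            shifted = y[(y > margin + shift) & (y < n - margin + shift)]
            assert np.array_equal(interior + shift, shifted), wave

    def test_monotone_degradation_with_noise(self):
        ses = []
        for sd in (0.0, 0.1, 0.3, 0.6):
            syn = generate_record(40, FS, 0.8, 0.0,
                                  noise=NoiseSpec(white_noise_sd=sd, seed=11))
            ann = detect_all(syn.record)
            ses.append(evaluate(ann.r_indices, syn.annotations.r_indices, FS).se)
        for a, b in zip(ses, ses[1:]):
            assert b <= a + 1.0  # allow 1 percentage point slack


def test_rereference_centers_isoelectric_level():
    x = np.concatenate([np.full(900, -0.25), np.ones(100)])
    out = rereference(x)
    assert np.median(out) == 0.0
    assert out[-1] == pytest.approx(1.25)


def test_empty_record_is_rejected_by_container():
    with pytest.raises(ValueError):
        ECGRecord(np.array([]), FS)
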