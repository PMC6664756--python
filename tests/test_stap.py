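import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfimpact.formats_io import Pwm
from tfimpact.stap import (
    CalibratedStap,
    LabeledWindow,
    LinearCalibration,
    OccupancyModel,
    fit_stap,
    predict_occupancy,
    predict_stap_score,
    reverse_complement,
    scan_sites,
)
from tfimpact.synthetic import gen_chip_windows, random_pwm


def brute_force_expected_bound(sites_K, tau):
    """Expected bound-site count by enumerating all 2^n configurations with
    factorized Boltzmann weights: weight(c) = prod_{i in c} tau * K_i."""
    total_w = 0.0
    total_bound = 0.0
    n = len(sites_K)
    for config in itertools.product([0, 1], repeat=n):
        w = 1.0
        for bit, K in zip(config, sites_K):
            if bit:
                w *= tau * K
        total_w += w
        total_bound += sum(config) * w
    return total_bound / total_w


class TestScanSites:
    def test_forward_llr(self, toy_pwm):
        hits = {(h.offset, h.strand): h for h in scan_sites("AG", toy_pwm)}
        assert hits[(0, "+")].llr == pytest.approx(2 * math.log(2.8), abs=1e-9)
        assert hits[(0, "+")].K == pytest.approx(1.0)

    def test_reverse_strand_scores_reverse_complement(self, toy_pwm):
        hits = {(h.offset, h.strand): h for h in scan_sites("AG", toy_pwm)}
        # reverse complement of AG is CT: both positions score 0.1/0.25
        assert hits[(0, "-")].llr == pytest.approx(2 * math.log(0.4), abs=1e-9)

    def test_n_bases_score_as_background(self, toy_pwm):
        for hit in scan_sites("NN", toy_pwm):
            assert hit.llr == 0.0

    def test_short_sequence_rejected(self, toy_pwm):
        with pytest.raises(ValueError):
            scan_sites("A", toy_pwm)

    def test_all_offsets_enumerated(self, toy_pwm):
        hits = scan_sites("ACGTT", toy_pwm)
        offsets = {(h.offset, h.strand) for h in hits}
        assert offsets == {(o, s) for o in range(4) for s in "+-"}


class TestPredictOccupancy:
    def test_single_consensus_site(self, toy_pwm):
        # eT = 0 retains only the consensus placement
        assert predict_occupancy("AG", OccupancyModel(toy_pwm, tau=1.0, eT=0.0)) == pytest.approx(0.5)
        assert predict_occupancy("AG", OccupancyModel(toy_pwm, tau=3.0, eT=0.0)) == pytest.approx(0.75)

    def test_no_site_passes_threshold(self, toy_pwm):
        assert predict_occupancy("CC", OccupancyModel(toy_pwm, tau=1.0, eT=0.5)) == 0.0

    def test_matches_configuration_enumeration_oracle(self, sharp_pwm):
        """Independent-site occupancy equals the expected bound count from
        exhaustive 2^n enumeration of bound/unbound configurations."""
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for tau in (0.1, 1.0, 10.0):
            for trial in range(5):
                # length 13 gives 2 * (13 - 8 + 1) = 12 candidate sites
                seq = "".join(bases[rng.integers(0, 4, size=13)])
                model = OccupancyModel(sharp_pwm, tau=tau, eT=float("inf"))
                hits = scan_sites(seq, sharp_pwm)
                Ks = [h.K for h in hits]
                assert len(Ks) <= 12
                expected = brute_force_expected_bound(Ks, tau)
                assert predict_occupancy(seq, model) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.text(alphabet="ACGTN", min_size=8, max_size=40), st.floats(0.01, 50.0))
    def test_strand_symmetry(self, sharp_pwm, seq, tau):
        model = OccupancyModel(sharp_pwm, tau=tau, eT=4.0)
        assert predict_occupancy(seq, model) == pytest.approx(
            predict_occupancy(reverse_complement(seq), model), abs=1e-9
        )

    def test_monotone_in_tau_and_eT(self, sharp_pwm):
        rng = np.random.default_rng(4)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=120)])
        taus = [0.01, 0.1, 1.0, 10.0, 100.0]
        occ = [predict_occupancy(seq, OccupancyModel(sharp_pwm, t, 4.0)) for t in taus]
        assert all(a <= b + 1e-12 for a, b in zip(occ, occ[1:]))
        eTs = [0.5, 1.0, 2.0, 4.0, 8.0]
        occ = [predict_occupancy(seq, OccupancyModel(sharp_pwm, 1.0, e)) for e in eTs]
        assert all(a <= b + 1e-12 for a, b in zip(occ, occ[1:]))

    def test_planted_signal_ordering(self, sharp_pwm):
        """Consensus site > 2-mismatch site > plain background, every tau."""
        rng = np.random.default_rng(6)
        consensus = sharp_pwm.consensus()
        mismatched = list(consensus)
        for j in (0, 1):
            mismatched[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mismatched[j]]
        mismatched = "".join(mismatched)
        bases = np.array(list("ACGT"))
        from tfimpact.stap import consensus_llr, scan_sites as _scan

        llr_max = consensus_llr(sharp_pwm)
        accepted = 0
        while accepted < 20:
            bg = "".join(bases[rng.integers(0, 4, size=100)])
            # planting replaces bases 40..47; a chance background site
            # overlapping that stretch would confound the comparison
            w = sharp_pwm.width
            overlap = [
                h.llr for h in _scan(bg, sharp_pwm)
                if 40 - w < h.offset < 40 + w
            ]
            if max(overlap) > llr_max - 7.0:
                continue
            accepted += 1
            planted = bg[:40] + consensus + bg[40 + len(consensus):]
            weak = bg[:40] + mismatched + bg[40 + len(consensus):]
            for tau in (0.01, 1.0, 100.0):
                model = OccupancyModel(sharp_pwm, tau, eT=8.0)
                o_c = predict_occupancy(planted, model)
                o_m = predict_occupancy(weak, model)
                o_b = predict_occupancy(bg, model)
                assert o_c > o_m > o_b


class TestFitStap:
    def test_recovers_planted_signal(self, sharp_pwm, chip_windows):
        train, test = chip_windows
        model = fit_stap(train, sharp_pwm, seed=0)
        pred = [model.occupancy(w.sequence) for w in test]
        y = [w.chip_signal for w in test]
        assert np.corrcoef(pred, y)[0, 1] >= 0.9

    def test_null_signal_gives_no_correlation(self, sharp_pwm):
        """Chip signal independent of sequence: held-out CC hovers near 0."""
        ccs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            windows, _ = gen_chip_windows(
                sharp_pwm, n_pos=30, n_neg=30, noise_sd=0.05, seed=200 + seed,
                window_length=200,
            )
            for w in windows:
                w.chip_signal = rng.normal()
            model = fit_stap(windows, sharp_pwm, seed=seed)
            held, _ = gen_chip_windows(
                sharp_pwm, n_pos=15, n_neg=15, noise_sd=0.05, seed=300 + seed,
                window_length=200,
            )
            pred = [model.occupancy(w.sequence) for w in held]
            y = rng.normal(size=len(held))
            ccs.append(np.corrcoef(pred, y)[0, 1])
        assert abs(float(np.mean(ccs))) <= 0.2

    def test_too_few_windows_rejected(self, sharp_pwm):
        windows = [LabeledWindow("ACGT" * 30, float(i)) for i in range(5)]
        with pytest.raises(ValueError):
            fit_stap(windows, sharp_pwm)

    def test_constant_signal_rejected(self, sharp_pwm):
        windows = [LabeledWindow("ACGT" * 30, 1.0) for _ in range(30)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_stap(windows, sharp_pwm)

    def test_deterministic_under_seed(self, sharp_pwm, chip_windows):
        train, _ = chip_windows
        m1 = fit_stap(train, sharp_pwm, seed=3)
        m2 = fit_stap(train, sharp_pwm, seed=3)
        assert (m1.tau, m1.eT) == (m2.tau, m2.eT)


class TestCalibration:
    def test_reference_linear_map(self):
        cal = LinearCalibration.from_reference([2.0, 4.0, 6.0])
        assert cal(4.0) == pytest.approx(0.5)
        assert cal(2.0) == pytest.approx(0.0)
        assert cal(6.0) == pytest.approx(1.0)
        # no clipping beyond the reference range
        assert cal(8.0) == pytest.approx(1.5)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            LinearCalibration.from_reference([3.0, 3.0, 3.0])

    def test_predict_stap_score_applies_map(self, toy_pwm):
        model = OccupancyModel(toy_pwm, tau=1.0, eT=0.0)
        cal = LinearCalibration.from_reference([0.0, 1.0])
        assert predict_stap_score("AG", model, cal) == pytest.approx(0.5)

    def test_calibrated_stap_round_trips_json(self, sharp_pwm, chip_windows):
        train, _ = chip_windows
        cs = CalibratedStap.train(train[:60], sharp_pwm, seed=0)
        back = CalibratedStap.from_dict(cs.to_dict())
        seq = train[0].sequence
        assert back.score(seq) == cs.score(seq)
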