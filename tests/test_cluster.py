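"""Cluster geometry, per-scan matching, and elution-profile extension."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from proteo18.chem import C13_MASS_SHIFT, O18_MASS_SHIFT
from proteo18.cluster import (
    LabelState,
    collect_observations,
    detect_charge,
    match_channels,
    predict_cluster,
    restrict_scan_range,
    sum_observed_vector,
)

D = O18_MASS_SHIFT
C = C13_MASS_SHIFT


class TestPredictCluster:
    def test_modified_form_anchors_heavy_monoisotope(self):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        assert cl.mz_channels[0] == pytest.approx(500.0 - D, abs=1e-5)
        assert cl.mz_channels[0] == pytest.approx(497.995755, abs=1e-5)
        assert cl.mz_channels[2] == pytest.approx(498.997877, abs=1e-5)
        assert cl.mz_channels[4] == pytest.approx(500.0, abs=1e-12)

    def test_unmodified_form_anchors_natural_monoisotope(self):
        cl = predict_cluster(500.0, 2, LabelState.UNMODIFIED)
        assert cl.mz_channels[0] == pytest.approx(500.0, abs=1e-12)
        assert cl.mz_channels[4] == pytest.approx(500.0 + D, abs=1e-5)
        assert cl.mz_channels[4] == pytest.approx(502.004245, abs=1e-5)

    def test_modified_unmodified_symmetry(self):
        a = predict_cluster(500.0, 2, LabelState.MODIFIED)
        b = predict_cluster(500.0 - D, 2, LabelState.UNMODIFIED)
        assert np.allclose(a.mz_channels, b.mz_channels, atol=1e-9)

    @given(
        mz=st.floats(200.0, 2000.0),
        z=st.integers(1, 5),
        state=st.sampled_from(list(LabelState)),
    )
    def test_channel_spacing_invariants(self, mz, z, state):
        cl = predict_cluster(mz, z, state)
        ch = cl.mz_channels
        assert all(b > a for a, b in zip(ch, ch[1:]))
        assert ch[1] - ch[0] == pytest.approx(C / z, abs=1e-9)
        assert ch[2] - ch[0] == pytest.approx(D / z, abs=1e-9)
        assert ch[4] - ch[2] == pytest.approx(D / z, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            predict_cluster(500.0, 0, LabelState.MODIFIED)
        with pytest.raises(ValueError):
            predict_cluster(-1.0, 2, LabelState.MODIFIED)


class TestMatchChannels:
    def test_exact_peak_matches_first_channel(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        scan = make_scan(1, [(cl.mz_channels[0], 123.0)])
        obs = match_channels(scan, cl, tol_ppm=10)
        assert obs.a[0] == 123.0 and not np.any(obs.a[1:])
        assert obs.matched[0] and not np.any(obs.matched[1:])

    def test_peak_outside_tolerance_unmatched(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        mz = cl.mz_channels[0] * (1 + 25e-6)
        obs = match_channels(make_scan(1, [(mz, 10.0)]), cl, tol_ppm=10)
        assert not np.any(obs.a)

    def test_tie_break_most_intense_matches_brute_force(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        target = cl.mz_channels[0]
        peaks = [(target * (1 - 6e-6), 40.0), (target * (1 + 8e-6), 70.0)]
        scan = make_scan(1, peaks)
        obs = match_channels(scan, cl, tol_ppm=10)
        # brute-force: scan every peak, keep the most intense within tolerance
        brute = max(
            (i for mz, i in peaks if abs(mz - target) <= target * 10e-6),
            default=0.0,
        )
        assert obs.a[0] == brute == 70.0

    def test_nearest_mode_prefers_closer_peak(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        target = cl.mz_channels[0]
        scan = make_scan(1, [(target * (1 - 2e-6), 40.0), (target * (1 + 8e-6), 70.0)])
        obs = match_channels(scan, cl, tol_ppm=10, mode="nearest")
        assert obs.a[0] == 40.0


class TestDetectCharge:
    def test_monoisotope_with_partner_is_evidence(self, make_scan):
        scan = make_scan(1, [(500.0, 100.0), (500.0 + C / 2, 30.0)])
        assert detect_charge(scan, 500.0, 2, tol_ppm=10)

    def test_missing_partner_is_no_evidence(self, make_scan):
        scan = make_scan(1, [(500.0, 100.0)])
        assert not detect_charge(scan, 500.0, 2, tol_ppm=10)

    def test_partner_below_min_fraction_rejected(self, make_scan):
        scan = make_scan(1, [(500.0, 100.0), (500.0 + C / 2, 1e-4)])
        assert not detect_charge(scan, 500.0, 2, tol_ppm=10, min_fraction=0.01)


def _signal_scan(make_scan, n, cl, intensity=1000.0):
    """Scan carrying charge evidence on both the 16O and 18O2 channels."""
    ch = cl.mz_channels
    return make_scan(
        n,
        [(ch[0], intensity), (ch[1], 0.4 * intensity), (ch[4], intensity), (ch[5], 0.4 * intensity)],
    )


class TestCollectObservations:
    def test_recovers_full_elution_window(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        run = [
            _signal_scan(make_scan, n, cl) if 10 <= n <= 20 else make_scan(n, [(400.0, 5.0)])
            for n in range(1, 26)
        ]
        obs = collect_observations(run, 15, cl, tol_ppm=10)
        assert [o.scan_number for o in obs] == list(range(10, 21))

    def test_single_evidenced_scan(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        run = [
            _signal_scan(make_scan, n, cl) if n == 15 else make_scan(n, [(400.0, 5.0)])
            for n in range(1, 26)
        ]
        obs = collect_observations(run, 15, cl, tol_ppm=10)
        assert [o.scan_number for o in obs] == [15]

    def test_id_scan_without_evidence_still_retained(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        run = [make_scan(n, [(400.0, 5.0)]) for n in range(1, 6)]
        obs = collect_observations(run, 3, cl, tol_ppm=10)
        assert [o.scan_number for o in obs] == [3]
        assert not obs[0].charge_evidence_16O and not obs[0].charge_evidence_18O2

    def test_ms2_scans_skipped_not_treated_as_gaps(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        run = []
        for n in range(1, 12):
            if n % 2 == 0:
                run.append(make_scan(n, [(600.0, 10.0)], ms_level=2))
            elif 3 <= n <= 9:
                run.append(_signal_scan(make_scan, n, cl))
            else:
                run.append(make_scan(n, [(400.0, 5.0)]))
        obs = collect_observations(run, 5, cl, tol_ppm=10)
        assert [o.scan_number for o in obs] == [3, 5, 7, 9]

    def test_unknown_id_scan_raises(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        run = [make_scan(1, [(400.0, 5.0)])]
        with pytest.raises(KeyError):
            collect_observations(run, 99, cl, tol_ppm=10)


class TestObservedVector:
    def _obs(self, make_scan, cl, scans):
        return [
            match_channels(_signal_scan(make_scan, n, cl, intensity=i), cl, 10)
            for n, i in scans
        ]

    def test_sum_by_hand(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        obs = self._obs(make_scan, cl, [(1, 1.0), (2, 10.0)])
        y = sum_observed_vector(obs)
        assert y.y[0] == 11.0 and y.y[4] == 11.0
        assert y.n_scans == 2 and y.scan_range == (1, 2)

    def test_single_scan_identity_and_permutation(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        obs = self._obs(make_scan, cl, [(1, 3.0), (2, 5.0), (3, 7.0)])
        assert sum_observed_vector([obs[0]]).y == tuple(obs[0].a)
        assert sum_observed_vector(obs).y == sum_observed_vector(obs[::-1]).y

    def test_additive_under_concatenation(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        obs = self._obs(make_scan, cl, [(n, float(n)) for n in range(1, 8)])
        whole = np.array(sum_observed_vector(obs).y)
        parts = np.array(sum_observed_vector(obs[:3]).y) + np.array(
            sum_observed_vector(obs[3:]).y
        )
        assert np.array_equal(whole, parts)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sum_observed_vector([])


class TestRestrictScanRange:
    def _obs11(self, make_scan):
        cl = predict_cluster(500.0, 2, LabelState.MODIFIED)
        return [
            match_channels(_signal_scan(make_scan, n, cl), cl, 10)
            for n in range(1, 12)
        ]

    def test_keep_last_four_scans(self, make_scan):
        obs = self._obs11(make_scan)
        kept = restrict_scan_range(obs, 8, 11)
        assert [o.scan_number for o in kept] == [8, 9, 10, 11]

    def test_full_range_is_identity(self, make_scan):
        obs = self._obs11(make_scan)
        assert restrict_scan_range(obs, 1, 11) == obs

    def test_disjoint_range_errors_naming_range(self, make_scan):
        obs = self._obs11(make_scan)
        with pytest.raises(ValueError, match=r"\[50, 60\]"):
            restrict_scan_range(obs, 50, 60)
        with pytest.raises(ValueError):
            restrict_scan_range(obs, 9, 3)
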