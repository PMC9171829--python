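"""The four consensus methods against hand computations and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speccons import (
    ConsensusParams,
    ContractError,
    Peak,
    SimConfig,
    UnidentifiedClusterError,
    PSM,
    consensus_average,
    consensus_best,
    consensus_bin,
    consensus_most,
    consensus_precursor,
    generate_consensus,
    make_dataset,
    merge_close_peaks,
    spectrum_dot_product,
)
from speccons.consensus import PrecursorChargeWarning

from conftest import spectrum

PARAMS = ConsensusParams()


def brute_force_medoid(members, params=PARAMS):
    """Independent MOST oracle: full pairwise similarity matrix, then argmax
    of row sums minus the diagonal; ties to the smallest spectrum id."""
    n = len(members)
    sims = np.zeros((n, n))
    for i, j in itertools.product(range(n), repeat=2):
        sims[i, j] = spectrum_dot_product(members[i], members[j], params)
    sums = sims.sum(axis=1) - np.diag(sims)
    best = sums.max()
    candidates = [i for i in range(n) if np.isclose(sums[i], best, atol=1e-12, rtol=0)]
    return min(candidates, key=lambda i: members[i].spectrum_id)


def scan_best_oracle(members, psms, direction="higher"):
    """Independent BEST oracle: linear scan for the extremum score."""
    chosen = None
    for i, member in enumerate(members):
        psm = psms.get(member.spectrum_id)
        if psm is None:
            continue
        if chosen is None:
            chosen = i
            continue
        held = psms[members[chosen].spectrum_id].score
        if (direction == "higher" and psm.score > held) or (
            direction == "lower" and psm.score < held
        ):
            chosen = i
    return chosen


class TestMergeClosePeaks:
    def test_weighted_mean_and_mean_intensity(self):
        merged = merge_close_peaks([Peak(100.00, 1.0), Peak(100.01, 3.0)], 0.02)
        assert merged == [pytest.approx((100.0075, 2.0), abs=1e-9)]

    def test_peaks_beyond_tolerance_unchanged(self):
        peaks = [Peak(100.00, 1.0), Peak(100.05, 1.0)]
        assert merge_close_peaks(peaks, 0.02) == peaks

    def test_zero_tolerance_is_identity_on_distinct_mz(self):
        peaks = [Peak(100.0, 1.0), Peak(100.0001, 2.0), Peak(200.0, 3.0)]
        assert merge_close_peaks(peaks, 0.0) == peaks

    def test_unsorted_input_rejected(self):
        with pytest.raises(ContractError, match="sorted"):
            merge_close_peaks([Peak(200.0, 1.0), Peak(100.0, 1.0)], 0.02)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(100.0, 1000.0),
                st.floats(0.0, 1e6),
            ),
            min_size=1,
            max_size=30,
        ),
        st.floats(0.0, 1.0),
    )
    def test_merged_peaks_stay_within_group_bounds(self, pairs, tolerance):
        peaks = [Peak(m, i) for m, i in sorted(pairs)]
        merged = merge_close_peaks(peaks, tolerance)
        assert len(merged) <= len(peaks)
        lo_mz, hi_mz = min(p.mz for p in peaks), max(p.mz for p in peaks)
        lo_i, hi_i = min(p.intensity for p in peaks), max(p.intensity for p in peaks)
        total = 1e-9 * max(1.0, hi_mz)
        for peak in merged:
            assert lo_mz - total <= peak.mz <= hi_mz + total
            assert lo_i - 1e-9 <= peak.intensity <= hi_i + 1e-9
        assert [p.mz for p in merged] == sorted(p.mz for p in merged)


class TestAverage:
    def test_singleton_identity(self):
        member = spectrum("s1", [(100.0, 1.0), (150.0, 2.0)])
        assert consensus_average([member], PARAMS).peaks == member.peaks

    def test_two_single_peak_spectra(self):
        a = spectrum("a", [(100.00, 1.0)])
        b = spectrum("b", [(100.01, 3.0)])
        (peak,) = consensus_average([a, b], PARAMS).peaks
        assert peak == pytest.approx((100.0075, 2.0), abs=1e-9)

    def test_identical_copies_reproduce_spectrum(self):
        member = spectrum("s", [(100.0, 4.0), (100.5, 8.0), (200.0, 2.0)])
        copies = [spectrum(f"s{i}", [(100.0, 4.0), (100.5, 8.0), (200.0, 2.0)]) for i in range(5)]
        result = consensus_average(copies, PARAMS)
        assert np.allclose(result.mz, member.mz, atol=1e-9)
        assert np.allclose(result.intensity, member.intensity, atol=1e-9)

    def test_empty_members_rejected(self):
        with pytest.raises(ContractError):
            consensus_average([], PARAMS)


class TestBin:
    def test_occupancy_below_quarter_discarded(self):
        members = [spectrum(f"s{i}", [(200.0 + 0.001 * i, 10.0)]) for i in range(5)]
        members[0] = spectrum("s0", [(200.0, 10.0), (300.0, 99.0)])
        result = consensus_bin(members, PARAMS)
        assert result.n_peaks == 1
        assert 200.0 <= result.mz[0] < 200.02

    def test_unweighted_bin_means(self):
        members = [spectrum("a", [(100.004, 10.0)]), spectrum("b", [(100.012, 30.0)])]
        (peak,) = consensus_bin(members, PARAMS).peaks
        assert peak == pytest.approx((100.008, 20.0), abs=1e-9)

    def test_exact_quarter_occupancy_retained(self):
        members = [spectrum(f"s{i}", [(500.0 + 0.001 * i, 5.0)]) for i in range(4)]
        members[0] = spectrum("s0", [(500.0, 5.0), (700.0, 1.0)])
        result = consensus_bin(members, PARAMS)
        # occupancy 1/4 is not strictly below 0.25, so the 700 bin survives
        assert result.n_peaks == 2
        assert result.mz[-1] == pytest.approx(700.0)

    def test_member_denominator_downweights_sparse_bins(self):
        members = [spectrum(f"s{i}", [(500.0, 8.0)]) for i in range(4)]
        members[0] = spectrum("s0", [(500.0, 8.0), (700.0, 8.0)])
        result = consensus_bin(
            members, ConsensusParams(bin_intensity_denominator="members")
        )
        # main bin: 4*8/4 = 8; 1-of-4 bin: 8/4 = 2
        assert np.allclose(result.intensity, [8.0, 2.0], atol=1e-9)
        default = consensus_bin(members, PARAMS)
        assert np.allclose(default.intensity, [8.0, 8.0], atol=1e-9)

    def test_identical_copies_reproduce_spectrum(self):
        peaks = [(100.004, 4.0), (100.052, 8.0), (200.010, 2.0)]
        copies = [spectrum(f"s{i}", peaks) for i in range(4)]
        result = consensus_bin(copies, PARAMS)
        assert np.allclose(result.mz, [p[0] for p in peaks], atol=1e-9)
        assert np.allclose(result.intensity, [p[1] for p in peaks], atol=1e-9)

    def test_output_mz_inside_generating_bin(self, small_dataset):
        store = small_dataset.spectrum_index
        for cluster in small_dataset.clusters:
            members = [store[m] for m in cluster.member_ids]
            result = consensus_bin(members, PARAMS)
            idx = np.floor(result.mz / PARAMS.bin_width)
            member_bins = set()
            for m in members:
                member_bins.update(np.floor(m.mz / PARAMS.bin_width).astype(int))
            assert set(idx.astype(int)) <= member_bins

    def test_noise_peak_below_occupancy_never_survives(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            base = [(float(m), 100.0) for m in rng.uniform(100, 900, size=10)]
            members = [spectrum(f"s{i}", sorted(base)) for i in range(8)]
            noise_mz = 950.123
            noisy = sorted(base + [(noise_mz, 5.0)])
            members[0] = spectrum("s0", noisy)  # 1/8 < 0.25
            result = consensus_bin(members, PARAMS)
            assert not np.any(np.floor(result.mz / 0.02) == np.floor(noise_mz / 0.02))


class TestDotProduct:
    def test_identical_spectra_similarity_one(self):
        s = spectrum("s", [(100.0, 1.0), (200.0, 5.0)])
        assert spectrum_dot_product(s, s, PARAMS) == pytest.approx(1.0)

    def test_disjoint_spectra_similarity_zero(self):
        a = spectrum("a", [(100.0, 1.0)])
        b = spectrum("b", [(500.0, 1.0)])
        assert spectrum_dot_product(a, b, PARAMS) == 0.0

    def test_hand_computed_overlap(self):
        a = spectrum("a", [(100.00, 1.0)])
        b = spectrum("b", [(100.00, 1.0), (200.00, 1.0)])
        assert spectrum_dot_product(a, b, PARAMS) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_sqrt_transform_changes_weighting(self):
        a = spectrum("a", [(100.0, 1.0), (200.0, 4.0)])
        b = spectrum("b", [(100.0, 1.0)])
        plain = spectrum_dot_product(a, b, PARAMS)
        transformed = spectrum_dot_product(
            a, b, ConsensusParams(intensity_transform="sqrt")
        )
        assert plain == pytest.approx(1 / np.sqrt(17))
        assert transformed == pytest.approx(1 / np.sqrt(5))

    def test_all_zero_intensity_rejected(self):
        a = spectrum("a", [(100.0, 0.0)])
        with pytest.raises(ContractError, match="all-zero"):
            spectrum_dot_product(a, a, PARAMS)


class TestMost:
    def test_singleton_returns_member(self):
        member = spectrum("only", [(100.0, 1.0)])
        selected, idx = consensus_most([member], PARAMS)
        assert idx == 0 and selected is member

    def test_identical_members_tie_to_smallest_id(self):
        members = [spectrum(sid, [(100.0, 1.0)]) for sid in ("s3", "s1", "s2")]
        _, idx = consensus_most(members, PARAMS)
        assert members[idx].spectrum_id == "s1"

    def test_random_tie_break_is_seeded(self):
        members = [spectrum(sid, [(100.0, 1.0)]) for sid in ("s3", "s1", "s2")]
        params = ConsensusParams(tie_break="random", seed=11)
        picks = {consensus_most(members, params)[1] for _ in range(5)}
        assert len(picks) == 1

    def test_matches_brute_force_on_simulated_clusters(self, small_dataset):
        store = small_dataset.spectrum_index
        for cluster in small_dataset.clusters:
            members = [store[m] for m in cluster.member_ids]
            _, idx = consensus_most(members, PARAMS)
            assert idx == brute_force_medoid(members)


class TestBest:
    def _members_and_psms(self):
        members = [spectrum(f"s{i}", [(100.0 + i, 1.0)]) for i in (1, 2, 3)]
        psms = {
            "s1": PSM("s1", "PEPA", 5.0),
            "s2": PSM("s2", "PEPB", 9.0),
            "s3": PSM("s3", "PEPC", 7.0),
        }
        return members, psms

    def test_argmax_by_score(self):
        members, psms = self._members_and_psms()
        selected, idx = consensus_best(members, psms, PARAMS)
        assert selected.spectrum_id == "s2"

    def test_lower_is_better_direction(self):
        members, psms = self._members_and_psms()
        selected, _ = consensus_best(members, psms, ConsensusParams(score_direction="lower"))
        assert selected.spectrum_id == "s1"

    def test_single_identified_member_wins_regardless(self):
        members, psms = self._members_and_psms()
        only = {"s3": psms["s3"]}
        selected, _ = consensus_best(members, only, PARAMS)
        assert selected.spectrum_id == "s3"

    def test_fully_unidentified_cluster_raises(self):
        members, _ = self._members_and_psms()
        with pytest.raises(UnidentifiedClusterError):
            consensus_best(members, {}, PARAMS)


class TestPrecursor:
    def test_median_mz_and_modal_charge(self):
        members = [
            spectrum("a", [(100.0, 1.0)], precursor_mz=500.0, precursor_charge=2),
            spectrum("b", [(100.0, 1.0)], precursor_mz=500.2, precursor_charge=2),
            spectrum("c", [(100.0, 1.0)], precursor_mz=500.4, precursor_charge=3),
        ]
        with pytest.warns(PrecursorChargeWarning):
            mz, charge = consensus_precursor(members)
        assert mz == pytest.approx(500.2)
        assert charge == 2

    def test_charge_tie_goes_to_smaller(self):
        members = [
            spectrum("a", [(100.0, 1.0)], precursor_mz=500.0, precursor_charge=3),
            spectrum("b", [(100.0, 1.0)], precursor_mz=500.0, precursor_charge=2),
        ]
        with pytest.warns(PrecursorChargeWarning):
            _, charge = consensus_precursor(members)
        assert charge == 2

    def test_unknown_charge_propagates(self):
        members = [spectrum("a", [(100.0, 1.0)], precursor_mz=500.0)]
        mz, charge = consensus_precursor(members)
        assert mz == 500.0 and charge is None


class TestGenerateConsensus:
    def test_one_record_per_cluster(self, small_dataset):
        run = generate_consensus(
            small_dataset.clusters, small_dataset.spectrum_index, "bin", params=PARAMS
        )
        assert run.n_clusters_in == run.n_records_out == 10
        assert run.n_skipped == 0
        assert [r.cluster_id for r in run.records] == [
            c.cluster_id for c in small_dataset.clusters
        ]

    def test_best_skips_fully_unidentified_clusters(self, small_dataset):
        psms = dict(small_dataset.psms)
        dropped = small_dataset.clusters[3]
        for member in dropped.member_ids:
            del psms[member]
        run = generate_consensus(
            small_dataset.clusters, small_dataset.spectrum_index, "best", psms=psms
        )
        assert run.n_records_out == 9
        assert run.n_skipped == 1
        assert dropped.cluster_id not in {r.cluster_id for r in run.records}

    def test_member_selecting_methods_return_verbatim_member(self, small_dataset):
        store = small_dataset.spectrum_index
        for method in ("most", "best"):
            run = generate_consensus(
                small_dataset.clusters, store, method, psms=small_dataset.psms
            )
            for record in run.records:
                assert record.source_member_id in store
                assert record.spectrum is store[record.source_member_id]

    def test_unresolvable_member_names_cluster(self, small_dataset):
        store = dict(small_dataset.spectrum_index)
        victim = small_dataset.clusters[0].member_ids[0]
        del store[victim]
        with pytest.raises(ContractError, match=victim):
            generate_consensus(small_dataset.clusters, store, "average")

    def test_singleton_clusters_identity_for_all_methods(self):
        dataset = make_dataset(SimConfig(n_clusters=5, members_per_cluster=1, seed=9))
        store = dataset.spectrum_index
        for method in ("average", "bin", "most", "best"):
            run = generate_consensus(dataset.clusters, store, method, psms=dataset.psms)
            for record, cluster in zip(run.records, dataset.clusters):
                member = store[cluster.member_ids[0]]
                assert np.allclose(record.spectrum.mz, member.mz, atol=1e-9)
                assert np.allclose(record.spectrum.intensity, member.intensity, atol=1e-9)
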