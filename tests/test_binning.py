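import numpy as np
import pandas as pd
import pytest

from cnarec.binning import (
    assign_to_bins, bin_scheme_from_cohort, build_bin_scheme, frequency_profile,
    harmonize, mean_alteration_size, read_bin_matrix, write_bin_matrix,
)
from cnarec.genome import GenomeBuild, GenomicInterval, hg19
from cnarec.segments import GAIN, LOSS, NOREC, REC, CNASegment, Cohort, PatientRecord

from conftest import random_cohort


def brute_force_matrix(cohort, scheme, min_overlap_fraction=0.0):
    """Independent O(segments x bins) oracle for assign_to_bins."""
    values = {}
    for pid in cohort.patient_ids:
        row = []
        for b in scheme.bins:
            gain = sum(
                s.interval.overlap_bp(b.interval)
                for s in cohort.segments
                if s.patient_id == pid and s.call == GAIN
            )
            loss = sum(
                s.interval.overlap_bp(b.interval)
                for s in cohort.segments
                if s.patient_id == pid and s.call == LOSS
            )
            thr = min_overlap_fraction * b.width
            gain = gain if gain > thr else 0
            loss = loss if loss > thr else 0
            if gain > loss:
                row.append(1)
            elif loss > gain:
                row.append(-1)
            elif gain > 0:
                row.append(1)
            else:
                row.append(0)
        values[pid] = row
    return pd.DataFrame.from_dict(values, orient="index", columns=scheme.names).loc[
        cohort.patient_ids
    ]


class TestMeanAlterationSize:
    def test_arithmetic_mean(self, tiny_build):
        cohort = Cohort(
            build=tiny_build,
            patients=[PatientRecord("A")],
            segments=[
                CNASegment("A", GenomicInterval("1", 0, 10), GAIN),
                CNASegment("A", GenomicInterval("1", 20, 40), LOSS),
                CNASegment("A", GenomicInterval("1", 50, 80), GAIN),
            ],
        )
        assert mean_alteration_size(cohort)["1"] == 20

    def test_half_rounds_up(self, tiny_build):
        cohort = Cohort(
            build=tiny_build,
            patients=[PatientRecord("A")],
            segments=[
                CNASegment("A", GenomicInterval("1", 0, 3), GAIN),
                CNASegment("A", GenomicInterval("1", 10, 14), LOSS),
            ],
        )
        assert mean_alteration_size(cohort)["1"] == 4  # mean 3.5 -> 4

    def test_chromosome_without_segments_falls_back_to_whole(self, tiny_build):
        cohort = Cohort(
            build=tiny_build,
            patients=[PatientRecord("A")],
            segments=[CNASegment("A", GenomicInterval("1", 0, 7), GAIN)],
        )
        sizes = mean_alteration_size(cohort)
        assert sizes == {"1": 7, "2": 100}

    def test_empty_cohort_is_error(self, tiny_build):
        with pytest.raises(ValueError):
            mean_alteration_size(Cohort(build=tiny_build))


class TestBinScheme:
    @pytest.mark.parametrize("L,w,n_bins,last_len", [(100, 40, 3, 20), (100, 100, 1, 100)])
    def test_ceiling_tiling(self, L, w, n_bins, last_len):
        build = GenomeBuild(name="t", chromosomes=(("1", L),))
        scheme = build_bin_scheme(build, {"1": w})
        assert scheme.n_bins == n_bins
        assert scheme.bins[-1].width == last_len

    def test_hg19_chr17_two_megabase_bins(self):
        scheme = build_bin_scheme(hg19(), {c: 2_000_000 for c, _ in hg19().chromosomes})
        chr17 = scheme.chrom_bins("17")
        assert len(chr17) == 41
        assert chr17[-1].width == 1_195_210

    def test_tiling_invariant_sums_to_chromosome_length(self, tiny_build):
        scheme = build_bin_scheme(tiny_build, {"1": 33, "2": 7})
        for chrom, length in tiny_build.chromosomes:
            bins = scheme.chrom_bins(chrom)
            assert sum(b.width for b in bins) == length
            for a, b in zip(bins, bins[1:]):
                assert a.interval.end == b.interval.start

    def test_bed_export(self, tiny_build, tmp_path):
        scheme = build_bin_scheme(tiny_build, {"1": 100, "2": 50})
        scheme.to_bed(tmp_path / "scheme.bed")
        lines = (tmp_path / "scheme.bed").read_text().splitlines()
        assert lines[0].split("\t")[:3] == ["1", "0", "100"]
        assert len(lines) == scheme.n_bins


class TestAssignToBins:
    def test_gain_equal_to_bin(self, tiny_build):
        scheme = build_bin_scheme(tiny_build, {"1": 100, "2": 50})
        cohort = Cohort(
            build=tiny_build,
            patients=[PatientRecord("A"), PatientRecord("B")],
            segments=[CNASegment("A", GenomicInterval("1", 0, 100), GAIN)],
        )
        m = assign_to_bins(cohort, scheme)
        assert m.loc["A", "1:0-100"] == 1
        assert m.loc["A"].drop("1:0-100").eq(0).all()
        assert m.loc["B"].eq(0).all()  # patient without segments: all-zero row

    def test_dominant_overlap_wins(self, tiny_build):
        scheme = build_bin_scheme(tiny_build, {"1": 100, "2": 50})
        cohort = Cohort(
            build=tiny_build,
            patients=[PatientRecord("A")],
            segments=[
                CNASegment("A", GenomicInterval("1", 0, 60), GAIN),   # 60% of bin
                CNASegment("A", GenomicInterval("1", 60, 90), LOSS),  # 30% of bin
            ],
        )
        assert assign_to_bins(cohort, scheme).loc["A", "1:0-100"] == 1

    def test_exact_tie_is_gain(self, tiny_build):
        scheme = build_bin_scheme(tiny_build, {"1": 100, "2": 50})
        cohort = Cohort(
            build=tiny_build,
            patients=[PatientRecord("A")],
            segments=[
                CNASegment("A", GenomicInterval("1", 0, 40), GAIN),
                CNASegment("A", GenomicInterval("1", 40, 80), LOSS),
            ],
        )
        assert assign_to_bins(cohort, scheme).loc["A", "1:0-100"] == 1

    def test_matches_brute_force_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(20240917)
        for _ in range(25):
            cohort = random_cohort(rng, n_patients=int(rng.integers(1, 8)))
            scheme = build_bin_scheme(
                cohort.build, {"1": int(rng.integers(10, 120)), "2": int(rng.integers(10, 60))}
            )
            frac = float(rng.choice([0.0, 0.1, 0.5]))
            fast = assign_to_bins(cohort, scheme, frac)
            oracle = brute_force_matrix(cohort, scheme, frac)
            pd.testing.assert_frame_equal(fast, oracle, check_dtype=False, check_names=False)

    def test_min_overlap_monotone(self):
        rng = np.random.default_rng(7)
        cohort = random_cohort(rng, n_patients=6)
        scheme = build_bin_scheme(cohort.build, {"1": 37, "2": 23})
        prev = assign_to_bins(cohort, scheme, 0.0)
        for frac in (0.2, 0.5, 0.9):
            cur = assign_to_bins(cohort, scheme, frac)
            # entries that were zero stay zero as the threshold rises
            assert not ((prev.values == 0) & (cur.values != 0)).any()
            prev = cur

    def test_build_mismatch_rejected(self, tiny_build, tiny_cohort):
        other = GenomeBuild(name="other", chromosomes=(("1", 300),))
        scheme = build_bin_scheme(other, {"1": 100})
        with pytest.raises(ValueError, match="build"):
            assign_to_bins(tiny_cohort, scheme)


class TestFrequencyProfile:
    def test_counts_and_bounds(self):
        m = pd.DataFrame({"b1": [1, 1, -1, 0], "b2": [0, 0, 0, 0], "b3": [1, 1, 1, 1]},
                         index=list("wxyz"))
        prof = frequency_profile(m)
        assert prof.loc["b1", "gain_fraction"] == 0.5
        assert prof.loc["b1", "loss_fraction"] == 0.25
        assert prof.loc["b2"].eq(0).all()
        assert prof.loc["b3", "gain_fraction"] == 1.0
        assert ((prof.sum(axis=1)) <= 1.0 + 1e-12).all()

    def test_fraction_times_n_is_integer(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(-1, 2, size=(7, 5)))
        prof = frequency_profile(m)
        counts = prof.values * 7
        assert np.allclose(counts, np.round(counts))

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError):
            frequency_profile(pd.DataFrame(columns=["b1"]))


class TestHarmonize:
    def test_identical_cohort_gives_identical_matrix(self, tiny_cohort):
        scheme = bin_scheme_from_cohort(tiny_cohort)
        ref = assign_to_bins(tiny_cohort, scheme)
        again = harmonize(tiny_cohort, scheme)
        pd.testing.assert_frame_equal(ref, again)

    def test_empty_second_cohort(self, tiny_build, tiny_cohort):
        scheme = bin_scheme_from_cohort(tiny_cohort)
        empty = Cohort(build=tiny_build)
        m = harmonize(empty, scheme)
        assert m.shape == (0, scheme.n_bins)
        assert list(m.columns) == scheme.names

    def test_build_mismatch_rejected(self, tiny_cohort):
        other = GenomeBuild(name="other", chromosomes=(("1", 300),))
        scheme = build_bin_scheme(other, {"1": 100})
        with pytest.raises(ValueError):
            harmonize(tiny_cohort, scheme)


def test_frequency_profile_plot_renders(tiny_cohort):
    import matplotlib

    matplotlib.use("Agg")
    from cnarec.binning import plot_frequency_profile

    scheme = bin_scheme_from_cohort(tiny_cohort)
    m = assign_to_bins(tiny_cohort, scheme)
    ax = plot_frequency_profile(frequency_profile(m), scheme)
    assert ax.get_ylabel() == "fraction of patients"


def test_bin_matrix_tsv_round_trip(tmp_path, tiny_cohort):
    scheme = bin_scheme_from_cohort(tiny_cohort)
    m = assign_to_bins(tiny_cohort, scheme)
    write_bin_matrix(m, tmp_path / "m.tsv")
    again = read_bin_matrix(tmp_path / "m.tsv")
    pd.testing.assert_frame_equal(m, again, check_dtype=False)
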