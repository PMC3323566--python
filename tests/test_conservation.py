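import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mondocons import (
    Alignment,
    CountVector,
    Grouping,
    JsParams,
    ThresholdSet,
    column_counts,
    conservation_profile,
    default_grouping,
    entropy_js_regression,
    functional_group_entropy,
    invariant_sites,
    js_score,
    js_threshold,
    logo_counts,
    occupancy_filter,
    segment_conserved_regions,
    shannon_entropy,
    windowed_js,
)
from mondocons.conservation import BLOSUM62_BACKGROUND, LOG2_20, ConfigError, count_matrix
from mondocons.seqio import AA20, AA_INDEX

from oracles import entropy_oracle, jsd_oracle, ols_oracle, windowed_oracle


def counts_of(**kw):
    counts = np.zeros(20, dtype=np.int64)
    for aa, n in kw.items():
        counts[AA_INDEX[aa]] = n
    return CountVector(counts=counts)


def random_alignment(rng, n_rows=12, n_cols=40, gap_rate=0.1):
    mat = rng.choice(list(AA20), size=(n_rows, n_cols))
    mat[rng.random((n_rows, n_cols)) < gap_rate] = "-"
    return Alignment(
        tuple(f"s{i}" for i in range(n_rows)),
        tuple("".join(row) for row in mat),
    )


count_vectors = st.builds(
    lambda pairs: CountVector(
        counts=np.asarray(
            [sum(v for j, v in pairs if j == i) for i in range(20)], dtype=np.int64
        )
    ),
    st.lists(st.tuples(st.integers(0, 19), st.integers(1, 30)), min_size=1, max_size=6),
)


class TestColumnCounts:
    def test_counts_exclude_gaps(self):
        aln = Alignment(("a", "b", "c", "d"), ("A", "A", "-", "A"))
        cv = column_counts(aln, 0)
        assert cv.counts[AA_INDEX["A"]] == 3 and cv.occupancy == 3

    def test_all_gap_column_has_zero_occupancy(self):
        aln = Alignment(("a", "b"), ("-K", "-R"))
        assert column_counts(aln, 0).occupancy == 0

    def test_unknowns_tallied_separately(self):
        aln = Alignment(("a", "b", "c"), ("X", "A", "A"))
        cv = column_counts(aln, 0)
        assert cv.occupancy == 2 and cv.n_unknown == 1

    def test_out_of_range_column(self):
        aln = Alignment(("a", "b"), ("MK", "ML"))
        with pytest.raises(IndexError):
            column_counts(aln, 2)

    def test_occupancy_mass_conservation(self, rng):
        aln = random_alignment(rng)
        total = sum(column_counts(aln, c).occupancy for c in range(aln.length))
        expected = sum(len(r) - r.count("-") for r in aln.rows)
        assert total == expected


class TestEntropies:
    @pytest.mark.parametrize(
        "cv,expected",
        [
            (CountVector(counts=np.ones(20, dtype=np.int64)), LOG2_20),
            (counts_of(W=12), 0.0),
            (counts_of(A=2, D=2), 1.0),
        ],
    )
    def test_shannon_entropy_worked_examples(self, cv, expected):
        assert shannon_entropy(cv) == pytest.approx(expected, abs=1e-12)

    def test_empty_column_is_nan(self):
        assert np.isnan(shannon_entropy(CountVector(counts=np.zeros(20, dtype=np.int64))))

    @pytest.mark.parametrize(
        "cv,expected",
        [
            (counts_of(I=3, V=3, L=3, M=3), 0.0),  # co-grouped hydrophobics
            (counts_of(D=2, E=2), 0.0),            # co-grouped acidics
            (counts_of(D=2, K=2), 1.0),            # acidic vs basic
        ],
    )
    def test_functional_group_entropy_worked_examples(self, cv, expected):
        assert functional_group_entropy(cv) == pytest.approx(expected, abs=1e-12)

    @given(count_vectors)
    def test_group_entropy_never_exceeds_residue_entropy(self, cv):
        assert functional_group_entropy(cv) <= shannon_entropy(cv) + 1e-12
        assert shannon_entropy(cv) <= LOG2_20 + 1e-12

    def test_shannon_matches_direct_formula(self, rng):
        from conftest import random_counts

        for _ in range(200):
            counts = random_counts(rng)
            cv = CountVector(counts=counts)
            assert shannon_entropy(cv) == pytest.approx(entropy_oracle(counts), abs=1e-12)

    def test_grouping_from_file_round_trip(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("hydro: AVLIMFWYC\npolar: STNQG\ncharged: DEHKRP\n")
        g = Grouping.from_file(p)
        assert g.k == 3
        assert functional_group_entropy(counts_of(A=1, C=1), g) == 0.0

    def test_grouping_must_partition_alphabet(self):
        with pytest.raises(ConfigError):
            Grouping.from_dict({"a": "ACDE", "b": "FGHIK"})


class TestJsScore:
    def test_background_column_scores_zero_without_pseudocount(self):
        counts = (BLOSUM62_BACKGROUND * 1000).round().astype(np.int64)
        bg = counts / counts.sum()
        params = JsParams(background=bg, pseudocount=0.0)
        assert js_score(CountVector(counts=counts), params) == pytest.approx(0.0, abs=1e-12)

    def test_single_residue_column_matches_formula_oracle(self):
        params = JsParams(pseudocount=0.0)
        cv = counts_of(W=25)
        p = np.zeros(20)
        p[AA_INDEX["W"]] = 1.0
        assert js_score(cv, params) == pytest.approx(
            jsd_oracle(p, BLOSUM62_BACKGROUND), abs=1e-10
        )

    def test_random_columns_match_oracle_and_stay_bounded(self, rng):
        from conftest import random_counts

        params = JsParams()
        for _ in range(300):
            counts = random_counts(rng)
            got = js_score(CountVector(counts=counts), params)
            p = counts / counts.sum() + params.pseudocount
            p = p / p.sum()
            assert got == pytest.approx(jsd_oracle(p, params.background), abs=1e-10)
            assert 0.0 <= got <= 1.0

    def test_invalid_background_rejected(self):
        with pytest.raises(ConfigError):
            JsParams(background=np.ones(20))


class TestWindowedJs:
    def test_weight_zero_equals_raw(self, rng):
        aln = random_alignment(rng, n_rows=14, n_cols=30, gap_rate=0.05)
        profile = windowed_js(aln, JsParams(weight=0.0), ThresholdSet(min_occupancy=1))
        np.testing.assert_allclose(profile.JS, profile.JS_raw)

    def test_window_zero_equals_raw_regardless_of_weight(self, rng):
        aln = random_alignment(rng, n_rows=14, n_cols=30, gap_rate=0.05)
        profile = windowed_js(aln, JsParams(window=0, weight=0.7), ThresholdSet(min_occupancy=1))
        np.testing.assert_allclose(profile.JS, profile.JS_raw)

    def test_constant_raw_profile_stays_constant(self):
        rows = tuple("WWWWWWWWWW" for _ in range(12))
        aln = Alignment(tuple(f"s{i}" for i in range(12)), rows)
        profile = windowed_js(aln, JsParams(), ThresholdSet(min_occupancy=10))
        np.testing.assert_allclose(profile.JS, profile.JS_raw)

    def test_matches_brute_force_window_oracle(self, rng):
        aln = random_alignment(rng, n_rows=16, n_cols=120, gap_rate=0.3)
        params = JsParams(window=3, weight=0.5)
        thr = ThresholdSet(min_occupancy=12)  # some columns excluded
        profile = windowed_js(aln, params, thr)
        expected = windowed_oracle(profile.JS_raw, profile.included, 3, 0.5)
        np.testing.assert_allclose(profile.JS, expected, equal_nan=True, atol=1e-12)


class TestFiltersAndDetection:
    def test_occupancy_filter_is_strict(self):
        rows_9 = tuple("A" for _ in range(9)) + tuple("-" for _ in range(5))
        rows_10 = tuple("A" for _ in range(10)) + tuple("-" for _ in range(4))
        for rows, expect in ((rows_9, False), (rows_10, True)):
            aln = Alignment(tuple(f"s{i}" for i in range(14)), rows)
            profile = windowed_js(aln)
            profile = occupancy_filter(profile, ThresholdSet(min_occupancy=10))
            assert bool(profile.included[0]) is expect

    def test_min_occupancy_one_keeps_all_nonempty(self, rng):
        aln = random_alignment(rng, gap_rate=0.4)
        profile = occupancy_filter(windowed_js(aln), ThresholdSet(min_occupancy=1))
        np.testing.assert_array_equal(profile.included, profile.occupancy >= 1)

    def test_invariant_sites_on_small_alignment(self):
        rows = tuple("WA" + ("R" if i == 0 else "W") for i in range(34))
        aln = Alignment(tuple(f"s{i}" for i in range(34)), rows)
        # col 0: 34 W's -> invariant; col 1: A's -> invariant; col 2: 33 W + 1 R -> not
        assert invariant_sites(aln) == [0, 1]

    def test_invariant_sites_recover_planted_truth(self, default_family):
        aln, truth = default_family
        assert set(invariant_sites(aln)) == truth.invariant_columns

    def test_invariants_subset_of_zero_group_entropy(self, default_family):
        aln, _ = default_family
        profile = conservation_profile(aln)
        inv = set(invariant_sites(aln))
        hfg_zero = {int(c) for c in np.flatnonzero(profile.included & (profile.H_FG == 0.0))}
        hfg_low = {int(c) for c in np.flatnonzero(profile.included & (profile.H_FG < 0.1))}
        assert inv <= hfg_zero <= hfg_low


class TestJsThreshold:
    def test_nearest_rank_definition(self):
        profile = _profile_with_js(np.arange(1.0, 101.0) / 100.0)
        assert js_threshold(profile, 0.90) == pytest.approx(0.90)

    def test_all_equal_threshold_has_nothing_strictly_above(self):
        profile = _profile_with_js(np.full(50, 0.4))
        thr = js_threshold(profile, 0.90)
        assert thr == pytest.approx(0.4)
        assert np.sum(profile.JS > thr) == 0

    def test_fraction_above_bounded(self, rng):
        for _ in range(20):
            vals = rng.random(rng.integers(10, 200))
            profile = _profile_with_js(vals)
            thr = js_threshold(profile, 0.90)
            assert np.mean(vals > thr) <= 0.10 + 1.0 / len(vals)

    def test_empty_profile_errors(self):
        profile = _profile_with_js(np.array([]))
        with pytest.raises(ValueError):
            js_threshold(profile, 0.90)


def _profile_with_js(js):
    from mondocons.conservation import ConservationProfile

    n = len(js)
    return ConservationProfile(
        occupancy=np.full(n, 20, dtype=int),
        H=np.linspace(0, 4, n) if n else np.array([]),
        H_FG=np.zeros(n),
        JS_raw=np.asarray(js, dtype=float),
        JS=np.asarray(js, dtype=float),
        included=np.ones(n, dtype=bool),
    )


class TestRegression:
    def test_exact_line_recovered(self):
        h = np.linspace(0.0, 4.0, 30)
        profile = _profile_with_js(0.9 - 0.1 * h)
        profile.H[:] = h
        fit = entropy_js_regression(profile)
        assert fit.intercept == pytest.approx(0.9, abs=1e-12)
        assert fit.slope == pytest.approx(-0.1, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_gives_zero_slope(self):
        profile = _profile_with_js(np.full(20, 0.5))
        profile.H[:] = np.linspace(0, 4, 20)
        fit = entropy_js_regression(profile)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        h = rng.random(200) * 4
        js = 0.8 - 0.15 * h + rng.normal(0, 0.05, 200)
        profile = _profile_with_js(js)
        profile.H[:] = h
        fit = entropy_js_regression(profile)
        b0, b1, r2 = ols_oracle(h, js)
        assert fit.intercept == pytest.approx(b0, abs=1e-10)
        assert fit.slope == pytest.approx(b1, abs=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_predictor_errors(self):
        profile = _profile_with_js(np.linspace(0, 1, 10))
        profile.H[:] = 2.0
        with pytest.raises(ValueError, match="variance"):
            entropy_js_regression(profile)


class TestSegmentation:
    def test_single_block_above_threshold(self):
        js = np.full(40, 0.2)
        js[10:22] = 0.9
        profile = _profile_with_js(js)
        assert segment_conserved_regions(profile, 0.5, min_run=5) == [(10, 22)]

    def test_nothing_above_threshold(self):
        profile = _profile_with_js(np.full(30, 0.2))
        assert segment_conserved_regions(profile, 0.5, min_run=5) == []

    def test_short_runs_dropped_and_excluded_columns_break_runs(self):
        js = np.full(30, 0.9)
        profile = _profile_with_js(js)
        profile.included[10] = False
        regions = segment_conserved_regions(profile, 0.5, min_run=5)
        assert regions == [(0, 10), (11, 30)]
        assert segment_conserved_regions(profile, 0.5, min_run=25) == []


class TestLogoCounts:
    def test_invariant_column_single_cell(self):
        rows = tuple("W" for _ in range(12))
        aln = Alignment(tuple(f"s{i}" for i in range(12)), rows)
        mat = logo_counts(aln, (0, 1))
        assert mat.loc[1, "W"] == 12 and mat.to_numpy().sum() == 12

    def test_column_sums_equal_occupancy(self, rng):
        aln = random_alignment(rng)
        mat = logo_counts(aln, (0, aln.length))
        occ = count_matrix(aln).sum(axis=1)
        np.testing.assert_array_equal(mat.sum(axis=1).to_numpy(), occ)

    def test_information_content_identity(self, rng):
        aln = random_alignment(rng, gap_rate=0.0)
        mat = logo_counts(aln, (0, aln.length))
        for pos in range(aln.length):
            counts = mat.iloc[pos].to_numpy()
            ic = LOG2_20 - entropy_oracle(counts)
            h = shannon_entropy(column_counts(aln, pos))
            assert ic == pytest.approx(LOG2_20 - h, abs=1e-12)
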