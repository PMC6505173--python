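"""Per-sample QC statistics: missingness, sex, duplicates, frequencies,
crossovers, error rates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from doqc import sample_diagnostics as sd
from doqc.do_hmm import STATE_PAIRS, state_index
from doqc.genotype_io import (
    GENO_AA,
    GENO_AB,
    GENO_BB,
    GENO_NA,
    GenotypeMatrix,
    IntensityMatrix,
)
from doqc.sample_diagnostics import (
    QcThresholds,
    count_crossovers,
    flag_duplicates,
    genotype_freq_by_maf,
    intensity_profile,
    pair_state_distance,
    pairwise_match,
    percent_missing_by_sample,
    sex_check,
    ternary_coords,
    x_heterozygosity,
)


def geno_matrix(rows, samples=None):
    rows = np.asarray(rows, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    return GenotypeMatrix(
        pd.DataFrame(rows, index=pd.Index([f"m{i}" for i in range(rows.shape[0])]),
                     columns=samples)
    )


def min_crossovers_dp(states):
    """Exhaustive minimal-switch oracle over phased haplotype assignments."""
    seqs = [s for s in states if s >= 0]
    if len(seqs) < 2:
        return 0
    ordered = []
    for s in seqs:
        k, j = STATE_PAIRS[s]
        ordered.append([(k, j)] if k == j else [(k, j), (j, k)])
    best = {o: 0 for o in ordered[0]}
    for opts in ordered[1:]:
        nxt = {}
        for o in opts:
            nxt[o] = min(
                cost + (o[0] != p[0]) + (o[1] != p[1]) for p, cost in best.items()
            )
        best = nxt
    return min(best.values())


class TestMissing:
    def test_examples(self):
        gm = geno_matrix(
            np.column_stack([
                np.zeros(100),                       # complete
                [GENO_NA] * 20 + [GENO_AB] * 80,     # 20% missing
                [GENO_NA] * 100,                     # all missing
            ])
        )
        pct = percent_missing_by_sample(gm)
        assert pct.tolist() == [0.0, 20.0, 100.0]
        th = QcThresholds()
        assert (pct >= 100 * th.sample_missing_omit).tolist() == [False, True, True]

    def test_empty_informative_set_rejected(self):
        gm = geno_matrix([[0, 1]])
        with pytest.raises(ValueError):
            percent_missing_by_sample(gm, pd.Index([]))


class TestSexCheck:
    def intens(self, means):
        # one X marker and one Y marker; 'means' maps sample -> (mx, my)
        samples = list(means)
        x = pd.DataFrame(
            {s: [means[s][0], means[s][1]] for s in samples},
            index=pd.Index(["xm", "ym"]),
        )
        return IntensityMatrix(x, x.copy())

    def test_classification_with_given_thresholds(self):
        im = self.intens({
            "f": (0.52, 0.10),   # XX
            "m": (0.22, 0.55),   # XY
            "xo": (0.22, 0.08),  # XO: reduced X, low Y
            "xxy": (0.52, 0.55), # XXY: high on both
        })
        got = sex_check(im, ["xm"], ["ym"], thresholds=(0.35, 0.30))
        assert got["inferred_sex"].tolist() == ["XX", "XY", "XO", "XXY"]

    def test_mislabeled_male_flagged(self):
        im = self.intens({"a": (0.52, 0.1), "b": (0.2, 0.5), "c": (0.5, 0.12)})
        nominal = pd.Series({"a": "F", "b": "M", "c": "M"})
        got = sex_check(im, ["xm"], ["ym"], nominal, thresholds=(0.35, 0.3))
        assert got.loc["c", "inferred_sex"] == "XX"
        assert bool(got.loc["c", "sex_mismatch"])
        assert not got.loc[["a", "b"], "sex_mismatch"].any()

    def test_single_sex_cohort_without_thresholds_ambiguous(self):
        im = self.intens({"a": (0.5, 0.1), "b": (0.5, 0.1)})
        got = sex_check(im, ["xm"], ["ym"], pd.Series({"a": "F", "b": "F"}))
        assert (got["inferred_sex"] == "ambiguous").all()

    def test_midpoint_thresholds_recover_all_classes(self, default_sim):
        ds = default_sim
        x = ds.gmap.markers_on("X")
        y = ds.gmap.markers_on("Y")
        used = sd.select_sex_informative_x_markers(
            ds.intensities, x, ds.truth.nominal_sex
        )
        got = sex_check(ds.intensities, used, y, ds.truth.nominal_sex)
        # zero misclassifications at default cluster separation
        assert (got["inferred_sex"] == ds.truth.true_sex).all()
        mism = set(got.index[got["sex_mismatch"]])
        expected = {
            s
            for s in got.index
            if (ds.truth.nominal_sex[s] == "M") != (ds.truth.true_sex[s] in ("XY", "XXY"))
        }
        assert mism == expected


class TestXHeterozygosity:
    def test_examples(self):
        gm = geno_matrix(
            np.column_stack([
                [GENO_AA, GENO_BB, GENO_AA, GENO_BB],  # all hom, male-like
                [GENO_AB, GENO_AA, GENO_AB, GENO_BB],  # half het
                [GENO_NA] * 4,                          # nothing called
            ])
        )
        het = x_heterozygosity(gm, gm.marker_ids)
        assert het.iloc[0] == 0.0
        assert het.iloc[1] == 0.5
        assert np.isnan(het.iloc[2])


class TestPairwiseMatch:
    def test_toy_pair(self):
        gm = geno_matrix(
            [[GENO_AA, GENO_AA],
             [GENO_AB, GENO_BB],
             [GENO_BB, GENO_BB],
             [GENO_NA, GENO_AA]]
        )
        table = pairwise_match(gm, min_shared=1)
        assert len(table) == 1  # self-pairs excluded
        assert table.loc[0, "n_shared"] == 3
        assert table.loc[0, "prop_match"] == pytest.approx(2 / 3)

    def test_symmetry_and_self_match(self):
        rng = np.random.default_rng(0)
        gm = geno_matrix(rng.integers(-1, 3, size=(60, 4)))
        t1 = pairwise_match(gm, min_shared=1)
        reversed_gm = geno_matrix(
            gm.calls.to_numpy()[:, ::-1], samples=list(gm.sample_ids[::-1])
        )
        t2 = pairwise_match(reversed_gm, min_shared=1)
        key = lambda t: {frozenset((a, b)): p for a, b, p in
                         zip(t["sample1"], t["sample2"], t["prop_match"])}
        k1, k2 = key(t1), key(t2)
        for pair in k1:
            assert k1[pair] == pytest.approx(k2[pair], nan_ok=True)

    def test_low_overlap_unscored(self):
        gm = geno_matrix([[GENO_AA, GENO_NA], [GENO_NA, GENO_AA], [GENO_AB, GENO_AB]])
        table = pairwise_match(gm, min_shared=2)
        assert table.loc[0, "n_shared"] == 1
        assert np.isnan(table.loc[0, "prop_match"])

    def test_simulated_duplicates_separate_from_unrelated(self, default_sim):
        ds = default_sim
        table = pairwise_match(ds.genotypes, min_shared=1000)
        dup = {frozenset(p) for p in ds.truth.duplicates}
        is_dup = [frozenset((a, b)) in dup for a, b in
                  zip(table["sample1"], table["sample2"])]
        dup_scores = table["prop_match"][is_dup]
        other = table["prop_match"][[not d for d in is_dup]].dropna()
        eps = ds.config.epsilon_sim
        assert (dup_scores >= 1 - 2 * eps * 1.5).all()
        assert other.max() < QcThresholds().duplicate_share


class TestFlagDuplicates:
    def make_table(self, props):
        return pd.DataFrame(
            {
                "sample1": [f"a{i}" for i in range(len(props))],
                "sample2": [f"b{i}" for i in range(len(props))],
                "n_shared": 5000,
                "prop_match": props,
            }
        )

    def test_high_sharing_flagged(self):
        got = flag_duplicates(self.make_table([0.999, 0.671, 0.45]))
        assert got["sample1"].tolist() == ["a0"]
        assert got["omit_recommended"].tolist() == ["b0"]

    def test_sibling_level_not_flagged(self):
        assert len(flag_duplicates(self.make_table([0.671]))) == 0

    def test_empty_input(self):
        assert len(flag_duplicates(self.make_table([]))) == 0


class TestIntensityProfile:
    def make(self, values):
        df = pd.DataFrame({"s": values}, index=pd.Index([f"m{i}" for i in range(len(values))]))
        return IntensityMatrix(df, df.copy())

    def test_all_zero(self):
        prof = intensity_profile(self.make([0.0] * 10), "s")
        assert prof.p1 == 0.0 and prof.p99 == 0.0

    def test_constant_nine(self):
        prof = intensity_profile(self.make([9.0] * 10), "s")
        assert prof.p1 == pytest.approx(1.0)
        assert prof.p99 == pytest.approx(1.0)

    def test_percentiles_match_sort_interpolation_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.gamma(2.0, 0.3, size=501)
        prof = intensity_profile(self.make(list(vals)), "s")
        pooled = np.sort(np.log10(np.concatenate([vals, vals]) + 1.0))
        # linear interpolation between order statistics (type 7)
        def type7(q):
            h = (len(pooled) - 1) * q
            lo = int(np.floor(h))
            return pooled[lo] + (h - lo) * (pooled[min(lo + 1, len(pooled) - 1)] - pooled[lo])
        assert prof.p1 == pytest.approx(type7(0.01), abs=1e-12)
        assert prof.p99 == pytest.approx(type7(0.99), abs=1e-12)


class TestGenotypeFreqs:
    def test_expected_points(self, clean_sim):
        freqs = genotype_freq_by_maf(clean_sim.genotypes, clean_sim.founders)
        four = freqs[freqs["maf_class"] == 4].iloc[0]
        assert (four["exp_AA"], four["exp_AB"], four["exp_BB"]) == (0.25, 0.5, 0.25)
        one = freqs[freqs["maf_class"] == 1].iloc[0]
        assert one["exp_AB"] == pytest.approx(0.21875)

    def test_contamination_shows_excess_het_in_every_class(self, clean_sim):
        ds = clean_sim
        gm = ds.genotypes
        # contaminated array: mixing two samples' DNA yields a het call
        # wherever the underlying genotypes differ
        s1, s2 = gm.sample_ids[0], gm.sample_ids[1]
        g1 = gm.calls[s1].to_numpy()
        g2 = gm.calls[s2].to_numpy()
        mixed = np.where(g1 == g2, g1, GENO_AB)
        calls = gm.calls[[s1, s2]].copy()
        calls["mix"] = mixed.astype(np.int8)
        gmix = GenotypeMatrix(calls)
        freqs = genotype_freq_by_maf(gmix, ds.founders, samples=["mix"])
        for _, row in freqs.iterrows():
            assert row["f_AB"] > row["exp_AB"]


class TestTernary:
    @pytest.mark.parametrize(
        "f,expect",
        [
            ((1, 0, 0), (0.0, 0.0)),
            ((0, 1, 0), (0.5, np.sqrt(3) / 2)),
            ((0, 0, 1), (1.0, 0.0)),
        ],
    )
    def test_corners(self, f, expect):
        x, y = ternary_coords(*f)
        assert (x, y) == pytest.approx(expect)
        assert y == pytest.approx(expect[1], abs=1e-4)

    def test_requires_simplex(self):
        with pytest.raises(ValueError):
            ternary_coords(0.5, 0.5, 0.5)


class TestCrossovers:
    def S(self, *labels):
        from doqc.do_hmm import STATE_LABELS

        return np.array([STATE_LABELS.index(l) if l else -1 for l in labels])

    def test_constant_sequence(self):
        assert count_crossovers({"1": self.S("AA", "AA", "AA")}) == 0

    def test_single_steps(self):
        assert count_crossovers({"1": self.S("AA", "AB", "BB")}) == 2

    def test_disjoint_pairs(self):
        assert count_crossovers({"1": self.S("AB", "CD")}) == 2

    def test_missing_skipped_flanking_distance(self):
        assert count_crossovers({"1": self.S("AA", None, "AB")}) == 1
        assert count_crossovers({"1": self.S(None, None)}) == 0

    def test_chromosomes_sum(self):
        assert count_crossovers(
            {"1": self.S("AA", "AB"), "2": self.S("CC", "DD")}
        ) == 1 + 2

    def test_pair_distance_cases(self):
        assert pair_state_distance(state_index(0, 0), state_index(0, 0)) == 0
        assert pair_state_distance(state_index(0, 1), state_index(1, 0)) == 0
        assert pair_state_distance(state_index(0, 0), state_index(0, 1)) == 1
        assert pair_state_distance(state_index(0, 0), state_index(1, 1)) == 2
        assert pair_state_distance(state_index(0, 1), state_index(2, 3)) == 2

    def test_matches_exhaustive_oracle_random_sequences(self):
        rng = np.random.default_rng(12)
        founder_states = [state_index(k, j) for j in range(4) for k in range(j + 1)]
        for _ in range(300):
            n = rng.integers(2, 13)
            seq = rng.choice(founder_states, size=n)
            seq[rng.random(n) < 0.15] = -1
            assert count_crossovers({"1": seq}) == min_crossovers_dp(seq)

    @settings(derandomize=True, max_examples=150)
    @given(
        st.lists(
            st.one_of(st.just(-1), st.integers(min_value=0, max_value=9)),
            min_size=2,
            max_size=12,
        )
    )
    def test_matches_oracle_property(self, seq):
        # states over founders A..D (indices 0..9 in lower-triangle order)
        seq = np.array(seq)
        assert count_crossovers({"1": seq}) == min_crossovers_dp(seq)


class TestSampleErrorRate:
    def make_lod(self, lods_by_sample):
        rows = []
        for s, lods in lods_by_sample.items():
            for i, l in enumerate(lods):
                rows.append({"sample": s, "marker": f"m{i}", "lod": l})
        return pd.DataFrame(rows)

    def test_extremes(self):
        table = self.make_lod({"a": [0.1, -2.0, 1.9], "b": [3.0, 4.0]})
        rates = sd.sample_error_rate(table)
        assert rates["a"] == 0.0
        assert rates["b"] == 1.0

    def test_nan_excluded_from_denominator(self):
        table = self.make_lod({"a": [3.0, np.nan, -1.0]})
        assert sd.sample_error_rate(table)["a"] == pytest.approx(0.5)

    def test_clean_simulation_rates_tiny(self, dense_clean_sim):
        from doqc import do_hmm

        ds = dense_clean_sim
        samples = list(ds.genotypes.sample_ids)
        post = do_hmm.reconstruct(ds.genotypes, ds.founders, ds.gmap, samples=samples)
        lod = do_hmm.error_lod_table(post, ds.genotypes, ds.founders, 0.002)
        rates = sd.sample_error_rate(lod)
        assert rates.median() < 1e-3


class TestSampleReport:
    def test_assembly_flags(self, small_sim):
        ds = small_sim
        report = sd.build_sample_report(
            ds.genotypes, ds.genotypes.marker_ids, QcThresholds()
        )
        bad = set(ds.truth.bad_samples)
        for s in bad:
            assert report.loc[s, "flag_omit_missing"]
        assert not report.loc[~report.index.isin(bad), "flag_omit_missing"].any()
        assert report["pct_missing"].between(0, 100).all()
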