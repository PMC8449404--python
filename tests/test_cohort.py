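"""Repertoire, pathogen, and HLA-association analyses."""

import numpy as np
import pandas as pd
import pytest

from tcemtools.cohort import (
    NpCutoffs,
    allele_presented_np_fraction,
    eligible_allele_peptide_pairs,
    group_level_np_fraction,
    np_flag,
    paired_group_comparison,
    pathogen_np_fraction,
    per_individual_fractions,
    rank_percentile_aggregation,
    variance_vs_proteome_size,
)
from tcemtools.motifs import ProteomeIndex


class TestNpFlag:
    def make_profile(self, count, expr, thymo):
        cutoffs = NpCutoffs(expression_cutoff=1.0, thymo_cutoff=0.9)
        return np_flag(pd.Series({"MOTIF": count}), pd.Series({"MOTIF": expr}),
                       pd.Series({"MOTIF": thymo}), cutoffs)

    @pytest.mark.parametrize("count,expr,thymo,is_np,criterion", [
        (3, 5.0, 1.2, True, "by_frequency"),     # rare despite the rest
        (10, 5.0, 1.2, False, None),             # all attributes fine
        (10, 5.0, 0.5, True, "by_cleavage"),     # low thymo score
        (10, 0.2, 1.2, True, "by_expression"),   # low cTEC expression
    ])
    def test_disjunction_and_provenance(self, count, expr, thymo, is_np, criterion):
        profile = self.make_profile(count, expr, thymo)
        assert profile.is_np("MOTIF") is is_np
        if criterion:
            assert bool(profile.table.loc["MOTIF", criterion])

    def test_missing_expression_counts_as_low(self):
        profile = self.make_profile(10, np.nan, 1.2)
        assert profile.is_np("MOTIF")

    def test_monotone_in_attributes(self):
        base = self.make_profile(10, 5.0, 1.2)
        assert not base.is_np("MOTIF")
        for kwargs in [(3, 5.0, 1.2), (10, 0.5, 1.2), (10, 5.0, 0.1)]:
            assert self.make_profile(*kwargs).is_np("MOTIF")

    def test_unseen_motif_defaults_np(self):
        profile = self.make_profile(10, 5.0, 1.2)
        assert profile.is_np("WWWWW")


class TestEligiblePairs:
    def setup_tables(self, aff, rank, n_recognizers):
        predictions = pd.DataFrame({"peptide": ["ACDEFGHIK"], "allele": ["HLA-A*01:01"],
                                    "affinity_nm": [aff], "rank_pct": [rank]})
        individuals = [f"I{i}" for i in range(3)]
        recognition = pd.DataFrame({
            "individual": individuals,
            "peptide": ["ACDEFGHIK"] * 3,
            "recognized": [i < n_recognizers for i in range(3)],
        })
        genotypes = pd.DataFrame({"individual": individuals,
                                  "allele": ["HLA-A*01:01"] * 3})
        return predictions, recognition, genotypes

    @pytest.mark.parametrize("aff,rank,n_rec,kept", [
        (40.0, 0.4, 2, True),
        (40.0, 0.4, 1, False),   # fewer than two carriers
        (60.0, 0.4, 2, False),   # affinity fails
        (40.0, 0.6, 2, False),   # rank fails
    ])
    def test_thresholds(self, aff, rank, n_rec, kept):
        pred, rec, geno = self.setup_tables(aff, rank, n_rec)
        pairs = eligible_allele_peptide_pairs(pred, rec, geno)
        assert (len(pairs) == 1) is kept


class TestPerIndividualFractions:
    def make_inputs(self, recognized_count=25, n_peptides=40):
        peptides = [f"PEP{i:03d}" for i in range(n_peptides)]
        pairs = pd.DataFrame({"peptide": peptides, "allele": "HLA-A*01:01"})
        genotypes = pd.DataFrame({"individual": ["I1"], "allele": ["HLA-A*01:01"]})
        recognition = pd.DataFrame({
            "individual": "I1", "peptide": peptides,
            "recognized": [i < recognized_count for i in range(n_peptides)],
        })
        groups = pd.Series(["rare" if i % 2 else "nonrare" for i in range(n_peptides)],
                           index=peptides)
        return recognition, genotypes, pairs, groups

    def test_fraction_is_recognized_over_presented(self):
        rec, geno, pairs, groups = self.make_inputs()
        out = per_individual_fractions(rec, geno, pairs, groups)
        assert set(out["group"]) == {"rare", "nonrare"}
        total = out["n_recognized"].sum()
        assert total == 25
        assert (out["fraction"] == out["n_recognized"] / out["n_presented"]).all()

    def test_individual_below_twenty_recognized_excluded(self):
        rec, geno, pairs, groups = self.make_inputs(recognized_count=19)
        assert per_individual_fractions(rec, geno, pairs, groups).empty

    def test_full_recognition_gives_unit_fractions(self):
        rec, geno, pairs, groups = self.make_inputs(recognized_count=40)
        out = per_individual_fractions(rec, geno, pairs, groups)
        assert (out["fraction"] == 1.0).all()


class TestPairedComparison:
    def test_identical_vectors_p_one(self):
        rows = []
        for i in range(8):
            rows.append({"individual": f"I{i}", "group": "a", "fraction": 0.5})
            rows.append({"individual": f"I{i}", "group": "b", "fraction": 0.5})
        res = paired_group_comparison(pd.DataFrame(rows), "a", "b")
        assert res["p_value"] == 1.0

    def test_planted_gap_detected_with_direction(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(22):
            base = rng.uniform(0.3, 0.5)
            rows.append({"individual": f"I{i}", "group": "nonrare", "fraction": base})
            rows.append({"individual": f"I{i}", "group": "rare",
                         "fraction": base * 0.5 + rng.normal(0, 0.02)})
        res = paired_group_comparison(pd.DataFrame(rows), "nonrare", "rare")
        assert res["p_value"] < 0.05
        assert res["median_difference"] > 0

    def test_too_few_pairs_error(self):
        rows = [{"individual": f"I{i}", "group": g, "fraction": 0.1 * i}
                for i in range(4) for g in ("a", "b")]
        with pytest.raises(ValueError):
            paired_group_comparison(pd.DataFrame(rows), "a", "b")


class TestPathogenFraction:
    def make_profile(self, np_motifs, ok_motifs):
        motifs = list(np_motifs) + list(ok_motifs)
        counts = pd.Series(10, index=motifs)
        expr = pd.Series([0.0] * len(np_motifs) + [5.0] * len(ok_motifs), index=motifs)
        thymo = pd.Series(1.0, index=motifs)
        return np_flag(counts, expr, thymo,
                       NpCutoffs(expression_cutoff=1.0, thymo_cutoff=0.5,
                                 missing_expression_is_low=True))

    def test_planted_composition_recovered(self):
        profile = self.make_profile(["CCCCC"], ["DDDDD"])
        # 3 windows exposing CCCCC (np), 7 exposing DDDDD (not np)
        records = [(f"N{i}", "AAACCCCCA") for i in range(3)]
        records += [(f"K{i}", "AAADDDDDA") for i in range(7)]
        index = ProteomeIndex.build(records)
        assert pathogen_np_fraction(index, profile) == pytest.approx(0.3)

    def test_all_unknown_motifs_fraction_one(self):
        profile = self.make_profile(["CCCCC"], ["DDDDD"])
        index = ProteomeIndex.build([("P", "AAAWWWWWA")])
        assert pathogen_np_fraction(index, profile) == 1.0

    def test_concatenation_is_window_weighted_mean(self):
        profile = self.make_profile(["CCCCC"], ["DDDDD"])
        part1 = ProteomeIndex.build([("A", "AAACCCCCA")])
        part2 = ProteomeIndex.build([("B", "AAADDDDDA"), ("C", "AAADDDDDA")])
        merged = ProteomeIndex.build([("A", "AAACCCCCA"), ("B", "AAADDDDDA"),
                                      ("C", "AAADDDDDA")])
        f1 = pathogen_np_fraction(part1, profile)
        f2 = pathogen_np_fraction(part2, profile)
        fm = pathogen_np_fraction(merged, profile)
        w1, w2 = part1.total_windows(), part2.total_windows()
        assert fm == pytest.approx((f1 * w1 + f2 * w2) / (w1 + w2))


class TestAllelePresentedFraction:
    def make_predictions(self, rows):
        return pd.DataFrame(rows, columns=["peptide", "allele", "affinity_nm",
                                           "rank_pct"])

    def profile_for(self, peptides, np_flags):
        from tcemtools.motifs import extract_tcem

        motifs = [extract_tcem(p) for p in peptides]
        counts = pd.Series([1 if f else 10 for f in np_flags], index=motifs)
        expr = pd.Series(5.0, index=motifs)
        thymo = pd.Series(1.0, index=motifs)
        return np_flag(counts, expr, thymo,
                       NpCutoffs(expression_cutoff=0.5, thymo_cutoff=0.5,
                                 missing_expression_is_low=False))

    def test_bound_fraction(self):
        peptides = ["AAACCCCCA", "AAADDDDDA", "AAAEEEEEA", "AAAFFFFFA"]
        profile = self.profile_for(peptides, [True, True, True, False])
        rows = [(p, "HLA-A*01:01", 20.0, 0.2) for p in peptides]
        frac = allele_presented_np_fraction(pd.DataFrame({"peptide": peptides}),
                                            self.make_predictions(rows), profile)
        assert frac["HLA-A*01:01"] == pytest.approx(0.75)

    def test_fallback_median_rule(self):
        peptides = [f"AAA{m}A" for m in
                    ["CCCCC", "DDDDD", "EEEEE", "FFFFF", "GGGGG", "HHHHH", "KKKKK",
                     "MMMMM", "NNNNN", "PPPPP"]]
        profile = self.profile_for(peptides, [True] * 5 + [False] * 5)
        rows = []
        # three alleles with 1, 3, 5 binders; the failing allele binds none
        for allele, n_bound in [("HLA-A*01:01", 1), ("HLA-A*02:01", 3),
                                ("HLA-A*03:01", 5)]:
            for i, p in enumerate(peptides):
                bound = i < n_bound
                rows.append((p, allele, 20.0 if bound else 5000.0,
                             0.2 if bound else 10.0))
        for i, p in enumerate(peptides):
            rows.append((p, "HLA-A*24:02", 1000.0 + i, 10.0))
        frac = allele_presented_np_fraction(pd.DataFrame({"peptide": peptides}),
                                            self.make_predictions(rows), profile)
        # fallback N = median(1, 3, 5) = 3 lowest-affinity peptides, all np
        assert frac["HLA-A*24:02"] == pytest.approx(1.0)

    def test_single_allele_locus_without_binders_errors(self):
        peptides = ["AAACCCCCA"]
        profile = self.profile_for(peptides, [True])
        rows = [(peptides[0], "HLA-C*01:02", 5000.0, 10.0)]
        with pytest.raises(ValueError):
            allele_presented_np_fraction(pd.DataFrame({"peptide": peptides}),
                                         self.make_predictions(rows), profile)


class TestVarianceVsSize:
    def test_identical_fractions_zero_variance(self):
        fractions = pd.DataFrame(0.5, index=["s1", "s2", "s3"], columns=["a1", "a2"])
        variance, _, _ = variance_vs_proteome_size(
            fractions, pd.Series({"s1": 100, "s2": 200, "s3": 300}))
        assert (variance == 0).all()

    def test_binomial_noise_shrinks_with_size(self):
        rng = np.random.default_rng(1)
        sizes = pd.Series({f"s{i}": n for i, n in
                           enumerate([30, 60, 120, 250, 500, 1000, 2000, 4000])})
        rows = {}
        for species, n in sizes.items():
            rows[species] = rng.binomial(n, 0.5, size=12) / n
        fractions = pd.DataFrame(rows).T
        _, rho, p = variance_vs_proteome_size(fractions, sizes)
        assert rho < -0.7 and p < 0.05

    def test_permuted_sizes_kill_correlation(self):
        rng = np.random.default_rng(2)
        sizes = pd.Series({f"s{i}": n for i, n in
                           enumerate([30, 60, 120, 250, 500, 1000, 2000, 4000])})
        rows = {s: rng.binomial(n, 0.5, size=12) / n for s, n in sizes.items()}
        fractions = pd.DataFrame(rows).T
        permuted = pd.Series(rng.permutation(sizes.to_numpy()), index=sizes.index)
        _, rho, _ = variance_vs_proteome_size(fractions, permuted)
        assert abs(rho) < 0.7


class TestAssociationAggregation:
    def test_lowest_or_everywhere_is_protective(self):
        studies = pd.DataFrame([
            ("s1", "A", 0.4), ("s1", "B", 1.0), ("s1", "C", 2.0),
            ("s2", "A", 0.5), ("s2", "B", 2.5), ("s2", "C", 1.5),
        ], columns=["study_id", "allele_group", "odds_ratio"])
        out = rank_percentile_aggregation(studies)
        labels = out.set_index("allele_group")["label"]
        assert labels["A"] == "protective"

    def test_hand_computed_percentiles(self):
        studies = pd.DataFrame([
            ("s1", "A", 0.5), ("s1", "B", 1.0), ("s1", "C", 2.0),
            ("s2", "A", 1.0), ("s2", "B", 3.0), ("s2", "C", 2.0),
        ], columns=["study_id", "allele_group", "odds_ratio"])
        out = rank_percentile_aggregation(studies).set_index("allele_group")
        # s1 ranks: A 1/3, B 2/3, C 3/3 ; s2: A 1/3, C 2/3, B 3/3
        assert out.loc["A", "mean_rank_percentile"] == pytest.approx(1 / 3)
        assert out.loc["B", "mean_rank_percentile"] == pytest.approx((2 / 3 + 1) / 2)
        assert out.loc["C", "mean_rank_percentile"] == pytest.approx((1 + 2 / 3) / 2)
        assert out.loc["A", "label"] == "protective"
        assert out.loc["B", "label"] == "risk"

    def test_coverage_rule_excludes_sparse_group(self):
        studies = pd.DataFrame([
            ("s1", "A", 0.5), ("s1", "B", 1.0),
            ("s2", "A", 1.0), ("s2", "B", 3.0),
            ("s1", "RAREGRP", 9.0),
        ], columns=["study_id", "allele_group", "odds_ratio"])
        out = rank_percentile_aggregation(studies, coverage=0.75)
        assert "RAREGRP" not in set(out["allele_group"])

    def test_invariant_under_monotone_or_transform(self):
        rng = np.random.default_rng(3)
        rows = [(f"s{s}", f"G{g}", float(rng.lognormal()))
                for s in range(4) for g in range(5)]
        studies = pd.DataFrame(rows, columns=["study_id", "allele_group", "odds_ratio"])
        transformed = studies.assign(odds_ratio=np.exp(2 * np.log(studies["odds_ratio"])))
        a = rank_percentile_aggregation(studies)
        b = rank_percentile_aggregation(transformed)
        pd.testing.assert_frame_equal(a, b)


class TestGroupLevelFraction:
    def test_serotype_mean(self):
        values = pd.Series({"HLA-A*01:01": 0.4, "HLA-A*02:01": 0.6})
        assert group_level_np_fraction(values, list(values.index)) == pytest.approx(0.5)

    def test_common_allele_restriction(self):
        values = pd.Series({"a": 0.4, "b": 0.9})
        assert group_level_np_fraction(values, ["a", "b"], common_alleles={"b"}) == 0.9

    def test_empty_membership_error(self):
        with pytest.raises(ValueError):
            group_level_np_fraction(pd.Series({"a": 0.4}), ["zzz"])
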