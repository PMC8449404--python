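"""Immunogenicity dataset curation."""

import math

import numpy as np
import pandas as pd
import pytest

from tcemtools.curation import (
    anchor_positions,
    curate,
    dataset1_binding_filter,
    dataset2_binding_filter,
    filter_assays,
    iterative_dedup,
    ktuple_distance,
    label_immunogenicity,
    position_entropies,
    secondary_anchor_exclusion,
    tcem_window,
)
from tcemtools.motifs import AMINO_ACIDS


def assay(peptide, allele="HLA-A*02:01", kind="tcell", outcome="positive",
          organism="Vaccinia virus"):
    return {"peptide": peptide, "allele": allele, "assay_kind": kind,
            "outcome": outcome, "source_organism": organism}


class TestFilterAssays:
    def test_keeps_valid_nine_mer(self):
        records = pd.DataFrame([assay("ACDEFGHIK")])
        assert len(filter_assays(records)) == 1

    @pytest.mark.parametrize("row,reason", [
        (assay("ACDEFGHIKLM"), "length 11"),
        (assay("ACDEFGHI"), "length 8"),
        (assay("ACDEXGHIK"), "nonstandard letter"),
        (assay("ACDEFGHIK", organism="Homo sapiens"), "human source"),
        (assay("ACDEFGHIK", allele="HLA-A*02"), "2-digit allele"),
        (assay("ACDEFGHIK", allele="HLA-A2"), "serotype-only allele"),
    ])
    def test_rejections(self, row, reason):
        assert filter_assays(pd.DataFrame([row])).empty, reason


class TestLabeling:
    def make(self, n_pos, n_neg, peptide="ACDEFGHIK", allele="HLA-A*02:01"):
        rows = [assay(peptide, allele, outcome="positive")] * n_pos
        rows += [assay(peptide, allele, outcome="negative")] * n_neg
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("n_pos,n_neg,label", [
        (0, 3, "nonimmunogenic"),   # solely negative
        (2, 1, "immunogenic"),      # more positive than negative
        (3, 0, "immunogenic"),
    ])
    def test_labels(self, n_pos, n_neg, label):
        out = label_immunogenicity(self.make(n_pos, n_neg))
        assert list(out["label"]) == [label]
        assert out.loc[0, "n_pos"] == n_pos and out.loc[0, "n_neg"] == n_neg

    @pytest.mark.parametrize("n_pos,n_neg", [(1, 1), (2, 2), (1, 2)])
    def test_ambiguous_pairs_excluded(self, n_pos, n_neg):
        assert label_immunogenicity(self.make(n_pos, n_neg)).empty

    def test_discordant_peptide_across_alleles_fully_excluded(self):
        frames = [
            self.make(2, 0, allele="HLA-A*02:01"),
            self.make(0, 2, allele="HLA-B*07:02"),
            self.make(2, 0, peptide="WIKVACDEF"),
        ]
        out = label_immunogenicity(pd.concat(frames, ignore_index=True))
        assert set(out["peptide"]) == {"WIKVACDEF"}


class TestBindingFilters:
    def pairs(self):
        return pd.DataFrame({
            "peptide": ["ACDEFGHIK"], "allele": ["HLA-A*02:01"],
            "label": ["immunogenic"], "n_pos": [2], "n_neg": [0],
        })

    @pytest.mark.parametrize("aff,rank,kept", [
        (400.0, 3.0, True),    # affinity branch
        (600.0, 1.5, True),    # rank branch
        (600.0, 3.0, False),   # both fail
        (500.0, 2.0, False),   # boundaries are strict
    ])
    def test_dataset1_prediction_filter(self, aff, rank, kept):
        pred = pd.DataFrame({"peptide": ["ACDEFGHIK"], "allele": ["HLA-A*02:01"],
                             "affinity_nm": [aff], "rank_pct": [rank]})
        out = dataset1_binding_filter(self.pairs(), pred)
        assert (len(out) == 1) is kept

    def test_dataset1_missing_prediction_drops_pair(self):
        pred = pd.DataFrame({"peptide": ["OTHER"], "allele": ["HLA-A*02:01"],
                             "affinity_nm": [10.0], "rank_pct": [0.1]})
        assert dataset1_binding_filter(self.pairs(), pred).empty

    @pytest.mark.parametrize("n_bind,n_bind_pos,kept", [
        (3, 2, True),    # 66.7% positive
        (5, 3, False),   # exactly 60%: not strictly more
        (1, 1, False),   # fewer than two binding assays
    ])
    def test_dataset2_empirical_filter(self, n_bind, n_bind_pos, kept):
        rows = [assay("ACDEFGHIK", kind="mhc_binding",
                      outcome="positive" if i < n_bind_pos else "negative")
                for i in range(n_bind)]
        out = dataset2_binding_filter(self.pairs(), pd.DataFrame(rows))
        assert (len(out) == 1) is kept

    def test_dataset2_requires_two_tcell_assays(self):
        pairs = self.pairs().assign(n_pos=1, n_neg=0)
        rows = [assay("ACDEFGHIK", kind="mhc_binding")] * 3
        assert dataset2_binding_filter(pairs, pd.DataFrame(rows)).empty


class TestKtupleDistance:
    def test_identical_is_zero(self):
        assert ktuple_distance("ACDEFGHIK", "ACDEFGHIK") == 0.0

    def test_disjoint_alphabets_is_one(self):
        assert ktuple_distance("AAAAAAAAA", "WWWWWWWWW") == 1.0

    def test_shared_multiset_formula(self):
        # shares the multiset {A, A, C, D, E}: d = 1 - 5/9
        a = "AACDEWWWW"
        b = "KLMNPAACDE"[:9] + ""  # K L M N P A A C D -> shares A,A,C,D
        b = "KLMNPAACD"
        assert ktuple_distance(a, b) == pytest.approx(1 - 4 / 9)
        c = "AACDEKLMN"
        assert ktuple_distance(a, c) == pytest.approx(1 - 5 / 9)

    def test_half_distance_is_half_overlap(self):
        # 10-mers sharing exactly 5 of 10 residues: d = 0.5
        a = "AAAAACDEFG"
        b = "AAAAAWWWWW"
        assert ktuple_distance(a, b) == pytest.approx(0.5)

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            ktuple_distance("", "ACDEF")


def brute_force_dedup(peptides, threshold=0.5, k=1):
    """Literal reimplementation of the iterative exclusion rule."""
    remaining = list(peptides)
    while len(remaining) > 1:
        n = len(remaining)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i, j] = ktuple_distance(remaining[i], remaining[j], k)
        pair_vals = [d[i, j] for i in range(n) for j in range(i + 1, n)]
        dmin = min(pair_vals)
        if dmin >= threshold:
            break
        members = set()
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] == dmin:
                    members |= {i, j}
        mean_d = d.sum(axis=1) / (n - 1)
        victim = min(sorted(members), key=lambda i: (mean_d[i], remaining[i]))
        remaining.pop(victim)
    return remaining


class TestIterativeDedup:
    def test_identical_pair_keeps_one(self):
        assert len(iterative_dedup(["ACDEFGHIK", "ACDEFGHIK"])) == 1

    def test_distant_set_unchanged(self):
        peptides = ["AAAAAAAAA", "WWWWWWWWW", "CCCCCCCCC"]
        assert iterative_dedup(peptides) == peptides

    def test_three_peptide_removal_sequence(self):
        # two near-duplicates and one distant peptide
        peptides = ["AAAAAAAAC", "AAAAAAAAD", "WWWWWWWWW"]
        result = iterative_dedup(peptides)
        assert result == brute_force_dedup(peptides)
        assert len(result) == 2 and "WWWWWWWWW" in result

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        letters = list("ACDEFG")  # small alphabet forces collisions
        peptides = ["".join(rng.choice(letters, size=9)) for _ in range(40)]
        result = iterative_dedup(peptides)
        assert result == brute_force_dedup(peptides)

    @pytest.mark.parametrize("seed", range(3))
    def test_postcondition_all_pairs_distant(self, seed):
        rng = np.random.default_rng(100 + seed)
        peptides = ["".join(rng.choice(list("ACDE"), size=9)) for _ in range(200)]
        result = iterative_dedup(peptides)
        for i, a in enumerate(result):
            for b in result[i + 1:]:
                assert ktuple_distance(a, b) >= 0.5


class TestAnchors:
    def test_entropy_closed_forms(self):
        single = ["A" * 9] * 25
        assert position_entropies(single)[0] == 0.0
        fifty_fifty = ["A" * 9] * 10 + ["C" + "A" * 8] * 10
        assert position_entropies(fifty_fifty)[0] == pytest.approx(math.log(2))
        uniform = [aa + "A" * 8 for aa in AMINO_ACIDS]
        assert position_entropies(uniform)[0] == pytest.approx(math.log(20))

    def test_anchor_threshold_in_nats(self):
        # 50/50 split: ln 2 ~ 0.693 < 0.8 -> anchor; uniform-ish -> not
        rng = np.random.default_rng(0)
        peptides = []
        for _ in range(40):
            body = "".join(rng.choice(list(AMINO_ACIDS), size=8))
            first = "A" if rng.random() < 0.5 else "C"
            peptides.append(first + body)
        anchors = anchor_positions({"HLA-A*02:01": peptides})
        assert 1 in anchors[("HLA-A*02:01", 9)]
        assert 5 not in anchors[("HLA-A*02:01", 9)]

    def test_too_few_peptides_skips_allele(self):
        anchors = anchor_positions({"HLA-A*02:01": ["ACDEFGHIK"] * 5})
        assert anchors == {}

    def test_tcem_window(self):
        assert tcem_window(9) == {4, 5, 6, 7, 8}
        assert tcem_window(10) == {5, 6, 7, 8, 9}


class TestSecondaryAnchorExclusion:
    def curated(self, alleles):
        return pd.DataFrame({
            "peptide": ["ACDEFGHIK"] * len(alleles), "allele": alleles,
            "label": ["immunogenic"] * len(alleles),
        })

    def test_anchor_in_tcem_excludes(self):
        anchors = {("HLA-A*02:01", 9): {2, 5}}
        out = secondary_anchor_exclusion(self.curated(["HLA-A*02:01"]), anchors)
        assert out.empty

    def test_one_anchor_free_allele_retains(self):
        anchors = {("HLA-A*02:01", 9): {2, 5}, ("HLA-B*07:02", 9): {2, 9}}
        out = secondary_anchor_exclusion(
            self.curated(["HLA-A*02:01", "HLA-B*07:02"]), anchors)
        assert len(out) == 2

    def test_anchors_outside_tcem_retain(self):
        anchors = {("HLA-A*02:01", 9): {2, 9}}
        out = secondary_anchor_exclusion(self.curated(["HLA-A*02:01"]), anchors)
        assert len(out) == 1


class TestFullCuration:
    @pytest.fixture()
    def synthetic_tables(self, config, study):
        from tcemtools.simulate import gen_assay_dataset

        assays, predictions, _ = gen_assay_dataset(config, study.attributes,
                                                   n_peptides=150, seed=77)
        return assays, predictions

    def test_datasets_disjoint_and_deterministic(self, synthetic_tables):
        assays, predictions = synthetic_tables
        first = curate(assays, predictions)
        second = curate(assays, predictions)
        assert set(first.dataset1["peptide"]).isdisjoint(first.dataset2["peptide"])
        pd.testing.assert_frame_equal(first.dataset1, second.dataset1)
        pd.testing.assert_frame_equal(first.dataset2, second.dataset2)

    def test_labels_partition(self, synthetic_tables):
        assays, predictions = synthetic_tables
        combined = curate(assays, predictions).combined()
        assert set(combined["label"]) <= {"immunogenic", "nonimmunogenic"}
        assert combined["dataset"].isin([1, 2]).all()
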