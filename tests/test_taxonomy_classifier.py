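import math

import numpy as np
import pytest

from vrbench.io_core import TaxonomyTable, UNCLASSIFIED
from vrbench.taxonomy_classifier import (
    RankedAssignment,
    classify,
    classify_many,
    depth_table,
    genus_accuracy,
    phylum_counts,
    population_category,
    representation,
    representation_from_counts,
    train,
)


def _random_seq(rng, n=200):
    return "".join(rng.choice(list("ACGT"), size=n))


def _disjoint_pair(rng, n=200, k=8):
    """Two sequences sharing no k-mer."""
    while True:
        s1, s2 = _random_seq(rng, n), _random_seq(rng, n)
        w1 = {s1[i : i + k] for i in range(n - k + 1)}
        w2 = {s2[i : i + k] for i in range(n - k + 1)}
        if not w1 & w2:
            return s1, s2


def _two_genus_model(rng):
    s1, s2 = _disjoint_pair(rng)
    tax = TaxonomyTable({
        "a": ("Bacteria", "P1", "C1", "O1", "F1", "G1"),
        "b": ("Bacteria", "P2", "C2", "O2", "F2", "G2"),
    })
    model = train({"a": s1, "b": s2}, tax)
    return model, s1, s2


class TestTrain:
    def test_smoothed_probabilities(self, rng):
        model, s1, _ = _two_genus_model(rng)
        g1 = model.genera.index(("Bacteria", "P1", "C1", "O1", "F1", "G1"))
        g2 = 1 - g1
        w = s1[:8]
        v = model.vocabulary[w]
        p_own = math.exp(model.log_conditional[g1, v])
        p_other = math.exp(model.log_conditional[g2, v])
        # word in 1 of 2 training sequences: prior = 1.5/3 = 0.5;
        # P(w|own genus of size 1) = (1 + 0.5)/2 = 0.75
        assert p_own == pytest.approx(0.75)
        # absent word smoothing stays positive: prior/(M+1) = 0.25
        assert p_other == pytest.approx(0.25)
        assert p_own > p_other

    def test_separation_for_every_word(self, rng):
        model, s1, s2 = _two_genus_model(rng)
        for seq, genus in ((s1, "G1"), (s2, "G2")):
            gi = next(i for i, g in enumerate(model.genera) if g[5] == genus)
            for i in range(len(seq) - 7):
                v = model.vocabulary[seq[i : i + 8]]
                assert model.log_conditional[gi, v] > model.log_conditional[1 - gi, v]

    def test_short_sequences_skipped(self, rng):
        s1, s2 = _disjoint_pair(rng)
        tax = TaxonomyTable({
            "a": ("B", "P1", "C1", "O1", "F1", "G1"),
            "b": ("B", "P2", "C2", "O2", "F2", "G2"),
            "tiny": ("B", "P1", "C1", "O1", "F1", "G1"),
        })
        model = train({"a": s1, "b": s2, "tiny": "ACGT"}, tax)
        assert model.genus_sizes.sum() == 2

    def test_single_genus_rejected(self, rng):
        tax = TaxonomyTable({"a": ("B", "P", "C", "O", "F", "G")})
        with pytest.raises(ValueError, match="2 genera"):
            train({"a": _random_seq(rng)}, tax)


class TestClassify:
    def test_exact_training_sequence_fully_confident(self, rng):
        model, s1, _ = _two_genus_model(rng)
        a = classify(s1, model, rng=0)
        assert a.taxa[5] == "G1"
        np.testing.assert_array_equal(a.confidences, 1.0)
        assert a.effective_depth == 6
        assert a.effective == ("Bacteria", "P1", "C1", "O1", "F1", "G1")

    def test_unknown_words_unclassified(self, rng):
        model, s1, s2 = _two_genus_model(rng)
        while True:
            q = _random_seq(rng, 100)
            qwords = {q[i : i + 8] for i in range(93)}
            if not qwords & set(model.vocabulary):
                break
        a = classify(q, model, rng=0)
        assert a.effective_depth == 0
        assert a.effective == (UNCLASSIFIED,) * 6
        assert a.confidences.sum() == 0.0

    def test_chimera_splits_genus_confidence(self, rng):
        model, s1, s2 = _two_genus_model(rng)
        q = s1[:100] + s2[100:]
        a = classify(q, model, n_bootstrap=1000, rng=42)
        # symmetric word content: each genus should win about half the
        # bootstrap replicates
        genus_conf = a.confidences[5]
        assert genus_conf == pytest.approx(0.5, abs=0.05)
        # domain rank always agrees (both lineages share "Bacteria")
        assert a.confidences[0] == 1.0

    def test_effective_is_lineage_prefix(self, rng):
        model, s1, s2 = _two_genus_model(rng)
        q = s1[:100] + s2[100:]
        a = classify(q, model, n_bootstrap=200, rng=7)
        d = a.effective_depth
        assert a.effective[:d] == a.taxa[:d]
        assert all(t == UNCLASSIFIED for t in a.effective[d:])

    def test_duplicating_training_genus_leaves_decisions_unchanged(self, rng):
        s1, s2 = _disjoint_pair(rng)
        lin1 = ("B", "P1", "C1", "O1", "F1", "G1")
        lin2 = ("B", "P2", "C2", "O2", "F2", "G2")
        tax = TaxonomyTable({"a": lin1, "b": lin2})
        model = train({"a": s1, "b": s2}, tax)
        tax_dup = TaxonomyTable({"a": lin1, "a2": lin1, "a3": lin1, "b": lin2})
        model_dup = train({"a": s1, "a2": s1, "a3": s1, "b": s2}, tax_dup)
        for q in (s1, s2):
            a = classify(q, model, rng=11)
            b = classify(q, model_dup, rng=11)
            assert a.taxa == b.taxa
            assert a.effective == b.effective

    def test_classify_many_is_seed_deterministic(self, rng):
        model, s1, s2 = _two_genus_model(rng)
        seqs = {"x": s1, "y": s2, "z": s1[:150] + s2[150:]}
        r1 = classify_many(seqs, model, seed=3)
        r2 = classify_many(seqs, model, seed=3)
        for k in seqs:
            assert r1[k].effective == r2[k].effective
            np.testing.assert_array_equal(r1[k].confidences, r2[k].confidences)


def _fake_assignment(depth, lineage=("B", "P", "C", "O", "F", "G")):
    conf = np.array([1.0] * depth + [0.0] * (6 - depth))
    return RankedAssignment(taxa=lineage, confidences=conf,
                            effective_depth=depth, cutoff=0.5)


class TestDepthTable:
    def test_all_classified_to_genus(self):
        a = {f"q{i}": _fake_assignment(6) for i in range(10)}
        df = depth_table({"FL": a})
        assert (df["FL"] == 1.0).all()

    def test_half_unclassified_at_rank_one(self):
        a = {f"q{i}": _fake_assignment(0 if i % 2 else 6) for i in range(10)}
        df = depth_table({"FL": a})
        assert df.loc[1, "FL"] == 0.5

    def test_matches_brute_force_recount(self, rng):
        depths = rng.integers(0, 7, size=50)
        a = {f"q{i}": _fake_assignment(int(d)) for i, d in enumerate(depths)}
        df = depth_table({"X": a})
        for rank in range(1, 7):
            brute = float(np.mean(depths >= rank))
            assert df.loc[rank, "X"] == pytest.approx(brute)

    def test_id_mismatch_rejected(self):
        a = {"q1": _fake_assignment(6)}
        b = {"q2": _fake_assignment(6)}
        with pytest.raises(ValueError, match="different query ids"):
            depth_table({"FL": a, "V3": b})


# Published phylum counts for the full-length dataset and its V6-trimmed
# variant, used as printed input for the representation arithmetic.
TABLE1_FL = {
    "Proteobacteria": 15786, "Firmicutes": 7388, "Actinobacteria": 7373,
    "Acidobacteria": 4607, "Bacteroidetes": 1861, "unclassified": 1521,
    "Planctomycetes": 808, "Verrucomicrobia": 759, "Chloroflexi": 690,
    "Gemmatimonadetes": 446, "Cyanobacteria": 319, "TM7": 162,
    "Nitrospira": 114, "Deinococcus-Thermus": 97, "OP10": 59, "WS3": 45,
    "Spirochaetes": 12, "Deferribacteres": 11, "BRC1": 9, "OD1": 7,
    "OP11": 7, "Tenericutes": 7, "Thermotogae": 5, "Chlamydiae": 4,
    "Chlorobi": 4, "Synergistetes": 4, "Aquificae": 2, "Fusobacteria": 2,
    "Lentisphaerae": 0, "Thermodesulfobacteria": 0,
}
TABLE1_V6 = {
    "Proteobacteria": 15760, "Firmicutes": 7144, "Actinobacteria": 7353,
    "Acidobacteria": 3781, "Bacteroidetes": 1894, "unclassified": 3383,
    "Planctomycetes": 725, "Verrucomicrobia": 688, "Chloroflexi": 477,
    "Gemmatimonadetes": 124, "Cyanobacteria": 280, "TM7": 169,
    "Nitrospira": 101, "Deinococcus-Thermus": 58, "OP10": 41, "WS3": 9,
    "Spirochaetes": 12, "Deferribacteres": 8, "BRC1": 7, "OD1": 12,
    "OP11": 6, "Tenericutes": 6, "Thermotogae": 6, "Chlamydiae": 4,
    "Chlorobi": 3, "Synergistetes": 4, "Aquificae": 3, "Fusobacteria": 2,
    "Lentisphaerae": 0, "Thermodesulfobacteria": 2,
}


class TestRepresentation:
    def test_published_percent_difference(self):
        df = representation_from_counts(TABLE1_FL, TABLE1_V6)
        assert df.loc["Gemmatimonadetes", "percent_difference"] == (
            pytest.approx(-72.2, abs=0.05)
        )

    def test_population_categories(self):
        df = representation_from_counts(TABLE1_FL, TABLE1_V6)
        assert df.loc["Proteobacteria", "category"] == "A"
        assert df.loc["Nitrospira", "category"] == "C"
        assert df.loc["Spirochaetes", "category"] == "D"
        assert df.loc["unclassified", "category"] == "B"

    def test_equal_counts_give_zero_percent(self):
        df = representation_from_counts({"X": 10}, {"X": 10})
        assert df.loc["X", "percent_difference"] == 0.0

    def test_novel_in_region_is_undefined_marker(self):
        df = representation_from_counts(TABLE1_FL, TABLE1_V6)
        assert math.isnan(df.loc["Thermodesulfobacteria", "percent_difference"])
        assert df.loc["Thermodesulfobacteria", "note"] == "novel in region"

    def test_category_thresholds(self):
        assert population_category(1001) == "A"
        assert population_category(1000) == "C"
        assert population_category(101) == "C"
        assert population_category(100) == "D"

    def test_representation_from_assignments(self):
        fl = {f"q{i}": _fake_assignment(6) for i in range(4)}
        rg = {f"q{i}": _fake_assignment(1 if i == 0 else 6) for i in range(4)}
        df = representation(fl, rg)
        assert df.loc["P", "full_length"] == 4
        assert df.loc["P", "region"] == 3
        assert df.loc["P", "percent_difference"] == pytest.approx(-25.0)
        assert df.loc["unclassified", "region"] == 1

    def test_phylum_counts_pools_shallow_assignments(self):
        a = {"q1": _fake_assignment(6), "q2": _fake_assignment(1)}
        c = phylum_counts(a)
        assert c["P"] == 1 and c[UNCLASSIFIED] == 1


def test_genus_accuracy_counts_exact_effective_matches():
    tax = TaxonomyTable({
        "q1": ("B", "P", "C", "O", "F", "G"),
        "q2": ("B", "P", "C", "O", "F", "G2"),
    })
    a = {"q1": _fake_assignment(6), "q2": _fake_assignment(6)}
    assert genus_accuracy(a, tax) == 0.5
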