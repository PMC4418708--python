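import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from dmipred.bayes import (
    DmiBayesClassifier,
    DmiMatch,
    LREntry,
    LRTable,
    aggregate_pair,
    combine_with_ns,
    dmi_lr_prd_motif,
    dmi_lr_struct,
    estimate_clue_lr,
    flag_strong,
    merge_preppi,
    posterior,
    read_lr_table,
    write_lr_table,
)
from dmipred.io import NsEvidenceTable, PairSet
from dmipred.synthetic import SynthConfig, generate_training_sets


def make_table(**lrs) -> LRTable:
    entries = {}
    for clue_id, value_lr in lrs.items():
        for value, lr in value_lr.items():
            entries[(clue_id, value)] = LREntry(1, 1, lr)
    return LRTable(entries, 10, 100)


def brute_force_lr(observations, pairs: PairSet):
    """Oracle: literally count matching pairs in the TP and TN lists."""
    out = {}
    clue_values = {cv for clues in observations.values() for cv in clues}
    for cv in clue_values:
        n_tp = sum(1 for p in pairs.positives if cv in observations.get(p, set()))
        n_tn = sum(1 for p in pairs.negatives if cv in observations.get(p, set()))
        if n_tn == 0:
            out[cv] = 1e6 if n_tp else 1.0
        else:
            out[cv] = (n_tp / pairs.n_tp) / (n_tn / pairs.n_tn)
    return out


class TestEstimateClueLr:
    def test_direct_formula(self, small_pair_set):
        obs = {p: {("diso", True)} for p in small_pair_set.positives[:4]}
        obs |= {p: {("diso", True)} for p in small_pair_set.negatives[:2]}
        table = estimate_clue_lr(obs, small_pair_set)
        assert table.lr("diso", True) == pytest.approx((4 / 10) / (2 / 100))  # = 20

    def test_clue_never_in_tp_gives_zero(self, small_pair_set):
        obs = {p: {("diso", True)} for p in small_pair_set.negatives[:2]}
        table = estimate_clue_lr(obs, small_pair_set)
        assert table.lr("diso", True) == 0.0

    def test_clue_never_in_tn_is_capped_and_flagged(self, small_pair_set):
        obs = {p: {("diso", True)} for p in small_pair_set.positives[:4]}
        table = estimate_clue_lr(obs, small_pair_set)
        entry = table.entries[("diso", True)]
        assert entry.lr == 1e6 and entry.capped

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_clue_lr({}, PairSet([("A", "B")], []))

    def test_smoothing_shrinks_extreme_ratios(self, small_pair_set):
        obs = {p: {("diso", True)} for p in small_pair_set.positives[:4]}
        raw = estimate_clue_lr(obs, small_pair_set)
        smoothed = estimate_clue_lr(obs, small_pair_set, alpha=1.0)
        assert smoothed.lr("diso", True) < raw.lr("diso", True)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_tp, n_tn = int(rng.integers(5, 60)), int(rng.integers(20, 300))
        pairs = PairSet(
            [(f"A{i}", f"B{i}") for i in range(n_tp)],
            [(f"C{i}", f"D{i}") for i in range(n_tn)],
        )
        vocab = [("diso", True), ("diso", False), ("psd", "P1"), ("sim", "B2"),
                 ("class", "CLS0"), ("match", "present")]
        obs = {}
        for p in pairs.positives + pairs.negatives:
            k = int(rng.integers(0, 4))
            if k:
                idx = rng.choice(len(vocab), size=k, replace=False)
                obs[p] = {vocab[i] for i in idx}
        table = estimate_clue_lr(obs, pairs)
        oracle = brute_force_lr(obs, pairs)
        for cv, lr in oracle.items():
            assert table.lr(*cv) == pytest.approx(lr)


class TestDmiFormulas:
    def test_consensus_route_substitution(self):
        table = make_table(
            match={"present": 2.0}, **{"class": {"X": 8.0}},
            diso={True: 4.0}, consv={True: 3.0},
        )
        clues = {"match": "present", "class": "X", "diso": True, "consv": True}
        assert dmi_lr_prd_motif(clues, table) == pytest.approx(2 * 4 * 2 * 1.5)  # 24

    def test_template_route_substitution(self):
        table = make_table(
            match={"present": 2.0}, psd={"P1": 6.0}, sim={"B1": 10.0},
            diso={True: 4.0}, consv={True: 2.0},
        )
        clues = {"match": "present", "psd": "P1", "sim": "B1", "diso": True, "consv": True}
        assert dmi_lr_struct(clues, table) == pytest.approx(2 * 3 * 5 * 2 * 1)  # 60

    @pytest.mark.parametrize("m", [0.5, 1.0, 7.0])
    def test_all_equal_collapses_to_identity(self, m):
        table = make_table(
            match={"present": m}, **{"class": {"X": m}}, psd={"P1": m},
            sim={"B1": m}, diso={True: m}, consv={True: m},
        )
        prd = {"match": "present", "class": "X", "diso": True, "consv": True}
        stc = {"match": "present", "psd": "P1", "sim": "B1", "diso": True, "consv": True}
        assert dmi_lr_prd_motif(prd, table) == pytest.approx(m)
        assert dmi_lr_struct(stc, table) == pytest.approx(m)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.01, 1e3), min_size=5, max_size=5))
    def test_algebraic_reductions(self, lrs):
        m, a, b, c = lrs[0], lrs[1], lrs[2], lrs[3]
        table = make_table(
            match={"present": m}, **{"class": {"X": a}}, psd={"P1": a},
            sim={"B1": lrs[4]}, diso={True: b}, consv={True: c},
        )
        prd = dmi_lr_prd_motif(
            {"match": "present", "class": "X", "diso": True, "consv": True}, table
        )
        assert prd == pytest.approx(a * b * c / m**2, rel=1e-12)
        stc = dmi_lr_struct(
            {"match": "present", "psd": "P1", "sim": "B1", "diso": True, "consv": True},
            table,
        )
        assert stc == pytest.approx(a * lrs[4] * b * c / m**3, rel=1e-12)

    def test_missing_clue_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            dmi_lr_prd_motif({"match": "present"}, make_table(match={"present": 1.0}))

    def test_zero_match_lr_is_an_error(self):
        table = make_table(match={"present": 0.0}, **{"class": {"X": 1.0}},
                           diso={True: 1.0}, consv={True: 1.0})
        with pytest.raises(ValueError, match="match"):
            dmi_lr_prd_motif(
                {"match": "present", "class": "X", "diso": True, "consv": True}, table
            )


def scored_match(pair, lr, method="prd_motif", source="X"):
    return DmiMatch(pair, method, source, (("match", "present"),), lr_dmi=lr)


class TestAggregation:
    def test_max_policy(self):
        ms = [scored_match(("A", "B"), 50.0), scored_match(("A", "B"), 200.0)]
        assert aggregate_pair(ms) == 200.0

    def test_single_match(self):
        assert aggregate_pair([scored_match(("A", "B"), 7.0)]) == 7.0

    def test_product_policy(self):
        ms = [scored_match(("A", "B"), 50.0), scored_match(("A", "B"), 200.0)]
        assert aggregate_pair(ms, policy="product") == pytest.approx(10000.0)

    def test_adding_a_match_never_lowers_the_max(self):
        ms = [scored_match(("A", "B"), 50.0)]
        more = ms + [scored_match(("A", "B"), 3.0)]
        assert aggregate_pair(more) >= aggregate_pair(ms)

    def test_empty_is_neutral(self):
        assert aggregate_pair([]) == 1.0

    def test_mixed_pairs_are_an_error(self):
        ms = [scored_match(("A", "B"), 1.0), scored_match(("A", "C"), 1.0)]
        with pytest.raises(ValueError):
            aggregate_pair(ms)


class TestCombination:
    def test_product_crosses_strong_threshold(self):
        lr = combine_with_ns(24.0, 30.0)
        assert lr == 720.0 and flag_strong(lr)

    def test_neutral_ns(self):
        assert combine_with_ns(24.0, 1.0) == 24.0

    def test_below_threshold(self):
        assert not flag_strong(combine_with_ns(20.0, 20.0))

    def test_nonpositive_is_an_error(self):
        with pytest.raises(ValueError):
            combine_with_ns(0.0, 5.0)

    @pytest.mark.parametrize(
        "orig, dmi, ns, expected",
        [(100.0, 40.0, 2.0, 200.0), (40.0, 100.0, 2.0, 200.0), (0.0, 0.0, 5.0, 0.0)],
    )
    def test_preppi_merge_takes_the_larger(self, orig, dmi, ns, expected):
        assert merge_preppi(orig, dmi, ns) == expected


class TestPosterior:
    def test_calibration_point(self):
        assert posterior(600.0, 1 / 600) == 0.5

    def test_zero_lr(self):
        assert posterior(0.0, 1 / 600) == 0.0

    def test_halved_prior(self):
        assert posterior(600.0, 1 / 1200) == pytest.approx(1 / 3)

    def test_strictly_increasing_in_lr(self):
        lrs = np.linspace(0, 1e6, 50)
        values = [posterior(lr, 1 / 600) for lr in lrs]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert posterior(1e12, 1 / 600) > 0.999999


class TestStrongFlag:
    @pytest.mark.parametrize("lr, expected", [(600.0, False), (600.01, True), (0.0, False)])
    def test_strict_threshold(self, lr, expected):
        assert flag_strong(lr) is expected


class TestClassifier:
    @pytest.fixture
    def fitted(self):
        pairs, matches, _ = generate_training_sets(SynthConfig(seed=5, n_tp=300, n_tn=300))
        clf = DmiBayesClassifier().fit(matches, pairs)
        return clf, pairs, matches

    def test_fit_builds_route_tables(self, fitted):
        clf, *_ = fitted
        assert set(clf.lr_tables_) == {"prd_motif", "struct"}
        assert clf.n_tp_ == clf.n_tn_ == 300

    def test_match_lr_reflects_planted_frequencies(self, fitted):
        clf, *_ = fitted
        lr = clf.lr_tables_["prd_motif"].lr("match", "present")
        assert 10 < lr < 40  # planted ratio 0.4 / 0.02 = 20

    def test_predictions_cover_requested_pairs(self, fitted):
        clf, pairs, matches = fitted
        preds = clf.predict_pairs(matches, pairs.positives[:10])
        assert [p.pair for p in preds] == pairs.positives[:10]
        assert all(p.lr_final > 0 for p in preds)

    def test_pair_without_matches_is_neutral(self, fitted):
        clf, *_ = fitted
        (pred,) = clf.predict_pairs([], [("ZZ1", "ZZ2")])
        assert pred.lr_dmi == 1.0 and pred.lr_final == 1.0 and not pred.strong

    def test_ns_evidence_multiplies(self, fitted):
        clf, *_ = fitted
        ns = NsEvidenceTable({("ZZ1", "ZZ2"): 700.0})
        (pred,) = clf.predict_pairs([], [("ZZ1", "ZZ2")], ns_table=ns)
        assert pred.lr_final == 700.0 and pred.strong

    def test_clue_unseen_in_positives_zeroes_the_pair(self):
        pairs = PairSet([("A1", "B1")], [("C1", "D1"), ("C2", "D2")])
        clues_tp = (("match", "present"), ("class", "X"), ("diso", True), ("consv", True))
        clues_tn = (("match", "present"), ("class", "X"), ("diso", False), ("consv", True))
        train = [
            DmiMatch(("A1", "B1"), "prd_motif", "X", clues_tp),
            DmiMatch(("C1", "D1"), "prd_motif", "X", clues_tn),
        ]
        clf = DmiBayesClassifier().fit(train, pairs)
        test = DmiMatch(("C2", "D2"), "prd_motif", "X", clues_tn)
        ns = NsEvidenceTable({("C2", "D2"): 1e6})
        (pred,) = clf.predict_pairs([test], [("C2", "D2")], ns_table=ns)
        assert pred.lr_dmi == 0.0 and pred.lr_final == 0.0 and not pred.strong

    def test_sklearn_clone_round_trip(self):
        clf = DmiBayesClassifier(alpha=0.5, lr_cap=1e4, policy="product")
        params = clf.get_params()
        assert params["alpha"] == 0.5
        cloned = clone(clf)
        assert cloned.get_params() == params

    def test_unfitted_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            DmiBayesClassifier().score_matches([])


def test_lr_table_round_trip(tmp_path):
    pairs = PairSet([("A", "B"), ("C", "D")], [("E", "F"), ("G", "H"), ("I", "J")])
    obs = {
        ("A", "B"): {("match", "present"), ("diso", True)},
        ("E", "F"): {("match", "present"), ("diso", False)},
    }
    table = estimate_clue_lr(obs, pairs)
    write_lr_table(tmp_path / "lr.tsv", table)
    back = read_lr_table(tmp_path / "lr.tsv")
    assert back.n_tp_total == 2 and back.n_tn_total == 3
    for cv, entry in table.entries.items():
        assert back.lr(*cv) == pytest.approx(entry.lr)
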