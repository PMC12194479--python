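"""Tanimoto applicability domain: similarity oracles, threshold logic,
stratified metrics and high-confidence-error reporting."""

import numpy as np
import pytest

from qsdar.descriptors import FingerprintVector, compute_fingerprint
from qsdar.domain import (HighConfidenceError, assess_domain,
                          high_confidence_errors, in_domain,
                          max_train_similarity, stratified_metrics, tanimoto)
from qsdar.models import ConfusionMatrix


def _fp64(bits_on):
    """A path2048-kind fingerprint with the given bits set (set-based oracle
    uses only the first 64 positions)."""
    bits = np.zeros(2048, dtype=np.uint8)
    bits[list(bits_on)] = 1
    return FingerprintVector("path2048", bits)


def set_tanimoto(a: set, b: set) -> float:
    """Independent set-based oracle."""
    return len(a & b) / len(a | b) if (a | b) else 0.0


class TestTanimoto:
    def test_identical_nonempty_is_one(self):
        fp = _fp64({1, 5, 9})
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(_fp64({0, 1}), _fp64({5, 6})) == 0.0

    def test_set_formula(self):
        # |A∩B|=3, |A|=5, |B|=4 -> 3/6
        a = _fp64({0, 1, 2, 3, 4})
        b = _fp64({2, 3, 4, 10})
        assert tanimoto(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert tanimoto(_fp64(set()), _fp64(set())) == 0.0

    def test_kind_mismatch_rejected(self):
        a = compute_fingerprint("CCO", "maccs166")
        b = compute_fingerprint("CCO", "path2048")
        with pytest.raises(ValueError):
            tanimoto(a, b)

    def test_matches_set_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            a = set(rng.choice(64, size=rng.integers(0, 20), replace=False).tolist())
            b = set(rng.choice(64, size=rng.integers(0, 20), replace=False).tolist())
            if not a and not b:
                continue
            assert tanimoto(_fp64(a), _fp64(b)) == pytest.approx(set_tanimoto(a, b))

    def test_symmetry(self, rng):
        for _ in range(50):
            a = _fp64(set(rng.choice(64, size=10, replace=False).tolist()))
            b = _fp64(set(rng.choice(64, size=10, replace=False).tolist()))
            assert tanimoto(a, b) == tanimoto(b, a)

    def test_agrees_with_rdkit_oracle(self):
        from rdkit import DataStructs
        from rdkit.Chem import rdFingerprintGenerator
        from rdkit import Chem
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)
        pairs = [("CCO", "CCN"), ("c1ccccc1O", "c1ccccc1N"),
                 ("CC(=O)Oc1ccccc1C(=O)O", "O=C(O)c1ccccc1O")]
        for s1, s2 in pairs:
            ours = tanimoto(compute_fingerprint(s1, "path2048"),
                            compute_fingerprint(s2, "path2048"))
            theirs = DataStructs.TanimotoSimilarity(
                gen.GetFingerprint(Chem.MolFromSmiles(s1)),
                gen.GetFingerprint(Chem.MolFromSmiles(s2)))
            assert ours == pytest.approx(theirs)


class TestMaxTrainSimilarity:
    def test_query_in_training_set_is_one(self, rng):
        train = [_fp64(set(rng.choice(64, size=8, replace=False).tolist()))
                 for _ in range(20)]
        tc, idx = max_train_similarity(train[7], train)
        assert tc == 1.0

    def test_single_disjoint_training_fp(self):
        tc, idx = max_train_similarity(_fp64({1, 2}), [_fp64({40, 41})])
        assert tc == 0.0 and idx == 0

    def test_matches_exhaustive_scan(self, rng):
        train = [_fp64(set(rng.choice(64, size=int(rng.integers(1, 20)),
                                      replace=False).tolist()))
                 for _ in range(100)]
        for _ in range(20):
            q = _fp64(set(rng.choice(64, size=10, replace=False).tolist()))
            tc, idx = max_train_similarity(q, train)
            brute = [tanimoto(q, t) for t in train]
            assert tc == pytest.approx(max(brute))
            assert idx == int(np.argmax(brute))  # first-by-order tie break

    def test_ids_returned_when_given(self):
        train = [_fp64({1}), _fp64({1, 2})]
        tc, ident = max_train_similarity(_fp64({1}), train, ["t0", "t1"])
        assert (tc, ident) == (1.0, "t0")

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            max_train_similarity(_fp64({1}), [])


class TestInDomain:
    @pytest.mark.parametrize("tc,prob,expected", [
        (0.95, 0.50, True),   # similarity branch
        (0.90, 0.00, True),   # inclusive TC bound
        (0.50, 0.85, True),   # probability branch
        (0.50, 0.80, True),   # inclusive probability bound
        (0.89, 0.79, False),  # both just below
        (0.00, 0.00, False),
    ])
    def test_disjunction(self, tc, prob, expected):
        assert in_domain(tc, prob) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            in_domain(1.5, 0.5)
        with pytest.raises(ValueError):
            in_domain(0.5, -0.1)

    def test_monotone_in_thresholds(self, rng):
        # raising either threshold can only shrink the in-domain set
        tcs = rng.uniform(size=200)
        probs = rng.uniform(size=200)
        base = np.array([in_domain(t, p) for t, p in zip(tcs, probs)])
        for tc_thr, p_thr in [(0.95, 0.8), (0.90, 0.9), (0.99, 0.99)]:
            tighter = np.array([in_domain(t, p, tc_thr, p_thr)
                                for t, p in zip(tcs, probs)])
            assert not np.any(tighter & ~base)

    def test_training_member_always_in_domain(self, rng):
        train = [_fp64(set(rng.choice(64, size=8, replace=False).tolist()))
                 for _ in range(10)]
        ad = assess_domain(["q"], [train[3]], [0.0], train, list("abcdefghij"))
        assert ad[0].in_domain and ad[0].tc_max == 1.0


class TestStratifiedMetrics:
    def _random_case(self, rng, n=200):
        y_true = rng.choice(["active", "inactive"], size=n)
        y_pred = rng.choice(["active", "inactive"], size=n)
        mask = rng.uniform(size=n) < 0.6
        return y_pred, y_true, mask

    def test_stratum_additivity(self, rng):
        for _ in range(20):
            y_pred, y_true, mask = self._random_case(rng)
            rep = stratified_metrics(y_pred, y_true, mask)
            total = rep.in_domain.confusion + rep.out_of_domain.confusion
            assert total == rep.overall

    def test_all_in_domain_equals_overall(self, rng):
        y_pred, y_true, _ = self._random_case(rng)
        rep = stratified_metrics(y_pred, y_true, np.ones(len(y_pred), bool))
        assert rep.in_domain.confusion == rep.overall
        assert rep.out_of_domain.confusion is None
        assert rep.out_of_domain.metrics is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stratified_metrics(["active"], ["active", "inactive"], [True, False])


class TestHighConfidenceErrors:
    def _setup(self, rng):
        train = [_fp64(set(rng.choice(64, size=8, replace=False).tolist()))
                 for _ in range(5)]
        train_ids = [f"t{i}" for i in range(5)]
        cv_pred = ["active", "inactive", "active", "inactive", "active"]
        return train, train_ids, cv_pred

    def test_perfect_classifier_empty_list(self, rng):
        train, train_ids, cv = self._setup(rng)
        out = high_confidence_errors(
            ["a"], ["active"], [0.99], ["active"], [train[0]], train,
            train_ids, cv)
        assert out == []

    def test_strict_probability_threshold(self, rng):
        train, train_ids, cv = self._setup(rng)
        common = dict(training_fps=train, training_ids=train_ids,
                      training_cv_predictions=cv)
        listed = high_confidence_errors(
            ["a"], ["inactive"], [0.81], ["active"], [train[0]], **common)
        assert len(listed) == 1 and listed[0].error_type == "FN"
        boundary = high_confidence_errors(
            ["a"], ["inactive"], [0.80], ["active"], [train[0]], **common)
        assert boundary == []

    def test_neighbour_annotation(self, rng):
        train, train_ids, cv = self._setup(rng)
        err = high_confidence_errors(
            ["q"], ["active"], [0.95], ["inactive"], [train[2]], train,
            train_ids, cv)[0]
        assert isinstance(err, HighConfidenceError)
        assert err.error_type == "FP"
        assert err.nearest_training_id == "t2"
        assert err.tc_to_nearest == 1.0
        assert err.nearest_training_predicted_class == "active"

    def test_threshold_validated(self, rng):
        train, train_ids, cv = self._setup(rng)
        with pytest.raises(ValueError):
            high_confidence_errors(["a"], ["active"], [0.9], ["inactive"],
                                   [train[0]], train, train_ids, cv,
                                   prob_threshold=1.5)


def test_admission_fraction_consistent_with_counts():
    # 992 of 1202 in-domain is 83% to the nearest percent
    report = stratified_metrics(
        ["active"] * 1202,
        ["active"] * 1202,
        [True] * 992 + [False] * 210)
    n_in = report.in_domain.confusion.total
    n_out = report.out_of_domain.confusion.total
    assert (n_in, n_out) == (992, 210)
    assert round(100 * n_in / (n_in + n_out)) == 83
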