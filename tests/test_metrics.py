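import numpy as np
import pytest

from conftest import random_scored
from designbench.io_formats import ALPHABET, AA_INDEX
from designbench.metrics import (GroupMetrics, ScoredResidue, argmax_labels,
                                 build_confusion, group_metrics,
                                 per_class_metrics, resolution_correlation,
                                 similar_pairs, stratified_metrics,
                                 true_labels)


def one_hot(letter):
    v = np.zeros(20)
    v[AA_INDEX[letter]] = 1.0
    return v


def make(aa_true, probs, **kw):
    defaults = dict(chain_key="x_A", ss="C", fold_class="special",
                    architecture_code="6.10")
    defaults.update(kw)
    return ScoredResidue(aa_true=aa_true, probs=probs, **defaults)


def perfect_scored(seq, **kw):
    return [make(a, one_hot(a), **kw) for a in seq]


class TestConfusion:
    def test_perfect_predictor_is_diagonal(self):
        scored = perfect_scored("ACDEFACDEF")
        cm = build_confusion(scored)
        assert cm.n == 10
        assert np.trace(cm.counts) == 10
        assert (cm.counts == np.diag(np.diag(cm.counts))).all()

    def test_constant_predictor_single_column(self):
        scored = [make(a, one_hot("A")) for a in "CDEFG"]
        cm = build_confusion(scored)
        assert cm.counts[:, 0].sum() == 5
        assert cm.counts[:, 1:].sum() == 0

    def test_matches_brute_force_on_random_rows(self):
        rng = np.random.default_rng(11)
        scored = random_scored(rng, 200)
        cm = build_confusion(scored)
        # independent double loop over the same rows
        brute = np.zeros((20, 20), dtype=int)
        for r in scored:
            t = AA_INDEX[r.aa_true]
            p = int(np.argmax(r.probs))
            brute[t, p] += 1
        np.testing.assert_array_equal(cm.counts, brute)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_confusion([])


def brute_force_auc(scores, positive):
    """Pairwise concordance count: (#concordant + 0.5 * #ties) / #pairs."""
    pos = scores[positive]
    neg = scores[~positive]
    if len(pos) == 0 or len(neg) == 0:
        return None
    conc = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                conc += 1
            elif p == q:
                ties += 1
    return (conc + 0.5 * ties) / (len(pos) * len(neg))


class TestPerClass:
    def test_perfect_predictor_identity_values(self):
        scored = perfect_scored("ACDEFGHIKLMNPQRSTVWY")
        df = per_class_metrics(scored)
        assert (df["recall"] == 1.0).all()
        assert (df["precision"] == 1.0).all()
        assert (df["f1"] == 1.0).all()
        assert (df["auc"] == 1.0).all()
        assert (df["entropy_bits"] == 0.0).all()
        assert (df["bias"] == 0.0).all()

    def test_bias_formula(self):
        # A occurs 10 times, predicted 15 times -> bias +0.5
        # C occurs 10 times, never predicted -> bias -1.0
        scored = [make("A", one_hot("A")) for _ in range(10)] + \
                 [make("C", one_hot("A")) for _ in range(5)] + \
                 [make("C", one_hot("D")) for _ in range(5)]
        df = per_class_metrics(scored)
        assert df.loc["A", "bias"] == pytest.approx(0.5)
        assert df.loc["C", "bias"] == pytest.approx(-1.0)

    def test_absent_class_metrics_are_nan(self):
        df = per_class_metrics(perfect_scored("AAAA"))
        assert np.isnan(df.loc["W", "recall"])
        assert np.isnan(df.loc["W", "bias"])

    def test_uniform_confusion_row_entropy_is_log2_20(self):
        scored = [make("A", one_hot(b)) for b in ALPHABET]
        df = per_class_metrics(scored)
        assert df.loc["A", "entropy_bits"] == pytest.approx(np.log2(20))

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        scored = random_scored(rng, 300)
        df = per_class_metrics(scored)
        probs = np.array([r.probs for r in scored])
        t = true_labels(scored)
        for i, aa in enumerate(ALPHABET):
            expected = brute_force_auc(probs[:, i], t == i)
            if expected is None:
                assert np.isnan(df.loc[aa, "auc"])
            else:
                assert df.loc[aa, "auc"] == pytest.approx(expected, abs=1e-9)

    def test_auc_with_ties_uses_midranks(self):
        # identical scores for every residue: AUC = 0.5 for present classes
        scored = [make(a, np.full(20, 0.05)) for a in "AACC"]
        df = per_class_metrics(scored)
        assert df.loc["A", "auc"] == pytest.approx(0.5)
        assert df.loc["C", "auc"] == pytest.approx(0.5)

    def test_auc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        scored = random_scored(rng, 250)
        df = per_class_metrics(scored)
        probs = np.array([r.probs for r in scored])
        t = true_labels(scored)
        for i, aa in enumerate(ALPHABET):
            y = (t == i).astype(int)
            if 0 < y.sum() < len(y):
                assert df.loc[aa, "auc"] == pytest.approx(
                    roc_auc_score(y, probs[:, i]), abs=1e-12)


class TestGroupMetrics:
    def test_perfect_predictor(self):
        gm = group_metrics(perfect_scored("ACDEFGHIKL"))
        assert gm.accuracy == gm.macro_recall == gm.similarity == gm.top3 == 1.0

    def test_macro_recall_is_unweighted_mean(self):
        # class A recall 1.0 (2/2), class C recall 0.5 (1/2)
        scored = [make("A", one_hot("A")), make("A", one_hot("A")),
                  make("C", one_hot("C")), make("C", one_hot("A"))]
        gm = group_metrics(scored)
        assert gm.macro_recall == pytest.approx(0.75)

    def test_similarity_counts_conservative_substitution(self):
        # BLOSUM62 score(L, I) = 2 > 0: I-for-L is similar but inaccurate
        sim = similar_pairs()
        assert sim[AA_INDEX["L"], AA_INDEX["I"]]
        scored = [make("L", one_hot("I")) for _ in range(10)]
        gm = group_metrics(scored)
        assert gm.accuracy == 0.0
        assert gm.similarity == 1.0

    def test_dissimilar_substitution_not_counted(self):
        sim = similar_pairs()
        assert not sim[AA_INDEX["W"], AA_INDEX["C"]]  # BLOSUM62 -2
        gm = group_metrics([make("W", one_hot("C"))])
        assert gm.similarity == 0.0

    def test_top3_with_alphabet_tie_break(self):
        # uniform vector: top-3 = {A, C, D} by alphabet order
        scored = [make("A", np.full(20, 0.05)),
                  make("D", np.full(20, 0.05)),
                  make("E", np.full(20, 0.05))]
        gm = group_metrics(scored)
        assert gm.top3 == pytest.approx(2 / 3)

    def test_top3_never_below_accuracy(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            gm = group_metrics(random_scored(rng, 80))
            assert gm.top3 >= gm.accuracy

    def test_imbalance_property(self):
        """Constant majority-class predictor on a 90/10 set: accuracy 0.9
        but macro-recall 0.5 — the reason macro-recall is the headline
        imbalance-resistant score."""
        scored = [make("L", one_hot("L")) for _ in range(90)] + \
                 [make("W", one_hot("L")) for _ in range(10)]
        gm = group_metrics(scored)
        assert gm.accuracy == pytest.approx(0.9)
        assert gm.macro_recall == pytest.approx(0.5)

    def test_bounds_on_random_inputs(self):
        rng = np.random.default_rng(22)
        df = per_class_metrics(random_scored(rng, 150))
        for col in ("recall", "precision", "f1", "auc"):
            vals = df[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
        ent = df["entropy_bits"].dropna()
        assert ((ent >= 0) & (ent <= np.log2(20) + 1e-12)).all()
        assert (df["bias"].dropna() >= -1).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(23)
        scored = random_scored(rng, 120)
        gm1 = group_metrics(scored)
        shuffled = list(scored)
        rng.shuffle(shuffled)
        assert group_metrics(shuffled) == gm1


class TestStratified:
    def test_single_stratum_equals_global(self):
        rng = np.random.default_rng(31)
        scored = random_scored(rng, 100)
        strat = stratified_metrics(scored, lambda r: "all")
        assert strat == {"all": group_metrics(scored)}

    def test_perfect_predictor_every_stratum(self):
        scored = perfect_scored("ACDEFGHIKL" * 3)
        for i, r in enumerate(scored):
            r.ss = "HEC"[i % 3]
        strat = stratified_metrics(scored, lambda r: r.ss)
        assert all(gm.accuracy == 1.0 for gm in strat.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_weighted_stratum_accuracy_conserves_global(self, seed):
        rng = np.random.default_rng(500 + seed)
        scored = random_scored(rng, 200)
        strat = stratified_metrics(scored, lambda r: r.fold_class)
        total = sum(gm.n_residues for gm in strat.values())
        weighted = sum(gm.accuracy * gm.n_residues
                       for gm in strat.values()) / total
        assert weighted == pytest.approx(group_metrics(scored).accuracy,
                                         abs=1e-12)


class TestResolutionCorrelation:
    def test_exact_linear_negative(self):
        pts = [(1.0 - 0.1 * r, float(r)) for r in range(1, 8)]
        assert resolution_correlation(pts) == pytest.approx(-1.0)

    def test_constant_accuracy_is_absent(self):
        assert resolution_correlation([(0.5, 1.0), (0.5, 2.0),
                                       (0.5, 3.0)]) is None

    def test_too_few_points_is_absent(self):
        assert resolution_correlation([(0.4, 1.0), (0.9, None),
                                       (0.5, 2.0)]) is None

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(61)
        pts = [(float(a), float(r))
               for a, r in zip(rng.random(50), 1 + 2 * rng.random(50))]
        acc = np.array([a for a, _ in pts])
        res = np.array([r for _, r in pts])
        expected = (np.mean(acc * res) - acc.mean() * res.mean()) / \
            (acc.std() * res.std())
        assert resolution_correlation(pts) == pytest.approx(expected,
                                                            abs=1e-12)
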