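"""Stratified, class-imbalance-aware metrics for sequence-design output.

The evaluation unit is a list of :class:`ScoredResidue` — aligned
(native residue, predicted probability vector) pairs carrying the
stratification labels (chain, secondary structure, CATH fold class and
architecture, crystal resolution).  Four metric groups are computed:

1. per amino-acid class: recall, precision, F1, one-vs-rest ROC AUC,
   Shannon entropy of the confusion row, and prediction bias;
2. per chain: accuracy, macro-precision, macro-recall, similarity,
   top-3 accuracy;
3. the same, per secondary-structure state;
4. the same, per CATH architecture (and fold class).

Amino-acid composition in proteins is heavily imbalanced, so a method
overpredicting common residues can score deceptively well on plain
accuracy; macro-recall (the unweighted mean of per-class recalls) is
the imbalance-resistant headline number, and prediction bias makes the
over/under-prediction per class explicit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ALPHABET, AA_INDEX

logger = logging.getLogger(__name__)

N_AA = len(ALPHABET)


@dataclass
class ScoredResidue:
    """One aligned (native, predicted-distribution) observation."""

    chain_key: str
    aa_true: str
    probs: np.ndarray
    ss: str = "C"
    fold_class: str = "special"
    architecture_code: str = "0.0"
    resolution: float | None = None

    def __post_init__(self):
        if self.aa_true not in AA_INDEX:
            raise ValueError(f"aa_true {self.aa_true!r} not in alphabet")


@dataclass
class ConfusionMatrix:
    """20x20 count table; rows = native class, columns = argmax class."""

    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(ALPHABET),
                            columns=list(ALPHABET))


@dataclass
class GroupMetrics:
    accuracy: float
    macro_precision: float | None
    macro_recall: float | None
    similarity: float
    top3: float
    n_residues: int


def argmax_labels(scored: list[ScoredResidue]) -> np.ndarray:
    """Predicted class index per residue: argmax of the probability
    vector, ties broken by alphabet order (first maximum)."""
    probs = np.array([r.probs for r in scored])
    return probs.argmax(axis=1)


def true_labels(scored: list[ScoredResidue]) -> np.ndarray:
    return np.array([AA_INDEX[r.aa_true] for r in scored])


def build_confusion(scored: list[ScoredResidue]) -> ConfusionMatrix:
    """Count native-vs-predicted pairs into the 20x20 confusion matrix."""
    if not scored:
        raise ValueError("cannot build confusion matrix from no residues")
    t = true_labels(scored)
    p = argmax_labels(scored)
    counts = np.zeros((N_AA, N_AA), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts)


def _auc_mann_whitney(scores: np.ndarray, positive: np.ndarray) -> float | None:
    """One-vs-rest ROC AUC via the rank-sum (Mann-Whitney) statistic with
    midrank tie handling.  None when a class is empty."""
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(scores)  # midranks
    rank_sum = ranks[positive].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def per_class_metrics(scored: list[ScoredResidue],
                      cm: ConfusionMatrix | None = None) -> pd.DataFrame:
    """Per amino-acid recall, precision, F1, AUC, confusion-row entropy
    and prediction bias.

    * recall(a) = cm[a,a] / row-sum(a); precision(a) = cm[a,a] /
      column-sum(a); F1 their harmonic mean.
    * AUC(a): one-vs-rest, using the predicted probability of ``a`` as
      the score over all residues.
    * entropy_bits(a): Shannon entropy of row ``a`` of the confusion
      matrix, normalized — 0 for a class always predicted as one letter,
      log2(20) if its predictions are spread uniformly.
    * bias(a) = (n_predicted(a) - n_true(a)) / n_true(a) — signed
      over/under-prediction relative to the class's natural abundance
      (-1: never predicted; 0: calibrated).

    Metrics with a zero denominator are NaN (absent).
    """
    if cm is None:
        cm = build_confusion(scored)
    counts = cm.counts.astype(float)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    diag = np.diag(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, diag / row, np.nan)
        precision = np.where(col > 0, diag / col, np.nan)
        f1 = np.where((recall + precision) > 0,
                      2 * recall * precision / (recall + precision), np.nan)
        bias = np.where(row > 0, (col - row) / row, np.nan)
    entropy = np.full(N_AA, np.nan)
    for i in range(N_AA):
        if row[i] > 0:
            q = counts[i] / row[i]
            q = q[q > 0]
            entropy[i] = float(-(q * np.log2(q)).sum())
    probs = np.array([r.probs for r in scored])
    t = true_labels(scored)
    auc = np.full(N_AA, np.nan)
    for i in range(N_AA):
        a = _auc_mann_whitney(probs[:, i], t == i)
        if a is not None:
            auc[i] = a
    return pd.DataFrame(
        {"recall": recall, "precision": precision, "f1": f1, "auc": auc,
         "entropy_bits": entropy, "bias": bias},
        index=list(ALPHABET))


# -- similarity -------------------------------------------------------------

def _blosum62_similar() -> np.ndarray:
    """Boolean 20x20 table: substitution-matrix log-odds score > 0.

    Positive BLOSUM62 score means the pair substitutes more often than
    chance in nature — the relaxation used by the similarity metric.
    """
    from Bio.Align import substitution_matrices
    m = substitution_matrices.load("BLOSUM62")
    sim = np.zeros((N_AA, N_AA), dtype=bool)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            sim[i, j] = m[a, b] > 0
    np.fill_diagonal(sim, True)
    return sim


_SIMILAR: np.ndarray | None = None


def similar_pairs() -> np.ndarray:
    global _SIMILAR
    if _SIMILAR is None:
        _SIMILAR = _blosum62_similar()
    return _SIMILAR


def group_metrics(scored: list[ScoredResidue]) -> GroupMetrics:
    """Accuracy, macro-precision, macro-recall, similarity and top-3
    accuracy over one evaluation unit.

    Macro averages are over classes that occur (recall) or occur and are
    predicted (precision); absent classes are skipped, not imputed, so a
    short chain is not penalized for missing rare residues.  Similarity
    counts a substitution-matrix-positive predicted residue as correct.
    Top-3 ranks probabilities with alphabet-order tie-breaking.
    """
    if not scored:
        raise ValueError("cannot compute metrics for no residues")
    t = true_labels(scored)
    p = argmax_labels(scored)
    n = len(scored)
    accuracy = float((t == p).mean())

    cm = build_confusion(scored)
    counts = cm.counts.astype(float)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    diag = np.diag(counts)
    rec = diag[row > 0] / row[row > 0]
    macro_recall = float(rec.mean()) if len(rec) else None
    mask_p = (row > 0) & (col > 0)
    prec = diag[mask_p] / col[mask_p]
    macro_precision = float(prec.mean()) if len(prec) else None

    sim = similar_pairs()
    similarity = float(sim[t, p].mean())

    probs = np.array([r.probs for r in scored])
    # stable sort on (-prob, alphabet index): ties go to earlier letters
    order = np.argsort(-probs, axis=1, kind="stable")
    top3 = float(np.mean([t[i] in order[i, :3] for i in range(n)]))

    return GroupMetrics(accuracy=accuracy, macro_precision=macro_precision,
                        macro_recall=macro_recall, similarity=similarity,
                        top3=top3, n_residues=n)


def stratified_metrics(scored: list[ScoredResidue],
                       label_fn) -> dict[str, GroupMetrics]:
    """Group metrics computed independently within each stratum that
    ``label_fn`` assigns; empty strata are simply absent."""
    buckets: dict[str, list[ScoredResidue]] = {}
    for r in scored:
        buckets.setdefault(label_fn(r), []).append(r)
    return {k: group_metrics(v) for k, v in sorted(buckets.items())}


def resolution_correlation(per_chain: list[tuple[float, float | None]]
                           ) -> float | None:
    """Pearson correlation between per-chain accuracy and crystal
    resolution.

    Chains without a resolution are excluded; needs >= 3 usable points
    and non-zero variance in both variables, otherwise None with a
    logged warning.
    """
    pts = [(a, r) for a, r in per_chain if r is not None]
    if len(pts) < 3:
        logger.warning("resolution correlation: only %d usable chains (<3)",
                       len(pts))
        return None
    acc = np.array([a for a, _ in pts])
    res = np.array([r for _, r in pts])
    if np.ptp(acc) == 0 or np.ptp(res) == 0:
        logger.warning("resolution correlation: zero variance")
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, _ = stats.pearsonr(acc, res)
    return float(r)
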