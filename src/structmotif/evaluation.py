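"""Assessment metrics: Ψ-divergence between PFMs and ROC/AUC over rankings.

The Ψ statistic compares two column-stochastic PFMs of equal width:

    Ψ = (1/w) Σ_j Σ_i (a_ij − b_ij)² / (a_ij + b_ij)        (0/0 terms = 0)

It is zero iff the matrices are identical, symmetric, and bounded by 2 per
column; smaller means more consistent.  PFMs of unequal width are compared
after an ungapped alignment scan over both strands.  AUC is the rank-sum
(Mann–Whitney) statistic, with ties contributing half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from . import chemistry
from .specificity import Pfm


class EvaluationError(ValueError):
    pass


@dataclass
class LabeledRanking:
    """Scored sequences with binary labels (True = positive)."""

    items: list[tuple[str, float, bool]]

    @property
    def n_positive(self) -> int:
        return sum(1 for _, _, lab in self.items if lab)

    @property
    def n_negative(self) -> int:
        return sum(1 for _, _, lab in self.items if not lab)


def psi_test(predicted: Pfm, annotated: Pfm) -> float:
    """Width-averaged symmetric quadratic divergence between two PFMs."""
    if predicted.width != annotated.width:
        raise EvaluationError(
            f"width mismatch {predicted.width} != {annotated.width}; "
            "use align_pfms for unequal widths")
    a = predicted.frequencies
    b = annotated.frequencies
    num = (a - b) ** 2
    den = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(terms.sum() / predicted.width)


def align_pfms(predicted: Pfm, annotated: Pfm) -> tuple[int, str, float]:
    """Best ungapped alignment of two PFMs over both strands.

    Scans every offset of the shorter matrix along the longer one (overlap
    >= 1 column) on the forward and reverse-complement strand of the
    annotated matrix, minimizing the overlap-normalized Ψ.  Returns
    (offset, strand, psi) where `offset` is the shift of `annotated`
    relative to `predicted` (may be negative) and strand is 'forward' or
    'reverse'.  Ties prefer forward strand, then the smallest offset.
    """
    best: tuple[float, int, int] | None = None  # (psi, strand_rank, offset)
    strands = {"forward": annotated, "reverse": annotated.reverse_complement()}
    wp = predicted.width
    for rank, (strand, ann) in enumerate(strands.items()):
        wa = ann.width
        for offset in range(-(wa - 1), wp):
            lo_p = max(0, offset)
            hi_p = min(wp, offset + wa)
            if hi_p <= lo_p:
                continue
            sub_p = Pfm(predicted.frequencies[lo_p:hi_p])
            sub_a = Pfm(ann.frequencies[lo_p - offset:hi_p - offset])
            psi = psi_test(sub_p, sub_a)
            cand = (psi, rank, offset)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise EvaluationError("no valid overlap between the PFMs")
    psi, rank, offset = best
    return offset, ("forward", "reverse")[rank], psi


def auc(ranking: LabeledRanking) -> float:
    """Mann-Whitney AUC of the positives over the negatives."""
    n_pos, n_neg = ranking.n_positive, ranking.n_negative
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC needs at least one positive and one negative")
    scores = np.array([s for _, s, _ in ranking.items], dtype=float)
    labels = np.array([lab for _, _, lab in ranking.items], dtype=bool)
    ranks = rankdata(scores)  # average ranks on ties -> 0.5 per tied pair
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def top_k_positives(scores: list[tuple[str, float]], k: int) -> LabeledRanking:
    """Label the top-k reference-scored sequences positive.

    Boundary ties are broken by sequence lexicographic order so the labeling
    is deterministic.  The returned ranking keeps the input order and the
    input scores.
    """
    if k <= 0:
        raise EvaluationError("k must be positive")
    if k >= len(scores):
        raise EvaluationError("k must be smaller than the number of sequences")
    order = sorted(scores, key=lambda t: (-t[1], t[0]))
    positives = {seq for seq, _ in order[:k]}
    return LabeledRanking([(seq, sc, seq in positives) for seq, sc in scores])


def sensitivity_specificity(ranking: LabeledRanking,
                            threshold: float) -> tuple[float, float]:
    """(TPR, TNR) calling scores >= threshold positive."""
    tp = fn = tn = fp = 0
    for _, score, label in ranking.items:
        called = score >= threshold
        if label:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    tnr = tn / (tn + fp) if (tn + fp) else float("nan")
    return tpr, tnr


def average_probe_scores(probes: list[tuple[str, float]], kmer: str) -> float:
    """Mean intensity over probes containing the k-mer or its reverse complement.

    Generic stand-in for probe-level binding data: each probe is a
    (sequence, intensity) pair; the relative specificity of `kmer` is the
    average intensity across every probe containing it on either strand.
    """
    kmer = kmer.upper()
    rc = chemistry.reverse_complement(kmer)
    hits = [x for seq, x in probes
            if kmer in seq.upper() or rc in seq.upper()]
    if not hits:
        raise EvaluationError(f"no probe contains {kmer} or its complement")
    return float(np.mean(hits))
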