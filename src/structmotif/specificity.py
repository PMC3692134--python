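"""Mutant enumeration, energy-based selection, PFM construction and scoring.

The pipeline enumerates every sequence within a Hamming ball of the native
binding site (each mutated position can take any of the three non-native
bases), synthesizes the corresponding structure by rigid base-pair
replacement, scores it with the knowledge-based potential, keeps mutants
passing the flexibility criterion, and summarizes the survivors as a
position frequency matrix (PFM) used to score and re-rank sequences.

Flexibility criterion: with T = |min over mutants of (dG' - dG_native)|,
a mutant is kept iff its dG change is <= T.  A negative change is preferred,
but a positive change within the acceptable flexibility range still counts
as favourable; the native sequence always passes (its change is 0 <= T).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import chemistry
from .base_geometry import BaseTemplate, mutate_pair, rmsd
from .potential import PotentialTable, delta_delta_g, delta_g
from .structure_io import ComplexStructure, DsDnaDuplex

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

#: pseudo-frequency added when scoring against a PFM
PFM_EPSILON = 0.01
_BACKGROUND = 0.25


class SpecificityError(ValueError):
    pass


@dataclass
class MutantRecord:
    """One (possibly mutated) binding-site sequence with its scores."""

    sequence: str
    n_mutations: int
    dg: float
    ddg: float
    rmsd: float
    pfm_score: float = math.nan
    selected: bool = False


@dataclass(frozen=True)
class Pfm:
    """A w x 4 column-stochastic position frequency matrix (order A,C,G,T)."""

    frequencies: np.ndarray
    support: int = 0

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise SpecificityError("PFM must be w x 4")
        if np.any(freq < 0):
            raise SpecificityError("PFM entries must be non-negative")
        sums = freq.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise SpecificityError("PFM columns must sum to 1")
        object.__setattr__(self, "frequencies", freq)

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    def reverse_complement(self) -> "Pfm":
        # reverse position order and swap A<->T, C<->G
        rc = self.frequencies[::-1][:, [3, 2, 1, 0]]
        return Pfm(rc, self.support)


def enumerate_mutants(native: str, positions: tuple[int, int] | None = None,
                      max_mutations: int = 2,
                      include_native: bool = False) -> list[str]:
    """All sequences within `max_mutations` of `native` inside `positions`.

    `positions` is a 1-based inclusive range along the site (default: the
    whole site); each mutated position takes any of its three non-native
    bases.  The result is in lexicographic order and deterministic.
    """
    native = native.upper()
    if set(native) - set(BASE_ORDER):
        raise SpecificityError(f"invalid native sequence {native!r}")
    w = len(native)
    lo, hi = positions if positions is not None else (1, w)
    if not (1 <= lo <= hi <= w):
        raise SpecificityError(
            f"position range {lo}:{hi} outside sequence of length {w}")
    region = list(range(lo - 1, hi))
    k = min(max_mutations, len(region))
    if k < 1:
        raise SpecificityError("max_mutations must be >= 1")
    out: list[str] = [native] if include_native else []
    for m in range(1, k + 1):
        for pos_combo in itertools.combinations(region, m):
            alt = [[b for b in BASE_ORDER if b != native[p]] for p in pos_combo]
            for bases in itertools.product(*alt):
                s = list(native)
                for p, b in zip(pos_combo, bases):
                    s[p] = b
                out.append("".join(s))
    out.sort()
    return out


def mutant_count(w: int, k: int, include_native: bool = False) -> int:
    """Closed form: sum_{m=1..k} C(w, m) * 3^m (+1 if native included)."""
    total = sum(math.comb(w, m) * 3 ** m for m in range(1, k + 1))
    return total + (1 if include_native else 0)


def flexibility_filter(records: list[MutantRecord],
                       native_dg: float) -> list[MutantRecord]:
    """Set `selected` flags by the flexibility criterion (in place)."""
    mutants = [r for r in records if r.n_mutations > 0]
    if not mutants:
        warnings.warn("no mutants to filter; selecting native only",
                      stacklevel=2)
        for r in records:
            r.selected = r.n_mutations == 0
        return records
    threshold = abs(min(r.ddg for r in mutants))
    for r in records:
        r.selected = r.ddg <= threshold
    return records


def build_pfm(sequences: list[str]) -> Pfm:
    """Per-position base frequencies of equal-length sequences, no pseudocount."""
    if not sequences:
        raise SpecificityError("need at least one sequence")
    w = len(sequences[0])
    if any(len(s) != w for s in sequences):
        raise SpecificityError("sequences must have equal length")
    counts = np.zeros((w, 4))
    for s in sequences:
        for j, b in enumerate(s.upper()):
            counts[j, _BASE_INDEX[b]] += 1
    return Pfm(counts / len(sequences), support=len(sequences))


def score_pfm(pfm: Pfm, sequence: str, k: int = 1,
              consider_rc: bool = False, scan: bool = False,
              epsilon: float = PFM_EPSILON) -> float:
    """Log-likelihood-ratio score of `sequence` against the PFM.

    Position k of the sequence (1-based) is aligned with the first PFM
    column, ungapped; Score = sum_j log2((P[j][base] + eps) / 0.25) over the
    overlap (the effective width shrinks when the remaining substring is
    shorter than the PFM).  With `consider_rc` the reverse complement is
    scored too and the maximum returned; with `scan` the maximum over all
    alignment offsets is returned.
    """
    sequence = sequence.upper()
    if scan:
        return max(score_pfm(pfm, sequence, kk, consider_rc, scan=False,
                             epsilon=epsilon)
                   for kk in range(1, len(sequence) + 1))
    if not 1 <= k <= len(sequence):
        raise SpecificityError(f"offset k={k} out of range")

    def one(seq: str) -> float:
        w_eff = min(pfm.width, len(seq) - k + 1)
        total = 0.0
        for j in range(w_eff):
            f = pfm.frequencies[j, _BASE_INDEX[seq[k - 1 + j]]]
            total += math.log2((f + epsilon) / _BACKGROUND)
        return total

    best = one(sequence)
    if consider_rc:
        best = max(best, one(chemistry.reverse_complement(sequence)))
    return best


def random_sites(n: int, w: int, seed: int) -> list[str]:
    """n i.i.d. uniform sequences over {A,C,G,T}^w, reproducible under seed."""
    if n < 1 or w < 1:
        raise SpecificityError("n and w must be >= 1")
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(BASE_ORDER), size=(n, w))
    return ["".join(row) for row in letters]


@dataclass
class PipelineResult:
    records: list[MutantRecord]
    pfm: Pfm
    native_sequence: str
    native_dg: float
    positions: tuple[int, int]


def sort_records(records: list[MutantRecord], by: str = "ddg",
                 descending: bool = False) -> list[MutantRecord]:
    """Stable sort by any record column, ties broken by sequence."""
    if by not in ("sequence", "n_mutations", "dg", "ddg", "pfm_score", "rmsd"):
        raise SpecificityError(f"cannot sort by {by!r}")
    key = lambda r: (getattr(r, by), r.sequence)
    if descending:
        return sorted(records, key=lambda r: (-getattr(r, by), r.sequence))
    return sorted(records, key=key)


def run_pipeline(cx: ComplexStructure, duplex: DsDnaDuplex,
                 potential: PotentialTable,
                 templates: dict[str, BaseTemplate],
                 positions: tuple[int, int] | None = None,
                 max_mutations: int = 2) -> PipelineResult:
    """Enumerate, mutate, score, filter and summarize as a PFM.

    `positions` is a 1-based inclusive range of base-pair positions along
    duplex strand_a (default: all pairs).  Every record (native included)
    gets dG, ddG = dG' - dG_native, RMSD to the native complex, a selection
    flag, and a PFM score computed with alignment offset k = 1.
    """
    full = duplex.sequence
    lo, hi = positions if positions is not None else (1, len(full))
    if not (1 <= lo <= hi <= len(full)):
        raise SpecificityError(f"positions {lo}:{hi} outside the duplex")
    native_site = full[lo - 1:hi]
    native_dg = delta_g(cx, potential)

    sequences = enumerate_mutants(native_site, None, max_mutations,
                                  include_native=True)
    records: list[MutantRecord] = []
    for seq in sequences:
        diffs = [i for i, (a, b) in enumerate(zip(native_site, seq)) if a != b]
        if not diffs:
            records.append(MutantRecord(seq, 0, native_dg, 0.0, 0.0))
            continue
        mutated = cx
        for i in diffs:
            pair_index = lo - 1 + i
            new_pair = seq[i] + chemistry.COMPLEMENT[seq[i]]
            mutated = mutate_pair(mutated, duplex, pair_index, new_pair,
                                  templates)
        dg_m = delta_g(mutated, potential)
        records.append(MutantRecord(
            seq, len(diffs), dg_m, delta_delta_g(dg_m, native_dg),
            rmsd(mutated, cx)))

    flexibility_filter(records, native_dg)
    pfm = build_pfm([r.sequence for r in records if r.selected])
    for r in records:
        r.pfm_score = score_pfm(pfm, r.sequence, k=1)
    records = sort_records(records, "ddg")
    return PipelineResult(records, pfm, native_site, native_dg, (lo, hi))


def records_to_tsv(records: list[MutantRecord]) -> str:
    lines = ["sequence\tn_mutations\tdG\tddG\tpfm_score\trmsd\tselected"]
    for r in records:
        lines.append(f"{r.sequence}\t{r.n_mutations}\t{r.dg:.6f}\t"
                     f"{r.ddg:.6f}\t{r.pfm_score:.6f}\t{r.rmsd:.6f}\t"
                     f"{int(r.selected)}")
    return "\n".join(lines) + "\n"
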