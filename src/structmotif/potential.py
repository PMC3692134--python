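"""Distance-dependent knowledge-based potential for protein-DNA complexes.

Atom types are residue-specific: every (residue, heavy-atom) combination is
its own type, giving 167 protein types and 82 DNA types.  Training counts
every protein-DNA heavy-atom pair within a distance cutoff into bins of
N_obs(i, j, r).  The pair score is

    S(i, j, r) = -ln( P(i, j, r) / P_ref(r) )

with P(i, j, r) the per-type-pair distance distribution (pseudocounted) and
P_ref(r) the type-pooled distance distribution — the weight that discounts
long distances, since long-distance bins carry most of the pooled mass.  The
binding free energy of a complex, dG, is the sum of S over all observed
in-range atom pairs (kT = 1, dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import chemistry
from .structure_io import ComplexStructure


class PotentialError(ValueError):
    pass


@dataclass(frozen=True)
class AtomTypeCatalog:
    """Dense indices for residue-specific heavy-atom types (167 + 82)."""

    protein_types: dict[tuple[str, str], int]
    dna_types: dict[tuple[str, str], int]

    @classmethod
    def standard(cls) -> "AtomTypeCatalog":
        protein = {}
        for res in sorted(chemistry.AMINO_ACID_ATOMS):
            for atom in chemistry.AMINO_ACID_ATOMS[res]:
                protein[(res, atom)] = len(protein)
        dna = {}
        for base in "ACGT":
            for atom in chemistry.SUGAR_PHOSPHATE_ATOMS:
                dna[(base, atom)] = len(dna)
            for atom in chemistry.BASE_ATOMS[base]:
                dna[(base, atom)] = len(dna)
        return cls(protein, dna)

    @property
    def n_protein(self) -> int:
        return len(self.protein_types)

    @property
    def n_dna(self) -> int:
        return len(self.dna_types)


_DEFAULT_CATALOG: AtomTypeCatalog | None = None


def standard_catalog() -> AtomTypeCatalog:
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = AtomTypeCatalog.standard()
    return _DEFAULT_CATALOG


def atom_type(residue_name: str, atom_name: str,
              catalog: AtomTypeCatalog) -> tuple[str, int] | None:
    """Return ('protein'|'dna', index) or None for untyped atoms.

    OXT and other termination variants are untyped so the catalogue keeps
    its exact cardinality; waters and ligands are untyped.
    """
    atom = chemistry.normalize_atom_name(atom_name)
    aa = chemistry.protein_residue(residue_name)
    if aa is not None:
        idx = catalog.protein_types.get((aa, atom))
        return ("protein", idx) if idx is not None else None
    nt = chemistry.nucleotide_letter(residue_name)
    if nt is not None:
        idx = catalog.dna_types.get((nt, atom))
        return ("dna", idx) if idx is not None else None
    return None


@dataclass
class PotentialTable:
    """Binned pair counts and derived scores.

    ``counts[i, j, b]`` is N_obs for protein type i, DNA type j, distance bin
    b; bins have uniform width on [0, cutoff].  Scores are recomputed from
    counts deterministically, so serialization stores counts only.
    """

    counts: np.ndarray
    bin_width: float
    cutoff: float
    pseudocount: float
    catalog: AtomTypeCatalog = field(default_factory=standard_catalog)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = (self.catalog.n_protein, self.catalog.n_dna, self.n_bins)
        if self.counts.shape != expected:
            raise PotentialError(
                f"counts shape {self.counts.shape} != {expected}")
        self._scores: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return int(round(self.cutoff / self.bin_width))

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.cutoff, self.n_bins + 1)

    def probabilities(self) -> np.ndarray:
        """Pseudocounted per-(i,j) distance distribution P(i, j, bin)."""
        c = (self.counts + self.pseudocount).astype(float)
        sums = c.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore"):
            p = np.where(sums > 0, c / np.where(sums > 0, sums, 1.0), 0.0)
        return p

    def reference(self) -> np.ndarray:
        """Type-pooled distance distribution P_ref(bin)."""
        pooled = (self.counts + self.pseudocount).sum(axis=(0, 1))
        return pooled / pooled.sum()

    @property
    def scores(self) -> np.ndarray:
        """S(i, j, bin) = -ln(P / P_ref)."""
        if self._scores is None:
            with np.errstate(divide="ignore"):
                # unseen (i, j) rows at pseudocount 0 score +inf (never
                # observed -> infinitely unfavourable); finite otherwise
                self._scores = -np.log(self.probabilities() /
                                       self.reference())
        return self._scores

    def bin_of(self, r: np.ndarray) -> np.ndarray:
        b = np.floor(np.asarray(r) / self.bin_width).astype(int)
        return np.clip(b, 0, self.n_bins - 1)

    # -- serialization ------------------------------------------------------

    def dumps(self) -> str:
        """Self-describing tabular text; reloads bit-exactly."""
        inv_p = {v: k for k, v in self.catalog.protein_types.items()}
        inv_d = {v: k for k, v in self.catalog.dna_types.items()}
        lines = [
            "# structmotif potential table v1",
            f"bin_width\t{self.bin_width!r}",
            f"cutoff\t{self.cutoff!r}",
            f"pseudocount\t{self.pseudocount!r}",
            "# prot_res\tprot_atom\tdna_base\tdna_atom\tbin\tcount",
        ]
        pi, dj, bb = np.nonzero(self.counts)
        for i, j, b in zip(pi.tolist(), dj.tolist(), bb.tolist()):
            pr, pa = inv_p[i]
            db, da = inv_d[j]
            lines.append(f"{pr}\t{pa}\t{db}\t{da}\t{b}\t{self.counts[i, j, b]}")
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "PotentialTable":
        catalog = standard_catalog()
        header: dict[str, float] = {}
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                header[parts[0]] = float(parts[1])
            elif len(parts) == 6:
                rows.append(parts)
            else:
                raise PotentialError(f"unreadable potential line: {line!r}")
        try:
            bin_width = header["bin_width"]
            cutoff = header["cutoff"]
            pseudocount = header["pseudocount"]
        except KeyError as exc:
            raise PotentialError(f"missing header field {exc}") from exc
        n_bins = int(round(cutoff / bin_width))
        counts = np.zeros((catalog.n_protein, catalog.n_dna, n_bins),
                          dtype=np.int64)
        for pr, pa, db, da, b, c in rows:
            i = catalog.protein_types[(pr, pa)]
            j = catalog.dna_types[(db, da)]
            counts[i, j, int(b)] = int(c)
        return cls(counts, bin_width, cutoff, pseudocount, catalog)


def _typed_atoms(cx: ComplexStructure, catalog: AtomTypeCatalog):
    """(protein indices+coords, dna indices+coords) for typed heavy atoms."""
    p_idx, p_xyz, d_idx, d_xyz = [], [], [], []
    for a in cx.atoms:
        if a.chain_id in cx.protein_chains:
            t = atom_type(a.residue_name, a.atom_name, catalog)
            if t is not None and t[0] == "protein":
                p_idx.append(t[1])
                p_xyz.append(a.coords)
        elif a.chain_id in cx.dna_chains:
            t = atom_type(a.residue_name, a.atom_name, catalog)
            if t is not None and t[0] == "dna":
                d_idx.append(t[1])
                d_xyz.append(a.coords)
    return (np.array(p_idx, dtype=int),
            np.stack(p_xyz) if p_xyz else np.zeros((0, 3)),
            np.array(d_idx, dtype=int),
            np.stack(d_xyz) if d_xyz else np.zeros((0, 3)))


def train_potential(complexes: list[ComplexStructure],
                    bin_width: float = 0.5,
                    cutoff: float = 15.0,
                    pseudocount: float = 0.5,
                    catalog: AtomTypeCatalog | None = None) -> PotentialTable:
    """Accumulate N_obs(i, j, r) over a complex collection and derive scores."""
    if bin_width <= 0 or cutoff <= bin_width:
        raise PotentialError("need 0 < bin_width < cutoff")
    catalog = catalog or standard_catalog()
    n_bins = int(round(cutoff / bin_width))
    counts = np.zeros((catalog.n_protein, catalog.n_dna, n_bins),
                      dtype=np.int64)
    total = 0
    for cx in complexes:
        pi, pxyz, dj, dxyz = _typed_atoms(cx, catalog)
        if pi.size == 0 or dj.size == 0:
            continue
        dist = cdist(pxyz, dxyz)
        ii, jj = np.nonzero(dist <= cutoff)
        if ii.size == 0:
            continue
        bins = np.clip((dist[ii, jj] / bin_width).astype(int), 0, n_bins - 1)
        np.add.at(counts, (pi[ii], dj[jj], bins), 1)
        total += ii.size
    if total == 0:
        raise PotentialError("no protein-DNA atom pairs within the cutoff")
    return PotentialTable(counts, bin_width, cutoff, pseudocount, catalog)


def delta_g(cx: ComplexStructure, pot: PotentialTable) -> float:
    """Sum of pair scores over all typed in-range protein-DNA atom pairs."""
    if pot.counts.sum() == 0:
        raise PotentialError("potential table is untrained")
    if not cx.protein_chains or not cx.dna_chains:
        raise PotentialError("complex needs both protein and DNA chains")
    pi, pxyz, dj, dxyz = _typed_atoms(cx, pot.catalog)
    if pi.size == 0 or dj.size == 0:
        return 0.0
    dist = cdist(pxyz, dxyz)
    ii, jj = np.nonzero(dist <= pot.cutoff)
    if ii.size == 0:
        return 0.0
    bins = pot.bin_of(dist[ii, jj])
    return float(pot.scores[pi[ii], dj[jj], bins].sum())


def delta_delta_g(mutant_dg: float, native_dg: float) -> float:
    """ddG = dG' - dG_native (negative favours the mutant)."""
    if not (np.isfinite(mutant_dg) and np.isfinite(native_dg)):
        raise PotentialError("dG values must be finite")
    return mutant_dg - native_dg
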