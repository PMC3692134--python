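"""PDB-format I/O, chain classification, dsDNA pairing and contact flagging.

Parsing and serialization are delegated to gemmi; this module flattens the
hierarchy into the light-weight containers the rest of the package consumes
and implements the domain logic gemmi does not provide: classifying chains
as protein or DNA, detecting antiparallel Watson-Crick paired duplexes, and
flagging bases contacted by the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from . import chemistry


class StructureError(ValueError):
    """Raised for unparseable or chemically inconsistent structures."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a complex (hydrogens are dropped at parse time)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    coords: np.ndarray
    element: str
    insertion_code: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise StructureError(f"non-finite coordinates for atom {self.atom_name}")
        object.__setattr__(self, "coords", coords)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class ComplexStructure:
    """A protein-DNA complex as a flat, ordered atom list.

    Chains holding at least one standard amino acid are protein chains; chains
    holding at least one deoxyribonucleotide are DNA chains.  Atoms in neither
    set (waters, ligands) are retained but excluded from scoring and contacts.
    """

    atoms: list[Atom]
    protein_chains: frozenset[str] = field(default_factory=frozenset)
    dna_chains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.protein_chains & self.dna_chains:
            raise StructureError("a chain cannot be both protein and DNA")

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id in self.protein_chains]

    def dna_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id in self.dna_chains]

    def residue_atoms(self, chain_id: str, residue_number: int,
                      insertion_code: str = "") -> list[Atom]:
        key = (chain_id, residue_number, insertion_code)
        return [a for a in self.atoms if a.residue_key == key]

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(list(self.atoms), self.protein_chains,
                                self.dna_chains)

    def coords_array(self, atoms: list[Atom] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else atoms
        if not src:
            return np.zeros((0, 3))
        return np.stack([a.coords for a in src])


@dataclass(frozen=True)
class DuplexBase:
    chain_id: str
    residue_number: int
    base: str
    insertion_code: str = ""


@dataclass
class DsDnaDuplex:
    """Two antiparallel Watson-Crick paired strands.

    ``pairs[i] = (index_a, index_b)`` indexes into the strand base lists;
    strand_b indices strictly decrease as strand_a indices increase.
    Duplex positions used elsewhere are 1-based along strand_a 5'->3'.
    """

    strand_a: list[DuplexBase]
    strand_b: list[DuplexBase]
    pairs: list[tuple[int, int]]
    contact_flags: list[bool] = field(default_factory=list)
    contact_residues: list[list[tuple[str, int, str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise StructureError("a duplex needs at least one pair")
        for ia, ib in self.pairs:
            a, b = self.strand_a[ia], self.strand_b[ib]
            if chemistry.COMPLEMENT[a.base] != b.base:
                raise StructureError(
                    f"pair {a.base}-{b.base} is not Watson-Crick complementary")
        ibs = [ib for _, ib in self.pairs]
        if any(y >= x for x, y in zip(ibs, ibs[1:])):
            raise StructureError("strands are not antiparallel")
        if not self.contact_flags:
            self.contact_flags = [False] * len(self.pairs)
            self.contact_residues = [[] for _ in self.pairs]

    @property
    def sequence(self) -> str:
        """Strand-a base sequence over the paired region, 5'->3'."""
        return "".join(self.strand_a[ia].base for ia, _ in self.pairs)

    def pair_residues(self, pair_index: int) -> tuple[DuplexBase, DuplexBase]:
        """0-based pair index -> (strand_a base, strand_b base)."""
        ia, ib = self.pairs[pair_index]
        return self.strand_a[ia], self.strand_b[ib]

    @property
    def chain_ids(self) -> tuple[str, str]:
        return (self.strand_a[0].chain_id, self.strand_b[0].chain_id)


# ---------------------------------------------------------------------------
# parsing / writing

def parse_complex(pdb_text: str) -> ComplexStructure:
    """Parse PDB-format text into a :class:`ComplexStructure`.

    Hydrogens are dropped; of alternate locations only the primary (blank or
    'A') is kept; chains mixing amino acids and nucleotides are rejected.
    """
    lines = pdb_text.splitlines()
    has_atom = any(l.startswith(("ATOM", "HETATM")) for l in lines)
    if not has_atom:
        first = next((l for l in lines if l.strip()), "<empty input>")
        raise StructureError(f"no ATOM/HETATM records; first line: {first!r}")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise StructureError(f"PDB parse failure: {exc}") from exc

    atoms: list[Atom] = []
    chain_has_aa: dict[str, bool] = {}
    chain_has_nt: dict[str, bool] = {}
    for model in st:
        for chain in model:
            cid = chain.name or " "
            for res in chain:
                aa = chemistry.protein_residue(res.name)
                nt = chemistry.nucleotide_letter(res.name)
                if aa:
                    chain_has_aa[cid] = True
                if nt:
                    chain_has_nt[cid] = True
                for atom in res:
                    if atom.is_hydrogen():
                        continue
                    if atom.altloc not in ("\x00", "", "A"):
                        continue
                    name = chemistry.normalize_atom_name(atom.name)
                    atoms.append(Atom(
                        chain_id=cid,
                        residue_number=res.seqid.num,
                        residue_name=res.name.strip(),
                        atom_name=name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        element=atom.element.name,
                        insertion_code=(res.seqid.icode or " ").strip(),
                    ))
        break  # first model only

    mixed = set(chain_has_aa) & set(chain_has_nt)
    if mixed:
        raise StructureError(
            f"chain(s) {sorted(mixed)} mix amino acids and nucleotides")
    protein = frozenset(chain_has_aa)
    dna = frozenset(chain_has_nt)
    if not protein and not dna:
        raise StructureError("no protein or DNA chains")
    return ComplexStructure(atoms, protein, dna)


_COORD_MIN, _COORD_MAX = -999.999, 9999.999


def write_complex(cx: ComplexStructure) -> str:
    """Serialize to PDB-format text (fixed columns, 3-decimal coordinates)."""
    if not cx.atoms:
        raise StructureError("cannot write an empty structure")
    for a in cx.atoms:
        if np.any(a.coords < _COORD_MIN) or np.any(a.coords > _COORD_MAX):
            raise StructureError(
                f"coordinate overflows PDB fixed columns: {a.coords}")
    # gemmi's add_* methods copy their argument, so build bottom-up:
    # group atoms into residues per chain, then assemble.
    grouped: dict[str, dict[tuple, list[Atom]]] = {}
    for a in cx.atoms:
        rkey = a.residue_key + (a.residue_name,)
        grouped.setdefault(a.chain_id, {}).setdefault(rkey, []).append(a)

    st = gemmi.Structure()
    st.name = "structmotif"
    model = gemmi.Model("1")
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for (_, num, icode, name), res_atoms in residues.items():
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(num, icode or " ")
            res.het_flag = "A"
            for a in res_atoms:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.pos = gemmi.Position(*a.coords)
                atom.element = gemmi.Element(a.element)
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# duplex detection and contacts

_WC_DISTANCE = 3.5   # Å, purine N1 <-> pyrimidine N3
_MIN_RUN = 3         # minimum consecutive pairs to report a duplex


def _chain_bases(cx: ComplexStructure, chain_id: str):
    """Ordered standard nucleotides of a chain with their WC-atom coordinate."""
    out = []
    seen: set[tuple] = set()
    for a in cx.atoms:
        if a.chain_id != chain_id:
            continue
        letter = chemistry.nucleotide_letter(a.residue_name)
        if letter is None:
            continue
        key = a.residue_key
        if key in seen:
            continue
        res_atoms = {at.atom_name: at.coords
                     for at in cx.atoms if at.residue_key == key}
        wc = res_atoms.get(chemistry.WC_ATOM[letter])
        if wc is None:
            continue
        seen.add(key)
        out.append((DuplexBase(chain_id, a.residue_number, letter,
                               a.insertion_code), wc))
    return out


def detect_dsdna(cx: ComplexStructure) -> list[DsDnaDuplex]:
    """Detect antiparallel Watson-Crick duplexes among the DNA chains.

    Bases are paired when complementary and their Watson-Crick hydrogen-bond
    atoms (purine N1 <-> pyrimidine N3) lie within 3.5 Å; a duplex is reported
    for every run of >= 3 consecutive pairs.  A chain is never paired with
    itself, so a self-complementary hairpin yields nothing.
    """
    chains = sorted(cx.dna_chains)
    duplexes: list[DsDnaDuplex] = []
    for i, ca in enumerate(chains):
        bases_a = _chain_bases(cx, ca)
        if not bases_a:
            continue
        for cb in chains[i + 1:]:
            bases_b = _chain_bases(cx, cb)
            if not bases_b:
                continue
            matches: list[tuple[int, int]] = []
            for ia, (ba, wa) in enumerate(bases_a):
                best: tuple[float, int] | None = None
                for ib, (bb, wb) in enumerate(bases_b):
                    if chemistry.COMPLEMENT[ba.base] != bb.base:
                        continue
                    d = float(np.linalg.norm(wa - wb))
                    if d <= _WC_DISTANCE and (best is None or d < best[0]):
                        best = (d, ib)
                if best is not None:
                    matches.append((ia, best[1]))
            # split into antiparallel consecutive runs
            run: list[tuple[int, int]] = []
            for m in matches:
                if run and (m[0] == run[-1][0] + 1 and m[1] == run[-1][1] - 1):
                    run.append(m)
                else:
                    if len(run) >= _MIN_RUN:
                        duplexes.append(_make_duplex(bases_a, bases_b, run))
                    run = [m]
            if len(run) >= _MIN_RUN:
                duplexes.append(_make_duplex(bases_a, bases_b, run))
    return duplexes


def _make_duplex(bases_a, bases_b, run) -> DsDnaDuplex:
    ia0, ia1 = run[0][0], run[-1][0]
    ib1, ib0 = run[-1][1], run[0][1]
    strand_a = [b for b, _ in bases_a[ia0:ia1 + 1]]
    strand_b = [b for b, _ in bases_b[ib1:ib0 + 1]]
    pairs = [(ia - ia0, ib - ib1) for ia, ib in run]
    return DsDnaDuplex(strand_a, strand_b, pairs)


def base_moiety_atoms(cx: ComplexStructure, base: DuplexBase) -> list[Atom]:
    """Heavy atoms of the base moiety only (no sugar-phosphate)."""
    names = set(chemistry.BASE_ATOMS[base.base])
    key = (base.chain_id, base.residue_number, base.insertion_code)
    return [a for a in cx.atoms if a.residue_key == key and a.atom_name in names]


def flag_contacts(cx: ComplexStructure, duplex: DsDnaDuplex,
                  threshold: float = 4.5) -> DsDnaDuplex:
    """Flag pairs whose base moiety lies within `threshold` Å of the protein.

    Only base-moiety heavy atoms count on the DNA side; any heavy atom of any
    protein chain counts on the protein side.  Contacting protein residues
    (name, number, chain) are recorded per flagged pair.
    """
    if threshold <= 0:
        raise ValueError("contact threshold must be positive")
    prot = cx.protein_atoms()
    flags = [False] * len(duplex.pairs)
    residues: list[list[tuple[str, int, str]]] = [[] for _ in duplex.pairs]
    if prot:
        tree = cKDTree(np.stack([a.coords for a in prot]))
        for pi in range(len(duplex.pairs)):
            ba, bb = duplex.pair_residues(pi)
            atoms = base_moiety_atoms(cx, ba) + base_moiety_atoms(cx, bb)
            if not atoms:
                continue
            hits = tree.query_ball_point(np.stack([a.coords for a in atoms]),
                                         threshold)
            contact: dict[tuple[str, int, str], None] = {}
            for lst in hits:
                for j in lst:
                    p = prot[j]
                    contact[(p.residue_name, p.residue_number, p.chain_id)] = None
            if contact:
                flags[pi] = True
                residues[pi] = sorted(contact)
    out = replace(duplex)
    out.contact_flags = flags
    out.contact_residues = residues
    return out


def duplex_report(duplex: DsDnaDuplex) -> str:
    """Human-readable pair table (1-based positions along strand_a)."""
    lines = ["pos\tbase_a\tbase_b\tcontact\tprotein_residues"]
    for pi in range(len(duplex.pairs)):
        ba, bb = duplex.pair_residues(pi)
        res = ";".join(f"{n}{num}:{c}" for n, num, c in duplex.contact_residues[pi])
        lines.append(f"{pi + 1}\t{ba.base}{ba.residue_number}\t"
                     f"{bb.base}{bb.residue_number}\t"
                     f"{'yes' if duplex.contact_flags[pi] else 'no'}\t{res}")
    return "\n".join(lines) + "\n"
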