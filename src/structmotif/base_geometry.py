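"""Base templates, canonical frames, rigid base-pair replacement and RMSD.

A mutation replaces the base moiety of a nucleotide by a template of the new
base type, treated as a rigid body, while the sugar-phosphate backbone stays
bit-identical.  The placement follows a four-step rule: (i) superimpose the
template's glycosidic nitrogen (N9 purines, N1 pyrimidines) onto the old
one, (ii) align the base-plane normals, (iii) align the interior bisector of
a fixed ring angle (C4-N9-C8 purines, C2-N1-C6 pyrimidines), and (iv) delete
the old base atoms.

Every base type has a canonical frame: anchor at the origin, base plane
normal on +z (sign fixed by ring chirality), interior bisector on +x.
Templates are stored in that frame, so placement is a single rigid motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation as ScipyRotation

from . import chemistry
from .geometry import RigidTransform
from .structure_io import Atom, ComplexStructure, DsDnaDuplex


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class BaseTemplate:
    """Averaged heavy-atom model of one base type in its canonical frame."""

    base_type: str
    atom_names: tuple[str, ...]
    coords: np.ndarray            # (n, 3), anchor at origin, plane z=0
    anchor_atom: str
    plane_atoms: tuple[str, ...]
    bisector_atoms: tuple[str, str, str]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        expected = len(chemistry.BASE_ATOMS[self.base_type])
        if len(self.atom_names) != expected:
            raise GeometryError(
                f"{self.base_type} template must have {expected} base atoms")

    def atom_dict(self) -> dict[str, np.ndarray]:
        return dict(zip(self.atom_names, self.coords))


def canonical_frame(base_atoms: dict[str, np.ndarray],
                    base_type: str) -> RigidTransform:
    """Transform mapping a base into its canonical frame.

    Anchor -> origin; best-fit plane normal (principal axis of the plane-atom
    covariance, sign chosen so that the ring traversal p -> anchor -> q is
    right-handed, which fixes chirality) -> +z; the interior bisector of the
    (p, anchor, q) angle projected into the plane -> +x.
    """
    anchor_name = chemistry.ANCHOR_ATOM[base_type]
    plane_names = chemistry.RING_ATOMS[base_type]
    p_name, _, q_name = chemistry.BISECTOR_ATOMS[base_type]
    missing = [n for n in (anchor_name, p_name, q_name, *plane_names)
               if n not in base_atoms]
    if missing:
        raise GeometryError(
            f"missing frame atoms for {base_type}: {sorted(set(missing))}")

    anchor = np.asarray(base_atoms[anchor_name], dtype=float)
    plane = np.stack([base_atoms[n] for n in plane_names]).astype(float)
    centered = plane - plane.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-8:
        raise GeometryError("plane atoms are collinear")
    normal = evecs[:, 0]

    v_p = base_atoms[p_name] - anchor
    v_q = base_atoms[q_name] - anchor
    if np.dot(np.cross(v_p, v_q), normal) < 0:
        normal = -normal

    bis = v_p / np.linalg.norm(v_p) + v_q / np.linalg.norm(v_q)
    bis = bis - np.dot(bis, normal) * normal
    nb = np.linalg.norm(bis)
    if nb < 1e-8:
        raise GeometryError("degenerate bisector direction")
    x_axis = bis / nb
    z_axis = normal / np.linalg.norm(normal)
    y_axis = np.cross(z_axis, x_axis)
    rot = np.stack([x_axis, y_axis, z_axis])
    return RigidTransform(rot, -rot @ anchor)


def build_template(base_instances: list[dict[str, np.ndarray]],
                   base_type: str) -> BaseTemplate:
    """Average base instances atom-wise after mapping each to the canonical frame.

    Atoms missing from some instances are averaged over the instances that
    have them.  Each instance is first mapped to the canonical frame, then
    re-superimposed onto the running average by least-squares (Kabsch)
    rotation over its shared atoms, which uses every atom rather than just
    the frame atoms and so suppresses frame noise.  The average is re-framed
    so the canonical-frame invariants hold exactly.
    """
    if not base_instances:
        raise GeometryError("need at least one base instance")
    names = chemistry.BASE_ATOMS[base_type]
    framed = []
    for inst in base_instances:
        frame = canonical_frame(inst, base_type)
        framed.append({n: frame.apply(inst[n]) for n in names if n in inst})

    def average(instances):
        sums = {n: np.zeros(3) for n in names}
        counts = {n: 0 for n in names}
        for inst in instances:
            for n, c in inst.items():
                sums[n] += c
                counts[n] += 1
        absent = [n for n in names if counts[n] == 0]
        if absent:
            raise GeometryError(f"atom(s) {absent} missing from every instance")
        return {n: sums[n] / counts[n] for n in names}

    mean = average(framed)
    for _ in range(2):  # Kabsch refinement onto the running mean
        refined = []
        for inst in framed:
            shared = [n for n in names if n in inst]
            a = np.stack([inst[n] for n in shared])
            b = np.stack([mean[n] for n in shared])
            ca, cb = a.mean(axis=0), b.mean(axis=0)
            rot, _ = ScipyRotation.align_vectors(b - cb, a - ca)
            mat = rot.as_matrix()
            refined.append({n: mat @ (inst[n] - ca) + cb for n in shared})
        mean = average(refined)
        framed = refined
    # re-frame the averaged coordinates so invariants hold exactly
    refit = canonical_frame(mean, base_type)
    coords = np.stack([refit.apply(mean[n]) for n in names])
    return BaseTemplate(
        base_type=base_type,
        atom_names=names,
        coords=coords,
        anchor_atom=chemistry.ANCHOR_ATOM[base_type],
        plane_atoms=chemistry.RING_ATOMS[base_type],
        bisector_atoms=chemistry.BISECTOR_ATOMS[base_type],
    )


# ---------------------------------------------------------------------------
# idealized base geometry (planar rings, standard bond lengths)

_BOND_RING = 1.39      # Å, aromatic ring bond
_BOND_C_O = 1.23       # Å, carbonyl
_BOND_C_N = 1.34       # Å, exocyclic amine
_BOND_C_C = 1.50       # Å, methyl
_BOND_N_C1 = 1.47      # Å, glycosidic


def _hexagon(names: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Regular hexagon in the z=0 plane, circumradius = ring bond length."""
    out = {}
    for k, n in enumerate(names):
        ang = math.radians(60.0 * k)
        out[n] = np.array([_BOND_RING * math.cos(ang),
                           _BOND_RING * math.sin(ang), 0.0])
    return out


def _exocyclic(atoms: dict[str, np.ndarray], ring_names: tuple[str, ...],
               at: str, bond: float) -> np.ndarray:
    center = np.mean([atoms[n] for n in ring_names], axis=0)
    d = atoms[at] - center
    d = d / np.linalg.norm(d)
    return atoms[at] + bond * d


def ideal_base_coords(base_type: str) -> dict[str, np.ndarray]:
    """Idealized planar base geometry in the canonical frame.

    Rings are regular polygons with 1.39 Å bonds; exocyclic substituents sit
    on the external bisector at standard bond lengths.  The returned dict
    also carries the glycosidic C1' position (not a base-moiety atom) so the
    synthetic-structure builder can attach the sugar.
    """
    hex_names = ("N1", "C2", "N3", "C4", "C5", "C6")
    atoms = _hexagon(hex_names)
    if base_type in chemistry.PURINES:
        # fuse a regular pentagon on the C4-C5 edge, outside the hexagon
        c4, c5 = atoms["C4"], atoms["C5"]
        mid = 0.5 * (c4 + c5)
        hex_center = np.mean([atoms[n] for n in hex_names], axis=0)
        w = mid - hex_center
        w = w / np.linalg.norm(w)
        apothem = _BOND_RING / (2.0 * math.tan(math.pi / 5.0))
        circum = _BOND_RING / (2.0 * math.sin(math.pi / 5.0))
        pc = mid + apothem * w
        th4 = math.atan2(c4[1] - pc[1], c4[0] - pc[0])
        th5 = math.atan2(c5[1] - pc[1], c5[0] - pc[0])
        delta = (th5 - th4 + math.pi) % (2.0 * math.pi) - math.pi
        step = math.copysign(math.radians(72.0), delta)
        for k, n in enumerate(("N9", "C8", "N7"), start=1):
            th = th4 - k * step
            atoms[n] = pc + circum * np.array([math.cos(th), math.sin(th), 0.0])
        penta = ("C4", "N9", "C8", "N7", "C5")
        if base_type == "A":
            atoms["N6"] = _exocyclic(atoms, hex_names, "C6", _BOND_C_N)
        else:  # G
            atoms["O6"] = _exocyclic(atoms, hex_names, "C6", _BOND_C_O)
            atoms["N2"] = _exocyclic(atoms, hex_names, "C2", _BOND_C_N)
        atoms["C1'"] = _exocyclic(atoms, penta, "N9", _BOND_N_C1)
    else:
        atoms["O2"] = _exocyclic(atoms, hex_names, "C2", _BOND_C_O)
        if base_type == "C":
            atoms["N4"] = _exocyclic(atoms, hex_names, "C4", _BOND_C_N)
        else:  # T
            atoms["O4"] = _exocyclic(atoms, hex_names, "C4", _BOND_C_O)
            atoms["C7"] = _exocyclic(atoms, hex_names, "C5", _BOND_C_C)
        atoms["C1'"] = _exocyclic(atoms, hex_names, "N1", _BOND_N_C1)
    frame = canonical_frame(atoms, base_type)
    return {n: frame.apply(c) for n, c in atoms.items()}


def default_templates() -> dict[str, BaseTemplate]:
    """Templates built from the idealized base geometries."""
    out = {}
    for b in "ACGT":
        coords = ideal_base_coords(b)
        names = chemistry.BASE_ATOMS[b]
        out[b] = BaseTemplate(
            base_type=b,
            atom_names=names,
            coords=np.stack([coords[n] for n in names]),
            anchor_atom=chemistry.ANCHOR_ATOM[b],
            plane_atoms=chemistry.RING_ATOMS[b],
            bisector_atoms=chemistry.BISECTOR_ATOMS[b],
        )
    return out


def template_to_pdb(template: BaseTemplate) -> str:
    """Serialize a template as a PDB fragment (one residue, chain T)."""
    atoms = [Atom("T", 1, "D" + template.base_type, n, c, n[0])
             for n, c in zip(template.atom_names, template.coords)]
    from .structure_io import write_complex
    return write_complex(ComplexStructure(atoms, frozenset(), frozenset({"T"})))


# ---------------------------------------------------------------------------
# mutation

def mutate_base(cx: ComplexStructure, site: tuple[str, int], new_type: str,
                templates: dict[str, BaseTemplate]) -> ComplexStructure:
    """Replace the base moiety at `site` by the `new_type` template.

    The sugar-phosphate atoms are untouched (bit-identical); the new base is
    the template mapped through the inverse canonical frame of the old base,
    i.e. anchor-on-anchor, normal-on-normal, bisector-on-bisector.
    """
    chain_id, resnum = site
    res_atoms = cx.residue_atoms(chain_id, resnum)
    if not res_atoms:
        raise GeometryError(f"no residue {resnum} in chain {chain_id}")
    old_letter = chemistry.nucleotide_letter(res_atoms[0].residue_name)
    if old_letter is None:
        raise GeometryError(
            f"residue {res_atoms[0].residue_name} is not a standard nucleotide")
    if new_type not in templates:
        raise GeometryError(f"no template for base type {new_type}")
    template = templates[new_type]

    old_names = set(chemistry.BASE_ATOMS[old_letter])
    old_base = {a.atom_name: a.coords for a in res_atoms
                if a.atom_name in old_names}
    frame = canonical_frame(old_base, old_letter)
    placement = frame.inverse()
    new_coords = placement.apply(template.coords)
    new_resname = "D" + new_type
    new_atoms = [
        Atom(chain_id, resnum, new_resname, n, c, n[0],
             res_atoms[0].insertion_code)
        for n, c in zip(template.atom_names, new_coords)
    ]

    out: list[Atom] = []
    inserted = False
    key = res_atoms[0].residue_key
    for a in cx.atoms:
        if a.residue_key != key:
            out.append(a)
            continue
        if a.atom_name in old_names:
            if not inserted:
                out.extend(new_atoms)
                inserted = True
            continue
        # backbone atom: keep coordinates bitwise, rename residue
        out.append(Atom(a.chain_id, a.residue_number, new_resname,
                        a.atom_name, a.coords, a.element, a.insertion_code))
    if not inserted:
        raise GeometryError("residue has no base-moiety atoms to replace")
    return ComplexStructure(out, cx.protein_chains, cx.dna_chains)


def mutate_pair(cx: ComplexStructure, duplex: DsDnaDuplex, pair_index: int,
                new_pair: str, templates: dict[str, BaseTemplate]
                ) -> ComplexStructure:
    """Mutate both bases of a Watson-Crick pair, e.g. new_pair='C<->G'.

    `pair_index` is 0-based into duplex.pairs; the first letter goes to
    strand_a, the second to strand_b, and they must be complementary.
    """
    letters = [c for c in new_pair.upper() if c in "ACGT"]
    if len(letters) != 2:
        raise GeometryError(f"cannot parse new pair {new_pair!r}")
    a_new, b_new = letters
    if chemistry.COMPLEMENT[a_new] != b_new:
        raise GeometryError(f"{a_new}<->{b_new} is not complementary")
    if not 0 <= pair_index < len(duplex.pairs):
        raise GeometryError(f"pair index {pair_index} out of range")
    ba, bb = duplex.pair_residues(pair_index)
    cx = mutate_base(cx, (ba.chain_id, ba.residue_number), a_new, templates)
    cx = mutate_base(cx, (bb.chain_id, bb.residue_number), b_new, templates)
    return cx


def rmsd(cx_a: ComplexStructure, cx_b: ComplexStructure) -> float:
    """RMSD over equivalent atoms (same chain, residue number, atom name).

    No superposition is performed: mutants live in the native frame by
    construction, so equivalent atoms are directly comparable.
    """
    idx_b = {(a.chain_id, a.residue_number, a.insertion_code, a.atom_name): a.coords
             for a in cx_b.atoms}
    sq, n = 0.0, 0
    for a in cx_a.atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.atom_name)
        cb = idx_b.get(key)
        if cb is not None:
            d = a.coords - cb
            sq += float(d @ d)
            n += 1
    if n == 0:
        raise GeometryError("no equivalent atoms between the two structures")
    return math.sqrt(sq / n)
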