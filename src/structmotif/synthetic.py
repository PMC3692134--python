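"""Synthetic protein-DNA complexes with known ground truth.

Builds idealized antiparallel B-DNA duplexes (full heavy-atom nucleotides,
fixed rise/twist, exact Watson-Crick N1-N3 hydrogen-bond distance) and places
single-residue protein probes at controlled distances from chosen base pairs.
Everything is deterministic under a seed, so duplex pairing, contact flags
and atom-pair distance distributions are known by construction.

The emulated features are the ones the pipeline consumes: chain topology,
complementarity, base-moiety geometry compatible with the canonical frames,
and protein atoms at prescribed distances.  No attempt is made at
crystallographic realism (no propeller, roll, sequence-dependent steps, or
real protein folds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import chemistry
from .base_geometry import ideal_base_coords
from .geometry import RigidTransform
from .structure_io import Atom, ComplexStructure


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class BdnaSpec:
    """Parameters of an idealized B-DNA duplex."""

    sequence: str
    rise: float = 3.38       # Å per step
    twist: float = 36.0      # degrees per step
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FixtureError("sequence must be non-empty")
        bad = set(self.sequence.upper()) - set("ACGT")
        if bad:
            raise FixtureError(f"invalid base letters: {sorted(bad)}")
        if self.rise <= 0:
            raise FixtureError("rise must be positive")
        object.__setattr__(self, "sequence", self.sequence.upper())


_WC_NN = 2.9  # Å, purine N1 <-> pyrimidine N3 by construction

# Sugar-phosphate offsets relative to C1' in the local nucleotide frame
# (x = glycosidic direction away from the ring, z = base normal).
_SUGAR_OFFSETS: tuple[tuple[str, tuple[float, float, float]], ...] = (
    ("O4'", (0.7, 1.2, 0.2)),
    ("C2'", (1.2, -0.6, 0.8)),
    ("C4'", (1.9, 1.6, 0.5)),
    ("C3'", (2.3, 0.3, 1.0)),
    ("O3'", (3.6, 0.1, 1.2)),
    ("C5'", (2.2, 3.0, 0.7)),
    ("O5'", (1.5, 4.0, 0.0)),
    ("P", (2.0, 5.5, 0.2)),
    ("OP1", (3.4, 5.7, 0.4)),
    ("OP2", (1.3, 6.3, 1.3)),
)


def _nucleotide_coords(letter: str, base_coords: dict[str, np.ndarray],
                       normal: np.ndarray) -> dict[str, np.ndarray]:
    """Attach idealized sugar-phosphate atoms to placed base coordinates."""
    anchor = base_coords[chemistry.ANCHOR_ATOM[letter]]
    c1 = base_coords["C1'"]
    x_l = c1 - anchor
    x_l = x_l / np.linalg.norm(x_l)
    z_l = normal / np.linalg.norm(normal)
    z_l = z_l - np.dot(z_l, x_l) * x_l
    z_l = z_l / np.linalg.norm(z_l)
    y_l = np.cross(z_l, x_l)
    out = {n: base_coords[n] for n in chemistry.BASE_ATOMS[letter]}
    out["C1'"] = c1
    for name, (dx, dy, dz) in _SUGAR_OFFSETS:
        out[name] = c1 + dx * x_l + dy * y_l + dz * z_l
    return out


def _ring_center(coords: dict[str, np.ndarray], letter: str) -> np.ndarray:
    return np.mean([coords[n] for n in chemistry.RING_ATOMS[letter]], axis=0)


def _pair_geometry(strand_a_letter: str) -> tuple[dict, dict]:
    """Coordinates of one Watson-Crick pair in the pair frame.

    Returns (strand_a nucleotide, strand_b nucleotide) atom dicts including
    backbone; the midpoint of the two glycosidic nitrogens is the origin and
    the pair plane is z = 0.
    """
    a_letter = strand_a_letter
    b_letter = chemistry.COMPLEMENT[a_letter]
    pur = a_letter if a_letter in chemistry.PURINES else b_letter
    pyr = chemistry.COMPLEMENT[pur]

    pur_c = ideal_base_coords(pur)                 # canonical frame, normal +z
    pyr_c = ideal_base_coords(pyr)

    # hydrogen-bond direction of the purine: ring center -> N1, in-plane
    pc = _ring_center(pur_c, pur)
    h = pur_c["N1"] - pc
    h[2] = 0.0
    h = h / np.linalg.norm(h)

    # flip the pyrimidine (normal -> -z), then rotate about z so its own
    # H-bond direction (ring center -> N3) opposes h, then translate so that
    # N3 lands exactly _WC_NN along h from the purine N1.
    flip = np.diag([1.0, -1.0, -1.0])              # rotation by pi about x
    pyr_f = {n: flip @ c for n, c in pyr_c.items()}
    pyc = _ring_center(pyr_f, pyr)
    hp = pyr_f["N3"] - pyc
    hp[2] = 0.0
    hp = hp / np.linalg.norm(hp)
    alpha = math.atan2(-h[1], -h[0]) - math.atan2(hp[1], hp[0])
    rz = np.array([[math.cos(alpha), -math.sin(alpha), 0.0],
                   [math.sin(alpha), math.cos(alpha), 0.0],
                   [0.0, 0.0, 1.0]])
    pyr_p = {n: rz @ c for n, c in pyr_f.items()}
    target = pur_c["N1"] + _WC_NN * h
    shift = target - pyr_p["N3"]
    pyr_p = {n: c + shift for n, c in pyr_p.items()}

    pur_nt = _nucleotide_coords(pur, pur_c, np.array([0.0, 0.0, 1.0]))
    pyr_nt = _nucleotide_coords(pyr, pyr_p, np.array([0.0, 0.0, -1.0]))

    # center the pair on the midpoint of the glycosidic nitrogens
    a_pur = pur_nt[chemistry.ANCHOR_ATOM[pur]]
    a_pyr = pyr_nt[chemistry.ANCHOR_ATOM[pyr]]
    mid = 0.5 * (a_pur + a_pyr)
    pur_nt = {n: c - mid for n, c in pur_nt.items()}
    pyr_nt = {n: c - mid for n, c in pyr_nt.items()}

    if a_letter in chemistry.PURINES:
        nt_a, nt_b = pur_nt, pyr_nt
    else:
        # pseudo-dyad flip: rotate the pair by pi about the in-plane axis
        # perpendicular to the anchor-anchor line so strand roles swap sides
        u = a_pyr - a_pur
        u[2] = 0.0
        u = u / np.linalg.norm(u)
        dyad = np.cross(np.array([0.0, 0.0, 1.0]), u)
        rot = RigidTransform.about_axis(dyad, math.pi).rotation
        nt_a = {n: rot @ c for n, c in pyr_nt.items()}
        nt_b = {n: rot @ c for n, c in pur_nt.items()}
    return nt_a, nt_b


_ATOM_ORDER = chemistry.SUGAR_PHOSPHATE_ATOMS  # backbone listed first


def build_bdna(spec: BdnaSpec) -> ComplexStructure:
    """Build a full heavy-atom idealized B-DNA duplex (chains B and C).

    Strand A (chain B) carries ``spec.sequence`` 5'->3' with residue numbers
    1..n; strand B (chain C) carries the complement, also numbered 1..n in
    its own 5'->3' direction, so chain C residue 1 pairs with chain B
    residue n.  Consecutive base pairs are related by ``rise`` along z and
    ``twist`` about z.
    """
    seq = spec.sequence
    n = len(seq)
    placed_a: list[tuple[int, str, dict[str, np.ndarray]]] = []
    placed_b: list[tuple[int, str, dict[str, np.ndarray]]] = []
    for p, letter in enumerate(seq):
        nt_a, nt_b = _pair_geometry(letter)
        step = RigidTransform.about_axis(
            np.array([0.0, 0.0, 1.0]), math.radians(spec.twist) * p)
        lift = np.array([0.0, 0.0, spec.rise * p])
        nt_a = {k: step.rotation @ c + lift for k, c in nt_a.items()}
        nt_b = {k: step.rotation @ c + lift for k, c in nt_b.items()}
        placed_a.append((p + 1, letter, nt_a))
        placed_b.append((n - p, chemistry.COMPLEMENT[letter], nt_b))

    atoms: list[Atom] = []

    def emit(chain_id: str, resnum: int, letter: str,
             coords: dict[str, np.ndarray]) -> None:
        resname = "D" + letter
        order = list(_ATOM_ORDER) + list(chemistry.BASE_ATOMS[letter])
        for name in order:
            atoms.append(Atom(chain_id, resnum, resname, name,
                              coords[name], name[0]))

    for resnum, letter, coords in placed_a:
        emit("B", resnum, letter, coords)
    for resnum, letter, coords in sorted(placed_b):
        emit("C", resnum, letter, coords)
    return ComplexStructure(atoms, frozenset(), frozenset({"B", "C"}))


# ---------------------------------------------------------------------------
# protein probes

# Internal heavy-atom geometries for probe residues (arbitrary local frame).
_PROBE_GEOMETRY: dict[str, tuple[tuple[str, tuple[float, float, float]], ...]] = {
    "GLY": (("N", (0.0, 0.0, 0.0)), ("CA", (1.46, 0.0, 0.0)),
            ("C", (2.0, 1.3, 0.3)), ("O", (1.4, 2.3, 0.5))),
    "ALA": (("N", (0.0, 0.0, 0.0)), ("CA", (1.46, 0.0, 0.0)),
            ("C", (2.0, 1.3, 0.3)), ("O", (1.4, 2.3, 0.5)),
            ("CB", (2.0, -0.8, 1.1))),
    "SER": (("N", (0.0, 0.0, 0.0)), ("CA", (1.46, 0.0, 0.0)),
            ("C", (2.0, 1.3, 0.3)), ("O", (1.4, 2.3, 0.5)),
            ("CB", (2.0, -0.8, 1.1)), ("OG", (3.4, -0.9, 1.1))),
    "ASN": (("N", (0.0, 0.0, 0.0)), ("CA", (1.46, 0.0, 0.0)),
            ("C", (2.0, 1.3, 0.3)), ("O", (1.4, 2.3, 0.5)),
            ("CB", (2.0, -0.8, 1.1)), ("CG", (3.5, -0.9, 1.2)),
            ("OD1", (4.1, -1.9, 0.8)), ("ND2", (4.2, 0.1, 1.7))),
    "LYS": (("N", (0.0, 0.0, 0.0)), ("CA", (1.46, 0.0, 0.0)),
            ("C", (2.0, 1.3, 0.3)), ("O", (1.4, 2.3, 0.5)),
            ("CB", (2.0, -0.8, 1.1)), ("CG", (3.5, -0.9, 1.2)),
            ("CD", (4.1, -2.2, 1.5)), ("CE", (5.6, -2.3, 1.6)),
            ("NZ", (6.2, -3.6, 1.9))),
    "ARG": (("N", (0.0, 0.0, 0.0)), ("CA", (1.46, 0.0, 0.0)),
            ("C", (2.0, 1.3, 0.3)), ("O", (1.4, 2.3, 0.5)),
            ("CB", (2.0, -0.8, 1.1)), ("CG", (3.5, -0.9, 1.2)),
            ("CD", (4.1, -2.2, 1.5)), ("NE", (5.5, -2.3, 1.6)),
            ("CZ", (6.2, -3.4, 1.8)), ("NH1", (5.6, -4.6, 1.9)),
            ("NH2", (7.5, -3.4, 1.9))),
}

_MIN_SEPARATION = 1.5  # Å, steric limit for probe placement


def add_probe_protein(cx: ComplexStructure,
                      contacts: list[tuple],
                      chain_id: str = "P") -> ComplexStructure:
    """Place single-residue protein probes at controlled distances.

    Each contact is ``(pair_index, distance, residue_name, atom_name)`` with
    an optional fifth element naming a specific target base atom.  The named
    probe atom is placed radially outward (from the helix axis) from the
    target so that its distance to the nearest base-moiety heavy atom of the
    indicated pair — or to the named target atom — equals ``distance``
    exactly.  The remaining residue atoms extend further outward with
    idealized internal geometry.

    Pair indices are 0-based into the duplex detected on the fixture; for
    fixtures built by :func:`build_bdna`, pair ``i`` is chain B residue
    ``i + 1`` with its chain C partner.
    """
    from .structure_io import base_moiety_atoms, detect_dsdna

    duplexes = detect_dsdna(cx)
    if not duplexes:
        raise FixtureError("no duplex found to attach probes to")
    duplex = duplexes[0]
    new_atoms = list(cx.atoms)
    existing = cx.coords_array()
    resnum = 1 + max((a.residue_number for a in cx.atoms
                      if a.chain_id == chain_id), default=0)
    for contact in contacts:
        pair_index, distance, residue_name, atom_name = contact[:4]
        target_atom = contact[4] if len(contact) > 4 else None
        if distance <= _MIN_SEPARATION:
            raise FixtureError(f"requested distance {distance} below steric limit")
        if residue_name not in _PROBE_GEOMETRY:
            raise FixtureError(f"no probe geometry for residue {residue_name}")
        ba, bb = duplex.pair_residues(pair_index)
        pair_atoms = base_moiety_atoms(cx, ba) + base_moiety_atoms(cx, bb)
        pair_xyz = np.stack([a.coords for a in pair_atoms])
        if target_atom is not None:
            cand = [a for a in pair_atoms if a.atom_name == target_atom]
            if not cand:
                raise FixtureError(
                    f"pair {pair_index} has no base atom {target_atom}")
            origin = cand[0].coords
            ref_xyz = origin[None, :]
        else:
            # aim from the most radially exposed atom of the pair
            radii = np.linalg.norm(pair_xyz[:, :2], axis=1)
            origin = pair_xyz[int(np.argmax(radii))]
            ref_xyz = pair_xyz
        direction = np.array([origin[0], origin[1], 0.0])
        nd = np.linalg.norm(direction)
        direction = direction / nd if nd > 0.5 else np.array([1.0, 0.0, 0.0])

        def min_dist(t: float) -> float:
            p = origin + t * direction
            return float(np.min(np.linalg.norm(ref_xyz - p, axis=1)))

        lo, hi = 0.0, float(distance)
        while min_dist(hi) < distance:
            hi += 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if min_dist(mid) < distance:
                lo = mid
            else:
                hi = mid
        anchor_point = origin + hi * direction

        geom = dict((n, np.array(c)) for n, c in _PROBE_GEOMETRY[residue_name])
        if atom_name not in geom:
            raise FixtureError(
                f"probe residue {residue_name} has no atom {atom_name}")
        local = {n: c - geom[atom_name] for n, c in geom.items()}
        centroid = np.mean(list(local.values()), axis=0)
        nc = np.linalg.norm(centroid)
        if nc > 1e-6:
            axis = np.cross(centroid / nc, direction)
            s = np.linalg.norm(axis)
            if s > 1e-9:
                ang = math.atan2(s, float(np.dot(centroid / nc, direction)))
                rot = RigidTransform.about_axis(axis, ang).rotation
            elif float(np.dot(centroid, direction)) < 0:
                perp = np.cross(direction, np.array([0.0, 0.0, 1.0]))
                if np.linalg.norm(perp) < 1e-9:
                    perp = np.array([1.0, 0.0, 0.0])
                rot = RigidTransform.about_axis(perp, math.pi).rotation
            else:
                rot = np.eye(3)
            local = {n: rot @ c for n, c in local.items()}
        placed = {n: anchor_point + c for n, c in local.items()}

        xyz = np.stack(list(placed.values()))
        gaps = np.linalg.norm(existing[:, None, :] - xyz[None, :, :], axis=2)
        if gaps.min() < _MIN_SEPARATION:
            raise FixtureError(
                f"probe {residue_name} overlaps existing atoms "
                f"(min separation {gaps.min():.2f} Å)")
        order = [n for n, _ in _PROBE_GEOMETRY[residue_name]]
        for n in order:
            new_atoms.append(Atom(chain_id, resnum, residue_name, n,
                                  placed[n], n[0] if n[0] != "O" else "O"))
        existing = np.vstack([existing, xyz])
        resnum += 1
    return ComplexStructure(new_atoms, cx.protein_chains | {chain_id},
                            cx.dna_chains)


# ---------------------------------------------------------------------------
# training sets

_PROBE_MENU = (
    ("SER", "OG"), ("LYS", "NZ"), ("ASN", "ND2"), ("ARG", "NH1"), ("ALA", "CB"),
)
_SAFE_TARGETS = {"A": "N6", "G": "O6", "T": "O4", "C": "N4"}


def make_training_set(n_complexes: int, seed: int,
                      planted: tuple[str, str, str, str, float] | None = None,
                      length: int = 8,
                      return_truth: bool = False):
    """Random-sequence duplexes with probes at seeded random distances.

    ``planted`` = (residue_name, probe_atom, base_letter, base_atom, distance)
    adds one probe at that exact distance from that atom of every occurrence
    of ``base_letter`` on strand A, enriching the corresponding atom-type
    pair at short range — ground truth for potential-training tests.

    With ``return_truth`` the per-probe records
    (complex index, residue, atom, pair index, requested distance) are
    returned alongside the complexes.
    """
    if n_complexes < 1:
        raise FixtureError("need at least one complex")
    rng = np.random.default_rng(seed)
    complexes: list[ComplexStructure] = []
    truth: list[dict] = []
    for ci in range(n_complexes):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        cx = build_bdna(BdnaSpec(seq))
        contacts: list[tuple] = []
        for _ in range(3):
            res, at = _PROBE_MENU[int(rng.integers(len(_PROBE_MENU)))]
            pair = int(rng.integers(1, length - 1))
            dist = float(rng.uniform(3.0, 8.0))
            contacts.append((pair, dist, res, at,
                             _SAFE_TARGETS[seq[pair]]))
        if planted is not None:
            res, at, base, base_atom, dist = planted
            for pair, letter in enumerate(seq):
                if letter == base and 0 < pair < length - 1:
                    contacts.append((pair, float(dist), res, at, base_atom))
        placed = cx
        for contact in contacts:
            try:
                placed = add_probe_protein(placed, [contact])
            except FixtureError:
                continue  # skip sterically impossible draws
            truth.append({"complex": ci, "residue": contact[2],
                          "atom": contact[3], "pair": contact[0],
                          "distance": contact[1]})
        complexes.append(placed)
    if return_truth:
        return complexes, truth
    return complexes
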