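"""Canonical frames, template averaging, base replacement and RMSD."""

import math

import numpy as np
import pytest

import structmotif as sm
from structmotif import chemistry
from structmotif.base_geometry import (GeometryError, canonical_frame,
                                       ideal_base_coords)
from structmotif.geometry import RigidTransform

from conftest import base_atom_dict


def random_transform(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return RigidTransform(rot, rng.normal(scale=5.0, size=3))


class TestRigidTransform:
    def test_inverse_and_compose(self):
        rng = np.random.default_rng(0)
        t = random_transform(rng)
        pts = rng.normal(size=(7, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)
        comp = t.compose(t.inverse())
        assert np.allclose(comp.rotation, np.eye(3), atol=1e-12)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestCanonicalFrame:
    @pytest.mark.parametrize("base", "ACGT")
    def test_template_already_canonical_gives_identity(self, base):
        coords = ideal_base_coords(base)
        frame = canonical_frame(coords, base)
        assert np.allclose(frame.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(frame.translation, 0.0, atol=1e-9)

    @pytest.mark.parametrize("base", "ACGT")
    def test_recovers_applied_transform(self, base):
        rng = np.random.default_rng(3)
        coords = ideal_base_coords(base)
        t = random_transform(rng)
        moved = {n: t.apply(c) for n, c in coords.items()}
        frame = canonical_frame(moved, base)
        # frame must be t^-1: frame(t(x)) = x
        assert np.allclose(frame.rotation, t.inverse().rotation, atol=1e-6)
        assert np.allclose(frame.translation, t.inverse().translation,
                           atol=1e-6)

    def test_missing_anchor_reported(self):
        coords = ideal_base_coords("A")
        del coords["N9"]
        with pytest.raises(GeometryError, match="N9"):
            canonical_frame(coords, "A")

    def test_mirror_image_not_silently_accepted(self):
        # chirality: a mirrored base yields a proper rotation whose frame
        # differs from the original (the ring normal flips with traversal)
        coords = ideal_base_coords("A")
        mirrored = {n: c * np.array([1.0, 1.0, -1.0]) for n, c in coords.items()}
        f = canonical_frame(mirrored, "A")
        assert np.linalg.det(f.rotation) > 0


class TestBuildTemplate:
    def test_single_instance_is_identity(self):
        coords = {n: c for n, c in ideal_base_coords("C").items()
                  if n in chemistry.BASE_ATOMS["C"]}
        tpl = sm.build_template([coords], "C")
        assert np.allclose(tpl.coords, np.stack(
            [coords[n] for n in tpl.atom_names]), atol=1e-9)

    def test_rigid_motions_average_to_the_same_base(self):
        rng = np.random.default_rng(5)
        base = {n: c for n, c in ideal_base_coords("G").items()
                if n in chemistry.BASE_ATOMS["G"]}
        instances = [{n: random_transform(rng).apply(c) for n, c in
                      ((k, base[k]) for k in base)} for _ in range(2)]
        # apply one transform per instance, not per atom
        instances = []
        for _ in range(2):
            t = random_transform(rng)
            instances.append({n: t.apply(c) for n, c in base.items()})
        tpl = sm.build_template(instances, "G")
        ref = sm.build_template([base], "G")
        assert np.allclose(tpl.coords, ref.coords, atol=1e-6)

    def test_noisy_instances_average_out(self):
        rng = np.random.default_rng(42)
        base = {n: c for n, c in ideal_base_coords("A").items()
                if n in chemistry.BASE_ATOMS["A"]}
        instances = []
        for _ in range(100):
            t = random_transform(rng)
            instances.append({n: t.apply(c) + rng.normal(scale=0.05, size=3)
                              for n, c in base.items()})
        tpl = sm.build_template(instances, "A")
        ref = sm.build_template([base], "A")
        # compare shapes (best-fit aligned) so the frame convention's own
        # sensitivity to residual distortion does not enter the measurement
        from scipy.spatial.transform import Rotation
        a, b = tpl.coords, ref.coords
        rot, _ = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        aligned = (a - a.mean(0)) @ rot.as_matrix().T + b.mean(0)
        dev = np.linalg.norm(aligned - b, axis=1)
        assert dev.max() < 0.02

    def test_zero_instances_rejected(self):
        with pytest.raises(GeometryError):
            sm.build_template([], "A")


class TestMutateBase:
    def test_identity_mutation_reproduces_base(self, bare_duplex):
        native = base_atom_dict(bare_duplex, "B", 1, "A")
        tpl = sm.build_template([native], "A")
        mut = sm.mutate_base(bare_duplex, ("B", 1), "A", {"A": tpl})
        for name, coords in native.items():
            new = next(a.coords for a in mut.residue_atoms("B", 1)
                       if a.atom_name == name)
            assert np.allclose(new, coords, atol=1e-6)

    def test_anchor_superposition(self, bare_duplex, templates):
        old_n9 = next(a.coords for a in bare_duplex.residue_atoms("B", 1)
                      if a.atom_name == "N9")
        mut = sm.mutate_base(bare_duplex, ("B", 1), "C", templates)
        new_n1 = next(a.coords for a in mut.residue_atoms("B", 1)
                      if a.atom_name == "N1")
        assert np.linalg.norm(old_n9 - new_n1) < 1e-6

    def test_plane_normal_alignment_and_backbone(self, bare_duplex, templates):
        old = base_atom_dict(bare_duplex, "B", 1, "A")
        mut = sm.mutate_base(bare_duplex, ("B", 1), "C", templates)
        new = base_atom_dict(mut, "B", 1, "C")
        nz_old = canonical_frame(old, "A").rotation[2]
        nz_new = canonical_frame(new, "C").rotation[2]
        angle = math.acos(min(1.0, abs(float(nz_old @ nz_new))))
        assert angle < 1e-6
        for a in bare_duplex.residue_atoms("B", 1):
            if a.atom_name in chemistry.SUGAR_PHOSPHATE_ATOMS:
                same = next(b.coords for b in mut.residue_atoms("B", 1)
                            if b.atom_name == a.atom_name)
                assert np.array_equal(same, a.coords)  # bitwise

    def test_non_nucleotide_rejected(self, duplex_complex, templates):
        with pytest.raises(GeometryError):
            sm.mutate_base(duplex_complex, ("P", 1), "A", templates)


class TestMutatePair:
    def test_pair_replacement_renames_both_strands(self, bare_duplex,
                                                   templates):
        dup = sm.detect_dsdna(bare_duplex)[0]
        mut = sm.mutate_pair(bare_duplex, dup, 0, "C<->G", templates)
        assert {a.residue_name for a in mut.residue_atoms("B", 1)} == {"DC"}
        assert {a.residue_name for a in mut.residue_atoms("C", 6)} == {"DG"}

    def test_round_trip_restores_native_bases(self, bare_duplex, templates):
        dup = sm.detect_dsdna(bare_duplex)[0]
        native_templates = {
            "A": sm.build_template([base_atom_dict(bare_duplex, "B", 1, "A")],
                                   "A"),
            "T": sm.build_template([base_atom_dict(bare_duplex, "C", 6, "T")],
                                   "T"),
        }
        fwd = sm.mutate_pair(bare_duplex, dup, 0, "G<->C", templates)
        back = sm.mutate_pair(fwd, dup, 0, "A<->T",
                              {**templates, **native_templates})
        assert sm.rmsd(back, bare_duplex) < 1e-6

    def test_non_complementary_pair_rejected(self, bare_duplex, templates):
        dup = sm.detect_dsdna(bare_duplex)[0]
        with pytest.raises(GeometryError, match="complementary"):
            sm.mutate_pair(bare_duplex, dup, 0, "A<->C", templates)

    def test_pair_index_out_of_range(self, bare_duplex, templates):
        dup = sm.detect_dsdna(bare_duplex)[0]
        with pytest.raises(GeometryError, match="range"):
            sm.mutate_pair(bare_duplex, dup, 99, "C<->G", templates)


class TestRmsd:
    def test_self_is_zero(self, bare_duplex):
        assert sm.rmsd(bare_duplex, bare_duplex) == 0.0

    def test_uniform_translation_closed_form(self, bare_duplex):
        moved = sm.ComplexStructure(
            [sm.Atom(a.chain_id, a.residue_number, a.residue_name,
                     a.atom_name, a.coords + np.array([3.0, 4.0, 0.0]),
                     a.element) for a in bare_duplex.atoms],
            bare_duplex.protein_chains, bare_duplex.dna_chains)
        assert sm.rmsd(bare_duplex, moved) == pytest.approx(5.0, abs=1e-12)

    def test_single_displacement_closed_form(self, bare_duplex):
        atoms = list(bare_duplex.atoms)
        d = 2.0
        atoms[0] = sm.Atom(atoms[0].chain_id, atoms[0].residue_number,
                           atoms[0].residue_name, atoms[0].atom_name,
                           atoms[0].coords + np.array([d, 0.0, 0.0]),
                           atoms[0].element)
        moved = sm.ComplexStructure(atoms, bare_duplex.protein_chains,
                                    bare_duplex.dna_chains)
        n = len(atoms)
        assert sm.rmsd(bare_duplex, moved) == pytest.approx(
            d / math.sqrt(n), rel=1e-12)

    def test_disjoint_structures_rejected(self, bare_duplex, duplex_complex):
        probe_only = sm.ComplexStructure(
            [a for a in duplex_complex.atoms if a.chain_id == "P"],
            frozenset({"P"}), frozenset())
        with pytest.raises(GeometryError):
            sm.rmsd(bare_duplex, probe_only)
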