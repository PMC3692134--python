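import math

import numpy as np
import pytest
from hypothesis import settings

import structmotif as sm
from structmotif import chemistry

settings.register_profile("default", derandomize=True, max_examples=30,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def templates():
    return sm.default_templates()


@pytest.fixture(scope="session")
def duplex_complex():
    """6-mer idealized duplex with one serine probe 2.9 A from the A at pair 3."""
    cx = sm.build_bdna(sm.BdnaSpec("GCATGC"))
    return sm.add_probe_protein(cx, [(2, 2.9, "SER", "OG", "N6")])


@pytest.fixture(scope="session")
def bare_duplex():
    return sm.build_bdna(sm.BdnaSpec("ACGTAC"))


@pytest.fixture(scope="session")
def training_set():
    return sm.make_training_set(20, seed=11,
                                planted=("SER", "OG", "A", "N6", 2.9))


@pytest.fixture(scope="session")
def potential(training_set):
    return sm.train_potential(training_set)


def brute_force_dg(cx, pot):
    """Independent O(n^2) double loop over all typed atom pairs."""
    total = 0.0
    for a in cx.protein_atoms():
        ta = sm.atom_type(a.residue_name, a.atom_name, pot.catalog)
        if ta is None or ta[0] != "protein":
            continue
        for d in cx.dna_atoms():
            td = sm.atom_type(d.residue_name, d.atom_name, pot.catalog)
            if td is None or td[0] != "dna":
                continue
            r = math.dist(a.coords, d.coords)
            if r <= pot.cutoff:
                b = min(int(r / pot.bin_width), pot.n_bins - 1)
                total += float(pot.scores[ta[1], td[1], b])
    return total


def base_atom_dict(cx, chain_id, resnum, letter):
    names = set(chemistry.BASE_ATOMS[letter])
    return {a.atom_name: a.coords
            for a in cx.residue_atoms(chain_id, resnum)
            if a.atom_name in names}


def shift_chain(cx, chain_map, offset=(0.0, 0.0, 0.0)):
    """Relabel chains and translate: test helper for composite fixtures."""
    off = np.asarray(offset, dtype=float)
    atoms = [sm.Atom(chain_map.get(a.chain_id, a.chain_id), a.residue_number,
                     a.residue_name, a.atom_name, a.coords + off, a.element,
                     a.insertion_code)
             for a in cx.atoms]
    remap = lambda s: frozenset(chain_map.get(c, c) for c in s)
    return sm.ComplexStructure(atoms, remap(cx.protein_chains),
                               remap(cx.dna_chains))
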