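"""Contact-dot surrogate, RIN construction, and residue selection."""

import math

import numpy as np
import pytest

import rincluster as rc
from rincluster import fixtures as fx
from rincluster.contacts import (ContactParams, _fibonacci_directions,
                                 add_bridging_residues, build_rin,
                                 count_contacts, generate_surface_dots,
                                 select_residues, RIN, ContactEdge, Selection)
from rincluster.structure import Atom, Fragment, Structure


def _atom(coords, element="O", serial=1):
    return Atom(serial=serial, name=element, element=element, coords=coords)


def test_isolated_atom_dot_count_matches_sphere_area():
    params = ContactParams(dot_density=16.0)
    atom = _atom([0.0, 0.0, 0.0])
    dots = generate_surface_dots(atom, [], params)
    expected = round(4 * math.pi * atom.vdw_radius ** 2 * params.dot_density)
    assert len(dots) == expected
    radii = np.linalg.norm(dots - atom.coords, axis=1)
    np.testing.assert_allclose(radii, atom.vdw_radius, atol=1e-9)


def test_zero_density_gives_no_dots():
    dots = generate_surface_dots(_atom([0, 0, 0]), [], ContactParams(dot_density=0.0))
    assert len(dots) == 0


def test_coincident_equal_spheres_occlude_everything():
    a = _atom([0.0, 0.0, 0.0], serial=1)
    b = _atom([0.0, 0.0, 0.0], serial=2)
    assert len(generate_surface_dots(a, [b], ContactParams())) == 0
    assert len(generate_surface_dots(b, [a], ContactParams())) == 0


def _two_waters(separation):
    st = Structure(fragments=[
        Fragment(chain="W", resnum=1, resname="HOH", kind="water",
                 atoms=[_atom([0.0, 0.0, 0.0])]),
        Fragment(chain="W", resnum=2, resname="HOH", kind="water",
                 atoms=[_atom([separation, 0.0, 0.0], serial=2)]),
    ])
    return rc.add_hydrogens(st)


def test_two_waters_match_brute_force_enumeration():
    """Independent loop-level occlusion + gap count over the raw dot lattice."""
    st = _two_waters(2.8)
    params = ContactParams()
    fast = count_contacts(st, "W:1", "W:2", params)

    def directed(fa, fb):
        total = 0
        occluders = fa.atoms + fb.atoms
        for atom in fa.atoms:
            r = atom.vdw_radius
            n = round(4 * math.pi * r * r * params.dot_density)
            # same lattice and frame as the implementation, raw (unoccluded)
            from rincluster.contacts import _local_frame
            frame = _local_frame(atom, fa.atoms)
            for direction in _fibonacci_directions(n):
                dot = atom.coords + r * (frame @ direction)
                buried = any(
                    np.linalg.norm(dot - o.coords) <= o.vdw_radius + 1e-9
                    for o in occluders if o is not atom)
                if buried:
                    continue
                gap = min(np.linalg.norm(dot - b.coords) - b.vdw_radius
                          for b in fb.atoms)
                if gap <= params.max_gap:
                    total += 1
        return total

    fa, fb = st.fragments
    assert fast == directed(fa, fb) + directed(fb, fa)
    assert fast > 0


def test_count_is_symmetric(protonated_site):
    p = ContactParams()
    assert (count_contacts(protonated_site, "X:1", "A:212", p)
            == count_contacts(protonated_site, "A:212", "X:1", p))


def test_distant_fragments_have_zero_count():
    st = _two_waters(100.0)
    assert count_contacts(st, "W:1", "W:2") == 0


def test_count_monotone_when_separating_beyond_contact(protonated_site):
    """Past vdW-surface contact, pulling a fragment away never adds dots."""
    base = protonated_site
    prev = None
    for extra in (0.4, 0.8, 1.2, 1.6, 2.4):
        st = base.copy()
        for a in st.fragment(("A", 212)).atoms:
            a.coords = a.coords + extra * np.array([0.0, 1.0, 0.0])
        c = count_contacts(st, "X:1", "A:212")
        if prev is not None:
            assert c <= prev
        prev = c
    assert prev == 0 or prev < count_contacts(base, "X:1", "A:212")


def test_counts_invariant_under_rigid_motion(protonated_site):
    from rincluster.fixtures import _axis_rotation
    st = protonated_site.copy()
    R = _axis_rotation(np.array([1.0, 2.0, 3.0]) / math.sqrt(14.0), 1.1)
    t = np.array([7.0, -4.0, 2.5])
    for a in st.all_atoms():
        a.coords = R @ a.coords + t
    for pair in (("X:1", "A:212"), ("X:2", "A:214")):
        assert (count_contacts(st, *pair)
                == count_contacts(protonated_site, *pair))


class TestRIN:
    def test_ladder_ranking(self, protonated_site):
        net = build_rin(protonated_site, {"X:1", "X:2"})
        counts = {k: net.seed_contact(k) for k in net.nodes if k not in net.seed}
        assert ("A", 228) not in counts          # 12 A residue: zero dots
        assert counts[("A", 212)] > counts[("A", 214)] > 0

    def test_empty_seed_rejected(self, protonated_site):
        with pytest.raises(ValueError, match="seed"):
            build_rin(protonated_site, set())

    def test_seed_without_neighbors_gives_seed_only(self):
        st = _two_waters(100.0)
        net = build_rin(st, {"W:1"})
        assert set(net.nodes) == {("W", 1)}


class TestSelection:
    @pytest.fixture()
    def net(self):
        edges = [ContactEdge(("S", 1), ("A", 10), 80),
                 ContactEdge(("S", 1), ("A", 20), 55),
                 ContactEdge(("S", 1), ("A", 30), 12)]
        return RIN(nodes=[("S", 1), ("A", 10), ("A", 20), ("A", 30)],
                   edges=edges, seed={("S", 1)})

    def test_threshold_keeps_strictly_greater(self, net):
        sel = select_residues(net, mode="threshold", threshold=50)
        assert sel.chosen == [("A", 10), ("A", 20)]

    def test_huge_threshold_selects_nothing(self, net):
        assert select_residues(net, threshold=10 ** 9).chosen == []

    def test_maximal_contains_every_threshold_selection(self, net):
        maximal = set(select_residues(net, mode="maximal").chosen)
        for thr in (0, 10, 50, 70, 100):
            assert set(select_residues(net, threshold=thr).chosen) <= maximal

    def test_ordering_descending_counts_ties_by_resnum(self):
        edges = [ContactEdge(("S", 1), ("A", 30), 55),
                 ContactEdge(("S", 1), ("A", 10), 55),
                 ContactEdge(("S", 1), ("A", 20), 80)]
        net = RIN(nodes=[("S", 1), ("A", 30), ("A", 10), ("A", 20)],
                  edges=edges, seed={("S", 1)})
        sel = select_residues(net, mode="maximal")
        assert sel.chosen == [("A", 20), ("A", 10), ("A", 30)]

    def test_negative_threshold_rejected(self, net):
        with pytest.raises(ValueError):
            select_residues(net, mode="threshold", threshold=-1)


class TestBridging:
    def _structure(self, resnums):
        frags = [fx.build_residue("GLY", resnum=n) for n in resnums]
        for f in frags:
            for a in f.atoms:
                a.coords = a.coords + np.array([0.0, 0.0, 8.0 * f.resnum])
        return Structure(fragments=frags)

    def test_single_gap_is_bridged(self):
        st = self._structure([143, 144, 145])
        sel = Selection(chosen=[("A", 143), ("A", 145)], mode="maximal")
        out = add_bridging_residues(sel, st)
        assert out.bridging == [("A", 144)]

    def test_contiguous_block_needs_no_bridges(self):
        st = self._structure([257, 258, 259])
        sel = Selection(chosen=[("A", 257), ("A", 258), ("A", 259)], mode="maximal")
        assert add_bridging_residues(sel, st).bridging == []

    def test_gap_scan_matches_hand_enumeration(self):
        resnums = [255, 256, 257, 258, 259, 260, 261]
        chosen = [255, 257, 259, 261]
        st = self._structure(resnums)
        sel = Selection(chosen=[("A", n) for n in chosen], mode="maximal")
        out = add_bridging_residues(sel, st)
        expected = [("A", n) for n in (256, 258, 260)]
        assert out.bridging == expected
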