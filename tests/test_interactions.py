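"""Salt-bridge and hydrogen-bond detection against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smnprofiler.chemistry import CHARGED_GROUPS, DH_COVALENT_CUTOFF, SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS
from smnprofiler.interactions import (
    AtomSelector,
    DetectionConfig,
    atom_pair_distance_series,
    charged_groups,
    classify_contact_scope,
    detect_hydrogen_bonds,
    detect_salt_bridges,
    donor_acceptor_inventory,
    hbond_criteria_satisfied,
)
from smnprofiler.structure_io import Atom, Model, ProfilerWarning, Residue, StructureEnsemble
from smnprofiler.synthetic import FixtureSpec, make_hbond_model, make_salt_bridge_model

from conftest import random_model


# ---------------------------------------------------------------------------
# Independent brute-force oracles (plain double loops, law-of-cosines angles)
# ---------------------------------------------------------------------------

def brute_force_salt_bridges(model, cutoff, mode):
    found = set()
    for r1 in model.residues:
        for r2 in model.residues:
            if r1.key == r2.key:
                continue
            s1, s2 = CHARGED_GROUPS.get(r1.res_type), CHARGED_GROUPS.get(r2.res_type)
            if s1 is None or s2 is None or s1[0] != "negative" or s2[0] != "positive":
                continue
            atoms1 = [r1.get_atom(n) for n in s1[1] if r1.get_atom(n)]
            atoms2 = [r2.get_atom(n) for n in s2[1] if r2.get_atom(n)]
            if not atoms1 or not atoms2:
                continue
            if mode == "group_center":
                c1 = sum(a.coord for a in atoms1) / len(atoms1)
                c2 = sum(a.coord for a in atoms2) / len(atoms2)
                if math.dist(c1, c2) <= cutoff:
                    found.add((r1.key, r2.key))
            else:
                for a1 in atoms1:
                    for a2 in atoms2:
                        if math.dist(a1.coord, a2.coord) <= cutoff:
                            found.add((r1.key, r2.key, a1.name, a2.name))
    return found


def brute_force_hbonds(model, da_cutoff, angle_cutoff, backbone_o=True):
    found = set()
    for rd in model.residues:
        donor_names = SIDECHAIN_DONORS.get(rd.res_type, ())
        for dn in donor_names:
            d = rd.get_atom(dn)
            if d is None:
                continue
            hydrogens = [a for a in rd.atoms if a.element == "H"
                         and math.dist(a.coord, d.coord) < DH_COVALENT_CUTOFF]
            for h in hydrogens:
                for ra in model.residues:
                    if ra.key == rd.key:
                        continue
                    acc_names = list(SIDECHAIN_ACCEPTORS.get(ra.res_type, ()))
                    if backbone_o:
                        acc_names.append("O")
                    for an in acc_names:
                        a = ra.get_atom(an)
                        if a is None:
                            continue
                        if ra.res_type == "HIS" and an in ("ND1", "NE2"):
                            if any(math.dist(x.coord, a.coord) < DH_COVALENT_CUTOFF
                                   for x in ra.atoms if x.element == "H"):
                                continue
                        d_da = math.dist(d.coord, a.coord)
                        d_dh = math.dist(d.coord, h.coord)
                        d_ha = math.dist(h.coord, a.coord)
                        # law of cosines: angle at the donor vertex
                        cosang = (d_da**2 + d_dh**2 - d_ha**2) / (2 * d_da * d_dh)
                        angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                        if d_da <= da_cutoff and angle <= angle_cutoff:
                            found.add((rd.key, dn, h.name, ra.key, an))
    return found


# ---------------------------------------------------------------------------
# Oracle equivalence on randomized multi-residue scenes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mode", ["group_center", "atom_pair"])
@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_salt_bridge_detection_matches_brute_force(mode, seed):
    model = random_model(np.random.default_rng(seed), n_residues=16, box=24.0)
    config = DetectionConfig(sb_mode=mode)
    detected = detect_salt_bridges(model, config)
    if mode == "group_center":
        got = {(b.group_a.residue.key, b.group_b.residue.key) for b in detected}
    else:
        got = {(b.group_a.residue.key, b.group_b.residue.key, b.atom_a, b.atom_b)
               for b in detected}
    assert got == brute_force_salt_bridges(model, 4.0, mode)
    assert len(got) == len(detected)  # each interaction emitted exactly once


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_hbond_detection_matches_brute_force(seed):
    model = random_model(np.random.default_rng(100 + seed), n_residues=16, box=24.0)
    got = {(b.donor_residue.key, b.donor_atom, b.hydrogen_atom,
            b.acceptor_residue.key, b.acceptor_atom)
           for b in detect_hydrogen_bonds(model)}
    assert got == brute_force_hbonds(model, 3.0, 30.0)


def test_detection_monotone_in_cutoffs(crowded_model):
    sb_sets, hb_sets = [], []
    for factor in (0.8, 1.0, 1.3, 1.8):
        sb = detect_salt_bridges(crowded_model, DetectionConfig(sb_cutoff=4.0 * factor))
        hb = detect_hydrogen_bonds(crowded_model, DetectionConfig(
            hb_da_cutoff=3.0 * factor, hb_angle_cutoff=30.0 * factor))
        sb_sets.append({(b.group_a.residue.key, b.group_b.residue.key, b.atom_a, b.atom_b)
                        for b in sb})
        hb_sets.append({(b.donor_residue.key, b.hydrogen_atom, b.acceptor_residue.key,
                         b.acceptor_atom) for b in hb})
    for smaller, larger in zip(sb_sets, sb_sets[1:]):
        assert smaller <= larger
    for smaller, larger in zip(hb_sets, hb_sets[1:]):
        assert smaller <= larger


def test_no_self_interactions(crowded_model):
    for b in detect_salt_bridges(crowded_model):
        assert b.group_a.residue.key != b.group_b.residue.key
    for b in detect_hydrogen_bonds(crowded_model):
        assert b.donor_residue.key != b.acceptor_residue.key


# ---------------------------------------------------------------------------
# Charged groups
# ---------------------------------------------------------------------------

def test_charged_groups_polarity_and_center():
    model = make_salt_bridge_model(FixtureSpec(distance=5.0))
    groups = {g.residue.res_type: g for g in charged_groups(model)}
    assert groups["ASP"].polarity == "negative"
    assert groups["LYS"].polarity == "positive"
    od1 = model.residues[0].get_atom("OD1").coord
    od2 = model.residues[0].get_atom("OD2").coord
    np.testing.assert_allclose(groups["ASP"].center, (od1 + od2) / 2)


def test_degenerate_group_center_at_single_atom():
    model = make_salt_bridge_model(FixtureSpec(distance=5.0))
    asp = model.residues[0]
    asp.atoms = [a for a in asp.atoms if a.name != "OD2"]
    groups = charged_groups(Model(index=1, residues=model.residues))
    asp_group = next(g for g in groups if g.residue.res_type == "ASP")
    np.testing.assert_allclose(asp_group.center, asp.get_atom("OD1").coord)


def test_chargeless_sidechain_skipped_with_warning():
    model = make_salt_bridge_model(FixtureSpec(distance=5.0))
    asp = model.residues[0]
    asp.atoms = [a for a in asp.atoms if a.name not in ("OD1", "OD2")]
    with pytest.warns(ProfilerWarning, match="no charged-group atoms"):
        groups = charged_groups(Model(index=1, residues=model.residues))
    assert [g.residue.res_type for g in groups] == ["LYS"]


# ---------------------------------------------------------------------------
# Boundary inclusivity and constructed geometries
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("distance,expected", [(3.8, 1), (4.0, 1), (4.2, 0)])
def test_salt_bridge_cutoff_boundary(distance, expected):
    model = make_salt_bridge_model(FixtureSpec(distance=distance))
    bridges = detect_salt_bridges(model, DetectionConfig(sb_mode="group_center"))
    assert len(bridges) == expected
    if expected:
        assert bridges[0].distance == pytest.approx(distance, abs=1e-3)


@pytest.mark.parametrize("partner", ["LYS", "ARG", "HIS"])
def test_salt_bridge_partner_types(partner):
    model = make_salt_bridge_model(FixtureSpec(distance=3.5), partner=partner)
    assert len(detect_salt_bridges(model, DetectionConfig(sb_mode="group_center"))) == 1


@pytest.mark.parametrize("d,angle,expected", [
    (2.63, 18.83, 1),
    (3.0, 30.0, 1),    # double boundary: both criteria inclusive
    (2.9, 35.0, 0),    # angle fails
    (3.2, 10.0, 0),    # distance fails
    (2.5, 45.0, 0),
])
def test_hbond_criteria_on_constructed_geometry(d, angle, expected):
    model = make_hbond_model(FixtureSpec(kind="hbond", distance=d, angle=angle))
    bonds = [b for b in detect_hydrogen_bonds(model) if b.hydrogen_atom == "HZ1"]
    assert len(bonds) == expected
    if expected:
        assert bonds[0].d_da == pytest.approx(d, abs=1e-3)
        assert bonds[0].angle_adh == pytest.approx(angle, abs=0.05)


@given(d=st.floats(2.0, 4.0), angle=st.floats(0.5, 60.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_hbond_detection_agrees_with_direct_criteria(d, angle):
    """Detection on a constructed triple equals the two-criteria predicate."""
    model = make_hbond_model(FixtureSpec(kind="hbond", distance=d, angle=angle))
    bonds = [b for b in detect_hydrogen_bonds(model) if b.hydrogen_atom == "HZ1"]
    # evaluate the predicate on the geometry actually emitted (PDB precision)
    if bonds:
        assert hbond_criteria_satisfied(bonds[0].d_da, bonds[0].angle_adh)
    elif abs(d - 3.0) > 2e-3 and abs(angle - 30.0) > 0.1:
        assert not hbond_criteria_satisfied(d, angle)


def test_donor_acceptor_inventory_contents():
    model = make_hbond_model(FixtureSpec(kind="hbond", distance=2.8, angle=15.0))
    donors, acceptors = donor_acceptor_inventory(model)
    lys_donors = [(d.name, h.name) for r, d, h in donors if r.res_type == "LYS"]
    assert sorted(lys_donors) == [("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")]
    acc_names = {(r.res_type, a.name) for r, a in acceptors}
    assert ("GLN", "OE1") in acc_names
    assert ("GLN", "O") in acc_names    # backbone carbonyl in the default scope
    strict = donor_acceptor_inventory(model, DetectionConfig(hb_acceptor_scope="sidechain_only"))
    assert all(a.name != "O" for _, a in strict[1])


def test_hydrogen_free_model_yields_no_donors():
    model = make_hbond_model(FixtureSpec(kind="hbond", distance=2.8, angle=15.0))
    stripped = Model(index=1, residues=[
        Residue(r.chain_id, r.number, r.icode, r.res_type,
                [a for a in r.atoms if a.element != "H"])
        for r in model.residues
    ])
    with pytest.warns(ProfilerWarning, match="without bound hydrogens"):
        donors, _ = donor_acceptor_inventory(stripped)
    assert donors == []
    assert detect_hydrogen_bonds(stripped) == []


# ---------------------------------------------------------------------------
# Distance series and scope
# ---------------------------------------------------------------------------

def _two_model_pair_ensemble(d1, d2):
    models = []
    for k, d in enumerate((d1, d2), 1):
        m = make_salt_bridge_model(FixtureSpec(distance=5.0))
        lys = m.residues[1]
        shift = np.array([d - 5.0, 0.0, 0.0])
        lys.atoms = [Atom(a.name, a.element, a.coord + shift) for a in lys.atoms]
        models.append(Model(index=k, residues=m.residues))
    return StructureEnsemble("pair", models)


def test_distance_series_closed_form():
    # NZ sits exactly at (d, 0, 0) and the carboxylate midpoint at the origin;
    # OD2 is offset by 0.8 A in y, so the expected distances are hypot(d, 0.8)
    ens = _two_model_pair_ensemble(2.0, 4.0)
    series = atom_pair_distance_series(
        ens, AtomSelector("A", 1, "OD2"), AtomSelector("A", 2, "NZ"))
    expected = [math.hypot(d, 0.8) for d in (2.0, 4.0)]
    assert series.distances == pytest.approx(expected, abs=1e-3)
    assert series.mean == pytest.approx(np.mean(expected), abs=1e-3)
    assert series.std == pytest.approx(np.std(expected), abs=1e-3)  # population std


def test_distance_series_mean_and_population_std_exact():
    ens = StructureEnsemble("twopoint", [
        Model(index=k, residues=[
            Residue("A", 1, "", "ASP", [Atom("OD1", "O", np.zeros(3))]),
            Residue("A", 2, "", "LYS", [Atom("NZ", "N", np.array([d, 0.0, 0.0]))]),
        ])
        for k, d in enumerate((2.0, 4.0), 1)
    ])
    series = atom_pair_distance_series(
        ens, AtomSelector("A", 1, "OD1"), AtomSelector("A", 2, "NZ"))
    assert series.mean == pytest.approx(3.0)
    assert series.std == pytest.approx(1.0)


def test_distance_series_identical_models_zero_std():
    ens = _two_model_pair_ensemble(3.0, 3.0)
    series = atom_pair_distance_series(
        ens, AtomSelector("A", 1, "OD1"), AtomSelector("A", 2, "NZ"))
    assert series.std == pytest.approx(0.0, abs=1e-9)


def test_distance_series_skips_unresolvable_models():
    ens = _two_model_pair_ensemble(2.0, 4.0)
    ens.models[1].residues[1].atoms = [
        a for a in ens.models[1].residues[1].atoms if a.name != "NZ"]
    with pytest.warns(ProfilerWarning, match="unresolved"):
        series = atom_pair_distance_series(
            ens, AtomSelector("A", 1, "OD2"), AtomSelector("A", 2, "NZ"))
    assert series.model_indices == [1]


def test_contact_scope_by_chain():
    same = make_salt_bridge_model(FixtureSpec(distance=3.5))
    bridge = detect_salt_bridges(same, DetectionConfig(sb_mode="group_center"))[0]
    assert classify_contact_scope(bridge) == "intramolecular"
    cross = make_hbond_model(FixtureSpec(kind="hbond", distance=2.63, angle=18.83))
    bond = detect_hydrogen_bonds(cross)[0]  # donor chain B, acceptor chain A
    assert classify_contact_scope(bond) == "intermolecular"
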