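"""Synthetic structure and assignment fixtures with controlled geometry.

Every generator emits plain text (PDB or NMR-STAR/TSV) built from real
residue/atom nomenclature so the chemistry tables are exercised end to end:
a charged pair at an exact group-center distance, a donor-hydrogen-acceptor
triple at an exact distance and ADH angle, a residue buried behind an
occluding carbon shell, a multi-model ensemble with seeded coordinate jitter,
and an assignment table with an explicit dropped-nucleus set.

Because PDB coordinates carry three decimals, constructed distances are exact
to about 1e-3 A and constructed angles to about 0.05 degrees; the generators
place the controlled atoms on 3-decimal-representable positions wherever the
target geometry allows.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .shift_audit import load_expected_nuclei
from .structure_io import (
    Atom,
    Model,
    Residue,
    StructureEnsemble,
    ensemble_to_pdb_text,
    model_to_pdb_lines,
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture (seed fixed => byte-identical output)."""

    kind: str = "salt_bridge"       # salt_bridge | hbond | burial | ensemble | assignments
    distance: float = 3.8           # A: group-center or donor-acceptor distance
    angle: float = 20.0             # deg: ADH angle (hbond fixtures)
    shell_radius: float = 6.0       # A (burial fixtures)
    n_occluders: int = 150          # shell atom count (burial fixtures)
    n_models: int = 1
    jitter_sd: float = 0.0          # A, isotropic per-atom Gaussian jitter
    seed: int = 0

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


def _atom(name: str, element: str, coord) -> Atom:
    # exact coordinates in memory; PDB serialization rounds to 3 decimals
    return Atom(name=name, element=element, coord=np.asarray(coord, dtype=float))


def _residue(chain: str, number: int, res_type: str,
             atoms: list[tuple[str, str, tuple]]) -> Residue:
    return Residue(chain, number, "", res_type,
                   [_atom(n, e, c) for n, e, c in atoms])


# Rough but self-consistent local templates.  The charged/donor group sits at
# the local origin; the rest of the residue extends along -x (or +x for the
# mirrored partner) so two residues facing each other only approach through
# the controlled atoms.

def _asp(chain: str, number: int, origin) -> Residue:
    ox, oy, oz = origin
    return _residue(chain, number, "ASP", [
        ("N",   "N", (ox - 4.2, oy + 1.5, oz + 0.5)),
        ("CA",  "C", (ox - 3.5, oy + 0.5, oz)),
        ("CB",  "C", (ox - 2.0, oy + 0.6, oz)),
        ("CG",  "C", (ox - 0.7, oy, oz)),
        ("OD1", "O", (ox, oy + 0.8, oz)),
        ("OD2", "O", (ox, oy - 0.8, oz)),     # carboxylate midpoint == origin
        ("C",   "C", (ox - 4.2, oy - 0.6, oz - 0.5)),
        ("O",   "O", (ox - 5.2, oy - 0.8, oz - 1.2)),
    ])


def _lys(chain: str, number: int, origin, hydrogens: dict[str, tuple] | None = None) -> Residue:
    """Lys with NZ at *origin*, backbone extending +x; HZ positions overridable."""
    ox, oy, oz = origin
    hz = hydrogens if hydrogens is not None else {
        "HZ1": (ox + 0.35, oy + 0.94, oz),
        "HZ2": (ox + 0.35, oy - 0.47, oz + 0.82),
        "HZ3": (ox + 0.35, oy - 0.47, oz - 0.82),
    }
    atoms = [
        ("NZ", "N", (ox, oy, oz)),
        *[(name, "H", coord) for name, coord in hz.items()],
        ("CE", "C", (ox + 1.47, oy, oz)),
        ("CD", "C", (ox + 2.9, oy + 0.3, oz)),
        ("CG", "C", (ox + 4.0, oy - 0.5, oz)),
        ("CB", "C", (ox + 5.4, oy, oz)),
        ("CA", "C", (ox + 6.5, oy + 0.7, oz)),
        ("N",  "N", (ox + 7.3, oy + 1.4, oz + 0.6)),
        ("C",  "C", (ox + 7.2, oy - 0.4, oz - 0.6)),
        ("O",  "O", (ox + 8.3, oy - 0.5, oz - 1.0)),
    ]
    return _residue(chain, number, "LYS", atoms)


def _arg(chain: str, number: int, origin) -> Residue:
    """Arg with the guanidinium-nitrogen center exactly at *origin*, extending +x."""
    ox, oy, oz = origin
    ne = np.array([0.0, 1.15, 0.0])
    nh1 = np.array([0.0, -0.6, 1.0])
    nh2 = np.array([0.0, -0.6, -1.0])
    shift = (ne + nh1 + nh2) / 3.0          # recenter so the mean is the origin
    base = np.array([ox, oy, oz]) - shift
    return _residue(chain, number, "ARG", [
        ("NE",  "N", tuple(base + ne)),
        ("NH1", "N", tuple(base + nh1)),
        ("NH2", "N", tuple(base + nh2)),
        ("CZ",  "C", tuple(base + np.array([0.5, 0.0, 0.0]))),
        ("CD",  "C", tuple(base + np.array([0.6, 2.3, 0.0]))),
        ("CG",  "C", tuple(base + np.array([1.9, 3.0, 0.0]))),
        ("CB",  "C", tuple(base + np.array([3.2, 2.4, 0.0]))),
        ("CA",  "C", tuple(base + np.array([4.4, 3.2, 0.0]))),
        ("N",   "N", tuple(base + np.array([5.2, 3.9, 0.7]))),
        ("C",   "C", tuple(base + np.array([5.1, 2.5, -0.8]))),
        ("O",   "O", tuple(base + np.array([6.2, 2.4, -1.2]))),
    ])


def _his(chain: str, number: int, origin) -> Residue:
    """His with the ND1/NE2 midpoint at *origin*, extending +x."""
    ox, oy, oz = origin
    return _residue(chain, number, "HIS", [
        ("ND1", "N", (ox, oy + 1.1, oz)),
        ("NE2", "N", (ox, oy - 1.1, oz)),
        ("CE1", "C", (ox - 0.7, oy, oz + 0.3)),
        ("CD2", "C", (ox + 1.0, oy - 1.0, oz - 0.3)),
        ("CG",  "C", (ox + 1.2, oy + 0.9, oz)),
        ("CB",  "C", (ox + 2.6, oy + 1.3, oz)),
        ("CA",  "C", (ox + 3.8, oy + 0.6, oz)),
        ("N",   "N", (ox + 4.6, oy + 1.3, oz + 0.7)),
        ("C",   "C", (ox + 4.5, oy - 0.1, oz - 0.8)),
        ("O",   "O", (ox + 5.6, oy - 0.2, oz - 1.2)),
    ])


def _gln_acceptor(chain: str, number: int, origin) -> Residue:
    """Gln with OE1 at *origin*, the rest of the residue extending +x."""
    ox, oy, oz = origin
    return _residue(chain, number, "GLN", [
        ("OE1",  "O", (ox, oy, oz)),
        ("CD",   "C", (ox + 1.0, oy + 0.5, oz)),
        ("NE2",  "N", (ox + 1.2, oy + 1.85, oz)),
        ("HE21", "H", (ox + 2.1, oy + 2.25, oz)),
        ("HE22", "H", (ox + 0.45, oy + 2.5, oz)),
        ("CG",   "C", (ox + 2.1, oy - 0.4, oz)),
        ("CB",   "C", (ox + 3.5, oy + 0.1, oz)),
        ("CA",   "C", (ox + 4.6, oy - 0.7, oz)),
        ("N",    "N", (ox + 5.4, oy - 1.3, oz + 0.8)),
        ("C",    "C", (ox + 5.3, oy + 0.1, oz - 0.9)),
        ("O",    "O", (ox + 6.4, oy + 0.2, oz - 1.3)),
    ])


_POSITIVE_PARTNERS = {"LYS": _lys, "ARG": _arg, "HIS": _his}


def make_salt_bridge_model(spec: FixtureSpec, partner: str = "LYS") -> Model:
    """Asp plus a positive partner with group centers exactly spec.distance apart."""
    if partner not in _POSITIVE_PARTNERS:
        raise ValueError(f"partner must be one of {sorted(_POSITIVE_PARTNERS)}")
    asp = _asp("A", 1, (0.0, 0.0, 0.0))
    pos = _POSITIVE_PARTNERS[partner]("A", 2, (spec.distance, 0.0, 0.0))
    return Model(index=1, residues=[asp, pos])


def make_salt_bridge_fixture(spec: FixtureSpec, partner: str = "LYS") -> str:
    """PDB text for the two-residue charged-pair fixture."""
    return "\n".join(model_to_pdb_lines(make_salt_bridge_model(spec, partner)) + ["END", ""])


def make_hbond_model(spec: FixtureSpec) -> Model:
    """Lys(NZ/HZ1) donor and Gln(OE1) acceptor at exact (distance, ADH angle).

    The donor NZ sits at the origin, the acceptor OE1 along +x at
    spec.distance, and HZ1 at 1.0 A from NZ in the xy-plane at exactly
    spec.angle degrees from the NZ->OE1 direction.  The in-memory model
    carries this geometry exactly; the PDB text rounds coordinates to the
    format's 3 decimals (distance error < 1e-3 A, angle error < 0.05 deg).
    """
    if spec.angle >= 90.0:
        raise ValueError("ADH angle must be < 90 degrees for a bound-hydrogen geometry")
    theta = np.radians(spec.angle)
    h = np.array([np.cos(theta), np.sin(theta), 0.0])

    donor = _lys("B", 1, (0.0, 0.0, 0.0), hydrogens={
        "HZ1": tuple(h),
        "HZ2": (0.35, -0.47, 0.82),
        "HZ3": (0.35, -0.47, -0.82),
    })
    # keep the Lys tail out of the donor-acceptor corridor: it extends +x from
    # NZ, so flip it to -x by mirroring every non-controlled atom
    mirrored = []
    for atom in donor.atoms:
        if atom.name in ("NZ", "HZ1", "HZ2", "HZ3"):
            mirrored.append(atom)
        else:
            mirrored.append(Atom(atom.name, atom.element,
                                 atom.coord * np.array([-1.0, 1.0, 1.0])))
    donor = Residue("B", 1, "", "LYS", mirrored)
    acceptor = _gln_acceptor("A", 2, (spec.distance, 0.0, 0.0))
    return Model(index=1, residues=[donor, acceptor])


def make_hbond_fixture(spec: FixtureSpec) -> str:
    return "\n".join(model_to_pdb_lines(make_hbond_model(spec)) + ["END", ""])


def _ala(chain: str, number: int, origin) -> Residue:
    ox, oy, oz = origin
    return _residue(chain, number, "ALA", [
        ("N",  "N", (ox - 1.2, oy + 0.9, oz)),
        ("CA", "C", (ox, oy, oz)),
        ("CB", "C", (ox + 1.5, oy + 0.4, oz)),
        ("C",  "C", (ox - 0.3, oy - 1.4, oz)),
        ("O",  "O", (ox - 1.4, oy - 1.9, oz)),
    ])


def make_burial_model(spec: FixtureSpec, shell: bool = True) -> Model:
    """A central Ala, optionally enclosed in a spherical carbon-occluder shell.

    Shell atoms are lone glycine CA carbons on a golden-section spiral of
    radius spec.shell_radius; with the default density the central residue's
    relative SASA drops below 0.30, and without the shell it exceeds 0.8.
    """
    from .sasa import sphere_points

    residues = [_ala("A", 1, (0.0, 0.0, 0.0))]
    if shell and spec.n_occluders > 0:
        for i, unit in enumerate(sphere_points(spec.n_occluders)):
            pos = spec.shell_radius * unit
            residues.append(_residue("S", i + 2, "GLY", [("CA", "C", tuple(pos))]))
    return Model(index=1, residues=residues)


def make_burial_fixture(spec: FixtureSpec, shell: bool = True) -> str:
    return "\n".join(model_to_pdb_lines(make_burial_model(spec, shell)) + ["END", ""])


def make_ensemble_fixture(spec: FixtureSpec, base: Model | None = None,
                          pdb_id: str = "fixture") -> str:
    """Multi-model PDB text: *base* replicated spec.n_models times with jitter.

    Jitter is isotropic per-atom Gaussian noise of sd spec.jitter_sd, drawn
    from ``numpy.random.default_rng(spec.seed)``; identical specs therefore
    produce byte-identical files.
    """
    if spec.n_models < 1:
        raise ValueError("n_models must be >= 1")
    base = base or make_salt_bridge_model(spec)
    rng = np.random.default_rng(spec.seed)
    models = []
    for k in range(spec.n_models):
        residues = []
        for res in base.residues:
            atoms = [
                Atom(a.name, a.element,
                     a.coord + rng.normal(0.0, spec.jitter_sd, 3)
                     if spec.jitter_sd > 0 else a.coord,
                     a.altloc, a.occupancy)
                for a in res.atoms
            ]
            residues.append(Residue(res.chain_id, res.number, res.icode, res.res_type, atoms))
        models.append(Model(index=k + 1, residues=residues))
    return ensemble_to_pdb_text(StructureEnsemble(pdb_id=pdb_id, models=models))


# ---------------------------------------------------------------------------
# Assignment fixtures
# ---------------------------------------------------------------------------

@dataclass
class AssignmentFixture:
    text: str
    dropped: set[tuple[str, int, str]] = field(default_factory=set)   # (entity, residue, atom)


def _star_text(rows: list[tuple[str, int, str, str, float]]) -> str:
    lines = [
        "data_synthetic_assignments",
        "",
        "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
        "   loop_",
        "      _Atom_chem_shift.ID",
        "      _Atom_chem_shift.Entity_ID",
        "      _Atom_chem_shift.Seq_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Val",
        "      _Atom_chem_shift.Ambiguity_code",
        "",
    ]
    for i, (entity, residue, res_type, atom, shift) in enumerate(rows, 1):
        lines.append(f"      {i} {entity} {residue} {res_type} {atom} {shift:.3f} 1")
    lines += ["   stop_", "save_", ""]
    return "\n".join(lines)


def _tsv_text(rows: list[tuple[str, int, str, str, float]]) -> str:
    lines = ["entity\tresidue\tres_type\tatom\tshift"]
    lines += [f"{e}\t{r}\t{t}\t{a}\t{s:.3f}" for e, r, t, a, s in rows]
    return "\n".join(lines) + "\n"


def _synthetic_shift(res_type: str, atom: str) -> float:
    # deterministic placeholder value in a plausible ppm range (crc32, not
    # hash(): str hashing is salted per interpreter run)
    return 10.0 + (zlib.crc32(f"{res_type}:{atom}".encode()) % 1000) / 10.0


def make_assignment_fixture(residues: list[tuple[str, int, str]],
                            drop: set[tuple[str, int, str]] | None = None,
                            fmt: str = "star",
                            expected: dict[str, set[str]] | None = None) -> AssignmentFixture:
    """Complete expected side-chain assignments minus exactly *drop*.

    *residues* is a list of (entity, residue number, res_type); *drop* a set
    of (entity, residue number, atom name).  ``fmt`` selects NMR-STAR or the
    simplified TSV dialect.
    """
    expected = expected if expected is not None else load_expected_nuclei()
    drop = set(drop or ())
    rows = []
    for entity, number, res_type in residues:
        for atom in sorted(expected[res_type]):
            if (entity, number, atom) in drop:
                continue
            rows.append((entity, number, res_type, atom,
                         round(_synthetic_shift(res_type, atom), 3)))
    text = _star_text(rows) if fmt == "star" else _tsv_text(rows)
    return AssignmentFixture(text=text, dropped=drop)


def make_random_drop_fixture(residues: list[tuple[str, int, str]],
                             fraction: float, seed: int, fmt: str = "star",
                             expected: dict[str, set[str]] | None = None) -> AssignmentFixture:
    """Drop a seeded random *fraction* of the expected nuclei; log the drop set."""
    expected = expected if expected is not None else load_expected_nuclei()
    candidates = [(entity, number, atom)
                  for entity, number, res_type in residues
                  for atom in sorted(expected[res_type])]
    rng = np.random.default_rng(seed)
    n_drop = int(round(fraction * len(candidates)))
    chosen = rng.choice(len(candidates), size=n_drop, replace=False)
    drop = {candidates[i] for i in chosen}
    return make_assignment_fixture(residues, drop, fmt=fmt, expected=expected)
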