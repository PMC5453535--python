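"""Geometric detection of salt bridges and side-chain hydrogen bonds.

Criteria
--------
* Salt bridge: two oppositely charged titratable side-chain groups
  (Asp/Glu carboxylate vs Lys/Arg/His amine, guanidinium or imidazolium)
  within 4.0 A (inclusive).  Two modes: ``group_center`` measures the
  distance between the geometric centers of the two charged groups;
  ``atom_pair`` emits one bridge per oxygen-nitrogen atom pair under the
  cutoff, which is how per-atom bridge tables are reported.
* Hydrogen bond: donor D with covalently bound hydrogen H and acceptor A,
  accepted iff d(D,A) <= 3.0 A and the angle at D between the D->A and D->H
  directions (the ADH angle) is <= 30 deg, both inclusive.  The H-A distance
  is recorded for reporting but is not a criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chemistry import (
    CHARGED_GROUPS,
    CONDITIONAL_ACCEPTORS,
    DH_COVALENT_CUTOFF,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
)
from .structure_io import Atom, Model, ProfilerWarning, Residue, StructureEnsemble

INTRA = "intramolecular"
INTER = "intermolecular"


@dataclass
class DetectionConfig:
    """Cutoffs and modes for interaction detection (all comparisons inclusive)."""

    sb_cutoff: float = 4.0          # A, charged-group distance cutoff
    hb_da_cutoff: float = 3.0       # A, donor-acceptor distance cutoff
    hb_angle_cutoff: float = 30.0   # deg, ADH angle cutoff at the donor
    sb_mode: str = "atom_pair"      # or "group_center"
    hb_acceptor_scope: str = "sidechain_plus_backbone_O"  # or "sidechain_only"
    ddof: int = 0                   # std convention for ensemble statistics

    def __post_init__(self):
        if min(self.sb_cutoff, self.hb_da_cutoff, self.hb_angle_cutoff) <= 0:
            raise ValueError("all cutoffs must be positive")
        if self.sb_mode not in ("atom_pair", "group_center"):
            raise ValueError(f"unknown sb_mode {self.sb_mode!r}")
        if self.hb_acceptor_scope not in ("sidechain_only", "sidechain_plus_backbone_O"):
            raise ValueError(f"unknown hb_acceptor_scope {self.hb_acceptor_scope!r}")


@dataclass(frozen=True)
class ChargedGroup:
    residue: Residue
    polarity: str                       # "positive" | "negative"
    member_atoms: tuple[str, ...]       # names of the atoms actually present
    center: np.ndarray                  # unweighted mean of member coordinates

    @property
    def atoms(self) -> list[Atom]:
        return [a for name in self.member_atoms if (a := self.residue.get_atom(name))]


@dataclass(frozen=True)
class SaltBridge:
    model_index: int
    group_a: ChargedGroup               # negative partner
    group_b: ChargedGroup               # positive partner
    distance: float
    mode: str                           # "group_center" | "atom_pair"
    atom_a: str | None = None           # negative-group oxygen (atom_pair mode)
    atom_b: str | None = None           # positive-group nitrogen (atom_pair mode)

    @property
    def scope(self) -> str:
        return classify_contact_scope(self)

    @property
    def residues(self) -> tuple[Residue, Residue]:
        return (self.group_a.residue, self.group_b.residue)


@dataclass(frozen=True)
class HydrogenBond:
    model_index: int
    donor_residue: Residue
    donor_atom: str
    hydrogen_atom: str
    acceptor_residue: Residue
    acceptor_atom: str
    d_da: float
    d_ha: float
    angle_adh: float

    @property
    def scope(self) -> str:
        return classify_contact_scope(self)

    @property
    def residues(self) -> tuple[Residue, Residue]:
        return (self.donor_residue, self.acceptor_residue)


def classify_contact_scope(interaction) -> str:
    """``intermolecular`` iff the two partner residues sit on different chains."""
    res_a, res_b = interaction.residues
    return INTER if res_a.chain_id != res_b.chain_id else INTRA


# ---------------------------------------------------------------------------
# Charged groups and salt bridges
# ---------------------------------------------------------------------------

def charged_groups(model: Model) -> list[ChargedGroup]:
    """Charged side-chain groups of all titratable residues in *model*.

    The group center is the unweighted mean of the member atoms present; a
    titratable residue whose member atoms are all missing is skipped with a
    warning.
    """
    groups = []
    for res in model.residues:
        spec = CHARGED_GROUPS.get(res.res_type)
        if spec is None:
            continue
        polarity, member_names = spec
        present = [(n, res.get_atom(n)) for n in member_names]
        present = [(n, a) for n, a in present if a is not None]
        if not present:
            warnings.warn(
                f"model {model.index}: {res.label} has no charged-group atoms; skipped",
                ProfilerWarning, stacklevel=2)
            continue
        center = np.mean([a.coord for _, a in present], axis=0)
        groups.append(ChargedGroup(res, polarity, tuple(n for n, _ in present), center))
    return groups


def detect_salt_bridges(model: Model, config: DetectionConfig | None = None) -> list[SaltBridge]:
    """All salt bridges in one model under *config* (inclusive cutoff).

    Each bridge is emitted once, with the negative group first.  Pairs within
    a single residue are never emitted (cannot occur for standard residues).
    """
    config = config or DetectionConfig()
    groups = charged_groups(model)
    negatives = [g for g in groups if g.polarity == "negative"]
    positives = [g for g in groups if g.polarity == "positive"]
    bridges: list[SaltBridge] = []
    for neg in negatives:
        for pos in positives:
            if neg.residue.key == pos.residue.key:
                continue
            if config.sb_mode == "group_center":
                dist = float(np.linalg.norm(neg.center - pos.center))
                if dist <= config.sb_cutoff:
                    bridges.append(SaltBridge(model.index, neg, pos, dist, "group_center"))
            else:
                for o_atom in neg.atoms:
                    for n_atom in pos.atoms:
                        dist = o_atom.distance_to(n_atom)
                        if dist <= config.sb_cutoff:
                            bridges.append(SaltBridge(
                                model.index, neg, pos, dist, "atom_pair",
                                atom_a=o_atom.name, atom_b=n_atom.name))
    return bridges


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _bound_hydrogens(res: Residue, heavy: Atom) -> list[Atom]:
    """Hydrogens of *res* covalently bound to *heavy* (< 1.3 A)."""
    return [a for a in res.atoms
            if a.element == "H" and heavy.distance_to(a) < DH_COVALENT_CUTOFF]


def donor_acceptor_inventory(
    model: Model, config: DetectionConfig | None = None,
) -> tuple[list[tuple[Residue, Atom, Atom]], list[tuple[Residue, Atom]]]:
    """Side-chain (donor, hydrogen) pairs and acceptor atoms of one model.

    Donors without a resolvable bound hydrogen (e.g. every donor of a
    hydrogen-free X-ray model) are skipped; one summary warning is emitted
    per model.  His ring nitrogens are acceptors only when unprotonated.
    Backbone carbonyl oxygens are included as acceptors iff the config scope
    is ``sidechain_plus_backbone_O``.
    """
    config = config or DetectionConfig()
    donors: list[tuple[Residue, Atom, Atom]] = []
    acceptors: list[tuple[Residue, Atom]] = []
    skipped_donors = 0
    for res in model.residues:
        for name in SIDECHAIN_DONORS.get(res.res_type, ()):
            heavy = res.get_atom(name)
            if heavy is None:
                continue
            hydrogens = _bound_hydrogens(res, heavy)
            if not hydrogens:
                skipped_donors += 1
                continue
            donors.extend((res, heavy, h) for h in hydrogens)
        for name in SIDECHAIN_ACCEPTORS.get(res.res_type, ()):
            atom = res.get_atom(name)
            if atom is None:
                continue
            if (res.res_type, name) in CONDITIONAL_ACCEPTORS and _bound_hydrogens(res, atom):
                continue  # protonated His nitrogen cannot accept
            acceptors.append((res, atom))
        if config.hb_acceptor_scope == "sidechain_plus_backbone_O":
            bb_o = res.get_atom("O")
            if bb_o is not None:
                acceptors.append((res, bb_o))
    if skipped_donors:
        warnings.warn(
            f"model {model.index}: {skipped_donors} donor atom(s) without bound "
            "hydrogens skipped (structure may lack explicit hydrogens)",
            ProfilerWarning, stacklevel=2)
    return donors, acceptors


def hbond_geometry(donor: Atom, hydrogen: Atom, acceptor: Atom) -> tuple[float, float, float]:
    """(d_DA, d_HA, ADH angle in degrees) for one donor/hydrogen/acceptor triple."""
    d_da = donor.distance_to(acceptor)
    d_ha = hydrogen.distance_to(acceptor)
    v_a = acceptor.coord - donor.coord
    v_h = hydrogen.coord - donor.coord
    cosang = np.dot(v_a, v_h) / (np.linalg.norm(v_a) * np.linalg.norm(v_h))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return d_da, d_ha, angle


def hbond_criteria_satisfied(d_da: float, angle_adh: float,
                             config: DetectionConfig | None = None) -> bool:
    """Apply the two geometric acceptance criteria (both inclusive)."""
    config = config or DetectionConfig()
    return d_da <= config.hb_da_cutoff and angle_adh <= config.hb_angle_cutoff


def detect_hydrogen_bonds(model: Model, config: DetectionConfig | None = None) -> list[HydrogenBond]:
    """All side-chain hydrogen bonds in one model under *config*."""
    config = config or DetectionConfig()
    donors, acceptors = donor_acceptor_inventory(model, config)
    bonds = []
    for d_res, d_atom, h_atom in donors:
        for a_res, a_atom in acceptors:
            if d_res.key == a_res.key:
                continue
            d_da, d_ha, angle = hbond_geometry(d_atom, h_atom, a_atom)
            if hbond_criteria_satisfied(d_da, angle, config):
                bonds.append(HydrogenBond(
                    model.index, d_res, d_atom.name, h_atom.name,
                    a_res, a_atom.name, d_da, d_ha, angle))
    return bonds


# ---------------------------------------------------------------------------
# Atom-pair distance series across an ensemble
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomSelector:
    """(chain, residue number, atom name[, icode]) address of one atom."""

    chain: str
    residue_number: int
    atom_name: str
    icode: str = ""

    def resolve(self, model: Model) -> Atom | None:
        res = model.get_residue(self.chain, self.residue_number, self.icode)
        if res is None:
            return None
        matches = res.get_atoms(self.atom_name)
        if len(matches) > 1:
            # multiple altlocs resolve deterministically; anything else is ambiguous
            altlocs = {a.altloc for a in matches}
            if len(altlocs) != len(matches) or "" in altlocs:
                raise ValueError(f"selector {self} matches {len(matches)} atoms")
            return res.get_atom(self.atom_name)
        return matches[0] if matches else None


@dataclass
class DistanceSeries:
    selector_a: AtomSelector
    selector_b: AtomSelector
    model_indices: list[int]
    distances: list[float]
    mean: float
    std: float


def atom_pair_distance_series(ensemble: StructureEnsemble, a: AtomSelector,
                              b: AtomSelector, ddof: int = 0) -> DistanceSeries:
    """Per-model distance between two addressed atoms, with mean +/- std.

    Models where either atom is missing are skipped with a warning.
    """
    indices, dists = [], []
    for model in ensemble:
        atom_a, atom_b = a.resolve(model), b.resolve(model)
        if atom_a is None or atom_b is None:
            warnings.warn(
                f"model {model.index}: selector(s) unresolved; model skipped",
                ProfilerWarning, stacklevel=2)
            continue
        indices.append(model.index)
        dists.append(atom_a.distance_to(atom_b))
    arr = np.asarray(dists, dtype=float)
    mean = float(arr.mean()) if len(arr) else float("nan")
    std = float(arr.std(ddof=ddof)) if len(arr) > ddof else float("nan")
    return DistanceSeries(a, b, indices, dists, mean, std)
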