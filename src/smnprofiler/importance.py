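"""Residue importance classification and mutation impact annotation.

A residue is *potentially important* when its side chain takes part in at
least one detected salt bridge or hydrogen bond in at least one ensemble
model, or when it is buried (ensemble-mean SASA below 30% of the intrinsic
reference).  Important residues are cross-referenced against a packaged
catalogue of disease-linked SMN point mutations, and each missense mutation is
annotated with a qualitative electrostatic impact category: removing a charged
side chain deletes its salt-bridge attractions; reversing the charge sign (or
replacing a donor group by an acceptor) turns hydrogen-bond attraction into
repulsion; replacing a buried hydrophobic side chain by glycine removes
packing without any electrostatic sign change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .chemistry import FORMAL_CHARGE, HYDROPHOBIC, ONE_TO_THREE, POLAR_DONORS, THREE_TO_ONE, is_backbone
from .ensemble_stats import InteractionSummary
from .sasa import DEFAULT_BURIAL_THRESHOLD, SasaProfile
from .structure_io import ProfilerWarning


@dataclass(frozen=True)
class MutationRecord:
    """One point mutation in SMN author numbering, e.g. D44V (mut ``X`` = stop)."""

    position: int
    wt: str
    mut: str
    label: str
    source: str = "packaged"

    def __post_init__(self):
        if self.wt == self.mut:
            raise ValueError(f"{self.label}: wild-type and mutant are identical")
        if self.position < 1:
            raise ValueError(f"{self.label}: position must be >= 1")

    @classmethod
    def from_label(cls, label: str, source: str = "user") -> "MutationRecord":
        """Parse a compact label such as ``D44V`` or ``W102X``."""
        wt, mut = label[0], label[-1]
        return cls(position=int(label[1:-1]), wt=wt, mut=mut, label=label, source=source)


def load_mutation_catalogue(path: str | Path | None = None) -> list[MutationRecord]:
    """The packaged SMA-linked SMN mutation catalogue, or a user TSV.

    TSV columns: position, wt, mut, label (hash comments ignored).
    """
    if path is None:
        text = resources.files("smnprofiler.data").joinpath("sma_mutations.tsv").read_text()
        source = "packaged"
    else:
        text = Path(path).read_text()
        source = "user"
    records = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos, wt, mut, label = line.split("\t")
        records.append(MutationRecord(int(pos), wt, mut, label, source))
    return records


@dataclass
class ImportanceRecord:
    """Three-part importance verdict for one residue."""

    chain_id: str
    number: int
    icode: str
    res_type: str
    in_salt_bridge: bool
    in_hydrogen_bond: bool
    buried: bool
    sasa_ratio: float
    matched_mutations: list[MutationRecord] = field(default_factory=list)

    @property
    def important(self) -> bool:
        return self.in_salt_bridge or self.in_hydrogen_bond or self.buried

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.number}{self.icode}{self.res_type.capitalize()}"


def _sidechain_participants(summary: InteractionSummary) -> set[str]:
    """Labels of residues whose *side chain* carries the interaction.

    Salt-bridge partners always participate through side-chain atoms.  For
    hydrogen bonds the donor is always side-chain (the inventory is side-chain
    only), but a backbone carbonyl acceptor does not flag the acceptor
    residue's side chain.
    """
    if summary.kind == "salt_bridge":
        return {summary.residue_a, summary.residue_b}
    out = {summary.residue_a}
    if summary.atom_b is not None and not is_backbone(summary.atom_b):
        out.add(summary.residue_b)
    return out


def classify_important_residues(
    profiles: list[SasaProfile],
    summaries: list[InteractionSummary],
    burial_threshold: float = DEFAULT_BURIAL_THRESHOLD,
) -> list[ImportanceRecord]:
    """One importance record per profiled residue.

    The salt-bridge / hydrogen-bond flags require side-chain participation in
    at least one detected interaction in at least one model; burial uses the
    ensemble-mean SASA ratio (strictly below *burial_threshold*).
    """
    sb_residues: set[str] = set()
    hb_residues: set[str] = set()
    for summary in summaries:
        target = sb_residues if summary.kind == "salt_bridge" else hb_residues
        target |= _sidechain_participants(summary)

    records = []
    for prof in profiles:
        records.append(ImportanceRecord(
            chain_id=prof.chain_id, number=prof.number, icode=prof.icode,
            res_type=prof.res_type,
            in_salt_bridge=prof.label in sb_residues,
            in_hydrogen_bond=prof.label in hb_residues,
            buried=prof.sasa_ratio < burial_threshold,
            sasa_ratio=prof.sasa_ratio,
        ))
    return records


def cross_reference_mutations(records: list[ImportanceRecord],
                              catalogue: list[MutationRecord],
                              smn_chains: set[str] | None = None) -> list[ImportanceRecord]:
    """Attach catalogue mutations to matching records; return the matched subset.

    Matching is by residue number, restricted to the chains named in
    *smn_chains* (all chains when ``None``); chain roles are data supplied by
    the caller, never assumed.  A catalogue row whose wild-type letter
    disagrees with the record's residue type, or whose position matches no
    record at all, is skipped with a warning.
    """
    by_position: dict[int, list[ImportanceRecord]] = {}
    for rec in records:
        if smn_chains is not None and rec.chain_id not in smn_chains:
            continue
        by_position.setdefault(rec.number, []).append(rec)

    matched: list[ImportanceRecord] = []
    for mut in catalogue:
        hits = by_position.get(mut.position, [])
        good = [r for r in hits if THREE_TO_ONE.get(r.res_type) == mut.wt]
        if hits and not good:
            warnings.warn(
                f"{mut.label}: residue {mut.position} present but is "
                f"{hits[0].res_type}, not {ONE_TO_THREE.get(mut.wt, mut.wt)}; skipped",
                ProfilerWarning, stacklevel=2)
            continue
        if not good:
            warnings.warn(f"{mut.label}: position {mut.position} not in the "
                          "analysed structure(s); skipped", ProfilerWarning, stacklevel=2)
            continue
        for rec in good:
            rec.matched_mutations.append(mut)
            if rec not in matched:
                matched.append(rec)
    return matched


# ---------------------------------------------------------------------------
# Mutation impact typology
# ---------------------------------------------------------------------------

CATEGORIES = (
    "charge_removal",
    "charge_reversal_neg_to_pos",
    "charge_reversal_donor_to_neg",
    "hydrophobic_removal",
    "truncation",
    "other",
)

#: Residues whose substitution in place of a hydrophobic side chain amounts to
#: removing the hydrophobic group (glycine has no side chain; Ser/Ala leave a
#: minimal one).
_HYDROPHOBIC_REMOVERS = {"G", "S", "A"}


@dataclass(frozen=True)
class ImpactAnnotation:
    mutation: MutationRecord
    category: str
    affected_interactions: tuple[InteractionSummary, ...]
    predicted_sign_change: str   # "attraction_lost" | "attraction_to_repulsion" | "none"


def annotate_mutation_impact(mutation: MutationRecord,
                             interactions: list[InteractionSummary] | None = None,
                             ) -> ImpactAnnotation:
    """Qualitative impact category for one mutation.

    Pure, table-driven sign logic on (wild type, mutant, interaction roles):

    * stop codon -> ``truncation``;
    * negative -> positive (e.g. E->K): ``charge_reversal_neg_to_pos``; the
      wild type's hydrogen-bond/salt-bridge attractions become repulsions;
    * polar donor -> negative (e.g. Q->E): ``charge_reversal_donor_to_neg``,
      likewise attraction to repulsion;
    * charged -> uncharged hydrophobic (e.g. D->V): ``charge_removal``; the
      attractions are lost;
    * hydrophobic -> Gly/Ser/Ala (e.g. A->G, W->S): ``hydrophobic_removal``,
      no electrostatic sign change;
    * anything else -> ``other``.
    """
    interactions = interactions or []
    wt, mut = mutation.wt, mutation.mut
    if wt not in THREE_TO_ONE.values():
        raise ValueError(f"{mutation.label}: unknown wild-type code {wt!r}")
    if mut != "X" and mut not in THREE_TO_ONE.values():
        raise ValueError(f"{mutation.label}: unknown mutant code {mut!r}")

    affected = tuple(interactions)
    wt_charge = FORMAL_CHARGE.get(wt, 0)
    mut_charge = 0 if mut == "X" else FORMAL_CHARGE.get(mut, 0)

    if mut == "X":
        category, sign = "truncation", "none"
    elif wt_charge < 0 and mut_charge > 0:
        category = "charge_reversal_neg_to_pos"
        sign = "attraction_to_repulsion" if affected else "none"
    elif wt in POLAR_DONORS and mut_charge < 0:
        category = "charge_reversal_donor_to_neg"
        sign = "attraction_to_repulsion" if affected else "none"
    elif wt_charge != 0 and mut_charge == 0 and (mut in HYDROPHOBIC or mut == "G"):
        category = "charge_removal"
        sign = "attraction_lost" if affected else "none"
    elif wt in HYDROPHOBIC and mut in _HYDROPHOBIC_REMOVERS:
        category, sign = "hydrophobic_removal", "none"
    else:
        category, sign = "other", "none"

    return ImpactAnnotation(mutation, category, affected, sign)
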