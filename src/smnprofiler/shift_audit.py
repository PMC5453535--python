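"""Chemical-shift assignment completeness audit.

NMR structure quality depends on which nuclei actually carry chemical-shift
assignments: a side chain whose nuclei are unassigned is geometrically
under-restrained in the deposited ensemble, so an apparent contact (or its
absence) involving that side chain carries little evidential weight.  This
module reads an assigned-chemical-shift table (NMR-STAR v3 loop, parsed with
gemmi's STAR reader, or a simplified TSV) and reports, for selected residues,
every expected side-chain nucleus that has no assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi

from .structure_io import ProfilerWarning


class AssignmentFormatError(ValueError):
    """File holds no usable assigned-chemical-shift data."""


@dataclass(frozen=True)
class Assignment:
    entity: str          # entity / chain identifier ("" when absent)
    residue: int
    res_type: str
    atom: str
    shift: float
    ambiguity: str = ""


@dataclass
class AssignmentTable:
    """Residue-indexed set of assigned nuclei."""

    entries: dict[tuple[str, int, str], Assignment] = field(default_factory=dict)

    @staticmethod
    def key(entity: str, residue: int, atom: str) -> tuple[str, int, str]:
        return (entity, residue, atom)

    def add(self, a: Assignment) -> None:
        self.entries[self.key(a.entity, a.residue, a.atom)] = a

    def assigned_atoms(self, entity: str, residue: int) -> set[str]:
        return {k[2] for k in self.entries if k[0] == entity and k[1] == residue}

    def res_type_of(self, entity: str, residue: int) -> str | None:
        for k, a in self.entries.items():
            if k[0] == entity and k[1] == residue:
                return a.res_type
        return None

    def __len__(self) -> int:
        return len(self.entries)


def load_expected_nuclei(path: str | Path | None = None) -> dict[str, set[str]]:
    """Expected side-chain nuclei per residue type (editable packaged table)."""
    if path is None:
        text = resources.files("smnprofiler.data").joinpath(
            "expected_sidechain_nuclei.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, set[str]] = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        res_type = parts[0]
        nuclei = parts[1].split(",") if len(parts) > 1 and parts[1] else []
        table[res_type] = set(nuclei)
    return table


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_STAR_TAGS = ["Seq_ID", "Comp_ID", "Atom_ID", "Val", "Ambiguity_code", "Entity_ID"]


def _iter_star_blocks(doc: gemmi.cif.Document):
    for block in doc:
        yield block
        for item in block:
            frame = getattr(item, "frame", None)
            if frame is not None:
                yield frame


def _read_star(path: Path) -> AssignmentTable:
    doc = gemmi.cif.read_string(path.read_text())
    table = AssignmentTable()
    for block in _iter_star_blocks(doc):
        loop = block.find("_Atom_chem_shift.", _STAR_TAGS[:4])
        if len(loop) == 0:
            continue
        has_amb = block.find_values("_Atom_chem_shift.Ambiguity_code")
        has_ent = block.find_values("_Atom_chem_shift.Entity_ID")
        full = block.find("_Atom_chem_shift.",
                          _STAR_TAGS[:4]
                          + (["Ambiguity_code"] if has_amb else [])
                          + (["Entity_ID"] if has_ent else []))
        for row in full:
            try:
                residue = int(row[0])
                shift = float(row[3])
            except ValueError:
                warnings.warn(f"{path.name}: malformed shift row {list(row)}; skipped",
                              ProfilerWarning, stacklevel=3)
                continue
            idx = 4
            ambiguity = row[idx] if has_amb else ""
            if has_amb:
                idx += 1
            entity = row[idx] if has_ent else ""
            table.add(Assignment(entity, residue, row[1].upper(), row[2].upper(),
                                 shift, ambiguity))
    if len(table) == 0:
        raise AssignmentFormatError(f"{path}: no assigned-chemical-shift loop found")
    return table


def _read_tsv(path: Path) -> AssignmentTable:
    table = AssignmentTable()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("entity\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            warnings.warn(f"{path.name}: malformed TSV row {line!r}; skipped",
                          ProfilerWarning, stacklevel=3)
            continue
        try:
            table.add(Assignment(parts[0], int(parts[1]), parts[2].upper(),
                                 parts[3].upper(), float(parts[4])))
        except ValueError:
            warnings.warn(f"{path.name}: malformed TSV row {line!r}; skipped",
                          ProfilerWarning, stacklevel=3)
    if len(table) == 0:
        raise AssignmentFormatError(f"{path}: no assignment rows found")
    return table


def read_assignments(path: str | Path) -> AssignmentTable:
    """Parse an NMR-STAR v3 file or the simplified TSV dialect.

    The TSV dialect has columns ``entity, residue, res_type, atom, shift``.
    Malformed rows are skipped with warnings; a file yielding zero assignments
    raises :class:`AssignmentFormatError`.
    """
    path = Path(path)
    text_head = path.read_text()[:4096].lstrip()
    if path.suffix in (".str", ".star", ".nef") or text_head.startswith("data_"):
        return _read_star(path)
    return _read_tsv(path)


# ---------------------------------------------------------------------------
# Audit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueSelector:
    entity: str
    residue: int
    res_type: str


def find_missing_assignments(table: AssignmentTable,
                             residues: list[ResidueSelector],
                             expected: dict[str, set[str]] | None = None,
                             entity_offsets: dict[str, int] | None = None,
                             ) -> list[tuple[ResidueSelector, str]]:
    """Expected side-chain nuclei with no assignment, per selected residue.

    *entity_offsets* maps entity id -> (table numbering - selector numbering)
    for depositions whose author numbering differs from the structure's.
    A selector whose residue type disagrees with the table's is still audited,
    with a warning.  Fully assigned residues contribute nothing.
    """
    expected = expected if expected is not None else load_expected_nuclei()
    entity_offsets = entity_offsets or {}
    missing: list[tuple[ResidueSelector, str]] = []
    for sel in residues:
        if sel.res_type not in expected:
            raise KeyError(f"no expected-nuclei entry for {sel.res_type}")
        number = sel.residue + entity_offsets.get(sel.entity, 0)
        table_type = table.res_type_of(sel.entity, number)
        if table_type is not None and table_type != sel.res_type:
            warnings.warn(
                f"entity {sel.entity} residue {number}: table says {table_type}, "
                f"selector says {sel.res_type}", ProfilerWarning, stacklevel=2)
        assigned = table.assigned_atoms(sel.entity, number)
        for nucleus in sorted(expected[sel.res_type] - assigned):
            missing.append((sel, nucleus))
    return missing
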