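"""Reading, splitting and writing multi-model PDB structures.

An NMR entry deposits its ensemble as one PDB file with MODEL/ENDMDL blocks;
an X-ray entry has a single implicit model.  This module parses either into a
:class:`StructureEnsemble` (backed by gemmi's PDB parser), splits ensembles
into per-model PDB files, and resolves atom selections with deterministic
altloc handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .chemistry import STANDARD_AMINO_ACIDS


class ProfilerWarning(UserWarning):
    """Non-fatal data issue (skipped residue, missing atoms, topology drift)."""


class PdbFormatError(ValueError):
    """Input file is not a usable PDB structure (e.g. no ATOM records)."""


@dataclass(frozen=True)
class Atom:
    """One atom of one residue: PDB name, element symbol, position (A)."""

    name: str
    element: str
    coord: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.coord - other.coord))


@dataclass
class Residue:
    """A residue identified by (chain_id, number, icode), e.g. B44Asp."""

    chain_id: str
    number: int
    icode: str
    res_type: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.res_type in STANDARD_AMINO_ACIDS

    @property
    def label(self) -> str:
        """Compact residue label in chain-number-type form, e.g. ``B36Asp``."""
        return f"{self.chain_id}{self.number}{self.icode}{self.res_type.capitalize()}"

    def get_atoms(self, name: str) -> list[Atom]:
        return [a for a in self.atoms if a.name == name]

    def get_atom(self, name: str) -> Atom | None:
        """Highest-occupancy altloc for *name* (first in file order on ties)."""
        matches = self.get_atoms(name)
        if not matches:
            return None
        return max(matches, key=lambda a: a.occupancy)  # max() keeps first on ties


@dataclass
class Model:
    """One structure model (one MODEL block, or the whole file for X-ray)."""

    index: int
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        self._by_key = {r.key: r for r in self.residues}

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for res in self.residues:
            out.setdefault(res.chain_id, []).append(res)
        return out

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        return self._by_key.get((chain_id, number, icode))

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass
class StructureEnsemble:
    """Ordered models of one PDB entry plus any topology warnings."""

    pdb_id: str
    models: list[Model]
    topology_warnings: list[str] = field(default_factory=list)

    @property
    def num_models(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


def _convert_model(gmodel: gemmi.Model, index: int, include_het: bool,
                   include_nonstandard: bool) -> Model:
    residues: list[Residue] = []
    for chain in gmodel:
        for gres in chain:
            if gres.is_water():
                continue
            if gres.het_flag == "H" and not include_het:
                continue
            if gres.name not in STANDARD_AMINO_ACIDS and not (include_het or include_nonstandard):
                continue
            icode = gres.seqid.icode.strip()
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float),
                    altloc="" if ga.altloc in ("\0", " ") else ga.altloc,
                    occupancy=float(ga.occ),
                )
                for ga in gres
            ]
            residues.append(Residue(chain.name, gres.seqid.num, icode, gres.name, atoms))
    return Model(index=index, residues=residues)


def read_multimodel_pdb(path: str | Path, include_het: bool = False,
                        include_nonstandard: bool = False) -> StructureEnsemble:
    """Parse a (possibly multi-model) PDB file into a :class:`StructureEnsemble`.

    One :class:`Model` is produced per MODEL/ENDMDL block; a file without
    MODEL records yields a single model.  Hydrogens are retained.  Waters are
    always dropped; other HETATM records and non-standard residues are dropped
    unless the corresponding flag is set.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    PdbFormatError
        If the file contains no ATOM records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    models = [
        _convert_model(gm, i + 1, include_het, include_nonstandard)
        for i, gm in enumerate(st)
    ]
    models = [m for m in models if m.atom_count > 0] or models
    if not models or all(m.atom_count == 0 for m in models):
        raise PdbFormatError(f"{path}: no ATOM records found")

    ensemble = StructureEnsemble(pdb_id=path.stem.lower(), models=models)
    _check_topology(ensemble)
    return ensemble


def _check_topology(ensemble: StructureEnsemble) -> None:
    """Record a warning if models do not share the same residue identifiers."""
    if ensemble.num_models < 2:
        return
    ref = [(r.key, r.res_type) for r in ensemble.models[0].residues]
    for model in ensemble.models[1:]:
        topo = [(r.key, r.res_type) for r in model.residues]
        if topo != ref:
            msg = (f"{ensemble.pdb_id}: model {model.index} residue topology "
                   f"differs from model {ensemble.models[0].index}")
            ensemble.topology_warnings.append(msg)
            warnings.warn(msg, ProfilerWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def format_atom_record(serial: int, atom: Atom, res: Residue) -> str:
    """One fixed-width PDB ATOM record (coordinates at 3 decimals)."""
    name = atom.name
    # Names shorter than 4 chars start in column 14 (standard PDB padding).
    if len(name) < 4:
        name = " " + name
    altloc = atom.altloc or " "
    icode = res.icode or " "
    x, y, z = atom.coord
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{res.res_type:>3s} "
        f"{res.chain_id}{res.number:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def model_to_pdb_lines(model: Model) -> list[str]:
    lines = []
    serial = 0
    for res in model.residues:
        for atom in res.atoms:
            serial += 1
            lines.append(format_atom_record(serial, atom, res))
    return lines


def write_model_pdb(model: Model, path: str | Path) -> Path:
    """Write one model as a single-model PDB file."""
    path = Path(path)
    path.write_text("\n".join(model_to_pdb_lines(model) + ["END", ""]))
    return path


def ensemble_to_pdb_text(ensemble: StructureEnsemble) -> str:
    """Serialize an ensemble with MODEL/ENDMDL framing (single model: none)."""
    if ensemble.num_models == 1:
        return "\n".join(model_to_pdb_lines(ensemble.models[0]) + ["END", ""])
    lines: list[str] = []
    for model in ensemble.models:
        lines.append(f"MODEL     {model.index:4d}")
        lines.extend(model_to_pdb_lines(model))
        lines.append("ENDMDL")
    lines += ["END", ""]
    return "\n".join(lines)


def split_ensemble(ensemble: StructureEnsemble, out_dir: str | Path) -> list[Path]:
    """Write each model to ``<pdb_id>_model<k>.pdb`` under *out_dir*.

    Atom order is preserved; coordinates round-trip at PDB precision
    (3 decimals).  Returns the written paths in model order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for model in ensemble.models:
        paths.append(write_model_pdb(model, out_dir / f"{ensemble.pdb_id}_model{model.index}.pdb"))
    return paths


def select_atoms(model: Model, chain: str, residue_number: int,
                 atom_names: set[str] | list[str] | tuple[str, ...],
                 icode: str = "") -> list[Atom]:
    """All atoms matching (chain, residue number, names), altloc-resolved.

    When alternate locations exist for a name, only the highest-occupancy one
    is returned (first in file order on ties).  An empty list is returned when
    nothing matches.
    """
    res = model.get_residue(chain, residue_number, icode)
    if res is None:
        return []
    out = []
    for name in atom_names:
        atom = res.get_atom(name)
        if atom is not None:
            out.append(atom)
    return out
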