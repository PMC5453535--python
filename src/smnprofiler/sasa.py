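"""Solvent accessible surface area (SASA) and burial classification.

SASA is computed with the Shrake-Rupley rolling-probe quadrature: each atom's
solvent-accessible sphere (van der Waals radius + probe radius) is sampled on
a deterministic golden-section spiral of points; a point is accessible when it
lies outside the expanded sphere of every neighbouring atom, and the atom's
SASA is the accessible fraction times the sphere area.  Radii follow the
NACCESS/Chothia set so that relative SASA can be taken against the NACCESS
standard (intrinsic) per-residue reference values packaged with the module.

A residue is classified "buried" when its ensemble-mean SASA falls below 30%
of the intrinsic value for its residue type (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import vdw_radius
from .structure_io import Model, Residue, StructureEnsemble

DEFAULT_PROBE_RADIUS = 1.4   # A, water probe
DEFAULT_N_POINTS = 960
DEFAULT_BURIAL_THRESHOLD = 0.30


class UnknownResidueError(KeyError):
    """Residue type missing from the intrinsic SASA reference table."""


def load_intrinsic_sasa(path: str | Path | None = None) -> dict[str, float]:
    """The standard per-residue reference SASA table (res_type -> A^2)."""
    if path is None:
        text = resources.files("smnprofiler.data").joinpath("intrinsic_sasa.tsv").read_text()
    else:
        text = Path(path).read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res_type, value = line.split("\t")
        table[res_type] = float(value)
    return table


def sphere_points(n: int) -> np.ndarray:
    """*n* near-uniform unit-sphere points on a golden-section spiral.

    Deterministic (no random state), so SASA values are reproducible bitwise.
    """
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))        # golden angle
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_sasa(model: Model, probe_radius: float = DEFAULT_PROBE_RADIUS,
              n_sphere_points: int = DEFAULT_N_POINTS,
              include_hydrogens: bool = False,
              radius_fn=vdw_radius) -> dict[tuple[tuple[str, int, str], str, str], float]:
    """Per-atom SASA (A^2) for one model.

    Returns a map ``(residue key, atom name, altloc) -> sasa``.  Hydrogens are
    excluded from both the surface and the occluding set by default, which
    keeps hydrogen-bearing NMR models comparable with hydrogen-free X-ray
    models.  *radius_fn(res_type, atom_name, element)* overrides the packaged
    NACCESS-style van der Waals radii.
    """
    entries = []   # (key, atom)
    for res in model.residues:
        for atom in res.atoms:
            if atom.element == "H" and not include_hydrogens:
                continue
            entries.append((res, atom))
    if not entries:
        return {}

    coords = np.array([a.coord for _, a in entries])
    radii = np.array([radius_fn(r.res_type, a.name, a.element) for r, a in entries])
    expanded = radii + probe_radius
    unit = sphere_points(n_sphere_points)

    tree = cKDTree(coords)
    r_max = expanded.max()
    out = {}
    for i, (res, atom) in enumerate(entries):
        r_i = expanded[i]
        pts = coords[i] + r_i * unit
        candidates = tree.query_ball_point(coords[i], r_i + r_max)
        neighbours = [j for j in candidates
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < r_i + expanded[j]]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        out[(res.key, atom.name, atom.altloc)] = float(
            accessible.mean() * 4.0 * np.pi * r_i ** 2)
    return out


def residue_sasa(model: Model, **kwargs) -> dict[tuple[str, int, str], float]:
    """Per-residue SASA for one model (sum of member-atom SASA)."""
    per_atom = atom_sasa(model, **kwargs)
    out: dict[tuple[str, int, str], float] = {}
    for (res_key, _name, _alt), value in per_atom.items():
        out[res_key] = out.get(res_key, 0.0) + value
    return out


@dataclass
class SasaProfile:
    """Ensemble-aggregated SASA of one residue, relative to its reference."""

    chain_id: str
    number: int
    icode: str
    res_type: str
    sasa_mean: float
    sasa_std: float
    sasa_intrinsic: float
    per_model: list[float]

    @property
    def sasa_ratio(self) -> float:
        return self.sasa_mean / self.sasa_intrinsic

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.number}{self.icode}{self.res_type.capitalize()}"


def residue_sasa_profile(ensemble: StructureEnsemble,
                         table: dict[str, float] | None = None,
                         probe_radius: float = DEFAULT_PROBE_RADIUS,
                         n_sphere_points: int = DEFAULT_N_POINTS,
                         include_hydrogens: bool = False,
                         ddof: int = 0) -> list[SasaProfile]:
    """Per-residue SASA mean/std across models plus the relative (ratio) SASA.

    Raises :class:`UnknownResidueError` when a residue type has no entry in
    the intrinsic reference table.
    """
    table = table if table is not None else load_intrinsic_sasa()
    residues: dict[tuple[str, int, str], Residue] = {}
    values: dict[tuple[str, int, str], list[float]] = {}
    for model in ensemble:
        per_res = residue_sasa(model, probe_radius=probe_radius,
                               n_sphere_points=n_sphere_points,
                               include_hydrogens=include_hydrogens)
        for res in model.residues:
            residues.setdefault(res.key, res)
            values.setdefault(res.key, []).append(per_res.get(res.key, 0.0))

    profiles = []
    for key, res in residues.items():
        if res.res_type not in table:
            raise UnknownResidueError(
                f"{res.label}: no intrinsic SASA reference for {res.res_type}")
        arr = np.asarray(values[key])
        profiles.append(SasaProfile(
            chain_id=res.chain_id, number=res.number, icode=res.icode,
            res_type=res.res_type,
            sasa_mean=float(arr.mean()),
            sasa_std=float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0,
            sasa_intrinsic=table[res.res_type],
            per_model=[float(v) for v in arr],
        ))
    return profiles


def classify_burial(profile: SasaProfile,
                    threshold: float = DEFAULT_BURIAL_THRESHOLD) -> str:
    """``"buried"`` iff the relative SASA is strictly below *threshold*."""
    return "buried" if profile.sasa_ratio < threshold else "exposed"
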