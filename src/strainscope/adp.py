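"""Anisotropic displacement parameter (ADP) analysis.

Anisotropy is defined as the ratio of smallest to largest eigenvalue of the
displacement tensor U (1 = isotropic, -> 0 = extremely elongated). Group
statistics use the arithmetic mean and the population standard deviation, and
by default exclude hydrogen/deuterium atoms and non-positive-definite
tensors (both exclusions are reported via counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .structure_io import AtomRecord, StructureModel

__all__ = [
    "AnisoTensor",
    "GroupStats",
    "atom_anisotropy",
    "group_anisotropy",
    "group_b_factor",
    "anisotropy_table",
    "export_axes",
]

_EIGHT_PI_SQ_OVER_3 = 8.0 * math.pi**2 / 3.0

GROUPS = ("polymer", "ligand", "solvent")


@dataclass(frozen=True)
class AnisoTensor:
    """Eigen-decomposition of a symmetric displacement tensor."""

    u: np.ndarray  # 3x3 symmetric, A^2
    eigenvalues: np.ndarray  # descending, A^2
    eigenvectors: np.ndarray  # columns match eigenvalues, orthonormal
    anisotropy: float  # lambda_min / lambda_max
    b_eq: float  # (8 pi^2 / 3) * trace(U)
    valid: bool  # positive definite

    @property
    def major_axis(self) -> np.ndarray:
        """Unit eigenvector of the largest eigenvalue."""
        return self.eigenvectors[:, 0]


def atom_anisotropy(atom: AtomRecord) -> AnisoTensor:
    """Eigen-analysis of an atom's ADP tensor.

    Non-positive-definite tensors are flagged ``valid=False`` (their
    anisotropy is still reported as the raw eigenvalue ratio but they are
    excluded from group statistics).
    """
    if atom.uij is None:
        raise ValueError(f"atom {atom.atom_name} has no ADP tensor")
    u = np.asarray(atom.uij, dtype=float)
    if not np.allclose(u, u.T, atol=1e-8):
        raise ValueError("ADP tensor is not symmetric")
    eigenvalues, eigenvectors = np.linalg.eigh(u)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    valid = bool(eigenvalues[-1] > 0.0)
    anisotropy = float(eigenvalues[-1] / eigenvalues[0]) if eigenvalues[0] != 0.0 else float("nan")
    return AnisoTensor(
        u=u,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        anisotropy=anisotropy,
        b_eq=_EIGHT_PI_SQ_OVER_3 * float(np.trace(u)),
        valid=valid,
    )


@dataclass(frozen=True)
class GroupStats:
    """Mean +/- sd of a per-atom quantity over one atom class."""

    group: str
    mean: float
    sd: float
    n: int
    n_invalid: int = 0
    n_hydrogen_excluded: int = 0


def _group_atoms(model: StructureModel, group: str, exclude_hydrogen: bool):
    n_h = 0
    atoms = []
    for atom in model.atoms(group):
        if atom.is_hydrogen and exclude_hydrogen:
            n_h += 1
            continue
        atoms.append(atom)
    return atoms, n_h


def group_anisotropy(
    model: StructureModel, group: str = "polymer", exclude_hydrogen: bool = True
) -> Optional[GroupStats]:
    """Mean and population sd of per-atom anisotropy for one atom class.

    Returns ``None`` (absent, not zero) when the group holds no valid tensor.
    """
    if group == "protein":
        group = "polymer"
    atoms, n_h = _group_atoms(model, group, exclude_hydrogen)
    values = []
    n_invalid = 0
    for atom in atoms:
        if atom.uij is None:
            continue
        tensor = atom_anisotropy(atom)
        if not tensor.valid:
            n_invalid += 1
            continue
        values.append(tensor.anisotropy)
    if not values:
        return None
    arr = np.asarray(values)
    return GroupStats(
        group=group,
        mean=float(arr.mean()),
        sd=float(arr.std()),  # population sd (divisor N)
        n=len(values),
        n_invalid=n_invalid,
        n_hydrogen_excluded=n_h,
    )


def group_b_factor(
    model: StructureModel, group: str = "polymer", exclude_hydrogen: bool = True
) -> Optional[GroupStats]:
    """Mean and population sd of isotropic B per atom class (absent if empty)."""
    if group == "protein":
        group = "polymer"
    atoms, n_h = _group_atoms(model, group, exclude_hydrogen)
    if not atoms:
        return None
    arr = np.asarray([atom.b_iso for atom in atoms])
    return GroupStats(
        group=group,
        mean=float(arr.mean()),
        sd=float(arr.std()),
        n=len(atoms),
        n_hydrogen_excluded=n_h,
    )


def anisotropy_table(model: StructureModel, exclude_hydrogen: bool = True) -> pd.DataFrame:
    """Per-atom anisotropy table over all atoms carrying ADP tensors."""
    rows = []
    for res in model.residues():
        for atom in res.atoms:
            if atom.uij is None or (exclude_hydrogen and atom.is_hydrogen):
                continue
            tensor = atom_anisotropy(atom)
            rows.append(
                {
                    "chain": atom.chain_id,
                    "resnum": atom.residue_number,
                    "resname": atom.residue_name,
                    "atom": atom.atom_name,
                    "altloc": atom.altloc,
                    "class": res.category,
                    "anisotropy": round(tensor.anisotropy, 4),
                    "b_eq": round(tensor.b_eq, 3),
                    "valid": tensor.valid,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=["chain", "resnum", "resname", "atom", "altloc", "class", "anisotropy", "b_eq", "valid"],
    )
    return frame.sort_values(["chain", "resnum", "atom", "altloc"], kind="stable").reset_index(drop=True)


def export_axes(model: StructureModel, scale: float = 2.0, min_elongation: float = 0.05) -> str:
    """Per-residue averaged major-axis segments as a PyMOL CGO script.

    For each residue the largest-eigenvalue eigenvectors of its valid atom
    tensors are averaged (sign-aligned to the first atom's axis), then the
    averaged direction is sign-fixed to point outward from the molecular
    centroid so repeated runs are deterministic. Nearly isotropic residues
    (relative eigenvalue spread below *min_elongation*) are omitted.
    Segment length is ``scale`` times the mean largest eigenvalue (A per A^2).
    """
    all_positions = [atom.position for atom in model.atoms() if not atom.is_hydrogen]
    if not all_positions:
        return "# no atoms\n"
    center = np.mean(all_positions, axis=0)

    lines = [
        "# anisotropy major-axis field (PyMOL CGO)",
        "from pymol.cgo import CYLINDER",
        "obj = []",
    ]
    n_segments = 0
    for res in model.residues():
        axes = []
        weights = []
        positions = []
        for atom in res.atoms:
            if atom.uij is None or atom.is_hydrogen:
                continue
            tensor = atom_anisotropy(atom)
            if not tensor.valid:
                continue
            spread = (tensor.eigenvalues[0] - tensor.eigenvalues[-1]) / tensor.eigenvalues[0]
            if spread < min_elongation:
                continue  # degenerate (isotropic) axis
            axes.append(tensor.major_axis)
            weights.append(tensor.eigenvalues[0])
            positions.append(atom.position)
        if not axes:
            continue
        reference = axes[0]
        aligned = [a if np.dot(a, reference) >= 0 else -a for a in axes]
        mean_axis = np.mean(aligned, axis=0)
        norm = np.linalg.norm(mean_axis)
        if norm < 1e-9:
            continue
        mean_axis /= norm
        centroid = np.mean(positions, axis=0)
        outward = centroid - center
        if np.dot(mean_axis, outward) < 0:
            mean_axis = -mean_axis
        half = 0.5 * scale * float(np.mean(weights)) * mean_axis
        p1 = centroid - half
        p2 = centroid + half
        lines.append(
            "obj += [CYLINDER, "
            f"{p1[0]:.3f}, {p1[1]:.3f}, {p1[2]:.3f}, "
            f"{p2[0]:.3f}, {p2[1]:.3f}, {p2[2]:.3f}, "
            "0.08, 1.0, 0.6, 0.1, 1.0, 0.6, 0.1]"
            f"  # {res.label}"
        )
        n_segments += 1
    lines.append(f'cmd.load_cgo(obj, "adp_axes")  # {n_segments} segments')
    return "\n".join(lines) + "\n"
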