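"""Synthetic coordinate generator with exactly known geometry.

Builds residues and secondary-structure elements from internal coordinates
(standard bond lengths/angles, NeRF chain extension), applies controlled
distortions (guanidinium twist, aromatic CB bend, prescribed peptide omega),
and attaches ADP tensors with prescribed anisotropy. Every generator returns
the ground truth it built, so analysis modules can be validated by closure.

Templates are idealized: aromatic rings and guanidinium groups are exactly
planar, so the undistorted bending metrics are exactly zero. No physical
plausibility (sterics, energies) is attempted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .geometry import rotation_about_axis
from .structure_io import AtomRecord, ResidueView, StructureModel, write_structure

__all__ = [
    "DistortionSpec",
    "SUPPORTED_RESIDUES",
    "place_atom",
    "build_chain",
    "build_residue",
    "build_element",
    "attach_adps",
    "generate_fixture_suite",
]

#: Residue types with a side-chain template.
SUPPORTED_RESIDUES = frozenset(
    {"ARG", "PHE", "TRP", "TYR", "ALA", "GLY", "LEU", "ASN", "ILE", "MET",
     "THR", "LYS", "GLU", "ASP", "VAL"}
)

_EIGHT_PI_SQ_OVER_3 = 8.0 * math.pi**2 / 3.0

# Backbone ideal values (Engh & Huber style).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
# Improper torsion C-N-CA-CB fixing L chirality.
TORSION_CB = -122.5


@dataclass(frozen=True)
class DistortionSpec:
    """A controlled distortion request for a synthetic fixture."""

    kind: str  # guanidinium_twist | cb_bend | omega_set | ss_element | adp_set
    magnitude: float  # degrees, or anisotropy ratio for adp_set
    target: Optional[object] = None  # residue type or peptide-bond index
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind in ("guanidinium_twist", "cb_bend", "omega_set"):
            if not -180.0 < self.magnitude <= 180.0:
                raise ValueError(f"angle magnitude {self.magnitude} outside (-180, 180]")
        elif self.kind == "adp_set":
            if not 0.0 < self.magnitude <= 1.0:
                raise ValueError(f"anisotropy {self.magnitude} outside (0, 1]")


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) and
    dihedral(a,b,c,d) as given."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# Side-chain z-matrix rows: (atom, c, b, a, bond, angle(b,c,atom), torsion).
# Torsions may be the name of a chi parameter or "chiN+offset".
_SIDE_CHAINS: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "VAL": [
        ("CG1", "CB", "CA", "N", 1.521, 110.5, "chi1"),
        ("CG2", "CB", "CA", "N", 1.521, 110.5, "chi1-122"),
    ],
    "THR": [
        ("OG1", "CB", "CA", "N", 1.433, 109.6, "chi1"),
        ("CG2", "CB", "CA", "N", 1.521, 110.5, "chi1-122"),
    ],
    "ILE": [
        ("CG1", "CB", "CA", "N", 1.530, 110.4, "chi1"),
        ("CG2", "CB", "CA", "N", 1.521, 110.5, "chi1-122"),
        ("CD1", "CG1", "CB", "CA", 1.513, 113.8, "chi2"),
    ],
    "LEU": [
        ("CG", "CB", "CA", "N", 1.530, 116.3, "chi1"),
        ("CD1", "CG", "CB", "CA", 1.521, 110.7, "chi2"),
        ("CD2", "CG", "CB", "CA", 1.521, 110.7, "chi2+122"),
    ],
    "MET": [
        ("CG", "CB", "CA", "N", 1.520, 114.1, "chi1"),
        ("SD", "CG", "CB", "CA", 1.803, 112.7, "chi2"),
        ("CE", "SD", "CG", "CB", 1.791, 100.9, "chi3"),
    ],
    "ASP": [
        ("CG", "CB", "CA", "N", 1.516, 112.6, "chi1"),
        ("OD1", "CG", "CB", "CA", 1.249, 118.4, "chi2"),
        ("OD2", "CG", "CB", "CA", 1.249, 118.4, "chi2+180"),
    ],
    "ASN": [
        ("CG", "CB", "CA", "N", 1.516, 112.6, "chi1"),
        ("OD1", "CG", "CB", "CA", 1.231, 120.8, "chi2"),
        ("ND2", "CG", "CB", "CA", 1.328, 116.4, "chi2+180"),
    ],
    "GLU": [
        ("CG", "CB", "CA", "N", 1.520, 114.1, "chi1"),
        ("CD", "CG", "CB", "CA", 1.516, 112.6, "chi2"),
        ("OE1", "CD", "CG", "CB", 1.249, 118.4, "chi3"),
        ("OE2", "CD", "CG", "CB", 1.249, 118.4, "chi3+180"),
    ],
    "LYS": [
        ("CG", "CB", "CA", "N", 1.520, 114.1, "chi1"),
        ("CD", "CG", "CB", "CA", 1.520, 111.3, "chi2"),
        ("CE", "CD", "CG", "CB", 1.520, 111.3, "chi3"),
        ("NZ", "CE", "CD", "CG", 1.489, 111.9, "chi4"),
    ],
    "ARG": [
        ("CG", "CB", "CA", "N", 1.520, 114.1, "chi1"),
        ("CD", "CG", "CB", "CA", 1.520, 111.3, "chi2"),
        ("NE", "CD", "CG", "CB", 1.461, 112.0, "chi3"),
        ("CZ", "NE", "CD", "CG", 1.329, 124.2, "chi4"),
        # Exactly planar guanidinium, NH1 cis to CD (twist 0 by construction).
        ("NH1", "CZ", "NE", "CD", 1.326, 120.0, "0"),
        ("NH2", "CZ", "NE", "CD", 1.326, 120.0, "180"),
    ],
    "PHE": [
        ("CG", "CB", "CA", "N", 1.502, 113.8, "chi1"),
        # Regular planar hexagon: CB lands exactly on the CG-CZ para axis.
        ("CD1", "CG", "CB", "CA", 1.390, 120.0, "chi2"),
        ("CD2", "CG", "CB", "CD1", 1.390, 120.0, "180"),
        ("CE1", "CD1", "CG", "CB", 1.390, 120.0, "180"),
        ("CE2", "CD2", "CG", "CB", 1.390, 120.0, "180"),
        ("CZ", "CE1", "CD1", "CG", 1.390, 120.0, "0"),
    ],
    "TRP": [
        ("CG", "CB", "CA", "N", 1.498, 113.6, "chi1"),
        # Exactly planar indole (all ring torsions 0/180).
        ("CD1", "CG", "CB", "CA", 1.370, 126.9, "chi2"),
        ("CD2", "CG", "CB", "CD1", 1.433, 126.8, "180"),
        ("NE1", "CD1", "CG", "CD2", 1.374, 110.1, "0"),
        ("CE2", "NE1", "CD1", "CG", 1.370, 109.0, "0"),
        ("CE3", "CD2", "CG", "CD1", 1.398, 133.9, "180"),
        ("CZ2", "CE2", "NE1", "CD1", 1.394, 130.4, "180"),
        ("CZ3", "CE3", "CD2", "CG", 1.382, 118.8, "180"),
        ("CH2", "CZ2", "CE2", "NE1", 1.368, 117.5, "180"),
    ],
}
_SIDE_CHAINS["TYR"] = _SIDE_CHAINS["PHE"] + [
    # In-plane para OH: both tyr_bend component angles are exactly 180.
    ("OH", "CZ", "CE1", "CD1", 1.377, 120.0, "180"),
]

_DEFAULT_CHI = {"chi1": -65.0, "chi2": 180.0, "chi3": 180.0, "chi4": 180.0}
_DEFAULT_CHI_AROMATIC = {"chi1": -65.0, "chi2": 90.0}

_ELEMENT_BY_INITIAL = {"C": "C", "N": "N", "O": "O", "S": "S", "H": "H"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_BY_INITIAL.get(atom_name[0], atom_name[0])


def _resolve_torsion(expr: str, chi: dict[str, float]) -> float:
    expr = expr.strip()
    for name, value in chi.items():
        if expr.startswith(name):
            rest = expr[len(name):]
            return value + (float(rest) if rest else 0.0)
    return float(expr)


def _default_chi(residue_name: str) -> dict[str, float]:
    if residue_name in ("PHE", "TYR", "TRP"):
        return dict(_DEFAULT_CHI_AROMATIC)
    return dict(_DEFAULT_CHI)


def build_chain(
    sequence: Sequence[str],
    phi: Sequence[float],
    psi: Sequence[float],
    omega: Optional[Sequence[float]] = None,
    chi: Optional[dict[int, dict[str, float]]] = None,
    chain_id: str = "A",
    start_resnum: int = 1,
    b_iso: float = 10.0,
) -> StructureModel:
    """Build a polypeptide from backbone dihedrals (heavy atoms only).

    ``phi[0]`` and ``omega`` entries beyond the ``len(sequence) - 1`` peptide
    bonds are ignored; ``psi[-1]`` only orients the final carbonyl. Side-chain
    chi angles may be overridden per residue index via *chi*.
    """
    n = len(sequence)
    if n < 1:
        raise ValueError("sequence must contain at least one residue")
    for name in sequence:
        if name not in SUPPORTED_RESIDUES:
            raise ValueError(
                f"unsupported residue type {name!r}; supported: "
                + ", ".join(sorted(SUPPORTED_RESIDUES))
            )
    if len(phi) != n or len(psi) != n:
        raise ValueError("phi/psi must match sequence length")
    omega = list(omega) if omega is not None else [180.0] * (n - 1)
    if len(omega) != n - 1:
        raise ValueError("omega needs one value per peptide bond")

    model = StructureModel(entry_id="SYNTH")
    residues: list[ResidueView] = []
    coords: list[dict[str, np.ndarray]] = []

    for i, resname in enumerate(sequence):
        atom_pos: dict[str, np.ndarray] = {}
        if i == 0:
            atom_pos["N"] = np.zeros(3)
            atom_pos["CA"] = np.array([BOND_N_CA, 0.0, 0.0])
            theta = np.radians(ANGLE_N_CA_C)
            atom_pos["C"] = atom_pos["CA"] + BOND_CA_C * np.array(
                [-np.cos(theta), np.sin(theta), 0.0]
            )
        else:
            prev = coords[i - 1]
            atom_pos["N"] = place_atom(
                prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi[i - 1]
            )
            atom_pos["CA"] = place_atom(
                prev["CA"], prev["C"], atom_pos["N"], BOND_N_CA, ANGLE_C_N_CA, omega[i - 1]
            )
            atom_pos["C"] = place_atom(
                prev["C"], atom_pos["N"], atom_pos["CA"], BOND_CA_C, ANGLE_N_CA_C, phi[i]
            )
        atom_pos["O"] = place_atom(
            atom_pos["N"], atom_pos["CA"], atom_pos["C"], BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0
        )
        if resname != "GLY":
            atom_pos["CB"] = place_atom(
                atom_pos["C"], atom_pos["N"], atom_pos["CA"], 1.530, 110.5, TORSION_CB
            )
        chi_values = _default_chi(resname)
        if chi and i in chi:
            chi_values.update(chi[i])
        for row in _SIDE_CHAINS[resname]:
            name, c_ref, b_ref, a_ref, bond, ang, torsion = row
            atom_pos[name] = place_atom(
                atom_pos[a_ref],
                atom_pos[b_ref],
                atom_pos[c_ref],
                bond,
                ang,
                _resolve_torsion(torsion, chi_values),
            )

        res = ResidueView(chain_id, start_resnum + i, "", resname, category="polymer")
        for name, pos in atom_pos.items():
            res.add_atom(
                AtomRecord(
                    chain_id=chain_id,
                    residue_number=start_resnum + i,
                    insertion_code="",
                    residue_name=resname,
                    atom_name=name,
                    element=_element_of(name),
                    position=pos,
                    b_iso=b_iso,
                )
            )
        residues.append(res)
        coords.append(atom_pos)

    for left, right in zip(residues, residues[1:]):
        left.next = right
        right.prev = left
    model.chains[chain_id] = residues
    return model


def _rotate_atoms(
    res: ResidueView, atom_names: Sequence[str], pivot: np.ndarray, axis: np.ndarray, angle_deg: float
) -> None:
    rot = rotation_about_axis(axis, angle_deg)
    for atom in res.atoms:
        if atom.atom_name in atom_names:
            atom.position = pivot + rot @ (atom.position - pivot)


def _apply_signed_rotation(res, atom_names, pivot, axis, magnitude, measure) -> float:
    """Rotate the named atoms so that *measure* returns +magnitude exactly."""
    _rotate_atoms(res, atom_names, pivot, axis, magnitude)
    achieved = measure()
    if abs(achieved - magnitude) > 1e-6:
        _rotate_atoms(res, atom_names, pivot, axis, -2.0 * magnitude)
        achieved = measure()
    return achieved


def build_residue(
    residue_type: str, distortion: Optional[DistortionSpec] = None
) -> tuple[ResidueView, dict]:
    """One residue with ideal internal geometry plus an optional distortion.

    Returns the residue and a ground-truth record holding the applied
    distortion (the value the matching strain metric must recover).
    """
    if residue_type not in SUPPORTED_RESIDUES:
        raise ValueError(
            f"unsupported residue type {residue_type!r}; supported: "
            + ", ".join(sorted(SUPPORTED_RESIDUES))
        )
    model = build_chain([residue_type], [-139.0], [135.0])
    res = model.chains["A"][0]
    truth: dict = {"residue_type": residue_type, "distortion": None, "applied": 0.0}
    if distortion is None or distortion.kind == "ss_element":
        return res, truth

    from . import strain  # local import to avoid cycle at module load

    atoms = res.conformer()
    truth["distortion"] = distortion.kind
    if distortion.kind == "guanidinium_twist":
        if residue_type != "ARG":
            raise ValueError("guanidinium_twist applies to ARG only")
        axis = atoms["CZ"].position - atoms["NE"].position
        achieved = _apply_signed_rotation(
            res,
            ("NH1", "NH2"),
            atoms["CZ"].position,
            axis,
            distortion.magnitude,
            lambda: strain.arg_twist(res).value,
        )
    elif distortion.kind == "cb_bend":
        if residue_type == "PHE":
            # Rotate CB about the ring normal through CG: bends CB off the
            # para axis by exactly the requested angle.
            normal = np.cross(
                atoms["CD1"].position - atoms["CG"].position,
                atoms["CD2"].position - atoms["CG"].position,
            )
            achieved = _apply_signed_rotation(
                res, ("CB",), atoms["CG"].position, normal,
                distortion.magnitude, lambda: strain.phe_bend(res).value,
            )
        elif residue_type == "TYR":
            # Rotate OH in-plane about CZ: shifts the second component angle.
            normal = np.cross(
                atoms["CE1"].position - atoms["CZ"].position,
                atoms["CE2"].position - atoms["CZ"].position,
            )
            achieved = _apply_signed_rotation(
                res, ("OH",), atoms["CZ"].position, normal,
                distortion.magnitude, lambda: strain.tyr_bend(res).value,
            )
        elif residue_type == "TRP":
            # Rotate CB about the CG->CE2 pseudo-torsion axis.
            axis = atoms["CE2"].position - atoms["CG"].position
            achieved = _apply_signed_rotation(
                res, ("CB",), atoms["CG"].position, axis,
                distortion.magnitude, lambda: strain.trp_bend(res).value,
            )
        else:
            raise ValueError("cb_bend applies to PHE, TYR or TRP")
    else:
        raise ValueError(f"unsupported residue distortion kind {distortion.kind!r}")
    truth["applied"] = achieved
    return res, truth


def residue_model(res: ResidueView, entry_id: str = "SYNTH") -> StructureModel:
    """Wrap a single residue in a one-chain model."""
    model = StructureModel(entry_id=entry_id)
    model.chains[res.chain_id] = [res]
    return model


# ---------------------------------------------------------------------------
# Secondary-structure elements
# ---------------------------------------------------------------------------

_PHI_PSI = {
    "helix": (-57.0, -47.0),
    "sheet": (-139.0, 135.0),
}


def _residue_frame(res: ResidueView) -> tuple[np.ndarray, np.ndarray]:
    atoms = res.conformer()
    n, ca, c = atoms["N"].position, atoms["CA"].position, atoms["C"].position
    e1 = c - n
    e1 /= np.linalg.norm(e1)
    v = ca - n
    e2 = v - np.dot(v, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3]), ca


def _screw_trace(phi: float, psi: float) -> float:
    """Trace of the per-residue rotation of a uniform (phi, psi) chain."""
    model = build_chain(["GLY", "GLY"], [phi, phi], [psi, psi])
    f0, _ = _residue_frame(model.chains["A"][0])
    f1, _ = _residue_frame(model.chains["A"][1])
    return float(np.trace(f1 @ f0.T))


def _flat_strand_dihedrals(phi_guess: float, psi_guess: float) -> tuple[float, float]:
    """(phi, psi) making a uniform strand exactly 2-residue periodic.

    A flat pleated strand needs the residue-to-residue screw rotation to be
    exactly 180 deg (trace -1), so that every second residue is related by a
    pure translation and an inter-strand register can close exactly. The
    trace is bounded below by -1, so the flat-strand set is found by
    minimizing (trace + 1) from the canonical guess.
    """

    def objective(params) -> float:
        return _screw_trace(params[0], params[1]) + 1.0

    result = minimize(
        objective,
        np.array([phi_guess, psi_guess]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    return float(result.x[0]), float(result.x[1])


def _virtual_amide_h(res: ResidueView) -> Optional[np.ndarray]:
    prev = res.prev
    if prev is None:
        return None
    atoms = res.conformer()
    prev_atoms = prev.conformer()
    n = atoms.get("N")
    ca = atoms.get("CA")
    c = prev_atoms.get("C")
    if n is None or ca is None or c is None:
        return None
    u1 = (n.position - c.position) / np.linalg.norm(n.position - c.position)
    u2 = (n.position - ca.position) / np.linalg.norm(n.position - ca.position)
    direction = u1 + u2
    direction /= np.linalg.norm(direction)
    return n.position + 1.01 * direction


def _transform_chain(residues: list[ResidueView], rotation: np.ndarray, translation: np.ndarray) -> None:
    for res in residues:
        for atom in res.atoms:
            atom.position = rotation @ atom.position + translation


def _dock_strand(
    strand_a: list[ResidueView],
    strand_b: list[ResidueView],
    nh_to_o: list[tuple[ResidueView, ResidueView]],
    init_rotation: np.ndarray,
    init_translation: np.ndarray,
) -> None:
    """Rigidly place strand B so the requested N-H...O=C register forms.

    Minimizes deviations of N...O (2.9 A) and H...O (1.9 A) distances for the
    intended donor/acceptor residue pairs, plus a soft CA-CA repulsion to
    avoid collapse. Deterministic local optimization from the supplied guess.
    """
    _transform_chain(strand_b, init_rotation, init_translation)
    b_coords0 = {
        id(atom): atom.position.copy() for res in strand_b for atom in res.atoms
    }
    ca_a = np.array([r.conformer()["CA"].position for r in strand_a])

    def apply_params(params: np.ndarray) -> None:
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        shift = params[3:]
        for res in strand_b:
            for atom in res.atoms:
                atom.position = rot @ b_coords0[id(atom)] + shift

    def cost(params: np.ndarray) -> float:
        apply_params(params)
        total = 0.0
        for donor_res, acceptor_res in nh_to_o:
            n_atom = donor_res.conformer().get("N")
            o_atom = acceptor_res.conformer().get("O")
            if n_atom is None or o_atom is None:
                continue
            d_no = np.linalg.norm(n_atom.position - o_atom.position)
            total += (d_no - 2.9) ** 2
            h = _virtual_amide_h(donor_res)
            if h is not None:
                total += (np.linalg.norm(h - o_atom.position) - 1.9) ** 2
        ca_b = np.array([r.conformer()["CA"].position for r in strand_b])
        diff = ca_a[:, None, :] - ca_b[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        total += float(np.clip(4.2 - dist, 0.0, None).sum() ** 2)
        return total

    result = minimize(cost, np.zeros(6), method="Powell", options={"maxiter": 4000, "xtol": 1e-10, "ftol": 1e-12})
    apply_params(result.x)


def build_element(
    kind: str,
    length: int = 10,
    sequence: Optional[Sequence[str]] = None,
    omega_overrides: Optional[dict[int, float]] = None,
    chi: Optional[dict[int, dict[str, float]]] = None,
) -> tuple[StructureModel, dict]:
    """Canonical secondary-structure element plus ground-truth labels.

    ``kind`` is one of ``helix``, ``antiparallel_sheet``, ``parallel_sheet``
    or ``beta_turn_I``; *length* is residues per strand (sheets build two
    strands, chains A and B). The ground truth holds intended per-residue SS
    labels and the intended backbone H-bond register as
    ``(donor_chain, donor_resnum, acceptor_chain, acceptor_resnum)`` tuples
    for N-H...O=C bonds.
    """
    if length < 3:
        raise ValueError("element length must be >= 3 residues")
    omega_overrides = omega_overrides or {}

    def seq(default_len: int) -> list[str]:
        if sequence is not None:
            if len(sequence) != default_len:
                raise ValueError(f"sequence must have length {default_len}")
            return list(sequence)
        return ["ALA"] * default_len

    truth: dict = {"kind": kind, "ss": {}, "register": [], "omega": {}}

    if kind == "helix":
        phi0, psi0 = _PHI_PSI["helix"]
        names = seq(length)
        omega = [omega_overrides.get(i, 180.0) for i in range(length - 1)]
        model = build_chain(names, [phi0] * length, [psi0] * length, omega, chi=chi)
        residues = model.chains["A"]
        for res in residues:
            truth["ss"][("A", res.residue_number)] = "H"
        # i -> i+4 register: donor N-H of residue i+4, acceptor O of residue i.
        for i in range(length - 4):
            truth["register"].append(("A", residues[i + 4].residue_number, "A", residues[i].residue_number))
        truth["omega"] = {i: omega[i] for i in range(length - 1)}
        return model, truth

    if kind == "beta_turn_I":
        total = max(length, 4)
        names = seq(total)
        phi = [-139.0] * total
        psi = [135.0] * total
        # Type I turn at residues 1 and 2 (0-based); donor i+3 -> acceptor i=0.
        phi[1], psi[1] = -60.0, -30.0
        phi[2], psi[2] = -90.0, 0.0
        # Exit-residue phi chosen so the i+3 side chain's CB-H points back at
        # the carbonyl of residue i (the side-chain turn-cap geometry).
        phi[3] = -100.0
        omega = [omega_overrides.get(i, 180.0) for i in range(total - 1)]
        model = build_chain(names, phi, psi, omega, chi=chi)
        residues = model.chains["A"]
        for res in residues:
            truth["ss"][("A", res.residue_number)] = "C"
        truth["ss"][("A", residues[1].residue_number)] = "T"
        truth["ss"][("A", residues[2].residue_number)] = "T"
        truth["register"].append(("A", residues[3].residue_number, "A", residues[0].residue_number))
        truth["turn"] = ("A", residues[0].residue_number, "A", residues[3].residue_number)
        return model, truth

    if kind in ("antiparallel_sheet", "parallel_sheet"):
        phi_guess, psi_guess = _PHI_PSI["sheet"]
        phi0, psi0 = _flat_strand_dihedrals(phi_guess, psi_guess)
        names = seq(length)
        omega = [omega_overrides.get(i, 180.0) for i in range(length - 1)]
        model_a = build_chain(names, [phi0] * length, [psi0] * length, omega, chi=chi, chain_id="A")
        model_b = build_chain(names, [phi0] * length, [psi0] * length, omega, chi=chi, chain_id="B")
        strand_a = model_a.chains["A"]
        strand_b = model_b.chains["B"]

        ca = [r.conformer()["CA"].position for r in strand_a]
        period = ca[2] - ca[0]  # exact 2-residue translation of the strand
        axis = period / np.linalg.norm(period)
        # Pleating plane normal from the CA zigzag.
        zigzag = ca[1] - 0.5 * (ca[0] + ca[2])
        normal = np.cross(axis, zigzag)
        normal /= np.linalg.norm(normal)
        lateral = np.cross(normal, axis)  # in-sheet, perpendicular to strands
        centroid = np.mean([a.position for r in strand_a for a in r.atoms], axis=0)

        nh_to_o: list[tuple[ResidueView, ResidueView]] = []
        if kind == "antiparallel_sheet":
            # C2 rotation about the sheet normal reverses the strand while
            # keeping the sheet plane: exact register closure by symmetry.
            rot = rotation_about_axis(normal, 180.0)
            # Hydrogen-bonded pairs i <-> (length-1-i) at even i.
            pairs = []
            for i in range(0, length, 2):
                j = length - 1 - i
                if 0 <= j < length:
                    pairs.append((i, j))
                    if i >= 1:
                        nh_to_o.append((strand_a[i], strand_b[j]))
                    if j >= 1:
                        nh_to_o.append((strand_b[j], strand_a[i]))
            # Initial shift: paired CAs side by side, 4.8 A apart laterally.
            targets = []
            for i, j in pairs:
                rotated = rot @ (ca[j] - centroid) + centroid
                targets.append(ca[i] + 4.8 * lateral - rotated)
            translation = centroid - rot @ centroid + np.mean(targets, axis=0)
        else:
            rot = np.eye(3)
            # Parallel register: N-H(B_i) -> O(A_{i-1}), N-H(A_{i+1}) -> O(B_i).
            for i in range(1, length - 1, 2):
                nh_to_o.append((strand_b[i], strand_a[i - 1]))
                if i + 1 < length:
                    nh_to_o.append((strand_a[i + 1], strand_b[i]))
            translation = 4.8 * lateral

        _dock_strand(strand_a, strand_b, nh_to_o, rot, translation)

        model = StructureModel(entry_id="SYNTH")
        model.chains["A"] = strand_a
        model.chains["B"] = strand_b
        for res in strand_a + strand_b:
            truth["ss"][(res.chain_id, res.residue_number)] = "E"
        for donor, acceptor in nh_to_o:
            truth["register"].append(
                (donor.chain_id, donor.residue_number, acceptor.chain_id, acceptor.residue_number)
            )
        return model, truth

    raise ValueError(
        f"unknown element kind {kind!r}; use helix, antiparallel_sheet, parallel_sheet or beta_turn_I"
    )


# ---------------------------------------------------------------------------
# ADP attachment
# ---------------------------------------------------------------------------

def attach_adps(
    model: StructureModel,
    anisotropy: float,
    axis=(0.0, 0.0, 1.0),
    b_eq: float = 10.0,
) -> StructureModel:
    """Give every atom a U tensor with the prescribed anisotropy and B_eq.

    The largest principal axis points along *axis* (normalized silently); the
    middle eigenvalue is the mean of the extremes.
    """
    if not 0.0 < anisotropy <= 1.0:
        raise ValueError(f"anisotropy {anisotropy} outside (0, 1]")
    if b_eq <= 0.0:
        raise ValueError("b_eq must be positive")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("axis must be non-zero")
    e1 = axis / norm
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, e1)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    basis = np.column_stack([e1, e2, e3])

    trace = 3.0 * b_eq / (8.0 * math.pi**2)
    lam_max = trace / (1.5 * (1.0 + anisotropy))
    lam_min = anisotropy * lam_max
    lam_mid = 0.5 * (lam_max + lam_min)
    u = basis @ np.diag([lam_max, lam_mid, lam_min]) @ basis.T

    for res in model.residues():
        for atom in res.atoms:
            atom.b_iso = b_eq
            atom.uij = u.copy()
    return model


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

_BEND_FIXTURES = [
    ("ARG", "guanidinium_twist", "arg_twist"),
    ("PHE", "cb_bend", "phe_bend"),
    ("TRP", "cb_bend", "trp_bend"),
    ("TYR", "cb_bend", "tyr_bend"),
]


def generate_fixture_suite(out_dir, seed: int = 0, deltas=(0.0, 1.0, 2.0, 5.0, 10.0, 20.0)) -> dict:
    """Write the named fixture suite as PDB files plus a manifest JSON.

    The manifest maps each file name to its ground truth (metric and exact
    applied value, SS labels, H-bond register, or ADP parameters). The same
    seed always produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    for residue_type, kind, metric in _BEND_FIXTURES:
        for delta in deltas:
            spec = DistortionSpec(kind=kind, magnitude=delta, seed=seed) if delta else None
            res, truth = build_residue(residue_type, spec)
            name = f"{metric}_{delta:g}.pdb"
            write_structure(residue_model(res), out_dir / name)
            manifest["files"][name] = {
                "kind": "bend",
                "metric": metric,
                "ground_truth": truth["applied"],
            }

    for delta in deltas:
        n = 6
        omega = {2: 180.0 - delta}
        model, truth = build_element("beta_turn_I", length=n, omega_overrides=omega)
        # Rebuild as a plain extended chain so only the prescribed bond bends.
        model = build_chain(["ALA"] * n, [-139.0] * n, [135.0] * n,
                            [omega.get(i, 180.0) for i in range(n - 1)])
        name = f"omega_dev_{delta:g}.pdb"
        write_structure(model, out_dir / name)
        manifest["files"][name] = {
            "kind": "omega",
            "metric": "omega_dev",
            "bond_index": 2,
            "ground_truth": -delta,
        }

    for kind, n in (("helix", 12), ("antiparallel_sheet", 6), ("beta_turn_I", 6)):
        model, truth = build_element(kind, length=n)
        name = f"{kind}.pdb"
        write_structure(model, out_dir / name)
        manifest["files"][name] = {
            "kind": "ss_element",
            "element": kind,
            "ss": {f"{c}:{r}": label for (c, r), label in truth["ss"].items()},
            "register": truth["register"],
        }

    for ratio in (0.25, 0.5, 1.0):
        model, _ = build_element("helix", length=8)
        attach_adps(model, ratio, axis=(0.0, 0.0, 1.0), b_eq=10.0)
        name = f"adp_{ratio:g}.pdb"
        write_structure(model, out_dir / name)
        manifest["files"][name] = {
            "kind": "adp",
            "anisotropy": ratio,
            "b_eq": 10.0,
        }

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
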