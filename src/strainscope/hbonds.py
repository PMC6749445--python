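"""Weak hydrogen-bond analysis: riding-hydrogen placement, N-H...O and
C-H...O detection, secondary-structure assignment from backbone bonds, and
capping-motif classification.

Default geometric criteria (ours, configurable): C-H...O requires
d(H...O) <= 2.8 A, d(C...O) <= 3.8 A and angle(C-H...O) >= 110 deg;
N-H...O requires d(H...O) <= 2.5 A, d(N...O) <= 3.5 A and angle >= 120 deg.
Acceptors are restricted to oxygen. Observed hydrogens win over placed ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import angle
from .structure_io import AtomRecord, ResidueView, StructureModel

__all__ = [
    "HBondCriteria",
    "HydrogenBond",
    "SSAssignment",
    "place_hydrogens",
    "find_hbonds",
    "assign_secondary_structure",
    "classify_motifs",
    "hbond_table",
]

logger = logging.getLogger(__name__)

BOND_C_H = 1.09
BOND_N_H = 1.01
_H_PARENT_CUTOFF = 1.5  # max H-heavy distance for parent assignment
_TETRAHEDRAL_HALF = 54.25  # half H-X-H angle for sp3 CH2

MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class HBondCriteria:
    """Distance/angle thresholds for emitted bonds (all configurable)."""

    ch_max_ha: float = 2.8
    ch_max_da: float = 3.8
    ch_min_angle: float = 110.0
    nh_max_ha: float = 2.5
    nh_max_da: float = 3.5
    nh_min_angle: float = 120.0


@dataclass(frozen=True)
class HydrogenBond:
    """A D-H...A contact satisfying the criteria, with classification."""

    donor: AtomRecord
    hydrogen: AtomRecord
    acceptor: AtomRecord
    donor_residue: ResidueView = field(repr=False)
    acceptor_residue: ResidueView = field(repr=False)
    d_ha: float = 0.0
    d_da: float = 0.0
    theta_dha: float = 0.0
    donor_class: str = ""  # main_chain | side_chain
    acceptor_class: str = ""  # main_chain_carbonyl | side_chain_O | water | ligand_O
    bond_type: str = ""  # NH_O | CH_O
    hydrogen_placed: bool = False
    motif: str = "other"

    @property
    def key(self) -> tuple:
        return (
            self.donor.chain_id, self.donor.residue_number, self.donor.atom_name,
            self.hydrogen.atom_name,
            self.acceptor.chain_id, self.acceptor.residue_number, self.acceptor.atom_name,
        )


# ---------------------------------------------------------------------------
# Riding hydrogen placement
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place_sp3_one(parent, neighbors, bond):
    direction = -sum(_unit(n - parent) for n in neighbors)
    return [parent + bond * _unit(direction)]


def _place_sp3_two(parent, neighbors, bond):
    u1, u2 = (_unit(n - parent) for n in neighbors)
    bisector = -_unit(u1 + u2)
    perp = _unit(np.cross(u1, u2))
    half = np.radians(_TETRAHEDRAL_HALF)
    return [
        parent + bond * _unit(np.cos(half) * bisector + np.sin(half) * perp),
        parent + bond * _unit(np.cos(half) * bisector - np.sin(half) * perp),
    ]


def _place_sp2_one(parent, neighbors, bond):
    direction = -sum(_unit(n - parent) for n in neighbors)
    return [parent + bond * _unit(direction)]


def _place_methyl(parent, heavy, ref, bond):
    """Three staggered H: torsions 180/60/-60 relative to *ref* about the
    heavy->parent axis, tetrahedral angle to the heavy neighbor."""
    from .synthetic import place_atom

    return [
        place_atom(ref, heavy, parent, bond, 109.5, torsion)
        for torsion in (180.0, 60.0, -60.0)
    ]


def _place_amide_two(parent, heavy, ref, bond):
    """Two in-plane H on an sp2 N (e.g. Arg NH1/NH2, Asn ND2), at +-120 deg
    from the N->heavy direction within the (ref, heavy, parent) plane."""
    u = _unit(heavy - parent)
    normal = _unit(np.cross(ref - heavy, parent - heavy))
    in_plane = _unit(np.cross(normal, u))
    cos120, sin120 = np.cos(np.radians(120.0)), np.sin(np.radians(120.0))
    return [
        parent + bond * _unit(cos120 * u + sin120 * in_plane),
        parent + bond * _unit(cos120 * u - sin120 * in_plane),
    ]


# Side-chain topology: (parent, H names, kind, reference atom names).
# kind: ch1 (sp3, 3 heavy refs), ch2 (sp3, 2 heavy refs), ar (sp2, 2 refs),
# me3 (methyl; refs = [heavy, stagger ref]), am2 (planar NH2; refs =
# [heavy, plane ref]).
_SIDE_CHAIN_H: dict[str, list[tuple]] = {
    "ALA": [("CB", ["HB1", "HB2", "HB3"], "me3", ["CA", "N"])],
    "ARG": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CG", ["HG2", "HG3"], "ch2", ["CB", "CD"]),
        ("CD", ["HD2", "HD3"], "ch2", ["CG", "NE"]),
        ("NE", ["HE"], "ar", ["CD", "CZ"]),
        ("NH1", ["HH11", "HH12"], "am2", ["CZ", "NE"]),
        ("NH2", ["HH21", "HH22"], "am2", ["CZ", "NE"]),
    ],
    "ASN": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("ND2", ["HD21", "HD22"], "am2", ["CG", "OD1"]),
    ],
    "ASP": [("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"])],
    "CYS": [("CB", ["HB2", "HB3"], "ch2", ["CA", "SG"])],
    "GLN": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CG", ["HG2", "HG3"], "ch2", ["CB", "CD"]),
        ("NE2", ["HE21", "HE22"], "am2", ["CD", "OE1"]),
    ],
    "GLU": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CG", ["HG2", "HG3"], "ch2", ["CB", "CD"]),
    ],
    "GLY": [],
    "HIS": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CD2", ["HD2"], "ar", ["CG", "NE2"]),
        ("CE1", ["HE1"], "ar", ["ND1", "NE2"]),
        ("NE2", ["HE2"], "ar", ["CD2", "CE1"]),
    ],
    "ILE": [
        ("CB", ["HB"], "ch1", ["CA", "CG1", "CG2"]),
        ("CG1", ["HG12", "HG13"], "ch2", ["CB", "CD1"]),
        ("CG2", ["HG21", "HG22", "HG23"], "me3", ["CB", "CA"]),
        ("CD1", ["HD11", "HD12", "HD13"], "me3", ["CG1", "CB"]),
    ],
    "LEU": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CG", ["HG"], "ch1", ["CB", "CD1", "CD2"]),
        ("CD1", ["HD11", "HD12", "HD13"], "me3", ["CG", "CB"]),
        ("CD2", ["HD21", "HD22", "HD23"], "me3", ["CG", "CB"]),
    ],
    "LYS": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CG", ["HG2", "HG3"], "ch2", ["CB", "CD"]),
        ("CD", ["HD2", "HD3"], "ch2", ["CG", "CE"]),
        ("CE", ["HE2", "HE3"], "ch2", ["CD", "NZ"]),
        ("NZ", ["HZ1", "HZ2", "HZ3"], "me3", ["CE", "CD"]),
    ],
    "MET": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CG", ["HG2", "HG3"], "ch2", ["CB", "SD"]),
        ("CE", ["HE1", "HE2", "HE3"], "me3", ["SD", "CG"]),
    ],
    "PHE": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CD1", ["HD1"], "ar", ["CG", "CE1"]),
        ("CD2", ["HD2"], "ar", ["CG", "CE2"]),
        ("CE1", ["HE1"], "ar", ["CD1", "CZ"]),
        ("CE2", ["HE2"], "ar", ["CD2", "CZ"]),
        ("CZ", ["HZ"], "ar", ["CE1", "CE2"]),
    ],
    "PRO": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CG", ["HG2", "HG3"], "ch2", ["CB", "CD"]),
        ("CD", ["HD2", "HD3"], "ch2", ["CG", "N"]),
    ],
    "SER": [("CB", ["HB2", "HB3"], "ch2", ["CA", "OG"])],
    "THR": [
        ("CB", ["HB"], "ch1", ["CA", "OG1", "CG2"]),
        ("CG2", ["HG21", "HG22", "HG23"], "me3", ["CB", "CA"]),
    ],
    "TRP": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CD1", ["HD1"], "ar", ["CG", "NE1"]),
        ("NE1", ["HE1"], "ar", ["CD1", "CE2"]),
        ("CE3", ["HE3"], "ar", ["CD2", "CZ3"]),
        ("CZ2", ["HZ2"], "ar", ["CH2", "CE2"]),
        ("CZ3", ["HZ3"], "ar", ["CE3", "CH2"]),
        ("CH2", ["HH2"], "ar", ["CZ2", "CZ3"]),
    ],
    "TYR": [
        ("CB", ["HB2", "HB3"], "ch2", ["CA", "CG"]),
        ("CD1", ["HD1"], "ar", ["CG", "CE1"]),
        ("CD2", ["HD2"], "ar", ["CG", "CE2"]),
        ("CE1", ["HE1"], "ar", ["CD1", "CZ"]),
        ("CE2", ["HE2"], "ar", ["CD2", "CZ"]),
    ],
    "VAL": [
        ("CB", ["HB"], "ch1", ["CA", "CG1", "CG2"]),
        ("CG1", ["HG11", "HG12", "HG13"], "me3", ["CB", "CA"]),
        ("CG2", ["HG21", "HG22", "HG23"], "me3", ["CB", "CA"]),
    ],
}


def _existing_h_count(res_atoms: dict[str, AtomRecord], parent: AtomRecord, all_h: Iterable[AtomRecord]) -> int:
    count = 0
    for h in all_h:
        if np.linalg.norm(h.position - parent.position) <= _H_PARENT_CUTOFF:
            count += 1
    return count


def _make_h(parent: AtomRecord, name: str, position: np.ndarray) -> AtomRecord:
    return AtomRecord(
        chain_id=parent.chain_id,
        residue_number=parent.residue_number,
        insertion_code=parent.insertion_code,
        residue_name=parent.residue_name,
        atom_name=name,
        element="H",
        position=position,
        occupancy=parent.occupancy,
        b_iso=parent.b_iso,
        altloc=parent.altloc,
        source="placed",
    )


def _place_for_rule(res_atoms, parent_name, h_names, kind, refs, extra=None):
    """Compute H positions for one topology rule; None if refs missing."""
    parent = res_atoms.get(parent_name)
    if parent is None:
        return None
    ref_positions = []
    for ref in refs:
        atom = res_atoms.get(ref) if not (extra and ref in extra) else extra[ref]
        if atom is None:
            return None
        ref_positions.append(atom.position if isinstance(atom, AtomRecord) else atom)
    p = parent.position
    bond = BOND_N_H if parent.element.upper() in ("N", "D") or parent.element.upper() == "N" else BOND_C_H
    if parent.element.upper() == "N":
        bond = BOND_N_H
    else:
        bond = BOND_C_H
    if kind == "ch1":
        return _place_sp3_one(p, ref_positions, bond)
    if kind == "ch2":
        return _place_sp3_two(p, ref_positions, bond)
    if kind == "ar":
        return _place_sp2_one(p, ref_positions, bond)
    if kind == "me3":
        return _place_methyl(p, ref_positions[0], ref_positions[1], bond)
    if kind == "am2":
        return _place_amide_two(p, ref_positions[0], ref_positions[1], bond)
    raise ValueError(f"unknown placement kind {kind}")


def place_hydrogens(model: StructureModel, mode: str = "keep_existing") -> StructureModel:
    """Add riding hydrogens at ideal geometry (C-H 1.09 A, N-H 1.01 A).

    ``keep_existing`` skips parents that already carry their hydrogen count;
    ``rebuild_all`` removes existing H/D first and replaces them. Placed atoms
    are flagged ``source='placed'``. Residues with unknown topology are left
    untouched (logged). The model is modified in place and returned.
    """
    if mode not in ("keep_existing", "rebuild_all"):
        raise ValueError("mode must be 'keep_existing' or 'rebuild_all'")
    for res in model.residues("polymer"):
        rules = _SIDE_CHAIN_H.get(res.residue_name)
        if rules is None:
            logger.info("no hydrogen topology for %s; left as-is", res.label)
            continue
        if mode == "rebuild_all":
            res.atoms = [a for a in res.atoms if not a.is_hydrogen]
        atoms = res.conformer()
        existing_h = [a for a in res.atoms if a.is_hydrogen and a.altloc in ("", res.preferred_altloc())]

        all_rules = list(rules)
        # Backbone amide H (not for PRO or chain-start without preceding C).
        if res.residue_name != "PRO" and res.prev is not None:
            prev_c = res.prev.conformer().get("C")
            if prev_c is not None:
                all_rules.append(("N", ["H"], "ar", ["CA", "__PREV_C"]))
        # Alpha hydrogens.
        if res.residue_name == "GLY":
            all_rules.append(("CA", ["HA2", "HA3"], "ch2", ["N", "C"]))
        else:
            all_rules.append(("CA", ["HA"], "ch1", ["N", "C", "CB"]))

        extra = {}
        if res.prev is not None:
            prev_c = res.prev.conformer().get("C")
            if prev_c is not None:
                extra["__PREV_C"] = prev_c.position

        for parent_name, h_names, kind, refs in all_rules:
            parent = atoms.get(parent_name)
            if parent is None:
                logger.info("missing parent %s in %s; hydrogens skipped", parent_name, res.label)
                continue
            if mode == "keep_existing":
                n_existing = _existing_h_count(atoms, parent, existing_h)
                if n_existing >= len(h_names):
                    continue
            positions = _place_for_rule(atoms, parent_name, h_names, kind, refs, extra)
            if positions is None:
                logger.info("missing reference atoms for %s H in %s", parent_name, res.label)
                continue
            for name, pos in zip(h_names, positions):
                if mode == "keep_existing" and res.get(name) is not None:
                    continue
                res.add_atom(_make_h(parent, name, pos))
    return model


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _acceptor_class(res: ResidueView, atom: AtomRecord) -> str:
    if res.category == "solvent":
        return "water"
    if res.category == "ligand":
        return "ligand_O"
    return "main_chain_carbonyl" if atom.atom_name in ("O", "OXT") else "side_chain_O"


def find_hbonds(
    model: StructureModel, criteria: HBondCriteria = HBondCriteria()
) -> list[HydrogenBond]:
    """All D-H...O contacts (D in {N, C}) satisfying the criteria.

    Hydrogens must be present (observed or placed) — raises otherwise.
    Same-residue contacts and the trivial backbone N-H(i)...O(i-1)
    through-bond contact are excluded. Output order is deterministic.
    """
    donors: list[tuple[AtomRecord, AtomRecord, ResidueView]] = []  # (H, parent, residue)
    acceptors: list[tuple[AtomRecord, ResidueView]] = []
    any_h = False
    for res in model.residues():
        conformer = res.conformer()
        heavy = [a for a in conformer.values() if not a.is_hydrogen]
        for atom in conformer.values():
            if atom.is_hydrogen:
                any_h = True
                parent = None
                best = _H_PARENT_CUTOFF
                for h_parent in heavy:
                    d = float(np.linalg.norm(atom.position - h_parent.position))
                    if d < best:
                        best = d
                        parent = h_parent
                if parent is not None and parent.element.upper() in ("N", "C"):
                    donors.append((atom, parent, res))
            elif atom.element.upper() == "O":
                acceptors.append((atom, res))

    if not any_h:
        raise ValueError(
            "no hydrogen atoms in model; run place_hydrogens() before find_hbonds()"
        )
    if not donors or not acceptors:
        return []

    acceptor_coords = np.array([a.position for a, _ in acceptors])
    tree = cKDTree(acceptor_coords)
    max_ha = max(criteria.ch_max_ha, criteria.nh_max_ha)

    bonds: list[HydrogenBond] = []
    for h_atom, donor, donor_res in donors:
        is_nh = donor.element.upper() == "N"
        lim_ha = criteria.nh_max_ha if is_nh else criteria.ch_max_ha
        lim_da = criteria.nh_max_da if is_nh else criteria.ch_max_da
        lim_angle = criteria.nh_min_angle if is_nh else criteria.ch_min_angle
        for idx in tree.query_ball_point(h_atom.position, max_ha):
            acceptor, acceptor_res = acceptors[idx]
            if acceptor_res is donor_res:
                continue
            # Skip the through-bond backbone contact N-H(i)...O(i-1).
            if (
                donor.atom_name == "N"
                and acceptor.atom_name == "O"
                and donor_res.prev is acceptor_res
            ):
                continue
            d_ha = float(np.linalg.norm(h_atom.position - acceptor.position))
            if d_ha > lim_ha:
                continue
            d_da = float(np.linalg.norm(donor.position - acceptor.position))
            if d_da > lim_da or d_ha > d_da:
                continue
            theta = angle(donor.position, h_atom.position, acceptor.position)
            if theta < lim_angle:
                continue
            bonds.append(
                HydrogenBond(
                    donor=donor,
                    hydrogen=h_atom,
                    acceptor=acceptor,
                    donor_residue=donor_res,
                    acceptor_residue=acceptor_res,
                    d_ha=d_ha,
                    d_da=d_da,
                    theta_dha=theta,
                    donor_class="main_chain" if donor.atom_name in MAIN_CHAIN_ATOMS else "side_chain",
                    acceptor_class=_acceptor_class(acceptor_res, acceptor),
                    bond_type="NH_O" if is_nh else "CH_O",
                    hydrogen_placed=h_atom.source == "placed",
                )
            )
    bonds.sort(key=lambda b: (b.key, b.d_ha))
    return bonds


# ---------------------------------------------------------------------------
# Secondary structure and motifs
# ---------------------------------------------------------------------------

@dataclass
class SSAssignment:
    """Per-residue secondary-structure label: H, E, T or C."""

    labels: dict[tuple[str, int, str], str] = field(default_factory=dict)

    def label(self, res: ResidueView) -> str:
        return self.labels.get((res.chain_id, res.residue_number, res.insertion_code), "C")

    def set(self, res: ResidueView, label: str) -> None:
        self.labels[(res.chain_id, res.residue_number, res.insertion_code)] = label


def _backbone_nho(bonds: list[HydrogenBond]) -> set[tuple]:
    """(donor chain, donor key, acceptor chain, acceptor key) for backbone
    N-H...O=C bonds."""
    out = set()
    for b in bonds:
        if (
            b.bond_type == "NH_O"
            and b.donor.atom_name == "N"
            and b.acceptor.atom_name in ("O", "OXT")
            and b.donor_residue.category == "polymer"
            and b.acceptor_residue.category == "polymer"
        ):
            out.add((_res_key(b.donor_residue), _res_key(b.acceptor_residue)))
    return out


def _res_key(res: ResidueView) -> tuple:
    return (res.chain_id, res.residue_number, res.insertion_code)


def assign_secondary_structure(
    model: StructureModel,
    bonds: Optional[list[HydrogenBond]] = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> SSAssignment:
    """Assign H/E/T/C from backbone N-H...O=C bond patterns.

    Helix: two consecutive i->i+4 bonds mark residues i+1..i+4+1 as H.
    Strand: residues in ladders of inter-strand bridges (DSSP-style pairing
    of |i-j| >= 3 bonds) become E. Turn: an i->i+3 bond outside helix/strand
    marks i+1 and i+2 as T. Everything else is C.
    """
    if bonds is None:
        place_hydrogens(model, mode="keep_existing")
        bonds = find_hbonds(model, criteria)
    nho = _backbone_nho(bonds)

    ss = SSAssignment()
    chains = model.polymer_chains()
    index: dict[tuple, tuple[str, int]] = {}
    for chain_id, residues in chains.items():
        for pos, res in enumerate(residues):
            index[_res_key(res)] = (chain_id, pos)
            ss.set(res, "C")

    def has_bond(chain_id: str, i: int, j: int) -> bool:
        residues = chains[chain_id]
        if not (0 <= i < len(residues) and 0 <= j < len(residues)):
            return False
        return (_res_key(residues[i]), _res_key(residues[j])) in nho

    # Helices.
    helix: dict[str, set[int]] = {c: set() for c in chains}
    for chain_id, residues in chains.items():
        for i in range(len(residues)):
            if has_bond(chain_id, i + 4, i) and has_bond(chain_id, i + 5, i + 1):
                helix[chain_id].update(range(i + 1, min(i + 6, len(residues))))
    for chain_id, positions in helix.items():
        for pos in positions:
            ss.set(chains[chain_id][pos], "H")

    # Strand bridges: same- or cross-chain N-H...O pairs far apart in sequence.
    bridges: dict[tuple, set[tuple]] = {}
    keys_by_pos = {(c, p): _res_key(r) for c, residues in chains.items() for p, r in enumerate(residues)}

    def bonded(a: tuple, b: tuple) -> bool:
        ka, kb = keys_by_pos.get(a), keys_by_pos.get(b)
        return ka is not None and kb is not None and (ka, kb) in nho

    positions = list(keys_by_pos)
    for a in positions:
        for b in positions:
            if a >= b:
                continue
            if a[0] == b[0] and abs(a[1] - b[1]) < 3:
                continue
            antiparallel = (bonded(a, b) and bonded(b, a)) or (
                bonded((b[0], b[1] + 1), (a[0], a[1] - 1)) and bonded((a[0], a[1] + 1), (b[0], b[1] - 1))
            )
            parallel = (
                bonded(b, (a[0], a[1] - 1)) and bonded((a[0], a[1] + 1), b)
            ) or (
                bonded(a, (b[0], b[1] - 1)) and bonded((b[0], b[1] + 1), a)
            )
            if antiparallel or parallel:
                bridges.setdefault(a, set()).add(b)
                bridges.setdefault(b, set()).add(a)

    # Ladder: a bridge with a neighboring bridge on adjacent residues.
    strand_positions = set()
    for a, partners in bridges.items():
        for b in partners:
            for da in (-1, 1):
                neighbor_a = (a[0], a[1] + da)
                for db in (-1, 1):
                    neighbor_b = (b[0], b[1] + db)
                    if neighbor_b in bridges.get(neighbor_a, set()):
                        strand_positions.update([a, b, neighbor_a, neighbor_b])
    for chain_id, pos in strand_positions:
        res = chains[chain_id][pos]
        if ss.label(res) != "H":
            ss.set(res, "E")

    # Turns.
    for chain_id, residues in chains.items():
        for i in range(len(residues)):
            if has_bond(chain_id, i + 3, i):
                for pos in (i + 1, i + 2):
                    if pos < len(residues) and ss.label(residues[pos]) == "C":
                        ss.set(residues[pos], "T")
    return ss


def classify_motifs(
    bonds: list[HydrogenBond], ss: SSAssignment, model: StructureModel
) -> tuple[list[HydrogenBond], dict[str, int]]:
    """Annotate bonds with capping-motif labels; return the motif summary.

    Motifs (in priority order): ``turn_i_i3_sc_cap`` (carbonyl(i) accepting
    from the side chain of residue i+3 inside a turn that also has the
    backbone i->i+3 bond), ``helix_sc_cap_i3``/``helix_sc_cap_i4``
    (carbonyl(i) in a helix accepting from a side-chain C-H at i+3/i+4),
    ``helix_c_cap`` (same geometry but the donor lies beyond the helix end),
    ``sheet_sc_extension`` (side-chain donor to a strand carbonyl),
    ``sheet_mc_mc`` (backbone-backbone bond between strand residues), else
    ``other``.
    """
    nho = _backbone_nho(bonds)
    chains = model.polymer_chains()
    position: dict[tuple, tuple[str, int]] = {}
    for chain_id, residues in chains.items():
        for pos, res in enumerate(residues):
            position[_res_key(res)] = (chain_id, pos)

    annotated: list[HydrogenBond] = []
    counts: dict[str, int] = {
        "sheet_mc_mc": 0, "sheet_sc_extension": 0, "turn_i_i3_sc_cap": 0,
        "helix_sc_cap_i3": 0, "helix_sc_cap_i4": 0, "helix_c_cap": 0, "other": 0,
    }
    for bond in bonds:
        motif = "other"
        donor_pos = position.get(_res_key(bond.donor_residue))
        acceptor_pos = position.get(_res_key(bond.acceptor_residue))
        donor_label = ss.label(bond.donor_residue)
        acceptor_label = ss.label(bond.acceptor_residue)
        offset = None
        if donor_pos and acceptor_pos and donor_pos[0] == acceptor_pos[0]:
            offset = donor_pos[1] - acceptor_pos[1]

        is_sc_to_carbonyl = (
            bond.donor_class == "side_chain"
            and bond.acceptor_class == "main_chain_carbonyl"
        )
        if (
            is_sc_to_carbonyl
            and bond.bond_type == "CH_O"
            and offset == 3
            and (_res_key(bond.donor_residue), _res_key(bond.acceptor_residue)) in nho
            and acceptor_label not in ("H",)
        ):
            motif = "turn_i_i3_sc_cap"
        elif (
            is_sc_to_carbonyl
            and bond.bond_type == "CH_O"
            and offset in (3, 4)
            and acceptor_label == "H"
        ):
            if donor_label == "H":
                motif = f"helix_sc_cap_i{offset}"
            else:
                motif = "helix_c_cap"
        elif is_sc_to_carbonyl and acceptor_label == "E":
            motif = "sheet_sc_extension"
        elif (
            bond.donor_class == "side_chain"
            and bond.bond_type == "NH_O"
            and bond.acceptor_class == "main_chain_carbonyl"
            and acceptor_label == "E"
        ):
            motif = "sheet_sc_extension"
        elif (
            bond.donor_class == "main_chain"
            and bond.acceptor_class == "main_chain_carbonyl"
            and donor_label == "E"
            and acceptor_label == "E"
        ):
            motif = "sheet_mc_mc"
        counts[motif] += 1
        annotated.append(replace(bond, motif=motif))
    return annotated, counts


def hbond_table(bonds: list[HydrogenBond], entry_id: str = "") -> pd.DataFrame:
    """Flat, deterministically ordered bond report."""
    rows = [
        {
            "entry": entry_id,
            "donor_chain": b.donor.chain_id,
            "donor_resnum": b.donor.residue_number,
            "donor_resname": b.donor.residue_name,
            "donor_atom": b.donor.atom_name,
            "hydrogen": b.hydrogen.atom_name,
            "hydrogen_source": b.hydrogen.source,
            "acceptor_chain": b.acceptor.chain_id,
            "acceptor_resnum": b.acceptor.residue_number,
            "acceptor_resname": b.acceptor.residue_name,
            "acceptor_atom": b.acceptor.atom_name,
            "d_HA": round(b.d_ha, 3),
            "d_DA": round(b.d_da, 3),
            "theta_DHA": round(b.theta_dha, 1),
            "donor_class": b.donor_class,
            "acceptor_class": b.acceptor_class,
            "bond_type": b.bond_type,
            "motif": b.motif,
        }
        for b in bonds
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "entry", "donor_chain", "donor_resnum", "donor_resname", "donor_atom",
            "hydrogen", "hydrogen_source", "acceptor_chain", "acceptor_resnum",
            "acceptor_resname", "acceptor_atom", "d_HA", "d_DA", "theta_DHA",
            "donor_class", "acceptor_class", "bond_type", "motif",
        ],
    )
    return frame.sort_values(
        ["entry", "donor_chain", "donor_resnum", "donor_atom", "acceptor_chain", "acceptor_resnum", "acceptor_atom"],
        kind="stable",
    ).reset_index(drop=True)
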