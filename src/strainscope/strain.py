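"""Residue-type-specific bending angles and peptide-bond omega distortion.

The five metrics quantify deviation from ideal planarity:

* ``arg_twist``  — signed torsion CD-NE-CZ-NH1 of the arginine guanidinium
  (0 deg when planar with NH1 cis to CD).
* ``phe_bend``   — 180 deg minus the angle CB-CG-CZ of phenylalanine
  (0 deg when CB lies on the ring para axis).
* ``trp_bend``   — signed pseudo-torsion CB-CG-CE2-CZ3 of tryptophan.
* ``tyr_bend``   — [180 - angle(CB,CG,CZ)] + [180 - angle(CB,CZ,OH)] of
  tyrosine.
* ``omega_dev``  — deviation of the peptide torsion CA(i)-C(i)-N(i+1)-CA(i+1)
  from its nearest ideal (180 deg trans / 0 deg cis).

Signs are preserved so that concerted, compensating distortions remain
visible. Hydrogens are never used. All measurements are taken on a single
conformer per residue (highest occupancy altloc).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .geometry import angle, dihedral, wrap_angle
from .structure_io import ResidueView, StructureModel

__all__ = [
    "BendMeasurement",
    "OutlierPolicy",
    "arg_twist",
    "phe_bend",
    "trp_bend",
    "tyr_bend",
    "measure_residue",
    "omega_scan",
    "scan_structure",
    "flag_outliers",
    "measurements_table",
]

logger = logging.getLogger(__name__)

#: Metric applicable to each residue type.
METRIC_BY_RESIDUE = {"ARG": "arg_twist", "PHE": "phe_bend", "TRP": "trp_bend", "TYR": "tyr_bend"}


@dataclass(frozen=True)
class BendMeasurement:
    """One geometric-strain measurement on one residue (or peptide bond)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    metric: str  # arg_twist | phe_bend | trp_bend | tyr_bend | omega_dev
    value: float  # signed degrees
    reference: float  # ideal value: 0 for bends, 180/0 for omega trans/cis
    is_outlier: bool = False
    threshold_used: Optional[float] = None
    note: str = ""

    @property
    def residue_label(self) -> str:
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}{self.insertion_code}"


@dataclass(frozen=True)
class OutlierPolicy:
    """Fixed-degree outlier thresholds (documented defaults, configurable).

    The defaults are |arg_twist| >= 6, phe_bend >= 5, |trp_bend| >= 5,
    tyr_bend >= 6 and |omega_dev| >= 10 degrees.
    """

    arg_twist: float = 6.0
    phe_bend: float = 5.0
    trp_bend: float = 5.0
    tyr_bend: float = 6.0
    omega_dev: float = 10.0

    def threshold(self, metric: str) -> float:
        return float(getattr(self, metric))


def _measurement(res: ResidueView, metric: str, value: float, reference: float = 0.0, note: str = "") -> BendMeasurement:
    return BendMeasurement(
        chain_id=res.chain_id,
        residue_number=res.residue_number,
        insertion_code=res.insertion_code,
        residue_name=res.residue_name,
        metric=metric,
        value=value,
        reference=reference,
        note=note,
    )


def _conformer_positions(res: ResidueView, names: Iterable[str], altloc: Optional[str] = None):
    atoms = res.conformer(altloc)
    positions = []
    for name in names:
        atom = atoms.get(name)
        if atom is None:
            return None, name
        positions.append(atom.position)
    return positions, None


def arg_twist(res: ResidueView, altloc: Optional[str] = None) -> Optional[BendMeasurement]:
    """Guanidinium twist: signed torsion CD-NE-CZ-NH1, ideal 0 deg.

    If the raw torsion magnitude exceeds 90 deg the eta-nitrogen names are
    assumed swapped (NH1 <-> NH2) and the torsion to NH2 is reported instead;
    the normalization is recorded in the measurement note.
    """
    if res.residue_name != "ARG":
        raise ValueError(f"arg_twist() requires ARG, got {res.residue_name}")
    positions, missing = _conformer_positions(res, ["CD", "NE", "CZ", "NH1"], altloc)
    if positions is None:
        logger.info("skipping arg_twist for %s: missing atom %s", res.label, missing)
        return None
    value = dihedral(*positions)
    note = ""
    if abs(value) > 90.0:
        alt, missing = _conformer_positions(res, ["CD", "NE", "CZ", "NH2"], altloc)
        if alt is not None:
            value = dihedral(*alt)
            note = "eta-nitrogen names swapped; torsion reported to NH2"
        else:
            value = wrap_angle(value - 180.0)
            note = "eta-nitrogen names swapped; torsion folded about 180"
    return _measurement(res, "arg_twist", value, 0.0, note)


def phe_bend(res: ResidueView, altloc: Optional[str] = None) -> Optional[BendMeasurement]:
    """Phenylalanine bend: 180 deg - angle(CB, CG, CZ), ideal 0 deg."""
    if res.residue_name != "PHE":
        raise ValueError(f"phe_bend() requires PHE, got {res.residue_name}")
    positions, missing = _conformer_positions(res, ["CB", "CG", "CZ"], altloc)
    if positions is None:
        logger.info("skipping phe_bend for %s: missing atom %s", res.label, missing)
        return None
    return _measurement(res, "phe_bend", 180.0 - angle(*positions))


def trp_bend(res: ResidueView, altloc: Optional[str] = None) -> Optional[BendMeasurement]:
    """Tryptophan bend: signed pseudo-torsion CB-CG-CE2-CZ3, ideal 0 deg."""
    if res.residue_name != "TRP":
        raise ValueError(f"trp_bend() requires TRP, got {res.residue_name}")
    positions, missing = _conformer_positions(res, ["CB", "CG", "CE2", "CZ3"], altloc)
    if positions is None:
        logger.info("skipping trp_bend for %s: missing atom %s", res.label, missing)
        return None
    return _measurement(res, "trp_bend", dihedral(*positions))


def tyr_bend(res: ResidueView, altloc: Optional[str] = None) -> Optional[BendMeasurement]:
    """Tyrosine bend: [180 - angle(CB,CG,CZ)] + [180 - angle(CB,CZ,OH)]."""
    if res.residue_name != "TYR":
        raise ValueError(f"tyr_bend() requires TYR, got {res.residue_name}")
    positions, missing = _conformer_positions(res, ["CB", "CG", "CZ", "OH"], altloc)
    if positions is None:
        logger.info("skipping tyr_bend for %s: missing atom %s", res.label, missing)
        return None
    cb, cg, cz, oh = positions
    value = (180.0 - angle(cb, cg, cz)) + (180.0 - angle(cb, cz, oh))
    return _measurement(res, "tyr_bend", value)


_METRIC_FUNCS = {"ARG": arg_twist, "PHE": phe_bend, "TRP": trp_bend, "TYR": tyr_bend}


def measure_residue(res: ResidueView, altloc: Optional[str] = None) -> Optional[BendMeasurement]:
    """Apply the residue-type-specific bending metric, if one exists."""
    func = _METRIC_FUNCS.get(res.residue_name)
    if func is None:
        return None
    return func(res, altloc)


def omega_scan(chain: list[ResidueView]) -> list[BendMeasurement]:
    """Omega deviation for every peptide bond of a linked residue list.

    The measurement is attached to the *second* residue of each bond (the
    conventional owner of omega). Bonds across chain breaks (no polymer link)
    are skipped.
    """
    out: list[BendMeasurement] = []
    for res in chain:
        prev = res.prev
        if prev is None:
            continue
        names_prev = prev.conformer()
        names = res.conformer()
        needed = [names_prev.get("CA"), names_prev.get("C"), names.get("N"), names.get("CA")]
        if any(a is None for a in needed):
            logger.info("skipping omega for bond %s-%s: incomplete backbone", prev.label, res.label)
            continue
        omega = dihedral(*(a.position for a in needed))
        if abs(omega) > 90.0:  # trans
            deviation = wrap_angle(omega - 180.0)
            reference = 180.0
            conf = "trans"
        else:  # cis
            deviation = omega
            reference = 0.0
            conf = "cis"
        out.append(
            _measurement(
                res,
                "omega_dev",
                deviation,
                reference,
                note=f"{conf} peptide bond {prev.residue_number}-{res.residue_number}",
            )
        )
    return out


def scan_structure(model: StructureModel) -> list[BendMeasurement]:
    """All side-chain bending metrics plus the omega scan, per polymer chain."""
    out: list[BendMeasurement] = []
    for residues in model.polymer_chains().values():
        for res in residues:
            m = measure_residue(res)
            if m is not None:
                out.append(m)
        out.extend(omega_scan(residues))
    return out


def flag_outliers(
    measurements: list[BendMeasurement], policy: OutlierPolicy = OutlierPolicy()
) -> tuple[list[BendMeasurement], dict[str, int]]:
    """Annotate measurements with the outlier policy; return summary counts."""
    annotated: list[BendMeasurement] = []
    counts: dict[str, int] = {}
    for m in measurements:
        threshold = policy.threshold(m.metric)
        is_outlier = abs(m.value) >= threshold
        annotated.append(replace(m, is_outlier=is_outlier, threshold_used=threshold))
        if is_outlier:
            counts[m.metric] = counts.get(m.metric, 0) + 1
    return annotated, counts


def measurements_table(measurements: list[BendMeasurement], entry_id: str = "") -> pd.DataFrame:
    """Flat table of measurements, sorted for deterministic reports."""
    rows = [
        {
            "entry": entry_id,
            "chain": m.chain_id,
            "resnum": m.residue_number,
            "icode": m.insertion_code,
            "resname": m.residue_name,
            "metric": m.metric,
            "value_deg": round(m.value, 3),
            "reference_deg": m.reference,
            "outlier": m.is_outlier,
            "threshold_deg": m.threshold_used,
            "note": m.note,
        }
        for m in measurements
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "entry", "chain", "resnum", "icode", "resname", "metric",
            "value_deg", "reference_deg", "outlier", "threshold_deg", "note",
        ],
    )
    return frame.sort_values(["entry", "chain", "resnum", "metric"], kind="stable").reset_index(drop=True)
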