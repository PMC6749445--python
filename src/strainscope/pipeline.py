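"""Report orchestration: run every analysis stage on one or more structures
and aggregate a cross-structure outlier summary.

All reports are deterministic: fixed sort orders, no timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import adp, hbonds, strain
from .config import AnalysisConfig
from .structure_io import StructureModel, read_structure

__all__ = ["AnalysisResult", "analyze_structure", "run_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """All per-structure outputs of one pipeline run."""

    entry_id: str
    strain_table: pd.DataFrame
    hbond_table: pd.DataFrame
    motif_counts: dict
    adp_summary: dict
    outlier_rows: pd.DataFrame
    altloc_choices: dict = field(default_factory=dict)


def _adp_summary(model: StructureModel, config: AnalysisConfig) -> dict:
    summary: dict = {"anisotropy": {}, "b_factor": {}}
    for group in ("polymer", "ligand", "solvent"):
        stats = adp.group_anisotropy(model, group, exclude_hydrogen=config.exclude_hydrogen)
        if stats is not None:
            summary["anisotropy"][group] = {
                "mean": round(stats.mean, 4),
                "sd": round(stats.sd, 4),
                "n": stats.n,
                "n_invalid": stats.n_invalid,
                "n_hydrogen_excluded": stats.n_hydrogen_excluded,
            }
        b_stats = adp.group_b_factor(model, group, exclude_hydrogen=config.exclude_hydrogen)
        if b_stats is not None:
            summary["b_factor"][group] = {
                "mean": round(b_stats.mean, 3),
                "sd": round(b_stats.sd, 3),
                "n": b_stats.n,
            }
    return summary


def analyze_structure(model: StructureModel, config: AnalysisConfig = AnalysisConfig()) -> AnalysisResult:
    """Run strain, omega, H-bond and ADP analyses on a parsed model."""
    measurements = strain.scan_structure(model)
    measurements, _ = strain.flag_outliers(measurements, config.outlier_policy())
    strain_table = strain.measurements_table(measurements, model.entry_id)

    hbonds.place_hydrogens(model, mode=config.hydrogen_mode)
    bonds = hbonds.find_hbonds(model, config.hbond_criteria())
    ss = hbonds.assign_secondary_structure(model, bonds=bonds)
    bonds, motif_counts = hbonds.classify_motifs(bonds, ss, model)
    bond_table = hbonds.hbond_table(bonds, model.entry_id)

    outliers = strain_table[strain_table["outlier"]].copy()
    outliers = outliers.reindex(
        outliers["value_deg"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)

    altloc_choices = {
        res.label: res.preferred_altloc()
        for res in model.residues("polymer")
        if res.altlocs()
    }

    return AnalysisResult(
        entry_id=model.entry_id,
        strain_table=strain_table,
        hbond_table=bond_table,
        motif_counts=motif_counts,
        adp_summary=_adp_summary(model, config),
        outlier_rows=outliers,
        altloc_choices=altloc_choices,
    )


def _write_result(result: AnalysisResult, out_dir: Path) -> None:
    prefix = out_dir / result.entry_id.lower()
    result.strain_table.to_csv(f"{prefix}_strain.tsv", sep="\t", index=False)
    result.hbond_table.to_csv(f"{prefix}_hbonds.tsv", sep="\t", index=False)
    with open(f"{prefix}_motifs.json", "w") as handle:
        json.dump(result.motif_counts, handle, indent=2, sort_keys=True)
        handle.write("\n")
    with open(f"{prefix}_adp.json", "w") as handle:
        json.dump(result.adp_summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    with open(f"{prefix}_altloc_choices.json", "w") as handle:
        json.dump(result.altloc_choices, handle, indent=2, sort_keys=True)
        handle.write("\n")


def run_analysis(inputs, config: AnalysisConfig = AnalysisConfig()) -> tuple[list[AnalysisResult], list[str]]:
    """Analyze a batch of structure files; continue past unreadable inputs.

    Writes per-structure reports plus a cross-structure outlier summary
    (sorted by |value|) into ``config.out_dir``. Returns the results and the
    list of per-file error messages (non-empty means overall failure).
    """
    if not inputs:
        raise ValueError("at least one input structure is required")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    results: list[AnalysisResult] = []
    errors: list[str] = []
    for path in inputs:
        try:
            model = read_structure(path)
            result = analyze_structure(model, config)
        except Exception as exc:
            logger.error("failed to analyze %s: %s", path, exc)
            errors.append(f"{path}: {exc}")
            continue
        results.append(result)
        _write_result(result, out_dir)

    if results:
        summary = pd.concat([r.outlier_rows for r in results], ignore_index=True)
        summary = summary.reindex(
            summary["value_deg"].abs().sort_values(ascending=False, kind="stable").index
        ).reset_index(drop=True)
        summary.to_csv(out_dir / "outlier_summary.tsv", sep="\t", index=False)
    return results, errors
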