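"""Analysis configuration: every threshold used anywhere in the pipeline,
with lossless round-tripping through a plain key=value file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .hbonds import HBondCriteria
from .strain import OutlierPolicy

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """All knobs of the pipeline, with documented defaults."""

    # Outlier thresholds (degrees).
    arg_twist_threshold: float = 6.0
    phe_bend_threshold: float = 5.0
    trp_bend_threshold: float = 5.0
    tyr_bend_threshold: float = 6.0
    omega_dev_threshold: float = 10.0
    # Hydrogen-bond criteria (Angstrom / degrees).
    ch_max_ha: float = 2.8
    ch_max_da: float = 3.8
    ch_min_angle: float = 110.0
    nh_max_ha: float = 2.5
    nh_max_da: float = 3.5
    nh_min_angle: float = 120.0
    # Policies.
    altloc_policy: str = "highest_occupancy"
    hydrogen_mode: str = "keep_existing"  # keep_existing | rebuild_all
    exclude_hydrogen: bool = True  # group statistics
    # Output.
    out_dir: str = "strainscope_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in (
            "arg_twist_threshold", "phe_bend_threshold", "trp_bend_threshold",
            "tyr_bend_threshold", "omega_dev_threshold", "ch_max_ha",
            "ch_max_da", "ch_min_angle", "nh_max_ha", "nh_max_da",
            "nh_min_angle",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def outlier_policy(self) -> OutlierPolicy:
        return OutlierPolicy(
            arg_twist=self.arg_twist_threshold,
            phe_bend=self.phe_bend_threshold,
            trp_bend=self.trp_bend_threshold,
            tyr_bend=self.tyr_bend_threshold,
            omega_dev=self.omega_dev_threshold,
        )

    def hbond_criteria(self) -> HBondCriteria:
        return HBondCriteria(
            ch_max_ha=self.ch_max_ha,
            ch_max_da=self.ch_max_da,
            ch_min_angle=self.ch_min_angle,
            nh_max_ha=self.nh_max_ha,
            nh_max_da=self.nh_max_da,
            nh_min_angle=self.nh_min_angle,
        )

    def save(self, path) -> None:
        lines = [f"{key} = {value}" for key, value in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
            kind = types[key]
            if kind == "float":
                kwargs[key] = float(value)
            elif kind == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            else:
                kwargs[key] = value
        return cls(**kwargs)
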