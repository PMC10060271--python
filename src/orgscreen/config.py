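"""Configuration and plate-map types shared across the pipeline.

Concentrations are stored in molar, times in hours from T0, physical
scale in micrometres per pixel. All randomness flows from integer seeds
held in these objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml


class ValidationError(ValueError):
    """Raised when a config or plate-map field violates its contract."""


WELL_ROLES = ("vehicle", "positive", "treated", "empty")


@dataclass(frozen=True)
class DrugSpec:
    """One drug titration in the simulated panel.

    ``ec50_true`` is the half-maximal-effect concentration (molar) of the
    Hill response E(c) = c^h / (c^h + EC50^h); ``mode`` selects whether
    E(c) scales down the growth rate (cytostatic) or drives the viable
    fraction toward ``1 - max_kill_fraction`` (cytotoxic).
    """

    name: str
    concentrations: tuple[float, ...]
    ec50_true: float
    hill_true: float = 1.0
    max_kill_fraction: float = 1.0
    mode: str = "cytotoxic"

    def __post_init__(self) -> None:
        if not self.concentrations or any(c <= 0 for c in self.concentrations):
            raise ValidationError("concentrations: must be non-empty and > 0")
        if self.ec50_true <= 0:
            raise ValidationError("ec50_true: must be > 0")
        if self.hill_true <= 0:
            raise ValidationError("hill_true: must be > 0")
        if not 0.0 <= self.max_kill_fraction <= 1.0:
            raise ValidationError("max_kill_fraction: must lie in [0, 1]")
        if self.mode not in ("cytostatic", "cytotoxic"):
            raise ValidationError("mode: must be 'cytostatic' or 'cytotoxic'")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic plate generator.

    Defaults emulate a down-scaled whole-well field: a 256 px square at
    4 µm/px (~1 mm of a 384-well), ~15 organoids per field, area doubling
    every 24 h, frames every 6 h over 48 h.
    """

    plate_format: int = 384
    image_size_px: tuple[int, int] = (256, 256)
    um_per_px: float = 4.0
    n_timepoints: int = 9
    dt_h: float = 6.0
    seed: int = 0
    seeding_density: int = 15
    morphology_mix: float = 0.5  # fraction of solid (vs cystic) organoids
    growth_rate_h: float = 0.028881  # ln(2)/24 h: area doubles per day
    density_slowdown_threshold: int = 25
    density_slowdown_factor: float = 0.5
    # Fractional-kill kinetics: a cytotoxic dose can kill at most the
    # fraction max_kill_fraction * E(c) of each organoid (the floor of its
    # alive fraction); the floor is approached at rate kill_rate_h * E(c).
    kill_rate_h: float = 0.15
    # Positive (maximal-kill) control acts at E = 1 with this rate, so the
    # well reaches alive_fraction ~= 0 by the final frame.
    control_kill_rate_h: float = 0.15
    drug_panel: tuple[DrugSpec, ...] = ()
    bubble_rate: float = 0.3  # expected air bubbles per well
    debris_rate: float = 2.0  # expected debris specks per well
    read_noise_sd: float = 0.02
    illumination_gradient: float = 0.08
    init_area_um2: float = 3000.0  # median initial organoid area
    init_area_cv: float = 0.35

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise ValidationError("dt_h: must be > 0")
        if self.n_timepoints < 2:
            raise ValidationError("n_timepoints: must be >= 2")
        if self.um_per_px <= 0:
            raise ValidationError("um_per_px: must be > 0")
        if not 0.0 <= self.morphology_mix <= 1.0:
            raise ValidationError("morphology_mix: must lie in [0, 1]")
        if self.seeding_density < 0:
            raise ValidationError("seeding_density: must be >= 0")
        if len(self.image_size_px) != 2 or any(s < 16 for s in self.image_size_px):
            raise ValidationError("image_size_px: must be a pair of ints >= 16")
        if not 0.0 < self.density_slowdown_factor <= 1.0:
            raise ValidationError("density_slowdown_factor: must lie in (0, 1]")
        if self.growth_rate_h < 0:
            raise ValidationError("growth_rate_h: must be >= 0")

    @property
    def times_h(self) -> list[float]:
        return [i * self.dt_h for i in range(self.n_timepoints)]

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if hasattr(v, "item"):  # numpy scalar -> python scalar
                return v.item()
            return v

        d = asdict(self)
        d["drug_panel"] = [asdict(s) for s in self.drug_panel]
        return plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        panel = tuple(
            DrugSpec(**{**s, "concentrations": tuple(s["concentrations"])})
            for s in d.pop("drug_panel", [])
        )
        d["image_size_px"] = tuple(d["image_size_px"])
        return cls(drug_panel=panel, **d)


def _well_ids(plate_format: int) -> list[str]:
    layouts = {6: (2, 3), 12: (3, 4), 24: (4, 6), 48: (6, 8), 96: (8, 12), 384: (16, 24)}
    if plate_format not in layouts:
        raise ValidationError(f"plate_format: unsupported format {plate_format}")
    nrow, ncol = layouts[plate_format]
    rows = [chr(ord("A") + i) for i in range(nrow)]
    return [f"{r}{c:02d}" for r in rows for c in range(1, ncol + 1)]


@dataclass
class PlateMap:
    """Assignment of each well to a role, drug and concentration.

    Backed by a DataFrame with columns well_id, role, drug, concentration
    (molar; NaN for controls) and replicate (replicate-group index).
    """

    table: pd.DataFrame

    REQUIRED = ("well_id", "role", "drug", "concentration", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"plate map missing columns: {missing}")
        ids = self.table["well_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"well_id: duplicate well {dup!r}")
        bad_role = ~self.table["role"].isin(WELL_ROLES)
        if bad_role.any():
            raise ValidationError(
                f"role: invalid role {self.table.loc[bad_role, 'role'].iloc[0]!r}"
            )
        treated = self.table[self.table["role"] == "treated"]
        if treated["drug"].isna().any() or (treated["concentration"] <= 0).any() or treated[
            "concentration"
        ].isna().any():
            raise ValidationError("treated wells require a drug and a concentration > 0")

    def validate_for_format(self, plate_format: int) -> None:
        valid = set(_well_ids(plate_format))
        unknown = [w for w in self.table["well_id"] if w not in valid]
        if unknown:
            raise ValidationError(
                f"well_id: {unknown[0]!r} not valid for a {plate_format}-well plate"
            )

    @property
    def wells(self) -> list[str]:
        return list(self.table["well_id"])

    def rows(self) -> Iterable[pd.Series]:
        return (row for _, row in self.table.iterrows())

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "PlateMap":
        df = pd.DataFrame.from_records(records)
        for col in cls.REQUIRED:
            if col not in df.columns:
                df[col] = pd.NA
        df["concentration"] = pd.to_numeric(df["concentration"], errors="coerce")
        df["replicate"] = df["replicate"].fillna(0).astype(int)
        return cls(df[list(cls.REQUIRED)])

    @classmethod
    def read_csv(cls, path: str | Path) -> "PlateMap":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - message plumbing
            raise ValidationError(f"plate map {path}: parse error: {exc}") from exc
        return cls.from_records(df.to_dict("records"))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def make_plate_map(
    n_vehicle: int,
    n_positive: int,
    drug_panel: Sequence[DrugSpec],
    replicates: int = 1,
    plate_format: int = 384,
) -> PlateMap:
    """Lay out controls and drug titrations onto consecutive wells."""
    ids = iter(_well_ids(plate_format))
    recs: list[dict] = []
    for i in range(n_vehicle):
        recs.append(
            {"well_id": next(ids), "role": "vehicle", "drug": None, "concentration": None,
             "replicate": i}
        )
    for i in range(n_positive):
        recs.append(
            {"well_id": next(ids), "role": "positive", "drug": None, "concentration": None,
             "replicate": i}
        )
    for spec in drug_panel:
        for rep in range(replicates):
            for conc in spec.concentrations:
                recs.append(
                    {"well_id": next(ids), "role": "treated", "drug": spec.name,
                     "concentration": conc, "replicate": rep}
                )
    return PlateMap.from_records(recs)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (mirrors the CLI flags)."""

    output_dir: str
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    plate_map_path: str | None = None
    images_dir: str | None = None
    backend: str = "classical"  # classical | fcn
    metric: str = "viable_area_um2"
    endpoint_time_h: float | None = None
    seed: int = 0
    log_level: str = "INFO"
    segmentation_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend not in ("classical", "fcn"):
            raise ValidationError("backend: must be 'classical' or 'fcn'")

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "output_dir": self.output_dir,
            "simulation": self.simulation.to_dict(),
            "plate_map_path": self.plate_map_path,
            "images_dir": self.images_dir,
            "backend": self.backend,
            "metric": self.metric,
            "endpoint_time_h": self.endpoint_time_h,
            "seed": self.seed,
            "log_level": self.log_level,
            "segmentation_params": self.segmentation_params,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ValidationError(f"config {path}: parse error: {exc}") from exc
        sim = SimulationConfig.from_dict(d.pop("simulation", {}))
        return cls(simulation=sim, **d)
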