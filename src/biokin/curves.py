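"""Domain types and file I/O for time-activity data, species profiles and scaling config.

Time-activity curves carry organ uptake as percent of injected activity
(``pct_ia``) or blood concentration as percent of injected activity per mL
(``pct_ia_per_ml``).  Measurements without a stated uncertainty receive a
10% relative sigma, the systematic activity-quantification error assumed
throughout the analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TimeActivitySample",
    "TimeActivityCurve",
    "SpeciesProfile",
    "ScalingSpec",
    "CurveInputError",
    "read_curves",
    "write_curves",
    "read_species_profiles",
    "read_scaling_spec",
    "write_report",
    "UNIT_ORGAN",
    "UNIT_BLOOD",
    "DEFAULT_SIGMA_CV",
]

#: canonical unit labels
UNIT_ORGAN = "pct_ia"
UNIT_BLOOD = "pct_ia_per_ml"

#: relative uncertainty assigned when a sample carries no sigma (10% systematic)
DEFAULT_SIGMA_CV = 0.10

_UNIT_SYNONYMS = {
    "pct_ia": UNIT_ORGAN,
    "%ia": UNIT_ORGAN,
    "%": UNIT_ORGAN,
    "percent_ia": UNIT_ORGAN,
    "pct_ia_per_ml": UNIT_BLOOD,
    "%ia/ml": UNIT_BLOOD,
    "pct_ia/ml": UNIT_BLOOD,
    "percent_ia_per_ml": UNIT_BLOOD,
}

_CURVE_COLUMNS = ["species", "region", "time_h", "value", "unit", "sigma"]


class CurveInputError(ValueError):
    """Raised for malformed or inconsistent curve/profile input."""


@dataclass(frozen=True)
class TimeActivitySample:
    """One uptake measurement: time since administration (h), value, 1-sigma error."""

    t: float
    value: float
    sigma: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise CurveInputError(f"negative time {self.t}")
        if self.value < 0:
            raise CurveInputError(f"negative uptake value {self.value}")
        if self.sigma <= 0:
            raise CurveInputError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled uptake versus time for one (species, region) group."""

    species: str
    region: str
    unit: str
    samples: tuple[TimeActivitySample, ...]

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise CurveInputError(
                f"{self.species}/{self.region}: need >= 2 samples, got {len(self.samples)}"
            )
        times = [s.t for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise CurveInputError(
                f"{self.species}/{self.region}: times must be strictly increasing"
            )

    @property
    def t(self):
        import numpy as np

        return np.array([s.t for s in self.samples])

    @property
    def y(self):
        import numpy as np

        return np.array([s.value for s in self.samples])

    @property
    def sigma(self):
        import numpy as np

        return np.array([s.sigma for s in self.samples])

    @property
    def group(self) -> str:
        return f"{self.species}/{self.region}"


@dataclass(frozen=True)
class SpeciesProfile:
    """Whole-body mass, optional organ masses (kg) and blood volume (mL)."""

    name: str
    m_wb: float
    organ_masses: Mapping[str, float] = field(default_factory=dict)
    blood_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.m_wb <= 0:
            raise CurveInputError(f"{self.name}: whole-body mass must be positive")
        for region, m in self.organ_masses.items():
            if m <= 0:
                raise CurveInputError(f"{self.name}/{region}: organ mass must be positive")
        if self.blood_volume_ml is not None and self.blood_volume_ml <= 0:
            raise CurveInputError(f"{self.name}: blood volume must be positive")

    def organ_mass(self, region: str) -> float | None:
        return self.organ_masses.get(region)


@dataclass(frozen=True)
class ScalingSpec:
    """Configuration of the interspecies extrapolation methods.

    ``time_exponent`` is the exponent of the whole-body mass ratio used for
    time scaling (1/4 by convention).  ``allometric_b`` maps region to the
    allometric exponent b of the TIAC power law; the defaults (liver 0.92,
    kidneys 0.85) follow the published organ-specific exponents.
    ``scale_physical_decay=False`` restricts time scaling to biological
    clearance, leaving radioactive decay untouched.
    """

    method: int | None = None
    time_exponent: float = 0.25
    allometric_b: Mapping[str, float] = field(
        default_factory=lambda: {"liver": 0.92, "kidneys": 0.85}
    )
    scale_physical_decay: bool = False

    def __post_init__(self) -> None:
        if self.time_exponent <= 0:
            raise CurveInputError("time_exponent must be positive")
        for region, b in self.allometric_b.items():
            if not 0 < b <= 1:
                raise CurveInputError(f"allometric exponent for {region} must be in (0, 1]")
        if self.method is not None and self.method not in {1, 2, 3, 4, 5}:
            raise CurveInputError(f"unknown method {self.method}")


def _canonical_unit(unit: str, policy: str) -> str:
    u = str(unit).strip()
    if u in (UNIT_ORGAN, UNIT_BLOOD):
        return u
    if policy == "coerce":
        key = u.lower()
        if key in _UNIT_SYNONYMS:
            return _UNIT_SYNONYMS[key]
    raise CurveInputError(f"unrecognized unit {unit!r} (policy={policy})")


def read_curves(path: str | Path, unit_policy: str = "strict") -> list[TimeActivityCurve]:
    """Read a curves CSV (species,region,time_h,value,unit[,sigma]) into curves.

    Rows are grouped by (species, region) and sorted by time.  A missing
    sigma is filled as 0.10 x value.  Duplicate times within a group,
    negative times or values, and mixed units within a group are rejected.
    """
    if unit_policy not in ("strict", "coerce"):
        raise ValueError(f"unit_policy must be 'strict' or 'coerce', got {unit_policy!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"species", "region", "time_h", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise CurveInputError(f"missing columns: {sorted(missing)}")
    if "sigma" not in df.columns:
        df["sigma"] = float("nan")

    curves: list[TimeActivityCurve] = []
    for (species, region), grp in df.groupby(["species", "region"], sort=True):
        grp = grp.sort_values("time_h")
        if grp["time_h"].duplicated().any():
            raise CurveInputError(
                f"duplicate time points in group {species}/{region}"
            )
        units = {_canonical_unit(u, unit_policy) for u in grp["unit"]}
        if len(units) != 1:
            raise CurveInputError(f"mixed units in group {species}/{region}: {sorted(units)}")
        samples = []
        for row in grp.itertuples():
            sigma = row.sigma
            if pd.isna(sigma):
                sigma = DEFAULT_SIGMA_CV * row.value
            samples.append(TimeActivitySample(t=float(row.time_h), value=float(row.value), sigma=float(sigma)))
        curves.append(
            TimeActivityCurve(
                species=str(species), region=str(region), unit=units.pop(), samples=tuple(samples)
            )
        )
    return curves


def write_curves(curves: Iterable[TimeActivityCurve], path: str | Path) -> None:
    """Write curves to the canonical CSV dialect (comma, dot decimal, header, UTF-8).

    Numbers are serialized with ``repr`` so a write/read round trip is
    bit-identical.
    """
    rows = []
    for c in curves:
        for s in c.samples:
            rows.append(
                {
                    "species": c.species,
                    "region": c.region,
                    "time_h": repr(float(s.t)),
                    "value": repr(float(s.value)),
                    "unit": c.unit,
                    "sigma": repr(float(s.sigma)),
                }
            )
    pd.DataFrame(rows, columns=_CURVE_COLUMNS).to_csv(path, index=False, encoding="utf-8")


def read_species_profiles(path: str | Path) -> dict[str, SpeciesProfile]:
    """Read a profiles JSON: {name: {m_wb, organ_masses: {region: kg}, blood_volume_ml}}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    profiles: dict[str, SpeciesProfile] = {}
    for name, entry in raw.items():
        if name.startswith("_"):
            continue
        if not isinstance(entry, dict) or "m_wb" not in entry:
            raise CurveInputError(f"profile {name!r}: m_wb is required")
        profiles[name] = SpeciesProfile(
            name=name,
            m_wb=float(entry["m_wb"]),
            organ_masses={k: float(v) for k, v in entry.get("organ_masses", {}).items()},
            blood_volume_ml=(
                float(entry["blood_volume_ml"]) if entry.get("blood_volume_ml") is not None else None
            ),
        )
    return profiles


def default_profiles() -> dict[str, SpeciesProfile]:
    """Profiles shipped with the package (cohort-mean body masses; organ
    masses are literature assumptions, see data/default_profiles.json)."""
    from importlib.resources import files

    path = files("biokin.data").joinpath("default_profiles.json")
    with path.open(encoding="utf-8") as fh:
        raw = json.load(fh)
    return {
        name: SpeciesProfile(
            name=name,
            m_wb=float(entry["m_wb"]),
            organ_masses={k: float(v) for k, v in entry.get("organ_masses", {}).items()},
            blood_volume_ml=(
                float(entry["blood_volume_ml"]) if entry.get("blood_volume_ml") is not None else None
            ),
        )
        for name, entry in raw.items()
        if not name.startswith("_")
    }


def read_scaling_spec(path: str | Path) -> ScalingSpec:
    """Read a scaling JSON: {method, time_exponent, allometric_b, scale_physical_decay}."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    kwargs = {}
    if "method" in raw:
        kwargs["method"] = int(raw["method"])
    if "time_exponent" in raw:
        kwargs["time_exponent"] = float(raw["time_exponent"])
    if "allometric_b" in raw:
        kwargs["allometric_b"] = {k: float(v) for k, v in raw["allometric_b"].items()}
    if "scale_physical_decay" in raw:
        kwargs["scale_physical_decay"] = bool(raw["scale_physical_decay"])
    return ScalingSpec(**kwargs)


def write_report(report, path: str | Path, format: str = "csv") -> None:
    """Serialize a ComparisonReport as CSV or JSON with deterministic column order.

    Full-precision numbers are kept alongside a display-rounding field so
    the file can both be re-read losslessly and quoted at table precision.
    """
    df = report.to_frame()
    path = Path(path)
    if format == "csv":
        out = df.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].map(lambda v: repr(float(v)))
        out.to_csv(path, index=False, encoding="utf-8")
    elif format == "json":
        records = df.to_dict(orient="records")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
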