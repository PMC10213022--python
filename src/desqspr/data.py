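"""Solubility datasets: schema, catalog, readers/writers, synthetic generator.

The experimental record is one (donor, T, P, x, ratio) observation of CO2
solubility in a choline-chloride deep eutectic solvent.  The packaged
catalog transcribes the twelve published dataset summaries (temperature
window, molar ratio, donors, pressure/solubility ranges, point counts);
the per-point data themselves are not redistributable, so the synthetic
generator emulates them from the ln-linear law

    ln(x) = a*ln(P) + b*T + c*D + d + eps,   eps ~ Normal(0, sigma^2)

over donor/temperature/pressure grids, which is exactly the structure the
published three-variable models assume.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, SupplementaryMissingError

#: Physically plausible temperature window for a liquid DES record (K).
T_BOUNDS_K = (250.0, 400.0)

COLUMNS = ("hbd", "T_K", "P_bar", "x", "ratio")


@dataclass(frozen=True)
class SolubilityRecord:
    """One observed CO2 solubility point: x in mol CO2 / mol DES."""

    hbd: str
    T_K: float
    P_bar: float
    x: float
    ratio: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.P_bar > 0:
            raise DataValidationError(f"P must be positive, got {self.P_bar} ({self.hbd})")
        if not self.x > 0:
            raise DataValidationError(f"x must be positive, got {self.x} ({self.hbd})")
        if not T_BOUNDS_K[0] <= self.T_K <= T_BOUNDS_K[1]:
            raise DataValidationError(
                f"T={self.T_K} K outside plausible range {T_BOUNDS_K} ({self.hbd})"
            )


@dataclass
class Dataset:
    """A list of solubility records, optionally tied to a catalog entry."""

    records: list[SolubilityRecord]
    id: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def hbds(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.hbd, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"hbd": r.hbd, "T_K": r.T_K, "P_bar": r.P_bar, "x": r.x, "ratio": r.ratio}
                for r in self.records
            ],
            columns=list(COLUMNS),
        )

    def subset(self, hbds: Iterable[str]) -> "Dataset":
        wanted = set(hbds)
        return Dataset([r for r in self.records if r.hbd in wanted], self.id)


@dataclass(frozen=True)
class CatalogEntry:
    """Published summary of one dataset (point counts and variable ranges)."""

    id: int
    ratio: str
    temperatures_K: tuple[float, ...]
    fixed_T_K: float | None
    hbds: tuple[str, ...]
    P_range_bar: tuple[float, float]
    x_range: tuple[float, float]
    n: int
    fixed_T_subsets: tuple[int, ...]
    role: str


def _load_catalog() -> tuple[CatalogEntry, ...]:
    text = resources.files("desqspr").joinpath("data/catalog.json").read_text()
    entries = []
    for item in json.loads(text):
        entries.append(
            CatalogEntry(
                id=item["id"],
                ratio=item["ratio"],
                temperatures_K=tuple(float(t) for t in item["temperatures_K"]),
                fixed_T_K=item["fixed_T_K"],
                hbds=tuple(item["hbds"]),
                P_range_bar=tuple(item["P_range_bar"]),
                x_range=tuple(item["x_range"]),
                n=item["n"],
                fixed_T_subsets=tuple(item["fixed_T_subsets"]),
                role=item["role"],
            )
        )
    return tuple(entries)


_CATALOG = _load_catalog()


def catalog() -> tuple[CatalogEntry, ...]:
    """The twelve packaged dataset summaries."""
    return _CATALOG


def catalog_entry(dataset_id: int) -> CatalogEntry:
    for e in _CATALOG:
        if e.id == dataset_id:
            return e
    raise DataValidationError(f"no catalog entry with id {dataset_id}; ids run 1-12")


def reference_tables() -> dict:
    """Packaged descriptor reference values (with conflict annotations)."""
    text = resources.files("desqspr").joinpath("data/reference_descriptors.json").read_text()
    return json.loads(text)


def reference_eeig02d(calibration_only: bool = False) -> dict[str, float]:
    """Authoritative EEig02d per donor; optionally only the text-consistent
    rows used for convention calibration (conflicted rows excluded)."""
    table = reference_tables()["eeig02d"]
    return {
        name: row["authoritative"]
        for name, row in table.items()
        if row["calibration"] or not calibration_only
    }


def read_solubility_table(path) -> Dataset:
    """Read a delimited solubility table with columns hbd, T_K, P_bar, x, ratio."""
    try:
        # round_trip parsing keeps write->read lossless for every float
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - normalise to our error type
        raise DataValidationError(f"cannot read {path}: {exc}") from exc
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                SolubilityRecord(
                    hbd=str(row["hbd"]),
                    T_K=float(row["T_K"]),
                    P_bar=float(row["P_bar"]),
                    x=float(row["x"]),
                    ratio=str(row["ratio"]),
                    source=str(path),
                )
            )
        except (DataValidationError, ValueError) as exc:
            raise DataValidationError(f"{path} row {idx}: {exc}") from exc
    return Dataset(records)


def write_solubility_table(dataset: Dataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


@dataclass
class ValidationReport:
    dataset_id: int
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_against_catalog(dataset: Dataset, dataset_id: int | None = None) -> ValidationReport:
    """Check a dataset's counts, ranges, temperatures and ratio against the
    published summary.  Violations are reported, not raised."""
    did = dataset_id if dataset_id is not None else dataset.id
    if did is None:
        raise DataValidationError("dataset has no id; pass dataset_id explicitly")
    entry = catalog_entry(did)
    rep = ValidationReport(did)
    if len(dataset) != entry.n:
        rep.violations.append(f"record count {len(dataset)} != published n={entry.n}")
    for r in dataset.records:
        if r.ratio != entry.ratio:
            rep.violations.append(f"ratio {r.ratio!r} != {entry.ratio!r} ({r.hbd})")
        if not entry.P_range_bar[0] <= r.P_bar <= entry.P_range_bar[1]:
            rep.violations.append(
                f"P={r.P_bar} bar outside published range {entry.P_range_bar} ({r.hbd})"
            )
        if not entry.x_range[0] <= r.x <= entry.x_range[1]:
            rep.violations.append(
                f"x={r.x} outside published range {entry.x_range} ({r.hbd})"
            )
        if min(abs(r.T_K - t) for t in entry.temperatures_K) > 0.5:
            rep.violations.append(
                f"T={r.T_K} K not among published temperatures {entry.temperatures_K}"
            )
        if r.hbd not in entry.hbds:
            rep.violations.append(f"donor {r.hbd!r} not in the published set")
    return rep


@dataclass
class SynthSpec:
    """Generating law for synthetic solubility data (seed mandatory).

    Defaults emulate the published unfixed-temperature 1:3 study design:
    the three-variable model coefficients, the nine donors with their
    reference descriptor values, the four temperatures, five pressures
    log-spaced across the published pressure window, and a residual noise
    of sigma = 0.1 on ln(x) (the magnitude of the published regression
    standard error for that model).
    """

    a: float = 1.0372
    b: float = -0.0171
    c: float = 0.3067
    d: float = -1.134
    hbd_descriptors: Mapping[str, float] = field(default_factory=lambda: reference_eeig02d())
    T_grid: tuple[float, ...] = (293.0, 303.0, 313.0, 323.0)
    P_grid: tuple[float, ...] = tuple(np.geomspace(0.515, 5.853, 5).round(3))
    sigma: float = 0.1
    seed: int = 0
    ratio: str = "1:3"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DataValidationError("noise sigma must be >= 0")
        if not self.hbd_descriptors or not self.T_grid or not self.P_grid:
            raise DataValidationError("donor set and grids must be non-empty")
        if self.seed is None:
            raise DataValidationError("a seed is mandatory")


def synth_generate(spec: SynthSpec) -> Dataset:
    """One record per (donor, T, P) grid point, ln-linear law plus noise."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for hbd, D in spec.hbd_descriptors.items():
        for T in spec.T_grid:
            for P in spec.P_grid:
                ln_x = (
                    spec.a * math.log(P) + spec.b * T + spec.c * D + spec.d
                    + (rng.normal(0.0, spec.sigma) if spec.sigma > 0 else 0.0)
                )
                records.append(
                    SolubilityRecord(hbd, T, P, math.exp(ln_x), spec.ratio, "synthetic")
                )
    return Dataset(records)


# --- optional supplementary spreadsheet -----------------------------------

_SHEET_COLUMN_ALIASES = {
    "hbd": ("hbd", "hbd name", "name", "structure", "donor"),
    "T_K": ("t_k", "t", "t (k)", "temperature", "temperature (k)", "temp"),
    "P_bar": ("p_bar", "p", "p (bar)", "pressure", "pressure (bar)"),
    "x": ("x", "x_exp", "solubility", "xco2", "x (exp)", "experimental x"),
    "ratio": ("ratio", "molar ratio", "chcl:hbd"),
}


def _map_columns(columns: Sequence[str]) -> dict[str, str]:
    lowered = {str(c).strip().lower(): c for c in columns}
    mapping = {}
    for target, aliases in _SHEET_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[target] = lowered[alias]
                break
    return mapping


def import_supplementary(path, dataset_ids: Sequence[int] | None = None) -> list[Dataset]:
    """Import per-point data from the optional supporting spreadsheet.

    The sheet layout is mapped tolerantly: each sheet must expose columns
    recognisable as donor, temperature, pressure, solubility and ratio
    (a missing ratio column falls back to a per-sheet constant if the sheet
    name contains one).  The importer reports what it finds; an absent file
    raises a clean "optional input missing" error so pipelines can fall
    back to the synthetic generator.
    """
    p = Path(path)
    if not p.exists():
        raise SupplementaryMissingError(
            f"optional input missing: supplementary spreadsheet not found at {p}"
        )
    sheets = pd.read_excel(p, sheet_name=None)
    datasets = []
    diagnostics = []
    for sheet_name, df in sheets.items():
        mapping = _map_columns(df.columns)
        missing = {"hbd", "T_K", "P_bar", "x"} - set(mapping)
        if missing:
            diagnostics.append(f"sheet {sheet_name!r}: unmappable, missing {sorted(missing)}")
            continue
        records = []
        for idx, row in df.iterrows():
            try:
                ratio = str(row[mapping["ratio"]]) if "ratio" in mapping else _ratio_from_name(sheet_name)
                records.append(
                    SolubilityRecord(
                        hbd=str(row[mapping["hbd"]]),
                        T_K=float(row[mapping["T_K"]]),
                        P_bar=float(row[mapping["P_bar"]]),
                        x=float(row[mapping["x"]]),
                        ratio=ratio,
                        source=f"{p.name}:{sheet_name}",
                    )
                )
            except (DataValidationError, ValueError, TypeError) as exc:
                raise DataValidationError(
                    f"sheet {sheet_name!r} row {idx}: {exc}"
                ) from exc
        ds_id = _dataset_id_from_name(sheet_name)
        datasets.append(Dataset(records, ds_id))
    if not datasets:
        raise DataValidationError(
            "no sheet in the spreadsheet could be mapped; diagnostics: "
            + "; ".join(diagnostics)
        )
    if dataset_ids is not None:
        datasets = [d for d in datasets if d.id in set(dataset_ids)]
    return datasets


def _ratio_from_name(sheet_name: str) -> str:
    for ratio in ("1:3", "1:4"):
        if ratio in sheet_name:
            return ratio
    raise DataValidationError(
        f"sheet {sheet_name!r} has no ratio column and no ratio in its name"
    )


def _dataset_id_from_name(sheet_name: str) -> int | None:
    digits = "".join(ch for ch in sheet_name if ch.isdigit())
    if digits and 1 <= int(digits) <= 12:
        return int(digits)
    return None


def with_id(dataset: Dataset, dataset_id: int) -> Dataset:
    return replace(dataset, id=dataset_id)
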