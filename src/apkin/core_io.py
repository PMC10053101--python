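"""Shared data model, delimited-table I/O and result serialization.

Substrate concentrations are stored internally in micromolar (µM) regardless of
the unit of the input table; reported Michaelis constants are therefore always
in µM.  Activities are specific activities in nmol p-nitrophenol per mg protein
per minute (1 U = 1 nmol/min), unless a series is flagged as percent-of-control
(``is_relative``).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

#: marker used wherever a parameter estimate could not be obtained from a
#: significant fit (never silently absent)
NS = "NS"

# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class ApkinError(Exception):
    """Base class for all package errors."""


class SchemaError(ApkinError):
    """A mandatory column is missing or a table has the wrong shape."""


class ParseError(ApkinError):
    """A cell could not be parsed; the message carries the row number."""


class EmptyInputError(ApkinError):
    """The input table has no data rows."""


class DomainError(ApkinError):
    """An argument is outside the mathematical domain of the operation."""


class DegenerateDataError(ApkinError):
    """Data carry no usable signal for the requested fit."""


class UnderDeterminedError(ApkinError):
    """Fewer informative points than free parameters."""


class FitFailureError(ApkinError):
    """Nonlinear fit did not converge after bounded restarts."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class GridMismatchError(ApkinError):
    """Two kinetic datasets do not share a substrate grid."""

    def __init__(self, message: str, unmatched=()):
        super().__init__(message)
        self.unmatched = tuple(unmatched)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivityMeasurement:
    """One velocity measurement at one substrate level.

    ``substrate_conc`` is in µM; ``activity`` in nmol·mg⁻¹·min⁻¹ and may be any
    real number (activation above a control is legal).
    """

    specimen_id: str
    condition: str
    substrate_conc: float
    activity: float
    replicate: int = 1

    def __post_init__(self):
        if self.substrate_conc < 0:
            raise DomainError(
                f"substrate_conc must be >= 0, got {self.substrate_conc}"
            )
        if self.replicate < 1:
            raise DomainError(f"replicate must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class KineticDataset:
    """Replicate substrate-vs-velocity measurements for one specimen/condition.

    Concentrations are normalized to µM on construction (``mM`` inputs are
    multiplied by 1000); normalization is idempotent because the stored unit is
    rewritten to ``"uM"``.
    """

    measurements: tuple[ActivityMeasurement, ...]
    substrate_unit: str = "uM"

    def __post_init__(self):
        if self.substrate_unit not in ("uM", "mM"):
            raise SchemaError(
                f"substrate_unit must be 'uM' or 'mM', got {self.substrate_unit!r}"
            )
        if self.substrate_unit == "mM":
            scaled = tuple(
                replace(m, substrate_conc=m.substrate_conc * 1000.0)
                for m in self.measurements
            )
            object.__setattr__(self, "measurements", scaled)
            object.__setattr__(self, "substrate_unit", "uM")
        else:
            object.__setattr__(self, "measurements", tuple(self.measurements))

    @property
    def substrate(self) -> np.ndarray:
        """Substrate concentrations in µM, row order preserved."""
        return np.array([m.substrate_conc for m in self.measurements], dtype=float)

    @property
    def velocity(self) -> np.ndarray:
        return np.array([m.activity for m in self.measurements], dtype=float)

    @property
    def n_levels(self) -> int:
        return len(set(self.substrate.tolist()))

    def level_means(self) -> "KineticDataset":
        """Collapse replicates to per-level mean velocities (entry mode used
        when a study fitted replicate means rather than raw replicates)."""
        df = pd.DataFrame({"s": self.substrate, "v": self.velocity})
        g = df.groupby("s", sort=True)["v"].mean().reset_index()
        ms = tuple(
            ActivityMeasurement("mean", "mean", s, v, 1)
            for s, v in zip(g["s"], g["v"])
        )
        return KineticDataset(ms, "uM")

    @staticmethod
    def from_arrays(
        substrate: Sequence[float],
        velocity: Sequence[float],
        unit: str = "uM",
        specimen_id: str = "synthetic",
        condition: str = "",
        replicate: Sequence[int] | None = None,
    ) -> "KineticDataset":
        substrate = np.asarray(substrate, dtype=float)
        velocity = np.asarray(velocity, dtype=float)
        if substrate.shape != velocity.shape:
            raise SchemaError("substrate and velocity must have the same length")
        reps = (
            np.asarray(replicate, dtype=int)
            if replicate is not None
            else np.ones(len(substrate), dtype=int)
        )
        ms = tuple(
            ActivityMeasurement(specimen_id, condition, float(s), float(v), int(r))
            for s, v, r in zip(substrate, velocity, reps)
        )
        return KineticDataset(ms, unit)


@dataclass(frozen=True)
class ThermalSeries:
    """Residual activity versus thermal-treatment temperature (°C).

    The control is the lowest temperature present (22 °C in the assay design).
    ``is_relative`` marks percent-of-control series.
    """

    temperature: tuple[float, ...]
    residual_activity: tuple[float, ...]
    is_relative: bool = False

    def __post_init__(self):
        t = tuple(float(x) for x in self.temperature)
        j = tuple(float(x) for x in self.residual_activity)
        if len(t) != len(j):
            raise SchemaError("temperature and residual_activity length mismatch")
        if len(t) == 0:
            raise EmptyInputError("empty thermal series")
        if min(t) < 0 or max(t) > 100:
            raise DomainError("temperatures must lie within [0, 100] °C")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "residual_activity", j)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.temperature, dtype=float)

    @property
    def j(self) -> np.ndarray:
        return np.asarray(self.residual_activity, dtype=float)

    @property
    def control_temperature(self) -> float:
        return float(min(self.temperature))


@dataclass(frozen=True)
class DoseResponseTable:
    """Enzyme dose (U per mg protein) versus residual specific activity."""

    dose: tuple[float, ...]
    activity: tuple[float, ...]

    def __post_init__(self):
        d = tuple(float(x) for x in self.dose)
        a = tuple(float(x) for x in self.activity)
        if len(d) != len(a):
            raise SchemaError("dose and activity length mismatch")
        if len(d) == 0:
            raise EmptyInputError("empty dose-response table")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "activity", a)

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.dose, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.activity, dtype=float)

    @property
    def n_doses(self) -> int:
        return len(set(self.dose))


@dataclass
class AnalysisResult:
    """Uniform container for a fitted stage.

    ``parameters`` maps a name to ``(estimate, se)``; the estimate slot may hold
    the string ``"NS"`` when a fit was gated non-significant — never a silent
    absence.  ``provenance`` records input digest, seed, entry mode and package
    version so a result file is self-describing.
    """

    stage: str
    parameters: dict
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION


# ---------------------------------------------------------------------------
# table readers
# ---------------------------------------------------------------------------

#: mandatory columns per schema
CSV_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "kinetic": ("specimen_id", "condition", "substrate_conc", "activity", "replicate"),
    "thermal": ("temperature_C", "activity"),
    "dose_response": ("dose_U_per_mg", "activity"),
    "inhibition": ("inhibitor", "conc_mM", "activity", "replicate"),
}

_NUMERIC_COLS = {
    "kinetic": ("substrate_conc", "activity", "replicate"),
    "thermal": ("temperature_C", "activity"),
    "dose_response": ("dose_U_per_mg", "activity"),
    "inhibition": ("conc_mM", "activity", "replicate"),
}


def _read_checked(path, schema: str) -> pd.DataFrame:
    if schema not in CSV_SCHEMAS:
        raise SchemaError(
            f"unknown schema {schema!r}; expected one of {sorted(CSV_SCHEMAS)}"
        )
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing} for schema {schema!r}"
        )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: table has a header but no data rows")
    for col in _NUMERIC_COLS[schema]:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering, the row a user sees
            rows = ", ".join(str(i + 2) for i in bad[:5])
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at file row(s) {rows}"
            )
        if parsed.isna().any():
            rows = ", ".join(str(i + 2) for i in df.index[parsed.isna()][:5])
            raise ParseError(f"{path}: empty cell in column {col!r} at row(s) {rows}")
        df[col] = parsed
    return df


def read_assay_table(path, schema: str, substrate_unit: str = "uM"):
    """Read a CSV assay table into its typed dataset.

    ``schema`` is one of ``kinetic``, ``thermal``, ``dose_response``,
    ``inhibition`` (column contracts in :data:`CSV_SCHEMAS`).  For the kinetic
    schema ``substrate_unit`` declares the unit of ``substrate_conc`` in the
    file; concentrations are normalized to µM in the returned dataset.
    """
    df = _read_checked(path, schema)
    if schema == "kinetic":
        ms = tuple(
            ActivityMeasurement(
                str(r.specimen_id),
                str(r.condition),
                float(r.substrate_conc),
                float(r.activity),
                int(r.replicate),
            )
            for r in df.itertuples()
        )
        return KineticDataset(ms, substrate_unit)
    if schema == "thermal":
        return ThermalSeries(
            tuple(df["temperature_C"]), tuple(df["activity"]), is_relative=False
        )
    if schema == "dose_response":
        return DoseResponseTable(tuple(df["dose_U_per_mg"]), tuple(df["activity"]))
    # inhibition: keep the long table; normalization happens downstream
    return df[list(CSV_SCHEMAS["inhibition"])].copy()


def write_assay_table(dataset, path) -> None:
    """Inverse of :func:`read_assay_table` for the typed datasets."""
    path = Path(path)
    if isinstance(dataset, KineticDataset):
        df = pd.DataFrame(
            {
                "specimen_id": [m.specimen_id for m in dataset.measurements],
                "condition": [m.condition for m in dataset.measurements],
                "substrate_conc": dataset.substrate,
                "activity": dataset.velocity,
                "replicate": [m.replicate for m in dataset.measurements],
            }
        )
    elif isinstance(dataset, ThermalSeries):
        df = pd.DataFrame(
            {"temperature_C": dataset.t, "activity": dataset.j}
        )
    elif isinstance(dataset, DoseResponseTable):
        df = pd.DataFrame({"dose_U_per_mg": dataset.x, "activity": dataset.y})
    elif isinstance(dataset, pd.DataFrame):
        df = dataset
    else:
        raise SchemaError(f"cannot serialize {type(dataset).__name__}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return [_jsonable(v) for v in value.tolist()]
    if isinstance(value, (tuple, list)):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, float) and math.isnan(value):
        return "NaN"
    return value


def result_to_dict(result: AnalysisResult) -> dict:
    return {
        "schema_version": result.schema_version,
        "stage": result.stage,
        "parameters": _jsonable(result.parameters),
        "diagnostics": _jsonable(result.diagnostics),
        "provenance": _jsonable(result.provenance),
    }


def write_result(result: AnalysisResult, path) -> None:
    """Serialize an :class:`AnalysisResult` as key-sorted JSON.

    Serialization is deterministic: two writes of the same result are
    byte-identical, and ``read_result(write_result(x)) == x``.
    """
    payload = json.dumps(result_to_dict(result), sort_keys=True, indent=1)
    Path(path).write_text(payload + "\n")


def read_result(path) -> AnalysisResult:
    raw = json.loads(Path(path).read_text())
    params = {k: tuple(v) if isinstance(v, list) else v
              for k, v in raw["parameters"].items()}
    return AnalysisResult(
        stage=raw["stage"],
        parameters=params,
        diagnostics=raw["diagnostics"],
        provenance=raw["provenance"],
        schema_version=raw["schema_version"],
    )


def digest(*arrays: Iterable) -> str:
    """Short SHA-256 digest of numeric inputs, for provenance records."""
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    return h.hexdigest()[:16]
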