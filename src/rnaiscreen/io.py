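"""Well-level screen tables, screen configuration and plate-layout validation.

The on-disk exchange format is a long-format TSV with one row per well.
Long format is used instead of a plate-matrix layout because replicates and
the dual stimulus arms (elicitor vs. TNF counter-stimulus) do not fit a
single matrix. Well coordinates follow the standard 384-well convention
("A01".."P24"), parsed case-insensitively and stored upper-case zero-padded.

Control wells (non-targeting, pathway-positive, receptor-positive, toxicity)
carry an empty ``gene_id``; they never enter gene-level scoring.
"""

from __future__ import annotations

import hashlib
import math
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class ScreenFormatError(ValueError):
    """A table is structurally malformed (e.g. a required column is missing)."""


class ScreenValidationError(ValueError):
    """A row violates a record invariant (negative readout, bad coordinate...)."""


class InsufficientControlsError(ValueError):
    """A plate lacks the control wells a computation requires."""


class DegenerateControlsError(ValueError):
    """Negative- and positive-control means coincide; NPI is undefined."""


class DegenerateScaleError(ValueError):
    """The robust scale estimate of a plate is zero; z-scores are undefined."""


# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

ROLES = ("sample", "neg_ctrl", "pos_ctrl_pathway", "pos_ctrl_receptor", "tox_ctrl")
STIMULI = ("TriDAP", "TNF", "mock")

#: Column order of the well-level TSV.
WELL_COLUMNS = [
    "screen_id",
    "plate_id",
    "well",
    "replicate",
    "sirna_id",
    "gene_id",
    "role",
    "stimulus",
    "readout_activity",
    "readout_viability",
]

_ROW_LETTERS = string.ascii_uppercase


def plate_shape(plate_format: int) -> tuple[int, int]:
    """Rows x columns of a standard 3:2 microplate (96 -> 8x12, 384 -> 16x24)."""
    rows = int(round(math.sqrt(plate_format / 6))) * 2
    cols = plate_format // rows
    if rows * cols != plate_format:
        raise ValueError(f"not a standard microplate format: {plate_format}")
    return rows, cols


def parse_well(well: str, plate_format: int = 384) -> tuple[int, int]:
    """Parse 'A01' (case-insensitive) into 0-based (row, column).

    Raises :class:`ScreenValidationError` for coordinates outside the plate.
    """
    rows, cols = plate_shape(plate_format)
    w = str(well).strip().upper()
    if len(w) < 2 or w[0] not in _ROW_LETTERS[:rows] or not w[1:].isdigit():
        raise ScreenValidationError(f"malformed well coordinate {well!r}")
    r = _ROW_LETTERS.index(w[0])
    c = int(w[1:]) - 1
    if not (0 <= c < cols):
        raise ScreenValidationError(
            f"well coordinate {well!r} outside {plate_format}-well plate"
        )
    return r, c


def format_well(row: int, col: int) -> str:
    """Inverse of :func:`parse_well`: (0, 0) -> 'A01'."""
    return f"{_ROW_LETTERS[row]}{col + 1:02d}"


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


class Thresholds(BaseModel):
    """All hit-calling and QC cut-offs of the pipeline in one place.

    Stage logic never hard-codes a threshold; every rule reads from here so
    the defaults are visible and overridable in a single document.

    plate_viability_hi/lo
        Bounds on the plate mean of the non-targeting controls' viability
        readout; outside them the whole plate is discarded.
    plate_viability_cv
        Maximum coefficient of variation (SD/mean) of those controls.
    well_viability_frac
        Wells below this fraction of the plate's non-targeting-control mean
        viability are excluded (low transfection efficiency or siRNA
        toxicity).
    validation_sd, thp1_sd, thp1_strong_sd
        SD margins over the non-targeting-control median z-score used by the
        validation-screen, THP1 and THP1 strong-hit rules.
    """

    plate_viability_hi: float = 2.5
    plate_viability_lo: float = 0.2
    plate_viability_cv: float = 0.50
    well_viability_frac: float = 0.40
    validation_sd: float = 2.0
    thp1_sd: float = 1.5
    thp1_strong_sd: float = 3.0

    @field_validator("*")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("thresholds must be strictly positive")
        return v

    @model_validator(mode="after")
    def _ordered(self) -> "Thresholds":
        if not self.plate_viability_lo < self.plate_viability_hi:
            raise ValueError("plate_viability_lo must be < plate_viability_hi")
        return self


class ScreenConfig(BaseModel):
    """Screen design and analysis parameters.

    ``control_layout`` maps control roles to the minimum number of wells
    each plate must carry. ``zscore_scale`` selects the robust scale used in
    plate z-scores: the scaled median absolute deviation of the plate's
    sample wells (default) or the SD of its non-targeting controls.
    ``gene_hit_rule`` selects how a gene-level validation call is derived
    from its siRNAs: the strongest siRNA qualifying, or both.
    """

    plate_format: int = 384
    sirnas_per_gene: int = Field(default=4, ge=1)
    replicates: int = Field(default=4, ge=1)
    control_layout: dict[str, int] = Field(
        default_factory=lambda: {
            "neg_ctrl": 6,
            "pos_ctrl_pathway": 4,
            "pos_ctrl_receptor": 3,
            "tox_ctrl": 3,
        }
    )
    thresholds: Thresholds = Field(default_factory=Thresholds)
    zscore_scale: Literal["sample_mad", "neg_sd"] = "sample_mad"
    gene_hit_rule: Literal["strongest", "both"] = "strongest"
    rng_seed: int = 0

    @field_validator("plate_format")
    @classmethod
    def _known_format(cls, v: int) -> int:
        plate_shape(v)  # raises for non-standard formats
        return v

    @field_validator("control_layout")
    @classmethod
    def _known_roles(cls, v: dict[str, int]) -> dict[str, int]:
        for role in v:
            if role not in ROLES or role == "sample":
                raise ValueError(f"unknown control role {role!r}")
        return v

    def digest(self) -> str:
        """Stable SHA-256 of the configuration, for run manifests."""
        blob = yaml.safe_dump(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path) -> ScreenConfig:
    """Read a :class:`ScreenConfig` from a YAML (or JSON) document."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return ScreenConfig.model_validate(data or {})


def save_config(config: ScreenConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


# --------------------------------------------------------------------------
# Well records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WellRecord:
    """One annotated well: raw reporter and viability/transfection readouts.

    ``readout_activity`` holds the reporter channel (luciferase RLU or
    QUANTI-Blue absorbance); ``readout_viability`` the co-measured viability
    or transfection channel (beta-gal ABS405 or XTT absorbance).
    """

    screen_id: str
    plate_id: str
    well: str
    replicate: int
    sirna_id: str
    gene_id: str
    role: str
    stimulus: str
    readout_activity: float
    readout_viability: float


def wells_from_records(records: list[WellRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=WELL_COLUMNS)


def validate_wells(wells: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Validate and canonicalize a well table in place of row-wise parsing.

    Checks every :class:`WellRecord` invariant; raises
    :class:`ScreenValidationError` naming the first offending row (1-based,
    excluding the header).
    """
    for col in ("readout_activity", "readout_viability"):
        vals = pd.to_numeric(wells[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ScreenValidationError(
                f"row {row}: {col} must be a non-negative number "
                f"(got {wells[col].iloc[row - 1]!r})"
            )
        wells[col] = vals.astype(float)

    repl = pd.to_numeric(wells["replicate"], errors="coerce")
    bad = repl.isna() | (repl < 1) | (repl != repl.round())
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ScreenValidationError(f"row {row}: replicate must be an integer >= 1")
    wells["replicate"] = repl.astype(int)

    for col, allowed in (("role", ROLES), ("stimulus", STIMULI)):
        bad = ~wells[col].isin(allowed)
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ScreenValidationError(
                f"row {row}: {col} {wells[col].iloc[row - 1]!r} not in {allowed}"
            )

    canonical = []
    for i, w in enumerate(wells["well"]):
        try:
            r, c = parse_well(w, config.plate_format)
        except ScreenValidationError as err:
            raise ScreenValidationError(f"row {i + 1}: {err}") from None
        canonical.append(format_well(r, c))
    wells["well"] = canonical

    is_sample = wells["role"] == "sample"
    bad = is_sample & ((wells["gene_id"] == "") | (wells["sirna_id"] == ""))
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ScreenValidationError(
            f"row {row}: sample wells require non-empty gene_id and sirna_id"
        )
    return wells


def read_wells(path: str | Path, config: ScreenConfig) -> pd.DataFrame:
    """Read a long-format well table (TSV) and validate every record.

    Column order in the file is irrelevant; surrounding whitespace in cells
    is stripped. Row order is preserved. Missing columns raise
    :class:`ScreenFormatError`; invariant violations raise
    :class:`ScreenValidationError` citing the row.
    """
    wells = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ScreenFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    wells = wells[WELL_COLUMNS].copy()
    for col in wells.columns:
        wells[col] = wells[col].str.strip()
    return validate_wells(wells, config)


def write_wells(wells: pd.DataFrame, path: str | Path) -> None:
    """Write a well table as UTF-8 TSV ('.' decimal separator, full precision)."""
    wells.to_csv(path, sep="\t", index=False, encoding="utf-8")


# --------------------------------------------------------------------------
# Layout validation
# --------------------------------------------------------------------------


def validate_layout(
    wells: pd.DataFrame, config: ScreenConfig
) -> pd.DataFrame:
    """Per-plate control census.

    Every plate must carry at least the control wells declared in
    ``config.control_layout`` (the assay design places non-targeting,
    pathway-positive, receptor-positive and toxicity control siRNAs on every
    plate). Returns a report frame with one row per plate: counts per role,
    a ``complete`` flag and the comma-joined ``missing_roles``. Flags, never
    raises. The check is presence-only: physical positions of control wells
    are not part of the contract.
    """
    if wells.empty:
        return pd.DataFrame(
            columns=["plate_id", *ROLES, "complete", "missing_roles"]
        )
    counts = (
        wells.groupby(["plate_id", "role"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(ROLES), fill_value=0)
        .reset_index()
    )
    required: Mapping[str, int] = config.control_layout
    missing = counts.apply(
        lambda row: ",".join(
            role for role, n in required.items() if row[role] < n
        ),
        axis=1,
    )
    counts["complete"] = missing == ""
    counts["missing_roles"] = missing
    return counts
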