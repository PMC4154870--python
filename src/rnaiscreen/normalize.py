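"""Plate/well QC exclusions and the normalization cascade.

Order of operations, per screen:

1. **Plate QC** — a plate is discarded outright if the mean viability
   readout of its non-targeting controls is above ``plate_viability_hi``,
   below ``plate_viability_lo``, or if their coefficient of variation
   exceeds ``plate_viability_cv``. The ">50% standard deviation" rule is a
   CV (SD/mean) rule: an absolute SD bound of 0.5 would contradict the 0.2
   lower mean bound.
2. **Well viability filter** — on surviving plates, any well whose
   viability readout is strictly below ``well_viability_frac`` (40%) of the
   plate's non-targeting-control mean is excluded (low transfection
   efficiency or siRNA toxicity). Controls are subject to the same rule.
   Wells exactly at the boundary are kept (strict ``<``).
3. **Activity ratio** — reporter / viability (nRLU = RLU/ABS405 for the
   luciferase assay, nQB = QB/XTT for the SEAP assay).
4. **NPI** — normalized percent inhibition, rescaling each plate so the
   negative-control mean maps to 0 and the positive-control mean to 1.
   Control means use only wells surviving the viability filter.
5. **Robust z-scores** — per replicate plate, centered to the *median* of
   the non-targeting controls; scale is 1.4826 x MAD of the plate's sample
   wells by default (configurable to the neg-control SD). The per-siRNA
   screen score is the median z over surviving replicates.

Because NPI is inhibition-positive (1 at the positive control), z-scores
computed on NPI already carry the orientation "larger positive score =
stronger inhibition of the reporter"; this convention is recorded in the
metadata returned by :func:`orient_and_combine`.

Exclusion order is strictly plate-level before well-level: a well on a
failed plate carries reason ``plate_failed`` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    DegenerateControlsError,
    DegenerateScaleError,
    InsufficientControlsError,
    ScreenConfig,
)

#: Consistency constant making the MAD an unbiased scale estimate under
#: normality (1 / Phi^-1(3/4)).
MAD_SCALE = 1.4826

ORIENTATION = "+z = stronger inhibition of reporter activity (NPI-based z-score)"

class UndefinedRatioError(ValueError):
    """Activity ratio requested for a well with zero viability readout."""


REASON_NONE = "none"
REASON_PLATE = "plate_failed"
REASON_VIABILITY = "low_viability"


@dataclass(frozen=True)
class PlateQC:
    """Outcome of the plate-level viability-control QC."""

    plate_id: str
    neg_mean_viability: float
    neg_cv_viability: float
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold exactly when reasons is empty")


def plate_qc(plate: pd.DataFrame, config: ScreenConfig) -> PlateQC:
    """Apply the plate-exclusion rule to one plate's wells.

    All three failure reasons (``mean_too_high``, ``mean_too_low``,
    ``cv_too_high``) are evaluated independently and may co-occur.
    Requires at least two non-targeting control wells.
    """
    plate_id = str(plate["plate_id"].iloc[0])
    neg = plate.loc[plate["role"] == "neg_ctrl", "readout_viability"].to_numpy(float)
    if neg.size < 2:
        raise InsufficientControlsError(
            f"plate {plate_id}: needs >=2 neg_ctrl wells for QC, found {neg.size}"
        )
    mean = float(neg.mean())
    sd = float(neg.std(ddof=1))
    cv = sd / mean if mean > 0 else float("inf")
    thr = config.thresholds
    reasons: list[str] = []
    if mean > thr.plate_viability_hi:
        reasons.append("mean_too_high")
    if mean < thr.plate_viability_lo:
        reasons.append("mean_too_low")
    if cv > thr.plate_viability_cv:
        reasons.append("cv_too_high")
    return PlateQC(plate_id, mean, cv, passed=not reasons, reasons=tuple(reasons))


def exclude_low_viability(
    plate: pd.DataFrame, config: ScreenConfig
) -> pd.Series:
    """Boolean mask of wells failing the 40%-of-neg-control viability rule.

    The reference is the mean viability readout of the plate's non-targeting
    controls; a well is excluded iff its viability is strictly below
    ``well_viability_frac`` times that reference. Controls are evaluated by
    the same rule. Assumes the plate already passed :func:`plate_qc`.
    """
    neg_mean = plate.loc[plate["role"] == "neg_ctrl", "readout_viability"].mean()
    cutoff = config.thresholds.well_viability_frac * neg_mean
    return plate["readout_viability"] < cutoff


def normalize_activity(readout_activity: float, readout_viability: float) -> float:
    """Viability-corrected activity ratio (nRLU or nQB).

    Raises :class:`UndefinedRatioError` for zero viability: such wells must
    already have been excluded.
    """
    if readout_viability <= 0:
        raise UndefinedRatioError(
            "activity ratio undefined for readout_viability <= 0; "
            "the well should have been excluded"
        )
    return readout_activity / readout_viability


def npi_normalize(
    n_activity: float | np.ndarray, neg_mean: float, pos_mean: float
) -> float | np.ndarray:
    """Normalized percent inhibition.

    0 at the negative-control (non-targeting) mean, 1 at the
    positive-control mean; monotone decreasing in activity when the
    positive control inhibits. Invariant to rescaling all activities on a
    plate by a common positive factor (plate effects cancel).
    """
    if neg_mean == pos_mean:
        raise DegenerateControlsError(
            "negative- and positive-control means coincide; NPI undefined"
        )
    return (neg_mean - n_activity) / (neg_mean - pos_mean)


def plate_zscores(
    values: np.ndarray,
    neg_values: np.ndarray,
    sample_values: np.ndarray,
    method: str = "sample_mad",
) -> np.ndarray:
    """Robust z-scores for one replicate plate.

    ``z = (value - median(neg_values)) / scale`` where the scale is
    ``MAD_SCALE * MAD`` of the plate's sample values (``sample_mad``) or the
    SD of its non-targeting controls (``neg_sd``). The neg-control median
    maps to exactly 0 on every plate by construction.
    """
    center = float(np.median(neg_values))
    if method == "sample_mad":
        scale = MAD_SCALE * float(
            np.median(np.abs(sample_values - np.median(sample_values)))
        )
    elif method == "neg_sd":
        scale = float(np.std(neg_values, ddof=1))
    else:
        raise ValueError(f"unknown z-score scale method {method!r}")
    if scale == 0:
        raise DegenerateScaleError("zero scale estimate; z-scores undefined")
    return (np.asarray(values, float) - center) / scale


def normalize_screen(
    wells: pd.DataFrame,
    config: ScreenConfig,
    positive_role: str = "pos_ctrl_pathway",
) -> tuple[pd.DataFrame, list[PlateQC]]:
    """Run the full per-plate QC + normalization cascade on a well table.

    Parameters
    ----------
    wells
        Validated long-format well table (one screen or several; plates are
        processed independently).
    positive_role
        Control role anchoring NPI = 1. The luciferase screen uses the p65
        pathway control; the THP1 screen anchors to its receptor (NOD1)
        controls instead — pass ``"pos_ctrl_receptor"`` there.

    Returns
    -------
    (normalized, reports)
        ``normalized`` is the input plus columns ``excluded``,
        ``exclusion_reason``, ``n_activity``, ``npi`` and ``z`` (NaN where
        undefined); ``reports`` one :class:`PlateQC` per plate.
    """
    out = wells.copy()
    out["excluded"] = False
    out["exclusion_reason"] = REASON_NONE
    out["n_activity"] = np.nan
    out["npi"] = np.nan
    out["z"] = np.nan

    reports: list[PlateQC] = []
    for plate_id, idx in out.groupby("plate_id", sort=True).groups.items():
        plate = out.loc[idx]
        qc = plate_qc(plate, config)
        reports.append(qc)
        if not qc.passed:
            out.loc[idx, "excluded"] = True
            out.loc[idx, "exclusion_reason"] = REASON_PLATE
            continue

        low = exclude_low_viability(plate, config)
        out.loc[idx[low], "excluded"] = True
        out.loc[idx[low], "exclusion_reason"] = REASON_VIABILITY

        alive = idx[~low]
        viab = out.loc[alive, "readout_viability"].to_numpy(float)
        positive = viab > 0
        ratio_idx = alive[positive]
        out.loc[ratio_idx, "n_activity"] = (
            out.loc[ratio_idx, "readout_activity"].to_numpy(float)
            / out.loc[ratio_idx, "readout_viability"].to_numpy(float)
        )

        roles = out.loc[ratio_idx, "role"]
        neg_act = out.loc[ratio_idx[roles == "neg_ctrl"], "n_activity"]
        pos_act = out.loc[ratio_idx[roles == positive_role], "n_activity"]
        if neg_act.empty or pos_act.empty:
            raise InsufficientControlsError(
                f"plate {plate_id}: no surviving {'neg_ctrl' if neg_act.empty else positive_role} "
                "wells; NPI undefined"
            )
        out.loc[ratio_idx, "npi"] = npi_normalize(
            out.loc[ratio_idx, "n_activity"].to_numpy(float),
            float(neg_act.mean()),
            float(pos_act.mean()),
        )

        npi_vals = out.loc[ratio_idx, "npi"].to_numpy(float)
        neg_npi = out.loc[ratio_idx[roles == "neg_ctrl"], "npi"].to_numpy(float)
        sample_npi = out.loc[ratio_idx[roles == "sample"], "npi"].to_numpy(float)
        if sample_npi.size == 0:
            raise InsufficientControlsError(
                f"plate {plate_id}: no surviving sample wells; scale undefined"
            )
        try:
            out.loc[ratio_idx, "z"] = plate_zscores(
                npi_vals, neg_npi, sample_npi, method=config.zscore_scale
            )
        except DegenerateScaleError as err:
            raise DegenerateScaleError(f"plate {plate_id}: {err}") from None
    return out, reports


def qc_report_frame(reports: list[PlateQC]) -> pd.DataFrame:
    """Tabular per-plate QC report (for the qc_report.tsv artifact)."""
    return pd.DataFrame(
        {
            "plate_id": [r.plate_id for r in reports],
            "neg_mean_viability": [r.neg_mean_viability for r in reports],
            "neg_cv_viability": [r.neg_cv_viability for r in reports],
            "passed": [r.passed for r in reports],
            "reasons": [",".join(r.reasons) for r in reports],
        }
    )


def orient_and_combine(
    normalized: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Collapse per-well z-scores into one oriented score per siRNA per arm.

    Groups surviving sample wells by (screen, stimulus arm, siRNA) and takes
    the median z over replicates; siRNAs whose every replicate was excluded
    are emitted with a missing ``median_z`` and ``n_replicates_used = 0``.
    Returns the score table and metadata recording the sign convention
    (z-scores on NPI are already inhibition-positive, so no sign flip is
    applied).
    """
    samples = normalized[normalized["role"] == "sample"]
    rows = []
    for (screen_id, stim, sirna), grp in samples.groupby(
        ["screen_id", "stimulus", "sirna_id"], sort=True
    ):
        alive = grp[~grp["excluded"] & grp["z"].notna()]
        zs = alive.sort_values("replicate")["z"].to_numpy(float)
        rows.append(
            {
                "screen_id": screen_id,
                "stimulus": stim,
                "sirna_id": sirna,
                "gene_id": grp["gene_id"].iloc[0],
                "replicate_z": ";".join(f"{z:.6g}" for z in zs),
                "median_z": float(np.median(zs)) if zs.size else np.nan,
                "n_replicates_used": int(zs.size),
            }
        )
    scores = pd.DataFrame(
        rows,
        columns=[
            "screen_id",
            "stimulus",
            "sirna_id",
            "gene_id",
            "replicate_z",
            "median_z",
            "n_replicates_used",
        ],
    )
    return scores, {"orientation": ORIENTATION}


def neg_control_zstats(normalized: pd.DataFrame) -> tuple[float, float]:
    """Median and SD of the surviving non-targeting-control z-scores.

    This is the null score distribution against which the SD-margin hit
    rules (validation 2-SD, THP1 1.5/3.0-SD) are applied; compute it from
    the same screen arm as the scores being thresholded.
    """
    neg = normalized[
        (normalized["role"] == "neg_ctrl")
        & ~normalized["excluded"]
        & normalized["z"].notna()
    ]["z"].to_numpy(float)
    if neg.size < 2:
        raise InsufficientControlsError(
            "need >=2 surviving neg_ctrl z-scores for control statistics"
        )
    return float(np.median(neg)), float(np.std(neg, ddof=1))
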