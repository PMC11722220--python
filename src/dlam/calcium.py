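"""Neuropil-corrected dF/F analysis of ROI fluorescence.

Estimated true fluorescence is the measured ROI trace minus 7/10ths of the
surrounding neuropil trace.  dF/F is computed relative to the average
fluorescence over all interblock gray periods, (F - F_avg_gray)/F_avg_gray.
Sessions with fewer than 100 ROIs in the field of view are excluded (low
ROI counts indicate excessive recording noise).  Condition responses are
the mean evoked dF/F over all frames of each condition's blocks, per ROI
and averaged over the population.
"""

from __future__ import annotations

import logging

import numpy as np

from .io_core import RoiTraceSet, StimulusSchedule, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "neuropil_correct",
    "dff_vs_gray",
    "qc_session",
    "condition_responses",
    "NEUROPIL_COEFFICIENT",
    "MIN_ROI_COUNT",
]

NEUROPIL_COEFFICIENT = 0.7
MIN_ROI_COUNT = 100


def neuropil_correct(f_roi: np.ndarray, f_np: np.ndarray,
                     coefficient: float = NEUROPIL_COEFFICIENT) -> np.ndarray:
    """F_true(t) = F_roi(t) - coefficient * F_neuropil(t)."""
    f_roi = np.asarray(f_roi, dtype=float)
    f_np = np.asarray(f_np, dtype=float)
    if f_roi.shape != f_np.shape:
        raise ValidationError("ROI and neuropil traces must have matching shapes")
    return f_roi - coefficient * f_np


def dff_vs_gray(f_true: np.ndarray, schedule: StimulusSchedule,
                frame_rate: float) -> np.ndarray:
    """(F - F_avg_gray) / F_avg_gray with the gray mean over all interblock frames."""
    f = np.atleast_2d(np.asarray(f_true, dtype=float))
    mask = schedule.interblock_mask(f.shape[1], frame_rate)
    if not mask.any():
        raise ValidationError("no interblock frames to define the gray baseline")
    f_gray = f[:, mask].mean(axis=1, keepdims=True)
    if np.any(f_gray <= 0):
        raise ValidationError("non-positive gray baseline fluorescence")
    return (f - f_gray) / f_gray


def qc_session(roi_count: int) -> bool:
    """True (include) iff the field of view has at least 100 ROIs."""
    if roi_count < 0:
        raise ValidationError("ROI count cannot be negative")
    include = roi_count >= MIN_ROI_COUNT
    logger.info("session QC: %d ROIs -> %s", roi_count,
                "include" if include else "exclude")
    return include


def condition_responses(dff: np.ndarray, schedule: StimulusSchedule,
                        frame_rate: float,
                        conditions: list[str] | None = None) -> dict:
    """Per-ROI and population mean evoked dF/F per condition.

    Per-ROI means pool all in-block frames across every block of the
    condition (blocks are equal length by design, so this weights blocks
    equally); the population mean averages over ROIs.  Also returns the
    per-block time courses for plotting block-average responses.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    conditions = conditions or schedule.conditions
    per_roi, population, block_courses = {}, {}, {}
    for cond in conditions:
        idx = schedule.blocks_for(cond)
        if not idx:
            raise ValidationError(f"condition {cond!r} missing from the schedule")
        mask = schedule.block_mask(dff.shape[1], frame_rate, cond)
        per_roi[cond] = dff[:, mask].mean(axis=1)
        population[cond] = float(per_roi[cond].mean())
        courses = []
        for i in idx:
            b = schedule.blocks[i]
            i0 = int(round(b.start_s * frame_rate))
            i1 = min(int(round(b.end_s * frame_rate)), dff.shape[1])
            courses.append(dff[:, i0:i1].mean(axis=0))
        n = min(c.size for c in courses)
        block_courses[cond] = np.mean([c[:n] for c in courses], axis=0)
    return {"per_roi": per_roi, "population": population, "block_courses": block_courses}
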