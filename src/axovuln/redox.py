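"""roGFP trace quality control and relative-oxidation quantification.

A mitochondrially targeted roGFP reports redox state as a single-channel
fluorescence intensity calibrated per ROI by full chemical reduction
(DTT, fluorescence maximum FDTT) and full oxidation (aldrithiol,
fluorescence minimum FALD).  Relative oxidation is

    1 - (F - FALD) / (FDTT - FALD)

with F the baseline fluorescence: 0 = fully reduced, 1 = fully oxidized.
Traces with a baseline drift above 10% or failing to respond to DTT/ALD
in the expected directions are excluded before quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import shift as nd_shift
from skimage.registration import phase_cross_correlation

from .synthetic import FluorTrace

DEFAULT_DRIFT_LIMIT = 0.10
DEFAULT_RESPONSE_K = 3.0


@dataclass
class QCResult:
    included: bool
    excluded_drift: bool
    excluded_nonresponder: bool
    drift_fraction: float


@dataclass
class OxidationResult:
    """Per-ROI calibrated oxidation summary."""

    roi_id: str
    F: float
    FDTT: float
    FALD: float
    relative_oxidation: float  # NaN unless qc.included
    qc: QCResult
    clipped: bool = False
    compartment: str = "axonal"


def register_stack(frames: np.ndarray, upsample: int = 1) -> np.ndarray:
    """Per-frame integer (dy, dx) offsets aligning each frame to frame 0.

    Offsets maximize the cross-correlation with the first frame; applying
    ``apply_offsets`` with them undoes the drift.  A frame shifted by
    (+3, -2) px relative to frame 0 yields offset (-3, +2).
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of >= 2 frames")
    offsets = np.zeros((frames.shape[0], 2))
    for i in range(1, frames.shape[0]):
        shift_est, _, _ = phase_cross_correlation(
            frames[0], frames[i], upsample_factor=upsample, normalization=None
        )
        offsets[i] = shift_est
    return np.rint(offsets).astype(int)


def apply_offsets(frames: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Translate each frame by its offset (nearest-neighbour fill at edges)."""
    out = np.empty_like(np.asarray(frames, float))
    for i, (dy, dx) in enumerate(offsets):
        out[i] = nd_shift(frames[i], (dy, dx), order=0, mode="nearest")
    return out


def extract_traces(
    stack: np.ndarray,
    roi_labels: np.ndarray,
    epochs: np.ndarray,
    compartment: str = "axonal",
) -> list[FluorTrace]:
    """Per-ROI mean intensity per frame from a registered stack.

    ``roi_labels`` is an integer label raster (0 = background);
    ``epochs`` assigns each frame its epoch name.
    """
    stack = np.asarray(stack, float)
    if stack.shape[0] != len(epochs):
        raise ValueError("one epoch label per frame required")
    if roi_labels.shape != stack.shape[1:]:
        raise ValueError("ROI raster and frames differ in shape")
    traces = []
    for lab in np.unique(roi_labels):
        if lab == 0:
            continue
        mask = roi_labels == lab
        vals = stack[:, mask].mean(axis=1)
        traces.append(
            FluorTrace(f"roi{int(lab)}", vals, np.asarray(epochs, str), compartment)
        )
    return traces


def _epoch_summary(trace: FluorTrace, name: str) -> float:
    """Plateau summary: median of the last half of the epoch."""
    vals = trace.epoch_values(name)
    if vals.size == 0:
        raise ValueError(f"trace {trace.roi_id!r}: epoch {name!r} is empty")
    return float(np.median(vals[vals.size // 2 :]))


def qc_trace(
    trace: FluorTrace,
    drift_limit: float = DEFAULT_DRIFT_LIMIT,
    response_k: float = DEFAULT_RESPONSE_K,
) -> QCResult:
    """Apply the two exclusion rules.

    Drift: |least-squares baseline slope x baseline duration| divided by
    the fitted value at baseline start; excluded when above
    ``drift_limit``.  Responsiveness: DTT must raise and ALD must lower
    fluorescence by at least ``response_k`` baseline (detrended) SDs.
    """
    base = trace.epoch_values("baseline")
    if base.size == 0 or trace.epoch_values("dtt").size == 0 or (
        trace.epoch_values("ald").size == 0
    ):
        raise ValueError("all three epochs (baseline, dtt, ald) must be present")
    t = np.arange(base.size, dtype=float)
    if base.size >= 2:
        slope, intercept = np.polyfit(t, base, 1)
    else:
        slope, intercept = 0.0, float(base[0])
    start = intercept if intercept != 0 else max(base.mean(), 1e-12)
    drift = abs(slope * (base.size - 1)) / abs(start)
    excluded_drift = drift > drift_limit
    resid_sd = float(np.std(base - (slope * t + intercept)))
    threshold = max(response_k * resid_sd, 1e-9)
    f = _epoch_summary(trace, "baseline")
    fdtt = _epoch_summary(trace, "dtt")
    fald = _epoch_summary(trace, "ald")
    excluded_nonresponder = (fdtt - f) < threshold or (f - fald) < threshold
    return QCResult(
        included=not (excluded_drift or excluded_nonresponder),
        excluded_drift=bool(excluded_drift),
        excluded_nonresponder=bool(excluded_nonresponder),
        drift_fraction=float(drift),
    )


def relative_oxidation(
    F: float, FDTT: float, FALD: float, clip: bool = True
) -> float:
    """Relative oxidation 1 - (F - FALD)/(FDTT - FALD).

    Endpoints: F = FDTT -> 0 (fully reduced), F = FALD -> 1 (fully
    oxidized).  Invariant under common affine rescaling of all three
    inputs.  Values outside [0, 1] are clipped when ``clip`` is true.
    """
    if not FDTT > FALD:
        raise ValueError("calibration requires FDTT > FALD")
    val = 1.0 - (F - FALD) / (FDTT - FALD)
    if clip:
        val = min(max(val, 0.0), 1.0)
    return float(val)


def quantify_trace(
    trace: FluorTrace,
    drift_limit: float = DEFAULT_DRIFT_LIMIT,
    response_k: float = DEFAULT_RESPONSE_K,
) -> OxidationResult:
    """QC one trace and, if included, compute its relative oxidation."""
    qc = qc_trace(trace, drift_limit, response_k)
    f = _epoch_summary(trace, "baseline")
    fdtt = _epoch_summary(trace, "dtt")
    fald = _epoch_summary(trace, "ald")
    value = float("nan")
    clipped = False
    if qc.included:
        raw = relative_oxidation(f, fdtt, fald, clip=False)
        value = min(max(raw, 0.0), 1.0)
        clipped = raw != value
    return OxidationResult(
        roi_id=trace.roi_id,
        F=f,
        FDTT=fdtt,
        FALD=fald,
        relative_oxidation=value,
        qc=qc,
        clipped=clipped,
        compartment=trace.compartment,
    )


def intermito_distances(centers_um: np.ndarray) -> np.ndarray:
    """Consecutive center-to-center gaps (um) along an axon after ordering
    by arc position; empty for fewer than two centers."""
    centers = np.sort(np.asarray(centers_um, float).ravel())
    if centers.size < 2:
        return np.empty(0)
    return np.diff(centers)
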