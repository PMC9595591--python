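"""Synthetic fluorescence-microscopy fields, redox traces and puncta spacings.

This module emulates the statistical structure of the study system the
downstream analysis assumes — sparse marker-positive somata over a field of
background nuclei, long curvature-bounded branched neurites carrying focal
enlargements (varicosities) whose Syt-1 signal follows a two-component
positive/negative intensity mixture, single-ROI roGFP fluorescence traces
with baseline / DTT (full reduction, fluorescence maximum) / ALD (full
oxidation, fluorescence minimum) epochs, and gamma-spaced mitochondrial
puncta along an axon.  Every generator returns ground truth alongside the
raster so that each analysis stage can be benchmarked without real data.

Conventions
-----------
* Pixel coordinates are 0-based ``(x, y) = (col, row)``; physical
  coordinates are pixel centers times ``pixel_size_um``.
* The camera model is a constant background plus additive Gaussian noise.
  Channel bleed-through and shot noise are not simulated.
* Equal seeds give bit-identical images, truths and traces.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import CHANNEL_ROLES, ImageField

# rendering amplitudes (arbitrary fluorescence units)
_SOMA_AMP = (150.0, 250.0)
_NEURITE_AMP = 40.0
_VARICOSITY_AMP = (60.0, 100.0)
_NUCLEUS_AMP = (60.0, 120.0)
_LINE_SMOOTH_SIGMA_PX = 0.5  # keeps neurite FWHM ~0.35 um at 0.3 um/px

EPOCHS = ("baseline", "dtt", "ald")


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic multichannel field.

    Defaults describe a 115 x 115 um field at a 60x-like sampling of
    0.3 um/px with ten well-separated marker-positive somata and ~1.2 mm
    of branched neurite carrying varicosities every ~5 um on average.
    ``offgate_fraction`` of planted enlargements are oversized (width above
    the 1 um gate) and carry Syt-1 from the negative mixture component
    only; they model the background-like structures whose Syt-1 signal
    calibrates the positivity cutoff.
    """

    width_px: int = 384
    height_px: int = 384
    pixel_size_um: float = 0.3
    n_neurons: int = 10
    n_nuclei: int = 30
    neurite_total_length_um: float = 1200.0
    branch_prob_per_um: float = 0.02
    varicosity_spacing_um: float = 5.0
    varicosity_min_gap_um: float = 1.5
    varicosity_width_range_um: tuple[float, float] = (0.3, 0.9)
    varicosity_length_range_um: tuple[float, float] = (0.6, 2.0)
    offgate_fraction: float = 0.15
    offgate_width_range_um: tuple[float, float] = (1.2, 1.8)
    syt1_pos_fraction: float = 0.5
    syt1_pos_mean: float = 120.0
    syt1_neg_mean: float = 20.0
    syt1_sd: float = 10.0
    soma_diameter_range_um: tuple[float, float] = (8.0, 15.0)
    background_level: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.width_px, self.height_px) <= 0 or self.pixel_size_um <= 0:
            raise ValueError("field extents and pixel size must be > 0")
        if not 0.0 <= self.syt1_pos_fraction <= 1.0:
            raise ValueError("syt1_pos_fraction must lie in [0, 1]")
        if self.syt1_pos_mean <= self.syt1_neg_mean:
            raise ValueError("syt1_pos_mean must exceed syt1_neg_mean")
        if min(self.n_neurons, self.n_nuclei) < 0:
            raise ValueError("counts must be >= 0")
        if self.neurite_total_length_um < 0:
            raise ValueError("neurite_total_length_um must be >= 0")
        n_px = self.width_px * self.height_px
        if self.neurite_total_length_um / self.pixel_size_um > 0.5 * n_px:
            raise ValueError(
                "requested neurite length exceeds 50% of the field's pixels"
            )


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one synthetic roGFP fluorescence trace.

    The baseline epoch is multiplied by a linear ramp spanning
    ``(1, 1 + drift_fraction)``; non-responders hold ``f_baseline``
    through the DTT and ALD epochs.
    """

    n_baseline: int = 60
    n_dtt: int = 40
    n_ald: int = 40
    f_baseline: float = 120.0
    f_dtt: float = 200.0
    f_ald: float = 40.0
    drift_fraction: float = 0.0
    responder: bool = True
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_baseline, self.n_dtt, self.n_ald) < 1:
            raise ValueError("every epoch needs at least one frame")
        if not self.f_dtt > self.f_ald > 0:
            raise ValueError("requires f_dtt > f_ald > 0")
        if self.responder and not self.f_ald <= self.f_baseline <= self.f_dtt:
            raise ValueError("responder requires f_ald <= f_baseline <= f_dtt")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class MitoSpacingSpec:
    """Gamma-distributed consecutive gaps between mitochondrial puncta
    along a simulated axon.  Defaults are the consensus spacing observed
    across neuron types (mean ~13 um, SD 5.4 um)."""

    n_puncta: int = 100
    spacing_mean_um: float = 13.0
    spacing_sd_um: float = 5.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_puncta < 2:
            raise ValueError("need at least two puncta")
        if self.spacing_mean_um <= 0 or self.spacing_sd_um < 0:
            raise ValueError("spacing_mean_um > 0 and spacing_sd_um >= 0 required")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class VaricosityTruth:
    centroid_um: tuple[float, float]
    width_um: float
    length_um: float
    syt1_intensity: float
    is_syt1_positive: bool


@dataclass
class GroundTruth:
    """Generator-side annotation for one field, used only by benchmarks."""

    soma_centers_um: list[tuple[float, float]]
    skeleton_polylines_um: list[np.ndarray]  # each (N, 2) of (x, y)
    polyline_lengths_um: list[float]
    varicosities: list[VaricosityTruth]

    @property
    def n_neurons(self) -> int:
        return len(self.soma_centers_um)

    @property
    def total_neurite_length_um(self) -> float:
        return float(sum(self.polyline_lengths_um))

    @property
    def n_varicosities(self) -> int:
        return len(self.varicosities)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "soma_centers_um": [list(c) for c in self.soma_centers_um],
            "skeleton_polylines_um": [p.tolist() for p in self.skeleton_polylines_um],
            "polyline_lengths_um": self.polyline_lengths_um,
            "varicosities": [asdict(v) for v in self.varicosities],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            soma_centers_um=[tuple(c) for c in d["soma_centers_um"]],
            skeleton_polylines_um=[np.asarray(p, float) for p in d["skeleton_polylines_um"]],
            polyline_lengths_um=[float(x) for x in d["polyline_lengths_um"]],
            varicosities=[
                VaricosityTruth(
                    tuple(v["centroid_um"]), v["width_um"], v["length_um"],
                    v["syt1_intensity"], v["is_syt1_positive"],
                )
                for v in d["varicosities"]
            ],
        )


@dataclass
class FluorTrace:
    """One ROI's fluorescence time course with per-frame epoch labels."""

    roi_id: str
    frames: np.ndarray
    epochs: np.ndarray  # same length, values in EPOCHS
    compartment: str = "axonal"

    def epoch_values(self, name: str) -> np.ndarray:
        vals = self.frames[self.epochs == name]
        return vals

    def validate(self) -> None:
        if self.frames.shape != self.epochs.shape:
            raise ValueError("frames and epoch labels differ in length")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be >= 0")


# ---------------------------------------------------------------------------
# neurite growth (curvature-bounded random walk with Poisson branching)


#: Halo (um) around each soma inside which axon segments are occluded by
#: the fluorophore-dense cell body and excluded from the visible truth.
SOMA_OCCLUSION_MARGIN_UM = 2.0
#: Visible fragments shorter than this are below what tracing can resolve
#: and are dropped from truth and rendering alike.
MIN_FRAGMENT_UM = 2.0


def _split_visible(
    poly: np.ndarray, occluded: np.ndarray, min_vertices: int
) -> list[np.ndarray]:
    """Sub-polylines of consecutive non-occluded vertices."""
    out = []
    visible = ~occluded
    boundaries = np.flatnonzero(np.diff(visible.astype(int)))
    starts = [0] if visible[0] else []
    starts += [b + 1 for b in boundaries if visible[b + 1]]
    ends = [b + 1 for b in boundaries if visible[b]]
    ends += [len(poly)] if visible[-1] else []
    for s, e in zip(starts, ends):
        if e - s >= min_vertices:
            out.append(poly[s:e])
    return out


def _grow_neurites(
    spec: FieldSpec,
    rng: np.random.Generator,
    soma_centers_px: list[tuple[float, float]],
    soma_radii_px: list[float],
) -> list[np.ndarray]:
    """Random-walk polylines (pixel coords) whose *visible* (outside the
    soma occlusion halos) summed length hits the requested total."""
    target_steps = int(round(spec.neurite_total_length_um / spec.pixel_size_um))
    if target_steps == 0:
        return []
    margin = 3.0
    lo_x, hi_x = margin, spec.width_px - 1 - margin
    lo_y, hi_y = margin, spec.height_px - 1 - margin
    halo_px = SOMA_OCCLUSION_MARGIN_UM / spec.pixel_size_um
    min_vertices = max(int(round(MIN_FRAGMENT_UM / spec.pixel_size_um)) + 1, 2)
    centers = np.asarray(soma_centers_px, float).reshape(-1, 2)
    radii = np.asarray(soma_radii_px, float) + halo_px if len(centers) else None
    polylines: list[np.ndarray] = []
    budget = target_steps
    # queue of pending walk starts: (x, y, heading) — None means random
    queue: list[tuple[float, float, float] | None] = [None]
    p_branch_per_step = spec.branch_prob_per_um * spec.pixel_size_um
    guard = 0
    while budget > 0 and guard < 10 * target_steps:
        start = queue.pop() if queue else None
        if start is None:
            x0 = rng.uniform(lo_x, hi_x)
            y0 = rng.uniform(lo_y, hi_y)
            theta0 = rng.uniform(0.0, 2.0 * np.pi)
        else:
            x0, y0, theta0 = start
        n_steps = max(min(int(rng.integers(100, 500)), budget + 20), 2)
        # low per-step curvature: axons are nearly straight at the 10-um scale
        dtheta = rng.normal(0.0, 0.05, size=n_steps)
        xs = np.empty(n_steps + 1)
        ys = np.empty(n_steps + 1)
        xs[0], ys[0] = x0, y0
        theta = np.empty(n_steps)
        th = theta0
        cx_field = 0.5 * (lo_x + hi_x)
        cy_field = 0.5 * (lo_y + hi_y)
        steer_band = 15.0
        for k in range(n_steps):
            x, y = xs[k], ys[k]
            near = min(x - lo_x, hi_x - x, y - lo_y, hi_y - y)
            if near < steer_band:
                # steer smoothly toward the field center instead of
                # mirror-reflecting (avoids self-retracing at the border)
                phi = np.arctan2(cy_field - y, cx_field - x)
                delta = np.arctan2(np.sin(phi - th), np.cos(phi - th))
                th += np.clip(delta, -0.25, 0.25) * (1.0 - near / steer_band)
            th += dtheta[k]
            theta[k] = th
            xs[k + 1] = x + np.cos(th)
            ys[k + 1] = y + np.sin(th)
        np.clip(xs, lo_x, hi_x, out=xs)
        np.clip(ys, lo_y, hi_y, out=ys)
        poly = np.column_stack([xs, ys])
        guard += n_steps
        if radii is not None and len(centers):
            d2 = ((poly[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
            occluded = (d2 < radii[None, :] ** 2).any(axis=1)
        else:
            occluded = np.zeros(len(poly), bool)
        for sub in _split_visible(poly, occluded, min_vertices):
            if budget <= 0:
                break
            n_sub = len(sub) - 1
            if n_sub > budget:
                sub = sub[: budget + 1]
                n_sub = budget
            polylines.append(sub)
            budget -= n_sub
        # Poisson branch events along this walk
        n_branch = rng.binomial(n_steps, min(p_branch_per_step, 1.0))
        if n_branch > 0:
            at = rng.integers(1, n_steps, size=n_branch)
            for i in at:
                side = 1.0 if rng.random() < 0.5 else -1.0
                queue.append(
                    (xs[i], ys[i], theta[i - 1] + side * rng.normal(1.0, 0.2))
                )
    return polylines


def _polyline_length(poly_px: np.ndarray, pixel_size_um: float) -> float:
    d = np.diff(poly_px, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1]))) * pixel_size_um


def _stamp_gaussian(
    canvas: np.ndarray,
    cx: float,
    cy: float,
    sigma_along: float,
    sigma_trans: float,
    tangent: tuple[float, float],
    amplitude: float,
) -> None:
    """Add an anisotropic Gaussian blob aligned with `tangent` (pixel units)."""
    r = int(np.ceil(4.0 * max(sigma_along, sigma_trans))) + 1
    h, w = canvas.shape
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    tx, ty = tangent
    u = dx * tx + dy * ty  # along
    v = -dx * ty + dy * tx  # transverse
    canvas[y0:y1, x0:x1] += amplitude * np.exp(
        -0.5 * ((u / sigma_along) ** 2 + (v / sigma_trans) ** 2)
    )


def _stamp_disk(
    canvas: np.ndarray, cx: float, cy: float, radius: float, amplitude: float,
    edge: float = 1.0,
) -> None:
    r = int(np.ceil(radius + edge)) + 1
    h, w = canvas.shape
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    canvas[y0:y1, x0:x1] += amplitude * np.clip((radius - dist) / edge + 1.0, 0.0, 1.0)


def _place_somata(
    spec: FieldSpec, rng: np.random.Generator
) -> tuple[list[tuple[float, float]], list[float]]:
    """Dart-throwing placement with a separation floor (pixel coords, radii px)."""
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    d_lo, d_hi = spec.soma_diameter_range_um
    max_r_px = 0.5 * d_hi / spec.pixel_size_um
    min_sep_px = (d_hi + 3.0) / spec.pixel_size_um  # centers > max diameter apart
    for _ in range(spec.n_neurons):
        r_px = 0.5 * rng.uniform(d_lo, d_hi) / spec.pixel_size_um
        placed = False
        for _attempt in range(200):
            cx = rng.uniform(max_r_px + 2, spec.width_px - 1 - max_r_px - 2)
            cy = rng.uniform(max_r_px + 2, spec.height_px - 1 - max_r_px - 2)
            if all(np.hypot(cx - px, cy - py) >= min_sep_px for px, py in centers):
                placed = True
                break
        # after 200 failed darts accept the crowded position; the census
        # matching rule tolerates occasional merged somata
        centers.append((cx, cy))
        radii.append(r_px)
        if not placed:
            continue
    return centers, radii


def _plant_varicosities(
    spec: FieldSpec,
    polylines_px: list[np.ndarray],
    rng: np.random.Generator,
) -> list[tuple[VaricosityTruth, tuple[float, float], tuple[float, float]]]:
    """Sample enlargement sites along polylines.

    Returns (truth, centroid_px, tangent) triples.  Within-gate sites draw
    Syt-1 from the positive/negative mixture; oversized (off-gate) sites
    draw from the negative component only.
    """
    out = []
    px = spec.pixel_size_um
    for poly in polylines_px:
        seg = np.diff(poly, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1]) * px
        arc = np.concatenate(([0.0], np.cumsum(seg_len)))
        total = arc[-1]
        # enlargements are discrete ~um-scale structures: consecutive sites
        # keep a minimum gap, with the exponential excess restoring the
        # requested mean spacing
        gap_mean = max(spec.varicosity_spacing_um - spec.varicosity_min_gap_um, 0.1)
        pos = spec.varicosity_min_gap_um + rng.exponential(gap_mean)
        while pos < total:
            i = int(np.searchsorted(arc, pos) - 1)
            i = min(max(i, 0), len(seg) - 1)
            frac = (pos - arc[i]) / max(seg_len[i], 1e-9) * px
            cx, cy = poly[i] + frac * seg[i]
            norm = np.hypot(seg[i, 0], seg[i, 1])
            tangent = (seg[i, 0] / norm, seg[i, 1] / norm)
            if rng.random() < spec.offgate_fraction:
                width = rng.uniform(*spec.offgate_width_range_um)
                length = rng.uniform(*spec.varicosity_length_range_um)
                positive = False
            else:
                width = rng.uniform(*spec.varicosity_width_range_um)
                length = rng.uniform(*spec.varicosity_length_range_um)
                positive = rng.random() < spec.syt1_pos_fraction
            mean = spec.syt1_pos_mean if positive else spec.syt1_neg_mean
            syt1 = max(float(rng.normal(mean, spec.syt1_sd)), 0.0)
            truth = VaricosityTruth(
                centroid_um=(float(cx * px), float(cy * px)),
                width_um=float(width),
                length_um=float(length),
                syt1_intensity=syt1,
                is_syt1_positive=bool(positive),
            )
            out.append((truth, (float(cx), float(cy)), tangent))
            pos += spec.varicosity_min_gap_um + rng.exponential(gap_mean)
    return out


# ---------------------------------------------------------------------------
# public generators


def generate_field(spec: FieldSpec) -> tuple[ImageField, GroundTruth]:
    """Render a 4-channel field (marker, MAP2, Syt-1, nuclei) plus truth.

    With ``n_neurons == 0`` the marker channel contains background noise
    only (no somata implies no axonal field) and the truth lists are empty.
    Identical specs (including seed) give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    px = spec.pixel_size_um
    marker = np.zeros((h, w))
    map2 = np.zeros((h, w))
    syt1 = np.zeros((h, w))
    nuclei = np.zeros((h, w))

    if spec.n_neurons > 0:
        centers_px, radii_px = _place_somata(spec, rng)
        for (cx, cy), r in zip(centers_px, radii_px):
            amp = rng.uniform(*_SOMA_AMP)
            _stamp_disk(marker, cx, cy, r, amp)
            _stamp_disk(map2, cx, cy, r, 0.7 * amp)
            _stamp_disk(nuclei, cx, cy, 0.5 * r, rng.uniform(*_NUCLEUS_AMP))
        polylines_px = _grow_neurites(spec, rng, centers_px, radii_px)
        splat = np.zeros((h, w))
        for poly in polylines_px:
            cols = np.clip(np.rint(poly[:, 0]).astype(int), 0, w - 1)
            rows = np.clip(np.rint(poly[:, 1]).astype(int), 0, h - 1)
            np.add.at(splat, (rows, cols), 1.0)
        np.clip(splat, 0.0, 1.0, out=splat)
        marker += _NEURITE_AMP * gaussian_filter(splat, _LINE_SMOOTH_SIGMA_PX)
        planted = _plant_varicosities(spec, polylines_px, rng)
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
        for truth_v, (cx, cy), tangent in planted:
            s_along = truth_v.length_um / fwhm / px
            s_trans = truth_v.width_um / fwhm / px
            amp = rng.uniform(*_VARICOSITY_AMP)
            _stamp_gaussian(marker, cx, cy, s_along, s_trans, tangent, amp)
            _stamp_gaussian(
                syt1, cx, cy, max(s_along, 1.0), max(s_trans, 1.0), tangent,
                truth_v.syt1_intensity,
            )
        soma_centers_um = [(cx * px, cy * px) for cx, cy in centers_px]
        polylines_um = [poly * px for poly in polylines_px]
        lengths_um = [_polyline_length(poly, px) for poly in polylines_px]
        varicosities = [t for t, _, _ in planted]
    else:
        soma_centers_um, polylines_um, lengths_um, varicosities = [], [], [], []

    # background nuclei (non-marker cells)
    for _ in range(spec.n_nuclei):
        cx = rng.uniform(2, w - 3)
        cy = rng.uniform(2, h - 3)
        r = 0.5 * rng.uniform(6.0, 10.0) / px
        _stamp_disk(nuclei, cx, cy, r, rng.uniform(*_NUCLEUS_AMP))

    channels = {}
    for role, canvas in zip(CHANNEL_ROLES, (marker, map2, syt1, nuclei)):
        noisy = canvas + spec.background_level
        if spec.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
        channels[role] = np.clip(noisy, 0.0, None)

    field = ImageField(channels, px, meta={"spec": asdict(spec)})
    truth = GroundTruth(soma_centers_um, polylines_um, lengths_um, varicosities)
    return field, truth


def generate_straight_field(
    widths_um,
    lengths_um=None,
    syt1_positive=None,
    spacing_um: float = 8.0,
    pixel_size_um: float = 0.3,
    syt1_pos_mean: float = 120.0,
    syt1_neg_mean: float = 20.0,
    syt1_sd: float = 10.0,
    background_level: float = 10.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[ImageField, GroundTruth]:
    """Controlled fixture: one horizontal neurite with enlargements at
    regular spacing.

    ``widths_um`` fixes each planted enlargement's width (one site per
    entry); ``lengths_um`` defaults to 1.2 um each; ``syt1_positive`` is a
    boolean per site (default: all positive).  Rendering (line splat,
    Gaussian blobs, camera model) matches :func:`generate_field`, so
    detector benchmarks on this fixture transfer to the full generator.
    """
    widths = np.atleast_1d(np.asarray(widths_um, float))
    n = widths.size
    lengths = (
        np.full(n, 1.2) if lengths_um is None
        else np.broadcast_to(np.asarray(lengths_um, float), (n,))
    )
    positive = (
        np.ones(n, bool) if syt1_positive is None
        else np.broadcast_to(np.asarray(syt1_positive, bool), (n,))
    )
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    margin_px = int(round(10.0 / px))
    spacing_px = spacing_um / px
    w = int(2 * margin_px + (n - 1) * spacing_px) + 1 if n else 4 * margin_px
    h = int(round(20.0 / px))
    y0 = h // 2
    marker = np.zeros((h, w))
    syt1 = np.zeros((h, w))
    xs = np.arange(margin_px // 2, w - margin_px // 2)
    splat = np.zeros((h, w))
    splat[y0, xs] = 1.0
    marker += _NEURITE_AMP * gaussian_filter(splat, _LINE_SMOOTH_SIGMA_PX)
    poly_px = np.column_stack([xs.astype(float), np.full(xs.size, float(y0))])
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
    varicosities = []
    for i in range(n):
        cx = margin_px + i * spacing_px
        amp = rng.uniform(*_VARICOSITY_AMP)
        _stamp_gaussian(
            marker, cx, y0, lengths[i] / fwhm / px, widths[i] / fwhm / px,
            (1.0, 0.0), amp,
        )
        mean = syt1_pos_mean if positive[i] else syt1_neg_mean
        intensity = max(float(rng.normal(mean, syt1_sd)), 0.0)
        _stamp_gaussian(
            syt1, cx, y0, max(lengths[i] / fwhm / px, 1.0),
            max(widths[i] / fwhm / px, 1.0), (1.0, 0.0), intensity,
        )
        varicosities.append(
            VaricosityTruth(
                (float(cx * px), float(y0 * px)), float(widths[i]),
                float(lengths[i]), intensity, bool(positive[i]),
            )
        )
    channels = {}
    for role, canvas in zip(
        CHANNEL_ROLES, (marker, np.zeros((h, w)), syt1, np.zeros((h, w)))
    ):
        noisy = canvas + background_level
        if noise_sd > 0:
            noisy = noisy + rng.normal(0.0, noise_sd, size=canvas.shape)
        channels[role] = np.clip(noisy, 0.0, None)
    field = ImageField(channels, px, field_id="straight")
    truth = GroundTruth(
        [], [poly_px * px], [_polyline_length(poly_px, px)], varicosities
    )
    return field, truth


def generate_trace(spec: TraceSpec) -> tuple[FluorTrace, TraceSpec]:
    """Piecewise-plateau roGFP trace with optional baseline drift and noise.

    Returns the trace and an echo of the spec (the trace's ground truth).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ramp = np.linspace(1.0, 1.0 + spec.drift_fraction, spec.n_baseline)
    base = spec.f_baseline * ramp
    if spec.responder:
        dtt = np.full(spec.n_dtt, spec.f_dtt)
        ald = np.full(spec.n_ald, spec.f_ald)
    else:
        dtt = np.full(spec.n_dtt, spec.f_baseline)
        ald = np.full(spec.n_ald, spec.f_baseline)
    frames = np.concatenate([base, dtt, ald])
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.size)
    epochs = np.concatenate(
        [
            np.full(spec.n_baseline, "baseline"),
            np.full(spec.n_dtt, "dtt"),
            np.full(spec.n_ald, "ald"),
        ]
    )
    trace = FluorTrace("roi", np.clip(frames, 0.0, None), epochs)
    return trace, replace(spec)


def generate_mito_positions(spec: MitoSpacingSpec) -> np.ndarray:
    """1-D puncta centers (um) with gamma-distributed consecutive gaps.

    ``spacing_sd_um == 0`` degenerates to exactly equal gaps.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_gaps = spec.n_puncta - 1
    if spec.spacing_sd_um == 0.0:
        gaps = np.full(n_gaps, spec.spacing_mean_um)
    else:
        shape = (spec.spacing_mean_um / spec.spacing_sd_um) ** 2
        scale = spec.spacing_sd_um**2 / spec.spacing_mean_um
        gaps = rng.gamma(shape, scale, size=n_gaps)
    return np.concatenate(([0.0], np.cumsum(gaps)))


# ---------------------------------------------------------------------------
# fixture I/O


def write_field_fixture(
    field: ImageField, truth: GroundTruth, out_dir: str | Path, stem: str
) -> dict[str, Path]:
    """Write <stem>.tif (one page per channel) plus <stem>.truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / f"{stem}.tif"
    sidecar = out_dir / f"{stem}.truth.json"
    field.to_tiff(tif)
    truth.to_json(sidecar)
    return {"tiff": tif, "truth": sidecar}


def trace_to_frame(trace: FluorTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "roi_id": trace.roi_id,
            "frame": np.arange(trace.frames.size),
            "epoch": trace.epochs,
            "intensity": trace.frames,
            "compartment": trace.compartment,
        }
    )


def traces_to_csv(traces: list[FluorTrace], path: str | Path) -> None:
    pd.concat([trace_to_frame(t) for t in traces], ignore_index=True).to_csv(
        path, index=False
    )


def traces_from_csv(path: str | Path) -> list[FluorTrace]:
    df = pd.read_csv(path)
    out = []
    for roi_id, sub in df.groupby("roi_id", sort=True):
        sub = sub.sort_values("frame")
        compartment = str(sub["compartment"].iloc[0]) if "compartment" in sub else "axonal"
        out.append(
            FluorTrace(
                str(roi_id),
                sub["intensity"].to_numpy(float),
                sub["epoch"].to_numpy(str),
                compartment,
            )
        )
    return out
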