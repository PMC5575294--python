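"""Measurement extraction from corrected radiograph stacks.

Everything here operates on flat-field-corrected (transmission) frames.
The relative content of solution (RCS) at a pixel is the added path length
of injected solution along the X-ray propagation direction, obtained from
the attenuation increase relative to a pre-injection baseline.  From RCS
maps the module extracts axial profiles, wetting-front (WF) distances,
depot aspect ratios, onset and quasi-saturation times, temporal RCS
variation and ROI coefficients of variation.

Coordinate convention: row 0 at the top; "vertical" runs along image rows
(tissue depth), "horizontal" along image columns; the needle tip is given
as (row, col).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from . import constants as C
from .imaging import ImageStack
from .transport import InjectionProtocol, TissueParameters

__all__ = [
    "WFTrace",
    "RCSProfileSeries",
    "ROIStats",
    "rcs_map",
    "rcs_profile",
    "build_rcs_series",
    "rcs_temporal_variation",
    "detect_wf",
    "track_wf",
    "aspect_ratio",
    "onset_time",
    "quasi_saturation_time",
    "roi_cv",
    "define_rois",
]

Direction = Literal["horizontal", "vertical"]


@dataclass
class WFTrace:
    """Per-frame wetting-front distances from the needle tip.

    wf_h / wf_v in mm; NaN marks frames where no front was detectable.
    Region labels: "IR" (injection region, t <= Q/q) or "DR" (diffusion
    region, after the end of infusion).
    """

    times_s: np.ndarray
    wf_h_mm: np.ndarray
    wf_v_mm: np.ndarray
    region: np.ndarray  # array of "IR"/"DR" strings

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.wf_h_mm = np.asarray(self.wf_h_mm, dtype=float)
        self.wf_v_mm = np.asarray(self.wf_v_mm, dtype=float)
        self.region = np.asarray(self.region)
        n = self.times_s.size
        if not (self.wf_h_mm.size == self.wf_v_mm.size == self.region.size == n):
            raise ValueError("all trace fields must share one length")
        with np.errstate(invalid="ignore"):
            if np.any(self.wf_h_mm < 0) or np.any(self.wf_v_mm < 0):
                raise ValueError("WF distances must be nonnegative")

    def in_region(self, region: str) -> np.ndarray:
        return self.region == region


@dataclass
class RCSProfileSeries:
    """Normalized RCS profiles vs distance from the needle, over time."""

    direction: Direction
    distances_mm: np.ndarray
    values: np.ndarray  # (T, N), normalized to a global max of 1
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(np.diff(self.distances_mm) <= 0) or np.any(self.distances_mm < 0):
            raise ValueError("distances must be nonnegative and increasing")
        if self.values.shape != (self.times_s.size, self.distances_mm.size):
            raise ValueError("values must be (n_times, n_distances)")


@dataclass
class ROIStats:
    """Per-frame intensity statistics of one region of interest."""

    name: str
    bounds: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    times_s: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    cv: np.ndarray  # sigma/mu, NaN where mu == 0


# --------------------------------------------------------------------------- #
# RCS maps and profiles
# --------------------------------------------------------------------------- #


def rcs_map(
    frame: np.ndarray,
    baseline: np.ndarray,
    mu_abs_per_mm: float = C.DEFAULT_MU_ABS_PER_MM,
) -> np.ma.MaskedArray:
    """Added solution path length per pixel [mm]: ln(baseline/frame)/mu.

    ``frame`` and ``baseline`` are transmission maps; the baseline comes
    from frames acquired before injection onset.  Negative values (noise)
    are clipped to zero; non-positive or masked pixels propagate as masks.
    """
    if mu_abs_per_mm <= 0:
        raise ValueError("absorption coefficient must be positive")
    f = np.ma.asarray(frame).astype(float)
    b = np.ma.asarray(baseline).astype(float)
    invalid = (
        np.ma.getmaskarray(f)
        | np.ma.getmaskarray(b)
        | (f.filled(0.0) <= 0)
        | (b.filled(0.0) <= 0)
    )
    ratio = np.where(invalid, 1.0, b.filled(1.0) / np.where(f.filled(1.0) <= 0, 1.0, f.filled(1.0)))
    rcs = np.log(ratio) / mu_abs_per_mm
    rcs = np.clip(rcs, 0.0, None)
    return np.ma.MaskedArray(rcs, mask=invalid)


def _window_px(window_mm: float, pixel_size_um: float) -> int:
    w = max(1, int(round(window_mm * 1000.0 / pixel_size_um)))
    return w


def rcs_profile(
    rcs: np.ndarray,
    needle_tip: tuple[int, int],
    direction: Direction,
    pixel_size_um: float,
    window_mm: float = C.DEFAULT_ROI_SIZE_MM,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial RCS profile: sliding-window averages outward from the needle.

    A ``window_mm`` x ``window_mm`` box is slid along the chosen axis
    (columns for "horizontal", rows for "vertical", in the direction of
    increasing index) and its mean RCS recorded per step of one pixel.
    Returns (distances_mm, values); with ``normalize`` the profile is scaled
    by its own maximum (series-level normalization uses the global maximum,
    see :func:`build_rcs_series`).
    """
    arr = np.ma.asarray(rcs).astype(float)
    h, w = arr.shape
    r0, c0 = needle_tip
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("needle tip must lie inside the frame")
    wpx = _window_px(window_mm, pixel_size_um)
    if wpx > min(h, w):
        raise ValueError("averaging window larger than frame")
    filled = arr.filled(0.0)
    smoothed = ndimage.uniform_filter(filled, size=wpx, mode="nearest")
    half = wpx // 2
    if r0 - half < 0 or c0 - half < 0 or r0 + half >= h or c0 + half >= w:
        warnings.warn("needle near border: averaging window truncated", stacklevel=2)
    if direction == "horizontal":
        line = smoothed[r0, c0:]
    elif direction == "vertical":
        line = smoothed[r0:, c0]
    else:
        raise ValueError("direction must be 'horizontal' or 'vertical'")
    distances = np.arange(line.size) * pixel_size_um * 1e-3
    values = line.copy()
    if normalize:
        peak = values.max()
        if peak > 0:
            values = values / peak
    return distances, values


def build_rcs_series(
    rcs_maps: Sequence[np.ndarray],
    times_s: Sequence[float],
    needle_tip: tuple[int, int],
    direction: Direction,
    pixel_size_um: float,
    window_mm: float = C.DEFAULT_ROI_SIZE_MM,
) -> RCSProfileSeries:
    """Profiles for a whole sequence, normalized by the global maximum.

    A single normalization constant across all times keeps temporal
    comparisons on one scale.
    """
    profiles = []
    distances = None
    for m in rcs_maps:
        d, v = rcs_profile(m, needle_tip, direction, pixel_size_um, window_mm, normalize=False)
        distances = d
        profiles.append(v)
    values = np.stack(profiles, axis=0)
    peak = values.max()
    if peak > 0:
        values = values / peak
    return RCSProfileSeries(
        direction=direction,
        distances_mm=distances,
        values=values,
        times_s=np.asarray(times_s, dtype=float),
    )


def rcs_temporal_variation(
    profile_t1: np.ndarray,
    profile_t2: np.ndarray,
    t1: float,
    t2: float,
) -> np.ndarray:
    """Pointwise RCS change rate (RCS(t2) - RCS(t1)) / (t2 - t1) [1/s]."""
    p1 = np.asarray(profile_t1, dtype=float)
    p2 = np.asarray(profile_t2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("profiles must share one distance grid")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return (p2 - p1) / (t2 - t1)


# --------------------------------------------------------------------------- #
# wetting-front detection
# --------------------------------------------------------------------------- #


def detect_wf(
    distances_mm: np.ndarray,
    values: np.ndarray,
    noise_floor: float = 0.0,
    threshold_fraction: float = 0.1,
) -> float | None:
    """Wetting-front distance: outermost profile crossing of the threshold.

    The profile is median-smoothed over 3 samples, then the front is the
    outermost distance where it exceeds
    ``noise_floor + threshold_fraction * (peak - noise_floor)``.
    Returns None ("no front") when the whole profile stays below threshold —
    distinct from a front at distance 0.
    """
    d = np.asarray(distances_mm, dtype=float)
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("profile must be nonempty")
    if v.size >= 3:
        v = ndimage.median_filter(v, size=3, mode="nearest")
    peak = v.max()
    if peak <= noise_floor:
        return None
    thr = noise_floor + threshold_fraction * (peak - noise_floor)
    above = np.nonzero(v > thr)[0]
    if above.size == 0:
        return None
    return float(d[above[-1]])


def _line_profile(
    rcs: np.ndarray,
    needle_tip: tuple[int, int],
    direction: Direction,
    pixel_size_um: float,
    line_halfwidth_px: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Thin line profile outward from the needle (for WF detection).

    Averages over ``2*line_halfwidth_px + 1`` rows/cols perpendicular to the
    profile axis; unlike the 0.9 mm RCS window this does not smear the front.
    """
    arr = np.ma.asarray(rcs).astype(float).filled(0.0)
    r0, c0 = needle_tip
    hw = line_halfwidth_px
    if direction == "horizontal":
        band = arr[max(r0 - hw, 0) : r0 + hw + 1, c0:]
        line = band.mean(axis=0)
    elif direction == "vertical":
        band = arr[r0:, max(c0 - hw, 0) : c0 + hw + 1]
        line = band.mean(axis=1)
    else:
        raise ValueError("direction must be 'horizontal' or 'vertical'")
    distances = np.arange(line.size) * pixel_size_um * 1e-3
    return distances, line


def track_wf(
    stack: ImageStack,
    protocol: InjectionProtocol,
    tissue: TissueParameters,
    n_baseline: int = 1,
    threshold_fraction: float = 0.1,
) -> WFTrace:
    """Track horizontal and vertical wetting fronts over a corrected stack.

    ``stack`` holds transmission frames; the first ``n_baseline`` frames
    (pre-onset) are averaged into the attenuation baseline.  Per frame the
    RCS map is profiled along thin lines through the needle tip in both
    directions and the front located by :func:`detect_wf`, with the noise
    floor taken from the first frame's own profile.  Samples are labelled
    IR while t <= Q/q and DR afterwards; undetectable fronts propagate as
    NaN.
    """
    if len(stack) <= n_baseline:
        raise ValueError("stack must extend beyond the baseline frames")
    baseline = np.mean(stack.frames[:n_baseline], axis=0)
    t_end = protocol.duration_s
    # noise floor per direction from the first (pre-onset) frame's own profile
    floors: dict[str, float] = {}
    m0 = rcs_map(stack.frames[0], baseline, tissue.mu_abs_per_mm)
    for direction in ("horizontal", "vertical"):
        _, v0 = _line_profile(m0, protocol.needle_tip, direction, stack.pixel_size_um)
        floors[direction] = float(np.median(v0) + 3.0 * np.std(v0))
    times, wf_h, wf_v, region = [], [], [], []
    for i in range(len(stack)):
        m = rcs_map(stack.frames[i], baseline, tissue.mu_abs_per_mm)
        row: dict[str, float] = {}
        for direction in ("horizontal", "vertical"):
            d, v = _line_profile(m, protocol.needle_tip, direction, stack.pixel_size_um)
            wf = detect_wf(d, v, noise_floor=floors[direction], threshold_fraction=threshold_fraction)
            row[direction] = np.nan if wf is None else wf
        t = float(stack.timestamps[i])
        times.append(t)
        wf_h.append(row["horizontal"])
        wf_v.append(row["vertical"])
        region.append("IR" if t <= t_end else "DR")
    return WFTrace(
        times_s=np.array(times),
        wf_h_mm=np.array(wf_h),
        wf_v_mm=np.array(wf_v),
        region=np.array(region),
    )


def aspect_ratio(trace: WFTrace, region: str = "IR") -> tuple[float, float]:
    """Depot aspect ratio WF_v / WF_h over one region: (mean, std).

    The spread is the population standard deviation across the region's
    frames.  Samples with undetected or zero horizontal front are skipped
    with a warning.
    """
    sel = trace.in_region(region)
    if not np.any(sel):
        raise ValueError(f"no samples in region {region!r}")
    wf_h = trace.wf_h_mm[sel]
    wf_v = trace.wf_v_mm[sel]
    usable = np.isfinite(wf_h) & np.isfinite(wf_v) & (wf_h > 0)
    if usable.sum() < sel.sum():
        warnings.warn(
            f"{int(sel.sum() - usable.sum())} samples skipped (missing or zero WF_h)",
            stacklevel=2,
        )
    if not np.any(usable):
        raise ValueError(f"no usable samples in region {region!r}")
    ratios = wf_v[usable] / wf_h[usable]
    return float(np.mean(ratios)), float(np.std(ratios))


# --------------------------------------------------------------------------- #
# onset and saturation timing
# --------------------------------------------------------------------------- #


def onset_time(
    times_s: np.ndarray,
    central_rcs: np.ndarray,
    n_baseline: int = 3,
    n_sustained: int = 3,
) -> float | None:
    """First time the needle-adjacent RCS rises above the baseline band.

    The detection threshold is baseline mean + 3 baseline sigma over the
    first ``n_baseline`` samples, and the exceedance must persist for
    ``n_sustained`` consecutive frames.  Returns None if never exceeded.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(central_rcs, dtype=float)
    if n_baseline < 3:
        raise ValueError("need at least 3 baseline frames")
    if v.size < n_baseline + n_sustained:
        raise ValueError("series too short for onset detection")
    base = v[:n_baseline]
    thr = base.mean() + 3.0 * base.std()
    above = v > thr
    for i in range(n_baseline, v.size - n_sustained + 1):
        if above[i : i + n_sustained].all():
            return float(t[i])
    return None


def quasi_saturation_time(
    times_s: np.ndarray,
    wf_mm: np.ndarray,
    rel_tol: float = 0.01,
    window_s: float = 60.0,
) -> float | None:
    """Earliest time after which the front effectively stops advancing.

    Quasi-saturation is declared at the earliest sample such that, in every
    subsequent sliding window of length ``window_s`` that fits fully inside
    the trace, the relative max-min WF change stays below ``rel_tol``.
    Trailing partial windows are inconclusive and ignored; at least one full
    window must exist after the candidate time.  None if never met.
    """
    t = np.asarray(times_s, dtype=float)
    w = np.asarray(wf_mm, dtype=float)
    if t.size == 0 or t[-1] - t[0] < window_s:
        raise ValueError("trace must span at least one window")
    ok = np.zeros(t.size, dtype=bool)
    for i in range(t.size):
        sel = (t >= t[i]) & np.isfinite(w)
        ws = w[sel]
        ts = t[sel]
        full_starts = np.nonzero(ts + window_s <= t[-1] + 1e-9)[0]
        if ws.size == 0 or full_starts.size == 0:
            continue
        stable = True
        for j in full_starts:
            win = ws[(ts >= ts[j]) & (ts <= ts[j] + window_s)]
            ref = win.max()
            if ref > 0 and (win.max() - win.min()) / ref >= rel_tol:
                stable = False
                break
        ok[i] = stable
    hits = np.nonzero(ok)[0]
    return float(t[hits[0]]) if hits.size else None


# --------------------------------------------------------------------------- #
# ROI statistics
# --------------------------------------------------------------------------- #


def roi_cv(
    stack: ImageStack,
    bounds: tuple[int, int, int, int],
    name: str = "ROI",
) -> ROIStats:
    """Coefficient of variation C_v = sigma/mu of ROI pixels, per frame.

    Population sigma is used.  A zero-mean ROI yields NaN (undefined C_v).
    """
    r0, r1, c0, c1 = bounds
    h, w = stack.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("ROI must lie inside the frames")
    patch = stack.frames[:, r0:r1, c0:c1].reshape(len(stack), -1).astype(float)
    mu = patch.mean(axis=1)
    sigma = patch.std(axis=1)  # population sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu != 0, sigma / np.where(mu == 0, 1.0, mu), np.nan)
    return ROIStats(name=name, bounds=bounds, times_s=stack.timestamps.copy(), mean=mu, std=sigma, cv=cv)


def define_rois(
    needle_tip: tuple[int, int],
    trace: WFTrace,
    pixel_size_um: float,
    frame_shape: tuple[int, int],
    size_mm: float = C.DEFAULT_ROI_SIZE_MM,
) -> dict[str, tuple[int, int, int, int]]:
    """Place the SC / SWF_h / SWF_v analysis boxes.

    SC is centred at the needle tip; SWF_h / SWF_v at the first post-onset
    wetting-front positions along the horizontal / vertical axes.  Boxes
    exceeding the frame are clipped with a warning.
    """
    post = np.isfinite(trace.wf_h_mm) & np.isfinite(trace.wf_v_mm) & (trace.wf_h_mm > 0)
    if not np.any(post):
        raise ValueError("trace has no post-onset sample")
    i0 = int(np.nonzero(post)[0][0])
    px_mm = pixel_size_um * 1e-3
    half = _window_px(size_mm, pixel_size_um) // 2
    r0, c0 = needle_tip
    centers = {
        "SC": (r0, c0),
        "SWF_h": (r0, c0 + int(round(trace.wf_h_mm[i0] / px_mm))),
        "SWF_v": (r0 + int(round(trace.wf_v_mm[i0] / px_mm)), c0),
    }
    h, w = frame_shape
    rois = {}
    for name, (rc, cc) in centers.items():
        rr0, rr1 = rc - half, rc + half
        cc0, cc1 = cc - half, cc + half
        if rr0 < 0 or cc0 < 0 or rr1 > h or cc1 > w:
            warnings.warn(f"ROI {name} exceeds the frame; clipping", stacklevel=2)
        rois[name] = (max(rr0, 0), min(rr1, h), max(cc0, 0), min(cc1, w))
    return rois
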