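"""Preprocessing chain: raw image → quality-filtered, normalized spectra.

Stage order follows the measurement workflow: wavenumber calibration against
reference peaks, interpolation onto a common axis, rubberband (lower convex
hull) background correction, cosmic-spike removal, area normalization over
400–3100 cm⁻¹, substrate/outlier removal by correlation quality control,
and Savitzky–Golay smoothing.  A final renormalization restores the
unit-area contract after smoothing, so downstream concentrations read as
area fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .core import HyperspectralImage, Spectrum, WavenumberAxis, window_trapz

logger = logging.getLogger("pollenraman")

__all__ = [
    "PreprocessConfig",
    "SpikeReport",
    "calibrate_axis",
    "interpolate_axis",
    "rubberband_baseline",
    "rubberband_correct_image",
    "despike",
    "area_normalize",
    "quality_filter",
    "sg_smooth",
    "preprocess",
]

DEFAULT_STAGES = ("calibrate", "interpolate", "rubberband", "despike",
                  "normalize", "quality_filter", "smooth")


@dataclass
class PreprocessConfig:
    """Parameters of the full chain; stages not listed are skipped."""

    calibration_pairs: tuple[tuple[float, float], ...] | None = None
    calibration_degree: int = 1
    target_axis: tuple[float, float, float] | None = (400.0, 3100.0, 2.0)
    despike_window: int = 5
    despike_zmax: float = 25.0
    normalization_range: tuple[float, float] = (400.0, 3100.0)
    qc_threshold: float = 0.75
    qc_ch_window: tuple[float, float] = (2800.0, 3010.0)
    sg_window: int = 9
    sg_order: int = 2
    stages: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self):
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise ValueError("despike window must be odd and >= 3")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValueError("SG window must be odd and >= 3")
        if self.sg_order >= self.sg_window:
            raise ValueError("SG order must be < window length")
        if not (0 < self.qc_threshold < 1):
            raise ValueError("QC threshold must be in (0, 1)")
        if self.despike_zmax <= 0:
            raise ValueError("despike zmax must be > 0")
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")


# ---------------------------------------------------------------------------
# wavenumber calibration and interpolation
# ---------------------------------------------------------------------------

def calibrate_axis(img: HyperspectralImage,
                   peak_pairs: "Sequence[tuple[float, float]]",
                   degree: int = 1) -> HyperspectralImage:
    """Map the measured axis onto reference band positions.

    Least-squares polynomial fit of measured → reference peak positions
    (e.g., a paracetamol reference table) applied to the whole axis; fit
    residuals are recorded in the history.
    """
    if degree not in (1, 2):
        raise ValueError("calibration degree must be 1 or 2")
    pairs = np.asarray(peak_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < degree + 1:
        raise ValueError(f"need at least {degree + 1} (measured, reference) pairs")
    coeffs = np.polyfit(pairs[:, 0], pairs[:, 1], degree)
    resid = np.polyval(coeffs, pairs[:, 0]) - pairs[:, 1]
    new_axis = WavenumberAxis(np.polyval(coeffs, img.axis.values))
    out = img.copy_with(axis=new_axis)
    out.log("calibrate_axis", degree=degree, n_pairs=len(pairs),
            coeffs=coeffs.tolist(), rms_residual=float(np.sqrt(np.mean(resid ** 2))))
    return out


def interpolate_axis(img: HyperspectralImage,
                     target: WavenumberAxis) -> HyperspectralImage:
    """Channel-wise linear interpolation of every pixel onto a common axis."""
    lo, hi = img.axis.span
    if target.values[0] < lo or target.values[-1] > hi:
        raise ValueError(
            f"extrapolation requested: target {target.span} outside "
            f"source axis {img.axis.span}")
    x, xt = img.axis.values, target.values
    data = np.empty((img.n_pixels, len(target)))
    for i in range(img.n_pixels):
        data[i] = np.interp(xt, x, img.data[i])
    out = img.copy_with(data=data, axis=target)
    out.log("interpolate_axis", lo=float(xt[0]), hi=float(xt[-1]),
            n_channels=len(target))
    return out


# ---------------------------------------------------------------------------
# rubberband baseline
# ---------------------------------------------------------------------------

def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of (x, y), endpoints included.

    Uses Qhull; falls back to a monotone-chain scan for degenerate
    (collinear) input where Qhull cannot build a 2-D hull.
    """
    n = x.size
    try:
        from scipy.spatial import ConvexHull, QhullError
        hull = ConvexHull(np.column_stack([x, y]))
        v = hull.vertices  # counter-clockwise; leftmost (0) and rightmost
        v = np.roll(v, -int(np.nonzero(v == 0)[0][0]))
        # CCW from the leftmost vertex walks the lower chain first,
        # ending at the rightmost vertex (index n-1)
        end = int(np.nonzero(v == n - 1)[0][0])
        return np.sort(v[:end + 1])
    except (QhullError, IndexError):
        # monotone chain, lower hull only
        idx = [0]
        for i in range(1, n):
            while len(idx) >= 2:
                a, b = idx[-2], idx[-1]
                cross = (x[b] - x[a]) * (y[i] - y[a]) - \
                        (y[b] - y[a]) * (x[i] - x[a])
                if cross <= 0:
                    idx.pop()
                else:
                    break
            idx.append(i)
        return np.asarray(idx)


def rubberband_baseline(spectrum: Spectrum | tuple[WavenumberAxis, np.ndarray]
                        ) -> tuple[Spectrum, Spectrum]:
    """Lower-convex-hull ("rubberband") background of one spectrum.

    Returns ``(baseline, corrected)`` with ``corrected = input − baseline``;
    the corrected spectrum is ≥ 0 everywhere and exactly 0 at every hull
    vertex, and baseline + corrected reproduces the input exactly.
    """
    if isinstance(spectrum, Spectrum):
        axis, y = spectrum.axis, spectrum.intensities
    else:
        axis, y = spectrum
        y = np.asarray(y, dtype=float)
    if len(axis) < 3:
        raise ValueError("rubberband needs at least 3 channels")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    base = _rubberband_row(axis.values, y)
    return Spectrum(axis, base), Spectrum(axis, y - base)


def _rubberband_row(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    idx = _lower_hull_indices(x, y)
    base = np.interp(x, x[idx], y[idx])
    # guard rounding so corrected = y - base stays >= 0 while base+corr == y
    return np.minimum(base, y)


def rubberband_correct_image(img: HyperspectralImage) -> HyperspectralImage:
    """Apply the rubberband correction to every pixel spectrum."""
    x = img.axis.values
    data = np.empty_like(img.data)
    for i in range(img.n_pixels):
        data[i] = img.data[i] - _rubberband_row(x, img.data[i])
    out = img.copy_with(data=data)
    out.log("rubberband", n_pixels=img.n_pixels)
    return out


# ---------------------------------------------------------------------------
# cosmic spike removal
# ---------------------------------------------------------------------------

@dataclass
class SpikeReport:
    """Flagged cosmic-ray events: (pixel, channel, original, replacement)."""

    events: list[tuple[int, int, float, float]] = field(default_factory=list)
    masked_pixels: list[int] = field(default_factory=list)

    @property
    def n_spikes(self) -> int:
        return len(self.events)

    def channels(self) -> set[tuple[int, int]]:
        return {(p, c) for p, c, _, _ in self.events}


def despike(img: HyperspectralImage, window: int = 5, zmax: float = 25.0
            ) -> tuple[HyperspectralImage, SpikeReport]:
    """Robust-z cosmic spike removal per spectrum.

    Residuals against a running median (``window`` channels) are scored by
    1.4826·MAD; channels with residual > zmax·scale are replaced by linear
    interpolation between the nearest unflagged neighbors.  Spikes are
    positive single-channel events, so only positive residuals are flagged.
    A spectrum whose channels are all flagged is masked out instead.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if zmax <= 0:
        raise ValueError("zmax must be > 0")
    data = img.data.copy()
    med = median_filter(data, size=(1, window), mode="nearest")
    resid = data - med
    mad = np.median(np.abs(resid), axis=1)
    scale = 1.4826 * mad
    # noiseless smooth spectra have MAD ~ 0 (median filter is exact on
    # monotone stretches); floor the scale at 0.1% of the spectrum range so
    # band curvature is never mistaken for a cosmic event
    floor = 1e-3 * np.ptp(data, axis=1)
    scale = np.maximum(scale, np.maximum(floor, np.finfo(float).tiny))
    flags = resid > zmax * scale[:, None]

    report = SpikeReport()
    mask = img.mask.copy()
    n_chan = data.shape[1]
    cols = np.arange(n_chan)
    for i in np.nonzero(flags.any(axis=1))[0]:
        f = flags[i]
        if f.all():
            mask[i] = False
            report.masked_pixels.append(int(i))
            continue
        good = ~f
        repl = np.interp(cols[f], cols[good], data[i, good])
        for j, r in zip(np.nonzero(f)[0], repl):
            report.events.append((int(i), int(j), float(data[i, j]), float(r)))
        data[i, f] = repl
    out = img.copy_with(data=data, mask=mask)
    out.log("despike", window=window, zmax=zmax, n_spikes=report.n_spikes,
            n_masked=len(report.masked_pixels))
    return out, report


# ---------------------------------------------------------------------------
# normalization, quality control, smoothing
# ---------------------------------------------------------------------------

def area_normalize(img: HyperspectralImage,
                   range: tuple[float, float] = (400.0, 3100.0)
                   ) -> HyperspectralImage:
    """Scale each retained spectrum to unit trapezoidal area over ``range``.

    Pixels with a nonpositive integral cannot be normalized; they are
    masked out with a warning rather than propagated.
    """
    lo, hi = range
    if not img.axis.covers(lo, hi):
        raise ValueError(
            f"normalization range [{lo}, {hi}] not covered by axis "
            f"{img.axis.span}")
    areas = window_trapz(img.axis, img.data, lo, hi)
    bad = img.mask & (areas <= 0)
    if bad.any():
        logger.warning("area_normalize: masking %d pixel(s) with "
                       "nonpositive integral", int(bad.sum()))
    mask = img.mask & ~bad
    data = img.data.copy()
    ok = areas > 0
    data[ok] = data[ok] / areas[ok, None]
    out = img.copy_with(data=data, mask=mask)
    out.log("area_normalize", lo=lo, hi=hi, n_masked=int(bad.sum()))
    return out


def _otsu_threshold(values: np.ndarray) -> float:
    from skimage.filters import threshold_otsu
    return float(threshold_otsu(values))


def quality_filter(img: HyperspectralImage, threshold: float = 0.75,
                   ch_window: tuple[float, float] = (2800.0, 3010.0)
                   ) -> HyperspectralImage:
    """Two-stage substrate/outlier removal.

    Stage 1 separates grain from slide: foreground candidates are pixels
    whose CH-stretch band integral exceeds an automatic two-class (Otsu)
    threshold over the image.  Stage 2 removes outliers: candidates whose
    Pearson correlation with the candidate mean spectrum falls below
    ``threshold`` are dropped, and the test is repeated once against the
    refined mean.  Only the mask is updated; no data is deleted.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    ch = window_trapz(img.axis, img.data, *ch_window)
    active = img.mask.copy()
    vals = ch[active]
    if vals.size == 0:
        raise ValueError("no foreground: image has no retained pixels")
    cut = _otsu_threshold(vals) if np.unique(vals).size > 1 else vals[0] - 1
    candidates = active & (ch > cut)
    if not candidates.any():
        raise ValueError("no foreground: no pixel passes the CH-band threshold")
    rest = active & ~candidates
    if rest.any():
        # the two-class split must show real contrast: organic grain pixels
        # carry far more CH signal than the slide; a near-unimodal split
        # (e.g., an all-substrate image) is not a foreground
        hi, lo = float(np.mean(ch[candidates])), float(np.mean(ch[rest]))
        if not (hi > 3.0 * max(lo, 0.0) + 1e-300):
            raise ValueError("no foreground: CH-band contrast too weak to "
                             "separate grain from substrate")

    kept = candidates.copy()
    for _ in range(2):  # initial pass + one refinement with the updated mean
        mean = img.data[kept].mean(axis=0)
        r = _pearson_to_reference(img.data, mean)
        kept = candidates & (r >= threshold)
        if not kept.any():
            raise ValueError("no foreground: correlation filter removed "
                             "all candidates")
    out = img.copy_with(mask=kept)
    out.log("quality_filter", threshold=threshold,
            n_candidates=int(candidates.sum()), n_retained=int(kept.sum()))
    return out


def _pearson_to_reference(data: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of each row against a reference spectrum (NaN-safe → -1)."""
    dc = data - data.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    denom = np.linalg.norm(dc, axis=1) * np.linalg.norm(rc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dc @ rc) / denom
    return np.where(np.isfinite(r), r, -1.0)


def sg_smooth(img: HyperspectralImage, window: int = 9, order: int = 2
              ) -> HyperspectralImage:
    """Savitzky–Golay smoothing of every spectrum (edges by truncated fit)."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if order >= window:
        raise ValueError("order must be < window")
    if window > img.data.shape[1]:
        raise ValueError("window longer than spectrum")
    data = savgol_filter(img.data, window, order, axis=1, mode="interp")
    out = img.copy_with(data=data)
    out.log("sg_smooth", window=window, order=order)
    return out


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def preprocess(img: HyperspectralImage,
               config: PreprocessConfig | None = None) -> HyperspectralImage:
    """Run the enabled stages in the fixed chain order.

    Order: calibrate → interpolate → rubberband → despike → normalize →
    quality_filter → smooth, followed by a renormalization when both
    normalize and smooth ran, so the final output keeps unit area.
    """
    if config is None:
        config = PreprocessConfig()
    out = img
    enabled = [s for s in DEFAULT_STAGES if s in config.stages]
    for stage in enabled:
        if stage == "calibrate":
            if config.calibration_pairs is None:
                continue  # no reference table supplied -> nothing to correct
            out = calibrate_axis(out, config.calibration_pairs,
                                 config.calibration_degree)
        elif stage == "interpolate":
            lo, hi, step = config.target_axis
            n = int(round((hi - lo) / step)) + 1
            out = interpolate_axis(out, WavenumberAxis(lo + step * np.arange(n)))
        elif stage == "rubberband":
            out = rubberband_correct_image(out)
        elif stage == "despike":
            out, _ = despike(out, config.despike_window, config.despike_zmax)
        elif stage == "normalize":
            out = area_normalize(out, config.normalization_range)
        elif stage == "quality_filter":
            out = quality_filter(out, config.qc_threshold, config.qc_ch_window)
        elif stage == "smooth":
            out = sg_smooth(out, config.sg_window, config.sg_order)
    if "smooth" in enabled and "normalize" in enabled:
        out = area_normalize(out, config.normalization_range)
    return out
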