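"""Core domain types and hyperspectral image plumbing.

A Raman image is a rectangular grid of pixels, each carrying one spectrum on
a shared wavenumber axis.  The whole image is stored as the matrix ``D`` of
shape ``(width * height, n_channels)`` — the object every later stage
(baseline correction, clustering, curve resolution) operates on.  Pixels are
0-based, row-major, origin top-left; pixel index ``i = y * width + x``.

Intensities are arbitrary detector units throughout; only relative /
normalized quantities are ever interpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pollenraman")

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "HyperspectralImage",
    "IntensityMap",
    "load_image",
    "save_image",
    "band_integral",
    "mean_spectrum",
    "window_trapz",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing spectral axis in cm⁻¹ (Raman shift)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavenumber axis needs at least 2 values")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavenumber axis must be finite")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def covers(self, lo: float, hi: float) -> bool:
        return self.values[0] <= lo and hi <= self.values[-1]

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels with lo <= ν <= hi."""
        return (self.values >= lo) & (self.values <= hi)


@dataclass(frozen=True)
class Spectrum:
    axis: WavenumberAxis
    intensities: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (len(self.axis),):
            raise ValueError("intensity length must match axis length")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "intensities", y)


@dataclass
class HyperspectralImage:
    """Grid of spectra; ``data`` is the pixels × channels matrix D.

    ``mask`` marks pixels retained after quality control (all True on load);
    ``meta`` carries provenance, including an append-only ``history`` list of
    ``{"op": ..., **params}`` records — every processing stage appends one.
    """

    width: int
    height: int
    axis: WavenumberAxis
    data: np.ndarray
    mask: np.ndarray | None = None
    pixel_size: float = 1.0  # µm, instrument step size
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("image must have at least one pixel")
        self.data = np.asarray(self.data, dtype=float)
        n = self.width * self.height
        if self.data.shape != (n, len(self.axis)):
            raise ValueError(
                f"data shape {self.data.shape} != ({n}, {len(self.axis)})")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n,):
            raise ValueError("mask length must equal pixel count")
        self.meta.setdefault("history", [])

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    @property
    def history(self) -> list[dict]:
        return self.meta["history"]

    def log(self, op: str, **params) -> None:
        """Append one record to the processing history (append-only)."""
        self.meta["history"].append({"op": op, **params})
        logger.info("stage=%s %s", op,
                    " ".join(f"{k}={v!r}" for k, v in params.items()))

    def pixel_index(self, x: int, y: int) -> int:
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise IndexError(f"pixel ({x}, {y}) outside grid")
        return y * self.width + x

    def retained_matrix(self) -> np.ndarray:
        """Spectra of retained pixels, in pixel order."""
        return self.data[self.mask]

    def copy_with(self, *, data=None, axis=None, mask=None) -> "HyperspectralImage":
        import copy as _copy
        return HyperspectralImage(
            width=self.width, height=self.height,
            axis=self.axis if axis is None else axis,
            data=self.data.copy() if data is None else data,
            mask=self.mask.copy() if mask is None else mask,
            pixel_size=self.pixel_size,
            meta=_copy.deepcopy(self.meta),
        )


@dataclass(frozen=True)
class IntensityMap:
    """One scalar per pixel, integrated over a wavenumber window."""

    width: int
    height: int
    values: np.ndarray
    window: tuple[float, float]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.width * self.height,):
            raise ValueError("values length must equal pixel count")
        object.__setattr__(self, "values", v)

    def grid(self) -> np.ndarray:
        """(height, width) array, y-down, for rendering."""
        return self.values.reshape(self.height, self.width)


# ---------------------------------------------------------------------------
# I/O — long and wide delimited text
# ---------------------------------------------------------------------------

def load_image(path, format: str = "wide_csv", pixel_size: float = 1.0,
               meta: dict | None = None) -> HyperspectralImage:
    """Read a hyperspectral image from delimited text.

    long_csv: columns ``x,y,wavenumber,intensity`` (optional ``retained``);
    wide_csv: header ``x,y[,retained],<ν1>,<ν2>,...``, one row per pixel.
    The grid must be a complete rectangle; channels are sorted into a
    strictly increasing axis (duplicate wavenumbers are an error).
    """
    path = Path(path)
    if format == "long_csv":
        df = pd.read_csv(path)
        required = {"x", "y", "wavenumber", "intensity"}
        if not required.issubset(df.columns):
            raise ValueError(f"long CSV needs columns {sorted(required)}")
        xs = np.sort(df["x"].unique())
        ys = np.sort(df["y"].unique())
        wns = np.sort(df["wavenumber"].unique())
        if np.unique(wns).size != wns.size or np.any(np.diff(wns) <= 0):
            raise ValueError("duplicate or non-monotone wavenumbers")
        width, height, nchan = xs.size, ys.size, wns.size
        pivot = df.pivot_table(index=["y", "x"], columns="wavenumber",
                               values="intensity", aggfunc="first")
        pivot = pivot.reindex(
            pd.MultiIndex.from_product([ys, xs], names=["y", "x"]))
        pivot = pivot.reindex(columns=wns)
        if pivot.isna().any().any():
            bad = pivot.index[pivot.isna().any(axis=1)][0]
            raise ValueError(
                f"incomplete grid: pixel (x={bad[1]}, y={bad[0]}) has "
                "missing channels")
        data = pivot.to_numpy(dtype=float)
        mask = None
        if "retained" in df.columns:
            m = df.drop_duplicates(["y", "x"]).set_index(["y", "x"])["retained"]
            m = m.reindex(pd.MultiIndex.from_product([ys, xs]))
            mask = m.to_numpy(dtype=float).astype(bool)
        axis = WavenumberAxis(wns)
    elif format == "wide_csv":
        df = pd.read_csv(path)
        if df.shape[0] == 0:
            raise ValueError("empty image: no pixel rows")
        cols = list(df.columns)
        if cols[:2] != ["x", "y"]:
            raise ValueError("wide CSV must start with x,y columns")
        has_mask = len(cols) > 2 and cols[2] == "retained"
        spec_cols = cols[3:] if has_mask else cols[2:]
        wns = np.array([float(c) for c in spec_cols])
        order = np.argsort(wns)
        wns = wns[order]
        if np.any(np.diff(wns) <= 0):
            raise ValueError("duplicate or non-monotone wavenumbers")
        xs = np.sort(df["x"].unique())
        ys = np.sort(df["y"].unique())
        width, height = xs.size, ys.size
        df = df.set_index(["y", "x"])
        full = pd.MultiIndex.from_product([ys, xs], names=["y", "x"])
        missing = full.difference(df.index)
        if len(missing) or len(df) != len(full):
            if len(missing):
                bad = missing[0]
                raise ValueError(
                    f"incomplete grid: missing pixel (x={bad[1]}, y={bad[0]})")
            raise ValueError("incomplete grid: duplicate pixel rows")
        df = df.reindex(full)
        data = df[spec_cols].to_numpy(dtype=float)[:, order]
        mask = (df["retained"].to_numpy(dtype=float).astype(bool)
                if has_mask else None)
        axis = WavenumberAxis(wns)
    else:
        raise ValueError(f"unknown format {format!r}")
    img = HyperspectralImage(width=width, height=height, axis=axis,
                             data=data, mask=mask, pixel_size=pixel_size,
                             meta=dict(meta or {}))
    img.log("load_image", path=str(path), format=format)
    return img


def save_image(img: HyperspectralImage, path, format: str = "wide_csv") -> None:
    """Write an image so that :func:`load_image` round-trips it.

    Pandas emits shortest round-tripping float representations, so reload
    reproduces the values bit-compatibly for the CSV dialect.  The mask is
    persisted as a ``retained`` 0/1 sidecar column.
    """
    if img.n_pixels == 0:
        raise ValueError("cannot save an empty image")
    path = Path(path)
    xs = np.tile(np.arange(img.width), img.height)
    ys = np.repeat(np.arange(img.height), img.width)
    if format == "wide_csv":
        out = pd.DataFrame({"x": xs, "y": ys,
                            "retained": img.mask.astype(int)})
        spec = pd.DataFrame(img.data, columns=[repr(float(v)) for v in
                                               img.axis.values])
        pd.concat([out, spec], axis=1).to_csv(path, index=False)
    elif format == "long_csv":
        n, c = img.data.shape
        out = pd.DataFrame({
            "x": np.repeat(xs, c),
            "y": np.repeat(ys, c),
            "wavenumber": np.tile(img.axis.values, n),
            "intensity": img.data.ravel(),
            "retained": np.repeat(img.mask.astype(int), c),
        })
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# band-window integrals and summary spectra
# ---------------------------------------------------------------------------

def window_trapz(axis: WavenumberAxis, data: np.ndarray,
                 lo: float, hi: float) -> np.ndarray:
    """Trapezoidal integral of each row of ``data`` over [lo, hi].

    The window edges are included by linear interpolation, so the integral
    is exactly additive over adjacent windows and exact for windows that do
    not start or end on a grid point.
    """
    x = axis.values
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    lo_c, hi_c = max(lo, x[0]), min(hi, x[-1])
    if lo_c >= hi_c:
        raise ValueError(f"window [{lo}, {hi}] outside axis span {axis.span}")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    interior = (x > lo_c) & (x < hi_c)
    y_lo = _interp_columns(x, data, lo_c)
    y_hi = _interp_columns(x, data, hi_c)
    xs = np.concatenate(([lo_c], x[interior], [hi_c]))
    ys = np.column_stack([y_lo, data[:, interior], y_hi])
    return np.trapezoid(ys, xs, axis=1)


def _interp_columns(x: np.ndarray, data: np.ndarray, x0: float) -> np.ndarray:
    """Linear interpolation of every row of data at a single abscissa."""
    j = int(np.searchsorted(x, x0))
    if x[j] == x0:
        return data[:, j]
    t = (x0 - x[j - 1]) / (x[j] - x[j - 1])
    return (1.0 - t) * data[:, j - 1] + t * data[:, j]


def band_integral(img: HyperspectralImage,
                  window: tuple[float, float]) -> IntensityMap:
    """Per-pixel trapezoidal band intensity over a wavenumber window.

    Raw (no interior baseline subtraction); masked-out pixels map to NaN.
    """
    lo, hi = window
    vals = window_trapz(img.axis, img.data, lo, hi)
    vals = np.where(img.mask, vals, np.nan)
    return IntensityMap(width=img.width, height=img.height,
                        values=vals, window=(float(lo), float(hi)))


def mean_spectrum(img: HyperspectralImage,
                  mask: np.ndarray | None = None) -> tuple[Spectrum, Spectrum]:
    """Channel-wise mean and population sd over retained pixels."""
    m = img.mask if mask is None else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask: no retained pixels")
    sub = img.data[m]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    return Spectrum(img.axis, mean), Spectrum(img.axis, sd)
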