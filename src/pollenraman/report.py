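"""End-to-end orchestration: simulate → preprocess → HCA → MCR → report.

``run_pipeline`` executes the whole analysis from a :class:`RunConfig` and
writes every artifact (CSV tables, label maps, concentration maps, figures)
plus a manifest with SHA-256 checksums, so reruns are verifiable
end-to-end.  Every figure has a machine-readable CSV twin; figures are
rendering only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import importlib

from . import cluster as _cluster
from . import mcr as _mcr
from . import synth as _synth

# `preprocess` names both the submodule and the chain entry point, so fetch
# the module explicitly rather than through the package attribute
_pre = importlib.import_module(__package__ + ".preprocess")
from .core import HyperspectralImage, band_integral, load_image, mean_spectrum

logger = logging.getLogger("pollenraman")

__all__ = ["RunConfig", "run_pipeline", "render_report", "DEFAULT_WINDOWS"]

#: diagnostic band windows: CH stretch, sporopollenin, amide I / C=C
DEFAULT_WINDOWS = (("ch_stretch", 2800.0, 3010.0),
                   ("sporopollenin", 1570.0, 1620.0),
                   ("amide_lipid", 1620.0, 1680.0))


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    input_paths: tuple[str, ...] = ()
    phantom: _synth.PhantomSpec | None = None
    n_phantoms: int = 1
    preprocess: _pre.PreprocessConfig = field(
        default_factory=_pre.PreprocessConfig)
    k_cluster: int = 5
    k_mcr: int = 5
    max_exact_n: int = 20_000
    band_windows: tuple = DEFAULT_WINDOWS
    outdir: str = "pollenraman_out"
    seed: int = 0
    figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if self.k_cluster < 1 or self.k_mcr < 1:
            raise ValueError("k must be >= 1")
        if not self.input_paths and self.phantom is None:
            self.phantom = _synth.PhantomSpec()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the artifact manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    for p in config.input_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"stage=inputs missing input path: {p}")
    images: list[HyperspectralImage] = []
    truths: list[_synth.GroundTruth] = []
    if config.input_paths:
        for p in config.input_paths:
            images.append(load_image(p, format="wide_csv"))
    else:
        for i in range(config.n_phantoms):
            spec = dataclasses.replace(config.phantom,
                                       seed=config.seed + i)
            img, truth, _ = _synth.simulate_phantom(spec)
            images.append(img)
            truths.append(truth)

    # ---- preprocess -------------------------------------------------------
    try:
        processed = [_pre.preprocess(im, config.preprocess) for im in images]
    except ValueError as exc:
        raise ValueError(f"stage=preprocess {exc}") from exc

    # ---- HCA --------------------------------------------------------------
    hca = _cluster.hca_images(processed, k=config.k_cluster,
                              max_exact_n=config.max_exact_n,
                              seed=config.seed)

    # ---- MCR-ALS ----------------------------------------------------------
    D = np.concatenate([im.retained_matrix() for im in processed])
    if config.k_mcr == config.k_cluster:
        S0 = hca.mean_spectra
    else:
        S0 = _cluster.hca_images(processed, k=config.k_mcr,
                                 max_exact_n=config.max_exact_n,
                                 seed=config.seed).mean_spectra
    result = _mcr.mcr_als(D, S0, processed[0].axis,
                          component_names=[f"component_{i + 1}"
                                           for i in range(config.k_mcr)])

    grain_slices = []
    start = 0
    for im in processed:
        n = int(im.mask.sum())
        grain_slices.append(slice(start, start + n))
        start += n
    grain_meta = [{"grain_id": im.meta.get("sample_id", f"grain{i}"),
                   "species": im.meta.get("species"),
                   "site": im.meta.get("site")}
                  for i, im in enumerate(images)]
    grain_table = _mcr.grain_mean_concentrations(result, grain_meta,
                                                 grain_slices)

    # ---- report -----------------------------------------------------------
    manifest = render_report(outdir, processed, hca, result, grain_table,
                             config)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("stage=run_pipeline artifacts=%d outdir=%s",
                len(manifest["artifacts"]), outdir)
    return manifest


def render_report(outdir: Path, images: list[HyperspectralImage],
                  hca: _cluster.ClusterResult, result: _mcr.MCRResult,
                  grain_table: pd.DataFrame, config: RunConfig) -> dict:
    """Write tables, maps and figures; return the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_csv(name: str, df: pd.DataFrame):
        p = outdir / name
        df.to_csv(p, index=False)
        artifacts[name] = _sha256(p)

    axis = images[0].axis

    # component spectra + fit report
    scols = {"wavenumber": axis.values}
    names = result.component_names or tuple(
        f"component_{i + 1}" for i in range(result.S.shape[0]))
    for name, row in zip(names, result.S):
        scols[name] = row
    save_csv("mcr_spectra.csv", pd.DataFrame(scols))
    save_csv("grain_mean_concentrations.csv", grain_table)
    fit = pd.DataFrame([{"n_iter": result.n_iter,
                         "lack_of_fit_percent": result.lof_percent,
                         "r_squared": result.r_squared,
                         "converged": result.converged}])
    save_csv("mcr_fit_report.csv", fit)

    mcols = {"wavenumber": axis.values}
    for c, row in enumerate(hca.mean_spectra, start=1):
        mcols[f"cluster_{c}"] = row
    save_csv("cluster_mean_spectra.csv", pd.DataFrame(mcols))

    per_image_rows = []
    start = 0
    for i, im in enumerate(images):
        gid = im.meta.get("sample_id", f"grain{i}")
        lab = hca.labels[i].reshape(im.height, im.width)
        save_csv(f"cluster_map_{i}.csv", pd.DataFrame(lab))

        total = band_integral(im, (axis.values[0], axis.values[-1]))
        save_csv(f"total_intensity_map_{i}.csv", pd.DataFrame(total.grid()))
        for label, lo, hi in config.band_windows:
            bm = band_integral(im, (lo, hi))
            save_csv(f"band_map_{label}_{i}.csv", pd.DataFrame(bm.grid()))

        mean, sd = mean_spectrum(im)
        save_csv(f"mean_spectrum_{i}.csv", pd.DataFrame(
            {"wavenumber": axis.values, "mean": mean.intensities,
             "sd": sd.intensities}))

        n = int(im.mask.sum())
        conc = np.full((im.n_pixels, result.C.shape[1]), np.nan)
        conc[im.mask] = result.C[start:start + n]
        start += n
        for ci, name in enumerate(names):
            save_csv(f"concentration_map_{name}_{i}.csv",
                     pd.DataFrame(conc[:, ci].reshape(im.height, im.width)))
        per_image_rows.append({"image": i, "grain_id": gid,
                               "n_retained": n})
    save_csv("images_summary.csv", pd.DataFrame(per_image_rows))

    if config.figures:
        _render_figures(outdir, images, hca, result, grain_table, config,
                        artifacts)
    return {"seed": config.seed, "k_cluster": config.k_cluster,
            "k_mcr": config.k_mcr, "artifacts": artifacts}


def _render_figures(outdir, images, hca, result, grain_table, config,
                    artifacts):
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.colors import ListedColormap
    from matplotlib.figure import Figure

    def save_fig(fig, name):
        p = outdir / name
        FigureCanvasAgg(fig)
        fig.savefig(p, dpi=100, metadata={"Software": None})
        artifacts[name] = _sha256(p)

    axis = images[0].axis
    names = result.component_names or tuple(
        f"component_{i + 1}" for i in range(result.S.shape[0]))
    cmap = ListedColormap(["#ffffff", *hca.colors])

    for i, im in enumerate(images):
        fig = Figure(figsize=(10, 6))
        axs = fig.subplots(2, 3).ravel()
        total = band_integral(im, (axis.values[0], axis.values[-1]))
        axs[0].imshow(total.grid(), cmap="gray")
        axs[0].set_title("total intensity")
        for ax, (label, lo, hi) in zip(axs[1:4], config.band_windows):
            bm = band_integral(im, (lo, hi))
            ax.imshow(bm.grid(), cmap="gray")
            ax.set_title(f"{label} {lo:.0f}-{hi:.0f}")
        lab = hca.labels[i].reshape(im.height, im.width)
        axs[4].imshow(lab, cmap=cmap, vmin=0, vmax=hca.k, interpolation="nearest")
        axs[4].set_title(f"HCA k={hca.k}")
        mean, sd = mean_spectrum(im)
        axs[5].fill_between(axis.values, mean.intensities - sd.intensities,
                            mean.intensities + sd.intensities, color="0.7")
        axs[5].plot(axis.values, mean.intensities, "k", lw=0.8)
        axs[5].set_title("mean ± sd spectrum")
        for ax in axs[:5]:
            ax.set_axis_off()
        fig.tight_layout()
        save_fig(fig, f"overview_{i}.png")

    fig = Figure(figsize=(8, 5))
    ax = fig.subplots()
    for name, row in zip(names, result.S):
        ax.plot(axis.values, row, lw=0.8, label=name)
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("unit-area intensity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    save_fig(fig, "mcr_spectra.png")

    fig = Figure(figsize=(7, 4))
    ax = fig.subplots()
    pivot = grain_table.pivot(index="grain_id", columns="component",
                              values="mean_coefficient")
    pivot.plot.bar(ax=ax, width=0.8)
    ax.set_ylabel("mean MCR coefficient (area fraction)")
    fig.tight_layout()
    save_fig(fig, "grain_mean_concentrations.png")
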