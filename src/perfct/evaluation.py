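"""Quantitative evaluation of reconstructed series and perfusion maps.

PSNR over the whole 4D series, per-frame mean SSIM (Wang et al. defaults:
11x11 Gaussian window with sigma 1.5, K1 = 0.01, K2 = 0.03, dynamic range
taken from the reference frame) averaged over frames, ordinary
least-squares regression of perfusion maps against the noise-free
reference, ROI mean/SD statistics, and the regularization-parameter sweep
driver that ties them together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress
from skimage.metrics import structural_similarity

from perfct.pd_recon import RegularizerConfig, reconstruct
from perfct.perfusion import (
    AifCurve,
    PerfusionMaps,
    compute_maps,
    contrast_enhancement,
)
from perfct.phantom import DynamicSeries


@dataclass(frozen=True)
class RegressionResult:
    cc: float
    slope: float
    intercept: float
    n_pixels: int


def psnr(series: DynamicSeries | np.ndarray, ref: DynamicSeries | np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB over the full dynamic series.

    ``-10 log10( MSE / max(ref)^2 )`` with the peak taken as the maximum of
    the reference.  Identical inputs return ``inf``.
    """
    a = series.data if isinstance(series, DynamicSeries) else np.asarray(series, float)
    b = ref.data if isinstance(ref, DynamicSeries) else np.asarray(ref, float)
    if a.shape != b.shape:
        raise ValueError("series dimensions differ")
    peak = float(np.max(b))
    if peak == 0:
        raise ValueError("reference peak is zero")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return float("inf")
    return -10.0 * np.log10(mse / peak**2)


def ssim_mean(series: DynamicSeries | np.ndarray, ref: DynamicSeries | np.ndarray) -> float:
    """Mean SSIM per frame, averaged over frames.

    The dynamic range L of each frame is the max-min of the reference frame.
    """
    a = series.data if isinstance(series, DynamicSeries) else np.asarray(series, float)
    b = ref.data if isinstance(ref, DynamicSeries) else np.asarray(ref, float)
    if a.shape != b.shape:
        raise ValueError("series dimensions differ")
    if a.ndim == 2:
        a = a[:, :, None]
        b = b[:, :, None]
    vals = []
    for i in range(a.shape[2]):
        rng = float(b[:, :, i].max() - b[:, :, i].min())
        if rng == 0:
            rng = 1.0
        vals.append(structural_similarity(
            b[:, :, i], a[:, :, i],
            gaussian_weights=True, sigma=1.5, win_size=11,
            use_sample_covariance=False, K1=0.01, K2=0.03, data_range=rng,
        ))
    return float(np.mean(vals))


def regress_maps(map_img: np.ndarray, ref_map: np.ndarray, mask: np.ndarray) -> RegressionResult:
    """OLS of method map values (y) on reference values (x) inside ``mask``."""
    x = np.asarray(ref_map, float)[mask]
    y = np.asarray(map_img, float)[mask]
    if x.size < 3:
        raise ValueError("need at least 3 masked pixels")
    if np.var(x) == 0:
        raise ValueError("reference has zero variance inside the mask")
    res = linregress(x, y)
    return RegressionResult(
        cc=float(res.rvalue), slope=float(res.slope),
        intercept=float(res.intercept), n_pixels=int(x.size),
    )


def roi_stats(maps: PerfusionMaps, rois: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean and population SD of CBF/CBV/MTT per named ROI (tidy table)."""
    rows = []
    for name, roi in rois.items():
        if not roi.any():
            raise ValueError(f"ROI {name!r} is empty")
        for pname, img in (("cbf", maps.cbf), ("cbv", maps.cbv), ("mtt", maps.mtt)):
            vals = img[roi]
            rows.append({
                "roi": name, "parameter": pname,
                "mean": float(vals.mean()), "sd": float(vals.std()),
                "n_pixels": int(vals.size),
            })
    return pd.DataFrame(rows)


def parameter_sweep(
    sino_series,
    geometry,
    methods,
    alphas,
    ref_series: DynamicSeries,
    base_config: RegularizerConfig | None = None,
    aif: AifCurve | None = None,
    brain_mask: np.ndarray | None = None,
    rois: dict[str, np.ndarray] | None = None,
    ref_maps: PerfusionMaps | None = None,
    baseline_frames: tuple[int, int] = (0, 8),
    init: np.ndarray | None = None,
) -> pd.DataFrame:
    """Reconstruct over a (method, alpha) grid and tabulate all metrics.

    For every combination the series is reconstructed (warm-started from the
    shared FBP initializer when ``init`` is given), PSNR/SSIM against
    ``ref_series`` are recorded, and — when an AIF and brain mask are
    supplied — perfusion maps are computed and evaluated by ROI statistics
    and, with ``ref_maps``, by regression against the reference maps.

    Returns a tidy frame with columns (method, alpha, metric, value).
    """
    base = base_config or RegularizerConfig()
    rows = []
    for method in methods:
        for alpha in alphas:
            cfg = RegularizerConfig(
                method=method, alpha=alpha, alpha1=alpha,
                beta=base.beta, sigma=base.sigma, tau=base.tau,
                eps_tol=base.eps_tol, n_max=base.n_max,
                temporal_weight=base.temporal_weight,
            )
            series, _, report = reconstruct(sino_series, geometry, cfg, init=init)
            rows.append((method, alpha, "psnr", psnr(series, ref_series)))
            rows.append((method, alpha, "ssim", ssim_mean(series, ref_series)))
            rows.append((method, alpha, "n_iters", float(report.n_iters)))
            if aif is not None and brain_mask is not None:
                ce = contrast_enhancement(series, baseline_frames)
                maps = compute_maps(ce, aif, brain_mask)
                if ref_maps is not None:
                    for pname, img, ref_img in (
                        ("cbf", maps.cbf, ref_maps.cbf),
                        ("cbv", maps.cbv, ref_maps.cbv),
                        ("mtt", maps.mtt, ref_maps.mtt),
                    ):
                        reg = regress_maps(img, ref_img, brain_mask)
                        rows.append((method, alpha, f"cc_{pname}", reg.cc))
                        rows.append((method, alpha, f"slope_{pname}", reg.slope))
                        rows.append((method, alpha, f"intercept_{pname}", reg.intercept))
                if rois:
                    stats = roi_stats(maps, rois)
                    for _, row in stats.iterrows():
                        rows.append((
                            method, alpha,
                            f"mean_{row['parameter']}_{row['roi']}", row["mean"],
                        ))
                        rows.append((
                            method, alpha,
                            f"sd_{row['parameter']}_{row['roi']}", row["sd"],
                        ))
    return pd.DataFrame(rows, columns=["method", "alpha", "metric", "value"])
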