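"""Quantitative evaluation: SoS accuracy (RMSE), aberration-correction
quality (region SSIM against the correct-SoS reconstruction or the known
initial pressure), lateral resolution (FWHM of point-source profiles) and
SNR of normalized PA images, plus a batch harness that compares the
conventional constant-1540 assumption, the autofocus baseline and a
pixel-wise SoS map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .phantoms import (PhantomSpec, SoSLabel, LABEL_N, ellipse_mask, layer_mask,
                       EXTENT_MM, LABEL_DX_MM)
from .parecon import PAImage


@dataclass
class SSIMParams:
    """Stabilization constants of the single-window SSIM with dynamic range L."""

    L: float = 1.0

    @property
    def C1(self) -> float:
        return 0.01 ** 2 * self.L ** 2  # 1e-4 for L = 1

    @property
    def C2(self) -> float:
        return 0.03 ** 2 * self.L ** 2  # 9e-4 for L = 1


def rmse(est: Union[float, np.ndarray], gt: np.ndarray,
         mask: Optional[np.ndarray] = None) -> float:
    """Root-mean-square error over `mask` (m/s); a scalar estimate is
    broadcast as a constant field (conventional / autofocus rows)."""
    gt = np.asarray(gt, dtype=np.float64)
    est_arr = np.broadcast_to(np.asarray(est, dtype=np.float64), gt.shape)
    if mask is None:
        mask = np.ones(gt.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    d = est_arr[mask] - gt[mask]
    return float(np.sqrt(np.mean(d ** 2)))


def region_ssim(x: np.ndarray, y: np.ndarray, mask: Optional[np.ndarray] = None,
                params: SSIMParams = SSIMParams()) -> float:
    """Single-window SSIM with statistics over the masked pixel set.

    SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2) /
           ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("image shapes differ")
    if mask is None:
        mask = np.ones(x.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    xv, yv = x[mask], y[mask]
    mx, my = xv.mean(), yv.mean()
    vx, vy = xv.var(), yv.var()
    cxy = ((xv - mx) * (yv - my)).mean()
    C1, C2 = params.C1, params.C2
    return float((2 * mx * my + C1) * (2 * cxy + C2) /
                 ((mx ** 2 + my ** 2 + C1) * (vx + vy + C2)))


def lateral_fwhm(image: Union[PAImage, np.ndarray], peak_rc: Tuple[int, int],
                 pixel_mm: Optional[float] = None) -> float:
    """Full width at half maximum of the lateral (X) profile through a local
    maximum, with sub-pixel half-max crossings by linear interpolation (mm).

    Returns NaN (flagged unresolved) when the profile never falls below half
    maximum on either side.
    """
    if isinstance(image, PAImage):
        arr = np.abs(image.values)
        pixel_mm = image.pixel_size_mm
    else:
        arr = np.abs(np.asarray(image, dtype=np.float64))
        if pixel_mm is None:
            raise ValueError("pixel_mm required for raw arrays")
    r, c = peak_rc
    profile = arr[r].astype(np.float64)
    peak = profile[c]
    if peak <= 0:
        raise ValueError("peak location has zero intensity")
    half = peak / 2.0

    def crossing(direction: int) -> Optional[float]:
        i = c
        while 0 <= i + direction < profile.size:
            j = i + direction
            if profile[j] < half:
                # linear interpolation between i and j
                frac = (profile[i] - half) / (profile[i] - profile[j])
                return abs(i - c) + frac
            i = j
        return None

    left = crossing(-1)
    right = crossing(+1)
    if left is None or right is None:
        return float("nan")
    return (left + right) * pixel_mm


def snr_db(image: Union[PAImage, np.ndarray], threshold: float = 0.35) -> float:
    """20 log10(mu/sigma): mu = mean of normalized pixels >= threshold
    (signal), sigma = std of pixels below it (background noise).  Returns NaN
    when either class is degenerate."""
    img = image.normalized() if isinstance(image, PAImage) else np.asarray(image, np.float64)
    sig = img[img >= threshold]
    bg = img[img < threshold]
    if sig.size == 0 or bg.size == 0 or bg.std() == 0:
        return float("nan")
    return float(20 * np.log10(sig.mean() / bg.std()))


# ---------------------------------------------------------------------------
# evaluation harness


def region_masks(spec: PhantomSpec, n: int = LABEL_N) -> Dict[str, np.ndarray]:
    """Per-structure masks on the label grid: each layer/inclusion plus the
    remaining background; together they partition the medium."""
    dx = EXTENT_MM / n
    masks: Dict[str, np.ndarray] = {}
    claimed = np.zeros((n, n), dtype=bool)
    for i, inc in enumerate(spec.inclusions):
        m = ellipse_mask(inc, n, dx) & ~claimed
        masks[f"inclusion_{i}"] = m
        claimed |= m
    for i, layer in enumerate(spec.layers or []):
        m = layer_mask(layer, n, dx) & ~claimed
        masks[f"layer_{i}"] = m
        claimed |= m
    masks["background"] = ~claimed
    return masks


def point_source_roi(coords_mm: Sequence[Tuple[float, float]], shape: Tuple[int, int],
                     pixel_mm: float, half_mm: float = 1.0) -> np.ndarray:
    """Union of square windows (2 mm side by default) centered on the known
    point sources: the ROI used for point-source SSIM."""
    nz, nx = shape
    mask = np.zeros(shape, dtype=bool)
    for (x_mm, z_mm) in coords_mm:
        col = int(round(x_mm / pixel_mm + nx / 2 - 0.5))
        row = int(round(z_mm / pixel_mm))
        h = int(round(half_mm / pixel_mm))
        mask[max(0, row - h):row + h + 1, max(0, col - h):col + h + 1] = True
    return mask


@dataclass
class EvaluationRecord:
    phantom_id: int
    pattern: str
    rmse_global: Dict[str, float] = field(default_factory=dict)  # method -> m/s
    rmse_regions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    ssim: Dict[str, float] = field(default_factory=dict)
    fwhm_mm: Dict[str, List[float]] = field(default_factory=dict)
    snr_db: Dict[str, float] = field(default_factory=dict)


def evaluate_phantom(phantom_id: int, spec: PhantomSpec, label: SoSLabel,
                     estimates: Dict[str, Union[float, np.ndarray]],
                     pa_images: Optional[Dict[str, PAImage]] = None,
                     reference: Optional[np.ndarray] = None,
                     source_coords: Optional[Sequence[Tuple[float, float]]] = None,
                     roi_half_mm: float = 1.0) -> EvaluationRecord:
    """Metrics for one phantom.

    `estimates` maps method name (conventional / autofocus / dl / ...) to a
    scalar SoS or 384 x 384 map; `pa_images` optionally maps methods to
    reconstructions scored against `reference` (normalized correct-SoS
    reconstruction or rasterized initial pressure) inside the point-source
    ROI.
    """
    rec = EvaluationRecord(phantom_id, spec.pattern_id)
    masks = region_masks(spec, n=label.values.shape[0])
    for method, est in estimates.items():
        est_v = est.values if isinstance(est, SoSLabel) else est
        rec.rmse_global[method] = rmse(est_v, label.values)
        rec.rmse_regions[method] = {name: rmse(est_v, label.values, m)
                                    for name, m in masks.items() if m.any()}
    if pa_images:
        if reference is None:
            raise ValueError("reference image required to score reconstructions")
        ref_n = reference / reference.max() if reference.max() > 0 else reference
        for method, img in pa_images.items():
            norm = img.normalized()
            roi = None
            if source_coords:
                roi = point_source_roi(source_coords, norm.shape, img.pixel_size_mm,
                                       half_mm=roi_half_mm)
            rec.ssim[method] = region_ssim(norm, ref_n, mask=roi)
            rec.snr_db[method] = snr_db(norm)
            if source_coords:
                widths = []
                for (x_mm, z_mm) in source_coords:
                    nz, nx = norm.shape
                    col = int(round(x_mm / img.pixel_size_mm + nx / 2 - 0.5))
                    row = int(round(z_mm / img.pixel_size_mm))
                    # snap to the local max inside the ROI window
                    h = int(round(roi_half_mm / img.pixel_size_mm))
                    win = norm[max(0, row - h):row + h + 1, max(0, col - h):col + h + 1]
                    dr, dc = np.unravel_index(np.argmax(win), win.shape)
                    widths.append(lateral_fwhm(norm, (max(0, row - h) + dr,
                                                      max(0, col - h) + dc),
                                               pixel_mm=img.pixel_size_mm))
                rec.fwhm_mm[method] = widths
    return rec


def evaluate_suite(records: List[EvaluationRecord]) -> pd.DataFrame:
    """Per-pattern mean +/- std summary table over a batch of records, one row
    per (pattern, method) with RMSE and, where available, SSIM columns."""
    rows = []
    for rec in records:
        for method in rec.rmse_global:
            rows.append({
                "pattern": rec.pattern,
                "method": method,
                "rmse": rec.rmse_global[method],
                "ssim": rec.ssim.get(method, np.nan),
                "snr_db": rec.snr_db.get(method, np.nan),
            })
    df = pd.DataFrame(rows)
    out = df.groupby(["pattern", "method"]).agg(
        rmse_mean=("rmse", "mean"), rmse_std=("rmse", "std"),
        ssim_mean=("ssim", "mean"), ssim_std=("ssim", "std"),
        snr_mean=("snr_db", "mean"), n=("rmse", "size")).reset_index()
    return out
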