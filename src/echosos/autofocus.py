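"""Autofocus baseline: pick one global sound speed by maximizing image
sharpness of the reconstruction over a candidate sweep.

This is the classical alternative to pixel-wise SoS estimation: reconstruct
the PA frame at each candidate speed, score the result with a sharpness
functional, and keep the argmax.  With a homogeneous medium the sweep
recovers the true speed; with layered media no single scalar can focus all
depths, which is the failure mode the learned map addresses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .parecon import PAImage, reconstruct
from .wavesim import ProbeGeometry

TIE_BREAK_SOS = 1540.0


def sharpness(image: PAImage | np.ndarray, metric: str = "intensity_power") -> float:
    """Sharpness of a normalized PA image.

    ``intensity_power``: sum(I^4) / (sum(I^2))^2 — scale-invariant, maximal
    when energy concentrates in few pixels.  ``brenner``: mean squared
    adjacent-pixel intensity difference (gradient energy).
    """
    img = image.normalized() if isinstance(image, PAImage) else np.abs(np.asarray(image, float))
    if img.max() == 0:
        warnings.warn("all-zero image has zero sharpness")
        return 0.0
    if metric == "intensity_power":
        i2 = (img ** 2).sum()
        return float((img ** 4).sum() / i2 ** 2)
    if metric == "brenner":
        dz = img[1:, :] - img[:-1, :]
        dx = img[:, 1:] - img[:, :-1]
        return float((dz ** 2).mean() + (dx ** 2).mean())
    raise ValueError(f"unknown sharpness metric {metric!r}")


@dataclass
class AutofocusResult:
    c_opt: float
    sweep: pd.DataFrame  # columns: sos, sharpness
    metric: str


def autofocus_sos(rf_raw: np.ndarray, probe: ProbeGeometry,
                  c_range: Tuple[float, float] = (1400.0, 1600.0),
                  step: float = 5.0, nx: int = 256,
                  metric: str = "intensity_power", n_zero: int = 0,
                  time_window_s: Optional[float] = None) -> AutofocusResult:
    """Exhaustive sweep over candidate speeds; ties break toward 1540 m/s.

    The sweep table is returned alongside the argmax as a diagnostic (it
    should be unimodal around the true speed for point-source frames).
    """
    if step <= 0:
        raise ValueError("sweep step must be positive")
    lo, hi = c_range
    if lo > hi:
        raise ValueError("empty sweep range")
    candidates = np.arange(lo, hi + step / 2, step)
    scores = []
    for c in candidates:
        img = reconstruct(rf_raw, float(c), probe, nx=nx, sos_source="autofocus",
                          n_zero=n_zero, time_window_s=time_window_s)
        scores.append(sharpness(img, metric=metric))
    scores = np.asarray(scores)
    best = scores.max()
    tied = candidates[scores >= best * (1 - 1e-12)]
    c_opt = float(tied[np.argmin(np.abs(tied - TIE_BREAK_SOS))])
    table = pd.DataFrame({"sos": candidates, "sharpness": scores})
    return AutofocusResult(c_opt=c_opt, sweep=table, metric=metric)
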