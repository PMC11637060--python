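"""Conditioning of raw solver RF into network-ready 128 x 1024 frames.

The acquisition chain mirrors a clinical plane-wave system: time gain
compensation for soft-tissue attenuation, decimation to the 20 MHz RF clock,
injection of system (transmit-interference) and thermal (Gaussian) noise,
zeroing of the crosstalk-contaminated early samples, and per-channel
standardization.  A delay-and-sum beamformer is included for B-mode
visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal

from .phantoms import substream
from .wavesim import RFFrame, ProbeGeometry, RF_RATE_HZ

N_SAMPLES = 1024
N_ZERO_EARLY = 50


def apply_tgc(rf: RFFrame, alpha_db_mhz_cm: float = 0.5, c_ref: float = 1540.0,
              fc_hz: float = 7e6) -> RFFrame:
    """Exponential depth gain 10^(alpha * fc[MHz] * depth[cm] / 20) with the
    two-way depth mapping depth = c_ref * t / 2."""
    if alpha_db_mhz_cm < 0:
        raise ValueError("TGC slope must be >= 0")
    t = rf.t0_s + np.arange(rf.data.shape[1]) / rf.sample_rate_hz
    depth_cm = c_ref * t / 2 * 100.0
    gain = 10.0 ** (alpha_db_mhz_cm * (fc_hz / 1e6) * depth_cm / 20.0)
    return replace(rf, data=rf.data * gain[None, :].astype(rf.data.dtype))


def downsample_to_20mhz(rf: RFFrame, n_out: int = N_SAMPLES) -> RFFrame:
    """Anti-aliased resampling to 20 MHz, truncated/zero-padded to 1024 samples."""
    ratio = rf.sample_rate_hz / RF_RATE_HZ
    if ratio < 1 - 1e-9:
        raise ValueError("solver rate below 20 MHz")
    if abs(ratio - round(ratio)) < 1e-6:
        out = signal.resample_poly(rf.data.astype(np.float64), up=1,
                                   down=int(round(ratio)), axis=1)
    else:
        from fractions import Fraction
        fr = Fraction(RF_RATE_HZ / rf.sample_rate_hz).limit_denominator(1000)
        out = signal.resample_poly(rf.data.astype(np.float64), up=fr.numerator,
                                   down=fr.denominator, axis=1)
    if out.shape[1] >= n_out:
        out = out[:, :n_out]
    else:
        out = np.pad(out, ((0, 0), (0, n_out - out.shape[1])))
    return replace(rf, data=out, sample_rate_hz=RF_RATE_HZ)


def zero_early_samples(rf: RFFrame, n: int = N_ZERO_EARLY) -> RFFrame:
    if n >= rf.data.shape[1]:
        raise ValueError("cannot zero the entire frame")
    out = rf.data.copy()
    out[:, :n] = 0.0
    return replace(rf, data=out)


def normalize_channels(rf: RFFrame, active_from: int = 0) -> RFFrame:
    """Standardize every channel to mean 0 / std 1; all-zero channels are left
    at zero and flagged in the frame metadata.

    When the first `active_from` samples have been blanked, statistics are
    computed on the active region and rescaled so the blanked samples stay
    exactly zero while the full channel still has mean 0 / std 1.
    """
    data = rf.data.astype(np.float64)
    m = data.shape[1]
    active = data[:, active_from:]
    mu = active.mean(axis=1, keepdims=True)
    sd = active.std(axis=1, keepdims=True)
    dead = (sd[:, 0] == 0)
    sd[dead] = 1.0
    scale = np.sqrt(m / (m - active_from))
    out = np.zeros_like(data)
    out[:, active_from:] = (active - mu) / sd * scale
    out[dead] = 0.0
    meta = dict(rf.meta)
    if dead.any():
        meta["dead_channels"] = np.flatnonzero(dead).tolist()
    return replace(rf, data=out, meta=meta)


def add_thermal_noise(rf: RFFrame, snr_db: float, seed: int = 0) -> RFFrame:
    """White Gaussian noise per channel at the given signal-to-noise ratio
    (dB, per-channel signal power over noise power).  snr_db = inf disables."""
    if not np.isfinite(snr_db):
        return rf
    rng = substream(seed, "thermal")
    psig = (rf.data.astype(np.float64) ** 2).mean(axis=1, keepdims=True)
    sigma = np.sqrt(psig * 10.0 ** (-snr_db / 10.0))
    noise = rng.standard_normal(rf.data.shape) * sigma
    return replace(rf, data=rf.data + noise,
                   meta={**rf.meta, "thermal_snr_db": float(snr_db)})


def draw_thermal_snr(seed: int, lo_db: float = 40.0, hi_db: float = 80.0) -> float:
    """Per-frame noise floor 40-80 dB below the channel signal power."""
    if lo_db > hi_db:
        raise ValueError("SNR bounds inverted")
    return float(substream(seed, "thermal_snr").uniform(lo_db, hi_db))


def synthetic_noise_bank(n_segments: int = 16, n_samples: int = N_ZERO_EARLY,
                         fc_hz: float = 7e6, fs_hz: float = RF_RATE_HZ,
                         seed: int = 1234) -> np.ndarray:
    """Synthetic stand-in for a measured system-noise bank: band-limited
    transmit-interference bursts confined to the first `n_samples` samples."""
    rng = substream(seed, "noise_bank")
    t = np.arange(n_samples) / fs_hz
    bank = []
    for _ in range(n_segments):
        f = fc_hz * rng.uniform(0.5, 1.2)
        envelope = np.exp(-((t - t[n_samples // 3]) / (t[-1] / 3)) ** 2)
        bank.append(np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) * envelope)
    return np.asarray(bank)


def add_system_noise(rf: RFFrame, noise_bank: Optional[np.ndarray], seed: int = 0,
                     amplitude: float = 1.0) -> RFFrame:
    """Add a randomly drawn bank segment to the early-time region of every
    channel (transmit-interference emulation).  `noise_bank=None` disables."""
    if noise_bank is None:
        return rf
    if len(noise_bank) == 0:
        raise ValueError("empty system-noise bank")
    rng = substream(seed, "system")
    out = rf.data.astype(np.float64).copy()
    n = noise_bank.shape[1]
    rms = np.sqrt((rf.data.astype(np.float64) ** 2).mean())
    for ch in range(out.shape[0]):
        seg = noise_bank[rng.integers(0, len(noise_bank))]
        out[ch, :n] += amplitude * rms * seg
    return replace(rf, data=out)


@dataclass
class PipelineConfig:
    """The full acquisition-emulation chain and its stage order."""

    tgc_alpha_db_mhz_cm: float = 0.5
    tgc_c_ref: float = 1540.0
    tgc_fc_hz: float = 7e6
    thermal_snr_db: Optional[float] = None  # None -> drawn U[40, 80] dB
    system_noise: bool = True
    n_zero: int = N_ZERO_EARLY
    order: Tuple[str, ...] = ("tgc", "downsample", "system_noise",
                              "thermal_noise", "zero_early", "normalize")


def condition(rf: RFFrame, cfg: Optional[PipelineConfig] = None, seed: int = 0,
              noise_bank: Optional[np.ndarray] = None) -> RFFrame:
    """Apply the acquisition chain; returns a finite 128 x 1024 frame with
    per-channel mean 0 / std 1.  Stage order is configurable and logged."""
    cfg = cfg or PipelineConfig()
    if cfg.system_noise and noise_bank is None:
        noise_bank = synthetic_noise_bank(fc_hz=cfg.tgc_fc_hz)
    snr = cfg.thermal_snr_db if cfg.thermal_snr_db is not None else draw_thermal_snr(seed)
    for stage in cfg.order:
        if stage == "tgc":
            rf = apply_tgc(rf, cfg.tgc_alpha_db_mhz_cm, cfg.tgc_c_ref, cfg.tgc_fc_hz)
        elif stage == "downsample":
            rf = downsample_to_20mhz(rf)
        elif stage == "system_noise":
            rf = add_system_noise(rf, noise_bank if cfg.system_noise else None, seed)
        elif stage == "thermal_noise":
            rf = add_thermal_noise(rf, snr, seed)
        elif stage == "zero_early":
            rf = zero_early_samples(rf, cfg.n_zero)
        elif stage == "normalize":
            blanked = cfg.n_zero if "zero_early" in cfg.order[:cfg.order.index(stage)] else 0
            rf = normalize_channels(rf, active_from=blanked)
        else:
            raise ValueError(f"unknown pipeline stage {stage!r}")
    rf.meta["pipeline_order"] = list(cfg.order)
    return rf


def domain_shift(rf: RFFrame, seed: int = 0, kernel_len: int = 7,
                 extra_noise_snr_db: float = 25.0) -> RFFrame:
    """Synthetic acquisition-domain shift for transfer-learning studies.

    Emulates a probe with a different electro-mechanical response by
    convolving each channel with a short random FIR kernel, then adds excess
    noise.  Applied before normalization of an already-conditioned frame the
    result is re-standardized.
    """
    rng = substream(seed, "domain_shift")
    k = rng.standard_normal(kernel_len)
    k[kernel_len // 2] += 3.0  # keep the response near-identity + ringing
    k /= np.abs(k).sum()
    data = np.apply_along_axis(lambda x: np.convolve(x, k, mode="same"), 1,
                               rf.data.astype(np.float64))
    shifted = replace(rf, data=data)
    shifted = add_thermal_noise(shifted, extra_noise_snr_db, seed + 1)
    return normalize_channels(shifted)


def das_bmode(rf: RFFrame, c: float, probe: ProbeGeometry,
              image_shape: Tuple[int, int] = (384, 384), pixel_mm: float = 0.1,
              dynamic_range_db: float = 50.0, zero_top_mm: float = 2.0,
              f_number: float = 1.0) -> np.ndarray:
    """Delay-and-sum B-mode of plane-wave RF: dynamic receive delays at the
    assumed sound speed, Hilbert envelope, log compression; the top 2 mm are
    zeroed to mirror the crosstalk-blanked display region."""
    if not (1300.0 <= c <= 1700.0):
        import warnings
        warnings.warn(f"assumed SoS {c} m/s outside the plausible tissue range")
    nz, nx = image_shape
    fs = rf.sample_rate_hz
    analytic = signal.hilbert(rf.data.astype(np.float64), axis=1)
    z = (np.arange(nz) + 0.5) * pixel_mm * 1e-3
    x = ((np.arange(nx) + 0.5) * pixel_mm - nx * pixel_mm / 2) * 1e-3
    ex = probe.element_x_mm() * 1e-3
    img = np.zeros((nz, nx), dtype=np.complex128)
    nsamp = rf.data.shape[1]
    weight = np.zeros((nz, nx))
    for e in range(probe.n_elements):
        dxe = x[None, :] - ex[e]
        t = (z[:, None] + np.sqrt(z[:, None] ** 2 + dxe ** 2)) / c
        idx = t * fs
        i0 = np.floor(idx).astype(int)
        frac = idx - i0
        valid = (i0 >= 0) & (i0 < nsamp - 1)
        # aperture growth with depth (receive f-number)
        accept = np.abs(dxe) <= np.maximum(z[:, None] / (2 * f_number), probe.pitch_mm * 1e-3)
        use = valid & accept
        i0c = np.clip(i0, 0, nsamp - 2)
        vals = analytic[e, i0c] * (1 - frac) + analytic[e, i0c + 1] * frac
        img[use] += vals[use]
        weight[use] += 1
    env = np.abs(img) / np.maximum(weight, 1)
    top = int(round(zero_top_mm / pixel_mm))
    env[:top] = 0.0
    m = env.max()
    if m == 0:
        return np.full(image_shape, -dynamic_range_db)
    db = 20 * np.log10(np.maximum(env / m, 10 ** (-dynamic_range_db / 20)))
    return db
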