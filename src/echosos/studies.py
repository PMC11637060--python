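"""Desk-scale validation studies.

Each function runs one self-contained experiment end to end — phantom
generation, wave simulation, conditioning, reconstruction or training,
measurement — and returns plain numbers.  They are shared by the acceptance
script and the acceptance test suite.

The full-scale study conditions (1536^2 simulation grid at 7 MHz, 6000
training samples, 788 x 768 reconstruction grid) are supported by the
underlying modules but these studies run reduced grids (128^2 - 384^2) with
the transmit frequency scaled to keep the medium acoustically resolved, so a
complete validation pass fits in CPU minutes.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import hilbert

from . import phantoms as ph
from . import wavesim as ws
from . import rfpipe as rp
from .autofocus import autofocus_sos
from .metrics import region_ssim, lateral_fwhm, rmse, point_source_roi
from .parecon import reconstruct
from .sosnet import (NetworkConfig, TrainConfig, build_model, predict_sos,
                     attach_residual_head, train, fine_tune)


def _envelope_peak_time(trace: np.ndarray, fs: float) -> float:
    env = np.abs(hilbert(np.asarray(trace, dtype=np.float64)))
    return float(env.argmax() / fs)


def _sos_below_probe(medium: ph.AcousticMedium, pml: int = 10) -> np.ndarray:
    """True-SoS field on the imaging grid: medium rows from the probe line
    down, edge-extended to a square (nx, nx) block."""
    n = medium.shape[1]
    field = np.empty((n, n))
    body = medium.sos[pml:, :]
    field[:body.shape[0]] = body
    field[body.shape[0]:] = body[-1]
    return field


# ---------------------------------------------------------------------------
# solver oracles


def travel_time_study(seed: int = 0) -> Dict[str, float]:
    """Point source at 15 mm depth in homogeneous 1500 m/s tissue (256^2
    grid): first arrival at the on-axis element should be 10 us."""
    n = 256
    med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1500.0), n=n)
    probe = ws.desk_probe(med.dx_mm)
    p0 = ph.place_point_absorbers([(0.0, 15.0)], med.shape, med.dx_mm, z0_row=10)
    grid = ws.grid_for_medium(med, duration_s=14e-6)
    rf = ws.pa_forward(med, p0, probe, grid)
    t = _envelope_peak_time(rf.data[63], rf.sample_rate_hz)
    return {"first_arrival_us": t * 1e6, "expected_us": 10.0, "n": n}


def roundtrip_study(seed: int = 0) -> Dict[str, float]:
    """Forward PA + time reversal with the true SoS map in a two-layer medium
    localizes three point sources; reports the worst error in pixels."""
    n = 256
    rng = np.random.default_rng(seed)
    spec = ph.PhantomSpec(1480.0, layers=[ph.LayerInclusion(
        z0_mm=float(rng.uniform(11.0, 14.0)), sos=1560.0)])
    med = ph.rasterize_medium(spec, n=n)
    probe = ws.desk_probe(med.dx_mm)
    coords = [(-6.0, 12.0), (0.0, 20.0), (6.0, 25.0)]
    p0 = ph.place_point_absorbers(coords, med.shape, med.dx_mm, z0_row=10)
    grid = ws.grid_for_medium(med, duration_s=26e-6)
    rf = ws.pa_forward(med, p0, probe, grid)
    rf20 = rp.downsample_to_20mhz(rf, n_out=rf.data.shape[1]
                                  * 20_000_000 // int(rf.sample_rate_hz))
    img = reconstruct(rf20.data, _sos_below_probe(med), probe, nx=n, n_zero=0,
                      sos_source="ground_truth", time_window_s=26e-6)
    vals = np.abs(img.values)
    worst = 0.0
    for (x_mm, z_mm) in coords:
        col = int(round(x_mm / med.dx_mm + n / 2 - 0.5))
        row = int(round(z_mm / med.dx_mm))
        h = 8
        win = vals[row - h:row + h + 1, col - h:col + h + 1]
        dr, dc = np.unravel_index(np.argmax(win), win.shape)
        err = float(np.hypot(dr - h, dc - h))
        worst = max(worst, err)
    return {"max_localization_error_px": worst, "n": n}


def wrong_sos_study(seed: int = 0) -> Dict[str, float]:
    """Point at 20 mm in 1500 m/s tissue reconstructed at 1540 m/s: ray
    time-of-flight predicts an apparent depth 20 x 1540/1500 = 20.53 mm."""
    n = 384
    med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1500.0), n=n)
    probe = ws.desk_probe(med.dx_mm)
    p0 = ph.place_point_absorbers([(0.0, 20.0)], med.shape, med.dx_mm, z0_row=10)
    grid = ws.grid_for_medium(med, duration_s=22e-6)
    rf = ws.pa_forward(med, p0, probe, grid)
    rf20 = rp.downsample_to_20mhz(rf, n_out=rf.data.shape[1]
                                  * 20_000_000 // int(rf.sample_rate_hz))
    img = reconstruct(rf20.data, 1540.0, probe, nx=n, n_zero=0,
                      time_window_s=22e-6)
    vals = np.abs(img.values)
    col = n // 2
    profile = vals[:, col - 2:col + 3].max(axis=1)
    r = int(profile.argmax())
    # sub-pixel apex by parabolic interpolation
    y0, y1, y2 = profile[r - 1], profile[r], profile[r + 1]
    denom = (y0 - 2 * y1 + y2)
    frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    depth_mm = (r + frac) * img.pixel_size_mm
    return {"apparent_depth_mm": float(depth_mm),
            "expected_mm": 20.0 * 1540.0 / 1500.0, "n": n}


def autofocus_study(seed: int = 0,
                    speeds: Sequence[float] = (1450.0, 1500.0, 1550.0),
                    step: float = 5.0) -> Dict[str, float]:
    """Autofocus sweep recovery on homogeneous phantoms: the selected global
    SoS should sit within one sweep step of the true value."""
    n = 128
    errors = []
    for c_true in speeds:
        med = ph.rasterize_medium(ph.PhantomSpec(background_sos=float(c_true)), n=n)
        probe = ws.desk_probe(med.dx_mm)
        p0 = ph.place_point_absorbers([(0.0, 18.0)], med.shape, med.dx_mm, z0_row=10)
        grid = ws.grid_for_medium(med, duration_s=20e-6)
        rf = ws.pa_forward(med, p0, probe, grid)
        rf20 = rp.downsample_to_20mhz(rf, n_out=rf.data.shape[1]
                                      * 20_000_000 // int(rf.sample_rate_hz))
        res = autofocus_sos(rf20.data, probe, c_range=(1400.0, 1600.0),
                            step=step, nx=n, time_window_s=20e-6)
        errors.append(abs(res.c_opt - c_true))
    return {"max_autofocus_error_ms": float(max(errors)), "step_ms": step,
            "n": len(speeds)}


# ---------------------------------------------------------------------------
# metric closed forms


def metric_oracle_study() -> Dict[str, float]:
    """Evaluate the quantitative metrics on their closed-form cases."""
    hand_rmse = rmse(np.array([[1500.0, 1520.0]]), np.array([[1510.0, 1540.0]]))
    ssim_01 = region_ssim(np.zeros((8, 8)), np.ones((8, 8)))
    pix = 0.05
    x = (np.arange(201) - 100) * pix
    gauss = np.tile(np.exp(-x ** 2 / (2 * 0.5 ** 2)), (3, 1))
    fwhm = lateral_fwhm(gauss, (1, 100), pixel_mm=pix)
    rng = np.random.default_rng(0)
    img = np.clip(rng.normal(0.1, 0.1, (200, 200)), 0, 0.349)
    img[80:120, 80:120] = 1.0
    from .metrics import snr_db as _snr
    snr = _snr(img) - 20 * np.log10(1.0 / img[img < 0.35].std())
    return {"rmse_hand_case_ms": float(hand_rmse),
            "ssim_zero_vs_one": float(ssim_01),
            "fwhm_gaussian_mm": float(fwhm),
            "snr_consistency_db": float(snr)}


def baseline_study(seed: int = 0, n_draws: int = 10_000) -> Dict[str, float]:
    """RMSE of the constant-1540 estimator against U[1400, 1600] backgrounds:
    closed form sqrt(40^2 + 200^2/12) ~ 70.2 m/s."""
    rng = np.random.default_rng(seed)
    c = rng.uniform(1400.0, 1600.0, n_draws)
    return {"baseline_rmse_1540_ms": float(np.sqrt(np.mean((1540.0 - c) ** 2))),
            "closed_form_ms": float(np.sqrt(40.0 ** 2 + 200.0 ** 2 / 12)),
            "n": n_draws}


# ---------------------------------------------------------------------------
# learning studies


def simulate_training_sample(seed: int, n: int = 128,
                             spec: Optional[ph.PhantomSpec] = None
                             ) -> Tuple[np.ndarray, np.ndarray]:
    """One (conditioned RF, label) pair on the desk simulation grid."""
    probe = ws.desk_probe(ph.EXTENT_MM / n)
    spec = spec or ph.sample_training_phantom(seed)
    _, med, label = ph.realize(spec, n, probe.center_frequency_hz)
    rf = ws.plane_wave_pulse_echo(med, probe, grid=ws.grid_for_medium(med))
    frame = rp.condition(rf, seed=seed)
    return frame.data.astype(np.float32), label.values.astype(np.float32)


def build_training_dataset(seed: int, n_phantoms: int = 200,
                           n: int = 128) -> List[Tuple[np.ndarray, np.ndarray]]:
    base = (seed * 10_007) % (2 ** 31 - 1)
    return [simulate_training_sample(base + i, n=n) for i in range(n_phantoms)]


def learning_study(seed: int = 0, n_phantoms: int = 200, epochs: int = 22,
                   dataset: Optional[List[Tuple[np.ndarray, np.ndarray]]] = None,
                   ) -> Dict[str, object]:
    """Scaled-down end-to-end parameter recovery.

    Trains the thin-channel network on `n_phantoms` simulated acquisitions and
    reports (a) held-out same-distribution RMSE against the constant-1540
    baseline and (b) the mean-prediction error on held-out homogeneous
    phantoms.
    """
    if dataset is None:
        dataset = build_training_dataset(seed, n_phantoms)
    model = build_model(NetworkConfig().small(), seed=seed)
    cfg = TrainConfig(lr=0.02, momentum=0.9, batch=10, epochs=epochs, seed=seed,
                      lr_steps=((max(epochs - 6, 1), 0.006),), ema_decay=0.98)
    model, history = train(model, dataset, cfg)

    base = (seed * 10_007 + 500_003) % (2 ** 31 - 1)
    se = cnt = 0
    se_base = 0.0
    for i in range(12):
        x, y = simulate_training_sample(base + i)
        p = predict_sos(model, x).values
        se += float(((p - y) ** 2).sum())
        se_base += float(((1540.0 - y) ** 2).sum())
        cnt += y.size
    heldout_rmse = float(np.sqrt(se / cnt))
    baseline_rmse = float(np.sqrt(se_base / cnt))

    errors = []
    for j, c in enumerate((1450.0, 1500.0, 1550.0)):
        spec = ph.PhantomSpec(background_sos=c, rng_seed=base + 100 + j)
        x, _ = simulate_training_sample(base + 100 + j, spec=spec)
        est = predict_sos(model, x)
        errors.append(abs(float(est.values.mean()) - c))
    return {"heldout_rmse_ms": heldout_rmse,
            "heldout_baseline_1540_ms": baseline_rmse,
            "homogeneous_mean_error_ms": float(max(errors)),
            "history": history, "model": model, "dataset": dataset,
            "n": n_phantoms}


def transfer_study(seed: int = 0, model=None,
                   dataset: Optional[List[Tuple[np.ndarray, np.ndarray]]] = None,
                   n_samples: int = 48) -> Dict[str, float]:
    """Frozen-base transfer learning on a synthetic domain-shifted set.

    48 conditioned frames are passed through a surrogate acquisition response
    (channel FIR + excess noise); the residual head is fine-tuned on them.
    Reports validation MSE before/after and whether the base stayed frozen.
    """
    if model is None or dataset is None:
        res = learning_study(seed)
        model, dataset = res["model"], res["dataset"]
    shifted = []
    for i, (x, y) in enumerate(dataset[:n_samples]):
        frame = ws.RFFrame(x.astype(np.float64), ws.RF_RATE_HZ)
        shifted.append((rp.domain_shift(frame, seed=seed + i).data.astype(np.float32), y))
    aug = attach_residual_head(model, hidden=4, seed=seed)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(shifted))
    n_train = int(round(0.9 * len(shifted)))
    train_set = [shifted[i] for i in order[:n_train]]
    valid_set = [shifted[i] for i in order[n_train:]]

    def val_mse(m):
        se = cnt = 0
        for x, y in valid_set:
            p = m.forward(x[None], train=False)[0]
            yn = (y - 1500.0) / 100.0
            se += float(((p - yn) ** 2).sum())
            cnt += y.size
        return se / cnt

    before = val_mse(aug)
    checksum_before = model.checksum()
    aug, _ = fine_tune(aug, train_set,
                       TrainConfig(lr=0.05, momentum=0.9, batch=10, epochs=20,
                                   seed=seed, patience=5),
                       valid_set=valid_set)
    after = val_mse(aug)
    return {"val_mse_before": float(before), "val_mse_after": float(after),
            "val_mse_ratio": float(after / before) if before > 0 else float("nan"),
            "base_frozen": float(model.checksum() == checksum_before),
            "n": len(shifted)}


# ---------------------------------------------------------------------------
# aberration correction


def aberration_study(seed: int = 0, n_phantoms: int = 10) -> Dict[str, float]:
    """True-SoS-map time reversal vs the constant-1540 assumption on layered
    phantoms with >= 60 m/s contrast: fraction of phantoms where the true map
    wins on both point-source SSIM and mean lateral FWHM."""
    n = 128
    rng = np.random.default_rng(seed + 17)
    wins = 0
    probe = ws.desk_probe(ph.EXTENT_MM / n)
    for k in range(n_phantoms):
        bg = float(rng.uniform(1420.0, 1480.0))
        contrast = float(rng.uniform(60.0, 100.0))
        spec = ph.PhantomSpec(bg, layers=[ph.LayerInclusion(
            z0_mm=float(rng.uniform(10.0, 15.0)), sos=bg + contrast)])
        med = ph.rasterize_medium(spec, n=n)
        coords = [(float(rng.uniform(-8.0, -2.0)), float(rng.uniform(19.0, 23.0))),
                  (float(rng.uniform(2.0, 8.0)), float(rng.uniform(24.0, 28.0)))]
        p0 = ph.place_point_absorbers(coords, med.shape, med.dx_mm, z0_row=10)
        grid = ws.grid_for_medium(med, duration_s=27e-6)
        rf = ws.pa_forward(med, p0, probe, grid)
        rf20 = rp.downsample_to_20mhz(rf, n_out=rf.data.shape[1]
                                      * 20_000_000 // int(rf.sample_rate_hz))
        true_field = _sos_below_probe(med)
        img_true = reconstruct(rf20.data, true_field, probe, nx=n, n_zero=0,
                               sos_source="ground_truth", time_window_s=27e-6)
        img_1540 = reconstruct(rf20.data, 1540.0, probe, nx=n, n_zero=0,
                               time_window_s=27e-6)
        ref = ph.place_point_absorbers(coords, (n, n), med.dx_mm, z0_row=0)
        roi = point_source_roi(coords, (n, n), med.dx_mm, half_mm=2.0)

        def score(img):
            norm = img.normalized()
            s = region_ssim(norm, ref, mask=roi)
            widths = []
            for (x_mm, z_mm) in coords:
                col = int(round(x_mm / med.dx_mm + n / 2 - 0.5))
                row = int(round(z_mm / med.dx_mm))
                h = int(round(2.0 / med.dx_mm))
                win = norm[row - h:row + h + 1, col - h:col + h + 1]
                dr, dc = np.unravel_index(np.argmax(win), win.shape)
                w = lateral_fwhm(norm, (row - h + dr, col - h + dc),
                                 pixel_mm=med.dx_mm)
                if np.isfinite(w):
                    widths.append(w)
            return s, float(np.mean(widths)) if widths else float("inf")

        ssim_t, fwhm_t = score(img_true)
        ssim_c, fwhm_c = score(img_1540)
        if ssim_t > ssim_c and fwhm_t < fwhm_c:
            wins += 1
    return {"aberration_win_fraction": wins / n_phantoms, "wins": float(wins),
            "n": n_phantoms}


# ---------------------------------------------------------------------------
# RF pipeline contract


def pipeline_study(seed: int = 0) -> Dict[str, float]:
    """Full conditioning chain contract on solver-like RF: 128 x 1024 frame,
    standardized channels, blanked early samples, and a post-hoc thermal SNR
    estimate within 0.5 dB of the drawn value."""
    rng = np.random.default_rng(seed)
    decay = np.exp(-np.arange(4096) / 1500.0)
    raw = ws.RFFrame(rng.standard_normal((128, 4096)) * decay[None, :], 80e6)
    cfg = rp.PipelineConfig(system_noise=False)
    snr = rp.draw_thermal_snr(seed)
    clean = rp.downsample_to_20mhz(rp.apply_tgc(raw))
    noisy = rp.add_thermal_noise(clean, snr, seed=seed)
    noise = noisy.data - clean.data
    measured = 10 * np.log10((clean.data ** 2).mean() / (noise ** 2).mean())
    out = rp.condition(raw, cfg, seed=seed)
    ok_shape = out.data.shape == (128, 1024)
    ok_moments = (np.abs(out.data.mean(axis=1)).max() < 1e-6
                  and np.allclose(out.data.std(axis=1), 1.0, atol=1e-6))
    ok_blank = not out.data[:, :50].any()
    return {"thermal_snr_error_db": float(abs(measured - snr)),
            "drawn_snr_db": float(snr),
            "frame_contract_ok": float(ok_shape and ok_moments and ok_blank),
            "n": 128 * 1024}
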