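"""Time-reversal photoacoustic reconstruction with heterogeneous sound speed.

The recorded element traces are reversed in time and re-emitted as Dirichlet
pressure sources on the transducer line of a simulated medium whose SoS is
either a constant or a pixel-wise map (network estimate or ground truth); the
wave field refocuses onto the original optical absorbers.  The full-scale
path follows the clinical-geometry recipe: a 788 (Z) x 768 (X) grid at
0.05 mm with 10-point absorbing layers at the probe and opposing edges, RF
resampled from 128 x 1024 to 640 x 4096 (5 grid points per element, 1 kerf),
and the 384 x 384 SoS map interpolated to 768 x 768.  Desk-scale grids use
the same machinery with every length scaled by the grid pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import signal, ndimage

from .phantoms import AcousticMedium, SoSLabel, EXTENT_MM, DENSITY_KG_M3
from .wavesim import (KSpaceSolver, SimulationGrid, ProbeGeometry, RFFrame,
                      RF_RATE_HZ, DEFAULT_PML, solver_dt)

FULL_NX = 768
FULL_NZ = 788
FULL_DX_MM = 0.05
N_ZERO_TR = 150


@dataclass
class PAImage:
    values: np.ndarray
    pixel_size_mm: float = FULL_DX_MM
    sos_source: str = "constant"  # constant | autofocus | dl | ground_truth
    meta: dict = field(default_factory=dict)

    def normalized(self) -> np.ndarray:
        """Max-abs normalization to [0, 1] (display / intensity-threshold scale)."""
        m = np.abs(self.values).max()
        if m == 0:
            return np.zeros_like(self.values)
        return np.abs(self.values) / m


def upsample_rf(rf: np.ndarray, channel_factor: int = 5,
                time_factor: int = 4) -> np.ndarray:
    """Anti-aliased resampling of a 128 x 1024 frame to 640 x 4096 (5 sensor
    grid points per element, 80 MHz time base)."""
    if rf.shape != (128, 1024):
        raise ValueError(f"expected (128, 1024) RF, got {rf.shape}")
    out = signal.resample_poly(rf.astype(np.float64), up=time_factor, down=1, axis=1)
    out = signal.resample_poly(out, up=channel_factor, down=1, axis=0)
    return out


def interpolate_sos_map(sos_map: np.ndarray, n_out: int = FULL_NX) -> np.ndarray:
    """Bilinear interpolation of a 384 x 384 SoS map onto the reconstruction
    grid (768 x 768 at full scale).  Constant maps are preserved exactly."""
    sos_map = np.asarray(sos_map, dtype=np.float64)
    if not np.all(np.isfinite(sos_map)):
        raise ValueError("SoS map contains non-finite values")
    if sos_map.shape[0] == n_out:
        return sos_map.copy()
    if np.ptp(sos_map) == 0:
        return np.full((n_out, n_out), sos_map.flat[0])
    zoom = n_out / sos_map.shape[0]
    return ndimage.zoom(sos_map, zoom, order=1, mode="nearest", grid_mode=True)


def zero_first_time_steps(rf: np.ndarray, n: int = N_ZERO_TR,
                          resample_factor: int = 1) -> np.ndarray:
    """Blank the first `n` (of 1024) RF samples; `resample_factor` scales the
    count when the time axis has already been upsampled (150 -> 600 at 4x)."""
    n_eff = n * resample_factor
    if n_eff >= rf.shape[1]:
        raise ValueError("cannot zero the entire frame")
    out = rf.copy()
    out[:, :n_eff] = 0.0
    return out


def _build_recon_medium(sos: Union[float, np.ndarray], nx: int,
                        pml: int = DEFAULT_PML) -> AcousticMedium:
    """(nx + 2*pml) x nx medium: the SoS field occupies the interior rows
    between the probe-edge and far-edge absorbing layers."""
    nz = nx + 2 * pml
    dx_mm = EXTENT_MM / nx
    if np.isscalar(sos):
        if sos <= 0:
            raise ValueError("sound speed must be positive")
        field_ = np.full((nz, nx), float(sos))
    else:
        sos = np.asarray(sos, dtype=np.float64)
        if sos.shape != (nx, nx):
            raise ValueError(f"SoS field shape {sos.shape} != ({nx}, {nx})")
        if np.any(sos <= 0):
            raise ValueError("SoS field contains non-positive values")
        field_ = np.empty((nz, nx))
        field_[pml:pml + nx] = sos
        field_[:pml] = sos[0]
        field_[pml + nx:] = sos[-1]
    density = np.full((nz, nx), DENSITY_KG_M3)
    attenuation = np.zeros((nz, nx))  # lossless reversal (no gain compensation)
    return AcousticMedium(field_, density, attenuation, dx_mm)


def time_reversal(rf: np.ndarray, sos: Union[float, np.ndarray],
                  probe: ProbeGeometry, nx: int = FULL_NX,
                  pml: int = DEFAULT_PML, rf_rate_hz: float = RF_RATE_HZ,
                  sos_source: str = "constant",
                  time_window_s: Optional[float] = None) -> PAImage:
    """Re-emit time-reversed element traces as Dirichlet pressure sources.

    `rf` is (n_elements, T) at `rf_rate_hz` (or (n_sensor_points, T) when the
    channels were upsampled to the per-element grid points).  The final
    interior pressure field, cropped to nx x nx, is the reconstruction;
    negative lobes are retained until display normalization.
    """
    medium = _build_recon_medium(sos, nx, pml)
    dx_mm = medium.dx_mm
    dt = solver_dt(dx_mm, float(medium.sos.max()))
    duration = rf.shape[1] / rf_rate_hz
    if time_window_s is not None:
        keep = int(round(time_window_s * rf_rate_hz))
        rf = rf[:, :min(keep, rf.shape[1])]
        duration = rf.shape[1] / rf_rate_hz
    n_steps = int(round(duration / dt))

    cols = probe.element_columns(nx, dx_mm)
    n_points = sum(len(c) for c in cols)
    flat_cols = np.concatenate(cols)
    rows = np.full(flat_cols.size, pml)

    # map traces to sensor grid points
    if rf.shape[0] == probe.n_elements:
        per_elem = [rf[e] for e in range(probe.n_elements)]
        traces = np.vstack([np.tile(per_elem[e], (len(cols[e]), 1))
                            for e in range(probe.n_elements)])
    elif rf.shape[0] == n_points:
        traces = rf
    else:
        raise ValueError(f"RF rows {rf.shape[0]} match neither n_elements "
                         f"({probe.n_elements}) nor sensor points ({n_points})")

    # reverse in time and interpolate onto the solver clock
    rev = traces[:, ::-1].astype(np.float64)
    t_rf = np.arange(rev.shape[1]) / rf_rate_hz
    t_solver = np.arange(n_steps) * dt
    drive = np.empty((rev.shape[0], n_steps), dtype=np.float32)
    for i in range(rev.shape[0]):
        drive[i] = np.interp(t_solver, t_rf, rev[i], left=0.0, right=0.0)

    solver = KSpaceSolver(medium, SimulationGrid(medium.shape, dx_mm, pml, dt, n_steps),
                          use_absorption=False,
                          dispersion_ref_hz=probe.center_frequency_hz)
    _, final_p = solver.run(n_steps, dirichlet_rows=rows, dirichlet_cols=flat_cols,
                            dirichlet_traces=drive, record_final=True)
    image = final_p[pml:pml + nx, :].astype(np.float64)
    return PAImage(image, pixel_size_mm=dx_mm, sos_source=sos_source,
                   meta={"nx": nx, "pml": pml, "dt_s": dt})


def reconstruct(rf_raw: np.ndarray, sos_spec: Union[float, np.ndarray, SoSLabel],
                probe: ProbeGeometry, nx: int = FULL_NX,
                sos_source: Optional[str] = None, n_zero: int = N_ZERO_TR,
                time_window_s: Optional[float] = None) -> PAImage:
    """Composed reconstruction path: early-sample blanking, RF resampling (at
    full scale), SoS-map interpolation, then time reversal.

    `sos_spec` is a scalar (conventional / autofocus SoS), a 384 x 384 map
    (network output or ground-truth label) or an `SoSLabel`.
    """
    rf = np.asarray(rf_raw, dtype=np.float64)
    if rf.ndim != 2:
        raise ValueError("RF must be 2-D (channels x samples)")
    rf = zero_first_time_steps(rf, n=n_zero) if n_zero else rf

    if isinstance(sos_spec, SoSLabel):
        sos_spec = sos_spec.values
    if np.isscalar(sos_spec):
        sos_field: Union[float, np.ndarray] = float(sos_spec)
        source = sos_source or "constant"
    else:
        sos_field = interpolate_sos_map(np.asarray(sos_spec), n_out=nx)
        source = sos_source or "dl"

    rate = RF_RATE_HZ
    if nx == FULL_NX and rf.shape == (128, 1024):
        rf = upsample_rf(rf)  # 640 x 4096: 5 points/element, 80 MHz
        rate = RF_RATE_HZ * 4
    return time_reversal(rf, sos_field, probe, nx=nx, rf_rate_hz=rate,
                         sos_source=source, time_window_s=time_window_s)
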