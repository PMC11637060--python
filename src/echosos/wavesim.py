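"""2-D linear-acoustics forward solver (k-space pseudospectral time domain).

Solves the coupled first-order equations for heterogeneous sound speed c(x)
and mass density rho0(x),

    du/dt   = -(1/rho0) grad p
    drho/dt = -rho0 div u          (split into x/z components for the PML)
    p       = c^2 (rho + absorption terms)

with spectral spatial derivatives on spatially staggered grids, the exact
k-space temporal correction sinc(c_ref |k| dt / 2), split-field perfectly
matched layers, and fractional-Laplacian power-law absorption (exponent
y = 1.01 approximating the soft-tissue dB/(MHz cm) law).

The same stepper serves pulse-echo transmit (additive pressure sources at the
transducer elements), photoacoustic forward propagation (initial-pressure
release) and time-reversal reconstruction (Dirichlet pressure enforcement on
the sensor line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import fft as sfft

from .phantoms import AcousticMedium, EXTENT_MM

RF_RATE_HZ = 20e6  # target RF clock of the imaging system
DEFAULT_PML = 10
DEFAULT_CFL = 0.3


@dataclass
class ProbeGeometry:
    """128-element linear array spanning one grid edge (38.4 mm aperture)."""

    n_elements: int = 128
    pitch_mm: float = 0.3
    center_frequency_hz: float = 7e6
    kerf_grid_points: int = 1

    @property
    def aperture_mm(self) -> float:
        return self.n_elements * self.pitch_mm

    def element_columns(self, nx: int, dx_mm: float) -> List[np.ndarray]:
        """Grid columns covered by each element (kerf columns excluded).

        At the full 0.025 mm grid this yields 11 points per element + 1 kerf;
        on coarser desk grids the pattern scales down proportionally.
        """
        per_pitch = self.pitch_mm / dx_mm
        if abs(per_pitch - round(per_pitch)) > 1e-6:
            raise ValueError(f"pitch {self.pitch_mm} mm not commensurate with dx {dx_mm} mm")
        per_pitch = int(round(per_pitch))
        n_active = max(1, per_pitch - self.kerf_grid_points)
        cols = []
        for i in range(self.n_elements):
            start = i * per_pitch
            cols.append(np.arange(start, start + n_active))
        if cols[-1][-1] >= nx:
            raise ValueError("probe does not fit on the grid edge")
        return cols

    def element_x_mm(self) -> np.ndarray:
        """Element center abscissae relative to the array center."""
        return (np.arange(self.n_elements) + 0.5) * self.pitch_mm - self.aperture_mm / 2


@dataclass
class SimulationGrid:
    shape: Tuple[int, int]
    dx_mm: float
    pml_thickness: int = DEFAULT_PML
    time_step_s: float = 0.0
    n_time_steps: int = 0

    @property
    def dx_m(self) -> float:
        return self.dx_mm * 1e-3


@dataclass
class Waveform:
    samples: np.ndarray
    sample_rate_hz: float


@dataclass
class RFFrame:
    """Per-element time series (channels x samples)."""

    data: np.ndarray
    sample_rate_hz: float
    transmit: str = "plane_wave"  # plane_wave | pa_passive
    t0_s: float = 0.0
    meta: dict = field(default_factory=dict)


def tone_burst(fc_hz: float, n_cycles: int, fs_hz: float) -> Waveform:
    """Hann-windowed tone burst of `n_cycles` at `fc_hz`, sampled at `fs_hz`."""
    if fs_hz <= 2 * fc_hz:
        raise ValueError("sampling rate must exceed twice the center frequency")
    if n_cycles <= 0:
        return Waveform(np.zeros(0), fs_hz)
    n = max(2, int(round(n_cycles / fc_hz * fs_hz)))
    t = np.arange(n) / fs_hz
    w = np.sin(2 * np.pi * fc_hz * t) * np.hanning(n)
    return Waveform(w.astype(np.float64), fs_hz)


def solver_dt(dx_mm: float, c_max: float = 1600.0, cfl: float = DEFAULT_CFL) -> float:
    """Largest dt = 50 ns / k (integer k) satisfying the CFL bound, so the
    solver rate is an exact integer multiple of the 20 MHz RF clock."""
    base = 1.0 / RF_RATE_HZ
    k = 1
    while c_max * (base / k) / (dx_mm * 1e-3) > cfl:
        k += 1
    return base / k


def grid_for_medium(medium: AcousticMedium, n_time_steps: Optional[int] = None,
                    duration_s: Optional[float] = None,
                    pml: int = DEFAULT_PML) -> SimulationGrid:
    dt = solver_dt(medium.dx_mm, float(medium.sos.max()))
    if n_time_steps is None:
        if duration_s is None:
            duration_s = 1024 / RF_RATE_HZ  # 51.2 us: full RF window
        n_time_steps = int(round(duration_s / dt))
    return SimulationGrid(medium.shape, medium.dx_mm, pml, dt, n_time_steps)


def _db_mhz_cm_to_nepers(alpha_db: np.ndarray, y: float) -> np.ndarray:
    # dB/(MHz^y cm) -> Np (rad/s)^-y m^-1
    return 100.0 * alpha_db * (1e-6 / (2 * np.pi)) ** y / (20.0 / np.log(10.0))


class KSpaceSolver:
    """Pseudospectral stepper bound to one medium + grid."""

    def __init__(self, medium: AcousticMedium, grid: SimulationGrid,
                 power_law_y: float = 1.01, pml_alpha: float = 2.0,
                 use_absorption: bool = True, dispersion_ref_hz: float = 5e6):
        nz, nx = medium.shape
        self.grid = grid
        self.dt = grid.time_step_s
        dx = grid.dx_m
        self.c = medium.sos.astype(np.float32)
        self.c2 = (self.c.astype(np.float64) ** 2).astype(np.float32)
        self.rho0 = medium.density.astype(np.float32)
        c_ref = float(medium.sos.max())

        # operators live on the rfft2 half-spectrum (fields are real)
        kz = 2 * np.pi * np.fft.fftfreq(nz, d=dx)
        kx = 2 * np.pi * np.fft.rfftfreq(nx, d=dx)
        K = np.sqrt(kz[:, None] ** 2 + kx[None, :] ** 2)
        kappa = np.sinc(c_ref * K * self.dt / 2 / np.pi)
        self.ddz_pos = (1j * kz[:, None] * np.exp(1j * kz[:, None] * dx / 2) * kappa).astype(np.complex64)
        self.ddz_neg = (1j * kz[:, None] * np.exp(-1j * kz[:, None] * dx / 2) * kappa).astype(np.complex64)
        self.ddx_pos = (1j * kx[None, :] * np.exp(1j * kx[None, :] * dx / 2) * kappa).astype(np.complex64)
        self.ddx_neg = (1j * kx[None, :] * np.exp(-1j * kx[None, :] * dx / 2) * kappa).astype(np.complex64)
        self._shape = (nz, nx)

        # split-field PML (quartic profile, all four sides)
        def pml_profile(n: int, staggered: bool) -> np.ndarray:
            sigma = np.zeros(n)
            L = grid.pml_thickness
            i = np.arange(n) + (0.5 if staggered else 0.0)
            left = i < L
            sigma[left] = ((L - i[left]) / L) ** 4
            right = i > n - 1 - L
            sigma[right] = ((i[right] - (n - 1 - L)) / L) ** 4
            sigma *= pml_alpha * c_ref / dx
            return np.exp(-sigma * self.dt / 2)

        self.pml_z = pml_profile(nz, False)[:, None].astype(np.float32)
        self.pml_z_sg = pml_profile(nz, True)[:, None].astype(np.float32)
        self.pml_x = pml_profile(nx, False)[None, :].astype(np.float32)
        self.pml_x_sg = pml_profile(nx, True)[None, :].astype(np.float32)

        self.use_absorption = use_absorption and float(medium.attenuation.max()) > 0
        if self.use_absorption:
            y = power_law_y
            a0 = _db_mhz_cm_to_nepers(medium.attenuation.astype(np.float64), y)
            cd = self.c.astype(np.float64)
            self.absorb_tau = (-2.0 * a0 * cd ** (y - 1)).astype(np.float32)
            self.absorb_eta = (2.0 * a0 * cd ** y * np.tan(np.pi * y / 2)).astype(np.float32)
            Ksafe = K.copy()
            Ksafe[0, 0] = 1.0
            self.nabla1 = (Ksafe ** (y - 2)).astype(np.float32)
            # Dispersion re-referenced to the transmit band center: with the
            # zero-frequency reference of the raw fractional Laplacian, y near
            # 1 shifts the in-band phase velocity by several percent (the
            # tan(pi*y/2) factor diverges).  Subtracting k_ref^(y-1) makes the
            # stated SoS the phase speed at dispersion_ref_hz.
            k_ref = 2 * np.pi * max(dispersion_ref_hz, 1.0) / c_ref
            self.nabla2 = (Ksafe ** (y - 1) - k_ref ** (y - 1)).astype(np.float32)
            self.nabla1[0, 0] = 0.0
            self.nabla2[0, 0] = np.float32(-(k_ref ** (y - 1)))

    def run(self, n_steps: int,
            p0: Optional[np.ndarray] = None,
            source_mask: Optional[np.ndarray] = None,
            source_signal: Optional[np.ndarray] = None,
            dirichlet_rows: Optional[np.ndarray] = None,
            dirichlet_cols: Optional[np.ndarray] = None,
            dirichlet_traces: Optional[np.ndarray] = None,
            sensor_elements: Optional[List[Tuple[int, np.ndarray]]] = None,
            record_final: bool = False,
            smooth_p0: bool = True) -> Tuple[Optional[np.ndarray], Optional[np.ndarray]]:
        """March `n_steps`; returns (sensor RF at solver rate, final pressure).

        Sources: `p0` (initial-pressure release), additive `source_signal`
        applied on `source_mask` points, or Dirichlet traces enforced at
        (row, col) points each step (time reversal).
        """
        nz, nx = self.c.shape
        f32 = np.float32
        p = np.zeros((nz, nx), f32)
        ux = np.zeros_like(p)
        uz = np.zeros_like(p)
        rhox = np.zeros_like(p)
        rhoz = np.zeros_like(p)
        shape = (nz, nx)

        def fft2(a):
            return sfft.rfft2(a)

        def ifft2(a):
            return sfft.irfft2(a, s=shape)

        if p0 is not None:
            p0 = p0.astype(f32)
            if smooth_p0:
                p0 = _smooth(p0)
            p = p0.copy()
            rhox = (p0 / (2 * self.c2)).astype(f32)
            rhoz = rhox.copy()

        if source_mask is not None:
            src_rows, src_cols = np.nonzero(source_mask)
        rec = None
        if sensor_elements is not None:
            rec = np.zeros((len(sensor_elements), n_steps), f32)
            sens_row = sensor_elements[0][0]
            pts_per = len(sensor_elements[0][1])
            sens_flat = np.concatenate([c for _, c in sensor_elements])

        dt = f32(self.dt)
        inv_rho0_dt = (dt / self.rho0).astype(f32)
        rho0_dt = (dt * self.rho0).astype(f32)

        for step in range(n_steps):
            Fp = fft2(p)
            dpdz = ifft2(self.ddz_pos * Fp).astype(f32)
            dpdx = ifft2(self.ddx_pos * Fp).astype(f32)
            # dt/2 first step pairs the initial-pressure release with the
            # staggered velocity grid
            scale = f32(0.5) if (step == 0 and p0 is not None) else f32(1.0)
            uz = self.pml_z_sg * (self.pml_z_sg * uz - scale * inv_rho0_dt * dpdz)
            ux = self.pml_x_sg * (self.pml_x_sg * ux - scale * inv_rho0_dt * dpdx)

            duzdz = ifft2(self.ddz_neg * fft2(uz)).astype(f32)
            duxdx = ifft2(self.ddx_neg * fft2(ux)).astype(f32)
            rhoz = self.pml_z * (self.pml_z * rhoz - rho0_dt * duzdz)
            rhox = self.pml_x * (self.pml_x * rhox - rho0_dt * duxdx)

            if source_mask is not None and source_signal is not None and step < len(source_signal):
                s = f32(0.5 * source_signal[step]) * dt
                rhoz[src_rows, src_cols] += s
                rhox[src_rows, src_cols] += s

            rho_sum = rhoz + rhox
            if self.use_absorption:
                div = duzdz + duxdx
                t1 = ifft2(self.nabla1 * fft2(self.rho0 * div)).astype(f32)
                t2 = ifft2(self.nabla2 * fft2(rho_sum)).astype(f32)
                p = self.c2 * (rho_sum + self.absorb_tau * t1 - self.absorb_eta * t2)
            else:
                p = self.c2 * rho_sum

            if dirichlet_traces is not None:
                vals = dirichlet_traces[:, step].astype(f32)
                p[dirichlet_rows, dirichlet_cols] = vals
                half = vals / (2 * self.c2[dirichlet_rows, dirichlet_cols])
                rhoz[dirichlet_rows, dirichlet_cols] = half
                rhox[dirichlet_rows, dirichlet_cols] = half

            if rec is not None:
                rec[:, step] = p[sens_row, sens_flat].reshape(-1, pts_per).mean(axis=1)

            if not np.isfinite(p[nz // 2, nx // 2]):
                raise FloatingPointError(f"solver diverged at step {step}")

        return rec, (p if record_final else None)


def _smooth(field: np.ndarray) -> np.ndarray:
    """Frequency-domain Blackman smoothing of an initial-pressure field
    (suppresses the checkerboard ringing of spectral release)."""
    nz, nx = field.shape
    wz = np.fft.ifftshift(np.blackman(nz))[:, None]
    wx = np.fft.ifftshift(np.blackman(nx))[None, :]
    F = sfft.fft2(field) * wz * wx
    out = sfft.ifft2(F).real
    m = np.abs(field).max()
    if m > 0 and np.abs(out).max() > 0:
        out *= m / np.abs(out).max()
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# acquisition front-ends


def _sensor_elements(probe: ProbeGeometry, nx: int, dx_mm: float,
                     row: int) -> List[Tuple[int, np.ndarray]]:
    return [(row, cols) for cols in probe.element_columns(nx, dx_mm)]


def propagate(medium: AcousticMedium, probe: ProbeGeometry,
              grid: Optional[SimulationGrid] = None,
              p0: Optional[np.ndarray] = None,
              source_mask: Optional[np.ndarray] = None,
              source_signal: Optional[np.ndarray] = None,
              transmit: str = "pa_passive",
              use_absorption: bool = True) -> RFFrame:
    """Run the solver and record per-element RF at the solver rate."""
    if grid is None:
        grid = grid_for_medium(medium)
    solver = KSpaceSolver(medium, grid, use_absorption=use_absorption,
                          dispersion_ref_hz=probe.center_frequency_hz)
    row = grid.pml_thickness
    sensors = _sensor_elements(probe, medium.shape[1], medium.dx_mm, row)
    rec, _ = solver.run(grid.n_time_steps, p0=p0, source_mask=source_mask,
                        source_signal=source_signal, sensor_elements=sensors)
    return RFFrame(rec, 1.0 / grid.time_step_s, transmit=transmit,
                   meta={"dx_mm": medium.dx_mm, "probe_row": row})


def plane_wave_pulse_echo(medium: AcousticMedium, probe: ProbeGeometry,
                          burst: Optional[Waveform] = None,
                          grid: Optional[SimulationGrid] = None,
                          use_absorption: bool = True) -> RFFrame:
    """Single 0-degree plane-wave transmit: all elements fire the tone burst
    simultaneously; backscatter is recorded per element (no focusing)."""
    if grid is None:
        grid = grid_for_medium(medium)
    if burst is None:
        burst = tone_burst(probe.center_frequency_hz, 2, 1.0 / grid.time_step_s)
    if abs(burst.sample_rate_hz * grid.time_step_s - 1.0) > 1e-6:
        raise ValueError("burst must be sampled at the solver rate")
    nz, nx = medium.shape
    mask = np.zeros((nz, nx), dtype=bool)
    row = grid.pml_thickness
    for cols in probe.element_columns(nx, medium.dx_mm):
        mask[row, cols] = True
    frame = propagate(medium, probe, grid, source_mask=mask,
                      source_signal=burst.samples, transmit="plane_wave",
                      use_absorption=use_absorption)
    return frame


def pa_forward(medium: AcousticMedium, p0: np.ndarray, probe: ProbeGeometry,
               grid: Optional[SimulationGrid] = None,
               use_absorption: bool = True) -> RFFrame:
    """Photoacoustic forward model: release of the initial pressure `p0`."""
    if p0.shape != medium.shape:
        raise ValueError("p0 must be shaped to the medium grid")
    return propagate(medium, probe, grid, p0=p0, transmit="pa_passive",
                     use_absorption=use_absorption)


def desk_frequency(dx_mm: float, c_min: float = 1400.0, ppw: float = 3.2) -> float:
    """Transmit frequency keeping `ppw` grid points per minimum wavelength.

    The full-scale grid (0.025 mm) supports the probe's native 7 MHz; coarser
    desk grids scale the frequency down to stay resolved.
    """
    return c_min / (ppw * dx_mm * 1e-3)


def desk_probe(dx_mm: float) -> ProbeGeometry:
    return ProbeGeometry(center_frequency_hz=min(7e6, desk_frequency(dx_mm)))
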