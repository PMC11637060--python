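"""Shared fixtures: desk-scale simulation products reused across test modules.

All heavy solver products are session-scoped so each wave simulation runs at
most once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from echosos import phantoms as ph
from echosos import wavesim as ws
from echosos import rfpipe as rp


@pytest.fixture(scope="session")
def probe_256():
    return ws.desk_probe(ph.EXTENT_MM / 256)


@pytest.fixture(scope="session")
def point_rf_256(probe_256):
    """PA frame of a single point source at (0, 15 mm) in homogeneous
    1500 m/s tissue on a 256-per-side desk grid (travel-time oracle)."""
    med = ph.rasterize_medium(ph.PhantomSpec(background_sos=1500.0), n=256)
    p0 = ph.place_point_absorbers([(0.0, 15.0)], med.shape, med.dx_mm, z0_row=10)
    grid = ws.grid_for_medium(med, duration_s=16e-6)
    rf = ws.pa_forward(med, p0, probe_256, grid)
    return rf


@pytest.fixture(scope="session")
def point_rf_256_20mhz(point_rf_256):
    """The same frame decimated to the 20 MHz RF clock (reconstruction input)."""
    frame = rp.downsample_to_20mhz(point_rf_256, n_out=point_rf_256.data.shape[1]
                                   * 20_000_000 // int(point_rf_256.sample_rate_hz))
    return frame


@pytest.fixture(scope="session")
def scatterer_rf_128():
    """Plane-wave pulse-echo frame of a single strong point scatterer at
    (3 mm, 18 mm) in homogeneous 1540 m/s tissue (128-per-side grid), plus the
    geometry needed to predict its echo hyperbola."""
    n = 128
    probe = ws.desk_probe(ph.EXTENT_MM / n)
    clean = ph.rasterize_medium(ph.PhantomSpec(background_sos=1540.0), n=n)
    med = clean.copy()
    row = 10 + int(round(18.0 / med.dx_mm))
    col = int(round(3.0 / med.dx_mm + n / 2 - 0.5))
    med.density[row, col] *= 1.5
    grid = ws.grid_for_medium(med, duration_s=40e-6)
    rf = ws.plane_wave_pulse_echo(med, probe, grid=grid)
    rf_ref = ws.plane_wave_pulse_echo(clean, probe, grid=grid)
    scattered = ws.RFFrame(rf.data - rf_ref.data, rf.sample_rate_hz)
    # report the scatterer position actually rasterized (pixel centers)
    x_mm = (col + 0.5) * med.dx_mm - ph.EXTENT_MM / 2
    depth_mm = (row - 10) * med.dx_mm
    return {"rf": rf, "scattered": scattered, "probe": probe, "c": 1540.0,
            "x_mm": x_mm, "depth_mm": depth_mm, "dx_mm": med.dx_mm,
            "burst_center_s": 1.0 / probe.center_frequency_hz}
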