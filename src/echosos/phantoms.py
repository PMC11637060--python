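"""Digital tissue phantoms for pulse-echo ultrasound and photoacoustic simulation.

A phantom is described parametrically (:class:`PhantomSpec`): a homogeneous
background speed of sound (SoS), elliptical inclusions and/or layered
structures with their own bulk SoS, plus sub-resolution scatterers that give
rise to speckle.  Specs are rasterized onto a simulation grid covering a
38.4 mm x 38.4 mm medium as an :class:`AcousticMedium` (SoS, mass density and
acoustic attenuation fields).  The bulk SoS field, free of speckle and
echogenicity perturbations, is the ground-truth label for the SoS regression
network (:class:`SoSLabel`, 384 x 384 at 0.1 mm).

Randomness flows from a single top-level seed through named substreams so a
dataset build is reproducible bit for bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

# Fixed physical extent of every phantom (mm per side).
EXTENT_MM = 38.4
# Canonical rasterization (matches the full-scale simulation grid).
FULL_GRID_N = 1536
FULL_GRID_DX_MM = 0.025
# Canonical label geometry.
LABEL_N = 384
LABEL_DX_MM = 0.1

DENSITY_KG_M3 = 1020.0
ATTENUATION_DB_MHZ_CM = 0.5

TRAINING_PATTERN = "training"
PATTERN1 = "pattern1_layered_curved"
PATTERN2 = "pattern2_layered_straight"
PATTERN3 = "pattern3_ellipse_hypoechoic"
EVAL_PATTERNS = (PATTERN1, PATTERN2, PATTERN3)


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of a top-level seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,)))


@dataclass
class EllipseInclusion:
    """Elliptical heterogeneity: bulk SoS region + echogenicity class."""

    center_mm: Tuple[float, float]  # (x, z), x in [-19.2, 19.2], z in [0, 38.4]
    semi_axes_mm: Tuple[float, float]  # (a, b): a along the rotated long axis
    orientation_rad: float
    sos: float  # m/s, bulk value
    echogenicity: str = "hyperechoic"  # hyperechoic | hypoechoic | isoechoic


@dataclass
class LayerInclusion:
    """Horizontal layer below a (possibly sine-deformed) boundary.

    The layer occupies z >= z0 + amplitude*sin(2*pi*periods*(x/extent) + phase).
    """

    z0_mm: float
    sos: float
    amplitude_mm: float = 0.0
    periods: float = 0.0
    phase_rad: float = 0.0


@dataclass
class PhantomSpec:
    background_sos: float
    inclusions: List[EllipseInclusion] = field(default_factory=list)
    layers: Optional[List[LayerInclusion]] = None
    scatterer_density: float = 3.0  # mean count per lambda^2
    pattern_id: str = TRAINING_PATTERN
    rng_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "PhantomSpec":
        d = json.loads(s)
        d["inclusions"] = [EllipseInclusion(**{**e, "center_mm": tuple(e["center_mm"]),
                                               "semi_axes_mm": tuple(e["semi_axes_mm"])})
                           for e in d["inclusions"]]
        if d.get("layers") is not None:
            d["layers"] = [LayerInclusion(**l) for l in d["layers"]]
        return cls(**d)


@dataclass
class ScattererField:
    rows: np.ndarray  # grid row indices
    cols: np.ndarray
    amplitudes: np.ndarray  # fractional perturbations in [-0.03, 0.03]


@dataclass
class AcousticMedium:
    """Gridded acoustic properties on an (nz, nx) grid, z = depth axis."""

    sos: np.ndarray  # m/s
    density: np.ndarray  # kg/m^3
    attenuation: np.ndarray  # dB/(MHz cm)
    dx_mm: float

    @property
    def shape(self) -> Tuple[int, int]:
        return self.sos.shape

    def copy(self) -> "AcousticMedium":
        return AcousticMedium(self.sos.copy(), self.density.copy(),
                              self.attenuation.copy(), self.dx_mm)


@dataclass
class SoSLabel:
    values: np.ndarray  # (384, 384) m/s
    pixel_size_mm: float = LABEL_DX_MM


# ---------------------------------------------------------------------------
# sampling


@dataclass
class TrainingBounds:
    """Generation bounds for randomized training phantoms."""

    sos_min: float = 1400.0
    sos_max: float = 1600.0
    inclusion_frac_min: float = 0.01  # inclusion SoS = background * (1 + u)
    inclusion_frac_max: float = 0.07
    n_inclusions_min: int = 1
    n_inclusions_max: int = 5
    long_semi_axis_max_mm: float = EXTENT_MM  # long axis up to 2 x 38.4 mm
    short_semi_axis_max_mm: float = EXTENT_MM / 2.0
    scatterer_density: float = 3.0

    def validate(self) -> None:
        if self.sos_min > self.sos_max:
            raise ValueError("sos bounds inverted")
        if self.inclusion_frac_min > self.inclusion_frac_max:
            raise ValueError("inclusion fraction bounds inverted")
        if self.n_inclusions_min > self.n_inclusions_max or self.n_inclusions_min < 0:
            raise ValueError("inclusion count bounds invalid")


def sample_training_phantom(seed: int, config: TrainingBounds | None = None) -> PhantomSpec:
    """Draw a randomized training phantom.

    Background SoS ~ U[1400, 1600] m/s; each elliptical inclusion is 1-7 %
    faster than the background and hyperechoic; geometry is uniform over the
    allowed axis/orientation ranges.
    """
    cfg = config or TrainingBounds()
    cfg.validate()
    geo = substream(seed, "geometry")
    sos_rng = substream(seed, "sos")
    background = float(sos_rng.uniform(cfg.sos_min, cfg.sos_max))
    n_inc = int(geo.integers(cfg.n_inclusions_min, cfg.n_inclusions_max + 1))
    inclusions = []
    for _ in range(n_inc):
        u = float(sos_rng.uniform(cfg.inclusion_frac_min, cfg.inclusion_frac_max))
        a = float(geo.uniform(0.0, cfg.long_semi_axis_max_mm))
        b = float(geo.uniform(0.0, min(a, cfg.short_semi_axis_max_mm)))
        inclusions.append(EllipseInclusion(
            center_mm=(float(geo.uniform(-EXTENT_MM / 2, EXTENT_MM / 2)),
                       float(geo.uniform(0.0, EXTENT_MM))),
            semi_axes_mm=(a, b),
            orientation_rad=float(geo.uniform(0.0, np.pi)),
            sos=background * (1.0 + u),
            echogenicity="hyperechoic",
        ))
    return PhantomSpec(background_sos=background, inclusions=inclusions,
                       scatterer_density=cfg.scatterer_density,
                       pattern_id=TRAINING_PATTERN, rng_seed=int(seed))


def make_evaluation_phantom(pattern: str | int, seed: int) -> PhantomSpec:
    """Evaluation phantoms drawn from geometries absent from the training set.

    Pattern 1: two layers separated by a sine-deformed boundary, uniform
    echogenicity.  Pattern 2: straight isoechoic layers.  Pattern 3:
    homogeneous background with hypoechoic elliptical inclusions.
    """
    names = {1: PATTERN1, 2: PATTERN2, 3: PATTERN3}
    if isinstance(pattern, (int, np.integer)):
        if pattern not in names:
            raise ValueError(f"unknown pattern id {pattern!r}")
        pattern = names[pattern]
    if pattern not in EVAL_PATTERNS:
        raise ValueError(f"unknown pattern id {pattern!r}")
    geo = substream(seed, "geometry")
    sos_rng = substream(seed, "sos")
    background = float(sos_rng.uniform(1400.0, 1600.0))
    if pattern == PATTERN1:
        layer_sos = float(sos_rng.uniform(1400.0, 1600.0))
        layers = [LayerInclusion(
            z0_mm=float(geo.uniform(12.0, 26.0)),
            sos=layer_sos,
            amplitude_mm=float(geo.uniform(1.0, 4.0)),
            periods=float(geo.uniform(1.0, 2.0)),
            phase_rad=float(geo.uniform(0.0, 2 * np.pi)),
        )]
        return PhantomSpec(background, [], layers, 3.0, PATTERN1, int(seed))
    if pattern == PATTERN2:
        n_layers = int(geo.integers(1, 3))
        z0s = np.sort(geo.uniform(8.0, 30.0, size=n_layers))
        layers = [LayerInclusion(z0_mm=float(z), sos=float(sos_rng.uniform(1400.0, 1600.0)))
                  for z in z0s]
        return PhantomSpec(background, [], layers, 3.0, PATTERN2, int(seed))
    # Pattern 3: hypoechoic ellipses on a homogeneous background.
    n_inc = int(geo.integers(1, 4))
    inclusions = []
    for _ in range(n_inc):
        u = float(sos_rng.uniform(0.01, 0.07))
        inclusions.append(EllipseInclusion(
            center_mm=(float(geo.uniform(-12.0, 12.0)), float(geo.uniform(8.0, 30.0))),
            semi_axes_mm=(float(geo.uniform(3.0, 8.0)), float(geo.uniform(2.0, 6.0))),
            orientation_rad=float(geo.uniform(0.0, np.pi)),
            sos=background * (1.0 + u),
            echogenicity="hypoechoic",
        ))
    return PhantomSpec(background, inclusions, None, 3.0, PATTERN3, int(seed))


# ---------------------------------------------------------------------------
# rasterization


def _grid_coords_mm(n: int, dx_mm: float) -> Tuple[np.ndarray, np.ndarray]:
    # Pixel centers; x symmetric about the array axis, z from the probe face.
    z = (np.arange(n) + 0.5) * dx_mm
    x = (np.arange(n) + 0.5) * dx_mm - EXTENT_MM / 2
    return z[:, None], x[None, :]


def ellipse_mask(inc: EllipseInclusion, n: int, dx_mm: float) -> np.ndarray:
    z, x = _grid_coords_mm(n, dx_mm)
    xr = x - inc.center_mm[0]
    zr = z - inc.center_mm[1]
    c, s = np.cos(inc.orientation_rad), np.sin(inc.orientation_rad)
    u = xr * c + zr * s
    v = -xr * s + zr * c
    a = max(inc.semi_axes_mm[0], 1e-9)
    b = max(inc.semi_axes_mm[1], 1e-9)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def layer_mask(layer: LayerInclusion, n: int, dx_mm: float) -> np.ndarray:
    z, x = _grid_coords_mm(n, dx_mm)
    boundary = layer.z0_mm + layer.amplitude_mm * np.sin(
        2 * np.pi * layer.periods * (x + EXTENT_MM / 2) / EXTENT_MM + layer.phase_rad)
    return z >= boundary


def rasterize_medium(spec: PhantomSpec, n: int = FULL_GRID_N,
                     dx_mm: float | None = None) -> AcousticMedium:
    """Rasterize the bulk (speckle-free) SoS field of a phantom.

    Membership is decided per pixel center; later-listed structures overwrite
    earlier ones on overlap.  Density and attenuation are uniform soft-tissue
    averages (1020 kg/m^3, 0.5 dB/(MHz cm)).
    """
    dx = EXTENT_MM / n if dx_mm is None else dx_mm
    if abs(n * dx - EXTENT_MM) > 1e-6:
        raise ValueError(f"grid extent {n * dx:.4f} mm != {EXTENT_MM} mm")
    sos = np.full((n, n), spec.background_sos, dtype=np.float64)
    for layer in (spec.layers or []):
        sos[layer_mask(layer, n, dx)] = layer.sos
    for inc in spec.inclusions:
        sos[ellipse_mask(inc, n, dx)] = inc.sos
    density = np.full((n, n), DENSITY_KG_M3, dtype=np.float64)
    attenuation = np.full((n, n), ATTENUATION_DB_MHZ_CM, dtype=np.float64)
    return AcousticMedium(sos, density, attenuation, dx)


def apply_echogenicity(medium: AcousticMedium, spec: PhantomSpec,
                       seed: int) -> AcousticMedium:
    """Hyperechoic contrast: raise SoS by 7-11 % of background at ~10 % of the
    grid points inside each hyperechoic inclusion.  Iso/hypoechoic inclusions
    are untouched here (hypoechogenicity acts on scatterer amplitudes)."""
    rng = substream(seed, "echogenicity")
    out = medium.copy()
    n = medium.shape[0]
    for inc in spec.inclusions:
        if inc.echogenicity != "hyperechoic":
            continue
        mask = ellipse_mask(inc, n, medium.dx_mm)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sel = idx[rng.random(idx.size) < 0.10]
        incr = rng.uniform(0.07, 0.11, size=sel.size)
        out.sos.flat[sel] = spec.background_sos * (1.0 + incr)
    return out


def sprinkle_scatterers(medium: AcousticMedium, density: float, fc_hz: float,
                        seed: int, spec: PhantomSpec | None = None
                        ) -> Tuple[AcousticMedium, ScattererField]:
    """Sprinkle sub-resolution scatterers at `density` per wavelength^2.

    Scatterers perturb the mass density fractionally, rho -> rho*(1+a) with
    a ~ U[-0.03, 0.03], which creates speckle in pulse-echo imaging while
    leaving the SoS label clean.  Inside hypoechoic inclusions the amplitudes
    are scaled down by a factor drawn from U[0.1, 0.5].
    """
    if density < 0:
        raise ValueError("scatterer density must be >= 0")
    rng = substream(seed, "scatterers")
    out = medium.copy()
    n = medium.shape[0]
    if density == 0:
        empty = np.empty(0, dtype=np.int64)
        return out, ScattererField(empty, empty, np.empty(0))
    c_bg = spec.background_sos if spec is not None else float(np.median(medium.sos))
    lam_mm = c_bg / fc_hz * 1e3
    expected = density * EXTENT_MM ** 2 / lam_mm ** 2
    count = int(rng.poisson(expected))
    rows = rng.integers(0, n, size=count)
    cols = rng.integers(0, n, size=count)
    amps = rng.uniform(-0.03, 0.03, size=count)
    if spec is not None:
        hypo = [inc for inc in spec.inclusions if inc.echogenicity == "hypoechoic"]
        if hypo:
            scale_map = np.ones((n, n))
            for inc in hypo:
                scale_map[ellipse_mask(inc, n, medium.dx_mm)] = rng.uniform(0.1, 0.5)
            amps = amps * scale_map[rows, cols]
    np.add.at(out.density, (rows, cols), DENSITY_KG_M3 * amps)
    return out, ScattererField(rows, cols, amps)


def label_from_medium(medium: AcousticMedium) -> SoSLabel:
    """Reduce (or expand) a rasterized bulk-SoS field to the 384x384, 0.1 mm
    label grid.  Integer-divisible shapes use exact block means; integer
    upsampling replicates pixels (desk-scale grids below 384)."""
    n = medium.shape[0]
    if medium.shape[0] != medium.shape[1]:
        raise ValueError("label derivation expects a square medium")
    if n % LABEL_N == 0:
        k = n // LABEL_N
        vals = medium.sos.reshape(LABEL_N, k, LABEL_N, k).mean(axis=(1, 3))
    elif LABEL_N % n == 0:
        k = LABEL_N // n
        vals = np.kron(medium.sos, np.ones((k, k)))
    else:
        raise ValueError(f"medium size {n} not commensurate with label size {LABEL_N}")
    return SoSLabel(vals.astype(np.float32))


def ground_truth_label(spec: PhantomSpec) -> SoSLabel:
    """Label rasterized directly on the 384x384 grid (bulk SoS only)."""
    return label_from_medium(rasterize_medium(spec, n=LABEL_N))


def place_point_absorbers(coords_mm: Sequence[Tuple[float, float]], shape: Tuple[int, int],
                          dx_mm: float, z0_row: int = 0, radius_mm: float = 0.0) -> np.ndarray:
    """Initial-pressure field with unit-amplitude point (or small-disk) sources.

    `coords_mm` are (x, z) with x measured from the array center and z the
    depth below the probe face (grid row `z0_row`).
    """
    p0 = np.zeros(shape, dtype=np.float64)
    nz, nx = shape
    for (x_mm, z_mm) in coords_mm:
        col = x_mm / dx_mm + nx / 2 - 0.5
        row = z0_row + z_mm / dx_mm
        ir, ic = int(round(row)), int(round(col))
        if not (0 <= ir < nz and 0 <= ic < nx):
            raise ValueError(f"source ({x_mm}, {z_mm}) mm outside the grid")
        if radius_mm <= 0:
            p0[ir, ic] = 1.0
        else:
            r = radius_mm / dx_mm
            half = int(np.ceil(r)) + 1
            zz, xx = np.mgrid[ir - half:ir + half + 1, ic - half:ic + half + 1]
            keep = ((zz - row) ** 2 + (xx - col) ** 2 <= r ** 2)
            keep &= (zz >= 0) & (zz < nz) & (xx >= 0) & (xx < nx)
            p0[zz[keep], xx[keep]] = 1.0
    return p0


def realize(spec: PhantomSpec, n: int, fc_hz: float,
            seed: int | None = None) -> Tuple[AcousticMedium, AcousticMedium, SoSLabel]:
    """Full phantom realization: (bulk medium, scattering medium, label)."""
    seed = spec.rng_seed if seed is None else seed
    bulk = rasterize_medium(spec, n=n)
    med = apply_echogenicity(bulk, spec, seed)
    med, _ = sprinkle_scatterers(med, spec.scatterer_density, fc_hz, seed, spec=spec)
    return bulk, med, label_from_medium(bulk)
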