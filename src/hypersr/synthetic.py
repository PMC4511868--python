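"""Ground-truth scenes and acquisition simulators standing in for the
instrument.

Two study scenes are emulated:

* a lithography-style resolution target — bars of equal width and spacing
  (and a step-edge marker) on an otherwise empty canvas, imaged through a
  Gaussian PSF with 1 μm low-resolution pixels and a 100 nm shift grid;
* a multi-component sub-micron particle field over a 900-1190 cm^-1 Raman
  axis, with per-component pure spectra (sums of Gaussian bands), a smooth
  fluorescence-like additive baseline and additive Gaussian noise, acquired
  as a series of cubes shifted by multiples of 200 nm.

Every generator is deterministic given its seed.  The acquisition model is
exactly the forward operator of the reconstruction (translate, blur,
decimate) plus noise, so recovery tests exercise the genuine inverse
problem rather than an idealized one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hyperdata import HyperCube, MapImage
from .superres import PSFModel, ShiftedMapSeries, _blur_matrix, apply_forward

__all__ = ["SyntheticScene", "make_bar_target", "make_edge_target",
           "raster_shift_grid", "simulate_map_series", "make_mixture_scene",
           "simulate_cube_series", "DEFAULT_BAND_TABLE"]

# Per-component Gaussian bands (center cm^-1, width sigma cm^-1, height) in
# 900-1190 cm^-1, loosely shaped like sulfate/nitrate particle spectra; any
# user table can replace it.
DEFAULT_BAND_TABLE = [
    [(940.0, 6.0, 1.0), (1130.0, 12.0, 0.35)],
    [(992.0, 5.0, 1.0)],
    [(1008.0, 6.0, 1.0), (970.0, 8.0, 0.25)],
    [(1050.0, 7.0, 1.0)],
    [(1085.0, 9.0, 1.0), (1160.0, 10.0, 0.3)],
    [(920.0, 10.0, 0.6), (1105.0, 8.0, 1.0)],
]


@dataclass
class SyntheticScene:
    """Ground truth the instrument never gives us: per-component HR maps,
    pure spectra, baseline parameters and the noise level."""

    hr_truth: list
    pure_spectra: np.ndarray
    wavenumbers: np.ndarray
    # fluorescence varies slowly across a ~300 cm^-1 Raman window; the decay
    # constant is several window widths so the background is gently curved
    baseline_tau: float = 600.0
    baseline_amp_sigma: float = 0.5
    noise_sigma: float = 0.0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {m.values.shape for m in self.hr_truth}
        pitches = {m.pixel_size for m in self.hr_truth}
        if len(shapes) != 1 or len(pitches) != 1:
            raise ValueError("truth maps must share shape and pitch")
        self.pure_spectra = np.asarray(self.pure_spectra, dtype=float)
        if np.any(self.pure_spectra < 0):
            raise ValueError("pure spectra must be non-negative")
        if self.pure_spectra.shape != (len(self.hr_truth), self.wavenumbers.size):
            raise ValueError("pure_spectra must be (n_components, n_wavenumbers)")

    @property
    def n_components(self) -> int:
        return len(self.hr_truth)


def make_bar_target(bar_width: int, n_bars: int = 5, canvas=None,
                    pixel_size: float = 0.1) -> MapImage:
    """Binary bar pattern: n vertical bars of width w separated by gaps of w.

    The pattern's bounding box is (2n-1)*w wide and (2n-1)*w tall, centred
    on the canvas (default canvas: bounding box plus a 2w margin).  Halving
    the width replicates the pattern homothetically, as on a resolution
    test chart.
    """
    if bar_width < 1 or n_bars < 1:
        raise ValueError("bar_width and n_bars must be >= 1")
    box = (2 * n_bars - 1) * bar_width
    if canvas is None:
        canvas = (box + 4 * bar_width, box + 4 * bar_width)
    elif np.isscalar(canvas):
        canvas = (int(canvas), int(canvas))
    ny, nx = canvas
    if box > ny or box > nx:
        raise ValueError(f"pattern box {box} px exceeds canvas {canvas}")
    values = np.zeros((ny, nx))
    y0 = (ny - box) // 2
    x0 = (nx - box) // 2
    for b in range(n_bars):
        x = x0 + 2 * b * bar_width
        values[y0:y0 + box, x:x + bar_width] = 1.0
    return MapImage(values, pixel_size=pixel_size)


def make_edge_target(canvas, edge_position: int, axis: str = "x",
                     pixel_size: float = 0.1) -> MapImage:
    """Binary step along the chosen axis (the location-marker analogue)."""
    if np.isscalar(canvas):
        canvas = (int(canvas), int(canvas))
    ny, nx = canvas
    limit = nx if axis == "x" else ny
    if not 0 < edge_position < limit:
        raise ValueError(f"edge_position must lie in (0, {limit})")
    values = np.zeros((ny, nx))
    if axis == "x":
        values[:, edge_position:] = 1.0
    elif axis == "y":
        values[edge_position:, :] = 1.0
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return MapImage(values, pixel_size=pixel_size)


def raster_shift_grid(n_side: int, step_um: float) -> np.ndarray:
    """(n_side^2, 2) stage shifts (dx, dy) covering a square sub-pixel grid
    in raster order (x fastest), starting at the (0, 0) reference."""
    g = np.arange(n_side) * step_um
    dx, dy = np.meshgrid(g, g)
    return np.column_stack([dx.ravel(), dy.ravel()])


def simulate_map_series(hr: MapImage, shifts, psf: PSFModel, k: int,
                        noise_sigma: float = 0.0, seed: int = 0,
                        strict: bool = True) -> ShiftedMapSeries:
    """Acquire N low-resolution maps of one HR scene (forward model + noise)."""
    shifts = np.asarray(shifts, dtype=float)
    rng = np.random.default_rng(seed)
    H = _blur_matrix(hr.values.shape, psf.kernel_at(hr.pixel_size))
    maps = []
    for dx, dy in shifts:
        lr = apply_forward(hr, (dx, dy), psf, k, _H=H)
        if noise_sigma > 0:
            lr = MapImage(lr.values + rng.normal(0.0, noise_sigma, lr.values.shape),
                          pixel_size=lr.pixel_size, origin=lr.origin)
        maps.append(lr)
    return ShiftedMapSeries(maps=maps, shifts=shifts,
                            lr_pixel_size=hr.pixel_size * k, strict=strict)


def _gaussian_bands(axis, bands):
    s = np.zeros(axis.size)
    for center, width, height in bands:
        if not axis[0] <= center <= axis[-1]:
            raise ValueError(f"band center {center} outside axis "
                             f"[{axis[0]}, {axis[-1]}] cm^-1")
        s += height * np.exp(-0.5 * ((axis - center) / width) ** 2)
    return s


def make_mixture_scene(n_components: int = 5, band_table=None,
                       particle_spec=None, axis=None,
                       hr_shape=(60, 30), hr_pixel_size: float = 0.2,
                       include_background: bool = False,
                       noise_sigma: float = 0.0, seed: int = 0) -> SyntheticScene:
    """Random multi-component particle field with pure Gaussian-band spectra.

    Concentration truth per component is a union of random disks
    ("particles", overlaps allowed) kept clear of a margin so the blurred,
    shifted acquisitions stay on-canvas.  ``include_background`` adds one
    extra smooth component whose spectrum rises at the domain boundary,
    emulating residual uncorrected fluorescence.
    """
    rng = np.random.default_rng(seed)
    if axis is None:
        axis = np.arange(900.0, 1190.0 + 1e-9, 2.0)
    axis = np.asarray(axis, dtype=float)
    if band_table is None:
        band_table = DEFAULT_BAND_TABLE[:n_components]
    if len(band_table) < n_components:
        raise ValueError("band table shorter than n_components")
    spec = dict(n_particles=(2, 5), radius_um=(0.3, 0.9))
    if particle_spec:
        spec.update(particle_spec)

    ny, nx = hr_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    margin = 4  # HR px kept empty so blur + shifts stay on-canvas
    maps = []
    for _ in range(n_components):
        values = np.zeros((ny, nx))
        n_part = rng.integers(spec["n_particles"][0], spec["n_particles"][1] + 1)
        for _ in range(n_part):
            r_um = rng.uniform(*spec["radius_um"])
            r_px = max(r_um / hr_pixel_size, 1.0)
            cy = rng.uniform(margin + r_px, ny - margin - r_px)
            cx = rng.uniform(margin + r_px, nx - margin - r_px)
            disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r_px**2
            values[disk] = np.maximum(values[disk], rng.uniform(0.5, 1.0))
        maps.append(MapImage(values, pixel_size=hr_pixel_size))

    spectra = np.vstack([_gaussian_bands(axis, bands)
                         for bands in band_table[:n_components]])
    if include_background:
        bg_map = MapImage(0.3 + 0.2 * np.cos(np.pi * xx / nx) * np.cos(np.pi * yy / ny),
                          pixel_size=hr_pixel_size)
        span = axis[-1] - axis[0]
        bg_spec = np.exp(-(axis - axis[0]) / (0.25 * span)) \
            + np.exp((axis - axis[-1]) / (0.25 * span))
        maps.append(bg_map)
        spectra = np.vstack([spectra, bg_spec])

    return SyntheticScene(hr_truth=maps, pure_spectra=spectra,
                          wavenumbers=axis, noise_sigma=noise_sigma, seed=seed,
                          meta={"hr_pixel_size": hr_pixel_size})


def simulate_cube_series(scene: SyntheticScene, shifts, psf: PSFModel, k: int,
                         baseline_scale: float = 0.0, noise_sigma=None,
                         seed: int | None = None, poisson: bool = False):
    """Acquire shifted hyperspectral cubes of a mixture scene.

    Per shift, every component's HR truth is forward-imaged to LR and the
    cube is assembled as sum_c (LR map)_c (x) (pure spectrum)_c, plus a
    smooth per-pixel fluorescence-like baseline (amplitude log-normal,
    scaled by ``baseline_scale``) and additive Gaussian noise.
    """
    shifts = np.asarray(shifts, dtype=float)
    if noise_sigma is None:
        noise_sigma = scene.noise_sigma
    if seed is None:
        seed = scene.seed
    rng = np.random.default_rng(seed)
    axis = scene.wavenumbers
    hr0 = scene.hr_truth[0]
    H = _blur_matrix(hr0.values.shape, psf.kernel_at(hr0.pixel_size))
    span = axis[-1] - axis[0]
    baseline_shape = np.exp(-(axis - axis[0]) / scene.baseline_tau) \
        + 0.3 * (1.0 - (axis - axis[0]) / span)

    cubes = []
    for dx, dy in shifts:
        lr_maps = [apply_forward(m, (dx, dy), psf, k, _H=H) for m in scene.hr_truth]
        ny, nx = lr_maps[0].values.shape
        cube = np.zeros((ny, nx, axis.size))
        for m, s in zip(lr_maps, scene.pure_spectra):
            cube += m.values[:, :, None] * s[None, None, :]
        if baseline_scale > 0:
            amp = baseline_scale * rng.lognormal(0.0, scene.baseline_amp_sigma,
                                                 (ny, nx))
            cube += amp[:, :, None] * baseline_shape[None, None, :]
        if poisson:
            cube = rng.poisson(np.maximum(cube, 0.0)).astype(float)
        if noise_sigma > 0:
            cube += rng.normal(0.0, noise_sigma, cube.shape)
        cubes.append(HyperCube(
            cube, axis.copy(), pixel_size=lr_maps[0].pixel_size,
            origin=(float(dx), float(dy)),
            meta={"shift_dx_um": float(dx), "shift_dy_um": float(dy),
                  "seed": int(seed)},
        ))
    return cubes
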