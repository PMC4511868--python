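"""Data model and I/O for hyperspectral map cubes and scalar chemical maps.

A confocal Raman map is a data cube: at every (x, y) stage position a full
spectrum is recorded, so the cube has axes (y, x, wavenumber).  Chemometric
methods operate on the *unfolded* cube — a matrix ``D`` whose rows are pixel
spectra — and several cubes acquired over the same spectral axis can be
stacked row-wise into a column-wise augmented *multiset* matrix that is
factored jointly.  This module owns those containers, the unfold/refold and
augmentation plumbing, band integration, and plain-text / HDF5 / TIFF I/O.

Raster convention: row-major with y as the outer loop (y increases downward,
origin at the top-left pixel centre); indices are 0-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "HyperCube",
    "MapImage",
    "MultisetMatrix",
    "read_long_table",
    "write_long_table",
    "integrate_band",
    "unfold_cube",
    "augment_multiset",
    "refold_maps",
    "save_cube",
    "load_cube",
    "save_map",
    "load_map",
    "export_map_image",
]


class RaggedGridError(ValueError):
    """The long-table export does not form a complete (x, y, wavenumber) grid."""


@dataclass
class HyperCube:
    """A spatially registered spectral image.

    Parameters
    ----------
    intensities : ndarray, shape (ny, nx, n_wavenumbers)
        Counts at every pixel and spectral channel.
    wavenumbers : ndarray, shape (n_wavenumbers,)
        Strictly increasing Raman-shift axis in cm^-1.
    pixel_size : float
        Square pixel pitch in micrometres.
    origin : tuple of float
        (x0, y0) stage offset of the first pixel centre, in micrometres.
    meta : dict
        Free-form provenance (processing parameters, seeds, ...).
    """

    intensities: np.ndarray
    wavenumbers: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size < 2:
            raise ValueError("wavenumber axis must be 1-D with length >= 2")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.intensities.ndim != 3:
            raise ValueError("intensities must have axes (y, x, wavenumber)")
        if self.intensities.shape[2] != self.wavenumbers.size:
            raise ValueError(
                f"intensity grid has {self.intensities.shape[2]} spectral "
                f"channels but the axis has {self.wavenumbers.size}"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def ny(self) -> int:
        return self.intensities.shape[0]

    @property
    def nx(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    def spectrum(self, y: int, x: int) -> np.ndarray:
        return self.intensities[y, x, :]


@dataclass
class MapImage:
    """A scalar chemical map: one value per pixel, physical pitch in μm."""

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("map values must be 2-D (ny, nx)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]


@dataclass
class MultisetMatrix:
    """Column-wise augmented data matrix D for (multi-)cube factorization.

    ``data`` stacks the unfolded pixel spectra of one or more cubes; every
    row is traceable back to its source pixel through ``row_index`` (columns:
    cube id, y, x) so concentration columns can be refolded into maps.
    """

    data: np.ndarray
    wavenumbers: np.ndarray
    row_index: np.ndarray  # (n_rows, 3) int: cube id, y, x
    block_shapes: list[tuple[int, int]]  # (ny, nx) per cube
    pixel_size: float | None = None
    origins: list[tuple[float, float]] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.row_index = np.asarray(self.row_index, dtype=int)
        expected = sum(ny * nx for ny, nx in self.block_shapes)
        if self.data.shape[0] != expected:
            raise ValueError(
                f"row count {self.data.shape[0]} does not match "
                f"sum of block sizes {expected}"
            )
        if self.row_index.shape != (self.data.shape[0], 3):
            raise ValueError("row_index must be (n_rows, 3)")
        # the (cube, y, x) -> row mapping must be invertible
        if len(np.unique(self.row_index, axis=0)) != self.data.shape[0]:
            raise ValueError("row_index contains duplicate (cube, y, x) entries")

    @property
    def n_blocks(self) -> int:
        return len(self.block_shapes)

    def block_rows(self, which_block: int) -> np.ndarray:
        """Boolean mask of the rows belonging to one cube."""
        if not 0 <= which_block < self.n_blocks:
            raise IndexError(f"block {which_block} of {self.n_blocks} does not exist")
        return self.row_index[:, 0] == which_block


# ---------------------------------------------------------------------------
# long-format text I/O

def read_long_table(path, columns=("x", "y", "wavenumber", "intensity"),
                    pixel_size=None, sep=None) -> HyperCube:
    """Read a long-format map export (one row per x, y, wavenumber, intensity).

    The reader is order-invariant: rows may come in any order as long as the
    (x, y) positions form a complete rectangular grid and every position
    carries the same wavenumber set.  ``pixel_size`` defaults to the spacing
    of the x positions (assumed square pixels); pass it explicitly for
    single-column maps.
    """
    try:
        df = pd.read_csv(path, sep=sep, engine="python", comment="#",
                         names=list(columns), header=None,
                         skip_blank_lines=True, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if len(df) == 0:
        raise ValueError(f"{path}: empty long-table file")

    def _is_number(v):
        try:
            float(v)
            return True
        except (TypeError, ValueError):
            return False

    # tolerate a header line: drop it if the first row is non-numeric
    if not all(_is_number(v) for v in df.iloc[0]):
        df = df.iloc[1:]
        if len(df) == 0:
            raise ValueError(f"{path}: no data rows after header")
    # Python's float() is correctly rounded, so text written with 17
    # significant digits round-trips bit-exactly
    converted = {}
    for col in columns:
        out = np.empty(len(df))
        for i, v in enumerate(df[col].to_numpy()):
            if not _is_number(v):
                raise ValueError(
                    f"{path}: non-numeric value {v!r} in column {col!r} "
                    f"near line {df.index[i] + 1}"
                )
            out[i] = float(v)
        converted[col] = out
    df = pd.DataFrame(converted)

    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    ws = np.sort(df["wavenumber"].unique())
    nx, ny, nw = len(xs), len(ys), len(ws)
    if len(df) != nx * ny * nw:
        # locate the first missing triple for the error message
        have = set(zip(df["x"], df["y"], df["wavenumber"]))
        for y in ys:
            for x in xs:
                for w in ws:
                    if (x, y, w) not in have:
                        raise RaggedGridError(
                            f"incomplete grid: missing (x={x}, y={y}, "
                            f"wavenumber={w}); expected {nx * ny * nw} rows, "
                            f"got {len(df)}"
                        )
        raise RaggedGridError("duplicate rows in long table")

    ix = np.searchsorted(xs, df["x"].to_numpy())
    iy = np.searchsorted(ys, df["y"].to_numpy())
    iw = np.searchsorted(ws, df["wavenumber"].to_numpy())
    cube = np.empty((ny, nx, nw), dtype=float)
    cube[iy, ix, iw] = df["intensity"].to_numpy()

    if pixel_size is None:
        if nx >= 2:
            pixel_size = float(xs[1] - xs[0])
        elif ny >= 2:
            pixel_size = float(ys[1] - ys[0])
        else:
            pixel_size = 1.0
    return HyperCube(cube, ws, pixel_size=pixel_size,
                     origin=(float(xs[0]), float(ys[0])))


def write_long_table(cube: HyperCube, path, sep="\t") -> None:
    """Write a cube as long-format text (x, y, wavenumber, intensity)."""
    x0, y0 = cube.origin
    xs = x0 + np.arange(cube.nx) * cube.pixel_size
    ys = y0 + np.arange(cube.ny) * cube.pixel_size
    Y, X, W = np.meshgrid(ys, xs, cube.wavenumbers, indexing="ij")
    df = pd.DataFrame({
        "x": X.ravel(),
        "y": Y.ravel(),
        "wavenumber": W.ravel(),
        "intensity": cube.intensities.ravel(),
    })
    df.to_csv(path, sep=sep, header=False, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# band integration and unfolding

def integrate_band(cube: HyperCube, center: float, half_width: float = 10.0) -> MapImage:
    """Trapezoidal per-pixel integral of intensity over a spectral window.

    Emulates generating a chemical map by integrating a marker band (e.g.
    the 520.7 cm^-1 silicon line).  The window ``[center - half_width,
    center + half_width]`` is clipped to the axis; an empty overlap is an
    error.
    """
    lo, hi = center - half_width, center + half_width
    w = cube.wavenumbers
    mask = (w >= lo) & (w <= hi)
    if not mask.any():
        raise ValueError(
            f"integration window [{lo}, {hi}] cm^-1 does not overlap the "
            f"axis [{w[0]}, {w[-1]}] cm^-1"
        )
    sel = np.flatnonzero(mask)
    vals = np.trapezoid(cube.intensities[:, :, sel], x=w[sel], axis=2)
    return MapImage(vals, pixel_size=cube.pixel_size, origin=cube.origin)


def unfold_cube(cube: HyperCube, cube_id: int = 0) -> MultisetMatrix:
    """Unfold a cube into matrix D (rows = pixels in raster order, y outer)."""
    ny, nx, nw = cube.intensities.shape
    data = cube.intensities.reshape(ny * nx, nw)
    yy, xx = np.divmod(np.arange(ny * nx), nx)
    row_index = np.column_stack([np.full(ny * nx, cube_id), yy, xx])
    return MultisetMatrix(
        data=data.copy(), wavenumbers=cube.wavenumbers.copy(),
        row_index=row_index, block_shapes=[(ny, nx)],
        pixel_size=cube.pixel_size, origins=[cube.origin],
    )


def augment_multiset(cubes) -> MultisetMatrix:
    """Stack the unfolded rows of several cubes into one augmented matrix.

    All cubes must share an identical wavenumber axis (the multiset is
    column-wise augmented: common spectral direction, stacked pixels).
    """
    cubes = list(cubes)
    if not cubes:
        raise ValueError("no cubes to augment")
    ref = cubes[0].wavenumbers
    for i, c in enumerate(cubes[1:], start=1):
        if c.wavenumbers.shape != ref.shape or not np.array_equal(c.wavenumbers, ref):
            diff = (np.flatnonzero(c.wavenumbers != ref)[0]
                    if c.wavenumbers.shape == ref.shape else 0)
            raise ValueError(
                f"cube {i} wavenumber axis differs from cube 0 starting at "
                f"channel {diff}"
            )
    blocks = [unfold_cube(c, cube_id=i) for i, c in enumerate(cubes)]
    return MultisetMatrix(
        data=np.vstack([b.data for b in blocks]),
        wavenumbers=ref.copy(),
        row_index=np.vstack([b.row_index for b in blocks]),
        block_shapes=[(c.ny, c.nx) for c in cubes],
        pixel_size=cubes[0].pixel_size,
        origins=[c.origin for c in cubes],
    )


def refold_maps(multiset: MultisetMatrix, columns: np.ndarray,
                which_block: int = 0) -> list[MapImage]:
    """Fold concentration columns back into 2-D maps for one cube block.

    ``columns`` is (n_rows, n_components) — e.g. the C matrix of an MCR
    model over the full multiset; one MapImage per component is returned
    with the block's shape, pitch and origin.
    """
    columns = np.atleast_2d(np.asarray(columns, dtype=float))
    if columns.shape[0] == 1 and columns.shape[1] == multiset.data.shape[0]:
        columns = columns.T
    if columns.shape[0] != multiset.data.shape[0]:
        raise ValueError(
            f"column length {columns.shape[0]} != row count "
            f"{multiset.data.shape[0]}"
        )
    mask = multiset.block_rows(which_block)
    ny, nx = multiset.block_shapes[which_block]
    sub = columns[mask]
    idx = multiset.row_index[mask]
    order = np.lexsort((idx[:, 2], idx[:, 1]))
    sub = sub[order]
    pitch = multiset.pixel_size if multiset.pixel_size else 1.0
    origin = (multiset.origins[which_block]
              if multiset.origins else (0.0, 0.0))
    return [MapImage(sub[:, c].reshape(ny, nx), pixel_size=pitch, origin=origin)
            for c in range(columns.shape[1])]


def refold_cube(multiset: MultisetMatrix, which_block: int = 0) -> HyperCube:
    """Inverse of unfold: rebuild the block's full cube from its rows."""
    mask = multiset.block_rows(which_block)
    ny, nx = multiset.block_shapes[which_block]
    sub = multiset.data[mask]
    idx = multiset.row_index[mask]
    order = np.lexsort((idx[:, 2], idx[:, 1]))
    pitch = multiset.pixel_size if multiset.pixel_size else 1.0
    origin = (multiset.origins[which_block]
              if multiset.origins else (0.0, 0.0))
    return HyperCube(sub[order].reshape(ny, nx, -1), multiset.wavenumbers.copy(),
                     pixel_size=pitch, origin=origin)


# ---------------------------------------------------------------------------
# hierarchical containers (HDF5)

def save_cube(cube: HyperCube, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("wavenumbers", data=cube.wavenumbers)
        f.create_dataset("intensities", data=cube.intensities)
        f.attrs["pixel_size"] = cube.pixel_size
        f.attrs["origin"] = cube.origin
        for k, v in cube.meta.items():
            f.attrs[f"meta/{k}"] = v


def load_cube(path) -> HyperCube:
    with h5py.File(path, "r") as f:
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta/")}
        return HyperCube(
            f["intensities"][...], f["wavenumbers"][...],
            pixel_size=float(f.attrs["pixel_size"]),
            origin=tuple(f.attrs["origin"]), meta=meta,
        )


def save_map(m: MapImage, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=m.values)
        f.attrs["pixel_size"] = m.pixel_size
        f.attrs["origin"] = m.origin


def load_map(path) -> MapImage:
    with h5py.File(path, "r") as f:
        return MapImage(f["values"][...], pixel_size=float(f.attrs["pixel_size"]),
                        origin=tuple(f.attrs["origin"]))


def export_map_image(m: MapImage, path) -> None:
    """Export a map as a scaled 16-bit TIFF/PNG plus a sidecar scale record.

    The linear scale (min/max mapped to 0..65535) is written next to the
    image as ``<path>.scale.txt`` so quantitative values remain recoverable.
    """
    import pathlib

    lo, hi = float(m.values.min()), float(m.values.max())
    span = hi - lo if hi > lo else 1.0
    scaled = np.round((m.values - lo) / span * 65535.0).astype(np.uint16)
    path = pathlib.Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, scaled)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, scaled)
    path.with_suffix(path.suffix + ".scale.txt").write_text(
        f"min {lo!r}\nmax {hi!r}\npixel_size_um {m.pixel_size!r}\n"
        f"origin_um {m.origin[0]!r} {m.origin[1]!r}\n"
    )
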