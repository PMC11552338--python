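"""Containers and file I/O for masks, tracks, gridded fields and run configs.

Conventions fixed here and used everywhere else in the package:

* the flow axis is +x; x increases with column index, y with row index;
* pixel (row r, col c) has its physical centre at
  ``(x0 + c * dx, y0 + r * dx)`` with isotropic spacing ``dx`` in um;
* units are um, seconds and nM.

Track tables are delimited text in either the canonical dialect
(``cell_id,t_s,x_um,y_um``) or the particle-tracking dialect
(``particle,frame,x,y``), for which an explicit frame interval (and, if the
coordinates are in pixels, a pixel size) must be supplied.  Gridded fields
round-trip through a platform-neutral binary array (``.npy``) plus a JSON
sidecar carrying the grid metadata.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DataError, DomainError, FormatError, ParameterError
from .params import ChemokineParams, WalkerParams

__all__ = [
    "FieldGrid", "ThrombusMask", "Trajectory", "RunConfig",
    "read_tracks", "write_tracks", "read_mask",
    "read_field", "write_field",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class FieldGrid:
    """A regular 2D grid with isotropic spacing.

    ``values`` has shape ``(ny, nx)``; the payload meaning (mask, velocity
    component, concentration) is given by the carrier type.
    """

    values: np.ndarray
    dx: float
    origin: tuple[float, float] = (0.0, 0.0)
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError(f"grid values must be 2D, got ndim={self.values.ndim}")
        ny, nx = self.values.shape
        if nx < 8 or ny < 8:
            raise DataError(f"grid must be at least 8x8 pixels, got {nx}x{ny}")
        if not self.dx > 0:
            raise ParameterError(f"pixel size dx={self.dx} must be > 0")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def x(self) -> np.ndarray:
        """Physical x coordinates of pixel centres, um."""
        return self.origin[0] + np.arange(self.nx) * self.dx

    @property
    def y(self) -> np.ndarray:
        """Physical y coordinates of pixel centres, um."""
        return self.origin[1] + np.arange(self.ny) * self.dx

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the pixel-centre hull, um."""
        return (self.origin[0], self.origin[0] + (self.nx - 1) * self.dx,
                self.origin[1], self.origin[1] + (self.ny - 1) * self.dx)

    def contains(self, x, y) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.bounds
        return ((np.asarray(x) >= xmin) & (np.asarray(x) <= xmax)
                & (np.asarray(y) >= ymin) & (np.asarray(y) <= ymax))

    def interp(self, x, y):
        """Bilinear interpolation of the payload at physical points (um).

        Raises
        ------
        DomainError
            If any query point lies outside the pixel-centre hull.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.contains(x, y)):
            raise DomainError("interpolation point outside field bounds")
        fx = (x - self.origin[0]) / self.dx
        fy = (y - self.origin[1]) / self.dx
        i0 = np.clip(np.floor(fy).astype(int), 0, self.ny - 2)
        j0 = np.clip(np.floor(fx).astype(int), 0, self.nx - 2)
        ty = fy - i0
        tx = fx - j0
        v = self.values
        return ((1 - ty) * (1 - tx) * v[i0, j0]
                + (1 - ty) * tx * v[i0, j0 + 1]
                + ty * (1 - tx) * v[i0 + 1, j0]
                + ty * tx * v[i0 + 1, j0 + 1])

    def pixel_at(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the nearest pixel for physical points (um)."""
        c = np.rint((np.asarray(x) - self.origin[0]) / self.dx).astype(int)
        r = np.rint((np.asarray(y) - self.origin[1]) / self.dx).astype(int)
        return r, c


@dataclass
class ThrombusMask:
    """Binary thrombus mask on a :class:`FieldGrid` (1 = thrombus)."""

    grid: FieldGrid
    provenance: str = ""

    def __post_init__(self) -> None:
        v = self.grid.values
        if not np.isin(v, (0.0, 1.0)).all():
            raise DataError("thrombus mask values must be 0 or 1")
        if v.min() != 0.0:
            raise DataError("mask has no free pixels (all thrombus)")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def n_components(self) -> int:
        from scipy import ndimage
        _, n = ndimage.label(self.grid.values > 0)
        return int(n)

    def area_fraction(self) -> float:
        """Fraction of the field covered by thrombus, in [0, 1]."""
        return float(self.grid.values.mean())


@dataclass
class Trajectory:
    """Time-ordered (t, x, y) polyline for one cell, um and seconds."""

    cell_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise DataError(f"trajectory '{self.cell_id}': t, x, y must be 1D and equal length")
        if self.t.size < 1:
            raise DataError(f"trajectory '{self.cell_id}' is empty")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.x)) \
                or not np.all(np.isfinite(self.y)):
            raise DataError(f"trajectory '{self.cell_id}' contains non-finite values")
        if np.any(np.diff(self.t) <= 0):
            raise DataError(
                f"trajectory '{self.cell_id}': timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def step_lengths(self) -> np.ndarray:
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def path_length(self) -> float:
        return float(self.step_lengths().sum())


@dataclass
class RunConfig:
    """Top-level run configuration for a field + walker computation."""

    shear_rate: float = 100.0           # 1/s, wall shear rate
    chamber_height: float = 100.0       # um (0.1 mm channel)
    h_ref: float = 5.0                  # um, crawling-plane reference height
    chemokine: ChemokineParams = field(default_factory=ChemokineParams)
    walker: WalkerParams = field(default_factory=WalkerParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shear_rate <= 500.0):
            raise ParameterError(
                f"shear rate {self.shear_rate} 1/s outside the chamber range [0, 500]")
        if not self.chamber_height > 0 or not self.h_ref > 0:
            raise ParameterError("chamber_height and h_ref must be > 0")
        if isinstance(self.chemokine, dict):
            self.chemokine = ChemokineParams.from_dict(self.chemokine)
        if isinstance(self.walker, dict):
            self.walker = WalkerParams.from_dict(self.walker)

    def to_dict(self) -> dict:
        return {
            "shear_rate": self.shear_rate,
            "chamber_height": self.chamber_height,
            "h_ref": self.h_ref,
            "chemokine": self.chemokine.to_dict(),
            "walker": self.walker.to_dict(),
            "rng_seed": self.rng_seed,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"config {path} is not valid JSON: {exc}") from exc
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# track tables

_CANONICAL_COLS = ("cell_id", "t_s", "x_um", "y_um")
_TRACKING_COLS = ("particle", "frame", "x", "y")


def read_tracks(path, dialect: str = "seconds", frame_interval: float | None = None,
                px_size: float = 1.0) -> list[Trajectory]:
    """Read a delimited track table into one :class:`Trajectory` per cell.

    Parameters
    ----------
    path : path-like
        CSV file with header ``cell_id,t_s,x_um,y_um`` (``dialect="seconds"``)
        or ``particle,frame,x,y`` (``dialect="frame-index"``).
    dialect : {"seconds", "frame-index"}
        Time column interpretation.
    frame_interval : float, optional
        Seconds per frame; required for the ``frame-index`` dialect.  The
        acquisition interval is instrument-specific and is never defaulted.
    px_size : float
        um per coordinate unit of the file (1.0 if already in um).

    Returns
    -------
    list of Trajectory, sorted by cell id, each sorted by time.
    """
    if dialect not in ("seconds", "frame-index"):
        raise ParameterError(f"unknown track dialect '{dialect}'")
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect == "seconds":
        cols = _CANONICAL_COLS
    else:
        cols = _TRACKING_COLS
        if frame_interval is None:
            raise ParameterError(
                "frame-index dialect requires an explicit frame_interval (s/frame)")
        if not frame_interval > 0:
            raise ParameterError("frame_interval must be > 0")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"track table {path} is missing columns {missing}")
    idc, tc, xc, yc = cols
    out: list[Trajectory] = []
    for cid, g in df.groupby(idc, sort=True):
        t = g[tc].to_numpy(dtype=float)
        if dialect == "frame-index":
            t = t * frame_interval
        order = np.argsort(t, kind="stable")
        t = t[order]
        if np.any(np.diff(t) <= 0):
            raise DataError(f"track '{cid}': non-monotone or duplicate timestamps")
        if t.size < 2:
            raise DataError(f"track '{cid}' has fewer than 2 points")
        x = g[xc].to_numpy(dtype=float)[order] * px_size
        y = g[yc].to_numpy(dtype=float)[order] * px_size
        out.append(Trajectory(str(cid), t, x, y))
    return out


def write_tracks(trajs: Iterable[Trajectory], path) -> None:
    """Write trajectories as canonical CSV (``cell_id,t_s,x_um,y_um``)."""
    frames = [pd.DataFrame({"cell_id": tr.cell_id, "t_s": tr.t,
                            "x_um": tr.x, "y_um": tr.y}) for tr in trajs]
    df = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=list(_CANONICAL_COLS))
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# masks


def read_mask(path, dx: float, origin: tuple[float, float] = (0.0, 0.0),
              provenance: str | None = None) -> ThrombusMask:
    """Read a single-channel image as a binary thrombus mask.

    Any strictly positive pixel is thrombus.  Multi-channel images are
    rejected: segmentation happens upstream (pixel classification), this
    reader only ingests its binary output.
    """
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(
            f"mask {path} must be single-channel, got shape {arr.shape}")
    binary = (arr > 0).astype(float)
    grid = FieldGrid(binary, dx=dx, origin=origin, units="mask")
    return ThrombusMask(grid, provenance=provenance or str(path))


# ---------------------------------------------------------------------------
# gridded fields (binary payload + JSON sidecar)


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_field(grid: FieldGrid, path) -> None:
    """Write a grid as a ``.npy`` payload plus JSON metadata sidecar."""
    path = Path(path)
    with open(path, "wb") as fh:
        np.save(fh, grid.values)
    meta = {"dx_um": grid.dx, "origin_um": list(grid.origin),
            "units": grid.units, "shape": list(grid.values.shape)}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_field(path) -> FieldGrid:
    """Read a grid written by :func:`write_field`; round-trip is bit-faithful."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"field {path} has no metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {sidecar} is not valid JSON: {exc}") from exc
    try:
        with open(path, "rb") as fh:
            values = np.load(fh)
    except (ValueError, OSError, EOFError) as exc:
        raise FormatError(f"field {path} payload is unreadable: {exc}") from exc
    if list(values.shape) != list(meta.get("shape", [])):
        raise FormatError(
            f"field {path}: payload shape {values.shape} does not match "
            f"sidecar shape {meta.get('shape')}")
    return FieldGrid(values, dx=float(meta["dx_um"]),
                     origin=tuple(meta["origin_um"]), units=meta.get("units", ""))
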