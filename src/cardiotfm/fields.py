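"""Regular-grid vector fields and imaging geometry shared across the pipeline.

Coordinate convention: origin at the image top-left, x rightward (columns),
y downward (rows), all positions in µm.  Grids are node-centered and regular;
arrays are indexed ``[row, col] == [y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from cardiotfm.substrate import ElasticSubstrate


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry of the TFM video.

    Defaults reproduce a typical 40x single-cell cardiomyocyte recording:
    0.275 µm/px (after 2x2 camera binning), 30 frames/s, and an
    85 x 200 µm (height x width) analysis crop that leaves room around the
    cell to capture far-field substrate deformation.
    """

    px_size: float = 0.275            # µm per pixel
    fps: float = 30.0                 # frames per second
    frame_shape: tuple[int, int] = (310, 728)   # (rows, cols) px
    crop_window_um: tuple[float, float] = (85.0, 200.0)  # (height, width) µm
    binning: int = 2

    def __post_init__(self) -> None:
        if self.px_size <= 0:
            raise ValueError("px_size must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        h_px = self.crop_window_um[0] / self.px_size
        w_px = self.crop_window_um[1] / self.px_size
        if h_px > self.frame_shape[0] + 1e-9 or w_px > self.frame_shape[1] + 1e-9:
            raise ValueError(
                f"crop window {self.crop_window_um} µm does not fit inside "
                f"frame {self.frame_shape} px at {self.px_size} µm/px"
            )

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height, width) of the full frame in µm."""
        return (self.frame_shape[0] * self.px_size, self.frame_shape[1] * self.px_size)


def _check_regular(coords: np.ndarray, name: str) -> float:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 1 or coords.size < 2:
        raise ValueError(f"{name} must be a 1-D array with >= 2 nodes")
    d = np.diff(coords)
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{name} is not a regular grid")
    return float(d[0])


@dataclass
class DisplacementField:
    """Substrate displacement on a regular grid.

    ``u_x``/``u_y`` are in µm, shaped ``(len(grid_y), len(grid_x))``.
    ``valid`` marks nodes that passed tracking quality checks and
    ``correlation`` holds the final zero-normalized cross-correlation value
    per node (1.0 where the match is perfect or the field is synthetic).
    """

    grid_x: np.ndarray          # node x coordinates, µm
    grid_y: np.ndarray          # node y coordinates, µm
    u_x: np.ndarray             # µm
    u_y: np.ndarray             # µm
    valid: Optional[np.ndarray] = None
    correlation: Optional[np.ndarray] = None
    reference_frame_index: int = 0

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        shape = (self.grid_y.size, self.grid_x.size)
        if self.u_x.shape != shape or self.u_y.shape != shape:
            raise ValueError(f"u arrays must have shape {shape}")
        if self.valid is None:
            self.valid = np.ones(shape, dtype=bool)
        if self.correlation is None:
            self.correlation = np.ones(shape, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.correlation = np.asarray(self.correlation, dtype=float)

    @property
    def spacing(self) -> float:
        """Grid spacing in µm (identical along x and y)."""
        dx = _check_regular(self.grid_x, "grid_x")
        dy = _check_regular(self.grid_y, "grid_y")
        if not np.isclose(dx, dy, rtol=1e-6):
            raise ValueError("grid spacing differs along x and y")
        return dx

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u_x, self.u_y)

    def copy(self) -> "DisplacementField":
        return DisplacementField(
            self.grid_x.copy(), self.grid_y.copy(),
            self.u_x.copy(), self.u_y.copy(),
            self.valid.copy(), self.correlation.copy(),
            self.reference_frame_index,
        )

    def scaled(self, factor: float) -> "DisplacementField":
        out = self.copy()
        out.u_x *= factor
        out.u_y *= factor
        return out

    def to_frame(self, frame: int = 0) -> pd.DataFrame:
        """Tabular per-node representation (one row per grid node)."""
        yy, xx = np.meshgrid(self.grid_y, self.grid_x, indexing="ij")
        return pd.DataFrame({
            "frame": frame,
            "node_x_um": xx.ravel(),
            "node_y_um": yy.ravel(),
            "ux_um": self.u_x.ravel(),
            "uy_um": self.u_y.ravel(),
            "valid": self.valid.ravel(),
            "correlation": self.correlation.ravel(),
        })


@dataclass
class TractionField:
    """Traction stress on a regular grid, in Pa.

    By the Fourier-transform traction cytometry convention the k = 0 mode is
    nulled, so each component has zero mean over the grid: tractions of an
    isolated cell are defined up to a uniform offset and must integrate to
    zero net force.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    t_x: np.ndarray             # Pa
    t_y: np.ndarray             # Pa
    lambda_used: float = 0.0
    substrate: Optional[ElasticSubstrate] = None

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        self.t_x = np.asarray(self.t_x, dtype=float)
        self.t_y = np.asarray(self.t_y, dtype=float)
        shape = (self.grid_y.size, self.grid_x.size)
        if self.t_x.shape != shape or self.t_y.shape != shape:
            raise ValueError(f"traction arrays must have shape {shape}")

    @property
    def spacing(self) -> float:
        dx = _check_regular(self.grid_x, "grid_x")
        dy = _check_regular(self.grid_y, "grid_y")
        if not np.isclose(dx, dy, rtol=1e-6):
            raise ValueError("grid spacing differs along x and y")
        return dx

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.t_x, self.t_y)

    @property
    def node_area_um2(self) -> float:
        return self.spacing ** 2

    def total_scalar_force_nN(self, mask: Optional[np.ndarray] = None) -> float:
        """Integral of |T| over the grid (optionally within ``mask``), in nN.

        Pa·µm² = pN, hence the 1e-3 factor to nN.
        """
        mag = self.magnitude
        if mask is not None:
            mag = mag[mask]
        return float(np.sum(mag) * self.node_area_um2 * 1e-3)

    def net_force_nN(self) -> tuple[float, float]:
        """Vector sum of traction over the grid in nN (should be ~0)."""
        a = self.node_area_um2 * 1e-3
        return (float(self.t_x.sum() * a), float(self.t_y.sum() * a))

    def copy(self) -> "TractionField":
        return TractionField(
            self.grid_x.copy(), self.grid_y.copy(),
            self.t_x.copy(), self.t_y.copy(),
            self.lambda_used, self.substrate,
        )

    def to_frame(self, frame: int = 0) -> pd.DataFrame:
        yy, xx = np.meshgrid(self.grid_y, self.grid_x, indexing="ij")
        return pd.DataFrame({
            "frame": frame,
            "x_um": xx.ravel(),
            "y_um": yy.ravel(),
            "tx_Pa": self.t_x.ravel(),
            "ty_Pa": self.t_y.ravel(),
        })


def make_grid(extent_um: tuple[float, float], spacing_um: float,
              offset_um: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Node-centered regular grid covering ``(height, width)`` µm.

    Returns ``(grid_x, grid_y)`` 1-D coordinate arrays starting at
    ``offset_um`` with step ``spacing_um``.
    """
    h, w = extent_um
    nx = int(np.floor((w - 2 * offset_um) / spacing_um)) + 1
    ny = int(np.floor((h - 2 * offset_um) / spacing_um)) + 1
    gx = offset_um + spacing_um * np.arange(nx)
    gy = offset_um + spacing_um * np.arange(ny)
    return gx, gy
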