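"""Synthetic TFM inputs with known ground truth.

A contracting cardiomyocyte on a micropatterned hydrogel is emulated as a
force dipole: two inward-pointing Gaussian traction patches at the ends of
the pattern's long axis, time-modulated by a raised-cosine pulse train at
the pacing frequency.  The substrate response is the forward Boussinesq
half-space solution evaluated in Fourier space; fluorescent fiducial beads
at the gel surface are advected by the displacement field and rendered as
Gaussian spots with optional shot and read noise.

Everything downstream of this module (displacement tracking, traction
reconstruction, contractile metrics, cell location) can therefore be
benchmarked against exact ground truth without any experimental data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from cardiotfm.fields import DisplacementField, ImagingConfig, TractionField, make_grid
from cardiotfm.fttc import _greens_grid, _kgrid_r
from cardiotfm.substrate import ElasticSubstrate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# micropattern geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicropatternSpec:
    """Rectangular micropattern geometry: A = L*W = r*W^2.

    ``aspect_ratio_r`` is the length:width ratio (>= 1).  ``pitch_um`` is the
    center-to-center spacing between neighboring patterns on the array
    (200 µm by default, enough to mechanically decouple neighboring cells).
    """

    area_A_um2: float
    length_L_um: float
    width_W_um: float
    aspect_ratio_r: float
    pitch_um: float = 200.0

    def __post_init__(self) -> None:
        if self.length_L_um < self.width_W_um:
            raise ValueError("pattern length must be >= width")
        if self.pitch_um <= self.length_L_um:
            raise ValueError("pattern pitch must exceed pattern length")
        a1 = self.length_L_um * self.width_W_um
        a2 = self.aspect_ratio_r * self.width_W_um ** 2
        for a in (a1, a2):
            if abs(a - self.area_A_um2) > 1e-3 * self.area_A_um2:
                raise ValueError(
                    f"inconsistent geometry: A={self.area_A_um2}, L*W={a1}, r*W^2={a2}"
                )


@dataclass
class TractionPattern:
    """Parametric dipole traction: Gaussian patches with unit directions.

    The integrated traction over all patches sums to zero (force balance);
    ``modulation`` maps time (s) to a contraction level s(t) in [0, 1],
    periodic with period 1/``pulse_frequency_hz``.
    """

    patch_centers_um: list[tuple[float, float]]
    patch_sigma_um: float
    peak_stress_Pa: float
    directions: list[tuple[float, float]]
    pulse_frequency_hz: float = 1.0
    duty_fraction: float = 0.4
    modulation: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_fraction < 1.0:
            raise ValueError("duty_fraction must lie in (0, 1)")
        if self.modulation is None:
            self.modulation = lambda t: raised_cosine_modulation(
                t, self.pulse_frequency_hz, self.duty_fraction)


def raised_cosine_modulation(t: np.ndarray, frequency_hz: float,
                             duty_fraction: float = 0.4) -> np.ndarray:
    """Raised-cosine pulse train s(t) in [0, 1].

    Each period starts fully relaxed (s = 0), rises smoothly to 1 at the
    middle of the active fraction ``duty_fraction`` of the period, returns
    to 0, and stays relaxed for the rest of the period.  Smooth and
    differentiable, with distinct contraction and relaxation phases, which
    is what the velocity metrics need.
    """
    t = np.asarray(t, dtype=float)
    period = 1.0 / frequency_hz
    phase = np.mod(t, period) / period
    s = np.zeros_like(t)
    active = phase < duty_fraction
    s[active] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[active] / duty_fraction))
    return s


# ---------------------------------------------------------------------------
# forward elasticity
# ---------------------------------------------------------------------------

def boussinesq_displacement(traction: TractionField, substrate: ElasticSubstrate,
                            padding_factor: int = 2) -> DisplacementField:
    """Surface displacement of the half-space under a tangential traction.

    Evaluates u(k) = G(k) T(k) per wavevector with the Boussinesq surface
    Green's tensor (see :mod:`cardiotfm.fttc`), nulling the k = 0 mode.  The
    traction is zero-meaned first and zero-padded by ``padding_factor`` to
    suppress periodic wrap-around.  Output grid and units (µm) match the
    input grid.
    """
    if substrate.youngs_modulus_E <= 0:
        raise ValueError("Young's modulus must be positive")
    spacing = traction.spacing      # raises on non-regular grids
    ny, nx = traction.t_x.shape
    py, px = ny * padding_factor, nx * padding_factor
    tx = np.zeros((py, px))
    ty = np.zeros((py, px))
    tx[:ny, :nx] = traction.t_x - traction.t_x.mean()
    ty[:ny, :nx] = traction.t_y - traction.t_y.mean()
    KX, KY, _ = _kgrid_r(py, px, spacing)
    gxx, gxy, gyy = _greens_grid(KX, KY, substrate)
    Tx = np.fft.rfft2(tx)
    Ty = np.fft.rfft2(ty)
    Ux = gxx * Tx + gxy * Ty
    Uy = gxy * Tx + gyy * Ty
    ux = np.fft.irfft2(Ux, s=(py, px))[:ny, :nx]
    uy = np.fft.irfft2(Uy, s=(py, px))[:ny, :nx]
    return DisplacementField(traction.grid_x.copy(), traction.grid_y.copy(), ux, uy)


def make_dipole_traction(pattern: MicropatternSpec, peak_stress_Pa: float,
                         grid: tuple[np.ndarray, np.ndarray],
                         patch_sigma_um: float = 6.0,
                         center_um: Optional[tuple[float, float]] = None
                         ) -> TractionField:
    """Force-balanced dipole traction for a micropatterned cell.

    Two Gaussian patches of width ``patch_sigma_um`` sit at the ends of the
    pattern's long axis (along x), with peak magnitude ``peak_stress_Pa``
    pointing inward.  The returned field is exactly zero-mean per component,
    so the integrated vector force vanishes.
    """
    grid_x, grid_y = (np.asarray(g, dtype=float) for g in grid)
    if peak_stress_Pa < 0:
        raise ValueError("peak stress must be >= 0")
    if center_um is None:
        center_um = (float(grid_x.mean()), float(grid_y.mean()))
    half = pattern.length_L_um / 2.0 - patch_sigma_um
    centers = [(center_um[0] - half, center_um[1]), (center_um[0] + half, center_um[1])]
    if np.hypot(centers[1][0] - centers[0][0], centers[1][1] - centers[0][1]) \
            < 2.0 * patch_sigma_um:
        raise ValueError("dipole patches overlap (centers closer than 2 sigma)")
    directions = [(1.0, 0.0), (-1.0, 0.0)]       # pointing inward
    XX, YY = np.meshgrid(grid_x, grid_y, indexing="xy")
    tx = np.zeros_like(XX)
    ty = np.zeros_like(XX)
    for (cx, cy), (dx, dy) in zip(centers, directions):
        g = np.exp(-((XX - cx) ** 2 + (YY - cy) ** 2) / (2.0 * patch_sigma_um ** 2))
        tx += peak_stress_Pa * g * dx
        ty += peak_stress_Pa * g * dy
    # numerical force balance: remove the (tiny) discretization residual
    tx -= tx.mean()
    ty -= ty.mean()
    return TractionField(grid_x, grid_y, tx, ty)


# ---------------------------------------------------------------------------
# bead rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadNoiseModel:
    """Camera noise for rendered bead frames.

    ``shot`` applies Poisson noise to the photon signal; ``read_sigma``
    adds Gaussian read noise in camera counts.
    """

    shot: bool = True
    read_sigma: float = 60.0


def sample_bead_positions(imaging: ImagingConfig, density_per_um2: float,
                          seed: int) -> np.ndarray:
    """Uniform random bead positions (µm) over the full frame, seeded.

    The default surface density used by the simulator (0.08 beads/µm²)
    puts >= 5 beads inside every default DIC subset, which keeps subset
    tracking well-posed.
    """
    rng = np.random.default_rng(seed)
    h, w = imaging.extent_um
    n = rng.poisson(density_per_um2 * h * w)
    pos = np.empty((n, 2))
    pos[:, 0] = rng.uniform(0.0, w, n)
    pos[:, 1] = rng.uniform(0.0, h, n)
    return pos


def _sample_displacement_at(displacement: DisplacementField,
                            positions_um: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of (u_x, u_y) at arbitrary positions (µm)."""
    spacing = displacement.spacing
    cx = (positions_um[:, 0] - displacement.grid_x[0]) / spacing
    cy = (positions_um[:, 1] - displacement.grid_y[0]) / spacing
    coords = np.vstack([cy, cx])
    ux = ndimage.map_coordinates(displacement.u_x, coords, order=1, mode="nearest")
    uy = ndimage.map_coordinates(displacement.u_y, coords, order=1, mode="nearest")
    return np.column_stack([ux, uy])


def render_bead_frame(reference_beads_um: np.ndarray,
                      displacement: Optional[DisplacementField],
                      imaging: ImagingConfig,
                      noise_model: Optional[BeadNoiseModel] = None,
                      seed: int = 0,
                      psf_sigma_um: float = 0.3,
                      amplitude: float = 6000.0,
                      background: float = 300.0) -> np.ndarray:
    """Render one 16-bit bead-channel frame.

    Each bead becomes a 2-D Gaussian spot of width ``psf_sigma_um`` at its
    reference position plus the local displacement (bilinear interpolation of
    the displacement field).  Noise is drawn after seeding, so a fixed seed
    gives a bit-identical frame.  Beads that leave the field of view are
    silently dropped (their count is logged).
    """
    rows, cols = imaging.frame_shape
    px = imaging.px_size
    pos = np.array(reference_beads_um, dtype=float, copy=True)
    if displacement is not None:
        pos += _sample_displacement_at(displacement, pos)
    img = np.zeros((rows, cols), dtype=float)
    sig = psf_sigma_um / px
    halfw = max(2, int(np.ceil(4.0 * sig)))
    xs = pos[:, 0] / px
    ys = pos[:, 1] / px
    inside = (xs > -halfw) & (xs < cols + halfw) & (ys > -halfw) & (ys < rows + halfw)
    n_dropped = int(np.count_nonzero(~inside))
    if n_dropped:
        logger.info("render_bead_frame: dropped %d beads outside the field of view",
                    n_dropped)
    for x, y in zip(xs[inside], ys[inside]):
        ix, iy = int(round(x)), int(round(y))
        x0, x1 = max(0, ix - halfw), min(cols, ix + halfw + 1)
        y0, y1 = max(0, iy - halfw), min(rows, iy + halfw + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.arange(x0, x1) - x
        gy = np.arange(y0, y1) - y
        img[y0:y1, x0:x1] += amplitude * np.outer(
            np.exp(-gy ** 2 / (2 * sig ** 2)), np.exp(-gx ** 2 / (2 * sig ** 2)))
    img += background
    if noise_model is not None:
        rng = np.random.default_rng(seed)
        if noise_model.shot:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        if noise_model.read_sigma > 0:
            img += rng.normal(0.0, noise_model.read_sigma, img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# full simulated recordings
# ---------------------------------------------------------------------------

@dataclass
class BeadSequence:
    """Time-ordered bead-channel frames: the raw TFM observable."""

    frames: np.ndarray            # (T, rows, cols) uint16
    px_size: float                # µm/px
    fps: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def save_tiff(self, path: str | Path) -> None:
        import tifffile
        tifffile.imwrite(str(path), self.frames)

    @classmethod
    def from_tiff(cls, path: str | Path, px_size: float, fps: float) -> "BeadSequence":
        import tifffile
        frames = tifffile.imread(str(path))
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames=frames, px_size=px_size, fps=fps)


@dataclass
class PhantomTruth:
    """Ground-truth bundle for a simulated recording.

    Per-frame truth fields are the peak fields scaled by the modulation
    s(t) (the forward model is linear), so only the peak fields and the
    modulation trace are stored.
    """

    traction_peak: TractionField
    displacement_peak: DisplacementField
    modulation: np.ndarray                 # s(t) per frame, in [0, 1]
    bead_positions_reference_um: np.ndarray
    total_force_truth_nN: np.ndarray       # per frame, nN
    seed: int
    substrate: ElasticSubstrate

    def traction_at(self, frame: int) -> TractionField:
        out = self.traction_peak.copy()
        out.t_x *= self.modulation[frame]
        out.t_y *= self.modulation[frame]
        return out

    def displacement_at(self, frame: int) -> DisplacementField:
        return self.displacement_peak.scaled(self.modulation[frame])

    @property
    def peak_total_force_nN(self) -> float:
        return self.traction_peak.total_scalar_force_nN()


@dataclass
class SimulatedTfm:
    """A complete simulated single-cell TFM recording."""

    sequence: BeadSequence
    brightfield: np.ndarray
    truth: PhantomTruth
    imaging: ImagingConfig
    pattern: MicropatternSpec

    def save(self, outdir: str | Path) -> None:
        """Write bead video, brightfield, truth fields and metadata to a directory."""
        import tifffile
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sequence.save_tiff(outdir / "beads.tif")
        tifffile.imwrite(str(outdir / "brightfield.tif"), self.brightfield)
        t = self.truth
        tifffile.imwrite(str(outdir / "truth_traction_peak.tif"),
                         np.stack([t.traction_peak.t_x, t.traction_peak.t_y]).astype(np.float32))
        tifffile.imwrite(str(outdir / "truth_displacement_peak.tif"),
                         np.stack([t.displacement_peak.u_x, t.displacement_peak.u_y]).astype(np.float32))
        meta = {
            "seed": t.seed,
            "px_size_um": self.imaging.px_size,
            "fps": self.imaging.fps,
            "grid_x0_um": float(t.traction_peak.grid_x[0]),
            "grid_y0_um": float(t.traction_peak.grid_y[0]),
            "grid_spacing_um": t.traction_peak.spacing,
            "youngs_modulus_Pa": t.substrate.youngs_modulus_E,
            "poisson_ratio": t.substrate.poisson_ratio_nu,
            "modulation": t.modulation.tolist(),
            "total_force_truth_nN": t.total_force_truth_nN.tolist(),
            "pattern": {
                "area_A_um2": self.pattern.area_A_um2,
                "length_L_um": self.pattern.length_L_um,
                "width_W_um": self.pattern.width_W_um,
                "aspect_ratio_r": self.pattern.aspect_ratio_r,
            },
        }
        (outdir / "truth.json").write_text(json.dumps(meta, indent=2))


def make_brightfield(pattern: MicropatternSpec, imaging: ImagingConfig,
                     seed: int, center_um: Optional[tuple[float, float]] = None
                     ) -> np.ndarray:
    """Brightfield frame with a textured cell body on the pattern footprint.

    The footprint is a capsule (rectangle with semicircular caps) of the
    pattern's length and width; the interior carries strong speckle texture
    while the background is smooth with mild noise, which is the contrast
    the texture-based outline detector keys on.
    """
    rng = np.random.default_rng(seed)
    rows, cols = imaging.frame_shape
    px = imaging.px_size
    if center_um is None:
        center_um = (cols * px / 2.0, rows * px / 2.0)
    yy, xx = np.mgrid[0:rows, 0:cols]
    x_um = xx * px - center_um[0]
    y_um = yy * px - center_um[1]
    half_core = pattern.length_L_um / 2.0 - pattern.width_W_um / 2.0
    dx = np.maximum(np.abs(x_um) - half_core, 0.0)
    dist = np.hypot(dx, y_um)
    footprint = dist <= pattern.width_W_um / 2.0
    img = 2000.0 + 1.5 * xx + rng.normal(0.0, 12.0, (rows, cols))
    speckle = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (rows, cols)), 0.8)
    img[footprint] += 350.0 * speckle[footprint] - 150.0
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def simulate_tfm_sequence(pattern: MicropatternSpec,
                          substrate: ElasticSubstrate,
                          imaging: ImagingConfig,
                          duration_s: float,
                          pulse_frequency_hz: float = 1.0,
                          seed: int = 0,
                          peak_stress_Pa: float = 400.0,
                          patch_sigma_um: float = 6.0,
                          bead_density_per_um2: float = 0.08,
                          duty_fraction: float = 0.4,
                          truth_spacing_um: Optional[float] = None,
                          noise_model: Optional[BeadNoiseModel] = BeadNoiseModel(),
                          ) -> SimulatedTfm:
    """Simulate a beating micropatterned cell: video + brightfield + truth.

    Traction(t) = s(t) * dipole peak traction with a raised-cosine pulse
    train; frame 0 coincides with full relaxation (s = 0).  The number of
    frames is duration x fps, capped at 1e5 as a resource guard.
    """
    if duration_s * pulse_frequency_hz < 2:
        raise ValueError("duration must cover at least 2 contraction pulses")
    n_frames = int(round(duration_s * imaging.fps))
    if n_frames > 1e5:
        raise ValueError(f"{n_frames} frames exceeds the 1e5 resource guard")
    if truth_spacing_um is None:
        truth_spacing_um = 5 * imaging.px_size
    grid = make_grid(imaging.extent_um, truth_spacing_um)
    traction_peak = make_dipole_traction(pattern, peak_stress_Pa, grid,
                                         patch_sigma_um=patch_sigma_um)
    traction_peak.substrate = substrate
    displacement_peak = boussinesq_displacement(traction_peak, substrate)
    times = np.arange(n_frames) / imaging.fps
    s = raised_cosine_modulation(times, pulse_frequency_hz, duty_fraction)
    beads = sample_bead_positions(imaging, bead_density_per_um2, seed)
    u_beads_peak = _sample_displacement_at(displacement_peak, beads)

    rng = np.random.default_rng(seed + 1)
    frame_seeds = rng.integers(0, 2 ** 31 - 1, size=n_frames)
    frames = np.empty((n_frames, *imaging.frame_shape), dtype=np.uint16)
    for i in range(n_frames):
        pos = beads + s[i] * u_beads_peak
        frames[i] = _render_prepositioned(pos, imaging, noise_model,
                                          int(frame_seeds[i]))
    sequence = BeadSequence(frames=frames, px_size=imaging.px_size, fps=imaging.fps)
    brightfield = make_brightfield(pattern, imaging, seed + 2)
    total_force = traction_peak.total_scalar_force_nN() * s
    truth = PhantomTruth(
        traction_peak=traction_peak,
        displacement_peak=displacement_peak,
        modulation=s,
        bead_positions_reference_um=beads,
        total_force_truth_nN=total_force,
        seed=seed,
        substrate=substrate,
    )
    return SimulatedTfm(sequence=sequence, brightfield=brightfield, truth=truth,
                        imaging=imaging, pattern=pattern)


def _render_prepositioned(positions_um: np.ndarray, imaging: ImagingConfig,
                          noise_model: Optional[BeadNoiseModel], seed: int) -> np.ndarray:
    """Render beads already moved to their displaced positions."""
    return render_bead_frame(positions_um, None, imaging, noise_model, seed)


# ---------------------------------------------------------------------------
# survey phantom for the cell locator
# ---------------------------------------------------------------------------

def make_survey_phantom(cell_specs: Sequence[tuple[tuple[float, float], float, float, float]],
                        imaging: ImagingConfig,
                        seed: int = 0):
    """Synthetic 10x brightfield survey with an exact truth table.

    ``cell_specs`` is a sequence of ``((x_um, y_um), area_um2, aspect_ratio,
    orientation_deg)``.  Cells are rendered as filled, textured ellipses
    darker than the background (transmitted-light contrast).  Overlapping
    specs are rejected.  Returns ``(image, truth)`` where ``truth`` is a
    DataFrame listing the exact requested area, aspect ratio and center of
    every rendered cell.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows, cols = imaging.frame_shape
    px = imaging.px_size
    # semi-axes: area = pi*a*b, a/b = aspect ratio
    semis = []
    for (cx, cy), area, ar, theta in cell_specs:
        b = np.sqrt(area / (np.pi * ar))
        a = ar * b
        semis.append((a, b))
    for i in range(len(cell_specs)):
        for j in range(i + 1, len(cell_specs)):
            (xi, yi) = cell_specs[i][0]
            (xj, yj) = cell_specs[j][0]
            if np.hypot(xi - xj, yi - yj) < semis[i][0] + semis[j][0]:
                raise ValueError(f"cell specs {i} and {j} overlap")
    img = 3000.0 + rng.normal(0.0, 15.0, (rows, cols))
    yy, xx = np.mgrid[0:rows, 0:cols]
    speckle = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (rows, cols)), 1.0)
    records = []
    for idx, ((cx, cy), area, ar, theta) in enumerate(cell_specs):
        a, b = semis[idx]
        th = np.deg2rad(theta)
        x_um = xx * px - cx
        y_um = yy * px - cy
        xr = x_um * np.cos(th) + y_um * np.sin(th)
        yr = -x_um * np.sin(th) + y_um * np.cos(th)
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        img[inside] += -700.0 + 120.0 * speckle[inside]
        records.append({
            "cell_id": f"phantom-{idx:03d}",
            "x_um": cx, "y_um": cy,
            "area_um2": area, "aspect_ratio": ar,
            "orientation_deg": theta,
        })
    truth = pd.DataFrame(records, columns=["cell_id", "x_um", "y_um", "area_um2",
                                           "aspect_ratio", "orientation_deg"])
    image = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return image, truth
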