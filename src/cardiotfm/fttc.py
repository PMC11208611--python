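"""Regularized Fourier-transform traction cytometry (FTTC).

The substrate is a linearly elastic half-space.  In Fourier space the
surface displacement u(k) produced by a tangential surface traction T(k)
is ``u(k) = G(k) T(k)`` with the 2x2 Boussinesq surface Green's tensor

    G(k) = 2(1+nu) / (E |k|^3) * [[(1-nu)k^2 + nu ky^2,  -nu kx ky],
                                  [-nu kx ky,  (1-nu)k^2 + nu kx^2]]

(k in rad/µm, E in Pa, G in µm/Pa).  The inverse problem is ill-posed and
is solved per wavevector with zeroth-order Tikhonov damping,

    T(k) = (G(k)^T G(k) + lam_abs^2 I)^-1 G(k)^T u(k),    T(0) = 0,

where the regularization parameter is chosen automatically at the corner
of the L-curve (residual norm vs solution norm over a lambda grid).

The dimensionless parameter ``lam`` used throughout this module is scaled
so that ``lam_abs = lam * sqrt(mean_k diag(G^T G))``; the default lambda
grid is therefore independent of substrate stiffness and grid spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from cardiotfm.fields import DisplacementField, TractionField
from cardiotfm.substrate import ElasticSubstrate


@dataclass
class TractionSolverConfig:
    """Solver settings for the regularized inversion.

    ``lambda_grid`` is dimensionless (see module docstring), log-spaced over
    ten decades by default.  ``padding_factor`` zero-pads the displacement
    before the transform to suppress periodic wrap-around.  ``window`` may
    be ``"none"`` or ``"cosine"`` (Tukey taper on the mean-subtracted
    displacement).
    """

    lambda_grid: np.ndarray = field(default_factory=lambda: np.logspace(-6.0, 4.0, 40))
    padding_factor: int = 2
    window: str = "none"
    poisson_ratio_override: Optional[float] = None

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if np.any(self.lambda_grid <= 0) or np.any(np.diff(self.lambda_grid) <= 0):
            raise ValueError("lambda_grid must be strictly increasing and positive")
        if self.padding_factor < 1:
            raise ValueError("padding_factor must be >= 1")
        if self.window not in ("none", "cosine"):
            raise ValueError("window must be 'none' or 'cosine'")


class LCurveWarning(UserWarning):
    """Raised when the L-curve has no well-defined corner."""


def greens_tensor(k_x: float, k_y: float, substrate: ElasticSubstrate) -> np.ndarray:
    """Boussinesq surface Green's tensor at a single wavevector (rad/µm).

    Returns the symmetric 2x2 tensor in µm/Pa.  The zero wavevector is
    rejected: the k = 0 mode is handled separately by the caller (nulled).
    """
    if k_x == 0.0 and k_y == 0.0:
        raise ValueError("Green's tensor is singular at k = 0; handle the zero mode separately")
    E = substrate.youngs_modulus_E
    nu = substrate.poisson_ratio_nu
    k2 = k_x * k_x + k_y * k_y
    k = np.sqrt(k2)
    pref = 2.0 * (1.0 + nu) / (E * k2 * k)
    gxx = pref * ((1.0 - nu) * k2 + nu * k_y * k_y)
    gyy = pref * ((1.0 - nu) * k2 + nu * k_x * k_x)
    gxy = pref * (-nu * k_x * k_y)
    return np.array([[gxx, gxy], [gxy, gyy]])


def _kgrid(ny: int, nx: int, spacing_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Angular wavevector grids (rad/µm) matching numpy FFT ordering."""
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing_um)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing_um)
    return np.meshgrid(kx, ky, indexing="xy")


def _kgrid_r(ny: int, nx: int, spacing_um: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Half-spectrum wavevector grids for rfft2, plus Parseval weights.

    Working in the real-input half spectrum keeps the inverse transform
    exactly real (Hermitian symmetry by construction), which matters when
    near-singular inversions amplify rounding asymmetries.  The weights
    count each off-axis column twice so spectral norms match the full
    spectrum.
    """
    kx = 2.0 * np.pi * np.fft.rfftfreq(nx, d=spacing_um)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing_um)
    KX, KY = np.meshgrid(kx, ky, indexing="xy")
    w = np.full(kx.size, 2.0)
    w[0] = 1.0
    if nx % 2 == 0:
        w[-1] = 1.0
    weights = np.broadcast_to(w[None, :], KX.shape)
    return KX, KY, weights


def _greens_grid(KX: np.ndarray, KY: np.ndarray, substrate: ElasticSubstrate,
                 nu: Optional[float] = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Green's tensor components (Gxx, Gxy, Gyy) with G(0) := 0."""
    E = substrate.youngs_modulus_E
    if nu is None:
        nu = substrate.poisson_ratio_nu
    k2 = KX * KX + KY * KY
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k2 * np.sqrt(k2))
        gxx = pref * ((1.0 - nu) * k2 + nu * KY * KY)
        gyy = pref * ((1.0 - nu) * k2 + nu * KX * KX)
        gxy = pref * (-nu * KX * KY)
    zero = k2 == 0.0
    for g in (gxx, gxy, gyy):
        g[zero] = 0.0
    return gxx, gxy, gyy


def _padded_fft(u_x: np.ndarray, u_y: np.ndarray, pad_factor: int,
                window: str) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    ny, nx = u_x.shape
    ux = u_x - u_x.mean()
    uy = u_y - u_y.mean()
    if window == "cosine":
        from scipy.signal.windows import tukey
        wy = tukey(ny, 0.2)[:, None]
        wx = tukey(nx, 0.2)[None, :]
        ux = ux * wy * wx
        uy = uy * wy * wx
    py, px = ny * pad_factor, nx * pad_factor
    buf_x = np.zeros((py, px))
    buf_y = np.zeros((py, px))
    buf_x[:ny, :nx] = ux
    buf_y[:ny, :nx] = uy
    return np.fft.rfft2(buf_x), np.fft.rfft2(buf_y), (py, px)


def _tikhonov_kspace(Ux: np.ndarray, Uy: np.ndarray,
                     gxx: np.ndarray, gxy: np.ndarray, gyy: np.ndarray,
                     lam_abs2: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavevector Tikhonov solve for a symmetric 2x2 Green's tensor."""
    # G^T G components (G symmetric)
    a = gxx * gxx + gxy * gxy
    b = gxy * (gxx + gyy)
    c = gyy * gyy + gxy * gxy
    rhs_x = gxx * Ux + gxy * Uy
    rhs_y = gxy * Ux + gyy * Uy
    det = (a + lam_abs2) * (c + lam_abs2) - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        Tx = ((c + lam_abs2) * rhs_x - b * rhs_y) / det
        Ty = (-b * rhs_x + (a + lam_abs2) * rhs_y) / det
    zero = (gxx == 0.0) & (gyy == 0.0) & (gxy == 0.0)
    Tx[zero] = 0.0
    Ty[zero] = 0.0
    return Tx, Ty


def _mean_gtg_diag(gxx: np.ndarray, gxy: np.ndarray, gyy: np.ndarray,
                   weights: Optional[np.ndarray] = None) -> float:
    a = gxx * gxx + gxy * gxy
    c = gyy * gyy + gxy * gxy
    nonzero = (gxx != 0.0) | (gyy != 0.0) | (gxy != 0.0)
    if weights is None:
        return float(0.5 * (a[nonzero].mean() + c[nonzero].mean()))
    w = weights[nonzero]
    return float(0.5 * (np.sum((a[nonzero] + c[nonzero]) * w) / w.sum()))


def solve_traction(displacement: DisplacementField, substrate: ElasticSubstrate,
                   lam: float, config: Optional[TractionSolverConfig] = None) -> TractionField:
    """Recover the traction field from a displacement field.

    ``lam`` is the dimensionless regularization parameter (module docstring).
    Invalid nodes must be pre-filled; the displacement mean is subtracted,
    the arrays zero-padded, the per-wavevector damped inverse applied, the
    k = 0 mode nulled and the padding removed.  Each traction component is
    returned with zero mean, so the recovered field is force-balanced.
    """
    if config is None:
        config = TractionSolverConfig()
    if lam <= 0:
        raise ValueError(f"regularization parameter must be > 0, got {lam}")
    if np.any(~np.isfinite(displacement.u_x)) or np.any(~np.isfinite(displacement.u_y)):
        raise ValueError("displacement field contains NaN/inf; fill invalid nodes first")
    spacing = displacement.spacing
    ny, nx = displacement.u_x.shape
    Ux, Uy, (py, px) = _padded_fft(displacement.u_x, displacement.u_y,
                                   config.padding_factor, config.window)
    KX, KY, weights = _kgrid_r(py, px, spacing)
    gxx, gxy, gyy = _greens_grid(KX, KY, substrate, config.poisson_ratio_override)
    lam_abs2 = lam * lam * _mean_gtg_diag(gxx, gxy, gyy, weights)
    Tx, Ty = _tikhonov_kspace(Ux, Uy, gxx, gxy, gyy, lam_abs2)
    # half-spectrum inverse: exactly real by construction (no imaginary residue)
    tx = np.fft.irfft2(Tx, s=(py, px))[:ny, :nx]
    ty = np.fft.irfft2(Ty, s=(py, px))[:ny, :nx]
    # cropping the padded solution leaves a small residual mean; remove it so
    # each component is exactly zero-mean (k = 0 convention)
    tx -= tx.mean()
    ty -= ty.mean()
    return TractionField(displacement.grid_x.copy(), displacement.grid_y.copy(),
                         tx, ty, lambda_used=lam, substrate=substrate)


def lcurve_sweep(displacement: DisplacementField, substrate: ElasticSubstrate,
                 config: Optional[TractionSolverConfig] = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residual norm rho(lam) = ||G T - u|| and solution norm eta(lam) = ||T||.

    Norms are evaluated in Fourier space (Parseval), which is exact up to a
    constant factor that cancels in the log-log L-curve.
    """
    if config is None:
        config = TractionSolverConfig()
    lams = config.lambda_grid
    spacing = displacement.spacing
    Ux, Uy, (py, px) = _padded_fft(displacement.u_x, displacement.u_y,
                                   config.padding_factor, config.window)
    KX, KY, weights = _kgrid_r(py, px, spacing)
    gxx, gxy, gyy = _greens_grid(KX, KY, substrate, config.poisson_ratio_override)
    scale = _mean_gtg_diag(gxx, gxy, gyy, weights)
    u_norm = np.sqrt(np.sum(weights * (np.abs(Ux) ** 2 + np.abs(Uy) ** 2)))
    rho = np.empty_like(lams)
    eta = np.empty_like(lams)
    for i, lam in enumerate(lams):
        Tx, Ty = _tikhonov_kspace(Ux, Uy, gxx, gxy, gyy, lam * lam * scale)
        Rx = gxx * Tx + gxy * Ty - Ux
        Ry = gxy * Tx + gyy * Ty - Uy
        rho[i] = np.sqrt(np.sum(weights * (np.abs(Rx) ** 2 + np.abs(Ry) ** 2)))
        eta[i] = np.sqrt(np.sum(weights * (np.abs(Tx) ** 2 + np.abs(Ty) ** 2)))
    # guard against exactly-zero residuals (noiseless synthetic input)
    rho = np.maximum(rho, 1e-15 * max(u_norm, 1e-300))
    eta = np.maximum(eta, 1e-300)
    return lams, rho, eta


def _smooth(x: np.ndarray, window: int = 3) -> np.ndarray:
    if window <= 1:
        return x
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")


def select_lambda_lcurve(displacement: DisplacementField, substrate: ElasticSubstrate,
                         config: Optional[TractionSolverConfig] = None
                         ) -> tuple[float, dict]:
    """Choose the regularization parameter at the L-curve corner.

    Computes (log rho, log eta) over the lambda grid, smooths both with a
    3-point moving average, and locates the corner as an extremum of the
    discrete curvature (with the curve traversed in increasing lambda the
    corner bends clockwise, so corners are the most negative signed
    curvature).  The curve of a square FTTC system has a second, often
    stronger knee at very large lambda where the regularization starts
    erasing the signal itself (the residual approaches ||u||); the corner
    returned is therefore the *first* significant curvature minimum from
    the under-regularized side, with ties broken toward smaller lambda.
    If the curve never bends (monotone curvature) the lambda at the
    largest second difference of log eta is returned with a warning.
    """
    if config is None:
        config = TractionSolverConfig()
    if config.lambda_grid.size < 10:
        raise ValueError("lambda grid needs >= 10 points for corner detection")
    lams, rho, eta = lcurve_sweep(displacement, substrate, config)
    t = np.log(lams)
    x = _smooth(np.log(rho))
    y = _smooth(np.log(eta))
    dx = np.gradient(x, t)
    dy = np.gradient(y, t)
    d2x = np.gradient(dx, t)
    d2y = np.gradient(dy, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        curvature = (dx * d2y - dy * d2x) / np.power(dx * dx + dy * dy, 1.5)
    curvature = np.nan_to_num(curvature, nan=np.inf)
    diagnostics = {"lambda_grid": lams, "rho": rho, "eta": eta, "curvature": curvature}
    # a genuine noise corner must occur while the data are still well fitted;
    # past rho ~ ||u|| the bend is the over-smoothing knee, not a corner.
    # The corner shows up either as a local extremum of the curvature or,
    # when it blends into the over-smoothing knee, as a plateau where the
    # curvature's descent stalls before steepening again.
    guarded = rho <= 0.2 * rho.max()
    corners = [i for i in range(1, len(curvature) - 1)
               if guarded[i] and curvature[i] <= -0.05
               and (curvature[i + 1] - curvature[i]) >= -0.2 * abs(curvature[i])
               and curvature[i] <= curvature[i - 1]]
    if corners:
        idx = corners[0]
    else:
        warnings.warn("L-curve has no corner on the well-fitted branch; "
                      "falling back to the maximum second difference of log ||T||",
                      LCurveWarning)
        n_guard = int(np.count_nonzero(guarded))
        if n_guard >= 3:
            d2 = np.abs(np.diff(np.log(eta[:n_guard]), 2))
            idx = int(np.argmax(d2)) + 1
        else:
            idx = 0
    diagnostics["corner_index"] = idx
    return float(lams[idx]), diagnostics


def oracle_lambda_sweep(displacement: DisplacementField, substrate: ElasticSubstrate,
                        truth: TractionField,
                        config: Optional[TractionSolverConfig] = None
                        ) -> tuple[float, np.ndarray]:
    """Lambda minimizing the true traction error against a known ground truth.

    Only available for synthetic data; used to benchmark the L-curve choice.
    Returns ``(lambda_best, errors)`` with relative L2 errors per grid point.
    """
    if config is None:
        config = TractionSolverConfig()
    truth_norm = np.sqrt(np.sum(truth.t_x ** 2 + truth.t_y ** 2))
    errors = np.empty_like(config.lambda_grid)
    for i, lam in enumerate(config.lambda_grid):
        rec = solve_traction(displacement, substrate, lam, config)
        err = np.sqrt(np.sum((rec.t_x - truth.t_x) ** 2 + (rec.t_y - truth.t_y) ** 2))
        errors[i] = err / max(truth_norm, 1e-300)
    return float(config.lambda_grid[int(np.argmin(errors))]), errors
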