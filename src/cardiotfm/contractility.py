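"""Cell outline, contraction traces and contractile metrics.

From per-frame traction and displacement fields plus one brightfield image
this module segments the cell, integrates force and strain energy over the
(2 µm-dilated) cell mask, detects individual contraction cycles on the
force trace, and averages per-cycle quantities into eleven scalar
contractile metrics:

F_max (nN)      peak force above baseline
W_max (fJ)      mechanical work along the contraction stroke
P_max (fW)      peak contractile power
E_max (fJ)      peak substrate strain energy above baseline
f_contr (Hz)    beating frequency
v_contr (µm/s)  peak contraction velocity
v_rel (µm/s)    peak relaxation velocity
I_contr (nN s)  contraction impulse (force integral, onset -> peak)
I_rel (nN s)    relaxation impulse (peak -> end)
t_vmax (s)      onset -> peak-velocity interval
t_contr (s)     overall contraction duration

Unit bookkeeping: Pa·µm² = pN and Pa·µm³ = aJ, so forces integrate to nN
with a 1e-3 factor and energies to fJ with a 1e-3 factor; nN·µm/s = fW and
nN·µm = fJ fall out directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from scipy import ndimage

from cardiotfm.fields import DisplacementField, ImagingConfig, TractionField


class SegmentationError(RuntimeError):
    """No usable cell found in the brightfield image."""


class ContractionDetectionError(RuntimeError):
    """Unidentifiable contraction peaks (flat or noisy trace)."""


@dataclass
class CellMask:
    """Segmented cell with morphology descriptors.

    ``mask`` is a boolean image in brightfield pixel coordinates; the
    aspect ratio is the major/minor axis ratio of the second-moment
    equivalent ellipse (>= 1).
    """

    mask: np.ndarray
    px_size: float
    area_um2: float
    aspect_ratio: float
    centroid_um: tuple[float, float]
    outline_um: np.ndarray          # (n, 2) polygon vertices, µm


@dataclass
class ContractionTraces:
    """Per-frame scalar traces of a contracting cell."""

    time_s: np.ndarray
    F_nN: np.ndarray          # total scalar force over the mask
    U_fJ: np.ndarray          # substrate strain energy over the mask
    X_um: np.ndarray          # mean displacement magnitude over the mask
    v_um_s: np.ndarray        # smoothed dX/dt
    baseline_F_nN: float

    @property
    def fps(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time_s)))

    @property
    def baseline_U_fJ(self) -> float:
        return float(np.percentile(self.U_fJ, 5))


@dataclass
class ContractionEvent:
    """One contraction cycle on the force trace."""

    onset_t: float
    peak_t: float
    end_t: float
    peak_F: float
    amplitude: float
    onset_i: int = 0
    peak_i: int = 0
    end_i: int = 0


@dataclass
class ContractileMetrics:
    F_max_nN: float
    W_max_fJ: float
    P_max_fW: float
    E_max_fJ: float
    f_contr_Hz: float
    v_contr_um_s: float
    v_rel_um_s: float
    I_contr_nNs: float
    I_rel_nNs: float
    t_vmax_s: float
    t_contr_s: float
    n_cycles: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# outline detection
# ---------------------------------------------------------------------------

def detect_outline(brightfield: np.ndarray, px_size: float,
                   texture_window_px: int = 9,
                   min_area_um2: float = 100.0) -> CellMask:
    """Texture-based segmentation of the single dominant cell.

    The cell body carries strong intensity texture against a smooth
    background, so a local-standard-deviation map thresholded with Otsu's
    method isolates it.  Morphological closing bridges texture gaps, the
    mask is eroded back by the texture-window half-width (the variance map
    spreads the boundary outward by that much), the largest connected
    component is kept and holes are filled.  Deterministic.
    """
    img = np.asarray(brightfield, dtype=float)
    w = texture_window_px
    mean = ndimage.uniform_filter(img, w)
    sq = ndimage.uniform_filter(img * img, w)
    std = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    thr = threshold_otsu(std)
    # on a blank frame Otsu just splits the noise floor; a real cell's texture
    # pushes the threshold far above the background's local std
    if thr < 2.0 * np.median(std):
        raise SegmentationError("no textured cell found (blank pattern?)")
    rough = std > thr
    rough = morphology.closing(rough, morphology.disk(2))
    rough = ndimage.binary_fill_holes(rough)
    rough = morphology.erosion(rough, morphology.disk(w // 2))
    labels = measure.label(rough)
    if labels.max() == 0:
        raise SegmentationError("no textured component found")
    props = measure.regionprops(labels)
    props.sort(key=lambda p: p.area, reverse=True)
    best = props[0]
    area_um2 = best.area * px_size ** 2
    if area_um2 < min_area_um2:
        raise SegmentationError(
            f"largest component is {area_um2:.0f} µm² < {min_area_um2} µm² (empty pattern?)")
    mask = ndimage.binary_fill_holes(labels == best.label)
    minor = max(best.axis_minor_length, 1e-9)
    contours = measure.find_contours(mask.astype(float), 0.5)
    outline = max(contours, key=len)[:, ::-1] * px_size     # (row,col)->(x,y)
    return CellMask(
        mask=mask,
        px_size=px_size,
        area_um2=float(np.count_nonzero(mask) * px_size ** 2),
        aspect_ratio=float(best.axis_major_length / minor),
        centroid_um=(best.centroid[1] * px_size, best.centroid[0] * px_size),
        outline_um=outline,
    )


def mask_on_grid(cell: CellMask, grid_x: np.ndarray, grid_y: np.ndarray,
                 dilation_um: float = 2.0) -> np.ndarray:
    """Sample the (dilated) cell mask at field grid nodes.

    FTTC spreads traction slightly beyond the cell edge, so the mask is
    dilated by ``dilation_um`` before integration; with 200 µm pattern
    pitch this cannot engulf a neighboring cell.
    """
    r = max(1, int(round(dilation_um / cell.px_size)))
    dilated = morphology.dilation(cell.mask, morphology.disk(r))
    iy = np.clip(np.round(np.asarray(grid_y) / cell.px_size).astype(int),
                 0, dilated.shape[0] - 1)
    ix = np.clip(np.round(np.asarray(grid_x) / cell.px_size).astype(int),
                 0, dilated.shape[1] - 1)
    return dilated[np.ix_(iy, ix)]


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def compute_traces(traction_frames: Sequence[TractionField],
                   displacement_frames: Sequence[DisplacementField],
                   cell: CellMask, imaging: ImagingConfig,
                   dilation_um: float = 2.0) -> ContractionTraces:
    """Integrate force, strain energy and displacement over the cell mask.

    F(t) = sum |T| a over the mask (nN); U(t) = 1/2 sum T·u a (fJ);
    X(t) = mean |u| over the mask (µm); v(t) = smoothed dX/dt via a local
    quadratic polynomial over 5 frames (µm/s).  The force baseline is the
    5th percentile of F(t), robust to recordings that never fully relax.
    """
    if len(traction_frames) != len(displacement_frames) or not traction_frames:
        raise ValueError("need matching, non-empty traction and displacement frame lists")
    t0 = traction_frames[0]
    d0 = displacement_frames[0]
    if (t0.t_x.shape != d0.u_x.shape
            or not np.allclose(t0.grid_x, d0.grid_x)
            or not np.allclose(t0.grid_y, d0.grid_y)):
        raise ValueError("traction and displacement grids are not aligned")
    node_mask = mask_on_grid(cell, t0.grid_x, t0.grid_y, dilation_um)
    if not node_mask.any():
        raise ValueError("cell mask does not overlap the field grid")
    a = t0.node_area_um2
    n = len(traction_frames)
    F = np.empty(n)
    U = np.empty(n)
    X = np.empty(n)
    for i, (tf, df) in enumerate(zip(traction_frames, displacement_frames)):
        tm = tf.magnitude[node_mask]
        F[i] = tm.sum() * a * 1e-3
        dot = (tf.t_x * df.u_x + tf.t_y * df.u_y)[node_mask]
        U[i] = 0.5 * dot.sum() * a * 1e-3
        X[i] = df.magnitude[node_mask].mean()
    time = np.arange(n) / imaging.fps
    if n >= 5:
        v = savgol_filter(X, 5, 2, deriv=1, delta=1.0 / imaging.fps)
    else:
        v = np.gradient(X, time) if n > 1 else np.zeros(n)
    return ContractionTraces(
        time_s=time, F_nN=F, U_fJ=U, X_um=X, v_um_s=v,
        baseline_F_nN=float(np.percentile(F, 5)),
    )


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_contraction_events(traces: ContractionTraces,
                              expected_band_hz: tuple[float, float] = (0.4, 1.6)
                              ) -> list[ContractionEvent]:
    """Detect individual contraction cycles on the force trace.

    Peaks must rise at least 25% of (max - baseline) above their
    surroundings and be separated by at least one period of the upper
    pacing frequency.  Onset and end are located where the force crosses
    baseline + 10% of the cycle amplitude on each side of the peak,
    bounded by the midpoints to the neighboring peaks so events never
    overlap.  Fewer than two peaks is a rejection (unidentifiable
    contraction peaks), mirroring standard exclusion bookkeeping.
    """
    F = traces.F_nN
    t = traces.time_s
    baseline = traces.baseline_F_nN
    f_min, f_max = expected_band_hz
    if t[-1] * f_min < 2:
        raise ContractionDetectionError(
            "recording shorter than two expected contraction cycles")
    amp_ref = float(F.max() - baseline)
    if amp_ref <= 0:
        raise ContractionDetectionError("unidentifiable contraction peaks (flat trace)")
    # the excursion must clear the trace's own noise floor, otherwise the
    # "peaks" are measurement noise (a non-contracting or low-SNR cell)
    from scipy.signal import medfilt
    noise = 1.4826 * float(np.median(np.abs(F - medfilt(F, 5))))
    if amp_ref < 8.0 * noise:
        raise ContractionDetectionError(
            "unidentifiable contraction peaks (excursion within the noise floor)")
    distance = max(1, int(round(traces.fps / f_max)))
    peaks, _ = find_peaks(F, prominence=0.25 * amp_ref, distance=distance)
    if peaks.size < 2:
        raise ContractionDetectionError(
            f"unidentifiable contraction peaks ({peaks.size} found)")
    events: list[ContractionEvent] = []
    for j, p in enumerate(peaks):
        left = 0 if j == 0 else (peaks[j - 1] + p) // 2
        right = len(F) - 1 if j == len(peaks) - 1 else (p + peaks[j + 1]) // 2
        amplitude = float(F[p] - baseline)
        thr = baseline + 0.1 * amplitude
        onset = p
        while onset > left and F[onset - 1] > thr:
            onset -= 1
        onset = max(left, min(onset - 1, p - 1))    # last sample below threshold
        end = p
        while end < right and F[end + 1] > thr:
            end += 1
        end = min(right, max(end + 1, p + 1))       # first sample back below threshold
        events.append(ContractionEvent(
            onset_t=float(t[onset]), peak_t=float(t[p]), end_t=float(t[end]),
            peak_F=float(F[p]), amplitude=amplitude,
            onset_i=int(onset), peak_i=int(p), end_i=int(end),
        ))
    return events


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(traces: ContractionTraces, events: list[ContractionEvent],
                    f_max_mode: str = "mean") -> ContractileMetrics:
    """Average per-cycle contractile quantities into the eleven metrics.

    Cycle quantities are measured as deltas between the most relaxed and
    most contracted states (force relative to the trace baseline, strain
    energy relative to its 5th percentile) and averaged over all detected
    cycles; ``f_max_mode="max"`` switches F_max to the single largest
    cycle instead.
    """
    if not events:
        raise ValueError("empty event list")
    if f_max_mode not in ("mean", "max"):
        raise ValueError("f_max_mode must be 'mean' or 'max'")
    F = traces.F_nN
    U = traces.U_fJ
    v = traces.v_um_s
    t = traces.time_s
    baseline = traces.baseline_F_nN
    base_U = traces.baseline_U_fJ
    amps, e_amps, v_cs, v_rs, i_cs, i_rs, t_cs, t_vs, w_ms, p_ms = ([] for _ in range(10))
    for ev in events:
        o, p, e = ev.onset_i, ev.peak_i, ev.end_i
        rise = slice(o, p + 1)
        decay = slice(p, e + 1)
        amps.append(ev.amplitude)
        e_amps.append(U[o:e + 1].max() - base_U)
        v_cs.append(v[rise].max())
        v_rs.append(abs(v[decay].min()))
        i_cs.append(np.trapezoid(F[rise] - baseline, t[rise]))
        i_rs.append(np.trapezoid(F[decay] - baseline, t[decay]))
        t_cs.append(ev.end_t - ev.onset_t)
        t_vs.append(t[o + int(np.argmax(v[rise]))] - ev.onset_t)
        frel = F[rise] - baseline
        w_ms.append(np.trapezoid(frel * v[rise], t[rise]))
        p_ms.append((frel * v[rise]).max())
    peak_times = np.array([ev.peak_t for ev in events])
    f_contr = 1.0 / float(np.mean(np.diff(peak_times)))
    f_max = float(np.max(amps)) if f_max_mode == "max" else float(np.mean(amps))
    return ContractileMetrics(
        F_max_nN=f_max,
        W_max_fJ=float(np.mean(w_ms)),
        P_max_fW=float(np.mean(p_ms)),
        E_max_fJ=float(np.mean(e_amps)),
        f_contr_Hz=f_contr,
        v_contr_um_s=float(np.mean(v_cs)),
        v_rel_um_s=float(np.mean(v_rs)),
        I_contr_nNs=float(np.mean(i_cs)),
        I_rel_nNs=float(np.mean(i_rs)),
        t_vmax_s=float(np.mean(t_vs)),
        t_contr_s=float(np.mean(t_cs)),
        n_cycles=len(events),
    )
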