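"""Shared fixtures: seeded phantoms and the full pipeline run.

The heavy artifacts (a 7 s simulated recording and its complete analysis)
are session-scoped so the expensive DIC pass runs once for the whole
suite.  The simulated cell is a scaled-down 7:1 micropatterned
cardiomyocyte (900 µm² footprint in a 110 x 44 µm field of view) at the
standard imaging settings (0.275 µm/px, 30 fps), paced at 1 Hz on a
10 kPa substrate with 400 Pa peak patch stress.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from cardiotfm import cohort, phantom
from cardiotfm.fields import DisplacementField, ImagingConfig, TractionField
from cardiotfm.substrate import ElasticSubstrate

PX = 0.275
SEED = 42


@pytest.fixture(scope="session")
def small_imaging() -> ImagingConfig:
    return ImagingConfig(px_size=PX, fps=30.0, frame_shape=(160, 400),
                         crop_window_um=(44.0, 110.0))


@pytest.fixture(scope="session")
def pattern() -> phantom.MicropatternSpec:
    return cohort.micropattern_geometry(area_A_um2=900.0, aspect_ratio_r=7.0)


@pytest.fixture(scope="session")
def substrate_10kpa() -> ElasticSubstrate:
    return ElasticSubstrate(10_000.0)


@pytest.fixture(scope="session")
def sim7s(pattern, substrate_10kpa, small_imaging) -> phantom.SimulatedTfm:
    """7 s, 1 Hz, 30 fps seeded recording with truth bundle."""
    return phantom.simulate_tfm_sequence(
        pattern, substrate_10kpa, small_imaging, duration_s=7.0,
        pulse_frequency_hz=1.0, seed=SEED, peak_stress_Pa=400.0,
        patch_sigma_um=5.0)


@pytest.fixture(scope="session")
def pipeline7s(sim7s, substrate_10kpa, small_imaging) -> cohort.PipelineResult:
    """Full analysis of the 7 s phantom (reference DIC FTTC metrics)."""
    return cohort.run_tfm_pipeline(sim7s.sequence.frames, sim7s.brightfield,
                                   substrate_10kpa, small_imaging, crop=False)


@pytest.fixture(scope="session")
def beads(small_imaging) -> np.ndarray:
    return phantom.sample_bead_positions(small_imaging, 0.08, seed=1)


def truth_on_grid(truth_traction: TractionField, fld: DisplacementField,
                  scale: float = 1.0) -> TractionField:
    """Resample a truth traction field onto another field's grid."""
    def resamp(arr):
        itp = RegularGridInterpolator(
            (truth_traction.grid_y, truth_traction.grid_x), arr,
            bounds_error=False, fill_value=None)
        yy, xx = np.meshgrid(fld.grid_y, fld.grid_x, indexing="ij")
        return itp(np.stack([yy.ravel(), xx.ravel()], -1)).reshape(yy.shape)
    return TractionField(fld.grid_x.copy(), fld.grid_y.copy(),
                         resamp(truth_traction.t_x) * scale,
                         resamp(truth_traction.t_y) * scale)
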