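"""Elastic substrate description for the half-space traction model."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ElasticSubstrate:
    """Linearly elastic hydrogel substrate, modeled as a semi-infinite half-space.

    Parameters
    ----------
    youngs_modulus_E : float
        Young's modulus in Pa.  Polyacrylamide TFM substrates for
        cardiomyocytes are typically 10 000 Pa (healthy myocardium) or
        35 000 Pa (fibrotic myocardium).
    poisson_ratio_nu : float
        Poisson ratio, dimensionless in [0, 0.5].  Defaults to 0.5
        (incompressible polyacrylamide, the standard assumption in
        Fourier-transform traction cytometry).
    thickness_um : float
        Gel thickness in µm.  Informational: the mechanical model assumes a
        half-space, which is conventionally regarded as valid for gels at
        least 100 µm thick.
    """

    youngs_modulus_E: float
    poisson_ratio_nu: float = 0.5
    thickness_um: float = 150.0

    def __post_init__(self) -> None:
        if not self.youngs_modulus_E > 0:
            raise ValueError(f"Young's modulus must be > 0 Pa, got {self.youngs_modulus_E}")
        if not 0.0 <= self.poisson_ratio_nu <= 0.5:
            raise ValueError(f"Poisson ratio must lie in [0, 0.5], got {self.poisson_ratio_nu}")

    @property
    def half_space_valid(self) -> bool:
        """True when the gel is thick enough for the half-space assumption."""
        return self.thickness_um >= 100.0
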