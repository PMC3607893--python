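"""Mutation-rate calibration converting mutation-scaled quantities to years.

Defaults: L = 1124 analyzed sites, mu = 1.0e-7 substitutions per site per
year, generation time g = 25 years.  These give

* ``years_per_mutation`` = 1/(L*mu) ~ 8896.8 years per mutation on the
  combined control-region segments, and
* ``u_locus_gen`` = L*mu*g, the per-locus per-generation rate used for
  theta -> Ne conversion (Ne = theta / (2 u)).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RateCalibration:
    L: int = 1124
    mu_site_year: float = 1.0e-7
    generation_years: float = 25.0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.mu_site_year <= 0 or self.generation_years <= 0:
            raise ValueError("calibration parameters must be positive")

    @property
    def years_per_mutation(self) -> float:
        return 1.0 / (self.L * self.mu_site_year)

    @property
    def u_locus_gen(self) -> float:
        """Per-locus mutation rate per generation."""
        return self.L * self.mu_site_year * self.generation_years


DEFAULT_CALIBRATION = RateCalibration()
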