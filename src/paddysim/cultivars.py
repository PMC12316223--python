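"""CERES-style rice genotype coefficients and packaged cultivar sets.

The eight coefficients follow the CERES-Rice convention:

========  =============================================================
P1        thermal time of the basic vegetative (juvenile) phase (degC day)
P2O       critical photoperiod below which development is unaffected (h)
P2R       delay in degC day per hour of daylength above P2O
P5        grain-filling thermal time from beginning of grain fill (degC day)
G1        potential spikelet-number coefficient (per g of stem dry weight)
G2        single-grain weight under ideal conditions (g)
G3        tillering / relative-growth coefficient (scaler, ~1)
G4        temperature-tolerance coefficient (scaler, ~1)
========  =============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .exceptions import ConfigurationError

__all__ = ["GenotypeParams", "CULTIVARS", "PHENOLOGY_PARAMS", "GROWTH_PARAMS"]

PHENOLOGY_PARAMS = ("P1", "P2O", "P2R", "P5")
GROWTH_PARAMS = ("G1", "G2", "G3", "G4")


@dataclass(frozen=True)
class GenotypeParams:
    P1: float
    P2O: float
    P2R: float
    P5: float
    G1: float
    G2: float
    G3: float
    G4: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ConfigurationError(f"{f.name} must be strictly positive, got {v}")
        if not 0 < self.P2O < 24:
            raise ConfigurationError(f"P2O must lie in (0, 24) h, got {self.P2O}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kwargs) -> "GenotypeParams":
        d = self.as_dict()
        d.update(kwargs)
        return GenotypeParams(**d)

    @classmethod
    def from_dict(cls, d: dict) -> "GenotypeParams":
        return cls(**{k: float(d[k]) for k in (*PHENOLOGY_PARAMS, *GROWTH_PARAMS)})


#: Published coefficient sets for the three Taiwanese cultivars the analysis
#: targets: Tai-Keng 9 (GLUE-calibrated), Tainung 67 and Taichung Sen 10.
CULTIVARS: dict[str, GenotypeParams] = {
    "TK9": GenotypeParams(P1=351.7, P2O=11.2, P2R=98.5, P5=554.2, G1=61.1, G2=0.027, G3=1.20, G4=1.00),
    "TNG67": GenotypeParams(P1=520.0, P2O=11.7, P2R=100.0, P5=450.0, G1=75.0, G2=0.024, G3=1.00, G4=1.00),
    "TCS10": GenotypeParams(P1=500.0, P2O=12.0, P2R=90.0, P5=350.0, G1=70.0, G2=0.026, G3=1.00, G4=1.00),
}
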