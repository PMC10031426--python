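"""The estimand: sex-specific variance components of a quantitative trait.

All values are in squared trait units (mg^2 for beetle body mass).  The
vector covers autosomal additive variance per sex with its cross-sex
covariance, sex-specific dominance and X-linked additive variances, Y-linked
(patriline) variance for males, maternal-environment variances and residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

# canonical parameter order used for posterior draws and reports
PARAM_NAMES = [
    "VA_fa", "VA_ma", "COV_Aa",
    "VD_f", "VD_m",
    "VA_fX", "VA_mX",
    "VA_Y",
    "VME_f", "VME_m",
    "VR_f", "VR_m",
]


@dataclass
class VarianceComponents:
    VA_fa: float = 0.0   # autosomal additive, female-expressed
    VA_ma: float = 0.0   # autosomal additive, male-expressed
    COV_Aa: float = 0.0  # cross-sex autosomal additive covariance
    VD_f: float = 0.0    # dominance, female
    VD_m: float = 0.0    # dominance, male
    VA_fX: float = 0.0   # X-linked additive, female
    VA_mX: float = 0.0   # X-linked additive, male
    VA_Y: float = 0.0    # Y-linked (patriline), male only
    VME_f: float = 0.0   # maternal environment, female offspring
    VME_m: float = 0.0   # maternal environment, male offspring
    VR_f: float = 0.0    # residual, female
    VR_m: float = 0.0    # residual, male

    def __post_init__(self):
        for f in fields(self):
            v = float(getattr(self, f.name))
            if f.name != "COV_Aa" and v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")
            setattr(self, f.name, v)
        bound = np.sqrt(self.VA_fa * self.VA_ma)
        if abs(self.COV_Aa) > bound + 1e-9:
            raise ValueError("COV_Aa exceeds Cauchy-Schwarz bound")

    # -- derived quantities -----------------------------------------------------
    @property
    def VG_f(self) -> float:
        return self.VA_fa + self.VD_f + self.VA_fX

    @property
    def VG_m(self) -> float:
        return self.VA_ma + self.VD_m + self.VA_mX + self.VA_Y

    @property
    def VG(self) -> float:
        return self.VG_f + self.VG_m

    @property
    def VP_f(self) -> float:
        return self.VG_f + self.VME_f + self.VR_f

    @property
    def VP_m(self) -> float:
        return self.VG_m + self.VME_m + self.VR_m

    @property
    def r_mf(self) -> float:
        denom = np.sqrt(self.VA_fa * self.VA_ma)
        return float(self.COV_Aa / denom) if denom > 0 else np.nan

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "VarianceComponents":
        return cls(**{k: d.get(k, 0.0) for k in PARAM_NAMES})
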