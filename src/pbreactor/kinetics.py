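"""Ping Pong Bi Bi rate law for the lipase-catalysed transesterification.

The apparent specific rate of acylation of (R)-2-pentanol (CR) by vinyl
butyrate (CA) over immobilized Candida antarctica lipase B is

    r'' = Vmax * CR * CA / (KA*CR + KR*CA + CR*CA)    [mmol / g enzyme / min]

with Vmax = 4.16 mmol/g/min, KA = 51.17 mM and KR = 103.73 mM.  The law is
irreversible with no product inhibition (the vinyl alcohol by-product
tautomerises away).  The constants are named positionally — KA multiplies CR
and KR multiplies CA in the denominator; which of the two is the Michaelis
constant of which substrate is not asserted here.

``volumetric_rate`` converts the specific rate to a volumetric sink in the
reactor void volume: r''*me/(eps*V), i.e. with me in g and V in mL,
r''*me*1000/(V*eps) mM/min, divided by 60 for mM/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .geometry import ReactorSpec

__all__ = ["PingPongParams", "rate", "volumetric_rate"]


@dataclass(frozen=True)
class PingPongParams:
    vmax_mmol_g_min: float = 4.16
    ka_mM: float = 51.17   # multiplies CR in the denominator
    kr_mM: float = 103.73  # multiplies CA in the denominator

    def __post_init__(self) -> None:
        for name in ("vmax_mmol_g_min", "ka_mM", "kr_mM"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(
                    f"PingPongParams.{name} must be strictly positive, "
                    f"got {getattr(self, name)!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.vmax_mmol_g_min, self.ka_mM, self.kr_mM)


def rate(cr_mM, ca_mM, params: PingPongParams):
    """Apparent specific rate r'' in mmol/g/min; 0 when either substrate is 0.

    Accepts scalars or numpy arrays; raises on negative concentrations.
    """
    cr = np.asarray(cr_mM, dtype=float)
    ca = np.asarray(ca_mM, dtype=float)
    if np.any(cr < 0) or np.any(ca < 0):
        raise InvalidInputError("concentrations must be non-negative")
    r = _rate_clamped(cr, ca, params)
    if np.isscalar(cr_mM) and np.isscalar(ca_mM):
        return float(r)
    return r


def _rate_clamped(cr, ca, params: PingPongParams):
    """Rate with concentrations clamped at zero; safe for solver iterates."""
    cr = np.maximum(np.asarray(cr, dtype=float), 0.0)
    ca = np.maximum(np.asarray(ca, dtype=float), 0.0)
    vmax, ka, kr = params.as_tuple()
    den = ka * cr + kr * ca + cr * ca
    num = vmax * cr * ca
    return np.divide(num, den, out=np.zeros_like(den), where=den > 0)


def _rate_partials(cr, ca, params: PingPongParams):
    """(dr/dCR, dr/dCA) of the clamped rate, for Newton Jacobians.

    With D = KA*CR + KR*CA + CR*CA the closed forms are
    dr/dCR = Vmax*KR*CA^2/D^2 and dr/dCA = Vmax*KA*CR^2/D^2.
    """
    cr = np.maximum(np.asarray(cr, dtype=float), 0.0)
    ca = np.maximum(np.asarray(ca, dtype=float), 0.0)
    vmax, ka, kr = params.as_tuple()
    den = ka * cr + kr * ca + cr * ca
    den2 = den * den
    zeros = np.zeros_like(den)
    d_cr = np.divide(vmax * kr * ca * ca, den2, out=zeros.copy(), where=den > 0)
    d_ca = np.divide(vmax * ka * cr * cr, den2, out=zeros.copy(), where=den > 0)
    return d_cr, d_ca


def volumetric_rate(r_mmol_g_min, spec: ReactorSpec):
    """Volumetric consumption rate in the void volume, in mM/s.

    R = r'' * me / (eps * V * 60) with SI me (kg) and V (m3); equivalently
    r''[mmol/g/min] * me[g] * 1000 / (V[mL] * eps) mM/min divided by 60.
    """
    r = np.asarray(r_mmol_g_min, dtype=float)
    out = r * spec.enzyme_mass_kg / (spec.volume_m3 * spec.void_fraction * 60.0)
    if np.isscalar(r_mmol_g_min):
        return float(out)
    return out
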