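"""Performance metrics: conversion, enantiomeric excess, productivity.

Conversion on the racemate basis,

    c% = (1 - (CS + CR)/(CS0 + CR0)) * 100,

substrate enantiomeric excess,

    eeS% = (CS - CR)/(CS + CR) * 100,

continuous productivity P = CP*Q/me (mmol of ester per g enzyme per minute,
with CP in mmol/L and Q in L/min) and batch productivity P = n/(t*me).

For an equimolar racemate with an inert slow enantiomer (CS = CS0 = CR0) the
two metrics are tied by eeS = c/(1 - c) in fractional form.  Kinetic
resolution caps the useful racemate-basis conversion at 50%; a per-fast-
enantiomer basis (1 - CR/CR0) is also provided because a statement like
"50% conversion" can be read on either basis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError
from .model import AxialProfile, OperatingPoint

__all__ = [
    "BatchRun",
    "OutletState",
    "outlet_state",
    "conversion",
    "conversion_fast_enantiomer",
    "enantiomeric_excess",
    "productivity_continuous",
    "productivity_batch",
]


@dataclass(frozen=True)
class BatchRun:
    """A reference batch experiment: product amount, time, enzyme load."""

    product_mmol: float
    time_min: float
    enzyme_mass_g: float

    def __post_init__(self) -> None:
        if self.product_mmol < 0:
            raise InvalidInputError(
                f"product_mmol must be >= 0, got {self.product_mmol!r}")
        if not self.time_min > 0:
            raise InvalidInputError(f"time_min must be positive, got {self.time_min!r}")
        if not self.enzyme_mass_g > 0:
            raise InvalidInputError(
                f"enzyme_mass_g must be positive, got {self.enzyme_mass_g!r}")


@dataclass(frozen=True)
class OutletState:
    """Outlet concentrations referenced to the inlet of the same run."""

    cr_mM: float
    cs_mM: float
    ca_mM: float
    cp_mM: float
    cr0_mM: float
    cs0_mM: float
    flow_mL_min: float

    def __post_init__(self) -> None:
        for name in ("cr_mM", "cs_mM", "ca_mM", "cp_mM", "cr0_mM", "cs0_mM"):
            if getattr(self, name) < 0:
                raise InvalidInputError(
                    f"OutletState.{name} must be >= 0, got {getattr(self, name)!r}")
        if not self.flow_mL_min > 0:
            raise InvalidInputError(
                f"flow_mL_min must be positive, got {self.flow_mL_min!r}")
        if self.cr_mM > self.cr0_mM + 1e-9 * max(self.cr0_mM, 1.0):
            raise InvalidInputError(
                f"outlet CR = {self.cr_mM!r} exceeds inlet CR0 = {self.cr0_mM!r}")


def outlet_state(profile: AxialProfile, op: OperatingPoint) -> OutletState:
    """Outlet state of a solved profile; CP = CR0 - CR by 1:1 stoichiometry."""
    cr = profile.outlet_cr_mM
    return OutletState(cr_mM=cr, cs_mM=profile.outlet_cs_mM,
                       ca_mM=profile.outlet_ca_mM,
                       cp_mM=max(op.cr0_mM - cr, 0.0),
                       cr0_mM=op.cr0_mM, cs0_mM=op.cs0_mM,
                       flow_mL_min=op.flow_mL_min)


def conversion(out: OutletState) -> float:
    """Racemate-basis conversion c% = (1 - (CS + CR)/(CS0 + CR0)) * 100."""
    total0 = out.cs0_mM + out.cr0_mM
    if not total0 > 0:
        raise InvalidInputError("conversion undefined for zero total inlet "
                                "substrate (CS0 + CR0 = 0)")
    return (1.0 - (out.cs_mM + out.cr_mM) / total0) * 100.0


def conversion_fast_enantiomer(out: OutletState) -> float:
    """Per-fast-enantiomer conversion (1 - CR/CR0) * 100."""
    if not out.cr0_mM > 0:
        raise InvalidInputError("fast-enantiomer conversion undefined for CR0 = 0")
    return (1.0 - out.cr_mM / out.cr0_mM) * 100.0


def enantiomeric_excess(out: OutletState) -> float:
    """Substrate enantiomeric excess eeS% = (CS - CR)/(CS + CR) * 100."""
    total = out.cs_mM + out.cr_mM
    if not total > 0:
        raise InvalidInputError("eeS undefined when CS + CR = 0 at the outlet")
    return (out.cs_mM - out.cr_mM) / total * 100.0


def productivity_continuous(out: OutletState, enzyme_mass_g: float) -> float:
    """Continuous productivity P = CP*Q/me in mmol/(min g enzyme)."""
    if not enzyme_mass_g > 0:
        raise InvalidInputError(
            f"enzyme_mass_g must be positive, got {enzyme_mass_g!r}")
    flow_L_min = out.flow_mL_min / 1000.0
    return out.cp_mM * flow_L_min / enzyme_mass_g


def productivity_batch(run: BatchRun) -> float:
    """Batch productivity P = n/(t*me) in mmol/(min g enzyme)."""
    return run.product_mmol / (run.time_min * run.enzyme_mass_g)
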