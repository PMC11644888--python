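"""Closed-form forward model of the electrode-eye capacitor and LC resonance.

A copper-foil electrode on an eyeglass lens forms one plate of a parallel-plate
capacitor; the effective ground plane behind the head is the other. The stack
of dielectrics between the plates differs between an open and a closed eye:
with the eye closed the eyelid (mostly water, relative permittivity near 100)
sits in the gap, raising the sensed capacitance ``Cx`` and therefore lowering
the resonance frequency of the LC tank it is wired into,

    f_x = 1 / (2 pi sqrt(L (C + Cx))).

A blink is thus a transient *dip* in the resonance frequency; this module is
both the unit-level physics reference and the signal-level ground truth used
by :mod:`capblink.synth`.

All quantities are SI (metres, farads, henries, hertz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ELECTROSTATIC_K",
    "CircuitParams",
    "EyeDielectricModel",
    "CapacitancePair",
    "resonance_frequency",
    "capacitance_closed",
    "capacitance_open",
    "capacitance_ratio",
    "capacitance_pair",
    "frequency_pair",
]

#: Coulomb constant 1/(4 pi eps0), N m^2 / C^2.
ELECTROSTATIC_K = 8.99e9


@dataclass(frozen=True)
class CircuitParams:
    """LC tank of the capacitance-to-frequency front end.

    Parameters
    ----------
    inductance:
        Tank inductance L in henries. Must be positive.
    capacitance:
        Fixed tank capacitance C in farads, in parallel with the sensed
        electrode capacitance. Must be non-negative.
    """

    inductance: float = 18e-6
    capacitance: float = 33e-12

    def __post_init__(self) -> None:
        if not self.inductance > 0:
            raise ValueError(f"inductance must be > 0, got {self.inductance}")
        if self.capacitance < 0:
            raise ValueError(f"capacitance must be >= 0, got {self.capacitance}")


@dataclass(frozen=True)
class EyeDielectricModel:
    """Three-layer dielectric stack between the electrode and the ground plate.

    Layer 1 is the air gap between electrode and eyelid, layer 2 the eyelid
    itself (present only when the eye is closed), layer 3 everything behind it.
    Defaults: air gap 5 mm, eyelid 1 mm, tissue 50 mm, plate area 25 mm x 8 mm
    (the electrode dimensions), eyelid/tissue permittivity 100 (water-like).
    """

    eps_air: float = 1.0
    eps_lid: float = 100.0
    eps_tissue: float = 100.0
    d_air: float = 5e-3
    d_lid: float = 1e-3
    d_tissue: float = 50e-3
    plate_area: float = 25e-3 * 8e-3
    k: float = ELECTROSTATIC_K

    def __post_init__(self) -> None:
        for name in ("eps_air", "eps_lid", "eps_tissue"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("d_air", "d_lid", "d_tissue", "plate_area", "k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def eps(self) -> tuple[float, float, float]:
        return (self.eps_air, self.eps_lid, self.eps_tissue)

    @property
    def d(self) -> tuple[float, float, float]:
        return (self.d_air, self.d_lid, self.d_tissue)


@dataclass(frozen=True)
class CapacitancePair:
    """Sensed capacitance with the eye closed and open, in farads."""

    cx_closed: float
    cx_open: float

    def __post_init__(self) -> None:
        if not (self.cx_closed > 0 and self.cx_open > 0):
            raise ValueError("capacitances must be positive")


def resonance_frequency(circuit: CircuitParams, cx: float) -> float:
    """Resonance frequency in Hz of the LC tank loaded with sensed capacitance ``cx``.

    Strictly decreasing in ``cx``: a rise in capacitance (eye closing) lowers
    the frequency.
    """
    total_c = circuit.capacitance + cx
    if total_c <= 0:
        raise ValueError(f"C + cx must be > 0, got {total_c}")
    return 1.0 / (2.0 * math.pi * math.sqrt(circuit.inductance * total_c))


def capacitance_closed(model: EyeDielectricModel) -> float:
    """Closed-eye capacitance: air, eyelid and tissue layers in series."""
    gap = (
        model.d_air / model.eps_air
        + model.d_lid / model.eps_lid
        + model.d_tissue / model.eps_tissue
    )
    return model.plate_area / (4.0 * math.pi * model.k * gap)


def capacitance_open(model: EyeDielectricModel) -> float:
    """Open-eye capacitance: the eyelid retracts and air fills its place."""
    gap = (model.d_air + model.d_lid) / model.eps_air + model.d_tissue / model.eps_tissue
    return model.plate_area / (4.0 * math.pi * model.k * gap)


def capacitance_ratio(model: EyeDielectricModel) -> float:
    """Closed/open capacitance ratio; >= 1 whenever the eyelid is the denser dielectric.

    Equals the quotient of effective gaps,
    ``((d1 + d2)/eps1 + d3/eps3) / (d1/eps1 + d2/eps2 + d3/eps3)``.
    """
    num = (model.d_air + model.d_lid) / model.eps_air + model.d_tissue / model.eps_tissue
    den = (
        model.d_air / model.eps_air
        + model.d_lid / model.eps_lid
        + model.d_tissue / model.eps_tissue
    )
    return num / den


def capacitance_pair(model: EyeDielectricModel) -> CapacitancePair:
    """Both sensed capacitances for one dielectric model."""
    return CapacitancePair(
        cx_closed=capacitance_closed(model), cx_open=capacitance_open(model)
    )


def frequency_pair(circuit: CircuitParams, model: EyeDielectricModel) -> tuple[float, float]:
    """(open-eye frequency, closed-eye frequency) in Hz; open > closed for eps_lid > eps_air."""
    pair = capacitance_pair(model)
    return (
        resonance_frequency(circuit, pair.cx_open),
        resonance_frequency(circuit, pair.cx_closed),
    )
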