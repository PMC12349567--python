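"""Wheatstone-bridge model of a strain-gauge load cell.

Four strain gauges of nominal resistance R are wired in a full bridge and
excited with V_in. Deformation of the beam changes each gauge's resistance
by dR_i; the bridge converts those changes into a differential output
voltage. In the usual symmetric configuration two gauges elongate and two
compress by the same amount (dR2 = dR3 = +dR, dR1 = dR4 = -dR), for which
the exact quotient expression collapses to the linear small-signal form
V_out = (dR / R) * V_in.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidSpecError

# |dR|/R beyond this leaves the small-deformation regime the linear
# approximation (and the gauge itself) is designed for.
SMALL_DEFORMATION_LIMIT = 0.05


@dataclass(frozen=True)
class BridgeSpec:
    """Electrical state of one strain-gauge bridge.

    Parameters
    ----------
    nominal_resistance : float
        Unstrained gauge resistance R in ohms.
    delta_r : tuple of 4 floats
        Resistance changes (dR1, dR2, dR3, dR4) in ohms.
    excitation : float
        Excitation voltage V_in in volts.
    """

    nominal_resistance: float
    delta_r: tuple[float, float, float, float]
    excitation: float

    def __post_init__(self) -> None:
        if self.nominal_resistance <= 0:
            raise InvalidSpecError("nominal resistance must be positive")
        if self.excitation <= 0:
            raise InvalidSpecError("excitation voltage must be positive")
        if len(self.delta_r) != 4:
            raise InvalidSpecError("exactly four gauge resistance changes required")
        for dr in self.delta_r:
            if abs(dr) >= self.nominal_resistance:
                raise InvalidSpecError(
                    "|dR| must stay below the nominal resistance"
                )

    @property
    def is_small_deformation(self) -> bool:
        """True while every gauge stays within the small-deformation regime."""
        return all(
            abs(dr) / self.nominal_resistance <= SMALL_DEFORMATION_LIMIT
            for dr in self.delta_r
        )

    @classmethod
    def symmetric(
        cls, nominal_resistance: float, delta: float, excitation: float
    ) -> "BridgeSpec":
        """Symmetric full-bridge state: dR2 = dR3 = +delta, dR1 = dR4 = -delta."""
        return cls(nominal_resistance, (-delta, delta, delta, -delta), excitation)


def bridge_output_exact(spec: BridgeSpec) -> float:
    """Exact bridge output voltage from the full quotient expression.

    V_out = [ (R+dR2)/((R+dR1)+(R+dR2)) - (R+dR4)/((R+dR3)+(R+dR4)) ] * V_in
    """
    r = spec.nominal_resistance
    d1, d2, d3, d4 = spec.delta_r
    left = (r + d2) / ((r + d1) + (r + d2))
    right = (r + d4) / ((r + d3) + (r + d4))
    return (left - right) * spec.excitation


def bridge_output_linear(spec: BridgeSpec) -> float:
    """Small-signal approximation V_out = (dR / R) * V_in.

    Assumes the symmetric configuration dR2 = dR3 = dR, dR1 = dR4 = -dR;
    ``delta_r[1]`` is taken as dR. For symmetric specs both bridge arms
    have denominator 2R and this equals :func:`bridge_output_exact` exactly.
    """
    dr = spec.delta_r[1]
    return dr / spec.nominal_resistance * spec.excitation
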