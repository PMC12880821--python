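"""Polarimetric sign and angle conventions.

The raw data never disambiguate these on their own: the handedness of S3
depends on whether circular polarization is named from the receiver's or the
source's point of view, and the microgrid analyzer angles and the quarter-wave
plate fast-axis angle each need a stated reference axis.  A single
:class:`PolarimetricConvention` is fixed per run and recorded in every output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from enum import Enum


class Handedness(str, Enum):
    """Reference point for circular-polarization handedness.

    ``from_receiver``: S3 > 0 means right-handed as seen looking toward the
    source (against propagation) -- the common optics convention.
    ``from_source``: right-handed as seen looking along propagation.
    The two differ by a sign flip of S2 and S3.
    """

    FROM_RECEIVER = "from_receiver"
    FROM_SOURCE = "from_source"


@dataclass(frozen=True)
class PolarimetricConvention:
    """Immutable record of the sign/angle conventions in force for a run.

    Parameters
    ----------
    handedness:
        Viewpoint defining the sign of S3. Default receiver-referenced;
        S3 > 0 means a preponderance of right-handed circular polarization.
    polarizer_angle_reference:
        Axis from which the 0/45/90/135 degree microgrid analyzer angles are
        measured. Default the horizontal image axis.
    qwp_angle_reference:
        Axis from which the quarter-wave-plate fast-axis angle theta is
        measured. Default vertical (theta = 0 means fast axis vertical).
    """

    handedness: Handedness = Handedness.FROM_RECEIVER
    polarizer_angle_reference: str = "horizontal"
    qwp_angle_reference: str = "vertical"

    def __post_init__(self) -> None:
        if not isinstance(self.handedness, Handedness):
            object.__setattr__(self, "handedness", Handedness(self.handedness))
        if self.polarizer_angle_reference not in ("horizontal", "vertical"):
            raise ValueError(
                f"unknown polarizer_angle_reference "
                f"{self.polarizer_angle_reference!r}"
            )
        if self.qwp_angle_reference not in ("horizontal", "vertical"):
            raise ValueError(
                f"unknown qwp_angle_reference {self.qwp_angle_reference!r}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["handedness"] = self.handedness.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PolarimetricConvention":
        return cls(**d)


#: The one global default; never mixed within a run.
DEFAULT_CONVENTION = PolarimetricConvention()
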