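"""Tissue electrical properties for the layered thigh volume conductor.

Conductivities are the 2 kHz quasistatic values for the tissues of a human
thigh (skin, subcutaneous fat, skeletal muscle, cortical bone, bone marrow,
blood, peripheral nerve).  A single real conductivity per tissue is used —
the quasistatic approximation neglects dispersion, with the 2 kHz value
standing in for the square-pulse spectrum.  Muscle is anisotropic: fibres
run along the limb axis (z), so the longitudinal conductivity applies along
z and the transverse value in the cross-sectional plane.  All other tissues
are isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ConductivityTensor", "conductivity_of", "TISSUES"]


@dataclass(frozen=True)
class ConductivityTensor:
    """Axisymmetric conductivity, in mS/m.

    ``transverse`` applies in the plane perpendicular to the limb axis,
    ``longitudinal`` along the limb (z) axis.
    """

    transverse: float
    longitudinal: float

    def __post_init__(self) -> None:
        if not (self.transverse > 0.0 and self.longitudinal > 0.0):
            raise ValueError(
                f"conductivity components must be strictly positive, got "
                f"({self.transverse}, {self.longitudinal}) mS/m"
            )

    @property
    def isotropic(self) -> bool:
        return self.transverse == self.longitudinal

    @property
    def si(self) -> tuple[float, float]:
        """(transverse, longitudinal) in S/m."""
        return (self.transverse * 1e-3, self.longitudinal * 1e-3)

    @staticmethod
    def iso(value_mS_per_m: float) -> "ConductivityTensor":
        return ConductivityTensor(value_mS_per_m, value_mS_per_m)


#: 2 kHz tissue conductivities, mS/m.
TISSUES: dict[str, ConductivityTensor] = {
    "skin": ConductivityTensor.iso(0.790),
    "fat": ConductivityTensor.iso(42.27),
    "muscle": ConductivityTensor(transverse=82.38, longitudinal=329.53),
    "cortical_bone": ConductivityTensor.iso(20.24),
    "bone_marrow": ConductivityTensor.iso(101.93),
    "blood": ConductivityTensor.iso(700.0),
    "nerve": ConductivityTensor.iso(29.89),
}


def conductivity_of(name: str) -> ConductivityTensor:
    """Look up the conductivity tensor for a tissue label.

    Parameters
    ----------
    name
        One of ``skin, fat, muscle, cortical_bone, bone_marrow, blood, nerve``.
    """
    try:
        return TISSUES[name]
    except KeyError:
        raise KeyError(
            f"unknown tissue label {name!r}; expected one of {sorted(TISSUES)}"
        ) from None
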