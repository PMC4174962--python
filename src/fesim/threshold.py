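"""Activation-threshold search by bisection over stimulus amplitude.

Because the volume-conduction problem is linear, the extracellular profile
for any stimulus amplitude is a scalar multiple of the unit lead field, so
one field solve per geometry suffices; the bisection rescales the profile
inside the fibre simulation.  The bracket is refined until its width is at
most 10 μA and the reported threshold is the final bracket midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiber import FiberModel, StimulusWaveform, simulate_response

__all__ = [
    "ThresholdResult",
    "find_threshold",
    "activation_monotonicity_check",
    "NonMonotoneActivationError",
]

#: Amplitude search range, mA.
DEFAULT_BRACKET_MA = (5.0, 500.0)
#: Final bracket width, mA (10 μA).
DEFAULT_TOL_MA = 0.01
#: One downward extension applied before flagging out-of-range-low, mA.
EXTENDED_LOW_MA = 0.1


class NonMonotoneActivationError(RuntimeError):
    """Activation is not monotone in amplitude; bisection is invalid."""


@dataclass
class ThresholdResult:
    """Activation threshold with its bracket and search provenance."""

    threshold_mA: float | None
    bracket_mA: tuple[float, float] | None
    n_bisections: int
    n_fiber_sims: int
    out_of_range: str | None = None  # None | "low" | "high"
    context: dict = field(default_factory=dict)

    @property
    def in_range(self) -> bool:
        return self.out_of_range is None


def find_threshold(
    unit_profile_V_per_A: np.ndarray | None,
    fiber: FiberModel | None,
    waveform: StimulusWaveform,
    bracket_mA: tuple[float, float] = DEFAULT_BRACKET_MA,
    tol_mA: float = DEFAULT_TOL_MA,
    predicate=None,
    dt_ms: float = 2e-3,
    context: dict | None = None,
) -> ThresholdResult:
    """Bisection for the lowest amplitude that elicits a propagating spike.

    ``predicate(amplitude_mA) -> bool`` may replace the fibre simulation
    (used for search-logic verification); otherwise each probe simulates the
    cable response to ``amplitude × unit_profile``.  Results outside the
    bracket are flagged, never clamped; before flagging out-of-range-low the
    bracket is extended downward once to 0.1 mA.
    """
    sims = {"n": 0}
    if predicate is None:
        if unit_profile_V_per_A is None or fiber is None:
            raise ValueError("need a unit profile and fibre when no predicate is given")

        def predicate(amp_mA: float) -> bool:
            sims["n"] += 1
            trace = simulate_response(
                fiber, unit_profile_V_per_A, waveform.with_amplitude(amp_mA),
                dt_ms=dt_ms,
            )
            return trace.activated

    lo, hi = bracket_mA
    ctx = dict(context or {})
    if not predicate(hi):
        return ThresholdResult(None, None, 0, sims["n"], out_of_range="high",
                               context=ctx)
    if predicate(lo):
        lo_ext = EXTENDED_LOW_MA
        if predicate(lo_ext):
            return ThresholdResult(None, None, 0, sims["n"], out_of_range="low",
                                   context=ctx)
        hi, lo = lo, lo_ext
    n_bis = 0
    while hi - lo > tol_mA:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
        n_bis += 1
    return ThresholdResult(
        threshold_mA=0.5 * (lo + hi),
        bracket_mA=(lo, hi),
        n_bisections=n_bis,
        n_fiber_sims=sims["n"],
        context=ctx,
    )


def activation_monotonicity_check(
    unit_profile_V_per_A,
    fiber,
    waveform: StimulusWaveform,
    amplitudes_mA,
    predicate=None,
) -> list[bool]:
    """Evaluate activation at ascending amplitudes and verify monotonicity.

    Returns the flags; raises :class:`NonMonotoneActivationError` if an
    activated amplitude is followed by a non-activated one, in which case
    bisection would be unreliable for this configuration.
    """
    amps = list(amplitudes_mA)
    if any(a2 <= a1 for a1, a2 in zip(amps, amps[1:])):
        raise ValueError("amplitudes must be sorted ascending")
    if predicate is None:
        def predicate(amp_mA: float) -> bool:
            return simulate_response(
                fiber, unit_profile_V_per_A, waveform.with_amplitude(amp_mA)
            ).activated

    flags = [bool(predicate(a)) for a in amps]
    seen_true = False
    for a, f in zip(amps, flags):
        if seen_true and not f:
            raise NonMonotoneActivationError(
                f"activation lost at {a} mA after activating at a lower "
                f"amplitude; flags={flags}"
            )
        seen_true = seen_true or f
    return flags
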