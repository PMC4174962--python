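"""Myelinated-fibre compartment model (McNeal cable, CRRSS nodal kinetics).

The fibre is a chain of Ranvier nodes connected by myelinated internodes.
By default the myelin is a perfect insulator, so only the nodes carry
membrane current and the cable reduces to the classic nodal form

    C dV_n/dt = G_a (V_{n-1} - 2 V_n + V_{n+1}
                     + Ve_{n-1} - 2 Ve_n + Ve_{n+1}) - I_ion,n ,

where G_a is the internodal axial conductance and the extracellular
potentials Ve sampled at the nodes drive the membrane through their second
spatial difference.  An optional variant represents each internode by
passive compartments with a small constant membrane conductance.

Nodal ionic currents follow the Chiu–Ritchie–Rogart–Stagg–Sweeney (CRRSS)
description of the mammalian node at body temperature: a fast sodium
conductance gated by m²h plus a linear leak.  All membrane potentials are
expressed as deviations from rest (mV); the leak reversal is calibrated so
that V = 0 is an exact equilibrium of the adopted constants.

Constants (37 °C, Sweeney–Mortimer–Durand fit of the CRRSS data):
g_Na = 1445 mS/cm², g_L = 128 mS/cm², E_Na = +115.5 mV above rest,
c_node = 2.5 μF/cm², axoplasmic resistivity 54.7 Ω·cm, rest −80 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "FiberModel",
    "MembraneState",
    "StimulusWaveform",
    "SimulationTrace",
    "build_fiber",
    "crrss_rates",
    "crrss_steady_state",
    "simulate_response",
    "detect_activation",
    "node_positions_m",
    "ACTIVATION_THRESHOLD_MV",
    "PROPAGATION_GUARD_INTERNODES",
]

#: Transmembrane depolarization (above rest) that defines an action potential, mV.
ACTIVATION_THRESHOLD_MV = 80.0

#: Minimum distance (in internodes) from the end-of-pulse depolarization peak
#: at which a crossing counts as a propagating action potential.
PROPAGATION_GUARD_INTERNODES = 5


@dataclass(frozen=True)
class FiberModel:
    """Geometry and membrane constants of one straight myelinated fibre."""

    diameter_um: float
    length_mm: float
    node_count: int
    internode_length_mm: float
    axon_diameter_um: float
    node_length_um: float = 1.5
    rho_axoplasm_ohm_cm: float = 54.7
    c_node_uF_cm2: float = 2.5
    g_na_mS_cm2: float = 1445.0
    g_leak_mS_cm2: float = 128.0
    e_na_mV: float = 115.5
    resting_potential_mV: float = -80.0
    passive_internodes: bool = False
    internode_segments: int = 10
    g_myelin_mS_cm2: float = 0.01
    c_myelin_uF_cm2: float = 0.005

    def __post_init__(self) -> None:
        if self.node_count < 11:
            raise ValueError(
                f"fibre needs at least 11 nodes for propagation detection, "
                f"got {self.node_count}"
            )
        if self.node_count % 2 == 0:
            raise ValueError("node count must be odd (one node at the midpoint)")

    # -- derived SI quantities -------------------------------------------
    @property
    def node_area_m2(self) -> float:
        return math.pi * self.axon_diameter_um * 1e-6 * self.node_length_um * 1e-6

    @property
    def axial_conductance_S(self) -> float:
        """Internodal axial conductance G_a."""
        d = self.axon_diameter_um * 1e-6
        rho = self.rho_axoplasm_ohm_cm * 1e-2  # Ω·m
        return math.pi * d * d / (4.0 * rho * self.internode_length_mm * 1e-3)

    @property
    def node_capacitance_F(self) -> float:
        return self.c_node_uF_cm2 * 1e-2 * self.node_area_m2  # μF/cm² → F/m²

    @property
    def e_leak_mV(self) -> float:
        """Leak reversal calibrated so V = 0 is an exact resting equilibrium."""
        m0, h0 = crrss_steady_state(0.0)
        return -(self.g_na_mS_cm2 / self.g_leak_mS_cm2) * m0 * m0 * h0 * self.e_na_mV


@dataclass
class MembraneState:
    """Nodal state: V (mV above rest), sodium gates m, h, time (ms)."""

    V: np.ndarray
    m: np.ndarray
    h: np.ndarray
    t: float = 0.0


@dataclass(frozen=True)
class StimulusWaveform:
    """Square current pulse; amplitude is carried as a magnitude (mA) with
    the polarity separate (cathodic: negative potential under the proximal
    electrode)."""

    amplitude_mA: float = 0.0
    pulse_width_ms: float = 0.5
    total_duration_ms: float = 2.0
    polarity: str = "cathodic"
    shape: str = "square"

    def __post_init__(self) -> None:
        if self.pulse_width_ms <= 0.0:
            raise ValueError("pulse width must be > 0")
        if self.amplitude_mA < 0.0:
            raise ValueError("amplitude is a magnitude; polarity is separate")
        if self.polarity not in ("cathodic", "anodic"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.shape != "square":
            raise ValueError("only square pulses are supported")

    def with_amplitude(self, amplitude_mA: float) -> "StimulusWaveform":
        return replace(self, amplitude_mA=amplitude_mA)


@dataclass
class SimulationTrace:
    """Time course of the nodal membrane response."""

    times_ms: np.ndarray
    V_mV: np.ndarray  # (n_times, n_nodes), deviation from rest
    pulse_width_ms: float
    internode_length_mm: float
    activated: bool = False
    activation_node: int | None = None
    activation_time_ms: float | None = None
    conduction_latency_ms: float | None = None
    first_crossing_ms: np.ndarray | None = None


def crrss_rates(V):
    """CRRSS gate rate constants (α_m, β_m, α_h, β_h) in 1/ms.

    V is the membrane potential in mV above rest.  The fit is the 37 °C
    mammalian-node parameterization; all four rates are positive and finite
    for finite V.
    """
    V = np.asarray(V, dtype=float)
    alpha_m = (97.0 + 0.363 * V) / (1.0 + np.exp((31.8 - V) / 4.17))
    beta_m = alpha_m * np.exp((23.8 - V) / 4.17)
    beta_h = 15.6 / (1.0 + np.exp((24.0 - V) / 10.0))
    alpha_h = beta_h * np.exp((5.5 - V) / 5.0)
    # α_m changes sign at V ≈ −267 mV, far outside the physiological range;
    # clip to keep the rates positive as total functions.
    alpha_m = np.maximum(alpha_m, 1e-9)
    beta_m = np.maximum(beta_m, 1e-9)
    return alpha_m, beta_m, alpha_h, beta_h


def crrss_steady_state(V):
    """Steady-state gate values (m_inf, h_inf) at potential V (mV above rest)."""
    am, bm, ah, bh = crrss_rates(V)
    return am / (am + bm), ah / (ah + bh)


def build_fiber(diameter_um: float, length_mm: float = 63.0, **overrides) -> FiberModel:
    """Construct a fibre from its outer diameter.

    Standard myelinated-fibre ratios: internode length 100 × diameter, axon
    diameter 0.7 × diameter, node length 1.5 μm.  The node count is the
    largest odd integer whose span (node_count − 1) × internode fits in the
    stated length, so one node sits exactly at the fibre midpoint.
    """
    if diameter_um <= 0.0 or length_mm <= 0.0:
        raise ValueError("diameter and length must be > 0")
    internode_mm = 100.0 * diameter_um * 1e-3
    n = int(math.floor(length_mm / internode_mm + 1e-9)) + 1
    if n % 2 == 0:
        n -= 1
    if n < 11:
        raise ValueError(
            f"{diameter_um} μm fibre of {length_mm} mm has only {n} nodes; "
            "the cable is too short for propagation detection"
        )
    return FiberModel(
        diameter_um=diameter_um,
        length_mm=length_mm,
        node_count=n,
        internode_length_mm=internode_mm,
        axon_diameter_um=0.7 * diameter_um,
        **overrides,
    )


def node_positions_m(model, placement, electrodes, fiber: FiberModel) -> np.ndarray:
    """3-D positions of the Ranvier nodes (metres), midpoint node under the
    cathode patch centre.  The node chain must lie inside the muscle."""
    from .geometry import fiber_axis_xy

    x, y = fiber_axis_xy(model, placement, electrodes)
    n = fiber.node_count
    z_c = electrodes.cathode_center_z_cm * 1e-2
    z = z_c + (np.arange(n) - (n - 1) / 2.0) * fiber.internode_length_mm * 1e-3
    pts = np.column_stack([np.full(n, x), np.full(n, y), z])
    labels = model.tissue_at(pts)
    bad = np.nonzero(labels != "muscle")[0]
    if bad.size:
        raise ValueError(
            f"fibre node {bad[0]} leaves the muscle domain "
            f"(tissue {labels[bad[0]]!r} at depth {placement.depth_mm} mm)"
        )
    return pts


# ---------------------------------------------------------------------------
# cable integration
# ---------------------------------------------------------------------------


def _compartment_chain(fiber: FiberModel, node_profile_mV: np.ndarray):
    """Compartment arrays: (is_node mask, C (F), axial G (S) between
    neighbours, Ve per compartment per unit waveform amplitude (mV))."""
    n = fiber.node_count
    if not fiber.passive_internodes:
        C = np.full(n, fiber.node_capacitance_F)
        Ga = np.full(n - 1, fiber.axial_conductance_S)
        return np.ones(n, dtype=bool), C, Ga, np.asarray(node_profile_mV, float)
    s = fiber.internode_segments
    total = n + (n - 1) * s
    is_node = np.zeros(total, dtype=bool)
    is_node[::s + 1] = True
    d = fiber.axon_diameter_um * 1e-6
    rho = fiber.rho_axoplasm_ohm_cm * 1e-2
    seg_len = fiber.internode_length_mm * 1e-3 / s
    area_seg = math.pi * d * seg_len
    C = np.where(is_node, fiber.node_capacitance_F,
                 fiber.c_myelin_uF_cm2 * 1e-2 * area_seg)
    # distances between adjacent compartment centres
    dist = np.full(total - 1, seg_len)
    dist[::s + 1] = seg_len / 2.0  # node ↔ first segment
    dist[s::s + 1] = seg_len / 2.0  # last segment ↔ node
    Ga = math.pi * d * d / (4.0 * rho * dist)
    # linear interpolation of the nodal extracellular profile
    xi = np.arange(total) / (s + 1)
    Ve = np.interp(xi, np.arange(n), node_profile_mV)
    return is_node, C, Ga, Ve


def simulate_response(
    fiber: FiberModel,
    extracellular_profile_V_per_A: np.ndarray,
    waveform: StimulusWaveform,
    dt_ms: float = 2e-3,
) -> SimulationTrace:
    """Integrate the cable response to the extracellular potential profile.

    ``extracellular_profile_V_per_A`` holds the lead-field potential at each
    Ranvier node for +1 A driven anode→cathode (cathodic configuration);
    multiplying by the stimulus amplitude in mA gives the nodal potential in
    mV.  Integration is semi-implicit: gates advance by exact exponential
    update at the current potential, then the linear-in-V system is solved
    implicitly (banded), which is stable at the stiff nodal kinetics.
    """
    profile = np.asarray(extracellular_profile_V_per_A, dtype=float)
    if profile.shape != (fiber.node_count,):
        raise ValueError(
            f"profile length {profile.shape} does not match node count "
            f"{fiber.node_count}"
        )
    sign = 1.0 if waveform.polarity == "cathodic" else -1.0
    node_ve_mV = sign * waveform.amplitude_mA * profile  # mA × V/A = mV
    is_node, C, Ga, Ve_on = _compartment_chain(fiber, node_ve_mV)
    ncomp = len(C)
    n_steps = int(round(waveform.total_duration_ms / dt_ms))
    pulse_steps = int(round(waveform.pulse_width_ms / dt_ms))

    # unit bookkeeping: V in mV, t in ms, C in F, G in S  →  C dV/dt has
    # units F·mV/ms = A·1e0... using (C/dt)[F/ms] with G[S] keeps every term
    # in S·mV = mA·1e-3; consistent throughout, so no scaling is needed.
    area = np.where(is_node, fiber.node_area_m2, 0.0)
    if fiber.passive_internodes:
        s = fiber.internode_segments
        d = fiber.axon_diameter_um * 1e-6
        seg_len = fiber.internode_length_mm * 1e-3 / s
        area_my = math.pi * d * seg_len
        g_my = fiber.g_myelin_mS_cm2 * 10.0  # mS/cm² → S/m²
        g_passive = np.where(is_node, 0.0, g_my * area_my)
    else:
        g_passive = np.zeros(ncomp)
    g_na = fiber.g_na_mS_cm2 * 10.0 * area  # S at each node
    g_l = fiber.g_leak_mS_cm2 * 10.0 * area
    e_l = fiber.e_leak_mV

    # banded Laplacian of axial conductances (sealed ends)
    diag_l = np.zeros(ncomp)
    diag_l[:-1] += Ga
    diag_l[1:] += Ga

    V = np.zeros(ncomp)
    m0, h0 = crrss_steady_state(0.0)
    m = np.full(fiber.node_count, m0)
    h = np.full(fiber.node_count, h0)
    c_dt = C / dt_ms

    n_nodes = fiber.node_count
    times = np.arange(n_steps + 1) * dt_ms
    V_rec = np.zeros((n_steps + 1, n_nodes))
    ab = np.zeros((3, ncomp))
    node_idx = np.nonzero(is_node)[0]

    for step in range(1, n_steps + 1):
        Ve = Ve_on if step <= pulse_steps else np.zeros(ncomp)
        # exact exponential gate update at the current nodal potential
        Vn = V[node_idx]
        am, bm, ah, bh = crrss_rates(Vn)
        m = _gate_step(m, am, bm, dt_ms)
        h = _gate_step(h, ah, bh, dt_ms)
        g_ion = g_passive.copy()
        ge = g_passive * 0.0
        gna_eff = g_na[node_idx] * m * m * h
        g_ion[node_idx] = gna_eff + g_l[node_idx]
        ge_arr = np.zeros(ncomp)
        ge_arr[node_idx] = gna_eff * fiber.e_na_mV + g_l[node_idx] * e_l
        # implicit solve: (C/dt + g_ion + L) V_new = C/dt V_old + L_off(Ve) + ge
        rhs = c_dt * V + ge_arr + _laplacian(Ve, Ga)
        ab[0, 1:] = -Ga
        ab[1] = c_dt + g_ion + diag_l
        ab[2, :-1] = -Ga
        V = solve_banded((1, 1), ab, rhs, overwrite_ab=True, overwrite_b=True)
        if not np.all(np.isfinite(V)):
            raise FloatingPointError(
                f"cable integration diverged at t = {step * dt_ms:.3f} ms"
            )
        V_rec[step] = V[node_idx]

    trace = SimulationTrace(
        times_ms=times,
        V_mV=V_rec,
        pulse_width_ms=waveform.pulse_width_ms,
        internode_length_mm=fiber.internode_length_mm,
    )
    detect_activation(trace)
    return trace


def _gate_step(g, alpha, beta, dt):
    tau = 1.0 / (alpha + beta)
    g_inf = alpha * tau
    g_new = g_inf + (g - g_inf) * np.exp(-dt / tau)
    return np.clip(g_new, 0.0, 1.0)


def _laplacian(v, Ga):
    out = np.zeros_like(v)
    flux = Ga * (v[1:] - v[:-1])
    out[:-1] += flux
    out[1:] -= flux
    return out


def detect_activation(trace: SimulationTrace,
                      threshold_mV: float = ACTIVATION_THRESHOLD_MV,
                      guard_internodes: int = PROPAGATION_GUARD_INTERNODES) -> bool:
    """Mark the trace activated iff the membrane crossed ``threshold_mV``
    at a node at least ``guard_internodes`` away from the end-of-pulse
    depolarization peak (a propagation guard against counting the purely
    local response under the cathode).
    """
    V = trace.V_mV
    n_t, n_nodes = V.shape
    k_pulse = min(n_t - 1, int(round(trace.pulse_width_ms
                                     / (trace.times_ms[1] - trace.times_ms[0]))))
    peak_node = int(np.argmax(V[k_pulse]))
    crossed = V > threshold_mV
    first = np.full(n_nodes, np.nan)
    any_cross = crossed.any(axis=0)
    idx = np.argmax(crossed, axis=0)
    first[any_cross] = trace.times_ms[idx[any_cross]]
    trace.first_crossing_ms = first
    far = np.abs(np.arange(n_nodes) - peak_node) >= guard_internodes
    candidates = np.nonzero(any_cross & far)[0]
    if candidates.size == 0:
        trace.activated = False
        trace.activation_node = None
        trace.activation_time_ms = None
        trace.conduction_latency_ms = None
        return False
    times = first[candidates]
    j = int(candidates[np.argmin(times)])
    trace.activated = True
    trace.activation_node = j
    trace.activation_time_ms = float(first[j])
    onset = np.nanmin(first) if np.any(any_cross) else None
    trace.conduction_latency_ms = float(first[j] - onset) if onset is not None else None
    return True
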