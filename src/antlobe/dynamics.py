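"""Per-neuron and per-synapse dynamical building blocks.

Four elements make up every executable circuit:

* **OTP** (odorant transduction process) — receptor kinetics converting
  odorant concentration into a transduction current.  The binding stage is
  the exact ODE ``dx/dt = b·u·(1−x) − d·x`` (bound-receptor fraction ``x``);
  downstream, a saturating current map with one slow adaptation state turns
  occupancy into current.  Both stages are monotone and saturating in the
  concentration-modulated affinity (b/d)·u, the two properties the
  steady-state characterization depends on.
* **Connor–Stevens** point neuron — the axon hillock of OSNs, PNs and LNs.
  Type-I excitability (firing rates continuous from zero above rheobase),
  with transient Na, delayed-rectifier K and A-type K currents.
* **α-synapse** — conductance ``g(t) = ḡ·((t−t_s)/τ)·exp(1−(t−t_s)/τ)``
  summed over presynaptic spikes; peak ḡ at ``t_s + τ``; synaptic current
  ``g·(E_rev − V_post)``.  Synapse count scales ḡ linearly.
* **Presynaptic terminal** — divisive modulation of an OSN axon terminal's
  feedforward conductance by LN activity: ``gain = 1/(1 + κ·s(t))`` with
  ``s`` the α-filtered LN spike train, so gain ∈ (0, 1].

All parameters are recorded in ``data/neuron_params.yaml`` (point-neuron
units: mS/cm², µA/cm², µF/cm², mV, ms).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "default_params",
    "ConnorStevensParams",
    "OTPParams",
    "OTPState",
    "AlphaSynapseParams",
    "otp_step",
    "otp_binding_fixed_point",
    "otp_steady_current",
    "connor_stevens_rates",
    "connor_stevens_integrate",
    "alpha_synapse_conductance",
    "presynaptic_gain",
]


def default_params() -> dict:
    """Load the versioned neuron/synapse parameter config shipped with the package."""
    ref = importlib.resources.files("antlobe.data").joinpath("neuron_params.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


_DEFAULTS = default_params()


@dataclass(frozen=True)
class ConnorStevensParams:
    capacitance: float = _DEFAULTS["connor_stevens"]["capacitance"]
    g_na: float = _DEFAULTS["connor_stevens"]["g_na"]
    g_k: float = _DEFAULTS["connor_stevens"]["g_k"]
    g_a: float = _DEFAULTS["connor_stevens"]["g_a"]
    g_leak: float = _DEFAULTS["connor_stevens"]["g_leak"]
    e_na: float = _DEFAULTS["connor_stevens"]["e_na"]
    e_k: float = _DEFAULTS["connor_stevens"]["e_k"]
    e_a: float = _DEFAULTS["connor_stevens"]["e_a"]
    e_leak: float = _DEFAULTS["connor_stevens"]["e_leak"]

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.capacitance,
                self.g_na,
                self.g_k,
                self.g_a,
                self.g_leak,
                self.e_na,
                self.e_k,
                self.e_a,
                self.e_leak,
            ],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class OTPParams:
    i_max: float = _DEFAULTS["otp"]["i_max"]
    k_half: float = _DEFAULTS["otp"]["k_half"]
    gamma: float = _DEFAULTS["otp"]["gamma"]
    tau_z: float = _DEFAULTS["otp"]["tau_z"]  # ms

    def as_array(self) -> np.ndarray:
        return np.array([self.i_max, self.k_half, self.gamma, self.tau_z], np.float64)


@dataclass
class AlphaSynapseParams:
    """ḡ ≥ 0 (mS/cm², point convention), τ > 0 (ms); sign is carried by E_rev."""

    g_max: float
    tau: float = _DEFAULTS["synapse"]["tau"]
    e_rev: float = _DEFAULTS["synapse"]["e_rev_excitatory"]

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be nonnegative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @classmethod
    def from_count(
        cls, count: int, sign: str = "excitatory", g_unit: float | None = None
    ) -> "AlphaSynapseParams":
        """Linear synapse-count scaling: ḡ = ḡ_unit × count."""
        g_unit = _DEFAULTS["synapse"]["g_unit"] if g_unit is None else g_unit
        e_rev = (
            _DEFAULTS["synapse"]["e_rev_excitatory"]
            if sign == "excitatory"
            else _DEFAULTS["synapse"]["e_rev_inhibitory"]
        )
        return cls(g_max=g_unit * count, e_rev=e_rev)


# ---------------------------------------------------------------------------
# Odorant transduction process
# ---------------------------------------------------------------------------

@dataclass
class OTPState:
    """State of one transduction unit: occupancy x ∈ [0,1], adaptation z, output current."""

    x: float = 0.0
    z: float = 0.0
    current: float = 0.0
    params: OTPParams = field(default_factory=OTPParams)


def otp_step(state: OTPState, b: float, d: float, u: float, dt: float) -> OTPState:
    """Advance an OTP unit by ``dt`` seconds under concentration ``u``.

    The binding stage uses the exact exponential solution of
    dx/dt = b·u·(1−x) − d·x over the step (unconditionally stable for any
    dt), so the fixed point x* = b·u/(b·u + d) is reached to machine
    precision.  The adaptation state relaxes toward x with time constant
    tau_z; the output current is the saturating map of (x, z).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if u < 0:
        raise ValueError("concentration must be nonnegative")
    if d <= 0:
        raise ValueError("dissociation rate must be positive")
    p = state.params
    bu = b * u
    total = bu + d
    x_inf = bu / total
    x = x_inf + (state.x - x_inf) * np.exp(-total * dt)
    x = min(max(x, 0.0), 1.0)
    tau_z_s = p.tau_z * 1e-3
    z = x + (state.z - x) * np.exp(-dt / tau_z_s)
    current = p.i_max * x / (x + p.k_half * (1.0 + p.gamma * z))
    return OTPState(x=x, z=z, current=current, params=p)


def otp_binding_fixed_point(b: float, d: float, u: float) -> float:
    """Closed-form steady-state occupancy x* = b·u / (b·u + d)."""
    bu = np.asarray(b, float) * np.asarray(u, float)
    return bu / (bu + np.asarray(d, float))


def otp_steady_current(
    b: float, d: float, u: float, params: OTPParams | None = None
) -> float:
    """Fixed-point transduction current under constant concentration.

    Strictly increasing in the affinity (b/d)·u and saturating at
    i_max / (1 + k_half·γ / (…)) for large inputs; zero at u = 0.
    """
    p = params or OTPParams()
    x = otp_binding_fixed_point(b, d, u)
    z = x  # adaptation fixed point equals occupancy
    out = p.i_max * x / (x + p.k_half * (1.0 + p.gamma * z))
    out = np.where(np.asarray(x) > 0, out, 0.0)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Connor-Stevens kinetics
# ---------------------------------------------------------------------------

def _safe_exprel(x: np.ndarray) -> np.ndarray:
    """x / (1 - exp(-x)), with the removable singularity at 0 filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    xs = np.where(small, 1.0, x)
    out = xs / (1.0 - np.exp(-xs))
    return np.where(small, 1.0 + x / 2.0, out)


def connor_stevens_rates(v: np.ndarray) -> dict[str, np.ndarray]:
    """Steady states and time constants (ms) of all six gates at voltage ``v`` (mV).

    m³h gates Na, n⁴ the delayed rectifier, a³b the transient A-current.
    The standard 18 °C rate constants are used (Na kinetics sped up 3.8×,
    K kinetics 2× relative to the squid-axon formulation, already folded
    into the coefficients).
    """
    v = np.asarray(v, dtype=float)
    am = 3.8 * _safe_exprel((v + 29.7) / 10.0)  # 0.38·(v+29.7)/(1−e^{−(v+29.7)/10})
    bm = 15.2 * np.exp(-(v + 54.7) / 18.0)
    ah = 0.266 * np.exp(-(v + 48.0) / 20.0)
    bh = 3.8 / (1.0 + np.exp(-(v + 18.0) / 10.0))
    an = 0.2 * _safe_exprel((v + 45.7) / 10.0)  # 0.02·(v+45.7)/(1−e^{−(v+45.7)/10})
    bn = 0.25 * np.exp(-(v + 55.7) / 80.0)
    a_inf = (
        0.0761
        * np.exp((v + 94.22) / 31.84)
        / (1.0 + np.exp((v + 1.17) / 28.93))
    ) ** (1.0 / 3.0)
    tau_a = 0.3632 + 1.158 / (1.0 + np.exp((v + 55.96) / 20.12))
    b_inf = (1.0 / (1.0 + np.exp((v + 53.3) / 14.54))) ** 4.0
    tau_b = 1.24 + 2.678 / (1.0 + np.exp((v + 50.0) / 16.027))
    return {
        "m_inf": am / (am + bm),
        "tau_m": 1.0 / (am + bm),
        "h_inf": ah / (ah + bh),
        "tau_h": 1.0 / (ah + bh),
        "n_inf": an / (an + bn),
        "tau_n": 1.0 / (an + bn),
        "a_inf": a_inf,
        "tau_a": tau_a,
        "b_inf": b_inf,
        "tau_b": tau_b,
    }


def connor_stevens_integrate(
    i_ext,
    dt: float,
    duration: float,
    v0: float | None = None,
    params: ConnorStevensParams | None = None,
    record_v: bool = False,
):
    """Integrate one Connor–Stevens neuron under an external current.

    Parameters
    ----------
    i_ext
        Constant current (µA/cm²) or an array sampled at 1 ms resolution.
    dt
        Step in ms (fixed-step integration; deterministic for fixed inputs).
    duration
        Run length in seconds.
    record_v
        When true, also return the voltage trace sampled every step.

    Returns
    -------
    (trajectory, spike_times)
        ``trajectory`` is the voltage trace (empty array unless
        ``record_v``); spike times are in seconds, detected as upward
        crossings of 0 mV with a 2 ms lockout.

    Raises
    ------
    FloatingPointError
        If the membrane potential leaves ±500 mV (numerical blow-up).
    """
    from . import engine  # deferred: jit compilation on first use

    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params or ConnorStevensParams()
    i_samples = np.atleast_1d(np.asarray(i_ext, dtype=np.float64)).reshape(1, -1)
    return engine.integrate_single(
        i_samples, dt, duration, p.as_array(), v0=v0, record_v=record_v
    )


# ---------------------------------------------------------------------------
# Alpha synapse and presynaptic gain (closed forms)
# ---------------------------------------------------------------------------

def alpha_synapse_conductance(
    spike_times, params: AlphaSynapseParams, t_grid
) -> np.ndarray:
    """Closed-form α-conductance waveform on ``t_grid`` (same time unit as spikes).

    g(t) = Σ_s ḡ·((t−t_s)/τ)·exp(1−(t−t_s)/τ) for t ≥ t_s; linear in the
    spike train (superposed trains add pointwise).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size > 1 and np.any(np.diff(spike_times) < 0):
        raise ValueError("spike_times must be sorted")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    g = np.zeros_like(t_grid)
    for t_s in spike_times:
        rel = (t_grid - t_s) / params.tau
        g += np.where(rel >= 0, params.g_max * rel * np.exp(1.0 - rel), 0.0)
    return g


def presynaptic_gain(s_ln, kappa: float):
    """Divisive terminal gain 1/(1 + κ·s); equals 1 with no LN activity, →0 as s→∞."""
    s_ln = np.asarray(s_ln, dtype=float)
    if np.any(s_ln < 0):
        raise ValueError("filtered LN activity must be nonnegative")
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    out = 1.0 / (1.0 + kappa * s_ln)
    return float(out) if out.ndim == 0 else out
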