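"""Execute composed circuits and characterize steady-state PN responses.

The entry points are :func:`run` (one circuit, one odorant environment),
:func:`sweep_affinity` (1-D input/output curve of PN steady-state rates
against the concentration-modulated affinity (b/d)·u of the glomerular
receptors), :func:`sweep_affinity_grid` (2-D mesh for interconnected pairs)
and :func:`inject_current`.

Sweeps drive each glomerulus through a private virtual odorant with unit
binding and dissociation rates, so the waveform amplitude *is* the affinity
value — the characterization variable — independent of any particular
environment calibration.

The integration itself is deterministic fixed-step co-integration of OTP,
Connor–Stevens, α-synapse and presynaptic-terminal states (see
:mod:`antlobe.engine`); identical inputs give bitwise-identical spike
trains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine
from .composer import CircuitModel
from .dynamics import ConnorStevensParams, OTPParams, default_params
from .odor import ConcentrationWaveform, OdorantEnvironment

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SweepResult",
    "run",
    "steady_state_rate",
    "sweep_affinity",
    "sweep_affinity_grid",
    "inject_current",
    "affinity_environment",
]

U_SAMPLE_MS = 1.0  # waveform / injected-current sampling resolution


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol parameters.  The core simulation is deterministic; the seed
    exists for stochastic extensions and is recorded in run manifests."""

    dt: float = 0.01  # ms
    duration: float = 4.0  # s
    steady_window: float = 1.0  # s, trailing
    seed: int | None = None
    record: tuple[str, ...] = ()  # neuron ids whose V to trace
    record_stride: int = 10  # steps between trace samples

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.steady_window > self.duration:
            raise ValueError("steady-state window may not exceed the duration")


@dataclass
class SimulationResult:
    spike_trains: dict[str, np.ndarray]  # neuron id -> spike times (s)
    rates: dict[str, float]  # steady-state rate (Hz)
    duration: float
    config: SimulationConfig
    traces: dict[str, np.ndarray] = field(default_factory=dict)
    trace_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mean_ff_conductance: float = 0.0  # window-averaged OSN→PN conductance (mS/cm²)

    def pn_rates(self, circuit: CircuitModel) -> dict[str, float]:
        return {
            nid: self.rates[nid]
            for nid, n in circuit.neurons.items()
            if n.cell_class == "PN"
        }


@dataclass
class SweepResult:
    """PN steady-state rates over a 1-D or 2-D affinity grid."""

    values: np.ndarray  # 1-D grid, or axis x of a 2-D grid
    values_y: np.ndarray | None
    rates: dict[str, np.ndarray]  # PN id -> (len(values),) or (len x, len y)
    mean_ff_conductance: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        if self.values_y is not None:
            rows = []
            for i, vx in enumerate(self.values):
                for j, vy in enumerate(self.values_y):
                    rows.append(
                        {"affinity_x": vx, "affinity_y": vy}
                        | {pn: r[i, j] for pn, r in self.rates.items()}
                    )
            return pd.DataFrame(rows)
        return pd.DataFrame({"affinity": self.values} | self.rates)


def steady_state_rate(spike_train, window: float, duration: float) -> float:
    """Spike count in the trailing window divided by the window length (Hz)."""
    if window > duration:
        raise ValueError("window may not exceed duration")
    if window <= 0:
        raise ValueError("window must be positive")
    spikes = np.asarray(spike_train, dtype=float)
    return float(np.count_nonzero(spikes >= duration - window) / window)


# ---------------------------------------------------------------------------
# Circuit compilation
# ---------------------------------------------------------------------------

class _Compiled:
    """Flat-array form of a circuit, ready for the engine kernel."""

    def __init__(self, circuit: CircuitModel):
        self.circuit = circuit
        self.ids = sorted(circuit.neurons)
        self.index = {nid: i for i, nid in enumerate(self.ids)}
        p = circuit.params
        self.cs = ConnorStevensParams(**p["connor_stevens"]).as_array()
        self.otp = OTPParams(**p["otp"])
        syn = p["synapse"]
        self.g_unit = syn["g_unit"]
        self.tau_ff = syn["tau"]
        self.tau_ln = syn.get("tau_ln", syn["tau"])
        self.e_exc = syn["e_rev_excitatory"]
        self.e_inh = syn["e_rev_inhibitory"]
        pre = p["presynaptic"]
        self.kappa_unit = pre["kappa_unit"]
        self.tau_mod = pre["tau_mod"]

        classes = {nid: circuit.neurons[nid].cell_class for nid in self.ids}
        self.osn_ids = [nid for nid in self.ids if classes[nid] == "OSN"]
        self.osn_slot = {nid: k for k, nid in enumerate(self.osn_ids)}
        self.osn_neuron = np.array(
            [self.index[nid] for nid in self.osn_ids], dtype=np.int64
        )

        syn_pre, syn_post, syn_gmax, syn_erev, syn_tau = [], [], [], [], []
        syn_modulated, syn_ffpn = [], []
        mod_entries: list[tuple[str, int, float]] = []  # (ln id, osn neuron idx, kappa)
        for e in circuit.edges:
            if e.presynaptic:
                # LN → OSN terminal: divisive modulation, not a somatic conductance
                mod_entries.append(
                    (e.pre, self.index[e.post], self.kappa_unit * e.count)
                )
                continue
            syn_pre.append(self.index[e.pre])
            syn_post.append(self.index[e.post])
            syn_gmax.append(self.g_unit * e.count)
            syn_erev.append(self.e_exc if e.sign == "excitatory" else self.e_inh)
            syn_tau.append(self.tau_ff if e.kind == "feedforward" else self.tau_ln)
            pre_is_osn = classes[e.pre] == "OSN"
            syn_modulated.append(pre_is_osn)
            syn_ffpn.append(e.kind == "feedforward")
        self.syn_pre = np.array(syn_pre, dtype=np.int64)
        self.syn_post = np.array(syn_post, dtype=np.int64)
        self.syn_gmax = np.array(syn_gmax, dtype=np.float64)
        self.syn_erev = np.array(syn_erev, dtype=np.float64)
        self.syn_tau = np.array(syn_tau, dtype=np.float64)
        self.syn_modulated = np.array(syn_modulated, dtype=np.bool_)
        self.syn_ffpn = np.array(syn_ffpn, dtype=np.bool_)

        # one modulation filter per distinct LN that acts presynaptically
        filt_lns = sorted({ln for ln, _, _ in mod_entries})
        self.modf_ln = np.array([self.index[ln] for ln in filt_lns], dtype=np.int64)
        filt_slot = {ln: f for f, ln in enumerate(filt_lns)}
        self.mod_f = np.array([filt_slot[ln] for ln, _, _ in mod_entries], dtype=np.int64)
        self.mod_osn = np.array([osn for _, osn, _ in mod_entries], dtype=np.int64)
        self.mod_kappa = np.array([k for _, _, k in mod_entries], dtype=np.float64)

    def n_neurons(self) -> int:
        return len(self.ids)


def _osn_channels(
    compiled: _Compiled,
    env: OdorantEnvironment,
    waveform: ConcentrationWaveform,
    n_samples: int,
    dt_ms: float,
):
    """Per-(OSN, active odorant) transduction channels with precomputed updates."""
    circuit = compiled.circuit
    active = waveform.active_odorants()
    t_grid = np.arange(n_samples) * (U_SAMPLE_MS * 1e-3)
    ch_osn, ch_xinf, ch_decay = [], [], []
    dt_s = dt_ms * 1e-3
    for nid in compiled.osn_ids:
        receptor = circuit.neurons[nid].receptor_type
        if receptor not in env.receptor_labels:
            raise ValueError(
                f"environment lacks receptor {receptor!r} required by OSN {nid!r}"
            )
        for odorant in active:
            b, d = env.rates(receptor, odorant)
            if b == 0.0:
                continue
            u = waveform.sample(odorant, t_grid)
            bu = b * u
            total = bu + d
            ch_osn.append(compiled.osn_slot[nid])
            ch_xinf.append(bu / total)
            ch_decay.append(np.exp(-total * dt_s))
    if ch_osn:
        return (
            np.array(ch_osn, dtype=np.int64),
            np.ascontiguousarray(np.array(ch_xinf, dtype=np.float64)),
            np.ascontiguousarray(np.array(ch_decay, dtype=np.float64)),
        )
    return (
        np.zeros(0, dtype=np.int64),
        np.zeros((0, 1), dtype=np.float64),
        np.zeros((0, 1), dtype=np.float64),
    )


def _execute(
    compiled: _Compiled,
    config: SimulationConfig,
    ch_osn,
    ch_xinf,
    ch_decay,
    iext_samples: np.ndarray,
) -> SimulationResult:
    dt = config.dt
    n_steps = int(round(config.duration * 1000.0 / dt))
    n = compiled.n_neurons()
    v_rest, g_rest = engine.resting_state()
    V = np.full(n, v_rest, dtype=np.float64)
    gates = np.ascontiguousarray(np.repeat(g_rest[:, None], n, axis=1))
    inf_t, edt_t = engine.build_rate_tables(dt)

    n_syn = compiled.syn_pre.shape[0]
    syn_g = np.zeros(n_syn)
    syn_h = np.zeros(n_syn)
    syn_edt = np.exp(-dt / compiled.syn_tau)
    syn_bump = np.e * compiled.syn_gmax / compiled.syn_tau

    n_filt = compiled.modf_ln.shape[0]
    modf_s = np.zeros(n_filt)
    modf_h = np.zeros(n_filt)
    modf_edt = np.full(n_filt, np.exp(-dt / compiled.tau_mod))
    modf_bump = np.full(n_filt, np.e / compiled.tau_mod)

    otp_z = np.zeros(len(compiled.osn_ids))
    ez = np.exp(-dt / compiled.otp.tau_z)

    max_spk = int(config.duration * 600) + 8
    spk_step = np.zeros((n, max_spk), dtype=np.int64)
    spk_count = np.zeros(n, dtype=np.int64)
    last_spk = np.full(n, -(10**9), dtype=np.int64)

    record_ids = [nid for nid in config.record if nid in compiled.index]
    trace_stride = config.record_stride if record_ids else 0
    n_rec = (n_steps // config.record_stride + 1) if record_ids else 0
    trace = np.zeros((len(record_ids), n_rec), dtype=np.float64)
    trace_idx = np.array([compiled.index[r] for r in record_ids], dtype=np.int64)

    win_start = int(round((config.duration - config.steady_window) * 1000.0 / dt))
    acc = np.zeros(2, dtype=np.float64)
    err = np.zeros(2, dtype=np.int64)
    u_stride = max(1, int(round(U_SAMPLE_MS / dt)))

    status = engine._run_kernel(
        dt,
        n_steps,
        compiled.cs,
        V,
        gates,
        np.ascontiguousarray(iext_samples),
        u_stride,
        compiled.osn_neuron,
        otp_z,
        ez,
        compiled.otp.i_max,
        compiled.otp.k_half,
        compiled.otp.gamma,
        ch_osn,
        np.zeros(ch_osn.shape[0], dtype=np.float64),
        ch_xinf,
        ch_decay,
        u_stride,
        compiled.syn_pre,
        compiled.syn_post,
        syn_bump,
        compiled.syn_erev,
        syn_edt,
        syn_g,
        syn_h,
        compiled.syn_modulated,
        compiled.syn_ffpn,
        compiled.modf_ln,
        modf_bump,
        modf_edt,
        modf_s,
        modf_h,
        compiled.mod_f,
        compiled.mod_osn,
        compiled.mod_kappa,
        inf_t,
        edt_t,
        engine.V_MIN,
        (engine.N_TABLE - 1) / (engine.V_MAX - engine.V_MIN),
        spk_step,
        spk_count,
        max_spk,
        int(round(engine.SPIKE_LOCKOUT / dt)),
        last_spk,
        win_start,
        acc,
        trace,
        trace_idx,
        trace_stride,
        err,
    )
    if status != 0:
        nid = compiled.ids[int(err[0])]
        raise engine.IntegrationError(int(err[0]), float(err[1]) * dt * 1e-3, nid)

    spike_trains = {}
    rates = {}
    for i, nid in enumerate(compiled.ids):
        k = min(int(spk_count[i]), max_spk)
        times = spk_step[i, :k].astype(np.float64) * dt * 1e-3
        spike_trains[nid] = times
        rates[nid] = steady_state_rate(times, config.steady_window, config.duration)
    traces = {nid: trace[j] for j, nid in enumerate(record_ids)}
    mean_ff = float(acc[0] / acc[1]) if acc[1] > 0 else 0.0
    return SimulationResult(
        spike_trains=spike_trains,
        rates=rates,
        duration=config.duration,
        config=config,
        traces=traces,
        trace_times=(
            np.arange(n_rec) * config.record_stride * dt * 1e-3 if record_ids else np.zeros(0)
        ),
        mean_ff_conductance=mean_ff,
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def run(
    circuit: CircuitModel,
    env: OdorantEnvironment,
    waveform: ConcentrationWaveform,
    config: SimulationConfig | None = None,
    extra_current: dict[str, float] | None = None,
) -> SimulationResult:
    """Deterministic fixed-step simulation of a circuit under an odorant stimulus."""
    config = config or SimulationConfig()
    compiled = _Compiled(circuit)
    n_samples = int(np.ceil(config.duration * 1000.0 / U_SAMPLE_MS)) + 1
    ch_osn, ch_xinf, ch_decay = _osn_channels(
        compiled, env, waveform, n_samples, config.dt
    )
    iext = np.zeros((compiled.n_neurons(), 1), dtype=np.float64)
    if extra_current:
        for nid, amp in extra_current.items():
            if nid not in compiled.index:
                raise KeyError(f"unknown neuron {nid!r}")
            iext[compiled.index[nid], 0] = amp
    return _execute(compiled, config, ch_osn, ch_xinf, ch_decay, iext)


def inject_current(
    circuit: CircuitModel,
    neuron_id: str,
    amplitude: float,
    config: SimulationConfig | None = None,
    env: OdorantEnvironment | None = None,
    waveform: ConcentrationWaveform | None = None,
) -> SimulationResult:
    """Run with a constant current (µA/cm²) added to one neuron's input."""
    if neuron_id not in circuit.neurons:
        raise KeyError(f"unknown neuron {neuron_id!r}")
    if env is None or waveform is None:
        env, waveform = affinity_environment(circuit, 0.0)
    return run(circuit, env, waveform, config, extra_current={neuron_id: amplitude})


def affinity_environment(
    circuit: CircuitModel,
    affinity,
) -> tuple[OdorantEnvironment, ConcentrationWaveform]:
    """Virtual environment driving each glomerular receptor at a given affinity.

    One private odorant per receptor with b = d = 1, so the constant
    concentration amplitude equals the concentration-modulated affinity
    (b/d)·u.  ``affinity`` is a scalar or a mapping glomerulus → value.
    """
    from .odor import WaveformSpec

    gloms = sorted(circuit.glomeruli)
    if not gloms:
        raise ValueError("circuit has no glomeruli")
    if np.isscalar(affinity):
        affinity = {g: float(affinity) for g in gloms}
    receptors = [circuit.glomeruli[g].receptor_type for g in gloms]
    odorants = [f"odor:{r}" for r in receptors]
    n = len(receptors)
    b = np.eye(n)
    d = np.ones((n, n))
    env = OdorantEnvironment.from_matrices(b, d, receptors, odorants)
    specs = {}
    for g, od in zip(gloms, odorants):
        val = float(affinity.get(g, 0.0))
        if val < 0:
            raise ValueError("affinity values must be nonnegative")
        if val > 0:
            specs[od] = WaveformSpec("constant", {"amplitude": val})
    waveform = ConcentrationWaveform(odorants, specs, duration=1.0)
    return env, waveform


def sweep_affinity(
    circuit: CircuitModel,
    values,
    config: SimulationConfig | None = None,
    glomerulus: str | None = None,
) -> SweepResult:
    """Steady-state PN rates across a sorted 1-D affinity grid.

    Each grid point is one run with constant input scaled so that (b/d)·u
    equals the grid value for the target receptor(s).  By default every
    glomerulus in the circuit is driven; pass ``glomerulus`` to drive one.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("sweep needs at least 2 grid values")
    if np.any(np.diff(values) <= 0):
        raise ValueError("sweep values must be sorted ascending")
    config = config or SimulationConfig()
    pn_ids = sorted(
        nid for nid, n in circuit.neurons.items() if n.cell_class == "PN"
    )
    rates = {pn: np.zeros(values.size) for pn in pn_ids}
    ff = np.zeros(values.size)
    for i, v in enumerate(values):
        if glomerulus is None:
            aff = float(v)
        else:
            aff = {glomerulus: float(v)}
        env, waveform = affinity_environment(circuit, aff)
        result = run(circuit, env, waveform, config)
        for pn in pn_ids:
            rates[pn][i] = result.rates[pn]
        ff[i] = result.mean_ff_conductance
    return SweepResult(values=values, values_y=None, rates=rates, mean_ff_conductance=ff)


def sweep_affinity_grid(
    circuit: CircuitModel,
    values_x,
    values_y,
    config: SimulationConfig | None = None,
    glomeruli: tuple[str, str] | None = None,
) -> SweepResult:
    """Steady-state PN rate mesh over a 2-D affinity grid (one axis per glomerulus)."""
    values_x = np.asarray(values_x, dtype=float)
    values_y = np.asarray(values_y, dtype=float)
    for vals in (values_x, values_y):
        if vals.size < 2 or np.any(np.diff(vals) <= 0):
            raise ValueError("each axis needs >= 2 sorted values")
    config = config or SimulationConfig()
    if glomeruli is None:
        names = sorted(circuit.glomeruli)
        if len(names) != 2:
            raise ValueError(
                "specify glomeruli=(x_axis, y_axis) unless the circuit has exactly two"
            )
        glomeruli = (names[0], names[1])
    gx, gy = glomeruli
    for g in (gx, gy):
        if g not in circuit.glomeruli:
            raise ValueError(f"unknown glomerulus {g!r}")
    pn_ids = sorted(
        nid for nid, n in circuit.neurons.items() if n.cell_class == "PN"
    )
    rates = {pn: np.zeros((values_x.size, values_y.size)) for pn in pn_ids}
    for i, vx in enumerate(values_x):
        for j, vy in enumerate(values_y):
            env, waveform = affinity_environment(circuit, {gx: vx, gy: vy})
            result = run(circuit, env, waveform, config)
            for pn in pn_ids:
                rates[pn][i, j] = result.rates[pn]
    return SweepResult(values=values_x, values_y=values_y, rates=rates)


def write_spike_trains(result: SimulationResult, path) -> None:
    """Two-column text export: neuron id, spike time (s)."""
    with open(path, "w") as fh:
        fh.write("neuron_id\tspike_time_s\n")
        for nid in sorted(result.spike_trains):
            for t in result.spike_trains[nid]:
                fh.write(f"{nid}\t{t:.6f}\n")
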