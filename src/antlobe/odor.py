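"""Receptor-centric model of the odorant space.

An odorant is not described by its chemical structure but by how fast it
associates with and dissociates from each olfactory receptor type.  The
stimulus space is therefore a tensor trio:

* ``b`` — binding (association) rates, indexed ``[receptor, odorant, neuron]``,
  units 1/(concentration·s);
* ``d`` — dissociation rates, same indexing, units 1/s;
* ``u(t)`` — per-odorant concentration waveforms, units of concentration
  (arbitrary but consistent).

The dimensionless product ``(b/d)·u`` — the concentration-modulated affinity —
is the single number that summarizes how strongly a constant stimulus drives a
receptor, and is the sweep variable used throughout the input/output
characterization of circuits.

Units for ``b`` and ``d`` are documented conventions, not physical
calibrations: all downstream characterization happens on the dimensionless
affinity scale, so only the product ``(b/d)·u`` matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "OdorantEnvironment",
    "WaveformSpec",
    "ConcentrationWaveform",
    "make_pure_odorant",
    "concentration_modulated_affinity",
    "validate_environment",
    "affinity_sweep_values",
    "load_environment",
    "save_environment",
]


@dataclass
class OdorantEnvironment:
    """The (b, d) tensor pair plus labels.

    ``binding_rates`` and ``dissociation_rates`` have shape ``(R, O, N)``;
    when ``share_across_neurons`` is true the two tensors are constant along
    the neuron axis (the common simplification: all neurons expressing the
    same receptor type share one rate).
    """

    binding_rates: np.ndarray
    dissociation_rates: np.ndarray
    receptor_labels: list[str]
    odorant_labels: list[str]
    share_across_neurons: bool = True

    def __post_init__(self) -> None:
        self.binding_rates = np.asarray(self.binding_rates, dtype=float)
        self.dissociation_rates = np.asarray(self.dissociation_rates, dtype=float)
        if self.binding_rates.ndim == 2:
            self.binding_rates = self.binding_rates[:, :, None]
        if self.dissociation_rates.ndim == 2:
            self.dissociation_rates = self.dissociation_rates[:, :, None]

    @classmethod
    def from_matrices(
        cls,
        b: np.ndarray,
        d: np.ndarray,
        receptor_labels: Sequence[str],
        odorant_labels: Sequence[str],
    ) -> "OdorantEnvironment":
        """Build a shared-across-neurons environment from (R, O) matrices."""
        return cls(
            binding_rates=np.asarray(b, dtype=float),
            dissociation_rates=np.asarray(d, dtype=float),
            receptor_labels=list(receptor_labels),
            odorant_labels=list(odorant_labels),
            share_across_neurons=True,
        )

    @property
    def n_receptors(self) -> int:
        return len(self.receptor_labels)

    @property
    def n_odorants(self) -> int:
        return len(self.odorant_labels)

    def receptor_index(self, label: str) -> int:
        try:
            return self.receptor_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown receptor label {label!r}") from None

    def odorant_index(self, label: str) -> int:
        try:
            return self.odorant_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown odorant label {label!r}") from None

    def rates(self, receptor: str, odorant: str, neuron: int = 0) -> tuple[float, float]:
        """Return the (b, d) pair for one receptor/odorant/neuron triple."""
        r = self.receptor_index(receptor)
        o = self.odorant_index(odorant)
        n = 0 if self.share_across_neurons else neuron
        n = min(n, self.binding_rates.shape[2] - 1)
        return float(self.binding_rates[r, o, n]), float(self.dissociation_rates[r, o, n])

    def validate(self) -> list[str]:
        return validate_environment(self)


def validate_environment(env: OdorantEnvironment) -> list[str]:
    """Return a list of violated invariants; empty when the environment is valid."""
    problems: list[str] = []
    b, d = env.binding_rates, env.dissociation_rates
    if b.shape != d.shape:
        problems.append(
            f"binding/dissociation shape mismatch: {b.shape} vs {d.shape}"
        )
    expected = (env.n_receptors, env.n_odorants)
    if b.shape[:2] != expected:
        problems.append(
            f"tensor shape {b.shape[:2]} does not match label lengths {expected}"
        )
    if np.any(b < 0):
        problems.append("binding rates must be nonnegative")
    if b.shape == d.shape and np.any(d <= 0):
        problems.append("dissociation must be positive")
    if env.share_across_neurons and b.shape == d.shape and b.shape[2] > 1:
        if np.ptp(b, axis=2).max() > 0 or np.ptp(d, axis=2).max() > 0:
            problems.append(
                "share_across_neurons is set but rates vary along the neuron axis"
            )
    return problems


# ---------------------------------------------------------------------------
# Concentration waveforms
# ---------------------------------------------------------------------------

def _constant(params: Mapping[str, float]) -> Callable[[np.ndarray], np.ndarray]:
    amp = float(params["amplitude"])
    return lambda t: np.full_like(np.asarray(t, dtype=float), amp)


def _step(params: Mapping[str, float]) -> Callable[[np.ndarray], np.ndarray]:
    t_on = float(params.get("t_on", 0.0))
    t_off = float(params.get("t_off", np.inf))
    amp = float(params["amplitude"])
    base = float(params.get("baseline", 0.0))

    def f(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.where((t >= t_on) & (t < t_off), amp, base)

    return f


def _ramp(params: Mapping[str, float]) -> Callable[[np.ndarray], np.ndarray]:
    t0, t1 = float(params.get("t0", 0.0)), float(params["t1"])
    u0, u1 = float(params.get("u0", 0.0)), float(params["u1"])

    def f(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.interp(t, [t0, t1], [u0, u1])

    return f


def _piecewise(params: Mapping[str, Sequence[float]]) -> Callable[[np.ndarray], np.ndarray]:
    times = np.asarray(params["times"], dtype=float)
    values = np.asarray(params["values"], dtype=float)
    if times.shape != values.shape:
        raise ValueError("piecewise waveform needs equal-length times and values")
    if np.any(np.diff(times) <= 0):
        raise ValueError("piecewise sample times must be strictly increasing")
    return lambda t: np.interp(np.asarray(t, dtype=float), times, values)


_GENERATORS: dict[str, Callable[[Mapping], Callable[[np.ndarray], np.ndarray]]] = {
    "constant": _constant,
    "step": _step,
    "ramp": _ramp,
    "piecewise": _piecewise,
}


@dataclass
class WaveformSpec:
    """Named generator + parameters for one odorant's concentration trace."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _GENERATORS:
            raise ValueError(
                f"unknown waveform kind {self.kind!r}; choose from {sorted(_GENERATORS)}"
            )

    def sample(self, t: np.ndarray) -> np.ndarray:
        return _GENERATORS[self.kind](self.params)(t)


@dataclass
class ConcentrationWaveform:
    """Concentration-vs-time for every odorant in an environment.

    Stored as generator + parameters and sampled on whatever time grid the
    simulator uses, so the description is resolution independent.  Odorants
    without an explicit spec are identically zero.
    """

    odorant_labels: list[str]
    specs: dict[str, WaveformSpec] = field(default_factory=dict)
    duration: float = 1.0  # seconds

    def __post_init__(self) -> None:
        for label in self.specs:
            if label not in self.odorant_labels:
                raise KeyError(f"waveform refers to unknown odorant {label!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def sample(self, odorant: str, t: np.ndarray) -> np.ndarray:
        """Sample u_o(t) for one odorant on time grid ``t`` (seconds)."""
        if odorant not in self.odorant_labels:
            raise KeyError(f"unknown odorant label {odorant!r}")
        spec = self.specs.get(odorant)
        t = np.asarray(t, dtype=float)
        if spec is None:
            return np.zeros_like(t)
        u = spec.sample(t)
        if np.any(u < -1e-12):
            raise ValueError(f"waveform for {odorant!r} is negative")
        return np.clip(u, 0.0, None)

    def active_odorants(self) -> list[str]:
        return [o for o in self.odorant_labels if o in self.specs]


def make_pure_odorant(
    env: OdorantEnvironment, odorant_label: str, amplitude: float, duration: float
) -> ConcentrationWaveform:
    """Constant-concentration stimulus of a single odorant.

    A pure odorant has u_o(t) = 0 for every odorant other than the named one.
    """
    env.odorant_index(odorant_label)  # raises KeyError on absent label
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    return ConcentrationWaveform(
        odorant_labels=list(env.odorant_labels),
        specs={odorant_label: WaveformSpec("constant", {"amplitude": amplitude})},
        duration=duration,
    )


def concentration_modulated_affinity(b_ron: float, d_ron: float, u_o: float) -> float:
    """Dimensionless stimulus drive (b/d)·u for one receptor/odorant pair."""
    b_ron = np.asarray(b_ron, dtype=float)
    d_ron = np.asarray(d_ron, dtype=float)
    u_o = np.asarray(u_o, dtype=float)
    if np.any(d_ron <= 0):
        raise ValueError("dissociation rate must be positive")
    if np.any(u_o < 0):
        raise ValueError("concentration must be nonnegative")
    out = b_ron / d_ron * u_o
    return float(out) if out.ndim == 0 else out


def affinity_sweep_values(
    lo: float, hi: float, count: int, spacing: str = "log"
) -> np.ndarray:
    """Sorted grid of affinity values spanning [lo, hi]."""
    if count < 2:
        raise ValueError("count must be at least 2")
    if not lo < hi:
        raise ValueError("min must be strictly below max")
    if lo < 0:
        raise ValueError("affinity values are nonnegative")
    if spacing == "linear":
        return np.linspace(lo, hi, count)
    if spacing == "log":
        if lo <= 0:
            raise ValueError("log spacing requires min > 0")
        return np.geomspace(lo, hi, count)
    raise ValueError(f"unknown spacing {spacing!r}; use 'linear' or 'log'")


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

def save_environment(
    env: OdorantEnvironment,
    path,
    waveform: ConcentrationWaveform | None = None,
) -> None:
    doc: dict = {
        "receptors": env.receptor_labels,
        "odorants": env.odorant_labels,
        "share_across_neurons": env.share_across_neurons,
        "binding_rates": env.binding_rates[:, :, 0].tolist(),
        "dissociation_rates": env.dissociation_rates[:, :, 0].tolist(),
    }
    if waveform is not None:
        doc["waveforms"] = {
            label: {"kind": spec.kind, "params": dict(spec.params)}
            for label, spec in waveform.specs.items()
        }
        doc["duration"] = waveform.duration
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_environment(path) -> tuple[OdorantEnvironment, ConcentrationWaveform | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    env = OdorantEnvironment.from_matrices(
        np.asarray(doc["binding_rates"], dtype=float),
        np.asarray(doc["dissociation_rates"], dtype=float),
        doc["receptors"],
        doc["odorants"],
    )
    problems = validate_environment(env)
    if problems:
        raise ValueError("invalid environment config: " + "; ".join(problems))
    waveform = None
    if "waveforms" in doc:
        waveform = ConcentrationWaveform(
            odorant_labels=list(doc["odorants"]),
            specs={
                label: WaveformSpec(w["kind"], dict(w.get("params", {})))
                for label, w in doc["waveforms"].items()
            },
            duration=float(doc.get("duration", 1.0)),
        )
    return env, waveform
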