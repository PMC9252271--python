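# antlobe

Composable circuit models of the *Drosophila* antennal lobe (AL): extract
local-neuron connectivity motifs from synaptome tables, assemble executable
glomerular circuits from them, and characterize projection-neuron responses
by simulation.

The AL is the fly's first olfactory relay.  Olfactory sensory neurons
(OSNs) expressing one receptor type converge inside a glomerulus onto its
projection neurons (PNs); a large population of local neurons (LNs) wraps
this feedforward path in feedback loops.  `antlobe` is written for
computational and systems neuroscientists who want to ask *what those
feedback loops do*: it treats each glomerulus as a channel exposing four LN
ports — LN→OSN, LN←OSN, LN→PN, LN←PN — and describes any LN's innervation
of a glomerulus as a 4-digit binary **port connectivity pattern** in that
digit order (15 nonzero patterns; 8 of them close a loop within the
glomerulus, namely those matching `11xx`, `xx11` or `1xx1`).

On top of that algebra the package provides:

* **Motif extraction** (`antlobe.motifs`) — from synapse tables (one row
  per synapse with pre/post ids, site confidences and a glomerulus label),
  derive port patterns and feedback-loop classes with strict thresholds:
  keep synapses with both confidences > 0.70; a pattern is `0000` if the
  LN's glomerular total is < 5; each digit is 1 if its directed count > 5.
  An LN forms an OSN-LN-OSN loop if it exchanges > 5 synapses with OSNs in
  both directions and has < 5 with PNs (symmetrically PN-LN-PN; all four
  directions > 5 is the mixed class).  Plus cell-type graph abstractions
  with GraphML export.
* **Stimulus model** (`antlobe.odor`) — odorants as binding/dissociation
  rate tensors `(b, d)` with concentration waveforms `u(t)`; the
  dimensionless drive `(b/d)·u` (concentration-modulated affinity) is the
  sweep variable of all input/output characterization.
* **Dynamics** (`antlobe.dynamics`, `antlobe.engine`) — receptor
  transduction (exact binding kinetics `dx/dt = b·u·(1−x) − d·x` feeding a
  saturating, adapting current map), Connor–Stevens spiking for every axon
  hillock, α-synapses scaled by anatomical synapse count, and divisive
  presynaptic modulation `1/(1 + κ·s(t))` of OSN axon terminals by LN
  activity — in a deterministic, numba-accelerated fixed-step integrator.
* **Composition** (`antlobe.composer`) — feedback motifs as abstract LNs
  (LN1 ≡ pattern 1100, acting presynaptically on OSN terminals; LN2 ≡ 0011
  with excitatory or inhibitory output; LN3 port-less, bidirectionally
  coupled to other motifs), pairwise glomerulus interconnection, full-AL
  crossbars from arbitrary pattern matrices, ablation/restore, and a port-
  licensing audit.
* **Simulation** (`antlobe.simulate`) — steady-state PN rates under 1-D and
  2-D affinity sweeps and current injection.
* **Synthetic ground truth** (`antlobe.synth`) — planted-pattern
  connectomes and ready-made circuit fixtures, so the whole toolchain is
  testable without downloading any dataset.

## Worked example

Build a 40-OSN / 2-PN glomerulus, attach the presynaptic gain-control motif
LN1, and sweep the affinity axis:

```python
from antlobe.composer import CircuitModel, FeedbackMotif, attach_motif
from antlobe.odor import affinity_sweep_values
from antlobe.simulate import SimulationConfig, sweep_affinity
from antlobe.synth import make_pair_fixture

glom, _, _ = make_pair_fixture()        # the 40-OSN, 2-PN glomerulus
circuit = CircuitModel()
circuit.add_glomerulus(glom)
attach_motif(circuit, FeedbackMotif("LN1"), ["DM4"])

values = affinity_sweep_values(0.01, 100.0, 6, "log")
config = SimulationConfig(duration=2.5, steady_window=1.0)
result = sweep_affinity(circuit, values, config)
print(result.frame().to_string(index=False))
```

```
  affinity  DM4/PN0  DM4/PN1
  0.010000      0.0      0.0
  0.063096      0.0      0.0
  0.398107     59.0     62.0
  2.511886     77.0     80.0
 15.848932     80.0     82.0
100.000000     80.0     82.0
```

Each row is one run at a constant concentration-modulated affinity; the PN
columns are steady-state firing rates (Hz) in the trailing 1 s window.  The
sigmoidal rise to a regulated ~80 Hz plateau is LN1's doing — without it
the same glomerulus saturates near 180 Hz almost as soon as the OSNs fire.
Composition is incremental from here: `attach_motif(...,
FeedbackMotif("LN2", sign="inhibitory"), ...)` adds a PN-side loop,
`add_ln3` couples motifs (and thereby glomeruli), `ablate` removes any
motif in place.

The same toolchain is scriptable from the shell:

```sh
antlobe synth --seed 7 --out-dir tables/          # planted connectome
antlobe extract-motifs tables/synthetic_synapses.csv \
    tables/synthetic_neurons.csv --out report.csv  # patterns + loop classes
antlobe build-circuit --pair --out circuit.json
antlobe sweep circuit.json --points 20 --out sweep.csv
```

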