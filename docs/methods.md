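# Methods

`antlobe` models the *Drosophila* antennal lobe (AL) as a composition of
glomerular channels and local-neuron (LN) feedback motifs, and provides the
extraction machinery that derives those motifs from synaptome tables.  This
note documents the models, the numerical choices, and what the synthetic
test beds do and do not establish.

## The odorant space

Stimuli are described receptor-centrically, not chemically.  An odorant *o*
interacts with receptor type *r* through a binding rate `b[r,o,n]`
(1/(concentration·s)) and a dissociation rate `d[r,o,n]` (1/s); `u_o(t)` is
the concentration waveform.  By default the rates are shared across all
neurons *n* expressing the same receptor.  Concentration units are arbitrary
but consistent: every input/output characterization in the package is done
on the dimensionless **concentration-modulated affinity** `(b/d)·u`, so no
physical calibration is asserted.  Affinity sweeps use a private virtual
odorant per receptor with `b = d = 1`, making the waveform amplitude equal
to the affinity — the sweep variable is then independent of any particular
(b, d) table.

## Transduction (OTP)

Each OSN carries one transduction unit per active odorant.  The binding
stage is the exact kinetics of receptor occupancy `x ∈ [0, 1]`:

    dx/dt = b·u·(1 − x) − d·x ,    x* = b·u / (b·u + d)

integrated with the exact exponential update for piecewise-constant `u`, so
the fixed point is reached to machine precision at any step size.
Downstream, occupancy is converted to current through a saturating map with
one slow adaptation state `z`:

    dz/dt = (x − z)/τ_z ,    I = I_max · x / (x + K·(1 + γ·z))

with `I_max = 60 µA/cm²`, `K = 0.2`, `γ = 0.5`, `τ_z = 150 ms`
(`data/neuron_params.yaml`).  This cascade is deliberately minimal: it
preserves the two properties the steady-state characterization relies on —
the output current is strictly increasing and saturating in `(b/d)·u` — and
nothing downstream depends on its finer temporal structure.  It is not a
fit to transduction-current recordings.

## Spike generation

All axon hillocks (OSN, PN, LN) are Connor–Stevens point neurons with the
canonical parameter set (C = 1 µF/cm²; ḡ_Na = 120, ḡ_K = 20, ḡ_A = 47.7,
ḡ_L = 0.3 mS/cm²; E_Na = 55, E_K = −72, E_A = −75, E_L = −17 mV; standard
18 °C rate functions).  The A-current makes the model Type I: firing rates
rise continuously from zero above rheobase (≈ 8.5 µA/cm²), which is what
lets the PN input/output curves grade smoothly instead of stepping.  The
model rests near −68 mV and is quiescent without input.  Every value is in
`data/neuron_params.yaml`.

Spikes are upward crossings of 0 mV with a 2 ms lockout.  Both choices are
conventions fixed for reproducibility; the lockout only guards against
double-detection on one action potential (the refractory dynamics themselves
come from the conductances).

## Synapses and presynaptic terminals

Synapses are α-conductances: a presynaptic spike at `t_s` contributes
`ḡ·((t−t_s)/τ)·exp(1−(t−t_s)/τ)`, peaking at `ḡ` after `τ`; the current is
`g·(E_rev − V_post)` with `E_rev = 0 mV` (excitatory) or −80 mV
(inhibitory).  Anatomical synapse count scales conductance linearly,
`ḡ_edge = ḡ_unit · count` — the simplest monotone mapping.  Feedforward
OSN→PN synapses use τ = 5 ms; LN-associated synapses use τ = 20 ms,
reflecting the slower local-neuron transmission of the AL.

LN feedback onto OSNs acts on the **axon terminal**, not the soma: the LN
spike train is filtered by a unit-peak α-kernel (τ = 50 ms) into `s(t)`,
and every conductance the terminal drives is multiplied by the divisive
gain

    gain = 1 / (1 + κ·s(t)) ∈ (0, 1] ,    κ = κ_unit · count .

Divisive gain is the simplest form bounded in (0, 1]; it implements
presynaptic inhibition without shunting the OSN's own spiking.

### Operating-point calibration

No quantitative synaptic parameters are available for this abstraction
level (one motif LN stands for a whole LN population), so the defaults were
fixed once, by exploratory simulation, to put the circuit in its intended
operating regime and were not tuned afterwards:

| parameter | value | role |
|---|---|---|
| `g_unit` | 2·10⁻⁴ mS/cm² per synapse | keeps the fully driven PN below depolarization block while still saturating |
| port total | 400 synapses per active port, split over partner neurons | population-level budget of a motif LN's arbor in one glomerulus |
| LN3 edge count | 200 | enough drive for LN3 to relay between motifs |
| `kappa_unit` | 0.005 per synapse | LN1 gain control strong enough for a sigmoid, weak enough not to silence the PN |

With these values the package reproduces the qualitative composition logic:
bare feedforward drives the PN to a saturating plateau; adding LN1 yields a
sigmoidal curve with an interior inflection; excitatory LN2 amplifies the
LN1-regulated response pointwise; inhibitory LN2 suppresses it (ablating it
raises the rate); and LN3 couples otherwise independent glomeruli.

## Motif extraction

Port connectivity patterns are 4-digit codes in the order (LN→OSN, LN←OSN,
LN→PN, LN←PN).  The pipeline applies, in order: a strict confidence filter
(both synaptic sites > 0.70), the glomerular total rule (< 5 synapses →
"0000"), and the strict digit rule (count > 5 → '1').  Feedback-loop
classes use whole-scope directed totals: OSN-LN-OSN requires both OSN
directions > 5 and the PN total (both directions summed) < 5; PN-LN-PN is
symmetric; the mixed class requires all four directed totals > 5.  LNs
enter the AL report only with > 10 total synapses.  All thresholds are
strict and live in `ExtractionConfig`.

Two readings were genuinely open and are resolved as follows, with the
affected rows flagged rather than silently dropped:

* a glomerular total ≥ 5 with no single count > 5 still yields "0000"
  (the two stated rules compose that way); such rows carry
  `ambiguous=True` in the pattern report;
* "fewer than 5 synapses with" the opposite cell type is read as the *sum*
  of both directions;
* per-pattern occurrence tallies are reported both per (LN, glomerulus)
  pair and per LN (`pattern_occurrences`).

vPNs (lateral-horn-only projection neurons) are excluded from PN port
counts by default (`exclude_vpn`), since they mostly receive from other PNs
rather than OSNs.

## Circuit composition

A glomerulus is a channel exposing four LN ports around a feedforward
OSN→PN core whose per-pair synapse counts are *inputs* (taken from a
connectome or a fixture, never recomputed).  Motifs attach one LN per motif
across any set of glomeruli: LN1 ≡ pattern 1100 everywhere it attaches
(its LN→OSN digit realized presynaptically), LN2 ≡ 0011 with configurable
output sign, LN3 has no glomerular ports and connects bidirectionally to
other motifs (inputs excitatory, output inhibitory).  A full-AL circuit is
the crossbar of an arbitrary LN×glomerulus pattern matrix; every '1' digit
becomes a port connection, and an audit operation verifies the converse
(no edge without a licensing digit).  Ablation removes a motif's edges into
a log, is idempotent, and is inverted by `restore`.

Serializing a composed circuit as a synapse table (confidence 1.0, one row
per synapse) and re-extracting patterns reproduces the composing matrix
exactly whenever the port counts clear the digit threshold — the round-trip
consistency check between the composer and the extractor.

## Numerical integration

The engine co-integrates all states on one global grid, `dt = 0.01 ms` by
default:

* gating variables and the membrane equation use exponential-Euler updates
  (V relaxes toward the instantaneous reversal with rate g_tot/C), which is
  robust for these stiff conductances at the chosen step;
* voltage-dependent gate steady states and decay factors are tabulated on a
  0.05 mV grid and linearly interpolated — the tables are rebuilt for each
  dt, so refining dt refines the physics, not just the lookup;
* the α-synapse two-state system and the OTP binding stage have *exact*
  exponential updates (no truncation error for piecewise-constant input);
* waveforms and injected currents are sampled at 1 ms resolution.

The kernel is numba-compiled and fully deterministic: identical inputs give
bitwise-identical spike trains.  Halving dt changes steady-state rates by
well under 2 %.  A membrane potential outside ±500 mV aborts the run with
an error naming the neuron and time.

## Protocols and problem sizes

Steady-state rates are spike counts in a trailing window divided by the
window length.  The default protocol is 4 s with a 1 s window; the
characterization suites use 2.5 s with a 1 s window for 1-D sweeps (1 Hz
rate resolution, needed to resolve monotonicity at the grid spacing) and
2 s with a 0.5 s window for 2-D meshes, sizes chosen so a full
motif-composition study runs in minutes on one core.  Sweeps default to 20
log-spaced points over four decades of affinity (10⁻² – 10²); pair meshes
use 8×8 grids.

## Synthetic test beds

The planted-connectome generator emits tables in the extraction schema with
a known pattern matrix: '1' digits draw counts from 8–12 (strictly above
the digit threshold), '0' digits from 0–1 (so even four zero-ports total
below the glomerular threshold), and decoy synapses with sub-threshold
confidences are added where they would flip '0' digits if the confidence
filter were skipped.  Loop-class ground truth follows from the planted
pattern because the ranges separate cleanly.  Counts are uniform draws, not
fits to any real synaptome — the generator provides separability for
recovery tests, nothing more.  Consequences: 100 % recovery on these tables
shows the thresholds and filters are implemented exactly as specified; it
does *not* show robustness to the count distributions, confidence profiles,
multi-glomerular overlaps or annotation errors of real reconstructions,
where counts near the thresholds are common rather than excluded by
construction.

The circuit fixtures are likewise structural stand-ins: a 40-OSN/2-PN
glomerulus and a 15-OSN/single-PN glomerulus (the single PN with 40–60
contacts per OSN, reflecting its concentrated dendritic field) wired with
the five-motif complement — one LN1 and one LN2 per glomerulus plus one
LN3.  Their synapse counts are seeded draws, so simulation results
characterize the model class at a plausible operating point, not any
measured circuit.

## Known limitations

* The transduction cascade is a minimal monotone-saturating stand-in; it
  does not reproduce measured transduction-current waveforms or spike-
  frequency adaptation profiles of real OSNs.
* One LN per motif (with an optional multiplicity parameter) abstracts away
  LN population heterogeneity.
* No synaptic plasticity, no noise, no conduction delays, no
  multi-compartment morphology; mixtures drive parallel binding channels
  per odorant without competitive interaction at the receptor.
* LN3 wiring is glomerulus-agnostic (it targets motifs, not ports); whether
  biological LN3-like neurons are glomerulus-specific is untested here.
* Physical calibration of the affinity scale (and of "nA-scale" injected
  currents for a point neuron) is intentionally left open; all results are
  stated on the model's own scales.
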