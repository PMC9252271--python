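"""Composable executable circuits: glomeruli, feedback motifs, crossbars.

A glomerulus is modeled as a channel: a group of OSNs (one receptor type,
each an OTP unit feeding a Connor–Stevens axon hillock), a group of PNs
(Connor–Stevens), feedforward α-synapses weighted by anatomical synapse
counts, and four open *ports* through which LNs connect — LN→OSN, LN←OSN,
LN→PN, LN←PN, in the digit order of the port connectivity pattern.

Feedback motifs are abstract LNs:

* **LN1** — pattern "1100" in every attached glomerulus: it is driven by the
  OSNs and feeds back onto their axon terminals *presynaptically*
  (divisively), the canonical gain-control loop.
* **LN2** — pattern "0011": a loop with the PNs; its output sign is
  configurable (excitatory by default, inhibitory as a toggle).
* **LN3** — no glomerular ports at all; it connects bidirectionally to other
  motifs (inputs excitatory, output inhibitory by default) and is the
  substrate of cross-glomerular interaction.

Each motif is realized as one LN neuron (a ``multiplicity`` parameter allows
k identical copies).  Synapse count scales conductance linearly:
ḡ_edge = ḡ_unit × count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dynamics import default_params

__all__ = [
    "GlomerulusModel",
    "FeedbackMotif",
    "CircuitNeuron",
    "CircuitEdge",
    "CircuitModel",
    "PairMotifSpec",
    "build_glomerulus",
    "attach_motif",
    "add_ln3",
    "interconnect_pair",
    "build_crossbar",
    "ablate",
    "restore",
    "audit_port_licensing",
]

PATTERN_LN1 = "1100"
PATTERN_LN2 = "0011"

# A motif LN stands for a whole population of biological LNs, so its synapse
# budget at a port is a population-level total, split evenly among the
# partner neurons of that port.
DEFAULT_PORT_TOTAL = 400
DEFAULT_LN3_COUNT = 200


@dataclass
class GlomerulusModel:
    """One glomerular channel: OSN group, PN group, feedforward matrix, 4 ports."""

    name: str
    n_osn: int
    n_pn: int
    ff_counts: np.ndarray  # (n_osn, n_pn) anatomical synapse counts
    receptor_type: str = ""

    def __post_init__(self) -> None:
        if self.n_osn < 1 or self.n_pn < 1:
            raise ValueError("a glomerulus needs at least 1 OSN and 1 PN")
        self.ff_counts = np.asarray(self.ff_counts)
        if self.ff_counts.shape != (self.n_osn, self.n_pn):
            raise ValueError(
                f"ff_counts shape {self.ff_counts.shape} does not match "
                f"({self.n_osn}, {self.n_pn})"
            )
        if np.any(self.ff_counts < 0) or not np.issubdtype(self.ff_counts.dtype, np.integer):
            raise ValueError("ff_counts must be nonnegative integers")
        if not self.receptor_type:
            self.receptor_type = f"OR-{self.name}"

    @property
    def osn_ids(self) -> list[str]:
        return [f"{self.name}/OSN{i}" for i in range(self.n_osn)]

    @property
    def pn_ids(self) -> list[str]:
        return [f"{self.name}/PN{i}" for i in range(self.n_pn)]


def build_glomerulus(
    name: str,
    n_osn: int,
    n_pn: int,
    ff_counts,
    receptor_type: str = "",
) -> GlomerulusModel:
    """Validate and build a glomerulus model (counts are inputs, not recomputed)."""
    g = GlomerulusModel(name, n_osn, n_pn, np.asarray(ff_counts), receptor_type)
    if g.ff_counts.sum() == 0:
        warnings.warn(
            f"glomerulus {name!r} has an all-zero feedforward matrix "
            f"(OSNs are disconnected from PNs)",
            stacklevel=2,
        )
    return g


@dataclass
class FeedbackMotif:
    """Abstract LN with per-glomerulus port patterns and an output sign."""

    kind: str  # LN1 | LN2 | LN3 | custom
    patterns: dict[str, str] = field(default_factory=dict)
    sign: str = "excitatory"
    port_total: int = DEFAULT_PORT_TOTAL  # synapses per active port, split over partners
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.kind not in {"LN1", "LN2", "LN3", "custom"}:
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if self.sign not in {"excitatory", "inhibitory"}:
            raise ValueError("sign must be 'excitatory' or 'inhibitory'")
        if self.kind == "LN3" and self.patterns:
            raise ValueError("LN3 has no glomerular ports")
        for glom, p in self.patterns.items():
            if self.kind == "LN1" and p != PATTERN_LN1:
                raise ValueError(f"LN1 must use pattern {PATTERN_LN1} (got {p!r})")
            if self.kind == "LN2" and p != PATTERN_LN2:
                raise ValueError(f"LN2 must use pattern {PATTERN_LN2} (got {p!r})")
            if len(p) != 4 or any(ch not in "01" for ch in p):
                raise ValueError(f"malformed pattern {p!r} for glomerulus {glom!r}")

    def pattern_for(self, glomerulus: str) -> str:
        if self.kind == "LN1":
            return PATTERN_LN1
        if self.kind == "LN2":
            return PATTERN_LN2
        return self.patterns.get(glomerulus, "0000")


@dataclass(frozen=True)
class CircuitNeuron:
    neuron_id: str
    cell_class: str  # OSN | PN | LN
    glomerulus: str = ""
    receptor_type: str = ""
    motif_id: str = ""


@dataclass(frozen=True)
class CircuitEdge:
    """One synaptic connection (pre → post) with anatomical count and sign via E_rev."""

    pre: str
    post: str
    count: int
    sign: str = "excitatory"  # ignored when presynaptic
    presynaptic: bool = False  # acts on the OSN axon terminal, not the soma
    kind: str = "port"  # feedforward | port | ln
    glomerulus: str = ""
    motif_id: str = ""


class CircuitModel:
    """Executable network: neurons, synapse edges, glomeruli and the port wiring table."""

    def __init__(self, params: dict | None = None):
        self.neurons: dict[str, CircuitNeuron] = {}
        self.edges: list[CircuitEdge] = []
        self.glomeruli: dict[str, GlomerulusModel] = {}
        self.motifs: dict[str, FeedbackMotif] = {}
        self._ablated: dict[str, list[CircuitEdge]] = {}
        self.params = params or default_params()

    # -- construction -------------------------------------------------------

    def _add_neuron(self, neuron: CircuitNeuron) -> None:
        if neuron.neuron_id in self.neurons:
            raise ValueError(f"duplicate neuron id {neuron.neuron_id!r}")
        self.neurons[neuron.neuron_id] = neuron

    def _add_edge(self, edge: CircuitEdge) -> None:
        if edge.pre not in self.neurons or edge.post not in self.neurons:
            raise ValueError(f"edge {edge.pre!r}->{edge.post!r} references unknown neuron")
        self.edges.append(edge)

    def add_glomerulus(self, glom: GlomerulusModel) -> "CircuitModel":
        if glom.name in self.glomeruli:
            raise ValueError(f"duplicate glomerulus name {glom.name!r}")
        self.glomeruli[glom.name] = glom
        for osn in glom.osn_ids:
            self._add_neuron(
                CircuitNeuron(osn, "OSN", glom.name, glom.receptor_type)
            )
        for pn in glom.pn_ids:
            self._add_neuron(CircuitNeuron(pn, "PN", glom.name))
        for i, osn in enumerate(glom.osn_ids):
            for j, pn in enumerate(glom.pn_ids):
                count = int(glom.ff_counts[i, j])
                if count > 0:
                    self._add_edge(
                        CircuitEdge(
                            osn, pn, count, "excitatory",
                            kind="feedforward", glomerulus=glom.name,
                        )
                    )
        return self

    # -- queries -------------------------------------------------------------

    def motif_neurons(self, motif_id: str) -> list[str]:
        return [n.neuron_id for n in self.neurons.values() if n.motif_id == motif_id]

    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def ln_edges(self) -> list[CircuitEdge]:
        return [
            e
            for e in self.edges
            if self.neurons[e.pre].cell_class == "LN"
            or self.neurons[e.post].cell_class == "LN"
        ]

    # -- serialization -------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "neurons": [asdict(n) for n in self.neurons.values()],
            "edges": [asdict(e) for e in self.edges],
            "glomeruli": [
                {
                    "name": g.name,
                    "n_osn": g.n_osn,
                    "n_pn": g.n_pn,
                    "receptor_type": g.receptor_type,
                    "ff_counts": g.ff_counts.tolist(),
                }
                for g in self.glomeruli.values()
            ],
            "motifs": {
                mid: {
                    "kind": m.kind,
                    "patterns": m.patterns,
                    "sign": m.sign,
                    "port_total": m.port_total,
                }
                for mid, m in self.motifs.items()
            },
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "CircuitModel":
        if isinstance(path_or_text, str) and path_or_text.lstrip().startswith("{"):
            doc = json.loads(path_or_text)
        else:
            with open(path_or_text) as fh:
                doc = json.load(fh)
        circuit = cls()
        for g in doc.get("glomeruli", []):
            circuit.glomeruli[g["name"]] = GlomerulusModel(
                g["name"], g["n_osn"], g["n_pn"],
                np.asarray(g["ff_counts"], dtype=int), g["receptor_type"],
            )
        for n in doc["neurons"]:
            circuit.neurons[n["neuron_id"]] = CircuitNeuron(**n)
        for e in doc["edges"]:
            circuit.edges.append(CircuitEdge(**e))
        for mid, m in doc.get("motifs", {}).items():
            circuit.motifs[mid] = FeedbackMotif(
                m["kind"], dict(m["patterns"]), m["sign"], m["port_total"]
            )
        return circuit

    def to_graph(self):
        """Abstract diagram as a networkx DiGraph (edge weight = synapse count)."""
        import networkx as nx

        g = nx.DiGraph()
        for n in self.neurons.values():
            g.add_node(
                n.neuron_id,
                cell_class=n.cell_class,
                glomerulus=n.glomerulus,
                motif=n.motif_id,
            )
        for e in self.edges:
            w = g.edges[e.pre, e.post]["weight"] if g.has_edge(e.pre, e.post) else 0
            g.add_edge(
                e.pre, e.post, weight=w + e.count, kind=e.kind,
                presynaptic=e.presynaptic,
            )
        return g

    def to_synapse_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Serialize as synaptome tables (one row per synapse, confidence 1).

        The output conforms to the extraction schema of
        :mod:`antlobe.motifs`, so port patterns can be re-derived from a
        composed circuit (the round trip used to validate crossbars).
        """
        syn_rows = []
        for e in self.edges:
            for _ in range(e.count):
                syn_rows.append(
                    {
                        "pre_id": e.pre,
                        "post_id": e.post,
                        "pre_conf": 1.0,
                        "post_conf": 1.0,
                        "glomerulus": e.glomerulus,
                    }
                )
        neuron_rows = []
        for n in self.neurons.values():
            neuron_rows.append(
                {
                    "neuron_id": n.neuron_id,
                    "cell_class": n.cell_class,
                    "receptor_type": n.receptor_type,
                    "pn_subtype": "uPN-adPN" if n.cell_class == "PN" else "none",
                    "glomeruli": n.glomerulus,
                }
            )
        return pd.DataFrame(syn_rows), pd.DataFrame(neuron_rows)


# ---------------------------------------------------------------------------
# Motif attachment
# ---------------------------------------------------------------------------

def _next_motif_id(circuit: CircuitModel, kind: str) -> str:
    k = 1
    while f"{kind}#{k}" in circuit.motifs or f"{kind}#{k}" in circuit._ablated:
        k += 1
    return f"{kind}#{k}"


def attach_motif(
    circuit: CircuitModel,
    motif: FeedbackMotif,
    glomeruli: list[str],
    motif_id: str | None = None,
) -> str:
    """Add one LN realizing ``motif`` across the named glomeruli.

    Edges are created exactly at the ports whose pattern digit is 1:
    LN→OSN connections are flagged presynaptic (terminal modulation);
    OSN→LN and PN→LN inputs are excitatory; LN→PN outputs carry the motif's
    sign.  Returns the motif id.
    """
    if motif.kind == "LN3":
        raise ValueError("LN3 connects to other motifs, not to glomerular ports; use add_ln3")
    for name in glomeruli:
        if name not in circuit.glomeruli:
            raise KeyError(f"unknown glomerulus {name!r}")
    mid = motif_id or _next_motif_id(circuit, motif.kind)
    if mid in circuit.motifs:
        raise ValueError(f"duplicate motif id {mid!r}")
    circuit.motifs[mid] = motif
    ln_id = f"{mid}/LN"
    circuit._add_neuron(CircuitNeuron(ln_id, "LN", motif_id=mid))
    n_edges = 0
    for name in glomeruli:
        glom = circuit.glomeruli[name]
        pattern = motif.pattern_for(name)
        if pattern == "0000":
            warnings.warn(
                f"motif {mid!r} has pattern 0000 in glomerulus {name!r}: no edges",
                stacklevel=2,
            )
            continue
        c_osn = max(1, round(motif.port_total / glom.n_osn))
        c_pn = max(1, round(motif.port_total / glom.n_pn))
        if pattern[0] == "1":
            for osn in glom.osn_ids:
                circuit._add_edge(
                    CircuitEdge(ln_id, osn, c_osn, "inhibitory", presynaptic=True,
                                glomerulus=name, motif_id=mid)
                )
                n_edges += 1
        if pattern[1] == "1":
            for osn in glom.osn_ids:
                circuit._add_edge(
                    CircuitEdge(osn, ln_id, c_osn, "excitatory",
                                glomerulus=name, motif_id=mid)
                )
                n_edges += 1
        if pattern[2] == "1":
            for pn in glom.pn_ids:
                circuit._add_edge(
                    CircuitEdge(ln_id, pn, c_pn, motif.sign,
                                glomerulus=name, motif_id=mid)
                )
                n_edges += 1
        if pattern[3] == "1":
            for pn in glom.pn_ids:
                circuit._add_edge(
                    CircuitEdge(pn, ln_id, c_pn, "excitatory",
                                glomerulus=name, motif_id=mid)
                )
                n_edges += 1
    return mid


def add_ln3(
    circuit: CircuitModel,
    targets: list[str],
    count: int = DEFAULT_LN3_COUNT,
    motif_id: str | None = None,
) -> str:
    """Add an LN3 motif with bidirectional edges to every target motif.

    Inputs to LN3 are excitatory; LN3's output is inhibitory.  Targets must
    be LN1/LN2 (or custom) motifs already in the circuit.
    """
    if not targets:
        raise ValueError("LN3 needs at least one target motif")
    for t in targets:
        if t not in circuit.motifs:
            raise ValueError(f"unknown target motif {t!r}")
        if circuit.motifs[t].kind == "LN3":
            raise ValueError("LN3 may not target another LN3")
    mid = motif_id or _next_motif_id(circuit, "LN3")
    motif = FeedbackMotif("LN3", sign="inhibitory", port_total=count)
    circuit.motifs[mid] = motif
    ln3_id = f"{mid}/LN"
    circuit._add_neuron(CircuitNeuron(ln3_id, "LN", motif_id=mid))
    for t in targets:
        for target_ln in circuit.motif_neurons(t):
            if target_ln == ln3_id:
                continue
            circuit._add_edge(
                CircuitEdge(target_ln, ln3_id, count, "excitatory",
                            kind="ln", motif_id=mid)
            )
            circuit._add_edge(
                CircuitEdge(ln3_id, target_ln, count, "inhibitory",
                            kind="ln", motif_id=mid)
            )
    return mid


@dataclass
class PairMotifSpec:
    """Motif complement of a two-glomerulus circuit.

    The default is the five-motif composition: one LN1 and one LN2 per
    glomerulus plus one LN3 bidirectionally connected to all four.
    """

    ln1_per_glomerulus: bool = True
    ln2_per_glomerulus: bool = True
    shared_ln2: bool = False  # a single LN2 spanning both glomeruli instead
    with_ln3: bool = True
    ln2_sign: str = "excitatory"
    port_total: int = DEFAULT_PORT_TOTAL


def interconnect_pair(
    glom_a: GlomerulusModel,
    glom_b: GlomerulusModel,
    spec: PairMotifSpec | None = None,
) -> CircuitModel:
    """Compose two glomeruli with the configured feedback motifs."""
    if glom_a.name == glom_b.name:
        raise ValueError("glomeruli must have distinct names")
    spec = spec or PairMotifSpec()
    circuit = CircuitModel()
    circuit.add_glomerulus(glom_a)
    circuit.add_glomerulus(glom_b)
    motif_ids: list[str] = []
    if spec.ln1_per_glomerulus:
        for g in (glom_a, glom_b):
            motif_ids.append(
                attach_motif(
                    circuit,
                    FeedbackMotif("LN1", port_total=spec.port_total),
                    [g.name],
                )
            )
    if spec.shared_ln2:
        motif_ids.append(
            attach_motif(
                circuit,
                FeedbackMotif("LN2", sign=spec.ln2_sign, port_total=spec.port_total),
                [glom_a.name, glom_b.name],
            )
        )
    elif spec.ln2_per_glomerulus:
        for g in (glom_a, glom_b):
            motif_ids.append(
                attach_motif(
                    circuit,
                    FeedbackMotif("LN2", sign=spec.ln2_sign, port_total=spec.port_total),
                    [g.name],
                )
            )
    if spec.with_ln3:
        add_ln3(circuit, motif_ids)
    return circuit


def build_crossbar(
    glomeruli: list[GlomerulusModel],
    ln_patterns,
    port_total: int = DEFAULT_PORT_TOTAL,
    ln_ln_count: int = 0,
) -> CircuitModel:
    """Full-AL composition: every LN row of the pattern matrix becomes a motif.

    ``ln_patterns`` maps LN name → {glomerulus → 4-digit pattern} (a pandas
    DataFrame with glomerulus columns also works).  Every '1' digit becomes a
    port connection; ``ln_ln_count`` > 0 additionally wires all LN pairs
    bidirectionally (the LN-LN submatrix).
    """
    if isinstance(ln_patterns, pd.DataFrame):
        ln_patterns = {
            str(ln): {
                str(g): str(p)
                for g, p in row.items()
                if isinstance(p, str) and p != "0000"
            }
            for ln, row in ln_patterns.iterrows()
        }
    circuit = CircuitModel()
    for g in glomeruli:
        circuit.add_glomerulus(g)
    known = set(circuit.glomeruli)
    for ln_name in sorted(ln_patterns):
        patterns = {g: p for g, p in ln_patterns[ln_name].items() if p != "0000"}
        unknown = set(patterns) - known
        if unknown:
            raise ValueError(
                f"LN {ln_name!r} has patterns for unknown glomeruli: {sorted(unknown)}"
            )
        if not patterns:
            warnings.warn(f"LN {ln_name!r} has no nonzero patterns: no edges", stacklevel=2)
        motif = FeedbackMotif("custom", patterns, port_total=port_total)
        attach_motif(circuit, motif, sorted(patterns), motif_id=f"xbar:{ln_name}")
    if ln_ln_count > 0:
        ln_ids = [n.neuron_id for n in circuit.neurons.values() if n.cell_class == "LN"]
        for i, a in enumerate(ln_ids):
            for b in ln_ids[i + 1:]:
                circuit._add_edge(CircuitEdge(a, b, ln_ln_count, "inhibitory", kind="ln"))
                circuit._add_edge(CircuitEdge(b, a, ln_ln_count, "inhibitory", kind="ln"))
    return circuit


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------

def ablate(circuit: CircuitModel, motif_id: str) -> CircuitModel:
    """Remove all edges of a motif (idempotent); the LN neuron stays, disconnected.

    The removed edges are logged so :func:`restore` can invert the operation.
    """
    if motif_id not in circuit.motifs and motif_id not in circuit._ablated:
        raise KeyError(f"unknown motif {motif_id!r}")
    removed = [e for e in circuit.edges if e.motif_id == motif_id]
    circuit.edges = [e for e in circuit.edges if e.motif_id != motif_id]
    if motif_id not in circuit._ablated:
        circuit._ablated[motif_id] = removed
    return circuit


def restore(circuit: CircuitModel, motif_id: str) -> CircuitModel:
    """Re-insert the logged edges of an ablated motif."""
    if motif_id not in circuit._ablated:
        raise KeyError(f"motif {motif_id!r} is not ablated")
    circuit.edges.extend(circuit._ablated.pop(motif_id))
    return circuit


# ---------------------------------------------------------------------------
# Audit
# ---------------------------------------------------------------------------

def audit_port_licensing(circuit: CircuitModel) -> list[str]:
    """Check that every LN port edge is licensed by a '1' digit of its motif's pattern.

    Returns a list of violations (empty when the circuit is consistent).
    """
    violations: list[str] = []
    for e in circuit.edges:
        if e.kind != "port" or not e.motif_id:
            continue
        motif = circuit.motifs.get(e.motif_id)
        if motif is None:
            violations.append(f"edge {e.pre}->{e.post}: unknown motif {e.motif_id!r}")
            continue
        pattern = motif.pattern_for(e.glomerulus)
        pre_class = circuit.neurons[e.pre].cell_class
        post_class = circuit.neurons[e.post].cell_class
        if pre_class == "LN" and post_class == "OSN":
            digit = 0
        elif pre_class == "OSN" and post_class == "LN":
            digit = 1
        elif pre_class == "LN" and post_class == "PN":
            digit = 2
        elif pre_class == "PN" and post_class == "LN":
            digit = 3
        else:
            violations.append(
                f"edge {e.pre}->{e.post}: not a port connection ({pre_class}->{post_class})"
            )
            continue
        if pattern[digit] != "1":
            violations.append(
                f"edge {e.pre}->{e.post}: digit {digit} of pattern {pattern} "
                f"({e.motif_id} @ {e.glomerulus}) does not license it"
            )
    return violations
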