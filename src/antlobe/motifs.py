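"""Port connectivity patterns and feedback-loop classes from synapse tables.

A glomerulus exposes four *ports* through which local neurons (LNs) interact
with it: LN→OSN, LN←OSN, LN→PN, LN←PN.  An LN's innervation of a glomerulus
is summarized by a 4-digit binary *port connectivity pattern* in that digit
order — e.g. "1100" is an LN that loops with the OSNs only.  Patterns are
derived from synapse counts with strict thresholds:

* only synapses whose presynaptic AND postsynaptic confidences exceed 0.70
  are counted;
* a pattern is "0000" when the LN's glomerular total is below 5 synapses;
* otherwise each digit is 1 when its directed count exceeds 5.

Feedback-loop classes follow the same style on whole-scope totals: an LN
forms an OSN-LN-OSN loop when it exchanges more than 5 synapses with OSNs in
both directions and has fewer than 5 with PNs (summed over both directions);
symmetrically for PN-LN-PN; an OSN/PN-LN-OSN/PN loop requires all four
directed totals above 5.

All thresholds are strict inequalities and live in
:class:`ExtractionConfig`, so a user who reads "larger than 5" differently
can change them in one place.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CellClass",
    "FeedbackLoopClass",
    "NeuronRecord",
    "SynapseRecord",
    "PortCounts",
    "ExtractionConfig",
    "ParseError",
    "read_tables",
    "filter_by_confidence",
    "count_port_synapses",
    "derive_port_pattern",
    "enumerate_port_patterns",
    "is_feedback_pattern",
    "classify_feedback_loop",
    "select_al_lns",
    "celltype_graph",
    "pattern_report",
    "write_graphml",
]

SYNAPSE_COLUMNS = ["pre_id", "post_id", "pre_conf", "post_conf", "glomerulus"]
NEURON_COLUMNS = ["neuron_id", "cell_class", "receptor_type", "pn_subtype", "glomeruli"]

PORT_NAMES = ("ln_to_osn", "osn_to_ln", "ln_to_pn", "pn_to_ln")


class CellClass(str, enum.Enum):
    OSN = "OSN"
    PN = "PN"
    LN = "LN"


PN_SUBTYPES = {"uPN-adPN", "uPN-lPN", "vPN", "none"}


class FeedbackLoopClass(str, enum.Enum):
    OSN_LN_OSN = "OSN-LN-OSN"
    PN_LN_PN = "PN-LN-PN"
    MIXED = "OSN/PN-LN-OSN/PN"
    NONE = "none"


@dataclass(frozen=True)
class NeuronRecord:
    neuron_id: str
    cell_class: CellClass
    receptor_type: str = ""
    pn_subtype: str = "none"
    glomeruli: frozenset = frozenset()


@dataclass(frozen=True)
class SynapseRecord:
    pre_id: str
    post_id: str
    pre_confidence: float
    post_confidence: float
    glomerulus: str = ""


@dataclass(frozen=True)
class PortCounts:
    """Directed synapse counts of one (LN, glomerulus) pair, port order as in PORT_NAMES."""

    ln_to_osn: int = 0
    osn_to_ln: int = 0
    ln_to_pn: int = 0
    pn_to_ln: int = 0

    def total(self) -> int:
        return self.ln_to_osn + self.osn_to_ln + self.ln_to_pn + self.pn_to_ln

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.ln_to_osn, self.osn_to_ln, self.ln_to_pn, self.pn_to_ln)


@dataclass(frozen=True)
class ExtractionConfig:
    """Thresholds of the extraction pipeline.  All comparisons are strict."""

    confidence_threshold: float = 0.70  # keep a synapse iff both confidences > this
    pattern_total_threshold: int = 5  # pattern is 0000 if glomerular total < this
    digit_threshold: int = 5  # digit is 1 iff directed count > this
    loop_high: int = 5  # loop side counts must be > this
    loop_low: int = 5  # opposite-side total must be < this
    ln_inclusion_min: int = 10  # LN kept iff total synapse count > this
    exclude_vpn: bool = True  # drop vPNs from PN port counts


class ParseError(ValueError):
    """Raised when an input table violates the documented schema."""


# ---------------------------------------------------------------------------
# Table input
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)


def read_tables(synapse_file, neuron_file) -> tuple[list[SynapseRecord], list[NeuronRecord]]:
    """Parse and validate the synapse and neuron annotation tables (CSV or TSV).

    Synapse columns: ``pre_id, post_id, pre_conf, post_conf, glomerulus``.
    Neuron columns: ``neuron_id, cell_class, receptor_type, pn_subtype,
    glomeruli`` (semicolon-joined set).  Errors carry the offending row
    number (1-based, excluding the header).
    """
    ndf = _read_delimited(neuron_file)
    missing = [c for c in NEURON_COLUMNS if c not in ndf.columns]
    if missing:
        raise ParseError(f"neuron table is missing column(s): {', '.join(missing)}")
    neurons: list[NeuronRecord] = []
    seen: set[str] = set()
    for row_no, row in enumerate(ndf.itertuples(index=False), start=1):
        nid = str(row.neuron_id)
        if nid in seen:
            raise ParseError(f"neuron table row {row_no}: duplicate neuron_id {nid!r}")
        seen.add(nid)
        try:
            cell_class = CellClass(str(row.cell_class))
        except ValueError:
            raise ParseError(
                f"neuron table row {row_no}: cell_class {row.cell_class!r} "
                f"not one of OSN/PN/LN"
            ) from None
        receptor = "" if pd.isna(row.receptor_type) else str(row.receptor_type)
        subtype = "none" if pd.isna(row.pn_subtype) else str(row.pn_subtype)
        if subtype not in PN_SUBTYPES:
            raise ParseError(
                f"neuron table row {row_no}: pn_subtype {subtype!r} "
                f"not one of {sorted(PN_SUBTYPES)}"
            )
        if cell_class is CellClass.OSN and not receptor:
            raise ParseError(f"neuron table row {row_no}: OSN {nid!r} lacks a receptor_type")
        if cell_class is CellClass.PN and subtype == "none":
            raise ParseError(f"neuron table row {row_no}: PN {nid!r} lacks a pn_subtype")
        gloms = (
            frozenset()
            if pd.isna(row.glomeruli) or not str(row.glomeruli)
            else frozenset(str(row.glomeruli).split(";"))
        )
        neurons.append(NeuronRecord(nid, cell_class, receptor, subtype, gloms))

    sdf = _read_delimited(synapse_file)
    missing = [c for c in SYNAPSE_COLUMNS if c not in sdf.columns]
    if missing:
        raise ParseError(f"synapse table is missing column(s): {', '.join(missing)}")
    synapses: list[SynapseRecord] = []
    for row_no, row in enumerate(sdf.itertuples(index=False), start=1):
        pre, post = str(row.pre_id), str(row.post_id)
        for nid in (pre, post):
            if nid not in seen:
                raise ParseError(
                    f"synapse table row {row_no}: neuron id {nid!r} "
                    f"does not appear in the neuron table"
                )
        try:
            pre_c, post_c = float(row.pre_conf), float(row.post_conf)
        except (TypeError, ValueError):
            raise ParseError(f"synapse table row {row_no}: non-numeric confidence") from None
        if not (0.0 <= pre_c <= 1.0 and 0.0 <= post_c <= 1.0):
            raise ParseError(
                f"synapse table row {row_no}: confidence outside [0, 1] "
                f"({pre_c}, {post_c})"
            )
        glom = "" if pd.isna(row.glomerulus) else str(row.glomerulus)
        synapses.append(SynapseRecord(pre, post, pre_c, post_c, glom))
    return synapses, neurons


def filter_by_confidence(
    synapses: list[SynapseRecord], cfg: ExtractionConfig | None = None
) -> list[SynapseRecord]:
    """Keep a synapse iff both site confidences are strictly above the threshold."""
    cfg = cfg or ExtractionConfig()
    t = cfg.confidence_threshold
    return [s for s in synapses if s.pre_confidence > t and s.post_confidence > t]


# ---------------------------------------------------------------------------
# Pattern derivation
# ---------------------------------------------------------------------------

def _index_neurons(neurons: list[NeuronRecord]) -> dict[str, NeuronRecord]:
    return {n.neuron_id: n for n in neurons}


def _is_counted_pn(rec: NeuronRecord, cfg: ExtractionConfig) -> bool:
    if rec.cell_class is not CellClass.PN:
        return False
    return not (cfg.exclude_vpn and rec.pn_subtype == "vPN")


def count_port_synapses(
    ln_id: str,
    glomerulus: str,
    synapses: list[SynapseRecord],
    neurons: list[NeuronRecord] | dict[str, NeuronRecord],
    cfg: ExtractionConfig | None = None,
) -> PortCounts:
    """Count the four directed port totals of an LN within one glomerulus.

    Only synapses labelled with the query glomerulus contribute; vPN partners
    are excluded from the PN ports unless the config says otherwise.
    """
    cfg = cfg or ExtractionConfig()
    idx = neurons if isinstance(neurons, dict) else _index_neurons(neurons)
    ln = idx.get(ln_id)
    if ln is None or ln.cell_class is not CellClass.LN:
        raise ValueError(f"{ln_id!r} is not an LN")
    c = [0, 0, 0, 0]
    for s in synapses:
        if s.glomerulus != glomerulus:
            continue
        if s.pre_id == ln_id:
            partner = idx.get(s.post_id)
            if partner is None:
                continue
            if partner.cell_class is CellClass.OSN:
                c[0] += 1
            elif _is_counted_pn(partner, cfg):
                c[2] += 1
        elif s.post_id == ln_id:
            partner = idx.get(s.pre_id)
            if partner is None:
                continue
            if partner.cell_class is CellClass.OSN:
                c[1] += 1
            elif _is_counted_pn(partner, cfg):
                c[3] += 1
    return PortCounts(*c)


def derive_port_pattern(counts: PortCounts, cfg: ExtractionConfig | None = None) -> str:
    """Map port counts to the 4-digit code.

    Below-total pairs collapse to "0000"; above it, each digit is set iff its
    count strictly exceeds the digit threshold.  A total at-or-above the
    threshold with no single count above the digit threshold also yields
    "0000" (the two rules compose that way); see :func:`pattern_is_ambiguous`.
    """
    cfg = cfg or ExtractionConfig()
    if counts.total() < cfg.pattern_total_threshold:
        return "0000"
    return "".join("1" if c > cfg.digit_threshold else "0" for c in counts.as_tuple())


def pattern_is_ambiguous(counts: PortCounts, cfg: ExtractionConfig | None = None) -> bool:
    """True when the glomerular total passes but no digit does (flagged band)."""
    cfg = cfg or ExtractionConfig()
    return counts.total() >= cfg.pattern_total_threshold and all(
        c <= cfg.digit_threshold for c in counts.as_tuple()
    )


def enumerate_port_patterns() -> list[str]:
    """All 15 nonzero port connectivity patterns, sorted ("0000" means no connection)."""
    codes = ["".join(bits) for bits in itertools.product("01", repeat=4)]
    return sorted(c for c in codes if c != "0000")


def is_feedback_pattern(pattern: str) -> bool:
    """True iff the pattern closes a loop within the glomerulus: 11xx, xx11 or 1xx1.

    Eight of the fifteen nonzero patterns qualify.
    """
    if len(pattern) != 4 or any(ch not in "01" for ch in pattern):
        raise ValueError(f"malformed port pattern {pattern!r}")
    return (
        (pattern[0] == "1" and pattern[1] == "1")
        or (pattern[2] == "1" and pattern[3] == "1")
        or (pattern[0] == "1" and pattern[3] == "1")
    )


# ---------------------------------------------------------------------------
# Feedback-loop classification
# ---------------------------------------------------------------------------

def _directed_totals(
    ln_id: str,
    glomerulus_scope: str | None,
    synapses: list[SynapseRecord],
    idx: dict[str, NeuronRecord],
    cfg: ExtractionConfig,
) -> tuple[int, int, int, int]:
    """(from_osn, to_osn, from_pn, to_pn) totals within the scope (None = everywhere)."""
    from_osn = to_osn = from_pn = to_pn = 0
    for s in synapses:
        if glomerulus_scope is not None and s.glomerulus != glomerulus_scope:
            continue
        if s.post_id == ln_id:
            partner = idx.get(s.pre_id)
            if partner is None:
                continue
            if partner.cell_class is CellClass.OSN:
                from_osn += 1
            elif _is_counted_pn(partner, cfg):
                from_pn += 1
        elif s.pre_id == ln_id:
            partner = idx.get(s.post_id)
            if partner is None:
                continue
            if partner.cell_class is CellClass.OSN:
                to_osn += 1
            elif _is_counted_pn(partner, cfg):
                to_pn += 1
    return from_osn, to_osn, from_pn, to_pn


def classify_totals(
    from_osn: int, to_osn: int, from_pn: int, to_pn: int,
    cfg: ExtractionConfig | None = None,
) -> FeedbackLoopClass:
    """Apply the loop rules to four directed totals (single-valued by construction)."""
    cfg = cfg or ExtractionConfig()
    hi, lo = cfg.loop_high, cfg.loop_low
    osn_loop = from_osn > hi and to_osn > hi
    pn_loop = from_pn > hi and to_pn > hi
    if osn_loop and pn_loop:
        return FeedbackLoopClass.MIXED
    if osn_loop and (from_pn + to_pn) < lo:
        return FeedbackLoopClass.OSN_LN_OSN
    if pn_loop and (from_osn + to_osn) < lo:
        return FeedbackLoopClass.PN_LN_PN
    return FeedbackLoopClass.NONE


def classify_feedback_loop(
    ln_id: str,
    glomerulus_scope: str | None,
    synapses: list[SynapseRecord],
    neurons: list[NeuronRecord] | dict[str, NeuronRecord],
    cfg: ExtractionConfig | None = None,
) -> FeedbackLoopClass:
    """Classify an LN's feedback-loop membership within a glomerulus (or the whole AL)."""
    cfg = cfg or ExtractionConfig()
    idx = neurons if isinstance(neurons, dict) else _index_neurons(neurons)
    ln = idx.get(ln_id)
    if ln is None or ln.cell_class is not CellClass.LN:
        raise ValueError(f"{ln_id!r} is not an LN")
    totals = _directed_totals(ln_id, glomerulus_scope, synapses, idx, cfg)
    return classify_totals(*totals, cfg=cfg)


def select_al_lns(
    neurons: list[NeuronRecord],
    synapses: list[SynapseRecord],
    cfg: ExtractionConfig | None = None,
) -> list[str]:
    """LN ids whose total synapse count (pre + post) strictly exceeds the inclusion minimum."""
    cfg = cfg or ExtractionConfig()
    totals: dict[str, int] = {}
    ln_ids = {n.neuron_id for n in neurons if n.cell_class is CellClass.LN}
    for s in synapses:
        if s.pre_id in ln_ids:
            totals[s.pre_id] = totals.get(s.pre_id, 0) + 1
        if s.post_id in ln_ids:
            totals[s.post_id] = totals.get(s.post_id, 0) + 1
    return sorted(ln for ln in ln_ids if totals.get(ln, 0) > cfg.ln_inclusion_min)


# ---------------------------------------------------------------------------
# Cell-type graph abstraction
# ---------------------------------------------------------------------------

def _default_type_key(rec: NeuronRecord) -> str:
    if rec.cell_class is CellClass.OSN:
        return f"OSN:{rec.receptor_type}"
    if rec.cell_class is CellClass.PN:
        gl = "+".join(sorted(rec.glomeruli)) or "?"
        return f"PN:{rec.pn_subtype}:{gl}"
    return f"LN:{rec.neuron_id}"


def celltype_graph(
    neurons: list[NeuronRecord],
    synapses: list[SynapseRecord],
    group_by: str = "cell_type",
    min_synapses: int = 0,
    type_key=None,
) -> nx.DiGraph:
    """Directed connectivity graph at neuron or cell-type level.

    A directed edge (u, v) exists iff the total synapse count from group u to
    group v is at least ``max(1, min_synapses)``; its ``weight`` is that
    count.  Self-loops are kept — they represent within-type (e.g.
    axo-axonal OSN-OSN) connectivity blocks.
    """
    if min_synapses < 0:
        raise ValueError("min_synapses must be nonnegative")
    if group_by not in {"neuron", "cell_type"}:
        raise ValueError("group_by must be 'neuron' or 'cell_type'")
    key = type_key or _default_type_key
    idx = _index_neurons(neurons)

    def node_of(nid: str) -> str:
        if group_by == "neuron":
            return nid
        return key(idx[nid])

    counts: dict[tuple[str, str], int] = {}
    for s in synapses:
        if s.pre_id not in idx or s.post_id not in idx:
            continue
        pair = (node_of(s.pre_id), node_of(s.post_id))
        counts[pair] = counts.get(pair, 0) + 1

    g = nx.DiGraph()
    for nid, rec in idx.items():
        node = node_of(nid)
        if not g.has_node(node):
            g.add_node(node, cell_class=rec.cell_class.value)
    cutoff = max(1, min_synapses)
    for (u, v), w in sorted(counts.items()):
        if w >= cutoff:
            g.add_edge(u, v, weight=w)
    return g


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)


def graph_edge_list(graph: nx.DiGraph) -> pd.DataFrame:
    rows = [(u, v, d.get("weight", 1)) for u, v, d in graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


# ---------------------------------------------------------------------------
# Pattern report
# ---------------------------------------------------------------------------

def pattern_report(
    synapses: list[SynapseRecord],
    neurons: list[NeuronRecord],
    cfg: ExtractionConfig | None = None,
    confidence_filtered: bool = False,
) -> pd.DataFrame:
    """One row per (LN, glomerulus) pair: counts, pattern, feedback flag, loop class.

    Applies confidence filtering and LN inclusion, then derives the port
    pattern and per-glomerulus loop class for every pair with at least one
    surviving synapse.  Rows in the ambiguous counting band (total passes
    but no digit does) are flagged, never silently dropped.
    """
    cfg = cfg or ExtractionConfig()
    kept = synapses if confidence_filtered else filter_by_confidence(synapses, cfg)
    idx = _index_neurons(neurons)
    included = set(select_al_lns(neurons, kept, cfg))

    pairs: dict[tuple[str, str], list[int]] = {}
    for s in kept:
        if not s.glomerulus:
            continue
        for ln_id, partner_id, offset in (
            (s.pre_id, s.post_id, 0),
            (s.post_id, s.pre_id, 1),
        ):
            ln = idx.get(ln_id)
            if ln is None or ln.cell_class is not CellClass.LN or ln_id not in included:
                continue
            partner = idx.get(partner_id)
            if partner is None:
                continue
            if partner.cell_class is CellClass.OSN:
                port = 0 if offset == 0 else 1
            elif _is_counted_pn(partner, cfg):
                port = 2 if offset == 0 else 3
            else:
                continue
            c = pairs.setdefault((ln_id, s.glomerulus), [0, 0, 0, 0])
            c[port] += 1

    rows = []
    for (ln_id, glom), c in sorted(pairs.items()):
        counts = PortCounts(*c)
        pattern = derive_port_pattern(counts, cfg)
        loop = classify_feedback_loop(ln_id, glom, kept, idx, cfg)
        rows.append(
            {
                "ln_id": ln_id,
                "glomerulus": glom,
                **dict(zip(PORT_NAMES, counts.as_tuple())),
                "total": counts.total(),
                "pattern": pattern,
                "feedback": pattern != "0000" and is_feedback_pattern(pattern),
                "loop_class": loop.value,
                "ambiguous": pattern_is_ambiguous(counts, cfg),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ln_id",
            "glomerulus",
            *PORT_NAMES,
            "total",
            "pattern",
            "feedback",
            "loop_class",
            "ambiguous",
        ],
    )


def pattern_occurrences(report: pd.DataFrame, tally: str = "pairs") -> pd.Series:
    """Per-pattern occurrence counts, tallied over (LN, glomerulus) pairs or over LNs."""
    if tally == "pairs":
        return report["pattern"].value_counts().sort_index()
    if tally == "lns":
        return (
            report.groupby("pattern")["ln_id"].nunique().sort_index()
        )
    raise ValueError("tally must be 'pairs' or 'lns'")
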