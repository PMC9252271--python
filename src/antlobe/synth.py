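"""Synthetic connectomes with planted ground truth.

Real synaptome tables come from electron-microscopy reconstructions that are
large, external downloads.  For testing the extraction pipeline end to end
we instead *plant* a known port-pattern matrix and emit synapse/neuron
tables that encode it:

* every '1' digit of a planted pattern produces a directed synapse count
  drawn from a super-threshold range (default 8–12, strictly above the
  digit threshold of 5);
* every '0' digit draws from a sub-threshold range (default 0–1, so even
  four zero-ports sum below the glomerular total threshold of 5 and the
  pattern is unambiguous);
* a configurable fraction of *decoy* synapses carries site confidences at or
  below 0.70 — they would flip '0' digits to '1' if the confidence filter
  were skipped, so recovery exercises the filter, not just the counter.

Counts are drawn uniformly from integer ranges rather than fitted to any
real dataset: the tests need separability, not realism.  Fixed seed →
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composer import GlomerulusModel, PairMotifSpec, build_glomerulus
from .motifs import ExtractionConfig, FeedbackLoopClass, classify_totals

__all__ = [
    "PlantedSpec",
    "SyntheticConnectome",
    "generate_connectome",
    "make_pair_fixture",
    "corrupt_fixture",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Ground-truth layout of a synthetic connectome."""

    glomeruli: tuple[str, ...] = tuple(f"G{i:02d}" for i in range(10))
    n_osn_per_glomerulus: int = 5
    n_pn_per_glomerulus: int = 2
    n_ln: int = 200
    gloms_per_ln: tuple[int, int] = (2, 5)
    super_range: tuple[int, int] = (8, 12)  # counts for planted '1' digits
    sub_range: tuple[int, int] = (0, 1)  # counts for planted '0' digits
    decoy_fraction: float = 0.15  # sub-threshold-confidence synapses per planted one
    n_weak_ln: int = 10  # LNs below the AL inclusion threshold
    seed: int = 0

    def validate(self) -> None:
        cfg = ExtractionConfig()
        if self.super_range[0] > self.super_range[1] or self.sub_range[0] > self.sub_range[1]:
            raise ValueError("count ranges must be (lo, hi) with lo <= hi")
        if self.super_range[0] <= cfg.digit_threshold:
            raise ValueError(
                f"super-threshold range must lie strictly above the digit "
                f"threshold {cfg.digit_threshold}"
            )
        if self.sub_range[1] > cfg.digit_threshold:
            raise ValueError(
                f"sub-threshold range must not exceed the digit threshold "
                f"{cfg.digit_threshold}"
            )
        if self.sub_range[0] < 0:
            raise ValueError("counts are nonnegative")
        if not 0 <= self.decoy_fraction <= 1:
            raise ValueError("decoy_fraction must be in [0, 1]")

    def ambiguous_band_possible(self) -> bool:
        """True when all-zero patterns could land in the flagged counting band."""
        cfg = ExtractionConfig()
        return 4 * self.sub_range[1] >= cfg.pattern_total_threshold


@dataclass
class SyntheticConnectome:
    synapses: pd.DataFrame
    neurons: pd.DataFrame
    truth: pd.DataFrame  # one row per planted (LN, glomerulus): pattern + loop class
    spec: PlantedSpec

    def write(self, out_dir, prefix: str = "synthetic") -> dict[str, str]:
        import os

        paths = {}
        for name, df in (
            ("synapses", self.synapses),
            ("neurons", self.neurons),
            ("truth", self.truth),
        ):
            path = os.path.join(out_dir, f"{prefix}_{name}.csv")
            df.to_csv(path, index=False)
            paths[name] = path
        return paths


# the 15 nonzero patterns, weighted toward the motif-defining ones
_PATTERN_POOL = [
    "1100", "0011", "1111",  # loop-class-bearing patterns
    "0001", "0010", "0100", "1000",
    "0101", "0110", "0111", "1001", "1010", "1011", "1101", "1110",
]


def _expected_class(pattern: str, spec: PlantedSpec) -> str:
    """Loop class implied by a planted pattern under the drawn count ranges.

    Digit order is (LN→OSN, LN←OSN, LN→PN, LN←PN); '1' counts exceed the
    loop threshold, '0' sides sum below it by construction of the ranges.
    """
    hi = spec.super_range[0]
    lo = spec.sub_range[1]
    to_osn = hi if pattern[0] == "1" else lo
    from_osn = hi if pattern[1] == "1" else lo
    to_pn = hi if pattern[2] == "1" else lo
    from_pn = hi if pattern[3] == "1" else lo
    return classify_totals(from_osn, to_osn, from_pn, to_pn).value


def generate_connectome(spec: PlantedSpec | None = None) -> SyntheticConnectome:
    """Emit synapse/neuron tables plus the planted pattern matrix."""
    spec = spec or PlantedSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    neuron_rows = []
    osn_ids: dict[str, list[str]] = {}
    pn_ids: dict[str, list[str]] = {}
    for g in spec.glomeruli:
        osn_ids[g] = [f"{g}/OSN{i}" for i in range(spec.n_osn_per_glomerulus)]
        pn_ids[g] = [f"{g}/PN{i}" for i in range(spec.n_pn_per_glomerulus)]
        for nid in osn_ids[g]:
            neuron_rows.append((nid, "OSN", f"OR-{g}", "none", g))
        for nid in pn_ids[g]:
            neuron_rows.append((nid, "PN", "", "uPN-adPN", g))

    ln_names = [f"LN{i:03d}" for i in range(spec.n_ln)]
    weak = set(ln_names[-spec.n_weak_ln:]) if spec.n_weak_ln else set()
    for nid in ln_names:
        neuron_rows.append((nid, "LN", "", "none", ""))

    syn_rows: list[tuple] = []
    truth_rows: list[dict] = []

    def high_conf() -> tuple[float, float]:
        p, q = rng.uniform(0.71, 1.0, size=2)
        return round(float(p), 3), round(float(q), 3)

    def low_conf() -> tuple[float, float]:
        # at least one site at or below the 0.70 threshold
        which = rng.integers(0, 3)
        lo = lambda: round(float(rng.uniform(0.2, 0.70)), 3)
        hi = lambda: round(float(rng.uniform(0.71, 1.0)), 3)
        if which == 0:
            return lo(), hi()
        if which == 1:
            return hi(), lo()
        return lo(), lo()

    def emit_port(ln: str, glom: str, digit: int, count: int, confidence) -> None:
        """Append `count` synapse rows on one port of an (LN, glomerulus) pair."""
        partners = osn_ids[glom] if digit in (0, 1) else pn_ids[glom]
        for k in range(count):
            partner = partners[int(rng.integers(0, len(partners)))]
            pre, post = (ln, partner) if digit in (0, 2) else (partner, ln)
            pc, qc = confidence()
            syn_rows.append((pre, post, pc, qc, glom))

    for ln in ln_names:
        if ln in weak:
            # below the AL-inclusion threshold: a few scattered synapses
            n_syn = int(rng.integers(1, ExtractionConfig().ln_inclusion_min - 3))
            for _ in range(n_syn):
                g = spec.glomeruli[int(rng.integers(0, len(spec.glomeruli)))]
                emit_port(ln, g, int(rng.integers(0, 4)), 1, high_conf)
            continue
        lo_g, hi_g = spec.gloms_per_ln
        hi_g = min(hi_g, len(spec.glomeruli))
        lo_g = min(lo_g, hi_g)
        n_g = int(rng.integers(lo_g, hi_g + 1))
        chosen = rng.choice(len(spec.glomeruli), size=n_g, replace=False)
        for gi in sorted(chosen):
            glom = spec.glomeruli[gi]
            pattern = _PATTERN_POOL[int(rng.integers(0, len(_PATTERN_POOL)))]
            for digit in range(4):
                if pattern[digit] == "1":
                    count = int(rng.integers(spec.super_range[0], spec.super_range[1] + 1))
                else:
                    count = int(rng.integers(spec.sub_range[0], spec.sub_range[1] + 1))
                emit_port(ln, glom, digit, count, high_conf)
                n_decoy = rng.binomial(8, spec.decoy_fraction)
                if pattern[digit] == "0" and n_decoy:
                    # enough low-confidence rows to flip the digit if unfiltered
                    emit_port(ln, glom, digit, 6 + n_decoy, low_conf)
            truth_rows.append(
                {
                    "ln_id": ln,
                    "glomerulus": glom,
                    "pattern": pattern,
                    "loop_class": _expected_class(pattern, spec),
                }
            )

    synapses = pd.DataFrame(
        syn_rows, columns=["pre_id", "post_id", "pre_conf", "post_conf", "glomerulus"]
    )
    neurons = pd.DataFrame(
        neuron_rows,
        columns=["neuron_id", "cell_class", "receptor_type", "pn_subtype", "glomeruli"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["ln_id", "glomerulus", "pattern", "loop_class"]
    )
    return SyntheticConnectome(synapses, neurons, truth, spec)


# ---------------------------------------------------------------------------
# Ready-made circuit fixture
# ---------------------------------------------------------------------------

def make_pair_fixture(
    style: str = "DM4-DL5", seed: int = 0
) -> tuple[GlomerulusModel, GlomerulusModel, PairMotifSpec]:
    """Two glomeruli in the canonical interconnected-pair configuration.

    The first is a large many-PN glomerulus (40 OSNs, 2 PNs); the second has
    a single PN, the distinguishing feature of DL5.  Feedforward synapse
    counts are drawn once from a seeded generator: 15–25 contacts per
    OSN→PN pair in the large glomerulus, 40–60 in the single-PN one (the
    lone PN concentrates its dendritic field, so per-OSN convergence is
    high).  The returned motif spec is the default five-motif composition
    (LN1 and LN2 per glomerulus, one shared LN3).
    """
    if style != "DM4-DL5":
        raise ValueError(f"unknown fixture style {style!r}")
    rng = np.random.default_rng(seed)
    ff_a = rng.integers(15, 26, size=(40, 2))
    ff_b = rng.integers(40, 61, size=(15, 1))
    glom_a = build_glomerulus("DM4", 40, 2, ff_a)
    glom_b = build_glomerulus("DL5", 15, 1, ff_b)
    return glom_a, glom_b, PairMotifSpec()


# ---------------------------------------------------------------------------
# Negative-path fixtures
# ---------------------------------------------------------------------------

_CORRUPT_MODES = {"dangling_id", "bad_confidence", "missing_column"}


def corrupt_fixture(
    tables: tuple[pd.DataFrame, pd.DataFrame], mode: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject exactly one schema defect into (synapses, neurons) for parser tests."""
    if mode not in _CORRUPT_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; choose from {sorted(_CORRUPT_MODES)}")
    synapses, neurons = tables
    synapses = synapses.copy()
    if mode == "dangling_id":
        synapses.loc[len(synapses)] = ["GHOST", synapses.iloc[0]["post_id"], 0.9, 0.9, ""]
    elif mode == "bad_confidence":
        synapses.loc[0, "pre_conf"] = 1.2
    elif mode == "missing_column":
        synapses = synapses.drop(columns=["post_conf"])
    return synapses, neurons
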