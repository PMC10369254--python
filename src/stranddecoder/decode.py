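"""Fluorescence-pattern decoding, dose rules, and pipeline orchestration.

A channel is ON when its normalised fluorescence exceeds ``on_threshold``
(default 0.4) and OFF when it is at or below the *off* level (the minimum
of the on-threshold and 0.4).  A decode rule matches when exactly its
channels are ON and all other channels are OFF; readings between the two
levels are ambiguous, so raising the on-threshold can only push a call
toward ``indeterminate``, never flip it between definite classes.

``run_pipeline`` composes the full in-silico workflow: genetic-code
encoding -> LDR signal transformation -> (cached) circuit compilation ->
reaction-network expansion -> stiff ODE integration -> endpoint RFU ->
pattern decoding.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .compiler import (
    Circuit,
    DEFAULT_BASE_UNIT_NM,
    DualGeneRuleSet,
    compile_circuit,
)
from .crn import (
    RateConfig,
    build_reaction_network,
    default_calibration,
    endpoint_rfu,
    simulate,
)
from .errors import InputError, StrandDecoderError
from .genotype import Diplotype, GeneticCode, Panel, encode_genetic_code
from .learn import ClassIntervalSpec, CoefficientArray
from .ldr import LdrConfig, PrimerPair, default_primer_panel, transform

logger = logging.getLogger(__name__)

DEFAULT_ON_THRESHOLD = 0.4
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class FluorescencePattern:
    """Per-channel RFU readings plus the ON/OFF demarcation threshold."""

    rfu: Mapping[str, float]
    on_threshold: float = DEFAULT_ON_THRESHOLD

    def __post_init__(self):
        if not (0.0 < self.on_threshold < 1.0):
            raise InputError("on_threshold must lie in (0, 1)")
        if any(v < 0 for v in self.rfu.values()):
            raise InputError("RFU values must be non-negative")

    @property
    def off_threshold(self) -> float:
        return min(self.on_threshold, DEFAULT_ON_THRESHOLD)

    def on_channels(self) -> frozenset:
        return frozenset(
            ch for ch, v in self.rfu.items() if v > self.on_threshold
        )

    def ambiguous_channels(self) -> frozenset:
        return frozenset(
            ch
            for ch, v in self.rfu.items()
            if self.off_threshold < v <= self.on_threshold
        )


@dataclass(frozen=True)
class DecodeTable:
    """Ordered ON-pattern -> class rules over a fixed channel set."""

    channels: tuple[str, ...]
    rules: tuple[tuple[frozenset, str], ...]

    def __post_init__(self):
        seen = set()
        for on_set, _ in self.rules:
            if on_set in seen:
                raise InputError(f"duplicate decode rule for pattern {set(on_set)}")
            seen.add(on_set)

    def labels(self) -> list[str]:
        return [label for _, label in self.rules]

    def call(self, pattern: FluorescencePattern) -> str:
        missing = [ch for ch in self.channels if ch not in pattern.rfu]
        if missing:
            raise InputError(f"missing channels in pattern: {missing}")
        if pattern.ambiguous_channels():
            return INDETERMINATE
        on = pattern.on_channels() & frozenset(self.channels)
        for on_set, label in self.rules:
            if on == on_set:
                return label
        return INDETERMINATE


@dataclass(frozen=True)
class PhenotypeCall:
    sample_id: str
    label: str
    pattern: FluorescencePattern
    margins: Mapping[str, float]  # per-channel RFU minus on-threshold

    @property
    def indeterminate(self) -> bool:
        return self.label == INDETERMINATE


@dataclass(frozen=True)
class GeneBranchCall:
    """Per-gene summary of a dual-gene circuit readout."""

    gene: str
    status: str  # NM | IM | PM | indeterminate


@dataclass(frozen=True)
class DoseRecommendation:
    drug: str
    category: str  # normal | reduced | alternative_agent | indeterminate
    rationale: str


def call_phenotype(
    pattern: FluorescencePattern, table: DecodeTable, sample_id: str = ""
) -> PhenotypeCall:
    """Decode one fluorescence pattern; unmatched patterns are
    ``indeterminate`` rather than an error."""
    label = table.call(pattern)
    margins = {
        ch: pattern.rfu[ch] - pattern.on_threshold for ch in table.channels
    }
    return PhenotypeCall(
        sample_id=sample_id, label=label, pattern=pattern, margins=margins
    )


def recommend_dose(
    call_1: GeneBranchCall,
    call_2: GeneBranchCall,
    collective_pass: bool | None = None,
    drug: str = "thiopurine",
) -> DoseRecommendation:
    """Dual-gene dosing: any poor-metabolizer branch demands an alternative
    agent, any intermediate branch a dose reduction, and the normal dose
    requires both branches normal plus a passing collective comparison."""
    statuses = (call_1.status, call_2.status)
    rationale = f"{call_1.gene}={call_1.status}, {call_2.gene}={call_2.status}"
    if INDETERMINATE in statuses:
        return DoseRecommendation(drug, INDETERMINATE, rationale)
    if "PM" in statuses:
        return DoseRecommendation(drug, "alternative_agent", rationale)
    if "IM" in statuses:
        return DoseRecommendation(drug, "reduced", rationale)
    if collective_pass is False:
        return DoseRecommendation(
            drug, INDETERMINATE, rationale + ", collective comparison failed"
        )
    return DoseRecommendation(drug, "normal", rationale)


def decode_dual_gene(
    pattern: FluorescencePattern, rules: DualGeneRuleSet
) -> tuple[GeneBranchCall, GeneBranchCall, bool]:
    """Split a dual-gene fluorescence pattern into per-gene branch calls."""
    cm = rules.channel_map
    needed = [cm[k] for k in (
        "gene1_presence", "gene1_threshold", "gene2_presence",
        "gene2_threshold", "collective",
    )]
    missing = [ch for ch in needed if ch not in pattern.rfu]
    if missing:
        raise InputError(f"missing channels in pattern: {missing}")
    on = pattern.on_channels()
    ambiguous = pattern.ambiguous_channels()

    def branch(gene: str, pres_key: str, thr_key: str) -> GeneBranchCall:
        pres, thr = cm[pres_key], cm[thr_key]
        if pres in ambiguous or thr in ambiguous:
            return GeneBranchCall(gene, INDETERMINATE)
        if thr in on:
            # severity threshold requires the presence channel as well
            return GeneBranchCall(gene, "PM" if pres in on else INDETERMINATE)
        if pres in on:
            return GeneBranchCall(gene, "IM")
        return GeneBranchCall(gene, "NM")

    g1, g2 = rules.gene1, rules.gene2
    return (
        branch(g1, "gene1_presence", "gene1_threshold"),
        branch(g2, "gene2_presence", "gene2_threshold"),
        cm["collective"] in on,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    base_unit: float = DEFAULT_BASE_UNIT_NM
    ldr: LdrConfig = field(default_factory=LdrConfig)
    primers: Sequence[PrimerPair] | None = None  # default: one per allele
    rates: RateConfig = field(default_factory=RateConfig)
    t_end: float = 9000.0  # 2.5 h endpoint
    on_threshold: float = DEFAULT_ON_THRESHOLD
    reltol: float = 1e-8
    abstol: float = 1e-6
    seed: int = 0


def _sample_seed(base_seed: int, sample_id: str) -> int:
    # stable per-sample seed: batch order must not affect any draw
    return (base_seed * 100003 + zlib.crc32(sample_id.encode())) % (2**31)


def _stage(name: str):
    def wrap(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except StrandDecoderError as e:
            raise type(e)(f"[stage:{name}] {e}") from e

    return wrap


def run_pipeline(
    samples: Sequence[tuple[str, Diplotype | GeneticCode | str]],
    panel: Panel,
    weights: CoefficientArray | None,
    spec: ClassIntervalSpec | None,
    decode_table: DecodeTable,
    config: PipelineConfig | None = None,
    circuit: Circuit | None = None,
) -> list[PhenotypeCall]:
    """Sample in, answer out: decode a cohort of genotypes.

    ``samples`` pairs a sample id with a star-diplotype string,
    :class:`Diplotype`, or pre-encoded :class:`GeneticCode`.  The circuit
    is compiled once from ``weights``/``spec`` unless given directly.
    """
    cfg = config or PipelineConfig()
    if circuit is None:
        if weights is None or spec is None:
            raise InputError("need either a circuit or weights + spec")
        circuit = _stage("compile")(
            compile_circuit, weights, spec, cfg.base_unit
        )
    primers = (
        list(cfg.primers)
        if cfg.primers is not None
        else default_primer_panel(panel)
    )
    calibration = default_calibration(circuit)
    calls: list[PhenotypeCall] = []
    for sample_id, genotype in samples:
        logger.info("decoding sample %s", sample_id)
        if isinstance(genotype, str):
            genotype = Diplotype.parse(panel.gene, genotype)
        if isinstance(genotype, Diplotype):
            code = _stage("encode")(encode_genetic_code, genotype, panel)
        else:
            code = genotype
        ldr_cfg = replace(cfg.ldr, seed=_sample_seed(cfg.seed, sample_id))
        inputs = _stage("ldr")(
            transform, code, primers, ldr_cfg, "endpoint",
            panel.allele_labels(),
        )
        # primers of zero-weight alleles have no gate: inert in the pot
        wired = {
            a: c for a, c in inputs.items() if a in circuit.input_map
        }
        network = _stage("network")(
            build_reaction_network, circuit, wired, cfg.rates
        )
        traj = _stage("simulate")(
            simulate, network, cfg.t_end, cfg.reltol, cfg.abstol
        )
        rfu = _stage("rfu")(endpoint_rfu, traj, calibration)
        pattern = FluorescencePattern(rfu=rfu, on_threshold=cfg.on_threshold)
        calls.append(
            _stage("decode")(call_phenotype, pattern, decode_table, sample_id)
        )
    return calls


def calls_to_frame(calls: Sequence[PhenotypeCall]):
    import pandas as pd

    rows = []
    for c in calls:
        row = {"sample_id": c.sample_id, "class": c.label}
        for ch, v in sorted(c.pattern.rfu.items()):
            row[f"rfu_{ch}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def decode_table_from_rules(
    rules: Sequence[tuple[frozenset, str]], channels: Sequence[str]
) -> DecodeTable:
    return DecodeTable(channels=tuple(channels), rules=tuple(rules))
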