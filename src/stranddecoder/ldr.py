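"""Ligase-dependent reaction (LDR) front end.

A thermostable ligase joins an allele-specific upstream primer (carrying the
circuit-facing toehold) to a shared phosphorylated downstream primer only
when both are perfectly matched to the template at the junction.  Thermal
cycling accumulates *linked primers* — the single-stranded inputs of the
multiplication gates — for every allele present in the sample, plus a small
unspecific (cross-ligation) background for absent alleles.

The endpoint model converts a binary genetic code into linked-primer
concentrations:

    linked_i = P_i * e   if allele i is present
    linked_i = P_i * c   if allele i is absent

with per-pair primer amount P_i, ligation efficiency e and cross-ligation
fraction c (c < e).  A per-cycle linear-accumulation variant is provided for
sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, DefinitionError, InputError
from .genotype import GeneticCode, Panel

#: Default total primer-pair concentration entering the circuit (nM).
DEFAULT_PRIMER_NM = 10.0


@dataclass(frozen=True)
class PrimerPair:
    """Primer pair for one allele: toehold-tagged upstream + downstream."""

    allele_id: str
    toehold: str  # name of the toehold domain wired to the allele's M gate
    total_concentration: float = DEFAULT_PRIMER_NM  # nM

    def __post_init__(self):
        if self.total_concentration <= 0:
            raise ConfigError(
                f"primer pair {self.allele_id}: total concentration must be > 0"
            )


@dataclass(frozen=True)
class LdrConfig:
    """Ligation yield model parameters.

    ``efficiency`` is the endpoint linked fraction for a present allele;
    ``cross_ligation`` the linked fraction for an absent allele.  The
    per-cycle model uses ``cycles`` rounds of template-limited ligation at
    probability ``per_cycle_probability`` per template per cycle.
    """

    efficiency: float = 0.45
    cross_ligation: float = 1e-4
    cycles: int = 30
    template_concentration: float = 5.0  # nM
    per_cycle_probability: float = 0.015
    efficiency_range: tuple[float, float] | None = None  # per-allele jitter
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.cross_ligation < self.efficiency <= 1):
            raise ConfigError(
                "require 0 <= cross_ligation < efficiency <= 1 "
                f"(got c={self.cross_ligation}, e={self.efficiency})"
            )
        if self.cycles < 1:
            raise ConfigError("cycles must be >= 1")


@dataclass
class InputVector:
    """Map allele_id -> linked-primer concentration (nM)."""

    concentrations: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, allele_id: str) -> float:
        return self.concentrations[allele_id]

    def items(self):
        return self.concentrations.items()


def default_primer_panel(
    panel: Panel, total_concentration: float = DEFAULT_PRIMER_NM
) -> list[PrimerPair]:
    """One primer pair per panel allele, toehold named after the allele."""
    return [
        PrimerPair(
            allele_id=a.label,
            toehold=f"t_{a.label}",
            total_concentration=total_concentration,
        )
        for a in panel.alleles
    ]


def transform(
    code: GeneticCode,
    primers: Sequence[PrimerPair],
    config: LdrConfig | None = None,
    mode: str = "endpoint",
    allele_order: Sequence[str] | None = None,
) -> InputVector:
    """Convert a genetic code into linked-primer input concentrations.

    ``allele_order`` gives the allele_id corresponding to each bit of the
    code (defaults to the primer list order, which must then match the
    panel's allele order).  Deterministic; per-allele efficiency jitter, if
    enabled, is drawn from the config's seeded RNG.
    """
    cfg = config or LdrConfig()
    if mode not in ("endpoint", "per_cycle"):
        raise ConfigError(f"unknown LDR mode {mode!r}")
    order = list(allele_order) if allele_order is not None else [
        p.allele_id for p in primers
    ]
    if len(order) != len(code.bits):
        raise DefinitionError(
            f"allele order length {len(order)} != code length {len(code.bits)}"
        )
    by_id = {p.allele_id: p for p in primers}
    missing = [a for a in order if a not in by_id]
    if missing:
        raise DefinitionError(f"missing primer pairs for alleles {missing}")

    if cfg.efficiency_range is not None:
        lo, hi = cfg.efficiency_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("efficiency_range must satisfy 0 <= lo <= hi <= 1")
        rng = np.random.default_rng(cfg.seed)
        eff = rng.uniform(lo, hi, size=len(order))
    else:
        eff = np.full(len(order), cfg.efficiency)

    out: dict[str, float] = {}
    for i, (allele_id, bit) in enumerate(zip(order, code.bits)):
        pair = by_id[allele_id]
        p_total = pair.total_concentration
        if mode == "endpoint":
            frac = eff[i] if bit else cfg.cross_ligation
            linked = p_total * frac
        else:
            # linear accumulation: one template can ligate at most one pair
            # per cycle, at the per-cycle probability, scaled down to the
            # cross-ligation level when the allele is absent.
            per_cycle = cfg.template_concentration * cfg.per_cycle_probability
            scale = 1.0 if bit else cfg.cross_ligation / cfg.efficiency
            linked = min(p_total, per_cycle * cfg.cycles * scale)
        out[allele_id] = float(linked)
    return InputVector(concentrations=out)


def apply_enrichment(
    code: GeneticCode, vaf: float, enrichment_factor: float
) -> list[float]:
    """Effective template share per set allele after rare-allele enrichment.

    Models pre-amplification (blocker displacement amplification) purely as
    a fold-change on the variant allele fraction, clipped at 1; no chemistry
    is simulated.
    """
    if not (0 < vaf <= 1):
        raise InputError(f"variant allele fraction must be in (0, 1], got {vaf}")
    if enrichment_factor < 1:
        raise ConfigError("enrichment factor must be >= 1")
    share = min(1.0, vaf * enrichment_factor)
    return [share if bit else 0.0 for bit in code.bits]


def with_efficiency(config: LdrConfig, efficiency: float) -> LdrConfig:
    """Copy of a config with a different ligation efficiency."""
    return replace(config, efficiency=efficiency)
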