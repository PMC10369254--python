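"""Compile coefficient arrays into strand-displacement gate circuits.

A compiled circuit is an inventory of DNA gates with initial concentrations:

* one *multiplication* (seesaw) gate per nonzero-weight allele, at
  ``|w| * base_unit`` nM, with a fuel strand in 2x excess — catalysis makes
  the released output stoichiometric in the gate, so the gate concentration
  *is* the multiplicative coefficient;
* two *summation* gates funnelling positively weighted outputs into species
  X and negatively weighted outputs into species Y;
* a cooperative-hybridization *subtraction* gate annihilating X and Y
  stoichiometrically, so only the excess of the larger species survives;
* per comparator channel, a *transformation* gate with a truncated (slower)
  toehold converting the leftover into that channel's H species.  The
  channel gates on one side are identical in size and rate, so they split
  the leftover into exact equal shares — giving every channel an
  independent copy it can threshold at its own level;
* *threshold* gates with extended (faster) toeholds absorbing a channel's
  H up to its comparator level.  Presence channels (VIC on the negative
  side, Cy5 on the positive) carry a small *deadband* threshold that
  swallows circuit leak, so "H > 0" is read as "H beyond the noise floor";
* slow catalytic *reporters* (restoration gates): H is restored on every
  reporting event, so fluorescence integrates H exposure without
  perturbing the comparator arithmetic.

Gate excesses (fuel 2x, summation 1.5x, subtraction 4x the maximum
attainable min(X, Y), transformation 4x its channel share) are engineering
choices; a channel's threshold concentration is exactly its comparator
level divided by the number of channel copies on its side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .errors import CompileError, UnsupportedEncodingError, WiringError
from .learn import ClassIntervalSpec, CoefficientArray

#: Default 1x concentration (nM) for pharmacogene circuits.
DEFAULT_BASE_UNIT_NM = 10.0
#: Default 1x concentration (nM) for polygenic-risk circuits.
PRS_BASE_UNIT_NM = 50.0
#: Default per-lnOR gate multiplier (nM) for polygenic-risk circuits.
PRS_MULTIPLIER_NM = 100.0

FUEL_EXCESS = 2.0
SUMMATION_EXCESS = 1.5
SUBTRACTION_EXCESS = 4.0
TRANSFORMATION_EXCESS = 4.0
REPORTER_EXCESS = 1.5
REPORTER_FLOOR_NM = 50.0
#: Deadband (1x units) of the presence channels' noise-absorbing threshold.
PRESENCE_DEADBAND_UNITS = 0.35

STANDARD_TOEHOLD_NT = 7
TRUNCATED_TOEHOLD_NT = STANDARD_TOEHOLD_NT - 2
EXTENDED_TOEHOLD_NT = STANDARD_TOEHOLD_NT + 2


@dataclass(frozen=True)
class Domain:
    name: str
    length: int
    role: str  # toehold | branch | clamp

    def __post_init__(self):
        if self.length < 1:
            raise CompileError(f"domain {self.name}: length must be >= 1")
        if self.role == "toehold" and not (4 <= self.length <= 10):
            raise CompileError(
                f"domain {self.name}: toehold length must be 4-10 nt"
            )


@dataclass(frozen=True)
class Strand:
    name: str
    domains: tuple[str, ...]
    orientation: str = "5to3"

    def __post_init__(self):
        if not self.domains:
            raise CompileError(f"strand {self.name}: empty domain list")


GATE_KINDS = (
    "multiplication",
    "fuel",
    "summation",
    "subtraction",
    "transformation",
    "threshold",
    "reporter",
)


@dataclass(frozen=True)
class Gate:
    name: str
    kind: str
    top_strand: str
    bottom_strand: str | None
    initial_concentration: float  # nM
    toehold_class: str = "standard"  # standard | truncated | extended
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in GATE_KINDS:
            raise CompileError(f"gate {self.name}: unknown kind {self.kind!r}")
        if self.initial_concentration < 0:
            raise CompileError(
                f"gate {self.name}: negative initial concentration"
            )


@dataclass
class Circuit:
    """Gate inventory plus wiring metadata for the simulator."""

    circuit_id: str
    kind: str  # single | dual | prs
    base_unit: float  # nM per 1x
    gates: list[Gate]
    domains: dict[str, Domain]
    strands: dict[str, Strand]
    input_map: dict[str, str]  # allele/input id -> input species name
    reporter_map: dict[str, str]  # fluorophore -> reporter gate name
    channels: list[dict]  # fluorophore, h_species, side, mode, threshold_nM
    metadata: dict = field(default_factory=dict)

    def gates_of_kind(self, kind: str) -> list[Gate]:
        return [g for g in self.gates if g.kind == kind]

    def gate(self, name: str) -> Gate:
        for g in self.gates:
            if g.name == name:
                return g
        raise WiringError(f"no gate named {name!r}")

    def to_dict(self) -> dict:
        def _py(value):
            if isinstance(value, dict):
                return {k: _py(v) for k, v in value.items()}
            if isinstance(value, (list, tuple)):
                return [_py(v) for v in value]
            if hasattr(value, "item"):  # numpy scalar
                return value.item()
            return value

        return _py({
            "circuit_id": self.circuit_id,
            "kind": self.kind,
            "base_unit": self.base_unit,
            "gates": [
                {
                    "name": g.name,
                    "kind": g.kind,
                    "top_strand": g.top_strand,
                    "bottom_strand": g.bottom_strand,
                    "initial_concentration": g.initial_concentration,
                    "toehold_class": g.toehold_class,
                    "params": dict(g.params),
                }
                for g in self.gates
            ],
            "domains": {
                name: {"length": d.length, "role": d.role}
                for name, d in sorted(self.domains.items())
            },
            "strands": {
                name: {"domains": list(s.domains), "orientation": s.orientation}
                for name, s in sorted(self.strands.items())
            },
            "input_map": dict(sorted(self.input_map.items())),
            "reporter_map": dict(sorted(self.reporter_map.items())),
            "channels": self.channels,
            "metadata": self.metadata,
        })

    def to_text(self) -> str:
        """Stable, diffable serialization."""
        return yaml.safe_dump(self.to_dict(), sort_keys=True, width=100)


class _Builder:
    """Accumulates gates/domains/strands for one circuit."""

    def __init__(self, circuit_id: str, kind: str, base_unit: float):
        if base_unit <= 0:
            raise CompileError("base_unit must be positive")
        self.circuit_id = circuit_id
        self.kind = kind
        self.base_unit = base_unit
        self.gates: list[Gate] = []
        self.domains: dict[str, Domain] = {}
        self.strands: dict[str, Strand] = {}
        self.input_map: dict[str, str] = {}
        self.reporter_map: dict[str, str] = {}
        self.channels: list[dict] = []
        self.metadata: dict = {}

    def domain(self, name: str, length: int, role: str) -> str:
        if name not in self.domains:
            self.domains[name] = Domain(name=name, length=length, role=role)
        return name

    def strand(self, name: str, domains: Sequence[str]) -> str:
        if name not in self.strands:
            self.strands[name] = Strand(name=name, domains=tuple(domains))
        return name

    def add_gate(self, **kw) -> Gate:
        g = Gate(**kw)
        self.gates.append(g)
        return g

    # ---- weighted-sum arithmetic (M gates + fuels + S pair + subtraction)

    def weighted_sum_branch(
        self,
        ns: str,
        alleles: Sequence[str],
        weights: Sequence[float],
        catalytic: bool = True,
        input_ids: Sequence[str] | None = None,
    ) -> dict:
        """Emit arithmetic gates for one weighted-sum computation."""
        base = self.base_unit
        x_cap = sum(w for w in weights if w > 0)
        y_cap = sum(-w for w in weights if w < 0)
        x_species, y_species = f"X:{ns}", f"Y:{ns}"
        ids = list(input_ids) if input_ids is not None else list(alleles)

        for allele, input_id, w in zip(alleles, ids, weights):
            if w == 0:
                continue
            branch = "X" if w > 0 else "Y"
            t = self.domain(f"t_{allele}", STANDARD_TOEHOLD_NT, "toehold")
            b = self.domain(f"b_{allele}", 15, "branch")
            d = self.domain(f"d_{ns}_{branch}", STANDARD_TOEHOLD_NT, "toehold")
            out_top = self.strand(f"out_top:{allele}", [b, d])
            m_bot = self.strand(f"m_bot:{allele}", [t, b, d])
            conc = abs(w) * base
            self.add_gate(
                name=f"M:{allele}",
                kind="multiplication",
                top_strand=out_top,
                bottom_strand=m_bot,
                initial_concentration=conc,
                toehold_class="standard",
                params={
                    "allele": allele,
                    "weight": w,
                    "branch": branch,
                    "ns": ns,
                    "input_species": f"in:{input_id}",
                    "output_species": f"out:{allele}",
                    "catalytic": catalytic,
                },
            )
            if catalytic:
                fuel = self.strand(f"fuel:{allele}", [b, d])
                self.add_gate(
                    name=f"F:{allele}",
                    kind="fuel",
                    top_strand=fuel,
                    bottom_strand=None,
                    initial_concentration=FUEL_EXCESS * conc,
                    toehold_class="standard",
                    params={"allele": allele, "ns": ns},
                )
            self.input_map[input_id] = f"in:{input_id}"

        for branch, cap, common in (("X", x_cap, x_species), ("Y", y_cap, y_species)):
            d = self.domain(f"d_{ns}_{branch}", STANDARD_TOEHOLD_NT, "toehold")
            sb = self.domain(f"s_{ns}_{branch}", 15, "branch")
            top = self.strand(f"s_top:{ns}:{branch}", [sb])
            bot = self.strand(f"s_bot:{ns}:{branch}", [d, sb])
            self.add_gate(
                name=f"S:{ns}:{branch}",
                kind="summation",
                top_strand=top,
                bottom_strand=bot,
                initial_concentration=SUMMATION_EXCESS * cap * base,
                toehold_class="standard",
                params={
                    "branch": branch,
                    "ns": ns,
                    "output_species": common,
                    "capacity": cap * base,
                },
            )

        min_cap = min(x_cap, y_cap)
        sub_t = self.domain(f"sub_t_{ns}", STANDARD_TOEHOLD_NT, "toehold")
        self.add_gate(
            name=f"SUB:{ns}",
            kind="subtraction",
            top_strand=self.strand(f"sub_top:{ns}", [sub_t]),
            bottom_strand=self.strand(f"sub_bot:{ns}", [sub_t, f"s_{ns}_X"]),
            initial_concentration=SUBTRACTION_EXCESS * min_cap * base,
            toehold_class="standard",
            params={
                "ns": ns,
                "x_species": x_species,
                "y_species": y_species,
                "capacity": min_cap * base,
            },
        )
        return {
            "ns": ns,
            "x_species": x_species,
            "y_species": y_species,
            "x_cap": x_cap * base,
            "y_cap": y_cap * base,
        }

    # ---- comparators -------------------------------------------------

    def comparator_side(
        self,
        ns: str,
        side: str,  # "H1" (leftover Y) or "H2" (leftover X)
        src_species: str,
        cap_nm: float,
        channels: Sequence[tuple[str, str, float | None]],
        emit_reporters: bool = True,
    ) -> list[str]:
        """Emit one transformation copy + threshold (+ reporter) per channel.

        ``channels`` lists (fluorophore, mode, threshold in 1x units);
        presence channels get the deadband threshold.  The n identical
        transformation gates split the side's leftover into exact n-ths,
        so each channel thresholds its own copy at level/n nM.
        """
        if not channels:
            return []
        n = len(channels)
        share = cap_nm / n
        h_names = []
        for fluor, mode, level in channels:
            tt = self.domain(f"tg_t_{ns}_{fluor}", TRUNCATED_TOEHOLD_NT,
                             "toehold")
            tb = self.domain(f"tg_b_{ns}_{fluor}", 15, "branch")
            h_species = f"{side}:{ns}:{fluor}"
            self.add_gate(
                name=f"TG:{ns}:{fluor}",
                kind="transformation",
                top_strand=self.strand(f"h_top:{ns}:{fluor}", [tb]),
                bottom_strand=self.strand(f"tg_bot:{ns}:{fluor}", [tt, tb]),
                initial_concentration=TRANSFORMATION_EXCESS * share,
                toehold_class="truncated",
                params={
                    "ns": ns,
                    "side": side,
                    "channel": fluor,
                    "input_species": src_species,
                    "output_species": h_species,
                    "capacity": share,
                    "n_split": n,
                },
            )
            units = PRESENCE_DEADBAND_UNITS if mode == "presence" else level
            th_nm = (units * self.base_unit) / n if units else 0.0
            if th_nm > 0:
                t = self.domain(f"th_t_{ns}_{fluor}", EXTENDED_TOEHOLD_NT,
                                "toehold")
                self.add_gate(
                    name=f"TH:{ns}:{fluor}",
                    kind="threshold",
                    top_strand=self.strand(f"th_top:{ns}:{fluor}", [t]),
                    bottom_strand=self.strand(
                        f"th_bot:{ns}:{fluor}", [t, f"tg_b_{ns}_{fluor}"]
                    ),
                    initial_concentration=th_nm,
                    toehold_class="extended",
                    params={"h_species": h_species, "channel": fluor,
                            "ns": ns},
                )
            if emit_reporters:
                self._reporter(ns, fluor, h_species, mode, share, th_nm, n)
            h_names.append(h_species)
        return h_names

    def _reporter(self, ns, fluor, h_species, mode, capacity_hint, th_nm, n):
        conc = max(REPORTER_FLOOR_NM, REPORTER_EXCESS * capacity_hint)
        rb = self.domain(f"rep_b_{fluor}", 15, "branch")
        g = self.add_gate(
            name=f"REP:{fluor}",
            kind="reporter",
            top_strand=self.strand(f"rep_top:{fluor}", [rb]),
            bottom_strand=self.strand(f"rep_bot:{fluor}", [rb]),
            initial_concentration=conc,
            toehold_class="standard",
            params={
                "h_species": h_species,
                "fluorophore": fluor,
                "mode": mode,
            },
        )
        self.reporter_map[fluor] = g.name
        self.channels.append(
            {
                "fluorophore": fluor,
                "h_species": h_species,
                "ns": ns,
                "mode": mode,
                "threshold_nM": th_nm,
                "n_split": n,
            }
        )

    def build(self) -> Circuit:
        return Circuit(
            circuit_id=self.circuit_id,
            kind=self.kind,
            base_unit=self.base_unit,
            gates=self.gates,
            domains=self.domains,
            strands=self.strands,
            input_map=self.input_map,
            reporter_map=self.reporter_map,
            channels=self.channels,
            metadata=self.metadata,
        )


def _split_boundaries(spec: ClassIntervalSpec):
    neg = [b for b in spec.boundaries if b < 0]
    pos = [b for b in spec.boundaries if b > 0]
    if len(neg) > 1 or len(pos) > 1:
        raise CompileError(
            "at most one negative and one positive comparator boundary are "
            f"supported; got {spec.boundaries}"
        )
    return (neg[0] if neg else None), (pos[0] if pos else None)


def compile_circuit(
    weights: CoefficientArray,
    spec: ClassIntervalSpec,
    base_unit: float = DEFAULT_BASE_UNIT_NM,
    circuit_id: str | None = None,
) -> Circuit:
    """Compile a single-gene weighted-sum comparator circuit.

    VIC reports net < 0 (H1 beyond the noise deadband), Cy5 net > 0; a
    negative boundary adds the FAM channel (H1 beyond ``|boundary|``) and a
    positive boundary the ROX channel (H2 beyond ``boundary``).
    """
    w = list(weights.weights)
    if not any(v != 0 for v in w):
        raise CompileError("empty circuit: all weights are zero")
    labels = list(weights.allele_labels) or [f"allele_{i}" for i in range(len(w))]
    b = _Builder(circuit_id or f"{weights.panel_id}-decoder", "single", base_unit)
    br = b.weighted_sum_branch("main", labels, w)
    neg, pos = _split_boundaries(spec)
    h1_channels = [("VIC", "presence", None)]
    if neg is not None:
        h1_channels.append(("FAM", "threshold", abs(neg)))
    h2_channels = [("Cy5", "presence", None)]
    if pos is not None:
        h2_channels.append(("ROX", "threshold", pos))
    b.comparator_side("main", "H1", br["y_species"], br["y_cap"], h1_channels)
    b.comparator_side("main", "H2", br["x_species"], br["x_cap"], h2_channels)
    b.metadata = {
        "panel_id": weights.panel_id,
        "boundaries": list(spec.boundaries),
        "classes": list(spec.classes),
        "weights": {lab: float(v) for lab, v in zip(labels, w)},
        "branches": [br],
    }
    circuit = b.build()
    validate_topology(circuit)
    return circuit


@dataclass(frozen=True)
class DualGeneRuleSet:
    """Dual-gene dosing comparator layout.

    Each gene gets its own weighted-sum branch with a presence channel
    (net < 0: reduced function) and a severity threshold channel on the
    negative side (``pm_boundary``: poor-metabolizer genotype).  The
    positive leftovers of both genes are pooled and compared collectively
    against ``collective_boundary``.
    """

    gene1: str
    gene2: str
    pm_boundary: float = 4.0  # |net| in 1x units flagging a PM genotype
    collective_boundary: float = 0.5  # pooled positive excess, 1x units
    channel_map: Mapping[str, str] = field(
        default_factory=lambda: {
            "gene1_presence": "VIC",
            "gene1_threshold": "FAM",
            "gene2_presence": "Cy5",
            "gene2_threshold": "ROX",
            "collective": "HEX",
        }
    )


def compile_dual_gene(
    weights_1: CoefficientArray,
    weights_2: CoefficientArray,
    rules: DualGeneRuleSet,
    base_unit: float = DEFAULT_BASE_UNIT_NM,
) -> Circuit:
    """Compile two parallel weighted-sum branches plus a collective comparator."""
    w1 = list(weights_1.weights)
    w2 = list(weights_2.weights)
    if not any(w1) and not any(w2):
        raise CompileError("empty circuit: both weight arrays are all-zero")
    l1 = list(weights_1.allele_labels)
    l2 = list(weights_2.allele_labels)
    overlap = set(l1) & set(l2)
    if overlap:
        raise CompileError(f"overlapping allele namespaces: {sorted(overlap)}")
    b = _Builder(f"{rules.gene1}+{rules.gene2}-dosing", "dual", base_unit)
    br1 = b.weighted_sum_branch(rules.gene1, l1, w1)
    br2 = b.weighted_sum_branch(rules.gene2, l2, w2)
    cm = rules.channel_map
    for br, pres_key, thr_key in (
        (br1, "gene1_presence", "gene1_threshold"),
        (br2, "gene2_presence", "gene2_threshold"),
    ):
        ns = br["ns"]
        b.comparator_side(
            ns,
            "H1",
            br["y_species"],
            br["y_cap"],
            [
                (cm[pres_key], "presence", None),
                (cm[thr_key], "threshold", rules.pm_boundary),
            ],
        )
        # positive leftover feeds the collective pool via its own copy
        (h2,) = b.comparator_side(
            ns, "H2", br["x_species"], br["x_cap"],
            [(f"pool-{ns}", "pool", None)], emit_reporters=False,
        )
        pt = b.domain(f"pool_t_{ns}", STANDARD_TOEHOLD_NT, "toehold")
        pb = b.domain(f"pool_b_{ns}", 15, "branch")
        b.add_gate(
            name=f"POOL:{ns}",
            kind="summation",
            top_strand=b.strand(f"pool_top:{ns}", [pb]),
            bottom_strand=b.strand(f"pool_bot:{ns}", [pt, pb]),
            initial_concentration=TRANSFORMATION_EXCESS * br["x_cap"],
            toehold_class="standard",
            params={
                "branch": "pool",
                "ns": ns,
                "input_species": h2,
                "output_species": "C:pool",
                "capacity": br["x_cap"],
            },
        )
    # collective threshold + reporter on the pooled species
    th_nm = rules.collective_boundary * base_unit
    t = b.domain("th_t_pool", EXTENDED_TOEHOLD_NT, "toehold")
    pbc = b.domain("pool_b_collective", 15, "branch")
    b.add_gate(
        name=f"TH:pool:{cm['collective']}",
        kind="threshold",
        top_strand=b.strand("th_top:pool", [t]),
        bottom_strand=b.strand("th_bot:pool", [t, pbc]),
        initial_concentration=th_nm,
        toehold_class="extended",
        params={"h_species": "C:pool", "channel": cm["collective"],
                "ns": "pool"},
    )
    b._reporter(
        "pool", cm["collective"], "C:pool", "threshold",
        br1["x_cap"] + br2["x_cap"], th_nm, 1,
    )
    b.metadata = {
        "genes": [rules.gene1, rules.gene2],
        "pm_boundary": rules.pm_boundary,
        "collective_boundary": rules.collective_boundary,
        "channel_map": dict(cm),
        "branches": [br1, br2],
        "weights": {
            **{lab: float(v) for lab, v in zip(l1, w1)},
            **{lab: float(v) for lab, v in zip(l2, w2)},
        },
    }
    circuit = b.build()
    validate_topology(circuit)
    return circuit


def compile_prs(
    model,
    encoding: str = "paper_literal",
    base_unit: float = PRS_BASE_UNIT_NM,
    multiplier: float = PRS_MULTIPLIER_NM,
    screen_threshold: float | None = None,
    circuit_id: str | None = None,
) -> Circuit:
    """Compile a polygenic-risk-score circuit from a scoring model.

    ``paper_literal`` emits, per variant, a catalytic effect-allele M gate
    at ``2 * lnOR * multiplier`` nM routed to X and an other-allele gate at
    ``lnOR * multiplier`` nM routed to Y, so the circuit's net
    concentration is ``multiplier`` nM per unit of the literal ternary
    score.  ``exact_dosage`` emits one stoichiometric (fuel-less)
    effect-allele gate per variant at ``2 * lnOR * multiplier`` nM; inputs
    are then given at ``dosage * lnOR * multiplier`` nM so the released
    output is exactly proportional to the allelic dosage.

    ``screen_threshold`` (lnOR-score units) adds the high-risk ROX channel
    at ``screen_threshold * multiplier`` nM on the positive side.
    """
    variants = list(model.variants)
    if not variants:
        raise CompileError("empty circuit: scoring model has no variants")
    if encoding not in ("paper_literal", "exact_dosage"):
        raise CompileError(f"unknown encoding {encoding!r}")
    bad = [v.variant_id for v in variants if v.effect_weight < 0]
    if bad:
        raise UnsupportedEncodingError(
            "negative lnOR weights cannot be represented by this encoding; "
            f"remap variants {bad} to the opposite allele first"
        )
    b = _Builder(circuit_id or f"{model.pgs_id}-prs", "prs", base_unit)
    scale = multiplier / base_unit  # weights are stored in 1x units
    alleles, input_ids, weights = [], [], []
    for v in variants:
        alleles.append(f"{v.variant_id}:eff")
        input_ids.append(f"{v.variant_id}:eff")
        weights.append(2.0 * v.effect_weight * scale)
        if encoding == "paper_literal":
            alleles.append(f"{v.variant_id}:oth")
            input_ids.append(f"{v.variant_id}:oth")
            weights.append(-1.0 * v.effect_weight * scale)
    br = b.weighted_sum_branch(
        "prs",
        alleles,
        weights,
        catalytic=(encoding == "paper_literal"),
        input_ids=input_ids,
    )
    h2_channels = [("Cy5", "presence", None)]
    if screen_threshold is not None:
        h2_channels.append(
            ("ROX", "threshold", screen_threshold * multiplier / base_unit)
        )
    b.comparator_side("prs", "H1", br["y_species"], br["y_cap"],
                      [("VIC", "presence", None)])
    b.comparator_side("prs", "H2", br["x_species"], br["x_cap"], h2_channels)
    b.metadata = {
        "pgs_id": model.pgs_id,
        "encoding": encoding,
        "multiplier": multiplier,
        "screen_threshold": screen_threshold,
        "variants": [v.variant_id for v in variants],
        "branches": [br],
        "weights": {lab: float(w) for lab, w in zip(alleles, weights)},
    }
    circuit = b.build()
    validate_topology(circuit)
    return circuit


def validate_topology(circuit: Circuit) -> bool:
    """Structural checks: wiring completeness and reporter reachability."""
    m_gates = circuit.gates_of_kind("multiplication")
    sum_gates = {
        (g.params["ns"], g.params["branch"]): g
        for g in circuit.gates_of_kind("summation")
        if g.params.get("branch") in ("X", "Y")
    }
    for g in m_gates:
        key = (g.params["ns"], g.params["branch"])
        if key not in sum_gates:
            raise WiringError(
                f"M gate {g.name}: no summation gate for branch {key}"
            )
        if g.params["input_species"] not in circuit.input_map.values():
            raise WiringError(f"M gate {g.name}: orphan input toehold")
        if g.params.get("catalytic"):
            fuels = [
                f
                for f in circuit.gates_of_kind("fuel")
                if f.params.get("allele") == g.params["allele"]
            ]
            if len(fuels) != 1:
                raise WiringError(f"M gate {g.name}: expected exactly one fuel")
    produced = set()
    for g in circuit.gates_of_kind("transformation"):
        produced.add(g.params["output_species"])
    for g in circuit.gates_of_kind("summation"):
        if g.params.get("branch") == "pool":
            if g.params["input_species"] not in produced:
                raise WiringError(
                    f"pool gate {g.name}: unreachable input "
                    f"{g.params['input_species']}"
                )
            produced.add(g.params["output_species"])
    for g in circuit.gates_of_kind("reporter"):
        if g.params["h_species"] not in produced:
            raise WiringError(
                f"reporter {g.name}: species {g.params['h_species']} is not "
                "produced by any transformation/pool gate"
            )
    for g in circuit.gates_of_kind("threshold"):
        if g.params["h_species"] not in produced:
            raise WiringError(
                f"threshold {g.name}: unreachable species "
                f"{g.params['h_species']}"
            )
    return True


def annotate_sequences(circuit: Circuit, seed: int = 0) -> dict[str, str]:
    """Assign concrete sequences to every strand (via the sequence designer).

    Returns strand name -> sequence; also stored in circuit.metadata.
    """
    from .seqdesign import SequenceConstraintSet, generate_domain

    constraints = SequenceConstraintSet()
    pool: list[str] = []
    dom_seqs: dict[str, str] = {}
    for i, (name, dom) in enumerate(sorted(circuit.domains.items())):
        role = "generic" if dom.role == "toehold" else "gate"
        # the 35% shared-stretch screen applies to branch-length domains;
        # short toeholds cannot satisfy it pairwise across a large pool
        screen = pool if dom.length >= 12 else []
        seq = generate_domain(
            dom.length, role, constraints, screen, seed=seed + i
        )
        dom_seqs[name] = seq
        if dom.length >= 12:
            pool.append(seq)
    strand_seqs = {
        name: "".join(dom_seqs[d] for d in s.domains if d in dom_seqs)
        for name, s in sorted(circuit.strands.items())
    }
    circuit.metadata["strand_sequences"] = strand_seqs
    return strand_seqs


def export_fasta(circuit: Circuit) -> str:
    """FASTA export of annotated strand sequences (one record per strand)."""
    seqs = circuit.metadata.get("strand_sequences")
    if seqs is None:
        raise CompileError("circuit has no sequence annotation; "
                           "call annotate_sequences first")
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        lines.append(seq)
    return "\n".join(lines) + "\n"
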