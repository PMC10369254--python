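"""Mass-action expansion and ODE integration of compiled circuits.

Every gate kind expands into at most bimolecular toehold-mediated
strand-displacement reactions:

* multiplication (seesaw): ``input + gate -> output + intermediate`` and
  ``fuel + intermediate -> input + waste`` — the input is regenerated, so a
  sub-stoichiometric input releases the full, gate-limited output;
* summation: ``output_i + S -> common + waste``;
* subtraction (cooperative hybridization): ``X + G <=> I`` (reversible
  toehold association) followed by irreversible capture ``I + Y -> waste``,
  annihilating X and Y stoichiometrically;
* transformation (truncated toehold, slow): leftover ``Y + TG1 -> H1``,
  leftover ``X + TG2 -> H2``;
* threshold (extended toehold, fast): ``H + TH -> waste``;
* reporter (catalytic): ``H + REP -> H + fluorophore`` — H is restored, so
  reporting does not perturb the comparator arithmetic.

Rate constants are model parameters chosen to honour the designed timescale
ordering (threshold >> transformation, subtraction >> transformation); see
the package methods note for the calibration reasoning.  Strand-composition
bookkeeping is attached to every species so that conservation of each
elementary strand can be asserted along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .compiler import Circuit
from .errors import CalibrationError, IntegrationError, WiringError
from .ldr import InputVector

_NM = 1e-9  # convert M^-1 s^-1 -> nM^-1 s^-1


@dataclass(frozen=True)
class RateConfig:
    """Displacement rate constants (M^-1 s^-1 unless noted).

    ``report`` drives the slow catalytic restoration reporters behind
    threshold gates — seesaw thresholding requires threshold >> reporter,
    so that sub-threshold H is absorbed before it can light its channel.
    ``report_presence`` is kept separate for presence channels (same
    default).  ``subtraction_reverse`` (s^-1) is the dissociation rate of
    the singly-bound cooperative-gate intermediate; ``cooperative`` the
    second-arm capture rate that completes an annihilation event.
    """

    standard: float = 1.0e6
    truncated: float = 3.75e3
    extended: float = 6.0e6
    cooperative: float = 1.0e7
    report: float = 3.5e5
    report_presence: float = 3.5e5
    subtraction_reverse: float = 0.25  # s^-1
    leak: float = 0.0  # s^-1, spontaneous gate opening (default off)

    def scaled(self, factor: float) -> "RateConfig":
        """Uniformly speed up all reactions (fast-kinetics limit)."""
        return RateConfig(
            standard=self.standard * factor,
            truncated=self.truncated * factor,
            extended=self.extended * factor,
            cooperative=self.cooperative * factor,
            report=self.report * factor,
            report_presence=self.report_presence * factor,
            subtraction_reverse=self.subtraction_reverse * factor,
            leak=self.leak * factor,
        )


@dataclass(frozen=True)
class Reaction:
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float  # nM^-1 s^-1 (bimolecular) or s^-1 (unimolecular)
    note: str = ""

    def __post_init__(self):
        if self.rate_constant <= 0:
            raise WiringError(f"non-positive rate constant in {self.note}")
        if not (1 <= len(self.reactants) <= 2):
            raise WiringError("reactions must be uni- or bimolecular")


@dataclass
class ReactionNetwork:
    species: list[str]
    initial: dict[str, float]  # nM
    reactions: list[Reaction]
    compositions: dict[str, dict[str, int]] = field(default_factory=dict)

    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def initial_vector(self) -> np.ndarray:
        return np.array([self.initial.get(s, 0.0) for s in self.species])

    def validate(self):
        known = set(self.species)
        for r in self.reactions:
            for s in r.reactants + r.products:
                if s not in known:
                    raise WiringError(f"undeclared species {s!r} in {r.note}")
            if self.compositions:
                lhs: dict[str, int] = {}
                rhs: dict[str, int] = {}
                for s in r.reactants:
                    for strand, n in self.compositions.get(s, {}).items():
                        lhs[strand] = lhs.get(strand, 0) + n
                for s in r.products:
                    for strand, n in self.compositions.get(s, {}).items():
                        rhs[strand] = rhs.get(strand, 0) + n
                if lhs != rhs:
                    raise WiringError(
                        f"reaction {r.note}: strand composition not conserved "
                        f"({lhs} -> {rhs})"
                    )
        return True


@dataclass
class Trajectory:
    times: np.ndarray  # s
    concentrations: np.ndarray  # species x time, nM
    species: list[str]
    network: ReactionNetwork
    metadata: dict = field(default_factory=dict)

    def series(self, species: str) -> np.ndarray:
        try:
            i = self.species.index(species)
        except ValueError:
            raise WiringError(f"no species {species!r} in trajectory")
        return self.concentrations[i]

    def at(self, species: str, t: float) -> float:
        y = self.series(species)
        return float(np.interp(t, self.times, y))

    def endpoint(self, species: str) -> float:
        return float(self.series(species)[-1])

    def mass_conservation_residual(self) -> float:
        """Max relative drift of any strand-composition total over time."""
        comp = self.network.compositions
        if not comp:
            return 0.0
        strands = sorted({s for c in comp.values() for s in c})
        s_index = {s: i for i, s in enumerate(strands)}
        mat = np.zeros((len(strands), len(self.species)))
        for j, sp in enumerate(self.species):
            for strand, n in comp.get(sp, {}).items():
                mat[s_index[strand], j] = n
        totals = mat @ self.concentrations  # strands x time
        ref = totals[:, :1]
        scale = np.maximum(np.abs(ref), 1e-12)
        return float(np.max(np.abs(totals - ref) / scale))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.concentrations.T, columns=self.species
        )
        df.insert(0, "time_s", self.times)
        return df


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-fluorophore RFU normalisation anchors (nM)."""

    baseline: dict[str, float]
    saturation: dict[str, float]

    def __post_init__(self):
        for f, sat in self.saturation.items():
            base = self.baseline.get(f, 0.0)
            if sat <= base:
                raise CalibrationError(
                    f"{f}: saturation ({sat}) must exceed baseline ({base})"
                )


class _NetworkBuilder:
    def __init__(self):
        self.species: list[str] = []
        self.initial: dict[str, float] = {}
        self.reactions: list[Reaction] = []
        self.compositions: dict[str, dict[str, int]] = {}

    def sp(self, name: str, conc: float = 0.0, comp: dict | None = None):
        if name not in self.initial:
            self.species.append(name)
            self.initial[name] = conc
            self.compositions[name] = dict(comp or {})
        else:
            if conc:
                self.initial[name] += conc
            if comp and not self.compositions[name]:
                self.compositions[name] = dict(comp)
        return name

    def rxn(self, reactants, products, k, note=""):
        self.reactions.append(
            Reaction(tuple(reactants), tuple(products), k, note)
        )

    def network(self) -> ReactionNetwork:
        net = ReactionNetwork(
            species=self.species,
            initial=self.initial,
            reactions=self.reactions,
            compositions=self.compositions,
        )
        net.validate()
        return net


def build_reaction_network(
    circuit: Circuit,
    inputs: InputVector | Mapping[str, float],
    rates: RateConfig | None = None,
) -> ReactionNetwork:
    """Expand a compiled circuit plus an input vector into reactions."""
    rc = rates or RateConfig()
    k_std = rc.standard * _NM
    k_trunc = rc.truncated * _NM
    k_ext = rc.extended * _NM
    k_coop = rc.cooperative * _NM
    k_rep = rc.report * _NM
    k_pres = rc.report_presence * _NM

    conc_map = dict(inputs.items()) if isinstance(inputs, InputVector) else dict(
        inputs
    )
    unknown = [a for a in conc_map if a not in circuit.input_map]
    if unknown:
        raise WiringError(f"input species not in circuit: {sorted(unknown)}")

    b = _NetworkBuilder()

    # declare inputs for every wired allele (absent -> 0 nM)
    for input_id, species in circuit.input_map.items():
        b.sp(species, conc_map.get(input_id, 0.0), {f"prim.{input_id}": 1})

    for g in circuit.gates_of_kind("multiplication"):
        a = g.params["allele"]
        ns = g.params["ns"]
        branch = g.params["branch"]
        inp = g.params["input_species"]
        out = g.params["output_species"]
        gate = b.sp(f"M:{a}", g.initial_concentration,
                    {f"mtop.{a}": 1, f"mbot.{a}": 1})
        prim = next(iter(b.compositions[inp]))
        out_s = b.sp(out, 0.0, {f"mtop.{a}": 1})
        inter = b.sp(f"Mint:{a}", 0.0, {prim: 1, f"mbot.{a}": 1})
        b.rxn([inp, gate], [out_s, inter], k_std, f"M displacement {a}")
        if g.params.get("catalytic", True):
            fuel = b.sp(f"FUEL:{a}", 0.0, {f"fuel.{a}": 1})
            waste = b.sp(f"MW:{a}", 0.0, {f"fuel.{a}": 1, f"mbot.{a}": 1})
            b.rxn([fuel, inter], [inp, waste], k_std, f"fuel turnover {a}")
        if rc.leak > 0:
            shed = b.sp(f"MLEAK:{a}", 0.0, {f"mbot.{a}": 1})
            b.rxn([gate], [out_s, shed], rc.leak, f"leak {a}")

    for g in circuit.gates_of_kind("fuel"):
        a = g.params["allele"]
        b.sp(f"FUEL:{a}", g.initial_concentration, {f"fuel.{a}": 1})

    for g in circuit.gates_of_kind("summation"):
        ns = g.params["ns"]
        branch = g.params["branch"]
        if branch == "pool":
            continue  # handled after transformation gates exist
        gate = b.sp(f"S:{ns}:{branch}", g.initial_concentration,
                    {f"stop.{ns}.{branch}": 1, f"sbot.{ns}.{branch}": 1})
        common = b.sp(g.params["output_species"], 0.0,
                      {f"stop.{ns}.{branch}": 1})
        for m in circuit.gates_of_kind("multiplication"):
            if m.params["ns"] != ns or m.params["branch"] != branch:
                continue
            a = m.params["allele"]
            out_s = b.sp(m.params["output_species"], 0.0, {f"mtop.{a}": 1})
            waste = b.sp(f"SW:{a}", 0.0,
                         {f"mtop.{a}": 1, f"sbot.{ns}.{branch}": 1})
            b.rxn([out_s, gate], [common, waste], k_std, f"summation {a}")

    for g in circuit.gates_of_kind("subtraction"):
        ns = g.params["ns"]
        x = b.sp(g.params["x_species"], 0.0, {f"stop.{ns}.X": 1})
        y = b.sp(g.params["y_species"], 0.0, {f"stop.{ns}.Y": 1})
        gate = b.sp(f"SUBG:{ns}", g.initial_concentration, {f"sub.{ns}": 1})
        inter = b.sp(f"SUBI:{ns}", 0.0, {f"stop.{ns}.X": 1, f"sub.{ns}": 1})
        waste = b.sp(
            f"SUBW:{ns}", 0.0,
            {f"stop.{ns}.X": 1, f"stop.{ns}.Y": 1, f"sub.{ns}": 1},
        )
        b.rxn([x, gate], [inter], k_std, f"subtraction bind {ns}")
        b.rxn([inter], [x, gate], rc.subtraction_reverse,
              f"subtraction unbind {ns}")
        b.rxn([inter, y], [waste], k_coop, f"cooperative capture {ns}")

    for g in circuit.gates_of_kind("transformation"):
        ns = g.params["ns"]
        ch = g.params["channel"]
        src = g.params["input_species"]
        dst = g.params["output_species"]
        branch = "Y" if g.params["side"] == "H1" else "X"
        gate = b.sp(f"TGG:{ns}:{ch}", g.initial_concentration,
                    {f"htop.{ns}.{ch}": 1, f"tgbot.{ns}.{ch}": 1})
        src_s = b.sp(src, 0.0, {f"stop.{ns}.{branch}": 1})
        dst_s = b.sp(dst, 0.0, {f"htop.{ns}.{ch}": 1})
        waste = b.sp(f"TW:{ns}:{ch}", 0.0,
                     {f"stop.{ns}.{branch}": 1, f"tgbot.{ns}.{ch}": 1})
        b.rxn([src_s, gate], [dst_s, waste], k_trunc, f"transformation {dst}")

    for g in circuit.gates_of_kind("summation"):
        if g.params.get("branch") != "pool":
            continue
        ns = g.params["ns"]
        src = g.params["input_species"]
        dst = g.params["output_species"]
        src_comp = b.compositions.get(src) or {src: 1}
        src_s = b.sp(src, 0.0, src_comp)
        gate = b.sp(f"POOLG:{ns}", g.initial_concentration,
                    {"pooltop.common": 1, f"poolbot.{ns}": 1})
        dst_s = b.sp(dst, 0.0, {"pooltop.common": 1})
        waste = b.sp(f"PW:{ns}", 0.0, {**src_comp, f"poolbot.{ns}": 1})
        b.rxn([src_s, gate], [dst_s, waste], k_std, f"pool {ns}")

    for g in circuit.gates_of_kind("threshold"):
        ch = g.params["channel"]
        ns = g.params["ns"]
        h = g.params["h_species"]
        h_comp = b.compositions.get(h) or {h: 1}
        h_s = b.sp(h, 0.0, h_comp)
        gate = b.sp(f"THG:{ns}:{ch}", g.initial_concentration,
                    {f"th.{ns}.{ch}": 1})
        waste = b.sp(f"THW:{ns}:{ch}", 0.0, {**h_comp, f"th.{ns}.{ch}": 1})
        b.rxn([h_s, gate], [waste], k_ext, f"threshold {ns}:{ch}")

    for g in circuit.gates_of_kind("reporter"):
        f = g.params["fluorophore"]
        h = g.params["h_species"]
        h_comp = b.compositions.get(h) or {h: 1}
        h_s = b.sp(h, 0.0, h_comp)
        gate = b.sp(f"REPG:{f}", g.initial_concentration, {f"rep.{f}": 1})
        fluor = b.sp(f"FLUOR:{f}", 0.0, {f"rep.{f}": 1})
        k = k_pres if g.params["mode"] == "presence" else k_rep
        b.rxn([h_s, gate], [h_s, fluor], k, f"reporter {f}")

    return b.network()


def side_totals(trajectory: Trajectory, circuit: Circuit) -> dict:
    """Total H material produced per comparator side, from gate turnover.

    Each transformation event consumes one gate copy, so the side's total
    production is the summed depletion of its transformation gates —
    independent of how much H was later absorbed by thresholds.
    """
    totals: dict[tuple[str, str], float] = {}
    for g in circuit.gates_of_kind("transformation"):
        key = (g.params["ns"], g.params["side"])
        gate_species = f"TGG:{g.params['ns']}:{g.params['channel']}"
        consumed = g.initial_concentration - trajectory.endpoint(gate_species)
        totals[key] = totals.get(key, 0.0) + consumed
    return totals


def simulate(
    network: ReactionNetwork,
    t_end: float = 9000.0,
    reltol: float = 1e-8,
    abstol: float = 1e-6,
    output_interval: float = 120.0,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the mass-action ODEs to a fixed output grid.

    Deterministic for fixed tolerances; raises IntegrationError on solver
    failure and asserts strand-material conservation to within 1e-6
    relative as a post-condition.
    """
    if t_end <= 0:
        raise IntegrationError("t_end must be positive")
    idx = network.index()
    y0 = network.initial_vector()
    n_sp = len(network.species)
    n_rx = len(network.reactions)

    r1 = np.empty(n_rx, dtype=int)
    r2 = np.full(n_rx, -1, dtype=int)
    ks = np.empty(n_rx)
    stoich = np.zeros((n_sp, n_rx))
    for j, r in enumerate(network.reactions):
        ks[j] = r.rate_constant
        r1[j] = idx[r.reactants[0]]
        if len(r.reactants) == 2:
            r2[j] = idx[r.reactants[1]]
        for s in r.reactants:
            stoich[idx[s], j] -= 1
        for s in r.products:
            stoich[idx[s], j] += 1
    bimol = r2 >= 0
    r2_safe = np.where(bimol, r2, 0)

    def rates_of(y):
        r = ks * y[r1]
        r = np.where(bimol, r * y[r2_safe], r)
        return r

    def rhs(_t, y):
        return stoich @ rates_of(y)

    def jac(_t, y):
        d = np.zeros((n_rx, n_sp))
        contrib1 = np.where(bimol, ks * y[r2_safe], ks)
        d[np.arange(n_rx), r1] += contrib1
        contrib2 = ks * y[r1]
        d[np.arange(n_rx)[bimol], r2[bimol]] += contrib2[bimol]
        return stoich @ d

    t_eval = np.arange(0.0, t_end + 0.5 * output_interval, output_interval)
    if t_eval[-1] > t_end:
        t_eval[-1] = t_end
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method=method,
        jac=jac,
        rtol=reltol,
        atol=abstol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    conc = np.maximum(sol.y, 0.0)  # clip tolerance-level negatives
    traj = Trajectory(
        times=sol.t,
        concentrations=conc,
        species=list(network.species),
        network=network,
        metadata={
            "method": method,
            "reltol": reltol,
            "abstol": abstol,
            "t_end": t_end,
        },
    )
    residual = traj.mass_conservation_residual()
    traj.metadata["mass_conservation_residual"] = residual
    if residual > 1e-6:
        raise IntegrationError(
            f"mass conservation violated: relative residual {residual:.2e}"
        )
    return traj


def default_calibration(circuit: Circuit) -> CalibrationCurve:
    """Baseline 0 (no-input negative control), saturation at full reporter
    turnover — the standard-initiator anchor of the RFU scale."""
    sat = {}
    for fluor, gate_name in circuit.reporter_map.items():
        sat[fluor] = circuit.gate(gate_name).initial_concentration
    return CalibrationCurve(baseline={f: 0.0 for f in sat}, saturation=sat)


def endpoint_rfu(
    trajectory: Trajectory,
    calibration: CalibrationCurve,
    t: float | None = None,
) -> dict[str, float]:
    """Normalised fluorescence per channel at time t (default: endpoint)."""
    t_used = trajectory.times[-1] if t is None else t
    if t_used > trajectory.times[-1] + 1e-9:
        raise CalibrationError("requested time beyond trajectory end")
    out = {}
    for fluor, sat in calibration.saturation.items():
        species = f"FLUOR:{fluor}"
        if species not in trajectory.species:
            raise CalibrationError(f"no fluorophore species for {fluor}")
        base = calibration.baseline.get(fluor, 0.0)
        c = trajectory.at(species, t_used)
        out[fluor] = max(0.0, (c - base) / (sat - base))
    return out


# ---------------------------------------------------------------------------
# stand-alone scenario networks (single computing stages)
# ---------------------------------------------------------------------------


def mgate_network(
    gate_nm: float = 60.0,
    fuel_nm: float | None = None,
    input_nm: float = 10.0,
    rates: RateConfig | None = None,
) -> ReactionNetwork:
    """One seesaw multiplication gate with fuel, in isolation."""
    rc = rates or RateConfig()
    k = rc.standard * _NM
    b = _NetworkBuilder()
    inp = b.sp("in:a", input_nm, {"prim.a": 1})
    gate = b.sp("M:a", gate_nm, {"mtop.a": 1, "mbot.a": 1})
    out = b.sp("out:a", 0.0, {"mtop.a": 1})
    inter = b.sp("Mint:a", 0.0, {"prim.a": 1, "mbot.a": 1})
    fuel = b.sp("FUEL:a", 2.0 * gate_nm if fuel_nm is None else fuel_nm,
                {"fuel.a": 1})
    waste = b.sp("MW:a", 0.0, {"fuel.a": 1, "mbot.a": 1})
    b.rxn([inp, gate], [out, inter], k, "M displacement")
    b.rxn([fuel, inter], [inp, waste], k, "fuel turnover")
    return b.network()


def arithmetic_network(
    x0: float,
    y0: float,
    capacity: float = 120.0,
    rates: RateConfig | None = None,
) -> ReactionNetwork:
    """Subtraction + transformation stage fed with X and Y directly.

    ``capacity`` is the largest X or Y the stage must handle; gate excesses
    follow the compiler's sizing rules.
    """
    from .compiler import SUBTRACTION_EXCESS, TRANSFORMATION_EXCESS

    rc = rates or RateConfig()
    k_std = rc.standard * _NM
    k_tr = rc.truncated * _NM
    k_coop = rc.cooperative * _NM
    b = _NetworkBuilder()
    x = b.sp("X:main", x0, {"stop.main.X": 1})
    y = b.sp("Y:main", y0, {"stop.main.Y": 1})
    sub = b.sp("SUBG:main", SUBTRACTION_EXCESS * capacity, {"sub.main": 1})
    inter = b.sp("SUBI:main", 0.0, {"stop.main.X": 1, "sub.main": 1})
    sw = b.sp("SUBW:main", 0.0,
              {"stop.main.X": 1, "stop.main.Y": 1, "sub.main": 1})
    b.rxn([x, sub], [inter], k_std, "subtraction bind")
    b.rxn([inter], [x, sub], rc.subtraction_reverse, "subtraction unbind")
    b.rxn([inter, y], [sw], k_coop, "cooperative capture")
    for tag, src, strand in (("1", y, "Y"), ("2", x, "X")):
        gate = b.sp(f"TG{tag}:main", TRANSFORMATION_EXCESS * capacity,
                    {f"h{tag}top.main": 1, f"tg{tag}bot.main": 1})
        h = b.sp(f"H{tag}:main", 0.0, {f"h{tag}top.main": 1})
        w = b.sp(f"TW{tag}:main", 0.0,
                 {f"stop.main.{strand}": 1, f"tg{tag}bot.main": 1})
        b.rxn([src, gate], [h, w], k_tr, f"transformation H{tag}")
    return b.network()
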