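"""Learning allele coefficient arrays that linearly separate phenotype classes.

The decoding circuit computes, for a binary allele-presence vector x, the
pair of non-negative sums

    X = sum_i max(w_i, 0) x_i        (positively weighted alleles)
    Y = sum_i max(-w_i, 0) x_i       (negatively weighted alleles)

and reports net = X - Y against fixed comparator boundaries.  A coefficient
array w is *feasible* for a genotype–phenotype table when every genotype's
net score lies strictly inside the interval assigned to its class, with at
least ``margin`` clearance from the interval boundaries.  Feasible arrays
are found by linear programming (one two-sided inequality per genotype),
minimising total gate material sum_i |w_i|; the solution is snapped to a
small-denominator rational grid so that weights are realisable as pipetted
gate concentrations, with a bounded integer program as fallback when
snapping breaks feasibility.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import optimize

from .errors import ConfigError, DimensionError, InfeasibilityError
from .genotype import GeneticCode, GenotypePhenotypeTable


@dataclass(frozen=True)
class ClassIntervalSpec:
    """Ordered phenotype classes and the score boundaries separating them.

    ``boundaries`` has one entry fewer than ``classes``; class k occupies
    the open interval (boundaries[k-1], boundaries[k]) on the net-score
    line, with -inf/+inf at the extremes.  All quantities are in 1x
    concentration units.
    """

    classes: tuple[str, ...]
    boundaries: tuple[float, ...]
    margin: float = 0.5

    def __post_init__(self):
        if len(self.boundaries) != len(self.classes) - 1:
            raise ConfigError(
                "number of boundaries must be number of classes minus one"
            )
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ConfigError("boundaries must be strictly increasing")
        if self.margin < 0:
            raise ConfigError("margin must be non-negative")

    def interval(self, label: str) -> tuple[float, float]:
        try:
            k = self.classes.index(label)
        except ValueError:
            raise ConfigError(f"label {label!r} not in interval spec")
        lo = -np.inf if k == 0 else self.boundaries[k - 1]
        hi = np.inf if k == len(self.classes) - 1 else self.boundaries[k]
        return lo, hi

    def scaled(self, c: float) -> "ClassIntervalSpec":
        return ClassIntervalSpec(
            classes=self.classes,
            boundaries=tuple(c * b for b in self.boundaries),
            margin=c * self.margin,
        )


@dataclass(frozen=True)
class CoefficientArray:
    """Signed per-allele weights in 1x concentration units."""

    panel_id: str
    weights: tuple[float, ...]
    allele_labels: tuple[str, ...] = ()

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.size == 0:
            raise DimensionError("empty coefficient array")
        if not np.all(np.isfinite(w)):
            raise DimensionError("coefficients must be finite")
        object.__setattr__(self, "weights", tuple(float(v) for v in w))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def to_frame(self):
        import pandas as pd

        labels = self.allele_labels or tuple(
            f"allele_{i}" for i in range(len(self.weights))
        )
        return pd.DataFrame({"allele": labels, "weight": self.weights})


@dataclass
class SeparabilityReport:
    """Scores, per-class ranges and achieved margin for a weight array."""

    scores: list[float]
    labels: list[str]
    class_ranges: dict[str, tuple[float, float]]
    achieved_margin: float
    feasible: bool
    violations: list[tuple[int, str, float]] = field(default_factory=list)

    def __bool__(self):
        return self.feasible


@dataclass(frozen=True)
class SolverConfig:
    margin: float | None = None  # None -> take the spec's margin
    weight_bound: float = 8.0
    integer_only: bool = False
    snap_denominators: tuple[int, ...] = (1, 2, 4, 8)
    seed: int = 0  # kept for config-file compatibility; the LP is deterministic


def score(code: GeneticCode, weights: CoefficientArray) -> tuple[float, float, float]:
    """Split a genetic code into (X_total, Y_total, net) under a weight array.

    X_total aggregates positively weighted present alleles, Y_total the
    negatively weighted ones; the circuit's subtraction stage computes
    net = X_total - Y_total.
    """
    w = weights.as_array()
    x = np.asarray(code.bits, dtype=float)
    if x.shape != w.shape:
        raise DimensionError(
            f"code length {x.size} does not match weight count {w.size}"
        )
    x_tot = float(np.sum(np.maximum(w, 0.0) * x))
    y_tot = float(np.sum(np.maximum(-w, 0.0) * x))
    return x_tot, y_tot, x_tot - y_tot


def verify_separability(
    table: GenotypePhenotypeTable,
    weights: CoefficientArray,
    spec: ClassIntervalSpec,
) -> SeparabilityReport:
    """Check interval membership of every genotype score; never raises."""
    scores, labels, violations = [], [], []
    clearances = []
    for i, (_, code, label) in enumerate(table.entries):
        _, _, net = score(code, weights)
        scores.append(net)
        labels.append(label)
        lo, hi = spec.interval(label)
        clearance = min(net - lo, hi - net)
        clearances.append(clearance)
        if clearance < spec.margin - 1e-9:
            violations.append((i, label, net))
    class_ranges: dict[str, tuple[float, float]] = {}
    for lab in spec.classes:
        vals = [s for s, l in zip(scores, labels) if l == lab]
        if vals:
            class_ranges[lab] = (min(vals), max(vals))
    achieved = float(min(clearances)) if clearances else np.inf
    return SeparabilityReport(
        scores=scores,
        labels=labels,
        class_ranges=class_ranges,
        achieved_margin=achieved,
        feasible=not violations,
        violations=violations,
    )


def _find_conflicting_pair(table: GenotypePhenotypeTable):
    seen: dict[tuple[int, ...], tuple[int, str]] = {}
    for i, (_, code, label) in enumerate(table.entries):
        prev = seen.get(code.bits)
        if prev is not None and prev[1] != label:
            return (prev[0], i)
        seen[code.bits] = (i, label)
    return None


def _constraint_rows(table, spec, margin):
    """Per-genotype inequality rows: lb <= w . x <= ub."""
    rows = []
    for _, code, label in table.entries:
        lo, hi = spec.interval(label)
        lb = -np.inf if np.isinf(lo) else lo + margin
        ub = np.inf if np.isinf(hi) else hi - margin
        rows.append((np.asarray(code.bits, dtype=float), lb, ub))
    return rows


def _solve_lp(rows, n, bound):
    """Min sum|w| subject to the interval constraints; returns w or None."""
    # variables: w (n) then t (n) with t >= |w|
    c = np.concatenate([np.zeros(n), np.ones(n)])
    a_ub, b_ub = [], []
    for x, lb, ub in rows:
        if np.isfinite(ub):
            a_ub.append(np.concatenate([x, np.zeros(n)]))
            b_ub.append(ub)
        if np.isfinite(lb):
            a_ub.append(np.concatenate([-x, np.zeros(n)]))
            b_ub.append(-lb)
    for i in range(n):
        row = np.zeros(2 * n)
        row[i], row[n + i] = 1.0, -1.0
        a_ub.append(row.copy())
        b_ub.append(0.0)
        row2 = np.zeros(2 * n)
        row2[i], row2[n + i] = -1.0, -1.0
        a_ub.append(row2)
        b_ub.append(0.0)
    bounds = [(-bound, bound)] * n + [(0, bound)] * n
    res = optimize.linprog(
        c,
        A_ub=np.array(a_ub),
        b_ub=np.array(b_ub),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        return None
    return res.x[:n]


def _solve_integer(rows, n, bound, denominator=1):
    """Exact fallback: bounded integer program on a 1/denominator grid."""
    d = denominator
    c = np.concatenate([np.zeros(n), np.ones(n)])
    a, lo_list, hi_list = [], [], []
    for x, lb, ub in rows:
        a.append(np.concatenate([x / d, np.zeros(n)]))
        lo_list.append(lb if np.isfinite(lb) else -np.inf)
        hi_list.append(ub if np.isfinite(ub) else np.inf)
    for i in range(n):
        row = np.zeros(2 * n)
        row[i], row[n + i] = 1.0, -1.0
        a.append(row.copy())
        lo_list.append(-np.inf)
        hi_list.append(0.0)
        row2 = np.zeros(2 * n)
        row2[i], row2[n + i] = -1.0, -1.0
        a.append(row2)
        lo_list.append(-np.inf)
        hi_list.append(0.0)
    constraints = optimize.LinearConstraint(np.array(a), lo_list, hi_list)
    b = bound * d
    res = optimize.milp(
        c,
        constraints=constraints,
        integrality=np.ones(2 * n),
        bounds=optimize.Bounds([-b] * n + [0] * n, [b] * (2 * n)),
    )
    if not res.success:
        return None
    return res.x[:n] / d


def _snap(w, denominator):
    return np.array([float(Fraction(round(v * denominator), denominator)) for v in w])


def learn_coefficients(
    table: GenotypePhenotypeTable,
    spec: ClassIntervalSpec,
    search: SolverConfig | None = None,
) -> CoefficientArray:
    """Find a rational coefficient array separating all classes.

    Raises :class:`InfeasibilityError` (naming a minimal conflicting
    genotype pair when one exists) if no array within the weight bound
    achieves the requested margin.
    """
    cfg = search or SolverConfig()
    margin = spec.margin if cfg.margin is None else cfg.margin
    missing = set(table.distinct_labels()) - set(spec.classes)
    if missing:
        raise ConfigError(f"interval spec does not cover labels {sorted(missing)}")
    pair = _find_conflicting_pair(table)
    if pair is not None:
        i, j = pair
        raise InfeasibilityError(
            "identical genetic codes with different classes: "
            f"rows {i} ({table.entries[i][2]}) and {j} ({table.entries[j][2]})",
            conflict=pair,
        )
    table.validate()
    n = table.panel.n_alleles
    rows = _constraint_rows(table, spec, margin)

    def _fail():
        pair = _find_conflicting_pair(table)
        if pair is not None:
            i, j = pair
            raise InfeasibilityError(
                "identical genetic codes with different classes: "
                f"rows {i} ({table.entries[i][2]}) and {j} ({table.entries[j][2]})",
                conflict=pair,
            )
        raise InfeasibilityError(
            f"no coefficient array within |w| <= {cfg.weight_bound} achieves "
            f"margin {margin} for the given boundaries"
        )

    candidates = []
    if not cfg.integer_only:
        w_lp = _solve_lp(rows, n, cfg.weight_bound)
        if w_lp is not None:
            for denom in cfg.snap_denominators:
                candidates.append(_snap(w_lp, denom))
    w_int = None
    weights = None
    labels = tuple(table.panel.allele_labels())
    for cand in candidates:
        arr = CoefficientArray(
            panel_id=table.panel.panel_id,
            weights=tuple(cand),
            allele_labels=labels,
        )
        report = verify_separability(table, arr, spec_with_margin(spec, margin))
        if report.feasible:
            weights = arr
            break
    if weights is None:
        # snapping broke feasibility (or LP skipped): exact grid search
        denom = 1 if cfg.integer_only else max(cfg.snap_denominators)
        w_int = _solve_integer(rows, n, cfg.weight_bound, denominator=denom)
        if w_int is None:
            _fail()
        weights = CoefficientArray(
            panel_id=table.panel.panel_id,
            weights=tuple(w_int),
            allele_labels=labels,
        )
    # solver soundness: every returned array must verify
    report = verify_separability(table, weights, spec_with_margin(spec, margin))
    if not report.feasible:
        _fail()
    return weights


def spec_with_margin(spec: ClassIntervalSpec, margin: float) -> ClassIntervalSpec:
    if margin == spec.margin:
        return spec
    return ClassIntervalSpec(
        classes=spec.classes, boundaries=spec.boundaries, margin=margin
    )


def brute_force_feasible(
    table: GenotypePhenotypeTable,
    spec: ClassIntervalSpec,
    bound: int = 8,
    margin: float | None = None,
) -> bool:
    """Exhaustive integer-weight feasibility check for small panels.

    Enumerates every integer weight vector in [-bound, bound]^n; intended as
    an independent oracle for panels with few alleles.
    """
    m = spec.margin if margin is None else margin
    n = table.panel.n_alleles
    codes = np.array([code.bits for _, code, _ in table.entries], dtype=float)
    lbs, ubs = [], []
    for _, _, label in table.entries:
        lo, hi = spec.interval(label)
        lbs.append(lo + m if np.isfinite(lo) else -np.inf)
        ubs.append(hi - m if np.isfinite(hi) else np.inf)
    lbs, ubs = np.array(lbs), np.array(ubs)
    grid = np.arange(-bound, bound + 1)
    for combo in itertools.product(grid, repeat=n):
        s = codes @ np.asarray(combo, dtype=float)
        if np.all(s >= lbs - 1e-9) and np.all(s <= ubs + 1e-9):
            return True
    return False
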