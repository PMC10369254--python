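"""Coefficient-array learning: feasibility, scoring arithmetic, oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stranddecoder import fixtures
from stranddecoder.errors import InfeasibilityError
from stranddecoder.genotype import (
    GeneticCode,
    GenotypePhenotypeTable,
    Locus,
    Panel,
    table_from_diplotypes,
)
from stranddecoder.learn import (
    ClassIntervalSpec,
    CoefficientArray,
    SolverConfig,
    brute_force_feasible,
    learn_coefficients,
    score,
    verify_separability,
)


def _one_locus_panel():
    return Panel(
        "TOY",
        "TOY",
        [Locus("snp1", "TOY", 100, "A", "G")],
        {"wt": {}, "var": {"snp1": "alt"}},
    )


def _two_locus_panel():
    return Panel(
        "TOY2",
        "TOY2",
        [Locus("snp1", "TOY2", 100, "A", "G"),
         Locus("snp2", "TOY2", 200, "C", "T")],
        {"wt": {}, "v1": {"snp1": "alt"}, "v2": {"snp2": "alt"}},
    )


def test_single_locus_carrier_model_is_feasible():
    panel = _one_locus_panel()
    table = table_from_diplotypes(
        panel,
        [("wt/wt", "non-carrier"), ("wt/var", "carrier"),
         ("var/var", "carrier")],
        ("non-carrier", "carrier"),
    )
    spec = ClassIntervalSpec(("non-carrier", "carrier"), (0.0,), margin=0.5)
    w = learn_coefficients(table, spec)
    for _, code, label in table.entries:
        _, _, net = score(code, w)
        assert (net < 0) == (label == "non-carrier")


def test_identical_codes_with_different_classes_are_infeasible():
    panel = _one_locus_panel()
    code = GeneticCode("TOY", (1, 1))
    table = GenotypePhenotypeTable(
        panel=panel,
        entries=[(None, code, "a")],
    )
    table.entries.append((None, code, "b"))  # appended after validation
    spec = ClassIntervalSpec(("a", "b"), (0.0,), margin=0.5)
    with pytest.raises(InfeasibilityError) as err:
        learn_coefficients(table, spec)
    # infeasibility diagnostics name a minimal conflicting pair
    assert err.value.conflict == (0, 1) or "identical" in str(err.value)


@pytest.mark.parametrize(
    "code,weights,expected",
    [
        ((0, 0), (-1.0, 2.0), (0.0, 0.0, 0.0)),
        ((1, 1), (-1.0, 2.0), (2.0, 1.0, 1.0)),
        ((1, 0), (-1.0, 2.0), (0.0, 1.0, -1.0)),
    ],
)
def test_score_splits_positive_and_negative_weights(code, weights, expected):
    arr = CoefficientArray("p", weights)
    assert score(GeneticCode("p", code), arr) == expected


def test_cyp2c19_classes_occupy_their_intervals(cyp_fit):
    spec = fixtures.cyp2c19_interval_spec()
    report = cyp_fit.separability
    assert report.feasible
    assert report.achieved_margin >= spec.margin - 1e-9
    for s, label in zip(report.scores, report.labels):
        if label == "PM":
            assert s <= -2.0 - spec.margin + 1e-9
        if label == "UM":
            assert s >= 4.0 + spec.margin - 1e-9
        if label == "IM":
            assert -2.0 + spec.margin <= s <= -spec.margin
        if label == "EM":
            assert spec.margin <= s <= 4.0 - spec.margin


def test_dpyd_thirty_genotypes_separate_into_three_intervals(dpyd_fit):
    report = dpyd_fit.separability
    assert report.feasible
    assert len(report.scores) == 30
    for s, label in zip(report.scores, report.labels):
        if label == "poor":
            assert s < 0
        elif label == "normal":
            assert s > 4
        else:
            assert 0 < s < 4


def test_all_zero_weights_are_not_separable():
    table = fixtures.cyp2c19_table()
    w = CoefficientArray("CYP2C19", (0.0,) * 6,
                         tuple(table.panel.allele_labels()))
    report = verify_separability(table, w, fixtures.cyp2c19_interval_spec())
    assert not report.feasible


def test_learned_weights_live_on_a_small_denominator_grid(cyp_fit, dpyd_fit):
    for fit in (cyp_fit, dpyd_fit):
        for w in fit.weights.weights:
            frac = Fraction(w).limit_denominator(8)
            assert float(frac) == pytest.approx(w, abs=1e-12)


def _random_two_locus_table(rng):
    panel = _two_locus_panel()
    stars = list(panel.star_definitions)
    rows = []
    for i, a in enumerate(stars):
        for b in stars[i:]:
            label = rng.choice(["lo", "hi"])
            rows.append((f"{a}/{b}", label))
    return table_from_diplotypes(panel, rows, ("lo", "hi"))


@pytest.mark.parametrize("seed", range(6))
def test_lp_feasibility_matches_integer_brute_force(seed):
    """On 2-locus panels the LP+snap learner and exhaustive integer search
    must agree about feasibility (margin 0.5, |w| <= 8)."""
    rng = np.random.default_rng(seed)
    table = _random_two_locus_table(rng)
    spec = ClassIntervalSpec(("lo", "hi"), (0.0,), margin=0.5)
    oracle = brute_force_feasible(table, spec, bound=8)
    try:
        w = learn_coefficients(table, spec, SolverConfig(weight_bound=8))
        solver_feasible = verify_separability(table, w, spec).feasible
    except InfeasibilityError:
        solver_feasible = False
    assert solver_feasible == oracle


@settings(max_examples=20, deadline=None, derandomize=True)
@given(c=st.floats(min_value=0.25, max_value=4.0))
def test_feasibility_is_invariant_under_positive_scaling(c):
    table = fixtures.cyp2c19_table()
    spec = fixtures.cyp2c19_interval_spec()
    w = learn_coefficients(table, spec)
    scaled_w = CoefficientArray(
        w.panel_id, tuple(c * v for v in w.weights), w.allele_labels
    )
    assert verify_separability(table, scaled_w, spec.scaled(c)).feasible


def test_solver_output_always_reverifies(cyp_fit, dpyd_fit):
    # solver soundness: verify_separability holds for every returned array
    assert cyp_fit.separability.feasible
    assert dpyd_fit.separability.feasible
    for name in ("TPMT", "NUDT15"):
        from stranddecoder.model import GeneticDecoder

        fit = GeneticDecoder.from_fixture(name).fit()
        assert fit.separability.feasible
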