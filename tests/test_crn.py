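"""Mass-action simulation: stoichiometry, conservation, thresholding."""

import numpy as np
import pytest

from stranddecoder.crn import (
    CalibrationCurve,
    RateConfig,
    Reaction,
    ReactionNetwork,
    Trajectory,
    arithmetic_network,
    build_reaction_network,
    default_calibration,
    endpoint_rfu,
    mgate_network,
    simulate,
)
from stranddecoder.errors import (
    CalibrationError,
    IntegrationError,
    WiringError,
)

T_END = 9000.0  # 2.5 h


def test_single_seesaw_gate_expands_to_two_bimolecular_reactions():
    net = mgate_network(60.0, 120.0, 10.0)
    assert len(net.reactions) == 2
    assert all(len(r.reactants) == 2 for r in net.reactions)


def test_substoichiometric_input_releases_the_full_gate_output():
    """10 nM input fully displaces a 60 nM gate within 2.5 h (catalysis)."""
    traj = simulate(mgate_network(60.0, 120.0, 10.0), T_END)
    assert traj.endpoint("out:a") >= 0.95 * 60.0


def test_catalytic_output_is_insensitive_to_input_level():
    outs = [
        simulate(mgate_network(60.0, 120.0, inp), T_END).endpoint("out:a")
        for inp in (10.0, 20.0, 40.0, 60.0)
    ]
    assert (max(outs) - min(outs)) / max(outs) < 0.05


@pytest.mark.parametrize("x0,y0", [(0, 0), (60, 20), (30, 30), (0, 90)])
def test_annihilation_endpoints_follow_the_difference(x0, y0):
    traj = simulate(arithmetic_network(x0, y0, 120.0), T_END)
    scale = 120.0
    assert traj.endpoint("H1:main") == pytest.approx(
        max(0.0, y0 - x0), abs=0.1 * scale
    )
    assert traj.endpoint("H2:main") == pytest.approx(
        max(0.0, x0 - y0), abs=0.1 * scale
    )


def test_sixty_twenty_example_matches_the_stoichiometric_limit():
    traj = simulate(arithmetic_network(60.0, 20.0, 120.0), T_END)
    assert traj.endpoint("H2:main") == pytest.approx(40.0, abs=4.0)
    assert traj.endpoint("H1:main") < 2.0


def test_mass_conservation_holds_along_every_trajectory():
    traj = simulate(arithmetic_network(90.0, 60.0, 120.0), T_END)
    assert traj.metadata["mass_conservation_residual"] < 1e-6


def test_unbalanced_reaction_is_rejected_by_the_validator():
    net = ReactionNetwork(
        species=["a", "b"],
        initial={"a": 1.0, "b": 0.0},
        reactions=[Reaction(("a",), ("b", "b"), 1.0, "dup")],
        compositions={"a": {"s": 1}, "b": {"s": 1}},
    )
    with pytest.raises(WiringError):
        net.validate()


def test_no_input_leaves_all_fluorophores_dark(cyp_fit):
    circuit = cyp_fit.compile()
    net = build_reaction_network(circuit, {})
    traj = simulate(net, T_END)
    for fluor in circuit.reporter_map:
        assert traj.endpoint(f"FLUOR:{fluor}") == pytest.approx(0.0, abs=1e-6)


def test_unknown_input_species_is_a_wiring_error(cyp_fit):
    with pytest.raises(WiringError):
        build_reaction_network(cyp_fit.compile(), {"no-such-allele": 5.0})


def test_solver_rejects_nonpositive_horizon():
    with pytest.raises(IntegrationError):
        simulate(mgate_network(), t_end=0.0)


def _threshold_channel_network(h_total, th, k):
    """Threshold gate + slow catalytic reporter, with H produced gradually
    by a truncated-toehold transformation stage as in the full circuit."""
    return ReactionNetwork(
        species=["PRE", "TG", "TW", "H", "TH", "THW", "REP", "FLUOR"],
        initial={"PRE": h_total, "TG": 4.0 * h_total, "TH": th,
                 "REP": 100.0},
        reactions=[
            Reaction(("PRE", "TG"), ("H", "TW"), k.truncated * 1e-9,
                     "transformation"),
            Reaction(("H", "TH"), ("THW",), k.extended * 1e-9, "threshold"),
            Reaction(("H", "REP"), ("H", "FLUOR"), k.report * 1e-9,
                     "reporter"),
        ],
        compositions={
            "PRE": {"x": 1},
            "TG": {"h": 1, "g": 1},
            "TW": {"x": 1, "g": 1},
            "H": {"h": 1},
            "TH": {"t": 1},
            "THW": {"h": 1, "t": 1},
            "REP": {"r": 1},
            "FLUOR": {"r": 1},
        },
    )


@pytest.mark.parametrize("th", [10.0, 20.0, 40.0])
def test_threshold_gates_give_sharp_on_off_transitions(th):
    """Below 0.8x threshold the channel stays < 0.1 RFU; above 1.5x it
    exceeds 0.6 RFU by the 2.5 h endpoint."""
    k = RateConfig()
    lo = simulate(_threshold_channel_network(0.8 * th, th, k), T_END)
    hi = simulate(_threshold_channel_network(1.5 * th, th, k), T_END)
    assert lo.endpoint("FLUOR") / 100.0 < 0.1
    assert hi.endpoint("FLUOR") / 100.0 > 0.6


def test_rfu_normalisation_anchors():
    times = np.array([0.0, 100.0])
    conc = np.array([[0.0, 0.0], [0.0, 50.0], [0.0, 100.0]])
    net = ReactionNetwork(
        species=["FLUOR:base", "FLUOR:mid", "FLUOR:sat"],
        initial={}, reactions=[],
    )
    traj = Trajectory(times=times, concentrations=conc,
                      species=list(net.species), network=net)
    cal = CalibrationCurve(
        baseline={"base": 0.0, "mid": 0.0, "sat": 0.0},
        saturation={"base": 100.0, "mid": 100.0, "sat": 100.0},
    )
    rfu = endpoint_rfu(traj, cal)
    assert rfu == {"base": 0.0, "mid": 0.5, "sat": 1.0}


def test_missing_fluorophore_in_calibration_is_an_error(cyp_fit):
    circuit = cyp_fit.compile()
    traj = simulate(build_reaction_network(circuit, {}), 600.0)
    cal = CalibrationCurve(baseline={"nope": 0.0}, saturation={"nope": 10.0})
    with pytest.raises(CalibrationError):
        endpoint_rfu(traj, cal)


def test_default_calibration_saturates_at_reporter_capacity(cyp_fit):
    circuit = cyp_fit.compile()
    cal = default_calibration(circuit)
    for fluor, gate_name in circuit.reporter_map.items():
        assert cal.saturation[fluor] == circuit.gate(
            gate_name
        ).initial_concentration


def test_calibration_requires_saturation_above_baseline():
    with pytest.raises(CalibrationError):
        CalibrationCurve(baseline={"VIC": 5.0}, saturation={"VIC": 5.0})
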