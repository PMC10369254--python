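"""Circuit compilation: concentrations, counts, determinism, topology."""

import yaml
import pytest

from stranddecoder import fixtures
from stranddecoder.compiler import (
    Circuit,
    DualGeneRuleSet,
    compile_circuit,
    compile_dual_gene,
    compile_prs,
    validate_topology,
    annotate_sequences,
    export_fasta,
)
from stranddecoder.errors import CompileError, UnsupportedEncodingError, WiringError
from stranddecoder.learn import ClassIntervalSpec, CoefficientArray
from stranddecoder.prs import ScoringModel, ScoringVariant


@pytest.fixture(scope="module")
def cyp_circuit(cyp_fit):
    return cyp_fit.compile(base_unit=10.0)


def test_mgate_concentration_encodes_each_nonzero_weight(cyp_fit, cyp_circuit):
    weights = dict(zip(cyp_fit.weights.allele_labels, cyp_fit.weights.weights))
    m_gates = {g.params["allele"]: g
               for g in cyp_circuit.gates_of_kind("multiplication")}
    assert set(m_gates) == {a for a, w in weights.items() if w != 0}
    for allele, gate in m_gates.items():
        assert gate.initial_concentration == pytest.approx(
            abs(weights[allele]) * 10.0
        )
        # round trip: concentration / base_unit reproduces |w| exactly
        assert gate.initial_concentration / cyp_circuit.base_unit == abs(
            weights[allele]
        )
        assert (gate.params["branch"] == "X") == (weights[allele] > 0)


def test_fuel_strands_are_double_their_gate(cyp_circuit):
    m = {g.params["allele"]: g.initial_concentration
         for g in cyp_circuit.gates_of_kind("multiplication")}
    fuels = {g.params["allele"]: g.initial_concentration
             for g in cyp_circuit.gates_of_kind("fuel")}
    assert set(fuels) == set(m)
    for a in m:
        assert fuels[a] == pytest.approx(2.0 * m[a])


def test_comparator_levels_match_the_printed_boundaries(cyp_circuit):
    """FAM fires above 2x (20 nM at 1x = 10 nM), ROX above 4x (40 nM)."""
    by_fluor = {c["fluorophore"]: c for c in cyp_circuit.channels}
    fam = by_fluor["FAM"]
    rox = by_fluor["ROX"]
    assert fam["threshold_nM"] * fam["n_split"] == pytest.approx(20.0)
    assert rox["threshold_nM"] * rox["n_split"] == pytest.approx(40.0)


def test_zero_weight_allele_gets_no_multiplication_gate():
    w = CoefficientArray("p", (1.0, 0.0, -2.0), ("a", "b", "c"))
    spec = ClassIntervalSpec(("lo", "hi"), (0.0,), margin=0.5)
    circuit = compile_circuit(w, spec)
    alleles = {g.params["allele"]
               for g in circuit.gates_of_kind("multiplication")}
    assert alleles == {"a", "c"}


def test_gate_counts_follow_the_construction_rule():
    """6 nonzero alleles, boundaries [-2, 0, 4]: 6 M + 6 fuel + 2 S + 1 SUB
    + one transformation and one threshold per channel (VIC, FAM, Cy5, ROX)
    + 4 reporters."""
    w = CoefficientArray("p", (1, -2, 3, -4, 5, -6),
                         tuple("abcdef"))
    spec = ClassIntervalSpec(
        ("c1", "c2", "c3", "c4"), (-2.0, 0.0, 4.0), margin=0.5
    )
    circuit = compile_circuit(w, spec)
    kinds = {}
    for g in circuit.gates:
        kinds[g.kind] = kinds.get(g.kind, 0) + 1
    assert kinds == {
        "multiplication": 6,
        "fuel": 6,
        "summation": 2,
        "subtraction": 1,
        "transformation": 4,
        "threshold": 4,
        "reporter": 4,
    }


def test_compilation_is_deterministic_and_serializable(cyp_fit):
    a = cyp_fit.compile(base_unit=10.0).to_text()
    b = compile_circuit(
        cyp_fit.weights, fixtures.cyp2c19_interval_spec(), 10.0
    ).to_text()
    assert a == b
    parsed = yaml.safe_load(a)
    assert parsed["base_unit"] == 10.0
    assert len(parsed["gates"]) > 0


def test_empty_or_invalid_compiles_are_rejected():
    spec = ClassIntervalSpec(("lo", "hi"), (0.0,), margin=0.5)
    with pytest.raises(CompileError):
        compile_circuit(CoefficientArray("p", (0.0, 0.0), ("a", "b")), spec)
    with pytest.raises(CompileError):
        compile_circuit(CoefficientArray("p", (1.0,), ("a",)), spec,
                        base_unit=-5.0)


def test_dual_gene_layout_counts_and_namespacing():
    from stranddecoder.model import GeneticDecoder

    wt = GeneticDecoder.from_fixture("TPMT").fit().weights
    wn = GeneticDecoder.from_fixture("NUDT15").fit().weights
    rules = DualGeneRuleSet("TPMT", "NUDT15")
    circuit = compile_dual_gene(wt, wn, rules)
    assert len(circuit.gates_of_kind("multiplication")) == 12  # 8 + 4 alleles
    s_gates = [g for g in circuit.gates_of_kind("summation")
               if g.params.get("branch") in ("X", "Y")]
    assert len(s_gates) == 4  # one X/Y pair per gene
    assert len(circuit.gates_of_kind("subtraction")) == 2
    presence = [c for c in circuit.channels if c["mode"] == "presence"]
    assert {c["fluorophore"] for c in presence} == {"VIC", "Cy5"}
    assert "HEX" in circuit.reporter_map
    # per-gene branch gate concentrations match single-gene compiles
    single = compile_circuit(wt, fixtures.thiopurine_interval_spec())
    dual_m = {g.params["allele"]: g.initial_concentration
              for g in circuit.gates_of_kind("multiplication")
              if g.params["ns"] == "TPMT"}
    single_m = {g.params["allele"]: g.initial_concentration
                for g in single.gates_of_kind("multiplication")}
    assert dual_m == single_m


def test_dual_gene_rejects_overlapping_allele_names():
    w = CoefficientArray("A", (1.0, -1.0), ("x", "y"))
    with pytest.raises(CompileError):
        compile_dual_gene(w, w, DualGeneRuleSet("g1", "g2"))


def test_prs_gate_concentrations_scale_with_lnor(synthetic_scoring):
    model = ScoringModel(
        "T", (ScoringVariant("rs1", "A", "G", 0.25, 0.5),)
    )
    circuit = compile_prs(model, multiplier=100.0)
    concs = {g.params["allele"]: g.initial_concentration
             for g in circuit.gates_of_kind("multiplication")}
    assert concs["rs1:eff"] == pytest.approx(50.0)  # 2 * lnOR * 100
    assert concs["rs1:oth"] == pytest.approx(25.0)  # lnOR * 100
    full = compile_prs(synthetic_scoring)
    assert len(full.gates_of_kind("multiplication")) == 44  # 2 per variant


def test_prs_exact_dosage_uses_stoichiometric_effect_gates(synthetic_scoring):
    circuit = compile_prs(synthetic_scoring, encoding="exact_dosage")
    m = circuit.gates_of_kind("multiplication")
    assert len(m) == 22
    assert all(not g.params["catalytic"] for g in m)
    assert not circuit.gates_of_kind("fuel")


def test_prs_rejects_negative_lnor_and_empty_models():
    with pytest.raises(UnsupportedEncodingError):
        compile_prs(
            ScoringModel("T", (ScoringVariant("rs1", "A", "G", -0.2, 0.5),))
        )
    with pytest.raises(CompileError):
        compile_prs(ScoringModel("T", ()))


def test_topology_validator_catches_missing_summation(cyp_circuit):
    broken = Circuit(
        circuit_id="broken",
        kind="single",
        base_unit=10.0,
        gates=[g for g in cyp_circuit.gates if g.kind != "summation"],
        domains=cyp_circuit.domains,
        strands=cyp_circuit.strands,
        input_map=cyp_circuit.input_map,
        reporter_map=cyp_circuit.reporter_map,
        channels=cyp_circuit.channels,
    )
    with pytest.raises(WiringError):
        validate_topology(broken)


def test_sequence_annotation_exports_fasta(cyp_circuit):
    seqs = annotate_sequences(cyp_circuit, seed=11)
    assert set(seqs) == set(cyp_circuit.strands)
    fasta = export_fasta(cyp_circuit)
    assert fasta.count(">") == len(seqs)
    for seq in seqs.values():
        assert set(seq) <= set("ACGT")
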