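"""Pattern decoding, dose rules and pipeline behaviour."""

import pytest
from hypothesis import given, settings, strategies as st

from stranddecoder import fixtures
from stranddecoder.decode import (
    DecodeTable,
    FluorescencePattern,
    GeneBranchCall,
    INDETERMINATE,
    PipelineConfig,
    call_phenotype,
    decode_table_from_rules,
    recommend_dose,
    run_pipeline,
)
from stranddecoder.errors import InputError
from stranddecoder.ldr import LdrConfig

CHANNELS = ("VIC", "Cy5", "FAM", "ROX")


@pytest.fixture(scope="module")
def cyp_decode_table():
    return decode_table_from_rules(fixtures.cyp2c19_decode_rules(), CHANNELS)


def _pattern(threshold=0.4, **rfu):
    full = {ch: rfu.get(ch, 0.0) for ch in CHANNELS}
    return FluorescencePattern(rfu=full, on_threshold=threshold)


@pytest.mark.parametrize(
    "rfu,expected",
    [
        ({"VIC": 0.9, "FAM": 0.8}, "PM"),
        ({"VIC": 0.9}, "IM"),
        ({"Cy5": 0.95}, "EM"),
        ({"Cy5": 0.95, "ROX": 0.7}, "UM"),
        ({}, INDETERMINATE),  # all channels below threshold
        ({"FAM": 0.9}, INDETERMINATE),  # FAM without VIC matches no rule
    ],
)
def test_patterns_decode_to_their_metabolizer_class(
    cyp_decode_table, rfu, expected
):
    call = call_phenotype(_pattern(**rfu), cyp_decode_table, "s")
    assert call.label == expected


def test_a_reading_at_the_threshold_is_off(cyp_decode_table):
    # 0.39 < 0.4 and exactly 0.4 both count as OFF
    call = call_phenotype(
        _pattern(VIC=0.39, Cy5=0.95), cyp_decode_table
    )
    assert call.label == "EM"
    call = call_phenotype(_pattern(VIC=0.4, Cy5=0.95), cyp_decode_table)
    assert call.label == "EM"


def test_missing_channel_is_an_input_error(cyp_decode_table):
    pattern = FluorescencePattern(rfu={"VIC": 0.9}, on_threshold=0.4)
    with pytest.raises(InputError):
        call_phenotype(pattern, cyp_decode_table)


def test_duplicate_decode_rules_are_rejected():
    with pytest.raises(InputError):
        DecodeTable(
            channels=("VIC",),
            rules=((frozenset({"VIC"}), "a"), (frozenset({"VIC"}), "b")),
        )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    rfu=st.lists(
        st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=4
    ),
    t1=st.floats(min_value=0.4, max_value=0.95),
    t2=st.floats(min_value=0.4, max_value=0.95),
)
def test_raising_the_threshold_never_flips_definite_calls(
    cyp_decode_table, rfu, t1, t2
):
    """Moving the ON threshold up from the calibrated 0.4 may only push a
    call to indeterminate, never swap one definite class for another."""
    lo, hi = sorted((t1, t2))
    pat_lo = FluorescencePattern(dict(zip(CHANNELS, rfu)), on_threshold=lo)
    pat_hi = FluorescencePattern(dict(zip(CHANNELS, rfu)), on_threshold=hi)
    call_lo = cyp_decode_table.call(pat_lo)
    call_hi = cyp_decode_table.call(pat_hi)
    if call_hi != INDETERMINATE:
        assert call_hi == call_lo


@pytest.mark.parametrize(
    "s1,s2,collective,expected",
    [
        ("NM", "NM", True, "normal"),
        ("NM", "NM", False, INDETERMINATE),
        ("IM", "NM", True, "reduced"),
        ("NM", "IM", True, "reduced"),
        ("IM", "IM", False, "reduced"),
        ("PM", "NM", True, "alternative_agent"),
        ("IM", "PM", False, "alternative_agent"),
        (INDETERMINATE, "NM", True, INDETERMINATE),
    ],
)
def test_dual_gene_dose_recommendation_rules(s1, s2, collective, expected):
    rec = recommend_dose(
        GeneBranchCall("TPMT", s1), GeneBranchCall("NUDT15", s2), collective
    )
    assert rec.category == expected


def test_pipeline_on_empty_sample_list_returns_empty(cyp_fit):
    calls = run_pipeline(
        [],
        cyp_fit.model.panel,
        cyp_fit.weights,
        cyp_fit.model.interval_spec,
        cyp_fit.model.decode_table,
    )
    assert calls == []


def test_calls_are_invariant_to_batch_order(cyp_fit):
    """Shuffling the cohort must not change any per-sample call, even with
    per-allele ligation-efficiency jitter enabled."""
    samples = [("s1", "*1/*1"), ("s2", "*2/*2"), ("s3", "*1/*17"),
               ("s4", "*2/*17")]
    cfg = PipelineConfig(ldr=LdrConfig(efficiency_range=(0.35, 0.64)), seed=3)

    def run(order):
        calls = run_pipeline(
            order, cyp_fit.model.panel, cyp_fit.weights,
            cyp_fit.model.interval_spec, cyp_fit.model.decode_table, cfg,
        )
        return {c.sample_id: (c.label, tuple(sorted(c.pattern.rfu.items())))
                for c in calls}

    assert run(samples) == run(list(reversed(samples)))


def test_stage_errors_carry_stage_provenance(cyp_fit):
    with pytest.raises(Exception, match=r"\[stage:encode\]"):
        run_pipeline(
            [("bad", "*1/*99")],
            cyp_fit.model.panel,
            cyp_fit.weights,
            cyp_fit.model.interval_spec,
            cyp_fit.model.decode_table,
        )
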