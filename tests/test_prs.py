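"""Polygenic scoring: parsing, dosage arithmetic, encodings, cohorts."""

import numpy as np
import pytest
from scipy import stats

from stranddecoder import fixtures
from stranddecoder.errors import (
    CohortSizeError,
    ConfigError,
    ConsistencyError,
    InputError,
    ParseError,
    UnsupportedEncodingError,
)
from stranddecoder.prs import (
    GenotypeMatrix,
    ScoringModel,
    ScoringVariant,
    circuit_net_score,
    compute_prs,
    genotype_matrix_from_vcf,
    parse_scoring_text,
    sample_population,
    stratify,
    ternary_encode,
)


def test_toy_scoring_file_round_trips_weights_exactly():
    model = parse_scoring_text(fixtures.TOY_SCORING_TEXT)
    assert model.pgs_id == "TOY003"
    assert model.n_variants == 3
    assert list(model.weights()) == [0.3, 0.2, 0.5]
    assert model.variants[0].effect_allele == "A"


def test_odds_ratio_column_is_converted_to_lnor():
    text = "rsID\teffect_allele\tother_allele\tOR\nrs1\tA\tG\t2.0\n"
    model = parse_scoring_text(text)
    assert model.variants[0].effect_weight == pytest.approx(np.log(2.0))


def test_malformed_scoring_files_raise_parse_errors():
    with pytest.raises(ParseError):
        parse_scoring_text("# only metadata\n")
    with pytest.raises(ParseError):
        parse_scoring_text("rsID\teffect_allele\teffect_weight\n")
    with pytest.raises(ParseError):
        parse_scoring_text("rsID\teffect_allele\nrs1\tA\n")  # no weights
    dup = ("rsID\teffect_allele\tother_allele\teffect_weight\n"
           "rs1\tA\tG\t0.1\nrs1\tA\tG\t0.2\n")
    with pytest.raises(ConsistencyError):
        parse_scoring_text(dup)


def _toy_model():
    return ScoringModel(
        "TOY",
        (
            ScoringVariant("rs1", "A", "G", 0.3, 0.5),
            ScoringVariant("rs2", "C", "T", 0.2, 0.2),
            ScoringVariant("rs3", "G", "A", 0.5, 0.8),
        ),
    )


def test_prs_is_the_dosage_weighted_sum():
    model = _toy_model()
    g = GenotypeMatrix(["s0", "s1", "s2"], ["rs1", "rs2", "rs3"],
                       np.array([[0, 0, 0], [2, 1, 0], [1, 1, 1]]))
    res = compute_prs(g, model)
    assert res.scores[0] == 0.0
    assert res.scores[1] == pytest.approx(0.8)
    assert res.scores[2] == pytest.approx(2 * res.scores[2] / 2)  # linearity
    doubled = GenotypeMatrix(["s"], ["rs1", "rs2", "rs3"],
                             np.array([[2, 2, 2]]))
    single = GenotypeMatrix(["s"], ["rs1", "rs2", "rs3"],
                            np.array([[1, 1, 1]]))
    assert compute_prs(doubled, model).scores[0] == pytest.approx(
        2 * compute_prs(single, model).scores[0]
    )


def test_dosages_outside_ternary_range_are_rejected():
    with pytest.raises(InputError):
        GenotypeMatrix(["s"], ["rs1"], np.array([[3]]))


@pytest.mark.parametrize(
    "dosage,mode,expected_net",
    [
        (2, "paper_literal", 0.6),
        (1, "paper_literal", 0.3),
        (0, "paper_literal", -0.3),
        (2, "exact_dosage", 0.6),
        (1, "exact_dosage", 0.3),
        (0, "exact_dosage", 0.0),
    ],
)
def test_ternary_encoding_nets(dosage, mode, expected_net):
    x, y = ternary_encode(dosage, 0.3, mode)
    assert x - y == pytest.approx(expected_net)


def test_literal_encoding_rejects_negative_lnor():
    with pytest.raises(UnsupportedEncodingError):
        ternary_encode(1, -0.1, "paper_literal")


def test_literal_circuit_score_equals_prs_minus_absent_allele_offset(
    synthetic_scoring,
):
    """Exact identity: literal net = PRS - sum of lnOR over dosage-0
    variants, for every sample."""
    cohort = sample_population(synthetic_scoring, 500, seed=11)
    w = synthetic_scoring.weights()
    for row in cohort.dosages:
        prs = float(row @ w)
        offset = float(w[np.asarray(row) == 0].sum())
        lit = circuit_net_score(row, synthetic_scoring, "paper_literal")
        exact = circuit_net_score(row, synthetic_scoring, "exact_dosage")
        assert lit == pytest.approx(prs - offset, abs=1e-12)
        assert exact == pytest.approx(prs, abs=1e-12)


def test_hardy_weinberg_sampler_matches_binomial_expectations():
    model = ScoringModel(
        "HW", (ScoringVariant("rs1", "A", "G", 0.1, 0.5),)
    )
    g = sample_population(model, 10_000, seed=5)
    assert g.dosages.mean() == pytest.approx(1.0, abs=0.03)
    zero = ScoringModel("Z", (ScoringVariant("rs1", "A", "G", 0.1, 0.0),))
    assert sample_population(zero, 100, seed=1).dosages.sum() == 0


def test_genotype_class_counts_pass_a_chi_square_hwe_check(synthetic_scoring):
    g = sample_population(synthetic_scoring, 10_000, seed=3)
    p = synthetic_scoring.frequencies()
    pvals = []
    for j, pj in enumerate(p):
        counts = np.bincount(g.dosages[:, j], minlength=3)
        expected = 10_000 * np.array(
            [(1 - pj) ** 2, 2 * pj * (1 - pj), pj**2]
        )
        keep = expected > 0
        pvals.append(
            stats.chisquare(counts[keep], expected[keep]).pvalue
        )
    # seeded draw: every variant consistent with Hardy-Weinberg at alpha=0.01
    assert min(pvals) > 0.01


def test_missing_frequency_blocks_population_sampling():
    model = ScoringModel("X", (ScoringVariant("rs1", "A", "G", 0.1, None),))
    with pytest.raises(ConfigError):
        sample_population(model, 10, seed=0)


def test_decile_stratification_partitions_the_cohort():
    from stranddecoder.prs import PrsResult

    scores = np.arange(100, dtype=float)
    res = stratify(
        PrsResult([f"s{i}" for i in range(100)], scores,
                  float(scores.mean()), float(scores.std(ddof=1)))
    )
    counts = {c: res.categories.count(c) for c in set(res.categories)}
    assert counts == {"low": 10, "high": 10, "intermediate": 80}
    assert sum(counts.values()) == 100
    assert res.categories[0] == "low" and res.categories[99] == "high"


def test_degenerate_all_equal_scores_are_all_intermediate():
    from stranddecoder.prs import PrsResult

    res = PrsResult([f"s{i}" for i in range(20)],
                    np.full(20, 1.5), 1.5, 0.0)
    out = stratify(res)
    assert set(out.categories) == {"intermediate"}
    assert out.notes


def test_small_cohorts_cannot_be_stratified():
    from stranddecoder.prs import PrsResult

    res = PrsResult(["a", "b", "c", "d", "e"], np.arange(5.0), 2.0, 1.6)
    with pytest.raises(CohortSizeError):
        stratify(res)


def test_vcf_dosages_count_effect_alleles(tmp_path):
    model = ScoringModel(
        "V",
        (
            ScoringVariant("rs1", "A", "G", 0.1, 0.5),
            ScoringVariant("rs2", "T", "C", 0.2, 0.5),
        ),
    )
    vcf = tmp_path / "c.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "1\t100\trs1\tG\tA\t.\t.\t.\tGT\t0/1\t1/1\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/0\t0/1\n"
    )
    g = genotype_matrix_from_vcf(vcf, model)
    assert g.dosages.tolist() == [[1, 0], [2, 1]]
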