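"""Embedded pharmacogene panels, genotype–phenotype tables and scenarios.

The tables are programmatic reconstructions of standard clinical
genotype–phenotype correlations (CPIC-style activity scoring), built from
star-allele definitions over small biallelic SNP panels:

* CYP2C19 — 3 loci / 6 alleles (c.681G>A defines *2, c.636G>A defines *3,
  c.-806C>T defines *17), 10 diplotypes over {*1, *2, *3, *17} spanning the
  four metabolizer classes PM/IM/EM/UM;
* DPYD — 7 SNPs / 14 alleles, 30 genotypes in three activity classes
  (normal / intermediate / poor);
* TPMT (4 SNPs / 8 alleles) and NUDT15 (2 SNPs / 4 alleles) — the
  dual-gene thiopurine dosing panels;
* a 3-variant toy polygenic scoring file and a seeded synthetic 22-variant
  scoring model (explicitly *not* a real catalog entry) with effect-allele
  frequencies for Hardy–Weinberg cohort simulation.

Everything is generated in memory; ``emit_fixtures`` writes byte-stable
files for external tooling.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, StrandDecoderError
from .genotype import GenotypePhenotypeTable, Locus, Panel, table_from_diplotypes
from .learn import ClassIntervalSpec

# ---------------------------------------------------------------------------
# CYP2C19
# ---------------------------------------------------------------------------


def cyp2c19_panel() -> Panel:
    loci = [
        Locus("c.681G>A", "CYP2C19", 94781859, "G", "A"),   # rs4244285, *2
        Locus("c.636G>A", "CYP2C19", 94780653, "G", "A"),   # rs4986893, *3
        Locus("c.-806C>T", "CYP2C19", 94761900, "C", "T"),  # rs12248560, *17
    ]
    labels = {
        ("c.681G>A", "ref"): "681G",
        ("c.681G>A", "alt"): "681A",
        ("c.636G>A", "ref"): "636G",
        ("c.636G>A", "alt"): "636A",
        ("c.-806C>T", "ref"): "-806C",
        ("c.-806C>T", "alt"): "-806T",
    }
    stars = {
        "*1": {},
        "*2": {"c.681G>A": "alt"},
        "*3": {"c.636G>A": "alt"},
        "*17": {"c.-806C>T": "alt"},
    }
    return Panel("CYP2C19", "CYP2C19", loci, stars, labels)


#: Loss-of-function star alleles of CYP2C19.
_CYP2C19_LOF = {"*2", "*3"}


def _cyp2c19_class(a: str, b: str, star_2_17_label: str = "IM") -> str:
    lof = sum(1 for s in (a, b) if s in _CYP2C19_LOF)
    has_17 = "*17" in (a, b)
    if lof == 2:
        return "PM"
    if lof == 1:
        # one loss-of-function allele; *2/*17 and *3/*17 stay intermediate
        # by default (configurable, as the increased-function promoter does
        # not compensate a null allele)
        return star_2_17_label if has_17 else "IM"
    if has_17:
        return "UM"
    return "EM"


def cyp2c19_table(star_2_17_label: str = "IM") -> GenotypePhenotypeTable:
    """All 10 unordered diplotypes over {*1, *2, *3, *17}."""
    panel = cyp2c19_panel()
    stars = ["*1", "*2", "*3", "*17"]
    rows = []
    for i, a in enumerate(stars):
        for b in stars[i:]:
            rows.append((f"{a}/{b}", _cyp2c19_class(a, b, star_2_17_label)))
    classes = ["PM", "IM", "EM", "UM"]
    if star_2_17_label not in classes:
        classes.insert(1, star_2_17_label)
    return table_from_diplotypes(panel, rows, tuple(classes))


def cyp2c19_interval_spec() -> ClassIntervalSpec:
    return ClassIntervalSpec(("PM", "IM", "EM", "UM"), (-2.0, 0.0, 4.0), 0.5)


def cyp2c19_decode_rules() -> list[tuple[frozenset, str]]:
    """Fluorescence pattern -> metabolizer class (4-channel comparator)."""
    return [
        (frozenset({"VIC", "FAM"}), "PM"),
        (frozenset({"VIC"}), "IM"),
        (frozenset({"Cy5"}), "EM"),
        (frozenset({"Cy5", "ROX"}), "UM"),
    ]


# ---------------------------------------------------------------------------
# DPYD
# ---------------------------------------------------------------------------

# haplotype name -> (locus id, activity value of the haplotype)
_DPYD_VARIANTS = [
    ("*2A", "c.1905+1G>A", 0.0),     # rs3918290, splice donor loss
    ("*13", "c.1679T>G", 0.0),       # rs55886062
    ("c.2846T", "c.2846A>T", 0.5),   # rs67376798, decreased function
    ("HapB3", "c.1129-5923C>G", 0.5),  # rs75017182, decreased function
    ("*5", "c.1627A>G", 1.0),        # rs1801159, normal function
    ("*6", "c.2194G>A", 1.0),        # rs1801160, normal function
    ("*9A", "c.85T>C", 1.0),         # rs1801265, normal function
]

_DPYD_LOCI = [
    Locus("c.1905+1G>A", "DPYD", 97450058, "C", "T"),
    Locus("c.1679T>G", "DPYD", 97515865, "A", "C"),
    Locus("c.2846A>T", "DPYD", 97305364, "T", "A"),
    Locus("c.1129-5923C>G", "DPYD", 97579893, "G", "C"),
    Locus("c.1627A>G", "DPYD", 97515839, "T", "C"),
    Locus("c.2194G>A", "DPYD", 97450065, "C", "T"),
    Locus("c.85T>C", "DPYD", 97883329, "A", "G"),
]


def dpyd_panel() -> Panel:
    stars = {"*1": {}}
    for name, locus_id, _ in _DPYD_VARIANTS:
        stars[name] = {locus_id: "alt"}
    labels = {}
    for loc in _DPYD_LOCI:
        short = loc.id.replace("c.", "").split(">")[0]
        base = short[:-1]
        labels[(loc.id, "ref")] = f"{base}{short[-1]}"
        labels[(loc.id, "alt")] = f"{base}{loc.id.split('>')[1]}"
    return Panel("DPYD", "DPYD", _DPYD_LOCI, stars, labels)


def _dpyd_activity(star: str) -> float:
    if star == "*1":
        return 1.0
    for name, _, value in _DPYD_VARIANTS:
        if name == star:
            return value
    raise InputError(f"unknown DPYD haplotype {star}")


def dpyd_table() -> GenotypePhenotypeTable:
    """30 genotypes over the 8 DPYD haplotypes, classed by activity score.

    All unordered haplotype pairs except those combining two distinct or
    identical *normal-function* variant haplotypes (which are clinically
    indistinguishable from *1-carrying genotypes) — leaving 30 genotypes.
    Activity score >= 2 is a normal metabolizer, 1–1.5 intermediate,
    <= 0.5 poor.
    """
    panel = dpyd_panel()
    haps = ["*1"] + [name for name, _, _ in _DPYD_VARIANTS]
    normal_variants = {name for name, _, v in _DPYD_VARIANTS if v == 1.0}
    rows = []
    for i, a in enumerate(haps):
        for b in haps[i:]:
            if a in normal_variants and b in normal_variants:
                continue
            score = _dpyd_activity(a) + _dpyd_activity(b)
            if score >= 2.0:
                label = "normal"
            elif score >= 1.0:
                label = "intermediate"
            else:
                label = "poor"
            rows.append((f"{a}/{b}", label))
    table = table_from_diplotypes(
        panel, rows, ("poor", "intermediate", "normal")
    )
    if table.n_genotypes != 30:
        raise StrandDecoderError(
            f"DPYD fixture drift: {table.n_genotypes} genotypes"
        )
    return table


def dpyd_interval_spec() -> ClassIntervalSpec:
    return ClassIntervalSpec(("poor", "intermediate", "normal"), (0.0, 4.0), 0.5)


def dpyd_decode_rules() -> list[tuple[frozenset, str]]:
    return [
        (frozenset({"VIC"}), "poor"),
        (frozenset({"Cy5"}), "intermediate"),
        (frozenset({"Cy5", "ROX"}), "normal"),
    ]


# ---------------------------------------------------------------------------
# TPMT / NUDT15 (thiopurine dosing)
# ---------------------------------------------------------------------------


def tpmt_panel() -> Panel:
    loci = [
        Locus("c.238G>C", "TPMT", 18143724, "C", "G"),    # rs1800462, *2
        Locus("c.460G>A", "TPMT", 18139228, "C", "T"),    # rs1800460, *3B
        Locus("c.719A>G", "TPMT", 18130918, "T", "C"),    # rs1142345, *3C
        Locus("c.626-1G>A", "TPMT", 18131012, "C", "T"),  # rs1800584, *4
    ]
    stars = {
        "*1": {},
        "*2": {"c.238G>C": "alt"},
        "*3B": {"c.460G>A": "alt"},
        "*3C": {"c.719A>G": "alt"},
        "*4": {"c.626-1G>A": "alt"},
    }
    return Panel("TPMT", "TPMT", loci, stars)


def nudt15_panel() -> Panel:
    loci = [
        Locus("c.415C>T", "NUDT15", 48045719, "C", "T"),  # rs116855232, *3
        Locus("c.416G>A", "NUDT15", 48045720, "G", "A"),  # rs147390019, *4
    ]
    stars = {
        "*1": {},
        "*3": {"c.415C>T": "alt"},
        "*4": {"c.416G>A": "alt"},
    }
    return Panel("NUDT15", "NUDT15", loci, stars)


def _lof_pair_table(panel: Panel) -> GenotypePhenotypeTable:
    """All unordered diplotypes, classed NM / IM / PM by count of
    loss-of-function haplotypes (every variant haplotype in these panels
    is loss-of-function)."""
    stars = list(panel.star_definitions)
    rows = []
    for i, a in enumerate(stars):
        for b in stars[i:]:
            lof = sum(1 for s in (a, b) if s != "*1")
            label = ("NM", "IM", "PM")[lof]
            rows.append((f"{a}/{b}", label))
    return table_from_diplotypes(panel, rows, ("PM", "IM", "NM"))


def tpmt_table() -> GenotypePhenotypeTable:
    return _lof_pair_table(tpmt_panel())


def nudt15_table() -> GenotypePhenotypeTable:
    return _lof_pair_table(nudt15_panel())


def thiopurine_interval_spec() -> ClassIntervalSpec:
    """Per-gene spec: net > 0 normal, (-4, 0) intermediate, < -4 poor."""
    return ClassIntervalSpec(("PM", "IM", "NM"), (-4.0, 0.0), 0.5)


# ---------------------------------------------------------------------------
# polygenic scoring fixtures
# ---------------------------------------------------------------------------

TOY_SCORING_TEXT = """\
### synthetic toy scoring file in catalog layout (not a real accession)
#pgs_id=TOY003
#trait_reported=toy trait
rsID\teffect_allele\tother_allele\teffect_weight\tallelefrequency_effect
rs1000001\tA\tG\t0.3\t0.5
rs1000002\tC\tT\t0.2\t0.2
rs1000003\tG\tA\t0.5\t0.8
"""


def toy_scoring_model():
    from .prs import parse_scoring_text

    return parse_scoring_text(TOY_SCORING_TEXT)


def synthetic_scoring_text(
    n_variants: int = 22, seed: int = 20230101
) -> str:
    """Seeded synthetic scoring file with plausible GWAS effect sizes.

    lnOR weights are drawn uniformly from [0.05, 0.6] and effect-allele
    frequencies from [0.05, 0.95].  This file is a synthetic stand-in for a
    real catalog scoring file and is labelled as such in its header.
    """
    rng = np.random.default_rng(seed)
    lnor = rng.uniform(0.05, 0.6, size=n_variants)
    freq = rng.uniform(0.05, 0.95, size=n_variants)
    bases = ["A", "C", "G", "T"]
    lines = [
        "### synthetic scoring file (seeded stand-in, not a real accession)",
        f"#pgs_id=SYNTH{n_variants:03d}",
        "#trait_reported=synthetic pancreatic-cancer-like trait",
        "rsID\teffect_allele\tother_allele\teffect_weight\tallelefrequency_effect",
    ]
    for i in range(n_variants):
        eff = bases[int(rng.integers(0, 4))]
        oth = bases[(bases.index(eff) + 1 + int(rng.integers(0, 3))) % 4]
        lines.append(
            f"rs9{i:06d}\t{eff}\t{oth}\t{lnor[i]:.4f}\t{freq[i]:.4f}"
        )
    return "\n".join(lines) + "\n"


def synthetic_scoring_model(n_variants: int = 22, seed: int = 20230101):
    from .prs import parse_scoring_text

    return parse_scoring_text(synthetic_scoring_text(n_variants, seed))


# ---------------------------------------------------------------------------
# bundle emission and experiment scenarios
# ---------------------------------------------------------------------------

_FIXTURE_VERSION = "1"


def _table_to_frame(table: GenotypePhenotypeTable) -> pd.DataFrame:
    rows = []
    for dip, code, label in table.entries:
        rows.append(
            {
                "diplotype": str(dip) if dip else "",
                **{
                    lab: bit
                    for lab, bit in zip(table.panel.allele_labels(), code.bits)
                },
                "phenotype": label,
            }
        )
    return pd.DataFrame(rows)


def emit_fixtures(out_dir: str | Path, seed: int = 20230101) -> dict:
    """Write every fixture to ``out_dir``; byte-identical for a given seed.

    Returns a manifest with per-file SHA-256 checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def write(name: str, text: str):
        p = out / name
        p.write_text(text)
        files[name] = hashlib.sha256(text.encode()).hexdigest()

    for name, table in (
        ("cyp2c19_genotype_phenotype.csv", cyp2c19_table()),
        ("dpyd_genotype_phenotype.csv", dpyd_table()),
        ("tpmt_genotype_phenotype.csv", tpmt_table()),
        ("nudt15_genotype_phenotype.csv", nudt15_table()),
    ):
        write(name, _table_to_frame(table).to_csv(index=False))

    decode_rows = []
    for panel_id, rules in (
        ("CYP2C19", cyp2c19_decode_rules()),
        ("DPYD", dpyd_decode_rules()),
    ):
        for on_set, label in rules:
            decode_rows.append(
                {
                    "panel_id": panel_id,
                    "on_channels": "+".join(sorted(on_set)),
                    "class": label,
                }
            )
    write(
        "decode_tables.csv", pd.DataFrame(decode_rows).to_csv(index=False)
    )
    write("toy_scores.txt", TOY_SCORING_TEXT)
    write("synthetic22_scores.txt", synthetic_scoring_text(22, seed))
    manifest = {
        "version": _FIXTURE_VERSION,
        "seed": seed,
        "files": dict(sorted(files.items())),
    }
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return manifest


#: The five prevalent CYP2C19 diplotypes used for the synthetic cohort.
PREVALENT_CYP2C19 = ("*1/*1", "*1/*2", "*1/*17", "*2/*2", "*2/*17")
COHORT_BATCH_SIZES = (2, 6, 15, 7)


def synthesize_experiment(name: str, seed: int = 0) -> dict:
    """Build a runnable in-silico scenario (inputs + expected properties)."""
    rng = np.random.default_rng(seed)
    if name == "fig3_weighted_sums":
        grid = [0.0, 30.0, 60.0, 90.0, 120.0]
        return {
            "name": name,
            "pairs": [(x, y) for x in grid for y in grid],
            "capacity": 120.0,
            "expected": "H1 ~ max(0, Y0-X0); H2 ~ max(0, X0-Y0)",
        }
    if name == "fig4_cohort":
        table = cyp2c19_table()
        label_of = {str(d): lab for d, _, lab in (
            (dip, code, lab) for dip, code, lab in table.entries
        )}
        samples = []
        i = 0
        for batch, size in enumerate(COHORT_BATCH_SIZES, start=1):
            for _ in range(size):
                dip = PREVALENT_CYP2C19[int(rng.integers(0, len(PREVALENT_CYP2C19)))]
                samples.append(
                    {
                        "sample_id": f"S{i:03d}",
                        "batch": batch,
                        "diplotype": dip,
                        "expected_class": label_of[dip],
                    }
                )
                i += 1
        return {"name": name, "samples": samples,
                "batch_sizes": COHORT_BATCH_SIZES}
    if name == "fig5_dpyd":
        table = dpyd_table()
        return {
            "name": name,
            "samples": [
                {"sample_id": f"D{i:03d}", "diplotype": str(dip),
                 "expected_class": lab}
                for i, (dip, _, lab) in enumerate(table.entries)
            ],
        }
    if name == "fig6_prs":
        from .prs import compute_prs, sample_population, stratify

        model = synthetic_scoring_model()
        cohort = sample_population(model, n=2504, seed=seed)
        result = compute_prs(cohort, model)
        result = stratify(result)
        return {
            "name": name,
            "model": model,
            "cohort": cohort,
            "result": result,
        }
    raise InputError(f"unknown scenario {name!r}")
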