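"""Polygenic score parsing, computation, molecular encoding and stratification.

The polygenic risk score of sample s is the dosage-weighted sum

    PRS_s = sum_v d_{s,v} * lnOR_v,    d in {0, 1, 2}

over the scoring model's risk variants.  The molecular circuit encodes the
ternary dosage with binary allele-presence inputs (the *literal* encoding):
the effect-allele gate carries weight 2*lnOR and the other-allele gate
-lnOR, so a homozygote contributes 2*lnOR, a heterozygote lnOR (2*lnOR
from the effect allele minus lnOR from the other allele), and a
non-carrier -lnOR.  The literal circuit score therefore equals

    PRS_s - sum_{v: d=0} lnOR_v,

a documented, exactly testable offset from the true PRS.  The alternative
``exact_dosage`` encoding uses stoichiometric gates with dosage-scaled
inputs and reproduces the PRS without offset.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CohortSizeError,
    ConfigError,
    ConsistencyError,
    InputError,
    ParseError,
    UnsupportedEncodingError,
)

_NUCLEOTIDES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class ScoringVariant:
    variant_id: str
    effect_allele: str
    other_allele: str
    effect_weight: float  # lnOR
    effect_allele_frequency: float | None = None

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ParseError(
                f"{self.variant_id}: effect and other allele identical"
            )
        if not np.isfinite(self.effect_weight):
            raise ParseError(f"{self.variant_id}: non-finite effect weight")


@dataclass(frozen=True)
class ScoringModel:
    pgs_id: str
    variants: tuple[ScoringVariant, ...]

    def __post_init__(self):
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConsistencyError(f"duplicate variant ids {dup}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def weights(self) -> np.ndarray:
        return np.array([v.effect_weight for v in self.variants])

    def frequencies(self) -> np.ndarray:
        freqs = [v.effect_allele_frequency for v in self.variants]
        if any(f is None for f in freqs):
            missing = [
                v.variant_id
                for v in self.variants
                if v.effect_allele_frequency is None
            ]
            raise ConfigError(f"missing effect-allele frequency for {missing}")
        return np.array(freqs, dtype=float)


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix, entries in {0,1,2}."""

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dosages)
        if d.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise InputError("dosage matrix shape mismatch")
        if not np.isin(d, (0, 1, 2)).all():
            raise InputError("dosages must be 0, 1 or 2")
        self.dosages = d.astype(np.int8)


@dataclass
class PrsResult:
    sample_ids: list[str]
    scores: np.ndarray
    mean: float
    sd: float
    decile_boundaries: np.ndarray | None = None
    categories: list[str] | None = None
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "prs": self.scores})
        if self.categories is not None:
            df["category"] = self.categories
        return df


_COLUMN_ALIASES = {
    "rsID": "variant_id",
    "rsid": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "reference_allele": "other_allele",
    "effect_weight": "effect_weight",
    "OR": "odds_ratio",
    "allelefrequency_effect": "effect_allele_frequency",
}


def parse_scoring_text(text: str, pgs_id: str | None = None) -> ScoringModel:
    """Parse catalog-layout scoring text: '#' metadata, tab-separated body."""
    meta = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if line.strip():
            body_lines.append(line)
    if not body_lines:
        raise ParseError("scoring file has no data section")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    if df.empty:
        raise ParseError("scoring file has a header but no data rows")
    df = df.rename(columns={c: _COLUMN_ALIASES.get(c, c) for c in df.columns})
    needed = {"variant_id", "effect_allele"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"scoring file missing mandatory columns {missing}")
    if "effect_weight" not in df.columns:
        if "odds_ratio" in df.columns:
            df["effect_weight"] = np.log(df["odds_ratio"].astype(float))
        else:
            raise ParseError(
                "scoring file needs an effect_weight (or OR) column"
            )
    variants = []
    for _, row in df.iterrows():
        freq = row.get("effect_allele_frequency")
        freq = None if freq is None or pd.isna(freq) else float(freq)
        other = row.get("other_allele")
        if other is None or pd.isna(other):
            eff = str(row["effect_allele"])
            other = next(b for b in "ACGT" if b != eff)
        variants.append(
            ScoringVariant(
                variant_id=str(row["variant_id"]),
                effect_allele=str(row["effect_allele"]),
                other_allele=str(other),
                effect_weight=float(row["effect_weight"]),
                effect_allele_frequency=freq,
            )
        )
    return ScoringModel(
        pgs_id=pgs_id or meta.get("pgs_id", "unknown"),
        variants=tuple(variants),
    )


def parse_scoring_file(path: str | Path, pgs_id: str | None = None) -> ScoringModel:
    return parse_scoring_text(Path(path).read_text(), pgs_id=pgs_id)


def compute_prs(g: GenotypeMatrix, model: ScoringModel) -> PrsResult:
    """Theoretical PRS: dosage-weighted sum of lnOR effect weights."""
    if g.variant_ids != [v.variant_id for v in model.variants]:
        raise InputError("genotype matrix columns do not match scoring model")
    scores = g.dosages @ model.weights()
    return PrsResult(
        sample_ids=list(g.sample_ids),
        scores=scores.astype(float),
        mean=float(np.mean(scores)),
        sd=float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
    )


def ternary_encode(
    dosage: int, ln_or: float, mode: str = "paper_literal"
) -> tuple[float, float]:
    """Per-variant (X, Y) contributions of one dosage under an encoding."""
    if dosage not in (0, 1, 2):
        raise InputError(f"dosage {dosage} outside {{0,1,2}}")
    if mode == "paper_literal":
        if ln_or < 0:
            raise UnsupportedEncodingError(
                "literal ternary encoding cannot represent negative lnOR; "
                "remap the variant to the opposite allele"
            )
        if dosage == 2:
            return (2.0 * ln_or, 0.0)
        if dosage == 1:
            return (2.0 * ln_or, ln_or)
        return (0.0, ln_or)
    if mode == "exact_dosage":
        return (dosage * ln_or, 0.0)
    raise ConfigError(f"unknown encoding {mode!r}")


def circuit_net_score(
    dosages: Sequence[int], model: ScoringModel, mode: str = "paper_literal"
) -> float:
    """Closed-form net (X - Y) score the compiled circuit computes."""
    net = 0.0
    for d, v in zip(dosages, model.variants):
        x, y = ternary_encode(int(d), v.effect_weight, mode)
        net += x - y
    return net


def prs_input_vector(
    model: ScoringModel,
    dosages: Sequence[int],
    encoding: str = "paper_literal",
    base_unit: float = 50.0,
    multiplier: float = 100.0,
) -> dict[str, float]:
    """Input strand concentrations (nM) for a compiled scoring circuit.

    Literal encoding: binary inputs at 1x — the effect-allele strand is
    present when dosage >= 1 and the other-allele strand when dosage <= 1.
    Exact encoding: one input per variant at ``dosage * lnOR * multiplier``
    (stoichiometric gates).
    """
    out: dict[str, float] = {}
    for d, v in zip(dosages, model.variants):
        if d not in (0, 1, 2):
            raise InputError(f"dosage {d} outside {{0,1,2}}")
        if encoding == "paper_literal":
            out[f"{v.variant_id}:eff"] = base_unit if d >= 1 else 0.0
            out[f"{v.variant_id}:oth"] = base_unit if d <= 1 else 0.0
        elif encoding == "exact_dosage":
            out[f"{v.variant_id}:eff"] = d * v.effect_weight * multiplier
        else:
            raise ConfigError(f"unknown encoding {encoding!r}")
    return out


def sample_population(
    model: ScoringModel, n: int, seed: int = 0
) -> GenotypeMatrix:
    """Hardy–Weinberg cohort: per-variant dosages ~ Binomial(2, p_v)."""
    if n < 1:
        raise InputError("population size must be >= 1")
    p = model.frequencies()
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, p, size=(n, model.n_variants))
    return GenotypeMatrix(
        sample_ids=[f"sim{i:05d}" for i in range(n)],
        variant_ids=[v.variant_id for v in model.variants],
        dosages=dosages,
    )


def genotype_matrix_from_vcf(
    path: str | Path, model: ScoringModel
) -> GenotypeMatrix:
    """Effect-allele dosages from diploid GT fields of a VCF."""
    import pysam

    by_id = {v.variant_id: i for i, v in enumerate(model.variants)}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        dosages = np.zeros((len(samples), model.n_variants), dtype=np.int8)
        seen = set()
        for rec in vcf:
            vid = rec.id
            if vid not in by_id:
                continue
            j = by_id[vid]
            v = model.variants[j]
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(f"skipping non-biallelic record {vid}")
                continue
            alleles = {0: rec.ref, 1: rec.alts[0]}
            seen.add(vid)
            for i, sid in enumerate(samples):
                gt = rec.samples[sid].get("GT")
                if gt is None or any(g is None for g in gt):
                    raise ParseError(f"missing GT for {sid} at {vid}")
                dosages[i, j] = sum(
                    1 for g in gt if alleles.get(g) == v.effect_allele
                )
        missing = set(by_id) - seen
        if missing:
            warnings.warn(
                f"variants absent from VCF treated as dosage 0: {sorted(missing)}"
            )
    return GenotypeMatrix(
        sample_ids=samples,
        variant_ids=[v.variant_id for v in model.variants],
        dosages=dosages,
    )


def stratify(result: PrsResult) -> PrsResult:
    """Decile risk categories: bottom decile low, top decile high.

    Every sample strictly between the bottom and top decile is
    ``intermediate``, so the categories partition the cohort.  Ties are
    resolved by rank with stable sample order.  A degenerate all-equal
    cohort is entirely intermediate (with a note), since no score exceeds
    any decile boundary strictly.
    """
    n = len(result.scores)
    if n < 10:
        raise CohortSizeError(f"need >= 10 samples to stratify, got {n}")
    scores = np.asarray(result.scores, dtype=float)
    notes = list(result.notes)
    k = n // 10
    if np.ptp(scores) == 0:
        categories = ["intermediate"] * n
        notes.append("all scores identical; every sample intermediate")
        boundaries = np.quantile(scores, np.arange(0.1, 1.0, 0.1))
    else:
        order = np.argsort(scores, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        categories = [
            "low" if r < k else ("high" if r >= n - k else "intermediate")
            for r in ranks
        ]
        boundaries = np.quantile(scores, np.arange(0.1, 1.0, 0.1))
    return PrsResult(
        sample_ids=result.sample_ids,
        scores=scores,
        mean=result.mean,
        sd=result.sd,
        decile_boundaries=boundaries,
        categories=categories,
        notes=notes,
    )
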