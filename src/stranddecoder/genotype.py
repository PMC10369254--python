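"""Loci, alleles, star-allele diplotypes and binary "genetic codes".

A *panel* is an ordered set of biallelic loci for one gene (or a pair of
genes), together with a star-allele definition table mapping each named
haplotype to its variant status at every locus.  A diploid sample is encoded
as a binary vector with two bits per locus — one for the reference allele,
one for the alternate — where a bit is 1 iff at least one chromosome carries
that allele.  These vectors are the inputs over which the decoder circuit
computes its weighted sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConsistencyError,
    DefinitionError,
    DimensionError,
    ParseError,
    UnsupportedPanelError,
)

_NUCLEOTIDES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class Locus:
    """One biallelic genomic position.

    Coordinates are 1-based (dbSNP convention); alleles are reported on the
    forward strand of the reference.
    """

    id: str
    gene: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.position < 1:
            raise UnsupportedPanelError(f"locus {self.id}: position must be >= 1")
        for a in (self.ref_allele, self.alt_allele):
            if not a or set(a) - _NUCLEOTIDES:
                raise UnsupportedPanelError(
                    f"locus {self.id}: allele {a!r} is not a nucleotide string"
                )
        if self.ref_allele == self.alt_allele:
            raise UnsupportedPanelError(
                f"locus {self.id}: ref and alt alleles must differ"
            )


@dataclass(frozen=True)
class Allele:
    """One of the two alleles of a biallelic locus."""

    locus_id: str
    which: str  # "ref" or "alt"
    label: str

    def __post_init__(self):
        if self.which not in ("ref", "alt"):
            raise DefinitionError(f"allele {self.label}: which must be ref|alt")


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of star-allele names for one gene."""

    gene: str
    star_pair: tuple[str, str]

    @classmethod
    def parse(cls, gene: str, text: str) -> "Diplotype":
        parts = text.split("/")
        if len(parts) != 2:
            raise ParseError(f"cannot parse diplotype {text!r}")
        return cls(gene=gene, star_pair=(parts[0].strip(), parts[1].strip()))

    def __str__(self):
        return "/".join(self.star_pair)


@dataclass(frozen=True)
class GeneticCode:
    """Binary allele-presence vector over a panel, fixed allele order."""

    panel_id: str
    bits: tuple[int, ...]

    def __post_init__(self):
        if any(b not in (0, 1) for b in self.bits):
            raise DimensionError("genetic code bits must be 0/1")


class Panel:
    """An ordered biallelic locus panel plus its star-allele definitions.

    ``star_definitions`` maps star-allele name -> {locus_id: "alt"} for every
    locus at which the haplotype differs from reference; loci not mentioned
    are reference.  Allele order is (ref, alt) per locus, loci in the order
    given — this order defines the bit layout of every
    :class:`GeneticCode` for the panel.
    """

    def __init__(
        self,
        panel_id: str,
        gene: str,
        loci: Sequence[Locus],
        star_definitions: Mapping[str, Mapping[str, str]],
        allele_labels: Mapping[tuple[str, str], str] | None = None,
    ):
        if not loci:
            raise UnsupportedPanelError("panel must contain at least one locus")
        self.panel_id = panel_id
        self.gene = gene
        self.loci = tuple(loci)
        self._locus_index = {loc.id: i for i, loc in enumerate(self.loci)}
        if len(self._locus_index) != len(self.loci):
            raise UnsupportedPanelError("duplicate locus ids in panel")
        self.star_definitions = {
            name: dict(defn) for name, defn in star_definitions.items()
        }
        for name, defn in self.star_definitions.items():
            for locus_id, which in defn.items():
                if locus_id not in self._locus_index:
                    raise DefinitionError(
                        f"star allele {name}: unknown locus {locus_id}"
                    )
                if which != "alt":
                    raise DefinitionError(
                        f"star allele {name}: only 'alt' entries are stored"
                    )
        labels = dict(allele_labels or {})
        self.alleles: tuple[Allele, ...] = tuple(
            Allele(
                locus_id=loc.id,
                which=which,
                label=labels.get(
                    (loc.id, which),
                    f"{loc.id}:{loc.ref_allele if which == 'ref' else loc.alt_allele}",
                ),
            )
            for loc in self.loci
            for which in ("ref", "alt")
        )
        self._allele_index = {
            (a.locus_id, a.which): i for i, a in enumerate(self.alleles)
        }

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def allele_index(self, locus_id: str, which: str) -> int:
        try:
            return self._allele_index[(locus_id, which)]
        except KeyError:
            raise DefinitionError(f"no allele ({locus_id}, {which}) in panel")

    def allele_labels(self) -> list[str]:
        return [a.label for a in self.alleles]

    def haplotype_bits(self, star: str) -> list[int]:
        """Per-locus allele choice of one haplotype: 0=ref, 1=alt."""
        if star not in self.star_definitions:
            raise DefinitionError(
                f"unknown star allele {star!r} for panel {self.panel_id}"
            )
        defn = self.star_definitions[star]
        return [1 if loc.id in defn else 0 for loc in self.loci]


def encode_genetic_code(diplotype: Diplotype, panel: Panel) -> GeneticCode:
    """Encode a star-allele diplotype as a binary allele-presence vector.

    A bit is set iff at least one of the two haplotypes carries the allele,
    so a heterozygous locus sets both of its bits while a homozygous locus
    sets exactly one.
    """
    bits = [0] * panel.n_alleles
    for star in diplotype.star_pair:
        for loc, is_alt in zip(panel.loci, panel.haplotype_bits(star)):
            which = "alt" if is_alt else "ref"
            bits[panel.allele_index(loc.id, which)] = 1
    return GeneticCode(panel_id=panel.panel_id, bits=tuple(bits))


def encode_dosages(dosages: Mapping[str, int], panel: Panel) -> GeneticCode:
    """Encode per-locus alt-allele dosages (0/1/2) as a genetic code."""
    bits = [0] * panel.n_alleles
    for loc in panel.loci:
        d = dosages.get(loc.id)
        if d is None:
            raise DefinitionError(f"missing dosage for locus {loc.id}")
        if d not in (0, 1, 2):
            raise DimensionError(f"dosage {d} for {loc.id} outside {{0,1,2}}")
        if d < 2:
            bits[panel.allele_index(loc.id, "ref")] = 1
        if d > 0:
            bits[panel.allele_index(loc.id, "alt")] = 1
    return GeneticCode(panel_id=panel.panel_id, bits=tuple(bits))


@dataclass
class GenotypePhenotypeTable:
    """Validated genotype–phenotype correlation table for one panel."""

    panel: Panel
    entries: list[tuple[Diplotype | None, GeneticCode, str]] = field(
        default_factory=list
    )
    class_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.validate()

    def validate(self):
        seen: dict[tuple[int, ...], str] = {}
        declared = set(self.class_labels)
        for dip, code, label in self.entries:
            if len(code.bits) != self.panel.n_alleles:
                raise DimensionError(
                    f"code length {len(code.bits)} != panel allele count"
                )
            if declared and label not in declared:
                raise ConsistencyError(
                    f"class label {label!r} not in declared set {self.class_labels}"
                )
            prev = seen.get(code.bits)
            if prev is not None and prev != label:
                raise ConsistencyError(
                    f"identical genetic codes labelled {prev!r} and {label!r}"
                    + (f" (diplotype {dip})" if dip else "")
                )
            seen[code.bits] = label

    @property
    def n_genotypes(self) -> int:
        return len(self.entries)

    def codes(self) -> list[GeneticCode]:
        return [code for _, code, _ in self.entries]

    def labels(self) -> list[str]:
        return [label for _, _, label in self.entries]

    def distinct_labels(self) -> list[str]:
        if self.class_labels:
            return list(self.class_labels)
        out = []
        for _, _, label in self.entries:
            if label not in out:
                out.append(label)
        return out


def table_from_diplotypes(
    panel: Panel,
    rows: Iterable[tuple[str, str]],
    class_labels: Sequence[str] = (),
) -> GenotypePhenotypeTable:
    """Build a table from (star diplotype text, class label) pairs."""
    entries = []
    for dip_text, label in rows:
        dip = Diplotype.parse(panel.gene, dip_text)
        entries.append((dip, encode_genetic_code(dip, panel), label))
    return GenotypePhenotypeTable(
        panel=panel, entries=entries, class_labels=tuple(class_labels)
    )


def load_genotype_phenotype_table(
    path: str | Path,
    panel: Panel,
    fmt: str = "csv",
    labels_path: str | Path | None = None,
) -> GenotypePhenotypeTable:
    """Read a genotype–phenotype table from disk.

    ``csv`` expects a header with either a ``diplotype`` column (star pair)
    or one column per allele bit (named by allele label), plus a
    ``phenotype`` column.  ``vcf+labels`` reads diploid GT fields from a VCF
    for the panel loci and joins per-sample class labels from a two-column
    CSV (sample_id, phenotype).
    """
    path = Path(path)
    if fmt == "csv":
        return _load_csv_table(path, panel)
    if fmt == "vcf+labels":
        if labels_path is None:
            raise ParseError("vcf+labels format requires labels_path")
        return _load_vcf_table(path, Path(labels_path), panel)
    raise ParseError(f"unknown table format {fmt!r}")


def _load_csv_table(path: Path, panel: Panel) -> GenotypePhenotypeTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    if "phenotype" not in df.columns:
        raise ParseError(f"{path}: missing 'phenotype' column")
    if df["phenotype"].isna().any():
        raise ParseError(f"{path}: missing class label in some rows")
    entries = []
    if "diplotype" in df.columns:
        for _, row in df.iterrows():
            dip = Diplotype.parse(panel.gene, str(row["diplotype"]))
            entries.append(
                (dip, encode_genetic_code(dip, panel), str(row["phenotype"]))
            )
    else:
        labels = panel.allele_labels()
        missing = [c for c in labels if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing allele bit columns {missing}")
        for _, row in df.iterrows():
            bits = tuple(int(row[c]) for c in labels)
            entries.append(
                (
                    None,
                    GeneticCode(panel_id=panel.panel_id, bits=bits),
                    str(row["phenotype"]),
                )
            )
    return GenotypePhenotypeTable(panel=panel, entries=entries)


def _load_vcf_table(
    vcf_path: Path, labels_path: Path, panel: Panel
) -> GenotypePhenotypeTable:
    import warnings

    import pysam

    labels_df = pd.read_csv(labels_path)
    if not {"sample_id", "phenotype"} <= set(labels_df.columns):
        raise ParseError(f"{labels_path}: need sample_id and phenotype columns")
    label_map = dict(zip(labels_df["sample_id"].astype(str), labels_df["phenotype"]))

    wanted = {(loc.gene, loc.position): loc for loc in panel.loci}
    by_pos = {loc.position: loc for loc in panel.loci}
    dosages: dict[str, dict[str, int]] = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for sid in samples:
            dosages[sid] = {loc.id: 0 for loc in panel.loci}
        for rec in vcf:
            loc = by_pos.get(rec.pos)
            if loc is None:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(
                    f"{vcf_path}: skipping non-biallelic record at {rec.pos}"
                )
                continue
            if rec.ref != loc.ref_allele or rec.alts[0] != loc.alt_allele:
                warnings.warn(
                    f"{vcf_path}: allele mismatch at {rec.pos}; record ignored"
                )
                continue
            for sid in samples:
                gt = rec.samples[sid].get("GT")
                if gt is None or any(g is None for g in gt):
                    raise ParseError(f"{vcf_path}: missing GT for {sid} at {rec.pos}")
                dosages[sid][loc.id] = sum(1 for g in gt if g == 1)
    entries = []
    for sid in samples:
        if sid not in label_map:
            raise ParseError(f"{labels_path}: no phenotype label for sample {sid}")
        code = encode_dosages(dosages[sid], panel)
        entries.append((None, code, str(label_map[sid])))
    if not entries:
        raise ParseError(f"{vcf_path}: no usable samples")
    return GenotypePhenotypeTable(panel=panel, entries=entries)
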