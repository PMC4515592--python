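"""Sequence input and haplotype calling against the rCRS coordinate system.

The human mitochondrial genome is conventionally described as a set of
differences from the 16,569-bp revised Cambridge Reference Sequence (rCRS).
This module converts rCRS-aligned sequences into :class:`Haplotype` records:
it calls variants, classifies substitutions as synonymous or not using the
mitochondrial gene map and the vertebrate mitochondrial genetic code, masks
unstable positions, and extracts control-region fragments such as the 276-bp
hypervariable segment I (HVS-I) window 16090-16365 used for population
comparison.

The module does *not* align: input sequences must already be in rCRS
coordinates (equal length to the reference, gap characters allowed), or be
declared as fragments with an explicit start coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

RCRS_LENGTH = 16569
HVS1_START = 16090
HVS1_END = 16365

REGIONS = ("Western", "Central", "Eastern", "Southern", "other")

_NUCLEOTIDES = set("ACGT")
# IUPAC ambiguity codes are treated as no-calls and never yield variants.
_AMBIGUOUS = set("RYSWKMBDHVN")
_GAP = "-"

#: vertebrate mitochondrial genetic code (NCBI translation table 2)
MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SequenceIOError(ValueError):
    """Raised for malformed sequence/metadata input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Variant:
    """A single difference from the rCRS reference.

    ``position`` is the 1-based rCRS coordinate.  Insertions are anchored to
    the preceding reference position with a sub-index (``insertion_index``),
    following PhyloTree-style naming (e.g. ``573.1C``).  ``synonymous`` is a
    tri-state: ``"yes"`` / ``"no"`` for classified coding substitutions and
    ``"not_coding"`` for control-region, rRNA and tRNA positions (the default
    for unclassified variants).
    """

    position: int
    ref_base: str
    derived_base: str
    var_class: str = "substitution"
    synonymous: str = "not_coding"
    insertion_index: int = 0

    def __post_init__(self):
        if not 1 <= self.position <= RCRS_LENGTH:
            raise ValueError(f"position {self.position} outside rCRS [1, {RCRS_LENGTH}]")
        if self.var_class not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"bad var_class {self.var_class!r}")
        if self.var_class == "substitution" and self.derived_base == self.ref_base:
            raise ValueError("substitution with derived base equal to reference")
        if self.synonymous not in ("yes", "no", "not_coding"):
            raise ValueError(f"bad synonymous state {self.synonymous!r}")

    def __str__(self) -> str:
        if self.var_class == "deletion":
            return f"{self.ref_base}{self.position}d"
        if self.var_class == "insertion":
            return f"{self.position}.{self.insertion_index}{self.derived_base}"
        return f"{self.ref_base}{self.position}{self.derived_base}"


@dataclass(frozen=True)
class Haplotype:
    """A sample's variant set plus population/region metadata."""

    sample_id: str
    population: str
    region: str
    variants: frozenset[Variant]
    covered_range: tuple[int, int] = (1, RCRS_LENGTH)

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"region {self.region!r} not in {REGIONS}")
        lo, hi = self.covered_range
        positions = [v.position for v in self.variants]
        if any(not lo <= p <= hi for p in positions):
            raise ValueError("variant positions outside covered_range")
        if len(set(positions)) != len(positions):
            # insertions at the same anchor differ by insertion_index
            keyed = {(v.position, v.insertion_index, v.var_class) for v in self.variants}
            if len(keyed) != len(self.variants):
                raise ValueError("duplicate variant positions within haplotype")

    @property
    def fragment_length(self) -> int:
        lo, hi = self.covered_range
        return hi - lo + 1

    def variant_string(self) -> str:
        return " ".join(str(v) for v in sorted(self.variants))


@dataclass(frozen=True)
class Gene:
    name: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class Annotation:
    """rCRS gene map plus a reference sequence for codon lookup.

    ``genes`` carry the true gene coordinates; overlapping protein-coding
    genes (ATP8/ATP6, ND4L/ND4, ATP6/CO3) are trimmed to non-overlapping
    *classification intervals* — a position inside an overlap is classified
    against the upstream gene only, so synonymy is single-valued.  Reading
    frames stay anchored to the true gene start (or end, on the light
    strand).  Positions in terminal incomplete codons (stop codons completed
    by polyadenylation) are treated as non-coding.
    """

    genes: Sequence[Gene]
    reference: str
    classification_intervals: list[tuple[int, int, Gene]] = field(init=False)

    def __post_init__(self):
        ordered = sorted(self.genes, key=lambda g: g.start)
        intervals: list[tuple[int, int, Gene]] = []
        prev_end = 0
        for g in ordered:
            lo = max(g.start, prev_end + 1)
            if lo <= g.end:
                intervals.append((lo, g.end, g))
            prev_end = max(prev_end, g.end)
        self.classification_intervals = intervals

    def gene_at(self, position: int) -> Gene | None:
        for lo, hi, g in self.classification_intervals:
            if lo <= position <= hi:
                return g
        return None


def load_gene_table() -> list[Gene]:
    """Load the packaged rCRS protein-coding gene coordinate table."""
    with resources.files("mtphylo.data").joinpath("mt_genes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [Gene(r["name"], int(r["start"]), int(r["end"]), r["strand"]) for _, r in df.iterrows()]


def default_annotation(reference: str) -> Annotation:
    return Annotation(genes=load_gene_table(), reference=reference)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_fasta_with_metadata(
    fasta_path,
    metadata_path,
    fragment_start: int | None = None,
    reference_length: int = RCRS_LENGTH,
) -> list[tuple[str, dict]]:
    """Read an rCRS-aligned FASTA plus a per-sample metadata TSV.

    The TSV must contain at least ``sample_id``, ``population`` and
    ``region`` columns; records are joined on ``sample_id``.  Sequences must
    have the reference length unless ``fragment_start`` declares them as
    fragments anchored at that rCRS coordinate.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "population", "region"}
    if not required <= set(meta.columns):
        raise SequenceIOError(f"metadata must contain columns {sorted(required)}")
    meta = meta.set_index("sample_id", verify_integrity=True)

    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id not in meta.index:
            raise SequenceIOError(f"sample {rec.id!r} missing from metadata")
        ungapped_ref_len = len(seq.replace(_GAP, "")) if _GAP not in seq else len(seq)
        if fragment_start is None:
            if len(seq) != reference_length and ungapped_ref_len != reference_length:
                raise SequenceIOError(
                    f"sample {rec.id!r}: length {len(seq)} != reference "
                    f"{reference_length} and no fragment start declared"
                )
            start = 1
        else:
            start = fragment_start
            if start + len(seq) - 1 > RCRS_LENGTH:
                raise SequenceIOError(f"sample {rec.id!r}: fragment exceeds rCRS range")
        row = meta.loc[rec.id]
        md = {"sample_id": rec.id, "start": start, **row.to_dict()}
        records.append((seq, md))
    return records


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

def call_variants(sequence: str, reference: str, offset: int = 0) -> set[Variant]:
    """Call differences between a positionally aligned sequence and reference.

    ``offset`` shifts coordinates for fragments (offset = start - 1).  Gaps in
    the sample produce deletions; gaps in the reference produce insertions
    anchored to the preceding reference position.  Ambiguity codes (N etc.)
    never produce variants.
    """
    sequence = sequence.upper()
    reference = reference.upper()
    if len(sequence) != len(reference):
        raise SequenceIOError(
            f"sequence length {len(sequence)} != reference length {len(reference)}"
        )
    variants: set[Variant] = set()
    ref_pos = offset  # last consumed 1-based reference coordinate
    ins_index = 0
    for s, r in zip(sequence, reference):
        if r != _GAP:
            ref_pos += 1
            ins_index = 0
        for ch, which in ((s, "sample"), (r, "reference")):
            if ch not in _NUCLEOTIDES and ch not in _AMBIGUOUS and ch != _GAP:
                raise SequenceIOError(f"non-nucleotide character {ch!r} in {which}")
        if s == r:
            continue
        if s in _AMBIGUOUS or r in _AMBIGUOUS:
            continue
        if r == _GAP:
            if s == _GAP:
                continue
            ins_index += 1
            variants.add(Variant(ref_pos, _GAP, s, "insertion", insertion_index=ins_index))
        elif s == _GAP:
            variants.add(Variant(ref_pos, r, _GAP, "deletion"))
        else:
            variants.add(Variant(ref_pos, r, s, "substitution"))
    return variants


def apply_variants(reference: str, variants: Iterable[Variant]) -> str:
    """Apply substitution variants to the reference (round-trip helper)."""
    seq = list(reference.upper())
    for v in variants:
        if v.var_class != "substitution":
            raise SequenceIOError("apply_variants handles substitutions only")
        if seq[v.position - 1] != v.ref_base:
            raise SequenceIOError(f"reference mismatch at {v.position}")
        seq[v.position - 1] = v.derived_base
    return "".join(seq)


# ---------------------------------------------------------------------------
# synonymy
# ---------------------------------------------------------------------------

def _codon_for(position: int, gene: Gene, reference: str) -> tuple[str, int] | None:
    """Return (codon, index-within-codon) for a position, in coding orientation.

    Returns None for positions in a terminal incomplete codon.
    """
    if gene.strand == "+":
        off = position - gene.start
        codon_idx, within = divmod(off, 3)
        codon_start = gene.start + 3 * codon_idx
        if codon_start + 2 > gene.end:
            return None
        codon = reference[codon_start - 1 : codon_start + 2]
        return codon, within
    # light strand: frame anchored at gene end, read toward gene start
    off = gene.end - position
    codon_idx, within = divmod(off, 3)
    codon_hi = gene.end - 3 * codon_idx
    if codon_hi - 2 < gene.start:
        return None
    fwd = reference[codon_hi - 3 : codon_hi]
    codon = "".join(_COMPLEMENT[b] for b in reversed(fwd))
    return codon, within


def _translate(codon: str) -> str:
    if codon in MITO_TABLE.stop_codons:
        return "*"
    return MITO_TABLE.forward_table[codon]


def classify_synonymous(variant: Variant, annotation: Annotation) -> str:
    """Classify a substitution as synonymous / non-synonymous / not coding.

    A substitution is synonymous iff the codon containing it translates to
    the same amino acid before and after the change under the vertebrate
    mitochondrial code.  Control-region, rRNA and tRNA positions (anything
    outside the protein-coding gene map) are ``not_coding``.
    """
    if variant.var_class != "substitution":
        raise ValueError("synonymy is undefined for indels")
    gene = annotation.gene_at(variant.position)
    if gene is None:
        return "not_coding"
    got = _codon_for(variant.position, gene, annotation.reference)
    if got is None:
        return "not_coding"
    codon, within = got
    ref_b = annotation.reference[variant.position - 1]
    if ref_b != variant.ref_base:
        raise SequenceIOError(
            f"variant ref base {variant.ref_base} != reference {ref_b} at {variant.position}"
        )
    new_base = variant.derived_base if gene.strand == "+" else _COMPLEMENT[variant.derived_base]
    mutated = codon[:within] + new_base + codon[within + 1 :]
    return "yes" if _translate(codon) == _translate(mutated) else "no"


def classify_haplotype(hap: Haplotype, annotation: Annotation) -> Haplotype:
    """Return a haplotype with synonymy filled in for every substitution."""
    new = set()
    for v in hap.variants:
        if v.var_class == "substitution":
            new.add(replace(v, synonymous=classify_synonymous(v, annotation)))
        else:
            new.add(v)
    return replace(hap, variants=frozenset(new))


# ---------------------------------------------------------------------------
# masking and fragments
# ---------------------------------------------------------------------------

def mask_haplotype(
    hap: Haplotype, masked_positions: Iterable[int], drop_indels: bool = False
) -> Haplotype:
    masked = set(masked_positions)
    kept = frozenset(
        v
        for v in hap.variants
        if v.position not in masked
        and not (drop_indels and v.var_class in ("insertion", "deletion"))
    )
    return replace(hap, variants=kept)


def extract_fragment(hap: Haplotype, start: int, end: int) -> Haplotype:
    if start > end:
        raise ValueError("fragment start > end")
    lo, hi = hap.covered_range
    if start < lo or end > hi:
        raise ValueError(
            f"fragment [{start}, {end}] outside covered range [{lo}, {hi}]"
        )
    kept = frozenset(v for v in hap.variants if start <= v.position <= end)
    return replace(hap, variants=kept, covered_range=(start, end))


# ---------------------------------------------------------------------------
# haplotype construction and export
# ---------------------------------------------------------------------------

def haplotypes_from_records(
    records: list[tuple[str, dict]],
    reference: str,
    annotation: Annotation | None = None,
    masked_positions: Iterable[int] = (),
    drop_indels: bool = False,
) -> list[Haplotype]:
    """Convert aligned sequence records into haplotypes ("sequences→haplotypes")."""
    haps = []
    for seq, md in records:
        start = int(md.get("start", 1))
        ref_slice = reference[start - 1 : start - 1 + len(seq)]
        variants = call_variants(seq, ref_slice, offset=start - 1)
        hap = Haplotype(
            sample_id=md["sample_id"],
            population=md["population"],
            region=md["region"],
            variants=frozenset(variants),
            covered_range=(start, start + len(seq) - 1),
        )
        if annotation is not None:
            hap = classify_haplotype(hap, annotation)
        hap = mask_haplotype(hap, masked_positions, drop_indels=drop_indels)
        haps.append(hap)
    return haps


def haplotype_table(haplotypes: Iterable[Haplotype]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": h.sample_id,
            "population": h.population,
            "region": h.region,
            "range_start": h.covered_range[0],
            "range_end": h.covered_range[1],
            "variants": h.variant_string(),
        }
        for h in haplotypes
    ]
    return pd.DataFrame(rows, columns=[
        "sample_id", "population", "region", "range_start", "range_end", "variants"
    ])


def write_haplotypes_tsv(haplotypes: Iterable[Haplotype], path) -> None:
    haplotype_table(haplotypes).to_csv(path, sep="\t", index=False)


def write_haplotypes_json(haplotypes: Iterable[Haplotype], path) -> None:
    payload = [
        {
            "sample_id": h.sample_id,
            "population": h.population,
            "region": h.region,
            "covered_range": list(h.covered_range),
            "variants": [
                {
                    "position": v.position,
                    "ref_base": v.ref_base,
                    "derived_base": v.derived_base,
                    "var_class": v.var_class,
                    "synonymous": v.synonymous,
                    "insertion_index": v.insertion_index,
                }
                for v in sorted(h.variants)
            ],
        }
        for h in haplotypes
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_haplotypes_json(path) -> list[Haplotype]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        Haplotype(
            sample_id=d["sample_id"],
            population=d["population"],
            region=d["region"],
            covered_range=tuple(d["covered_range"]),
            variants=frozenset(Variant(**v) for v in d["variants"]),
        )
        for d in payload
    ]
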