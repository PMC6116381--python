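"""Containers and file I/O for the MA-line analysis pipeline.

External formats are 1-based inclusive (FASTA/GFF3/VCF conventions); the
conversion to Python's 0-based indexing is confined to this module. Genomes
are single-contig; genes wrapping a circular origin are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Gene:
    """A CDS feature: 1-based inclusive coordinates on '+' or '-' strand."""

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"gene {self.gene_id}: invalid span {self.start}..{self.end}")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {self.end - self.start + 1} "
                "is not divisible by 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """Reference sequence plus gene models.

    The coordinate frame for all mutation classification and the site pool
    for the Monte Carlo null. Genes are kept sorted by start; overlapping
    gene pairs are recorded in ``overlapping_pairs``.
    """

    id: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)
    circular: bool = True
    overlapping_pairs: list[tuple[str, str]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
        L = len(self.sequence)
        for g in self.genes:
            if g.end > L:
                raise ValueError(f"gene {g.gene_id} extends past genome end ({g.end} > {L})")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        self.overlapping_pairs = [
            (a.gene_id, b.gene_id)
            for a, b in zip(self.genes, self.genes[1:])
            if b.start <= a.end
        ]

    def __len__(self) -> int:
        return len(self.sequence)

    @cached_property
    def coding_mask(self) -> np.ndarray:
        """Boolean array, True where a site (0-based) lies in any CDS."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for g in self.genes:
            mask[g.start - 1 : g.end] = True
        return mask

    @property
    def coding_fraction(self) -> float:
        return float(self.coding_mask.mean()) if len(self.sequence) else 0.0

    @property
    def gc_fraction(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s) if s else 0.0

    def gene_at(self, position: int) -> Gene | None:
        """First gene (coordinate order) containing a 1-based position."""
        for g in self.genes:
            if g.start <= position <= g.end:
                return g
            if g.start > position:
                break
        return None


@dataclass(frozen=True)
class MutationCall:
    """One called variant in one MA line.

    SNVs have single-base ref and alt. Indels are stored in normalized form:
    insertions carry ``ref == ""`` and ``position`` = the base immediately
    left of the insertion point; deletions carry ``alt == ""`` and
    ``position`` = the first deleted base. Net size is limited to 4 bp.
    """

    line_id: str
    position: int
    ref: str
    alt: str
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be 1-based and >= 1")
        if self.ref and self.alt:
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SNV calls must have single-base ref and alt")
            if self.ref == self.alt:
                raise ValueError("SNV ref and alt must differ")
            if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
                raise ValueError(f"non-ACGT allele in call at {self.position}")
        else:
            changed = self.ref or self.alt
            if not changed or not 1 <= len(changed) <= 4:
                raise ValueError("indel net length change must be 1-4 bp")
            if set(changed) - _VALID_BASES:
                raise ValueError(f"non-ACGT allele in call at {self.position}")

    @property
    def kind(self) -> str:
        if self.ref and self.alt:
            return "SNV"
        return "insertion" if self.alt else "deletion"

    @property
    def size(self) -> int:
        """Net length change in bp (0 for SNVs)."""
        return 0 if self.kind == "SNV" else len(self.ref or self.alt)


@dataclass
class FilterReport:
    """Per-line tallies from the read-depth filter."""

    min_depth: int
    kept: dict[str, int] = field(default_factory=dict)
    removed_low_depth: dict[str, int] = field(default_factory=dict)
    removed_missing_depth: dict[str, int] = field(default_factory=dict)

    def to_table(self) -> str:
        lines = ["line_id\tkept\tremoved_low_depth\tremoved_missing_depth"]
        for lid in sorted(set(self.kept) | set(self.removed_low_depth) | set(self.removed_missing_depth)):
            lines.append(
                f"{lid}\t{self.kept.get(lid, 0)}\t{self.removed_low_depth.get(lid, 0)}"
                f"\t{self.removed_missing_depth.get(lid, 0)}"
            )
        return "\n".join(lines) + "\n"


def parse_reference(fasta_path: str | Path, gff_path: str | Path) -> AnnotatedGenome:
    """Read a single-record FASTA and the CDS features of a GFF3 file.

    Raises on multi-record FASTA, CDS length not divisible by 3, or CDS
    coordinates outside the sequence. Overlapping genes are accepted but
    recorded (and warned about) on the returned genome.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()

    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(gff_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        features = list(db.features_of_type("CDS"))
    except EmptyInputError:
        features = []   # annotation with no features: fully noncoding genome
    genes = []
    for feat in features:
        if feat.seqid != rec.id:
            raise ValueError(f"CDS on unknown sequence {feat.seqid!r} (FASTA record is {rec.id!r})")
        gid = feat.attributes.get("ID", [feat.id])[0]
        if feat.end > len(seq) or feat.start < 1:
            raise ValueError(f"gene {gid}: coordinates {feat.start}..{feat.end} out of range")
        genes.append(Gene(gid, feat.start, feat.end, feat.strand))

    genome = AnnotatedGenome(id=rec.id, sequence=seq, genes=genes)
    if genome.overlapping_pairs:
        warnings.warn(
            f"{len(genome.overlapping_pairs)} overlapping gene pair(s) in annotation",
            stacklevel=2,
        )
    return genome


def write_reference(genome: AnnotatedGenome, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write the genome as FASTA plus a GFF3 of its CDS features."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for g in genome.genes:
            fh.write(
                f"{genome.id}\tmutaccum\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0"
                f"\tID={g.gene_id}\n"
            )


def parse_calls(vcf_path: str | Path, line_id: str) -> tuple[list[MutationCall], dict[str, int]]:
    """Read one MA line's VCF into normalized calls.

    SNVs and indels with a net length change of at most 4 bp are retained.
    Multi-allelic records, larger indels and complex (multi-base
    substitution) records are skipped and counted in the returned report.
    The VCF's left-anchored indel convention (shared leading base in
    REF/ALT) is normalized away.
    """
    from cyvcf2 import VCF

    calls: list[MutationCall] = []
    skipped = {"multi_allelic": 0, "indel_gt_4bp": 0, "complex": 0}
    for var in VCF(str(vcf_path)):
        if len(var.ALT) != 1:
            skipped["multi_allelic"] += 1
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        dp = var.INFO.get("DP")
        depth = int(dp) if dp is not None else None
        if len(ref) == 1 and len(alt) == 1:
            calls.append(MutationCall(line_id, var.POS, ref, alt, depth))
        elif len(ref) == 1 and alt.startswith(ref):
            inserted = alt[1:]
            if len(inserted) > 4:
                skipped["indel_gt_4bp"] += 1
                continue
            calls.append(MutationCall(line_id, var.POS, "", inserted, depth))
        elif len(alt) == 1 and ref.startswith(alt):
            deleted = ref[1:]
            if len(deleted) > 4:
                skipped["indel_gt_4bp"] += 1
                continue
            calls.append(MutationCall(line_id, var.POS + 1, deleted, "", depth))
        else:
            skipped["complex"] += 1
    return calls, skipped


def write_calls(
    calls: list[MutationCall], genome: AnnotatedGenome, vcf_path: str | Path
) -> None:
    """Write calls for one line as a VCF v4.2 text file (DP in INFO)."""
    seq = genome.sequence
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.id},length={len(genome)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: c.position):
            if c.kind == "SNV":
                pos, ref, alt = c.position, c.ref, c.alt
            elif c.kind == "insertion":
                anchor = seq[c.position - 1]
                pos, ref, alt = c.position, anchor, anchor + c.alt
            else:
                if c.position < 2:
                    raise ValueError("cannot left-anchor a deletion starting at position 1")
                anchor = seq[c.position - 2]
                pos, ref, alt = c.position - 1, anchor + c.ref, anchor
            info = f"DP={c.depth}" if c.depth is not None else "."
            fh.write(f"{genome.id}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def filter_by_depth(
    calls: list[MutationCall],
    min_depth: int = 20,
    keep_missing: bool = False,
    report: FilterReport | None = None,
) -> tuple[list[MutationCall], FilterReport]:
    """Drop calls whose read depth is below ``min_depth``.

    Calls lacking a depth value are removed (conservatively) unless
    ``keep_missing`` is set; they are tallied separately either way.
    The operation is idempotent.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    rep = report or FilterReport(min_depth=min_depth)
    kept: list[MutationCall] = []
    for c in calls:
        if c.depth is None:
            if keep_missing:
                kept.append(c)
                rep.kept[c.line_id] = rep.kept.get(c.line_id, 0) + 1
            else:
                rep.removed_missing_depth[c.line_id] = rep.removed_missing_depth.get(c.line_id, 0) + 1
        elif c.depth < min_depth:
            rep.removed_low_depth[c.line_id] = rep.removed_low_depth.get(c.line_id, 0) + 1
        else:
            kept.append(c)
            rep.kept[c.line_id] = rep.kept.get(c.line_id, 0) + 1
    return kept, rep


def subtract_ancestor(
    calls: list[MutationCall], ancestor_calls: list[MutationCall]
) -> tuple[list[MutationCall], int]:
    """Remove calls matching an ancestral variant (position/ref/alt).

    Standard MA practice: variants already present in the sequenced
    ancestor are not mutations accumulated during the experiment.
    """
    ancestral = {(c.position, c.ref, c.alt) for c in ancestor_calls}
    kept = [c for c in calls if (c.position, c.ref, c.alt) not in ancestral]
    return kept, len(calls) - len(kept)
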