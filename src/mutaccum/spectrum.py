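"""Molecular-spectrum classification of base-pair substitutions and indels.

Substitutions are labelled by the six strand-collapsed types (A:T>G:C,
G:C>A:T, A:T>C:G, G:C>T:A, A:T>T:A, G:C>C:G), transition/transversion,
coding/noncoding region, synonymous/nonsynonymous consequence under the
bacterial genetic code (NCBI translation table 11), and — for
nonsynonymous changes — conservative/non-conservative by BLOSUM62 score
(>= 0 is conservative). Small indels (1-4 bp) are labelled by size,
gain/loss, the affected pair for 1 bp events, and whether they fall in a
homopolymer run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import AnnotatedGenome, Gene, MutationCall

SIX_TYPES = ("A:T>G:C", "G:C>A:T", "A:T>C:G", "G:C>T:A", "A:T>T:A", "G:C>C:G")
TRANSITIONS = ("A:T>G:C", "G:C>A:T")

NA = "not-applicable"

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

# strand-collapsed lookup: (ref, alt) -> six-type label
_SIX_TYPE_OF: dict[tuple[str, str], str] = {}
for _ref, _alt, _label in [
    ("A", "G", "A:T>G:C"), ("G", "A", "G:C>A:T"),
    ("A", "C", "A:T>C:G"), ("G", "T", "G:C>T:A"),
    ("A", "T", "A:T>T:A"), ("G", "C", "G:C>C:G"),
]:
    _SIX_TYPE_OF[(_ref, _alt)] = _label
    _SIX_TYPE_OF[(_COMPLEMENT[_ref], _COMPLEMENT[_alt])] = _label


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class BPSClass:
    six_type: str
    ts_tv: str            # "transition" | "transversion"
    region: str           # "coding" | "noncoding"
    effect: str           # "synonymous" | "nonsynonymous" | not-applicable
    conservation: str     # "conservative" | "non-conservative" | not-applicable


@dataclass(frozen=True)
class IndelClass:
    size: int             # 1-4 bp
    direction: str        # "gain" | "loss"
    pair: str             # "A:T" | "G:C" | not-applicable (size > 1)
    in_run: bool
    region: str           # "coding" | "noncoding" (by leftmost affected base)


def six_type_of(ref: str, alt: str) -> tuple[str, str]:
    """Strand-collapsed substitution class and transition/transversion.

    A mutation and its reverse complement map to the same label, e.g. both
    A>G and T>C are A:T>G:C transitions.
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"bases must be one of ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    label = _SIX_TYPE_OF[(ref, alt)]
    return label, "transition" if label in TRANSITIONS else "transversion"


@lru_cache(maxsize=None)
def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def _conservation(aa_ref: str, aa_alt: str) -> str:
    # BLOSUM62 has no meaningful stop row: stop gain/loss is non-conservative
    if "*" in (aa_ref, aa_alt):
        return "non-conservative"
    return "conservative" if _BLOSUM62[aa_ref, aa_alt] >= 0 else "non-conservative"


def classify_bps(
    call: MutationCall, genome: AnnotatedGenome, on_overlap: str = "first"
) -> BPSClass:
    """Classify an SNV against the genome's gene models.

    For coding sites the affected codon is reconstructed on the gene's
    sense strand (minus-strand genes are reverse-complemented), mutated,
    and translated under table 11; nonsynonymous changes are scored with
    BLOSUM62. Sites in overlapping genes are classified against the gene
    listed first in coordinate order (``on_overlap="first"``, with a
    warning) or raise (``on_overlap="drop"``).
    """
    if call.kind != "SNV":
        raise ValueError("classify_bps expects an SNV call")
    if call.position > len(genome):
        raise ValueError(f"position {call.position} outside genome of length {len(genome)}")
    if genome.sequence[call.position - 1] != call.ref:
        raise ValueError(
            f"reference mismatch at {call.position}: genome has "
            f"{genome.sequence[call.position - 1]}, call says {call.ref}"
        )
    label, ts_tv = six_type_of(call.ref, call.alt)

    gene = genome.gene_at(call.position)
    if gene is None:
        return BPSClass(label, ts_tv, "noncoding", NA, NA)
    others = [
        a for a, b in genome.overlapping_pairs if b == gene.gene_id
    ] + [b for a, b in genome.overlapping_pairs if a == gene.gene_id]
    if others and any(
        g.start <= call.position <= g.end
        for g in genome.genes
        if g.gene_id in others
    ):
        if on_overlap == "drop":
            raise ValueError(f"position {call.position} lies in overlapping genes")
        warnings.warn(
            f"position {call.position} in overlapping genes; using {gene.gene_id}",
            stacklevel=2,
        )

    codon, within, ref_sense, alt_sense = _codon_context(call, genome, gene)
    aa_ref = _translate(codon)
    aa_alt = _translate(codon[:within] + alt_sense + codon[within + 1 :])
    if aa_ref == aa_alt:
        return BPSClass(label, ts_tv, "coding", "synonymous", NA)
    return BPSClass(label, ts_tv, "coding", "nonsynonymous", _conservation(aa_ref, aa_alt))


def _codon_context(
    call: MutationCall, genome: AnnotatedGenome, gene: Gene
) -> tuple[str, int, str, str]:
    """Sense-strand codon containing the call, offset within it, and the
    ref/alt bases expressed on the sense strand."""
    pos0 = call.position - 1
    if gene.strand == "+":
        offset = pos0 - (gene.start - 1)
        codon_idx, within = divmod(offset, 3)
        cstart = gene.start - 1 + 3 * codon_idx
        codon = genome.sequence[cstart : cstart + 3]
        return codon, within, call.ref, call.alt
    offset = (gene.end - 1) - pos0
    codon_idx, within = divmod(offset, 3)
    cend = gene.end - 3 * codon_idx          # exclusive, genomic
    codon = revcomp(genome.sequence[cend - 3 : cend])
    return codon, within, _COMPLEMENT[call.ref], _COMPLEMENT[call.alt]


def _run_span(seq: str, pos0: int) -> tuple[int, int]:
    """Maximal run of identical bases containing 0-based ``pos0`` as
    (start, length)."""
    b = seq[pos0]
    lo = pos0
    while lo > 0 and seq[lo - 1] == b:
        lo -= 1
    hi = pos0
    while hi + 1 < len(seq) and seq[hi + 1] == b:
        hi += 1
    return lo, hi - lo + 1


def classify_indel(
    call: MutationCall, genome: AnnotatedGenome, run_min_len: int = 3
) -> IndelClass:
    """Classify a 1-4 bp indel.

    1 bp events are assigned a strand-collapsed pair (A:T or G:C) from the
    inserted/deleted base, and are "in run" when a homopolymer of at least
    ``run_min_len`` copies of that base lies at or adjacent to the site.
    Multi-base events are "in run" when the site sits inside any
    homopolymer of length >= ``run_min_len``. Region is taken from the
    leftmost affected base.
    """
    if call.kind == "SNV":
        raise ValueError("classify_indel expects an indel call")
    seq = genome.sequence
    size = call.size
    direction = "gain" if call.kind == "insertion" else "loss"
    changed = call.alt if call.kind == "insertion" else call.ref

    # leftmost affected base: first deleted base, or the base right of the
    # insertion anchor
    left0 = call.position - 1 if call.kind == "deletion" else min(call.position, len(seq) - 1)
    region = "coding" if genome.coding_mask[left0] else "noncoding"

    if size == 1:
        base = changed
        pair = "A:T" if base in "AT" else "G:C"
        in_run = False
        # positions whose runs could contain/abut the event
        probe = {call.position - 1, call.position} if call.kind == "insertion" else {left0}
        for p in probe:
            if 0 <= p < len(seq) and seq[p] == base:
                _, run_len = _run_span(seq, p)
                if run_len >= run_min_len:
                    in_run = True
                    break
        return IndelClass(1, direction, pair, in_run, region)

    _, run_len = _run_span(seq, left0)
    in_run = run_len >= run_min_len
    return IndelClass(size, direction, NA, in_run, region)


# ---------------------------------------------------------------------------
# per-site effect tables (vectorized classification for the MC null)

# codes in the effect table
SITE_NONCODING = 0
SITE_SYNONYMOUS = 1
SITE_NONSYN_CONSERVATIVE = 2
SITE_NONSYN_NONCONSERVATIVE = 3


@lru_cache(maxsize=None)
def _codon_effect_codes(codon: str) -> np.ndarray:
    """(3 positions x 4 alt bases) effect codes for one sense codon."""
    out = np.zeros((3, 4), dtype=np.int8)
    aa_ref = _translate(codon)
    for within in range(3):
        for ai, alt in enumerate(_BASES):
            if alt == codon[within]:
                out[within, ai] = -1  # not a mutation
                continue
            aa_alt = _translate(codon[:within] + alt + codon[within + 1 :])
            if aa_alt == aa_ref:
                out[within, ai] = SITE_SYNONYMOUS
            elif _conservation(aa_ref, aa_alt) == "conservative":
                out[within, ai] = SITE_NONSYN_CONSERVATIVE
            else:
                out[within, ai] = SITE_NONSYN_NONCONSERVATIVE
    return out


def site_effect_table(genome: AnnotatedGenome) -> np.ndarray:
    """(L x 4) int8 table: effect code of mutating site i (0-based) to
    alt base ACGT[j]. Noncoding sites are 0; alt == ref cells are -1.

    Sites in overlapping genes follow the first gene in coordinate order,
    matching :func:`classify_bps`.
    """
    L = len(genome)
    table = np.zeros((L, 4), dtype=np.int8)
    seq = genome.sequence
    base_idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    ref_idx = lut[base_idx]
    table[np.arange(L), ref_idx] = -1

    claimed = np.zeros(L, dtype=bool)  # first gene wins at overlaps
    comp_idx = np.array([_BASE_INDEX[_COMPLEMENT[b]] for b in _BASES])
    for g in genome.genes:
        span = slice(g.start - 1, g.end)
        if g.strand == "+":
            for ci in range(g.length // 3):
                cstart = g.start - 1 + 3 * ci
                codes = _codon_effect_codes(seq[cstart : cstart + 3])
                for within in range(3):
                    p = cstart + within
                    if not claimed[p]:
                        table[p] = codes[within]
        else:
            for ci in range(g.length // 3):
                cend = g.end - 3 * ci
                codon = revcomp(seq[cend - 3 : cend])
                codes = _codon_effect_codes(codon)
                for within in range(3):
                    p = cend - 1 - within  # genomic position of sense offset
                    if not claimed[p]:
                        # alt on sense strand = complement of genomic alt
                        table[p] = codes[within][comp_idx]
        claimed[span] = True
    return table


# ---------------------------------------------------------------------------
# tabulation

BPS_COLUMNS = [
    "bps_total", *SIX_TYPES, "transitions", "transversions",
    "coding", "noncoding", "synonymous", "nonsynonymous",
    "conservative", "non_conservative",
]
INDEL_COLUMNS = [
    "indels_total", "gains", "losses",
    "ins1_AT", "ins1_GC", "del1_AT", "del1_GC",
    "ins2", "ins3", "ins4", "del2", "del3", "del4",
    "indels_in_runs",
]
ALL_COLUMNS = BPS_COLUMNS + INDEL_COLUMNS + ["mutations_total"]


@dataclass
class SpectrumCounts:
    """Per-line (and derived per-group) counts for every spectrum category."""

    per_line: pd.DataFrame          # index line_id, columns ALL_COLUMNS
    line_groups: dict[str, str]

    @property
    def per_group(self) -> pd.DataFrame:
        groups = pd.Series(self.line_groups, name="group")
        return self.per_line.groupby(groups).sum()

    def validate(self) -> None:
        df = self.per_line
        checks = [
            (df[list(SIX_TYPES)].sum(axis=1), df["bps_total"], "six types vs total BPS"),
            (df["transitions"] + df["transversions"], df["bps_total"], "ts+tv vs total BPS"),
            (df["coding"] + df["noncoding"], df["bps_total"], "coding+noncoding vs total BPS"),
            (df["synonymous"] + df["nonsynonymous"], df["coding"], "syn+nonsyn vs coding"),
            (df["conservative"] + df["non_conservative"], df["nonsynonymous"],
             "cons+noncons vs nonsynonymous"),
            (df[["ins1_AT", "ins1_GC", "del1_AT", "del1_GC", "ins2", "ins3", "ins4",
                 "del2", "del3", "del4"]].sum(axis=1), df["indels_total"],
             "indel categories vs total indels"),
            (df["gains"] + df["losses"], df["indels_total"], "gains+losses vs total indels"),
            (df["bps_total"] + df["indels_total"], df["mutations_total"],
             "BPS+indels vs total mutations"),
        ]
        for got, want, what in checks:
            if not got.equals(want):
                raise ValueError(f"spectrum count invariant violated: {what}")


def tabulate_spectrum(
    classified: list[tuple[MutationCall, BPSClass | IndelClass]],
    line_groups: dict[str, str],
) -> SpectrumCounts:
    """Aggregate classified calls into per-line category counts.

    Every line in ``line_groups`` appears in the table (zero row when it
    accumulated no mutations); a call from an unknown line is an error.
    """
    counts = {lid: dict.fromkeys(ALL_COLUMNS, 0) for lid in line_groups}
    for call, cls in classified:
        if call.line_id not in counts:
            raise ValueError(f"call from unknown line {call.line_id!r}")
        row = counts[call.line_id]
        row["mutations_total"] += 1
        if isinstance(cls, BPSClass):
            row["bps_total"] += 1
            row[cls.six_type] += 1
            row["transitions" if cls.ts_tv == "transition" else "transversions"] += 1
            row[cls.region] += 1
            if cls.effect != NA:
                row[cls.effect] += 1
            if cls.conservation == "conservative":
                row["conservative"] += 1
            elif cls.conservation == "non-conservative":
                row["non_conservative"] += 1
        else:
            row["indels_total"] += 1
            row["gains" if cls.direction == "gain" else "losses"] += 1
            if cls.size == 1:
                tag = ("ins1_" if cls.direction == "gain" else "del1_") + (
                    "AT" if cls.pair == "A:T" else "GC"
                )
            else:
                tag = ("ins" if cls.direction == "gain" else "del") + str(cls.size)
            row[tag] += 1
            if cls.in_run:
                row["indels_in_runs"] += 1
    per_line = pd.DataFrame.from_dict(counts, orient="index", dtype=int)
    per_line = per_line.reindex(columns=ALL_COLUMNS).sort_index()
    per_line.index.name = "line_id"
    result = SpectrumCounts(per_line=per_line, line_groups=dict(line_groups))
    result.validate()
    return result


def classified_table(
    classified: list[tuple[MutationCall, BPSClass | IndelClass]]
) -> pd.DataFrame:
    """Long-format table of classified calls (one row per mutation)."""
    columns = ["line_id", "position", "ref", "alt", "kind", "six_type", "ts_tv",
               "region", "effect", "conservation", "size", "direction", "pair",
               "in_run"]
    if not classified:
        return pd.DataFrame(columns=columns)
    rows = []
    for call, cls in classified:
        if isinstance(cls, BPSClass):
            rows.append(dict(
                line_id=call.line_id, position=call.position, ref=call.ref,
                alt=call.alt, kind="SNV", six_type=cls.six_type, ts_tv=cls.ts_tv,
                region=cls.region, effect=cls.effect, conservation=cls.conservation,
                size=0, direction=NA, pair=NA, in_run=False,
            ))
        else:
            rows.append(dict(
                line_id=call.line_id, position=call.position, ref=call.ref,
                alt=call.alt, kind=call.kind, six_type=NA, ts_tv=NA,
                region=cls.region, effect=NA, conservation=NA,
                size=cls.size, direction=cls.direction, pair=cls.pair,
                in_run=cls.in_run,
            ))
    return pd.DataFrame(rows).sort_values(["line_id", "position"]).reset_index(drop=True)
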