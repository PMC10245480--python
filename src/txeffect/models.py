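"""Core data model: genome, spliced transcripts, ORFs, variants.

All internal coordinates are 0-based half-open on the genome. Transcript
coordinates run 5'→3' along the mature (spliced) transcript, so position 0
is the leftmost base of the first exon on the + strand and the rightmost
base of the last exon on the - strand. Conversions to the 1-based
conventions of GTF and VCF happen only at the I/O boundary (see
:mod:`txeffect.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A position fell outside the object it was resolved against."""


class ValidationError(ValueError):
    """An input object violated a structural invariant."""


@dataclass
class GenomeRef:
    """In-memory genome: contig name → uppercase nucleotide sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValidationError(f"contig {name!r} has empty sequence")

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self._seq(contig))

    def _seq(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise CoordinateError(f"contig {contig!r} not in genome") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """0-based half-open subsequence; bounds-checked."""
        seq = self._seq(contig)
        if not (0 <= start <= end <= len(seq)):
            raise CoordinateError(
                f"[{start},{end}) outside contig {contig} of length {len(seq)}"
            )
        return seq[start:end]


@dataclass
class TranscriptModel:
    """A spliced transcript: ordered exon blocks on one contig and strand."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    gene_symbol: Optional[str] = None
    novelty: str = "known"  # {known, novel}
    source: str = "reference"  # {custom, reference}
    #: genomic CDS blocks annotated in the source GTF, if any (ascending)
    annotated_cds: Optional[list[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        exons = sorted(tuple(e) for e in self.exons)
        for s, e in exons:
            if e <= s:
                raise ValidationError(f"{self.transcript_id}: empty exon [{s},{e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons at {e1}/{s2}"
                )
        self.exons = exons
        if self.novelty not in ("known", "novel"):
            raise ValidationError(f"bad novelty {self.novelty!r}")
        if self.source not in ("custom", "reference"):
            raise ValidationError(f"bad source {self.source!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    # ---- splice-aware coordinate arithmetic -------------------------------

    def tx_to_genome(self, tx_pos: int) -> int:
        """Genomic position of transcript base ``tx_pos`` (both 0-based)."""
        n = self.spliced_length
        if not (0 <= tx_pos < n):
            raise CoordinateError(
                f"{self.transcript_id}: tx_pos {tx_pos} outside [0,{n})"
            )
        if self.strand == "-":
            tx_pos = n - 1 - tx_pos
        for s, e in self.exons:
            if tx_pos < e - s:
                return s + tx_pos
            tx_pos -= e - s
        raise AssertionError("unreachable")

    def genome_to_tx(self, g_pos: int) -> int:
        """Transcript position of exonic genomic base ``g_pos``."""
        offset = 0
        for s, e in self.exons:
            if s <= g_pos < e:
                plus = offset + (g_pos - s)
                if self.strand == "-":
                    return self.spliced_length - 1 - plus
                return plus
            offset += e - s
        raise CoordinateError(
            f"{self.transcript_id}: genomic {g_pos} is not exonic"
        )

    def tx_span_to_blocks(self, tx_start: int, tx_end: int) -> list[tuple[int, int]]:
        """Project transcript span [tx_start, tx_end) to ascending genomic blocks."""
        if not (0 <= tx_start < tx_end <= self.spliced_length):
            raise CoordinateError(
                f"{self.transcript_id}: span [{tx_start},{tx_end}) out of range"
            )
        lo = self.tx_to_genome(tx_start)
        hi = self.tx_to_genome(tx_end - 1)
        g_lo, g_hi = min(lo, hi), max(lo, hi) + 1
        blocks = []
        for s, e in self.exons:
            bs, be = max(s, g_lo), min(e, g_hi)
            if bs < be:
                blocks.append((bs, be))
        return blocks

    def spliced_sequence(self, genome: GenomeRef) -> str:
        parts = [genome.fetch(self.contig, s, e) for s, e in self.exons]
        seq = "".join(parts)
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass
class OrfModel:
    """A (predicted or annotated) open reading frame on one transcript.

    ``tx_start``/``tx_end`` are transcript coordinates 5'→3'; when
    ``has_stop`` the final codon of the span is the stop codon, which is not
    part of ``protein``.
    """

    transcript_id: str
    tx_start: int
    tx_end: int
    coding_probability: float
    protein: str
    has_stop: bool
    cds_blocks: list[tuple[int, int]] = field(default_factory=list)
    orf_id: str = ""

    def __post_init__(self) -> None:
        if (self.tx_end - self.tx_start) % 3 != 0 or self.tx_end <= self.tx_start:
            raise ValidationError(
                f"ORF span [{self.tx_start},{self.tx_end}) not a positive codon multiple"
            )
        if "*" in self.protein:
            raise ValidationError("protein carries an internal stop symbol")
        if not 0.0 <= self.coding_probability <= 1.0:
            raise ValidationError("coding_probability outside [0,1]")

    @property
    def n_codons(self) -> int:
        return (self.tx_end - self.tx_start) // 3


@dataclass
class Variant:
    """One normalized VCF allele. ``pos`` is 1-based (VCF convention)."""

    contig: str
    pos: int
    ref: str
    alt: str
    variant_id: Optional[str] = None
    allele_frequency: Optional[float] = None
    ref_mismatch: bool = False

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(f"{self}: ref equals alt")
        ok = set("ACGTN")
        if set(self.ref) - ok or set(self.alt) - ok:
            raise ValidationError(f"{self.contig}:{self.pos} non-ACGTN allele")

    @property
    def pos0(self) -> int:
        """0-based genomic position of the first ref base."""
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - repr helper
        return f"{self.contig}:{self.pos}{self.ref}>{self.alt}"


def normalize_variant(v: Variant, genome: Optional[GenomeRef]) -> Variant:
    """Left-normalize and trim a variant against the genome.

    Follows the usual parsimony/left-alignment rules: shared trailing bases
    are trimmed (extending left with genomic context when an allele would
    empty), then shared leading bases beyond the single anchor are trimmed.
    Without a genome the variant is returned with suffix/prefix trimming
    only (no left-shifting).
    """
    ref, alt, pos0 = v.ref, v.alt, v.pos0
    if genome is not None and v.contig in genome:
        seq = genome.contigs[v.contig]
        while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and not (
            len(ref) == 1 and len(alt) == 1
        ):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos0 == 0:
                    break
                pos0 -= 1
                base = seq[pos0]
                ref, alt = base + ref, base + alt
    else:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    mismatch = v.ref_mismatch
    if genome is not None and v.contig in genome:
        expect = genome.contigs[v.contig][pos0 : pos0 + len(ref)]
        if expect != ref:
            mismatch = True
    return Variant(
        contig=v.contig,
        pos=pos0 + 1,
        ref=ref,
        alt=alt,
        variant_id=v.variant_id,
        allele_frequency=v.allele_frequency,
        ref_mismatch=mismatch,
    )


def orf_from_annotated_cds(
    t: TranscriptModel, genome: GenomeRef, coding_probability: float = 1.0
) -> Optional[OrfModel]:
    """Build an OrfModel from a transcript's annotated CDS blocks.

    GTFs in the wild differ on whether the stop codon is part of the CDS;
    when the annotated span does not end in a stop the next three
    transcript bases are probed and absorbed if they are one.
    """
    from .orf import STOP_CODONS, translate  # local import avoids a cycle

    if not t.annotated_cds:
        return None
    positions = sorted(
        t.genome_to_tx(p) for s, e in t.annotated_cds for p in (s, e - 1)
    )
    tx_start, tx_end = positions[0], positions[-1] + 1
    if (tx_end - tx_start) % 3 != 0:
        raise ValidationError(
            f"{t.transcript_id}: annotated CDS length not a multiple of 3"
        )
    seq = t.spliced_sequence(genome)
    cds_seq = seq[tx_start:tx_end]
    has_stop = cds_seq[-3:] in STOP_CODONS
    if not has_stop and tx_end + 3 <= t.spliced_length:
        nxt = seq[tx_end : tx_end + 3]
        if nxt in STOP_CODONS:
            tx_end += 3
            cds_seq += nxt
            has_stop = True
    protein = translate(cds_seq[:-3] if has_stop else cds_seq)
    return OrfModel(
        transcript_id=t.transcript_id,
        tx_start=tx_start,
        tx_end=tx_end,
        coding_probability=coding_probability,
        protein=protein,
        has_stop=has_stop,
        cds_blocks=t.tx_span_to_blocks(tx_start, tx_end),
        orf_id=f"{t.transcript_id}.orf0",
    )
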