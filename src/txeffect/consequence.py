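"""Per-transcript molecular consequence calling.

Each (variant, transcript, ORF) triple receives a set of Sequence-Ontology
terms determined by where the variant falls (upstream/downstream, intron,
splice site, UTR, CDS) and — inside the CDS — by the codon-level effect of
the allele. Splice definitions follow the Ensembl conventions: the first
and last two intron bases are donor/acceptor sites, intron bases 3–8 and
the last/first three exon bases of an internal junction are splice region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .models import GenomeRef, OrfModel, TranscriptModel, Variant
from .orf import CODON_TABLE, STOP_CODONS

DEFAULT_WINDOW = 5000

#: terms that carry an amino-acid substitution annotation
PROTEIN_SUBSTITUTION_TERMS = frozenset(
    {"missense_variant", "stop_gained", "stop_lost", "start_lost"}
)


class NoCallError(ValueError):
    """Variant and transcript cannot be compared (different contigs)."""


@dataclass
class ConsequenceCall:
    variant: Variant
    transcript_id: str
    source: str
    terms: frozenset[str]
    gene_id: str = ""
    gene_symbol: Optional[str] = None
    aa_change: Optional[tuple[str, int, str]] = None  # (ref_aa, 1-based pos, alt_aa)
    codon_change: Optional[tuple[str, str]] = None
    missense_score: Optional[tuple[float, str]] = None  # (score, prediction)
    orf_id: Optional[str] = None
    coding_probability: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a consequence call must carry at least one term")
        self.terms = frozenset(self.terms)

    @property
    def is_missense(self) -> bool:
        return "missense_variant" in self.terms


def _codon_aa(codon: str) -> str:
    return "X" if "N" in codon else CODON_TABLE[codon]


def _affected_positions(v: Variant) -> list[int]:
    """Genomic 0-based positions whose identity the allele changes.

    Pure insertions are anchored at the right edge of the VCF position;
    anchored deletions exclude the anchor base.
    """
    if v.is_snv:
        return [v.pos0]
    anchored = v.ref[0] == v.alt[0]
    if v.is_insertion and len(v.ref) == 1 and anchored:
        return [v.pos0 + 1]
    if anchored and len(v.alt) == 1:
        return list(range(v.pos0 + 1, v.pos0 + len(v.ref)))
    return list(range(v.pos0, v.pos0 + len(v.ref)))


def _locate(t: TranscriptModel, p: int) -> tuple[str, int]:
    """("exon", i) | ("intron", i) | ("outside", 0) for genomic position p."""
    for i, (s, e) in enumerate(t.exons):
        if s <= p < e:
            return "exon", i
    for i, (s, e) in enumerate(t.introns):
        if s <= p < e:
            return "intron", i
    return "outside", 0


def _intron_terms(t: TranscriptModel, intron_idx: int, p: int) -> set[str]:
    s, e = t.introns[intron_idx]
    if t.strand == "+":
        from_donor, from_acceptor = p - s, e - 1 - p
    else:
        from_donor, from_acceptor = e - 1 - p, p - s
    if from_donor < 2:
        return {"splice_donor_variant"}
    if from_acceptor < 2:
        return {"splice_acceptor_variant"}
    if from_donor < 8 or from_acceptor < 8:
        return {"splice_region_variant"}
    return {"intron_variant"}


def _exon_junction_region(t: TranscriptModel, exon_idx: int, p: int) -> bool:
    s, e = t.exons[exon_idx]
    if exon_idx > 0 and p - s < 3:
        return True
    if exon_idx < len(t.exons) - 1 and e - 1 - p < 3:
        return True
    return False


def _alt_on_transcript(base: str, strand: str) -> str:
    from .models import reverse_complement

    return reverse_complement(base) if strand == "-" else base


def _snv_cds_terms(
    v: Variant, t: TranscriptModel, orf: OrfModel, spliced: str, tx: int
) -> tuple[set[str], Optional[tuple[str, int, str]], Optional[tuple[str, str]]]:
    ci = (tx - orf.tx_start) // 3
    off = (tx - orf.tx_start) % 3
    codon_start = orf.tx_start + 3 * ci
    ref_codon = spliced[codon_start : codon_start + 3]
    alt_base = _alt_on_transcript(v.alt, t.strand)
    alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1 :]
    ref_aa, alt_aa = _codon_aa(ref_codon), _codon_aa(alt_codon)
    change = (ref_aa, ci + 1, alt_aa)
    codons = (ref_codon, alt_codon)
    if ci == 0 and ref_aa == "M" and alt_aa != "M":
        return {"start_lost"}, change, codons
    if orf.has_stop and ci == orf.n_codons - 1:
        if alt_codon in STOP_CODONS:
            return {"stop_retained_variant"}, None, codons
        return {"stop_lost"}, change, codons
    if alt_aa == "*":
        return {"stop_gained"}, change, codons
    if ref_aa == alt_aa:
        return {"synonymous_variant"}, None, codons
    return {"missense_variant"}, change, codons


def call_consequence(
    v: Variant,
    t: Optional[TranscriptModel],
    orf: Optional[OrfModel],
    genome: GenomeRef,
    source: str = "reference",
    window: int = DEFAULT_WINDOW,
) -> ConsequenceCall:
    """Assign SO terms for one variant against one transcript model.

    With ``t=None`` an intergenic placeholder call is produced. A variant
    spanning several classes of position (e.g. an exon–intron deletion)
    receives the union of the per-position terms.
    """
    if t is None:
        return ConsequenceCall(v, "", source, frozenset({"intergenic_variant"}))
    if v.contig != t.contig:
        raise NoCallError(
            f"variant {v} on {v.contig!r} vs transcript {t.transcript_id} on {t.contig!r}"
        )

    positions = _affected_positions(v)
    inside = [p for p in positions if t.start <= p < t.end]
    if not inside:
        anchor = positions[0]
        if t.start - window <= anchor < t.end + window:
            left = anchor < t.start
            upstream = left == (t.strand == "+")
            term = "upstream_gene_variant" if upstream else "downstream_gene_variant"
        else:
            term = "intergenic_variant"
        return ConsequenceCall(
            v, t.transcript_id, source, frozenset({term}),
            gene_id=t.gene_id, gene_symbol=t.gene_symbol,
        )

    terms: set[str] = set()
    aa_change = codon_change = None
    spliced = t.spliced_sequence(genome) if orf is not None else ""

    exonic_tx: list[int] = []
    for p in inside:
        where, idx = _locate(t, p)
        if where == "intron":
            terms |= _intron_terms(t, idx, p)
            continue
        if _exon_junction_region(t, idx, p):
            terms.add("splice_region_variant")
        tx = t.genome_to_tx(p)
        exonic_tx.append(tx)
        if orf is None:
            terms.add("non_coding_transcript_exon_variant")
        elif tx < orf.tx_start:
            terms.add("5_prime_UTR_variant")
        elif tx >= orf.tx_end:
            terms.add("3_prime_UTR_variant")

    cds_tx = [
        tx for tx in exonic_tx
        if orf is not None and orf.tx_start <= tx < orf.tx_end
    ]
    if cds_tx and orf is not None:
        if v.is_snv:
            coding, aa_change, codon_change = _snv_cds_terms(
                v, t, orf, spliced, cds_tx[0]
            )
            terms |= coding
        else:
            net = v.length_change
            if net % 3 != 0:
                terms.add("frameshift_variant")
            elif net > 0:
                terms.add("inframe_insertion")
            elif net < 0:
                terms.add("inframe_deletion")
            else:
                terms.add("protein_altering_variant")
            initiator = range(orf.tx_start, orf.tx_start + 3)
            if v.is_insertion:
                # disruptive only when strictly inside the initiator codon
                if any(tx in initiator[1:] for tx in cds_tx):
                    terms.add("start_lost")
            elif any(tx in initiator for tx in cds_tx):
                terms.add("start_lost")

    if not terms:
        terms = {"intron_variant"}  # defensive; cannot normally happen
    return ConsequenceCall(
        v, t.transcript_id, source, frozenset(terms),
        gene_id=t.gene_id, gene_symbol=t.gene_symbol,
        aa_change=aa_change, codon_change=codon_change,
        orf_id=orf.orf_id if orf is not None else None,
        coding_probability=orf.coding_probability if orf is not None else None,
    )


ScoreLookup = Callable[[str, int, str, str], Optional[tuple[float, str]]]


def annotate_all(
    variants: Iterable[Variant],
    sources: dict[str, tuple[list[TranscriptModel], dict[str, list[OrfModel]]]],
    genome: GenomeRef,
    window: int = DEFAULT_WINDOW,
    score_lookup: Optional[ScoreLookup] = None,
) -> list[ConsequenceCall]:
    """Call consequences for every variant against every nearby transcript.

    ``sources`` maps a source label ("custom"/"reference") to its
    transcripts and per-transcript ORF lists; a transcript with k ORFs
    yields k calls, one with no ORF yields a single ORF-less call, and a
    variant near no transcript of a source yields one intergenic call for
    that source. Missense calls are scored through ``score_lookup``
    (protein_id, protein_pos, ref_aa, alt_aa) when provided.
    """
    calls: list[ConsequenceCall] = []
    for v in variants:
        for src in sorted(sources):
            transcripts, orf_map = sources[src]
            nearby = [
                t for t in transcripts
                if t.contig == v.contig
                and t.start - window <= v.pos0 < t.end + window
            ]
            if not nearby:
                calls.append(call_consequence(v, None, None, genome, source=src))
                continue
            for t in sorted(nearby, key=lambda t: t.transcript_id):
                t_orfs = orf_map.get(t.transcript_id, [])
                for orf in t_orfs or [None]:
                    call = call_consequence(v, t, orf, genome, src, window)
                    if call.is_missense and call.aa_change is not None:
                        hit = None
                        if score_lookup is not None and call.orf_id:
                            ref_aa, pos, alt_aa = call.aa_change
                            hit = score_lookup(call.orf_id, pos, ref_aa, alt_aa)
                        call.missense_score = hit if hit is not None else (
                            float("nan"), "unknown"
                        )
                    calls.append(call)
    calls.sort(
        key=lambda c: (
            c.variant.key(), c.source, c.transcript_id, c.orf_id or ""
        )
    )
    return calls


CSQ_FIELDS = [
    "Allele", "Consequence", "IMPACT", "Gene", "Transcript",
    "Protein_position", "Amino_acids", "CodingProbability", "Source",
]


def csq_entry(call: ConsequenceCall, impact: str) -> str:
    """One pipe-delimited CSQ entry for a call."""
    if call.aa_change:
        pos = str(call.aa_change[1])
        aas = f"{call.aa_change[0]}/{call.aa_change[2]}"
    else:
        pos = aas = ""
    cp = (
        f"{call.coding_probability:.3f}"
        if call.coding_probability is not None
        else ""
    )
    return "|".join(
        [
            call.variant.alt,
            "&".join(sorted(call.terms)),
            impact,
            call.gene_symbol or call.gene_id,
            call.transcript_id,
            pos,
            aas,
            cp,
            call.source,
        ]
    )
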