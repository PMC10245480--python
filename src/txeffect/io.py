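"""File I/O for the formats at the pipeline boundary.

FASTA, GTF and VCF are parsed with Biopython, gffutils and pysam
respectively; BED12/GTF/VCF output is emitted directly since the writers
only ever serialize objects this package built itself. GTF coordinates are
1-based inclusive, BED and internal coordinates 0-based half-open.
All readers accept gzip-compressed input.
"""

from __future__ import annotations

import gzip
import os
import tempfile
from typing import Iterable, Optional, TextIO

import gffutils
import pysam
from Bio import SeqIO

from .models import (
    GenomeRef,
    OrfModel,
    TranscriptModel,
    ValidationError,
    Variant,
    normalize_variant,
)


class ParseError(ValueError):
    pass


def _open_text(path: str) -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# FASTA


def read_genome(path: str) -> GenomeRef:
    """Read a (possibly gzipped) FASTA into memory, uppercasing sequences."""
    contigs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise ParseError(f"duplicate contig name {rec.id!r} in {path}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"contig {rec.id!r} in {path} has no sequence")
            contigs[rec.id] = seq
    if not contigs:
        raise ParseError(f"no FASTA records found in {path}")
    return GenomeRef(contigs)


def write_genome(genome: GenomeRef, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF


def read_gtf(
    path: str,
    source: str,
    reference_ids: Optional[set[str]] = None,
    novelty_attribute: Optional[str] = None,
) -> list[TranscriptModel]:
    """Read transcript models (exons + optional CDS) from a GTF file.

    Novelty of a custom transcript defaults to membership of its id in
    ``reference_ids``; a GTF attribute named ``novelty_attribute`` (value
    ``novel``/``known``), when present, takes precedence.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # sqlite/gffutils raise various types
        raise ParseError(f"cannot parse GTF {path}: {exc}") from exc

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for f in db.features_of_type(ftype):
            attrs = f.attributes
            if "transcript_id" not in attrs:
                raise ParseError(
                    f"{path}: {ftype} feature at {f.seqid}:{f.start} lacks transcript_id"
                )
            tid = attrs["transcript_id"][0]
            store.setdefault(tid, []).append((f.start - 1, f.end))
            info = meta.setdefault(
                tid, {"contig": f.seqid, "strand": f.strand, "gene_id": None,
                      "gene_symbol": None, "status": None}
            )
            if info["contig"] != f.seqid:
                raise ValidationError(f"{tid}: features on multiple contigs")
            if info["strand"] != f.strand:
                raise ValidationError(f"{tid}: features on multiple strands")
            if "gene_id" in attrs:
                info["gene_id"] = attrs["gene_id"][0]
            if "gene_name" in attrs:
                info["gene_symbol"] = attrs["gene_name"][0]
            if novelty_attribute and novelty_attribute in attrs:
                info["status"] = attrs[novelty_attribute][0]

    transcripts = []
    for tid in sorted(exons):
        info = meta[tid]
        if info["status"] in ("novel", "known"):
            novelty = info["status"]
        elif source == "custom" and reference_ids is not None:
            novelty = "known" if tid in reference_ids else "novel"
        else:
            novelty = "known"
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"] or tid,
                gene_symbol=info["gene_symbol"],
                contig=info["contig"],
                strand=info["strand"],
                exons=exons[tid],
                novelty=novelty,
                source=source,
                annotated_cds=sorted(cds[tid]) if tid in cds else None,
            )
        )
    return transcripts


def _gtf_attrs(t: TranscriptModel) -> str:
    parts = [f'gene_id "{t.gene_id}"', f'transcript_id "{t.transcript_id}"']
    if t.gene_symbol:
        parts.append(f'gene_name "{t.gene_symbol}"')
    return "; ".join(parts) + ";"


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str,
    orfs: Optional[dict[str, list[OrfModel]]] = None,
    feature_source: str = "txeffect",
) -> None:
    """Emit transcript/exon/CDS features, 1-based inclusive, with CDS phase.

    Each transcript's first listed ORF (if any) provides its CDS features;
    the CDS span includes the stop codon. Phase follows the GTF frame
    convention: number of bases to skip to reach the first complete codon.
    """
    orfs = orfs or {}
    with open(path, "w") as fh:
        for t in transcripts:
            row = [
                t.contig, feature_source, "transcript",
                str(t.start + 1), str(t.end), ".", t.strand, ".", _gtf_attrs(t),
            ]
            fh.write("\t".join(row) + "\n")
            for s, e in t.exons:
                fh.write(
                    "\t".join(
                        [t.contig, feature_source, "exon", str(s + 1), str(e),
                         ".", t.strand, ".", _gtf_attrs(t)]
                    ) + "\n"
                )
            for orf in orfs.get(t.transcript_id, [])[:1]:
                blocks = orf.cds_blocks
                ordered = blocks if t.strand == "+" else list(reversed(blocks))
                consumed = 0
                frames = {}
                for s, e in ordered:
                    frames[(s, e)] = (3 - consumed % 3) % 3
                    consumed += e - s
                for s, e in blocks:
                    fh.write(
                        "\t".join(
                            [t.contig, feature_source, "CDS", str(s + 1), str(e),
                             ".", t.strand, str(frames[(s, e)]), _gtf_attrs(t)]
                        ) + "\n"
                    )


# ---------------------------------------------------------------------------
# BED12


def format_bed12_entry(entry: dict) -> str:
    """Serialize one parsed BED12 entry dict back to its tab-separated line."""
    start = entry["start"]
    exons = entry["exons"]
    sizes = ",".join(str(e - s) for s, e in exons)
    starts = ",".join(str(s - start) for s, e in exons)
    return "\t".join(
        [
            entry["contig"], str(start), str(entry["end"]), entry["name"],
            "0", entry["strand"], str(entry["thick_start"]),
            str(entry["thick_end"]), "0", str(len(exons)),
            sizes + ",", starts + ",",
        ]
    )


def write_bed12(
    transcripts: Iterable[TranscriptModel],
    path: str,
    orfs: Optional[dict[str, list[OrfModel]]] = None,
) -> None:
    """One BED12 line per (transcript, ORF) pair, one per ORF-less transcript.

    thickStart/thickEnd carry the genomic CDS span; for ORF-less entries
    thickStart == thickEnd == chromStart.
    """
    orfs = orfs or {}
    with open(path, "w") as fh:
        for t in transcripts:
            t_orfs = orfs.get(t.transcript_id, [])
            entries = [(o.orf_id or t.transcript_id, o) for o in t_orfs] or [
                (t.transcript_id, None)
            ]
            for name, orf in entries:
                if orf is None:
                    thick_s = thick_e = t.start
                else:
                    thick_s = orf.cds_blocks[0][0]
                    thick_e = orf.cds_blocks[-1][1]
                fh.write(
                    format_bed12_entry(
                        {
                            "contig": t.contig, "start": t.start,
                            "end": t.end, "name": name, "strand": t.strand,
                            "thick_start": thick_s, "thick_end": thick_e,
                            "exons": t.exons,
                        }
                    ) + "\n"
                )


def read_bed12(path: str) -> list[dict]:
    """Parse BED12 lines into dicts with exon blocks and the thick span."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED columns")
            chrom_start = int(cols[1])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != int(cols[9]) or len(starts) != int(cols[9]):
                raise ParseError(f"{path}:{lineno}: blockCount mismatch")
            exons = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            out.append(
                {
                    "contig": cols[0],
                    "start": chrom_start,
                    "end": int(cols[2]),
                    "name": cols[3],
                    "strand": cols[5],
                    "thick_start": int(cols[6]),
                    "thick_end": int(cols[7]),
                    "exons": exons,
                }
            )
    return out


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str,
    genome: Optional[GenomeRef] = None,
    af_info_key: str = "AF",
) -> list[Variant]:
    """Read VCF 4.x records into normalized per-allele variants.

    Multi-allelic records are split; allele frequency is taken from the
    per-alt INFO key ``af_info_key`` when present; indels are left-
    normalized when a genome is supplied. A ref allele disagreeing with the
    genome flags (but keeps) the variant.
    """
    variants: list[Variant] = []
    save = pysam.set_verbosity(0)  # silence missing-contig-header warnings
    try:
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if rec.ref is None or not rec.alts:
                    continue
                afs = None
                if af_info_key in rec.info:
                    raw = rec.info[af_info_key]
                    afs = list(raw) if isinstance(raw, tuple) else [raw]
                for i, alt in enumerate(rec.alts):
                    if alt is None or set(alt.upper()) - set("ACGTN"):
                        continue  # symbolic/breakend alleles are out of scope
                    af = None
                    if afs is not None:
                        af = float(afs[i]) if i < len(afs) else float(afs[0])
                    v = Variant(
                        contig=rec.contig,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        variant_id=rec.id,
                        allele_frequency=af,
                    )
                    variants.append(normalize_variant(v, genome))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    finally:
        pysam.set_verbosity(save)
    return variants


def write_vcf_header(
    fh: TextIO,
    genome: Optional[GenomeRef] = None,
    csq_fields: Optional[list[str]] = None,
    extra_info: Optional[list[str]] = None,
) -> None:
    fh.write("##fileformat=VCFv4.2\n")
    fh.write("##source=txeffect\n")
    if genome is not None:
        for name, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
    fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
    if csq_fields:
        fh.write(
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
            f'annotations. Format: {"|".join(csq_fields)}">\n'
        )
    for line in extra_info or []:
        fh.write(line + "\n")
    fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")


def format_vcf_record(v: Variant, info: str = ".") -> str:
    parts = []
    if v.allele_frequency is not None:
        parts.append(f"AF={v.allele_frequency:g}")
    if info not in (".", ""):
        parts.append(info)
    return "\t".join(
        [
            v.contig, str(v.pos), v.variant_id or ".", v.ref, v.alt,
            ".", ".", ";".join(parts) if parts else ".",
        ]
    )
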