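"""End-to-end reannotation pipeline.

Stages: validate inputs → predict ORFs on novel custom transcripts →
call consequences against both the custom and the reference transcript
sets → compare best severities per variant → apply the candidate filter
cascade → write the annotated VCF, the severity comparison table, and the
increasing-severity candidate subset.
"""

from __future__ import annotations

import logging
import os
import sys
import time
from dataclasses import dataclass, field
from typing import Optional

from . import io as txio
from .consequence import CSQ_FIELDS, annotate_all, csq_entry
from .filters import FilterConfig, filter_candidates
from .models import GenomeRef, OrfModel, TranscriptModel, orf_from_annotated_cds
from .orf import CodingPotentialModel, DEFAULT_CODING_CUTOFF, predict_orfs
from .severity import (
    DAMAGING_MISSENSE,
    IMPACT_NAMES,
    MODERATE,
    MissensePredictorAdapter,
    ReannotationRecord,
    SeverityScheme,
    compare,
    level_name,
)

log = logging.getLogger("txeffect")


@dataclass
class PipelineResult:
    records: list[ReannotationRecord]
    candidates: list[ReannotationRecord]
    counts: dict[str, int] = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)


def _aa_change_str(call) -> str:
    if call is None or call.aa_change is None:
        return ""
    ref_aa, pos, alt_aa = call.aa_change
    return f"{ref_aa}{pos}{alt_aa}"


def _prediction_str(call) -> str:
    if call is None or call.missense_score is None:
        return ""
    return call.missense_score[1]


def attach_known_cds(
    custom_transcripts: list[TranscriptModel],
    reference_transcripts: list[TranscriptModel],
    genome: GenomeRef,
) -> dict[str, list[OrfModel]]:
    """CDS for known custom transcripts, borrowed from the reference GTF.

    Assembler GTFs typically carry no CDS features; for transcripts the
    assembler matched to a reference model the reference CDS applies
    whenever it fits inside the custom exon structure.
    """
    by_id = {t.transcript_id: t for t in reference_transcripts}
    orfs: dict[str, list[OrfModel]] = {}
    for t in custom_transcripts:
        if t.novelty != "known":
            continue
        cds = t.annotated_cds
        if cds is None and t.transcript_id in by_id:
            cds = by_id[t.transcript_id].annotated_cds
        if cds is None:
            continue
        probe = TranscriptModel(
            transcript_id=t.transcript_id, gene_id=t.gene_id,
            gene_symbol=t.gene_symbol, contig=t.contig, strand=t.strand,
            exons=list(t.exons), novelty=t.novelty, source=t.source,
            annotated_cds=cds,
        )
        try:
            orf = orf_from_annotated_cds(probe, genome)
        except Exception:
            log.warning(
                "reference CDS does not fit custom transcript %s; treated "
                "as non-coding", t.transcript_id,
            )
            continue
        if orf is not None:
            orfs[t.transcript_id] = [orf]
    return orfs


def run_pipeline(
    genome_path: str,
    custom_gtf: str,
    reference_gtf: str,
    vcf_path: str,
    out_dir: str,
    scorer_path: Optional[str] = None,
    scores_tsv: Optional[str] = None,
    af_threshold: float = 0.01,
    coding_cutoff: Optional[float] = None,
    unknown_missense: str = "damaging",
    benign_in_both: bool = False,
    min_orf_len: int = 75,
    window: int = 5000,
    af_info_key: str = "AF",
    novelty_attribute: Optional[str] = None,
) -> PipelineResult:
    t0 = time.time()
    counts: dict[str, int] = {}

    genome = txio.read_genome(genome_path)
    ref_tx = txio.read_gtf(reference_gtf, "reference")
    ref_ids = {t.transcript_id for t in ref_tx}
    custom_tx = txio.read_gtf(
        custom_gtf, "custom", reference_ids=ref_ids,
        novelty_attribute=novelty_attribute,
    )
    variants = txio.read_vcf(vcf_path, genome=genome, af_info_key=af_info_key)
    counts["reference_transcripts"] = len(ref_tx)
    counts["custom_transcripts"] = len(custom_tx)
    counts["novel_transcripts"] = sum(t.novelty == "novel" for t in custom_tx)
    counts["variants"] = len(variants)
    n_mismatch = sum(v.ref_mismatch for v in variants)
    if n_mismatch:
        log.warning("%d variant(s) disagree with the genome ref allele", n_mismatch)
    log.info(
        "inputs: %d reference / %d custom transcripts (%d novel), %d variants",
        len(ref_tx), len(custom_tx), counts["novel_transcripts"], len(variants),
    )

    if scorer_path is not None:
        model = CodingPotentialModel.from_json(scorer_path)
    else:
        log.warning(
            "no coding-potential scorer given; every candidate ORF scores "
            "0.5 and passes the default cutoff"
        )
        model = CodingPotentialModel()
    if coding_cutoff is not None:
        model.probability_cutoff = coding_cutoff

    novel = [t for t in custom_tx if t.novelty == "novel"]
    custom_orfs = predict_orfs(novel, genome, model, min_len_nt=min_orf_len)
    custom_orfs.update(attach_known_cds(custom_tx, ref_tx, genome))
    ref_orfs: dict[str, list[OrfModel]] = {}
    for t in ref_tx:
        orf = orf_from_annotated_cds(t, genome)
        if orf is not None:
            ref_orfs[t.transcript_id] = [orf]
    counts["novel_orfs"] = sum(
        len(v) for tid, v in custom_orfs.items() if tid not in ref_ids
    )
    log.info("predicted %d novel ORF(s)", counts["novel_orfs"])

    adapter = (
        MissensePredictorAdapter.from_tsv(scores_tsv)
        if scores_tsv is not None
        else MissensePredictorAdapter()
    )
    calls = annotate_all(
        variants,
        {
            "custom": (custom_tx, custom_orfs),
            "reference": (ref_tx, ref_orfs),
        },
        genome,
        window=window,
        score_lookup=adapter.lookup,
    )
    counts["consequence_calls"] = len(calls)

    scheme = SeverityScheme(
        unknown_missense_level=(
            DAMAGING_MISSENSE if unknown_missense == "damaging" else MODERATE
        )
    )
    records = compare(variants, calls, scheme)
    counts["increased_severity"] = sum(r.increased for r in records)
    cfg = FilterConfig(
        af_threshold=af_threshold, drop_benign_in_both=benign_in_both
    )
    candidates, removed = filter_candidates(records, cfg)
    counts["candidates"] = len(candidates)
    for r in removed:
        for flag in r.filter_flags:
            counts[f"removed_{flag}"] = counts.get(f"removed_{flag}", 0) + 1
    log.info(
        "%d/%d variants increase in severity; %d candidate(s) after filters",
        counts["increased_severity"], len(records), len(candidates),
    )

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "annotated_vcf": os.path.join(out_dir, "annotated.vcf"),
        "comparison_tsv": os.path.join(out_dir, "comparison.tsv"),
        "candidates_tsv": os.path.join(out_dir, "candidates.tsv"),
        "candidates_vcf": os.path.join(out_dir, "candidates.vcf"),
    }
    _write_annotated_vcf(paths["annotated_vcf"], variants, calls, scheme, genome)
    write_comparison_tsv(paths["comparison_tsv"], records)
    write_comparison_tsv(paths["candidates_tsv"], candidates)
    candidate_keys = {r.variant.key() for r in candidates}
    with open(paths["candidates_vcf"], "w") as fh:
        txio.write_vcf_header(fh, genome)
        for v in variants:
            if v.key() in candidate_keys:
                fh.write(txio.format_vcf_record(v) + "\n")

    log.info("pipeline finished in %.2f s", time.time() - t0)
    return PipelineResult(
        records=records, candidates=candidates, counts=counts, paths=paths
    )


def _write_annotated_vcf(path, variants, calls, scheme, genome) -> None:
    by_variant: dict[tuple, list] = {}
    for c in calls:
        by_variant.setdefault(c.variant.key(), []).append(c)
    with open(path, "w") as fh:
        txio.write_vcf_header(fh, genome, csq_fields=CSQ_FIELDS)
        for v in variants:
            entries = [
                csq_entry(c, IMPACT_NAMES[scheme.severity_of(c)])
                for c in by_variant.get(v.key(), [])
            ]
            info = f"CSQ={','.join(entries)}" if entries else "."
            fh.write(txio.format_vcf_record(v, info=info) + "\n")


COMPARISON_COLUMNS = [
    "variant_id", "contig", "pos", "ref", "alt", "allele_frequency", "gene",
    "ref_transcript", "ref_consequence", "ref_level", "custom_transcript",
    "custom_consequence", "custom_level", "increased",
    "ref_missense_change", "ref_missense_prediction",
    "custom_missense_change", "custom_missense_prediction",
    "coding_probability", "filter_flags", "candidate",
]


def write_comparison_tsv(path: str, records: list[ReannotationRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COMPARISON_COLUMNS) + "\n")
        for r in records:
            v = r.variant
            ref_level, ref_call = r.ref_best
            cus_level, cus_call = r.custom_best
            cp = (
                f"{cus_call.coding_probability:.4f}"
                if cus_call.coding_probability is not None
                else ""
            )
            row = [
                v.variant_id or "", v.contig, str(v.pos), v.ref, v.alt,
                f"{v.allele_frequency:g}" if v.allele_frequency is not None else "",
                cus_call.gene_symbol or cus_call.gene_id or ref_call.gene_id,
                ref_call.transcript_id, "&".join(sorted(ref_call.terms)),
                level_name(ref_level),
                cus_call.transcript_id, "&".join(sorted(cus_call.terms)),
                level_name(cus_level),
                str(r.increased).lower(),
                _aa_change_str(r.ref_best_missense),
                _prediction_str(r.ref_best_missense),
                _aa_change_str(r.custom_best_missense),
                _prediction_str(r.custom_best_missense),
                cp,
                ",".join(sorted(r.filter_flags)),
                str(r.candidate).lower(),
            ]
            fh.write("\t".join(row) + "\n")
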