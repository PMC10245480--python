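"""Self-contained synthetic input bundles for the full pipeline.

Each enabled scenario plants, once per strand, a small gene whose custom
(novel) transcript changes the predicted severity of one variant relative
to the reference transcript — the situations a sample-specific
transcriptome is meant to surface: an ORF reading into a retained intron
hit by a stop-gain, a novel upstream start codon destroyed by an SNV or an
in-frame deletion, missense calls landing in different proteoforms, and
the filter-cascade exclusions (identical substitution in both annotations,
common allele). The manifest records, by construction, the expected terms,
levels and candidate status of every planted variant, making the bundle
its own oracle.

Sequence construction keeps scoring deterministic: planted coding regions
are built from a fixed "preferred" codon alphabet favoured by the bundled
hexamer scorer, and all filler sequence is scrubbed of ATG (and of CAT,
its reverse-strand image) so no spurious reading frames arise.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import numpy as np

from .io import write_genome, write_gtf
from .models import GenomeRef, TranscriptModel, reverse_complement
from .orf import CodingPotentialModel

#: codons used for planted coding sequence: no stop, no ATG, and no codon
#: junction can spell ATG (none ends in T/AT, none starts with TG)
PREFERRED_CODONS = ["GCC", "GAG", "CTG", "AAG", "GAC", "TTC", "ATC", "CAG"]

SCENARIOS = [
    "retained_intron_stop_gain",
    "novel_start_loss",
    "benign_to_unknown_missense",
    "same_substitution_pair",
    "common_missense",
    "inframe_del_start_loss",
]

_CONDITIONS = {
    "retained_intron_stop_gain": "Immunodeficiency, synthetic retained-intron scenario",
    "novel_start_loss": "Immunodeficiency, synthetic start-loss scenario",
    "benign_to_unknown_missense": "Retinal dystrophy, synthetic proteoform scenario",
    "same_substitution_pair": "Combined immunodeficiency, synthetic shared-substitution scenario",
    "common_missense": "Cardiomyopathy, synthetic common-allele scenario",
    "inframe_del_start_loss": "Autoimmune lymphoproliferative syndrome, synthetic deletion scenario",
}

_STRIDE = 7000  # keeps neighbouring genes outside each other's 5 kb window
_MARGIN = 500


@dataclass
class FixtureSpec:
    seed: int = 1
    n_genes: int = 2  # decoy gene pairs in addition to the scenarios
    scenarios: dict[str, bool] = field(
        default_factory=lambda: {name: True for name in SCENARIOS}
    )
    contig_length: int = 100_000
    contig_name: str = "chrS"


def toy_scorer() -> CodingPotentialModel:
    """The bundle's deterministic coding-potential model.

    Hexamers made of two preferred codons score +1, everything else 0
    (absent), so planted ORFs sit near logistic(-2 + 8·1) ≈ 0.998 and
    random sequence near logistic(-2) ≈ 0.12, well apart from the 0.364
    cutoff on both sides.
    """
    table = {a + b: 1.0 for a, b in product(PREFERRED_CODONS, PREFERRED_CODONS)}
    return CodingPotentialModel(
        hexamer_table=table, coefficients=(-2.0, 0.0, 0.0, 0.0, 8.0)
    )


def _codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(PREFERRED_CODONS), size=n)
    return "".join(PREFERRED_CODONS[i] for i in idx)


# ---------------------------------------------------------------------------
# Scenario builders (local, + strand coordinates)
#
# Each returns a dict with: length, placements [(start, seq)], ref/custom
# transcript shapes, the planted variant, score-table rows for the
# reference protein, and the expected outcome.


def _retained_intron_stop_gain(rng) -> dict:
    cds = "ATG" + _codons(rng, 164) + "TAA"  # 498 nt spliced reference CDS
    intron_plant = "CC" + _codons(rng, 33) + "AAA" + "AAG" + "GAC" + "TAA"
    return {
        "length": 1000,
        "placements": [(150, cds[:250]), (600, cds[250:]), (400, intron_plant)],
        "ref": {"exons": [(100, 400), (600, 900)], "cds": [(150, 400), (600, 848)]},
        "custom": {"exons": [(100, 900)]},
        "variant": {"kind": "snv", "pos": 501, "alt": "T"},
        "score_rows": [],
        "expected": {
            "ref_terms": ["intron_variant"],
            "custom_terms": ["stop_gained"],
            "ref_level": 1,
            "custom_level": 4,
            "candidate": True,
        },
    }


def _novel_start_loss(rng) -> dict:
    orf = "ATG" + _codons(rng, 40) + "TAA"  # novel upstream ORF, 126 nt
    ref_cds = "ATG" + _codons(rng, 40) + "TAA"
    return {
        "length": 900,
        "placements": [(160, orf), (560, ref_cds)],
        "ref": {"exons": [(100, 350), (500, 800)], "cds": [(560, 686)]},
        "custom": {"exons": [(100, 350)]},
        "variant": {"kind": "snv", "pos": 161, "alt": "C"},  # ATG -> ACG, M>T
        "score_rows": [],
        "expected": {
            "ref_terms": ["5_prime_UTR_variant"],
            "custom_terms": ["start_lost"],
            "ref_level": 0,
            "custom_level": 4,
            "candidate": True,
        },
    }


def _benign_to_unknown_missense(rng) -> dict:
    # Reference CDS [210,471): frame 210+3k. A "GAA"-repeat segment is
    # readable without stops in every frame; the custom transcript splices
    # out the reference start codon and uses its own ATG one frame off, so
    # the same SNV is E>G (pos 41) on the reference protein but K>E
    # (pos 12) on the novel proteoform.
    plant = (
        "GCC"            # [206,209) junction guard
        + "C"            # [209,210) spliced out by the custom intron
        + "ATG"          # [210,213) reference start
        + _codons(rng, 27)  # [213,294)
        + "GACGAT"       # [294,300); the T+G at 299|300 is the custom ATG's tail
        + "GAA" * 30     # [300,390) dual-frame-safe segment
        + "G"            # [390,391) completes the last custom AAG codon
        + "TAA"          # [391,394) custom-frame stop
        + "GC"           # [394,396) completes reference codon AGC
        + _codons(rng, 24)  # [396,468)
        + "TAA"          # [468,471) reference stop
    )
    assert len(plant) == 265
    return {
        "length": 700,
        "placements": [(206, plant)],
        "ref": {"exons": [(100, 600)], "cds": [(210, 471)]},
        "custom": {"exons": [(80, 209), (212, 600)]},
        "variant": {"kind": "snv", "pos": 331, "alt": "G"},
        "score_rows": [(41, "E", "G", 0.05, "benign")],
        "expected": {
            "ref_terms": ["missense_variant"],
            "custom_terms": ["missense_variant"],
            "ref_level": 2,
            "custom_level": 3,
            "candidate": True,
        },
    }


def _same_substitution_pair(rng) -> dict:
    cds = "ATG" + _codons(rng, 18) + "AAA" + _codons(rng, 62) + "TAA"  # 249 nt
    return {
        "length": 660,
        "placements": [(150, cds)],
        "ref": {"exons": [(100, 500)], "cds": [(150, 399)]},
        "custom": {"exons": [(100, 560)]},  # 3'-extended novel isoform
        "variant": {"kind": "snv", "pos": 207, "alt": "G"},  # K20E in both
        "score_rows": [(20, "K", "E", 0.03, "benign")],
        "expected": {
            "ref_terms": ["missense_variant"],
            "custom_terms": ["missense_variant"],
            "ref_level": 2,
            "custom_level": 3,
            "candidate": False,
        },
    }


def _common_missense(rng) -> dict:
    orf = "ATG" + _codons(rng, 9) + "AAA" + _codons(rng, 30) + "TAA"  # 126 nt
    ref_cds = "ATG" + _codons(rng, 40) + "TAA"
    return {
        "length": 800,
        "placements": [(150, orf), (460, ref_cds)],
        "ref": {"exons": [(100, 300), (400, 700)], "cds": [(460, 586)]},
        "custom": {"exons": [(100, 300)]},
        "variant": {"kind": "snv", "pos": 180, "alt": "G", "af": 0.05},
        "score_rows": [],
        "expected": {
            "ref_terms": ["5_prime_UTR_variant"],
            "custom_terms": ["missense_variant"],
            "ref_level": 0,
            "custom_level": 3,
            "candidate": False,
        },
    }


def _inframe_del_start_loss(rng) -> dict:
    # A 3 bp deletion removes the novel proteoform's initiator ATG, which
    # sits in-frame inside the reference CDS as an ordinary internal Met.
    cds = (
        "ATG" + _codons(rng, 15) + "GCC"  # codon 16 ends in C: stable anchor
        + "ATG"                           # [201,204) custom initiator
        + "GCC"                           # starts with G: stable under mirroring
        + _codons(rng, 89) + "TAA"
    )
    assert len(cds) == 327
    return {
        "length": 700,
        "placements": [(150, cds)],
        "ref": {"exons": [(100, 600)], "cds": [(150, 477)]},
        "custom": {"exons": [(130, 600)]},
        "variant": {"kind": "del", "anchor": 200, "del_len": 3},
        "score_rows": [],
        "expected": {
            "ref_terms": ["inframe_deletion"],
            "custom_terms": ["inframe_deletion", "start_lost"],
            "ref_level": 2,
            "custom_level": 4,
            "candidate": True,
        },
    }


_BUILDERS = {
    "retained_intron_stop_gain": _retained_intron_stop_gain,
    "novel_start_loss": _novel_start_loss,
    "benign_to_unknown_missense": _benign_to_unknown_missense,
    "same_substitution_pair": _same_substitution_pair,
    "common_missense": _common_missense,
    "inframe_del_start_loss": _inframe_del_start_loss,
}


# ---------------------------------------------------------------------------
# Assembly helpers


def _scrub(seq: list[str], protected: np.ndarray) -> None:
    """Remove every ATG/CAT whose bases are not all protected.

    The replacement base is chosen so that no new ATG/CAT appears in the
    5-base window around the edit; such a base always exists.
    """
    s = "".join(seq)
    for _ in range(60):
        dirty = False
        for pat in ("ATG", "CAT"):
            start = 0
            while True:
                i = s.find(pat, start)
                if i < 0:
                    break
                start = i + 1
                if protected[i : i + 3].all():
                    continue
                js = [j for j in range(i, i + 3) if not protected[j]]
                j = js[len(js) // 2]
                for cand in "CGTA":
                    if cand == s[j]:
                        continue
                    window = list(s[max(0, j - 2) : j + 3])
                    window[j - max(0, j - 2)] = cand
                    w = "".join(window)
                    if "ATG" not in w and "CAT" not in w:
                        seq[j] = cand
                        s = s[:j] + cand + s[j + 1 :]
                        dirty = True
                        break
                else:  # pragma: no cover - proven impossible
                    raise RuntimeError("no safe scrub replacement")
        if not dirty:
            return
    raise RuntimeError("scrub did not converge")  # pragma: no cover


def _mirror_interval(iv: tuple[int, int], length: int) -> tuple[int, int]:
    s, e = iv
    return length - e, length - s


@dataclass
class _Instance:
    scenario: str
    strand: str
    offset: int
    spec: dict
    suffix: str


def _place_instance(
    inst: _Instance, seq: list[str], protected: np.ndarray
) -> dict:
    """Paste one scenario instance into the contig; return global geometry."""
    L = inst.spec["length"]
    off = inst.offset
    if inst.strand == "+":
        for start, frag in inst.spec["placements"]:
            for k, base in enumerate(frag):
                seq[off + start + k] = base
            protected[off + start : off + start + len(frag)] = True
        tx = lambda iv: (off + iv[0], off + iv[1])
    else:
        for start, frag in inst.spec["placements"]:
            rc = reverse_complement(frag)
            gs, ge = _mirror_interval((start, start + len(frag)), L)
            for k, base in enumerate(rc):
                seq[off + gs + k] = base
            protected[off + gs : off + ge] = True
        tx = lambda iv: tuple(off + c for c in _mirror_interval(iv, L))

    def exons(ivs):
        return sorted(tx(iv) for iv in ivs)

    geom = {
        "ref_exons": exons(inst.spec["ref"]["exons"]),
        "ref_cds": exons(inst.spec["ref"]["cds"]) if inst.spec["ref"].get("cds") else None,
        "custom_exons": exons(inst.spec["custom"]["exons"]),
    }
    v = inst.spec["variant"]
    if v["kind"] == "snv":
        if inst.strand == "+":
            geom["variant"] = ("snv", off + v["pos"], v["alt"])
        else:
            geom["variant"] = (
                "snv", off + L - 1 - v["pos"], reverse_complement(v["alt"]),
            )
    else:
        local_del = (v["anchor"] + 1, v["anchor"] + 1 + v["del_len"])
        if inst.strand == "+":
            ds, de = (off + local_del[0], off + local_del[1])
        else:
            ds, de = tuple(off + c for c in _mirror_interval(local_del, L))
        geom["variant"] = ("del", ds, de)
    geom["af"] = v.get("af")
    return geom


def generate(spec: FixtureSpec, out_dir: str) -> dict:
    """Generate the bundle (FASTA, GTF ×2, VCF, scores TSV, scorer JSON,
    manifest JSON) under ``out_dir`` and return the manifest."""
    rng = np.random.default_rng(spec.seed)
    enabled = [s for s in SCENARIOS if spec.scenarios.get(s, False)]
    instances: list[_Instance] = []
    offset = _MARGIN
    for name in enabled:
        for strand, tag in (("+", "fwd"), ("-", "rev")):
            instances.append(
                _Instance(name, strand, offset, _BUILDERS[name](rng), f"{name}_{tag}")
            )
            offset += _STRIDE
    n_decoys = spec.n_genes
    decoy_offsets = []
    for i in range(n_decoys):
        decoy_offsets.append(offset)
        offset += _STRIDE
    if offset + _MARGIN > spec.contig_length:
        raise ValueError(
            f"layout needs {offset + _MARGIN} bp but contig_length is "
            f"{spec.contig_length}; disable scenarios or enlarge the contig"
        )

    seq = list("".join(np.random.default_rng(spec.seed + 1).choice(
        list("ACGT"), size=spec.contig_length
    )))
    protected = np.zeros(spec.contig_length, dtype=bool)

    geoms = [_place_instance(inst, seq, protected) for inst in instances]
    _scrub(seq, protected)
    contig = "".join(seq)
    genome = GenomeRef({spec.contig_name: contig})

    ref_transcripts: list[TranscriptModel] = []
    custom_transcripts: list[TranscriptModel] = []
    variants_out = []
    score_rows = []
    manifest_entries = []

    for inst, geom in zip(instances, geoms):
        ref_tid = f"REFT_{inst.suffix}"
        custom_tid = f"NOVELT_{inst.suffix}"
        gene = f"GENE_{inst.suffix}"
        ref_transcripts.append(
            TranscriptModel(
                transcript_id=ref_tid, gene_id=gene, gene_symbol=gene,
                contig=spec.contig_name, strand=inst.strand,
                exons=geom["ref_exons"], annotated_cds=geom["ref_cds"],
            )
        )
        custom_transcripts.append(
            TranscriptModel(
                transcript_id=custom_tid, gene_id=gene, gene_symbol=gene,
                contig=spec.contig_name, strand=inst.strand,
                exons=geom["custom_exons"], novelty="novel", source="custom",
            )
        )
        v = geom["variant"]
        if v[0] == "snv":
            pos0, alt = v[1], v[2]
            ref_allele = contig[pos0]
            assert ref_allele != alt
        else:
            ds, de = v[1], v[2]
            pos0 = ds - 1
            ref_allele = contig[pos0:de]
            alt = contig[pos0]
        var_id = f"var_{inst.suffix}"
        variants_out.append(
            {"id": var_id, "pos0": pos0, "ref": ref_allele, "alt": alt,
             "af": geom["af"]}
        )
        for p_pos, ref_aa, alt_aa, score, pred in inst.spec["score_rows"]:
            score_rows.append(
                (f"{ref_tid}.orf0", p_pos, ref_aa, alt_aa, "polyphen2", score, pred)
            )
        exp = inst.spec["expected"]
        manifest_entries.append(
            {
                "scenario": inst.scenario,
                "strand": inst.strand,
                "variant_id": var_id,
                "contig": spec.contig_name,
                "pos": pos0 + 1,
                "ref": ref_allele,
                "alt": alt,
                "allele_frequency": geom["af"],
                "expected_ref_terms": sorted(exp["ref_terms"]),
                "expected_custom_terms": sorted(exp["custom_terms"]),
                "expected_ref_level": exp["ref_level"],
                "expected_custom_level": exp["custom_level"],
                "expected_candidate": exp["candidate"],
                "condition": _CONDITIONS[inst.scenario],
            }
        )

    for i, off in enumerate(decoy_offsets):
        gene = f"GENE_decoy{i}"
        ref_transcripts.append(
            TranscriptModel(
                transcript_id=f"REFT_decoy{i}", gene_id=gene, gene_symbol=gene,
                contig=spec.contig_name, strand="+" if i % 2 == 0 else "-",
                exons=[(off + 100, off + 400), (off + 700, off + 1000)],
            )
        )
        custom_transcripts.append(
            TranscriptModel(
                transcript_id=f"NOVELT_decoy{i}", gene_id=gene, gene_symbol=gene,
                contig=spec.contig_name, strand="+" if i % 2 == 0 else "-",
                exons=[(off + 100, off + 1000)], novelty="novel", source="custom",
            )
        )

    ref_transcripts.sort(key=lambda t: (t.start, t.transcript_id))
    # the custom annotation carries both the known transcripts (same ids as
    # the reference, no CDS — assembler style) and the novel ones
    custom_all = sorted(
        custom_transcripts + [
            TranscriptModel(
                transcript_id=t.transcript_id, gene_id=t.gene_id,
                gene_symbol=t.gene_symbol, contig=t.contig, strand=t.strand,
                exons=list(t.exons), source="custom",
            )
            for t in ref_transcripts
        ],
        key=lambda t: (t.start, t.transcript_id),
    )

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "reference_gtf": os.path.join(out_dir, "reference.gtf"),
        "custom_gtf": os.path.join(out_dir, "custom.gtf"),
        "vcf": os.path.join(out_dir, "variants.vcf"),
        "scores": os.path.join(out_dir, "missense_scores.tsv"),
        "scorer": os.path.join(out_dir, "scorer.json"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    write_genome(genome, paths["genome"])
    # reference GTF carries CDS; write per-transcript ORF models for that
    from .models import orf_from_annotated_cds

    ref_orfs = {}
    for t in ref_transcripts:
        orf = orf_from_annotated_cds(t, genome)
        if orf is not None:
            ref_orfs[t.transcript_id] = [orf]
    write_gtf(ref_transcripts, paths["reference_gtf"], orfs=ref_orfs)
    write_gtf(custom_all, paths["custom_gtf"])

    variants_out.sort(key=lambda v: v["pos0"])
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={spec.contig_name},length={spec.contig_length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants_out:
            info = f"AF={v['af']:g}" if v["af"] is not None else "."
            fh.write(
                f"{spec.contig_name}\t{v['pos0'] + 1}\t{v['id']}\t{v['ref']}\t"
                f"{v['alt']}\t.\t.\t{info}\n"
            )

    with open(paths["scores"], "w") as fh:
        fh.write("protein_id\tprotein_pos\tref_aa\talt_aa\ttool\tscore\tprediction\n")
        for row in score_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    toy_scorer().to_json(paths["scorer"])

    manifest = {
        "seed": spec.seed,
        "contig": spec.contig_name,
        "contig_length": spec.contig_length,
        "paths": {k: os.path.basename(p) for k, p in paths.items()},
        "variants": manifest_entries,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
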