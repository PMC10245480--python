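"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from txeffect.models import GenomeRef, OrfModel, TranscriptModel, reverse_complement
from txeffect.orf import translate
from txeffect.simulate import FixtureSpec, generate

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
NON_STOP_CODONS = [
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOPS
]


def random_coding_transcript(rng: np.random.Generator, strand: str):
    """A random multi-exon transcript whose CDS spans a planted full ORF.

    Returns (genome, transcript, orf). The spliced sequence is
    5'UTR + ATG + body + TAA + 3'UTR distributed over 1–4 exons.
    """
    n_body = int(rng.integers(6, 40))
    cds = "ATG" + "".join(
        NON_STOP_CODONS[i] for i in rng.integers(0, len(NON_STOP_CODONS), n_body)
    ) + "TAA"
    utr5 = "".join(BASES[i] for i in rng.integers(0, 4, int(rng.integers(0, 30))))
    utr3 = "".join(BASES[i] for i in rng.integers(0, 4, int(rng.integers(0, 30))))
    spliced = utr5 + cds + utr3

    n_exons = int(rng.integers(1, 5))
    cuts = sorted(rng.choice(np.arange(1, len(spliced)), size=n_exons - 1,
                             replace=False).tolist()) if n_exons > 1 else []
    bounds = [0] + cuts + [len(spliced)]
    pieces = [spliced[a:b] for a, b in zip(bounds, bounds[1:])]
    if strand == "-":
        pieces = [reverse_complement(p) for p in reversed(pieces)]

    flank = 20
    parts, exons, cursor = [], [], 0
    for i, piece in enumerate(pieces):
        gap = "".join(BASES[j] for j in rng.integers(0, 4, int(rng.integers(20, 60))))
        parts.append(gap)
        cursor += len(gap)
        exons.append((cursor, cursor + len(piece)))
        parts.append(piece)
        cursor += len(piece)
    parts.append("".join(BASES[j] for j in rng.integers(0, 4, flank)))
    genome = GenomeRef({"chrR": "".join(parts)})
    t = TranscriptModel(
        transcript_id="t_rand", gene_id="g_rand", contig="chrR",
        strand=strand, exons=exons,
    )
    assert t.spliced_sequence(genome) == spliced
    tx_start = len(utr5)
    orf = OrfModel(
        transcript_id="t_rand", tx_start=tx_start, tx_end=tx_start + len(cds),
        coding_probability=1.0, protein=translate(cds[:-3]), has_stop=True,
        cds_blocks=t.tx_span_to_blocks(tx_start, tx_start + len(cds)),
        orf_id="t_rand.orf0",
    )
    return genome, t, orf


def oracle_coding_effect(genome, t, orf, pos0: int, alt: str) -> str:
    """Whole-protein mutate-and-translate oracle for a CDS SNV.

    Classifies by diffing Biopython translations of the reference and
    mutated spliced CDS: no_change | start_lost | stop_gained | stop_lost
    | missense. Independent of the engine's codon-local logic.
    """
    spliced = t.spliced_sequence(genome)
    tx = t.genome_to_tx(pos0)
    alt_tx = reverse_complement(alt) if t.strand == "-" else alt
    mutated = spliced[:tx] + alt_tx + spliced[tx + 1 :]
    ref_cds = spliced[orf.tx_start : orf.tx_end]
    alt_cds = mutated[orf.tx_start : orf.tx_end]
    ref_p = str(Seq(ref_cds).translate())
    alt_p = str(Seq(alt_cds).translate())
    if alt_p == ref_p:
        return "no_change"
    if alt_p[0] != "M" and ref_p[0] == "M":
        return "start_lost"
    if "*" in alt_p[:-1]:
        return "stop_gained"
    if ref_p[-1] == "*" and alt_p[-1] != "*":
        return "stop_lost"
    diffs = [i for i, (a, b) in enumerate(zip(ref_p, alt_p)) if a != b]
    assert len(diffs) == 1
    return "missense"


ENGINE_TO_ORACLE = {
    "synonymous_variant": "no_change",
    "stop_retained_variant": "no_change",
    "start_lost": "start_lost",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "missense_variant": "missense",
}


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Seed-1 synthetic input bundle plus its manifest."""
    d = tmp_path_factory.mktemp("bundle")
    manifest = generate(FixtureSpec(seed=1), str(d))
    return {"dir": str(d), "manifest": manifest}
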