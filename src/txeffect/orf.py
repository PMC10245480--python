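"""ORF enumeration, coding-potential scoring, and translation.

Candidate ORFs are ATG→stop spans on the already-oriented (5'→3') spliced
transcript sequence; all three forward frames are scanned and every
distinct start sharing a stop is kept as its own candidate. Coding
potential is a logistic model over four sequence features — ORF length,
ORF coverage of the transcript, the Fickett TESTCODE statistic, and an
in-frame hexamer usage score — thresholded at a configurable probability
cutoff (default 0.364, the conventional human cutoff).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .models import GenomeRef, OrfModel, TranscriptModel, ValidationError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(seq: str) -> str:
    """Translate a codon-multiple nucleotide string with the standard code.

    Codons containing N translate to 'X'; a single terminal stop codon is
    dropped; an internal stop raises (it violates the ORF invariant).
    """
    if len(seq) % 3 != 0:
        raise ValidationError(f"sequence length {len(seq)} not a multiple of 3")
    aas = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = "X" if "N" in codon else CODON_TABLE[codon]
        aas.append(aa)
    if aas and aas[-1] == "*":
        aas.pop()
    protein = "".join(aas)
    if "*" in protein:
        raise ValidationError(f"internal stop codon at aa {protein.index('*') + 1}")
    return protein


@dataclass(frozen=True)
class OrfCandidate:
    """An ATG→stop (or ATG→end) span in one forward frame of a sequence."""

    frame: int
    tx_start: int
    tx_end: int
    complete: bool


def enumerate_orfs(
    seq: str,
    min_len_nt: int = 75,
    allow_incomplete_3prime: bool = False,
    start_codons: Sequence[str] = (START_CODON,),
) -> list[OrfCandidate]:
    """All maximal start→stop spans in the three forward frames.

    Every start codon yields its own candidate (nested starts sharing a
    stop are all reported). With ``allow_incomplete_3prime``, starts with
    no downstream in-frame stop yield a candidate trimmed to a codon
    multiple and flagged ``complete=False``.
    """
    if min_len_nt < 3 or min_len_nt % 3 != 0:
        raise ValueError("min_len_nt must be a positive multiple of 3")
    seq = seq.upper()
    starts = set(start_codons)
    out = []
    for frame in range(3):
        open_starts: list[int] = []
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                for s in open_starts:
                    if i + 3 - s >= min_len_nt:
                        out.append(OrfCandidate(frame, s, i + 3, True))
                open_starts = []
            elif codon in starts:
                open_starts.append(i)
            i += 3
        if allow_incomplete_3prime:
            end = frame + 3 * ((len(seq) - frame) // 3)
            for s in open_starts:
                if end - s >= min_len_nt:
                    out.append(OrfCandidate(frame, s, end, False))
    out.sort(key=lambda c: (c.tx_start, c.tx_end))
    return out


# ---------------------------------------------------------------------------
# Fickett TESTCODE statistic
#
# Published lookup tables: for each base, the position parameter is
# max(count per codon position) / (min + 1) and the content parameter is the
# base's overall fraction; each is mapped through a stepped probability table
# and weighted by the base's discriminative weight.

_POSITION_PARAMETER = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_POSITION_PROBABILITY = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.49, 0.37, 0.38, 0.24, 0.30, 0.23],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.52, 0.41, 0.31, 0.17],
    "T": [0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.40, 0.31, 0.33],
}
_POSITION_WEIGHT = {"A": 0.062, "C": 0.093, "G": 0.205, "T": 0.154}
_CONTENT_PARAMETER = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]
_CONTENT_PROBABILITY = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.31, 0.33, 0.29, 0.25, 0.26],
    "G": [0.21, 0.40, 0.47, 0.50, 0.52, 0.60, 0.57, 0.52, 0.48, 0.28],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.52, 0.57, 0.60, 0.25],
}
_CONTENT_WEIGHT = {"A": 0.084, "C": 0.076, "G": 0.081, "T": 0.055}


def _lookup(value: float, parameters: list[float], probabilities: list[float]) -> float:
    for threshold, prob in zip(parameters, probabilities):
        if value >= threshold:
            return prob
    return probabilities[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence (length ≥ 6)."""
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("Fickett statistic needs at least 6 nt")
    score = 0.0
    total = len(seq)
    for base in "ACGT":
        counts = [seq[p::3].count(base) for p in range(3)]
        position_value = max(counts) / (min(counts) + 1)
        content_value = sum(counts) / total
        score += _POSITION_WEIGHT[base] * _lookup(
            position_value, _POSITION_PARAMETER, _POSITION_PROBABILITY[base]
        )
        score += _CONTENT_WEIGHT[base] * _lookup(
            content_value, _CONTENT_PARAMETER, _CONTENT_PROBABILITY[base]
        )
    return score


# ---------------------------------------------------------------------------
# Coding-potential model

_FEATURE_NAMES = ("orf_length", "orf_coverage", "fickett", "hexamer")
DEFAULT_CODING_CUTOFF = 0.364


@dataclass
class CodingPotentialModel:
    """Logistic coding-potential scorer over four ORF sequence features.

    ``hexamer_table`` maps each of the 4096 hexamers to a log-ratio of
    coding vs noncoding usage (absent keys score 0, as do hexamers with N).
    ``coefficients`` is (intercept, w_length, w_coverage, w_fickett,
    w_hexamer).
    """

    hexamer_table: dict[str, float] = field(default_factory=dict)
    coefficients: tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    probability_cutoff: float = DEFAULT_CODING_CUTOFF

    def hexamer_score(self, seq: str) -> float:
        """Mean log-ratio of the in-frame (frame 0) hexamers of ``seq``."""
        seq = seq.upper()
        if len(seq) < 6:
            raise ValueError("hexamer score needs at least 6 nt")
        values = [
            self.hexamer_table.get(seq[i : i + 6], 0.0)
            if "N" not in seq[i : i + 6]
            else 0.0
            for i in range(0, len(seq) - 5, 3)
        ]
        return float(sum(values) / len(values))

    def features(self, orf_seq: str, transcript_length: int) -> tuple[float, ...]:
        return (
            float(len(orf_seq)),
            len(orf_seq) / transcript_length,
            fickett_score(orf_seq),
            self.hexamer_score(orf_seq),
        )

    def probability(self, orf_seq: str, transcript_length: int) -> float:
        b0, *w = self.coefficients
        z = b0 + sum(wi * fi for wi, fi in zip(w, self.features(orf_seq, transcript_length)))
        return 1.0 / (1.0 + math.exp(-z))

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "hexamer_table": self.hexamer_table,
                    "coefficients": list(self.coefficients),
                    "probability_cutoff": self.probability_cutoff,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "CodingPotentialModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            hexamer_table=d["hexamer_table"],
            coefficients=tuple(d["coefficients"]),
            probability_cutoff=d.get("probability_cutoff", DEFAULT_CODING_CUTOFF),
        )


def build_hexamer_table(
    coding_seqs: Iterable[str], noncoding_seqs: Iterable[str], pseudocount: float = 1.0
) -> dict[str, float]:
    """Log-ratio table of in-frame coding vs sliding noncoding hexamer usage."""
    def counts(seqs: Iterable[str], step: int) -> dict[str, float]:
        c: dict[str, float] = {}
        for s in seqs:
            s = s.upper()
            for i in range(0, len(s) - 5, step):
                h = s[i : i + 6]
                if "N" not in h:
                    c[h] = c.get(h, 0.0) + 1.0
        return c

    cod = counts(coding_seqs, 3)
    non = counts(noncoding_seqs, 1)
    keys = set(cod) | set(non)
    cod_total = sum(cod.values()) + pseudocount * len(keys)
    non_total = sum(non.values()) + pseudocount * len(keys)
    return {
        k: math.log(
            ((cod.get(k, 0.0) + pseudocount) / cod_total)
            / ((non.get(k, 0.0) + pseudocount) / non_total)
        )
        for k in sorted(keys)
    }


def train(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    probability_cutoff: float = DEFAULT_CODING_CUTOFF,
) -> CodingPotentialModel:
    """Fit the logistic coding-potential model from labelled training sets.

    Each training sequence contributes its longest ORF-like span (or the
    whole sequence in frame 0 when no ORF is found) as the feature source.
    """
    from sklearn.linear_model import LogisticRegression

    table = build_hexamer_table(coding_seqs, noncoding_seqs)
    model = CodingPotentialModel(hexamer_table=table)

    def row(seq: str) -> tuple[float, ...]:
        cands = enumerate_orfs(seq, min_len_nt=30, allow_incomplete_3prime=True)
        if cands:
            best = max(cands, key=lambda c: c.tx_end - c.tx_start)
            sub = seq[best.tx_start : best.tx_end]
        else:
            sub = seq[: 3 * (len(seq) // 3)]
        return model.features(sub, len(seq))

    X = np.array([row(s) for s in coding_seqs] + [row(s) for s in noncoding_seqs])
    y = np.array([1] * len(coding_seqs) + [0] * len(noncoding_seqs))
    clf = LogisticRegression(max_iter=2000)
    clf.fit(X, y)
    model.coefficients = (float(clf.intercept_[0]), *map(float, clf.coef_[0]))
    model.probability_cutoff = probability_cutoff
    return model


# ---------------------------------------------------------------------------
# Genome placement


def predict_orfs(
    transcripts: Iterable[TranscriptModel],
    genome: GenomeRef,
    model: CodingPotentialModel,
    min_len_nt: int = 75,
    allow_incomplete_3prime: bool = True,
    start_codons: Sequence[str] = (START_CODON,),
    probability_table: Optional[dict[tuple[str, int, int], float]] = None,
) -> dict[str, list[OrfModel]]:
    """Predict and place ORFs for the novel transcripts of a set.

    Known transcripts are skipped (their CDS comes from reference
    annotation). Every candidate at or above the model's probability
    cutoff is kept, not only the best per transcript. An optional
    ``probability_table`` keyed by (transcript_id, tx_start, tx_end)
    overrides the model's probability, letting an external scorer's run be
    mirrored exactly.
    """
    result: dict[str, list[OrfModel]] = {}
    for t in transcripts:
        if t.novelty != "novel":
            continue
        seq = t.spliced_sequence(genome)
        kept = []
        for cand in enumerate_orfs(seq, min_len_nt, allow_incomplete_3prime, start_codons):
            orf_seq = seq[cand.tx_start : cand.tx_end]
            key = (t.transcript_id, cand.tx_start, cand.tx_end)
            if probability_table is not None and key in probability_table:
                p = probability_table[key]
            else:
                p = model.probability(orf_seq, len(seq))
            if p >= model.probability_cutoff:
                kept.append((cand, p, orf_seq))
        orfs = []
        for idx, (cand, p, orf_seq) in enumerate(kept):
            protein = translate(orf_seq[:-3] if cand.complete else orf_seq)
            orfs.append(
                OrfModel(
                    transcript_id=t.transcript_id,
                    tx_start=cand.tx_start,
                    tx_end=cand.tx_end,
                    coding_probability=p,
                    protein=protein,
                    has_stop=cand.complete,
                    cds_blocks=t.tx_span_to_blocks(cand.tx_start, cand.tx_end),
                    orf_id=f"{t.transcript_id}.orf{idx}",
                )
            )
        result[t.transcript_id] = orfs
    return result


def write_protein_fasta(orfs: dict[str, list[OrfModel]], path: str) -> None:
    with open(path, "w") as fh:
        for tid in sorted(orfs):
            for orf in orfs[tid]:
                fh.write(f">{orf.orf_id} coding_probability={orf.coding_probability:.4f}\n")
                for i in range(0, len(orf.protein), 60):
                    fh.write(orf.protein[i : i + 60] + "\n")
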