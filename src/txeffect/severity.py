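"""Five-level severity scheme and custom-vs-reference comparison.

Levels: 0 modifier < 1 low < 2 moderate < 3 damaging missense < 4 high.
Levels 3 and 4 are considered deleterious. Missense calls start at
moderate and move to damaging missense when the external predictor calls
them damaging — or when no prediction is available (provisional damaging,
configurable), so that an unscored novel proteoform is not silently
demoted below a scored reference one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .consequence import ConsequenceCall
from .models import Variant

MODIFIER, LOW, MODERATE, DAMAGING_MISSENSE, HIGH = range(5)
DELETERIOUS_LEVELS = frozenset({DAMAGING_MISSENSE, HIGH})

LEVEL_NAMES = ["modifier", "low", "moderate", "damaging_missense", "high"]
_NAME_TO_LEVEL = {n: i for i, n in enumerate(LEVEL_NAMES)}


def level_name(level: int) -> str:
    return LEVEL_NAMES[level]


def level_from_name(name: str) -> int:
    return _NAME_TO_LEVEL[name]


#: base severity per SO term. intron_variant sits at LOW so that a deep
#: intronic reference call ranks below any coding consequence but above
#: purely positional (modifier) classes.
DEFAULT_TERM_LEVELS: dict[str, int] = {
    "intergenic_variant": MODIFIER,
    "upstream_gene_variant": MODIFIER,
    "downstream_gene_variant": MODIFIER,
    "5_prime_UTR_variant": MODIFIER,
    "3_prime_UTR_variant": MODIFIER,
    "non_coding_transcript_exon_variant": MODIFIER,
    "non_coding_transcript_variant": MODIFIER,
    "intron_variant": LOW,
    "splice_region_variant": LOW,
    "synonymous_variant": LOW,
    "stop_retained_variant": LOW,
    "start_retained_variant": LOW,
    "missense_variant": MODERATE,
    "inframe_insertion": MODERATE,
    "inframe_deletion": MODERATE,
    "protein_altering_variant": MODERATE,
    "splice_donor_variant": HIGH,
    "splice_acceptor_variant": HIGH,
    "stop_gained": HIGH,
    "stop_lost": HIGH,
    "start_lost": HIGH,
    "frameshift_variant": HIGH,
}

IMPACT_NAMES = {
    MODIFIER: "MODIFIER", LOW: "LOW", MODERATE: "MODERATE",
    DAMAGING_MISSENSE: "DAMAGING_MISSENSE", HIGH: "HIGH",
}


class UnknownTermError(KeyError):
    """A consequence term has no severity assignment (configuration error)."""


@dataclass
class SeverityScheme:
    term_levels: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TERM_LEVELS)
    )
    #: level assigned to a missense call with no predictor verdict
    unknown_missense_level: int = DAMAGING_MISSENSE

    def __post_init__(self) -> None:
        bad = {t: l for t, l in self.term_levels.items() if l not in range(5)}
        if bad:
            raise ValueError(f"levels outside 0..4: {bad}")

    def severity_of(self, call: ConsequenceCall) -> int:
        """Max severity over the call's terms, with the missense split."""
        level = MODIFIER
        for term in call.terms:
            if term not in self.term_levels:
                raise UnknownTermError(
                    f"no severity configured for SO term {term!r}"
                )
            base = self.term_levels[term]
            if term == "missense_variant":
                prediction = (
                    call.missense_score[1] if call.missense_score else "unknown"
                )
                if prediction == "damaging":
                    base = DAMAGING_MISSENSE
                elif prediction == "benign":
                    base = MODERATE
                else:
                    base = self.unknown_missense_level
            level = max(level, base)
        return level


@dataclass
class MissensePredictorAdapter:
    """Deterministic lookup of external missense deleteriousness calls.

    Keyed by (protein id, 1-based protein position, ref AA, alt AA);
    a missing key means "unknown". Rows from tools other than the
    configured primary one are carried but do not drive the level.
    """

    name: str = "table"
    scores: dict[tuple[str, int, str, str], tuple[float, str]] = field(
        default_factory=dict
    )

    @classmethod
    def from_tsv(cls, path: str, tool: Optional[str] = None) -> "MissensePredictorAdapter":
        """Load a score table (protein_id, protein_pos, ref_aa, alt_aa,
        tool, score, prediction); optionally keep a single tool's rows."""
        scores = {}
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                if tool is not None and row.get("tool") not in (tool, None, ""):
                    continue
                pred = row["prediction"].strip().lower()
                if pred not in ("benign", "damaging", "unknown"):
                    raise ValueError(f"bad prediction {pred!r} in {path}")
                key = (
                    row["protein_id"],
                    int(row["protein_pos"]),
                    row["ref_aa"],
                    row["alt_aa"],
                )
                scores[key] = (float(row["score"]), pred)
        return cls(name=tool or "table", scores=scores)

    def lookup(
        self, protein_id: str, protein_pos: int, ref_aa: str, alt_aa: str
    ) -> Optional[tuple[float, str]]:
        return self.scores.get((protein_id, protein_pos, ref_aa, alt_aa))


def stub_scorer(seed: int = 0, damaging_threshold: float = 0.5):
    """Deterministic stand-in scorer for tests: hashes the substitution.

    Synthetic by construction — it reflects no biology. Scores are uniform
    in [0,1) from a seeded hash; scores >= ``damaging_threshold`` are
    called damaging.
    """
    import hashlib

    def lookup(protein_id: str, protein_pos: int, ref_aa: str, alt_aa: str):
        h = hashlib.sha256(
            f"{seed}:{protein_id}:{protein_pos}:{ref_aa}:{alt_aa}".encode()
        ).digest()
        score = int.from_bytes(h[:8], "big") / 2**64
        return (score, "damaging" if score >= damaging_threshold else "benign")

    return lookup


@dataclass
class ReannotationRecord:
    variant: Variant
    ref_best: tuple[int, ConsequenceCall]
    custom_best: tuple[int, ConsequenceCall]
    increased: bool
    filter_flags: set[str] = field(default_factory=set)
    candidate: bool = False
    #: best missense call per source, for the same-substitution filter
    ref_best_missense: Optional[ConsequenceCall] = None
    custom_best_missense: Optional[ConsequenceCall] = None


def _specificity(call: ConsequenceCall) -> tuple:
    # deterministic tie-break: more terms first, then transcript id
    return (-len(call.terms), tuple(sorted(call.terms)), call.transcript_id,
            call.orf_id or "")


def best_per_source(
    calls: Iterable[ConsequenceCall], scheme: SeverityScheme
) -> dict[str, tuple[int, ConsequenceCall]]:
    """Per source, the maximal-severity call (deterministic tie-break)."""
    best: dict[str, tuple[int, ConsequenceCall]] = {}
    for call in sorted(calls, key=_specificity):
        level = scheme.severity_of(call)
        cur = best.get(call.source)
        if cur is None or level > cur[0]:
            best[call.source] = (level, call)
    return best


def _best_missense(calls: list[ConsequenceCall], scheme: SeverityScheme):
    mis = [c for c in calls if c.is_missense and c.aa_change is not None]
    if not mis:
        return None
    return max(
        mis,
        key=lambda c: (scheme.severity_of(c), tuple(sorted(c.terms)), c.transcript_id),
    )


def compare(
    variants: Iterable[Variant],
    calls: Iterable[ConsequenceCall],
    scheme: SeverityScheme,
) -> list[ReannotationRecord]:
    """One record per variant: best reference vs best custom severity."""
    by_variant: dict[tuple, list[ConsequenceCall]] = {}
    for call in calls:
        by_variant.setdefault(call.variant.key(), []).append(call)
    records = []
    for v in sorted(variants, key=lambda v: v.key()):
        vcalls = by_variant.get(v.key(), [])
        best = best_per_source(vcalls, scheme)
        missing = {"reference", "custom"} - set(best)
        if missing:
            raise ValueError(f"variant {v} lacks calls for source(s) {missing}")
        ref_best, custom_best = best["reference"], best["custom"]
        records.append(
            ReannotationRecord(
                variant=v,
                ref_best=ref_best,
                custom_best=custom_best,
                increased=custom_best[0] > ref_best[0],
                ref_best_missense=_best_missense(
                    [c for c in vcalls if c.source == "reference"], scheme
                ),
                custom_best_missense=_best_missense(
                    [c for c in vcalls if c.source == "custom"], scheme
                ),
            )
        )
    return records
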