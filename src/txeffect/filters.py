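"""Filter cascade over reannotation records, plus the keyword-category
Fisher enrichment used for candidate lists.

A variant survives as a candidate iff its custom severity strictly exceeds
its reference severity and no exclusion applies: already deleterious on
the reference (level ≥ 3), identical amino-acid substitution in both
annotations, common (AF above threshold) custom missense, and — as an
opt-in — missense predicted benign in both annotations. Each predicate
depends only on the record itself, so the cascade is order-independent
and idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .severity import DAMAGING_MISSENSE, MODERATE, ReannotationRecord

FLAG_NOT_INCREASED = "not_increased"
FLAG_ALREADY_DELETERIOUS = "already_deleterious"
FLAG_SAME_SUBSTITUTION = "same_substitution"
FLAG_COMMON_MISSENSE = "common_missense"
FLAG_BENIGN_IN_BOTH = "benign_in_both"


@dataclass
class FilterConfig:
    af_threshold: float = 0.01
    drop_already_deleterious: bool = True
    drop_same_substitution: bool = True
    drop_benign_in_both: bool = False
    category_keyword: str = "immun"

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_threshold <= 1.0:
            raise ValueError("af_threshold must be in [0,1]")


def _flags_for(r: ReannotationRecord, cfg: FilterConfig) -> set[str]:
    flags: set[str] = set()
    if not r.increased:
        flags.add(FLAG_NOT_INCREASED)
    if cfg.drop_already_deleterious and r.ref_best[0] >= DAMAGING_MISSENSE:
        flags.add(FLAG_ALREADY_DELETERIOUS)
    ref_mis, cus_mis = r.ref_best_missense, r.custom_best_missense
    if (
        cfg.drop_same_substitution
        and ref_mis is not None
        and cus_mis is not None
        and ref_mis.aa_change == cus_mis.aa_change
    ):
        flags.add(FLAG_SAME_SUBSTITUTION)
    af = r.variant.allele_frequency
    custom_is_missense = r.custom_best[1].is_missense
    if custom_is_missense and af is not None and af > cfg.af_threshold:
        flags.add(FLAG_COMMON_MISSENSE)
    if cfg.drop_benign_in_both and ref_mis is not None and cus_mis is not None:
        preds = {
            (c.missense_score[1] if c.missense_score else "unknown")
            for c in (ref_mis, cus_mis)
        }
        if preds == {"benign"}:
            flags.add(FLAG_BENIGN_IN_BOTH)
    return flags


def filter_candidates(
    records: Iterable[ReannotationRecord], cfg: Optional[FilterConfig] = None
) -> tuple[list[ReannotationRecord], list[ReannotationRecord]]:
    """Split records into (candidates, flagged-out), recording every reason.

    Variants with no allele-frequency annotation are treated as rare.
    The AF comparison is strict: AF exactly at the threshold is kept.
    """
    cfg = cfg or FilterConfig()
    candidates, removed = [], []
    for r in records:
        r.filter_flags = _flags_for(r, cfg)
        r.candidate = not r.filter_flags
        (candidates if r.candidate else removed).append(r)
    return candidates, removed


def flag_category(clinical_description: Optional[str], keyword: str = "immun") -> bool:
    """Case-insensitive substring match of a category keyword."""
    if not clinical_description:
        return False
    return keyword.lower() in clinical_description.lower()


def enrichment_test(
    candidate_flags: Sequence[bool], background_flags: Sequence[bool]
) -> tuple[float, float]:
    """Two-sided Fisher's exact test for category enrichment in candidates.

    The 2×2 table is (candidate vs background) × (category vs not); the
    odds ratio is the unconditional sample estimate ad/bc (inf or 0 when a
    margin cell is zero; nan for 0/0), the p-value the exact two-sided
    hypergeometric probability.
    """
    if not len(candidate_flags) or not len(background_flags):
        raise ValueError("both groups must be non-empty")
    a = sum(bool(x) for x in candidate_flags)
    b = len(candidate_flags) - a
    c = sum(bool(x) for x in background_flags)
    d = len(background_flags) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    return odds, float(p)
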