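# txeffect

Variant effect reannotation against custom transcriptomes.

Standard variant annotation works against a fixed reference transcript
set, so a variant that is harmless in every reference isoform — deep
intronic, UTR, or a benign missense — can still be deleterious in a
transcript the reference does not contain: an ORF reading into a retained
intron, a novel upstream start codon, a proteoform with a shifted reading
frame. Sample-specific transcriptomes from long-read RNA sequencing
routinely contain thousands of such novel transcripts. `txeffect` is for
researchers in rare-disease genetics who have (1) a patient variant set
(VCF), (2) a custom transcript annotation (GTF, e.g. from a long-read
assembly tool such as TALON), and (3) the genome FASTA, and who want the
short list of variants whose predicted severity *increases* when the
custom transcriptome is used instead of the reference.

## Method

1. **ORF prediction.** Novel transcripts (those absent from the
   reference GTF, or flagged by a GTF attribute) are scanned for
   ATG→stop spans in all three forward frames of the spliced sequence
   (minimum 75 nt, nested starts kept). Each candidate is scored with a
   logistic coding-potential model over four sequence features — ORF
   length, ORF coverage of the transcript, the Fickett TESTCODE
   statistic, and an in-frame hexamer usage log-ratio:

   P(coding) = σ(β₀ + β₁·len + β₂·cov + β₃·Fickett + β₄·hexamer)

   Every ORF with P ≥ 0.364 (the conventional cutoff for human ORFs) is
   kept — not only the best per transcript. The model is supplied as a
   JSON file, trained from labelled FASTA sets with `txeffect.orf.train`,
   or bypassed with a precomputed per-ORF probability table.

2. **Consequence calling.** Each variant is annotated against every
   nearby transcript of both sources with Sequence-Ontology terms
   (splice donor/acceptor = first/last 2 intron bases; splice region =
   intron bases 3–8 or the outer 3 exon bases of internal junctions;
   UTR/CDS effects resolved at codon level: synonymous, missense,
   stop_gained, stop_lost, start_lost, frameshift, in-frame indels).

3. **Severity.** Terms map onto five ordered levels —
   0 modifier < 1 low < 2 moderate < 3 damaging missense < 4 high —
   with levels 3–4 considered deleterious. Missense calls start at
   moderate and are promoted to damaging missense when an external
   predictor (e.g. a PolyPhen-2 score table, via a pluggable adapter)
   calls them damaging, or when no prediction exists for the novel
   proteoform.

4. **Comparison and filters.** Per variant, the best custom-source level
   is compared with the best reference-source level. Candidates are
   variants with a strict increase that survive the cascade: not already
   deleterious (level ≥ 3) on the reference, not the identical amino-acid
   substitution in both annotations, not a common (AF > 0.01) custom
   missense, and — optionally — not benign-in-both.

A Fisher's exact utility (`txeffect.filters.enrichment_test`) tests
whether a keyword-defined category (default `"immun"` in the clinical
description) is enriched among candidates.

## Worked example

The package ships a generator for fully synthetic input bundles whose
planted scenarios mirror the situations above, with a manifest of the
expected outcome of every planted variant:

```
$ txeffect simulate --seed 7 --out-dir demo
variants        12
$ txeffect run --genome demo/genome.fa --custom-gtf demo/custom.gtf \
    --reference-gtf demo/reference.gtf --vcf demo/variants.vcf \
    --scorer demo/scorer.json --scores demo/missense_scores.tsv \
    --out-dir demo/out
candidates      8
consequence_calls       38
custom_transcripts      28
increased_severity      12
novel_orfs      14
novel_transcripts       14
reference_transcripts   14
removed_common_missense 2
removed_same_substitution       2
variants        12
```

All 12 planted variants (6 scenarios × 2 strands) increase in severity;
8 survive the filters — the common-allele missense pair and the
same-substitution pair are removed, each with its reason recorded. The
candidate table shows, e.g., the retained-intron stop-gain plants:

```
variant_id                          ref_consequence  ref_level  custom_consequence  custom_level
var_retained_intron_stop_gain_fwd   intron_variant   low        stop_gained         high
var_retained_intron_stop_gain_rev   intron_variant   low        stop_gained         high
```

Outputs: `annotated.vcf` (CSQ-style per-transcript annotations),
`comparison.tsv` (per-variant best reference vs custom severity),
`candidates.tsv` and `candidates.vcf` (the increasing-severity subset).

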