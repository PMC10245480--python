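# Methods

## Model and procedure

`txeffect` compares, per variant, the most severe predicted molecular
consequence under two transcript annotations of the same genome: a
reference GTF and a custom (sample-specific) GTF containing novel
transcripts. The pipeline is deterministic end to end; its stages and the
choices inside them are documented here.

### Coordinates

All internal coordinates are 0-based half-open on the genome; transcript
coordinates run 5'→3' along the spliced transcript. GTF I/O is 1-based
inclusive, BED 0-based half-open, VCF positions 1-based; every conversion
happens at the I/O boundary and nowhere else. The round-trip identity
`genome_to_tx(tx_to_genome(p)) == p` is enforced by property tests on
both strands.

### Variant normalization

Multi-allelic VCF records are split into independent alleles before
annotation (severity comparison is per allele). When a genome is
available, indels are left-aligned and trimmed (shared suffix removed
with leftward extension, shared prefix trimmed to one anchor base). A ref
allele disagreeing with the genome is flagged but retained, since users
may annotate against a patched assembly. Variants lacking an allele
frequency are treated as rare in the filter stage — absence of an AF
annotation is not evidence of commonness.

### ORF prediction

Only novel transcripts are scanned (known transcripts take their CDS from
the reference annotation, which is also how custom-GTF entries sharing a
reference transcript id are handled). Candidate ORFs are ATG→stop spans
in the three forward frames of the spliced sequence; the reverse strand
is never scanned because the transcript sequence is already oriented.
Defaults: start codon ATG only (configurable), minimum length 75 nt,
3'-incomplete ORFs (no stop before the transcript end) kept but flagged —
long-read transcripts may be 3'-truncated; `stop_lost` is never emitted
for them because there is no annotated stop to lose. Every distinct start
sharing a stop is its own candidate and **all** candidates at or above
the probability cutoff are kept, not one per transcript; non-coding gene
biotypes are not excluded from the scan.

The coding-potential score is a logistic model over (ORF length, ORF
coverage, Fickett TESTCODE statistic, mean in-frame hexamer log-ratio),
with the cutoff defaulting to 0.364, the conventional threshold for
human ORFs. The Fickett statistic uses the published TESTCODE lookup
tables (position parameter = max/(min+1) of per-codon-position base
counts; content parameter = base fraction; both stepped through the
published probability tables and weighted). Hexamers containing N
contribute zero, as do hexamers absent from the table. No pretrained
human coefficients are bundled as ground truth: the model is either
fitted from user-supplied coding/non-coding training FASTAs
(`txeffect.orf.train`, logistic regression on the four features of each
sequence's longest ORF), loaded from JSON, or bypassed entirely with a
per-ORF probability table so an external scorer's run can be mirrored
exactly.

### Consequence calling

Splice definitions follow the Ensembl conventions: donor/acceptor are the
first/last two intron bases (high severity), splice region covers intron
bases 3–8 and the outer three exon bases of internal junctions (low). The
upstream/downstream window is 5000 bp (configurable). A variant spanning
several positional classes (e.g. an exon–intron deletion) receives the
union of the per-position terms; ranking then uses the most severe.
Insertions are anchored at the right edge of the VCF position for
exon-membership tests, matching left-normalized VCF semantics. Stop
codons are TAA/TAG/TGA (standard code only); codons containing N
translate to X. An SNV in the initiator codon that removes the encoded
methionine is `start_lost` (sole coding term); an SNV in the terminal
stop is `stop_retained_variant` or `stop_lost`; elsewhere the codon diff
yields synonymous/missense/stop_gained. Indels are `frameshift_variant`
when the length change is not a multiple of 3, otherwise
`inframe_insertion`/`inframe_deletion`, with `start_lost` co-assigned
when the initiator codon is disrupted. Equal-length multi-base
substitutions fall back to `protein_altering_variant`.

The engine is validated against an independent whole-protein
mutate-and-translate oracle (Biopython translation, protein diff) on
thousands of random transcript/SNV pairs per strand, and against a
strand-mirroring symmetry property.

### Severity scheme

Five ordered levels: 0 modifier, 1 low, 2 moderate, 3 damaging missense,
4 high; levels 3–4 are deleterious. High holds stop_gained, stop_lost,
start_lost, frameshift and splice donor/acceptor; moderate holds missense
and in-frame indels; low holds splice region, synonymous and
`intron_variant`. Placing `intron_variant` at low (rather than the
annotation-tool-conventional modifier) keeps deep intronic reference
calls strictly below any coding consequence while ranking them above
purely positional classes, and matches the worked reannotation examples
this scheme reproduces. Level 3 is reserved for missense: a missense call
is promoted from moderate when the external predictor says damaging —
or when no prediction exists (default; `--unknown-missense moderate`
selects the conservative alternative). Scoring unknown at moderate would
silently demote exactly the novel proteoforms the method exists to
surface, since external predictors have no precomputed scores for them.
Unknown consequence terms raise a configuration error rather than
defaulting to 0.

### Missense predictor adapter

External deleteriousness calls enter through a TSV keyed by
(protein id, protein position, ref AA, alt AA) with a tool name, score
and benign/damaging/unknown verdict — the format one would export from a
PolyPhen-2/SIFT run over the predicted proteome. Only the primary tool's
verdict moves the level; other tools' rows are carried through. A
deterministic hash-based stub scorer exists for tests only and is
labelled synthetic; it reflects no biology.

### Aggregation, comparison, filters

Per variant and source the maximal-severity call wins (ties broken by
term-set specificity then transcript id, for determinism); the comparison
is per-variant custom-max vs reference-max, not transcript-pairwise. A
candidate must increase strictly and survive four independent predicates:
reference level < 3; not the identical (ref AA, position, alt AA)
substitution in both sources — identical residues at *different*
positions in different proteoforms are kept, positions are part of the
identity; custom-missense allele frequency not above 0.01 (strict: AF
exactly 0.01 is kept, following the printed inequality); and, only when
enabled, not benign-in-both. Each predicate depends only on the record,
so the cascade is order-independent and idempotent; every removal reason
is recorded. The enrichment utility is a two-sided Fisher's exact test on
the candidate × keyword 2×2 table; the reported odds ratio is the
unconditional sample estimate ad/bc (infinite/zero on degenerate margins,
with the exact p still computed).

## Synthetic data generator

`txeffect.simulate` builds complete input bundles (genome FASTA,
reference and custom GTF, VCF, score table, scorer JSON) with one planted
gene per scenario per strand on a single 100 kb contig, genes spaced
7 kb apart so neighbours stay outside each other's upstream/downstream
window. Scenarios: retained-intron ORF hit by a stop-gain (reference:
intron, low → custom: stop gained, high); novel upstream ORF whose ATG an
SNV destroys (5'UTR → start lost); the same SNV striking different
proteoforms (benign missense → unscored missense); an identical
substitution in both annotations (filtered out); a common (AF 0.05)
custom missense (filtered out); and a 3 bp deletion removing a novel
initiator that is an ordinary internal Met of the reference CDS (in-frame
deletion → start lost & in-frame deletion). Decoy novel transcripts with
no ORF exercise the non-coding path.

Planted coding sequence is drawn from a fixed eight-codon alphabet chosen
so that no codon or codon junction can spell ATG or a stop, and all
filler sequence is scrubbed of ATG and CAT (its reverse-strand image)
outside planted regions, so the set of reading frames is exactly the
planted one. The bundled scorer awards hexamers composed of two preferred
codons +1 and everything else 0, with logistic coefficients (−2, 0, 0, 0,
8): planted ORFs score ≈ 0.998 and random decoy sequence ≈ 0.12, leaving
the 0.364 cutoff far from both. The manifest records each planted
variant's expected terms, levels and candidate status **by construction**
— the bundle is its own oracle, and a multi-seed sweep asserts exact
recovery.

What the generator does *not* emulate: sequencing error, read support,
expression levels, realistic splice-site motifs (splice classification is
positional), hexamer statistics of real coding sequence, or genome-scale
transcript density. Passing the sweep therefore demonstrates the
correctness of the coordinate arithmetic, ORF enumeration/scoring
plumbing, consequence logic, severity comparison and filter cascade — not
the biological accuracy of any coding-potential model on real data.

## Numerical and degenerate-input choices

Problem sizes in the test-suite sweeps (≥1000 oracle SNVs per strand,
≥10 000 round-trip positions, 20-seed end-to-end sweep, all Fisher tables
with grand total ≤ 30) were chosen to finish in well under a minute each
on a single core while exhausting the relevant case space. Logistic
probabilities use the closed form, no iteration; ties in best-call
selection are broken lexicographically; empty candidate or background
groups for the enrichment test are an error; a transcript with no
overlapping variant contributes nothing; a variant near no transcript of
a source receives an explicit intergenic call for that source so every
variant always has a best level per source.

## Known limitations

- No HGVS output, regulatory consequences, structural variants, or
  phased multi-variant codon effects.
- CDS features written by `write_gtf` include the stop codon (no
  `stop_codon` feature); the reader compensates for annotations that
  exclude it by probing the next in-frame codon.
- Equal-length multi-nucleotide substitutions are not resolved to
  per-codon effects.
- The severity scheme's intron placement and the unknown-missense
  promotion are deliberate interpretive choices (documented above);
  both are configurable where a flag is noted.
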