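# Methods

This note documents the models, conventions and design choices behind
`afmock`, in the order the pipeline runs.

## Amplicon layout and trimming

A clone is modeled as `18S flank (310 b) + ITS1 (192–282 b) + 5.8S flank
(116 b)`, giving clone amplicons of 618–708 bases. The nested sequencing
primers sit inside the flanks: the forward primer core starts 130 bases
before the 18S flank's 3' end and the reverse-primer site ends 31 bases
into the 5.8S flank, so the trimmed barcoded-amplicon template is
`130 + ITS1 + 31` = 353–443 bases — the size window of the ARISA primer
system this layout follows. Trimming locates primer cores after stripping
the 18-base UniTag adapter prefixes from the printed oligos; the split is
configurable (`adapter_prefix_len_*`) because the adapter/primer boundary
is a convention, not something the sequence alone determines. Exactly one
site per primer is required; multiple or missing sites raise an error
rather than guessing, since a silently mis-trimmed template corrupts
every downstream size and abundance. The reverse primer is matched as its
reverse complement on the deposited strand only: clones are directional
PCR products, so the opposite orientation is rejected. Subject `N` bases
match no primer base by default (an uncalled base should not satisfy a
primer site); a wildcard switch exists. Coordinates are 0-based,
half-open everywhere. ITS1 length is pure flank arithmetic,
`L_clone − 310 − 116`, and is measured from the dominant repeat; trimmed
templates retain the primer cores, so trimming is idempotent.

## Theoretical composition

Mock communities are mixed by amplicon mass, so expectations are molar:
`p_i ∝ m_i / L̄_i`. The molecular-weight constant cancels in the
normalization and masses are treated as exact. `L̄_i` is the
count-weighted mean template length; the default basis is the trimmed
barcoded-amplicon length (the template actually amplified in the
sequencing PCR), with a `length_basis="clone"` switch because the
full-clone convention is equally defensible and the choice moves
abundances by under a percent. Strain mass splits to clones
proportionally to clone counts, and aggregates to taxa by annotation.
No thresholding happens at the composition stage — arbitrarily small
theoretical taxa are retained so detection limits can be measured, not
assumed.

## Read synthesis

Theoretical fastq files are idealized: no sequencing errors, flat quality
(`I`), both mates carrying the same 8-nt sample barcode, the forward read
covering the template 5' end and the reverse read the reverse-complemented
3' end. An error model would confound the OTU-caller evaluation, which is
exactly about thresholds and one-mismatch correction. Read counts are
apportioned by largest remainder (ties broken lexicographically by clone
key) so the total is exact — 200,000 pairs per sample by default, 20,000
in the test-suite end-to-end runs, which keeps the whole benchmark at a
few seconds per mock without changing any qualitative behaviour.

## PCR length bias

The preferential-amplification hypothesis — shorter templates gain share
over many PCR cycles — is made explicit as per-cycle geometric growth,
`N_i ← N_i (1 + e(L_i))^c`, with `c = 40 + 5` cycles by default (target
amplification plus barcoding) and a logistic efficiency curve
`e(L) = e_max − s·σ(k(L − L₀))`, `e_max = 0.95`, midpoint `L₀ = 400`
(mid amplicon range), steepness `0.03`/base. No functional form is
canonical for `e(L)`; logistic decay was chosen as the simplest bounded
monotone curve, and the bias strength `s` (the short-vs-long efficiency
gap) is the single knob the bias experiments vary. A stochastic mode
draws per-cycle gains binomially; its mean trajectory matches the
deterministic model, which is what the pipeline uses.

## OTU calling

The caller follows the open-reference unique-sequence strategy: truncate
mates to 150 bases, dereplicate on the (forward, reverse) pair, keep pairs
at ≥0.6% of sample reads, remove chimeric candidates, then error-correct
remaining reads into the most abundant OTU within 1 mismatch per segment
(ties broken lexicographically by OTU sequence). Two points were
genuinely open and are resolved as documented conventions:

- the 2.0 "abundance ratio" is read as the chimera parent test — a
  candidate is chimeric when one other candidate matches its forward
  segment exactly and a different one its reverse segment, each at ≥2×
  its abundance (switchable off via `chimera_check=False`);
- the 0.6% threshold applies to pre-correction dereplicated abundance
  ("unique sequences above a threshold"), with relative abundances
  recomputed after correction.

Mismatches are Hamming distances on the fixed-length segments — reads are
equal length by construction, so no gapped comparison is needed. Relative
abundances are reported over *all* sample reads; reads no OTU explains
stay in an explicit unassigned tally rather than being renormalized away.
This makes recovery exact for taxa whose every unique template clears the
threshold, and makes detection-limit losses visible as unassigned mass.
OTU spaces are per sample; cross-sample joins match exact sequence pairs.
Control (NTC) filtering removes an OTU everywhere when its relative
abundance in any control exceeds a configurable multiple (default 1.0) of
its maximum across samples.

## Annotation

BLAST-style database search is replaced by direct alignment identity:
queries and references are same-region amplicons, so an end-to-end
(global) alignment with match +1 / mismatch −1 / gap −2 honors the cutoff
semantics without an external tool. Identity is `100 · matches /
alignment columns`; in global mode the two sequences are aligned in
canonical (sorted) order because co-optimal alignments can differ in
identity and this makes the function symmetric. Truncated queries
(150-base segments against full templates) use a semi-global mode — free,
uncounted end gaps on the reference — so flank truncation is not
penalized; paired OTU segments score each segment separately and combine
by length-weighted mean. Cutoffs are strict inequalities: >98% for clade,
>95% for genus, else NA. Ties on identity break toward higher reference
coverage, then lexicographic reference id.

Taxon profiles on the theoretical side are built by annotating each
clone's *read segments* with the same annotator used for OTUs. This keeps
labels on identical footing — an error-free OTU derived from a clone
annotates exactly as the clone does — and mirrors how a theoretical mock
acquires annotation-derived keys such as `Genus;NA` when a divergent
repeat exceeds the clade cutoff distance.

## Accuracy metrics

Per-taxon deviation is `100 (obs − theor)/theor`, defined only when both
sides are positive; ND flags an expected-but-undetected taxon, D an
unexpected detection, and the report presents mean (SD) over replicates.
Pearson *r* runs over the union of taxa with absent keys as zero
(flagged taxa thus enter as zeros), and is undefined below three taxa or
at zero variance. Weighted UniFrac is the raw form `Σ_b ℓ_b |A_b − B_b|`
(normalized variant by flag) over a UPGMA tree of per-taxon
representative sequences at alignment distance `1 − identity/100`;
UPGMA is implemented directly because merge ties must break
deterministically (lexicographic cluster names), which generic linkage
routines do not guarantee. Profiles are renormalized over annotated taxa
before UniFrac (the metric needs relative abundances on the tree's leaf
set); deviations and Pearson use the unrenormalized observed masses.
Across-mock comparison is one-way ANOVA plus Tukey HSD, with grouping
letters derived from the maximal cliques of the non-significance graph.

## Synthetic data

The generator emulates the clone-library structure of a five-strain
anaerobic-fungal study: 14–20 clones per strain collapsing to 3–10 unique
sequences with dominant-heavy multiplicities; one ancestral ITS1 per
strain (uniform 192–282 b); minor variants carrying `1 + Poisson(1)`
ITS1-confined edits (substitutions:indels 4:1) — the few-substitution
pattern typical of rDNA repeat arrays — capped at 13% of the ITS1 length,
the documented extreme of within-culture divergence. By default each
strain additionally carries one minority clone pushed to that cap and
labeled with a sister genus, reproducing the observed phenomenon of a
single clone in a library annotating to a different genus; this also
gives every mock enough distinct taxa for correlation metrics to be
defined. Flanks are conserved across strains (they are genic), contain
exactly one site per primer, and divergence is measured against the
dominant repeat. Reference databases carry one record per ground-truth
taxon (the trimmed amplicon of its highest-count clone) plus optional
decoy records far below every cutoff. All generation is
`numpy.random.Generator`-seeded and regeneration under a fixed seed is
byte-identical, including gzip output (zero mtime, no embedded
filenames).

What the generator does *not* emulate: sequencing error and quality
decay, chimera formation during PCR, index hopping, phylogenetically
realistic ITS1 evolution, or secondary-structure constraints. Passing
end-to-end tests therefore demonstrate that the *bioinformatic* pipeline
is unbiased and that composition distortions produced by the explicit
PCR model propagate as predicted — not that real sequencing data will be
error-free.

## End-to-end evaluation conventions

A taxon is treated as *callable* in a sample when every unique template
contributing to it meets the caller's minimum-abundance threshold; only
callable taxa are held to exact recovery, because a taxon above the
threshold in aggregate can still hide below-threshold unique sequences
whose reads are legitimately lost — the detection-limit effect the
benchmark exists to expose. With no PCR bias, callable taxa recover to
within read-allocation rounding, Pearson *r* exceeds 0.999 and weighted
UniFrac stays below 0.01 for all four packaged designs; with
length-monotone bias the shortest-amplicon taxa show positive deviation
and *r* falls monotonically with bias strength.

## Known limitations

- Identity among co-optimal alignments is convention-dependent; the
  canonical-order rule makes it deterministic and symmetric but other
  tools may report slightly different values for gappy pairs.
- The chimera rule uses exact segment parentage, a simplification of
  breakpoint-aware chimera detection; it is adequate for fixed-length
  error-free segments.
- Theoretical abundances depend on the mean-length convention
  (amplicon vs clone basis) at the sub-percent level; both are exposed.
- ANOVA/Tukey letters assume roughly normal replicate metrics; with the
  idealized simulator replicates can be identical, in which case the
  degenerate path (F = 0, shared letter) applies.
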