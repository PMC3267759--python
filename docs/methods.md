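# Methods

## Scope and model

`carpmir` re-implements, as a tested library, the primary analysis chain of
a bulk small-RNA sequencing survey of teleost skeletal muscle: raw-read
cleaning and collapsing, ncRNA annotation, exact genome mapping,
conserved-miRNA identification with isomiR clustering, hairpin-based novel
miRNA prediction, cross-species conservation partitioning, and 2^−ΔΔCt
qPCR expression profiling. The original sequencing dataset is not publicly
deposited, so the pipeline is exercised end to end on ground-truthed
synthetic reads plus the published result tables shipped as frozen
fixtures (`carpmir.tables`).

## Read cleaning (`preprocess`)

Reads are discarded, in a fixed cascade, as: low quality (mean Phred <
`min_mean_quality`, default 20), 5′-adapter pollution (the read begins
with a ≥10 nt prefix of the 5′ adapter), missing 3′ adapter (no ungapped
match with ≥8 nt overlap and ≤10% mismatches), empty insert, poly(A)
artefact (≥80% A or a run of ≥10 A), or insert <18 nt. The sequenced
assay states the discard categories but neither their order nor numeric
thresholds; the order here is fixed for deterministic reports and every
threshold is exposed in `CleanParams`. Inserts longer than the 30 nt
gel-purification window are retained truncated to 30 nt. The 3′-adapter
locator prefers fewest mismatches, then longest overlap, then the leftmost
position — with an error-free adapter this makes a partial-adapter match
at the read end lose against the true full-length hit.

Collapsing converts to the RNA alphabet (DNA exists only on disk), tallies
exact duplicates, and orders by descending count with lexicographic
tie-breaks, making it order-independent and idempotent.

## Annotation and mapping (`annotate`)

At 18–30 nt, exact sense-strand substring search against the
rRNA/tRNA/snRNA/snoRNA reference replaces a heuristic aligner; multi-class
hits resolve by the priority rRNA > tRNA > snRNA > snoRNA. Annotated reads
leave the analysis. Mapping is exact, full-length and zero-mismatch (the
source analysis kept only perfectly mapping reads), through a forward
k-mer index (k = 12 by default; k ≥ 4 accepted for didactic examples);
minus-strand hits are found by querying the reverse complement and are
reported at plus-strand window coordinates. Loci are reported up to a cap
(default 20); reads over the cap are flagged multi-mapped but kept, since
discarding them would silently remove repeat-derived miRNAs.

## Folding engine (`fold`)

`fold_mfe` is a Zuker-style dynamic program over pseudoknot-free
structures with Watson–Crick and G·U pairs, minimum hairpin loop 3 nt and
internal/bulge loops capped at 30 unpaired bases. The energy model is
deliberately small and fully self-documented rather than the Turner 2004
tables: stacking of two pairs contributes −(w₁+w₂) with w(CG)=1.65,
w(AU)=0.45, w(GU)=0.25 kcal/mol; hairpin loops cost 4.5+0.2·L; internal
and bulge loops 1.8+0.5·L; multiloops 3.4 + 0.4 per branch + 0.1 per
unpaired base. These magnitudes keep designed stem-loops in the −35…−60
kcal/mol range while random 70-mers land between −15 and 0, which is the
discrimination a precursor filter needs. Parameters live in
`ENERGY_PARAMS` so a richer table can be dropped in. Energies are integer
centi-kcal internally, so the optimum is exact, platform-independent and
reproducible; tie-breaking prefers stacked continuations and 5′-most
branch points. The DP is verified against exhaustive enumeration of all
nested structures for sequences up to 16 nt (beyond that the structure
count explodes combinatorially, so the exhaustive oracle is restricted to
short sequences and long-sequence correctness rests on the DP's agreement
with it at small n plus structural-validity property tests).

## Novel miRNA prediction (`novel`)

For each merged read locus two windows are folded: 20 nt upstream + read +
120 nt downstream, and the mirror arrangement (Mireap-style defaults; the
source analysis names the tool but no parameters). Because a 160 nt window
is itself longer than a pre-miRNA, the stem-loop harbouring the read is
excised from the window fold — walking outward from the hairpin loop
through stacks and small internal loops to the stem's outermost pair —
and refolded standalone. Six criteria are then evaluated independently:
(a) single stem-loop topology; (b) energy ≤ −18 kcal/mol; (c) mature
entirely on one arm with ≥14 of its bases paired and no >4 nt asymmetric
bulge inside it; (d) Dicer-site plausibility, simplified to the mature 5′
end being anchored on the stem within 2 nt of a paired base (the geometry
that leaves the canonical 2 nt 3′ overhang); (e) precursor length 55–120
nt; (f) mature length 18–23 nt with read count ≥ 5 (the published novel
set's minimum frequency is 8, so 5 leaves margin). Reads whose windows
overlap merge into one precursor represented by the highest-count member;
accepted loci are named `CM1-mNNNN_5p|_3p` in descending count order.

## Conserved miRNA identification (`discovery`)

Reads of 18–23 nt match a catalog mature when one is obtainable from the
other by end trims/extensions of ≤5 nt total with ≤2 internal
substitutions and identical seed (positions 2–8); best match = fewest
edits, ties by catalog order. "Sequence similarity" clustering is
operationalized as single linkage under seed identity plus an
end-trim/extension relation of ≤5 nt with ≤1 internal mismatch — the
published observation that category members differ by only 1–5 nt in
length is the basis for the end-length band. The representative is the
highest-count member (ties: lexicographically smallest sequence).
Clustering is computed in a canonical order, so it is invariant to input
permutation.

Conservation classes are a pure function of the species set carrying a
mature (by normalized name) in the catalog: `pan_bilaterian` (an
invertebrate and a mammal), `vertebrate_conserved` (all of xtr, dre, gga,
mmu, hsa), `teleost_only` (non-empty subset of dre, ola, fru, tni, hno,
hmo), `carp_specific` (empty), in that precedence. A fifth class,
`partially_conserved`, covers the remaining combinations (e.g. zebrafish +
mouse only) so the classification is exhaustive. Whether "conserved"
should demand full-sequence identity or seed identity is not specified in
the source; presence-by-name in the catalog is the documented choice here.

## Expression profiling (`expression`)

ΔCt = mean Ct(target) − mean Ct(reference, U6) per (miRNA, group); ΔΔCt is
taken against the calibrator group (30 dph skeletal muscle defined as fold
1); fold = 2^−ΔΔCt with amplification efficiency fixed at 2.0 — no
efficiency correction, a documented limitation. SEM is computed on
per-replicate folds (each replicate's ΔCt against the calibrator mean) so
error bars match a mean ± SEM fold-scale presentation; the source does not
state the scale, and SEM on the ΔCt scale would be the main alternative.
One-way ANOVA across groups runs on per-replicate ΔCt values; the p-value
comes from the F distribution via the regularized incomplete beta
function, checked against an independent statistics library in tests.
Tissue specificity formalizes a semi-quantitative gel readout: a miRNA is
specific to the tissues reaching ≥τ (default 0.2) of its maximum, provided
that set has ≤4 tissues (the breadth of the muscle/heart/gut/eye pattern),
else ubiquitous.

## Synthetic data (`simulate`)

The generator defines the study conditions the tests assume.

- **Genome**: i.i.d. uniform A/C/G/T background (50 kb default), 20
  planted hairpins, alternating strands, non-overlapping loci spaced so
  that prediction windows of neighbouring precursors cannot merge.
- **Precursors**: constructed, not sampled — a 22–30 nt arm, its reverse
  complement with 0–3 mismatches, a 6–10 nt loop. Each precursor is folded
  and must pass all six criteria before planting; matures (22 nt) are
  placed so every isomiR end variant stays inside the precursor, and arm
  seeds are kept distinct across hairpins so categories cannot merge.
- **Reads**: per-read origin drawn from hairpin expression weights
  (log-normal), a contaminant fraction (default 0.15) of exact ncRNA
  substrings, and a junk fraction (default 0.12) split evenly over six
  artefact classes exercising each discard reason. miRNA inserts get a
  3′-end offset from the isomiR profile; the default profile puts 0.9349
  of its mass on insert lengths 21–23 nt, the share of 21–23 nt reads the
  emulated library showed. Reads are insert + 3′ adapter + random pad,
  truncated to 42 nt, quality "I" (Phred 40) or "#" for the low-quality
  class. The assay's adapters and quality model are unknown; Illumina
  TruSeq small-RNA adapters and the two-level quality model are
  configurable defaults.
- **Round-trip guarantee**: every emitted read is passed through the
  cleaning cascade at generation time and resampled until it classifies
  as intended, so manifest counts are an exact oracle for the cleaner —
  by construction, not by luck.
- **Ct tables**: Ct(target) = 25 − log₂(fold) + N(0, σ), Ct(U6) = 18 +
  N(0, σ), default σ = 0.1 cycles and 5 replicates per group (the
  profiled time course used ≥5 animals per timepoint).

What the generator does **not** emulate: sequencing errors beyond the
low-quality class, templated/non-templated 5′ isomiRs, expression
structure across tissues in the read set, real ncRNA sequence families,
genome repeats. Recovery results on synthetic data therefore demonstrate
the pipeline's internal correctness, not its performance on a real
library.

## Problem sizes and determinism

Default validation runs use a 50 kb genome, 20 hairpins and 10^5 reads —
sizes at which every stage, including folding, completes in well under a
minute on one core while keeping binomial noise on composition fractions
near 0.1%. All randomness flows from a single integer seed through
per-stage `numpy` generator streams; identical configurations reproduce
byte-identical FASTA/FASTQ/TSV outputs and reports.

## Known limitations

- The energy model is a teaching-grade approximation: no dangling ends,
  terminal-AU penalties, special tetraloops or Turner parameters, so
  absolute energies are not comparable to ViennaRNA/mfold values.
- Exact substring annotation cannot annotate contaminants carrying
  sequencing errors; with the synthetic error model this does not arise.
- Novel-miRNA precursor boundaries come from a single window fold; the
  original analysis cross-checked candidate precursors against ESTs, a
  step without an in-repo equivalent.
- No multiple-testing correction across miRNAs in the ANOVA stage (none
  was applied in the emulated analysis).
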