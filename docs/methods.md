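# Methods

This note documents the models and procedures implemented in `vitiflora`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical conventions.

## Probe-to-gene remapping

A probe *binds* a gene model iff the probe, or its reverse complement,
aligns end to end (ungapped) at some offset of the cDNA with Hamming
distance ≤ `max_mm` (default 2).  We use an exhaustive sliding-window scan
rather than a heuristic local aligner: at ≤ 2 mismatches over a short
oligo, a gapped alignment cannot satisfy the full-length rule anyway, and
the exhaustive scan is exact, dependency-free and directly checkable
against a brute-force oracle (the test suite and acceptance script do
exactly that).  Conventions:

- `N` and other IUPAC ambiguity letters never match anything — even an
  identical ambiguity letter — and therefore count as mismatches.
  Conservative and deterministic.
- Both orientations are scanned by default (`both_strands=False`
  restricts to forward) because transcript-orientation conventions in
  input FASTA files vary; the collapse below makes orientation immaterial
  to the counts.
- Multiple placements of one probe within one gene collapse to a single
  (probe, gene) entry carrying the minimal mismatch count; ties break by
  smallest offset, forward before reverse.  This makes output independent
  of input order.
- Coordinates are 0-based, half-open internally and in files; 1-based
  only where a human-readable report says so.

Classification partitions the probe universe: unique (exactly one gene),
ambiguous (≥ 2 genes, ambiguity ratio `1:n`), unmapped.  Per-gene unique
probe counts (`probes_per_gene(..., unique_only=True)`) determine which
genes are quantifiable at all.  Whether the original BLAST-based protocol
on the real platform scanned both strands or how it collapsed multiple
placements is not recorded anywhere we could consult, so exact
reproduction of the published platform-level counts is a validation goal
for when the platform table and gene models are at hand, not a promise of
this implementation.

## Gene-level summarization and hotspots

Gene expression is the arithmetic mean of the gene's uniquely-binding
probe rows, on the log2 (RMA-like) scale — mean, not median, and not
anti-logged, matching the averaging convention the expression values were
produced under.  Genes with zero unique probes are dropped and listed,
never imputed.  Missing values are rejected: RMA matrices are complete by
construction, so a hole indicates an upstream error.

Hotspot detection operationalizes what is otherwise done by eye on a
clustermap.  It is a stated heuristic with all parameters surfaced:

1. Each gene row is z-scored against its median and MAD (scaled by
   1.4826).  Median/MAD rather than mean/sd because a hotspot confined to
   a minority of samples inflates its own row mean and sd, diluting a
   mean/sd z-score below any useful threshold; against median/MAD a +3·σ
   block stays near z ≈ +3.  Zero-MAD (constant) rows get z = 0.
2. Genes and samples are average-linkage clustered under correlation
   distance on the z matrix.  Correlation, not euclidean: block membership
   is a shared *pattern* across a subset of the axis, which correlation
   detects even when per-cell noise dominates total euclidean distance.
   Zero-variance vectors are treated as uncorrelated with everything.
3. Both dendrograms are cut at their largest merge-height gap, and every
   (gene cluster × sample cluster) pair meeting the size minima is a
   candidate block.
4. Each candidate is refined to a fixed point: alternately re-select the
   samples whose z over the block's genes clears the threshold and the
   genes whose z over those samples does.  Membership requires the
   threshold both in mean and in a majority of the member's cells, so one
   lucky cell cannot drag a background row or sample into a block.
   Refinement trims diluting members the cut merged in and re-admits ones
   it misplaced.  Deduplicated blocks are reported sorted by mean z.

Defaults: `z_threshold=1.5`, `min_genes=2`, `min_samples=2`.  Under the
synthetic study conditions (below) a planted +3·σ 5 × 5 block is
recovered exactly in ≥ 95% of seeded simulations; the residual failures
are borderline background rows whose mean over the block columns
genuinely clears the threshold.

## Volatile quantification and chemotype statistics

Calibration is ordinary least squares of the response ratio (analyte
area / internal-standard area) on the analyte amount in the extraction
vial (µg): ratio = *a*·amount + *b*.  The intercept is free, not forced
through the origin — the safer default when the acquisition protocol is
not known to be blank-corrected — and is configurable.  Two calibration
points define an exact line, so r² is reported as 1 by construction.

Quantification inverts the compound's curve and divides by tissue mass:
conc = max(0, (ratio − *b*)/*a*) / mass, in µg/g fresh weight.  Negative
back-calculated amounts clamp to 0 and are flagged (physical
non-negativity); compounds served by the fallback curve — the
(+)-valencene curve in the original study design — are flagged
semi-quantitative per compound.

Compositions are percentages over a compound-class total per sample; rows
sum to 100 to numerical tolerance and all-zero samples are excluded and
listed.  Stage-relative change is 100·(mean_a − mean_b)/mean_b over
replicate concentrations — arithmetic group means, no outlier removal.
PCA is an SVD of the centered (optionally unit-variance scaled)
samples × compounds matrix; percent variance derives from squared
singular values, and component signs are fixed by making each loading
vector's largest-magnitude entry positive.  The default is centered,
unscaled concentrations; whether to scale, and whether to run on
concentrations or compositions, genuinely changes the variance split, so
both are exposed (`scale=`, or feed `composition()` output) rather than
hidden.

## Carbocation cascades and flux

The packaged `data/cascade_map.tsv` assigns each flower sesquiterpene to
the cation intermediate its biosynthesis requires: farnesyl (direct
deprotonation → linear farnesenes), humulyl (1,11-ring closure →
humulenes/caryophyllenes), (*E,E*)-germacradienyl (1,10-closure →
selinenes, valencene, germacrenes, elemenes), nerolidyl/bisabolyl
(FPP → NPP isomerisation).  The cation class of γ-cadinene, α-amorphene
and camphene is mechanistically unsettled in the literature we relied
on; their rows are marked provisional in the TSV and the map is config,
not code — `CascadeMap.reassign` moves exactly that compound's share
between two classes and nothing else (property-tested).

Flux profiles sum concentrations by class and divide by the class-subset
total.  Unknown compounds land in an explicit `unassigned` class that
stays in the denominator, keeping the named percentages conservative and
auditable.  Group profiles average replicates on the concentration scale
*before* forming percentages (percentages of mean blends, matching how
per-group summaries are drawn), not mean-of-percentages.

## Enzyme → product network

Product profiles are percentage spectra per enzyme, used as printed — no
renormalization.  The validation gate flags enzymes whose percentages sum
outside [90, 101] (sub-100 sums are normal in printed tables where trace
products are dropped).  Edges carry the printed weight; an edge is
`major` iff weight > `major_threshold` (strictly; default 10).  The
packaged product table contains two distinct rows both labelled
β-selinene; we preserve them as "beta-Selinene (a)"/"beta-Selinene (b)"
— a suspected typo in the source table, documented rather than silently
merged.  One figure caption in the source material describes the
major-edge rule inverted ("< 10% … thicker edge"); we follow the methods
text (> 10%, strict) and treat the caption as a typo.  Enzyme nodes are
colored by the cascade with the largest summed product percentage; ties
break lexicographically and are flagged.  GraphML and edge-TSV exports
round-trip losslessly; SIF carries topology and edge class only.

## Sequence screening

`find_longest_orf` returns the longest ATG-initiated, stop-terminated
reading frame across the three forward frames (ties: smallest start); the
reported span includes the stop codon, the protein does not.  Forward
frames only by default because cloned cDNA orientation is known in the
isolation workflow; raw inputs can be pre-flipped.  Premature-stop
classification is a length ratio against the reference protein with an
operational cutoff of 0.9 (boundary counts as full length); the cutoff is
an invented convention, surfaced as a parameter.  Motif patterns —
`RR.{8}W`, `DD..D`, `[ND]D[LIV].[ST]...E` — are explicit simplifications
of the literature consensus for the N-terminal RRx8W and the C-terminal
metal-binding DDxxD and NSE/DTE motifs, matched overlappingly and
overridable per call.

## Synthetic study conditions

The generators define the conditions every test and acceptance number is
computed under:

- **Probe designs**: random ACGT backgrounds (default genes 600 nt,
  probes 60-mers; tests use 24-mers on 150 nt genes for speed), probes
  planted with exact Hamming distances drawn from `mismatch_range`
  (default 0–2).  Backgrounds are rejection-sampled until no probe has
  any unplanted placement within 2 mismatches and every planted placement
  is minimal — the planted truth is therefore an *exact* oracle, not a
  statistical one.  `ambiguous_only_genes=k` reserves k genes whose every
  probe is ambiguous, fixing the retained-gene count at n − k.
- **Expression**: probe value = gene baseline (8.0) + N(0, 1), hotspot
  cells shifted by +3 (log2 units); the acceptance simulations use 20
  genes × 4 probes × 20 samples with a 5 × 5 planted block, so the
  summarized gene matrix has noise sd 0.5 — the four-probes-per-gene
  design the real platform intended.
- **Volatile study**: Muscat of Alexandria (MA), Sauvignon Blanc (SB),
  Shiraz (SH) × stages EL-18/EL-26 × 4 biological replicates × 12
  sesquiterpenes, one dominant compound per cultivar.  Replicate noise is
  multiplicative lognormal (default σ = 0.25): concentrations are
  positive and right-skewed.  The per-cell means were fixed once so the
  noise-free study reproduces the qualitative chemotype story — MA's
  (*E*)-β-farnesene 74% higher at EL-18 than EL-26, SH's
  (*E,E*)-α-farnesene rising 85% into bloom, > 10-point farnesene-flux
  increases in SB/SH, humulyl shares spanning ≈ 14.7–18.6% across the six
  groups, MA's total output lowest.  Peak tables are back-computed
  through the calibration curves and internal-standard area, so
  quantification recovers the truth exactly at σ = 0 (machine precision).

What the generators do *not* emulate: chromatographic peak shape,
retention time or spectral identity (quantification starts from
integrated areas); probe thermodynamics (binding is a pure sequence
rule); RMA itself (matrices are generated already normalized); biological
correlation structure between genes beyond the planted block.  Passing
tests therefore certify the computational pipeline — matching, averaging,
calibration algebra, percentage bookkeeping, detection — under known
ground truth, not the upstream measurement chemistry or array physics.

## Numerical conventions and degenerate inputs

- Seeds: every stochastic routine takes an explicit seed; identical seed
  ⇒ byte-identical outputs (manifest checksums verify this end to end).
- Percentage sums are asserted to 1e-9; round-trips at zero noise hold to
  ~1e-15 relative.
- Degenerate inputs fail loudly with the offending item named: non-nucleotide
  characters, duplicate probe/gene ids, constant rows under the
  correlation metric, zero-variance compounds under PCA scaling,
  zero internal-standard areas, zero reference means, identical
  calibration concentrations, empty sample lists, impossible probe
  designs.
- All-zero samples (compositions, flux) are excluded and reported, not
  errors; unknown compounds in flux are `unassigned`, never errors.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as comfortable for
a laptop: 1000 random instances for the scanner oracle, 100 random
designs for planted-truth recovery, 100 seeded simulations for hotspot
recovery, 10 random 24 × 12 matrices for the PCA cross-check.  The
full-scale inputs (the real platform's probe table against the curated
gene models; the published supplementary volatile table) drop into the
same entry points unchanged; those runs are validation exercises whose
outcome additionally depends on unrecorded details of the original
protocols (see the remapping section).

## Known limitations

- The hotspot detector is a heuristic for a task the original analysis
  did visually; its blocks depend on the stated cut-and-refine rules, and
  real atlas data need not contain blocks as crisp as the planted ones.
- Cascade assignment is a lookup, not a mechanistic prediction; novel
  compounds land in `unassigned` by design.
- The ≤ k-mismatch rule ignores hybridization energetics; two probes with
  equal mismatch counts can behave differently on a real array.
- Premature-stop classification compares protein lengths only; it cannot
  see internal deletions that preserve length.
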