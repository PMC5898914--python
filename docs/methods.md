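# Methods

This note documents the models and procedures implemented in `cortevo`,
the parameters that matter, what the synthetic data emulate, and the
numerical choices made where the design was genuinely open. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## The enrichment screen

Each of the five source datasets is consumed as a *summary table* — the
differential-expression statistics or correlation scores published with
the original studies — never as raw reads or counts. This mirrors the real
pipeline boundary: differential expression and correlation estimation
belong to the source studies, and re-running them is out of scope.

Two rule families cover all five datasets (`ScreenCriteria`):

* **Threshold rules** (Fietz-style zones, Florio/Johnson-style sorted
  populations): a gene passes if, for at least one qualifying contrast,
  `p < p_max` and `abundance >= min_abundance` with a positive effect
  direction. "Across all stages" is implemented as a conjunction over
  stages for the same contrast (a literal reading; `across_stages="any"`
  relaxes it). Direction comes from a signed `log2fc` column when present,
  since the source datasets report effect direction differently; without
  it, rows are assumed pre-oriented progenitor-over-reference.
* **Correlation rules** (Miller-style laminar arrays, Pollen-style single
  cells): positive correlation above `pos_corr_min` with at least one
  target class, optionally a correlation below `neg_corr_max` with the
  excluded (neuron) class, optionally a detected-cell floor. The neuron
  rule is implemented verbatim as `corr < 0.03` even though that cutoff is
  slightly positive; a strict `corr < 0` variant is a configuration away.
  When sample pairing is configured, the positive criterion must hold in
  both samples of at least one stage pair.

Comparisons are strict exactly as printed (`<`, `>=`); ties at a threshold
fail. Defaults per dataset: p < 0.01 with FPKM floors 1.5 / 0.5 / 0.1
(Fietz / Florio / Johnson), correlation > 0.25 with stage pairing
(Miller), correlation > 0.1 positive and < 0.03 with neurons with a 9-cell
floor (Pollen).

Intersection uses support counts: a gene is catalogue-enriched when found
in ≥ 2 of the 5 sets. The published per-screen set sizes (2780, 3802,
2030, 4391, 1617; 3458 intersected) require the original external
datasets and are deliberately not reproduction targets.

**Overlap metric.** The published pairwise-overlap heatmap does not state
its formula; the default here is `over_min = |A∩B| / min(|A|,|B|)`
because the published 32–60% range is sensitive to unequal set sizes.
`jaccard` and `over_mean` are available, and the metric used is visible in
the output.

**Over-representation.** Term enrichment is the exact hypergeometric upper
tail `P(X >= overlap)` (scipy), adjusted by Benjamini–Yekutieli
(statsmodels), which controls FDR under arbitrary dependence — the
appropriate choice for nested GO-like terms. Significance defaults to
adjusted p < 0.05.

## ORF intactness and gene dating

`scan_orf` consumes a gapped pairwise alignment of an ortholog against a
reference CDS (start codon, terminal stop, length divisible by 3; the
alignment itself is an input — codon-aware alignment construction is out
of scope). Indels are processed left-to-right with a cumulative
reading-frame phase:

* a stop codon reached while the phase is shifted, or a shift never
  compensated by the end of the alignment, is a **frameshift** (event at
  the position where the uncompensated shift began);
* an in-frame stop strictly before the reference's terminal codon is a
  **premature stop** (event at that codon);
* otherwise the ortholog is **intact**. Compensating indels that restore
  phase before any stop therefore do not break the gene, and in-frame
  indels never do.

The predicted protein length is the number of codons translated from the
ortholog's own start to its first stop. An all-gap ortholog is
**missing**. A deliberate consequence of this contract: a terminal
frameshift that leaves the frame open to a *new* downstream stop (the
PTTG2-style 1-bp insertion) is flagged rather than called intact; the
published clade calls in the packaged catalogue already encode the
authors' judgment on such cases, so the scanner's stricter rule affects
only synthetic orthologs.

`assign_clade` dates a gene as the MRCA of the species with intact
orthologs, requiring the human ortholog to be intact (the catalogue is
conditioned on human expression). Broken descendants inside the clade do
not pull the assignment tipward, and adding an intact species can only
move it rootward. When the MRCA node carries no clade label the nearest
labeled ancestor is used. The eight clade labels (Homo … Haplorrhini)
form a nested chain toward the human leaf; "Homo" names the terminal
branch to human, and the two human sub-categories (before/after the
Neandertal–Denisovan split) are annotation flags, not branches.

`branch_birth_rates` compares per-branch birth counts with neutral branch
lengths: global rate λ = total births / total length, per-branch upper
tail `P(X >= k)` under Poisson(λ·length), outlier at p < α (default
0.05) — a reproducible replacement for the visual outlier call. Branch
lengths are user-supplied Newick; the bundled `primate_tree.nwk` carries
*illustrative* neutral-substitution lengths for demonstration only, since
the study's neutral branch lengths are not published. Outlier calls on
real data therefore depend on the user's tree.

## Paralog-specific read classification

Ancestral/derived mRNA pairs are aligned globally with affine gap scoring
(match +2, mismatch −3, gap open −8, extend −1 — standard
megablast-magnitude parameters; exposed as arguments). The **core** is
the column span between the first and last both-aligned column, trimming
unalignable termini automatically (the original analysis trimmed
manually). The equal-length constraint of the original design is relaxed
to allow internal indels, because indel diagnostic sites are part of the
same design; both core lengths are reported.

Diagnostic sites are every mismatch column (SNP) and every maximal
one-sided gap run (indel), in alignment order, with coordinates in both
cores (0-based, half-open; an indel's position on the gapped side is the
insertion point).

`classify_reads` implements unique zero-mismatch alignment as exact
substring search: a read is paralog-specific iff it occurs exactly once in
that core (either strand) and never in the other; both-core occurrence or
multiple occurrences within one core → ambiguous (multi-mapper
suppression); no occurrence → unassigned; reads containing N never match.
A palindromic read (equal to its reverse complement) counts once per
position, not once per strand. With error-free reads this is exactly
equivalent to unique exact-match alignment and is fully reproducible.

Quantification reports raw and per-million-normalized specific-read
counts per cell population (both normalizations, since the published bar
heights do not state theirs); ambiguous and unassigned reads are reported
but excluded from paralog counts. TPM aggregation sums transcript TPM over
protein-coding transcripts only (linear by construction). Profile
comparison takes per-population medians; the total-level ratio is
sum(derived)/sum(ancestral), the level verdict uses a configurable fold
threshold (default 2), and the cell-type pattern is concordant iff all
pairwise median comparisons share their sign between the two genes (a tie
in one gene but not the other is discordant).

## Comparative-Ct copy number

`relative_copy_number` implements the textbook ΔΔCt estimator with
amplification efficiency E as a parameter (default 2.0, perfect
doubling; the estimate is `E^-ΔΔCt`). Replicates aggregate by mean Ct
before differencing (median by flag); the replicate SD of the target Ct
is reported alongside. The estimator is invariant to any constant Ct
shift and returns exactly 1 for the reference species. Primer
compatibility is Hamming distance ≤ 1 over equal-length binding sites.

`amplicon_assignment` assigns each read to the locus with the strictly
best infix edit distance (edlib, both strands) within `max_mismatches`;
ties between loci are dropped from per-locus counts but retained in the
library size (conservative unique-hit counting), and specificity is
assigned/total × 100. Edit distance equals mismatch count at the default
`max_mismatches = 0` and is slightly more permissive than Hamming for
larger allowances (it also admits small indels).

The four validated gene families (ARHGAP11, FAM72, GTF2H2, SMN) are
encoded as assay designs: the human copy count is the ancestral gene plus
the catalogue's human-specific members plus co-amplified human-specific
paralogs outside the catalogue (*GTF2H2B*), giving 2, 4, 3 and 2 human
copies against single-copy chimpanzee and bonobo.

## Synthetic data

All generators are deterministic under a fixed seed (one numpy
`default_rng` stream per generator call) and emit a truth record covering
every generated entity.

* **Screen tables** (default 200 genes, 20 planted, margin 0.5): planted
  genes clear every threshold of their chosen datasets with a fractional
  margin; background genes *straddle* the thresholds on the failing side
  (near-miss p-values, abundances just under the floor, a failing stage,
  violated pairing, too-high neuron correlation, or a sub-floor cell
  count) and fail every dataset by construction, so planted recovery at
  min-sets 2 is exact by design. What passing shows: the rules and the
  intersection are implemented correctly — not that real data separate so
  cleanly; real summary tables have genes genuinely at the boundary.
* **Paralog pairs** (600 nt, 6 SNPs + 2 indels ≤ 3 nt, spaced, read
  length 50): edits are planted at recorded positions; both sequences are
  checked free of internal repeats ≥ read length so unique-occurrence
  classification is well posed. Reads are error-free, uniform-start,
  sense-strand — no sequencing-error model, GC bias or fragment-length
  distribution, so classifier results here bound real performance from
  above.
* **Ortholog sets** (100 codons): a random intact CDS is born on the
  origin node; each branch below it loses the gene independently with
  `loss_prob`, losses are inherited, and the human lineage is kept intact
  by construction (the catalogue conditions on an intact human gene).
  Broken species receive a 1-bp deletion or a planted TAG at a random
  internal codon. Species outside the origin clade are absent.
* **Ct tables** (3 replicates, noise SD 0.05 cycles, species offset SD
  0.3): measurement = target base Ct − log_E(copies) + species template
  offset + Gaussian noise; the offset is shared with the single-copy
  normalizer, as in a real ΔΔCt design, and cancels. With SD 0.05 and 3
  replicates, rounded integer-copy recovery for copies ≤ 4 exceeds 95%;
  the error budget is ΔΔCt SD = 2σ/√n cycles, and a 4-copy call tolerates
  only ~0.17 cycles of log₂ error, so noisier settings (σ = 0.1) fall
  measurably below that bar — the default is chosen to represent a
  well-run assay.

## Problem sizes

The shipped tests and drivers use deliberately small instances: 100–300
genes per screen table, 40–100-codon ortholog sets with 200–4000
replicates per recovery estimate, 600-nt paralog pairs with up to 20 000
reads, 1000 Ct simulations. These sizes give binomial standard errors
well inside the asserted tolerances while the full suite runs in seconds.

## Known limitations

* The harmonizer's one-to-many ID policy (an old ID mapping to several
  current IDs) is not modeled; maps are expected many-to-one or
  one-to-one, matching the fixture's needs.
* The ORF scanner judges intactness relative to a single reference
  alignment; it does not model alternative start codons, splice-variant
  rescue, or stop read-through, and it is stricter than expert curation
  for terminal frameshifts (see above).
* MRCA dating resolves non-monophyletic intact patterns mechanically;
  the original analysis resolved such cases by expert judgment.
* The bundled tree's branch lengths are illustrative; branch-rate outlier
  calls are only meaningful with user-supplied neutral lengths.
* Venn partitioning enumerates 2^n − 1 regions and is intended for the
  five-set case, not for large collections.
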