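# Methods

This note documents the models and procedures casforge implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Conservation profile and junction selection

The profile scores each alignment column by **mean pairwise identity**: over
all row pairs, a pair contributes 1 when both residues are identical and
non-gap, otherwise 0 (a gap against anything, including another gap, is a
mismatch). Scores are smoothed with a centred moving average of odd width
`window` (default 11 columns, roughly the width of the conserved motifs that
make usable junctions; the window truncates at the alignment edges). Mean
pairwise identity was chosen over entropy-based scores because it is
parameter-free and requires no background amino-acid frequency model; the
design requirement is only that junctions sit at local conservation maxima.

Junctions are selected **greedily**: gap-free columns are visited in
descending smoothed score (ties to the smaller column), and a column is
accepted only if, for *every* parent, its nucleotide position (3 × residue
index on that parent's CDS) is at least `min_segment_nt` from both CDS ends
and from every already-accepted junction. `min_segment_nt` defaults to
500 bp — exchanged segments should each span a substantial, domain-scale
stretch — and is measured on each parent's CDS rather than in alignment
columns because the constraint is physical (synthesis and recombination act
on DNA). Columns containing any gap are ineligible so every parent has a
well-defined crossover coordinate. Greedy selection is not guaranteed
optimal in adversarial geometries; the test suite verifies it against a
brute-force subset search on small alignments, where it attains the optimal
total score.

Coordinates throughout: sequence intervals 0-based half-open; alignment
columns 1-based. The crossover sits immediately **before** the junction
residue (the junction residue opens the downstream segment). The MSA is
consumed, not computed — any standard aligner can produce it, and
identity-dependent quantities shift by roughly a percentage point with
aligner choice.

## Chimera enumeration and assembly

Two deterministic schemes:

- **sequential** (1 crossover): parent A up to junction j, parent B after;
  J·P·(P−1) designs over J junctions and P parents, ordered by junction,
  then A, then B.
- **backbone-swap** (2 crossovers): the contiguous region between junctions
  i < j of a backbone parent is replaced by the donor's; C(J,2)·P·(P−1)
  designs over all backbones or C(J,2)·(P−1) for a fixed backbone.

At the study scale (9 parents, 6 junctions) these give 432 and 120
(fixed-backbone) designs, 552 combined. Design ids (`S{j}_{A}-{B}`,
`D{i}.{j}_{backbone}+{donor}`) are sortable and reproducible. Realized CDSs
are concatenations of donor CDS slices between projected junction
coordinates, so every segment is a verbatim donor substring and the
translation is exact by construction; `deduplicate` collapses designs whose
parents agree across a crossover and therefore realize identical proteins.

`design_gblocks` lays a CDS out as ≤ `max_fragment_len` (default 3000 nt,
synthesis-scale) fragments. Adjacent fragments share exactly
`homology_len` nt (default 40, the standard Gibson arm length); terminal
fragments carry `homology_len` nt of the flanking vector sequence. Merging
the overlaps once reproduces `vector_left[-h:] + CDS + vector_right[:h]`
exactly (pass the arm regions themselves to obtain the literal construct).
Overlap sequences are checked for uniqueness within a construct; collisions
(possible mis-assembly) are reported as warnings, not errors, since highly
repetitive constructs can still be assembled with care.

## Screen statistics

- Cutting efficiency: `(1 − a/b) × 100`, `a` = colonies with the targeting
  guide plasmid, `b` = non-targeting control. `a > b` clamps to 0% with a
  warning rather than reporting a negative efficiency.
- Colour-screen editing efficiency: `white/(white+coloured) × 100` — the
  standard reading of galK red/white (or lacZ blue/white) indicator plates.
- Transformation efficiency: CFU per µg of plasmid, with an optional
  plated-dilution factor.
- T7E1 indel rate: `100 × (1 − √(1 − (b+c)/(a+b+c)))` with `a` the
  undigested band and `b`, `c` the cleavage products. The square root
  accounts for heteroduplex formation between edited and unedited strands.

Binomial point estimates carry **Wilson score intervals** (default 95%,
via statsmodels); intervals are additive reporting and never alter the
point estimate. A dCas12a-binding "repression level" readout, where needed,
reduces to `cutting_efficiency` applied to antibiotic-selection colony
counts — an interpretation, since that assay has no separate formula.
`batch_table` applies a statistic row-wise to a count table and flags
malformed rows in an `error` column instead of dropping them.

## PAM-depletion screen analysis

Reads carry a randomized `pam_len`-mer (default 4, the NNNN library)
between two fixed anchors. Extraction slides both anchors over the read
with a Hamming-distance budget (`max_anchor_mismatches`, default 1; no
indels, for speed and determinism); reads with zero or multiple consistent
placements, or with non-ACGT bases in the PAM, are rejected into tallied
categories, so kept + rejected always equals the input count. Counting is
vectorized over same-length read batches. Read-quality filtering is off by
default (an optional minimum mean Phred is provided).

Frequencies are pseudocounted, `freq_i = (n_i + c)/Σ(n_j + c)` with `c = 1`
by default to keep logarithms finite (set 0 for exact-count work). Two
score conventions are implemented because the two natural readings of
"enrichment" differ:

- `log2_ratio` (default): `E_i = log2(Y_i/X_i)`, the log2 frequency change
  between the non-targeting (Y) and targeting (X) samples. A functional
  PAM is depleted from X, so it scores positive — the conventional sign.
- `ratio_of_logs`: `E_i = log2(Y_i)/log2(X_i)`, a ratio of log
  frequencies. Undefined where a frequency is 0 or 1; such PAMs are
  flagged and ranked last rather than scored.

Ranking is descending by score with lexicographic tie-break. The logo
matrix weights the top-k ranked PAMs by `max(score, 0)` and reports
per-position base frequencies (rows sum to 1) for rendering with any logo
tool. PAM orientation follows the Cas12a convention (5′ of the
protospacer); both-strand search is off by default because the amplicon is
directional.

## Off-target panel and summaries

The cassette panel perturbs three guide positions — by default one per
PAM-proximal, middle and PAM-distal third (positions ⌈L/6⌉, ⌈L/2⌉, ⌈5L/6⌉;
4, 10 and 17 on a 20-nt guide) — with one substitution, one single-base
deletion and one single-base insertion each: nine cassettes, every one at
unit edit distance from the guide. Substituted (and inserted) bases default
to the **transversion** partner of the guide base (A↔T, G↔C), which
maximally perturbs base pairing; transition or fixed-base policies are
available. The exact positions are configurable because they are a design
choice, not a derivable quantity.

Site-to-target annotation uses Needleman–Wunsch global alignment (match +1,
mismatch −1, gap −2) restricted to length differences ≤ 2. Among equal-score
alignments the one with leftmost gaps is reported, implemented as a
forward traceback that prefers a target-gap, then a site-gap, then a
diagonal step whenever each lies on an optimal path; the tests verify exact
agreement with an independent exhaustive-recursion oracle.

The off-target share of a site/count table is
`100 × Σ(off reads) / (on reads + Σ(off reads))` after dropping sites with
reads ≤ `min_reads` (default 10; the filter is strict — a site must exceed
the threshold). This off/(on+off) convention is the one consistent with
reporting 0% when no off-target site passes and with sub-percent shares at
high on-target counts. Upstream processing of genome-wide assays
(read merging, mapping) is consumed as a finished table, never computed.

## Synthetic data generators

All generators are pure functions of their config; a single seed fans out
to fixed per-generator substreams.

- **Ortholog family**: a uniform-random ancestor; inside evenly spaced
  planted blocks (default 6 blocks × 15 aa in 1300 aa) every parent copies
  the ancestor; outside, parent i copies with probability q_i and otherwise
  mutates uniformly over the other 19 residues. The q_i are spaced so that
  realized overall pairwise identities span the configured band (default
  33.8–42.99%, the low-identity regime of diverse Cas12a-type sets),
  solving q² + (1−q)²/19 = t for the band edges after discounting the
  conserved-block floor. At length 1300 the binomial fluctuation of a
  single pairwise identity is ±1.4 points, so realized band edges scatter
  by roughly ±3 points; the mean sits within ±0.05 of the band midpoint.
  CDSs are back-generated with uniform synonymous codons. No phylogeny or
  indels are simulated — the alignment is trivially gap-free, so gap
  handling is exercised only by hand-built fixtures, and real alignments
  will have junction-projection ambiguity the generator cannot produce.
- **PAM screen**: non-targeting sample multinomial-uniform over 256 PAMs;
  targeting sample with functional PAMs (default TTTV) down-weighted by
  `depletion_factor` (default 0.01) and renormalized; 10⁵ reads per sample
  by default, built as anchor+PAM+anchor with uniform substitution errors
  (rate 0.001). No PCR bias, indel errors or quality-score structure.
- **Colony counts**: `a ~ Binomial(n_plated, 1 − efficiency)` against a
  full control plate (killing), or `white ~ Binomial(n_plated, efficiency)`
  (colour). Plate-to-plate overdispersion is not modeled, so interval
  coverage on real colony data will be somewhat below the binomial nominal.
- **Off-target tables**: decoy sites at 1–4 substitutions from the guide;
  reads multinomial over sites with a nonincreasing per-mismatch propensity
  curve; the truth records the propensity-mass off-target share.

Passing recovery tests on these generators shows the pipeline is correct
under its own assumptions (independent reads, binomial counts, gap-free
families); it does not validate aligner choice, sequencing artifacts or
biological escape dynamics on real data.

## Numerical choices and problem sizes

- Wilson bounds are clamped to [0, 1] against floating-point excursions at
  zero counts; efficiency intervals always bracket the point estimate.
- Greedy junction ties break to the smaller column; enrichment ranking ties
  break lexicographically; all output orders are deterministic.
- Recovery and calibration suites use 100 seeded replicates at the default
  generator scales (nine 1300-aa parents; 10⁵ reads per screen sample;
  200-colony plates), sizes at which the planted effects are comfortably
  identifiable while a full run completes in well under a minute.
- Formula and alignment checks run against independent oracles
  (exact-rational arithmetic; exhaustive recursion) on 1000 and 500 random
  inputs respectively.

## Known limitations

- Junction selection reproduces the stated constraints (conservation
  maxima, minimum segment span, gap-free columns); where experts also used
  structural domain boundaries, their specific choices are not recoverable
  from sequence alone.
- The exact composition of a physical chimera library depends on scheme
  and exclusions; casforge reports scheme-exact counts (432 + 120 = 552 at
  the study scale) rather than asserting any particular published total.
- `ratio_of_logs` scores are scale-dependent (they change with pseudocount
  and library size in ways `log2_ratio` does not); the default mode is the
  log2 frequency change.
- The global aligner is intended for near-cognate sites (length difference
  ≤ 2); it is not a general-purpose aligner.
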