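# Methods

## The screening model

The package prioritizes candidate regulators by set arithmetic over
thresholded contrasts, not by statistical testing. This mirrors how small
multi-genotype designs (three genotypes × two biological replicates) are
screened in practice: with n = 2 there is no usable dispersion estimate, so
the procedure operates on replicate means and explicit fold thresholds, and
every reported quantity is a count over named gene sets. No p-values or
multiple-testing corrections are computed anywhere — adding them would
misrepresent the procedure's evidential basis.

### Transcriptome cascade

* **Presence.** A gene is *expressed* in a genotype when its mean FPKM is at
  least `presence_min_fpkm` (default 0.02), inclusive. All inclusive
  comparisons apply a `tolerance` of 1e-9 (on the FPKM or log₂ scale) so
  that effects planted as exact ratios pass deterministically.
* **Fold-changes.** For each pair (p1 = high vs low mutant, p2 = high
  mutant vs parent, p3 = low mutant vs parent), log₂FC = log₂ of the ratio
  of replicate means, defined only when both means pass the presence
  threshold. The classic rule discards pairs where one genotype has zero
  FPKM (absence is uninterpretable); we generalize it to the presence
  threshold so that a 0.001-FPKM denominator cannot manufacture a huge
  fold. An excluded pair carries an explicit reason and can satisfy no rule
  clause.
* **Identity constraint.** For a gene expressed in all three genotypes,
  log₂FC(p1) = log₂FC(p2) − log₂FC(p3) holds algebraically. A consequence
  used throughout: such a gene cannot be ≥ 4-fold DE *unique* to one pair,
  so strong unique-pair candidates necessarily arise via pair exclusion.
* **Candidate rules** (F = log₂ `candidate_fold`, default log₂ 5), applied
  per DE-Venn region: U1 (unique to p1, |log₂FC₁| ≥ F), U2 (unique to p2),
  C12 (p1∩p2 only, same sign and ≥ F in both), C123 (all three pairs:
  same-sign ≥ F in p1 and p2 and opposite-sign ≥ F in p3 — the two mutants'
  effects bracket the parent). U and C12 rules are direction-symmetric even
  though a given study may observe only one direction; the criteria are
  magnitude thresholds. Regions p13-only, p23-only and unique-p3 yield no
  calls because p3 does not involve the high-amylose line. Direction
  (positive/negative regulator) is the sign of the high-amylose-line fold.

### qPCR screen

ΔCt = mean Ct(gene) − mean Ct(reference) per (genotype, stage); replicates
(technical and biological are not distinguished) pool by arithmetic
averaging. ΔΔCt between genotypes gives relative expression 2^(−ΔΔCt), with
amplification efficiency fixed at perfect doubling (no efficiency
correction). The negative rule (QN) demands log₂ relative expression ≤ −1
(≥ 2-fold lower — the study reports "lower expression" without a numeric
cutoff; we adopt the 2-fold convention used everywhere else and expose it
as `qpcr_negative_log2`) in both p1 and p2 at all three stages: same
direction and at least 2-fold at every stage. The positive flag (QP)
demands log₂ ≥ +2 in both pairs at both late stages (28, 35 DAA); QP genes
are reported but never counted in the candidate total, matching the
arithmetic 19 transcriptome + 5 QN = 24.

### Correlation screen

Pearson r is computed on ΔCt values directly (the source-data convention;
note ΔCt is inversely related to expression, but since expression is a
monotone decreasing function of ΔCt, two genes positively correlated on the
ΔCt scale are also positively co-expressed). Profiles are the 9 grid points
flattened genotypes-in-design-order × stages-ascending; this order is fixed
so r is reproducible bit-for-bit. "Moderate" correlation is |r| ≥ 0.3
(inclusive) — the conventional moderate cutoff, exposed as `moderate_r`.
The CORR rule (r_GBSSI ≤ −0.3 and r_SBEIIb ≥ +0.3) annotates genes already
identified elsewhere; it never adds to the total. Constant or incomplete
profiles are skipped with a warning rather than failing the screen.

### Integration

Candidates merge by gene id; the grand total counts unique genes carrying a
transcriptome rule or QN. A gene called positive by one source and negative
by another is surfaced as `conflicting` and excluded from totals — silent
resolution would hide a real data problem.

### Promoter scan and protein properties

All four motifs (ACGT, CACGTG, GACGTC, TACGTA) are reverse-complement
palindromes, so single forward-strand scanning reports every
double-stranded occurrence (property-tested). Overlapping matches count at
every start — the information-preserving choice, since the convention is
unspecified in most reports; box hits are tallied separately from (and in
addition to) core hits. Sequences longer than `upstream_limit` (default
1000 bp) keep their 3′-most bases, those nearest the ORF. Coordinates are
1-based inclusive in the hit list and BED-style 0-based half-open in the
exported table.

Protein molecular weight is the sum of average residue masses plus one
water (18.02 Da); GRAVY is the plain mean of Kyte–Doolittle indices;
theoretical pI solves net charge = 0 by bisection on pH ∈ [0, 14] to 1e-4,
with Henderson–Hasselbalch charges over the termini and D/E/C/Y/K/R/H side
chains using the Bjellqvist pKa set (the ExPASy ProtParam convention;
tables imported from Biopython's data modules). Net charge is strictly
decreasing in pH, so the root is unique. Ambiguity codes are rejected, not
guessed: a silently substituted residue corrupts the charge balance.

## Synthetic generators

The generators exist because studies of this design typically leave the raw
transcriptome undeposited; validation therefore runs against planted ground
truth recorded in a JSON manifest that round-trips losslessly.

### Expression

Genes are allocated to presence-Venn regions, DE-Venn regions and candidate
classes; allocations are scattered across gene ids by a seeded permutation.
For a gene expressed in all three genotypes, FPKMs are baseline × 2^effect
with (f2, f3) planted and f1 = f2 − f3, so the identity constraint holds by
construction. Unique-pair candidates (≥ 5-fold) are realized by setting the
third genotype's FPKM to exactly zero — the only construction consistent
with the identity — which also places them in the corresponding
two-genotype presence region; weak (2- to < 4-fold) unique-pair genes live
in the all-three region with cancelling sub-threshold effects in the other
pairs. Configurations that violate these feasibility constraints (e.g. more
exclusion-based candidates than two-genotype slots, planted candidate
effects below the 5-fold rule) are rejected with a diagnostic naming the
class.

Defaults are the study-replica conditions: 370 genes, two replicates,
presence regions (all-three 177, high∩low 20, high∩parent 27, low∩parent
13, unique-high 12, unique-low 31, unique-parent 9, silent 81). The
marginals 236/241/226 with union 289, center 177 and unique-high 12 leave
one degree of freedom in the three-set system; high∩low-only is fixed at 20
(any value in [11, 47] is consistent) so results are stable. DE occupancies
are (18, 8, 15, 9, 23, 35, 39) for (unique-p1, unique-p2, unique-p3, p1∩p2,
p1∩p3, p2∩p3, all-three), summing to 147; the unique-p3 count is the value
forced by the total. Planted candidates: U1 2 up + 3 down, U2 1 down, C12
7 down, C123 3 up + 3 down, all at |log₂FC| = 2.5 (≈ 5.7-fold, comfortably
past the 5-fold rule without sitting on the boundary).

Numerical choices: baselines are log-normal (natural-log mean 2.0, sd 1.0 —
median ≈ 7.4 FPKM, a typical moderately-expressed gene) floored at 0.5 FPKM
so that every planted effect (down to 2^−2.5) stays above the presence
threshold; silent cells are uniform on [0, 0.019]; genes unique to the high
mutant are uniform on (0.02, 0.5), reflecting the observation that such
genes sit at trace expression levels; replicate noise is multiplicative
log-normal (exp N(0, sd)), preserving non-negativity and exact zeros, with
sd = 0 in the replica preset so recovery is exact.

### qPCR / correlation

The GBSSI ΔCt profile is a pure genotype contrast (−a, +a, 0 cycles in
high/low/parent; a = 2, i.e. GBSSI expression elevated in the high-amylose
line) and the SBEIIb profile a pure stage trend (−c, 0, +c across 21/28/35
DAA; c = 2). The two profiles are centered, orthogonal and of equal norm,
so a background gene built as α·g + β·s has Pearson sign class exactly
(sign α, sign β) at zero noise, and |r| against each anchor is set purely
by the α:β ratio. Background weight ratios are chosen so that (i) no
background gene crosses the moderate-|r| cutoff on the GBSSI axis, and
(ii) no background gene's genotype contrast reaches the QN/QP fold rules
(|4α| < 1 cycle). QN genes add a +2-cycle shift in the high-amylose
genotype (4-fold lower expression at every stage); the three
correlation-overlap QN genes carry a stage-trend weight β = 1 (r ≈ −0.43 /
+0.87 against GBSSI/SBEIIb), the other two β = 0.15 (r_SBEIIb ≈ +0.25,
below the cutoff). QP genes subtract 2 cycles at the two late stages only.
The replica occupancy (31 positive with GBSSI, 34 with SBEIIb, 14 with
both, over 52 genes) is stated as margins and solved to background class
counts, rejecting infeasible tables. Ct = 20 + ΔCt + 5 (reference at a
constant Ct of 20, targets ~5 cycles above it); three technical replicates
with optional Gaussian Ct noise (sd 0 in the preset).

In pipeline runs the 52 qPCR target ids are drawn from the synthetic
expression gene set, disjoint from the planted transcriptome candidates, so
the integrated total is 19 + 5 = 24 as in the study design where the qPCR
negatives were distinct from the transcriptome candidates.

### Promoters and proteins

Promoters are i.i.d. backgrounds at a configurable GC fraction (default
0.45, typical of plant promoter regions) with motifs planted at explicit
non-overlapping positions. Because the background can create extra
occurrences, the manifest's counts are recomputed by brute-force scan of
the finished sequence — the manifest, not the plant plan, is the
authoritative truth. Protein sequences are uniform over the 20 standard
residues with lengths spanning the 129–920 range observed across the wheat
bZIP family.

### What the generators do not emulate

Sequencing depth, FPKM estimation noise, homoeologous wheat loci, EMS
mutation spectra, realistic gene-gene correlation structure in the
transcriptome, amplification-efficiency variation in qPCR, and motif
clustering/positional bias in promoters. Passing the recovery tests
demonstrates that the screening arithmetic is implemented exactly as
specified and is invertible on data that satisfies its assumptions; it does
not demonstrate robustness to the biological and technical variability of
real mutant-line data (the Ct-noise recovery test probes only a narrow
slice of that).

## Problem sizes and determinism

All validation runs use the study-scale designs (370 genes × 3 genotypes ×
2 replicates; 55 qPCR genes × 9 grid points × 3 replicates; 100 × 1 kb
promoter scans), which complete in seconds. A single integer seed drives
every stochastic draw through one `numpy` generator per dataset; the replica
presets are noise-free, so their screen outputs are identical across seeds
and byte-identical across reruns at the same seed.

## Known limitations

* The screen is threshold arithmetic; it inherits the fragility of hard
  cutoffs near boundaries (mitigated by the 1e-9 tolerance, which makes
  inclusive boundaries deterministic but cannot help data that genuinely
  straddles a threshold).
* Correlations on 9-point profiles are descriptive; with n = 9, |r| = 0.3
  is far from significant, which is why no p-values are attached.
* The pI model ignores conformational effects and cysteine oxidation state,
  as all sequence-only pI calculators do.
* `QpcrTable` assumes exactly three stages; other stage designs would need
  the QN/QP rules re-parameterized.
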