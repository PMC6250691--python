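# bzipscreen

Candidate bZIP transcription-factor prioritization for high-amylose wheat.

High-amylose (resistant-starch) wheat lines can be raised by EMS mutagenesis,
but the regulators behind the amylose shift are largely unknown. Given a
high-amylose mutant, a low-amylose mutant and their shared parent variety,
`bzipscreen` implements the threshold-based screening cascade used to
prioritize bZIP transcription factors as putative positive or negative
regulators of amylose biosynthesis:

1. **Transcriptome screen** — per-genotype presence calls (mean FPKM ≥ 0.02)
   and their three-set Venn decomposition; pairwise log₂ fold-changes of
   replicate means over the pairs p1 = high vs low mutant, p2 = high mutant
   vs parent, p3 = low mutant vs parent, with a gene excluded from a pair
   when either genotype is below the presence threshold; 2-fold
   differential-expression (DE) sets and their Venn; and four region-based
   candidate rules at a stringent 5-fold cutoff (unique-to-p1, unique-to-p2,
   shared p1∩p2, and all-three-pairs with the mutant effects bracketing the
   parent).
2. **qRT-PCR screen** — ΔCt normalization to the ARF reference gene,
   relative expression 2^(−ΔΔCt) per genotype pair and seed-development
   stage (21/28/35 days after anthesis), a three-stage negative-consistency
   rule (≥ 2-fold lower in the high-amylose line in both pairs at every
   stage) and a late-stage positive flag (≥ 4-fold higher at 28 and 35 DAA).
3. **Correlation screen** — Pearson r of each gene's ΔCt profile against the
   two key starch genes GBSSI (amylose synthesis) and SBEIIb (amylopectin
   branching); genes with moderate negative correlation to GBSSI and
   moderate positive to SBEIIb (|r| ≥ 0.3) are corroborating candidates.
4. **Promoter scan** — exact-match scanning of ≤ 1 kb upstream sequences for
   the ACGT core and the palindromic bZIP boxes G (CACGTG), C (GACGTC) and
   A (TACGTA).
5. **Protein properties** — length, average molecular weight, theoretical pI
   (Bjellqvist pKa set, bisection) and GRAVY (Kyte–Doolittle mean).

Because screens of this kind are usually run against undeposited in-house
transcriptomes, the package ships first-class synthetic generators
(`bzipscreen.synthetic`) that plant every class — presence regions, DE
regions, candidate rules, qPCR classes, correlation sign classes, promoter
motifs — with a ground-truth manifest, including deterministic
*study-replica presets* that reproduce the published set arithmetic of the
wheat TAC 75 / TAC 6 / C 306 study (370 bZIP genes, 19 + 5 = 24 candidates).

## Worked example

```sh
bzipscreen run --preset study-replica --seed 1 --out out/
```

prints

```json
{"by_direction": {"negative": 19, "positive": 5}, "conflicting": 0, "correlation": 3, "grand_total": 24, "qpcr_negative": 5, "qpcr_positive_flags": 2, "transcriptome": 19}
```

i.e. the transcriptome cascade yields 19 candidates (5 putative positive
regulators, 14 negative), the qPCR screen adds 5 distinct negative
candidates (24 unique genes in total), 2 genes are flagged as late-stage
positives outside the total, and 3 of the qPCR negatives are corroborated
by the correlation rule. `out/` contains every intermediate: presence and
DE Venn memberships, fold-change tables, ΔCt profiles, per-screen candidate
TSVs, the integrated report (JSON + TSV) and the generator manifests.

The same cascade runs on real data from files:

```sh
bzipscreen screen-expression --matrix expression.tsv --out out/
bzipscreen screen-qpcr --ct qpcr.tsv --out out/
bzipscreen screen-correlation --ct qpcr.tsv --out out/
bzipscreen scan-cis --fasta promoters.fasta --out out/
bzipscreen protein-props --fasta proteins.fasta --out props.tsv
```

Library use mirrors the CLI:

```python
from bzipscreen import run_expression_screen
from bzipscreen.synthetic import generate_expression, replica_preset

matrix, manifest = generate_expression(replica_preset(seed=1))
result = run_expression_screen(matrix)
result["summary"]["candidates_by_direction"]   # {'positive': 5, 'negative': 14}
```

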