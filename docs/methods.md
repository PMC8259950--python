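# Methods

## The affinity model

TBP recognition of a core promoter is treated as three coupled steps —
one-dimensional sliding along DNA, retardation at a TATA/TBP-site, and
fixation of the complex by bending the helix — and collapsed into one
additive score per 15-bp window on the −ln(K_D) scale:

    S = w0 + w_pwm·PWM + w_ta·mean(ta_richness)
           + w_mg·mean(minor_groove_width) + w_melt·mean(melting)

* `PWM` is the sum of log-frequency weights of the packaged 15-position
  TATA matrix (counts → frequencies with a +0.5 pseudocount → natural log).
  Rows 1–8 carry the canonical TATAWAWR core; rows 9–15 a mildly G/C-biased
  downstream context.
* The three dinucleotide terms average a property over the 14 steps of the
  window: `ta_richness` (fraction of A/T bases per step, 0/0.5/1),
  `minor_groove_width` (Å; A/T-rich steps narrow), and `melting`
  (nearest-neighbour duplex ΔG°37, kcal/mol; less negative = easier local
  melting). All three tables are reverse-complement symmetric, which is
  what makes the whole scan strand-symmetric.
* `w0` absorbs non-specific TBP–DNA affinity and sets the absolute scale;
  `w_mg` is negative (narrow, deformable grooves favour the bent complex)
  and `w_melt` positive (easy melting favours fixation).

A promoter's **affinity estimate** is the maximum window score over every
window on both strands (configurable to sense-only). Ties resolve to the
sense strand, then the 5'-most offset, so results are bit-deterministic.
The **standard error δ** is the sample standard error of the top-K window
scores (K = 10 by default): the scan's own score spread around its maximum,
which is reproducible, scan-local, and positive on any non-degenerate
promoter. An additive score in −ln(K_D) corresponds to a multiplicative
decomposition of K_D itself; the additive form was chosen for
transparency and is exposed term-by-term via the scorer's explain mode.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| w0 | 29.0 | non-specific baseline, −ln(K_D) units; puts typical promoters in the 12–22 range |
| w_pwm | 1.0 | weight of the log-frequency PWM sum (dominant term) |
| w_ta | 0.2 | TA-richness context (dimensionless property) |
| w_mg | −0.1 | minor-groove width, per Å |
| w_melt | 0.1 | duplex stability, per kcal/mol |
| L | 15 | TBP footprint |
| top_k_for_se | 10 | windows entering δ |
| alpha | 0.05 | significance level of the allele comparison |

The context weights are deliberately small relative to the PWM term: the
smallest per-row log-frequency gap of the matrix (0.15) exceeds the largest
possible context change of a single-base edit (≈0.08), which guarantees
that replacing any base of the best window with the matrix-preferred base
never lowers the promoter's value (a property the test suite asserts).

### Calibration

The weights and matrix were calibrated once against the synthetic
generator, before the downstream analyses were built, to a pre-registered
target: consensus-damaging core mutations should be called significant
deficiency at α = 0.05 in at least 80% of cases, with at most 10% of
neutral variants called significant. The shipped defaults achieve 83–88%
damage sensitivity and 0% neutral false-significance across independent
generator seeds (200 variants per class); they have not been adjusted
since.

## Allele comparison

The minor allele is produced by editing the variant into the basic
sequence (substitutions in place; indels change the length — no re-padding
to 70 bp, mirroring free-text editing of the scanned sequence). Both
alleles are scored independently and compared with Fisher's Z; the
two-sided normal tail converts Z to p, reflecting the symmetric two-branch
alternative (deficiency vs excess). If both standard errors are zero while
the values differ, Z is infinite; the comparison is flagged degenerate and
reported with a p = 0 sentinel and a warning rather than an exception.

## Markers, tallies, and selection-mode tests

A per-gene catalog maps an expression deficit or excess to a disease
effect (aggravate/relieve rheumatoid arthritis). Narrative
"complication/comorbidity-risk" effects are binarised to *aggravate*, so
every significant marker maps to exactly one direction and the
conservation laws N_> + N_< = N_R and N_↑ + N_↓ = N_R hold identically.
Gene symbols match case-insensitively (human symbols are upper-case,
rodent orthologs title-case).

The drift column uses the one-sided exact binomial upper tail
P(X ≥ N_> | n, ½) because its null is directional (damaging variants are
expected to outnumber improving ones under neutral evolution); the
↑↓-equivalence column uses the doubled-tail two-sided binomial
min(1, 2·min(P(X ≤ k), P(X ≥ k))), chosen over "sum of small p" for
reproducibility. Tails are computed with scipy's exact binomial
distribution functions, which remain accurate far into the tails at
n ≥ 10⁵, and are verified against full enumeration for all n ≤ 20.

## Cross-validation against domestication DEGs

Published DEG summaries (dataset, species pair, tissue, gene, log2 fold
change domestic-over-wild, adjusted p) are filtered at P_ADJ ≤ 0.05. The
threshold is inclusive because the retained published records themselves
print P_ADJ = 0.05. Animal genes pair to annotated human genes by
case-insensitive symbol with a small alias table for species-specific
locus names (Hbbl → HBB); sequence-level homology is out of scope. Each
DEG is read as divergence from the nearest common ancestor: the domestic
lineage is in excess iff log2FC > 0, the wild lineage always in the
complementary state; log2FC = 0 has no direction and is excluded with a
warning. Both lineage states map through the catalog to disease effects
and accumulate into a 2×2 lineage × effect table in which each ortholog
pair contributes one count per row (margins = pair count).

Statistics on the table:

* **Pearson χ²** (1 df), uncorrected by default, with the Yates-corrected
  statistic also reported. The headline statistic is the uncorrected one.
* **Fisher's exact test**, two-sided by the sum-of-smaller-point-
  probabilities rule (point probabilities ≤ the observed one within a
  1e−12 relative tolerance), computed by hypergeometric enumeration over
  all tables with the observed margins.
* **Per-lineage exact binomials**, one-sided on the larger cell of each
  row, testing each lineage's aggravate/relieve split against ½.

Tables with a zero column margin report NaN/1 for χ²/Fisher instead of
raising; those and single-pair tables carry a `degenerate` flag.

## The synthetic generator

`gen_promoters` draws i.i.d. background at a given GC content (default
0.5) and plants the TATA consensus 8-mer `TATAAAAG` at offset −30 (the
canonical TBP-site position); `box_strength` is the fraction of the eight
consensus positions planted. `gen_snps` derives variants with known ground
truth: *damage* mutates a planted consensus position to the matrix-worst
base; *improve* sets a non-preferred position inside the box window to the
matrix-best base; *neutral* substitutes a position at least 10 bp clear of
the best-scoring window and outside as many of the remaining top-K window
spans as the 70-bp geometry allows (the spans are peeled off lowest rank
first when they would otherwise block every position — on a 70-bp
promoter the union of ten 15-bp spans can cover the whole sequence).
`gen_deg_table` emulates the seven published DEG datasets (sizes
883/30/17/20/13/450/327, total 1740 by default) and plants a tunable
lineage-effect correlation (`frac_domestic_aggravate`, default 0.9) that
the recovery tests re-detect.

What the generator does **not** emulate: real promoters are not i.i.d.
background (CpG islands, Inr/DPE elements, phylogenetic footprints), real
minor alleles are not restricted to the three planted classes, and real
DEG tables carry correlated fold-change/significance structure. Passing
tests therefore demonstrate that the inference chain is correct and
well-calibrated under its own model, not that the affinity model's
absolute −ln(K_D) values are experimentally accurate — the published
regression coefficients behind the original affinity estimates are not
public, and this re-parameterisation reproduces the decision behaviour,
not the numeric scale.

## Numerical choices and degenerate inputs

* Offsets are 0-based internally and reported TSS-relative (−70…−1).
* Scan ties: sense strand first, then smallest (5'-most) offset.
* p-values are clamped into (0, 1]; the only 0 is the flagged degenerate
  Fisher-Z sentinel.
* δ = 0 promoters (e.g. homopolymers) are legal; comparisons against them
  fall through to the degenerate branch only if both alleles have δ = 0
  and different values.
* Edited sequences shorter than L raise an input error before scoring.

## Problem sizes

The shipped analyses are desk-scale: the cross-validation fixture has 11
pairs, the selection tests take printed counts directly, and the
recovery/property tests use 50–200 seeded promoters (each scanned over 112
windows), which keeps the full suite and the acceptance script in the
seconds-to-a-minute range on one CPU.

## Known limitations

* The affinity scale is internally consistent but not fitted to measured
  dissociation constants; only ordering and significance calls are
  meaningful.
* The gene catalog ships the ortholog-comparison genes plus MMP12; wider
  catalogs are user-supplied TSV/JSON.
* Ortholog pairing is symbol-based; paralog confusion (e.g. Hbb-like
  cluster members) is handled only through the explicit alias table.
* The two-sided Fisher rule and the doubled-tail binomial are conventions;
  other defensible conventions (mid-p, central intervals) give slightly
  different borderline p-values.
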