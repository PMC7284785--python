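# Methods

## Dose–response model

M1 damage endpoints (relative seedling survival, relative seed set) are
modelled with the single-hit multi-target (SHMT) survival function
S(D) = (1 − (1 − e^(−D/D₀))^N)·100, where D is dose in Gy, D₀ > 0 the
mean lethal dose and N ≥ 1 the extrapolation number. S(0) = 100 exactly,
S is strictly decreasing in D and increasing in N. The shoulder width is
summarized by the quasi-threshold dose Dq = D₀·ln N — a standard derived
radiobiology statistic adopted here because no other numeric shoulder
measure is in common use; Dq = 0 iff N = 1. Iso-effect doses come from
the closed-form inverse D = −D₀·ln(1 − (1 − S/100)^(1/N)), verified in
tests against numerical root finding to 1e−9 relative tolerance.

Fitting is nonlinear least squares on the percent scale
(`scipy.optimize.least_squares`) with bounds D₀ ∈ (0, 10·max dose],
N ∈ [1, 50]. The (D₀, N) likelihood surface is a curved ridge (larger N
trades off against smaller D₀), so the optimizer is multi-started from
N ∈ {1, 2, 4, 8} and the lowest-RSS solution kept. Replicates enter as
individual points (no pre-averaging), and responses above 100% are
retained because clipping them biases D₀ upward. A series with fewer
than three distinct doses is rejected; a series carrying no mortality
signal (no response below 80%) is returned with `converged=False` rather
than a spurious estimate, as is a fit pinned at the D₀ bound. On
noiseless generated curves the fit recovers (D₀, N) to better than 0.1%
relative error; at 3% Gaussian noise with 10 replicates per dose over
{0, 50, 100, 150, 200} Gy, D₀ is recovered within ±15% in ≥ 95% of
seeded replicates (the acceptance script reports the achieved rate).

## Progenitor-cell (chimera) model

The model for M2 segregation: an M1 plant's k harvested panicles are
allocated to P progenitor cells present in the dry-seed embryo; each
progenitor carries a scorable induced mutation independently with
probability m; each panicle from a mutated progenitor yields a detected
mutant in its M2 panicle row with probability d. The observable is
x ∈ [0, k], the number of mutant-bearing panicles per plant.

Allocation defaults to **balanced**: progenitors contribute ⌈k/P⌉ or
⌊k/P⌋ panicles, the remainder assigned at random — consistent with each
progenitor producing two or three panicles when k ∈ {3, 5} and P ≤ 6. A
**uniform-random** alternative (each panicle picks a progenitor
independently) is provided for sensitivity analysis. Under balanced
allocation the pmf of x is the exact convolution over progenitors of
(1−m)·δ₀ + m·Binomial(cᵢ, d); under uniform-random allocation it is the
binomial mixture Σⱼ C(P,j)mʲ(1−m)^(P−j)·Binomial(k, dj/P). Both are
algebraically identical to enumerating all 2^P mutation states (tested
against a brute-force enumerator) but cost O(P·k). Exact evaluation is
refused for P > 20 unless Monte-Carlo estimation is requested.

Detection defaults to d = 1: with 36 M2 seedlings scored per panicle, a
monogenic recessive mutation segregating 3:1 is seen with probability
1 − 0.75³⁶ ≈ 0.99997. d is exposed as a parameter because dominance and
seedling mortality in real data are unknown.

Inference of P conditions on plants with x ≥ 1 (the observable summary
in practice, and it removes the absolute mutation-rate scale from the
problem). For each P in the grid (default 1..6), m is profiled out by
bounded 1-D maximization (`minimize_scalar(method="bounded")` on
m ∈ (1e−6, 1−1e−6), xatol 1e−8) of the multinomial log-likelihood of the
conditional distribution; tables mixing several k are handled by summing
per-k log-likelihoods. The full profile is returned so flat regions are
visible; the argmax is taken with ties broken toward smaller P
(parsimony).

**Identifiability.** When k < P, balanced allocation gives some
progenitors zero panicles and (P, m) becomes observationally identical
to (k, m): with k = 5, the P = 6 model equals the P = 5 model for every
m, so P = 6 can never be selected (the parsimony tie-break returns 5).
Achieved recovery rates at m = 0.2, k = 5, d = 1, n = 2,000 plants
(100 seeded datasets each): P = 1: 100%, 2: 100%, 3: 100%, 4: 99%,
5: 74%, 6: 0%. Recovery claims are therefore anchored at P = 4, where
the model is well identified.

Mutation frequencies are reported on two bases: plant (share of M1
plants with ≥ 1 mutant-bearing panicle) and panicle (share of all
harvested panicles bearing mutants). With a common k per table — the
experimental design here — plant-basis ≥ panicle-basis always; the
report module emits every frequency with its denominator because
small-n groups are otherwise easy to over-interpret.

## Variant consensus pipeline

Stage order is fixed: per-caller calls → left-normalization → background
exclusion → depth/allele-fraction filter → three-caller intersection →
annotation. Every stage only removes or annotates records; per-stage
removal counts go to the run log.

* **Parsing.** VCFs are read with cyvcf2; multi-allelic records are
  split per alt allele. DP comes from FORMAT DP (fallback INFO DP); AF
  from FORMAT AF, else alt-reads/DP from AD, else INFO AF. Records with
  neither are excluded and counted.
* **Normalization.** Indels are left-aligned and trimmed to the minimal
  representation keeping one anchor base (idempotent; tested against
  `bcftools norm` on crafted homopolymer cases). At position 1 the
  trailing shared base is kept since no left anchor exists.
* **Background exclusion.** A normalized (chrom, pos, ref, alt) key seen
  in ≥ 2 samples' call sets (per-sample sets pooled over callers,
  computed before quality filtering; the unirradiated control is one of
  the samples) is removed from every sample. Matching is exact — no
  positional tolerance for near-miss indel representations — and by
  site, not genotype.
* **Filter.** 10 ≤ DP ≤ 100 and AF ≥ 0.25, all boundaries inclusive.
* **Consensus.** Three-way intersection on the normalized key; the
  consensus record's DP/AF are taken from the first caller
  (deterministic provenance; max/mean alternatives were rejected for
  reproducibility simplicity).
* **Classification.** The 12 ordered substitutions collapse to 6
  strand-symmetric classes; C:G>T:A and T:A>C:G are transitions. InDel
  size is |len(ref) − len(alt)| after normalization, with the spectrum
  reported over 1–50 bp plus an overflow bin.
* **Annotation.** Region by precedence exonic > splicing > UTR5/UTR3 >
  intronic > upstream/downstream > intergenic, with a 1-kb
  strand-aware flank and splicing defined as ±2 bp around intron
  boundaries (the conventional annotation defaults). Deletions are
  located by their first deleted base, insertions by their anchor. When
  several genes overlap, the highest-precedence call wins. Exonic SBS
  effects come from codon translation under the standard code
  (synonymous / nonsynonymous / stopgain / stoploss); exonic InDels are
  frameshift iff size mod 3 ≠ 0, with stop gain/loss additionally
  assessed for in-frame events by translating the edited coding
  sequence. Window densities tile each chromosome with non-overlapping
  1-based right-closed windows (500 kb default).

## Synthetic data

The generators emulate the study's inputs with full ground truth:

* **Genome/genes:** random chromosomes with strand-annotated
  protein-coding genes (1–3 exons, CDS a multiple of 3 starting ATG and
  ending in a stop, UTRs, ≥ 2.5 kb intergenic gaps) written as
  FASTA/GFF3. The default analysis uses 2 × 300 kb with ~24 genes — big
  enough for every annotation class to occur, small enough for fast
  tests.
* **Truth sets:** each sample gets exactly `n_induced` private variants
  at unique genomic positions (hence pairwise disjoint induced sets);
  each background variant is written identically into ≥ 2 randomly
  chosen samples. Composition defaults: 85% SBS (the observed SBS:InDel
  ratio is ~4–8:1), Ti/Tv target 2.0 via P(transition) = r/(1+r), indel
  sizes truncated-geometric on [1, 50] (p = 0.45, majority 1–4 bp),
  deletions:insertions 0.6:0.4, het:hom 1:1.
* **Caller calls:** induced variants are dropped per caller with
  probability `fn_rate`; background variants are emitted by every caller
  (they mimic polymorphism visible to all tools, which the exclusion
  step must catch); false positives arrive at `fp_rate_per_mb` at
  positions absent from truth and disjoint between callers. DP is
  negative-binomial (default mean 50, size 50 ≈ CV 0.2, matching ~50–65×
  WGS); AF is Gaussian around 0.5 (het) or 1.0 (hom), clipped to
  (0, 1]. "Zero-error" scenarios use size 400 and AF sd 0.02 so that the
  nuisance fields cannot trip the DP/AF filter and recovery comparisons
  are exact.
* **Phenotype tables:** dose-response points are SHMT means plus
  Gaussian noise clipped to [0, 100]; panicle tables are forward draws
  from the chimera model (vectorized, 10⁶ plants in well under a
  second).

What the synthetic data does **not** emulate: read-level artifacts
(mapping bias, strand bias, repeat-induced systematic errors shared
between callers), structural variants, clustered mutations, linked
detection failures between neighbouring sites, and real inter-caller
representation differences beyond indel normalization. Passing recovery
tests therefore demonstrates the pipeline's bookkeeping and decision
rules, not robustness to every failure mode of real sequencing data.

## Problem sizes and numerical choices

Tests and the acceptance script use 2 × 300 kb genomes, 6 + 1 samples
with 40 induced and 50 background variants, 200 SHMT noise replicates,
10⁶-draw chimera simulations per grid point and 100 recovery datasets —
sizes chosen so the whole suite runs in well under a minute while
keeping Monte-Carlo acceptance margins comfortable. Probability vectors
are validated to sum to 1 within 1e−12; likelihood evaluations floor
probabilities at 1e−300 to keep impossible-outcome penalties finite;
chi-square comparisons pool bins with expectation < 5 and require
structurally impossible outcomes to have zero observations.

## Known limitations

* The SHMT fit reports no confidence intervals; the D₀/N ridge makes
  per-parameter Wald intervals misleading, and bootstrap support was
  deliberately left out of scope.
* P > k progenitor numbers are not identifiable from panicle counts
  (see above); the likelihood profile makes such flatness visible but
  the point estimate alone should not be trusted there.
* Region annotation reports only the highest-precedence call per
  variant; overlapping-transcript alternates are not enumerated.
* The pipeline consumes caller output; it does not model or correct
  caller-internal biases, and near-miss indel matching across callers
  (position ± a few bp) is intentionally not attempted.
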