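# Methods

This note documents the models, procedures and design choices behind
`mutbench`, and what the synthetic cohort does and does not establish.

## Problem setting

A tumour-normal pair is sequenced, somatic mutations are called by many
pipelines, and the calls disagree. A truth ("gold") set curated from much
deeper coverage of the same pair allows tier-stratified accuracy
measurement: recall against progressively harder strata of true
mutations, precision against an enlarged stratum that forgives
hard-to-align calls. The package implements that curation, the evaluation
arithmetic, and the surrounding diagnostics; the deep read data itself is
replaced by a generative model of allele counts.

## Beta-posterior concordance score

For a candidate site with tumour counts (t_alt, t_ref) and normal counts
(n_alt, n_ref), independent beta posteriors are placed on the two mutant
allele fractions with a Jeffreys prior (½, ½) — the prior is configurable,
and the objective Jeffreys choice is used because no specific prior is
canonical for this score. The score is the one-sided probability

    SCORE = P(p_T > p_N) = ∫₀¹ f_T(x) F_N(x) dx,

evaluated by adaptive quadrature with break points at both posterior
means (absolute tolerance 1e-9, well inside the 1e-6 contract). A
closed form exists only for integer parameters, so the test suite pins the
integral against a seeded Monte-Carlo oracle (10⁶ posterior draws). The
one-sided convention is chosen because the sameAF feature transform,
`1 − 2(SCORE − ½)` for SCORE ≥ ½ else 0, is only meaningful on [½, 1].
Two useful identities follow and are tested: swapping tumour and normal
maps SCORE to 1 − SCORE, and identical count pairs score exactly ½.

## Curation rules

Candidates are the union of verification call sets. Sites supported by
more than three distinct submitters are auto-accepted; all other
supported sites are reviewed. Classification of a scored candidate:

1. *Clean gate*: tumour and normal depth ≥ 20, mean 100-mer window
   mappability = 1, no segmental-duplication overlap. Clean candidates
   with SCORE ≥ 0.98 (or auto-accepted by consensus — consensus skips the
   score gate but never the evidence gates) are classified by observed
   MAF: class 1 (≥ 0.10), class 2 (≥ 0.05), class 3 (≥ 0.02); below the
   2 % floor a call is deemed unreliable and rejected (class 0).
2. *Review branch* (SCORE > 0.9): ambiguous-alignment flag → class 4;
   tumour depth outside 0.5×–2× the cohort median → class 5; otherwise
   class by MAF if clean, else class 0.
3. SCORE ≤ 0.9 → class 0.

All inequality directions follow the printed thresholds exactly. Tiers
are cumulative: Tier 1 = class 1, …, Tier 5 = classes 1–5. Indels are
classified coarsely (classes 1 and 4 only; candidates falling in classes
2/3/5 are rejected), giving SIM Tiers 1 and 4.

The original classes 4 and 5 were produced by expert review of
alignments. A reusable implementation must be machine-decidable, so the
review is replaced by deterministic proxies: the generator plants
ambiguity flags (class 4) and depth multipliers in low-mappability
context (class 5), and curation applies the flag/threshold rules above.
Passing tests therefore validate the *rule machinery*, not human
judgement.

## Evaluation

With recall tier R (default Tier 3 for SSMs, Tier 1 for SIMs) and
precision tier 4: tp = |sub ∩ R|, tp_extra = |sub ∩ (Tier 4 \ R)|,
fp = |sub| − tp − tp_extra, fn = |R| − tp;
P = (tp + tp_extra)/(tp + tp_extra + fp), R = tp/(tp + fn), and
F1 = 2PR/(P + R) computed on unrounded values (verified against published
rows, which also fixes the convention that recall uses tp + fn verbatim
when only printed counts are available). Matching is by position and
exact alleles; a position-only switch exists for indels because allele
representations differ across callers even after left-alignment. Zero
denominators are reported as missing with F1 = 0 rather than raising, so
cohort-scale batch evaluation never aborts.

Indel identity uses the left-aligned representation: the minimal,
left-most variant whose application to the reference reproduces the
alternate haplotype. The test oracle is independent of the shifting
algorithm — it diffs whole haplotypes, trimming the common suffix first
(which is what makes the result left-most), then the prefix.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not reads:

- **Genome**: random sequence (default two contigs, 5 Mb total) with
  per-10-kb GC targets ~ N(0.41, 0.06) clipped to [0.25, 0.65]; planted
  homopolymers (8–15 bp), microsatellites (unit 2–6 bp, 6–12 copies),
  simple repeats (unit 7–20 bp), nested repeats, verbatim-copied 2-kb
  segmental duplications, a 171-bp satellite tiled centromere per contig
  plus DAC/Duke-style blacklist intervals, and exon/enhancer ROI tracks.
  Densities are per-Mb settings chosen to give each feature non-trivial
  representation at 5 Mb.
- **Truth**: mutation rate 100/Mb (a desk-scale rate chosen so every
  class and tier is populated with usable statistics at 5 Mb; tier
  *proportions*, not absolute sizes, mirror the curated-set breakdown
  ≈ 74.5/10.8/11.9/0.6/2.2 % for classes 1–5). Tumour purity 0.98 over a
  tetraploid background with one diploid contig. Allele fractions obey
  af = purity × mutated_copies × clone_fraction / copy_number: clonal
  mutations on 1–2 (occasionally more) of the available copies; class-2
  and class-3 strata are subclones back-solved from target AF ranges
  (0.055–0.095 and 0.022–0.048). Class-4 mutations are planted inside
  segmental duplications with an ambiguity flag; class-5 mutations carry
  depth multipliers {0.3, 3×} and sit in centromeric (low-mappability)
  context, as aberrant-depth sites do in real genomes. About 83 % of
  indels are planted inside tandem repeats/homopolymers, reflecting the
  observed concentration of somatic indels in such context.
- **Counts**: per-site depth ~ NegativeBinomial(mean 300× tumour / 270×
  normal, dispersion 10), mean optionally modulated linearly by window GC
  (slope 0 by default — a PCR-free profile); t_alt ~ Binomial(depth,
  af·(1 − contamination) + error) with per-base error 10⁻³; error-only
  sites emit the same model with af = 0. Downsampling thins each read
  binomially; contamination replaces tumour reads with draws at the
  normal sample's empirical alternate rate.
- **Callers**: step-function sensitivity over the three AF strata plus
  Poisson false positives at a per-Mb rate, multiplied inside flagged
  intervals (blacklist/segdup/repeat) — enough to reproduce
  centromere-clustered FP patterns and feature-enrichment signals.

What this does **not** emulate: alignment artefacts (soft-clipping,
strand/positional bias), context-dependent sequencing error, structural
variation, library-specific GC curves beyond a linear response, and
caller behaviour that depends on read evidence rather than true AF.
Passing tests show the analysis machinery is correct under the stated
model; they do not certify performance numbers on real tumours, and the
genome-scale empirical values from the original deep dataset are treated
as context, not targets.

## Saturation and contamination models

Counts from serial downsampling are fitted by nonlinear least squares to
n(c) = n_max·c/(k_half + c), initialised from the largest count and the
half-maximum crossing with two coarse alternative starts (positivity
bounds; best of the multi-start kept). The contamination surface uses the
general two-constant mixed-inhibition form
n(c, f) = n_max·c/(k_half·α + c·α′), α = 1 + f/K_ic, α′ = 1 + f/K_iu,
parameterised internally by inverse constants ≥ 0 so the no-inhibition
limit is reachable smoothly; f = 0 reduces exactly to the plain curve and
any f > 0 caps the plateau at n_max/α′. The internal threshold caller
(≥ 4 tumour alt reads, ≤ 1 normal alt read, AF ≥ 0.02) stands in for a
production pipeline and is configurable; fraction-of-maximum at coverage
c is c/(k_half + c), independent of n_max.

## Signatures

Catalogues use the canonical 96-bin order (substitution-major C>A … T>G,
then 5′ and 3′ base alphabetical); purine-reference mutations are
reverse-complemented with their context. Exposures solve
min ‖S·e − m‖² s.t. e ≥ 0 by NNLS (the equivalent quadratic program),
with no sum constraint; the 5 % reporting threshold is applied as
exposure / catalogue-total, the natural reading of "at least 5 % of the
mutations in a sample". KKT conditions and exact/noisy mixture recovery
are tested.

## Mappability

Window mappability is exact k-mer uniqueness (1/occurrences, forward
strand) over 100-mers and 150-mers, averaged over the upstream windows
−90…−10 and −140…−10 so every averaged k-mer covers the call. Real
pipelines use mismatch-tolerant mappability from external tools; exact
uniqueness is a documented simplification that behaves identically on the
synthetic genome (duplications are verbatim copies), and a brute-force
dictionary oracle defines truth in tests. Counting uses two independent
31-bit rolling hashes combined into 64 bits; at ≤ tens of Mb the collision
probability is negligible (~10⁻³ expected colliding pairs at 5 Mb).

## Coverage QC

GC bias: fixed windows (10 kb default), window coverage divided by the
mean over retained windows (those with ≤ 100 N bases), so the retained
mean is 1 by construction. Cumulative coverage is the base-weighted
complementary CDF of depth. Low-coverage fractions use the strict
"fewer than 10 reads" reading (the threshold is configurable, since the
companion "≤ 10×" phrasing also circulates).

## Numerical and tie-break choices

- Jaccard clustering: average linkage on 1 − J, sources pre-sorted by
  name for deterministic tie-breaking; empty call sets yield missing
  values and are excluded from clustering.
- Correspondence analysis: SVD of standardised residuals of the
  correspondence matrix; axes with singular value ≤ 1e-12 are dropped;
  duality and reconstruction identities are tested to 1e-8.
- Tandem-repeat scan: periods 1–6, ≥ 6 copies, within the 201-bp window
  centred on the call; "immediately adjacent" means within 1 bp of the
  call footprint. Homopolymer = period-1 run longer than 6 bases (hence
  hp ⇒ inTR ∨ adjTR). Longer-period repeats are annotated from the
  planted tracks instead.
- Enrichment weights: FP rate = FP/(TP+TP₄+FP) and FN rate = FN/(TP+FN),
  the natural complements of precision and recall from the same run.
- Normal-depth outlier flags (DPNhi/DPNlo) default to >2× / <0.5× the
  median normal depth; no canonical thresholds exist, so they are
  configurable.
- Michaelis–Menten fits refuse series with fewer than three distinct
  coverages; non-convergence raises with solver diagnostics instead of
  returning silently.

## Problem sizes

Default scales were chosen for single-CPU reproducibility: a 5-Mb genome
at 300×/270× (~450 planted mutations, ~2,600 scored candidate sites)
drives the end-to-end suites; the Monte-Carlo score oracle uses 10⁶ draws
per configuration; saturation series use the seven standard coverage
levels × four contamination fractions. The full test suite runs in a few
minutes; `scripts/acceptance.py` in about a minute.

## Known limitations

- Classes 4/5 validate rule proxies, not human review (above).
- SIM matching semantics beyond left-alignment (e.g. complex-region
  equivalence) are simplified to exact or position-only identity.
- Mappability ignores mismatch tolerance and reverse-strand hits.
- The contamination model mixes counts, not reads; sequencing-error
  context and mapping artefacts are out of scope.
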