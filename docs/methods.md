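# Methods

## The problem

In an outbred ("four-way") cross, two heterozygous parents each carry two
distinct haplotypes (dam *a/b*, sire *c/d*). Where marker alleles permit,
each offspring genotype resolves into one maternal and one paternal
contribution, so every offspring chromosome is a mosaic of the two
haplotypes of that parent, and each switch in the mosaic is a crossover
from that parent's meiosis. Counting and locating these switches per
parent measures **heterochiasmy** — the difference in recombination rate
and placement between the sexes. Salmonids are an extreme case: females
recombine severalfold more than males, male crossovers sit at chromosome
ends, and the residually tetraploid parts of the genome (homeologous arms
still pairing after the ancestral whole-genome duplication) lose
male-informative markers during diploid genotype filtering, which biases
naive sex ratios. The same genotype matrix supports QTL mapping of
quantitative traits by marker regression with permutation thresholds.

This package implements that analysis chain — phased crossover detection,
genotyping-error-aware correction, sex- and stratum-wise summaries,
centromere-end inference, and the QTL scan — and pairs it with a
synthetic-cross generator so every stage can be validated against known
ground truth without any external data.

## Crossover detection

For one offspring, one parent, one linkage group, the ordered haplotype
labels (0/1, unknown where the call is missing or the hkxhk double
heterozygote `hk` leaves phase unresolved) yield the minimum number of
obligate phase switches: one event per change between consecutive known
labels. Unknown runs never force a switch; a label change across a run of
unknowns is a single event at the midpoint of the bounding known markers.
This equals the dynamic-programming minimal-switch assignment (verified
exhaustively in the tests). Event positions are midpoints of the flanking
informative markers; percent positions divide by the LG length (last
marker position). Heterochiasmy comparisons restrict the marker set to
types informative in both parents (efxeg, hkxhk) so that a one-sex
difference in marker density cannot masquerade as a rate difference.

## Double-crossover correction

A single genotyping error looks like two tight crossovers with no net
phase change. Events on one haplotype are chained into clusters while the
gap to the previous event is at most W (default 50 cM; 25 and 10 cM are
standard sensitivity variants; an "anchor" chaining mode referenced to
the cluster's first event is available). Even clusters are removed
entirely. Odd clusters larger than one collapse to a single retained
representative: the member most isolated from its within-cluster
neighbours, with exact ties falling back to the median member. The
isolation rule matters: when a real crossover chains with a tight error
pair, the sorted median is always a member of the pair, so a plain median
rule would keep a spurious event and discard the real one, corrupting
positional analyses. Under the collapse policy the correction preserves
the parity of the event count on every haplotype — the net phase change
across the chromosome is invariant.

The correction presumes crossover interference: it reads *any* even
number of nearby events as error, so it inevitably removes genuinely
close double crossovers too. With W comparable to the LG length this
makes counts conservative; the window-sensitivity table (ratios at
W = 50/25/10) quantifies the effect.

Centromere-end inference and other position-sensitive analyses use events
corrected at W = 10 cM: tight windows still cancel the 1–2 cM error
pairs but leave true events in place, whereas a 50 cM window on a
40–90 cM linkage group merges the whole haplotype into one cluster and
the surviving representative can sit far from any real crossover.

## Summaries and centromere calls

Totals and female:male ratios (reported to one decimal, raw quotient kept)
are computed overall and per stratum: fused metacentric vs acrocentric
class, and residually tetraploid vs rediploidized status; the sex-linked
LG is excluded from all autosomal totals and reported separately.
Positional distributions bin percent positions (5% bins) per parent and
class; the "external 20%" share uses the closed intervals [0, 20] and
[80, 100]. For an acrocentric LG with at least 5 male events, if at least
80% of them fall in one terminal 20%, the centromere is placed at the
opposite end (salmonid male crossovers cluster at the telomere away from
the centromere); otherwise the call is undetermined. Residually
tetraploid LGs are always reported undetermined: the censored distal male
markers are exactly where the evidence would be, and the residue of
proximal events points the wrong way.

## QTL scan

The scan statistic is marker regression:
`LOD = (n/2)·log10(RSS_reduced / RSS_full)`, full model = covariates +
genotype-class factor, reduced = covariates only, computed on the
complete cases at each marker. Observable genotype classes are used as-is
(two for one-parent-informative markers, {hh, hk, kk} for hkxhk with the
ambiguous het as its own class, four for efxeg); no phase reconstruction
or interval mapping between markers is attempted. A sex covariate enters
when a two-group F-test gives P ≤ 0.20. Significance is empirical: traits
are permuted across offspring (within sex strata when sex is a
covariate); the genome-wide threshold is the conservative ("higher"
order-statistic) 1−α quantile of per-permutation maximum LOD
(α = 0.05), chromosome-wide thresholds are per-LG quantiles at α = 0.01.
Support intervals take the widest contiguous span within 1.5 LOD of the
peak, extended one marker beyond each side. The joint multi-QTL fit
(trait ~ QTL₁ + … + QTLₙ [+ sex]) reports total PVE = 100·(1−RSS/TSS)
and drop-one per-term PVE, with genotype-class means (sex-split when sex
is in the model). Sex-by-genotype interactions are tested by F-comparison
of the full (genotype + sex + genotype:sex) vs additive model, and only
when the full model is itself significant. Offspring sex coded 0/1 and
scanned the same way localizes the sex-linked LG; a logistic variant is
deliberately out of scope since a 1:1 binary trait leaves the max-LOD
permutation null valid.

Implementation: per-marker orthonormal design bases are precomputed, so
scoring a batch of (permuted) trait vectors is one matrix product. This
makes 10,000-permutation thresholds and nested calibration studies
(thousands of null scans) run in seconds; a numerically perfect fit is
reported as a capped LOD of 50.

## Synthetic cross generator

The generator is the test surface and defines the study conditions:

* **Family geometry** — 170 offspring; 42 LGs: 8 fused metacentric, 34
  acrocentric of which one is sex-linked; 91 evenly spaced markers per LG
  (≈3,820 total) drawn from the type mix 0.35 nnxnp / 0.35 efxeg /
  0.30 hkxhk. Marker spacing is uniform to isolate algorithmic behavior
  from map-density artifacts.
* **Map lengths** — female: 88 cM per fused, 42 cM per acrocentric LG
  (chosen so expected female crossover totals match the source family's
  per-chromosome means); male lengths are female/1.85, the
  female:male ratio estimated on rediploidized chromosomes where male
  markers are not censored. The marker axis is the female map, as in
  published salmonid maps; male crossover positions are rescaled onto it.
* **Meiosis** — crossover counts and positions follow a stationary
  gamma-renewal process (shape ν = 8, mean inter-crossover distance
  100 cM), giving E[count] = length/100 with strong positive
  interference; positional bias is imposed by warping the uniform axis
  through the target density's quantile function, preserving counts.
  Interference is the default because it is the premise of the
  double-crossover correction — without it, close true doubles are
  common and the correction removes them differentially by sex, so no
  estimator could recover the simulated ratio. A pure Poisson gamete
  model (`simulate_gamete`, `interference="none"`) is available.
* **Densities** — dam crossovers are center-biased (Beta(2,2); the
  literature states only "biased toward the center", so a mild symmetric
  hump is a modeling choice); sire crossovers place 95% of their mass in
  the 20% of the axis farthest from the centromere, reflecting the
  near-total terminal restriction of male salmonid recombination.
* **Residual tetraploidy** — on 16 flagged chromosomes (4 fused + 12
  acrocentric) markers in the distal 30% are demoted to the
  dam-informative type, emulating male-informative markers lost to
  diploid genotype filtering in homeolog-pairing regions.
* **Sex linkage** — offspring sex is the sire haplotype at a sex locus at
  the centromeric end of the sex LG (XY-like, 1:1 expected); male
  crossovers on that LG are confined to the distal 20% pseudoautosomal
  segment, and its male map length (42 cM) is set so the Y recombines
  more than an average acrocentric, as observed in the source family.
* **Observation model** — genotyping errors substitute another legal
  observed code uniformly at rate ε = 0.005 per call; calls go missing at
  0.03. Both are recorded in the ground truth.
* **Phenotypes** — a growth-like trait with one planted additive QTL
  (0.47 trait-SD per haplotype substitution ≈ 10% PVE) plus a 0.5 SD sex
  effect, and a pure-noise control trait. Effects add on the true
  haplotype dosage; residuals are Gaussian.

What the generator does **not** emulate: linkage-map construction error
(marker order and cM positions are exact), map inflation from residual
genotyping error, segregation distortion (the distortion filter therefore
removes only the ~1% false positives expected at P ≤ 0.01), population
structure beyond a single family, and sequence-level artifacts. Passing
tests therefore demonstrate correctness of the analysis chain under a
faithful meiosis/observation model, not robustness to map mis-ordering.

Known emulation gap: with 95%-terminal male crossovers and 30% distal
censoring, the tetraploid-stratum ratio comes out near 20, well above the
~6 seen in the real family — the real censoring is evidently partial.
The rediploidized stratum (≈1.9) and the overall ratio (≈2.7–2.8) do
match the published pattern.

## Numerical and procedural choices

* Chi-square segregation tests use the observed-class expectations
  (1:1 for nnxnp/lmxll, 1:2:1 for hkxhk, 1:1:1:1 for efxeg) with raw
  P ≤ 0.01, no multiple-testing correction, matching map-building
  convention.
* Phenotype outliers: single-pass |x−mean| > 3 SD (ddof = 1); zero SD
  removes nothing. Single-pass is deliberately conservative at small n.
* The per-offspring crossover-outlier rule (median + 10·max(MAD, 1) on
  raw obligate counts) operationalizes the ad hoc removal of one grossly
  error-inflated sample in the source family; an explicit id-exclusion
  list is supported.
* Permutation thresholds use `numpy` "higher" quantiles; linear
  interpolation is anti-conservative at small permutation counts
  (measured type-I ≈ 0.074 at n_perm = 200 vs 0.050 with the
  conservative order statistic over 3,000 null scans).
* Degenerate cases: markers with one observed class score LOD 0 and are
  flagged uninformative; RSS_full < 10⁻¹²·TSS reports the capped LOD;
  ratios with a zero male total are reported as null; all-missing markers
  are skipped (never removed) by the segregation filter.
* Reduced problem sizes in the test suite (miniature six-LG families,
  n_perm = 200 calibration runs, 20-replicate sex-linkage studies) were
  chosen so the full battery, including two study-scale simulations,
  completes in a few minutes while keeping every Monte-Carlo margin wide
  (binomial CIs stated per test).

## Limitations

* Marker regression at marker positions only — no interval mapping or
  mixture-model genotype probabilities; with ~1 cM spacing the practical
  difference is negligible, but sparse maps localize QTL only to the
  nearest marker.
* The correction cannot distinguish a genuine tight double crossover from
  an error pair; its output is a lower bound on crossover counts within
  each window choice.
* Centromere calls depend on the male telomere-bias assumption and are
  undetermined wherever male information is censored.
* hkxhk `hk` offspring are an unresolved class; no probabilistic phase
  imputation is attempted.
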