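# Methods

## Pooled-screen growth model and hit calling

The screen caller assumes a pool of barcoded insertional mutants grown
competitively for *g* doublings. An allele of a gene with per-doubling
selection coefficient *s* multiplies its abundance by 2^{g(1−s)} under
treatment and by 2^g under control; there is no death term and no
interaction between alleles. Reads are the interface: the simulator draws
them multinomially at a fixed per-sample depth (an optional
Dirichlet-multinomial concentration models PCR/jackpot overdispersion,
default off), and every source of randomness flows from one integer seed
per call.

The phenotype ratio Φ is a ratio of *within-sample relative abundances*
(depth normalization is required to compare libraries sequenced to
different depths). A consequence worth stating precisely: the model-level
expectation for an allele is Φ = 2^{−g·s}, but renormalizing the treatment
pool multiplies every realized Φ by the common composition factor
N / Σ_j 2^{−g·s_j} (N = pool size). The factor is exactly 1 for an
all-neutral pool and within 0.5 % of 1 for the default study conditions
(20 hit genes × 5 alleles of s = 0.5 among 5,000 alleles); `GroundTruth`
stores the per-allele expectation 2^{−g·s} and exposes the composition
factor, and the deterministic (no-sampling) simulator path reproduces
Φ·Σ/N = 2^{−g·s} to machine precision.

Hit calling follows the screen recipe exactly:

- 50-read minimum for a phenotype to be calculated. The recipe does not say
  which sample the minimum applies to; the default is the **control** count
  (a low control count makes Φ unstable, while treatment dropout is the
  signal and must stay observable). `min_reads_on` switches to
  sum/both/treatment.
- Fixed 8-bin Φ grid with left-closed, right-open bins. The printed grid
  ends at 16; alleles with Φ ≥ 16 are clipped into the top bin rather than
  dropped.
- Per gene, a two-sided exact conditional test of the 2×8 table (gene row
  versus all-insertions-minus-gene row, margins fixed): under the null the
  gene row is multivariate hypergeometric, and p is the total probability
  of outcomes no more likely than the one observed, ties included with a
  10⁻¹² relative tolerance. Enumeration over the C(n+7,7) compositions is
  exact for n ≤ 12 alleles; above the cap a seeded Monte-Carlo estimate
  (default 10⁵ draws, add-one estimator) is returned and flagged. The
  gene's own alleles are kept inside the background ("all insertions");
  a flag removes them, which leaves the realized table — and hence p —
  unchanged, since the comparison row is background-minus-gene either way.
- Benjamini–Hochberg step-up q-values (via `statsmodels`) computed only
  over genes with ≥ 3 alleles, separately within each (condition,
  replicate) screen; hit ⟺ q < 0.3, strictly.

The test is discrete and therefore conservative; on all-neutral pools the
realized false-discovery proportion is far below the nominal level.

## Secondary plate screens

Scanned plates are collapsed to grayscale with Rec. 601 luminance weights
(0.299 R + 0.587 G + 0.114 B — the common image-software default;
configurable), and each well's mean intensity is taken over its full
circular sampling area. Wells flagged for bubbles or irregular clamping are
excluded before quantification. Z-scores are computed per plate against
that plate's wild-type wells — Z = (mean of the genotype's replicate wells
− wild-type mean) / wild-type sample SD (ddof = 1) — never pooling across
plates, since wild-type colonies are placed on every plate precisely to
absorb positional effects. Replicate wells are averaged before scoring
(per-well mode available). Z is invariant under affine rescaling of a whole
plate. A perfectly flat plate (zero wild-type variance, every well at the
wild-type mean) scores 0 by convention; zero variance with real differences
is flagged as unscorable.

## Label-swap phosphopeptide filter

Raw ratios are light/heavy peak areas. Orientation handling is the crux of
"reciprocal": forward pairs (treated grown in the light label) pass
through, reverse pairs are inverted, so every ratio is treated/control
before thresholding. A peptide is called when ≥ 2 replicates (of 3) have
|log₂ ratio| ≥ log₂(fold) with one consistent sign; fold = 2.0 for the
primary call set and 1.5 for the relaxed set used in cross-species homolog
matching. Thresholds are inclusive (exactly 2-fold passes). Peptides seen
in fewer replicates than `min_reps` cannot be called, but a peptide seen in
just 2 of 3 replicates can still pass — mass-spec missingness is pervasive
and the rule counts passing replicates. An optional strict mode requires
the passing replicates to cover both label orientations (off by default;
the plain rule does not demand it). Protein roll-up: a protein is called if
any peptide is called, direction by majority of called peptides, exact
ties flagged ambiguous. The filter is exactly invariant under flipping
every orientation flag while reciprocating every raw ratio.

## RBH orthology and overlap statistics

Best hits are taken from precomputed 12-column tabular BLAST output: per
query, the subject with the lowest e-value among hits with e ≤ 10⁻¹⁰. The
e-value criterion alone is ambiguous under ties, so ties are broken by
higher bitscore, then lexicographically smallest subject id, making the
result independent of input row order. A pair (a, b) is orthologous iff a's
best hit is b and b's best hit is a; the map is a partial bijection and
mirror-symmetric by construction. Isoform ids are used verbatim; an
optional regex collapse keeps the best hit per gene. Overlap percentages
are reported relative to an explicitly stated reference set, rounded to two
decimals for display; enrichment uses the standard two-sided 2×2 Fisher
exact test (scipy) against a declared universe.

## Imaging metrics

**Skewness.** g1 = m₃/m₂^{3/2} with population (biased) central moments
over all pixels of the crop, computed on raw maximum-intensity-projection
values with no background subtraction or preprocessing; crops are a fixed
10 × 10 µm. All-pixel computation (rather than suprathreshold-only) is
deliberate, matching the no-processing convention; a sample-adjusted
variant is available as a flag at the call site via scipy if needed.
g1 is affine-invariant, so gain/offset differences between images cancel.

**Angle.** Dominant orientation from the gradient structure tensor (Sobel
free, plain gradients of a Gaussian-smoothed crop, σ = 2 px; smaller σ
leaves a 2–3° discretization bias on synthetic lines). Filaments run
perpendicular to the dominant gradient direction; the angle is folded into
[0, 90]° relative to the configured reference axis (longitudinal =
horizontal after alignment, or radial). The tensor's coherence
(λ₁−λ₂)/(λ₁+λ₂) is returned, and values below 0.2 flag near-isotropic
crops whose angle is not meaningful.

**Max-entropy threshold.** Kapur's criterion: choose t maximizing the sum
of Shannon entropies of the normalized sub-histograms at or below and above
t; lowest maximizer on ties; 256 integer bins for 8-bit data. This operator
is written in-repo (the installed image library ships Otsu/Yen/Li but not
Kapur) and is checked against a naive per-threshold search.

**Spike detection.** Per ROI (default: 8 ROIs of 24 × 24 µm spaced evenly
across a 150 µm span, so neighbours overlap), the threshold is computed
once over the ROI's whole sub-stack and floored at
median + 5 × (1.4826 · MAD): on a signal-free ROI the intensity histogram
is unimodal and an entropy threshold splits it near the middle, marking
about half the noise pixels as foreground; the robust noise floor is the
standard detection-limit remedy and leaves genuinely bimodal (spiking)
ROIs untouched, since their entropy threshold sits far above it.
Suprathreshold connected components smaller than 6 pixels are discarded as
sporadic signals; surviving components that touch across consecutive
frames (full 3×3×3 connectivity, gap tolerance 0) merge into one event
with a duration. Rates are reported as events / movie duration in hours.

**Shrinkage.** 100 × (1 − protoplast area / total cell area). Segmentation
of the two areas is out of scope; they arrive from masks or manual tracing.

## Synthetic data: what it does and does not emulate

The generators reproduce the *structure* of the real assays — competitive
pool growth with multinomial read sampling, label-swap ratio tables with
log-normal noise, line-like filament scenes whose bundling concentrates a
constant total signal onto fewer brighter cables, movies with compact
suprathreshold events on Gaussian noise, plates of uniform disks. They do
not emulate PCR chemistry or barcode sequencing errors, peptide
missingness patterns correlated with abundance, filament curvature or
crossing statistics, photobleaching, or plate illumination gradients.
Passing tests therefore demonstrate correctness of the statistical
procedures under their stated models, not robustness to every artifact of
real data.

Default study conditions: screens of 1,000 genes × 5 alleles with 20 hit
genes at s = 0.5 over g = 4 doublings (expected Φ = 0.25) and 10⁷ reads
per sample; label-swap tables of 100 peptides with 10 changed 4-fold,
log2 noise SD 0.2, forward/reverse/forward replicate orientations; movies
of 120 frames at 10 s intervals with 12-pixel spikes of amplitude 150 on
background 10 ± 2. The number of doublings in the real pooled screens is
not published, so g is a free parameter with default 4.

## Numerical choices

- Probability ties in the exact test are included with a 10⁻¹² relative
  tolerance; enumeration cap n = 12 (50,388 compositions).
- Monte-Carlo p uses the add-one estimator (never exactly 0).
- BH is validated against an independent step-up implementation on random
  vectors in the test suite.
- Φ-bin edges are compared with left-closed semantics via `np.digitize`;
  Φ = 0 (treatment dropout with a qualified control count) lands in the
  lowest bin.
- All generators accept and require integer seeds; identical seeds give
  bit-identical outputs.

## Known limitations

- The screen test conditions on the observed background table; very small
  screens (a handful of genes) make the background itself gene-dominated
  and the test conservative.
- Monte-Carlo p-values for genes with > 12 alleles carry sampling error
  ~(p(1−p)/draws)^{1/2}; raise `n_mc` where that matters.
- The angle estimator reports a single dominant orientation; crops with
  two strong filament populations return their tensor average with reduced
  coherence rather than a bimodal summary.
- Spike counting assumes a registered stack; drift masquerades as events.
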