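# Methods

## The analysis in one paragraph

DNRA (dissimilatory nitrate reduction to ammonium) communities are profiled
two ways at each sediment site: functionally, by a ¹⁵N tracer incubation
that measures the potential rate at which nitrate-derived label accumulates
in the extractable ammonium pool; and structurally, by barcoded amplicon
sequencing of the *nrfA* marker gene.  Reads are filtered and translated to
NrfA protein fragments, clustered into OTUs, and summarised per site as
diversity indices and as a dominant/rare/endemic partition.  The linking
question is statistical: does the share of a community held by its dominant
populations predict the community's rate?

## Rate estimation

The tracer model assumes label transfer is linear over the incubation:
excess ¹⁵NH₄⁺ mass (nmol ¹⁵N g⁻¹) grows as `rate · MF₁₅NO₃ · t`, where
`MF₁₅NO₃` is the tracer enrichment (default 0.99, i.e. 99 atom-%; it is a
configurable constant because enrichment is set when the tracer is added)
and `t` is hours.  The measured mole fraction of the trapped ammonium pool
is first corrected for the unlabelled carrier (default 3 µmol = 3000 nmol)
added before diffusion trapping: `MF_true = MF_measured · (pool+carrier)/pool`.
Two estimators are provided:

* **endpoint** — the closed form `MF·[NH₄] / (MF₁₅NO₃·t)` at one time point;
* **regression** (default) — OLS slope of excess mass against time divided
  by the tracer MF, with the slope standard error propagated.  For exactly
  linear zero-intercept data the two coincide; with noise the regression is
  the more robust choice for a sacrificed-time-series design.

Negative fitted slopes are reported as-is with a warning rather than
clamped: a negative estimate is diagnostic (tracer loss, mis-labelled
series), and clamping would hide it.  Pool sizes given in µmol g⁻¹
(geochemistry-table units) are converted to nmol g⁻¹; rates are always
nmol N g⁻¹ h⁻¹.

## Read processing

The chain is demultiplex → primer trim → length/quality filter → denoise →
chimera screen → translate → dereplicate, with stage counts recorded and
checked monotone.  Choices worth noting:

* **Quality** means per-read mean Phred; "shorter than 200 bp and lower
  than 25" is read as `len ≥ 200 and mean Q ≥ 25` with inclusive
  boundaries.  Per-base trimming is deliberately not applied.
* **Denoising** is a homopolymer merge: reads identical except for a
  single one-base homopolymer-length difference collapse onto the most
  abundant variant.  This targets the dominant Ion-Torrent error mode
  (homopolymer over/under-calls) without flowgram data; it is idempotent
  by construction and conserves read counts.  Its known blind spot: an
  indel-bearing read that also carries a substitution lands in a different
  homopolymer-compressed bucket and is not rescued — such reads are later
  dropped as frame-shifted.
* **Chimera screening** is a half-split bimera test: the read is split at
  its midpoint, each half is matched to its best reference, and the read
  is chimeric when the halves' parents differ and each half beats the full
  read's best identity by ≥5 percentage points.  Reads under 80 bp skip
  the screen.
* **Translation** scans the three forward frames only (the barcoded forward
  primer fixes orientation in a single-direction library; reverse frames
  sit behind a flag).  The frame closest to any reference is selected; a
  read is rejected, with a frameshift flag, when its best translation has
  an internal stop or its best local BLOSUM62 alignment covers <70% of the
  translated length — the signature of an uncorrected indel.  Rejected
  reads are removed, not repaired.
* Ambiguous bases count as mismatches in barcode/primer matching and
  translate to X.

## Distances, OTUs and diversity

Protein p-distance is the fraction of differing aligned columns, terminal
gaps excluded; Kimura's correction d = −ln(1 − p − 0.2p²) accounts for
multiple hits, capped at 10.0 beyond its domain (p ≳ 0.854).  Pairwise
global alignment replaces a multiple alignment: the amplicons cover one
fixed ~80-residue region, so pairwise and multiple alignment give the same
columns at these divergences.  The default alignment engine is unit-cost
(edit-distance) global alignment, fast enough for matrices over thousands
of sequences; a BLOSUM62 affine-gap engine is available and agrees with it
on near-identical fragments (property-tested).  Arguments are canonically
ordered before alignment so that co-optimal paths cannot break the symmetry
p(a,b) = p(b,a).

OTUs for diversity are furthest-neighbour (complete-linkage) clusters: the
within-OTU maximum pairwise distance never exceeds the cutoff, asserted on
every output.  The working cutoff of 0.1 protein distance is the sub-genus
level, checked by clustering a genus/species-labelled reference pool over a
cutoff grid and flagging where the OTU count falls between the species and
genus counts (≈0.2 lands at genus level).  Estimators are fed
unique-variant counts per OTU by default (diversity of distinct sequences,
reducing read-abundance redundancy); read-weighted counts are a flag away.
Chao1 uses the classic form `S + n1²/(2n2)` and switches to the
bias-corrected form only when doubletons are absent; ACE uses the standard
rare/abundant split at 10.  Shannon is in nats, so Pielou's J = H/ln(S).
Rarefaction is the analytic hypergeometric expectation (computed with
log-gamma, no simulation).

## Cross-site structure

The cross-site OTU table uses greedy incremental clustering at >90%
identity: sequences ordered by total count (ties: longer, then
lexicographic) either join the first cluster whose *representative* they
match above threshold or found a new cluster.  This keeps the
abundant-sequence-as-centroid behaviour of word-filter clusterers while
using exact alignment identity, which is affordable at amplicon scale.
"More than 90%" is a strict inequality; an OTU at exactly 1.0% of a site
is likewise *not* dominant (strict >), while "rare" is ≤0.1% inclusive.

Neighbour joining follows Saitou–Nei with the usual fix for negative branch
lengths (clamped to zero, deficit moved to the sister branch so the joined
distance is preserved); additive matrices are recovered exactly.  Trees are
midpoint-rooted before UniFrac since the metric needs a root and no
outgroup is available.  Weighted normalized UniFrac is computed by branch
enumeration — `Σ bᵢ·|Aᵢ/A_T − Bᵢ/B_T|` over branches, normalized by
`Σ dⱼ·(Aⱼ/A_T + Bⱼ/B_T)` over leaves — with one representative sequence
per OTU weighted by OTU counts.  PCoA is Gower double-centering with
negative eigenvalues dropped from axes and variance denominators but
reported.  Bootstrap support resamples alignment columns, rebuilds the NJ
tree, and reports percent recovery per bipartition; values under the 50%
threshold are left unlabeled.

## Linking statistics

Pearson correlations use the two-tailed t transform on n−2 degrees of
freedom; with n = 5 sites these are fragile, which is why the report layer
rounds r to 2 decimals and applies no multiple-testing correction (matching
how such surveys report).  CCA follows ter Braak: chi-square-standardized
species matrix, weighted least-squares projection onto the environmental
space, SVD of the fitted matrix.  Five sites cannot support seven
environmental variables, so the implementation refuses more than n−2
variables and the documented procedure is forward selection by
constrained-inertia gain; consequently the cumulative-variance figure of a
full-variable ordination is not a reproducible quantity here.  The CCA
eigenvalues agree with an independent R implementation (vegan) to 1e-8 on a
fixed test matrix.

## What the synthetic data emulates — and what it does not

The generator reproduces the study's observable structure: 5 barcoded
libraries of ~8,000 reads; amplicons of barcode (8 bp, pairwise Hamming ≥5)
+ degenerate forward primer + ~240 bp coding insert + reverse-complemented
reverse primer (~282 bp total, matching the ~290 bp fragment design);
genus-structured reference proteins (within-genus divergence below
between-genus by construction); long-tailed lognormal site communities with
disjoint endemic taxon blocks and per-site σ as the tunable dominant
fraction; Ion-Torrent-style errors (substitutions at 0.005/base and ±1
homopolymer-length indels at 0.01 per run of ≥3 — rates chosen to match
published PGM error profiles, where indels in long homopolymers dominate);
per-read mean quality Normal(30, 4) clamped to [2, 40] so a realistic
~10% of reads fail the mean-Q25 filter; and linear tracer series with
multiplicative Gaussian noise, invertible exactly at zero noise.  Reverse
translation uses one fixed codon per residue — only DNA-level error realism
matters downstream, not codon usage.  A truth sidecar (read → site, taxon)
is always written and is the contract every recovery test is scored
against.

It does **not** model flowgram signal intensities, PCR amplification bias,
chimera formation kinetics (an optional two-parent midpoint splice stands
in), quality-correlated error rates, or real NrfA sequence composition.
Passing recovery tests therefore demonstrates that the pipeline's logic is
faithful under realistic error modes and abundance structure — not that
real Ion Torrent data would be filtered with identical yield.

## Problem sizes and numerical choices

The full-scale recovery check runs 5 sites × 8,000 reads over a 200-taxon
pool (120 taxa per site, endemic fraction 0.15, σ from 0.8 to 2.4 across
sites so the true dominant fraction climbs from ~50% to ~85%) — large
enough that per-site percentages are stable to well under a percentage
point of sampling noise, while completing in minutes on one core.  Unit
fixtures use 3 sites × 400 reads.  Distance-matrix work is O(n²) in unique
sequences and is the scaling bottleneck beyond a few thousand variants; the
cross-site greedy clusterer and the translation stage use banded
edit-distance search with early abandonment to stay linear-ish in practice.
Ties in furthest-neighbour clustering merge the lexicographically smallest
pair first; representatives are highest-count, ties lexicographic.
Degenerate inputs (single-OTU evenness, empty count vectors, all-zero
UniFrac communities, sub-3-point regressions) raise or return a missing
marker rather than guessing.

## Known limitations

* The denoiser cannot rescue reads carrying both an indel and a
  substitution; at default error rates this costs ~8–10% of quality-passed
  reads, a retention in line with what functional-gene amplicon pipelines
  of this design report.
* Greedy >90% clustering is order-dependent by design (abundance-first);
  a different tie order can move singleton error reads between clusters,
  which is why recovery guarantees are stated in percentage points, not
  OTU counts.
* CCA axis scores are reported in one common scaling; alternative scalings
  (site-focused vs species-focused) are not exposed.
* With five sites every correlation has n = 5; p-values are indicative
  only.
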