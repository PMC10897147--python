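# Methods

## Isotopologue envelopes

A peptide's envelope is computed exactly on the integer neutron-shift grid:
each element contributes the n-fold convolution of its single-atom isotope
distribution (binomial for two-isotope elements, multinomial otherwise), and
per shift bin we carry both the probability and the probability-weighted mass
offset, so bin abundances and bin mean masses are exact by linearity of
expectation. Isotope masses and abundances come from a single embedded table
(`turnoverms.constants`) shared by the production path and the enumeration
oracle used in the tests — comparisons therefore test the algorithm, not the
constants.

Label schemes modify the element distributions, not the line positions
directly: ¹⁵N enrichment replaces nitrogen's natural abundance with
`(1−p, p)`; ¹³C₆-lysine removes six carbons per labeled lysine from the
natural carbon pool and adds a fixed `6 × 1.00335484 = 6.020129 Da` per
label, because those six positions are isotopically pure. Modifications are
likewise split into a natural-abundance formula part (carbamidomethyl
C₂H₃NO; the TMT tag's C₈H₂₀NO₂ backbone; diGly C₄H₆N₂O₂) and a fixed-mass
part (the TMT tag's four ¹³C and one ¹⁵N), so envelopes of TMT-labeled
peptides keep the correct shape. Unrecognized bracketed deltas enter as pure
fixed mass — they shift but do not reshape the envelope.

Envelope lines below a relative abundance threshold (default 1e-6) are
dropped and the remainder renormalized; m/z uses a proton mass of
1.007276 Da. Truncation is the one approximation in this layer: identities
that hold exactly for the untruncated distribution (e.g. linearity of the
mean mass in the enrichment p) hold only to ~1e-6 at the default threshold,
which is why the exactness tests tighten the threshold instead of loosening
their tolerances.

## MS1 quantification

Old and new species of a peptide co-elute; their FA is measured from
reconstructed XIC areas. For each theoretical line, intensities within
±10 ppm are summed per scan and integrated over retention time by the
trapezoid rule (a single-scan window falls back to intensity × 1 s). The
10 ppm default is an XIC matching tolerance — deliberately narrower than the
50 ppm precursor tolerance a search engine would use, which serves a
different purpose. No intensity floor is applied. Charge states are
quantified independently and their areas summed per peptide.

Where the two species overlap in one window, `fit_fraction` bins both
theoretical envelopes onto the observed grid and solves a two-column
non-negative least squares for the pool weights; the old fraction is
`a_old/(a_old+a_new)` and the residual is the relative L2 misfit. NNLS is
ill-conditioned when the binned envelopes are nearly collinear, so fits with
cosine similarity > 0.99 (or fewer than two resolvable lines per species) are
flagged `unresolvable` and excluded from rollup. The exact deconvolution
used by the original instrument software is not public; NNLS on binned
envelopes is this package's defined, tested stand-in.

Identification is consumed, not performed: PSM tables carry the label-pool
assignment (mirroring a two-database search strategy), and the standard
filters are peptide length ≥ 5 residues, q ≤ 0.01, and optionally the
+114.042927 diGly remnant subset.

## Split-pool TMT

Each TMT channel is one animal; PSMs are split by precursor pool (old = fully
¹⁴N, new = ¹⁵N) before reporter quantification, and per protein and channel
`FA = Σ old intensity / (Σ old + Σ new)`. Channel loading is corrected by
total-intensity equalization ("divide by the channel sum, rescale by the mean
of the original totals"). Because a channel's loading affects its old and new
PSMs identically, the pipeline computes the equalization factors from the
combined old+new channel totals and applies them to both pool matrices
(`normalize_split_pair`); normalizing each pool to its own totals would force
every channel toward the same aggregate FA and erase the age trend. The
per-matrix `normalize_total` remains available for single-pool uses. Column
(per-channel) normalization was chosen over row normalization as the standard
reading of loading correction; both the choice and the pool handling are
explicit functions, so either convention can be swapped in.

Plexes are aligned on the bridge channel: per plex, protein-level aggregated
bridge intensities are compared to the first plex and the median ratio over
shared proteins becomes the plex scale factor (median for robustness when few
proteins are shared; protein-level rather than PSM-level aggregation for the
same reason). Missing channels propagate as missing, never zero-imputed.
Isotopic-impurity correction of reporter channels is out of scope.

## Rollup and statistics

Protein FA is area-weighted: `Σ I_old / (Σ I_old + Σ I_new)` over the
protein's unflagged peptides, matching chromatogram-area quantification
(a mean-of-peptide-FA rollup would weight a weak peptide equally with a
strong one). A protein quantified in fewer than `min_replicates` samples of
a metadata group is blanked for that group. NSAF abundance is
`(SpC/L)/Σ(SpC/L)`.

Group comparisons offer one-way ANOVA with Tukey HSD, Kruskal–Wallis, Welch
and Student t, and a two-way ANOVA (e.g. complex × age). After
Kruskal–Wallis the default post-hoc is Dunn's rank z-test with BH adjustment;
"Tukey after Kruskal–Wallis" is a nonstandard pairing sometimes reported in
the literature, so a Tukey-on-ranks mode is provided for comparability, with
Dunn/BH remaining the statistically defensible default. Reference-group
adjustment subtracts the reference-age median per protein (a difference, not
a ratio, so later row z-scoring is unaffected by the choice). Differential
abundance between arms is a per-protein Welch t on log₂ values with BH-FDR
(default α = 0.05) and up/down/ns classes; zero-variance rows are flagged
rather than tested.

## Trend clustering

Profiles (protein × age-group means, reference-adjusted) are z-scored per row
with the n−1 standard-deviation convention (stated so tests can be exact);
constant rows are dropped with a logged count. K-means uses Euclidean
distance, 50 random initializations, 300 max iterations and a required seed;
k is selected over 2–8 by maximum mean silhouette among candidates whose
smallest cluster has ≥ 10 members — the size bound acts as a filter on k,
not by merging small clusters — with ties resolved toward the smaller k.
`TrendClusterer` follows the scikit-learn estimator contract (`fit`,
`fit_predict`, `get_params`, trailing-underscore attributes) and composes
with sklearn tooling. Replicate reproducibility is checked by a centered PCA
of samples in protein space over complete-case proteins.

## Enrichment and overlap

Overrepresentation is the one-sided Fisher exact test (hypergeometric upper
tail) of a query set against each term of a GMT collection, restricted to an
explicit background, with BH-FDR across terms and significance at FDR < 0.05.
Terms are ranked by a combined score, `(−log₁₀ FDR) × log₂ fold`, with the
FDR floored at 1e-300 so numerically zero p-values still rank; this score is
this package's own definition of "combined FDR and fold enrichment". The
top four terms are reported by default. Set-overlap questions use the full
2×2 table against a stated universe with the two-sided Fisher test and the
cross-product odds ratio. No GO-graph ancestor propagation is performed.

## The synthetic cohort

The generator emulates the pulse-step design: five 3-month ¹⁵N windows over
ages 9–24 months, sexes M and F with the female profile shifted 9 months
later, 4 replicates per group except n = 3 for female 15 M and 24 M, and a
separate 7-day ¹³C₆-lysine pulse. Ground truth is first-order turnover with
a non-turning long-lived fraction,

```
FA_true = λ + (1 − λ) · exp(−k(a_mid − Δ_sex) · T),   T = 3 months,
```

the minimal generative model consistent with an old-pool fraction.
Defaults, chosen once as representative study conditions:

- ¹⁵N chow enrichment p = 0.96 (a generator parameter; the true chow value
  is not published).
- Base rates k₀ ~ lognormal(ln 0.5, 0.4) per month; archetype modulation is
  a Gaussian dip of depth 0.6 and width 1.8 months in k, centered at one of
  the five window midpoints — turnover slows, FA rises, around the
  archetype's age. Five archetypes are assigned round-robin over the default
  500 proteins and tied to compartment annotations (synapse, mitochondrion,
  chromatin, membrane envelope, nucleosome); the nucleosome archetype gets
  λ ~ U(0.2, 0.5), everything else λ = 0.
- Replicate (biological) noise: logit-normal jitter, σ = 0.15.
- Measurement noise: multiplicative lognormal, CV 10 %, per species and scan
  (MS1) or per reporter cell (TMT); channel loading factors U(0.7, 1.3)
  unless overridden.
- Proteasome structure: the packaged complex definitions (20S = Psma1–7 +
  Psmb1–7; 19S = Psmc1–6 + Psmd1–14; catalytic = Psmb1/2/5) are embedded
  under their gene symbols, with 19S rates scaled ×0.7 and 20S ×1.4 so the
  regulatory particle keeps a higher old-pool fraction, as observed for
  purified proteasomes.
- Peptide panels: 3–8 fully tryptic peptides per protein, length 7–16,
  charge 2–3, drawn deterministically from the seed.
- Inhibition arm: daily rates around ln 2 / 8 d (typical subunit half-life
  ≈ 8 days); the inhibitor multiplies degradation of the
  proteasome-associated set (complex members + 80 co-purifying substrates)
  by a factor (default 0.5) for 7 days, and inflates substrate abundance by
  1 + (1 − factor); n = 5 per arm.

The MS1 emitter writes Gaussian elution peaks (σ = 3 s, 2 s scan interval)
whose old/new amplitude split encodes each sample's realized replicate FA.
Elution apexes are placed in retention-time slots with a greedy m/z-conflict
check (no two co-eluting species within 25 ppm), because co-isolation
interference is deliberately not simulated — peptides that would collide
overflow into slots appended after the gradient. Recovery is therefore
judged against the realized per-replicate truth: measurement error alone,
with biological jitter part of the truth being recovered.

What the generator does **not** emulate — and hence what passing round-trips
do not establish about real data: chromatographic drift and peak-shape
asymmetry, co-isolation interference, missed cleavages, identification
errors, ratio compression in reporter channels, and real biological effect
sizes (the planted archetype separation is chosen to be recoverable; real
trends may not be).

## Numerical choices and degenerate inputs

Envelope truncation 1e-6 (1e-3 in the simulator, shared by its quant path so
noiseless round trips are exact); NNLS via active-set (scipy), with the
fraction left NaN when both coefficients are zero; Kruskal–Wallis on
all-identical data returns statistic 0, p 1 (no evidence of difference)
instead of propagating a 0/0; the two-way complex contrast returns p = 1 on
zero-variance input; BH adjustment is the standard step-up; zero-total
channels, empty term sets, all-zero observations and sub-minimum group sizes
raise immediately rather than producing silent NaNs. All stochastic stages
require an explicit seed and are deterministic given it; CSV/JSON writers use
fixed column orders and no timestamps so repeated runs are byte-identical.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run the full default cohort
(500 proteins, 38 samples, ~2 700 peptides, ~5 400 species) through the MS1
and TMT round trips, clustering and enrichment; envelope exactness is checked
by exhaustive enumeration on 50 peptides of length ≤ 6 (where enumeration is
cheap and exact); mixture recovery on a 21-point weight grid plus 100 noisy
replicates; and the statistics layer against closed forms and a
10 000-permutation oracle. These sizes were chosen as the smallest at which
every planted structure is identifiable.
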