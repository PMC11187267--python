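# Methods

Statistical conventions implemented by `mrmediate`. Throughout, instrument
*j* has exposure association β̂ₓⱼ (SE σₓⱼ) and outcome association β̂ᵧⱼ
(SE σᵧⱼ) after harmonization; k is the number of instruments.

## Instrument selection

SNPs are retained when the exposure p-value is strictly below 5×10⁻⁸, then
greedily LD-clumped: candidates are visited in ascending p-value (rsID
tie-break); a SNP is pruned when it has r² > 0.001 with an already-kept SNP
within a 10,000 kb window. Missing pairwise r² within the window is treated
as in-window and recorded as a warning. Instrument strength uses the
per-SNP variance explained R²ⱼ = 2·EAFⱼ(1−EAFⱼ)·β̂ₓⱼ² and
F = (R²/(1−R²))·((n−k−1)/k), with k = 1 per SNP and the summed R² for the
set-level F. SNPs with F ≤ 10 are removed.

## Harmonization

Outcome alleles are matched to the exposure's effect/other alleles in this
order: identical labels (no action), swapped labels (negate the outcome
effect and flip its EAF), strand complement (relabel only), swapped strand
complement (relabel, negate, flip EAF). Palindromic SNPs (A/T or C/G) are
strand-ambiguous: after nominal label alignment their orientation is
resolved by comparing effect-allele frequencies across studies, and they are
excluded when either study's EAF lies in the intermediate window
(0.42, 0.58). Unresolvable allele sets and SNPs absent from the outcome are
excluded with reason codes.

## Estimators

- **Wald ratio**: β̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ, SE σᵧⱼ/|β̂ₓⱼ| (first-order, no
  measurement-error term in β̂ₓ).
- **IVW**: inverse-variance weighted mean of the Wald ratios with weights
  wⱼ = (β̂ₓⱼ/σᵧⱼ)², equivalent to weighted regression through the origin.
  Fixed-effect SE is 1/√Σw; the default multiplicative random-effects model
  scales it by max(1, √(Q/(k−1))). One instrument degrades to the Wald
  ratio.
- **MR-Egger**: weighted least squares of β̂ᵧ on β̂ₓ with a free intercept
  and weights 1/σᵧ², after orienting all instruments to β̂ₓ > 0. Standard
  errors are scaled by max(1, √(RSS/(k−2))) and p-values use the t
  distribution with k−2 degrees of freedom. A non-zero intercept indicates
  directional pleiotropy; the slope is the pleiotropy-adjusted effect
  (InSIDE assumption).
- **Weighted median**: the 50% point of the weighted empirical CDF of the
  ratios, interpolated between adjacent order statistics; SE by parametric
  bootstrap (resampling β̂ₓ, β̂ᵧ from their sampling distributions).
  Consistent when ≥50% of instrument weight is valid.
- **Mode-based estimate**: the mode of a normal-kernel-smoothed density of
  the ratios, with the modified Silverman bandwidth
  0.9·min(sd, MAD/0.6745)·k^(−1/5). Weighted variant uses inverse ratio
  variance weights; the simple variant weights equally. The mode is located
  by a 2048-point grid scan refined by root-finding on the analytic density
  derivative; SE by parametric bootstrap.
- For binary outcomes, estimates are reported as odds ratios,
  OR = exp(β), with CI exp(β ± 1.96·SE).

## Sensitivity

- **Cochran's Q** around the IVW fit: Q = Σwⱼ(β̂ⱼ − β̂_IVW)², referred to
  χ²(k−1); the Egger variant uses the weighted regression RSS on k−2 df.
- **Egger intercept test**: intercept, SE and t-test (k−2 df) from the
  Egger regression.
- **Leave-one-out**: IVW re-estimated with each SNP omitted; SNPs whose
  omission moves the estimate outside the full-set CI are flagged
  influential.
- **Radial MR**: IVW re-expressed in radial coordinates with iterated
  modified second-order weights wⱼ = β̂ₓⱼ²/(σᵧⱼ² + β̂²σₓⱼ²); per-SNP Q
  contributions are referred to χ²(1) and SNPs with p < 0.05 are flagged.
- **MR-PRESSO**: the observed global RSS (leave-one-out weighted residuals)
  is compared with parametric simulations under the leave-one-out fits;
  the global p-value is the rank-based (r+1)/(n_sim+1). Per-SNP outlier
  p-values are raw simulation exceedance fractions, Bonferroni-compared to
  α/k, and only reported when the global test rejects (p < 0.05). The
  distortion test compares the outlier-corrected IVW shift against random
  removals of the same size.

## Mediation (two-step MR)

With b₁ the exposure→mediator effect (exposure instruments), b₂ the
mediator→outcome effect (mediator instruments), and total the
exposure→outcome effect, the indirect effect is b₁·b₂ with Sobel SE
√(b₁²·se₂² + b₂²·se₁²). The proportion mediated is indirect/total with
ratio-delta variance se_ind²/total² + ind²·se_tot²/total⁴ (on the log-odds
scale for binary outcomes). Exposure instruments that reach genome-wide
significance in the mediator GWAS are excluded from the b₂ leg: their
mediator association is induced by the exposure, and using them would pull
b₂ toward total/b₁.

## Synthetic data

Per instrument: MAF ~ U(0.05, 0.5); true exposure effect γⱼ = |N(0, σ_γ²)|
(effect alleles oriented to the trait-increasing allele, the convention for
published instrument panels); mediator truth b₁γⱼ; outcome truth
(θ_direct + b₁b₂)γⱼ + αⱼ with pleiotropic offsets αⱼ ~ N(μ, σ_α²) on a
configurable SNP fraction. A second, independent set of mediator-specific
instruments (effects δⱼ on the mediator, b₂δⱼ on the outcome) identifies
the b₂ leg. Observed effects add independent noise per study with
SE = 1/√(2·MAF(1−MAF)·n) — the studies are non-overlapping by construction,
matching the two-sample design. Variants are placed far apart so LD clumping
is a no-op, consistent with post-clumping data.

## Error-control conventions

Type-I error for Cochran's Q and the Egger intercept is verified under the
global null (θ = 0), where the outcome associations are pure noise and both
statistics have their nominal reference distributions exactly. Under a
non-zero causal effect the first-order Wald-ratio variance omits the β²σₓ²
term, so Q is conservative/anticonservative depending on instrument
strength; pipeline defaults mitigate this through the F > 10 screen.
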