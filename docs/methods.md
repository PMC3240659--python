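# Methods

## Experimental structure modeled

The pipeline targets a repeated-small-perturbation time course: cells are
dosed three times, eight hours apart, and harvested with paired controls at
six time points — T1, T3, T5 thirty minutes after each dose, T2, T4, T6
eight hours after each dose (immediately before the next one).  The twelve
resulting samples (C1..C6, UV1..UV6) are measured on seventeen dual-color
slides arranged as a loop: a twelve-slide cycle
C1→UV1→C2→…→C6→UV6→C1 (Cy3 at the arrow tail, Cy5 at the head), two
dye-swap hybridizations, two technical replicates, and one self–self mock
slide used for QC only.  The role-to-slide-number map (11 and 15 technical
replicates, 14 and 16 dye swaps, 17 mock) follows the published design;
the exact placement of the extra slides on particular sample pairs is not
recoverable from the published description, so the default is one
consistent reconstruction (swaps of cycle slides 2 and 8, replicates of
cycle slides 1 and 7, C1/C1 mock).  Any other topology can be supplied as
a design-sheet CSV.

## Measurement model and loop estimation

For one gene, the normalized log ratio of slide k is modeled as

    m_k = γ + λ(head_k) − λ(tail_k) + ε_k,   ε_k ~ N(0, σ²)

with a single dye-bias term γ per gene shared across the sixteen non-mock
arrays, a relative log2 level λ per sample, and iid residuals.  Replicate
spots are averaged to one slide-level response before fitting (equal
weights), so QC dropouts do not bias the within-slide mean.  Technical
replicate slides enter as independent equations.  λ is identifiable only
up to an additive constant; λ(C1) = 0 is pinned, which cannot affect the
reported contrasts x_i = λ(UVi) − λ(Ci).

The least-squares solution uses the SVD (minimum-norm when rank
deficient).  A contrast is *estimable* iff its coefficient vector lies in
the row space of the gene's design matrix, tested by projection onto the
right singular vectors with a fixed tolerance (1e−8 relative).
Combinatorially this is a gain-graph condition, not plain connectivity:
walking from Ci to UVi through available slides accumulates ±γ with each
crossing, so the contrast is estimable iff the two samples are connected
*and* either some cycle anywhere in the gene's slide graph has nonzero
net orientation (identifying γ — e.g. a dye-swap pair, or the full
twelve-slide cycle) or the connecting path's orientation sum is zero.
The test suite checks the algebraic flags against an independent BFS
implementation of exactly this rule.  A gene with any non-estimable
contrast is *singular* and excluded downstream.  Standard errors come from
σ̂² · cᵀ(XᵀX)⁺c with σ̂² = RSS/(n − rank); when the residual degrees of
freedom are zero the contrasts are still reported but σ̂ and the standard
errors are flagged missing.

## Spot QC and normalization

Validity requires, with strict inequalities as printed in the original
criteria: SNR = (FG − BG)/SD(BG) > 5 in both channels, diameter > 75 µm,
and pixel CV < 1.0 (100%) in both channels.  CV is a fraction internally;
percentage conversion is an I/O concern.  Zero background SD makes SNR
undefined; such spots are flagged invalid by default (`zero_bsd_policy=
"invalid"`), with an `"infinite"` policy available for noiseless synthetic
data.  Background correction is plain subtraction (FG − BG), consistent
with the SNR definition's signal-minus-background usage.

Normalization removes the intensity-dependent trend of M on A within each
(slide, print-tip block) group: M′ = M − ĉ(A), ĉ fitted by lowess with
span 0.4 and 3 robustness iterations (the community default for
print-tip-group normalization; configurable).  Groups under 20 spots are
median-centred instead of curve-fitted.  A is never modified, and
normalization is shift-equivariant by construction.

## Steady-state statistic and null calibration

The template v = (r, s, r, s, r, s) encodes response (r) at T1, T3, T5 and
relaxation (s) at T2, T4, T6; r and s are arbitrary with r ≠ s.  The
statistic is the Pearson correlation R between a complete profile x and v.
Because v is two-valued, R reduces exactly to

    R = sign(r − s) · [mean(x₁,x₃,x₅) − mean(x₂,x₄,x₆)] / (2 · SD_pop(x)),

using the population (n-denominator) SD, which keeps R ∈ [−1, 1]; the
package validates this closed form against brute-force Pearson correlation
to 1e−12 over random profiles and patterns.

Two conventions coexist deliberately: the variability filter uses the
*sample* SD (n−1 denominator, default cut 0.21, strict), while R uses the
population SD internally as the algebra requires.  Both are exposed
(`sd_ddof`), and the defaults are documented here because the choice is
genuinely underdetermined; with six points the two differ by a factor
√(6/5) ≈ 1.095.

The null model draws profiles of six iid standard normals and scores them
against v (mode `"normal"`); a per-profile permutation mode is also
provided.  Both are exchangeable nulls; the marginal density of R for
profile length n is the fixed-vector correlation density

    f_n(r) = (1 − r²)^((n−4)/2) / B(1/2, (n−2)/2),  r ∈ [−1, 1],

whose n = 6 member is 0.75·(1 − r²).  The Monte-Carlo default is 10⁶
draws; at that size the empirical density at zero sits within ±0.01 of
0.75 and the KS distance to the analytic CDF is well under 0.002.  Note
the permutation null of one *fixed* profile is discrete (720 atoms), so it
is tested against exact enumeration, not against the continuous density.
P(|R| > 0.75) under the analytic null is exactly 0.0859375.

Classification: genes failing the SD filter are "none"; otherwise
R > 0.75 → "up" (class I), R < −0.75 → "down" (class II), with strict
inequalities.  Profiles with any missing time point are excluded from
scoring rather than rescored on a shorter template, because f_n depends
on n.  In directional-consistency counts, exact zeros count as neither
direction and are reported separately; missing entries leave the
denominator.

## Synthetic data generator

The generator emulates the measurement chain so that ground truth is
available at every stage.  Gene archetypes fix the true contrasts:
steady_up (+a, 0, +a, 0, +a, 0), steady_down its negation, cumulative up/
down a monotone ramp a·(1..6)/6, and flat all-zero.  Per gene, a dye bias
γ ~ U(−0.3, 0.3), noise σ ~ U(0.05, 0.15), and an intensity baseline
A₀ ~ U(8, 12) log2 units are drawn.  Each spot's log ratio is
γ + Δλ + N(0, σ) (+ an optional injected per-block M-vs-A trend for
normalization tests); channel intensities are reconstructed as
2^(A₀ ± M/2) above a lognormal background floor, so background-corrected
M and A recover the intended values exactly.  Defective spots (probability
0.2 by default) violate exactly one QC criterion — low SNR, small
diameter, or high CV, chosen uniformly — making QC truth labels exact.
One top-level seed drives per-gene substreams spawned from (seed, gene
index), so adding genes never perturbs existing ones and identical
configurations are byte-identical on disk.

Default scale: 600 genes (100 steady up, 100 steady down, 50 + 50
cumulative, 300 flat) in quadruplicate over 4 print-tip blocks, effect
size a = 0.5 log2 units.  The block count is deliberately small so that
each block carries ~600 spots per slide: lowess trend estimation needs
realistically dense blocks (production arrays carry thousands of spots
per pin group), and miniature blocks would let a gene's own replicates
drag the local trend and attenuate its contrasts — an artifact of scale,
not of the method.  The default defect rate (0.2) keeps the loop fully
estimable for almost all genes; the high-defect regime observed in real
scans (~56% defective, ~44% survival) is exercised explicitly in tests
and in the acceptance script, where it reproduces the expected survival
fraction and a realistic singularity load.

What the generator does **not** emulate: spatial artifacts beyond
per-block trends, scanner saturation, correlated technical-replicate
errors, intensity-dependent variance, and cross-hybridization.  Passing
tests therefore demonstrate correctness of the inference chain under its
own model assumptions, not robustness to every failure mode of real scans.

## Numerical choices and problem sizes

Rank decisions use a tolerance of max(dim)·eps·σ_max (floored at 1e−9);
estimability projection uses 1e−8 relative.  Lowess groups below 20 spots
fall back to median centring.  Missing values are "NA" in all TSV output.
Monte-Carlo checks in the test-suite and acceptance script use 10⁶ null
draws, 500-gene recovery runs, 200 random dropout patterns, and the
600-gene default pipeline — sizes chosen to make sampling error small
relative to the tolerances tested while keeping a full run in well under
a minute each.

## Known limitations

* The dye bias γ is one constant per gene across arrays; array-specific
  dye effects are assumed absorbed by normalization.
* No empirical-Bayes shrinkage or mixed-effects variance partitioning;
  technical replicates are treated as independent.
* The SD > 0.21 and |R| > 0.75 cut-offs are fixed operating points of the
  published procedure, not re-derived from the null here; the null-model
  tooling (`analytic_tail_probability`, `NullModel`) lets users map any
  threshold to its null tail mass.
* Genes with missing time points are excluded from R scoring rather than
  rescored on shorter templates.
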