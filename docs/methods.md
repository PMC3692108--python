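# Methods

This note documents the statistical machinery behind `biosimgen`: the models,
their assumptions, the defaults that matter, and what the synthetic test data
do and do not establish about behavior on real data.

## 1-D density estimation (`densities`)

Every scalar characteristic — sequence length, per-record symbol fraction,
numerical feature — is modelled by a smooth 1-D density and sampled by
inverse-CDF interpolation on a 2048-point grid spanning the data range
extended by 1% (clamped to any declared bounds).

The primary estimator is a log-spline density fitted by Lindsey's method:
the data are binned (30–150 bins, ~n/4), bin counts are modelled by a
Poisson regression on a cubic B-spline basis of the bin centres (IRLS with a
tiny ridge for stability), and the number of interior knots is chosen by BIC
over the candidate grid {3, 5, 8, 12}. The fitted log-density is therefore a
cubic spline with maximum-likelihood coefficients. Two guards apply:

* fewer than 10 distinct values → empirical quantile-function fallback
  (exact for point masses; degenerate all-equal input returns a point mass
  with a warning);
* a goodness-of-fit check compares the fitted CDF with the empirical CDF at
  the data points; if the sup-distance exceeds max(0.05, 1.36/√n) — the
  asymptotic 95% KS band — the fit falls back to a Gaussian KDE (Silverman
  bandwidth) with boundary reflection at finite bounds. This matters for
  boundary-piled data such as composition fractions of rare residues, where
  an unpenalized exponential spline can spike at 0.

Integer-valued characteristics (lengths) are fitted as continuous and
rounded at sampling time, truncated below at 1.

## Blueprint sequence model (`seqsim`)

A sequence set is summarized by one length density and one density per core
alphabet symbol (4 nucleotides or 20 amino acids) of the per-record symbol
fraction; ambiguity codes (N/X) are accepted on input, excluded from
composition denominators, and never emitted. Composition components are
sampled independently per symbol, clipped at 0 and renormalized to the
simplex; residues within a sequence are drawn i.i.d. from the blueprint
composition. Order structure is deliberately out of scope for this model —
it is the profile HMM's job. A joint (Dirichlet or record-bootstrap)
blueprint model that couples length with composition is a documented
alternative we did not implement; for composition-only downstream uses the
independent per-symbol model preserves every marginal by construction.

## Profile HMM (`profilehmm`)

A minimal plan-7-like topology (match/insert/delete per node, begin/end, no
flanking states). Columns with gap fraction < 0.5 become match states (the
HMMER-style heuristic). Match emissions are column counts with Laplace
pseudocount (default 0.1); insert emissions are the overall residue
background; transitions are counted from each row's implied state path and
smoothed with the same pseudocount, which also guarantees the insert
self-loop probability stays below 1 so traversal terminates. The profile is
serializable to a plain-text state table. Alignment is an input
(aligned FASTA), not a pipeline stage.

## Gaussian copula feature simulation (`featsim`)

The preserved dependence quantity is the Spearman rank correlation, mapped
to the normal-score scale by the exact transform r = 2 sin(πρ/6) before
Cholesky factorization. Grouping modes: `independent_1D` (no copula),
`pairwise_2D` and `triplet_3D` (each declared or auto-formed group simulated
jointly; independence between groups; auto-grouping greedily pairs the
strongest |ρ|), and `full`. Non-positive-definite targets are repaired by
eigenvalue clipping at 1e-10 followed by re-normalization to unit diagonal;
the Frobenius repair distance is recorded on the model and reported, never
silent. Marginals on the copula path are the same fitted densities as
everywhere else; because sampling inverts each marginal's own CDF, the
copula cannot alter marginal laws.

## Monte Carlo rejection (`mcreject`)

Defaults: two-sided per-feature tail mass q = 0.025 (empirical quantile
bounds with linear interpolation) and Mahalanobis tail probability
α = 0.025, i.e. reject when d² exceeds the χ² quantile at 1−α with df equal
to the multivariate subset size. α is the *rejected* tail mass: under a
matched multivariate-normal null the acceptance rate is 1−α, and α→0
disables the rule. The subset for the multivariate rule is configurable
because a full pseudo-AA vector is simplex-constrained (components sum to
1), making its sample covariance singular; the sequence-order components
(θ₁..θ_λ) are a natural default subset. Covariance may be the sample
estimate or a median/MAD-based robust variant. Batch size per round defaults
to max(target_n, 1000) with a 50-round budget; an unmet target returns the
partial set with a shortfall flag, and zero acceptance raises a diagnostic
error citing the criteria.

## Feature extraction (`featex`)

Pseudo-amino-acid composition uses the classical three scales
(hydrophobicity, Hopp–Woods hydrophilicity, side-chain mass), each
standardized to mean 0 / SD 1 over the 20 residues before use. With
sequence-order depth λ (1..10, default 4) and weight w (default 0.05), the
vector of length 20+λ is a probability vector by construction. The
"fourth-degree" configuration used in the evaluation study corresponds to
λ = 4.

Dinucleotide features are means of per-property values over all overlapping
windows; U maps to T for lookup and windows containing N are skipped. The
bundled table holds 12 representative conformational/thermodynamic
properties transcribed from standard literature tables (base-step geometry:
twist, tilt, roll, shift, slide, rise; stacking energy; unified
nearest-neighbor ΔH, ΔS, ΔG°37; propeller twist; duplex stability/melting).
It is a reduced working set, not a replica of the full public catalogs
(122 conformational/thermodynamic and 38 physicochemical properties); those
load from a user TSV with header `property<TAB>AA<TAB>...<TAB>TT`.

## Validation machinery (`analysis`)

Spearman matrices use average-rank ties; constant columns yield NaN flags
rather than silent zeros. 1-D normality is Shapiro–Wilk (subsampled to 5000
points where larger); 2-D/3-D multivariate normality uses Mardia's skewness
(n·b₁/6 ~ χ² with d(d+1)(d+2)/6 df) and kurtosis (asymptotically normal)
tests, flagged at the fixed 0.05 level per test, uncorrected but reported
per-test. The "Bayesian" evaluation classifier is Gaussian naive Bayes
(scikit-learn); the probabilistic neural networks are Parzen kernel
classifiers scoring each class by the prior-weighted mean kernel similarity
to its training points, kernel exp(−‖x−xᵢ‖²/2σ²) or exp(−‖x−xᵢ‖/σ), with σ
defaulting to the mean nearest-neighbor distance in training space. MCC is
reported as 0 (flagged by construction) when a confusion-matrix marginal is
zero. Exhaustive feature-combination search is capped at 10 features (2¹⁰
subsets).

## Synthetic data (`fixtures`)

Sequence families draw per-record compositions from a Dirichlet law
(default concentration 5 per symbol; the two-class protein family biases
hydrophobic vs charged residues), lengths from log-normal/uniform/fixed
laws, with optional motif implantation under a per-position mutation rate.
The ground-truth correlated-feature sampler is a second, independent
Gaussian-copula implementation used as the oracle for the simulation path.
RNG streams are namespaced per operation (CRC-keyed seed sequences) so new
fixtures never perturb existing seeded outputs.

What the fixtures emulate: length laws, compositional spread, motif
conservation, rank-correlated features with non-normal marginals. What they
do not: residue-order statistics of real genomes (codon structure,
long-range correlation), indel evolution, alignment uncertainty, and
realistic feature tails beyond the laws above — so passing tests demonstrate
the machinery's calibration and fidelity guarantees, not biological realism
of any particular family.

## Problem sizes and numerical choices

The validation suite and the reproduction script run at desk scale, chosen
as the smallest sizes at which the asserted sampling bounds are sharp:
n = 4000 for correlation recovery (±0.05 on Spearman ρ), n = 5000 for
marginal KS (< 0.08), 10,000 candidates for rejection calibration
(0.975 ± 0.01 at α = 0.025), 2000 sequences simulated from a 50-record
family (length KS < 0.15, pooled symbol frequencies ± 0.02), and 150
training / 200 test records per class with 300 filtered simulated sequences
per class for the classifier-parity study (within 5 accuracy points for all
three classifier kinds). Ties in PNN class scores fall back to the majority
prior; degenerate inputs (constant features, all-equal samples, all-gap
alignments) raise explicit errors or return labelled point masses as
documented per module.

## Known limitations

* Length and composition are sampled independently; families in which long
  sequences systematically differ in composition are only partially
  captured.
* Group-wise copulas assume independence *between* groups; cross-group
  correlations are preserved only in `full` mode.
* The profile HMM has no flanking/local-alignment states and uses plain
  Laplace priors, adequate at the scale of curated input families but not a
  replacement for full profile-HMM suites.
* The χ² threshold for Mahalanobis rejection is exact only under
  multivariate normality of the feature subset; for heavy-tailed features
  the realized acceptance under the null deviates from 1−α (the robust
  covariance option mitigates, not removes, this).
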