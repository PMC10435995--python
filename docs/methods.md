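# Methods

This note documents the models, parameter choices and numerical decisions
behind `thermoshift`, and what the synthetic-data benchmarks do and do not
demonstrate about real data.

## TPP scoring model

A TPP experiment measures, per protein, the soluble fraction remaining
after brief heating at each of ten ladder temperatures (37–66.3 °C), in a
treatment and a vehicle arm, with each (condition, replicate) pair
occupying one TMT10 plex. The default ladder is
37, 40.4, 44, 46.9, 49.8, 52.9, 55.5, 58.6, 62, 66.3 °C. Protocols of this
family are sometimes printed with 68.6 °C in the eighth position, which
breaks monotonicity and is almost certainly a digit transposition of
58.6 °C; the literal variant is available as
`syndata.LADDER_AS_PRINTED` for anyone who wants to mirror such a listing.

**Normalization.** Each temperature is calibrated independently, because
absolute signal collapses at high temperatures and pooling would let the
low-temperature channels dominate. Within a temperature, every channel is
rescaled through the origin so its median matches the cross-channel
median target, then transformed with glog2
(`log2((x + sqrt(x² + c²))/2)`). Scale-only calibration (rather than a
full affine fit) reflects how TMT reporter distortions arise — labelling
efficiency and sampling depth act multiplicatively — and makes the
equal-median contract exact. The glog offset `c` defaults to 0 (plain
log2) so that fold-change arithmetic stays exact (a doubled signal is
exactly +1); a positive `c` is available to tame near-zero intensities in
data with additive background. Both transforms are strictly increasing,
so within-channel ranks are never altered.

**Batch removal.** Additive log-scale batch offsets are estimated per
temperature by least squares on a design with condition indicators plus
mean-centred batch indicators, and subtracted. Centring makes the
correction leave condition means untouched in balanced designs.
Confounded designs (batch aliased with condition) are rejected rather
than silently half-corrected. Because the default simulation assigns one
batch per replicate pair (both arms of a plex share a batch), batch
correction never touches the paired treatment−vehicle contrast; it
matters for melting-curve fits and unbalanced real designs.

**Scores and testing.** Fold changes pair treatment to vehicle by
replicate label. Scores are computed per replicate and tested across
replicates — with only two replicates, per-protein variance estimates on
one degree of freedom are hopeless individually, which is exactly the
regime variance moderation addresses. The moderated one-sample t follows
the standard empirical-Bayes scheme: per-protein variances are assumed
scaled-inverse-chi-square around a prior variance s₀² with d₀ prior
degrees of freedom, both estimated by matching moments of the
log-variances (digamma/trigamma inversion); posterior variances
`(d₀s₀² + d·s²)/(d₀ + d)` feed a t statistic on `d₀ + d` degrees of
freedom. When the observed variances are no more dispersed than chi-square
sampling noise predicts (the homoscedastic case, common in simulation),
d₀ → ∞ and the test reduces to a z-test against the pooled variance.
`prior_df=0` recovers the ordinary t-test.

FDR is Benjamini–Hochberg by default. An empirical-null alternative
(`fdr_method="empirical"`) rescales the statistic by a robust half-normal
null width (median |t| / Φ⁻¹(0.75)) before BH, for experiments where the
theoretical null is visibly miscalibrated; it is an option, not the
default, because BH on the moderated p-values already controls type-I
error in the simulated regime (pooled p < 0.05 fraction ≈ 0.042 across 20
global-null runs of 2000 proteins).

**Hit calling.** Classes are assigned purely by FDR: hit ≤ 0.01,
candidate ≤ 0.05, both configurable. The stability score's sign carries
the direction. These defaults are a design choice — there is no canonical
pair of cutoffs for this assay — and the recovery benchmark (sensitivity
≥ 0.9 at candidate level, FPR ≤ 5% under 5% noise and ±4 °C shifts) holds
with them.

**Melting curves.** Soluble fractions (replicate-averaged, scaled to the
lowest temperature = 1) are fitted with
`f(T) = plateau + (1 − plateau)/(1 + exp(slope·(T − tm)))` by bounded
multi-start least squares (tm over ladder quantiles, slope ∈ {0.1, 0.3, 1},
plateau bounded in [0, 1)). This logistic-in-T is the simplest monotone
sigmoid whose midpoint is directly the melting temperature. Flat or
poorly fitting profiles (amplitude < 0.2 or R² < 0.8) come back flagged
with diagnostics instead of raising, since a proteome-wide sweep must not
die on the first non-melter.

## CETSA dose series

Ratios are target/loading band intensities; Z-scoring is per
(drug, context) group with population SD (so a 3-point series maps to
±1.2247), sample SD selectable. Z-scoring within a group removes blot-to-
blot gain, which is why the transform is invariant to rescaling all
intensities in a group. The "minimal stabilising dose" summary is the
lowest dose with z ≥ threshold (default 0.5). Note a structural caveat:
the z-profile of a saturating dose series depends on how the dose window
brackets the EC50 — a window extending far into saturation drags the
group mean up and pushes the z = 0.5 crossing roughly one half-log step
above the EC50. The summary is therefore a *reading aid* for a given
panel, not an EC50 estimator.

## ITC model and fitting

Reverse titration is modelled exactly as performed: the ligand sits in
the cell (default 1 µM, 169 µl effective volume — overfill beyond the
working volume only guarantees a full cell), the protein is the titrant
(default 4.3 µM, 50 µl syringe, one 0.96 µl conditioning injection then
24 × 2 µl every 300 s at 37 °C; 24 injections is what the syringe volume
admits). Each injection displaces cell liquid at pre-injection
composition (cell-species totals scaled by 1 − v/V; the no-displacement
variant is selectable for sensitivity checks), the one-site quadratic
gives [PL] with the protein's site concentration scaled by *n*, and the
injection heat is ΔH·V·Δ[PL] net of complex carried out by the expelled
volume. Mass balance (free + bound = diluted total; K_d relation at every
step) is enforced by construction and verified in tests to 1e-8 relative.

Fitting estimates (log₁₀K_d, ΔH, n, offset) by trust-region least squares
from five log-spaced K_d starts, with ΔH initialised from the total heat
under the all-bound assumption. The first injection is down-weighted
(weight 0.1) per standard practice — conditioning injections suffer
syringe-tip diffusion. *n* floats by default (`fix_n=1.0` pins it).
Low-information fits are flagged rather than trusted: either a Wiseman
c-value (cell concentration / K_d) below 1, or a delta-method K_d
standard error above 50% of the estimate. The second criterion matters
because a featureless weak-binding isotherm can seduce the optimiser into
a spurious tight-binding optimum whose fitted c-value looks healthy; the
covariance check catches it.

Simulated noise is Gaussian per injection with SD = 2% of the largest
expected heat — the scale of peak-integration error in a clean run. At
the two simulated regimes (K_d 28.10 nM → c ≈ 36; 4.75 nM → c ≈ 211) the
median recovered K_d over 25 runs lands within a few percent of truth.

## Dose–response and expression

5PL fitting works on log₁₀ dose, with a zero-dose anchor mapped two
decades below the lowest nonzero dose (configurable). Multi-start
initialisation covers hill ∈ {0.5, 1, 2} × c_mid at dose quantiles;
`model="4pl"` pins asym = 1. "IC50" means the *relative* IC50 — the dose
at the midpoint between the fitted asymptotes, closed-form from the
parameters — matching the convention of mainstream graphing software;
responses are not renormalised before fitting since the generator already
produces vehicle-anchored viability. Rescue shifts are IC50 ratios with a
delta-method SE on the log fold propagated from both fit covariances;
flagged fits propagate flagged ratios. Degenerate inputs (flat curves,
midpoints outside the dose support) flag the fit instead of raising.

Enzyme inhibition is modelled as competitive
(`v = Vmax·S/(Km(1 + I/Ki) + S)`) — the natural mechanism for an
active-site-directed antifolate, and the model makes the rate-vs-inhibitor
curve *exactly* hill-1 log-logistic with IC50 = Ki(1 + S/Km), which the
IC50 extractor and its tests exploit.

Spearman correlation reports Pearson on mid-ranks, with an exact
permutation p for n ≤ 9 (fully enumerated) and the large-sample
approximation above. 2^−ΔCt expression is the direct formula with
validation of the reference Ct.

## Overrepresentation and chemistry scores

ORA is the one-sided upper-tail binomial (overrepresentation;
`underrepresentation=True` flips the tail), fold enrichment
`(k/n)/(K/N)`, BH across terms. The annotation database is caller input.
Tversky similarity consumes MCS atom counts directly (weights default
0.8 target / 0.2 template); whether the caller counts atoms or
atoms+bonds is their convention — only consistency across comparisons
matters. The two HADDOCK stage scores are fixed linear combinations as
published for that software's rigid-body and refinement stages.

## Synthetic data: what it shows and what it does not

The generators encode the study conditions: 2000 proteins, the
10-temperature ladder, two arms × two replicate plexes, 5% stabilised
(+4 °C) / 2% destabilised (−4 °C), 5% multiplicative log-normal channel
noise (TMT reporter noise is approximately multiplicative), optional
per-plex log2 batch offsets, melt parameters drawn as tm ~ U(46, 56) °C,
slope ~ U(0.25, 0.6) /°C, plateau ~ U(0, 0.25), abundance log-normal
around 10⁶ — ranges chosen to resemble a mammalian meltome's spread. All
generators are bit-reproducible from their seed.

Deliberately *not* simulated: peptide-to-protein rollup, reporter-ion
interference and ratio compression, missing values (optional dropout is
the only gesture), protein-protein covariance, and heteroscedastic
per-protein noise. Consequently the benchmarks demonstrate correctness of
the scoring arithmetic, calibration of the testing machinery under a
faithful null, and recoverability of realistic effect sizes at realistic
noise — they do not certify performance on real meltomes, where ratio
compression and co-melting complexes flatten effects, and where the
empirical-FDR option and peptide-level QC upstream earn their keep.

Problem sizes in the shipped benchmarks (2000-protein cubes, 20-seed null
sweeps, 25-fit medians) were chosen as the smallest sizes at which the
binomial/KS acceptance bands are meaningful.
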