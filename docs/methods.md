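# Methods

`deerscr` estimates population density of white-tailed deer (or any
comparable species) from non-invasive genetic sampling, propagating the data
through four stages: consensus genotyping of replicated PCR calls, matching
of samples to individuals, construction of spatial encounter histories, and
maximum-likelihood spatial capture-recapture (SCR) with habitat covariates.
A synthetic-data generator emulating the field design makes every stage
testable end to end.

## The SCR model

Activity centers `s` live on a discrete state space: the minimum-area
axis-aligned rectangle around the sampling plots, buffered (default 1000 m)
and tiled into pixels (default 120 m, area 0.0144 km²). Buffering by
roughly 8 half-normal scales ensures the state space contains essentially
all home ranges that could produce detections. Centers follow an
inhomogeneous Poisson point process with per-pixel expected count

    log mu_g(s) = x_d(s, g)' beta_d

per session `g` (sessions are closed annual sampling periods). Density
covariates are the pixel habitat class (treatment contrasts against
agricultural fields) and optional distances to water and artificial
surfaces. Detection of an individual with center `s` at trap `j` on
occasion `k` is Bernoulli with half-normal distance decline

    p_jk(s, sex) = p0_jk(sex) * exp(-d(s,j)^2 / (2 sigma^2)),

`p0` on the logit scale (occasion, sex, session, trap habitat class with
coniferous reference, and distances, centered at their mean so intercepts
refer to an average plot) and `sigma` on the log scale in meters (session,
sex, and their interaction coded as cells against the female/first-session
cell, matching the usual reporting layout). Sex is a two-point mixture with
probability `psi` (logit intercept) of being female; unknown-sex histories
are marginalised over both components.

The likelihood is the integrated (Poisson) form: per session,

    logL_g = sum_i log[ psi_{m_i} sum_s mu_g(s) P(y_i | s, m_i) ]
             - sum_s sum_m psi_m mu_g(s) pbar_g(s, m)

with `pbar = 1 - prod_jk (1 - p_jk)` the probability of at least one
detection. Additive constants free of parameters are dropped. The Poisson
(rather than binomial-N) form was chosen because it yields a deterministic
ML fit in which total abundance is a derived quantity, which suits an
AIC-driven workflow; the two forms agree up to the abundance model.
Individuals seen in more than one session contribute an independent history
per session, the standard closed multi-session treatment.

Fitting is quasi-Newton (BFGS) on the summed negative log-likelihood,
gradient tolerance 1e-8, from a deterministic start (coefficients 0, log σ
at half the maximum inter-trap distance, density intercept at the observed
count per pixel). Standard errors come from the inverse numerical Hessian
(Wald inference, delta method for back-transformed quantities); profile or
bootstrap intervals are out of scope. Pixel integration is the midpoint
rule at pixel centers, standard for discrete-state-space SCR; resolution is
a parameter with 120 m default.

Numerical notes: the per-pixel log detection odds are floored at −800
before the observed-history matrix product (exp(−800) already underflows
to zero, so the floor only replaces −inf from underflowed probabilities by
a finite stand-in); when baseline detection is occasion-constant the
occasion axis is collapsed before the log-sums; individual marginals use
log-sum-exp over pixels. A non-finite likelihood evaluates to 1e300 so the
optimizer retreats rather than aborts.

## Model selection

AIC = 2·negLogL + 2K, with Akaike weights exp(−ΔAIC/2) normalised over the
candidate set. Selection is two-step: rank homogeneous models (density,
detection, σ varying only by session, occasion, sex) first, then rank
habitat-covariate extensions of the winner. This mirrors common SCR
practice and keeps the candidate count manageable. The default homogeneous
grid crosses {1, session} × occasion/sex/session structures for detection
× {1, sex, session, session*sex} for σ; the published analyses this
emulates used a hand-chosen set of similar size, whose exact composition is
not recorded, so the grid is user-editable. Ties in the AIC sort break by
fewer parameters, then label, for reproducibility. Non-converged candidates
are excluded with a warning.

## Genotyping model

Each fecal sample is genotyped in triplicate at 14 microsatellite loci.
The multitubes consensus rule accepts a heterozygote when each allele
appears in at least two replicates and a homozygote when its allele appears
in at least three with no second allele confirmed; a replicate showing
(A,B) counts one amplification for each allele. Two alleles that each
reach the homozygote threshold without ever being seen together twice are
treated as irreconcilable and the locus stays uncalled — a conservative
choice for a situation the standard rule leaves open. Samples with at
least 11 called loci proceed to matching; pairs match when, over loci
called in both samples, at most 2 differ and at least 6 agree (loci called
in only one sample are neither matches nor mismatches). Individuals are
single-linkage components of the match graph; components containing a
non-matching pair (the relation is not transitive) are flagged rather than
split, and conflicting sex assignments within an individual flag it and set
sex to unknown.

Marker informativeness is summarised by the probability of identity,
per locus `PI = 2(Σp²)² − Σp⁴` and `PIsib = 0.25 + 0.5Σp² + 0.5(Σp²)² −
0.25Σp⁴`, multiplied over the k least informative loci (largest per-locus
values, default k = 6 to match the minimum-matching-loci rule), plus
expected (1 − Σp²) and observed heterozygosity per locus.

## What the synthetic generator emulates — and what it does not

The generator reproduces the survey's statistical structure: a 23-cluster
× 4-plot design (60 m within clusters, nominally 300 m between), a
landscape dominated by agricultural fields (~76% of the state space) with
a forest patch of coniferous/mixed/transitional mosaic around the plots,
two sessions with 2 and 5 occasions, half-normal Bernoulli detections, and
triplicate genotyping with amplification failure f = 0.21 and allelic
dropout d = 0.18 per replicate. Those error rates were calibrated once, by
exact enumeration of replicate outcomes through the consensus rule, so
that the ≥11-loci pass rate is ≈32%, the success rate characteristic of
fecal DNA in this system; allele frequencies default to four equifrequent
alleles per locus, a deliberately simple spectrum for an introduced
population with reduced allelic richness (true spectra are not public).

Two deliberate departures from strict field geometry: the cluster grid is
4 columns × 6 rows minus one corner cluster (23 clusters, 92 plots) with a
row pitch of 278 m instead of 300 m, chosen so the buffered bounding
rectangle tiles to exactly 25 × 29 = 725 pixels (10.44 km²), the state
space extent of the real survey; and the landscape's forest patch is a
rectangle with a Voronoi mosaic inside, which matches class proportions
but not real patch shapes. The generator also ignores DNA degradation over
exposure time (only aggregate success rates), deposits at most one sample
per individual per trap-occasion (anything more is invisible after
binarisation), has no false alleles (dropout dominates fecal-DNA error),
and places activity centers independently — real deer form groups, so
field data can be over-dispersed relative to the simulation. Passing
recovery tests therefore demonstrates correctness of the estimator under
the model's own assumptions, not robustness to these violations.

## Default study conditions

Truth defaults for simulation: density intercept log(16 × 0.0144) (≈16
deer/km² in the reference class and session) with a +0.88 session-2
effect; baseline detection logit −2.08 (p0 ≈ 0.11) with a −1.13 session-2
effect; σ = 270 m on the log scale; ψ = 0.5. These are the magnitudes of
the published estimates this package was built to reproduce in structure.
The recovery experiment runs 50 replicates at this preset and fits the
generating model (session-specific density and detection, common σ); 50
replicates keeps the Monte-Carlo error on a 95% coverage proportion near
±3 points while the full experiment stays in the low minutes on one core.

## Tie-breaks and degenerate inputs

Majority aggregation of the fine land-cover raster onto pixels excludes
artificial cells (≈2% of the area) and breaks ties by the fixed priority
agricultural > mixed > coniferous > transitional; trap-buffer assignment is
restricted to the three forest classes with priority mixed > coniferous >
transitional. The original analysis resolved ties from field notes, which
are not available, so a deterministic rule was chosen and documented.
Pixels with no covering fine cells, traps with no eligible buffer cells,
empty feature sets and empty trap arrays are errors; a session with no
detected individuals is dropped from the encounter array; no recaptures
yields an empty distance table with a warning rather than an error.

## Known limitations

Planar metric coordinates only (no CRS handling); distances to features
are point-set distances (features must be supplied pre-densified);
detection is binary per trap-occasion (no counts); no ecological-distance
σ, no open-population dynamics, no Bayesian fitting, no model averaging,
no AICc. Back-transformed tables recomputed from rounded printed
coefficients can differ from originally published data-scale values in the
last digit; the reporting helper flags such rows instead of forcing
agreement.
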