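# Methods

This note documents the models, parameters, numerical choices and known
limitations of `nestwebs`, in the order the pipeline runs.

## System and data model

The unit of observation is one red wood ant nest mound with counts of 16
symbiont functional groups — 9 obligately ant-associated (identified to
species and pooled by feeding ecology: predator, scavenger,
scavenger-predator, detritivore, brood predator) and 7 facultative pooled
higher taxa — plus covariates: age class (new: < 1.5 years; old: ≥ 5
years), connectivity (old nests within 100 m), moisture, pH, canopy
openness and coordinates.

Trophic structure is stored as explicit (consumer, resource) edge records
over the 16 groups and two aggregate basal resources (ant brood; nest food
= corpses, organic material, fungi, spores). Matrix views are derived on
demand in either orientation, never stored, so no row/column convention can
silently flip.

**The packaged adjacency is a synthetic reconstruction**, not a transcribed
field diet table. Edges follow each group's documented feeding ecology:
detritivores and scavengers consume nest food; the brood predator (and the
large generalist scavenger-predator) consume ant brood; predators and
scavenger-predators take the small soft-bodied groups (springtails, mite
and fly/booklouse larvae pools), with the generalist also taking beetle
larvae and isopods. One structural calibration criterion guided the
reconstruction: equal-size webs of obligate-rich versus facultative-rich
composition should be near-equivalent in trophic-link and competition-pair
density, because in this system the wiring is not what differentiates the
age classes — only then can the even-abundance scenarios act as a clean
control. Users with a field diet table can substitute it via
`io.read_adjacency`.

Missing abundance cells are an error, never an imputed zero: rarity
thresholds are empirical quantiles of the observed counts, and silent zeros
would shift every threshold.

## Synthetic-data generator

Counts are lognormal-Poisson:

    count_gj ~ Poisson(exp(b_g + beta_g * 1{old_j} + env_g' z_j + q_j + e_gj))

with per-group baseline `b_g` and age effect `beta_g`, small standardized
environment effects, a shared per-nest quality intercept `q_j ~ N(0,
nest_sd²)`, and per-cell overdispersion `e ~ N(0, overdispersion²)`. The
Poisson mixing keeps counts integer while the lognormal mean reproduces the
right-skewed abundance structure of such surveys. The nest-quality term
induces the positive across-group abundance covariance seen in these
communities and spreads community richness within each age class; because
relative abundances are ratios, it leaves the evenness contrast intact.

The default preset (`data/preset_studylike.yaml`) encodes the study
conditions the generator emulates: 51 nests, half old; strongly positive
age effects for all nine obligate groups (log-scale 1.8–2.4); negative age
effects for the two dominant facultative detritivore pools and flat
responses for the rest; overdispersion 0.8 and nest-quality SD 0.65.
Per-group effect magnitudes are free parameters (no numeric values exist
for them); they were tuned once, by simulation, to aggregate targets —
mean Pielou J ≈ 0.73 in old and ≈ 0.55 in new nests, on the order of 8 000
obligate and 20 000 facultative individuals in total, and overlapping
community-size ranges between classes — and then frozen. Covariates are
drawn from field-plausible ranges (moisture ≈ N(0.45, 0.12), pH ≈ N(4.6,
0.4) — organic thatch is mildly acidic — canopy Beta(2.5, 4), connectivity
Poisson(1.5), coordinates in a 500 m square). A smooth Gaussian spatial
field (squared-exponential covariance, 150 m range) can be added to the log
means; it is off by default so unit tests stay interpretable.

What the generator does *not* emulate: species-level records below the
functional-group pooling, temporal dynamics, real spatial layouts along
forest edges, and any fitted posterior of a joint species distribution
model. Passing tests therefore demonstrate that the pipeline detects the
evenness-stability mechanism when it is present with realistic noise — not
that any particular field dataset contains it.

## Community statistics

* **Evenness.** J = H/ln S with H the Shannon entropy (natural log) over a
  nest's positive counts. S < 2 is flagged undefined rather than propagated
  as NaN. All 16 groups with positive counts enter J.
* **Bray–Curtis** on raw counts (no transformation or standardization).
* **PERMANOVA** is implemented from the Gower-centred matrix G of −d²/2
  (McArdle–Anderson): sequential (type-I) sums of squares tr(H_k G) for the
  cumulative hat matrices of age + connectivity + age:connectivity, free
  row permutation, p = (1 + #{F* ≥ F}) / (1 + n_perm) with a relative
  tolerance of 1e-12 on the comparison so tied permutations count (exact
  discrete cases would otherwise lose ties to rounding). It is written
  in-house because the study design needs sequential multi-term
  partitioning; one-way results agree with scikit-bio's PERMANOVA to
  floating-point precision, and on six samples the permutation p matches
  full enumeration of all 720 labelings.
* **PERMDISP** delegates to scikit-bio (distances to group spatial medians
  in principal-coordinate space, permutation F).
* **Beta regression** of J (logit mean link, single constant precision) via
  statsmodels' BetaModel; per-coefficient Wald χ² = (β̂/se)². Exact 0/1
  responses are shrunk with (y(n−1) + 0.5)/n and flagged.

## Food-web construction

A group is a member of its nest's web iff its count is positive *and* at
least the level-0.1 empirical quantile (linear interpolation, zeros and all
nests included) of that group's counts. "Falls below" is read strictly:
count = threshold is retained. Relative abundances are renormalised over
members after exclusion. Basal resources are not dynamical nodes — only
sampled groups have abundances for D — and act through the links they
mediate and through competition: every member pair whose diets intersect
within {ant brood, nest food} is an exploitative-competition pair. The
quantile level and an occupied-nests-only variant are configurable.

## Stability analysis

Per replicate, every trophic link contributes two draws (consumer on
resource ~ N(−0.1, 0.05); resource on consumer ~ N(+0.1, 0.05)) and every
competition pair two draws (N(−0.1, 0.05) each direction); a directed cell
receiving both a trophic and a competitive effect gets the *sum of two
independent draws*, not one draw from a shifted mean. Diagonal −1. The
community matrix is M = DA\* (row i scaled by dᵢ) and stability is
ℜ(λ₁) = max over eigenvalues of the real part — the standard local
asymptotic stability criterion; the mean over 50 replicates summarises the
nest and log |mean| is the regression response. Unstable replicates are
retained in the mean; a nonnegative *mean* flags the nest instead of a log
of a negative number.

Rewiring shuffles all off-diagonal elements of the sampled signed matrix —
zeros included, diagonal untouched — so the value multiset is conserved
exactly. An alternative reading (shuffle the binary structure, then
resample strengths) was considered and not made default: shuffling the
realised matrix is the literal operation on the object whose eigenvalues
are computed.

Randomness uses one root seed: per nest × scenario × μ a SeedSequence is
derived (CRC-32 of the identifiers), and each replicate gets its own
spawned substream, so any subset of the computation is reproducible in
isolation.

Useful closed forms used as test oracles: with even abundances the
eigenvalues of DA\* are exactly those of A\*/n; a link-free web has
ℜ(λ₁) = −min dᵢ in every replicate; the 2-member consumer-resource system
has eigenvalues (−1 ± √(ab))/2, giving ℜ(λ₁) = −0.5 except on the ≈ 4.6% of
draws where the off-diagonal product turns positive.

## Scenario GLMs

Per scenario, `response ~ age + size + age:size` is fitted by Gaussian OLS
on nests with ≥ 6 members (in the study system smaller communities occur
essentially only among new nests, which would confound the age contrast).
Age is coded new = 0, old = 1; size enters uncentered.

Term tests are **marginal (type-II, car::Anova-style) by default**, with
sequential type-I available via `anova_type=1`. This was a genuinely open
design point; the marginal choice follows from the system itself: community
size is strongly age-correlated (old nests host more groups), and under
even abundances the response is a nearly deterministic function of size, so
a sequential age-first test would attribute the size-mediated difference to
age and could never register the even-abundance null that is the analysis's
control condition. Residual diagnostics (Shapiro, Breusch–Pagan) are
reported but never gate execution.

The scenario report evaluates, at α = 0.05 by default: age effect present
in both observed-abundance scenarios, absent in both even-abundance
scenarios, and a significantly negative size slope everywhere — the
signature that evenness, not wiring, carries the succession-stability link.

## Problem sizes and determinism

The acceptance script and tests run the full design at its native scale —
51 nests, 50 replicate matrices per nest × scenario, 999 permutations —
which completes in seconds per dataset; the verdict-pattern rate is
estimated over 10 seeded end-to-end runs and the μ-scan over
μ ∈ {−0.05, −0.1, −0.2}. All stochastic steps accept explicit seeds; equal
seeds give byte-identical outputs.

## Known limitations

* The adjacency fixture is a reconstruction; absolute stability levels
  (not the scenario contrasts) depend on its density.
* Only the leading-eigenvalue notion of stability is computed — no press,
  structural, feasibility or temporal stability.
* The GLMs assume independent Gaussian errors; no spatial error structure
  or mixed effects.
* The four scenario tests share one dataset and are not corrected for
  multiplicity.
* Pielou J is undefined for single-group nests; such nests are flagged and
  excluded from the beta regression rather than imputed.
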