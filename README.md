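# nestwebs

Succession, evenness and local stability of ant-nest symbiont food webs.

Red wood ant (*Formica rufa*) nest mounds house a hidden community of
arthropod symbionts — myrmecophiles — that form a local food web in every
nest. As a nest ages, obligately ant-associated functional groups surge in
abundance while facultative soil dwellers stagnate or decline, so the
community's abundance distribution becomes markedly more *even*. `nestwebs`
is a pipeline for asking whether that successional evenness shift makes the
food web more dynamically stable, and for separating the contribution of the
abundance distribution from that of the web's wiring.

The package is used from Python: the importable API is the interface, and
`examples/` holds one short narrative script per capability.

## The model

Counts of 16 functional groups (9 obligate, 7 facultative) are observed in
*N* nests of two age classes. Per nest:

1. **Local web.** The general 18-node trophic adjacency (16 groups + two
   aggregate basal resources, ant brood and nest food) is induced on the
   groups present in the nest, excluding any group whose count falls below
   the 0.1 empirical quantile of that group's counts over all nests. Member
   pairs whose diets share a basal resource compete exploitatively.
2. **Community matrix.** A signed interaction matrix A\* is sampled:
   aᵢⱼ ~ N(μ, σ) with μ = −0.1 for the effect of a consumer on its resource
   and for competition, μ = +0.1 for the effect of a resource on its
   consumer (coinciding trophic and competitive effects are summed), σ =
   0.05, diagonal −1. With D the diagonal of relative abundances, the
   community matrix is M = DA\* and local asymptotic stability is read from
   ℜ(λ₁), the largest real part among M's eigenvalues. Each nest is
   summarised by the mean ℜ(λ₁) over 50 draws and the response
   log |mean ℜ(λ₁)|.
3. **Four scenarios.** Observed vs perfectly even abundances (dᵢ = 1/n)
   crossed with observed vs randomized topology (all off-diagonal elements
   of A\* shuffled). Per scenario, a Gaussian GLM
   `response ~ age * community_size` (communities of ≥ 6 groups) tests
   whether nest age predicts stability.

Supporting statistics: Pielou evenness J = H/ln S per nest, Bray–Curtis
distances with PERMANOVA (sequential multi-term partitioning, 999
permutations) and PERMDISP, beta regression of J on nest predictors, and
rank-abundance summaries. A seeded synthetic-data generator
(lognormal-Poisson counts with age, environment, nest-quality and optional
spatial terms) emulates the study system so the whole pipeline is testable
without field data.

## Worked example

```python
import nestwebs as nw
from nestwebs.inference import fit_all_scenarios, scenario_report
from nestwebs.stability import run_scenarios

ds = nw.generate_dataset(nw.preset_studylike(seed=1))
webs = nw.build_all_webs(ds)
ages = {n.nest_id: n.age_class for n in ds.nests}
res = run_scenarios(webs, n_reps=50, seed=1)
res["age_class"] = res["nest_id"].map(ages)
report = scenario_report(fit_all_scenarios(res, min_size=6))
```

Running `python examples/04_stability_scenarios.py` (which is exactly this)
prints:

```
scenario                 age F   age p  size F size slope
even/observed             0.10   0.753 3208.33     -0.096
even/randomized           0.02   0.886 2222.02     -0.108
observed/observed         8.98   0.004   32.04     -0.214
observed/randomized       9.35   0.004   31.60     -0.214
verdicts: {'age_effect_obs_abundance': True, 'age_effect_even_abundance': False,
           'size_effect_negative_everywhere': True, 'pattern_matches': True}
```

Reading it: with the observed abundance distributions, old nests are
significantly more stable than new ones (age F ≈ 9, p ≈ 0.004), and
randomizing the wiring changes nothing — but evening out the abundances
erases the age difference entirely (p ≈ 0.75/0.89). Stability declines with
community size everywhere (negative size slope). Succession stabilises these
webs through evenness, not topology. The compositional side
(`examples/02_community_structure.py`) prints the matching community
statistics, e.g. PERMANOVA age R² = 0.110, F = 5.97, p = 0.001 and mean
Pielou J of 0.749 (old) vs 0.551 (new) for the same dataset.

## Layout

```
src/nestwebs/
  catalog.py    domain types: functional groups, adjacency, nests, dataset
  io.py         bundle readers/writers + the packaged trophic fixture
  simulate.py   synthetic nest-community generator
  metrics.py    evenness, Bray-Curtis, PERMANOVA, PERMDISP, beta regression
  foodweb.py    rarity thresholds and per-nest web induction
  stability.py  interaction sampling, M = DA*, eigenvalues, scenarios
  inference.py  per-scenario GLMs and the comparison report
```

The packaged trophic adjacency is a synthetic reconstruction from the
functional groups' documented feeding ecologies (see
`docs/methods.md`); users with field data can load their own edge list via
`nestwebs.io.read_adjacency`.
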