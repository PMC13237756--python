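"""Fit the seven-model suite and tabulate the moderation evidence.

Models 1-2 give the group and sleep main effects; Model 3 the primary
sleep x group interaction; Models 4-7 let eye condition or one scalp
axis (ML, AP, IS) moderate that interaction. For each model the highest-
order sleep-involved coefficient is printed with its posterior
probability and verbal evidence stratum, plus the stratified sleep
slopes for the axis models.
"""

from restalpha.bayes import ModelSpec, build_design, gibbs_sample, marginal_slopes, summarize
from restalpha.geometry import build_default_layout
from restalpha.pipeline import MODEL_MODERATORS
from restalpha.simulate import GenerativeParams, generate_alpha_table, generate_cohort

HEADLINE = {
    1: "Group",
    2: "Sleep",
    3: "Sleep:Group",
    4: "Sleep:Group:Eyes",
    5: "Sleep:Group:ML",
    6: "Sleep:Group:AP",
    7: "Sleep:Group:IS",
}

params = GenerativeParams(seed=3, extra_terms={"Sleep:Group:AP": -0.02})
layout = build_default_layout()
cohort = generate_cohort(15, 17, params)
table = generate_alpha_table(cohort, layout, params)

for mid in range(1, 8):
    spec = ModelSpec.for_model(mid)
    design = build_design(table, spec)
    draws = gibbs_sample(design, spec, chains=2, iterations=800, warmup=400, seed=mid)
    row = summarize(draws).row(HEADLINE[mid])
    print(
        f"Model {mid}: {HEADLINE[mid]:<18} median {row['median']:+.3f} "
        f"[{row['cri_lower']:+.3f}, {row['cri_upper']:+.3f}] "
        f"PP {row['pp']:.1f}% ({row['stratum']})"
    )
    if mid in (5, 6, 7):
        slopes = marginal_slopes(draws, design, MODEL_MODERATORS[mid])
        for _, s in slopes.iterrows():
            print(
                f"   {s['group']:<14} {s['moderator']:<14} "
                f"slope {s['slope_median']:+.3f} PP {s['pp']:.1f}%"
            )
print(
    "\nThe generative truth couples sleep to alpha power mainly in the "
    "abstinent group and adds a small sleep x group x AP term; Model 6 "
    "recovers that three-way moderation. With only 32 participants the "
    "two-way interaction estimate is noisy, so its PP varies across "
    "simulated cohorts — exactly the uncertainty the PP quantifies."
)
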