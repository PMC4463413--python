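"""Run the full screening funnel on the 83-compound synthetic library.

Generates the descriptor-annotated library with planted stage failures
(10 rule-of-five, 20 Arg168-distance, 30 twin-bond, 15 single-loop-contact),
runs the staged funnel under both receptor models, and prints the per-stage
survivor counts.
"""

from pose_triage import ScreenConfig, run_funnel
from pose_triage.synthetic_data import FUNNEL83_PLAN, make_active_site, make_library

site, criteria = make_active_site(seed=7)
records, poses, manifest = make_library(
    plan=FUNNEL83_PLAN, seed=7, site=site, criteria=criteria
)

for model_id in (1, 2):
    cfg = ScreenConfig(receptor=site, chain_id="A", criteria=criteria, model_id=model_id)
    report = run_funnel(records, poses, cfg)
    print(f"\nModel {model_id} (>= {cfg.min_loop_interactions} loop interaction(s)):")
    for stage, count in report.survivor_counts.items():
        print(f"  {stage:14s} {count}")
    print(f"  selected ids: {', '.join(report.selected_ids[:5])}"
          + (" ..." if len(report.selected_ids) > 5 else ""))

print(
    "\nSurvivor counts shrink monotonically through the funnel. The 15 poses "
    "with exactly one loop interaction pass Model 1 but are rejected by the "
    "stricter Model 2 criterion, hence the smaller Model 2 selection."
)
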