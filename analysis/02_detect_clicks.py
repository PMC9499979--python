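#!/usr/bin/env python
"""Detect beaked-whale clicks in the demonstration scene.

Runs the Teager–Kaiser detector, extracts per-click features, applies the
deletion criteria under both connectives, classifies 75-s segments and
writes candidates/segments/presence tables to results/.
"""

import os

from pamscape import assemble_scene
from pamscape import clickdet
from pamscape.clickdet import ClassifierConfig
from pamscape.scene import example_scene_spec

os.makedirs("results", exist_ok=True)

rec, truth = assemble_scene(example_scene_spec(seed=0))
candidates = clickdet.detect_candidates(rec)
n_true = (truth["signal_class"].isin(["cuvier_fm", "delphinid"])).sum()
print(f"{len(candidates)} candidates detected ({n_true} scheduled transients; "
      "UA pulse onsets also trigger the energy detector)")

for logic in ("conjunctive", "disjunctive"):
    cfg = ClassifierConfig(deletion_logic=logic)
    flagged = clickdet.apply_deletion_criteria(candidates, cfg)
    print(f"  {logic}: {int(flagged['retained'].sum())} retained after deletion criteria")

cfg = ClassifierConfig(deletion_logic="disjunctive")
flagged = clickdet.apply_deletion_criteria(candidates, cfg)
decisions = clickdet.segment_decisions(candidates, rec.duration, cfg)
presence = clickdet.log_bw_presence(decisions, rec.start_utc)

# the full candidate table is dominated by UA pulse-onset triggers; keep
# the archived table to the retained (whale-like) candidates
flagged[flagged["retained"]].to_csv("results/click_candidates.csv", index=False)
decisions.to_csv("results/click_segments.csv", index=False)
presence["encounters"].to_csv("results/bw_encounters.csv", index=False)
presence["hourly"].to_csv("results/bw_hourly.csv", index=False)

print(decisions[["start_s", "end_s", "n_detected", "n_retained", "label"]].to_string(index=False))
print(f"Beaked-whale presence: {len(presence['encounters'])} encounter(s), "
      f"{presence['hourly']['bw_minutes'].sum()} minute-bins")
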