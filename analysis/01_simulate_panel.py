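#!/usr/bin/env python
"""Generate the default synthetic screening panel used by the later steps.

Builds a 12-system x 12-biomarker, 4-dose panel with 100-replicate vehicle
control histories (noise sd 0.025 log10 units) and injects twelve
dose-response effects of amplitude 0.3 cycling through monotone-down,
monotone-up and U-shaped profiles.  Writes profile.tsv, controls.tsv and
truth.json under results/synthetic/.
"""

import dataclasses
import json
from pathlib import Path

from phenoprofiler import generate_controls, generate_profile, write_controls_table, write_profile_table
from phenoprofiler.synthetic import EffectSpec, PanelSpec

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 17


def build_effects(spec: PanelSpec) -> list[EffectSpec]:
    shapes = ["monotone_down", "monotone_up", "u_shape"]
    effects = []
    for i, system in enumerate(spec.systems):
        shape = shapes[i % len(shapes)]
        onset = len(spec.doses) // 2 if shape == "u_shape" else 1
        effects.append(EffectSpec(system, "BM01", shape, 0.3, onset, direction="down"))
    return effects


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = PanelSpec(seed=SEED)
    effects = build_effects(spec)
    profile, truth = generate_profile(spec, effects)
    controls = generate_controls(spec)
    write_profile_table(profile, OUT / "profile.tsv")
    write_controls_table(controls, OUT / "controls.tsv")
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "spec": dataclasses.asdict(spec),
                "effects": [dataclasses.asdict(e) for e in truth.effects],
                "expected_annotations": sorted(truth.expected_annotations),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    print(f"panel: {len(profile.readouts())} readouts x {len(spec.doses)} doses (seed {SEED})")
    print(f"injected effects: {len(effects)}; expected annotations: "
          f"{len(truth.expected_annotations)}")
    print(f"wrote {OUT}/profile.tsv, controls.tsv, truth.json")


if __name__ == "__main__":
    main()
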