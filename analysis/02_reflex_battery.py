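"""Run the ten-condition aberrant-reflex battery and score it.

For each parameter preset (wrist, shoulder) simulates the reference plus the
nine scenario x pathway conditions, scores the five dystonia characteristics
against the reference, and writes the score table and settled-window
summary measures under results/battery/.  Full trajectories are not stored;
rerun `dystonia-reflex battery` for those.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from dystonia_reflex import run_battery, score_battery
from dystonia_reflex.scoring import (condition_measures,
                                     max_zero_crossings_in_window)

OUT = Path(__file__).resolve().parents[1] / "results" / "battery"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for preset in ("wrist", "shoulder"):
        battery = run_battery(preset)
        scores = score_battery(battery)
        scores.to_csv(OUT / f"{preset}_scores.csv", index=False)
        rows = []
        for label, res in battery.items():
            m = dataclasses.asdict(condition_measures(res))
            rest_torque = m.pop("rest_torque")
            rows.append({"condition": label, **m,
                         **{f"rest_torque_{k}": v
                            for k, v in rest_torque.items()},
                         "max_zero_crossings_2s":
                             max_zero_crossings_in_window(res),
                         "unstable": res.unstable})
        pd.DataFrame(rows).to_csv(OUT / f"{preset}_measures.csv", index=False)
        top = scores.set_index("condition").loc["imbalanced_sensitivity:force",
                                                "total"]
        print(f"{preset}: imbalanced force sensitivity scores {top}/5; "
              "score table:")
        print(scores[["condition", "total"]].to_string(index=False))
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
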