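"""Build the posture combination tables and their marginal counts.

Runs the clinical analytics on the deterministic fixture cohorts (one limb
record per published table entry) and writes the combination tables,
marginals and containment check under results/clinical/.
"""

from pathlib import Path

import pandas as pd

from dystonia_reflex import (combination_table, marginal_counts,
                             proximal_distal_containment)
from dystonia_reflex.synth import fixture_table3_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "clinical"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    marg_rows = []
    for limb in ("arm", "leg"):
        cohort = fixture_table3_cohort(limb)
        table = combination_table(cohort, limb)
        table.to_frame().to_csv(OUT / f"{limb}_combinations.csv", index=False)
        marg = marginal_counts(table)
        violators = proximal_distal_containment(cohort, limb)
        marg_rows.append({"limb": limb, **marg,
                          "containment_violations": len(violators)})
        print(f"{limb}: {marg['total']} limbs with a common pattern; "
              f"marginals {marg}; containment violations: {len(violators)}")
    pd.DataFrame(marg_rows).to_csv(OUT / "marginals.csv", index=False)
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
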