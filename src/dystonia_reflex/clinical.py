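"""Clinical posture-pattern analytics for per-limb dystonia records.

A cohort is a list of per-limb records (one row per limb, four joints per
limb).  The analyses mirror the descriptive study: combination tables of the
four common-pattern indicators per limb type, their marginal counts, the
distal-to-proximal containment property (proximal involvement never occurs
without distal involvement), an exact test of left/right symmetry, and the
per-patient severity distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "SIDES", "LIMBS", "ARM_JOINTS", "LEG_JOINTS", "JOINT_CATEGORIES",
    "SEVERITY_GRADES", "ARM_INDICATORS", "LEG_INDICATORS",
    "ANKLE_INDICATOR_CATEGORIES", "COHORT_COLUMNS",
    "PostureRecord", "CombinationTable", "CohortLoadError",
    "indicator_tuple", "load_cohort", "save_cohort", "cohort_frame",
    "combination_table", "marginal_counts", "proximal_distal_containment",
    "lr_symmetry_test", "severity_summary",
]

SIDES = ("left", "right")
LIMBS = ("arm", "leg")
ARM_JOINTS = ("fingers", "wrist", "elbow", "shoulder")
LEG_JOINTS = ("toes", "ankle", "knee", "hip")

JOINT_CATEGORIES: dict[str, frozenset] = {
    "fingers": frozenset({"flexion", "extension", "none"}),
    "wrist": frozenset({"flexion", "extension", "none"}),
    "elbow": frozenset({"flexion", "pronation", "none"}),
    "shoulder": frozenset({"adduction", "none"}),
    "toes": frozenset({"plantar_flexion", "dorsiflexion", "none"}),
    "ankle": frozenset({"plantar_flexion", "inversion",
                        "plantar_flexion_inversion", "dorsiflexion",
                        "eversion", "dorsiflexion_inversion",
                        "plantar_flexion_eversion", "none"}),
    "knee": frozenset({"flexion", "extension", "none"}),
    "hip": frozenset({"internal_rotation", "none"}),
}

SEVERITY_GRADES = ("slight", "mild", "moderate", "severe")

# the four "common pattern" indicators per limb type
ARM_INDICATORS = ("finger_flexion", "wrist_flexion", "elbow_flexion",
                  "shoulder_adduction")
LEG_INDICATORS = ("toe_plantar_flexion", "ankle_plantar_flexion_or_inversion",
                  "knee_flexion", "hip_internal_rotation")
ANKLE_INDICATOR_CATEGORIES = frozenset(
    {"plantar_flexion", "inversion", "plantar_flexion_inversion"})

COHORT_COLUMNS = ("patient_id", "side", "limb", "fingers", "wrist", "elbow",
                  "shoulder", "toes", "ankle", "knee", "hip", "severity")


class CohortLoadError(ValueError):
    """Raised when a cohort file violates the schema; carries row messages."""


def _joints_for(limb: str) -> tuple[str, ...]:
    return ARM_JOINTS if limb == "arm" else LEG_JOINTS


@dataclass(frozen=True)
class PostureRecord:
    """One limb of one patient: a posture category per joint plus severity.

    A limb with all joints ``"none"`` is non-dystonic and must carry severity
    ``"none"``; a dystonic limb must carry a severity grade.
    """

    patient_id: str
    side: str
    limb: str
    postures: dict = field(hash=False)
    severity: str = "none"

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.limb not in LIMBS:
            raise ValueError(f"unknown limb {self.limb!r}")
        joints = _joints_for(self.limb)
        if set(self.postures) != set(joints):
            raise ValueError(
                f"{self.limb} record must give postures for joints {joints}")
        for joint, cat in self.postures.items():
            if cat not in JOINT_CATEGORIES[joint]:
                raise ValueError(
                    f"unknown category {cat!r} for joint {joint!r}")
        if self.severity not in SEVERITY_GRADES + ("none",):
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.is_dystonic != (self.severity != "none"):
            raise ValueError(
                "severity must be 'none' iff all joints are 'none'")

    @property
    def is_dystonic(self) -> bool:
        return any(cat != "none" for cat in self.postures.values())


def indicator_tuple(record: PostureRecord) -> tuple[bool, bool, bool, bool]:
    """The limb's four common-pattern indicators.

    Arms: finger/wrist/elbow flexion and shoulder adduction.  Legs: toe
    plantar flexion, ankle plantar-flexion-or-inversion (the merged ankle
    indicator), knee flexion and hip internal rotation.
    """
    p = record.postures
    if record.limb == "arm":
        return (p["fingers"] == "flexion", p["wrist"] == "flexion",
                p["elbow"] == "flexion", p["shoulder"] == "adduction")
    return (p["toes"] == "plantar_flexion",
            p["ankle"] in ANKLE_INDICATOR_CATEGORIES,
            p["knee"] == "flexion", p["hip"] == "internal_rotation")


@dataclass(frozen=True)
class CombinationTable:
    """Pattern x count summary of the dystonic limbs of one type.

    ``rows`` map each observed indicator tuple to its limb count, most common
    first.  Limbs whose four indicators are all false are excluded from the
    rows but counted as ``other_pattern_count``; non-dystonic limbs are
    counted separately, so the three counts conserve the cohort.
    """

    limb: str
    indicators: tuple
    rows: tuple                   # ((bool, bool, bool, bool), count), ...
    column_totals: tuple
    grand_total: int
    other_pattern_count: int
    non_dystonic_count: int

    def to_frame(self) -> pd.DataFrame:
        data = [{"count": count,
                 **{name: ("X" if flag else "")
                    for name, flag in zip(self.indicators, tup)}}
                for tup, count in self.rows]
        df = pd.DataFrame(data, columns=["count", *self.indicators])
        totals = {"count": self.grand_total,
                  **dict(zip(self.indicators, self.column_totals))}
        return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def combination_table(cohort: list[PostureRecord], limb: str) -> CombinationTable:
    """Build the combination table of common-pattern indicators for one limb type."""
    if limb not in LIMBS:
        raise ValueError(f"unknown limb {limb!r}")
    indicators = ARM_INDICATORS if limb == "arm" else LEG_INDICATORS
    counts: dict[tuple, int] = {}
    other = 0
    non_dystonic = 0
    for rec in cohort:
        if rec.limb != limb:
            continue
        if not rec.is_dystonic:
            non_dystonic += 1
            continue
        tup = indicator_tuple(rec)
        if not any(tup):
            other += 1
            continue
        counts[tup] = counts.get(tup, 0) + 1
    rows = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    col_totals = tuple(sum(c for tup, c in rows if tup[j]) for j in range(4))
    return CombinationTable(
        limb=limb, indicators=indicators, rows=rows,
        column_totals=col_totals, grand_total=sum(counts.values()),
        other_pattern_count=other, non_dystonic_count=non_dystonic)


def marginal_counts(table: CombinationTable) -> dict[str, int]:
    """Per-indicator totals plus the number of limbs with >= 1 indicator."""
    out = dict(zip(table.indicators, table.column_totals))
    out["total"] = table.grand_total
    return out


def proximal_distal_containment(cohort: list[PostureRecord],
                                limb: str) -> list[PostureRecord]:
    """Records violating "proximal involvement implies distal involvement".

    For arms every shoulder-involved limb must have affected fingers; for
    legs every hip-involved limb must have an affected ankle.  An empty list
    means the containment property holds.
    """
    proximal, distal = (("shoulder", "fingers") if limb == "arm"
                        else ("hip", "ankle"))
    return [rec for rec in cohort
            if rec.limb == limb
            and rec.postures[proximal] != "none"
            and rec.postures[distal] == "none"]


def lr_symmetry_test(cohort: list[PostureRecord], limb: str) -> float:
    """Two-sided Fisher exact p for side x dystonia-present, one limb type.

    Summing hypergeometric probabilities of all tables at least as extreme
    (probability <= the observed table's) at fixed margins.  A degenerate
    table (any zero margin) carries no information and returns p = 1.
    """
    table = [[0, 0], [0, 0]]
    for rec in cohort:
        if rec.limb != limb:
            continue
        i = SIDES.index(rec.side)
        j = 0 if rec.is_dystonic else 1
        table[i][j] += 1
    rows = [sum(r) for r in table]
    cols = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in rows or 0 in cols:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def severity_summary(cohort: list[PostureRecord]) -> pd.DataFrame:
    """Distribution of each patient's most-affected-limb severity.

    Severity of a patient is the maximum grade over their dystonic limbs
    (slight < mild < moderate < severe); patients with no dystonic limb are
    excluded.  Returns counts and percentages per grade.
    """
    order = {g: i for i, g in enumerate(SEVERITY_GRADES)}
    per_patient: dict[str, int] = {}
    for rec in cohort:
        if rec.severity == "none":
            continue
        rank = order[rec.severity]
        pid = rec.patient_id
        per_patient[pid] = max(per_patient.get(pid, -1), rank)
    counts = {g: 0 for g in SEVERITY_GRADES}
    for rank in per_patient.values():
        counts[SEVERITY_GRADES[rank]] += 1
    n = max(sum(counts.values()), 1)
    return pd.DataFrame(
        {"severity": SEVERITY_GRADES,
         "count": [counts[g] for g in SEVERITY_GRADES],
         "pct": [100.0 * counts[g] / n for g in SEVERITY_GRADES]})


def cohort_frame(cohort: list[PostureRecord]) -> pd.DataFrame:
    """Cohort as a delimited-ready table (one row per limb)."""
    rows = []
    for rec in cohort:
        row = dict.fromkeys(COHORT_COLUMNS, "")
        row.update(patient_id=rec.patient_id, side=rec.side, limb=rec.limb,
                   severity=rec.severity, **rec.postures)
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def save_cohort(cohort: list[PostureRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort_frame(cohort).to_csv(path, index=False)


def load_cohort(path: str | Path) -> list[PostureRecord]:
    """Read and validate a cohort file; row-numbered messages on failure."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortLoadError(f"missing columns: {missing}")
    records: list[PostureRecord] = []
    errors: list[str] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = 1
        row = row._asdict()
        try:
            limb = row["limb"]
            joints = _joints_for(limb) if limb in LIMBS else ()
            for joint in ARM_JOINTS + LEG_JOINTS:
                if joint not in joints and row[joint] not in ("", "none"):
                    raise ValueError(
                        f"joint {joint!r} not applicable to limb {limb!r}")
            rec = PostureRecord(
                patient_id=row["patient_id"], side=row["side"], limb=limb,
                postures={j: (row[j] or "none") for j in joints},
                severity=row["severity"] or "none")
            key = (rec.patient_id, rec.side, rec.limb)
            if key in seen:
                raise ValueError(f"duplicate record for {key}")
            seen.add(key)
            records.append(rec)
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise CohortLoadError("; ".join(errors))
    return records
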