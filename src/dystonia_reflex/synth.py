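"""Synthetic cohort generation with the statistical structure of the study.

The raw per-patient data behind the descriptive study are unpublished, so the
generator emulates a cohort at the study's published summary statistics: each
patient contributes two arms and two legs; each limb is independently
affected with a side-independent probability calibrated to the reported
bilateral-involvement fractions; affected limbs draw a posture combination
pattern at the published combination-table frequencies (plus the rare
postures at their reported rates); per-patient maximal severity follows the
published four-grade distribution.

Limbs are treated as independent given the patient - the study publishes no
joint distribution across a patient's limbs - and no disease-progression
structure is modelled.  Deterministic fixture cohorts realising the published
combination tables exactly are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clinical import (ARM_JOINTS, LEG_JOINTS, SEVERITY_GRADES, PostureRecord,
                       indicator_tuple)

__all__ = [
    "ARM_PATTERNS", "LEG_PATTERNS", "ANKLE_SUBTYPES",
    "CohortSpec", "default_cohort_spec", "generate_cohort",
    "fixture_table3_cohort", "classify_pattern",
    "empirical_pattern_frequencies",
]

# Arm posture combination patterns: id -> (count weight, postures).
# The ten common patterns carry the published combination-table counts
# (118 limbs); the rare-only patterns split the remaining 5 of the 123
# affected arms across the reported rare categories.
ARM_PATTERNS: dict[str, tuple[int, dict]] = {
    "F":    (60, {"fingers": "flexion"}),
    "FWE":  (20, {"fingers": "flexion", "wrist": "flexion", "elbow": "flexion"}),
    "FW":   (15, {"fingers": "flexion", "wrist": "flexion"}),
    "FE":   (9,  {"fingers": "flexion", "elbow": "flexion"}),
    "FES":  (4,  {"fingers": "flexion", "elbow": "flexion",
                  "shoulder": "adduction"}),
    "FWES": (4,  {"fingers": "flexion", "wrist": "flexion", "elbow": "flexion",
                  "shoulder": "adduction"}),
    "FS":   (3,  {"fingers": "flexion", "shoulder": "adduction"}),
    "FWS":  (1,  {"fingers": "flexion", "wrist": "flexion",
                  "shoulder": "adduction"}),
    "W":    (1,  {"wrist": "flexion"}),
    "E":    (1,  {"elbow": "flexion"}),
    "rare_finger_extension": (3, {"fingers": "extension"}),
    "rare_wrist_extension":  (1, {"wrist": "extension"}),
    "rare_elbow_pronation":  (1, {"elbow": "pronation"}),
}

# Leg patterns; "ANKLE" is a placeholder for the merged plantar-flexion-or-
# inversion indicator, realised as a concrete subtype at draw time.
LEG_PATTERNS: dict[str, tuple[int, dict]] = {
    "A":    (42, {"ankle": "ANKLE"}),
    "TA":   (24, {"toes": "plantar_flexion", "ankle": "ANKLE"}),
    "TAK":  (17, {"toes": "plantar_flexion", "ankle": "ANKLE",
                  "knee": "flexion"}),
    "T":    (6,  {"toes": "plantar_flexion"}),
    "AK":   (6,  {"ankle": "ANKLE", "knee": "flexion"}),
    "AH":   (6,  {"ankle": "ANKLE", "hip": "internal_rotation"}),
    "K":    (4,  {"knee": "flexion"}),
    "TAH":  (3,  {"toes": "plantar_flexion", "ankle": "ANKLE",
                  "hip": "internal_rotation"}),
    "TK":   (3,  {"toes": "plantar_flexion", "knee": "flexion"}),
    "TAKH": (2,  {"toes": "plantar_flexion", "ankle": "ANKLE",
                  "knee": "flexion", "hip": "internal_rotation"}),
    "rare_knee_extension": (1, {"knee": "extension"}),
}

# Published split of the merged ankle indicator: plantar flexion + inversion,
# plantar flexion only, inversion only (73 : 11 : 16 legs).
ANKLE_SUBTYPES: dict[str, int] = {
    "plantar_flexion_inversion": 73,
    "plantar_flexion": 11,
    "inversion": 16,
}

# Per-patient maximal severity distribution (fractions of 85 patients).
_SEVERITY_PROBS = {"slight": 0.118, "mild": 0.412,
                   "moderate": 0.247, "severe": 0.223}


def _both_sides_rate(frac_both: float) -> float:
    """P(one side affected) given P(both | >= one) under side independence."""
    return 2.0 * frac_both / (1.0 + frac_both)


def _normalised(weights: dict[str, float]) -> dict[str, float]:
    total = float(sum(weights.values()))
    return {k: v / total for k, v in weights.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification for a synthetic cohort.

    Pattern distributions are conditional on the limb being affected and sum
    to 1; ``p_arm_affected`` / ``p_leg_affected`` give the probability that a
    given side's limb is affected, independently of the other side.
    ``severity`` is the distribution of a patient's maximal grade.
    """

    n_patients: int
    arm_patterns: dict = field(hash=False)
    leg_patterns: dict = field(hash=False)
    ankle_subtypes: dict = field(hash=False)
    severity: dict = field(hash=False)
    p_arm_affected: float = 0.5
    p_leg_affected: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name in ("arm_patterns", "leg_patterns", "ankle_subtypes",
                     "severity"):
            dist = getattr(self, name)
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} probabilities must be >= 0")
        for name in ("p_arm_affected", "p_leg_affected"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def default_cohort_spec(n_patients: int = 200, seed: int = 0) -> CohortSpec:
    """Spec at the study's published frequencies.

    Pattern probabilities are proportional to the combination-table counts
    plus the rare-posture counts; laterality is calibrated so that, of
    patients with any affected arm, 46/77 have both affected (37/77 for
    legs); severity follows the published per-patient grade distribution.
    """
    return CohortSpec(
        n_patients=n_patients,
        arm_patterns=_normalised({k: w for k, (w, _) in ARM_PATTERNS.items()}),
        leg_patterns=_normalised({k: w for k, (w, _) in LEG_PATTERNS.items()}),
        ankle_subtypes=_normalised(dict(ANKLE_SUBTYPES)),
        severity=dict(_SEVERITY_PROBS),
        p_arm_affected=_both_sides_rate(46.0 / 77.0),
        p_leg_affected=_both_sides_rate(37.0 / 77.0),
        seed=seed,
    )


def _realise(limb: str, pattern_id: str, ankle_subtype: str) -> dict:
    joints = ARM_JOINTS if limb == "arm" else LEG_JOINTS
    patterns = ARM_PATTERNS if limb == "arm" else LEG_PATTERNS
    postures = dict.fromkeys(joints, "none")
    for joint, cat in patterns[pattern_id][1].items():
        postures[joint] = ankle_subtype if cat == "ANKLE" else cat
    return postures


def generate_cohort(spec: CohortSpec) -> list[PostureRecord]:
    """Draw a reproducible synthetic cohort (2 arms + 2 legs per patient).

    Each affected limb draws an independent combination pattern; one randomly
    chosen affected limb carries the patient's maximal severity grade and the
    others draw uniformly from the grades at or below it.
    """
    rng = np.random.default_rng(spec.seed)
    arm_ids = list(spec.arm_patterns)
    arm_p = np.array([spec.arm_patterns[k] for k in arm_ids])
    leg_ids = list(spec.leg_patterns)
    leg_p = np.array([spec.leg_patterns[k] for k in leg_ids])
    ankle_ids = list(spec.ankle_subtypes)
    ankle_p = np.array([spec.ankle_subtypes[k] for k in ankle_ids])
    sev_ids = list(spec.severity)
    sev_p = np.array([spec.severity[k] for k in sev_ids])
    sev_rank = {g: i for i, g in enumerate(SEVERITY_GRADES)}

    cohort: list[PostureRecord] = []
    for i in range(spec.n_patients):
        pid = f"S{i:05d}"
        drawn: list[tuple[str, str, dict]] = []   # (side, limb, postures)
        for limb, p_aff in (("arm", spec.p_arm_affected),
                            ("leg", spec.p_leg_affected)):
            for side in ("left", "right"):
                if rng.random() >= p_aff:
                    drawn.append((side, limb, None))
                    continue
                ids, pvec = (arm_ids, arm_p) if limb == "arm" else (leg_ids, leg_p)
                pattern = ids[rng.choice(len(ids), p=pvec)]
                ankle = ankle_ids[rng.choice(len(ankle_ids), p=ankle_p)]
                drawn.append((side, limb, _realise(limb, pattern, ankle)))

        affected = [k for k, (_, _, post) in enumerate(drawn) if post]
        severities = [None] * len(drawn)
        if affected:
            top = sev_ids[rng.choice(len(sev_ids), p=sev_p)]
            carrier = affected[rng.integers(len(affected))]
            for k in affected:
                if k == carrier:
                    severities[k] = top
                else:
                    severities[k] = SEVERITY_GRADES[
                        rng.integers(sev_rank[top] + 1)]
        for (side, limb, postures), sev in zip(drawn, severities):
            joints = ARM_JOINTS if limb == "arm" else LEG_JOINTS
            cohort.append(PostureRecord(
                patient_id=pid, side=side, limb=limb,
                postures=postures or dict.fromkeys(joints, "none"),
                severity=sev or "none"))
    return cohort


def fixture_table3_cohort(limb: str) -> list[PostureRecord]:
    """Deterministic cohort realising the published combination table exactly.

    One limb record per table entry (118 arms or 113 legs across the ten
    common patterns); the merged ankle indicator is realised as plantar
    flexion with inversion, which the published table does not separate.
    """
    if limb not in ("arm", "leg"):
        raise ValueError(f"unknown limb {limb!r}")
    patterns = ARM_PATTERNS if limb == "arm" else LEG_PATTERNS
    cohort: list[PostureRecord] = []
    n = 0
    for pattern_id, (count, _) in patterns.items():
        if pattern_id.startswith("rare_"):
            continue
        for _ in range(count):
            cohort.append(PostureRecord(
                patient_id=f"T3{limb[0].upper()}{n:04d}",
                side=("left", "right")[n % 2], limb=limb,
                postures=_realise(limb, pattern_id,
                                  "plantar_flexion_inversion"),
                severity="mild"))
            n += 1
    return cohort


def classify_pattern(record: PostureRecord) -> str | None:
    """Map a record back to its pattern id (None if non-dystonic).

    Ankle subtypes within the merged indicator are collapsed, mirroring the
    published table.
    """
    if not record.is_dystonic:
        return None
    patterns = ARM_PATTERNS if record.limb == "arm" else LEG_PATTERNS

    def canon(postures: dict) -> tuple:
        out = []
        for joint, cat in sorted(postures.items()):
            if cat == "none":
                continue
            if joint == "ankle" and cat in ("plantar_flexion", "inversion",
                                            "plantar_flexion_inversion",
                                            "ANKLE"):
                cat = "ANKLE"
            out.append((joint, cat))
        return tuple(out)

    key = canon(record.postures)
    joints = ARM_JOINTS if record.limb == "arm" else LEG_JOINTS
    for pattern_id, (_, spec_postures) in patterns.items():
        full = dict.fromkeys(joints, "none") | spec_postures
        if canon(full) == key:
            return pattern_id
    return "unclassified"


def empirical_pattern_frequencies(cohort: list[PostureRecord],
                                  limb: str) -> dict[str, float]:
    """Observed pattern frequencies among the affected limbs of one type."""
    counts: dict[str, int] = {}
    total = 0
    for rec in cohort:
        if rec.limb != limb or not rec.is_dystonic:
            continue
        pid = classify_pattern(rec)
        counts[pid] = counts.get(pid, 0) + 1
        total += 1
    return {k: v / total for k, v in counts.items()} if total else {}
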