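"""Outcome prediction by nearest-risk-curve matching.

An incoming patient's risk curve (cluster death probability vs. stage) is
compared against every database patient's curve by the absolute difference
of the areas under them, up to a stage horizon.  The predicted outcome
class is the binarized GOS of the closest-curve patient(s).  Leave-one-out
evaluation rebuilds all stage partitions without the held-out patient, so
the incoming curve is produced exactly as it would be for a genuinely new
admission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .profiling import (
    DEFAULT_CLINICAL_VARS,
    DEFAULT_K,
    DEFAULT_RESTARTS,
    RiskCurve,
    assign_new_patient,
    build_partitions,
    patient_stage_row,
    risk_curve,
)

LOW, HIGH = "Low", "High"


def classify_gos(gos: int, rule: str = "low_high") -> str:
    """Binarize a GOS score into Low / High.

    ``low_high``: Low for GOS <= 3 (poor outcome), High for GOS >= 4.
    ``survival``: Low for GOS = 1 (death), High otherwise.
    """
    if rule == "low_high":
        return LOW if gos <= 3 else HIGH
    if rule == "survival":
        return LOW if gos == 1 else HIGH
    raise ValueError(f"unknown GOS rule {rule!r}")


@dataclass
class CurveMatch:
    incoming_id: str
    matched_ids: list[str]
    distance: float
    stage_horizon: int
    predicted_class: str


def curve_area(curve: RiskCurve, up_to_stage: int | None = None) -> float:
    """Trapezoidal area under the curve over stages up to ``up_to_stage``.

    The x-axis is the stage index (unit spacing between consecutive
    stages); a single-point curve has area 0.
    """
    if not curve.stages:
        raise ValueError("empty risk curve")
    if up_to_stage is not None and up_to_stage < curve.stages[0]:
        raise ValueError(
            f"horizon {up_to_stage} precedes first stage {curve.stages[0]}"
        )
    stages = np.asarray(curve.stages, dtype=float)
    probs = np.asarray(curve.probs, dtype=float)
    if up_to_stage is not None:
        keep = stages <= up_to_stage
        stages, probs = stages[keep], probs[keep]
    if stages.size < 2:
        return 0.0
    return float(np.trapezoid(probs, stages))


def curve_distance(a: RiskCurve, b: RiskCurve, up_to_stage: int | None = None) -> float:
    """|area(a) − area(b)| over the stages the two curves share.

    Restricting to common stages is what makes curves of unequal length
    (e.g. a patient who died early) comparable.
    """
    common = sorted(set(a.stages) & set(b.stages))
    if up_to_stage is not None:
        common = [s for s in common if s <= up_to_stage]
    if not common:
        raise ValueError("curves have no common stages within the horizon")
    sub_a = RiskCurve(a.patient_id, common,
                      [a.probs[a.stages.index(s)] for s in common])
    sub_b = RiskCurve(b.patient_id, common,
                      [b.probs[b.stages.index(s)] for s in common])
    return abs(curve_area(sub_a) - curve_area(sub_b))


def predict_incoming(
    incoming: RiskCurve,
    database: list[tuple[RiskCurve, int]],
    stage: int,
    gos_rule: str = "low_high",
) -> CurveMatch:
    """Nearest-curve prediction at a stage horizon.

    ``database`` holds (risk curve, GOS) pairs.  Exact distance ties vote
    by majority class; a residual tie predicts Low — the conservative
    (poor-outcome) call.  Database curves with no common stages are
    skipped.
    """
    if not database:
        raise ValueError("empty curve database")
    best: list[tuple[str, str]] = []  # (matched id, class)
    best_d = np.inf
    for curve, gos in database:
        if curve.patient_id == incoming.patient_id:
            continue
        try:
            d = curve_distance(incoming, curve, up_to_stage=stage)
        except ValueError:
            continue
        if d < best_d - 1e-12:
            best_d = d
            best = [(curve.patient_id, classify_gos(gos, gos_rule))]
        elif abs(d - best_d) <= 1e-12:
            best.append((curve.patient_id, classify_gos(gos, gos_rule)))
    if not best:
        raise ValueError("no database curve shares stages with the incoming curve")
    classes = [c for _, c in best]
    n_low, n_high = classes.count(LOW), classes.count(HIGH)
    predicted = HIGH if n_high > n_low else LOW
    return CurveMatch(
        incoming_id=incoming.patient_id,
        matched_ids=[pid for pid, _ in best],
        distance=float(best_d),
        stage_horizon=stage,
        predicted_class=predicted,
    )


@dataclass
class LOOResult:
    success_rate: float
    n_evaluated: int
    records: list[dict] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    baseline: float = 0.5  # chance level for a random Low/High assignment


def loo_success_rate(
    cohort: Cohort,
    degree: int = 2,
    k: int = DEFAULT_K,
    method: str = "kmeans",
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    clinical_vars=DEFAULT_CLINICAL_VARS,
    trend_terms: list[str] | None = None,
    gos_rule: str = "survival",
) -> LOOResult:
    """Leave-one-out curve-matching evaluation.

    For each patient with a known GOS and at least one reading round: all
    stage partitions are rebuilt without them (same seed, so differences
    come only from their removal); their risk curve is derived by
    nearest-centroid assignment stage by stage; the prediction at their
    final round is compared with their true class.
    """
    eligible = [p for p in cohort if p.gos is not None]
    if len(eligible) < 3:
        raise ValueError("need at least 3 patients with known GOS for LOO")
    records: list[dict] = []
    skipped: list[str] = []
    n_correct = 0
    for p in eligible:
        horizon = p.n_rounds
        if horizon == 0:
            skipped.append(p.id)
            continue
        rest = cohort.without(p.id)
        partitions, _ = build_partitions(
            rest, degree=degree, k=k, method=method, seed=seed,
            n_restarts=n_restarts, clinical_vars=clinical_vars,
            trend_terms=trend_terms, max_stage=horizon,
        )
        stages: list[int] = []
        probs: list[float] = []
        for part in partitions:
            row = patient_stage_row(
                p, part.stage, degree, clinical_vars, trend_terms,
                cohort.mediator_panel,
            )
            if row is None:
                continue
            _, prob = assign_new_patient(part, row)
            stages.append(part.stage)
            probs.append(prob)
        if not stages:
            skipped.append(p.id)
            continue
        incoming = RiskCurve(p.id, stages, probs)
        database = [
            (risk_curve(q.id, partitions), q.gos)
            for q in rest
            if q.gos is not None and any(q.id in part.assignment for part in partitions)
        ]
        match = predict_incoming(incoming, database, stage=horizon, gos_rule=gos_rule)
        true_class = classify_gos(p.gos, gos_rule)
        correct = match.predicted_class == true_class
        n_correct += int(correct)
        records.append(
            {
                "patient_id": p.id,
                "true_class": true_class,
                "predicted_class": match.predicted_class,
                "matched_ids": match.matched_ids,
                "distance": match.distance,
                "horizon_stage": match.stage_horizon,
                "correct": bool(correct),
            }
        )
    if not records:
        raise ValueError("no patient could be evaluated")
    return LOOResult(
        success_rate=n_correct / len(records),
        n_evaluated=len(records),
        records=records,
        skipped=skipped,
    )
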