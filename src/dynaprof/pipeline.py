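"""End-to-end orchestration: simulate/load → rounds → trends → outcome
model → stage partitions → risk curves → leave-one-out prediction.

All randomness funnels through one root seed; each stage derives a child
seed from it so any output file is re-derivable from the run log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cio
from . import matching, outcome, profiling, trends
from .simulate import SimulationConfig, simulate_cohort

_SEED_SPAN = 2**31 - 1


def child_seed(root: int, label: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the root seed."""
    h = np.uint64(root)
    for ch in label:
        h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**61 - 1))
    return int(h) % _SEED_SPAN


@dataclass
class RunConfig:
    clinical_csv: str | None = None
    mediators_csv: str | None = None
    simulate_n: int = 27
    effect_scale: float = 1.0
    degree: int = 2
    k: int = 3
    method: str = "kmeans"
    n_restarts: int = 25
    link: str = "logit"
    gos_rule: str = "survival"
    t_cut: float = 1.5
    train_fraction: float = 0.8
    round_scheme: str = "ordinal"
    bin_width: float = 24.0
    seed: int = 0
    out_dir: str = "dynaprof_run"

    def __post_init__(self) -> None:
        if not 0 <= self.degree <= trends.MAX_DEGREE:
            raise ValueError(f"degree must lie in [0, {trends.MAX_DEGREE}]")
        for path in (self.clinical_csv, self.mediators_csv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


def load_or_simulate(config: RunConfig) -> cio.Cohort:
    if config.clinical_csv and config.mediators_csv:
        cohort = cio.read_clinical(config.clinical_csv)
        cio.read_mediators(config.mediators_csv, cohort)
        cio.assign_rounds(cohort, scheme=config.round_scheme,
                          bin_width=config.bin_width)
        return cohort
    sim = SimulationConfig(
        n_patients=config.simulate_n,
        effect_scale=config.effect_scale,
        seed=child_seed(config.seed, "simulate"),
    )
    cohort, _ = simulate_cohort(sim)
    return cohort


def fit_outcome_model(
    cohort: cio.Cohort, config: RunConfig
) -> tuple[outcome.OutcomeModelFit | None, pd.DataFrame, dict]:
    """Screened-then-selected outcome model on the clinical + trend pool.

    Per-mediator trend blocks and the clinical block are screened
    marginally (the full 10 + 13(d+1) pool cannot be fit jointly at
    cohort scale), surviving terms are pooled, then backward elimination
    prunes to |t| >= t_cut.
    """
    tmat, excluded = trends.trend_matrix(cohort, config.degree)
    clin = pd.DataFrame(
        {
            pid: {
                "gcs": float(cohort.get(pid).clinical.gcs),
                **{
                    v: profiling._clinical_value(cohort.get(pid), v)
                    for v in profiling.DEFAULT_CLINICAL_VARS
                },
            }
            for pid in tmat.index
        }
    ).T
    features = pd.concat([clin, tmat], axis=1)
    outcomes = pd.Series(
        {pid: outcome.binarize_gos(cohort.get(pid).gos, config.gos_rule)
         for pid in features.index}
    )
    known = outcomes.notna()
    features, outcomes = features[known], outcomes[known].astype(int)
    info: dict = {"excluded": excluded, "n_model": int(len(features))}
    if len(features) < 6 or outcomes.nunique() < 2:
        info["status"] = "too few patients or single outcome class"
        return None, features, info

    train_ids, test_ids = outcome.split_cohort(
        list(features.index), outcomes.to_numpy(),
        train_fraction=config.train_fraction,
        seed=child_seed(config.seed, "split"),
    )
    blocks = [list(clin.columns)] + [
        [c for c in tmat.columns if c.startswith(f"{m}.")]
        for m in cohort.mediator_panel
    ]
    screened = outcome.screen_terms(
        features.loc[train_ids], outcomes[train_ids], blocks,
        link=config.link, t_cut=config.t_cut,
    )
    selected = outcome.select_terms(
        features.loc[train_ids, screened], outcomes[train_ids],
        link=config.link, t_cut=config.t_cut,
    ) if screened else []
    info.update(screened=screened, selected=selected,
                train_ids=train_ids, test_ids=test_ids)
    if not selected:
        info["status"] = "no terms survived selection"
        return None, features, info
    fit = outcome.fit(features.loc[train_ids, selected], outcomes[train_ids],
                      link=config.link)
    fit.train_ids, fit.test_ids = train_ids, test_ids
    test_probs = outcome.predict_prob(fit, features.loc[test_ids])
    info["test_eval"] = outcome.evaluate(test_probs, outcomes[test_ids])
    info["status"] = "ok"
    return fit, features, info


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Outputs: simulated CSVs (when simulating), a fit report (term / value /
    SE / t-value), fitted probabilities per patient, per-stage partitions
    with cluster weights, risk curves, the LOO prediction report, and a
    run log recording every seed and knob.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {**vars(config)}, "seeds": {}}

    cohort = load_or_simulate(config)
    log["n_patients"] = len(cohort)
    if not (config.clinical_csv and config.mediators_csv):
        log["seeds"]["simulate"] = child_seed(config.seed, "simulate")
        cio.write_clinical(cohort, out / "clinical.csv")
        cio.write_mediators(cohort, out / "mediators.csv")

    # Outcome model (fit-report + fitted-probability tables)
    fit, features, fit_info = fit_outcome_model(cohort, config)
    log["seeds"]["split"] = child_seed(config.seed, "split")
    log["outcome_model"] = {
        k: v for k, v in fit_info.items() if k not in ("train_ids", "test_ids")
    }
    if fit is not None:
        outcome.fit_report(fit).to_csv(out / "fit_report.csv")
        probs = outcome.predict_prob(fit, features)
        observed = [
            outcome.binarize_gos(cohort.get(pid).gos, config.gos_rule)
            for pid in features.index
        ]
        pd.DataFrame(
            {"patient_id": features.index, "outcome": observed,
             "probability_of_survival": probs.to_numpy().round(2)}
        ).to_csv(out / "fitted_probabilities.csv", index=False)

    # Dynamic profiling
    prof_seed = child_seed(config.seed, "profile")
    log["seeds"]["profile"] = prof_seed
    partitions, skipped = profiling.build_partitions(
        cohort, degree=config.degree, k=config.k, method=config.method,
        seed=prof_seed, n_restarts=config.n_restarts,
    )
    log["skipped_stages"] = {str(s): r for s, r in skipped.items()}
    rows, weight_dump = [], []
    for part in partitions:
        for pid, c in part.assignment.items():
            rows.append(
                {"stage": part.stage, "patient_id": pid, "cluster": c + 1,
                 "prob_death": part.weights[c].prob_death if c in part.weights else ""}
            )
        weight_dump.append(
            {
                "stage": part.stage, "k": part.k, "seed": part.seed,
                "method": part.method,
                "features_used": part.features_used,
                "centroids": part.centroids.tolist(),
                "weights": {
                    str(c + 1): vars(w) for c, w in part.weights.items()
                },
            }
        )
    pd.DataFrame(rows).to_csv(out / "partitions.csv", index=False)
    (out / "partitions.json").write_text(json.dumps(weight_dump, indent=2))

    curves = []
    for p in cohort:
        try:
            rc = profiling.risk_curve(p.id, partitions)
        except KeyError:
            continue
        curves.extend(
            {"patient_id": p.id, "stage": s, "prob_death": pr}
            for s, pr in zip(rc.stages, rc.probs)
        )
    pd.DataFrame(curves).to_csv(out / "risk_curves.csv", index=False)

    # Leave-one-out evaluation
    loo_seed = child_seed(config.seed, "loo")
    log["seeds"]["loo"] = loo_seed
    loo = matching.loo_success_rate(
        cohort, degree=config.degree, k=config.k, method=config.method,
        seed=loo_seed, n_restarts=config.n_restarts, gos_rule=config.gos_rule,
    )
    pd.DataFrame(loo.records).to_csv(out / "loo_predictions.csv", index=False)
    n, s = loo.n_evaluated, loo.success_rate
    half_width = 1.96 * float(np.sqrt(max(s * (1 - s), 1e-12) / n))
    summary = {
        "success_rate": s,
        "n_evaluated": n,
        "binomial_ci95": [max(0.0, s - half_width), min(1.0, s + half_width)],
        "random_baseline": loo.baseline,
        "skipped": loo.skipped,
    }
    (out / "loo_summary.json").write_text(json.dumps(summary, indent=2))
    log["loo"] = {k: summary[k] for k in ("success_rate", "n_evaluated")}

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log
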