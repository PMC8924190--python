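"""End-to-end patient pipeline: features -> MOEA runs -> testing ->
surrogate validation -> phenotype mining, with run artifacts on disk.

The MOEA is stochastic, so a patient is processed with ``n_runs``
independent executions (default 30); each run's Decision-Maker-selected
individuals are tested pseudoprospectively, run-level mean seizure
sensitivities enter the one-tailed t-test against surrogate sensitivities,
and all selected individuals are pooled for the phenotype study.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import phenotype as ph
from .evaluation import (
    null_report, surrogate_sensitivity, test_patient, validate_above_chance,
)
from .features import build_feature_tensor, FeatureTensor
from .genotype import Individual
from .hyperfitness import AlarmConfig, FitnessEvaluator, POSTICTAL_GUARD_MIN
from .io import (
    MIN_SEIZURE_SPACING_H, InsufficientSeizuresError, Recording,
    read_recording,
)
from .nsga2 import decision_maker, evolve, pareto_front
from .synth import SynthConfig, generate_recording


@dataclass
class RunConfig:
    """Configuration of a full patient run."""

    edf_path: str | None = None
    annotation_path: str | None = None
    synth: SynthConfig | None = None
    population_size: int = 100
    generations: int = 50
    recombination_rate: float = 0.90
    mutation_rate: float = 0.015
    n_runs: int = 30
    dm_thresholds: tuple[float, float] = (0.9, 0.8)
    n_train_seizures: int = 3
    hours_before: float = 4.0
    n_surrogates: int = 30
    alpha: float = 0.01
    seed: int = 0
    out_dir: str = "runs/patient"
    alarm: AlarmConfig = field(default_factory=AlarmConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_recording(config: RunConfig) -> Recording:
    if config.synth is not None:
        return generate_recording(config.synth)
    if config.edf_path is None:
        raise ValueError("config needs either synth or edf_path")
    return read_recording(config.edf_path, config.annotation_path)


def check_selection_criteria(recording: Recording,
                             n_train_seizures: int = 3) -> None:
    """Patient selection: >= n_train+1 seizures, >= 4.5 h apart."""
    onsets = recording.onsets
    if onsets.size < n_train_seizures + 1:
        raise InsufficientSeizuresError(
            f"recording has {onsets.size} seizures; "
            f"need >= {n_train_seizures + 1}")
    gaps = np.diff(onsets)
    if gaps.size and gaps.min() < MIN_SEIZURE_SPACING_H * 3600.0:
        raise InsufficientSeizuresError(
            f"seizures closer than {MIN_SEIZURE_SPACING_H} h")


def fit_patient(tensor: FeatureTensor, onsets, config: RunConfig,
                run_seed: int):
    """One MOEA execution on the training seizures of a prepared tensor.

    Returns ``(selected, below_threshold, population, history)``.
    """
    train_onsets = onsets[: config.n_train_seizures]
    segments = [
        tensor.crop(o - config.hours_before * 3600.0, o) for o in train_onsets
    ]
    evaluator = FitnessEvaluator(segments, train_onsets,
                                 alarm_config=config.alarm)
    rng = np.random.default_rng(run_seed)
    population, history = evolve(
        evaluator, rng,
        population_size=config.population_size,
        generations=config.generations,
        recombination_rate=config.recombination_rate,
        mutation_rate=config.mutation_rate,
    )
    front = pareto_front(population)
    selected, below = decision_maker(front, thresholds=config.dm_thresholds)
    return selected, below, population, history


def run_patient(config: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts under ``out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    try:
        recording = load_recording(config)
        check_selection_criteria(recording, config.n_train_seizures)
        manifest["stages"]["data"] = {
            "n_seizures": int(recording.onsets.size),
            "duration_h": recording.duration / 3600.0,
        }

        tensor = build_feature_tensor(recording)
        manifest["stages"]["features"] = {
            "n_windows": int(tensor.times.size),
            "n_electrodes": len(tensor.electrodes),
        }

        ss = np.random.SeedSequence(config.seed)
        run_seeds = [int(s.generate_state(1)[0] % (2**31))
                     for s in ss.spawn(config.n_runs + 1)]
        surrogate_seed = run_seeds.pop()
        manifest["run_seeds"] = run_seeds

        onsets = recording.onsets
        span = (float(onsets[config.n_train_seizures - 1]
                      + POSTICTAL_GUARD_MIN * 60.0),
                float(recording.duration))
        all_selected: list[Individual] = []
        real_ss, sur_ss, run_records = [], [], []
        sur_rng = np.random.default_rng(surrogate_seed)
        for r, run_seed in enumerate(run_seeds):
            selected, below, population, history = fit_patient(
                tensor, onsets, config, run_seed)
            reports = []
            for ind in selected:
                try:
                    reports.append(test_patient(
                        ind, tensor, onsets,
                        n_train=config.n_train_seizures,
                        hours_before=config.hours_before,
                        alarm_config=config.alarm))
                except KeyError:  # electrodes outside this montage
                    reports.append(null_report(
                        int(onsets.size) - config.n_train_seizures))
            run_ss = float(np.mean([rep.ss for rep in reports]))
            sur_means = []
            for ind, rep in zip(selected, reports):
                sur = surrogate_sensitivity(
                    rep.alarms, n_onsets=rep.n_seizures, span=span,
                    preictal_min=ind.preictal_min, rng=sur_rng,
                    n_surrogates=config.n_surrogates)
                sur_means.append(float(sur.mean()))
            real_ss.append(run_ss)
            sur_ss.append(float(np.mean(sur_means)))
            all_selected.extend(selected)
            run_records.append({
                "seed": run_seed,
                "below_threshold": below,
                "n_selected": len(selected),
                "mean_ss": run_ss,
                "mean_fpr_h": float(np.mean([rep.fpr_h for rep in reports])),
                "reports": [rep.to_dict() for rep in reports],
            })
            sel_path = out / f"selected_run{r:02d}.json"
            sel_path.write_text(json.dumps(
                [ind.to_dict() for ind in selected], indent=1))
            with open(out / f"population_run{r:02d}.jsonl", "w") as fh:
                for ind in population:
                    fh.write(ind.to_json() + "\n")

        validated, p = validate_above_chance(real_ss, sur_ss,
                                             alpha=config.alpha)
        evaluation = {
            "run_mean_ss": real_ss,
            "run_mean_surrogate_ss": sur_ss,
            "p_value": p,
            "validated": validated,
            "runs": run_records,
        }
        (out / "evaluation.json").write_text(
            json.dumps(evaluation, indent=1))
        manifest["stages"]["evaluation"] = {
            "mean_ss": float(np.mean(real_ss)),
            "mean_surrogate_ss": float(np.mean(sur_ss)),
            "validated": validated,
            "p_value": p,
        }

        presence = ph.gene_presence(all_selected)
        tx = ph.transactions_from_individuals(all_selected)
        rules = ph.apriori_rules(tx)
        import pandas as pd

        pd.Series(presence, name="presence").rename_axis("item") \
            .to_csv(out / "gene_presence.csv")
        pd.DataFrame([
            {"antecedent": "&".join(sorted(r.antecedent)),
             "consequent": "&".join(sorted(r.consequent)),
             "support": r.support, "confidence": r.confidence,
             "lift": r.lift}
            for r in rules
        ]).to_csv(out / "rules.csv", index=False)
        ph.interaction_matrix(rules).to_csv(out / "interaction_matrix.csv")
        ph.electrode_connectivity(rules, tx).to_csv(
            out / "electrode_connectivity.csv", index=False)
        manifest["stages"]["phenotype"] = {
            "n_transactions": len(tx),
            "n_rules": len(rules),
        }
    except Exception as exc:  # surface the failing stage, keep partial output
        manifest["error"] = {"stage": _last_stage(manifest), "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _last_stage(manifest: dict) -> str:
    stages = list(manifest.get("stages", {}))
    order = ["data", "features", "evaluation", "phenotype"]
    done = set(stages)
    for s in order:
        if s not in done:
            return s
    return "finalise"
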