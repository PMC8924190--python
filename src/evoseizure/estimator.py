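"""Scikit-learn-style estimator wrapping the evolutionary predictor.

``SeizurePredictor.fit`` takes a :class:`~evoseizure.io.Recording`, extracts
features, runs the NSGA-II search on the first training seizures and applies
the Decision Maker; ``predict`` replays the remaining seizures
pseudoprospectively and returns alarm times.  Parameters follow sklearn
conventions (``get_params`` / ``set_params`` via ``BaseEstimator``), fitted
state carries a trailing underscore.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .evaluation import EvaluationReport, null_report, test_patient
from .features import build_feature_tensor
from .hyperfitness import AlarmConfig
from .io import Recording
from .pipeline import RunConfig, check_selection_criteria, fit_patient


class SeizurePredictor(BaseEstimator):
    """Patient-specific seizure predictor evolved by NSGA-II.

    Parameters
    ----------
    population_size, generations, recombination_rate, mutation_rate
        MOEA settings (reference values 100 / 50 / 0.90 / 0.015).
    n_train_seizures, hours_before
        Training uses the last ``hours_before`` hours before each of the
        first ``n_train_seizures`` seizures.
    dm_thresholds
        Decision-Maker thresholds on sample sensitivity/specificity.
    fp_threshold
        Firing Power alarm threshold.
    random_state
        Seed of the evolutionary run.

    Attributes
    ----------
    tensor_ : FeatureTensor of the fitted recording.
    selected_individuals_ : Decision-Maker-selected individuals.
    below_threshold_ : True when even the relaxed 0.8 threshold failed and
        the max-min fallback individual was returned.
    population_ : final MOEA population.
    history_ : per-generation fitness log.
    """

    def __init__(self, population_size: int = 100, generations: int = 50,
                 recombination_rate: float = 0.90,
                 mutation_rate: float = 0.015,
                 n_train_seizures: int = 3, hours_before: float = 4.0,
                 dm_thresholds: tuple = (0.9, 0.8),
                 fp_threshold: float = 0.7,
                 random_state: int | None = None):
        self.population_size = population_size
        self.generations = generations
        self.recombination_rate = recombination_rate
        self.mutation_rate = mutation_rate
        self.n_train_seizures = n_train_seizures
        self.hours_before = hours_before
        self.dm_thresholds = dm_thresholds
        self.fp_threshold = fp_threshold
        self.random_state = random_state

    def _run_config(self) -> RunConfig:
        return RunConfig(
            population_size=self.population_size,
            generations=self.generations,
            recombination_rate=self.recombination_rate,
            mutation_rate=self.mutation_rate,
            n_train_seizures=self.n_train_seizures,
            hours_before=self.hours_before,
            dm_thresholds=tuple(self.dm_thresholds),
            alarm=AlarmConfig(fp_threshold=self.fp_threshold),
        )

    def fit(self, X: Recording, y=None) -> "SeizurePredictor":
        """Evolve and select prediction models on the recording's first
        training seizures."""
        if not isinstance(X, Recording):
            raise TypeError("X must be a Recording")
        check_selection_criteria(X, self.n_train_seizures)
        self.tensor_ = build_feature_tensor(X)
        self.onsets_ = np.asarray(X.onsets, dtype=float)
        seed = 0 if self.random_state is None else int(self.random_state)
        cfg = self._run_config()
        (self.selected_individuals_, self.below_threshold_,
         self.population_, self.history_) = fit_patient(
            self.tensor_, self.onsets_, cfg, run_seed=seed)
        return self

    def _check_fitted(self):
        if not hasattr(self, "selected_individuals_"):
            raise AttributeError("SeizurePredictor is not fitted")

    def evaluate(self) -> list[EvaluationReport]:
        """Pseudoprospective reports of each selected individual on the
        fitted recording's test seizures."""
        self._check_fitted()
        cfg = self._run_config()
        reports = []
        for ind in self.selected_individuals_:
            try:
                reports.append(test_patient(
                    ind, self.tensor_, self.onsets_,
                    n_train=self.n_train_seizures,
                    hours_before=self.hours_before,
                    alarm_config=cfg.alarm))
            except KeyError:  # electrodes outside this montage
                reports.append(null_report(
                    int(self.onsets_.size) - self.n_train_seizures))
        return reports

    def predict(self, X=None) -> np.ndarray:
        """Alarm times (seconds) of the first selected individual on the
        fitted recording's test stream."""
        self._check_fitted()
        reports = self.evaluate()
        return reports[0].alarms

    def score(self, X=None, y=None) -> float:
        """Mean seizure sensitivity of the selected individuals."""
        return float(np.mean([r.ss for r in self.evaluate()]))
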