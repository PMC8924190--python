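"""Pseudoprospective testing, surrogate validation and meta-statistics.

Testing replays the recording chronologically: before each test seizure the
logistic regression is retrained on the 4-h segments of every seizure seen
so far, the classifier output is smoothed with Firing Power, alarms obey a
refractory period equal to the pre-ictal duration, and a seizure counts as
predicted iff at least one alarm falls inside its pre-ictal interval.
FPR/h counts false alarms per hour of *eligible* time — inter-ictal time
outside pre-ictal windows and refractory periods.

Chance level is estimated with a surrogate analysis: the alarm train is kept
fixed while seizure onsets are re-placed uniformly at random (respecting the
4.5-h spacing), and sensitivity is re-scored.  A one-tailed Welch t-test at
alpha = 0.01 decides whether the real sensitivity is above chance.  Eq-style
population significance uses the binomial tail probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import FeatureTensor
from .genotype import Individual
from .hyperfitness import (
    AlarmConfig, DegenerateTrainingError, firing_power, label_samples,
    construct_hyperfeature, raise_alarms, train_classifier, zscore_fit_apply,
    POSTICTAL_GUARD_MIN,
)
from .io import MIN_SEIZURE_SPACING_H


@dataclass
class EvaluationReport:
    """Outcome of testing one individual pseudoprospectively."""

    ss: float                       # seizure sensitivity
    fpr_h: float                    # false alarms / eligible hour
    n_seizures: int
    n_predicted: int
    alarms: np.ndarray              # alarm times, seconds
    refractory_intervals: list[tuple[float, float]]
    eligible_hours: float
    surrogate_sensitivities: np.ndarray | None = None
    p_value: float | None = None
    validated: bool | None = None

    def to_dict(self) -> dict:
        return {
            "ss": self.ss,
            "fpr_h": self.fpr_h,
            "n_seizures": self.n_seizures,
            "n_predicted": self.n_predicted,
            "alarms_s": list(map(float, self.alarms)),
            "refractory_intervals_s": [list(map(float, r))
                                       for r in self.refractory_intervals],
            "eligible_hours": self.eligible_hours,
            "surrogate_sensitivities": (
                None if self.surrogate_sensitivities is None
                else list(map(float, self.surrogate_sensitivities))),
            "p_value": self.p_value,
            "validated": self.validated,
        }


def null_report(n_test: int) -> EvaluationReport:
    """Report of an undeployable model (e.g. one whose electrodes are not in
    the recording's montage): no alarms, zero sensitivity."""
    return EvaluationReport(
        ss=0.0, fpr_h=0.0, n_seizures=n_test, n_predicted=0,
        alarms=np.empty(0), refractory_intervals=[], eligible_hours=0.0,
    )


def _design_matrix(tensor: FeatureTensor, specs):
    series = [construct_hyperfeature(tensor, s) for s in specs]
    t_first = max(s.times[0] for s in series)
    t_last = min(s.times[-1] for s in series)
    cols, times = [], None
    for s in series:
        m = (s.times >= t_first) & (s.times <= t_last)
        cols.append(s.values[m])
        times = s.times[m]
    return times, np.column_stack(cols)


def test_patient(individual: Individual, tensor: FeatureTensor,
                 onsets, n_train: int = 3, hours_before: float = 4.0,
                 alarm_config: AlarmConfig | None = None) -> EvaluationReport:
    """Chronological pseudoprospective test of one individual.

    ``tensor`` must cover the whole recording; the first ``n_train`` onsets
    are training seizures, the rest are tested.  Before each test seizure
    the classifier is retrained on the 4-h pre-onset segments of all
    seizures seen so far.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size <= n_train:
        raise ValueError("no test seizures")
    cfg = alarm_config or AlarmConfig()
    specs = individual.specs()
    p_s = individual.preictal_min * 60.0
    tau = int(individual.preictal_min)
    guard_s = POSTICTAL_GUARD_MIN * 60.0

    times, X = _design_matrix(tensor, specs)

    def segment_data(onset):
        m = (times >= onset - hours_before * 3600.0) & (times < onset)
        y, valid = label_samples(times[m], [onset], individual.preictal_min)
        return X[m][valid], y[valid]

    all_alarm_times: list[float] = []
    refractory: list[tuple[float, float]] = []
    n_pred = 0
    n_false = 0
    eligible_min = 0.0

    for k in range(n_train, onsets.size):
        X_tr = np.vstack([segment_data(o)[0] for o in onsets[:k]])
        y_tr = np.concatenate([segment_data(o)[1] for o in onsets[:k]])
        chunk_start = onsets[k - 1] + guard_s
        m = (times >= chunk_start) & (times < onsets[k])
        t_chunk = times[m]
        if t_chunk.size == 0:
            continue
        try:
            Z_tr, Z_chunk, *_ = zscore_fit_apply(X_tr, X[m])
            clf = train_classifier(Z_tr, y_tr)
            yhat = clf.predict(Z_chunk)
        except DegenerateTrainingError:
            yhat = np.zeros(t_chunk.size, dtype=int)
        fp = firing_power(yhat, tau)
        idx = raise_alarms(fp, refractory_samples=tau,
                           threshold=cfg.fp_threshold)
        alarm_t = t_chunk[idx]
        preictal = (t_chunk >= onsets[k] - p_s) & (t_chunk < onsets[k])
        in_pre = (alarm_t >= onsets[k] - p_s) & (alarm_t < onsets[k])
        if in_pre.any():
            n_pred += 1
        n_false += int((~in_pre).sum())
        all_alarm_times.extend(alarm_t)

        # eligible time: chunk minus pre-ictal window minus refractory
        refr = np.zeros(t_chunk.size, dtype=bool)
        for i in idx:
            refr[i + 1: i + 1 + tau] = True
            refractory.append((float(t_chunk[i]),
                               float(min(t_chunk[i] + p_s, onsets[k]))))
        eligible_min += float((~preictal & ~refr).sum())

    n_test = onsets.size - n_train
    eligible_h = eligible_min / 60.0
    return EvaluationReport(
        ss=n_pred / n_test,
        fpr_h=(n_false / eligible_h) if eligible_h > 0 else 0.0,
        n_seizures=n_test,
        n_predicted=n_pred,
        alarms=np.asarray(all_alarm_times),
        refractory_intervals=refractory,
        eligible_hours=eligible_h,
    )


# ---------------------------------------------------------------------------
# surrogate analysis

def surrogate_sensitivity(alarms, n_onsets: int, span: tuple[float, float],
                          preictal_min: float, rng: np.random.Generator,
                          n_surrogates: int = 30,
                          min_spacing_h: float = MIN_SEIZURE_SPACING_H
                          ) -> np.ndarray:
    """Seizure sensitivities of surrogate onset placements.

    Each surrogate re-places ``n_onsets`` onsets uniformly within ``span``
    (not earlier than ``start + preictal`` and respecting the minimum
    spacing) while keeping the real alarm train fixed, then re-scores the
    fraction of surrogate onsets preceded by an alarm inside their
    pre-ictal interval.
    """
    alarms = np.asarray(alarms, dtype=float)
    start, end = span
    p_s = preictal_min * 60.0
    gap = min_spacing_h * 3600.0
    lo, hi = start + p_s, end
    slack = (hi - lo) - (n_onsets - 1) * gap
    if slack < 0:
        raise ValueError("span too short for spaced surrogate onsets")
    out = np.empty(n_surrogates)
    for s in range(n_surrogates):
        u = np.sort(rng.uniform(0.0, slack, size=n_onsets))
        onsets = lo + u + gap * np.arange(n_onsets)
        if alarms.size == 0:
            out[s] = 0.0
            continue
        hit = [
            np.any((alarms >= o - p_s) & (alarms < o)) for o in onsets
        ]
        out[s] = float(np.mean(hit))
    return out


def validate_above_chance(real_ss, surrogate_ss, alpha: float = 0.01):
    """One-tailed Welch t-test: is the real seizure sensitivity above the
    surrogate one?  Returns ``(validated, p)``; validated requires both
    mean(real) > mean(surrogate) and p < alpha."""
    real = np.asarray(real_ss, dtype=float)
    sur = np.asarray(surrogate_ss, dtype=float)
    if real.size == 0 or sur.size == 0:
        raise ValueError("both samples must be non-empty")
    if real.std() == 0 and sur.std() == 0:
        if real.mean() == sur.mean():
            return False, 1.0
        return bool(real.mean() > sur.mean()), 0.0
    t, p = stats.ttest_ind(real, sur, equal_var=False,
                           alternative="greater")
    if math.isnan(p):
        return False, 1.0
    return bool(real.mean() > sur.mean() and p < alpha), float(p)


def binom_meta(i: int, I: int, alpha: float = 0.05) -> float:
    """Tail probability of observing at least ``i`` of ``I`` patient models
    above chance under a per-model false-positive rate ``alpha``:
    ``sum_{j=i}^{I} C(I, j) alpha^j (1 - alpha)^(I - j)``."""
    if not 0 <= i <= I:
        raise ValueError("need 0 <= i <= I")
    if i == 0:
        return 1.0  # whole sample space, exactly
    return float(sum(
        math.comb(I, j) * alpha**j * (1 - alpha) ** (I - j)
        for j in range(i, I + 1)
    ))
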