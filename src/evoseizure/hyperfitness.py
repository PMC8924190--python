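"""Hyper-feature construction, classification and the three fitness objectives.

A hyper-feature is a second-level feature: a mathematical operator (mean,
median, variance, max, min) applied over a look-back window of a first-level
feature series, placed on a 1-minute grid through a delay.  The value at
grid time ``t`` reduces the 5-s-resolution feature over
``[t - delay - window, t - delay)``.

Fitness of an individual is evaluated by iterative retraining on its
training seizures: for each validation seizure the class-weighted logistic
regression is trained on all earlier seizures' segments and its raw binary
outputs are scored sample-wise.  Sample sensitivity and specificity are
averaged over validation seizures; the third objective is the
electrode-comfort term computed from the genotype alone.  Firing Power
smoothing (threshold 0.7, window = pre-ictal duration) regularises the
*alarm* stream during testing; it is deliberately not applied to the sample
metrics — a trailing average of pre-ictal length crossing 0.7 only after
70% of the window would bound sample sensitivity near 0.3 even for a
perfect classifier, which is incompatible with sensitivity/specificity
objectives thresholded at 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.linear_model import LogisticRegression

from .features import FeatureTensor, WINDOW_S
from .genotype import HyperFeatureSpec, Individual
from .montage import lobes_of

GRID_STEP_S = 60.0          # sliding-window analysis step
POSTICTAL_GUARD_MIN = 30.0  # samples after onset excluded from both classes
FP_THRESHOLD = 0.7

_OPERATORS = {
    "mean": lambda W: W.mean(axis=-1),
    "median": lambda W: np.median(W, axis=-1),
    "variance": lambda W: W.var(axis=-1),
    "max": lambda W: W.max(axis=-1),
    "min": lambda W: W.min(axis=-1),
}


class DegenerateTrainingError(ValueError):
    pass


class FitnessTriple(NamedTuple):
    sss: float   # sample sensitivity
    ssp: float   # sample specificity
    pcf: float   # patient comfort


@dataclass
class AlarmConfig:
    """Alarm generation settings.  The Firing Power window and the
    refractory period both equal the individual's pre-ictal duration."""

    fp_threshold: float = FP_THRESHOLD
    intervention_min: float = 10.0

    def __post_init__(self):
        if not 0.0 < self.fp_threshold <= 1.0:
            raise ValueError("fp_threshold must be in (0, 1]")


@dataclass
class HyperFeatureSeries:
    """A constructed hyper-feature on the 1-min grid (times in seconds)."""

    times: np.ndarray
    values: np.ndarray
    labels: np.ndarray | None = None


# ---------------------------------------------------------------------------
# construction and labelling

def construct_hyperfeature(tensor: FeatureTensor, spec: HyperFeatureSpec,
                           grid_step: float = GRID_STEP_S) -> HyperFeatureSeries:
    """Reduce a first-level feature into a hyper-feature series.

    Grid times are absolute multiples of ``grid_step``; a point is defined
    only where its look-back window ``[t - delay - window, t - delay)`` is
    fully covered by the tensor.
    """
    x = tensor.feature_series(spec.electrode, spec.feature_id)
    t0 = tensor.start_s
    seg_end = t0 + tensor.times.size * WINDOW_S
    d = spec.delay_min * 60.0
    w = spec.window_min * 60.0
    w5 = int(round(w / WINDOW_S))

    t_first = np.ceil((t0 + d + w) / grid_step) * grid_step
    t_last = np.floor(seg_end / grid_step) * grid_step
    if t_first > t_last:
        return HyperFeatureSeries(np.empty(0), np.empty(0))
    times = np.arange(t_first, t_last + grid_step / 2, grid_step)

    starts = np.round((times - d - w - t0) / WINDOW_S).astype(int)
    view = sliding_window_view(x, w5)
    values = _OPERATORS[spec.operator](view[starts])
    return HyperFeatureSeries(times, values)


def label_samples(times: np.ndarray, onsets: Sequence[float],
                  preictal_min: float,
                  postictal_min: float = POSTICTAL_GUARD_MIN):
    """Pre-ictal / inter-ictal labels for sample times.

    Label 1 iff ``t in [onset - preictal, onset)`` for some onset; samples
    in ``[onset, onset + postictal]`` are marked invalid (post-ictal guard);
    everything else is 0.  Returns ``(labels, valid)`` arrays.
    """
    times = np.asarray(times, dtype=float)
    labels = np.zeros(times.size, dtype=int)
    valid = np.ones(times.size, dtype=bool)
    for onset in onsets:
        labels[(times >= onset - preictal_min * 60.0) & (times < onset)] = 1
        valid[(times >= onset) & (times <= onset + postictal_min * 60.0)] = False
    return labels, valid


# ---------------------------------------------------------------------------
# standardisation and classification

def zscore_fit_apply(train_X: np.ndarray, other_X: np.ndarray | None = None):
    """Column z-scoring with parameters fitted on the training matrix only.

    Uses population standard deviation; zero-SD columns standardise to zero
    (SD replaced by 1) and are flagged.  Returns
    ``(train_Z, other_Z, mean, sd, constant_flags)``.
    """
    train_X = np.asarray(train_X, dtype=float)
    if train_X.size == 0:
        raise DegenerateTrainingError("empty training matrix")
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    flags = sd == 0.0
    sd_safe = np.where(flags, 1.0, sd)
    train_Z = (train_X - mean) / sd_safe
    other_Z = None if other_X is None else (np.asarray(other_X) - mean) / sd_safe
    return train_Z, other_Z, mean, sd_safe, flags


def train_classifier(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Class-weighted logistic regression (weights inversely proportional to
    class frequency, i.e. ``n / (2 n_c)``)."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    clf = LogisticRegression(class_weight="balanced", solver="lbfgs",
                             max_iter=1000)
    clf.fit(X, y)
    return clf


# ---------------------------------------------------------------------------
# Firing Power and alarms

def firing_power(yhat: np.ndarray, tau_samples: int) -> np.ndarray:
    """Trailing moving average of a binary classifier output.

    ``tau_samples`` is the pre-ictal duration in 1-min samples.  Partial
    windows at the stream start average over the available samples.
    """
    if tau_samples < 1:
        raise ValueError("tau_samples must be >= 1")
    y = np.asarray(yhat, dtype=float)
    c = np.cumsum(y)
    n = y.size
    idx = np.arange(n)
    prev = c[np.clip(idx - tau_samples, 0, None)]
    window_sum = c - np.where(idx >= tau_samples, prev, 0.0)
    counts = np.minimum(idx + 1, tau_samples)
    return window_sum / counts


def raise_alarms(fp: np.ndarray, refractory_samples: int,
                 threshold: float = FP_THRESHOLD) -> np.ndarray:
    """Alarm sample indices: upward crossings of ``threshold``, with crossings
    during the refractory period after each alarm ignored."""
    fp = np.asarray(fp)
    alarms = []
    blocked_until = -1
    for i in range(fp.size):
        if fp[i] >= threshold and (i == 0 or fp[i - 1] < threshold):
            if i > blocked_until:
                alarms.append(i)
                blocked_until = i + refractory_samples
    return np.asarray(alarms, dtype=int)


# ---------------------------------------------------------------------------
# objectives

def patient_comfort(electrodes) -> float:
    """Comfort objective from the electrode set, exactly as printed:
    ``Pcf = 1.25 (1 - (N_el * N_lobes) / (N_el * 5))``.

    1 when a single electrode in a single lobe is used; 0 for five
    electrodes across five lobes.
    """
    electrodes = set(electrodes)
    if not electrodes:
        raise ValueError("empty electrode set")
    n_el = len(electrodes)
    n_lobes = len(lobes_of(electrodes))
    return 1.25 * (1.0 - (n_el * n_lobes) / (n_el * 5.0))


class FitnessEvaluator:
    """Evaluates individuals against the training seizures' 4-h segments.

    Parameters
    ----------
    segments
        Chronological list of FeatureTensor objects, one per training
        seizure, each covering the hours before (and ending at) its onset.
    onsets
        The matching onset times (seconds, absolute timeline).

    Hyper-feature series are cached per (segment, spec), which makes the
    population loop cheap: individuals share most decoded specs after a few
    generations.
    """

    def __init__(self, segments: Sequence[FeatureTensor],
                 onsets: Sequence[float],
                 alarm_config: AlarmConfig | None = None):
        if len(segments) != len(onsets):
            raise ValueError("one onset per segment required")
        if len(segments) < 2:
            raise ValueError("need >= 2 training seizures for "
                             "iterative retraining")
        self.segments = list(segments)
        self.onsets = [float(o) for o in onsets]
        self.alarm_config = alarm_config or AlarmConfig()
        self._cache: dict = {}

    def series(self, seg_idx: int, spec: HyperFeatureSpec) -> HyperFeatureSeries:
        key = (seg_idx, spec)
        if key not in self._cache:
            self._cache[key] = construct_hyperfeature(
                self.segments[seg_idx], spec)
        return self._cache[key]

    def design_matrix(self, seg_idx: int, specs: Sequence[HyperFeatureSpec]):
        """(times, X) on the intersection grid of the five hyper-features."""
        series = [self.series(seg_idx, s) for s in specs]
        if any(s.times.size == 0 for s in series):
            return np.empty(0), np.empty((0, len(specs)))
        t_first = max(s.times[0] for s in series)
        t_last = min(s.times[-1] for s in series)
        cols, times = [], None
        for s in series:
            m = (s.times >= t_first) & (s.times <= t_last)
            cols.append(s.values[m])
            times = s.times[m]
        return times, np.column_stack(cols)

    def __call__(self, ind: Individual) -> FitnessTriple:
        return self.evaluate(ind)

    def evaluate(self, ind: Individual) -> FitnessTriple:
        """Iteratively retrained fitness: validate on seizure k after
        training on seizures 1..k-1; average Sss/Ssp over validation
        seizures; Pcf from the genotype's electrode set."""
        specs = ind.specs()
        pcf = patient_comfort({s.electrode for s in specs})

        data = []
        for k in range(len(self.segments)):
            times, X = self.design_matrix(k, specs)
            y, valid = label_samples(times, [self.onsets[k]], ind.preictal_min)
            data.append((X[valid], y[valid]))

        sss_list, ssp_list = [], []
        for k in range(1, len(data)):
            X_tr = np.vstack([data[j][0] for j in range(k)])
            y_tr = np.concatenate([data[j][1] for j in range(k)])
            X_val, y_val = data[k]
            if X_val.shape[0] == 0:
                continue
            try:
                Z_tr, Z_val, *_ = zscore_fit_apply(X_tr, X_val)
                clf = train_classifier(Z_tr, y_tr)
            except DegenerateTrainingError:
                sss_list.append(0.0)
                ssp_list.append(0.0)
                continue
            pred = clf.predict(Z_val).astype(bool)
            pos = y_val == 1
            neg = ~pos
            if pos.any():
                sss_list.append(float(pred[pos].mean()))
            if neg.any():
                ssp_list.append(float((~pred[neg]).mean()))
        sss = float(np.mean(sss_list)) if sss_list else 0.0
        ssp = float(np.mean(ssp_list)) if ssp_list else 0.0
        return FitnessTriple(sss, ssp, pcf)
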