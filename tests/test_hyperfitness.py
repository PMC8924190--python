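import numpy as np
import pytest

from evoseizure.features import FEATURE_IDS, FEATURE_INDEX, FeatureTensor
from evoseizure.genotype import HyperFeatureGenotype, HyperFeatureSpec, Individual
from evoseizure.hyperfitness import (
    AlarmConfig, DegenerateTrainingError, FitnessEvaluator,
    construct_hyperfeature, firing_power, label_samples, patient_comfort,
    raise_alarms, train_classifier, zscore_fit_apply,
)


def make_tensor(values_1d, electrode="C3", feature="variance", start=0.0):
    """Single-electrode tensor with one feature set to a given series."""
    n = len(values_1d)
    vals = np.zeros((n, 1, len(FEATURE_IDS)))
    vals[:, 0, FEATURE_INDEX[feature]] = values_1d
    return FeatureTensor(start + 5.0 * np.arange(n), [electrode], vals,
                         np.zeros((n, 1), bool))


def spec(feature="variance", electrode="C3", delay=0, operator="mean",
         window=5):
    return HyperFeatureSpec(feature, electrode, delay, operator, window)


# ---------------------------------------------------------------------------
# construction

def test_constant_feature_reduces_to_constant_or_zero():
    tensor = make_tensor(np.full(240, 7.0))  # 20 min of data
    s = construct_hyperfeature(tensor, spec(operator="mean"))
    assert s.times.size > 0
    np.testing.assert_allclose(s.values, 7.0)
    v = construct_hyperfeature(tensor, spec(operator="variance"))
    np.testing.assert_allclose(v.values, 0.0)


def test_lookback_window_coverage_and_grid():
    tensor = make_tensor(np.arange(360.0))  # 30 min
    s = construct_hyperfeature(tensor, spec(window=10, delay=5))
    # first defined point needs delay+window = 15 min of history
    assert s.times[0] == 15 * 60.0
    assert s.times[-1] == 30 * 60.0
    assert np.all(np.diff(s.times) == 60.0)


def test_delay_shifts_response():
    x = np.zeros(600)
    x[360:] = 1.0  # step at t = 1800 s
    tensor = make_tensor(x)
    for d in (0, 10):
        s = construct_hyperfeature(tensor, spec(operator="max", window=5,
                                                delay=d))
        first = s.times[np.nonzero(s.values > 0)[0][0]]
        assert first == 1800.0 + d * 60.0 + 60.0  # next grid point after rise


def test_missing_electrode_raises():
    tensor = make_tensor(np.ones(240))
    with pytest.raises(KeyError):
        construct_hyperfeature(tensor, spec(electrode="O1"))


# ---------------------------------------------------------------------------
# labels

def test_label_interval_arithmetic():
    labels, valid = label_samples([7500.0], [10_000.0], preictal_min=50)
    assert labels[0] == 1 and valid[0]


def test_onset_sample_excluded_and_postictal_guard():
    t = np.array([9_999.0, 10_000.0, 10_900.0, 12_000.0])
    labels, valid = label_samples(t, [10_000.0], preictal_min=30)
    assert labels[0] == 1
    assert not valid[1] and not valid[2]  # ictal + 30-min guard
    assert valid[3] and labels[3] == 0


def test_no_onsets_all_interictal():
    labels, valid = label_samples(np.arange(10.0), [], 45)
    assert not labels.any() and valid.all()


# ---------------------------------------------------------------------------
# standardisation / classifier

def test_zscore_hand_computed_population_sd():
    Z, other, mean, sd, flags = zscore_fit_apply(
        np.array([[1.0], [2.0], [3.0]]), np.array([[1.0], [2.0], [3.0]]))
    np.testing.assert_allclose(Z[:, 0], [-1.2247449, 0.0, 1.2247449])
    np.testing.assert_allclose(other, Z)
    assert not flags.any()


def test_zscore_constant_column_flagged():
    Z, _, _, _, flags = zscore_fit_apply(np.full((4, 2), 3.0))
    assert flags.all()
    np.testing.assert_allclose(Z, 0.0)


def test_classifier_separable_and_symmetric():
    rng = np.random.default_rng(0)
    X = np.r_[rng.normal(-3, 0.1, 100), rng.normal(3, 0.1, 100)][:, None]
    y = np.r_[np.zeros(100), np.ones(100)]
    clf = train_classifier(X, y)
    assert (clf.predict(X) == y).mean() >= 0.99
    flipped = train_classifier(X, 1 - y)
    assert np.sign(flipped.coef_[0, 0]) == -np.sign(clf.coef_[0, 0])


def test_class_weighting_beats_unweighted_on_imbalance():
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import balanced_accuracy_score

    rng = np.random.default_rng(1)
    X = np.r_[rng.normal(0, 1, 950), rng.normal(1.5, 1, 50)][:, None]
    y = np.r_[np.zeros(950), np.ones(50)]
    weighted = train_classifier(X, y)
    plain = LogisticRegression(solver="lbfgs").fit(X, y)
    assert balanced_accuracy_score(y, weighted.predict(X)) > \
        balanced_accuracy_score(y, plain.predict(X))


def test_single_class_training_refused():
    with pytest.raises(DegenerateTrainingError):
        train_classifier(np.zeros((5, 1)), np.zeros(5))


# ---------------------------------------------------------------------------
# Firing Power and alarms

def test_firing_power_bounds_and_saturation():
    assert (firing_power(np.zeros(100), 10) == 0).all()
    fp = firing_power(np.ones(100), 10)
    assert (fp[9:] == 1.0).all()
    y = np.random.default_rng(2).integers(0, 2, 500)
    fp = firing_power(y, 45)
    assert fp.min() >= 0 and fp.max() <= 1


def test_firing_power_half_window_step():
    tau = 40
    y = np.r_[np.zeros(100), np.ones(tau // 2)]
    assert firing_power(y, tau)[-1] == 0.5


def test_alarm_on_first_threshold_crossing_only():
    fp = np.r_[np.linspace(0, 1, 50), np.linspace(1, 0, 50)]
    alarms = raise_alarms(fp, refractory_samples=60)
    assert alarms.tolist() == [int(np.argmax(fp >= 0.7))]
    assert raise_alarms(np.full(100, 0.69), 10).size == 0


def test_refractory_suppresses_second_crossing():
    fp = np.zeros(120)
    fp[10] = 0.8
    fp[20] = 0.9      # 10 min later, inside 50-sample refractory
    fp[80] = 0.9      # outside refractory
    assert raise_alarms(fp, refractory_samples=50).tolist() == [10, 80]


def test_alarm_config_validation():
    with pytest.raises(ValueError):
        AlarmConfig(fp_threshold=0.0)


# ---------------------------------------------------------------------------
# comfort

def test_patient_comfort_printed_values():
    assert patient_comfort({"C3"}) == 1.0
    assert patient_comfort({"Fp1", "C3", "P3", "O1", "T3"}) == 0.0
    # 3 electrodes across 2 lobes
    assert patient_comfort({"C3", "Cz", "P3"}) == pytest.approx(0.75)


def test_patient_comfort_depends_only_on_lobe_count():
    # as printed, the electrode count cancels: Pcf = 1.25 (1 - N_lobes / 5)
    for els in ({"C3"}, {"C3", "C4"}, {"C3", "Cz", "C4"}):
        assert patient_comfort(els) == pytest.approx(1.25 * (1 - 1 / 5))
    with pytest.raises(ValueError):
        patient_comfort(set())


# ---------------------------------------------------------------------------
# individual evaluation

def oracle_individual(preictal=45, electrode="C3"):
    hf = HyperFeatureGenotype(
        "time", "moment", "band_power", "relative_power", "variance",
        "activity", "delta", "d1", 50, 0, electrode, "mean", 15)
    return Individual(
        [hf, hf.replace(delay=5), hf.replace(delay=10),
         hf.replace(operator="median"), hf.replace(operator="max")],
        preictal)


@pytest.fixture(scope="module")
def planted_evaluator(planted_tensor, planted_recording):
    onsets = planted_recording.onsets
    segments = [planted_tensor.crop(o - 4 * 3600.0, o) for o in onsets]
    return FitnessEvaluator(segments, onsets)


def test_planted_drift_yields_high_sample_metrics(planted_evaluator):
    fit = planted_evaluator(oracle_individual(preictal=45))
    assert fit.sss >= 0.95 and fit.ssp >= 0.95
    assert fit.pcf == 1.0


def test_unplanted_electrode_near_chance(planted_evaluator):
    fit = planted_evaluator(oracle_individual(electrode="C4"))
    assert 0.6 <= fit.sss + fit.ssp <= 1.4  # chance level ~1


def test_comfort_objective_is_data_independent(planted_evaluator):
    ind = oracle_individual()
    assert planted_evaluator(ind).pcf == patient_comfort(ind.electrodes())
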