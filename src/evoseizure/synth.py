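"""Synthetic continuous EEG with planted pre-ictal structure.

The generator emulates the study conditions of a long-term scalp monitoring
session: stationary EEG-like background noise on all 19 10-20 electrodes,
seizure onsets separated by at least 4.5 h, and — in a configurable pre-ictal
window before each onset — a drift of one chosen first-level feature on a
chosen electrode set, expressed in units of that feature's baseline
window-to-window standard deviation.

The drift is calibrated numerically against the generated baseline so that a
``drift_magnitude`` of ``k`` moves the window-level feature mean by
``k x SD`` at full drift strength.  Supported planted features:

* ``variance`` (equivalently Hjorth activity) — an amplitude gain; absolute
  wavelet sub-band energies co-drift, relative band powers do not;
* ``mean`` — a DC offset (only visible without the 0.5 Hz high-pass; meant
  for unfiltered unit tests);
* ``rel_power_<band>`` — a band-centre sinusoid with bisection-calibrated
  amplitude.

Everything is driven by one integer seed; identical configs produce
bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (
    BANDS, TARGET_FS, WINDOW_SAMPLES, _window_features, FEATURE_INDEX,
)
from .io import MIN_SEIZURE_SPACING_H, Recording
from .montage import ELECTRODES

DRIFT_SHAPES = ("linear-ramp", "step", "exponential")
NOISE_MODELS = ("pink", "white")

PLANTABLE = ("variance", "mean") + tuple(f"rel_power_{b}" for b in BANDS)

BAND_CENTRES = {f"rel_power_{b}": (lo + hi) / 2.0
                for b, (lo, hi) in BANDS.items()}


class InvalidConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Configuration of a synthetic patient recording.

    Defaults define the reference study conditions: 19 channels of pink
    noise at 20 uV RMS, four seizures >= 4.5 h apart, and a 3-SD step drift
    of the variance feature on C3 during the 45 min before each onset.
    ``duration_s=None`` picks the shortest duration that hosts
    ``n_seizures`` with the required spacing plus one hour of slack.
    """

    n_channels: int = 19
    duration_s: float | None = None
    n_seizures: int = 4
    planted_preictal_min: float = 45.0
    planted_electrodes: tuple[str, ...] = ("C3",)
    planted_feature: str = "variance"
    drift_shape: str = "step"
    drift_magnitude: float = 3.0
    noise_model: str = "pink"
    noise_rms_uv: float = 20.0
    fs: float = float(TARGET_FS)
    seed: int = 0
    channels: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.channels:
            self.channels = ELECTRODES[: self.n_channels]
        if not 30.0 <= self.planted_preictal_min <= 75.0:
            raise InvalidConfigError("planted_preictal_min must be in [30, 75]")
        if self.drift_magnitude < 0:
            raise InvalidConfigError("drift_magnitude must be >= 0")
        if self.drift_shape not in DRIFT_SHAPES:
            raise InvalidConfigError(f"drift_shape must be one of {DRIFT_SHAPES}")
        if self.noise_model not in NOISE_MODELS:
            raise InvalidConfigError(f"noise_model must be one of {NOISE_MODELS}")
        if self.planted_feature not in PLANTABLE:
            raise InvalidConfigError(
                f"planted_feature {self.planted_feature!r} not plantable; "
                f"choose one of {PLANTABLE}"
            )
        for e in self.planted_electrodes:
            if e not in self.channels:
                raise InvalidConfigError(f"planted electrode {e!r} not generated")
        lead = self._lead_s
        min_dur = self._min_duration_s
        if self.duration_s is None:
            self.duration_s = min_dur + 3600.0
        if self.n_seizures and self.duration_s < min_dur:
            raise InvalidConfigError(
                f"duration {self.duration_s} s too short for {self.n_seizures} "
                f"seizures with {MIN_SEIZURE_SPACING_H} h spacing and "
                f"{lead / 3600:.2f} h lead (need >= {min_dur} s)"
            )

    @property
    def _lead_s(self) -> float:
        # one hour of guaranteed baseline before the first pre-ictal window
        return self.planted_preictal_min * 60.0 + 3600.0

    @property
    def _min_duration_s(self) -> float:
        if self.n_seizures == 0:
            return 0.0
        return (self._lead_s
                + (self.n_seizures - 1) * MIN_SEIZURE_SPACING_H * 3600.0
                + 600.0)


# ---------------------------------------------------------------------------

def _place_onsets(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Random onsets with >= 4.5 h spacing via the order-statistics trick."""
    n = cfg.n_seizures
    if n == 0:
        return np.empty(0)
    gap = MIN_SEIZURE_SPACING_H * 3600.0
    lo = cfg._lead_s
    hi = cfg.duration_s - 600.0
    slack = (hi - lo) - (n - 1) * gap
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + u + gap * np.arange(n)


def _noise(cfg: SynthConfig, n_samples: int, rng: np.random.Generator):
    """(n_channels, n_samples) background noise at noise_rms_uv RMS."""
    from scipy import fft as sfft

    # pink noise is synthesised in power-of-two FFT blocks (fast transforms,
    # bounded memory); block length 2^20 at 256 Hz resolves the spectrum
    # down to ~2.4e-4 Hz, far below the 0.5 Hz analysis high-pass
    block = min(1 << 20, sfft.next_fast_len(n_samples))
    f = sfft.rfftfreq(block, d=1.0 / cfg.fs)
    scale = np.zeros_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    # float32 storage: one float64 block in flight at a time
    out = np.empty((len(cfg.channels), n_samples), dtype=np.float32)
    for c in range(len(cfg.channels)):
        pos = 0
        acc = np.empty(n_samples)
        while pos < n_samples:
            w = rng.standard_normal(block)
            if cfg.noise_model == "pink":
                w = sfft.irfft(sfft.rfft(w) * scale, n=block)
            take = min(block, n_samples - pos)
            acc[pos: pos + take] = w[:take]
            pos += take
        acc *= cfg.noise_rms_uv / np.sqrt(np.mean(acc**2))
        out[c] = acc
    return out


def _drift_profile(shape: str, frac: np.ndarray) -> np.ndarray:
    """Drift strength in [0, 1] as a function of position in the window."""
    if shape == "step":
        return np.ones_like(frac)
    if shape == "linear-ramp":
        return frac
    return (np.expm1(3.0 * frac)) / np.expm1(3.0)  # exponential


def _feature_on_windows(x: np.ndarray, feature: str) -> np.ndarray:
    n_win = x.size // WINDOW_SAMPLES
    W = x[: n_win * WINDOW_SAMPLES].reshape(n_win, WINDOW_SAMPLES)
    vals, _ = _window_features(W)
    return vals[:, FEATURE_INDEX[feature]]


def _calibrate_sinusoid(baseline: np.ndarray, feature: str,
                        target: float, fs: float) -> float:
    """Bisection: amplitude of a band-centre sinusoid whose addition moves the
    mean of ``feature`` on the baseline windows to ``target``."""
    fc = BAND_CENTRES[feature]
    n = baseline.size
    t = np.arange(n) / fs
    tone = np.sin(2 * np.pi * fc * t)

    def mean_feat(a: float) -> float:
        return float(np.mean(_feature_on_windows(baseline + a * tone, feature)))

    lo, hi = 0.0, float(4.0 * np.sqrt(np.mean(baseline**2)))
    while mean_feat(hi) < target:
        hi *= 2.0
        if hi > 1e6:
            raise InvalidConfigError("cannot calibrate band-power drift")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if mean_feat(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_recording(config: SynthConfig) -> Recording:
    """Generate a synthetic Recording per ``config``.

    In the ``planted_preictal_min`` minutes before each onset, the planted
    feature (on 5-s windows of the planted electrodes) drifts by
    ``drift_magnitude`` baseline SDs following ``drift_shape``; elsewhere the
    signal is stationary noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration_s * cfg.fs))
    onsets = _place_onsets(cfg, rng)
    data = _noise(cfg, n_samples, rng)

    if cfg.drift_magnitude > 0 and cfg.n_seizures > 0:
        pre_s = cfg.planted_preictal_min * 60.0
        for lbl in cfg.planted_electrodes:
            ci = cfg.channels.index(lbl)
            x = data[ci]
            # baseline statistics from the guaranteed-clean first hour
            n_base = min(int(3600 * cfg.fs), x.size)
            base = x[:n_base]
            feats = _feature_on_windows(base, cfg.planted_feature)
            mu, sd = float(np.mean(feats)), float(np.std(feats))
            target = mu + cfg.drift_magnitude * sd

            if cfg.planted_feature.startswith("rel_power_"):
                target = min(target, 0.999)
                amp = _calibrate_sinusoid(base, cfg.planted_feature,
                                          target, cfg.fs)
            for onset in onsets:
                i0 = int(round((onset - pre_s) * cfg.fs))
                i1 = int(round(onset * cfg.fs))
                idx = np.arange(i0, i1)
                frac = (idx - i0) / max(i1 - i0, 1)
                s = _drift_profile(cfg.drift_shape, frac)
                if cfg.planted_feature == "variance":
                    gain = np.sqrt(1.0 + (target - mu) / mu * s)
                    x[i0:i1] *= gain
                elif cfg.planted_feature == "mean":
                    x[i0:i1] += (target - mu) * s
                else:  # relative band power: band-centre sinusoid
                    fc = BAND_CENTRES[cfg.planted_feature]
                    t = idx / cfg.fs
                    x[i0:i1] += amp * s * np.sin(2 * np.pi * fc * t)

    return Recording(
        channels=list(cfg.channels),
        fs=cfg.fs,
        samples=data,
        onsets=onsets,
    )
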