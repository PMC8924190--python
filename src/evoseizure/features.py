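"""Pre-processing and first-level feature extraction.

Signals are brought to 256 Hz, notch- and high-pass-filtered, cut into
non-overlapping 5-second windows (1280 samples), and 24 linear univariate
features are computed per electrode per window:

====================  =====================================================
time domain           mean, variance, skewness, kurtosis (population
                      moments); Hjorth mobility and complexity (Hjorth
                      activity is the variance and shares its feature id)
relative band power   delta 0.5-4, theta 4-8, alpha 8-12, beta 13-30,
                      low-gamma 30-79, high-gamma 79-128 Hz, each divided
                      by the sum of the six band powers
spectral edge         SEF50, SEF75, SEF90 over 0.5-128 Hz
wavelet energy        db4, 8 levels: D1 ... D8, A8 sub-band energies
====================  =====================================================

Spectral quantities use a Hann-tapered one-sided periodogram.  The wavelet
transform uses periodization boundaries so that the decomposition is
orthogonal and sub-band energies sum to the window energy.

Windows with zero variance are flagged degenerate: higher moments, Hjorth
ratios and SEF are set to 0 and band-power fractions to 1/6.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .io import Recording

TARGET_FS = 256
WINDOW_S = 5
WINDOW_SAMPLES = TARGET_FS * WINDOW_S  # 1280

BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "low_gamma": (30.0, 79.0),
    "high_gamma": (79.0, 128.0),
}
SEF_PCTS = (50, 75, 90)
WAVELET_SUBBANDS = tuple(f"d{i}" for i in range(1, 9)) + ("a8",)

#: Canonical ordering of the 24 first-level feature identifiers.
FEATURE_IDS: tuple[str, ...] = (
    "mean", "variance", "skewness", "kurtosis",
    "hjorth_mobility", "hjorth_complexity",
    *(f"rel_power_{b}" for b in BANDS),
    *(f"sef{p}" for p in SEF_PCTS),
    *(f"wavelet_{s}" for s in WAVELET_SUBBANDS),
)
FEATURE_INDEX = {f: i for i, f in enumerate(FEATURE_IDS)}


class UnsupportedRateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pre-processing

def preprocess(raw_signal: np.ndarray, fs: float) -> np.ndarray:
    """Downsample to 256 Hz and apply zero-phase 50 Hz notch (4th order) and
    0.5 Hz Butterworth high-pass (4th order) filters.

    Accepts 1-D ``(n,)`` or 2-D ``(n_channels, n)`` input; filtering acts on
    the last axis.  Rates below 256 Hz are refused.
    """
    if fs < TARGET_FS:
        raise UnsupportedRateError(f"sampling rate {fs} Hz < {TARGET_FS} Hz")
    x = np.asarray(raw_signal, dtype=np.float64)
    if fs != TARGET_FS:
        frac = Fraction(TARGET_FS) / Fraction(fs).limit_denominator(100000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    sos_notch = sps.butter(2, [49.0, 51.0], btype="bandstop", fs=TARGET_FS,
                           output="sos")
    sos_hp = sps.butter(4, 0.5, btype="highpass", fs=TARGET_FS, output="sos")
    # cascade both filters into one zero-phase pass
    return sps.sosfiltfilt(np.vstack([sos_notch, sos_hp]), x, axis=-1)


# ---------------------------------------------------------------------------
# vectorised core: W is (n_windows, WINDOW_SAMPLES)

def _moments_block(W):
    mean = W.mean(axis=1)
    var = W.var(axis=1)
    degenerate = var <= 0.0
    sd = np.where(degenerate, 1.0, np.sqrt(var))
    c = W - mean[:, None]
    skew = np.where(degenerate, 0.0, (c**3).mean(axis=1) / sd**3)
    kurt = np.where(degenerate, 0.0, (c**4).mean(axis=1) / sd**4)
    return mean, var, skew, kurt, degenerate


def _hjorth_block(W):
    var = W.var(axis=1)
    d1 = np.diff(W, axis=1)
    d2 = np.diff(d1, axis=1)
    v1 = d1.var(axis=1)
    v2 = d2.var(axis=1)
    bad = var <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mobility = np.where(bad, 0.0, np.sqrt(np.divide(v1, var,
                            out=np.zeros_like(var), where=~bad)))
        mob1 = np.sqrt(np.divide(v2, v1, out=np.zeros_like(v1), where=v1 > 0))
        complexity = np.divide(mob1, mobility,
                               out=np.zeros_like(mobility),
                               where=(mobility > 0) & ~bad)
    return mobility, complexity


def _periodogram_block(W):
    f, P = sps.periodogram(W, fs=TARGET_FS, window="hann", detrend=False,
                           axis=-1)
    return f, P


def _band_powers(f, P):
    """Absolute power per band, shape (n_windows, 6), band order as BANDS."""
    out = np.empty((P.shape[0], len(BANDS)))
    items = list(BANDS.items())
    for j, (_, (lo, hi)) in enumerate(items):
        if j == len(items) - 1:
            mask = (f >= lo) & (f <= hi)
        else:
            mask = (f >= lo) & (f < hi)
        out[:, j] = P[:, mask].sum(axis=1)
    return out


def _relative_band_powers_block(f, P):
    bp = _band_powers(f, P)
    tot = bp.sum(axis=1)
    degenerate = tot <= 0.0
    rel = np.where(degenerate[:, None], 1.0 / len(BANDS),
                   bp / np.where(degenerate, 1.0, tot)[:, None])
    return rel, degenerate


def _sef_block(f, P, pcts=SEF_PCTS):
    mask = (f >= 0.5) & (f <= 128.0)
    fm = f[mask]
    Pm = P[:, mask]
    cum = np.cumsum(Pm, axis=1)
    tot = cum[:, -1]
    degenerate = tot <= 0.0
    safe_tot = np.where(degenerate, 1.0, tot)
    out = np.zeros((P.shape[0], len(pcts)))
    for j, pct in enumerate(pcts):
        target = (pct / 100.0) * safe_tot
        # relative epsilon absorbs round-off when the target falls exactly
        # on a bin boundary
        k = np.argmax(cum >= target[:, None] * (1.0 - 1e-9), axis=1)
        prev_cum = np.where(k > 0, np.take_along_axis(
            cum, np.maximum(k - 1, 0)[:, None], axis=1)[:, 0], 0.0)
        prev_f = np.where(k > 0, fm[np.maximum(k - 1, 0)], fm[0])
        cur_cum = np.take_along_axis(cum, k[:, None], axis=1)[:, 0]
        cur_f = fm[k]
        dc = cur_cum - prev_cum
        frac = np.divide(target - prev_cum, dc,
                         out=np.ones_like(dc), where=dc > 0)
        out[:, j] = np.where(degenerate, 0.0,
                             prev_f + frac * (cur_f - prev_f))
    return out


def _wavelet_energies_block(W):
    """Sub-band energies in order D1..D8, A8 (periodization -> orthogonal)."""
    # pywt warns that 8 levels exceed dwt_max_level's boundary-effect
    # heuristic; with periodization and 1280 = 2^8 x 5 samples the transform
    # is exact and orthogonal, so the warning is moot.
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(W, "db4", mode="periodization", level=8, axis=-1)
    a8, details = coeffs[0], coeffs[1:]  # details: D8 ... D1
    energies = [np.sum(d**2, axis=-1) for d in reversed(details)]  # D1..D8
    energies.append(np.sum(a8**2, axis=-1))
    return np.stack(energies, axis=1)


def _window_features(W):
    """All 24 features for a block of windows -> (values, degenerate)."""
    W = np.asarray(W, dtype=np.float64)
    mean, var, skew, kurt, degenerate = _moments_block(W)
    mobility, complexity = _hjorth_block(W)
    f, P = _periodogram_block(W)
    rel, deg_spec = _relative_band_powers_block(f, P)
    sef = _sef_block(f, P)
    sef[deg_spec] = 0.0
    wav = _wavelet_energies_block(W)
    values = np.column_stack([
        mean, var, skew, kurt, mobility, complexity, rel, sef, wav,
    ])
    return values, degenerate | deg_spec


# ---------------------------------------------------------------------------
# scalar API (single 5-s window)

def statistical_moments(window):
    """(mean, variance, skewness, kurtosis) as population moments.

    Zero-variance windows return skewness = kurtosis = 0 (degenerate).
    """
    m, v, s, k, _ = _moments_block(np.atleast_2d(window))
    return float(m[0]), float(v[0]), float(s[0]), float(k[0])


def hjorth_parameters(window):
    """(activity, mobility, complexity); activity is the signal variance."""
    W = np.atleast_2d(window)
    mob, comp = _hjorth_block(W)
    return float(W.var(axis=1)[0]), float(mob[0]), float(comp[0])


def relative_band_powers(window):
    """Six band-power fractions (delta..high-gamma) summing to 1."""
    f, P = _periodogram_block(np.atleast_2d(window))
    rel, _ = _relative_band_powers_block(f, P)
    return rel[0]


def spectral_edge_frequency(window, pct):
    """Frequency (Hz) below which ``pct`` % of 0.5-128 Hz power lies."""
    if pct not in SEF_PCTS:
        raise ValueError(f"pct must be one of {SEF_PCTS}")
    f, P = _periodogram_block(np.atleast_2d(window))
    return float(_sef_block(f, P, pcts=(pct,))[0, 0])


def wavelet_band_energies(window):
    """Nine db4 sub-band energies in order D1..D8, A8."""
    return _wavelet_energies_block(np.atleast_2d(window))[0]


# ---------------------------------------------------------------------------
# tensor

@dataclass
class FeatureTensor:
    """Per-electrode, per-5-s-window matrix of the 24 first-level features.

    ``values`` has shape ``(n_windows, n_electrodes, 24)``; ``times`` are
    window-start seconds on the recording timeline (5-s grid);
    ``degenerate`` flags zero-variance windows.
    """

    times: np.ndarray
    electrodes: list[str]
    values: np.ndarray
    degenerate: np.ndarray
    feature_ids: tuple[str, ...] = FEATURE_IDS

    @property
    def start_s(self) -> float:
        return float(self.times[0]) if self.times.size else 0.0

    def electrode_index(self, label: str) -> int:
        try:
            return self.electrodes.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in tensor") from None

    def feature_series(self, electrode: str, feature_id: str) -> np.ndarray:
        """1-D series of one feature on one electrode over the 5-s grid."""
        return self.values[:, self.electrode_index(electrode),
                           FEATURE_INDEX[feature_id]]

    def crop(self, start_s: float, end_s: float) -> "FeatureTensor":
        """Windows whose start time lies in [start_s, end_s)."""
        m = (self.times >= start_s) & (self.times < end_s)
        return FeatureTensor(self.times[m], self.electrodes,
                             self.values[m], self.degenerate[m],
                             self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per window x electrode."""
        n_w, n_e, _ = self.values.shape
        df = pd.DataFrame(
            self.values.reshape(n_w * n_e, -1), columns=list(self.feature_ids)
        )
        df.insert(0, "electrode", np.tile(self.electrodes, n_w))
        df.insert(0, "time_s", np.repeat(self.times, n_e))
        df["degenerate"] = self.degenerate.reshape(-1)
        return df


def build_feature_tensor(recording: Recording, preprocessed: bool = False,
                         start_s: float = 0.0) -> FeatureTensor:
    """Extract the 24 features per electrode per 5-s window of a recording.

    ``preprocessed=False`` runs :func:`preprocess` first (requires
    ``fs >= 256``); ``start_s`` sets the timeline origin of the first window.
    """
    if preprocessed and recording.fs != TARGET_FS:
        raise UnsupportedRateError("preprocessed recordings must be 256 Hz")
    n_ch = len(recording.channels)
    # channels are processed one at a time to bound peak memory on
    # multi-hour recordings
    n_win = None
    values = degenerate = None
    for c in range(n_ch):
        x = (np.asarray(recording.samples[c], dtype=np.float64)
             if preprocessed
             else preprocess(recording.samples[c], recording.fs))
        if n_win is None:
            n_win = x.size // WINDOW_SAMPLES
            values = np.empty((n_win, n_ch, len(FEATURE_IDS)))
            degenerate = np.empty((n_win, n_ch), dtype=bool)
        W = x[: n_win * WINDOW_SAMPLES].reshape(n_win, WINDOW_SAMPLES)
        values[:, c, :], degenerate[:, c] = _window_features(W)
    times = start_s + WINDOW_S * np.arange(n_win, dtype=float)
    return FeatureTensor(times, list(recording.channels), values, degenerate)
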