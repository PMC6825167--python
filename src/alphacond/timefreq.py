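"""Taper, Morlet wavelet power, baseline normalization, band summaries.

Power is computed by convolving each trial and channel with complex
Morlet wavelets of constant time–frequency ratio ``m_w = f/σ_f`` (default
12), so the spectral SD grows with frequency.  Single-trial power is
averaged within condition and then rescaled to percent change from the
pre-stimulus baseline:  ``100 · (P / P_baseline − 1)``.

Wavelets are truncated at ``support_sigmas`` temporal SDs (default 3.5)
and normalized to unit energy, which makes the expected output power of
white noise identical across frequencies.  Samples closer than one σ_t
to the epoch edge are flagged in ``TFPower.edge_invalid``; summaries that
touch flagged samples emit a warning (the default baseline window sits
within one σ_t of the epoch start at the low end of the alpha band, so a
hard error would be unusable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len

from .epochs import EpochArray
from .montage import ROI_CHANNELS

ALPHA_BAND_HZ = (8.1, 11.9)
ANALYSIS_WINDOW_MS = (500.0, 1200.0)

#: condition label -> (contingency, extinction) factor levels
CONDITION_FACTORS = {
    "CS+E": ("CS+", "E"), "CS+N": ("CS+", "N"),
    "CS-E": ("CS-", "E"), "CS-N": ("CS-", "N"),
}


@dataclass(frozen=True)
class WaveletBank:
    """Linearly spaced Morlet wavelet family.

    ``m_w = f/σ_f`` is the ratio of centre frequency to spectral SD; the
    temporal SD is ``σ_t = 1/(2π σ_f)``.
    """

    freqs: np.ndarray = field(repr=False)
    m_w: float = 12.0
    srate: float = 500.0
    support_sigmas: float = 3.5

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if np.any(f <= 0):
            raise ValueError("all wavelet frequencies must be positive")
        if self.m_w <= 5:
            raise ValueError("Morlet parameter m_w must exceed 5 (admissibility)")
        if len(f) > 1 and not np.allclose(np.diff(f), f[1] - f[0], atol=1e-9):
            raise ValueError("frequency grid must be uniformly spaced")

    @property
    def step(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if len(self.freqs) > 1 else 0.0

    def sigma_t(self, f: float) -> float:
        """Temporal SD (s) of the wavelet at centre frequency f."""
        return self.m_w / (2 * np.pi * f)

    def wavelet(self, f: float) -> np.ndarray:
        """Unit-energy complex Morlet wavelet at centre frequency f."""
        st = self.sigma_t(f)
        half = int(np.ceil(self.support_sigmas * st * self.srate))
        t = np.arange(-half, half + 1) / self.srate
        w = np.exp(-(t**2) / (2 * st**2)) * np.exp(2j * np.pi * f * t)
        return w / np.sqrt(np.sum(np.abs(w) ** 2))

    def subset(self, band_hz: tuple[float, float]) -> "WaveletBank":
        """Bank restricted to grid bins inside ``band_hz`` (half-step slack)."""
        idx = band_indices(self.freqs, band_hz, self.step)
        return WaveletBank(self.freqs[idx], self.m_w, self.srate,
                           self.support_sigmas)


def default_bank(srate: float = 500.0, support_sigmas: float = 3.5) -> WaveletBank:
    """3.8–30.4 Hz in 0.38 Hz steps, m_w = 12."""
    return WaveletBank(3.8 + 0.38 * np.arange(71), 12.0, srate, support_sigmas)


def spectral_ratio(bank: WaveletBank, f: float, n_fft: int = 1 << 16) -> float:
    """Measured centre-frequency-to-spectral-SD ratio of the wavelet at f.

    The amplitude spectrum of a Morlet wavelet is Gaussian, so its log
    is a parabola; fitting one over the region above 10% of the peak
    recovers the centre and SD exactly while ignoring the truncation
    sidelobes that corrupt raw spectral moments.
    """
    w = bank.wavelet(f)
    spec = np.abs(np.fft.fft(w, n_fft))
    fax = np.fft.fftfreq(n_fft, d=1.0 / bank.srate)
    sel = spec >= 0.1 * spec.max()
    a, b, _ = np.polyfit(fax[sel], np.log(spec[sel]), 2)
    sigma_f = np.sqrt(-1.0 / (2.0 * a))
    centre = -b / (2.0 * a)
    return float(centre / sigma_f)


def band_indices(freqs: np.ndarray, band_hz: tuple[float, float],
                 step: float) -> np.ndarray:
    """Grid bins inside the band, edges matched with half-step tolerance."""
    tol = step / 2 + 1e-9
    lo, hi = band_hz
    idx = np.where((freqs >= lo - tol) & (freqs <= hi + tol))[0]
    if idx.size == 0:
        raise ValueError(f"band {band_hz} Hz selects no frequency bins")
    return idx


@dataclass
class TFPower:
    """Time–frequency power: (freqs, time, channels[, trials]).

    ``normalized`` marks percent-change units; ``baseline_power`` stores
    the divisor so normalization is invertible.
    """

    power: np.ndarray = field(repr=False)
    freqs: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    ch_names: tuple[str, ...]
    srate: float
    normalized: bool = False
    baseline_window_ms: tuple[float, float] | None = None
    baseline_power: np.ndarray | None = field(default=None, repr=False)
    edge_invalid: np.ndarray | None = field(default=None, repr=False)

    def time_indices(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        idx = np.where((self.times >= lo - 1e-9) & (self.times <= hi + 1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"window {window_ms} ms selects no samples")
        return idx

    def _warn_if_edge(self, idx: np.ndarray, what: str) -> None:
        if self.edge_invalid is not None and np.any(self.edge_invalid[:, idx]):
            warnings.warn(
                f"{what} touches convolution-edge samples (within one wavelet "
                "sigma_t of the epoch boundary)", RuntimeWarning, stacklevel=3,
            )


def _conv_power(data: np.ndarray, bank: WaveletBank) -> tuple[np.ndarray, np.ndarray]:
    """Morlet power of (rows, n_time) data; returns (n_freq, rows, n_time)
    power and an (n_freq, n_time) edge-invalid mask."""
    rows, n_t = data.shape
    wavelets = [bank.wavelet(f) for f in bank.freqs]
    too_long = [f for f, w in zip(bank.freqs, wavelets) if len(w) > n_t]
    if too_long:
        need = max(len(bank.wavelet(f)) for f in too_long)
        raise ValueError(
            f"wavelet support exceeds epoch length at {too_long[0]:.3g} Hz "
            f"(and {len(too_long) - 1} more); epoch needs >= {need} samples "
            f"or a smaller support_sigmas"
        )
    L = next_fast_len(n_t + max(len(w) for w in wavelets) - 1)
    D = fft(data, n=L, axis=-1)
    power = np.empty((len(wavelets), rows, n_t))
    edge = np.zeros((len(wavelets), n_t), dtype=bool)
    for k, w in enumerate(wavelets):
        W = fft(w, n=L)
        y = ifft(D * W, axis=-1)
        start = (len(w) - 1) // 2  # 'same' alignment
        power[k] = np.abs(y[:, start:start + n_t]) ** 2
        guard = int(np.ceil(bank.sigma_t(bank.freqs[k]) * bank.srate))
        edge[k, :guard] = True
        edge[k, n_t - guard:] = True
    return power, edge


def taper_and_baseline(epochs: EpochArray,
                       baseline_ms: tuple[float, float] = (-600.0, -500.0),
                       rise_fall_samples: int = 20) -> EpochArray:
    """Subtract the pre-stimulus baseline mean and taper the epoch edges.

    Per trial and channel, the mean over ``baseline_ms`` (inclusive) is
    subtracted; the first and last ``rise_fall_samples`` samples are then
    multiplied by cosine-square ramps whose outermost sample is exactly 0.
    """
    bidx = epochs.time_indices(baseline_ms)
    data = epochs.data - epochs.data[:, bidx, :].mean(axis=1, keepdims=True)
    r = rise_fall_samples
    if r > 0:
        if 2 * r > epochs.n_times:
            raise ValueError("taper ramps longer than the epoch")
        ramp = np.sin(np.pi / 2 * np.arange(r) / r) ** 2
        data[:, :r, :] *= ramp[None, :, None]
        data[:, epochs.n_times - r:, :] *= ramp[::-1][None, :, None]
    return EpochArray(data, epochs.srate, epochs.times, epochs.ch_names,
                      epochs.trial_labels, epochs.subject_id)


def morlet_power(epochs: EpochArray, bank: WaveletBank,
                 channels=None) -> TFPower:
    """Single-trial Morlet power, (freqs, time, channels, trials)."""
    if not np.isclose(bank.srate, epochs.srate):
        raise ValueError("wavelet bank srate does not match epochs")
    ep = epochs.pick(channels) if channels is not None else epochs
    n_ch, n_t, n_tr = ep.data.shape
    rowdata = ep.data.transpose(2, 0, 1).reshape(n_ch * n_tr, n_t)
    p, edge = _conv_power(rowdata, bank)
    p = p.reshape(len(bank.freqs), n_tr, n_ch, n_t).transpose(0, 3, 2, 1)
    return TFPower(p, bank.freqs.copy(), ep.times.copy(), ep.ch_names,
                   ep.srate, edge_invalid=edge)


def condition_power(epochs: EpochArray, bank: WaveletBank,
                    channels=None) -> dict[str, TFPower]:
    """Trial-averaged power per condition, (freqs, time, channels)."""
    tf = morlet_power(epochs, bank, channels)
    labels = np.array(epochs.trial_labels)
    out = {}
    for cond in dict.fromkeys(epochs.trial_labels):
        avg = tf.power[:, :, :, labels == cond].mean(axis=3)
        out[cond] = TFPower(avg, tf.freqs.copy(), tf.times.copy(), tf.ch_names,
                            tf.srate, edge_invalid=tf.edge_invalid)
    return out


def baseline_normalize(tf: TFPower,
                       baseline_ms: tuple[float, float] = (-400.0, -200.0),
                       amplitude_domain: bool = False) -> TFPower:
    """Rescale power to percent change from the pre-stimulus baseline.

    Default divides power by the mean baseline *power*; with
    ``amplitude_domain=True`` the division happens on amplitude
    (sqrt-power) and the result is squared back, the literal
    "mean amplitude" reading.
    """
    if tf.normalized:
        raise ValueError("TFPower is already normalized")
    bidx = tf.time_indices(baseline_ms)
    tf._warn_if_edge(bidx, "baseline window")
    if amplitude_domain:
        amp = np.sqrt(tf.power)
        base = amp[:, bidx].mean(axis=1, keepdims=True)
        if np.any(base <= 0):
            raise ValueError("baseline amplitude is zero for some freq/channel")
        pct = 100.0 * ((amp / base) ** 2 - 1.0)
        base = base**2
    else:
        base = tf.power[:, bidx].mean(axis=1, keepdims=True)
        if np.any(base <= 0):
            raise ValueError("baseline power is zero for some freq/channel")
        pct = 100.0 * (tf.power / base - 1.0)
    return TFPower(pct, tf.freqs.copy(), tf.times.copy(), tf.ch_names, tf.srate,
                   normalized=True, baseline_window_ms=tuple(baseline_ms),
                   baseline_power=np.squeeze(base, axis=1),
                   edge_invalid=tf.edge_invalid)


def _band_roi_mean(tf: TFPower, band_hz, roi) -> np.ndarray:
    """Mean over band bins and ROI channels -> (time[, trials]) series."""
    if not tf.normalized:
        raise ValueError("summaries require baseline-normalized power")
    fidx = band_indices(tf.freqs, band_hz, tf.freqs[1] - tf.freqs[0]
                        if len(tf.freqs) > 1 else 1.0)
    missing = [ch for ch in roi if ch not in tf.ch_names]
    if missing:
        raise ValueError(f"ROI channels not present: {missing}")
    cidx = [tf.ch_names.index(ch) for ch in roi]
    return tf.power[np.ix_(fidx, range(tf.power.shape[1]), cidx)].mean(axis=(0, 2))


def alpha_summary(tf: TFPower, band_hz=ALPHA_BAND_HZ, roi=ROI_CHANNELS,
                  window_ms=ANALYSIS_WINDOW_MS) -> float:
    """Scalar mean percent change over band x ROI x analysis window."""
    series = _band_roi_mean(tf, band_hz, roi)
    tidx = tf.time_indices(window_ms)
    tf._warn_if_edge(tidx, "analysis window")
    return float(series[tidx].mean())


def timecourse_summary(tf_by_condition: dict[str, TFPower],
                       band_hz=ALPHA_BAND_HZ,
                       roi=ROI_CHANNELS) -> dict[str, np.ndarray]:
    """Per-contingency alpha time series (both E/N members averaged)."""
    groups: dict[str, list[np.ndarray]] = {"CS+": [], "CS-": []}
    for cond, tf in tf_by_condition.items():
        cont = CONDITION_FACTORS[cond][0]
        groups[cont].append(_band_roi_mean(tf, band_hz, roi))
    empty = [k for k, v in groups.items() if not v]
    if empty:
        raise ValueError(f"no conditions for contingency level(s) {empty}")
    return {k: np.mean(v, axis=0) for k, v in groups.items()}


def effect_table_rows(subject_id: str, tf_by_condition: dict[str, TFPower],
                      band_hz=ALPHA_BAND_HZ, roi=ROI_CHANNELS,
                      window_ms=ANALYSIS_WINDOW_MS) -> pd.DataFrame:
    """One EffectTable row per condition cell for one subject."""
    rows = []
    for cond, tf in tf_by_condition.items():
        cont, ext = CONDITION_FACTORS[cond]
        rows.append((subject_id, cont, ext,
                     alpha_summary(tf, band_hz, roi, window_ms)))
    return pd.DataFrame(rows, columns=["subject_id", "contingency",
                                       "extinction", "alpha_pct"])


def validate_effect_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the 4-cells-per-subject contract; returns the table."""
    required = {"subject_id", "contingency", "extinction", "alpha_pct"}
    if not required.issubset(table.columns):
        raise ValueError(f"effect table missing columns {required - set(table.columns)}")
    counts = table.groupby("subject_id").size()
    bad = counts[counts != 4]
    if len(bad):
        raise ValueError(f"subjects without exactly 4 cells: {list(bad.index)}")
    if not np.all(np.isfinite(table["alpha_pct"])):
        raise ValueError("non-finite alpha_pct values in effect table")
    return table
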