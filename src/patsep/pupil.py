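"""Pupillometric statistical-learning analysis: preprocessing and
inter-trial phase coherence (ITC) at the face-pair frequency.

A 1 Hz image stream of learned pairs has a 0.5 Hz pair frequency; pupil
entrainment at 0.5 Hz marks acquisition of the pair structure. The pipeline
interpolates blinks and MAD outliers, low-pass filters with a one-pass
zero-phase Kaiser-windowed sinc FIR (5 Hz cutoff, 2 Hz transition, -60 dB),
detrends per run and per block, subtracts a 2-s pre-block baseline, cuts
32-s pseudo-trials locked to pair onsets (30-s overlap by default), computes
DPSS-multitaper ITC at 0.0625 Hz spectral resolution, and normalizes the
pair-frequency ITC by its four flanking bins; normalized values above 1
indicate entrainment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .synthdata import PupilTrace


@dataclass
class CleanPupilTrace:
    samples: np.ndarray
    rate_hz: float
    interpolation_mask: np.ndarray        # True where samples were interpolated
    pair_onsets: np.ndarray
    block_bounds: list[tuple[float, float]]
    filter_spec: dict = field(default_factory=dict)
    baselines: dict = field(default_factory=dict)   # block index -> baseline value


def _interpolate_nan(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = x.copy()
    bad = ~np.isfinite(x)
    if bad.all():
        raise ValueError("trace has no finite samples")
    if bad.any():
        idx = np.arange(x.size)
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x, bad


def design_lowpass_fir(rate_hz: float, cutoff_hz: float = 5.0,
                       transition_hz: float = 2.0, atten_db: float = 60.0) -> np.ndarray:
    """Kaiser-windowed sinc low-pass FIR with the stated band edges
    (pass band up to cutoff - transition/2, stop band from cutoff + transition/2)."""
    numtaps, beta = signal.kaiserord(atten_db, transition_hz / (rate_hz / 2.0))
    numtaps |= 1  # odd length -> integer group delay, exact zero-phase one-pass
    return signal.firwin(numtaps, cutoff_hz, window=("kaiser", beta), fs=rate_hz)


def preprocess_pupil(
    trace: PupilTrace,
    mad_cutoff: float = 3.5,
    cutoff_hz: float = 5.0,
    transition_hz: float = 2.0,
    atten_db: float = 60.0,
) -> CleanPupilTrace:
    """Interpolate blinks and MAD outliers, low-pass filter (one-pass
    zero-phase FIR), detrend per run and per block, subtract the 2-s
    pre-block baseline."""
    x, blink_mask = _interpolate_nan(np.asarray(trace.samples, dtype=float))

    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        out = np.abs(x - med) / (1.4826 * mad) > mad_cutoff
        if out.any():
            x[out] = np.nan
            x, _ = _interpolate_nan(x)
    else:
        out = np.zeros_like(blink_mask)

    taps = design_lowpass_fir(trace.rate_hz, cutoff_hz, transition_hz, atten_db)
    if x.size <= taps.size:
        raise ValueError(f"trace shorter than the filter order ({taps.size} taps)")
    # one-pass zero-phase: symmetric FIR, group delay compensated exactly
    pad = taps.size // 2
    xp = np.pad(x, pad, mode="edge")
    x = signal.lfilter(taps, 1.0, xp)[2 * pad:]

    x = signal.detrend(x, type="linear")
    fs = trace.rate_hz
    baselines = {}
    for bi, (b0, b1) in enumerate(trace.block_bounds):
        i0, i1 = int(round(b0 * fs)), min(int(round(b1 * fs)), x.size)
        if i1 - i0 > 1:
            x[i0:i1] = signal.detrend(x[i0:i1], type="linear")
        j0 = max(0, i0 - int(round(2.0 * fs)))
        base = float(x[j0:i0].mean()) if i0 > j0 else 0.0
        baselines[bi] = base
        x[i0:i1] -= base

    return CleanPupilTrace(
        samples=x,
        rate_hz=fs,
        interpolation_mask=blink_mask | out,
        pair_onsets=np.asarray(trace.pair_onsets, dtype=float),
        block_bounds=list(trace.block_bounds),
        filter_spec={"cutoff_hz": cutoff_hz, "transition_hz": transition_hz,
                     "atten_db": atten_db, "numtaps": int(taps.size)},
        baselines=baselines,
    )


def make_pseudo_trials(
    clean: CleanPupilTrace,
    length_s: float = 32.0,
    overlap_s: float = 30.0,
    detrend: bool = False,
) -> np.ndarray:
    """Overlapping epochs locked to pair onsets.

    Epochs start at every pair onset on the step grid implied by
    length - overlap and must fit entirely inside the trace; when block bounds
    are known, an epoch must also lie entirely inside one block (epochs that
    straddle a silent gap would carry block-edge transients that are
    artifactually phase-locked on the pair-onset grid). Each epoch is
    baseline-corrected by its block's 2-s pre-block baseline (already applied
    during preprocessing). Returns (n_epochs, n_samples).
    """
    if length_s <= overlap_s:
        raise ValueError("epoch length must exceed the overlap")
    fs = clean.rate_hz
    n_samp = int(round(length_s * fs))
    step = length_s - overlap_s
    onsets = np.sort(clean.pair_onsets)
    if onsets.size == 0:
        raise ValueError("no pair onsets")
    bounds = clean.block_bounds or None
    epochs = []
    last_start = -np.inf
    for on in onsets:
        if on - last_start < step - 1e-9:
            continue
        i0 = int(round(on * fs))
        if i0 + n_samp > clean.samples.size:
            continue
        if bounds is not None and not any(
                b0 - 1e-9 <= on and on + length_s <= b1 + 1e-9 for b0, b1 in bounds):
            continue
        seg = clean.samples[i0:i0 + n_samp].copy()
        if detrend:
            seg = signal.detrend(seg, type="linear")
        epochs.append(seg)
        last_start = on
    if not epochs:
        raise ValueError("no complete pseudo-trial fits in the trace")
    return np.array(epochs)


@dataclass
class ITCSpectrum:
    frequencies: np.ndarray
    itc: np.ndarray
    n_pseudo_trials: int
    resolution_hz: float
    normalized_pair_itc: float | None = None


def multitaper_itc(epochs: np.ndarray, rate_hz: float,
                   resolution_hz: float = 0.0625, fmax_hz: float = 5.0) -> ITCSpectrum:
    """DPSS-multitaper inter-trial phase coherence on the pupil band.

    Per taper, every epoch's spectrum is normalized to unit modulus; ITC(f)
    is the modulus of the across-epoch mean, averaged over tapers. The taper
    count follows the time-bandwidth product NW = T * resolution/2:
    K = max(1, floor(2 NW - 1)). The spectrum is returned up to ``fmax_hz``
    (default: the 5 Hz low-pass edge -- pupil dynamics carry no signal above
    it); pass None for the full range.
    """
    E = np.asarray(epochs, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2:
        raise ValueError("need at least 2 epochs")
    n_ep, n_samp = E.shape
    T = n_samp / rate_hz
    nw = max(T * resolution_hz / 2.0, 0.5 + 1e-9)
    K = max(1, int(np.floor(2 * nw - 1)))
    tapers = signal.windows.dpss(n_samp, nw, Kmax=K, sym=False)
    if K == 1:
        tapers = tapers[np.newaxis, :] if tapers.ndim == 1 else tapers
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / rate_hz)
    itc_per_taper = np.empty((K, freqs.size))
    for k in range(K):
        spec = np.fft.rfft(E * tapers[k], axis=1)
        mag = np.abs(spec)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(mag > 0, spec / mag, 0.0)
        itc_per_taper[k] = np.abs(unit.mean(axis=0))
    itc = itc_per_taper.mean(axis=0)
    if fmax_hz is not None:
        keep = freqs <= fmax_hz + 1e-12
        freqs, itc = freqs[keep], itc[keep]
    return ITCSpectrum(frequencies=freqs, itc=np.clip(itc, 0.0, 1.0),
                       n_pseudo_trials=n_ep, resolution_hz=resolution_hz)


def normalize_itc(spectrum: ITCSpectrum, target_freq: float = 0.5,
                  n_neighbors: int = 2) -> float:
    """ITC at the target bin divided by the mean of its 2n flanking bins
    (n above, n below); values above 1 indicate entrainment."""
    f = spectrum.frequencies
    i = int(np.argmin(np.abs(f - target_freq)))
    if i - n_neighbors < 0 or i + n_neighbors >= f.size:
        raise ValueError("target frequency too close to the spectrum edge")
    neigh = np.r_[spectrum.itc[i - n_neighbors:i], spectrum.itc[i + 1:i + 1 + n_neighbors]]
    denom = neigh.mean()
    if denom == 0:
        raise ValueError("flat zero spectrum around the target")
    value = float(spectrum.itc[i] / denom)
    spectrum.normalized_pair_itc = value
    return value


def normalized_itc_profile(spectrum: ITCSpectrum, n_neighbors: int = 2):
    """Normalized ITC at every interior bin. Returns (frequencies, values)."""
    f, itc = spectrum.frequencies, spectrum.itc
    lo, hi = n_neighbors, f.size - n_neighbors
    vals = np.empty(hi - lo)
    for j, i in enumerate(range(lo, hi)):
        neigh = np.r_[itc[i - n_neighbors:i], itc[i + 1:i + 1 + n_neighbors]]
        m = neigh.mean()
        vals[j] = itc[i] / m if m > 0 else np.nan
    return f[lo:hi], vals


def itc_significance(normalized_values) -> tuple[float, float]:
    """One-sample t test (one-sided) of normalized ITC values against 1."""
    v = np.asarray(normalized_values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.allclose(v, v[0]):
        raise ValueError("zero variance: t test degenerate")
    res = stats.ttest_1samp(v, 1.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def entrainment_phase_contrast(early, late) -> tuple[float, float]:
    """Unpaired one-sided t test: ITC higher in the late training phase."""
    e = np.asarray(early, dtype=float)
    l = np.asarray(late, dtype=float)
    if min(e.size, l.size) < 3:
        raise ValueError("need at least 3 values per phase")
    res = stats.ttest_ind(l, e, alternative="greater")
    return float(res.statistic), float(res.pvalue)
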