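"""Binaural white-noise stimulus generation.

The generative model is the one used in classic interaural-time-difference
(ITD) psychophysics: a common white-noise "signal" presented to both ears,
offset in the left ear by the ITD delta, plus independent external noise per
ear and independent internal (sensory) noise per ear::

    s_R(t) = sigma_S * s(t)         + sigma_N * eta_R(t) + sigma_0 * nu_R(t)
    s_L(t) = sigma_S * s(t - delta) + sigma_N * eta_L(t) + sigma_0 * nu_L(t)

All five processes are unit-variance Gaussian white noise. The experimenter's
knob is the binaural correlation BC = sigma_S^2 / (sigma_S^2 + sigma_N^2),
which excludes the internal noise by construction. Stimuli are sampled at
48 kHz and low-pass filtered at 8 kHz (zero-phase, circular), after which
both channels are rescaled so the per-sample variance remains
sigma_S^2 + sigma_N^2 + sigma_0^2.

The ITD shift is circular at integer-sample resolution: one sample at 48 kHz
is 1e6/48000 ~ 20.83 us, so the 25-point delay grid spanning [-250, 250] us
is exactly representable. Circular shifts commute with the circular
frequency-domain filtering, which keeps the covariance algebra of the ideal
observers exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 48_000
DEFAULT_CUTOFF_HZ = 8_000.0
DEFAULT_SIGMA_0 = 0.9
ITD_RANGE_US = 250.0

#: sample period in microseconds at the default rate
DT_US = 1e6 / DEFAULT_SAMPLE_RATE


def binaural_correlation(sigma_s: float, sigma_n: float) -> float:
    """Binaural correlation BC = sigma_S^2 / (sigma_S^2 + sigma_N^2).

    The internal noise sigma_0 is deliberately excluded: BC quantifies the
    externally controlled information content of the stimulus.
    """
    if sigma_s < 0 or sigma_n < 0:
        raise ValueError("amplitudes must be non-negative")
    denom = sigma_s**2 + sigma_n**2
    if denom == 0:
        raise ValueError("BC undefined for sigma_S = sigma_N = 0")
    return sigma_s**2 / denom


def sigmas_from_bc(bc: float) -> tuple[float, float]:
    """Invert BC under the unit-power convention sigma_S^2 + sigma_N^2 = 1."""
    if not 0.0 <= bc <= 1.0:
        raise ValueError("BC must lie in [0, 1]")
    return float(np.sqrt(bc)), float(np.sqrt(1.0 - bc))


@dataclass(frozen=True)
class StimulusParams:
    """Generative parameters of a binaural stimulus.

    Parameters
    ----------
    sigma_s, sigma_n : float
        Signal and external-noise amplitudes. The standard convention keeps
        sigma_s**2 + sigma_n**2 == 1 so that BC == sigma_s**2.
    sigma_0 : float
        Internal-noise amplitude (default 0.9).
    delta_us : float
        True ITD in microseconds; must be an integer number of samples
        within +/-250 us (one sample ~ 20.83 us at 48 kHz).
    duration : float
        Stimulus duration in seconds; duration * sample_rate must be an
        integer number of samples.
    lowpass_cutoff : float or None
        High-frequency cutoff in Hz (default 8 kHz); ``None`` disables
        filtering (useful for exact small-T oracles).
    """

    sigma_s: float
    sigma_n: float
    sigma_0: float = DEFAULT_SIGMA_0
    delta_us: float = 0.0
    duration: float = 0.001
    sample_rate: int = DEFAULT_SAMPLE_RATE
    lowpass_cutoff: float | None = DEFAULT_CUTOFF_HZ
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.sigma_s, self.sigma_n, self.sigma_0) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if abs(self.delta_us) > ITD_RANGE_US:
            raise ValueError(
                f"delta_us={self.delta_us} outside the representable "
                f"[-{ITD_RANGE_US}, {ITD_RANGE_US}] us range"
            )
        n = self.duration * self.sample_rate
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration * sample_rate = {n} is not a positive integer"
            )
        if self.lowpass_cutoff is not None and not (
            0 < self.lowpass_cutoff <= self.sample_rate / 2
        ):
            raise ValueError("lowpass_cutoff must lie in (0, Nyquist]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def delta_samples(self) -> int:
        """Nearest integer sample offset for the ITD."""
        return int(round(self.delta_us * self.sample_rate / 1e6))

    @property
    def delta_residual_us(self) -> float:
        """Rounding residual between the requested and realized ITD."""
        return self.delta_us - self.delta_samples * 1e6 / self.sample_rate

    @property
    def bc(self) -> float:
        return binaural_correlation(self.sigma_s, self.sigma_n)

    @classmethod
    def from_bc(cls, bc: float, **kwargs) -> "StimulusParams":
        sigma_s, sigma_n = sigmas_from_bc(bc)
        return cls(sigma_s=sigma_s, sigma_n=sigma_n, **kwargs)


@dataclass(frozen=True)
class BinauralStimulus:
    """A single two-eared stimulus plus the parameters that produced it."""

    s_r: np.ndarray
    s_l: np.ndarray
    params: StimulusParams
    band: tuple[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.s_r.shape != self.s_l.shape or self.s_r.ndim != 1:
            raise ValueError("channels must be 1-D arrays of equal length")

    @property
    def n_samples(self) -> int:
        return self.s_r.shape[-1]


def _band_mask_and_gain(
    n: int, sample_rate: float, f_lo: float, f_hi: float
) -> tuple[np.ndarray, float]:
    """Brick-wall rfft mask for [f_lo, f_hi] plus the variance-restoring gain.

    The gain compensates for the power removed by the mask so that filtered
    unit-variance white noise keeps unit per-sample variance.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz keeps no frequency bins")
    # full-FFT bin multiplicities: DC and (for even n) Nyquist occur once
    weights = np.where((freqs == 0) | (2 * freqs == sample_rate), 1.0, 2.0)
    kept = float(np.sum(weights * mask))
    return mask.astype(float), float(np.sqrt(n / kept))


def bandlimit(
    x: np.ndarray, sample_rate: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Zero-phase circular band-limiting with variance restoration."""
    n = x.shape[-1]
    mask, gain = _band_mask_and_gain(n, sample_rate, f_lo, f_hi)
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * mask, n=n, axis=-1) * gain


def simulate_ears(
    params: StimulusParams,
    n_trials: int = 1,
    rng: np.random.Generator | None = None,
    band: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a batch of stimuli; returns (s_R, s_L), each (n_trials, T).

    ``band`` restricts the *external* stimulus (common signal + external
    noise) to [lo, hi] Hz by removing out-of-band content, leaving in-band
    amplitudes untouched; the internal noise keeps the full cochlear band
    (up to ``lowpass_cutoff``) regardless, since it arises downstream of
    the stimulus. Used for the frequency-content manipulations.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = params.n_samples
    d = params.delta_samples
    sig = rng.standard_normal((n_trials, t))
    eta_r, eta_l = rng.standard_normal((2, n_trials, t))
    nu_r, nu_l = rng.standard_normal((2, n_trials, t))
    ext_r = params.sigma_s * sig + params.sigma_n * eta_r
    # s_L(t) = sigma_S s(t - d): circular shift of the common signal
    ext_l = params.sigma_s * np.roll(sig, d, axis=-1) + params.sigma_n * eta_l
    int_r = params.sigma_0 * nu_r
    int_l = params.sigma_0 * nu_l
    if params.lowpass_cutoff is None and band is None:
        return ext_r + int_r, ext_l + int_l
    cutoff = (
        params.lowpass_cutoff
        if params.lowpass_cutoff is not None
        else params.sample_rate / 2
    )
    mask0, gain0 = _band_mask_and_gain(t, params.sample_rate, 0.0, cutoff)
    if band is None:
        ext_mask = mask0
    else:
        ext_mask, _ = _band_mask_and_gain(
            t, params.sample_rate, max(band[0], 0.0), min(band[1], cutoff)
        )
        ext_mask = ext_mask * mask0

    def _filt(x, mask):
        return np.fft.irfft(
            np.fft.rfft(x, axis=-1) * mask, n=t, axis=-1
        ) * gain0

    s_r = _filt(ext_r, ext_mask) + _filt(int_r, mask0)
    s_l = _filt(ext_l, ext_mask) + _filt(int_l, mask0)
    return s_r, s_l


def generate_stimulus(
    params: StimulusParams, band: tuple[float, float] | None = None
) -> BinauralStimulus:
    """Generate one stimulus (bit-reproducible given ``params.seed``)."""
    s_r, s_l = simulate_ears(params, n_trials=1, band=band)
    return BinauralStimulus(s_r[0], s_l[0], params, band=band)


def manipulate_stimulus(
    stim: BinauralStimulus, mode: str, param: float
) -> BinauralStimulus:
    """Apply one of the stimulus manipulations used to probe the OT model.

    mode='shorten'
        Truncate to ``param`` seconds.
    mode='lowpass' / 'highpass'
        Regenerate from the stored params and seed with every noise process
        limited to [0, param] / [param, original cutoff] Hz, so only the
        requested band carries the common component while within-band
        correlations are unchanged.
    """
    p = stim.params
    cutoff = p.lowpass_cutoff or p.sample_rate / 2
    if mode == "shorten":
        t_new = int(round(param * p.sample_rate))
        if not 0 < t_new <= stim.n_samples:
            raise ValueError("target duration must be in (0, duration]")
        new_params = replace(p, duration=t_new / p.sample_rate)
        return BinauralStimulus(
            stim.s_r[:t_new].copy(), stim.s_l[:t_new].copy(), new_params,
            band=stim.band,
        )
    if mode == "lowpass":
        if not 0 < param <= cutoff:
            raise ValueError("cutoff must lie in (0, lowpass_cutoff]")
        return generate_stimulus(p, band=(0.0, param))
    if mode == "highpass":
        if not 0 < param <= cutoff:
            raise ValueError("cutoff must lie in (0, lowpass_cutoff]")
        return generate_stimulus(p, band=(param, cutoff))
    raise ValueError(f"unknown manipulation mode {mode!r}")


def write_wav(stim: BinauralStimulus, path) -> None:
    """Export as a two-channel float32 WAV at the stimulus sample rate."""
    data = np.stack([stim.s_l, stim.s_r], axis=1).astype(np.float32)
    wavfile.write(path, stim.params.sample_rate, data)


def read_wav(path, params: StimulusParams) -> BinauralStimulus:
    """Import a two-channel WAV written by :func:`write_wav`."""
    rate, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("expected a two-channel WAV file")
    if rate != params.sample_rate:
        warnings.warn(
            f"WAV sample rate {rate} differs from params.sample_rate "
            f"{params.sample_rate}"
        )
    return BinauralStimulus(
        data[:, 1].astype(float), data[:, 0].astype(float), params
    )
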