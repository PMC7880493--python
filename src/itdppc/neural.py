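"""Population models of the owl's ITD pathway (IC and OT stages).

The inferior-colliculus (IC) stage is a cross-correlator bank: the ear
signals are decomposed by a self-invertible filterbank (four raised-cosine
bands, log-spaced centers 0.5-12 kHz), band pairs are multiplied at every
candidate delay, passed through a static nonlinearity per time sample and
summed over time. Self-invertibility means the squared transfer functions
tile to one below the cutoff, so (i) filtering twice and summing bands
reconstructs the signal and (ii) band-wise cross-covariances sum exactly to
the broadband cross-covariance — which makes the pre-rectification IC
population an exact linear probabilistic population code (lPPC) for the
known-BC observer.

The optic-tectum (OT) stage implements the marginalized observer: frequency
convergence (band-summed cross-covariance), divisive normalization by the
channel energy, the marginalization nonlinearity, then a smoothing with a
self-invertible quadrature filter pair along the delay axis and a final
half-rectification. Pre-rectification the OT population is an exact lPPC
for the marginalized observer, with readout weights that do not depend on
BC (an invariant lPPC).

A descriptive comparison model (per-band normalized cross-correlation,
fixed linear band weighting, no marginalization nonlinearity) is also
provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ideal_observer import LOG_FLOOR, DelayGrid, SufficientStats, \
    post_marg_loglik
from .stimulus import DEFAULT_SAMPLE_RATE, StimulusParams, simulate_ears

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# nonlinearities

def _half_rect(x: np.ndarray, **_) -> np.ndarray:
    return np.maximum(x, 0.0)


def _linear(x: np.ndarray, **_) -> np.ndarray:
    return x


def _sigmoid(x, threshold: float = 0.0, slope: float = 1.0) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(x - threshold) / slope))


def _exponential(x, gain: float = 1.0) -> np.ndarray:
    return np.exp(np.minimum(gain * x, 30.0))


NONLINEARITIES = {
    "half_rect": _half_rect,
    "linear": _linear,
    "sigmoid": _sigmoid,
    "exponential": _exponential,
}


# ---------------------------------------------------------------------------
# filterbank

@dataclass(frozen=True)
class FilterBank:
    """Self-invertible raised-cosine filterbank, frequency-domain form.

    ``response[n, j]`` is the (real, zero-phase) amplitude of band n at the
    j-th rfft frequency of a length-``n_samples`` signal; squared amplitudes
    sum to one at every frequency below ``cutoff``.
    """

    response: np.ndarray
    center_freqs: np.ndarray
    cutoff: float
    sample_rate: int
    n_samples: int

    @property
    def n_bands(self) -> int:
        return self.response.shape[0]

    @property
    def impulse_responses(self) -> np.ndarray:
        """Time-domain kernels, one per band (circular, zero-phase)."""
        return np.fft.irfft(self.response, n=self.n_samples, axis=-1)

    def apply(self, x: np.ndarray, band: int) -> np.ndarray:
        """Filter ``x`` (shape (..., n_samples)) through one band."""
        xf = np.fft.rfft(x, axis=-1)
        return np.fft.irfft(
            xf * self.response[band], n=self.n_samples, axis=-1
        )

    def apply_all(self, x: np.ndarray) -> np.ndarray:
        """Filter through every band; returns shape (n_bands, ..., T)."""
        xf = np.fft.rfft(x, axis=-1)
        resp = self.response.reshape(
            (self.n_bands,) + (1,) * (x.ndim - 1) + (-1,)
        )
        return np.fft.irfft(xf * resp, n=self.n_samples, axis=-1)


def build_filterbank(
    n_samples: int,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    n_bands: int = 4,
    f_lo: float = 500.0,
    f_hi: float = 12_000.0,
) -> FilterBank:
    """Raised-cosine power-complementary tiling on a log-frequency axis.

    Bands cross-fade between successive log-spaced center frequencies with
    cos/sin ramps, so squared responses sum to exactly one from DC up to the
    cutoff ``f_hi``; the lowest (highest) band is flat below (above) its
    center. The exact band shape is a free choice — the tiling identities
    are the contract.
    """
    if n_bands < 2:
        raise ValueError("need at least two bands")
    if f_lo >= f_hi:
        raise ValueError("f_lo must be below f_hi")
    centers = np.geomspace(f_lo, f_hi, n_bands)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    resp = np.zeros((n_bands, len(freqs)))
    log_c = np.log(centers)
    with np.errstate(divide="ignore"):
        log_f = np.where(freqs > 0, np.log(np.maximum(freqs, 1e-300)), -np.inf)
    resp[0, log_f <= log_c[0]] = 1.0
    resp[-1, (log_f >= log_c[-1]) & (freqs <= f_hi)] = 1.0
    for n in range(n_bands - 1):
        sel = (log_f > log_c[n]) & (log_f < log_c[n + 1])
        u = (log_f[sel] - log_c[n]) / (log_c[n + 1] - log_c[n])
        resp[n, sel] = np.cos(u * np.pi / 2)
        resp[n + 1, sel] = np.sin(u * np.pi / 2)
    return FilterBank(
        response=resp,
        center_freqs=centers,
        cutoff=f_hi,
        sample_rate=sample_rate,
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# population containers

@dataclass(frozen=True)
class PopulationResponse:
    """Rates of a model population, shape (..., n_units).

    ``preferred_delay`` (us) and ``band`` (frequency band for IC,
    sub-population index for OT) label the unit axis.
    """

    rates: np.ndarray
    preferred_delay: np.ndarray
    band: np.ndarray
    nonlinearity: str

    @property
    def n_units(self) -> int:
        return self.rates.shape[-1]


# ---------------------------------------------------------------------------
# IC model

def ic_response(
    s_r: np.ndarray,
    s_l: np.ndarray,
    bank: FilterBank,
    grid: DelayGrid,
    nonlinearity: str = "half_rect",
    nl_params: dict | None = None,
) -> PopulationResponse:
    """Cross-correlator IC population: one unit per (band, delay).

    For band n and preferred delay d the rate is
    ``sum_t g[(F_n * s_R)(t) * (F_n * P_d s_L)(t)]`` with g the chosen
    static nonlinearity applied per time sample. ``nonlinearity='linear'``
    gives the pre-rectification band-wise cross-covariances (an exact lPPC
    of the known-BC observer).
    """
    try:
        g = NONLINEARITIES[nonlinearity]
    except KeyError:
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}") from None
    nl_params = nl_params or {}
    s_r = np.atleast_2d(np.asarray(s_r, dtype=float))
    s_l = np.atleast_2d(np.asarray(s_l, dtype=float))
    delays = grid.delta_samples
    k = grid.n
    batch = s_r.shape[:-1]
    rates = np.empty(batch + (bank.n_bands * k,))
    band_r = bank.apply_all(s_r)
    band_l = bank.apply_all(s_l)
    for n in range(bank.n_bands):
        for j, d in enumerate(delays):
            # (F_n * P_d^T s_L)(t) = (F_n * s_L)(t + d): circular roll
            prod = band_r[n] * np.roll(band_l[n], -d, axis=-1)
            rates[..., n * k + j] = np.sum(g(prod, **nl_params), axis=-1)
    return PopulationResponse(
        rates=rates,
        preferred_delay=np.tile(grid.delta_us, bank.n_bands),
        band=np.repeat(np.arange(bank.n_bands), k),
        nonlinearity=nonlinearity,
    )


# ---------------------------------------------------------------------------
# OT model

def _quadrature_pair(n_points: int, ramp_exponent: float = 1.0) -> np.ndarray:
    """Real zero-phase transfer pair with |H1|^2 + |H2|^2 = 1 on the delay
    axis: H1 = cos(theta), H2 = sin(theta), theta a ramp from 0 at DC to
    pi/2 at the axis Nyquist. H1 is a ~2-grid-step smoother, H2 its
    power-complement."""
    n_rbins = n_points // 2 + 1
    u = np.linspace(0.0, 1.0, n_rbins) ** ramp_exponent
    theta = u * np.pi / 2
    return np.stack([np.cos(theta), np.sin(theta)])


@dataclass(frozen=True)
class OTConfig:
    """Smoothing/rectification configuration of the OT stage."""

    transfer: np.ndarray | None = None
    rectifier: str = "half_rect"
    split_point: str = "mean_average"
    lm_floor: float = field(default=LOG_FLOOR)

    def transfer_for(self, n_points: int) -> np.ndarray:
        if self.transfer is not None:
            if self.transfer.shape != (2, n_points // 2 + 1):
                raise ValueError("transfer pair has the wrong shape")
            return self.transfer
        return _quadrature_pair(n_points)


def smooth_along_delays(values: np.ndarray, transfer: np.ndarray) -> np.ndarray:
    """Circular zero-phase convolution of (..., K) values with each filter
    of the pair; returns shape (..., 2, K)."""
    k = values.shape[-1]
    vf = np.fft.rfft(values, axis=-1)
    out = np.fft.irfft(vf[..., np.newaxis, :] * transfer, n=k, axis=-1)
    return out


def ot_response(
    stats: SufficientStats,
    grid: DelayGrid | None = None,
    config: OTConfig | None = None,
) -> PopulationResponse:
    """OT population: marginalized log-likelihood, smoothed and rectified.

    ``r = rect( sum_d LM(d) H_i(d - d_n) )`` for the two self-invertible
    smoothing filters H_1, H_2; two sub-populations of K units each.
    """
    grid = grid or stats.grid
    config = config or OTConfig()
    lm = post_marg_loglik(
        stats.cc, stats.v, stats.t,
        split_point=config.split_point, log_floor=config.lm_floor,
    )
    transfer = config.transfer_for(grid.n)
    smoothed = smooth_along_delays(lm, transfer)
    g = NONLINEARITIES[config.rectifier]
    rates = g(smoothed).reshape(smoothed.shape[:-2] + (2 * grid.n,))
    return PopulationResponse(
        rates=rates,
        preferred_delay=np.tile(grid.delta_us, 2),
        band=np.repeat(np.arange(2), grid.n),
        nonlinearity=config.rectifier,
    )


# ---------------------------------------------------------------------------
# descriptive comparison model

def descriptive_model_response(
    s_r: np.ndarray,
    s_l: np.ndarray,
    bank: FilterBank,
    grid: DelayGrid,
    weights: np.ndarray | None = None,
) -> PopulationResponse:
    """Descriptive OT model: per-band normalized cross-correlation, fixed
    linear band weighting (uniform by default), final half-rectification.

    By design this model is sensitive only to the within-band correlations,
    not to stimulus duration or band occupancy.
    """
    s_r = np.atleast_2d(np.asarray(s_r, dtype=float))
    s_l = np.atleast_2d(np.asarray(s_l, dtype=float))
    if weights is None:
        weights = np.full(bank.n_bands, 1.0 / bank.n_bands)
    delays = grid.delta_samples
    band_r = bank.apply_all(s_r)
    band_l = bank.apply_all(s_l)
    out = np.zeros(s_r.shape[:-1] + (grid.n,))
    for n in range(bank.n_bands):
        v_band = 0.5 * (
            np.sum(band_r[n] ** 2, axis=-1) + np.sum(band_l[n] ** 2, axis=-1)
        )
        bad = v_band <= 1e-12
        if np.any(bad):
            logger.warning(
                "band %d has (near-)zero energy on %d trials; skipped",
                n, int(np.sum(bad)),
            )
        safe_v = np.where(bad, 1.0, v_band)
        for j, d in enumerate(delays):
            cc = np.sum(band_r[n] * np.roll(band_l[n], -d, axis=-1), axis=-1)
            corr = np.where(bad, 0.0, cc / safe_v)
            out[..., j] += weights[n] * corr
    return PopulationResponse(
        rates=np.maximum(out, 0.0),
        preferred_delay=grid.delta_us.copy(),
        band=np.zeros(grid.n, dtype=int),
        nonlinearity="half_rect",
    )


# ---------------------------------------------------------------------------
# tuning curves

def tuning_curve(
    model: str,
    bc: float,
    grid: DelayGrid,
    n_trials: int = 200,
    duration: float = 0.009,
    sigma_0: float = 0.9,
    seed: int = 0,
    nonlinearity: str = "half_rect",
    config: OTConfig | None = None,
    stim_band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Monte-Carlo mean rate of every unit as a function of the true ITD.

    Returns an array of shape (n_true_deltas, n_units) where the true ITDs
    run over the grid delays within the +/-250 us stimulus range;
    ``model`` is one of 'ic', 'ot', 'descriptive'.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    n_samples = int(round(duration * DEFAULT_SAMPLE_RATE))
    bank = build_filterbank(n_samples)
    true_deltas = grid.delta_us[np.abs(grid.delta_us) <= 250.0 + 1e-9]
    ss = np.random.SeedSequence(seed)
    curves = []
    for delta, child in zip(true_deltas, ss.spawn(len(true_deltas))):
        params = StimulusParams.from_bc(
            bc, sigma_0=sigma_0, delta_us=float(delta), duration=duration
        )
        rng = np.random.default_rng(child)
        s_r, s_l = simulate_ears(params, n_trials, rng=rng, band=stim_band)
        if model == "ic":
            resp = ic_response(s_r, s_l, bank, grid, nonlinearity)
        elif model == "ot":
            from .ideal_observer import sufficient_stats

            stats = sufficient_stats(s_r, s_l, grid)
            resp = ot_response(stats, grid, config)
        elif model == "descriptive":
            resp = descriptive_model_response(s_r, s_l, bank, grid)
        else:
            raise ValueError(f"unknown model {model!r}")
        curves.append(resp.rates.mean(axis=0))
    return np.asarray(curves)
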