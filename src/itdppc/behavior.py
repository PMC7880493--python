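"""Simulated head-turn behavior of the ideal observers.

On each trial the observer's ITD report is the MAP of its posterior; the
report is converted to a head-turn angle through the owl's ITD/azimuth
relation ``delta = A sin(omega * theta)`` (A = 260 us, omega = 0.0143 per
degree, the product omega*theta in radians). Summaries are the mean and
standard deviation of reported angles per (BC, true angle), which exhibit
the classic low-BC bias toward the front and variability decrease with BC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ideal_observer import (
    DelayGrid,
    Posterior,
    make_prior,
    post_marg_logpost,
    pre_marg_logpost,
    sufficient_stats,
)
from .stimulus import StimulusParams, simulate_ears


@dataclass(frozen=True)
class BehaviorParams:
    """ITD/azimuth mapping constants: delta = A sin(omega theta)."""

    a_us: float = 260.0
    omega_per_deg: float = 0.0143
    angle_precision_deg: float = 4.0


def itd_to_angle(
    delta_us: np.ndarray | float, p: BehaviorParams = BehaviorParams()
) -> np.ndarray | float:
    """Head-turn angle (degrees) for an ITD; |delta| beyond A is clipped."""
    delta = np.asarray(delta_us, dtype=float)
    if np.any(np.abs(delta) > p.a_us):
        warnings.warn("ITD beyond +/-A clipped to the representable range")
        delta = np.clip(delta, -p.a_us, p.a_us)
    theta = np.arcsin(delta / p.a_us) / p.omega_per_deg
    return float(theta) if np.isscalar(delta_us) else theta


def angle_to_itd(
    theta_deg: np.ndarray | float, p: BehaviorParams = BehaviorParams()
) -> np.ndarray | float:
    """Inverse mapping: delta = A sin(omega theta)."""
    delta = p.a_us * np.sin(p.omega_per_deg * np.asarray(theta_deg, float))
    return float(delta) if np.isscalar(theta_deg) else delta


def map_estimate(p: Posterior) -> np.ndarray:
    """MAP ITD estimate(s); ties broken toward the front (delta = 0)."""
    return p.map_estimate


def behavior_experiment(
    bcs,
    true_angles_deg,
    n_trials: int = 500,
    observer: str = "post",
    prior: str | DelayGrid = "box",
    duration: float = 0.001,
    sigma_0: float = 0.9,
    seed: int = 0,
    quantize: bool = False,
    behavior_params: BehaviorParams = BehaviorParams(),
) -> pd.DataFrame:
    """Mean and SD of head-turn responses per (BC, true angle).

    ``observer`` is 'post' (BC marginalized out) or 'pre' (BC known);
    ``prior`` a kind accepted by :func:`make_prior` or a ready grid;
    ``quantize`` rounds reported angles to the measurement precision.
    """
    grid = prior if isinstance(prior, DelayGrid) else make_prior(prior)
    ss = np.random.SeedSequence(seed)
    rows = []
    conditions = [(bc, ang) for bc in bcs for ang in true_angles_deg]
    for (bc, angle), child in zip(conditions, ss.spawn(len(conditions))):
        delta_true = angle_to_itd(angle, behavior_params)
        # snap the true ITD to the sample lattice
        dt_us = 1e6 / grid.sample_rate
        delta_true = np.round(delta_true / dt_us) * dt_us
        params = StimulusParams.from_bc(
            bc, sigma_0=sigma_0, delta_us=float(delta_true), duration=duration
        )
        rng = np.random.default_rng(child)
        s_r, s_l = simulate_ears(params, n_trials, rng=rng)
        stats = sufficient_stats(s_r, s_l, grid)
        if observer == "post":
            post = post_marg_logpost(stats, grid)
        elif observer == "pre":
            post = pre_marg_logpost(
                stats, params.sigma_s, params.sigma_n, params.sigma_0, grid
            )
        else:
            raise ValueError(f"unknown observer {observer!r}")
        angles = itd_to_angle(map_estimate(post), behavior_params)
        if quantize:
            prec = behavior_params.angle_precision_deg
            angles = np.round(angles / prec) * prec
        rows.append(dict(
            bc=float(bc),
            true_angle=float(angle),
            mean_angle=float(np.mean(angles)),
            sd_angle=float(np.std(angles, ddof=1)),
            n=n_trials,
        ))
    return pd.DataFrame(rows)
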