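"""Figure-level experiment orchestration.

Everything here is deterministic given the config seed: every (BC, delta)
condition draws from its own child of one SeedSequence, every run writes
its resolved config next to its outputs, and TSV outputs are byte-stable.

The central builders — :func:`build_dataset` and
:func:`decoder_information_loss` — are shared by the command-line
interface, the test suite and the acceptance script.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import behavior_experiment
from .decoding import (
    PosteriorDecoder,
    information_loss,
    split_trials,
)
from .estimators import estimator_comparison
from .ideal_observer import (
    DelayGrid,
    Posterior,
    make_prior,
    post_marg_loglik,
    pre_marg_loglik,
    sufficient_stats,
)
from .neural import (
    OTConfig,
    build_filterbank,
    descriptive_model_response,
    ic_response,
    ot_response,
    tuning_curve,
)
from .stimulus import StimulusParams, simulate_ears

logger = logging.getLogger(__name__)

#: external-noise amplitudes used throughout (BC ~ 0.94, 0.41, 0.19, 0.10)
SIGMA_N_LEVELS = (0.25, 0.77, 0.9, 0.95)


@dataclass
class ExperimentConfig:
    """Resolved configuration of one experiment run."""

    sigma_n_levels: tuple[float, ...] = SIGMA_N_LEVELS
    sigma_0: float = 0.9
    duration_posterior: float = 0.001
    duration_tuning: float = 0.009
    trials_per_condition: int = 1000
    seed: int = 0
    prior: str = "box"
    nonlinearity: str = "half_rect"
    full: bool = False

    def __post_init__(self) -> None:
        self.sigma_n_levels = tuple(self.sigma_n_levels)
        if self.full:
            self.trials_per_condition = 6000

    @property
    def bc_levels(self) -> tuple[float, ...]:
        return tuple(1.0 - sn**2 for sn in self.sigma_n_levels)

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Dataset:
    """Trial-aligned responses, true posteriors and condition labels."""

    rates: dict[str, np.ndarray]
    log_true: dict[str, np.ndarray]
    bc: np.ndarray
    delta_true: np.ndarray
    grid: DelayGrid
    populations: dict[str, object] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.bc)

    def strata(self) -> np.ndarray:
        """Condition labels for stratified splitting."""
        _, inv = np.unique(
            np.stack([self.bc, self.delta_true]), axis=1, return_inverse=True
        )
        return inv


def build_dataset(
    bc_levels,
    grid: DelayGrid,
    n_per_condition: int,
    models: tuple[str, ...] = ("ic_rect",),
    duration: float = 0.001,
    sigma_0: float = 0.9,
    seed: int = 0,
    nonlinearity: str = "half_rect",
    ot_config: OTConfig | None = None,
) -> Dataset:
    """Simulate ``n_per_condition`` stimuli per (BC, grid delay) and compute
    model responses plus both ideal-observer posteriors.

    ``models`` may contain 'ic_rect' (rectified IC), 'ic_lin'
    (pre-rectification band cross-covariances), 'ot' and 'descriptive'.
    """
    n_samples = int(round(duration * grid.sample_rate))
    bank = build_filterbank(n_samples, grid.sample_rate)
    true_deltas = grid.delta_us[np.abs(grid.delta_us) <= 250.0 + 1e-9]
    conditions = [(bc, d) for bc in bc_levels for d in true_deltas]
    ss = np.random.SeedSequence(seed)
    blocks: dict[str, list] = {m: [] for m in models}
    log_pre_blocks, log_post_blocks = [], []
    bc_out, delta_out = [], []
    need_ic = [m for m in models if m.startswith("ic")]
    for (bc, delta), child in zip(conditions, ss.spawn(len(conditions))):
        params = StimulusParams.from_bc(
            bc, sigma_0=sigma_0, delta_us=float(delta), duration=duration
        )
        rng = np.random.default_rng(child)
        s_r, s_l = simulate_ears(params, n_per_condition, rng=rng)
        stats = sufficient_stats(s_r, s_l, grid)
        log_pre_blocks.append(
            Posterior.from_loglik(
                pre_marg_loglik(
                    stats, params.sigma_s, params.sigma_n, params.sigma_0
                ),
                grid,
            ).log_post.astype(np.float32)
        )
        log_post_blocks.append(
            Posterior.from_loglik(
                post_marg_loglik(stats.cc, stats.v, stats.t), grid
            ).log_post.astype(np.float32)
        )
        for m in need_ic:
            nl = "linear" if m == "ic_lin" else nonlinearity
            resp = ic_response(s_r, s_l, bank, grid, nl)
            blocks[m].append(resp.rates.astype(np.float32))
        if "ot" in models:
            resp = ot_response(stats, grid, ot_config)
            blocks["ot"].append(resp.rates.astype(np.float32))
        if "descriptive" in models:
            resp = descriptive_model_response(s_r, s_l, bank, grid)
            blocks["descriptive"].append(resp.rates.astype(np.float32))
        bc_out.append(np.full(n_per_condition, bc))
        delta_out.append(np.full(n_per_condition, delta))
    populations = {}
    for m in models:
        if m.startswith("ic"):
            populations[m] = dict(
                preferred_delay=np.tile(grid.delta_us, bank.n_bands),
                band=np.repeat(np.arange(bank.n_bands), grid.n),
            )
        elif m == "ot":
            populations[m] = dict(
                preferred_delay=np.tile(grid.delta_us, 2),
                band=np.repeat(np.arange(2), grid.n),
            )
        else:
            populations[m] = dict(
                preferred_delay=grid.delta_us.copy(),
                band=np.zeros(grid.n, dtype=int),
            )
    return Dataset(
        rates={m: np.concatenate(blocks[m]) for m in models},
        log_true={
            "pre": np.concatenate(log_pre_blocks),
            "post": np.concatenate(log_post_blocks),
        },
        bc=np.concatenate(bc_out),
        delta_true=np.concatenate(delta_out),
        grid=grid,
        populations=populations,
    )


def decoder_information_loss(
    ds: Dataset,
    model: str,
    observer: str,
    per_bc: bool,
    seed: int = 0,
    gtol: float = 1e-6,
    return_decoders: bool = False,
):
    """Train decoder(s) and report percent information loss per BC.

    ``per_bc=True`` trains one decoder per BC level (the known-BC, IC
    convention); ``per_bc=False`` trains a single decoder pooled across BC
    (the marginalized, OT convention). The split is 50/50 stratified by
    (BC, delta).
    """
    x = np.asarray(ds.rates[model], dtype=float)
    log_true = np.asarray(ds.log_true[observer], dtype=float)
    targets = np.exp(log_true)
    train = split_trials(ds.n_trials, seed=seed, strata=ds.strata())
    rows, decoders = [], {}
    if per_bc:
        groups = [(bc, ds.bc == bc) for bc in np.unique(ds.bc)]
    else:
        groups = [(None, np.ones(ds.n_trials, dtype=bool))]
    for bc_key, sel in groups:
        res = PosteriorDecoder(
            x[sel & train], targets[sel & train], ds.grid
        ).fit(gtol=gtol)
        decoders[bc_key] = res
        for bc in np.unique(ds.bc[sel]):
            te = sel & ~train & (ds.bc == bc)
            rep = information_loss(
                log_true[te],
                res.predict_log_posterior(x[te]),
                ds.grid,
                n_train=int((sel & train).sum()),
            )
            rows.append(dict(
                model=model, observer=observer, bc=float(bc),
                per_bc=per_bc, n_train=rep.n_train, n_test=rep.n_test,
                percent_info_loss=rep.percent_info_loss,
                kl_to_true=rep.kl_to_true,
                kl_true_to_prior=rep.kl_true_to_prior,
            ))
    df = pd.DataFrame(rows)
    if return_decoders:
        return df, decoders, train
    return df


def decoded_log_variance(
    ds: Dataset, model: str, decoders: dict, train: np.ndarray
) -> np.ndarray:
    """Log-variance of the decoded posterior on every trial (per-BC or
    pooled decoders as trained)."""
    x = np.asarray(ds.rates[model], dtype=float)
    out = np.empty(ds.n_trials)
    for bc_key, res in decoders.items():
        sel = np.ones(ds.n_trials, bool) if bc_key is None else ds.bc == bc_key
        post = Posterior(res.predict_log_posterior(x[sel]), ds.grid)
        out[sel] = np.log(np.maximum(post.variance, 1e-12))
    del train
    return out


def save_dataset(ds: Dataset, path) -> None:
    """Archive responses and true posteriors, keyed by condition labels."""
    arrays = {
        "bc": ds.bc,
        "delta_true": ds.delta_true,
        "delta_us": ds.grid.delta_us,
        "log_prior": ds.grid.log_prior,
    }
    for m, r in ds.rates.items():
        arrays[f"rates_{m}"] = r
    for obs, lp in ds.log_true.items():
        arrays[f"log_true_{obs}"] = lp
    np.savez_compressed(path, **arrays)


def load_dataset(path) -> Dataset:
    """Inverse of :func:`save_dataset` (population metadata not restored)."""
    with np.load(path) as z:
        grid = DelayGrid(z["delta_us"], z["log_prior"])
        rates = {
            k[len("rates_"):]: z[k] for k in z.files if k.startswith("rates_")
        }
        log_true = {
            k[len("log_true_"):]: z[k]
            for k in z.files if k.startswith("log_true_")
        }
        return Dataset(
            rates=rates, log_true=log_true, bc=z["bc"],
            delta_true=z["delta_true"], grid=grid,
        )


# ---------------------------------------------------------------------------
# experiment runners

def run_behavior(cfg: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    df = behavior_experiment(
        bcs=cfg.bc_levels,
        true_angles_deg=(10.0, 30.0, 60.0),
        n_trials=cfg.trials_per_condition,
        observer="post",
        prior=cfg.prior,
        duration=cfg.duration_posterior,
        sigma_0=cfg.sigma_0,
        seed=cfg.seed,
    )
    df.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
    return df

def run_tuning(cfg: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    grid = make_prior(cfg.prior)
    frames = []
    for model in ("ot", "descriptive"):
        for bc in cfg.bc_levels:
            curves = tuning_curve(
                model, bc, grid,
                n_trials=max(100, cfg.trials_per_condition // 5),
                duration=cfg.duration_tuning, sigma_0=cfg.sigma_0,
                seed=cfg.seed, nonlinearity=cfg.nonlinearity,
            )
            n_units = curves.shape[1]
            frames.append(pd.DataFrame(dict(
                model=model, bc=bc,
                delta_true=np.repeat(grid.delta_us, n_units),
                unit=np.tile(np.arange(n_units), grid.n),
                mean_rate=curves.ravel(),
            )))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(outdir / "tuning.tsv", sep="\t", index=False, float_format="%.6g")
    return df


def run_info_loss(cfg: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    grid = make_prior(cfg.prior)
    ds = build_dataset(
        cfg.bc_levels, grid, cfg.trials_per_condition,
        models=("ic_rect", "ic_lin", "ot"),
        duration=cfg.duration_posterior, sigma_0=cfg.sigma_0,
        seed=cfg.seed, nonlinearity=cfg.nonlinearity,
    )
    frames = [
        decoder_information_loss(ds, "ic_rect", "pre", per_bc=True,
                                 seed=cfg.seed),
        decoder_information_loss(ds, "ic_lin", "pre", per_bc=True,
                                 seed=cfg.seed),
        decoder_information_loss(ds, "ot", "post", per_bc=False,
                                 seed=cfg.seed),
    ]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(outdir / "info_loss.tsv", sep="\t", index=False)
    return df


def run_uncertainty(cfg: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    grid = make_prior(cfg.prior)
    ds = build_dataset(
        cfg.bc_levels, grid, cfg.trials_per_condition,
        models=("ic_rect", "ot"),
        duration=cfg.duration_posterior, sigma_0=cfg.sigma_0,
        seed=cfg.seed, nonlinearity=cfg.nonlinearity,
    )
    frames = []
    for model, observer, pooled in (
        ("ic_rect", "pre", False), ("ot", "post", True),
    ):
        _, decoders, train = decoder_information_loss(
            ds, model, observer, per_bc=not pooled, seed=cfg.seed,
            return_decoders=True,
        )
        dec_logv = decoded_log_variance(ds, model, decoders, train)
        true_logv = np.log(np.maximum(
            Posterior(ds.log_true[observer].astype(float), grid).variance,
            1e-12,
        ))
        from .neural import PopulationResponse

        resp = PopulationResponse(
            rates=ds.rates[model].astype(float),
            nonlinearity=cfg.nonlinearity,
            **ds.populations[model],
        )
        frames.append(estimator_comparison(
            resp, true_logv, dec_logv, ds.bc, pooled=pooled,
            split_seed=cfg.seed, model_tag=model,
        ))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(outdir / "uncertainty.tsv", sep="\t", index=False)
    return df


def run_manipulations(cfg: ExperimentConfig, outdir: Path) -> pd.DataFrame:
    grid = make_prior(cfg.prior)
    bc = max(cfg.bc_levels)
    n = max(100, cfg.trials_per_condition // 5)
    rows = []
    variants = {
        "original": dict(duration=cfg.duration_tuning, stim_band=None),
        "short": dict(duration=cfg.duration_tuning / 3, stim_band=None),
        "lowpass": dict(duration=cfg.duration_tuning,
                        stim_band=(0.0, 2000.0)),
        "highpass": dict(duration=cfg.duration_tuning,
                         stim_band=(4000.0, 8000.0)),
    }
    for model in ("ot", "descriptive"):
        for name, kw in variants.items():
            curves = tuning_curve(
                model, bc, grid, n_trials=n, sigma_0=cfg.sigma_0,
                seed=cfg.seed, **kw,
            )
            n_units = curves.shape[1]
            rows.append(pd.DataFrame(dict(
                model=model, variant=name, bc=bc,
                delta_true=np.repeat(grid.delta_us, n_units),
                unit=np.tile(np.arange(n_units), grid.n),
                mean_rate=curves.ravel(),
            )))
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(outdir / "manipulations.tsv", sep="\t", index=False,
              float_format="%.6g")
    return df


def run_descriptive_compare(cfg: ExperimentConfig, outdir: Path):
    grid = make_prior(cfg.prior)
    ds = build_dataset(
        cfg.bc_levels, grid, cfg.trials_per_condition,
        models=("descriptive",),
        duration=cfg.duration_posterior, sigma_0=cfg.sigma_0,
        seed=cfg.seed,
    )
    df, decoders, train = decoder_information_loss(
        ds, "descriptive", "post", per_bc=False, seed=cfg.seed,
        return_decoders=True,
    )
    df.to_csv(outdir / "descriptive_info_loss.tsv", sep="\t", index=False)
    return df


EXPERIMENTS = {
    "behavior": run_behavior,
    "tuning": run_tuning,
    "info_loss": run_info_loss,
    "uncertainty": run_uncertainty,
    "manipulations": run_manipulations,
    "descriptive_compare": run_descriptive_compare,
}


def run(experiment: str, cfg: ExperimentConfig, outdir) -> pd.DataFrame:
    """Run one named experiment; outputs land in ``outdir/<experiment>``.

    Partial outputs are removed on failure so a results directory is either
    complete (with its resolved config) or absent.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {experiment!r}; "
            f"choose from {sorted(EXPERIMENTS)}"
        )
    dest = Path(outdir) / experiment
    dest.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        result = EXPERIMENTS[experiment](cfg, dest)
    except Exception:
        shutil.rmtree(dest, ignore_errors=True)
        raise
    cfg.to_yaml(dest / "config.yaml")
    logger.info(
        "experiment %s finished in %.1f s", experiment,
        time.perf_counter() - t0,
    )
    return result
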