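"""Single-feature ("correlational") estimators of momentary uncertainty.

The correlational approach posits that a scalar feature of population
activity — tuning-curve width, gain, or each unit's rate — carries the
momentary uncertainty. Each feature q^f(r) enters a linear model of the
ideal observer's posterior log-variance,

    log v = beta_0 + sum_f beta_f q^f(r),

fitted by ordinary least squares on half of the trials and scored by the
cross-validated R^2 on the other half. The reference estimator is the
log-variance of the posterior decoded by the full lPPC readout, pushed
through the same linear-fit machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import split_trials
from .neural import PopulationResponse

logger = logging.getLogger(__name__)

DEFAULT_PAIR_CAP = 300


@dataclass(frozen=True)
class FeatureSet:
    """Design matrix of correlational features, one row per trial.

    ``valid`` flags trials where every feature is defined (all-zero
    sub-populations make the width undefined; such trials are excluded
    rather than imputed, and the exclusion count is logged).
    """

    matrix: np.ndarray
    names: list[str]
    valid: np.ndarray
    tag: str

    @property
    def n_excluded(self) -> int:
        return int(np.sum(~self.valid))


def _subpop_width_gain(rates, deltas, want_width, want_gain):
    cols, names_w, names_g = [], [], []
    total = rates.sum(axis=-1)
    ok = total > 0
    safe = np.where(ok, total, 1.0)
    rel = rates / safe[..., None]
    mu = rel @ deltas
    width = rel @ deltas**2 - mu**2
    if want_width:
        cols.append(np.where(ok, width, np.nan))
    if want_gain:
        cols.append(total)
    return cols


def compute_features(
    resp: PopulationResponse,
    which: tuple[str, ...] = ("width",),
    pairs_cap: int = DEFAULT_PAIR_CAP,
    seed: int = 0,
    tag: str | None = None,
) -> FeatureSet:
    """Build the requested feature columns from population activity.

    Supported features: ``width`` and ``gain`` (one column per frequency
    sub-population, per the band labels of the response), ``gengain`` (the
    full rate vector), ``products`` (pairwise rate products over a capped
    random subset of unit pairs), ``ratio`` (pooled gain / pooled width).
    """
    rates = np.atleast_2d(resp.rates)
    deltas = resp.preferred_delay
    bands = resp.band
    cols: list[np.ndarray] = []
    names: list[str] = []
    for feat in which:
        if feat in ("width", "gain"):
            for b in np.unique(bands):
                sel = bands == b
                sub = _subpop_width_gain(
                    rates[..., sel], deltas[sel],
                    feat == "width", feat == "gain",
                )
                cols.extend(sub)
                names.append(f"{feat}[band{b}]")
        elif feat == "gengain":
            cols.append(rates)
            names.extend(f"r[{i}]" for i in range(rates.shape[-1]))
        elif feat == "products":
            rng = np.random.default_rng(seed)
            u = rates.shape[-1]
            ii, jj = np.triu_indices(u, k=1)
            if len(ii) > pairs_cap:
                pick = rng.choice(len(ii), size=pairs_cap, replace=False)
                ii, jj = ii[pick], jj[pick]
            cols.append(rates[..., ii] * rates[..., jj])
            names.extend(f"r[{i}]*r[{j}]" for i, j in zip(ii, jj))
        elif feat == "ratio":
            pooled = _subpop_width_gain(rates, deltas, True, True)
            width, gain = pooled
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(width > 0, gain / width, np.nan)
            cols.append(ratio)
            names.append("gain/width")
        else:
            raise ValueError(f"unknown feature {feat!r}")
    matrix = np.column_stack(
        [c if c.ndim == 2 else c[:, None] for c in cols]
    )
    valid = np.all(np.isfinite(matrix), axis=1)
    n_bad = int(np.sum(~valid))
    if n_bad:
        logger.info(
            "%d/%d trials excluded (undefined features)", n_bad, len(valid)
        )
    return FeatureSet(
        matrix=matrix, names=names, valid=valid, tag=tag or "+".join(which)
    )


class UncertaintyModel:
    """OLS model of the observer's posterior log-variance on features.

    Follows the fit/results pattern: construct from a feature matrix and
    per-trial log-variances, call :meth:`fit` to obtain an
    :class:`UncertaintyResults` with coefficients and cross-validated R^2.
    """

    def __init__(self, features, log_variance: np.ndarray):
        if isinstance(features, FeatureSet):
            self.feature_tag = features.tag
            keep = features.valid
            self.x = features.matrix[keep]
            self.y = np.asarray(log_variance, dtype=float)[keep]
            self.n_excluded = features.n_excluded
        else:
            self.feature_tag = "custom"
            self.x = np.atleast_2d(np.asarray(features, dtype=float))
            if self.x.shape[0] == 1 and np.ndim(log_variance) == 1:
                self.x = self.x.T
            self.y = np.asarray(log_variance, dtype=float)
            self.n_excluded = 0
        if len(self.x) != len(self.y):
            raise ValueError("feature/target length mismatch")

    def fit(
        self, split_seed: int = 0, train_mask: np.ndarray | None = None
    ) -> "UncertaintyResults":
        """Train on half the trials, score out-of-sample on the rest."""
        if train_mask is None:
            train_mask = split_trials(len(self.y), seed=split_seed)
        xtr = np.column_stack(
            [np.ones(train_mask.sum()), self.x[train_mask]]
        )
        beta, *_ = np.linalg.lstsq(xtr, self.y[train_mask], rcond=None)
        rank = np.linalg.matrix_rank(xtr)
        if rank < xtr.shape[1]:
            logger.warning(
                "rank-deficient design (%d < %d); least-norm solution used",
                rank, xtr.shape[1],
            )
        xte = np.column_stack([np.ones((~train_mask).sum()), self.x[~train_mask]])
        yte = self.y[~train_mask]
        pred = xte @ beta
        ss_res = float(np.sum((yte - pred) ** 2))
        ss_tot = float(np.sum((yte - yte.mean()) ** 2))
        return UncertaintyResults(
            beta0=float(beta[0]),
            betas=beta[1:],
            feature_tag=self.feature_tag,
            r2_cv=1.0 - ss_res / ss_tot,
            n_train=int(train_mask.sum()),
            n_test=int((~train_mask).sum()),
            n_excluded=self.n_excluded,
        )


@dataclass(frozen=True)
class UncertaintyResults:
    beta0: float
    betas: np.ndarray
    feature_tag: str
    r2_cv: float
    n_train: int
    n_test: int
    n_excluded: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.beta0 + np.atleast_2d(x) @ self.betas

    def summary(self) -> str:
        return (
            f"Uncertainty estimator [{self.feature_tag}]: "
            f"{len(self.betas)} features, cross-validated R^2 = "
            f"{self.r2_cv:.4f} (n_train={self.n_train}, "
            f"n_test={self.n_test}, excluded={self.n_excluded})"
        )


#: feature bundles compared in the estimator benchmark
STANDARD_FEATURES: dict[str, tuple[str, ...]] = {
    "width": ("width",),
    "gain": ("gain",),
    "gengain": ("gengain",),
}


def fit_uncertainty(
    features, log_variances, split_seed: int = 0, train_mask=None
) -> UncertaintyResults:
    """One-call OLS fit + cross-validated R^2 (see UncertaintyModel)."""
    return UncertaintyModel(features, log_variances).fit(
        split_seed=split_seed, train_mask=train_mask
    )


def estimator_comparison(
    resp: PopulationResponse,
    log_v_true: np.ndarray,
    decoded_log_v: np.ndarray,
    bc_labels: np.ndarray,
    pooled: bool = False,
    features: dict[str, tuple[str, ...]] | None = None,
    split_seed: int = 0,
    model_tag: str = "",
) -> pd.DataFrame:
    """R^2 of every estimator per BC level, decoded variance included.

    ``pooled=False`` fits each estimator separately within each BC level
    (the known-BC convention); ``pooled=True`` fits once across all BC and
    still reports R^2 split by BC (the marginalized convention). The
    decoded posterior's log-variance enters the identical linear-fit
    machinery as feature "decoded".
    """
    features = features or STANDARD_FEATURES
    bc_labels = np.asarray(bc_labels)
    rows = []
    sets: dict[str, FeatureSet] = {
        name: compute_features(resp, which, seed=split_seed, tag=name)
        for name, which in features.items()
    }
    sets["decoded"] = FeatureSet(
        matrix=np.asarray(decoded_log_v, dtype=float)[:, None],
        names=["log_var_decoded"],
        valid=np.isfinite(decoded_log_v),
        tag="decoded",
    )
    for name, fs in sets.items():
        keep = fs.valid
        x, y = fs.matrix[keep], np.asarray(log_v_true)[keep]
        labels = bc_labels[keep]
        if pooled:
            mask = split_trials(len(y), seed=split_seed, strata=labels)
            xtr = np.column_stack([np.ones(mask.sum()), x[mask]])
            beta, *_ = np.linalg.lstsq(xtr, y[mask], rcond=None)
            for bc in np.unique(labels):
                te = (~mask) & (labels == bc)
                pred = beta[0] + x[te] @ beta[1:]
                ss_res = np.sum((y[te] - pred) ** 2)
                ss_tot = np.sum((y[te] - y[te].mean()) ** 2)
                rows.append(dict(
                    model=model_tag, bc=float(bc), feature=name,
                    r2_cv=1.0 - ss_res / ss_tot, n_used=int(te.sum()),
                ))
        else:
            for bc in np.unique(labels):
                sel = labels == bc
                res = UncertaintyModel(x[sel], y[sel]).fit(
                    split_seed=split_seed
                )
                rows.append(dict(
                    model=model_tag, bc=float(bc), feature=name,
                    r2_cv=res.r2_cv, n_used=res.n_test,
                ))
    return pd.DataFrame(rows)
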