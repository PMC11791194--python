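"""Elastic-net age clocks: fitting, prediction, and cross-validation.

A clock is a penalized linear model mapping CpG beta values to transformed
chronological age. The elastic-net mixing parameter is fixed at 0.5 (midway
between ridge and lasso); the penalty strength lambda is chosen by internal
k-fold cross-validation minimizing mean squared error on the transformed-age
scale. Accuracy is evaluated with two schemes:

* leave-one-sample-out (LOO): one refit per left-out sample; summarized by
  the Pearson correlation of predicted vs observed age in years and the
  median absolute error (median over samples of |predicted - observed|).
* leave-one-species-out (LOSO): one refit per left-out species; summarized
  by the repeated-measures correlation (species as the grouping factor) and
  the median across species of per-species median absolute errors.

By default the LOO driver selects lambda once on the full data and refits
each fold at that value (per-fold re-selection is available via
``reselect_lambda=True``); LOSO re-selects lambda within every fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold, StratifiedKFold

from .transform import TransformSpec, inverse_transform, transform_age
from .types import BetaMatrix, ClockModel, SamplePanel, ValidationError

logger = logging.getLogger(__name__)

_MAX_ITER = 5000


@dataclass
class CVResult:
    """Per-sample cross-validated predictions plus scheme-level summaries."""

    scheme: str  # "loo" | "loso"
    predictions: pd.DataFrame  # sample_id species tissue age_years dnam_age fold
    summary: dict

    @property
    def n(self) -> int:
        return len(self.predictions)


def _impute_and_standardize(X: np.ndarray):
    """Column mean-impute NaNs, then center/scale. Returns (Xs, mu, sd, means)."""
    X = np.array(X, dtype=float)
    col_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / safe_sd, mu, safe_sd, col_means, sd


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, alpha: float, n_lambdas: int,
                 eps: float | None = None) -> np.ndarray:
    n = Xs.shape[0]
    if eps is None:
        # glmnet convention: wider ratio when there are fewer samples than CpGs
        eps = 1e-2 if n < Xs.shape[1] else 1e-4
    yc = y - y.mean()
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * alpha)
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(np.log10(lam_max), np.log10(lam_max * eps), n_lambdas)


def _internal_folds(n: int, species: list[str], n_folds: int, seed: int):
    """Seeded internal CV folds, stratified by species when feasible."""
    counts = pd.Series(species).value_counts()
    if len(counts) >= 2 and counts.min() >= n_folds:
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(n), species))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(n)))


def _select_lambda(Xs, y, species, alpha, n_folds, seed, n_lambdas) -> float:
    grid = _lambda_grid(Xs, y, alpha, n_lambdas)
    mse = np.zeros((n_folds, len(grid)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for f, (tr, va) in enumerate(_internal_folds(len(y), species, n_folds, seed)):
            ybar = y[tr].mean()
            # enet_path fits no intercept: center y and the fold's X ourselves
            Xtr = Xs[tr] - Xs[tr].mean(axis=0)
            _, coefs, _ = enet_path(
                Xtr, y[tr] - ybar, l1_ratio=alpha, alphas=grid, max_iter=_MAX_ITER
            )
            pred = (Xs[va] - Xs[tr].mean(axis=0)) @ coefs + ybar
            mse[f] = ((pred - y[va][:, None]) ** 2).mean(axis=0)
    return float(grid[int(np.argmin(mse.mean(axis=0)))])


def fit_clock(
    betas: BetaMatrix,
    panel: SamplePanel,
    spec: TransformSpec = TransformSpec(),
    alpha: float = 0.5,
    n_internal_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_: float | None = None,
) -> ClockModel:
    """Fit an elastic-net clock on all samples of ``panel``.

    The penalty ``lambda_`` may be supplied directly to skip internal CV
    (used by the fixed-penalty LOO driver and by near-unpenalized fits).
    Coefficients are reported on the original beta scale with the internal
    standardization undone; only nonzero weights are stored.
    """
    n = len(panel)
    if betas.sample_ids != panel.sample_id:
        raise ValidationError("beta matrix is not aligned to the sample panel")
    if n < 3:
        raise ValidationError("need at least 3 samples to fit a clock")
    y = np.asarray(transform_age(panel.age_years, spec), dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError("no age variance in training panel")
    n_folds = n_internal_folds
    if n < n_folds:
        n_folds = max(3, n)
        logger.warning("reducing internal CV folds to %d (only %d samples)", n_folds, n)

    Xs, mu, safe_sd, col_means, sd = _impute_and_standardize(betas.values)
    if not (sd > 0).any():
        raise ValidationError("all predictors have zero variance")

    if lambda_ is None:
        lambda_ = _select_lambda(Xs, y, panel.species, alpha, n_folds, seed, n_lambdas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        en = ElasticNet(alpha=lambda_, l1_ratio=alpha, max_iter=_MAX_ITER)
        en.fit(Xs, y)
    w_std = en.coef_
    w = w_std / safe_sd
    intercept = float(en.intercept_ - np.sum(w_std * mu / safe_sd))
    nz = np.nonzero(w)[0]
    return ClockModel(
        intercept=intercept,
        weights={betas.cpg_ids[j]: float(w[j]) for j in nz},
        transform_spec=spec,
        training_means={betas.cpg_ids[j]: float(col_means[j]) for j in nz},
        training_meta={
            "alpha": alpha,
            "lambda": float(lambda_),
            "n_samples": n,
            "n_internal_folds": n_folds,
            "seed": seed,
            "species": sorted(set(panel.species)),
            "tissues": sorted(set(panel.tissue)),
        },
    )


def predict_age(
    model: ClockModel, betas: BetaMatrix, missing_threshold: float = 0.2
) -> np.ndarray:
    """Predict DNAm age in years for every sample of ``betas``.

    Model CpGs absent from the matrix (or NaN in a sample) are imputed from
    the training means stored in the model; a sample missing more than
    ``missing_threshold`` of the model's CpGs raises.
    """
    cpgs = list(model.weights)
    col = betas.column_index()
    n = len(betas.sample_ids)
    if cpgs:
        vals = np.empty((n, len(cpgs)))
        missing = np.zeros((n, len(cpgs)), dtype=bool)
        for j, c in enumerate(cpgs):
            if c in col:
                vals[:, j] = betas.values[:, col[c]]
            else:
                vals[:, j] = np.nan
            missing[:, j] = np.isnan(vals[:, j])
        frac = missing.mean(axis=1)
        over = frac > missing_threshold
        if over.any():
            bad = [betas.sample_ids[i] for i in np.nonzero(over)[0]]
            raise ValidationError(
                f">{missing_threshold:.0%} of model CpGs missing for samples: {bad}"
            )
        if missing.any():
            fills = np.asarray([model.training_means.get(c, np.nan) for c in cpgs])
            vals = np.where(missing, fills[None, :], vals)
        score = model.intercept + vals @ np.asarray([model.weights[c] for c in cpgs])
    else:
        score = np.full(n, model.intercept)
    return np.asarray(inverse_transform(score, model.transform_spec), dtype=float)


def _cv_frame(panel: SamplePanel, pred: np.ndarray, fold: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": panel.sample_id,
            "species": panel.species,
            "tissue": panel.tissue,
            "age_years": panel.age_years,
            "dnam_age": pred,
            "fold": fold,
        }
    )


def loocv(
    betas: BetaMatrix,
    panel: SamplePanel,
    spec: TransformSpec = TransformSpec(),
    alpha: float = 0.5,
    seed: int = 0,
    n_internal_folds: int = 10,
    n_lambdas: int = 50,
    reselect_lambda: bool = False,
) -> CVResult:
    """Leave-one-sample-out cross-validation: one refit per sample.

    With ``reselect_lambda=False`` (default) the penalty is selected once by
    internal CV on the full data and every fold refits at that value with
    warm starts; ``True`` re-runs the internal CV inside every fold.
    """
    n = len(panel)
    if n < 10:
        raise ValidationError("LOO cross-validation needs at least 10 samples")
    y = np.asarray(transform_age(panel.age_years, spec), dtype=float)
    preds = np.empty(n)

    if reselect_lambda:
        for i in range(n):
            keep = np.arange(n) != i
            try:
                model = fit_clock(
                    betas.subset_samples(keep), panel.subset(keep), spec,
                    alpha=alpha, n_internal_folds=n_internal_folds, seed=seed,
                    n_lambdas=n_lambdas,
                )
            except ValidationError as exc:
                raise ValidationError(f"LOO fold {panel.sample_id[i]}: {exc}") from exc
            preds[i] = predict_age(model, betas.subset_samples(~keep))[0]
    else:
        Xs_full, _, _, col_means, sd = _impute_and_standardize(betas.values)
        if not (sd > 0).any():
            raise ValidationError("all predictors have zero variance")
        lam = _select_lambda(
            Xs_full, y, panel.species, alpha, min(n_internal_folds, n - 1), seed,
            n_lambdas,
        )
        X = np.array(betas.values, dtype=float)
        nan_mask = np.isnan(X)
        if nan_mask.any():
            X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
        en = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=_MAX_ITER, warm_start=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for i in range(n):
                keep = np.arange(n) != i
                Xt = X[keep]
                mu = Xt.mean(axis=0)
                sdt = Xt.std(axis=0)
                safe = np.where(sdt > 0, sdt, 1.0)
                en.fit((Xt - mu) / safe, y[keep])
                preds[i] = float(en.intercept_ + ((X[i] - mu) / safe) @ en.coef_)

    pred_years = np.asarray(inverse_transform(preds, spec), dtype=float)
    frame = _cv_frame(panel, pred_years, list(panel.sample_id))
    r = float(stats.pearsonr(pred_years, panel.age_years).statistic)
    mae = float(np.median(np.abs(pred_years - panel.age_years)))
    return CVResult(
        scheme="loo",
        predictions=frame,
        summary={"n": n, "pearson_r": r, "median_mae_years": mae},
    )


def losocv(
    betas: BetaMatrix,
    panel: SamplePanel,
    spec: TransformSpec = TransformSpec(),
    alpha: float = 0.5,
    seed: int = 0,
    n_internal_folds: int = 10,
    n_lambdas: int = 50,
) -> CVResult:
    """Leave-one-species-out cross-validation: one refit per species.

    Summaries: the repeated-measures correlation of predicted vs observed
    age treating species as the repeated-measures grouping factor
    (species with < 2 samples are excluded from that statistic, with a
    warning), and the median across species of per-species median absolute
    errors in years.
    """
    species = sorted(set(panel.species))
    if len(species) < 3:
        raise ValidationError("LOSO cross-validation needs at least 3 species")
    pred_years = np.empty(len(panel))
    fold = [""] * len(panel)
    for sp in species:
        mask = np.asarray([s == sp for s in panel.species])
        try:
            model = fit_clock(
                betas.subset_samples(~mask), panel.subset(~mask), spec,
                alpha=alpha, n_internal_folds=n_internal_folds, seed=seed,
                n_lambdas=n_lambdas,
            )
        except ValidationError as exc:
            raise ValidationError(f"LOSO fold {sp}: {exc}") from exc
        pred_years[mask] = predict_age(model, betas.subset_samples(mask))
        for i in np.nonzero(mask)[0]:
            fold[i] = sp

    frame = _cv_frame(panel, pred_years, fold)
    counts = frame.groupby("species")["sample_id"].count()
    small = counts[counts < 2].index.tolist()
    if small:
        logger.warning(
            "species with < 2 samples excluded from repeated-measures r: %s", small
        )
    ok = frame[~frame["species"].isin(small)]
    rm_r = repeated_measures_correlation(
        ok["age_years"].to_numpy(), ok["dnam_age"].to_numpy(), ok["species"].tolist()
    )
    per_species = (
        frame.assign(abs_err=(frame["dnam_age"] - frame["age_years"]).abs())
        .groupby("species")["abs_err"]
        .median()
    )
    return CVResult(
        scheme="loso",
        predictions=frame,
        summary={
            "n": len(frame),
            "n_species": len(species),
            "repeated_measures_r": rm_r,
            "median_mae_years": float(per_species.median()),
            "per_species_median_mae": per_species.to_dict(),
        },
    )


def repeated_measures_correlation(x, y, group) -> float:
    """Common within-group correlation of x and y.

    Equivalent to the ANCOVA formulation (y ~ group + x): both variables
    are centered within groups and the Pearson correlation of the centered
    values is returned; its sign is the sign of the common slope. With a
    single group this reduces to the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if x.shape != y.shape or x.shape != group.shape:
        raise ValidationError("x, y, group must have equal length")
    df = pd.DataFrame({"x": x, "y": y, "g": group})
    sizes = df.groupby("g")["x"].transform("size")
    df = df[sizes >= 2]
    if df.empty:
        raise ValidationError("all groups are singletons")
    xc = df["x"] - df.groupby("g")["x"].transform("mean")
    yc = df["y"] - df.groupby("g")["y"].transform("mean")
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValidationError("zero within-group variance")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
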