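"""Elastic-net metabolomic age clocks and the age-acceleration test.

A clock is a penalized linear regression predicting chronological age (days
from egg) from standardized normalized metabolite abundances.  Within a
regime, honest predictions come from a leave-one-replicate-out (LORO)
scheme: every sample is predicted by a clock whose training set excluded
that sample's entire replicate population.  Between regimes, a clock
trained on all samples of one regime predicts the other regime's samples.

The age-acceleration test pools within-LORO and between-regime predictions
into one OLS fit::

    predicted_age ~ alpha + beta1 * age + beta2 * mode + beta3 * age * mode

with mode = 0 for within-regime and 1 for between-regime predictions.
beta2 is an age-independent shift of the between-regime predictions
("looks older/younger overall"); beta3 is the difference in slope ("appears
to age faster/slower").  A positive beta3 for a control-regime clock
applied to an accelerated regime is the metabolomic signature of
accelerated biological aging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .tables import AbundanceTable

__all__ = [
    "ClockModel",
    "AgePredictionSet",
    "AgeAccelerationFit",
    "FeatureComparison",
    "fit_clock",
    "loro_predictions",
    "between_regime_predictions",
    "r_squared",
    "fit_age_acceleration",
    "compare_features",
    "fisher_overlap",
]

#: Default penalty mixing grid: L1 fraction 0.1..1.0; per mixing value the
#: penalty-strength path runs from lambda_max (all coefficients zero) down
#: four decades in 100 log-spaced steps.
DEFAULT_L1_RATIOS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
DEFAULT_N_ALPHAS = 100
DEFAULT_EPS = 1e-4


@dataclass
class ClockModel:
    """A fitted elastic-net age predictor with its training standardization."""

    regime: str
    l1_ratio: float
    alpha: float
    coef: pd.Series  # per-metabolite coefficients on the standardized scale
    intercept: float
    feature_means: pd.Series
    feature_sds: pd.Series
    cv_rmse: float

    @property
    def nonzero_features(self) -> list[str]:
        return self.coef.index[self.coef != 0.0].tolist()

    def predict(self, values: pd.DataFrame) -> pd.Series:
        """Predicted age (days) for rows of a samples x metabolites frame."""
        missing = [c for c in self.coef.index if c not in values.columns]
        if missing:
            raise ValueError(f"metabolite panel mismatch; missing: {missing[:10]}")
        x = values[self.coef.index]
        z = (x - self.feature_means) / self.feature_sds
        return z @ self.coef + self.intercept


@dataclass
class AgePredictionSet:
    """Per-sample chronological and predicted ages for one prediction mode."""

    predictions: pd.DataFrame  # sample_id, age_days, predicted_age, regime,
    #                            clock_regime, mode, replicate
    mode: str  # "within-LORO" or "between"
    clock_regime: str
    leakage_free: bool


@dataclass
class AgeAccelerationFit:
    """OLS comparison of between- vs within-regime age predictions."""

    params: pd.Series  # alpha, beta1, beta2, beta3
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    residual_variance: float
    n: int
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)


@dataclass
class FeatureComparison:
    """Overlap and coefficient comparison between two clocks' feature sets."""

    n_features_a: int
    n_features_c: int
    n_shared: int
    panel_size: int
    contingency: np.ndarray  # [[both, a_only], [c_only, neither]]
    odds_ratio: float
    fisher_p: float
    shared_correlation: float | None
    shared_correlation_p: float | None
    ranksum_a: tuple[float, float] | None  # (statistic, p) |beta| shared vs A-unique
    ranksum_c: tuple[float, float] | None


def _standardize(x: pd.DataFrame) -> tuple[np.ndarray, pd.Series, pd.Series]:
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    sds = sds.where(sds > 0, 1.0)  # constant columns contribute nothing
    return ((x - means) / sds).to_numpy(), means, sds


def fit_clock(
    table: AbundanceTable,
    folds: int = 5,
    seed: int = 0,
    l1_ratios=DEFAULT_L1_RATIOS,
    n_alphas: int = DEFAULT_N_ALPHAS,
    eps: float = DEFAULT_EPS,
    regime: str | None = None,
) -> ClockModel:
    """Fit an elastic-net age clock with seeded 5-fold CV penalty selection.

    Predictors are standardized to unit variance within the training set
    (parameters stored for held-out use); the (L1 fraction, penalty
    strength) pair minimizing cross-validated RMSE is selected from the
    grid.
    """
    ages = table.metadata["age_days"].to_numpy(dtype=float)
    if table.n_samples < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    if np.var(ages) == 0:
        raise ValueError("age has zero variance; a clock cannot be fit")
    z, means, sds = _standardize(table.values)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(
        l1_ratio=list(l1_ratios),
        alphas=n_alphas,
        eps=eps,
        cv=cv,
        max_iter=3000,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        # the deep (near-unpenalized) end of the path may stop at max_iter;
        # those candidates lose the CV selection anyway
        warnings.simplefilter("ignore", ConvergenceWarning)
        enet.fit(z, ages)
    mse = np.asarray(enet.mse_path_)
    if np.allclose(mse.max(), mse.min()):
        raise ValueError("all candidate penalty settings give identical RMSE; degenerate input")
    if regime is None:
        uniq = table.metadata["regime"].unique()
        regime = uniq[0] if len(uniq) == 1 else "+".join(sorted(uniq))
    return ClockModel(
        regime=regime,
        l1_ratio=float(enet.l1_ratio_),
        alpha=float(enet.alpha_),
        coef=pd.Series(enet.coef_, index=table.values.columns),
        intercept=float(enet.intercept_),
        feature_means=means,
        feature_sds=sds,
        cv_rmse=float(np.sqrt(mse.min())),
    )


def loro_predictions(
    regime_table: AbundanceTable,
    folds: int = 5,
    seed: int = 0,
    **grid,
) -> AgePredictionSet:
    """Within-regime predictions by leave-one-replicate-out clock fitting.

    For each replicate population, a clock is fit on all other replicates
    (CV seeded as ``seed + replicate index``) and predicts the held-out
    replicate's samples, so no sample is ever predicted by a model that saw
    its replicate.
    """
    meta = regime_table.metadata
    replicates = sorted(meta["replicate"].unique())
    if len(replicates) < 3:
        raise ValueError("leave-one-replicate-out needs at least 3 replicate populations")
    all_ages = set(meta["age_days"])
    frames = []
    # canonical sample order makes the seeded CV split independent of the
    # caller's row ordering
    regime_table = regime_table.subset(regime_table.values.index.sort_values())
    meta = regime_table.metadata
    for i, rep in enumerate(replicates):
        train = regime_table.subset(meta["replicate"] != rep)
        lost = all_ages - set(train.metadata["age_days"])
        if lost:
            raise ValueError(
                f"withholding replicate {rep!r} removes all samples of ages {sorted(lost)}"
            )
        clock = fit_clock(train, folds=folds, seed=seed + i, **grid)
        held = regime_table.subset(meta["replicate"] == rep)
        pred = clock.predict(held.values)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": held.metadata["sample_id"].to_numpy(),
                    "age_days": held.metadata["age_days"].to_numpy(),
                    "predicted_age": pred.to_numpy(),
                    "regime": held.metadata["regime"].to_numpy(),
                    "replicate": held.metadata["replicate"].to_numpy(),
                    "excluded_replicate": rep,
                }
            )
        )
    preds = pd.concat(frames, ignore_index=True).sort_values("sample_id", ignore_index=True)
    clock_regime = "+".join(sorted(meta["regime"].unique()))
    preds["mode"] = "within-LORO"
    preds["clock_regime"] = clock_regime
    leakage_free = bool((preds["replicate"] == preds["excluded_replicate"]).all())
    return AgePredictionSet(
        predictions=preds, mode="within-LORO", clock_regime=clock_regime,
        leakage_free=leakage_free,
    )


def between_regime_predictions(
    clock_regime_table: AbundanceTable,
    target_regime_table: AbundanceTable,
    folds: int = 5,
    seed: int = 0,
    **grid,
) -> tuple[ClockModel, AgePredictionSet]:
    """Fit a clock on one regime's samples and predict the opposite regime."""
    clock_regimes = set(clock_regime_table.metadata["regime"])
    target_regimes = set(target_regime_table.metadata["regime"])
    if clock_regimes & target_regimes:
        raise ValueError(
            f"clock and target regimes overlap ({sorted(clock_regimes & target_regimes)}); "
            "between-regime prediction requires disjoint regimes"
        )
    if list(clock_regime_table.values.columns) != list(target_regime_table.values.columns):
        raise ValueError("clock and target tables have different metabolite panels")
    clock_regime_table = clock_regime_table.subset(
        clock_regime_table.values.index.sort_values()
    )
    clock = fit_clock(clock_regime_table, folds=folds, seed=seed, **grid)
    pred = clock.predict(target_regime_table.values)
    meta = target_regime_table.metadata
    preds = pd.DataFrame(
        {
            "sample_id": meta["sample_id"].to_numpy(),
            "age_days": meta["age_days"].to_numpy(),
            "predicted_age": pred.to_numpy(),
            "regime": meta["regime"].to_numpy(),
            "replicate": meta["replicate"].to_numpy(),
            "excluded_replicate": "",
            "mode": "between",
            "clock_regime": clock.regime,
        }
    ).sort_values("sample_id", ignore_index=True)
    return clock, AgePredictionSet(
        predictions=preds, mode="between", clock_regime=clock.regime, leakage_free=True
    )


def r_squared(actual, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("actual and predicted must be equal-length 1-d arrays, n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual ages are constant; R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def fit_age_acceleration(
    within: AgePredictionSet, between: AgePredictionSet
) -> AgeAccelerationFit:
    """OLS of predicted age on age, prediction mode, and their interaction."""
    if within.predictions.empty or between.predictions.empty:
        raise ValueError("both prediction sets must be non-empty")
    for name, s in (("within", within), ("between", between)):
        if s.predictions["age_days"].nunique() < 2:
            raise ValueError(f"{name} predictions cover a single age; slope unidentifiable")
    frames = []
    for mode_code, s in ((0.0, within), (1.0, between)):
        f = s.predictions[["age_days", "predicted_age"]].copy()
        f["mode"] = mode_code
        frames.append(f)
    d = pd.concat(frames, ignore_index=True)
    age = d["age_days"].to_numpy(dtype=float)
    mode = d["mode"].to_numpy()
    x = np.column_stack([np.ones(len(d)), age, mode, age * mode])
    y = d["predicted_age"].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    resid = y - fitted
    dof = len(y) - x.shape[1]
    if dof <= 0:
        raise ValueError("too few predictions for the four-coefficient model")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    names = ["alpha", "beta1", "beta2", "beta3"]
    return AgeAccelerationFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(t, index=names),
        pvalues=pd.Series(p, index=names),
        residual_variance=sigma2,
        n=len(y),
        fitted=fitted,
        residuals=resid,
    )


def fisher_overlap(
    panel_size: int, n_a: int, n_c: int, n_shared: int
) -> tuple[np.ndarray, float, float]:
    """2x2 feature-membership table, sample odds ratio, and Fisher p.

    Table cells: [[both, A-only], [C-only, neither]], summing to the panel.
    The odds ratio is the sample (cross-product) estimate ad/bc, reported as
    ``inf`` when bc = 0 with ad > 0 and ``nan`` when both products vanish.
    """
    a_only, c_only = n_a - n_shared, n_c - n_shared
    neither = panel_size - (n_shared + a_only + c_only)
    if min(a_only, c_only, neither) < 0 or n_shared < 0:
        raise ValueError("inconsistent counts: panel smaller than the feature-set union")
    tab = np.array([[n_shared, a_only], [c_only, neither]])
    ad, bc = n_shared * neither, a_only * c_only
    if bc > 0:
        odds = ad / bc
    else:
        odds = float("inf") if ad > 0 else float("nan")
    _, p = stats.fisher_exact(tab)
    return tab, float(odds), float(p)


def compare_features(
    clock_a: ClockModel, clock_c: ClockModel, panel_size: int
) -> FeatureComparison:
    """Compare the nonzero feature sets and coefficients of two clocks.

    Membership overlap is tested by Fisher's exact test on the 2x2 table;
    shared-feature coefficients are compared by Pearson correlation (needs
    at least 3 shared features, otherwise undefined); and per clock a
    two-sided rank-sum test compares |beta| of shared vs clock-unique
    features.
    """
    set_a, set_c = set(clock_a.nonzero_features), set(clock_c.nonzero_features)
    shared = sorted(set_a & set_c)
    if panel_size < len(set_a | set_c):
        raise ValueError("panel_size smaller than the union of feature sets")
    tab, odds, fisher_p = fisher_overlap(panel_size, len(set_a), len(set_c), len(shared))

    corr = corr_p = None
    if len(shared) >= 3:
        r, p = stats.pearsonr(clock_a.coef[shared], clock_c.coef[shared])
        corr, corr_p = float(r), float(p)

    def _ranksum(clock: ClockModel, own: set):
        unique = sorted(own - set(shared))
        if not shared or not unique:
            return None
        stat, p = stats.mannwhitneyu(
            clock.coef[shared].abs(), clock.coef[unique].abs(), alternative="two-sided"
        )
        return float(stat), float(p)

    return FeatureComparison(
        n_features_a=len(set_a),
        n_features_c=len(set_c),
        n_shared=len(shared),
        panel_size=panel_size,
        contingency=tab,
        odds_ratio=odds,
        fisher_p=fisher_p,
        shared_correlation=corr,
        shared_correlation_p=corr_p,
        ranksum_a=_ranksum(clock_a, set_a),
        ranksum_c=_ranksum(clock_c, set_c),
    )
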