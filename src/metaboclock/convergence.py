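"""Metabolomic convergence between selection histories within regimes.

Two complementary tests of whether recently derived populations have
converged on the metabolome of the long-standing populations under the same
selection regime:

1. A covariance-matrix PCA of the normalized metabolome restricted to the
   ages sampled in both regimes, followed by, per component, a mixed model
   ``score ~ age x regime x history + (1 | replicate)``.  Divergence is
   declared when any tested component shows a regime x history or
   regime x history x age effect at unadjusted p < alpha (a deliberately
   liberal criterion: failing even this is strong evidence of convergence).
   Main effects are additionally reported with Bonferroni correction over
   the tested components.

2. A two-component partial least-squares discriminant trained to predict
   regime from the long-standing populations only, then asked to classify
   the recently derived populations it never saw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score, roc_curve

from ._lmm import dummy_columns, fit_ml, interaction_columns, lr_test
from .tables import AbundanceTable

__all__ = [
    "PCModel",
    "PCTestResult",
    "DiscriminationModel",
    "pca_covariance",
    "test_pc_divergence",
    "train_regime_discriminator",
    "predict_regime",
]


@dataclass
class PCModel:
    """PCA of the metabolite covariance matrix (no unit-variance rescaling)."""

    loadings: pd.DataFrame  # metabolites x components
    scores: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    metadata: pd.DataFrame
    mean_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class PCTestResult:
    """Per-component mixed-model term tests with the divergence verdict."""

    table: pd.DataFrame  # index component; columns p_<term>, p_adj_<term>
    n_components_tested: int
    alpha: float
    divergence: bool

    def components_flagging(self) -> list[int]:
        t = self.table
        hit = (t["p_regime_history"] < self.alpha) | (t["p_regime_history_age"] < self.alpha)
        return t.index[hit].tolist()


@dataclass
class DiscriminationModel:
    """Two-class latent-projection (PLS) discriminant for regime."""

    pls: PLSRegression
    metabolites: list[str]
    n_components: int
    threshold: float
    training_accuracy: float
    training_auc: float
    roc: pd.DataFrame
    cv_probabilities: pd.Series = field(repr=False)
    feature_sds: pd.Series = field(repr=False, default=None)

    @property
    def weights(self) -> pd.Series:
        """Projection weights per standardized metabolite unit.

        The raw regression coefficients are per original abundance unit;
        multiplying by the training SD expresses each metabolite's
        contribution on a comparable scale.
        """
        coef = pd.Series(self.pls.coef_.ravel(), index=self.metabolites)
        return coef * self.feature_sds if self.feature_sds is not None else coef


def pca_covariance(table: AbundanceTable, ages: set | None = None) -> PCModel:
    """PCA on the covariance matrix of normalized abundances.

    ``ages`` restricts the analysis to timepoints sampled in every regime
    present (the directly comparable data); metabolites are centered but not
    rescaled, so high-variance metabolites weigh more, as covariance PCA
    intends.
    """
    sub = table
    if ages is not None:
        ages = set(ages)
        for regime in sub.metadata["regime"].unique():
            have = set(sub.metadata.loc[sub.metadata["regime"] == regime, "age_days"])
            missing = ages - have
            if missing:
                raise ValueError(f"regime {regime!r} lacks requested ages {sorted(missing)}")
        sub = sub.subset(sub.metadata["age_days"].isin(ages))
    if sub.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = sub.values.to_numpy()
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCModel(
        loadings=pd.DataFrame(pca.components_.T, index=sub.values.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=sub.values.index, columns=comp_names),
        eigenvalues=pca.explained_variance_,
        variance_explained=pca.explained_variance_ratio_,
        metadata=sub.metadata,
        mean_=pca.mean_,
    )


def _design_blocks(meta: pd.DataFrame):
    age = dummy_columns(meta["age_days"].to_numpy())
    regime = dummy_columns(meta["regime"].to_numpy())
    history = dummy_columns(meta["history"].to_numpy())
    return age, regime, history


def test_pc_divergence(
    pcs: PCModel,
    n_components: int = 12,
    alpha: float = 0.05,
    main_effects: bool = True,
) -> PCTestResult:
    """Mixed-model tests of history divergence on the leading components.

    Per component the fixed design is the full age x regime x history
    factorial (age as an unordered categorical factor) with a random
    replicate intercept; term p-values are hierarchical likelihood-ratio
    tests on ML fits.  The divergence verdict uses the unadjusted
    regime x history and regime x history x age p-values; main effects (if
    requested) are reported Bonferroni-adjusted over the components tested.
    """
    if n_components > pcs.n_components:
        raise ValueError(
            f"requested {n_components} components but only {pcs.n_components} available"
        )
    meta = pcs.metadata
    cells = meta.groupby(["regime", "history", "age_days"], observed=True).size()
    n_cells = (
        meta["regime"].nunique() * meta["history"].nunique() * meta["age_days"].nunique()
    )
    if len(cells) < n_cells:
        raise ValueError("empty (regime, history, age) cell; factorial model unidentifiable")

    age, regime, history = _design_blocks(meta)
    groups = meta["replicate"].to_numpy()
    ones = np.ones((len(meta), 1))
    ar = interaction_columns(age, regime)
    ah = interaction_columns(age, history)
    rh = interaction_columns(regime, history)
    arh = interaction_columns(ar, history)

    x_full = np.hstack([ones, age, regime, history, ar, ah, rh, arh])
    x_two = np.hstack([ones, age, regime, history, ar, ah, rh])
    x_two_no_rh = np.hstack([ones, age, regime, history, ar, ah])
    x_main = np.hstack([ones, age, regime, history])

    rows = []
    for k in range(n_components):
        y = pcs.scores.iloc[:, k].to_numpy()
        full = fit_ml(y, x_full, groups)
        two = fit_ml(y, x_two, groups)
        two_no_rh = fit_ml(y, x_two_no_rh, groups)
        row = {
            "p_regime_history_age": lr_test(full, two),
            "p_regime_history": lr_test(two, two_no_rh),
        }
        if main_effects:
            main = fit_ml(y, x_main, groups)
            for name, block_drop in (
                ("age", np.hstack([ones, regime, history])),
                ("regime", np.hstack([ones, age, history])),
                ("history", np.hstack([ones, age, regime])),
            ):
                red = fit_ml(y, block_drop, groups)
                row[f"p_{name}"] = lr_test(main, red)
        rows.append(row)

    tab = pd.DataFrame(rows, index=pcs.scores.columns[:n_components])
    for col in list(tab.columns):
        tab[col.replace("p_", "p_adj_")] = np.minimum(1.0, tab[col] * n_components)
    divergence = bool(
        ((tab["p_regime_history"] < alpha) | (tab["p_regime_history_age"] < alpha)).any()
    )
    return PCTestResult(
        table=tab, n_components_tested=n_components, alpha=alpha, divergence=divergence
    )


def train_regime_discriminator(
    table: AbundanceTable,
    ages: set = frozenset({21, 28, 35}),
    n_components: int = 2,
    folds: int = 5,
    seed: int = 0,
) -> DiscriminationModel:
    """Fit the PLS regime discriminant on (long-standing) training samples.

    The A regime is coded 1, C coded 0; the continuous PLS prediction is
    clipped to [0, 1] as the class-A probability and thresholded at 0.5.
    Training accuracy and the ROC/AUC are computed from seeded, stratified
    5-fold cross-validated predictions on the training partition; the
    returned projection is refit on all training samples.
    """
    sub = table.subset(table.metadata["age_days"].isin(set(ages)))
    y = (sub.metadata["regime"] == "A").astype(float).to_numpy()
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 samples per regime")
    x = sub.values.to_numpy()
    n_min = int(min((y == 1).sum(), (y == 0).sum()))
    if folds > n_min:
        raise ValueError(
            f"{folds}-fold CV would lose a class (smallest class has {n_min} samples); "
            "reduce folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    prob = np.empty_like(y)
    for train_idx, test_idx in skf.split(x, y):
        pls = PLSRegression(n_components=n_components)
        pls.fit(x[train_idx], y[train_idx])
        prob[test_idx] = np.clip(pls.predict(x[test_idx]).ravel(), 0.0, 1.0)
    accuracy = float(((prob >= 0.5) == (y == 1)).mean())
    auc = float(roc_auc_score(y, prob))
    fpr, tpr, thr = roc_curve(y, prob)
    final = PLSRegression(n_components=n_components)
    final.fit(x, y)
    return DiscriminationModel(
        pls=final,
        metabolites=list(sub.values.columns),
        n_components=n_components,
        threshold=0.5,
        training_accuracy=accuracy,
        training_auc=auc,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        cv_probabilities=pd.Series(prob, index=sub.values.index),
        feature_sds=sub.values.std(axis=0, ddof=0),
    )


def predict_regime(
    model: DiscriminationModel, held_out: AbundanceTable
) -> tuple[pd.DataFrame, float]:
    """Class-A probabilities and accuracy on held-out samples.

    P(A) + P(C) = 1 per sample; the class is decided at probability 0.5.
    """
    missing = [c for c in model.metabolites if c not in held_out.values.columns]
    extra = [c for c in held_out.values.columns if c not in model.metabolites]
    if missing or extra:
        raise ValueError(
            f"metabolite panel mismatch; missing from held-out: {missing[:10]}, "
            f"unexpected: {extra[:10]}"
        )
    x = held_out.values[model.metabolites].to_numpy()
    p_a = np.clip(model.pls.predict(x).ravel(), 0.0, 1.0)
    predicted = np.where(p_a >= model.threshold, "A", "C")
    out = pd.DataFrame(
        {
            "p_A": p_a,
            "p_C": 1.0 - p_a,
            "predicted_regime": predicted,
            "regime": held_out.metadata["regime"].to_numpy(),
        },
        index=held_out.values.index,
    )
    accuracy = float((out["predicted_regime"] == out["regime"]).mean())
    return out, accuracy
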