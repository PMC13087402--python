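"""Model/Results front-end for the QSAR workflow.

Follows the statsmodels idiom: a model object is built from data (here a
descriptor table joined to an activity endpoint, or raw arrays), ``fit()``
returns a results object carrying the estimates and diagnostics, and the
validation machinery — cross-validated Q², Y-randomization, the
applicability domain — hangs off the results object.  ``summary()`` prints
the equation and the statistics table a QSAR report would tabulate.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import domain as _domain
from . import validation as _validation
from .linear import FitResult, LinearModel, fit_ols
from .tables import ActivityTable, DescriptorTable, PipelineConfig, join_tables
from .tree import (
    ClassificationMetrics,
    ConfusionMatrix,
    TreeModel,
    apply_tree,
    classification_metrics,
    cv_classification,
    induce_tree,
)

__all__ = [
    "QSARRegression",
    "QSARRegressionResults",
    "TreeClassifier",
    "TreeClassifierResults",
]


class QSARRegression:
    """Multiple-linear-regression QSAR model specification.

    Parameters
    ----------
    X : (n, p) array
        Descriptor matrix (selected descriptors only).
    y : (n,) array
        Response endpoint (%inhibition, pIC50, ...).
    names : sequence of str, optional
        Descriptor names in column order.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        names: Sequence[str] | None = None,
        ids: Sequence[str] | None = None,
        response_label: str = "y",
        name: str = "qsar",
    ):
        self.X = np.atleast_2d(np.asarray(X, float))
        self.y = np.asarray(y, float).ravel()
        self.names = list(names) if names is not None else [
            f"x{j + 1}" for j in range(self.X.shape[1])
        ]
        self.ids = list(ids) if ids is not None else [
            str(i) for i in range(len(self.y))
        ]
        self.response_label = response_label
        self.name = name

    @classmethod
    def from_tables(
        cls,
        desc: DescriptorTable,
        act: ActivityTable,
        response: str,
        descriptors: Sequence[str] | None = None,
        name: str = "qsar",
    ) -> "QSARRegression":
        """Join a descriptor table with an activity endpoint.

        Rows lacking the endpoint are dropped (never imputed); columns are
        restricted to ``descriptors`` when given.
        """
        sub = desc.select_columns(descriptors) if descriptors is not None else desc
        X, y, ids = join_tables(sub, act, response)
        return cls(
            y, X, names=list(sub.descriptor_names), ids=ids,
            response_label=response, name=name,
        )

    def fit(self) -> "QSARRegressionResults":
        fit = fit_ols(
            self.X, self.y, names=self.names,
            name=self.name, response_label=self.response_label,
        )
        return QSARRegressionResults(self, fit)


class QSARRegressionResults:
    """Fitted QSAR equation plus its validation surface."""

    def __init__(self, model_spec: QSARRegression, fit: FitResult):
        self.model_spec = model_spec
        self.model: LinearModel = fit.model
        self.fittedvalues = fit.fitted_values
        self.resid = fit.residuals
        self.nobs = fit.n
        self.df_model = fit.p
        r2, r2a, rmse, mae, ccc = _validation.regression_metrics(
            model_spec.y, fit.fitted_values, p=fit.p
        )
        self.rsquared = r2
        self.rsquared_adj = r2a
        self.rmse = rmse
        self.mae = mae
        self.ccc = ccc

    @property
    def params(self) -> dict[str, float]:
        out = {"intercept": self.model.intercept}
        out.update(zip(self.model.descriptor_names, self.model.coefficients))
        return out

    def loo(self):
        """Leave-one-out Q², RMSE, MAE, CCC and the LOO predictions."""
        return _validation.q2_loo(self.model_spec.X, self.model_spec.y)

    def kfold(self, k: int = 5, seed: int = 0):
        """k-fold Q², RMSE, fold assignment and pooled predictions."""
        return _validation.q2_kfold(self.model_spec.X, self.model_spec.y, k, seed)

    def validate(self, k: int = 5, seed: int = 0) -> _validation.ValidationReport:
        return _validation.validation_report(
            self.model_spec.X, self.model_spec.y, k=k, seed=seed
        )

    def y_randomization(
        self, n_reps: int = 10, seed: int = 0
    ) -> _validation.YRandomizationReport:
        return _validation.y_randomization(
            self.model_spec.X, self.model_spec.y, n_reps=n_reps, seed=seed
        )

    def applicability_domain(self, variant: str = "simple") -> _domain.ADReport:
        """Leverage/Williams-plot applicability-domain report."""
        h = _domain.leverages(self.model_spec.X)
        h_star = _domain.critical_leverage(self.df_model, self.nobs)
        sr = _domain.standardized_residuals(self.resid, variant=variant, leverage=h)
        in_domain = (h < h_star) & (np.abs(sr) <= _domain.SIGMA_BAND)
        return _domain.ADReport(
            ids=list(self.model_spec.ids),
            leverages=h,
            h_star=h_star,
            standardized_residuals=sr,
            in_domain=in_domain,
            residual_variant=variant,
        )

    def predict(self, table: DescriptorTable) -> np.ndarray:
        from .linear import predict as _predict

        return _predict(self.model, table)

    def summary(self, decimals: int = 4, seed: int = 0, k: int = 5) -> str:
        q2, rmse_loo, mae_loo, ccc_loo, _ = self.loo()
        q2k, rmse_k, _, _ = self.kfold(k=k, seed=seed)
        lines = [
            f"QSAR regression results — {self.model.name}",
            "=" * 58,
            self.model.equation(decimals),
            "-" * 58,
            f"N                    {self.nobs}",
            f"descriptors (p)      {self.df_model}",
            f"R2                   {self.rsquared:.4f}",
            f"R2 adjusted          {self.rsquared_adj:.4f}",
            f"RMSE (train)         {self.rmse:.4f}",
            f"MAE (train)          {self.mae:.4f}",
            f"CCC (train)          {self.ccc:.4f}",
            f"Q2 (LOO)             {q2:.4f}",
            f"RMSE (LOO)           {rmse_loo:.4f}",
            f"Q2 ({k}-fold)          {q2k:.4f}",
            f"RMSE ({k}-fold)        {rmse_k:.4f}",
            "-" * 58,
            f"thresholds: R2>0.6 {'pass' if self.rsquared > 0.6 else 'FAIL'}, "
            f"Q2>0.5 {'pass' if q2 > 0.5 else 'FAIL'}, "
            f"MAE<0.6 {'pass' if self.mae < 0.6 else 'FAIL'}, "
            f"CCC>0.85 {'pass' if self.ccc > 0.85 else 'FAIL'}",
        ]
        return "\n".join(lines)


class TreeClassifier:
    """Gain-ratio decision-tree QSPR classifier specification."""

    def __init__(
        self,
        table: DescriptorTable,
        classes: Sequence[str],
        min_leaf: int = 2,
    ):
        self.table = table
        self.classes = [str(c) for c in classes]
        self.min_leaf = min_leaf

    @classmethod
    def from_tables(
        cls, desc: DescriptorTable, act: ActivityTable, min_leaf: int = 2
    ) -> "TreeClassifier":
        """Classes derive from the activity table: active iff any MIC record."""
        ids = [c for c in desc.compound_ids if c in act]
        if not ids:
            raise ValueError("no shared compounds between tables")
        sub = desc.select_rows(ids)
        classes = [act[c].antimicrobial_class for c in ids]
        return cls(sub, classes, min_leaf=min_leaf)

    def fit(self) -> "TreeClassifierResults":
        tree = induce_tree(self.table, self.classes, min_leaf=self.min_leaf)
        return TreeClassifierResults(self, tree)


class TreeClassifierResults:
    """Induced tree plus training and cross-validated classification metrics."""

    def __init__(self, model_spec: TreeClassifier, tree: TreeModel):
        self.model_spec = model_spec
        self.tree = tree
        self.predicted = apply_tree(tree, model_spec.table)
        self.confusion, self.metrics = classification_metrics(
            model_spec.classes, self.predicted
        )

    def predict(self, table: DescriptorTable) -> list[str]:
        return apply_tree(self.tree, table)

    def cv(
        self, scheme: str = "loo", k: int = 5, seed: int = 0
    ) -> tuple[ConfusionMatrix, ClassificationMetrics]:
        return cv_classification(
            self.model_spec.table,
            self.model_spec.classes,
            scheme=scheme,
            k=k,
            seed=seed,
            min_leaf=self.model_spec.min_leaf,
        )

    def summary(self) -> str:
        cm, m = self.confusion, self.metrics
        lines = [
            "Tree classifier results",
            "=" * 46,
            f"leaves               {self.tree.n_leaves()}",
            f"descriptors used     {', '.join(self.tree.descriptors_used())}",
            f"confusion (tp fp tn fn)  {cm.tp} {cm.fp} {cm.tn} {cm.fn}",
            f"accuracy             {m.accuracy:.2f}",
            f"precision (weighted) {m.precision:.3f}",
            f"recall (weighted)    {m.recall:.3f}",
            f"F-measure (weighted) {m.f_measure:.3f}",
        ]
        return "\n".join(lines)
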