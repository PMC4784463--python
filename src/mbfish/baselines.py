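"""Comparator methods: trend test with Bonferroni / B-H correction, and
L1-penalized logistic selection.

The p-values fed into the corrections come from the same trend-test
code path as the CI-test module, so baseline and MB search disagree
only in strategy, never in the underlying statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .citests import trend_test_all
from .dataset import GenotypeDataset

__all__ = ["SelectionResult", "bonferroni_select", "bh_select", "lasso_select"]


@dataclass
class SelectionResult:
    """Markers selected by one method plus its per-marker evidence."""

    selected: np.ndarray
    method: str
    p_values: np.ndarray | None = None
    coefficients: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.selected)


def _clean_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)  # untestable markers never selected


def bonferroni_select(p_values, alpha: float = 0.05) -> SelectionResult:
    """Select markers with p below the Bonferroni threshold alpha/m."""
    p = _clean_p(p_values)
    selected = np.flatnonzero(p < alpha / p.size)
    return SelectionResult(selected, "bonferroni", p_values=p)


def bh_select(p_values, q: float = 0.05) -> SelectionResult:
    """Benjamini-Hochberg step-up selection at FDR level q."""
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    from statsmodels.stats.multitest import multipletests

    p = _clean_p(p_values)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return SelectionResult(np.flatnonzero(reject), "bh", p_values=p)


def trend_pvalues(data: GenotypeDataset) -> np.ndarray:
    """Armitage trend p-values for every marker (NaN for constants)."""
    return trend_test_all(data.genotypes, data.phenotype)


def lasso_select(
    data: GenotypeDataset,
    lambda_rule: str = "cv1se",
    C: float | None = None,
    n_folds: int = 10,
    n_grid: int = 20,
    seed: int = 0,
) -> SelectionResult:
    """L1-penalized logistic regression over all (standardized) markers.

    With ``lambda_rule='cv1se'`` the penalty is chosen by k-fold
    cross-validated log-loss with the one-standard-error rule (the
    strongest penalty whose mean CV loss is within one SE of the best);
    ``lambda_rule='fixed'`` with ``C`` overrides. Selected markers are
    those with a nonzero coefficient. Non-convergence is surfaced in
    ``extra['converged']``.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import log_loss
    from sklearn.model_selection import StratifiedKFold

    if not data.is_binary_phenotype:
        raise ValueError("lasso_select requires a binary phenotype")
    X = data.genotypes.astype(float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    y = np.asarray(data.phenotype, dtype=float)

    def fit_at(C_val, Xtr, ytr):
        model = LogisticRegression(
            penalty="l1", C=C_val, solver="liblinear", max_iter=2000,
            random_state=seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model.fit(Xtr, ytr)
        converged = not any("onverge" in str(w.message) for w in caught)
        return model, converged

    extra: dict = {"rule": lambda_rule}
    if lambda_rule == "fixed":
        if C is None:
            raise ValueError("fixed lambda_rule requires C")
        chosen_C = C
    elif lambda_rule == "cv1se":
        Cs = np.logspace(-3, 1, n_grid)
        folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        losses = np.zeros((n_grid, n_folds))
        for f, (tr, te) in enumerate(folds.split(X, y)):
            for i, C_val in enumerate(Cs):
                model, _ = fit_at(C_val, X[tr], y[tr])
                prob = model.predict_proba(X[te])[:, 1]
                losses[i, f] = log_loss(y[te], prob, labels=[0.0, 1.0])
        mean = losses.mean(axis=1)
        se = losses.std(axis=1, ddof=1) / np.sqrt(n_folds)
        best = int(np.argmin(mean))
        # smallest C (strongest penalty) within one SE of the best loss
        ok = np.flatnonzero(mean <= mean[best] + se[best])
        chosen_C = float(Cs[ok.min()])
        extra.update(cv_mean_loss=mean, cv_se=se, C_grid=Cs)
    else:
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")

    model, converged = fit_at(chosen_C, X, y)
    coef = model.coef_.ravel()
    extra.update(C=chosen_C, converged=converged)
    if not converged:
        warnings.warn("lasso_select: final fit did not fully converge")
    return SelectionResult(
        np.flatnonzero(np.abs(coef) > 1e-8), "lasso", coefficients=coef, extra=extra
    )
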