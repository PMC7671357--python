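"""Random-forest regression baseline for regulator ranking.

For one gene, an ensemble regression is fit with the gene's cross-sample
expression as the response and candidate lncRNAs' expression as regressors;
candidate regulators are ranked by impurity-based feature importance.  No
importance cutoff is imposed: the full ranking is reported and thresholding
is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from irdl.learner import evaluate_aupr


@dataclass
class RFResult:
    gene_id: str
    lncrna_importances: dict[str, float]
    selected: list[str]  # lncRNA ids, importance descending


def rf_regulator_ranking(
    gene_id: str,
    gene_expr,
    lnc_ids: list[str],
    lnc_expr_matrix,
    n_trees: int = 500,
    seed: int = 0,
    importance: str = "impurity",
) -> RFResult:
    """Rank candidate lncRNA regulators of one gene by RF feature importance.

    ``lnc_expr_matrix`` is lncRNAs x samples, sample-aligned with
    ``gene_expr``.  ``importance`` is ``"impurity"`` (default) or
    ``"permutation"``.  Deterministic under a fixed seed.
    """
    gene_expr = np.asarray(gene_expr, dtype=float)
    lnc_expr_matrix = np.atleast_2d(np.asarray(lnc_expr_matrix, dtype=float))
    if lnc_expr_matrix.shape != (len(lnc_ids), gene_expr.size):
        raise ValueError(
            f"regressor matrix shape {lnc_expr_matrix.shape} does not match "
            f"{len(lnc_ids)} lncRNAs x {gene_expr.size} samples"
        )
    if gene_expr.size < 2:
        raise ValueError("need at least 2 samples for regression")

    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    X = lnc_expr_matrix.T  # samples x lncRNAs
    rf.fit(X, gene_expr)
    if importance == "impurity":
        imp = rf.feature_importances_
    elif importance == "permutation":
        imp = permutation_importance(rf, X, gene_expr, random_state=seed).importances_mean
        imp = np.maximum(imp, 0.0)
    else:
        raise ValueError(f"unknown importance type {importance!r}")

    importances = {lid: float(v) for lid, v in zip(lnc_ids, imp)}
    # stable ranking: importance descending, id ascending on ties
    selected = sorted(lnc_ids, key=lambda lid: (-importances[lid], lid))
    return RFResult(gene_id=gene_id, lncrna_importances=importances, selected=selected)


def compare_methods_aupr(irdl_scores, rf_importances, labels) -> tuple[float, float]:
    """AUPR of the self-training scores and of the RF importances, side by side."""
    return evaluate_aupr(irdl_scores, labels), evaluate_aupr(rf_importances, labels)
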