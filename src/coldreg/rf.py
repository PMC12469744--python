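"""Random-forest baseline on transcription-factor binding-site counts.

Predicts DEG vs non-DEG from per-TF putative-binding-site counts in the
1 kb upstream window (one column per TF plus a total-count column; 413
columns with the canonical 412-motif library). The ensemble itself is
scikit-learn's RandomForestClassifier — the bespoke content here is the
feature construction, the Altmann permutation wrapper for importance
p-values, and the prAUC permutation significance.

Notes on fidelity: mtry maps to ``max_features``; the importance statistic
is sklearn's impurity decrease (MDI), and the Altmann label-permutation
p-values provide the bias correction that ranger's ``impurity_corrected``
mode approximates analytically. prAUC is computed from out-of-bag scores
by default so no extra held-out split is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._seq import count_occurrences
from .cnn import prauc


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 500
    mtry: int = 200
    importance_mode: str = "impurity"
    n_perm_importance: int = 100
    n_perm_prauc: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.mtry < 1:
            raise ValueError("n_trees and mtry must be positive")


TOTAL_COLUMN = "total_tfbs"


def build_feature_table(
    upstream_windows: dict[str, str],
    tfbs_library: list[tuple[str, str]],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Per-gene TFBS occurrence counts plus a total column.

    ``upstream_windows`` maps gene_id -> 1 kb upstream sequence;
    ``tfbs_library`` is a list of (tf_id, consensus) pairs. With a 412-entry
    library the table has 413 columns.
    """
    genes = list(upstream_windows)
    data = {}
    for tf_id, consensus in tfbs_library:
        data[tf_id] = [
            count_occurrences(upstream_windows[g].upper(), consensus, both_strands)
            for g in genes
        ]
    df = pd.DataFrame(data, index=genes, dtype=np.int64)
    df[TOTAL_COLUMN] = df.sum(axis=1) if len(tfbs_library) else 0
    return df


class TFBSRandomForest:
    """Model object: a feature table and binary labels (DEG = 0, non = 1)."""

    def __init__(self, features: pd.DataFrame, labels: np.ndarray):
        self.features = features
        self.labels = np.asarray(labels)
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("labels are single-class; nothing to fit")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels differ in length")

    def fit(self, config: RFConfig = RFConfig()) -> "RFResults":
        X = self.features.to_numpy(dtype=np.float64)
        y = self.labels
        obs = _fit_forest(X, y, config, config.seed)
        rng = np.random.default_rng(config.seed + 1)

        # Altmann importance: refit under shuffled labels, p = (b+1)/(n+1)
        perm_importances = np.empty((config.n_perm_importance, X.shape[1]))
        for b in range(config.n_perm_importance):
            yp = rng.permutation(y)
            perm_importances[b] = _fit_forest(X, yp, config, config.seed + 2 + b, oob=False)[
                "importance"
            ]
        exceed = (perm_importances >= obs["importance"][None, :]).sum(axis=0)
        importance_p = (exceed + 1) / (config.n_perm_importance + 1)

        perm_prauc = np.empty(config.n_perm_prauc)
        for b in range(config.n_perm_prauc):
            yp = rng.permutation(y)
            perm_prauc[b] = _fit_forest(
                X, yp, config, config.seed + 5000 + b
            )["prauc"]
        prauc_p = float(((perm_prauc >= obs["prauc"]).sum() + 1) / (config.n_perm_prauc + 1))

        return RFResults(
            model=self,
            config=config,
            oob_error=obs["oob_error"],
            importances=pd.Series(obs["importance"], index=self.features.columns),
            importance_pvalues=pd.Series(importance_p, index=self.features.columns),
            prauc=obs["prauc"],
            prauc_pvalue=prauc_p,
        )


def _fit_forest(X, y, config: RFConfig, seed: int, oob: bool = True) -> dict:
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=min(config.mtry, X.shape[1]),
        oob_score=oob,
        bootstrap=True,
        n_jobs=1,
        random_state=seed % (2**31),
    )
    clf.fit(X, y)
    out = {"importance": clf.feature_importances_}
    if oob:
        # out-of-bag scores; prAUC with the DEG class (label 0) as positive
        oob_p = clf.oob_decision_function_
        p_deg = np.nan_to_num(oob_p[:, list(clf.classes_).index(0)], nan=0.5)
        pred = (p_deg < 0.5).astype(int)
        out["oob_error"] = float(np.mean(pred != y))
        out["prauc"] = prauc(p_deg, y == 0)
    return out


@dataclass
class RFResults:
    """Fit results: OOB error, per-feature Altmann p-values, prAUC and its
    label-permutation significance."""

    model: TFBSRandomForest
    config: RFConfig
    oob_error: float
    importances: pd.Series
    importance_pvalues: pd.Series
    prauc: float
    prauc_pvalue: float

    def significant_features(self, alpha: float = 0.05) -> pd.Series:
        return self.importance_pvalues[self.importance_pvalues <= alpha].sort_values()

    def summary(self) -> str:
        top = self.importances.sort_values(ascending=False).head(10)
        lines = [
            "TFBS-count random forest baseline",
            "=================================",
            f"n records: {len(self.model.labels)}   n features: {self.model.features.shape[1]}",
            f"trees: {self.config.n_trees}   mtry: {self.config.mtry}",
            f"out-of-bag error: {self.oob_error:.4f}",
            f"prAUC (OOB, DEG positive): {self.prauc:.4f}   "
            f"permutation p ({self.config.n_perm_prauc} shuffles): {self.prauc_pvalue:.3f}",
            "top features by importance (Altmann p):",
        ]
        for name, imp in top.items():
            lines.append(f"  {name:<20s} {imp:8.4f}   p={self.importance_pvalues[name]:.3f}")
        return "\n".join(lines)


def fit_and_evaluate(
    table: pd.DataFrame, labels: np.ndarray, config: RFConfig = RFConfig()
) -> tuple[float, pd.Series, float, float]:
    """Functional wrapper: (oob_error, importance p-values, prauc, prauc_perm_p)."""
    res = TFBSRandomForest(table, labels).fit(config)
    return res.oob_error, res.importance_pvalues, res.prauc, res.prauc_pvalue
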