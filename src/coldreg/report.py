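"""Cross-variant aggregation and comparative statistics for grid results.

Operates purely on ModelRecord tables — no retraining is ever needed to
regenerate a summary. Provides the Kolmogorov-Smirnov comparison of metric
distributions between training variants, generalized-linear(-mixed) models
of hyperparameter effects on performance, and the rank-sum comparison of
discovered-motif counts between correctly and incorrectly predicted genes.

Mixed-model availability: statsmodels fits a gaussian random-intercept
model (MixedLM) and a Bayesian binomial mixed GLM; for Gamma and beta
families no mixed routine exists, so the model falls back to a
fixed-effects-only fit and says so in the returned table's ``random_effect``
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cnn import ModelRecord

VARIANTS = (
    "up_deg", "down_deg", "spiked", "upstream_only",
    "col0_only", "col0_upsampled", "cbf_subset", "no_cbf_snp_subset",
)


@dataclass(frozen=True)
class EffectModelSpec:
    """Which response, which formula, which family.

    The two canonical specs are
    ``class_diff ~ cl * dl + pl + du + (1|fl)`` with a Gamma family and
    ``prauc_test ~ cl * dl * pl + dr + (1|fl)`` with a binomial family.
    """

    response: str = "class_diff"
    family: str = "gamma"

    @property
    def fixed_formula(self) -> str:
        if self.response == "class_diff":
            return "class_diff ~ cl * dl + pl + du"
        if self.response == "prauc_test":
            return "prauc_test ~ cl * dl * pl + dr"
        raise ValueError(f"unknown response {self.response!r}")


def records_frame(records: list[ModelRecord]) -> pd.DataFrame:
    """Flatten records (dropping failed ones) into an analysis table."""
    rows = []
    for r in records:
        if r.error is not None:
            continue
        rows.append(
            {
                "variant": r.variant,
                "cl": r.cl, "fl": r.fl, "pl": r.pl, "dl": r.dl,
                "du": r.du, "dr": r.dr,
                "prauc_train": r.prauc_train,
                "prauc_test": r.prauc_test,
                "class_diff": r.class_diff,
                "acc_class_deg": r.acc_class_deg,
                "acc_class_non": r.acc_class_non,
                "overfit": r.overfit,
            }
        )
    return pd.DataFrame(rows)


def compare_distributions(records_a, records_b, metric: str = "prauc_test"):
    """Two-sample Kolmogorov-Smirnov test on a ModelRecord metric (or on raw
    numeric samples)."""
    a = _metric_values(records_a, metric)
    b = _metric_values(records_b, metric)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 records per side")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def _metric_values(records, metric) -> np.ndarray:
    if len(records) and isinstance(records[0], ModelRecord):
        vals = [getattr(r, metric) for r in records if r.error is None]
    else:
        vals = list(records)
    return np.asarray(vals, dtype=float)


def overfit_fraction(records: list[ModelRecord]) -> dict[str, float]:
    """Fraction of grid points with extreme test prAUC, split by side."""
    pr = _metric_values(records, "prauc_test")
    return {
        "above_0.8": float(np.mean(pr > 0.8)),
        "below_0.2": float(np.mean(pr < 0.2)),
        "total": float(np.mean((pr > 0.8) | (pr < 0.2))),
    }


def fit_effect_model(records, spec: EffectModelSpec) -> pd.DataFrame:
    """Hyperparameter-effect model; returns a coefficient table with columns
    estimate, p_value, sign, plus attrs ``family`` and ``random_effect``.

    Random intercept on fl (first conv layer's filters) where a routine
    exists (gaussian: MixedLM; binomial: Bayesian mixed GLM); otherwise a
    fixed-effects-only GLM with the fallback flagged.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    if df.empty or df[_rhs_terms(spec)].drop_duplicates().shape[0] < 3:
        raise ValueError("rank-deficient design: need variation in the hyperparameters")
    df = df.dropna(subset=[spec.response]).copy()
    random_effect = "fl"
    family = spec.family

    if family == "gaussian":
        if df["fl"].nunique() > 1:
            try:
                fit = smf.mixedlm(spec.fixed_formula, df, groups=df["fl"]).fit(reml=True)
                table = _coef_table(fit.params, fit.pvalues)
                return _attach(table, family, "random intercept (MixedLM)")
            except Exception:
                pass
        fit = smf.ols(spec.fixed_formula, df).fit()
        return _attach(_coef_table(fit.params, fit.pvalues), family, "dropped")

    if family == "binomial" and df["fl"].nunique() > 1:
        try:
            from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

            md = BinomialBayesMixedGLM.from_formula(
                spec.fixed_formula, {"fl": "0 + C(fl)"}, df
            )
            fit = md.fit_vb()
            k = len(fit.fep_mean)
            z = fit.fep_mean / fit.fep_sd
            p = 2 * stats.norm.sf(np.abs(z))
            table = _coef_table(
                pd.Series(fit.fep_mean, index=fit.model.exog_names[:k]),
                pd.Series(p, index=fit.model.exog_names[:k]),
            )
            return _attach(table, family, "random intercept (BayesMixedGLM)")
        except Exception:
            pass

    fam = {
        "binomial": sm.families.Binomial(),
        "gamma": sm.families.Gamma(link=sm.families.links.Log()),
    }.get(family)
    if fam is not None:
        resp = df[spec.response]
        if family == "binomial":
            df[spec.response] = resp.clip(1e-6, 1 - 1e-6)
        elif (resp <= 0).any():
            df[spec.response] = resp.clip(lower=1e-6)
        fit = smf.glm(spec.fixed_formula, df, family=fam).fit()
        return _attach(_coef_table(fit.params, fit.pvalues), family, "dropped")
    if family == "beta":
        from statsmodels.othermod.betareg import BetaModel

        df[spec.response] = df[spec.response].clip(1e-6, 1 - 1e-6)
        fit = BetaModel.from_formula(spec.fixed_formula, df).fit()
        params = fit.params[[i for i in fit.params.index if i != "precision"]]
        pvals = fit.pvalues[params.index]
        return _attach(_coef_table(params, pvals), family, "dropped")
    raise ValueError(f"unknown family {family!r}")


def _rhs_terms(spec: EffectModelSpec) -> list[str]:
    return ["cl", "dl", "pl", "du"] if spec.response == "class_diff" else ["cl", "dl", "pl", "dr"]


def _coef_table(params: pd.Series, pvalues: pd.Series) -> pd.DataFrame:
    table = pd.DataFrame({"estimate": params, "p_value": pvalues})
    table["sign"] = np.sign(table["estimate"]).astype(int)
    return table


def _attach(table: pd.DataFrame, family: str, random_effect: str) -> pd.DataFrame:
    table.attrs["family"] = family
    table.attrs["random_effect"] = random_effect
    return table


def rank_sum_motif_comparison(correct_counts, incorrect_counts):
    """Two-sided Wilcoxon rank-sum test on per-gene discovered-motif counts
    split by prediction correctness. Returns (statistic, p)."""
    x = np.asarray(list(correct_counts), dtype=float)
    y = np.asarray(list(incorrect_counts), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0:
        # ties-only degenerate input: no evidence either way
        return float(x.size * y.size / 2), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def variant_summary(records: list[ModelRecord]) -> pd.DataFrame:
    """Per-variant medians/means of test prAUC and class difference plus
    overfit fractions — the figure-2-style table, from records alone."""
    df = records_frame(records)
    if df.empty:
        return df
    rows = []
    for variant, sub in df.groupby("variant"):
        pr = sub["prauc_test"].to_numpy()
        rows.append(
            {
                "variant": variant,
                "n": len(sub),
                "median_prauc_test": float(np.median(pr)),
                "mean_prauc_test": float(np.mean(pr)),
                "median_class_diff": float(sub["class_diff"].median()),
                "overfit_above_0.8": float(np.mean(pr > 0.8)),
                "overfit_below_0.2": float(np.mean(pr < 0.2)),
            }
        )
    return pd.DataFrame(rows)


def plot_variant_distributions(records: list[ModelRecord], path: str) -> None:
    """Violin plots of test prAUC and class difference per variant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_frame(records)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, metric in zip(axes, ("prauc_test", "class_diff")):
        groups = [g[metric].dropna().to_numpy() for _, g in df.groupby("variant")]
        names = [v for v, _ in df.groupby("variant")]
        if all(len(g) for g in groups):
            ax.violinplot(groups, showmedians=True)
        ax.set_xticks(range(1, len(names) + 1), names, rotation=45, ha="right")
        ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
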