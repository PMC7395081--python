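"""Statistical validation of learned features against clinical metadata.

Three instruments, mirroring how imaging-biomarker candidates are
typically vetted:

* a univariate Pearson correlation screen of every feature against every
  metadata variable, with two-sided tests of zero correlation and no
  multiplicity correction (deliberately — this is an explorative screen,
  and correcting would inflate type II error);
* multiple linear regression from a feature set to each clinical target,
  with elastic-net regularisation, hyper-parameters chosen by 5-fold
  cross-validation over the mixing-ratio grid
  [0.001, 0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 1], evaluated as R^2 and MAE on
  a held-out test split;
* a paired two-sided Wilcoxon signed-rank test on absolute-error
  differences between two regression models on the same test split, at
  significance level 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ValidationError

#: The elastic-net mixing-ratio grid searched by cross-validation.
L1_RATIO_GRID = (0.001, 0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# correlation screen

@dataclass
class CorrelationTable:
    """Pearson r, two-sided p and significance flags per (feature, variable).

    ``undefined`` marks cells where r does not exist (a constant column);
    such cells are flagged, never silently zero.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    undefined: pd.DataFrame
    n: pd.DataFrame
    alpha: float = ALPHA


def _pearson_cell(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan, np.nan, n
    res = sps.pearsonr(xs, ys)
    return float(res.statistic), float(res.pvalue), n


def pearson_screen(features: pd.DataFrame, metadata: pd.DataFrame) -> CorrelationTable:
    """Correlate every feature column with every metadata column.

    Both frames must carry a ``scan_id`` column (rows are aligned on it)
    or already share an index. Pairwise-complete observations are used;
    p-values come from the two-sided t-transform test of zero correlation
    (n - 2 degrees of freedom). No multiplicity correction is applied.
    """
    f = features.set_index("scan_id") if "scan_id" in features.columns else features.copy()
    m = metadata.set_index("scan_id") if "scan_id" in metadata.columns else metadata.copy()
    common = f.index.intersection(m.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 scans common to features and metadata")
    f = f.loc[common].apply(pd.to_numeric, errors="coerce")
    m = m.loc[common].apply(pd.to_numeric, errors="coerce")
    r = pd.DataFrame(index=f.columns, columns=m.columns, dtype=float)
    p = pd.DataFrame(index=f.columns, columns=m.columns, dtype=float)
    n = pd.DataFrame(index=f.columns, columns=m.columns, dtype=int)
    for fc in f.columns:
        for mc in m.columns:
            r_, p_, n_ = _pearson_cell(f[fc].to_numpy(float), m[mc].to_numpy(float))
            r.loc[fc, mc] = r_
            p.loc[fc, mc] = p_
            n.loc[fc, mc] = n_
    undefined = r.isna()
    significant = (p < ALPHA).fillna(False)
    return CorrelationTable(r=r, p=p, significant=significant, undefined=undefined, n=n)


# ---------------------------------------------------------------------------
# elastic-net regression

@dataclass
class RegressionResult:
    """Held-out performance of one penalised linear model."""

    target: str
    feature_set: str
    l1_ratio: float
    penalty: float
    r2: float
    mae_mean: float
    mae_sd: float
    abs_errors: np.ndarray
    predictions: np.ndarray
    test_scan_ids: list[str]
    coef: np.ndarray
    intercept: float
    n_train: int
    n_test: int
    n_dropped: int = 0


def fit_regression_cv(
    features: pd.DataFrame,
    target: pd.Series,
    split: tuple[list[str], list[str]],
    grid: tuple[float, ...] = L1_RATIO_GRID,
    seed: int = 0,
    folds: int = 5,
    feature_set: str = "",
) -> RegressionResult:
    """Elastic-net linear regression with cross-validated hyper-parameters.

    ``features`` must carry a ``scan_id`` column or be indexed by it;
    ``target`` must be indexed by scan_id. ``split`` gives disjoint
    train/test scan_id lists. The grid values are the L1/L2 mixing
    ratios; the penalty strength is searched on an internal logarithmic
    path per ratio, both chosen by minimum mean squared error over
    ``folds`` seeded CV folds. Features are standardised with train-split
    statistics; coefficients are reported on the original scale. Rows
    with a missing target are dropped (counted in ``n_dropped``).
    """
    f = features.set_index("scan_id") if "scan_id" in features.columns else features.copy()
    train_ids, test_ids = list(split[0]), list(split[1])
    if set(train_ids) & set(test_ids):
        raise ValidationError("train and test splits overlap")
    missing = [i for i in train_ids + test_ids if i not in f.index]
    if missing:
        raise ValidationError(f"scan_ids absent from feature table: {missing[:5]}")
    y = pd.to_numeric(target, errors="coerce")

    def _take(ids: list[str]) -> tuple[np.ndarray, np.ndarray, list[str], int]:
        yy = y.reindex(ids)
        keep = yy.notna().to_numpy()
        kept = [i for i, k in zip(ids, keep) if k]
        return (
            f.loc[kept].to_numpy(float),
            yy.loc[kept].to_numpy(float),
            kept,
            int((~keep).sum()),
        )

    x_train, y_train, _, drop_tr = _take(train_ids)
    x_test, y_test, kept_test, drop_te = _take(test_ids)
    if len(y_train) < folds:
        raise ValidationError(f"{len(y_train)} training rows < {folds} CV folds")

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(
        l1_ratio=list(grid), alphas=40, cv=cv, max_iter=20000, tol=1e-6,
    )
    model = Pipeline([("scale", StandardScaler()), ("enet", enet)])
    model.fit(x_train, y_train)
    pred = model.predict(x_test)
    abs_err = np.abs(pred - y_test)
    sse = float(np.sum((y_test - pred) ** 2))
    sst = float(np.sum((y_test - y_test.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    scaler: StandardScaler = model.named_steps["scale"]
    coef = enet.coef_ / scaler.scale_
    intercept = float(enet.intercept_ - np.sum(coef * scaler.mean_))
    return RegressionResult(
        target=str(target.name or "target"),
        feature_set=feature_set,
        l1_ratio=float(enet.l1_ratio_),
        penalty=float(enet.alpha_),
        r2=float(r2),
        mae_mean=float(abs_err.mean()),
        mae_sd=float(abs_err.std()),
        abs_errors=abs_err,
        predictions=pred,
        test_scan_ids=kept_test,
        coef=coef,
        intercept=intercept,
        n_train=len(y_train),
        n_test=len(y_test),
        n_dropped=drop_tr + drop_te,
    )


def evaluate_on(
    result: RegressionResult, features: pd.DataFrame, target: pd.Series, feature_set: str = ""
) -> RegressionResult:
    """Apply a fitted linear model to a new cohort (external validation)."""
    f = features.set_index("scan_id") if "scan_id" in features.columns else features.copy()
    y = pd.to_numeric(target, errors="coerce").reindex(f.index)
    keep = y.notna().to_numpy()
    x = f.loc[keep].to_numpy(float)
    yy = y[keep].to_numpy(float)
    pred = x @ result.coef + result.intercept
    abs_err = np.abs(pred - yy)
    sst = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - float(np.sum((yy - pred) ** 2)) / sst if sst > 0 else np.nan
    return RegressionResult(
        target=result.target,
        feature_set=feature_set or result.feature_set,
        l1_ratio=result.l1_ratio,
        penalty=result.penalty,
        r2=float(r2),
        mae_mean=float(abs_err.mean()),
        mae_sd=float(abs_err.std()),
        abs_errors=abs_err,
        predictions=pred,
        test_scan_ids=list(f.index[keep]),
        coef=result.coef,
        intercept=result.intercept,
        n_train=result.n_train,
        n_test=int(keep.sum()),
        n_dropped=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# paired model comparison

@dataclass
class PairedComparison:
    """Two-sided Wilcoxon signed-rank verdict on paired absolute errors."""

    label: str
    statistic: float | None
    p_value: float | None
    significant: bool
    degenerate: bool
    n_pairs: int
    n_zero_dropped: int
    alpha: float = ALPHA

    @property
    def verdict(self) -> str:
        if self.degenerate:
            return "not significant, degenerate"
        return "significant" if self.significant else "not significant"


def compare_models(a: RegressionResult, b: RegressionResult, label: str = "") -> PairedComparison:
    """Compare two models' absolute errors on the same test split.

    Zero differences are dropped (the classic zero-exclusion convention);
    the exact null distribution is used for n <= 25 remaining pairs, the
    normal approximation with continuity correction above. If all
    differences are zero the comparison is degenerate and reported as
    such rather than with a numeric p.
    """
    if len(a.abs_errors) != len(b.abs_errors):
        raise ValidationError(
            f"error vectors differ in length: {len(a.abs_errors)} vs {len(b.abs_errors)}"
        )
    if a.test_scan_ids != b.test_scan_ids:
        raise ValidationError("compared models were evaluated on different test samples")
    diff = np.asarray(a.abs_errors, float) - np.asarray(b.abs_errors, float)
    nonzero = diff[diff != 0.0]
    n_dropped = len(diff) - len(nonzero)
    label = label or f"{a.feature_set} vs {b.feature_set} ({a.target})"
    if len(nonzero) == 0:
        return PairedComparison(
            label=label, statistic=None, p_value=None, significant=False,
            degenerate=True, n_pairs=0, n_zero_dropped=n_dropped,
        )
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = sps.wilcoxon(
        nonzero, alternative="two-sided", zero_method="wilcox",
        correction=(method == "approx"), method=method,
    )
    return PairedComparison(
        label=label,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < ALPHA),
        degenerate=False,
        n_pairs=len(nonzero),
        n_zero_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# report bundle

@dataclass
class ValidationReport:
    """Collected validation outputs plus the files they were written to."""

    correlations: CorrelationTable | None
    regressions: list[RegressionResult] = field(default_factory=list)
    comparisons: list[PairedComparison] = field(default_factory=list)
    paths: dict[str, Path] = field(default_factory=dict)

    def regression_table(self) -> pd.DataFrame:
        rows = [
            {
                "feature_set": r.feature_set,
                "target": r.target,
                "R2": r.r2,
                "MAE_mean": r.mae_mean,
                "MAE_sd": r.mae_sd,
                "l1_ratio": r.l1_ratio,
                "penalty": r.penalty,
                "n_train": r.n_train,
                "n_test": r.n_test,
                "n_dropped": r.n_dropped,
            }
            for r in self.regressions
        ]
        return pd.DataFrame(rows)

    def comparison_table(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": c.label,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "verdict": c.verdict,
                "n_pairs": c.n_pairs,
                "n_zero_dropped": c.n_zero_dropped,
            }
            for c in self.comparisons
        ]
        return pd.DataFrame(rows)


def build_report(
    correlations: CorrelationTable | None,
    regressions: list[RegressionResult],
    comparisons: list[PairedComparison],
    outdir: str | Path,
) -> ValidationReport:
    """Render the validation bundle: CSV matrices, a correlation heatmap
    with non-significant cells greyed out, and a small HTML summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = ValidationReport(
        correlations=correlations, regressions=regressions, comparisons=comparisons
    )
    sections: list[str] = []
    if correlations is not None:
        correlations.r.to_csv(outdir / "correlation_r.csv")
        correlations.p.to_csv(outdir / "correlation_p.csv")
        correlations.significant.to_csv(outdir / "correlation_significant.csv")
        report.paths["correlation_r"] = outdir / "correlation_r.csv"
        report.paths["correlation_p"] = outdir / "correlation_p.csv"
        heat = _correlation_heatmap(correlations, outdir / "correlation_heatmap.png")
        report.paths["heatmap"] = heat
        sections.append(
            "<h2>Correlation screen</h2>"
            + correlations.r.round(3).to_html()
            + f'<p><img src="{heat.name}" alt="correlation heatmap"/></p>'
            + "<p>No multiplicity correction is applied to the per-cell tests "
            "(explorative screen; greyed cells have p &ge; 0.05).</p>"
        )
    if regressions:
        rt = report.regression_table()
        rt.to_csv(outdir / "regression_summary.csv", index=False)
        report.paths["regression_summary"] = outdir / "regression_summary.csv"
        sections.append("<h2>Regression (held-out)</h2>" + rt.round(4).to_html(index=False))
    if comparisons:
        ct = report.comparison_table()
        ct.to_csv(outdir / "comparisons.csv", index=False)
        report.paths["comparisons"] = outdir / "comparisons.csv"
        sections.append("<h2>Paired model comparisons</h2>" + ct.round(4).to_html(index=False))
    html = (
        "<html><head><title>octmark validation report</title></head><body>"
        "<h1>Validation report</h1>" + "".join(sections) + "</body></html>"
    )
    (outdir / "report.html").write_text(html)
    report.paths["html"] = outdir / "report.html"
    return report


def _correlation_heatmap(corr: CorrelationTable, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = corr.r.to_numpy(float)
    sig = corr.significant.to_numpy(bool)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.5 * r.shape[1] + 2), max(3.0, 0.25 * r.shape[0] + 1.5))
    )
    shown = np.ma.masked_where(~sig, r)
    greyed = np.ma.masked_where(sig, r)
    ax.imshow(greyed, cmap="Greys", vmin=-1, vmax=1, aspect="auto", alpha=0.35)
    im = ax.imshow(shown, cmap="RdYlGn", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(r.shape[1]), corr.r.columns, rotation=45, ha="right")
    ax.set_yticks(range(r.shape[0]), corr.r.index)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("Feature-metadata correlation (grey: p >= 0.05)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
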