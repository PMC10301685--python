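"""Per-cell-line metrics and the benchmark's comparison analyses.

Every model is scored per cell line: for a fixed cell line, predictions
across the test drugs are compared with the measured responses, giving one
Spearman correlation (SCC), Pearson correlation (PCC), RMSE, MSE, R² and
concordance index per cell line; means and standard deviations are then
taken across cell lines. Correlations and the concordance index are
undefined for cell lines with fewer than two pairs or a constant vector on
either side — notably the naive predictor under leave-drugs-out, which
assigns one value per cell line.

On top of the metrics sit the study's comparisons: per-cell-line
improvement over the naive predictor, paired two-sided Wilcoxon
signed-rank contrasts, percent improvement of biological pathways over the
mean of size-matched random collections, pathway-downsampling curves, and
the drug-versus-cell-line response-specificity analysis (Mann-Whitney U
per entity against the global pool, Benjamini-Hochberg FDR per family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pathways import PathwayCollection, downsample_collection
from .prediction import PredictionTable

__all__ = [
    "PerCCLMetrics",
    "ComparisonResult",
    "per_ccl_metrics",
    "improvement_vs_naive",
    "paired_wilcoxon",
    "percent_improvement",
    "downsampling_experiment",
    "response_specificity",
]

METRICS = ("scc", "pcc", "rmse", "mse", "r2", "c_index")


# ---------------------------------------------------------------------------
# metric primitives (authored here; scipy serves as the test oracle)


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks (midranks for ties)."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def _concordance(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Fraction of concordant among comparable pairs.

    Pairs tied in the measured values are non-comparable; ties in the
    predictions among comparable pairs count one half.
    """
    n = len(y_true)
    concordant = 0.0
    comparable = 0
    for i in range(n):
        for j in range(i + 1, n):
            if y_true[i] == y_true[j]:
                continue
            comparable += 1
            d_true = y_true[i] - y_true[j]
            d_pred = y_pred[i] - y_pred[j]
            if d_pred == 0:
                concordant += 0.5
            elif (d_true > 0) == (d_pred > 0):
                concordant += 1.0
    if comparable == 0:
        return np.nan
    return concordant / comparable


def _metrics_one(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    err = y_pred - y_true
    out["mse"] = float(np.mean(err**2))
    out["rmse"] = float(np.sqrt(out["mse"]))
    degenerate = (
        len(y_true) < 2 or np.ptp(y_true) == 0 or np.ptp(y_pred) == 0
    )
    if degenerate:
        out["scc"] = out["pcc"] = out["c_index"] = np.nan
    else:
        out["pcc"] = _pearson(y_true, y_pred)
        out["scc"] = _pearson(_rank(y_true), _rank(y_pred))
        out["c_index"] = _concordance(y_true, y_pred)
    sst = float(((y_true - y_true.mean()) ** 2).sum()) if len(y_true) > 1 else 0.0
    out["r2"] = np.nan if sst == 0 else 1.0 - float((err**2).sum()) / sst
    return out


@dataclass
class PerCCLMetrics:
    """Per-cell-line metric table plus mean/SD aggregates.

    ``table`` has one row per cell line with columns METRICS + n_pairs;
    undefined values are NaN and are excluded from (but counted in) the
    aggregates. SD uses the n-1 denominator.
    """

    table: pd.DataFrame
    aggregates: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = {}
        for m in METRICS:
            vals = self.table[m].dropna()
            rows[m] = {
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "n_defined": len(vals),
                "n_undefined": self.table[m].isna().sum(),
            }
        self.aggregates = pd.DataFrame(rows).T

    def mean(self, metric: str) -> float:
        return float(self.aggregates.loc[metric, "mean"])

    def values(self, metric: str) -> pd.Series:
        return self.table[metric]


def per_ccl_metrics(predictions: PredictionTable) -> PerCCLMetrics:
    """Group predictions by cell line and score each group."""
    if len(predictions) == 0:
        raise ValueError("empty prediction table")
    rows = {}
    for cell, grp in predictions.groupby("cellline_id"):
        y_true = grp["y_true"].to_numpy(dtype=float)
        y_pred = grp["y_pred"].to_numpy(dtype=float)
        rows[cell] = {**_metrics_one(y_true, y_pred), "n_pairs": len(grp)}
    return PerCCLMetrics(pd.DataFrame(rows).T)


def improvement_vs_naive(model: PerCCLMetrics, naive: PerCCLMetrics) -> pd.DataFrame:
    """Per-cell-line deltas, signed so positive always means improvement.

    delta_scc = scc_model - scc_naive; delta_rmse = rmse_naive - rmse_model.
    Undefined inputs propagate as NaN.
    """
    a, b = model.table, naive.table
    if set(a.index) != set(b.index):
        raise ValueError("model and naive metrics cover different cell lines")
    b = b.loc[a.index]
    return pd.DataFrame(
        {
            "delta_scc": a["scc"] - b["scc"],
            "delta_rmse": b["rmse"] - a["rmse"],
        },
        index=a.index,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact small-sample distribution via convolution)


@dataclass
class ComparisonResult:
    n_used: int
    n_zero: int
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    median_diff: float
    all_zero: bool = False


def _exact_sf_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Probability mass of W+ (on doubled ranks) over all sign assignments."""
    total = int(double_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in double_ranks:
        r = int(r)
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt * 0.5
    return pmf


def paired_wilcoxon(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-cell-line values.

    NaN pairs are dropped; zero differences are discarded (signed-rank
    convention). The null distribution is exact (all 2^n sign assignments,
    computed by convolution over midranks) for n <= 25, and a tie-corrected
    normal approximation above. If every difference is zero, p = 1 with the
    ``all_zero`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("no valid pairs")
    d = a - b
    nz = d[d != 0]
    n_zero = int((d == 0).sum())
    med = dict(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        median_diff=float(np.median(d)),
    )
    if len(nz) == 0:
        return ComparisonResult(0, n_zero, 0.0, 1.0, all_zero=True, **med)
    ranks = _rank(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    n = len(nz)
    if n <= 25:
        dr = np.round(2 * ranks).astype(int)
        pmf = _exact_sf_distribution(dr)
        w2 = int(round(2 * w_plus))
        p_low = pmf[: w2 + 1].sum()
        p_high = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return ComparisonResult(n, n_zero, w_plus, p, **med)


# ---------------------------------------------------------------------------
# pathway-control comparisons


def percent_improvement(
    real_metric: float, random_metrics: Sequence[float], metric: str = "scc"
) -> float:
    """Percent gain of biological pathways over the random-collection mean.

    Positive always means the biological collection is better: for
    correlations, 100*(real - mean)/|mean|; for errors (RMSE/MSE),
    100*(mean - real)/mean.
    """
    random_metrics = np.asarray(list(random_metrics), dtype=float)
    if random_metrics.size == 0:
        raise ValueError("need at least one random-collection replicate")
    mean = random_metrics.mean()
    if metric in ("rmse", "mse"):
        return float(100.0 * (mean - real_metric) / mean)
    if mean == 0:
        return np.nan
    return float(100.0 * (real_metric - mean) / abs(mean))


def downsampling_experiment(
    collection: PathwayCollection,
    evaluate: Callable[[PathwayCollection, int], float],
    removal_levels: Sequence[int],
    n_repeats: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Performance as pathways are removed at random.

    For each removal level, ``n_repeats`` independently downsampled
    collections are built and passed (with a repeat seed) to ``evaluate``,
    which trains/scores a model and returns its aggregate metric. Failed
    repeats are recorded and excluded from the mean/SD.
    """
    rows = []
    for li, level in enumerate(removal_levels):
        vals, failures = [], 0
        for rep in range(n_repeats):
            seed = base_seed + 1000 * li + rep
            sub = downsample_collection(collection, level, seed) if level else collection
            try:
                vals.append(float(evaluate(sub, seed)))
            except Exception:  # noqa: BLE001 - a failed repeat must not kill the curve
                failures += 1
        vals = np.asarray(vals)
        rows.append(
            {
                "n_removed": level,
                "n_pathways": collection.m - level,
                "mean": vals.mean() if vals.size else np.nan,
                "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                "n_ok": int(vals.size),
                "n_failed": failures,
            }
        )
    return pd.DataFrame(rows)


def _bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(pvals, method="fdr_bh")[1]


def response_specificity(responses, fdr_q: float = 0.05) -> dict:
    """How drug-specific versus cell-line-specific the responses are.

    For every drug, its response values are compared to the pool of all
    other responses with a two-sided Mann-Whitney U test; likewise per cell
    line. Benjamini-Hochberg FDR is applied within each family, and the
    fraction of entities below ``fdr_q`` is reported. A much larger drug
    fraction than cell-line fraction is the signature of drug-identity-
    dominated responses, the regime in which naive per-drug means already
    rank drugs well for an unseen cell line.
    """
    df = responses.records
    if df["drug_id"].nunique() < 2 or df["cellline_id"].nunique() < 2:
        raise ValueError("need at least 2 drugs and 2 cell lines")
    values = df["value"].to_numpy(dtype=float)

    def family(key: str) -> dict:
        pvals, names, skipped = [], [], 0
        for name, grp in df.groupby(key):
            local = grp["value"].to_numpy(dtype=float)
            if len(local) < 2:
                skipped += 1
                continue
            rest = np.delete(values, grp.index.to_numpy())
            p = stats.mannwhitneyu(local, rest, alternative="two-sided").pvalue
            pvals.append(p)
            names.append(name)
        fdr = _bh_fdr(np.asarray(pvals)) if pvals else np.array([])
        return {
            "n_tested": len(pvals),
            "n_skipped": skipped,
            "fraction_significant": float((fdr < fdr_q).mean()) if len(fdr) else np.nan,
            "fdr": pd.Series(fdr, index=names),
        }

    return {"drugs": family("drug_id"), "celllines": family("cellline_id")}
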