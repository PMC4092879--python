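"""Truth-aware performance metrics and truth-free concordance metrics.

Performance against simulation ground truth: the number of significant
genes Ns, the false positive rate FPR = FP / (# truly non-DE), the true
positive rate TPR = TP / (# truly DE) at BH-FDR cutoffs, and the area
under the ROC curve for ranking DE against non-DE genes.  Concordance
across methods (no truth needed): pairwise Spearman correlations,
intraclass correlation, per-direction Venn-cell overlaps, identification
frequencies and singleton counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "confusion_at_cutoffs",
    "roc_auc",
    "aggregate_scenario",
    "spearman_matrix",
    "icc",
    "overlap_report",
    "concordance_report",
    "ConcordanceReport",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS = (0.1, 0.05, 0.01)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _truth_flags(truth) -> np.ndarray:
    """Boolean truly-DE vector from a TruthTable or an array of d/bool."""
    d = getattr(truth, "d", truth)
    return np.asarray(d) != 0


def confusion_at_cutoffs(result, truth, cutoffs=DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Ns / FP / TP / FPR / TPR at each BH-FDR cutoff for one dataset.

    A gene is called significant when its adjusted p-value is at or below
    the cutoff; false and true positives are split by the simulation
    truth, and the rates use the truth denominators.
    """
    is_de = _truth_flags(truth)
    p_adj = np.asarray(result.p_adjusted, dtype=float)
    if len(p_adj) != len(is_de):
        raise ValueError("result and truth must cover the same genes")
    n_de = int(is_de.sum())
    n_null = int(len(is_de) - n_de)
    rows = []
    for cut in cutoffs:
        called = p_adj <= cut
        tp = int((called & is_de).sum())
        fp = int((called & ~is_de).sum())
        rows.append(
            {
                "method": result.method,
                "fdr_cutoff": cut,
                "ns": tp + fp,
                "fp": fp,
                "tp": tp,
                "fpr": fp / n_null if n_null else np.nan,
                "tpr": tp / n_de if n_de else np.nan,
            }
        )
    return pd.DataFrame(rows)


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve for ranking DE vs non-DE genes.

    Computed via the rank-sum identity with midrank tie handling;
    ``scores`` rank genes by evidence for differential expression
    (e.g. ``1 - p``).  Raises if the truth contains a single class.
    """
    is_de = _truth_flags(truth)
    scores = np.asarray(scores, dtype=float)
    if is_de.all() or not is_de.any():
        raise ValueError("ROC AUC is undefined with a single truth class")
    return float(roc_auc_score(is_de.astype(int), scores))


def aggregate_scenario(per_dataset: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-dataset arithmetic means of per-dataset metric tables.

    Accepts the output of :func:`confusion_at_cutoffs` for each dataset;
    returns the mean of every numeric column by (method, fdr_cutoff).
    """
    if len(per_dataset) == 0:
        raise ValueError("need at least one per-dataset summary")
    stacked = pd.concat(per_dataset, ignore_index=True)
    keys = [k for k in ("method", "fdr_cutoff") if k in stacked.columns]
    return stacked.groupby(keys, as_index=False).mean(numeric_only=True)


def spearman_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations (midranks) of a gene x method table.

    Constant columns yield NaN correlations for their pairs.
    """
    df = pd.DataFrame(values)
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValueError("need >= 2 methods and >= 3 genes")
    with np.errstate(invalid="ignore"):
        rho = stats.spearmanr(df.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    const = df.nunique().to_numpy() <= 1
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def icc(values, log_scale: bool = True) -> float:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    Treats methods as interchangeable raters of a per-gene quantity
    (fold change by default on the log scale).  From the mean squares of
    the two-way layout with n genes (rows) and k methods (columns):

        ICC(2,1) = (MSR - MSE) /
                   (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Raises on degenerate input with zero total variance.
    """
    x = np.asarray(pd.DataFrame(values).to_numpy(), dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 genes and >= 2 methods")
    if log_scale:
        if np.any(x <= 0):
            raise ValueError("log-scale ICC requires strictly positive values")
        x = np.log(x)
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("ICC undefined: zero total variance")
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_err = ((x - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


@dataclass
class ConcordanceReport:
    """Cross-method agreement summary over a shared gene universe."""

    alpha: float
    methods: list[str]
    spearman_fc: pd.DataFrame | None = None
    spearman_p: pd.DataFrame | None = None
    icc_fc: float | None = None
    icc_p: float | None = None
    venn_up: dict[frozenset, int] = field(default_factory=dict)
    venn_down: dict[frozenset, int] = field(default_factory=dict)
    identification_frequency: np.ndarray | None = None
    singletons: dict[str, int] = field(default_factory=dict)
    frequency_summary: pd.DataFrame | None = None

    def venn_frame(self) -> pd.DataFrame:
        rows = [
            {"direction": dname, "methods": "&".join(sorted(cell)), "count": c}
            for dname, cells in (("up", self.venn_up), ("down", self.venn_down))
            for cell, c in sorted(cells.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "methods": self.methods,
            "icc_fc": self.icc_fc,
            "icc_p": self.icc_p,
            "spearman_fc": None if self.spearman_fc is None
            else self.spearman_fc.to_dict(),
            "spearman_p": None if self.spearman_p is None
            else self.spearman_p.to_dict(),
            "venn_up": {"&".join(sorted(k)): v for k, v in self.venn_up.items()},
            "venn_down": {"&".join(sorted(k)): v for k, v in self.venn_down.items()},
            "singletons": self.singletons,
            "identification_frequency":
                None if self.identification_frequency is None
                else self.identification_frequency.tolist(),
        }


def _venn_cells(call_sets: dict[str, np.ndarray]) -> dict[frozenset, int]:
    """Counts of genes called by exactly each non-empty method subset."""
    names = list(call_sets)
    calls = np.column_stack([call_sets[m] for m in names])
    cells: dict[frozenset, int] = {}
    any_called = calls.any(axis=1)
    patterns, counts = np.unique(calls[any_called], axis=0, return_counts=True)
    for pat, c in zip(patterns, counts):
        cells[frozenset(np.array(names)[pat.astype(bool)])] = int(c)
    return cells


def overlap_report(results: list, alpha: float = 0.05) -> ConcordanceReport:
    """Venn overlaps, identification frequencies and singleton counts.

    Significance calls use BH-adjusted p <= ``alpha``.  Directional Venn
    cells (up / down) only include methods that report a direction;
    directionless (posterior-only) methods still contribute to the
    identification-frequency and singleton counts.  Also summarizes the
    distribution of fold changes and p-values by identification
    frequency.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if len(results) < 1:
        raise ValueError("need at least one method result")
    gene_id = np.asarray(results[0].gene_id)
    for r in results[1:]:
        if not np.array_equal(np.asarray(r.gene_id), gene_id):
            raise ValueError("results must share one gene universe")
    methods = [r.method for r in results]
    calls = {r.method: np.asarray(r.p_adjusted) <= alpha for r in results}

    freq = np.sum([calls[m] for m in methods], axis=0)
    singletons = {
        m: int((calls[m] & (freq == 1)).sum()) for m in methods
    }
    directional = [r for r in results if r.direction is not None]
    venn_up = _venn_cells(
        {r.method: calls[r.method] & (r.direction > 0) for r in directional}
    ) if directional else {}
    venn_down = _venn_cells(
        {r.method: calls[r.method] & (r.direction < 0) for r in directional}
    ) if directional else {}

    fc = np.column_stack([r.fc_estimate for r in results]).mean(axis=1)
    pmin = np.column_stack([r.p for r in results]).min(axis=1)
    freq_summary = (
        pd.DataFrame({"frequency": freq, "abs_log2_fc": np.abs(np.log2(fc)),
                      "min_p": pmin})
        .groupby("frequency")
        .agg(n_genes=("min_p", "size"),
             median_abs_log2_fc=("abs_log2_fc", "median"),
             median_min_p=("min_p", "median"))
        .reset_index()
    )
    return ConcordanceReport(
        alpha=alpha,
        methods=methods,
        venn_up=venn_up,
        venn_down=venn_down,
        identification_frequency=freq,
        singletons=singletons,
        frequency_summary=freq_summary,
    )


def concordance_report(results: list, alpha: float = 0.05) -> ConcordanceReport:
    """Full cross-method concordance: correlations, ICC and overlaps."""
    if len(results) < 2:
        raise ValueError("need >= 2 method results for concordance")
    report = overlap_report(results, alpha=alpha)
    fc = pd.DataFrame({r.method: r.fc_estimate for r in results})
    pv = pd.DataFrame({r.method: r.p for r in results})
    report.spearman_fc = spearman_matrix(fc)
    report.spearman_p = spearman_matrix(pv)
    report.icc_fc = icc(fc, log_scale=True)
    # p-values contain exact zeros/ones; ICC on the raw scale
    report.icc_p = icc(pv, log_scale=False)
    return report
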