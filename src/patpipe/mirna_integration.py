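"""miRNA-target integration: target filtering, cumulative-shift (KS) tests,
count-stratified shifts, negative-correlation screening and nested-model
ANOVA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust, bonferroni_adjust

CONTEXT_SCORE_THRESHOLD = -0.2
MIN_TARGETS = 5


@dataclass
class ShiftTestResult:
    set_label: str
    metric: str
    n_targets: int
    n_background: int
    D: float
    p_raw: float
    p_adjusted: float
    direction: int  # sign of targets' median shift vs background

    def __post_init__(self) -> None:
        if not 0.0 <= self.D <= 1.0:
            raise ValueError("KS D must lie in [0, 1]")


def filter_target_pairs(
    pairs: pd.DataFrame,
    threshold: float = CONTEXT_SCORE_THRESHOLD,
    exclusion_list: set[str] | None = None,
) -> pd.DataFrame:
    """Drop low-confidence pairs (context score above ``threshold``) and all
    pairs of excluded miRNAs."""
    keep = pairs["context_score"] <= threshold
    if exclusion_list:
        keep &= ~pairs["mirna_id"].isin(exclusion_list)
    return pairs.loc[keep]


def _ks_shift(
    label: str, metric: str, targets: np.ndarray, background: np.ndarray
) -> ShiftTestResult | None:
    targets = targets[np.isfinite(targets)]
    background = background[np.isfinite(background)]
    if len(targets) < MIN_TARGETS or len(background) < MIN_TARGETS:
        return None
    res = stats.ks_2samp(targets, background)
    direction = int(np.sign(np.median(targets) - np.median(background)))
    return ShiftTestResult(
        set_label=label,
        metric=metric,
        n_targets=len(targets),
        n_background=len(background),
        D=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=float(res.pvalue),  # adjusted later, batch-wise
        direction=direction,
    )


def _finalize(results: list[ShiftTestResult]) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(
            columns=[
                "set_label",
                "metric",
                "n_targets",
                "n_background",
                "D",
                "p_raw",
                "p_adjusted",
                "direction",
            ]
        )
    df = pd.DataFrame([vars(r) for r in results])
    df["p_adjusted"] = bonferroni_adjust(df["p_raw"], n_tests=len(df))
    return df


def target_shift_test(
    pairs: pd.DataFrame,
    metrics: pd.DataFrame,
    metric: str,
    per_mirna: bool = True,
    set_label: str = "pooled",
) -> pd.DataFrame:
    """KS comparison of target vs non-target genes on one metric column.

    ``metrics`` is indexed by gene_id. Per miRNA (default) or pooled over
    all targets; Bonferroni across the batch of tests performed here.
    miRNAs with < 5 targets carrying the metric are skipped.
    """
    vals = metrics[metric]
    results = []
    if per_mirna:
        for mirna, sub in pairs.groupby("mirna_id", sort=True):
            tset = set(sub["gene_id"])
            t = vals[vals.index.isin(tset)].to_numpy(float)
            b = vals[~vals.index.isin(tset)].to_numpy(float)
            r = _ks_shift(str(mirna), metric, t, b)
            if r is not None:
                results.append(r)
    else:
        tset = set(pairs["gene_id"])
        r = _ks_shift(
            set_label,
            metric,
            vals[vals.index.isin(tset)].to_numpy(float),
            vals[~vals.index.isin(tset)].to_numpy(float),
        )
        if r is not None:
            results.append(r)
    return _finalize(results)


def stratified_shift_test(
    strata: pd.Series,
    metrics: pd.DataFrame,
    metric: str,
    bins: list[tuple[int, float]] | None = None,
) -> tuple[pd.DataFrame, float]:
    """KS of each count-stratum vs the whole transcriptome background.

    ``strata`` maps gene_id -> integer count (MRE or CLIP-peak count);
    ``bins`` is a list of (lower, upper) inclusive bounds, default
    {0},{1-2},{3-5},{>=6}. Returns the shift table plus a monotone-trend
    summary (Spearman rho of stratum rank vs stratum median metric).
    """
    if bins is None:
        bins = [(0, 0), (1, 2), (3, 5), (6, np.inf)]
    vals = metrics[metric]
    background = vals.to_numpy(float)
    results = []
    medians = []
    for rank, (lo, hi) in enumerate(bins):
        genes = strata[(strata >= lo) & (strata <= hi)].index
        t = vals[vals.index.isin(set(genes))].to_numpy(float)
        label = f"{lo}" if lo == hi else (f">={lo}" if np.isinf(hi) else f"{lo}-{int(hi)}")
        r = _ks_shift(label, metric, t, background)
        if r is None:
            continue
        results.append(r)
        medians.append((rank, float(np.median(t[np.isfinite(t)]))))
    df = _finalize(results)
    if len(medians) >= 3:
        ranks, meds = zip(*medians)
        trend = float(stats.spearmanr(ranks, meds).statistic)
    else:
        trend = float("nan")
    return df, trend


def negative_correlation_screen(
    mirna_expr: pd.DataFrame,
    gene_metric: pd.DataFrame,
    candidate_pairs: pd.DataFrame,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Pearson screen for negatively correlated miRNA-gene pairs.

    ``mirna_expr`` (miRNAs x samples, e.g. logCPM) and ``gene_metric``
    (genes x samples) must share >= 4 sample columns. Per candidate pair the
    one-sided p-value for r < 0 is computed; BH FDR over tested pairs.
    Zero-variance series are skipped.
    """
    shared = [s for s in mirna_expr.columns if s in gene_metric.columns]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples")
    rows = []
    for _, pair in candidate_pairs.iterrows():
        m, g = pair["mirna_id"], pair["gene_id"]
        if m not in mirna_expr.index or g not in gene_metric.index:
            continue
        x = mirna_expr.loc[m, shared].to_numpy(float)
        y = gene_metric.loc[g, shared].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r, p_two = stats.pearsonr(x, y)
        p_neg = p_two / 2.0 if r < 0 else 1.0 - p_two / 2.0
        rows.append((m, g, float(r), float(p_neg)))
    out = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "pearson_r", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"])
    out["significant"] = (out["pearson_r"] < 0) & (out["fdr"] < fdr_cut)
    return out


def correlation_network(edges: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge tables of the significant negative-correlation network."""
    sig = edges[edges["significant"]]
    nodes = pd.concat(
        [
            pd.DataFrame({"id": sig["mirna_id"].unique(), "kind": "mirna"}),
            pd.DataFrame({"id": sig["gene_id"].unique(), "kind": "gene"}),
        ],
        ignore_index=True,
    )
    edge_table = sig[["mirna_id", "gene_id", "pearson_r", "fdr"]].rename(
        columns={"mirna_id": "source", "gene_id": "target"}
    )
    return nodes, edge_table.reset_index(drop=True)


def nested_model_anova(
    response: np.ndarray, base: np.ndarray, added: np.ndarray
) -> tuple[float, float]:
    """Extra-sum-of-squares F test: does ``added`` improve
    ``response ~ base``? Returns (F, p); collinear covariates give (nan, nan).
    """
    y = np.asarray(response, float)
    mask = np.isfinite(y) & np.isfinite(base) & np.isfinite(added)
    y, b, a = y[mask], np.asarray(base, float)[mask], np.asarray(added, float)[mask]
    n = y.size
    if n < 10:
        raise ValueError("need >= 10 complete cases")
    X0 = np.column_stack([np.ones(n), b])
    X1 = np.column_stack([np.ones(n), b, a])
    if np.linalg.matrix_rank(X1) < 3:
        return float("nan"), float("nan")
    rss0 = np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2)
    rss1 = np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2)
    df_resid = n - 3
    F = (rss0 - rss1) / 1.0 / (rss1 / df_resid)
    p = float(stats.f.sf(F, 1, df_resid))
    return float(F), p
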