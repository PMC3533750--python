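"""Condition-specific differential splice events, confound filtering, and
sample clustering.

Per event, tumor and matched-normal RPKM vectors are compared with a t
test on log2(RPKM + 1): paired across individuals by default (the study
design is matched pairs), Welch's unpaired test as an option.  The fold
change is log2 of the ratio of pseudocounted group means.  The signature
is the set of events below a raw p-value ceiling with linear fold change
above a floor; Benjamini-Hochberg q-values are reported alongside but
take no part in the threshold filters.

Events from genes that are themselves differentially expressed are
removed by the confound filter: differential junction counts there are
expected from expression alone, not from a splicing change.

Samples are clustered agglomeratively on log2 RPKM profiles over the
signature events (correlation distance, average linkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

#: thresholds used throughout the original analysis
PAPER_THRESHOLDS = dict(alpha_strict=1e-4, alpha_loose=1e-3, fc_min=1.5, gene_alpha=0.01)

_TINY_P = np.nextafter(0, 1)


def _pair_columns(
    sample_sheet: pd.DataFrame, condition: str = "tumor", control: str = "normal"
) -> tuple[list[str], list[str]]:
    """Condition/control sample ids aligned by individual."""
    cond, ctrl = [], []
    for individual, group in sample_sheet.groupby("individual_id", sort=True):
        by_cond = group.set_index("condition")["sample_id"]
        if condition not in by_cond.index or control not in by_cond.index:
            raise ValueError(f"individual {individual} lacks a matched pair")
        cond.append(by_cond[condition])
        ctrl.append(by_cond[control])
    return cond, ctrl


def test_events_matrix(
    cond: np.ndarray,
    ctrl: np.ndarray,
    paired: bool = True,
    eps: float = 1.0,
) -> pd.DataFrame:
    """Vectorized per-row location test on log2(x + eps).

    ``cond`` and ``ctrl`` are events x observations arrays; in paired mode
    columns must be aligned by individual.  Returns p_value,
    log2_fold_change, group means and an untestable flag per row.
    Degenerate rows follow fixed conventions: both groups all zero, or
    zero variance with equal means, give p = 1; zero variance with unequal
    means gives the smallest positive p.
    """
    cond = np.asarray(cond, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if cond.ndim == 1:
        cond = cond[None, :]
        ctrl = ctrl[None, :]
    if cond.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need at least two observations per group")
    if paired and cond.shape != ctrl.shape:
        raise ValueError("paired mode requires equal-length, aligned groups")
    lc = np.log2(cond + eps)
    ln = np.log2(ctrl + eps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            res = stats.ttest_rel(lc, ln, axis=1)
        else:
            res = stats.ttest_ind(lc, ln, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    mean_c = cond.mean(axis=1)
    mean_n = ctrl.mean(axis=1)
    log2fc = np.log2((mean_c + eps) / (mean_n + eps))
    equal_means = np.isclose(lc.mean(axis=1), ln.mean(axis=1))
    pvals = np.where(np.isnan(pvals), np.where(equal_means, 1.0, _TINY_P), pvals)
    pvals = np.maximum(pvals, _TINY_P)  # zero-variance unequal means: t=inf, p=0
    untestable = (cond.sum(axis=1) == 0) & (ctrl.sum(axis=1) == 0)
    pvals = np.where(untestable, 1.0, pvals)
    log2fc = np.where(untestable, 0.0, log2fc)
    return pd.DataFrame(
        {
            "p_value": pvals,
            "log2_fold_change": log2fc,
            "mean_rpkm_condition": mean_c,
            "mean_rpkm_control": mean_n,
            "untestable": untestable,
        }
    )


def test_event(
    rpkm_condition: Sequence[float],
    rpkm_control: Sequence[float],
    paired: bool = True,
    eps: float = 1.0,
) -> tuple[float, float]:
    """(p_value, log2_fold_change) for a single event; see test_events_matrix."""
    row = test_events_matrix(
        np.asarray(rpkm_condition, float),
        np.asarray(rpkm_control, float),
        paired=paired,
        eps=eps,
    ).iloc[0]
    return float(row["p_value"]), float(row["log2_fold_change"])


def compute_event_stats(
    rpkm_table: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    paired: bool = True,
    eps: float = 1.0,
    condition: str = "tumor",
    control: str = "normal",
) -> pd.DataFrame:
    """Per-event statistics table over a full RPKM matrix (events x samples)."""
    if paired:
        cond_cols, ctrl_cols = _pair_columns(sample_sheet, condition, control)
    else:
        cond_cols = sample_sheet.loc[sample_sheet.condition == condition, "sample_id"].tolist()
        ctrl_cols = sample_sheet.loc[sample_sheet.condition == control, "sample_id"].tolist()
    stats_df = test_events_matrix(
        rpkm_table[cond_cols].to_numpy(),
        rpkm_table[ctrl_cols].to_numpy(),
        paired=paired,
        eps=eps,
    )
    stats_df.index = rpkm_table.index
    stats_df.index.name = "event_id"
    stats_df["q_value"] = multipletests(stats_df["p_value"], method="fdr_bh")[1]
    return stats_df


def call_signature(
    stats_df: pd.DataFrame, p_max: float = 1e-4, fc_min: float = 1.5
) -> pd.DataFrame:
    """Events with p below ``p_max`` and |linear fold change| above ``fc_min``."""
    mask = (
        (stats_df["p_value"] < p_max)
        & (stats_df["log2_fold_change"].abs() > np.log2(fc_min))
        & ~stats_df["untestable"].astype(bool)
    )
    return stats_df.loc[mask]


def confound_filter(
    signature: pd.DataFrame,
    gene_stats: pd.DataFrame,
    event_genes: Mapping[str, Sequence[str]],
    gene_alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a signature into splicing-driven and expression-confounded events.

    An event is removed iff any of its genes is differentially expressed
    at ``gene_alpha`` (raw p).  Events with no resolvable gene are kept
    and flagged.  Returns (kept, removed), each annotated with the worst
    gene p-value and flags.
    """
    gene_p = gene_stats["p_value"]
    out = signature.copy()
    min_gene_p = np.full(len(out), np.nan)
    unknown = np.zeros(len(out), dtype=bool)
    for i, event_id in enumerate(out.index):
        genes = [g for g in event_genes.get(event_id, []) if g and g != "NULL"]
        known = [g for g in genes if g in gene_p.index]
        if not known:
            unknown[i] = True
            continue
        min_gene_p[i] = min(gene_p[g] for g in known)
    out["gene_p_value"] = min_gene_p
    out["gene_unknown"] = unknown
    out["confounded"] = (min_gene_p < gene_alpha) & ~np.isnan(min_gene_p)
    kept = out.loc[~out["confounded"]]
    removed = out.loc[out["confounded"]]
    return kept, removed


@dataclass
class SampleClustering:
    linkage: np.ndarray
    samples: list[str]
    leaf_order: list[str]
    degenerate: bool = False

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.samples, name="cluster")

    def to_newick(self) -> str:
        """Nested-parenthesis rendering of the tree with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_dist):
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.samples[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(tree, tree.dist) + ";"


def cluster_samples(
    rpkm_table: pd.DataFrame,
    eps: float = 1.0,
    metric: str = "correlation",
    method: str = "average",
) -> SampleClustering:
    """Agglomerative clustering of samples on log2(RPKM + eps) profiles."""
    if rpkm_table.shape[1] < 2 or rpkm_table.shape[0] < 1:
        raise ValueError("need at least two samples and one event")
    profiles = np.log2(rpkm_table.to_numpy().T + eps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dists = pdist(profiles, metric=metric)
    degenerate = bool(np.isnan(dists).any() or np.allclose(dists, 0))
    if degenerate:
        warnings.warn("degenerate distance matrix (constant profiles); tree is arbitrary")
        dists = np.nan_to_num(dists, nan=0.0)
    linkage = hierarchy.linkage(dists, method=method)
    samples = list(rpkm_table.columns)
    order = [samples[i] for i in hierarchy.leaves_list(linkage)]
    return SampleClustering(linkage=linkage, samples=samples,
                            leaf_order=order, degenerate=degenerate)


def cluster_purity(labels: pd.Series, conditions: Mapping[str, str]) -> float:
    """Weighted majority-condition fraction over clusters (1.0 = pure)."""
    df = pd.DataFrame({"cluster": labels})
    df["condition"] = [conditions[s] for s in labels.index]
    correct = sum(
        group["condition"].value_counts().iloc[0] for _, group in df.groupby("cluster")
    )
    return correct / len(df)


def volcano_table(stats_df: pd.DataFrame) -> pd.DataFrame:
    """log2 fold change and -log10 p per event, for volcano plotting."""
    return pd.DataFrame(
        {
            "log2_fold_change": stats_df["log2_fold_change"],
            "neg_log10_p": -np.log10(stats_df["p_value"]),
        },
        index=stats_df.index,
    )
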