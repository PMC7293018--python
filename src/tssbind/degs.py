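"""Per-clone differential expression, cross-clone consensus, and binding
integration.

The DE statistic is deliberately simple plumbing for synthetic counts
(median-of-ratios normalization, Welch t on log2 values, BH adjustment)
— not an edgeR/DESeq2 reimplementation. When published per-clone DEG
tables are available they are read directly and the consensus operates on
those lists, which is the path that reproduces printed counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConsensusSets",
    "BoundFractionReport",
    "call_degs",
    "consensus_sets",
    "bound_fraction_by_cluster",
    "responding_promoters",
    "read_deg_table",
]


@dataclass
class ConsensusSets:
    direction: str
    n_clones: int
    all_clones: set
    at_least_two: set
    union: set

    def __post_init__(self) -> None:
        assert self.all_clones <= self.at_least_two <= self.union


@dataclass
class BoundFractionReport:
    set_name: str
    n_genes: int
    bound_fraction: float
    cluster_fractions: dict[int, float]
    unbound_fraction: float
    missing_from_table: int = 0


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric reference over genes with
    all-positive counts)."""
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no gene with all-positive counts for normalization")
    logc = np.log(counts[pos])
    ref = logc.mean(axis=1)
    sf = np.exp(np.median(logc - ref[:, None], axis=0))
    return sf


def _moderated_t(a: np.ndarray, b: np.ndarray, prior_df: float = 10.0) -> np.ndarray:
    """Two-sample t with empirical-Bayes variance moderation.

    Per-gene pooled variances are squeezed toward the median gene variance
    with ``prior_df`` pseudo-observations; p-values use the augmented
    degrees of freedom. At 2-3 replicates per group a raw Welch test is
    hopelessly noisy in its variance estimate; borrowing strength across
    genes is the standard remedy.
    """
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df
    s2_prior = float(np.median(s2))
    s2_mod = (prior_df * s2_prior + df * s2) / (prior_df + df)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (a.mean(axis=1) - b.mean(axis=1)) / se
    pval = 2 * stats.t.sf(np.abs(t), df + prior_df)
    return np.nan_to_num(pval, nan=1.0)


def call_degs(counts: pd.DataFrame, groups: dict[str, str], contrast: tuple[str, str],
              fc_threshold: float = 1.5, alpha: float = 0.05,
              pseudocount: float = 0.5) -> pd.DataFrame:
    """Two-group DE table for ``contrast = (test, control)``.

    Normalizes by median-of-ratios, applies a variance-moderated t test to
    log2(normalized + pc) between groups, adjusts with Benjamini-Hochberg,
    and calls a gene up (down) when adjusted p < alpha and fold change is
    strictly above the threshold (below its reciprocal). Fold change is
    the ratio of normalized group means. Zero-library samples are dropped
    with a note in ``DataFrame.attrs['warnings']``.
    """
    test, control = contrast
    warnings = []
    totals = counts.sum(axis=0)
    dead = totals[totals == 0].index.tolist()
    if dead:
        warnings.append(f"dropped zero-library samples: {dead}")
        counts = counts.drop(columns=dead)
    cols_t = [c for c in counts.columns if groups.get(c) == test]
    cols_c = [c for c in counts.columns if groups.get(c) == control]
    if len(cols_t) < 2 or len(cols_c) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = counts[cols_t + cols_c].to_numpy(float)
    sf = _size_factors(sub)
    norm = sub / sf
    logv = np.log2(norm + pseudocount)
    a = logv[:, : len(cols_t)]
    b = logv[:, len(cols_t):]
    pval = _moderated_t(a, b)
    _, padj, _, _ = multipletests(pval, method="fdr_bh")
    mean_t = norm[:, : len(cols_t)].mean(axis=1)
    mean_c = norm[:, len(cols_t):].mean(axis=1)
    fc = (mean_t + pseudocount) / (mean_c + pseudocount)
    log2fc = np.log2(fc)
    direction = np.where(
        (padj < alpha) & (fc > fc_threshold), "up",
        np.where((padj < alpha) & (fc < 1.0 / fc_threshold), "down", "unchanged"),
    )
    out = pd.DataFrame(
        {
            f"mean_{test}": mean_t,
            f"mean_{control}": mean_c,
            "log2fc": log2fc,
            "pvalue": pval,
            "padj": padj,
            "direction": direction,
        },
        index=counts.index,
    )
    out.attrs["warnings"] = warnings
    return out


def _direction_set(table, direction: str) -> set:
    if isinstance(table, pd.DataFrame):
        return set(table.index[table["direction"] == direction])
    return set(table)  # already a gene list


def consensus_sets(tables, direction: str) -> ConsensusSets:
    """Exact all-clones and at-least-two intersections over per-clone DEG
    lists (DataFrames from call_degs/read_deg_table, or plain gene lists)."""
    sets = [_direction_set(t, direction) for t in tables]
    if len(sets) < 2:
        raise ValueError("need >= 2 clones")
    union = set().union(*sets)
    all_clones = set.intersection(*sets)
    counts: dict = {}
    for s in sets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    at_least_two = {g for g, c in counts.items() if c >= 2}
    return ConsensusSets(direction, len(sets), all_clones, at_least_two, union)


def bound_fraction_by_cluster(gene_set, binding: dict[str, int],
                              set_name: str = "genes") -> BoundFractionReport:
    """Fractions of a gene set bound in each positional cluster.

    ``binding`` maps gene -> cluster label (1..k, from the gene-level
    reduction: a gene takes the cluster of its highest-scoring promoter
    peak). Genes absent from the table count as unbound and are reported.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    labels = [binding.get(g, 0) for g in genes]
    missing = sum(g not in binding for g in genes)
    n = len(genes)
    clusters = sorted({l for l in labels if l > 0})
    cluster_fractions = {c: labels.count(c) / n for c in clusters}
    unbound = labels.count(0) / n
    return BoundFractionReport(set_name, n, 1.0 - unbound, cluster_fractions,
                               unbound, missing)


def responding_promoters(bound_down, rescued_up) -> set:
    """Genes bound + downregulated in the knockouts that re-activate upon
    re-expression: the exact intersection."""
    return set(bound_down) & set(rescued_up)


def read_deg_table(path, gene_col: str = "gene_id", logfc_col: str = "logFC",
                   p_col: str = "PValue", fdr_col: str = "FDR",
                   fc_threshold: float = 1.5, alpha: float = 0.05,
                   sep: str = "\t") -> pd.DataFrame:
    """Read a published per-clone DEG table (column names configurable) and
    attach a direction call at |FC| > fc_threshold and FDR < alpha."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (gene_col, logfc_col, fdr_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    logfc = df[logfc_col].to_numpy(float)
    fdr = df[fdr_col].to_numpy(float)
    lo = np.log2(fc_threshold)
    direction = np.where(
        (fdr < alpha) & (logfc > lo), "up",
        np.where((fdr < alpha) & (logfc < -lo), "down", "unchanged"),
    )
    out = pd.DataFrame(
        {
            "log2fc": logfc,
            "pvalue": df[p_col] if p_col in df.columns else np.nan,
            "padj": fdr,
            "direction": direction,
        },
        index=df[gene_col],
    )
    return out
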