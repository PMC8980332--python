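"""Cell-type-enriched gene selection from a clustered single-cell count matrix.

Workflow: filter cells on mitochondrial-read fraction (< 20%) and
detected-gene count (> 900, both strict), normalise counts per cell to
ln(1 + count / total x 10,000), then for a target cluster test every
gene expressed in at least ``min_pct`` of either group with a two-sided
Wilcoxon rank-sum test and a log2 fold-change of mean normalised
expression (target vs rest).  Genes with log2FC > 2 and p < 0.05 pass;
a TF list intersects the passing markers into a TF panel for motif
scanning.  No multiple-testing correction enters the ``passes`` flag
(a Benjamini-Hochberg column is reported for reference only).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """A genes x cells count matrix with per-cell cluster labels."""

    genes: list[str]
    cells: list[str]
    counts: np.ndarray  # genes x cells, non-negative
    cluster_of: dict[str, str]
    mito_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.genes)}, {len(self.cells)})"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.cells if c not in self.cluster_of]
        if missing:
            raise ValueError(f"cells without cluster label: {missing[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cluster_labels(self) -> np.ndarray:
        return np.array([self.cluster_of[c] for c in self.cells])

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        cells = [c for c, k in zip(self.cells, keep) if k]
        return ExpressionMatrix(
            genes=list(self.genes),
            cells=cells,
            counts=self.counts[:, keep],
            cluster_of={c: self.cluster_of[c] for c in cells},
            mito_genes=self.mito_genes,
        )


@dataclass(frozen=True)
class MarkerResult:
    gene_id: str
    target_cluster: str
    log2fc: float
    p_value: float
    p_adjusted: float
    pct_in: float
    pct_out: float
    is_tf: bool = False
    passes: bool = False


class EmptyResultError(RuntimeError):
    pass


def qc_filter_cells(
    mat: ExpressionMatrix,
    max_mito_frac: float = 0.20,
    min_genes: int = 900,
) -> ExpressionMatrix:
    """Keep cells with mito fraction strictly below ``max_mito_frac`` and
    strictly more than ``min_genes`` detected genes.

    Both bounds are strict: a cell at exactly 20% mito or exactly 900
    genes is removed.
    """
    totals = mat.counts.sum(axis=0).astype(float)
    mito_idx = [i for i, g in enumerate(mat.genes) if g in mat.mito_genes]
    mito = mat.counts[mito_idx].sum(axis=0).astype(float) if mito_idx else np.zeros(mat.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    genes_detected = (mat.counts > 0).sum(axis=0)
    keep = (mito_frac < max_mito_frac) & (genes_detected > min_genes)
    if not keep.any():
        raise EmptyResultError(
            f"QC removed all {mat.n_cells} cells "
            f"(mito < {max_mito_frac}, genes > {min_genes})"
        )
    return mat.subset_cells(keep)


def normalize(mat: ExpressionMatrix, scale_factor: float = 1e4) -> tuple[ExpressionMatrix, np.ndarray]:
    """Log-normalise: value = ln(1 + count / cell_total x scale_factor).

    Cells with zero total counts are removed with a warning.  Returns
    the (possibly cell-subset) matrix and the aligned normalised array.
    """
    totals = mat.counts.sum(axis=0).astype(float)
    nonzero = totals > 0
    if not nonzero.all():
        warnings.warn(f"removed {int((~nonzero).sum())} zero-count cells before normalisation")
        mat = mat.subset_cells(nonzero)
        totals = totals[nonzero]
    norm = np.log1p(mat.counts / totals * scale_factor)
    return mat, norm


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p via the permutation distribution of the
    rank sum of group a, ties handled through midranks.

    Counts subsets by dynamic programming over doubled midranks (always
    integral), so it stays exact and fast for moderate sample sizes.
    """
    na, nb = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks2 = np.round(stats.rankdata(combined) * 2).astype(int)  # midranks x2
    w_obs = int(ranks2[:na].sum())
    n = na + nb
    mean2 = na * (n + 1)  # doubled expected rank sum
    dev = abs(w_obs - mean2)
    lo, hi = mean2 - dev, mean2 + dev
    # dp[k] maps achievable doubled rank-sum -> number of k-subsets
    dp: list[dict[int, int]] = [dict() for _ in range(na + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for k in range(min(na, n) - 1, -1, -1):
            if not dp[k]:
                continue
            nxt = dp[k + 1]
            for s, cnt in dp[k].items():
                nxt[s + r] = nxt.get(s + r, 0) + cnt
    total = math.comb(n, na)
    extreme = sum(cnt for s, cnt in dp[na].items() if s <= lo or s >= hi)
    return min(1.0, extreme / total)


def rank_sum_test(a, b, exact_max_n: int = 50) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact (tie-aware permutation distribution) when the combined sample
    size is <= ``exact_max_n``; otherwise the normal approximation with
    tie and continuity corrections.  Identical pooled values give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if a.size + b.size <= exact_max_n:
        return _exact_ranksum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def find_markers(
    mat: ExpressionMatrix,
    target_cluster: str,
    log2fc_min: float = 2.0,
    p_max: float = 0.05,
    min_pct: float = 0.25,
    eps: float = 1e-9,
) -> list[MarkerResult]:
    """Per-gene rank-sum test of the target cluster against all other cells.

    Genes expressed (count > 0) in fewer than ``min_pct`` of both groups
    are skipped.  The rank-sum test runs on log-normalised values; the
    log2 fold change is the log-ratio of mean depth-normalised (linear)
    expression with an ``eps`` guard, so a gene whose underlying mean is
    k-fold higher reports log2FC close to log2(k).  Results are sorted
    by (p, -log2fc).
    """
    labels = mat.cluster_labels()
    in_target = labels == target_cluster
    if not in_target.any():
        raise ValueError(f"cluster {target_cluster!r} has no cells")
    if in_target.all():
        raise ValueError("no cells outside the target cluster")
    mat, norm = normalize(mat)
    labels = mat.cluster_labels()
    in_target = labels == target_cluster

    expressed = mat.counts > 0
    pct_in = expressed[:, in_target].mean(axis=1)
    pct_out = expressed[:, ~in_target].mean(axis=1)
    candidates = np.nonzero(np.maximum(pct_in, pct_out) >= min_pct)[0]

    results = []
    target_vals = norm[:, in_target]
    rest_vals = norm[:, ~in_target]
    totals = mat.counts.sum(axis=0).astype(float)
    lin = mat.counts / totals * 1e4  # depth-normalised, linear scale
    lin_t = lin[:, in_target]
    lin_r = lin[:, ~in_target]
    pvals = np.empty(candidates.size)
    for k, gi in enumerate(candidates):
        pvals[k] = rank_sum_test(target_vals[gi], rest_vals[gi])
    padj = (
        stats.false_discovery_control(pvals, method="bh")
        if candidates.size
        else np.array([])
    )
    for k, gi in enumerate(candidates):
        mean_t = float(lin_t[gi].mean())
        mean_r = float(lin_r[gi].mean())
        log2fc = math.log2((mean_t + eps) / (mean_r + eps))
        ok = (
            log2fc > log2fc_min
            and pvals[k] < p_max
            and max(pct_in[gi], pct_out[gi]) >= min_pct
        )
        results.append(
            MarkerResult(
                gene_id=mat.genes[gi],
                target_cluster=target_cluster,
                log2fc=log2fc,
                p_value=float(pvals[k]),
                p_adjusted=float(padj[k]),
                pct_in=float(pct_in[gi]),
                pct_out=float(pct_out[gi]),
                passes=bool(ok),
            )
        )
    results.sort(key=lambda r: (r.p_value, -r.log2fc))
    return results


def passing_markers(
    results: list[MarkerResult],
    log2fc_min: float = 2.0,
    p_max: float = 0.05,
    min_pct: float = 0.25,
) -> list[MarkerResult]:
    return [
        r
        for r in results
        if r.log2fc > log2fc_min
        and r.p_value < p_max
        and max(r.pct_in, r.pct_out) >= min_pct
    ]


def select_tfs(markers: list[MarkerResult], tf_list) -> list[MarkerResult]:
    """Intersect passing markers with a TF gene set, preserving marker order.

    Duplicate ids in the TF list are ignored; an empty intersection
    returns an empty panel with a warning.
    """
    tfs = set(tf_list)
    panel = [replace(r, is_tf=True) for r in markers if r.passes and r.gene_id in tfs]
    if not panel:
        warnings.warn("no passing marker is in the TF list; TF panel is empty")
    return panel


def markers_to_frame(results: list[MarkerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "target_cluster": r.target_cluster,
                "log2fc": r.log2fc,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "pct_in": r.pct_in,
                "pct_out": r.pct_out,
                "is_tf": r.is_tf,
                "passes": r.passes,
            }
            for r in results
        ]
    )


def read_counts_tsv(path, clusters_path, mito_prefix: str = "mt-") -> ExpressionMatrix:
    """Read a genes x cells TSV (first column gene ids) plus a two-column
    cell/cluster TSV; genes starting with ``mito_prefix`` are flagged."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    clusters = pd.read_csv(clusters_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(
        genes=list(df.index),
        cells=list(df.columns),
        counts=df.to_numpy(),
        cluster_of=clusters.to_dict(),
        mito_genes=frozenset(g for g in df.index if g.startswith(mito_prefix)),
    )


def read_tf_list(path) -> list[str]:
    """One TF gene id per line (first column of a TSV); deduplicated."""
    seen, out = set(), []
    with open(path) as fh:
        for line in fh:
            name = line.strip().split("\t")[0]
            if name and not name.startswith("#") and name not in seen:
                seen.add(name)
                out.append(name)
    return out
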