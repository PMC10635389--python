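"""Single-cell spatial count-matrix pipeline.

QC → total-count normalization → Pearson-residual HVG selection → PCA/kNN →
Leiden clustering → marker gating → macrophage exclusion → transcript-count
enrichment classes → Wilcoxon/BH differential expression → Gini markers →
subclustering. Matrices are AnnData objects: raw integer counts in ``X``,
``layers["normalized"]`` and ``layers["scaled"]`` added by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import anndata as ad
import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

T_MIN_DEFAULT = 20
SCALE_CLIP = 10.0
EXACT_RANKSUM_N = 12


@dataclass
class ClusterParams:
    n_hvgs: int = 200
    n_pcs: int = 20
    k_neighbors: int = 15
    resolution: float = 0.1
    iteration_budget: int = 1000
    seed: int = 0

    def validate(self, n_cells: int | None = None) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if n_cells is not None and self.k_neighbors >= n_cells:
            raise ValueError("k_neighbors must be < number of cells")


@dataclass
class GateSpec:
    """Microglia inclusion markers and the macrophage up/down gene matrix."""

    inclusion: tuple[str, ...] = (
        "Csf1r", "Ctss", "Cx3cr1", "Hexb", "Selplg",
        "Itgam", "P2ry12", "Tmem119", "Trem2",
    )
    macrophage_up: tuple[str, ...] = (
        "Crip1", "Cd74", "Fxyd5", "H2-Aa", "H2-Ab1", "H3f3b",
    )
    macrophage_down: tuple[str, ...] = ("Cd9", "Ctsd")
    score_threshold: float = 0.0      # gate score must exceed this
    min_markers_detected: int = 2     # distinct inclusion markers with count>0
    macrophage_percentile: float = 95.0

    def __post_init__(self) -> None:
        up, down = set(self.macrophage_up), set(self.macrophage_down)
        if up & down:
            raise ValueError("macrophage up/down panels overlap")


@dataclass
class EnrichmentRule:
    """Per-cell enrichment by raw transcript count.

    Single-gene mode: cell is enriched when the gene's raw count ≥ k_min.
    Set mode: the summed raw count over the gene set must reach k_min.
    """

    genes: tuple[str, ...]
    k_min: int = 2
    mode: str = "single"              # "single" | "set"

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.mode not in ("single", "set"):
            raise ValueError("mode must be 'single' or 'set'")
        if self.mode == "single" and len(self.genes) != 1:
            raise ValueError("single mode takes exactly one gene")


def _dense(X) -> np.ndarray:
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def qc_filter(adata: ad.AnnData, t_min: int = T_MIN_DEFAULT) -> tuple[ad.AnnData, dict]:
    """Drop cells with fewer than ``t_min`` total transcripts.

    The boundary is inclusive for keeping: a cell with exactly ``t_min``
    transcripts survives. Returns the filtered matrix and an exclusion report.
    """
    X = _dense(adata.X)
    if not np.issubdtype(X.dtype, np.integer) and not np.allclose(X, np.round(X)):
        raise ValueError("counts must be integers")
    totals = X.sum(axis=1)
    keep = totals >= t_min
    if not keep.any():
        raise ValueError("empty after QC")
    out = adata[keep].copy()
    out.obs["total_counts"] = totals[keep]
    report = {
        "n_input": int(adata.n_obs),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "t_min": int(t_min),
    }
    return out, report


def normalize_scale(adata: ad.AnnData) -> ad.AnnData:
    """Add ``normalized`` (per-cell total scaled to the median total) and
    ``scaled`` (log1p then per-gene z-score clipped at ±10) layers in place."""
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero-total cell present; run qc_filter first")
    target = float(np.median(totals))
    norm = X / totals[:, None] * target
    logged = np.log1p(norm)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scaled = np.clip((logged - mu) / sd, -SCALE_CLIP, SCALE_CLIP)
    adata.layers["normalized"] = norm
    adata.layers["scaled"] = scaled
    adata.obs["total_counts"] = totals
    adata.uns["normalization_target"] = target
    return adata


def select_hvg(adata: ad.AnnData, n: int) -> list[str]:
    """Top-``n`` genes by variance of Pearson residuals.

    Residuals are computed against a constant-proportion model (expected
    count = cell total × gene proportion, Poisson error), clipped at √n_cells.
    Ties rank by gene-name order.
    """
    if n > adata.n_vars:
        raise ValueError("n exceeds gene count")
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    colsum = X.sum(axis=0)
    p = colsum / colsum.sum()
    mu = totals[:, None] * p[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(mu > 0, (X - mu) / np.sqrt(mu), 0.0)
    clip = np.sqrt(adata.n_obs)
    resid = np.clip(resid, -clip, clip)
    var = resid.var(axis=0, ddof=0)
    ranking = sorted(zip(-var, adata.var_names))
    return [g for _, g in ranking[:n]]


def pca_knn(
    adata: ad.AnnData, params: ClusterParams, hvgs: list[str] | None = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """PCA of the scaled HVG submatrix and an undirected kNN graph.

    Returns the (cells × n_pcs) embedding and a deduplicated edge list over
    cell indices (Euclidean neighbours in PC space).
    """
    if "scaled" not in adata.layers:
        raise ValueError("scaled layer missing; run normalize_scale")
    params.validate(adata.n_obs)
    if hvgs is None:
        hvgs = list(adata.var_names)
    sub = adata[:, hvgs]
    Z = _dense(sub.layers["scaled"])
    d = params.n_pcs
    if d >= min(Z.shape):
        raise ValueError("n_pcs must be < min(n_cells, n_genes)")
    pca = PCA(n_components=d, svd_solver="full")
    emb = pca.fit_transform(Z)
    # deterministic sign: largest-|loading| coordinate positive per component
    for j in range(d):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            emb[:, j] *= -1
    nn = NearestNeighbors(n_neighbors=params.k_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return emb, sorted(edges)


def leiden_cluster(
    edges: list[tuple[int, int]],
    n_nodes: int,
    resolution: float = 0.1,
    iteration_budget: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Leiden partition of an undirected graph (RB-modularity).

    Labels are renumbered by descending cluster size (ties by first cluster
    id) so output is stable for a fixed seed.
    """
    if n_nodes == 0:
        raise ValueError("empty graph")
    g = ig.Graph(n=n_nodes, edges=list(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        n_iterations=iteration_budget,
        seed=seed,
    )
    raw = np.asarray(part.membership)
    sizes = pd.Series(raw).value_counts().sort_values(ascending=False)
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in raw])


def cluster_pipeline(
    adata: ad.AnnData, params: ClusterParams | None = None
) -> np.ndarray:
    """normalize → HVG → PCA/kNN → Leiden, returning per-cell labels."""
    params = params or ClusterParams()
    if "scaled" not in adata.layers:
        normalize_scale(adata)
    hvgs = select_hvg(adata, min(params.n_hvgs, adata.n_vars))
    _, edges = pca_knn(adata, params, hvgs)
    return leiden_cluster(
        edges, adata.n_obs, params.resolution, params.iteration_budget, params.seed
    )


def gate_microglia(
    adata: ad.AnnData, gate: GateSpec | None = None
) -> tuple[np.ndarray, dict]:
    """Microglia gate: mean scaled expression over inclusion markers.

    A cell passes when its gate score exceeds the threshold AND at least
    ``min_markers_detected`` distinct inclusion markers have nonzero raw
    counts. Returns the boolean mask and a kept-fraction report.
    """
    gate = gate or GateSpec()
    missing = [g for g in gate.inclusion if g not in adata.var_names]
    if missing:
        raise ValueError(f"gate gene(s) absent from panel: {missing}")
    if "scaled" not in adata.layers:
        raise ValueError("scaled layer missing; run normalize_scale")
    sub = adata[:, list(gate.inclusion)]
    score = _dense(sub.layers["scaled"]).mean(axis=1)
    detected = (_dense(sub.X) > 0).sum(axis=1)
    mask = (score > gate.score_threshold) & (detected >= gate.min_markers_detected)
    report = {
        "n_input": int(adata.n_obs),
        "n_kept": int(mask.sum()),
        "kept_fraction": float(mask.mean()),
    }
    return mask, report


def exclude_macrophages(
    adata: ad.AnnData, gate: GateSpec | None = None
) -> tuple[np.ndarray, dict]:
    """Flag macrophages inside a gated microglia subset.

    Macrophage score = mean scaled z over the up-panel − mean over the
    down-panel; cells above max(0, the configured percentile) are removed.
    Returns a keep-mask over the input cells and a report.
    """
    gate = gate or GateSpec()
    for panel in (gate.macrophage_up, gate.macrophage_down):
        missing = [g for g in panel if g not in adata.var_names]
        if missing:
            raise ValueError(f"macrophage panel gene(s) absent: {missing}")
    if "scaled" not in adata.layers:
        raise ValueError("scaled layer missing; run normalize_scale")
    up = _dense(adata[:, list(gate.macrophage_up)].layers["scaled"]).mean(axis=1)
    down = _dense(adata[:, list(gate.macrophage_down)].layers["scaled"]).mean(axis=1)
    score = up - down
    thr = max(0.0, float(np.percentile(score, gate.macrophage_percentile)))
    keep = score <= thr
    report = {
        "n_input": int(adata.n_obs),
        "n_removed": int((~keep).sum()),
        "threshold": thr,
    }
    return keep, report


def classify_enriched(adata: ad.AnnData, rule: EnrichmentRule) -> np.ndarray:
    """Per-cell enrichment class from RAW counts (normalization-invariant)."""
    missing = [g for g in rule.genes if g not in adata.var_names]
    if missing:
        raise ValueError(f"gene(s) absent from panel: {missing}")
    counts = _dense(adata[:, list(rule.genes)].X)
    if rule.mode == "single":
        return counts[:, 0] >= rule.k_min
    return counts.sum(axis=1) >= rule.k_min


# -- rank-sum test ---------------------------------------------------------

def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value with tie correction.

    Exact by full enumeration of labelings when n_a + n_b ≤ 12; otherwise a
    tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    t_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    if n <= EXACT_RANKSUM_N:
        count = 0
        total = 0
        dev = abs(t_obs - mu)
        for combo in combinations(range(n), n_a):
            t = ranks[list(combo)].sum()
            if abs(t - mu) >= dev - 1e-9:
                count += 1
            total += 1
        return count / total
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return 1.0
    z = (t_obs - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def de_wilcoxon(
    adata: ad.AnnData,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    layer: str = "normalized",
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two cell groups with BH adjustment.

    log2FC = log2((mean_A + ε)/(mean_B + ε)) on the chosen layer with
    ε = 1e−9 × median per-cell total.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if (mask_a & mask_b).any():
        raise ValueError("groups overlap")
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs >= 3 cells")
    M = _dense(adata.layers[layer] if layer in adata.layers else adata.X).astype(float)
    A, B = M[mask_a], M[mask_b]
    totals = M.sum(axis=1)
    eps = 1e-9 * float(np.median(totals))
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    lfc = np.log2((mean_a + eps) / (mean_b + eps))
    pvals = np.array([rank_sum_test(A[:, j], B[:, j]) for j in range(M.shape[1])])
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": list(adata.var_names),
        "log2fc": lfc,
        "p_raw": pvals,
        "p_adj": padj,
        "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
    })


def gini_coefficient(values: np.ndarray) -> float:
    """Gini coefficient of a nonnegative vector (0 = uniform)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    s = v.sum()
    if s == 0:
        return 0.0
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * v).sum() / (n * s))


def gini_markers(
    adata: ad.AnnData, labels: np.ndarray, layer: str = "normalized"
) -> pd.DataFrame:
    """Cluster-specificity score per gene: Gini of per-cluster mean expression.

    High Gini means the gene concentrates in few clusters; the assigned
    cluster is the argmax of the per-cluster means. All-zero genes score 0
    and are flagged.
    """
    labels = np.asarray(labels)
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    M = _dense(adata.layers[layer] if layer in adata.layers else adata.X).astype(float)
    order = sorted(clusters, key=str)
    means = np.vstack([M[labels == c].mean(axis=0) for c in order])
    rows = []
    for j, gene in enumerate(adata.var_names):
        col = means[:, j]
        rows.append({
            "gene": gene,
            "gini": gini_coefficient(col),
            "cluster": order[int(np.argmax(col))],
            "all_zero": bool(col.sum() == 0),
        })
    return pd.DataFrame(rows)


def subcluster(
    adata: ad.AnnData,
    labels: np.ndarray,
    selected: list,
    params: ClusterParams | None = None,
    prefix: str = "S",
) -> pd.Series:
    """Re-cluster the cells of selected parent clusters only.

    Runs select_hvg → pca_knn → leiden_cluster on the subset; returns
    namespaced labels (e.g. ``S-0``) indexed like the subset's obs names.
    """
    params = params or ClusterParams()
    labels = np.asarray(labels)
    present = set(labels.tolist())
    missing = [c for c in selected if c not in present]
    if missing:
        raise ValueError(f"selected cluster(s) absent: {missing}")
    mask = np.isin(labels, list(selected))
    if int(mask.sum()) < 2 * params.k_neighbors:
        raise ValueError("subset too small for the neighbor graph")
    sub = adata[mask].copy()
    normalize_scale(sub)
    new = cluster_pipeline(sub, params)
    return pd.Series(
        [f"{prefix}-{c}" for c in new], index=sub.obs_names, name="subcluster"
    )


__all__ = [
    "ClusterParams", "GateSpec", "EnrichmentRule",
    "qc_filter", "normalize_scale", "select_hvg", "pca_knn", "leiden_cluster",
    "cluster_pipeline", "gate_microglia", "exclude_macrophages",
    "classify_enriched", "rank_sum_test", "de_wilcoxon",
    "gini_coefficient", "gini_markers", "subcluster",
]
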