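"""Markdown summary report with ECDF, PCA and cluster-map figures."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def _ecdf_plot(morpho: pd.DataFrame, path: Path) -> bool:
    fim = morpho[morpho["region"] == "fimbria"].dropna(subset=["angle_offset"])
    if fim.empty:
        return False
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sub in fim.groupby("group", observed=True):
        v = sub["angle_offset"].sort_values()
        ax.step(v, (1 + pd.RangeIndex(len(v))) / len(v), where="post", label=str(g))
    ax.set_xlabel("tract-angle offset (deg)")
    ax.set_ylabel("ECDF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return True


def _pca_plot(index: pd.DataFrame, path: Path) -> bool:
    if not {"PC1", "PC2"}.issubset(index.columns):
        return False
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sub in index.groupby("group", observed=True):
        ax.scatter(sub["PC1"], sub["PC2"], label=str(g))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return True


def _cluster_map(clusters: pd.DataFrame, path: Path) -> bool:
    if clusters[["x", "y"]].isna().all().all():
        return False
    fig, ax = plt.subplots(figsize=(5, 4))
    for c, sub in clusters.groupby("cluster", observed=True):
        ax.scatter(sub["x"], sub["y"], s=4, label=str(c))
    ax.invert_yaxis()
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.legend(markerscale=2, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return True


def make_report(run_dir: str | Path) -> Path:
    """Summarize a completed run directory into report.md (+ PNG figures)."""
    run_dir = Path(run_dir)
    lines = ["# gliamap run report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        lines += [
            f"- seed: {manifest['seed']}",
            f"- config hash: `{manifest['config_hash'][:16]}…`",
            f"- stages: {', '.join(manifest['stages'])}",
            "",
        ]
    stats_path = run_dir / "stats.json"
    if stats_path.exists():
        stats = json.loads(stats_path.read_text(encoding="utf-8"))
        lines.append("## Spatial statistics\n")
        lines.append("```json")
        lines.append(json.dumps(stats, indent=1)[:4000])
        lines.append("```\n")
    morpho_path = run_dir / "stratified.csv"
    if morpho_path.exists() and _ecdf_plot(pd.read_csv(morpho_path), run_dir / "ecdf.png"):
        lines += ["## Tract-alignment ECDF", "", "![ecdf](ecdf.png)", ""]
    index_path = run_dir / "index.csv"
    if index_path.exists() and _pca_plot(pd.read_csv(index_path), run_dir / "pca.png"):
        lines += ["## Composite phenotyping index", "", "![pca](pca.png)", ""]
    clusters_path = run_dir / "clusters.csv"
    if clusters_path.exists() and _cluster_map(
        pd.read_csv(clusters_path), run_dir / "clusters.png"
    ):
        lines += ["## Cluster map", "", "![clusters](clusters.png)", ""]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines), encoding="utf-8")
    return out


__all__ = ["make_report"]
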