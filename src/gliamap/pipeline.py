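"""Run configuration and the end-to-end pipeline driver.

A run writes every stage output plus a manifest (config hash, seed, stage
order, file checksums) so reruns with the same config are byte-verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gliamap import io as gio
from gliamap import morphometrics as gm
from gliamap import spatialstats as gs
from gliamap import transcriptomics as gt
from gliamap.synthetic import (
    default_counts_config,
    default_scene_config,
    simulate_counts,
    simulate_section,
)
from gliamap.transcriptomics import ClusterParams, EnrichmentRule, GateSpec


@dataclass
class RunConfig:
    """Every stage default in one serializable object. Unknown keys reject."""

    seed: int = 0
    groups: tuple[str, ...] = ("YNG", "OLD")
    mice_per_group: int = 3
    reference_group: str = "YNG"
    threshold_k: float = 2.0
    qc_min_transcripts: int = 20
    n_genes: int = 400
    dam_lfc: float = 2.0
    enrichment_genes: tuple[str, ...] = ("Lgals3", "Cdkn2a")
    enrichment_min_count: int = 2
    cluster: ClusterParams = field(default_factory=ClusterParams)
    verbosity: int = 1

    def validate(self) -> None:
        self.cluster.validate()
        if self.reference_group not in self.groups:
            raise ValueError("reference_group must be one of groups")
        if self.qc_min_transcripts < 0:
            raise ValueError("qc_min_transcripts must be >= 0")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be > 0")
        if self.enrichment_min_count < 1:
            raise ValueError("enrichment_min_count must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["enrichment_genes"] = list(self.enrichment_genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "cluster" in d and isinstance(d["cluster"], dict):
            ck = {f.name for f in dataclasses.fields(ClusterParams)}
            cu = set(d["cluster"]) - ck
            if cu:
                raise ValueError(f"unknown cluster key(s): {sorted(cu)}")
            d["cluster"] = ClusterParams(**d["cluster"])
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        if "enrichment_genes" in d:
            d["enrichment_genes"] = tuple(d["enrichment_genes"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _stratify(outdir: Path, config: RunConfig) -> None:
    morpho = pd.read_csv(outdir / "morphometrics.csv")
    from gliamap.scene import SectionScene

    scene = SectionScene.from_json(outdir / "scene.json")
    stats: dict = {}

    ref = morpho[morpho["group"] == config.reference_group]
    calls = {}
    for ch in ("GAL3", "APOE"):
        spec = gs.derive_threshold(
            ref[f"norm_{ch}"].to_numpy(), config.threshold_k,
            reference_group=config.reference_group, channel=ch,
        )
        stats[f"threshold_{ch}"] = dataclasses.asdict(spec)
        calls[ch] = gm.marker_calls(morpho, f"norm_{ch}", spec.threshold)
        morpho[f"{ch}_positive"] = calls[ch]

    # densities per mouse x region
    rows = []
    for (mouse, region), sub in morpho.groupby(["mouse", "region"], observed=True):
        rows.append({
            "mouse": mouse, "group": sub["group"].iloc[0], "region": region,
            "n_cells": len(sub),
            "density_mm2": gm.cell_density(len(sub), scene.regions[region]),
            "mean_area": sub["area"].mean(),
            "mean_circularity": sub["circularity"].mean(),
            "mean_angle_offset": sub["angle_offset"].mean(),
            "gal3_pct": 100.0 * sub["GAL3_positive"].mean(),
        })
    density = pd.DataFrame(rows)
    fim = density[density["region"] == "fimbria"]
    if fim["group"].nunique() >= 2 and (fim.groupby("group").size() >= 2).all():
        cmp_res = gs.group_compare(
            fim["density_mm2"].to_numpy(), fim["group"].to_numpy(),
            config.reference_group,
        )
        stats["density_anova"] = {
            "F": cmp_res.f_statistic, "p": cmp_res.p_anova,
            "comparisons": cmp_res.comparisons.to_dict(orient="records"),
        }

    # KS on tract-angle offsets, reference vs each other group (fimbria cells)
    fcells = morpho[morpho["region"] == "fimbria"]
    ref_off = fcells.loc[fcells["group"] == config.reference_group, "angle_offset"]
    stats["ks_angle_offset"] = {}
    for g in config.groups:
        if g == config.reference_group:
            continue
        other = fcells.loc[fcells["group"] == g, "angle_offset"]
        if len(ref_off) >= 2 and len(other) >= 2:
            ks = gs.ks_two_sample(ref_off.dropna(), other.dropna())
            stats["ks_angle_offset"][g] = dataclasses.asdict(ks)

    # composite phenotyping index over per-mouse fimbria features
    feats = fim.set_index("mouse")[
        ["density_mm2", "mean_area", "mean_circularity", "mean_angle_offset"]
    ]
    if len(feats) >= 3:
        idx = gs.composite_pca_index(feats)
        scores = pd.DataFrame(
            idx.scores, index=feats.index,
            columns=[f"PC{i+1}" for i in range(idx.scores.shape[1])],
        ).reset_index()
        scores = scores.merge(
            fim[["mouse", "group"]].drop_duplicates(), on="mouse"
        )
        scores.to_csv(outdir / "index.csv", index=False)
        stats["index_variance_explained"] = idx.variance_explained.tolist()

    # APOE+ distance statistics in the fimbria
    apoe = fcells[fcells["APOE_positive"]]
    if len(apoe) and scene.midline is not None:
        pts = apoe[["cx", "cy"]].to_numpy()
        dist = pd.DataFrame({
            "cell_id": apoe["cell_id"].to_numpy(),
            "group": apoe["group"].to_numpy(),
            "midline_distance": gs.distance_to_polyline(pts, scene.midline),
        })
        if scene.ventricle is not None:
            dist["ventricle_distance"] = gs.distance_to_polyline(pts, scene.ventricle)
            dist["signed_midline_offset"] = gs.signed_midline_offset(
                pts, scene.midline, scene.ventricle
            )
        dist.to_csv(outdir / "distances.csv", index=False)
        stats["midline_distance_by_group"] = (
            dist.groupby("group")["midline_distance"].mean().to_dict()
        )

    gio.write_tables(outdir, densities=density, stratified=morpho)
    (outdir / "stats.json").write_text(
        json.dumps(stats, indent=1, default=float), encoding="utf-8"
    )


def _cluster_stage(outdir: Path, config: RunConfig) -> None:
    adata = gio.read_counts(outdir / "counts" / "counts.mtx")
    adata, qc_report = gt.qc_filter(adata, config.qc_min_transcripts)
    gt.normalize_scale(adata)
    gate = GateSpec()
    mask, gate_report = gt.gate_microglia(adata, gate)
    glia = adata[mask].copy()
    gt.normalize_scale(glia)
    keep, mac_report = gt.exclude_macrophages(glia, gate)
    glia = glia[keep].copy()
    gt.normalize_scale(glia)
    labels = gt.cluster_pipeline(glia, config.cluster)
    clusters = pd.DataFrame({
        "cell_id": list(glia.obs_names),
        "cluster": labels,
        "x": glia.obs["x"].to_numpy() if "x" in glia.obs else np.nan,
        "y": glia.obs["y"].to_numpy() if "y" in glia.obs else np.nan,
        "region": glia.obs["region"].to_numpy() if "region" in glia.obs else "",
    })
    if pd.Series(labels).nunique() >= 2:
        markers = gt.gini_markers(glia, labels)
    else:  # single cluster: marker specificity undefined
        markers = pd.DataFrame(columns=["gene", "gini", "cluster", "all_zero"])
    gio.write_tables(outdir, clusters=clusters, markers=markers)
    (outdir / "cluster_report.json").write_text(
        json.dumps({"qc": qc_report, "gate": gate_report, "macrophage": mac_report},
                   indent=1, default=float),
        encoding="utf-8",
    )


def _enrich_stage(outdir: Path, config: RunConfig) -> None:
    adata = gio.read_counts(outdir / "counts" / "counts.mtx")
    adata, _ = gt.qc_filter(adata, config.qc_min_transcripts)
    clusters = pd.read_csv(outdir / "clusters.csv")
    glia = adata[adata.obs_names.isin(clusters["cell_id"])].copy()
    out = pd.DataFrame({"cell_id": list(glia.obs_names)})
    for gene in config.enrichment_genes:
        rule = EnrichmentRule((gene,), config.enrichment_min_count, "single")
        out[f"{gene}_enriched"] = gt.classify_enriched(glia, rule)
    cdkn = tuple(g for g in ("Cdkn1a", "Cdkn1b", "Cdkn2a", "Cdkn2d")
                 if g in glia.var_names)
    if len(cdkn) >= 2:
        out["cdkn_set_enriched"] = gt.classify_enriched(
            glia, EnrichmentRule(cdkn, config.enrichment_min_count, "set")
        )
    gio.write_tables(outdir, enrichment=out)


def _de_stage(outdir: Path, config: RunConfig) -> None:
    adata = gio.read_counts(outdir / "counts" / "counts.mtx")
    adata, _ = gt.qc_filter(adata, config.qc_min_transcripts)
    enrich = pd.read_csv(outdir / "enrichment.csv")
    gene = config.enrichment_genes[0]
    glia = adata[adata.obs_names.isin(enrich["cell_id"])].copy()
    gt.normalize_scale(glia)
    flag = enrich.set_index("cell_id")[f"{gene}_enriched"].loc[glia.obs_names]
    mask_a = flag.to_numpy(dtype=bool)
    if mask_a.sum() < 3 or (~mask_a).sum() < 3:
        raise ValueError(f"too few cells for the {gene} contrast")
    de = gt.de_wilcoxon(glia, mask_a, ~mask_a)
    de.to_csv(outdir / "de.csv", index=False)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages on synthetic data; returns the manifest dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    def _stage(name: str, fn) -> None:
        try:
            fn()
            stages.append(name)
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    def _simulate_section() -> None:
        cfg = default_scene_config(config.seed, config.groups, config.mice_per_group)
        scene, cells, tracts, truth = simulate_section(cfg)
        gio.write_tables(outdir, cells=cells, tracts=tracts, truth_cells=truth)
        scene.to_json(outdir / "scene.json")
        gio.write_data_dictionary(outdir)

    def _morpho() -> None:
        cells = pd.read_csv(outdir / "cells.csv")
        tracts = pd.read_csv(outdir / "tracts.csv")
        morpho = gm.compute_morphometrics(
            cells, tracts, reference_group=config.reference_group
        )
        morpho.to_csv(outdir / "morphometrics.csv", index=False)

    def _simulate_counts() -> None:
        from gliamap.scene import SectionScene

        scene = SectionScene.from_json(outdir / "scene.json")
        ccfg = default_counts_config(
            config.seed, n_genes=config.n_genes, dam_lfc=config.dam_lfc
        )
        adata, truth = simulate_counts(ccfg, scene)
        gio.write_counts(adata, outdir / "counts")
        truth.to_csv(outdir / "truth_counts.csv", index=False)

    _stage("simulate-section", _simulate_section)
    _stage("morpho", _morpho)
    _stage("stratify", lambda: _stratify(outdir, config))
    _stage("simulate-counts", _simulate_counts)
    _stage("cluster", lambda: _cluster_stage(outdir, config))
    _stage("enrich", lambda: _enrich_stage(outdir, config))
    _stage("de", lambda: _de_stage(outdir, config))

    files = sorted(
        p for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": stages,
        "checksums": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1), encoding="utf-8"
    )
    return manifest


__all__ = ["RunConfig", "run_pipeline"]
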