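"""Simulate per-cell spatial count matrices with planted cell-type signatures.

Counts are negative binomial around type-specific mean vectors with lognormal
per-cell library-size scaling. Cell types are placed region by region so that
disease-associated (DAM/senescent) cells concentrate in white matter, and a
set of genes carries a planted log2 fold-change between DAM and homeostatic
microglia for differential-expression power checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from gliamap.scene import SectionScene
from gliamap.synthetic.scene_sim import _poisson_points, _substream

GATE_GENES = (
    "Csf1r", "Ctss", "Cx3cr1", "Hexb", "Selplg",
    "Itgam", "P2ry12", "Tmem119", "Trem2",
)
MACROPHAGE_UP = ("Crip1", "Cd74", "Fxyd5", "H2-Aa", "H2-Ab1", "H3f3b")
MACROPHAGE_DOWN = ("Cd9", "Ctsd")
KEY_GENES = (
    "Lgals3", "Cdkn2a", "Cdkn1a", "Cdkn1b", "Cdkn2d", "Spp1",
    "Lyz1", "Lyz2", "Bcl2", "Apoe", "Itgax",
    "Plp1", "Mbp", "Mog", "Gfap", "Aqp4", "Slc1a2",
)


@dataclass
class CountsConfig:
    """Panel, type signatures and noise model for count simulation.

    ``type_means`` maps cell type -> {gene: mean count at library size 1};
    genes absent from a type's dict default to ``baseline_mean``. The panel
    always contains the gating and macrophage-matrix genes.
    """

    seed: int = 0
    genes: tuple[str, ...] = ()
    type_means: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_mean: float = 0.05
    nb_dispersion: float = 2.0          # NB size; np.inf -> Poisson limit
    cells_per_region: dict[str, dict[str, int]] = field(default_factory=dict)
    libsize_sigma: float = 0.35
    planted_lfc: dict[str, float] = field(default_factory=dict)  # DAM vs homeostatic
    fov_size_um: float = 500.0

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be >= 0")
        panel = set(self.genes)
        for g in (*GATE_GENES, *MACROPHAGE_UP, *MACROPHAGE_DOWN):
            if g not in panel:
                raise ValueError(f"gate/matrix gene missing from panel: {g}")
        for tname, means in self.type_means.items():
            for g, m in means.items():
                if g not in panel:
                    raise ValueError(f"type {tname} references unknown gene {g}")
                if m < 0:
                    raise ValueError("means must be >= 0")


def _filler(n: int) -> tuple[str, ...]:
    return tuple(f"Gene{i:04d}" for i in range(n))


def default_counts_config(
    seed: int = 0,
    n_genes: int = 1000,
    n_de_genes: int = 10,
    dam_lfc: float = 2.0,
    cells: dict[str, dict[str, int]] | None = None,
) -> CountsConfig:
    """Panel of ``n_genes`` with five planted cell types.

    DAM cells carry ``dam_lfc`` log2 fold-change over homeostatic microglia in
    ``n_de_genes`` dedicated genes (named ``DEplus###``) plus the canonical
    DAM/senescence markers; macrophages mimic microglia in the gate genes but
    show the up/down matrix signature used for exclusion.
    """
    de_genes = tuple(f"DEplus{i:03d}" for i in range(n_de_genes))
    named = (*GATE_GENES, *MACROPHAGE_UP, *MACROPHAGE_DOWN, *KEY_GENES, *de_genes)
    genes = named + _filler(max(0, n_genes - len(named)))

    homeostatic = {g: 3.0 for g in GATE_GENES}
    homeostatic.update({"P2ry12": 5.0, "Tmem119": 4.0, "Cx3cr1": 5.0,
                        "Cd9": 1.0, "Ctsd": 1.5, "Apoe": 0.5})
    homeostatic.update({g: 0.5 for g in de_genes})

    # DAM keep most sensing markers high; only the homeostatic triad drops
    dam = {"Csf1r": 3.0, "Ctss": 4.0, "Hexb": 4.0, "Trem2": 5.0,
           "Itgam": 3.0, "Selplg": 2.0}
    dam.update({"P2ry12": 0.8, "Tmem119": 0.6, "Cx3cr1": 0.8,
                "Apoe": 8.0, "Lgals3": 10.0, "Spp1": 5.0, "Itgax": 3.0,
                "Cdkn2a": 1.5, "Cdkn1a": 1.0, "Lyz1": 2.0, "Lyz2": 2.0,
                "Bcl2": 1.5, "Cd9": 2.0, "Ctsd": 3.0})
    dam.update({g: homeostatic[g] * 2.0**dam_lfc for g in de_genes})

    macrophage = {"Csf1r": 2.0, "Itgam": 2.0, "Ctss": 2.0, "Hexb": 1.0,
                  "Selplg": 1.0, "Trem2": 1.0, "Lyz2": 3.0, "Apoe": 2.0}
    macrophage.update({g: 4.0 for g in MACROPHAGE_UP})
    macrophage.update({"Cd9": 0.1, "Ctsd": 0.15})

    oligodendrocyte = {"Plp1": 12.0, "Mbp": 10.0, "Mog": 5.0, "Ctsd": 0.5}
    astrocyte = {"Gfap": 8.0, "Aqp4": 6.0, "Slc1a2": 8.0}

    if cells is None:
        cells = {
            "hippocampus": {"homeostatic": 500, "astrocyte": 200,
                            "oligodendrocyte": 100, "macrophage": 15},
            "fimbria": {"homeostatic": 350, "dam": 150,
                        "oligodendrocyte": 300, "macrophage": 20},
        }
    return CountsConfig(
        seed=seed,
        genes=genes,
        type_means={
            "homeostatic": homeostatic, "dam": dam, "macrophage": macrophage,
            "oligodendrocyte": oligodendrocyte, "astrocyte": astrocyte,
        },
        cells_per_region=cells,
        planted_lfc={g: dam_lfc for g in de_genes},
    )


def _mean_matrix(config: CountsConfig) -> tuple[list[str], np.ndarray]:
    types = sorted(config.type_means)
    mat = np.full((len(types), len(config.genes)), config.baseline_mean)
    gene_idx = {g: j for j, g in enumerate(config.genes)}
    for i, t in enumerate(types):
        for g, m in config.type_means[t].items():
            mat[i, gene_idx[g]] = m
    return types, mat


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size: float) -> np.ndarray:
    if not np.isfinite(size):
        return rng.poisson(mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = size / (size + mu[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_counts(
    config: CountsConfig, scene: SectionScene
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Generate an AnnData of raw counts plus a ground-truth table.

    obs columns: x, y (µm), fov, region. Truth (per-cell true type) and the
    per-gene planted log2FC table are returned separately and must only be
    consumed by tests/oracles.
    """
    config.validate()
    types, means = _mean_matrix(config)
    type_idx = {t: i for i, t in enumerate(types)}

    blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []
    truth_rows: list[dict] = []
    for ri, region in enumerate(sorted(config.cells_per_region)):
        if region not in scene.regions:
            raise ValueError(f"region not in scene: {region}")
        for ti, (ctype, n) in enumerate(sorted(config.cells_per_region[region].items())):
            if ctype not in type_idx:
                raise ValueError(f"unknown cell type: {ctype}")
            if n == 0:
                continue
            rng = _substream(config.seed, 100, ri, ti)
            pts = _poisson_points(rng, scene.regions[region], n)
            lib = rng.lognormal(0.0, config.libsize_sigma, n)
            mu = means[type_idx[ctype]][None, :] * lib[:, None]
            blocks.append(_nb_draw(rng, mu, config.nb_dispersion))
            for i in range(n):
                cid = f"{region}-{ctype}-{i}"
                obs_rows.append(
                    {"cell_id": cid, "x": pts[i, 0], "y": pts[i, 1],
                     "fov": f"F{int(pts[i, 0] // config.fov_size_um)}-"
                            f"{int(pts[i, 1] // config.fov_size_um)}",
                     "region": region}
                )
                truth_rows.append({"cell_id": cid, "true_type": ctype})

    if not blocks:
        raise ValueError("no cells configured")
    X = np.concatenate(blocks).astype(np.int64)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    obs.index.name = None
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(config.genes, name=None))
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["planted_lfc"] = dict(config.planted_lfc)
    return adata, truth


__all__ = [
    "CountsConfig", "default_counts_config", "simulate_counts",
    "GATE_GENES", "MACROPHAGE_UP", "MACROPHAGE_DOWN",
]
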