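"""Simulate tissue-section scenes with cells, tracts and planted group effects.

Cells are placed by a homogeneous Poisson process within each region polygon.
Each cell is an ellipse rasterized to a 16-vertex polygon; orientation is
wrapped-normal around the nearest tract's angle with a group-specific SD, so
alignment effects can be planted and recovered downstream. Intensities follow
a lognormal model: integrated density = lognormal mean intensity x area, with
a per-section lognormal background shared across cells of the same channel.

Randomness: one sub-stream per (group, mouse, region) derived from the config
seed with a fixed ordering, so adding a group does not perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from gliamap.scene import SectionScene, shoelace_area

ELLIPSE_VERTICES = 16
CHANNELS = ("IBA1", "GAL3", "APOE")


@dataclass
class GroupParams:
    """Planted per-group effects.

    density           cells per mm² (Poisson intensity)
    area_mu/sigma     lognormal parameters of cell area (log of µm²)
    aspect            ellipse major/minor axis ratio (spindle ~3, ramified ~1.2)
    align_sd          wrapped-normal SD (deg) of cell axis around nearest tract
    gal3_frac         fraction of cells in the planted GAL3+ subpopulation
    apoe_frac         fraction of APOE+ cells
    apoe_offset       lateral displacement (µm) of APOE+ cells toward the
                      ventricle side of the fimbria
    """

    density: float = 200.0
    area_mu: float = np.log(80.0)
    area_sigma: float = 0.35
    aspect: float = 1.2
    align_sd: float = 40.0
    gal3_frac: float = 0.02
    apoe_frac: float = 0.10
    apoe_offset: float = 0.0

    def validate(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if not (0.0 <= self.gal3_frac <= 1.0 and 0.0 <= self.apoe_frac <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.area_sigma <= 0:
            raise ValueError("area_sigma must be > 0")
        if self.aspect < 1.0:
            raise ValueError("aspect must be >= 1")


@dataclass
class SceneConfig:
    seed: int = 0
    groups: dict[str, GroupParams] = field(default_factory=dict)
    mice_per_group: int = 3
    scene: SectionScene = field(default_factory=SectionScene)
    tracts_per_region: dict[str, int] = field(default_factory=dict)
    tract_angle: dict[str, float] = field(default_factory=dict)   # deg, axial
    tract_angle_sd: dict[str, float] = field(default_factory=dict)
    tract_length: float = 200.0
    # lognormal (mu, sigma) of per-cell mean intensity, per channel
    intensity: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {c: (np.log(50.0), 0.3) for c in CHANNELS}
    )
    # additive log-space boost of the marker channel for marker+ cells
    marker_boost: float = 1.5
    background: tuple[float, float] = (np.log(2.0), 0.2)

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for g in self.groups.values():
            g.validate()
        self.scene.validate()
        if self.mice_per_group < 1:
            raise ValueError("mice_per_group must be >= 1")


def default_scene_config(
    seed: int = 0,
    groups: tuple[str, ...] = ("YNG", "OLD", "OLD_AP", "OLD_VEN"),
    mice_per_group: int = 3,
) -> SceneConfig:
    """Fimbria + hippocampus scene with aging/treatment effect directions.

    OLD plants: higher density, larger area, spindle shape, tighter tract
    alignment, higher GAL3+ fraction and APOE lateralization; the two treated
    groups sit between YNG and OLD.
    """
    fimbria = np.array([[0, 0], [2000, 0], [2000, 500], [0, 500]], float)
    hippocampus = np.array([[0, 700], [2000, 700], [2000, 1700], [0, 1700]], float)
    scene = SectionScene(
        regions={"fimbria": fimbria, "hippocampus": hippocampus},
        midline=np.array([[0, 250], [2000, 250]], float),
        ventricle=np.array([[0, 0], [2000, 0]], float),
    )
    presets = {
        "YNG": GroupParams(density=150, area_mu=np.log(60), aspect=1.2,
                           align_sd=40, gal3_frac=0.02, apoe_offset=0.0),
        "OLD": GroupParams(density=300, area_mu=np.log(110), aspect=3.0,
                           align_sd=10, gal3_frac=0.35, apoe_offset=400.0),
        "OLD_AP": GroupParams(density=220, area_mu=np.log(85), aspect=2.0,
                              align_sd=25, gal3_frac=0.15, apoe_offset=150.0),
        "OLD_VEN": GroupParams(density=230, area_mu=np.log(90), aspect=2.0,
                               align_sd=25, gal3_frac=0.18, apoe_offset=150.0),
    }
    return SceneConfig(
        seed=seed,
        groups={g: presets.get(g, GroupParams()) for g in groups},
        mice_per_group=mice_per_group,
        scene=scene,
        tracts_per_region={"fimbria": 12, "hippocampus": 8},
        tract_angle={"fimbria": 0.0, "hippocampus": 90.0},
        tract_angle_sd={"fimbria": 5.0, "hippocampus": 30.0},
    )


def _substream(seed: int, *key: int) -> np.random.Generator:
    # fixed ordering (group, mouse, region) so extending config keeps old draws
    return np.random.default_rng([seed, *key])


def _poisson_points(
    rng: np.random.Generator, polygon: np.ndarray, n: int, max_batches: int = 1000
) -> np.ndarray:
    """Uniform points in a polygon via rejection sampling (bounded retries)."""
    if n == 0:
        return np.empty((0, 2))
    poly = Polygon(polygon)
    if poly.area <= 0:
        raise ValueError("degenerate region")
    xmin, ymin, xmax, ymax = poly.bounds
    out: list[np.ndarray] = []
    got = 0
    for _ in range(max_batches):
        m = max(64, 2 * (n - got))
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        keep = contains_xy(poly, pts[:, 0], pts[:, 1])
        out.append(pts[keep])
        got += int(keep.sum())
        if got >= n:
            return np.concatenate(out)[:n]
    raise RuntimeError("cell placement failed: rejection budget exhausted")


def _ellipse_polygon(
    cx: float, cy: float, area: float, aspect: float, theta_deg: float
) -> np.ndarray:
    a = np.sqrt(area * aspect / np.pi)   # semi-major
    b = a / aspect
    t = np.linspace(0.0, 2.0 * np.pi, ELLIPSE_VERTICES, endpoint=False)
    th = np.deg2rad(theta_deg)
    x = a * np.cos(t)
    y = b * np.sin(t)
    return np.column_stack(
        [cx + x * np.cos(th) - y * np.sin(th), cy + x * np.sin(th) + y * np.cos(th)]
    )


def _ellipse_area_factor() -> float:
    """Area of the 16-gon relative to its generating ellipse."""
    n = ELLIPSE_VERTICES
    return n / (2 * np.pi) * np.sin(2 * np.pi / n)


def encode_polygon(vertices: np.ndarray) -> str:
    return ";".join(f"{x:.4f} {y:.4f}" for x, y in vertices)


def decode_polygon(text: str) -> np.ndarray:
    return np.array([[float(v) for v in pt.split()] for pt in text.split(";")])


def _simulate_tracts(
    config: SceneConfig, rng_factory, mouse_idx: int
) -> pd.DataFrame:
    rows = []
    tid = 0
    for ri, (region, n_tracts) in enumerate(sorted(config.tracts_per_region.items())):
        rng = rng_factory(1, mouse_idx, ri)
        base = config.tract_angle.get(region, 0.0)
        sd = config.tract_angle_sd.get(region, 10.0)
        centers = _poisson_points(rng, config.scene.regions[region], n_tracts)
        angles = base + rng.normal(0.0, sd, n_tracts)
        half = config.tract_length / 2.0
        for (cx, cy), ang in zip(centers, angles):
            th = np.deg2rad(ang)
            dx, dy = half * np.cos(th), half * np.sin(th)
            rows.append(
                {"tract_id": tid, "region": region, "angle_deg": float(ang % 180.0),
                 "x1": cx - dx, "y1": cy - dy, "x2": cx + dx, "y2": cy + dy}
            )
            tid += 1
    return pd.DataFrame(rows)


def _nearest_tract_angle(cx, cy, tracts: pd.DataFrame) -> float:
    p = np.array([cx, cy])
    a = tracts[["x1", "y1"]].to_numpy()
    b = tracts[["x2", "y2"]].to_numpy()
    ab = b - a
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab), 0, 1)
    d = np.linalg.norm(a + t[:, None] * ab - p, axis=1)
    return float(tracts.iloc[int(np.argmin(d))]["angle_deg"])


def simulate_section(
    config: SceneConfig,
) -> tuple[SectionScene, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (scene, cells, tracts, truth) tables for one experiment.

    Returns
    -------
    scene : SectionScene
    cells : DataFrame with one row per cell — ids, group/mouse/region labels,
        centroid, encoded polygon, area, and per channel ``intdens_<CH>`` /
        ``bg_<CH>`` columns (integrated density a.u., background a.u./µm²).
    tracts : DataFrame of straight fiber-tract segments (shared per mouse
        layout; ``mouse`` column keys them to sections).
    truth : DataFrame of planted per-cell labels (never consumed by pipeline
        stages — test/oracle use only).
    """
    config.validate()
    scene = config.scene
    cell_rows: list[dict] = []
    truth_rows: list[dict] = []
    tract_frames: list[pd.DataFrame] = []
    channels = tuple(config.intensity)
    af = _ellipse_area_factor()

    group_names = list(config.groups)
    region_names = sorted(scene.regions)
    for gi, gname in enumerate(group_names):
        gp = config.groups[gname]
        for mi in range(config.mice_per_group):
            mouse = f"{gname}-m{mi}"
            tracts = _simulate_tracts(config, lambda *k: _substream(config.seed, gi, *k), mi)
            tracts.insert(0, "mouse", mouse)
            tract_frames.append(tracts)
            # per-section background, shared across cells within the section
            bg_rng = _substream(config.seed, gi, 2, mi)
            bg = {c: float(bg_rng.lognormal(*config.background)) for c in channels}
            for ri, region in enumerate(region_names):
                rng = _substream(config.seed, gi, 0, mi, ri)
                area_mm2 = scene.region_area_mm2(region)
                n = int(rng.poisson(gp.density * area_mm2))
                pts = _poisson_points(rng, scene.regions[region], n)
                areas = rng.lognormal(gp.area_mu, gp.area_sigma, n) / af
                gal3 = rng.random(n) < gp.gal3_frac
                apoe = rng.random(n) < gp.apoe_frac
                region_tracts = tracts[tracts["region"] == region]
                mean_int = {
                    c: rng.lognormal(*config.intensity[c], n) for c in channels
                }
                if "GAL3" in mean_int:
                    mean_int["GAL3"] *= np.where(gal3, np.exp(config.marker_boost), 1.0)
                if "APOE" in mean_int:
                    mean_int["APOE"] *= np.where(apoe, np.exp(config.marker_boost), 1.0)
                jitter = rng.normal(0.0, gp.align_sd, n)
                lateral = rng.uniform(0.5, 1.0, n)  # APOE+ shift magnitude factor
                for i in range(n):
                    cx, cy = pts[i]
                    if apoe[i] and gp.apoe_offset > 0 and region == "fimbria" \
                            and scene.ventricle is not None:
                        # displace toward the ventricle side (planted
                        # lateralization); overshoot past the edge is clamped
                        # by halving, concentrating cells near the edge
                        poly_region = Polygon(scene.regions[region])
                        shift = gp.apoe_offset * lateral[i]
                        for _ in range(8):
                            if contains_xy(poly_region, cx, cy - shift):
                                cy = float(cy - shift)
                                break
                            shift *= 0.5
                    if len(region_tracts):
                        base = _nearest_tract_angle(cx, cy, region_tracts)
                    else:
                        base = 0.0
                    theta = (base + jitter[i]) % 180.0
                    poly = _ellipse_polygon(cx, cy, areas[i] * af, gp.aspect, theta)
                    cell_id = f"{mouse}-{region}-{len(cell_rows)}"
                    row = {
                        "cell_id": cell_id, "mouse": mouse, "group": gname,
                        "region": region, "cx": cx, "cy": cy,
                        "polygon": encode_polygon(poly),
                        "area": shoelace_area(poly),
                    }
                    for c in channels:
                        row[f"intdens_{c}"] = mean_int[c][i] * row["area"]
                        row[f"bg_{c}"] = bg[c]
                    cell_rows.append(row)
                    truth_rows.append(
                        {"cell_id": cell_id, "group": gname, "region": region,
                         "subtype": "spindle" if gp.aspect >= 2 else "ramified",
                         "gal3_true": bool(gal3[i]), "apoe_true": bool(apoe[i]),
                         "planted_theta": theta}
                    )

    cells = pd.DataFrame(cell_rows)
    truth = pd.DataFrame(truth_rows)
    tracts_all = (
        pd.concat(tract_frames, ignore_index=True)
        if tract_frames else pd.DataFrame(
            columns=["mouse", "tract_id", "region", "angle_deg", "x1", "y1", "x2", "y2"])
    )
    return scene, cells, tracts_all, truth


__all__ = [
    "GroupParams", "SceneConfig", "default_scene_config", "simulate_section",
    "encode_polygon", "decode_polygon",
]
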