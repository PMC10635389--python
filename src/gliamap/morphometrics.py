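"""Per-cell morphometric and intensity features from segmentation-level input.

Angle conventions: degrees from the +x axis in image coordinates (y grows
downward), axial (reduced modulo 180 into [0, 180)). Tract-alignment offsets
are the acute axial difference, so they never exceed 90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gliamap.scene import polygon_perimeter, shoelace_area
from gliamap.synthetic.scene_sim import decode_polygon


@dataclass
class NormalizationFactors:
    """Per-channel factors applied to corrected fluorescence.

    control_mean  mean TCCF of the reference (control) group
    min / max     post-division channel extrema used for min-max scaling
    """

    control_mean: float
    min: float
    max: float


def feret_axis(polygon: np.ndarray) -> tuple[float, float]:
    """Longest chord of a polygon and its axial angle.

    Returns ``(length, theta)`` where length is the maximum pairwise vertex
    distance and theta is the chord's angle in [0, 180). Ties are broken to
    the smaller angle, then by lexicographic vertex order.
    """
    p = np.asarray(polygon, dtype=float)
    if p.ndim != 2 or p.shape[0] < 3:
        raise ValueError("polygon needs >= 3 vertices")
    d = p[:, None, :] - p[None, :, :]
    dist = np.hypot(d[..., 0], d[..., 1])
    best = dist.max()
    ii, jj = np.nonzero(np.isclose(dist, best, rtol=0.0, atol=1e-12))
    candidates = []
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        ang = np.degrees(np.arctan2(p[j, 1] - p[i, 1], p[j, 0] - p[i, 0])) % 180.0
        # exact 180.0 folds to 0 under the axial convention
        if np.isclose(ang, 180.0):
            ang = 0.0
        candidates.append((round(ang, 12), i, j))
    ang = min(candidates)[0]
    return float(best), float(ang)


def axial_difference(theta_a: float, theta_b: float) -> float:
    """Acute difference between two axial angles, in [0, 90]."""
    d = abs(theta_a - theta_b) % 180.0
    return float(min(d, 180.0 - d))


def point_segment_distance(point, a, b) -> float:
    """Distance from a point to segment ab (perpendicular foot or endpoint)."""
    p = np.asarray(point, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(a + t * ab - p))


def tract_angle_offset(
    theta_cell: float, centroid, tracts: pd.DataFrame
) -> tuple[float, int, float]:
    """Acute angular offset of a cell axis to its nearest tract.

    ``tracts`` needs columns tract_id, x1, y1, x2, y2 (same region as the
    cell). Nearest-distance ties break to the lowest tract id.

    Returns (theta_off in [0, 90], nearest tract id, distance µm).
    """
    if len(tracts) == 0:
        raise ValueError("no reference tract")
    t = tracts.sort_values("tract_id")
    dists = np.array([
        point_segment_distance(centroid, (r.x1, r.y1), (r.x2, r.y2))
        for r in t.itertuples()
    ])
    k = int(np.argmin(dists))  # argmin takes first minimum -> lowest id wins
    row = t.iloc[k]
    theta_tract = np.degrees(np.arctan2(row.y2 - row.y1, row.x2 - row.x1)) % 180.0
    return axial_difference(theta_cell, theta_tract), int(row.tract_id), float(dists[k])


def corrected_fluorescence(
    integrated_density: float, background_mean: float, area: float
) -> float:
    """Total corrected cellular fluorescence: ID − background × area.

    May be negative; callers flag rather than clip negatives so downstream
    distributions are not silently censored.
    """
    if area <= 0:
        raise ValueError("area must be > 0")
    return float(integrated_density - background_mean * area)


def cell_density(n_cells: int, region_polygon: np.ndarray) -> float:
    """Cells per mm² given a region polygon in µm."""
    area_mm2 = shoelace_area(region_polygon) / 1e6
    if area_mm2 <= 0:
        raise ValueError("zero-area region polygon")
    return n_cells / area_mm2


def circularity(polygon: np.ndarray) -> float:
    """4πA/P² shape descriptor; 1 for a circle, →0 for needles."""
    area = shoelace_area(polygon)
    perim = polygon_perimeter(np.asarray(polygon, dtype=float))
    if perim <= 0:
        raise ValueError("zero perimeter")
    return float(4.0 * np.pi * area / perim**2)


def marker_calls(
    cells: pd.DataFrame, channel: str, threshold: float
) -> pd.Series:
    """Boolean positivity per cell: intensity strictly above threshold.

    Values equal to the threshold are negative (documented boundary
    convention). ``channel`` names a column of ``cells``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if channel not in cells.columns:
        raise KeyError(f"channel column missing: {channel}")
    return cells[channel] > threshold


def colocalization_fraction(calls_a: pd.Series, calls_b: pd.Series) -> float:
    """Percentage of A-positive cells that are also B-positive."""
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("call vectors must share the cell universe")
    n_a = int(a.sum())
    if n_a == 0:
        raise ValueError("no A-positive cells: fraction undefined")
    return 100.0 * int((a & b).sum()) / n_a


def normalize_intensities(
    tccf: pd.DataFrame,
    groups: pd.Series,
    reference_group: str,
    channels: list[str],
) -> tuple[pd.DataFrame, dict[str, NormalizationFactors]]:
    """Normalize TCCF to the control group then min-max scale per channel.

    Division by the reference-group mean implements control normalization;
    scaling maps each channel onto [0, 1] across the experiment. Factors are
    returned so calls are reproducible on held-out data.
    """
    out = pd.DataFrame(index=tccf.index)
    factors: dict[str, NormalizationFactors] = {}
    ref_mask = (groups == reference_group).to_numpy()
    if ref_mask.sum() == 0:
        raise ValueError(f"reference group empty: {reference_group}")
    for ch in channels:
        ref_mean = float(tccf.loc[ref_mask, ch].mean())
        if ref_mean == 0:
            raise ValueError(f"reference mean is zero for channel {ch}")
        v = tccf[ch] / ref_mean
        vmin, vmax = float(v.min()), float(v.max())
        span = vmax - vmin
        out[ch] = 0.0 if span == 0 else (v - vmin) / span
        factors[ch] = NormalizationFactors(ref_mean, vmin, vmax)
    return out, factors


def compute_morphometrics(
    cells: pd.DataFrame,
    tracts: pd.DataFrame,
    channels: list[str] | None = None,
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Build the per-cell morphometric table.

    ``cells`` follows the simulator/reader schema (cell_id, mouse, group,
    region, cx, cy, polygon, area, intdens_<CH>, bg_<CH>). Tracts are matched
    within (mouse, region). One row per cell:

    feret_length, feret_angle, area, perimeter, circularity, nearest_tract,
    tract_distance, angle_offset, tccf_<CH>, tccf_<CH>_negative,
    norm_<CH> (when ``reference_group`` given).
    """
    if channels is None:
        channels = sorted(
            c.removeprefix("intdens_") for c in cells.columns if c.startswith("intdens_")
        )
    rows = []
    for rec in cells.itertuples():
        poly = decode_polygon(rec.polygon)
        length, theta = feret_axis(poly)
        area = shoelace_area(poly)
        sub = tracts[(tracts["mouse"] == rec.mouse) & (tracts["region"] == rec.region)]
        if len(sub):
            off, tid, dist = tract_angle_offset(theta, (rec.cx, rec.cy), sub)
        else:
            off, tid, dist = np.nan, -1, np.nan
        row = {
            "cell_id": rec.cell_id, "mouse": rec.mouse, "group": rec.group,
            "region": rec.region, "cx": rec.cx, "cy": rec.cy,
            "feret_length": length, "feret_angle": theta,
            "area": area, "perimeter": polygon_perimeter(poly),
            "circularity": circularity(poly),
            "nearest_tract": tid, "tract_distance": dist, "angle_offset": off,
        }
        for ch in channels:
            t = corrected_fluorescence(
                getattr(rec, f"intdens_{ch}"), getattr(rec, f"bg_{ch}"), area
            )
            row[f"tccf_{ch}"] = t
            row[f"tccf_{ch}_negative"] = t < 0
        rows.append(row)
    morpho = pd.DataFrame(rows)
    if reference_group is not None and len(morpho):
        tccf_cols = {ch: f"tccf_{ch}" for ch in channels}
        norm, factors = normalize_intensities(
            morpho[list(tccf_cols.values())].rename(
                columns={v: k for k, v in tccf_cols.items()}
            ),
            morpho["group"],
            reference_group,
            channels,
        )
        for ch in channels:
            morpho[f"norm_{ch}"] = norm[ch]
        morpho.attrs["normalization"] = {
            ch: vars(f) for ch, f in factors.items()
        }
    return morpho


__all__ = [
    "feret_axis", "axial_difference", "point_segment_distance",
    "tract_angle_offset", "corrected_fluorescence", "cell_density",
    "circularity", "marker_calls", "colocalization_fraction",
    "normalize_intensities", "compute_morphometrics", "NormalizationFactors",
]
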