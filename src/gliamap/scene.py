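"""Section-scene geometry: region polygons, reference polylines, scale.

Coordinates are micrometres in image convention (origin top-left, y grows
downward). Polygons are (n, 2) float arrays of vertices, implicitly closed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon


def shoelace_area(polygon: np.ndarray) -> float:
    """Unsigned polygon area via the shoelace formula (input units squared)."""
    p = np.asarray(polygon, dtype=float)
    if p.ndim != 2 or p.shape[0] < 3 or p.shape[1] != 2:
        raise ValueError("polygon must be an (n>=3, 2) array")
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(polygon: np.ndarray) -> float:
    p = np.asarray(polygon, dtype=float)
    return float(np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1).sum())


def is_simple_polygon(polygon: np.ndarray) -> bool:
    try:
        return Polygon(np.asarray(polygon, dtype=float)).is_valid
    except Exception:
        return False


@dataclass
class SectionScene:
    """Geometry of one simulated/real tissue section.

    Attributes
    ----------
    regions
        Mapping region label -> polygon vertices (µm).
    midline
        Fimbria midline polyline, (n, 2) µm.
    ventricle
        Ventricle-edge polyline, (n, 2) µm.
    scale_um
        Micrometres per coordinate unit (1.0 when coordinates are µm).
    """

    regions: dict[str, np.ndarray] = field(default_factory=dict)
    midline: np.ndarray | None = None
    ventricle: np.ndarray | None = None
    scale_um: float = 1.0

    def __post_init__(self) -> None:
        self.regions = {k: np.asarray(v, dtype=float) for k, v in self.regions.items()}
        if self.midline is not None:
            self.midline = np.asarray(self.midline, dtype=float)
        if self.ventricle is not None:
            self.ventricle = np.asarray(self.ventricle, dtype=float)

    def region_area_mm2(self, label: str) -> float:
        """Region area in mm² (coordinates are µm)."""
        return shoelace_area(self.regions[label]) * self.scale_um**2 / 1e6

    def validate(self) -> None:
        for label, poly in self.regions.items():
            if poly.shape[0] < 3 or shoelace_area(poly) <= 0:
                raise ValueError(f"degenerate region: {label}")
            if not is_simple_polygon(poly):
                raise ValueError(f"self-intersecting region polygon: {label}")
        for name in ("midline", "ventricle"):
            line = getattr(self, name)
            if line is not None and line.shape[0] < 2:
                raise ValueError(f"{name} polyline needs >=2 vertices")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "scale_um": self.scale_um,
            "regions": {k: v.tolist() for k, v in self.regions.items()},
        }
        if self.midline is not None:
            d["midline"] = self.midline.tolist()
        if self.ventricle is not None:
            d["ventricle"] = self.ventricle.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SectionScene":
        return cls(
            regions={k: np.asarray(v) for k, v in d.get("regions", {}).items()},
            midline=np.asarray(d["midline"]) if "midline" in d else None,
            ventricle=np.asarray(d["ventricle"]) if "ventricle" in d else None,
            scale_um=float(d.get("scale_um", 1.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SectionScene":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
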