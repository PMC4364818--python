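"""Landscape Elements metrics per landscape unit.

Patch delineation dissolves same-class polygons that share a boundary
segment of positive length (corner contact does not merge: patches are the
polygonal parts of the per-class union, which keeps point-touching parts
separate).  Metrics:

* ``NP``  — number of patches;
* ``MSI`` — mean shape index, mean over patches of p / (2 sqrt(pi a))
  (circle-normalised, vector formulation; 1 for a circle).  A raster-style
  variant 0.25 p / sqrt(a) (square-normalised) is available behind a flag;
* ``ED``  — edge density, sum of patch perimeters per hectare of unit area
  (m/ha); unit-boundary segments are included by default and excludable;
* ``SDI`` — Shannon diversity -sum p_i ln p_i over class area shares;
* ``SEI`` — Shannon evenness SDI / ln(m) for m >= 2 classes, 0 for m = 1.

Metrics are computed either over all classes in the unit or over
farmland-role classes only (``all_classes`` / ``farmland_only`` scope).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .core_model import ClassRegistry, LandCoverFeature, LandCoverMap, LandscapeUnit, area_ha

logger = logging.getLogger("hnvf")

#: drop classes whose area share falls below this when computing diversity
SHARE_EPS = 1e-12


@dataclass(frozen=True)
class Patch:
    """Maximal edge-connected same-class region within one landscape unit."""

    unit_id: str
    code: str
    geometry: BaseGeometry
    area_ha: float
    perimeter_m: float

    @property
    def shape_index(self) -> float:
        """Circle-normalised shape index p / (2 sqrt(pi a)); >= 1, 1 for a circle."""
        a_m2 = self.area_ha * 10_000.0
        return self.perimeter_m / (2.0 * math.sqrt(math.pi * a_m2))

    @property
    def shape_index_raster(self) -> float:
        """Square-normalised variant 0.25 p / sqrt(a); 1 for a square."""
        a_m2 = self.area_ha * 10_000.0
        return 0.25 * self.perimeter_m / math.sqrt(a_m2)


def clip_to_unit(landcover: LandCoverMap, unit: LandscapeUnit) -> LandCoverMap:
    """Intersect every land-cover feature with the unit boundary.

    Features fully outside disappear; straddling features are cut at the
    boundary.  An empty result is a valid (empty) map.
    """
    boundary = unit.boundary
    clipped: list[LandCoverFeature] = []
    for feat in landcover.features:
        if not feat.geometry.intersects(boundary):
            continue
        geom = feat.geometry.intersection(boundary)
        geom = _polygonal_part(geom)
        if geom is None or geom.is_empty or geom.area <= 0:
            continue
        clipped.append(LandCoverFeature(geom, feat.code))
    return LandCoverMap(clipped, crs=landcover.crs)


def _polygonal_part(geom: BaseGeometry) -> BaseGeometry | None:
    """Keep only the areal component of an intersection result."""
    if geom.is_empty:
        return None
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if not polys:
            return None
        return unary_union(polys)
    return None  # lines/points carry no area


def _scope_codes(registry: ClassRegistry, scope: str) -> set[str] | None:
    if scope == "all_classes":
        return None
    if scope == "farmland_only":
        return registry.codes_with_role("farmland", "off_farm_grazing")
    raise ValueError(f"unknown metric scope {scope!r}")


def delineate_patches(
    landcover: LandCoverMap,
    unit: LandscapeUnit,
    scope: str = "all_classes",
    registry: ClassRegistry | None = None,
) -> list[Patch]:
    """Dissolve the (already clipped) mosaic into per-class patches.

    Same-class polygons sharing an edge merge into one patch; polygons
    meeting only at a point stay separate.  Under ``farmland_only`` scope a
    registry is required and only farmland / off-farm-grazing classes are
    delineated.
    """
    keep = None
    if scope != "all_classes":
        if registry is None:
            raise ValueError("farmland_only scope requires a class registry")
        keep = _scope_codes(registry, scope)
    by_class: dict[str, list[BaseGeometry]] = {}
    for feat in landcover.features:
        if keep is not None and feat.code not in keep:
            continue
        by_class.setdefault(feat.code, []).append(feat.geometry)
    patches: list[Patch] = []
    for code in sorted(by_class):
        dissolved = unary_union(by_class[code])
        for part in shapely.get_parts(dissolved):
            if part.geom_type != "Polygon" or part.area <= 0:
                continue
            patches.append(
                Patch(
                    unit_id=unit.unit_id,
                    code=code,
                    geometry=part,
                    area_ha=area_ha(part),
                    perimeter_m=part.length,
                )
            )
    return patches


def shannon_diversity(proportions: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity index -sum p_i ln p_i.

    Shares must be non-negative and sum to 1 (within 1e-9); zero shares are
    dropped.  An empty vector raises.
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ValueError("no classes present")
    if (p < 0).any():
        raise ValueError("negative class shares")
    total = p.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"class shares must sum to 1, got {total!r}")
    p = p[p > SHARE_EPS]
    if p.size == 0:
        raise ValueError("no classes present")
    return float(-(p * np.log(p)).sum())


def shannon_evenness(sdi: float, n_classes: int) -> float:
    """Shannon evenness SDI / ln(m); 0 for a single class (no evenness
    information at minimal diversity)."""
    if n_classes <= 0:
        raise ValueError("n_classes must be >= 1")
    if sdi < 0:
        raise ValueError("sdi must be >= 0")
    if n_classes == 1:
        return 0.0
    sei = sdi / math.log(n_classes)
    if not -1e-9 <= sei <= 1 + 1e-9:
        raise ValueError(f"evenness {sei} outside [0, 1]")
    return min(max(sei, 0.0), 1.0)


def patch_metrics(
    patches: Iterable[Patch],
    unit: LandscapeUnit,
    exclude_unit_boundary: bool = False,
    raster_shape_index: bool = False,
) -> tuple[int, float, float]:
    """NP, MSI and ED for one unit.

    ``ED`` divides summed patch perimeters (metres) by the unit's total area
    (hectares).  With ``exclude_unit_boundary`` the perimeter segments
    coincident with the unit boundary are removed before summing.  An empty
    patch set yields ``(0, 0.0, 0.0)`` with a warning.
    """
    patches = list(patches)
    if not patches:
        logger.warning("unit %s: no patches; NP/MSI/ED set to 0", unit.unit_id)
        return 0, 0.0, 0.0
    np_p = len(patches)
    if raster_shape_index:
        msi_p = float(np.mean([p.shape_index_raster for p in patches]))
    else:
        msi_p = float(np.mean([p.shape_index for p in patches]))
    total_perim = 0.0
    ring = unit.boundary.boundary if exclude_unit_boundary else None
    for p in patches:
        perim = p.perimeter_m
        if ring is not None:
            shared = p.geometry.boundary.intersection(ring)
            perim -= shared.length
        total_perim += perim
    ed_p = total_perim / unit.t_area_ha
    return np_p, msi_p, ed_p


def class_shares(landcover: LandCoverMap, scope: str = "all_classes",
                 registry: ClassRegistry | None = None) -> dict[str, float]:
    """Area share per class within the (clipped) map, restricted to scope."""
    keep = None
    if scope != "all_classes":
        if registry is None:
            raise ValueError("farmland_only scope requires a class registry")
        keep = _scope_codes(registry, scope)
    areas = {
        code: a for code, a in landcover.area_by_class().items()
        if keep is None or code in keep
    }
    total = sum(areas.values())
    if total <= 0:
        return {}
    shares = {code: a / total for code, a in areas.items()}
    return {code: s for code, s in shares.items() if s > SHARE_EPS}


@dataclass(frozen=True)
class LandscapeElements:
    sdi_p: float
    sei_p: float
    np_p: int
    msi_p: float
    ed_p: float


def landscape_elements(
    landcover: LandCoverMap,
    unit: LandscapeUnit,
    scope: str = "all_classes",
    registry: ClassRegistry | None = None,
    exclude_unit_boundary: bool = False,
    raster_shape_index: bool = False,
) -> LandscapeElements:
    """Clip, delineate and compute all five Landscape Elements metrics.

    Deterministic for fixed input.  A unit fully covered by one class yields
    ``sdi=0, sei=0, np=1``.
    """
    clipped = clip_to_unit(landcover, unit)
    shares = class_shares(clipped, scope, registry)
    if shares:
        sdi = shannon_diversity(list(shares.values()))
        sei = shannon_evenness(sdi, len(shares))
    else:
        logger.warning("unit %s: no classes in scope %s", unit.unit_id, scope)
        sdi, sei = 0.0, 0.0
    patches = delineate_patches(clipped, unit, scope, registry)
    np_p, msi_p, ed_p = patch_metrics(
        patches, unit,
        exclude_unit_boundary=exclude_unit_boundary,
        raster_shape_index=raster_shape_index,
    )
    return LandscapeElements(sdi, sei, np_p, msi_p, ed_p)
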