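"""Step 3 — indicator-species coincidence and complementary type-3 areas.

Records of plant species whose survival depends on extensive farming
(reported as 1-km grid squares) and Important Bird and Biodiversity Area
(IBA) polygons act as a sensitivity check on the mapped type-1/2 extent:
each occurrence is tallied as partially within a type (its geometry
intersects the extent with positive area) or completely within (covered by
it).  Species-supported utilized agricultural area that the intensity
cascades did not capture can optionally be designated HNV type 3.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .core_model import SpeciesOccurrence

#: positive-area test tolerance (m^2) against rounding slivers
_AREA_EPS = 1e-6


def _areal_geometry(occ: SpeciesOccurrence, grid_m: float) -> BaseGeometry:
    """Occurrence footprint; zero-area (point) records are buffered to a
    square of the stated grid resolution (default 1 km)."""
    geom = occ.geometry
    if geom.area > 0:
        return geom
    half = grid_m / 2.0
    return geom.buffer(half, cap_style="square", join_style="mitre")


def coincidence(
    hnvf_geoms: Mapping[str, BaseGeometry | None],
    occurrences: Sequence[SpeciesOccurrence],
    grid_m: float = 1000.0,
) -> pd.DataFrame:
    """Per-species coincidence counts against each HNV type extent.

    Returns one row per (species_id, kind): total record count, and for each
    type ``n_partial_<type>`` (records intersecting the extent with positive
    area; includes complete ones) and ``n_complete_<type>`` (records covered
    by the extent).
    """
    rows: dict[tuple[str, str], dict[str, float]] = {}
    types = list(hnvf_geoms)
    for occ in occurrences:
        key = (occ.species_id, occ.kind)
        row = rows.setdefault(
            key,
            {"species_id": occ.species_id, "kind": occ.kind, "n_total": 0,
             **{f"n_partial_{t}": 0 for t in types},
             **{f"n_complete_{t}": 0 for t in types}},
        )
        row["n_total"] += 1
        footprint = _areal_geometry(occ, grid_m)
        for t in types:
            extent = hnvf_geoms[t]
            if extent is None or extent.is_empty:
                continue
            inter = footprint.intersection(extent)
            if inter.area > _AREA_EPS:
                row[f"n_partial_{t}"] += 1
                if footprint.difference(extent).area <= _AREA_EPS:
                    row[f"n_complete_{t}"] += 1
    return pd.DataFrame(sorted(rows.values(), key=lambda r: (r["kind"], r["species_id"])))


def designate_hnvf3(
    occurrences: Sequence[SpeciesOccurrence],
    hnvf12_extent: BaseGeometry | None,
    uaa_extent: BaseGeometry,
    within: BaseGeometry | None = None,
    grid_m: float = 1000.0,
) -> BaseGeometry | None:
    """Complementary type-3 extent: species-supported UAA not already mapped.

    HNVf3 = (union of occurrence and IBA footprints) intersected with the
    UAA, minus the type-1/2 extent; optionally restricted to one unit's
    boundary via *within*.  Returns None when nothing remains (all records
    already coincide with mapped HNV farmland, or fall outside the UAA).
    """
    if not occurrences:
        return None
    footprints = [_areal_geometry(o, grid_m) for o in occurrences]
    supported = unary_union(footprints).intersection(uaa_extent)
    if within is not None:
        supported = supported.intersection(within)
    if hnvf12_extent is not None and not hnvf12_extent.is_empty:
        supported = supported.difference(hnvf12_extent)
    if supported.is_empty or supported.area <= _AREA_EPS:
        return None
    return supported
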