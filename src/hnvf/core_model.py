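"""Domain types, class registry and I/O for High Nature Value farmland mapping.

The pipeline analyses a municipality of local administrative units (LAUs;
civil parishes) from four inputs: a classed land-cover map, unit boundary
polygons, an agrarian-statistics table (livestock, irrigation, crops) and a
natural-constraints (ANC) layer, plus indicator-species occurrences for the
type-3 validation step.  Everything spatial is planar geometry in a single
projected, metre-unit coordinate reference system; areas are reported in
hectares (m^2 / 10 000).

Vector layers are read and written as GeoJSON FeatureCollections (plain
text); tables as UTF-8 CSV with a header row and "." decimal separator;
registries and thresholds as YAML; run manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger("hnvf")

M2_PER_HA = 10_000.0

#: roles a land-cover class can play in the analysis
ROLES = frozenset({"farmland", "forest", "off_farm_grazing", "other"})
#: position of a class in the minimum-maximum HNV candidate scheme
LIKELIHOODS = frozenset({"minimum", "maximum_only", "none"})
#: three-level natural-constraint (ANC) vocabulary
LIMITATIONS = frozenset({"none", "moderate", "severe"})
#: CRS identifiers known to be geographic (degree units) -> rejected
_GEOGRAPHIC_CRS = frozenset(
    {"EPSG:4326", "EPSG:4258", "EPSG:4269", "CRS84", "OGC:CRS84", "WGS84"}
)

#: Eurostat standard livestock-unit coefficients (LSU per head)
EUROSTAT_LSU = {
    "dairy_cows": 1.0,
    "cattle": 0.8,
    "cattle_under_1yr": 0.4,
    "sheep": 0.1,
    "goats": 0.1,
    "equidae": 0.8,
    "pigs": 0.3,
    "sows": 0.5,
    "poultry": 0.014,
}


class RegistryError(ValueError):
    """A land-cover class code cannot be resolved or a registry is ill-formed."""


class CrsError(ValueError):
    """Input layer declares a geographic (degree-unit) or missing CRS."""


def area_ha(geometry: BaseGeometry) -> float:
    """Planar area of *geometry* in hectares (m^2 / 10 000)."""
    return geometry.area / M2_PER_HA


def clean_geometry(geometry: BaseGeometry, feature_id: str = "?") -> BaseGeometry:
    """Return a valid geometry, repairing self-intersections if possible.

    Invalid inputs are passed through ``make_valid`` (zero-buffer semantics);
    geometries that cannot be repaired to a non-empty polygonal result raise
    ``ValueError`` naming the feature.
    """
    if geometry.is_valid:
        return geometry
    repaired = make_valid(geometry)
    if repaired.is_empty or repaired.area <= 0:
        raise ValueError(f"unrepairable geometry for feature {feature_id!r}")
    return repaired


def check_projected_crs(crs: str | None, source: str = "input") -> str:
    """Reject geographic CRSs; computation requires projected metre units."""
    if not crs:
        raise CrsError(
            f"{source}: no CRS declared; a projected CRS with metre units is required"
        )
    if crs.upper().replace("URN:OGC:DEF:CRS:", "").replace("::", ":") in _GEOGRAPHIC_CRS:
        raise CrsError(
            f"{source}: CRS {crs!r} is geographic (degree units); "
            "reproject to a projected CRS with metre units first"
        )
    return crs


# ---------------------------------------------------------------------------
# class registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandCoverClass:
    """One land-cover class: its role and its HNV candidate likelihood.

    ``hnvf_likelihood`` follows the minimum-maximum candidate scheme:
    ``minimum`` classes consist primarily of HNV farmland (semi-natural
    pastures, grazed heathland); ``maximum_only`` classes are potentially HNV
    depending on farming intensity (arable mosaics, vineyards); ``none``
    classes are never HNV candidates (forest, urban, water).
    """

    code: str
    label: str
    role: str
    hnvf_likelihood: str = "none"
    crop_group: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise RegistryError(f"class {self.code!r}: unknown role {self.role!r}")
        if self.hnvf_likelihood not in LIKELIHOODS:
            raise RegistryError(
                f"class {self.code!r}: unknown hnvf_likelihood {self.hnvf_likelihood!r}"
            )
        if self.hnvf_likelihood == "minimum" and self.role not in (
            "farmland",
            "off_farm_grazing",
        ):
            raise RegistryError(
                f"class {self.code!r}: minimum-likelihood classes must have role "
                "farmland or off_farm_grazing"
            )


class ClassRegistry:
    """Lookup table from class code to :class:`LandCoverClass`.

    The minimum candidate set is by construction a subset of the maximum set:
    ``maximum`` = classes with likelihood ``minimum`` or ``maximum_only``.
    """

    def __init__(self, classes: Iterable[LandCoverClass]):
        self._classes: dict[str, LandCoverClass] = {}
        for cls in classes:
            if cls.code in self._classes:
                raise RegistryError(f"duplicate class code {cls.code!r}")
            self._classes[cls.code] = cls
        if not self._classes:
            raise RegistryError("empty class registry")

    def __getitem__(self, code: str) -> LandCoverClass:
        try:
            return self._classes[code]
        except KeyError:
            raise RegistryError(f"unknown land-cover class code {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self._classes

    def __iter__(self):
        return iter(self._classes.values())

    def __len__(self) -> int:
        return len(self._classes)

    @property
    def codes(self) -> list[str]:
        return list(self._classes)

    def codes_with_role(self, *roles: str) -> set[str]:
        return {c.code for c in self if c.role in roles}

    @property
    def uaa_codes(self) -> set[str]:
        """Classes counting toward utilized agricultural area (UAA)."""
        return self.codes_with_role("farmland", "off_farm_grazing")

    @property
    def forest_codes(self) -> set[str]:
        return self.codes_with_role("forest")

    @property
    def minimum_codes(self) -> set[str]:
        return {c.code for c in self if c.hnvf_likelihood == "minimum"}

    @property
    def maximum_codes(self) -> set[str]:
        """Minimum plus maximum_only classes (minimum is always a subset)."""
        return {
            c.code for c in self if c.hnvf_likelihood in ("minimum", "maximum_only")
        }

    def validate_codes(self, codes: Iterable[str]) -> None:
        unknown = sorted({c for c in codes if c not in self})
        if unknown:
            raise RegistryError(
                "unknown land-cover class code(s): " + ", ".join(repr(c) for c in unknown)
            )

    # -- YAML round-trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "classes": [
                {k: v for k, v in dataclasses.asdict(c).items() if v is not None}
                for c in self
            ]
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassRegistry":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(payload, dict) or "classes" not in payload:
            raise RegistryError(f"{path}: expected a mapping with a 'classes' list")
        return cls(LandCoverClass(**entry) for entry in payload["classes"])


def default_registry() -> ClassRegistry:
    """An illustrative mountain-agriculture class palette.

    Modelled on the infield/outfield structure of north-Iberian mountain
    municipalities: hay meadows and grazed heathland commons as near-certain
    HNV (minimum set), arable/vineyard mosaics as intensity-dependent HNV
    (maximum_only), forest plantations and artificial classes as non-candidates.
    Real deployments supply their own registry YAML.
    """
    return ClassRegistry(
        [
            LandCoverClass("PP", "permanent pasture / hay meadow", "farmland", "minimum", "pasture"),
            LandCoverClass("HE", "heathland & scrub commons", "off_farm_grazing", "minimum"),
            LandCoverClass("AM", "annual-crop mosaic", "farmland", "maximum_only", "arable"),
            LandCoverClass("VI", "vineyard & orchard", "farmland", "maximum_only", "vineyard"),
            LandCoverClass("IC", "intensive irrigated cropland", "farmland", "maximum_only", "horticulture"),
            LandCoverClass("BF", "broadleaf forest", "forest"),
            LandCoverClass("CF", "conifer plantation", "forest"),
            LandCoverClass("UR", "artificial surfaces", "other"),
            LandCoverClass("WA", "water", "other"),
        ]
    )


# ---------------------------------------------------------------------------
# spatial containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandCoverFeature:
    geometry: BaseGeometry
    code: str


@dataclass
class LandCoverMap:
    """Classed polygons forming the mosaic analysed per landscape unit."""

    features: list[LandCoverFeature]
    crs: str = "EPSG:3763"

    def __post_init__(self) -> None:
        check_projected_crs(self.crs, "land-cover map")

    def codes(self) -> set[str]:
        return {f.code for f in self.features}

    def area_by_class(self) -> dict[str, float]:
        """Total hectares per class code."""
        out: dict[str, float] = {}
        for f in self.features:
            out[f.code] = out.get(f.code, 0.0) + area_ha(f.geometry)
        return out

    def total_area_ha(self) -> float:
        return sum(area_ha(f.geometry) for f in self.features)


@dataclass(frozen=True)
class ConstraintFeature:
    geometry: BaseGeometry
    limitation: str

    def __post_init__(self) -> None:
        if self.limitation not in LIMITATIONS:
            raise ValueError(
                f"unknown limitation class {self.limitation!r}; expected one of "
                + ", ".join(sorted(LIMITATIONS))
            )


@dataclass
class ConstraintMap:
    """Natural-constraints (ANC) polygons: none / moderate / severe limitation."""

    features: list[ConstraintFeature]
    crs: str = "EPSG:3763"


@dataclass(frozen=True)
class LandscapeUnit:
    """One parish / LAU: the landscape of analysis.

    ``uaa_ha`` and the shares are filled in by the pipeline's UAA step;
    freshly loaded units carry zeros there.
    """

    unit_id: str
    name: str
    boundary: BaseGeometry
    t_area_ha: float
    uaa_ha: float = 0.0
    p_uaa_pct: float = 0.0
    p_forest_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.t_area_ha <= 0:
            raise ValueError(f"unit {self.unit_id!r}: t_area_ha must be > 0")
        if not (0.0 <= self.p_uaa_pct <= 100.0 and 0.0 <= self.p_forest_pct <= 100.0):
            raise ValueError(f"unit {self.unit_id!r}: shares must lie in [0, 100]")
        if self.uaa_ha > self.t_area_ha * (1 + 1e-9):
            raise ValueError(f"unit {self.unit_id!r}: uaa_ha exceeds t_area_ha")

    @classmethod
    def from_boundary(cls, unit_id: str, name: str, boundary: BaseGeometry) -> "LandscapeUnit":
        return cls(unit_id, name, boundary, t_area_ha=area_ha(boundary))


@dataclass(frozen=True)
class AgrarianRecord:
    """Per-unit agrarian statistics: livestock head counts, irrigation, crops."""

    unit_id: str
    livestock: Mapping[str, float] = field(default_factory=dict)
    irrigated_ha: float = 0.0
    crops: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, v in self.livestock.items() if v < 0]
        bad += [k for k, v in self.crops.items() if v < 0]
        if bad or self.irrigated_ha < 0:
            raise ValueError(
                f"record {self.unit_id!r}: negative counts/areas ({', '.join(bad) or 'irrigated_ha'})"
            )


class LsuCoefficients:
    """Animal-category -> livestock-unit (LSU per head) coefficients."""

    def __init__(self, coefficients: Mapping[str, float] | None = None):
        coeffs = dict(coefficients if coefficients is not None else EUROSTAT_LSU)
        for cat, c in coeffs.items():
            if c <= 0:
                raise ValueError(f"LSU coefficient for {cat!r} must be > 0")
        self._coeffs = coeffs

    def __getitem__(self, category: str) -> float:
        try:
            return self._coeffs[category]
        except KeyError:
            raise KeyError(
                f"no livestock-unit coefficient for category {category!r}"
            ) from None

    def __contains__(self, category: str) -> bool:
        return category in self._coeffs

    def items(self):
        return self._coeffs.items()


@dataclass(frozen=True)
class SpeciesOccurrence:
    """One indicator-species record: a 1-km grid square or an IBA polygon."""

    species_id: str
    kind: str  # plant_grid | iba_polygon
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.kind not in ("plant_grid", "iba_polygon"):
            raise ValueError(f"unknown occurrence kind {self.kind!r}")
        if not self.geometry.is_valid:
            raise ValueError(f"occurrence {self.species_id!r}: invalid geometry")


INDICATOR_COLUMNS = [
    "sdi_p", "sei_p", "np_p", "msi_p", "ed_p",
    "lsi_p", "irrig_p", "sdi_c", "sei_c", "scrop_p",
]
#: CSV export header names (field convention)
INDICATOR_CSV_NAMES = {
    "sdi_p": "SDI_p", "sei_p": "SEI_p", "np_p": "NP_p", "msi_p": "MSI_p",
    "ed_p": "ED_p", "lsi_p": "LSI_p", "irrig_p": "Irrig_p",
    "sdi_c": "SDI_c", "sei_c": "SEI_c", "scrop_p": "SCrop_p",
}


class IndicatorTable:
    """Per-unit values of the landscape, intensity and crop-diversity indicators.

    Backed by a DataFrame indexed by unit_id with columns ``sdi_p, sei_p,
    np_p, msi_p, ed_p`` (Landscape Elements), ``lsi_p, irrig_p`` (Extensive
    Practices) and ``sdi_c, sei_c, scrop_p`` (Crop Diversity).  Missing values
    (indicator not computed for a unit) are NaN.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in INDICATOR_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"indicator table missing columns: {missing}")
        df = data[INDICATOR_COLUMNS].astype(float).copy()
        df.index = data.index.astype(str)
        df.index.name = "unit_id"
        self._validate(df)
        self.data = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        for col in ("sei_p", "sei_c"):
            vals = df[col].dropna()
            if ((vals < -1e-9) | (vals > 1 + 1e-9)).any():
                raise ValueError(f"{col} values must lie in [0, 1]")
        for col in ("np_p", "ed_p", "scrop_p"):
            vals = df[col].dropna()
            if (vals < 0).any():
                raise ValueError(f"{col} values must be >= 0")

    def __len__(self) -> int:
        return len(self.data)

    def value(self, unit_id: str, indicator: str) -> float:
        return float(self.data.loc[unit_id, indicator])

    @classmethod
    def from_rows(cls, rows: Mapping[str, Mapping[str, float]]) -> "IndicatorTable":
        df = pd.DataFrame.from_dict(rows, orient="index")
        for col in INDICATOR_COLUMNS:
            if col not in df.columns:
                df[col] = float("nan")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.rename(columns=INDICATOR_CSV_NAMES)
        out.to_csv(path, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "IndicatorTable":
        df = pd.read_csv(path, index_col="unit_id")
        df.index = df.index.astype(str)
        inverse = {v: k for k, v in INDICATOR_CSV_NAMES.items()}
        return cls(df.rename(columns=inverse))


@dataclass
class ThresholdConfig:
    """Thresholds of the classification cascade.

    Boundary semantics retain at equality: a unit is farmland-dominant when
    p_uaa >= ``uaa_dominance_pct``; HNV type 1 requires lsi <= ``lsi_max``
    and irrig <= ``irrig_max_pct``; type 2 requires sei >= ``sei_min`` and
    ed >= ``ed_min``.  ``lsi_max=None`` disables the livestock filter.
    """

    uaa_dominance_pct: float = 40.0
    lsi_max: float | None = 0.2
    irrig_max_pct: float = 15.0
    sei_min: float = 0.60
    ed_min: float = 300.0
    tau_max: float = 0.7
    metric_scope: str = "all_classes"
    cd_confirmation: bool = True

    def __post_init__(self) -> None:
        for name in ("uaa_dominance_pct", "irrig_max_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.metric_scope not in ("all_classes", "farmland_only"):
            raise ValueError(f"unknown metric_scope {self.metric_scope!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


TRENDS = ("increase", "decrease", "unchanged", "not_applicable")


@dataclass
class UnitResult:
    """Per-unit candidate and refined HNV extents (geometries may be None
    for ineligible units)."""

    unit_id: str
    name: str
    eligible: bool
    phnvf_min_geom: BaseGeometry | None = None
    phnvf_max_geom: BaseGeometry | None = None
    phnvf_min_ha: float = 0.0
    phnvf_max_ha: float = 0.0
    hnvf1_geom: BaseGeometry | None = None
    hnvf2_geom: BaseGeometry | None = None
    hnvf3_geom: BaseGeometry | None = None
    hnvf1_ha: float = 0.0
    hnvf2_ha: float = 0.0
    hnvf3_ha: float = 0.0
    trend1: str = "not_applicable"
    trend2: str = "not_applicable"


@dataclass
class HnvfResult:
    """Full per-unit results plus municipality totals (hectares)."""

    units: list[UnitResult]
    crs: str = "EPSG:3763"

    def by_id(self, unit_id: str) -> UnitResult:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    @property
    def totals(self) -> dict[str, float]:
        t = {
            "phnvf_min_ha": sum(u.phnvf_min_ha for u in self.units),
            "phnvf_max_ha": sum(u.phnvf_max_ha for u in self.units),
            "hnvf1_ha": sum(u.hnvf1_ha for u in self.units),
            "hnvf2_ha": sum(u.hnvf2_ha for u in self.units),
            "hnvf3_ha": sum(u.hnvf3_ha for u in self.units),
        }
        t["total_hnvf_ha"] = t["hnvf1_ha"] + t["hnvf2_ha"] + t["hnvf3_ha"]
        return t

    def area_table(self) -> pd.DataFrame:
        """Per-unit accounting table in the published layout, plus a totals row."""
        rows = []
        for u in self.units:
            if u.eligible:
                rows.append(
                    {
                        "unit_id": u.unit_id, "name": u.name, "status": "eligible",
                        "phnvf_min_ha": round(u.phnvf_min_ha, 2),
                        "phnvf_max_ha": round(u.phnvf_max_ha, 2),
                        "hnvf1_ha": round(u.hnvf1_ha, 2), "trend1": u.trend1,
                        "hnvf2_ha": round(u.hnvf2_ha, 2), "trend2": u.trend2,
                        "hnvf3_ha": round(u.hnvf3_ha, 2),
                    }
                )
            else:
                rows.append(
                    {
                        "unit_id": u.unit_id, "name": u.name, "status": "n.a.",
                        "phnvf_min_ha": float("nan"), "phnvf_max_ha": float("nan"),
                        "hnvf1_ha": float("nan"), "trend1": "not_applicable",
                        "hnvf2_ha": float("nan"), "trend2": "not_applicable",
                        "hnvf3_ha": float("nan"),
                    }
                )
        df = pd.DataFrame(rows)
        totals = self.totals
        df.loc[len(df)] = {
            "unit_id": "TOTAL", "name": "municipality", "status": "",
            "phnvf_min_ha": round(totals["phnvf_min_ha"], 2),
            "phnvf_max_ha": round(totals["phnvf_max_ha"], 2),
            "hnvf1_ha": round(totals["hnvf1_ha"], 2), "trend1": "",
            "hnvf2_ha": round(totals["hnvf2_ha"], 2), "trend2": "",
            "hnvf3_ha": round(totals["hnvf3_ha"], 2),
        }
        return df


# ---------------------------------------------------------------------------
# GeoJSON helpers
# ---------------------------------------------------------------------------


def _read_feature_collection(path: str | Path) -> tuple[list[dict], str | None]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    crs = None
    if "crs" in payload:  # legacy named-CRS member
        crs = payload["crs"].get("properties", {}).get("name")
    return payload.get("features", []), crs


def write_feature_collection(
    path: str | Path, features: Iterable[tuple[BaseGeometry, dict]], crs: str
) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection with
    a legacy named-CRS member carrying the projected CRS identifier."""
    payload = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": [
            {"type": "Feature", "geometry": geom_mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def load_landcover(path: str | Path, registry: ClassRegistry) -> LandCoverMap:
    """Read a classed land-cover layer (GeoJSON; property ``class``).

    Every class code must resolve in *registry*; invalid geometries are
    repaired (zero-buffer) or rejected with the feature index.
    """
    raw, crs = _read_feature_collection(path)
    check_projected_crs(crs, str(path))
    features = []
    for i, feat in enumerate(raw):
        code = feat.get("properties", {}).get("class")
        if code is None:
            raise ValueError(f"{path}: feature {i} has no 'class' property")
        geom = clean_geometry(geom_shape(feat["geometry"]), f"{path}#{i}")
        if geom.is_empty:
            continue
        features.append(LandCoverFeature(geom, str(code)))
    registry.validate_codes(f.code for f in features)
    return LandCoverMap(features, crs=crs)


def load_constraints(path: str | Path) -> ConstraintMap:
    """Read a natural-constraints layer (GeoJSON; property ``limitation``)."""
    raw, crs = _read_feature_collection(path)
    check_projected_crs(crs, str(path))
    features = []
    for i, feat in enumerate(raw):
        lim = feat.get("properties", {}).get("limitation")
        geom = clean_geometry(geom_shape(feat["geometry"]), f"{path}#{i}")
        features.append(ConstraintFeature(geom, str(lim)))
    return ConstraintMap(features, crs=crs)


def load_units(path: str | Path) -> list[LandscapeUnit]:
    """Read administrative-unit boundaries (GeoJSON; properties ``unit_id``,
    ``name``)."""
    raw, crs = _read_feature_collection(path)
    check_projected_crs(crs, str(path))
    units = []
    for i, feat in enumerate(raw):
        props = feat.get("properties", {})
        uid = props.get("unit_id")
        if uid is None:
            raise ValueError(f"{path}: feature {i} has no 'unit_id' property")
        geom = clean_geometry(geom_shape(feat["geometry"]), f"{path}#{i}")
        units.append(LandscapeUnit.from_boundary(str(uid), str(props.get("name", uid)), geom))
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate unit_id values")
    return units


def load_occurrences(path: str | Path) -> list[SpeciesOccurrence]:
    """Read species occurrences (GeoJSON; properties ``species_id``, ``kind``)."""
    raw, crs = _read_feature_collection(path)
    check_projected_crs(crs, str(path))
    occs = []
    for i, feat in enumerate(raw):
        props = feat.get("properties", {})
        geom = clean_geometry(geom_shape(feat["geometry"]), f"{path}#{i}")
        occs.append(
            SpeciesOccurrence(str(props.get("species_id", f"sp{i}")),
                              str(props.get("kind", "plant_grid")), geom)
        )
    return occs


def load_agrarian(path: str | Path) -> dict[str, AgrarianRecord]:
    """Read the per-unit agrarian-statistics CSV.

    Expected columns: ``unit_id``, ``irrigated_ha``, livestock head counts in
    columns prefixed ``livestock_`` and crop areas (ha) in columns prefixed
    ``crop_``.  Missing numeric cells are read as 0 with a warning (census
    tables commonly leave zero cells blank); negative values and duplicated
    unit ids are errors.
    """
    df = pd.read_csv(path, dtype={"unit_id": str})
    if "unit_id" not in df.columns:
        raise ValueError(f"{path}: missing 'unit_id' column")
    if df["unit_id"].duplicated().any():
        dup = df.loc[df["unit_id"].duplicated(), "unit_id"].tolist()
        raise ValueError(f"{path}: duplicate unit_id values: {dup}")
    numeric_cols = [c for c in df.columns if c != "unit_id"]
    n_missing = int(df[numeric_cols].isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d missing numeric cells read as 0", path, n_missing)
    df[numeric_cols] = df[numeric_cols].fillna(0.0)
    for col in numeric_cols:
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValueError(f"{path}: negative value in column {col!r}, row {neg[0] + 2}")
    records = {}
    for _, row in df.iterrows():
        livestock = {
            c[len("livestock_"):]: float(row[c])
            for c in numeric_cols if c.startswith("livestock_")
        }
        crops = {
            c[len("crop_"):]: float(row[c])
            for c in numeric_cols if c.startswith("crop_")
        }
        records[row["unit_id"]] = AgrarianRecord(
            unit_id=row["unit_id"],
            livestock=livestock,
            irrigated_ha=float(row.get("irrigated_ha", 0.0)),
            crops=crops,
        )
    return records


def write_agrarian(records: Mapping[str, AgrarianRecord], path: str | Path) -> None:
    """Inverse of :func:`load_agrarian` (column order is deterministic)."""
    livestock_cats = sorted({c for r in records.values() for c in r.livestock})
    crop_types = sorted({c for r in records.values() for c in r.crops})
    rows = []
    for uid in records:
        r = records[uid]
        row: dict[str, object] = {"unit_id": uid, "irrigated_ha": r.irrigated_ha}
        for c in livestock_cats:
            row[f"livestock_{c}"] = r.livestock.get(c, 0.0)
        for c in crop_types:
            row[f"crop_{c}"] = r.crops.get(c, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result writer
# ---------------------------------------------------------------------------


def write_result(
    result: HnvfResult,
    out_dir: str | Path,
    indicators: IndicatorTable | None = None,
    manifest: dict | None = None,
) -> list[Path]:
    """Write per-type HNV geometries (GeoJSON layers), the per-unit area table
    and indicator table (CSV), and a JSON run manifest.  Returns written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for layer, attr in (
        ("hnvf1", "hnvf1_geom"), ("hnvf2", "hnvf2_geom"), ("hnvf3", "hnvf3_geom"),
        ("phnvf_min", "phnvf_min_geom"), ("phnvf_max", "phnvf_max_geom"),
    ):
        feats = []
        for u in result.units:
            geom = getattr(u, attr)
            if geom is not None and not geom.is_empty:
                feats.append(
                    (geom, {"unit_id": u.unit_id, "name": u.name,
                            "area_ha": round(area_ha(geom), 4)})
                )
        path = out / f"{layer}.geojson"
        write_feature_collection(path, feats, result.crs)
        written.append(path)
    areas_path = out / "hnvf_areas.csv"
    result.area_table().to_csv(areas_path, index=False)
    written.append(areas_path)
    if indicators is not None:
        ind_path = out / "indicators.csv"
        indicators.to_csv(ind_path)
        written.append(ind_path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest or {}, indent=2, sort_keys=True, default=str),
        encoding="utf-8",
    )
    written.append(manifest_path)
    return written
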