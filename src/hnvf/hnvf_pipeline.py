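"""The four-step High Nature Value farmland mapping framework.

Step 1 establishes, per landscape unit, the utilized agricultural area
(farmland classes plus off-farm grazing under no/moderate natural
constraints), screens units for farmland dominance, and maps the
minimum-maximum HNV candidate envelope (pHNVf_min: classes almost certainly
HNV; pHNVf_max: adding intensity-dependent classes).  Step 2 refines the
envelope with intensity thresholds: type 1 = minimum-candidate area of units
under extensive practices (low stocking rate, low irrigated share); type 2 =
the additional (maximum-only) candidate area of units whose landscapes show
high evenness and edge density, optionally confirmed by crop diversity.
Step 3 overlays indicator-species records (see :mod:`hnvf.species_overlay`)
and may designate complementary type-3 areas.  Step 4 assembles extents,
accounts areas per unit and municipality, and labels per-unit trends against
the unrefined envelope.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .core_model import (
    AgrarianRecord,
    ClassRegistry,
    ConstraintMap,
    HnvfResult,
    IndicatorTable,
    LandCoverMap,
    LandscapeUnit,
    LsuCoefficients,
    SpeciesOccurrence,
    ThresholdConfig,
    UnitResult,
    area_ha,
    write_result,
)
from .indicators import crop_diversity, irrigation_share, kendall_screen, livestock_density
from .landscape_metrics import clip_to_unit, landscape_elements
from .species_overlay import coincidence, designate_hnvf3

logger = logging.getLogger("hnvf")

#: tolerance (ha) for trend comparison and accounting closure
AREA_TOL_HA = 0.01


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Step 1 — UAA, dominance, candidate envelope
# ---------------------------------------------------------------------------


def compute_uaa(
    landcover: LandCoverMap,
    constraints: ConstraintMap | None,
    unit: LandscapeUnit,
    registry: ClassRegistry,
    uncovered_limitation: str = "none",
) -> tuple[LandscapeUnit, BaseGeometry]:
    """Utilized agricultural area of one unit, with natural-constraint masking.

    UAA = farmland-role classes plus off-farm-grazing classes restricted to
    areas under no or moderate limitation to agriculture.  Area not covered
    by the constraint layer is treated as having ``uncovered_limitation``
    (default ``none``, i.e. included).  Returns the unit with ``uaa_ha``,
    ``p_uaa_pct`` and ``p_forest_pct`` filled in, plus the UAA geometry.

    *landcover* must already be clipped to the unit.
    """
    farm_codes = registry.codes_with_role("farmland")
    graze_codes = registry.codes_with_role("off_farm_grazing")
    forest_codes = registry.forest_codes
    if not farm_codes and not graze_codes:
        raise PipelineError("class registry defines no farmland-role classes")

    farm_geoms = [f.geometry for f in landcover.features if f.code in farm_codes]
    graze_geoms = [f.geometry for f in landcover.features if f.code in graze_codes]
    forest_geoms = [f.geometry for f in landcover.features if f.code in forest_codes]

    parts: list[BaseGeometry] = list(farm_geoms)
    if graze_geoms:
        graze_union = unary_union(graze_geoms)
        allowed = _allowed_constraint_area(constraints, unit, uncovered_limitation)
        masked = graze_union.intersection(allowed) if allowed is not None else graze_union
        if not masked.is_empty:
            parts.append(masked)
    uaa_geom = unary_union(parts) if parts else unary_union([])
    uaa = area_ha(uaa_geom)
    uaa = min(uaa, unit.t_area_ha)  # guard against sliver overshoot
    forest_ha = sum(area_ha(g) for g in forest_geoms)
    updated = dataclasses.replace(
        unit,
        uaa_ha=uaa,
        p_uaa_pct=100.0 * uaa / unit.t_area_ha,
        p_forest_pct=min(100.0, 100.0 * forest_ha / unit.t_area_ha),
    )
    return updated, uaa_geom


def _allowed_constraint_area(
    constraints: ConstraintMap | None, unit: LandscapeUnit, uncovered_limitation: str
) -> BaseGeometry | None:
    """Area of the unit under no/moderate limitation; None means 'everywhere'."""
    if constraints is None:
        if uncovered_limitation == "severe":
            logger.warning(
                "unit %s: no constraint layer and uncovered area treated as severe; "
                "off-farm grazing contributes nothing", unit.unit_id,
            )
            return Polygon()
        return None
    ok_geoms = [
        f.geometry for f in constraints.features if f.limitation in ("none", "moderate")
    ]
    allowed = unary_union(ok_geoms) if ok_geoms else None
    covered = unary_union([f.geometry for f in constraints.features])
    uncovered = unit.boundary.difference(covered)
    if not uncovered.is_empty and uncovered.area > 0 and uncovered_limitation != "severe":
        allowed = uncovered if allowed is None else allowed.union(uncovered)
    if allowed is None:
        return uncovered if uncovered_limitation != "severe" else Polygon()
    return allowed


def dominance_screen(
    units: Sequence[LandscapeUnit], thresholds: ThresholdConfig
) -> list[LandscapeUnit]:
    """Retain units where farmland dominates the landscape.

    Inclusive boundary: p_uaa_pct >= uaa_dominance_pct retains the unit.
    Excluded units are reported n.a. downstream.
    """
    return [u for u in units if u.p_uaa_pct >= thresholds.uaa_dominance_pct]


@dataclass(frozen=True)
class CandidateEnvelope:
    """Per-unit minimum-maximum HNV candidate extents (geometry + hectares)."""

    phnvf_min_geom: BaseGeometry
    phnvf_max_geom: BaseGeometry

    @property
    def phnvf_min_ha(self) -> float:
        return area_ha(self.phnvf_min_geom)

    @property
    def phnvf_max_ha(self) -> float:
        return area_ha(self.phnvf_max_geom)


def min_max_candidates(
    landcover: LandCoverMap,
    unit: LandscapeUnit,
    registry: ClassRegistry,
    uaa_geom: BaseGeometry,
) -> CandidateEnvelope:
    """Minimum-maximum candidate envelope for one (clipped) unit.

    pHNVf_min = UAA area in minimum-likelihood classes; pHNVf_max adds
    maximum_only classes.  The minimum extent is contained in the maximum by
    construction.  Either may be empty.
    """
    min_codes = registry.minimum_codes
    max_codes = registry.maximum_codes
    min_geoms = [f.geometry for f in landcover.features if f.code in min_codes]
    max_geoms = [f.geometry for f in landcover.features if f.code in max_codes]
    min_geom = unary_union(min_geoms).intersection(uaa_geom) if min_geoms else unary_union([])
    max_geom = unary_union(max_geoms).intersection(uaa_geom) if max_geoms else unary_union([])
    max_geom = max_geom.union(min_geom)  # numerical safety: keep containment exact
    return CandidateEnvelope(min_geom, max_geom)


# ---------------------------------------------------------------------------
# Step 2 — threshold cascades (selection is purely tabular)
# ---------------------------------------------------------------------------


@dataclass
class CascadeSelection:
    """Which eligible units pass each cascade, and why others fell out."""

    hnvf1: list[str]
    hnvf2: list[str]
    excluded_lsi: list[str] = field(default_factory=list)
    excluded_irrig: list[str] = field(default_factory=list)
    excluded_sei: list[str] = field(default_factory=list)
    excluded_ed: list[str] = field(default_factory=list)
    cd_flagged: list[str] = field(default_factory=list)


def _indicator_value(indicators: IndicatorTable, unit_id: str, name: str) -> float:
    try:
        v = indicators.value(unit_id, name)
    except KeyError:
        raise PipelineError(
            f"step 2: missing indicator {name!r} for eligible unit {unit_id!r}"
        ) from None
    if math.isnan(v):
        raise PipelineError(
            f"step 2: missing indicator {name!r} for eligible unit {unit_id!r}"
        )
    return v


def select_hnvf1(
    eligible_ids: Sequence[str],
    indicators: IndicatorTable,
    thresholds: ThresholdConfig,
) -> tuple[list[str], list[str], list[str]]:
    """Extensive-practices cascade for HNV type 1.

    A unit passes iff lsi <= lsi_max (skipped when lsi_max is None) and
    irrig <= irrig_max_pct; boundaries retain.  Returns (selected,
    excluded_by_lsi, excluded_by_irrig); the filters apply sequentially, as
    the indicator sets were ranked and thresholded one at a time.
    """
    selected, excl_lsi, excl_irrig = [], [], []
    for uid in eligible_ids:
        if thresholds.lsi_max is not None:
            lsi = _indicator_value(indicators, uid, "lsi_p")
            if lsi > thresholds.lsi_max:
                excl_lsi.append(uid)
                continue
        irrig = _indicator_value(indicators, uid, "irrig_p")
        if irrig > thresholds.irrig_max_pct:
            excl_irrig.append(uid)
            continue
        selected.append(uid)
    return selected, excl_lsi, excl_irrig


def select_hnvf2(
    eligible_ids: Sequence[str],
    indicators: IndicatorTable,
    thresholds: ThresholdConfig,
    cd_mode: str = "confirm",
) -> tuple[list[str], list[str], list[str], list[str]]:
    """Landscape-structure cascade for HNV type 2.

    Sequential: units failing sei >= sei_min drop first; edge density
    (ed >= ed_min) is then required only of the remaining candidates, so a
    unit already excluded on evenness needs no edge-density value.  Crop
    diversity acts as confirmation by default: the bottom tercile of sdi_c
    among the evenness-passers is flagged (``cd_mode='confirm'``) or also
    excluded (``cd_mode='strict'``).

    Returns (selected, excluded_by_sei, excluded_by_ed, cd_flagged).
    """
    if cd_mode not in ("confirm", "strict"):
        raise ValueError(f"unknown cd_mode {cd_mode!r}")
    after_sei, excl_sei = [], []
    for uid in eligible_ids:
        sei = _indicator_value(indicators, uid, "sei_p")
        if sei < thresholds.sei_min:
            excl_sei.append(uid)
        else:
            after_sei.append(uid)
    selected, excl_ed = [], []
    for uid in after_sei:
        ed = _indicator_value(indicators, uid, "ed_p")
        if ed < thresholds.ed_min:
            excl_ed.append(uid)
        else:
            selected.append(uid)
    cd_flagged: list[str] = []
    if thresholds.cd_confirmation and len(after_sei) >= 3:
        sdi_c = {uid: _indicator_value(indicators, uid, "sdi_c") for uid in after_sei}
        k = math.ceil(len(after_sei) / 3)
        cd_flagged = sorted(sdi_c, key=sdi_c.get)[:k]
        confirmed = set(cd_flagged) & set(excl_ed)
        if confirmed:
            logger.info(
                "crop diversity confirms edge-density exclusion of: %s",
                ", ".join(sorted(confirmed)),
            )
        if cd_mode == "strict":
            selected = [uid for uid in selected if uid not in cd_flagged]
    return selected, excl_sei, excl_ed, cd_flagged


def run_cascade(
    eligible_ids: Sequence[str],
    indicators: IndicatorTable,
    thresholds: ThresholdConfig,
    cd_mode: str = "confirm",
    hnvf2_pool: str = "all_eligible",
) -> CascadeSelection:
    """Both Step-2 cascades on a table of eligible units.

    ``hnvf2_pool`` chooses the type-2 candidate population: all
    farmland-dominant units (default; type 1 and 2 can overlap in a unit) or
    only units failing the type-1 cascade (``intensive_only``).
    """
    sel1, excl_lsi, excl_irrig = select_hnvf1(eligible_ids, indicators, thresholds)
    if hnvf2_pool == "all_eligible":
        pool2 = list(eligible_ids)
    elif hnvf2_pool == "intensive_only":
        pool2 = [uid for uid in eligible_ids if uid not in sel1]
    else:
        raise ValueError(f"unknown hnvf2_pool {hnvf2_pool!r}")
    sel2, excl_sei, excl_ed, cd_flagged = select_hnvf2(
        pool2, indicators, thresholds, cd_mode
    )
    return CascadeSelection(
        hnvf1=sel1, hnvf2=sel2,
        excluded_lsi=excl_lsi, excluded_irrig=excl_irrig,
        excluded_sei=excl_sei, excluded_ed=excl_ed, cd_flagged=cd_flagged,
    )


# ---------------------------------------------------------------------------
# Step 4 — assembly, accounting, trends
# ---------------------------------------------------------------------------


def _trend(refined_ha: float, candidate_ha: float, tol: float = AREA_TOL_HA) -> str:
    if refined_ha < candidate_ha - tol:
        return "decrease"
    if refined_ha > candidate_ha + tol:
        return "increase"
    return "unchanged"


def assemble(
    units: Sequence[LandscapeUnit],
    eligible_ids: Sequence[str],
    envelopes: Mapping[str, CandidateEnvelope],
    selection: CascadeSelection,
    hnvf3_geoms: Mapping[str, BaseGeometry] | None = None,
    crs: str = "EPSG:3763",
) -> HnvfResult:
    """Assemble per-unit extents and municipality totals (Step 4).

    Type-1 extent of a selected unit is its minimum-candidate geometry;
    type-2 extent is the maximum-minus-minimum geometry; the two are
    geometrically disjoint by construction.  Trends compare refined areas
    against the candidate envelope at 0.01-ha tolerance.
    """
    eligible = set(eligible_ids)
    sel1, sel2 = set(selection.hnvf1), set(selection.hnvf2)
    results = []
    for unit in units:
        uid = unit.unit_id
        if uid not in eligible:
            results.append(UnitResult(uid, unit.name, eligible=False))
            continue
        env = envelopes[uid]
        min_geom, max_geom = env.phnvf_min_geom, env.phnvf_max_geom
        min_ha, max_ha = env.phnvf_min_ha, env.phnvf_max_ha
        hnvf1_geom = min_geom if uid in sel1 else None
        hnvf2_geom = max_geom.difference(min_geom) if uid in sel2 else None
        hnvf3_geom = (hnvf3_geoms or {}).get(uid)
        hnvf1_ha = area_ha(hnvf1_geom) if hnvf1_geom is not None else 0.0
        hnvf2_ha = area_ha(hnvf2_geom) if hnvf2_geom is not None else 0.0
        hnvf3_ha = area_ha(hnvf3_geom) if hnvf3_geom is not None else 0.0
        results.append(
            UnitResult(
                uid, unit.name, eligible=True,
                phnvf_min_geom=min_geom, phnvf_max_geom=max_geom,
                phnvf_min_ha=min_ha, phnvf_max_ha=max_ha,
                hnvf1_geom=hnvf1_geom, hnvf2_geom=hnvf2_geom, hnvf3_geom=hnvf3_geom,
                hnvf1_ha=hnvf1_ha, hnvf2_ha=hnvf2_ha, hnvf3_ha=hnvf3_ha,
                trend1=_trend(hnvf1_ha, min_ha),
                trend2=_trend(hnvf2_ha, max_ha - min_ha),
            )
        )
    return HnvfResult(results, crs=crs)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineOptions:
    """Switches the published account leaves open; defaults follow the
    framework's reference configuration and are recorded in the manifest."""

    uncovered_limitation: str = "none"
    exclude_unit_boundary: bool = False
    raster_shape_index: bool = False
    cd_mode: str = "confirm"
    hnvf2_pool: str = "all_eligible"
    hnvf3_designation: bool = True
    occurrence_grid_m: float = 1000.0
    lsu_coefficients: Mapping[str, float] | None = None
    run_kendall_screen: bool = True


@dataclass
class PipelineOutput:
    result: HnvfResult
    indicators: IndicatorTable
    selection: CascadeSelection
    eligible_ids: list[str]
    units: list[LandscapeUnit]
    uaa_geoms: dict[str, BaseGeometry]
    coincidence: pd.DataFrame | None
    manifest: dict

    def predicted_labels(self) -> dict[str, str]:
        """Per-unit classification: not_applicable / hnvf1 / hnvf2 / none.

        Type 1 takes precedence where a unit qualifies for both cascades.
        """
        labels = {}
        sel1, sel2 = set(self.selection.hnvf1), set(self.selection.hnvf2)
        eligible = set(self.eligible_ids)
        for u in self.units:
            if u.unit_id not in eligible:
                labels[u.unit_id] = "not_applicable"
            elif u.unit_id in sel1:
                labels[u.unit_id] = "hnvf1"
            elif u.unit_id in sel2:
                labels[u.unit_id] = "hnvf2"
            else:
                labels[u.unit_id] = "none"
        return labels


def run_pipeline(
    landcover: LandCoverMap,
    units: Sequence[LandscapeUnit],
    agrarian: Mapping[str, AgrarianRecord],
    registry: ClassRegistry,
    constraints: ConstraintMap | None = None,
    occurrences: Sequence[SpeciesOccurrence] | None = None,
    thresholds: ThresholdConfig | None = None,
    options: PipelineOptions | None = None,
) -> PipelineOutput:
    """Execute Steps 1-4 on in-memory inputs.  Deterministic for fixed input."""
    thresholds = thresholds or ThresholdConfig()
    options = options or PipelineOptions()
    coeffs = LsuCoefficients(options.lsu_coefficients)

    # Step 1 -- UAA, dominance, candidate envelope
    try:
        clipped: dict[str, LandCoverMap] = {}
        uaa_geoms: dict[str, BaseGeometry] = {}
        updated_units: list[LandscapeUnit] = []
        for unit in units:
            cm = clip_to_unit(landcover, unit)
            clipped[unit.unit_id] = cm
            updated, uaa_geom = compute_uaa(
                cm, constraints, unit, registry, options.uncovered_limitation
            )
            uaa_geoms[unit.unit_id] = uaa_geom
            updated_units.append(updated)
        eligible_units = dominance_screen(updated_units, thresholds)
        eligible_ids = [u.unit_id for u in eligible_units]
        envelopes = {
            u.unit_id: min_max_candidates(
                clipped[u.unit_id], u, registry, uaa_geoms[u.unit_id]
            )
            for u in eligible_units
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate the stage
        raise PipelineError(f"step 1 (UAA/dominance/envelope) failed: {exc}") from exc

    # indicators for eligible units
    try:
        rows: dict[str, dict[str, float]] = {}
        for unit in eligible_units:
            le = landscape_elements(
                landcover, unit,
                scope=thresholds.metric_scope, registry=registry,
                exclude_unit_boundary=options.exclude_unit_boundary,
                raster_shape_index=options.raster_shape_index,
            )
            record = agrarian.get(unit.unit_id)
            if record is None:
                raise PipelineError(
                    f"no agrarian record for eligible unit {unit.unit_id!r}"
                )
            sdi_c, sei_c, scrop = crop_diversity(record)
            rows[unit.unit_id] = {
                "sdi_p": le.sdi_p, "sei_p": le.sei_p, "np_p": le.np_p,
                "msi_p": le.msi_p, "ed_p": le.ed_p,
                "lsi_p": livestock_density(record, coeffs, unit),
                "irrig_p": irrigation_share(record, unit),
                "sdi_c": sdi_c, "sei_c": sei_c, "scrop_p": scrop,
            }
        indicators = IndicatorTable.from_rows(rows)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"step 2 (indicators) failed: {exc}") from exc

    screen = None
    if options.run_kendall_screen and len(rows) >= 3:
        screen = kendall_screen(indicators, tau_max=thresholds.tau_max)

    # Step 2 -- cascades
    selection = run_cascade(
        eligible_ids, indicators, thresholds,
        cd_mode=options.cd_mode, hnvf2_pool=options.hnvf2_pool,
    )

    # Step 3 -- species overlay
    coincidence_df = None
    hnvf3_geoms: dict[str, BaseGeometry] = {}
    if occurrences:
        try:
            sel1, sel2 = set(selection.hnvf1), set(selection.hnvf2)
            hnvf1_union = unary_union(
                [envelopes[u].phnvf_min_geom for u in sel1]
            ) if sel1 else None
            hnvf2_union = unary_union(
                [envelopes[u].phnvf_max_geom.difference(envelopes[u].phnvf_min_geom)
                 for u in sel2]
            ) if sel2 else None
            coincidence_df = coincidence(
                {"hnvf1": hnvf1_union, "hnvf2": hnvf2_union},
                occurrences, grid_m=options.occurrence_grid_m,
            )
            if options.hnvf3_designation:
                mapped = unary_union(
                    [g for g in (hnvf1_union, hnvf2_union) if g is not None]
                ) if (hnvf1_union is not None or hnvf2_union is not None) else None
                for unit in eligible_units:
                    geom = designate_hnvf3(
                        occurrences, mapped, uaa_geoms[unit.unit_id],
                        within=unit.boundary, grid_m=options.occurrence_grid_m,
                    )
                    if geom is not None and not geom.is_empty:
                        hnvf3_geoms[unit.unit_id] = geom
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"step 3 (species overlay) failed: {exc}") from exc

    # Step 4 -- assembly
    result = assemble(
        updated_units, eligible_ids, envelopes, selection,
        hnvf3_geoms=hnvf3_geoms, crs=landcover.crs,
    )
    manifest = {
        "thresholds": thresholds.to_dict(),
        "options": dataclasses.asdict(options),
        "n_units": len(units),
        "eligible_units": eligible_ids,
        "excluded_not_dominant": sorted(
            set(u.unit_id for u in updated_units) - set(eligible_ids)
        ),
        "selection": dataclasses.asdict(selection),
        "indicator_screen": {
            "retained": screen.retained, "dropped": screen.dropped,
        } if screen is not None else None,
        "totals_ha": {k: round(v, 2) for k, v in result.totals.items()},
    }
    return PipelineOutput(
        result=result, indicators=indicators, selection=selection,
        eligible_ids=eligible_ids, units=updated_units, uaa_geoms=uaa_geoms,
        coincidence=coincidence_df, manifest=manifest,
    )


# -- tabular worked example -------------------------------------------------


def run_worked_example(fixture, thresholds: ThresholdConfig | None = None) -> dict:
    """Drive the Step-2 cascade with printed per-unit indicator values.

    *fixture* supplies per-unit indicators, candidate envelope areas and
    refined areas (see ``synthetic_landscape.melgaco_table_fixture``); no
    geometry is involved.  The type-1 extent of a selected unit is its
    minimum-candidate area; type-2 areas come from the fixture's refined
    values, because the published type-2 extents carry an additional spatial
    mask that only the (undeposited) source layers could reproduce.

    By default the livestock filter is disabled, mirroring the published
    narrative where all stocking rates were treated as below the cut and
    irrigation alone discriminated type 1.
    """
    thresholds = thresholds or ThresholdConfig(lsi_max=None)
    eligible = fixture.eligible_ids
    selection = run_cascade(eligible, fixture.indicators, thresholds)
    hnvf1_total = sum(fixture.candidate_areas[u][0] for u in selection.hnvf1)
    hnvf2_total = sum(fixture.refined_areas[u][1] for u in selection.hnvf2)
    return {
        "n_units": fixture.n_units,
        "n_eligible": len(eligible),
        "n_not_dominant": fixture.n_units - len(eligible),
        "selection": selection,
        "hnvf1_total_ha": hnvf1_total,
        "hnvf2_total_ha": hnvf2_total,
        "total_hnvf_ha": hnvf1_total + hnvf2_total,
    }


# -- config-file driven run -------------------------------------------------

_CONFIG_KEYS = {"inputs", "thresholds", "options", "output_dir", "seed"}
_INPUT_KEYS = {"landcover", "units", "agrarian", "registry", "constraints", "occurrences"}


def load_config(path: str | Path) -> dict:
    """Read and validate a YAML run configuration (unknown keys are errors)."""
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"config: unknown keys {sorted(unknown)}")
    inputs = cfg.get("inputs", {})
    unknown = set(inputs) - _INPUT_KEYS
    if unknown:
        raise ValueError(f"config inputs: unknown keys {sorted(unknown)}")
    for required in ("landcover", "units", "agrarian"):
        if required not in inputs:
            raise ValueError(f"config inputs: missing required key {required!r}")
    thr_fields = {f.name for f in dataclasses.fields(ThresholdConfig)}
    unknown = set(cfg.get("thresholds", {})) - thr_fields
    if unknown:
        raise ValueError(f"config thresholds: unknown keys {sorted(unknown)}")
    opt_fields = {f.name for f in dataclasses.fields(PipelineOptions)}
    unknown = set(cfg.get("options", {})) - opt_fields
    if unknown:
        raise ValueError(f"config options: unknown keys {sorted(unknown)}")
    return cfg


def run_from_config(config_path: str | Path, out_dir: str | Path | None = None) -> PipelineOutput:
    """Load all inputs named in a config file, run the pipeline, write outputs."""
    from . import core_model as cm  # local import to keep module load light

    cfg = load_config(config_path)
    base = Path(config_path).parent
    inputs = cfg["inputs"]

    def _p(key: str) -> Path:
        p = Path(inputs[key])
        return p if p.is_absolute() else base / p

    registry = (
        ClassRegistry.from_yaml(_p("registry")) if "registry" in inputs
        else cm.default_registry()
    )
    landcover = cm.load_landcover(_p("landcover"), registry)
    units = cm.load_units(_p("units"))
    agrarian = cm.load_agrarian(_p("agrarian"))
    constraints = cm.load_constraints(_p("constraints")) if "constraints" in inputs else None
    occurrences = cm.load_occurrences(_p("occurrences")) if "occurrences" in inputs else None
    thresholds = ThresholdConfig(**cfg.get("thresholds", {}))
    options = PipelineOptions(**cfg.get("options", {}))
    output = run_pipeline(
        landcover, units, agrarian, registry,
        constraints=constraints, occurrences=occurrences,
        thresholds=thresholds, options=options,
    )
    output.manifest["seed"] = cfg.get("seed")
    output.manifest["config"] = str(config_path)
    target = out_dir or cfg.get("output_dir")
    if target is not None:
        write_result(output.result, target, output.indicators, output.manifest)
        if output.coincidence is not None:
            output.coincidence.to_csv(Path(target) / "species_coincidence.csv", index=False)
    return output
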