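# Methods

## Model and procedure

The package classifies High Nature Value farmland (HNVf) per landscape
unit — a civil parish or other local administrative unit (LAU) — by a
deterministic threshold cascade over three indicator sets, then accounts
areas per unit and municipality. The unit of analysis is always the whole
parish landscape: indicator values attach to units, and selected units
contribute candidate *areas* (not indicator-weighted surfaces) to the
mapped extent.

**Utilized agricultural area (UAA).** UAA is the union of farmland-role
land-cover classes plus off-farm-grazing classes (heathland and similar
commons used as forage), the latter restricted to ground under no or
moderate natural constraints to agriculture (ANC). The constraint
vocabulary is fixed at none/moderate/severe. Area not covered by the
constraint layer is treated, by default, as unconstrained
(`uncovered_limitation="none"`), on the argument that ANC layers map
handicaps rather than their absence; the strict alternative ("uncovered =
severe") is a config switch.

**Candidate envelope.** Each class carries an HNV likelihood: `minimum`
(primarily HNV wherever it occurs: semi-natural pasture, grazed heath),
`maximum_only` (HNV depending on intensity: arable mosaics, vineyards), or
`none`. Per unit, pHNVf_m is the UAA area in minimum classes and pHNVf_M
adds the maximum-only classes, so pHNVf_m ⊆ pHNVf_M by construction. The
registry enforces that minimum classes have a grazeable role, and that
codes are unique.

**Cascade.** Boundary semantics retain at equality throughout, because the
source account phrases every exclusion strictly ("above", "under" the
cut): a unit is farmland-dominant at p_UAA ≥ 40 %; type 1 requires
LSI ≤ 0.2 LSU/ha and Irrig ≤ 15 %; type 2 requires SEI ≥ 0.60 and
ED ≥ 300 m/ha. The filters run sequentially, so a unit dropped on evenness
never needs an edge-density value — this matters for the worked-example
fixture, where the published table reports grain metrics only for
evenness-passers. The type-2 cascade applies to all farmland-dominant
units, not only those failing type 1 (the published per-parish results
list two parishes under both types); `hnvf2_pool="intensive_only"`
selects the narrower reading. Crop diversity acts as *confirmation* by
default: the bottom tercile of SDI_c among evenness-passers is flagged and
compared with the edge-density exclusions; `cd_mode="strict"` turns the
flag into an exclusion.

The type-1 extent of a selected unit is its pHNVf_m geometry; the type-2
extent is pHNVf_M − pHNVf_m, making types 1 and 2 geometrically disjoint
within a unit. Trends compare refined against candidate areas at 0.01 ha,
the precision of the published accounting.

**Worked example and the stocking-rate filter.** The package ships the
published per-parish tables (12 eligible parishes of 18) as a tabular
fixture. Driving the cascade with them reproduces the published exclusion
sets and totals exactly — *provided* the livestock filter is disabled
(`lsi_max=None`), mirroring the source narrative in which all stocking
rates were treated as below 0.2 LSU/ha and irrigation alone discriminated
type 1. The same tables print one parish at 0.23 LSU/ha yet retain it,
an internal inconsistency of the source; the package keeps `lsi_max=0.2`
as a genuine filter in the default configuration for fresh data and
disables it only in the worked example. Published per-parish type-2 areas
are smaller than pHNVf_M − pHNVf_m, implying an unpublished spatial mask;
the worked example therefore takes type-2 areas from the printed refined
values, and per-parish type-2 geometry is not an acceptance surface.

**Species overlay and type 3.** Occurrences (1-km grid squares for plants;
IBA polygons for birds) are tallied as partially within a type (positive
intersection area) or completely within (covered). Because the source uses
species data only as a sensitivity check and states no construction rule
for type 3, the package adopts a set-algebra definition — species-supported
UAA minus the mapped type-1/2 extent, per unit — and gates it behind
`hnvf3_designation`; coincidence reporting alone mirrors the source
exactly. Point records are buffered to their stated grid resolution
(default 1 km, squares). IBA and plant records follow the same designation
rule.

## Landscape metrics

Patches are delineated by per-class polygon dissolve: same-class polygons
sharing a boundary segment of positive length merge; corner contact does
not (vector dissolve semantics; corner-merging is a raster 8-connectivity
artefact). Metrics per unit:

- NP: patch count; MSI: mean of p/(2√(πa)) over patches (circle-normalised
  vector shape index, ≥ 1; a raster-style square-normalised 0.25·p/√a is
  available behind `raster_shape_index` since the tooling the framework
  was developed with offers both);
- ED: Σ patch perimeters / unit area (m/ha). Unit-boundary segments are
  included by default, matching the upstream tool's default, and
  excludable via `exclude_unit_boundary`; the choice is recorded in the
  run manifest. Note ED counts each interior class boundary from both
  sides, which is what summing patch perimeters does;
- SDI/SEI: Shannon diversity and evenness over class area shares within
  the chosen scope (`all_classes` or `farmland_only`), shares below 1e-12
  dropped; SEI of a single-class landscape is defined as 0 (ln 1 division
  undefined; 0 encodes minimal diversity). The published grain threshold
  is stated with unit "ha" in prose but defined in m/ha; 300 is treated
  as m/ha.

The metric engine is validated against an independent raster oracle on
grid-aligned mosaics: connected-component labelling (4-connectivity,
scipy) for NP, per-cell neighbour counting for total edge, and direct
summation for SDI/SEI. Agreement is exact for NP and edge totals because
axis-aligned integer-coordinate unions keep lengths exactly representable.

**Kendall screening.** τ-b (tie-corrected, scipy) because small
administrative tables tie heavily; the redundancy rule applies to |τ| ≥ 0.7
(anti-correlation is equally redundant), dropping the lower-priority
member of a pair under a declared ecological-priority order (default:
Extensive Practices, then Landscape Elements, then Crop Diversity).
Constant columns have undefined τ and are retained with a warning.
Screening is reported in the manifest; it does not remove cascade inputs.

## Synthetic municipalities

The generator emulates the infield/outfield structure of north-Iberian
mountain municipalities: a rows×cols tiling of square units (default 2×3
units of 20×20 cells at 25 m, i.e. 25-ha units — small enough to keep a
100-municipality experiment within minutes on one CPU while leaving
hundreds of cells per unit for patch structure). Each unit draws a profile:

| profile | class mix | grain | Irrig (% UAA) | LSI (LSU/ha) | planted label |
|---|---|---|---|---|---|
| extensive_seminatural | pasture 0.45, heath 0.30, forest 0.15, arable 0.10 | 6–10 seeds | 0–8 | 0.02–0.12 | hnvf1 |
| mosaic_diverse | 7 classes, 0.08–0.18 each | 30–45 seeds | 20–40 | 0.02–0.12 | hnvf2 |
| intensive | irrigated crops 0.85, forest 0.10, artificial 0.05 | 3–6 seeds | 20–40 | 0.02–0.12 | none |
| forest_dominated | forest 0.70, pasture+heath 0.20, artificial 0.10 | 8–14 seeds | 0–10 | 0.02–0.12 | not_applicable |

Mosaics come from quota-bounded multi-source region growing (random
frontier expansion, 4-neighbour) and are polygonised by per-class cell
union, so class areas tile each unit exactly. The ranges are chosen to
keep profiles separable by the default thresholds with margin: the
mosaic profile sits far above the evenness (≈0.95 vs 0.60) and
edge-density (≈500–700 vs 300 m/ha) cuts, the intensive profile far below
evenness (≈0.45–0.55), and both sit well above the 15 % irrigation cut
that separates them from type 1. Stocking rates stay below the 0.2 LSU/ha
cut for every profile, as in the source setting where the livestock filter
did not bind. Constraint layers put severe limitation over the north half
of forest units (exercising the ANC mask); species squares (default 150 m
in the scaled-down scenario) are placed in extensive units with
probability `species_bias` (default 0.8), plus one IBA rectangle over the
first extensive unit.

What the generator does **not** emulate: irregular parish boundaries,
autocorrelated terrain-driven class gradients, census noise or reporting
error, multi-scale patch-size distributions, and real species clustering.
Passing recovery tests therefore demonstrates that the cascade recovers
labels when profiles are separable as constructed, not classification
accuracy on real municipalities.

## Numerical choices

- Areas are planar m²/10 000; one projected metric CRS is assumed for all
  layers, with geographic (degree) CRSs rejected at load.
- Invalid input polygons are repaired via `make_valid` (zero-buffer
  semantics); unrepairable features abort with the feature id.
- Clipping keeps only the areal component of intersections; slivers below
  1e-6 m² are ignored in species overlap tests.
- The candidate maximum is unioned with the minimum after masking, keeping
  the containment chain exact under floating-point overlay.
- Missing agrarian cells read as 0 with a warning (census tables commonly
  blank zero cells); negative values and duplicate unit ids are errors.
- Livestock-unit coefficients default to the Eurostat standard table
  (dairy cows 1.0, cattle 0.8, sheep/goats 0.1, …), overridable.
- Trend and accounting tolerance: 0.01 ha. Tie-break in the crop-diversity
  tercile: sort by SDI_c, then unit id (stable).
- Irrigated area exceeding UAA (different survey frames) warns and is
  capped at 100 % by default.

## Known limitations

- The shipped default class registry is illustrative; the original
  municipal land-cover nomenclature is not public, so real deployments
  must supply their own registry YAML.
- Exact reproduction of the published per-parish SDI/MSI/ED values is not
  attainable (source GIS layers and tool options unpublished); the metric
  engine is instead pinned by closed forms and the raster oracle, and the
  cascade by the published tables.
- Vector I/O is GeoJSON (with a named-CRS member); tables are CSV,
  configs YAML, manifests JSON. Raster ingestion and database backends
  are out of scope.
- CRS checking is by identifier blacklist of common geographic systems,
  not a full projection database; supplying an exotic geographic CRS
  under an unrecognised name would silently mis-scale areas.
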