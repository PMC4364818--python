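# hnvf — mapping High Nature Value farmland at administrative-unit level

High Nature Value farmland (HNVf) is agricultural land whose conservation
value depends on the continuation of low-intensity farming: semi-natural
pastures and grazed commons (type 1), fine-grained low-intensity mosaics
with small-scale landscape features (type 2), and farmland supporting
species of conservation concern, often within otherwise intensive
landscapes (type 3). EU rural-development monitoring requires Member States
to assess the extent of each type, but land-cover maps alone cannot
distinguish extensive from intensive use.

`hnvf` implements a spatially explicit, four-step threshold-cascade
framework that combines a fine-scale land-cover map with agrarian census
statistics and species records, working parish by parish (local
administrative units, LAUs):

1. **Step 1 — candidate envelope.** Per unit, the utilized agricultural
   area (UAA) is the union of farmland classes and off-farm grazing classes
   (e.g. heathland commons) restricted to areas under no or moderate
   natural constraints (ANC). Units where farmland covers at least 40 % of
   the landscape are retained. Within the UAA, land-cover classes map to a
   minimum–maximum candidate envelope: pHNVf_m (classes almost certainly
   HNV) ⊆ pHNVf_M (adding intensity-dependent classes).
2. **Step 2 — intensity refinement.** Type 1 = pHNVf_m of units under
   extensive practices: stocking rate LSI ≤ 0.2 LSU/ha of UAA and irrigated
   share Irrig ≤ 15 % of UAA. Type 2 = pHNVf_M − pHNVf_m of units whose
   landscape shows Shannon evenness SEI ≥ 0.60 and edge density
   ED ≥ 300 m/ha, with crop diversity (SDI_c) as confirmation. Landscape
   metrics (SDI = −Σ pᵢ ln pᵢ, SEI = SDI/ln m, NP, MSI = p/(2√(πa)), ED)
   are computed from edge-dissolved patches, over all classes or farmland
   only. Indicator redundancy is screened with Kendall's τ-b at |τ| ≥ 0.7.
3. **Step 3 — species validation.** Occurrences of indicator plants (1-km
   grid squares) and Important Bird Areas are overlaid on the mapped
   extent; species-supported UAA not already mapped can be designated
   type 3.
4. **Step 4 — assembly.** Per-unit and municipality area accounting, with
   trend labels (increase/decrease/unchanged) against the unrefined
   envelope.

A seeded synthetic-municipality generator (region-grown class mosaics,
per-unit census tables, biased species placement) provides complete inputs
with planted ground-truth labels, so the whole pipeline is testable without
the original GIS layers, which were never deposited.

## Worked example

The case-study tables that accompany the framework (per-parish indicator
values and candidate areas for an 18-parish municipality) ship as an
in-memory fixture; the cascade can be driven directly from them:

```sh
$ hnvf fixture-check
units: 18  eligible: 12  n.a.: 6
type-1 cascade excluded (irrigation): Alvaredo, Prado, Vila
type-2 cascade excluded (evenness):   Castro Laboreiro, Cubalhão, Lamas de Mouro, Parada do Monte
type-2 cascade excluded (edge dens.): Cousso, Fiães, Gave
        quantity   reproduced    printed
  hnvf1_total_ha      9478.17    9478.18
  hnvf2_total_ha       618.17     618.17
   total_hnvf_ha     10096.34   10096.35
```

Of the 18 parishes, 12 are farmland-dominant; irrigation above 15 % of UAA
removes three from type 1, and the evenness and edge-density cuts leave
five type-2 parishes. Reproduced totals differ from the printed ones only
by the 0.01-ha rounding carried by the published per-parish values.

The same cascade runs end-to-end on generated data:

```sh
hnvf synth --seed 5 --out demo/          # synthetic municipality + truth labels
hnvf run --config demo/config.yaml --out demo_out/
```

which prints the per-type totals and writes GeoJSON layers
(`hnvf1/2/3.geojson`, `phnvf_min/max.geojson`), the per-unit accounting and
indicator CSVs, and a JSON manifest recording every threshold applied.

As a library:

```python
from hnvf import PipelineOptions, run_pipeline
from hnvf.synthetic_landscape import SyntheticScenario, generate

m = generate(SyntheticScenario(seed=1))
out = run_pipeline(m.landcover, m.units, m.agrarian, m.registry,
                   constraints=m.constraints, occurrences=m.occurrences,
                   options=PipelineOptions(occurrence_grid_m=150.0))
print(out.result.totals)      # per-type hectares
print(out.predicted_labels()) # per-unit classification vs m.truth
```

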