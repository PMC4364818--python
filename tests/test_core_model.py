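"""Registry, domain-type invariants and I/O round-trips."""

import math

import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from hnvf import (
    AgrarianRecord,
    ClassRegistry,
    IndicatorTable,
    LandCoverClass,
    LandscapeUnit,
    LsuCoefficients,
    ThresholdConfig,
    area_ha,
    default_registry,
    load_agrarian,
    load_landcover,
    load_units,
    write_result,
)
from hnvf.core_model import (
    CrsError,
    RegistryError,
    clean_geometry,
    write_agrarian,
    write_feature_collection,
)
from hnvf.synthetic_landscape import SyntheticScenario, generate


class TestRegistry:
    def test_minimum_subset_of_maximum(self, registry):
        assert registry.minimum_codes <= registry.maximum_codes

    def test_duplicate_code_rejected(self):
        cls = LandCoverClass("A", "a", "farmland", "minimum")
        with pytest.raises(RegistryError, match="duplicate"):
            ClassRegistry([cls, cls])

    def test_minimum_requires_grazeable_role(self):
        with pytest.raises(RegistryError, match="minimum"):
            LandCoverClass("F", "forest", "forest", "minimum")

    def test_unknown_code_named_in_error(self, registry):
        with pytest.raises(RegistryError, match="'X9'"):
            registry.validate_codes(["PP", "X9"])

    def test_yaml_round_trip(self, registry, tmp_path):
        path = tmp_path / "registry.yaml"
        registry.to_yaml(path)
        back = ClassRegistry.from_yaml(path)
        assert back.minimum_codes == registry.minimum_codes
        assert back.codes == registry.codes
        assert back["PP"].role == "farmland"


class TestGeometry:
    def test_area_convention_m2_per_ha(self):
        assert area_ha(box(0, 0, 100, 100)) == pytest.approx(1.0)

    def test_self_intersection_repaired(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        fixed = clean_geometry(bowtie, "f0")
        assert fixed.is_valid and fixed.area == pytest.approx(2.0)

    def test_unit_invariants(self):
        with pytest.raises(ValueError, match="t_area"):
            LandscapeUnit("u", "u", box(0, 0, 1, 1), t_area_ha=0.0)
        with pytest.raises(ValueError, match="uaa_ha"):
            LandscapeUnit("u", "u", box(0, 0, 100, 100), t_area_ha=1.0, uaa_ha=2.0)


class TestVectorIO:
    def test_landcover_pass_through(self, registry, tmp_path):
        path = tmp_path / "lc.geojson"
        feats = [(box(i * 10, 0, i * 10 + 10, 10), {"class": c})
                 for i, c in enumerate(["PP", "HE", "BF"])]
        write_feature_collection(path, feats, "EPSG:3763")
        lc = load_landcover(path, registry)
        assert len(lc.features) == 3
        assert lc.codes() == {"PP", "HE", "BF"}

    def test_unknown_class_code_error(self, registry, tmp_path):
        path = tmp_path / "lc.geojson"
        write_feature_collection(path, [(box(0, 0, 1, 1), {"class": "X9"})], "EPSG:3763")
        with pytest.raises(RegistryError, match="'X9'"):
            load_landcover(path, registry)

    def test_geographic_crs_rejected(self, registry, tmp_path):
        path = tmp_path / "lc.geojson"
        write_feature_collection(path, [(box(0, 0, 1, 1), {"class": "PP"})], "EPSG:4326")
        with pytest.raises(CrsError, match="projected"):
            load_landcover(path, registry)

    def test_synthetic_export_round_trip(self, tmp_path):
        """Write-then-read preserves per-class areas within 1e-6 ha."""
        muni = generate(SyntheticScenario(seed=3))
        paths = muni.write(tmp_path)
        lc = load_landcover(paths["landcover"], muni.registry)
        assert lc.area_by_class() == pytest.approx(
            muni.landcover.area_by_class(), abs=1e-6
        )
        units = load_units(paths["units"])
        assert [u.unit_id for u in units] == [u.unit_id for u in muni.units]
        for a, b in zip(units, muni.units):
            assert a.t_area_ha == pytest.approx(b.t_area_ha, abs=1e-6)


class TestAgrarianIO:
    def test_two_rows(self, tmp_path):
        path = tmp_path / "agri.csv"
        path.write_text(
            "unit_id,irrigated_ha,livestock_cattle,crop_rye\nu1,5,10,2\nu2,0,0,8\n"
        )
        records = load_agrarian(path)
        assert set(records) == {"u1", "u2"}
        assert records["u1"].livestock == {"cattle": 10.0}
        assert records["u2"].crops == {"rye": 8.0}

    def test_duplicate_unit_id_error(self, tmp_path):
        path = tmp_path / "agri.csv"
        path.write_text("unit_id,irrigated_ha\nu1,5\nu1,6\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_agrarian(path)

    def test_missing_cells_read_as_zero(self, tmp_path, caplog):
        path = tmp_path / "agri.csv"
        path.write_text("unit_id,irrigated_ha,livestock_cattle\nu1,,3\n")
        records = load_agrarian(path)
        assert records["u1"].irrigated_ha == 0.0
        assert any("missing" in r.message for r in caplog.records)

    def test_negative_value_names_row(self, tmp_path):
        path = tmp_path / "agri.csv"
        path.write_text("unit_id,irrigated_ha\nu1,3\nu2,-1\n")
        with pytest.raises(ValueError, match="row 3"):
            load_agrarian(path)

    def test_generator_round_trip(self, municipality, tmp_path):
        path = tmp_path / "agri.csv"
        write_agrarian(municipality.agrarian, path)
        back = load_agrarian(path)
        for uid, rec in municipality.agrarian.items():
            assert back[uid].irrigated_ha == pytest.approx(rec.irrigated_ha)
            assert back[uid].livestock == pytest.approx(rec.livestock)
            # absent crops round-trip as explicit zero cells
            for crop in set(back[uid].crops) | set(rec.crops):
                assert back[uid].crops.get(crop, 0.0) == pytest.approx(
                    rec.crops.get(crop, 0.0)
                )

    def test_negative_count_rejected_in_record(self):
        with pytest.raises(ValueError, match="negative"):
            AgrarianRecord("u", livestock={"cattle": -1})


class TestTablesAndConfig:
    def test_indicator_table_bounds(self):
        with pytest.raises(ValueError, match="sei_p"):
            IndicatorTable.from_rows({"u": {"sei_p": 1.5}})

    def test_indicator_csv_round_trip(self, tmp_path):
        table = IndicatorTable.from_rows(
            {"u1": {"sdi_p": 1.2, "sei_p": 0.7, "np_p": 4, "msi_p": 1.3,
                    "ed_p": 250.0, "lsi_p": 0.1, "irrig_p": 12.0,
                    "sdi_c": 0.9, "sei_c": 0.8, "scrop_p": 3}}
        )
        path = tmp_path / "ind.csv"
        table.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert "SDI_p" in header and "Irrig_p" in header
        back = IndicatorTable.from_csv(path)
        pd.testing.assert_frame_equal(back.data, table.data, atol=1e-9)

    def test_lsu_coefficients(self):
        coeffs = LsuCoefficients()
        assert coeffs["sheep"] == 0.1
        with pytest.raises(ValueError):
            LsuCoefficients({"cattle": 0.0})

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="irrig_max_pct"):
            ThresholdConfig(irrig_max_pct=150.0)
        with pytest.raises(ValueError, match="metric_scope"):
            ThresholdConfig(metric_scope="bogus")


class TestResultWriter:
    def test_written_result_consistency(self, pipeline_output, tmp_path):
        """One feature per unit in each non-empty layer; CSV totals row equals
        the sum of unit rows within 0.01 ha."""
        out = pipeline_output
        written = write_result(out.result, tmp_path, out.indicators, out.manifest)
        names = {p.name for p in written}
        assert {"hnvf1.geojson", "hnvf_areas.csv", "manifest.json"} <= names
        df = pd.read_csv(tmp_path / "hnvf_areas.csv")
        totals = df[df.unit_id == "TOTAL"].iloc[0]
        body = df[df.unit_id != "TOTAL"]
        for col in ("phnvf_min_ha", "phnvf_max_ha", "hnvf1_ha", "hnvf2_ha"):
            assert totals[col] == pytest.approx(body[col].sum(), abs=0.01 + 1e-9)
        import json
        layer = json.loads((tmp_path / "hnvf1.geojson").read_text())
        sel = set(out.selection.hnvf1)
        ids = {f["properties"]["unit_id"] for f in layer["features"]}
        assert ids <= sel and len(layer["features"]) == len(ids)

    def test_area_csv_round_trip(self, pipeline_output, tmp_path):
        pipeline_output.result.area_table().to_csv(tmp_path / "a.csv", index=False)
        back = pd.read_csv(tmp_path / "a.csv")
        orig = pipeline_output.result.area_table()
        assert math.isclose(
            back[back.unit_id == "TOTAL"].hnvf1_ha.iloc[0],
            orig[orig.unit_id == "TOTAL"].hnvf1_ha.iloc[0],
        )
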