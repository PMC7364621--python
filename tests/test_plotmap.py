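import json

import numpy as np
import pandas as pd
import pytest

from fieldhtp.plotmap import (
    PlotMapError,
    clip_observations,
    load_plot_map,
    row_deviation,
)
from oracles import assign_plots_raycast


def _geojson(features, epsg=32612):
    return {"type": "FeatureCollection",
            "crs": {"type": "name", "properties": {"name": f"EPSG:{epsg}"}},
            "features": features}


def _rect_feature(pid, x0, y0, w, h, **props):
    ring = [[x0, y0], [x0 + w, y0], [x0 + w, y0 + h], [x0, y0 + h], [x0, y0]]
    return {"type": "Feature",
            "properties": {"plot_id": pid, **props},
            "geometry": {"type": "Polygon", "coordinates": [ring]}}


class TestLoadPlotMap:
    def test_simulator_map_loads(self, small_sim):
        m = load_plot_map(small_sim.plot_map_path)
        assert len(m) == small_sim.config.n_plots
        assert m.zone == 12 and m.hemisphere == "N"
        assert "line_id" in m.attribute_table().columns

    def test_duplicate_plot_id_fatal(self, tmp_path):
        doc = _geojson([_rect_feature("A", 0, 0, 1, 2),
                        _rect_feature("A", 5, 0, 1, 2)])
        p = tmp_path / "dup.geojson"
        p.write_text(json.dumps(doc))
        with pytest.raises(PlotMapError, match="'A'"):
            load_plot_map(p)

    def test_missing_plot_id_fatal(self, tmp_path):
        feat = _rect_feature("A", 0, 0, 1, 2)
        del feat["properties"]["plot_id"]
        p = tmp_path / "noid.geojson"
        p.write_text(json.dumps(_geojson([feat])))
        with pytest.raises(PlotMapError, match="plot_id"):
            load_plot_map(p)

    def test_empty_collection_warns(self, tmp_path):
        p = tmp_path / "empty.geojson"
        p.write_text(json.dumps(_geojson([])))
        with pytest.warns(UserWarning, match="empty"):
            m = load_plot_map(p)
        assert len(m) == 0


class TestClipping:
    @pytest.fixture()
    def grid_map(self, tmp_path):
        feats = [_rect_feature(f"P{c}{r}", c * 1.02, r * 12.0, 1.02, 12.0)
                 for c in range(3) for r in range(4)]
        p = tmp_path / "grid.geojson"
        p.write_text(json.dumps(_geojson(feats)))
        return load_plot_map(p)

    def test_interior_and_exterior_points(self, grid_map):
        obs = pd.DataFrame({"sensor_e": [0.51, -1.0], "sensor_n": [6.0, 6.0]})
        out = clip_observations(obs, grid_map)
        assert out["plot_id"].tolist() == ["P00", None]

    def test_boundary_point_counts_inside(self, grid_map):
        obs = pd.DataFrame({"sensor_e": [0.0], "sensor_n": [0.0]})
        out = clip_observations(obs, grid_map)
        assert out["plot_id"].iloc[0] == "P00"

    def test_matches_raycasting_oracle(self, grid_map):
        rng = np.random.default_rng(9)
        pts = np.column_stack([rng.uniform(-1, 4.1, 10_000),
                               rng.uniform(-1, 49.0, 10_000)])
        obs = pd.DataFrame({"sensor_e": pts[:, 0], "sensor_n": pts[:, 1]})
        got = clip_observations(obs, grid_map)["plot_id"].tolist()
        plots = [(p.plot_id, list(p.polygon.exterior.coords))
                 for p in grid_map.plots]
        expected = assign_plots_raycast(pts, plots)
        assert got == expected

    def test_count_conservation(self, grid_map):
        rng = np.random.default_rng(2)
        obs = pd.DataFrame({"sensor_e": rng.uniform(-2, 6, 500),
                            "sensor_n": rng.uniform(-2, 50, 500)})
        out = clip_observations(obs, grid_map)
        assigned = out["plot_id"].notna().sum()
        assert assigned + out["plot_id"].isna().sum() == len(obs)

    def test_zone_mismatch_fatal(self, grid_map):
        obs = pd.DataFrame({"sensor_e": [0.5], "sensor_n": [6.0],
                            "utm_zone": [13]})
        with pytest.raises(PlotMapError, match="zone mismatch"):
            clip_observations(obs, grid_map)


class TestRowDeviation:
    @pytest.fixture()
    def one_plot(self, tmp_path):
        p = tmp_path / "one.geojson"
        p.write_text(json.dumps(_geojson([_rect_feature("A", 0, 0, 1.02, 12.0)])))
        return load_plot_map(p)

    def test_centerline_is_zero(self, one_plot):
        obs = pd.DataFrame({"sensor_e": [0.51], "sensor_n": [6.0],
                            "plot_id": ["A"]})
        dev = row_deviation(obs, one_plot)
        assert dev.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_plot_edge_is_half_width(self, one_plot):
        obs = pd.DataFrame({"sensor_e": [1.02, 0.0], "sensor_n": [6.0, 6.0],
                            "plot_id": ["A", "A"]})
        dev = row_deviation(obs, one_plot)
        assert sorted(np.abs(dev).round(6)) == [0.51, 0.51]

    def test_simulated_wobble_recovered(self, messy_sim):
        """Max |deviation| over the run approximately equals the wobble
        amplitude, using the simulator's true sensor track."""
        m = load_plot_map(messy_sim.plot_map_path)
        gt = messy_sim.ground_truth
        gt = gt[(gt["corrupted"] == 0) & (gt["trait"] == "height")]
        obs = pd.DataFrame({"sensor_e": gt["sensor_e"].to_numpy(),
                            "sensor_n": gt["sensor_n"].to_numpy(),
                            "plot_id": gt["plot_id"].astype(str).to_numpy()})
        dev = row_deviation(obs, m)
        amp = messy_sim.config.wobble_amplitude
        assert np.nanmax(np.abs(dev)) == pytest.approx(amp, rel=0.1)
        # the signed deviation (east-positive) is exactly the injected wobble
        assert np.allclose(dev.to_numpy(), gt["wobble_m"].to_numpy(), atol=1e-9)
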