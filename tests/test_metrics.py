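import numpy as np
import pandas as pd
import pytest

from vascage.graph import VesselEdge, VesselGraph
from vascage.metrics import (
    RegionAtlas,
    branching_density,
    layer_profile,
    length_density,
    mean_radius,
    nearest_vessel_distance,
    pericyte_coverage,
    pericyte_density,
    region_length_um,
    region_metrics,
    vessel_surface_voxels,
)
from vascage.synthetic import generate_pericytes


def single_region_atlas(extent_um=1000.0, voxel_um=50.0):
    n = int(extent_um / voxel_um)
    return RegionAtlas.single_region((n, n, n), (voxel_um,) * 3)


def line_graph(length_um=1000.0, radius=3.0, origin=(10.0, 10.0, 10.0), direction=(1, 0, 0)):
    g = VesselGraph()
    origin = np.asarray(origin, dtype=float)
    end = origin + np.asarray(direction, dtype=float) * length_um
    a, b = g.add_node(origin), g.add_node(end)
    poly = np.linspace(origin, end, max(int(length_um // 10), 2))
    g.add_edge(VesselEdge(a, b, poly, np.full(poly.shape[0], radius)))
    return g


class TestDensities:
    def test_one_millimeter_edge_in_cubic_millimeter(self):
        # 1000 µm of vessel in 1 mm³ is 0.001 m/mm³ by definition
        atlas = single_region_atlas()
        g = line_graph(980.0)  # fits the 1 mm box with margin
        assert length_density(g, atlas, 1) == pytest.approx(980e-6, rel=1e-12)

    def test_empty_region_has_zero_density(self):
        atlas = single_region_atlas()
        assert length_density(VesselGraph(), atlas, 1) == 0.0
        assert branching_density(VesselGraph(), atlas, 1) == 0.0

    def test_absent_region_raises(self):
        atlas = single_region_atlas()
        with pytest.raises(KeyError):
            length_density(line_graph(), atlas, 99)

    def test_ledger_oracle_on_generated_network(self, phantom_network, phantom_params):
        graph, ledger = phantom_network
        extent = float(phantom_params.domain_shape_um[0])
        atlas = RegionAtlas.single_region((30, 30, 30), (extent / 30,) * 3)
        vol_mm3 = extent**3 * 1e-9
        assert length_density(graph, atlas, 1) == pytest.approx(
            ledger.total_length_um * 1e-6 / vol_mm3, rel=1e-6
        )
        assert branching_density(graph, atlas, 1) * vol_mm3 == pytest.approx(
            ledger.branch_point_count
        )

    def test_straight_vessel_has_no_branches(self):
        atlas = single_region_atlas()
        assert branching_density(line_graph(), atlas, 1) == 0.0

    def test_single_trifurcation_counts_once(self):
        atlas = single_region_atlas()
        g = VesselGraph()
        c = g.add_node([500.0, 500, 500])
        for k, d in enumerate(([1, 0, 0], [0, 1, 0], [0, 0, 1])):
            e = g.add_node(np.array([500.0, 500, 500]) + np.asarray(d) * 100)
            poly = np.linspace([500.0, 500, 500], g.nodes[e], 11)
            g.add_edge(VesselEdge(c, e, poly, np.full(11, 2.0)))
        assert branching_density(g, atlas, 1) == pytest.approx(1.0)

    def test_partition_additivity_of_length(self, phantom_network):
        graph, ledger = phantom_network
        # 8 octant regions tile the 300 µm cube
        n = 30
        labels = np.zeros((n, n, n), dtype=np.int32)
        for i, (ox, oy, oz) in enumerate(
            [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)], start=1
        ):
            labels[
                ox * n // 2 : (ox + 1) * n // 2,
                oy * n // 2 : (oy + 1) * n // 2,
                oz * n // 2 : (oz + 1) * n // 2,
            ] = i
        table = pd.DataFrame(
            [{"region_id": i, "name": f"oct{i}", "parent": 0, "layer": None} for i in range(1, 9)]
        )
        atlas = RegionAtlas(labels, np.full(3, 10.0), table)
        total = sum(region_length_um(graph, atlas, i) for i in range(1, 9))
        assert total == pytest.approx(ledger.total_length_um, rel=1e-9)


class TestMeanRadius:
    def test_uniform_radius(self):
        atlas = single_region_atlas()
        assert mean_radius(line_graph(500, radius=3.0), atlas, 1) == pytest.approx(3.0)

    def test_equal_lengths_average(self):
        atlas = single_region_atlas()
        g = VesselGraph()
        a, b, c = (
            g.add_node(p) for p in ([10.0, 10, 10], [210.0, 10, 10], [410.0, 10, 10])
        )
        p1 = np.linspace([10.0, 10, 10], [210.0, 10, 10], 5)
        p2 = np.linspace([210.0, 10, 10], [410.0, 10, 10], 5)
        g.add_edge(VesselEdge(a, b, p1, np.full(5, 2.0)))
        g.add_edge(VesselEdge(b, c, p2, np.full(5, 4.0)))
        assert mean_radius(g, atlas, 1) == pytest.approx(3.0)

    def test_length_weighted_average(self):
        atlas = single_region_atlas()
        g = VesselGraph()
        a, b, c = (
            g.add_node(p) for p in ([10.0, 10, 10], [20.0, 10, 10], [50.0, 10, 10])
        )
        g.add_edge(VesselEdge(a, b, np.linspace([10.0, 10, 10], [20.0, 10, 10], 3), np.full(3, 2.0)))
        g.add_edge(VesselEdge(b, c, np.linspace([20.0, 10, 10], [50.0, 10, 10], 3), np.full(3, 4.0)))
        # lengths 10 and 30: (10*2 + 30*4)/40 = 3.5
        assert mean_radius(g, atlas, 1) == pytest.approx(3.5)


class TestPericytes:
    def test_density_by_arithmetic(self):
        rng = np.random.default_rng(1)
        atlas = RegionAtlas.single_region((10, 10, 10), (50.0,) * 3)  # 0.125 mm³
        pts = pd.DataFrame(
            {
                "x_um": rng.uniform(0, 500, 50),
                "y_um": rng.uniform(0, 500, 50),
                "z_um": rng.uniform(0, 500, 50),
                "subtype": ["mesh"] * 50,
            }
        )
        assert pericyte_density(pts, atlas, 1) == pytest.approx(50 / 0.125)
        assert pericyte_density(pts, atlas, 1, subtype="thin-strand") == 0.0

    def test_empty_set_zero_density(self):
        atlas = single_region_atlas()
        empty = pd.DataFrame(columns=["x_um", "y_um", "z_um", "subtype"])
        assert pericyte_density(empty, atlas, 1) == 0.0

    def test_generated_counts_exact_against_ledger(self, phantom_network):
        graph, _ = phantom_network
        pts = generate_pericytes(graph, {"mesh": 30.0}, seed=7)
        atlas = RegionAtlas.single_region((30, 30, 30), (10.0,) * 3)
        density = pericyte_density(pts, atlas, 1)
        # cells sit up to one vessel radius off the centerline, so a few may
        # poke out of the atlas box; count those inside
        xyz = pts[["x_um", "y_um", "z_um"]].to_numpy()
        inside = int(np.all((xyz >= 0) & (xyz < 300.0), axis=1).sum())
        assert density * atlas.region_volume_mm3(1) == pytest.approx(inside)

    def test_coverage_cells_per_mm_vessel(self):
        # 100 cells on 1 mm of vessel in the region -> 100 cells per mm
        atlas = single_region_atlas()
        g = line_graph(1000.0, origin=(0.0, 10, 10))
        rng = np.random.default_rng(0)
        pts = pd.DataFrame(
            {
                "x_um": rng.uniform(0, 999, 100),
                "y_um": np.full(100, 10.0),
                "z_um": np.full(100, 10.0),
                "subtype": ["mesh"] * 100,
            }
        )
        assert pericyte_coverage(pts, g, atlas, 1) == pytest.approx(100.0)

    def test_coverage_scale_invariance(self, phantom_network):
        graph, _ = phantom_network
        atlas = RegionAtlas.single_region((30, 30, 30), (10.0,) * 3)
        pts = generate_pericytes(graph, {"mesh": 25.0}, seed=3)
        cov = pericyte_coverage(pts, graph, atlas, 1)
        doubled = pd.concat([pts, pts], ignore_index=True)
        g2 = VesselGraph(nodes=dict(graph.nodes), edges=list(graph.edges))
        assert pericyte_coverage(doubled, g2, atlas, 1) == pytest.approx(2 * cov)

    def test_zero_vessel_length_raises(self):
        atlas = single_region_atlas()
        pts = pd.DataFrame(columns=["x_um", "y_um", "z_um", "subtype"])
        with pytest.raises(ValueError, match="vessel length"):
            pericyte_coverage(pts, VesselGraph(), atlas, 1)


class TestNearestVesselDistance:
    def small_phantom(self):
        vol = np.zeros((60, 60, 60), dtype=bool)
        vol[28:33, 28:33, 5:55] = True  # rough tube along z
        return vol

    def test_probe_on_surface_is_zero(self):
        vol = self.small_phantom()
        res = nearest_vessel_distance(binary=vol, probe_spacing_um=5.0)
        surf = (vessel_surface_voxels(vol) + 0.5).astype(float)
        # the probe grid at 5 µm spacing includes points at surface voxel centers
        on_surface = [
            i
            for i, p in enumerate(res.probe_positions_um)
            if np.any(np.all(np.isclose(surf, p), axis=1))
        ]
        assert on_surface
        assert np.all(res.distance_um[on_surface][~np.isnan(res.distance_um[on_surface])] == 0)

    def test_matches_brute_force_within_cube(self):
        vol = self.small_phantom()
        res = nearest_vessel_distance(binary=vol, probe_spacing_um=10.0, cube_halfwidth_um=100.0)
        surf = (vessel_surface_voxels(vol) + 0.5).astype(float)
        for p, d in zip(res.probe_positions_um, res.distance_um):
            if np.isnan(d):
                continue
            cheb = np.abs(surf - p).max(axis=1)
            inside = cheb <= 100.0
            brute = np.linalg.norm(surf[inside] - p, axis=1).min()
            assert d == pytest.approx(brute, abs=1e-9)

    def test_graph_distance_simple_geometry(self):
        # straight vessel radius 5 on the z axis; probe 30 µm off-axis -> 25 µm
        g = line_graph(190.0, radius=5.0, origin=(100.0, 100.0, 5.0), direction=(0, 0, 1))
        res = nearest_vessel_distance(
            graph=g, probe_spacing_um=10.0, extent_um=(200.0, 200.0, 200.0)
        )
        probes = res.probe_positions_um
        sel = np.isclose(probes[:, 0], 135.0) & np.isclose(probes[:, 1], 95.0) & (
            np.abs(probes[:, 2] - 95.0) < 6
        )
        assert sel.any()
        # probe at (135, 95, 95): axial distance sqrt(35² + 5²) ≈ 35.36, minus r=5
        expected = np.hypot(35.0, 5.0) - 5.0
        assert res.distance_um[sel][0] == pytest.approx(expected, abs=0.5)

    def test_monotone_under_added_vasculature(self):
        vol1 = self.small_phantom()
        vol2 = vol1.copy()
        vol2[5:10, 5:10, 5:55] = True  # extra tube
        r1 = nearest_vessel_distance(binary=vol1, probe_spacing_um=10.0)
        r2 = nearest_vessel_distance(binary=vol2, probe_spacing_um=10.0)
        both = ~np.isnan(r1.distance_um) & ~np.isnan(r2.distance_um)
        assert np.all(r2.distance_um[both] <= r1.distance_um[both] + 1e-9)

    def test_empty_vasculature_raises(self):
        with pytest.raises(ValueError, match="empty"):
            nearest_vessel_distance(binary=np.zeros((10, 10, 10), dtype=bool))

    def test_censoring_flagged_when_cube_empty(self):
        vol = np.zeros((150, 150, 150), dtype=bool)
        vol[2:6, 2:6, 2:6] = True  # tiny corner blob
        res = nearest_vessel_distance(binary=vol, probe_spacing_um=20.0, cube_halfwidth_um=40.0)
        assert res.censored.any()
        assert np.all(res.distance_um[res.censored] == 40.0)


class TestLayerProfile:
    def make_metrics(self):
        return pd.DataFrame(
            {
                "region_id": [1, 2, 3],
                "name": ["a", "b", "c"],
                "layer": ["L6", "L6", "L1"],
                "volume_mm3": [1.0, 3.0, 2.0],
                "length_density_m_per_mm3": [0.4, 0.8, 0.5],
            }
        )

    def test_single_region_layer_passes_through(self):
        prof = layer_profile(self.make_metrics(), "length_density_m_per_mm3")
        l1 = prof[prof["layer"] == "L1"].iloc[0]
        assert l1["length_density_m_per_mm3"] == pytest.approx(0.5)

    def test_volume_weighted_mean_matches_pooled(self):
        prof = layer_profile(self.make_metrics(), "length_density_m_per_mm3")
        l6 = prof[prof["layer"] == "L6"].iloc[0]
        # pooled: (0.4*1 + 0.8*3) / 4
        assert l6["length_density_m_per_mm3"] == pytest.approx(0.7)

    def test_equal_volume_regions_arithmetic_mean(self):
        df = self.make_metrics()
        df["volume_mm3"] = 2.0
        prof = layer_profile(df, "length_density_m_per_mm3")
        l6 = prof[prof["layer"] == "L6"].iloc[0]
        assert l6["length_density_m_per_mm3"] == pytest.approx(0.6)


class TestRegionMetricsTable:
    def test_tidy_table_with_pericytes(self, phantom_network):
        graph, ledger = phantom_network
        atlas = RegionAtlas.single_region((30, 30, 30), (10.0,) * 3)
        pts = generate_pericytes(graph, {"mesh": 20.0}, seed=5)
        df = region_metrics(graph, atlas, pts)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["length_density_m_per_mm3"] == pytest.approx(
            ledger.total_length_um * 1e-6 / 0.027, rel=1e-6
        )
        assert row["pericyte_density_per_mm3"] * 0.027 == pytest.approx(len(pts))
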