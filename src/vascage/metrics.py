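"""Region-wise structural statistics over vessel graphs.

Implements the morphometric quantities of cerebrovascular aging studies:
vascular length density (m/mm³), branching density (1/mm³), length-weighted
mean radius (µm), nearest-vessel distance (µm), arc-chord tortuosity,
pericyte density (1/mm³) and pericyte coverage (cells per mm vessel), all
aggregated within the regions of a label atlas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .graph import VesselGraph, arc_chord_ratio  # noqa: F401  (re-exported)
from .synthetic import _resample_polyline


@dataclass
class RegionAtlas:
    """3D integer label volume plus a region table.

    ``labels`` holds one region id per voxel (0 = outside); ``table`` maps
    region id to name, parent id and an optional cortical-layer tag.  Region
    volume is voxel count times voxel volume.
    """

    labels: np.ndarray
    voxel_size_um: np.ndarray
    table: pd.DataFrame  # columns: region_id, name, parent, layer

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.voxel_size_um = np.asarray(self.voxel_size_um, dtype=float)
        if np.any(self.voxel_size_um <= 0):
            raise ValueError("voxel sizes must be > 0")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.table["region_id"])
        missing = present - known
        if missing:
            raise ValueError(f"labels {sorted(missing)} absent from region table")

    @classmethod
    def single_region(cls, shape, voxel_size_um, region_id: int = 1, name: str = "region"):
        labels = np.full(shape, region_id, dtype=np.int32)
        table = pd.DataFrame(
            [{"region_id": region_id, "name": name, "parent": 0, "layer": None}]
        )
        return cls(labels, np.asarray(voxel_size_um, dtype=float), table)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_um)) * 1e-9

    def region_volume_mm3(self, region_id: int) -> float:
        if region_id not in set(self.table["region_id"]):
            raise KeyError(f"region {region_id} not in atlas table")
        return int((self.labels == region_id).sum()) * self.voxel_volume_mm3()

    def label_at(self, positions_um: np.ndarray) -> np.ndarray:
        """Region label at world positions (µm); 0 outside the volume."""
        pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
        idx = np.floor(pos / self.voxel_size_um).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.labels.shape)), axis=1)
        out = np.zeros(len(pos), dtype=self.labels.dtype)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


def validate_cell_points(points: pd.DataFrame) -> pd.DataFrame:
    """Check a pericyte point table (x_um, y_um, z_um, subtype)."""
    from .synthetic import PERICYTE_SUBTYPES

    required = {"x_um", "y_um", "z_um", "subtype"}
    if not required <= set(points.columns):
        raise ValueError(f"cell table needs columns {sorted(required)}")
    xyz = points[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("cell coordinates must be finite")
    bad = set(points["subtype"]) - set(PERICYTE_SUBTYPES)
    if bad:
        raise ValueError(f"unknown pericyte subtypes {sorted(bad)}")
    return points


# ---------------------------------------------------------------------------
# per-region metrics
# ---------------------------------------------------------------------------


def _segment_midpoints_lengths(graph: VesselGraph):
    mids, lengths, radii = [], [], []
    for e in graph.edges:
        p = e.polyline
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        mids.append(0.5 * (p[:-1] + p[1:]))
        lengths.append(seg)
        radii.append(0.5 * (e.radii[:-1] + e.radii[1:]))
    if not mids:
        return np.zeros((0, 3)), np.zeros(0), np.zeros(0)
    return np.vstack(mids), np.concatenate(lengths), np.concatenate(radii)


def region_length_um(graph: VesselGraph, atlas: RegionAtlas, region_id: int) -> float:
    """Total centerline length (µm) of segments whose midpoint is in the region."""
    mids, lengths, _ = _segment_midpoints_lengths(graph)
    if mids.shape[0] == 0:
        return 0.0
    lab = atlas.label_at(mids)
    return float(lengths[lab == region_id].sum())


def length_density(graph: VesselGraph, atlas: RegionAtlas, region_id: int) -> float:
    """Vascular length density in m/mm³ (µm of centerline per mm³, × 1e-6)."""
    vol = atlas.region_volume_mm3(region_id)
    if vol <= 0:
        raise ValueError(f"region {region_id} has zero volume")
    return region_length_um(graph, atlas, region_id) * 1e-6 / vol


def branching_density(graph: VesselGraph, atlas: RegionAtlas, region_id: int) -> float:
    """Branch points (graph nodes of degree >= 3) per mm³."""
    vol = atlas.region_volume_mm3(region_id)
    if vol <= 0:
        raise ValueError(f"region {region_id} has zero volume")
    branch_ids = graph.branch_nodes()
    if not branch_ids:
        return 0.0
    pos = np.vstack([graph.nodes[n] for n in branch_ids])
    lab = atlas.label_at(pos)
    return float((lab == region_id).sum()) / vol


def mean_radius(graph: VesselGraph, atlas: RegionAtlas, region_id: int) -> float:
    """Length-weighted mean vessel radius (µm) over segments in the region."""
    mids, lengths, radii = _segment_midpoints_lengths(graph)
    if mids.shape[0] == 0:
        return 0.0
    lab = atlas.label_at(mids)
    sel = lab == region_id
    if not sel.any() or lengths[sel].sum() == 0:
        return 0.0
    return float(np.average(radii[sel], weights=lengths[sel]))


def pericyte_density(
    points: pd.DataFrame, atlas: RegionAtlas, region_id: int, subtype: str | None = None
) -> float:
    """Pericyte count per mm³ in a region, optionally for one subtype."""
    vol = atlas.region_volume_mm3(region_id)
    if vol <= 0:
        raise ValueError(f"region {region_id} has zero volume")
    if len(points) == 0:
        return 0.0
    pts = points if subtype is None else points[points["subtype"] == subtype]
    if len(pts) == 0:
        return 0.0
    lab = atlas.label_at(pts[["x_um", "y_um", "z_um"]].to_numpy(dtype=float))
    return float((lab == region_id).sum()) / vol


def pericyte_coverage(
    points: pd.DataFrame, graph: VesselGraph, atlas: RegionAtlas, region_id: int
) -> float:
    """Pericytes per mm of vessel in a region (density over length density).

    With counts and lengths measured in the same region this reduces to
    cell count divided by vessel length in mm.
    """
    length_mm = region_length_um(graph, atlas, region_id) / 1000.0
    if length_mm == 0:
        raise ValueError(f"region {region_id} contains no vessel length")
    if len(points) == 0:
        return 0.0
    lab = atlas.label_at(points[["x_um", "y_um", "z_um"]].to_numpy(dtype=float))
    return float((lab == region_id).sum()) / length_mm


# ---------------------------------------------------------------------------
# nearest-vessel distance
# ---------------------------------------------------------------------------


def vessel_surface_voxels(binary: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background 6-neighbor."""
    binary = np.asarray(binary).astype(bool)
    eroded = ndimage.binary_erosion(
        binary, structure=ndimage.generate_binary_structure(3, 1), border_value=1
    )
    return np.argwhere(binary & ~eroded)


@dataclass
class NearestDistanceResult:
    """Probe-grid nearest-vessel distances.

    ``distance_um`` is NaN at probes inside the vasculature; ``censored``
    flags probes whose ±cube contained no vessel surface (distance reported
    as the cube half-width).
    """

    probe_positions_um: np.ndarray
    distance_um: np.ndarray
    censored: np.ndarray
    probe_spacing_um: float
    cube_halfwidth_um: float

    def mean_distance(self) -> float:
        d = self.distance_um[~np.isnan(self.distance_um)]
        return float(d.mean()) if d.size else float("nan")


def nearest_vessel_distance(
    binary: np.ndarray | None = None,
    voxel_size_um=(1.0, 1.0, 1.0),
    graph: VesselGraph | None = None,
    probe_spacing_um: float = 10.0,
    cube_halfwidth_um: float = 100.0,
    atlas: RegionAtlas | None = None,
    extent_um=None,
) -> NearestDistanceResult | tuple[NearestDistanceResult, pd.DataFrame]:
    """Distance from tissue probe points to the nearest vessel surface.

    Probes sit on a regular grid (default 10 µm isotropic).  For each probe
    outside the vasculature, the reported distance is the minimum straight-line
    distance to any vessel surface point inside the ±``cube_halfwidth_um``
    Cartesian cube around the probe.  Probes inside the vessel lumen are
    excluded (NaN): intravascular distance is not a perfusion metric.  If the
    cube holds no surface point the distance is censored at the cube
    half-width and flagged.

    Either a binary volume (surface = foreground voxels with a background
    6-neighbor) or a graph (surface = centerline points offset by local
    radius, i.e. ``max(0, |probe−centerline| − r)``) may be supplied.

    With ``atlas`` given, also returns a per-region mean-distance table.
    """
    voxel_size = np.asarray(voxel_size_um, dtype=float)
    if binary is not None:
        binary = np.asarray(binary).astype(bool)
        if not binary.any():
            raise ValueError("empty vasculature")
        extent = voxel_size * np.asarray(binary.shape)
        surface = (vessel_surface_voxels(binary) + 0.5) * voxel_size
        tree = cKDTree(surface)
        radii = None
    elif graph is not None and graph.edges:
        lo, hi = graph.bounding_box()
        extent = hi if extent_um is None else np.asarray(extent_um, dtype=float)
        pts_list, rad_list = [], []
        for e in graph.edges:
            p, r = _resample_polyline(e.polyline, e.radii, probe_spacing_um / 4)
            pts_list.append(p)
            rad_list.append(r)
        cloud = np.vstack(pts_list)
        radii = np.concatenate(rad_list)
        tree = cKDTree(cloud)
    else:
        raise ValueError("empty vasculature")

    grids = [np.arange(probe_spacing_um / 2, extent[d], probe_spacing_um) for d in range(3)]
    probes = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)

    dist = np.full(len(probes), np.nan)
    censored = np.zeros(len(probes), dtype=bool)
    # Euclidean nearest neighbor; a neighbor within the cube half-width is
    # automatically inside the cube (Chebyshev <= Euclidean).
    if radii is None:
        d_near, _ = tree.query(probes, k=1, distance_upper_bound=cube_halfwidth_um)
        inside = _probes_inside(binary, probes, voxel_size)
        for i, (d, inn) in enumerate(zip(d_near, inside)):
            if inn:
                continue
            if np.isfinite(d):
                dist[i] = d
            else:
                dist[i], censored[i] = _cube_search(tree, probes[i], cube_halfwidth_um)
    else:
        dd, jj = tree.query(probes, k=1)
        surf_d = dd - radii[jj]
        for i in range(len(probes)):
            if surf_d[i] <= 0:
                continue  # probe inside the lumen
            if dd[i] <= cube_halfwidth_um:
                dist[i] = max(surf_d[i], 0.0)
            else:
                d_c, cen = _cube_search(tree, probes[i], cube_halfwidth_um, radii)
                dist[i], censored[i] = d_c, cen

    result = NearestDistanceResult(probes, dist, censored, probe_spacing_um, cube_halfwidth_um)
    if atlas is None:
        return result
    lab = atlas.label_at(probes)
    rows = []
    for rid in atlas.table["region_id"]:
        sel = (lab == rid) & ~np.isnan(dist)
        rows.append(
            {
                "region_id": rid,
                "mean_nearest_distance_um": float(dist[sel].mean()) if sel.any() else np.nan,
                "n_probes": int(sel.sum()),
            }
        )
    return result, pd.DataFrame(rows)


def _probes_inside(binary: np.ndarray, probes: np.ndarray, voxel_size: np.ndarray) -> np.ndarray:
    idx = np.floor(probes / voxel_size).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(binary.shape)), axis=1)
    out = np.zeros(len(probes), dtype=bool)
    ii = idx[ok]
    out[ok] = binary[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def _cube_search(tree: cKDTree, probe: np.ndarray, half: float, radii=None):
    """Min distance over points with Chebyshev distance <= half (cube corners
    can hold points with Euclidean distance up to sqrt(3) x half)."""
    cand = tree.query_ball_point(probe, np.sqrt(3.0) * half)
    if cand:
        pts = tree.data[cand]
        cheb = np.abs(pts - probe).max(axis=1)
        inside = cheb <= half
        if inside.any():
            d = np.linalg.norm(pts[inside] - probe, axis=1)
            if radii is not None:
                d = np.maximum(d - np.asarray(radii)[np.asarray(cand)[inside]], 0.0)
            return float(d.min()), False
    return half, True


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

METRIC_COLUMNS = (
    "length_density_m_per_mm3",
    "branching_density_per_mm3",
    "mean_radius_um",
    "pericyte_density_per_mm3",
    "pericyte_coverage_per_mm",
)


def region_metrics(
    graph: VesselGraph,
    atlas: RegionAtlas,
    points: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy per-region metric table (one row per region)."""
    rows = []
    for _, reg in atlas.table.iterrows():
        rid = reg["region_id"]
        length_um = region_length_um(graph, atlas, rid)
        row = {
            "region_id": rid,
            "name": reg["name"],
            "layer": reg.get("layer"),
            "volume_mm3": atlas.region_volume_mm3(rid),
            "length_density_m_per_mm3": length_density(graph, atlas, rid),
            "branching_density_per_mm3": branching_density(graph, atlas, rid),
            "mean_radius_um": mean_radius(graph, atlas, rid),
        }
        if points is not None:
            row["pericyte_density_per_mm3"] = pericyte_density(points, atlas, rid)
            row["pericyte_coverage_per_mm"] = (
                pericyte_coverage(points, graph, atlas, rid) if length_um > 0 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def layer_profile(metrics: pd.DataFrame, value_column: str) -> pd.DataFrame:
    """Aggregate a per-region metric over cortical layer tags.

    Region-volume-weighted mean per layer — for densities this equals pooling
    the underlying counts/lengths over the layer's regions.
    """
    if value_column not in metrics.columns:
        raise KeyError(value_column)
    df = metrics[metrics["layer"].notna()]
    rows = []
    for layer, grp in df.groupby("layer"):
        w = grp["volume_mm3"].to_numpy(dtype=float)
        v = grp[value_column].to_numpy(dtype=float)
        rows.append(
            {
                "layer": layer,
                value_column: float(np.average(v, weights=w)),
                "volume_mm3": float(w.sum()),
                "n_regions": len(grp),
            }
        )
    return pd.DataFrame(rows).sort_values("layer").reset_index(drop=True)


# ---------------------------------------------------------------------------
# atlas I/O
# ---------------------------------------------------------------------------


def save_atlas(atlas: RegionAtlas, volume_path, table_path) -> None:
    import tifffile

    tifffile.imwrite(volume_path, atlas.labels.astype(np.int32))
    meta = {
        "voxel_size_um": atlas.voxel_size_um.tolist(),
        "regions": atlas.table.to_dict(orient="records"),
    }
    Path(table_path).write_text(json.dumps(meta))


def load_atlas(volume_path, table_path) -> RegionAtlas:
    import tifffile

    labels = tifffile.imread(volume_path)
    meta = json.loads(Path(table_path).read_text())
    return RegionAtlas(
        labels, np.asarray(meta["voxel_size_um"], dtype=float), pd.DataFrame(meta["regions"])
    )
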