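"""Synthetic data generators with ground-truth ledgers.

Every input the analysis pipeline consumes can be generated here with known
ground truth: vascular networks (controllable length density, branching rate,
radii and tortuosity) voxelized to binary volumes, pericyte point sets placed
on vessels, treadmill locomotion sessions, and hemodynamic traces built by
convolving locomotion events with a known gamma-variate response kernel.

The network generator grows a seeded forest of branching random walks.  This
is a phenomenological model: it reproduces the observables the structural
metrics measure (length density in m/mm³, branch points per mm³, radius
distributions, arc-chord tortuosity), not the developmental biology of
angiogenesis.  All generators are deterministic given their seed; per-stage
RNGs are spawned from a single ``SeedSequence`` so partial pipelines remain
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .graph import VesselEdge, VesselGraph, prune_terminal_stubs

PERICYTE_SUBTYPES = ("ensheathing", "mesh", "thin-strand", "capillary-unspecified")


def power_radius_law(base_um: float = 4.0, decay: float = 0.85, sigma: float = 0.1):
    """Radius law: mean radius ``base_um * decay**order`` with lognormal sigma.

    Returns a callable mapping branch order to ``(mean_um, lognormal_sigma)``.
    The defaults cover the capillary range (2-4 µm) for the branch orders a
    small simulated volume reaches; they are repository choices, not
    measured anatomy.
    """

    def law(order: int) -> tuple[float, float]:
        return base_um * decay**order, sigma

    return law


@dataclass
class NetworkGenParams:
    """Knobs of the branching-random-walk vessel generator.

    Parameters
    ----------
    domain_shape_um
        Edge lengths of the axis-aligned simulation box (µm).
    target_length_density
        Desired total centerline length per volume, in m/mm³ (whole-brain
        mouse values are around 0.4-1 m/mm³).
    branch_rate
        Expected branch points per mm of generated vessel.
    radius_law
        Callable mapping branch order -> (mean radius µm, lognormal sigma).
    tortuosity_amp
        Amplitude of the per-step random direction perturbation
        (dimensionless; 0 gives perfectly straight segments).
    seed
        Integer seed; identical seeds give byte-identical networks.
    step_um
        Centerline step length of the growth walk (µm).
    """

    domain_shape_um: Sequence[float] = (300.0, 300.0, 300.0)
    target_length_density: float = 0.4
    branch_rate: float = 3.0
    radius_law: Callable[[int], tuple[float, float]] = field(default_factory=power_radius_law)
    tortuosity_amp: float = 0.0
    seed: int = 0
    step_um: float = 5.0
    min_separation_um: float = 0.0
    min_fork_spacing_um: float = 25.0

    def __post_init__(self) -> None:
        self.domain_shape_um = np.asarray(self.domain_shape_um, dtype=float)
        if self.domain_shape_um.shape != (3,) or np.any(self.domain_shape_um <= 0):
            raise ValueError("domain_shape_um must be 3 positive lengths")
        if self.target_length_density <= 0:
            raise ValueError("target_length_density must be > 0")
        if self.branch_rate <= 0:
            raise ValueError("branch_rate must be > 0")
        if self.tortuosity_amp < 0:
            raise ValueError("tortuosity_amp must be >= 0")
        if self.step_um <= 0:
            raise ValueError("step_um must be > 0")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")

    @property
    def target_length_um(self) -> float:
        vol_mm3 = float(np.prod(self.domain_shape_um)) * 1e-9
        return self.target_length_density * vol_mm3 * 1e6  # m -> µm


@dataclass
class GroundTruthLedger:
    """Book of record for a synthetic dataset.

    Every entry is recomputable from the generated objects by direct
    enumeration; tests rely on that invariant.
    """

    total_length_um: float | None = None
    branch_point_count: int | None = None
    mean_radius_um: float | None = None
    edge_arc_lengths_um: list[float] = field(default_factory=list)
    edge_chord_lengths_um: list[float] = field(default_factory=list)
    pericyte_counts: dict[str, int] = field(default_factory=dict)
    hrf_true: tuple[float, float, float] | None = None
    event_intervals: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total_length_um": self.total_length_um,
            "branch_point_count": self.branch_point_count,
            "mean_radius_um": self.mean_radius_um,
            "edge_arc_lengths_um": list(self.edge_arc_lengths_um),
            "edge_chord_lengths_um": list(self.edge_chord_lengths_um),
            "pericyte_counts": dict(self.pericyte_counts),
            "hrf_true": list(self.hrf_true) if self.hrf_true else None,
            "event_intervals": [list(ev) for ev in self.event_intervals],
        }


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular_jitter(direction: np.ndarray, angle_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``direction`` by ``angle_deg`` about a random perpendicular axis."""
    perp = np.cross(direction, _random_unit_vector(rng))
    n = np.linalg.norm(perp)
    while n < 1e-9:
        perp = np.cross(direction, _random_unit_vector(rng))
        n = np.linalg.norm(perp)
    perp /= n
    a = np.deg2rad(angle_deg)
    return np.cos(a) * direction + np.sin(a) * perp


class _SpatialHash:
    """Uniform-grid point hash for separation queries during growth."""

    def __init__(self, cell: float) -> None:
        self.cell = cell
        self.cells: dict[tuple[int, int, int], list[int]] = {}
        self.points: list[np.ndarray] = []
        self.branch_of: list[int] = []
        self.step_of: list[int] = []

    def add(self, p: np.ndarray, branch: int, step: int) -> None:
        i = len(self.points)
        self.points.append(p)
        self.branch_of.append(branch)
        self.step_of.append(step)
        key = tuple((p // self.cell).astype(int))
        self.cells.setdefault(key, []).append(i)

    def too_close(
        self, p: np.ndarray, min_sep: float, branch: int, step: int,
        exclude_steps: int, junction: np.ndarray | None,
        related: frozenset | None = None,
    ) -> bool:
        k = tuple((p // self.cell).astype(int))
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for i in self.cells.get((k[0] + dz, k[1] + dy, k[2] + dx), ()):
                        if (
                            self.branch_of[i] == branch
                            and step - self.step_of[i] <= exclude_steps
                        ):
                            continue
                        q = self.points[i]
                        if (
                            junction is not None
                            and related is not None
                            and self.branch_of[i] in related
                            and np.linalg.norm(q - junction) < min_sep + self.cell
                        ):
                            continue  # parent/sibling points near the shared fork
                        if np.linalg.norm(q - p) < min_sep:
                            return True
        return False


def generate_vessel_network(params: NetworkGenParams) -> tuple[VesselGraph, GroundTruthLedger]:
    """Grow a branching-random-walk vessel forest to a target length density.

    Trees are seeded at uniform random interior points and grown step by step.
    At each step the heading is perturbed by a Gaussian angle proportional to
    ``tortuosity_amp``; with probability ``branch_rate * step/1000`` the walk
    forks at a junction node (degree 3).  Branches terminate at the domain
    boundary (clipped to it), when stepping would approach another vessel
    closer than ``min_separation_um`` (set it to a few vessel diameters to
    get well-separated, unambiguously traceable phantoms), or when the global
    length budget is exhausted — so the ledger total matches the requested
    density to within one step.

    Raises
    ------
    ValueError
        If the requested density is infeasible for the domain (the implied
        vessel volume at the order-0 radius would exceed ~30% of the box).
    """
    target = params.target_length_um
    r0 = params.radius_law(0)[0]
    vessel_vol = target * np.pi * r0**2
    if vessel_vol > 0.3 * float(np.prod(params.domain_shape_um)):
        raise ValueError(
            f"infeasible density: requested {target:.3g} µm of vessel at radius "
            f"{r0:.3g} µm would fill >30% of the domain"
        )

    ss = np.random.SeedSequence(params.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    lo = np.zeros(3)
    hi = params.domain_shape_um
    step = params.step_um
    p_branch = min(params.branch_rate * step / 1000.0, 0.5)
    angle_sd_deg = 40.0 * params.tortuosity_amp  # per-step heading jitter

    graph = VesselGraph()
    grown = 0.0
    min_sep = params.min_separation_um
    hash_ = _SpatialHash(max(min_sep, step)) if min_sep > 0 else None
    exclude_steps = int(np.ceil(min_sep / step)) + 2
    branch_counter = 0

    def clip_to_box(p: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Last in-box point on segment p->q (p inside, q outside)."""
        d = q - p
        t = 1.0
        for ax in range(3):
            if d[ax] > 0 and q[ax] > hi[ax]:
                t = min(t, (hi[ax] - p[ax]) / d[ax])
            elif d[ax] < 0 and q[ax] < lo[ax]:
                t = min(t, (lo[ax] - p[ax]) / d[ax])
        return p + max(t, 0.0) * d

    while grown < target:
        root = lo + rng.uniform(0.05, 0.95, size=3) * (hi - lo)
        if hash_ is not None:
            tries = 0
            while hash_.too_close(root, min_sep, -1, 0, 0, None) and tries < 200:
                root = lo + rng.uniform(0.05, 0.95, size=3) * (hi - lo)
                tries += 1
            if tries >= 200:
                raise ValueError(
                    "cannot place a new tree at the requested separation; "
                    "density infeasible with min_separation_um"
                )
        root_id = graph.add_node(root)
        branch_counter += 1
        # stack of branches: (start node, heading, order, fork pos, id, related ids)
        stack = [(root_id, _random_unit_vector(rng), 0, None, branch_counter, None)]
        while stack and grown < target:
            start_id, direction, order, junction, branch_id, related = stack.pop()
            branch_start = graph.nodes[start_id].copy()
            mean_r, sigma_r = params.radius_law(order)
            radius = float(mean_r * np.exp(rng.normal(0.0, sigma_r)))
            pts = [branch_start.copy()]
            if hash_ is not None:
                hash_.add(pts[0], branch_id, 0)
            n_step = 0
            while grown < target:
                if params.tortuosity_amp > 0:
                    direction = _perpendicular_jitter(
                        direction, rng.normal(0.0, angle_sd_deg), rng
                    )
                nxt = pts[-1] + direction * step
                if np.any(nxt < lo) or np.any(nxt > hi):
                    nxt = clip_to_box(pts[-1], nxt)
                    if np.linalg.norm(nxt - pts[-1]) > 1e-9:
                        grown += float(np.linalg.norm(nxt - pts[-1]))
                        pts.append(nxt)
                    break
                n_step += 1
                if hash_ is not None and hash_.too_close(
                    nxt, min_sep, branch_id, n_step, exclude_steps, junction, related
                ):
                    break
                grown += step
                pts.append(nxt)
                if hash_ is not None:
                    hash_.add(nxt, branch_id, n_step)
                # fork only if the straight-ahead continuation has room for a
                # few more steps; a fork whose continuation dies immediately
                # would leave a bent merged edge once the stub is retracted
                def continuation_has_room() -> bool:
                    for j in range(1, 4):
                        q = nxt + direction * step * j
                        if np.any(q < lo) or np.any(q > hi):
                            return False
                        if hash_ is not None and hash_.too_close(
                            q, min_sep, branch_id, n_step + j, exclude_steps + j,
                            junction, related,
                        ):
                            return False
                    return True

                if (
                    n_step * step >= params.min_fork_spacing_um
                    and rng.uniform() < p_branch
                    and grown < target
                    and continuation_has_room()
                ):
                    # fork: close this edge at a junction, queue two children
                    end_id = graph.add_node(pts[-1])
                    poly = np.asarray(pts)
                    graph.add_edge(
                        VesselEdge(start_id, end_id, poly, np.full(len(poly), radius))
                    )
                    child_dir = _perpendicular_jitter(
                        direction, rng.uniform(45.0, 90.0), rng
                    )
                    id_branch = branch_counter + 1
                    id_cont = branch_counter + 2
                    branch_counter += 2
                    kin = frozenset({branch_id, id_branch, id_cont})
                    stack.append((end_id, child_dir, order + 1, pts[-1].copy(), id_branch, kin))
                    stack.append((end_id, direction, order, pts[-1].copy(), id_cont, kin))
                    pts = None
                    break
            if pts is not None and len(pts) >= 2:
                end_id = graph.add_node(pts[-1])
                poly = np.asarray(pts)
                graph.add_edge(
                    VesselEdge(start_id, end_id, poly, np.full(len(poly), radius))
                )

    prune_terminal_stubs(graph, 3.0 * step)

    ledger = GroundTruthLedger(
        total_length_um=graph.total_length(),
        branch_point_count=len(graph.branch_nodes()),
        mean_radius_um=graph.mean_radius(),
        edge_arc_lengths_um=[e.arc_length() for e in graph.edges],
        edge_chord_lengths_um=[e.chord_length() for e in graph.edges],
    )
    return graph, ledger


def voxelize_network(
    graph: VesselGraph,
    voxel_size_um,
    shape,
) -> np.ndarray:
    """Rasterize a vessel graph to a binary volume.

    A voxel is foreground iff its center lies within the local vessel radius
    of some centerline point; polylines are resampled at 0.4x the smallest
    voxel edge so the discrete test approximates the continuous tube.  Voxel
    index ``(i, j, k)`` has its center at ``((i+0.5), (j+0.5), (k+0.5)) *
    voxel_size_um`` — the same convention the tracing stage uses to map
    skeleton voxels back to µm.

    Raises
    ------
    ValueError
        If any edge (inflated by its radius) leaves the volume bounds; the
        error message lists the offending edge indices.
    """
    voxel_size = np.asarray(voxel_size_um, dtype=float)
    shape = tuple(int(s) for s in shape)
    if voxel_size.shape != (3,) or np.any(voxel_size <= 0):
        raise ValueError("voxel_size_um must be 3 positive lengths")
    vol = np.zeros(shape, dtype=bool)
    if not graph.edges:
        return vol

    extent = voxel_size * np.asarray(shape)
    bad = [
        i
        for i, e in enumerate(graph.edges)
        if np.any(e.polyline < -1e-6) or np.any(e.polyline > extent + 1e-6)
    ]
    if bad:
        raise ValueError(f"graph exceeds volume bounds at edges {bad}")

    spacing = 0.4 * voxel_size.min()
    for e in graph.edges:
        pts, radii = _resample_polyline(e.polyline, e.radii, spacing)
        for p, r in zip(pts, radii):
            lo_idx = np.maximum(np.floor((p - r) / voxel_size - 0.5).astype(int), 0)
            hi_idx = np.minimum(
                np.ceil((p + r) / voxel_size - 0.5).astype(int) + 1, np.asarray(shape)
            )
            if np.any(lo_idx >= hi_idx):
                continue
            ax = [
                (np.arange(lo_idx[d], hi_idx[d]) + 0.5) * voxel_size[d] - p[d]
                for d in range(3)
            ]
            d2 = (
                ax[0][:, None, None] ** 2
                + ax[1][None, :, None] ** 2
                + ax[2][None, None, :] ** 2
            )
            vol[
                lo_idx[0] : hi_idx[0], lo_idx[1] : hi_idx[1], lo_idx[2] : hi_idx[2]
            ] |= d2 <= r * r
    return vol


def _resample_polyline(
    polyline: np.ndarray, radii: np.ndarray, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline (and its radii) at uniform arc-length spacing."""
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return polyline[:1], radii[:1]
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, n)
    pts = np.column_stack([np.interp(si, s, polyline[:, d]) for d in range(3)])
    rr = np.interp(si, s, radii)
    return pts, rr


def generate_pericytes(
    graph: VesselGraph,
    density_per_mm: dict[str, float] | float,
    seed: int = 0,
) -> pd.DataFrame:
    """Place pericyte somata on a vessel network by a Poisson process.

    For each subtype the count is Poisson with mean ``rate * total vessel
    length (mm)``; each cell sits at a uniform arc-length position along the
    network, displaced from the centerline by a uniform draw inside the local
    vessel radius.

    Parameters
    ----------
    density_per_mm
        Either a single rate applied to the ``capillary-unspecified`` subtype
        or a mapping subtype -> cells per mm of vessel.

    Returns
    -------
    pandas.DataFrame
        Columns ``x_um, y_um, z_um, subtype``.
    """
    if not isinstance(density_per_mm, dict):
        density_per_mm = {"capillary-unspecified": float(density_per_mm)}
    for k, v in density_per_mm.items():
        if k not in PERICYTE_SUBTYPES:
            raise ValueError(f"unknown pericyte subtype {k!r}")
        if v < 0:
            raise ValueError("pericyte rates must be >= 0")
    total_rate = sum(density_per_mm.values())
    if not graph.edges:
        if total_rate > 0:
            raise ValueError("cannot place pericytes on an empty graph")
        return pd.DataFrame(columns=["x_um", "y_um", "z_um", "subtype"])

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    lengths = np.array([e.arc_length() for e in graph.edges])
    total_mm = lengths.sum() / 1000.0
    edge_p = lengths / lengths.sum()

    rows = []
    for subtype, rate in density_per_mm.items():
        n = rng.poisson(rate * total_mm)
        for _ in range(n):
            e = graph.edges[rng.choice(len(graph.edges), p=edge_p)]
            seg = np.linalg.norm(np.diff(e.polyline, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            si = rng.uniform(0.0, s[-1])
            center = np.array([np.interp(si, s, e.polyline[:, d]) for d in range(3)])
            radius = float(np.interp(si, s, e.radii))
            offset = _random_unit_vector(rng) * radius * rng.uniform() ** (1 / 3)
            p = center + offset
            rows.append((p[0], p[1], p[2], subtype))
    return pd.DataFrame(rows, columns=["x_um", "y_um", "z_um", "subtype"])


# ---------------------------------------------------------------------------
# behavior and hemodynamics
# ---------------------------------------------------------------------------


@dataclass
class BehaviorTrace:
    """Uniformly sampled treadmill velocity trace."""

    time_s: np.ndarray
    velocity_cmps: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.velocity_cmps = np.asarray(self.velocity_cmps, dtype=float)
        if self.time_s.shape != self.velocity_cmps.shape:
            raise ValueError("time and velocity must have equal length")
        if not np.all(np.isfinite(self.velocity_cmps)):
            raise ValueError("velocity must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.time_s, "velocity_cmps": self.velocity_cmps})


def generate_locomotion_session(
    duration_s: float,
    fs_hz: float,
    event_spec: Sequence[tuple[float, float]] | Sequence[tuple[float, float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_cmps: float = 10.0,
    ramp_s: float = 1.0,
    gait_hz: float = 3.0,
    gait_amp_cmps: float = 1.5,
) -> tuple[BehaviorTrace, GroundTruthLedger]:
    """Simulate a treadmill velocity trace with embedded locomotion bouts.

    Each event ``(onset_s, offset_s)`` (optionally ``(onset, offset, peak)``)
    is a linear ramp up over ``ramp_s``, a plateau, and a linear ramp down
    ending at the offset.  A stride-frequency sinusoid (``gait_hz``, amplitude
    ``gait_amp_cmps``) rides on the bout so the acceleration stays above the
    detection threshold throughout, as it does for a running mouse; without it
    a constant plateau would read as rest.  Gaussian noise is added on top.

    Raises
    ------
    ValueError
        If events overlap or extend outside the session.
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be > 0")
    events = []
    for ev in event_spec:
        onset, offset = float(ev[0]), float(ev[1])
        peak = float(ev[2]) if len(ev) > 2 else peak_cmps
        if not 0 <= onset < offset <= duration_s:
            raise ValueError(f"event ({onset}, {offset}) outside session")
        events.append((onset, offset, peak))
    events.sort()
    for (a0, b0, _), (a1, b1, _) in zip(events, events[1:]):
        if a1 < b0:
            raise ValueError(f"overlapping events ({a0},{b0}) and ({a1},{b1})")

    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    v = np.zeros(n)
    for onset, offset, peak in events:
        ramp = min(ramp_s, (offset - onset) / 2)
        env = np.clip(
            np.minimum((t - onset) / ramp, (offset - t) / ramp), 0.0, 1.0
        ) * (t >= onset) * (t < offset)
        gait = gait_amp_cmps * np.sin(2 * np.pi * gait_hz * (t - onset))
        v += env * (peak + gait)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)

    ledger = GroundTruthLedger(event_intervals=[(a, b) for a, b, _ in events])
    return BehaviorTrace(t, v, fs_hz), ledger


def gamma_variate(t, A: float, T: float, W: float):
    """Gamma-variate response kernel ``A (t/T)^alpha exp(-(t-T)/beta)``.

    ``alpha = (T/W)^2 * 8 ln 2`` and ``beta = W^2 / (T * 8 ln 2)``, so the
    kernel peaks with value ``A`` at time ``T`` and has half-maximum width
    close to ``W``.  Defined as 0 at ``t = 0`` (alpha > 0) and for ``t < 0``.
    """
    if A is None or T <= 0 or W <= 0:
        raise ValueError("T and W must be > 0")
    t = np.asarray(t, dtype=float)
    alpha = (T / W) ** 2 * 8.0 * np.log(2.0)
    beta = W**2 / (T * 8.0 * np.log(2.0))
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = A * np.exp(alpha * np.log(tp / T) - (tp - T) / beta)
    return out if out.ndim else float(out)


def events_to_delta(
    event_intervals: Sequence[tuple[float, float]], n: int, fs_hz: float
) -> np.ndarray:
    """Binarized event vector: 1 on samples inside any half-open [onset, offset)."""
    t = np.arange(n) / fs_hz
    delta = np.zeros(n)
    for onset, offset in event_intervals:
        delta[(t >= onset) & (t < offset)] = 1.0
    return delta


def generate_hemodynamics(
    events,
    hrf_true: tuple[float, float, float],
    offset: float = 0.0,
    noise_sd: float = 0.0,
    fs_hz: float | None = None,
    seed: int = 0,
    kernel_s: float = 10.0,
    hbo_gain: float = 1.5,
):
    """Forward-model hemodynamic traces from locomotion events.

    The total-hemoglobin response is ``offset + (delta ⊛ kernel) + noise``
    where ``delta`` is the binarized event vector and the kernel is the
    gamma-variate ``hrf_true = (A, T, W)`` sampled at lags ``0..k/fs``.
    Oxy-hemoglobin is the same response scaled by ``hbo_gain`` (oxygen
    delivery overshoots volume during functional hyperemia, driving ΔHbR
    negative); deoxy is defined as ΔHbT − ΔHbO so the identity holds exactly.

    Parameters
    ----------
    events
        A ``LocomotionEvents`` (from :mod:`vascage.hemodynamics`), or a
        ``(delta, fs_hz)`` pair, or a list of ``(onset_s, offset_s)`` with
        ``fs_hz`` given separately (then the trace length covers the last
        offset plus the kernel duration).

    Returns
    -------
    (HemoTraces, GroundTruthLedger)
    """
    from .hemodynamics import LocomotionEvents
    from .spectroscopy import HemoTraces

    A, T, W = hrf_true
    if A < 0 or T <= 0 or W <= 0:
        raise ValueError("hrf_true requires A >= 0 and T, W > 0")

    if isinstance(events, LocomotionEvents):
        delta, fs = events.delta, events.fs_hz
        intervals = list(events.events)
    elif isinstance(events, tuple) and len(events) == 2 and np.ndim(events[0]) == 1:
        delta, fs = np.asarray(events[0], dtype=float), float(events[1])
        intervals = []
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required when passing raw event intervals")
        intervals = [(float(a), float(b)) for a, b in events]
        if not intervals:
            raise ValueError("empty event list")
        fs = float(fs_hz)
        n = int(round((max(b for _, b in intervals) + kernel_s + 5.0) * fs))
        delta = events_to_delta(intervals, n, fs)
    if delta.size == 0 or not np.any(delta):
        raise ValueError("event vector is empty; nothing to convolve")

    n = delta.size
    k = int(round(kernel_s * fs))
    kern = gamma_variate(np.arange(k + 1) / fs, A, T, W)
    response = np.convolve(delta, kern)[:n]
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    noise_t = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    noise_o = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    hbt = offset + response + noise_t
    hbo = offset + hbo_gain * response + noise_o
    hbr = hbt - hbo
    t = np.arange(n) / fs
    traces = HemoTraces(time_s=t, hbt_um=hbt, hbo_um=hbo, hbr_um=hbr, fs_hz=fs)
    ledger = GroundTruthLedger(hrf_true=(A, T, W), event_intervals=intervals)
    return traces, ledger


# ---------------------------------------------------------------------------
# cohort generation for aging-contrast studies
# ---------------------------------------------------------------------------


def simulate_aging_study(
    n_per_group: int = 5,
    n_effect_regions: int = 4,
    n_null_regions: int = 12,
    region_shape_um: Sequence[float] = (200.0, 200.0, 200.0),
    base_density: float = 0.4,
    branch_rate: float = 3.0,
    length_effect: float = -0.10,
    radius_effect: float = 0.07,
    tortuosity_young: float = 0.15,
    tortuosity_aged: float = 0.35,
    animal_cv: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a two-cohort regional morphometry study.

    Each "brain region" is an independent simulation box; every animal gets
    its own network per region, with per-animal lognormal variability
    (coefficient of variation ``animal_cv``) on the density and radius
    targets.  In the first ``n_effect_regions`` regions the aged group's
    generator means carry the programmed aging contrast (fractional
    ``length_effect`` and ``radius_effect``, raised tortuosity); the
    remaining ``n_null_regions`` regions use identical settings for both
    groups.  Region metrics (length density, branching density, mean radius,
    mean arc-chord ratio) are measured with the metrics pipeline on a
    single-region atlas per box.

    Returns
    -------
    (table, truth)
        Long-form table with columns ``region, group, animal, metric, value``
        and a dict recording which regions carry which programmed effect.
    """
    from .graph import arc_chord_ratio
    from .metrics import RegionAtlas, branching_density, length_density, mean_radius

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sigma = np.sqrt(np.log(1 + animal_cv**2))
    n_regions = n_effect_regions + n_null_regions
    shape_um = np.asarray(region_shape_um, dtype=float)
    vox = 10.0
    atlas = RegionAtlas.single_region(
        tuple(int(s / vox) for s in shape_um), (vox, vox, vox)
    )
    rid = int(atlas.table["region_id"].iloc[0])

    rows = []
    for region in range(n_regions):
        has_effect = region < n_effect_regions
        for group in ("young", "aged"):
            aged = group == "aged"
            dens_mean = base_density * (1.0 + (length_effect if has_effect and aged else 0.0))
            rad_scale = 1.0 + (radius_effect if has_effect and aged else 0.0)
            tort = tortuosity_aged if has_effect and aged else tortuosity_young
            for animal in range(n_per_group):
                dens = dens_mean * np.exp(rng.normal(0.0, sigma) - sigma**2 / 2)
                rad = rad_scale * np.exp(rng.normal(0.0, sigma) - sigma**2 / 2)
                params = NetworkGenParams(
                    domain_shape_um=shape_um,
                    target_length_density=dens,
                    branch_rate=branch_rate,
                    radius_law=power_radius_law(3.5 * rad, 0.9, 0.08),
                    tortuosity_amp=tort,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                graph, _ = generate_vessel_network(params)
                acr = [
                    arc_chord_ratio(e.polyline)
                    for e in graph.edges
                    if e.polyline.shape[0] > 2 and e.chord_length() > 1e-9
                ]
                values = {
                    "length_density": length_density(graph, atlas, rid),
                    "branching_density": branching_density(graph, atlas, rid),
                    "mean_radius": mean_radius(graph, atlas, rid),
                    "arc_chord_ratio": float(np.mean(acr)) if acr else np.nan,
                }
                for metric, value in values.items():
                    rows.append(
                        {
                            "region": f"region_{region:02d}",
                            "group": group,
                            "animal": f"{group}_{animal}",
                            "metric": metric,
                            "value": value,
                        }
                    )
    truth = {
        "effect_regions": [f"region_{i:02d}" for i in range(n_effect_regions)],
        "null_regions": [f"region_{i:02d}" for i in range(n_effect_regions, n_regions)],
        "length_effect": length_effect,
        "radius_effect": radius_effect,
        "tortuosity_young": tortuosity_young,
        "tortuosity_aged": tortuosity_aged,
    }
    return pd.DataFrame(rows), truth


def generate_aging_cohorts(
    n_per_group: int = 5,
    base_params: NetworkGenParams | None = None,
    length_effect: float = -0.10,
    radius_effect: float = 0.07,
    tortuosity_young: float = 0.15,
    tortuosity_aged: float = 0.35,
    animal_cv: float = 0.05,
    seed: int = 0,
):
    """Generate young/aged cohorts of networks with programmed effects.

    Each animal's length-density target and radius scale are drawn lognormally
    around its group mean with coefficient of variation ``animal_cv``
    (between-animal biological variability; without it group variances would
    collapse and two-sample tests would be degenerate).  The aged group means
    are the young means shifted by ``length_effect`` (fractional),
    ``radius_effect`` (fractional) and a raised tortuosity amplitude.

    Returns
    -------
    dict
        ``{"young": [(graph, ledger), ...], "aged": [...]}``.
    """
    if base_params is None:
        base_params = NetworkGenParams()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sigma = np.sqrt(np.log(1 + animal_cv**2))

    cohorts: dict[str, list] = {"young": [], "aged": []}
    for group, dens_scale, rad_scale, tort in (
        ("young", 1.0, 1.0, tortuosity_young),
        ("aged", 1.0 + length_effect, 1.0 + radius_effect, tortuosity_aged),
    ):
        for i in range(n_per_group):
            animal_seed = int(rng.integers(0, 2**31 - 1))
            dens = base_params.target_length_density * dens_scale * np.exp(
                rng.normal(0.0, sigma) - sigma**2 / 2
            )
            rad = rad_scale * np.exp(rng.normal(0.0, sigma) - sigma**2 / 2)
            base_mean, base_sigma = base_params.radius_law(0)
            decay = base_params.radius_law(1)[0] / base_mean
            params = NetworkGenParams(
                domain_shape_um=base_params.domain_shape_um,
                target_length_density=dens,
                branch_rate=base_params.branch_rate,
                radius_law=power_radius_law(base_mean * rad, decay, base_sigma),
                tortuosity_amp=tort,
                seed=animal_seed,
                step_um=base_params.step_um,
            )
            cohorts[group].append(generate_vessel_network(params))
    return cohorts
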