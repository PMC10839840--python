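"""Synthetic cohorts with planted, fully recoverable ground truth.

Generates every input the pipeline consumes: two-hemisphere meshes
(icospheres or planar grids) with homolog maps, geodesic-Voronoi
parcellations with a core area ringed by penumbra neighbors from distinct
networks, activation cohorts built from area-level means plus
border-directed within-area gradients, border-centered activation bumps,
subject offsets and spatially smoothed noise, per-subject standard errors,
and a connectivity matrix whose seed rows mirror the task topographies.

The generator's defaults are the study conditions: three executive-style
contrasts (n-back, switch, stop), area means in the 0-1.5 percent-signal-
change range, noise sd 0.3 smoothed to about two mean edge lengths,
preference effects twice the noise sd, and four pseudo-runs behind each
subject's standard errors.  Each task is yoked to a resting-state network
(n-back to DMN, switch to DAN, stop to CON), so planted gradients and
border bumps point from the core area toward the matching network's
territory — the spatial arrangement the pipeline is designed to detect.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation import NO_PREFERENCE, ContrastCohort
from .fingerprint import ConnectivityMatrix
from .geometry import (
    BorderSet,
    Parcellation,
    SmoothingSpec,
    SurfaceMesh,
    extract_borders,
    geodesic_distance,
    smooth_map,
)

__all__ = [
    "GroundTruth",
    "make_mesh",
    "make_parcellation",
    "default_ground_truth",
    "simulate_cohort",
    "simulate_connectivity",
    "homolog_area_pairs",
    "preference_balanced_accuracy",
    "DEFAULT_TASKS",
    "TASK_NETWORK",
]

DEFAULT_TASKS = ["nback", "switch", "stop"]
# task <-> adjacent-network affinity mirrored throughout the defaults
TASK_NETWORK = {"nback": "DMN", "switch": "DAN", "stop": "CON"}
NETWORK_TASK = {v: k for k, v in TASK_NETWORK.items()}


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def _icosphere(subdivisions: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64)


def _planar_grid(n: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """n x n vertex grid in the z=0 plane, consistently diagonal-triangulated."""
    xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    verts = np.column_stack(
        [xs.ravel() * spacing, ys.ravel() * spacing, np.zeros(n * n)]
    )
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            v00 = i * n + j
            v01 = v00 + 1
            v10 = v00 + n
            v11 = v10 + 1
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    return verts, np.asarray(tris, dtype=np.int64)


def make_mesh(
    kind: str = "icosphere",
    resolution: int = 2,
    two_hemispheres: bool = True,
    seed: int = 0,
    radius: float = 32.0,
    spacing: float = 1.0,
) -> SurfaceMesh:
    """Synthetic surface mesh, optionally with a mirrored second hemisphere.

    kind "icosphere": ``resolution`` = subdivision level (level 2 gives 162
    vertices per component, 10*4^n + 2 in general); ``radius`` in mm.
    kind "planar-grid": ``resolution`` x ``resolution`` vertex grid at
    ``spacing`` mm.  With ``two_hemispheres`` the second component is the
    x-mirrored copy, offset so the components do not overlap, and the
    homolog map pairs each vertex with its mirror image.
    """
    if kind == "icosphere":
        verts, tris = _icosphere(resolution, radius)
        extent = 2.0 * radius
    elif kind == "planar-grid":
        verts, tris = _planar_grid(resolution, spacing)
        extent = resolution * spacing
    else:
        raise ValueError(f"unknown mesh kind {kind!r}")
    n = verts.shape[0]
    if n < 100:
        raise ValueError("resolution must yield >= 100 vertices per component")
    if not two_hemispheres:
        return SurfaceMesh(vertex_coords=verts, triangles=tris)
    mirror = verts.copy()
    mirror[:, 0] = -mirror[:, 0]
    mirror[:, 0] += 2.5 * extent  # keep components spatially separate
    tris_r = tris[:, ::-1] + n  # reversed winding preserves orientation
    coords = np.vstack([verts, mirror])
    triangles = np.vstack([tris, tris_r])
    comp = np.empty(2 * n, dtype=object)
    comp[:n] = "L"
    comp[n:] = "R"
    homologs = {i: i + n for i in range(n)}
    homologs.update({i + n: i for i in range(n)})
    return SurfaceMesh(
        vertex_coords=coords,
        triangles=triangles,
        component_id=comp,
        homolog_map=homologs,
    )


# ---------------------------------------------------------------------------
# parcellations
# ---------------------------------------------------------------------------


def _farthest_point_sample(
    mesh: SurfaceMesh, candidates: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    first = candidates[rng.integers(candidates.size)]
    chosen = [int(first)]
    d = geodesic_distance(mesh, [first])
    for _ in range(k - 1):
        nxt = candidates[int(np.argmax(d[candidates]))]
        chosen.append(int(nxt))
        d = np.minimum(d, geodesic_distance(mesh, [nxt]))
    return np.asarray(chosen)


def make_parcellation(
    mesh: SurfaceMesh,
    n_areas: int = 12,
    network_scheme: str = "core-penumbra",
    seed: int = 0,
) -> Parcellation:
    """Geodesic-Voronoi parcellation with mirrored hemisphere labels.

    Per hemisphere, ``n_areas`` seed vertices are farthest-point sampled
    and every vertex takes the label of its geodesically nearest seed;
    with a homolog map, the second hemisphere mirrors the first.  Under
    the ``core-penumbra`` scheme the area with most neighbors becomes the
    core multiple-demand area; its neighbors become penumbra areas cycling
    through the CON / DAN / DMN networks (so the core touches at least two
    distinct networks); remaining areas get network ``other``.
    """
    if n_areas < 4:
        raise ValueError("need n_areas >= 4 per component")
    comp = np.asarray(mesh.component_id)
    rng = np.random.default_rng(seed)
    left = np.flatnonzero(comp == comp[0])
    seeds = _farthest_point_sample(mesh, left, n_areas, rng)
    dists = np.stack([geodesic_distance(mesh, [s]) for s in seeds])
    labels = np.empty(mesh.n_vertices, dtype=object)
    win = np.argmin(dists[:, left], axis=0)
    for i in range(n_areas):
        labels[left[win == i]] = f"L{i:02d}"
    rest = np.flatnonzero(comp != comp[0])
    if rest.size:
        if mesh.homolog_map:
            for v in rest:
                labels[v] = "R" + labels[mesh.homolog_map[v]][1:]
        else:
            seeds_r = _farthest_point_sample(mesh, rest, n_areas, rng)
            dists_r = np.stack([geodesic_distance(mesh, [s]) for s in seeds_r])
            win_r = np.argmin(dists_r[:, rest], axis=0)
            for i in range(n_areas):
                labels[rest[win_r == i]] = f"R{i:02d}"
    parc = Parcellation(area_label=labels)
    if network_scheme == "core-penumbra":
        _assign_networks(mesh, parc)
    elif network_scheme not in (None, "none"):
        raise ValueError(f"unknown network scheme {network_scheme!r}")
    return parc


def _assign_networks(mesh: SurfaceMesh, parc: Parcellation) -> None:
    borders = extract_borders(mesh, parc)
    nets = ["CON", "DAN", "DMN"]
    for prefix in sorted({str(a)[0] for a in parc.areas}):
        areas = [a for a in parc.areas if str(a)[0] == prefix]
        nbrs = {a: sorted(n for n in borders.neighbors_of_area(a) if n in areas)
                for a in areas}
        core = max(areas, key=lambda a: (len(nbrs[a]), a))
        if len(nbrs[core]) < 2:
            raise ValueError("core area has < 2 neighbors: scheme unsatisfiable")
        parc.area_network[core] = "coreMD"
        parc.area_role[core] = "core"
        for i, a in enumerate(nbrs[core]):
            parc.area_network[a] = nets[i % len(nets)]
            parc.area_role[a] = "penumbra"
        for a in areas:
            if a != core and a not in nbrs[core]:
                parc.area_network[a] = "other"
                parc.area_role[a] = "none"


def homolog_area_pairs(parc: Parcellation) -> dict:
    """Map each area to its opposite-hemisphere homolog (L01 <-> R01)."""
    out = {}
    areas = set(parc.areas)
    for a in areas:
        s = str(a)
        other = ("R" if s[0] == "L" else "L") + s[1:]
        if other in areas:
            out[a] = other
    return out


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    area_task_means : (n_areas, n_tasks) mean percent signal change,
        ordered as (parc.areas, task_names)
    gradient_spec : list of (area, task, border_pair, amplitude, extent_mm);
        within ``area``, the task's mean rises linearly toward the shared
        border of ``border_pair``, peaking there at +amplitude and fading
        to zero at ``extent_mm`` from the border.
    bump_spec : list of (border_pair, task, amplitude, width_mm); a
        Gaussian ridge amplitude*exp(-d^2 / (2 width^2)) centered on the
        pair's border vertices.
    seed_assignment : core seed vertex -> intended task.
    noise_sd : per-vertex noise sd before spatial smoothing (PSC units)
    noise_fwhm_mm : noise smoothing kernel FWHM
    subject_sd : sd of the per-subject global offset
    pseudo_runs : run count behind the per-subject standard errors
    preference_margin : minimum lead of the top task over the runner-up in
        the noiseless field for a vertex to carry a true preference label.
    """

    task_names: list[str]
    area_task_means: np.ndarray
    gradient_spec: list = field(default_factory=list)
    bump_spec: list = field(default_factory=list)
    seed_assignment: dict[int, str] = field(default_factory=dict)
    noise_sd: float = 0.3
    noise_fwhm_mm: float = 8.0
    subject_sd: float = 0.2
    pseudo_runs: int = 4
    preference_margin: float = 0.15

    def __post_init__(self) -> None:
        self.area_task_means = np.asarray(self.area_task_means, dtype=float)
        if not np.isfinite(self.area_task_means).all():
            raise ValueError("area means must be finite")
        for _, _, _, amp, ext in self.gradient_spec:
            if not np.isfinite(amp) or ext <= 0:
                raise ValueError("gradient amplitudes finite, extents > 0")
        for _, _, amp, width in self.bump_spec:
            if not np.isfinite(amp) or width <= 0:
                raise ValueError("bump amplitudes finite, widths > 0")

    def mean_field(
        self, mesh: SurfaceMesh, parc: Parcellation, borders: BorderSet
    ) -> np.ndarray:
        """Noiseless (n_tasks, n_vertices) expectation of the cohort."""
        areas = parc.areas
        T = len(self.task_names)
        n = mesh.n_vertices
        out = np.zeros((T, n))
        for j, area in enumerate(areas):
            idx = parc.vertices_of(area)
            out[:, idx] += self.area_task_means[j][:, None]
        for area, task, pair, amp, extent in self.gradient_spec:
            t = self.task_names.index(task)
            bverts = borders.pair_vertices(*pair)
            d = geodesic_distance(mesh, bverts)
            idx = parc.vertices_of(area)
            out[t, idx] += amp * np.maximum(0.0, 1.0 - d[idx] / extent)
        for pair, task, amp, width in self.bump_spec:
            t = self.task_names.index(task)
            bverts = borders.pair_vertices(*pair)
            d = geodesic_distance(mesh, bverts)
            out[t] += amp * np.exp(-(d**2) / (2.0 * width**2))
        return out

    def preference_truth(
        self, mesh: SurfaceMesh, parc: Parcellation, borders: BorderSet
    ) -> np.ndarray:
        """Intended winning task per vertex (``none`` below the margin)."""
        field_ = self.mean_field(mesh, parc, borders)
        order = np.sort(field_, axis=0)
        margin = order[-1] - order[-2]
        win = np.argmax(field_, axis=0)
        truth = np.full(mesh.n_vertices, NO_PREFERENCE, dtype=object)
        ok = margin >= self.preference_margin
        truth[ok] = np.asarray(self.task_names, dtype=object)[win[ok]]
        return truth


def default_ground_truth(
    mesh: SurfaceMesh,
    parc: Parcellation,
    borders: BorderSet,
    seed: int = 0,
    task_names: list[str] | None = None,
    base_mean: float = 0.0,
    pref_amplitude: float = 0.6,
    core_mean: float = 0.8,
    gradient_amplitude: float = 0.3,
    bump_amplitude: float = 0.6,
    bump_width_mm: float | None = None,
    noise_sd: float = 0.3,
    plant_bumps: bool = True,
) -> GroundTruth:
    """The study-default planted structure.

    Baseline activation is zero (executive contrasts are near zero over
    uninvolved cortex), so core areas — strongly active in every task —
    are the only all-task conjunction targets;
    each penumbra area prefers its network's yoked task by
    ``pref_amplitude`` (default twice the noise sd); every fourth ``other``
    area has no preference, the rest cycle through the tasks.  Within each
    core area, each task's activation ramps up toward the border shared
    with that task's yoked network, and (optionally) Gaussian bumps of the
    yoked task sit on those borders.  Core seed vertices are assigned the
    task of their geodesically nearest yoked border.
    """
    tasks = list(task_names or DEFAULT_TASKS)
    T = len(tasks)
    areas = parc.areas
    mel = mesh.mean_edge_length()
    if bump_width_mm is None:
        bump_width_mm = 1.0 * mel
    means = np.full((len(areas), T), base_mean)
    other_counter = 0
    for j, area in enumerate(areas):
        role = parc.area_role[area]
        net = parc.area_network[area]
        if role == "core":
            means[j, :] = core_mean
        elif net in NETWORK_TASK:
            means[j, tasks.index(NETWORK_TASK[net])] += pref_amplitude
        else:
            # cycle preferred tasks over "other" areas; every fourth has none
            if other_counter % 4 != 3:
                means[j, other_counter % T] += pref_amplitude
            other_counter += 1
    gradients = []
    bumps = []
    core_areas = [a for a in areas if parc.area_role[a] == "core"]
    yoked_pairs: dict = {}
    for core in core_areas:
        for nbr in sorted(borders.neighbors_of_area(core)):
            net = parc.area_network.get(nbr)
            if net in NETWORK_TASK:
                task = NETWORK_TASK[net]
                pair = tuple(sorted((core, nbr)))
                gradients.append((core, task, pair, gradient_amplitude, 4.0 * mel))
                if plant_bumps:
                    bumps.append((pair, task, bump_amplitude, bump_width_mm))
                yoked_pairs.setdefault(core, []).append((pair, task))
    # seed assignment: nearest yoked border's task, per core vertex
    assignment: dict[int, str] = {}
    for core, pair_tasks in yoked_pairs.items():
        idx = parc.vertices_of(core)
        dmat = np.stack(
            [geodesic_distance(mesh, borders.pair_vertices(*p)) for p, _ in pair_tasks]
        )
        nearest = np.argmin(dmat[:, idx], axis=0)
        for k, v in enumerate(idx):
            assignment[int(v)] = pair_tasks[int(nearest[k])][1]
    return GroundTruth(
        task_names=tasks,
        area_task_means=means,
        gradient_spec=gradients,
        bump_spec=bumps,
        seed_assignment=assignment,
        noise_sd=noise_sd,
        noise_fwhm_mm=2.0 * mel,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    mesh: SurfaceMesh,
    parc: Parcellation,
    truth: GroundTruth,
    n_subjects: int = 20,
    seed: int = 0,
    borders: BorderSet | None = None,
) -> ContrastCohort:
    """Cohort = mean field + subject offset + spatially smoothed noise.

    value(s, t, v) = mean_field(t, v) + offset_s + noise, with
    offset_s ~ Normal(0, subject_sd) shared across tasks and vertices and
    noise i.i.d. Normal(0, noise_sd) smoothed to ``noise_fwhm_mm`` (no
    variance rescale after smoothing, so the effective per-vertex noise sd
    lies below noise_sd).  Standard errors are noise_sd / sqrt(pseudo_runs)
    with a large-sample (normal) reference distribution.  Fully
    reproducible from ``seed``.
    """
    borders = borders or extract_borders(mesh, parc)
    rng = np.random.default_rng(seed)
    T = len(truth.task_names)
    n = mesh.n_vertices
    base = truth.mean_field(mesh, parc, borders)  # (T, n)
    offsets = rng.normal(0.0, truth.subject_sd, size=n_subjects)
    vals = np.broadcast_to(base, (n_subjects, T, n)).copy()
    vals += offsets[:, None, None]
    if truth.noise_sd > 0:
        noise = rng.normal(0.0, truth.noise_sd, size=(n_subjects, T, n))
        if truth.noise_fwhm_mm > 0:
            noise = smooth_map(mesh, noise, SmoothingSpec(fwhm_mm=truth.noise_fwhm_mm))
        vals += noise
    se = np.full_like(vals, truth.noise_sd / np.sqrt(truth.pseudo_runs))
    if truth.noise_sd == 0:
        se[:] = 1e-12  # degenerate-noise cohorts still carry positive SEs
    return ContrastCohort(
        values=vals,
        task_names=list(truth.task_names),
        se=se,
        se_df=np.inf,
        element_space=mesh,
    )


# ---------------------------------------------------------------------------
# connectivity simulation
# ---------------------------------------------------------------------------


def simulate_connectivity(
    mesh: SurfaceMesh,
    parc: Parcellation,
    task_maps: np.ndarray,
    truth: GroundTruth,
    seed: int = 0,
    noise_rel: float = 0.0,
    seed_gain: float = 1.0,
) -> ConnectivityMatrix:
    """Low-rank connectivity whose seed rows mirror the task topographies.

    matrix = sum_t lambda_t lambda_t^T + noise, where lambda_t is the
    z-scored task-t map for ordinary vertices while each core seed vertex
    loads only on its assigned task (gain ``seed_gain``), so its row is an
    affine image of that task's topography.  ``noise_rel`` scales i.i.d.
    symmetric Gaussian noise by the rms of the off-diagonal signal.  The
    result is symmetrized and given a unit diagonal.
    """
    task_maps = np.asarray(task_maps, dtype=float)
    T, n = task_maps.shape
    if T != len(truth.task_names):
        raise ValueError("task_maps rows must match truth.task_names")
    lam = (task_maps - task_maps.mean(axis=1, keepdims=True)) / task_maps.std(
        axis=1, keepdims=True
    )
    seeds = np.asarray(sorted(truth.seed_assignment), dtype=np.int64)
    if seeds.size:
        lam[:, seeds] = 0.0
        for v in seeds:
            t = truth.task_names.index(truth.seed_assignment[int(v)])
            lam[t, v] = seed_gain
    sig = lam.T @ lam
    if noise_rel > 0:
        off = sig[~np.eye(n, dtype=bool)]
        scale = noise_rel * float(np.sqrt(np.mean(off**2)))
        rng = np.random.default_rng(seed)
        e = rng.normal(0.0, scale, size=(n, n))
        sig = sig + (e + e.T) / np.sqrt(2.0)
    sig = (sig + sig.T) / 2.0
    np.fill_diagonal(sig, 1.0)
    return ConnectivityMatrix(matrix=sig, element_space=mesh)


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------


def preference_balanced_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Balanced accuracy of predicted vs planted preference labels.

    Evaluated on labeled vertices whose planted truth is a task (not
    ``none``): mean over true task classes of the within-class hit rate.
    Returns NaN when no such vertex exists.
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    mask = (pred != NO_PREFERENCE) & (truth != NO_PREFERENCE)
    if not mask.any():
        return np.nan
    recalls = []
    for t in sorted({x for x in truth[mask].tolist()}):
        sel = mask & (truth == t)
        recalls.append(float(np.mean(pred[sel] == t)))
    return float(np.mean(recalls))
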