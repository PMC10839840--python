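"""Border-zone activation analyses and the smoothing null simulation.

Distance-binned activation profiles across an areal border (with the
segment x task repeated-measures interaction), top-fraction subject
overlap maps, spatially homogeneous null cohorts smoothed at several FWHM
levels (with per-subject border jitter emulating inter-subject
parcellation misalignment), and the border-proximity summary that turns
the qualitative "activations peak at borders" claim into a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activation import ContrastCohort, OverlapMap
from .geometry import (
    BorderSet,
    Parcellation,
    SmoothingSpec,
    SurfaceMesh,
    extract_borders,
    geodesic_distance,
    smooth_map,
)
from .stats import AnovaResult, rm_anova

__all__ = [
    "BorderProfile",
    "NullSimConfig",
    "border_profile",
    "top_fraction_overlap",
    "homogeneous_null",
    "border_proximity",
    "jitter_parcellation",
]


@dataclass
class BorderProfile:
    """Per-task activation profile along a distance-segment axis.

    The axis spans area A far-to-border (segments n..1) then area B
    border-to-far (segments 1..n): 2*n_segments positions with the shared
    border between positions n and n+1.
    """

    area_pair: tuple
    n_segments: int
    mean: np.ndarray  # (n_tasks, 2*n_segments)
    sem: np.ndarray  # (n_tasks, 2*n_segments)
    task_names: list[str]
    anova: AnovaResult | None = None
    subject_grid: np.ndarray | None = None  # (S, 2*n_segments, T)

    @property
    def interaction(self) -> dict:
        """The segment x task interaction test."""
        return self.anova[("segment", "task")]


@dataclass
class NullSimConfig:
    """Areal-homogeneous null simulation settings.

    fwhm_levels : smoothing levels in mm (default 4, 12, 20)
    jitter_mm : per-subject border displacement scale (geodesic jitter of
        the parcellation, emulating inter-subject border misalignment);
        default one mean edge length (None).
    """

    fwhm_levels: tuple = (4.0, 12.0, 20.0)
    n_subjects: int = 20
    seed: int = 0
    jitter_mm: float | None = None

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fwhm_levels):
            raise ValueError("fwhm_levels must be positive")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def border_profile(
    cohort: ContrastCohort,
    segments: np.ndarray,
    area_pair: tuple,
    parc: Parcellation,
    run_anova: bool = True,
) -> BorderProfile:
    """Distance-binned activation profile across an areal border.

    ``segments`` is the per-vertex segment index from
    :func:`mdsurf.geometry.distance_segments` (1 = nearest the border).
    Per subject and task, each segment's value is the mean over its
    vertices; the profile reports the across-subject mean and SEM, and the
    subjects x (segment, task) grid is handed to the repeated-measures
    ANOVA for the segment x task interaction.
    """
    a, b = sorted(area_pair)
    n_seg = int(segments.max())
    labels = parc.area_label
    S, T = cohort.n_subjects, cohort.n_tasks
    grid = np.empty((S, 2 * n_seg, T))
    # axis: area a far->border (seg n..1), then area b border->far (seg 1..n)
    for pos in range(2 * n_seg):
        if pos < n_seg:
            area, seg = a, n_seg - pos
        else:
            area, seg = b, pos - n_seg + 1
        idx = np.flatnonzero((labels == area) & (segments == seg))
        if idx.size == 0:
            raise ValueError(f"empty segment {seg} in area {area!r}")
        grid[:, pos, :] = cohort.values[:, :, idx].mean(axis=2).reshape(S, T)
    mean = grid.mean(axis=0).T  # (T, 2n)
    sem = grid.std(axis=0, ddof=1).T / np.sqrt(S)
    anova = (
        rm_anova(grid, {"segment": 2 * n_seg, "task": T}) if run_anova else None
    )
    return BorderProfile(
        area_pair=(a, b),
        n_segments=n_seg,
        mean=mean,
        sem=sem,
        task_names=list(cohort.task_names),
        anova=anova,
        subject_grid=grid,
    )


def top_fraction_overlap(
    cohort: ContrastCohort,
    fraction: float = 0.05,
    threshold: float = 0.5,
    task: str | None = None,
) -> tuple[dict[str, OverlapMap], np.ndarray]:
    """Top-``fraction`` activation overlap across subjects.

    Per subject and task, the ``ceil(fraction * n_elements)`` highest
    valued elements are flagged (ties broken by element index: among equal
    values, lower indices are flagged first) and the binary maps are
    summed across subjects.  The surviving set pools the per-task maps:
    elements whose count for *any* task strictly exceeds
    ``threshold * n_subjects``.  Restrict to one task via ``task``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_el = cohort.n_elements
    k = int(np.ceil(fraction * n_el))
    tasks = [task] if task is not None else list(cohort.task_names)
    maps: dict[str, OverlapMap] = {}
    surviving = np.zeros(n_el, dtype=bool)
    for name in tasks:
        t = cohort.task_index(name)
        counts = np.zeros(n_el, dtype=np.int64)
        for s in range(cohort.n_subjects):
            v = cohort.values[s, t]
            # stable top-k with index tie-break: sort by (-value, index)
            order = np.lexsort((np.arange(n_el), -v))
            counts[order[:k]] += 1
        om = OverlapMap(counts=counts, n_subjects=cohort.n_subjects)
        maps[name] = om
        surviving |= counts > threshold * cohort.n_subjects
    return maps, np.flatnonzero(surviving)


def jitter_parcellation(
    mesh: SurfaceMesh, parc: Parcellation, rounds: int, rng: np.random.Generator
) -> Parcellation:
    """Seeded geodesic border jitter: each round, every current border
    vertex adopts the label of a uniformly chosen differently-labeled
    neighbor with probability 1/2.  ``rounds`` approximates the
    displacement in mean-edge-length units."""
    labels = parc.area_label.copy()
    adj = mesh.adjacency()
    for _ in range(max(0, rounds)):
        bs = extract_borders(mesh, Parcellation(area_label=labels))
        bverts = bs.border_vertices
        flip = rng.random(bverts.size) < 0.5
        new = labels.copy()
        for v in bverts[flip]:
            nbr = adj[v].indices
            diff = nbr[labels[nbr] != labels[v]]
            if diff.size:
                new[v] = labels[rng.choice(diff)]
        labels = new
    return Parcellation(
        area_label=labels,
        area_network=dict(parc.area_network),
        area_role=dict(parc.area_role),
    )


def homogeneous_null(
    areal: np.ndarray,
    parc: Parcellation,
    mesh: SurfaceMesh,
    cfg: NullSimConfig,
    task_names: list[str] | None = None,
) -> dict[float, ContrastCohort]:
    """Areal-homogeneous cohorts smoothed at each FWHM level.

    Every vertex of an area receives that subject's areal mean (spatially
    flat within areas), after a per-subject jitter of the area borders
    (seeded; emulates inter-subject parcellation misalignment), then the
    map is smoothed at each requested FWHM.  Returns one cohort per FWHM
    level, keyed by the level.  At FWHM -> 0 the maps are exactly
    piecewise constant.
    """
    areal = np.asarray(areal, dtype=float)
    if not np.isfinite(areal).all():
        raise ValueError("areal values must be finite")
    S, T, A = areal.shape
    areas = parc.areas
    if A != len(areas):
        raise ValueError("areal axis 2 must match parcellation areas")
    if task_names is None:
        task_names = [f"task{t}" for t in range(T)]
    rng = np.random.default_rng(cfg.seed)
    jitter = cfg.jitter_mm if cfg.jitter_mm is not None else mesh.mean_edge_length()
    rounds = int(round(jitter / mesh.mean_edge_length()))
    n_el = mesh.n_vertices
    flat = np.empty((S, T, n_el))
    use_subjects = min(S, cfg.n_subjects)
    for s in range(use_subjects):
        p_s = jitter_parcellation(mesh, parc, rounds, rng) if rounds else parc
        for j, area in enumerate(areas):
            idx = p_s.vertices_of(area)
            if idx.size == 0:
                idx = parc.vertices_of(area)  # jitter erased the area: fall back
            flat[s, :, idx] = areal[s, :, j]
    flat = flat[:use_subjects]
    out: dict[float, ContrastCohort] = {}
    for f in cfg.fwhm_levels:
        sm = smooth_map(mesh, flat, SmoothingSpec(fwhm_mm=float(f)))
        out[float(f)] = ContrastCohort(
            values=sm, task_names=list(task_names), element_space=mesh
        )
    return out


def border_proximity(
    surviving: np.ndarray,
    borders: BorderSet,
    mesh: SurfaceMesh,
    radius_mm: float | None = None,
    network_pair: tuple | None = None,
    parc: Parcellation | None = None,
) -> float:
    """Proportion of surviving vertices within ``radius_mm`` of a border.

    ``radius_mm`` defaults to twice the mean edge length.  With
    ``network_pair`` (and ``parc``), only borders between areas of those
    two networks count.  Returns NaN (flagged undefined) for an empty
    surviving set.
    """
    surviving = np.asarray(surviving)
    if surviving.dtype == bool:
        surviving = np.flatnonzero(surviving)
    if surviving.size == 0:
        return np.nan
    if radius_mm is None:
        radius_mm = 2.0 * mesh.mean_edge_length()
    if network_pair is not None:
        if parc is None:
            raise ValueError("network_pair restriction requires parc")
        na, nb = network_pair
        bverts: set[int] = set()
        for (a, b), verts in borders.pair_index.items():
            nets = {parc.area_network[a], parc.area_network[b]}
            if nets == {na, nb} or (na == nb and nets == {na}):
                bverts.update(verts.tolist())
        border_vertices = np.asarray(sorted(bverts))
    else:
        border_vertices = borders.border_vertices
    if border_vertices.size == 0:
        return 0.0
    d = geodesic_distance(mesh, border_vertices)
    return float(np.mean(d[surviving] <= radius_mm))
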