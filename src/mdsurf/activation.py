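"""Contrast-map handling and group-level activation analyses.

Percent-signal-change conversion, areal averaging, the across-task areal
conjunction (Bonferroni over areas), per-subject vertex-wise conjunction
overlap maps (element-wise FDR), winner-take-all task-preference labeling
(FDR over elements, Bonferroni over task comparisons), the RGB composite
map, and network-level task / lateralization comparisons.

"Elements" are surface vertices or, for the subcortical variant, voxels of
a labeled grid — every operation here is agnostic to which.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Parcellation, SurfaceMesh
from .stats import (
    MultipleComparisonConfig,
    adjust,
    one_sample_t,
    paired_t,
    t_pvalues,
)

__all__ = [
    "ContrastCohort",
    "OverlapMap",
    "PreferenceMap",
    "CompositeColorMap",
    "to_percent_signal_change",
    "areal_mean",
    "areal_conjunction",
    "subject_conjunction_overlap",
    "task_preference",
    "composite_rgb",
    "network_compare",
]

NO_PREFERENCE = "none"


@dataclass
class ContrastCohort:
    """Per-subject, per-task activation maps in percent signal change.

    values : (n_subjects, n_tasks, n_elements) array
    task_names : ordered task identifiers (e.g. nback, switch, stop)
    subject_ids : ordered subject identifiers
    se : optional (n_subjects, n_tasks, n_elements) within-subject standard
        errors of each element's effect estimate (run-level variability);
        required by per-subject inference.
    se_df : degrees of freedom of the SE estimate (pseudo-runs - 1).
    element_space : optional reference to the SurfaceMesh / grid.
    """

    values: np.ndarray
    task_names: list[str]
    subject_ids: list | None = None
    se: np.ndarray | None = None
    se_df: int = 3
    element_space: object | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (subjects, tasks, elements)")
        if len(self.task_names) != self.values.shape[1]:
            raise ValueError("task_names must match values axis 1")
        if len(self.task_names) < 2:
            raise ValueError("need >= 2 tasks")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i:03d}" for i in range(self.values.shape[0])]
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.values.shape:
                raise ValueError("se must match values shape")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.values.shape[1]

    @property
    def n_elements(self) -> int:
        return self.values.shape[2]

    def task_index(self, task: str) -> int:
        return self.task_names.index(task)


@dataclass
class OverlapMap:
    """Per-element count of subjects satisfying a criterion."""

    counts: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any() or (self.counts > self.n_subjects).any():
            raise ValueError("counts must lie in [0, n_subjects]")

    @property
    def proportion(self) -> np.ndarray:
        return self.counts / self.n_subjects


@dataclass
class PreferenceMap:
    """Per-element winning task label, or ``none`` where no test passed."""

    label: np.ndarray  # object array of task name / NO_PREFERENCE

    def labeled_fraction(self, restrict=None) -> float:
        lab = self.label if restrict is None else self.label[restrict]
        return float(np.mean(lab != NO_PREFERENCE))


@dataclass
class CompositeColorMap:
    rgb: np.ndarray  # (n_elements, 3) uint8-range integers

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.int64)
        if (self.rgb < 0).any() or (self.rgb > 255).any():
            raise ValueError("rgb channels must lie in [0, 255]")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def to_percent_signal_change(beta) -> np.ndarray:
    """Convert scanner beta units to percent signal change: 100*(beta/10000).

    The divisor 10 000 is the grand mean to which each element's time
    series is scaled during preprocessing, so the conversion reduces to
    beta / 100.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.isfinite(beta).all():
        raise ValueError("beta values must be finite")
    return 100.0 * (beta / 10000.0)


def areal_mean(cohort: ContrastCohort, parc: Parcellation) -> np.ndarray:
    """Unweighted mean over each area's elements, per subject per task.

    Returns (n_subjects, n_tasks, n_areas) ordered by ``parc.areas``.
    """
    labels = parc.area_label
    if labels.shape[0] != cohort.n_elements:
        raise ValueError("parcellation not defined on the cohort's element space")
    areas = parc.areas
    out = np.empty((cohort.n_subjects, cohort.n_tasks, len(areas)))
    for j, area in enumerate(areas):
        idx = np.flatnonzero(labels == area)
        if idx.size == 0:
            raise ValueError(f"area {area!r} has no elements")
        out[:, :, j] = cohort.values[:, :, idx].mean(axis=2)
    return out


def areal_conjunction(
    areal: np.ndarray,
    cfg: MultipleComparisonConfig,
    areas: list | None = None,
    homolog_area_pairs: dict | None = None,
) -> list:
    """Areas significantly activated (positive) in every task.

    ``areal`` is the (subjects, tasks, areas) array from :func:`areal_mean`.
    Each area x task cell gets a one-sample t-test against zero; rejection
    under ``cfg`` (Bonferroni over the tested areas by convention) with a
    positive mean counts as activated.  An area enters the conjunction iff
    it is activated in all tasks.

    ``homolog_area_pairs`` (optional, area -> homologous area) switches on
    the "at least one hemisphere" mode: per task, an area counts as
    activated if it or its homolog is, and the returned set contains every
    area whose homolog-union passes all tasks.
    """
    n_areas = areal.shape[2]
    if areas is None:
        areas = list(range(n_areas))
    sig = np.zeros((areal.shape[1], n_areas), dtype=bool)
    for t in range(areal.shape[1]):
        for j in range(n_areas):
            res = one_sample_t(areal[:, t, j])
            p = 0.0 if res.degenerate and res.effect_direction else res.p_value
            sig[t, j] = (
                np.isfinite(p)
                and adjust([p], cfg)[0]
                and res.effect_direction > 0
            )
    if homolog_area_pairs:
        pos = {a: i for i, a in enumerate(areas)}
        union = sig.copy()
        for a, b in homolog_area_pairs.items():
            if a in pos and b in pos:
                union[:, pos[a]] |= sig[:, pos[b]]
        sig = union
    keep = sig.all(axis=0)
    return [areas[j] for j in range(n_areas) if keep[j]]


def subject_conjunction_overlap(
    cohort: ContrastCohort,
    cfg: MultipleComparisonConfig | None = None,
) -> OverlapMap:
    """Probabilistic overlap map of per-subject all-task conjunctions.

    Per subject and task, elements are tested with t = value / SE
    (within-subject error from the cohort's run-level SEs, df = se_df) and
    flagged at element-wise FDR with positive direction; per subject the
    conjunction across all tasks is formed, and the per-subject binary
    maps are summed across subjects.
    """
    if cohort.se is None:
        raise ValueError("cohort must carry per-subject standard errors")
    if cfg is None:
        cfg = MultipleComparisonConfig(method="bh_fdr", n_comparisons=cohort.n_elements)
    if cfg.method != "bh_fdr":
        raise ValueError("subject-level vertex inference uses bh_fdr")
    counts = np.zeros(cohort.n_elements, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmaps = cohort.values / cohort.se
    for s in range(cohort.n_subjects):
        conj = np.ones(cohort.n_elements, dtype=bool)
        for t in range(cohort.n_tasks):
            p = t_pvalues(tmaps[s, t], cohort.se_df)
            rej = adjust(p, cfg)
            conj &= rej & (cohort.values[s, t] > 0)
        counts += conj
    return OverlapMap(counts=counts, n_subjects=cohort.n_subjects)


def task_preference(
    cohort: ContrastCohort,
    cfg: MultipleComparisonConfig | None = None,
    restrict: np.ndarray | None = None,
) -> PreferenceMap:
    """Winner-take-all task-preference labeling of elements.

    An element gets task t's label iff the paired t-test of t against each
    other task rejects with positive direction, after Benjamini-Hochberg
    FDR across the restricted elements (pooled per candidate task over its
    pairwise comparisons) at level alpha / extra_bonferroni, with
    extra_bonferroni defaulting to the number of tasks.  Directional
    exclusivity guarantees at most one winning task per element.
    """
    n_el = cohort.n_elements
    if restrict is None:
        restrict = np.arange(n_el)
    else:
        restrict = np.asarray(restrict)
        if restrict.dtype == bool:
            restrict = np.flatnonzero(restrict)
    if cfg is None:
        cfg = MultipleComparisonConfig(
            method="bh_fdr",
            n_comparisons=len(restrict),
            extra_bonferroni=cohort.n_tasks,
        )
    T = cohort.n_tasks
    vals = cohort.values[:, :, restrict]  # (S, T, R)
    n = cohort.n_subjects
    label = np.full(n_el, NO_PREFERENCE, dtype=object)
    win = np.full((T, len(restrict)), False)
    for t in range(T):
        others = [u for u in range(T) if u != t]
        # paired t statistics, vectorised over elements
        rej_all = np.ones(len(restrict), dtype=bool)
        pos_all = np.ones(len(restrict), dtype=bool)
        pvals = np.empty((len(others), len(restrict)))
        diffs_mean = np.empty((len(others), len(restrict)))
        for k, u in enumerate(others):
            d = vals[:, t, :] - vals[:, u, :]
            m = d.mean(axis=0)
            s = d.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = m / (s / np.sqrt(n))
            p = t_pvalues(tstat, n - 1)
            p[np.isnan(p) & (m != 0)] = 0.0  # degenerate zero-variance, nonzero mean
            pvals[k] = p
            diffs_mean[k] = m
        # pooled FDR family: this task's pairwise p-values across elements
        rej = adjust(pvals, cfg)
        rej_all = rej.all(axis=0)
        pos_all = (diffs_mean > 0).all(axis=0)
        win[t] = rej_all & pos_all
    # directional exclusivity makes double wins impossible; assert cheaply
    assert (win.sum(axis=0) <= 1).all()
    for t in range(T):
        label[restrict[win[t]]] = cohort.task_names[t]
    return PreferenceMap(label=label)


def composite_rgb(group_means: np.ndarray, round_half_away: bool = True) -> CompositeColorMap:
    """RGB composite of three task maps under joint min-max normalization.

    Normalization constants are the minimum and maximum across *all* maps
    jointly; channels follow the task order of ``group_means`` (row 0 ->
    red, 1 -> green, 2 -> blue), scaled by 255 and rounded half away from
    zero.
    """
    g = np.asarray(group_means, dtype=float)
    if g.ndim != 2 or g.shape[0] != 3:
        raise ValueError("group_means must be (3 tasks, n_elements)")
    if not np.isfinite(g).all():
        raise ValueError("group means must be finite")
    lo, hi = g.min(), g.max()
    if hi == lo:
        raise ValueError("constant input: overall max equals overall min")
    norm = (g - lo) / (hi - lo)
    scaled = norm * 255.0
    rgb = np.floor(scaled + 0.5).astype(np.int64)  # half away from zero (all >= 0)
    return CompositeColorMap(rgb=rgb.T)


def network_compare(
    cohort: ContrastCohort,
    parc: Parcellation,
    networks: list,
    mesh: SurfaceMesh | None = None,
    alpha: float = 0.05,
) -> dict:
    """Network-level task means, task contrasts, and lateralization tests.

    Per subject, a network's value is the mean over its member elements,
    split by hemisphere when the element space carries component labels.
    Task contrasts are pairwise paired t-tests Bonferroni-corrected over
    tasks x networks; lateralization is paired_t(left, right) per task and
    network (requires hemisphere labels).
    """
    mesh = mesh if mesh is not None else cohort.element_space
    comp = None
    if isinstance(mesh, SurfaceMesh):
        comp = np.asarray(mesh.component_id)
    T = cohort.n_tasks
    n_pairs = T * (T - 1) // 2
    bonf = MultipleComparisonConfig(
        alpha=alpha, method="bonferroni", n_comparisons=n_pairs * len(networks)
    )
    out: dict = {"networks": {}, "effective_alpha": bonf.effective_alpha}
    for net in networks:
        verts = parc.vertices_of_network(net)  # raises if empty
        entry: dict = {"tasks": {}, "contrasts": {}, "lateralization": {}}
        hemis = {"all": verts}
        if comp is not None:
            for h in ("L", "R"):
                sel = verts[comp[verts] == h]
                if sel.size:
                    hemis[h] = sel
        subj_means = {
            h: cohort.values[:, :, idx].mean(axis=2) for h, idx in hemis.items()
        }  # each (S, T)
        for t, name in enumerate(cohort.task_names):
            entry["tasks"][name] = {
                h: {
                    "mean": float(sm[:, t].mean()),
                    "sem": float(sm[:, t].std(ddof=1) / np.sqrt(cohort.n_subjects)),
                }
                for h, sm in subj_means.items()
            }
        for i in range(T):
            for j in range(i + 1, T):
                res = paired_t(subj_means["all"][:, i], subj_means["all"][:, j])
                entry["contrasts"][(cohort.task_names[i], cohort.task_names[j])] = {
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p_value,
                    "reject": bool(
                        np.isfinite(res.p_value)
                        and res.p_value <= bonf.effective_alpha
                    ),
                    "direction": res.effect_direction,
                }
        if "L" in subj_means and "R" in subj_means:
            for t, name in enumerate(cohort.task_names):
                res = paired_t(subj_means["L"][:, t], subj_means["R"][:, t])
                entry["lateralization"][name] = {
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p_value,
                    "direction": res.effect_direction,
                    "degenerate": res.degenerate,
                }
        out["networks"][net] = entry
    return out
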