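"""Seed connectivity-activation fingerprint mapping.

For each seed vertex (typically within core multiple-demand areas), the
seed's row of a dense connectivity matrix is correlated with each task
activation map over an exclusion-masked element set (dropping the seed's
own area, all adjacent areas, and the contralateral homologs of the
dropped vertices, so local connectivity cannot drive the correlation).
Seeds with a significant correlation above an r threshold get the label
of the task they correlate with most strongly; per-subject labels are
pooled into probabilistic task maps and a winner-take-all final labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BorderSet, Parcellation
from .stats import MultipleComparisonConfig, adjust, pearson, t_pvalues

__all__ = [
    "ConnectivityMatrix",
    "FingerprintConfig",
    "exclusion_mask",
    "seed_fingerprint",
    "fingerprint_cohort",
    "winner_take_all",
]

NO_LABEL = "none"


@dataclass
class ConnectivityMatrix:
    """Dense symmetric element-by-element association matrix, unit diagonal."""

    matrix: np.ndarray
    element_space: object | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.isfinite(m).all():
            raise ValueError("matrix must be finite")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("matrix must be symmetric to 1e-10")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("diagonal must be 1 after normalization")
        self.matrix = m

    @property
    def n_elements(self) -> int:
        return self.matrix.shape[0]

    def row(self, v: int) -> np.ndarray:
        return self.matrix[v]


@dataclass
class FingerprintConfig:
    """Fingerprint labeling thresholds.

    r_threshold : minimum correlation for a label (default 0.2)
    alpha : FDR level for the correlation p-values (default 0.05)
    min_retained : smallest admissible exclusion-masked element count
    """

    r_threshold: float = 0.2
    alpha: float = 0.05
    min_retained: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")


def exclusion_mask(
    seed: int,
    parc: Parcellation,
    borders: BorderSet,
    homologs: dict[int, int],
    min_retained: int = 10,
) -> np.ndarray:
    """Retained element indices for a seed's fingerprint correlation.

    Excludes every vertex of the seed's own area, of every area sharing at
    least one border vertex with it (a junction-touching area counts as
    adjacent), and the contralateral homolog of every excluded vertex.
    """
    labels = parc.area_label
    n = labels.shape[0]
    if not 0 <= seed < n:
        raise ValueError("seed index out of range")
    own = labels[seed]
    drop_areas = {own} | borders.neighbors_of_area(own)
    drop = np.isin(labels, list(drop_areas))
    for v in np.flatnonzero(drop.copy()):
        h = homologs.get(int(v))
        if h is not None:
            drop[h] = True
    retained = np.flatnonzero(~drop)
    if retained.size < min_retained:
        raise ValueError(
            f"exclusion leaves {retained.size} elements (< {min_retained})"
        )
    return retained


def seed_fingerprint(
    conn: ConnectivityMatrix,
    seed: int,
    task_maps: np.ndarray,
    task_names: list[str],
    parc: Parcellation,
    borders: BorderSet,
    homologs: dict[int, int],
    cfg: FingerprintConfig | None = None,
    reject: np.ndarray | None = None,
) -> dict:
    """Correlate a seed's connectivity row with each task map and label it.

    Returns ``{"r": per-task correlations, "p": p-values, "label": task or
    none}``.  P-values use the t transform with df = retained - 2.  When
    ``reject`` (per-task flags from a family-wide FDR pass) is given it
    replaces the raw alpha threshold; label = argmax r among tasks passing
    both significance and r > r_threshold.  Zero-variance correlations are
    flagged undefined and cannot win.
    """
    cfg = cfg or FingerprintConfig()
    retained = exclusion_mask(seed, parc, borders, homologs, cfg.min_retained)
    row = conn.row(seed)
    task_maps = np.asarray(task_maps, dtype=float)
    r = np.array(
        [pearson(row, task_maps[t], mask=retained) for t in range(len(task_names))]
    )
    m = retained.size
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((m - 2) / (1.0 - r**2))
    p = t_pvalues(tstat, m - 2)
    p[np.abs(r) >= 1.0] = 0.0
    if reject is None:
        reject = np.isfinite(p) & (p <= cfg.alpha)
    passing = reject & (np.nan_to_num(r, nan=-np.inf) > cfg.r_threshold)
    if passing.any():
        label = task_names[int(np.argmax(np.where(passing, r, -np.inf)))]
    else:
        label = NO_LABEL
    return {"r": r, "p": p, "label": label, "retained": retained.size}


def fingerprint_cohort(
    conn: ConnectivityMatrix,
    seeds: np.ndarray,
    cohort_values: np.ndarray,
    task_names: list[str],
    parc: Parcellation,
    borders: BorderSet,
    homologs: dict[int, int],
    cfg: FingerprintConfig | None = None,
) -> np.ndarray:
    """Per-subject fingerprint labels for a set of seed vertices.

    ``cohort_values`` is (subjects, tasks, elements); for each subject the
    correlation p-values are FDR-adjusted over the full seeds x tasks
    family before labeling.  Returns an object array (subjects, seeds).
    """
    cfg = cfg or FingerprintConfig()
    seeds = np.asarray(seeds, dtype=np.int64)
    S, T, _ = cohort_values.shape
    labels = np.full((S, seeds.size), NO_LABEL, dtype=object)
    masks = [exclusion_mask(v, parc, borders, homologs, cfg.min_retained) for v in seeds]
    mc = MultipleComparisonConfig(alpha=cfg.alpha, method="bh_fdr",
                                  n_comparisons=seeds.size * T)
    for s in range(S):
        r = np.empty((seeds.size, T))
        p = np.empty((seeds.size, T))
        for i, v in enumerate(seeds):
            row = conn.row(int(v))
            m = masks[i].size
            for t in range(T):
                r[i, t] = pearson(row, cohort_values[s, t], mask=masks[i])
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = r[i] * np.sqrt((m - 2) / (1.0 - r[i] ** 2))
            p[i] = t_pvalues(tstat, m - 2)
            p[i][np.abs(r[i]) >= 1.0] = 0.0
        rej = adjust(p, mc)
        passing = rej & (np.nan_to_num(r, nan=-np.inf) > cfg.r_threshold)
        for i in range(seeds.size):
            if passing[i].any():
                labels[s, i] = task_names[
                    int(np.argmax(np.where(passing[i], r[i], -np.inf)))
                ]
    return labels


def winner_take_all(
    per_subject_labels: np.ndarray, task_names: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Probabilistic counts per task and the winner-take-all final label.

    ``per_subject_labels`` is (subjects, seeds) of task names / ``none``.
    ``none`` labels never count; the final label is the task with the
    strictly greatest subject count, with ties (and all-none seeds)
    labeled ``none``.  Returns (counts (tasks, seeds), final (seeds,)).
    """
    lab = np.asarray(per_subject_labels, dtype=object)
    if lab.ndim != 2:
        raise ValueError("labels must be (subjects, seeds)")
    valid = set(task_names) | {NO_LABEL}
    bad = {x for x in lab.ravel().tolist()} - valid
    if bad:
        raise ValueError(f"unknown labels {bad!r}")
    counts = np.stack([(lab == t).sum(axis=0) for t in task_names])
    final = np.full(lab.shape[1], NO_LABEL, dtype=object)
    top = counts.max(axis=0)
    n_top = (counts == top).sum(axis=0)
    winner = counts.argmax(axis=0)
    decided = (top > 0) & (n_top == 1)
    final[decided] = np.asarray(task_names, dtype=object)[winner[decided]]
    return counts, final
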