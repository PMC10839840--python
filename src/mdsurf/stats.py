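"""Statistical primitives used by every analysis stage.

One-sample and paired t-tests against zero, Bonferroni / Benjamini-Hochberg
multiple-comparison control (optionally combined with a secondary Bonferroni
factor, e.g. 3 task comparisons), a generic fully-crossed within-subject
repeated-measures ANOVA, and masked Pearson correlation.

Conventions: all p-values are two-sided; "significantly activated" in the
pipeline means reject *and* positive effect direction.  No sphericity
correction is applied to the ANOVA (uncorrected degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "MultipleComparisonConfig",
    "AnovaResult",
    "one_sample_t",
    "paired_t",
    "adjust",
    "rm_anova",
    "pearson",
    "t_pvalues",
]


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    effect_direction: int  # sign of the mean effect: -1, 0, +1
    degenerate: bool = False  # zero-variance sample


@dataclass
class MultipleComparisonConfig:
    """Family-wise / FDR control configuration.

    method : "bonferroni" or "bh_fdr"
    n_comparisons : primary family size (e.g. 360 areas, or #vertices)
    extra_bonferroni : secondary factor applied as an alpha division
        (e.g. 3 task comparisons, 3 subcortical structures)
    """

    alpha: float = 0.05
    method: str = "bonferroni"
    n_comparisons: int = 1
    extra_bonferroni: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_comparisons < 1 or self.extra_bonferroni < 1:
            raise ValueError("family sizes must be >= 1")
        if self.method not in ("bonferroni", "bh_fdr"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def effective_alpha(self) -> float:
        """Per-test alpha (bonferroni) or BH level (bh_fdr)."""
        if self.method == "bonferroni":
            return self.alpha / (self.n_comparisons * self.extra_bonferroni)
        return self.alpha / self.extra_bonferroni


@dataclass
class AnovaResult:
    """Within-subject ANOVA results, one entry per effect.

    Keys of ``effects`` are tuples of factor names, e.g. ("task",) or
    ("segment", "task").  Each value carries F, df_effect, df_error, p.
    """

    effects: dict[tuple, dict] = field(default_factory=dict)
    degenerate: bool = False

    def __getitem__(self, key):
        if isinstance(key, str):
            key = (key,)
        return self.effects[tuple(key)]


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def one_sample_t(values) -> TestResult:
    """Two-sided one-sample t-test of the mean against zero."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample with n >= 2")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    n = x.size
    m = x.mean()
    s = x.std(ddof=1)
    df = n - 1
    if s == 0.0:
        if m == 0.0:
            # exactly-zero sample: statistic 0, no evidence either way
            return TestResult(0.0, df, 1.0, 0, degenerate=True)
        return TestResult(np.sign(m) * np.inf, df, 0.0, int(np.sign(m)), degenerate=True)
    t = m / (s / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), df, float(p), int(np.sign(m)) if m else 0)


def paired_t(a, b) -> TestResult:
    """Paired t-test: identical to ``one_sample_t(a - b)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b)


def t_pvalues(t: np.ndarray, df: float) -> np.ndarray:
    """Vectorised two-sided p-values for t statistics (NaN-propagating)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        return 2.0 * sps.t.sf(np.abs(t), df)


# ---------------------------------------------------------------------------
# multiple comparisons
# ---------------------------------------------------------------------------


def adjust(p_values, cfg: MultipleComparisonConfig) -> np.ndarray:
    """Per-item reject flags under the configured procedure.

    bonferroni: reject iff p <= alpha / (n_comparisons * extra_bonferroni).
    bh_fdr: Benjamini-Hochberg step-up at level alpha / extra_bonferroni
    over the supplied family.  NaN p-values never reject.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    if cfg.method == "bonferroni":
        reject[finite] = p[finite] <= cfg.effective_alpha
        return reject
    if finite.any():
        flags, *_ = multipletests(
            p[finite].ravel(), alpha=cfg.effective_alpha, method="fdr_bh"
        )
        reject[finite] = flags.reshape(p[finite].shape)
    return reject


# ---------------------------------------------------------------------------
# within-subject ANOVA
# ---------------------------------------------------------------------------


def _subsets(names):
    return chain.from_iterable(combinations(names, k) for k in range(len(names) + 1))


def rm_anova(data: np.ndarray, factors: dict[str, int]) -> AnovaResult:
    """Fully-crossed within-subject (repeated-measures) ANOVA.

    Parameters
    ----------
    data : array of shape (n_subjects, l1, l2, ...) — one value per subject
        per cell of the crossed within-subject design.
    factors : ordered mapping factor name -> level count, matching the
        trailing axes of ``data``.

    Every within-subject effect (main effects and all interactions) is
    tested against its own subject-by-effect interaction mean square.  The
    sums of squares come from the classical inclusion-exclusion identity
    over marginal-mean squared totals, with the subject factor treated as
    a fully-crossed random factor.  For a single 2-level factor the F
    statistic equals the squared paired-t statistic exactly.
    """
    data = np.asarray(data, dtype=float)
    names = list(factors)
    levels = [factors[f] for f in names]
    if data.ndim != 1 + len(names) or list(data.shape[1:]) != levels:
        raise ValueError(
            f"data shape {data.shape} does not match subjects x {tuple(levels)}"
        )
    if data.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    n_sub = data.shape[0]
    all_names = ["__subject__"] + names
    axis_of = {f: i for i, f in enumerate(all_names)}
    n_levels = {"__subject__": n_sub, **factors}
    total_cells = n_sub * int(np.prod(levels))

    # U_T = sum over T-marginal cells of (cells collapsed) * mean^2
    U: dict[tuple, float] = {}
    for T in _subsets(all_names):
        keep = set(T)
        axes = tuple(axis_of[f] for f in all_names if f not in keep)
        marg = data.mean(axis=axes) if axes else data
        n_collapsed = total_cells // int(
            np.prod([n_levels[f] for f in keep]) if keep else 1
        )
        U[tuple(sorted(T))] = float(n_collapsed * np.sum(np.square(marg)))

    def ss(effect: tuple) -> float:
        e = tuple(sorted(effect))
        total = 0.0
        for k in range(len(e) + 1):
            for sub in combinations(e, k):
                total += (-1) ** (len(e) - k) * U[tuple(sorted(sub))]
        return total

    def df(effect: tuple) -> int:
        out = 1
        for f in effect:
            out *= n_levels[f] - 1
        return out

    result = AnovaResult()
    for E in _subsets(names):
        if not E:
            continue
        ss_e = max(ss(E), 0.0)  # guard tiny negative rounding
        ss_err = max(ss(("__subject__",) + E), 0.0)
        df_e = df(E)
        df_err = df(("__subject__",) + E)
        ms_err = ss_err / df_err
        if ms_err == 0.0:
            f_val, p = (0.0, 1.0) if ss_e == 0.0 else (np.inf, 0.0)
            result.degenerate = True
        else:
            f_val = (ss_e / df_e) / ms_err
            p = float(sps.f.sf(f_val, df_e, df_err))
        result.effects[tuple(E)] = {
            "F": float(f_val),
            "df_effect": df_e,
            "df_error": df_err,
            "p_value": p,
        }
    return result


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def pearson(x, y, mask=None) -> float:
    """Product-moment correlation over the retained (masked) elements.

    ``mask`` is a boolean array or index set of elements to retain.
    Returns NaN (flagged undefined) when either retained vector has zero
    variance.  Requires >= 3 retained elements.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal shape")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            x, y = x[mask], y[mask]
        else:
            x, y = x[mask.astype(np.int64)], y[mask.astype(np.int64)]
    if x.size < 3:
        raise ValueError("need >= 3 retained elements")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))
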