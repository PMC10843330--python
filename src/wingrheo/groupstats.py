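"""Genotype-comparison statistics and subsample power analysis.

The comparison protocol is normality-gated: Shapiro-Wilk on every group
first; if all groups look normal, parametric tests (Student's t for two
groups, one-way ANOVA for more), otherwise rank tests (Mann-Whitney U for
two, Kruskal-Wallis for more).  Any single non-normal group sends the whole
comparison down the nonparametric branch.

The power analysis asks how often a small subsample of the full genotype
pools would have revealed the phenotype: draw m wings with replacement from
every genotype, run Kruskal-Wallis across the groups, repeat (10,000
iterations by default) and report the fraction of significant resamples per
subsample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .elongation import polygon_second_moments

__all__ = [
    "GenotypeSample",
    "PowerCurve",
    "TestRecord",
    "dispatch_test",
    "subsample_power",
    "power_curve",
    "aspect_ratio",
    "DEFAULT_SUBSAMPLE_SIZES",
]

#: subsample sizes used for the published power curve
DEFAULT_SUBSAMPLE_SIZES = (3, 4, 5, 6, 7, 8, 9, 10, 20, 40)
DEFAULT_N_ITER = 10_000
DEFAULT_ALPHA = 0.05


@dataclass
class GenotypeSample:
    """Per-specimen scalar measurements (aspect ratio, recoil velocity, ...)
    for one genotype."""

    genotype: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) < 1 or not np.all(np.isfinite(self.values)):
            raise ValueError("values must be non-empty and finite")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class TestRecord:
    """Which branch of the normality-gated dispatch fired, and its result."""

    test_name: str
    statistic: float
    p_value: float
    all_normal: bool
    shapiro_p: dict[str, float]


@dataclass
class PowerCurve:
    sizes: np.ndarray
    fractions: np.ndarray
    n_iterations: int
    alpha: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m": self.sizes,
                "fraction_significant": self.fractions,
                "n_iter": self.n_iterations,
                "alpha": self.alpha,
                "seed": self.seed,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def dispatch_test(groups: list[GenotypeSample], alpha: float = DEFAULT_ALPHA) -> TestRecord:
    """Normality-gated comparison of two or more genotype samples.

    Shapiro-Wilk needs n >= 3 in every group.  The gate level equals the
    comparison ``alpha`` (0.05 by default).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.n < 3 for g in groups):
        raise ValueError("every group needs n >= 3 to test normality")
    shapiro_p = {g.genotype: float(stats.shapiro(g.values).pvalue) for g in groups}
    all_normal = all(p > alpha for p in shapiro_p.values())
    vals = [g.values for g in groups]
    if all_normal:
        if len(groups) == 2:
            res = stats.ttest_ind(*vals)
            name = "student_t"
        else:
            res = stats.f_oneway(*vals)
            name = "anova"
    else:
        if len(groups) == 2:
            res = stats.mannwhitneyu(*vals, alternative="two-sided")
            name = "mann_whitney_u"
        else:
            res = stats.kruskal(*vals)
            name = "kruskal_wallis"
    return TestRecord(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        all_normal=all_normal,
        shapiro_p=shapiro_p,
    )


def _kw_pvalue(samples: list[np.ndarray], rng: np.random.Generator | None, n_perm: int) -> float:
    """Kruskal-Wallis p-value; chi-squared reference or seeded permutations."""
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):  # fully degenerate resample
        return 1.0
    try:
        stat, p = stats.kruskal(*samples)
    except ValueError:
        return 1.0
    if rng is None:
        return float(p)
    # permutation reference: recompute H under random relabelling.  For the
    # small per-group sizes where the chi-squared approximation is poor this
    # gives a calibrated p-value (ties included automatically).
    sizes = [len(s) for s in samples]
    cuts = np.cumsum(sizes)[:-1]
    count = 1  # add-one: include the observed statistic
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, cuts)
        try:
            h, _ = stats.kruskal(*parts)
        except ValueError:
            h = 0.0
        if h >= stat - 1e-12:
            count += 1
    return count / (n_perm + 1)


def subsample_power(
    groups: list[GenotypeSample],
    m: int,
    n_iter: int = DEFAULT_N_ITER,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    *,
    p_method: str = "chi2",
    n_perm: int = 400,
) -> float:
    """Fraction of m-per-group resamples whose Kruskal-Wallis test is significant.

    Each iteration draws ``m`` values with replacement from every group and
    tests them jointly.  Degenerate resamples (all values tied across all
    groups) count as non-significant.  ``p_method='permutation'`` replaces
    the chi-squared reference by a seeded permutation reference, useful for
    m <= 5 where the asymptotic approximation is poor.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if p_method not in ("chi2", "permutation"):
        raise ValueError("p_method must be 'chi2' or 'permutation'")
    rng = np.random.default_rng(seed)
    n_sig = 0
    for _ in range(n_iter):
        samples = [rng.choice(g.values, size=m, replace=True) for g in groups]
        perm_rng = rng if p_method == "permutation" else None
        p = _kw_pvalue(samples, perm_rng, n_perm)
        if p <= alpha:
            n_sig += 1
    return n_sig / n_iter


def power_curve(
    groups: list[GenotypeSample],
    sizes=DEFAULT_SUBSAMPLE_SIZES,
    n_iter: int = DEFAULT_N_ITER,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    **kwargs,
) -> PowerCurve:
    """Subsample power at each size in ``sizes`` (independent streams per size)."""
    sizes = np.asarray(list(sizes), dtype=int)
    if len(sizes) == 0:
        raise ValueError("sizes must be non-empty")
    seeds = np.random.SeedSequence(seed).spawn(len(sizes))
    fractions = np.array(
        [
            subsample_power(groups, int(m), n_iter, alpha, seed=int(s.generate_state(1)[0] % 2**31), **kwargs)
            for m, s in zip(sizes, seeds)
        ]
    )
    return PowerCurve(sizes=sizes, fractions=fractions, n_iterations=n_iter, alpha=alpha, seed=seed)


def aspect_ratio(outline) -> float:
    """Major-to-minor axis ratio of a shape's second-moment ellipse (>= 1).

    ``outline`` is either an (n, 2) polygon vertex array or a 2-D boolean
    mask.  The ratio is sqrt(lambda_max / lambda_min) of the area-normalized
    central second moments, i.e. the axis ratio of the equivalent ellipse;
    it is invariant to rotation, translation and uniform scaling.
    """
    outline = np.asarray(outline)
    if outline.ndim == 2 and outline.shape[1] == 2 and outline.dtype != bool:
        area, ixx, ixy, iyy = polygon_second_moments(outline)
        if area <= 0:
            raise ValueError("outline must have positive area")
    elif outline.ndim == 2 and outline.dtype == bool:
        ys, xs = np.nonzero(outline)
        if len(xs) == 0:
            raise ValueError("empty mask")
        x = xs - xs.mean()
        y = ys - ys.mean()
        area = float(len(xs))
        ixx, ixy, iyy = float(x @ x), float(x @ y), float(y @ y)
    else:
        raise ValueError("outline must be an (n,2) float array or boolean mask")
    m = np.array([[ixx, ixy], [ixy, iyy]]) / area
    evals = np.linalg.eigvalsh(m)
    if evals[0] <= 0:
        raise ValueError("degenerate outline (zero minor axis)")
    return float(np.sqrt(evals[1] / evals[0]))
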