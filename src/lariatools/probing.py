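"""Chemical-probing reactivities, Hill binding fits, and shared statistics.

DMS methylates the Watson-Crick face of unpaired A/C; SHAPE reagents such as
NAI acylate flexible 2'-OH groups.  In both protocols the adduct blocks
reverse transcription, so lane intensities report per-position modification.
A reactivity profile is the difference of the normalised modified and
control lanes; the sign convention here is modified - control (positive =
flexible/unpaired), with a flag to flip it for pipelines defined the other
way round.

EMSA titrations are fitted to the Hill isotherm
``B = B_max * L^n / (L^n + K_d^n)`` by a deterministic coarse log-grid over
(K_d, n) followed by local least-squares refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TestResult",
    "HillFit",
    "normalize_lane",
    "reactivity",
    "pearson_r",
    "binomial_test",
    "hill_curve",
    "hill_fit",
]


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class HillFit:
    """Hill-equation parameters recovered from a binding curve."""

    b_max: float
    k_d: float
    n: float
    rss: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.k_d <= 0 or self.n <= 0:
            raise ValueError("K_d and n must be positive")
        if not 0 < self.b_max <= 1.2:  # calibration slack above a bound fraction of 1
            raise ValueError(f"B_max {self.b_max} outside (0, 1.2]")


def normalize_lane(profile: Sequence[float], rule: str = "total") -> np.ndarray:
    """Scale a lane of non-negative intensities.

    'total' divides by the summed signal (unit total).  'top10' applies the
    2-8% style rule: divide by the mean of the top 10% of values after
    excluding the top 2% (outlier-robust scaling used for probing data).
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("profile must be a non-empty 1-D array")
    if (x < 0).any():
        raise ValueError("negative intensities")
    if x.sum() == 0:
        raise ValueError("all-zero lane cannot be normalised")
    if rule == "total":
        return x / x.sum()
    if rule == "top10":
        order = np.sort(x)[::-1]
        n = len(x)
        lo = max(1, int(np.ceil(0.02 * n)))
        hi = max(lo + 1, int(np.ceil(0.10 * n)))
        denom = order[lo:hi].mean()
        if denom == 0:
            raise ValueError("top-10% normaliser is zero")
        return x / denom
    raise ValueError(f"unknown normalisation rule {rule!r}")


def reactivity(
    modified: Sequence[float],
    control: Sequence[float],
    floor: float | None = None,
    sign: str = "modified-minus-control",
    rule: str = "total",
) -> np.ndarray:
    """Per-position reactivity from paired modified/control lanes.

    Both lanes are normalised with ``rule`` first.  ``sign`` selects the
    subtraction direction; ``floor`` optionally clips low values (e.g. -1)
    for display.  reactivity(m, c) == -reactivity(c, m).
    """
    m = np.asarray(modified, dtype=float)
    c = np.asarray(control, dtype=float)
    if m.shape != c.shape:
        raise ValueError(f"lane length mismatch: {m.shape} vs {c.shape}")
    diff = normalize_lane(m, rule) - normalize_lane(c, rule)
    if sign == "control-minus-modified":
        diff = -diff
    elif sign != "modified-minus-control":
        raise ValueError(f"unknown sign convention {sign!r}")
    if floor is not None:
        diff = np.maximum(diff, floor)
    return diff


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with a two-sided p from the F (= t^2) distribution.

    The p-value is the classical regression F-test on n-2 df, identical to
    the two-sided t-test with t = r * sqrt((n-2)/(1-r^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >=3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return TestResult(float(r), float(len(x) - 2), float(p), "pearson (F-test)")


def binomial_test(k: int, n: int, p0: float, alternative: str = "two-sided") -> TestResult:
    """Exact binomial tail probability for k successes out of n."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    res = stats.binomtest(k, n, p0, alternative=alternative)
    return TestResult(float(k), None, float(res.pvalue), f"binomial ({alternative})")


def hill_curve(concentration, b_max: float, k_d: float, n: float):
    """The Hill isotherm B = B_max * L^n / (L^n + K_d^n) (B=0 at L=0)."""
    L = np.asarray(concentration, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ln = np.where(L > 0, L, np.nan) ** n
        b = b_max * Ln / (Ln + k_d**n)
    return np.where(L > 0, b, 0.0)


def hill_fit(
    curve: Sequence[tuple[float, float]],
    kd_grid: tuple[float, float, int] | None = None,
    n_grid: tuple[float, float, int] = (0.3, 6.0, 25),
) -> HillFit:
    """Least-squares Hill fit via coarse log-grid then local refinement.

    ``curve`` is a list of (L, B) points; at least 4 points and 2 distinct
    positive concentrations are required.  The (K_d, n) grid bounds default
    to [L_min/10, L_max*10] log-spaced; B_max is solved linearly at each grid
    node.  Deterministic given the data.
    """
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need >=4 (L, B) points")
    L, B = pts[:, 0], pts[:, 1]
    pos = L > 0
    if len(np.unique(L[pos])) < 2:
        raise ValueError("need >=2 distinct positive concentrations")
    if np.allclose(B, B[0]):
        raise ValueError("degenerate curve: all bound fractions equal")

    if kd_grid is None:
        kd_lo, kd_hi, kd_n = L[pos].min() / 10, L[pos].max() * 10, 40
    else:
        kd_lo, kd_hi, kd_n = kd_grid
    kds = np.geomspace(kd_lo, kd_hi, kd_n)
    ns = np.geomspace(n_grid[0], n_grid[1], n_grid[2])

    def bmax_for(kd: float, n: float) -> tuple[float, float]:
        f = hill_curve(L, 1.0, kd, n)
        denom = float(f @ f)
        if denom == 0:
            return 0.0, float(B @ B)
        bmax = float(f @ B) / denom
        bmax = min(max(bmax, 1e-6), 1.2)
        resid = B - bmax * f
        return bmax, float(resid @ resid)

    best = None
    for kd in kds:
        for n in ns:
            bmax, rss = bmax_for(kd, n)
            if best is None or rss < best[0]:
                best = (rss, bmax, kd, n)
    _, bmax0, kd0, n0 = best

    def residual(theta):
        bmax, log_kd, log_n = theta
        return hill_curve(L, bmax, np.exp(log_kd), np.exp(log_n)) - B

    sol = optimize.least_squares(
        residual,
        x0=[bmax0, np.log(kd0), np.log(n0)],
        bounds=([1e-6, np.log(kd_lo / 10), np.log(n_grid[0] / 2)],
                [1.2, np.log(kd_hi * 10), np.log(n_grid[1] * 2)]),
        method="trf",
    )
    bmax, kd, n = sol.x[0], float(np.exp(sol.x[1])), float(np.exp(sol.x[2]))
    resid = residual(sol.x)
    return HillFit(float(bmax), kd, n, float(resid @ resid), resid)
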