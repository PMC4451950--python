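"""Two-sample testing decision procedure and multiple-testing adjustment.

The decision procedure mirrors common wet-lab practice: Shapiro–Wilk on each
series; if both look normal at the gate alpha, Levene's test decides between
the pooled-variance Student's t-test and Welch's t-test; any normality
failure (or a series too short / constant for Shapiro–Wilk) falls back to
the Mann–Whitney rank-sum test with continuity correction.  All tests are
two-tailed.  Every :class:`TestResult` records the gate outcomes so the
choice of test is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "compare_two_samples", "bh_adjust"]

GATE_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    test_used: str  # student_t | welch_t | mann_whitney
    statistic: float
    p_value: float
    shapiro_p: tuple[float, float] | None
    levene_p: float | None
    gate_alpha: float
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _shapiro_p(x: np.ndarray) -> float | None:
    if x.size < 3 or np.ptp(x) == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(sps.shapiro(x).pvalue)
        except Exception:
            return None


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, list[str]]:
    notes: list[str] = []
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence of a difference
        notes.append("degenerate: all observations identical")
        return float(a.size * b.size / 2.0), 1.0, notes
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size <= 8 and b.size <= 8
    method = "exact" if small and not has_ties else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", use_continuity=True, method=method
    )
    return float(res.statistic), float(res.pvalue), notes


def compare_two_samples(
    a, b, gate_alpha: float = GATE_ALPHA
) -> TestResult:
    """Two-tailed comparison of two real-valued series with a normality gate.

    Both series normal (Shapiro–Wilk p > ``gate_alpha``) and homoscedastic
    (Levene p > ``gate_alpha``): pooled Student's t.  Normal but
    heteroscedastic: Welch's t.  Otherwise (including series too short or
    constant for Shapiro–Wilk): Mann–Whitney with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty series")
    notes: list[str] = []
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    shapiro = None if pa is None or pb is None else (pa, pb)
    if shapiro is None:
        notes.append("normality gate not applicable (short or constant series)")
    if shapiro is not None and pa > gate_alpha and pb > gate_alpha:
        lev = float(sps.levene(a, b).pvalue)
        if lev > gate_alpha:
            res = sps.ttest_ind(a, b, equal_var=True)
            return TestResult(
                "student_t", float(res.statistic), float(res.pvalue),
                shapiro, lev, gate_alpha, tuple(notes),
            )
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(
            "welch_t", float(res.statistic), float(res.pvalue),
            shapiro, lev, gate_alpha, tuple(notes),
        )
    stat, p, mw_notes = _mann_whitney(a, b)
    return TestResult(
        "mann_whitney", stat, p, shapiro, None, gate_alpha,
        tuple(notes + mw_notes),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone envelope).

    Input order is preserved; every output is >= its input and <= 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")
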