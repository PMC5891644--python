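"""Clinical-outcome analytics for single-case motor-rehabilitation data.

Covers Wolf Motor Function Test (WMFT) bookkeeping (timed tasks capped at
120 s, strength tasks excluded from time averages), percent improvement
against the mean of three baseline assessments, a natural-log regression
of scores on session index with a slope F-test, Pearson correlation with
the t-transform p-value, and Spearman correlation with an exact two-sided
permutation p-value by full enumeration (suitable for the n = 5..8 samples
a single-case design produces).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats as _st

WMFT_CAP_S = 120.0

BASELINE_SESSIONS = ("baseline_1", "baseline_2", "baseline_3")
DEFAULT_SESSIONS = BASELINE_SESSIONS + ("week_1", "week_2", "week_3", "week_4",
                                        "retention")


@dataclass
class WMFTTable:
    """Task x session score matrix with per-task units.

    ``values`` is a DataFrame indexed by task label with one column per
    session; ``units`` maps each task to "seconds", "lbs" or "kg".  Timed
    tasks the subject could not complete are capped at 120 s.
    """

    values: pd.DataFrame
    units: dict[str, str]
    cap_s: float = WMFT_CAP_S

    def __post_init__(self) -> None:
        missing = set(self.values.index) - set(self.units)
        if missing:
            raise ValueError(f"tasks without units: {sorted(missing)}")
        timed = self.timed_tasks()
        vals = self.values.loc[timed].to_numpy(dtype=float)
        if np.any(vals <= 0) or np.any(vals > self.cap_s):
            raise ValueError(f"timed scores must lie in (0, {self.cap_s}] s")

    def timed_tasks(self) -> list[str]:
        return [t for t in self.values.index if self.units[t] == "seconds"]

    @property
    def session_labels(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_csv(cls, path) -> "WMFTTable":
        df = pd.read_csv(path)
        units = dict(zip(df["task"], df["unit"]))
        values = df.drop(columns=["unit"]).set_index("task")
        values.index.name = None
        return cls(values, units)

    def to_csv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "unit", [self.units[t] for t in df.index])
        df.to_csv(path, index_label="task")


# WMFT scores of a chronic-stroke case over three baselines, four in-training
# assessments and a retention visit (tasks never completed in any session are
# omitted from the source table; never-completed attempts score the 120-s cap).
_CASE_WMFT_ROWS = [
    ("Forearm to table (side)", "seconds",
     [3.62, 3.83, 3.72, 3.44, 3.08, 4.24, 3.74, 4.13]),
    ("Forearm to box (side)", "seconds",
     [120.00, 120.00, 16.91, 120.00, 16.02, 120.00, 14.88, 9.22]),
    ("Hand to table (front)", "seconds",
     [2.17, 5.01, 3.49, 2.23, 3.205, 4.55, 4.69, 2.58]),
    ("Hand to box (front)", "seconds",
     [120.00, 120.00, 120.00, 8.57, 10.28, 27.36, 30.51, 4.78]),
    ("Weight to box (highest)", "lbs",
     [0.00, 0.00, 0.00, 3, 2, 2, 2, 3]),
    ("Reach and retrieve", "seconds",
     [6.36, 4.17, 3.26, 7.04, 2.80, 2.98, 4.13, 16.81]),
    ("Grip strength (mean)", "kg",
     [7.12, 4.34, 9.29, 6.34, 9.47, 4.43, 6.45, 6.37]),
    ("Fold towel", "seconds",
     [120, 82.56, 120, 120.00, 89.22, 71.81, 120.00, 120]),
    ("Lift basket", "seconds",
     [4.16, 9.52, 7.82, 9.45, 5.74, 6.06, 8.34, 7.49]),
]


def case_wmft_table() -> WMFTTable:
    """Bundled WMFT table of the six-week single-case training study."""
    values = pd.DataFrame(
        {task: row for task, _unit, row in _CASE_WMFT_ROWS},
        index=list(DEFAULT_SESSIONS)).T
    units = {task: unit for task, unit, _row in _CASE_WMFT_ROWS}
    # the weight task scores 0 lbs at baseline; exclude it from the timed
    # invariant by construction (non-"seconds" unit)
    return WMFTTable(values, units)


def average_wmft_time(table: WMFTTable, session: str) -> float:
    """Mean completion time over timed tasks for one session (caps included)."""
    if session not in table.values.columns:
        raise ValueError(f"unknown session {session!r}")
    timed = table.timed_tasks()
    if not timed:
        raise ValueError("table contains no timed tasks")
    return float(table.values.loc[timed, session].mean())


def percent_improvement(table: WMFTTable, task: str,
                        final_session: str = "retention",
                        baseline: str = "mean") -> int:
    """Percent reduction of a timed task against the baseline.

    ``baseline='mean'`` uses the mean of the three baseline assessments;
    ``baseline='third'`` uses only the third.  Rounded to the nearest
    integer percent.
    """
    if table.units.get(task) != "seconds":
        raise ValueError(f"task {task!r} is not a timed task")
    if baseline == "mean":
        base = float(table.values.loc[task, list(BASELINE_SESSIONS)].mean())
    elif baseline == "third":
        base = float(table.values.loc[task, BASELINE_SESSIONS[2]])
    else:
        raise ValueError("baseline must be 'mean' or 'third'")
    final = float(table.values.loc[task, final_session])
    return int(round(100.0 * (base - final) / base))


@dataclass
class RegressionFit:
    intercept: float
    slope: float
    r: float
    F: float
    p: float
    n: int


def fit_log_model(y, x=None) -> RegressionFit:
    """Least squares of y = a + b*ln(x) with a slope F-test.

    ``x`` defaults to session indices 1..n.  ``r`` is the correlation of
    the data with the fitted values, signed by the slope; F = r^2 (n-2) /
    (1 - r^2) on (1, n-2) degrees of freedom, two-sided p.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if x is None:
        x = np.arange(1, n + 1)
    x = np.asarray(x, dtype=float)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0):
        raise ValueError("x must be positive for a log model")
    if np.allclose(y, y[0]):
        raise ValueError("constant y: correlation undefined")
    lx = np.log(x)
    b, a = np.polyfit(lx, y, 1)
    fitted = a + b * lx
    r = float(np.sign(b) * abs(np.corrcoef(y, fitted)[0, 1]))
    r2 = min(r * r, 1.0 - 1e-15)
    F = r2 * (n - 2) / (1.0 - r2)
    p = float(_st.f.sf(F, 1, n - 2))
    return RegressionFit(float(a), float(b), r, float(F), p, n)


@dataclass
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int
    p_method: str


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a sample Pearson r via the t-transform, n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * _st.t.sf(abs(t), n - 2))


def pearson_with_p(x, y) -> CorrelationResult:
    """Sample Pearson correlation with the t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult("pearson", r, pearson_p_from_r(r, len(x)),
                             len(x), "t-transform")


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    n = len(rx)
    d2 = float(np.sum((rx - ry) ** 2))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def spearman_exact(x, y, exact_max_n: int = 8) -> CorrelationResult:
    """Spearman rho with an exact permutation p-value for small n.

    For 3 <= n <= ``exact_max_n`` with tie-free data, the two-sided p is the
    fraction of all n! rank permutations whose |rho| is at least the
    observed |rho|.  Larger samples fall back to the t-approximation
    (flagged in ``p_method``); ties in exact mode raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or n < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if n > exact_max_n:
        rho = float(_st.spearmanr(x, y).statistic)
        return CorrelationResult("spearman", rho, pearson_p_from_r(rho, n),
                                 n, "t-approximation")
    if len(np.unique(x)) != n or len(np.unique(y)) != n:
        raise ValueError("ties present: exact permutation p undefined; use "
                         "the t-approximation on larger samples")
    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    count = 0
    eps = 1e-12
    target = abs(rho) - eps
    for perm in permutations(range(1, n + 1)):
        if abs(_rho_from_ranks(rx, np.asarray(perm, dtype=float))) >= target:
            count += 1
    p = count / factorial(n)
    return CorrelationResult("spearman", float(rho), float(p), n,
                             "exact permutation")


def spearman_null_distribution(n: int) -> dict[float, float]:
    """Exact null distribution of rho over all n! permutations (small n)."""
    if n > 8:
        raise ValueError("enumeration limited to n <= 8")
    base = np.arange(1, n + 1, dtype=float)
    masses: dict[float, int] = {}
    for perm in permutations(range(1, n + 1)):
        rho = round(_rho_from_ranks(base, np.asarray(perm, dtype=float)), 12)
        masses[rho] = masses.get(rho, 0) + 1
    total = factorial(n)
    return {rho: c / total for rho, c in masses.items()}
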