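"""Survey statistics for scat-based species inventories.

Incidence-based sample coverage and rarefaction/extrapolation in the
Chao-style incidence-frequency framework, Chao2 asymptotic richness,
attempt-ledger accounting for the multi-extraction laboratory workflow,
and the two categorical tests used to interrogate spatial defaecation
patterns (chi-square goodness of fit, Fisher's exact test).

The sampling unit throughout is one identified scat sample.  With T
sampling units, incidence frequencies Y_i (number of units in which
species i occurs, here the per-species sample counts), U = sum(Y_i), and
Q1/Q2 the numbers of species seen in exactly one/two units:

* sample coverage  C = 1 - (Q1/U) * [(T-1)Q1 / ((T-1)Q1 + 2 Q2)]
* rarefied coverage C(m) = 1 - sum_i (Y_i/U) * C(T-Y_i, m)/C(T-1, m)
* Chao2 richness   S = S_obs + ((T-1)/T) * Q1^2 / (2 Q2)
  (bias-corrected  S_obs + ((T-1)/T) * Q1 (Q1 - 1) / 2 when Q2 = 0)

Binomial coefficients are evaluated exactly (integer arithmetic), so the
rarefaction formula is overflow-free at any realistic survey size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assigner import AssignmentResult, AssignmentStatus

__all__ = [
    "IncidenceTable",
    "CoverageResult",
    "AttemptLedger",
    "incidence_from_assignments",
    "sample_coverage",
    "rarefied_coverage",
    "extrapolated_coverage",
    "expected_richness",
    "asymptotic_richness",
    "chisq_gof",
    "fisher_exact_2x2",
    "summarize_attempts",
]


@dataclass(frozen=True)
class IncidenceTable:
    """Per-species incidence frequencies over T sampling units."""

    T: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be at least 1")
        if not self.counts:
            raise ValueError("incidence table has no species")
        for sp, y in self.counts.items():
            if not 1 <= y <= self.T:
                raise ValueError(
                    f"incidence of {sp!r} is {y}, outside [1, T={self.T}]"
                )
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def Y(self) -> list[int]:
        return list(self.counts.values())

    @property
    def U(self) -> int:
        """Total incidences."""
        return sum(self.Y)

    @property
    def Q1(self) -> int:
        return sum(1 for y in self.Y if y == 1)

    @property
    def Q2(self) -> int:
        return sum(1 for y in self.Y if y == 2)

    @property
    def S_obs(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class CoverageResult:
    C_hat: float
    S_obs: int
    S_asymptotic: float
    T: int


def incidence_from_assignments(
    results: Sequence[AssignmentResult],
) -> IncidenceTable:
    """Tabulate incidence frequencies, one sampling unit per assigned sample."""
    if not results:
        raise ValueError("no assignment results")
    bad = [r.query_id for r in results if r.status is not AssignmentStatus.ASSIGNED]
    if bad:
        raise ValueError(
            f"incidence table accepts assigned results only; offending: {bad[:5]}"
        )
    counts: dict[str, int] = {}
    for r in results:
        counts[r.best_species] = counts.get(r.best_species, 0) + 1
    return IncidenceTable(T=len(results), counts=dict(sorted(counts.items())))


def sample_coverage(t: IncidenceTable) -> float:
    """Estimated sample coverage at the observed size T (fraction in [0,1])."""
    if t.T < 2:
        raise ValueError("coverage estimation needs T >= 2")
    U, Q1, Q2, T = t.U, t.Q1, t.Q2, t.T
    if U == 0:
        raise ValueError("no incidences recorded")
    if Q1 == 0:
        return 1.0
    denom = (T - 1) * Q1 + 2 * Q2
    return float(1 - Fraction(Q1, U) * Fraction((T - 1) * Q1, denom))


def rarefied_coverage(t: IncidenceTable, m: int) -> float:
    """Expected coverage of a size-m subsample (1 <= m < T), exact arithmetic."""
    if not 1 <= m < t.T:
        raise ValueError(f"m must satisfy 1 <= m < T={t.T}, got {m}")
    T, U = t.T, t.U
    total = Fraction(0)
    cT1m = comb(T - 1, m)
    for y in t.Y:
        total += Fraction(y, U) * Fraction(comb(T - y, m), cT1m)
    return float(1 - total)


def extrapolated_coverage(t: IncidenceTable, m: int) -> float:
    """Coverage extrapolated beyond T (m > T); flagged as extrapolation.

    Uses the standard geometric continuation
    C(T + m*) = 1 - (Q1/U) * [(T-1)Q1 / ((T-1)Q1 + 2 Q2)]^(m* + 1).
    """
    if m <= t.T:
        raise ValueError("extrapolation requires m > T")
    warnings.warn("coverage beyond the observed sample size is extrapolated")
    U, Q1, Q2, T = t.U, t.Q1, t.Q2, t.T
    if Q1 == 0:
        return 1.0
    m_star = m - T
    a = (T - 1) * Q1 / ((T - 1) * Q1 + 2 * Q2)
    return float(1 - (Q1 / U) * a ** (m_star + 1))


def coverage(t: IncidenceTable, m: int | None = None) -> float:
    """Coverage at size m: rarefied (m < T), observed (m in {None, T}), or
    extrapolated (m > T)."""
    if m is None or m == t.T:
        return sample_coverage(t)
    if m < t.T:
        return rarefied_coverage(t, m)
    return extrapolated_coverage(t, m)


def expected_richness(t: IncidenceTable, m: int) -> float:
    """Expected species richness of a size-m sample (rarefaction for m <= T,
    Chao-style extrapolation for m > T)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    T = t.T
    if m <= T:
        total = 0.0
        cTm = comb(T, m)
        for y in t.Y:
            total += 1 - comb(T - y, m) / cTm
        return total
    q0 = asymptotic_richness(t) - t.S_obs
    if q0 == 0 or t.Q1 == 0:
        return float(t.S_obs)
    m_star = m - T
    return float(
        t.S_obs + q0 * (1 - (1 - t.Q1 / (t.Q1 + T * q0)) ** m_star)
    )


def asymptotic_richness(t: IncidenceTable) -> float:
    """Chao2-type asymptotic species richness (>= S_obs).

    Falls back to the bias-corrected form when there are no duplicates
    (Q2 = 0), which avoids division by zero.
    """
    T, Q1, Q2 = t.T, t.Q1, t.Q2
    if Q1 == 0:
        return float(t.S_obs)
    if Q2 > 0:
        return float(t.S_obs + (T - 1) / T * Q1**2 / (2 * Q2))
    return float(t.S_obs + (T - 1) / T * Q1 * (Q1 - 1) / 2)


def coverage_summary(t: IncidenceTable) -> CoverageResult:
    return CoverageResult(
        C_hat=sample_coverage(t),
        S_obs=t.S_obs,
        S_asymptotic=asymptotic_richness(t),
        T=t.T,
    )


def chisq_gof(
    observed: Sequence[int], expected_proportions: Sequence[float]
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of counts against expected proportions.

    Returns (chi2, df, p).  Asymptotic upper-tail p, no continuity
    correction.  Proportions must sum to 1 and all expected counts must be
    positive.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected_proportions differ in length")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    expected = obs.sum() * props
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return float(chi2), len(obs) - 1, float(p)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Sums hypergeometric probabilities (margins fixed) of all tables no more
    probable than the observed one.  A zero margin makes the table
    degenerate: p = 1 by convention, with a warning.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("expected a 2x2 table of nonnegative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1 by convention")
        return 1.0
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


@dataclass(frozen=True)
class AttemptLedger:
    """Multi-extraction / multi-PCR retry bookkeeping for a scat cohort.

    ``stages`` is the ordered list of (stage name, n attempted, n assigned);
    samples not assigned at a stage roll forward to later stages, and those
    never assigned are ``n_failed``.
    """

    stages: tuple[tuple[str, int, int], ...]
    n_total: int
    n_failed: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("ledger has no samples")
        if not self.stages:
            raise ValueError("ledger has no stages")
        assigned_total = 0
        prev_attempted, prev_assigned = None, None
        for name, attempted, assigned in self.stages:
            if assigned > attempted:
                raise ValueError(
                    f"stage {name!r}: assigned {assigned} exceeds attempted "
                    f"{attempted}"
                )
            if prev_attempted is not None and attempted > prev_attempted - prev_assigned:
                raise ValueError(
                    f"stage {name!r}: attempted {attempted} exceeds the "
                    f"{prev_attempted - prev_assigned} samples unresolved at "
                    "the previous stage"
                )
            prev_attempted, prev_assigned = attempted, assigned
            assigned_total += assigned
        if assigned_total + self.n_failed != self.n_total:
            raise ValueError(
                f"assigned ({assigned_total}) + failed ({self.n_failed}) != "
                f"total ({self.n_total})"
            )


def summarize_attempts(ledger: AttemptLedger) -> pd.DataFrame:
    """Per-stage and cumulative identification percentages (1 decimal).

    Mirrors the published attempt-table layout: each stage's percent of the
    full cohort assigned at that stage, the failure percentage, and the
    running cumulative percent assigned.
    """
    rows = []
    cum = 0
    for name, attempted, assigned in ledger.stages:
        cum += assigned
        rows.append(
            {
                "stage": name,
                "n_attempted": attempted,
                "n_assigned": assigned,
                "percent": round(100 * assigned / ledger.n_total, 1),
                "cumulative_percent": round(100 * cum / ledger.n_total, 1),
            }
        )
    rows.append(
        {
            "stage": "failed_to_amplify",
            "n_attempted": ledger.n_failed,
            "n_assigned": 0,
            "percent": round(100 * ledger.n_failed / ledger.n_total, 1),
            "cumulative_percent": round(100 * cum / ledger.n_total, 1),
        }
    )
    return pd.DataFrame(rows)
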