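"""Two-group cohort statistics: Mann–Whitney U, χ², φ coefficient, Cohen's d.

Continuous covariates are compared with the Mann–Whitney U test and summarised
with Cohen's d; binary covariates with the Pearson χ² test (1 df, no continuity
correction) and the φ coefficient. Effect sizes are reported as absolute values
rounded to two decimals, matching the usual clinical-table presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2×2 counts; rows = factor present/absent, columns = survived/died."""

    a: int  # present, survived
    b: int  # present, died
    c: int  # absent, survived
    d: int  # absent, died

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group n/mean/SD for a standardized mean difference."""

    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be non-negative")


def phi_coefficient(t: ContingencyTable2x2) -> float:
    """Signed φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)).

    Raises on a zero margin, where the coefficient is undefined.
    """
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("phi undefined: a table margin is zero")
    num = t.a * t.d - t.b * t.c
    den = np.sqrt(float(r1) * r2 * c1 * c2)
    return float(num / den)


def chi_square_2x2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson χ² (1 df, no continuity correction) and its p-value.

    Satisfies the identity χ² = n·φ² exactly.
    """
    phi = phi_coefficient(t)
    stat = t.n * phi**2
    p = float(sps.chi2.sf(stat, df=1))
    return float(stat), p


def cohens_d(g: GroupSummary) -> float:
    """Standardized mean difference (mean2 − mean1) / pooled SD.

    The pooled SD uses (n−1) weights (the standard two-sample definition).
    """
    pooled_var = ((g.n1 - 1) * g.sd1**2 + (g.n2 - 1) * g.sd2**2) / (g.n1 + g.n2 - 2)
    if pooled_var == 0:
        raise ValueError("Cohen's d undefined: pooled SD is zero")
    return float((g.mean2 - g.mean1) / np.sqrt(pooled_var))


def cohens_d_from_samples(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohens_d(
        GroupSummary(
            n1=len(x), mean1=float(np.mean(x)), sd1=float(np.std(x, ddof=1)),
            n2=len(y), mean2=float(np.mean(y)), sd2=float(np.std(y, ddof=1)),
        )
    )


#: largest per-group size for which the exact U null distribution is used
EXACT_MW_MAX_N = 8


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney U statistic (for x) and two-tailed p-value.

    Uses the exact null distribution when both groups have at most
    :data:`EXACT_MW_MAX_N` observations and there are no ties across samples;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(x) <= EXACT_MW_MAX_N and len(y) <= EXACT_MW_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _is_binary(col: pd.Series) -> bool:
    vals = pd.unique(col.dropna())
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def table2_report(
    clinical: pd.DataFrame,
    outcome_col: str = "outcome",
    round_effects: int = 2,
) -> pd.DataFrame:
    """Per-variable two-group comparison of a clinical table.

    Continuous variables get Mann–Whitney U + Cohen's d; 0/1 variables get
    χ² + |φ|. ``outcome_col`` is 0 = survived, 1 = died. Variables with a
    single observed level are skipped with a warning.

    Returns a frame with columns: variable, kind, total_summary, p_value,
    effect_size (|d| or |φ|, rounded).
    """
    if outcome_col not in clinical.columns:
        raise ValueError(f"outcome column {outcome_col!r} missing")
    y = clinical[outcome_col].astype(int).to_numpy()
    rows = []
    for name in clinical.columns:
        if name in (outcome_col, "subject_id"):
            continue
        col = clinical[name]
        if not pd.api.types.is_numeric_dtype(col):
            continue
        if col.nunique(dropna=True) < 2:
            warnings.warn(f"variable {name!r} has a single level; skipped")
            continue
        v = col.to_numpy(dtype=float)
        surv, died = v[y == 0], v[y == 1]
        if _is_binary(col):
            t = ContingencyTable2x2(
                a=int(np.sum((v == 1) & (y == 0))),
                b=int(np.sum((v == 1) & (y == 1))),
                c=int(np.sum((v == 0) & (y == 0))),
                d=int(np.sum((v == 0) & (y == 1))),
            )
            _, p = chi_square_2x2(t)
            eff = abs(phi_coefficient(t))
            kind = "binary"
            summary = f"{int(v.sum())} ({100 * v.mean():.2f}%)"
        else:
            _, p = mann_whitney_u(died, surv)
            eff = abs(cohens_d_from_samples(surv, died))
            kind = "continuous"
            summary = f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
        rows.append(
            {
                "variable": name,
                "kind": kind,
                "total_summary": summary,
                "p_value": p,
                "effect_size": round(eff, round_effects),
            }
        )
    return pd.DataFrame(rows)
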