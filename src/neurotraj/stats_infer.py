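"""Inferential battery for trajectory statistics.

Paired two-sided t-tests and within-subject (repeated-measures) ANOVA
compare trajectory lengths across load, performance, and session; Pearson
correlations assess trajectory-behavior associations; dependent
non-overlapping correlations are compared across sessions with the
Dunn-Clark z (Fisher-transformed correlations with a covariance correction
from the cross-correlations of the four involved variables); families of
p-values are adjusted with the Benjamini-Hochberg step-up FDR procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ContractError

__all__ = [
    "StatResult",
    "paired_t",
    "rm_anova",
    "rm_anova_two_way",
    "pearson",
    "compare_dependent_correlations",
    "bh_fdr",
    "adjust_family",
]


@dataclass
class StatResult:
    name: str
    statistic: float
    df: float | tuple
    p: float
    p_fdr: float | None = None
    family_id: str | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p": self.p,
            "p_fdr": self.p_fdr,
            "family_id": self.family_id,
            **self.extra,
        }


def paired_t(a, b, name: str = "paired_t") -> StatResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("paired samples must be 1-D and equal length")
    n = len(a)
    if n < 2:
        raise ContractError(f"need n >= 2 pairs, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ContractError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return StatResult(name=name, statistic=float(t), df=float(n - 1), p=float(p))


def rm_anova(values: np.ndarray, name: str = "rm_anova") -> StatResult:
    """One-way within-subject ANOVA on a complete subjects x conditions
    table (subject as blocking factor).

    F = MS_condition / MS_error with df = (k-1, (n-1)(k-1)), from the
    standard sums-of-squares partition SS_total = SS_subject +
    SS_condition + SS_error.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 2:
        raise ContractError("values must be a 2-D subjects x conditions table")
    if np.any(~np.isfinite(Y)):
        raise ContractError("missing or non-finite cells (no imputation)")
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ContractError("need >= 2 subjects and >= 2 conditions")
    grand = Y.mean()
    ss_subj = k * np.sum((Y.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_cond
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        raise ContractError("zero error mean square; ANOVA undefined")
    F = (ss_cond / df_cond) / ms_err
    p = sps.f.sf(F, df_cond, df_err)
    return StatResult(name=name, statistic=float(F), df=(float(df_cond), float(df_err)), p=float(p))


def rm_anova_two_way(values: np.ndarray, name: str = "rm_anova_2w") -> dict:
    """Two-way fully-within ANOVA on a subjects x A-levels x B-levels cube.

    Each effect is tested against its own subject-interaction error term.
    Returns {"A": StatResult, "B": StatResult, "AxB": StatResult}.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 3:
        raise ContractError("values must be 3-D: subjects x A x B")
    if np.any(~np.isfinite(Y)):
        raise ContractError("missing or non-finite cells (no imputation)")
    n, a, b = Y.shape
    if n < 2 or a < 2 or b < 2:
        raise ContractError("need >= 2 levels on every factor and >= 2 subjects")
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = np.sum(resid**2)

    out = {}
    for key, ss_eff, df_eff, ss_err, df_err in (
        ("A", ss_a, a - 1, ss_sa, (n - 1) * (a - 1)),
        ("B", ss_b, b - 1, ss_sb, (n - 1) * (b - 1)),
        ("AxB", ss_ab, (a - 1) * (b - 1), ss_sab, (n - 1) * (a - 1) * (b - 1)),
    ):
        ms_err = ss_err / df_err
        if ms_err <= 0:
            raise ContractError(f"zero error mean square for effect {key}")
        F = (ss_eff / df_eff) / ms_err
        p = sps.f.sf(F, df_eff, df_err)
        out[key] = StatResult(
            name=f"{name}:{key}", statistic=float(F),
            df=(float(df_eff), float(df_err)), p=float(p),
        )
    return out


def pearson(x, y, name: str = "pearson") -> StatResult:
    """Pearson r with a two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("inputs must be 1-D and equal length")
    n = len(x)
    if n < 4:
        raise ContractError(f"need n >= 4, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ContractError("constant input vector")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return StatResult(name=name, statistic=r, df=float(n - 2), p=p, extra={"r": r})


def compare_dependent_correlations(r1: float, r2: float, cross: dict, n: int,
                                   name: str = "dunn_clark_z") -> StatResult:
    """Dunn-Clark z for two dependent, non-overlapping correlations.

    ``r1`` correlates variables (1, 2) and ``r2`` variables (3, 4), all
    measured on the same n subjects; ``cross`` supplies the four
    cross-correlations r13, r14, r23, r24.  The Fisher transforms z1, z2
    are compared with ``z = (z1 - z2) sqrt((n - 3) / (2 - 2 c))`` where c
    is the correlation between the transformed estimates derived from the
    Pearson-Filon covariance of r1 and r2.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ContractError("correlations must satisfy |r| < 1")
    if n < 10:
        raise ContractError(f"need n >= 10, got {n}")
    required = ("r13", "r14", "r23", "r24")
    missing = [k for k in required if k not in cross]
    if missing:
        raise ContractError(f"incomplete cross-correlation set; missing {missing}")
    r13, r14, r23, r24 = (float(cross[k]) for k in required)
    for val in (r13, r14, r23, r24):
        if abs(val) > 1:
            raise ContractError("cross-correlations must lie in [-1, 1]")
    psi = (
        0.5 * r1 * r2 * (r13**2 + r14**2 + r23**2 + r24**2)
        + r13 * r24
        + r14 * r23
        - (r1 * r13 * r14 + r1 * r23 * r24 + r2 * r13 * r23 + r2 * r14 * r24)
    )
    c = psi / ((1.0 - r1**2) * (1.0 - r2**2))
    c = float(np.clip(c, -0.999999, 0.999999))
    z1 = np.arctanh(r1)
    z2 = np.arctanh(r2)
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return StatResult(
        name=name, statistic=float(z), df=float(n), p=p,
        extra={"r1": r1, "r2": r2, "c": c},
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ContractError("p_values must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ContractError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results: list[StatResult], family_id: str = "family") -> list[StatResult]:
    """Attach BH-adjusted p-values to a family of results, in place."""
    adj = bh_fdr([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
        r.family_id = family_id
    return results
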