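"""Repeated-measures inference: one-way RM-ANOVA with Greenhouse-Geisser
correction and Sidak-adjusted pairwise contrasts.

The RM-ANOVA uses the standard within-subject decomposition

    F = MS_conditions / MS_error,  df = (k-1), (k-1)(n-1)

with the Greenhouse-Geisser epsilon estimated from the double-centered
sample covariance of the condition columns,

    eps = tr(S~)^2 / ((k-1) * sum(S~^2)),   1/(k-1) <= eps <= 1,

scaling both degrees of freedom before the p value is read off the F
distribution.  Pairwise contrasts are paired t tests with the Sidak
family-wise adjustment p_adj = 1 - (1 - p)^m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .io_core import ValidationError

__all__ = [
    "RmAnovaResult",
    "PairedContrast",
    "rm_anova_oneway",
    "sidak_adjust",
    "paired_contrasts",
]


@dataclass
class RmAnovaResult:
    f: float
    df1: float               # uncorrected k-1
    df2: float               # uncorrected (k-1)(n-1)
    epsilon: float           # Greenhouse-Geisser estimate
    df1_corrected: float
    df2_corrected: float
    p: float                 # at the corrected degrees of freedom
    p_uncorrected: float
    n_subjects: int
    n_conditions: int

    def __post_init__(self) -> None:
        k = self.n_conditions
        if not (1.0 / (k - 1) - 1e-12 <= self.epsilon <= 1.0 + 1e-12):
            raise ValidationError("epsilon outside its bounds")
        if not (0.0 <= self.p <= 1.0) or self.f < 0:
            raise ValidationError("invalid F or p")


@dataclass
class PairedContrast:
    pair: tuple
    t: float
    p_raw: float
    p_adjusted: float
    degenerate: bool = False


def rm_anova_oneway(data: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValidationError("data must be a subjects x conditions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError("need at least 2 subjects and 2 conditions")
    if np.any(~np.isfinite(x)):
        raise ValidationError("missing cells are not supported")

    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1.0
    df2 = (k - 1.0) * (n - 1.0)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        f = 0.0 if ms_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err

    # Greenhouse-Geisser epsilon from the double-centered covariance
    s = np.cov(x, rowvar=False, ddof=1)
    row = s.mean(axis=0, keepdims=True)
    col = s.mean(axis=1, keepdims=True)
    s_dc = s - row - col + s.mean()
    denom = (k - 1.0) * float((s_dc ** 2).sum())
    eps = 1.0 if denom == 0 else float(np.trace(s_dc)) ** 2 / denom
    eps = float(np.clip(eps, 1.0 / (k - 1.0), 1.0))

    p_unc = float(scipy.stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    p_gg = float(scipy.stats.f.sf(f, eps * df1, eps * df2)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p_unc = p_gg = 1.0
    return RmAnovaResult(float(f), df1, df2, eps, eps * df1, eps * df2,
                         p_gg, p_unc, n, k)


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak family-wise adjustment: p_adj = 1 - (1 - p)^m, clipped to 1."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p values must lie in [0, 1]")
    m = m if m is not None else p.size
    if m < 1:
        raise ValidationError("family size must be at least 1")
    return np.minimum(1.0 - (1.0 - p) ** m, 1.0)


def paired_contrasts(data: np.ndarray, pairs: list[tuple[int, int]],
                     family_size: int | None = None) -> list[PairedContrast]:
    """Paired t tests on condition-column pairs with Sidak adjustment.

    ``pairs`` index columns of the subjects x conditions matrix.  A pair
    with zero within-pair variance is degenerate: t = 0, p = 1 when the
    columns are identical, otherwise flagged with p = 0.
    """
    x = np.asarray(data, dtype=float)
    m = family_size if family_size is not None else len(pairs)
    raw = []
    for a, b in pairs:
        if a == b:
            raise ValidationError("a contrast needs two distinct conditions")
        d = x[:, a] - x[:, b]
        sd = d.std(ddof=1)
        if sd == 0:
            if d.mean() == 0:
                raw.append((0.0, 1.0, True))
            else:
                raw.append((np.inf if d.mean() > 0 else -np.inf, 0.0, True))
        else:
            t, p = scipy.stats.ttest_rel(x[:, a], x[:, b])
            raw.append((float(t), float(p), False))
    adj = sidak_adjust([p for _, p, _ in raw], m)
    return [PairedContrast(tuple(pair), t, p, float(pa), deg)
            for pair, (t, p, deg), pa in zip(pairs, raw, adj)]
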