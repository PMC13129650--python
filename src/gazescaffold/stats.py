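"""Condition-level statistics on window-mean gaze biases.

A 2 × 2 repeated-measures ANOVA (distance × scaffold) via the classic
within-subject sum-of-squares decomposition, Bonferroni-corrected post hoc
paired t tests with Cohen's d, partial η², the JZS (Cauchy-prior) Bayes
factor for paired/one-sample t statistics computed by adaptive quadrature,
and the Pearson correlation (with Bayes factor) between the gaze-bias
interaction index and condition accuracy differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, stats

CELL_ORDER = [("direction_insufficient", "near"), ("direction_insufficient", "far"),
              ("direction_sufficient", "near"), ("direction_sufficient", "far")]


@dataclass
class EffectResult:
    F: float
    df: Tuple[int, int]
    p: float
    partial_eta_sq: float


@dataclass
class AnovaResult:
    effects: Dict[str, EffectResult]
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"effect": k, "F": e.F, "df1": e.df[0], "df2": e.df[1],
             "p": e.p, "partial_eta_sq": e.partial_eta_sq}
            for k, e in self.effects.items()])


@dataclass
class TTestResult:
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    cohens_d: float
    family_size: int = 1


@dataclass
class BayesResult:
    bf01: float
    bf10: float
    t: float
    n: int
    r_scale: float


@dataclass
class CorrelationResult:
    r: float
    p: float
    bf01: float
    n: int


def partial_eta_squared(F: float, df_error: int) -> float:
    """η²p for a single-df effect: F / (F + df_error)."""
    return F / (F + df_error)


def rm_anova_2x2(cells: np.ndarray,
                 factor_names: Tuple[str, str] = ("scaffold", "distance")) -> AnovaResult:
    """Two-way fully within-subject ANOVA on an (n, 2, 2) cell array.

    Axis 1 is the first factor, axis 2 the second.  Each effect has a single
    df, so its F equals the squared paired t of the corresponding contrast
    and η²p = F/(F + n − 1).  The implementation is the sum-of-squares
    decomposition with subject-by-effect error terms.
    """
    Y = np.asarray(cells, float)
    if Y.ndim != 2 or Y.shape[1] != 4:
        if Y.ndim == 3 and Y.shape[1:] == (2, 2):
            pass
        else:
            raise ValueError("cells must be (n, 2, 2) or (n, 4)")
    if Y.ndim == 2:
        Y = Y.reshape(-1, 2, 2)
    if not np.isfinite(Y).all():
        keep = np.isfinite(Y).all(axis=(1, 2))
        import warnings
        warnings.warn(f"{(~keep).sum()} participant(s) with missing cells dropped")
        Y = Y[keep]
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 complete participants")
    g = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_as = Y.mean(axis=2)
    m_bs = Y.mean(axis=1)

    ss_a = n * 2 * np.sum((m_a - g) ** 2)
    ss_b = n * 2 * np.sum((m_b - g) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_as = 2 * np.sum((m_as - m_a[None, :] - m_s[:, None] + g) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_b[None, :] - m_s[:, None] + g) ** 2)
    resid = (Y - m_ab[None] - m_as[:, :, None] - m_bs[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None] - g)
    ss_abs = np.sum(resid ** 2)

    dfe = n - 1
    # degenerate inputs (identical conditions) leave effect and error SS at
    # rounding level; treat both as exact zeros relative to the total SS
    tol = 1e-12 * max(float(np.sum((Y - g) ** 2)), 1e-300)
    effects: Dict[str, EffectResult] = {}
    for name, ss_eff, ss_err in ((factor_names[0], ss_a, ss_as),
                                 (factor_names[1], ss_b, ss_bs),
                                 ("interaction", ss_ab, ss_abs)):
        if ss_eff < tol:
            ss_eff = 0.0
        if ss_err < tol:
            ss_err = 0.0
        if ss_err <= 0:
            F = 0.0 if ss_eff <= 0 else float("inf")
        else:
            F = (ss_eff / 1.0) / (ss_err / dfe)
        p = float(stats.f.sf(F, 1, dfe)) if np.isfinite(F) else 0.0
        effects[name] = EffectResult(F=float(F), df=(1, dfe), p=p,
                                     partial_eta_sq=partial_eta_squared(F, dfe)
                                     if np.isfinite(F) else 1.0)
    return AnovaResult(effects=effects, n=n)


def paired_t(a: np.ndarray, b: np.ndarray, family_size: int = 1) -> TTestResult:
    """Paired t test with Cohen's d (mean difference / SD of differences).

    ``family_size`` is the number of post hoc comparisons in the Bonferroni
    family; the corrected p is min(1, m × p).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length 1-d arrays with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=n - 1, p_raw=float(p),
                       p_bonferroni=float(min(1.0, family_size * p)),
                       cohens_d=float(d.mean() / sd), family_size=family_size)


def bf10_jzs(t: float, n: int, r_scale: float = 0.707) -> float:
    """JZS Bayes factor BF10 for a one-sample/paired t statistic.

    Effect size prior: Cauchy(0, r); equivalently g ~ inverse-χ²(1) in

        BF10 = ∫₀^∞ (1+ngr²)^(-1/2) [1 + t²/((1+ngr²)(n−1))]^(-n/2) π(g) dg
               ───────────────────────────────────────────────────────────
                               [1 + t²/(n−1)]^(-n/2)

    computed by adaptive quadrature to relative error < 1e-6.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if r_scale <= 0:
        raise ValueError("r_scale must be > 0")
    nu = n - 1
    t2 = float(t) ** 2

    def integrand(g):
        a = 1.0 + n * g * r_scale ** 2
        return (a ** -0.5 * (1.0 + t2 / (a * nu)) ** (-(nu + 1) / 2.0)
                * g ** -1.5 * np.exp(-1.0 / (2.0 * g)) / np.sqrt(2.0 * np.pi))

    num, err = integrate.quad(integrand, 0, np.inf, epsabs=0, epsrel=1e-9, limit=400)
    if num <= 0 or err / num > 1e-6:
        raise RuntimeError(f"quadrature did not converge (value {num}, abserr {err})")
    den = (1.0 + t2 / nu) ** (-(nu + 1) / 2.0)
    return num / den


def bf01_paired(t: float, n: int, r_scale: float = 0.707) -> BayesResult:
    """Evidence for the null over the alternative, BF01 = 1/BF10."""
    bf10 = bf10_jzs(t, n, r_scale)
    return BayesResult(bf01=1.0 / bf10, bf10=bf10, t=float(t), n=n, r_scale=r_scale)


def accuracy_correlation(interaction_index: np.ndarray,
                         accuracy_diff: np.ndarray) -> CorrelationResult:
    """Pearson correlation of gaze-bias interaction index with accuracy diff.

    Reports the two-sided p and a default-prior Bayes factor for the
    correlation (Jeffreys stretched-beta prior, width 1) as BF01.
    """
    x = np.asarray(interaction_index, float)
    y = np.asarray(accuracy_diff, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-d vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a correlation input")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0:
        bf01 = 0.0
    else:
        from pingouin import bayesfactor_pearson
        bf10 = float(bayesfactor_pearson(r, len(x)))
        bf01 = 1.0 / bf10
    return CorrelationResult(r=float(r), p=float(p), bf01=bf01, n=len(x))


def bias_matrix(bias_df: pd.DataFrame) -> Tuple[np.ndarray, list]:
    """Pivot a long bias table into an (n, 2, 2) scaffold × distance array.

    Cell order on the flattened last axes follows ``CELL_ORDER``.
    Participants with missing cells carry NaN (handled downstream).
    """
    wide = bias_df.pivot_table(index="participant", columns=["scaffold", "cued_distance"],
                               values="bias")
    cols = [(s, d) for s, d in CELL_ORDER]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    Y = wide.to_numpy().reshape(-1, 2, 2)
    return Y, list(wide.index)
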