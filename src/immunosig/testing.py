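"""Per-peptide group-difference screening.

Group sizes and variances in immunosignature studies are routinely unequal,
so the workhorse two-group test is the Welch t-test with Satterthwaite
degrees of freedom

    t  = (x̄₁ − x̄₂) / sqrt(w₁ + w₂),          wᵢ = sᵢ²/nᵢ
    df = (w₁ + w₂)² / (w₁²/(n₁−1) + w₂²/(n₂−1))

run on log10 median-normalized intensities, one test per printed peptide,
with Bonferroni familywise control over the full array.  Logistic and
multinomial logistic models are provided as regression alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeptideTestResult",
    "RegressionResult",
    "welch_t_test",
    "p_from_t",
    "bonferroni_threshold",
    "test_all_peptides",
    "results_frame",
    "fit_logistic",
    "fit_multinomial",
]


@dataclass
class PeptideTestResult:
    peptide_id: str
    t_value: float
    df: float
    p_value: float
    mean_diff: float
    n1: int
    n2: int
    significant_after_bonferroni: bool = False
    sequence: str | None = None


@dataclass
class RegressionResult:
    """Coefficients of a (multinomial) logistic fit.

    ``coefficients`` etc. are DataFrames with one column per non-reference
    outcome level and one row per predictor (plus intercept).
    """

    outcome_levels: list[str]
    reference_level: str
    coefficients: pd.DataFrame
    odds_ratios: pd.DataFrame
    std_errors: pd.DataFrame
    p_values: pd.DataFrame
    converged: bool


def p_from_t(t: float, df: float) -> float:
    """Two-tailed tail probability of Student's t; symmetric in sign of t."""
    if df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    return float(2.0 * stats.t.sf(abs(t), df))


def welch_t_test(a, b, peptide_id: str = "") -> PeptideTestResult:
    """Welch t-test of two groups with Satterthwaite degrees of freedom.

    Zero variance in both groups with equal means returns t=0, p=1 by
    convention (no evidence of a difference, not an error).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    w1 = a.var(ddof=1) / n1
    w2 = b.var(ddof=1) / n2
    diff = a.mean() - b.mean()
    if w1 + w2 == 0.0:
        if diff == 0.0:
            return PeptideTestResult(peptide_id, 0.0, float(n1 + n2 - 2), 1.0,
                                     0.0, n1, n2)
        return PeptideTestResult(peptide_id, np.inf * np.sign(diff),
                                 float(n1 + n2 - 2), 0.0, float(diff), n1, n2)
    t = diff / np.sqrt(w1 + w2)
    df = (w1 + w2) ** 2 / (w1**2 / (n1 - 1) + w2**2 / (n2 - 1))
    return PeptideTestResult(peptide_id, float(t), float(df),
                             p_from_t(t, df), float(diff), n1, n2)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Familywise per-test threshold alpha/m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def test_all_peptides(x, g1: str, g2: str, alpha: float = 0.05) -> list[PeptideTestResult]:
    """Welch-test every printed (non-empty-spot) peptide between two groups.

    Runs on the values of *x* (a :class:`~immunosig.arraydata.NormalizedMatrix`;
    a raw IntensityMatrix is accepted but screening is intended on the log
    scale).  Results are sorted by ascending p, ties broken by descending
    |t| then peptide id, and flagged against the Bonferroni threshold
    ``alpha / m`` where m counts the peptides actually tested.
    """
    m1 = x.group_mask(g1)
    m2 = x.group_mask(g2)
    keep = ~x.empty_spot
    vals = x.values[:, keep]
    ids = [p for p, k in zip(x.peptide_ids, keep) if k]
    seqs = getattr(x, "peptide_sequences", None)
    if seqs is None and hasattr(x, "provenance"):
        seqs = x.provenance.peptide_sequences
    seqs = [s for s, k in zip(seqs, keep) if k] if seqs is not None else [None] * len(ids)

    a, b = vals[m1], vals[m2]
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    w1 = a.var(axis=0, ddof=1) / n1
    w2 = b.var(axis=0, ddof=1) / n2
    diff = a.mean(axis=0) - b.mean(axis=0)
    denom = w1 + w2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.sqrt(denom), 0.0)
        df = np.where(
            denom > 0,
            denom**2 / (w1**2 / (n1 - 1) + w2**2 / (n2 - 1)),
            float(n1 + n2 - 2),
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[(denom == 0) & (diff == 0)] = 1.0

    thresh = bonferroni_threshold(alpha, len(ids))
    results = [
        PeptideTestResult(pid, float(ti), float(dfi), float(pi), float(di),
                          n1, n2, bool(pi < thresh), seq)
        for pid, ti, dfi, pi, di, seq in zip(ids, t, df, p, diff, seqs)
    ]
    results.sort(key=lambda r: (r.p_value, -abs(r.t_value), r.peptide_id))
    return results


def results_frame(results: list[PeptideTestResult]) -> pd.DataFrame:
    """Ranked table mirroring the standard report layout."""
    return pd.DataFrame(
        {
            "Variable ID": [r.peptide_id for r in results],
            "Peptide Sequence": [r.sequence or "" for r in results],
            "T-Value": [r.t_value for r in results],
            "Degrees Of Freedom": [r.df for r in results],
            "P-Value": [r.p_value for r in results],
            "Bonferroni Significant": [r.significant_after_bonferroni for r in results],
        }
    )


def _regress(y, X, reference_level, multinomial: bool) -> RegressionResult:
    import statsmodels.api as sm

    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    levels = [str(v) for v in pd.unique(pd.Series(y).astype(str))]
    if len(levels) < 2:
        raise ValueError("outcome has a single level")
    if reference_level is None:
        reference_level = levels[0]
    if reference_level not in levels:
        raise ValueError(f"reference level {reference_level!r} not among outcome levels")
    others = [lv for lv in levels if lv != reference_level]
    Xc = sm.add_constant(X, has_constant="add")
    names = ["intercept"] + [f"x{i+1}" for i in range(X.shape[1])]

    ystr = pd.Series(y).astype(str)
    converged = True
    coefs, ses, ps = {}, {}, {}
    try:
        if multinomial and len(levels) > 2:
            # statsmodels MNLogit uses the first category code as reference
            cat = pd.Categorical(ystr, categories=[reference_level] + others)
            fit = sm.MNLogit(cat.codes, Xc).fit(disp=False, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            for j, lv in enumerate(others):
                coefs[lv] = np.asarray(fit.params)[:, j]
                ses[lv] = np.asarray(fit.bse)[:, j]
                ps[lv] = np.asarray(fit.pvalues)[:, j]
        else:
            lv = others[0]
            fit = sm.Logit((ystr == lv).astype(int), Xc).fit(disp=False, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            coefs[lv] = np.asarray(fit.params)
            ses[lv] = np.asarray(fit.bse)
            ps[lv] = np.asarray(fit.pvalues)
    except Exception:
        # perfect separation or a singular Hessian: report non-convergence
        converged = False
        for lv in others:
            coefs[lv] = np.full(len(names), np.nan)
            ses[lv] = np.full(len(names), np.nan)
            ps[lv] = np.full(len(names), np.nan)

    coef_df = pd.DataFrame(coefs, index=names)
    return RegressionResult(
        outcome_levels=levels,
        reference_level=reference_level,
        coefficients=coef_df,
        odds_ratios=np.exp(coef_df),
        std_errors=pd.DataFrame(ses, index=names),
        p_values=pd.DataFrame(ps, index=names),
        converged=converged,
    )


def fit_logistic(y, X, reference_level=None) -> RegressionResult:
    """Binary logistic regression by ML (IRLS); odds ratios = exp(coef).

    Non-convergence (e.g. complete separation) is reported through the
    ``converged`` flag rather than an exception.
    """
    return _regress(y, X, reference_level, multinomial=False)


def fit_multinomial(y, X, reference_level=None) -> RegressionResult:
    """Multinomial logistic regression: L-1 equations against *reference_level*."""
    return _regress(y, X, reference_level, multinomial=True)
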