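"""Multiple-testing control and genomic-inflation diagnostics.

Benjamini-Hochberg step-up FDR control with the derived working p-value
threshold (the largest p among declared-significant markers, which is what
downstream secondary-signal methods consume), and the genomic inflation
factor lambda = median observed chi-square / median of chi-square(1).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

#: Median of the chi-square(1) distribution; the conventional 3-decimal
#: rounding 0.455 is used in reports.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclasses.dataclass
class FdrResult:
    q: float
    m: int
    significant: np.ndarray      # boolean mask aligned with the input order
    p_threshold: float           # NaN when nothing is significant
    adjusted_p: np.ndarray

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def bh_fdr(p: np.ndarray, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up procedure at FDR level ``q``.

    Markers are ranked by ascending p; the highest rank k with
    p_(k) < q*k/m is found and all markers at ranks <= k are declared
    significant.  ``p_threshold`` is the largest significant p-value.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if np.isnan(p).any():
        raise ValueError("NaN p-values not allowed")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    passing = p[order] < q * ranks / m
    k = np.max(np.flatnonzero(passing)) + 1 if passing.any() else 0
    significant = np.zeros(m, dtype=bool)
    significant[order[:k]] = True
    p_threshold = float(p[order[k - 1]]) if k else float("nan")
    adjusted = np.minimum.accumulate((p[order] * m / ranks)[::-1])[::-1]
    adjusted_p = np.empty(m)
    adjusted_p[order] = np.minimum(adjusted, 1.0)
    return FdrResult(q=q, m=m, significant=significant,
                     p_threshold=p_threshold, adjusted_p=adjusted_p)


def fdr_at_threshold(p: np.ndarray, threshold: float) -> float:
    """Estimated FDR of declaring all p <= threshold significant:
    threshold * m / #{p <= threshold}.  Diagnostic companion to
    :func:`bh_fdr` for reporting the FDR a working threshold implies."""
    p = np.asarray(p, dtype=float)
    n_sig = int(np.sum(p <= threshold))
    if n_sig == 0:
        return float("nan")
    return float(min(1.0, threshold * p.size / n_sig))


@dataclasses.dataclass
class LambdaEstimate:
    lam: float
    n_tests: int
    mode: str = "plain"                  # "plain" | "decomposed"
    components: tuple | None = None      # (lambda_fe, lambda_het) if decomposed


def genomic_lambda(p: np.ndarray | None = None, chi2: np.ndarray | None = None,
                   components: tuple | None = None) -> LambdaEstimate:
    """Genomic inflation factor.

    Plain mode: lambda = median(chi2) / 0.455 (exact chi-square(1) median
    internally), with chi2 obtained from two-sided p-values if not given.
    Decomposed mode (``components=(s_fe, s_het)``): lambda is the sum of
    the component lambdas, each computed the same way -- the convention
    used for the heterogeneity-aware random-effects scan.
    """
    if components is not None:
        s_fe, s_het = components
        lam_fe = float(np.median(np.asarray(s_fe, dtype=float)) / CHI2_1_MEDIAN)
        lam_het = float(np.median(np.asarray(s_het, dtype=float)) / CHI2_1_MEDIAN)
        n = len(np.asarray(s_fe))
        _warn_small(n)
        return LambdaEstimate(lam=lam_fe + lam_het, n_tests=n,
                              mode="decomposed", components=(lam_fe, lam_het))
    if chi2 is None:
        if p is None:
            raise ValueError("provide p, chi2 or components")
        p = np.asarray(p, dtype=float)
        if p.size == 0:
            raise ValueError("empty input")
        chi2 = stats.chi2.isf(p, df=1)
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("empty input")
    _warn_small(chi2.size)
    return LambdaEstimate(lam=float(np.median(chi2) / CHI2_1_MEDIAN),
                          n_tests=chi2.size)


def _warn_small(n: int) -> None:
    if n < 30:
        warnings.warn(f"lambda estimated from only {n} tests is unstable")


def lambda_flag(estimate: LambdaEstimate) -> str:
    """'confounded' for lambda strictly above 1.1, else 'ok'."""
    return "confounded" if estimate.lam > 1.1 else "ok"
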