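"""Independent brute-force / closed-form oracles used by the tests.

Deliberately naive implementations, kept free of any code path they check.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational HWE test by enumerating every genotype table with the
    observed allele counts."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa
    n_b = 2 * n_aa + n_Aa
    if n_a == 0 or n_b == 0:
        return 1.0
    configs = []
    for k in range(n_Aa % 2, min(n_a, n_b) + 1, 2):
        hom1 = (n_a - k) // 2
        hom2 = (n_b - k) // 2
        # ways to assign genotypes x ways to order alleles within hets
        w = Fraction(comb(n, hom1) * comb(n - hom1, k) * (2 ** k))
        configs.append((k, w))
    total = sum(w for _, w in configs)
    probs = {k: w / total for k, w in configs}
    p_obs = probs[n_Aa]
    return float(sum(pr for pr in probs.values() if pr <= p_obs))


def bh_stepup_sets(p: np.ndarray, q: float) -> np.ndarray:
    """Step-up rejection set by scanning every rank explicitly."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] < q * k / m:
            best_k = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:best_k]] = True
    return mask


def greedy_clump(p, chrom, bp, r2, p1, r2_min, kb_max):
    """Literal greedy clumping: repeatedly take the smallest-p unassigned
    significant SNP, sweep in correlated significant neighbours."""
    m = len(p)
    unassigned = [i for i in range(m) if p[i] <= p1]
    clumps = []
    while unassigned:
        lead = min(unassigned, key=lambda i: (p[i], chrom[i], bp[i]))
        members = [i for i in unassigned if i != lead
                   and chrom[i] == chrom[lead]
                   and abs(bp[i] - bp[lead]) <= kb_max * 1000
                   and r2[lead, i] >= r2_min]
        clumps.append((lead, members))
        for i in [lead] + members:
            unassigned.remove(i)
    return clumps


def ivw_literal(b, se):
    """Direct transcription of the fixed-effects formulas."""
    b = np.asarray(b, dtype=float)
    w = 1.0 / np.asarray(se, dtype=float) ** 2
    beta = np.sum(b * w) / np.sum(w)
    v = 1.0 / np.sum(w)
    q = np.sum(w * (b - beta) ** 2)
    n = len(b)
    i2 = 0.0 if q == 0 else max(0.0, (q - (n - 1)) / q * 100)
    return beta, v, beta ** 2 / v, q, i2


def dl_tau2_literal(b, se):
    b = np.asarray(b, dtype=float)
    w = 1.0 / np.asarray(se, dtype=float) ** 2
    _, _, _, q, _ = ivw_literal(b, se)
    n = len(b)
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    return max(0.0, (q - (n - 1)) / denom)


def random_effects_literal(b, se, tau2=None):
    """Direct transcription of the decomposed random-effects statistic."""
    b = np.asarray(b, dtype=float)
    v = np.asarray(se, dtype=float) ** 2
    beta, _, _, _, _ = ivw_literal(b, se)
    if tau2 is None:
        tau2 = dl_tau2_literal(b, se)
    w_star = 1.0 / (tau2 + v)
    beta_star = np.sum(b * w_star) / np.sum(w_star)
    s_fe = np.sum(b ** 2 / v) - np.sum((b - beta) ** 2 / v)
    s_het = (np.sum(np.log(v / (v + tau2)))
             + np.sum((b - beta) ** 2 / v)
             - np.sum((b - beta_star) ** 2 / (v + tau2)))
    return s_fe, s_het, s_fe + s_het, beta_star


def stouffer_literal(p, sign, n):
    """Direct transcription of the sample-size-weighted Z combination."""
    from scipy import stats
    z = stats.norm.isf(np.asarray(p) / 2.0) * np.asarray(sign)
    w = np.sqrt(np.asarray(n, dtype=float))
    zc = np.sum(z * w) / np.sqrt(np.sum(w ** 2))
    return zc, 2 * stats.norm.sf(abs(zc))


def ols_scan(y, X, genotypes):
    """Per-SNP ordinary least squares of y on [X, x_k]; returns effect sizes."""
    y = np.asarray(y, dtype=float)
    b = np.empty(genotypes.shape[1])
    for k in range(genotypes.shape[1]):
        design = np.column_stack([X, genotypes[:, k]])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        b[k] = coef[-1]
    return b
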