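"""Meta-analysis of per-population GWAS summary statistics.

Three estimators, all operating on allele-harmonized per-population
association tables:

* **Stouffer Z-score** — combines signed z-scores with square-root-of-n
  weights: Z = sum(Z_ij sqrt(n_ij)) / sqrt(sum n_ij).
* **Inverse-variance weighted (IVW)** fixed effects — beta_j =
  sum(w b) / sum(w) with w = 1/SE^2, plus Cochran's Q and the I^2
  heterogeneity index.
* **Heterogeneity-aware random effects** (Han-Eskin) — test statistic
  S_rand = S_FE + S_Het with the DerSimonian-Laird between-population
  variance tau^2; S_FE equals the IVW chi-square.

The z -> (b, SE) conversion (b = z / sqrt(2p(1-p)(n+z^2))) supplies effect
sizes for methods that only produce z-scores, so their output can feed
summary-statistic secondary-signal analyses.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_TINY_P = float(np.finfo(float).tiny)

I2_BANDS = ((25, "none"), (50, "moderate"), (75, "high"), (np.inf, "very high"))


def classify_i2(i2: float) -> str:
    """Heterogeneity band for an I^2 value: <25 none, 25-50 moderate,
    50-75 high, >75 very high."""
    for bound, label in I2_BANDS:
        if i2 < bound or bound is np.inf:
            return label
    return "very high"


@dataclasses.dataclass
class HarmonizedTable:
    """Per-SNP summary statistics aligned to a common effect allele.

    Arrays have shape (n_snps, n_studies) with NaN marking a SNP absent
    from a study.
    """

    info: pd.DataFrame          # SNP CHR BP A1 A2 (reference alleles)
    b: np.ndarray
    se: np.ndarray
    p: np.ndarray
    z: np.ndarray
    n: np.ndarray
    freq: np.ndarray
    n_dropped: int = 0

    @property
    def n_studies_per_snp(self) -> np.ndarray:
        return np.sum(~np.isnan(self.b), axis=1)

    def directions(self) -> np.ndarray:
        sym = np.where(np.isnan(self.b), "?", np.where(self.b >= 0, "+", "-"))
        return np.array(["".join(row) for row in sym])


def harmonize(tables: list[pd.DataFrame]) -> HarmonizedTable:
    """Align a list of association tables to the first table's effect allele.

    Tables with swapped A1/A2 have b and z negated and freq reflected;
    SNPs whose allele pairs cannot be reconciled are dropped (counted in
    ``n_dropped``).  SNPs present in a subset of studies are carried with
    NaN in the absent studies.
    """
    if not tables:
        raise ValueError("no tables to harmonize")
    keyed = []
    for t in tables:
        if t["SNP"].duplicated().any():
            dupes = t.loc[t["SNP"].duplicated(), "SNP"].head().tolist()
            raise ValueError(f"duplicate SNP ids within a table: {dupes}")
        keyed.append(t.set_index("SNP"))

    ref = keyed[0]
    all_snps = ref.index
    for t in keyed[1:]:
        all_snps = all_snps.union(t.index, sort=False)
    # reference alleles come from the first table that carries each SNP
    info = pd.DataFrame(index=all_snps, columns=["CHR", "BP", "A1", "A2"])
    for t in keyed:
        fill = info["A1"].isna() & info.index.isin(t.index)
        idx = info.index[fill]
        info.loc[idx, ["CHR", "BP", "A1", "A2"]] = t.loc[idx, ["CHR", "BP", "A1", "A2"]].values

    k, s = len(all_snps), len(keyed)
    arrs = {f: np.full((k, s), np.nan) for f in ("b", "se", "p", "z", "n", "freq")}
    dropped = np.zeros(k, dtype=bool)
    a1 = info["A1"].to_numpy()
    a2 = info["A2"].to_numpy()
    for j, t in enumerate(keyed):
        sub = t.reindex(all_snps)
        present = ~sub["A1"].isna().to_numpy()
        same = present & (sub["A1"].to_numpy() == a1) & (sub["A2"].to_numpy() == a2)
        swap = present & (sub["A1"].to_numpy() == a2) & (sub["A2"].to_numpy() == a1)
        bad = present & ~same & ~swap
        dropped |= bad
        sign = np.where(swap, -1.0, 1.0)
        flip = np.where(swap, 1.0, 0.0)
        use = same | swap
        arrs["b"][use, j] = (sign * sub["B"].to_numpy())[use]
        arrs["z"][use, j] = (sign * sub["Z"].to_numpy())[use]
        arrs["freq"][use, j] = (flip + sign * sub["FREQ"].to_numpy())[use]
        for f, c in (("se", "SE"), ("p", "P"), ("n", "N")):
            arrs[f][use, j] = sub[c].to_numpy()[use]
    if dropped.any():
        logger.info("harmonize: dropped %d SNPs with irreconcilable alleles",
                    int(dropped.sum()))
    keep = ~dropped
    info = info.loc[keep].reset_index(names="SNP")
    return HarmonizedTable(
        info=info, n_dropped=int(dropped.sum()),
        **{f: a[keep] for f, a in arrs.items()},
    )


# ----------------------------------------------------------------------
# estimators; all accept (n_snps, n_studies) arrays with NaN = absent


def stouffer_z(p: np.ndarray, b: np.ndarray, n: np.ndarray):
    """Sample-size-weighted Z-score meta-analysis.

    Z_ij = Phi^-1(1 - p_ij/2) * sign(b_ij); Z = sum(Z_ij w_ij) /
    sqrt(sum w_ij^2) with w_ij = sqrt(n_ij); p = 2 Phi(-|Z|).
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n = np.atleast_2d(np.asarray(n, dtype=float))
    if np.any(p == 0):
        logger.info("stouffer_z: clamping %d zero p-values", int(np.sum(p == 0)))
        p = np.where(p == 0, _TINY_P, p)
    z_ij = stats.norm.isf(p / 2.0) * np.sign(b)
    w = np.sqrt(n)
    num = np.nansum(z_ij * w, axis=1)
    den = np.sqrt(np.nansum(np.where(np.isnan(z_ij), np.nan, w) ** 2, axis=1))
    z = num / den
    return z, 2 * stats.norm.sf(np.abs(z))


def ivw(b: np.ndarray, se: np.ndarray):
    """IVW fixed-effects meta-analysis with Cochran's Q and I^2.

    Returns (beta, V, chi2, p, Q, I2); I2 is truncated to [0, 100] and is
    0 when Q = 0 or a single study contributes.
    """
    b = np.atleast_2d(np.asarray(b, dtype=float))
    se = np.atleast_2d(np.asarray(se, dtype=float))
    if np.any(se[~np.isnan(se)] <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se ** 2
    sw = np.nansum(w, axis=1)
    beta = np.nansum(w * b, axis=1) / sw
    v = 1.0 / sw
    chi2 = beta ** 2 / v
    p = stats.chi2.sf(chi2, df=1)
    q = np.nansum(w * (b - beta[:, None]) ** 2, axis=1)
    n_st = np.sum(~np.isnan(b), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where((q > 0) & (n_st >= 2),
                      (q - (n_st - 1)) / np.where(q > 0, q, 1) * 100, 0.0)
    i2 = np.clip(i2, 0.0, 100.0)
    return beta, v, chi2, p, q, i2


def dl_tau2(b: np.ndarray, se: np.ndarray, q: np.ndarray | None = None) -> np.ndarray:
    """DerSimonian-Laird between-study variance:
    tau^2 = max(0, (Q - (N-1)) / (sum w - sum w^2 / sum w))."""
    b = np.atleast_2d(np.asarray(b, dtype=float))
    se = np.atleast_2d(np.asarray(se, dtype=float))
    if q is None:
        q = ivw(b, se)[4]
    q = np.atleast_1d(np.asarray(q, dtype=float))
    w = 1.0 / se ** 2
    sw = np.nansum(w, axis=1)
    denom = sw - np.nansum(w ** 2, axis=1) / sw
    n_st = np.sum(~np.isnan(b), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau2 = np.where(denom > 0, (q - (n_st - 1)) / denom, 0.0)
    tau2 = np.where(n_st < 2, 0.0, np.maximum(tau2, 0.0))
    return tau2


def han_eskin(b: np.ndarray, se: np.ndarray, tau2: np.ndarray | None = None):
    """Heterogeneity-aware random-effects statistic S_rand = S_FE + S_Het.

    S_FE = sum b^2/V - sum (b - beta)^2/V    (equals the IVW chi-square)
    S_Het = sum log(V/(V+tau^2)) + sum (b-beta)^2/V - sum (b-beta*)^2/(V+tau^2)
    beta* = sum(b w*) / sum(w*), w* = 1/(V + tau^2)

    The p-value uses the boundary-LRT asymptotic null, an equal mixture of
    chi-square(1) and chi-square(2).
    Returns (s_fe, s_het, s_rand, beta_star, p_rand).
    """
    b = np.atleast_2d(np.asarray(b, dtype=float))
    se = np.atleast_2d(np.asarray(se, dtype=float))
    v = se ** 2
    beta, _, _, _, q, _ = ivw(b, se)
    if tau2 is None:
        tau2 = dl_tau2(b, se, q)
    tau2 = np.atleast_1d(np.asarray(tau2, dtype=float))
    if np.any(tau2 < 0):
        raise ValueError("tau2 must be pre-truncated at 0")
    w_star = 1.0 / (v + tau2[:, None])
    beta_star = np.nansum(b * w_star, axis=1) / np.nansum(w_star, axis=1)
    dev = (b - beta[:, None]) ** 2 / v
    s_fe = np.nansum(b ** 2 / v, axis=1) - np.nansum(dev, axis=1)
    s_het = (np.nansum(np.log(v * w_star), axis=1)
             + np.nansum(dev, axis=1)
             - np.nansum((b - beta_star[:, None]) ** 2 * w_star, axis=1))
    s_rand = s_fe + s_het
    s_clip = np.maximum(s_rand, 0.0)
    p_rand = 0.5 * stats.chi2.sf(s_clip, df=1) + 0.5 * stats.chi2.sf(s_clip, df=2)
    return s_fe, s_het, s_rand, beta_star, p_rand


def mc_rand_null(se: np.ndarray, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded Monte-Carlo sample of S_rand under the null (b_ij drawn
    N(0, V_ij)), for empirical calibration of p_rand at small study counts."""
    se = np.atleast_2d(np.asarray(se, dtype=float))
    out = np.empty(n_sims)
    for i in range(n_sims):
        b0 = rng.normal(scale=np.where(np.isnan(se), 1.0, se))
        b0 = np.where(np.isnan(se), np.nan, b0)
        out[i] = han_eskin(b0, se)[2][0]
    return out


def z_to_beta_se(z, freq, n):
    """Effect size and SE from a z-score:
    b = z / sqrt(2p(1-p)(n + z^2)), SE = 1 / sqrt(2p(1-p)(n + z^2));
    b/SE = z holds exactly."""
    z = np.asarray(z, dtype=float)
    freq = np.asarray(freq, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((freq <= 0) | (freq >= 1)):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    root = np.sqrt(2 * freq * (1 - freq) * (n + z ** 2))
    return z / root, 1.0 / root


# ----------------------------------------------------------------------

META_METHODS = ("zscore", "ivw", "random")


def run_meta(tables: list[pd.DataFrame], method: str = "ivw",
             q_alpha: float = 0.10) -> pd.DataFrame:
    """Harmonize and combine per-population tables with all estimators.

    The ``method`` argument selects which estimator's p-value (and effect
    size) populates the generic P/B/SE columns consumed downstream; all
    estimator-specific columns are always present.  ``q_sig`` flags SNPs
    whose Cochran's Q is significant at ``q_alpha`` on chi-square(N-1).
    """
    if method not in META_METHODS:
        raise ValueError(f"method must be one of {META_METHODS}")
    if len(tables) < 2:
        raise ValueError("meta-analysis needs at least 2 tables")
    h = harmonize(tables)
    if len(h.info) == 0:
        raise ValueError("no overlapping SNPs after harmonization")
    z, p_z = stouffer_z(h.p, h.b, h.n)
    beta, v, chi2, p_ivw, q, i2 = ivw(h.b, h.se)
    tau2 = dl_tau2(h.b, h.se, q)
    s_fe, s_het, s_rand, beta_star, p_rand = han_eskin(h.b, h.se, tau2)

    n_st = h.n_studies_per_snp
    n_tot = np.nansum(h.n, axis=1)
    df_q = np.maximum(n_st - 1, 0)
    p_q = np.where(df_q > 0, stats.chi2.sf(q, df=np.maximum(df_q, 1)), 1.0)

    out = h.info.copy()
    out.columns = ["SNP", "CHR", "BP", "A1", "A2"]
    out["N_STUDIES"] = n_st
    out["N"] = n_tot
    out["FREQ"] = np.nansum(h.freq * h.n, axis=1) / n_tot  # n-weighted mean
    out["Z_META"] = z
    out["P_ZSCORE"] = p_z
    out["BETA_IVW"] = beta
    out["SE_IVW"] = np.sqrt(v)
    out["P_IVW"] = p_ivw
    out["Q"] = q
    out["DF_Q"] = df_q
    out["P_Q"] = p_q
    out["Q_SIG"] = p_q < q_alpha
    out["I2"] = i2
    out["I2_BAND"] = [classify_i2(x) for x in i2]
    out["TAU2"] = tau2
    out["BETA_RE"] = beta_star
    out["S_FE"] = s_fe
    out["S_HET"] = s_het
    out["S_RAND"] = s_rand
    out["P_RAND"] = p_rand
    out["DIRECTIONS"] = h.directions()

    if method == "zscore":
        b_z, se_z = z_to_beta_se(z, out["FREQ"].to_numpy(), n_tot)
        out["B"], out["SE"], out["P"] = b_z, se_z, p_z
    elif method == "ivw":
        out["B"], out["SE"], out["P"] = beta, np.sqrt(v), p_ivw
    else:
        out["B"], out["SE"], out["P"] = beta_star, np.sqrt(v), p_rand
    out["Z"] = out["B"] / out["SE"]
    return out


def meta_to_assoc(meta: pd.DataFrame) -> pd.DataFrame:
    """Project a meta table onto the standard association-table columns so
    it can feed summary-statistic secondary-signal methods."""
    return meta[["SNP", "CHR", "BP", "A1", "A2", "FREQ", "B", "SE", "Z", "P", "N"]].copy()
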