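"""Secondary-signal identification from summary statistics.

Two summary-statistic methods that need only an association table and a
reference genotype panel for LD:

* **Approximate conditional and joint analysis (COJO)** — stepwise model
  selection on summary statistics using least-squares identities with
  reference-panel LD correlations.  Markers farther apart than the window
  (default 100 Mb) or on different chromosomes are treated as being in
  linkage equilibrium; a candidate whose squared correlation with any
  selected SNP exceeds the collinearity bound has its conditional p-value
  set to 1 and can never enter.
* **Clumping** — greedy grouping of significant SNPs around lead variants
  by p-value, LD r^2 and physical distance (the PLINK clump rule).

LD r^2 is the squared Pearson correlation of genotype dosages in the
reference panel.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .mlm import QtlRegion
from .panel import MISSING, GenotypePanel


@dataclasses.dataclass
class CojoConfig:
    p_threshold: float
    collinearity_r2: float = 0.05
    window_bp: int = 100_000_000
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not 0 < self.collinearity_r2 <= 1:
            raise ValueError("collinearity_r2 must lie in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclasses.dataclass
class ClumpConfig:
    p1: float
    r2_min: float = 0.05
    kb_max: float = 5000.0

    def __post_init__(self) -> None:
        if not 0 < self.p1 < 1:
            raise ValueError("p1 must lie in (0, 1)")
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must lie in [0, 1]")
        if self.kb_max <= 0:
            raise ValueError("kb_max must be positive")


@dataclasses.dataclass
class SignalSet:
    """Selected lead SNPs with joint estimates (COJO) or clump membership."""

    snp_ids: list
    method: str
    joint: pd.DataFrame | None = None      # COJO: snp, chr, bp, a1, freq, b_marginal, b_joint, se_joint, p_joint
    clumps: dict | None = None             # clumping: lead snp -> list of member snps

    @property
    def n_qtl(self) -> int:
        return len(self.snp_ids)


class _Reference:
    """Centered reference genotypes with cached column norms."""

    def __init__(self, panel: GenotypePanel):
        if np.any(panel.genotypes == MISSING):
            raise ValueError("reference panel must be complete (imputed)")
        g = panel.genotypes.astype(float)
        self.x = g - g.mean(axis=0)
        self.norm = np.sqrt(np.sum(self.x ** 2, axis=0))
        self.var = np.var(g, axis=0)
        self.panel = panel

    def corr(self, k: int) -> np.ndarray:
        """Correlation of SNP k with every SNP (0 where either is constant)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (self.x.T @ self.x[:, k]) / (self.norm * self.norm[k])
        return np.nan_to_num(r)


def _align_to_reference(assoc: pd.DataFrame, panel: GenotypePanel) -> pd.DataFrame:
    """Reorder/flip an association table to the reference panel's markers
    and effect alleles; drops SNPs absent from the panel."""
    ref = pd.DataFrame({
        "SNP": panel.snp_ids, "a1_ref": panel.a1, "a2_ref": panel.a2,
        "order": np.arange(panel.n_snps),
    })
    df = assoc.merge(ref, on="SNP", how="inner").sort_values("order")
    same = (df["A1"] == df["a1_ref"]) & (df["A2"] == df["a2_ref"])
    swap = (df["A1"] == df["a2_ref"]) & (df["A2"] == df["a1_ref"])
    bad = ~(same | swap)
    if bad.any():
        raise ValueError(
            f"allele mismatch with reference for {df.loc[bad, 'SNP'].head().tolist()};"
            " harmonize first")
    sign = np.where(swap, -1.0, 1.0)
    df["B"] = df["B"] * sign
    df["Z"] = df["Z"] * sign
    df["FREQ"] = np.where(swap, 1 - df["FREQ"], df["FREQ"])
    df["A1"] = df["a1_ref"]
    df["A2"] = df["a2_ref"]
    return df.drop(columns=["a1_ref", "a2_ref"]).reset_index(drop=True)


def _pick(p: np.ndarray, b: np.ndarray, chrom: np.ndarray, bp: np.ndarray,
          candidates: np.ndarray) -> int:
    """Deterministic choice among candidates: min p, then max |b|, then
    lowest (chrom, bp)."""
    order = np.lexsort((bp[candidates], chrom[candidates],
                        -np.abs(b[candidates]), p[candidates]))
    return int(candidates[order[0]])


def cojo_select(assoc: pd.DataFrame, reference: GenotypePanel,
                cfg: CojoConfig) -> SignalSet:
    """Stepwise approximate conditional and joint selection.

    Summary statistics are combined with reference-panel LD through the
    least-squares normal equations: with D_k = n_k * var(x_k) the diagonal
    of X'X, off-diagonals are r_kl * sqrt(D_k D_l) (zero beyond the window),
    X'y_k = D_k b_k, and y'y is estimated per SNP from b_k, SE_k and n_k
    (median across SNPs).  Conditional effects and p-values follow from
    block inversion; selected sets are refitted jointly each step.
    """
    df = _align_to_reference(assoc, reference)
    df = df.dropna(subset=["B", "SE", "P"]).reset_index(drop=True)
    ref = _Reference(reference.subset(snps=np.isin(reference.snp_ids, df["SNP"])))
    m = len(df)
    p = df["P"].to_numpy()
    b = df["B"].to_numpy()
    se = df["SE"].to_numpy()
    n = df["N"].to_numpy(dtype=float)
    chrom = df["CHR"].to_numpy()
    bp = df["BP"].to_numpy(dtype=np.int64)

    d_k = n * ref.var
    xty = d_k * b
    yty = float(np.median(d_k * b ** 2 + d_k * se ** 2 * (n - 1)))
    n_eff = float(np.median(n))

    sig0 = np.flatnonzero(p <= cfg.p_threshold)
    if sig0.size == 0:
        return SignalSet(snp_ids=[], method="cojo",
                         joint=_cojo_frame(df, [], None, None, None))
    selected = [_pick(p, b, chrom, bp, sig0)]

    def window_r(k: int) -> np.ndarray:
        r = ref.corr(k)
        far = (chrom != chrom[k]) | (np.abs(bp - bp[k]) > cfg.window_bp)
        r[far] = 0.0
        return r

    def joint_fit(idx: list):
        """Joint LS of the selected set; returns (b_joint, se_joint, p_joint,
        sigma2, A_inv, rs) where rs[k] is the window-masked correlation row."""
        rs = np.array([window_r(k) for k in idx])            # (s, m)
        a = rs[:, idx] * np.sqrt(np.outer(d_k[idx], d_k[idx]))
        np.fill_diagonal(a, d_k[idx])
        a_inv = np.linalg.inv(a)
        bj = a_inv @ xty[idx]
        dof = max(n_eff - len(idx) - 1, 1.0)
        sigma2 = max((yty - bj @ xty[idx]) / dof, 1e-12)
        sej = np.sqrt(sigma2 * np.diag(a_inv))
        pj = stats.chi2.sf((bj / sej) ** 2, df=1)
        return bj, sej, pj, sigma2, a_inv, rs

    for _ in range(cfg.max_iter):
        changed = False
        bj, sej, pj, sigma2, a_inv, rs = joint_fit(selected)

        # conditional p-values of all non-selected SNPs given the model
        a_cs = (rs * np.sqrt(d_k[selected])[:, None]).T * np.sqrt(d_k)[:, None]
        t = a_inv @ xty[selected]
        num = xty - a_cs @ t
        den = d_k - np.einsum("ij,jk,ik->i", a_cs, a_inv, a_cs)
        with np.errstate(invalid="ignore", divide="ignore"):
            b_cond = num / den
            se_cond = np.sqrt(sigma2 / den)
        p_cond = np.where(den > 1e-8 * d_k,
                          stats.chi2.sf((b_cond / se_cond) ** 2, df=1), 1.0)
        # collinearity rule: r^2 with any selected SNP at/above the bound
        max_r2 = (rs ** 2).max(axis=0)
        p_cond = np.where(max_r2 >= cfg.collinearity_r2, 1.0, p_cond)
        p_cond[selected] = 1.0

        cand = np.flatnonzero(p_cond <= cfg.p_threshold)
        if cand.size:
            selected.append(_pick(p_cond, b_cond, chrom, bp, cand))
            changed = True
            bj, sej, pj, sigma2, a_inv, rs = joint_fit(selected)

        # drop the largest-p non-significant member of the joint model
        worst = int(np.argmax(pj))
        if len(selected) > 1 and pj[worst] > cfg.p_threshold:
            del selected[worst]
            changed = True
        if not changed:
            break

    bj, sej, pj, _, _, _ = joint_fit(selected)
    return SignalSet(
        snp_ids=[str(df["SNP"].iloc[k]) for k in selected],
        method="cojo",
        joint=_cojo_frame(df, selected, bj, sej, pj),
    )


def _cojo_frame(df: pd.DataFrame, idx: list, bj, sej, pj) -> pd.DataFrame:
    out = df.iloc[list(idx)][["SNP", "CHR", "BP", "A1", "FREQ", "B"]].copy()
    out = out.rename(columns={"B": "B_MARGINAL"})
    out["B_JOINT"] = bj if len(idx) else []
    out["SE_JOINT"] = sej if len(idx) else []
    out["P_JOINT"] = pj if len(idx) else []
    return out.reset_index(drop=True)


def clump(assoc: pd.DataFrame, reference: GenotypePanel,
          cfg: ClumpConfig) -> SignalSet:
    """Greedy clump formation around lead variants.

    Repeatedly takes the most significant unassigned SNP with p <= p1 as a
    lead and assigns to its clump every unassigned SNP with p <= p1,
    r^2 >= r2_min with the lead, and distance <= kb_max (same chromosome,
    boundary inclusive); iterates until no significant SNP remains.
    """
    df = _align_to_reference(assoc, reference)
    df = df.dropna(subset=["P"]).reset_index(drop=True)
    ref = _Reference(reference.subset(snps=np.isin(reference.snp_ids, df["SNP"])))
    p = df["P"].to_numpy()
    b = df["B"].to_numpy()
    chrom = df["CHR"].to_numpy()
    bp = df["BP"].to_numpy(dtype=np.int64)

    unassigned = p <= cfg.p1
    leads, clumps = [], {}
    while unassigned.any():
        lead = _pick(p, b, chrom, bp, np.flatnonzero(unassigned))
        r2 = ref.corr(lead) ** 2
        members = (unassigned & (chrom == chrom[lead])
                   & (np.abs(bp - bp[lead]) <= cfg.kb_max * 1000)
                   & (r2 >= cfg.r2_min))
        members[lead] = False
        lead_id = str(df["SNP"].iloc[lead])
        leads.append(lead_id)
        clumps[lead_id] = [str(s) for s in df["SNP"].iloc[np.flatnonzero(members)]]
        unassigned[members] = False
        unassigned[lead] = False
    return SignalSet(snp_ids=leads, method="clumping", clumps=clumps)


def qtl_intervals(signals: SignalSet, assoc: pd.DataFrame, threshold: float,
                  reference: GenotypePanel | None = None,
                  window_bp: int = 100_000_000) -> list[QtlRegion]:
    """QTL interval per lead: the span of significant SNPs attributed to it.

    Clump members come from the clump structure; for COJO each significant
    SNP is attributed to the same-chromosome selected SNP with the highest
    reference r^2 (nearest lead when no reference is given).  A lead with
    no members yields a zero-length region at the lead.
    """
    if not signals.snp_ids:
        return []
    loc = assoc.set_index("SNP")
    regions = []
    if signals.clumps is not None:
        for lead in signals.snp_ids:
            member_bp = [int(loc.loc[s, "BP"]) for s in signals.clumps[lead]
                         if float(loc.loc[s, "P"]) <= threshold]
            member_bp.append(int(loc.loc[lead, "BP"]))
            regions.append(QtlRegion(
                chrom=int(loc.loc[lead, "CHR"]), start_bp=min(member_bp),
                end_bp=max(member_bp), lead_snp=lead, method=signals.method))
        return regions

    sig = assoc[assoc["P"] <= threshold]
    lead_chrom = {lead: int(loc.loc[lead, "CHR"]) for lead in signals.snp_ids}
    lead_bp = {lead: int(loc.loc[lead, "BP"]) for lead in signals.snp_ids}
    r2_to_lead = {}
    if reference is not None:
        ref = _Reference(reference)
        snp_pos = pd.Index(reference.snp_ids)
        for lead in signals.snp_ids:
            k = snp_pos.get_loc(lead)
            r2_to_lead[lead] = pd.Series(ref.corr(k) ** 2, index=reference.snp_ids)
    members: dict = {lead: [lead_bp[lead]] for lead in signals.snp_ids}
    for _, row in sig.iterrows():
        cands = [ld for ld in signals.snp_ids
                 if lead_chrom[ld] == int(row["CHR"])
                 and abs(lead_bp[ld] - int(row["BP"])) <= window_bp]
        if not cands:
            continue
        if r2_to_lead and all(row["SNP"] in r2_to_lead[ld].index for ld in cands):
            best = max(cands, key=lambda ld: float(r2_to_lead[ld].get(row["SNP"], 0.0)))
        else:
            best = min(cands, key=lambda ld: abs(lead_bp[ld] - int(row["BP"])))
        members[best].append(int(row["BP"]))
    for lead in signals.snp_ids:
        bps = members[lead]
        regions.append(QtlRegion(
            chrom=lead_chrom[lead], start_bp=min(bps), end_bp=max(bps),
            lead_snp=lead, method=signals.method))
    return regions
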