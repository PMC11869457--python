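"""Mixed-linear-model association within and across populations.

The association model for a quantitative (here: ordinal-scored, analysed as
linear) trait is

    y = 1*mu + x*b + Z*u + e,   u ~ N(0, G sigma_u^2),  e ~ N(0, I sigma_e^2)

with G the VanRaden method-1 genomic relationship matrix.  Variance
components are estimated once by REML under the null (no candidate SNP) and
held fixed for the per-SNP generalized-least-squares scan, following the
standard MLMA convention.  The mega-analysis is the same scan on the pooled
panel with a fixed effect of population.  Conditional association analysis
iteratively refits the scan with the current lead significant SNP added as
a covariate until no significant SNP remains.

Everything is computed in the eigenbasis of G: after rotating by the
eigenvectors, V = sigma_u^2 G + sigma_e^2 I is diagonal, so REML is a 1-D
optimisation in the variance ratio and the scan is a set of weighted
least-squares problems solved in closed form for all SNPs at once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import MISSING, GenotypePanel, PhenotypeTable

#: Diagonal jitter added to G before factorisation, for numerical stability.
GRM_JITTER = 1e-6

ASSOC_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "B", "SE", "Z", "P", "N"]


@dataclasses.dataclass
class Grm:
    """Genomic relationship matrix with its (lazy) eigendecomposition."""

    matrix: np.ndarray
    sample_ids: np.ndarray
    method: str = "vanraden1"
    _eig: tuple | None = dataclasses.field(default=None, repr=False)
    _rot_cache: dict = dataclasses.field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.sample_ids):
            raise ValueError("GRM must be square and match sample_ids")
        if not np.isfinite(m).all():
            raise ValueError("GRM has non-finite entries")
        if np.abs(m - m.T).max() > 1e-10:
            raise ValueError("GRM not symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues/vectors of G + jitter*I (cached)."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.matrix + GRM_JITTER * np.eye(self.n))
            self._eig = (vals, vecs)
        return self._eig

    def rotate_genotypes(self, panel: GenotypePanel) -> np.ndarray:
        """U' @ genotypes, cached per panel (panels are treated as frozen);
        lets repeated scans against the same GRM skip the large rotation."""
        key = id(panel)
        if key not in self._rot_cache:
            _, u = self.eig()
            self._rot_cache[key] = u.T @ panel.genotypes.astype(float)
        return self._rot_cache[key]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")

    def to_gcta_bin(self, prefix, n_snps: int) -> None:
        """GCTA-compatible binary triple: grm.bin (float32 lower triangle,
        row-major), grm.N.bin (marker counts per pair), grm.id."""
        import pathlib
        prefix = pathlib.Path(prefix)
        tril = self.matrix[np.tril_indices(self.n)]
        tril.astype(np.float32).tofile(f"{prefix}.grm.bin")
        np.full(tril.size, n_snps, dtype=np.float32).tofile(f"{prefix}.grm.N.bin")
        pd.DataFrame({"fid": self.sample_ids, "iid": self.sample_ids}).to_csv(
            f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_gcta_grm(prefix) -> Grm:
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)[1].to_numpy(str)
    n = len(ids)
    tril = np.fromfile(f"{prefix}.grm.bin", dtype=np.float32).astype(float)
    m = np.zeros((n, n))
    m[np.tril_indices(n)] = tril
    m = m + m.T - np.diag(np.diag(m))
    return Grm(matrix=m, sample_ids=ids)


def compute_grm(panel: GenotypePanel) -> Grm:
    """VanRaden method-1 GRM: G = W W' / (2 sum_k p_k (1 - p_k)), with
    W the genotype matrix centred by twice the pooled allele frequency."""
    g = panel.genotypes
    if np.any(g == MISSING):
        raise ValueError("GRM requires a complete (imputed) panel")
    p = g.mean(axis=0) / 2.0
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        raise ValueError(
            f"monomorphic SNPs in GRM input: {panel.snp_ids[mono][:5].tolist()}")
    w = g.astype(float) - 2 * p
    denom = 2 * np.sum(p * (1 - p))
    return Grm(matrix=(w @ w.T) / denom, sample_ids=panel.sample_ids)


def population_summaries(grm: Grm, labels: np.ndarray,
                         panel: GenotypePanel | None = None):
    """Between/within-population mean relationships, plus Nei's standard
    genetic distance between populations if a panel is supplied.

    Returns ``(mean_relationship, nei_distance)``; the second element is
    None without a panel.
    """
    labels = np.asarray(labels)
    if len(labels) != grm.n:
        raise ValueError("labels must cover all GRM samples")
    pops = pd.unique(labels)
    for pop in pops:
        if np.sum(labels == pop) < 2:
            raise ValueError(f"population {pop} has fewer than 2 samples")
    rel = pd.DataFrame(index=pops, columns=pops, dtype=float)
    for a in pops:
        ia = labels == a
        for b in pops:
            ib = labels == b
            block = grm.matrix[np.ix_(ia, ib)]
            if a == b:  # within-population mean over distinct pairs
                n = block.shape[0]
                rel.loc[a, b] = (block.sum() - np.trace(block)) / (n * (n - 1))
            else:
                rel.loc[a, b] = block.mean()
    dist = nei_distance(panel, labels) if panel is not None else None
    return rel, dist


def nei_distance(panel: GenotypePanel, labels: np.ndarray) -> pd.DataFrame:
    """Nei's (1972) standard genetic distance from per-population allele
    frequencies of the biallelic markers."""
    labels = np.asarray(labels)
    pops = pd.unique(labels)
    freqs = {}
    for pop in pops:
        sub = panel.genotypes[labels == pop]
        g = np.ma.masked_equal(sub, MISSING)
        freqs[pop] = np.asarray(g.mean(axis=0) / 2.0)
    out = pd.DataFrame(index=pops, columns=pops, dtype=float)
    for a in pops:
        pa, qa = freqs[a], 1 - freqs[a]
        jaa = np.sum(pa ** 2 + qa ** 2)
        for b in pops:
            pb, qb = freqs[b], 1 - freqs[b]
            jab = np.sum(pa * pb + qa * qb)
            jbb = np.sum(pb ** 2 + qb ** 2)
            out.loc[a, b] = -np.log(jab / np.sqrt(jaa * jbb))
    return out


@dataclasses.dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    loglik: float
    grm: Grm
    converged: bool = True

    @property
    def ratio(self) -> float:
        return self.sigma_u2 / self.sigma_e2 if self.sigma_e2 > 0 else np.inf

    @property
    def h2(self) -> float:
        tot = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / tot if tot > 0 else np.nan


def _restricted_loglik(log_ratio: float, d: np.ndarray, yt: np.ndarray,
                       xt: np.ndarray) -> tuple[float, float]:
    """Profile restricted log-likelihood at sigma_u^2/sigma_e^2 = e^log_ratio.

    Returns (loglik, sigma_e2_hat).  All quantities in the eigenbasis of G,
    so V = sigma_e^2 * diag(ratio*d + 1).
    """
    n, p = xt.shape
    w = np.exp(log_ratio) * d + 1.0
    sw = np.sqrt(w)
    xw = xt / sw[:, None]
    yw = yt / sw
    xtx = xw.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yw)
    rss = float(np.sum((yw - xw @ beta) ** 2))
    sigma_e2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    ll = -0.5 * ((n - p) * (np.log(sigma_e2) + 1.0)
                 + np.sum(np.log(w)) + logdet_xtx)
    return ll, sigma_e2


def reml_fit(y: np.ndarray, X: np.ndarray, grm: Grm,
             log_ratio_bounds: tuple = (-12.0, 8.0)) -> VarianceComponents:
    """REML estimates of (sigma_u^2, sigma_e^2) via 1-D search in the
    variance ratio on the GRM eigenbasis; the boundary sigma_u^2 = 0 is
    compared explicitly against the interior optimum."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("y and X row mismatch")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    d, u = grm.eig()
    yt = u.T @ y
    xt = u.T @ X

    res = optimize.minimize_scalar(
        lambda lr: -_restricted_loglik(lr, d, yt, xt)[0],
        bounds=log_ratio_bounds, method="bounded",
        options={"xatol": 1e-8})
    ll_int, se2_int = _restricted_loglik(res.x, d, yt, xt)
    ll_null, se2_null = _restricted_loglik(-30.0, d, yt, xt)  # ratio ~ 0
    if ll_null >= ll_int - 1e-9 or res.x <= log_ratio_bounds[0] + 1e-6:
        return VarianceComponents(0.0, se2_null, ll_null, grm,
                                  converged=bool(res.success))
    ratio = float(np.exp(res.x))
    return VarianceComponents(ratio * se2_int, se2_int, ll_int, grm,
                              converged=bool(res.success))


def _aligned_scores(panel: GenotypePanel, phenotypes: PhenotypeTable) -> np.ndarray:
    return phenotypes.aligned_to(panel.sample_ids).scores


def _design(panel: GenotypePanel, covariates: np.ndarray | None,
            pop_effect: bool) -> np.ndarray:
    cols = [np.ones(panel.n_samples)]
    if pop_effect:
        pops = pd.unique(panel.populations)
        for pop in pops[1:]:  # first population absorbed by the intercept
            cols.append((panel.populations == pop).astype(float))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != panel.n_samples:
            cov = cov.T
        cols.extend(cov.T)
    return np.column_stack(cols)


def mlma_scan(panel: GenotypePanel, phenotypes: PhenotypeTable, grm: Grm,
              vc: VarianceComponents | None = None,
              covariates: np.ndarray | None = None,
              pop_effect: bool = False) -> pd.DataFrame:
    """Per-SNP mixed-model association scan.

    Generalized least squares of y on [intercept, covariates, x] with
    V = G sigma_u^2 + I sigma_e^2 held fixed at the null REML estimates.
    Returns a table with columns SNP CHR BP A1 A2 FREQ B SE Z P N; SNPs
    collinear with the covariates get NaN effect rows.
    """
    y = _aligned_scores(panel, phenotypes)
    X = _design(panel, covariates, pop_effect)
    if vc is None:
        vc = reml_fit(y, X, grm)
    d, u = grm.eig()
    v = vc.sigma_u2 * d + vc.sigma_e2
    sw = np.sqrt(v)

    if np.any(panel.genotypes == MISSING):
        raise ValueError("scan requires a complete (imputed) panel")
    yt = (u.T @ y) / sw
    xt = (u.T @ X) / sw[:, None]
    gt = grm.rotate_genotypes(panel) / sw[:, None]

    q, _ = np.linalg.qr(xt)
    yr = yt - q @ (q.T @ yt)
    gr = gt - q @ (q.T @ gt)

    # residual scale of the null GLS fit; ~1 at the REML optimum and makes
    # (b, SE) invariant to rescaling V by a constant
    sigma2 = float(yr @ yr) / (panel.n_samples - X.shape[1])
    gg = np.einsum("ij,ij->j", gr, gr)
    gy = gr.T @ yr
    ok = gg > 1e-10 * panel.n_samples
    b = np.full(panel.n_snps, np.nan)
    se = np.full(panel.n_snps, np.nan)
    b[ok] = gy[ok] / gg[ok]
    se[ok] = np.sqrt(sigma2 / gg[ok])
    z = b / se
    p = stats.chi2.sf(z ** 2, df=1)

    return pd.DataFrame({
        "SNP": panel.snp_ids,
        "CHR": panel.chromosomes,
        "BP": panel.positions_bp,
        "A1": panel.a1,
        "A2": panel.a2,
        "FREQ": panel.allele_freq(),
        "B": b,
        "SE": se,
        "Z": z,
        "P": p,
        "N": panel.n_samples,
    })


def mega_scan(panel: GenotypePanel, phenotypes: PhenotypeTable, grm: Grm,
              vc: VarianceComponents | None = None,
              covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Pooled-panel scan with a fixed effect of population."""
    have = set(phenotypes.sample_ids)
    for pop in pd.unique(panel.populations):
        ids = panel.sample_ids[panel.populations == pop]
        if not any(i in have for i in ids):
            raise ValueError(f"population {pop} has no phenotypes")
    return mlma_scan(panel, phenotypes, grm, vc, covariates, pop_effect=True)


@dataclasses.dataclass
class QtlRegion:
    chrom: int
    start_bp: int
    end_bp: int
    lead_snp: str
    method: str

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def interval_bp(self) -> int:
        return self.end_bp - self.start_bp


def pick_lead(assoc: pd.DataFrame) -> pd.Series:
    """Deterministic lead SNP: smallest p, then largest |b|, then lowest
    (chrom, bp)."""
    df = assoc.dropna(subset=["P"]).copy()
    df["_absb"] = -df["B"].abs()
    df = df.sort_values(["P", "_absb", "CHR", "BP"], kind="stable")
    return df.iloc[0].drop("_absb")


@dataclasses.dataclass
class ConditionalResult:
    leads: list
    regions: list
    n_signals: int
    scans: list  # per-round association tables

    def union_region(self) -> QtlRegion | None:
        if not self.regions:
            return None
        chroms = {r.chrom for r in self.regions}
        if len(chroms) > 1:
            return None
        return QtlRegion(chrom=self.regions[0].chrom,
                         start_bp=min(r.start_bp for r in self.regions),
                         end_bp=max(r.end_bp for r in self.regions),
                         lead_snp=self.leads[0],
                         method="conditional-union")


def conditional_scan(panel: GenotypePanel, phenotypes: PhenotypeTable, grm: Grm,
                     threshold: float, covariates: np.ndarray | None = None,
                     pop_effect: bool = False, max_rounds: int = 10) -> ConditionalResult:
    """Iterative conditional association analysis.

    Each round scans with all previously found lead SNPs as covariates,
    records the span of that round's significant SNPs (on the lead's
    chromosome) as a QTL region, and conditions on the new lead; stops when
    no SNP passes the threshold.  Variance components are re-estimated each
    round with the augmented fixed-effect design.
    """
    leads: list = []
    regions: list = []
    scans: list = []
    base_cov = (None if covariates is None
                else np.atleast_2d(np.asarray(covariates, dtype=float)))
    lead_genos: list = []
    for _ in range(max_rounds):
        cov_parts = []
        if base_cov is not None:
            cov_parts.append(base_cov.reshape(panel.n_samples, -1))
        if lead_genos:
            cov_parts.append(np.column_stack(lead_genos))
        cov = np.column_stack(cov_parts) if cov_parts else None
        assoc = mlma_scan(panel, phenotypes, grm, vc=None, covariates=cov,
                          pop_effect=pop_effect)
        assoc = assoc[~assoc["SNP"].isin(leads)]
        sig = assoc[assoc["P"] <= threshold]
        scans.append(assoc)
        if sig.empty:
            break
        lead = pick_lead(sig)
        on_chrom = sig[sig["CHR"] == lead["CHR"]]
        regions.append(QtlRegion(
            chrom=int(lead["CHR"]),
            start_bp=int(on_chrom["BP"].min()),
            end_bp=int(on_chrom["BP"].max()),
            lead_snp=str(lead["SNP"]),
            method="conditional",
        ))
        leads.append(str(lead["SNP"]))
        k = int(np.flatnonzero(panel.snp_ids == lead["SNP"])[0])
        lead_genos.append(panel.genotypes[:, k].astype(float))
    return ConditionalResult(leads=leads, regions=regions,
                             n_signals=len(leads), scans=scans)


def write_assoc(assoc: pd.DataFrame, path) -> None:
    assoc[ASSOC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_assoc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    missing = set(ASSOC_COLUMNS) - {"Z"} - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns {sorted(missing)}")
    if "Z" not in df.columns:
        df["Z"] = df["B"] / df["SE"]
    return df
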