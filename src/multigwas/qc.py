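"""Joint genotype quality control and sporadic-genotype imputation.

Filters, applied in a fixed order to the pooled multi-population panel:

1. SNP call rate        (drop SNPs with call rate below threshold)
2. sample call rate
3. sample heterozygosity band (computed on raw, pre-imputation calls)
4. minor allele frequency
5. Hardy-Weinberg exact test (within each population by default; a SNP is
   dropped if it fails in any population; a pooled mode is available)

Remaining sporadic missing genotypes are imputed to the within-population
modal genotype at that SNP.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import MISSING, GenotypePanel


@dataclasses.dataclass
class QcConfig:
    min_call_rate_sample: float = 0.95
    min_call_rate_snp: float = 0.95
    min_maf: float = 0.01
    hwe_p_min: float = 1e-25
    het_low: float = 0.25
    het_high: float = 0.45
    hwe_mode: str = "within"  # "within" (any population fails) or "pooled"

    def __post_init__(self) -> None:
        for name in ("min_call_rate_sample", "min_call_rate_snp", "min_maf",
                     "hwe_p_min", "het_low", "het_high"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.het_low >= self.het_high:
            raise ValueError("het_low must be < het_high")
        if self.hwe_mode not in ("within", "pooled"):
            raise ValueError("hwe_mode must be 'within' or 'pooled'")


@dataclasses.dataclass
class QcReport:
    """Itemized removal counts, in application order."""

    n_samples_in: int
    n_snps_in: int
    snps_removed_call_rate: int = 0
    samples_removed_call_rate: int = 0
    samples_removed_heterozygosity: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    n_genotypes_imputed: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0

    def check(self) -> None:
        if (self.n_samples_in - self.samples_removed_call_rate
                - self.samples_removed_heterozygosity != self.n_samples_out):
            raise AssertionError("sample accounting inconsistent")
        if (self.n_snps_in - self.snps_removed_call_rate - self.snps_removed_maf
                - self.snps_removed_hwe != self.n_snps_out):
            raise AssertionError("SNP accounting inconsistent")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    def __str__(self) -> str:
        d = dataclasses.asdict(self)
        return "\n".join(f"{k}: {v}" for k, v in d.items())


class QcError(RuntimeError):
    def __init__(self, message: str, report: QcReport):
        super().__init__(message)
        self.report = report


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value (Fisher-style, two-sided).

    Conditional on the observed allele counts, the probability of ``k``
    heterozygotes (k of the same parity as the observed count) is

        P(k) = 2^k n! / (n_hom1! k! n_hom2!) * n_A! n_a! / (2n)!

    and the p-value sums P over all configurations no more probable than
    the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype counts")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty genotype table")
    n_a1 = 2 * n_AA + n_Aa
    n_a2 = 2 * n_aa + n_Aa
    if n_a1 == 0 or n_a2 == 0:
        return 1.0  # monomorphic: single possible configuration
    ks = np.arange(n_Aa % 2, min(n_a1, n_a2) + 1, 2)
    hom1 = (n_a1 - ks) // 2
    hom2 = (n_a2 - ks) // 2
    logp = (ks * np.log(2.0) + gammaln(n + 1)
            - gammaln(hom1 + 1) - gammaln(ks + 1) - gammaln(hom2 + 1)
            + gammaln(n_a1 + 1) + gammaln(n_a2 + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(ks, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_vector(panel: GenotypePanel, mode: str) -> np.ndarray:
    """Per-SNP HWE p-value; in 'within' mode the minimum over populations."""
    g = panel.genotypes

    def table_p(sub: np.ndarray) -> np.ndarray:
        nAA = np.sum(sub == 2, axis=0)
        nAa = np.sum(sub == 1, axis=0)
        naa = np.sum(sub == 0, axis=0)
        return np.array([hwe_exact_p(a, h, b) for a, h, b in zip(nAA, nAa, naa)])

    if mode == "pooled":
        return table_p(g)
    pvals = np.ones(panel.n_snps)
    for pop in pd.unique(panel.populations):
        pvals = np.minimum(pvals, table_p(g[panel.populations == pop]))
    return pvals


def impute_sporadic(panel: GenotypePanel) -> tuple[GenotypePanel, int]:
    """Impute missing calls to the within-population modal genotype.

    Ties between equally common genotypes are broken toward the genotype of
    the higher-frequency allele (the larger dosage when the counted allele
    has frequency >= 0.5, else the smaller).
    """
    g = panel.genotypes.copy()
    n_imputed = int(np.sum(g == MISSING))
    for pop in pd.unique(panel.populations):
        rows = panel.populations == pop
        sub = g[rows]
        miss = sub == MISSING
        if not miss.any():
            continue
        counts = np.stack([np.sum(sub == v, axis=0) for v in (0, 1, 2)])
        freq = np.ma.masked_equal(sub, MISSING).mean(axis=0).filled(1.0) / 2.0
        best = np.where(freq >= 0.5,
                        2 - np.argmax(counts[::-1], axis=0),  # prefer larger dosage
                        np.argmax(counts, axis=0))            # prefer smaller dosage
        fill = np.broadcast_to(best.astype(np.int8), sub.shape)
        sub = np.where(miss, fill, sub)
        g[rows] = sub
    out = dataclasses.replace(panel, genotypes=g)
    return out, n_imputed


def run_qc(panel: GenotypePanel, cfg: QcConfig | None = None) -> tuple[GenotypePanel, QcReport]:
    """Apply the full filter chain and imputation; returns panel + report."""
    if cfg is None:
        cfg = QcConfig()
    if panel.n_samples == 0 or panel.n_snps == 0:
        raise ValueError("empty panel")
    report = QcReport(n_samples_in=panel.n_samples, n_snps_in=panel.n_snps)

    keep_snp = panel.call_rate_snp() >= cfg.min_call_rate_snp
    report.snps_removed_call_rate = int(np.sum(~keep_snp))
    panel = panel.subset(snps=keep_snp)
    _fail_if_empty(panel, report, "SNP call-rate filter")

    keep_sample = panel.call_rate_sample() >= cfg.min_call_rate_sample
    report.samples_removed_call_rate = int(np.sum(~keep_sample))
    panel = panel.subset(samples=keep_sample)
    _fail_if_empty(panel, report, "sample call-rate filter")

    het = panel.heterozygosity()
    keep_sample = (het >= cfg.het_low) & (het <= cfg.het_high)
    report.samples_removed_heterozygosity = int(np.sum(~keep_sample))
    panel = panel.subset(samples=keep_sample)
    _fail_if_empty(panel, report, "heterozygosity filter")

    freq = panel.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    keep_snp = maf >= cfg.min_maf
    report.snps_removed_maf = int(np.sum(~keep_snp))
    panel = panel.subset(snps=keep_snp)
    _fail_if_empty(panel, report, "MAF filter")

    hwe_p = _hwe_vector(panel, cfg.hwe_mode)
    keep_snp = hwe_p >= cfg.hwe_p_min
    report.snps_removed_hwe = int(np.sum(~keep_snp))
    panel = panel.subset(snps=keep_snp)
    _fail_if_empty(panel, report, "HWE filter")

    panel, report.n_genotypes_imputed = impute_sporadic(panel)
    report.n_samples_out = panel.n_samples
    report.n_snps_out = panel.n_snps
    report.check()
    return panel, report


def _fail_if_empty(panel: GenotypePanel, report: QcReport, stage: str) -> None:
    if panel.n_samples == 0 or panel.n_snps == 0:
        raise QcError(f"all samples or SNPs removed at {stage}", report)
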