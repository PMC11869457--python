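"""Genotype and phenotype containers with PLINK bed/bim/fam I/O.

The central container is :class:`GenotypePanel`: a samples x SNPs dosage
matrix coded as the count of the effect allele (``a1``), with ``-1`` as the
missing sentinel, together with the marker map, alleles and a population
label per sample.  Phenotypes travel in :class:`PhenotypeTable`, a thin
wrapper around a DataFrame keyed by sample id.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode

# 2-bit PLINK codes -> dosage of A1 (00=hom A1, 01=missing, 10=het, 11=hom A2)
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


@dataclasses.dataclass
class GenotypePanel:
    """Samples x SNPs genotype matrix plus marker and sample metadata.

    ``genotypes[i, k]`` is the number of copies of ``a1[k]`` carried by
    sample ``i`` (0, 1 or 2), or ``-1`` for a missing call.
    """

    genotypes: np.ndarray
    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions_bp: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    sample_ids: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        for field in ("snp_ids", "chromosomes", "positions_bp", "a1", "a2",
                      "sample_ids", "populations"):
            setattr(self, field, np.asarray(getattr(self, field)))
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n or len(self.populations) != n:
            raise ValueError("sample metadata length mismatch")
        for field in ("snp_ids", "chromosomes", "positions_bp", "a1", "a2"):
            if len(getattr(self, field)) != m:
                raise ValueError(f"{field} length mismatch")
        vals = np.unique(self.genotypes)
        bad = set(vals.tolist()) - {MISSING, 0, 1, 2}
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        # positions strictly increasing within each chromosome
        for c in pd.unique(self.chromosomes):
            bp = self.positions_bp[self.chromosomes == c]
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    # ------------------------------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Frequency of the effect allele (a1) per SNP over non-missing calls."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        return np.asarray(g.mean(axis=0) / 2.0)

    def call_rate_snp(self) -> np.ndarray:
        return 1.0 - np.mean(self.genotypes == MISSING, axis=0)

    def call_rate_sample(self) -> np.ndarray:
        return 1.0 - np.mean(self.genotypes == MISSING, axis=1)

    def heterozygosity(self) -> np.ndarray:
        """Per-sample heterozygous fraction over non-missing calls."""
        nonmiss = np.sum(self.genotypes != MISSING, axis=1)
        het = np.sum(self.genotypes == 1, axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)

    def subset(self, samples=None, snps=None) -> "GenotypePanel":
        """Return a new panel restricted to boolean/index selections."""
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        ki = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if ki.dtype == bool:
            ki = np.flatnonzero(ki)
        return GenotypePanel(
            genotypes=self.genotypes[np.ix_(si, ki)],
            snp_ids=self.snp_ids[ki],
            chromosomes=self.chromosomes[ki],
            positions_bp=self.positions_bp[ki],
            a1=self.a1[ki],
            a2=self.a2[ki],
            sample_ids=self.sample_ids[si],
            populations=self.populations[si],
        )

    def drop_monomorphic(self) -> "GenotypePanel":
        """Panel restricted to SNPs segregating in these samples."""
        freq = self.allele_freq()
        return self.subset(snps=(freq > 0) & (freq < 1))

    def snp_index(self) -> pd.Index:
        return pd.Index(self.snp_ids)

    # ------------------------------------------------------------------
    def to_plink(self, prefix: str | Path) -> None:
        """Write PLINK .bed/.bim/.fam (SNP-major bed, FID = population label)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        bim = pd.DataFrame({
            "chrom": self.chromosomes,
            "snp": self.snp_ids,
            "cm": 0,
            "bp": self.positions_bp,
            "a1": self.a1,
            "a2": self.a2,
        })
        bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
        fam = pd.DataFrame({
            "fid": self.populations,
            "iid": self.sample_ids,
            "pat": 0, "mat": 0, "sex": 0, "phen": -9,
        })
        fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

        n = self.n_samples
        n_bytes = (n + 3) // 4
        code_of = np.full(4, 0b01, dtype=np.uint8)  # indexed by dosage+1
        for dos, code in _DOSAGE_TO_BED_CODE.items():
            code_of[dos + 1] = code
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            codes = code_of[self.genotypes.T + 1]  # (n_snps, n_samples)
            pad = (-n) % 4
            if pad:
                codes = np.pad(codes, ((0, 0), (0, pad)), constant_values=0b01)
            codes = codes.reshape(self.n_snps, n_bytes, 4)
            packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
                      | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6))
            fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK bed/bim/fam triple into a :class:`GenotypePanel`."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "bp", "a1", "a2"],
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "phen"],
                      dtype={"fid": str, "iid": str})
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file")
    body = raw[3:].reshape(m, n_bytes)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    dosage = _BED_CODE_TO_DOSAGE[codes.reshape(m, -1)[:, :n]]
    return GenotypePanel(
        genotypes=dosage.T.copy(),
        snp_ids=bim["snp"].to_numpy(),
        chromosomes=bim["chrom"].to_numpy(),
        positions_bp=bim["bp"].to_numpy(),
        a1=bim["a1"].to_numpy(),
        a2=bim["a2"].to_numpy(),
        sample_ids=fam["iid"].to_numpy(),
        populations=fam["fid"].to_numpy(),
    )


@dataclasses.dataclass
class PhenotypeTable:
    """Ordinal scores (0-5) per sample, optionally keeping the latent liability."""

    table: pd.DataFrame  # columns: sample_id, population, score[, liability]

    def __post_init__(self) -> None:
        req = {"sample_id", "population", "score"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        scores = self.table["score"].to_numpy()
        if not np.isin(scores, np.arange(6)).all():
            raise ValueError("scores must lie in 0..5")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy(dtype=float)

    def aligned_to(self, sample_ids: np.ndarray) -> "PhenotypeTable":
        sub = self.table.set_index("sample_id").loc[np.asarray(sample_ids)]
        return PhenotypeTable(sub.reset_index())

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.rename(columns={"population": "FID", "sample_id": "IID"})
        out[["FID", "IID", "score"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    return PhenotypeTable(df.rename(columns={"FID": "population", "IID": "sample_id"}))
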