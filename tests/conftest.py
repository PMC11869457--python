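import numpy as np
import pandas as pd
import pytest

import multigwas as mg


@pytest.fixture(scope="session")
def salmon_small():
    """One desk-scale admixed four-population dataset with a planted QTL,
    QC'd, with per-population scans, mega scan and GRM, shared across tests."""
    cfg = mg.salmon_preset(scale=0.1, n_snps=1500, seed=11)
    panel, phen = mg.simulate_panel(cfg)
    clean, report = mg.run_qc(panel)
    grm = mg.compute_grm(clean)
    tables = []
    for pop in pd.unique(clean.populations):
        sub = clean.subset(samples=clean.populations == pop)
        freq = sub.allele_freq()
        sub = sub.subset(snps=(freq > 0) & (freq < 1))
        g = mg.compute_grm(sub)
        tables.append(mg.mlma_scan(sub, phen, g))
    mega = mg.mega_scan(clean, phen, grm)
    return {
        "config": cfg, "panel": panel, "phen": phen, "clean": clean,
        "report": report, "grm": grm, "pop_tables": tables, "mega": mega,
    }


@pytest.fixture()
def unrelated_panel():
    """Single unstructured population: no drift, no admixture, no families,
    large haplotype pool (effectively unrelated samples in HWE)."""
    cfg = mg.SimConfig(pop_sizes=[400], n_snps=800, n_chroms=4, fst=0.0,
                       n_pool_haplotypes=2000, h2_poly=0.0, seed=5)
    panel, phen = mg.simulate_panel(cfg)
    return panel, phen


def make_assoc(snp, chrom, bp, b, se, p=None, freq=0.5, n=100, a1="G", a2="A"):
    """Hand-built association table in the standard column layout."""
    b = np.asarray(b, dtype=float)
    se = np.asarray(se, dtype=float)
    z = b / se
    if p is None:
        from scipy import stats
        p = stats.chi2.sf(z ** 2, df=1)
    k = len(snp)
    return pd.DataFrame({
        "SNP": snp, "CHR": np.broadcast_to(chrom, k).copy(),
        "BP": np.broadcast_to(bp, k).copy(),
        "A1": np.broadcast_to(a1, k).copy(), "A2": np.broadcast_to(a2, k).copy(),
        "FREQ": np.broadcast_to(freq, k).astype(float),
        "B": b, "SE": se, "Z": z, "P": np.asarray(p, dtype=float),
        "N": np.broadcast_to(n, k).copy(),
    })
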