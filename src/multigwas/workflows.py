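"""High-level study workflows combining the analysis stages.

These functions wire together QC'd panels, per-population mixed-model
scans, the pooled mega-analysis and the meta-analysis estimators the way a
multi-population association study runs them, and collect the
genomic-inflation factors that diagnose cryptic-relatedness confounding.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .meta import run_meta
from .mlm import Grm, compute_grm, mega_scan, mlma_scan
from .multiple_testing import genomic_lambda
from .panel import GenotypePanel, PhenotypeTable


def population_tables(panel: GenotypePanel, phen: PhenotypeTable) -> list[pd.DataFrame]:
    """Within-population mixed-model scans, one association table per
    population (each against its own GRM, monomorphic SNPs dropped)."""
    tables = []
    for pop in pd.unique(panel.populations):
        sub = panel.subset(samples=panel.populations == pop).drop_monomorphic()
        grm = compute_grm(sub)
        tables.append(mlma_scan(sub, phen, grm))
    return tables


@dataclasses.dataclass
class StudyResult:
    mega: pd.DataFrame
    pop_tables: list
    meta: pd.DataFrame
    grm: Grm

    def lambdas(self) -> dict:
        """Genomic inflation factors: mega scan, Z-score and IVW meta
        p-values, and the decomposed random-effects convention."""
        return {
            "mega": genomic_lambda(p=self.mega["P"].dropna().to_numpy()).lam,
            "zscore": genomic_lambda(p=self.meta["P_ZSCORE"].to_numpy()).lam,
            "ivw": genomic_lambda(p=self.meta["P_IVW"].to_numpy()).lam,
            "random": genomic_lambda(components=(
                self.meta["S_FE"].to_numpy(),
                self.meta["S_HET"].to_numpy())).lam,
        }


def analyze_study(panel: GenotypePanel, phen: PhenotypeTable) -> StudyResult:
    """Mega-analysis plus all meta-analyses of one QC'd multi-population
    panel; the pooled GRM is reused by downstream conditional analysis."""
    grm = compute_grm(panel)
    mega = mega_scan(panel, phen, grm)
    tables = population_tables(panel, phen)
    meta = run_meta(tables, method="ivw")
    return StudyResult(mega=mega, pop_tables=tables, meta=meta, grm=grm)
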