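"""ΔΔCt relative quantification and qPCR vs RNA-seq concordance.

The ΔΔCt method normalizes a target gene's Ct to a housekeeping
reference gene within each sample (ΔCt = Ct_target − Ct_reference),
contrasts group means (ΔΔCt = mean ΔCt(test) − mean ΔCt(calibrator)),
and converts to a linear fold change FC = 2^(−ΔΔCt), assuming perfect
doubling per cycle. Concordance with sequencing-derived fold changes
is summarized by Pearson correlation on the log2 scale.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct_fold_change", "concordance", "load_ct_table"]

DEFAULT_REFERENCE_GENE = "GAPDH"


def load_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV with columns sample_id, gene_id, ct.

    Duplicate wells (repeated sample/gene rows) are averaged to one Ct
    per sample and gene.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene_id", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    return df.groupby(["sample_id", "gene_id"], as_index=False)["ct"].mean()


def ddct_fold_change(
    ct: pd.DataFrame,
    target_gene: str,
    group_test: Sequence[str],
    group_calibrator: Sequence[str],
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> float:
    """Relative expression of ``target_gene`` in test vs calibrator group.

    ``ct`` is a long-form table (sample_id, gene_id, ct), one Ct per
    sample and gene (duplicates already averaged). Raises if the
    reference or target Ct is missing for any listed sample.
    """
    table = ct.set_index(["sample_id", "gene_id"])["ct"]

    def delta_ct(sample: str) -> float:
        for gene in (target_gene, reference_gene):
            if (sample, gene) not in table.index:
                raise ValueError(f"sample {sample}: missing Ct for {gene}")
        return float(table[(sample, target_gene)] - table[(sample, reference_gene)])

    d_test = np.mean([delta_ct(s) for s in group_test])
    d_cal = np.mean([delta_ct(s) for s in group_calibrator])
    ddct = d_test - d_cal
    return float(2.0 ** (-ddct))


def concordance(
    qpcr_fc: Mapping[str, float],
    rnaseq_fc: Mapping[str, float],
) -> tuple[float, float, int]:
    """Pearson r of log2 fold changes over genes measured by both assays.

    Returns (r, p_value, n_genes). Requires at least 3 shared genes.
    """
    shared = sorted(set(qpcr_fc) & set(rnaseq_fc))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    x = np.log2([qpcr_fc[g] for g in shared])
    y = np.log2([rnaseq_fc[g] for g in shared])
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(shared)
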