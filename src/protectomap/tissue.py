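"""Brain-vs-periphery tissue enrichment of candidate genes.

Given a genes x tissues TPM table (GTEx-style, 54 tissues of which a subset
are brain tissues), a tissue "overexpresses" a gene when its TPM strictly
exceeds that gene's median TPM across all tissues. Two genes are compared
by a 2x2 chi-squared on how their overexpressing tissues split between
brain and non-brain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biostats import chi2_2x2


@dataclass
class TissueTable:
    """Genes x tissues TPM with a boolean brain flag per tissue."""

    tpm: pd.DataFrame          # genes x tissues, TPM >= 0
    is_brain: pd.Series        # indexed by tissue id

    def __post_init__(self):
        if not self.tpm.columns.equals(self.is_brain.index):
            self.is_brain = self.is_brain.reindex(self.tpm.columns)
        if self.is_brain.isna().any():
            raise ValueError("every tissue needs a brain/non-brain label")
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be >= 0")
        if self.tpm.columns.duplicated().any():
            raise ValueError("tissue ids must be unique")
        n_brain = int(self.is_brain.sum())
        if n_brain < 2 or len(self.is_brain) - n_brain < 2:
            raise ValueError("need >= 2 brain and >= 2 non-brain tissues")

    @property
    def tissues(self) -> list[str]:
        return list(self.tpm.columns)


def overexpressing_tissues(table: TissueTable, gene: str) -> set[str]:
    """Tissues whose TPM strictly exceeds the gene's across-tissue median.

    The median of an even-length vector is the mean of the two central order
    statistics; values tied with the median do not count as overexpression.
    """
    if gene not in table.tpm.index:
        raise KeyError(f"gene {gene!r} not in tissue table")
    vals = table.tpm.loc[gene]
    if vals.isna().any():
        raise ValueError(f"gene {gene!r} has missing tissue values")
    med = float(np.median(vals.to_numpy()))
    return set(vals.index[vals > med])


def brain_enrichment_compare(table: TissueTable, gene_a: str, gene_b: str,
                             continuity: bool = True):
    """Compare brain-tissue enrichment of two genes' overexpressing tissues.

    Builds a 2x2 table (rows = genes; columns = brain vs non-brain among each
    gene's overexpressing tissues) and applies the chi-squared test, with
    Yates continuity correction by default. Returns (counts 2x2, chi2, p).
    """
    counts = []
    for gene in (gene_a, gene_b):
        over = overexpressing_tissues(table, gene)
        if not over:
            raise ValueError(f"gene {gene!r} has no overexpressing tissues; "
                             "comparison undefined")
        n_brain = sum(bool(table.is_brain[t]) for t in over)
        counts.append([n_brain, len(over) - n_brain])
    counts = np.asarray(counts, dtype=int)
    if gene_a == gene_b:
        return counts, 0.0, 1.0
    chi2, _, p = chi2_2x2(counts, continuity=continuity)
    return counts, chi2, p


def brain_enrichment_single(table: TissueTable, gene: str,
                            continuity: bool = True):
    """One-vs-rest variant: does a gene's overexpression favor brain tissues?

    2x2 table with rows = brain vs non-brain tissues, columns = overexpressing
    vs not. Returns (counts 2x2, chi2, p).
    """
    over = overexpressing_tissues(table, gene)
    if not over:
        raise ValueError(f"gene {gene!r} has no overexpressing tissues")
    brain = set(table.is_brain[table.is_brain.astype(bool)].index)
    nonbrain = set(table.tissues) - brain
    counts = np.array([
        [len(over & brain), len(brain - over)],
        [len(over & nonbrain), len(nonbrain - over)],
    ])
    chi2, _, p = chi2_2x2(counts, continuity=continuity)
    return counts, chi2, p
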