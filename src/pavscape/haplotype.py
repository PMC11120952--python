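"""Split samples into presence/absence haplotype groups and compare traits.

Following the convention of the association figures, *group1* (Hap1) is the
reference class without the variant allele and *group2* (Hap2) carries it.
Group comparison is a two-sided Welch (unequal-variance) two-sample t-test
by default; the pooled-variance Student variant is available via
``equal_var=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ABSENT, PRESENT, GenotypeMatrix


@dataclass
class HaplotypeGroups:
    locus_id: str
    group1: list[str]  # reference (variant absent)
    group2: list[str]  # variant carriers
    excluded: list[str]  # missing genotype or missing phenotype


@dataclass
class GroupComparison:
    locus_id: str
    group1_mean: float
    group2_mean: float
    n1: int
    n2: int
    t: float
    df: float
    p: float
    significant: bool  # p < 0.05 marker, as starred in trait boxplots


def split_haplotypes(matrix: GenotypeMatrix, locus_id: str,
                     phenotype: pd.Series) -> HaplotypeGroups:
    """Partition samples by presence/absence at one locus.

    Samples with a missing genotype at the locus or a missing phenotype are
    excluded; the two groups and the excluded set partition all samples.
    """
    hits = matrix.loci.index[matrix.loci["locus_id"] == locus_id]
    if len(hits) == 0:
        raise KeyError(f"locus {locus_id!r} not in matrix")
    col = matrix.genotypes[:, hits[0]]
    g1, g2, excl = [], [], []
    for sample, g in zip(matrix.samples, col):
        pheno = phenotype.get(sample, np.nan)
        if pd.isna(pheno) or g not in (PRESENT, ABSENT):
            excl.append(sample)
        elif g == PRESENT:
            g2.append(sample)
        else:
            g1.append(sample)
    return HaplotypeGroups(locus_id=locus_id, group1=g1, group2=g2,
                           excluded=excl)


def compare_groups(groups: HaplotypeGroups, phenotype: pd.Series,
                   equal_var: bool = False) -> GroupComparison:
    """Two-sided t-test of the trait between the two haplotype groups."""
    x1 = phenotype.loc[groups.group1].to_numpy(dtype=float)
    x2 = phenotype.loc[groups.group2].to_numpy(dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError(
            f"locus {groups.locus_id}: both haplotype groups need >=2 samples "
            f"(got {len(x1)} and {len(x2)})")
    res = stats.ttest_ind(x1, x2, equal_var=equal_var)
    p = float(res.pvalue)
    return GroupComparison(
        locus_id=groups.locus_id,
        group1_mean=float(x1.mean()),
        group2_mean=float(x2.mean()),
        n1=len(x1),
        n2=len(x2),
        t=float(res.statistic),
        df=float(res.df),
        p=p,
        significant=p < 0.05,
    )
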