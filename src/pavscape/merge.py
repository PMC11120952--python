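"""Merge multi-caller PAV callsets into unified loci and filter them.

Clustering is single-linkage over a breakpoint-proximity relation: two
records are linkable iff they lie on the same chromosome, share the SV type
(when ``require_same_type``), and both |delta start| and |delta end| are at
most ``max_breakpoint_distance``.  Connected components are computed with a
position-sorted sweep plus union-find, so the result is independent of input
order; a component's consensus coordinates are per-field medians of its
members (even counts: the midpoint, floored on half-integers).  Note that
single-linkage chains can span more than the distance threshold end to end —
the same behaviour as common SV-merging tools.

Genotype union across callers is presence-dominant: a sample is *present*
at a merged locus if any member record calls it present, *absent* if any
member calls it absent (and none present), else *missing*.

Variant filters mirror standard population-genotyping practice: keep a locus
iff MAF >= ``maf_min`` (inclusive) and missing fraction < ``missing_max``
(strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ABSENT,
    MISSING,
    PRESENT,
    Callset,
    GenotypeMatrix,
    PAVRecord,
    natural_chrom_key,
)

logger = logging.getLogger(__name__)


@dataclass
class MergeParams:
    max_breakpoint_distance: int = 1000
    require_same_type: bool = True
    pass_only: bool = True

    def __post_init__(self) -> None:
        if self.max_breakpoint_distance < 0:
            raise ValueError("max_breakpoint_distance must be >= 0")


@dataclass
class FilterParams:
    maf_min: float = 0.01
    missing_max: float = 0.40  # exclusive bound

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 < self.missing_max <= 1.0:
            raise ValueError("missing_max must be in (0, 1]")


def filter_pass(records: list[PAVRecord]) -> list[PAVRecord]:
    """Keep only records whose FILTER tag is PASS."""
    kept = [r for r in records if r.filter == "PASS"]
    logger.info("PASS filter: kept %d of %d records", len(kept), len(records))
    return kept


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_records(records: list[PAVRecord],
                    params: MergeParams | None = None) -> list[list[PAVRecord]]:
    """Group records into breakpoint-proximity clusters (connected components).

    The sweep sorts records by (chromosome, type, start) and only compares
    each record with predecessors whose start lies within the distance
    threshold — |delta start| <= D is necessary for linkage, so no pair is
    missed.  Cluster order and member order are deterministic regardless of
    the input ordering.
    """
    params = params or MergeParams()
    D = params.max_breakpoint_distance
    order = sorted(
        range(len(records)),
        key=lambda i: (natural_chrom_key(records[i].chrom),
                       records[i].svtype if params.require_same_type else "",
                       records[i].start, records[i].end,
                       records[i].caller, records[i].record_id))
    uf = _UnionFind(len(records))
    window: list[int] = []  # sweep window of candidate predecessor indices
    prev_key = None
    for i in order:
        r = records[i]
        key = (r.chrom, r.svtype if params.require_same_type else None)
        if key != prev_key:
            window = []
            prev_key = key
        window = [j for j in window if r.start - records[j].start <= D]
        for j in window:
            if abs(r.end - records[j].end) <= D:
                uf.union(i, j)
        window.append(i)
    groups: dict[int, list[int]] = {}
    for i in order:
        groups.setdefault(uf.find(i), []).append(i)
    clusters = [[records[i] for i in members] for members in groups.values()]
    clusters.sort(key=lambda c: (natural_chrom_key(c[0].chrom),
                                 min(r.start for r in c),
                                 min(r.end for r in c), c[0].svtype))
    return clusters


def _median_int(values: list[int]) -> int:
    """Median; for even counts the midpoint, floored on half-integers."""
    return int(np.floor(np.median(values)))


def consensus_locus(cluster: list[PAVRecord]) -> dict:
    svtype = cluster[0].svtype
    start = _median_int([r.start for r in cluster])
    if svtype == "DEL":
        end = _median_int([r.end for r in cluster])
        end = max(end, start + 1)
        size = end - start
    else:
        end = start
        size = _median_int([abs(r.svlen) for r in cluster])
    callers = sorted({r.caller for r in cluster})
    return {
        "chrom": cluster[0].chrom,
        "start": start,
        "end": end,
        "svtype": svtype,
        "size": size,
        "callers": ",".join(callers),
        "n_members": len(cluster),
    }


def build_genotype_matrix(clusters: list[list[PAVRecord]],
                          samples: list[str]) -> GenotypeMatrix:
    """Collapse clusters to consensus loci with presence-dominant genotypes."""
    n_s = len(samples)
    for cl in clusters:
        for r in cl:
            if len(r.genotypes) != n_s:
                raise ValueError(
                    f"record {r.record_id}: genotype vector length "
                    f"{len(r.genotypes)} does not match {n_s} samples")
    loci_rows, geno_cols = [], []
    for k, cl in enumerate(clusters):
        meta = consensus_locus(cl)
        meta["locus_id"] = f"locus{k + 1:05d}"
        loci_rows.append(meta)
        member = np.stack([r.genotypes for r in cl], axis=1)  # n_s x members
        col = np.full(n_s, MISSING, dtype=np.int8)
        col[(member == ABSENT).any(axis=1)] = ABSENT
        col[(member == PRESENT).any(axis=1)] = PRESENT
        geno_cols.append(col)
    loci = pd.DataFrame(
        loci_rows,
        columns=["locus_id", "chrom", "start", "end", "svtype", "size",
                 "callers", "n_members"])
    geno = (np.stack(geno_cols, axis=1) if geno_cols
            else np.empty((n_s, 0), dtype=np.int8))
    return GenotypeMatrix(samples=list(samples), loci=loci, genotypes=geno)


def merge_callsets(callsets: list[Callset],
                   params: MergeParams | None = None) -> GenotypeMatrix:
    """PASS-filter (if configured), pool, cluster and genotype-union callsets."""
    params = params or MergeParams()
    samples = callsets[0].samples
    for cs in callsets[1:]:
        if cs.samples != samples:
            raise ValueError("callsets disagree on the sample list")
    records: list[PAVRecord] = []
    for cs in callsets:
        recs = filter_pass(cs.records) if params.pass_only else list(cs.records)
        records.extend(recs)
    clusters = cluster_records(records, params)
    return build_genotype_matrix(clusters, samples)


def compute_maf(genotypes: np.ndarray) -> float:
    """Minor-allele frequency of one presence/absence vector.

    p = presence / non-missing; MAF = min(p, 1 - p).  All-missing input is
    an error (undefined frequency).
    """
    g = np.asarray(genotypes)
    called = g != MISSING
    if not called.any():
        raise ValueError("MAF undefined: all genotypes missing")
    p = (g[called] == PRESENT).mean()
    return float(min(p, 1.0 - p))


def apply_variant_filters(matrix: GenotypeMatrix,
                          params: FilterParams | None = None) -> GenotypeMatrix:
    """Keep loci with MAF >= maf_min and missing fraction < missing_max."""
    params = params or FilterParams()
    maf = matrix.maf()
    miss = matrix.missing_rate()
    all_missing = np.isnan(maf)
    keep_maf = ~all_missing & (maf >= params.maf_min)
    keep_miss = miss < params.missing_max
    keep = keep_maf & keep_miss
    logger.info(
        "variant filters: %d loci in, %d fail MAF>=%.3g, %d fail missing<%.3g, %d kept",
        matrix.n_loci, int((~keep_maf).sum()), int((~keep_miss).sum()),
        int(keep.sum()))
    return matrix.subset_loci(keep)
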