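"""Core data containers shared across the pavscape pipeline.

Coordinates are 1-based inclusive throughout (the native convention of VCF
and GFF3); conversion to 0-based half-open happens only when writing BED.
Genotypes are binary presence/absence calls for inbred (homozygous) material,
encoded as ``int8``: 1 = present (carries the variant allele), 0 = absent,
-1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

PRESENT: int = 1
ABSENT: int = 0
MISSING: int = -1

#: Minimum structural-variant size (bp) — anything shorter is an indel, not a PAV.
MIN_PAV_SIZE: int = 50

SVTYPES = ("DEL", "INS")


class PavscapeError(Exception):
    """Base class for pavscape-specific errors."""


@dataclass
class PAVRecord:
    """One presence/absence variant call from a single caller.

    A deletion spans ``[start, end]`` with ``end > start`` and a negative
    ``svlen`` equal to ``-(end - start)``; an insertion is anchored at a
    single reference base (``end == start``) with ``svlen`` equal to the
    inserted length.  ``genotypes`` is an ``int8`` vector aligned to the
    sample list of the owning :class:`Callset`.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    caller: str
    filter: str
    genotypes: np.ndarray
    record_id: str = ""

    @property
    def size(self) -> int:
        return self.end - self.start if self.svtype == "DEL" else self.svlen

    def validate(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unsupported SVTYPE {self.svtype!r}")
        if self.svtype == "DEL":
            if not self.end > self.start:
                raise ValueError(
                    f"DEL record {self.record_id or self.chrom}: end must exceed start"
                )
            if abs(self.svlen) != self.end - self.start:
                raise ValueError(
                    f"DEL record {self.record_id or self.chrom}: |SVLEN| != end - start"
                )
        else:
            if self.end != self.start:
                raise ValueError(
                    f"INS record {self.record_id or self.chrom}: end must equal start"
                )
            if self.svlen <= 0:
                raise ValueError(
                    f"INS record {self.record_id or self.chrom}: SVLEN must be positive"
                )
        if abs(self.svlen) < MIN_PAV_SIZE:
            raise ValueError(
                f"record {self.record_id or self.chrom}: |SVLEN| below {MIN_PAV_SIZE} bp"
            )


@dataclass
class Callset:
    """A caller's records together with the sample list their genotypes index."""

    caller: str
    samples: list[str]
    records: list[PAVRecord]
    #: bookkeeping from parsing: e.g. {"non_pav_svtype": 3, "missing_svtype": 1}
    skipped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PAVRecord]:
        return iter(self.records)


@dataclass
class GeneModel:
    """A gene with its exon/CDS/UTR structure (1-based inclusive intervals)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utrs: list[tuple[int, int]]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (empty for single-exon genes)."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class GeneAnnotation:
    """An ordered collection of gene models."""

    genes: list[GeneModel]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.end))
        return out


# Column order for the locus-metadata frame of a GenotypeMatrix.
LOCUS_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "svtype",
    "size",
    "callers",
    "n_members",
]


@dataclass
class GenotypeMatrix:
    """Samples x merged PAV loci presence/absence matrix with locus metadata.

    ``genotypes`` has shape ``(n_samples, n_loci)`` with the PRESENT/ABSENT/
    MISSING encoding; ``loci`` is a DataFrame with :data:`LOCUS_COLUMNS`.
    """

    samples: list[str]
    loci: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def presence_frequency(self) -> np.ndarray:
        """Per-locus fraction of PRESENT calls among non-missing calls."""
        present = (self.genotypes == PRESENT).sum(axis=0)
        called = (self.genotypes != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, present / np.maximum(called, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.presence_frequency()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=self.loci.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[:, mask],
        )

    # -- plain-text persistence (matrix TSV = loci x samples, per the CLI contract)

    def to_tsv(self, matrix_path: str | Path, loci_path: str | Path) -> None:
        gt = pd.DataFrame(
            self.genotypes.T,
            index=pd.Index(self.loci["locus_id"], name="locus_id"),
            columns=self.samples,
            dtype=object,
        )
        gt = gt.where(gt != MISSING, "NA")
        gt.to_csv(matrix_path, sep="\t")
        self.loci.to_csv(loci_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, loci_path: str | Path) -> "GenotypeMatrix":
        gt = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA"])
        loci = pd.read_csv(loci_path, sep="\t")
        geno = gt.to_numpy(dtype=float).T
        geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
        if list(gt.index) != list(loci["locus_id"]):
            raise ValueError("locus order in matrix TSV and loci TSV disagree")
        return cls(samples=list(gt.columns), loci=loci, genotypes=geno)


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key for chromosome names: 'chr2' < 'chr10', '2' < '10'."""
    import re

    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def check_sortable_chroms(chroms: Sequence[str]) -> None:
    """Reject a mix of prefixed ('chr1') and bare ('1') chromosome names."""
    has_prefix = {c[:1].isalpha() for c in chroms if c}
    if len(has_prefix) > 1:
        raise ValueError(
            "mixed chromosome naming (prefixed and bare) cannot be sorted consistently"
        )
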