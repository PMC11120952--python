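"""Readers and writers for the formats the pipeline touches.

Supported dialects:

* **SV VCF 4.2** — symbolic ``<DEL>``/``<INS>`` alleles with ``INFO``
  ``SVTYPE``/``END``/``SVLEN`` and a ``GT`` FORMAT field.  Reading goes
  through :mod:`pysam`; writing is a deterministic plain-text emitter for
  exactly this dialect.  Breakend notation, multi-allelic rows and SV types
  other than DEL/INS are out of scope (non-DEL/INS rows are skipped and
  counted).
* **GFF3** gene models (gene/mRNA/exon/CDS/UTR), parsed with :mod:`gffutils`
  into :class:`~pavscape.core.GeneAnnotation`; introns are derived as gaps
  between exons.
* **Phenotype TSV** — first column ``sample_id``, one column per trait;
  replicate columns named ``trait.rep1 .. trait.repK`` are averaged over
  non-missing values.
* **BED** (0-based half-open) for region output.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import (
    ABSENT,
    MISSING,
    PRESENT,
    Callset,
    GeneAnnotation,
    GeneModel,
    PAVRecord,
    check_sortable_chroms,
    natural_chrom_key,
)

logger = logging.getLogger(__name__)

MISSING_MARKERS = {"", "NA", "na", "NaN", "nan", "."}


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------

def read_sv_vcf(path: str | Path, expected_samples: list[str] | None = None,
                caller: str | None = None) -> Callset:
    """Parse a DEL/INS structural-variant VCF into a :class:`Callset`.

    Genotype collapse for inbred material: any alt-bearing GT is *present*,
    an all-reference GT is *absent*, ``./.`` (or malformed) is *missing*.
    Rows whose SVTYPE is not DEL/INS are skipped (counted in
    ``Callset.skipped``); rows with no SVTYPE are rejected with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    skipped = {"non_pav_svtype": 0, "missing_svtype": 0, "multiallelic": 0}
    records: list[PAVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if expected_samples is not None and list(expected_samples) != samples:
            raise ValueError(
                f"{path}: header samples do not match the expected sample list"
            )
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                skipped["missing_svtype"] += 1
                warnings.warn(f"{path}: record at {rec.chrom}:{rec.pos} lacks SVTYPE; rejected")
                continue
            if svtype not in ("DEL", "INS"):
                skipped["non_pav_svtype"] += 1
                continue
            if rec.alts is not None and len(rec.alts) > 1:
                raise ValueError(
                    f"{path}: multi-allelic SV row at {rec.chrom}:{rec.pos} not supported"
                )
            start = rec.pos
            end = rec.stop if svtype == "DEL" else start  # pysam stop <- INFO END
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if svlen is None:
                if svtype == "DEL":
                    svlen = -(end - start)
                else:
                    raise ValueError(
                        f"{path}: INS at {rec.chrom}:{rec.pos} lacks SVLEN"
                    )
            geno = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                try:
                    gt = rec.samples[s].get("GT")
                except Exception:
                    gt = None
                if gt is None or all(a is None for a in gt):
                    geno[i] = MISSING
                elif any(a not in (0, None) for a in gt):
                    geno[i] = PRESENT
                else:
                    geno[i] = ABSENT
            pav = PAVRecord(
                chrom=rec.chrom,
                start=start,
                end=end,
                svtype=svtype,
                svlen=int(svlen),
                caller=caller or path.stem,
                filter=";".join(rec.filter.keys()) or "PASS",
                genotypes=geno,
                record_id=rec.id or "",
            )
            pav.validate()
            records.append(pav)
    total_skipped = skipped["non_pav_svtype"] + skipped["missing_svtype"]
    if total_skipped:
        logger.info("%s: skipped %d non-PAV/invalid rows", path, total_skipped)
    return Callset(caller=caller or path.stem, samples=samples,
                   records=records, skipped=skipped)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pavscape
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INS,Description="Insertion">
##FILTER=<ID=LowQual,Description="Low-quality call">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_sv_vcf(records: list[PAVRecord], samples: list[str],
                 path: str | Path) -> None:
    """Write records as a VCF 4.2 with the SVTYPE/END/SVLEN dialect.

    Output is sorted by (chromosome, position) with a natural chromosome
    key and is byte-deterministic for a given input.
    """
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in VCF sample list")
    chroms = sorted({r.chrom for r in records}, key=natural_chrom_key)
    check_sortable_chroms(chroms)
    gt_map = {PRESENT: "1/1", ABSENT: "0/0", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        ordered = sorted(records, key=lambda r: (natural_chrom_key(r.chrom),
                                                 r.start, r.end, r.record_id))
        for i, r in enumerate(ordered):
            rid = r.record_id or f"pav_{i + 1:06d}"
            info = f"SVTYPE={r.svtype};END={r.end};SVLEN={r.svlen}"
            gts = "\t".join(gt_map[int(g)] for g in r.genotypes)
            fh.write(f"{r.chrom}\t{r.start}\t{rid}\tN\t<{r.svtype}>\t.\t"
                     f"{r.filter}\t{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> GeneAnnotation:
    """Parse GFF3 gene models (gene/mRNA/exon/CDS/UTR features).

    A gene without exon children is treated as a single-exon gene spanning
    its whole extent (documented fallback).  A child feature extending
    outside its gene's span raises an error naming the feature.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons, cds, utrs = [], [], []
        for child in db.children(g.id):
            if child.start < g.start or child.end > g.end:
                raise ValueError(
                    f"feature {child.id or child.featuretype} at "
                    f"{child.seqid}:{child.start}-{child.end} lies outside "
                    f"its gene {g.id} span"
                )
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype in ("five_prime_UTR", "three_prime_UTR"):
                utrs.append(iv)
        if not exons:
            exons = [(g.start, g.end)]
        exons.sort()
        cds.sort()
        utrs.sort()
        genes.append(GeneModel(gene_id=g.id, chrom=g.seqid, start=g.start,
                               end=g.end, strand=g.strand or ".",
                               exons=exons, cds=cds, utrs=utrs))
    genes.sort(key=lambda m: (natural_chrom_key(m.chrom), m.start, m.end))
    return GeneAnnotation(genes=genes)


def write_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes,
                        key=lambda m: (natural_chrom_key(m.chrom), m.start)):
            mrna_id = f"{g.gene_id}.1"
            fh.write(f"{g.chrom}\tpavscape\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\tpavscape\tmRNA\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tpavscape\texon\t{s}\t{e}\t.\t{g.strand}"
                         f"\t.\tParent={g.gene_id}\n")
            for s, e in g.cds:
                fh.write(f"{g.chrom}\tpavscape\tCDS\t{s}\t{e}\t.\t{g.strand}"
                         f"\t0\tParent={g.gene_id}\n")
            for s, e in g.utrs:
                # 5' vs 3' determined by position relative to CDS and strand
                kind = _utr_kind(g, s, e)
                fh.write(f"{g.chrom}\tpavscape\t{kind}\t{s}\t{e}\t.\t"
                         f"{g.strand}\t.\tParent={g.gene_id}\n")


def _utr_kind(g: GeneModel, s: int, e: int) -> str:
    if not g.cds:
        return "five_prime_UTR"
    before_cds = e < g.cds[0][0]
    if g.strand == "-":
        return "three_prime_UTR" if before_cds else "five_prime_UTR"
    return "five_prime_UTR" if before_cds else "three_prime_UTR"


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a sample-by-trait TSV into a DataFrame indexed by sample id.

    Replicate columns ``trait.rep1 .. trait.repK`` are averaged over their
    non-missing values; a sample with every replicate missing gets NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    id_col = raw.columns[0]
    ids = raw[id_col]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    values: dict[str, pd.Series] = {}
    for col in raw.columns[1:]:
        parsed = _parse_numeric(raw[col], path, col)
        trait = col.split(".rep")[0] if ".rep" in col else col
        if trait in values:
            values[trait] = pd.concat([values[trait], parsed], axis=1).mean(
                axis=1, skipna=True)
        else:
            values[trait] = parsed
    table = pd.DataFrame(values)
    table.index = pd.Index(ids, name="sample_id")
    return table


def _parse_numeric(col: pd.Series, path: Path, name: str) -> pd.Series:
    vals = col.astype(str).str.strip()
    vals = vals.where(~vals.isin(MISSING_MARKERS) & col.notna(), other=np.nan)
    try:
        return vals.astype(float)
    except ValueError:
        for i, v in vals.items():
            if isinstance(v, str):
                try:
                    float(v)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {v!r} in column {name!r}, row {i + 2}"
                    ) from None
        raise


def write_phenotype_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(regions, path: str | Path) -> None:
    """Write (chrom, start_1based, end, name, score) tuples as 0-based BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score in regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score}\n")
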