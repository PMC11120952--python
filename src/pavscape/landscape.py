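"""Characterize a merged PAV set: size spectrum, genomic context, hotspots.

Context classes are non-exclusive: a PAV carries every class whose territory
it overlaps by at least one base, so class percentages can sum to more than
100%.  The five classes are

* ``flank_3kb`` — within 3 kb upstream/downstream of a gene (outside the
  gene body),
* ``CDS`` — coding sequence (exonic bases not annotated as UTR count as
  coding),
* ``UTR`` — untranslated exonic sequence,
* ``intron`` — gaps between exons,
* ``intergenic`` — any base outside all gene bodies and their flanks.

Hotspots follow the sliding-window construction: breakpoint counts per
1000 kb window at a 500 kb step, the top decile of windows genome-wide
(ties at the cutoff included, zero-count windows never hotspots), and
maximal runs of overlapping/touching hotspot windows merged into regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import IntervalSet, merge, subtract
from .core import (
    MIN_PAV_SIZE,
    GeneAnnotation,
    GenotypeMatrix,
    natural_chrom_key,
)

CONTEXT_CLASSES = ("flank_3kb", "CDS", "UTR", "intron", "intergenic")
GENIC_CLASSES = ("flank_3kb", "CDS", "UTR", "intron")

#: Default log2-spaced size bins from the 50 bp floor; open-ended final bin.
DEFAULT_SIZE_BINS = [50 * 2 ** k for k in range(12)] + [np.inf]


# ---------------------------------------------------------------------------
# Size spectrum
# ---------------------------------------------------------------------------

def size_spectrum(sizes, bin_edges=None) -> dict:
    """Bin PAV sizes into half-open bins and report the short-PAV share.

    Returns ``{"bin_edges", "counts", "short_fraction"}`` where the short
    fraction is the share of sizes in the 50-1000 bp range (inclusive), or
    None for empty input.
    """
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size and sizes.min() < MIN_PAV_SIZE:
        raise ValueError(f"PAV size below {MIN_PAV_SIZE} bp violates the type invariant")
    edges = np.asarray(bin_edges if bin_edges is not None else DEFAULT_SIZE_BINS,
                       dtype=float)
    counts = np.histogram(sizes, bins=edges)[0] if sizes.size else \
        np.zeros(len(edges) - 1, dtype=int)
    short = None
    if sizes.size:
        short = float(((sizes >= 50) & (sizes <= 1000)).mean())
    return {"bin_edges": edges.tolist(), "counts": counts.tolist(),
            "short_fraction": short}


# ---------------------------------------------------------------------------
# Context classification
# ---------------------------------------------------------------------------

class ContextClassifier:
    """Precomputed per-chromosome interval sets for the five context classes."""

    def __init__(self, annotation: GeneAnnotation, flank_bp: int = 3000):
        self.flank_bp = flank_bp
        by_chrom = annotation.by_chrom()
        self._sets: dict[str, dict[str, IntervalSet]] = {}
        for chrom, genes in by_chrom.items():
            flanks, cds, utr, introns, bodies = [], [], [], [], []
            for g in genes:
                bodies.append((g.start, g.end))
                if flank_bp > 0:
                    if g.start > 1:
                        flanks.append((max(1, g.start - flank_bp), g.start - 1))
                    flanks.append((g.end + 1, g.end + flank_bp))
                utr.extend(g.utrs)
                introns.extend(g.introns)
                # exonic bases not annotated UTR count as coding
                cds.extend(subtract(g.exons, g.utrs))
            # flanks never reach inside gene bodies
            flanks = subtract(flanks, bodies)
            self._sets[chrom] = {
                "flank_3kb": IntervalSet(flanks),
                "CDS": IntervalSet(cds),
                "UTR": IntervalSet(utr),
                "intron": IntervalSet(introns),
                "_nongenic_complement": IntervalSet(merge(bodies + flanks)),
            }

    def classify(self, chrom: str, start: int, end: int, svtype: str = "DEL") -> set[str]:
        if svtype == "INS":
            end = start  # insertions are breakpoints, classified as 1 bp points
        sets = self._sets.get(chrom)
        if sets is None:
            warnings.warn(f"chromosome {chrom!r} absent from annotation; "
                          "classifying as intergenic")
            return {"intergenic"}
        out = {cls for cls in GENIC_CLASSES if sets[cls].overlaps(start, end)}
        if not sets["_nongenic_complement"].covers(start, end):
            out.add("intergenic")
        if not out:  # inside a gene body but in no annotated subfeature
            out.add("intron")
        return out


def classify_context(locus, annotation, flank_bp: int = 3000) -> set[str]:
    """Classify one locus; `locus` is anything with chrom/start/end/svtype.

    For repeated calls build a :class:`ContextClassifier` once instead.
    """
    clf = annotation if isinstance(annotation, ContextClassifier) else \
        ContextClassifier(annotation, flank_bp)
    return clf.classify(locus.chrom, int(locus.start), int(locus.end),
                        str(locus.svtype))


def summarize_context(matrix: GenotypeMatrix, annotation: GeneAnnotation,
                      flank_bp: int = 3000) -> dict:
    """Percentage of loci carrying each class, plus the genic share and the
    flank share among genic loci (percentages may sum above 100)."""
    clf = ContextClassifier(annotation, flank_bp)
    classes = [clf.classify(r.chrom, int(r.start), int(r.end), str(r.svtype))
               for r in matrix.loci.itertuples()]
    n = len(classes)
    out = {}
    for cls in CONTEXT_CLASSES:
        out[f"pct_{cls}"] = 100.0 * sum(cls in c for c in classes) / n if n else None
    genic = [any(cls in c for cls in GENIC_CLASSES) for c in classes]
    n_genic = sum(genic)
    out["pct_genic"] = 100.0 * n_genic / n if n else None
    flank_in_genic = sum("flank_3kb" in c for c, g in zip(classes, genic) if g)
    out["pct_flank_within_genic"] = (100.0 * flank_in_genic / n_genic
                                     if n_genic else None)
    return out


# ---------------------------------------------------------------------------
# Windows & hotspots
# ---------------------------------------------------------------------------

@dataclass
class WindowCounts:
    """Per-chromosome sliding-window breakpoint counts.

    ``windows[chrom]`` is a DataFrame with 0-based window ``start``,
    clipped ``end`` and breakpoint ``count``.
    """

    windows: dict[str, pd.DataFrame]
    window_size: int
    step: int

    def flatten(self) -> pd.DataFrame:
        frames = [df.assign(chrom=c) for c, df in self.windows.items()]
        return pd.concat(frames, ignore_index=True) if frames else \
            pd.DataFrame(columns=["start", "end", "count", "chrom"])


@dataclass
class HotspotRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_windows: int
    total_breakpoints: int
    max_window_count: int


def count_breakpoints_in_windows(loci: pd.DataFrame,
                                 chromosome_lengths: dict[str, int],
                                 window_size: int = 1_000_000,
                                 step: int = 500_000) -> WindowCounts:
    """Count PAV start breakpoints per sliding window.

    Windows start at 0 every ``step`` while the start is inside the
    chromosome; the last windows are clipped at the chromosome end.  A
    breakpoint is counted once in *every* window containing it, so
    overlapping windows double-count by design.
    """
    per_point = max(1, math.ceil(window_size / step))
    windows: dict[str, pd.DataFrame] = {}
    for chrom, length in chromosome_lengths.items():
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        counts = np.zeros(len(starts), dtype=np.int64)
        sub = loci[loci["chrom"] == chrom]
        if len(sub):
            bp = sub["start"].to_numpy(dtype=np.int64) - 1  # 0-based points
            if (bp < 0).any() or (bp >= length).any():
                bad = sub["start"].to_numpy()[(bp < 0) | (bp >= length)][0]
                raise ValueError(
                    f"locus start {bad} outside chromosome {chrom} (length {length})")
            for k in range(per_point):
                j = bp // step - k
                ok = (j >= 0) & (starts[np.maximum(j, 0)] + window_size > bp)
                np.add.at(counts, j[ok], 1)
        windows[chrom] = pd.DataFrame({"start": starts, "end": ends,
                                       "count": counts})
    return WindowCounts(windows=windows, window_size=window_size, step=step)


def detect_hotspots(counts: WindowCounts, top_frac: float = 0.10,
                    per_chromosome: bool = False) -> list[HotspotRegion]:
    """Rank windows by breakpoint count and merge the top decile into regions.

    The cutoff is the k-th highest count with ``k = ceil(top_frac * n)``;
    all windows tied at the cutoff are kept, but zero-count windows never
    qualify.  Step-adjacent/overlapping hotspot windows on one chromosome
    are merged into maximal regions.  ``per_chromosome`` ranks within each
    chromosome instead of genome-wide.
    """
    if not 0.0 < top_frac <= 1.0:
        raise ValueError("top_frac must be in (0, 1]")
    flat = counts.flatten()
    if flat.empty:
        raise ValueError("no windows to rank")
    hot = []
    groups = flat.groupby("chrom", sort=False) if per_chromosome else \
        [(None, flat)]
    for _, df in groups:
        vals = np.sort(df["count"].to_numpy())[::-1]
        k = math.ceil(top_frac * len(vals))
        cutoff = vals[k - 1]
        hot.append(df[(df["count"] >= cutoff) & (df["count"] > 0)])
    hot_df = pd.concat(hot, ignore_index=True)
    regions: list[HotspotRegion] = []
    for chrom, df in hot_df.groupby("chrom", sort=False):
        df = df.sort_values("start")
        cur = None
        for w_start, w_end, w_count in df[["start", "end", "count"]].to_numpy():
            if cur is not None and w_start <= cur["end"]:
                cur["end"] = max(cur["end"], w_end)
                cur["n"] += 1
                cur["total"] += w_count
                cur["max"] = max(cur["max"], w_count)
            else:
                if cur is not None:
                    regions.append(_region(chrom, cur))
                cur = {"start": w_start, "end": w_end, "n": 1,
                       "total": w_count, "max": w_count}
        if cur is not None:
            regions.append(_region(chrom, cur))
    regions.sort(key=lambda r: (natural_chrom_key(r.chrom), r.start))
    return regions


def _region(chrom, cur) -> HotspotRegion:
    return HotspotRegion(chrom=chrom, start=int(cur["start"]) + 1,
                         end=int(cur["end"]), n_windows=int(cur["n"]),
                         total_breakpoints=int(cur["total"]),
                         max_window_count=int(cur["max"]))


# ---------------------------------------------------------------------------
# Per-chromosome reporting
# ---------------------------------------------------------------------------

def per_chromosome_counts(matrix: GenotypeMatrix) -> pd.Series:
    return matrix.loci.groupby("chrom")["locus_id"].count().rename("n_pavs")


def mean_per_chromosome(total: int, n_chromosomes: int) -> int:
    """Round-half-down integer mean of PAVs per chromosome."""
    return int(math.ceil(total / n_chromosomes - 0.5))
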