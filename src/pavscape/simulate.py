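"""Synthetic inbred-panel generator for end-to-end pipeline testing.

The generator emulates the statistical structure of a resequenced panel of
improved rice cultivars without any read-level simulation:

* a small multi-chromosome genome with non-overlapping gene models
  (exons, CDS, UTRs, introns);
* a PAV truth set whose sizes follow a truncated Pareto (power-law) decay —
  geometric decay across log-spaced size bins starting at the 50 bp
  structural-variant floor — and whose positions are uniform except inside
  planted hotspot regions, which are ``enrichment_factor`` times denser;
* fully inbred samples from two subpopulations (an *indica*-like majority
  and a *japonica*-like minority), each locus getting an independent
  per-subpopulation presence frequency, so population structure is strong;
* two imperfect pseudo-callers over the shared truth set, differing only by
  breakpoint jitter, per-locus dropout, low-quality tags and missing
  genotypes;
* quantitative traits with planted causal PAVs (effect sizes back-computed
  from a target variance-explained fraction), a subpopulation mean shift,
  and Gaussian noise, reported on each trait's natural scale.

All outputs are bit-deterministic functions of the
:class:`SimulationConfig` (including its seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _intervals
from .core import (
    MISSING,
    MIN_PAV_SIZE,
    Callset,
    GeneAnnotation,
    GeneModel,
    PAVRecord,
)

CALLER_NAMES = ("callerA", "callerB")


@dataclass(frozen=True)
class TraitSpec:
    """A quantitative trait: latent standardized scores are mapped to
    ``mean + scale * z`` so different traits live on their natural scales."""

    name: str
    mean: float = 0.0
    scale: float = 1.0


#: The five agronomic traits of the study panel, centred on the panel means
#: reported for the 148-cultivar population (days / cm / cm / cm / count).
DEFAULT_TRAITS = (
    TraitSpec("days_to_heading", 96.8, 12.0),
    TraitSpec("plant_height", 91.3, 15.0),
    TraitSpec("flag_leaf_length", 26.9, 4.0),
    TraitSpec("flag_leaf_width", 1.4, 0.2),
    TraitSpec("panicle_number", 9.2, 2.0),
)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples: int = 148
    n_chromosomes: int = 3
    chromosome_length_bp: int = 10_000_000
    n_genes: int = 900
    n_true_pavs: int = 2000
    min_pav_size_bp: int = MIN_PAV_SIZE
    max_pav_size_bp: int = 100_000
    #: Pareto tail exponent b: P(size > x) = (x / min)^-b (before truncation).
    #: The default gives ~74.6% of sizes in 50-1000 bp.
    size_decay: float = 0.42
    del_fraction: float = 0.97
    #: (chrom, start, end, enrichment_factor) regions with denser PAV
    #: placement; None plants one 8x hotspot over 20-30% of the last
    #: chromosome (the default study condition).
    hotspot_regions: tuple | None = None
    n_subpopulations: int = 2
    #: fraction of samples in the first (majority) subpopulation: 109/148.
    subpop_fraction: float = 109 / 148
    allele_freq_range: tuple = (0.05, 0.95)
    #: (locus index or "random", variance_explained) per trait.
    causal_pavs: tuple = (("random", 0.25),)
    subpop_phenotype_shift: float = 0.5
    noise_sd: float = 1.0
    caller_breakpoint_jitter_sd: float = 30.0
    caller_false_negative_rate: float = 0.05
    caller_lowqual_rate: float = 0.05
    genotype_missing_rate: float = 0.02
    #: optional minimum same-chromosome start separation between truth loci
    #: (0 = off); when on, distance-based merging is information-preserving.
    min_locus_separation_bp: int = 0
    traits: tuple = DEFAULT_TRAITS

    def __post_init__(self) -> None:
        if self.hotspot_regions is None:
            L = self.chromosome_length_bp
            self.hotspot_regions = (
                (self.chromosome_names()[-1], int(0.2 * L) + 1, int(0.3 * L), 8.0),)
        self.hotspot_regions = tuple(tuple(h) for h in self.hotspot_regions)
        self.validate()

    def validate(self) -> None:
        for name in ("caller_false_negative_rate", "caller_lowqual_rate",
                     "genotype_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.subpop_fraction < 1.0:
            raise ValueError("subpop_fraction must be in (0, 1)")
        if self.min_pav_size_bp < MIN_PAV_SIZE:
            raise ValueError(f"min_pav_size_bp must be >= {MIN_PAV_SIZE}")
        if self.max_pav_size_bp <= self.min_pav_size_bp:
            raise ValueError("max_pav_size_bp must exceed min_pav_size_bp")
        if self.size_decay <= 0:
            raise ValueError("size_decay must be positive")
        if not 0.0 <= self.del_fraction <= 1.0:
            raise ValueError("del_fraction must be in [0, 1]")
        total_ve = sum(ve for _, ve in self.causal_pavs)
        if total_ve >= 1.0:
            raise ValueError("variance_explained values must sum to < 1")
        chroms = set(self.chromosome_names())
        for chrom, start, end, enrich in self.hotspot_regions:
            if enrich <= 0:
                raise ValueError("hotspot enrichment_factor must be > 0")
            if chrom not in chroms:
                raise ValueError(f"hotspot chromosome {chrom!r} not in genome")
            if not (1 <= start <= end <= self.chromosome_length_bp):
                raise ValueError(
                    f"hotspot {chrom}:{start}-{end} outside chromosome bounds")

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chromosome_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length_bp for c in self.chromosome_names()}


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests: loci, inbred genotypes,
    subpopulation labels, per-trait causal effects (trait units) and the
    planted hotspot regions."""

    samples: list[str]
    loci: pd.DataFrame  # chrom, start, end, svtype, size
    genotypes: np.ndarray  # (n_samples, n_loci) int8 presence 0/1
    subpopulation_labels: np.ndarray
    causal_effects: dict  # trait name -> {locus index: effect in trait units}
    hotspot_truth: list

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "samples": self.samples,
            "loci": self.loci.to_dict(orient="list"),
            "genotypes": ["".join(str(int(g)) for g in row)
                          for row in self.genotypes],
            "subpopulation_labels": [int(x) for x in self.subpopulation_labels],
            "causal_effects": {t: {str(k): v for k, v in eff.items()}
                               for t, eff in self.causal_effects.items()},
            "hotspot_truth": [list(h) for h in self.hotspot_truth],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        geno = np.array([[int(ch) for ch in row] for row in payload["genotypes"]],
                        dtype=np.int8)
        return cls(
            samples=payload["samples"],
            loci=pd.DataFrame(payload["loci"])[
                ["chrom", "start", "end", "svtype", "size"]],
            genotypes=geno,
            subpopulation_labels=np.array(payload["subpopulation_labels"]),
            causal_effects={t: {int(k): v for k, v in eff.items()}
                            for t, eff in payload["causal_effects"].items()},
            hotspot_truth=[tuple(h) for h in payload["hotspot_truth"]],
        )


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def simulate_gene_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Place non-overlapping gene models on each chromosome.

    Genes get 1-5 exons separated by introns, terminal UTR segments when the
    flanking exons are long enough, and CDS covering the remaining exonic
    bases.  Raises ``ValueError`` when the genome cannot hold the requested
    number of genes.
    """
    rng = _rng(config, 11)
    genes: list[GeneModel] = []
    n_per = [config.n_genes // config.n_chromosomes
             + (i < config.n_genes % config.n_chromosomes)
             for i in range(config.n_chromosomes)]
    counter = 0
    for chrom, n_i in zip(config.chromosome_names(), n_per):
        if n_i == 0:
            continue
        lengths = rng.integers(2000, 8001, size=n_i)
        slack = config.chromosome_length_bp - int(lengths.sum()) - (n_i + 1)
        if slack < 0:
            raise ValueError(
                f"genome too small to place {n_i} genes on {chrom} "
                f"({config.chromosome_length_bp} bp)"
            )
        gaps = 1 + np.floor(rng.dirichlet(np.ones(n_i + 1)) * slack).astype(int)
        pos = 1 + gaps[0]
        for i in range(n_i):
            counter += 1
            span = int(lengths[i])
            start, end = pos, pos + span - 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _exon_structure(rng, start, span)
            utrs, cds = _utr_cds(exons)
            genes.append(GeneModel(
                gene_id=f"gene{counter:05d}", chrom=chrom, start=start,
                end=end, strand=strand, exons=exons, cds=cds, utrs=utrs))
            pos = end + 1 + gaps[i + 1]
    return GeneAnnotation(genes=genes)


def _exon_structure(rng, start, span):
    n_exons = int(rng.integers(1, 6))
    parts = 2 * n_exons - 1
    if span < parts * 60:
        n_exons, parts = 1, 1
    w = rng.dirichlet(np.ones(parts))
    seg = 60 + np.floor(w * (span - parts * 60)).astype(int)
    seg[-1] = span - int(seg[:-1].sum())  # exact total
    exons, pos = [], start
    for j, length in enumerate(seg):
        if j % 2 == 0:
            exons.append((pos, pos + int(length) - 1))
        pos += int(length)
    return exons

def _utr_cds(exons):
    utrs = []
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    if first_e - first_s + 1 >= 150:
        utrs.append((first_s, first_s + min(150, (first_e - first_s + 1) // 3) - 1))
    if len(exons) > 1 and last_e - last_s + 1 >= 150:
        utrs.append((last_e - min(150, (last_e - last_s + 1) // 3) + 1, last_e))
    cds = _intervals.subtract(exons, utrs)
    if not cds:  # degenerate single short exon: keep it all coding
        utrs, cds = [], list(exons)
    return utrs, cds


# ---------------------------------------------------------------------------
# PAV truth set
# ---------------------------------------------------------------------------

def simulate_pav_truth(config: SimulationConfig,
                       annotation: GeneAnnotation | None = None) -> TruthSet:
    """Draw the true PAV loci, inbred genotypes and per-trait causal effects.

    Positions are uniform per base outside hotspots and ``enrichment_factor``
    times denser inside; sizes follow the truncated power-law decay; each
    locus gets an independent presence frequency per subpopulation and
    samples are homozygous carriers/non-carriers.
    """
    rng = _rng(config, 23)
    n = config.n_true_pavs
    segs, weights = _placement_segments(config)
    positions, chrom_idx = _draw_positions(rng, config, segs, weights, n)
    if config.min_locus_separation_bp > 0:
        positions, chrom_idx = _enforce_separation(
            rng, config, segs, weights, positions, chrom_idx)

    sizes = _draw_sizes(rng, config, n)
    is_del = rng.random(n) < config.del_fraction
    chrom_names = config.chromosome_names()
    L = config.chromosome_length_bp
    starts = positions.copy()
    # keep deletions inside the chromosome
    over = is_del & (starts + sizes > L)
    starts[over] = np.maximum(1, L - sizes[over])
    ends = np.where(is_del, starts + sizes, starts)

    loci = pd.DataFrame({
        "chrom": [chrom_names[i] for i in chrom_idx],
        "start": starts,
        "end": ends,
        "svtype": np.where(is_del, "DEL", "INS"),
        "size": sizes,
    })
    order = loci.sort_values(["chrom", "start", "end"],
                             kind="mergesort").index.to_numpy()
    loci = loci.loc[order].reset_index(drop=True)

    labels = _subpop_labels(config)
    lo, hi = config.allele_freq_range
    freqs = lo + (hi - lo) * rng.random((config.n_subpopulations, len(loci)))
    genotypes = (rng.random((config.n_samples, len(loci)))
                 < freqs[labels]).astype(np.int8)

    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    causal = _resolve_causal_effects(rng, config, genotypes)
    return TruthSet(samples=samples, loci=loci, genotypes=genotypes,
                    subpopulation_labels=labels, causal_effects=causal,
                    hotspot_truth=list(config.hotspot_regions))


def _placement_segments(config):
    segs = []  # (chrom index, start, end, per-base weight)
    for ci, chrom in enumerate(config.chromosome_names()):
        hots = [(s, e, w) for c, s, e, w in config.hotspot_regions if c == chrom]
        hot_ivs = [(s, e) for s, e, _ in hots]
        for s, e in _intervals.subtract([(1, config.chromosome_length_bp)], hot_ivs):
            segs.append((ci, s, e, 1.0))
        for s, e, w in hots:
            segs.append((ci, s, e, float(w)))
    weights = np.array([(e - s + 1) * w for _, s, e, w in segs])
    return segs, weights / weights.sum()


def _draw_positions(rng, config, segs, weights, n):
    idx = rng.choice(len(segs), size=n, p=weights)
    starts = np.array([segs[i][1] for i in idx])
    lens = np.array([segs[i][2] - segs[i][1] + 1 for i in idx])
    pos = starts + np.floor(rng.random(n) * lens).astype(np.int64)
    chrom_idx = np.array([segs[i][0] for i in idx])
    return pos, chrom_idx


def _enforce_separation(rng, config, segs, weights, positions, chrom_idx):
    """Resample positions until same-chromosome starts differ by more than
    the configured separation (rejection loop; errors out if infeasible)."""
    sep = config.min_locus_separation_bp
    for _ in range(500):
        order = np.lexsort((positions, chrom_idx))
        p, c = positions[order], chrom_idx[order]
        close = np.zeros(len(p), dtype=bool)
        same = (c[1:] == c[:-1]) & (p[1:] - p[:-1] <= sep)
        close[1:][same] = True
        if not close.any():
            return positions, chrom_idx
        bad = order[close]
        new_pos, new_ci = _draw_positions(rng, config, segs, weights, len(bad))
        positions[bad], chrom_idx[bad] = new_pos, new_ci
    raise ValueError(
        f"could not place {len(positions)} loci with "
        f"min_locus_separation_bp={sep}; genome too crowded")


def _draw_sizes(rng, config, n):
    m, M, b = config.min_pav_size_bp, config.max_pav_size_bp, config.size_decay
    u = rng.random(n)
    tail = (M / m) ** (-b)
    sizes = np.floor(m * (1.0 - u * (1.0 - tail)) ** (-1.0 / b)).astype(np.int64)
    return np.minimum(sizes, M)


def _subpop_labels(config):
    n0 = int(round(config.n_samples * config.subpop_fraction))
    n0 = min(max(n0, 1), config.n_samples - (config.n_subpopulations - 1))
    labels = np.zeros(config.n_samples, dtype=np.int64)
    rest = config.n_samples - n0
    k = config.n_subpopulations - 1
    if k > 0:
        each = rest // k
        pos = n0
        for j in range(1, config.n_subpopulations):
            cnt = each + (1 if j - 1 < rest % k else 0)
            labels[pos:pos + cnt] = j
            pos += cnt
    return labels


def _resolve_causal_effects(rng, config, genotypes):
    """Back-compute per-trait effect sizes from variance_explained targets.

    With total latent variance sigma_T^2 = noise_sd^2 / (1 - sum(ve)), a
    locus with realized genotype variance v_g needs effect
    beta = sqrt(ve * sigma_T^2 / v_g) to explain fraction ve of the total.
    Effects are stored in trait units (latent beta times the trait scale).
    In the noiseless limit the total-variance decomposition degenerates; a
    unit latent variance is used so planted effects stay finite and nonzero.
    """
    n_loci = genotypes.shape[1]
    total_ve = sum(ve for _, ve in config.causal_pavs)
    sigma_t2 = (config.noise_sd ** 2 / (1.0 - total_ve)
                if config.noise_sd > 0 else 1.0)
    causal: dict[str, dict[int, float]] = {}
    poly = np.flatnonzero(genotypes.std(axis=0) > 0)
    for trait in config.traits:
        eff: dict[int, float] = {}
        for locus, ve in config.causal_pavs:
            if locus == "random":
                # a planted causal variant must segregate in the panel
                if len(poly) == 0:
                    raise ValueError(
                        f"variance_explained={ve} infeasible: no polymorphic "
                        "locus to plant a causal effect on")
                idx = int(poly[rng.integers(len(poly))])
            else:
                idx = int(locus)
            if not 0 <= idx < n_loci:
                raise ValueError(f"causal locus index {idx} out of range")
            v_g = float(np.var(genotypes[:, idx]))
            if v_g == 0.0:
                raise ValueError(
                    f"variance_explained={ve} infeasible: locus {idx} is "
                    "monomorphic in the sample")
            beta = float(np.sqrt(ve * sigma_t2 / v_g))
            eff[idx] = eff.get(idx, 0.0) + beta * trait.scale
        causal[trait.name] = eff
    return causal


# ---------------------------------------------------------------------------
# Pseudo-caller callsets
# ---------------------------------------------------------------------------

def simulate_caller_callsets(truth: TruthSet,
                             config: SimulationConfig) -> tuple[Callset, Callset]:
    """Produce two imperfect caller views of the truth set.

    Each caller independently drops whole loci at the false-negative rate,
    jitters breakpoints with rounded Gaussian noise (clamped to the
    chromosome and to the 50 bp size floor), tags a fraction of records
    LowQual, and blanks a fraction of genotypes to missing.
    """
    if truth.n_loci == 0:
        raise ValueError("truth set has no loci")
    rng = _rng(config, 37)
    L = config.chromosome_length_bp
    out = []
    for caller in CALLER_NAMES:
        keep = rng.random(truth.n_loci) >= config.caller_false_negative_rate
        d_start = np.rint(rng.normal(0.0, config.caller_breakpoint_jitter_sd,
                                     truth.n_loci)).astype(np.int64)
        d_end = np.rint(rng.normal(0.0, config.caller_breakpoint_jitter_sd,
                                   truth.n_loci)).astype(np.int64)
        lowqual = rng.random(truth.n_loci) < config.caller_lowqual_rate
        miss = rng.random((config.n_samples, truth.n_loci)) \
            < config.genotype_missing_rate
        records = []
        for j in range(truth.n_loci):
            if not keep[j]:
                continue
            row = truth.loci.iloc[j]
            start = int(np.clip(row.start + d_start[j], 1, L))
            if row.svtype == "DEL":
                end = int(np.clip(row.end + d_end[j], 1, L))
                end = max(end, start + MIN_PAV_SIZE)
                if end > L:
                    end = L
                    start = min(start, end - MIN_PAV_SIZE)
                svlen = -(end - start)
            else:
                end = start
                svlen = max(MIN_PAV_SIZE, int(row.size + d_end[j]))
            geno = truth.genotypes[:, j].copy()
            geno[miss[:, j]] = MISSING
            rec = PAVRecord(
                chrom=row.chrom, start=start, end=end, svtype=row.svtype,
                svlen=svlen, caller=caller,
                filter="LowQual" if lowqual[j] else "PASS",
                genotypes=geno, record_id=f"{caller}_L{j:05d}")
            rec.validate()
            records.append(rec)
        out.append(Callset(caller=caller, samples=list(truth.samples),
                           records=records))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(truth: TruthSet, config: SimulationConfig) -> pd.DataFrame:
    """Generate the sample-by-trait table.

    Latent score: sum of causal effects times presence, plus the
    subpopulation shift for non-majority samples, plus Gaussian noise; the
    score is centred on its panel mean and reported as
    ``trait.mean + trait.scale * z`` so each trait's sample mean sits at its
    configured panel mean (centring is an affine shift and changes no
    association or group-comparison statistic).
    """
    rng = _rng(config, 53)
    n = len(truth.samples)
    shift_ind = (truth.subpopulation_labels != 0).astype(float)
    cols = {}
    for trait in config.traits:
        z = np.zeros(n)
        for idx, effect in truth.causal_effects.get(trait.name, {}).items():
            z += (effect / trait.scale) * truth.genotypes[:, idx]
        z += config.subpop_phenotype_shift * shift_ind
        z += rng.normal(0.0, config.noise_sd, n)
        z -= z.mean()
        cols[trait.name] = trait.mean + trait.scale * z
    table = pd.DataFrame(cols, index=pd.Index(truth.samples, name="sample_id"))
    return table
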