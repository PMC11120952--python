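"""PC-adjusted single-locus association scan with a permutation threshold.

The engine is a fixed-effects linear model fitted per locus by ordinary
least squares:

    phenotype ~ intercept + locus + PC1..PCk

with a two-sided p-value from the t statistic of the locus coefficient.
Genome-wide significance is controlled by a permutation max-statistic
threshold: residuals of the phenotype (after regressing out the covariates)
are permuted across samples, the full scan is repeated, the genome-wide
maximum -log10(p) is recorded per permutation, and the empirical
(1 - alpha) quantile of those maxima is the threshold.  The permutation is
therefore *conditional* on the covariates (Freedman-Lane style); raw-label
permutation and a pooled-quantile variant are available as options.

The scan is fully vectorized across loci and permutations via the
Frisch-Waugh-Lovell decomposition: with Q an orthonormal basis of the
covariate design, the per-locus coefficient is a simple regression of the
residualized phenotype on the residualized genotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, PRESENT, GeneAnnotation, GenotypeMatrix

P_FLOOR = 1e-300  # numerical floor before taking -log10


@dataclass
class PCABasis:
    """Sample scores for the leading components plus the full variance split."""

    scores: np.ndarray  # (n_samples, k)
    variance_ratio: np.ndarray  # all components; sums to 1
    loadings: np.ndarray  # (k, n_loci)


@dataclass
class PermutationSpec:
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    conditioning: str = "residual_permutation"  # or "raw_permutation"
    statistic: str = "max"  # or "pooled"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.conditioning not in ("residual_permutation", "raw_permutation"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")
        if self.statistic not in ("max", "pooled"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


# ---------------------------------------------------------------------------
# Encoding & PCA
# ---------------------------------------------------------------------------

def encode_genotypes(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Numeric design columns: present=1, absent=0, missing=column mean.

    Returns ``(X, usable)`` where ``usable`` flags loci that are polymorphic
    after imputation (an all-missing or monomorphic locus is unusable).
    """
    g = matrix.genotypes
    X = (g == PRESENT).astype(float)
    miss = g == MISSING
    called = ~miss
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        col_mean = np.where(n_called > 0,
                            (X * called).sum(axis=0) / np.maximum(n_called, 1),
                            0.0)
    X = np.where(miss, col_mean[None, :], X)
    usable = (n_called > 0) & (X.std(axis=0) > 0)
    return X, usable


def compute_pcs(X: np.ndarray, k: int = 3) -> PCABasis:
    """Principal components of the column-centered encoded matrix.

    Scores are deterministic up to sign; the sign is fixed so that each
    component's largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the sample count {n}")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]),
                      np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    var = S ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    return PCABasis(scores=U[:, :k] * S[:k], variance_ratio=ratio,
                    loadings=Vt[:k])


# ---------------------------------------------------------------------------
# Scan internals
# ---------------------------------------------------------------------------

def _design_basis(n: int, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones((n, 1))]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    X0 = np.hstack(cols)
    Q, _ = np.linalg.qr(X0)
    return Q


def _bulk_stats(Gr: np.ndarray, gg: np.ndarray, Yr: np.ndarray,
                df: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS t statistics for every (locus, phenotype) pair.

    Gr: residualized genotypes (n x m); Yr: residualized phenotypes (n x q);
    gg: per-locus sum of squares.  Returns (beta, se, p), each (m x q).
    """
    gy = Gr.T @ Yr
    yy = (Yr * Yr).sum(axis=0)
    safe_gg = np.where(gg > 0, gg, np.nan)
    beta = gy / safe_gg[:, None]
    rss = np.maximum(yy[None, :] - beta * gy, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(rss / df / safe_gg[:, None])
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(beta), 1.0, p)
    beta = np.where(np.isnan(beta), 0.0, beta)
    return beta, se, np.clip(p, P_FLOOR, 1.0)


def _prepare(X, phenotype, covariates):
    y = np.asarray(phenotype, dtype=float)
    mask = ~np.isnan(y)
    y = y[mask]
    Xm = np.asarray(X, dtype=float)[mask]
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cov = cov[mask] if cov.ndim > 1 else cov[mask, None]
    n = len(y)
    if n == 0 or np.ptp(y) == 0:
        raise ValueError("phenotype is constant (or empty) after dropping missing")
    Q = _design_basis(n, cov)
    df = n - Q.shape[1] - 1
    if df < 1:
        raise ValueError(f"{n} samples are too few for {Q.shape[1] + 1} parameters")
    return Xm, y, Q, df


def association_scan(X: np.ndarray, phenotype, covariates=None,
                     locus_ids=None) -> pd.DataFrame:
    """Per-locus least-squares association scan.

    ``X`` is the encoded genotype matrix (samples x loci); samples with a
    missing phenotype are dropped.  Returns one row per locus with the
    effect estimate (trait units per presence allele), its standard error,
    t statistic, two-sided p and -log10(p).
    """
    Xm, y, Q, df = _prepare(X, phenotype, covariates)
    Gr = Xm - Q @ (Q.T @ Xm)
    gg = (Gr * Gr).sum(axis=0)
    yr = (y - Q @ (Q.T @ y))[:, None]
    beta, se, p = _bulk_stats(Gr, gg, yr, df)
    m = Xm.shape[1]
    ids = list(locus_ids) if locus_ids is not None else \
        [f"locus{i + 1:05d}" for i in range(m)]
    return pd.DataFrame({
        "locus_id": ids,
        "effect": beta[:, 0],
        "se": se[:, 0],
        "t": np.where(se[:, 0] > 0, beta[:, 0] / se[:, 0], 0.0),
        "p": p[:, 0],
        "minus_log10_p": -np.log10(p[:, 0]),
    })


def permutation_threshold(X: np.ndarray, phenotype, covariates=None,
                          spec: PermutationSpec | None = None) -> float:
    """Permutation-derived genome-wide -log10(p) significance threshold.

    Deterministic under ``spec.seed``.  The quantile uses the type-1
    (order-statistic, lower) convention: with B maxima sorted ascending the
    threshold is element ``ceil((1 - alpha) * B)`` (1-based).
    """
    spec = spec or PermutationSpec()
    if spec.n_permutations * spec.alpha < 1:
        warnings.warn(
            f"{spec.n_permutations} permutations are too few for a stable "
            f"quantile at alpha={spec.alpha}")
    Xm, y, Q, df = _prepare(X, phenotype, covariates)
    n = len(y)
    Gr = Xm - Q @ (Q.T @ Xm)
    gg = (Gr * Gr).sum(axis=0)
    resid = y - Q @ (Q.T @ y)
    base = resid if spec.conditioning == "residual_permutation" else y
    rng = np.random.default_rng(spec.seed)
    idx = np.stack([rng.permutation(n) for _ in range(spec.n_permutations)])
    Y = base[idx].T  # n x B
    Yr = Y - Q @ (Q.T @ Y)
    _, _, p = _bulk_stats(Gr, gg, Yr, df)
    mlp = -np.log10(p)
    if spec.statistic == "max":
        draws = mlp.max(axis=0)
    else:
        draws = mlp.ravel()
    return empirical_quantile(draws, 1.0 - spec.alpha)


def empirical_quantile(values: np.ndarray, q: float) -> float:
    """Type-1 (order-statistic, lower-tie) empirical quantile."""
    vals = np.sort(np.asarray(values, dtype=float))
    k = int(np.ceil(q * len(vals)))
    return float(vals[max(k, 1) - 1])


def call_significant(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Loci whose -log10(p) reaches the threshold, sorted by p ascending."""
    out = results.copy()
    out["significant"] = out["minus_log10_p"] >= threshold
    sig = out[out["significant"]].sort_values(
        ["p", "locus_id"], kind="mergesort").reset_index(drop=True)
    return sig


def map_to_genes(significant: pd.DataFrame, loci: pd.DataFrame,
                 annotation: GeneAnnotation, flank_bp: int = 3000) -> pd.DataFrame:
    """All genes whose span +-flank_bp overlaps each significant locus.

    Insertions are treated as 1 bp breakpoints.  Loci hitting no gene yield
    no rows.
    """
    meta = loci.set_index("locus_id")
    by_chrom = annotation.by_chrom()
    rows = []
    for lid in significant["locus_id"]:
        r = meta.loc[lid]
        s, e = int(r["start"]), int(r["end"])
        if r["svtype"] == "INS":
            e = s
        for g in by_chrom.get(r["chrom"], []):
            if g.start - flank_bp <= e and g.end + flank_bp >= s:
                rows.append({"locus_id": lid, "gene_id": g.gene_id,
                             "gene_chrom": g.chrom, "gene_start": g.start,
                             "gene_end": g.end, "gene_strand": g.strand})
    return pd.DataFrame(rows, columns=["locus_id", "gene_id", "gene_chrom",
                                       "gene_start", "gene_end", "gene_strand"])
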