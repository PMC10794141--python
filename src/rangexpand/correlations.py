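"""Distance matrices, f-statistics, Mantel tests, PCA and Procrustes.

Genetic differentiation is measured with Hudson's FST estimator in its
ratio-of-averages form: per SNP the numerator is
``(p1 - p2)^2 - p1 (1 - p1)/(n1 - 1) - p2 (1 - p2)/(n2 - 1)`` and the
denominator ``p1 (1 - p2) + p2 (1 - p1)``; both are averaged over SNPs
before the ratio is taken.  A Weir-Cockerham estimator is available as a
cross-check.  f3(C; A, B) and f4(A, B; C, D) are allele-frequency
covariance statistics with leave-one-block-out jackknife standard errors;
a negative f3 with a large |Z| is the classic admixture signal in C.

Mantel and partial Mantel tests correlate distance matrices over their
upper triangles, with significance from simultaneous row/column
permutation of one matrix (two-sided).  PCA follows the usual
allele-frequency scaling (centre by 2p, scale by sqrt(p(1-p))), and
Procrustes finds the least-squares similarity transform of one 2-D
configuration onto another with a label-permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import (
    DistanceMatrix,
    GenotypePanel,
    MISSING,
    SampleManifest,
)
from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    LookupError_,
    RangexpandError,
)
from .geo import great_circle_km

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Allele frequencies
# ----------------------------------------------------------------------

def _pop_freqs(panel: GenotypePanel, manifest: SampleManifest,
               populations: list[str]):
    """Per-population alternate-allele frequency and allele count per SNP."""
    panel_samples = set(panel.sample_ids)
    freqs, counts = {}, {}
    for pop in populations:
        samples = [s for s in manifest.samples_of(pop) if s in panel_samples]
        H = panel.haplotypes_of(samples).astype(float)
        H[H == MISSING] = np.nan
        n = np.sum(~np.isnan(H), axis=0)
        with np.errstate(invalid="ignore"):
            p = np.nansum(H, axis=0) / n
        freqs[pop] = p
        counts[pop] = n
    return freqs, counts


# ----------------------------------------------------------------------
# FST
# ----------------------------------------------------------------------

def hudson_fst(p1, n1, p2, n2) -> float:
    """Hudson FST (ratio of averages) from per-SNP freqs and allele counts."""
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    if not ok.any():
        return float("nan")
    a1, a2 = p1[ok], p2[ok]
    m1, m2 = n1[ok], n2[ok]
    num = (a1 - a2) ** 2 - a1 * (1 - a1) / (m1 - 1) - a2 * (1 - a2) / (m2 - 1)
    den = a1 * (1 - a2) + a2 * (1 - a1)
    d = den.mean()
    if d == 0:
        return float("nan")
    return float(num.mean() / d)


def weir_cockerham_fst(p1, n1, p2, n2) -> float:
    """Two-population Weir-Cockerham theta (haploid allele counts).

    Cross-check estimator; a, b variance components computed per SNP from
    allele counts, then summed before the ratio.
    """
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    a1, a2, m1, m2 = p1[ok], p2[ok], n1[ok], n2[ok]
    n_bar = (m1 + m2) / 2
    nc = (m1 + m2 - (m1 ** 2 + m2 ** 2) / (m1 + m2))  # r=2 populations
    p_bar = (m1 * a1 + m2 * a2) / (m1 + m2)
    s2 = (m1 * (a1 - p_bar) ** 2 + m2 * (a2 - p_bar) ** 2) / n_bar
    a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - s2 / 2) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 / 2)
    denom = (a + b).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


def hudson_fst_matrix(panel: GenotypePanel, manifest: SampleManifest,
                      estimator: str = "hudson") -> DistanceMatrix:
    """Pairwise FST matrix between manifest populations present in the panel.

    MISSING alleles are excluded per SNP per population.  A pair with no
    usable SNPs is set to NaN with a warning.
    """
    pops = [p for p in manifest.populations
            if any(s in set(panel.sample_ids)
                   for s in manifest.samples_of(p))]
    if len(pops) < 2:
        raise DegenerateInputError("need >= 2 populations")
    est = {"hudson": hudson_fst, "weir_cockerham": weir_cockerham_fst}
    if estimator not in est:
        raise ValueError(f"unknown estimator {estimator!r}")
    freqs, counts = _pop_freqs(panel, manifest, pops)
    M = np.zeros((len(pops), len(pops)))
    for i, j in combinations(range(len(pops)), 2):
        v = est[estimator](freqs[pops[i]], counts[pops[i]],
                           freqs[pops[j]], counts[pops[j]])
        if np.isnan(v):
            logger.warning("FST pair (%s, %s) has no usable SNPs",
                           pops[i], pops[j])
        M[i, j] = M[j, i] = v
    return DistanceMatrix(pops, M, "fst")


# ----------------------------------------------------------------------
# f3 / f4
# ----------------------------------------------------------------------

@dataclass
class FStatResult:
    statistic: str
    populations: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_blocks: int


def f_statistic(panel: GenotypePanel, manifest: SampleManifest, mode: str,
                pops: list[str], block_snps: int = 100,
                corrected: bool = True) -> FStatResult:
    """f3(C; A, B) or f4(A, B; C, D) with block-jackknife standard errors.

    For f3 the argument order is ``[C, A, B]`` (target first); the
    finite-sample correction ``c (1 - c) / (n_C - 1)`` is subtracted per
    SNP unless ``corrected=False``.  SNPs with an undefined frequency in
    any named population are dropped.
    """
    if mode == "f3":
        if len(pops) != 3:
            raise ValueError("f3 needs [C, A, B]")
    elif mode == "f4":
        if len(pops) != 4:
            raise ValueError("f4 needs [A, B, C, D]")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    freqs, counts = _pop_freqs(panel, manifest, list(dict.fromkeys(pops)))
    ok = np.ones(panel.n_variants, dtype=bool)
    for p in pops:
        ok &= np.isfinite(freqs[p]) & (counts[p] >= (2 if corrected else 1))
    if mode == "f3":
        c, a, b = (freqs[p][ok] for p in pops)
        per_snp = (c - a) * (c - b)
        if corrected:
            nc = counts[pops[0]][ok]
            per_snp = per_snp - c * (1 - c) / (nc - 1)
    else:
        a, b, c, d = (freqs[p][ok] for p in pops)
        per_snp = (a - b) * (c - d)
    n = len(per_snp)
    blocks = [per_snp[k:k + block_snps] for k in range(0, n, block_snps)]
    if len(blocks) < 2:
        raise DegenerateInputError(
            f"{len(blocks)} jackknife block(s); need >= 2")
    estimate = float(per_snp.mean())
    total = per_snp.sum()
    loo = np.array([(total - blk.sum()) / (n - len(blk)) for blk in blocks])
    B = len(blocks)
    se = float(np.sqrt((B - 1) / B * np.sum((loo - loo.mean()) ** 2)))
    z = estimate / se if se > 0 else float("nan")
    return FStatResult(mode, tuple(pops), estimate, se, float(z), B)


# ----------------------------------------------------------------------
# Geographic and linguistic distances
# ----------------------------------------------------------------------

def great_circle_matrix(manifest: SampleManifest) -> DistanceMatrix:
    """Pairwise great-circle km between population coordinates."""
    pops = manifest.populations
    coords = [manifest.coords_of(p) for p in pops]
    M = np.zeros((len(pops), len(pops)))
    for i, j in combinations(range(len(pops)), 2):
        M[i, j] = M[j, i] = great_circle_km(coords[i], coords[j])
    return DistanceMatrix(pops, M, "geographic_km")


def linguistic_distance_matrix(cognates: pd.DataFrame,
                               labels: list[str] | None = None,
                               ) -> DistanceMatrix:
    """Hamming-proportion distances from a multistate cognate matrix.

    Rows are languages, columns meaning slots, entries integer cognate
    states with NaN for missing.  The distance between two languages is
    the proportion of mutually non-missing slots at which their states
    differ; pairs sharing no slot are NaN with a warning.
    """
    if labels is not None:
        missing = set(labels) - set(cognates.index)
        if missing:
            raise LookupError_(f"languages {sorted(missing)} not in matrix")
        cognates = cognates.loc[labels]
    langs = list(cognates.index)
    X = cognates.to_numpy(dtype=float)
    M = np.zeros((len(langs), len(langs)))
    for i, j in combinations(range(len(langs)), 2):
        ok = np.isfinite(X[i]) & np.isfinite(X[j])
        if not ok.any():
            logger.warning("languages %s and %s share no scored slot",
                           langs[i], langs[j])
            M[i, j] = M[j, i] = np.nan
            continue
        M[i, j] = M[j, i] = float(np.mean(X[i][ok] != X[j][ok]))
    return DistanceMatrix(langs, M, "linguistic")


# ----------------------------------------------------------------------
# Mantel / partial Mantel
# ----------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int
    conditioned_on: str | None = None


def _triangle(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _residualise(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def mantel_test(X: DistanceMatrix, Y: DistanceMatrix,
                partial_on: DistanceMatrix | None = None,
                n_perm: int = 9999, seed: int = 0) -> MantelResult:
    """(Partial) Mantel permutation test between two distance matrices.

    r is the Pearson correlation over upper-triangle entries; for the
    partial test both triangles are first residualised on the third
    matrix.  The p-value is two-sided:
    ``(1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm)``, permuting the rows
    and columns of ``X`` simultaneously.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if set(X.labels) != set(Y.labels) or (
            partial_on is not None
            and set(partial_on.labels) != set(X.labels)):
        raise AlignmentError("distance matrices have different labels")
    Yv = Y.reorder(X.labels).values
    Zv = (partial_on.reorder(X.labels).values
          if partial_on is not None else None)
    rng = np.random.default_rng(seed)
    n = len(X.labels)

    def corr(xmat: np.ndarray) -> float:
        x = _triangle(xmat)
        y = _triangle(Yv)
        if Zv is not None:
            z = _triangle(Zv)
            x = _residualise(x, z)
            y = _residualise(y, z)
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(X.values)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr(X.values[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed,
                        conditioned_on=(partial_on.kind
                                        if partial_on is not None else None))


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

def genotype_pca(panel: GenotypePanel, n_components: int = 10):
    """PCA of diploid genotypes with allele-frequency scaling.

    Genotypes (0/1/2 alternate-allele dosages) are mean-imputed per SNP,
    centred by ``2p`` and scaled by ``sqrt(p (1 - p))``; all-MISSING and
    monomorphic SNPs are dropped with a warning.  Returns a DataFrame of
    sample coordinates (eigenvector * singular value) and the eigenvalues
    of the sample covariance.  The sign of each component is fixed by
    making its largest-magnitude SNP loading positive, so repeated runs
    are identical.
    """
    if panel.n_samples < 3:
        raise DegenerateInputError("PCA needs >= 3 samples")
    H = panel.haplotypes.astype(float)
    H[H == MISSING] = np.nan
    G = H[0::2] + H[1::2]                      # (n_samples, L) dosages
    p = np.nanmean(G, axis=0) / 2.0
    drop = ~np.isfinite(p) | (p <= 0) | (p >= 1)
    if drop.any():
        logger.warning("dropping %d all-missing/monomorphic SNPs from PCA",
                       int(drop.sum()))
    G = G[:, ~drop]
    p = p[~drop]
    if G.shape[1] == 0:
        raise RangexpandError("no polymorphic SNPs left for PCA")
    col_mean = 2 * p
    X = np.where(np.isnan(G), col_mean, G) - col_mean
    X /= np.sqrt(p * (1 - p))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for comp in range(k):
        j = int(np.argmax(np.abs(Vt[comp])))
        if Vt[comp, j] < 0:
            Vt[comp] *= -1
            U[:, comp] *= -1
    coords = pd.DataFrame(
        U * S, index=panel.sample_ids,
        columns=[f"PC{c + 1}" for c in range(k)])
    eigenvalues = S ** 2 / (panel.n_samples - 1)
    return coords, eigenvalues


# ----------------------------------------------------------------------
# Procrustes
# ----------------------------------------------------------------------

@dataclass
class ProcrustesResult:
    rotation: np.ndarray          # 2x2 orthogonal
    scale: float
    translation: np.ndarray       # length-2
    correlation: float
    perm_p: float

    def transform(self, A: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(A) @ self.rotation + self.translation


def procrustes_fit(A: np.ndarray, B: np.ndarray, n_perm: int = 999,
                   seed: int = 0) -> ProcrustesResult:
    """Least-squares similarity transform of configuration A onto B.

    Minimises ``||s A R + t - B||^2`` over rotation/reflection R, scale s
    and translation t via the singular-value solution.  The Procrustes
    correlation is ``sqrt(1 - SS_min / SS_B)``; the p-value permutes the
    row correspondence of A.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 2:
        raise ValueError("A and B must be matching (n, 2) configurations")
    if A.shape[0] < 3:
        raise DegenerateInputError("Procrustes needs >= 3 points")

    def fit_stat(Ax: np.ndarray):
        Ac = Ax - Ax.mean(axis=0)
        Bc = B - B.mean(axis=0)
        ssA = float((Ac ** 2).sum())
        ssB = float((Bc ** 2).sum())
        U, S, Vt = np.linalg.svd(Ac.T @ Bc)
        corr = float(S.sum() / np.sqrt(ssA * ssB))
        return Ac, Bc, U, S, Vt, ssA, corr

    Ac, Bc, U, S, Vt, ssA, corr = fit_stat(A)
    R = U @ Vt
    s = float(S.sum() / ssA)
    t = B.mean(axis=0) - s * A.mean(axis=0) @ R
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(A.shape[0])
        if fit_stat(A[perm])[-1] >= corr - 1e-12:
            hits += 1
    return ProcrustesResult(rotation=R, scale=s, translation=t,
                            correlation=corr,
                            perm_p=(1 + hits) / (1 + n_perm))
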