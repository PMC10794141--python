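"""Haplotype diversity, LD decay, ROH calling, and decline-with-distance.

These are the statistics that discriminate a serial-founder expansion from
an equilibrium isolation-by-distance regime: under serial founding,
haplotype richness and heterozygosity decay with distance from the origin
while background LD rises, whereas a stepping-stone equilibrium shows
distance-structured differentiation without an origin-anchored diversity
cline.

Richness is rarefied to a common number of gene copies ``g`` by Monte-Carlo
subsampling (default ten repetitions), computed in non-overlapping windows
of ``window_snps`` consecutive SNPs per chromosome and averaged across
windows and chromosomes.  Heterozygosity uses the unbiased estimator
``(n / (n - 1)) (1 - sum p_h^2)`` over within-window haplotype frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypePanel, MISSING, RegressionResult, SampleManifest
from .exceptions import DegenerateInputError, RangexpandError, RarefactionError
from .geo import great_circle_km

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Window helpers
# ----------------------------------------------------------------------

def _windows(panel: GenotypePanel, window_snps: int):
    """Yield column index arrays of complete windows, per chromosome."""
    for chrom, sl in panel.chrom_slices().items():
        start, stop = sl.start, sl.stop
        for w0 in range(start, stop - window_snps + 1, window_snps):
            yield chrom, np.arange(w0, w0 + window_snps)


def _pop_hap_rows(panel: GenotypePanel, manifest: SampleManifest,
                  population: str) -> np.ndarray:
    samples = [s for s in manifest.samples_of(population)
               if s in set(panel.sample_ids)]
    return panel.haplotypes_of(samples)


# ----------------------------------------------------------------------
# Haplotype richness (rarefied) and heterozygosity
# ----------------------------------------------------------------------

def haplotype_richness(panel: GenotypePanel, manifest: SampleManifest,
                       window_snps: int = 20, g: int = 20,
                       reps: int = 10, seed: int = 0) -> pd.Series:
    """Mean rarefied number of distinct haplotypes per window, per population.

    Within each window, ``g`` haplotypes are subsampled without replacement
    ``reps`` times and the distinct-row count averaged.  Haplotypes with a
    masked (MISSING) allele in the window are not eligible for that window;
    windows with fewer than ``g`` eligible haplotypes are skipped.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for pop in manifest.populations:
        H = _pop_hap_rows(panel, manifest, pop)
        if H.shape[0] < g:
            raise RarefactionError(
                f"population {pop!r} has {H.shape[0]} haplotypes; "
                f"cannot rarefy to g={g}")
        vals = []
        for _chrom, cols in _windows(panel, window_snps):
            W = H[:, cols]
            ok = ~(W == MISSING).any(axis=1)
            W = W[ok]
            if W.shape[0] < g:
                continue
            mean_distinct = 0.0
            for _ in range(reps):
                sel = rng.choice(W.shape[0], g, replace=False)
                mean_distinct += len({W[i].tobytes() for i in sel})
            vals.append(mean_distinct / reps)
        if not vals:
            raise RangexpandError(
                f"no usable windows for population {pop!r}")
        out[pop] = float(np.mean(vals))
    return pd.Series(out, name="haplotype_richness")


def haplotype_heterozygosity(panel: GenotypePanel, manifest: SampleManifest,
                             window_snps: int = 20) -> pd.Series:
    """Unbiased per-window haplotype heterozygosity, genome-averaged."""
    out = {}
    for pop in manifest.populations:
        H = _pop_hap_rows(panel, manifest, pop)
        if H.shape[0] < 2:
            raise DegenerateInputError(
                f"population {pop!r} has fewer than 2 haplotypes")
        vals = []
        for chrom, cols in _windows(panel, window_snps):
            W = H[:, cols]
            W = W[~(W == MISSING).any(axis=1)]
            n = W.shape[0]
            if n < 2:
                logger.info("window on %s skipped for %s (all-MISSING)",
                            chrom, pop)
                continue
            _, counts = np.unique(W, axis=0, return_counts=True)
            p = counts / n
            vals.append((n / (n - 1)) * (1.0 - np.sum(p ** 2)))
        if not vals:
            raise RangexpandError(
                f"no usable windows for population {pop!r}")
        out[pop] = float(np.mean(vals))
    return pd.Series(out, name="haplotype_heterozygosity")


# ----------------------------------------------------------------------
# LD decay
# ----------------------------------------------------------------------

def ld_decay(panel: GenotypePanel, manifest: SampleManifest,
             max_bp: int = 500_000,
             bins: np.ndarray | None = None) -> dict[str, pd.DataFrame]:
    """Mean r^2 between SNP pairs within ``max_bp``, binned by bp distance.

    r^2 is the squared Pearson correlation of haplotype allele indicators;
    MISSING entries are handled pairwise-complete.  Pairs involving a
    monomorphic SNP (among complete haplotypes) are skipped.
    """
    if bins is None:
        bins = np.linspace(0, max_bp, 11)
    bins = np.asarray(bins, dtype=float)
    result: dict[str, pd.DataFrame] = {}
    slices = panel.chrom_slices()
    bp_all = panel.variants["pos_bp"].to_numpy()
    for pop in manifest.populations:
        H = _pop_hap_rows(panel, manifest, pop).astype(float)
        if H.shape[0] < 4:
            raise DegenerateInputError(
                f"population {pop!r} has fewer than 4 haplotypes")
        H[H == MISSING] = np.nan
        dists, r2s = [], []
        for _chrom, sl in slices.items():
            bp = bp_all[sl]
            Hc = H[:, sl]
            for i in range(len(bp)):
                j_hi = np.searchsorted(bp, bp[i] + max_bp, side="right")
                for j in range(i + 1, j_hi):
                    x, y = Hc[:, i], Hc[:, j]
                    ok = ~(np.isnan(x) | np.isnan(y))
                    if ok.sum() < 4:
                        continue
                    xv, yv = x[ok], y[ok]
                    if xv.std() == 0 or yv.std() == 0:
                        continue
                    r = np.corrcoef(xv, yv)[0, 1]
                    dists.append(bp[j] - bp[i])
                    r2s.append(r * r)
        dists = np.asarray(dists)
        r2s = np.asarray(r2s)
        rows = []
        for k in range(len(bins) - 1):
            sel = (dists >= bins[k]) & (dists < bins[k + 1])
            rows.append((bins[k], bins[k + 1],
                         float(np.mean(r2s[sel])) if sel.any() else np.nan,
                         int(sel.sum())))
        result[pop] = pd.DataFrame(
            rows, columns=["bin_lo_bp", "bin_hi_bp", "mean_r2", "n_pairs"])
    return result


# ----------------------------------------------------------------------
# Runs of homozygosity
# ----------------------------------------------------------------------

#: ROH length class edges in Mb (half-open; final class is > 8 Mb).
ROH_CLASS_EDGES_MB = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, np.inf)
#: Short/long split in Mb.
ROH_SHORT_LONG_MB = 1.6


@dataclass
class ROHSummary:
    """Per-individual ROH segments and the five summary parameters.

    ``segments``: columns sample_id, chrom, start_bp, end_bp (half-open).
    ``per_individual``: mean_roh_size, total_roh_length, sum_short,
    sum_long, F_ROH, and the six length-class sums ``class_1`` ...
    ``class_6`` (bp), which total ``total_roh_length`` exactly.
    """

    segments: pd.DataFrame
    per_individual: pd.DataFrame


def call_roh(panel: GenotypePanel, min_snps: int = 50, min_kb: float = 500.0,
             het_allowance: int = 1) -> ROHSummary:
    """Call runs of homozygosity from paired haplotypes.

    Each sample's two haplotypes are paired into diploid genotypes; a run
    is a greedy left-to-right maximal stretch of consecutive SNPs
    containing at most ``het_allowance`` heterozygous calls (sites with a
    MISSING allele neither extend nor break a run's het count), reported
    when it spans at least ``min_snps`` SNPs and ``min_kb`` kb.
    """
    if "pos_bp" not in panel.variants.columns:
        raise RangexpandError("panel has no bp positions")
    bp_all = panel.variants["pos_bp"].to_numpy()
    slices = panel.chrom_slices()
    map_len = sum(int(bp_all[sl.stop - 1]) + 1 - int(bp_all[sl.start])
                  for sl in slices.values())
    seg_rows = []
    ind_rows = []
    for i, sid in enumerate(panel.sample_ids):
        h0 = panel.haplotypes[2 * i]
        h1 = panel.haplotypes[2 * i + 1]
        called = (h0 != MISSING) & (h1 != MISSING)
        het = called & (h0 != h1)
        segs: list[tuple[str, int, int]] = []
        for chrom, sl in slices.items():
            segs.extend(
                (chrom, s, e) for s, e in
                _greedy_runs(bp_all[sl], het[sl],
                             min_snps, min_kb * 1000.0, het_allowance))
        lengths = np.array([e - s for _c, s, e in segs], dtype=float)
        total = float(lengths.sum())
        class_sums = []
        for k in range(len(ROH_CLASS_EDGES_MB) - 1):
            lo = ROH_CLASS_EDGES_MB[k] * 1e6
            hi = ROH_CLASS_EDGES_MB[k + 1] * 1e6
            class_sums.append(float(lengths[(lengths >= lo)
                                            & (lengths < hi)].sum()))
        ind_rows.append({
            "sample_id": sid,
            "n_segments": len(segs),
            "mean_roh_size": float(lengths.mean()) if len(segs) else 0.0,
            "total_roh_length": total,
            "sum_short": float(
                lengths[lengths < ROH_SHORT_LONG_MB * 1e6].sum()),
            "sum_long": float(
                lengths[lengths >= ROH_SHORT_LONG_MB * 1e6].sum()),
            "F_ROH": total / map_len,
            **{f"class_{k + 1}": class_sums[k] for k in range(6)},
        })
        seg_rows.extend((sid, c, s, e) for c, s, e in segs)
    return ROHSummary(
        segments=pd.DataFrame(
            seg_rows, columns=["sample_id", "chrom", "start_bp", "end_bp"]),
        per_individual=pd.DataFrame(ind_rows),
    )


def _greedy_runs(bp: np.ndarray, het: np.ndarray, min_snps: int,
                 min_bp: float, allowance: int):
    """Greedy scan for qualifying homozygous runs on one chromosome."""
    out = []
    start = 0
    het_positions: list[int] = []
    i = 0
    n = len(bp)
    while i <= n:
        over = i < n and het[i] and len(het_positions) >= allowance
        if i == n or over:
            end = i - 1
            # trim trailing het calls off the run
            while end >= start and het[end]:
                end -= 1
            if end >= start:
                n_snps = end - start + 1
                span = int(bp[end]) + 1 - int(bp[start])
                if n_snps >= min_snps and span >= min_bp:
                    out.append((int(bp[start]), int(bp[end]) + 1))
            if i == n:
                break
            start = i + 1
            het_positions = []
        elif het[i]:
            het_positions.append(i)
        i += 1
    return out


# ----------------------------------------------------------------------
# Decline with distance from the origin
# ----------------------------------------------------------------------

def diversity_distance_regression(values: pd.Series | dict,
                                  manifest: SampleManifest,
                                  origin: tuple[float, float],
                                  ) -> RegressionResult:
    """OLS of a per-population statistic on great-circle km from an origin.

    Returns slope, intercept, r^2 and the two-sided t-test p-value on the
    slope.  A constant statistic yields slope 0, r^2 = 0, p = 1.
    """
    values = pd.Series(values)
    pops = [p for p in values.index if p in manifest.populations]
    if len(pops) < 3:
        raise DegenerateInputError(
            f"need >= 3 populations with coordinates, have {len(pops)}")
    d = np.array([great_circle_km(origin, manifest.coords_of(p))
                  for p in pops])
    y = values[pops].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(pops), 0.0)
    fit = stats.linregress(d, y)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2), p=float(fit.pvalue), n=len(pops),
        slope_se=float(fit.stderr))


def diversity_table(panel: GenotypePanel, manifest: SampleManifest,
                    window_snps: int = 20, g: int = 20, reps: int = 10,
                    seed: int = 0) -> pd.DataFrame:
    """Per-population richness, heterozygosity and diploid count."""
    rich = haplotype_richness(panel, manifest, window_snps, g, reps, seed)
    het = haplotype_heterozygosity(panel, manifest, window_snps)
    n_used = pd.Series({p: len(manifest.samples_of(p))
                        for p in manifest.populations}, name="n_used")
    return pd.DataFrame({"haplotype_richness": rich,
                         "haplotype_heterozygosity": het,
                         "n_used": n_used})
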