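"""Local-ancestry masking, ancestry-fraction filtering and tract dating.

Masking removes every allele lying inside a non-target ancestry tract from
each haploid genome, leaving a panel that carries only the target (by
default west-central-African-related, "WCA") ancestry.  Populations are
then filtered to those whose mean target-ancestry fraction reaches a
threshold (default 70 %) and downsampled to a common maximum size.

Admixture dating uses the exponential tract-length estimator: ``t``
generations after a single admixture pulse contributing a fraction ``m``
of non-target ancestry, non-target tract lengths are approximately
exponential with mean ``1 / ((1 - m) t)`` Morgans, so

    t_hat = 1 / ((1 - m_hat) * mean tract length in Morgans),

where ``m_hat`` is the cM-weighted mean non-target fraction.  Tracts that
touch a chromosome end are censored (their true length is unobserved) and
are excluded from the mean; confidence intervals come from a percentile
bootstrap over haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    AncestryTractSet,
    GenotypePanel,
    MISSING,
    RegressionResult,
    SampleManifest,
)
from .exceptions import (
    CoverageError,
    DatingError,
    EmptyDatasetError,
    RangexpandError,
)
from .diversity import diversity_distance_regression

logger = logging.getLogger(__name__)


def haplotype_ids_of(sample_id: str) -> tuple[str, str]:
    """The two haplotype ids of a sample (``<id>_h0``, ``<id>_h1``)."""
    return f"{sample_id}_h0", f"{sample_id}_h1"


# ----------------------------------------------------------------------
# Masking
# ----------------------------------------------------------------------

def mask_by_ancestry(panel: GenotypePanel, tracts: AncestryTractSet,
                     target: str = "WCA",
                     ) -> tuple[GenotypePanel, pd.Series]:
    """Mask non-target-ancestry alleles; return the panel and fractions.

    For every haplotype present in the tract set, alleles at variant
    positions inside non-target tracts are set to MISSING.  The returned
    per-sample fraction is the cM-weighted target share of each
    haplotype, averaged over the sample's two haplotypes.  Samples with
    no tracts are left untouched and receive no fraction.  Tracts must
    cover every variant position of a masked haplotype.
    """
    masked = panel.copy()
    tract_haps = set(tracts.haplotype_ids)
    slices = masked.chrom_slices()
    bp = masked.variants["pos_bp"].to_numpy()
    fractions: dict[str, float] = {}
    for i, sid in enumerate(masked.sample_ids):
        hap_ids = haplotype_ids_of(sid)
        if not any(h in tract_haps for h in hap_ids):
            continue
        hap_fracs = []
        for h, hap_id in enumerate(hap_ids):
            sub = tracts.for_haplotype(hap_id)
            if sub.empty:
                raise CoverageError(
                    f"haplotype {hap_id} has no tracts but its mate does")
            row = 2 * i + h
            total_cM = 0.0
            target_cM = 0.0
            for chrom, sl in slices.items():
                t = sub[sub["chrom"] == chrom]
                pos = bp[sl]
                covered = np.zeros(len(pos), dtype=bool)
                for _, tr in t.iterrows():
                    inside = (pos >= tr["start_bp"]) & (pos < tr["end_bp"])
                    covered |= inside
                    span = float(tr["end_cM"] - tr["start_cM"])
                    total_cM += span
                    if tr["ancestry"] == target:
                        target_cM += span
                    else:
                        cols = np.flatnonzero(inside) + sl.start
                        masked.haplotypes[row, cols] = MISSING
                if not covered.all():
                    missing_pos = pos[~covered][:5]
                    raise CoverageError(
                        f"haplotype {hap_id}: positions not covered by "
                        f"tracts on {chrom}: {list(missing_pos)}"
                        + ("..." if (~covered).sum() > 5 else ""))
            hap_fracs.append(target_cM / total_cM if total_cM else 0.0)
        fractions[sid] = float(np.mean(hap_fracs))
    return masked, pd.Series(fractions, name="target_fraction")


def prepare_masked_dataset(panel: GenotypePanel, fractions: pd.Series,
                           manifest: SampleManifest,
                           min_fraction: float = 0.70, min_n: int = 10,
                           max_n: int = 30, seed: int = 0) -> GenotypePanel:
    """Filter and downsample the masked panel for downstream analyses.

    Populations whose mean target-ancestry fraction is below
    ``min_fraction``, or with fewer than ``min_n`` samples, are dropped
    (populations with no fraction information at all are dropped too);
    populations larger than ``max_n`` are randomly downsampled to
    ``max_n`` without replacement, preserving panel row order.
    """
    rng = np.random.default_rng(seed)
    panel_samples = set(panel.sample_ids)
    keep: list[str] = []
    for pop in manifest.populations:
        samples = [s for s in manifest.samples_of(pop)
                   if s in panel_samples]
        with_frac = [s for s in samples if s in fractions.index]
        if not with_frac:
            continue
        mean_frac = float(fractions[with_frac].mean())
        if mean_frac < min_fraction or len(samples) < min_n:
            continue
        if len(samples) > max_n:
            sel = rng.choice(len(samples), max_n, replace=False)
            samples = [samples[k] for k in sorted(sel)]
        keep.extend(samples)
    if not keep:
        raise EmptyDatasetError(
            "no population passes the ancestry-fraction/size filters")
    return panel.subset_samples(keep)


# ----------------------------------------------------------------------
# Tract-length dating
# ----------------------------------------------------------------------

@dataclass
class AdmixtureDate:
    population: str
    t_hat: float                  # generations ago
    m_hat: float                  # non-target ancestry fraction
    n_tracts: int                 # uncensored non-target tracts used
    ci: tuple[float, float]       # percentile bootstrap interval on t_hat


def _chrom_spans(tracts: AncestryTractSet) -> dict[str, tuple[int, int]]:
    g = tracts.table.groupby("chrom")
    return {c: (int(lo), int(hi)) for c, lo, hi in
            zip(g.groups, g["start_bp"].min(), g["end_bp"].max())}


def date_admixture_from_tracts(tracts: AncestryTractSet,
                               target: str = "WCA",
                               population: str = "",
                               min_tracts: int = 20,
                               n_boot: int = 200,
                               seed: int = 0) -> AdmixtureDate:
    """Date a single admixture pulse from pooled non-target tract lengths."""
    t = tracts.table
    spans = _chrom_spans(tracts)
    lo = t["chrom"].map(lambda c: spans[c][0]).to_numpy()
    hi = t["chrom"].map(lambda c: spans[c][1]).to_numpy()
    censored = (t["start_bp"].to_numpy() <= lo) | (t["end_bp"].to_numpy() >= hi)
    nontarget = (t["ancestry"] != target).to_numpy()
    if not nontarget.any():
        raise DatingError(
            f"population {population!r} has no non-target tracts "
            "(unadmixed)")
    usable = nontarget & ~censored
    if usable.sum() < min_tracts:
        raise DatingError(
            f"{int(usable.sum())} uncensored non-target tracts pooled; "
            f"need >= {min_tracts}")
    length_M = (t["end_cM"] - t["start_cM"]).to_numpy() / 100.0

    # per-haplotype sufficient statistics, so the bootstrap honours
    # multiplicity when haplotypes are resampled with replacement
    haps = tracts.haplotype_ids
    hap_idx = {h: k for k, h in enumerate(haps)}
    rows = t["haplotype_id"].map(hap_idx).to_numpy()
    tot_M = np.zeros(len(haps))
    nt_M = np.zeros(len(haps))
    use_sum = np.zeros(len(haps))
    use_n = np.zeros(len(haps))
    np.add.at(tot_M, rows, length_M)
    np.add.at(nt_M, rows[nontarget], length_M[nontarget])
    np.add.at(use_sum, rows[usable], length_M[usable])
    np.add.at(use_n, rows[usable], 1.0)

    def estimate(weights: np.ndarray) -> tuple[float, float] | None:
        tot = float(weights @ tot_M)
        n_use = float(weights @ use_n)
        if tot == 0 or n_use == 0:
            return None
        m_hat = float(weights @ nt_M) / tot
        if m_hat >= 1.0:
            return None
        L_bar = float(weights @ use_sum) / n_use
        return 1.0 / ((1.0 - m_hat) * L_bar), m_hat

    point = estimate(np.ones(len(haps)))
    if point is None:
        raise DatingError("dating estimate undefined")
    t_hat, m_hat = point
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        draw = rng.integers(0, len(haps), len(haps))
        w = np.bincount(draw, minlength=len(haps)).astype(float)
        est = estimate(w)
        if est is not None:
            boots.append(est[0])
    ci = (float(np.percentile(boots, 2.5)),
          float(np.percentile(boots, 97.5))) if boots else (np.nan, np.nan)
    return AdmixtureDate(population=population, t_hat=float(t_hat),
                         m_hat=float(m_hat), n_tracts=int(usable.sum()),
                         ci=ci)


def date_all_populations(tracts: AncestryTractSet,
                         manifest: SampleManifest, target: str = "WCA",
                         min_tracts: int = 20, n_boot: int = 200,
                         seed: int = 0) -> list[AdmixtureDate]:
    """Per-population dating; populations that cannot be dated are skipped."""
    sample_of_hap = {}
    for sid in manifest.table["sample_id"]:
        for hap in haplotype_ids_of(sid):
            sample_of_hap[hap] = sid
    pop_of = dict(zip(manifest.table["sample_id"],
                      manifest.table["population"]))
    dates = []
    by_pop: dict[str, list[str]] = {}
    for hap in tracts.haplotype_ids:
        sid = sample_of_hap.get(hap)
        if sid is None:
            raise RangexpandError(f"haplotype {hap} not in manifest")
        by_pop.setdefault(pop_of[sid], []).append(hap)
    for pop, haps in by_pop.items():
        sub = AncestryTractSet(
            tracts.table[tracts.table["haplotype_id"].isin(haps)].copy())
        try:
            dates.append(date_admixture_from_tracts(
                sub, target=target, population=pop,
                min_tracts=min_tracts, n_boot=n_boot, seed=seed))
        except DatingError as exc:
            logger.info("population %s not dated: %s", pop, exc)
    return dates


def date_distance_regression(dates: list[AdmixtureDate],
                             manifest: SampleManifest,
                             origin: tuple[float, float],
                             ) -> RegressionResult:
    """OLS of admixture date (generations ago) on km from the origin.

    The signed slope is reported as-is; under an expansion with
    progressively later admixture away from the homeland the slope of
    generations-ago on distance is negative.
    """
    values = pd.Series({d.population: d.t_hat for d in dates})
    return diversity_distance_regression(values, manifest, origin)
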