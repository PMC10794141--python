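"""Core in-memory containers shared across the toolkit.

The central object is the :class:`GenotypePanel`: a phased, biallelic SNP
panel stored as a haplotype matrix with two rows per diploid sample, plus a
variant table carrying physical (bp) and genetic (cM) positions.  Sample
metadata (population membership, coordinates, linguistic grouping, QC flags)
lives in a :class:`SampleManifest`.  Symmetric labelled distance matrices
(genetic, geographic or linguistic) are :class:`DistanceMatrix` objects, and
per-haplotype local-ancestry intervals are an :class:`AncestryTractSet`.

All genomic intervals are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, LookupError_, RangexpandError

#: Sentinel for a masked / missing allele in a haplotype matrix.
MISSING: int = -1

#: Valid linguistic group labels for manifest rows.
LINGUISTIC_GROUPS = ("NW-BSP2", "WW-BSP", "SW-BSP", "E-BSP", "non-BSP")

#: Valid QC flags.
QC_FLAGS = ("low_call_rate", "kin_excluded")

#: Valid local-ancestry labels.
ANCESTRY_LABELS = ("WCA", "wRHG", "KhoeSan", "AfroAsiatic", "other")


@dataclass
class GenotypePanel:
    """Phased biallelic SNP haplotypes for a set of diploid samples.

    Parameters
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``chrom`` (str), ``pos_bp`` (int,
        strictly increasing within each chromosome) and ``pos_cM`` (float,
        non-decreasing within each chromosome).
    haplotypes : numpy.ndarray
        ``int8`` matrix of shape ``(2 * n_samples, n_variants)`` with entries
        in ``{0, 1, MISSING}``.  Rows ``2*i`` and ``2*i + 1`` are the two
        phased haplotypes of sample ``i``.
    sample_ids : list of str
        Ordered, unique sample identifiers.
    """

    variants: pd.DataFrame
    haplotypes: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        return list(dict.fromkeys(self.variants["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        """Column slice of each chromosome (variants are chrom-contiguous)."""
        out: dict[str, slice] = {}
        chroms = self.variants["chrom"].to_numpy()
        for c in self.chromosomes:
            idx = np.flatnonzero(chroms == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def validate(self) -> None:
        required = {"chrom", "pos_bp", "pos_cM"}
        if not required.issubset(self.variants.columns):
            raise RangexpandError(
                f"variant table must have columns {sorted(required)}"
            )
        if self.haplotypes.ndim != 2:
            raise RangexpandError("haplotype matrix must be 2-D")
        n_hap, n_var = self.haplotypes.shape
        if n_hap != 2 * len(self.sample_ids):
            raise RangexpandError(
                f"{n_hap} haplotype rows for {len(self.sample_ids)} samples; "
                "expected exactly two per diploid sample"
            )
        if n_var != len(self.variants):
            raise RangexpandError(
                f"haplotype matrix has {n_var} columns but the variant table "
                f"has {len(self.variants)} rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise RangexpandError("sample ids must be unique")
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING))
        if bad.any():
            raise RangexpandError("haplotype entries must be 0, 1 or MISSING")
        for c, sl in self.chrom_slices().items():
            bp = self.variants["pos_bp"].to_numpy()[sl]
            cm = self.variants["pos_cM"].to_numpy()[sl]
            if len(bp) > 1 and not (np.diff(bp) > 0).all():
                raise RangexpandError(f"pos_bp not strictly increasing on {c}")
            if len(cm) > 1 and not (np.diff(cm) >= 0).all():
                raise RangexpandError(f"pos_cM decreasing on {c}")

    # -- selection helpers ----------------------------------------------
    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise LookupError_(f"sample {sample_id!r} not in panel") from None

    def subset_samples(self, keep: list[str]) -> "GenotypePanel":
        """New panel restricted to ``keep``, preserving panel row order."""
        keep_set = set(keep)
        ids = [s for s in self.sample_ids if s in keep_set]
        rows = np.concatenate(
            [[2 * self.sample_ids.index(s), 2 * self.sample_ids.index(s) + 1]
             for s in ids]
        ) if ids else np.empty(0, dtype=int)
        return GenotypePanel(
            variants=self.variants.copy(),
            haplotypes=self.haplotypes[rows.astype(int)],
            sample_ids=ids,
        )

    def haplotypes_of(self, sample_ids: list[str]) -> np.ndarray:
        """Haplotype rows (2 per sample) for the given samples, in order."""
        rows = []
        for s in sample_ids:
            i = self.sample_index(s)
            rows.extend((2 * i, 2 * i + 1))
        return self.haplotypes[rows]

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            self.variants.copy(), self.haplotypes.copy(), list(self.sample_ids)
        )

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True))
            and np.array_equal(self.haplotypes, other.haplotypes)
        )


@dataclass
class SampleManifest:
    """Sample metadata table.

    Columns: ``sample_id``, ``population``, ``country``,
    ``linguistic_group``, ``latitude``, ``longitude``, ``qc_flags``
    (a ``set`` of flag strings, possibly empty).  Each population has a
    single coordinate pair.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        required = {"sample_id", "population", "country", "linguistic_group",
                    "latitude", "longitude", "qc_flags"}
        missing = required - set(self.table.columns)
        if missing:
            raise RangexpandError(f"manifest missing columns {sorted(missing)}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise RangexpandError(f"duplicate sample id {dup!r}")
        if ((t["latitude"] < -90) | (t["latitude"] > 90)).any():
            raise RangexpandError("latitude outside [-90, 90]")
        if ((t["longitude"] < -180) | (t["longitude"] > 180)).any():
            raise RangexpandError("longitude outside [-180, 180]")
        bad_grp = set(t["linguistic_group"]) - set(LINGUISTIC_GROUPS)
        if bad_grp:
            raise RangexpandError(f"unknown linguistic groups {sorted(bad_grp)}")
        for flags in t["qc_flags"]:
            if not isinstance(flags, (set, frozenset)):
                raise RangexpandError("qc_flags must be sets")
            if set(flags) - set(QC_FLAGS):
                raise RangexpandError(f"unknown qc flags {sorted(flags)}")
        coords = t.groupby("population")[["latitude", "longitude"]].nunique()
        multi = coords[(coords > 1).any(axis=1)]
        if len(multi):
            raise RangexpandError(
                f"population(s) with >1 coordinate: {list(multi.index)}"
            )

    # -- lookups ---------------------------------------------------------
    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    def samples_of(self, population: str) -> list[str]:
        sel = self.table["population"] == population
        if not sel.any():
            raise LookupError_(f"population {population!r} not in manifest")
        return list(self.table.loc[sel, "sample_id"])

    def population_of(self, sample_id: str) -> str:
        sel = self.table["sample_id"] == sample_id
        if not sel.any():
            raise LookupError_(f"sample {sample_id!r} not in manifest")
        return str(self.table.loc[sel, "population"].iloc[0])

    def coords_of(self, population: str) -> tuple[float, float]:
        """(latitude, longitude) of a population."""
        sel = self.table["population"] == population
        if not sel.any():
            raise LookupError_(f"population {population!r} not in manifest")
        row = self.table.loc[sel].iloc[0]
        return float(row["latitude"]), float(row["longitude"])

    def subset(self, sample_ids: list[str]) -> "SampleManifest":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleManifest(keep.copy())


@dataclass
class QCReport:
    """Bookkeeping of the sample-exclusion ledger."""

    n_input: int
    n_removed_call_rate: int
    n_removed_kinship: int
    n_retained: int

    def __post_init__(self) -> None:
        counts = (self.n_input, self.n_removed_call_rate,
                  self.n_removed_kinship, self.n_retained)
        if any(c < 0 for c in counts):
            raise RangexpandError("QC counts must be non-negative")
        if self.n_retained != (self.n_input - self.n_removed_call_rate
                               - self.n_removed_kinship):
            raise RangexpandError("QC counts do not sum")


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix.

    ``kind`` is one of ``fst``, ``geographic_km`` or ``linguistic``.
    """

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise RangexpandError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} labels")
        finite = np.isfinite(self.values)
        both = finite & finite.T
        if not np.allclose(self.values[both],
                           self.values.T[both], atol=1e-12):
            raise RangexpandError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise RangexpandError("distance matrix diagonal not zero")

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        """Same matrix with rows/columns in the given label order."""
        missing = set(labels) - set(self.labels)
        if missing:
            raise AlignmentError(f"labels {sorted(missing)} absent")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels),
                              self.values[np.ix_(idx, idx)], self.kind)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (i < j) order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class AncestryTractSet:
    """Per-haplotype local-ancestry intervals (0-based, half-open).

    Stored as a table with columns ``haplotype_id``, ``chrom``,
    ``start_bp``, ``end_bp``, ``start_cM``, ``end_cM``, ``ancestry``.
    Haplotype ids follow the ``"<sample>_h0" / "<sample>_h1"`` convention
    used when tracts accompany a :class:`GenotypePanel`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"haplotype_id", "chrom", "start_bp", "end_bp",
                    "start_cM", "end_cM", "ancestry"}
        missing = required - set(self.table.columns)
        if missing:
            raise RangexpandError(f"tract table missing {sorted(missing)}")
        self.table = self.table.sort_values(
            ["haplotype_id", "chrom", "start_bp"]).reset_index(drop=True)
        for (hap, chrom), grp in self.table.groupby(
                ["haplotype_id", "chrom"], sort=False):
            s = grp["start_bp"].to_numpy()
            e = grp["end_bp"].to_numpy()
            if (e <= s).any():
                raise RangexpandError(
                    f"empty/negative tract on {hap} {chrom}")
            if (s[1:] < e[:-1]).any():
                raise RangexpandError(
                    f"overlapping tracts on {hap} {chrom}")

    @property
    def haplotype_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["haplotype_id"]))

    def for_haplotype(self, haplotype_id: str) -> pd.DataFrame:
        return self.table[self.table["haplotype_id"] == haplotype_id]

    def ancestries(self) -> set[str]:
        return set(self.table["ancestry"])


@dataclass
class RegressionResult:
    """Ordinary least-squares fit of a statistic on distance from an origin."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    slope_se: float = field(default=float("nan"))
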