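"""Readers and writers for the on-disk formats, and the QC sample ledger.

Supported formats
-----------------
* PLINK text ``.ped``/``.map`` pairs (space-delimited, phased allele order,
  missing allele code ``"0"``, alleles coded ``1`` = reference/0 and
  ``2`` = alternate/1).
* A phased TSV genotype dialect: one row per variant, two columns per
  sample (``<id>_A``, ``<id>_B``), missing entries as ``"."``.
* Sample manifests as CSV with the exact :class:`SampleManifest` columns;
  ``qc_flags`` serialised as a ``;``-joined string.
* Ancestry tracts as BED-like TSV; labelled distance matrices as TSV;
  multistate cognate matrices as TSV with ``"?"`` for missing states.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    AncestryTractSet,
    DistanceMatrix,
    GenotypePanel,
    QCReport,
    SampleManifest,
)
from .exceptions import LookupError_, ParseError, PloidyError

_PED_CODE = {0: "1", 1: "2", MISSING: "0"}
_PED_DECODE = {"1": 0, "2": 1, "0": MISSING}
_TSV_CODE = {0: "0", 1: "1", MISSING: "."}
_TSV_DECODE = {"0": 0, "1": 1, ".": MISSING}


# ----------------------------------------------------------------------
# Genotype panels
# ----------------------------------------------------------------------

def read_panel(path: str | os.PathLike, format: str = "ped_map") -> GenotypePanel:
    """Read a phased genotype panel.

    For ``format="ped_map"``, ``path`` is the common prefix of a
    ``.ped``/``.map`` pair; for ``format="tsv"`` it is the TSV file itself.
    """
    if format == "ped_map":
        return _read_ped_map(Path(path))
    if format == "tsv":
        return _read_tsv(Path(path))
    raise ValueError(f"unknown panel format {format!r}")


def write_panel(panel: GenotypePanel, path: str | os.PathLike,
                format: str = "ped_map") -> None:
    """Write a panel so that :func:`read_panel` round-trips it exactly."""
    if format == "ped_map":
        _write_ped_map(panel, Path(path))
    elif format == "tsv":
        _write_tsv(panel, Path(path))
    else:
        raise ValueError(f"unknown panel format {format!r}")


def _read_ped_map(prefix: Path) -> GenotypePanel:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    variants = _read_map(map_path)
    n_var = len(variants)

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{ped_path}: line {lineno}: fewer than 6 leading fields")
            alleles = fields[6:]
            if len(alleles) != 2 * n_var:
                raise PloidyError(
                    f"{ped_path}: line {lineno}: expected {2 * n_var} alleles "
                    f"for {n_var} variants, found {len(alleles)}")
            try:
                coded = [_PED_DECODE[a] for a in alleles]
            except KeyError as exc:
                raise ParseError(
                    f"{ped_path}: line {lineno}: bad allele code "
                    f"{exc.args[0]!r}") from None
            arr = np.asarray(coded, dtype=np.int8).reshape(n_var, 2)
            rows.append(arr[:, 0])
            rows.append(arr[:, 1])
            sample_ids.append(fields[1])
    haps = (np.vstack(rows) if rows
            else np.empty((0, n_var), dtype=np.int8))
    return GenotypePanel(variants=variants, haplotypes=haps,
                         sample_ids=sample_ids)


def _read_map(map_path: Path) -> pd.DataFrame:
    recs = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(
                    f"{map_path}: line {lineno}: expected 4 fields, "
                    f"found {len(fields)}")
            chrom, _snp_id, cm, bp = fields
            try:
                recs.append((chrom, int(bp), float(cm)))
            except ValueError:
                raise ParseError(
                    f"{map_path}: line {lineno}: non-numeric position") from None
    return pd.DataFrame(recs, columns=["chrom", "pos_bp", "pos_cM"])


def _write_ped_map(panel: GenotypePanel, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for i, row in panel.variants.iterrows():
            fh.write(f"{row['chrom']} snp{i} {row['pos_cM']:.6f} "
                     f"{int(row['pos_bp'])}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            h0 = panel.haplotypes[2 * i]
            h1 = panel.haplotypes[2 * i + 1]
            alleles = " ".join(
                f"{_PED_CODE[int(a)]} {_PED_CODE[int(b)]}"
                for a, b in zip(h0, h1))
            lead = f"FAM{i} {sid} 0 0 0 -9"
            fh.write(lead + (" " + alleles if alleles else "") + "\n")


def _read_tsv(path: Path) -> GenotypePanel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chrom", "pos_bp", "pos_cM"]:
            raise ParseError(
                f"{path}: line 1: header must begin "
                "'chrom pos_bp pos_cM'")
        hap_cols = header[3:]
        if len(hap_cols) % 2:
            raise PloidyError(
                f"{path}: line 1: odd number of haplotype columns")
        sample_ids = []
        for j in range(0, len(hap_cols), 2):
            a, b = hap_cols[j], hap_cols[j + 1]
            if not (a.endswith("_A") and b.endswith("_B")
                    and a[:-2] == b[:-2]):
                raise ParseError(
                    f"{path}: line 1: columns {a!r}/{b!r} are not an "
                    "<id>_A/<id>_B pair")
            sample_ids.append(a[:-2])
        recs, cols = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"found {len(fields)}")
            try:
                recs.append((fields[0], int(fields[1]), float(fields[2])))
                cols.append([_TSV_DECODE[v] for v in fields[3:]])
            except (ValueError, KeyError):
                raise ParseError(
                    f"{path}: line {lineno}: bad value") from None
    variants = pd.DataFrame(recs, columns=["chrom", "pos_bp", "pos_cM"])
    haps = (np.asarray(cols, dtype=np.int8).T if cols
            else np.empty((2 * len(sample_ids), 0), dtype=np.int8))
    return GenotypePanel(variants=variants, haplotypes=haps,
                         sample_ids=sample_ids)


def _write_tsv(panel: GenotypePanel, path: Path) -> None:
    with open(path, "w") as fh:
        cols = ["chrom", "pos_bp", "pos_cM"]
        for sid in panel.sample_ids:
            cols.extend((f"{sid}_A", f"{sid}_B"))
        fh.write("\t".join(cols) + "\n")
        bp = panel.variants["pos_bp"].to_numpy()
        cm = panel.variants["pos_cM"].to_numpy()
        chroms = panel.variants["chrom"].to_numpy()
        for v in range(panel.n_variants):
            vals = [_TSV_CODE[int(x)] for x in panel.haplotypes[:, v]]
            fh.write(f"{chroms[v]}\t{int(bp[v])}\t{cm[v]:.6f}\t"
                     + "\t".join(vals) + "\n")


# ----------------------------------------------------------------------
# Sample manifests
# ----------------------------------------------------------------------

def read_manifest(path: str | os.PathLike) -> SampleManifest:
    df = pd.read_csv(path, dtype={"sample_id": str, "population": str,
                                  "country": str, "linguistic_group": str})
    df["qc_flags"] = [
        set(str(v).split(";")) if isinstance(v, str) and v else set()
        for v in df["qc_flags"].fillna("")
    ]
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path: str | os.PathLike) -> None:
    df = manifest.table.copy()
    df["qc_flags"] = [";".join(sorted(f)) for f in df["qc_flags"]]
    df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# QC ledger
# ----------------------------------------------------------------------

def apply_qc_ledger(manifest: SampleManifest,
                    panel: GenotypePanel) -> tuple[GenotypePanel, QCReport]:
    """Remove flagged samples from a panel per the manifest's QC ledger.

    Call-rate exclusions are applied first; a sample carrying both flags is
    counted once, under ``low_call_rate``.  Surviving samples keep their
    panel row order.
    """
    flags = dict(zip(manifest.table["sample_id"], manifest.table["qc_flags"]))
    absent = [s for s in panel.sample_ids if s not in flags]
    if absent:
        raise LookupError_(
            f"panel samples absent from manifest: {absent[:5]}"
            + ("..." if len(absent) > 5 else ""))
    n_call = n_kin = 0
    keep = []
    for sid in panel.sample_ids:
        f = flags[sid]
        if "low_call_rate" in f:
            n_call += 1
        elif "kin_excluded" in f:
            n_kin += 1
        else:
            keep.append(sid)
    report = QCReport(
        n_input=panel.n_samples,
        n_removed_call_rate=n_call,
        n_removed_kinship=n_kin,
        n_retained=len(keep),
    )
    return panel.subset_samples(keep), report


def qc_report_from_manifest(manifest: SampleManifest) -> QCReport:
    """QC bookkeeping from a manifest alone (no genotype data needed)."""
    n_call = n_kin = n_keep = 0
    for f in manifest.table["qc_flags"]:
        if "low_call_rate" in f:
            n_call += 1
        elif "kin_excluded" in f:
            n_kin += 1
        else:
            n_keep += 1
    return QCReport(len(manifest.table), n_call, n_kin, n_keep)


# ----------------------------------------------------------------------
# Ancestry tracts, distance matrices, cognate matrices
# ----------------------------------------------------------------------

def read_tracts(path: str | os.PathLike) -> AncestryTractSet:
    df = pd.read_csv(path, sep="\t",
                     dtype={"haplotype_id": str, "chrom": str,
                            "ancestry": str})
    return AncestryTractSet(df)


def write_tracts(tracts: AncestryTractSet, path: str | os.PathLike) -> None:
    tracts.table.to_csv(path, sep="\t", index=False)


def read_distance_matrix(path: str | os.PathLike,
                         kind: str) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float), kind)


def write_distance_matrix(dm: DistanceMatrix,
                          path: str | os.PathLike) -> None:
    pd.DataFrame(dm.values, index=dm.labels,
                 columns=dm.labels).to_csv(path, sep="\t")


def read_cognate_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Languages x meaning-slots multistate matrix; missing states as NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["?"])
    return df.astype(float)


def write_cognate_matrix(matrix: pd.DataFrame,
                         path: str | os.PathLike) -> None:
    out = matrix.copy()
    out = out.map(lambda v: "?" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t")
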