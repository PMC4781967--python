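"""Tabular input/output with a single fixed dialect.

Every table this pipeline reads or writes is tab-separated UTF-8 with
'#'-prefixed comment lines ignored and the key in the first column.  Genomic
coordinates are hg19, 1-based, inclusive internally; BED output converts to
the 0-based half-open convention.

The four input containers (:class:`ProbeManifest`, :class:`BetaMatrix`,
:class:`SampleSheet`, :class:`AbundanceTable`) are thin validated wrappers
around pandas DataFrames: construction enforces the domain invariants, and
downstream stages can rely on them without re-checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger("agedmr")

SOMATIC_CHROMS = tuple(str(i) for i in range(1, 23))
ALLOWED_CHROMS = SOMATIC_CHROMS + ("X", "Y")
GROUPS = ("control", "UC", "CD")

#: canonical column names -> Illumina 450K manifest column names
ILLUMINA_COLUMN_MAP = {
    "IlmnID": "probe_id",
    "CHR": "chrom",
    "MAPINFO": "pos",
    "UCSC_RefGene_Name": "genes",
}


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)
    except pd.errors.ParserError as exc:  # malformed row structure
        raise FormatError(f"{path}: {exc}") from exc


@dataclass(frozen=True)
class ProbeManifest:
    """Probe coordinates and annotation, indexed by probe id.

    ``df`` columns: chrom (str), pos (int, 1-based hg19), genes (frozenset of
    gene symbols, possibly empty), snp_flag (bool).  ``n_dropped_snp`` and
    ``n_dropped_xy`` record how many probes the read-time filters removed.
    """

    df: pd.DataFrame
    n_dropped_snp: int = 0
    n_dropped_xy: int = 0

    def __post_init__(self) -> None:
        if not self.df.index.is_unique:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id {dup!r} in manifest")
        if (self.df["pos"] < 1).any():
            bad = self.df.index[self.df["pos"] < 1][0]
            raise ValidationError(f"probe {bad!r} has position < 1")
        bad_chrom = ~self.df["chrom"].isin(ALLOWED_CHROMS)
        if bad_chrom.any():
            bad = self.df.index[bad_chrom][0]
            raise ValidationError(
                f"probe {bad!r} has chromosome {self.df.loc[bad, 'chrom']!r} "
                f"outside the allowed vocabulary"
            )

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.df.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def position_of(self, probe_id: str) -> tuple[str, int]:
        row = self.df.loc[probe_id]
        return str(row["chrom"]), int(row["pos"])

    def genes_of(self, probe_id: str) -> frozenset:
        return self.df.loc[probe_id, "genes"]


@dataclass(frozen=True)
class BetaMatrix:
    """Probe x subject methylation fractions in [0, 1]; NaN marks missing."""

    df: pd.DataFrame
    n_dropped_probes: int = 0

    def __post_init__(self) -> None:
        vals = self.df.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"beta value {vals[i, j]} outside [0, 1] at probe "
                f"{self.df.index[i]!r}, subject {self.df.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def subject_ids(self) -> pd.Index:
        return self.df.columns


@dataclass(frozen=True)
class SampleSheet:
    """Subject ages and group labels, indexed by subject id."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.df.index.is_unique:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        if (self.df["age_years"] <= 0).any():
            bad = self.df.index[self.df["age_years"] <= 0][0]
            raise ValidationError(f"subject {bad!r} has non-positive age")
        bad_group = ~self.df["group"].isin(GROUPS)
        if bad_group.any():
            bad = self.df.index[bad_group][0]
            raise ValidationError(
                f"subject {bad!r} has group {self.df.loc[bad, 'group']!r}; "
                f"allowed: {GROUPS}"
            )
        ctrl_ages = self.df.loc[self.df["group"] == "control", "age_years"]
        if len(ctrl_ages) and ctrl_ages.nunique() < 2:
            raise ValidationError("controls must span >= 2 distinct ages")

    @property
    def subject_ids(self) -> pd.Index:
        return self.df.index

    def subjects_in(self, group: str) -> list[str]:
        return list(self.df.index[self.df["group"] == group])

    def ages_of(self, subjects: Sequence[str]) -> np.ndarray:
        return self.df.loc[list(subjects), "age_years"].to_numpy(dtype=float)


@dataclass(frozen=True)
class AbundanceTable:
    """Genus x subject relative abundances (non-negative, column sums <= 1)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.df.to_numpy(dtype=float)
        if (vals < 0).any():
            i, j = map(int, np.argwhere(vals < 0)[0])
            raise ValidationError(
                f"negative abundance at genus {self.df.index[i]!r}, "
                f"subject {self.df.columns[j]!r}"
            )
        sums = np.nansum(vals, axis=0)
        if (sums > 1 + 1e-6).any():
            j = int(np.argmax(sums > 1 + 1e-6))
            raise ValidationError(
                f"subject {self.df.columns[j]!r} abundances sum to {sums[j]:.8f} > 1"
            )

    @property
    def genus_ids(self) -> pd.Index:
        return self.df.index

    @property
    def subject_ids(self) -> pd.Index:
        return self.df.columns


# ---------------------------------------------------------------------------
# readers


def _parse_genes(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(g for g in str(cell).split(";") if g)


def read_manifest(
    path,
    drop_snp: bool = True,
    somatic_only: bool = True,
    snp_list: Iterable[str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> ProbeManifest:
    """Read a probe manifest TSV.

    Required columns (after optional ``column_map`` renaming, e.g.
    :data:`ILLUMINA_COLUMN_MAP` for vendor manifests): probe_id, chrom, pos.
    Optional: genes (';'-separated symbols), snp_flag (0/1).

    ``drop_snp`` removes probes whose snp_flag is set or whose id appears in
    ``snp_list`` (union of the two sources).  ``somatic_only`` removes chrX/Y
    probes before any analysis.
    """
    df = _read_tsv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in ("probe_id", "chrom", "pos") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    try:
        df["pos"] = df["pos"].astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-integer position: {exc}") from exc
    df["chrom"] = df["chrom"].astype(str)
    df["genes"] = (
        df["genes"].map(_parse_genes)
        if "genes" in df.columns
        else [frozenset()] * len(df)
    )
    if "snp_flag" in df.columns:
        df["snp_flag"] = df["snp_flag"].astype(str).isin(("1", "True", "true"))
    else:
        df["snp_flag"] = False
    df = df.set_index("probe_id")[["chrom", "pos", "genes", "snp_flag"]]

    n_snp = n_xy = 0
    if drop_snp:
        mask = df["snp_flag"].copy()
        if snp_list is not None:
            mask |= df.index.isin(set(snp_list))
        n_snp = int(mask.sum())
        df = df[~mask]
    if somatic_only:
        xy = ~df["chrom"].isin(SOMATIC_CHROMS)
        n_xy = int(xy.sum())
        df = df[~xy]
    manifest = ProbeManifest(df=df, n_dropped_snp=n_snp, n_dropped_xy=n_xy)
    log.info(
        "manifest %s: %d probes retained (%d SNP-flagged, %d X/Y dropped)",
        path, len(manifest), n_snp, n_xy,
    )
    return manifest


def read_snp_list(path) -> set[str]:
    """One probe id per line; '#' comments and blank lines ignored."""
    ids = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids


def read_samples(path) -> SampleSheet:
    df = _read_tsv(path)
    missing = [c for c in ("subject_id", "age_years", "group") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    try:
        df["age_years"] = df["age_years"].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric age: {exc}") from exc
    return SampleSheet(df=df.set_index("subject_id")[["age_years", "group"]])


def read_beta(path, manifest: ProbeManifest, samples: SampleSheet) -> BetaMatrix:
    """Read a beta matrix TSV (first column probe id, header of subject ids).

    Subjects in the header must all appear in the sample sheet.  Any value
    outside [0, 1] is an error (never clipped).  Probes absent from the
    manifest are dropped with a logged warning; the drop count is reported on
    the returned object.
    """
    df = _read_tsv(path, index_col=0)
    unknown = [s for s in df.columns if s not in samples.subject_ids]
    if unknown:
        raise ValidationError(f"{path}: subjects {unknown} not in sample sheet")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = bad.idxmax()
            raise FormatError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at probe "
                f"{row!r}, subject {col!r}"
            )
        out[col] = converted
    keep = out.index.isin(manifest.probe_ids)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("%s: dropped %d probe(s) absent from manifest", path, n_dropped)
    return BetaMatrix(df=out[keep], n_dropped_probes=n_dropped)


def read_abundance(path, samples: SampleSheet | None = None) -> AbundanceTable:
    df = _read_tsv(path, index_col=0)
    if samples is not None:
        unknown = [s for s in df.columns if s not in samples.subject_ids]
        if unknown:
            raise ValidationError(f"{path}: subjects {unknown} not in sample sheet")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric abundance: {exc}") from exc
    return AbundanceTable(df=df)


def read_probe_set(path) -> set[str]:
    """External CpG compendium: one probe id per line."""
    return read_snp_list(path)


# ---------------------------------------------------------------------------
# writers


def _write_tsv(df: pd.DataFrame, path, index_label: str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def write_manifest(manifest: ProbeManifest, path) -> None:
    df = manifest.df.copy()
    df["genes"] = df["genes"].map(lambda s: ";".join(sorted(s)))
    df["snp_flag"] = df["snp_flag"].astype(int)
    _write_tsv(df, path, "probe_id")


def write_beta(beta: BetaMatrix, path) -> None:
    _write_tsv(beta.df, path, "probe_id")


def write_samples(samples: SampleSheet, path) -> None:
    _write_tsv(samples.df, path, "subject_id")


def write_abundance(abundance: AbundanceTable, path) -> None:
    _write_tsv(abundance.df, path, "genus")


_CHROM_ORDER = {c: i for i, c in enumerate(ALLOWED_CHROMS)}


def write_dmr_bed(dmrs, path) -> None:
    """Write DMRs as BED6: 0-based half-open intervals, sorted by (chrom, start).

    score = round(1000 * |mean rho|), capped at 1000; strand is always '.'.
    """
    rows = sorted(dmrs, key=lambda d: (_CHROM_ORDER.get(d.chrom, 99), d.start))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for d in rows:
            score = min(1000, round(1000 * abs(d.mean_rho)))
            fh.write(
                f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.dmr_id}\t{score}\t.\n"
            )
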