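"""Readers, writers and validation for the pipeline's tabular formats.

All on-disk formats are plain text: tab-separated tables for abundance
matrices, sample metadata and taxonomy, and GMT for pathway membership.
In memory, abundance matrices and metadata are pandas DataFrames —
matrices are samples x features with the sample ID as index; metadata is
one row per sample.

Serialization uses 10 significant digits, tab delimiters and UTF-8 so
that write-then-read round trips are bit-stable. Missing values are
written as ``NA`` and never imputed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSE_GROUPS",
    "GROUP_ORDER",
    "TIMEPOINT_WEEKS",
    "PathwayMap",
    "CohortValidation",
    "read_abundance",
    "write_abundance",
    "read_meta",
    "write_meta",
    "read_taxonomy",
    "write_taxonomy",
    "read_gmt",
    "write_gmt",
    "validate_cohort",
]

#: RECIST response categories used throughout; FD = fast death.
RESPONSE_GROUPS = ("PR", "SD", "PD", "FD")

#: Fixed preference order for tie-breaking (better response first).
GROUP_ORDER = ("PR", "SD", "PD")

#: Fecal collection grid, label -> week offset from treatment start.
TIMEPOINT_WEEKS = {"M0": 0, "W1": 1, "W2": 2, "M1": 4, "M2": 8, "M3": 12, "M4": 16}

#: Columns required in a sample metadata table.
META_COLUMNS = (
    "patient_id",
    "timepoint",
    "week",
    "response",
    "atb",
    "bmi",
    "tmb",
    "hla_e",
    "pfs_months",
    "pfs_event",
)

_FLOAT_FMT = "%.10g"
_NA = "NA"


class ProfileFormatError(ValueError):
    """Raised when an on-disk profile violates its format contract."""


def _check_abundance(df: pd.DataFrame, where: str = "matrix") -> pd.DataFrame:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ProfileFormatError(f"duplicate sample ID {dup!r} in {where}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ProfileFormatError(f"duplicate feature ID {dup!r} in {where}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ProfileFormatError(
            f"missing value at sample {df.index[i]!r}, feature {df.columns[j]!r} in {where}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ProfileFormatError(
            f"negative abundance {values[i, j]!r} at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r} in {where}"
        )
    sums = values.sum(axis=1)
    if (sums > 1 + 1e-9).any():
        i = int(np.argmax(sums))
        raise ProfileFormatError(
            f"per-sample sum {sums[i]!r} > 1 for sample {df.index[i]!r} in {where}"
        )
    return df


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a samples x features relative-abundance TSV.

    First column holds sample IDs, header row holds feature IDs. Row
    order is preserved. Raises :class:`ProfileFormatError` on negative
    values, duplicate IDs or ragged rows, naming the offending cell.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=[], keep_default_na=False
        )
        df = df.apply(pd.to_numeric)
    except ValueError as exc:  # ragged rows / non-numeric cells
        raise ProfileFormatError(f"{path.name}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return _check_abundance(df, where=path.name)


def write_abundance(df: pd.DataFrame, path: str | Path) -> None:
    _check_abundance(df)
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT, encoding="utf-8")


def read_meta(path: str | Path) -> pd.DataFrame:
    """Read per-sample clinical metadata (one row per sample ID)."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileFormatError(f"metadata missing columns: {missing}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ProfileFormatError(f"duplicate sample ID {dup!r} in metadata")
    df["atb"] = df["atb"].astype(bool)
    # pfs_event stays nullable: FD rows may carry NA clinical fields
    return df


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep=_NA, encoding="utf-8")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read MGS taxonomy (mgs_id, class, genus, species) TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     na_values=[_NA], keep_default_na=False)
    df.index.name = "mgs_id"
    for col in ("class", "genus", "species"):
        if col not in df.columns:
            raise ProfileFormatError(f"taxonomy missing column {col!r}")
    return df


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    out = tax.copy()
    out.index.name = "mgs_id"
    out.to_csv(path, sep="\t", na_rep=_NA, encoding="utf-8")


@dataclass(frozen=True)
class PathwayMap:
    """KO membership of pathways plus display names and level-1 categories.

    ``members`` maps a pathway ID (e.g. ``map02010``) to a frozenset of
    KO IDs; ``names``/``categories`` carry the display name and the
    top-level KEGG category used for grouping heatmap rows.
    """

    members: Mapping[str, frozenset[str]]
    names: Mapping[str, str] = field(default_factory=dict)
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, kos in self.members.items():
            if not kos:
                raise ProfileFormatError(f"pathway {pid!r} has no KO members")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.members[pathway_id]


def read_gmt(path: str | Path) -> PathwayMap:
    """Read a GMT file: pathway ID, description, then KO IDs, tab-separated.

    The description field may encode ``name|category``; a bare name is
    accepted with an empty category.
    """
    members: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    categories: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ProfileFormatError(f"GMT line {lineno}: fewer than 3 fields")
        pid, desc, kos = parts[0], parts[1], [k for k in parts[2:] if k]
        if pid in members:
            raise ProfileFormatError(f"GMT line {lineno}: duplicate pathway {pid!r}")
        if len(set(kos)) != len(kos):
            raise ProfileFormatError(f"GMT line {lineno}: duplicate KO in {pid!r}")
        members[pid] = frozenset(kos)
        name, _, cat = desc.partition("|")
        names[pid] = name
        categories[pid] = cat
    return PathwayMap(members=members, names=names, categories=categories)


def write_gmt(pmap: PathwayMap, path: str | Path) -> None:
    lines = []
    for pid in sorted(pmap.members):
        desc = pmap.names.get(pid, pid)
        cat = pmap.categories.get(pid, "")
        if cat:
            desc = f"{desc}|{cat}"
        lines.append("\t".join([pid, desc, *sorted(pmap.members[pid])]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class CohortValidation:
    """Result of cross-checking an abundance matrix against metadata.

    ``abundance``/``meta`` are the validated, aligned views (optionally
    with antibiotics-treated patients removed, mirroring the exclusion
    of ATB patients from microbiota analyses). Issue lists record
    samples lacking metadata, orphan metadata rows, and ATB-excluded
    samples.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame
    missing_meta: list[str]
    orphan_meta: list[str]
    excluded_atb: list[str]

    @property
    def issues(self) -> list[str]:
        out = [f"sample {s!r} has no metadata" for s in self.missing_meta]
        out += [f"orphan metadata row {s!r}" for s in self.orphan_meta]
        return out

    @property
    def n_patients(self) -> int:
        return int(self.meta["patient_id"].nunique())


def validate_cohort(
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    exclude_atb: bool = False,
) -> CohortValidation:
    """Align an abundance matrix with sample metadata.

    Returns the validated view; with ``exclude_atb`` every sample from a
    patient flagged for antibiotics exposure is dropped from it. An
    empty sample intersection is fatal.
    """
    shared = [s for s in abundance.index if s in meta.index]
    if not shared:
        raise ProfileFormatError("no samples shared between abundance matrix and metadata")
    missing = [s for s in abundance.index if s not in meta.index]
    orphan = [s for s in meta.index if s not in abundance.index]
    sub_meta = meta.loc[shared]
    excluded: list[str] = []
    if exclude_atb:
        atb_patients = set(sub_meta.loc[sub_meta["atb"].astype(bool), "patient_id"])
        excluded = [s for s in shared if sub_meta.at[s, "patient_id"] in atb_patients]
        shared = [s for s in shared if s not in set(excluded)]
        if not shared:
            raise ProfileFormatError("all samples excluded by the ATB filter")
        sub_meta = meta.loc[shared]
    return CohortValidation(
        abundance=abundance.loc[shared],
        meta=sub_meta,
        missing_meta=missing,
        orphan_meta=orphan,
        excluded_atb=excluded,
    )


def file_sha256(path: str | Path) -> str:
    """Hex digest of a file, for the CLI's structured log lines."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
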