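"""Readers and writers for the tabular formats the pipeline touches.

All readers validate strictly and raise :class:`DataIOError` on malformed
input rather than silently coercing; all writers emit files their readers
accept, so every format round-trips.

In-memory containers are deliberately plain:

* expression matrix — :class:`pandas.DataFrame`, genes in rows (index
  ``gene_id``), samples in columns, non-negative reals (FPKM or log2 scale);
* sample metadata — :class:`pandas.DataFrame` with one row per sample and
  the columns ``sample_id, subject_id, region, diagnosis, age, sex, apoe4,
  braak``;
* gene-set collection — :class:`GeneSetCollection`, an ordered name →
  members mapping parsed from Broad-convention GMT.

Gene-ID matching everywhere is exact-string and case-sensitive; the package
never translates identifiers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DataIOError",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "read_de_table",
    "write_de_table",
    "summarize_cohort",
    "METADATA_COLUMNS",
]


class DataIOError(ValueError):
    """Raised when an input file violates the expected format."""


METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "region",
    "diagnosis",
    "age",
    "sex",
    "apoe4",
    "braak",
)

_DIAGNOSIS_ALIASES = {
    "ad": "AD",
    "alzheimer": "AD",
    "alzheimers": "AD",
    "control": "control",
    "ctrl": "control",
    "no dementia": "control",
}


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets with descriptions.

    Members within each set are deduplicated preserving first occurrence;
    set names are unique; insertion order is preserved.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise DataIOError(f"duplicate gene-set name {name!r}")
        seen: dict[str, None] = dict.fromkeys(members)
        if not seen:
            raise DataIOError(f"gene set {name!r} is empty")
        self.sets[name] = list(seen)
        self.descriptions[name] = description

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.sets.items()}


def _check_ids(ids: Iterable[str], what: str) -> None:
    for x in ids:
        if not x or any(ch.isspace() for ch in str(x)):
            raise DataIOError(f"{what} {x!r} is empty or contains whitespace")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV (first column ``gene_id``) into a DataFrame.

    Rejects ragged rows, duplicated gene or sample IDs, missing values and
    negative entries.
    """
    path = Path(path)
    with open(path) as fh:  # pandas mangles duplicate headers; check raw line
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
        else:
            raise DataIOError(f"{path}: empty file")
    if len(set(header)) != len(header):
        raise DataIOError(f"{path}: duplicated sample IDs in header")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise DataIOError(f"{path}: expected gene_id column plus at least one sample")
    if df.columns[0] != "gene_id":
        raise DataIOError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    genes = df.iloc[:, 0]
    dup = genes[genes.duplicated()].tolist()
    if dup:
        raise DataIOError(f"{path}: duplicated gene IDs: {sorted(set(dup))}")
    mat = df.set_index("gene_id")
    try:
        mat = mat.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataIOError(f"{path}: non-numeric expression value ({exc})") from exc
    if mat.isna().any().any():
        raise DataIOError(f"{path}: missing values (ragged rows or empty cells)")
    if (mat.values < 0).any():
        bad = mat.index[(mat.values < 0).any(axis=1)].tolist()
        raise DataIOError(f"{path}: negative expression values for genes {bad[:5]}")
    mat.index.name = "gene_id"
    return mat


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path,
                            overwrite: bool = False, header_comment: str | None = None) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    _check_ids(matrix.index, "gene ID")
    _check_ids(matrix.columns, "sample ID")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = matrix.copy()
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t", float_format="%.10g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata CSV, normalizing diagnosis to {AD, control}."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise DataIOError(f"{path}: metadata table is empty")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataIOError(f"{path}: missing required columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise DataIOError(f"{path}: duplicated sample_id values: {sorted(set(dup))}")
    diag = df["diagnosis"].astype(str).str.strip()
    normalized = diag.str.lower().map(_DIAGNOSIS_ALIASES)
    unknown = diag[normalized.isna()].unique().tolist()
    if unknown:
        raise DataIOError(f"{path}: unrecognized diagnosis labels {unknown}; expected AD/control")
    df = df.copy()
    df["diagnosis"] = normalized.values
    df["age"] = df["age"].astype(float)
    return df.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path, overwrite: bool = False,
                   header_comment: str | None = None) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        meta.to_csv(fh, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-convention GMT file: name TAB description TAB members..."""
    coll = GeneSetCollection()
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataIOError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need ≥ 3 "
                    "(name, description, at least one member)"
                )
            name, description = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            try:
                coll.add(name, members, description)
            except DataIOError as exc:
                raise DataIOError(f"{path}:{lineno}: {exc}") from exc
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            fh.write("\t".join([name, coll.descriptions.get(name, "")] + members) + "\n")


DE_TABLE_COLUMNS = ("gene_id", "logFC", "AvExp", "t", "P.Value", "adj.P.Val", "B",
                    "converged", "tau2")


def write_de_table(table: pd.DataFrame, path: str | Path, overwrite: bool = False,
                   header_comment: str | None = None) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    missing = [c for c in DE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise DataIOError(f"DE table missing columns {missing}")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, index=False, float_format="%.12g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataIOError(f"{path}: DE table missing columns {missing}")
    return df


def summarize_cohort(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-diagnosis cohort summary computed at the subject level.

    Returns a table indexed by diagnosis with subject and sample counts,
    mean/sd age, percent female, and the percent of subjects carrying at
    least one APOE ε4 allele. Subject-level attributes (age, sex, apoe4) are
    taken from each subject's first row, so the summary is invariant to how
    many regional samples a subject contributes.
    """
    required = {"subject_id", "diagnosis"}
    missing = required - set(meta.columns)
    if missing:
        raise DataIOError(f"metadata missing columns {sorted(missing)}")
    subjects = meta.drop_duplicates("subject_id").set_index("subject_id")
    rows = {}
    for diag, grp in subjects.groupby("diagnosis"):
        row: dict[str, float] = {
            "n_subjects": len(grp),
            "n_samples": int((meta["diagnosis"] == diag).sum()),
        }
        if "age" in grp:
            row["age_mean"] = float(grp["age"].mean())
            row["age_sd"] = float(grp["age"].std(ddof=1))
        if "sex" in grp:
            sex = grp["sex"].astype(str).str.upper()
            row["pct_female"] = 100.0 * float((sex.isin({"F", "FEMALE", "1"})).mean())
        if "apoe4" in grp:
            carriers = grp["apoe4"].astype(float) > 0
            row["apoe4_pct"] = 100.0 * float(carriers.mean())
        rows[diag] = row
    return pd.DataFrame(rows).T.rename_axis("diagnosis")
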