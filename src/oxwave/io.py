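"""Readers and writers for every artifact file in the pipeline.

All tabular formats are UTF-8, tab-delimited, "." decimal TSV with a
versioned comment header of the form ``# oxwave-<kind> v1 rows=<n>``.
The ``rows=`` field lets every reader reject silently truncated files.
Site positions are 1-based; peptide termini are encoded as positions 0
(N-terminus) and ``len(peptide) + 1`` (C-terminus), matching Unimod
terminal-modification semantics.
"""

from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import fasta as _pfasta

HEADER_PREFIX = "# oxwave-"
FORMAT_VERSION = 1

#: marker tokens usable in ModAnnotation.allowed_residues
N_TERM = "N-term"
C_TERM = "C-term"
ANY_RESIDUE = "*"

PSM_MANDATORY_COLUMNS = [
    "spectrum_id",
    "peptide",
    "charge",
    "theoretical_mass",
    "observed_mass",
    "delta_mass",
    "score",
    "is_decoy",
    "protein",
    "site_position",
    "plex_id",
]
PSM_NUMERIC_COLUMNS = ["theoretical_mass", "observed_mass", "delta_mass", "score"]
REPORTER_PREFIX = "reporter_"

DESIGN_COLUMNS = [
    "plex_id",
    "channel_index",
    "sample_id",
    "group_label",
    "timepoint_label",
    "is_reference",
]

MOD_COLUMNS = ["name", "delta_mass", "allowed_residues", "is_artifact", "is_combination"]


class TableFormatError(ValueError):
    """A file violates the documented table contract."""


# ---------------------------------------------------------------------------
# generic versioned-TSV plumbing

def _write_table(df: pd.DataFrame, path, kind: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{HEADER_PREFIX}{kind} v{FORMAT_VERSION} rows={len(df)}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path, kind: str) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        expected_rows = None
        if first.startswith(HEADER_PREFIX):
            tag, _version, rows_field = first[len(HEADER_PREFIX):].split()
            if tag != kind:
                raise TableFormatError(
                    f"{path}: expected an oxwave-{kind} table, found oxwave-{tag}"
                )
            expected_rows = int(rows_field.split("=")[1])
            body = fh.read()
        else:
            body = first + fh.read()
    if not body.strip():
        warnings.warn(f"{path}: empty table")
        return pd.DataFrame()
    df = pd.read_csv(_stdio.StringIO(body), sep="\t", dtype=str, keep_default_na=False)
    if expected_rows is not None and len(df) != expected_rows:
        raise TableFormatError(
            f"{path}: truncated table — header promises {expected_rows} rows, "
            f"parsed {len(df)}"
        )
    return df


def _to_numeric(df: pd.DataFrame, column: str, path, *, header_lines: int = 2) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    na = converted.isna() & (df[column] != "")
    if na.any():
        line = int(np.flatnonzero(na.to_numpy())[0]) + header_lines + 1
        raise TableFormatError(
            f"{path}: non-numeric value {df[column][na].iloc[0]!r} in column "
            f"{column!r} at line {line}"
        )
    return converted


def _parse_bool(series: pd.Series) -> pd.Series:
    return series.str.strip().str.lower().isin({"true", "1", "yes"})


# ---------------------------------------------------------------------------
# PSM tables

def reporter_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith(REPORTER_PREFIX)]
    return sorted(cols, key=lambda c: int(c[len(REPORTER_PREFIX):]))


def write_psm_table(psms: pd.DataFrame, path) -> None:
    _write_table(psms, path, "psm")


def read_psm_table(path, *, n_channels: int | None = None, validate: bool = True,
                   tol: float = 1e-6) -> pd.DataFrame:
    """Read a PSM table, validating the documented contract.

    Missing mandatory columns are a hard error naming the column; a
    non-numeric mass is a row-level error with its line number; rows whose
    ``delta_mass`` disagrees with ``observed - theoretical`` beyond *tol*
    trigger a warning listing their spectrum_ids.
    """
    df = _read_table(path, "psm")
    for col in PSM_MANDATORY_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing mandatory column {col!r}")
    for col in PSM_NUMERIC_COLUMNS + reporter_columns(df):
        df[col] = _to_numeric(df, col, path)
    df["charge"] = _to_numeric(df, "charge", path).astype(int)
    df["site_position"] = _to_numeric(df, "site_position", path).astype("Int64")
    df["is_decoy"] = _parse_bool(df["is_decoy"])
    if "cys_tag_mass" in df.columns:
        df["cys_tag_mass"] = _to_numeric(df, "cys_tag_mass", path)
    # extra columns stay opaque, but fully numeric ones round-trip as numbers
    known = set(PSM_MANDATORY_COLUMNS) | set(reporter_columns(df)) | {"cys_tag_mass"}
    for col in df.columns:
        if col in known:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        if not (converted.isna() & (df[col] != "")).any():
            df[col] = converted
    if validate:
        resid = (df["observed_mass"] - df["theoretical_mass"] - df["delta_mass"]).abs()
        bad = resid > tol
        if bad.any():
            ids = ", ".join(df.loc[bad, "spectrum_id"].head(10))
            warnings.warn(
                f"{path}: delta_mass inconsistent with observed - theoretical for "
                f"{int(bad.sum())} rows (spectrum_ids: {ids})"
            )
        over = df["site_position"].notna() & (
            df["site_position"] > df["peptide"].str.len() + 1
        )
        if over.any():
            raise TableFormatError(
                f"{path}: site_position beyond peptide length for spectrum_id "
                f"{df.loc[over, 'spectrum_id'].iloc[0]}"
            )
        if n_channels is not None and len(reporter_columns(df)) != n_channels:
            raise TableFormatError(
                f"{path}: expected {n_channels} reporter columns, "
                f"found {len(reporter_columns(df))}"
            )
    return df


# ---------------------------------------------------------------------------
# FASTA

@dataclass
class FastaDatabase:
    """A concatenated target-decoy protein database."""

    sequences: dict[str, str]
    decoy_prefix: str = "DECOY_"

    def is_decoy(self, accession: str) -> bool:
        return accession.startswith(self.decoy_prefix)

    @property
    def targets(self) -> dict[str, str]:
        return {a: s for a, s in self.sequences.items() if not self.is_decoy(a)}

    @property
    def decoys(self) -> dict[str, str]:
        return {a: s for a, s in self.sequences.items() if self.is_decoy(a)}


def read_fasta(path, decoy_prefix: str = "DECOY_") -> FastaDatabase:
    sequences: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for header, seq in _pfasta.FASTA(fh):
            accession = header.split()[0]
            if accession in sequences:
                raise TableFormatError(f"{path}: duplicate accession {accession!r}")
            sequences[accession] = seq
    if not sequences:
        warnings.warn(f"{path}: empty FASTA file")
    return FastaDatabase(sequences, decoy_prefix)


def write_fasta(db: FastaDatabase, path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for accession, seq in db.sequences.items():
            fh.write(f">{accession}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# modification lists

@dataclass(frozen=True)
class ModAnnotation:
    """One known mass shift (Unimod-style entry)."""

    name: str
    delta_mass: float
    allowed_residues: frozenset[str] = frozenset({ANY_RESIDUE})
    is_artifact: bool = False
    is_combination: bool = False

    def allows(self, residue_or_terminus: str) -> bool:
        return (
            ANY_RESIDUE in self.allowed_residues
            or residue_or_terminus in self.allowed_residues
        )

    def __post_init__(self):
        if not np.isfinite(self.delta_mass):
            raise ValueError(f"{self.name}: delta_mass must be finite")
        if not self.allowed_residues:
            raise ValueError(f"{self.name}: allowed_residues must be non-empty")


def read_mod_list(path) -> list[ModAnnotation]:
    df = _read_table(path, "mods")
    for col in MOD_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing mandatory column {col!r}")
    df["delta_mass"] = _to_numeric(df, "delta_mass", path)
    mods = []
    for row in df.itertuples(index=False):
        tokens = frozenset(t for t in str(row.allowed_residues).split(",") if t)
        mods.append(
            ModAnnotation(
                name=row.name,
                delta_mass=float(row.delta_mass),
                allowed_residues=tokens,
                is_artifact=str(row.is_artifact).strip().lower() in {"true", "1"},
                is_combination=str(row.is_combination).strip().lower() in {"true", "1"},
            )
        )
    return mods


def write_mod_list(mods, path) -> None:
    df = pd.DataFrame(
        {
            "name": [m.name for m in mods],
            "delta_mass": [repr(m.delta_mass) for m in mods],
            "allowed_residues": [",".join(sorted(m.allowed_residues)) for m in mods],
            "is_artifact": [m.is_artifact for m in mods],
            "is_combination": [m.is_combination for m in mods],
        }
    )
    _write_table(df, path, "mods")


# ---------------------------------------------------------------------------
# category annotations

def read_categories(path) -> dict[str, set[str]]:
    """Category → accession sets; two-column or GMT dialect, auto-detected.

    GMT lines are ``name<TAB>description<TAB>member1<TAB>member2...``; the
    two-column dialect is ``category<TAB>accession`` one pair per line.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if rows and rows[0][:2] == ["category", "accession"]:
        rows = rows[1:]
    is_gmt = any(len(r) > 2 for r in rows)
    categories: dict[str, set[str]] = {}
    for r in rows:
        if is_gmt:
            name, members = r[0], r[2:]
        else:
            if len(r) != 2:
                raise TableFormatError(f"{path}: malformed two-column line {r!r}")
            name, members = r[0], [r[1]]
        categories.setdefault(name, set()).update(m for m in members if m)
    return categories


def write_categories(categories: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("category\taccession\n")
        for name in sorted(categories):
            for accession in sorted(categories[name]):
                fh.write(f"{name}\t{accession}\n")


# ---------------------------------------------------------------------------
# design tables

@dataclass
class DesignTable:
    """Mapping of (plex, TMT channel) to sample, group and time point.

    Row order defines the time ordering used by every downstream
    time-course matrix. Exactly one reference channel per plex.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.frame
        for col in DESIGN_COLUMNS:
            if col not in df.columns:
                raise TableFormatError(f"design table missing column {col!r}")
        refs = df[df["is_reference"]].groupby("plex_id").size()
        plexes = df["plex_id"].unique()
        if not all(refs.get(p, 0) == 1 for p in plexes):
            raise TableFormatError("design table must have exactly one reference channel per plex")
        samples = df[~df["is_reference"]]
        per_sample_groups = samples.groupby("sample_id")["group_label"].nunique()
        if (per_sample_groups > 1).any():
            raise TableFormatError("a sample maps to more than one group")
        if samples["sample_id"].duplicated().any():
            raise TableFormatError("duplicate sample_id in design table")

    @property
    def samples(self) -> pd.DataFrame:
        return self.frame[~self.frame["is_reference"]]

    @property
    def timepoint_order(self) -> list[str]:
        seen: list[str] = []
        for tp in self.samples["timepoint_label"]:
            if tp not in seen:
                seen.append(tp)
        return seen

    @property
    def group_order(self) -> list[str]:
        seen: list[str] = []
        for g in self.samples["group_label"]:
            if g not in seen:
                seen.append(g)
        return seen

    def sample_to_group(self) -> pd.Series:
        return self.samples.set_index("sample_id")["group_label"]

    def sample_to_timepoint(self) -> pd.Series:
        return self.samples.set_index("sample_id")["timepoint_label"]

    def reference_channel(self, plex_id: str) -> int:
        df = self.frame
        row = df[(df["plex_id"] == plex_id) & df["is_reference"]]
        return int(row["channel_index"].iloc[0])


def read_design(path) -> DesignTable:
    df = _read_table(path, "design")
    for col in DESIGN_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing mandatory column {col!r}")
    df["channel_index"] = _to_numeric(df, "channel_index", path).astype(int)
    df["is_reference"] = _parse_bool(df["is_reference"])
    return DesignTable(df)


def write_design(design: DesignTable, path) -> None:
    _write_table(design.frame, path, "design")
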