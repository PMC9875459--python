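"""Readers and writers for the formats the pipeline touches, plus run configuration.

Sequences live in plain FASTA, traits in a delimited table with a fixed header
(``accession,group,brix,sucrose,fiber,reducing_sugar``), and the run
configuration in a small dataclass.  Parsing is delegated to Biopython /
pandas; this module adds the validation layer (alphabet, uniqueness, group
vocabulary) with typed errors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "RunConfig",
    "ParseError",
    "GROUP_LABELS",
    "TRAIT_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_trait_table",
    "write_tsv",
    "load_sugar_traits",
]

#: Allowed nucleotide alphabet on input.  ``N`` is accepted here; downstream
#: haplotype confirmation rejects any sequence still containing it.
VALID_BASES = frozenset("ACGTN")

#: Fixed vocabulary for the accession grouping column: high-sucrose and
#: low-sucrose hybrid clones, ancestral Saccharum species, and the check
#: cultivar.
GROUP_LABELS = frozenset({"HS", "LS", "ANCESTRAL", "CK"})

TRAIT_COLUMNS = ("accession", "group", "brix", "sucrose", "fiber", "reducing_sugar")

#: Cell values treated as missing in trait tables (printed em-dashes etc.).
_MISSING = {"", "—", "-", "na", "NA", "n/a", "none", "None", "nan"}


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, optionally tagged with its source accession.

    Clone ids follow the pattern ``{accession}|clone{k}``; the accession field
    is filled from the id prefix when present.
    """

    id: str
    seq: str
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        if not self.seq:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )


@dataclass
class RunConfig:
    """Run-level knobs shared by the pipeline stages.

    min_support
        minimum number of identical assemblies required to confirm a
        haplotype (default 2).
    confidence
        binomial confidence level used for the required-clone computation.
    window, step
        sliding-window size and stride, in alignment columns, for windowed
        nucleotide diversity.
    alpha
        significance level for correlation / ANOVA flags (default 0.01,
        "extremely significant").
    """

    seed: int = 0
    min_support: int = 2
    confidence: float = 0.95
    window: int = 100
    step: int = 25
    alpha: float = 0.01
    out_dir: Path = field(default_factory=lambda: Path("polyhap_out"))

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must be in (0, 1)")
        if not (0 < self.step <= self.window):
            raise ValueError("require 0 < step <= window")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        self.out_dir = Path(self.out_dir)


def _accession_of(record_id: str) -> str:
    return record_id.split("|", 1)[0] if "|" in record_id else ""


def _find_offending_line(path: Path, needle: str) -> int:
    """Best-effort line number (1-based) of the first line containing *needle*."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if needle in line:
                return i
    return 0


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA into SequenceRecords.

    Sequences are case-folded to upper.  Duplicate ids, empty sequences and
    non-IUPAC characters raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        rid = rec.id
        if rid in seen:
            line = _find_offending_line(path, f">{rid}")
            raise ParseError(f"{path}:{line}: duplicate sequence id {rid!r}")
        seen.add(rid)
        if not seq:
            line = _find_offending_line(path, f">{rid}")
            raise ParseError(f"{path}:{line}: empty sequence for {rid!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            offender = next(c for c in seq if c not in VALID_BASES)
            line = _find_offending_line(path, offender) or _find_offending_line(
                path, offender.lower()
            )
            raise ParseError(
                f"{path}:{line}: non-IUPAC character {offender!r} in record {rid!r}"
            )
        records.append(SequenceRecord(id=rid, seq=seq, accession=_accession_of(rid)))
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60
) -> None:
    """Write records as FASTA with sequence lines wrapped at *wrap* columns."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def write_tsv(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as a TSV (no index column)."""
    rows.to_csv(path, sep="\t", index=False)


def _sniff_sep(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read the accession trait table (TSV or CSV, auto-detected).

    Columns: accession, group, brix, sucrose, fiber, reducing_sugar.  Missing
    cells (em-dash / "na" / empty) become NaN, never zero.  Group labels must
    come from :data:`GROUP_LABELS`; percents must be non-negative; accessions
    unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        return pd.DataFrame(columns=list(TRAIT_COLUMNS))
    sep = _sniff_sep(header)
    df = pd.read_csv(
        path, sep=sep, dtype={"accession": str, "group": str}, skipinitialspace=True
    )
    df.columns = [c.strip().lower() for c in df.columns]
    missing_cols = set(TRAIT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {sorted(missing_cols)}")
    df = df[list(TRAIT_COLUMNS)]
    if df.empty:
        return df
    df["accession"] = df["accession"].str.strip()
    df["group"] = df["group"].str.strip()
    for col in TRAIT_COLUMNS[2:]:
        df[col] = pd.to_numeric(
            df[col].astype(str).str.strip().map(lambda v: None if v in _MISSING else v),
            errors="raise",
        )
    dupes = df["accession"][df["accession"].duplicated()]
    if not dupes.empty:
        raise ParseError(f"{path}: duplicate accession {dupes.iloc[0]!r}")
    bad_groups = set(df["group"]) - GROUP_LABELS
    if bad_groups:
        raise ParseError(f"{path}: unknown group label(s) {sorted(bad_groups)}")
    for col in TRAIT_COLUMNS[2:]:
        if (df[col].dropna() < 0).any():
            raise ParseError(f"{path}: negative percent in column {col!r}")
    return df.reset_index(drop=True)


def load_sugar_traits() -> pd.DataFrame:
    """Load the packaged sugarcane accession trait table.

    Eighteen accessions: 6 high-sucrose (HS) and 7 low-sucrose (LS) hybrid
    clones, 4 ancestral Saccharum species, and the check cultivar ROC22, with
    field Brix, average sucrose, fiber and reducing-sugar percentages.
    """
    with importlib.resources.as_file(
        importlib.resources.files("polyhap").joinpath("data/sugar_traits.csv")
    ) as p:
        return read_trait_table(p)
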