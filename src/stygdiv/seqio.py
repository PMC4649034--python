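"""Alignment and metadata I/O, anchor-coordinate mapping, window extraction.

Sequences live in a gapped multiple sequence alignment of SSU rDNA.  Analysis
windows (e.g. the central SSU region or the V9 hypervariable region) are given
as 1-based inclusive coordinates on the *ungapped* residues of a designated
anchor row, and mapped through the alignment columns before any distance is
computed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: sequence provenance categories
SOURCES = ("culture", "clone", "pyrotag_v4", "pyrotag_v9", "pyrotag_v6v8")

# DNA alphabet after normalisation: canonical bases, N, IUPAC ambiguity, gap.
_ALLOWED = frozenset("ACGTNRYSWKMBDHV" + GAP)

#: metadata TSV column order
METADATA_COLUMNS = ("id", "species", "source", "count", "locality")


class SeqIOError(ValueError):
    """Malformed sequence or metadata input."""


def _log(level: str, msg: str) -> None:
    print(f"{level}: {msg}", file=sys.stderr)


def normalize_residues(residues: str, seq_id: str = "?") -> str:
    """Uppercase, map U->T, and reject characters outside the DNA alphabet."""
    s = residues.upper().replace("U", "T")
    bad = set(s) - _ALLOWED
    if bad:
        raise SeqIOError(
            f"sequence {seq_id!r} contains unsupported characters: "
            + ",".join(sorted(bad))
        )
    if not s:
        raise SeqIOError(f"sequence {seq_id!r} is empty")
    return s


@dataclass(frozen=True)
class AlignedSeq:
    """One (possibly gapped) alignment row with its survey metadata.

    ``count`` is read multiplicity (pyrotags arrive dereplicated); cultured
    strains and clones default to 1.
    """

    id: str
    residues: str
    species: str | None = None
    source: str = "clone"
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues, self.id))
        if self.source not in SOURCES:
            raise SeqIOError(f"{self.id}: unknown source {self.source!r}")
        if self.count < 0:
            raise SeqIOError(f"{self.id}: negative count")

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class AnchorWindow:
    """1-based inclusive interval on the ungapped anchor sequence."""

    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise SeqIOError(f"invalid window ({self.start},{self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


# the two analysis windows used throughout: the central SSU region and the
# short V9 hypervariable region, as anchor coordinates
SSU_WINDOW = AnchorWindow(545, 1544, "ssu")
V9_WINDOW = AnchorWindow(1645, 1774, "v9")


@dataclass
class Msa:
    """Equal-length alignment rows plus a designated coordinate anchor."""

    rows: list[AlignedSeq]
    anchor_id: str
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise SeqIOError("empty alignment")
        width = len(self.rows[0].residues)
        for r in self.rows:
            if len(r.residues) != width:
                raise SeqIOError(
                    f"ragged alignment: row {r.id!r} has length "
                    f"{len(r.residues)}, expected {width}"
                )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqIOError(f"duplicate sequence ids: {','.join(dupes)}")
        if self.anchor_id not in set(ids):
            raise SeqIOError(f"anchor {self.anchor_id!r} not in alignment")
        if not self.anchor().ungapped():
            raise SeqIOError("anchor row is all gaps")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def anchor(self) -> AlignedSeq:
        return next(r for r in self.rows if r.id == self.anchor_id)

    def row(self, seq_id: str) -> AlignedSeq:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)


def anchor_to_columns(msa: Msa, window: AnchorWindow) -> tuple[int, int]:
    """Map an ungapped-anchor interval to 1-based alignment columns.

    Returns the smallest column interval whose non-gap anchor positions are
    exactly ``window.start..window.end``; the position->column mapping is
    strictly increasing.
    """
    anchor = msa.anchor().residues
    cols = [i + 1 for i, ch in enumerate(anchor) if ch != GAP]
    if window.end > len(cols):
        raise SeqIOError(
            f"window ({window.start},{window.end}) exceeds ungapped anchor "
            f"length {len(cols)}"
        )
    return cols[window.start - 1], cols[window.end - 1]


def extract_window(msa: Msa, window: AnchorWindow) -> Msa:
    """Slice every row to the alignment columns spanned by ``window``.

    Rows that are entirely gaps inside the window are retained (downstream
    overlap rules decide their fate) but reported on standard error.
    """
    c1, c2 = anchor_to_columns(msa, window)
    rows = [replace(r, residues=r.residues[c1 - 1 : c2]) for r in msa.rows]
    n_empty = sum(1 for r in rows if not r.ungapped())
    if n_empty:
        _log("WARNING", f"{n_empty} rows are all-gap in window {window.name or window}")
    return Msa(rows=rows, anchor_id=msa.anchor_id)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the metadata TSV (columns id, species, source, count, locality)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(METADATA_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise SeqIOError(f"metadata missing columns: {','.join(sorted(missing))}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise SeqIOError(f"duplicate metadata ids: {','.join(dupes)}")
    return df.set_index("id")


def read_alignment(
    fasta_path: str | Path,
    metadata_path: str | Path | None,
    anchor_id: str,
) -> Msa:
    """Read a gapped FASTA plus optional metadata TSV into an :class:`Msa`.

    Rows without a metadata entry get species blank, source ``clone`` and
    count 1; a missing metadata file means all rows take the defaults.
    """
    meta = read_metadata(metadata_path) if metadata_path else None
    rows: list[AlignedSeq] = []
    n_joined = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        species, source, count = None, "clone", 1
        if meta is not None and rec.id in meta.index:
            m = meta.loc[rec.id]
            species = m["species"] or None
            source = m["source"] or "clone"
            count = int(m["count"]) if m["count"] else 1
            n_joined += 1
        rows.append(
            AlignedSeq(rec.id, str(rec.seq), species=species, source=source, count=count)
        )
    if not rows:
        raise SeqIOError(f"no sequences in {fasta_path}")
    _log("INFO", f"read {len(rows)} rows, {n_joined} with metadata")
    return Msa(rows=rows, anchor_id=anchor_id)


def write_alignment(msa_or_rows: Msa | Iterable[AlignedSeq], path: str | Path) -> None:
    rows = msa_or_rows.rows if isinstance(msa_or_rows, Msa) else list(msa_or_rows)
    records = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in rows]
    SeqIO.write(records, str(path), "fasta")


def write_metadata(rows: Iterable[AlignedSeq], path: str | Path,
                   locality: Mapping[str, str] | None = None) -> None:
    locality = locality or {}
    df = pd.DataFrame(
        [
            {
                "id": r.id,
                "species": r.species or "",
                "source": r.source,
                "count": r.count,
                "locality": locality.get(r.id, ""),
            }
            for r in rows
        ],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)
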