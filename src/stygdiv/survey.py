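"""Species x detection-method incidence tables and recovery statistics.

Compares what culturing and the culture-independent methods (environmental
clone libraries and pyrotag surveys of the V4, V9 and V6-V8 regions) each
reveal of a family's species diversity.  The packaged fixture
``stygiellidae_survey.tsv`` encodes the published incidence for the
Stygiellidae: 10 species (6 cultured, 4 known only as environmental clades),
21 cultured strains, 83 environmental clones and 629 pyrotags; published
per-species counts are sparse, so unprinted cells carry an ``NP`` marker —
detected, count unknown — and column totals ride in a ``TOTAL`` row.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import SOURCES

METHODS = list(SOURCES)  # culture, clone, pyrotag_v4, pyrotag_v9, pyrotag_v6v8
ENVIRONMENTAL_METHODS = METHODS[1:]
UNRESOLVED = "unresolved"

_ROMAN_VAL = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}


def _roman_to_int(s: str) -> int:
    total = 0
    for ch, nxt in zip(s, list(s[1:]) + [""]):
        v = _ROMAN_VAL[ch]
        total += -v if nxt and _ROMAN_VAL[nxt] > v else v
    return total


def _species_sort_key(label: str) -> tuple:
    if label == UNRESOLVED:
        return (2, 0, "")
    if label.startswith("EC "):
        return (1, _roman_to_int(label[3:]), label)
    return (0, 0, label)


@dataclass
class SurveyTable:
    """Counts and detection of each species/EC by each survey method.

    ``counts`` holds floats with ``NaN`` where a lineage is known to be
    detected but its count was never published; ``detected`` is the boolean
    incidence; ``method_totals`` carries per-method sequence totals (from the
    data when counts are complete, from a totals row otherwise).
    """

    counts: pd.DataFrame
    detected: pd.DataFrame
    method_totals: pd.Series

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    def total_environmental(self) -> int:
        return int(self.method_totals[ENVIRONMENTAL_METHODS].sum())

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.fillna(0).astype(int).astype(object)
        out[self.counts.isna() & self.detected] = "NP"
        out.loc["TOTAL"] = self.method_totals.astype(int)
        out.index.name = "species"
        out.to_csv(path, sep="\t")


def tally(records: pd.DataFrame | Iterable) -> SurveyTable:
    """Sum (species, source, count) records into a survey table.

    ``records`` is a DataFrame with columns species/source/count, or an
    iterable of objects or mappings exposing them.  Species order in the
    result: named species, then ECs by numeral, then ``unresolved``.
    """
    if not isinstance(records, pd.DataFrame):
        rows = []
        for r in records:
            if isinstance(r, dict):
                rows.append(r)
            else:
                rows.append(
                    {"species": r.species or UNRESOLVED, "source": r.source,
                     "count": r.count}
                )
        records = pd.DataFrame(rows, columns=["species", "source", "count"])
    bad = set(records["source"]) - set(METHODS) if len(records) else set()
    if bad:
        raise ValueError(f"unknown source(s): {','.join(sorted(map(str, bad)))}")
    species = sorted(set(records["species"]), key=_species_sort_key)
    counts = pd.DataFrame(0.0, index=species, columns=METHODS)
    for _, rec in records.iterrows():
        counts.loc[rec["species"], rec["source"]] += int(rec["count"])
    return SurveyTable(
        counts=counts,
        detected=counts > 0,
        method_totals=counts.sum(axis=0),
    )


def read_survey(path: str | Path) -> SurveyTable:
    """Read a survey TSV that may contain NP markers and a TOTAL row."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = set(METHODS) - set(raw.columns)
    if missing:
        raise ValueError(f"survey table missing methods: {','.join(sorted(missing))}")
    raw = raw[METHODS]
    if "TOTAL" in raw.index:
        totals = raw.loc["TOTAL"].astype(float)
        raw = raw.drop(index="TOTAL")
    else:
        totals = None
    counts = raw.replace("NP", np.nan).astype(float)
    detected = (raw == "NP") | (counts > 0)
    if totals is None:
        totals = counts.sum(axis=0)
    return SurveyTable(counts=counts, detected=detected, method_totals=totals)


def load_survey_fixture() -> SurveyTable:
    """The packaged Stygiellidae incidence table."""
    ref = resources.files("stygdiv.data").joinpath("stygiellidae_survey.tsv")
    with resources.as_file(ref) as path:
        return read_survey(path)


def default_universe(table: SurveyTable) -> list[str]:
    """Species counted toward diversity: everything except the unresolved
    bin and EC V (known only from a 172-bp fragment, left out of the
    at-least-10-species tally)."""
    return [s for s in table.species if s not in (UNRESOLVED, "EC V")]


def recovery_fraction(
    table: SurveyTable,
    methods: Sequence[str],
    species_universe: Sequence[str] | None = None,
) -> float:
    """Fraction of the species universe detected by >=1 of the given methods."""
    universe = list(species_universe) if species_universe is not None else default_universe(table)
    if not universe:
        raise ValueError("empty species universe")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s): {','.join(sorted(unknown))}")
    det = table.detected.reindex(universe).fillna(False)[list(methods)]
    return float(det.any(axis=1).sum()) / len(universe)


def relative_abundance(table: SurveyTable) -> pd.DataFrame:
    """Column-normalised fractions over the cells with published counts.

    Each column with a positive defined sum is scaled to sum to 1 across its
    defined cells; columns with no defined positive counts come back all-NaN.
    """
    counts = table.counts
    sums = counts.sum(axis=0, skipna=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts.div(sums.where(sums > 0), axis=1)
    return frac


_SHADES = " .:+*#"


def render_heatmap(table: SurveyTable) -> str:
    """Plain-text heat map: darker glyph = higher within-method abundance;
    ``?`` marks detected lineages with unpublished counts."""
    frac = relative_abundance(table)
    width = max(len(s) for s in table.species) + 2
    header = " " * width + " ".join(f"{m:>12}" for m in METHODS)
    lines = [header]
    for sp in table.species:
        cells = []
        for m in METHODS:
            if table.detected.loc[sp, m] and np.isnan(table.counts.loc[sp, m]):
                glyph = "?"
            elif not table.detected.loc[sp, m]:
                glyph = _SHADES[0]
            else:
                f = frac.loc[sp, m]
                glyph = _SHADES[min(int(np.ceil(float(f) * (len(_SHADES) - 1))), len(_SHADES) - 1)]
            cells.append(f"{glyph:>12}")
        lines.append(f"{sp:<{width}}" + " ".join(cells))
    return "\n".join(lines)
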