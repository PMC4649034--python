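"""Uncorrected p-distances with pairwise deletion, and intra/inter summaries.

The p-distance between two aligned rows is the fraction of mismatched sites
among the sites where *both* rows carry an unambiguous base (A/C/G/T); gaps,
N and IUPAC ambiguity codes are excluded pair-by-pair (pairwise deletion).
A comparison with fewer than ``min_sites`` usable sites is undefined — short
fragments can overlap a reference by almost nothing, and a distance computed
on a handful of sites is noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import AlignedSeq, Msa

#: default minimum comparable sites for full-length SSU comparisons
MIN_SITES_FULL = 100
#: default minimum for short V9-sized fragments (window is only 130 sites)
MIN_SITES_FRAGMENT = 80

# byte -> base code; 255 marks missing data (gap, N, ambiguity codes)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode(residues: str) -> np.ndarray:
    """Encode residues as uint8 codes, 255 for anything non-ACGT."""
    return _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def encode_rows(rows: Sequence[AlignedSeq] | Msa) -> np.ndarray:
    rows = rows.rows if isinstance(rows, Msa) else rows
    return np.vstack([encode(r.residues) for r in rows])


def p_distance(
    row_a: str | np.ndarray, row_b: str | np.ndarray, min_sites: int = MIN_SITES_FULL
) -> float:
    """Uncorrected p-distance; ``nan`` when fewer than ``min_sites`` sites align."""
    a = encode(row_a) if isinstance(row_a, str) else row_a
    b = encode(row_b) if isinstance(row_b, str) else row_b
    if a.shape != b.shape:
        raise ValueError(f"unequal lengths: {a.size} vs {b.size}")
    comparable = (a != 255) & (b != 255)
    n = int(comparable.sum())
    if n < min_sites:
        return float("nan")
    return float(((a != b) & comparable).sum()) / n


def cross_distances(
    queries: np.ndarray, refs: np.ndarray, min_sites: int
) -> tuple[np.ndarray, np.ndarray]:
    """All query x reference p-distances at once.

    Returns ``(distances, overlaps)``; undefined distances are ``nan``.
    Both inputs are code matrices from :func:`encode_rows`.
    """
    qv = queries[:, None, :] != 255
    rv = refs[None, :, :] != 255
    comparable = qv & rv
    n = comparable.sum(axis=2)
    mism = ((queries[:, None, :] != refs[None, :, :]) & comparable).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n >= min_sites, mism / np.maximum(n, 1), np.nan)
    return d, n


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix; ``nan`` marks undefined comparisons."""

    ids: list[str]
    values: np.ndarray
    min_sites: int

    def __post_init__(self) -> None:
        v = self.values
        assert v.shape == (len(self.ids), len(self.ids))
        assert np.allclose(np.diagonal(v), 0.0)

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.dataframe().round(4).to_csv(path, sep="\t", na_rep="NA")

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])


def distance_matrix(msa: Msa | Sequence[AlignedSeq], min_sites: int = MIN_SITES_FULL) -> DistanceMatrix:
    rows = msa.rows if isinstance(msa, Msa) else list(msa)
    if not rows:
        raise ValueError("empty alignment")
    codes = encode_rows(rows)
    d, _ = cross_distances(codes, codes, min_sites)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=[r.id for r in rows], values=d, min_sites=min_sites)


@dataclass
class DistanceSummary:
    """Per-species maximum intra- and per-pair minimum inter-species distance.

    ``max_intra`` omits singleton species (no intra pair); ``min_inter`` has
    an entry for every unordered species pair with at least one defined cross
    distance.
    """

    max_intra: dict[str, float]
    min_inter: dict[tuple[str, str], float]

    def dataframe(self) -> pd.DataFrame:
        recs = [
            {"group": sp, "statistic": "max_intra", "value": v}
            for sp, v in sorted(self.max_intra.items())
        ] + [
            {"group": f"{a}|{b}", "statistic": "min_inter", "value": v}
            for (a, b), v in sorted(self.min_inter.items())
        ]
        return pd.DataFrame(recs, columns=["group", "statistic", "value"])


def summarize(matrix: DistanceMatrix, species_labels: Mapping[str, str]) -> DistanceSummary:
    """Reduce a distance matrix to the intra/inter-species envelope."""
    labels = {i: species_labels[i] for i in matrix.ids if species_labels.get(i)}
    if not labels:
        raise ValueError("no species labels provided")
    by_species: dict[str, list[int]] = {}
    for idx, seq_id in enumerate(matrix.ids):
        if seq_id in labels:
            by_species.setdefault(labels[seq_id], []).append(idx)
    species = sorted(by_species)
    v = matrix.values
    max_intra: dict[str, float] = {}
    for sp in species:
        idxs = by_species[sp]
        if len(idxs) < 2:
            continue
        sub = v[np.ix_(idxs, idxs)]
        vals = sub[np.triu_indices(len(idxs), k=1)]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            max_intra[sp] = float(vals.max())
    min_inter: dict[tuple[str, str], float] = {}
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            cross = v[np.ix_(by_species[a], by_species[b])]
            cross = cross[~np.isnan(cross)]
            if cross.size:
                min_inter[(a, b)] = float(cross.min())
    return DistanceSummary(max_intra=max_intra, min_inter=min_inter)
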