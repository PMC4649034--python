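"""Synthetic reference communities, noisy fragments, and survey records.

The generator plants a community with the statistical structure the analysis
assumes: K species whose strains stay within a maximum intraspecific
p-distance while species ancestors keep every interspecific distance above a
floor (the barcoding gap), a subset of species with cultured members, short
hypervariable-window fragments with per-site sequencing error, and a
strongly skewed per-species abundance profile — a few hyper-abundant
lineages over a long rare tail, as pyrotag surveys of anoxic habitats show.

Everything is reproducible from ``SimConfig.seed``; each stage derives its
own stream so regenerating fragments never perturbs the references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, floor
from typing import Sequence

import numpy as np
import pandas as pd

from . import distance
from .seqio import SSU_WINDOW, V9_WINDOW, AlignedSeq, AnchorWindow, Msa, extract_window

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: expected fragment counts per species, most to least abundant
DEFAULT_ABUNDANCE = (250, 120, 100, 40, 15, 5, 3, 2, 1, 1)


@dataclass(frozen=True)
class SimConfig:
    n_species: int = 10
    n_cultured: int = 6
    strains_min: int = 2
    strains_max: int = 6
    seq_length: int = 1800
    d_intra_max: float = 0.046
    d_inter_min: float = 0.067
    windows: tuple[AnchorWindow, ...] = (SSU_WINDOW, V9_WINDOW)
    fragment_error: float = 0.002
    abundance_profile: tuple[int, ...] = DEFAULT_ABUNDANCE
    indel_columns: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_cultured <= self.n_species:
            raise ValueError("need 0 < n_cultured <= n_species")
        if not self.d_intra_max < self.d_inter_min:
            raise ValueError("d_intra_max must be below d_inter_min")
        for w in self.windows:
            if w.end > self.seq_length:
                raise ValueError(f"window {w} outside sequence length")
        for p in (self.fragment_error,):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        if self.strains_min < 1 or self.strains_max < self.strains_min:
            raise ValueError("bad strain range")

    def expected_counts(self) -> np.ndarray:
        prof = np.asarray(self.abundance_profile, dtype=float)
        if prof.size >= self.n_species:
            return prof[: self.n_species]
        return np.concatenate([prof, np.ones(self.n_species - prof.size)])


@dataclass
class ReferenceSet:
    """Generated reference alignment plus its ground truth."""

    msa: Msa
    metadata: pd.DataFrame
    planted: dict[str, str]  # id -> planted species label
    species_labels: list[str] = field(default_factory=list)

    def cultured_labels(self) -> list[str]:
        return sorted(
            {self.planted[r.id] for r in self.msa.rows if r.source == "culture"}
        )


def _mutate(codes: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    out[sites] = (out[sites] + rng.integers(1, 4, size=sites.size)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def generate_references(config: SimConfig, max_attempts: int = 1000) -> ReferenceSet:
    """Draw a community satisfying the distance envelope, audited post hoc.

    A random ancestor spawns one mutated ancestor per species; species
    ancestors are rejection-sampled until every pairwise p-distance reaches
    ``d_inter_min + d_intra_max``, which leaves room for strain noise.  Each
    strain then mutates its species ancestor at up to
    ``floor(d_intra_max/2 * L)`` sites.  The finished community is audited
    by brute-force distance summary and redrawn wholesale on any breach.
    """
    rng = np.random.default_rng([config.seed, 0])
    L = config.seq_length
    floor_sep = config.d_inter_min + config.d_intra_max
    m_anc = ceil(0.65 * floor_sep * L)
    max_strain_mut = floor(config.d_intra_max / 2 * L)
    labels = [f"sp{i + 1:02d}" for i in range(config.n_species)]

    for _ in range(max_attempts):
        ancestor = rng.integers(0, 4, size=L, dtype=np.uint8)
        anc_species = [
            _mutate(ancestor, rng.choice(L, size=m_anc, replace=False), rng)
            for _ in range(config.n_species)
        ]
        ok = all(
            np.mean(anc_species[i] != anc_species[j]) >= floor_sep
            for i in range(config.n_species)
            for j in range(i + 1, config.n_species)
        )
        if not ok:
            continue
        rows: list[AlignedSeq] = []
        planted: dict[str, str] = {}
        for i, label in enumerate(labels):
            cultured = i < config.n_cultured
            n_strains = int(rng.integers(config.strains_min, config.strains_max + 1))
            for j in range(n_strains):
                k = int(rng.integers(0, max_strain_mut + 1))
                codes = _mutate(
                    anc_species[i], rng.choice(L, size=k, replace=False), rng
                )
                seq_id = f"{label}_{'s' if cultured else 'c'}{j + 1:02d}"
                rows.append(
                    AlignedSeq(
                        seq_id,
                        _decode(codes),
                        species=label if cultured else None,
                        source="culture" if cultured else "clone",
                        count=1,
                    )
                )
                planted[seq_id] = label
        if config.indel_columns:
            rows = _plant_indel_columns(rows, config.indel_columns, rng)
        matrix = distance.distance_matrix(rows, min_sites=distance.MIN_SITES_FULL)
        summary = distance.summarize(matrix, planted)
        if summary.max_intra and max(summary.max_intra.values()) > config.d_intra_max:
            continue
        if summary.min_inter and min(summary.min_inter.values()) < config.d_inter_min:
            continue
        msa = Msa(rows=rows, anchor_id=rows[0].id)
        meta = pd.DataFrame(
            [
                {"id": r.id, "species": r.species or "", "source": r.source,
                 "count": r.count, "locality": ""}
                for r in rows
            ]
        )
        return ReferenceSet(msa=msa, metadata=meta, planted=planted, species_labels=labels)
    raise RuntimeError(
        "could not satisfy the distance envelope; loosen d_inter_min/d_intra_max "
        "or increase seq_length"
    )


def _plant_indel_columns(
    rows: list[AlignedSeq], n_columns: int, rng: np.random.Generator
) -> list[AlignedSeq]:
    """Insert alignment columns carried by ~30% of non-anchor rows.

    The anchor (first row) always takes a gap, so window coordinates on the
    ungapped anchor are unaffected; the new columns exercise pairwise
    deletion downstream.
    """
    L = len(rows[0].residues)
    positions = sorted(rng.integers(1, L, size=n_columns).tolist(), reverse=True)
    seqs = [list(r.residues) for r in rows]
    for pos in positions:
        carriers = rng.random(len(rows)) < 0.3
        carriers[0] = False
        base_idx = rng.integers(0, 4, size=len(rows))
        for ri, s in enumerate(seqs):
            s.insert(pos, chr(_BASES[base_idx[ri]]) if carriers[ri] else "-")
    return [
        AlignedSeq(r.id, "".join(s), species=r.species, source=r.source, count=r.count)
        for r, s in zip(rows, seqs)
    ]


def generate_fragments(
    refs: ReferenceSet,
    config: SimConfig,
    window: AnchorWindow | None = None,
) -> tuple[list[AlignedSeq], pd.DataFrame]:
    """Cut noisy window fragments with a skewed per-species abundance.

    Per-species fragment counts are Poisson draws around the expected
    abundance profile; each fragment is a uniformly chosen strain's window
    slice with independent per-site substitution errors at
    ``config.fragment_error`` (non-gap sites only).  Returns the fragments
    and a truth table (fragment, source strain, species, errors planted).
    """
    rng = np.random.default_rng([config.seed, 1])
    window = window or config.windows[-1]
    window_msa = extract_window(refs.msa, window)
    slices = {r.id: r.residues for r in window_msa.rows}
    by_species: dict[str, list[str]] = {}
    for seq_id, label in refs.planted.items():
        by_species.setdefault(label, []).append(seq_id)
    expected = refs_expected = config.expected_counts()

    fragments: list[AlignedSeq] = []
    truth_rows = []
    counter = 0
    for i, label in enumerate(refs.species_labels):
        n = int(rng.poisson(refs_expected[i]))
        members = sorted(by_species[label])
        for _ in range(n):
            strain = members[int(rng.integers(0, len(members)))]
            codes = distance.encode(slices[strain]).copy()
            sites = np.flatnonzero((rng.random(codes.size) < config.fragment_error) & (codes != 255))
            codes[sites] = (codes[sites] + rng.integers(1, 4, size=sites.size)) % 4
            residues = "".join(
                chr(_BASES[c]) if c != 255 else orig
                for c, orig in zip(codes, slices[strain])
            )
            counter += 1
            frag_id = f"frag{counter:05d}"
            fragments.append(
                AlignedSeq(frag_id, residues, source="pyrotag_v9", count=1)
            )
            truth_rows.append(
                {"id": frag_id, "strain": strain, "species": label,
                 "n_errors": int(sites.size)}
            )
    truth = pd.DataFrame(truth_rows, columns=["id", "strain", "species", "n_errors"])
    return fragments, truth


def generate_survey_records(
    truth: pd.DataFrame,
    refs: ReferenceSet,
    config: SimConfig,
    preset: str | None = None,
) -> pd.DataFrame:
    """Build (species, source, count) records for :func:`stygdiv.survey.tally`.

    Default mapping: cultured strains -> culture records, uncultured
    reference clones -> clone records, fragments -> V9 pyrotag records.  The
    ``"published_survey"`` preset instead reproduces the packaged
    Stygiellidae incidence pattern (6 cultured species of which 2 were never
    seen environmentally, 4 environmental clades), distributing each
    method's published total across its detected lineages: unpublished cells
    take 1 read each and the first detected lineage absorbs the remainder.
    The preset's per-cell counts are synthetic stand-ins; only the incidence
    pattern and column totals are faithful.
    """
    if preset == "published_survey":
        from .survey import load_survey_fixture

        table = load_survey_fixture()
        rows = []
        for method in table.counts.columns:
            col = table.counts[method]
            det = table.detected[method]
            np_rows = [s for s in table.species if det[s] and np.isnan(col[s])]
            defined = float(col.fillna(0).sum())
            remainder = int(table.method_totals[method] - defined) - len(np_rows)
            for k, sp in enumerate(np_rows):
                count = 1 + (remainder if k == 0 else 0)
                rows.append({"species": sp, "source": method, "count": count})
            for sp in table.species:
                if det[sp] and not np.isnan(col[sp]) and col[sp] > 0:
                    rows.append({"species": sp, "source": method, "count": int(col[sp])})
        return pd.DataFrame(rows, columns=["species", "source", "count"])
    if preset is not None:
        raise ValueError(f"unknown preset {preset!r}")

    rows = [
        {"species": refs.planted[r.id], "source": r.source, "count": r.count}
        for r in refs.msa.rows
    ]
    rows += [
        {"species": rec["species"], "source": "pyrotag_v9", "count": 1}
        for rec in truth.to_dict("records")
    ]
    return pd.DataFrame(rows, columns=["species", "source", "count"])
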