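"""Distance-envelope assignment of short environmental fragments.

A hypervariable-region fragment (e.g. a V9 pyrotag) is assigned to the
species or environmental clade whose members it approaches at least as
closely as that clade's own intraspecific spread — allowing a small slack,
since short reads carry sequencing error.  Fragments no species can claim
enter a founder pool; founder OTUs far enough (> t_inter) from everything
known establish new environmental clades, the route by which EC V entered
the family.  Also here: the helix-27 diagnostic base-pair check that
separates Andalucina (C:G) from other jakobids (A:T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import Cluster, OtuSet, Partition, otu_cluster, roman
from .distance import (
    MIN_SITES_FRAGMENT,
    cross_distances,
    distance_matrix,
    encode_rows,
    summarize,
)
from .seqio import AlignedSeq, Msa

SLACK_DEFAULT = 0.01  # ~1 substitution on a 130-site V9 fragment
AMBIGUITY_TOL = 1e-9


@dataclass(frozen=True)
class Assignment:
    query_id: str
    status: str  # assigned | ambiguous | unassigned_low_overlap | founder_pool
    species: str | None = None
    best_distance: float = float("nan")
    overlap_sites: int = 0
    nearest_reference: str = ""


def assignments_dataframe(assignments: Sequence[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query": a.query_id,
                "status": a.status,
                "species": a.species or "",
                "distance": a.best_distance,
                "overlap": a.overlap_sites,
                "nearest_reference": a.nearest_reference,
            }
            for a in assignments
        ],
        columns=["query", "status", "species", "distance", "overlap", "nearest_reference"],
    )


def species_envelopes(
    references: Msa | Sequence[AlignedSeq],
    partition: Partition,
    min_sites: int = MIN_SITES_FRAGMENT,
) -> dict[str, float]:
    """Per-cluster maximum intraspecific distance over the reference window.

    Singleton clusters (one member, hence no intra pair) get envelope 0.
    """
    matrix = distance_matrix(references, min_sites=min_sites)
    labels = {m: c.label for c in partition.clusters for m in c.members}
    summary = summarize(matrix, labels)
    return {c.label: summary.max_intra.get(c.label, 0.0) for c in partition.clusters}


def assign_fragments(
    queries: Sequence[AlignedSeq],
    references: Msa | Sequence[AlignedSeq],
    partition: Partition,
    slack: float = SLACK_DEFAULT,
    min_sites: int = MIN_SITES_FRAGMENT,
    max_intra: Mapping[str, float] | None = None,
) -> list[Assignment]:
    """Assign each query to the species whose distance envelope admits it.

    For query q and species s, d(q, s) is the minimum p-distance from q to
    the members of s over the shared window.  The closest species s* claims
    q iff d(q, s*) <= max_intra(s*) + slack; a second species satisfying its
    envelope at a distance within 1e-9 of the best makes the call ambiguous;
    queries too far from every envelope enter the founder pool; queries with
    fewer than ``min_sites`` comparable sites against every reference are
    unassignable for lack of overlap.
    """
    refs = references.rows if isinstance(references, Msa) else list(references)
    if not refs:
        raise ValueError("empty reference set")
    if not queries:
        return []
    if max_intra is None:
        max_intra = species_envelopes(refs, partition, min_sites=min_sites)
    ref_ids = [r.id for r in refs]
    member_cols = {
        c.label: [ref_ids.index(m) for m in c.members if m in ref_ids]
        for c in partition.clusters
    }
    d, overlap = cross_distances(encode_rows(queries), encode_rows(refs), min_sites)

    out: list[Assignment] = []
    for qi, q in enumerate(queries):
        dq, oq = d[qi], overlap[qi]
        if np.all(np.isnan(dq)):
            out.append(
                Assignment(q.id, "unassigned_low_overlap", overlap_sites=int(oq.max()))
            )
            continue
        d_species = {}
        for label, cols in member_cols.items():
            if not cols:
                continue
            vals = dq[cols]
            vals = vals[~np.isnan(vals)]
            if vals.size:
                d_species[label] = float(vals.min())
        best_label = min(d_species, key=lambda s: (d_species[s], s))
        best_d = d_species[best_label]
        ri = int(np.nanargmin(np.where(np.isnan(dq), np.inf, dq)))
        nearest = ref_ids[ri]
        satisfied = {
            s for s, ds in d_species.items() if ds <= max_intra.get(s, 0.0) + slack
        }
        if best_label not in satisfied:
            out.append(
                Assignment(q.id, "founder_pool", best_distance=best_d,
                           overlap_sites=int(oq[ri]), nearest_reference=nearest)
            )
        elif any(
            s != best_label and abs(d_species[s] - best_d) <= AMBIGUITY_TOL
            for s in satisfied
        ):
            out.append(
                Assignment(q.id, "ambiguous", best_distance=best_d,
                           overlap_sites=int(oq[ri]), nearest_reference=nearest)
            )
        else:
            out.append(
                Assignment(q.id, "assigned", species=best_label, best_distance=best_d,
                           overlap_sites=int(oq[ri]), nearest_reference=nearest)
            )
    return out


def assign_fragment(
    query: AlignedSeq,
    references: Msa | Sequence[AlignedSeq],
    partition: Partition,
    slack: float = SLACK_DEFAULT,
    min_sites: int = MIN_SITES_FRAGMENT,
    max_intra: Mapping[str, float] | None = None,
) -> Assignment:
    return assign_fragments([query], references, partition, slack, min_sites, max_intra)[0]


@dataclass
class NewClades:
    """Environmental clades founded from the unassignable-fragment pool."""

    clusters: list[Cluster]
    otus: OtuSet
    overlap_incomplete: set[str] = field(default_factory=set)


def found_new_ecs(
    founder_queries: Sequence[AlignedSeq],
    references: Msa | Sequence[AlignedSeq],
    partition: Partition,
    identity_cutoff: float = 0.97,
    t_intra: float | None = None,
    t_inter: float | None = None,
    min_sites: int = MIN_SITES_FRAGMENT,
) -> NewClades:
    """Cluster founder-pool fragments into OTUs and promote distant ones to ECs.

    An OTU becomes (part of) a new environmental clade when its minimum
    distance to every existing clade exceeds ``t_inter`` wherever the overlap
    suffices to compute one; OTUs that cannot be compared against some clade
    at all are still founded but flagged overlap-incomplete.  Founded OTUs
    mutually within ``t_intra`` merge into a single clade, numbered after the
    existing ECs.
    """
    t_intra = partition.t_intra if t_intra is None else t_intra
    t_inter = partition.t_inter if t_inter is None else t_inter
    if not founder_queries:
        return NewClades([], OtuSet([], identity_cutoff))
    refs = references.rows if isinstance(references, Msa) else list(references)
    ref_ids = [r.id for r in refs]
    otus = otu_cluster(founder_queries, identity_cutoff, min_sites=min_sites)
    q_by_id = {q.id: q for q in founder_queries}
    d, _ = cross_distances(encode_rows(founder_queries), encode_rows(refs), min_sites)
    q_row = {q.id: i for i, q in enumerate(founder_queries)}
    member_cols = {
        c.label: [ref_ids.index(m) for m in c.members if m in ref_ids]
        for c in partition.clusters
    }

    founded: list[int] = []
    incomplete: set[int] = set()
    for k, otu in enumerate(otus.otus):
        rows = [q_row[m] for m in otu.members]
        distant, incomparable = True, False
        for label, cols in member_cols.items():
            if not cols:
                continue
            vals = d[np.ix_(rows, cols)]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                incomparable = True
            elif float(vals.min()) <= t_inter:
                distant = False
                break
        if distant:
            founded.append(k)
            if incomparable:
                incomplete.add(k)
    if not founded:
        return NewClades([], otus)

    # merge founded OTUs mutually within t_intra (min member-to-member distance)
    dq, _ = cross_distances(
        encode_rows(founder_queries), encode_rows(founder_queries), min_sites
    )
    n = len(founded)
    adj = np.eye(n, dtype=bool)
    for a in range(n):
        ra = [q_row[m] for m in otus.otus[founded[a]].members]
        for b in range(a + 1, n):
            rb = [q_row[m] for m in otus.otus[founded[b]].members]
            vals = dq[np.ix_(ra, rb)]
            vals = vals[~np.isnan(vals)]
            if vals.size and float(vals.min()) <= t_intra:
                adj[a, b] = adj[b, a] = True
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    _, comp = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[int]] = {}
    for pos, c in enumerate(comp):
        groups.setdefault(int(c), []).append(founded[pos])

    n_existing_ec = sum(1 for c in partition.clusters if c.label.startswith("EC "))
    ordered = sorted(
        groups.values(),
        key=lambda ks: (
            -sum(len(otus.otus[k].members) for k in ks),
            min(min(otus.otus[k].members) for k in ks),
        ),
    )
    clusters: list[Cluster] = []
    flagged: set[str] = set()
    for j, ks in enumerate(ordered, start=n_existing_ec + 1):
        members = tuple(m for k in ks for m in otus.otus[k].members)
        label = f"EC {roman(j)}"
        clusters.append(Cluster(label, members, False))
        if any(k in incomplete for k in ks):
            flagged.add(label)
    return NewClades(clusters=clusters, otus=otus, overlap_incomplete=flagged)


@dataclass(frozen=True)
class SignatureCall:
    query_id: str
    call: str  # CG | AT | other
    columns: tuple[int, int]


def call_signature(row: AlignedSeq, col_pair: tuple[int, int]) -> SignatureCall:
    """Check the diagnostic paired-site motif at two 1-based alignment columns.

    Returns CG for a C:G pair (the Andalucina state), AT for A:T (other
    jakobids), and "other" for anything else, including gaps and ambiguity
    codes.  Orientation is strict: G:C does not count as CG.
    """
    c1, c2 = col_pair
    if not (1 <= c1 <= len(row.residues) and 1 <= c2 <= len(row.residues)):
        raise IndexError(f"signature columns {col_pair} outside alignment width {len(row.residues)}")
    pair = (row.residues[c1 - 1], row.residues[c2 - 1])
    if pair == ("C", "G"):
        call = "CG"
    elif pair == ("A", "T"):
        call = "AT"
    else:
        call = "other"
    return SignatureCall(row.id, call, (c1, c2))
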