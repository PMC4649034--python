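"""Greedy OTU clustering and single-linkage species delimitation."""

import numpy as np
import pytest

from stygdiv import AlignedSeq, DistanceMatrix, check_gap, delimit, distance_matrix, otu_cluster
from stygdiv.cluster import SpeciesConflictError, roman

from conftest import random_dna, seq_with_mismatches


def matrix_from(ids, dense):
    v = np.asarray(dense, dtype=float)
    return DistanceMatrix(ids=list(ids), values=v, min_sites=1)


def enumerate_partitions(items):
    """All set partitions (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in enumerate_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def single_linkage_oracle(ids, values, t):
    """The unique partition where every cluster is internally chained at <=t
    and no <=t edge crosses clusters; found by exhaustive enumeration."""
    n = len(ids)
    edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if not np.isnan(values[i, j]) and values[i, j] <= t
    }
    matches = []
    for part in enumerate_partitions(range(n)):
        cluster_of = {x: k for k, cl in enumerate(part) for x in cl}
        if any(cluster_of[i] != cluster_of[j] for i, j in edges):
            continue
        ok = True
        for cl in part:
            # internal connectivity via <=t edges only
            if len(cl) == 1:
                continue
            reach = {cl[0]}
            frontier = [cl[0]]
            members = set(cl)
            while frontier:
                x = frontier.pop()
                for y in members - reach:
                    if (min(x, y), max(x, y)) in edges:
                        reach.add(y)
                        frontier.append(y)
            if reach != members:
                ok = False
                break
        if ok:
            matches.append(frozenset(frozenset(ids[x] for x in cl) for cl in part))
    assert len(matches) == 1
    return matches[0]


class TestOtuCluster:
    def test_identical_sequences_one_otu(self):
        seqs = [AlignedSeq(f"s{i}", "ACGT" * 30) for i in range(3)]
        otus = otu_cluster(seqs, min_sites=10)
        assert len(otus) == 1
        assert otus.otus[0].total_count == 3

    def test_below_cutoff_splits(self):
        rng = np.random.default_rng(0)
        a = random_dna(rng, 100)
        b = seq_with_mismatches(a, range(5))  # identity 0.95 < 0.97
        otus = otu_cluster([AlignedSeq("a", a), AlignedSeq("b", b)], min_sites=10)
        assert len(otus) == 2

    def test_greedy_trace_representative_only(self):
        """B joins A (identity 0.98); C is 0.96 from representative A, so C
        founds its own OTU even though C is within 0.98 of B."""
        rng = np.random.default_rng(1)
        a = random_dna(rng, 100)
        b = seq_with_mismatches(a, [0, 1])
        c = seq_with_mismatches(b, [10, 11])
        seqs = [
            AlignedSeq("A", a, count=5),
            AlignedSeq("B", b, count=3),
            AlignedSeq("C", c, count=2),
        ]
        otus = otu_cluster(seqs, min_sites=10)
        members = sorted(tuple(sorted(o.members)) for o in otus.otus)
        assert members == [("A", "B"), ("C",)]
        assert {o.representative for o in otus.otus} == {"A", "C"}

    def test_empty_input(self):
        assert len(otu_cluster([], min_sites=10)) == 0

    def test_representatives_mutually_distinct(self):
        """No OTU representative lies within the cutoff of an earlier one."""
        rng = np.random.default_rng(5)
        base = random_dna(rng, 200)
        seqs = [
            AlignedSeq(f"s{i:02d}", seq_with_mismatches(base, rng.choice(200, size=rng.integers(0, 20), replace=False)))
            for i in range(30)
        ]
        otus = otu_cluster(seqs, min_sites=10)
        from stygdiv import p_distance

        by_id = {s.id: s.residues for s in seqs}
        reps = [by_id[o.representative] for o in otus.otus]
        for i, ra in enumerate(reps):
            # each later rep failed to join every earlier OTU
            for rb in reps[:i]:
                assert 1.0 - p_distance(ra, rb, min_sites=10) < otus.identity_cutoff


class TestDelimit:
    def test_two_groups_one_cultured(self):
        ids = ["c1", "c2", "c3", "e1", "e2", "e3"]
        v = np.full((6, 6), 0.10)
        v[:3, :3] = 0.01
        v[3:, 3:] = 0.01
        np.fill_diagonal(v, 0.0)
        records = [
            AlignedSeq(i, "ACGT", species="S. demo" if i.startswith("c") else None,
                       source="culture" if i.startswith("c") else "clone")
            for i in ids
        ]
        part = delimit(matrix_from(ids, v), records, t_intra=0.046, t_inter=0.067)
        assert sorted(part.labels) == ["EC I", "S. demo"]
        assert part.members_of("EC I") == ("e1", "e2", "e3")

    def test_single_sequence(self):
        part = delimit(
            matrix_from(["a"], [[0.0]]), [AlignedSeq("a", "ACGT")], 0.046, 0.067
        )
        assert len(part.clusters) == 1

    def test_planted_community_recovered(self, community):
        """Delimitation under the default envelope recovers all 10 planted
        species, labelling the 4 uncultured ones as environmental clades."""
        config, refs = community
        m = distance_matrix(refs.msa, min_sites=100)
        part = delimit(m, refs.msa.rows)
        assert len(part.clusters) == config.n_species
        assert part.n_environmental() == config.n_species - config.n_cultured
        planted_sets = {}
        for seq_id, label in refs.planted.items():
            planted_sets.setdefault(label, set()).add(seq_id)
        got = {frozenset(c.members) for c in part.clusters}
        assert got == {frozenset(s) for s in planted_sets.values()}

    def test_conflicting_cultured_labels_rejected(self):
        ids = ["a", "b"]
        v = [[0.0, 0.01], [0.01, 0.0]]
        records = [
            AlignedSeq("a", "ACGT", species="X", source="culture"),
            AlignedSeq("b", "ACGT", species="Y", source="culture"),
        ]
        with pytest.raises(SpeciesConflictError, match="a,b"):
            delimit(matrix_from(ids, v), records, 0.046, 0.067)

    def test_ec_numbering_by_size_then_id(self):
        ids = ["a1", "b1", "b2", "c1"]
        v = np.full((4, 4), 0.2)
        v[1, 2] = v[2, 1] = 0.0
        np.fill_diagonal(v, 0.0)
        records = [AlignedSeq(i, "ACGT") for i in ids]
        part = delimit(matrix_from(ids, v), records, 0.046, 0.067)
        assert part.members_of("EC I") == ("b1", "b2")  # largest
        assert part.members_of("EC II") == ("a1",)  # tie broken by min id
        assert part.members_of("EC III") == ("c1",)

    def test_input_order_does_not_change_clusters(self, community):
        config, refs = community
        rows = list(refs.msa.rows)
        m1 = distance_matrix(rows, min_sites=100)
        part1 = delimit(m1, rows)
        rng = np.random.default_rng(9)
        perm = list(rng.permutation(len(rows)))
        rows2 = [rows[i] for i in perm]
        m2 = distance_matrix(rows2, min_sites=100)
        part2 = delimit(m2, rows2)
        assert {frozenset(c.members) for c in part1.clusters} == {
            frozenset(c.members) for c in part2.clusters
        }
        # labels too: EC numbering follows the documented size/id rule
        assert {(c.label, frozenset(c.members)) for c in part1.clusters} == {
            (c.label, frozenset(c.members)) for c in part2.clusters
        }

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        """Single-linkage clusters equal the unique partition found by
        exhaustive enumeration, on random instances of <=8 sequences."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        v = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        vals = rng.choice([0.01, 0.03, 0.05, 0.08, 0.12], size=len(iu[0]))
        v[iu] = vals
        v = v + v.T
        ids = [f"s{i}" for i in range(n)]
        records = [AlignedSeq(i, "ACGT") for i in ids]
        part = delimit(matrix_from(ids, v), records, t_intra=0.046, t_inter=0.067)
        got = frozenset(frozenset(c.members) for c in part.clusters)
        assert got == single_linkage_oracle(ids, v, 0.046)


class TestCheckGap:
    def test_separation_above_threshold_unflagged(self):
        ids = ["a", "b"]
        v = [[0.0, 0.068], [0.068, 0.0]]
        part = delimit(matrix_from(ids, v), [AlignedSeq(i, "ACGT") for i in ids],
                       t_intra=0.046, t_inter=0.067)
        report = check_gap(part, matrix_from(ids, v))
        assert not report["below_t_inter"].any()
        assert part.gap_violations == []

    def test_separation_inside_gap_flagged(self):
        ids = ["a", "b"]
        v = [[0.0, 0.05], [0.05, 0.0]]
        part = delimit(matrix_from(ids, v), [AlignedSeq(i, "ACGT") for i in ids],
                       t_intra=0.046, t_inter=0.067)
        report = check_gap(part, matrix_from(ids, v))
        assert report["below_t_inter"].all()
        assert part.gap_violations == [("EC I", "EC II", 0.05)]

    def test_single_cluster_empty_report(self):
        ids = ["a", "b"]
        v = [[0.0, 0.01], [0.01, 0.0]]
        part = delimit(matrix_from(ids, v), [AlignedSeq(i, "ACGT") for i in ids],
                       t_intra=0.046, t_inter=0.067)
        assert check_gap(part, matrix_from(ids, v)).empty


def test_roman_numerals():
    assert [roman(n) for n in [1, 2, 3, 4, 5, 9, 14]] == [
        "I", "II", "III", "IV", "V", "IX", "XIV"
    ]
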