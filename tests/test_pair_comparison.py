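"""ANI, CDS clustering, congruence statistics and sanity filters."""

import numpy as np
import pandas as pd
import pytest

from pseudocheck.annotation_io import AssemblyAnnotation
from pseudocheck.orf_classifier import percent_identity
from pseudocheck.pair_comparison import (
    ani,
    congruence_summary,
    match_cds,
    nearest_neighbor,
    overlap_membership,
    overlap_region_counts,
    pair_run_filter,
    spurious_counts,
    subsample_filter,
)
from pseudocheck.synthetic_data import CorruptionModel, GenomeSpec, corrupt, make_genome

from conftest import make_feature


def random_genome(rng, length):
    return {"c1": "".join(rng.choice(list("ACGT"), size=length))}


class TestAni:
    def test_self_ani_exact_100(self):
        genome = random_genome(np.random.default_rng(0), 30_000)
        res = ani(genome, genome)
        assert res.ani == 100.0
        assert res.aligned_fraction == 1.0

    def test_unrelated_genomes_undefined(self):
        rng = np.random.default_rng(1)
        res = ani(random_genome(rng, 5_000), random_genome(rng, 5_000))
        assert res.ani is None
        assert res.aligned_fraction == 0.0

    def test_substitutions_lower_ani_matches_hamming(self):
        # substitution-only divergence: per-fragment identity is Hamming
        rng = np.random.default_rng(2)
        a = random_genome(rng, 20_000)
        seq = np.array(list(a["c1"]))
        pos = rng.choice(seq.size, size=int(0.02 * seq.size), replace=False)
        for p in pos:
            seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
        b = {"c1": "".join(seq)}
        res = ani(a, b)
        expected = 100.0 * (1 - len(pos) / seq.size)
        assert res.ani == pytest.approx(expected, abs=0.3)

    def test_monotone_in_substitution_rate(self):
        rng = np.random.default_rng(3)
        base = random_genome(rng, 20_000)
        values = []
        for rate in (0.0, 0.005, 0.01, 0.02):
            seq = np.array(list(base["c1"]))
            n_mut = int(rate * seq.size)
            if n_mut:
                pos = rng.choice(seq.size, size=n_mut, replace=False)
                for p in pos:
                    seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
            values.append(ani(base, {"c1": "".join(seq)}).ani)
        assert values == sorted(values, reverse=True)

    def test_empty_genome_error(self):
        with pytest.raises(ValueError):
            ani({}, {"c1": "ACGT"})


class TestNearestNeighbor:
    def test_simple_argmax(self):
        mat = pd.DataFrame(
            [[100, 99.9, 98], [99.9, 100, 97], [98, 97, 100]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        nn = nearest_neighbor(mat)
        assert nn["a"] == ("b", 99.9)
        assert nn["b"] == ("a", 99.9)

    def test_tie_breaks_lexicographic(self):
        mat = pd.DataFrame(
            [[100, 99, 99], [99, 100, 98], [99, 98, 100]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        assert nearest_neighbor(mat)["a"] == ("b", 99.0)

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            ids = [f"s{i}" for i in range(n)]
            m = rng.uniform(80, 100, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 100.0)
            mat = pd.DataFrame(m, index=ids, columns=ids)
            nn = nearest_neighbor(mat)
            for i, aid in enumerate(ids):
                best = max(
                    (m[i, j], ids[j]) for j in range(n) if j != i
                )
                # brute force: max ANI then lexicographic id among ties
                cands = [ids[j] for j in range(n) if j != i and m[i, j] == best[0]]
                assert nn[aid] == (min(cands), pytest.approx(best[0]))

    def test_all_nan_row_skipped(self):
        mat = pd.DataFrame(
            [[100, np.nan], [np.nan, 100]], index=list("ab"), columns=list("ab")
        )
        assert nearest_neighbor(mat) == {}


def _mutated(seq: str, n_subs: int, rng) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return "".join(out)


class TestMatchCds:
    def test_identical_sets_pair_up(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(10)]
        fa = [make_feature(f"a{i}", seq=s) for i, s in enumerate(seqs)]
        fb = [make_feature(f"b{i}", seq=s) for i, s in enumerate(seqs)]
        clusters = match_cds(fa, fb)
        assert len(clusters) == 10
        for cl in clusters:
            assert len(cl.members) == 2
            assert {m.assembly_id for m in cl.members} == {"A", "B"}
            assert not cl.excluded_paralog

    def test_paralog_triple_excluded(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        copy = _mutated(seq, 15, rng)  # 95% identical paralog
        fa = [make_feature("a1", seq=seq), make_feature("a2", seq=copy)]
        fb = [make_feature("b1", seq=seq)]
        (cluster,) = match_cds(fa, fb)
        assert len(cluster.members) == 3
        assert cluster.excluded_paralog

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(7)
        feats_a, feats_b = [], []
        for i in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=250))
            feats_a.append(make_feature(f"a{i:02d}", seq=seq))
            div = int(rng.integers(0, 50))  # 0-20% divergence
            feats_b.append(make_feature(f"b{i:02d}", seq=_mutated(seq, div, rng)))
        clusters = match_cds(feats_a, feats_b)
        # oracle: quadratic all-pairs thresholding + single-linkage components
        items = [("A", f) for f in feats_a] + [("B", f) for f in feats_b]
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(items)))
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if percent_identity(items[i][1].nt_sequence, items[j][1].nt_sequence) >= 0.90:
                    g.add_edge(i, j)
        oracle = {
            frozenset((items[i][0], items[i][1].feature_id) for i in comp)
            for comp in nx.connected_components(g)
        }
        got = {
            frozenset((m.assembly_id, m.feature_id) for m in cl.members) for cl in clusters
        }
        assert got == oracle

    def test_order_invariant(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(8)]
        fa = [make_feature(f"a{i}", seq=s) for i, s in enumerate(seqs)]
        fb = [make_feature(f"b{i}", seq=_mutated(s, 5, rng)) for i, s in enumerate(seqs)]
        c1 = match_cds(fa, fb)
        c2 = match_cds(list(reversed(fa)), list(reversed(fb)))
        assert c1 == c2

    def test_missing_sequence_error(self):
        with pytest.raises(ValueError, match="nt_sequence"):
            match_cds([make_feature("a", seq=None)], [make_feature("b", seq="ACGT")])


def pair_cluster(status_a, causes_a, status_b, causes_b):
    return match_cds(
        [make_feature("a0", status=status_a, causes=causes_a, seq="ACGTACGTACGTACGTACGT")],
        [make_feature("b0", status=status_b, causes=causes_b, seq="ACGTACGTACGTACGTACGT")],
    )[0]


class TestCongruence:
    def test_fraction_arithmetic(self):
        rng = np.random.default_rng(9)
        clusters = []
        for i in range(8):
            seq = "".join(rng.choice(list("ACGT"), size=100))
            clusters += match_cds(
                [make_feature(f"a{i}", status="pseudogene", causes={"internal_stop"}, seq=seq)],
                [make_feature(f"b{i}", status="pseudogene", causes={"internal_stop"}, seq=seq)],
            )
        for i in range(2):
            seq = "".join(rng.choice(list("ACGT"), size=100))
            clusters += match_cds(
                [make_feature(f"c{i}", status="pseudogene", causes={"internal_stop"}, seq=seq)],
                [make_feature(f"d{i}", status="gene", seq=seq)],
            )
        s = congruence_summary(clusters)
        assert s.n_congruent["internal_stop"] == 8
        assert s.n_incongruent["internal_stop"] == 2
        assert s.fraction_incongruent["internal_stop"] == pytest.approx(0.2)
        assert s.weight["internal_stop"] == 10

    def test_no_pseudogene_pairs_undefined(self):
        cl = pair_cluster("gene", frozenset(), "gene", frozenset())
        s = congruence_summary([cl])
        assert s.fraction_incongruent["frameshift"] is None
        assert s.weight["frameshift"] == 0

    def test_monotone_adding_congruent_pair(self):
        rng = np.random.default_rng(10)
        seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(6)]
        clusters = []
        for i, seq in enumerate(seqs[:3]):
            clusters += match_cds(
                [make_feature(f"a{i}", status="pseudogene", causes={"frameshift"}, seq=seq)],
                [make_feature(f"b{i}", status="gene", seq=seq)],
            )
        before = congruence_summary(clusters).fraction_incongruent["frameshift"]
        clusters += match_cds(
            [make_feature("ax", status="pseudogene", causes={"frameshift"}, seq=seqs[3])],
            [make_feature("bx", status="pseudogene", causes={"frameshift"}, seq=seqs[3])],
        )
        after = congruence_summary(clusters).fraction_incongruent["frameshift"]
        assert after <= before


class TestSpuriousCounts:
    def test_self_comparison_zero(self, small_genome):
        sc = spurious_counts(small_genome, small_genome)
        assert sc.counts == {"frameshift": 0, "internal_stop": 0}
        assert sc.n_cds == len(small_genome.features)

    def test_single_deletion_counts_frameshift(self, small_genome):
        from dataclasses import replace

        from pseudocheck.synthetic_data import annotate_with_classifier

        model = CorruptionModel(cause_mix=0.0, seed=13)  # frameshifts only
        st = corrupt(small_genome, 5.0, 20.0, model)
        n_planted = sum(
            1 for f in st.corrupted.features
            if f.status == "pseudogene" and "frameshift" in f.causes
        ) - sum(
            1 for f in small_genome.features
            if f.status == "pseudogene" and "frameshift" in f.causes
        )
        assert n_planted >= 1
        annotated = annotate_with_classifier(st.corrupted, small_genome)
        sc = spurious_counts(annotated, small_genome)
        assert sc.counts["frameshift"] == n_planted
        assert sc.counts["internal_stop"] == 0

    def test_paralog_cluster_contributes_single_best_pair(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        paralog = _mutated(seq, 20, rng)
        reasm = AssemblyAnnotation(
            "re",
            contig_lengths={"c1": 1000},
            features=[make_feature("r1", status="pseudogene", causes={"internal_stop"}, seq=seq)],
        )
        ref = AssemblyAnnotation(
            "ref",
            contig_lengths={"c1": 1000},
            features=[make_feature("f1", seq=seq), make_feature("f2", seq=paralog)],
        )
        sc = spurious_counts(reasm, ref)
        assert sc.counts["internal_stop"] == 1  # one retained pair, the exact match

    def test_reference_without_features_error(self, small_genome):
        empty = AssemblyAnnotation("e", contig_lengths={"c1": 1000})
        with pytest.raises(ValueError):
            spurious_counts(small_genome, empty)


class TestOverlap:
    def _assembly(self, aid, feats):
        return AssemblyAnnotation(aid, contig_lengths={"c1": 10_000}, features=feats)

    def test_identical_assemblies_full_overlap(self):
        rng = np.random.default_rng(12)
        seqs = ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(4)]
        assemblies = [
            self._assembly(
                f"asm{k}",
                [
                    make_feature(f"asm{k}_f{i}", status="pseudogene",
                                 causes={"frameshift"}, seq=s)
                    for i, s in enumerate(seqs)
                ],
            )
            for k in range(4)
        ]
        membership = overlap_membership(assemblies)
        assert len(membership) == 4
        for ids in membership.values():
            assert ids == {"asm0", "asm1", "asm2", "asm3"}

    def test_planted_sharing_pattern(self):
        rng = np.random.default_rng(13)
        mk = lambda: "".join(rng.choice(list("ACGT"), size=150))
        shared_all = [mk() for _ in range(5)]  # pseudogene in all 3
        shared_01 = [mk() for _ in range(2)]  # pseudogene in asm0, asm1
        private_0 = [mk()]  # pseudogene only in asm0
        def feats(aid, pseudo_seqs):
            return [
                make_feature(f"{aid}_p{i}", status="pseudogene", causes={"internal_stop"}, seq=s)
                for i, s in enumerate(pseudo_seqs)
            ]
        asm0 = self._assembly("a0", feats("a0", shared_all + shared_01 + private_0))
        asm1 = self._assembly("a1", feats("a1", shared_all + shared_01))
        asm2 = self._assembly("a2", feats("a2", shared_all))
        regions = overlap_region_counts(overlap_membership([asm0, asm1, asm2]))
        assert regions[frozenset({"a0", "a1", "a2"})] == 5
        assert regions[frozenset({"a0", "a1"})] == 2
        assert regions[frozenset({"a0"})] == 1

    def test_too_few_assemblies_error(self):
        with pytest.raises(ValueError):
            overlap_membership([self._assembly("a", [])])


class TestFilters:
    @pytest.mark.parametrize(
        "ratio, keep",
        [(1.00, True), (0.94, False), (1.05, True), (0.95, True), (1.06, False)],
    )
    def test_pair_run_filter_bounds(self, ratio, keep):
        assert pair_run_filter(ratio * 1_000_000, 1_000_000) is keep

    @pytest.mark.parametrize(
        "size_ratio, cov_ratio, af, keep",
        [
            (1.0, 1.0, 0.9, True),
            (0.79, 1.0, 0.9, False),
            (0.80, 1.0, 0.9, True),
            (1.0, 1.21, 0.9, False),
            (1.0, 1.20, 0.9, True),
            (1.0, 1.0, 0.80, False),  # alignment fraction bound is strict
            (1.0, 1.0, 0.801, True),
        ],
    )
    def test_subsample_filter_bounds(self, size_ratio, cov_ratio, af, keep):
        assert (
            subsample_filter(size_ratio * 5e6, 5e6, cov_ratio * 50, 50, af) is keep
        )
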