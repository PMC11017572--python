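"""Comparison of annotated assemblies.

Implements the cross-assembly half of the pipeline: fragment-based average
nucleotide identity (ANI), nearest-neighbor selection, clustering of coding
sequences at a nucleotide-similarity threshold, congruence statistics for
matched gene/pseudogene pairs, spurious-pseudogene counting against a
trusted reference, multi-assembly pseudogene overlap, and the assembly
sanity filters applied before model fitting.

ANI dialect: the query genome is cut into non-overlapping 1000-bp fragments;
each fragment is aligned to its best-matching locus in the subject (located
by exact k-mer seeding, aligned with a banded edit-distance alignment);
fragments with >= 70% identity over >= 70% of their length contribute, and
the reported ANI is the mean contributing identity averaged over both
directions.  These are the standard gANI-style conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd
from Bio.Seq import Seq

from pseudocheck.annotation_io import AssemblyAnnotation, CdsFeature, FRAMESHIFT, INTERNAL_STOP
from pseudocheck.orf_classifier import percent_identity

PAIR_CAUSES = (FRAMESHIFT, INTERNAL_STOP)

_ANI_MIN_IDENTITY = 0.70
_ANI_MIN_COVERAGE = 0.70
_SEED_K = 15
_SEED_STEP = 37
_WINDOW_PAD = 60
_CLUSTER_K = 14
_MAX_POSTINGS = 200


@dataclass(frozen=True)
class AniResult:
    """Bidirectional fragment ANI.  ``ani`` is a percent in [0, 100], or
    ``None`` when no fragment passed the identity/coverage cutoffs."""

    ani: float | None
    aligned_fraction: float
    n_fragments: int


@dataclass(frozen=True)
class ClusterMember:
    assembly_id: str
    feature_id: str
    status: str
    causes: frozenset[str]


@dataclass(frozen=True)
class CdsCluster:
    """A single-linkage cluster of coding sequences across assemblies.

    In pairwise mode a cluster with more than two members suggests paralogous
    copies and is flagged ``excluded_paralog``.
    """

    members: tuple[ClusterMember, ...]
    excluded_paralog: bool


@dataclass(frozen=True)
class CongruenceSummary:
    """Congruent/incongruent pseudogene pair counts per cause.

    For cause ``c``: a matched cross-assembly pair is *congruent* when both
    members are pseudogenes and at least one carries ``c``; *incongruent*
    when exactly one member is a pseudogene carrying ``c``.
    ``fraction_incongruent[c]`` is ``None`` when no pair involves ``c``.
    """

    n_congruent: dict[str, int]
    n_incongruent: dict[str, int]
    fraction_incongruent: dict[str, float | None]
    weight: dict[str, int]


@dataclass(frozen=True)
class SpuriousCounts:
    """Reassembly pseudogenes whose reference counterpart is an intact gene."""

    counts: dict[str, int]
    n_cds: int
    rates: dict[str, float]
    densities: dict[str, float]  # per Mbp of the reassembly


# --------------------------------------------------------------------------
# ANI
# --------------------------------------------------------------------------


def _coerce_contigs(genome: AssemblyAnnotation | Mapping[str, str]) -> dict[str, str]:
    if isinstance(genome, AssemblyAnnotation):
        return genome.contigs
    return dict(genome)


def _concat(contigs: Mapping[str, str], k: int) -> str:
    # 'N' spacers prevent k-mers from spanning contig boundaries
    return ("N" * k).join(contigs[c] for c in sorted(contigs))


def _fragments(contigs: Mapping[str, str], fragment_len: int) -> list[str]:
    frags = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        for i in range(0, len(seq) - fragment_len + 1, fragment_len):
            frags.append(seq[i : i + fragment_len])
    return frags


def _kmer_index(target: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        kmer = target[i : i + k]
        postings = index.setdefault(kmer, [])
        if len(postings) < _MAX_POSTINGS:
            postings.append(i)
    return index


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(aligned columns, matches) from an extended cigar string."""
    columns = matches = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return columns, matches


def _best_fragment_identity(
    frag: str, target: str, index: Mapping[str, Sequence[int]], k: int
) -> float | None:
    """Identity of the best local placement of ``frag`` in ``target``."""
    best = None
    for query in (frag, str(Seq(frag).reverse_complement())):
        votes: dict[int, int] = {}
        for off in range(0, len(query) - k + 1, _SEED_STEP):
            for pos in index.get(query[off : off + k], ()):
                diag = pos - off
                votes[diag] = votes.get(diag, 0) + 1
        if not votes:
            continue
        top = sorted(votes, key=lambda d: (-votes[d], d))[:3]
        for diag in top:
            lo = max(0, diag - _WINDOW_PAD)
            hi = min(len(target), diag + len(query) + _WINDOW_PAD)
            res = edlib.align(query, target[lo:hi], mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            columns, matches = _cigar_stats(res["cigar"])
            identity = matches / columns
            if best is None or identity > best:
                best = identity
    return best


def _ani_one_direction(
    query_contigs: Mapping[str, str], target_contigs: Mapping[str, str], fragment_len: int
) -> tuple[list[float], int]:
    target = _concat(target_contigs, _SEED_K)
    index = _kmer_index(target, _SEED_K)
    identities = []
    frags = _fragments(query_contigs, fragment_len)
    for frag in frags:
        ident = _best_fragment_identity(frag, target, index, _SEED_K)
        # seeding aligns the full fragment, so query coverage is complete
        # whenever a placement is found; the identity cutoff remains
        if ident is not None and ident >= _ANI_MIN_IDENTITY:
            identities.append(ident)
    return identities, len(frags)


def ani(
    genome_a: AssemblyAnnotation | Mapping[str, str],
    genome_b: AssemblyAnnotation | Mapping[str, str],
    fragment_len: int = 1000,
) -> AniResult:
    """Fragment-based average nucleotide identity between two genomes.

    Returns ANI as a percent averaged over both directions, the fraction of
    fragments passing the cutoffs, and the total fragment count.  When no
    fragment passes in either direction, ``ani`` is ``None`` (undefined, not
    zero).
    """
    contigs_a = _coerce_contigs(genome_a)
    contigs_b = _coerce_contigs(genome_b)
    if not contigs_a or not contigs_b:
        raise ValueError("both genomes must be nonempty")
    ids_ab, n_ab = _ani_one_direction(contigs_a, contigs_b, fragment_len)
    ids_ba, n_ba = _ani_one_direction(contigs_b, contigs_a, fragment_len)
    n_total = n_ab + n_ba
    n_pass = len(ids_ab) + len(ids_ba)
    per_direction = [
        100.0 * sum(ids) / len(ids) for ids in (ids_ab, ids_ba) if ids
    ]
    value = sum(per_direction) / len(per_direction) if per_direction else None
    return AniResult(
        ani=value,
        aligned_fraction=n_pass / n_total if n_total else 0.0,
        n_fragments=n_total,
    )


def nearest_neighbor(
    ani_matrix: pd.DataFrame,
) -> dict[str, tuple[str, float]]:
    """Nearest neighbor of each assembly by maximal ANI.

    ``ani_matrix`` is a square DataFrame (percent ANI, NaN for undefined).
    Ties are broken by lexicographic partner id; assemblies whose row is all
    NaN get no entry.
    """
    if len(ani_matrix.index) < 2:
        raise ValueError("need at least 2 assemblies")
    out: dict[str, tuple[str, float]] = {}
    for aid in ani_matrix.index:
        row = ani_matrix.loc[aid].drop(labels=[aid], errors="ignore").dropna()
        if row.empty:
            continue
        best = row.max()
        partner = min(p for p in row.index if row[p] == best)
        out[aid] = (partner, float(best))
    return out


# --------------------------------------------------------------------------
# CDS clustering
# --------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _cluster_items(
    items: list[tuple[str, CdsFeature]], min_similarity: float
) -> list[list[int]]:
    """Single-linkage components of features under identity >= threshold.

    Identical sequences are grouped exactly first; alignment is only run for
    candidate pairs of distinct sequences sharing at least one k-mer (a
    prefilter that cannot produce false edges and, at the thresholds used,
    does not drop true ones on sequences of coding length).
    """
    for _aid, f in items:
        if f.nt_sequence is None:
            raise ValueError(f"feature {f.feature_id} has no nt_sequence")
    seq_to_rep: dict[str, int] = {}
    rep_of_item: list[int] = []
    rep_seqs: list[str] = []
    for idx, (_aid, f) in enumerate(items):
        seq = f.nt_sequence
        if seq not in seq_to_rep:
            seq_to_rep[seq] = len(rep_seqs)
            rep_seqs.append(seq)
        rep_of_item.append(seq_to_rep[seq])

    uf = _UnionFind(len(rep_seqs))
    postings: dict[str, list[int]] = {}
    for u, seq in enumerate(rep_seqs):
        kmers = {seq[i : i + _CLUSTER_K] for i in range(len(seq) - _CLUSTER_K + 1)}
        for kmer in kmers:
            lst = postings.setdefault(kmer, [])
            if len(lst) < _MAX_POSTINGS:
                lst.append(u)
    seen: set[tuple[int, int]] = set()
    for lst in postings.values():
        if len(lst) < 2:
            continue
        for u, v in combinations(lst, 2):
            pair = (u, v) if u < v else (v, u)
            if pair in seen:
                continue
            seen.add(pair)
            if percent_identity(rep_seqs[pair[0]], rep_seqs[pair[1]]) >= min_similarity:
                uf.union(*pair)

    comps: dict[int, list[int]] = {}
    for idx in range(len(items)):
        root = uf.find(rep_of_item[idx])
        comps.setdefault(root, []).append(idx)
    return [comps[r] for r in sorted(comps)]


def _as_member(aid: str, f: CdsFeature) -> ClusterMember:
    return ClusterMember(aid, f.feature_id, f.status, f.causes)


def match_cds(
    features_a: Sequence[CdsFeature],
    features_b: Sequence[CdsFeature],
    min_similarity: float = 0.90,
    assembly_ids: tuple[str, str] = ("A", "B"),
) -> list[CdsCluster]:
    """Cluster coding sequences of two assemblies at >= ``min_similarity``.

    Single-linkage clusters under pairwise nucleotide identity.  Clusters of
    more than two members (suggesting paralogous copies) are flagged
    ``excluded_paralog``; singletons are retained but carry no pair.
    """
    items = [(assembly_ids[0], f) for f in features_a] + [
        (assembly_ids[1], f) for f in features_b
    ]
    items.sort(key=lambda t: (t[0], t[1].feature_id))
    clusters = []
    for comp in _cluster_items(items, min_similarity):
        members = tuple(
            sorted(
                (_as_member(*items[i]) for i in comp),
                key=lambda m: (m.assembly_id, m.feature_id),
            )
        )
        clusters.append(CdsCluster(members=members, excluded_paralog=len(members) > 2))
    return clusters


def congruence_summary(clusters: Iterable[CdsCluster]) -> CongruenceSummary:
    """Tally congruent and incongruent pseudogene pairs per cause.

    Only non-excluded size-2 clusters whose members come from the two
    different assemblies and contain at least one pseudogene contribute.
    The incongruent fraction per cause is pseudogene/gene pairs over all
    pseudogene-involving pairs for that cause.
    """
    clusters = list(clusters)
    assembly_ids = {m.assembly_id for cl in clusters for m in cl.members}
    if len(assembly_ids) != 2:
        raise ValueError(f"clusters must come from exactly 2 assemblies, got {sorted(assembly_ids)}")
    n_con = {c: 0 for c in PAIR_CAUSES}
    n_inc = {c: 0 for c in PAIR_CAUSES}
    for cl in clusters:
        if cl.excluded_paralog or len(cl.members) != 2:
            continue
        m1, m2 = cl.members
        if m1.assembly_id == m2.assembly_id:
            continue
        statuses = (m1.status, m2.status)
        if "pseudogene" not in statuses:
            continue
        for cause in PAIR_CAUSES:
            if statuses == ("pseudogene", "pseudogene"):
                if cause in m1.causes or cause in m2.causes:
                    n_con[cause] += 1
            else:
                pseudo = m1 if m1.status == "pseudogene" else m2
                if cause in pseudo.causes:
                    n_inc[cause] += 1
    weight = {c: n_con[c] + n_inc[c] for c in PAIR_CAUSES}
    frac = {
        c: (n_inc[c] / weight[c] if weight[c] > 0 else None) for c in PAIR_CAUSES
    }
    return CongruenceSummary(
        n_congruent=n_con, n_incongruent=n_inc, fraction_incongruent=frac, weight=weight
    )


def spurious_counts(
    reassembly: AssemblyAnnotation,
    reference: AssemblyAnnotation,
    min_similarity: float = 0.90,
) -> SpuriousCounts:
    """Count reassembly pseudogenes clustered with intact reference genes.

    Clusters are computed as in :func:`match_cds`; within each cluster only
    the single highest-identity cross-assembly pair is retained (ties broken
    lexicographically on feature ids), excluding potentially paralogous
    copies.  Counts are normalized by the reassembly's total CDS count and
    per Mbp of its length.
    """
    if not reference.features:
        raise ValueError("reference assembly has no features")
    reasm = reassembly.with_sequences() if reassembly.contigs else reassembly
    ref = reference.with_sequences() if reference.contigs else reference
    items = [("reassembly", f) for f in reasm.features] + [
        ("reference", f) for f in ref.features
    ]
    items.sort(key=lambda t: (t[0], t[1].feature_id))
    counts = {c: 0 for c in PAIR_CAUSES}
    for comp in _cluster_items(items, min_similarity):
        cross = [
            (i, j)
            for i in comp
            for j in comp
            if items[i][0] == "reassembly" and items[j][0] == "reference"
        ]
        if not cross:
            continue
        best_pair = None
        best_ident = -1.0
        for i, j in sorted(
            cross, key=lambda p: (items[p[0]][1].feature_id, items[p[1]][1].feature_id)
        ):
            ident = percent_identity(
                items[i][1].nt_sequence, items[j][1].nt_sequence
            )
            if ident > best_ident:  # ties keep the lexicographically first pair
                best_ident = ident
                best_pair = (i, j)
        fa, fb = items[best_pair[0]][1], items[best_pair[1]][1]
        if fa.status == "pseudogene" and fb.status == "gene":
            for cause in PAIR_CAUSES:
                if cause in fa.causes:
                    counts[cause] += 1
    n_cds = len(reasm.features)
    glen = reasm.genome_length
    return SpuriousCounts(
        counts=counts,
        n_cds=n_cds,
        rates={c: counts[c] / n_cds for c in PAIR_CAUSES},
        densities={c: counts[c] * 1e6 / glen for c in PAIR_CAUSES},
    )


def overlap_membership(
    assemblies: Sequence[AssemblyAnnotation],
    min_similarity: float = 0.90,
) -> dict[tuple[tuple[str, str], ...], set[str]]:
    """Map each pseudogene-containing cluster to the assemblies contributing
    a pseudogene member (the Venn-style membership of a multi-assembly
    comparison of the same sample)."""
    if len(assemblies) < 2:
        raise ValueError("need at least 2 assemblies")
    items: list[tuple[str, CdsFeature]] = []
    for asm in assemblies:
        src = asm.with_sequences() if asm.contigs else asm
        items.extend((asm.assembly_id, f) for f in src.features)
    items.sort(key=lambda t: (t[0], t[1].feature_id))
    membership: dict[tuple[tuple[str, str], ...], set[str]] = {}
    for comp in _cluster_items(items, min_similarity):
        pseudo_assemblies = {
            items[i][0] for i in comp if items[i][1].status == "pseudogene"
        }
        if not pseudo_assemblies:
            continue
        key = tuple(sorted((items[i][0], items[i][1].feature_id) for i in comp))
        membership[key] = pseudo_assemblies
    return membership


def overlap_region_counts(
    membership: Mapping[tuple, set[str]],
) -> dict[frozenset[str], int]:
    """Collapse a membership map into Venn-region counts."""
    regions: dict[frozenset[str], int] = {}
    for ids in membership.values():
        key = frozenset(ids)
        regions[key] = regions.get(key, 0) + 1
    return regions


# --------------------------------------------------------------------------
# Assembly sanity filters
# --------------------------------------------------------------------------


def pair_run_filter(assembly_len: float, reference_len: float) -> bool:
    """Keep an assembly whose length is within 95-105% of its reference
    (bounds inclusive)."""
    if assembly_len <= 0 or reference_len <= 0:
        raise ValueError("lengths must be positive")
    ratio = assembly_len / reference_len
    return 0.95 <= ratio <= 1.05


def subsample_filter(
    total_len: float,
    source_len: float,
    observed_cov: float,
    target_cov: float,
    alignment_fraction: float,
) -> bool:
    """Keep a subsampled reassembly that is reasonably complete.

    Size and coverage within 80-120% of the source/target (inclusive), and
    shared gene content with the source strictly greater than 80%.
    """
    if min(total_len, source_len, observed_cov, target_cov) <= 0:
        raise ValueError("lengths and coverages must be positive")
    size_ok = 0.8 <= total_len / source_len <= 1.2
    cov_ok = 0.8 <= observed_cov / target_cov <= 1.2
    align_ok = alignment_fraction > 0.80
    return size_ok and cov_ok and align_ok
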