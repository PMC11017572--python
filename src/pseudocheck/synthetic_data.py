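"""Synthetic bacterial genomes with coverage-dependent assembly errors.

The generator plays the role of the wet half of the study design: a
well-annotated reference genome, and "reassemblies" of it whose error burden
depends on nominal read coverage and mean base quality.  Errors are injected
directly at the assembly level — the read-simulation/assembly/annotation
chain is out of scope — in one of two modes:

- ``feature_level``: each intact gene independently becomes a spurious
  pseudogene with probability ``pi = expit(beta0 + beta_cov*log10(cov) +
  beta_q*Q)``, the exact model family the downstream binomial fit assumes.
  This makes parameter recovery a sharp test.
- ``base_level``: substitutions and indels are scattered genome-wide at
  per-base rates with the same logit-linear covariate dependence, anchored
  at a reference condition of 50-fold coverage and Q35.  This exercises the
  ORF classifier on realistic mutation patterns.

Ground-truth genomes are a single contig of random sense-codon ORFs with
intergenic spacers; a chosen fraction of genes are true pseudogenes (stop
substitution or out-of-frame indel).  Every corrupted feature's label is
derivable from the corruption event log alone.

A master seed derives independent per-condition streams through
``numpy.random.SeedSequence`` so replicate grids are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.special import expit, logit

from pseudocheck.annotation_io import (
    FRAMESHIFT,
    INTERNAL_STOP,
    AssemblyAnnotation,
    CdsFeature,
)
from pseudocheck.coverage_model import BinomialObservation
from pseudocheck.orf_classifier import classify_vs_reference

_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))

#: reference condition anchoring base-level rates
_REF_COVERAGE = 50.0
_REF_QUALITY = 35.0

#: fraction of the gene's 3' end avoided when placing frameshift indels,
#: matching the classifier's terminal guard with margin
_INDEL_3PRIME_AVOID = 0.10

DEFAULT_COVERAGE_GRID = (5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0)
DEFAULT_QUALITY_GRID = (20.0, 30.0, 35.0)


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a ground-truth genome.

    Defaults emulate a small enterobacterial chromosome scaled to desk size:
    ~900-bp genes, ~120-bp spacers, balanced GC, 2% true pseudogenes split
    evenly between internal stops and frameshifts.
    """

    n_genes: int = 1000
    gene_len_mean: float = 900.0
    gene_len_sd: float = 200.0
    intergenic_mean: float = 120.0
    gc: float = 0.5
    true_pseudo_fraction: float = 0.02
    cause_mix: float = 0.5  # fraction of true pseudogenes due to internal stops
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("gc", "true_pseudo_fraction", "cause_mix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class CorruptionModel:
    """Error-injection model; see the module docstring for the two modes."""

    mode: str = "feature_level"
    beta0: float = 2.0
    beta_cov: float = -3.0
    beta_q: float = -0.1
    sub_rate0: float = 3e-4
    indel_rate0: float = 3e-5
    indel_len_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)  # lengths 1,2,3
    cause_mix: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("feature_level", "base_level"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if abs(sum(self.indel_len_probs) - 1.0) > 1e-9:
            raise ValueError("indel_len_probs must sum to 1")

    def pseudogenization_probability(self, coverage: float, quality: float) -> float:
        """Per-CDS spurious-pseudogene probability (feature_level mode)."""
        pi = float(expit(self.beta0 + self.beta_cov * math.log10(coverage) + self.beta_q * quality))
        if not 0.0 <= pi < 1.0:
            raise ValueError(f"misconfigured model: pi={pi}")
        return pi

    def base_rates(self, coverage: float, quality: float) -> tuple[float, float]:
        """(substitution, indel) per-base rates (base_level mode)."""
        shift = self.beta_cov * (math.log10(coverage) - math.log10(_REF_COVERAGE))
        shift += self.beta_q * (quality - _REF_QUALITY)
        sub = float(expit(logit(self.sub_rate0) + shift))
        ind = float(expit(logit(self.indel_rate0) + shift))
        if max(sub, ind) >= 1.0:
            raise ValueError("misconfigured model: per-base rate >= 1")
        return sub, ind


@dataclass(frozen=True)
class CorruptionEvent:
    feature_id: str  # empty string for intergenic events
    kind: str  # substitution_to_stop | substitution | indel | truncation
    position: int  # 0-based within the ancestral feature (or contig) sequence
    length: int = 0  # signed indel length; 0 for substitutions


@dataclass
class SyntheticTruth:
    """A corrupted assembly together with its ground truth."""

    genome: AssemblyAnnotation
    corrupted: AssemblyAnnotation
    event_log: list[CorruptionEvent]
    coverage: float
    quality: float


# --------------------------------------------------------------------------
# genome construction
# --------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=probs))


def _random_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    """An intact ORF: ATG + random sense codons + a random stop codon."""
    n_body = length // 3 - 2
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codons = rng.choice(_BASES, size=(n_body, 3), p=probs)
    joined = np.char.add(np.char.add(codons[:, 0], codons[:, 1]), codons[:, 2])
    while True:  # resample any stop codons landing in the body
        bad = np.isin(joined, _STOP_CODONS)
        if not bad.any():
            break
        redo = rng.choice(_BASES, size=(int(bad.sum()), 3), p=probs)
        joined[bad] = np.char.add(np.char.add(redo[:, 0], redo[:, 1]), redo[:, 2])
    return "ATG" + "".join(joined) + _STOP_CODONS[rng.integers(0, 3)]


def _introduce_stop(seq: str, rng: np.random.Generator) -> tuple[str, int]:
    """Replace an internal codon with a stop codon; returns (seq, position)."""
    n_codons = len(seq) // 3
    j = int(rng.integers(1, n_codons - 2))  # internal codons only
    pos = 3 * j
    stop = _STOP_CODONS[rng.integers(0, 3)]
    return seq[:pos] + stop + seq[pos + 3 :], pos


def _introduce_frameshift(seq: str, rng: np.random.Generator) -> tuple[str, int, int]:
    """Apply a 1- or 2-bp indel clear of the start codon and the 3' guard
    region; returns (seq, position, signed length)."""
    hi = max(4, int(len(seq) * (1 - _INDEL_3PRIME_AVOID)))
    pos = int(rng.integers(3, hi))
    length = 1 if rng.random() < 0.5 else 2
    if rng.random() < 0.5:
        return seq[:pos] + seq[pos + length :], pos, -length
    ins = _random_bases(rng, length, 0.5)
    return seq[:pos] + ins + seq[pos:], pos, length


def make_genome(spec: GenomeSpec) -> AssemblyAnnotation:
    """Generate a single-contig ground-truth genome from ``spec``.

    Gene lengths are Normal(mean, sd) rounded to whole codons with a 150-bp
    floor.  Exactly ``round(n_genes * true_pseudo_fraction)`` genes are true
    pseudogenes, split by ``cause_mix`` (internal stops, rounded, then
    frameshifts).  Generation is seed-deterministic; each feature keeps its
    intact ancestral ORF in ``ancestral_nt``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pseudo = round(spec.n_genes * spec.true_pseudo_fraction)
    n_stop = round(n_pseudo * spec.cause_mix)
    pseudo_idx = set(rng.choice(spec.n_genes, size=n_pseudo, replace=False).tolist())
    pseudo_list = sorted(pseudo_idx)
    stop_idx = set(pseudo_list[:n_stop])

    parts: list[str] = []
    features: list[CdsFeature] = []
    pos = 0
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        spacer_len = max(10, int(round(rng.normal(spec.intergenic_mean, spec.intergenic_mean / 4))))
        spacer = _random_bases(rng, spacer_len, spec.gc)
        parts.append(spacer)
        pos += spacer_len

        length = int(round(rng.normal(spec.gene_len_mean, spec.gene_len_sd) / 3)) * 3
        length = max(150, length)
        ancestral = _random_orf(rng, length, spec.gc)
        seq = ancestral
        status, causes = "gene", frozenset()
        if i in pseudo_idx:
            status = "pseudogene"
            if i in stop_idx:
                seq, _ = _introduce_stop(seq, rng)
                causes = frozenset({INTERNAL_STOP})
            else:
                seq, _, _ = _introduce_frameshift(seq, rng)
                causes = frozenset({FRAMESHIFT})
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = seq if strand == "+" else str(Seq(seq).reverse_complement())
        parts.append(genomic)
        features.append(
            CdsFeature(
                feature_id=f"gene_{i:0{width}d}",
                contig_id="contig_1",
                start=pos + 1,
                end=pos + len(genomic),
                strand=strand,
                status=status,
                causes=causes,
                nt_sequence=seq,
                ancestral_nt=ancestral,
            )
        )
        pos += len(genomic)
    parts.append(_random_bases(rng, max(10, int(spec.intergenic_mean)), spec.gc))
    return AssemblyAnnotation(
        assembly_id=f"truth_seed{spec.seed}",
        contigs={"contig_1": "".join(parts)},
        features=features,
    )


# --------------------------------------------------------------------------
# corruption
# --------------------------------------------------------------------------


def _rebuild_contig(
    truth: AssemblyAnnotation,
    contig_id: str,
    new_feature_seqs: dict[str, str],
    intergenic_editor=None,
) -> tuple[str, list[CdsFeature]]:
    """Reassemble a contig from (possibly edited) feature and spacer pieces,
    recomputing coordinates."""
    contig = truth.contigs[contig_id]
    feats = sorted(
        (f for f in truth.features if f.contig_id == contig_id), key=lambda f: f.start
    )
    parts: list[str] = []
    new_feats: list[CdsFeature] = []
    cursor = 0  # 0-based position in the original contig
    out_pos = 0
    for f in feats:
        spacer = contig[cursor : f.start - 1]
        if intergenic_editor is not None:
            spacer = intergenic_editor(spacer)
        parts.append(spacer)
        out_pos += len(spacer)
        seq = new_feature_seqs.get(f.feature_id, f.nt_sequence)
        genomic = seq if f.strand == "+" else str(Seq(seq).reverse_complement())
        parts.append(genomic)
        new_feats.append(
            replace(
                f,
                start=out_pos + 1,
                end=out_pos + len(genomic),
                nt_sequence=seq,
            )
        )
        out_pos += len(genomic)
        cursor = f.end
    tail = contig[cursor:]
    if intergenic_editor is not None:
        tail = intergenic_editor(tail)
    parts.append(tail)
    return "".join(parts), new_feats


def _apply_base_events(
    seq: str, subs: list[tuple[int, str]], indels: list[tuple[int, int, str]]
) -> str:
    """Apply substitutions and indels given in original coordinates."""
    out = list(seq)
    for pos, base in subs:
        out[pos] = base
    # apply indels right-to-left so earlier positions stay valid
    for pos, length, ins in sorted(indels, key=lambda t: -t[0]):
        if length < 0:
            del out[pos : pos - length]
        else:
            out[pos:pos] = list(ins)
    return "".join(out)


def _base_level_causes(
    ancestral: str,
    subs: list[tuple[int, str]],
    indels: list[tuple[int, int, str]],
) -> frozenset[str]:
    """Ground-truth causes implied by a base-level event list.

    Frameshift: some prefix of the indel runs (outside the 3' guard) leaves
    the cumulative balance not divisible by 3.  Internal stop: a substitution
    turns an in-frame internal codon (no upstream net offset, no indel inside
    the codon) into a stop.
    """
    causes: set[str] = set()
    L = len(ancestral)
    guard = 0.95 * L
    net = 0
    for pos, length, _ins in sorted(indels):
        if pos >= guard:
            continue
        net += length
        if net % 3 != 0:
            causes.add(FRAMESHIFT)
    if subs:
        n_codons = L // 3
        sub_by_codon: dict[int, list[tuple[int, str]]] = {}
        for pos, base in subs:
            sub_by_codon.setdefault(pos // 3, []).append((pos, base))
        for j, codon_subs in sub_by_codon.items():
            if not 1 <= j <= n_codons - 3:
                continue
            offset = sum(l for p, l, _ in indels if p < 3 * j)
            if offset % 3 != 0:
                continue
            if any(3 * j <= p < 3 * j + 3 for p, _, _ in indels):
                continue
            codon = list(ancestral[3 * j : 3 * j + 3])
            for pos, base in codon_subs:
                codon[pos - 3 * j] = base
            if "".join(codon) in _STOP_CODONS:
                causes.add(INTERNAL_STOP)
    return frozenset(causes)


def _substitute(seq: str, pos: int, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != seq[pos]]
    return choices[rng.integers(0, 3)]


def corrupt(
    truth: AssemblyAnnotation,
    coverage: float,
    quality: float,
    model: CorruptionModel,
    rng: np.random.Generator | None = None,
    rebuild_contigs: bool = True,
) -> SyntheticTruth:
    """Produce a corrupted copy of ``truth`` at the given condition.

    In ``feature_level`` mode each intact gene independently flips to a
    spurious pseudogene with probability ``pi(coverage, quality)``; in
    ``base_level`` mode substitutions and indels are scattered genome-wide
    and labels follow from the event effects.  The returned corrupted
    assembly carries ground-truth statuses; use
    :func:`annotate_with_classifier` to re-derive statuses the way an
    annotation pipeline would.

    ``rebuild_contigs=False`` skips reconstruction of the contig sequences
    (features keep their truth coordinates, and the corrupted assembly
    carries contig lengths only) — statuses, sequences and the event log are
    unaffected, which is all the feature-level counting experiments need.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    events: list[CorruptionEvent] = []
    new_seqs: dict[str, str] = {}
    new_status: dict[str, tuple[str, frozenset[str]]] = {}

    if model.mode == "feature_level":
        pi = model.pseudogenization_probability(coverage, quality)
        for f in truth.features:
            if f.status != "gene" or rng.random() >= pi:
                continue
            if rng.random() < model.cause_mix:
                seq, pos = _introduce_stop(f.nt_sequence, rng)
                events.append(CorruptionEvent(f.feature_id, "substitution_to_stop", pos))
                causes = frozenset({INTERNAL_STOP})
            else:
                seq, pos, length = _introduce_frameshift(f.nt_sequence, rng)
                events.append(CorruptionEvent(f.feature_id, "indel", pos, length))
                causes = frozenset({FRAMESHIFT})
            new_seqs[f.feature_id] = seq
            new_status[f.feature_id] = ("pseudogene", causes)
        intergenic_editor = None
    else:
        sub_rate, indel_rate = model.base_rates(coverage, quality)
        len_values = (1, 2, 3)
        for f in truth.features:
            seq = f.nt_sequence
            L = len(seq)
            subs: list[tuple[int, str]] = []
            indels: list[tuple[int, int, str]] = []
            for pos in np.flatnonzero(rng.random(L) < sub_rate):
                subs.append((int(pos), _substitute(seq, int(pos), rng)))
            for pos in np.flatnonzero(rng.random(L) < indel_rate):
                length = int(rng.choice(len_values, p=model.indel_len_probs))
                if rng.random() < 0.5:
                    length = -length
                ins = _random_bases(rng, length, 0.5) if length > 0 else ""
                indels.append((int(pos), length, ins))
            if not subs and not indels:
                continue
            new_seqs[f.feature_id] = _apply_base_events(seq, subs, indels)
            extra = _base_level_causes(seq, subs, indels)
            for pos, _base in subs:
                kind = "substitution_to_stop" if INTERNAL_STOP in extra else "substitution"
                events.append(CorruptionEvent(f.feature_id, kind, pos))
            for pos, length, _ins in indels:
                events.append(CorruptionEvent(f.feature_id, "indel", pos, length))
            if f.status == "gene" and extra:
                new_status[f.feature_id] = ("pseudogene", extra)
            elif f.status == "pseudogene" and extra:
                new_status[f.feature_id] = ("pseudogene", f.causes | extra)

        def intergenic_editor(spacer: str) -> str:
            if not spacer:
                return spacer
            subs = [
                (int(p), _substitute(spacer, int(p), rng))
                for p in np.flatnonzero(rng.random(len(spacer)) < sub_rate)
            ]
            return _apply_base_events(spacer, subs, [])

    new_contigs: dict[str, str] = {}
    new_lengths: dict[str, int] = {}
    new_features: list[CdsFeature] = []
    if rebuild_contigs:
        for cid in truth.contigs:
            contig_seq, feats = _rebuild_contig(truth, cid, new_seqs, intergenic_editor)
            new_contigs[cid] = contig_seq
            new_lengths[cid] = len(contig_seq)
            new_features.extend(feats)
    else:
        new_lengths = dict(truth.contig_lengths)
        new_features = [
            replace(f, nt_sequence=new_seqs[f.feature_id])
            if f.feature_id in new_seqs
            else f
            for f in truth.features
        ]
    relabeled = [
        replace(f, status=new_status[f.feature_id][0], causes=new_status[f.feature_id][1])
        if f.feature_id in new_status
        else f
        for f in new_features
    ]
    corrupted = AssemblyAnnotation(
        assembly_id=f"{truth.assembly_id}_cov{coverage:g}_q{quality:g}",
        contigs=new_contigs,
        contig_lengths=new_lengths,
        features=relabeled,
        coverage=coverage,
        quality=quality,
        platform="synthetic",
        assembler="synthetic",
    )
    return SyntheticTruth(
        genome=truth,
        corrupted=corrupted,
        event_log=events,
        coverage=coverage,
        quality=quality,
    )


def annotate_with_classifier(
    assembly: AssemblyAnnotation, reference: AssemblyAnnotation, code_table: int = 11
) -> AssemblyAnnotation:
    """Re-derive gene/pseudogene statuses with the reference-based ORF
    classifier, the way an annotation pipeline would.

    Each feature is classified against the intact ancestral ORF of the
    reference feature sharing its id (features without a counterpart keep
    their status).
    """
    ref_by_id = {f.feature_id: f for f in reference.features}
    out_feats = []
    for f in assembly.features:
        ref = ref_by_id.get(f.feature_id)
        if ref is None or f.nt_sequence is None:
            out_feats.append(f)
            continue
        ref_orf = ref.ancestral_nt or ref.nt_sequence
        verdict = _classify_cached(ref_orf, f.nt_sequence, code_table)
        out_feats.append(replace(f, status=verdict.status, causes=verdict.causes))
    return AssemblyAnnotation(
        assembly_id=assembly.assembly_id,
        contigs=assembly.contigs,
        contig_lengths=dict(assembly.contig_lengths),
        features=out_feats,
        coverage=assembly.coverage,
        quality=assembly.quality,
        platform=assembly.platform,
        assembler=assembly.assembler,
    )


_classify_cache: dict[tuple[str, str, int], object] = {}


def _classify_cached(ref_orf: str, obs: str, code_table: int):
    key = (ref_orf, obs, code_table)
    if key not in _classify_cache:
        if len(_classify_cache) > 50_000:
            _classify_cache.clear()
        _classify_cache[key] = classify_vs_reference(ref_orf, obs, code_table)
    return _classify_cache[key]


# --------------------------------------------------------------------------
# fragmentation
# --------------------------------------------------------------------------


def fragment(
    assembly: AssemblyAnnotation,
    n_breaks: int,
    min_contig_len: int = 200,
    seed: int = 0,
) -> tuple[AssemblyAnnotation, list[CorruptionEvent]]:
    """Split contigs at ``n_breaks`` uniform random positions.

    Contigs shorter than ``min_contig_len`` are dropped.  Features spanning a
    break, or living on a dropped contig, disappear from the output and are
    recorded as truncation events — they are never counted as frameshift or
    internal-stop pseudogenes.
    """
    if n_breaks < 0:
        raise ValueError("n_breaks must be >= 0")
    rng = np.random.default_rng(seed)
    total = assembly.genome_length
    breakpoints = sorted(int(b) for b in rng.integers(1, total, size=n_breaks))
    new_contigs: dict[str, str] = {}
    new_features: list[CdsFeature] = []
    truncations: list[CorruptionEvent] = []
    offset = 0
    for cid in sorted(assembly.contigs):
        seq = assembly.contigs[cid]
        local = sorted({b - offset for b in breakpoints if 0 < b - offset < len(seq)})
        bounds = [0] + local + [len(seq)]
        pieces = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        kept: list[tuple[int, int, str]] = []
        for idx, (lo, hi) in enumerate(pieces):
            piece_id = f"{cid}.{idx}" if len(pieces) > 1 else cid
            if hi - lo >= min_contig_len:
                new_contigs[piece_id] = seq[lo:hi]
                kept.append((lo, hi, piece_id))
        for f in (f for f in assembly.features if f.contig_id == cid):
            home = next(
                ((lo, hi, pid) for lo, hi, pid in kept if f.start - 1 >= lo and f.end <= hi),
                None,
            )
            if home is None:
                truncations.append(CorruptionEvent(f.feature_id, "truncation", f.start - 1))
                continue
            lo, _hi, pid = home
            new_features.append(replace(f, contig_id=pid, start=f.start - lo, end=f.end - lo))
        offset += len(seq)
    return (
        AssemblyAnnotation(
            assembly_id=f"{assembly.assembly_id}_frag",
            contigs=new_contigs,
            features=new_features,
            coverage=assembly.coverage,
            quality=assembly.quality,
            platform=assembly.platform,
            assembler=assembly.assembler,
        ),
        truncations,
    )


# --------------------------------------------------------------------------
# full experiment grid
# --------------------------------------------------------------------------


def _spurious_causes(truth: AssemblyAnnotation, st: SyntheticTruth) -> dict[str, int]:
    """Spurious counts per cause straight from the ground truth: features
    intact in the truth genome but pseudogene in the corrupted copy."""
    truth_status = {f.feature_id: f.status for f in truth.features}
    counts = {FRAMESHIFT: 0, INTERNAL_STOP: 0}
    for f in st.corrupted.features:
        if truth_status.get(f.feature_id) != "gene" or f.status != "pseudogene":
            continue
        for cause in counts:
            if cause in f.causes:
                counts[cause] += 1
    return counts


def simulate_experiment(
    spec: GenomeSpec,
    coverages: Sequence[float] = DEFAULT_COVERAGE_GRID,
    qualities: Sequence[float] = (35.0,),
    replicates: int = 3,
    model: CorruptionModel = CorruptionModel(),
    seed: int = 0,
    count_mode: str = "event_log",
    keep_truths: bool = False,
) -> tuple[pd.DataFrame, list[SyntheticTruth]]:
    """Run the full factorial coverage x quality grid with replicates.

    Returns a tidy observation table (columns: cause, coverage, quality,
    replicate, k, n, genome_length) ready for the binomial fit, plus the
    per-condition truths when ``keep_truths``.

    ``count_mode='event_log'`` takes spurious counts directly from ground
    truth; ``count_mode='pipeline'`` re-annotates each corrupted assembly
    with the ORF classifier and counts spurious pseudogenes through CDS
    clustering against the truth genome, exercising the whole pipeline.
    """
    if not coverages or not qualities:
        raise ValueError("coverage and quality grids must be nonempty")
    if count_mode not in ("event_log", "pipeline"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    from pseudocheck.pair_comparison import spurious_counts  # deferred: avoid cycle

    truth = make_genome(spec)
    n_cds = len(truth.features)
    glen = truth.genome_length
    rows = []
    truths: list[SyntheticTruth] = []
    for ci, cov in enumerate(coverages):
        for qi, q in enumerate(qualities):
            for rep in range(replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), ci, qi, rep])
                )
                st = corrupt(
                    truth,
                    cov,
                    q,
                    model,
                    rng=rng,
                    rebuild_contigs=(count_mode == "pipeline" or keep_truths),
                )
                if count_mode == "event_log":
                    counts = _spurious_causes(truth, st)
                else:
                    annotated = annotate_with_classifier(st.corrupted, truth)
                    sc = spurious_counts(annotated, truth)
                    counts = sc.counts
                for cause, k in sorted(counts.items()):
                    rows.append(
                        {
                            "cause": cause,
                            "coverage": cov,
                            "quality": q,
                            "replicate": rep,
                            "k": k,
                            "n": n_cds,
                            "genome_length": glen,
                        }
                    )
                if keep_truths:
                    truths.append(st)
    return pd.DataFrame(rows), truths


def observations_from_table(df: pd.DataFrame, cause: str) -> list[BinomialObservation]:
    """Extract the per-cause observations feeding :func:`fit_binomial`."""
    sub = df[df["cause"] == cause]
    return [
        BinomialObservation(
            k=int(r.k), n=int(r.n), coverage=float(r.coverage), quality=float(r.quality)
        )
        for r in sub.itertuples()
    ]
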