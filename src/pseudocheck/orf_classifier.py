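"""Reference-based ORF classification.

Given a trusted reference ORF and an observed putative homolog, decide
whether the observed copy is an intact gene, an internal-stop pseudogene,
and/or a frameshifted pseudogene.  This is a desk-scale stand-in for
homology-based pseudogene callers: instead of searching a protein database,
the observed sequence is globally aligned to its reference ORF and the
reading frame is tracked along the alignment.

Calling rules
-------------
- *frameshift*: walking the alignment left to right, an insertion/deletion
  run leaves the cumulative indel balance not divisible by three — i.e. some
  downstream segment is read out of frame.  Indel runs anchored within the
  final 5% of the reference are ignored (alignment end-gaps are unreliable).
- *internal stop*: a codon of the observed sequence that is read in frame
  (frame inherited from the reference through the alignment, indel offset
  zero) translates to a stop strictly before the reference's terminal stop.
  Stops in the last complete codon before the terminal stop are not internal:
  they terminate where the gene terminates.

Scoring is fixed (match +1, mismatch -1, gap open -3, gap extend -1 per
base) with deterministic tie-breaking, so verdicts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
import numpy as np
from Bio import Align
from Bio.Data import CodonTable

#: bacterial start codons (genetic code table 11)
START_CODONS = frozenset({"ATG", "GTG", "TTG"})

#: fraction of the reference length, from the 3' end, inside which indel
#: runs are not trusted for frameshift calls
TERMINAL_GUARD = 0.05

#: maximum tolerated fraction of ambiguous (non-ACGT) bases
MAX_AMBIGUOUS_FRACTION = 0.10


class UnclassifiableError(ValueError):
    """Observed sequence too ambiguous (or empty) to classify."""


@dataclass(frozen=True)
class OrfVerdict:
    """Classification of an observed coding sequence against its reference.

    ``causes`` is nonempty exactly when ``status == 'pseudogene'``.
    ``net_indel_mod3`` is the final cumulative indel balance modulo 3 over
    frame-relevant indel runs; ``identity`` is matches over aligned columns
    (gap columns count in the denominator).
    """

    status: str
    causes: frozenset[str]
    n_premature_stops: int
    net_indel_mod3: int
    identity: float


def _stop_codons(code_table: int) -> frozenset[str]:
    table = CodonTable.unambiguous_dna_by_id[code_table]
    return frozenset(table.stop_codons)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    # Biopython charges open_gap_score for the first gap base, so a gap of
    # length L costs 3 + L: open -3 plus -1 per base.
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


def _validate_ref(ref_orf: str, code_table: int) -> None:
    if not ref_orf:
        raise UnclassifiableError("empty reference ORF")
    if len(ref_orf) % 3 != 0:
        raise ValueError(f"reference ORF length {len(ref_orf)} not divisible by 3")
    if ref_orf[:3] not in START_CODONS:
        raise ValueError(f"reference ORF does not begin with a start codon: {ref_orf[:3]}")
    if ref_orf[-3:] not in _stop_codons(code_table):
        raise ValueError(f"reference ORF does not end with a stop codon: {ref_orf[-3:]}")


def _scan_premature_stops(
    obs_codons: list[str], n_ref_codons: int, code_table: int
) -> int:
    """Count stop codons among in-frame observed codons strictly internal to
    the reference frame (codon index <= n_ref_codons - 3)."""
    stops = _stop_codons(code_table)
    return sum(
        1
        for i, codon in enumerate(obs_codons)
        if codon in stops and i <= n_ref_codons - 3
    )


def classify_vs_reference(ref_orf: str, obs: str, code_table: int = 11) -> OrfVerdict:
    """Classify ``obs`` against its reference ORF.

    ``ref_orf`` must be a complete ORF (start codon, terminal stop, length a
    multiple of 3), 5'->3'.  ``obs`` is the observed homolog, 5'->3'.

    Raises :class:`UnclassifiableError` for empty input or >10% ambiguous
    bases, and :class:`ValueError` for a malformed reference.
    """
    ref_orf = ref_orf.upper()
    obs = obs.upper()
    _validate_ref(ref_orf, code_table)
    if not obs:
        raise UnclassifiableError("empty observed sequence")
    n_ambig = sum(1 for b in obs if b not in "ACGT")
    if n_ambig > MAX_AMBIGUOUS_FRACTION * len(obs):
        raise UnclassifiableError(
            f"{n_ambig}/{len(obs)} ambiguous bases exceeds the "
            f"{MAX_AMBIGUOUS_FRACTION:.0%} threshold"
        )

    n_ref_codons = len(ref_orf) // 3

    if obs == ref_orf:
        # Identity alignment: no indels; stops read directly off the codons.
        codons = [ref_orf[3 * i : 3 * i + 3] for i in range(n_ref_codons)]
        n_stops = _scan_premature_stops(codons, n_ref_codons, code_table)
        causes = frozenset({"internal_stop"}) if n_stops else frozenset()
        return OrfVerdict(
            status="pseudogene" if causes else "gene",
            causes=causes,
            n_premature_stops=n_stops,
            net_indel_mod3=0,
            identity=1.0,
        )

    alignment = _aligner().align(ref_orf, obs)[0]
    ref_idx, obs_idx = alignment.indices  # -1 marks a gap in that row
    n_cols = ref_idx.shape[0]

    # --- frameshift: scan indel runs in column order -------------------
    guard_start = (1.0 - TERMINAL_GUARD) * len(ref_orf)
    frameshift = False
    net = 0
    col = 0
    ref_consumed = 0
    while col < n_cols:
        if ref_idx[col] >= 0 and obs_idx[col] >= 0:
            ref_consumed = ref_idx[col] + 1
            col += 1
            continue
        run_start = col
        run_net = 0
        while col < n_cols and (ref_idx[col] < 0 or obs_idx[col] < 0):
            run_net += 1 if ref_idx[col] < 0 else -1
            if ref_idx[col] >= 0:
                ref_consumed = ref_idx[col] + 1
            col += 1
        anchor = ref_idx[run_start] if ref_idx[run_start] >= 0 else ref_consumed
        if anchor >= guard_start:
            continue  # terminal sloppiness guard
        net += run_net
        if net % 3 != 0:
            frameshift = True

    # --- internal stops: in-frame translation inherited from ref -------
    ref_to_obs = np.full(len(ref_orf), -1, dtype=np.int64)
    offset_at_ref = np.zeros(len(ref_orf), dtype=np.int64)
    cum = 0
    for c in range(n_cols):
        r, o = ref_idx[c], obs_idx[c]
        if r >= 0 and o >= 0:
            ref_to_obs[r] = o
            offset_at_ref[r] = cum % 3
        elif r < 0:
            cum += 1
        else:
            cum -= 1
    obs_codons: list[str] = []
    for i in range(n_ref_codons):
        r0 = 3 * i
        o0, o1, o2 = ref_to_obs[r0], ref_to_obs[r0 + 1], ref_to_obs[r0 + 2]
        in_frame = (
            o0 >= 0
            and o1 == o0 + 1
            and o2 == o0 + 2
            and offset_at_ref[r0] == 0
        )
        obs_codons.append(obs[o0 : o0 + 3] if in_frame else "---")
    n_stops = _scan_premature_stops(obs_codons, n_ref_codons, code_table)

    causes = set()
    if frameshift:
        causes.add("frameshift")
    if n_stops:
        causes.add("internal_stop")

    counts = alignment.counts()
    identity = counts.identities / n_cols

    return OrfVerdict(
        status="pseudogene" if causes else "gene",
        causes=frozenset(causes),
        n_premature_stops=n_stops,
        net_indel_mod3=net % 3,
        identity=identity,
    )


def percent_identity(a: str, b: str) -> float:
    """Global-alignment nucleotide identity of two sequences, in [0, 1].

    Identity is matches divided by aligned columns, with gap columns in the
    denominator.  Computed from a unit-cost global alignment; symmetric by
    construction (inputs are canonically ordered) and exactly 1.0 iff the
    sequences are identical.
    """
    if not a or not b:
        raise ValueError("percent_identity requires nonempty sequences")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    if a > b:
        a, b = b, a
    result = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    num = ""
    for ch in result["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=":
            matches += n
    return matches / columns
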