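"""Assembly and annotation I/O.

Reads and writes multi-record FASTA plus GFF3 with pseudogene qualifiers,
extracts pseudogene causes (frameshift, internal stop, partial) from feature
attributes, and computes per-Mbp pseudogene densities.

Coordinates are GFF3-native: 1-based, inclusive on both ends.  A feature on
the minus strand has ``start < end`` in genome coordinates; its spliced
sequence is reverse-complemented on extraction.

Pseudogene recognition accepts the union of the dialects seen in prokaryotic
annotation output: a ``pseudo=true`` attribute, ``gene_biotype=pseudogene``,
or a feature of type ``pseudogene``.  Causes are recognized by
case-insensitive substring match in the ``Note`` and ``pseudogene``
attributes: "frameshift" -> frameshift, "internal stop" -> internal_stop,
"incomplete"/"partial" -> partial.  A single pseudogene may carry several
causes and is counted once per cause in cause-specific tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

FRAMESHIFT = "frameshift"
INTERNAL_STOP = "internal_stop"
PARTIAL = "partial"
CAUSES = frozenset({FRAMESHIFT, INTERNAL_STOP, PARTIAL})

#: substrings (lower-case) recognized in annotation free text, per cause
_CAUSE_KEYWORDS = {
    FRAMESHIFT: ("frameshift",),
    INTERNAL_STOP: ("internal stop",),
    PARTIAL: ("incomplete", "partial"),
}

#: canonical free-text phrases emitted on write, chosen to round-trip
_CAUSE_PHRASES = {
    FRAMESHIFT: "frameshifted",
    INTERNAL_STOP: "internal stop",
    PARTIAL: "incomplete",
}


class GffParseError(ValueError):
    """A malformed GFF3 line; the message names the offending line number."""


@dataclass(frozen=True)
class CdsFeature:
    """One annotated coding feature with gene/pseudogene status and causes.

    ``causes`` is empty for intact genes; for pseudogenes it is the (possibly
    empty, if the annotation gives no recognized cause) subset of
    ``{frameshift, internal_stop, partial}``.  ``nt_sequence`` is the spliced,
    strand-corrected (5'->3') nucleotide sequence when available.
    ``ancestral_nt`` optionally records the intact ancestral ORF a pseudogene
    derives from; it is populated by the synthetic generator and used by the
    reference-based classifier.
    """

    feature_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'
    status: str = "gene"  # 'gene' or 'pseudogene'
    causes: frozenset[str] = frozenset()
    nt_sequence: str | None = None
    ancestral_nt: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"feature {self.feature_id}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: strand must be '+' or '-'")
        if self.status not in ("gene", "pseudogene"):
            raise ValueError(f"feature {self.feature_id}: bad status {self.status!r}")
        if self.status == "gene" and self.causes:
            raise ValueError(f"feature {self.feature_id}: intact gene cannot carry causes")
        if not frozenset(self.causes) <= CAUSES:
            raise ValueError(f"feature {self.feature_id}: unknown causes {set(self.causes) - CAUSES}")
        object.__setattr__(self, "causes", frozenset(self.causes))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def extract_sequence(self, contigs: Mapping[str, str]) -> str:
        """Spliced, strand-corrected sequence from ``contigs``."""
        seq = contigs[self.contig_id][self.start - 1 : self.end]
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class AssemblyAnnotation:
    """A genome assembly: contigs, coding features and acquisition metadata.

    ``contigs`` maps contig id to nucleotide sequence; when only lengths are
    known, use :attr:`contig_lengths` and leave ``contigs`` empty.
    ``coverage`` is fold-coverage and ``quality`` a mean Phred Q-score; both
    optional, as in public assembly metadata.
    """

    assembly_id: str
    contigs: dict[str, str] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)
    features: list[CdsFeature] = field(default_factory=list)
    coverage: float | None = None
    quality: float | None = None
    platform: str | None = None
    assembler: str | None = None

    def __post_init__(self) -> None:
        if self.contigs and not self.contig_lengths:
            self.contig_lengths = {cid: len(s) for cid, s in self.contigs.items()}
        for f in self.features:
            clen = self.contig_lengths.get(f.contig_id)
            if clen is not None and f.end > clen:
                raise ValueError(
                    f"feature {f.feature_id} extends past contig {f.contig_id} "
                    f"({f.end} > {clen})"
                )

    @property
    def genome_length(self) -> int:
        return sum(self.contig_lengths.values())

    def with_sequences(self) -> "AssemblyAnnotation":
        """Return a copy whose features carry their extracted nt_sequence."""
        feats = [
            f if f.nt_sequence is not None else replace(f, nt_sequence=f.extract_sequence(self.contigs))
            for f in self.features
        ]
        out = AssemblyAnnotation(
            assembly_id=self.assembly_id,
            contigs=self.contigs,
            contig_lengths=dict(self.contig_lengths),
            features=feats,
            coverage=self.coverage,
            quality=self.quality,
            platform=self.platform,
            assembler=self.assembler,
        )
        return out


@dataclass(frozen=True)
class PseudogeneDensity:
    """Pseudogene counts and per-Mbp densities for one assembly."""

    n_frameshift: int
    n_internal_stop: int
    n_partial: int
    density_frameshift: float
    density_internal_stop: float
    n_cds_total: int


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    if attr_field in (".", ""):
        return attrs
    from urllib.parse import unquote

    for chunk in attr_field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise GffParseError(f"line {lineno}: attribute without '=': {chunk!r}")
        key, _, value = chunk.partition("=")
        attrs.setdefault(key, []).extend(unquote(v) for v in value.split(","))
    return attrs


def _causes_from_attrs(attrs: Mapping[str, list[str]]) -> frozenset[str]:
    text = " ; ".join(
        v.lower() for key in ("Note", "note", "pseudogene") for v in attrs.get(key, [])
    )
    found = {
        cause
        for cause, keywords in _CAUSE_KEYWORDS.items()
        if any(kw in text for kw in keywords)
    }
    return frozenset(found)


def _is_pseudogene(featuretype: str, attrs: Mapping[str, list[str]]) -> bool:
    if featuretype == "pseudogene":
        return True
    if any(v.lower() == "true" for v in attrs.get("pseudo", [])):
        return True
    if any(v.lower() == "pseudogene" for v in attrs.get("gene_biotype", [])):
        return True
    return False


def read_gff3(path: str | Path) -> list[CdsFeature]:
    """Parse CDS-bearing loci from a GFF3 file.

    Returns one :class:`CdsFeature` per ``CDS`` or ``pseudogene`` feature
    line, with pseudogene status and causes populated from the attributes.
    Other feature types (gene, tRNA, region, ...) are ignored.  Malformed
    lines raise :class:`GffParseError` naming the line number; a pseudogene
    whose attributes carry no recognized cause keyword yields empty causes
    and a logged warning.
    """
    features: list[CdsFeature] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                break  # embedded ##FASTA section
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attr_field = cols
            if ftype not in ("CDS", "pseudogene"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise GffParseError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
            attrs = _parse_attributes(attr_field, lineno)
            fid = attrs.get("ID", [f"feature_{lineno}"])[0]
            if fid in seen_ids:
                continue  # multi-line CDS: keep the first segment's locus entry
            seen_ids.add(fid)
            pseudo = _is_pseudogene(ftype, attrs)
            causes = _causes_from_attrs(attrs) if pseudo else frozenset()
            if pseudo and not causes and any(k in attrs for k in ("Note", "note", "pseudogene")):
                logger.warning(
                    "line %d: pseudogene %s carries no recognized cause keyword", lineno, fid
                )
            try:
                features.append(
                    CdsFeature(
                        feature_id=fid,
                        contig_id=contig,
                        start=start,
                        end=end,
                        strand=strand,
                        status="pseudogene" if pseudo else "gene",
                        causes=causes,
                    )
                )
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: {exc}") from exc
    return features


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{contig_id: uppercase sequence}``.

    IDs are the first whitespace-delimited token of each header.  Duplicate
    IDs and empty files are errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA record id: {rec.id}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return contigs


def _encode_attr(value: str) -> str:
    from urllib.parse import quote

    return quote(value, safe=" .:^*$@!+?|/()[]{}'\"-_")


def write_assembly(assembly: AssemblyAnnotation, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write contigs as FASTA and features as GFF3.

    Round-trips: ``read_gff3``/``read_fasta`` on the output reproduce the
    feature list (ids, coordinates, strands, statuses, causes) and sequences.
    """
    if not assembly.contigs:
        raise ValueError("assembly carries no contig sequences")
    with open(fasta_path, "w") as fh:
        for cid in assembly.contigs:
            fh.write(f">{cid}\n")
            seq = assembly.contigs[cid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, length in assembly.contig_lengths.items():
            fh.write(f"##sequence-region {cid} 1 {length}\n")
        for f in assembly.features:
            attrs = [f"ID={_encode_attr(f.feature_id)}"]
            if f.status == "pseudogene":
                attrs.append("pseudo=true")
                if f.causes:
                    note = "%3B ".join(
                        _encode_attr(_CAUSE_PHRASES[c]) for c in sorted(f.causes)
                    )
                    attrs.append(f"Note={note}")
            fh.write(
                "\t".join(
                    (
                        f.contig_id,
                        "pseudocheck",
                        "CDS",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        ";".join(attrs),
                    )
                )
                + "\n"
            )


def pseudogene_density(assembly: AssemblyAnnotation) -> PseudogeneDensity:
    """Count pseudogenes per cause and normalize per Mbp of assembly length.

    A pseudogene with several causes counts once in each cause-specific
    tally.  ``density_x = n_x * 1e6 / genome_length``, exactly.
    """
    glen = assembly.genome_length
    if glen <= 0:
        raise ValueError("assembly genome length must be positive")
    n_fs = sum(1 for f in assembly.features if FRAMESHIFT in f.causes)
    n_is = sum(1 for f in assembly.features if INTERNAL_STOP in f.causes)
    n_pt = sum(1 for f in assembly.features if PARTIAL in f.causes)
    return PseudogeneDensity(
        n_frameshift=n_fs,
        n_internal_stop=n_is,
        n_partial=n_pt,
        density_frameshift=n_fs * 1e6 / glen,
        density_internal_stop=n_is * 1e6 / glen,
        n_cds_total=len(assembly.features),
    )


_METADATA_COLUMNS = ["assembly_id", "coverage", "quality", "platform", "assembler"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Load a per-assembly metadata table (TSV with header).

    Expected columns: assembly_id, coverage, quality, platform, assembler.
    Missing cells are preserved as NA and propagated as absent metadata.
    """
    df = pd.read_csv(path, sep="\t", dtype={"assembly_id": str})
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    return df[_METADATA_COLUMNS + [c for c in df.columns if c not in _METADATA_COLUMNS]]


def apply_metadata(assembly: AssemblyAnnotation, metadata: pd.DataFrame) -> AssemblyAnnotation:
    """Fill coverage/quality/platform/assembler from a metadata table row."""
    rows = metadata[metadata["assembly_id"] == assembly.assembly_id]
    if rows.empty:
        return assembly
    row = rows.iloc[0]
    for attr in ("coverage", "quality", "platform", "assembler"):
        value = row[attr]
        if pd.notna(value):
            setattr(assembly, attr, value)
    return assembly


def features_to_frame(features: Iterable[CdsFeature]) -> pd.DataFrame:
    """Tidy one-row-per-feature DataFrame (used by CLI reports)."""
    return pd.DataFrame(
        {
            "feature_id": f.feature_id,
            "contig_id": f.contig_id,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
            "status": f.status,
            "causes": ",".join(sorted(f.causes)),
        }
        for f in features
    )
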