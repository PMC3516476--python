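"""Sequence and annotation I/O with a single circular-coordinate convention.

All internal coordinates are 1-based inclusive.  A feature on a circular
molecule may wrap the origin, in which case ``end < start`` and the ``wraps``
flag is set.  External formats keep their native conventions (GenBank and
GFF3 are 1-based inclusive, BED is 0-based half-open); conversion happens at
the boundary, never inside the detectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")
FEATURE_KINDS = ("CDS", "tRNA", "repeat_region", "oriV", "oriT", "misc")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# GFF3 type column <-> internal feature kind
_GFF_TYPE_FOR_KIND = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "repeat_region": "repeat_region",
    "oriV": "rep_origin",
    "oriT": "oriT",
    "misc": "region",
}
_KIND_FOR_GFF_TYPE = {v: k for k, v in _GFF_TYPE_FOR_KIND.items()}


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file does not parse in the declared format."""


class CoordinateError(ValueError):
    """Raised for coordinate requests outside a molecule."""


@dataclass(frozen=True)
class Feature:
    """An annotated interval (1-based inclusive, explicit wrap flag)."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    qualifiers: tuple = ()  # tuple of (key, value) pairs; hashable
    wraps: bool = False

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.wraps and self.start > self.end:
            raise ValueError(
                f"feature {self.kind} {self.start}..{self.end}: start > end "
                "without wrap flag"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def qualifier_dict(self) -> dict:
        return dict(self.qualifiers)

    def qualifier(self, key: str, default=None):
        return self.qualifier_dict.get(key, default)

    def span_length(self, molecule_length: int) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        return (molecule_length - self.start + 1) + self.end

    def label(self) -> str:
        q = self.qualifier_dict
        return q.get("locus_tag") or q.get("ID") or f"{self.kind}:{self.start}-{self.end}"


def make_feature(kind, start, end, strand="+", qualifiers=None, wraps=False) -> Feature:
    quals = tuple(sorted((qualifiers or {}).items()))
    return Feature(kind, int(start), int(end), strand, quals, wraps)


@dataclass
class AnnotatedReplicon:
    """A nucleotide sequence with topology and typed features."""

    id: str
    sequence: str
    circular: bool = False
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"replicon {self.id}: characters outside ACGTN: {sorted(bad)}"
            )
        for f in self.features:
            self._check_feature(f)

    def _check_feature(self, f: Feature) -> None:
        n = self.length
        if not (1 <= f.start <= n and 1 <= f.end <= n):
            raise CoordinateError(
                f"feature {f.kind} {f.start}..{f.end} outside [1, {n}]"
            )
        if f.wraps and not self.circular:
            raise CoordinateError(
                f"feature {f.kind} wraps the origin of a linear molecule"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def add_feature(self, feat: Feature) -> None:
        self._check_feature(feat)
        self.features.append(feat)

    def features_of_kind(self, kind: str) -> list:
        return [f for f in self.features if f.kind == kind]


def subsequence(replicon: AnnotatedReplicon, start: int, length: int,
                strand: str = "+") -> str:
    """Extract ``length`` bases starting at 1-based ``start``.

    Circular molecules wrap past the origin; ``strand == '-'`` returns the
    reverse complement of the extracted plus-strand segment.  Requests past
    the end of a linear molecule raise :class:`CoordinateError`.
    """
    n = replicon.length
    if not 1 <= start <= n:
        raise CoordinateError(f"start {start} outside [1, {n}]")
    if length < 0:
        raise CoordinateError("length must be >= 0")
    if length == 0:
        return ""
    if start + length - 1 > n:
        if not replicon.circular:
            raise CoordinateError(
                f"request {start}+{length} runs past the end of linear "
                f"molecule {replicon.id} (length {n})"
            )
        s = replicon.sequence
        out = []
        pos = start - 1
        remaining = length
        while remaining > 0:
            take = min(remaining, n - pos)
            out.append(s[pos:pos + take])
            remaining -= take
            pos = 0
        seg = "".join(out)
    else:
        seg = replicon.sequence[start - 1:start - 1 + length]
    return revcomp(seg) if strand == "-" else seg


def feature_sequence(replicon: AnnotatedReplicon, feat: Feature) -> str:
    """Strand-corrected sequence of a feature (5'->3' on its own strand)."""
    return subsequence(replicon, feat.start, feat.span_length(replicon.length),
                       feat.strand)


def interval_overlaps(a_start, a_end, a_wraps, b_start, b_end, b_wraps, n) -> bool:
    """Do two 1-based inclusive intervals on a length-``n`` molecule overlap?"""

    def segments(s, e, w):
        return [(s, n), (1, e)] if w else [(s, e)]

    for s1, e1 in segments(a_start, a_end, a_wraps):
        for s2, e2 in segments(b_start, b_end, b_wraps):
            if s1 <= e2 and s2 <= e1:
                return True
    return False


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _record_to_replicon(record: SeqRecord, circular: bool | None) -> AnnotatedReplicon:
    topo = record.annotations.get("topology")
    if circular is None:
        circular = topo == "circular"
    n = len(record.seq)
    feats = []
    for sf in record.features:
        kind = sf.type if sf.type in FEATURE_KINDS else "misc"
        quals = {k: "; ".join(map(str, v)) if isinstance(v, list) else str(v)
                 for k, v in sf.qualifiers.items()}
        strand = "-" if sf.location.strand == -1 else "+"
        parts = sorted(sf.location.parts, key=lambda p: int(p.start))
        if (len(parts) == 2 and int(parts[-1].end) == n and int(parts[0].start) == 0):
            # join over the circular origin
            start = int(parts[-1].start) + 1
            end = int(parts[0].end)
            feats.append(make_feature(kind, start, end, strand, quals, wraps=True))
        else:
            feats.append(make_feature(kind, int(sf.location.start) + 1,
                                      int(sf.location.end), strand, quals))
    return AnnotatedReplicon(record.id, str(record.seq), circular, feats)


def _read_gff3(gff_path, fasta_path, circular) -> AnnotatedReplicon:
    import gffutils

    record = SeqIO.read(str(fasta_path), "fasta")
    n = len(record.seq)
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    feats = []
    for f in db.all_features():
        kind = _KIND_FOR_GFF_TYPE.get(f.featuretype, "misc")
        quals = {k: ",".join(v) for k, v in f.attributes.items()}
        start, end, wraps = f.start, f.end, False
        if end > n:  # circular-landmark convention: end past the origin
            end, wraps = end - n, True
        strand = "-" if f.strand == "-" else "+"
        feats.append(make_feature(kind, start, end, strand, quals, wraps))
    return AnnotatedReplicon(record.id, str(record.seq), bool(circular), feats)


def read_replicon(path, fmt: str = "fasta", circular: bool | None = None,
                  fasta_path=None) -> AnnotatedReplicon:
    """Read one replicon from ``path`` in ``fmt`` (fasta, genbank, gff3).

    For ``gff3`` a companion FASTA is required (``fasta_path``).  ``circular``
    overrides the record topology; for formats that do not carry topology it
    defaults to linear.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "fasta":
            record = SeqIO.read(str(path), "fasta")
            return AnnotatedReplicon(record.id, str(record.seq), bool(circular), [])
        if fmt == "genbank":
            record = SeqIO.read(str(path), "genbank")
            return _record_to_replicon(record, circular)
        if fmt == "gff3":
            if fasta_path is None:
                raise ValueError("gff3 input needs a companion fasta_path")
            return _read_gff3(path, fasta_path, circular)
    except (ValueError, KeyError) as exc:
        if isinstance(exc, (ParseError, CoordinateError)):
            raise
        raise ParseError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    raise ValueError(f"unknown format {fmt!r}")


def _replicon_to_record(rep: AnnotatedReplicon) -> SeqRecord:
    record = SeqRecord(Seq(rep.sequence), id=rep.id, name=rep.id[:16],
                       description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if rep.circular else "linear"
    n = rep.length
    for f in rep.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps:
            loc = CompoundLocation([FeatureLocation(f.start - 1, n, strand),
                                    FeatureLocation(0, f.end, strand)])
        else:
            loc = FeatureLocation(f.start - 1, f.end, strand)
        quals = {k: [v] for k, v in f.qualifiers}
        record.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    return record


def write_replicon(rep: AnnotatedReplicon, path, fmt: str = "fasta",
                   fasta_path=None) -> None:
    """Write ``rep`` to ``path``; gff3 writes a companion FASTA as well."""
    path = Path(path)
    if fmt == "fasta":
        SeqIO.write(_replicon_to_record(rep), str(path), "fasta")
        return
    if fmt == "genbank":
        SeqIO.write(_replicon_to_record(rep), str(path), "genbank")
        return
    if fmt == "gff3":
        n = rep.length
        lines = ["##gff-version 3",
                 f"##sequence-region {rep.id} 1 {n}"]
        if rep.circular:
            lines.append(f"# circular topology; features with end > {n} wrap")
        for i, f in enumerate(sorted(rep.features, key=lambda f: (f.start, f.end))):
            end = f.end + n if f.wraps else f.end
            attrs = [f"ID={f.label()}.{i}"]
            for k, v in f.qualifiers:
                if k not in ("ID",):
                    attrs.append(f"{k}={v}")
            lines.append("\t".join([
                rep.id, "imescan", _GFF_TYPE_FOR_KIND[f.kind], str(f.start),
                str(end), ".", f.strand, ".", ";".join(attrs)]))
        path.write_text("\n".join(lines) + "\n")
        if fasta_path is not None:
            SeqIO.write(_replicon_to_record(rep), str(fasta_path), "fasta")
        return
    raise ValueError(f"unknown format {fmt!r}")


def read_bed(path) -> list:
    """Read a 3+ column BED file into 1-based inclusive intervals.

    Returns a list of ``(chrom, start, end)`` with BED's 0-based half-open
    coordinates converted to the internal convention.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [(str(r.chrom), int(r.start) + 1, int(r.end))
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# tRNA library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrnaEntry:
    source_id: str
    trna_id: str
    isotype: str
    sequence: str               # strand-corrected, 3' terminus last
    three_prime_terminus: str   # suffix of ``sequence``
    upstream_flank: str         # 5' flank, strand-corrected
    downstream_flank: str       # 3' flank, strand-corrected
    ambiguous_terminus: bool = False  # N in the terminus


@dataclass
class TrnaLibrary:
    entries: list = field(default_factory=list)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def build_trna_library(replicons: Sequence[AnnotatedReplicon],
                       flank_bp: int = 500,
                       terminus_bp: int = 25) -> TrnaLibrary:
    """One entry per tRNA feature, strand-corrected so the 3' terminus is the
    last ``terminus_bp`` characters.  Flanks are truncated at the ends of
    linear molecules and wrap on circular ones (capped at molecule length)."""
    entries = []
    for rep in replicons:
        n = rep.length
        for f in rep.features_of_kind("tRNA"):
            gene = feature_sequence(rep, f)
            span = f.span_length(n)
            # genomic flanks first (left of start / right of end), then
            # strand-correct so "upstream" means 5' of the tRNA
            if rep.circular:
                fl = min(flank_bp, max(0, n - span) // 2)
                left = subsequence(rep, (f.start - 1 - fl) % n + 1, fl, "+")
                right = subsequence(rep, f.end % n + 1, fl, "+")
            else:
                left = rep.sequence[max(0, f.start - 1 - flank_bp):f.start - 1]
                right = rep.sequence[f.end:f.end + flank_bp]
            if f.strand == "+":
                up, down = left, right
            else:
                up, down = revcomp(right), revcomp(left)
            terminus = gene[-terminus_bp:]
            iso = dict(f.qualifiers).get("product", dict(f.qualifiers).get("isotype", ""))
            entries.append(TrnaEntry(
                source_id=rep.id, trna_id=f.label(), isotype=iso,
                sequence=gene, three_prime_terminus=terminus,
                upstream_flank=up, downstream_flank=down,
                ambiguous_terminus="N" in terminus))
    return TrnaLibrary(entries)
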