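"""ORF calling, composition statistics and the functional-module report.

ORFs are called by plain six-frame scanning with the bacterial genetic code
(translation table 11): within each stop-to-stop segment of a frame the
longest open reading from the first accepted start codon is reported.  On a
circular molecule reading may continue across the origin, found by scanning
the doubled sequence.  Coding density is the fraction of the molecule
covered by the union of CDS spans.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data import CodonTable

from .seqio import AnnotatedReplicon, Feature, revcomp

DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")

# keyword -> functional group used by the module report; order is priority
DEFAULT_KEYWORD_MAP = (
    ("mobile_elements", ("transposase", "resolvase", "insertion sequence",
                         "istb", "tnpa", "tnpr", "transposon")),
    ("replication", ("replication initiat", "repa", "oriv", "iteron",
                     "dnaa", "rep-3", "primase")),
    ("partition_maintenance", ("para", "parb", "partition", "relb", "rele",
                               "toxin", "antitoxin", "addiction")),
    ("mobilization", ("relaxase", "mob", "orit", "repb",
                      "conjugal", "conjugative")),
    ("integration", ("integrase", "recombinase", "excisionase", "copg",
                     "attp", "attb", "phage int", "xerc", "xerd")),
    ("degradation", ("hydrolase", "dioxygenase", "phosphotriesterase",
                     "opd", "oph", "liga", "ligb", "monooxygenase",
                     "degradation", "lysr", "facilitator", "transporter",
                     "mutase")),
)


@dataclass(frozen=True)
class OrfCall:
    """A called open reading frame, stop codon included in the span."""

    start: int
    end: int
    strand: str
    frame: int            # 1..3 on the scanned strand
    length_aa: int        # codons before the stop
    wraps_origin: bool = False


@dataclass(frozen=True)
class RepliconStats:
    length_bp: int
    gc_percent: float
    orf_count: int
    coding_density_percent: float


def _stop_codons(table: int) -> set:
    return set(CodonTable.unambiguous_dna_by_id[table].stop_codons)


def _scan_strand(seq: str, n: int, circular: bool, strand: str,
                 min_length_aa: int, start_codons, stops) -> list:
    """Scan the three frames of one strand.  ``seq`` is already the strand
    to read (doubled when circular); coordinates are mapped back to the
    plus strand of the original molecule afterwards."""
    calls = []
    limit = len(seq)
    for f in range(3):
        starts_pending = []
        i = f
        while i + 3 <= limit:
            codon = seq[i:i + 3]
            if codon in stops:
                for s0 in starts_pending:
                    if s0 < n:  # count each wrap-equivalent ORF once
                        aa = (i - s0) // 3
                        if aa >= min_length_aa:
                            calls.append((s0, i + 2))
                        break   # longest reading in the segment only
                starts_pending = []
            elif codon in start_codons and not starts_pending:
                starts_pending.append(i)
            i += 3
        # segments with no stop before the scan limit are not ORFs
    out = []
    for s0, e0 in calls:
        if e0 - s0 + 1 > n:
            continue
        if strand == "+":
            g_start, g_end = s0, e0
        else:
            # position p on the reverse strand maps to n*-1-p of its source
            g_start, g_end = len(seq) - 1 - e0, len(seq) - 1 - s0
            g_start %= n if circular else len(seq)
            g_end = g_start + (e0 - s0)
        wraps = False
        if circular:
            g_start %= n
            g_end_mod = g_end % n
            if g_end >= n and g_start > g_end_mod:
                wraps = True
            g_end = g_end_mod if g_end >= n else g_end
        out.append(OrfCall(g_start + 1, g_end + 1, strand,
                           frame=(s0 % 3) + 1,
                           length_aa=(e0 - s0 + 1 - 3) // 3,
                           wraps_origin=wraps))
    return out


def call_orfs(replicon: AnnotatedReplicon, min_length_aa: int = 50,
              start_codons=DEFAULT_START_CODONS, table: int = 11) -> list:
    """Six-frame ORF scan; the longest reading per stop-to-stop segment.

    Circular molecules are scanned over their doubled sequence, so an ORF
    may wrap the origin (``wraps_origin``).  ``length_aa`` excludes the stop
    codon; the reported span includes it.
    """
    if min_length_aa < 1:
        raise ValueError("min_length_aa must be >= 1")
    stops = _stop_codons(table)
    starts = set(c.upper() for c in start_codons)
    n = replicon.length
    plus = replicon.sequence * 2 if replicon.circular else replicon.sequence
    minus = revcomp(plus)
    calls = (_scan_strand(plus, n, replicon.circular, "+",
                          min_length_aa, starts, stops)
             + _scan_strand(minus, n, replicon.circular, "-",
                            min_length_aa, starts, stops))
    # one ORF per stop codon: a reading that wraps the origin supersedes a
    # shorter one ending at the same genomic stop
    best = {}
    for c in calls:
        stop_pos = c.end if c.strand == "+" else c.start
        key = (stop_pos, c.strand)
        if key not in best or c.length_aa > best[key].length_aa:
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.start, c.end, c.strand))


def gc_content(replicon: AnnotatedReplicon) -> float:
    """GC percentage over unambiguous bases; Ns excluded from both sides."""
    s = replicon.sequence
    counts = {b: s.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / total


def coding_density(features, length_bp: int) -> float:
    """Percentage of the molecule covered by the union of CDS intervals.

    Overlaps are counted once; wrap-around intervals are split at the
    origin.  Intervals outside [1, length] raise a validation error.
    """
    segs = []
    for f in features:
        if getattr(f, "kind", "CDS") != "CDS":
            continue
        if not (1 <= f.start <= length_bp and 1 <= f.end <= length_bp):
            raise ValueError(
                f"CDS {f.start}..{f.end} outside molecule of {length_bp} bp")
        if f.wraps:
            segs.extend([(f.start, length_bp), (1, f.end)])
        else:
            segs.append((f.start, f.end))
    if not segs:
        return 0.0
    segs.sort()
    covered = 0
    cur_s, cur_e = segs[0]
    for s, e in segs[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    covered += cur_e - cur_s + 1
    return 100.0 * covered / length_bp


def replicon_stats(replicon: AnnotatedReplicon) -> RepliconStats:
    """Length, GC% (2 dp), annotated CDS count and coding density (1 dp).

    Computed from the record's own annotation, not from re-called ORFs, so
    the numbers are comparable with a deposited GenBank record.
    """
    cds = replicon.features_of_kind("CDS")
    return RepliconStats(
        length_bp=replicon.length,
        gc_percent=round(gc_content(replicon), 2),
        orf_count=len(cds),
        coding_density_percent=round(coding_density(cds, replicon.length), 1),
    )


# ---------------------------------------------------------------------------
# Module report
# ---------------------------------------------------------------------------

def _classify(feature: Feature, keyword_map) -> str:
    text = " ".join(v for _, v in feature.qualifiers).lower()
    for group, words in keyword_map:
        for w in words:
            if re.search(r"(?<![a-z0-9])" + re.escape(w), text):
                return group
    return "unassigned"


def module_report(replicon: AnnotatedReplicon, detections: dict | None = None,
                  keyword_map=DEFAULT_KEYWORD_MAP,
                  cross_reference_bp: int = 2000) -> dict:
    """Group annotation and detector output into functional modules.

    ``detections`` may carry ``ori_ter`` (an OriTerCall), ``iterons``,
    ``hairpins``, ``motif_hits``, ``at_rich``, ``att_candidates`` and
    ``transposons`` (a TransposonScan).  Detector results are placed in
    their natural groups; an ori call with an iteron array within
    ``cross_reference_bp`` is cross-referenced as a corroborated origin.
    """
    detections = detections or {}
    groups = {g: [] for g, _ in keyword_map}
    groups["unassigned"] = []

    def item(kind, start, end, strand, label, source):
        return {"kind": kind, "start": int(start), "end": int(end),
                "strand": strand, "label": label, "source": source}

    for f in replicon.features:
        groups[_classify(f, keyword_map)].append(
            item(f.kind, f.start, f.end, f.strand, f.label(), "annotation"))

    cross_references = []
    ori = detections.get("ori_ter")
    if ori is not None and getattr(ori, "called", False):
        groups["replication"].append(item(
            "oriV", ori.ori_position, ori.ori_position, "+",
            f"ori (cumulative-skew minimum, confidence {ori.confidence:.3g})",
            "skewscan"))
    for arr in detections.get("iterons", []):
        groups["replication"].append(item(
            "repeat_region", arr.start, arr.end, "+",
            f"iteron array {arr.unit_length}x{arr.copies}", "repeatscan"))
        if ori is not None and getattr(ori, "called", False):
            if min(abs(arr.start - ori.ori_position),
                   abs(arr.end - ori.ori_position)) <= cross_reference_bp:
                cross_references.append(
                    {"what": "oriV", "skew_position": ori.ori_position,
                     "iteron_start": arr.start,
                     "note": "skew minimum corroborated by iteron array"})
    for pos, strand, mm in detections.get("motif_hits", []):
        groups["replication"].append(item(
            "misc", pos, pos, strand, f"DnaA-box hit ({mm} mismatch)",
            "repeatscan"))
    for s, e in detections.get("at_rich", []):
        groups["replication"].append(item(
            "misc", s, e, "+", "AT-rich window", "repeatscan"))
    for hp in detections.get("hairpins", []):
        groups["mobilization"].append(item(
            "oriT", hp.left_start, hp.right_end, "+",
            f"hairpin arm {hp.arm_length} spacer {hp.spacer_bp}",
            "repeatscan"))
    for c in detections.get("att_candidates", []):
        groups["integration"].append(item(
            "misc", c.target_start, c.target_end, c.target_strand,
            f"att core {c.core_sequence} (E={c.expect_score:.3g})",
            "attscan"))
    tn = detections.get("transposons")
    if tn is not None:
        for u in tn.units:
            groups["mobile_elements"].append(item(
                "repeat_region", u.unit_start, u.unit_end, "+",
                f"transposable unit ({len(u.cargo_features)} cargo features)",
                "repeatscan"))
        for cp in tn.copies:
            groups["mobile_elements"].append(item(
                "repeat_region", cp.start, cp.end, cp.strand,
                f"terminal repeat copy ({cp.mismatches} mismatch)",
                "repeatscan"))

    stats = replicon_stats(replicon)
    return {
        "replicon": replicon.id,
        "length_bp": stats.length_bp,
        "gc_percent": stats.gc_percent,
        "cds_count": stats.orf_count,
        "coding_density_percent": stats.coding_density_percent,
        "groups": groups,
        "cross_references": cross_references,
    }
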