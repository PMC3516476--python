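"""attP/attB prediction and in-silico Campbell integration.

Attachment sites of tRNA-targeting integrases share a core sequence that is
identical between the element (attP) and the 3' end of a host tRNA gene
(attB).  Candidates are therefore maximal exact matches between tRNA 3'
termini and a target replicon, ranked by an expectation score: the expected
number of equally long or longer exact matches under a mononucleotide null
model of the target.  A Campbell-type single crossover within a shared core
turns a circular element plus a host molecule into one cointegrate with the
core duplicated at the attL/attR junctions.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace

from .seqio import (AnnotatedReplicon, TrnaLibrary, interval_overlaps,
                    revcomp, subsequence)


@dataclass(frozen=True)
class AttScanParams:
    min_match_bp: int = 10
    require_terminus_anchor: bool = True
    max_terminus_offset: int = 0   # used when the anchor requirement is relaxed
    search_both_strands: bool = True
    intergenic_only: bool = False

    def __post_init__(self):
        if self.min_match_bp < 4:
            raise ValueError("min_match_bp must be >= 4")


@dataclass(frozen=True)
class AttCandidate:
    """A maximal exact match between a tRNA suffix and the target."""

    trna_id: str
    target_id: str
    match_length: int
    trna_end_offset: int        # 0 = anchored at the 3' terminus
    target_start: int           # 1-based inclusive, plus-strand coordinates
    target_end: int
    target_strand: str
    target_wraps: bool
    core_sequence: str
    expect_score: float = float("nan")
    intergenic: bool | None = None
    in_genomic_island: bool | None = None


def _maximal_anchored_matches(query: str, offset: int, search: str, L: int,
                              strand: str, min_match: int, circular: bool):
    """Maximal exact matches of a suffix of ``query`` (its last ``offset``
    bases removed) against ``search`` (target, possibly doubled), left-
    extended from a seed of length ``min_match``.

    Yields (match_len, end_index_in_plus_coords_0based, strand).
    """
    q = query[:len(query) - offset] if offset else query
    if len(q) < min_match:
        return
    seed = q[-min_match:]
    if "N" in seed:
        return
    pos = search.find(seed)
    while pos != -1:
        end = pos + min_match - 1            # index of match end in `search`
        if "N" not in search[pos:end + 1]:
            # extend leftward into the query
            length = min_match
            while (length < len(q) and pos - 1 >= 0
                   and search[pos - 1] == q[-(length + 1)]
                   and search[pos - 1] != "N"):
                pos -= 1
                length += 1
            # right-maximality: an anchored match (offset 0) cannot extend
            # past the 3' terminus; a relaxed match must not be extendable,
            # otherwise it is contained in a smaller-offset match
            extendable = (offset > 0 and end + 1 < len(search)
                          and search[end + 1] == query[len(query) - offset]
                          and search[end + 1] != "N")
            if not extendable:
                start = end - length + 1
                if not circular or start < L:
                    yield length, start, end
        pos = search.find(seed, end - min_match + 2)


def find_att_candidates(trna_library: TrnaLibrary,
                        target: AnnotatedReplicon,
                        params: AttScanParams = AttScanParams()) -> list:
    """All maximal exact matches of tRNA 3'-anchored suffixes in the target.

    With ``require_terminus_anchor`` every match ends exactly at the tRNA 3'
    terminus; relaxing it admits matches ending within
    ``max_terminus_offset`` bases of the terminus.  Both target strands are
    searched by default and circular targets wrap.  Candidates are sorted by
    ascending expectation score, then coordinate.
    """
    if len(trna_library) == 0:
        return []
    L = target.length
    if L == 0:
        return []
    max_q = max(len(e.sequence) for e in trna_library)
    if target.circular:
        plus = target.sequence + target.sequence[:min(max_q, L) - 1]
    else:
        plus = target.sequence
    minus = revcomp(plus)
    offsets = (range(params.max_terminus_offset + 1)
               if not params.require_terminus_anchor else (0,))

    out = []
    seen = set()
    for entry in trna_library:
        q = entry.sequence
        for off in offsets:
            for strand in ("+", "-") if params.search_both_strands else ("+",):
                search = plus if strand == "+" else minus
                for length, s_idx, e_idx in _maximal_anchored_matches(
                        q, off, search, L, strand, params.min_match_bp,
                        target.circular and strand == "+"):
                    if strand == "-":
                        # map back to plus-strand coordinates
                        p_start = len(plus) - 1 - e_idx
                        p_end = len(plus) - 1 - s_idx
                        if target.circular and p_start >= L:
                            p_start -= L
                            p_end -= L
                        if target.circular and p_start >= L:
                            continue
                    else:
                        p_start, p_end = s_idx, e_idx
                    start1 = p_start % L + 1 if target.circular else p_start + 1
                    end1 = p_end % L + 1 if target.circular else p_end + 1
                    wraps = target.circular and (p_end >= L)
                    key = (entry.trna_id, strand, start1, end1, off)
                    if key in seen:
                        continue
                    seen.add(key)
                    core = q[len(q) - off - length:len(q) - off]
                    out.append(AttCandidate(
                        trna_id=entry.trna_id, target_id=target.id,
                        match_length=length, trna_end_offset=off,
                        target_start=start1, target_end=end1,
                        target_strand=strand, target_wraps=wraps,
                        core_sequence=core))
    out = [replace(c, expect_score=score_candidate(c, target, params))
           for c in out]
    out.sort(key=lambda c: (c.expect_score, c.target_start, c.trna_id))
    return out


def target_composition(target: AnnotatedReplicon) -> dict:
    """Mononucleotide frequencies of the target (Ns excluded)."""
    counts = Counter(b for b in target.sequence if b in "ACGT")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("target has no unambiguous bases")
    return {b: counts[b] / total for b in "ACGT"}


def score_candidate(candidate: AttCandidate, target: AnnotatedReplicon,
                    params: AttScanParams = AttScanParams()) -> float:
    """Expected count of equal-or-longer exact matches of the core under a
    mononucleotide null: S * L * prod(p(b)), S = 2 when both strands are
    searched."""
    if not candidate.core_sequence:
        raise ValueError("empty core sequence")
    p = target_composition(target)
    s = 2.0 if params.search_both_strands else 1.0
    e = s * target.length
    for b in candidate.core_sequence:
        e *= p.get(b, 0.0)
    return e


def filter_candidates(candidates, annotation: AnnotatedReplicon,
                      gi_intervals=None,
                      params: AttScanParams = AttScanParams()) -> list:
    """Set the intergenic / genomic-island flags and optionally drop
    candidates that overlap a CDS or tRNA feature.

    ``gi_intervals`` are 1-based inclusive ``(chrom, start, end)`` tuples
    (e.g. from :func:`imescan.seqio.read_bed`); intervals on a different
    molecule id trigger a warning and leave the flag False.
    """
    n = annotation.length
    genic = [f for f in annotation.features if f.kind in ("CDS", "tRNA")]
    gi = []
    for iv in gi_intervals or []:
        chrom, s, e = iv
        if chrom != annotation.id:
            warnings.warn(
                f"genomic-island interval on {chrom!r} does not match "
                f"molecule {annotation.id!r}; ignored")
            continue
        gi.append((s, e))
    out = []
    for c in candidates:
        hit_genic = any(interval_overlaps(
            c.target_start, c.target_end, c.target_wraps,
            f.start, f.end, f.wraps, n) for f in genic)
        hit_gi = any(interval_overlaps(
            c.target_start, c.target_end, c.target_wraps, s, e, False, n)
            for s, e in gi)
        c = replace(c, intergenic=not hit_genic, in_genomic_island=hit_gi)
        if params.intergenic_only and not c.intergenic:
            continue
        out.append(c)
    return out


def trim_to_core(cand: AttCandidate, k: int) -> AttCandidate:
    """Shorten an anchored candidate to its 3'-terminal ``k`` bases.

    Used to reduce an attB/attP pair to their shared core before
    integration (e.g. when the host match covers the whole tRNA gene but
    the element carries only the short core)."""
    if k > cand.match_length:
        raise ValueError("cannot extend a candidate")
    if k == cand.match_length:
        return cand
    if cand.target_wraps:
        raise ValueError("cannot trim a wrapping candidate")
    if cand.target_strand == "+":
        start, end = cand.target_end - k + 1, cand.target_end
    else:
        start, end = cand.target_start, cand.target_start + k - 1
    return replace(cand, match_length=k, target_start=start, target_end=end,
                   core_sequence=cand.core_sequence[-k:])


def shared_core_pairs(element_cands, host_cands, min_core: int = 10) -> list:
    """attP/attB pairs reduced to their longest shared core.

    Both candidate lists must be anchored at tRNA 3' termini; two
    candidates from the same tRNA share the suffix of the shorter match.
    Pairs are returned best (longest core) first.
    """
    pairs = []
    for p in element_cands:
        for h in host_cands:
            if p.trna_id != h.trna_id:
                continue
            k = min(p.match_length, h.match_length)
            if k < min_core:
                continue
            if p.core_sequence[-k:] != h.core_sequence[-k:]:
                continue
            pairs.append((trim_to_core(p, k), trim_to_core(h, k)))
    pairs.sort(key=lambda ph: -ph[0].match_length)
    return pairs


# ---------------------------------------------------------------------------
# Campbell integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegrationResult:
    cointegrate: AnnotatedReplicon
    attL_junction: str
    attR_junction: str
    host_insertion_point: int   # last base of the attB core on the host
    core_sequence: str


def _normalise(rep: AnnotatedReplicon, cand: AttCandidate):
    """Return (sequence, start, end) with the core on the plus strand and no
    wrap (circular molecules are rotated so the core is contiguous)."""
    seq = rep.sequence
    start, end, wraps = cand.target_start, cand.target_end, cand.target_wraps
    n = len(seq)
    if cand.target_strand == "-":
        seq = revcomp(seq)
        start, end = n - end + 1, n - start + 1
        # wrap status is preserved by the reflection
    if wraps:
        if not rep.circular:
            raise ValueError("wrapping core on a linear molecule")
        # rotate so the molecule starts at the core start
        shift = start - 1
        seq = seq[shift:] + seq[:shift]
        k = (n - start + 1) + end
        start, end = 1, k
    return seq, start, end


def integrate(plasmid: AnnotatedReplicon, host: AnnotatedReplicon,
              attP: AttCandidate, attB: AttCandidate,
              flank_bp: int = 50) -> IntegrationResult:
    """Single crossover within the shared core.

    The cointegrate keeps the host in its input orientation; the circular
    plasmid is rotated to begin just after its attP core, so the core is
    duplicated: one copy at the attL junction (host upstream + core +
    plasmid downstream) and one at attR (plasmid upstream + core + host
    downstream).  Total length is conserved.
    """
    if attP.core_sequence != attB.core_sequence:
        raise ValueError("attP and attB cores differ")
    if not plasmid.circular:
        raise ValueError("integration requires a circular element")
    core = attP.core_sequence
    p_seq, p_start, p_end = _normalise(plasmid, attP)
    h_seq, h_start, h_end = _normalise(host, attB)
    P, H = len(p_seq), len(h_seq)

    rotated = p_seq[p_end:] + p_seq[:p_end]       # ends with the attP core
    coint = h_seq[:h_end] + rotated + h_seq[h_end:]
    assert len(coint) == H + P

    def circ(seq, i, ln):
        d = seq + seq
        return d[(i - 1) % len(seq):(i - 1) % len(seq) + ln]

    f = flank_bp
    attL = (h_seq[max(0, h_start - 1 - f):h_end]
            + circ(p_seq, p_end + 1, f))
    attR = (circ(p_seq, p_start - f, min(f, P - len(core)))
            + p_seq[p_start - 1:p_end]
            + h_seq[h_end:h_end + f])
    rep = AnnotatedReplicon(
        id=f"{host.id}::{plasmid.id}", sequence=coint,
        circular=host.circular, features=[])
    return IntegrationResult(rep, attL, attR, host_insertion_point=h_end,
                             core_sequence=core)


def excise(cointegrate: AnnotatedReplicon, core: str):
    """Reverse the crossover at the duplicated cores.

    Returns ``(host_sequence, plasmid_sequence)``; the plasmid comes back as
    a rotation of its original circular sequence.
    """
    seq = cointegrate.sequence
    i = seq.find(core)
    if i == -1:
        raise ValueError("core not found in cointegrate")
    j = seq.find(core, i + 1)
    if j == -1:
        raise ValueError("core occurs only once; nothing to excise")
    a, b = i + len(core), j + len(core)
    host = seq[:a] + seq[b:]
    plasmid = seq[a:b]
    return host, plasmid
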