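"""Inverted/tandem repeat, motif and AT-rich window detection; composite
transposon delineation.

The detectors here serve the structural signatures of small mobilizable
plasmids: iteron arrays and a DnaA box next to an AT-rich window mark the
vegetative origin, a GC-rich hairpin marks oriT, inverted-repeat operators
sit upstream of copG-type regulators, and ~38 bp terminal inverted repeats
of the Tn3 family bound transposable units.

Inverted repeats are found by seed-and-extend.  For ``max_mismatch == 0``
this enumerates exactly the set of maximal pairs (every maximal pair of arm
length >= min_arm contains an exact seed, and extension from any seed inside
a pair converges to the same maximal pair), so the finder provably agrees
with a brute-force oracle.  With mismatches allowed, seeds are shortened by
pigeonhole and extension is greedy; every reported pair still verifies its
own definition, but enumeration is then heuristic rather than exhaustive.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .seqio import AnnotatedReplicon, revcomp

_COMP = str.maketrans("ACGTN", "TGCAN")


def _comp(ch: str) -> str:
    return ch.translate(_COMP)


@dataclass(frozen=True)
class RepeatPair:
    """Two repeat arms; for ``orientation == 'inverted'`` the right arm is the
    reverse complement of the left arm up to ``mismatches`` substitutions."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    arm_length: int
    orientation: str            # 'inverted' or 'direct'
    mismatches: int
    spacer_bp: int


@dataclass(frozen=True)
class IteronArray:
    """A tandem direct-repeat array (>= min_copies adjacent copies)."""

    unit_length: int
    copies: int
    start: int
    consensus: str
    per_copy_mismatches: tuple

    @property
    def end(self) -> int:
        return self.start + self.unit_length * self.copies - 1


@dataclass(frozen=True)
class RepeatCopy:
    """One located copy of a terminal-repeat seed."""

    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class TransposonCall:
    """A transposable unit bounded by oppositely oriented repeat copies."""

    unit_start: int
    unit_end: int
    terminal_repeat_copies: tuple   # RepeatCopy tuple (the bounding pair first)
    cargo_features: tuple           # labels of features between the bounds


@dataclass
class TransposonScan:
    """All located terminal-repeat copies plus the delineated units."""

    seed: str
    copies: list = field(default_factory=list)
    units: list = field(default_factory=list)


def shannon_entropy(s: str) -> float:
    """Shannon entropy in bits/symbol; the low-complexity guard."""
    if not s:
        return 0.0
    counts = Counter(s)
    n = len(s)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def _scan_sequence(replicon: AnnotatedReplicon, margin: int):
    """Return (working sequence, molecule length); circular molecules are
    doubled up to ``margin`` extra bases so features may wrap."""
    n = replicon.length
    if replicon.circular:
        return replicon.sequence + replicon.sequence[:min(margin, n)], n
    return replicon.sequence, n


# ---------------------------------------------------------------------------
# Inverted repeats
# ---------------------------------------------------------------------------

def _seed_positions(s: str, k: int) -> dict:
    index = {}
    for i in range(len(s) - k + 1):
        kmer = s[i:i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    return index


def _extend_exact(s: str, i: int, j: int, k: int):
    """Extend an exact seed (left arm [i, i+k), right arm ending at j+k-1
    pairing antiparallel) to the maximal run on its anti-diagonal."""
    t, u = i - 1, j + k
    while t >= 0 and u < len(s) and s[t] == _comp(s[u]) and s[t] != "N":
        t -= 1
        u += 1
    t2, u2 = i + k, j - 1
    while t2 < u2 and s[t2] == _comp(s[u2]) and s[t2] != "N":
        t2 += 1
        u2 -= 1
    return t + 1, t2 - 1, u2 + 1, u - 1   # left arm, right arm (0-based incl.)


def _extend_mismatch(s: str, i: int, j: int, k: int, budget: int):
    """Greedy extension with a shared mismatch budget; arms never start or
    end on a mismatch.  Returns (l1, l2, r1, r2, mismatches)."""
    mm = sum(1 for t in range(k) if s[i + t] != _comp(s[j + k - 1 - t]))
    if mm > budget:
        return None
    pairs = [(i + t, j + k - 1 - t) for t in range(k)]
    # outward
    t, u = i - 1, j + k
    while t >= 0 and u < len(s):
        match = s[t] == _comp(s[u]) and s[t] != "N"
        if not match and mm >= budget:
            break
        if not match:
            mm += 1
        pairs.insert(0, (t, u))
        t -= 1
        u += 1
    # inward
    t2, u2 = i + k, j - 1
    while t2 < u2:
        match = s[t2] == _comp(s[u2]) and s[t2] != "N"
        if not match and mm >= budget:
            break
        if not match:
            mm += 1
        pairs.append((t2, u2))
        t2 += 1
        u2 -= 1
    # trim terminal mismatches
    while pairs and s[pairs[0][0]] != _comp(s[pairs[0][1]]):
        pairs.pop(0)
        mm -= 1
    while pairs and s[pairs[-1][0]] != _comp(s[pairs[-1][1]]):
        pairs.pop()
        mm -= 1
    if not pairs:
        return None
    l1, r2 = pairs[0]
    l2, r1 = pairs[-1]
    return l1, l2, r1, r2, mm


def find_inverted_repeats(replicon: AnnotatedReplicon, min_arm: int = 8,
                          max_spacer: int = 100, max_mismatch: int = 0,
                          min_spacer: int = 0) -> list:
    """All maximal inverted-repeat pairs with arm >= ``min_arm`` and spacer
    in [min_spacer, max_spacer], circularly aware.

    Nested and overlapping pairs are all reported.  Results are sorted by
    (left_start, arm length).
    """
    if min_arm < 4:
        raise ValueError("min_arm must be >= 4")
    s, n = _scan_sequence(replicon, 2 * n_margin(replicon, min_arm, max_spacer))
    k = min_arm if max_mismatch == 0 else max(4, min_arm // (max_mismatch + 1))
    index = _seed_positions(s, k)
    found = {}
    for i in range(len(s) - k + 1):
        seed = s[i:i + k]
        if "N" in seed:
            continue
        for j in index.get(revcomp(seed), ()):  # right arm start candidates
            if j < i:
                continue
            if max_mismatch == 0:
                l1, l2, r1, r2 = _extend_exact(s, i, j, k)
                mm = 0
            else:
                ext = _extend_mismatch(s, i, j, k, max_mismatch)
                if ext is None:
                    continue
                l1, l2, r1, r2, mm = ext
            arm = l2 - l1 + 1
            spacer = r1 - l2 - 1
            if arm < min_arm or spacer < min_spacer or spacer > max_spacer:
                continue
            if replicon.circular:
                if l1 >= n or (r2 - l1 + 1) > n:
                    continue
            found[(l1, r2)] = (l1, l2, r1, r2, arm, mm, spacer)
    out = [RepeatPair(l1 + 1, l2 + 1, r1 + 1, r2 + 1, arm, "inverted", mm, sp)
           for (l1, l2, r1, r2, arm, mm, sp) in found.values()]
    out.sort(key=lambda p: (p.left_start, p.arm_length, p.right_start))
    return out


def n_margin(replicon, min_arm, max_spacer):
    # how far past the origin a wrapping pair can reach
    return min(replicon.length, max_spacer + 4 * max(min_arm, 64))


def rank_hairpins(pairs) -> list:
    """Order hairpin candidates the way oriT calls are reported.

    Overlapping alternatives are clustered; within a cluster the
    minimal-spacer pair ranks first, and clusters are ordered by their
    representative's arm length (longest first)."""
    pairs = sorted(pairs, key=lambda p: (p.spacer_bp, -p.arm_length,
                                         p.left_start))
    clusters = []
    for p in pairs:
        for cl in clusters:
            q = cl[0]
            if p.left_start <= q.right_end and q.left_start <= p.right_end:
                cl.append(p)
                break
        else:
            clusters.append([p])
    clusters.sort(key=lambda cl: (-cl[0].arm_length, cl[0].spacer_bp,
                                  cl[0].left_start))
    return [p for cl in clusters for p in cl]


# ---------------------------------------------------------------------------
# Tandem direct repeats (iterons)
# ---------------------------------------------------------------------------

def _consensus(copies) -> str:
    cols = zip(*copies)
    return "".join(Counter(col).most_common(1)[0][0] for col in cols)


def find_iterons(replicon: AnnotatedReplicon, unit_min: int = 15,
                 unit_max: int = 25, min_copies: int = 3,
                 max_mismatch_per_copy: int = 1,
                 entropy_min_bits: float = 1.0) -> list:
    """Tandem arrays of a unit in [unit_min, unit_max] with >= min_copies
    adjacent copies, each copy within ``max_mismatch_per_copy`` substitutions
    of the per-column majority consensus.

    Overlapping reports (e.g. the same array seen at unit length u and 2u)
    are merged to the longest span; low-complexity units (entropy below
    ``entropy_min_bits``) are suppressed.
    """
    if unit_min < 5:
        raise ValueError("unit_min must be >= 5")
    if min_copies < 3:
        raise ValueError("min_copies must be >= 3")
    s, n = _scan_sequence(replicon, unit_max * 12)
    m = len(s)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    candidates = []
    for u in range(unit_min, unit_max + 1):
        if m <= u:
            continue
        match = (arr[:-u] == arr[u:]) & (arr[:-u] != ord("N"))
        i = 0
        while i < len(match):
            if not match[i]:
                i += 1
                continue
            # greedy run allowing the per-copy budget chunk by chunk
            j = i
            mismatch_in_chunk = 0
            chunk_pos = 0
            end = i
            while j < len(match):
                if not match[j]:
                    mismatch_in_chunk += 1
                    if mismatch_in_chunk > max_mismatch_per_copy:
                        break
                chunk_pos += 1
                if match[j]:
                    end = j
                if chunk_pos == u:
                    chunk_pos = 0
                    mismatch_in_chunk = 0
                j += 1
            run_len = end - i + 1
            copies = run_len // u + 1
            if copies >= min_copies:
                candidates.append((i, u, copies))
            # resume after the first mismatch inside/after this run, so a
            # cleaner array hidden behind a lucky leading match is still seen
            nf = i + 1
            while nf < len(match) and match[nf]:
                nf += 1
            i = nf + 1
    arrays = []
    for i, u, copies in candidates:
        segs = [s[i + c * u:i + (c + 1) * u] for c in range(copies)]
        cons = _consensus(segs)
        mms = tuple(sum(a != b for a, b in zip(seg, cons)) for seg in segs)
        while copies > 1 and mms[-1] > max_mismatch_per_copy:
            copies -= 1
            segs = segs[:-1]
            cons = _consensus(segs)
            mms = tuple(sum(a != b for a, b in zip(seg, cons)) for seg in segs)
        if copies < min_copies or any(x > max_mismatch_per_copy for x in mms):
            continue
        if shannon_entropy(cons) < entropy_min_bits:
            continue
        if replicon.circular and (i >= n or copies * u > n):
            continue
        arrays.append(IteronArray(u, copies, i + 1, cons, mms))
    # merge overlapping reports: longest span first, then the cleanest
    # (fewest total mismatches), then the smaller unit
    arrays.sort(key=lambda a: (-(a.end - a.start + 1),
                               sum(a.per_copy_mismatches),
                               a.unit_length, a.start))
    kept = []
    for a in arrays:
        s_a, e_a = a.start, a.end
        if any(s_a <= k.end and k.start <= e_a for k in kept):
            continue
        kept.append(a)
    kept.sort(key=lambda a: a.start)
    return kept


# ---------------------------------------------------------------------------
# Motifs and AT-rich windows
# ---------------------------------------------------------------------------

def find_motif(replicon: AnnotatedReplicon, motif: str, max_mismatch: int = 1):
    """All occurrences of ``motif`` on both strands with at most
    ``max_mismatch`` substitutions (N never matches).

    Returns a sorted list of ``(position, strand, mismatches)``; the
    position is the 1-based plus-strand start of the window.
    """
    motif = motif.upper()
    if len(motif) < 6:
        raise ValueError("motif length must be >= 6")
    s, n = _scan_sequence(replicon, len(motif) - 1)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    m = len(motif)
    if len(arr) < m:
        return []
    win = np.lib.stride_tricks.sliding_window_view(arr, m)
    is_n = win == ord("N")
    hits = []
    for strand, pat in (("+", motif), ("-", revcomp(motif))):
        pat_a = np.frombuffer(pat.encode(), dtype=np.uint8)
        mm = ((win != pat_a) | is_n).sum(axis=1)
        for i in np.nonzero(mm <= max_mismatch)[0]:
            if i < n:
                hits.append((int(i) + 1, strand, int(mm[i])))
    hits.sort()
    return hits


def find_at_rich(replicon: AnnotatedReplicon, window_bp: int = 50,
                 min_at_fraction: float = 0.8) -> list:
    """Maximal merged intervals of windows whose A+T fraction is at least
    ``min_at_fraction`` (Ns count toward neither)."""
    if window_bp < 20:
        raise ValueError("window_bp must be >= 20")
    s, n = _scan_sequence(replicon, window_bp - 1)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    at = ((arr == ord("A")) | (arr == ord("T"))).astype(float)
    if len(at) < window_bp:
        return []
    frac = np.convolve(at, np.ones(window_bp), mode="valid") / window_bp
    ok = np.nonzero(frac >= min_at_fraction)[0]
    ok = ok[ok < n]
    if len(ok) == 0:
        return []
    intervals = []
    start = prev = int(ok[0])
    for i in map(int, ok[1:]):
        if i <= prev + window_bp:   # windows overlap or touch: merge
            prev = i
        else:
            intervals.append((start + 1, prev + window_bp))
            start = prev = i
    intervals.append((start + 1, prev + window_bp))
    # fold wrap-overs back and clamp to the molecule
    out = []
    for s1, e1 in intervals:
        if e1 >= s1 + n - 1:
            return [(1, n)]
        out.append((s1, e1 if e1 <= n or not replicon.circular else e1 - n))
    return out


# ---------------------------------------------------------------------------
# Composite transposons
# ---------------------------------------------------------------------------

def locate_repeat_copies(replicon: AnnotatedReplicon, seed: str,
                         min_copy_identity: float = 0.9) -> list:
    """All copies of ``seed`` on either strand at the given identity."""
    max_mm = int(len(seed) * (1.0 - min_copy_identity))
    hits = find_motif(replicon, seed, max_mm)
    copies = {}
    for pos, strand, mm in hits:
        prev = copies.get(pos)
        if prev is None or mm < prev.mismatches:
            end = pos + len(seed) - 1
            n = replicon.length
            if replicon.circular and end > n:
                end -= n
            copies[pos] = RepeatCopy(pos, end, strand, mm)
    return [copies[p] for p in sorted(copies)]


def delineate_transposon(replicon: AnnotatedReplicon,
                         repeat_seed: str | None = None,
                         min_copy_identity: float = 0.9,
                         min_seed_arm: int = 25) -> TransposonScan:
    """Locate terminal-repeat copies and call transposable units.

    A unit is the span between two oppositely oriented copies (inclusive of
    the repeats), because Tn3-family ends are inverted relative to each
    other; with three copies this yields the nested outer and inner units of
    a composite element.  Without a supplied seed, candidate seeds are the
    arms of long inverted-repeat pairs found de novo.
    """
    if repeat_seed is not None:
        if len(repeat_seed) < 20:
            raise ValueError("repeat_seed must be >= 20 bp")
        seeds = [repeat_seed.upper()]
    else:
        pairs = find_inverted_repeats(replicon, min_arm=min_seed_arm,
                                      max_spacer=replicon.length,
                                      max_mismatch=0)
        pairs.sort(key=lambda p: -p.arm_length)
        seeds = [replicon.sequence[p.left_start - 1:p.left_end] for p in pairs[:3]]
    best = TransposonScan(seed="")
    for seed in seeds:
        copies = locate_repeat_copies(replicon, seed, min_copy_identity)
        units = []
        for a in range(len(copies)):
            for b in range(a + 1, len(copies)):
                ci, cj = copies[a], copies[b]
                if ci.strand == cj.strand:
                    continue
                inside = [f.label() for f in replicon.features
                          if ci.end < f.start and f.end < cj.start]
                units.append(TransposonCall(
                    unit_start=ci.start, unit_end=cj.end,
                    terminal_repeat_copies=(ci, cj),
                    cargo_features=tuple(inside)))
        units.sort(key=lambda u: -(u.unit_end - u.unit_start))
        scan = TransposonScan(seed=seed, copies=copies, units=units)
        if (len(scan.units), len(scan.copies)) > (len(best.units), len(best.copies)):
            best = scan
    return best
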