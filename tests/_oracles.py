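"""Independent brute-force oracles used by the property and acceptance tests.

Each oracle takes a different computational route from the implementation it
checks: doubled-string slicing for circular extraction, suffix-by-suffix
comparison for anchored matching, a labelled comparison matrix for inverted
repeats, and start-codon-forward scanning for ORFs.
"""

import numpy as np
from scipy import ndimage

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s):
    return s.translate(COMP)[::-1]


def subsequence_oracle(seq, circular, start, length, strand="+"):
    doubled = seq * 2 if circular else seq
    seg = doubled[start - 1:start - 1 + length]
    if len(seg) < length:
        raise IndexError("past the end of a linear molecule")
    return rc(seg) if strand == "-" else seg


def anchored_matches_oracle(query, target, min_match, circular=False):
    """All maximal exact matches of a suffix of ``query`` anchored at its 3'
    end, by longest-common-suffix comparison at every target end position.

    Returns a set of (strand, target_start, target_end, length) in 1-based
    plus-strand coordinates (wrapped modulo the length when circular).
    """
    L = len(target)
    out = set()
    for strand in "+-":
        t = target if strand == "+" else rc(target)
        work = t * 2 if circular else t
        limit = 2 * L if circular else L
        for end in range(limit):
            length = 0
            while (length < len(query) and end - length >= 0
                   and work[end - length] == query[-1 - length]
                   and work[end - length] != "N"):
                length += 1
            if length < min_match:
                continue
            s_idx, e_idx = end - length + 1, end
            if circular and s_idx >= L:
                continue
            if strand == "-":
                s_idx, e_idx = limit - 1 - e_idx, limit - 1 - s_idx
                if circular and s_idx >= L:
                    s_idx, e_idx = s_idx - L, e_idx - L
                if circular and s_idx >= L:
                    continue
            if circular:
                out.add((strand, s_idx % L + 1, e_idx % L + 1, length))
            else:
                out.add((strand, s_idx + 1, e_idx + 1, length))
    return out


def inverted_repeats_oracle(seq, min_arm, max_spacer, min_spacer=0):
    """All maximal exact inverted-repeat pairs of a linear sequence, found
    by labelling anti-diagonal runs of the base-complement comparison
    matrix.  Returns a set of (left_start, left_end, right_start, right_end)
    1-based tuples."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGT", b"TGCA"):
        comp[x] = y
    m = (a[:, None] == comp[a][None, :])
    m &= a[:, None] != ord("N")
    m &= a[None, :] != ord("N")
    m &= np.triu(np.ones_like(m), k=1).astype(bool)
    structure = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]])
    labels, n_lab = ndimage.label(m, structure=structure)
    out = set()
    for sl in ndimage.find_objects(labels):
        i0, i1 = sl[0].start, sl[0].stop - 1
        j0, j1 = sl[1].start, sl[1].stop - 1
        arm = i1 - i0 + 1
        spacer = j0 - i1 - 1
        if arm >= min_arm and min_spacer <= spacer <= max_spacer:
            out.add((i0 + 1, i1 + 1, j0 + 1, j1 + 1))
    return out


def orf_oracle(seq, circular, min_length_aa,
               start_codons=("ATG", "GTG", "TTG"),
               stop_codons=("TAA", "TAG", "TGA")):
    """Start-forward brute force: from every start codon, read to the first
    in-frame stop; keep the longest reading per (stop, strand).  Returns a
    set of (start, end, strand, wraps)."""
    n = len(seq)
    best = {}
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        work = s * 2 if circular else s
        for i in range(len(work) - 2):
            if work[i:i + 3] not in start_codons:
                continue
            j = i + 3
            stop = None
            while j + 3 <= len(work) and j - i <= n:
                codon = work[j:j + 3]
                if codon in stop_codons:
                    stop = j
                    break
                j += 3
            if stop is None:
                continue
            aa = (stop - i) // 3
            if aa < min_length_aa:
                continue
            e0 = stop + 2
            if e0 - i + 1 > n or (circular and i >= n):
                continue
            if strand == "+":
                g_start, g_end = i, e0
            else:
                g_start = len(work) - 1 - e0
                g_end = g_start + (e0 - i)
                if circular:
                    g_start %= n
                    g_end = g_start + (e0 - i)
            wraps = circular and g_end >= n
            g_end_mod = g_end % n if circular else g_end
            # one ORF per stop codon: the stop is at the right (genomic) end
            # on the plus strand and at the left end on the minus strand
            stop_pos = g_end_mod if strand == "+" else g_start
            key = (stop_pos, strand)
            span = e0 - i + 1
            if key not in best or span > best[key][1]:
                best[key] = ((g_start + 1, g_end_mod + 1, strand, wraps), span)
    return {v[0] for v in best.values()}


def motif_oracle(seq, circular, motif, max_mismatch):
    """Position-by-position scan for a motif on both strands."""
    n = len(seq)
    work = seq + seq[:len(motif) - 1] if circular else seq
    out = []
    for strand, pat in (("+", motif), ("-", rc(motif))):
        for i in range(min(n, len(work) - len(pat) + 1)):
            window = work[i:i + len(pat)]
            mm = sum(1 for x, y in zip(window, pat) if x != y or x == "N")
            if mm <= max_mismatch:
                out.append((i + 1, strand, mm))
    return sorted(out)
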