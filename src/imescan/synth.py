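"""Truth-labelled synthetic replicons.

The generator emulates the architecture the detectors assume: a ~37 kb
circular plasmid whose two replichore arms carry opposite GC skew, an oriV
block (tandem iterons + DnaA box + AT-rich window) at the skew minimum, a
GC-rich oriT hairpin, an att core placed in an intergenic gap, three copies
of a 38 bp terminal repeat delimiting a nested composite transposon, and
background CDS features giving roughly 90 % coding density.  A companion
host molecule carries one tRNA gene whose 3' terminus ends in the plasmid's
att core.  The background model is i.i.d. with a position-dependent G<->C
bias realising the skew arms; all randomness flows from one seed.

Every planted element is recorded in a :class:`SyntheticTruth` table whose
intervals re-extract to their payloads exactly, so recovery tests need no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .seqio import AnnotatedReplicon, Feature, make_feature, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SpecError(ValueError):
    """Raised when planted elements collide or fall outside the molecule."""


_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_a] = _b


def _force_diff(arr: np.ndarray, idx: int, forbidden: int) -> None:
    """Ensure ``arr[idx] != forbidden`` by a deterministic substitution."""
    if arr[idx] == forbidden:
        arr[idx] = ord("A") if forbidden != ord("A") else ord("C")


@dataclass(frozen=True)
class PlasmidSpec:
    """Layout and statistics of the synthetic plasmid (all bp, 1-based)."""

    length_bp: int = 37_000
    gc_percent: float = 62.0
    skew_amplitude: float = 0.3
    ori_position: int = 19_000
    ter_position: int = 500
    iteron_unit_bp: int = 21
    iteron_copies: int = 4
    iteron_start: int = 19_100
    dnaa_box: str = "TTATCCACA"
    dnaa_position: int = 19_240
    at_rich_bp: int = 80
    at_rich_start: int = 19_320
    at_rich_fraction: float = 0.85
    orit_start: int = 34_900
    hairpin_arm_bp: int = 12
    hairpin_loop_bp: int = 6
    att_core_bp: int = 14
    att_position: int = 27_000
    terminal_repeat_bp: int = 38
    terminal_repeat_positions: tuple = (2_000, 6_000, 13_000)
    terminal_repeat_strands: tuple = ("+", "+", "-")
    cds_len_range: tuple = (600, 1500)
    cds_gap_range: tuple = (40, 120)
    element_margin_bp: int = 25
    seed: int = 0


@dataclass(frozen=True)
class TruthEntry:
    kind: str
    start: int
    end: int
    strand: str
    payload: str   # plus-strand sequence of the interval ('' for landmarks)


@dataclass
class SyntheticTruth:
    entries: list = field(default_factory=list)

    def by_kind(self, kind: str) -> list:
        return [e for e in self.entries if e.kind == kind]

    def one(self, kind: str) -> TruthEntry:
        hits = self.by_kind(kind)
        if len(hits) != 1:
            raise KeyError(f"{len(hits)} truth entries of kind {kind!r}")
        return hits[0]


def _random_seq(rng, length: int, gc: float) -> str:
    g = gc / 2.0
    probs = [(1 - gc) / 2, g, g, (1 - gc) / 2]
    return bytes(_BASES[rng.choice(4, size=length, p=probs)]).decode()


def _planted_intervals(spec: PlasmidSpec) -> list:
    iv = [("iteron_array", spec.iteron_start,
           spec.iteron_start + spec.iteron_unit_bp * spec.iteron_copies - 1),
          ("dnaa_box", spec.dnaa_position,
           spec.dnaa_position + len(spec.dnaa_box) - 1),
          ("at_rich", spec.at_rich_start,
           spec.at_rich_start + spec.at_rich_bp - 1),
          ("orit_hairpin", spec.orit_start,
           spec.orit_start + 2 * spec.hairpin_arm_bp + spec.hairpin_loop_bp - 1),
          ("att_core", spec.att_position,
           spec.att_position + spec.att_core_bp - 1)]
    for idx, (pos, strand) in enumerate(zip(spec.terminal_repeat_positions,
                                            spec.terminal_repeat_strands)):
        iv.append((f"terminal_repeat_{idx}", pos,
                   pos + spec.terminal_repeat_bp - 1))
    return iv


def _validate_spec(spec: PlasmidSpec) -> list:
    iv = _planted_intervals(spec)
    collisions = []
    m = spec.element_margin_bp
    for name, s, e in iv:
        if not (1 <= s <= e <= spec.length_bp):
            collisions.append(f"{name} {s}..{e} outside [1, {spec.length_bp}]")
    padded = sorted((s - m, e + m, name) for name, s, e in iv)
    for (s1, e1, n1), (s2, e2, n2) in zip(padded, padded[1:]):
        if s2 <= e1:
            collisions.append(f"{n1} and {n2} collide (margin {m} bp)")
    if collisions:
        raise SpecError("infeasible packing: " + "; ".join(collisions))
    return iv


def _background(rng, spec: PlasmidSpec) -> np.ndarray:
    """i.i.d. background with the G<->C bias switching sign at ori/ter."""
    n = spec.length_bp
    g = spec.gc_percent / 100.0
    amp = spec.skew_amplitude
    pos = np.arange(n)
    ori0, ter0 = spec.ori_position - 1, spec.ter_position - 1
    on_leading = ((pos - ori0) % n) < ((ter0 - ori0) % n)
    sign = np.where(on_leading, 1.0, -1.0)
    p_g = g / 2 * (1 + sign * amp)
    p_c = g / 2 * (1 - sign * amp)
    p_a = np.full(n, (1 - g) / 2)
    cum = np.cumsum(np.stack([p_a, p_c, p_g], axis=1), axis=1)  # A,C,G,(T)
    u = rng.random(n)
    idx = (u[:, None] >= cum).sum(axis=1)      # 0=A,1=C,2=G,3=T
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[idx].copy()


def _tile_cds(rng, spec: PlasmidSpec, reserved: list) -> list:
    """CDS features tiled into the stretches between reserved windows."""
    m = spec.element_margin_bp
    res = sorted((max(1, s - m), min(spec.length_bp, e + m))
                 for _, s, e in reserved)
    feats = []
    cursor, idx, counter = 1, 0, 0
    lo_len, hi_len = spec.cds_len_range
    lo_gap, hi_gap = spec.cds_gap_range
    while cursor < spec.length_bp:
        while idx < len(res) and res[idx][1] < cursor:
            idx += 1
        if idx < len(res) and res[idx][0] <= cursor:
            cursor = res[idx][1] + 1
            continue
        avail_end = res[idx][0] - 1 if idx < len(res) else spec.length_bp
        block = int(rng.integers(lo_len, hi_len + 1))
        gap = int(rng.integers(lo_gap, hi_gap + 1))
        end = min(cursor + block - 1, avail_end)
        if end - cursor + 1 >= 300:
            counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            feats.append(make_feature(
                "CDS", cursor, end, strand,
                {"locus_tag": f"SYN_{counter:03d}",
                 "product": "hypothetical protein"}))
            cursor = end + gap + 1
        else:
            cursor = (res[idx][1] + 1) if idx < len(res) else spec.length_bp + 1
    return feats


def _relabel_nearest_cds(features: list, position: int, product: str) -> None:
    """Give the CDS nearest (left of) ``position`` a descriptive product."""
    best, best_d = None, None
    for i, f in enumerate(features):
        if f.kind != "CDS" or f.end >= position:
            continue
        d = position - f.end
        if best_d is None or d < best_d:
            best, best_d = i, d
    if best is not None:
        f = features[best]
        quals = dict(f.qualifiers)
        quals["product"] = product
        features[best] = make_feature(f.kind, f.start, f.end, f.strand, quals)


def make_plasmid(spec: PlasmidSpec = PlasmidSpec()):
    """Generate the synthetic plasmid; returns (replicon, truth).

    Deterministic given ``spec.seed``.  Raises :class:`SpecError` when the
    planted elements collide or leave the molecule.
    """
    planted = _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    for _attempt in range(8):
        arr = _background(rng, spec)
        gc = spec.gc_percent / 100.0

        iteron_unit = _random_seq(rng, spec.iteron_unit_bp, gc)
        iterons = iteron_unit * spec.iteron_copies
        at_rich = _random_seq(rng, spec.at_rich_bp, 1 - spec.at_rich_fraction)
        arm = _random_seq(rng, spec.hairpin_arm_bp, 0.8)
        loop = _random_seq(rng, spec.hairpin_loop_bp, gc)
        if loop[0] == revcomp(loop[-1]):
            # forbid inward extension of the hairpin arms into the loop
            loop = ("A" if loop[-1] != "T" else "C") + loop[1:]
        hairpin = arm + loop + revcomp(arm)
        att_core = _random_seq(rng, spec.att_core_bp, gc)
        term_repeat = _random_seq(rng, spec.terminal_repeat_bp, gc)

        payloads = {"iteron_array": iterons, "dnaa_box": spec.dnaa_box,
                    "at_rich": at_rich, "orit_hairpin": hairpin,
                    "att_core": att_core}
        for idx, strand in enumerate(spec.terminal_repeat_strands):
            payloads[f"terminal_repeat_{idx}"] = (
                term_repeat if strand == "+" else revcomp(term_repeat))
        for name, s, _e in planted:
            pl = payloads[name]
            arr[s - 1:s - 1 + len(pl)] = np.frombuffer(pl.encode(), np.uint8)
        # pin the bases flanking the exact-coordinate elements so background
        # luck cannot extend them beyond their truth spans
        u = spec.iteron_unit_bp
        s0 = spec.iteron_start - 1
        e0 = s0 + spec.iteron_copies * u        # first base after the array
        _force_diff(arr, s0 - 1, arr[s0 - 1 + u])
        _force_diff(arr, e0, arr[e0 - u])
        hs = spec.orit_start - 1
        he = hs + 2 * spec.hairpin_arm_bp + spec.hairpin_loop_bp - 1
        _force_diff(arr, hs - 1, _COMP_LUT[arr[he + 1]])
        seq = bytes(arr).decode()
        double = seq + seq[:100]
        unique_ok = (
            _count_both_strands(double, att_core) == 1
            and _count_both_strands(double, term_repeat) == 3
            and _count_both_strands(double, iteron_unit) == spec.iteron_copies
            and _count_both_strands(double, arm) == 2)
        if unique_ok:
            break
    else:
        raise RuntimeError("could not generate collision-free payloads")

    features = _tile_cds(rng, spec, planted)
    _relabel_nearest_cds(features, spec.iteron_start,
                         "replication initiator protein RepA")
    _relabel_nearest_cds(features, spec.att_position,
                         "site-specific integrase")
    _relabel_nearest_cds(features, spec.orit_start, "relaxase MobA")
    _relabel_nearest_cds(features, spec.terminal_repeat_positions[1] + 1,
                         "Tn3 family transposase")

    tr = spec.terminal_repeat_bp
    a, b, c = spec.terminal_repeat_positions
    truth = SyntheticTruth([
        TruthEntry("ori", spec.ori_position, spec.ori_position, "+", ""),
        TruthEntry("ter", spec.ter_position, spec.ter_position, "+", ""),
        TruthEntry("iteron_array", spec.iteron_start,
                   spec.iteron_start + len(iterons) - 1, "+", iterons),
        TruthEntry("iteron_unit", spec.iteron_start,
                   spec.iteron_start + spec.iteron_unit_bp - 1, "+",
                   iteron_unit),
        TruthEntry("dnaa_box", spec.dnaa_position,
                   spec.dnaa_position + len(spec.dnaa_box) - 1, "+",
                   spec.dnaa_box),
        TruthEntry("at_rich", spec.at_rich_start,
                   spec.at_rich_start + spec.at_rich_bp - 1, "+", at_rich),
        TruthEntry("orit_hairpin", spec.orit_start,
                   spec.orit_start + len(hairpin) - 1, "+", hairpin),
        TruthEntry("hairpin_arm", spec.orit_start,
                   spec.orit_start + spec.hairpin_arm_bp - 1, "+", arm),
        TruthEntry("att_core", spec.att_position,
                   spec.att_position + spec.att_core_bp - 1, "+", att_core),
        TruthEntry("terminal_repeat", a, a + tr - 1,
                   spec.terminal_repeat_strands[0], seq[a - 1:a + tr - 1]),
        TruthEntry("terminal_repeat", b, b + tr - 1,
                   spec.terminal_repeat_strands[1], seq[b - 1:b + tr - 1]),
        TruthEntry("terminal_repeat", c, c + tr - 1,
                   spec.terminal_repeat_strands[2], seq[c - 1:c + tr - 1]),
        TruthEntry("terminal_repeat_seed", a, a + tr - 1, "+", term_repeat),
        TruthEntry("transposon_outer", a, c + tr - 1, "+", ""),
        TruthEntry("transposon_inner", b, c + tr - 1, "+", ""),
    ])

    features = features + [
        make_feature("oriV", spec.iteron_start,
                     spec.at_rich_start + spec.at_rich_bp - 1, "+",
                     {"note": "synthetic oriV block"}),
        make_feature("oriT", spec.orit_start,
                      spec.orit_start + len(hairpin) - 1, "+",
                      {"note": "synthetic oriT hairpin"}),
        make_feature("misc", spec.att_position,
                     spec.att_position + spec.att_core_bp - 1, "+",
                     {"note": "attP core"}),
    ] + [
        make_feature("repeat_region", p, p + tr - 1, strand,
                     {"note": f"terminal repeat copy {i}"})
        for i, (p, strand) in enumerate(zip(spec.terminal_repeat_positions,
                                            spec.terminal_repeat_strands))
    ]
    rep = AnnotatedReplicon("synthetic_plasmid", seq, circular=True,
                            features=sorted(features, key=lambda f: f.start))
    return rep, truth


def _count_both_strands(haystack: str, needle: str) -> int:
    total, start = 0, 0
    for pat in {needle, revcomp(needle)}:
        start = 0
        while True:
            i = haystack.find(pat, start)
            if i == -1:
                break
            total += 1
            start = i + 1
    return total


def make_host(attB_core: str, host_length: int = 20_000,
              gc_percent: float = 62.0, trna_sequence: str | None = None,
              trna_position: int | None = None, seed: int = 1,
              avoid_preceding: str | None = None):
    """Generate a host molecule carrying one tRNA whose 3' terminus ends in
    ``attB_core``; returns (replicon, truth).

    ``avoid_preceding`` forbids one base immediately 5' of the core inside
    the tRNA so that an anchored match against another molecule carrying the
    bare core cannot extend past it.
    """
    rng = np.random.default_rng(seed)
    gc = gc_percent / 100.0
    if trna_sequence is None:
        body = _random_seq(rng, 76 - len(attB_core), gc)
        if avoid_preceding and body[-1] == avoid_preceding:
            choices = [b for b in "ACGT" if b != avoid_preceding]
            body = body[:-1] + choices[int(rng.integers(len(choices)))]
        trna_sequence = body + attB_core
    if len(attB_core) > len(trna_sequence):
        raise SpecError("attB core longer than the tRNA gene")
    if not trna_sequence.endswith(attB_core):
        raise SpecError("tRNA sequence does not end with the attB core")
    pos = trna_position or host_length // 2 + 1
    t_end = pos + len(trna_sequence) - 1
    if not 1 <= pos <= t_end <= host_length:
        raise SpecError("tRNA does not fit in the host molecule")

    for _attempt in range(8):
        arr = _background(rng, PlasmidSpec(length_bp=host_length,
                                           gc_percent=gc_percent,
                                           skew_amplitude=0.0,
                                           ori_position=1, ter_position=2))
        arr[pos - 1:t_end] = np.frombuffer(trna_sequence.encode(), np.uint8)
        seq = bytes(arr).decode()
        if _count_both_strands(seq + seq[:60], attB_core) == 1:
            break
    else:
        raise RuntimeError("could not place a unique attB core")

    reserved = [("trna", pos, t_end)]
    spec = PlasmidSpec(length_bp=host_length, seed=seed)
    features = _tile_cds(rng, spec, reserved)
    features.append(make_feature("tRNA", pos, t_end, "+",
                                 {"locus_tag": "HOST_tRNA_1",
                                  "product": "tRNA-Ser"}))
    truth = SyntheticTruth([
        TruthEntry("trna", pos, t_end, "+", trna_sequence),
        TruthEntry("attB_core", t_end - len(attB_core) + 1, t_end, "+",
                   attB_core),
    ])
    rep = AnnotatedReplicon("synthetic_host", seq, circular=True,
                            features=sorted(features, key=lambda f: f.start))
    return rep, truth


def make_pair(spec: PlasmidSpec = PlasmidSpec(), host_length: int = 20_000,
              host_seed: int | None = None):
    """Matched plasmid/host pair sharing one att core.

    The host tRNA is built so its 3' terminus ends in the plasmid's planted
    core and the anchored match cannot extend leftward past the core.
    Returns (plasmid, plasmid_truth, host, host_truth).
    """
    plasmid, p_truth = make_plasmid(spec)
    core = p_truth.one("att_core")
    preceding = plasmid.sequence[core.start - 2]
    host, h_truth = make_host(
        core.payload, host_length=host_length,
        gc_percent=spec.gc_percent,
        seed=spec.seed + 10_000 if host_seed is None else host_seed,
        avoid_preceding=preceding)
    return plasmid, p_truth, host, h_truth
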