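"""Junction (breakpoint) nucleotide calling on satDNA array termini.

The transition from satellite to unrelated sequence is detected with the
windowed-identity rule: the junction region is compared position by
position against a periodic extension of the family consensus anchored on
the terminal monomer hit, and a breakpoint is present where the identity in
10-nt windows drops below 60% and stays there.  Because windows mixing
monomer and flank bases dip below the threshold a few bases before the
true junction, the detected run start only localises the breakpoint; the
reported nucleotide is then refined with a two-segment Bernoulli
changepoint model on the match profile (satellite-like positions match the
consensus with probability ~0.9, background with ~0.25), choosing the
position that maximises the posterior mass within the reporting tolerance.

Breakpoint sides are named in consensus orientation: ``array_start`` is the
junction at the monomer-start-facing terminus, ``array_end`` at the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._dna import revcomp
from .consensus import SatDnaFamily
from .io_formats import GenomicFragment
from .scan import ArrayAnnotation, MonomerHit

SIDES = ("array_start", "array_end")


@dataclass
class SimilarityTrace:
    """Windowed identity profile of a junction segment, in scan order.

    Scan order runs from the array into the flank: left to right for
    ``array_end``, right to left for ``array_start``.  ``values[d]`` is the
    fraction of matching positions in the length-``window`` stretch
    starting at scan index ``d``; ``match[d]`` is the per-position match
    indicator against the phased consensus.
    """

    values: list[float]
    match: list[bool]
    side: str
    segment_start: int
    segment_len: int
    window: int

    def fragment_pos(self, scan_index: int) -> int:
        """Fragment coordinate of a scan-order position index."""
        if self.side == "array_end":
            return self.segment_start + scan_index
        return self.segment_start + (self.segment_len - 1 - scan_index)


@dataclass
class Breakpoint:
    """A junction nucleotide: first non-satellite-like base at an array end."""

    fragment_id: str
    family: str
    side: str
    fragment_pos: int
    consensus_pos: int
    trace: list[float] = field(default_factory=list, repr=False)


@dataclass
class BreakpointEvent:
    """A deduplicated junction: one consensus position/side, with support."""

    consensus_pos: int
    side: str
    support: int
    members: list[Breakpoint] = field(default_factory=list, repr=False)


@dataclass
class BreakpointSet:
    family: str
    breakpoints: list[Breakpoint]
    deduplicated: bool = False
    events: list[BreakpointEvent] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


def similarity_trace(
    segment: str,
    family: SatDnaFamily,
    phase0: int,
    side: str,
    window: int = 10,
    segment_start: int = 0,
) -> SimilarityTrace:
    """Windowed identity of ``segment`` against the phased consensus.

    ``phase0`` is the consensus position paired with ``segment[0]``; the
    comparison extends the consensus periodically (ungapped), which equals
    the alignment-column profile when the monomers carry no indels.
    """
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    if len(segment) < window:
        raise ValueError(
            f"segment length {len(segment)} is shorter than window {window}"
        )
    L = family.length
    cons = family.consensus
    match_fragment = [
        segment[i] == cons[(phase0 + i) % L] for i in range(len(segment))
    ]
    match = match_fragment if side == "array_end" else match_fragment[::-1]
    arr = np.asarray(match, dtype=float)
    values = np.convolve(arr, np.ones(window) / window, mode="valid")
    return SimilarityTrace(
        values=[float(v) for v in values],
        match=match,
        side=side,
        segment_start=segment_start,
        segment_len=len(segment),
        window=window,
    )


def call_breakpoint(
    trace: SimilarityTrace | list[float],
    threshold: float = 0.6,
    min_stretch: int = 10,
) -> int | None:
    """Detect the sub-threshold run start in scan order.

    Returns the first scan index whose windowed identity is below
    ``threshold`` and which starts a run of at least ``min_stretch``
    consecutive sub-threshold windows; None if the identity never drops
    that persistently (no breakpoint: gradual or absent transition).
    """
    values = trace.values if isinstance(trace, SimilarityTrace) else list(trace)
    n = len(values)
    run = 0
    # scan backwards so run lengths are known at each start
    starts = [False] * n
    for d in range(n - 1, -1, -1):
        run = run + 1 if values[d] < threshold else 0
        starts[d] = run >= min_stretch
    for d in range(n):
        if starts[d]:
            return d
    return None


def _posterior_changepoint(
    match,
    lo: int,
    hi: int,
    p_sat: float,
    p_bg: float,
    radius: int,
) -> int:
    """Two-segment Bernoulli changepoint on a satellite->background profile.

    ``match`` is ordered from the satellite side into the flank; candidate
    changepoints (number of leading satellite-like positions) range over
    [lo, hi].  Returns the candidate maximising the posterior mass within
    ``radius`` positions — the estimator matched to a +-radius reporting
    tolerance rather than the point maximum.
    """
    w_match = math.log(p_sat / p_bg)
    w_mismatch = math.log((1 - p_sat) / (1 - p_bg))
    m = np.asarray(match, dtype=bool)
    w = np.where(m, w_match, w_mismatch)
    pref = np.concatenate([[0.0], np.cumsum(w)])
    cand = np.arange(max(0, lo), min(len(m), hi) + 1)
    loglik = pref[cand]  # two-segment loglik up to an additive constant
    post = np.exp(loglik - loglik.max())
    best_mass, best = -1.0, int(cand[0])
    for j, c in enumerate(cand):
        mass = post[max(0, j - radius) : j + radius + 1].sum()
        if mass > best_mass:
            best_mass, best = float(mass), int(c)
    return best


def refine_breakpoint(
    trace: SimilarityTrace,
    run_start: int,
    p_sat: float = 0.9,
    p_bg: float = 0.25,
    halo: int = 20,
    radius: int = 3,
) -> int:
    """Refine the breakpoint nucleotide near a detected run start.

    Fits a two-segment Bernoulli changepoint to the match profile
    (satellite-like positions match with probability ~``p_sat``,
    background with ~``p_bg``) and returns the scan index of the first
    background position, choosing the changepoint that maximises the
    posterior mass within ``radius`` positions.
    """
    return _posterior_changepoint(
        trace.match,
        run_start - halo,
        run_start + halo + trace.window,
        p_sat,
        p_bg,
        radius,
    )


def map_to_consensus(
    fragment_pos: int,
    hit: MonomerHit,
    L: int,
    max_extrapolation: int | None = None,
) -> int:
    """Map a fragment position onto consensus coordinates via an anchoring hit.

    Assumes an ungapped correspondence through the hit: for plus-strand
    hits consensus position cstart pairs with fragment position start; for
    minus-strand hits fragment position start pairs with consensus
    position cend - 1.
    """
    if max_extrapolation is None:
        max_extrapolation = 2 * L
    if not (hit.start - max_extrapolation <= fragment_pos < hit.end + max_extrapolation):
        raise ValueError(
            f"fragment position {fragment_pos} too far outside hit "
            f"[{hit.start},{hit.end})"
        )
    offset = fragment_pos - hit.start
    if hit.strand == "+":
        return (hit.cstart + offset) % L
    return (hit.cend - 1 - offset) % L


def dedupe(breakpoints: list[Breakpoint]) -> BreakpointSet:
    """Collapse breakpoints sharing (consensus_pos, side) into single events.

    Junction ends detected on the same consensus nucleotide are treated as
    copies of a single mutational event; each event carries the support
    count.  Never increases the event count; support sums to the input
    count.
    """
    families = {bp.family for bp in breakpoints}
    if len(families) > 1:
        raise ValueError(f"breakpoints from multiple families: {sorted(families)}")
    family = families.pop() if families else ""
    groups: dict[tuple[int, str], list[Breakpoint]] = {}
    for bp in breakpoints:
        groups.setdefault((bp.consensus_pos, bp.side), []).append(bp)
    events = [
        BreakpointEvent(pos, side, len(members), members)
        for (pos, side), members in sorted(groups.items())
    ]
    return BreakpointSet(
        family=family, breakpoints=list(breakpoints), deduplicated=True, events=events
    )


def palindrome_association(
    bpset: BreakpointSet,
    family: SatDnaFamily,
    slack: int = 0,
    motifs: list[tuple[int, int]] | None = None,
) -> dict:
    """Count deduplicated events inside each motif interval (plus outside).

    Motifs default to the family's palindromes.  An event at interval
    position end-1 counts; at end it does not (half-open); ``slack``
    expands each interval by that many bases on both sides.
    """
    if motifs is None:
        motifs = list(family.palindromes)
    counts = [
        {
            "interval": (s, e),
            "count": sum(
                1 for ev in bpset.events if s - slack <= ev.consensus_pos < e + slack
            ),
        }
        for s, e in motifs
    ]
    outside = sum(
        1
        for ev in bpset.events
        if not any(s - slack <= ev.consensus_pos < e + slack for s, e in motifs)
    )
    return {"motifs": counts, "outside": outside, "n_events": bpset.n_events}


def _oriented(
    fragment: GenomicFragment, array: ArrayAnnotation
) -> tuple[str, list[MonomerHit], bool]:
    """Return (sequence, member hits) with the array on the plus strand."""
    if array.strand == "+":
        return fragment.sequence, array.members, False
    n = len(fragment.sequence)
    flipped = [
        MonomerHit(
            fragment_id=h.fragment_id,
            start=n - h.end,
            end=n - h.start,
            strand="+",
            family=h.family,
            cstart=h.cstart,
            cend=h.cend,
            matches=h.matches,
            columns=h.columns,
            score=h.score,
            completeness=h.completeness,
        )
        for h in reversed(array.members)
    ]
    return revcomp(fragment.sequence), flipped, True


def _xdrop_cap(
    prof: list[bool],
    p_sat: float,
    p_bg: float,
    xdrop: float = 15.0,
) -> int:
    """Cap a boundary search where the profile stops looking satellite.

    Mirrors the scanner's segmentation rule: once the running
    log-likelihood falls ``xdrop`` below its peak, positions beyond the
    peak are unreachable for the boundary.  Prevents a terminus from
    extending across a sustained non-satellite stretch toward a chance
    in-phase match further out (e.g. a remnant across a spacer whose
    length happens to equal the missing segment).
    """
    w_match = math.log(p_sat / p_bg)
    w_mismatch = math.log((1 - p_sat) / (1 - p_bg))
    cum = runmax = 0.0
    pos = 0
    for i, m in enumerate(prof):
        cum += w_match if m else w_mismatch
        if cum > runmax:
            runmax, pos = cum, i + 1
        if runmax - cum >= xdrop:
            return pos
    return len(prof)


def _recount(hit: MonomerHit, seq: str, cons: str, L: int) -> None:
    """Re-derive match bookkeeping on an ungapped basis after polishing."""
    hit.columns = hit.span
    hit.matches = sum(
        1
        for o in range(hit.span)
        if seq[hit.start + o] == cons[(hit.cstart + o) % L]
    )


def _apply_start(members, new_start, seq, cons, L, min_keep):
    t = members[0]
    span = t.end - new_start
    if span < min_keep:
        members.pop(0)
        return
    cstart_new = t.cend - span
    if cstart_new >= 0:
        t.start, t.cstart = new_start, cstart_new
        _recount(t, seq, cons, L)
        return
    wrap = -cstart_new  # bases falling in the preceding monomer period
    t.start, t.cstart = t.end - t.cend, 0
    _recount(t, seq, cons, L)
    if wrap >= min_keep:
        extra = MonomerHit(
            fragment_id=t.fragment_id,
            start=new_start,
            end=t.start,
            strand=t.strand,
            family=t.family,
            cstart=L - wrap,
            cend=L,
            matches=0,
            columns=0,
            score=t.score,
        )
        _recount(extra, seq, cons, L)
        members.insert(0, extra)


def _apply_end(members, new_end, seq, cons, L, min_keep):
    t = members[-1]
    span = new_end - t.start
    if span < min_keep:
        members.pop()
        return
    cend_new = t.cstart + span
    if cend_new <= L:
        t.end, t.cend = new_end, cend_new
        _recount(t, seq, cons, L)
        return
    rest = cend_new - L  # bases continuing into the next monomer period
    t.end, t.cend = t.start + (L - t.cstart), L
    _recount(t, seq, cons, L)
    if rest >= min_keep:
        extra = MonomerHit(
            fragment_id=t.fragment_id,
            start=t.end,
            end=new_end,
            strand=t.strand,
            family=t.family,
            cstart=0,
            cend=rest,
            matches=0,
            columns=0,
            score=t.score,
        )
        _recount(extra, seq, cons, L)
        members.append(extra)


def polish_array(
    fragment: GenomicFragment,
    array: ArrayAnnotation,
    family: SatDnaFamily,
    reach: int = 90,
    p_sat: float = 0.9,
    p_bg: float = 0.25,
    min_keep: int = 5,
    radius: int = 0,
    lo_bound: int = 0,
    hi_bound: int | None = None,
) -> list[MonomerHit]:
    """Re-fit both array termini with a changepoint on an ungapped profile.

    Cheap affine gaps let local alignment bridge short random stretches at
    ~55% gapped identity, so raw terminal hits can swallow flank sequence
    (dragging their consensus frame off) or, conversely, shed a
    mismatch-rich real terminus.  This polisher anchors each terminus on
    the array-facing *inner* edge of the terminal hit — whose phase is
    fixed by the array interior — extends a periodic-consensus match
    profile up to ``reach`` bases beyond the current boundary (never past
    ``lo_bound``/``hi_bound``, e.g. neighbouring annotations), and places
    the boundary at the Bernoulli changepoint.  Reclaimed bases are split
    into per-period member hits; termini shrinking below ``min_keep``
    bases are dropped.  Returns the rebuilt member list in fragment
    coordinates (the input objects are not modified).
    """
    L = family.length
    cons = family.consensus
    n = len(fragment.sequence)
    if hi_bound is None:
        hi_bound = n
    seq, members, flipped = _oriented(fragment, array)
    members = [
        MonomerHit(
            fragment_id=h.fragment_id,
            start=h.start,
            end=h.end,
            strand=h.strand,
            family=h.family,
            cstart=h.cstart,
            cend=h.cend,
            matches=h.matches,
            columns=h.columns,
            score=h.score,
            completeness=h.completeness,
        )
        for h in members
    ]
    lo_o, hi_o = (lo_bound, hi_bound) if not flipped else (n - hi_bound, n - lo_bound)

    # start (outer-left) terminus, scanned inner -> outer
    t = members[0]
    x0 = max(lo_o, t.start - reach)
    prof = [
        seq[x] == cons[(t.cend - (t.end - x)) % L]
        for x in range(t.end - 1, x0 - 1, -1)
    ]
    if prof:
        cap = _xdrop_cap(prof, p_sat, p_bg)
        c = _posterior_changepoint(prof, 0, cap, p_sat, p_bg, radius)
        _apply_start(members, t.end - c, seq, cons, L, min_keep)
    if members:
        # end (outer-right) terminus, scanned inner -> outer
        t = members[-1]
        x1 = min(hi_o, t.end + reach)
        prof = [
            seq[x] == cons[(t.cstart + (x - t.start)) % L]
            for x in range(t.start, x1)
        ]
        if prof:
            cap = _xdrop_cap(prof, p_sat, p_bg)
            c = _posterior_changepoint(prof, 0, cap, p_sat, p_bg, radius)
            _apply_end(members, t.start + c, seq, cons, L, min_keep)

    for h in members:
        h.classify(L)
    if flipped:
        members = [
            MonomerHit(
                fragment_id=h.fragment_id,
                start=n - h.end,
                end=n - h.start,
                strand="-",
                family=h.family,
                cstart=h.cstart,
                cend=h.cend,
                matches=h.matches,
                columns=h.columns,
                score=h.score,
                completeness=h.completeness,
            )
            for h in reversed(members)
        ]
    return members


def call_array_junctions(
    fragment: GenomicFragment,
    array: ArrayAnnotation,
    family: SatDnaFamily,
    window: int = 10,
    threshold: float = 0.6,
    min_stretch: int = 10,
    flank_len: int = 80,
    refine: bool = True,
    keep_trace: bool = False,
) -> list[Breakpoint]:
    """Call the junction nucleotide at both termini of a tandem array.

    For each side the segment spans up to one monomer of satellite plus up
    to ``flank_len`` bases of flank; sides whose flank is too short to
    confirm a sub-threshold run (< window + min_stretch - 1 bases, e.g.
    truncated clones) are skipped, as are sides with no persistent drop.
    """
    L = family.length
    seq, members, was_flipped = _oriented(fragment, array)
    n = len(seq)
    need = window + min_stretch - 1
    out: list[Breakpoint] = []
    for side in SIDES:
        # phases are anchored on the array-facing inner edge of the terminal
        # hit, which is pinned by the array interior even when the outer
        # edge of the raw alignment is unreliable; the satellite side of
        # the segment extends across abutting members so that a short
        # partial terminal monomer still leaves the caller up to a full
        # monomer of satellite evidence
        if side == "array_start":
            t = members[0]
            inner = t.end
            for nxt in members[1:]:
                if nxt.start != inner or inner - t.start >= L:
                    break
                inner = nxt.end
            m = min(inner - t.start, L)
            seg_start = max(0, t.start - flank_len)
            seg_end = t.start + m
            flank_avail = t.start - seg_start
            phase0 = (t.cend - (t.end - seg_start)) % L
        else:
            t = members[-1]
            inner = t.start
            for nxt in reversed(members[:-1]):
                if nxt.end != inner or t.end - inner >= L:
                    break
                inner = nxt.start
            m = min(t.end - inner, L)
            seg_start = t.end - m
            seg_end = min(n, t.end + flank_len)
            flank_avail = seg_end - t.end
            phase0 = (t.cstart + (seg_start - t.start)) % L
        if flank_avail < need:
            continue
        segment = seq[seg_start:seg_end]
        trace = similarity_trace(
            segment, family, phase0, side, window=window, segment_start=seg_start
        )
        d = call_breakpoint(trace, threshold=threshold, min_stretch=min_stretch)
        if d is None:
            continue
        c = refine_breakpoint(trace, d) if refine else d
        pos = int(trace.fragment_pos(c))
        pos = max(seg_start, min(seg_end - 1, pos))
        cpos = int((phase0 + (pos - seg_start)) % L)
        if was_flipped:
            pos = n - 1 - pos
        out.append(
            Breakpoint(
                fragment_id=fragment.id,
                family=family.name,
                side=side,
                fragment_pos=pos,
                consensus_pos=cpos,
                trace=list(trace.values) if keep_trace else [],
            )
        )
    return out
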