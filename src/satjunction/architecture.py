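"""Classification of higher-order junction architectures.

Three patterns recur where satDNA monomers meet unrelated sequence:

* **split insertion** — a monomer precisely split by an insert, with no
  monomer sequence missing; often bracketed by a short target-site
  duplication (TSD) left by staggered-cut integration;
* **cut-and-replace** — a monomer segment excised and substituted by
  unrelated sequence of comparable length;
* **remnant/spacer** — a sub-monomer remnant in the array flank whose
  consensus phase is continuous with the array terminus, separated from it
  by a short spacer that replaced the missing monomer segment.

Classification works on monomer hits from the scanner: the consensus bases
missing between two flanking hits are compared with the fragment bases
inserted between them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._dna import revcomp
from .consensus import SatDnaFamily
from .io_formats import GenomicFragment
from .scan import ArrayAnnotation, MonomerHit

#: "similar length" tolerance for cut-and-replace: |insert - missing| must
#: not exceed max(TOLERANCE_BP, TOLERANCE_FRAC * missing).
TOLERANCE_BP = 15
TOLERANCE_FRAC = 0.25


@dataclass
class TsdCall:
    """A direct repeat bracketing an insert (one copy outside, one inside).

    ``polarity`` records which copy lies outside the insert: "left_out"
    (host copy immediately left of the insert, duplicate at the insert's
    right end) or "right_out" (the strand mirror).  The polarity is
    recorded, not interpreted.
    """

    sequence: str
    length: int
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    polarity: str = "left_out"


@dataclass
class ArchitectureEvent:
    fragment_id: str
    kind: str  # split_insertion | cut_and_replace | remnant_spacer
    host_family: str
    strand: str
    upstream_hit: MonomerHit | None
    downstream_hit: MonomerHit | None
    insert_interval: tuple[int, int]
    missing_consensus_interval: tuple[int, int] | None = None
    missing_len: int = 0
    tsd: TsdCall | None = None
    spacer_len: int | None = None
    remnant_len: int | None = None

    @property
    def insert_len(self) -> int:
        return self.insert_interval[1] - self.insert_interval[0]

    @property
    def length_delta(self) -> int:
        """Insert length minus missing monomer length (bp)."""
        return self.insert_len - self.missing_len


@dataclass
class HitPair:
    """Two same-strand hits of one family flanking an intervening segment."""

    upstream: MonomerHit
    downstream: MonomerHit
    gap_bp: int
    missing_raw: int  # consensus bases between the facing phase edges, mod L


def _phase_gap(upstream: MonomerHit, downstream: MonomerHit, L: int) -> int:
    """Consensus bases missing between the facing edges of the two hits."""
    if upstream.strand == "+":
        return (downstream.cstart - (upstream.cend % L)) % L
    return ((upstream.cstart - (downstream.cend % L))) % L


def pair_flanking_hits(
    hits: list[MonomerHit], family: SatDnaFamily
) -> list[HitPair]:
    """Candidate (upstream, downstream) pairs around intervening sequence.

    Hits must come from one fragment; only fragment-adjacent, same-strand
    pairs of the given family with >= 1 bp between them qualify
    (contiguous array members are not pairs).
    """
    fam_hits = sorted(
        (h for h in hits if h.family == family.name), key=lambda h: h.start
    )
    if len({h.fragment_id for h in fam_hits}) > 1:
        raise ValueError("hits must come from a single fragment")
    L = family.length
    pairs: list[HitPair] = []
    for up, down in zip(fam_hits, fam_hits[1:]):
        if up.strand != down.strand:
            continue
        gap = down.start - up.end
        if gap < 1:
            continue
        pairs.append(HitPair(up, down, gap, _phase_gap(up, down, L)))
    return pairs


def detect_tsd(
    fragment: GenomicFragment,
    insert_interval: tuple[int, int],
    min_len: int = 2,
    max_len: int = 10,
) -> TsdCall | None:
    """Longest exact direct repeat bracketing an insert.

    Searches k from ``max_len`` down to ``min_len`` for the k-mer
    immediately left of the insert equalling the k-mer at the insert's
    right end (the convention: one copy outside the insert, one copy as
    the insert's last bases).  The search is truncated, not an error, when
    the insert sits too close to a fragment edge.
    """
    start, end = insert_interval
    if not (0 <= start < end <= len(fragment.sequence)):
        raise ValueError(f"insert interval [{start},{end}) outside fragment")
    seq = fragment.sequence
    kmax = min(max_len, start, end - start)
    for k in range(kmax, min_len - 1, -1):
        left = seq[start - k : start]
        right = seq[end - k : end]
        if left == right and "N" not in left:
            return TsdCall(
                sequence=left,
                length=k,
                left_interval=(start - k, start),
                right_interval=(end - k, end),
            )
    return None


_W_HOST = math.log(0.9 / 0.25)
_W_HOST_MIS = math.log(0.1 / 0.75)
_W_TSD = math.log(4.0)  # an exactly duplicated base vs a chance match


def _find_split_tsd(
    seq: str,
    up: MonomerHit,
    down: MonomerHit,
    L: int,
    consensus: str,
    max_tsd: int = 10,
    slop: int = 8,
):
    """Locate the precise insert frame and its TSD for a split monomer.

    The polished outer edges of the flanking hits carry several bases of
    ambiguity (partial chance matches let the boundary overshoot into the
    insert), but their *inner* edges pin the consensus phase exactly.
    Candidate insert-start positions s are scanned within ``slop`` of the
    upstream edge; phase continuity then fixes the matching insert end e
    (the boundaries are coupled).  Frames are ranked by joint evidence:
    log-likelihood of the boundary placement on both junction profiles
    (host bases match the phased consensus at ~0.9, insert bases at 0.25)
    plus log(4) per exactly duplicated TSD base.  Ties go to the longer
    repeat (the canonical maximal form — adjacent frames sharing an edge
    base describe the same duplication), then the smaller displacement.
    Returns (s, e, TsdCall) or None.
    """
    n = len(seq)

    def phase_up(x: int) -> int:
        if up.strand == "+":
            return (up.cend + (x - up.end)) % L
        return (up.cstart - 1 - (x - up.end)) % L

    def phase_down(y: int) -> int:
        if down.strand == "+":
            return (down.cstart + (y - down.start)) % L
        return (down.cend - 1 - (y - down.start)) % L

    def base(x: int) -> str:
        b = seq[x]
        if up.strand == "-":
            b = revcomp(b)
        return b

    def w_up(x: int) -> float:
        return _W_HOST if base(x) == consensus[phase_up(x)] else _W_HOST_MIS

    def w_down(y: int) -> float:
        return _W_HOST if base(y) == consensus[phase_down(y)] else _W_HOST_MIS

    # S_up(s): host loglik of positions before s within the scan window
    s_lo, s_hi = max(up.start + 1, up.end - slop, 1), min(up.end + slop, n - 1)
    if s_lo > s_hi:
        return None
    up_pref = [0.0]
    for x in range(s_lo, s_hi):
        up_pref.append(up_pref[-1] + w_up(x))

    best = None  # (score key, s, e, TsdCall)
    for s in range(s_lo, s_hi + 1):
        t = phase_up(s)
        if down.strand == "+":
            r = (t - down.cstart) % L
        else:
            r = (down.cend - 1 - t) % L
        if r <= max_tsd + 2 * slop:
            e = down.start + r
        elif r >= L - slop:
            e = down.start + (r - L)
        else:
            continue
        if not (s < e <= n) or e >= down.end:
            continue
        call = None
        for k in range(max_tsd, 1, -1):
            if up.strand == "+":
                # host copy left of the insert, duplicate at its right end
                a_iv, b_iv = (s - k, s), (e - k, e)
                if a_iv[0] < 0 or b_iv[0] < s:
                    continue
                polarity = "left_out"
            else:
                # strand mirror: host copy right of the insert
                a_iv, b_iv = (s, s + k), (e, e + k)
                if b_iv[1] > n or a_iv[1] > e:
                    continue
                polarity = "right_out"
            a = seq[a_iv[0] : a_iv[1]]
            b = seq[b_iv[0] : b_iv[1]]
            if a == b and "N" not in a:
                call = TsdCall(a, k, a_iv, b_iv, polarity=polarity)
                break
        if call is None:
            continue
        s_up = up_pref[s - s_lo]
        # down-side: positions >= e are host; the fixed right window edge
        # must lie beyond every candidate e so the sums stay comparable
        d_hi = min(n, down.end, down.start + max_tsd + 3 * slop)
        s_down = sum(w_down(y) for y in range(e, d_hi))
        score = call.length * _W_TSD + s_up + s_down
        # frames inside a long duplication tie exactly (the duplicate is
        # in-phase satellite on both sides); the canonical form is the
        # rightmost maximal frame
        key = (score, call.length, s)
        if best is None or key > best[0]:
            best = (key, s, e, call)
    if best is None:
        return None
    return best[1], best[2], best[3]


def classify_pair(
    pair: HitPair,
    family: SatDnaFamily,
    fragment: GenomicFragment | None = None,
    tolerance_bp: int = TOLERANCE_BP,
    tolerance_frac: float = TOLERANCE_FRAC,
    max_tsd: int = 10,
    edge_slop: int = 6,
) -> ArchitectureEvent | None:
    """Classify a flanking-hit pair as split insertion or cut-and-replace.

    missing = consensus bases between the facing hit edges (mod L);
    insert = fragment bases between the hits.  missing 0 is a precise
    split; a small *negative* phase gap (downstream hit reaching back into
    upstream phase) is the signature of a target-site duplication and is
    treated as a split with the duplicated bases reassigned to the insert.
    Hit termini abutting unrelated sequence carry a few bases of genuine
    ambiguity (mutated terminal bases are indistinguishable from flank),
    so a phase gap of at most ``edge_slop`` combined with an insert far
    too long for a replacement is also read as a precise split.  Otherwise
    the pair is cut-and-replace when insert and missing lengths agree
    within tolerance, else unclassified (None).
    """
    L = family.length
    up, down = pair.upstream, pair.downstream
    missing = pair.missing_raw
    insert_start, insert_end = up.end, down.start
    overlap = L - missing if missing else 0
    if 0 < overlap <= max_tsd + 2 * edge_slop:
        # downstream hit starts `overlap` bases before upstream's end phase:
        # a duplicated stretch; count it as part of the insert
        missing = 0
        insert_end += overlap
    elif (
        0 < missing <= edge_slop
        and (insert_end - insert_start) - missing
        > max(tolerance_bp, tolerance_frac * missing)
    ):
        # terminus erosion, not a replacement: re-centre the frame
        insert_start += missing
        missing = 0
    if missing == 0:
        interval = (insert_start, insert_end)
        tsd = None
        if fragment is not None:
            found = _find_split_tsd(
                fragment.sequence, up, down, L, family.consensus,
                max_tsd=max_tsd, slop=max(edge_slop, 8),
            )
            if found is not None:
                s, e, tsd = found
                interval = (s, e)
        return ArchitectureEvent(
            fragment_id=up.fragment_id,
            kind="split_insertion",
            host_family=family.name,
            strand=up.strand,
            upstream_hit=up,
            downstream_hit=down,
            insert_interval=interval,
            missing_consensus_interval=None,
            missing_len=0,
            tsd=tsd,
        )
    insert_len = insert_end - insert_start
    if abs(insert_len - missing) <= max(tolerance_bp, tolerance_frac * missing):
        if up.strand == "+":
            mstart = up.cend % L
        else:
            mstart = down.cend % L
        return ArchitectureEvent(
            fragment_id=up.fragment_id,
            kind="cut_and_replace",
            host_family=family.name,
            strand=up.strand,
            upstream_hit=up,
            downstream_hit=down,
            insert_interval=(insert_start, insert_end),
            missing_consensus_interval=(mstart, mstart + missing),
            missing_len=missing,
        )
    return None


def detect_remnant_spacer(
    array: ArrayAnnotation,
    remnants: list[MonomerHit],
    family: SatDnaFamily,
    max_spacer: int = 100,
    phase_tolerance: int = 3,
) -> list[ArchitectureEvent]:
    """Remnants phase-continuous with an array terminus across a spacer.

    A remnant left of the array start (or right of the array end, or the
    strand mirror) whose consensus phase continues the array across a
    missing segment of >= 1 bp, separated by a spacer of at most
    ``max_spacer`` bp, is reported with the remnant, spacer and missing
    lengths — the cut-and-replace bookkeeping of interrupted monomers in
    array flanks.
    """
    L = family.length
    events: list[ArchitectureEvent] = []
    for rem in remnants:
        if rem.strand != array.strand or rem.family != array.family:
            continue
        if rem.end <= array.start:  # remnant left of the array
            spacer = array.start - rem.end
            terminal = array.members[0]
            if array.strand == "+":
                missing = (terminal.cstart - (rem.cend % L)) % L
            else:
                missing = ((rem.cstart - (terminal.cend % L))) % L
            upstream, downstream = rem, terminal
            insert_interval = (rem.end, array.start)
        elif rem.start >= array.end:  # remnant right of the array
            spacer = rem.start - array.end
            terminal = array.members[-1]
            if array.strand == "+":
                missing = (rem.cstart - (terminal.cend % L)) % L
            else:
                missing = ((terminal.cstart - (rem.cend % L))) % L
            upstream, downstream = terminal, rem
            insert_interval = (array.end, rem.start)
        else:
            continue
        if spacer > max_spacer or spacer < 1:
            continue
        if missing < 1 or missing > L - phase_tolerance:
            continue
        if array.strand == "+":
            mstart = upstream.cend % L
        else:
            mstart = downstream.cend % L
        events.append(
            ArchitectureEvent(
                fragment_id=rem.fragment_id,
                kind="remnant_spacer",
                host_family=family.name,
                strand=array.strand,
                upstream_hit=upstream,
                downstream_hit=downstream,
                insert_interval=insert_interval,
                missing_consensus_interval=(mstart, mstart + missing),
                missing_len=missing,
                spacer_len=spacer,
                remnant_len=rem.span,
            )
        )
    return events


def event_row(event: ArchitectureEvent) -> dict:
    """Flatten an ArchitectureEvent into an `events` report-schema row."""
    mci = event.missing_consensus_interval
    return {
        "fragment_id": event.fragment_id,
        "family": event.host_family,
        "kind": event.kind,
        "strand": event.strand,
        "insert_start": event.insert_interval[0],
        "insert_end": event.insert_interval[1],
        "insert_len": event.insert_len,
        "missing_cstart": mci[0] if mci else None,
        "missing_cend": mci[1] if mci else None,
        "missing_len": event.missing_len,
        "length_delta": event.length_delta,
        "tsd": event.tsd.sequence if event.tsd else None,
        "tsd_len": event.tsd.length if event.tsd else None,
        "spacer_len": event.spacer_len,
        "remnant_len": event.remnant_len,
    }
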