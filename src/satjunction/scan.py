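"""Annotate satDNA monomers, tandem arrays and monomer remnants on fragments.

The scanner aligns a fragment (both strands) against an *artificial
multimer* — the family consensus concatenated two or three times — so that
local alignments can span the monomer origin.  Surviving alignments are cut
at consensus-period boundaries into per-monomer hits; small unannotated
gaps between phase-congruent neighbouring hits (alignment end erosion) are
healed back.  All consensus coordinates are reported modulo the monomer
length L in the family's frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from ._dna import revcomp
from .consensus import SatDnaFamily
from .io_formats import GenomicFragment

#: completeness slack (nt): a hit is deemed to touch a monomer boundary if it
#: comes within this many bases of it.  Local alignment trims mismatch-rich
#: termini, so exact boundary contact cannot be required.
COMPLETENESS_SLACK = 3

#: maximal unannotated gap (nt) between phase-congruent neighbouring hits
#: that is reattached to the hits ("healing" of alignment end erosion).
HEAL_MAX_GAP = 12

_MIN_PIECE_LEN = 5


@dataclass
class MonomerHit:
    """One (possibly partial) monomer copy located on a fragment.

    ``cstart``/``cend`` are consensus coordinates within a single monomer
    period, 0 <= cstart < cend <= L.  For minus-strand hits the fragment
    interval is in fragment coordinates while consensus coordinates follow
    the consensus orientation: fragment position ``start`` pairs with
    consensus position ``cend - 1``.
    """

    fragment_id: str
    start: int
    end: int
    strand: str
    family: str
    cstart: int
    cend: int
    matches: int
    columns: int
    score: float = 0.0
    wrap: bool = False
    completeness: str = "internal_fragment"

    @property
    def percent_identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def span(self) -> int:
        return self.end - self.start

    def classify(self, L: int, slack: int = COMPLETENESS_SLACK) -> None:
        touches_start = self.cstart <= slack
        touches_end = L - self.cend <= slack
        if touches_start and touches_end:
            self.completeness = "complete"
        elif touches_end:
            self.completeness = "partial_start"  # monomer start missing
        elif touches_start:
            self.completeness = "partial_end"  # monomer end missing
        else:
            self.completeness = "internal_fragment"


@dataclass
class ArrayAnnotation:
    """A tandem array: chained same-family, same-strand monomer hits."""

    fragment_id: str
    family: str
    strand: str
    members: list[MonomerHit]
    max_gap_bp: int

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return self.members[-1].end

    @property
    def array_interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def total_span_bp(self) -> int:
        return self.end - self.start

    @property
    def copy_number(self) -> int:
        """Number of complete monomer copies in the array."""
        return sum(1 for h in self.members if h.completeness == "complete")

    @property
    def mean_identity(self) -> float:
        cols = sum(h.columns for h in self.members)
        if not cols:
            return 0.0
        return sum(h.matches for h in self.members) / cols

    def terminal_hit(self, side: str) -> MonomerHit:
        """Member at the array terminus facing the given junction side."""
        if side == "array_start":
            return self.members[0]
        if side == "array_end":
            return self.members[-1]
        raise ValueError(f"unknown side {side!r}")


def make_multimer(family: SatDnaFamily, k: int) -> str:
    """Consensus concatenated k times (k in {2,3}) so hits can span the origin."""
    if k not in (2, 3):
        raise ValueError("multimer order k must be 2 or 3")
    return family.consensus * k


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _alignment_columns(aln) -> list[tuple[int | None, int | None]]:
    """(target_pos, query_pos) per alignment column; None marks a gap."""
    tb, qb = aln.aligned
    cols: list[tuple[int | None, int | None]] = []
    prev_te = prev_qe = None
    for (ts, te), (qs, qe) in zip(tb, qb):
        if prev_te is not None:
            for t in range(prev_te, ts):
                cols.append((t, None))
            for q in range(prev_qe, qs):
                cols.append((None, q))
        for o in range(te - ts):
            cols.append((ts + o, qs + o))
        prev_te, prev_qe = te, qe
    return cols


def _segment_columns(
    cols: list[tuple[int | None, int | None]],
    target_seq: str,
    multimer: str,
    xdrop: int = 7,
    min_score: int = 6,
) -> list[tuple[int, int]]:
    """Cut an alignment into well-matching column segments (X-drop style).

    Cheap affine gaps let one local alignment bridge tens of bases of
    unrelated sequence at ~55% gapped identity, gluing two genuine
    satellite stretches across a replacement or spacer.  Columns are
    scored +1 (match) / -2 (mismatch or gap, i.e. a 2/3-identity
    break-even); whenever the running score falls ``xdrop`` below its
    peak, the segment is closed at the peak and a new one started.  Each
    emitted segment ends at its own peak, so junk edges are trimmed too.
    False cuts at chance mismatch clusters leave short, phase-congruent
    gaps that downstream healing reattaches; true bridges are
    phase-incongruent or too long to heal.
    """
    weights = [
        1
        if (t is not None and q is not None and target_seq[t] == multimer[q])
        else -2
        for t, q in cols
    ]
    segments: list[tuple[int, int]] = []
    seg_start = 0
    cum = peak = 0
    peak_pos = 0
    for i, w in enumerate(weights):
        cum += w
        if cum > peak:
            peak, peak_pos = cum, i + 1
        if peak == 0 and cum <= 0:
            seg_start, cum = i + 1, 0
            peak_pos = seg_start
        elif peak - cum >= xdrop:
            if peak >= min_score:
                segments.append((seg_start, peak_pos))
            seg_start, cum, peak = i + 1, 0, 0
            peak_pos = seg_start
    if peak >= min_score:
        segments.append((seg_start, peak_pos))
    return segments


def _split_into_pieces(
    cols: list[tuple[int | None, int | None]],
    target_seq: str,
    multimer: str,
    L: int,
    score: float,
) -> list[dict]:
    """Cut alignment columns at multiples of L (monomer period boundaries)."""
    pieces: list[list[tuple[int | None, int | None]]] = []
    current: list[tuple[int | None, int | None]] = []
    period = None
    for t, q in cols:
        if q is not None:
            p = q // L
            if period is None:
                period = p
            elif p != period:
                pieces.append(current)
                current = []
                period = p
        current.append((t, q))
    if current:
        pieces.append(current)

    out: list[dict] = []
    for piece in pieces:
        tpos = [t for t, _ in piece if t is not None]
        qpos = [q for _, q in piece if q is not None]
        if not tpos or not qpos:
            continue
        if max(tpos) + 1 - min(tpos) < _MIN_PIECE_LEN:
            continue
        matches = sum(
            1
            for t, q in piece
            if t is not None and q is not None and target_seq[t] == multimer[q]
        )
        out.append(
            {
                "start": min(tpos),
                "end": max(tpos) + 1,
                "cstart": min(qpos) % L,
                "cend": (max(qpos) % L) + 1,
                "matches": matches,
                "columns": len(piece),
                "score": score,
            }
        )
    return out


def _scan_strand(
    seq: str,
    family: SatDnaFamily,
    aligner,
    min_identity: float,
    min_len: int,
    multimer_order: int,
    max_iter: int,
    max_reject: int,
) -> list[dict]:
    """Iterative greedy masking scan of one strand; returns hit pieces."""
    L = family.length
    multimer = make_multimer(family, multimer_order)
    stop_score = max(8.0, math.ceil(min_len * (2 * min_identity - 1)))
    working = seq
    pieces: list[dict] = []
    rejects = 0
    for _ in range(max_iter):
        alignments = aligner.align(working, multimer)
        try:
            aln = alignments[0]
        except (IndexError, StopIteration):
            break
        if aln.score < stop_score:
            break
        cols = _alignment_columns(aln)
        tpos = [t for t, _ in cols if t is not None]
        if not tpos:
            break
        ts, te = min(tpos), max(tpos) + 1
        aligned_on = working  # snapshot: N-masked regions count as mismatch
        # mask the aligned region whether or not it survives the filters,
        # so the next iteration finds the next-best alignment
        working = working[:ts] + "N" * (te - ts) + working[te:]
        accepted_any = False
        for a, b in _segment_columns(cols, aligned_on, multimer):
            seg = cols[a:b]
            seg_t = [t for t, _ in seg if t is not None]
            if not seg_t:
                continue
            span = max(seg_t) + 1 - min(seg_t)
            matches = sum(
                1
                for t, q in seg
                if t is not None and q is not None and aligned_on[t] == multimer[q]
            )
            if span >= min_len and matches / len(seg) >= min_identity:
                pieces.extend(
                    _split_into_pieces(seg, aligned_on, multimer, L, aln.score)
                )
                accepted_any = True
        if accepted_any:
            rejects = 0
        else:
            rejects += 1
            if rejects > max_reject:
                break
    return pieces


def _heal_gaps(hits: list[MonomerHit], consensus: str) -> None:
    """Reattach short unannotated gaps between phase-congruent neighbours.

    Local alignment erodes mismatch-rich termini at the seams between
    greedy-masking iterations, leaving a few real monomer bases unannotated
    between two hits.  When the fragment gap length equals the consensus
    phase gap (mod L), those bases are assigned back to the flanking hits.
    """
    L = len(consensus)
    hits.sort(key=lambda h: h.start)
    for prev, nxt in zip(hits, hits[1:]):
        if prev.strand != nxt.strand or prev.family != nxt.family:
            continue
        g = nxt.start - prev.end
        if not (0 < g <= HEAL_MAX_GAP):
            continue
        if prev.strand == "+":
            phase_gap = (nxt.cstart - (prev.cend % L)) % L
        else:
            phase_gap = ((prev.cstart - (nxt.cend % L))) % L
        if phase_gap != g:
            continue
        if prev.strand == "+":
            a = min(g, L - prev.cend)
            r = g - a
            if r > nxt.cstart:
                continue
            if a:
                seg = prev.end  # fragment bases [prev.end, prev.end + a)
                prev.matches += sum(
                    1
                    for o in range(a)
                    if _frag_base(prev, seg + o) == consensus[prev.cend + o]
                )
                prev.columns += a
                prev.cend += a
                prev.end += a
            if r:
                base0 = nxt.start - r
                nxt.matches += sum(
                    1
                    for o in range(r)
                    if _frag_base(nxt, base0 + o) == consensus[nxt.cstart - r + o]
                )
                nxt.columns += r
                nxt.cstart -= r
                nxt.start -= r
        else:
            a = min(g, prev.cstart)
            r = g - a
            if nxt.cend + r > L:
                continue
            if a:
                seg = prev.end
                prev.matches += sum(
                    1
                    for o in range(a)
                    if _frag_base(prev, seg + o) == consensus[prev.cstart - 1 - o]
                )
                prev.columns += a
                prev.cstart -= a
                prev.end += a
            if r:
                base0 = nxt.start - r
                nxt.matches += sum(
                    1
                    for o in range(r)
                    if _frag_base(nxt, base0 + o) == consensus[nxt.cend + r - 1 - o]
                )
                nxt.columns += r
                nxt.cend += r
                nxt.start -= r


# fragment sequences are attached to hits transiently during healing
def _frag_base(hit: MonomerHit, pos: int) -> str:
    seq = getattr(hit, "_fragment_seq", None)
    if seq is None:
        return "?"
    base = seq[pos]
    return base if hit.strand == "+" else revcomp(base)


def merge_congruent_hits(hits: list[MonomerHit]) -> list[MonomerHit]:
    """Merge abutting, phase-continuous pieces of one monomer copy.

    Greedy masking iterations chunk long arrays at arbitrary positions, so
    one monomer copy can come back as two abutting pieces (e.g. [0,12) +
    [12,170)).  Same-strand, same-family neighbours that touch on the
    fragment and continue each other's consensus phase (without crossing
    the monomer origin) are merged in place.
    """
    if not hits:
        return hits
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    out = [hits[0]]
    for h in hits[1:]:
        prev = out[-1]
        if (
            h.strand == prev.strand
            and h.family == prev.family
            and h.start == prev.end
        ):
            # cstart/cend lie in [0, L], so equality cannot bridge the
            # monomer origin (a piece never starts at phase L)
            if prev.strand == "+":
                congruent = h.cstart == prev.cend
            else:
                congruent = h.cend == prev.cstart
            if congruent:
                if prev.strand == "+":
                    prev.cend = h.cend
                else:
                    prev.cstart = h.cstart
                prev.end = h.end
                prev.matches += h.matches
                prev.columns += h.columns
                prev.score = max(prev.score, h.score)
                continue
        out.append(h)
    return out


def scan_fragment(
    fragment: GenomicFragment,
    family: SatDnaFamily,
    min_identity: float = 0.7,
    min_len: int = 30,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
    multimer_order: int = 2,
    max_iter: int = 32,
    max_reject: int = 4,
    overlap_tol: int = 5,
) -> list[MonomerHit]:
    """Locate monomer copies of ``family`` on both strands of ``fragment``.

    Local alignments against the artificial multimer are collected greedily
    by score (iterative masking); alignments shorter than ``min_len`` or
    below ``min_identity`` are discarded; survivors are cut into
    per-monomer hits at consensus-period boundaries.  Overlap between
    strands is resolved greedily by score, ties by leftmost start then plus
    strand.  Returns hits sorted by fragment start.
    """
    L = family.length
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    n = len(fragment.sequence)

    raw: list[MonomerHit] = []
    for strand in "+-":
        seq = fragment.sequence if strand == "+" else revcomp(fragment.sequence)
        for p in _scan_strand(
            seq, family, aligner, min_identity, min_len,
            multimer_order, max_iter, max_reject,
        ):
            if strand == "+":
                start, end = p["start"], p["end"]
            else:
                start, end = n - p["end"], n - p["start"]
            raw.append(
                MonomerHit(
                    fragment_id=fragment.id,
                    start=start,
                    end=end,
                    strand=strand,
                    family=family.name,
                    cstart=p["cstart"],
                    cend=p["cend"],
                    matches=p["matches"],
                    columns=p["columns"],
                    score=p["score"],
                )
            )

    # cross-strand overlap resolution: greedy by score, leftmost, then +
    raw.sort(key=lambda h: (-h.score, h.start, h.strand != "+"))
    accepted: list[MonomerHit] = []
    for hit in raw:
        clash = False
        for other in accepted:
            if other.strand == hit.strand:
                continue
            ov = min(hit.end, other.end) - max(hit.start, other.start)
            if ov > overlap_tol:
                clash = True
                break
        if not clash:
            accepted.append(hit)

    for hit in accepted:
        hit._fragment_seq = fragment.sequence  # transient, for healing
    plus = [h for h in accepted if h.strand == "+"]
    minus = [h for h in accepted if h.strand == "-"]
    _heal_gaps(plus, family.consensus)
    _heal_gaps(minus, family.consensus)
    for hit in accepted:
        del hit._fragment_seq
    merged = merge_congruent_hits(plus) + merge_congruent_hits(minus)
    for hit in merged:
        hit.classify(L)
    merged.sort(key=lambda h: (h.start, h.end))
    return merged


def heal_and_merge(
    hits: list[MonomerHit],
    fragment: GenomicFragment,
    family: SatDnaFamily,
) -> list[MonomerHit]:
    """Heal phase-congruent gaps and merge abutting pieces, reclassifying.

    Used after any step that rebuilds hit boundaries (e.g. array-terminus
    polishing), which can leave seams that scanning-time healing already
    handles for raw hits.
    """
    plus = [h for h in hits if h.strand == "+"]
    minus = [h for h in hits if h.strand == "-"]
    for h in hits:
        h._fragment_seq = fragment.sequence
    _heal_gaps(plus, family.consensus)
    _heal_gaps(minus, family.consensus)
    for h in hits:
        del h._fragment_seq
    merged = merge_congruent_hits(plus) + merge_congruent_hits(minus)
    for h in merged:
        h.classify(family.length)
    merged.sort(key=lambda h: (h.start, h.end))
    return merged


def segment_arrays(hits: list[MonomerHit], max_gap_bp: int = 5) -> list[ArrayAnnotation]:
    """Chain same-family, same-strand hits with fragment gaps <= max_gap_bp.

    Hits must come from a single fragment.  Each chain becomes one
    ArrayAnnotation; copy number counts complete members.
    """
    if not hits:
        return []
    fragment_ids = {h.fragment_id for h in hits}
    if len(fragment_ids) > 1:
        raise ValueError(f"hits span multiple fragments: {sorted(fragment_ids)}")
    arrays: list[ArrayAnnotation] = []
    by_group: dict[tuple[str, str], list[MonomerHit]] = {}
    for h in sorted(hits, key=lambda h: h.start):
        by_group.setdefault((h.family, h.strand), []).append(h)
    for (family, strand), group in sorted(by_group.items()):
        chain = [group[0]]
        for h in group[1:]:
            if h.start - chain[-1].end <= max_gap_bp:
                chain.append(h)
            else:
                arrays.append(
                    ArrayAnnotation(h.fragment_id, family, strand, chain, max_gap_bp)
                )
                chain = [h]
        arrays.append(
            ArrayAnnotation(chain[0].fragment_id, family, strand, chain, max_gap_bp)
        )
    arrays.sort(key=lambda a: (a.start, a.end))
    return arrays


def find_remnants(
    fragment: GenomicFragment,
    family: SatDnaFamily,
    exclude_intervals: list[tuple[int, int]] | None = None,
    min_len: int = 19,
    min_identity: float = 0.8,
    **scan_kwargs,
) -> list[MonomerHit]:
    """Sub-monomer-length satellite fragments in array-flanking sequence.

    Annotated array intervals are masked out before scanning; hits spanning
    at least ``min_len`` but less than a full monomer are returned.  The
    default ``min_len`` of 19 nt admits the shortest remnants one can still
    call with reasonable specificity at the default identity threshold.
    """
    n = len(fragment.sequence)
    L = family.length
    merged: list[tuple[int, int]] = []
    for s, e in sorted(exclude_intervals or []):
        s, e = max(0, s), min(n, e)
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    keep: list[tuple[int, int]] = []
    pos = 0
    for s, e in merged:
        if s > pos:
            keep.append((pos, s))
        pos = max(pos, e)
    if pos < n:
        keep.append((pos, n))

    out: list[MonomerHit] = []
    for s, e in keep:
        if e - s < min_len:
            continue
        window = GenomicFragment(
            fragment.id, fragment.sequence[s:e], source=fragment.source
        )
        for h in scan_fragment(
            window, family, min_identity=min_identity, min_len=min_len, **scan_kwargs
        ):
            h.start += s
            h.end += s
            if min_len <= h.span < L and h.completeness != "complete":
                out.append(h)
    out.sort(key=lambda h: (h.start, h.end))
    return out
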