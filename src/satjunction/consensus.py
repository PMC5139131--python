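"""Majority-rule consensus building and motif annotation for satDNA families.

A satDNA family is summarised by its consensus monomer (built from a gapped
alignment of monomer copies by the majority principle), plus two kinds of
sequence features that recur in satellite monomers: DNA palindromes
(substrings equal to their own reverse complement) and conserved blocks
(runs of alignment columns with low per-column divergence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._dna import revcomp, is_palindrome

GAP = "-"
_ALN_ALPHABET = frozenset("ACGT-")


@dataclass
class MonomerAlignment:
    """A gapped multiple alignment of monomer copies (rows over {A,C,G,T,-})."""

    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        self.rows = [r.upper() for r in self.rows]
        width = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(f"row {i} has length {len(row)}, expected {width}")
            bad = set(row) - _ALN_ALPHABET
            if bad:
                raise ValueError(f"row {i} contains illegal characters {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class SatDnaFamily:
    """A named satDNA family: consensus monomer plus annotated motifs.

    ``conserved_blocks`` and ``palindromes`` are 0-based half-open intervals
    on the consensus.  The monomer "frame" (position 0) follows whatever
    convention the consensus was supplied in.
    """

    name: str
    consensus: str
    monomers: list[str] = field(default_factory=list)
    conserved_blocks: list[tuple[int, int]] = field(default_factory=list)
    palindromes: list[tuple[int, int]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        if "N" in self.consensus:
            raise ValueError("consensus sequences may not contain N")
        L = len(self.consensus)
        for s, e in list(self.conserved_blocks) + list(self.palindromes):
            if not (0 <= s < e <= L):
                raise ValueError(f"motif interval [{s},{e}) outside consensus [0,{L})")
        for s, e in self.palindromes:
            if not is_palindrome(self.consensus[s:e]):
                raise ValueError(
                    f"interval [{s},{e}) is not a reverse-complement palindrome"
                )

    @property
    def length(self) -> int:
        return len(self.consensus)

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "name": self.name,
            "consensus": self.consensus,
            "monomers": list(self.monomers),
            "conserved_blocks": [list(iv) for iv in self.conserved_blocks],
            "palindromes": [list(iv) for iv in self.palindromes],
            "provenance": dict(self.provenance),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SatDnaFamily":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            name=doc["name"],
            consensus=doc["consensus"],
            monomers=list(doc.get("monomers", [])),
            conserved_blocks=[tuple(iv) for iv in doc.get("conserved_blocks", [])],
            palindromes=[tuple(iv) for iv in doc.get("palindromes", [])],
            provenance=dict(doc.get("provenance", {})),
        )


def build_consensus(alignment: MonomerAlignment, tie_rule: str = "alphabetical") -> str:
    """Majority-rule consensus of a gapped monomer alignment.

    Per column the most frequent non-gap base is emitted; columns where the
    gap is the strict majority are dropped (all-gap columns dropped with a
    warning).  Ties among bases are broken alphabetically (A<C<G<T) so that
    downstream identity scans always see a concrete base; the tie rule is
    the only one implemented and is recorded by callers in provenance.
    """
    if tie_rule != "alphabetical":
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    out: list[str] = []
    half = alignment.n_rows / 2.0
    for col in range(alignment.n_columns):
        chars = [row[col] for row in alignment.rows]
        gaps = chars.count(GAP)
        if gaps == alignment.n_rows:
            warnings.warn(f"column {col} is all-gap; dropped", stacklevel=2)
            continue
        if gaps > half:
            continue  # gap is the strict majority
        counts: dict[str, int] = {}
        for ch in chars:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.values())
        out.append(min(ch for ch, c in counts.items() if c == best))
    return "".join(out)


def find_palindromes(
    seq: str, min_len: int = 6, max_len: int | None = None
) -> list[tuple[int, int]]:
    """Maximal reverse-complement palindromes of even length in [min_len, max_len].

    Palindromes are expanded around every inter-base center; a palindrome
    longer than ``max_len`` is reported trimmed to ``max_len`` around its
    center.  Shorter palindromes nested inside a reported one are
    suppressed.  Intervals are 0-based half-open on ``seq``.
    """
    if min_len < 4 or min_len % 2:
        raise ValueError("min_len must be even and >= 4")
    n = len(seq)
    if max_len is None:
        max_len = n - (n % 2)
    found: list[tuple[int, int]] = []
    comp = str.maketrans("ACGT", "TGCA")
    c = seq.translate(comp)
    for center in range(1, n):  # palindrome spans [center-r, center+r)
        r = 0
        while (
            center - r - 1 >= 0
            and center + r < n
            and seq[center - r - 1] == c[center + r]
            and 2 * (r + 1) <= max_len
        ):
            r += 1
        if 2 * r >= min_len:
            found.append((center - r, center + r))
    # suppress intervals nested inside another reported interval
    found.sort(key=lambda iv: (iv[0], -(iv[1] - iv[0])))
    kept: list[tuple[int, int]] = []
    for s, e in found:
        if any(ks <= s and e <= ke for ks, ke in kept):
            continue
        kept.append((s, e))
    return kept


def find_conserved_blocks(
    alignment: MonomerAlignment,
    window_len: int = 10,
    max_divergence: float = 0.2,
) -> list[tuple[int, int]]:
    """Low-divergence blocks on the consensus built from ``alignment``.

    A block is a maximal run of >= ``window_len`` consensus columns whose
    per-column mismatch frequency (fraction of rows differing from the
    consensus base; gaps count as differing) is <= ``max_divergence``.
    Intervals are reported in ungapped consensus coordinates, i.e. they can
    be sliced directly out of ``build_consensus(alignment)``.
    """
    if window_len < 5:
        raise ValueError("window_len must be >= 5")
    half = alignment.n_rows / 2.0
    low_div: list[bool] = []  # per kept (consensus) column
    for col in range(alignment.n_columns):
        chars = [row[col] for row in alignment.rows]
        gaps = chars.count(GAP)
        if gaps == alignment.n_rows or gaps > half:
            continue
        counts: dict[str, int] = {}
        for ch in chars:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.values())
        cons = min(ch for ch, c in counts.items() if c == best)
        mism = sum(1 for ch in chars if ch != cons)  # gap rows differ
        low_div.append(mism / alignment.n_rows <= max_divergence)
    blocks: list[tuple[int, int]] = []
    i = 0
    n = len(low_div)
    while i < n:
        if low_div[i]:
            j = i
            while j < n and low_div[j]:
                j += 1
            if j - i >= window_len:
                blocks.append((i, j))
            i = j
        else:
            i += 1
    return blocks


def annotate_family(
    name: str,
    alignment: MonomerAlignment,
    *,
    palindrome_min_len: int = 6,
    palindrome_max_len: int | None = None,
    block_window_len: int = 10,
    block_max_divergence: float = 0.2,
) -> SatDnaFamily:
    """Build a SatDnaFamily from an alignment: consensus plus motif scan."""
    consensus = build_consensus(alignment)
    return SatDnaFamily(
        name=name,
        consensus=consensus,
        monomers=list(alignment.rows),
        conserved_blocks=find_conserved_blocks(
            alignment, block_window_len, block_max_divergence
        ),
        palindromes=find_palindromes(consensus, palindrome_min_len, palindrome_max_len),
        provenance={
            "consensus_rule": "majority, ties alphabetical (A<C<G<T)",
            "block_window_len": block_window_len,
            "block_max_divergence": block_max_divergence,
            "palindrome_min_len": palindrome_min_len,
        },
    )
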