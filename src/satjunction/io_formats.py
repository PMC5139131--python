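"""Input/output: FASTA fragments, GFF3 annotations, and fixed TSV report schemas.

All on-disk coordinates follow the usual conventions of each format (GFF3 is
1-based inclusive); everything in memory is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import DNA_ALPHABET


@dataclass
class GenomicFragment:
    """A genomic fragment (cloned or simulated) carrying satellite repeats."""

    id: str
    sequence: str
    description: str = ""
    source: str = "user"  # "user" | "synthetic"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"fragment {self.id!r}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in DNA_ALPHABET:
                raise ValueError(
                    f"fragment {self.id!r}: illegal character {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationRecord:
    """A located feature on a fragment, destined for GFF3 output.

    ``kind`` is one of monomer, array, remnant, te_like, breakpoint, tsd,
    insert.  Breakpoint records are single nucleotides (end = start + 1).
    """

    fragment_id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "monomer"
    attributes: dict = field(default_factory=dict)

    KINDS = frozenset(
        {"monomer", "array", "remnant", "te_like", "breakpoint", "tsd", "insert"}
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad interval [{self.start},{self.end}) on {self.fragment_id}"
            )
        if self.kind == "breakpoint" and self.end != self.start + 1:
            raise ValueError("breakpoint records must satisfy end = start + 1")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def read_fasta(path: str | Path, *, source: str = "user") -> list[GenomicFragment]:
    """Read a FASTA file into GenomicFragments.

    Lowercase is normalized to uppercase; characters outside {A,C,G,T,N}
    are rejected with their position; duplicate ids and empty files are
    errors.  Record order is preserved.
    """
    path = Path(path)
    fragments: list[GenomicFragment] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate fragment id {rec.id!r} in {path}")
        seen.add(rec.id)
        for i, ch in enumerate(seq):
            if ch not in DNA_ALPHABET:
                raise ValueError(
                    f"{path}: record {rec.id!r}: illegal character {ch!r} "
                    f"at position {i}"
                )
        fragments.append(
            GenomicFragment(rec.id, seq, description=rec.description, source=source)
        )
    if not fragments:
        raise ValueError(f"no FASTA records in {path}")
    return fragments


def write_fasta(fragments: Iterable[GenomicFragment], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(f.sequence), id=f.id, description=f.description)
        for f in fragments
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _gff3_escape(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def write_gff3(
    records: Sequence[AnnotationRecord],
    path: str | Path,
    fragment_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write annotation records as GFF3 (1-based inclusive coordinates).

    Records are stably sorted by (fragment_id, start).  If
    ``fragment_lengths`` is given, out-of-bounds records are an error and
    sequence-region pragmas are emitted.
    """
    if fragment_lengths is not None:
        for rec in records:
            if rec.fragment_id not in fragment_lengths:
                raise ValueError(f"record references unknown fragment {rec.fragment_id!r}")
            if rec.end > fragment_lengths[rec.fragment_id]:
                raise ValueError(
                    f"record [{rec.start},{rec.end}) exceeds length of "
                    f"{rec.fragment_id}"
                )
    ordered = sorted(records, key=lambda r: (r.fragment_id, r.start, r.end, r.kind))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if fragment_lengths is not None:
            for fid in sorted(fragment_lengths):
                fh.write(f"##sequence-region {fid} 1 {fragment_lengths[fid]}\n")
        for rec in ordered:
            attrs = ";".join(
                f"{k}={_gff3_escape(v)}" for k, v in sorted(rec.attributes.items())
            )
            fh.write(
                "\t".join(
                    [
                        rec.fragment_id,
                        "satjunction",
                        rec.kind,
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


#: Fixed report schemas: schema name -> ordered column tuple.
REPORT_SCHEMAS: dict[str, tuple[str, ...]] = {
    "breakpoints": (
        "fragment_id",
        "family",
        "side",
        "fragment_pos",
        "consensus_pos",
        "support",
    ),
    "cluster_test": (
        "family",
        "n",
        "L",
        "obs_mean_dist",
        "null_mean",
        "null_sd",
        "z",
        "p",
        "p_empirical",
        "replicates",
        "seed",
    ),
    "events": (
        "fragment_id",
        "family",
        "kind",
        "strand",
        "insert_start",
        "insert_end",
        "insert_len",
        "missing_cstart",
        "missing_cend",
        "missing_len",
        "length_delta",
        "tsd",
        "tsd_len",
        "spacer_len",
        "remnant_len",
    ),
}


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_report(rows: Sequence[Mapping], path: str | Path, schema: str) -> None:
    """Write dict rows as a TSV under one of the fixed report schemas.

    Rows whose keys are not a subset of the schema columns are rejected
    (mixing schemas in one call is an error).  Missing values become NA;
    floats are rendered with 6 significant digits.  Row order is the
    caller's (callers sort deterministically).
    """
    if schema not in REPORT_SCHEMAS:
        raise ValueError(
            f"unknown report schema {schema!r}; expected one of "
            f"{sorted(REPORT_SCHEMAS)}"
        )
    columns = REPORT_SCHEMAS[schema]
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            extra = set(row) - set(columns)
            if extra:
                raise ValueError(
                    f"row fields {sorted(extra)} do not belong to schema {schema!r}"
                )
            fh.write("\t".join(_format_cell(row.get(c)) for c in columns) + "\n")
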