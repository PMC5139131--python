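"""Seeded generator of synthetic satDNA families and junction-bearing fragments.

The generator emulates the structure of short satellite-harbouring genomic
fragments: a tandem array of 1-17 diverged ~170-bp monomers flanked by
anonymous sequence, with abrupt junctions whose consensus positions follow
a configurable (uniform or clustered) distribution, and optional planted
events — TSD-flanked inserts that precisely split a monomer, cut-and-replace
substitutions of a monomer segment, and phase-continuous monomer remnants
separated from the array by a spacer.  Flanks are i.i.d. uniform random
sequence, optionally salted with mutated copies of a small library of
TE-like decoy segments reused across fragments.

Every fragment carries a TruthRecord; with the default substitution-only
mutation model all truth coordinates are exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._dna import BASES, revcomp
from .consensus import SatDnaFamily
from .io_formats import GenomicFragment, write_fasta

_EVENT_KINDS = ("split_insertion", "cut_and_replace", "remnant_spacer")

#: minimal monomer stub (bp) kept on each side of a planted split or cut, so
#: that the flanking segments remain alignable monomer hits
EDGE_MARGIN = 35


def _default_event_rates() -> dict:
    return {"split_insertion": 0.1, "cut_and_replace": 0.1, "remnant_spacer": 0.1}


@dataclass
class SimConfig:
    """Generator configuration; defaults reflect the fragment scale studied.

    ``breakpoint_mode`` is either "uniform" (junction consensus positions
    i.i.d. uniform on the monomer) or ("clustered", (lo, hi)) confining
    them to a consensus interval.
    """

    seed: int
    monomer_length: int = 170
    n_fragments: int = 20
    copy_number_range: tuple[int, int] = (1, 17)
    monomer_divergence: tuple[float, float] = (0.05, 0.15)
    flank_length_range: tuple[int, int] = (100, 500)
    event_rates: dict = field(default_factory=_default_event_rates)
    tsd_length_range: tuple[int, int] = (2, 10)
    palindrome_lengths: tuple[int, ...] = (10, 12)
    breakpoint_mode: object = "uniform"
    insert_length_range: tuple[int, int] = (200, 1000)
    cut_length_range: tuple[int, int] = (20, 80)
    cut_delta_max: int = 10
    remnant_length_range: tuple[int, int] = (19, 64)
    remnant_missing_range: tuple[int, int] = (1, 63)
    spacer_length_range: tuple[int, int] = (10, 60)
    n_decoys: int = 3
    decoy_length_range: tuple[int, int] = (40, 190)
    decoy_divergence: tuple[float, float] = (0.16, 0.34)
    decoy_rate: float = 0.3
    conserved_block_lengths: tuple[int, ...] = (15, 20)
    conserved_block_factor: float = 0.2
    indel_rate: float = 0.0
    family_name: str = "simfam"

    def __post_init__(self) -> None:
        L = self.monomer_length
        if L < 50:
            raise ValueError("monomer_length must be >= 50")
        for name in ("copy_number_range", "flank_length_range", "tsd_length_range",
                     "insert_length_range", "cut_length_range",
                     "remnant_length_range", "remnant_missing_range",
                     "spacer_length_range", "decoy_length_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be a non-empty range, got ({lo},{hi})")
        for rate in self.event_rates.values():
            if not 0 <= rate <= 1:
                raise ValueError("event rates must be probabilities")
        if sum(self.event_rates.values()) > 1:
            raise ValueError("event rates must sum to at most 1")
        bad = set(self.event_rates) - set(_EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds {sorted(bad)}")
        for p in self.palindrome_lengths:
            if p % 2 or p < 4:
                raise ValueError("palindrome lengths must be even and >= 4")
            if p > L:
                raise ValueError(f"palindrome length {p} exceeds monomer length {L}")
        if sum(self.palindrome_lengths) + sum(self.conserved_block_lengths) > L:
            raise ValueError("planted motifs do not fit in the monomer")
        lo, hi = self.monomer_divergence
        if not (0 <= lo <= hi <= 0.35):
            raise ValueError("monomer divergence must lie in [0, 0.35]")
        if isinstance(self.breakpoint_mode, (tuple, list)):
            kind, (lo, hi) = self.breakpoint_mode
            if kind != "clustered" or not (0 <= lo < hi <= L):
                raise ValueError(f"bad breakpoint_mode {self.breakpoint_mode!r}")
        elif self.breakpoint_mode != "uniform":
            raise ValueError(f"bad breakpoint_mode {self.breakpoint_mode!r}")


@dataclass
class TruthRecord:
    """Planted ground truth for one fragment, exact by construction."""

    fragment_id: str
    seed: int
    divergence: float
    arrays: list[dict] = field(default_factory=list)
    junctions: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _draw_breakpoint(mode, L: int, rng: np.random.Generator) -> int:
    if mode == "uniform":
        return int(rng.integers(0, L))
    _, (lo, hi) = mode
    return int(rng.integers(lo, hi))


def generate_family(config: SimConfig, rng: np.random.Generator | None = None) -> SatDnaFamily:
    """Random master monomer with planted palindromes and conserved blocks.

    Motif intervals are disjoint and returned as family ground truth;
    conserved blocks are realised by mutating them at a reduced rate (see
    ``mutate_monomer``).
    """
    if rng is None:
        # the domain tag keeps this stream distinct from plain
        # default_rng(seed) (SeedSequence pads trailing zeros away)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA]))
    L = config.monomer_length
    master = list(_random_dna(rng, L))

    lengths = [("palindrome", p) for p in config.palindrome_lengths]
    lengths += [("block", b) for b in config.conserved_block_lengths]
    taken: list[tuple[int, int]] = []
    placed: dict[str, list[tuple[int, int]]] = {"palindrome": [], "block": []}
    for kind, ln in lengths:
        if ln > L:
            raise ValueError(f"motif length {ln} exceeds monomer length {L}")
        for _ in range(1000):
            s = int(rng.integers(0, L - ln + 1))
            e = s + ln
            if all(e <= ts or s >= te for ts, te in taken):
                break
        else:  # pragma: no cover - motifs validated to fit
            raise ValueError("could not place motifs without overlap")
        taken.append((s, e))
        placed[kind].append((s, e))
        if kind == "palindrome":
            half = _random_dna(rng, ln // 2)
            pal = half + revcomp(half)
            master[s:e] = list(pal)

    return SatDnaFamily(
        name=config.family_name,
        consensus="".join(master),
        conserved_blocks=sorted(placed["block"]),
        palindromes=sorted(placed["palindrome"]),
        provenance={"synthetic": True, "seed": config.seed},
    )


def mutate_monomer(
    master: str,
    divergence: float,
    rng: np.random.Generator,
    protected: list[tuple[int, int]] | None = None,
    protected_factor: float = 0.2,
    indel_rate: float = 0.0,
) -> str:
    """Per-site substitution of ``master`` at the given probability.

    Sites inside ``protected`` intervals mutate at ``divergence *
    protected_factor`` (conserved blocks).  With ``indel_rate`` > 0 short
    indels (geometric lengths) are additionally introduced; note that
    indels break the exact coordinate bookkeeping of planted fragments and
    are for robustness experiments only.
    """
    if not 0 <= divergence <= 0.35:
        raise ValueError("divergence must lie in [0, 0.35]")
    L = len(master)
    rate = np.full(L, divergence)
    for s, e in protected or []:
        rate[s:e] = divergence * protected_factor
    hit = rng.random(L) < rate
    out = list(master)
    for i in np.nonzero(hit)[0]:
        choices = [b for b in BASES if b != master[i]]
        out[i] = choices[rng.integers(0, 3)]
    if indel_rate > 0:
        result: list[str] = []
        for ch in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            result.append(ch)
            if r > 1 - indel_rate / 2:
                ins = 1 + rng.geometric(0.5)
                result.append(_random_dna(rng, int(ins)))
        return "".join(result)
    return "".join(out)


def _fresh_monomer(family: SatDnaFamily, config: SimConfig, div: float,
                   rng: np.random.Generator) -> str:
    return mutate_monomer(
        family.consensus, div, rng,
        protected=family.conserved_blocks,
        protected_factor=config.conserved_block_factor,
        indel_rate=config.indel_rate,
    )


def generate_fragment(
    family: SatDnaFamily,
    config: SimConfig,
    rng: np.random.Generator,
    fragment_id: str,
    decoys: list[str] | None = None,
    seed: int | None = None,
) -> tuple[GenomicFragment, TruthRecord]:
    """One fragment: left flank + (possibly interrupted) array + right flank.

    The array holds k complete mutated monomers plus partial terminal
    copies fixing the two junction consensus positions drawn per
    ``breakpoint_mode``; at most one architecture event is injected per
    fragment according to ``event_rates``.
    """
    L = config.monomer_length
    cons = family.consensus
    k = int(rng.integers(config.copy_number_range[0], config.copy_number_range[1] + 1))
    div = float(rng.uniform(*config.monomer_divergence))

    j_start = _draw_breakpoint(config.breakpoint_mode, L, rng)
    j_end = _draw_breakpoint(config.breakpoint_mode, L, rng)
    b = (j_start + 1) % L  # first consensus phase present in the array
    e_phase = j_end  # array ends just before this phase (0 = whole monomer)

    # segment plan: ("sat", seq, cstart, cend, complete?) | ("ins", seq, meta)
    segments: list[list] = []
    if b != 0:
        mon = _fresh_monomer(family, config, div, rng)
        segments.append(["sat", mon[b:], b, L, False])
    complete_idx: list[int] = []
    for _ in range(k):
        mon = _fresh_monomer(family, config, div, rng)
        segments.append(["sat", mon, 0, L, True])
        complete_idx.append(len(segments) - 1)
    if e_phase != 0:
        mon = _fresh_monomer(family, config, div, rng)
        segments.append(["sat", mon[:e_phase], 0, e_phase, False])

    events: list[dict] = []
    u = rng.random()
    cum = 0.0
    event_kind = None
    for kind in _EVENT_KINDS:
        cum += config.event_rates.get(kind, 0.0)
        if u < cum:
            event_kind = kind
            break

    remnant_plan = None
    if event_kind == "split_insertion" and complete_idx:
        idx = int(rng.choice(complete_idx))
        tsd_len = int(rng.integers(config.tsd_length_range[0],
                                   config.tsd_length_range[1] + 1))
        lo = max(tsd_len, EDGE_MARGIN)
        s = _draw_breakpoint(config.breakpoint_mode, L, rng)
        s = min(max(s, lo), L - EDGE_MARGIN)
        mon = segments[idx][1]
        ins_len = int(rng.integers(*config.insert_length_range))
        tsd_seq = mon[s - tsd_len : s]
        insert = _random_dna(rng, ins_len) + tsd_seq
        segments[idx : idx + 1] = [
            ["sat", mon[:s], 0, s, False],
            ["ins", insert, {"kind": "split_insertion", "tsd": tsd_seq,
                             "split_phase": s}],
            ["sat", mon[s:], s, L, False],
        ]
        events.append({"kind": "split_insertion", "tsd": tsd_seq,
                       "tsd_len": tsd_len, "split_phase": s,
                       "insert_len": ins_len + tsd_len, "missing_len": 0})
    elif event_kind == "cut_and_replace" and complete_idx:
        idx = int(rng.choice(complete_idx))
        cut_len = int(rng.integers(config.cut_length_range[0],
                                   config.cut_length_range[1] + 1))
        cmax = L - cut_len - EDGE_MARGIN
        c = int(rng.integers(EDGE_MARGIN, cmax + 1))
        delta = int(rng.integers(-config.cut_delta_max, config.cut_delta_max + 1))
        repl_len = max(1, cut_len + delta)
        mon = segments[idx][1]
        replacement = _random_dna(rng, repl_len)
        segments[idx : idx + 1] = [
            ["sat", mon[:c], 0, c, False],
            ["ins", replacement, {"kind": "cut_and_replace",
                                  "missing": (c, c + cut_len)}],
            ["sat", mon[c + cut_len :], c + cut_len, L, False],
        ]
        events.append({"kind": "cut_and_replace", "missing_cstart": c,
                       "missing_cend": c + cut_len, "missing_len": cut_len,
                       "insert_len": repl_len, "length_delta": repl_len - cut_len})
    elif event_kind == "remnant_spacer":
        r_len = int(rng.integers(config.remnant_length_range[0],
                                 config.remnant_length_range[1] + 1))
        m_len = int(rng.integers(config.remnant_missing_range[0],
                                 config.remnant_missing_range[1] + 1))
        sp_len = int(rng.integers(config.spacer_length_range[0],
                                  config.spacer_length_range[1] + 1))
        mon = _fresh_monomer(family, config, div, rng)
        phases = [(b - m_len - r_len + i) % L for i in range(r_len)]
        remnant_seq = "".join(mon[p] for p in phases)
        remnant_plan = {"seq": remnant_seq, "spacer_len": sp_len,
                        "missing_len": m_len, "r_len": r_len,
                        "cstart": phases[0], "cend": (phases[-1] + 1) % L or L}

    # flanks
    fl_lo, fl_hi = config.flank_length_range
    left_len = int(rng.integers(fl_lo, fl_hi + 1))
    right_len = int(rng.integers(fl_lo, fl_hi + 1))
    if remnant_plan is not None:
        need = remnant_plan["r_len"] + remnant_plan["spacer_len"] + 25
        left_len = max(left_len, need)

    def _flank(n: int) -> str:
        seq = list(_random_dna(rng, n))
        if decoys and rng.random() < config.decoy_rate and n > config.decoy_length_range[0] + 10:
            d = decoys[int(rng.integers(0, len(decoys)))]
            ddiv = float(rng.uniform(*config.decoy_divergence))
            dm = mutate_monomer(d, min(ddiv, 0.35), rng)
            if len(dm) < n:
                off = int(rng.integers(0, n - len(dm) + 1))
                seq[off : off + len(dm)] = list(dm)
        return "".join(seq)

    truth = TruthRecord(
        fragment_id=fragment_id,
        seed=seed if seed is not None else -1,
        divergence=div,
        params={"k": k, "j_start": j_start, "j_end": j_end,
                "left_len": left_len, "right_len": right_len},
    )

    if remnant_plan is not None:
        outer = _flank(left_len - remnant_plan["r_len"] - remnant_plan["spacer_len"])
        spacer = _random_dna(rng, remnant_plan["spacer_len"])
        left = outer + remnant_plan["seq"] + spacer
        remnant_start = len(outer)
    else:
        left = _flank(left_len)
        remnant_start = None
    right = _flank(right_len)

    # assemble and record coordinates
    pos = len(left)
    array_start = pos
    parts: list[str] = [left]
    sat_runs: list[dict] = []
    current_run: dict | None = None
    for seg in segments:
        if seg[0] == "sat":
            _, seqpart, cstart, cend, complete = seg
            if current_run is None:
                current_run = {"start": pos, "end": pos + len(seqpart),
                               "n_complete": int(complete),
                               "phase_start": cstart, "phase_end": cend}
            else:
                current_run["end"] = pos + len(seqpart)
                current_run["n_complete"] += int(complete)
                current_run["phase_end"] = cend
        else:
            _, seqpart, meta = seg
            if current_run is not None:
                sat_runs.append(current_run)
                current_run = None
            ev = next(
                e for e in events if e["kind"] == meta["kind"] and "insert_start" not in e
            )
            ev["insert_start"] = pos
            ev["insert_end"] = pos + len(seqpart)
        parts.append(seqpart)
        pos += len(seqpart)
    if current_run is not None:
        sat_runs.append(current_run)
    array_end = pos
    parts.append(right)

    sequence = "".join(parts)
    # the realized direct repeat bracketing an insert can be longer than
    # the planted one when adjacent bases match by chance, on either edge;
    # record the canonical maximal form the sequence actually shows (a
    # shared edge base makes adjacent frames describe the same duplication)
    for ev in events:
        if ev["kind"] == "split_insertion" and "insert_start" in ev:
            s0, e0 = ev["insert_start"], ev["insert_end"]
            k0 = ev["tsd_len"]
            a = 0
            while (
                s0 - k0 - a - 1 >= 0
                and sequence[s0 - k0 - a - 1] == sequence[e0 - k0 - a - 1]
            ):
                a += 1
            b = 0
            while (
                e0 + b < len(sequence)
                and sequence[s0 + b] == sequence[e0 + b]
            ):
                b += 1
            length = min(10, k0 + a + b)
            ev["tsd_realized"] = sequence[s0 + b - length : s0 + b]
    truth.arrays = sat_runs
    truth.junctions = [
        {"side": "array_start", "fragment_pos": array_start - 1,
         "consensus_pos": j_start},
        {"side": "array_end", "fragment_pos": array_end, "consensus_pos": j_end},
    ]
    if remnant_plan is not None:
        events.append({
            "kind": "remnant_spacer",
            "remnant_start": remnant_start,
            "remnant_end": remnant_start + remnant_plan["r_len"],
            "remnant_len": remnant_plan["r_len"],
            "spacer_len": remnant_plan["spacer_len"],
            "missing_len": remnant_plan["missing_len"],
            "remnant_cstart": remnant_plan["cstart"],
            "remnant_cend": remnant_plan["cend"],
        })
    truth.events = events

    fragment = GenomicFragment(
        fragment_id, sequence, description="synthetic satDNA fragment",
        source="synthetic",
    )
    return fragment, truth


def generate_dataset(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[list[GenomicFragment], list[TruthRecord], SatDnaFamily]:
    """Full dataset: family + n_fragments fragments + truth, reproducibly.

    Per-fragment RNGs are seeded from SeedSequence([master_seed, tag, index]),
    recorded in each TruthRecord.  With ``out_dir`` set, writes
    fragments.fasta, truth.tsv and family.yaml.
    """
    fam_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA]))
    family = generate_family(config, fam_rng)
    decoys = [
        _random_dna(fam_rng, int(fam_rng.integers(*config.decoy_length_range)))
        for _ in range(config.n_decoys)
    ]
    fragments: list[GenomicFragment] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_fragments):
        child = np.random.SeedSequence([config.seed, 0xF0, 1 + i])
        child_seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
        rng = np.random.default_rng(child_seed)
        frag, truth = generate_fragment(
            family, config, rng, f"sim{i:04d}", decoys=decoys, seed=child_seed
        )
        fragments.append(frag)
        truths.append(truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(fragments, out / "fragments.fasta")
        family.to_yaml(out / "family.yaml")
        write_truth_table(truths, out / "truth.tsv")
    return fragments, truths, family


def write_truth_table(truths: list[TruthRecord], path: str | Path) -> None:
    cols = ["fragment_id", "seed", "divergence", "arrays", "junctions",
            "events", "params"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truths:
            fh.write(
                "\t".join([
                    t.fragment_id,
                    str(t.seed),
                    f"{t.divergence:.6g}",
                    json.dumps(t.arrays, sort_keys=True),
                    json.dumps(t.junctions, sort_keys=True),
                    json.dumps(t.events, sort_keys=True),
                    json.dumps(t.params, sort_keys=True),
                ]) + "\n"
            )


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    truths: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            truths.append(TruthRecord(
                fragment_id=row["fragment_id"],
                seed=int(row["seed"]),
                divergence=float(row["divergence"]),
                arrays=json.loads(row["arrays"]),
                junctions=json.loads(row["junctions"]),
                events=json.loads(row["events"]),
                params=json.loads(row["params"]),
            ))
    return truths
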