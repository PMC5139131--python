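"""End-to-end orchestration: scan -> breakpoints -> cluster test -> architecture.

The pipeline is deterministic: identical inputs, parameters and seed yield
byte-identical output files (no timestamps enter any report), and every
parameter any stage consumes is recorded in the JSON run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .architecture import (
    ArchitectureEvent,
    classify_pair,
    detect_remnant_spacer,
    event_row,
    pair_flanking_hits,
)
from .breakpoints import (
    Breakpoint,
    BreakpointSet,
    call_array_junctions,
    dedupe,
    polish_array,
)
from .cluster import ClusterTestResult, run_cluster_test
from .consensus import SatDnaFamily
from .io_formats import (
    AnnotationRecord,
    GenomicFragment,
    read_fasta,
    write_gff3,
    write_report,
)
from .scan import (
    ArrayAnnotation,
    MonomerHit,
    find_remnants,
    heal_and_merge,
    scan_fragment,
    segment_arrays,
)
from .simulate import TruthRecord


class PipelineError(RuntimeError):
    """A stage failure, labelled with stage name and fragment id."""


def default_params() -> dict:
    """All tunable stage parameters with their defaults."""
    return {
        "scan": {"min_identity": 0.7, "min_len": 30, "multimer_order": 2},
        "arrays": {"max_gap_bp": 5},
        "remnants": {"min_len": 19, "min_identity": 0.8},
        "breakpoints": {
            "window": 10,
            "threshold": 0.6,
            "min_stretch": 10,
            "flank_len": 80,
        },
        "cluster": {"replicates": 100_000},
        "architecture": {
            "tolerance_bp": 15,
            "tolerance_frac": 0.25,
            "max_tsd": 10,
            "max_spacer": 100,
        },
    }


def _merge_params(overrides: dict | None) -> dict:
    params = default_params()
    for stage, vals in (overrides or {}).items():
        if stage not in params:
            raise ValueError(f"unknown pipeline stage {stage!r}")
        for key, val in vals.items():
            if key not in params[stage]:
                raise ValueError(f"unknown parameter {key!r} for stage {stage!r}")
            params[stage][key] = val
    return params


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (YAML)."""

    fragments: str
    families: list[str]
    out_dir: str
    seed: int
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            return cls(
                fragments=doc["fragments"],
                families=list(doc["families"]),
                out_dir=doc["out_dir"],
                seed=int(doc["seed"]),
                params=dict(doc.get("params", {})),
            )
        except KeyError as exc:  # pragma: no cover - config error path
            raise ValueError(f"pipeline config missing key {exc}") from exc


@dataclass
class FragmentResult:
    fragment: GenomicFragment
    hits: dict[str, list[MonomerHit]] = field(default_factory=dict)
    arrays: dict[str, list[ArrayAnnotation]] = field(default_factory=dict)
    remnants: dict[str, list[MonomerHit]] = field(default_factory=dict)
    breakpoints: list[Breakpoint] = field(default_factory=list)
    events: list[ArchitectureEvent] = field(default_factory=list)


@dataclass
class PipelineResult:
    fragments: list[GenomicFragment]
    families: dict[str, SatDnaFamily]
    per_fragment: dict[str, FragmentResult]
    breakpoint_sets: dict[str, BreakpointSet]
    cluster_results: dict[str, ClusterTestResult]
    params: dict
    seed: int

    @property
    def all_events(self) -> list[ArchitectureEvent]:
        out: list[ArchitectureEvent] = []
        for fid in sorted(self.per_fragment):
            out.extend(self.per_fragment[fid].events)
        return out


def analyze_fragments(
    fragments: list[GenomicFragment],
    families: dict[str, SatDnaFamily] | list[SatDnaFamily],
    seed: int,
    params: dict | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory fragments and families."""
    if isinstance(families, list):
        families = {f.name: f for f in families}
    params = _merge_params(params)
    per_fragment: dict[str, FragmentResult] = {}
    pooled_bp: dict[str, list[Breakpoint]] = {name: [] for name in families}

    for frag in fragments:
        res = FragmentResult(fragment=frag)
        for name, fam in families.items():
            stage = "scan"
            try:
                hits = scan_fragment(
                    frag,
                    fam,
                    min_identity=params["scan"]["min_identity"],
                    min_len=params["scan"]["min_len"],
                    multimer_order=params["scan"]["multimer_order"],
                )
                stage = "arrays"
                arrays = segment_arrays(hits, max_gap_bp=params["arrays"]["max_gap_bp"])
                stage = "polish"
                polished: list[MonomerHit] = []
                lo = 0  # post-polish end of everything to the left
                for i, array in enumerate(arrays):
                    hi = (
                        arrays[i + 1].start
                        if i + 1 < len(arrays)
                        else len(frag.sequence)
                    )
                    members = polish_array(
                        frag, array, fam, lo_bound=lo, hi_bound=hi
                    )
                    polished.extend(members)
                    if members:
                        lo = max(lo, max(m.end for m in members))
                hits = heal_and_merge(polished, frag, fam)
                arrays = (
                    segment_arrays(hits, max_gap_bp=params["arrays"]["max_gap_bp"])
                    if hits
                    else []
                )
                stage = "remnants"
                remnants = find_remnants(
                    frag,
                    fam,
                    exclude_intervals=[a.array_interval for a in arrays],
                    min_len=params["remnants"]["min_len"],
                    min_identity=params["remnants"]["min_identity"],
                )
                stage = "breakpoints"
                bps: list[Breakpoint] = []
                for array in arrays:
                    # junctions are called on bona-fide arrays only; stray
                    # sub-third-monomer matches are left to remnant logic
                    if array.total_span_bp < fam.length / 3:
                        continue
                    bps.extend(
                        call_array_junctions(
                            frag,
                            array,
                            fam,
                            window=params["breakpoints"]["window"],
                            threshold=params["breakpoints"]["threshold"],
                            min_stretch=params["breakpoints"]["min_stretch"],
                            flank_len=params["breakpoints"]["flank_len"],
                        )
                    )
                stage = "architecture"
                events: list[ArchitectureEvent] = []
                # standalone sub-monomer matches found by the main scan are
                # remnant candidates, not arrays
                remnant_cands = list(remnants)
                for a in arrays:
                    if (
                        a.copy_number == 0
                        and len(a.members) == 1
                        and a.total_span_bp < fam.length
                    ):
                        remnant_cands.append(a.members[0])
                used_pairs: set[tuple[int, int, int, int]] = set()
                for array in arrays:
                    if array.copy_number < 1 and array.total_span_bp < fam.length:
                        continue
                    for ev in detect_remnant_spacer(
                        array,
                        remnant_cands,
                        fam,
                        max_spacer=params["architecture"]["max_spacer"],
                    ):
                        events.append(ev)
                        used_pairs.add(
                            (
                                ev.upstream_hit.start,
                                ev.upstream_hit.end,
                                ev.downstream_hit.start,
                                ev.downstream_hit.end,
                            )
                        )
                # noise-sized strays would break pair adjacency; genuine
                # sub-monomer residues (>= the remnant floor) still pair
                pairing_hits = [h for h in hits if h.span >= 19]
                for pair in pair_flanking_hits(pairing_hits, fam):
                    key = (
                        pair.upstream.start,
                        pair.upstream.end,
                        pair.downstream.start,
                        pair.downstream.end,
                    )
                    if key in used_pairs:
                        continue
                    ev = classify_pair(
                        pair,
                        fam,
                        fragment=frag,
                        tolerance_bp=params["architecture"]["tolerance_bp"],
                        tolerance_frac=params["architecture"]["tolerance_frac"],
                        max_tsd=params["architecture"]["max_tsd"],
                    )
                    if ev is not None:
                        events.append(ev)
            except Exception as exc:
                raise PipelineError(
                    f"stage {stage!r} failed on fragment {frag.id!r} "
                    f"(family {name!r}): {exc}"
                ) from exc
            res.hits[name] = hits
            res.arrays[name] = arrays
            res.remnants[name] = remnants
            res.breakpoints.extend(bps)
            res.events.extend(events)
            pooled_bp[name].extend(bps)
        per_fragment[frag.id] = res

    breakpoint_sets: dict[str, BreakpointSet] = {}
    cluster_results: dict[str, ClusterTestResult] = {}
    for name, fam in families.items():
        bpset = dedupe(pooled_bp[name])
        bpset.family = name
        breakpoint_sets[name] = bpset
        if bpset.n_events >= 2:
            cluster_results[name] = run_cluster_test(
                bpset,
                fam.length,
                replicates=params["cluster"]["replicates"],
                seed=seed,
                family=name,
            )

    return PipelineResult(
        fragments=fragments,
        families=families,
        per_fragment=per_fragment,
        breakpoint_sets=breakpoint_sets,
        cluster_results=cluster_results,
        params=params,
        seed=seed,
    )


def _hit_record(hit: MonomerHit, kind: str) -> AnnotationRecord:
    return AnnotationRecord(
        fragment_id=hit.fragment_id,
        start=hit.start,
        end=hit.end,
        strand=hit.strand,
        kind=kind,
        attributes={
            "family": hit.family,
            "consensus_start": str(hit.cstart),
            "consensus_end": str(hit.cend),
            "identity": f"{hit.percent_identity:.4f}",
            "completeness": hit.completeness,
        },
    )


def write_result_bundle(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write GFF3 + TSV reports + manifest; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lengths = {f.id: len(f.sequence) for f in result.fragments}

    records: list[AnnotationRecord] = []
    for fid in sorted(result.per_fragment):
        res = result.per_fragment[fid]
        for name in sorted(res.hits):
            for hit in res.hits[name]:
                records.append(_hit_record(hit, "monomer"))
            for rem in res.remnants[name]:
                records.append(_hit_record(rem, "remnant"))
            for array in res.arrays[name]:
                records.append(
                    AnnotationRecord(
                        fragment_id=fid,
                        start=array.start,
                        end=array.end,
                        strand=array.strand,
                        kind="array",
                        attributes={
                            "family": name,
                            "copy_number": str(array.copy_number),
                            "mean_identity": f"{array.mean_identity:.4f}",
                        },
                    )
                )
        for bp in res.breakpoints:
            records.append(
                AnnotationRecord(
                    fragment_id=fid,
                    start=bp.fragment_pos,
                    end=bp.fragment_pos + 1,
                    kind="breakpoint",
                    attributes={
                        "family": bp.family,
                        "side": bp.side,
                        "consensus_pos": str(bp.consensus_pos),
                    },
                )
            )
        for ev in res.events:
            records.append(
                AnnotationRecord(
                    fragment_id=fid,
                    start=ev.insert_interval[0],
                    end=ev.insert_interval[1],
                    strand=ev.strand,
                    kind="insert",
                    attributes={"event": ev.kind, "family": ev.host_family},
                )
            )
            if ev.tsd is not None:
                for iv in (ev.tsd.left_interval, ev.tsd.right_interval):
                    records.append(
                        AnnotationRecord(
                            fragment_id=fid,
                            start=iv[0],
                            end=iv[1],
                            kind="tsd",
                            attributes={"sequence": ev.tsd.sequence},
                        )
                    )
    files = {"annotations": out / "annotations.gff3"}
    write_gff3(records, files["annotations"], lengths)

    bp_rows = []
    for name in sorted(result.breakpoint_sets):
        bpset = result.breakpoint_sets[name]
        for ev in bpset.events:
            for bp in ev.members:
                bp_rows.append(
                    {
                        "fragment_id": bp.fragment_id,
                        "family": name,
                        "side": bp.side,
                        "fragment_pos": bp.fragment_pos,
                        "consensus_pos": bp.consensus_pos,
                        "support": ev.support,
                    }
                )
    bp_rows.sort(key=lambda r: (r["family"], r["fragment_id"], r["fragment_pos"]))
    files["breakpoints"] = out / "breakpoints.tsv"
    write_report(bp_rows, files["breakpoints"], "breakpoints")

    ct_rows = [
        result.cluster_results[name].as_row()
        for name in sorted(result.cluster_results)
    ]
    files["cluster_test"] = out / "cluster_test.tsv"
    write_report(ct_rows, files["cluster_test"], "cluster_test")

    ev_rows = [event_row(ev) for ev in result.all_events]
    files["events"] = out / "events.tsv"
    write_report(ev_rows, files["events"], "events")

    manifest = {
        "tool": "satjunction",
        "version": __version__,
        "seed": result.seed,
        "parameters": result.params,
        "n_fragments": len(result.fragments),
        "families": {
            name: {"length": fam.length}
            for name, fam in sorted(result.families.items())
        },
    }
    files["manifest"] = out / "manifest.json"
    with open(files["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return files


def run_all(config: PipelineConfig) -> PipelineResult:
    """File-level entry point: read inputs, analyse, write the bundle."""
    frag_path = Path(config.fragments)
    if not frag_path.exists():
        raise FileNotFoundError(f"fragments file not found: {frag_path}")
    fragments = read_fasta(frag_path)
    families = {}
    for fam_path in config.families:
        if not Path(fam_path).exists():
            raise FileNotFoundError(f"family file not found: {fam_path}")
        fam = SatDnaFamily.from_yaml(fam_path)
        families[fam.name] = fam
    result = analyze_fragments(fragments, families, config.seed, config.params)
    write_result_bundle(result, config.out_dir)
    return result


def _overlaps(interval: tuple[int, int], start: int, end: int) -> bool:
    """Detected interval covers most of the truth interval (>= 50%)."""
    ov = min(interval[1], end) - max(interval[0], start)
    return ov >= 0.5 * (end - start)


def validate_against_truth(
    result: PipelineResult,
    truths: list[TruthRecord],
    junction_tolerance: int = 3,
) -> dict:
    """Recovery metrics of a pipeline run against planted ground truth.

    Returns per-quantity metrics: junction recovery within the tolerance,
    exact copy-number accuracy of matched arrays, per-kind event recall,
    and TSD exactness among planted split insertions.
    """
    if not truths:
        raise ValueError("empty truth table")
    known = set(result.per_fragment)
    for t in truths:
        if t.fragment_id not in known:
            raise ValueError(f"truth fragment {t.fragment_id!r} not in results")

    junc_total = junc_ok = 0
    junc_errors: list[int] = []
    array_total = array_ok = 0
    ev_total: dict[str, int] = {}
    ev_ok: dict[str, int] = {}
    tsd_total = tsd_exact = 0

    for t in truths:
        res = result.per_fragment[t.fragment_id]
        for tj in t.junctions:
            junc_total += 1
            best = None
            for bp in res.breakpoints:
                if bp.side != tj["side"]:
                    continue
                err = abs(bp.fragment_pos - tj["fragment_pos"])
                if best is None or err < best:
                    best = err
            if best is not None:
                junc_errors.append(best)
                if best <= junction_tolerance:
                    junc_ok += 1
        for ta in t.arrays:
            array_total += 1
            matched = None
            for arrays in res.arrays.values():
                for arr in arrays:
                    ov = min(arr.end, ta["end"]) - max(arr.start, ta["start"])
                    if ov > 0 and (matched is None or ov > matched[0]):
                        matched = (ov, arr)
            if matched is not None and matched[1].copy_number == ta["n_complete"]:
                array_ok += 1
        # event matching tolerances: each array terminus flanking an event
        # carries +-2-3 nt of genuine ambiguity when the terminal monomer
        # base is mutated, so bookkeeping lengths combining two termini are
        # compared within +-6 nt while intervals must overlap the truth
        for te in t.events:
            kind = te["kind"]
            ev_total[kind] = ev_total.get(kind, 0) + 1
            found = [ev for ev in res.events if ev.kind == kind]
            if kind == "split_insertion":
                tsd_total += 1
                hit = [
                    ev
                    for ev in found
                    if _overlaps(ev.insert_interval, te["insert_start"], te["insert_end"])
                ]
                if hit:
                    ev_ok[kind] = ev_ok.get(kind, 0) + 1
                    want = te.get("tsd_realized", te.get("tsd"))
                    if any(
                        ev.tsd is not None and ev.tsd.sequence == want
                        for ev in hit
                    ):
                        tsd_exact += 1
            elif kind == "cut_and_replace":
                hit = [
                    ev
                    for ev in found
                    if _overlaps(ev.insert_interval, te["insert_start"], te["insert_end"])
                    and abs(ev.missing_len - te["missing_len"]) <= 6
                ]
                if hit:
                    ev_ok[kind] = ev_ok.get(kind, 0) + 1
            else:  # remnant_spacer
                hit = [
                    ev
                    for ev in found
                    if ev.spacer_len is not None
                    and abs(ev.spacer_len - te["spacer_len"]) <= 6
                    and abs(ev.missing_len - te["missing_len"]) <= 6
                ]
                if hit:
                    ev_ok[kind] = ev_ok.get(kind, 0) + 1

    metrics = {
        "junctions_total": junc_total,
        "junction_recovery": junc_ok / junc_total if junc_total else None,
        "junction_mean_abs_error": (
            sum(junc_errors) / len(junc_errors) if junc_errors else None
        ),
        "arrays_total": array_total,
        "copy_number_accuracy": array_ok / array_total if array_total else None,
        "tsd_exactness": tsd_exact / tsd_total if tsd_total else None,
    }
    for kind in sorted(ev_total):
        metrics[f"{kind}_total"] = ev_total[kind]
        metrics[f"{kind}_recall"] = ev_ok.get(kind, 0) / ev_total[kind]
    return metrics
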