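"""Benchmark experiments: recovery and calibration of the pipeline.

Each function generates its own synthetic data from an integer seed,
runs the relevant part of the pipeline, and returns summary numbers.
They are shared by the acceptance script, the acceptance tests and the
analysis drivers, so every reported figure is recomputed from scratch.

Conditions: monomer length 170 bp, monomer divergence drawn uniformly in
[5%, 10%] (the generator's default range is 5-15%; recovery experiments
use its low half, the regime of the cloned fragments' junction monomers),
flanks 100-500 bp.  Junction-recovery fragments carry no architecture
events — those get dedicated single-event batches.
"""

from __future__ import annotations

import numpy as np

from .cluster import (
    expected_pair_distance,
    mean_pairwise_distance,
    simulate_null,
    z_test,
)
from .consensus import MonomerAlignment, build_consensus
from .pipeline import analyze_fragments, validate_against_truth
from .simulate import SimConfig, generate_dataset, generate_family, mutate_monomer

RECOVERY_DIVERGENCE = (0.05, 0.10)


def _subseed(seed: int, k: int) -> int:
    # the domain tag avoids SeedSequence's trailing-zero padding collisions
    return int(np.random.SeedSequence([seed, 0x5E, k]).generate_state(1)[0]) & 0x7FFFFFFF


def null_mean_accuracy(seed: int, replicates: int = 100_000, n: int = 2,
                       L: int = 170) -> dict:
    """Monte-Carlo null mean vs the closed form (L^2 - 1) / (3 L)."""
    null = simulate_null(n, L, replicates=replicates, seed=seed)
    closed = expected_pair_distance(L)
    mc_se = null.sd / np.sqrt(replicates)
    return {
        "null_mean": null.mean,
        "closed_form": closed,
        "abs_error": abs(null.mean - closed),
        "mc_se": float(mc_se),
        "within_3se": bool(abs(null.mean - closed) <= 3 * mc_se),
        "replicates": replicates,
    }


def calibration_rejection_rate(
    seed: int,
    n_datasets: int = 2000,
    n: int = 16,
    L: int = 170,
    replicates: int = 100_000,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the one-sided Z-test under the uniform null.

    One simulated null distribution serves all datasets (same n, L);
    observed data are drawn from the very same uniform model, so the
    rejection rate should sit near alpha.
    """
    null = simulate_null(n, L, replicates=replicates, seed=_subseed(seed, 1))
    rng = np.random.default_rng(_subseed(seed, 2))
    rejections = 0
    for _ in range(n_datasets):
        obs = mean_pairwise_distance(rng.integers(0, L, size=n))
        _, p = z_test(obs, null.mean, null.sd)
        if p < alpha:
            rejections += 1
    return {
        "rate": rejections / n_datasets,
        "n_datasets": n_datasets,
        "alpha": alpha,
    }


def clustered_power(
    seed: int,
    runs: int = 200,
    n: int = 16,
    L: int = 166,
    interval: int = 12,
    replicates: int = 100_000,
    p_threshold: float = 1e-3,
) -> dict:
    """Power against breakpoints confined to a short interval.

    Mirrors the observed pattern of one family whose 16 junction events
    fall inside a 12-bp palindrome of a 166-bp (two-half) consensus.
    """
    null = simulate_null(n, L, replicates=replicates, seed=_subseed(seed, 1))
    rng = np.random.default_rng(_subseed(seed, 2))
    detected = 0
    for _ in range(runs):
        lo = int(rng.integers(0, L - interval))
        obs = mean_pairwise_distance(rng.integers(lo, lo + interval, size=n))
        _, p = z_test(obs, null.mean, null.sd)
        if p < p_threshold:
            detected += 1
    return {"fraction_detected": detected / runs, "runs": runs}


def breakpoint_recovery(
    seed: int,
    n_fragments: int = 500,
    tolerance_nt: int = 3,
) -> dict:
    """Junction-nucleotide recovery on plain array+flank fragments."""
    cfg = SimConfig(
        seed=_subseed(seed, 1),
        n_fragments=n_fragments,
        monomer_divergence=RECOVERY_DIVERGENCE,
        event_rates={},
    )
    fragments, truths, family = generate_dataset(cfg)
    result = analyze_fragments(fragments, [family], seed=_subseed(seed, 2))
    metrics = validate_against_truth(result, truths, junction_tolerance=tolerance_nt)
    return {
        "recovery": metrics["junction_recovery"],
        "mean_abs_error_nt": metrics["junction_mean_abs_error"],
        "copy_number_accuracy": metrics["copy_number_accuracy"],
        "n_junctions": metrics["junctions_total"],
        "n_fragments": n_fragments,
    }


def split_insertion_recovery(seed: int, n_fragments: int = 500) -> dict:
    """Recovery of planted TSD-flanked split insertions."""
    cfg = SimConfig(
        seed=_subseed(seed, 1),
        n_fragments=n_fragments,
        monomer_divergence=RECOVERY_DIVERGENCE,
        event_rates={"split_insertion": 1.0},
    )
    fragments, truths, family = generate_dataset(cfg)
    result = analyze_fragments(fragments, [family], seed=_subseed(seed, 2))
    metrics = validate_against_truth(result, truths)
    return {
        "recall": metrics["split_insertion_recall"],
        "tsd_exact": metrics["tsd_exactness"],
        "n_events": metrics["split_insertion_total"],
    }


def cut_and_replace_recovery(seed: int, n_fragments: int = 500) -> dict:
    """Recovery of planted cut-and-replace events (|delta| <= 10 bp)."""
    cfg = SimConfig(
        seed=_subseed(seed, 1),
        n_fragments=n_fragments,
        monomer_divergence=RECOVERY_DIVERGENCE,
        event_rates={"cut_and_replace": 1.0},
    )
    fragments, truths, family = generate_dataset(cfg)
    result = analyze_fragments(fragments, [family], seed=_subseed(seed, 2))
    metrics = validate_against_truth(result, truths)
    return {
        "recall": metrics["cut_and_replace_recall"],
        "n_events": metrics["cut_and_replace_total"],
    }


def consensus_recovery(
    seed: int,
    n_families: int = 1000,
    n_monomers: int = 20,
    divergence: float = 0.10,
    L: int = 170,
) -> dict:
    """Majority-rule consensus vs the generating master sequence."""
    rng = np.random.default_rng(_subseed(seed, 1))
    exact = 0
    for i in range(n_families):
        cfg = SimConfig(seed=_subseed(seed, 100 + i), monomer_length=L)
        family = generate_family(cfg)
        rows = [
            mutate_monomer(family.consensus, divergence, rng)
            for _ in range(n_monomers)
        ]
        consensus = build_consensus(MonomerAlignment(rows))
        if consensus == family.consensus:
            exact += 1
    return {"fraction_exact": exact / n_families, "n_families": n_families}
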