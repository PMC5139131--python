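# satjunction

Annotation and statistics of satellite-DNA junction regions.

Satellite DNAs (satDNAs) are tandemly repeated, non-coding sequences
whose monomers — besides forming long heterochromatic arrays — turn up
as short arrays and single copies interspersed in the genome, abutting
transposable elements and anonymous sequence.  The transition site
between a satellite monomer and whatever follows it (the **junction** or
**breakpoint** nucleotide) records how the repeat got there.
`satjunction` is a pipeline for studying such junctions on desk-scale
genomic fragments (cloned inserts or assembly excerpts, ~0.2–10 kb):

* **consensus & motifs** — majority-rule consensus monomers from gapped
  alignments; palindromes and conserved blocks on the consensus;
* **monomer scan** — local alignment of fragments against artificial
  consensus multimers; tandem-array segmentation with copy numbers;
  sub-monomer remnants in array flanks;
* **breakpoints** — the junction nucleotide, detected where windowed
  identity drops below 60% over a persistent 10-nt stretch and refined
  by a changepoint model; junctions sharing a consensus nucleotide
  collapse to single events;
* **clustering test** — the mean pairwise distance between junction
  positions against a 100,000-replicate discrete-uniform Monte-Carlo
  null, assessed with a one-sample Z-test (clustering = distances
  significantly smaller than the null);
* **architecture events** — monomers precisely split by TSD-flanked
  insertions, cut-and-replace events (a monomer segment substituted by
  unrelated sequence of comparable length), remnant/spacer patterns;
* **synthetic data** — a seeded generator of fragments with planted
  arrays, junctions, events and machine-readable truth tables, driving
  all validation.

The statistic at the core: for n deduplicated junction events at
consensus positions p₁…pₙ on a monomer of length L, the observed mean
pairwise distance d̄ = (2/n(n−1)) Σᵢ<ⱼ |pᵢ−pⱼ| is compared with the null
of n i.i.d. discrete-uniform positions, whose mean has the closed form
E|X−Y| = (L²−1)/(3L); significance is z = (d̄ − μ̂₀)/σ̂₀ with the
lower-tail normal p-value.

## Worked example

```python
import satjunction as sj

# a synthetic family (170-bp monomer, two palindromes) and 12 fragments
# whose junctions are confined to the 12-bp palindrome at (127, 139)
cfg = sj.SimConfig(seed=43, n_fragments=12, event_rates={},
                   breakpoint_mode=("clustered", (127, 139)))
fragments, truth, family = sj.generate_dataset(cfg)

result = sj.analyze_fragments(fragments, [family], seed=7)
ct = result.cluster_results[family.name]
print(f"n={ct.n} events, observed {ct.obs_mean_dist:.2f} bp, "
      f"null {ct.null_mean:.2f}±{ct.null_sd:.2f} bp, "
      f"z={ct.z:.2f}, p={ct.p:.3g}")
```

prints

```
n=15 events, observed 4.23 bp, null 56.62±7.43 bp, z=-7.05, p=8.65e-13
```

i.e. the 15 deduplicated junction events have a mean pairwise distance
of ~4 bp where ~57 bp would be expected under uniform placement —
decisive clustering, mirroring a family whose breakpoints concentrate in
a palindrome.  Running the same on `breakpoint_mode="uniform"` data
gives p ≈ 0.1–0.9: scattered junctions, no signal.

The same analysis is available stepwise (`scan_fragment`,
`segment_arrays`, `call_array_junctions`, `dedupe`, `run_cluster_test`,
`classify_pair`, `detect_tsd`, …), as numbered drivers under
`analysis/` (simulate → annotate → junction clustering → architecture →
recovery validation, writing tables under `results/`), and as a CLI:

```
satjunction simulate   --config sim.yaml --out-prefix sim/
satjunction scan       --fragments f.fasta --family fam.yaml --out hits.gff3
satjunction breakpoints --fragments f.fasta --family fam.yaml --out bp.tsv
satjunction cluster-test --breakpoints bp.tsv --family fam.yaml --seed 42 --out ct.tsv
satjunction run-all    --config pipeline.yaml
```

Outputs are plain formats: FASTA, GFF3 (1-based inclusive; internal
coordinates are 0-based half-open), TSV reports with fixed schemas, a
JSON run manifest.  Re-running with identical inputs and seed is
byte-identical.

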