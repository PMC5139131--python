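#!/usr/bin/env python
"""Generate the synthetic study datasets.

Two datasets stand in for the two junction-distribution regimes seen in
satellite families: one whose array junctions fall uniformly along the
monomer (the scattered regime) and one whose junctions are confined to a
12-bp interval containing the longer planted palindrome (the clustered
regime).  Both use the generator defaults otherwise: 20 fragments, 1-17
monomer copies of a 170-bp family, 5-15% monomer divergence, 100-500 bp
flanks, and the default architecture-event rates.
"""

from pathlib import Path

import satjunction as sj

OUT = Path("results/sim")
SEED = 42


def main() -> None:
    uniform_cfg = sj.SimConfig(seed=SEED, breakpoint_mode="uniform",
                               family_name="uniformfam")
    sj.generate_dataset(uniform_cfg, out_dir=OUT / "uniform")

    family = sj.generate_family(sj.SimConfig(seed=SEED + 1,
                                             family_name="clusterfam"))
    pal = max(family.palindromes, key=lambda iv: iv[1] - iv[0])
    clustered_cfg = sj.SimConfig(
        seed=SEED + 1,
        breakpoint_mode=("clustered", pal),
        family_name="clusterfam",
    )
    sj.generate_dataset(clustered_cfg, out_dir=OUT / "clustered")

    print(f"uniform dataset : {OUT/'uniform'} (junctions anywhere on the monomer)")
    print(f"clustered dataset: {OUT/'clustered'} "
          f"(junctions inside the {pal[1]-pal[0]}-bp palindrome at {pal})")


if __name__ == "__main__":
    main()
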