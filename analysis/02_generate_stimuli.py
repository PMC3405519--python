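#!/usr/bin/env python
"""Generate the synthetic study materials.

Samples the default study conditions — a 1000-word Zipfian lexicon over a
20-segment inventory and 50 source/novel/baseline triplets whose deviation
point lies 1-3 segments before word offset, each source word unique before
its DP — and writes them to results/ as TSV.
"""

from pathlib import Path

from lexicohort import SynthConfig, generate_lexicon, generate_triplets
from lexicohort.experiment import write_triplets
from lexicohort.lexicon import write_lexicon

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 12345


def main() -> None:
    config = SynthConfig(seed=SEED)
    lexicon = generate_lexicon(config)
    triplets = generate_triplets(lexicon, config)
    OUT.mkdir(exist_ok=True)
    write_lexicon(lexicon, OUT / "synthetic_lexicon.tsv")
    write_triplets(triplets, OUT / "synthetic_triplets.tsv")
    ups = [t.up_index for t in triplets]
    dps = [t.dp_index for t in triplets]
    print(f"lexicon: {len(lexicon)} words, total {lexicon.total_frequency:.0f} "
          "per million (Zipf exponent 1)")
    print(f"triplets: {len(triplets)}; UP range {min(ups)}-{max(ups)}, "
          f"DP range {min(dps)}-{max(dps)}, UP < DP for all")
    print(f"written to {OUT}/synthetic_lexicon.tsv and "
          f"{OUT}/synthetic_triplets.tsv (seed {SEED})")


if __name__ == "__main__":
    main()
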