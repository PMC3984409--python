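#!/usr/bin/env python
"""Generate the canonical synthetic ten-trial home-and-away study.

Writes the raw per-trial OTU tables, pot metadata and planted truth under
scratch/synthetic_study/ (large, regenerable) and prints a design summary.
Downstream analysis scripts regenerate the same study deterministically if
the scratch copy is absent, so this step is optional but convenient.
"""

import argparse
from pathlib import Path

from psfscreen.pipeline import write_study
from psfscreen.synthetic import SyntheticConfig, generate_study

ROOT = Path(__file__).resolve().parent.parent
DEFAULT_SEED = 42


def load_or_generate(seed: int = DEFAULT_SEED):
    return generate_study(SyntheticConfig(seed=seed))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = ap.parse_args()

    study = load_or_generate(args.seed)
    out = ROOT / "scratch" / "synthetic_study"
    write_study(study, out)

    n_pots = sum(len(t.metadata) for t in study)
    t0 = study.trials[0]
    print(f"wrote {len(study.trials)} trials ({n_pots} pots) to {out}")
    print(f"OTUs per group: {t0.bacteria.n_otus} bacteria, {t0.fungi.n_otus} fungi")
    print(
        f"trial T01 planted structure: {len(t0.truth.affinity_otus)} affinity OTUs, "
        f"{len(t0.truth.effect_otus)} effect OTUs, {len(t0.truth.psf_otus)} true PSF OTUs"
    )


if __name__ == "__main__":
    main()
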