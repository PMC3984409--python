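#!/usr/bin/env python
"""Affinity-effect regressions, candidate screening, and cross-trial tests.

Per trial x group: OLS of each plant's effect index on the affinity index,
then the dual 2.5 %-tail screen for potentially important feedback OTUs.
Study level: per-trial candidate counts, paired t-tests comparing ragweed
vs sunflower counts, screen recall/precision against the planted truth.

Writes results/regressions.tsv, results/screen_counts.tsv and
results/paired_t_tests.tsv.
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from psfscreen.pipeline import compute_index_table
from psfscreen.screen import (
    count_by_plant,
    paired_t_test,
    regress_effect_on_affinity,
    screen_trial,
)

ROOT = Path(__file__).resolve().parent.parent
_sim = importlib.util.spec_from_file_location("sim01", ROOT / "analysis" / "01_simulate.py")
sim01 = importlib.util.module_from_spec(_sim)
_sim.loader.exec_module(sim01)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=sim01.DEFAULT_SEED)
    ap.add_argument("--q", type=float, default=0.025)
    args = ap.parse_args()

    study = sim01.load_or_generate(args.seed)
    reg_rows, screens = [], []
    recalls, precisions = [], []
    for trial in study:
        for group, pref in (("bacteria", "b_"), ("fungi", "f_")):
            res = compute_index_table(trial.table(group), trial.metadata)
            for plant in ("ragweed", "sunflower"):
                r = regress_effect_on_affinity(res.index_table, plant)
                reg_rows.append(
                    {
                        "trial_id": r.trial_id, "group": r.group, "plant": r.plant,
                        "slope": round(r.slope, 3), "r_squared": round(r.r_squared, 3),
                        "p_value": f"{r.p_value:.2g}", "code": r.code,
                    }
                )
            sc = screen_trial(res.index_table, q=args.q)
            screens.append(sc)
            psf = {o for o in trial.truth.psf_otus if o.startswith(pref)}
            found = sc.important_ragweed | sc.important_sunflower
            recalls.append(len(found & psf) / len(psf))
            precisions.append(len(found & psf) / max(len(found), 1))

    out_dir = ROOT / "results"
    out_dir.mkdir(exist_ok=True)
    regs = pd.DataFrame(reg_rows)
    regs.to_csv(out_dir / "regressions.tsv", sep="\t", index=False)
    counts = count_by_plant(screens)
    counts.to_csv(out_dir / "screen_counts.tsv", sep="\t")

    paired_rows = []
    for group in ("bacteria", "fungi"):
        t = paired_t_test(counts[f"{group}_ragweed"], counts[f"{group}_sunflower"])
        paired_rows.append(
            {
                "group": group, "mean_difference": round(t.mean_difference, 2),
                "t_statistic": round(t.t_statistic, 3), "df": t.df,
                "p_value": round(t.p_value, 4),
            }
        )
    pd.DataFrame(paired_rows).to_csv(out_dir / "paired_t_tests.tsv", sep="\t", index=False)

    sig = (regs["code"] != "ns").mean()
    rag_pos = ((regs["plant"] == "ragweed") & (regs["slope"] > 0)).sum()
    print(f"significant affinity-effect regressions: {100 * sig:.1f}% of {len(regs)}")
    print(f"positive ragweed slopes: {rag_pos}/20 (negative-feedback signature)")
    print(
        f"screen vs planted truth: recall {sum(recalls)/len(recalls):.2f}, "
        f"precision {sum(precisions)/len(precisions):.2f}"
    )
    for row in paired_rows:
        print(
            f"{row['group']}: ragweed has {row['mean_difference']} more candidates per "
            f"trial (t={row['t_statistic']}, df={row['df']}, p={row['p_value']})"
        )


if __name__ == "__main__":
    main()
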