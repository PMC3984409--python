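"""End-to-end orchestration of the affinity-effect analysis for a study.

Per trial and microbial group: Hellinger transform -> Bray-Curtis -> CAP on
the 20 home pots (affinity index and its variance fraction) -> first-component
PLSR per plant on that plant's 20 home + away pots (effect indices and
variance fractions) -> effect-versus-affinity regressions -> dual-tail screen.
Study level: per-trial candidate counts, paired t-test of ragweed versus
sunflower counts per group, pooled three-way perMANOVA, and NMDS.

Trials are processed independently and never pooled before the cross-trial
t-test; all stochastic stages (perMANOVA permutations, NMDS restarts) draw
child streams of the single top-level seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from psfscreen.data_model import (
    GROUPS,
    PLANTS,
    IndexTable,
    OTUTable,
    PotMetadata,
    ValidationError,
    read_metadata,
    read_otu_table,
    subset,
    write_metadata,
    write_otu_table,
)
from psfscreen.community import NMDSResult, PermanovaTable, nmds, permanova_from_metadata
from psfscreen.ordination import cap_constrained, orient_ragweed_negative, pcoa, wa_affinity_scores
from psfscreen.plsr import effect_index, fit_plsr1
from psfscreen.screen import (
    PairedTTestResult,
    RegressionResult,
    ScreenResult,
    count_by_plant,
    paired_t_test,
    regress_effect_on_affinity,
    screen_trial,
    summarize_significance,
)
from psfscreen.synthetic import StudyBundle, SyntheticConfig, TrialData, generate_study
from psfscreen.transforms import bray_curtis, hellinger

__all__ = [
    "RunConfig",
    "TrialGroupResult",
    "StudyReport",
    "compute_index_table",
    "analyze_study",
    "run_study",
    "load_study",
    "write_study",
]


@dataclass
class RunConfig:
    """Configuration of a full study run.

    Exactly one of ``synthetic`` or ``input_dir`` must be set. All stochastic
    stages derive substreams from ``seed``.
    """

    synthetic: SyntheticConfig | None = None
    input_dir: str | Path | None = None
    q: float = 0.025
    alpha: float = 0.05
    n_perm: int = 1000
    nmds_starts: int = 20
    seed: int = 0
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ValidationError("set exactly one of synthetic config or input_dir")


@dataclass
class TrialGroupResult:
    """Indices and summaries for one trial x microbial group."""

    index_table: IndexTable
    affinity_variance_fraction: float
    effect_x_variance: dict[str, float]
    effect_y_variance: dict[str, float]
    regressions: list[RegressionResult] = field(default_factory=list)
    screen: ScreenResult | None = None


@dataclass
class StudyReport:
    results: list[TrialGroupResult]
    variance_summary: pd.DataFrame
    regression_table: pd.DataFrame
    count_table: pd.DataFrame
    paired_tests: dict[str, PairedTTestResult]
    significant_fraction: float
    permanova: dict[str, PermanovaTable]
    nmds: dict[str, NMDSResult]


def compute_index_table(table: OTUTable, meta: Sequence[PotMetadata]) -> TrialGroupResult:
    """Affinity and effect indices for one trial x group, plus screens.

    The affinity index uses only home pots; each plant's effect index uses
    the pots whose final plant is that species (home + away).
    """
    trial_meta = [m for m in meta if m.trial_id == table.trial_id]

    home = subset(table, trial_meta, lambda m: m.home)
    h_home = hellinger(home)
    pc = pcoa(bray_curtis(h_home))
    training = {m.pot_id: m.training_plant for m in trial_meta}
    constraint = [1.0 if training[s] == "sunflower" else 0.0 for s in home.sample_ids]
    cap = orient_ragweed_negative(cap_constrained(pc, constraint), trial_meta)
    affinity = wa_affinity_scores(h_home, cap.site_scores)

    effects: dict[str, np.ndarray] = {}
    x_var: dict[str, float] = {}
    y_var: dict[str, float] = {}
    biomass = {m.pot_id: m.biomass for m in trial_meta}
    for plant in PLANTS:
        sub = subset(table, trial_meta, lambda m, p=plant: m.final_plant == p)
        h = hellinger(sub)
        y = np.array([biomass[s] for s in sub.sample_ids])
        try:
            plsr = fit_plsr1(h, y)
        except ValidationError as exc:
            raise ValidationError(
                f"effect stage failed for trial {table.trial_id!r}, group "
                f"{table.group!r}, plant {plant!r}: {exc}"
            ) from exc
        effects[plant] = effect_index(plsr)
        x_var[plant] = plsr.x_variance_fraction
        y_var[plant] = plsr.y_variance_fraction

    index_table = IndexTable(
        trial_id=table.trial_id,
        group=table.group,
        otu_ids=list(table.otu_ids),
        affinity=affinity,
        effect_ragweed=effects["ragweed"],
        effect_sunflower=effects["sunflower"],
    )
    return TrialGroupResult(
        index_table=index_table,
        affinity_variance_fraction=cap.affinity_variance_fraction,
        effect_x_variance=x_var,
        effect_y_variance=y_var,
    )


def _pooled_table(study: StudyBundle | list[TrialData], group: str) -> OTUTable:
    trials = list(study)
    first = trials[0].table(group)
    for t in trials[1:]:
        if t.table(group).otu_ids != first.otu_ids:
            raise ValidationError("trials must share the same OTU columns to pool")
    return OTUTable(
        sample_ids=[s for t in trials for s in t.table(group).sample_ids],
        otu_ids=list(first.otu_ids),
        values=np.vstack([t.table(group).values for t in trials]),
        group=group,
        trial_id="pooled",
    )


def analyze_study(
    study: StudyBundle,
    q: float = 0.025,
    alpha: float = 0.05,
    n_perm: int = 1000,
    nmds_starts: int = 20,
    seed: int = 0,
    community: bool = True,
) -> StudyReport:
    """Run the full analysis over a study bundle."""
    results: list[TrialGroupResult] = []
    for trial in study:
        for group in GROUPS:
            res = compute_index_table(trial.table(group), trial.metadata)
            res.regressions = [
                regress_effect_on_affinity(res.index_table, plant) for plant in PLANTS
            ]
            res.screen = screen_trial(res.index_table, q=q)
            results.append(res)

    var_rows = []
    reg_rows = []
    for res in results:
        it = res.index_table
        for plant in PLANTS:
            var_rows.append(
                {
                    "trial_id": it.trial_id,
                    "group": it.group,
                    "plant": plant,
                    "affinity_variance_pct": 100 * res.affinity_variance_fraction,
                    "effect_community_variance_pct": 100 * res.effect_x_variance[plant],
                    "effect_biomass_variance_pct": 100 * res.effect_y_variance[plant],
                }
            )
        for r in res.regressions:
            reg_rows.append(
                {
                    "trial_id": r.trial_id,
                    "group": r.group,
                    "plant": r.plant,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "r_squared": r.r_squared,
                    "p_value": r.p_value,
                    "code": r.code,
                    "n_otus": r.n_otus,
                }
            )
    variance_summary = pd.DataFrame(var_rows)
    regression_table = pd.DataFrame(reg_rows)
    count_table = count_by_plant([r.screen for r in results])

    paired: dict[str, PairedTTestResult] = {}
    if len(count_table) >= 2:
        for group in GROUPS:
            try:
                paired[group] = paired_t_test(
                    count_table[f"{group}_ragweed"], count_table[f"{group}_sunflower"]
                )
            except ValidationError:
                # degenerate (identical per-trial differences): t undefined
                pass

    all_regressions = [r for res in results for r in res.regressions]
    significant_fraction = summarize_significance(all_regressions, alpha=alpha)

    perm: dict[str, PermanovaTable] = {}
    nm: dict[str, NMDSResult] = {}
    if community:
        meta = study.metadata
        ss = np.random.SeedSequence(seed)
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * len(GROUPS))]
        for i, group in enumerate(GROUPS):
            pooled = _pooled_table(study, group)
            d = bray_curtis(hellinger(pooled))
            perm[group] = permanova_from_metadata(
                d, meta, n_perm=n_perm, seed=child_seeds[2 * i]
            )
            nm[group] = nmds(d, k=2, n_starts=nmds_starts, seed=child_seeds[2 * i + 1])

    return StudyReport(
        results=results,
        variance_summary=variance_summary,
        regression_table=regression_table,
        count_table=count_table,
        paired_tests=paired,
        significant_fraction=significant_fraction,
        permanova=perm,
        nmds=nm,
    )


def load_study(input_dir: str | Path) -> StudyBundle:
    """Load a study written by ``write_study`` / the simulate command.

    Layout: one subdirectory per trial containing ``otu_table.bacteria.tsv``,
    ``otu_table.fungi.tsv`` and ``metadata.tsv``.
    """
    input_dir = Path(input_dir)
    trial_dirs = sorted(p for p in input_dir.iterdir() if p.is_dir())
    if not trial_dirs:
        raise ValidationError(f"no trial subdirectories under {input_dir}")
    trials = []
    for td in trial_dirs:
        meta = read_metadata(td / "metadata.tsv")
        trial_id = meta[0].trial_id
        tables = {
            g: read_otu_table(td / f"otu_table.{g}.tsv", group=g, trial_id=trial_id)
            for g in GROUPS
        }
        trials.append(
            TrialData(
                trial_id=trial_id,
                bacteria=tables["bacteria"],
                fungi=tables["fungi"],
                metadata=meta,
                truth=None,
            )
        )
    return StudyBundle(config=None, trials=trials)


def write_study(study: StudyBundle, output_dir: str | Path) -> None:
    """Write per-trial OTU tables, metadata and (if present) truth records."""
    output_dir = Path(output_dir)
    for trial in study:
        td = output_dir / trial.trial_id
        td.mkdir(parents=True, exist_ok=True)
        for g in GROUPS:
            write_otu_table(trial.table(g), td / f"otu_table.{g}.tsv")
        write_metadata(trial.metadata, td / "metadata.tsv")
        if trial.truth is not None:
            rows = []
            for otu, side in sorted(trial.truth.affinity_otus.items()):
                rows.append((otu, "affinity", side, "", ""))
            for otu, (gr, gs) in sorted(trial.truth.effect_otus.items()):
                rows.append((otu, "effect", "", f"{gr:.15g}", f"{gs:.15g}"))
            for otu in sorted(trial.truth.psf_otus):
                rows.append((otu, "psf", "", "", ""))
            pd.DataFrame(
                rows, columns=["otu_id", "role", "side", "gamma_ragweed", "gamma_sunflower"]
            ).to_csv(td / "truth.tsv", sep="\t", index=False)


def _comment_header(config: RunConfig) -> list[str]:
    items = [f"seed={config.seed}", f"q={config.q}", f"alpha={config.alpha}", f"n_perm={config.n_perm}"]
    return ["psfscreen run", " ".join(items)]


def run_study(config: RunConfig) -> StudyReport:
    """Run a study from a config; write result tables when output_dir is set."""
    if config.synthetic is not None:
        study = generate_study(config.synthetic)
    else:
        study = load_study(config.input_dir)
    report = analyze_study(
        study,
        q=config.q,
        alpha=config.alpha,
        n_perm=config.n_perm,
        nmds_starts=config.nmds_starts,
        seed=config.seed,
    )
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = _comment_header(config)
        for res in report.results:
            it = res.index_table
            it.write(out / f"indices.{it.trial_id}.{it.group}.tsv", comments=header)

        def _write(df: pd.DataFrame, name: str, index: bool) -> None:
            with open(out / name, "w") as fh:
                for c in header:
                    fh.write(f"# {c}\n")
                df.to_csv(fh, sep="\t", index=index, na_rep="NA", float_format="%.6g")

        _write(report.variance_summary, "variance_summary.tsv", index=False)
        _write(report.regression_table, "regressions.tsv", index=False)
        _write(report.count_table, "counts.tsv", index=True)
        paired_df = pd.DataFrame(
            {
                "group": list(report.paired_tests),
                "mean_difference": [t.mean_difference for t in report.paired_tests.values()],
                "t_statistic": [t.t_statistic for t in report.paired_tests.values()],
                "df": [t.df for t in report.paired_tests.values()],
                "p_value": [t.p_value for t in report.paired_tests.values()],
            }
        )
        _write(paired_df, "paired_t_tests.tsv", index=False)
        for group, pt in report.permanova.items():
            _write(pt.table, f"permanova.{group}.tsv", index=True)
        for group, nr in report.nmds.items():
            coords = pd.DataFrame(
                nr.coordinates, index=nr.ids, columns=[f"NMDS{i+1}" for i in range(nr.coordinates.shape[1])]
            )
            coords.index.name = "pot_id"
            _write(coords, f"nmds.{group}.tsv", index=True)
    return report
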