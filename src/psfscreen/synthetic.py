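"""Synthetic multi-trial home-and-away datasets with known ground truth.

The generator emulates the design of the field study the pipeline targets:
independent trials, each with 40 pots (2 training plants x 2 final plants x
10 replicates), bacterial and fungal OTU tables of continuous fingerprint
intensities, and per-pot plant dry biomass. Each trial draws a fresh
log-normal source pool of baseline OTU abundances, so between-trial turnover
dominates community variance, as it does in real multi-site soil data.

A minority of OTUs carry plant *affinity*: their expected abundance is
multiplied by ``affinity_multiplier`` in pots whose training plant matches
their side (the three real rounds of conditioning are collapsed into this
single multiplier). A minority carry *effects*: per-plant coefficients
gamma(plant) act on the Hellinger-transformed abundance, so pot biomass is

    y = beta0(final plant) + sum_j gamma_j(final plant) * h_j + eps,
    eps ~ Normal(0, noise_sd^2),  y clipped at 0.

``couple_sign`` correlates an OTU's affinity side with the sign of its effect
on its own plant: -1 means high-affinity microbes harm the plant they
associate with, the structure of negative plant-soil feedback.

Identical seeds give bit-identical output; each trial uses an independent
child stream of the top-level seed, so a trial's data do not change when
other trials are added or removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from psfscreen.data_model import GROUPS, OTUTable, PotMetadata, ValidationError
from psfscreen.transforms import hellinger

__all__ = ["SyntheticConfig", "TruthRecord", "TrialData", "StudyBundle", "generate_trial", "generate_study"]

#: dry biomass intercepts in grams; sunflower is the larger plant
BETA0 = {"ragweed": 15.0, "sunflower": 25.0}

#: log-scale center of baseline fingerprint peak intensities
LOG_BASELINE_MU = np.log(100.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults reproduce a ten-trial, 40-pot design with 500 OTUs per group,
    4 % of OTUs carrying plant affinity (balanced between sides), 4 %
    carrying biomass effects (half of them drawn from the affinity set, so
    the true-PSF intersection is a deliberate, non-trivial set), strong
    affinity and effect signal, and negative feedback coupling.
    """

    n_trials: int = 10
    n_pots_per_cell: int = 10
    n_otus: int = 500
    frac_affinity: float = 0.04
    frac_effect: float = 0.04
    frac_effect_from_affinity: float = 0.7
    affinity_multiplier: float = 6.0
    effect_scale: float = 6.0
    couple_sign: float = -1.0
    noise_sd: float = 0.5
    baseline_lognormal_sigma: float = 1.5
    pot_lognormal_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.frac_affinity < 1.0 and 0.0 < self.frac_effect < 1.0):
            raise ValidationError("frac_affinity and frac_effect must lie in (0, 1)")
        if not (0.0 <= self.frac_effect_from_affinity <= 1.0):
            raise ValidationError("frac_effect_from_affinity must lie in [0, 1]")
        if self.n_pots_per_cell < 2:
            raise ValidationError("need at least 2 pots per treatment cell")
        if self.n_trials < 1 or self.n_otus < 2:
            raise ValidationError("need at least 1 trial and 2 OTUs")
        if self.affinity_multiplier < 1.0:
            raise ValidationError("affinity_multiplier must be >= 1")
        if not (-1.0 <= self.couple_sign <= 1.0):
            raise ValidationError("couple_sign must lie in [-1, 1]")
        if self.noise_sd < 0 or self.effect_scale < 0:
            raise ValidationError("scales must be nonnegative")


@dataclass
class TruthRecord:
    """Planted structure of one synthetic trial.

    ``affinity_otus`` maps otu_id to its side: -1 = ragweed, +1 = sunflower
    (the sign convention of the oriented canonical axis). ``effect_otus``
    maps otu_id to (gamma_ragweed, gamma_sunflower). ``psf_otus`` is the
    intersection: taxa planted with both traits, the true feedback candidates.
    """

    affinity_otus: dict[str, int]
    effect_otus: dict[str, tuple[float, float]]
    psf_otus: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.psf_otus <= (set(self.affinity_otus) & set(self.effect_otus)):
            raise ValidationError("psf_otus must lie in the affinity/effect intersection")


@dataclass
class TrialData:
    trial_id: str
    bacteria: OTUTable
    fungi: OTUTable
    metadata: list[PotMetadata]
    truth: TruthRecord

    def table(self, group: str) -> OTUTable:
        return self.bacteria if group == "bacteria" else self.fungi


@dataclass
class StudyBundle:
    config: SyntheticConfig
    trials: list[TrialData]

    def __iter__(self) -> Iterator[TrialData]:
        return iter(self.trials)

    @property
    def metadata(self) -> list[PotMetadata]:
        return [m for t in self.trials for m in t.metadata]


def _plant_of_side(side: int) -> str:
    return "ragweed" if side < 0 else "sunflower"


def _plant_truth(cfg: SyntheticConfig, rng: np.random.Generator, prefix: str):
    """Choose affinity/effect OTUs and draw their parameters for one group."""
    ids = [f"{prefix}OTU{j:04d}" for j in range(cfg.n_otus)]
    n_aff = max(2, round(cfg.frac_affinity * cfg.n_otus))
    n_eff = max(2, round(cfg.frac_effect * cfg.n_otus))
    n_psf = round(cfg.frac_effect_from_affinity * n_eff)
    n_psf = min(n_psf, n_aff)

    perm = rng.permutation(cfg.n_otus)
    aff_idx = perm[:n_aff]
    # balanced sides: alternate so neither tail of the affinity axis overflows
    sides = np.array([-1 if k % 2 == 0 else 1 for k in range(n_aff)])
    affinity = {ids[j]: int(s) for j, s in zip(aff_idx, sides)}

    psf_idx = aff_idx[rng.permutation(n_aff)[:n_psf]]
    non_aff = perm[n_aff:]
    pure_idx = non_aff[: n_eff - n_psf]

    effects: dict[str, tuple[float, float]] = {}
    for j in psf_idx:
        side = affinity[ids[j]]
        own = _plant_of_side(side)
        own_sign = 1.0 if rng.random() < (1.0 + cfg.couple_sign) / 2.0 else -1.0
        g_own = own_sign * abs(rng.normal(0.0, cfg.effect_scale))
        g_other = rng.normal(0.0, cfg.effect_scale)
        g = (g_own, g_other) if own == "ragweed" else (g_other, g_own)
        effects[ids[j]] = g
    for j in pure_idx:
        effects[ids[j]] = (
            rng.normal(0.0, cfg.effect_scale),
            rng.normal(0.0, cfg.effect_scale),
        )
    psf = {ids[j] for j in psf_idx}
    return ids, affinity, effects, psf


def _group_tables(cfg: SyntheticConfig, rng: np.random.Generator, prefix: str, meta: list[PotMetadata]):
    ids, affinity, effects, psf = _plant_truth(cfg, rng, prefix)
    base_mu = rng.normal(LOG_BASELINE_MU, cfg.baseline_lognormal_sigma, size=cfg.n_otus)
    logmult = np.log(cfg.affinity_multiplier)
    mult = np.zeros((len(meta), cfg.n_otus))
    for i, m in enumerate(meta):
        for otu, side in affinity.items():
            if _plant_of_side(side) == m.training_plant:
                mult[i, ids.index(otu)] = logmult
    noise = rng.normal(0.0, cfg.pot_lognormal_sigma, size=mult.shape)
    values = np.exp(base_mu[None, :] + mult + noise)
    return ids, values, affinity, effects, psf


def generate_trial(config: SyntheticConfig, trial_index: int) -> TrialData:
    """Generate one trial: bacterial and fungal tables, metadata, truth.

    Deterministic in (config.seed, trial_index) alone.
    """
    if not (0 <= trial_index < config.n_trials):
        raise ValidationError(f"trial_index {trial_index} outside [0, {config.n_trials})")
    ss = np.random.SeedSequence(config.seed, spawn_key=(trial_index,))
    rng = np.random.default_rng(ss)
    trial_id = f"T{trial_index + 1:02d}"

    meta_stub = []
    k = 0
    for training in ("ragweed", "sunflower"):
        for final in ("ragweed", "sunflower"):
            for _ in range(config.n_pots_per_cell):
                meta_stub.append((f"{trial_id}_p{k:03d}", training, final))
                k += 1
    # placeholder biomass; filled after community effects are known
    meta = [PotMetadata(p, trial_id, tr, fi, 0.0) for p, tr, fi in meta_stub]

    tables = {}
    truth_aff: dict[str, int] = {}
    truth_eff: dict[str, tuple[float, float]] = {}
    truth_psf: set[str] = set()
    contribution = np.zeros(len(meta))
    for group, prefix in zip(GROUPS, ("b_", "f_")):
        ids, values, affinity, effects, psf = _group_tables(config, rng, prefix, meta)
        table = OTUTable(
            sample_ids=[m.pot_id for m in meta],
            otu_ids=ids,
            values=values,
            group=group,
            trial_id=trial_id,
        )
        tables[group] = table
        truth_aff.update(affinity)
        truth_eff.update(effects)
        truth_psf |= psf
        h = hellinger(table).values
        col = {o: j for j, o in enumerate(ids)}
        for otu, (g_rag, g_sun) in effects.items():
            j = col[otu]
            for i, m in enumerate(meta):
                g = g_rag if m.final_plant == "ragweed" else g_sun
                contribution[i] += g * h[i, j]

    eps = rng.normal(0.0, config.noise_sd, size=len(meta))
    biomass = np.clip(
        np.array([BETA0[m.final_plant] for m in meta]) + contribution + eps, 0.0, None
    )
    meta = [
        PotMetadata(m.pot_id, m.trial_id, m.training_plant, m.final_plant, float(b))
        for m, b in zip(meta, biomass)
    ]
    return TrialData(
        trial_id=trial_id,
        bacteria=tables["bacteria"],
        fungi=tables["fungi"],
        metadata=meta,
        truth=TruthRecord(truth_aff, truth_eff, truth_psf),
    )


def generate_study(config: SyntheticConfig) -> StudyBundle:
    """Generate all trials of a study; trials are mutually independent."""
    return StudyBundle(config=config, trials=[generate_trial(config, i) for i in range(config.n_trials)])
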