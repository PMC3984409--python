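"""Core domain types and TSV I/O for home-and-away trial data.

Orientation convention used throughout the package: samples (pots) are rows,
OTUs are columns. Community tables are tab-separated, first column the sample
id, header row the OTU ids. Missing index values are serialized as ``NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

PLANTS = ("ragweed", "sunflower")
GROUPS = ("bacteria", "fungi")

__all__ = [
    "PLANTS",
    "GROUPS",
    "ValidationError",
    "OTUTable",
    "PotMetadata",
    "DissimilarityMatrix",
    "IndexTable",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "subset",
    "validate_pot_ids",
]


class ValidationError(ValueError):
    """Raised when an input table or record violates a domain invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OTUTable:
    """Nonnegative sample-by-OTU abundance matrix (e.g., ARISA peak heights).

    Parameters
    ----------
    sample_ids : list of str
        Pot identifiers, one per row; unique.
    otu_ids : list of str
        OTU identifiers, one per column; unique.
    values : ndarray of shape (n_samples, n_otus)
        Nonnegative intensities; every row must contain at least one
        strictly positive entry.
    group : {"bacteria", "fungi"}
    trial_id : str
    """

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray
    group: str
    trial_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.otu_ids) != m:
            raise ValidationError(f"{len(self.otu_ids)} OTU ids for {m} columns")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at row {self.sample_ids[bad[0]]!r}, "
                f"column {self.otu_ids[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at row {self.sample_ids[bad[0]]!r}, "
                f"column {self.otu_ids[bad[1]]!r}"
            )
        empty = np.flatnonzero(~(self.values > 0).any(axis=1))
        if empty.size:
            raise ValidationError(f"row {self.sample_ids[empty[0]]!r} has no positive entry")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_otus(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)


@dataclass(frozen=True)
class PotMetadata:
    """One pot of a home-and-away trial.

    ``home`` is True when the plant grown in the final phase is the same
    species that conditioned ("trained") the soil.
    """

    pot_id: str
    trial_id: str
    training_plant: str
    final_plant: str
    biomass: float

    def __post_init__(self) -> None:
        if self.training_plant not in PLANTS:
            raise ValidationError(
                f"pot {self.pot_id!r}: unknown training plant {self.training_plant!r}"
            )
        if self.final_plant not in PLANTS:
            raise ValidationError(
                f"pot {self.pot_id!r}: unknown final plant {self.final_plant!r}"
            )
        if not math.isfinite(self.biomass) or self.biomass < 0:
            raise ValidationError(
                f"pot {self.pot_id!r}: biomass must be a nonnegative number, got {self.biomass}"
            )

    @property
    def home(self) -> bool:
        return self.training_plant == self.final_plant

    @property
    def treatment(self) -> str:
        return "home" if self.home else "away"


@dataclass
class DissimilarityMatrix:
    """Square symmetric pairwise dissimilarity matrix among pots."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"matrix shape {self.d.shape} does not match {n} ids")
        _check_unique(self.ids, "sample")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity matrix has a nonzero diagonal")
        if np.any(self.d < -1e-12):
            raise ValidationError("dissimilarity matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class IndexTable:
    """Per-OTU affinity and per-plant effect indices for one trial x group.

    OTUs that were absent from the pots used to compute a given index carry
    ``nan`` (serialized ``NA``), never a silent zero.
    """

    trial_id: str
    group: str
    otu_ids: list[str]
    affinity: np.ndarray
    effect_ragweed: np.ndarray
    effect_sunflower: np.ndarray

    def __post_init__(self) -> None:
        self.affinity = np.asarray(self.affinity, dtype=float)
        self.effect_ragweed = np.asarray(self.effect_ragweed, dtype=float)
        self.effect_sunflower = np.asarray(self.effect_sunflower, dtype=float)
        m = len(self.otu_ids)
        for name in ("affinity", "effect_ragweed", "effect_sunflower"):
            v = getattr(self, name)
            if v.shape != (m,):
                raise ValidationError(f"{name} has shape {v.shape}, expected ({m},)")

    def effect(self, plant: str) -> np.ndarray:
        if plant not in PLANTS:
            raise ValidationError(f"unknown plant {plant!r}")
        return self.effect_ragweed if plant == "ragweed" else self.effect_sunflower

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "otu_id": self.otu_ids,
                "affinity": self.affinity,
                "effect_ragweed": self.effect_ragweed,
                "effect_sunflower": self.effect_sunflower,
            }
        )

    def write(self, path: str | Path, comments: Iterable[str] = ()) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for c in comments:
                fh.write(f"# {c}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.15g")


# ---------------------------------------------------------------------------
# TSV I/O


def read_otu_table(path: str | Path, group: str, trial_id: str) -> OTUTable:
    """Read a sample-by-OTU TSV (first column sample id, header OTU ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from None
    return OTUTable(
        sample_ids=[str(s) for s in df.index],
        otu_ids=[str(c) for c in df.columns],
        values=values,
        group=group,
        trial_id=trial_id,
    )


def write_otu_table(table: OTUTable, path: str | Path, comments: Iterable[str] = ()) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("sample_id\t" + "\t".join(table.otu_ids) + "\n")
        for sid, row in zip(table.sample_ids, table.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


METADATA_COLUMNS = ("pot_id", "trial_id", "training_plant", "final_plant", "biomass")


def read_metadata(path: str | Path) -> list[PotMetadata]:
    """Read per-pot metadata TSV; plant names are matched case-insensitively."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            biomass = float(row["biomass"])
        except ValueError:
            raise ValidationError(
                f"{path}: pot {row['pot_id']!r}: non-numeric biomass {row['biomass']!r}"
            ) from None
        records.append(
            PotMetadata(
                pot_id=str(row["pot_id"]),
                trial_id=str(row["trial_id"]),
                training_plant=str(row["training_plant"]).strip().lower(),
                final_plant=str(row["final_plant"]).strip().lower(),
                biomass=biomass,
            )
        )
    _check_unique([r.pot_id for r in records], "pot")
    return records


def write_metadata(meta: Sequence[PotMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "pot_id": [m.pot_id for m in meta],
            "trial_id": [m.trial_id for m in meta],
            "training_plant": [m.training_plant for m in meta],
            "final_plant": [m.final_plant for m in meta],
            "biomass": [m.biomass for m in meta],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def validate_pot_ids(table: OTUTable, meta: Sequence[PotMetadata]) -> None:
    """Require every sample in the table to have a metadata record."""
    known = {m.pot_id for m in meta}
    unknown = [s for s in table.sample_ids if s not in known]
    if unknown:
        raise ValidationError(f"samples without metadata: {unknown[:5]}")


def subset(
    table: OTUTable,
    meta: Sequence[PotMetadata],
    selector: Callable[[PotMetadata], bool],
) -> OTUTable:
    """Restrict rows to pots whose metadata satisfies ``selector``.

    Rows are reordered to metadata order of the selected pots; OTU columns
    are unchanged (absent taxa keep their all-zero columns so that index
    vectors stay aligned across subsets).
    """
    validate_pot_ids(table, meta)
    selected = [m.pot_id for m in meta if selector(m) and m.pot_id in set(table.sample_ids)]
    if not selected:
        raise ValidationError("selector matched no pots present in the table")
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    rows = [pos[s] for s in selected]
    return OTUTable(
        sample_ids=selected,
        otu_ids=list(table.otu_ids),
        values=table.values[rows],
        group=table.group,
        trial_id=table.trial_id,
    )
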