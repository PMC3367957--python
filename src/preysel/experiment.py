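"""Domain types and tabular I/O for multiple-choice predation experiments.

The canonical on-disk format is tidy long CSV: one row per predator individual
x prey type, with the initial and surviving counts.  Wide supplementary-style
sheets (one block of rows per experiment, one row per prey) can be converted
with :func:`read_trials_wide`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MICROHABITATS = ("bottom", "water_column")
#: literature records use the field's benthic / water-column vocabulary
LIT_MICROHABITATS = ("benthic", "water_column")


class SchemaError(ValueError):
    """A table is missing required columns or has an unusable layout."""


class ValidationError(ValueError):
    """Row-level contents violate an invariant of the experimental design."""


@dataclass(frozen=True)
class PreyType:
    id: str
    taxon_order: str
    microhabitat: str
    n_offered_default: int
    body_length_mean: float = float("nan")
    body_length_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_offered_default <= 0:
            raise ValidationError(f"prey {self.id!r}: n_offered_default must be > 0")
        if self.microhabitat not in MICROHABITATS:
            raise ValidationError(
                f"prey {self.id!r}: microhabitat {self.microhabitat!r} "
                f"not in {MICROHABITATS}"
            )


@dataclass(frozen=True)
class PredatorStage:
    id: str
    species: str
    stage: str
    microhabitat: str
    n_replicates: int
    body_length_mean: float = float("nan")
    body_length_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError(f"predator {self.id!r}: n_replicates must be >= 1")
        if self.microhabitat not in MICROHABITATS:
            raise ValidationError(
                f"predator {self.id!r}: microhabitat {self.microhabitat!r} "
                f"not in {MICROHABITATS}"
            )


@dataclass(frozen=True)
class FeedingTrial:
    """One predator individual offered the full prey roster for 24 h."""

    predator_stage_id: str
    replicate_id: str
    n_offered: Mapping[str, int]
    n_surviving: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.n_offered) != set(self.n_surviving):
            raise ValidationError(
                f"trial {self.predator_stage_id}/{self.replicate_id}: offered and "
                "surviving counts cover different prey sets"
            )
        for prey_id, n0 in self.n_offered.items():
            ns = self.n_surviving[prey_id]
            if not 0 <= ns <= n0:
                raise ValidationError(
                    f"trial {self.predator_stage_id}/{self.replicate_id}, prey "
                    f"{prey_id!r}: surviving={ns} outside [0, offered={n0}]"
                )

    @property
    def prey_ids(self) -> tuple[str, ...]:
        return tuple(self.n_offered)

    def missing(self, prey_id: str) -> int:
        return self.n_offered[prey_id] - self.n_surviving[prey_id]


@dataclass(frozen=True)
class ControlSummary:
    """Mean background (predator-free) mortality per prey type, in counts."""

    mean_dead: Mapping[str, float]
    n_control_trials: int = 4

    def __post_init__(self) -> None:
        for prey_id, d in self.mean_dead.items():
            if d < 0:
                raise ValidationError(f"control mean_dead for {prey_id!r} is negative")


@dataclass(frozen=True)
class LiteratureRecord:
    """One published multiple-choice experiment.

    ``offered`` maps each offered prey taxon to its microhabitat; the
    ``most_preferred`` set is empty when the study found no selectivity, and
    may contain several taxa when they tied for most preferred.
    """

    study_id: str
    predator_taxon: str
    predator_stage: str
    predator_microhabitat: str
    offered: Mapping[str, str]
    most_preferred: frozenset[str] = frozenset()
    habitat_structure: bool = False
    multiple_choice: bool = True

    def __post_init__(self) -> None:
        if len(self.offered) < 1:
            raise ValidationError(f"record {self.study_id!r}: no prey offered")
        extra = set(self.most_preferred) - set(self.offered)
        if extra:
            raise ValidationError(
                f"record {self.study_id!r}: most_preferred taxa {sorted(extra)} "
                "absent from the offered set"
            )
        if self.predator_microhabitat not in LIT_MICROHABITATS:
            raise ValidationError(
                f"record {self.study_id!r}: predator microhabitat "
                f"{self.predator_microhabitat!r} not in {LIT_MICROHABITATS}"
            )


Roster = Sequence[PreyType]


def roster_ids(roster: Roster) -> list[str]:
    return [p.id for p in roster]


def roster_from_frame(df: pd.DataFrame) -> list[PreyType]:
    _require_columns(df, ["id", "taxon_order", "microhabitat", "n_offered_default"], "prey")
    return [
        PreyType(
            id=str(r["id"]),
            taxon_order=str(r["taxon_order"]),
            microhabitat=str(r["microhabitat"]),
            n_offered_default=int(r["n_offered_default"]),
            body_length_mean=float(r.get("body_length_mean", float("nan"))),
            body_length_sd=float(r.get("body_length_sd", float("nan"))),
        )
        for _, r in df.iterrows()
    ]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# readers / writers


def read_prey(path: str | Path) -> list[PreyType]:
    return roster_from_frame(pd.read_csv(path))


def read_predators(path: str | Path) -> list[PredatorStage]:
    df = pd.read_csv(path)
    _require_columns(df, ["id", "species", "stage", "microhabitat", "n_replicates"], "predators")
    return [
        PredatorStage(
            id=str(r["id"]),
            species=str(r["species"]),
            stage=str(r["stage"]),
            microhabitat=str(r["microhabitat"]),
            n_replicates=int(r["n_replicates"]),
            body_length_mean=float(r.get("body_length_mean", float("nan"))),
            body_length_sd=float(r.get("body_length_sd", float("nan"))),
        )
        for _, r in df.iterrows()
    ]


def read_trials(path: str | Path, roster: Roster) -> list[FeedingTrial]:
    """Read tidy long trials (predator_stage_id, replicate_id, prey_id, counts).

    Every trial must cover exactly the prey of ``roster``; a missing prey row
    is an error (the design offered every prey in every trial), as is a
    surviving count above the offered count.
    """
    df = pd.read_csv(path)
    return trials_from_frame(df, roster)


def trials_from_frame(df: pd.DataFrame, roster: Roster) -> list[FeedingTrial]:
    _require_columns(
        df, ["predator_stage_id", "replicate_id", "prey_id", "n_offered", "n_surviving"],
        "trials",
    )
    expected = set(roster_ids(roster))
    unknown = set(df["prey_id"]) - expected
    if unknown:
        raise SchemaError(f"trials table has prey absent from the roster: {sorted(unknown)}")
    bad = df.index[df["n_surviving"] > df["n_offered"]]
    if len(bad):
        raise ValidationError(
            f"n_surviving > n_offered at row index {bad[0]} "
            f"(prey {df.loc[bad[0], 'prey_id']!r})"
        )
    trials = []
    for (stage, rep), g in df.groupby(["predator_stage_id", "replicate_id"], sort=False):
        got = set(g["prey_id"])
        if got != expected:
            missing = sorted(expected - got)
            raise SchemaError(
                f"trial {stage}/{rep} does not cover the full prey roster; "
                f"missing: {missing}"
            )
        g = g.set_index("prey_id")
        trials.append(
            FeedingTrial(
                predator_stage_id=str(stage),
                replicate_id=str(rep),
                n_offered={p: int(g.loc[p, "n_offered"]) for p in g.index},
                n_surviving={p: int(g.loc[p, "n_surviving"]) for p in g.index},
            )
        )
    return trials


def trials_to_frame(trials: Iterable[FeedingTrial]) -> pd.DataFrame:
    rows = [
        (t.predator_stage_id, t.replicate_id, p, t.n_offered[p], t.n_surviving[p])
        for t in trials
        for p in t.prey_ids
    ]
    return pd.DataFrame(
        rows, columns=["predator_stage_id", "replicate_id", "prey_id", "n_offered", "n_surviving"]
    )


def write_trials(trials: Iterable[FeedingTrial], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials_wide(path: str | Path, roster: Roster) -> list[FeedingTrial]:
    """Convert a wide supplementary-style sheet to trials.

    Expected layout: one row per (experiment, prey) with columns identifying
    the predator stage, the experiment/replicate, the prey, the initial count
    and either the surviving or the consumed count.  Excel files are read via
    openpyxl; anything else is parsed as CSV.  Column names are matched
    case-insensitively against a small set of synonyms.
    """
    p = Path(path)
    if p.suffix.lower() in {".xls", ".xlsx"}:
        df = pd.read_excel(p)
    else:
        df = pd.read_csv(p)
    rename = {}
    synonyms = {
        "predator_stage_id": {"predator_stage_id", "predator", "predator id", "predator_id"},
        "replicate_id": {"replicate_id", "replicate", "experiment", "experiment id", "trial"},
        "prey_id": {"prey_id", "prey", "prey species"},
        "n_offered": {"n_offered", "initial", "n0", "initial number", "offered"},
        "n_surviving": {"n_surviving", "surviving", "survivors"},
        "n_consumed": {"n_consumed", "consumed", "eaten", "r"},
    }
    lower = {str(c).strip().lower(): c for c in df.columns}
    for canon, names in synonyms.items():
        for name in names:
            if name in lower:
                rename[lower[name]] = canon
                break
    df = df.rename(columns=rename)
    if "n_surviving" not in df.columns:
        if "n_consumed" not in df.columns:
            raise SchemaError("wide table needs a surviving or consumed column")
        df["n_surviving"] = df["n_offered"] - df["n_consumed"]
    return trials_from_frame(
        df[["predator_stage_id", "replicate_id", "prey_id", "n_offered", "n_surviving"]],
        roster,
    )


def read_controls(path: str | Path, roster: Roster) -> ControlSummary:
    """Read control mortality; accepts ``mean_dead`` or ``percent_dead``.

    Percentages are converted to mean dead counts with each prey's default
    offer from the roster (the selectivity equations need counts).
    """
    df = pd.read_csv(path)
    _require_columns(df, ["prey_id"], "controls")
    if "mean_dead" not in df.columns and "percent_dead" not in df.columns:
        raise SchemaError("controls table needs a mean_dead or percent_dead column")
    offers = {p.id: p.n_offered_default for p in roster}
    mean_dead: dict[str, float] = {}
    for _, r in df.iterrows():
        prey_id = str(r["prey_id"])
        if prey_id not in offers:
            raise SchemaError(f"controls table has prey absent from the roster: {prey_id!r}")
        if "mean_dead" in df.columns and not pd.isna(r.get("mean_dead")):
            mean_dead[prey_id] = float(r["mean_dead"])
        else:
            mean_dead[prey_id] = float(r["percent_dead"]) / 100.0 * offers[prey_id]
    missing = set(offers) - set(mean_dead)
    if missing:
        raise SchemaError(f"controls table is missing prey: {sorted(missing)}")
    n = int(df["n_control_trials"].iloc[0]) if "n_control_trials" in df.columns else 4
    return ControlSummary(mean_dead=mean_dead, n_control_trials=n)


LITERATURE_COLUMNS = [
    "study_id", "predator_taxon", "predator_stage", "predator_microhabitat",
    "prey_taxon", "prey_microhabitat", "offered_flag", "most_preferred_flag",
    "habitat_structure", "multiple_choice",
]


def read_literature(path: str | Path) -> list[LiteratureRecord]:
    """Read one-row-per-(experiment x prey) literature records.

    Rows with ``offered_flag`` = 0 are ignored; an experiment whose study
    found no selectivity simply has ``most_preferred_flag`` = 0 everywhere.
    """
    df = pd.read_csv(path)
    _require_columns(df, LITERATURE_COLUMNS[:8], "literature")
    records = []
    for study, g in df.groupby("study_id", sort=False):
        g = g[g["offered_flag"].astype(int) == 1]
        if g.empty:
            raise ValidationError(f"record {study!r}: no prey offered")
        offered = {
            str(r["prey_taxon"]): str(r["prey_microhabitat"]) for _, r in g.iterrows()
        }
        preferred = frozenset(
            str(r["prey_taxon"]) for _, r in g.iterrows()
            if int(r["most_preferred_flag"]) == 1
        )
        first = g.iloc[0]
        records.append(
            LiteratureRecord(
                study_id=str(study),
                predator_taxon=str(first["predator_taxon"]),
                predator_stage=str(first["predator_stage"]),
                predator_microhabitat=str(first["predator_microhabitat"]),
                offered=offered,
                most_preferred=preferred,
                habitat_structure=bool(first.get("habitat_structure", False)),
                multiple_choice=bool(first.get("multiple_choice", True)),
            )
        )
    return records


def write_literature(records: Iterable[LiteratureRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for taxon, micro in rec.offered.items():
            rows.append(
                (rec.study_id, rec.predator_taxon, rec.predator_stage,
                 rec.predator_microhabitat, taxon, micro, 1,
                 int(taxon in rec.most_preferred),
                 int(rec.habitat_structure), int(rec.multiple_choice))
            )
    pd.DataFrame(rows, columns=LITERATURE_COLUMNS).to_csv(path, index=False)


def replicate_counts(trials: Iterable[FeedingTrial]) -> dict[str, int]:
    """Number of replicate individuals per predator stage."""
    counts: dict[str, int] = {}
    for t in trials:
        counts[t.predator_stage_id] = counts.get(t.predator_stage_id, 0) + 1
    return counts
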