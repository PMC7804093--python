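"""Survey data model, CSV I/O, validation, and packaged table fixtures.

A survey *cell* is one area × season × survey × fish-species combination with
three integer counts: larvae collected, larvae carrying at least one
ectoparasite, and parasite individuals counted.  The packaged fixtures
digitize the study's printed per-survey prevalence / mean-intensity table and
its body-length summary table; integer counts are reconstructed from the
printed percentages at load time and flagged where the printed layout is
ambiguous or internally inconsistent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger("larvaldelta")

#: Fixed label vocabularies; unknown labels are validation errors.
AREAS = ("COL", "ISM")
SEASONS = ("autumn_winter", "spring_summer")
SPECIES = ("Ac", "Gm", "Hc", "Msp", "Oj")

SURVEY_COLUMNS = [
    "area",
    "season",
    "survey_id",
    "species",
    "n_collected",
    "n_parasitized",
    "n_parasites",
]


class ValidationError(ValueError):
    """A record or table violates a survey-data invariant."""


def round_half_away(x: float) -> int:
    """Round half away from zero (the reconstruction convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SurveyRecord:
    """One area × season × survey × species cell of a parasitism survey."""

    area: str
    season: str
    survey_id: int
    species: str
    n_collected: int
    n_parasitized: int
    n_parasites: int

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValidationError(f"unknown area {self.area!r} (expected one of {AREAS})")
        if self.season not in SEASONS:
            raise ValidationError(
                f"unknown season {self.season!r} (expected one of {SEASONS})"
            )
        if self.species not in SPECIES:
            raise ValidationError(
                f"unknown species {self.species!r} (expected one of {SPECIES})"
            )
        if int(self.survey_id) < 1:
            raise ValidationError(f"survey_id {self.survey_id} must be >= 1")
        for name in ("n_collected", "n_parasitized", "n_parasites"):
            v = getattr(self, name)
            if int(v) != v or int(v) < 0:
                raise ValidationError(f"{name}={v!r} is not a nonnegative integer")
        if self.n_parasitized > self.n_collected:
            raise ValidationError(
                f"n_parasitized={self.n_parasitized} exceeds n_collected={self.n_collected}"
            )
        if self.n_parasites < self.n_parasitized:
            raise ValidationError(
                f"n_parasites={self.n_parasites} below n_parasitized={self.n_parasitized}"
                " (each parasitized larva carries >= 1 parasite)"
            )
        if (self.n_parasites == 0) != (self.n_parasitized == 0):
            raise ValidationError(
                "n_parasites and n_parasitized must be zero together"
            )

    @property
    def key(self) -> tuple:
        return (self.area, self.season, int(self.survey_id), self.species)


@dataclass(frozen=True)
class LengthPair:
    """Paired host and parasite body lengths for one parasitized larva."""

    species: str
    area: str
    host_length: float
    parasite_length: float

    def __post_init__(self) -> None:
        if self.host_length <= 0 or self.parasite_length <= 0:
            raise ValidationError("lengths must be strictly positive")


@dataclass
class Dataset:
    """An ordered collection of survey records plus optional length pairs.

    ``cell_meta`` carries fixture-only metadata (printed prevalence/intensity,
    ambiguity and discrepancy flags) aligned with ``records``; analysis paths
    always recompute prevalence and intensity from the integer counts.
    """

    records: list[SurveyRecord]
    lengths: Optional[list[LengthPair]] = None
    provenance: str = ""
    cell_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (area, season, survey, species) keys: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-cell DataFrame view."""
        return pd.DataFrame(
            [
                {
                    "area": r.area,
                    "season": r.season,
                    "survey_id": int(r.survey_id),
                    "species": r.species,
                    "n_collected": int(r.n_collected),
                    "n_parasitized": int(r.n_parasitized),
                    "n_parasites": int(r.n_parasites),
                }
                for r in self.records
            ],
            columns=SURVEY_COLUMNS,
        )


def read_survey_table(path) -> Dataset:
    """Read a survey CSV (RFC-4180, UTF-8, '#' comment lines) into a Dataset."""
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in SURVEY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            counts = {}
            for name in ("survey_id", "n_collected", "n_parasitized", "n_parasites"):
                raw = getattr(row, name)
                try:
                    counts[name] = int(raw)
                except (TypeError, ValueError):
                    raise ValidationError(f"{name}={raw!r} is not an integer")
            records.append(
                SurveyRecord(
                    area=row.area, season=row.season, species=row.species, **counts
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 1}: {exc}") from exc
    return Dataset(records=records, provenance=f"read from {path}")


def write_survey_table(dataset: Dataset, path) -> None:
    """Write a Dataset as a survey CSV readable by :func:`read_survey_table`."""
    dataset.to_frame().to_csv(path, index=False, lineterminator="\n")


def read_length_table(path) -> list[LengthPair]:
    frame = pd.read_csv(path, comment="#")
    return [
        LengthPair(
            species=row.species,
            area=row.area,
            host_length=float(row.host_length),
            parasite_length=float(row.parasite_length),
        )
        for row in frame.itertuples(index=False)
    ]


def write_length_table(pairs: Sequence[LengthPair], path) -> None:
    pd.DataFrame(
        [
            {
                "species": p.species,
                "area": p.area,
                "host_length": p.host_length,
                "parasite_length": p.parasite_length,
            }
            for p in pairs
        ]
    ).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("larvaldelta.data").joinpath(name)


def load_table1_fixture() -> Dataset:
    """Load the digitized per-survey prevalence/intensity table.

    Integer counts are reconstructed from the printed values:
    ``n_parasitized = round(prevalence × n / 100)`` (half away from zero) and
    ``n_parasites = round(mean_intensity × n_parasitized)``; cells printed
    without a prevalence have no parasitized larvae.  The one cell printed
    with an intensity but no prevalence (n = 1) is reconstructed as a single
    parasitized larva and flagged.  ``cell_meta`` records, per cell, the
    printed values, the species-assignment ambiguity flag, and a
    ``discrepant`` flag where the reconstructed integers cannot reproduce the
    printed prevalence (±0.5 points) or intensity (±0.005) — such cells keep
    the printed numbers as metadata and the reconstructed integers as data.
    """
    with _fixture_path("table1_cells.csv").open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, comment="#")
    records, meta_rows = [], []
    for row in frame.itertuples(index=False):
        n = int(row.n_collected)
        prev = None if pd.isna(row.prevalence_pct) else float(row.prevalence_pct)
        inten = None if pd.isna(row.mean_intensity) else float(row.mean_intensity)
        note = "" if pd.isna(row.note) else str(row.note)
        if prev is not None:
            n_par = round_half_away(prev * n / 100.0)
        elif inten is not None:
            # printed "- (1) [1]": intensity without prevalence implies >= 1
            n_par = 1
        else:
            n_par = 0
        n_parasites = round_half_away(inten * n_par) if inten is not None else n_par
        if n_par == 0:
            n_parasites = 0
        discrepant = False
        if prev is not None and abs(100.0 * n_par / n - prev) > 0.5:
            discrepant = True
        if prev is None and inten is not None:
            discrepant = True
        if inten is not None and n_par > 0 and abs(n_parasites / n_par - inten) > 0.005:
            discrepant = True
        if discrepant:
            logger.warning(
                "table1 fixture cell %s/%s survey %s %s: reconstructed counts "
                "(%d/%d of %d) do not reproduce printed values (%s, %s)",
                row.area, row.season, row.survey_id, row.species,
                n_parasites, n_par, n, prev, inten,
            )
        records.append(
            SurveyRecord(
                area=row.area,
                season=row.season,
                survey_id=int(row.survey_id),
                species=row.species,
                n_collected=n,
                n_parasitized=n_par,
                n_parasites=n_parasites,
            )
        )
        meta_rows.append(
            {
                "area": row.area,
                "season": row.season,
                "survey_id": int(row.survey_id),
                "species": row.species,
                "printed_prevalence": prev,
                "printed_intensity": inten,
                "ambiguous": bool(int(row.ambiguous)),
                "discrepant": discrepant,
                "note": note,
            }
        )
    return Dataset(
        records=records,
        provenance="digitized per-survey prevalence/intensity table (printed layout)",
        cell_meta=pd.DataFrame(meta_rows),
    )


@dataclass(frozen=True)
class LengthSummary:
    """Printed per-species body-length ranges and correlation summary."""

    species: str
    unparasitized_range: tuple
    n_unparasitized: int
    parasitized_range: tuple
    n_parasitized: int
    parasite_size_range: tuple
    r_ism: Optional[float]
    n_ism: Optional[int]
    sig_ism: bool
    r_col: Optional[float]
    n_col: Optional[int]
    sig_col: bool
    unit: str = "paper units"

    def __post_init__(self) -> None:
        for lo, hi in (
            self.unparasitized_range,
            self.parasitized_range,
            self.parasite_size_range,
        ):
            if lo > hi:
                raise ValidationError(f"range ({lo}, {hi}) has min > max")


def load_table2_fixture() -> list[LengthSummary]:
    """Load the digitized body-length-range / correlation summary table."""
    with _fixture_path("table2_lengths.csv").open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, comment="#")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            LengthSummary(
                species=row.species,
                unparasitized_range=(float(row.unpar_min), float(row.unpar_max)),
                n_unparasitized=int(row.n_unpar),
                parasitized_range=(float(row.par_min), float(row.par_max)),
                n_parasitized=int(row.n_par),
                parasite_size_range=(float(row.psize_min), float(row.psize_max)),
                r_ism=None if pd.isna(row.r_ism) else float(row.r_ism),
                n_ism=None if pd.isna(row.n_ism) else int(row.n_ism),
                sig_ism=bool(int(row.sig_ism)),
                r_col=None if pd.isna(row.r_col) else float(row.r_col),
                n_col=None if pd.isna(row.n_col) else int(row.n_col),
                sig_col=bool(int(row.sig_col)),
            )
        )
    return out
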