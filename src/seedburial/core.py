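"""Burial-record data model and derived seed-fate statistics.

A burial experiment exhumes replicate seed bags at fixed times and counts
four seed fates per bag: spontaneously germinated, germinated only after
gibberellic-acid stimulation, viable-but-non-germinated (staining/squeeze
positive), and dead.  From these counts three percentages are derived
(viability, germinability, germination) and each species' soil seed bank is
classified as transient, short-term persistent, or long-term persistent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ValidationError",
    "ValidationReport",
    "BagRecord",
    "SpeciesTraits",
    "FateSummary",
    "PersistenceClass",
    "Persistence",
    "compute_viability",
    "compute_germinability",
    "compute_germination",
    "fate_summary",
    "fate_summary_table",
    "classify_persistence",
    "classify_all",
    "persistence_table",
    "read_records",
    "read_traits",
    "records_to_frame",
]

#: a bag at an exhumation time strictly greater than this confers at least
#: short-term persistence when it holds viable seeds
TRANSIENT_CUTOFF_YEARS = 1.5

#: viable seeds at a time strictly greater than this confer long-term persistence
LONG_TERM_CUTOFF_YEARS = 5.5


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


@dataclass
class ValidationReport:
    """Per-row outcome of reading a delimited record table."""

    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def reject(self, line_no: int, reason: str) -> None:
        self.rejected.append((line_no, reason))

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def __str__(self) -> str:  # pragma: no cover - logging convenience
        lines = [f"accepted={self.n_accepted} rejected={self.n_rejected}"]
        lines += [f"  line {ln}: {msg}" for ln, msg in self.rejected]
        return "\n".join(lines)


@dataclass(frozen=True)
class BagRecord:
    """One exhumed seed bag: fate counts plus design coordinates.

    Counts must satisfy ``n_germ_spont + n_germ_ga + n_viable_stained +
    n_dead == n_buried``; seeds missing from a bag are folded into
    ``n_dead`` upstream.
    """

    species_id: str
    replicate_id: int
    years_since_burial: float
    row_number: int
    row_sequence: int
    n_buried: int
    n_germ_spont: int
    n_germ_ga: int
    n_viable_stained: int
    n_dead: int

    def __post_init__(self) -> None:
        counts = (
            self.n_buried,
            self.n_germ_spont,
            self.n_germ_ga,
            self.n_viable_stained,
            self.n_dead,
        )
        if any(int(c) != c for c in counts):
            raise ValidationError(f"{self.species_id}: non-integer count in {counts}")
        if any(c < 0 for c in counts):
            raise ValidationError(f"{self.species_id}: negative count in {counts}")
        if self.n_buried <= 0:
            raise ValidationError(f"{self.species_id}: n_buried must be > 0")
        if self.years_since_burial <= 0:
            raise ValidationError(
                f"{self.species_id}: years_since_burial must be > 0, "
                f"got {self.years_since_burial}"
            )
        total = self.n_germ_spont + self.n_germ_ga + self.n_viable_stained + self.n_dead
        if total != self.n_buried:
            raise ValidationError(
                f"{self.species_id}: fate counts sum to {total}, "
                f"expected n_buried={self.n_buried}"
            )

    @property
    def n_germinated(self) -> int:
        """Seeds germinated in the lab test, with or without stimulation."""
        return self.n_germ_spont + self.n_germ_ga

    @property
    def n_viable(self) -> int:
        """Viable seeds exhumed: germinated plus staining/squeeze positive."""
        return self.n_germinated + self.n_viable_stained


class InvasionStatus(str, enum.Enum):
    invasive = "invasive"
    naturalized = "naturalized"


class LifeForm(str, enum.Enum):
    annual = "annual"
    perennial = "perennial"


class SeedBankType(str, enum.Enum):
    transient = "transient"
    persistent = "persistent"
    missing = "missing"


@dataclass(frozen=True)
class SpeciesTraits:
    """Species-level covariates used by the mixed models."""

    species_id: str
    invasion_status: InvasionStatus
    life_form: LifeForm
    seed_mass: float
    glossbank_type: SeedBankType = SeedBankType.missing
    pre_burial_viability: float = float("nan")

    def __post_init__(self) -> None:
        if self.seed_mass == self.seed_mass and self.seed_mass <= 0:  # not-NaN check
            raise ValidationError(f"{self.species_id}: seed_mass must be > 0")
        pv = self.pre_burial_viability
        if pv == pv and not (0.0 <= pv <= 100.0):
            raise ValidationError(
                f"{self.species_id}: pre_burial_viability must lie in [0, 100]"
            )


@dataclass(frozen=True)
class FateSummary:
    """Derived per-bag percentages; ``germinability_pct`` is None when no
    viable seed was exhumed (excluded from germinability models)."""

    species_id: str
    replicate_id: int
    years_since_burial: float
    viability_pct: float
    germinability_pct: float | None
    germination_pct: float


class Persistence(str, enum.Enum):
    transient = "transient"
    short_term_persistent = "short_term_persistent"
    long_term_persistent = "long_term_persistent"


@dataclass(frozen=True)
class PersistenceClass:
    species_id: str
    persistence: Persistence


def compute_viability(bag: BagRecord) -> float:
    """Percentage of buried seeds still viable at exhumation."""
    return 100.0 * bag.n_viable / bag.n_buried


def compute_germinability(bag: BagRecord) -> float | None:
    """Percentage of viable exhumed seeds that germinated in the lab test.

    Returns None when the bag held no viable seed (empty denominator).
    The numerator includes gibberellic-acid-stimulated germination; the
    no-stimulation fraction is the separate germination variable.
    """
    if bag.n_viable == 0:
        return None
    return 100.0 * bag.n_germinated / bag.n_viable


def compute_germination(bag: BagRecord) -> float:
    """Percentage of buried seeds germinating without stimulation."""
    return 100.0 * bag.n_germ_spont / bag.n_buried


def fate_summary(bag: BagRecord) -> FateSummary:
    return FateSummary(
        species_id=bag.species_id,
        replicate_id=bag.replicate_id,
        years_since_burial=bag.years_since_burial,
        viability_pct=compute_viability(bag),
        germinability_pct=compute_germinability(bag),
        germination_pct=compute_germination(bag),
    )


def fate_summary_table(records: Iterable[BagRecord]) -> pd.DataFrame:
    """Tidy table of the three derived variables, one row per bag."""
    rows = [fate_summary(r).__dict__ for r in records]
    return pd.DataFrame(rows)


def classify_persistence(records: Sequence[BagRecord]) -> PersistenceClass:
    """Classify one species' seed bank from its exhumation record.

    transient
        no bag at or beyond the first exhumation (1.5 yr) held a viable seed;
    long_term_persistent
        viable seeds recorded strictly after 5.5 yr (the 6.5- or 7.5-yr
        exhumations on the design grid);
    short_term_persistent
        everything in between.
    """
    if not records:
        raise ValidationError("classify_persistence: empty record list")
    species = {r.species_id for r in records}
    if len(species) > 1:
        raise ValidationError(
            f"classify_persistence: records span multiple species {sorted(species)}"
        )
    viable_times = [r.years_since_burial for r in records if r.n_viable > 0]
    if any(t > LONG_TERM_CUTOFF_YEARS for t in viable_times):
        cls = Persistence.long_term_persistent
    elif any(t >= TRANSIENT_CUTOFF_YEARS for t in viable_times):
        cls = Persistence.short_term_persistent
    else:
        cls = Persistence.transient
    return PersistenceClass(species_id=records[0].species_id, persistence=cls)


def classify_all(records: Iterable[BagRecord]) -> list[PersistenceClass]:
    by_species: dict[str, list[BagRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_id, []).append(r)
    return [classify_persistence(v) for v in by_species.values()]


def persistence_table(records: Iterable[BagRecord]) -> pd.DataFrame:
    rows = [
        {"species_id": c.species_id, "persistence": c.persistence.value}
        for c in classify_all(records)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delimited-text IO

_RECORD_COLUMNS = [
    "species_id",
    "replicate_id",
    "years_since_burial",
    "row_number",
    "row_sequence",
    "n_buried",
    "n_germ_spont",
    "n_germ_ga",
    "n_viable_stained",
    "n_dead",
]

_INT_COLUMNS = [
    "replicate_id",
    "row_number",
    "row_sequence",
    "n_buried",
    "n_germ_spont",
    "n_germ_ga",
    "n_viable_stained",
    "n_dead",
]

_TRAIT_COLUMNS = [
    "species_id",
    "invasion_status",
    "life_form",
    "seed_mass",
    "glossbank_type",
    "pre_burial_viability",
]


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: empty file")
    sep = delimiter if delimiter is not None else None
    return pd.read_csv(path, sep=sep, engine="python", dtype=str, skipinitialspace=True)


def read_records(
    path: str | Path, delimiter: str | None = None
) -> tuple[list[BagRecord], ValidationReport]:
    """Read and validate a bag-record table.

    Rows violating count invariants are rejected individually and logged with
    their file line number; duplicate (species, replicate, year) keys abort
    the read naming both lines.
    """
    df = _read_table(path, delimiter)
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    keys: dict[tuple, int] = {}
    report = ValidationReport()
    records: list[BagRecord] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            ints = {}
            for c in _INT_COLUMNS:
                raw = row[c]
                as_float = float(raw)
                if as_float != int(as_float):
                    raise ValidationError(f"column {c!r}: non-integer value {raw!r}")
                ints[c] = int(as_float)
            rec = BagRecord(
                species_id=str(row["species_id"]),
                years_since_burial=float(row["years_since_burial"]),
                **ints,
            )
        except (ValueError, TypeError) as exc:
            report.reject(line_no, str(exc))
            continue
        key = (rec.species_id, rec.replicate_id, rec.years_since_burial)
        if key in keys:
            raise ValidationError(
                f"{path}: duplicate key {key} at lines {keys[key]} and {line_no}"
            )
        keys[key] = line_no
        records.append(rec)
    report.n_accepted = len(records)
    return records, report


def read_traits(path: str | Path, delimiter: str | None = None) -> list[SpeciesTraits]:
    """Read a species-trait table; ``glossbank_type`` and
    ``pre_burial_viability`` may be blank."""
    df = _read_table(path, delimiter)
    required = ["species_id", "invasion_status", "life_form", "seed_mass"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    traits: list[SpeciesTraits] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        sp = str(row["species_id"])
        if sp in seen:
            raise ValidationError(f"{path}: duplicate species_id {sp!r}")
        seen.add(sp)
        gb_raw = str(row.get("glossbank_type", "") or "").strip().lower()
        gb = SeedBankType(gb_raw) if gb_raw in ("transient", "persistent") else SeedBankType.missing
        pv_raw = row.get("pre_burial_viability")
        pv = float(pv_raw) if pv_raw not in (None, "") and pv_raw == pv_raw else float("nan")
        traits.append(
            SpeciesTraits(
                species_id=sp,
                invasion_status=InvasionStatus(str(row["invasion_status"]).strip().lower()),
                life_form=LifeForm(str(row["life_form"]).strip().lower()),
                seed_mass=float(row["seed_mass"]),
                glossbank_type=gb,
                pre_burial_viability=pv,
            )
        )
    return traits


def records_to_frame(records: Iterable[BagRecord]) -> pd.DataFrame:
    """Raw counts as a tidy frame (column order matches the file format)."""
    return pd.DataFrame([r.__dict__ for r in records], columns=_RECORD_COLUMNS)
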