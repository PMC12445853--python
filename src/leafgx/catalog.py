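"""Machine-readable catalog of leaf traits and their response timescales.

Each record describes one leaf trait relevant to eco-evolutionary
optimality modelling: its functional category (stomata & hydraulics,
photosynthetic biochemistry, morphology & lifespan — dual membership
allowed), the mechanisms through which it responds to the environment
(physiological, phenotypic/developmental, evolutionary) and the time
band over which that response plays out, from seconds (internal CO2)
to millions of years (genome size, photosynthetic pathway).

The default 17-trait table bundled with the package
(``data/leaf_traits.tsv``) is a synthetic transcription assembled from
the ecophysiological literature on trait response timescales; the loader
accepts any replacement table with the same schema, so corrections need
no code change.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import timedelta
from importlib import resources
from pathlib import Path
from typing import Iterable

from .constants import ValidationError

__all__ = [
    "TraitRecord",
    "TIME_BANDS",
    "CATEGORIES",
    "MECHANISMS",
    "band_midpoint_log10s",
    "load_catalog",
    "traits_responsive_within",
    "query",
    "lint_catalog",
]

#: Time bands in ascending order with midpoints in log10 seconds.
TIME_BANDS: dict[str, float] = {
    "seconds": 0.5,
    "minutes": 1.8,
    "hours": 3.6,
    "days": 4.9,
    "weeks": 5.8,
    "months": 6.4,
    "years": 7.5,
    "decades": 8.5,
    "centuries": 9.5,
    "millennia": 10.5,
    "millions_of_years": 13.5,
}

CATEGORIES = frozenset(
    {"stomata_hydraulics", "photosynthetic_biochemistry",
     "morphology_lifespan"})
MECHANISMS = frozenset({"physiological", "phenotypic", "evolutionary"})

#: Citation keys the bundled catalog may use; the lint check resolves
#: every record's key_refs against this registry.
KNOWN_REFS = frozenset({
    "review:stomatal-kinetics",
    "review:internal-co2",
    "review:leaf-water-status",
    "review:leaf-hydraulic-conductance",
    "review:stomatal-anatomy",
    "review:vein-architecture",
    "review:hydraulic-capacity-evolution",
    "review:chi-acclimation",
    "review:capacity-acclimation",
    "review:photosynthesis-hydraulics-coordination",
    "review:photosynthetic-pathway-evolution",
    "review:leaf-economics",
    "review:genome-size",
})

SCHEMA_VERSION = "1"


def band_midpoint_log10s(band: str) -> float:
    """Midpoint of a time band in log10 seconds (for ordering arithmetic)."""
    try:
        return TIME_BANDS[band]
    except KeyError:
        raise ValidationError(
            f"unknown time band {band!r}; expected one of {list(TIME_BANDS)}")


@dataclass(frozen=True)
class TraitRecord:
    """One reviewed leaf trait."""

    name: str
    symbol: str
    category: frozenset[str]
    mechanisms: frozenset[str]
    timescale_min: str
    timescale_max: str
    description: str
    units: str
    key_refs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("trait name must be non-empty")
        if not self.category:
            raise ValidationError(f"{self.name}: category must be non-empty")
        if not self.category <= CATEGORIES:
            raise ValidationError(
                f"{self.name}: unknown category {sorted(self.category - CATEGORIES)}")
        if not self.mechanisms:
            raise ValidationError(f"{self.name}: mechanisms must be non-empty")
        if not self.mechanisms <= MECHANISMS:
            raise ValidationError(
                f"{self.name}: unknown mechanism "
                f"{sorted(self.mechanisms - MECHANISMS)}")
        lo = band_midpoint_log10s(self.timescale_min)
        hi = band_midpoint_log10s(self.timescale_max)
        if lo > hi:
            raise ValidationError(
                f"{self.name}: timescale_min ({self.timescale_min}) exceeds "
                f"timescale_max ({self.timescale_max})")


def _default_source():
    return resources.files("leafgx").joinpath("data/leaf_traits.tsv")


def load_catalog(source: str | Path | None = None) -> list[TraitRecord]:
    """Load and validate a trait catalog table.

    Parameters
    ----------
    source : path-like, optional
        Tab-separated table with a ``# leafgx-trait-catalog v<N>`` schema
        line followed by a header row.  Defaults to the bundled catalog.

    Raises
    ------
    ValidationError
        On schema mismatch, duplicate names or band violations, listing
        the offending records.
    """
    if source is None:
        text = _default_source().read_text(encoding="utf-8")
    else:
        text = Path(source).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# leafgx-trait-catalog"):
        raise ValidationError("missing schema line '# leafgx-trait-catalog v1'")
    if lines[0].split("v")[-1].strip() != SCHEMA_VERSION:
        raise ValidationError(f"unsupported catalog schema: {lines[0]!r}")
    reader = csv.DictReader(lines[1:], delimiter="\t")
    records, errors, seen = [], [], set()
    for row in reader:
        try:
            rec = TraitRecord(
                name=row["name"].strip(),
                symbol=row["symbol"].strip(),
                category=frozenset(filter(None, row["category"].split("|"))),
                mechanisms=frozenset(filter(None, row["mechanisms"].split("|"))),
                timescale_min=row["timescale_min"].strip(),
                timescale_max=row["timescale_max"].strip(),
                description=row["description"].strip(),
                units=row["units"].strip(),
                key_refs=tuple(filter(None, row["key_refs"].split("|"))),
            )
        except (ValidationError, KeyError) as exc:
            errors.append(f"{row.get('name', '<unnamed>')}: {exc}")
            continue
        if rec.name in seen:
            errors.append(f"duplicate trait name: {rec.name}")
        seen.add(rec.name)
        records.append(rec)
    if errors:
        raise ValidationError("invalid catalog records: " + "; ".join(errors))
    return records


def _elapsed_log10s(elapsed: float | timedelta) -> float:
    import math

    seconds = elapsed.total_seconds() if isinstance(elapsed, timedelta) \
        else float(elapsed)
    if seconds <= 0:
        raise ValidationError("elapsed must be positive")
    return math.log10(seconds)


def traits_responsive_within(elapsed: float | timedelta,
                             catalog: Iterable[TraitRecord] | None = None,
                             ) -> list[TraitRecord]:
    """Traits whose fastest response band fits within ``elapsed``.

    ``elapsed`` is seconds (or a timedelta); comparison uses band
    midpoints, so the result grows monotonically with elapsed time.
    """
    cat = list(catalog) if catalog is not None else load_catalog()
    cutoff = _elapsed_log10s(elapsed)
    return [r for r in cat
            if band_midpoint_log10s(r.timescale_min) <= cutoff]


def query(category: str | None = None, mechanism: str | None = None,
          catalog: Iterable[TraitRecord] | None = None) -> list[TraitRecord]:
    """Filter the catalog by category and/or mechanism (intersection)."""
    if category is not None and category not in CATEGORIES:
        raise ValidationError(
            f"unknown category {category!r}; expected one of {sorted(CATEGORIES)}")
    if mechanism is not None and mechanism not in MECHANISMS:
        raise ValidationError(
            f"unknown mechanism {mechanism!r}; expected one of {sorted(MECHANISMS)}")
    cat = list(catalog) if catalog is not None else load_catalog()
    out = []
    for rec in cat:
        if category is not None and category not in rec.category:
            continue
        if mechanism is not None and mechanism not in rec.mechanisms:
            continue
        out.append(rec)
    return out


def lint_catalog(catalog: Iterable[TraitRecord] | None = None) -> None:
    """Check that every record cites at least one known reference key."""
    cat = list(catalog) if catalog is not None else load_catalog()
    bad = [r.name for r in cat
           if not r.key_refs or not set(r.key_refs) <= KNOWN_REFS]
    if bad:
        raise ValidationError(f"records with missing/unknown key_refs: {bad}")
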