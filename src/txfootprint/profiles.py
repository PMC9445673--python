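"""Differential-expression profiles: data model, I/O and timing classification.

The unit of evidence throughout the package is the *profile*: one contrast's
list of differentially expressed genes (DEGs), each recorded only by its
direction of change versus the control (+1 up, -1 down), together with the
metadata needed downstream (which independent study it came from, genotype,
perturbation, treatment duration).  Expression magnitudes are optional and
never enter the consensus computation; they only arbitrate within-profile
direction conflicts when probe-level rows are merged.

Gene identifiers are normalized to the Arabidopsis AGI locus convention
(``AT[1-5CM]G\\d{5}``, uppercase, transcript suffixes stripped) because the
locus is the comparison unit across array platforms.  Nonstandard IDs are
kept but flagged with a warning.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AGI_PATTERN = re.compile(r"^AT[1-5CM]G\d{5}$")

_TRANSCRIPT_SUFFIX = re.compile(r"\.\d+$")

TIMING_CLASSES = ("short", "medium", "long")


class FormatError(ValueError):
    """A table or manifest does not have the required structure."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent or infeasible."""


def normalize_gene_id(raw: str) -> str:
    """Uppercase a gene identifier and strip a trailing transcript suffix.

    ``at2g38360.1`` -> ``AT2G38360``.  Returns the normalized string; whether
    it matches the AGI pattern is checked separately (see
    :func:`is_standard_gene_id`).
    """
    gid = str(raw).strip().upper()
    return _TRANSCRIPT_SUFFIX.sub("", gid)


def is_standard_gene_id(gene_id: str) -> bool:
    return bool(AGI_PATTERN.match(gene_id))


@dataclass(frozen=True, order=True)
class DEGRecord:
    """One signed gene occurrence inside a profile.

    direction is strictly +1 (up-regulated vs control) or -1 (down); a gene
    with no derivable direction is not a record.  magnitude, when present, is
    a unitless fold-change used only for conflict resolution at read time.
    """

    gene_id: str
    direction: int
    magnitude: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError(
                f"direction must be +1 or -1, got {self.direction!r} for {self.gene_id}"
            )


@dataclass(frozen=True)
class TimingBounds:
    """Boundaries of the treatment-duration classes, in hours.

    Defaults place 3 h in *short* and 24 h in *long*, reconciling the
    conventional short (0.5-3 h), medium (3-23 h) and long (>=24 h) bins.
    """

    short_max: float = 3.0
    long_min: float = 24.0

    def __post_init__(self) -> None:
        if not (0 < self.short_max < self.long_min):
            raise ConfigurationError(
                f"require 0 < short_max < long_min, got {self.short_max}, {self.long_min}"
            )


def classify_timing(timepoint_hours: float, bounds: TimingBounds = TimingBounds()) -> str:
    """Map a treatment duration to its timing class.

    short if 0 < t <= short_max, long if t >= long_min, medium in between.
    Total and piecewise constant on t > 0; t <= 0 is a domain error.
    """
    t = float(timepoint_hours)
    if not t > 0:
        raise ValueError(f"timepoint_hours must be positive, got {t}")
    if t <= bounds.short_max:
        return "short"
    if t >= bounds.long_min:
        return "long"
    return "medium"


@dataclass(frozen=True)
class ProfileMeta:
    """Metadata for one transcriptional profile (one contrast vs control)."""

    profile_id: str
    study_id: str
    genotype: str = ""
    perturbation: str = ""
    timepoint_hours: float = 1.0
    comparison: str = ""
    bounds: TimingBounds = TimingBounds()

    def __post_init__(self) -> None:
        if not self.profile_id:
            raise ConfigurationError("profile_id must be nonempty")
        if not self.study_id:
            raise ConfigurationError(f"study_id empty for profile {self.profile_id!r}")
        # validates timepoint > 0 as a side effect
        classify_timing(self.timepoint_hours, self.bounds)

    @property
    def timing_class(self) -> str:
        return classify_timing(self.timepoint_hours, self.bounds)


@dataclass(frozen=True)
class TableDialect:
    """How to read one profile's gene-list table.

    Either a signed ``direction`` column or a signed log-fold-change column
    must be present; when both are configured the direction column wins.  No
    auto-sniffing beyond the delimiter.
    """

    delimiter: str = "\t"
    gene_col: str = "gene"
    direction_col: str = "direction"
    logfc_col: str = "logFC"


def _resolve_conflict(
    gene_id: str, entries: list[tuple[int, float | None]]
) -> DEGRecord | None:
    """Collapse duplicate rows for one gene within one profile.

    A single signed state per gene per profile is the unit of evidence, so
    conflicting directions are resolved by the larger |magnitude|; on a tie,
    or when magnitudes are absent, the gene is dropped from the profile with
    a warning.
    """
    directions = {d for d, _ in entries}
    if len(directions) == 1:
        d = directions.pop()
        mags = [m for _, m in entries if m is not None]
        best = max(mags, key=abs) if mags else None
        return DEGRecord(gene_id, d, best)
    with_mag = [(d, m) for d, m in entries if m is not None]
    if with_mag:
        best_abs = max(abs(m) for _, m in with_mag)
        winners = {d for d, m in with_mag if abs(m) == best_abs}
        if len(winners) == 1:
            d = winners.pop()
            return DEGRecord(gene_id, d, best_abs if d > 0 else -best_abs)
    warnings.warn(
        f"gene {gene_id}: conflicting directions with no magnitude tie-break; "
        "dropped from this profile",
        stacklevel=3,
    )
    return None


def read_profile_table(path: str | Path, dialect: TableDialect = TableDialect()) -> set[DEGRecord]:
    """Read one profile's DEG list from a delimited table.

    Returns a deduplicated set of :class:`DEGRecord`.  Direction comes from
    the direction column when present, otherwise from the sign of the
    log-fold-change column; a zero fold-change row is rejected with a warning
    because no direction is derivable from it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    if dialect.gene_col not in df.columns:
        raise FormatError(f"{path}: missing required gene column {dialect.gene_col!r}")
    has_dir = dialect.direction_col in df.columns
    has_lfc = dialect.logfc_col in df.columns
    if not has_dir and not has_lfc:
        raise FormatError(
            f"{path}: need a {dialect.direction_col!r} or {dialect.logfc_col!r} column"
        )

    by_gene: dict[str, list[tuple[int, float | None]]] = {}
    nonstandard: list[str] = []
    for _, row in df.iterrows():
        gid = normalize_gene_id(row[dialect.gene_col])
        if not is_standard_gene_id(gid):
            nonstandard.append(gid)
        if has_dir:
            d = int(row[dialect.direction_col])
            if d not in (+1, -1):
                raise FormatError(
                    f"{path}: direction must be +1/-1, got {d!r} for {gid}"
                )
            mag = float(row[dialect.logfc_col]) if has_lfc and pd.notna(row[dialect.logfc_col]) else None
        else:
            lfc = float(row[dialect.logfc_col])
            if lfc == 0:
                warnings.warn(
                    f"{path}: zero fold-change for {gid}; no direction derivable, row rejected",
                    stacklevel=2,
                )
                continue
            d = +1 if lfc > 0 else -1
            mag = lfc
        by_gene.setdefault(gid, []).append((d, mag))

    if nonstandard:
        warnings.warn(
            f"{path}: {len(nonstandard)} nonstandard gene IDs kept "
            f"(e.g. {nonstandard[0]!r})",
            stacklevel=2,
        )

    records = set()
    for gid, entries in by_gene.items():
        rec = _resolve_conflict(gid, entries)
        if rec is not None:
            records.add(rec)
    return records


def write_profile_table(records: Iterable[DEGRecord], path: str | Path,
                        dialect: TableDialect = TableDialect()) -> None:
    """Write records as a normalized table readable by :func:`read_profile_table`."""
    rows = sorted(records)
    df = pd.DataFrame(
        {
            dialect.gene_col: [r.gene_id for r in rows],
            dialect.direction_col: [r.direction for r in rows],
            dialect.logfc_col: [r.magnitude for r in rows],
        }
    )
    df.to_csv(path, sep=dialect.delimiter, index=False)


@dataclass
class ProfileDatabase:
    """A validated collection of profiles and their DEG record sets."""

    profiles: dict[str, ProfileMeta]
    records: dict[str, frozenset[DEGRecord]]

    def __post_init__(self) -> None:
        unknown = set(self.records) - set(self.profiles)
        if unknown:
            raise ConfigurationError(f"records reference unknown profiles: {sorted(unknown)}")
        for pid in self.profiles:
            self.records.setdefault(pid, frozenset())
        for pid, recs in self.records.items():
            genes = [r.gene_id for r in recs]
            if len(genes) != len(set(genes)):
                raise ConfigurationError(f"profile {pid}: duplicate gene after dedup")

    def profile_ids(self, timing_class: str | None = None) -> list[str]:
        """Profile IDs in insertion (manifest) order, optionally one class."""
        if timing_class is None:
            return list(self.profiles)
        if timing_class not in TIMING_CLASSES:
            raise ConfigurationError(f"unknown timing class {timing_class!r}")
        return [p for p, m in self.profiles.items() if m.timing_class == timing_class]

    def deg_counts(self) -> dict[str, int]:
        return {pid: len(self.records[pid]) for pid in self.profiles}

    def timing_partition(self) -> dict[str, int]:
        part = {c: 0 for c in TIMING_CLASSES}
        for meta in self.profiles.values():
            part[meta.timing_class] += 1
        return part

    def study_of(self) -> dict[str, str]:
        return {pid: m.study_id for pid, m in self.profiles.items()}

    def summary(self) -> dict:
        return {
            "n_profiles": len(self.profiles),
            "n_studies": len({m.study_id for m in self.profiles.values()}),
            "timing_partition": self.timing_partition(),
            "deg_counts": self.deg_counts(),
        }


def build_database(
    specs: Sequence[tuple[str | Path, ProfileMeta]],
    dialect: TableDialect = TableDialect(),
) -> ProfileDatabase:
    """Read every (path, meta) spec into a validated :class:`ProfileDatabase`."""
    profiles: dict[str, ProfileMeta] = {}
    records: dict[str, frozenset[DEGRecord]] = {}
    for path, meta in specs:
        if meta.profile_id in profiles:
            raise ConfigurationError(f"duplicate profile_id {meta.profile_id!r}")
        profiles[meta.profile_id] = meta
        records[meta.profile_id] = frozenset(read_profile_table(path, dialect))
    db = ProfileDatabase(profiles, records)
    logger.info("built database: %s", db.summary())
    return db


def database_from_records(
    profiles: Sequence[ProfileMeta],
    records: Mapping[str, Iterable[DEGRecord]],
) -> ProfileDatabase:
    """Assemble a database from in-memory objects (synthetic data, tests)."""
    metas: dict[str, ProfileMeta] = {}
    for m in profiles:
        if m.profile_id in metas:
            raise ConfigurationError(f"duplicate profile_id {m.profile_id!r}")
        metas[m.profile_id] = m
    return ProfileDatabase(metas, {p: frozenset(r) for p, r in records.items()})


def write_database(db: ProfileDatabase, outdir: str | Path) -> None:
    """Serialize a database as a directory of normalized TSVs plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for pid, meta in db.profiles.items():
        fname = f"{pid}.tsv"
        write_profile_table(db.records[pid], outdir / fname)
        manifest.append(
            {
                "profile_id": pid,
                "study_id": meta.study_id,
                "genotype": meta.genotype,
                "perturbation": meta.perturbation,
                "timepoint_hours": meta.timepoint_hours,
                "comparison": meta.comparison,
                "path": fname,
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "summary.json").write_text(json.dumps(db.summary(), indent=1))


def read_database(indir: str | Path, bounds: TimingBounds = TimingBounds()) -> ProfileDatabase:
    """Read a database previously written by :func:`write_database`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    specs = []
    for entry in manifest:
        meta = ProfileMeta(
            profile_id=entry["profile_id"],
            study_id=entry["study_id"],
            genotype=entry.get("genotype", ""),
            perturbation=entry.get("perturbation", ""),
            timepoint_hours=float(entry["timepoint_hours"]),
            comparison=entry.get("comparison", ""),
            bounds=bounds,
        )
        specs.append((indir / entry["path"], meta))
    return build_database(specs)
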