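"""Presence matrices and vote-counting consensus footprints.

The consensus "transcriptional footprint" is the set of genes called
differentially expressed in at least ``min_profiles`` profiles of one timing
class, with those supporting profiles drawn from at least ``min_studies``
independent studies.  No p-value combination and no magnitude ranking: the
method is pure vote counting over direction-binarized gene calls, which is
robust to heterogeneous platforms and DEG-calling pipelines across studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .profiles import ConfigurationError, ProfileDatabase

DIRECTION_POLICIES = ("any", "majority-consistent", "strict-consistent")


@dataclass(frozen=True)
class PresenceMatrix:
    """Signed gene x profile incidence for one timing class.

    ``cells`` is a DataFrame indexed by gene_id with one column per profile,
    entries in {0, +1, -1}: nonzero iff the gene is a DEG in that profile,
    with its direction as the sign.  Collapsing signs with abs() gives the
    classic binary presence/absence heatmap.
    """

    cells: pd.DataFrame
    timing_class: str

    @property
    def genes(self) -> list[str]:
        return list(self.cells.index)

    @property
    def profiles(self) -> list[str]:
        return list(self.cells.columns)

    def binary(self) -> pd.DataFrame:
        """0/1 presence matrix (signs collapsed)."""
        return self.cells.abs()

    def to_tsv(self, path: str | Path, binary: bool = False) -> None:
        (self.binary() if binary else self.cells).to_csv(path, sep="\t", index_label="gene")


def presence_matrix(db: ProfileDatabase, timing_class: str) -> PresenceMatrix:
    """Build the signed presence matrix over all profiles of one timing class.

    Rows cover exactly the union of DEGs across the included profiles
    (sorted); columns keep manifest order.  Raises if the class is empty.
    """
    pids = db.profile_ids(timing_class)
    if not pids:
        raise ConfigurationError(f"no profiles of timing class {timing_class!r}")
    genes = sorted({r.gene_id for pid in pids for r in db.records[pid]})
    cells = pd.DataFrame(0, index=genes, columns=pids, dtype=np.int8)
    for pid in pids:
        for rec in db.records[pid]:
            cells.at[rec.gene_id, pid] = rec.direction
    return PresenceMatrix(cells, timing_class)


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds for footprint membership.

    min_profiles: minimum supporting profiles (5 for the early/short class,
    4 for the late/long class in the reference analysis).
    min_studies: minimum distinct studies among the supporting profiles (4).
    direction_policy: "any" counts presence regardless of sign;
    "majority-consistent" additionally requires max(n_up, n_down)/support >=
    majority_fraction; "strict-consistent" requires a single shared sign.
    """

    min_profiles: int = 5
    min_studies: int = 4
    direction_policy: str = "any"
    majority_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not (self.min_profiles >= self.min_studies >= 1):
            raise ConfigurationError(
                f"require min_profiles >= min_studies >= 1, got "
                f"{self.min_profiles}/{self.min_studies}"
            )
        if self.direction_policy not in DIRECTION_POLICIES:
            raise ConfigurationError(f"unknown direction_policy {self.direction_policy!r}")
        if not 0.5 < self.majority_fraction <= 1.0:
            raise ConfigurationError("majority_fraction must be in (0.5, 1]")

    @staticmethod
    def from_fraction(frac_profiles: float, n_profiles: int, min_studies: int = 4,
                      direction_policy: str = "any") -> "ConsensusConfig":
        """Convenience: a fractional profile threshold, rounded up to a count."""
        import math
        return ConsensusConfig(
            min_profiles=math.ceil(frac_profiles * n_profiles),
            min_studies=min_studies,
            direction_policy=direction_policy,
        )


@dataclass(frozen=True)
class FootprintSet:
    """Consensus genes with per-gene support bookkeeping.

    ``table`` columns: support (profiles containing the gene), study_support
    (distinct studies among those profiles), n_up, n_down, consistency =
    max(n_up, n_down)/support.  Indexed by gene_id, sorted.
    """

    table: pd.DataFrame
    config: ConsensusConfig
    timing_class: str

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def majority_direction(self, gene: str) -> int:
        """+1 / -1 by majority of supporting profiles; 0 on an exact tie."""
        row = self.table.loc[gene]
        if row["n_up"] > row["n_down"]:
            return +1
        if row["n_down"] > row["n_up"]:
            return -1
        return 0

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")

    def to_gene_list(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.table.index) + ("\n" if len(self.table) else ""))


def support_statistics(matrix: PresenceMatrix, study_of: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene support, study support and direction counts for every gene."""
    missing = [p for p in matrix.profiles if p not in study_of]
    if missing:
        raise ConfigurationError(f"profiles without study_id: {missing}")
    cells = matrix.cells
    studies = np.array([study_of[p] for p in matrix.profiles])
    vals = cells.to_numpy()
    n_up = (vals > 0).sum(axis=1)
    n_down = (vals < 0).sum(axis=1)
    support = n_up + n_down
    study_support = np.array(
        [len(set(studies[vals[i] != 0])) for i in range(vals.shape[0])]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        consistency = np.where(
            support > 0, np.maximum(n_up, n_down) / np.maximum(support, 1), 0.0
        )
    return pd.DataFrame(
        {
            "support": support,
            "study_support": study_support,
            "n_up": n_up,
            "n_down": n_down,
            "consistency": consistency,
        },
        index=cells.index,
    )


def consensus_footprint(
    matrix: PresenceMatrix,
    study_of: Mapping[str, str],
    config: ConsensusConfig = ConsensusConfig(),
) -> FootprintSet:
    """Extract the consensus footprint from a presence matrix.

    Deterministic and order-independent: membership depends only on per-gene
    support counts, never on gene or profile ordering.
    """
    if config.min_profiles > len(matrix.profiles):
        raise ConfigurationError(
            f"min_profiles={config.min_profiles} exceeds the {len(matrix.profiles)} "
            f"profiles in the matrix; the footprint would be trivially empty"
        )
    stats = support_statistics(matrix, study_of)
    keep = (stats["support"] >= config.min_profiles) & (
        stats["study_support"] >= config.min_studies
    )
    if config.direction_policy == "strict-consistent":
        keep &= stats["consistency"] == 1.0
    elif config.direction_policy == "majority-consistent":
        keep &= stats["consistency"] >= config.majority_fraction
    table = stats.loc[keep].sort_index()
    return FootprintSet(table, config, matrix.timing_class)


def footprint_overlap(a: FootprintSet, b: FootprintSet) -> tuple[frozenset[str], frozenset[str]]:
    """Genes shared by two footprints, and the direction-consistent subset.

    Direction consistency compares each set's per-gene majority direction;
    genes tied in either set are not counted as consistent.
    """
    shared = a.genes & b.genes
    consistent = frozenset(
        g
        for g in shared
        if a.majority_direction(g) == b.majority_direction(g) != 0
    )
    return frozenset(shared), consistent
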