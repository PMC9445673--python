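"""Multi-gene-list comparison: Venn partitions and overlap summaries.

Used to compare a consensus footprint against external gene collections
(abiotic-stress response sets, redox-perturbation clusters, TF-target sets).
Counts are always computed on deduplicated, ID-normalized sets; percentages
are reported as round-half-even to one decimal *alongside* the raw fraction,
because printed percentages in the literature are ambiguous about rounding
and denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .profiles import ConfigurationError, normalize_gene_id

MAX_VENN_SETS = 6


@dataclass(frozen=True)
class NamedGeneSet:
    """A named set of normalized gene IDs, with optional per-gene directions."""

    name: str
    genes: frozenset[str]
    directions: Mapping[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("gene set name must be nonempty")

    @staticmethod
    def from_iterable(name: str, genes: Iterable[str],
                      directions: Mapping[str, int] | None = None) -> "NamedGeneSet":
        norm = frozenset(normalize_gene_id(g) for g in genes)
        dirs = (
            {normalize_gene_id(g): d for g, d in directions.items()}
            if directions is not None
            else None
        )
        return NamedGeneSet(name, norm, dirs)

    def __len__(self) -> int:
        return len(self.genes)


def read_gene_list(path: str | Path, name: str | None = None) -> NamedGeneSet:
    """One gene per line; blank lines and ``#`` comments ignored."""
    path = Path(path)
    genes = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return NamedGeneSet.from_iterable(name or path.stem, genes)


def read_gmt(path: str | Path) -> list[NamedGeneSet]:
    """Read a GMT file (tab-separated: name, description, member genes...)."""
    sets = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ConfigurationError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
        sets.append(NamedGeneSet.from_iterable(parts[0], parts[2:]))
    return sets


def write_gmt(sets: Sequence[NamedGeneSet], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for s in sets:
        desc = (descriptions or {}).get(s.name, "na")
        lines.append("\t".join([s.name, desc, *sorted(s.genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ortholog_table(path: str | Path, delimiter: str = "\t") -> list[tuple[str, str]]:
    """Two-column gene_id -> ortholog_id table; malformed rows warned and skipped."""
    import warnings

    pairs: list[tuple[str, str]] = []
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split(delimiter)
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            skipped += 1
            continue
        pairs.append((normalize_gene_id(parts[0]), parts[1].strip()))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} malformed mapping rows", stacklevel=2)
    return pairs


@dataclass(frozen=True)
class VennPartition:
    """Disjoint regions of a k-set Venn diagram.

    ``regions`` maps a membership signature (a string of 0/1 per input set,
    in input order) to the sorted genes bearing exactly that signature.  The
    all-zero signature is excluded; regions are disjoint and their union is
    the union of the inputs.
    """

    set_names: tuple[str, ...]
    regions: Mapping[str, tuple[str, ...]]

    def region_sizes(self) -> dict[str, int]:
        return {sig: len(genes) for sig, genes in self.regions.items()}

    def union_size(self) -> int:
        return sum(len(g) for g in self.regions.values())


def venn_partition(sets: Sequence[NamedGeneSet]) -> VennPartition:
    """Partition the union of 2..6 sets into exact-membership regions."""
    k = len(sets)
    if not 2 <= k <= MAX_VENN_SETS:
        raise ConfigurationError(f"venn_partition needs 2..{MAX_VENN_SETS} sets, got {k}")
    universe = frozenset().union(*(s.genes for s in sets))
    regions: dict[str, list[str]] = {
        "".join(bits): []
        for n in range(1, k + 1)
        for idx in combinations(range(k), n)
        for bits in ["".join("1" if i in idx else "0" for i in range(k))]
    }
    for gene in universe:
        sig = "".join("1" if gene in s.genes else "0" for s in sets)
        regions[sig].append(gene)
    return VennPartition(
        tuple(s.name for s in sets),
        {sig: tuple(sorted(genes)) for sig, genes in regions.items()},
    )


def _round_half_even(x: float, decimals: int = 1) -> float:
    # Python's round() is banker's rounding, which is exactly what we document.
    return round(x, decimals)


def multi_overlap(target: NamedGeneSet, others: Sequence[NamedGeneSet]) -> dict:
    """Overlap summary of a target list against several comparator sets.

    Returns per-set shared counts with raw and rounded percentages of
    |target|, the genes shared with all comparators, the genes shared with
    none, and direction-concordant counts where both sides carry directions.
    """
    if len(target) < 1:
        raise ValueError("multi_overlap target must be nonempty")
    n = len(target)
    per_set = []
    for s in others:
        shared = target.genes & s.genes
        entry = {
            "name": s.name,
            "shared": len(shared),
            "fraction": len(shared) / n,
            "percent": _round_half_even(100.0 * len(shared) / n),
        }
        if target.directions is not None and s.directions is not None:
            entry["direction_concordant"] = sum(
                1
                for g in shared
                if target.directions.get(g) == s.directions.get(g)
                and target.directions.get(g) is not None
            )
        per_set.append(entry)
    in_all = target.genes.copy()
    in_any: frozenset[str] = frozenset()
    for s in others:
        in_all &= s.genes
        in_any |= s.genes
    in_none = target.genes - in_any
    return {
        "target": target.name,
        "target_size": n,
        "per_set": per_set,
        "shared_with_all": tuple(sorted(in_all)),
        "shared_with_none": tuple(sorted(in_none)),
        "n_shared_with_all": len(in_all),
        "n_shared_with_none": len(in_none),
    }
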