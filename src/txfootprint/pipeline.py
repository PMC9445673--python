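"""End-to-end orchestration: ingest -> footprints -> comparisons -> enrichment.

A run is driven by a YAML config naming a profile manifest, per-timing-class
consensus thresholds, optional external gene-set collections and an optional
GMT annotation with background.  Every stage writes its tables under the
output directory and the run ends with a machine-readable ``summary.json``
holding all counts and every threshold used.  Report counts are never
hard-coded: reproducing a published analysis is a matter of configuration
(e.g. early 5-of-N from >=4 studies, late 4-of-N from >=4 studies).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .enrichment import GeneSetCollection, enrich
from .footprint import (
    ConsensusConfig,
    FootprintSet,
    consensus_footprint,
    footprint_overlap,
    presence_matrix,
)
from .profiles import (
    ConfigurationError,
    ProfileDatabase,
    ProfileMeta,
    TimingBounds,
    build_database,
)
from .setops import (
    NamedGeneSet,
    multi_overlap,
    read_gene_list,
    read_gmt,
    read_ortholog_table,
    venn_partition,
)

logger = logging.getLogger(__name__)

DEFAULT_CONSENSUS = {
    "short": ConsensusConfig(min_profiles=5, min_studies=4),
    "long": ConsensusConfig(min_profiles=4, min_studies=4),
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    manifest: Path
    outdir: Path
    consensus: dict[str, ConsensusConfig] = field(
        default_factory=lambda: dict(DEFAULT_CONSENSUS)
    )
    bounds: TimingBounds = TimingBounds()
    external_sets: list[Path] = field(default_factory=list)
    annotation_gmt: Path | None = None
    background: Path | None = None
    ortholog_table: Path | None = None
    q: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ConfigurationError(f"q must lie in (0, 1), got {self.q}")
        for p in [self.manifest, *self.external_sets,
                  *( [self.annotation_gmt] if self.annotation_gmt else [] ),
                  *( [self.background] if self.background else [] ),
                  *( [self.ortholog_table] if self.ortholog_table else [] )]:
            if not Path(p).exists():
                raise ConfigurationError(f"configured path does not exist: {p}")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def rel(p):
            return (base / p) if p is not None else None

        consensus = dict(DEFAULT_CONSENSUS)
        for cls, spec in (raw.get("consensus") or {}).items():
            consensus[cls] = ConsensusConfig(
                min_profiles=int(spec["min_profiles"]),
                min_studies=int(spec["min_studies"]),
                direction_policy=spec.get("direction_policy", "any"),
            )
        bounds_raw = raw.get("timing_bounds") or {}
        bounds = TimingBounds(
            short_max=float(bounds_raw.get("short_max", 3.0)),
            long_min=float(bounds_raw.get("long_min", 24.0)),
        )
        return RunConfig(
            manifest=rel(raw["manifest"]),
            outdir=Path(raw.get("outdir", "out")),
            consensus=consensus,
            bounds=bounds,
            external_sets=[rel(p) for p in raw.get("external_sets", [])],
            annotation_gmt=rel(raw.get("annotation_gmt")),
            background=rel(raw.get("background")),
            ortholog_table=rel(raw.get("ortholog_table")),
            q=float(raw.get("q", 0.05)),
        )


def load_manifest(manifest: str | Path, bounds: TimingBounds = TimingBounds()) -> ProfileDatabase:
    """Build a database from a YAML manifest of profile entries."""
    manifest = Path(manifest)
    entries = yaml.safe_load(manifest.read_text())
    specs = []
    for e in entries:
        meta = ProfileMeta(
            profile_id=str(e["id"]),
            study_id=str(e["study"]),
            genotype=str(e.get("genotype", "")),
            perturbation=str(e.get("perturbation", "")),
            timepoint_hours=float(e["timepoint_hours"]),
            comparison=str(e.get("comparison", "")),
            bounds=bounds,
        )
        specs.append((manifest.parent / e["path"], meta))
    return build_database(specs)


def _load_external(path: Path) -> list[NamedGeneSet]:
    if path.suffix.lower() == ".gmt":
        return read_gmt(path)
    return [read_gene_list(path)]


def run_footprint_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    db = load_manifest(config.manifest, config.bounds)
    summary: dict = {"database": db.summary(), "thresholds": {}, "footprints": {}}

    footprints: dict[str, FootprintSet] = {}
    for cls, cc in config.consensus.items():
        pids = db.profile_ids(cls)
        if not pids:
            logger.info("no %s-class profiles; stage skipped", cls)
            continue
        if cc.min_profiles > len(pids):
            raise ConfigurationError(
                f"stage footprint[{cls}]: min_profiles={cc.min_profiles} exceeds "
                f"the {len(pids)} profiles of that class"
            )
        matrix = presence_matrix(db, cls)
        matrix.to_tsv(out / f"presence_{cls}.tsv")
        matrix.to_tsv(out / f"presence_{cls}_binary.tsv", binary=True)
        fp = consensus_footprint(matrix, db.study_of(), cc)
        fp.to_tsv(out / f"footprint_{cls}.tsv")
        fp.to_gene_list(out / f"footprint_{cls}_genes.txt")
        footprints[cls] = fp
        summary["thresholds"][cls] = {
            "min_profiles": cc.min_profiles,
            "min_studies": cc.min_studies,
            "direction_policy": cc.direction_policy,
            "n_profiles": len(pids),
        }
        summary["footprints"][cls] = {
            "n_genes": len(fp),
            "n_deg_union": matrix.cells.shape[0],
        }
        logger.info("footprint[%s]: %d genes of %d DEGs", cls, len(fp),
                    matrix.cells.shape[0])

    if "short" in footprints and "long" in footprints:
        shared, consistent = footprint_overlap(footprints["short"], footprints["long"])
        (out / "footprint_shared_genes.txt").write_text(
            "\n".join(sorted(shared)) + ("\n" if shared else "")
        )
        summary["short_long_overlap"] = {
            "n_shared": len(shared),
            "n_direction_consistent": len(consistent),
            "genes": sorted(shared),
        }

    if config.external_sets:
        externals = [s for p in config.external_sets for s in _load_external(p)]
        summary["external_comparisons"] = {}
        for cls, fp in footprints.items():
            target = NamedGeneSet(f"footprint_{cls}", fp.genes)
            if len(target) == 0:
                continue
            mo = multi_overlap(target, externals)
            summary["external_comparisons"][cls] = mo
            if 1 <= len(externals) <= 5:
                vp = venn_partition([target, *externals])
                pd.Series(vp.region_sizes()).rename("size").to_csv(
                    out / f"venn_{cls}.tsv", sep="\t", index_label="signature"
                )
                summary["external_comparisons"][cls]["venn_regions"] = vp.region_sizes()

    if config.annotation_gmt:
        background = None
        if config.background:
            background = read_gene_list(config.background).genes
        collection = GeneSetCollection.from_gmt(config.annotation_gmt, background)
        summary["enrichment"] = {}
        for cls, fp in footprints.items():
            if len(fp) == 0:
                continue
            res = enrich(NamedGeneSet(f"footprint_{cls}", fp.genes), collection,
                         q=config.q)
            res.to_csv(out / f"enrichment_{cls}.tsv", sep="\t", index=False)
            summary["enrichment"][cls] = {
                "q": config.q,
                "n_categories": int(len(res)),
                "n_significant": int(res["significant"].sum()),
                "top_category": res.iloc[0]["category"] if len(res) else None,
            }

    if config.ortholog_table:
        mapping = read_ortholog_table(config.ortholog_table)
        summary["orthologs"] = {}
        for cls, fp in footprints.items():
            joined = ortholog_join(fp, mapping)
            joined.to_csv(out / f"orthologs_{cls}.tsv", sep="\t", index=False)
            summary["orthologs"][cls] = {
                "n_rows": int(len(joined)),
                "n_mapped": int((joined["ortholog"] != "").sum()),
            }

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary


def ortholog_join(footprint: FootprintSet, mapping: list[tuple[str, str]]) -> pd.DataFrame:
    """Left-join a footprint against a gene -> ortholog mapping.

    Unmapped genes are retained with an empty ortholog field; a gene with
    several mappings yields several rows.
    """
    by_gene: dict[str, list[str]] = {}
    for g, o in mapping:
        by_gene.setdefault(g, []).append(o)
    rows = []
    for gene in footprint.table.index:
        support = int(footprint.table.at[gene, "support"])
        for o in by_gene.get(gene, [""]):
            rows.append((gene, o, support))
    return pd.DataFrame(rows, columns=["gene", "ortholog", "support"])
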