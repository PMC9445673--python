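"""Seeded generators with planted ground truth for every pipeline stage.

The default configuration mirrors the shape of the motivating study: 21
differential-expression profiles from 7 independent studies, split 9 short /
1 medium / 11 long by treatment duration, per-profile DEG counts log-uniform
between 4 and 6,266 against a ~25,000-gene genome, a planted early (short)
consensus footprint of 100 genes each supported by 5-9 of the short profiles
from at least 4 studies, a planted late (long) footprint of 85 genes
supported by 4-11 long profiles, and 6 genes shared between the two.
Background DEGs are drawn uniformly without replacement per profile from the
non-planted genes -- the simplest null consistent with vote counting.  An
optional "hot gene" propensity weights a fraction of background genes up, to
stress-test false-positive footprints.

Everything is deterministic given the seed: one integer-indexed generator
stream per profile, plus one planning stream, so adding profiles never
perturbs the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    ConfigurationError,
    DEGRecord,
    ProfileDatabase,
    ProfileMeta,
    database_from_records,
)

_PLANNING_STREAM = 1_000_003  # offset for the non-profile generator streams


def synthetic_genome(genome_size: int) -> list[str]:
    """Deterministic AGI-shaped gene identifiers (chromosomes cycle 1-5)."""
    if genome_size > 500000:
        raise ConfigurationError("synthetic genome capped at 5 chromosomes x 100k loci")
    return [f"AT{i % 5 + 1}G{i // 5:05d}" for i in range(genome_size)]


@dataclass(frozen=True)
class ProfilePlan:
    """One profile to simulate; degs_count None means draw log-uniformly."""

    profile_id: str
    study_id: str
    timepoint_hours: float
    genotype: str = ""
    perturbation: str = ""
    degs_count: int | None = None


@dataclass(frozen=True)
class PlantedFootprintPlan:
    """Planted consensus signal for one timing class."""

    size: int
    min_support: int
    max_support: int
    min_studies: int = 4
    direction_consistency: float = 0.9

    def __post_init__(self) -> None:
        if not 1 <= self.min_support <= self.max_support:
            raise ConfigurationError("need 1 <= min_support <= max_support")
        if not 0.0 <= self.direction_consistency <= 1.0:
            raise ConfigurationError("direction_consistency must be a probability")


def _default_profiles() -> tuple[ProfilePlan, ...]:
    studies = [f"S{i+1}" for i in range(7)]
    genotypes = ["cat2", "gox2", "35S::GOX2", "cat2gox1", "cat2gox2", "acx1", "cat2"]
    perturbs = ["CO2 shift", "Cd", "2,4-D", "high light", "CO2+HL", "Cd", "CO2 shift"]
    plans = []
    # 9 short-term profiles (0.5-3 h) over studies S1..S7,S1,S2
    short_tp = [0.5, 1, 1, 2, 3, 3, 1, 2, 3]
    for i in range(9):
        plans.append(
            ProfilePlan(
                profile_id=f"P{i+1:02d}",
                study_id=studies[i % 7],
                timepoint_hours=short_tp[i],
                genotype=genotypes[i % 7],
                perturbation=perturbs[i % 7],
            )
        )
    # 1 medium-term profile
    plans.append(ProfilePlan("P10", "S3", 8.0, "cat2", "CO2 shift"))
    # 11 long-term profiles (>=24 h) over studies S4..S7,S1..S7
    long_tp = [24, 24, 48, 48, 72, 72, 96, 24, 48, 72, 96]
    for i in range(11):
        plans.append(
            ProfilePlan(
                profile_id=f"P{i+11:02d}",
                study_id=studies[(i + 3) % 7],
                timepoint_hours=float(long_tp[i]),
                genotype=genotypes[(i + 3) % 7],
                perturbation=perturbs[(i + 3) % 7],
            )
        )
    return tuple(plans)


@dataclass(frozen=True)
class CategoryPlan:
    """One annotation category to plant: size K and target enrichment fold."""

    size: int
    fold: float
    name: str = ""


@dataclass(frozen=True)
class QpcrPlan:
    """Simulated qPCR design: treatments at 0/1/3 h against a 0-h calibrator."""

    target_genes: tuple[str, ...] = ("PEROX_UP", "PEROX_DOWN")
    true_folds: Mapping[str, float] = field(
        default_factory=lambda: {"PEROX_UP": 4.0, "PEROX_DOWN": 0.25}
    )
    reference_gene: str = "TUB4"
    treatments: tuple[str, ...] = ("PQ", "NaCl", "HS", "Cd")
    timepoints_h: tuple[float, ...] = (1.0, 3.0)
    calibrator: tuple[str, float] = ("control", 0.0)
    n_replicates: int = 3
    noise_sd: float = 0.2  # cycles
    efficiencies_pct: Mapping[str, float] = field(default_factory=dict)
    baseline_ct: float = 24.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_size: int = 25000
    profiles: tuple[ProfilePlan, ...] = field(default_factory=_default_profiles)
    planted: Mapping[str, PlantedFootprintPlan] = field(
        default_factory=lambda: {
            "short": PlantedFootprintPlan(size=100, min_support=5, max_support=9),
            "long": PlantedFootprintPlan(size=85, min_support=4, max_support=11),
        }
    )
    shared_planted: int = 6  # genes common to the short and long planted sets
    deg_count_range: tuple[int, int] = (4, 6266)
    hot_gene_fraction: float = 0.0  # background genes with elevated propensity
    hot_gene_weight: float = 1.0
    planted_categories: tuple[CategoryPlan, ...] = (
        CategoryPlan(size=2000, fold=5.0),   # GO-BP-scale stress-response category
        CategoryPlan(size=500, fold=8.0),
    )
    n_filler_categories: int = 30
    filler_category_size: int = 200
    qpcr: QpcrPlan = field(default_factory=QpcrPlan)

    def __post_init__(self) -> None:
        if self.deg_count_range[0] < 1 or self.deg_count_range[0] > self.deg_count_range[1]:
            raise ConfigurationError(f"bad deg_count_range {self.deg_count_range}")
        total_planted = sum(p.size for p in self.planted.values())
        if total_planted >= self.genome_size:
            raise ConfigurationError("planted footprints exceed the genome")


@dataclass
class GroundTruth:
    """Bookkeeping emitted with every simulated database.

    planted: timing_class -> gene -> dict(sign, profiles, signs per profile).
    """

    planted: dict[str, dict[str, dict]]
    genome: list[str]

    def planted_genes(self, timing_class: str) -> frozenset[str]:
        return frozenset(self.planted.get(timing_class, {}))

    def all_planted_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.planted.values():
            out |= set(genes)
        return frozenset(out)

    def planted_incidence(self, timing_class: str) -> dict[str, dict[str, int]]:
        """gene -> {profile_id: sign} for one class (the planted plan)."""
        return {
            g: dict(info["profile_signs"])
            for g, info in self.planted.get(timing_class, {}).items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, genes in self.planted.items():
            for g, info in genes.items():
                rows.append(
                    (cls, g, info["sign"], len(info["profile_signs"]),
                     ",".join(sorted(info["profile_signs"])))
                )
        return pd.DataFrame(
            rows, columns=["timing_class", "gene", "sign", "support", "profiles"]
        )


def _plan_supports(rng: np.random.Generator, plan: PlantedFootprintPlan,
                   pids: list[str], study_of: Mapping[str, str]) -> list[list[str]]:
    """Choose supporting-profile subsets guaranteeing the study spread."""
    if plan.max_support > len(pids):
        raise ConfigurationError(
            f"planted support {plan.max_support} exceeds the {len(pids)} profiles available"
        )
    studies = sorted({study_of[p] for p in pids})
    if plan.min_studies > len(studies):
        raise ConfigurationError(
            f"min_studies={plan.min_studies} but only {len(studies)} studies in class"
        )
    by_study: dict[str, list[str]] = {}
    for p in pids:
        by_study.setdefault(study_of[p], []).append(p)
    out = []
    for _ in range(plan.size):
        s = int(rng.integers(plan.min_support, plan.max_support + 1))
        # one profile from each of min_studies distinct studies, then fill
        chosen_studies = list(rng.choice(studies, size=plan.min_studies, replace=False))
        chosen = [by_study[st][rng.integers(len(by_study[st]))] for st in chosen_studies]
        rest = [p for p in pids if p not in chosen]
        extra = s - len(chosen)
        if extra > 0:
            chosen += list(rng.choice(rest, size=extra, replace=False))
        out.append(sorted(chosen))
    return out


def generate_profile_db(config: SimulationConfig) -> tuple[ProfileDatabase, GroundTruth]:
    """Simulate a profile database with a planted consensus footprint per class.

    Planted genes are placed into exactly their planned profiles with planned
    signs; the remainder of each profile is filled with background DEGs drawn
    uniformly (or hot-gene weighted) without replacement from the non-planted
    genes.  Deterministic given ``config.seed``.
    """
    genome = synthetic_genome(config.genome_size)
    plan_rng = np.random.default_rng([config.seed, _PLANNING_STREAM])

    metas = [
        ProfileMeta(
            profile_id=p.profile_id,
            study_id=p.study_id,
            genotype=p.genotype,
            perturbation=p.perturbation,
            timepoint_hours=p.timepoint_hours,
        )
        for p in config.profiles
    ]
    study_of = {m.profile_id: m.study_id for m in metas}
    by_class: dict[str, list[str]] = {}
    for m in metas:
        by_class.setdefault(m.timing_class, []).append(m.profile_id)

    # --- plant: pick gene identities with the configured cross-class overlap
    classes = [c for c in ("short", "medium", "long") if c in config.planted]
    planted_ids: dict[str, list[str]] = {}
    genome_arr = np.array(genome)
    pool = plan_rng.permutation(config.genome_size)
    cursor = 0
    shared: list[str] = []
    if len(classes) >= 2 and config.shared_planted > 0:
        shared = list(genome_arr[pool[cursor:cursor + config.shared_planted]])
        cursor += config.shared_planted
    for cls in classes:
        size = config.planted[cls].size
        own = size - (len(shared) if cls in classes[:2] and shared else 0)
        take = list(genome_arr[pool[cursor:cursor + own]])
        cursor += own
        planted_ids[cls] = (shared + take) if shared and cls in classes[:2] else take
        if len(planted_ids[cls]) != size:
            raise ConfigurationError(f"planted plan for {cls!r} infeasible")

    planted_truth: dict[str, dict[str, dict]] = {}
    per_profile_planted: dict[str, dict[str, int]] = {m.profile_id: {} for m in metas}
    for cls in classes:
        plan = config.planted[cls]
        pids = by_class.get(cls, [])
        if plan.min_support > len(pids):
            raise ConfigurationError(
                f"planted support for class {cls!r} exceeds its {len(pids)} profiles"
            )
        supports = _plan_supports(plan_rng, plan, pids, study_of)
        planted_truth[cls] = {}
        for gene, sup in zip(planted_ids[cls], supports):
            sign = int(plan_rng.choice([-1, 1]))
            profile_signs = {}
            for pid in sup:
                flip = plan_rng.random() > plan.direction_consistency
                profile_signs[pid] = -sign if flip else sign
                per_profile_planted[pid][gene] = profile_signs[pid]
            planted_truth[cls][gene] = {"sign": sign, "profile_signs": profile_signs}

    all_planted = {g for ids in planted_ids.values() for g in ids}
    background_pool = np.array([g for g in genome if g not in all_planted])
    weights = None
    if config.hot_gene_fraction > 0:
        n_hot = int(round(config.hot_gene_fraction * len(background_pool)))
        w = np.ones(len(background_pool))
        w[:n_hot] = config.hot_gene_weight
        weights = w / w.sum()

    lo, hi = config.deg_count_range
    records: dict[str, set[DEGRecord]] = {}
    for idx, p in enumerate(config.profiles):
        rng = np.random.default_rng([config.seed, idx])
        target = p.degs_count
        if target is None:
            target = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        target = min(target, config.genome_size)
        planted_here = per_profile_planted[p.profile_id]
        recs = {DEGRecord(g, s) for g, s in planted_here.items()}
        n_bg = max(0, target - len(recs))
        n_pool = min(n_bg, len(background_pool))
        bg = rng.choice(background_pool, size=n_pool, replace=False, p=weights)
        signs = rng.choice([-1, 1], size=n_pool)
        recs |= {DEGRecord(str(g), int(s)) for g, s in zip(bg, signs)}
        # near-saturated profiles can exhaust the non-planted pool; spill into
        # genes planted elsewhere (extra support only strengthens the plant)
        if n_bg > n_pool:
            present = {r.gene_id for r in recs}
            spill_pool = np.array([g for g in genome if g not in present])
            spill = rng.choice(spill_pool, size=n_bg - n_pool, replace=False)
            spill_signs = rng.choice([-1, 1], size=len(spill))
            recs |= {DEGRecord(str(g), int(s)) for g, s in zip(spill, spill_signs)}
        records[p.profile_id] = recs

    db = database_from_records(metas, records)
    return db, GroundTruth(planted_truth, genome)


def background_collisions(db: ProfileDatabase, truth: GroundTruth,
                          timing_class: str, min_profiles: int,
                          min_studies: int) -> frozenset[str]:
    """Non-planted genes that reach the consensus thresholds by chance.

    Brute-force bookkeeping scan over the database records, independent of
    the footprint module's implementation.
    """
    pids = db.profile_ids(timing_class)
    study_of = db.study_of()
    planted = truth.planted_genes(timing_class)
    support: dict[str, list[str]] = {}
    for pid in pids:
        for rec in db.records[pid]:
            if rec.gene_id not in planted:
                support.setdefault(rec.gene_id, []).append(pid)
    return frozenset(
        g
        for g, sup in support.items()
        if len(sup) >= min_profiles
        and len({study_of[p] for p in sup}) >= min_studies
    )


def generate_annotation(config: SimulationConfig, query: Sequence[str]):
    """Annotation collection over the simulated genome with planted enrichment.

    Each planted category of size K overlaps the query at
    min(n, K, round(fold * n * K / N)) genes -- ``fold`` times the null
    expectation n*K/N, capped at the feasible maximum.  A fold that needs
    more overlap than min(n, K) is a configuration error.  Filler categories
    are drawn uniformly from the genome, i.e. at null overlap rates.
    """
    from .enrichment import GeneSetCollection
    from .setops import NamedGeneSet

    genome = synthetic_genome(config.genome_size)
    rng = np.random.default_rng([config.seed, _PLANNING_STREAM + 1])
    query_set = [g for g in dict.fromkeys(query) if g in set(genome)]
    n, N = len(query_set), config.genome_size
    if n == 0:
        raise ConfigurationError("query has no genes in the simulated genome")
    non_query = np.array([g for g in genome if g not in set(query_set)])
    sets = []
    for i, cat in enumerate(config.planted_categories):
        K = cat.size
        if K > N:
            raise ConfigurationError(f"category size {K} exceeds genome {N}")
        want = int(round(cat.fold * n * K / N))
        if want > min(n, K):
            raise ConfigurationError(
                f"fold {cat.fold} infeasible for K={K}, n={n}, N={N}: "
                f"needs overlap {want} > min(n, K) = {min(n, K)}"
            )
        overlap = rng.choice(np.array(query_set), size=want, replace=False)
        rest = rng.choice(non_query, size=K - want, replace=False)
        name = cat.name or f"planted_{i+1}"
        sets.append(NamedGeneSet.from_iterable(name, [*overlap, *rest]))
    for j in range(config.n_filler_categories):
        members = rng.choice(np.array(genome), size=config.filler_category_size,
                             replace=False)
        sets.append(NamedGeneSet.from_iterable(f"filler_{j+1}", members))
    return GeneSetCollection.from_sets(sets, background=genome)


def generate_ct_table(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format Ct table plus its true fold-change table.

    Ct = baseline - log_b(expression) + Gaussian noise, with b the gene's
    amplification base (1 + E/100).  The reference gene has fold 1
    everywhere; expression at the calibrator is 1 by definition, so the
    Pfaffl pipeline should recover the planted folds up to Ct noise.
    """
    q = config.qpcr
    rng = np.random.default_rng([config.seed, _PLANNING_STREAM + 2])
    cal_cond, cal_tp = q.calibrator
    cells = [(cal_cond, cal_tp)] + [
        (tr, tp) for tr in q.treatments for tp in q.timepoints_h
    ]
    genes = [*q.target_genes, q.reference_gene]
    ct_rows, truth_rows = [], []
    for gene in genes:
        E = q.efficiencies_pct.get(gene, 100.0)
        b = 1.0 + E / 100.0
        for cond, tp in cells:
            if gene == q.reference_gene or (cond, tp) == (cal_cond, cal_tp):
                fold = 1.0
            else:
                fold = float(q.true_folds.get(gene, 1.0))
            truth_rows.append((gene, cond, tp, fold))
            for rep in range(1, q.n_replicates + 1):
                noise = rng.normal(0.0, q.noise_sd) if q.noise_sd > 0 else 0.0
                ct = q.baseline_ct - np.log(fold) / np.log(b) + noise
                ct_rows.append((gene, cond, tp, rep, ct))
    ct_df = pd.DataFrame(
        ct_rows, columns=["gene", "condition", "timepoint_h", "replicate", "Ct"]
    )
    truth_df = pd.DataFrame(
        truth_rows, columns=["gene", "condition", "timepoint_h", "true_fold"]
    )
    return ct_df, truth_df


def materialize_workspace(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a complete demo workspace: profile TSVs + manifest, GMT, Ct table.

    Emits the same formats the real pipeline reads, plus ground-truth files,
    and returns a dict of the paths written.
    """
    import yaml

    from .profiles import write_profile_table
    from .setops import NamedGeneSet, write_gmt

    outdir = Path(outdir)
    (outdir / "profiles").mkdir(parents=True, exist_ok=True)
    db, truth = generate_profile_db(config)
    manifest = []
    for pid, meta in db.profiles.items():
        path = outdir / "profiles" / f"{pid}.tsv"
        write_profile_table(db.records[pid], path)
        manifest.append(
            {
                "id": pid,
                "study": meta.study_id,
                "genotype": meta.genotype,
                "perturbation": meta.perturbation,
                "timepoint_hours": meta.timepoint_hours,
                "path": f"profiles/{pid}.tsv",
            }
        )
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)

    early = sorted(truth.planted_genes("short"))
    collection = generate_annotation(config, early)
    write_gmt(
        [NamedGeneSet(name, members) for name, members in collection.categories.items()],
        outdir / "annotation.gmt",
    )
    (outdir / "background.txt").write_text("\n".join(sorted(collection.background)) + "\n")

    ct_df, truth_df = generate_ct_table(config)
    ct_df.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
    truth_df.to_csv(outdir / "ct_truth.tsv", sep="\t", index=False)
    return {
        "manifest": str(outdir / "manifest.yaml"),
        "annotation": str(outdir / "annotation.gmt"),
        "background": str(outdir / "background.txt"),
        "ct_table": str(outdir / "ct_table.tsv"),
        "ground_truth": str(outdir / "ground_truth.tsv"),
    }
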