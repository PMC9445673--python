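"""Presence matrices and vote-counting consensus extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txfootprint import (
    ConsensusConfig,
    DEGRecord,
    ProfileMeta,
    consensus_footprint,
    footprint_overlap,
    presence_matrix,
)
from txfootprint.footprint import PresenceMatrix, support_statistics
from txfootprint.profiles import ConfigurationError, database_from_records

import pandas as pd


def tiny_db(records_by_profile, studies=None, timepoint=1.0):
    metas, records = [], {}
    for i, (pid, recs) in enumerate(records_by_profile.items()):
        study = (studies or {}).get(pid, f"S{i+1}")
        metas.append(ProfileMeta(pid, study, timepoint_hours=timepoint))
        records[pid] = {DEGRecord(g, d) for g, d in recs.items()}
    return database_from_records(metas, records)


def brute_force_footprint(cells: pd.DataFrame, study_of, config: ConsensusConfig):
    """Independent oracle: scan every gene, count profiles and studies."""
    out = set()
    for gene in cells.index:
        row = cells.loc[gene]
        sup_profiles = [p for p in cells.columns if row[p] != 0]
        n_up = sum(1 for p in sup_profiles if row[p] > 0)
        n_down = len(sup_profiles) - n_up
        if len(sup_profiles) < config.min_profiles:
            continue
        if len({study_of[p] for p in sup_profiles}) < config.min_studies:
            continue
        if config.direction_policy == "strict-consistent" and n_up and n_down:
            continue
        if (config.direction_policy == "majority-consistent"
                and max(n_up, n_down) / len(sup_profiles) < config.majority_fraction):
            continue
        out.add(gene)
    return out


def random_matrix(rng, n_genes, n_profiles, density=0.4):
    vals = rng.choice([0, 1, -1], size=(n_genes, n_profiles),
                      p=[1 - density, density / 2, density / 2])
    cells = pd.DataFrame(
        vals, index=[f"G{i}" for i in range(n_genes)],
        columns=[f"P{j}" for j in range(n_profiles)], dtype=np.int8,
    )
    return PresenceMatrix(cells, "short")


class TestPresenceMatrix:
    def test_direct_construction(self):
        db = tiny_db({"P1": {"AT1G00001": +1}, "P2": {"AT1G00001": -1, "AT1G00002": +1}})
        m = presence_matrix(db, "short")
        assert m.profiles == ["P1", "P2"]
        assert m.cells.loc["AT1G00001"].tolist() == [1, -1]
        assert m.cells.loc["AT1G00002"].tolist() == [0, 1]
        assert m.binary().loc["AT1G00001"].tolist() == [1, 1]

    def test_nonzero_cells_equal_total_deg_count(self, default_sim):
        _, db, _ = default_sim
        m = presence_matrix(db, "short")
        expected = sum(len(db.records[p]) for p in db.profile_ids("short"))
        assert int((m.cells.to_numpy() != 0).sum()) == expected

    def test_rows_cover_union_of_degs(self, small_sim):
        _, db, _ = small_sim
        m = presence_matrix(db, "long")
        union = {r.gene_id for p in db.profile_ids("long") for r in db.records[p]}
        assert set(m.genes) == union

    def test_planted_incidence_reproduced_exactly(self, small_sim):
        _, db, truth = small_sim
        m = presence_matrix(db, "short")
        for gene, signs in truth.planted_incidence("short").items():
            for pid in m.profiles:
                assert m.cells.at[gene, pid] == signs.get(pid, 0)

    def test_empty_class_is_an_error(self):
        db = tiny_db({"P1": {"AT1G00001": 1}})
        with pytest.raises(ConfigurationError, match="medium"):
            presence_matrix(db, "medium")


class TestConsensusFootprint:
    def test_threshold_boundary_on_studies(self):
        # gene in 5 of 9 profiles; study spread 4 -> in, 3 -> out
        profiles = {f"P{i}": ({"AT1G00001": 1} if i < 5 else {}) for i in range(9)}
        studies4 = {f"P{i}": f"S{min(i, 3)}" for i in range(9)}
        studies3 = {f"P{i}": f"S{min(i, 2)}" for i in range(9)}
        cfg = ConsensusConfig(5, 4)
        db4 = tiny_db(profiles, studies4)
        db3 = tiny_db(profiles, studies3)
        m4 = presence_matrix(db4, "short")
        m3 = presence_matrix(db3, "short")
        assert consensus_footprint(m4, db4.study_of(), cfg).genes == {"AT1G00001"}
        assert consensus_footprint(m3, db3.study_of(), cfg).genes == frozenset()

    def test_support_bookkeeping_columns(self):
        db = tiny_db(
            {"P1": {"g1": 1}, "P2": {"g1": 1}, "P3": {"g1": -1}},
            {"P1": "S1", "P2": "S2", "P3": "S3"},
        )
        m = presence_matrix(db, "short")
        fp = consensus_footprint(m, db.study_of(), ConsensusConfig(3, 3))
        row = fp.table.loc["g1"]
        assert row["support"] == 3 == row["n_up"] + row["n_down"]
        assert row["n_up"] == 2 and row["n_down"] == 1
        assert row["consistency"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("policy", ["any", "majority-consistent", "strict-consistent"])
    def test_matches_brute_force_oracle_on_random_matrices(self, policy):
        rng = np.random.default_rng(42)
        study_of = {f"P{j}": f"S{j % 4}" for j in range(6)}
        cfg = ConsensusConfig(3, 2, direction_policy=policy)
        for _ in range(100):
            m = random_matrix(rng, rng.integers(1, 11), 6)
            got = consensus_footprint(m, study_of, cfg).genes
            assert got == brute_force_footprint(m.cells, study_of, cfg)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_stricter_config_never_adds_genes(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 15, 6)
        study_of = {f"P{j}": f"S{j % 3}" for j in range(6)}
        loose = consensus_footprint(m, study_of, ConsensusConfig(2, 2)).genes
        tighter_p = consensus_footprint(m, study_of, ConsensusConfig(4, 2)).genes
        tighter_s = consensus_footprint(m, study_of, ConsensusConfig(3, 3)).genes
        strict = consensus_footprint(
            m, study_of, ConsensusConfig(2, 2, direction_policy="strict-consistent")
        ).genes
        assert tighter_p <= loose and tighter_s <= loose and strict <= loose

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 20, 6)
        study_of = {f"P{j}": f"S{j % 4}" for j in range(6)}
        cfg = ConsensusConfig(3, 2)
        base = consensus_footprint(m, study_of, cfg).genes
        perm = PresenceMatrix(
            m.cells.sample(frac=1, random_state=1)[list(rng.permutation(m.profiles))],
            m.timing_class,
        )
        assert consensus_footprint(perm, study_of, cfg).genes == base

    def test_trivial_thresholds_give_union(self, small_sim):
        _, db, _ = small_sim
        m = presence_matrix(db, "short")
        fp = consensus_footprint(m, db.study_of(), ConsensusConfig(1, 1))
        assert fp.genes == frozenset(m.genes)

    def test_min_profiles_above_matrix_width_is_config_error(self):
        db = tiny_db({"P1": {"g1": 1}, "P2": {"g1": 1}})
        m = presence_matrix(db, "short")
        with pytest.raises(ConfigurationError, match="min_profiles"):
            consensus_footprint(m, db.study_of(), ConsensusConfig(3, 1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ConsensusConfig(min_profiles=3, min_studies=4)
        with pytest.raises(ConfigurationError):
            ConsensusConfig(direction_policy="bogus")

    def test_fractional_threshold_rounds_up(self):
        cfg = ConsensusConfig.from_fraction(0.55, 9)
        assert cfg.min_profiles == 5

    def test_missing_study_mapping_is_error(self):
        db = tiny_db({"P1": {"g1": 1}})
        m = presence_matrix(db, "short")
        with pytest.raises(ConfigurationError, match="study"):
            support_statistics(m, {})


class TestFootprintOverlap:
    def _fp(self, genes_dirs, timing="short"):
        db = tiny_db({f"P{i}": {} for i in range(1)})
        table = pd.DataFrame(
            {
                "support": [sum(map(abs, d)) for d in genes_dirs.values()],
                "study_support": [1] * len(genes_dirs),
                "n_up": [sum(1 for x in d if x > 0) for d in genes_dirs.values()],
                "n_down": [sum(1 for x in d if x < 0) for d in genes_dirs.values()],
                "consistency": [1.0] * len(genes_dirs),
            },
            index=list(genes_dirs),
        )
        from txfootprint.footprint import FootprintSet
        return FootprintSet(table, ConsensusConfig(1, 1), timing)

    def test_disjoint_sets(self):
        a = self._fp({"g1": [1, 1]})
        b = self._fp({"g2": [1]})
        assert footprint_overlap(a, b) == (frozenset(), frozenset())

    def test_subset_identity(self):
        a = self._fp({"g1": [1], "g2": [-1]})
        b = self._fp({"g1": [1], "g2": [-1], "g3": [1]})
        shared, consistent = footprint_overlap(a, b)
        assert shared == a.genes
        assert consistent == a.genes  # same majority directions

    def test_direction_consistent_subset(self):
        a = self._fp({"g1": [1, 1], "g2": [-1, -1], "g3": [1, -1]})
        b = self._fp({"g1": [1], "g2": [1], "g3": [1]})
        shared, consistent = footprint_overlap(a, b)
        assert shared == {"g1", "g2", "g3"}
        # g2 flips direction, g3 is tied in a -> only g1 is consistent
        assert consistent == {"g1"}
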