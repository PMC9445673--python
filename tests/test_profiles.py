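"""Profile data model, table I/O and timing classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txfootprint import (
    DEGRecord,
    ProfileMeta,
    TimingBounds,
    build_database,
    classify_timing,
    normalize_gene_id,
    read_profile_table,
)
from txfootprint.profiles import (
    ConfigurationError,
    FormatError,
    ProfileDatabase,
    database_from_records,
    read_database,
    write_database,
    write_profile_table,
)


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(c) for c in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestGeneIDs:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("at2g38360", "AT2G38360"),
            ("AT1G05680.1", "AT1G05680"),
            ("ATCG00020.2", "ATCG00020"),
            ("  atmg00090 ", "ATMG00090"),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_gene_id(raw) == expected

    def test_direction_must_be_signed_unit(self):
        with pytest.raises(ValueError):
            DEGRecord("AT1G00001", 0)


class TestReadProfileTable:
    def test_dedup_and_normalization(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, ["gene", "direction"],
                  [["AT1G05680", 1], ["at2g38360", -1], ["AT1G05680", 1]])
        recs = read_profile_table(p)
        assert {(r.gene_id, r.direction) for r in recs} == {
            ("AT1G05680", +1), ("AT2G38360", -1)
        }

    def test_direction_from_logfc_sign(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, ["gene", "logFC"], [["AT1G00010", 2.3], ["AT1G00020", -0.7]])
        recs = {r.gene_id: r.direction for r in read_profile_table(p)}
        assert recs == {"AT1G00010": +1, "AT1G00020": -1}

    def test_zero_logfc_rejected_with_warning(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, ["gene", "logFC"], [["AT1G00010", 0.0], ["AT1G00020", 1.0]])
        with pytest.warns(UserWarning, match="zero fold-change"):
            recs = read_profile_table(p)
        assert {r.gene_id for r in recs} == {"AT1G00020"}

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, ["identifier", "direction"], [["AT1G00010", 1]])
        with pytest.raises(FormatError, match="gene"):
            read_profile_table(p)
        write_tsv(p, ["gene", "score"], [["AT1G00010", 1]])
        with pytest.raises(FormatError, match="direction|logFC"):
            read_profile_table(p)

    def test_conflict_resolved_by_larger_magnitude(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, ["gene", "logFC"], [["AT1G00010", 1.2], ["AT1G00010", -3.0]])
        recs = read_profile_table(p)
        assert {(r.gene_id, r.direction) for r in recs} == {("AT1G00010", -1)}

    def test_conflict_without_tiebreak_drops_gene(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, ["gene", "direction"], [["AT1G00010", 1], ["AT1G00010", -1]])
        with pytest.warns(UserWarning, match="conflicting directions"):
            recs = read_profile_table(p)
        assert recs == set()

    def test_nonstandard_ids_kept_with_warning(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, ["gene", "direction"], [["NOT_AGI_1", 1]])
        with pytest.warns(UserWarning, match="nonstandard"):
            recs = read_profile_table(p)
        assert {r.gene_id for r in recs} == {"NOT_AGI_1"}

    def test_round_trip_is_idempotent_on_synthetic_profile(self, tmp_path, default_sim):
        _, db, _ = default_sim
        pid = max(db.records, key=lambda p: len(db.records[p]))
        original = set(db.records[pid])
        path = tmp_path / "rt.tsv"
        write_profile_table(original, path)
        assert read_profile_table(path) == original
        write_profile_table(read_profile_table(path), path)
        assert read_profile_table(path) == original


class TestClassifyTiming:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.5, "short"), (3.0, "short"), (8.0, "medium"), (23.0, "medium"),
         (24.0, "long"), (96.0, "long")],
    )
    def test_default_boundaries(self, t, expected):
        assert classify_timing(t) == expected

    @pytest.mark.parametrize("t", [0.0, -1.0])
    def test_nonpositive_timepoint_is_domain_error(self, t):
        with pytest.raises(ValueError):
            classify_timing(t)

    @given(st.floats(min_value=1e-6, max_value=1e4, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_total_single_class_and_monotone(self, t):
        cls = classify_timing(t)
        assert cls in ("short", "medium", "long")
        order = {"short": 0, "medium": 1, "long": 2}
        # piecewise-constant monotone: a later timepoint never maps earlier
        assert order[classify_timing(t * 1.5)] >= order[cls]

    def test_configurable_bounds(self):
        b = TimingBounds(short_max=6.0, long_min=48.0)
        assert classify_timing(6.0, b) == "short"
        assert classify_timing(24.0, b) == "medium"


class TestDatabase:
    def test_study_shaped_fixture_partition(self, default_sim):
        _, db, _ = default_sim
        assert db.timing_partition() == {"short": 9, "medium": 1, "long": 11}
        assert db.summary()["n_studies"] == 7
        counts = db.deg_counts()
        assert all(c >= 1 for c in counts.values())

    def test_build_database_from_files(self, tmp_path):
        specs = []
        for i in range(3):
            p = tmp_path / f"p{i}.tsv"
            write_tsv(p, ["gene", "direction"], [[f"AT1G{j:05d}", 1] for j in range(i + 2)])
            specs.append((p, ProfileMeta(f"P{i}", f"S{i % 2}", timepoint_hours=1.0)))
        db = build_database(specs)
        assert db.deg_counts() == {"P0": 2, "P1": 3, "P2": 4}
        # distinct-study support by brute force: AT1G00000 in all three profiles
        sup = [pid for pid in db.profiles if any(r.gene_id == "AT1G00000" for r in db.records[pid])]
        assert len({db.profiles[p].study_id for p in sup}) == 2

    def test_duplicate_profile_id_rejected(self, tmp_path):
        p = tmp_path / "p.tsv"
        write_tsv(p, ["gene", "direction"], [["AT1G00001", 1]])
        meta = ProfileMeta("P1", "S1", timepoint_hours=1.0)
        with pytest.raises(ConfigurationError, match="duplicate"):
            build_database([(p, meta), (p, meta)])

    def test_empty_spec_list_gives_valid_empty_database(self):
        db = build_database([])
        assert db.summary()["n_profiles"] == 0

    def test_record_referencing_unknown_profile_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            ProfileDatabase({}, {"ghost": frozenset({DEGRecord("AT1G00001", 1)})})

    def test_empty_study_id_rejected(self):
        with pytest.raises(ConfigurationError):
            ProfileMeta("P1", "", timepoint_hours=1.0)

    def test_database_directory_round_trip(self, tmp_path, small_sim):
        _, db, _ = small_sim
        write_database(db, tmp_path / "db")
        db2 = read_database(tmp_path / "db")
        assert set(db2.profiles) == set(db.profiles)
        for pid in db.profiles:
            assert {(r.gene_id, r.direction) for r in db2.records[pid]} == {
                (r.gene_id, r.direction) for r in db.records[pid]
            }
            assert db2.profiles[pid].timing_class == db.profiles[pid].timing_class
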