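import pytest

from txfootprint import SimulationConfig, generate_profile_db


@pytest.fixture(scope="session")
def default_sim():
    """The study-shaped synthetic database (21 profiles / 7 studies), seed 7."""
    cfg = SimulationConfig(seed=7)
    db, truth = generate_profile_db(cfg)
    return cfg, db, truth


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast database for I/O and pipeline tests."""
    from txfootprint.synthetic import CategoryPlan, PlantedFootprintPlan, ProfilePlan

    profiles = tuple(
        ProfilePlan(f"Q{i+1:02d}", f"S{i % 5 + 1}", tp, degs_count=60)
        for i, tp in enumerate([1, 2, 3, 1, 2, 3, 1, 2, 3])
    ) + tuple(
        ProfilePlan(f"Q{i+10:02d}", f"S{i % 5 + 1}", 24.0 + i, degs_count=60)
        for i in range(6)
    )
    cfg = SimulationConfig(
        seed=11,
        genome_size=500,
        profiles=profiles,
        planted={
            "short": PlantedFootprintPlan(size=12, min_support=5, max_support=9),
            "long": PlantedFootprintPlan(size=10, min_support=4, max_support=6),
        },
        shared_planted=3,
        deg_count_range=(20, 80),
        planted_categories=(CategoryPlan(size=60, fold=4.0),),
        n_filler_categories=8,
        filler_category_size=40,
    )
    db, truth = generate_profile_db(cfg)
    return cfg, db, truth
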