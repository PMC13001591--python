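"""CSV parsing, culling rules, and aggregation to analysis units."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coccitrend as ct
from conftest import make_records


@pytest.fixture()
def registry():
    return ct.study_registry()


# -- read_trap_csv ----------------------------------------------------------

def test_read_well_formed_rows(tmp_path, registry):
    path = tmp_path / "r.csv"
    make_records([
        (1995, 150, "T1", "R1", "P1", "Coleomegilla maculata", 3),
        (1995, 150, "T1", "R1", "P2", "Harmonia axyridis", 0),
        (1996, 157, "T2", "R2", "P1", "Coccinella septempunctata", 5),
    ]).to_csv(path, index=False)
    df = ct.read_trap_csv(path, registry)
    assert len(df) == 3
    assert list(df.columns) == ct.RECORD_COLUMNS
    assert df["adults"].tolist() == [3, 0, 5]


def test_unknown_species_is_named_in_error(tmp_path, registry):
    path = tmp_path / "r.csv"
    make_records([(1995, 150, "T1", "R1", "P1", "Unknownus beetleus", 3)]).to_csv(path, index=False)
    with pytest.raises(KeyError, match="Unknownus beetleus"):
        ct.read_trap_csv(path, registry)


def test_header_only_file_gives_empty_frame(tmp_path, registry):
    path = tmp_path / "r.csv"
    path.write_text(",".join(ct.RECORD_COLUMNS) + "\n")
    df = ct.read_trap_csv(path, registry)
    assert len(df) == 0


def test_non_integer_count_reports_line_number(tmp_path, registry):
    path = tmp_path / "r.csv"
    path.write_text(
        ",".join(ct.RECORD_COLUMNS) + "\n"
        "1995,150,T1,R1,P1,Coleomegilla maculata,3\n"
        "1995,150,T1,R1,P2,Coleomegilla maculata,2.5\n"
    )
    with pytest.raises(ValueError, match=r"adults.*\[3\]"):
        ct.read_trap_csv(path, registry)


def test_column_remapping(tmp_path, registry):
    path = tmp_path / "r.csv"
    pd.DataFrame(
        [(1995, 150, "T1", "R1", "P1", "Coleomegilla maculata", 3)],
        columns=["yr", "doy", "treatment", "replicate", "trap_id", "species", "n_adults"],
    ).to_csv(path, index=False)
    df = ct.read_trap_csv(path, registry, column_map={"yr": "year", "doy": "day", "n_adults": "adults"})
    assert df.loc[0, "adults"] == 3


# -- cull -------------------------------------------------------------------

def test_cull_rules():
    rec = make_records([
        (1990, 150, "T1", "R1", "P1", "Coleomegilla maculata", 1),
        (1995, 100, "T1", "R1", "P1", "Coleomegilla maculata", 2),
        (1995, 230, "T1", "R1", "P1", "Coleomegilla maculata", 3),
    ])
    out = ct.cull(rec)
    assert len(out) == 1
    assert out.loc[0, "year"] == 1995 and out.loc[0, "day"] == 100


def test_cull_boundaries_inclusive():
    rec = make_records([(1993, 222, "T1", "R1", "P1", "Coleomegilla maculata", 1)])
    assert len(ct.cull(rec)) == 1


def test_cull_preserves_order_and_is_idempotent(default_run):
    culled = ct.cull(default_run["records"])
    again = ct.cull(culled)
    assert culled.equals(again)
    assert (culled["year"] >= 1993).all() and (culled["day"] <= 222).all()


# -- aggregate --------------------------------------------------------------

def test_two_traps_one_week_sums_and_effort(registry):
    rec = make_records([
        (1995, 150, "T1", "R1", "P1", "Coleomegilla maculata", 3),
        (1995, 150, "T1", "R1", "P2", "Coleomegilla maculata", 5),
    ])
    agg = ct.aggregate(rec, registry)
    row = agg[agg["taxon_key"] == "Coleomegilla maculata"].iloc[0]
    assert row["captures"] == 8 and row["effort"] == 2


def test_zero_count_rows_contribute_effort(registry):
    rec = make_records([
        (1995, 150, "T1", "R1", "P1", "Coleomegilla maculata", 0),
        (1995, 157, "T1", "R1", "P1", "Coleomegilla maculata", 2),
    ])
    agg = ct.aggregate(rec, registry)
    row = agg[agg["taxon_key"] == "Coleomegilla maculata"].iloc[0]
    assert row["captures"] == 2 and row["effort"] == 2


def test_group_effort_counts_distinct_trap_weeks(registry):
    # two species on the same trap-week: group effort must not double-count
    rec = make_records([
        (1995, 150, "T1", "R1", "P1", "Coleomegilla maculata", 1),
        (1995, 150, "T1", "R1", "P1", "Cycloneda munda", 2),
    ])
    agg = ct.aggregate(rec, registry).set_index("taxon_key")
    assert agg.loc["native", "effort"] == 1
    assert agg.loc["native", "captures"] == 3
    assert agg.loc["all", "effort"] == 1


def test_conservation_and_partition(default_run):
    agg = default_run["aggregates"]
    culled = ct.cull(default_run["records"])
    species_rows = agg[~agg["taxon_key"].isin(ct.GROUP_KEYS)]
    assert species_rows["captures"].sum() == culled["adults"].sum()
    unit = ["treatment", "replicate", "year"]
    g = agg[agg["taxon_key"].isin(ct.GROUP_KEYS)].pivot_table(
        index=unit, columns="taxon_key", values="captures", fill_value=0, observed=True
    )
    assert (g["native"] + g["exotic"] == g["all"]).all()


def test_aggregation_is_permutation_invariant(registry, small_scenario):
    cfg, species = small_scenario
    rec = ct.generate_scenario(cfg, species)
    reg = ct.registry_from_profiles(species)
    a = ct.aggregate(rec, reg).sort_values(ct.AGGREGATE_COLUMNS).reset_index(drop=True)
    shuffled = rec.sample(frac=1.0, random_state=4).reset_index(drop=True)
    b = ct.aggregate(shuffled, reg).sort_values(ct.AGGREGATE_COLUMNS).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_effort_reflects_missing_trap_weeks(small_scenario):
    # oracle: direct recount of distinct trap-weeks in the generated records
    cfg, species = small_scenario
    rec = ct.generate_scenario(cfg, species)
    reg = ct.registry_from_profiles(species)
    agg = ct.aggregate(rec, reg)
    all_rows = agg[agg["taxon_key"] == "all"]
    full = cfg.traps_per_plot * len(cfg.weeks)
    assert (all_rows["effort"] < full).any()
    for _, row in all_rows.iterrows():
        sub = rec[
            (rec["treatment"] == row["treatment"])
            & (rec["replicate"] == row["replicate"])
            & (rec["year"] == row["year"])
        ]
        assert row["effort"] == len(sub.drop_duplicates(["trap_id", "day"]))


# -- randomized properties --------------------------------------------------

record_rows = st.lists(
    st.tuples(
        st.integers(1985, 2025),
        st.integers(1, 366),
        st.sampled_from(["T1", "T2"]),
        st.sampled_from(["R1", "R2"]),
        st.sampled_from(["P1", "P2", "P3"]),
        st.sampled_from(["Coleomegilla maculata", "Harmonia axyridis"]),
        st.integers(0, 50),
    ),
    max_size=60,
)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(rows=record_rows)
def test_cull_idempotent_and_only_filters(rows):
    rec = make_records(rows)
    out = ct.cull(rec)
    assert len(out) <= len(rec)
    assert ct.cull(out).equals(out)
    kept = (rec["year"] >= 1993) & (rec["day"] <= 222)
    assert len(out) == int(kept.sum())


@settings(derandomize=True, max_examples=60, deadline=None)
@given(rows=record_rows.filter(lambda r: len(r) > 0))
def test_aggregation_conserves_captures(rows):
    rec = make_records(rows)
    agg = ct.aggregate(rec, ct.study_registry())
    species_rows = agg[~agg["taxon_key"].isin(ct.GROUP_KEYS)]
    assert species_rows["captures"].sum() == rec["adults"].sum()
    group_all = agg[agg["taxon_key"] == "all"]
    assert group_all["captures"].sum() == rec["adults"].sum()
    assert (agg.loc[agg["captures"] > 0, "effort"] > 0).all()
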