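"""Metadata cleaning, Q-score filtering, and two-tier redundancy filtering."""

import itertools
import json

import numpy as np
import pytest

from cryoset import (
    MetadataTable,
    clean_entries,
    fetch_entries,
    filter_qscore,
    pairwise_similarity_matrix,
    similarity_filter,
    uniqueness_filter,
    xref_similarity,
)
from cryoset.errors import MetadataParseError, RetrievalError, SimilarityUndefinedError

from conftest import make_entry, random_table


# ---------------------------------------------------------------------------
# retrieval (offline cache path)


def _write_cache(tmp_path, query, records):
    cache = tmp_path / "cache"
    cache.mkdir(exist_ok=True)
    slug = "".join(c if c.isalnum() else "_" for c in query)
    (cache / f"{slug}.json").write_text(json.dumps(records))
    return cache


def test_offline_fixture_roundtrip(tmp_path):
    records = [
        {"emdb_id": f"EMD-{i}", "title": f"t{i}", "resolution": 3.0 + i / 10,
         "fitted_pdbs": [f"7AB{i}"], "qscore": 0.5, "contour_level": 0.1,
         "uniprot_refs": ["P1"]}
        for i in range(5)
    ]
    cache = _write_cache(tmp_path, "ribosome", records)
    table = fetch_entries("ribosome", mode="offline", cache_dir=cache)
    assert len(table) == 5
    assert table.ids() == [f"EMD-{i}" for i in range(5)]


def test_first_fitted_pdb_retained(tmp_path):
    cache = _write_cache(
        tmp_path, "q", [{"emdb_id": "EMD-1", "fitted_pdbs": ["7ABC", "6XYZ"]}]
    )
    table = fetch_entries("q", mode="offline", cache_dir=cache)
    assert table.entries[0].pdb_id == "7ABC"


def test_truncated_cache_fails_closed(tmp_path):
    cache = tmp_path / "cache"
    cache.mkdir()
    (cache / "q.json").write_text('[{"emdb_id": "EMD-1"')
    with pytest.raises(MetadataParseError):
        fetch_entries("q", mode="offline", cache_dir=cache)


def test_missing_cache_is_retrieval_error(tmp_path):
    with pytest.raises(RetrievalError):
        fetch_entries("nothing", mode="offline", cache_dir=tmp_path)


# ---------------------------------------------------------------------------
# cleaning


def test_clean_removes_missing_critical_fields():
    table = MetadataTable(
        [
            make_entry("EMD-1"),
            make_entry("EMD-2", pdb_id=None),
            make_entry("EMD-3", resolution=None),
            make_entry("EMD-4", contour=None),
        ]
    )
    cleaned, report = clean_entries(table)
    assert cleaned.ids() == ["EMD-1"]
    stage = report.stage("missing-fields")
    assert set(stage.discarded) == {"EMD-2", "EMD-3", "EMD-4"}
    assert "pdb_id" in stage.discarded["EMD-2"]


def test_clean_identity_on_complete_table():
    table = MetadataTable([make_entry(f"EMD-{i}") for i in range(4)])
    cleaned, _ = clean_entries(table)
    assert cleaned.ids() == table.ids()


def test_duplicate_title_keeps_best_resolution():
    # exhaustive over both orderings of a 2-entry table
    for first_res, second_res in [(3.5, 3.0), (3.0, 3.5)]:
        table = MetadataTable(
            [
                make_entry("EMD-1", resolution=first_res, title="same"),
                make_entry("EMD-2", resolution=second_res, title="same"),
            ]
        )
        cleaned, _ = clean_entries(table)
        assert len(cleaned) == 1
        assert cleaned.entries[0].resolution == 3.0


# ---------------------------------------------------------------------------
# Q-score filter


def test_qscore_strictly_below_rule():
    scores = [0.30, 0.40, 0.45, 0.39, 0.50]
    table = MetadataTable(
        [make_entry(f"EMD-{i}", q_score=q) for i, q in enumerate(scores)]
    )
    kept, report = filter_qscore(table, 0.4)
    # enumerate all 5 comparisons: strictly-below discards 0.30 and 0.39
    assert len(kept) == 3
    assert set(report.stage("qscore").discarded) == {"EMD-0", "EMD-3"}
    assert any(e.q_score == 0.40 for e in kept)


def test_qscore_missing_fails_with_reason():
    table = MetadataTable([make_entry("EMD-1", q_score=None)])
    kept, report = filter_qscore(table, 0.0)
    assert len(kept) == 0
    assert report.stage("qscore").discarded["EMD-1"] == "missing Q-score"


def test_qscore_zero_threshold_vacuous():
    table = MetadataTable([make_entry(f"EMD-{i}", q_score=0.1 * i) for i in range(5)])
    kept, _ = filter_qscore(table, 0.0)
    assert kept.ids() == table.ids()


# ---------------------------------------------------------------------------
# similarity


def test_xref_similarity_examples():
    a = make_entry("EMD-1", xrefs={"U1", "U2", "U3"})
    b = make_entry("EMD-2", xrefs={"U2", "U3"})
    assert xref_similarity(a, b, "containment") == pytest.approx(1.0)
    assert xref_similarity(a, b, "jaccard") == pytest.approx(2 / 3)
    assert xref_similarity(a, a, "containment") == 1.0
    assert xref_similarity(a, a, "jaccard") == 1.0
    c = make_entry("EMD-3", xrefs={"X1"})
    assert xref_similarity(a, c, "containment") == 0.0
    assert xref_similarity(a, c, "jaccard") == 0.0
    # symmetry
    assert xref_similarity(b, a, "jaccard") == xref_similarity(a, b, "jaccard")


def test_xref_similarity_empty_set_undefined():
    a = make_entry("EMD-1", xrefs={"U1"})
    b = make_entry("EMD-2", xrefs=())
    with pytest.raises(SimilarityUndefinedError):
        xref_similarity(a, b)


def test_pairwise_similarity_matrix():
    mat = pairwise_similarity_matrix([{"a", "b"}, {"b", "c"}, {"d"}], "containment")
    assert np.allclose(np.diag(mat), 1.0)
    assert np.allclose(mat, mat.T)
    assert mat[0, 1] == pytest.approx(0.5)
    assert mat[0, 2] == 0.0 and mat[1, 2] == 0.0
    identical = pairwise_similarity_matrix([{"a"}] * 4)
    assert np.allclose(identical, 1.0)
    disjoint = pairwise_similarity_matrix([{f"x{i}"} for i in range(3)])
    assert np.allclose(disjoint, np.eye(3))


# ---------------------------------------------------------------------------
# uniqueness filter


def test_uniqueness_filter_four_entry_example():
    table = MetadataTable(
        [
            make_entry("EMD-A", resolution=3.2, xrefs={"U1", "U2"}),
            make_entry("EMD-B", resolution=3.0, xrefs={"U1", "U2"}),
            make_entry("EMD-C", resolution=3.5, xrefs={"U3"}),
            make_entry("EMD-D", resolution=3.1, xrefs=()),
        ]
    )
    kept, report = uniqueness_filter(table)
    assert kept.ids() == ["EMD-B", "EMD-C"]
    stage = report.stage("uniqueness")
    assert set(stage.discarded) == {"EMD-A"}
    assert set(stage.flagged) == {"EMD-D"}


def test_uniqueness_filter_identity_when_distinct():
    table = MetadataTable(
        [make_entry(f"EMD-{i}", xrefs={f"U{i}"}) for i in range(5)]
    )
    kept, _ = uniqueness_filter(table)
    assert kept.ids() == table.ids()


# ---------------------------------------------------------------------------
# similarity filter


def test_similarity_filter_greedy_sweep_example():
    table = MetadataTable(
        [
            make_entry("EMD-A", resolution=3.0, xrefs={"U1", "U2"}),
            make_entry("EMD-B", resolution=3.2, xrefs={"U1", "U2", "U3"}),
            make_entry("EMD-C", resolution=3.4, xrefs={"U4"}),
        ]
    )
    kept, report = similarity_filter(table, 0.7, "containment")
    assert kept.ids() == ["EMD-A", "EMD-C"]
    assert "EMD-B" in report.stage("similarity").discarded


def test_similarity_filter_threshold_one_vacuous(rng):
    table, _ = uniqueness_filter(random_table(rng, 20))
    kept, report = similarity_filter(table, 1.0)
    assert kept.ids() == table.ids()
    assert not report.stage("similarity").discarded


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("method", ["containment", "jaccard"])
def test_similarity_filter_pairwise_guarantee(seed, method):
    """Brute force: every retained pair has similarity <= threshold."""
    rng = np.random.default_rng(seed)
    table, _ = uniqueness_filter(random_table(rng, 30, n_accessions=6))
    threshold = 0.6
    kept, _ = similarity_filter(table, threshold, method)
    for a, b in itertools.combinations(kept.entries, 2):
        assert xref_similarity(a, b, method) <= threshold


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_similarity_filter_greedy_optimality(seed):
    """Each discarded entry clashes with a retained better-or-equal one."""
    rng = np.random.default_rng(seed)
    table, _ = uniqueness_filter(random_table(rng, 25, n_accessions=5))
    threshold = 0.5
    kept, report = similarity_filter(table, threshold)
    kept_by_id = {e.emdb_id: e for e in kept}
    all_by_id = {e.emdb_id: e for e in table}
    for eid in report.stage("similarity").discarded:
        e = all_by_id[eid]
        assert any(
            xref_similarity(e, r, "containment") > threshold
            and (r.resolution, r.emdb_id) <= (e.resolution, e.emdb_id)
            for r in kept_by_id.values()
        )


# ---------------------------------------------------------------------------
# shared filter properties


@pytest.mark.parametrize("seed", range(5))
def test_stage_accounting_conserves_entries(seed):
    rng = np.random.default_rng(seed)
    table = random_table(rng, 40)
    t1, r1 = clean_entries(table)
    t2, r2 = filter_qscore(t1, 0.4)
    t3, r3 = uniqueness_filter(t2)
    t4, r4 = similarity_filter(t3, 0.7)
    for report in (r1, r2, r3, r4):
        for stage in report.stages:
            assert (
                stage.n_retained + len(stage.discarded) + len(stage.flagged)
                == stage.n_input
            )
    total_removed = sum(
        len(s.discarded) + len(s.flagged)
        for r in (r1, r2, r3, r4)
        for s in r.stages
    )
    assert len(table) == len(t4) + total_removed


@pytest.mark.parametrize("seed", range(3))
def test_redundancy_filters_idempotent(seed):
    rng = np.random.default_rng(seed)
    table = random_table(rng, 30)
    once, _ = uniqueness_filter(table)
    twice, rep = uniqueness_filter(once)
    assert twice.ids() == once.ids()
    assert not rep.stage("uniqueness").discarded
    s_once, _ = similarity_filter(once, 0.6)
    s_twice, rep2 = similarity_filter(s_once, 0.6)
    assert s_twice.ids() == s_once.ids()
    assert not rep2.stage("similarity").discarded


def test_table_csv_roundtrip(tmp_path, rng):
    table = random_table(rng, 10)
    path = tmp_path / "meta.csv"
    table.to_csv(path)
    back = MetadataTable.from_csv(path)
    assert back.ids() == table.ids()
    for a, b in zip(table, back):
        assert a.xrefs == b.xrefs
        assert a.resolution == b.resolution
        assert a.q_score == b.q_score
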