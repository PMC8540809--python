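"""EC→substrate lookup, class distributions, chi-square, pathway matching."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from nafcflow.formula import CLASS_LABELS
from nafcflow.substrate_pathway import (
    class_distribution,
    compare_distributions,
    filter_substrates,
    match_cid_ec_to_pathways,
    presence_matrix,
    substrates_for_ecs,
)

RXDB = pd.DataFrame(
    [("R1", "1.1.1.1", "c1"), ("R1", "1.1.1.1", "c2"), ("R2", "3.5.1.4", "c1")],
    columns=["rxn_id", "ec", "cid"])
CMPDB = pd.DataFrame(
    [("c1", "octanoate-like", "C8H16O2"), ("c2", "amine-like", "C6H15N")],
    columns=["cid", "cmpdname", "mf"])


def test_substrate_lookup_and_unmatched_reporting():
    table, unmatched = substrates_for_ecs({"1.1.1.1"}, RXDB, CMPDB)
    assert len(table) == 2  # one EC -> one reaction -> two substrates
    assert unmatched == []
    assert set(table["nafc_class"]) == {"O", "N"}
    empty, miss = substrates_for_ecs({"4.1.1.1"}, RXDB, CMPDB)
    assert empty.empty and miss == ["4.1.1.1"]


def test_missing_compound_is_an_error_naming_the_cid():
    rx = pd.DataFrame([("R1", "1.1.1.1", "cX")], columns=["rxn_id", "ec", "cid"])
    with pytest.raises(KeyError, match="cX"):
        substrates_for_ecs({"1.1.1.1"}, rx, CMPDB)


def test_class_distribution_counts_distinct_cids_once():
    table, _ = substrates_for_ecs({"1.1.1.1", "3.5.1.4"}, RXDB, CMPDB)
    dist = class_distribution(table)
    assert dist["O"] == 1       # c1 reached via two ECs, counted once
    assert dist["N"] == 1
    assert dist.sum() == 2
    assert list(dist.index) == list(CLASS_LABELS)
    with pytest.raises(ValueError):
        class_distribution(table.iloc[0:0])


def test_filter_hook_restricts_by_descriptors():
    table, _ = substrates_for_ecs({"1.1.1.1"}, RXDB, CMPDB)
    assert len(filter_substrates(table)) == 2            # defaults off
    assert len(filter_substrates(table, carbon_range=(7, 26))) == 1
    assert len(filter_substrates(table, required_heteroatoms={"O"})) == 1


def dist(**counts):
    return pd.Series({lbl: counts.get(lbl, 0) for lbl in CLASS_LABELS})


def test_chi_square_identity_pinned_case_and_invariance():
    d = dist(O=20, NO=15, S=10)
    same = compare_distributions(d, d)
    assert same.statistic == pytest.approx(0.0, abs=1e-12)
    assert same.p == pytest.approx(1.0)

    res = compare_distributions(dist(O=10, NO=10), dist(O=10, NO=30))
    assert res.statistic == pytest.approx(3.75)
    assert res.df == 1

    d1, d2 = dist(O=12, NO=7, S=9), dist(O=5, NO=14, S=8)
    perm = ["S", "O", "NO"]
    r1 = compare_distributions(d1, d2)
    r2 = compare_distributions(d1.reindex(perm), d2.reindex(perm))
    assert r1.statistic == pytest.approx(r2.statistic)


def test_chi_square_requires_two_usable_classes_and_warns_when_sparse():
    with pytest.raises(ValueError):
        compare_distributions(dist(O=5), dist(O=3))
    with pytest.warns(UserWarning):
        compare_distributions(dist(O=2, NO=1), dist(O=1, NO=2))


def textbook_pearson(table):
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row * col / t.sum()
    stat = ((t - expected) ** 2 / expected).sum()
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, df, chi2.sf(stat, df)


def test_chi_square_agrees_with_textbook_formula_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(30):
        k = int(rng.integers(2, 9))
        labels = list(CLASS_LABELS[:k])
        c1 = {lbl: int(rng.integers(1, 31)) for lbl in labels}
        c2 = {lbl: int(rng.integers(1, 31)) for lbl in labels}
        res = compare_distributions(dist(**c1), dist(**c2))
        stat, df, p = textbook_pearson([[c1[lbl] for lbl in sorted(labels)],
                                        [c2[lbl] for lbl in sorted(labels)]])
        assert res.statistic == pytest.approx(stat, abs=1e-9)
        assert res.df == df
        assert res.p == pytest.approx(p, abs=1e-9)


PWDB = [
    {"pathway_id": "P1", "name": "one", "steps": [{"cid": "c1", "ec": "1.1.1.1"}]},
    {"pathway_id": "P2", "name": "two", "steps": [{"cid": "c1", "ec": "1.1.1.1"},
                                                  {"cid": "c9", "ec": "2.1.1.1"}]},
]


def test_pathway_matching_multiplicity_and_misses():
    with_pw, without = match_cid_ec_to_pathways(
        {("c1", "1.1.1.1"), ("c2", "1.1.1.1")}, PWDB)
    assert len(with_pw) == 2                       # c1 pair hits P1 and P2
    assert set(with_pw["pathway_id"]) == {"P1", "P2"}
    assert without.to_dict("records") == [{"cid": "c2", "ec": "1.1.1.1"}]


def test_pathway_split_is_a_partition_on_random_pair_sets():
    rng = np.random.default_rng(23)
    for _ in range(50):
        pairs = {(f"c{rng.integers(0, 30)}", f"{rng.integers(1, 8)}.1.1.{rng.integers(1, 9)}")
                 for _ in range(rng.integers(1, 40))}
        pwdb = []
        for j in range(rng.integers(1, 6)):
            steps = [{"cid": f"c{rng.integers(0, 30)}",
                      "ec": f"{rng.integers(1, 8)}.1.1.{rng.integers(1, 9)}"}
                     for _ in range(rng.integers(1, 6))]
            pwdb.append({"pathway_id": f"P{j}", "name": "", "steps": steps})
        with_pw, without = match_cid_ec_to_pathways(pairs, pwdb)
        matched = set(zip(with_pw["cid"], with_pw["ec"]))
        missed = set(zip(without["cid"], without["ec"]))
        assert matched | missed == pairs
        assert not matched & missed
        assert len(without) == len(missed)  # one row per missed pair


def hits_df(rows):
    return pd.DataFrame(rows, columns=["culture", "pathway_id", "nafc_class"])


def test_presence_matrix_panels_and_thresholds():
    hits = hits_df([("co", "P1", "O"), ("co", "P1", "O"), ("pure", "P1", "S")])
    pres = presence_matrix(hits).set_index(["culture", "group", "pathway_id"])["present"]
    assert bool(pres[("co", "O", "P1")])
    assert not bool(pres[("co", "S+SO", "P1")])
    assert bool(pres[("pure", "S+SO", "P1")])
    strict = presence_matrix(hits, min_hits=2).set_index(
        ["culture", "group", "pathway_id"])["present"]
    assert bool(strict[("co", "O", "P1")])
    assert not bool(strict[("pure", "S+SO", "P1")])


def test_presence_matrix_empty_and_monotone_under_added_hits():
    assert presence_matrix(hits_df([])).empty
    base = hits_df([("co", "P1", "O")])
    more = hits_df([("co", "P1", "O"), ("co", "P2", "NO"), ("co", "P1", "N")])
    p_base = presence_matrix(base).set_index(["culture", "group", "pathway_id"])["present"]
    p_more = presence_matrix(more).set_index(["culture", "group", "pathway_id"])["present"]
    for key, was_present in p_base.items():
        if was_present:
            assert bool(p_more.get(key, False))
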