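"""Coverage filtering, interval coverage, TPM normalization and MA statistics."""

import numpy as np
import pandas as pd
import pytest

from nafcflow.expression import (
    apply_coverage_filter,
    compute_gene_coverage,
    coverage_filter,
    ma_stats,
    rank_pathways_by_fc,
    tpm,
)


@pytest.mark.parametrize("covered,length,retained", [
    (150, 1000, True),    # absolute threshold, boundary
    (90, 100, True),      # 90% rule rescues a short gene
    (149, 1000, False),   # fails both clauses
    (900, 1000, True),    # 90% boundary
    (899, 1000, True),    # still >= 150 bases
    (0, 200, False),
])
def test_coverage_filter_disjunction(covered, length, retained):
    assert coverage_filter(covered, length) is retained


def test_coverage_filter_is_monotone_in_covered_bases():
    for length in (100, 167, 500, 2000):
        states = [coverage_filter(c, length) for c in range(length + 1)]
        assert states == sorted(states)  # False..False then True..True


def test_coverage_filter_input_validation():
    with pytest.raises(ValueError):
        coverage_filter(300, 200)
    with pytest.raises(ValueError):
        coverage_filter(-1, 200)


def intervals(rows, cols=("contig", "start", "end")):
    return pd.DataFrame(rows, columns=cols)


def test_gene_coverage_containment_abutting_and_overlap():
    genes = intervals([("g1", "c1", 100, 600)], cols=("gene_id", "contig", "start", "end"))
    contained = intervals([("c1", 200, 350)])
    assert compute_gene_coverage(contained, genes)["covered_bases"][0] == 150
    abutting = intervals([("c1", 100, 200), ("c1", 200, 300)])
    assert compute_gene_coverage(abutting, genes)["covered_bases"][0] == 200
    overlapping = intervals([("c1", 100, 200), ("c1", 150, 250)])
    assert compute_gene_coverage(overlapping, genes)["covered_bases"][0] == 150


def test_gene_coverage_rejects_inverted_intervals():
    genes = intervals([("g1", "c1", 0, 100)], cols=("gene_id", "contig", "start", "end"))
    with pytest.raises(ValueError):
        compute_gene_coverage(intervals([("c1", 50, 10)]), genes)


def per_base_oracle(reads, gene_start, gene_end):
    marks = np.zeros(gene_end - gene_start, dtype=bool)
    for s, e in reads:
        lo, hi = max(s, gene_start), min(e, gene_end)
        if lo < hi:
            marks[lo - gene_start:hi - gene_start] = True
    return int(marks.sum())


def test_gene_coverage_equals_per_base_marking_on_random_instances():
    rng = np.random.default_rng(5)
    for _ in range(50):
        g_start = int(rng.integers(0, 500))
        g_end = g_start + int(rng.integers(50, 1000))
        reads = []
        for _ in range(int(rng.integers(0, 50))):
            s = int(rng.integers(0, 1500))
            reads.append((s, s + int(rng.integers(1, 200))))
        genes = intervals([("g", "c1", g_start, g_end)],
                          cols=("gene_id", "contig", "start", "end"))
        rdf = intervals([("c1", s, e) for s, e in reads]) if reads else \
            intervals([], cols=("contig", "start", "end"))
        got = compute_gene_coverage(rdf, genes)["covered_bases"][0]
        assert got == per_base_oracle(reads, g_start, g_end)


GENES = pd.DataFrame({
    "gene_id": ["a", "b", "c"],
    "strain": ["s1", "s1", "s2"],
    "length": [1000, 2000, 500],
})


def counts_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "library", "count"])


def test_tpm_single_gene_library_is_one_million():
    t = tpm(counts_df([("a", "L1", 7)]), GENES)
    assert t["tpm"][0] == pytest.approx(1e6)


def test_tpm_rate_normalization_hand_case():
    t = tpm(counts_df([("a", "L1", 10), ("b", "L1", 40)]), GENES).set_index("gene_id")
    assert t.loc["a", "tpm"] == pytest.approx(333333.33, abs=0.01)
    assert t.loc["b", "tpm"] == pytest.approx(666666.67, abs=0.01)


def test_tpm_scale_invariance_and_library_sum():
    base = counts_df([("a", "L1", 10), ("b", "L1", 40)])
    doubled = base.assign(count=base["count"] * 2)
    pd.testing.assert_frame_equal(tpm(base, GENES), tpm(doubled, GENES))
    sums = tpm(base, GENES).groupby("library")["tpm"].sum()
    assert sums["L1"] == pytest.approx(1e6, abs=1e-3)


def test_tpm_modes_joint_vs_per_strain():
    rows = counts_df([("a", "L1", 10), ("c", "L1", 10)])  # two strains, one library
    per_strain = tpm(rows, GENES, mode="per_strain").set_index("gene_id")
    assert per_strain.loc["a", "tpm"] == pytest.approx(1e6)
    assert per_strain.loc["c", "tpm"] == pytest.approx(1e6)
    joint = tpm(rows, GENES, mode="joint")
    assert joint["tpm"].sum() == pytest.approx(1e6, abs=1e-3)


def test_tpm_zero_library_is_an_error():
    with pytest.raises(ValueError):
        tpm(counts_df([("a", "L1", 0)]), GENES)


def test_ma_symmetry_and_hand_case():
    m, a = ma_stats(100.0, 100.0, pseudocount=0.5)
    assert m == pytest.approx(0.0)
    m, a = ma_stats(200.0, 50.0, pseudocount=0.0)
    assert m == pytest.approx(2.0)
    assert a == pytest.approx(6.6439, abs=1e-4)
    m_swap, a_swap = ma_stats(50.0, 200.0, pseudocount=0.0)
    assert m_swap == pytest.approx(-m)
    assert a_swap == pytest.approx(a)


def test_ma_identity_holds_for_random_pairs():
    rng = np.random.default_rng(9)
    t_c = rng.uniform(0, 1e5, size=1000)
    t_i = rng.uniform(0, 1e5, size=1000)
    psi = 0.5
    m, a = ma_stats(t_c, t_i, pseudocount=psi)
    np.testing.assert_allclose(np.log2(t_c + psi), a + m / 2, atol=1e-9)


def test_ma_requires_pseudocount_for_zeros():
    with pytest.raises(ValueError):
        ma_stats(0.0, 10.0, pseudocount=0.0)


def gp(rows):
    return pd.DataFrame(rows, columns=["gene_id", "pathway_id", "pathway_name"])


def test_rank_pathways_empty_when_nothing_qualifies():
    m = pd.Series({"g1": -1.0, "g2": -2.0})
    ranked = rank_pathways_by_fc(m, gp([("g1", "p1", "P one")]), direction="up")
    assert ranked.empty


def test_rank_pathways_orders_by_count_then_id():
    m = pd.Series({f"g{i}": 1.0 for i in range(10)})
    rows = [(f"g{i}", "pB", "B") for i in range(8)]
    rows += [(f"g{i}", "pA", "A") for i in range(6)]
    rows += [(f"g{i}", "pC", "C") for i in range(6)]
    ranked = rank_pathways_by_fc(m, gp(rows), direction="up")
    assert list(ranked["pathway_id"]) == ["pB", "pA", "pC"]  # 8 first, ties lexicographic
    assert list(ranked["enzyme_count"]) == [8, 6, 6]
    down = rank_pathways_by_fc(m, gp(rows), direction="down")
    assert down.empty


def test_gff3_catalog_converts_one_based_closed_coordinates(tmp_path):
    gff = ("##gff-version 3\n"
           "chr1\tsrc\tgene\t100\t400\t.\t+\t.\tID=gene1\n"
           "chr1\tsrc\tgene\t600\t1000\t.\t-\t.\tID=gene2\n")
    path = tmp_path / "genes.gff3"
    path.write_text(gff)
    from nafcflow.expression import read_gene_catalog_gff
    cat = read_gene_catalog_gff(path, strain="putida").set_index("gene_id")
    assert cat.loc["gene1", "length"] == 301
    assert cat.loc["gene2", "length"] == 401


def test_fixture_tpm_sums_and_planted_top_pathway(bundle, result):
    sums = result.tpm.groupby(["library", "strain"])["tpm"].sum()
    assert np.allclose(sums, 1e6, atol=1e-3)
    top = result.pathway_ranking["up"].iloc[0]
    assert top["pathway_id"] == bundle.manifest["top_pathway_up"]
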