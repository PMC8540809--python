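"""Coverage-filtered TPM expression summaries and consortium/pure MA statistics.

SSH (suppression subtractive hybridization) RNA-seq libraries are enriched in
up-regulated transcripts, so the genes retained after the coverage filter in a
tester library are treated as that culture's up-regulated set.  This module
implements the retention rule (>= 150 covered bases OR >= 90% of gene length),
an interval-union coverage helper standing in for a bedtools step, TPM
normalization, MA statistics between co-culture and pure-culture expression,
and fold-change-based pathway ranking.

Coordinates are 0-based half-open throughout; 1-based GFF3 inputs are
converted at the reader boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "apply_coverage_filter",
    "compute_gene_coverage",
    "coverage_filter",
    "ma_stats",
    "rank_pathways_by_fc",
    "read_counts",
    "read_coverage",
    "read_gene_catalog",
    "read_gene_catalog_gff",
    "tpm",
]


def coverage_filter(covered_bases: int, length: int,
                    min_bases: int = 150, min_frac: float = 0.90) -> bool:
    """Gene retention rule: covered for >= min_bases OR >= min_frac of length.

    The disjunction keeps short genes that can never reach the absolute
    threshold but are almost fully covered.  Monotone in covered_bases.
    """
    if length < 1:
        raise ValueError("gene length must be >= 1")
    if not 0 <= covered_bases <= length:
        raise ValueError(f"covered_bases {covered_bases} outside [0, {length}]")
    return covered_bases >= min_bases or covered_bases / length >= min_frac


def apply_coverage_filter(coverage: pd.DataFrame, genes: pd.DataFrame,
                          min_bases: int = 150, min_frac: float = 0.90) -> pd.DataFrame:
    """Vectorized retention over a coverage table (gene_id[, library], covered_bases).

    Returns the coverage table with a boolean ``retained`` column.
    """
    lengths = genes.set_index("gene_id")["length"]
    df = coverage.copy()
    glen = df["gene_id"].map(lengths)
    if glen.isna().any():
        missing = df.loc[glen.isna(), "gene_id"].unique()[:5]
        raise KeyError(f"genes missing from catalog, e.g. {list(missing)}")
    bad = (df["covered_bases"] < 0) | (df["covered_bases"] > glen)
    if bad.any():
        raise ValueError("covered_bases outside [0, gene length]")
    df["retained"] = (df["covered_bases"] >= min_bases) | (df["covered_bases"] / glen >= min_frac)
    return df


def _union_size(starts: np.ndarray, ends: np.ndarray) -> int:
    order = np.argsort(starts, kind="stable")
    total, cur_s, cur_e = 0, None, None
    for s, e in zip(starts[order], ends[order]):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return int(total)


def compute_gene_coverage(read_intervals: pd.DataFrame,
                          gene_intervals: pd.DataFrame) -> pd.DataFrame:
    """Covered bases per gene from read and gene intervals (0-based half-open).

    covered_bases(g) is the size of the union of read intervals clipped to
    the gene interval, on the gene's contig; abutting reads do not double
    count the junction.  Replaces the usual bedtools coverage step when only
    plain interval tables are at hand.
    """
    for df, what in ((read_intervals, "read"), (gene_intervals, "gene")):
        if (df["end"] < df["start"]).any():
            raise ValueError(f"{what} interval with end < start")
    out = []
    by_contig = dict(tuple(read_intervals.groupby("contig")))
    for row in gene_intervals.itertuples(index=False):
        reads = by_contig.get(row.contig)
        covered = 0
        if reads is not None:
            s = np.maximum(reads["start"].to_numpy(), row.start)
            e = np.minimum(reads["end"].to_numpy(), row.end)
            keep = s < e
            if keep.any():
                covered = _union_size(s[keep], e[keep])
        out.append((row.gene_id, covered))
    return pd.DataFrame(out, columns=["gene_id", "covered_bases"])


def tpm(counts: pd.DataFrame, genes: pd.DataFrame, retained: set | None = None,
        mode: str = "per_strain") -> pd.DataFrame:
    """Transcripts-per-million from a tidy count table (gene_id, library, count).

    rate_g = count_g / length_g; tpm_g = 1e6 * rate_g / sum(rates), the sum
    running over the normalization group.  With mode="per_strain" (default)
    each strain of a composite-genome library is normalized separately, so
    per-organism TPM values are comparable across pure and co-culture
    libraries; mode="joint" normalizes each library as a whole.  ``retained``
    restricts to coverage-filtered genes before normalization.
    """
    if mode not in ("per_strain", "joint"):
        raise ValueError("mode must be 'per_strain' or 'joint'")
    meta = genes.set_index("gene_id")
    df = counts.copy()
    if retained is not None:
        df = df[df["gene_id"].isin(retained)]
    if (df["count"] < 0).any():
        raise ValueError("negative counts")
    df["length"] = df["gene_id"].map(meta["length"])
    if df["length"].isna().any():
        missing = df.loc[df["length"].isna(), "gene_id"].unique()[:5]
        raise KeyError(f"counted genes missing from catalog, e.g. {list(missing)}")
    df["strain"] = df["gene_id"].map(meta["strain"])
    df["rate"] = df["count"] / df["length"]
    group_cols = ["library"] if mode == "joint" else ["library", "strain"]
    totals = df.groupby(group_cols)["rate"].transform("sum")
    zero_groups = df.loc[totals == 0, group_cols].drop_duplicates()
    if len(zero_groups):
        raise ValueError(f"zero total count in {zero_groups.to_dict('records')}")
    df["tpm"] = 1e6 * df["rate"] / totals
    return df[["gene_id", "library", "strain", "tpm"]].reset_index(drop=True)


def ma_stats(tpm_consortium, tpm_individual, pseudocount: float = 0.5):
    """M and A for co-culture vs pure-culture expression of the same gene.

    M = log2((t_c + psi) / (t_i + psi)) — the log fold-change; positive M
    means the gene is more expressed in the consortium.
    A = 0.5 * log2((t_c + psi) * (t_i + psi)) — the mean log expression.
    The identity log2(t_c + psi) = A + M/2 holds exactly.  The pseudocount
    psi (TPM units) keeps genes detected in only one condition finite; it
    may be 0 when both values are positive.
    """
    t_c = np.asarray(tpm_consortium, dtype=float) + pseudocount
    t_i = np.asarray(tpm_individual, dtype=float) + pseudocount
    if (t_c <= 0).any() or (t_i <= 0).any():
        raise ValueError("need a positive pseudocount when a TPM value is 0")
    m = np.log2(t_c / t_i)
    a = 0.5 * np.log2(t_c * t_i)
    if m.ndim == 0:
        return float(m), float(a)
    return m, a


def rank_pathways_by_fc(m_per_gene: pd.Series, gene_pathways: pd.DataFrame,
                        direction: str = "up", top_k: int | None = None) -> pd.DataFrame:
    """Rank pathways by how many member enzymes changed in one direction.

    A gene qualifies when M > 0 (fold-change > 1) for direction="up", M < 0
    for "down".  Pathways are ranked by the count of qualifying member
    genes, descending, ties broken lexicographically on pathway ID so the
    output is deterministic.  Output columns: pathway_id, name (if present
    in the map), enzyme_count, genes.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    qualifying = m_per_gene[m_per_gene > 0] if direction == "up" else m_per_gene[m_per_gene < 0]
    hits = gene_pathways[gene_pathways["gene_id"].isin(qualifying.index)]
    if hits.empty:
        return pd.DataFrame(columns=["pathway_id", "name", "enzyme_count", "genes"])
    agg = {"gene_id": lambda g: sorted(set(g))}
    name_col = "pathway_name" if "pathway_name" in gene_pathways.columns else None
    grouped = hits.groupby("pathway_id").agg(genes=("gene_id", lambda g: sorted(set(g))))
    grouped["enzyme_count"] = grouped["genes"].map(len)
    if name_col:
        names = gene_pathways.drop_duplicates("pathway_id").set_index("pathway_id")[name_col]
        grouped["name"] = grouped.index.map(names)
    else:
        grouped["name"] = ""
    grouped = grouped.reset_index().sort_values(
        ["enzyme_count", "pathway_id"], ascending=[False, True]).reset_index(drop=True)
    grouped = grouped[["pathway_id", "name", "enzyme_count", "genes"]]
    return grouped.head(top_k) if top_k is not None else grouped


# ---------------------------------------------------------------- readers

def read_gene_catalog(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "strain": str})


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "library": str})


def read_coverage(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def read_gene_catalog_gff(path, strain: str, feature_type: str = "gene") -> pd.DataFrame:
    """Gene catalog from a GFF3 file; 1-based closed GFF coordinates become lengths."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for feat in db.features_of_type(feature_type):
        rows.append((feat.id, strain, feat.end - feat.start + 1))
    return pd.DataFrame(rows, columns=["gene_id", "strain", "length"])
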