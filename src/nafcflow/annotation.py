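"""Annotation merging, EC consolidation and GO-style over-representation.

Gene annotations arrive from two independent sources per evidence type (GO
terms from homology- and domain-based tools; EC numbers from an EC-mapping
tool and from curated reference proteomes).  This module merges them with
provenance, tabulates enzymes by top-level EC class, and performs
hypergeometric over-representation with Benjamini-Hochberg correction.

The GeneRatio reported here is k/K — up-regulated genes carrying the term
over genome genes carrying the term.  That differs from the common k/n
convention, which is emitted alongside as ``de_ratio``.
"""

from __future__ import annotations

import re
import warnings

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EC_CLASS_NAMES",
    "consolidate_ec",
    "enzyme_class_table",
    "is_partial_ec",
    "merge_term_sets",
    "overrepresentation",
    "read_annotations",
    "read_term_universe",
    "validate_ec",
]

EC_CLASS_NAMES = {
    1: "EC 1—Oxidoreductases",
    2: "EC 2—Transferases",
    3: "EC 3—Hydrolases",
    4: "EC 4—Lyases",
    5: "EC 5—Isomerases",
    6: "EC 6—Ligases",
    7: "EC 7—Translocases",
}

_EC_RE = re.compile(r"^([1-7])\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")


class AnnotationError(ValueError):
    """Raised for malformed annotation records (e.g. bad EC strings)."""


def validate_ec(ec: str, context: str = "") -> str:
    """Check d.d.d.d shape with top-level digit 1..7; '-' fields are partial."""
    if not isinstance(ec, str) or not _EC_RE.match(ec):
        where = f" ({context})" if context else ""
        raise AnnotationError(f"malformed EC number {ec!r}{where}")
    return ec


def is_partial_ec(ec: str) -> bool:
    validate_ec(ec)
    return "-" in ec


def top_level_class(ec: str) -> int:
    validate_ec(ec)
    return int(ec.split(".", 1)[0])


def merge_term_sets(records: pd.DataFrame) -> pd.DataFrame:
    """Union of term sets per gene across sources, keeping provenance.

    ``records`` has columns gene_id, source, term.  The union is commutative,
    associative and idempotent over sources.  Output: one row per (gene,
    term) with ``sources`` a sorted tuple of contributing sources.
    """
    if records.empty:
        return pd.DataFrame(columns=["gene_id", "term", "sources"])
    merged = (records.groupby(["gene_id", "term"])["source"]
              .agg(lambda s: tuple(sorted(set(s)))).rename("sources").reset_index())
    return merged.sort_values(["gene_id", "term"]).reset_index(drop=True)


def to_sets(merged: pd.DataFrame) -> dict[str, set]:
    """Collapse a merged annotation table to {gene_id: set of terms}."""
    if merged.empty:
        return {}
    return {g: set(t) for g, t in merged.groupby("gene_id")["term"]}


def consolidate_ec(source_a: dict[str, set], source_b: dict[str, set],
                   mode: str = "union",
                   names: tuple[str, str] = ("a", "b")) -> pd.DataFrame:
    """Cross-reference two gene→EC-set mappings.

    mode="union" (default) keeps every EC seen by either source and flags
    whether both agreed ("both") or only one saw it; mode="intersection"
    keeps only concordant ECs.  Malformed EC strings raise, naming the gene.
    Output columns: gene_id, ec, agreement.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    rows = []
    for gene in sorted(set(source_a) | set(source_b)):
        ecs_a = {validate_ec(e, f"gene {gene}, source {names[0]}") for e in source_a.get(gene, set())}
        ecs_b = {validate_ec(e, f"gene {gene}, source {names[1]}") for e in source_b.get(gene, set())}
        pool = ecs_a & ecs_b if mode == "intersection" else ecs_a | ecs_b
        for ec in sorted(pool):
            if ec in ecs_a and ec in ecs_b:
                flag = "both"
            elif ec in ecs_a:
                flag = names[0]
            else:
                flag = names[1]
            rows.append((gene, ec, flag))
    return pd.DataFrame(rows, columns=["gene_id", "ec", "agreement"])


def enzyme_class_table(culture_gene_ecs: dict[str, dict[str, set]]) -> pd.DataFrame:
    """Gene counts per top-level EC class per culture.

    ``culture_gene_ecs`` maps culture label -> {gene_id: EC set}.  A gene
    contributes at most once per top-level class even when it carries several
    ECs of that class; a multi-class gene contributes to each of its classes.
    Partial ECs still carry an unambiguous top-level digit and are counted.
    """
    data = {}
    for culture, gene_ecs in culture_gene_ecs.items():
        counts = dict.fromkeys(range(1, 8), 0)
        for gene, ecs in gene_ecs.items():
            for cls in {top_level_class(e) for e in ecs}:
                counts[cls] += 1
        data[culture] = counts
    table = pd.DataFrame(data)
    table.index = [EC_CLASS_NAMES[i] for i in table.index]
    table.index.name = "enzyme_class"
    return table


def overrepresentation(term_to_genes: dict[str, set], de_genes: set,
                       universe: set | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in an up-regulated gene set.

    For each term with K genome genes, of which k are among the n
    up-regulated genes in a genome of N, the upper-tail p-value
    P(X >= k) is computed under the hypergeometric null, then BH-adjusted
    across all tested terms.  gene_ratio = k/K; de_ratio = k/n.  Terms with
    K = 0 are skipped with a warning.
    """
    if universe is None:
        universe = set().union(*term_to_genes.values()) if term_to_genes else set()
    universe = set(universe)
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the gene universe")
    N, n = len(universe), len(de)
    rows = []
    for term in sorted(term_to_genes):
        genes = set(term_to_genes[term]) & universe
        K = len(genes)
        if K == 0:
            warnings.warn(f"term {term} has no genes in the universe; skipped")
            continue
        k = len(genes & de)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, k / K, k / n if n else 0.0, p))
    result = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N",
                                         "gene_ratio", "de_ratio", "p"])
    if result.empty:
        result["p_adj"] = []
        result["significant"] = []
        return result
    result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
    result["significant"] = result["p_adj"] < alpha
    return result.sort_values(["p", "term"]).reset_index(drop=True)


# ---------------------------------------------------------------- readers

def read_annotations(path) -> pd.DataFrame:
    """Annotation TSV with columns gene_id, source, term."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_term_universe(path) -> dict[str, set]:
    """Term-universe TSV (term, gene_id) -> {term: gene set}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {t: set(g) for t, g in df.groupby("term")["gene_id"]}
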