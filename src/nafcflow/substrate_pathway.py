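"""EC→substrate→heteroatom-class matching and pathway presence inference.

A local reaction/compound/pathway store (flat TSV/CSV/JSON files emulating
MetaCyc and PubChem exports) maps the EC numbers of up-regulated gene
products to the PubChem-style CIDs and molecular formulas of their canonical
substrates.  Substrates are classified into the eight NAFC heteroatom
classes, class distributions of different cultures are compared with
Pearson's chi-square test, and (CID, EC) pairs are interrogated against
pathway step sets to build presence/absence matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .formula import CLASS_LABELS, _parse_cached, classify, dbe

__all__ = [
    "DEFAULT_CLASS_GROUPS",
    "ChiSquareResult",
    "class_distribution",
    "compare_distributions",
    "filter_substrates",
    "load_compound_db",
    "load_pathway_db",
    "load_reaction_db",
    "match_cid_ec_to_pathways",
    "presence_matrix",
    "substrates_for_ecs",
]

#: The four heteroatom panels used for presence matrices; CH and NS fall in
#: a residual panel rather than being dropped.
DEFAULT_CLASS_GROUPS = {
    "N+NO": frozenset({"N", "NO"}),
    "O": frozenset({"O"}),
    "NOS": frozenset({"NOS"}),
    "S+SO": frozenset({"S", "SO"}),
    "other": frozenset({"CH", "NS"}),
}


def substrates_for_ecs(ecs, rxdb: pd.DataFrame, cmpdb: pd.DataFrame):
    """Canonical substrates for a set of complete EC numbers.

    rxdb has one row per (rxn_id, ec, cid) substrate; cmpdb maps cid to
    cmpdname and mf.  Returns ``(table, unmatched)``: one row per distinct
    (cid, ec) pair with formula, species and class columns, plus the sorted
    list of ECs that hit no reaction (reported, never silently dropped).
    A cid referenced by a reaction but absent from the compound table is an
    error naming the cid.
    """
    ecs = set(ecs)
    hits = rxdb[rxdb["ec"].isin(ecs)]
    unmatched = sorted(ecs - set(hits["ec"]))
    pairs = hits[["cid", "ec"]].drop_duplicates().sort_values(["ec", "cid"])
    meta = cmpdb.set_index("cid")
    missing = sorted(set(pairs["cid"]) - set(meta.index))
    if missing:
        raise KeyError(f"compound(s) {missing} referenced by reactions but missing "
                       f"from the compound table")
    out = pairs.reset_index(drop=True)
    parsed = out["cid"].map(meta["mf"]).map(_parse_cached)
    out["mf"] = parsed.map(lambda e: e.formula)
    out["nafc_class"] = parsed.map(classify)
    out["carbon"] = parsed.map(lambda e: e.c)
    out["dbe"] = parsed.map(dbe)
    return out, unmatched


def filter_substrates(table: pd.DataFrame, carbon_range: tuple | None = None,
                      dbe_range: tuple | None = None,
                      required_heteroatoms: set | None = None) -> pd.DataFrame:
    """Optional molecular-descriptor filter hook for candidate substrates.

    All criteria default to off; pass a (lo, hi) carbon or DBE range, or a
    set of heteroatom element symbols ({'N','O','S'}) that must be present.
    """
    df = table
    if carbon_range is not None:
        df = df[(df["carbon"] >= carbon_range[0]) & (df["carbon"] <= carbon_range[1])]
    if dbe_range is not None:
        df = df[(df["dbe"] >= dbe_range[0]) & (df["dbe"] <= dbe_range[1])]
    if required_heteroatoms:
        parsed = df["mf"].map(_parse_cached)
        mask = pd.Series(True, index=df.index)
        for sym in required_heteroatoms:
            mask &= parsed.map(lambda e, a=sym.lower(): getattr(e, a) > 0)
        df = df[mask]
    return df.reset_index(drop=True)


def class_distribution(substrates: pd.DataFrame) -> pd.Series:
    """Distinct-CID counts per heteroatom class, over all eight classes.

    A compound reached through several ECs counts once, preventing multi-EC
    inflation of its class.
    """
    if substrates.empty:
        raise ValueError("empty substrate table")
    counts = substrates.drop_duplicates("cid")["nafc_class"].value_counts()
    return counts.reindex(CLASS_LABELS, fill_value=0).astype(int)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def compare_distributions(d1: pd.Series, d2: pd.Series) -> ChiSquareResult:
    """Pearson chi-square on the 2×k table of two class distributions.

    Classes with zero combined count are dropped before computing, so
    df = k − 1 over usable classes; no continuity correction.  Low expected
    counts (< 5) trigger a warning, not a failure.
    """
    labels = sorted(set(d1.index) | set(d2.index))
    table = np.array([
        [int(d1.get(lbl, 0)) for lbl in labels],
        [int(d2.get(lbl, 0)) for lbl in labels],
    ])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("need at least two classes with nonzero combined count")
    stat, p, dof, expected = chi2_contingency(table, correction=False)
    if (expected < 5).any():
        warnings.warn("chi-square expected count below 5; p-value is approximate")
    return ChiSquareResult(statistic=float(stat), df=int(dof), p=float(p))


def match_cid_ec_to_pathways(pairs, pwdb: list[dict]):
    """Split (cid, ec) pairs by whether any pathway contains them as a step.

    ``pwdb`` is a list of {pathway_id, name, steps:[{cid, ec}]} records.
    Returns (with_pathway, without_pathway): the first lists every
    (pair, pathway) hit, the second the pairs hitting no pathway.  Every
    input pair lands in exactly one of the two outputs (hit pairs may span
    several rows, one per matching pathway).
    """
    pairs = {(str(c), str(e)) for c, e in pairs}
    hit_rows, matched = [], set()
    for pw in pwdb:
        steps = {(str(s["cid"]), str(s["ec"])) for s in pw["steps"]}
        for cid, ec in sorted(pairs & steps):
            hit_rows.append((cid, ec, pw["pathway_id"], pw.get("name", "")))
            matched.add((cid, ec))
    with_pw = pd.DataFrame(hit_rows, columns=["cid", "ec", "pathway_id", "pathway_name"])
    with_pw = with_pw.sort_values(["cid", "ec", "pathway_id"]).reset_index(drop=True)
    without = pd.DataFrame(sorted(pairs - matched), columns=["cid", "ec"])
    return with_pw, without


def presence_matrix(hits: pd.DataFrame, class_groups: dict | None = None,
                    min_hits: int = 1) -> pd.DataFrame:
    """Boolean culture × heteroatom-group × pathway presence table.

    ``hits`` needs columns culture, pathway_id, nafc_class (a with_pathway
    table annotated with the substrate class and culture).  A pathway is
    present for (culture, group) when at least ``min_hits`` supporting hits
    have a substrate class inside the group.  Long-form output: culture,
    group, pathway_id, present.
    """
    groups = class_groups or DEFAULT_CLASS_GROUPS
    cultures = sorted(hits["culture"].unique()) if len(hits) else []
    pathways = sorted(hits["pathway_id"].unique()) if len(hits) else []
    rows = []
    for culture in cultures:
        sub = hits[hits["culture"] == culture]
        for group, members in groups.items():
            in_group = sub[sub["nafc_class"].isin(members)]
            support = in_group.groupby("pathway_id").size()
            for pw in pathways:
                rows.append((culture, group, pw, bool(support.get(pw, 0) >= min_hits)))
    return pd.DataFrame(rows, columns=["culture", "group", "pathway_id", "present"])


# ---------------------------------------------------------------- loaders

def load_reaction_db(path) -> pd.DataFrame:
    """Reaction TSV: rxn_id, ec, cid — one row per reaction substrate."""
    return pd.read_csv(path, sep="\t", dtype=str)


def load_compound_db(path) -> pd.DataFrame:
    """Compound CSV: cid, cmpdname, mf."""
    df = pd.read_csv(path, dtype=str)
    if df["cid"].duplicated().any():
        dup = df.loc[df["cid"].duplicated(), "cid"].iloc[0]
        raise ValueError(f"duplicate cid {dup} in compound database")
    return df


def load_pathway_db(path) -> list[dict]:
    """Pathway JSON: [{pathway_id, name, steps:[{cid, ec}]}] with non-empty steps."""
    with open(path) as fh:
        pwdb = json.load(fh)
    for pw in pwdb:
        if not pw.get("steps"):
            raise ValueError(f"pathway {pw.get('pathway_id')} has no steps")
    return pwdb
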