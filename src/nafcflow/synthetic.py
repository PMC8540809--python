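"""Seeded synthetic fixtures with planted ground truth for every pipeline stage.

One integer seed drives a root generator; every file draws from its own named
sub-stream, so adding a file never perturbs the others and the same seed
yields byte-identical fixtures.  The generator emulates the study conditions
of an SSH RNA-seq + Orbitrap comparison of two Pseudomonas strains and their
1:1 co-culture degrading NAFCs:

* per-strain gene catalogs with planted up-regulated gene sets per culture
  (SSH tester libraries: retained genes ARE the up-regulated set);
* EC and GO annotations from two sources with partial cross-source agreement;
* a local reaction/compound/pathway store whose substrates span all eight
  heteroatom classes (carbons 5-25, DBE 1-10), with a planted class-
  distribution shift between pure cultures and the co-culture;
* pathways with planted culture-specific presence (co-culture-only,
  pure-only, everywhere);
* before/after MS feature tables with planted classic-NA percent removal
  (exact in aggregate, noisy per compound), completely-removed species and
  newly-produced species.

The manifest records every planted fact, so expected pipeline outputs can be
computed independently of the pipeline itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formula import CLASS_LABELS, ElementCounts

__all__ = [
    "CULTURES",
    "STRAINS",
    "FixtureBundle",
    "FixtureConfig",
    "FixtureError",
    "generate_fixture",
    "load_fixture",
    "null_config",
    "null_fixture",
    "simulate_class_counts",
    "write_fixture",
]

STRAINS = ("putida", "protegens")
CULTURES = ("putida", "protegens", "coculture")

# Pure-culture heteroatom-class mix: O and NO dominate (O+NO = 0.76, above
# the >75% share reported for degraded compounds), S/SO/N minor, CH trace.
PURE_CLASS_PROBS = {
    "CH": 0.01, "N": 0.06, "NS": 0.02, "NO": 0.30,
    "O": 0.46, "NOS": 0.04, "S": 0.06, "SO": 0.05,
}
# Co-culture mix: O grows at the expense of NO, and the S/SO classes are
# lost — the qualitative shift seen between pure cultures and the consortium.
COCULTURE_CLASS_PROBS = {
    "CH": 0.005, "N": 0.08, "NS": 0.005, "NO": 0.18,
    "O": 0.66, "NOS": 0.06, "S": 0.0, "SO": 0.01,
}

_BASE_SPECIES = {
    "O": ("O3", "O4", "O5", "O6"),
    "NO": ("NO", "N2O", "NO2"),
    "N": ("N", "N2"),
    "NS": ("NS",),
    "NOS": ("NOS",),
    "S": ("S2", "S3"),
    "SO": ("SO2", "SO3"),
    "CH": ("CH",),
}

_STREAMS = {name: i for i, name in enumerate(
    ["genes", "upregulated", "counts", "coverage", "ecs", "ec_annotations",
     "go", "substrates", "pathways", "gene_maps", "ms"])}


class FixtureError(ValueError):
    """Raised for infeasible fixture configurations, before any file is written."""


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the fixture generator; defaults are the study conditions."""

    seed: int = 0
    n_genes_per_strain: int = 200
    gene_length_range: tuple[int, int] = (200, 3000)
    fraction_upregulated: float = 0.25
    n_ecs_pure: int = 40
    n_ecs_coculture: int = 60
    substrates_per_reaction: tuple[int, int] = (1, 3)
    class_probs_pure: dict = field(default_factory=lambda: dict(PURE_CLASS_PROBS))
    class_probs_coculture: dict = field(default_factory=lambda: dict(COCULTURE_CLASS_PROBS))
    n_pathways: int = 25
    n_terms: int = 30
    n_gene_maps: int = 12
    plant_enriched_terms: bool = True
    classic_na_count: int = 131
    classic_na_total: float = 28.2
    removal: dict = field(default_factory=lambda: {
        "putida": 0.11, "protegens": 0.12, "coculture": 0.31})
    removed_species: tuple = ("S", "N2S3", "NOS2", "N2OS2")
    produced_species: tuple = ("O7", "O8", "N2O2", "S2O3")
    concentration_noise: float = 0.15
    annotation_agreement: float = 0.7


@dataclass
class FixtureBundle:
    """In-memory fixture: every module's input tables plus the manifest."""

    config: FixtureConfig | None
    genes: pd.DataFrame
    counts: pd.DataFrame
    coverage: pd.DataFrame
    ec_annotations: pd.DataFrame
    go_annotations: pd.DataFrame
    term_universe: pd.DataFrame
    gene_pathways: pd.DataFrame
    reactions: pd.DataFrame
    compounds: pd.DataFrame
    pathways: list
    ms_features: pd.DataFrame
    manifest: dict


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _species_counts(label: str) -> tuple[int, int, int]:
    """(n, o, s) atom counts from a species label such as 'N2O2' or 'CH'."""
    if label == "CH":
        return 0, 0, 0
    counts = {"N": 0, "O": 0, "S": 0}
    pos = 0
    for m in re.finditer(r"([NOS])(\d*)", label):
        if m.start() != pos:
            raise FixtureError(f"bad species label {label!r}")
        counts[m.group(1)] = int(m.group(2)) if m.group(2) else 1
        pos = m.end()
    if pos != len(label) or sum(counts.values()) == 0:
        raise FixtureError(f"bad species label {label!r}")
    return counts["N"], counts["O"], counts["S"]


def _canonical_species(label: str) -> str:
    """Rewrite a species label in canonical N, O, S order (e.g. S2O3 -> O3S2)."""
    from .formula import ElementCounts, species_label

    n, o, s = _species_counts(label)
    if n == o == s == 0:
        return "CH"
    return species_label(ElementCounts(c=1, h=2, n=n, o=o, s=s))


def _formula_for(rng: np.random.Generator, n: int, o: int, s: int,
                 carbon: int | None = None, dbe_val: int | None = None) -> ElementCounts:
    """A random composition with the requested heteroatoms, C 5-25, DBE 1-10."""
    c = int(carbon) if carbon is not None else int(rng.integers(5, 26))
    d = int(dbe_val) if dbe_val is not None else int(rng.integers(1, min(10, c) + 1))
    h = 2 * (c + 1 - d) + n  # integral DBE by construction
    return ElementCounts(c=c, h=h, n=n, o=o, s=s)


def _draw_substrate_classes(rng: np.random.Generator, probs: np.ndarray,
                            n_ecs: int, lo: int, hi: int):
    """Substrates per EC and a heteroatom class per substrate.

    Every substrate compound is unique to its reaction, so the class draws
    are iid across substrates — the property that keeps the chi-square
    comparison of distinct-CID class counts calibrated.
    """
    sizes = rng.integers(lo, hi + 1, size=n_ecs)
    total = int(sizes.sum())
    labels = [CLASS_LABELS[i] for i in rng.choice(len(CLASS_LABELS), size=total, p=probs)]
    return sizes, labels


def simulate_class_counts(rng: np.random.Generator, class_probs: dict, n_ecs: int,
                          substrates_per_reaction: tuple[int, int] = (1, 3)) -> pd.Series:
    """Distinct-CID class counts as the full generator would produce them.

    Each substrate compound is unique to its reaction, so class counts are
    the tallied iid class draws.  Used for chi-square calibration runs
    without writing any files.
    """
    probs = np.array([class_probs.get(lbl, 0.0) for lbl in CLASS_LABELS], dtype=float)
    probs = probs / probs.sum()
    _, labels = _draw_substrate_classes(rng, probs, n_ecs, *substrates_per_reaction)
    counts = Counter(labels)
    return pd.Series([counts.get(lbl, 0) for lbl in CLASS_LABELS], index=CLASS_LABELS)


def _validate(cfg: FixtureConfig) -> None:
    if not 0 < cfg.fraction_upregulated <= 0.5:
        raise FixtureError("fraction_upregulated must be in (0, 0.5] so the three "
                           "cultures can have disjoint up-regulated sets")
    n_up = int(round(cfg.fraction_upregulated * cfg.n_genes_per_strain))
    if cfg.n_ecs_pure > n_up:
        raise FixtureError("n_ecs_pure exceeds the up-regulated genes per pure culture")
    if cfg.n_ecs_coculture > 2 * n_up:
        raise FixtureError("n_ecs_coculture exceeds the co-culture up-regulated set")
    for culture, r in cfg.removal.items():
        if not 0 <= r < 1:
            raise FixtureError(f"removal[{culture}] = {r} outside [0, 1)")
    overlap = set(cfg.removed_species) & set(cfg.produced_species)
    if overlap:
        raise FixtureError(f"species {sorted(overlap)} cannot be both removed and produced")
    before_species = {s for pool in _BASE_SPECIES.values() for s in pool} | {"O2"}
    before_species |= {_canonical_species(s) for s in cfg.removed_species}
    clash = {_canonical_species(s) for s in cfg.produced_species} & before_species
    if clash:
        raise FixtureError(f"produced species {sorted(clash)} already occur before treatment")
    if "O2" in cfg.removed_species:
        raise FixtureError("classic NAs (O2) are partially removed via `removal`, "
                           "not planted as a completely removed species")
    for lbl in (*cfg.removed_species, *cfg.produced_species):
        _species_counts(lbl)
    for probs in (cfg.class_probs_pure, cfg.class_probs_coculture):
        vec = np.array([probs.get(lbl, 0.0) for lbl in CLASS_LABELS])
        if (vec < 0).any() or vec.sum() <= 0:
            raise FixtureError("class probabilities must be non-negative and sum > 0")
    if not 0 <= cfg.concentration_noise < 1:
        raise FixtureError("concentration_noise must be in [0, 1)")
    if cfg.classic_na_count > 21 * 10:
        raise FixtureError("cannot plant more unique classic NAs than carbon×DBE cells")


# ---------------------------------------------------------------- pieces

def _make_genes(cfg: FixtureConfig) -> pd.DataFrame:
    rng = _rng(cfg.seed, "genes")
    rows = []
    lo, hi = cfg.gene_length_range
    for strain in STRAINS:
        lengths = rng.integers(lo, hi + 1, size=cfg.n_genes_per_strain)
        for i, length in enumerate(lengths):
            rows.append((f"{strain}_g{i:04d}", strain, int(length)))
    return pd.DataFrame(rows, columns=["gene_id", "strain", "length"])


def _make_upregulated(cfg: FixtureConfig, genes: pd.DataFrame) -> dict[str, list]:
    rng = _rng(cfg.seed, "upregulated")
    n_up = int(round(cfg.fraction_upregulated * cfg.n_genes_per_strain))
    up: dict[str, list] = {}
    leftovers = {}
    for strain in STRAINS:
        ids = genes.loc[genes["strain"] == strain, "gene_id"].to_numpy()
        chosen = rng.choice(ids, size=n_up, replace=False)
        up[strain] = sorted(chosen)
        leftovers[strain] = np.array(sorted(set(ids) - set(chosen)))
    co = []
    for strain in STRAINS:
        co.extend(rng.choice(leftovers[strain], size=n_up, replace=False))
    up["coculture"] = sorted(co)
    return up


def _make_counts_coverage(cfg: FixtureConfig, genes: pd.DataFrame,
                          up: dict[str, list]) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng_c = _rng(cfg.seed, "counts")
    rng_v = _rng(cfg.seed, "coverage")
    lengths = genes.set_index("gene_id")["length"]
    lib_genes = {
        "putida": genes.loc[genes["strain"] == "putida", "gene_id"],
        "protegens": genes.loc[genes["strain"] == "protegens", "gene_id"],
        "coculture": genes["gene_id"],
    }
    count_rows, cov_rows = [], []
    for library in CULTURES:
        up_set = set(up[library])
        for gene in lib_genes[library]:
            if gene in up_set:
                count = int(rng_c.integers(200, 2001))
                covered = int(round(lengths[gene] * rng_v.uniform(0.92, 1.0)))
            else:
                count = int(rng_c.integers(0, 6))
                covered = int(rng_v.integers(0, 120))
            count_rows.append((gene, library, count))
            cov_rows.append((gene, library, covered))
    counts = pd.DataFrame(count_rows, columns=["gene_id", "library", "count"])
    coverage = pd.DataFrame(cov_rows, columns=["gene_id", "library", "covered_bases"])
    return counts, coverage


def _make_ecs(cfg: FixtureConfig, up: dict[str, list]):
    rng = _rng(cfg.seed, "ecs")
    total = 2 * cfg.n_ecs_pure + cfg.n_ecs_coculture
    # top-level class mix loosely follows a hydrolase-heavy enzyme census
    top_weights = np.array([0.12, 0.18, 0.35, 0.08, 0.07, 0.10, 0.10])
    pool: list[str] = []
    seen = set()
    while len(pool) < total:
        a = int(rng.choice(7, p=top_weights)) + 1
        ec = f"{a}.{rng.integers(1, 31)}.{rng.integers(1, 31)}.{rng.integers(1, 100)}"
        if ec not in seen:
            seen.add(ec)
            pool.append(ec)
    slices = {
        "putida": pool[:cfg.n_ecs_pure],
        "protegens": pool[cfg.n_ecs_pure:2 * cfg.n_ecs_pure],
        "coculture": pool[2 * cfg.n_ecs_pure:],
    }
    gene_to_ec: dict[str, str] = {}
    for culture in CULTURES:
        ecs = slices[culture]
        members = list(up[culture])
        rng.shuffle(members)
        for gene, ec in zip(members[:len(ecs)], ecs):
            gene_to_ec[gene] = ec
        for gene in members[len(ecs):]:
            if rng.random() < 0.5:
                gene_to_ec[gene] = str(rng.choice(ecs))
    return slices, gene_to_ec


def _split_sources(rng, keys, agreement, names):
    """Assign each (gene, term) record to both sources or one of them."""
    rows = []
    for gene, term in keys:
        u = rng.random()
        if u < agreement:
            rows.append((gene, names[0], term))
            rows.append((gene, names[1], term))
        elif u < agreement + (1 - agreement) / 2:
            rows.append((gene, names[0], term))
        else:
            rows.append((gene, names[1], term))
    return rows


def _make_annotations(cfg: FixtureConfig, genes: pd.DataFrame, up: dict[str, list],
                      gene_to_ec: dict[str, str]):
    rng = _rng(cfg.seed, "ec_annotations")
    ec_rows = _split_sources(rng, sorted(gene_to_ec.items()), cfg.annotation_agreement,
                             ("blast2go", "uniprot-prokka"))
    ec_ann = pd.DataFrame(ec_rows, columns=["gene_id", "source", "term"])

    rng_go = _rng(cfg.seed, "go")
    all_genes = genes["gene_id"].to_numpy()
    terms = [f"GO:{i:07d}" for i in range(1, cfg.n_terms + 1)]
    universe_rows = []
    enriched = {}
    for idx, term in enumerate(terms):
        if cfg.plant_enriched_terms and idx < len(CULTURES):
            culture = CULTURES[idx]
            hit = rng_go.choice(np.array(up[culture]), size=12, replace=False)
            background = rng_go.choice(all_genes, size=3, replace=False)
            members = sorted(set(hit) | set(background))
            enriched[culture] = term
        else:
            size = int(rng_go.integers(8, 61))
            members = sorted(rng_go.choice(all_genes, size=size, replace=False))
        for g in members:
            universe_rows.append((term, g))
    universe = pd.DataFrame(universe_rows, columns=["term", "gene_id"])

    up_all = set().union(*(set(v) for v in up.values()))
    go_keys = sorted((g, t) for t, g in universe_rows if g in up_all)
    go_rows = _split_sources(rng_go, go_keys, cfg.annotation_agreement,
                             ("blast2go", "interproscan"))
    go_ann = pd.DataFrame(go_rows, columns=["gene_id", "source", "term"])
    return ec_ann, go_ann, universe, enriched


def _make_substrates(cfg: FixtureConfig, culture_ecs: dict[str, list]):
    rng = _rng(cfg.seed, "substrates")
    lo, hi = cfg.substrates_per_reaction
    rxn_rows, cmp_rows = [], []
    substrate_classes: dict[str, dict[str, str]] = {}
    pairs: dict[str, list] = {}
    cid_idx, rxn_idx = 0, 0
    for culture in CULTURES:
        probs_map = (cfg.class_probs_coculture if culture == "coculture"
                     else cfg.class_probs_pure)
        probs = np.array([probs_map.get(lbl, 0.0) for lbl in CLASS_LABELS], dtype=float)
        probs = probs / probs.sum()
        ecs = culture_ecs[culture]
        sizes, labels = _draw_substrate_classes(rng, probs, len(ecs), lo, hi)
        offset = 0
        substrate_classes[culture] = {}
        pairs[culture] = []
        for ec, size in zip(ecs, sizes):
            rxn_idx += 1
            rxn_id = f"RXN-{rxn_idx:04d}"
            for lbl in labels[offset:offset + size]:
                cid_idx += 1
                cid = f"CID{cid_idx:06d}"
                n, o, s = _species_counts(_class_to_species(rng, lbl))
                ec_counts = _formula_for(rng, n, o, s)
                rxn_rows.append((rxn_id, ec, cid))
                cmp_rows.append((cid, f"compound-{cid_idx:06d}", ec_counts.formula))
                substrate_classes[culture][cid] = lbl
                pairs[culture].append((cid, ec))
            offset += size
    reactions = pd.DataFrame(rxn_rows, columns=["rxn_id", "ec", "cid"])
    compounds = pd.DataFrame(cmp_rows, columns=["cid", "cmpdname", "mf"])
    return reactions, compounds, substrate_classes, pairs


def _class_to_species(rng: np.random.Generator, label: str) -> str:
    """A concrete species label belonging to the given heteroatom class."""
    choices = {
        "CH": ["CH"], "N": ["N", "N2"], "NS": ["NS", "N2S"],
        "NO": ["NO", "N2O", "NO2"], "O": ["O", "O2", "O3", "O4"],
        "NOS": ["NOS", "N2OS"], "S": ["S", "S2"], "SO": ["SO", "SO2", "SO3"],
    }[label]
    return str(rng.choice(choices))


def _make_pathways(cfg: FixtureConfig, pairs: dict[str, list],
                   substrate_classes: dict[str, dict[str, str]],
                   compounds: pd.DataFrame, culture_ecs: dict[str, list]):
    rng = _rng(cfg.seed, "pathways")

    def pairs_of_class(culture, wanted):
        return [(c, e) for c, e in pairs[culture]
                if substrate_classes[culture][c] in wanted]

    def pick(pool, k):
        if len(pool) < k:
            raise FixtureError("not enough substrate pairs of the requested class "
                               "to plant culture-specific pathways")
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx)]

    planted = {}
    pathways = []

    steps = [p for cu in CULTURES for p in pick(pairs_of_class(cu, {"N", "NO"}), 1)]
    pathways.append({"pathway_id": "PWY-0001", "name": "heme b biosynthesis",
                     "steps": [{"cid": c, "ec": e} for c, e in steps]})
    planted["all_cultures"] = {"pathway_id": "PWY-0001", "group": "N+NO"}

    steps = pick(pairs_of_class("coculture", {"O"}), 3)
    pathways.append({"pathway_id": "PWY-0002", "name": "phenylacetate degradation",
                     "steps": [{"cid": c, "ec": e} for c, e in steps]})
    planted["coculture_only"] = {"pathway_id": "PWY-0002", "group": "O"}

    steps = (pick(pairs_of_class("putida", {"O"}), 1)
             + pick(pairs_of_class("protegens", {"O"}), 1))
    pathways.append({"pathway_id": "PWY-0003", "name": "methylsalicylate degradation",
                     "steps": [{"cid": c, "ec": e} for c, e in steps]})
    planted["pure_only"] = {"pathway_id": "PWY-0003", "group": "O"}

    all_pairs = [p for cu in CULTURES for p in pairs[cu]]
    real_pair_set = set(all_pairs)
    all_cids = compounds["cid"].tolist()
    all_ecs = [e for cu in CULTURES for e in culture_ecs[cu]]
    for i in range(4, cfg.n_pathways + 1):
        n_steps = int(rng.integers(2, 7))
        steps = []
        for _ in range(n_steps):
            if rng.random() < 0.6:
                steps.append(all_pairs[int(rng.integers(len(all_pairs)))])
            else:  # decoy step never reached by any culture
                while True:
                    cand = (all_cids[int(rng.integers(len(all_cids)))],
                            all_ecs[int(rng.integers(len(all_ecs)))])
                    if cand not in real_pair_set:
                        steps.append(cand)
                        break
        pathways.append({"pathway_id": f"PWY-{i:04d}", "name": f"synthetic pathway {i}",
                         "steps": [{"cid": c, "ec": e} for c, e in
                                   sorted(set(steps))]})
    return pathways, planted


def _make_gene_maps(cfg: FixtureConfig, genes: pd.DataFrame, up: dict[str, list]):
    rng = _rng(cfg.seed, "gene_maps")
    maps = [f"map{i:05d}" for i in range(1, cfg.n_gene_maps + 1)]
    names = {m: f"metabolic map {i}" for i, m in enumerate(maps, start=1)}
    names[maps[0]] = "fatty acid degradation"
    rows = []
    co_up = list(up["coculture"])
    half = len(co_up) // 2
    planted_members = (sorted(rng.choice(co_up[:half], size=5, replace=False))
                       + sorted(rng.choice(co_up[half:], size=5, replace=False)))
    for g in planted_members:
        rows.append((g, maps[0], names[maps[0]]))
    other_genes = sorted(set(genes["gene_id"]) - set(co_up))
    for m in maps[1:]:
        members = rng.choice(np.array(other_genes),
                             size=int(rng.integers(5, 15)), replace=False)
        for g in sorted(members):
            rows.append((g, m, names[m]))
        # a few consortium-enriched genes per map, always fewer than planted
        extra = rng.choice(np.array(sorted(set(co_up) - set(planted_members))),
                           size=int(rng.integers(0, 6)), replace=False)
        for g in sorted(extra):
            rows.append((g, m, names[m]))
    gene_pathways = pd.DataFrame(rows, columns=["gene_id", "pathway_id", "pathway_name"])
    return gene_pathways, maps[0]


def _make_ms(cfg: FixtureConfig):
    rng = _rng(cfg.seed, "ms")
    rows = []  # (mf, sample_id, concentration)

    # classic NAs: unique (carbon, DBE) cells weighted toward C16 and DBE 4
    carbons = np.arange(5, 26)
    dbes = np.arange(1, 11)
    cw = 1.0 / (1.0 + 0.35 * np.abs(carbons - 16))
    dw = 1.0 / (1.0 + 0.55 * np.abs(dbes - 4))
    cells = [(c, d) for c in carbons for d in dbes if d <= c]
    weights = np.array([cw[c - 5] * dw[d - 1] for c, d in cells])
    weights /= weights.sum()
    chosen = rng.choice(len(cells), size=cfg.classic_na_count, replace=False, p=weights)
    classic = []
    for i in sorted(chosen):
        c, d = cells[i]
        ec = _formula_for(rng, 0, 2, 0, carbon=c, dbe_val=d)
        classic.append(ec.formula)
    conc = rng.gamma(2.0, 1.0, size=len(classic))
    conc = conc / conc.sum() * cfg.classic_na_total
    before_classic = dict(zip(classic, conc))

    # non-classic species in the untreated water, incl. species planted for
    # complete removal; produced species are withheld until after treatment
    before_other: dict[str, tuple[str, float]] = {}
    species_before = []
    for cls in CLASS_LABELS:
        species_before.extend(_BASE_SPECIES[cls])
    species_before.extend(cfg.removed_species)
    for sp in species_before:
        n, o, s = _species_counts(sp)
        m = int(rng.integers(3, 8))
        cds = set()
        while len(cds) < m:
            c = int(rng.integers(5, 26))
            d = int(rng.integers(1, min(10, c) + 1))
            cds.add((c, d))
        for c, d in sorted(cds):
            ec = _formula_for(rng, n, o, s, carbon=c, dbe_val=d)
            before_other[ec.formula] = (sp, float(rng.lognormal(-1.5, 0.6)))

    for mf, v in before_classic.items():
        rows.append((mf, "OSPW", float(v)))
    for mf, (sp, v) in before_other.items():
        rows.append((mf, "OSPW", v))

    removed = set(cfg.removed_species)
    for culture in CULTURES:
        r = cfg.removal.get(culture, 0.0)
        factors = np.clip(rng.normal(1.0, cfg.concentration_noise, size=len(classic)),
                          0.2, 1.8)
        after = np.array([before_classic[mf] for mf in classic]) * factors
        after = after / after.sum() * (1 - r) * cfg.classic_na_total
        for mf, v in zip(classic, after):
            rows.append((mf, culture, float(v)))
        for mf, (sp, v) in before_other.items():
            if sp in removed:
                continue
            f = max(0.05, float(rng.normal(1.0, cfg.concentration_noise)))
            rows.append((mf, culture, v * f))
        for sp in cfg.produced_species:
            n, o, s = _species_counts(sp)
            for _ in range(int(rng.integers(2, 5))):
                ec = _formula_for(rng, n, o, s)
                rows.append((ec.formula, culture, float(rng.uniform(0.05, 0.5))))

    ms = (pd.DataFrame(rows, columns=["mf", "sample_id", "concentration"])
          .groupby(["mf", "sample_id"], as_index=False)["concentration"].sum()
          .sort_values(["sample_id", "mf"]).reset_index(drop=True))
    ms_manifest = {
        "percent_removal_classic": {cu: 100.0 * cfg.removal.get(cu, 0.0) for cu in CULTURES},
        "removed_species": sorted(_canonical_species(s) for s in cfg.removed_species),
        "produced_species": sorted(_canonical_species(s) for s in cfg.produced_species),
        "classic_na_count": int(cfg.classic_na_count),
        "classic_na_total": float(cfg.classic_na_total),
    }
    return ms, ms_manifest


# ---------------------------------------------------------------- driver

def generate_fixture(cfg: FixtureConfig) -> FixtureBundle:
    """Build the full fixture in memory; same config ⇒ identical bundle."""
    _validate(cfg)
    genes = _make_genes(cfg)
    up = _make_upregulated(cfg, genes)
    counts, coverage = _make_counts_coverage(cfg, genes, up)
    culture_ecs, gene_to_ec = _make_ecs(cfg, up)
    ec_ann, go_ann, universe, enriched = _make_annotations(cfg, genes, up, gene_to_ec)
    reactions, compounds, substrate_classes, pairs = _make_substrates(cfg, culture_ecs)
    pathways, planted_pw = _make_pathways(cfg, pairs, substrate_classes,
                                          compounds, culture_ecs)
    gene_pathways, top_map = _make_gene_maps(cfg, genes, up)
    ms, ms_manifest = _make_ms(cfg)

    ec_class_hist = {}
    for culture in CULTURES:
        counts_by_class = dict.fromkeys(range(1, 8), 0)
        for gene in up[culture]:
            ec = gene_to_ec.get(gene)
            if ec is not None:
                counts_by_class[int(ec.split(".", 1)[0])] += 1
        ec_class_hist[culture] = {str(k): v for k, v in counts_by_class.items()}

    class_counts = {
        cu: dict(Counter(substrate_classes[cu].values())) for cu in CULTURES
    }
    manifest = {
        "seed": cfg.seed,
        "upregulated": {cu: list(up[cu]) for cu in CULTURES},
        "gene_to_ec": gene_to_ec,
        "culture_ecs": culture_ecs,
        "ec_class_table": ec_class_hist,
        "substrate_classes": substrate_classes,
        "class_counts": {cu: {lbl: class_counts[cu].get(lbl, 0) for lbl in CLASS_LABELS}
                         for cu in CULTURES},
        "enriched_terms": enriched,
        "planted_pathways": planted_pw,
        "top_pathway_up": top_map,
        "ms": ms_manifest,
    }
    return FixtureBundle(config=cfg, genes=genes, counts=counts, coverage=coverage,
                         ec_annotations=ec_ann, go_annotations=go_ann,
                         term_universe=universe, gene_pathways=gene_pathways,
                         reactions=reactions, compounds=compounds, pathways=pathways,
                         ms_features=ms, manifest=manifest)


def null_config(cfg: FixtureConfig) -> FixtureConfig:
    """The no-effect version of a config: identical generating process for
    all cultures, no removal, no removed/produced species, no planted terms."""
    return dataclasses.replace(
        cfg,
        class_probs_coculture=dict(cfg.class_probs_pure),
        removal={cu: 0.0 for cu in CULTURES},
        removed_species=(),
        produced_species=(),
        plant_enriched_terms=False,
    )


def null_fixture(cfg: FixtureConfig) -> FixtureBundle:
    return generate_fixture(null_config(cfg))


_FILES = {
    "genes": ("genes.tsv", "\t"),
    "counts": ("counts.tsv", "\t"),
    "coverage": ("coverage.tsv", "\t"),
    "ec_annotations": ("annotations_ec.tsv", "\t"),
    "go_annotations": ("annotations_go.tsv", "\t"),
    "term_universe": ("term_universe.tsv", "\t"),
    "gene_pathways": ("gene_pathways.tsv", "\t"),
    "reactions": ("reactions.tsv", "\t"),
    "compounds": ("compounds.csv", ","),
    "ms_features": ("ms_features.csv", ","),
}


def write_fixture(bundle: FixtureBundle, out_dir) -> dict[str, Path]:
    """Write every table, the pathway JSON and manifest.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for attr, (fname, sep) in _FILES.items():
        path = out / fname
        getattr(bundle, attr).to_csv(path, sep=sep, index=False)
        written[attr] = path
    path = out / "pathways.json"
    path.write_text(json.dumps(bundle.pathways, indent=1, sort_keys=True))
    written["pathways"] = path
    path = out / "manifest.json"
    path.write_text(json.dumps(bundle.manifest, indent=1, sort_keys=True))
    written["manifest"] = path
    return written


def load_fixture(directory) -> FixtureBundle:
    """Read a written fixture back through the module readers."""
    from . import annotation, expression, ms_profile, substrate_pathway

    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    return FixtureBundle(
        config=None,
        genes=expression.read_gene_catalog(d / "genes.tsv"),
        counts=expression.read_counts(d / "counts.tsv"),
        coverage=expression.read_coverage(d / "coverage.tsv"),
        ec_annotations=annotation.read_annotations(d / "annotations_ec.tsv"),
        go_annotations=annotation.read_annotations(d / "annotations_go.tsv"),
        term_universe=pd.read_csv(d / "term_universe.tsv", sep="\t", dtype=str),
        gene_pathways=pd.read_csv(d / "gene_pathways.tsv", sep="\t", dtype=str),
        reactions=substrate_pathway.load_reaction_db(d / "reactions.tsv"),
        compounds=substrate_pathway.load_compound_db(d / "compounds.csv"),
        pathways=substrate_pathway.load_pathway_db(d / "pathways.json"),
        ms_features=ms_profile.read_ms_table(d / "ms_features.csv"),
        manifest=manifest,
    )


def fixture_digest(bundle: FixtureBundle) -> str:
    """SHA-256 over every emitted file's bytes; equal seeds give equal digests."""
    import io

    h = hashlib.sha256()
    for attr, (fname, sep) in sorted(_FILES.items()):
        buf = io.StringIO()
        getattr(bundle, attr).to_csv(buf, sep=sep, index=False)
        h.update(fname.encode())
        h.update(buf.getvalue().encode())
    h.update(json.dumps(bundle.pathways, sort_keys=True).encode())
    h.update(json.dumps(bundle.manifest, sort_keys=True).encode())
    return h.hexdigest()
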