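"""End-to-end orchestration: fixture (or real tables) in, linked results out.

Runs the full analysis in the order the study design implies: coverage filter
→ TPM → up-regulated sets → EC consolidation and enzyme-class census → GO
over-representation → EC→substrate→class distributions and their chi-square
comparison → CID–EC pathway interrogation and presence matrices → MA
statistics and fold-change pathway ranking → MS degradation profiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import annotation, expression, ms_profile, substrate_pathway
from .synthetic import CULTURES, STRAINS, FixtureBundle

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    upregulated: dict            # culture -> sorted list of retained genes
    tpm: pd.DataFrame            # gene_id, library, strain, tpm
    ma: pd.DataFrame             # gene_id, strain, M, A
    culture_ecs: dict            # culture -> set of consolidated complete ECs
    ec_table: pd.DataFrame       # enzyme-class × culture counts
    enrichment: dict             # culture -> over-representation table
    substrates: dict             # culture -> substrate table (cid, ec, class...)
    distributions: dict          # culture -> class-count Series
    chisq: dict                  # "<pure> vs coculture" -> ChiSquareResult
    hits: pd.DataFrame           # with_pathway rows across cultures, with class
    without_pathway: dict        # culture -> unmatched pair table
    presence: pd.DataFrame       # culture, group, pathway_id, present
    pathway_ranking: dict        # direction -> ranked pathway table
    ms: dict                     # removal / removed / produced / classic summary


def run_pipeline(bundle: FixtureBundle, pseudocount: float = 0.5,
                 alpha: float = 0.05) -> PipelineResult:
    genes = bundle.genes

    # SSH tester libraries: genes passing the coverage filter are the
    # up-regulated set of that culture.
    cov = expression.apply_coverage_filter(bundle.coverage, genes)
    upregulated = {
        lib: sorted(cov.loc[(cov["library"] == lib) & cov["retained"], "gene_id"])
        for lib in CULTURES
    }

    tpm_frames = []
    for lib in CULTURES:
        lib_counts = bundle.counts[bundle.counts["library"] == lib]
        tpm_frames.append(expression.tpm(lib_counts, genes,
                                         retained=set(upregulated[lib])))
    tpm_all = pd.concat(tpm_frames, ignore_index=True)

    # MA per strain: consortium library vs that strain's pure library
    ma_rows = []
    for strain in STRAINS:
        t_c = tpm_all[(tpm_all["library"] == "coculture") & (tpm_all["strain"] == strain)]
        t_i = tpm_all[tpm_all["library"] == strain]
        joined = pd.merge(t_c[["gene_id", "tpm"]], t_i[["gene_id", "tpm"]],
                          on="gene_id", how="outer", suffixes=("_co", "_pure")).fillna(0.0)
        m, a = expression.ma_stats(joined["tpm_co"], joined["tpm_pure"], pseudocount)
        ma_rows.append(pd.DataFrame({"gene_id": joined["gene_id"], "strain": strain,
                                     "M": m, "A": a}))
    ma = pd.concat(ma_rows, ignore_index=True)

    # EC consolidation per culture from the two annotation sources
    ec_ann = bundle.ec_annotations
    culture_gene_ecs: dict[str, dict[str, set]] = {}
    culture_ecs: dict[str, set] = {}
    for lib in CULTURES:
        sub = ec_ann[ec_ann["gene_id"].isin(upregulated[lib])]
        a_map = {g: set(t) for g, t in
                 sub[sub["source"] == "blast2go"].groupby("gene_id")["term"]}
        b_map = {g: set(t) for g, t in
                 sub[sub["source"] == "uniprot-prokka"].groupby("gene_id")["term"]}
        consolidated = annotation.consolidate_ec(a_map, b_map,
                                                 names=("blast2go", "uniprot-prokka"))
        gene_ecs = ({g: set(e) for g, e in consolidated.groupby("gene_id")["ec"]}
                    if len(consolidated) else {})
        culture_gene_ecs[lib] = gene_ecs
        complete = {e for ecs in gene_ecs.values() for e in ecs
                    if not annotation.is_partial_ec(e)}
        culture_ecs[lib] = complete
    ec_table = annotation.enzyme_class_table(culture_gene_ecs)

    # GO over-representation per culture against the genome universe
    term_to_genes = {t: set(g) for t, g in
                     bundle.term_universe.groupby("term")["gene_id"]}
    strain_genes = {s: set(genes.loc[genes["strain"] == s, "gene_id"]) for s in STRAINS}
    enrichment = {}
    for lib in CULTURES:
        universe = set(genes["gene_id"]) if lib == "coculture" else strain_genes[lib]
        terms_here = {t: g & universe for t, g in term_to_genes.items() if g & universe}
        enrichment[lib] = annotation.overrepresentation(
            terms_here, set(upregulated[lib]) & universe, universe=universe, alpha=alpha)

    # EC -> substrates -> heteroatom class distributions, compared by chi-square
    substrates, distributions = {}, {}
    without_pathway, hit_frames = {}, []
    for lib in CULTURES:
        table, _unmatched = substrate_pathway.substrates_for_ecs(
            culture_ecs[lib], bundle.reactions, bundle.compounds)
        substrates[lib] = table
        distributions[lib] = substrate_pathway.class_distribution(table)
        pairs = set(zip(table["cid"], table["ec"]))
        with_pw, without = substrate_pathway.match_cid_ec_to_pathways(
            pairs, bundle.pathways)
        without_pathway[lib] = without
        with_pw = with_pw.merge(table[["cid", "ec", "nafc_class"]].drop_duplicates(),
                                on=["cid", "ec"], how="left")
        with_pw["culture"] = lib
        hit_frames.append(with_pw)
    hits = pd.concat(hit_frames, ignore_index=True)
    presence = substrate_pathway.presence_matrix(hits)
    chisq = {
        f"{pure} vs coculture": substrate_pathway.compare_distributions(
            distributions[pure], distributions["coculture"])
        for pure in STRAINS
    }

    m_per_gene = ma.set_index("gene_id")["M"]
    pathway_ranking = {
        direction: expression.rank_pathways_by_fc(m_per_gene, bundle.gene_pathways,
                                                  direction=direction)
        for direction in ("up", "down")
    }

    ms = bundle.ms_features
    before = ms[ms["sample_id"] == "OSPW"]
    ms_results = {"abundance": {}, "percent_removal_classic": {},
                  "percent_removal_all": {}, "removed": {}, "produced": {}}
    ms_results["classic_summary"] = ms_profile.classic_na_summary(before, "OSPW")
    ms_results["abundance"]["OSPW"] = ms_profile.class_abundance(before, "OSPW")
    for lib in CULTURES:
        after = ms[ms["sample_id"] == lib]
        if after.empty:
            continue
        ms_results["abundance"][lib] = ms_profile.class_abundance(after, lib)
        ms_results["percent_removal_classic"][lib] = ms_profile.percent_removal(
            before, after, restrict_to_classic=True)
        ms_results["percent_removal_all"][lib] = ms_profile.percent_removal(before, after)
        removed, produced = ms_profile.removed_and_produced_classes(before, after)
        ms_results["removed"][lib] = removed
        ms_results["produced"][lib] = produced

    return PipelineResult(upregulated=upregulated, tpm=tpm_all, ma=ma,
                          culture_ecs=culture_ecs, ec_table=ec_table,
                          enrichment=enrichment, substrates=substrates,
                          distributions=distributions, chisq=chisq, hits=hits,
                          without_pathway=without_pathway, presence=presence,
                          pathway_ranking=pathway_ranking, ms=ms_results)
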