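"""End-to-end orchestration: clustering -> donor inference -> network ->
randomization -> barriers -> selection.

Every stage writes a plain-text artifact under the output directory and can be
resumed from it; the manifest records configuration, seeds and the filter
funnel (how many genes survive each inference step). All outputs are
deterministic given the input dataset and the seed: dictionaries are emitted
with sorted keys and rows in sorted order, so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import barriers, clustering, donors, io, network, randomize, selection
from .datatypes import Dataset, TransductionEvent
from .seqsim import SimilarityProfile, codon_usage_distance, gc_similarity, jaccard_from_sets


@dataclass
class PipelineConfig:
    outdir: str
    rbh_identity_threshold: float = 95.0
    homolog_identity_threshold: float = 90.0
    orthology_threshold: float = 0.7
    kmer_k: int = 20
    n_replicates: int = 1000
    swaps_per_edge: float = 100.0
    alpha: float = 0.05
    fdr: float = 0.05
    n_boot: int = 10000
    seed: int = 0
    resume: bool = True

    def __post_init__(self):
        for name, v, lo, hi in (
            ("rbh_identity_threshold", self.rbh_identity_threshold, 0, 100),
            ("homolog_identity_threshold", self.homolog_identity_threshold, 0, 100),
            ("orthology_threshold", self.orthology_threshold, 0, 1),
            ("alpha", self.alpha, 0, 1),
            ("fdr", self.fdr, 0, 1),
        ):
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.n_replicates < 1 or self.n_boot < 1 or self.kmer_k < 1:
            raise ValueError("counts must be positive")


def _dump_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join("" if v is None else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _read_tsv(path: Path) -> list[dict[str, str]]:
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:] if line]


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_clustering(dataset: Dataset, config: PipelineConfig, outdir: Path) -> dict[str, str]:
    """Protein families over prophage genes, then orthologous phage entities.

    Returns the prophage id -> phage entity id map. Resumable from
    ``phage_entities.tsv``.
    """
    ent_path = outdir / "phage_entities.tsv"
    if config.resume and ent_path.exists():
        mapping = {}
        for row in _read_tsv(ent_path):
            for pro in row["member_prophages"].split(","):
                mapping[pro] = row["phage_id"]
        return mapping

    proteins: dict[str, tuple[str, str]] = {}
    for genome in dataset.genomes.values():
        for pro in genome.prophages:
            for gid in pro.gene_ids:
                g = genome.genes[gid]
                proteins[gid] = (genome.genome_id, g.protein)
    families = clustering.build_protein_families(
        proteins, identity_threshold=config.rbh_identity_threshold
    )
    family_of_gene = {g: f.family_id for f in families for g in f.gene_ids}

    prophage_families: dict[str, set[str]] = {}
    has_bacterial: dict[str, bool] = {}
    for genome in dataset.genomes.values():
        for pro in genome.prophages:
            prophage_families[pro.prophage_id] = {
                family_of_gene[g] for g in pro.gene_ids if g in family_of_gene
            }
            has_bacterial[pro.prophage_id] = any(
                genome.genes[g].gene_class == "bacterial" for g in pro.gene_ids
            )
    entities = clustering.cluster_orthologous_prophages(
        prophage_families, has_bacterial, threshold=config.orthology_threshold
    )
    _write_tsv(outdir / "protein_families.tsv",
               ["family_id", "gene_ids", "genome_ids"],
               [(f.family_id, ",".join(f.gene_ids), ",".join(f.genome_ids))
                for f in families])
    _write_tsv(ent_path, ["phage_id", "member_prophages", "is_singleton"],
               [(e.phage_id, ",".join(e.member_prophages), e.is_singleton)
                for e in entities])
    return {pro: e.phage_id for e in entities for pro in e.member_prophages}


def stage_donors(dataset: Dataset, config: PipelineConfig, outdir: Path) -> list[donors.DonorCall]:
    calls_path = outdir / "donor_calls.tsv"
    if config.resume and calls_path.exists():
        calls = []
        for row in _read_tsv(calls_path):
            calls.append(donors.DonorCall(
                gene_id=row["gene_id"], recipient=row["recipient"],
                donor=row["donor"] or None,
                exclusion_reason=row["exclusion_reason"],
                p_consolidation=float(row["p_consolidation"]) if row["p_consolidation"] else None,
                family_size=int(row["family_size"]),
                poisson_ok=row["poisson_ok"] == "True",
                donor_gene_id=row["donor_gene_id"] or None,
            ))
        return calls
    calls = donors.infer_donors(
        dataset,
        similarity_threshold=config.homolog_identity_threshold,
        alpha=config.alpha, n_boot=config.n_boot, seed=config.seed,
    )
    _write_tsv(calls_path,
               ["gene_id", "recipient", "donor", "exclusion_reason",
                "p_consolidation", "family_size", "poisson_ok", "donor_gene_id"],
               [(c.gene_id, c.recipient, c.donor, c.exclusion_reason,
                 c.p_consolidation, c.family_size, c.poisson_ok, c.donor_gene_id)
                for c in calls])
    return calls


def events_from_calls(
    dataset: Dataset, calls: list[donors.DonorCall], phage_of_prophage: dict[str, str]
) -> list[TransductionEvent]:
    """Transduction events for every query whose prophage maps to an entity;
    unresolved donors yield donor-less (R-edge only) events."""
    pro_of_gene = dataset.prophage_of_gene()
    events = []
    for call in calls:
        prophage = pro_of_gene.get(call.gene_id)
        if prophage is None or prophage not in phage_of_prophage:
            continue
        events.append(TransductionEvent(
            gene_id=call.gene_id,
            phage_entity=phage_of_prophage[prophage],
            recipient=call.recipient,
            donor=call.donor,
        ))
    return events


def stage_network(dataset: Dataset, events: list[TransductionEvent], outdir: Path) -> dict:
    net = network.build_dlgt(events)
    autologs = network.detect_autologs(events)
    taxonomy = {gid: g.taxonomy for gid, g in dataset.genomes.items()}
    report = {
        "autologs": {
            "n_events": autologs.n_events,
            "n_autologs": autologs.n_autologs,
            "autolog_fraction": autologs.autolog_fraction,
            "genomes_with_autologs": autologs.genomes_with_autologs,
            "max_genes_per_genome": autologs.max_genes_per_genome,
        },
    }
    for subset in ("full", "D", "R"):
        st = network.component_and_degree_stats(net, subset)
        report[f"stats_{subset}"] = {
            "n_bacteria": st.n_bacteria, "n_phages": st.n_phages,
            "n_edges": st.n_edges,
            "component_sizes": st.component_sizes,
            "largest_component": st.largest_component,
            "total_weight": network.total_weight(net, subset),
        }
    hr = network.host_range_taxonomy(net, events, taxonomy)
    report["host_range"] = {
        "donor_rank_counts": hr.donor_rank_counts,
        "recipient_rank_counts": hr.recipient_rank_counts,
        "donor_recipient_rank_counts": hr.donor_recipient_rank_counts,
    }
    _write_tsv(outdir / "edges.tsv", ["source", "target", "direction_class", "weight"],
               network.edge_table(net))
    _dump_json(outdir / "network.json", report)
    return {"net": net, "report": report}


def stage_randomization(net, config: PipelineConfig, outdir: Path) -> dict:
    stats = {
        "largest_component": lambda g: float(
            network.component_and_degree_stats(g, "full").largest_component),
        "n_donor_recipient_pairs": lambda g: float(len(network.donor_recipient_pairs(g))),
    }
    ens = randomize.build_ensemble(
        net, stats, n_replicates=config.n_replicates,
        swaps_per_edge=config.swaps_per_edge, seed=config.seed,
    )
    observed = {name: fn(net) for name, fn in stats.items()}
    report = {"n_replicates": ens.n_replicates, "seed": ens.seed, "statistics": {}}
    for name, values in ens.statistics.items():
        report["statistics"][name] = {
            "observed": observed[name],
            "null_mean": float(np.mean(values)),
            "null_sd": float(np.std(values)),
            "p_upper": randomize.empirical_pvalue(observed[name], values, "upper"),
            "p_lower": randomize.empirical_pvalue(observed[name], values, "lower"),
        }
    _dump_json(outdir / "randomization.json", report)
    return report


def pair_profile(dataset: Dataset, a: str, b: str, k: int = 20) -> SimilarityProfile:
    """The four genome-similarity measures plus habitat sharing for a pair.

    k-mer measures are computed on prophage-masked sequences: prophages are
    mobile cargo, and leaving them in lets the transferred genes themselves
    (and shared phage backbones) masquerade as host similarity.
    """
    ga, gb = dataset.genomes[a], dataset.genomes[b]
    s_gs = jaccard_from_sets(ga.host_kmer_codes, gb.host_kmer_codes)
    s_cds = jaccard_from_sets(ga.host_cds_kmer_codes, gb.host_cds_kmer_codes)
    return SimilarityProfile(
        s_gs=s_gs if s_gs is not None else 0.0,
        s_cds=s_cds,
        s_gc=gc_similarity(ga.gc, gb.gc),
        d_cu=codon_usage_distance(ga.usage_profile, gb.usage_profile),
        habitat_shared=ga.habitat is not None and ga.habitat == gb.habitat,
    )


def stage_barriers(
    dataset: Dataset, net, events: list[TransductionEvent],
    config: PipelineConfig, outdir: Path,
) -> dict:
    gids = sorted(dataset.genomes)
    connected = {tuple(sorted(p)) for p in network.donor_recipient_pairs(net)
                 if p[0] != p[1]}
    profiles: dict[tuple[str, str], SimilarityProfile] = {}
    pos, neg = [], []
    for i, a in enumerate(gids):
        for b in gids[i + 1:]:
            prof = pair_profile(dataset, a, b, k=config.kmer_k)
            profiles[(a, b)] = prof
            (pos if (a, b) in connected else neg).append(prof)
    report: dict = {}
    if pos and neg:
        roc = barriers.roc_analysis(pos, neg)
        report["roc"] = {
            name: {"auc": e.auc, "tpr": e.tpr, "fpr": e.fpr,
                   "threshold": e.threshold, "degenerate": e.degenerate}
            for name, e in roc.entries.items()
        }
    habitat = {gid: g.habitat for gid, g in dataset.genomes.items()
               if g.habitat is not None}
    hab = barriers.habitat_transfer_analysis(
        events, habitat, net,
        null_networks=randomize.iter_randomized(
            net, config.n_replicates, config.swaps_per_edge, seed=config.seed + 1),
    )
    report["habitat"] = {
        "same_habitat_fraction_paths": hab.same_habitat_fraction_paths,
        "same_habitat_fraction_events": hab.same_habitat_fraction_events,
        "p_same_habitat": hab.p_same_habitat,
        "n_pairs": hab.n_pairs,
        "n_events_with_habitat": hab.n_events_with_habitat,
        "n_dropped": hab.n_dropped,
        "observed": {h: dict(zip(hab.habitats, map(int, row)))
                     for h, row in zip(hab.habitats, hab.observed.values)},
    }

    all_genes = dataset.all_genes()
    event_labels, strata = [], {}
    for ev in events:
        cat = all_genes[ev.gene_id].functional_category
        if cat is None:
            continue
        event_labels.append(cat)
        h = habitat.get(ev.recipient)
        if h is not None:
            strata.setdefault(h, []).append(cat)
    background_labels = [
        g.functional_category for g in all_genes.values()
        if not g.in_prophage and g.functional_category is not None
    ]
    if event_labels and background_labels:
        comp = barriers.functional_composition_test(
            event_labels, background_labels, strata=strata, fdr=config.fdr)
        report["composition"] = {
            "p_overall": comp.p_overall,
            "chi2": None if comp.chi2 != comp.chi2 else comp.chi2,
            "exact_fallback": comp.exact_fallback,
            "table": {cls: {"transferred": int(row["transferred"]),
                            "background": int(row["background"])}
                      for cls, row in comp.table.iterrows()},
        }

    sims, cats = [], []
    for ev in events:
        if ev.donor is None or ev.donor == ev.recipient:
            continue
        cat = all_genes[ev.gene_id].functional_category
        if cat is None:
            continue
        key = tuple(sorted((ev.donor, ev.recipient)))
        sims.append(profiles[key].s_gs)
        cats.append(cat)
    if sims:
        cs = barriers.similarity_by_category(sims, cats, alpha=config.alpha)
        report["similarity_by_category"] = {
            "means": {k: float(v) for k, v in cs.means.items()},
            "anova_p": cs.anova_p,
        }
    _dump_json(outdir / "barriers.json", report)
    return report


def stage_selection(
    dataset: Dataset, calls: list[donors.DonorCall], config: PipelineConfig, outdir: Path
) -> dict:
    all_genes = dataset.all_genes()
    rows = []
    autolog_pairs, cai_pairs = [], []
    for call in sorted(calls, key=lambda c: c.gene_id):
        if call.excluded or call.donor_gene_id is None:
            continue
        transferred = all_genes[call.gene_id].nt
        donor_copy = all_genes[call.donor_gene_id].nt
        if len(transferred) != len(donor_copy):
            continue
        res = selection.pairwise_dnds(transferred, donor_copy)
        rows.append((call.gene_id, call.recipient, call.donor,
                     res.dn, res.ds, res.omega, res.saturated))
        if call.donor == call.recipient:
            autolog_pairs.append((transferred, donor_copy))
            usage = dataset.genomes[call.recipient].usage_profile
            cai_pairs.append((selection.cai(transferred, usage),
                              selection.cai(donor_copy, usage)))
    _write_tsv(outdir / "selection.tsv",
               ["gene_id", "recipient", "donor", "dn", "ds", "omega", "saturated"],
               rows)
    summary = selection.autolog_selection_summary(autolog_pairs, cai_pairs or None)
    report = {
        "n_events_scored": len(rows),
        "autologs": {
            "n_total": summary.n_total,
            "n_zero_substitution": summary.n_zero_substitution,
            "n_tested": summary.n_tested,
            "median_omega": summary.median_omega,
            "median_dn": summary.median_dn,
            "median_ds": summary.median_ds,
            "p_ds_gt_dn": summary.p_ds_gt_dn,
            "p_cai_prophage_lt_genomic": summary.p_cai_prophage_lt_genomic,
        },
    }
    _dump_json(outdir / "selection.json", report)
    return report


# --------------------------------------------------------------------------
# Driver
# --------------------------------------------------------------------------

def run_pipeline(dataset: Dataset, config: PipelineConfig) -> dict:
    """Run all stages in order; returns the manifest (also written to disk).

    The manifest records the filter funnel: queries -> homolog-found ->
    tree-built -> consolidation-tested -> donor-called, with per-reason
    exclusion counts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    validation = io.validate_inputs(dataset)
    if not validation.ok:
        _dump_json(outdir / "validation.json", {"findings": validation.findings})
        raise ValueError(f"input validation failed with {len(validation.findings)} findings")
    _dump_json(outdir / "validation.json", {"findings": []})

    phage_of_prophage = stage_clustering(dataset, config, outdir)
    calls = stage_donors(dataset, config, outdir)
    events = events_from_calls(dataset, calls, phage_of_prophage)
    net_out = stage_network(dataset, events, outdir)
    rand_report = stage_randomization(net_out["net"], config, outdir)
    barrier_report = stage_barriers(dataset, net_out["net"], events, config, outdir)
    sel_report = stage_selection(dataset, calls, config, outdir)

    by_reason: dict[str, int] = {}
    for call in calls:
        by_reason[call.exclusion_reason] = by_reason.get(call.exclusion_reason, 0) + 1
    funnel = {
        "queries": len(calls),
        "homolog_found": sum(1 for c in calls if c.exclusion_reason != "no_homolog"),
        "tree_built": sum(1 for c in calls if c.family_size >= 3),
        "consolidation_tested": sum(1 for c in calls if c.p_consolidation is not None),
        "donor_called": sum(1 for c in calls if not c.excluded),
        "excluded_by_reason": {k: v for k, v in sorted(by_reason.items()) if k != "none"},
        "events_in_network": len(events),
    }
    config_echo = asdict(config)
    config_echo.pop("outdir")  # environment-dependent path, not a result
    manifest = {
        "config": config_echo,
        "n_genomes": len(dataset.genomes),
        "funnel": funnel,
        "network": net_out["report"],
        "randomization": rand_report,
        "barriers_keys": sorted(barrier_report),
        "selection": sel_report,
        "artifacts": sorted(p.name for p in outdir.iterdir()
                            if p.is_file() and p.name != "manifest.json"),
    }
    _dump_json(outdir / "manifest.json", manifest)
    return manifest
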