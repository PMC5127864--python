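"""End-to-end orchestration and cross-cutting set operations.

Besides wiring the stages together (simulate/profile -> pan-genome ->
core-gene tree -> gain/loss -> hallmark report), this module implements
the set algebra on gene-content matrices:

* core families — present in every analyzed taxon;
* group hallmark families — present in every member of one group and
  absent from every non-member;
* anti-hallmark families — absent from every member of one group but
  present in all other taxa (the mirror pattern);
* an exhaustive classification of every family into exactly one of
  core / hallmark / anti-hallmark / other.

The hallmark definition is strict presence/absence by default (no
tolerated missing member); a ``tolerance`` parameter relaxes it for
exploration. No multiple-testing machinery applies: the procedure is
set-algebraic, not inferential.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .io_formats import write_content_matrix, write_newick
from .ortholog_profiling import (
    assign_families,
    build_content_matrix,
    filter_queries,
    tally_best_hit_sources,
)
from .pan_genome import (
    build_similarity_graph,
    content_distance,
    content_from_clusters,
    mcl_cluster,
)
from .phylo import (
    Alignment,
    bootstrap_support,
    concatenate_alignments,
    neighbor_joining,
    strip_gap_columns,
)
from .gain_loss import WagnerParams, summarize_events, wagner_reconstruct
from .synthetic_data import (
    SimulationConfig,
    emit_hit_table,
    emit_proteomes,
    emit_reference_hits,
    plant_clade_families,
    simulate_gene_content,
    simulate_tree,
    verify_truth,
)

__all__ = [
    "HallmarkReport",
    "PipelineError",
    "validate_grouping",
    "find_core_families",
    "find_hallmark_families",
    "classify_families",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class HallmarkReport:
    """One group-restricted family: present in all members of ``group``
    (hallmark) or in all taxa except the group (anti-hallmark)."""

    group: str
    family_id: str
    kind: str  # "hallmark" | "anti-hallmark"
    all_pairs_significant: Optional[bool] = None
    description: str = ""


def validate_grouping(
    matrix: pd.DataFrame, grouping: Mapping[str, str]
) -> Dict[str, List[str]]:
    """Check that every matrix taxon is labelled exactly once and that
    there are >= 2 groups; return group -> sorted member list."""
    taxa = [str(t) for t in matrix.index]
    missing = sorted(set(taxa) - set(grouping))
    if missing:
        raise ValueError(f"taxa without a group label: {missing}")
    groups: Dict[str, List[str]] = {}
    for t in taxa:
        groups.setdefault(str(grouping[t]), []).append(t)
    if len(groups) < 2:
        raise ValueError("grouping must define at least 2 groups")
    return {g: sorted(ms) for g, ms in sorted(groups.items())}


def find_core_families(matrix: pd.DataFrame) -> List[str]:
    """Families with count >= 1 in every taxon, sorted by family id."""
    present = matrix >= 1
    return sorted(str(f) for f in matrix.columns[present.all(axis=0)])


def find_hallmark_families(
    matrix: pd.DataFrame,
    grouping: Mapping[str, str],
    reciprocal_flags: Optional[Mapping[str, bool]] = None,
    tolerance: int = 0,
) -> List[HallmarkReport]:
    """Hallmark and anti-hallmark families for every group.

    A hallmark of group G is present in every member of G (up to
    ``tolerance`` missing members) and absent from every non-member; an
    anti-hallmark is absent from every member of G and present in all
    other taxa. ``reciprocal_flags`` (family -> all-pairs-significant)
    is passed through to the report.
    """
    groups = validate_grouping(matrix, grouping)
    present = matrix >= 1
    reports: List[HallmarkReport] = []
    for group, members in groups.items():
        others = [t for t in matrix.index if str(t) not in members]
        in_members = present.loc[members]
        in_others = present.loc[others]
        for fam in matrix.columns:
            fam_id = str(fam)
            n_in = int(in_members[fam].sum())
            n_out = int(in_others[fam].sum())
            flag = reciprocal_flags.get(fam_id) if reciprocal_flags else None
            if n_in >= len(members) - tolerance and n_out == 0:
                reports.append(
                    HallmarkReport(group, fam_id, "hallmark", flag)
                )
            elif n_in == 0 and others and n_out == len(others):
                reports.append(
                    HallmarkReport(group, fam_id, "anti-hallmark", flag)
                )
    return reports


def classify_families(
    matrix: pd.DataFrame, grouping: Mapping[str, str]
) -> pd.Series:
    """Exhaustive, mutually exclusive family classification.

    Priority: core (in every taxon) > hallmark of some group >
    anti-hallmark of some group > other. Every family receives exactly
    one label.
    """
    core = set(find_core_families(matrix))
    reports = find_hallmark_families(matrix, grouping)
    hallmark: Dict[str, str] = {}
    anti: Dict[str, str] = {}
    for r in reports:
        target = hallmark if r.kind == "hallmark" else anti
        target.setdefault(r.family_id, r.group)
    labels = {}
    for fam in matrix.columns:
        fam_id = str(fam)
        if fam_id in core:
            labels[fam_id] = "core"
        elif fam_id in hallmark:
            labels[fam_id] = f"hallmark:{hallmark[fam_id]}"
        elif fam_id in anti:
            labels[fam_id] = f"anti-hallmark:{anti[fam_id]}"
        else:
            labels[fam_id] = "other"
    out = pd.Series(labels, name="category")
    out.index.name = "family_id"
    return out


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: Dict[str, object] = {
    "evalue_max": 1e-5,
    "min_identity": 20.0,
    "min_len": 100,
    "inflation": 2.0,
    "bootstrap": 1000,
    "gain_penalties": [1.0, 5.0],
    "core_genes_for_tree": 9,
    "plant_hallmarks_per_group": 3,
    "plant_anti_per_group": 2,
}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def run_pipeline(outdir: Path, config: Optional[Mapping[str, object]] = None,
                 sim_config: Optional[SimulationConfig] = None) -> Dict[str, object]:
    """Run the full synthetic-input pipeline into ``outdir``.

    Generates ground-truthed inputs, then executes profiling, pan-genome
    clustering + NJ dendrogram, core-gene concatenated NJ tree with
    bootstrap, Wagner gain/loss reconstruction under each configured gain
    penalty, and the hallmark report. Writes a manifest recording every
    threshold and seed. Deterministic: the same configuration and seed
    yield byte-identical outputs. Returns a summary dict (also written as
    ``manifest.json``).

    Grouping for the hallmark stage is derived from the true tree: the
    clades of the root's children. Hallmark and anti-hallmark families
    are planted on those clades so recovery can be scored exactly.
    """
    cfg: Dict[str, object] = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    sim = sim_config or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary: Dict[str, object] = {
        "viropan_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()},
        "simulation": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(sim).items()
        },
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        summary["stages"][name] = "started"

    try:
        # ---- simulate -------------------------------------------------
        stage("simulate")
        tree = simulate_tree(sim.n_taxa, sim.seed)
        truth = simulate_gene_content(tree, sim)
        root_children = [
            c for c in tree.seed_node.child_nodes()
        ]
        grouping: Dict[str, str] = {}
        planted_hallmarks: Dict[str, List[str]] = {}
        planted_anti: Dict[str, List[str]] = {}
        for k, child in enumerate(root_children, start=1):
            gname = f"group{k}"
            for lf in child.leaf_iter():
                grouping[lf.taxon.label] = gname
            planted_hallmarks[gname] = plant_clade_families(
                truth, child.label, int(cfg["plant_hallmarks_per_group"]),
                kind="hallmark",
            )
            planted_anti[gname] = plant_clade_families(
                truth, child.label, int(cfg["plant_anti_per_group"]), kind="anti"
            )
        verify_truth(truth)
        proteomes = emit_proteomes(truth, sim)
        allvall = emit_hit_table(proteomes, truth, sim)
        refhits = emit_reference_hits(proteomes, truth, sim)
        write_newick(truth.tree, outdir / "true_tree.nwk")
        with open(outdir / "grouping.tsv", "w", encoding="utf-8") as fh:
            fh.write("taxon\tgroup\n")
            for t in sorted(grouping):
                fh.write(f"{t}\t{grouping[t]}\n")
        summary["stages"]["simulate"] = {
            "n_taxa": sim.n_taxa,
            "n_families_total": len(truth.families),
            "n_proteins": sum(len(v) for v in proteomes.values()),
            "planted_hallmarks": planted_hallmarks,
            "planted_anti_hallmarks": planted_anti,
        }

        # ---- profile --------------------------------------------------
        stage("profile")
        evalue_max = float(cfg["evalue_max"])
        min_len = int(cfg["min_len"])
        protein_genome = {
            rec.id: taxon
            for taxon, recs in proteomes.items()
            for rec in recs
        }
        filtered_ids: Dict[str, List[str]] = {}
        assignments = {}
        for taxon in sorted(proteomes):
            queries = filter_queries(proteomes[taxon], min_len=min_len)
            filtered_ids[taxon] = [q.id for q in queries]
            assignments[taxon] = assign_families(
                taxon, refhits, evalue_max=evalue_max,
                query_ids=filtered_ids[taxon],
            )
        profile_matrix = build_content_matrix(assignments, mode="presence")
        write_content_matrix(profile_matrix, outdir / "profile_content_matrix.tsv")
        tallies = [
            tally_best_hit_sources(
                taxon, filtered_ids[taxon], allvall, protein_genome,
                evalue_max=evalue_max,
            )
            for taxon in sorted(proteomes)
        ]
        tally_df = pd.DataFrame(
            [
                {"genome": t.genome_id, **t.fractions}
                for t in tallies
            ]
        ).set_index("genome").fillna(0.0)
        _write_tsv(tally_df, outdir / "best_hit_source_tally.tsv")
        summary["stages"]["profile"] = {
            "n_families": int(profile_matrix.shape[1]),
            "n_assigned": int(sum(len(a) for a in assignments.values())),
        }

        # ---- pangenome ------------------------------------------------
        stage("pangenome")
        filtered_all = [p for ids in filtered_ids.values() for p in ids]
        graph = build_similarity_graph(
            allvall,
            min_identity=float(cfg["min_identity"]),
            evalue_max=evalue_max,
            proteins=sorted(filtered_all),
        )
        clusters = mcl_cluster(graph, inflation=float(cfg["inflation"]))
        pan_matrix = content_from_clusters(
            clusters, protein_genome, genomes=sorted(proteomes)
        )
        write_content_matrix(pan_matrix, outdir / "pan_content_matrix.tsv")
        with open(outdir / "pan_clusters.tsv", "w", encoding="utf-8") as fh:
            fh.write("cluster_id\tmembers\n")
            for cid in sorted(clusters.clusters):
                fh.write(f"{cid}\t{','.join(clusters.clusters[cid])}\n")
        pan_dm = content_distance(pan_matrix, metric="jaccard")
        pan_tree = neighbor_joining(pan_dm)
        write_newick(pan_tree, outdir / "pan_dendrogram.nwk")
        summary["stages"]["pangenome"] = {
            "n_clusters": len(clusters.clusters),
            "mcl_converged": clusters.converged,
        }

        # ---- core-gene tree -------------------------------------------
        stage("njtree")
        core = find_core_families(profile_matrix)
        n_core_use = min(int(cfg["core_genes_for_tree"]), len(core))
        if n_core_use < 1:
            raise PipelineError("njtree: no core families to build a tree from")
        rep_seq: Dict[Tuple[str, str], str] = {}
        for taxon, asgs in assignments.items():
            from .ortholog_profiling import dedupe_family_representatives

            kept, _ = dedupe_family_representatives(list(asgs))
            seqs = {r.id: r.residues for r in proteomes[taxon]}
            for a in kept:
                rep_seq[(taxon, a.family_id)] = seqs[a.orf_id]
        blocks = []
        taxa = sorted(proteomes)
        for fam in core[:n_core_use]:
            from .io_formats import SequenceRecord

            block = Alignment(
                tuple(
                    SequenceRecord(id=t, residues=rep_seq[(t, fam)]) for t in taxa
                )
            )
            blocks.append(strip_gap_columns(block))
        concat = concatenate_alignments(blocks, taxon_order=taxa)
        core_tree = bootstrap_support(
            concat, n_replicates=int(cfg["bootstrap"]), seed=sim.seed
        )
        write_newick(core_tree, outdir / "core_gene_tree.nwk")
        summary["stages"]["njtree"] = {
            "n_core_families": len(core),
            "n_used": n_core_use,
            "alignment_columns": concat.n_cols,
        }

        # ---- gain/loss ------------------------------------------------
        stage("gainloss")
        gl_summary = {}
        for g in cfg["gain_penalties"]:
            params = WagnerParams(gain_penalty=float(g))
            rec = wagner_reconstruct(truth.tree, profile_matrix, params)
            events, sizes = summarize_events(rec)
            tag = f"g{g:g}".replace(".", "_")
            _write_tsv(rec.counts, outdir / f"ancestral_counts_{tag}.tsv")
            _write_tsv(events, outdir / f"branch_events_{tag}.tsv")
            sizes.to_csv(outdir / f"node_sizes_{tag}.tsv", sep="\t")
            gl_summary[f"gain_penalty_{g:g}"] = {
                "root_size": int(rec.node_sizes()[rec.root_label]),
                "total_gains": int(events["gains"].sum()),
                "total_losses": int(events["losses"].sum()),
                "total_cost": rec.total_cost,
                "n_tied_families": len(rec.tied_families),
            }
        summary["stages"]["gainloss"] = gl_summary

        # ---- hallmark -------------------------------------------------
        stage("hallmark")
        reports = find_hallmark_families(profile_matrix, grouping)
        with open(outdir / "hallmark_report.tsv", "w", encoding="utf-8") as fh:
            fh.write("group\tfamily_id\tkind\tall_pairs_significant\n")
            for r in sorted(reports, key=lambda r: (r.group, r.kind, r.family_id)):
                fh.write(
                    f"{r.group}\t{r.family_id}\t{r.kind}\t{r.all_pairs_significant}\n"
                )
        categories = classify_families(profile_matrix, grouping)
        categories.to_csv(outdir / "family_categories.tsv", sep="\t")
        summary["stages"]["hallmark"] = {
            "n_core": len(core),
            "n_hallmark": sum(1 for r in reports if r.kind == "hallmark"),
            "n_anti_hallmark": sum(1 for r in reports if r.kind == "anti-hallmark"),
        }
    except PipelineError:
        raise
    except Exception as exc:
        failed = next(
            (k for k, v in summary["stages"].items() if v == "started"), "?"
        )
        raise PipelineError(f"stage {failed!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
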