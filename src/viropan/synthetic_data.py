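"""Ground-truthed synthetic inputs for the pipeline.

The generator emulates the statistical structure of a comparative study of
~18 giant-virus genomes: a known rooted tree, per-family gene presence
evolving by gain and loss events along its branches, one protein per
present family per genome (mutated copies of a family ancestor sequence,
so within-family similarity exceeds between-family similarity), and
pairwise-similarity hit tables consistent with that structure plus a
controlled rate of sub-threshold spurious hits.

Everything is driven by a single integer seed: identical configurations
produce byte-identical FASTA files and hit tables. The generator keeps a
complete truth ledger (ancestral contents, per-branch events, the true
family of every protein) against which downstream inference is scored.

Gain/loss events here are per-branch Bernoulli draws with probability
``1 - exp(-rate)`` independent of branch length — each branch is one
evolutionary "step" — which makes expected gene-content divergence
proportional to topological path length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import dendropy
import numpy as np
import yaml

from .io_formats import HitRecord, SequenceRecord, write_fasta, write_hit_table, write_newick

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_tree",
    "simulate_gene_content",
    "plant_clade_families",
    "emit_proteomes",
    "emit_hit_table",
    "emit_reference_hits",
    "verify_truth",
    "write_simulation",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
DECOY_FAMILY = "__decoy__"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults emulate the scale of the real analysis: 18 genomes, a root
    ancestor of 500 gene families, moderate per-branch gain/loss pressure,
    and proteins long enough (>= 100 aa) to pass the query length filter.
    """

    n_taxa: int = 18
    n_families_root: int = 500
    gain_rate: float = 0.05
    loss_rate: float = 0.05
    seq_length_range: Tuple[int, int] = (120, 180)
    within_family_divergence: float = 0.1
    spurious_hit_rate: float = 0.0
    novel_gain_prob: float = 0.5
    decoy_fraction: float = 0.0
    decoy_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.n_families_root < 1:
            raise ValueError("n_families_root must be >= 1")
        for name in ("gain_rate", "loss_rate", "spurious_hit_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.within_family_divergence <= 1.0):
            raise ValueError("within_family_divergence must be in [0, 1]")
        if not (0.0 <= self.novel_gain_prob <= 1.0):
            raise ValueError("novel_gain_prob must be in [0, 1]")
        lo, hi = self.seq_length_range
        if lo < 1 or hi < lo:
            raise ValueError("seq_length_range must be (lo, hi) with 1 <= lo <= hi")


@dataclass
class SimulationTruth:
    """The generator's ground truth.

    ``ancestral_contents`` maps node label -> family -> copy count (0/1
    here); ``branch_gained``/``branch_lost`` record the family sets gained
    and lost on the branch above each non-root node; ``branch_events``
    are the corresponding (gains, losses) counts. ``protein_family`` maps
    every emitted protein id to its true family.
    """

    tree: dendropy.Tree
    families: List[str]
    ancestral_contents: Dict[str, Dict[str, int]]
    branch_gained: Dict[str, Set[str]]
    branch_lost: Dict[str, Set[str]]
    gain_opportunities: Dict[str, int]
    loss_opportunities: Dict[str, int]
    protein_family: Dict[str, str] = field(default_factory=dict)
    family_ancestor_seq: Dict[str, str] = field(default_factory=dict)

    @property
    def branch_events(self) -> Dict[str, Tuple[int, int]]:
        return {
            node: (len(self.branch_gained[node]), len(self.branch_lost[node]))
            for node in self.branch_gained
        }

    @property
    def root_label(self) -> str:
        return self.tree.seed_node.label

    def content_of(self, node_label: str) -> Dict[str, int]:
        return self.ancestral_contents[node_label]

    def leaf_labels(self) -> List[str]:
        return sorted(
            lf.taxon.label for lf in self.tree.leaf_node_iter() if lf.taxon
        )

    def leaf_contents(self) -> Dict[str, Dict[str, int]]:
        return {t: self.ancestral_contents[t] for t in self.leaf_labels()}

    def present_families(self, node_label: str) -> Set[str]:
        return {f for f, c in self.ancestral_contents[node_label].items() if c > 0}


def _label_nodes(tree: dendropy.Tree) -> None:
    """Leaves carry their taxon label; internal nodes get stable preorder
    labels N001, N002, ..."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        else:
            k += 1
            node.label = f"N{k:03d}"


def simulate_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """A random binary rooted tree with exponential branch lengths
    (mean 0.1) and leaf labels T001..Tnnn; deterministic per seed."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_taxa)))
    labels = [f"T{i + 1:0{width}d}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    lineages: List[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        lineages.append(node)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = dendropy.Node()
        left, right = lineages[i], lineages[j]
        parent.add_child(left)
        parent.add_child(right)
        left.edge.length = float(rng.exponential(0.1))
        right.edge.length = float(rng.exponential(0.1))
        lineages = [n for k, n in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=lineages[0])
    tree.is_rooted = True
    _label_nodes(tree)
    return tree


def simulate_gene_content(
    tree: dendropy.Tree, config: SimulationConfig
) -> SimulationTruth:
    """Evolve family presence along the tree.

    The root carries ``n_families_root`` families. On each branch, every
    family present in the parent is lost with probability
    ``1 - exp(-loss_rate)``; every registered-but-absent family is gained
    with probability ``1 - exp(-gain_rate)``, and each such gain event is
    redirected, with probability ``novel_gain_prob``, to a brand-new
    family (an open pan-genome: lineages keep acquiring genes nobody else
    has). The returned ledger is self-consistent: replaying the branch
    events from the root reproduces every node's content.
    """
    config.validate()
    if tree.seed_node.label is None:
        _label_nodes(tree)
    rng = np.random.default_rng([config.seed, 11])
    p_loss = 1.0 - np.exp(-config.loss_rate)
    p_gain = 1.0 - np.exp(-config.gain_rate)

    families = [f"F{i + 1:04d}" for i in range(config.n_families_root)]
    registry = list(families)
    novel_counter = 0

    root = tree.seed_node
    contents: Dict[str, Dict[str, int]] = {
        root.label: {f: 1 for f in registry}
    }
    gained: Dict[str, Set[str]] = {}
    lost: Dict[str, Set[str]] = {}
    gain_opps: Dict[str, int] = {}
    loss_opps: Dict[str, int] = {}

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_content = contents[node.parent_node.label]
        present = [f for f in registry if parent_content.get(f, 0) > 0]
        absent = [f for f in registry if parent_content.get(f, 0) == 0]
        loss_opps[node.label] = len(present)
        gain_opps[node.label] = len(absent)

        lost_here = {
            f for f, u in zip(present, rng.random(len(present))) if u < p_loss
        }
        gained_here: Set[str] = set()
        hit = (
            [f for f, u in zip(absent, rng.random(len(absent))) if u < p_gain]
            if absent
            else []
        )
        for f in hit:
            if rng.random() < config.novel_gain_prob:
                novel_counter += 1
                novel = f"G{novel_counter:04d}"
                registry.append(novel)
                gained_here.add(novel)
            else:
                gained_here.add(f)

        content = dict(parent_content)
        for f in lost_here:
            content[f] = 0
        for f in gained_here:
            content[f] = 1
        contents[node.label] = content
        gained[node.label] = gained_here
        lost[node.label] = lost_here

    # backfill zero counts for late-registered families at every node
    for label in contents:
        for f in registry:
            contents[label].setdefault(f, 0)

    truth = SimulationTruth(
        tree=tree,
        families=list(registry),
        ancestral_contents=contents,
        branch_gained=gained,
        branch_lost=lost,
        gain_opportunities=gain_opps,
        loss_opportunities=loss_opps,
    )
    return truth


def plant_clade_families(
    truth: SimulationTruth,
    clade_node_label: str,
    n_families: int,
    kind: str = "hallmark",
    prefix: Optional[str] = None,
) -> List[str]:
    """Plant families with a known clade-restricted pattern, updating the
    truth ledger consistently.

    ``kind='hallmark'``: families gained on the branch into the clade node
    and present in its whole subtree, absent everywhere else.
    ``kind='anti'``: families present at the root and everywhere *except*
    the clade (lost on the clade's stem branch).
    Returns the new family ids. Must be called before :func:`emit_proteomes`.
    """
    if kind not in ("hallmark", "anti"):
        raise ValueError("kind must be 'hallmark' or 'anti'")
    nodes = {n.label: n for n in truth.tree.preorder_node_iter()}
    if clade_node_label not in nodes:
        raise ValueError(f"no node labelled {clade_node_label!r}")
    clade = nodes[clade_node_label]
    if clade is truth.tree.seed_node:
        raise ValueError("cannot plant on the root")
    inside = {n.label for n in clade.preorder_iter()}
    prefix = prefix or ("H" if kind == "hallmark" else "X")
    new: List[str] = []
    for k in range(n_families):
        fam = f"{prefix}{clade_node_label}_{k + 1:02d}"
        new.append(fam)
        truth.families.append(fam)
        for label, content in truth.ancestral_contents.items():
            if kind == "hallmark":
                content[fam] = 1 if label in inside else 0
            else:
                content[fam] = 0 if label in inside else 1
        if kind == "hallmark":
            truth.branch_gained[clade_node_label].add(fam)
        else:
            truth.branch_lost[clade_node_label].add(fam)
    return new


def verify_truth(truth: SimulationTruth) -> None:
    """Replay the event ledger from the root; raise if any node's recorded
    content disagrees (gains/losses must explain every content change)."""
    root = truth.tree.seed_node
    for node in truth.tree.preorder_node_iter():
        if node is root:
            continue
        parent = truth.ancestral_contents[node.parent_node.label]
        child = truth.ancestral_contents[node.label]
        gained = truth.branch_gained[node.label]
        lost = truth.branch_lost[node.label]
        for fam in truth.families:
            expect = parent.get(fam, 0) + (fam in gained) - (fam in lost)
            if child.get(fam, 0) != expect:
                raise AssertionError(
                    f"ledger inconsistent at node {node.label}, family {fam}: "
                    f"recorded {child.get(fam, 0)}, replay gives {expect}"
                )
            if expect < 0:
                raise AssertionError(f"negative count at {node.label}/{fam}")


# ---------------------------------------------------------------------------
# Sequences and hit tables
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    chars = np.array(list(seq))
    mask = rng.random(len(chars)) < divergence
    for i in np.nonzero(mask)[0]:
        alternatives = AMINO_ACIDS[AMINO_ACIDS != chars[i]]
        chars[i] = rng.choice(alternatives)
    return "".join(chars)


def emit_proteomes(
    truth: SimulationTruth, config: SimulationConfig
) -> Dict[str, List[SequenceRecord]]:
    """One protein per present family per leaf genome.

    Each protein is a copy of its family's ancestor sequence mutated at
    ``within_family_divergence`` substitutions/site (a star model within
    the family; sequences carry family membership, not tree signal).
    Fills ``truth.protein_family`` and ``truth.family_ancestor_seq``.
    With ``decoy_fraction > 0`` short random decoy proteins (below the
    100-aa query filter) are appended and labelled ``__decoy__``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 23])
    lo, hi = config.seq_length_range
    for fam in truth.families:  # registry order is deterministic
        if fam not in truth.family_ancestor_seq:
            length = int(rng.integers(lo, hi + 1))
            truth.family_ancestor_seq[fam] = _random_protein(rng, length)

    proteomes: Dict[str, List[SequenceRecord]] = {}
    truth.protein_family.clear()
    for taxon in truth.leaf_labels():
        content = truth.ancestral_contents[taxon]
        records: List[SequenceRecord] = []
        k = 0
        for fam in truth.families:
            if content.get(fam, 0) <= 0:
                continue
            k += 1
            pid = f"{taxon}|orf{k:04d}"
            seq = _mutate(
                rng, truth.family_ancestor_seq[fam], config.within_family_divergence
            )
            records.append(SequenceRecord(id=pid, residues=seq))
            truth.protein_family[pid] = fam
        n_decoys = int(round(config.decoy_fraction * k))
        for d in range(n_decoys):
            k += 1
            pid = f"{taxon}|orf{k:04d}"
            records.append(
                SequenceRecord(
                    id=pid, residues=_random_protein(rng, config.decoy_length)
                )
            )
            truth.protein_family[pid] = DECOY_FAMILY
        proteomes[taxon] = records
    return proteomes


def _score(pct_identity: float, aln_length: int, db_size: int) -> Tuple[float, float]:
    """Synthetic scoring model: bit score increasing in identity x length,
    E-value decreasing in bit score. Only the ordering matters downstream."""
    bit = 0.5 * pct_identity * aln_length / 100.0
    evalue = float(db_size) * 2.0 ** (-bit)
    return bit, evalue


def _pair_identity(a: str, b: str) -> Tuple[float, int, int]:
    """Ungapped identity of two equal-length family members."""
    arr_a = np.array(list(a))
    arr_b = np.array(list(b))
    matches = int((arr_a == arr_b).sum())
    length = len(a)
    return 100.0 * matches / length, matches, length


def _make_hit(qid: str, sid: str, pct: float, matches: int, length: int, db_size: int) -> HitRecord:
    bit, evalue = _score(pct, length, db_size)
    return HitRecord(
        query_id=qid,
        subject_id=sid,
        pct_identity=round(pct, 2),
        aln_length=length,
        mismatches=length - matches,
        gap_opens=0,
        q_start=1,
        q_end=length,
        s_start=1,
        s_end=length,
        evalue=evalue,
        bit_score=bit,
    )


def emit_hit_table(
    proteomes: Dict[str, List[SequenceRecord]],
    truth: SimulationTruth,
    config: SimulationConfig,
) -> List[HitRecord]:
    """All-vs-all hit table over every emitted protein.

    Every ordered within-family pair (and every self pair) yields a hit
    whose percent identity is the true ungapped identity. Spurious
    between-family hits are injected at ``spurious_hit_rate`` x (number of
    true non-self hits); they are sub-threshold by construction (identity
    < 20% and E-value > 1e-5) so correct filtering removes them all.
    """
    rng = np.random.default_rng([config.seed, 31])
    seqs: Dict[str, str] = {}
    order: List[str] = []
    for taxon in sorted(proteomes):
        for rec in proteomes[taxon]:
            seqs[rec.id] = rec.residues
            order.append(rec.id)
    db_size = len(order)

    by_family: Dict[str, List[str]] = {}
    for pid in order:
        fam = truth.protein_family[pid]
        if fam != DECOY_FAMILY:
            by_family.setdefault(fam, []).append(pid)

    hits: List[HitRecord] = []
    n_true = 0
    for pid in order:
        length = len(seqs[pid])
        hits.append(_make_hit(pid, pid, 100.0, length, length, db_size))
    for fam in sorted(by_family):
        members = by_family[fam]
        for qid in members:
            for sid in members:
                if qid == sid:
                    continue
                pct, matches, length = _pair_identity(seqs[qid], seqs[sid])
                hits.append(_make_hit(qid, sid, pct, matches, length, db_size))
                n_true += 1

    n_spurious = int(round(config.spurious_hit_rate * n_true))
    for _ in range(n_spurious):
        qid, sid = (order[i] for i in rng.integers(0, len(order), size=2))
        while truth.protein_family[qid] == truth.protein_family[sid]:
            qid, sid = (order[i] for i in rng.integers(0, len(order), size=2))
        pct = float(rng.uniform(8.0, 19.5))
        length = int(rng.integers(30, 60))
        matches = int(round(pct * length / 100.0))
        hits.append(_make_hit(qid, sid, pct, matches, length, db_size))
    return hits


def emit_reference_hits(
    proteomes: Dict[str, List[SequenceRecord]],
    truth: SimulationTruth,
    config: SimulationConfig,
) -> List[HitRecord]:
    """Query-vs-reference hit table: each protein against a reference
    database of one representative (the family ancestor sequence) per
    family, subject id = family id. Spurious sub-threshold hits against
    random other families are injected at ``spurious_hit_rate``."""
    rng = np.random.default_rng([config.seed, 37])
    db_size = len(truth.families)
    hits: List[HitRecord] = []
    n_true = 0
    all_pids: List[str] = []
    for taxon in sorted(proteomes):
        for rec in proteomes[taxon]:
            all_pids.append(rec.id)
            fam = truth.protein_family[rec.id]
            if fam == DECOY_FAMILY:
                continue
            pct, matches, length = _pair_identity(
                rec.residues, truth.family_ancestor_seq[fam]
            )
            hits.append(_make_hit(rec.id, fam, pct, matches, length, db_size))
            n_true += 1
    n_spurious = int(round(config.spurious_hit_rate * n_true))
    fams = sorted(truth.families)
    for _ in range(n_spurious):
        qid = all_pids[int(rng.integers(0, len(all_pids)))]
        fam = fams[int(rng.integers(0, len(fams)))]
        while fam == truth.protein_family[qid]:
            fam = fams[int(rng.integers(0, len(fams)))]
        pct = float(rng.uniform(8.0, 19.5))
        length = int(rng.integers(30, 60))
        matches = int(round(pct * length / 100.0))
        hits.append(_make_hit(qid, fam, pct, matches, length, db_size))
    return hits


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_simulation(outdir: Path, config: SimulationConfig) -> SimulationTruth:
    """Run the full generator and write a self-contained input bundle:
    per-taxon FASTA proteomes, truth label table, true tree, all-vs-all
    and query-vs-reference hit tables, and the config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config.n_taxa, config.seed)
    truth = simulate_gene_content(tree, config)
    proteomes = emit_proteomes(truth, config)
    allvall = emit_hit_table(proteomes, truth, config)
    refhits = emit_reference_hits(proteomes, truth, config)

    fasta_dir = outdir / "proteomes"
    fasta_dir.mkdir(exist_ok=True)
    for taxon in sorted(proteomes):
        write_fasta(proteomes[taxon], fasta_dir / f"{taxon}.faa")
    write_newick(truth.tree, outdir / "true_tree.nwk")
    write_hit_table(allvall, outdir / "hits_all_vs_all.tsv")
    write_hit_table(refhits, outdir / "hits_vs_reference.tsv")
    with open(outdir / "protein_families.tsv", "w", encoding="utf-8") as fh:
        fh.write("protein_id\tfamily_id\n")
        for pid in sorted(truth.protein_family):
            fh.write(f"{pid}\t{truth.protein_family[pid]}\n")
    with open(outdir / "protein_genomes.tsv", "w", encoding="utf-8") as fh:
        fh.write("protein_id\tgenome_id\n")
        for taxon in sorted(proteomes):
            for rec in proteomes[taxon]:
                fh.write(f"{rec.id}\t{taxon}\n")
    with open(outdir / "branch_events.tsv", "w", encoding="utf-8") as fh:
        fh.write("branch_child\tgains\tlosses\n")
        for node in sorted(truth.branch_gained):
            fh.write(
                f"{node}\t{len(truth.branch_gained[node])}\t{len(truth.branch_lost[node])}\n"
            )
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        cfg = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        }
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return truth
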