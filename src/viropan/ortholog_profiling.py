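"""Ortholog assignment from similarity hit tables.

Implements the selection rules used when annotating viral proteomes
against a reference ortholog database: queries must be >= 100 aa, hits
must pass a strict E-value cutoff (E < 1e-5 by convention; the inequality
is strict), one reference family per open reading frame (highest bit
score), and one ORF per family per genome (again highest bit score, with
the displaced ORFs reported as paralog candidates). On top of the
assignments the module builds gene-content matrices, confirms families by
reciprocal hits, tallies best-hit source organisms, and compares
within-genome paralog identity against ortholog identity to separate
recent duplications from independent acquisitions.

Tie-breaks are fixed and documented: bit score first, then lower E-value,
then lexicographic subject (or ORF) id, so results are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import HitRecord, SequenceRecord

__all__ = [
    "OrthologAssignment",
    "SourceTally",
    "ParalogGroupReport",
    "filter_queries",
    "filter_hits",
    "best_hit_per_query",
    "assign_families",
    "dedupe_family_representatives",
    "build_content_matrix",
    "reciprocal_confirmation",
    "tally_best_hit_sources",
    "analyze_paralog_groups",
]

logger = logging.getLogger(__name__)

NO_HIT = "no hit"


@dataclass(frozen=True)
class OrthologAssignment:
    """One ORF assigned to one reference family within one genome."""

    orf_id: str
    family_id: str
    bit_score: float
    evalue: float
    genome_id: str


@dataclass(frozen=True)
class SourceTally:
    """Per-genome distribution of best-hit sources; fractions (including
    the 'no hit' remainder) sum to 1."""

    genome_id: str
    fractions: Dict[str, float]
    counts: Dict[str, int]
    n_queries: int


@dataclass(frozen=True)
class ParalogGroupReport:
    """Within-genome redundant gene group compared to its orthologs.

    ``within_identity_range`` spans all pairwise identities among group
    members; ``ortholog_identity_range`` spans the members' best-ortholog
    identities. Verdict: 'duplication-likely' when even the least similar
    paralog pair is closer than the closest ortholog, 'transfer-likely'
    when the reverse holds, else 'ambiguous' ('no-ortholog' if the group
    has no external hit at all).
    """

    genome_id: str
    members: Tuple[str, ...]
    within_identity_range: Tuple[float, float]
    ortholog_identity_range: Optional[Tuple[float, float]]
    verdict: str


def filter_queries(
    sequences: Iterable[SequenceRecord], min_len: int = 100
) -> List[SequenceRecord]:
    """Keep sequences with length >= ``min_len`` (boundary inclusive)."""
    kept = [s for s in sequences if len(s) >= min_len]
    return kept


def filter_hits(hits: Iterable[HitRecord], evalue_max: float = 1e-5) -> List[HitRecord]:
    """Keep hits with E-value strictly below ``evalue_max``."""
    return [h for h in hits if h.evalue < evalue_max]


def _hit_rank(h: HitRecord) -> Tuple[float, float, str]:
    # maximal bit score, then minimal E-value, then lexicographic subject
    return (-h.bit_score, h.evalue, h.subject_id)


def best_hit_per_query(hits: Iterable[HitRecord]) -> Dict[str, HitRecord]:
    """Exactly one hit per query: highest bit score, ties broken by lower
    E-value and then lexicographic subject id."""
    best: Dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    return best


def assign_families(
    genome_id: str,
    hits: Iterable[HitRecord],
    evalue_max: float = 1e-5,
    query_ids: Optional[Iterable[str]] = None,
) -> List[OrthologAssignment]:
    """Filter hits, pick the best reference family per ORF, and return the
    raw (pre-dedupe) assignments for one genome.

    ``query_ids`` optionally restricts to the filtered query set (so ORFs
    below the length cutoff never acquire an assignment).
    """
    allowed = set(query_ids) if query_ids is not None else None
    passed = filter_hits(hits, evalue_max)
    if allowed is not None:
        passed = [h for h in passed if h.query_id in allowed]
    best = best_hit_per_query(passed)
    assignments = [
        OrthologAssignment(
            orf_id=q,
            family_id=h.subject_id,
            bit_score=h.bit_score,
            evalue=h.evalue,
            genome_id=genome_id,
        )
        for q, h in sorted(best.items())
    ]
    logger.info(
        "%s: %d hits passed E<%g, %d ORFs assigned", genome_id, len(passed),
        evalue_max, len(assignments),
    )
    return assignments


def dedupe_family_representatives(
    assignments: Sequence[OrthologAssignment],
) -> Tuple[List[OrthologAssignment], List[OrthologAssignment]]:
    """Within one genome keep, per family, only the highest-bit-score ORF.

    Returns ``(kept, paralog_candidates)``; the displaced ORFs are the
    candidates for within-genome paralogy. After this step the
    genome -> family relation is injective both ways.
    """
    genomes = {a.genome_id for a in assignments}
    if len(genomes) > 1:
        raise ValueError(f"assignments span multiple genomes: {sorted(genomes)}")
    by_family: Dict[str, List[OrthologAssignment]] = {}
    for a in assignments:
        by_family.setdefault(a.family_id, []).append(a)
    kept: List[OrthologAssignment] = []
    displaced: List[OrthologAssignment] = []
    for fam in sorted(by_family):
        group = sorted(
            by_family[fam], key=lambda a: (-a.bit_score, a.evalue, a.orf_id)
        )
        kept.append(group[0])
        displaced.extend(group[1:])
    if displaced:
        logger.info(
            "%s: %d ORFs displaced as paralog candidates",
            next(iter(genomes), "?"), len(displaced),
        )
    return kept, displaced


def build_content_matrix(
    assignments_by_genome: Mapping[str, Sequence[OrthologAssignment]],
    mode: str = "presence",
) -> pd.DataFrame:
    """Genomes x families content matrix.

    ``presence``: 0/1 after per-genome dedupe (one representative ORF per
    family). ``count``: pre-dedupe per-family ORF counts. Rows are the
    given genomes, columns the sorted union of families.
    """
    if mode not in ("presence", "count"):
        raise ValueError("mode must be 'presence' or 'count'")
    genomes = sorted(assignments_by_genome)
    cells: Dict[str, Dict[str, int]] = {g: {} for g in genomes}
    for g in genomes:
        assignments = assignments_by_genome[g]
        if mode == "presence":
            kept, _ = dedupe_family_representatives(list(assignments))
            for a in kept:
                if a.family_id in cells[g]:
                    raise ValueError(
                        f"duplicate (genome, family) after dedupe: "
                        f"({g}, {a.family_id})"
                    )
                cells[g][a.family_id] = 1
        else:
            for a in assignments:
                cells[g][a.family_id] = cells[g].get(a.family_id, 0) + 1
    families = sorted({f for g in genomes for f in cells[g]})
    matrix = pd.DataFrame(0, index=genomes, columns=families, dtype=int)
    for g in genomes:
        for f, c in cells[g].items():
            matrix.at[g, f] = c
    matrix.index.name = "taxon"
    return matrix


def reciprocal_confirmation(
    members: Sequence[str],
    hits: Iterable[HitRecord],
    evalue_max: float = 1e-5,
) -> Tuple[pd.DataFrame, bool]:
    """Confirm a family by reciprocal significant hits.

    Pair (i, j) is significant iff hits i->j AND j->i both pass the
    E-value cutoff. Returns the boolean pair matrix and the
    "all-combinations" flag (every distinct pair significant). Members
    absent from the hit table simply never pass.
    """
    members = list(members)
    significant = {
        (h.query_id, h.subject_id)
        for h in hits
        if h.evalue < evalue_max and h.query_id in members and h.subject_id in members
    }
    mat = pd.DataFrame(False, index=members, columns=members, dtype=bool)
    for i in members:
        mat.at[i, i] = True
        for j in members:
            if i != j and (i, j) in significant and (j, i) in significant:
                mat.at[i, j] = True
    all_pairs = all(
        mat.at[i, j] for i in members for j in members if i != j
    )
    missing = [
        m for m in members if not any((m, j) in significant for j in members if j != m)
    ]
    if missing:
        logger.info("members with no significant outgoing hit: %s", missing)
    return mat, all_pairs


def tally_best_hit_sources(
    genome_id: str,
    query_ids: Sequence[str],
    hits: Iterable[HitRecord],
    subject_source: Mapping[str, str],
    evalue_max: float = 1e-5,
) -> SourceTally:
    """Fraction of queries whose best hit comes from each source category.

    Subjects mapped to the query genome itself are excluded before the
    best hit is chosen (a genome is never its own source); queries with no
    surviving hit fall into the 'no hit' remainder. Fractions sum to 1
    over all categories including 'no hit'.
    """
    queries = list(query_ids)
    if not queries:
        raise ValueError("empty query set")
    qset = set(queries)
    candidates = [
        h
        for h in filter_hits(hits, evalue_max)
        if h.query_id in qset
        and subject_source.get(h.subject_id, h.subject_id) != genome_id
    ]
    best = best_hit_per_query(candidates)
    counts: Dict[str, int] = {}
    for q in queries:
        if q in best:
            src = subject_source.get(best[q].subject_id, best[q].subject_id)
            counts[src] = counts.get(src, 0) + 1
        else:
            counts[NO_HIT] = counts.get(NO_HIT, 0) + 1
    total = len(queries)
    fractions = {k: v / total for k, v in sorted(counts.items())}
    return SourceTally(
        genome_id=genome_id,
        fractions=fractions,
        counts=dict(sorted(counts.items())),
        n_queries=total,
    )


def _global_identity(a: str, b: str) -> float:
    """Percent identity of the best global alignment (Needleman–Wunsch with
    BLOSUM62, via Biopython)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    matches = sum(
        1
        for ca, cb in zip(str(aln[0]), str(aln[1]))
        if ca == cb and ca != "-"
    )
    return 100.0 * matches / aln.length


def analyze_paralog_groups(
    genome_id: str,
    groups: Sequence[Sequence[str]],
    within_hits: Iterable[HitRecord],
    ortholog_hits: Iterable[HitRecord],
    sequences: Optional[Mapping[str, str]] = None,
    global_identity: bool = False,
) -> List[ParalogGroupReport]:
    """Compare within-genome paralog identity to ortholog identity.

    For each candidate group (>= 2 ORFs): the within range spans the local
    percent identities of all ordered member pairs found in
    ``within_hits``; the ortholog range spans each member's best external
    hit identity from ``ortholog_hits``. With ``global_identity=True`` and
    ``sequences`` given, within-group identities are recomputed from full
    global alignments instead of the hit table's local identities.
    """
    within_hits = list(within_hits)
    ortho_best = best_hit_per_query(list(ortholog_hits))
    reports: List[ParalogGroupReport] = []
    for group in groups:
        members = tuple(sorted(group))
        if len(members) < 2:
            raise ValueError(f"paralog group {members} has fewer than 2 members")
        if global_identity and sequences is not None:
            within = [
                _global_identity(sequences[a], sequences[b])
                for ia, a in enumerate(members)
                for b in members[ia + 1 :]
            ]
        else:
            within = [
                h.pct_identity
                for h in within_hits
                if h.query_id in members
                and h.subject_id in members
                and h.query_id != h.subject_id
            ]
        if not within:
            raise ValueError(
                f"no within-group hits for paralog group {members}"
            )
        w_rng = (min(within), max(within))
        ortho = [
            ortho_best[m].pct_identity for m in members if m in ortho_best
        ]
        if not ortho:
            reports.append(
                ParalogGroupReport(genome_id, members, w_rng, None, "no-ortholog")
            )
            continue
        o_rng = (min(ortho), max(ortho))
        if w_rng[0] > o_rng[1]:
            verdict = "duplication-likely"
        elif w_rng[1] < o_rng[0]:
            verdict = "transfer-likely"
        else:
            verdict = "ambiguous"
        reports.append(ParalogGroupReport(genome_id, members, w_rng, o_rng, verdict))
    return reports
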