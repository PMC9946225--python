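"""Homology search, transitive grouping, and the old/new activity ratio.

The built-in search is a seed-and-extend local aligner: shared words seed
ungapped X-drop extensions whose scores are converted to expectation values
with the Karlin-Altschul formula E = K * m * n * exp(-lambda * S).  It is a
pluggable seam — any callable with the same signature (for instance an
external-tool adapter) can stand in for :func:`local_homology_search`
downstream.  The decision threshold the pipeline inherits is E < 1e-100,
applied both to insert-vs-insert grouping and to insert-vs-genome area
calculation; the regime is near-identical repeat copies where the
significant/insignificant split is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import exp, log
from typing import Callable, Iterable, Mapping, Sequence

import edlib
import networkx as nx

from .core_io import GenomicInterval, revcomp

DEFAULT_EVALUE_MAX = 1e-100


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scoring with its Karlin-Altschul constants."""

    match: int = 1
    mismatch: int = -2
    karlin_k: float = 0.28
    karlin_lambda: float = 1.07

    def __post_init__(self):
        if self.mismatch >= 0:
            raise ValueError("mismatch penalty must be negative")
        if self.match <= 0:
            raise ValueError("match score must be positive")

    def evalue(self, score: float, m: int, n: int) -> float:
        # computed in log space to survive scores of thousands
        log_e = log(self.karlin_k * m * n) - self.karlin_lambda * score
        if log_e < -745 * log(10):  # below float underflow, report 0-adjacent
            return 0.0
        return exp(min(log_e, 700.0))


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    q_interval: tuple[int, int]     # 0-based half-open offsets in the query
    s_interval: tuple[int, int]     # offsets in the subject
    strand: str                     # '+' or '-': subject strand of the match
    score: float
    evalue: float


def _extend_ungapped(q: str, s: str, qpos: int, spos: int, word: int,
                     scoring: ScoringScheme, x_drop: int):
    """X-drop extension around a seed; returns (q0, q1, score)."""
    match, mismatch = scoring.match, scoring.mismatch
    # rightward from seed end
    score = word * match
    best = score
    best_right = qpos + word
    i, j = qpos + word, spos + word
    while i < len(q) and j < len(s):
        score += match if q[i] == s[j] else mismatch
        i += 1
        j += 1
        if score > best:
            best, best_right = score, i
        elif best - score > x_drop:
            break
    # leftward from seed start
    score = best
    best_left = qpos
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        score += match if q[i] == s[j] else mismatch
        if score > best:
            best, best_left = score, i
        elif best - score > x_drop:
            break
        i -= 1
        j -= 1
    return best_left, best_right, best


def _search_one_strand(query: str, subject: str, word_size: int,
                       scoring: ScoringScheme, x_drop: int):
    """Seed on shared words, extend per diagonal, merge covered extents."""
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - word_size + 1):
        index.setdefault(subject[j:j + word_size], []).append(j)
    covered: dict[int, list[tuple[int, int]]] = {}
    hits = []
    for i in range(len(query) - word_size + 1):
        positions = index.get(query[i:i + word_size])
        if not positions:
            continue
        for j in positions:
            diag = i - j
            spans = covered.setdefault(diag, [])
            if any(lo <= i < hi for lo, hi in spans):
                continue
            q0, q1, score = _extend_ungapped(query, subject, i, j, word_size,
                                             scoring, x_drop)
            spans.append((q0, q1))
            if score > 0:
                hits.append((q0, q1, q0 - diag, q1 - diag, score))
    return hits


def local_homology_search(query: str, subjects: Mapping[str, str],
                          word_size: int = 11,
                          scoring: ScoringScheme = ScoringScheme(),
                          evalue_max: float | None = None,
                          query_id: str = "query",
                          both_strands: bool = True,
                          x_drop: int = 40) -> list[HomologyHit]:
    """Seed-and-extend local search of one query against a subject set.

    Returns hits with evalue <= evalue_max (all hits when None), highest
    score first.  Minus-strand hits record subject offsets of the matched
    subject region with strand '-'.
    """
    if not query:
        raise ValueError("empty query sequence")
    if word_size < 8:
        raise ValueError("word_size must be >= 8")
    hits: list[HomologyHit] = []
    m = len(query)
    for sid, subject in subjects.items():
        if not subject:
            raise ValueError(f"empty subject sequence {sid!r}")
        n = len(subject)
        for strand, qseq in (("+", query), ("-", revcomp(query))):
            if not both_strands and strand == "-":
                continue
            for q0, q1, s0, s1, score in _search_one_strand(
                    qseq, subject, word_size, scoring, x_drop):
                ev = scoring.evalue(score, m, n)
                if evalue_max is not None and ev > evalue_max:
                    continue
                if strand == "-":
                    q0, q1 = m - q1, m - q0
                hits.append(HomologyHit(query_id, sid, (q0, q1), (s0, s1),
                                        strand, float(score), ev))
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_interval))
    return hits


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

@dataclass
class InsertGroup:
    group_id: int
    member_ids: tuple[str, ...]
    focus: bool
    representative_id: str | None = None
    old_area_bp: int | None = None
    new_area_bp: int | None = None
    activity_ratio: float | None = None
    ratio_infinite: bool = False


SearchFn = Callable[..., list[HomologyHit]]


def build_homology_graph(inserts: Mapping[str, str],
                         evalue_max: float = DEFAULT_EVALUE_MAX,
                         search: SearchFn = local_homology_search,
                         **search_kwargs) -> nx.Graph:
    """All-vs-all search; undirected edge iff any hit in either direction
    meets the threshold."""
    graph = nx.Graph()
    graph.add_nodes_from(inserts)
    ids = list(inserts)
    for i, qid in enumerate(ids):
        subjects = {sid: inserts[sid] for sid in ids[i + 1:]}
        if not subjects:
            continue
        for hit in search(inserts[qid], subjects, evalue_max=evalue_max,
                          query_id=qid, **search_kwargs):
            graph.add_edge(qid, hit.subject_id)
    return graph


def connected_component_groups(graph: nx.Graph,
                               min_members: int = 5) -> list[InsertGroup]:
    """Transitive groups: connected components, ordered by descending size
    then smallest member id; group ids count from 1 (largest group first)."""
    comps = [tuple(sorted(c)) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [
        InsertGroup(group_id=i + 1, member_ids=c, focus=len(c) >= min_members)
        for i, c in enumerate(comps)
    ]


def select_representative(member_ids: Iterable[str],
                          insert_lengths: Mapping[str, int]) -> str:
    """Longest member; ties broken by lexicographically smallest id."""
    members = list(member_ids)
    if not members:
        raise ValueError("empty group")
    return min(members, key=lambda mid: (-insert_lengths[mid], mid))


def merged_interval_length(intervals: Iterable[tuple[str, int, int]]) -> int:
    """Total bp covered by the union of (chrom, start, end) intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    total = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_lo, cur_hi = spans[0]
        for lo, hi in spans[1:]:
            if lo > cur_hi:
                total += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        total += cur_hi - cur_lo
    return total


def compute_activity_ratio(group: InsertGroup,
                           genome_hits: Sequence[HomologyHit],
                           insert_lengths: Mapping[str, int],
                           evalue_max: float = DEFAULT_EVALUE_MAX) -> InsertGroup:
    """Fill old/new areas and their ratio.

    old_area = union of genomic regions homologous to the representative
    (merged across overlaps); new_area = plain sum of member insert lengths
    (inserts are distinct sequences, not genome intervals).
    """
    significant = [h for h in genome_hits if h.evalue <= evalue_max]
    old_area = merged_interval_length(
        (h.subject_id, h.s_interval[0], h.s_interval[1]) for h in significant)
    new_area = sum(insert_lengths[mid] for mid in group.member_ids)
    if old_area == 0:
        return replace(group, old_area_bp=0, new_area_bp=new_area,
                       activity_ratio=None, ratio_infinite=True)
    return replace(group, old_area_bp=old_area, new_area_bp=new_area,
                   activity_ratio=new_area / old_area, ratio_infinite=False)


def group_inserts(inserts: Mapping[str, str], genome: Mapping[str, str],
                  evalue_max: float = DEFAULT_EVALUE_MAX, min_members: int = 5,
                  search: SearchFn = local_homology_search) -> list[InsertGroup]:
    """End-to-end grouping: graph, components, representative, areas, ratio."""
    graph = build_homology_graph(inserts, evalue_max=evalue_max, search=search)
    lengths = {k: len(v) for k, v in inserts.items()}
    groups = []
    for group in connected_component_groups(graph, min_members=min_members):
        rep = select_representative(group.member_ids, lengths)
        genome_hits = search(inserts[rep], genome, evalue_max=evalue_max,
                             query_id=rep)
        group = replace(group, representative_id=rep)
        groups.append(compute_activity_ratio(group, genome_hits, lengths,
                                             evalue_max=evalue_max))
    return groups


# ---------------------------------------------------------------------------
# Global alignment helpers (shared by copy-MSA and genotyping)
# ---------------------------------------------------------------------------

def global_alignment(a: str, b: str) -> tuple[str, str, int]:
    """Edit-distance global alignment of two sequences.

    Returns (gapped_a, gapped_b, edit_distance).  Intended for the
    near-identical regime (element copies, allele models).
    """
    res = edlib.align(a, b, mode="NW", task="path")
    ga, gb = [], []
    i = j = 0
    for length, op in _parse_cigar(res["cigar"]):
        if op in ("=", "X", "M"):
            ga.append(a[i:i + length]); gb.append(b[j:j + length])
            i += length; j += length
        elif op == "I":  # in edlib NW, I consumes the query (a)
            ga.append(a[i:i + length]); gb.append("-" * length)
            i += length
        elif op == "D":
            ga.append("-" * length); gb.append(b[j:j + length])
            j += length
    return "".join(ga), "".join(gb), int(res["editDistance"])


def infix_alignment(read: str, target: str):
    """Best placement of ``read`` inside ``target`` (semi-global).

    Returns (edit_distance, target_start, target_end) with the read tried in
    both orientations; the better orientation wins.
    """
    best = None
    for seq in (read, revcomp(read)):
        res = edlib.align(seq, target, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        cand = (int(res["editDistance"]), int(loc[0]), int(loc[1]) + 1)
        if best is None or cand[0] < best[0]:
            best = cand
    return best


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
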