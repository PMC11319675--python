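"""Biosynthetic gene cluster filtering and domain-composition grouping.

Predicted BGCs (e.g. from SanntiS or antiSMASH, consumed as tables) are
filtered to drop contig-edge predictions and clusters shorter than 3 kb,
then clustered into groups of putatively similar products: pairwise
Sorensen-Dice similarity on protein-domain composition defines a weighted
graph, and Louvain community detection partitions it. Groups containing at
least one member backed by an annotation-grade source (antiSMASH, or MIBiG
when configured) are retained as the final set. Genome x group presence
matrices and per-class count tables feed the comparative regressions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .io import read_table

__all__ = [
    "BGCRecord",
    "BGCError",
    "BGCGroup",
    "read_bgc_table",
    "read_bgc_gff3",
    "read_contig_lengths",
    "filter_bgcs",
    "dice_similarity",
    "build_similarity_graph",
    "louvain_partition",
    "modularity",
    "assign_consensus_class",
    "make_groups",
    "retain_annotated_groups",
    "group_presence_matrix",
    "bgc_count_table",
]

ANNOTATED_SOURCES = frozenset({"antismash", "mibig"})


class BGCError(ValueError):
    pass


@dataclass
class BGCRecord:
    """One predicted cluster (1-based inclusive coordinates, GFF3-style)."""

    bgc_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    predicted_class: str
    domains: FrozenSet[str]
    source: str
    contig_edge: Optional[bool] = None
    product: Optional[str] = None

    def __post_init__(self):
        if self.start < 1:
            raise BGCError(f"{self.bgc_id}: start {self.start} < 1")
        if self.end < self.start:
            raise BGCError(f"{self.bgc_id}: end {self.end} < start {self.start}")
        self.domains = frozenset(self.domains)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class BGCGroup:
    group_id: int
    members: List[str]
    consensus_class: str
    annotated: bool
    genomes: Set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.members)


# -- input -------------------------------------------------------------


def _parse_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    if s in ("", "na", "nan"):
        return None
    raise BGCError(f"cannot interpret boolean value {v!r}")


def read_bgc_table(path) -> List[BGCRecord]:
    """TSV reader: one row per BGC, domains ';'-separated; columns
    bgc_id, genome_id, contig_id, start, end, strand, predicted_class,
    domains, source [, contig_edge, product]."""
    df = read_table(path)
    required = [
        "bgc_id", "genome_id", "contig_id", "start", "end",
        "strand", "predicted_class", "domains", "source",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise BGCError(f"{path}: missing column(s): {', '.join(missing)}")
    records = []
    for d in df.to_dict(orient="records"):
        doms = d["domains"]
        domset = frozenset(
            x for x in (doms.split(";") if isinstance(doms, str) else []) if x
        )
        records.append(
            BGCRecord(
                bgc_id=d["bgc_id"],
                genome_id=d["genome_id"],
                contig_id=d["contig_id"],
                start=int(d["start"]),
                end=int(d["end"]),
                strand=d["strand"],
                predicted_class=d["predicted_class"],
                domains=domset,
                source=d["source"],
                contig_edge=_parse_bool(d.get("contig_edge")),
                product=d.get("product") if isinstance(d.get("product"), str) else None,
            )
        )
    return records


def read_bgc_gff3(path) -> List[BGCRecord]:
    """Minimal GFF3-dialect reader: feature type ``BGC`` with attributes
    ``ID``, ``genome``, ``class``, ``domains`` (comma-separated), ``source``
    and optionally ``contig_edge`` and ``product``."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise BGCError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "BGC":
                continue
            attr = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attr[k.strip()] = v.strip()
            for key in ("ID", "genome", "class", "source"):
                if key not in attr:
                    raise BGCError(f"{path}:{lineno}: missing attribute {key}=")
            records.append(
                BGCRecord(
                    bgc_id=attr["ID"],
                    genome_id=attr["genome"],
                    contig_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    predicted_class=attr["class"],
                    domains=frozenset(x for x in attr.get("domains", "").split(",") if x),
                    source=attr["source"],
                    contig_edge=_parse_bool(attr.get("contig_edge")),
                    product=attr.get("product"),
                )
            )
    return records


def read_contig_lengths(path) -> Dict[str, int]:
    """Two-column TSV (contig_id, length) or .fai-style index (first two
    columns used)."""
    df = read_table(path, header=None)
    if df.shape[1] < 2:
        raise BGCError(f"{path}: need at least 2 columns (contig_id, length)")
    out = {}
    start = 0
    # tolerate a header row
    try:
        int(df.iloc[0, 1])
    except (TypeError, ValueError):
        start = 1
    for _, row in df.iloc[start:].iterrows():
        out[str(row.iloc[0])] = int(row.iloc[1])
    return out


# -- filtering ---------------------------------------------------------


def filter_bgcs(
    records: Sequence[BGCRecord],
    min_length_bp: int = 3000,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> List[BGCRecord]:
    """Drop contig-edge records and records shorter than ``min_length_bp``.

    A record is at a contig edge iff its flag says so, or — when the flag is
    absent — iff start == 1 or end == contig length. Records of exactly
    ``min_length_bp`` are retained (the cut removes strictly shorter ones).
    """
    kept = []
    for r in records:
        edge = r.contig_edge
        if edge is None:
            if contig_lengths is None or r.contig_id not in contig_lengths:
                raise BGCError(
                    f"{r.bgc_id}: no contig_edge flag and no contig length for "
                    f"{r.contig_id}"
                )
            edge = r.start == 1 or r.end == contig_lengths[r.contig_id]
        if not edge and r.length >= min_length_bp:
            kept.append(r)
    return kept


# -- similarity graph and Louvain grouping -----------------------------


def dice_similarity(a: Iterable[str], b: Iterable[str]) -> float:
    """Sorensen-Dice coefficient 2|A n B| / (|A| + |B|) for sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise BGCError("dice_similarity requires non-empty domain sets")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def build_similarity_graph(
    records: Sequence[BGCRecord], edge_threshold: float = 0.5
) -> nx.Graph:
    """Weighted graph over BGC ids; edge iff Dice >= ``edge_threshold``.

    Records with no qualifying edge stay as isolated nodes (they become
    singleton groups). Pairwise similarities are computed through a sparse
    record x domain incidence product, so disjoint domain vocabularies
    never meet.
    """
    if not 0 < edge_threshold <= 1:
        raise BGCError(f"edge_threshold must be in (0, 1], got {edge_threshold}")
    empty = [r.bgc_id for r in records if not r.domains]
    if empty:
        raise BGCError(f"records with empty domain sets: {empty[:5]}")
    g = nx.Graph()
    ids = [r.bgc_id for r in records]
    if len(set(ids)) != len(ids):
        raise BGCError("duplicate bgc_id values")
    g.add_nodes_from(ids)
    if len(records) < 2:
        return g
    vocab: Dict[str, int] = {}
    rows, cols = [], []
    for i, r in enumerate(records):
        for d in sorted(r.domains):
            rows.append(i)
            cols.append(vocab.setdefault(d, len(vocab)))
    A = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.float64), (rows, cols)),
        shape=(len(records), len(vocab)),
    )
    inter = (A @ A.T).tocoo()
    sizes = np.asarray(A.sum(axis=1)).ravel()
    for i, j, n_shared in zip(inter.row, inter.col, inter.data):
        if i >= j:
            continue
        w = 2.0 * n_shared / (sizes[i] + sizes[j])
        if w >= edge_threshold:
            g.add_edge(ids[i], ids[j], weight=w)
    return g


def modularity(
    g: nx.Graph, partition: Sequence[Set[str]], resolution: float = 1.0
) -> float:
    """Weighted Newman modularity Q = sum_c [ in_c/2m - gamma*(tot_c/2m)^2 ],
    computed directly from the formula (independent of the optimizer)."""
    two_m = 2.0 * sum(d.get("weight", 1.0) for _, _, d in g.edges(data=True))
    if two_m == 0:
        return 0.0
    degree = dict(g.degree(weight="weight"))
    q = 0.0
    for comm in partition:
        comm = set(comm)
        within = sum(
            d.get("weight", 1.0)
            for u, v, d in g.edges(comm, data=True)
            if u in comm and v in comm
        )
        tot = sum(degree[u] for u in comm)
        q += (2.0 * within) / two_m - resolution * (tot / two_m) ** 2
    return q


def louvain_partition(
    g: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> Tuple[List[Set[str]], float]:
    """Louvain community detection on the weighted similarity graph.

    Returns the partition (list of node sets, deterministic order: sorted by
    smallest member) and its modularity Q recomputed from the definition.
    An empty graph yields an empty partition.
    """
    if g.number_of_nodes() == 0:
        return [], 0.0
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    comms = [set(c) for c in comms]
    comms.sort(key=lambda c: min(c))
    return comms, modularity(g, comms, resolution=resolution)


def assign_consensus_class(members: Sequence[BGCRecord]) -> str:
    """Majority predicted_class; ties broken lexicographically. Hybrid
    ('+'-joined) labels count as their full label."""
    if not members:
        raise BGCError("empty group")
    counts = Counter(r.predicted_class for r in members)
    top = max(counts.values())
    return sorted(c for c, n in counts.items() if n == top)[0]


def make_groups(
    records: Sequence[BGCRecord],
    partition: Sequence[Set[str]],
    annotated_sources: FrozenSet[str] = ANNOTATED_SOURCES,
) -> List[BGCGroup]:
    """Materialize BGCGroups from a node partition (group ids are assigned
    in partition order, starting at 1)."""
    by_id = {r.bgc_id: r for r in records}
    groups = []
    for gid, comm in enumerate(partition, start=1):
        members = sorted(comm)
        recs = [by_id[m] for m in members]
        groups.append(
            BGCGroup(
                group_id=gid,
                members=members,
                consensus_class=assign_consensus_class(recs),
                annotated=any(r.source in annotated_sources for r in recs),
                genomes={r.genome_id for r in recs},
            )
        )
    return groups


def retain_annotated_groups(groups: Sequence[BGCGroup]) -> Tuple[List[BGCGroup], int]:
    """Keep groups with at least one annotation-grade member; also return
    the number of discarded groups."""
    kept = [g for g in groups if g.annotated]
    return kept, len(groups) - len(kept)


def group_presence_matrix(
    groups: Sequence[BGCGroup], genome_ids: Sequence[str]
) -> pd.DataFrame:
    """Binary genome x group matrix; 1 iff the genome contributes >= 1
    member BGC to the group."""
    known = set(genome_ids)
    tm = pd.DataFrame(
        0, index=list(genome_ids), columns=[f"group_{g.group_id}" for g in groups],
        dtype=np.int8,
    )
    for g in groups:
        stray = g.genomes - known
        if stray:
            raise BGCError(
                f"group {g.group_id}: member genome(s) not in genome list: "
                f"{sorted(stray)[:5]}"
            )
        tm.loc[sorted(g.genomes), f"group_{g.group_id}"] = 1
    return tm


def bgc_count_table(
    records: Sequence[BGCRecord], genome_ids: Sequence[str]
) -> pd.DataFrame:
    """Integer BGC counts per genome: 'total' plus one column per
    predicted_class (0 where absent)."""
    classes = sorted({r.predicted_class for r in records})
    counts = pd.DataFrame(
        0, index=list(genome_ids), columns=["total"] + classes, dtype=np.int64
    )
    for r in records:
        if r.genome_id not in counts.index:
            raise BGCError(f"{r.bgc_id}: genome {r.genome_id} not in genome list")
        counts.loc[r.genome_id, "total"] += 1
        counts.loc[r.genome_id, r.predicted_class] += 1
    return counts
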