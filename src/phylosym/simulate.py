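"""Synthetic study generator.

Emulates the statistical structure of a phylum-scale comparative
phylogenomics input set without any downloads: a Yule tree over genomes,
monophyletic host-associated clades planted on it, per-genome KO
annotations in which named molecular functions are present with a
lifestyle-dependent log-odds, and BGC prediction tables drawn from
domain-set archetypes with lifestyle-dependent prevalence, reduced totals
in host-associated genomes, annotation noise, and decoy records that the
length/contig-edge filter must remove.

Every generated table carries a ground-truth counterpart so that the
estimation modules can be scored on planted effects. Defaults describe a
desk-scale study: 300 tips (a Nostocaceae-like family), 8 host clades, 40
functions, 30 BGC archetypes, a -4 mean shift in host BGC totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import kegg
from .bgc import BGCRecord
from .io import metadata_frame, GenomeRecord, write_results_table
from .tree import FREE_LIVING, PhyloTree, find_host_clades, write_newick

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "plant_host_clades",
    "simulate_ko_table",
    "simulate_bgc_records",
    "simulate_metadata",
    "write_fixture_bundle",
]

HOST_CATEGORIES = (
    "lichen", "bryophyte", "cycad", "Azolla", "diatom",
    "haptophyte", "fruit tree", "macroalgae", "epidermal mat",
    "aquatic macrophyte",
)

BGC_CLASSES = (
    "NRP", "polyketide", "RiPP", "terpene", "alkaloid", "saccharide",
    "other", "NRP+polyketide", "saccharide+terpene",
)


@dataclass
class SimulationConfig:
    n_tips: int = 300
    birth_rate: float = 1.0
    n_host_clades: int = 8
    host_categories: Tuple[str, ...] = HOST_CATEGORIES
    # molecular functions
    n_functions: int = 40
    trait_threshold: float = 0.98
    enriched_function_effect: float = 3.0   # log-odds of host association
    depleted_function_effect: float = -3.0
    phylo_liability: bool = False           # Brownian copula on trait presence
    # BGC archetypes
    n_archetypes: int = 30
    n_unannotated_archetypes: int = 2       # never get antiSMASH backing
    archetype_domain_range: Tuple[int, int] = (5, 30)
    enriched_group_prev: Tuple[float, float] = (0.1, 0.9)  # (free, host)
    count_shift: float = 4.0                # mean reduction of host totals
    domain_dropout: float = 0.05
    domain_gain: float = 0.02
    decoy_short_rate: float = 0.05
    decoy_edge_rate: float = 0.05
    antismash_fraction: float = 0.3
    # metadata
    n_qc_fail: int = 15
    seed: int = 0

    def __post_init__(self):
        for p in (self.domain_dropout, self.domain_gain, self.decoy_short_rate,
                  self.decoy_edge_rate, self.antismash_fraction):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")


# ---------------------------------------------------------------------
# tree and labels
# ---------------------------------------------------------------------


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Yule (pure-birth) tree: exponential waiting times, uniform lineage
    choice, all tips extended to the present (ultrametric). Tips are
    labelled g0001, g0002, ... in tree order."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    birth_time = [0.0, 0.0, 0.0]  # time each node's branch started
    split_time = {0: 0.0}         # time each internal node's branch ended
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = active.pop(int(rng.integers(k)))
        split_time[i] = t
        for _ in range(2):
            parent.append(i)
            birth_time.append(t)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    n_all = len(parent)
    blen = [0.0] * n_all
    for i in range(n_all):
        if parent[i] >= 0:
            blen[i] = split_time.get(i, t_end) - birth_time[i]
    # map to PhyloTree layout: tips first, then internals
    is_tip = [True] * n_all
    for p in parent:
        if p >= 0:
            is_tip[p] = False
    tip_ids = [i for i in range(n_all) if is_tip[i]]
    int_ids = [i for i in range(n_all) if not is_tip[i]]
    remap = {old: new for new, old in enumerate(tip_ids)}
    remap.update({old: len(tip_ids) + j for j, old in enumerate(int_ids)})
    new_parent = [0] * n_all
    new_blen = [0.0] * n_all
    for old in range(n_all):
        new_parent[remap[old]] = remap[parent[old]] if parent[old] >= 0 else -1
        new_blen[remap[old]] = blen[old]
    labels = [f"g{k + 1:04d}" for k in range(len(tip_ids))]
    return PhyloTree(new_parent, new_blen, labels)


def plant_host_clades(
    tree: PhyloTree,
    n_host_clades: int,
    host_categories: Sequence[str] = HOST_CATEGORIES,
    seed: int = 0,
    clade_size_range: Tuple[int, int] = (2, 10),
) -> Dict[str, str]:
    """Select disjoint internal nodes (2-10 tips) and label their tips as
    host-associated, one category per clade (categories assigned
    cyclically); all other tips are free-living. The labelling is
    recoverable by ``find_host_clades``."""
    rng = np.random.default_rng(seed)
    labels = {t: FREE_LIVING for t in tree.tip_labels}
    if n_host_clades == 0:
        return labels
    sets = tree.tip_sets()
    lo, hi = clade_size_range
    candidates = [
        i for i in range(tree.n_nodes)
        if tree.children[i] and i != tree.root and lo <= len(sets[i]) <= hi
    ]
    order = rng.permutation(len(candidates))
    chosen: List[int] = []
    used: set = set()
    for idx in order:
        node = candidates[idx]
        tips = sets[node]
        if tips & used:
            continue
        # a clade nested inside a chosen clade is impossible (disjoint tips),
        # but a superset could merge two planted clades into one pure node;
        # requiring disjointness plus distinct cyclic categories avoids it
        chosen.append(node)
        used |= tips
        if len(chosen) == n_host_clades:
            break
    if len(chosen) < n_host_clades:
        raise ValueError(
            f"tree supports only {len(chosen)} disjoint clades of size "
            f"{lo}-{hi}; requested {n_host_clades}"
        )
    chosen.sort(key=lambda nd: min(sets[nd]))
    for k, node in enumerate(chosen):
        cat = host_categories[k % len(host_categories)]
        for t in sets[node]:
            labels[tree.tip_labels[t]] = cat
    return labels


def simulate_metadata(
    tree: PhyloTree,
    labels: Dict[str, str],
    n_qc_fail: int = 15,
    seed: int = 0,
) -> List[GenomeRecord]:
    """Metadata records: all tree genomes pass QC; ``n_qc_fail`` extra
    off-tree genomes fail it, always including the two exact boundary cases
    (completeness 90.0 and contamination 5.0)."""
    rng = np.random.default_rng(seed)
    records = []
    for t in tree.tip_labels:
        cat = labels[t]
        host = cat != FREE_LIVING
        habitat = cat if host else rng.choice(["freshwater", "marine", "soil"])
        records.append(GenomeRecord(
            genome_id=t,
            completeness=float(np.round(rng.uniform(90.5, 100.0), 2)),
            contamination=float(np.round(rng.uniform(0.0, 4.5), 2)),
            habitat=str(habitat),
            lifestyle="host-associated" if host else FREE_LIVING,
            host_category=cat if host else None,
        ))
    for k in range(n_qc_fail):
        if k == 0:
            comp, cont = 90.0, 1.0     # boundary: excluded under strict >
        elif k == 1:
            comp, cont = 95.0, 5.0     # boundary: excluded under strict <
        elif k % 2 == 0:
            comp, cont = float(np.round(rng.uniform(50, 89.9), 2)), 1.0
        else:
            comp, cont = 95.0, float(np.round(rng.uniform(5.1, 30), 2))
        records.append(GenomeRecord(
            genome_id=f"gfail{k + 1:03d}",
            completeness=comp,
            contamination=cont,
            habitat="freshwater",
            lifestyle=FREE_LIVING,
            host_category=None,
        ))
    return records


# ---------------------------------------------------------------------
# KO annotations with planted lifestyle effects
# ---------------------------------------------------------------------


def _make_definitions(n_functions: int, rng: np.random.Generator):
    """Synthetic multi-step function definitions over a private KO range."""
    defs = []
    ko_counter = 50000
    for f in range(n_functions):
        n_steps = int(rng.integers(3, 6))
        steps = []
        for _ in range(n_steps):
            n_kos = int(rng.integers(1, 4))
            kos = []
            for _ in range(n_kos):
                kos.append(f"K{ko_counter:05d}")
                ko_counter += 1
            expr = "+".join(kos)
            if rng.random() < 0.3:
                alt = f"K{ko_counter:05d}"
                ko_counter += 1
                expr = f"{expr},{alt}"
            steps.append(expr)
        defs.append((f"F{f + 1:03d}", f"synthetic function {f + 1}", " ".join(steps)))
    return defs


def simulate_ko_table(
    tree: PhyloTree,
    labels: Dict[str, str],
    config: SimulationConfig,
    seed: int = 0,
):
    """Per-genome KO sets with planted lifestyle effects.

    Function F001 is enriched in host-associated genomes (log-odds
    ``enriched_function_effect``), F002 depleted; the rest have zero
    lifestyle effect and baseline prevalences drawn in logit [-1, 1].
    Returns (kos_by_genome, definitions, truth trait DataFrame, effects).
    """
    rng = np.random.default_rng(seed)
    defs_rows = _make_definitions(config.n_functions, rng)
    definitions = [
        kegg.parse_function_definition(expr, fid, name)
        for fid, name, expr in defs_rows
    ]
    host = np.array(
        [labels[t] != FREE_LIVING for t in tree.tip_labels], dtype=float
    )
    n = tree.n_tips
    effects = {}
    truth = {}
    kos_by_genome: Dict[str, set] = {t: set() for t in tree.tip_labels}
    for j, d in enumerate(definitions):
        fid = d.function_id
        if j == 0:
            beta0, beta1 = -1.5, config.enriched_function_effect
        elif j == 1:
            beta0, beta1 = 1.5, config.depleted_function_effect
        else:
            beta0, beta1 = float(rng.uniform(-1, 1)), 0.0
        effects[fid] = (beta0, beta1)
        p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * host)))
        if config.phylo_liability:
            # Brownian copula: correlated uniforms, exact marginals p
            from scipy.stats import norm

            draws = rng.standard_normal(tree.n_nodes)
            sd = np.sqrt(tree.branch_length)
            liab = np.zeros(tree.n_nodes)
            for u in tree.preorder:
                pr = tree.parent[u]
                liab[u] = (liab[pr] if pr >= 0 else 0.0) + sd[u] * draws[u]
            tipl = liab[: n]
            scale = np.sqrt(np.maximum(np.diag(tree.vcv()), 1e-12))
            u01 = norm.cdf(tipl / scale)
            present = (u01 < p).astype(np.int8)
        else:
            present = (rng.random(n) < p).astype(np.int8)
        truth[fid] = present
        # translate presence into KO content
        n_steps = d.n_steps
        max_absent = int(np.floor(config.trait_threshold * n_steps))
        max_absent = min(max_absent, n_steps - 1)
        for i, g in enumerate(tree.tip_labels):
            if present[i]:
                kos_by_genome[g] |= d.kos()
            else:
                k = int(rng.integers(0, max_absent + 1))
                if k:
                    step_idx = rng.choice(n_steps, size=k, replace=False)
                    for s in step_idx:
                        kos_by_genome[g] |= d.steps[s].leaves()
    truth_df = pd.DataFrame(truth, index=list(tree.tip_labels))
    return kos_by_genome, definitions, truth_df, effects


# ---------------------------------------------------------------------
# BGC records with planted group structure
# ---------------------------------------------------------------------


@dataclass
class _Archetype:
    index: int
    domains: frozenset
    bgc_class: str
    prev_free: float
    prev_host: float
    annotated: bool


def _make_archetypes(config: SimulationConfig, rng: np.random.Generator):
    """Disjoint domain sets (pairwise Dice 0 before noise), lifestyle-
    dependent prevalences scaled so host totals drop by ``count_shift``
    on average."""
    lo, hi = config.archetype_domain_range
    archetypes = []
    counter = 1
    prev_free = rng.uniform(0.1, 0.5, size=config.n_archetypes)
    for a in range(config.n_archetypes):
        size = int(rng.integers(lo, hi + 1))
        doms = frozenset(f"PF{counter + k:05d}" for k in range(size))
        counter += size
        archetypes.append(_Archetype(
            index=a,
            domains=doms,
            bgc_class=str(rng.choice(BGC_CLASSES)),
            prev_free=float(prev_free[a]),
            prev_host=float(prev_free[a]),
            annotated=a >= config.n_unannotated_archetypes,
        ))
    # planted enriched group: first annotated archetype
    planted = config.n_unannotated_archetypes
    archetypes[planted].prev_free, archetypes[planted].prev_host = (
        config.enriched_group_prev
    )
    gain_from_planted = (
        archetypes[planted].prev_host - archetypes[planted].prev_free
    )
    others = [a for a in archetypes if a.index != planted]
    total_free = sum(a.prev_free for a in others)
    shrink = max(0.0, 1.0 - (config.count_shift + gain_from_planted) / total_free)
    for a in others:
        a.prev_host = a.prev_free * shrink
    noise_pool = [f"PF{90000 + k:05d}" for k in range(500)]
    return archetypes, noise_pool, planted


def simulate_bgc_records(
    tree: PhyloTree,
    labels: Dict[str, str],
    config: SimulationConfig,
    seed: int = 0,
):
    """BGC prediction records plus ground truth.

    Returns (records, truth) where truth maps bgc_id -> archetype index
    (-1 for decoys), plus the planted-enriched archetype index and the
    archetype list, as a dict.
    """
    rng = np.random.default_rng(seed)
    archetypes, noise_pool, planted = _make_archetypes(config, rng)
    records: List[BGCRecord] = []
    truth: Dict[str, int] = {}
    contig_lengths: Dict[str, int] = {}
    for g in tree.tip_labels:
        is_host = labels[g] != FREE_LIVING
        k = 0
        for arch in archetypes:
            prev = arch.prev_host if is_host else arch.prev_free
            if rng.random() >= prev:
                continue
            k += 1
            doms = set(arch.domains)
            if config.domain_dropout > 0:
                doms = {d for d in doms if rng.random() >= config.domain_dropout}
            n_gain = rng.binomial(len(arch.domains), config.domain_gain)
            if n_gain:
                doms |= set(rng.choice(noise_pool, size=n_gain, replace=False))
            if not doms:
                doms = {sorted(arch.domains)[0]}
            length = int(rng.integers(5000, 60001))
            start = 1001
            end = start + length - 1
            contig = f"{g}_c{k}"
            contig_lengths[contig] = end + 1000
            if arch.annotated:
                source = "antismash" if rng.random() < config.antismash_fraction else "sanntis"
            else:
                source = "sanntis"
            bgc_id = f"{g}_bgc{k}"
            records.append(BGCRecord(
                bgc_id=bgc_id, genome_id=g, contig_id=contig,
                start=start, end=end,
                strand="+" if rng.random() < 0.5 else "-",
                predicted_class=arch.bgc_class,
                domains=frozenset(doms), source=source,
            ))
            truth[bgc_id] = arch.index
        # decoys, guaranteed removable by the filter
        if rng.random() < config.decoy_short_rate:
            k += 1
            length = int(rng.integers(500, 3000))  # < 3000 bp
            contig = f"{g}_c{k}"
            contig_lengths[contig] = length + 5000
            bgc_id = f"{g}_bgc{k}"
            records.append(BGCRecord(
                bgc_id=bgc_id, genome_id=g, contig_id=contig,
                start=1001, end=1000 + length, strand="+",
                predicted_class="other",
                domains=frozenset(rng.choice(noise_pool, size=3, replace=False)),
                source="sanntis",
            ))
            truth[bgc_id] = -1
        if rng.random() < config.decoy_edge_rate:
            k += 1
            length = int(rng.integers(5000, 20000))
            contig = f"{g}_c{k}"
            contig_lengths[contig] = length + 8000
            bgc_id = f"{g}_bgc{k}"
            records.append(BGCRecord(
                bgc_id=bgc_id, genome_id=g, contig_id=contig,
                start=1, end=length, strand="+",  # contig edge
                predicted_class="other",
                domains=frozenset(rng.choice(noise_pool, size=3, replace=False)),
                source="sanntis",
            ))
            truth[bgc_id] = -1
    return records, {
        "assignment": truth,
        "planted_enriched": planted,
        "archetypes": archetypes,
        "contig_lengths": contig_lengths,
    }


# ---------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------


def write_fixture_bundle(config: SimulationConfig, outdir) -> Dict[str, Path]:
    """Generate a complete input bundle plus truth tables; byte-identical
    for identical config (the seed drives every stage through fixed
    offsets)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    tree = simulate_tree(config.n_tips, config.birth_rate, seed=seed)
    labels = plant_host_clades(
        tree, config.n_host_clades, config.host_categories, seed=seed + 1
    )
    records = simulate_metadata(tree, labels, config.n_qc_fail, seed=seed + 2)
    kos, definitions, truth_traits, effects = simulate_ko_table(
        tree, labels, config, seed=seed + 3
    )
    bgc_records, bgc_truth = simulate_bgc_records(tree, labels, config, seed=seed + 4)

    paths = {}

    def _p(name):
        paths[name] = outdir / name
        return paths[name]

    write_newick(tree, _p("tree.nwk"))
    write_results_table(metadata_frame(records), _p("metadata.tsv"))

    ko_rows = []
    for g in sorted(kos):
        for i, ko in enumerate(sorted(kos[g]), 1):
            ko_rows.append({"genome_id": g, "gene_id": f"{g}_{i:05d}", "ko": ko})
    write_results_table(pd.DataFrame(ko_rows), _p("ko_annotations.tsv"))

    def_rows = [
        {"function_id": fid, "name": name, "definition": expr}
        for fid, name, expr in _definition_rows(definitions)
    ]
    write_results_table(pd.DataFrame(def_rows), _p("function_definitions.tsv"))

    bgc_rows = [{
        "bgc_id": r.bgc_id, "genome_id": r.genome_id, "contig_id": r.contig_id,
        "start": r.start, "end": r.end, "strand": r.strand,
        "predicted_class": r.predicted_class,
        "domains": ";".join(sorted(r.domains)), "source": r.source,
    } for r in bgc_records]
    write_results_table(pd.DataFrame(bgc_rows), _p("bgc_records.tsv"))

    cl = bgc_truth["contig_lengths"]
    pd.DataFrame(
        {"contig_id": list(cl), "length": list(cl.values())}
    ).to_csv(_p("contig_lengths.tsv"), sep="\t", index=False, header=False)

    tt = truth_traits.copy()
    tt.insert(0, "genome_id", tt.index)
    write_results_table(tt, _p("truth_traits.tsv"))

    tg = pd.DataFrame(
        {"bgc_id": list(bgc_truth["assignment"]),
         "archetype": list(bgc_truth["assignment"].values())}
    )
    write_results_table(tg, _p("truth_groups.tsv"))

    truth_effects = pd.DataFrame(
        [{"function_id": f, "beta0": b0, "beta1": b1} for f, (b0, b1) in effects.items()]
    )
    write_results_table(truth_effects, _p("truth_effects.tsv"))

    cfg = asdict(config)
    cfg["host_categories"] = list(cfg["host_categories"])
    cfg["archetype_domain_range"] = list(cfg["archetype_domain_range"])
    cfg["enriched_group_prev"] = list(cfg["enriched_group_prev"])
    cfg["planted_enriched_archetype"] = bgc_truth["planted_enriched"]
    with open(_p("config.json"), "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _definition_rows(definitions) -> List[Tuple[str, str, str]]:
    """Serialize parsed definitions back to the definition-file grammar."""

    def render(node) -> str:
        from .kegg import _And, _Leaf, _Or

        if isinstance(node, _Leaf):
            return node.ko
        if isinstance(node, _And):
            return "+".join(
                f"({render(p)})" if isinstance(p, _Or) else render(p)
                for p in node.parts
            )
        if isinstance(node, _Or):
            return ",".join(render(p) for p in node.parts)
        raise TypeError(type(node))

    return [
        (d.function_id, d.name, " ".join(render(s) for s in d.steps))
        for d in definitions
    ]
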