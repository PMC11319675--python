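"""End-to-end orchestration: QC -> traits -> BGC grouping -> enrichment -> signal.

The library entry point is :func:`run_pipeline`, which the command-line
interface wraps. Every stochastic stage derives its RNG stream from the
single configured seed, so a rerun with the same inputs and config is
bit-reproducible (the manifest records input checksums for verification).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__, bgc, comparative, io, kegg, signal as signal_mod, tree as tree_mod

log = logging.getLogger("phylosym")

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    tree: str
    metadata: str
    ko_annotations: str
    function_definitions: str
    bgc_records: str
    contig_lengths: Optional[str] = None
    out_dir: str = "results"
    min_completeness: float = 90.0
    max_contamination: float = 5.0
    trait_threshold: float = 0.98
    bgc_min_length: int = 3000
    edge_threshold: float = 0.5
    resolution: float = 1.0
    bootstraps: int = 100
    n_null: int = 1000
    alpha_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.trait_threshold < 1:
            raise ValueError("trait_threshold must be in (0, 1)")
        if not 0 < self.edge_threshold <= 1:
            raise ValueError("edge_threshold must be in (0, 1]")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must be in (0, 1)")
        if self.bootstraps < 1 or self.n_null < 100:
            raise ValueError("bootstraps must be >= 1 and n_null >= 100")


CONFIG_FIELDS = {f for f in RunConfig.__dataclass_fields__}  # noqa: C416


def load_run_config(path, overrides: Optional[Dict] = None) -> RunConfig:
    """Flat key=value config file ('#' comments allowed); CLI overrides win."""
    values: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            k, v = line.split("=", 1)
            k = k.strip()
            if k not in CONFIG_FIELDS:
                raise ValueError(f"{path}:{lineno}: unknown key {k!r}")
            values[k] = v.strip()
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    typed = {}
    for k, v in values.items():
        ftype = RunConfig.__dataclass_fields__[k].type
        if isinstance(v, str) and ("float" in str(ftype)):
            typed[k] = float(v)
        elif isinstance(v, str) and ("int" in str(ftype)):
            typed[k] = int(v)
        else:
            typed[k] = v
    return RunConfig(**typed)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def bundle_config(bundle_dir, **kwargs) -> RunConfig:
    """RunConfig pointing at a fixture bundle directory."""
    b = Path(bundle_dir)
    return RunConfig(
        tree=str(b / "tree.nwk"),
        metadata=str(b / "metadata.tsv"),
        ko_annotations=str(b / "ko_annotations.tsv"),
        function_definitions=str(b / "function_definitions.tsv"),
        bgc_records=str(b / "bgc_records.tsv"),
        contig_lengths=str(b / "contig_lengths.tsv"),
        **kwargs,
    )


def run_pipeline(config: RunConfig, write: bool = True) -> Dict[str, pd.DataFrame]:
    """Execute all stages; returns the result tables keyed by stage name.

    Stages: genome QC; KEGG completeness and trait calling; function
    enrichment (phylogenetic logistic regression vs lifestyle); BGC
    filtering, Dice/Louvain grouping, antiSMASH-backed retention; group
    enrichment (logistic); count enrichment (linear, lambda covariance);
    D-statistic phylogenetic signal for the significant groups.
    """
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, pd.DataFrame] = {}
    summary: List[str] = []
    state = {"stage": "setup"}

    def stage(name):
        state["stage"] = name
        log.info("stage: %s", name)

    try:
        return _run_stages(config, write, out, results, summary, stage)
    except Exception as exc:
        if write and out.exists():
            (out / ".partial").touch()
        raise RuntimeError(f"pipeline failed in stage '{state['stage']}': {exc}") from exc


def _run_stages(config, write, out, results, summary, stage):

    def save(name, df):
        results[name] = df
        if write:
            io.write_results_table(df, out / f"{name}.tsv")

    # -- QC ------------------------------------------------------------
    stage("qc")
    phylo = tree_mod.read_newick(config.tree)
    records = io.read_genome_metadata(config.metadata)
    retained = io.qc_filter_genomes(
        records, config.min_completeness, config.max_contamination
    )
    retained_ids = [r.genome_id for r in retained]
    missing = set(phylo.tip_labels) - set(retained_ids)
    if missing:
        raise ValueError(
            f"tree tips not among QC-passing genomes: {sorted(missing)[:5]}"
        )
    genome_ids = list(phylo.tip_labels)
    by_id = {r.genome_id: r for r in retained}
    lifestyle = pd.Series({g: by_id[g].lifestyle for g in genome_ids})
    summary.append(f"genomes in metadata\t{len(records)}")
    summary.append(f"genomes passing QC\t{len(retained)}")
    summary.append(f"genomes on tree\t{len(genome_ids)}")
    save("qc_metadata", io.metadata_frame(retained))

    # -- KEGG traits ----------------------------------------------------
    stage("traits")
    kos = kegg.read_ko_annotations(config.ko_annotations)
    definitions = kegg.read_function_definitions(config.function_definitions)
    cm = kegg.completeness_matrix(kos, definitions, genome_ids=genome_ids)
    tm = kegg.classify_traits(cm, config.trait_threshold)
    tm_var, dropped = kegg.drop_invariant_traits(tm)
    summary.append(f"functions defined\t{len(definitions)}")
    summary.append(f"functions variably present\t{tm_var.shape[1]}")
    cm_out = cm.copy()
    cm_out.insert(0, "genome_id", cm_out.index)
    save("completeness", cm_out)
    tm_out = tm.copy()
    tm_out.insert(0, "genome_id", tm_out.index)
    save("traits", tm_out)

    # -- function enrichment -------------------------------------------
    stage("enrich-functions")
    fn_enrich = comparative.enrichment_scan(
        tm_var, lifestyle, phylo, alpha_level=config.alpha_level,
        B=config.bootstraps, seed=config.seed,
    )
    save("function_enrichment", fn_enrich)

    # -- BGC grouping ---------------------------------------------------
    stage("bgc-group")
    bgc_records = bgc.read_bgc_table(config.bgc_records)
    contig_lengths = (
        bgc.read_contig_lengths(config.contig_lengths)
        if config.contig_lengths
        else None
    )
    filtered = bgc.filter_bgcs(
        bgc_records, config.bgc_min_length, contig_lengths
    )
    filtered = [r for r in filtered if r.genome_id in set(genome_ids)]
    graph = bgc.build_similarity_graph(filtered, config.edge_threshold)
    partition, q = bgc.louvain_partition(
        graph, resolution=config.resolution, seed=config.seed
    )
    groups = bgc.make_groups(filtered, partition)
    kept_groups, n_discarded = bgc.retain_annotated_groups(groups)
    summary.append(f"BGC records\t{len(bgc_records)}")
    summary.append(f"BGC records after filter\t{len(filtered)}")
    summary.append(f"BGC groups\t{len(groups)}")
    summary.append(f"BGC groups retained (annotated)\t{len(kept_groups)}")
    summary.append(f"louvain modularity\t{q:.6g}")
    save("bgc_groups", pd.DataFrame([
        {
            "group_id": g.group_id,
            "consensus_class": g.consensus_class,
            "annotated": g.annotated,
            "n_members": len(g.members),
            "n_genomes": len(g.genomes),
            "members": ";".join(g.members),
        }
        for g in groups
    ]))

    presence = bgc.group_presence_matrix(kept_groups, genome_ids)
    presence_var, _ = kegg.drop_invariant_traits(presence)
    pres_out = presence.copy()
    pres_out.insert(0, "genome_id", pres_out.index)
    save("group_presence", pres_out)

    stage("enrich-groups")
    grp_enrich = comparative.enrichment_scan(
        presence_var, lifestyle, phylo, alpha_level=config.alpha_level,
        B=config.bootstraps, seed=config.seed + 1,
    )
    save("group_enrichment", grp_enrich)

    # -- count enrichment ----------------------------------------------
    stage("enrich-counts")
    counts = bgc.bgc_count_table(filtered, genome_ids)
    counts_out = counts.copy()
    counts_out.insert(0, "genome_id", counts_out.index)
    save("bgc_counts", counts_out)
    cnt_enrich = comparative.count_enrichment_scan(
        counts, lifestyle, phylo, alpha_level=config.alpha_level,
        B=config.bootstraps, seed=config.seed + 2,
    )
    save("count_enrichment", cnt_enrich)

    # -- phylogenetic signal of significant groups ----------------------
    stage("dstat")
    sig_groups = grp_enrich.loc[
        grp_enrich["significant"].astype(bool), "trait_id"
    ].tolist()
    sig_cols = [c for c in presence_var.columns if str(c) in set(sig_groups)]
    dstat = signal_mod.d_statistic_scan(
        presence_var[sig_cols], phylo, n_null=config.n_null, seed=config.seed + 3
    )
    save("dstat", dstat)

    n_sig_fn = int(fn_enrich["significant"].astype(bool).sum()) if len(fn_enrich) else 0
    n_sig_grp = len(sig_groups)
    summary.append(f"significant functions (p<{config.alpha_level})\t{n_sig_fn}")
    summary.append(f"significant groups (p<{config.alpha_level})\t{n_sig_grp}")

    if write:
        manifest = {
            "version": __version__,
            "config": asdict(config),
            "inputs": {
                k: _sha256(getattr(config, k))
                for k in ("tree", "metadata", "ko_annotations",
                          "function_definitions", "bgc_records")
                if getattr(config, k)
            },
        }
        if config.contig_lengths:
            manifest["inputs"]["contig_lengths"] = _sha256(config.contig_lengths)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "summary.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(summary) + "\n")
    if write and (out / ".partial").exists():
        (out / ".partial").unlink()
    results["summary"] = pd.DataFrame(
        [s.split("\t") for s in summary], columns=["quantity", "value"]
    )
    return results
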