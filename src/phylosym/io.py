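"""Genome metadata, quality-control filtering, and tabular results output.

Metadata tables are tab-separated with a header row and '#' comment lines;
gzip-compressed input is accepted everywhere. A genome record carries the
assembly QC estimates (completeness / contamination, as percentages), the
habitat annotation, the binary lifestyle classification and, for
host-associated genomes, the host category (lichen, bryophyte, cycad, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .tree import FREE_LIVING

__all__ = [
    "GenomeRecord",
    "MetadataError",
    "read_genome_metadata",
    "qc_filter_genomes",
    "write_results_table",
    "read_table",
]

HOST_ASSOCIATED = "host-associated"
REQUIRED_COLUMNS = ("genome_id", "completeness", "contamination", "habitat", "lifestyle")


class MetadataError(ValueError):
    pass


@dataclass
class GenomeRecord:
    """One genome's QC metrics and lifestyle annotation."""

    genome_id: str
    completeness: float
    contamination: float
    habitat: str
    lifestyle: str
    host_category: Optional[str] = None
    extra: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.completeness <= 100:
            raise MetadataError(
                f"{self.genome_id}: completeness {self.completeness} outside [0, 100]"
            )
        if not 0 <= self.contamination <= 100:
            raise MetadataError(
                f"{self.genome_id}: contamination {self.contamination} outside [0, 100]"
            )
        if self.lifestyle not in (FREE_LIVING, HOST_ASSOCIATED):
            raise MetadataError(
                f"{self.genome_id}: lifestyle must be '{FREE_LIVING}' or "
                f"'{HOST_ASSOCIATED}', got {self.lifestyle!r}"
            )
        if self.host_category == "":
            self.host_category = None
        if (self.lifestyle == HOST_ASSOCIATED) != (self.host_category is not None):
            raise MetadataError(
                f"{self.genome_id}: host_category must be set iff lifestyle is "
                f"{HOST_ASSOCIATED}"
            )

    @property
    def is_host_associated(self) -> bool:
        return self.lifestyle == HOST_ASSOCIATED


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a TSV (optionally gzipped), ignoring '#' comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


def read_genome_metadata(path) -> List[GenomeRecord]:
    df = read_table(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing required column(s): {', '.join(missing)}")
    known = set(REQUIRED_COLUMNS) | {"host_category"}
    extra_cols = [c for c in df.columns if c not in known]
    records = []
    for d in df.to_dict(orient="records"):
        host = d.get("host_category")
        if host is not None and pd.isna(host):
            host = None
        records.append(
            GenomeRecord(
                genome_id=d["genome_id"],
                completeness=float(d["completeness"]),
                contamination=float(d["contamination"]),
                habitat=d["habitat"],
                lifestyle=d["lifestyle"],
                host_category=host,
                extra={c: d[c] for c in extra_cols},
            )
        )
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        raise MetadataError(f"{path}: duplicate genome_id values")
    return records


def qc_filter_genomes(
    records: List[GenomeRecord],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> List[GenomeRecord]:
    """Retain genomes with completeness strictly above ``min_completeness``
    and contamination strictly below ``max_contamination`` (defaults: the
    conventional >90% / <5% high-quality cut). Order is preserved; boundary
    values are excluded."""
    return [
        r
        for r in records
        if r.completeness > min_completeness and r.contamination < max_contamination
    ]


def metadata_frame(records: List[GenomeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "genome_id": r.genome_id,
                "completeness": r.completeness,
                "contamination": r.contamination,
                "habitat": r.habitat,
                "lifestyle": r.lifestyle,
                "host_category": "" if r.host_category is None else r.host_category,
                **r.extra,
            }
        )
    return pd.DataFrame(rows)


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a results table as TSV: header always present, deterministic
    column order (as given), floats rendered to 6 significant digits."""
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
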