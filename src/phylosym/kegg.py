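"""KEGG-ortholog trait construction.

A molecular function is defined as an ordered list of reaction *steps*;
each step is a boolean expression over KEGG Orthology identifiers
(``K#####``) with ``,`` meaning OR (alternative orthologs), ``+`` meaning
AND (complex subunits, binding tighter than OR) and parentheses for
grouping. Function completeness for a genome is the fraction of steps whose
expression is satisfied by the genome's KO set, and binary traits are
called at a strict threshold: ``> 0.98`` ("complete" preset) or ``> 0.50``
("indicative" preset).

The module also maps fixed ortholog panels for the two nitrogenase
pathways (iron-molybdenum and vanadium dependent); KOs that are known to
be systematically absent from cyanobacterial genomes (anfG/K00531 in the
Fe-Mo panel, vnfH/K22899 in the V panel) can be marked as such so that
pathway detection does not require them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io import read_table

__all__ = [
    "FunctionDefinition",
    "DefinitionError",
    "parse_function_definition",
    "read_function_definitions",
    "read_ko_annotations",
    "compute_completeness",
    "completeness_matrix",
    "classify_traits",
    "drop_invariant_traits",
    "PathwaySpec",
    "pathway_ortholog_profile",
    "NIF_MO_FE",
    "VNF_V",
]

KO_PATTERN = re.compile(r"K\d{5}")

THRESHOLD_PRESETS = {"complete": 0.98, "indicative": 0.50}


class DefinitionError(ValueError):
    pass


# -- expression grammar ------------------------------------------------
# step  := or
# or    := and (',' and)*
# and   := atom ('+' atom)*
# atom  := KO | '(' or ')'


class _Node:
    __slots__ = ()

    def evaluate(self, kos: Set[str]) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def leaves(self) -> Set[str]:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class _Leaf(_Node):
    ko: str

    def evaluate(self, kos):
        return self.ko in kos

    def leaves(self):
        return {self.ko}


@dataclass(frozen=True)
class _Or(_Node):
    parts: Tuple[_Node, ...]

    def evaluate(self, kos):
        return any(p.evaluate(kos) for p in self.parts)

    def leaves(self):
        return set().union(*(p.leaves() for p in self.parts))


@dataclass(frozen=True)
class _And(_Node):
    parts: Tuple[_Node, ...]

    def evaluate(self, kos):
        return all(p.evaluate(kos) for p in self.parts)

    def leaves(self):
        return set().union(*(p.leaves() for p in self.parts))


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> DefinitionError:
        return DefinitionError(f"{msg} at position {self.pos} in {self.text!r}")

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def parse(self) -> _Node:
        node = self.parse_or()
        if self.pos != len(self.text):
            raise self.error(f"unexpected character {self.peek()!r}")
        return node

    def parse_or(self) -> _Node:
        parts = [self.parse_and()]
        while self.peek() == ",":
            self.pos += 1
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else _Or(tuple(parts))

    def parse_and(self) -> _Node:
        parts = [self.parse_atom()]
        while self.peek() == "+":
            self.pos += 1
            parts.append(self.parse_atom())
        return parts[0] if len(parts) == 1 else _And(tuple(parts))

    def parse_atom(self) -> _Node:
        ch = self.peek()
        if ch == "(":
            self.pos += 1
            node = self.parse_or()
            if self.peek() != ")":
                raise self.error("expected ')'")
            self.pos += 1
            return node
        m = KO_PATTERN.match(self.text, self.pos)
        if not m:
            raise self.error("expected KO identifier (K#####)")
        self.pos = m.end()
        return _Leaf(m.group())


@dataclass(frozen=True)
class FunctionDefinition:
    """A named molecular function as an ordered list of step expressions."""

    function_id: str
    name: str
    steps: Tuple[_Node, ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def kos(self) -> Set[str]:
        return set().union(*(s.leaves() for s in self.steps))


def parse_function_definition(expr: str, function_id: str, name: str) -> FunctionDefinition:
    """Parse a whitespace-separated list of step expressions."""
    tokens = expr.split()
    if not tokens:
        raise DefinitionError(f"{function_id}: definition has no steps")
    steps = tuple(_Parser(tok).parse() for tok in tokens)
    return FunctionDefinition(function_id, name, steps)


def read_function_definitions(path) -> List[FunctionDefinition]:
    """Definition file: TSV with columns function_id, name, definition."""
    df = read_table(path)
    for col in ("function_id", "name", "definition"):
        if col not in df.columns:
            raise DefinitionError(f"{path}: missing column {col}")
    return [
        parse_function_definition(r["definition"], r["function_id"], r["name"])
        for r in df.to_dict(orient="records")
    ]


def builtin_function_definitions() -> List[FunctionDefinition]:
    """The definitions shipped with the package (headline functions)."""
    from importlib import resources

    ref = resources.files("phylosym").joinpath("data/function_definitions.tsv")
    with resources.as_file(ref) as p:
        return read_function_definitions(p)


def read_ko_annotations(path) -> Dict[str, Set[str]]:
    """Read per-genome KO annotations.

    Accepts either a three-column table (genome_id, gene_id, ko) in the
    style of aggregated KofamScan output, or a two-column pre-aggregated
    table (genome_id, ko). Returns genome_id -> set of KO identifiers.
    """
    df = read_table(path)
    if "genome_id" not in df.columns or "ko" not in df.columns:
        raise DefinitionError(f"{path}: expected columns genome_id and ko")
    bad = [k for k in df["ko"].dropna() if not KO_PATTERN.fullmatch(k)]
    if bad:
        raise DefinitionError(f"{path}: malformed KO identifier(s): {bad[:5]}")
    table: Dict[str, Set[str]] = {}
    for g, sub in df.groupby("genome_id", sort=True):
        table[str(g)] = set(sub["ko"].dropna())
    return table


def compute_completeness(defn: FunctionDefinition, kos: Set[str]) -> float:
    """Fraction of the definition's steps satisfied by the KO set."""
    satisfied = sum(1 for s in defn.steps if s.evaluate(kos))
    return satisfied / defn.n_steps


def completeness_matrix(
    kos_by_genome: Dict[str, Set[str]],
    definitions: Sequence[FunctionDefinition],
    genome_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genome x function completeness fractions in [0, 1].

    Genomes absent from the annotation table get all-zero rows (no KOs).
    """
    if genome_ids is None:
        genome_ids = sorted(kos_by_genome)
    data = {
        d.function_id: [
            compute_completeness(d, kos_by_genome.get(g, set())) for g in genome_ids
        ]
        for d in definitions
    }
    return pd.DataFrame(data, index=list(genome_ids))


def classify_traits(cm: pd.DataFrame, threshold: float = 0.98) -> pd.DataFrame:
    """Binary trait matrix: 1 iff completeness strictly > ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return (cm > threshold).astype(np.int8)


def drop_invariant_traits(tm: pd.DataFrame) -> Tuple[pd.DataFrame, List[str]]:
    """Remove trait columns that are constant (all 0 or all 1) across
    genomes; returns the reduced matrix and the removed column ids."""
    if tm.shape[1] == 0:
        return tm, []
    nun = tm.nunique(axis=0)
    removed = [c for c in tm.columns if nun[c] <= 1]
    return tm.drop(columns=removed), removed


# -- nitrogen-fixation pathway panels ---------------------------------


@dataclass(frozen=True)
class PathwaySpec:
    """An ordered ortholog panel; ``known_absent`` marks KOs whose absence
    is systematic in the clade and does not count against detection."""

    pathway_id: str
    required_kos: Tuple[str, ...]
    known_absent: FrozenSet[str] = frozenset()


# Iron-molybdenum dependent nitrogenase: nifH/nifD/nifK structural genes
# plus anfG, which is systematically absent in cyanobacteria.
NIF_MO_FE = PathwaySpec(
    "nif-MoFe",
    ("K02588", "K02586", "K02591", "K00531"),
    known_absent=frozenset({"K00531"}),
)

# Vanadium dependent nitrogenase: vnfD/vnfK/vnfG plus vnfH (systematically
# absent in cyanobacteria).
VNF_V = PathwaySpec(
    "vnf-V",
    ("K22896", "K22897", "K22898", "K22899"),
    known_absent=frozenset({"K22899"}),
)


def pathway_ortholog_profile(
    kos_by_genome: Dict[str, Set[str]],
    pathway: PathwaySpec,
    genome_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-genome presence bits for each KO of the panel plus a ``detected``
    flag: all KOs present except those marked known-absent."""
    if not pathway.required_kos:
        raise ValueError("pathway KO list is empty")
    if genome_ids is None:
        genome_ids = sorted(kos_by_genome)
    required = [k for k in pathway.required_kos if k not in pathway.known_absent]
    rows = []
    for g in genome_ids:
        kos = kos_by_genome.get(g, set())
        bits = {ko: int(ko in kos) for ko in pathway.required_kos}
        bits["detected"] = int(all(ko in kos for ko in required))
        rows.append(bits)
    return pd.DataFrame(rows, index=list(genome_ids))
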