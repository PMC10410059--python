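"""Classify PSEN1 pathogenic variants by affected protein domain.

Carriers are grouped by whether the variant codon falls in a transmembrane (TM)
helix or a cytoplasmic (CY) topological domain of presenilin-1; an alternative
historical grouping splits carriers at codon 200 (pre/post). The packaged
default domain table is transcribed from the UniProt P49768 topology annotation
and ships as a data file so annotation updates need no code change.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError, ValidationError

__all__ = [
    "DomainTable",
    "VariantGroup",
    "default_domain_table",
    "load_domain_table",
    "classify_variant",
    "parse_variant",
    "classify_variants",
]

_VALID_LABELS = frozenset({"TM", "CY", "other"})

#: Codon boundary for the alternative grouping: "before codon 200" means
#: codon < 200; codon 200 itself is post-200. Configurable at call sites.
CODON200_BOUNDARY = 200


@dataclass(frozen=True)
class DomainTable:
    """Inclusive codon intervals labelled TM / CY / other, sorted and disjoint."""

    intervals: tuple[tuple[int, int, str], ...]
    provenance: str = ""

    def __post_init__(self):
        prev_end = 0
        for start, end, label in self.intervals:
            if label not in _VALID_LABELS:
                raise ValidationError(f"unknown domain label {label!r}")
            if start > end:
                raise ValidationError(f"interval ({start},{end}) has start > end")
            if start <= prev_end:
                raise ValidationError(
                    f"intervals overlap or are unsorted at codon {start}"
                )
            prev_end = end

    @classmethod
    def from_rows(cls, rows: Iterable[Sequence], provenance: str = "") -> "DomainTable":
        ordered = sorted(
            ((int(s), int(e), str(lab)) for s, e, lab in rows), key=lambda r: r[0]
        )
        return cls(intervals=tuple(ordered), provenance=provenance)

    def label_of(self, codon: int) -> str | None:
        """Label of the interval containing ``codon``; None outside all intervals."""
        for start, end, label in self.intervals:
            if start <= codon <= end:
                return label
        return None


@dataclass(frozen=True)
class VariantGroup:
    """Domain group (NC / CY / TM / unclassified) plus the codon-200 grouping."""

    group: str
    codon_group: str = "NA"  # pre200 / post200 / NA

    def __post_init__(self):
        if self.group not in {"NC", "CY", "TM", "unclassified"}:
            raise InputError(f"unknown group {self.group!r}")
        if self.group == "NC" and self.codon_group != "NA":
            raise InputError("non-carriers carry no codon grouping")


def load_domain_table(path: str | Path) -> DomainTable:
    """Read a 3-column (start, end, label) tab-delimited domain table.

    Leading ``#`` lines are treated as provenance commentary and preserved.
    """
    path = Path(path)
    provenance_lines = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                provenance_lines.append(line.lstrip("# ").rstrip("\n"))
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"start", "end", "label"} - set(df.columns)
    if missing:
        raise ValidationError(f"domain table {path} lacks columns {sorted(missing)}")
    return DomainTable.from_rows(
        df[["start", "end", "label"]].itertuples(index=False),
        provenance=" ".join(provenance_lines),
    )


def default_domain_table() -> DomainTable:
    """The packaged PSEN1 topology table (UniProt P49768 provenance)."""
    with resources.as_file(
        resources.files("psen1traj.data") / "psen1_domains.tsv"
    ) as p:
        return load_domain_table(p)


def classify_variant(
    codon: int,
    table: DomainTable | None = None,
    codon200_boundary: int = CODON200_BOUNDARY,
) -> VariantGroup:
    """Map a variant codon to its domain group and codon-200 grouping.

    Codons in lumenal/extracellular segments or outside all annotated intervals
    are returned as ``unclassified`` (they are neither TM nor CY).
    """
    codon = int(codon)
    if codon <= 0:
        raise InputError(f"codon must be >= 1, got {codon}")
    if table is None:
        table = default_domain_table()
    label = table.label_of(codon)
    group = label if label in ("TM", "CY") else "unclassified"
    codon_group = "pre200" if codon < codon200_boundary else "post200"
    return VariantGroup(group=group, codon_group=codon_group)


_VARIANT_RE = re.compile(r"^[A-Za-z]{1,3}(\d+)(?:[A-Za-z*]{1,3}|del|ins|dup)?$")


def parse_variant(name: str) -> int | None:
    """Extract the affected codon from a protein-change string such as 'A79V'.

    Unparseable strings yield ``None`` with a warning rather than an error, so a
    single malformed entry does not abort a batch classification.
    """
    m = _VARIANT_RE.match(str(name).strip())
    if m is None:
        warnings.warn(f"could not parse variant name {name!r}; left unclassified")
        return None
    return int(m.group(1))


def classify_variants(
    variants: Iterable[str | int],
    table: DomainTable | None = None,
    codon200_boundary: int = CODON200_BOUNDARY,
) -> pd.DataFrame:
    """Classify a list of codons or protein-change strings into a table."""
    if table is None:
        table = default_domain_table()
    rows = []
    for v in variants:
        if isinstance(v, (int,)) or (isinstance(v, str) and v.strip().isdigit()):
            codon = int(v)
        else:
            codon = parse_variant(v)
        if codon is None:
            rows.append({"variant": v, "codon": pd.NA, "group": "unclassified",
                         "codon_group": "NA"})
            continue
        vg = classify_variant(codon, table, codon200_boundary)
        rows.append({"variant": v, "codon": codon, "group": vg.group,
                     "codon_group": vg.codon_group})
    return pd.DataFrame(rows)
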