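"""Gene-disease annotation with gene-symbol alias expansion.

Joins the gene catalog against a flattened Orphadata-style gene-disease
association table, extending the associations to every gene-symbol alias
listed in an NCBI ``gene_info``-style table ("|"-separated Synonyms
column).  Symbol matching is case-insensitive (both sides uppercased);
an alias claimed by two different canonical symbols is dropped with a
warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation_db import DataError

logger = logging.getLogger(__name__)


@dataclass
class GeneDiseaseTable:
    """Canonical symbol -> disorder ids, plus alias -> canonical map."""

    associations: dict[str, frozenset[str]] = field(default_factory=dict)
    alias_map: dict[str, str] = field(default_factory=dict)

    def canonical(self, symbol: str) -> str:
        s = symbol.upper()
        return self.alias_map.get(s, s)

    def lookup(self, symbol: str) -> frozenset[str]:
        """Disorder ids for a symbol or any of its aliases."""
        return self.associations.get(self.canonical(symbol), frozenset())

    def is_associated(self, symbol: str) -> bool:
        return bool(self.lookup(symbol))


def load_gene_disease(disease_path: str | Path,
                      gene_info_path: str | Path | None = None
                      ) -> GeneDiseaseTable:
    """Load the disease TSV (symbol, disorder_id, disorder_name) and,
    optionally, a gene_info-style alias table (Symbol, Synonyms)."""
    disease = pd.read_csv(disease_path, sep="\t", dtype=str)
    required = {"symbol", "disorder_id"}
    if not required.issubset(disease.columns):
        raise DataError(
            f"{disease_path}: disease table must have columns {sorted(required)}"
        )

    alias_map: dict[str, str] = {}
    if gene_info_path is not None:
        info = pd.read_csv(gene_info_path, sep="\t", dtype=str)
        info.columns = [c.lstrip("#") for c in info.columns]
        if not {"Symbol", "Synonyms"}.issubset(info.columns):
            raise DataError(
                f"{gene_info_path}: gene_info table must have Symbol and Synonyms"
            )
        claimed: dict[str, str] = {}
        dropped: set[str] = set()
        for _, row in info.iterrows():
            canonical = str(row["Symbol"]).upper()
            alias_map[canonical] = canonical
            synonyms = str(row["Synonyms"] or "")
            for alias in synonyms.split("|"):
                alias = alias.strip().upper()
                if not alias or alias == "-" or alias == canonical:
                    continue
                if alias in claimed and claimed[alias] != canonical:
                    dropped.add(alias)
                    continue
                claimed[alias] = canonical
        for alias, canonical in claimed.items():
            if alias in dropped:
                continue
            # a canonical symbol always maps to itself, even if some other
            # gene lists it as a synonym
            if alias in alias_map and alias_map[alias] == alias:
                continue
            alias_map[alias] = canonical
        if dropped:
            warnings.warn(
                f"dropped {len(dropped)} ambiguous alias(es): "
                + ", ".join(sorted(dropped))
            )

    table = GeneDiseaseTable(alias_map=alias_map)
    assoc: dict[str, set[str]] = {}
    for _, row in disease.iterrows():
        canonical = table.canonical(str(row["symbol"]))
        assoc.setdefault(canonical, set()).add(str(row["disorder_id"]))
    table.associations = {k: frozenset(v) for k, v in assoc.items()}
    return table


def annotate_catalog(catalog: pd.DataFrame, table: GeneDiseaseTable,
                     symbol_column: str = "gene_id"
                     ) -> tuple[pd.DataFrame, dict]:
    """Flag catalog rows whose gene (or any alias) hits the disease table.

    Returns the annotated catalog and a summary with the unique flagged
    gene count (each gene counted once) and per-event-type tallies.
    """
    catalog = catalog.copy()
    catalog["disease_associated"] = [
        table.is_associated(sym) for sym in catalog[symbol_column]
    ]
    catalog["disorder_ids"] = [
        ";".join(sorted(table.lookup(sym))) for sym in catalog[symbol_column]
    ]
    flagged = catalog.loc[catalog["disease_associated"], symbol_column]
    canonical_flagged = {table.canonical(s) for s in flagged}
    summary = {
        "unique_flagged_genes": len(canonical_flagged),
        "unique_genes": len({table.canonical(s) for s in catalog[symbol_column]}),
    }
    if "label" in catalog.columns:
        summary["flagged_genes_per_event_type"] = {
            label: int(
                catalog.loc[
                    (catalog["label"] == label) & catalog["disease_associated"],
                    symbol_column,
                ].map(table.canonical).nunique()
            )
            for label in sorted(catalog["label"].unique())
        }
    return catalog, summary
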