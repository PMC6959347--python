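"""Taxon agglomeration and the per-locus / ensemble eDNA index.

The index standardises read evidence so loci with wildly different
amplification biases become comparable: within each locus, a taxon's
within-sample read proportion is divided by that taxon's largest
proportion across samples, giving values in [0, 1] with the maximum at
exactly 1.  Indices from loci that amplify a taxon are averaged into an
ensemble; a locus that never detects a taxon contributes nothing for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IndexTable",
    "agglomerate_taxa",
    "edna_index",
    "ensemble_index",
    "remove_terrestrial",
]

_RANK_ORDER = ("family", "order", "class")


@dataclass
class IndexTable:
    """Taxa x samples matrix of index values in [0, 1].

    ``provenance`` maps each taxon to the loci contributing to its
    (ensemble) values; for a single-locus table it is that locus for
    every detected taxon.  ``zero_rows`` flags taxa with no positive
    proportion anywhere (index 0 by the 0/0 := 0 convention).
    """

    values: pd.DataFrame
    locus: str
    provenance: dict[str, list[str]] = field(default_factory=dict)
    zero_rows: list[str] = field(default_factory=list)


def resolve_taxon_label(row: pd.Series) -> tuple[str, str] | None:
    """Most specific rank at or above Family, or None if unannotated."""
    for rank in _RANK_ORDER:
        label = row.get(rank, "")
        if isinstance(label, str) and label:
            return label, rank
    return None


def agglomerate_taxa(
    counts: pd.DataFrame, taxonomy: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Sum OTU counts into Family-or-higher taxa.

    OTUs sharing a label (Family if annotated, else Order, else Class)
    are summed per sample; unannotated OTUs are dropped and tallied in
    the audit.  Conflicting habitat flags within one taxon are a
    taxonomy error.

    Returns ``(taxon_counts, taxon_table, audit)`` where ``taxon_table``
    carries rank, habitat and trophic level per agglomerated taxon.
    """
    labels: dict[str, tuple[str, str]] = {}
    dropped: list[str] = []
    for otu in counts.index:
        if otu not in taxonomy.index:
            dropped.append(otu)
            continue
        resolved = resolve_taxon_label(taxonomy.loc[otu])
        if resolved is None:
            dropped.append(otu)
        else:
            labels[otu] = resolved

    kept = [otu for otu in counts.index if otu in labels]
    groups: dict[str, list[str]] = {}
    for otu in kept:
        groups.setdefault(labels[otu][0], []).append(otu)

    rows = {}
    meta_rows = []
    for taxon, otus in groups.items():
        rows[taxon] = counts.loc[otus].sum(axis=0)
        habitats = set(taxonomy.loc[otus, "habitat"])
        if len(habitats) > 1:
            raise ValueError(
                f"taxon {taxon!r} mixes habitat flags {sorted(habitats)}: "
                "dirty taxonomy")
        trophic = taxonomy.loc[otus, "trophic_level"]
        meta_rows.append({
            "taxon": taxon,
            "rank": labels[otus[0]][1],
            "habitat": habitats.pop(),
            "trophic_level": int(trophic.mode().iloc[0]),
            "n_otus": len(otus),
        })
    taxon_counts = pd.DataFrame(rows).T
    taxon_counts = taxon_counts[counts.columns] if len(taxon_counts) else taxon_counts
    taxon_table = pd.DataFrame(meta_rows).set_index("taxon") if meta_rows \
        else pd.DataFrame(columns=["rank", "habitat", "trophic_level", "n_otus"])
    audit = {
        "n_otus_in": int(len(counts.index)),
        "n_otus_dropped_unannotated": len(dropped),
        "dropped_otus": dropped,
        "n_taxa_out": int(len(taxon_counts)),
        "reads_in": int(counts.to_numpy().sum()),
        "reads_retained": int(taxon_counts.to_numpy().sum())
        if len(taxon_counts) else 0,
    }
    return taxon_counts, taxon_table, audit


def edna_index(props: pd.DataFrame, locus: str) -> IndexTable:
    """Per-locus index: each row divided by its own maximum (0/0 := 0)."""
    values = props.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("proportions must be nonnegative")
    row_max = values.max(axis=1)
    zero = row_max == 0
    safe = np.where(zero, 1.0, row_max)
    table = pd.DataFrame(values / safe[:, None],
                         index=props.index, columns=props.columns)
    provenance = {t: [locus] for t, z in zip(props.index, zero) if not z}
    return IndexTable(table, locus=locus, provenance=provenance,
                      zero_rows=list(props.index[zero]))


def ensemble_index(tables: list[IndexTable]) -> IndexTable:
    """Mean of per-locus indices over loci that detect each taxon.

    A locus contributes to a taxon iff it detected that taxon at one or
    more samples; its within-locus zeros then still carry information.
    Taxa no locus detects are all-zero.
    """
    if not tables:
        raise ValueError("need at least one per-locus index table")
    ref = tables[0].values
    for t in tables[1:]:
        if not (t.values.index.equals(ref.index)
                and t.values.columns.equals(ref.columns)):
            raise ValueError("per-locus index tables have misaligned axes")

    stack = np.stack([t.values.to_numpy() for t in tables])      # loci x taxa x samples
    detected = np.stack([~t.values.index.isin(t.zero_rows) for t in tables])
    weights = detected[:, :, None].astype(float)
    denom = weights.sum(axis=0)
    safe = np.where(denom == 0, 1.0, denom)
    values = (stack * weights).sum(axis=0) / safe

    provenance = {
        taxon: [t.locus for t, d in zip(tables, detected[:, i]) if d]
        for i, taxon in enumerate(ref.index)
    }
    zero_rows = [taxon for taxon, loci in provenance.items() if not loci]
    out = pd.DataFrame(values, index=ref.index, columns=ref.columns)
    return IndexTable(out, locus="ensemble", provenance=provenance,
                      zero_rows=zero_rows)


def remove_terrestrial(
    table: IndexTable, taxon_table: pd.DataFrame
) -> tuple[IndexTable, list[str]]:
    """Drop rows flagged terrestrial; returns the table and the removals."""
    habitat = taxon_table["habitat"].reindex(table.values.index, fill_value="marine")
    removed = list(table.values.index[habitat == "terrestrial"])
    keep = table.values.index[habitat != "terrestrial"]
    filtered = IndexTable(
        table.values.loc[keep],
        locus=table.locus,
        provenance={t: v for t, v in table.provenance.items() if t in set(keep)},
        zero_rows=[t for t in table.zero_rows if t in set(keep)],
    )
    return filtered, removed
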