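"""Cross-species conservation summaries for alternatively spliced genes.

Joins per-gene AS event counts against a user-supplied ortholog table
(gene id, ortholog id, ortholog AS-event count) and tabulates how many AS
genes have an ortholog, how many of those orthologs are themselves
alternatively spliced, and how many gene/ortholog pairs carry the same
number of AS events.  Event counts are pooled over kinds for the equality
comparison; a per-kind breakdown is emitted alongside.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["conservation_summary"]


def conservation_summary(events_by_kind: dict, ortholog_table: pd.DataFrame) -> dict:
    """Summarize conservation of AS genes against an ortholog table.

    Raises on duplicate (gene, ortholog) rows that disagree on the
    ortholog's AS-event count.  Results are invariant to row order.
    """
    counts: dict[str, dict[str, int]] = {}
    for kind, events in events_by_kind.items():
        for e in events:
            gene_counts = counts.setdefault(e.gene_id, {})
            gene_counts[kind] = gene_counts.get(kind, 0) + 1
    as_genes = set(counts)

    table = ortholog_table.copy()
    dup = table.groupby(["gene_id", "ortholog_id"])["ortholog_as_events"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        offender = conflicts.index[0]
        raise ValueError(
            f"conflicting ortholog AS-event counts for gene {offender[0]} / "
            f"ortholog {offender[1]}"
        )
    table = table.drop_duplicates(subset=["gene_id", "ortholog_id"])

    with_ortholog = set(table["gene_id"]) & as_genes
    as_ortholog_genes = set(
        table.loc[table["ortholog_as_events"] > 0, "gene_id"]
    ) & as_genes

    n_equal = 0
    per_gene_rows = []
    for gene in sorted(as_genes):
        total = sum(counts[gene].values())
        rows = table[table["gene_id"] == gene]
        equal = bool((rows["ortholog_as_events"] == total).any()) if len(rows) else False
        if equal:
            n_equal += 1
        per_gene_rows.append(
            {
                "gene": gene,
                "n_events": total,
                "has_ortholog": gene in with_ortholog,
                "ortholog_is_as": gene in as_ortholog_genes,
                "equal_event_count": equal,
                **{f"n_{kind}": counts[gene].get(kind, 0)
                   for kind in sorted(events_by_kind)},
            }
        )

    return {
        "n_as_genes": len(as_genes),
        "n_with_ortholog": len(with_ortholog),
        "n_with_as_ortholog": len(as_ortholog_genes),
        "n_equal_event_count": n_equal,
        "per_gene": pd.DataFrame(per_gene_rows),
    }
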