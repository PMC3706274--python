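"""GO-slim summarization of consensus differential-expression calls.

Mirrors the structure of a slim-mapper report: one row per GO term listing
the up- and down-regulated genes annotated to it per comparison, an
"Un-identified" bucket for genes with no slim annotation, and summary
totals that count unique genes per direction (a gene annotated to m terms
appears under m rows but is counted once).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .consensus import ConsensusCall
from .io import GOMapping


@dataclass
class GOSummary:
    """Per-comparison GO membership lists.

    ``rows`` maps (go_id, description) -> comparison label -> direction
    ("up"/"down") -> sorted gene list.  ``unidentified`` and ``totals`` are
    keyed by comparison label then direction.
    """

    rows: dict[tuple[str, str], dict[str, dict[str, list[str]]]] = field(default_factory=dict)
    unidentified: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    totals: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def comparisons(self) -> list[str]:
        return list(self.totals)

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: go_id, description, comparison, direction,
        genes (comma-joined)."""
        recs = []
        for (go_id, desc) in sorted(self.rows):
            for comp, by_dir in self.rows[(go_id, desc)].items():
                for direction, genes in by_dir.items():
                    if genes:
                        recs.append((go_id, desc, comp, direction, ",".join(genes)))
        for comp, by_dir in self.unidentified.items():
            for direction, genes in by_dir.items():
                if genes:
                    recs.append(("Un-identified", "", comp, direction, ",".join(genes)))
        return pd.DataFrame(
            recs, columns=["go_id", "description", "comparison", "direction", "genes"]
        )


def summarize_go(
    calls: Sequence[ConsensusCall],
    mapping: GOMapping,
    label: str = "comparison",
) -> GOSummary:
    """Summarize the *selected* calls of one comparison by GO term and
    direction.

    Unselected calls are ignored.  Genes with no mapped term land in the
    unidentified bucket; totals count unique genes per direction regardless
    of how many terms each maps to.
    """
    summary = GOSummary()
    up: set[str] = set()
    down: set[str] = set()
    for call in calls:
        if not call.selected:
            continue
        direction = call.consensus_direction
        (up if direction == "up" else down).add(call.feature_id)
        terms = mapping.terms_of(call.feature_id)
        if not terms:
            bucket = summary.unidentified.setdefault(label, {"up": [], "down": []})
            bucket[direction].append(call.feature_id)
            continue
        for go_id, desc in sorted(terms):
            row = summary.rows.setdefault((go_id, desc), {})
            by_dir = row.setdefault(label, {"up": [], "down": []})
            by_dir[direction].append(call.feature_id)

    for row in summary.rows.values():
        for by_dir in row.values():
            by_dir["up"].sort()
            by_dir["down"].sort()
    for by_dir in summary.unidentified.values():
        by_dir["up"].sort()
        by_dir["down"].sort()
    summary.totals[label] = {"up": len(up), "down": len(down)}
    return summary


def merge_summaries(summaries: Sequence[GOSummary]) -> GOSummary:
    """Combine single-comparison summaries into one multi-column report."""
    merged = GOSummary()
    for s in summaries:
        for key, row in s.rows.items():
            merged.rows.setdefault(key, {}).update(row)
        merged.unidentified.update(s.unidentified)
        merged.totals.update(s.totals)
    return merged
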