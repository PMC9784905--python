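"""Hypergeometric gene-set enrichment of a query list against a GMT collection.

A generic over-representation test: each set is intersected with the
expressed-gene universe, the overlap with the query is scored with the
upper-tail hypergeometric test (log-space), and Benjamini-Hochberg q-values
are computed across the whole collection. No ontology structure is assumed;
any GMT (GO slims, pathway collections, custom classes) works.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, ValidationError
from .quantify import GeneUniverse
from .translatome_sets import hypergeometric_overlap

logger = logging.getLogger("translatome")


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    universe_n: int
    set_in_universe: int
    query_n: int
    overlap_n: int
    log10_p: float
    p_value: float
    q_value: float


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment records sorted by ascending p (ties broken by set name)."""

    records: tuple[EnrichmentRecord, ...]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def enrich(
    query: Iterable[str], universe: GeneUniverse, collection: GeneSetCollection
) -> EnrichmentResult:
    """Test each gene set for over-representation in the query.

    Query genes outside the universe are logged and clipped; sets are
    intersected with the universe before testing and empty intersections are
    skipped. BH correction runs across all tested sets.
    """
    uni = set(universe.genes)
    query_set = set(query)
    outside = query_set - uni
    if outside:
        logger.warning(
            "%d query genes outside the universe were clipped (first: %s)",
            len(outside),
            sorted(outside)[0],
        )
    query_set &= uni
    if not query_set:
        raise ValidationError("query is empty after clipping to the universe")

    rows = []
    for gs in collection:
        members = set(gs.members) & uni
        if not members:
            continue
        overlap = len(members & query_set)
        test = hypergeometric_overlap(len(uni), len(members), len(query_set), overlap)
        rows.append(
            {
                "set_name": gs.name,
                "universe_n": len(uni),
                "set_in_universe": len(members),
                "query_n": len(query_set),
                "overlap_n": overlap,
                "log10_p": test.log10_p,
                "p_value": test.p_value,
            }
        )
    if not rows:
        raise ValidationError("no gene set intersects the universe")

    frame = pd.DataFrame(rows)
    frame["q_value"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    frame = frame.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(
        drop=True
    )
    records = tuple(EnrichmentRecord(**row) for row in frame.to_dict("records"))
    return EnrichmentResult(records=records)
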