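"""End-to-end, in-memory analysis of a mention corpus.

This is the library-level orchestration used by the file-based runner in
:mod:`golink.io`, by the test suite, and by the examples: records in,
counts / p-values / similarities / network / communities / enrichment out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from golink.association import (
    PValueMatrix,
    SimilarityMatrix,
    build_pvalue_matrix,
    cooccurrence_similarity,
    similarity_matrix,
    similarity_percentiles,
)
from golink.corpus import AbstractRecord, CooccurrenceCounts, tally_counts
from golink.network import (
    CommunityPartition,
    GeneNetwork,
    build_network,
    community_enrichment,
    label_propagation,
)

__all__ = ["PipelineResult", "analyze_records"]


@dataclass
class PipelineResult:
    """Every artifact produced by one pipeline run."""

    counts: CooccurrenceCounts
    pvalues: PValueMatrix
    similarity: SimilarityMatrix
    cooccurrence: SimilarityMatrix
    network: GeneNetwork
    partition: CommunityPartition
    enrichment: pd.DataFrame
    cutoff: float
    cutoff_quantile: float | None


def analyze_records(
    records: Iterable[AbstractRecord],
    *,
    cutoff: float | None = None,
    cutoff_quantile: float | None = 0.99,
    floor: float = 1e-6,
    log_base: float | None = None,
    percentile_method: str = "linear",
    seed: int = 0,
    max_iter: int = 100,
    enrich_gos: Sequence[str] | None = None,
) -> PipelineResult:
    """Run the full association pipeline over mention records.

    Either an absolute similarity ``cutoff`` or a ``cutoff_quantile`` of the
    corpus's own pair-similarity distribution must be given (quantile 0.99,
    the "high confidence" preset, by default).  The seed controls community
    detection only; everything upstream is deterministic.
    """
    if cutoff is not None and not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    counts = tally_counts(records)
    pmat = build_pvalue_matrix(counts)
    sim = similarity_matrix(pmat, floor=floor, log_base=log_base)
    quantile_used: float | None = None
    if cutoff is None:
        if cutoff_quantile is None:
            raise ValueError("either cutoff or cutoff_quantile must be given")
        pairs = sim.pair_values()
        if pairs.size:
            cutoff = similarity_percentiles(
                pairs, [cutoff_quantile], method=percentile_method
            )[0]
        else:
            cutoff = 1.0
        quantile_used = cutoff_quantile
    net = build_network(sim, min(cutoff, 1.0))
    part = label_propagation(net, seed=seed, max_iter=max_iter)
    enr = community_enrichment(pmat, part, list(enrich_gos) if enrich_gos else None)
    return PipelineResult(
        counts=counts,
        pvalues=pmat,
        similarity=sim,
        cooccurrence=cooccurrence_similarity(counts),
        network=net,
        partition=part,
        enrichment=enr,
        cutoff=float(min(cutoff, 1.0)),
        cutoff_quantile=quantile_used,
    )
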