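"""Cohort-level EVE conservation profiling.

Given per-sample depth tables, builds an EVE x sample presence matrix
(fraction of each element's bases covered at or above a depth threshold),
summarises how widely the core EVE set is carried across samples, scores
between-sample heterogeneity, and optionally embeds the coverage profiles
in 2-D to visualise clustering by integration event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .io import DepthTable, EveRecord

__all__ = [
    "QcReport",
    "sample_qc",
    "presence_matrix",
    "core_conservation",
    "heterogeneity_score",
    "embed_coverage",
]


@dataclass(frozen=True)
class QcReport:
    sample_id: str
    organelle_breadth: float
    passed: bool


def sample_qc(depths: Mapping[str, DepthTable] | Sequence[DepthTable],
              organelle_contig: str,
              min_breadth: float = 0.90,
              organelle_length: int | None = None) -> list[QcReport]:
    """Screen samples by breadth of >=1x coverage of the organellar genome.

    Libraries with incomplete mitochondrial coverage indicate poor
    sequencing or alignment quality and are excluded before presence
    calling. ``organelle_length`` defaults to the largest observed
    position on the contig across samples.
    """
    tables = list(depths.values()) if isinstance(depths, Mapping) else list(depths)
    if not any(organelle_contig in t.contigs for t in tables):
        raise ValueError(f"organelle contig {organelle_contig!r} absent from all depth tables")
    if organelle_length is None:
        organelle_length = max(
            int(t.contigs[organelle_contig][0][-1])
            for t in tables
            if organelle_contig in t.contigs and t.contigs[organelle_contig][0].size
        )
    reports = []
    for t in tables:
        breadth = t.breadth(organelle_contig, 1, organelle_length, min_depth=1)
        reports.append(QcReport(sample_id=t.sample_id, organelle_breadth=breadth,
                                passed=breadth >= min_breadth))
    return reports


def presence_matrix(depths: Mapping[str, DepthTable] | Sequence[DepthTable],
                    eves: Sequence[EveRecord],
                    depth_threshold: int = 5) -> pd.DataFrame:
    """EVE x sample matrix of coverage breadth at ``depth_threshold``.

    Cell = bases of the element covered >= threshold, divided by element
    length (clipped to 1.0; the inclusive footprint is one base longer
    than the difference-convention length). Samples should already have
    passed QC. An element on a contig absent from a sample's table gets
    0 with a warning.
    """
    tables = list(depths.values()) if isinstance(depths, Mapping) else list(depths)
    samples = [t.sample_id for t in tables]
    data = np.zeros((len(eves), len(tables)))
    for j, t in enumerate(tables):
        for i, eve in enumerate(eves):
            if eve.chrom not in t.contigs:
                warnings.warn(f"{eve.identifier}: contig {eve.chrom!r} absent from "
                              f"sample {t.sample_id}; breadth set to 0", stacklevel=2)
                continue
            span_breadth = t.breadth(eve.chrom, eve.h_lo, eve.h_hi, min_depth=depth_threshold)
            covered = span_breadth * (eve.h_hi - eve.h_lo + 1)
            data[i, j] = min(covered / max(eve.length, 1), 1.0)
    return pd.DataFrame(data, index=[e.identifier for e in eves], columns=samples)


def core_conservation(matrix: pd.DataFrame, presence_breadth: float = 0.99) -> dict:
    """Exact counts of full-complement carriage and per-EVE absence.

    Returns the fraction of samples carrying every element at
    >= ``presence_breadth`` breadth, the fraction missing all elements,
    and per-element missing-sample counts.
    """
    if matrix.empty:
        raise ValueError("empty presence matrix")
    present = matrix >= presence_breadth
    n_samples = present.shape[1]
    all_present = int(present.all(axis=0).sum())
    none_present = int((~present).all(axis=0).sum())
    missing_counts = (~present).sum(axis=1)
    return {
        "n_samples": n_samples,
        "n_all_present": all_present,
        "fraction_all_present": all_present / n_samples,
        "n_none_present": none_present,
        "fraction_none_present": none_present / n_samples,
        "missing_per_eve": missing_counts,
    }


def heterogeneity_score(matrix: pd.DataFrame, presence_breadth: float = 0.99) -> float:
    """Mean pairwise Jaccard distance between sample presence vectors.

    0 when all samples carry identical element sets; approaches 1 for
    disjoint sets. Invariant under sample permutation.
    """
    if matrix.shape[1] < 2:
        raise ValueError("heterogeneity requires >= 2 samples")
    present = (matrix >= presence_breadth).to_numpy().T.astype(bool)
    return float(np.mean(pdist(present, metric="jaccard")))


def embed_coverage(matrix: pd.DataFrame, seed: int = 0, perplexity: float = 5.0,
                   labels: Sequence | None = None,
                   n_iter: int = 1000) -> tuple[pd.DataFrame, float | None]:
    """2-D t-SNE embedding of coverage profiles (one point per matrix row).

    Pass the matrix transposed to embed samples instead. Deterministic for
    a fixed seed. When per-row ``labels`` (e.g. integration-event ids) are
    given, the silhouette score of those labels in the embedding is
    returned alongside — a number for how strongly rows cluster by label.
    """
    n = matrix.shape[0]
    if n < 4:
        raise ValueError("embedding requires >= 4 rows")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < number of rows ({n})")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                max_iter=n_iter, init="pca")
    coords = tsne.fit_transform(matrix.to_numpy())
    out = pd.DataFrame(coords, index=matrix.index, columns=["x", "y"])
    score = None
    if labels is not None:
        labels = np.asarray(labels)
        if len(set(labels.tolist())) > 1:
            score = float(silhouette_score(coords, labels))
    return out, score
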