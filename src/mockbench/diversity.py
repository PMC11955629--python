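"""Alpha and beta diversity at a chosen taxonomic rank.

Alpha measures: observed richness (taxa with nonzero abundance), Shannon
entropy −Σ p ln p (natural log by default) and the Gini–Simpson index
1 − Σ p², both on within-sample proportions.  Beta measures: Bray–Curtis
dissimilarity Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) and Jaccard distance on presence/absence,
1 − |A∩B| / |A∪B|.  Distances are returned as a scikit-bio
:class:`~skbio.stats.distance.DistanceMatrix` keyed by sample id.

Taxa with no label at the analysis rank are pooled into an ``unassigned``
bin which is excluded from every measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .profiles import AbundanceTable, Lineage, format_lineage

__all__ = ["DiversityResult", "alpha_diversity", "beta_diversity", "METRICS"]

METRICS = ("bray_curtis", "jaccard")

_UNASSIGNED = format_lineage(Lineage())


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    observed: int
    shannon: float
    simpson: float


def _rank_matrix(table: AbundanceTable, rank: str | None) -> np.ndarray:
    work = table if rank is None else table.collapse_to_rank(rank)
    keep = [t for t in work.taxa if t != _UNASSIGNED]
    return work.data.loc[keep].to_numpy(dtype=float)


def alpha_diversity(table: AbundanceTable, rank: str | None = "species",
                    log_base: float | None = None) -> list[DiversityResult]:
    """Per-sample observed richness, Shannon and Gini–Simpson indices.

    ``log_base`` switches Shannon's logarithm (default: natural log).
    Works on counts or relative tables — every measure here depends only
    on within-sample proportions.
    """
    mat = _rank_matrix(table, rank)
    results = []
    for j, sample_id in enumerate(table.sample_ids):
        col = mat[:, j]
        total = col.sum()
        if total <= 0:
            raise ValueError(f"sample {sample_id!r} is empty at this rank")
        p = col[col > 0] / total
        shannon = float(-(p * np.log(p)).sum())
        if log_base is not None:
            shannon /= float(np.log(log_base))
        results.append(DiversityResult(
            sample_id=sample_id, observed=int((col > 0).sum()),
            shannon=shannon, simpson=float(1.0 - (p ** 2).sum())))
    return results


def beta_diversity(table: AbundanceTable, metric: str = "bray_curtis",
                   rank: str | None = "species") -> DistanceMatrix:
    """Pairwise sample dissimilarities under Bray–Curtis or Jaccard."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; supported: {METRICS}")
    if len(table.sample_ids) < 2:
        raise ValueError("beta diversity needs at least 2 samples")
    mat = _rank_matrix(table, rank).T  # samples x taxa
    if metric == "bray_curtis":
        condensed = pdist(mat, metric="braycurtis")
    else:
        condensed = pdist(mat > 0, metric="jaccard")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)
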