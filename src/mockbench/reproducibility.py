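"""Paired-sample statistics for technical replicates and stool/swab pairs.

Two questions drive this module.  First, do paired samples (technical
replicates run on the same or different sequencing plates, or stool/rectal
swab pairs from the same infant) differ systematically in alpha diversity?
That is answered with a two-sided paired Wilcoxon signed-rank test plus a
95% Hodges–Lehmann confidence interval for the paired difference.  Second,
how reproducible is the *whole* community profile between pair members?
That is summarised by a distance-based intraclass correlation coefficient
(dICC) computed on a beta-diversity distance matrix.

The dICC estimator is method-of-moments on squared distances:

    MS_within = mean over pairs of d(a, b)^2
    MS_total  = mean of d(i, j)^2 over all sample pairs whose members
                belong to *different* pairs
    dICC      = 1 - MS_within / MS_total

For Euclidean distances on univariate data this reduces to the classical
one-way ICC: with subject variance sb^2 and replicate noise sw^2, the
expected within term is 2*sw^2 and the expected cross-subject term is
2*(sb^2 + sw^2), giving dICC -> sb^2 / (sb^2 + sw^2).  It is 1 when every
pair is duplicated exactly and ~0 when pairing labels carry no information.
Sampling noise can push the estimate slightly negative; values are
reported unclipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from skbio.stats.distance import DistanceMatrix

from .profiles import SampleMetadata

__all__ = [
    "PairedDesign", "WilcoxonResult", "DICCResult",
    "design_from_metadata", "paired_wilcoxon", "dicc", "interpret_dicc",
]


@dataclass(frozen=True)
class PairedDesign:
    """A set of disjoint sample pairs with a scope label."""

    pairs: tuple[tuple[str, str, str], ...]  # (sample_a, sample_b, pair_id)
    scope: str = "within_run"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, b, pid in self.pairs:
            for s in (a, b):
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in more than one pair")
                seen.add(s)
        pids = [pid for _, _, pid in self.pairs]
        if len(set(pids)) != len(pids):
            raise ValueError("duplicate pair ids")

    @property
    def sample_ids(self) -> list[str]:
        return [s for a, b, _ in self.pairs for s in (a, b)]

    def __len__(self) -> int:
        return len(self.pairs)


def design_from_metadata(meta: Sequence[SampleMetadata],
                         scope: str) -> PairedDesign:
    """Collect replicate pairs of the given scope from sample metadata."""
    groups: dict[str, list[SampleMetadata]] = {}
    for m in meta:
        if m.replicate_pair_id is not None and m.control_role != "negative":
            if scope in (m.replicate_scope, "any"):
                groups.setdefault(m.replicate_pair_id, []).append(m)
    pairs = []
    for pid in sorted(groups):
        members = groups[pid]
        if len(members) != 2:
            raise ValueError(f"pair {pid!r} has {len(members)} members, expected 2")
        a, b = sorted(m.sample_id for m in members)
        pairs.append((a, b, pid))
    return PairedDesign(pairs=tuple(pairs), scope=scope)


@dataclass(frozen=True)
class WilcoxonResult:
    n_pairs: int
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    estimate: float  # Hodges-Lehmann pseudo-median of the paired difference
    degenerate: bool = False


def _signed_rank_cdf_counts(n: int) -> np.ndarray:
    """Exact null distribution of the signed-rank sum W+ for sample size n.

    Returns subset counts over achievable sums 0..n(n+1)/2 (dynamic
    programming over rank inclusion; 2^n total mass).
    """
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return counts


def _hl_interval(diffs: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """Hodges–Lehmann estimate and CI from Walsh averages.

    The CI endpoints are order statistics of the n(n+1)/2 Walsh averages
    (d_i + d_j)/2, i <= j, at depths from the signed-rank null
    distribution (exact for n <= 60, normal approximation beyond).
    """
    n = len(diffs)
    walsh = []
    for i in range(n):
        for j in range(i, n):
            walsh.append(0.5 * (diffs[i] + diffs[j]))
    walsh = np.sort(np.asarray(walsh))
    m = len(walsh)
    estimate = float(np.median(walsh))
    if n <= 60:
        counts = _signed_rank_cdf_counts(n)
        cdf = np.cumsum(counts) / counts.sum()
        # largest k with P(W+ <= k) <= alpha/2
        ks = np.nonzero(cdf <= alpha / 2)[0]
        k = int(ks[-1]) if len(ks) else -1
    else:
        mean = n * (n + 1) / 4
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        k = int(np.floor(mean - stats.norm.ppf(1 - alpha / 2) * sd - 0.5))
        k = max(k, -1)
    # CI = [W_(qu), W_(m-qu+1)] in 1-based order statistics, qu = k+1 (>= 1)
    qu = max(k + 1, 1)
    lo = float(walsh[min(qu - 1, m - 1)])
    hi = float(walsh[max(m - qu, 0)])
    return estimate, lo, hi


def paired_wilcoxon(values_a: Sequence[float], values_b: Sequence[float],
                    alpha: float = 0.05) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test with a 95% HL interval.

    Differences are ``a - b``.  Zero differences are dropped from the test
    (Wilcoxon's original treatment); the exact null distribution is used
    for n <= 25 without ties, otherwise a normal approximation with
    continuity correction.  If every difference is zero the result is
    degenerate: p = 1 and a collapsed interval at 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("values_a and values_b must be equal-length 1-D sequences")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return WilcoxonResult(n_pairs=len(d), statistic=0.0, p_value=1.0,
                              ci_low=0.0, ci_high=0.0, estimate=0.0,
                              degenerate=True)
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    estimate, lo, hi = _hl_interval(d, alpha=alpha)
    return WilcoxonResult(n_pairs=len(d), statistic=float(res.statistic),
                          p_value=float(res.pvalue), ci_low=lo, ci_high=hi,
                          estimate=estimate)


@dataclass(frozen=True)
class DICCResult:
    dicc: float
    n_pairs: int
    mean_sq_within: float
    mean_sq_total: float

    @property
    def label(self) -> str:
        return interpret_dicc(self)


def dicc(dist: DistanceMatrix, design: PairedDesign) -> DICCResult:
    """Distance-based intraclass correlation for a paired design."""
    if len(design) < 2:
        raise ValueError("dICC needs at least 2 pairs (cross-pair term undefined)")
    missing = [s for s in design.sample_ids if s not in dist.ids]
    if missing:
        raise KeyError(f"paired samples missing from distance matrix: {missing}")
    idx = {s: i for i, s in enumerate(dist.ids)}
    d2 = np.asarray(dist.data, dtype=float) ** 2

    within = [d2[idx[a], idx[b]] for a, b, _ in design.pairs]
    mean_within = float(np.mean(within))

    members = [(idx[a], idx[b]) for a, b, _ in design.pairs]
    cross = []
    for p in range(len(members)):
        for q in range(p + 1, len(members)):
            for i in members[p]:
                for j in members[q]:
                    cross.append(d2[i, j])
    mean_total = float(np.mean(cross))
    if mean_total <= 0:
        raise ValueError("all cross-pair distances are zero; dICC undefined")
    return DICCResult(dicc=1.0 - mean_within / mean_total, n_pairs=len(design),
                      mean_sq_within=mean_within, mean_sq_total=mean_total)


def interpret_dicc(result: DICCResult | float) -> str:
    """Qualitative reproducibility band: poor < 0.5 <= moderate < 0.75 <= good."""
    value = result.dicc if isinstance(result, DICCResult) else float(result)
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    return "good"
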