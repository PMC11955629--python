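"""Plate-wise contaminant filtering and median library-size normalization.

Contaminant calling scores each taxon on one plate against that plate's own
negative controls.  Two evidence channels are combined:

* **prevalence** — a one-sided Fisher exact test on the 2x2 table of
  presence/absence versus negative/real sample, with the alternative that
  the taxon is enriched in negatives.  Small p ⇒ likely contaminant.
* **frequency** — when per-sample DNA concentrations are available, a
  one-sided Spearman rank test of the taxon's relative frequency against
  inverse concentration across real samples.  Reagent contaminants enter at
  a roughly fixed absolute level, so their relative share rises as input
  DNA falls.

Each channel yields a p-like score in [0, 1]; when both exist they are
combined with Fisher's method.  A taxon is flagged when its combined score
falls below the threshold (default 0.1).  Filtering is row deletion only:
surviving taxa keep their raw values, and conversion to relative abundance
is a separate explicit step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import AbundanceTable, Lineage, SampleMetadata

__all__ = ["DecontamResult", "decontaminate", "normalize_median_library"]


@dataclass(frozen=True)
class DecontamResult:
    taxon: str
    prevalence_score: float
    frequency_score: float | None
    combined_score: float
    is_contaminant: bool


def _fisher_combine(pvals: Sequence[float]) -> float:
    ps = np.clip(np.asarray(pvals, dtype=float), 1e-300, 1.0)
    statistic = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(statistic, 2 * len(ps)))


def decontaminate(
    table: AbundanceTable,
    meta: Sequence[SampleMetadata],
    threshold: float = 0.1,
    plate: str | None = None,
    frequency_threshold: float | None = None,
    presence_floor: float = 0.0,
    use_frequency: bool = True,
) -> tuple[AbundanceTable, list[DecontamResult]]:
    """Flag and remove contaminant taxa on one plate using its negatives.

    Only samples on ``plate`` are considered (all samples when ``plate`` is
    None and the metadata spans a single plate).  Raises if the plate has
    no negative control or no real sample: decontamination is refused, not
    silently skipped.

    ``presence_floor``: counts strictly above this value define presence
    (default 0, i.e. any nonzero count).  ``use_frequency=False`` forces
    prevalence-only scoring even when DNA concentrations are available.

    Returns the filtered table (all samples, contaminant rows deleted) and
    the per-taxon score records for the plate.
    """
    if table.mode != "counts":
        raise ValueError("decontaminate expects a counts table")
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    if plate is None:
        plates = {by_id[s].plate for s in table.sample_ids}
        if len(plates) > 1:
            raise ValueError(
                f"table spans plates {sorted(plates)}; pass plate= explicitly")
        plate = plates.pop()
    on_plate = [s for s in table.sample_ids if by_id[s].plate == plate]
    neg = [s for s in on_plate if by_id[s].control_role == "negative"]
    real = [s for s in on_plate if by_id[s].control_role != "negative"]
    if not neg:
        raise ValueError(f"plate {plate!r} has no negative controls; "
                         "decontamination refused")
    if not real:
        raise ValueError(f"plate {plate!r} has no non-negative samples")

    neg_mat = table.data[neg]
    real_mat = table.data[real]
    n_neg, n_real = len(neg), len(real)

    concentrations = np.array(
        [by_id[s].dna_concentration or np.nan for s in real], dtype=float)
    have_conc = use_frequency and np.isfinite(concentrations).sum() >= 3
    real_totals = real_mat.sum(axis=0).to_numpy()

    results: list[DecontamResult] = []
    for taxon in table.taxa:
        present_neg = int((neg_mat.loc[taxon] > presence_floor).sum())
        present_real = int((real_mat.loc[taxon] > presence_floor).sum())
        # one-sided Fisher: enrichment of presence among negatives
        _, prev_p = stats.fisher_exact(
            [[present_neg, n_neg - present_neg],
             [present_real, n_real - present_real]],
            alternative="greater")
        prev_p = float(prev_p)

        freq_p: float | None = None
        if have_conc:
            ok = np.isfinite(concentrations)
            rel = real_mat.loc[taxon].to_numpy()[ok] / real_totals[ok]
            if (rel > 0).sum() >= 3 and np.ptp(rel) > 0:
                rho, p_two = stats.spearmanr(rel, 1.0 / concentrations[ok])
                if np.isfinite(rho):
                    # one-sided: contaminant share rises with inverse input DNA
                    freq_p = float(p_two / 2.0 if rho > 0 else 1.0 - p_two / 2.0)
            if freq_p is None:
                freq_p = 1.0  # too sparse to show the contaminant signature

        if freq_p is None:
            combined = prev_p
            cut = threshold
        else:
            combined = _fisher_combine([prev_p, freq_p])
            cut = frequency_threshold if frequency_threshold is not None else threshold
        results.append(DecontamResult(
            taxon=taxon, prevalence_score=prev_p, frequency_score=freq_p,
            combined_score=combined, is_contaminant=bool(combined < cut)))

    flagged = [r.taxon for r in results if r.is_contaminant]
    return table.drop_taxa(flagged), results


def normalize_median_library(table: AbundanceTable) -> AbundanceTable:
    """Rescale every sample so its library total equals the median total.

    Values may become fractional; the mode stays ``counts`` (rescaled
    counts).  Within-sample proportions are preserved exactly.
    """
    if table.mode != "counts":
        raise ValueError("normalize_median_library expects a counts table")
    totals = table.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    median = float(np.median(totals.to_numpy()))
    scaled = table.data.mul(median / totals, axis=1)
    return AbundanceTable(scaled, mode="counts", lineages=dict(table.lineages))
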