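"""Scoring of observed mock-community profiles against the expected composition.

A mock (positive) control contains a known set of species at known
theoretical percentages — here typically the 8-species ZymoBIOMICS
microbial community standard.  Given an observed species-level profile,
this module computes:

* confusion counts — true positives (expected species detected at species
  rank), false negatives (expected species missed), false positives
  (species-rank taxa not in the reference);
* precision = TP/(TP+FP), sensitivity = TP/(TP+FN), and their harmonic
  mean, the F-score;
* observed/expected (O/E) abundance ratios per species, with the median
  and range across controls (non-detections contribute ratio 0);
* the percent of the profile correctly classified as an expected species;
* genus rescues — expected species missed at species rank whose genus is
  nonetheless present at genus rank.  These are reported but never counted
  as true positives: scoring is strictly species-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import AbundanceTable

__all__ = [
    "MockReference", "ConfusionCounts", "PerformanceScores", "OERatioRecord",
    "MockControlReport", "load_zymo8", "match_species", "confusion",
    "performance", "oe_ratios", "percent_correct", "evaluate_control",
    "aggregate_controls", "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed reports use."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


#: Label synonymy between classifier output and supplier species names.
DEFAULT_ALIASES: dict[str, str] = {
    "Escherichia coli": "Escherichia/Shigella coli",
    "Shigella coli": "Escherichia/Shigella coli",
    "Lactobacillus fermentum": "Limosilactobacillus fermentum",
}


@dataclass(frozen=True)
class MockReference:
    """Expected species with theoretical percentages, plus name aliases."""

    entries: tuple[tuple[str, float], ...]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [s for s, _ in self.entries]
        resolved = {self.resolve(lb) for lb in labels}
        if len(resolved) != len(labels):
            raise ValueError("species labels not unique after alias resolution")
        total = sum(p for _, p in self.entries)
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"theoretical percentages sum to {total}, expected 100")
        if any(p <= 0 for _, p in self.entries):
            raise ValueError("theoretical percentages must be positive")

    @property
    def species(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def theoretical_percent(self) -> dict[str, float]:
        return dict(self.entries)

    def resolve(self, label: str) -> str:
        return self.aliases.get(label, label)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 aliases: Mapping[str, str] | None = None) -> "MockReference":
        df = pd.read_csv(path, sep="\t", dtype={"species": str})
        entries = tuple(
            (str(r["species"]), float(r["theoretical_percent"])) for _, r in df.iterrows())
        return cls(entries=entries,
                   aliases=dict(DEFAULT_ALIASES if aliases is None else aliases))


def load_zymo8() -> MockReference:
    """The 8-species ZymoBIOMICS community standard shipped as a fixture."""
    path = resources.files("mockbench.data").joinpath("zymo8.tsv")
    with resources.as_file(path) as p:
        return MockReference.from_tsv(p)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class PerformanceScores:
    precision: float
    sensitivity: float
    f_score: float
    precision_undefined: bool = False


@dataclass(frozen=True)
class OERatioRecord:
    species_label: str
    theoretical_percent: float
    per_control: tuple[tuple[str, float, float], ...]  # (control, observed %, ratio)
    median: float
    min: float
    max: float

    def formatted(self) -> str:
        """``"1.07 (0.00–1.13)"`` — median (range), 2 decimals half-up."""
        return (f"{round_half_up(self.median):.2f} "
                f"({round_half_up(self.min):.2f}–{round_half_up(self.max):.2f})")


@dataclass(frozen=True)
class MockControlReport:
    control_id: str
    counts: ConfusionCounts
    scores: PerformanceScores
    percent_correct: float
    genus_rescues: tuple[str, ...]
    observed_percent: Mapping[str, float] = field(default_factory=dict)


def _percent_column(table: AbundanceTable, control_id: str) -> pd.Series:
    col = table.column(control_id)
    if table.mode == "relative":
        return col * 100.0
    if table.mode == "percent":
        return col
    raise ValueError(
        f"control {control_id!r}: mock evaluation needs a relative or percent "
        "table; convert counts with to_relative first")


def match_species(
    table: AbundanceTable, ref: MockReference, control_id: str, floor: float = 0.0,
) -> tuple[set[str], set[str], set[str]]:
    """Partition a control's species-rank taxa against the reference.

    Returns ``(detected, spurious, genus_rescues)``.  ``floor`` is a
    percent-scale detection threshold (default 0: any nonzero abundance
    counts, matching a pipeline that keeps rare taxa).
    """
    col = _percent_column(table, control_id)
    detected: set[str] = set()
    spurious: set[str] = set()
    genera_present: set[str] = set()
    for taxon, pct in col.items():
        lin = table.lineage(taxon)
        if lin.resolved_rank == "species" and pct > floor:
            label = ref.resolve(lin.species_label)
            if label in ref.species:
                detected.add(label)
            else:
                spurious.add(taxon)
        elif lin.resolved_rank == "genus" and pct > floor:
            genera_present.add(lin.genus)
    rescues = set()
    for label in ref.species:
        if label not in detected:
            genus = label.split()[0]
            if genus in genera_present:
                rescues.add(label)
    return detected, spurious, rescues


def confusion(detected: Iterable[str], spurious: Iterable[str],
              ref: MockReference) -> ConfusionCounts:
    detected = set(detected)
    unknown = detected - set(ref.species)
    if unknown:
        raise ValueError(f"detected labels not in reference: {sorted(unknown)}")
    return ConfusionCounts(tp=len(detected), fp=len(set(spurious)),
                           fn=len(ref) - len(detected))


def performance(counts: ConfusionCounts) -> PerformanceScores:
    """Precision, sensitivity and F-score from confusion counts.

    When TP+FP = 0 the precision is undefined; it is reported as 0 with
    ``precision_undefined`` set.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp + fn == 0:
        raise ValueError("empty confusion counts")
    undefined = (tp + fp) == 0
    precision = 0.0 if undefined else tp / (tp + fp)
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    if precision + sensitivity == 0:
        f = 0.0
    else:
        f = 2 * precision * sensitivity / (precision + sensitivity)
    return PerformanceScores(precision=precision, sensitivity=sensitivity,
                             f_score=f, precision_undefined=undefined)


def percent_correct(table: AbundanceTable, ref: MockReference,
                    control_id: str) -> float:
    """Percent of the profile classified at species rank to an expected species."""
    col = _percent_column(table, control_id)
    total = 0.0
    for taxon, pct in col.items():
        lin = table.lineage(taxon)
        if lin.resolved_rank == "species" and ref.resolve(lin.species_label) in ref.species:
            total += float(pct)
    return total


def _observed_percents(table: AbundanceTable, ref: MockReference,
                       control_id: str) -> dict[str, float]:
    col = _percent_column(table, control_id)
    obs = {label: 0.0 for label in ref.species}
    for taxon, pct in col.items():
        lin = table.lineage(taxon)
        if lin.resolved_rank == "species":
            label = ref.resolve(lin.species_label)
            if label in obs:
                obs[label] += float(pct)
    return obs


def oe_ratios(tables: Mapping[str, AbundanceTable],
              ref: MockReference) -> list[OERatioRecord]:
    """Observed/expected abundance ratios per species across controls.

    ``tables`` maps control id to the table holding that control's column.
    Non-detections enter as ratio 0.00 and are *included* in the median and
    range, so a species missed in some controls shows a zero-inflated
    range such as ``1.07 (0.00–1.13)``.
    """
    if not tables:
        raise ValueError("need at least one control")
    theo = ref.theoretical_percent
    per_species: dict[str, list[tuple[str, float, float]]] = {
        label: [] for label in ref.species}
    for control_id, table in tables.items():
        obs = _observed_percents(table, ref, control_id)
        for label in ref.species:
            per_species[label].append(
                (control_id, obs[label], obs[label] / theo[label]))
    records = []
    for label in ref.species:
        ratios = [r for _, _, r in per_species[label]]
        records.append(OERatioRecord(
            species_label=label, theoretical_percent=theo[label],
            per_control=tuple(per_species[label]),
            median=float(np.median(ratios)),
            min=float(np.min(ratios)), max=float(np.max(ratios))))
    return records


def evaluate_control(table: AbundanceTable, ref: MockReference, control_id: str,
                     floor: float = 0.0) -> MockControlReport:
    detected, spurious, rescues = match_species(table, ref, control_id, floor)
    counts = confusion(detected, spurious, ref)
    return MockControlReport(
        control_id=control_id,
        counts=counts,
        scores=performance(counts),
        percent_correct=percent_correct(table, ref, control_id),
        genus_rescues=tuple(sorted(rescues)),
        observed_percent=_observed_percents(table, ref, control_id),
    )


@dataclass(frozen=True)
class ControlSummary:
    n_controls: int
    f_median: float
    f_min: float
    f_max: float


def aggregate_controls(reports: Sequence[MockControlReport]) -> ControlSummary:
    """Median and range of F-scores across controls (computed unrounded)."""
    if not reports:
        raise ValueError("need at least one report")
    fs = [r.scores.f_score for r in reports]
    return ControlSummary(n_controls=len(reports), f_median=float(np.median(fs)),
                          f_min=float(np.min(fs)), f_max=float(np.max(fs)))
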