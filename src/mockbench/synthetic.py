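"""Seeded generators for every input the pipeline consumes.

The study design being emulated: sequencing plates carrying real stool and
rectal-swab samples, plate-specific negative controls, one mock
(extraction) and one mock (sequencing) control per plate, and technical
replicate pairs within and between runs.  Three generators cover this:

* :func:`simulate_mock_control` — a mock-control profile built around the
  reference composition with compositional noise, per-species dropout
  (optionally "rescued" at genus rank, i.e. the mass stays but only the
  genus is resolved), and low-abundance spurious taxa drawn from a fixed
  decoy catalogue.  A truth record lists the planted TP/FP/FN so evaluator
  output can be checked against ground truth.
* :func:`simulate_pairs` — replicate or stool/swab pairs from a
  variance-components model: per-subject latent log-abundance profiles
  with between-subject scale ``sigma_b``, replicate copies perturbed with
  within-pair scale ``sigma_w``, closed to compositions by softmax.  The
  implied intraclass correlation sigma_b^2/(sigma_b^2+sigma_w^2) is
  recorded as the truth target.
* :func:`simulate_plate` — a full plate: real samples, negative controls
  carrying planted contaminants at a chosen enrichment, and both mock
  controls, plus the matching sample metadata.

Everything is driven by numpy Generators seeded from ``SyntheticSpec.seed``
(per-control streams are derived with a stable CRC of the control id), so
identical spec + seed reproduces identical tables byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mock_eval import MockReference, load_zymo8
from .profiles import (AbundanceTable, Lineage, SampleMetadata, format_lineage)
from .reproducibility import PairedDesign

__all__ = [
    "PairModel", "ContaminantPlan", "SyntheticSpec",
    "MockControlTruth", "PairSimulation", "PlateSimulation",
    "simulate_mock_control", "simulate_pairs", "simulate_plate",
    "load_decoy_catalogue", "species_lineage",
]


def load_decoy_catalogue() -> list[str]:
    """Fixed 50-name catalogue of plausible spurious species."""
    path = resources.files("mockbench.data").joinpath("decoy_taxa.txt")
    names = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return names


def species_lineage(label: str) -> Lineage:
    """``"Bacillus subtilis"`` → ``g__Bacillus;s__subtilis`` (genus = all but
    the last whitespace-separated token, so slashed genera survive)."""
    genus, _, epithet = label.rpartition(" ")
    return Lineage(genus=genus, species=epithet)


@dataclass(frozen=True)
class PairModel:
    """Variance-components model for paired samples.

    ``sigma_b`` is the between-subject scale of latent log-abundances and
    ``sigma_w`` the within-pair replicate noise; the implied ICC is
    sigma_b^2 / (sigma_b^2 + sigma_w^2).  Defaults mimic tight technical
    replicates (ICC ~ 0.9) over 17 pairs, the within-run design size.

    ``detection_limit`` zeroes compositions below a proportion floor
    (then re-closes), emulating finite sequencing depth; without it every
    taxon is present in every sample and presence/absence distances
    degenerate.
    """

    sigma_b: float = 1.0
    sigma_w: float = 1.0 / 3.0
    n_pairs: int = 17
    n_taxa: int = 60
    detection_limit: float = 0.005

    @property
    def true_icc(self) -> float:
        return self.sigma_b ** 2 / (self.sigma_b ** 2 + self.sigma_w ** 2)


@dataclass(frozen=True)
class ContaminantPlan:
    """Contaminants planted in negative controls.

    Mean count ``base_mean`` in real samples when carried over (with
    probability ``real_presence``), enriched ``enrichment``-fold in every
    negative control.  The carryover probability is kept low so a planted
    contaminant actually carries the negative-enrichment signature its
    truth label claims: reagent contaminants dominate negatives but only
    sporadically reach real libraries, where template DNA outcompetes them.
    """

    n_contaminants: int = 3
    enrichment: float = 10.0
    base_mean: float = 30.0
    real_presence: float = 0.15


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of the generators (seeded, hence reproducible).

    ``noise_concentration`` acts like a Dirichlet concentration: species
    proportions are jittered by log-normal factors with standard deviation
    1/sqrt(noise_concentration), so larger values hug the theoretical
    composition (infinity reproduces it exactly).  ``dropout_probs`` is a
    per-species probability of species-level non-detection (a scalar
    applies to all species); a dropped species is rescued to genus rank
    with probability ``genus_rescue_prob``, otherwise its mass is
    redistributed proportionally.  Spurious taxa arrive Poisson at
    ``spurious_rate`` per control with percent abundances uniform in
    ``spurious_abundance_range``.
    """

    seed: int = 0
    reference: MockReference = field(default_factory=load_zymo8)
    noise_concentration: float = 400.0
    dropout_probs: Mapping[str, float] | float = 0.15
    genus_rescue_prob: float = 0.5
    spurious_rate: float = 4.0
    spurious_abundance_range: tuple[float, float] = (0.01, 0.5)
    library_size_range: tuple[int, int] = (50_000, 200_000)
    pair_model: PairModel = field(default_factory=PairModel)
    contaminant_plan: ContaminantPlan = field(default_factory=ContaminantPlan)
    n_real_samples: int = 12
    n_negatives: int = 4
    n_community_taxa: int = 17

    def __post_init__(self) -> None:
        if isinstance(self.dropout_probs, (int, float)):
            if not 0 <= self.dropout_probs <= 1:
                raise ValueError("dropout probability must be in [0, 1]")
        else:
            if any(not 0 <= p <= 1 for p in self.dropout_probs.values()):
                raise ValueError("dropout probabilities must be in [0, 1]")
        if not 0 <= self.genus_rescue_prob <= 1:
            raise ValueError("genus_rescue_prob must be in [0, 1]")
        for lo, hi in (self.spurious_abundance_range, self.library_size_range):
            if lo > hi:
                raise ValueError("range lower bound exceeds upper bound")

    def dropout_for(self, label: str) -> float:
        if isinstance(self.dropout_probs, (int, float)):
            return float(self.dropout_probs)
        return float(self.dropout_probs.get(label, 0.0))

    def rng_for(self, stream: str) -> np.random.Generator:
        """Deterministic per-stream generator derived from the master seed."""
        child = zlib.crc32(stream.encode("utf-8")) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([self.seed, child]))


@dataclass(frozen=True)
class MockControlTruth:
    control_id: str
    detected: tuple[str, ...]       # species present at species rank
    dropped: tuple[str, ...]        # planted false negatives
    genus_rescued: tuple[str, ...]  # subset of dropped kept at genus rank
    spurious: tuple[str, ...]       # planted false-positive species names

    @property
    def tp(self) -> int:
        return len(self.detected)

    @property
    def fp(self) -> int:
        return len(self.spurious)

    @property
    def fn(self) -> int:
        return len(self.dropped)


def _mock_column(spec: SyntheticSpec, rng: np.random.Generator,
                 control_id: str) -> tuple[pd.Series, MockControlTruth]:
    ref = spec.reference
    labels = ref.species
    theo = np.array([p for _, p in ref.entries], dtype=float) / 100.0

    sigma = (0.0 if np.isinf(spec.noise_concentration)
             else 1.0 / np.sqrt(spec.noise_concentration))
    noisy = theo * np.exp(sigma * rng.standard_normal(len(theo)))
    noisy /= noisy.sum()

    dropped, rescued, kept = [], [], []
    for i, label in enumerate(labels):
        if rng.random() < spec.dropout_for(label):
            dropped.append(label)
            if rng.random() < spec.genus_rescue_prob:
                rescued.append(label)
        else:
            kept.append(label)

    n_spurious = int(rng.poisson(spec.spurious_rate))
    decoys = [d for d in load_decoy_catalogue() if d not in labels]
    picks = list(rng.choice(len(decoys), size=min(n_spurious, len(decoys)),
                            replace=False))
    spurious = [decoys[i] for i in picks]
    lo, hi = spec.spurious_abundance_range
    spurious_prop = rng.uniform(lo, hi, size=len(spurious)) / 100.0

    values: dict[str, float] = {}
    for i, label in enumerate(labels):
        lin = species_lineage(label)
        if label in dropped:
            if label in rescued:
                # mass kept, but resolved only to genus rank
                genus_row = format_lineage(Lineage(genus=lin.genus))
                values[genus_row] = values.get(genus_row, 0.0) + noisy[i]
        else:
            values[format_lineage(lin)] = noisy[i]
    # species dropped without rescue: renormalise the surviving mass
    total = sum(values.values())
    values = {k: v / total for k, v in values.items()}
    # inject spurious taxa and re-close
    scale = 1.0 - spurious_prop.sum()
    values = {k: v * scale for k, v in values.items()}
    for label, prop in zip(spurious, spurious_prop):
        values[format_lineage(species_lineage(label))] = prop

    truth = MockControlTruth(
        control_id=control_id, detected=tuple(kept), dropped=tuple(dropped),
        genus_rescued=tuple(rescued), spurious=tuple(spurious))
    return pd.Series(values, name=control_id), truth


def simulate_mock_control(
    spec: SyntheticSpec, control_id: str = "mock1",
) -> tuple[AbundanceTable, MockControlTruth]:
    """One mock-control profile (relative mode) plus its truth record."""
    rng = spec.rng_for(f"mock:{control_id}")
    col, truth = _mock_column(spec, rng, control_id)
    table = AbundanceTable(col.to_frame(), mode="relative")
    return table, truth


@dataclass(frozen=True)
class PairSimulation:
    table: AbundanceTable          # softmax-closed compositions, relative mode
    design: PairedDesign
    latent: pd.DataFrame           # samples x taxa latent log-abundances
    true_icc: float


def simulate_pairs(spec: SyntheticSpec, scope: str = "within_run") -> PairSimulation:
    """Paired samples from the variance-components model in the spec."""
    pm = spec.pair_model
    rng = spec.rng_for(f"pairs:{scope}")
    taxa = [format_lineage(Lineage(genus=f"Taxon{i:03d}", species=f"sp{i:03d}"))
            for i in range(pm.n_taxa)]
    cols = {}
    latent_rows = {}
    pairs = []
    for k in range(pm.n_pairs):
        mu = pm.sigma_b * rng.standard_normal(pm.n_taxa)
        pid = f"pair{k:03d}"
        ids = (f"{pid}a", f"{pid}b")
        for sid in ids:
            x = mu + pm.sigma_w * rng.standard_normal(pm.n_taxa)
            latent_rows[sid] = x
            expx = np.exp(x - x.max())
            p = expx / expx.sum()
            p[p < pm.detection_limit] = 0.0
            cols[sid] = p / p.sum()
        pairs.append((ids[0], ids[1], pid))
    table = AbundanceTable(pd.DataFrame(cols, index=taxa), mode="relative")
    latent = pd.DataFrame(latent_rows).T
    latent.columns = taxa
    return PairSimulation(table=table, design=PairedDesign(tuple(pairs), scope=scope),
                          latent=latent, true_icc=pm.true_icc)


@dataclass(frozen=True)
class PlateSimulation:
    table: AbundanceTable                    # counts, whole plate
    metadata: list[SampleMetadata]
    contaminants: tuple[str, ...]            # planted contaminant row ids
    mock_truths: dict[str, MockControlTruth]


def simulate_plate(spec: SyntheticSpec, plate: str = "P1",
                   run: str = "R1") -> PlateSimulation:
    """A full plate of counts: real samples, negatives, both mock controls.

    Community taxa scale with per-sample input DNA while planted
    contaminants enter at a roughly fixed absolute level, enriched
    ``enrichment``-fold in negatives — the signature both decontamination
    channels look for.
    """
    rng = spec.rng_for(f"plate:{run}:{plate}")
    plan = spec.contaminant_plan

    decoys = load_decoy_catalogue()
    contam_labels = [decoys[i] for i in rng.choice(
        len(decoys), size=plan.n_contaminants, replace=False)]
    contam_rows = [format_lineage(species_lineage(s)) for s in contam_labels]
    community_rows = [
        format_lineage(Lineage(genus=f"Gut{i:03d}", species=f"sp{i:03d}"))
        for i in range(spec.n_community_taxa)]

    lo, hi = spec.library_size_range
    base_lambda = rng.uniform(0.5, 3.0, size=spec.n_community_taxa)
    base_lambda /= base_lambda.sum()

    columns: dict[str, np.ndarray] = {}
    meta: list[SampleMetadata] = []
    all_rows = community_rows + contam_rows

    concentrations = rng.lognormal(mean=np.log(10.0), sigma=0.6,
                                   size=spec.n_real_samples)
    mean_conc = concentrations.mean()
    for s in range(spec.n_real_samples):
        sid = f"{run}{plate}S{s:02d}"
        depth = rng.integers(lo, hi + 1)
        comm = rng.poisson(base_lambda * depth * concentrations[s] / mean_conc)
        contam = np.where(rng.random(plan.n_contaminants) < plan.real_presence,
                          rng.poisson(plan.base_mean, plan.n_contaminants), 0)
        columns[sid] = np.concatenate([comm, contam])
        meta.append(SampleMetadata(sample_id=sid, run=run, plate=plate,
                                   control_role="none",
                                   dna_concentration=float(concentrations[s])))

    for g in range(spec.n_negatives):
        sid = f"{run}{plate}NEG{g}"
        # sporadic cross-talk from the community at trace level
        comm = np.where(rng.random(spec.n_community_taxa) < 0.05,
                        rng.poisson(2.0, spec.n_community_taxa) + 1, 0)
        contam = rng.poisson(plan.base_mean * plan.enrichment,
                             plan.n_contaminants)
        columns[sid] = np.concatenate([comm, contam])
        meta.append(SampleMetadata(sample_id=sid, run=run, plate=plate,
                                   control_role="negative"))

    mock_truths: dict[str, MockControlTruth] = {}
    mock_series: dict[str, pd.Series] = {}
    for role, suffix in (("mock_extraction", "Zymoex"), ("mock_sequencing", "Zymoseq")):
        sid = f"{run}{plate}{suffix}"
        col, truth = _mock_column(spec, spec.rng_for(f"plate-mock:{run}:{plate}:{suffix}"), sid)
        depth = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(depth, col.to_numpy() / col.to_numpy().sum())
        mock_series[sid] = pd.Series(counts, index=col.index)
        mock_truths[sid] = truth
        meta.append(SampleMetadata(sample_id=sid, run=run, plate=plate,
                                   control_role=role))

    frame = pd.DataFrame(columns, index=all_rows)
    mock_frame = pd.DataFrame(mock_series)
    frame = pd.concat([frame, mock_frame], axis=1).fillna(0.0).astype(int)
    table = AbundanceTable(frame, mode="counts")
    return PlateSimulation(table=table, metadata=meta,
                           contaminants=tuple(contam_rows),
                           mock_truths=mock_truths)
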