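"""Data model and I/O for taxonomic abundance tables and sample metadata.

The central currency is the :class:`AbundanceTable`: a taxa-by-samples
matrix whose rows are identified by canonical lineage strings in the
Greengenes-style ``k__...;p__...;c__...;o__...;f__...;g__...;s__...``
dialect.  Taxon identity is the *full* lineage string, so a genus-only
record (``g__Bacillus;s__``) and a species-level record of the same genus
are distinct rows and are reported separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "Lineage",
    "AbundanceTable",
    "SampleMetadata",
    "LineageParseError",
    "TableFormatError",
    "parse_lineage",
    "format_lineage",
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "to_relative",
]

#: Taxonomic ranks in order, with their one-letter lineage prefixes.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")
_PREFIX_TO_RANK = dict(zip(_PREFIXES, RANKS))
_RANK_TO_PREFIX = dict(zip(RANKS, _PREFIXES))

_TOKEN_RE = re.compile(r"^\s*([A-Za-z])__(.*?)\s*$")


class LineageParseError(ValueError):
    """Raised when a lineage string cannot be parsed; carries the token."""

    def __init__(self, message: str, token: str | None = None):
        super().__init__(message)
        self.token = token


class TableFormatError(ValueError):
    """Raised when an abundance-table file violates the expected format."""


@dataclass(frozen=True)
class Lineage:
    """A taxonomic lineage with optional labels at each of the 7 ranks.

    ``resolved_rank`` is the deepest rank with a non-empty label, or
    ``None`` for a fully unassigned record.  A record whose species is
    populated but whose genus is empty is flagged ``rank_skipped``.
    """

    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def label(self, rank: str) -> str:
        if rank == "class":
            return self.class_
        if rank not in RANKS:
            raise ValueError(f"unknown rank: {rank!r}")
        return getattr(self, rank)

    @property
    def labels(self) -> tuple[str, ...]:
        return (self.kingdom, self.phylum, self.class_, self.order,
                self.family, self.genus, self.species)

    @property
    def resolved_rank(self) -> str | None:
        for rank, lab in zip(reversed(RANKS), reversed(self.labels)):
            if lab:
                return rank
        return None

    @property
    def rank_skipped(self) -> bool:
        """True when an empty rank sits between two populated ones.

        Missing ranks *above* the populated span are ordinary (short
        lineages); a hole inside the span marks a skipped rank.
        """
        populated = [i for i, lab in enumerate(self.labels) if lab]
        if len(populated) < 2:
            return False
        lo, hi = populated[0], populated[-1]
        return any(not self.labels[i] for i in range(lo, hi))

    @property
    def species_label(self) -> str:
        """Binomial-style label, e.g. ``"Escherichia/Shigella coli"``."""
        if not self.species:
            return ""
        return f"{self.genus} {self.species}".strip()

    def __str__(self) -> str:
        return format_lineage(self)


def parse_lineage(raw: str) -> Lineage:
    """Parse a semicolon-delimited lineage string into a :class:`Lineage`.

    Missing ranks may be written as empty tokens (``s__``) or omitted
    entirely; both normalise to the empty label.  Prefix case is
    normalised and surrounding whitespace trimmed.
    """
    labels = {rank: "" for rank in RANKS}
    if raw is None:
        raw = ""
    for token in raw.split(";"):
        if not token.strip():
            continue
        m = _TOKEN_RE.match(token)
        if m is None:
            raise LineageParseError(
                f"cannot parse lineage token {token.strip()!r}", token=token.strip()
            )
        prefix = m.group(1).lower()
        if prefix not in _PREFIX_TO_RANK:
            raise LineageParseError(
                f"unknown rank prefix {prefix!r} in token {token.strip()!r}",
                token=token.strip(),
            )
        labels[_PREFIX_TO_RANK[prefix]] = m.group(2).strip()
    return Lineage(
        kingdom=labels["kingdom"], phylum=labels["phylum"], class_=labels["class"],
        order=labels["order"], family=labels["family"], genus=labels["genus"],
        species=labels["species"],
    )


def format_lineage(lineage: Lineage) -> str:
    """Canonical string form; inverse of :func:`parse_lineage`."""
    return ";".join(
        f"{_RANK_TO_PREFIX[rank]}__{lab}" for rank, lab in zip(RANKS, lineage.labels)
    )


@dataclass
class AbundanceTable:
    """Taxa-by-samples abundance matrix with lineage-annotated rows.

    ``data`` is a DataFrame indexed by canonical lineage strings with one
    column per sample.  ``mode`` is ``"counts"`` (raw or rescaled library
    counts), ``"relative"`` (per-sample proportions summing to 1), or
    ``"percent"`` (published percent columns, rounded, summing to ~100 —
    the loose tolerance accommodates tables printed at 2 decimals).
    """

    data: pd.DataFrame
    mode: str = "counts"
    lineages: dict[str, Lineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative", "percent"):
            raise ValueError(
                f"mode must be 'counts', 'relative' or 'percent', got {self.mode!r}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise TableFormatError(f"duplicate sample ids: {dups}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate lineage rows: {dups}")
        vals = self.data.to_numpy()
        if vals.size and (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise TableFormatError(
                f"negative abundance at taxon {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if not self.lineages:
            # canonicalise row ids through the lineage parser so that any
            # spelling of the same lineage maps to one row identity
            lineages = {}
            canonical = []
            for raw in self.data.index:
                lin = parse_lineage(str(raw))
                key = format_lineage(lin)
                canonical.append(key)
                lineages[key] = lin
            if len(set(canonical)) != len(canonical):
                dups = [c for c in canonical if canonical.count(c) > 1]
                raise TableFormatError(f"duplicate lineage rows: {sorted(set(dups))}")
            self.data.index = canonical
            self.lineages = lineages
        if self.mode == "relative" and self.data.shape[1]:
            sums = self.data.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.columns[np.argmax(np.abs(sums - 1.0))]
                raise TableFormatError(
                    f"relative-mode column {bad!r} sums to "
                    f"{sums[np.argmax(np.abs(sums - 1.0))]:.6g}, expected 1"
                )
        if self.mode == "percent" and self.data.shape[1]:
            sums = self.data.sum(axis=0).to_numpy()
            if not np.allclose(sums, 100.0, atol=0.5):
                bad = self.data.columns[np.argmax(np.abs(sums - 100.0))]
                raise TableFormatError(
                    f"percent-mode column {bad!r} sums to "
                    f"{sums[np.argmax(np.abs(sums - 100.0))]:.6g}, expected ~100"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def lineage(self, taxon: str) -> Lineage:
        return self.lineages[taxon]

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.columns:
            raise KeyError(f"unknown sample id: {sample_id!r}")
        return self.data[sample_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return AbundanceTable(self.data[list(sample_ids)].copy(), mode=self.mode,
                              lineages=dict(self.lineages))

    def drop_taxa(self, taxa: Iterable[str]) -> "AbundanceTable":
        """Row deletion only; remaining values are untouched."""
        drop = set(taxa)
        keep = [t for t in self.data.index if t not in drop]
        return AbundanceTable(self.data.loc[keep].copy(), mode=self.mode,
                              lineages={t: self.lineages[t] for t in keep})

    def collapse_to_rank(self, rank: str) -> "AbundanceTable":
        """Pool rows by their label path down to ``rank``.

        Rows not resolved to ``rank`` are pooled into a single
        ``unassigned`` bin (kept so column totals are preserved; diversity
        code excludes it from richness).
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank: {rank!r}")
        depth = RANKS.index(rank) + 1
        groups: dict[str, list[str]] = {}
        for taxon in self.data.index:
            lin = self.lineages[taxon]
            if lin.label(rank):
                key = format_lineage(Lineage(*(lin.labels[:depth] + ("",) * (7 - depth))))
            else:
                key = format_lineage(Lineage())
            groups.setdefault(key, []).append(taxon)
        rows = {key: self.data.loc[members].sum(axis=0) for key, members in groups.items()}
        collapsed = pd.DataFrame(rows).T
        collapsed.columns = self.data.columns
        return AbundanceTable(collapsed, mode=self.mode)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample study annotations: run/plate layout, control role, pairing."""

    sample_id: str
    run: str = ""
    plate: str = ""
    control_role: str = "none"
    replicate_pair_id: str | None = None
    replicate_scope: str | None = None
    sample_type: str | None = None
    dna_concentration: float | None = None

    _ROLES = ("none", "mock_extraction", "mock_sequencing", "negative")
    _SCOPES = ("within_run", "between_run", "stool_swab")

    def __post_init__(self) -> None:
        if self.control_role not in self._ROLES:
            raise ValueError(f"control_role must be one of {self._ROLES}, "
                             f"got {self.control_role!r}")
        if self.replicate_scope is not None and self.replicate_scope not in self._SCOPES:
            raise ValueError(f"replicate_scope must be one of {self._SCOPES}")
        if self.dna_concentration is not None and not self.dna_concentration > 0:
            raise ValueError("dna_concentration must be positive")


def validate_metadata(records: Sequence[SampleMetadata]) -> None:
    """Check pairing invariants: each pair id names exactly two samples."""
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in metadata")
    counts: dict[str, int] = {}
    for r in records:
        if r.replicate_pair_id is not None:
            if r.control_role == "negative":
                raise ValueError(
                    f"negative control {r.sample_id!r} cannot be in a replicate pair")
            counts[r.replicate_pair_id] = counts.get(r.replicate_pair_id, 0) + 1
    bad = {k: v for k, v in counts.items() if v != 2}
    if bad:
        raise ValueError(f"replicate pair ids without exactly two members: {bad}")


def read_abundance_table(path: str | Path, mode_hint: str | None = None) -> AbundanceTable:
    """Read a taxa-table TSV: first column lineage strings, then sample columns.

    Counts are auto-detected when every cell is integral, unless
    ``mode_hint`` forces the mode.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise TableFormatError(f"{path}: no sample columns")
    numeric = pd.DataFrame(index=df.index.astype(str))
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}: non-numeric cell in column {col!r}") from exc
    vals = numeric.to_numpy(dtype=float)
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise TableFormatError(
            f"{path}: negative value at row {numeric.index[r]!r}, "
            f"column {numeric.columns[c]!r}")
    if mode_hint is not None:
        mode = mode_hint
    else:
        sums = vals.sum(axis=0)
        if vals.size and np.allclose(vals, np.round(vals)) and not np.allclose(sums, 1.0, atol=1e-9):
            mode = "counts"
        elif np.allclose(sums, 1.0, atol=1e-9):
            mode = "relative"
        elif np.allclose(sums, 100.0, atol=0.5):
            mode = "percent"
        else:
            raise TableFormatError(
                f"{path}: cannot auto-detect mode (non-integer values, column "
                "sums neither ~1 nor ~100); pass mode_hint")
    # normalise row ids through the lineage parser (trims stray whitespace,
    # unifies absent vs empty trailing ranks)
    lineages = {}
    canonical = []
    for raw in numeric.index:
        lin = parse_lineage(raw)
        key = format_lineage(lin)
        canonical.append(key)
        lineages[key] = lin
    numeric.index = canonical
    return AbundanceTable(numeric.astype(float), mode=mode, lineages=lineages)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "lineage"
    out.to_csv(path, sep="\t")


_META_COLS = ["sample_id", "run", "plate", "control_role", "replicate_pair_id",
              "replicate_scope", "sample_type", "dna_concentration"]


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise TableFormatError(f"{path}: missing required column 'sample_id'")
    records = []
    for _, row in df.iterrows():
        def get(col: str) -> str | None:
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
                return None
            return str(v)
        conc = get("dna_concentration")
        records.append(SampleMetadata(
            sample_id=str(row["sample_id"]),
            run=get("run") or "",
            plate=get("plate") or "",
            control_role=get("control_role") or "none",
            replicate_pair_id=get("replicate_pair_id"),
            replicate_scope=get("replicate_scope"),
            sample_type=get("sample_type"),
            dna_concentration=float(conc) if conc is not None else None,
        ))
    validate_metadata(records)
    return records


def write_sample_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id, "run": r.run, "plate": r.plate,
            "control_role": r.control_role,
            "replicate_pair_id": r.replicate_pair_id or "",
            "replicate_scope": r.replicate_scope or "",
            "sample_type": r.sample_type or "",
            "dna_concentration": "" if r.dna_concentration is None else r.dna_concentration,
        })
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert a counts table to per-sample proportions.

    Refuses already-relative input rather than silently renormalising, and
    refuses zero-total samples.
    """
    if table.mode != "counts":
        raise ValueError("to_relative expects a counts table; input is already relative")
    totals = table.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    rel = table.data.div(totals, axis=1)
    return AbundanceTable(rel, mode="relative", lineages=dict(table.lineages))
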