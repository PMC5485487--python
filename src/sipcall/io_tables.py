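"""Readers and writers for the three tab-separated input formats.

Formats
-------
``counts.tsv``
    First column ``taxon``, remaining columns one per sample; cells are
    non-negative integers.  Duplicate taxon rows are an error (no silent
    merging).
``fractions.tsv``
    Columns ``bottle_id``, ``fraction_index``, ``density``,
    ``dna_concentration`` (last one may be empty).
``design.tsv``
    Columns ``bottle_id``, ``isotope`` (13C/12C), ``substrate``,
    ``replicate``, ``oxygen`` (oxic/anoxic), ``source_well``, ``weeks``.

Lines starting with ``#`` are comments and are skipped on read; writers may
emit them as provenance stamps.  All serialization is deterministic so that
write/read round-trips are identities and reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

#: Plausibility window for CsCl buoyant densities, g/mL.
DENSITY_WINDOW = (1.60, 1.85)

FRACTIONS_HEADER = ["bottle_id", "fraction_index", "density", "dna_concentration"]
DESIGN_HEADER = [
    "bottle_id",
    "isotope",
    "substrate",
    "replicate",
    "oxygen",
    "source_well",
    "weeks",
]

ISOTOPES = ("13C", "12C")
OXYGEN_REGIMES = ("oxic", "anoxic")


@dataclass
class CountTable:
    """Non-negative integer read counts, taxa as rows, samples as columns."""

    taxon_labels: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        n_taxa, n_samples = self.counts.shape
        if n_taxa < 1 or n_samples < 1:
            raise ValidationError("count table needs at least 1 taxon and 1 sample")
        if len(self.taxon_labels) != n_taxa:
            raise ValidationError(
                f"{len(self.taxon_labels)} taxon labels for {n_taxa} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        _check_unique(self.taxon_labels, "taxon label")
        _check_unique(self.sample_ids, "sample id")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts are not allowed")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample id {sample_id!r}") from None

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return CountTable(
            list(self.taxon_labels), list(sample_ids), self.counts[:, idx].copy()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.taxon_labels == other.taxon_labels
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class FractionRecord:
    """One density-gradient fraction of one bottle."""

    bottle_id: str
    fraction_index: int
    density: float
    dna_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.fraction_index < 1:
            raise ValidationError(
                f"fraction_index must be >= 1, got {self.fraction_index}"
            )
        lo, hi = DENSITY_WINDOW
        if not (lo < self.density < hi):
            raise ValidationError(
                f"density {self.density} g/mL outside sanity window ({lo}, {hi}) "
                f"for bottle {self.bottle_id!r} fraction {self.fraction_index}"
            )


@dataclass(frozen=True)
class DesignRecord:
    """One bottle of the incubation design manifest."""

    bottle_id: str
    isotope: str
    substrate: str
    replicate: int
    oxygen: str
    source_well: str
    weeks: float

    def __post_init__(self) -> None:
        if self.isotope not in ISOTOPES:
            raise ValidationError(
                f"isotope must be one of {ISOTOPES}, got {self.isotope!r}"
            )
        if self.oxygen not in OXYGEN_REGIMES:
            raise ValidationError(
                f"oxygen must be one of {OXYGEN_REGIMES}, got {self.oxygen!r}"
            )

    @property
    def group_key(self) -> tuple[str, str, str, float]:
        """Condition group: bottles sharing substrate, oxygen regime, source
        well and incubation time; each 13C group needs one 12C control."""
        return (self.substrate, self.oxygen, self.source_well, self.weeks)


# ---------------------------------------------------------------------------
# helpers


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


def _data_lines(path: Path) -> list[tuple[int, str]]:
    """Return (1-based line number, stripped line) pairs, skipping comments
    and blank lines."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line))
    if not out:
        raise ValidationError(f"{path}: file has no data lines")
    return out


def _parse_int(cell: str, path: Path, lineno: int, what: str) -> int:
    try:
        value = int(cell)
    except ValueError:
        raise ValidationError(
            f"{path}:{lineno}: {what} {cell!r} is not an integer"
        ) from None
    return value


def _parse_float(cell: str, path: Path, lineno: int, what: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(
            f"{path}:{lineno}: {what} {cell!r} is not a number"
        ) from None


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path: str | Path) -> CountTable:
    """Parse a taxa-by-samples TSV of integer read counts.

    Errors (negative cells, non-integers, ragged rows, duplicate labels)
    are reported with the offending line number.
    """
    path = Path(path)
    lines = _data_lines(path)
    header_lineno, header = lines[0]
    cols = header.split("\t")
    if len(cols) < 2:
        raise ValidationError(
            f"{path}:{header_lineno}: header needs a taxon column and at least "
            "one sample column"
        )
    sample_ids = cols[1:]
    taxon_labels: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(cols):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(cols)} columns, got {len(cells)}"
            )
        taxon = cells[0]
        if taxon in taxon_labels:
            raise ValidationError(f"{path}:{lineno}: duplicate taxon row {taxon!r}")
        values = []
        for cell in cells[1:]:
            v = _parse_int(cell, path, lineno, "count")
            if v < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {v}")
            values.append(v)
        taxon_labels.append(taxon)
        rows.append(values)
    if not rows:
        raise ValidationError(f"{path}: no taxon rows")
    return CountTable(taxon_labels, sample_ids, np.array(rows, dtype=np.int64))


def write_count_table(
    table: CountTable, path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write ``table`` as TSV; inverse of :func:`read_count_table`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("taxon\t" + "\t".join(table.sample_ids) + "\n")
        for taxon, row in zip(table.taxon_labels, table.counts):
            fh.write(taxon + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# fraction metadata


def read_fractions(path: str | Path) -> list[FractionRecord]:
    """Parse ``fractions.tsv`` and enforce the per-record invariants plus
    uniqueness of (bottle_id, fraction_index)."""
    path = Path(path)
    lines = _data_lines(path)
    header_lineno, header = lines[0]
    if header.split("\t") != FRACTIONS_HEADER:
        raise ValidationError(
            f"{path}:{header_lineno}: expected header "
            f"{chr(9).join(FRACTIONS_HEADER)!r}"
        )
    records: list[FractionRecord] = []
    seen: set[tuple[str, int]] = set()
    for lineno, line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(FRACTIONS_HEADER):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(FRACTIONS_HEADER)} columns, "
                f"got {len(cells)}"
            )
        bottle, idx_s, dens_s, dna_s = cells
        idx = _parse_int(idx_s, path, lineno, "fraction_index")
        density = _parse_float(dens_s, path, lineno, "density")
        dna = None if dna_s == "" else _parse_float(dna_s, path, lineno, "dna")
        key = (bottle, idx)
        if key in seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate fraction {idx} for bottle {bottle!r}"
            )
        seen.add(key)
        try:
            records.append(FractionRecord(bottle, idx, density, dna))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    if not records:
        raise ValidationError(f"{path}: no fraction rows")
    return records


def write_fractions(
    records: Sequence[FractionRecord], path: str | Path, comments: Sequence[str] = ()
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(FRACTIONS_HEADER) + "\n")
        for rec in records:
            dna = "" if rec.dna_concentration is None else repr(rec.dna_concentration)
            fh.write(
                f"{rec.bottle_id}\t{rec.fraction_index}\t{rec.density!r}\t{dna}\n"
            )


# ---------------------------------------------------------------------------
# incubation design


def validate_design(records: Sequence[DesignRecord]) -> None:
    """Check design-wide invariants: unique bottle ids, unique replicate
    indices per (isotope, condition) group, and one 12C control per 13C
    group — the ratio-of-odds-ratios is undefined without one."""
    _check_unique([r.bottle_id for r in records], "bottle_id")
    by_group: dict[tuple, list[DesignRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.group_key, []).append(rec)
    for key, members in by_group.items():
        for isotope in ISOTOPES:
            reps = [m.replicate for m in members if m.isotope == isotope]
            if len(reps) != len(set(reps)):
                raise ValidationError(
                    f"duplicate replicate indices among {isotope} bottles of "
                    f"condition group {key}"
                )
        n13 = sum(1 for m in members if m.isotope == "13C")
        n12 = sum(1 for m in members if m.isotope == "12C")
        if n13 > 0 and n12 != 1:
            raise ValidationError(
                f"condition group {key} has {n13} 13C bottle(s) but {n12} 12C "
                "control(s); exactly one control is required"
            )


def read_design(path: str | Path) -> list[DesignRecord]:
    path = Path(path)
    lines = _data_lines(path)
    header_lineno, header = lines[0]
    if header.split("\t") != DESIGN_HEADER:
        raise ValidationError(
            f"{path}:{header_lineno}: expected header {chr(9).join(DESIGN_HEADER)!r}"
        )
    records: list[DesignRecord] = []
    for lineno, line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(DESIGN_HEADER):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(DESIGN_HEADER)} columns, "
                f"got {len(cells)}"
            )
        bottle, isotope, substrate, rep_s, oxygen, well, weeks_s = cells
        rep = _parse_int(rep_s, path, lineno, "replicate")
        weeks = _parse_float(weeks_s, path, lineno, "weeks")
        try:
            records.append(
                DesignRecord(bottle, isotope, substrate, rep, oxygen, well, weeks)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    if not records:
        raise ValidationError(f"{path}: no design rows")
    validate_design(records)
    return records


def write_design(
    records: Sequence[DesignRecord], path: str | Path, comments: Sequence[str] = ()
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(DESIGN_HEADER) + "\n")
        for rec in records:
            weeks = repr(rec.weeks) if rec.weeks != int(rec.weeks) else str(int(rec.weeks))
            fh.write(
                f"{rec.bottle_id}\t{rec.isotope}\t{rec.substrate}\t"
                f"{rec.replicate}\t{rec.oxygen}\t{rec.source_well}\t{weeks}\n"
            )
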