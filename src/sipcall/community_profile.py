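"""Relative-abundance profiles (percent of each sample's total reads).

Percentages are always computed per sample column, never over the whole
dataset, and no rarefaction or compositional transform is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io_tables import CountTable, _check_unique, _data_lines


@dataclass
class AbundanceProfile:
    """Taxa-by-samples percentages; every column sums to 100."""

    taxon_labels: list[str]
    sample_ids: list[str]
    percentages: np.ndarray

    def __post_init__(self) -> None:
        self.percentages = np.asarray(self.percentages, dtype=float)
        if self.percentages.shape != (len(self.taxon_labels), len(self.sample_ids)):
            raise ValidationError("percentage matrix shape does not match labels")
        _check_unique(self.taxon_labels, "taxon label")
        _check_unique(self.sample_ids, "sample id")
        if np.any(self.percentages < -1e-9) or np.any(self.percentages > 100 + 1e-9):
            raise ValidationError("percentages must lie in [0, 100]")
        sums = self.percentages.sum(axis=0)
        bad = np.where(np.abs(sums - 100.0) > 1e-9)[0]
        if bad.size:
            raise ValidationError(
                f"column {self.sample_ids[bad[0]]!r} sums to {sums[bad[0]]}, "
                "expected 100"
            )


def relative_abundance(table: CountTable) -> AbundanceProfile:
    """Convert counts to percent-of-sample-total; empty sample columns are
    an error."""
    sums = table.column_sums()
    empty = np.where(sums == 0)[0]
    if empty.size:
        raise ValidationError(
            f"sample {table.sample_ids[empty[0]]!r} has zero total reads"
        )
    pct = 100.0 * table.counts / sums[np.newaxis, :]
    return AbundanceProfile(list(table.taxon_labels), list(table.sample_ids), pct)


def aggregate_taxa(table: CountTable, mapping: Mapping[str, str]) -> CountTable:
    """Sum taxon rows into groups per ``mapping`` (taxon label -> group
    label); the mapping must cover every taxon.  Group order follows first
    appearance in the table, so aggregation is deterministic."""
    unmapped = [t for t in table.taxon_labels if t not in mapping]
    if unmapped:
        raise ValidationError(f"taxa missing from mapping: {unmapped[:5]}")
    groups: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for taxon, row in zip(table.taxon_labels, table.counts):
        group = mapping[taxon]
        if group not in rows:
            groups.append(group)
            rows[group] = row.astype(np.int64).copy()
        else:
            rows[group] += row
    counts = np.vstack([rows[g] for g in groups])
    return CountTable(groups, list(table.sample_ids), counts)


def shared_taxa(
    profile_a: AbundanceProfile, profile_b: AbundanceProfile, min_pct: float = 0.0
) -> set[str]:
    """Taxa reaching ``min_pct`` percent in at least one sample of *each*
    profile.  With min_pct = 0 this is the intersection of taxa with any
    nonzero reads."""
    if min_pct < 0:
        raise ValidationError("min_pct must be >= 0")

    def present(profile: AbundanceProfile) -> set[str]:
        hits = set()
        for taxon, row in zip(profile.taxon_labels, profile.percentages):
            if min_pct == 0:
                if np.any(row > 0):
                    hits.add(taxon)
            elif np.any(row >= min_pct):
                hits.add(taxon)
        return hits

    return present(profile_a) & present(profile_b)


# ---------------------------------------------------------------------------
# serialization (same TSV shape as count tables, float cells)


def write_profile(
    profile: AbundanceProfile, path: str | Path, comments: Sequence[str] = ()
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("taxon\t" + "\t".join(profile.sample_ids) + "\n")
        for taxon, row in zip(profile.taxon_labels, profile.percentages):
            fh.write(taxon + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_profile(path: str | Path) -> AbundanceProfile:
    path = Path(path)
    lines = _data_lines(path)
    _, header = lines[0]
    cols = header.split("\t")
    if len(cols) < 2:
        raise ValidationError(f"{path}: header needs at least one sample column")
    sample_ids = cols[1:]
    taxa: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(cols):
            raise ValidationError(
                f"{path}:{lineno}: expected {len(cols)} columns, got {len(cells)}"
            )
        taxa.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: non-numeric cell") from None
    if not rows:
        raise ValidationError(f"{path}: no taxon rows")
    return AbundanceProfile(taxa, sample_ids, np.array(rows, dtype=float))
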