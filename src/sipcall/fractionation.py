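"""Light/heavy classification of gradient fractions and per-bottle pooling.

A fraction is *light* when its buoyant density is below ``light_max``
(default 1.715 g/mL) and *heavy* when it is at or above ``heavy_min``
(default 1.72 g/mL).  Densities in between are *intermediate* and, under
the default policy, excluded from both pools; they can instead be assigned
to either pool via ``intermediate=``.

Fraction-level sample ids follow the convention ``"<bottle_id>:<index>"``
(see :func:`fraction_sample_id`); pooled sample ids are
``"<bottle_id>:light"`` and ``"<bottle_id>:heavy"``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UndefinedStatisticError, ValidationError
from .io_tables import CountTable, FractionRecord

DEFAULT_LIGHT_MAX = 1.715
DEFAULT_HEAVY_MIN = 1.72

INTERMEDIATE_POLICIES = ("drop", "light", "heavy")


class FractionClass(enum.Enum):
    LIGHT = "light"
    HEAVY = "heavy"
    INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class PooledSample:
    """Per-taxon counts of one bottle's light or heavy pool."""

    bottle_id: str
    pool: str  # "light" | "heavy"
    counts: np.ndarray  # per-taxon, int64
    member_fractions: tuple[int, ...]

    @property
    def sample_id(self) -> str:
        return pooled_sample_id(self.bottle_id, self.pool)


def fraction_sample_id(bottle_id: str, fraction_index: int) -> str:
    return f"{bottle_id}:{fraction_index}"


def pooled_sample_id(bottle_id: str, pool: str) -> str:
    return f"{bottle_id}:{pool}"


def split_pooled_sample_id(sample_id: str) -> tuple[str, str]:
    bottle, _, pool = sample_id.rpartition(":")
    if not bottle or pool not in ("light", "heavy"):
        raise ValidationError(
            f"sample id {sample_id!r} is not of the form '<bottle>:light|heavy'"
        )
    return bottle, pool


def classify_fraction(
    density: float,
    light_max: float = DEFAULT_LIGHT_MAX,
    heavy_min: float = DEFAULT_HEAVY_MIN,
) -> FractionClass:
    """Classify a fraction by density: ``< light_max`` is light,
    ``>= heavy_min`` is heavy, anything in between intermediate."""
    if not light_max < heavy_min:
        raise ValidationError(
            f"light_max ({light_max}) must be below heavy_min ({heavy_min})"
        )
    if density < light_max:
        return FractionClass.LIGHT
    if density >= heavy_min:
        return FractionClass.HEAVY
    return FractionClass.INTERMEDIATE


def pool_fractions(
    table: CountTable,
    fractions: Sequence[FractionRecord],
    light_max: float = DEFAULT_LIGHT_MAX,
    heavy_min: float = DEFAULT_HEAVY_MIN,
    intermediate: str = "drop",
) -> list[PooledSample]:
    """Sum fraction-level counts into one light and one heavy pool per bottle.

    Every sample column of ``table`` must be named
    ``"<bottle_id>:<fraction_index>"`` and have a matching
    :class:`FractionRecord`.  Counts are conserved exactly: the light pool,
    heavy pool and excluded intermediate fractions of a bottle partition its
    fraction columns.

    Raises :class:`UndefinedStatisticError` if any bottle ends up with no
    light or no heavy fractions — the enrichment odds ratio needs both.
    """
    if intermediate not in INTERMEDIATE_POLICIES:
        raise ValidationError(
            f"intermediate policy must be one of {INTERMEDIATE_POLICIES}, "
            f"got {intermediate!r}"
        )
    by_key = {(f.bottle_id, f.fraction_index): f for f in fractions}
    # bottle -> pool -> list of (fraction_index, column index)
    assignment: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for col, sample_id in enumerate(table.sample_ids):
        bottle, _, idx_s = sample_id.rpartition(":")
        try:
            idx = int(idx_s)
        except ValueError:
            raise ValidationError(
                f"sample id {sample_id!r} is not of the form '<bottle>:<index>'"
            ) from None
        rec = by_key.get((bottle, idx))
        if rec is None:
            raise ValidationError(
                f"sample {sample_id!r} has no matching fraction record"
            )
        cls = classify_fraction(rec.density, light_max, heavy_min)
        pool = cls.value
        if cls is FractionClass.INTERMEDIATE:
            if intermediate == "drop":
                pool = None
            else:
                pool = intermediate
        bucket = assignment.setdefault(bottle, {"light": [], "heavy": []})
        if pool is not None:
            bucket[pool].append((idx, col))
    pools: list[PooledSample] = []
    for bottle in sorted(assignment):
        for pool in ("light", "heavy"):
            members = sorted(assignment[bottle][pool])
            if not members:
                raise UndefinedStatisticError(
                    f"bottle {bottle!r} has no {pool} fractions under "
                    f"light_max={light_max}, heavy_min={heavy_min}; "
                    "labeling statistic undefined"
                )
            cols = [c for _, c in members]
            counts = table.counts[:, cols].sum(axis=1)
            pools.append(
                PooledSample(
                    bottle_id=bottle,
                    pool=pool,
                    counts=counts.astype(np.int64),
                    member_fractions=tuple(i for i, _ in members),
                )
            )
    return pools


def pools_from_table(table: CountTable) -> list[PooledSample]:
    """Rebuild PooledSample records from a pooled count table (sample ids
    '<bottle>:light' / '<bottle>:heavy'); member fractions are unknown at
    this point and left empty."""
    pools = []
    for col, sample_id in enumerate(table.sample_ids):
        bottle, pool = split_pooled_sample_id(sample_id)
        pools.append(
            PooledSample(
                bottle_id=bottle,
                pool=pool,
                counts=table.counts[:, col].copy(),
                member_fractions=(),
            )
        )
    return pools


def pooled_table(pools: Sequence[PooledSample], taxon_labels: Sequence[str]) -> CountTable:
    """Assemble pooled samples into a CountTable, columns sorted by
    (bottle_id, heavy-after-light) for deterministic output."""
    ordered = sorted(pools, key=lambda p: (p.bottle_id, p.pool != "light"))
    ids = [p.sample_id for p in ordered]
    counts = np.column_stack([p.counts for p in ordered])
    return CountTable(list(taxon_labels), ids, counts)
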