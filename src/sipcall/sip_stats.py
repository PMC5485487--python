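"""Heavy-fraction enrichment statistics and labeled-taxon calls.

The per-bottle statistic is an odds ratio over the bottle's pooled heavy
and light samples:

    OR = (H_arc / H_narc) / (L_arc / L_narc)

where ``H_arc`` is the taxon's read count in the heavy pool, ``H_narc``
the heavy pool's remaining reads, and ``L_arc`` / ``L_narc`` the same for
the light pool.  OR > 1 means the taxon is relatively more abundant in the
heavy pool.  For each labeled-substrate (13C) bottle, the ratio of odds
ratios against its paired unlabeled (12C) control,

    RoOR = OR_13C / OR_12C,

is the labeling criterion: RoOR > 1 calls the taxon labeled in that
replicate.  Only (taxon, bottle) pairs with at least ``min_reads`` reads
(default 5) in both pools enter the analysis; this taxon-level reading of
the filter also guarantees all four counts of the odds ratio are positive.

Undefined ratios are signalled as NaN, never silently dropped; calls on
undefined RoORs are ``None``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .fractionation import PooledSample
from .io_tables import CountTable, DesignRecord, validate_design

DEFAULT_MIN_READS = 5
DEFAULT_THRESHOLD = 1.0

FILTER_LEVELS = ("taxon", "total")


def odds_ratio(
    h_taxon: int,
    h_total: int,
    l_taxon: int,
    l_total: int,
    correction: float = 0.0,
) -> float:
    """Heavy/light enrichment odds ratio of one taxon in one bottle.

    Parameters are the taxon's reads and the total reads in the heavy and
    light pools; the "everything else" counts are formed internally.
    Returns NaN when the ratio is undefined (zero in a denominator), which
    is distinct from invalid input (negative or inconsistent counts), which
    raises.

    ``correction`` optionally adds a Haldane-style pseudocount to all four
    cells.  It is non-canonical — the read filter makes it unnecessary for
    eligible taxa — and is off by default.
    """
    if h_taxon < 0 or l_taxon < 0 or h_total < h_taxon or l_total < l_taxon:
        raise ValidationError(
            f"inconsistent counts: heavy {h_taxon}/{h_total}, "
            f"light {l_taxon}/{l_total}"
        )
    h_arc = h_taxon + correction
    h_narc = (h_total - h_taxon) + correction
    l_arc = l_taxon + correction
    l_narc = (l_total - l_taxon) + correction
    if h_narc == 0 or l_arc == 0 or l_narc == 0:
        return math.nan
    return (h_arc / h_narc) / (l_arc / l_narc)


def eligible(h_taxon: int, l_taxon: int, min_reads: int = DEFAULT_MIN_READS) -> bool:
    """True iff the taxon has at least ``min_reads`` reads in both the
    heavy and the light pool of a bottle."""
    if h_taxon < 0 or l_taxon < 0:
        raise ValidationError("counts must be non-negative")
    return h_taxon >= min_reads and l_taxon >= min_reads


def ratio_of_odds_ratios(or_13c: float, or_12c: float) -> float:
    """OR of a 13C bottle divided by OR of its 12C control; NaN propagates
    (an undefined member makes the ratio undefined)."""
    if math.isnan(or_13c) or math.isnan(or_12c):
        return math.nan
    if or_12c <= 0:
        return math.nan
    return or_13c / or_12c


@dataclass(frozen=True)
class ReplicateCall:
    """Labeling evidence for one taxon in one 13C replicate bottle."""

    taxon: str
    bottle_13c: str
    bottle_12c: str
    replicate: int
    h_arc_13c: int
    h_narc_13c: int
    l_arc_13c: int
    l_narc_13c: int
    h_arc_12c: int
    h_narc_12c: int
    l_arc_12c: int
    l_narc_12c: int
    or_13c: float
    or_12c: float
    eligible_13c: bool
    eligible_12c: bool
    roor: float
    labeled: bool | None


@dataclass(frozen=True)
class TaxonCall:
    """Consensus over a taxon's 13C replicates.

    ``labeled_any``: RoOR above threshold in at least one replicate.
    ``labeled_all``: at least one defined RoOR and all defined RoORs above
    threshold.  Both are reported; neither is "the" answer.
    """

    taxon: str
    n_replicates: int
    n_defined: int
    labeled_any: bool
    labeled_all: bool


@dataclass
class LabelingResult:
    replicate_calls: list[ReplicateCall]
    taxon_calls: list[TaxonCall]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per (taxon, 13C replicate), with every odds-
        ratio ingredient, eligibility and the consensus calls."""
        consensus = {t.taxon: t for t in self.taxon_calls}
        rows = []
        for rc in self.replicate_calls:
            row = {
                "taxon": rc.taxon,
                "replicate": rc.replicate,
                "bottle_13c": rc.bottle_13c,
                "bottle_12c": rc.bottle_12c,
                "h_arc_13c": rc.h_arc_13c,
                "h_narc_13c": rc.h_narc_13c,
                "l_arc_13c": rc.l_arc_13c,
                "l_narc_13c": rc.l_narc_13c,
                "or_13c": rc.or_13c,
                "h_arc_12c": rc.h_arc_12c,
                "h_narc_12c": rc.h_narc_12c,
                "l_arc_12c": rc.l_arc_12c,
                "l_narc_12c": rc.l_narc_12c,
                "or_12c": rc.or_12c,
                "eligible_13c": rc.eligible_13c,
                "eligible_12c": rc.eligible_12c,
                "roor": rc.roor,
                "labeled": "" if rc.labeled is None else rc.labeled,
                "labeled_any": consensus[rc.taxon].labeled_any,
                "labeled_all": consensus[rc.taxon].labeled_all,
            }
            rows.append(row)
        return pd.DataFrame(rows)


def _pools_by_bottle(
    pools: Sequence[PooledSample],
) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    for p in pools:
        out.setdefault(p.bottle_id, {})[p.pool] = np.asarray(p.counts, dtype=np.int64)
    for bottle, d in out.items():
        missing = {"light", "heavy"} - set(d)
        if missing:
            raise UndefinedStatisticError(
                f"bottle {bottle!r} lacks pool(s): {sorted(missing)}"
            )
    return out


def pair_bottles(design: Sequence[DesignRecord]) -> list[tuple[DesignRecord, DesignRecord]]:
    """Pair each 13C bottle with the single 12C control of its condition
    group; pairs sorted by (group, replicate) for determinism."""
    validate_design(design)
    by_group: dict[tuple, list[DesignRecord]] = {}
    for rec in design:
        by_group.setdefault(rec.group_key, []).append(rec)
    pairs = []
    for key in sorted(by_group):
        members = by_group[key]
        controls = [m for m in members if m.isotope == "12C"]
        labeled = sorted(
            (m for m in members if m.isotope == "13C"), key=lambda m: m.replicate
        )
        if labeled and not controls:
            raise ValidationError(f"no 12C control for condition group {key}")
        for bottle in labeled:
            pairs.append((bottle, controls[0]))
    return pairs


def _bottle_stats(
    counts: dict[str, np.ndarray],
    taxon_idx: int,
    min_reads: int,
    filter_level: str,
) -> tuple[int, int, int, int, float, bool]:
    heavy, light = counts["heavy"], counts["light"]
    h_tot, l_tot = int(heavy.sum()), int(light.sum())
    h_arc, l_arc = int(heavy[taxon_idx]), int(light[taxon_idx])
    o_r = odds_ratio(h_arc, h_tot, l_arc, l_tot)
    if filter_level == "taxon":
        elig = eligible(h_arc, l_arc, min_reads)
    else:  # "total": the filter applies to whole-pool read totals
        elig = h_tot >= min_reads and l_tot >= min_reads
    return h_arc, h_tot - h_arc, l_arc, l_tot - l_arc, o_r, elig


def labeling_analysis(
    pools: Sequence[PooledSample],
    design: Sequence[DesignRecord],
    taxon_labels: Sequence[str],
    min_reads: int = DEFAULT_MIN_READS,
    threshold: float = DEFAULT_THRESHOLD,
    filter_level: str = "taxon",
) -> LabelingResult:
    """Run the full per-taxon labeling procedure.

    For every taxon and every 13C replicate: compute the bottle odds ratios,
    apply the read filter to both the 13C bottle and its 12C control, and
    report RoOR only when both are eligible.  ``labeled`` uses strict
    ``roor > threshold``; a tie at the threshold is not labeled.  Output is
    sorted by taxon then replicate.
    """
    if filter_level not in FILTER_LEVELS:
        raise ValidationError(
            f"filter_level must be one of {FILTER_LEVELS}, got {filter_level!r}"
        )
    if min_reads < 1:
        raise ValidationError("min_reads must be >= 1")
    by_bottle = _pools_by_bottle(pools)
    pairs = pair_bottles(design)
    for b13, b12 in pairs:
        for b in (b13.bottle_id, b12.bottle_id):
            if b not in by_bottle:
                raise ValidationError(f"design bottle {b!r} has no pooled samples")
    replicate_calls: list[ReplicateCall] = []
    taxon_calls: list[TaxonCall] = []
    for taxon_idx, taxon in enumerate(taxon_labels):
        roors: list[float] = []
        for b13, b12 in pairs:
            h13, hn13, l13, ln13, or13, e13 = _bottle_stats(
                by_bottle[b13.bottle_id], taxon_idx, min_reads, filter_level
            )
            h12, hn12, l12, ln12, or12, e12 = _bottle_stats(
                by_bottle[b12.bottle_id], taxon_idx, min_reads, filter_level
            )
            if e13 and e12:
                roor = ratio_of_odds_ratios(or13, or12)
            else:
                roor = math.nan
            labeled = None if math.isnan(roor) else bool(roor > threshold)
            replicate_calls.append(
                ReplicateCall(
                    taxon=taxon,
                    bottle_13c=b13.bottle_id,
                    bottle_12c=b12.bottle_id,
                    replicate=b13.replicate,
                    h_arc_13c=h13,
                    h_narc_13c=hn13,
                    l_arc_13c=l13,
                    l_narc_13c=ln13,
                    h_arc_12c=h12,
                    h_narc_12c=hn12,
                    l_arc_12c=l12,
                    l_narc_12c=ln12,
                    or_13c=or13,
                    or_12c=or12,
                    eligible_13c=e13,
                    eligible_12c=e12,
                    roor=roor,
                    labeled=labeled,
                )
            )
            roors.append(roor)
        defined = [r for r in roors if not math.isnan(r)]
        taxon_calls.append(
            TaxonCall(
                taxon=taxon,
                n_replicates=len(roors),
                n_defined=len(defined),
                labeled_any=any(r > threshold for r in defined),
                labeled_all=bool(defined) and all(r > threshold for r in defined),
            )
        )
    return LabelingResult(replicate_calls, taxon_calls)


def permutation_chance_rate(
    pools: Sequence[PooledSample],
    bottle_ids: Sequence[str],
    taxon_labels: Sequence[str],
    min_reads: int = DEFAULT_MIN_READS,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[float, int]:
    """Chance rate of RoOR exceeding the threshold under role permutation.

    Treats the given bottles as exchangeable: every bottle in turn plays the
    unlabeled control while the others act as labeled replicates, and the
    RoOR criterion is evaluated for each eligible (taxon, replicate) pair
    under each assignment.  Returns (fraction above threshold, number of
    defined pairs evaluated).  Useful for quantifying how often
    "RoOR > threshold" fires by chance alone on null data.
    """
    by_bottle = _pools_by_bottle(pools)
    hits = 0
    total = 0
    for control in bottle_ids:
        others = [b for b in bottle_ids if b != control]
        for taxon_idx in range(len(taxon_labels)):
            _, _, _, _, or_c, e_c = _bottle_stats(
                by_bottle[control], taxon_idx, min_reads, "taxon"
            )
            for rep in others:
                _, _, _, _, or_r, e_r = _bottle_stats(
                    by_bottle[rep], taxon_idx, min_reads, "taxon"
                )
                if not (e_c and e_r):
                    continue
                roor = ratio_of_odds_ratios(or_r, or_c)
                if math.isnan(roor):
                    continue
                total += 1
                if roor > threshold:
                    hits += 1
    if total == 0:
        return math.nan, 0
    return hits / total, total


def or_grid(max_total: int) -> "itertools.product":
    """All (h_taxon, h_total, l_taxon, l_total) tuples with totals up to
    ``max_total`` — the exhaustive domain used for oracle checks."""
    pairs = [
        (t, tot) for tot in range(max_total + 1) for t in range(tot + 1)
    ]
    return itertools.product(pairs, pairs)
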