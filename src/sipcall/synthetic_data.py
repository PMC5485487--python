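"""Forward simulator for isotope-labeling gradient experiments.

Each taxon's DNA is modeled as a Gaussian band over buoyant density
(isopycnic-band approximation): unlabeled DNA bands at ``density_mean``;
assimilating the heavy substrate shifts the band up by
``atom_excess * label_shift``.  A gradient run slices the density axis into
ordered bins (fractions); the expected taxon composition of a fraction is
each taxon's base abundance weighted by its Gaussian mass in the bin,
renormalized within the fraction.  Sequencing a fraction is one multinomial
draw over taxa.

An experiment emits ``n_label_replicates`` labeled-substrate (13C) bottles
plus one unlabeled (12C) control, with per-fraction count tables, fraction
metadata (the per-fraction DNA concentration analogue is the unnormalized
Gaussian mass — for plotting only), a design manifest, and the ground-truth
labeled set (taxa with ``atom_excess > 0``).

Randomness: one seed per scenario; per-bottle generators are derived with
``numpy.random.SeedSequence(seed).spawn``, so adding a bottle never
perturbs the draws of existing ones, and identical scenarios reproduce
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from . import fractionation
from .errors import UndefinedStatisticError, ValidationError
from .io_tables import CountTable, DesignRecord, FractionRecord

#: Default density gain of fully labeled DNA, g/mL (typical CsCl shift for
#: full substitution of the heavy carbon isotope; configurable).
DEFAULT_LABEL_SHIFT = 0.036

#: Mass below which a fraction is considered empty of DNA.
EMPTY_MASS = 1e-12


@dataclass
class SimScenario:
    """Parameters of one simulated experiment; see module docstring."""

    taxa: list[str]
    base_abundance: np.ndarray
    density_mean: np.ndarray
    density_sd: np.ndarray
    atom_excess: np.ndarray
    fraction_edges: np.ndarray
    label_shift: float = DEFAULT_LABEL_SHIFT
    depth: int = 10_000
    n_label_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_abundance = np.asarray(self.base_abundance, dtype=float)
        self.density_mean = np.asarray(self.density_mean, dtype=float)
        self.density_sd = np.asarray(self.density_sd, dtype=float)
        self.atom_excess = np.asarray(self.atom_excess, dtype=float)
        self.fraction_edges = np.asarray(self.fraction_edges, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.taxa)
        if n == 0:
            raise ValidationError("scenario needs at least one taxon")
        if len(set(self.taxa)) != n:
            raise ValidationError("taxon labels must be unique")
        for name, arr in (
            ("base_abundance", self.base_abundance),
            ("density_mean", self.density_mean),
            ("density_sd", self.density_sd),
            ("atom_excess", self.atom_excess),
        ):
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have one entry per taxon")
        if np.any(self.base_abundance < 0):
            raise ValidationError("base_abundance entries must be non-negative")
        if abs(self.base_abundance.sum() - 1.0) > 1e-9:
            raise ValidationError("base_abundance must sum to 1 within 1e-9")
        if np.any(self.density_sd <= 0):
            raise ValidationError("density_sd must be positive")
        if np.any((self.atom_excess < 0) | (self.atom_excess > 1)):
            raise ValidationError("atom_excess must lie in [0, 1]")
        edges = self.fraction_edges
        if edges.ndim != 1 or not (12 <= edges.size <= 13):
            raise ValidationError(
                "fraction_edges must hold 12-13 edges (11-12 fractions)"
            )
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("fraction_edges must be strictly increasing")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.n_label_replicates < 1:
            raise ValidationError("n_label_replicates must be >= 1")

    @property
    def n_fractions(self) -> int:
        return self.fraction_edges.size - 1

    @property
    def fraction_midpoints(self) -> np.ndarray:
        e = self.fraction_edges
        return (e[:-1] + e[1:]) / 2.0

    @property
    def labeled_taxa(self) -> set[str]:
        return {t for t, a in zip(self.taxa, self.atom_excess) if a > 0}


#: Default per-taxon band spread, g/mL.  Must be wide enough that a fully
#: labeled taxon (shifted by ~0.036 g/mL) still leaves >= min_reads reads in
#: the light pool of a labeled bottle, and an unlabeled copy of it reaches
#: the heavy pool of the control: the read filter requires presence in all
#: four pools before a taxon is callable at all.
DEFAULT_DENSITY_SD = 0.01


def default_scenario(
    n_taxa: int = 20,
    n_labeled: int = 2,
    atom_excess: float = 1.0,
    label_shift: float = DEFAULT_LABEL_SHIFT,
    depth: int = 10_000,
    n_label_replicates: int = 2,
    seed: int = 1,
) -> SimScenario:
    """Reference scenario with recoverable planted truth.

    Dirichlet base abundances; 11 fractions spanning 1.68-1.768 g/mL; band
    sd 0.01 g/mL.  The first ``n_labeled`` taxa are the labeled set; their
    unlabeled band centers are drawn just below the heavy cut-off
    ([1.696, 1.700] g/mL) so that they stay detectable in every pool the
    read filter inspects, while background taxa band lower
    ([1.670, 1.680] g/mL) and never accumulate enough heavy-pool reads to
    be eligible — mirroring the regime where the labeling criterion is
    actually decidable.
    """
    if not 0 <= n_labeled <= n_taxa:
        raise ValidationError("n_labeled must lie in [0, n_taxa]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    taxa = [f"T{i + 1:02d}" for i in range(n_taxa)]
    base = rng.dirichlet(np.full(n_taxa, 8.0))
    means = rng.uniform(1.670, 1.680, size=n_taxa)
    means[:n_labeled] = rng.uniform(1.696, 1.700, size=n_labeled)
    excess = np.zeros(n_taxa)
    excess[:n_labeled] = atom_excess
    return SimScenario(
        taxa=taxa,
        base_abundance=base,
        density_mean=means,
        density_sd=np.full(n_taxa, DEFAULT_DENSITY_SD),
        atom_excess=excess,
        fraction_edges=np.linspace(1.68, 1.768, 12),
        label_shift=label_shift,
        depth=depth,
        n_label_replicates=n_label_replicates,
        seed=seed,
    )


def null_scenario(
    n_taxa: int = 20,
    depth: int = 10_000,
    n_label_replicates: int = 2,
    seed: int = 1,
) -> SimScenario:
    """Null-calibration scenario: nothing is labeled and every taxon bands
    close enough to the light/heavy boundary ([1.703, 1.713] g/mL, sd 0.01)
    to pass the read filter in every pool, so the ratio-of-odds-ratios is
    defined for (almost) all taxa and its null distribution around 1 can be
    measured."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    taxa = [f"T{i + 1:02d}" for i in range(n_taxa)]
    base = rng.dirichlet(np.full(n_taxa, 8.0))
    means = rng.uniform(1.703, 1.713, size=n_taxa)
    return SimScenario(
        taxa=taxa,
        base_abundance=base,
        density_mean=means,
        density_sd=np.full(n_taxa, DEFAULT_DENSITY_SD),
        atom_excess=np.zeros(n_taxa),
        fraction_edges=np.linspace(1.68, 1.768, 12),
        depth=depth,
        n_label_replicates=n_label_replicates,
        seed=seed,
    )


@dataclass
class FractionComposition:
    """Expected per-fraction taxon proportions plus raw Gaussian mass."""

    proportions: np.ndarray  # taxa x fractions; non-empty columns sum to 1
    mass: np.ndarray  # taxa x fractions, unnormalized
    empty: np.ndarray  # bool per fraction

    @property
    def fraction_mass(self) -> np.ndarray:
        return self.mass.sum(axis=0)


def simulate_fraction_composition(
    scenario: SimScenario, isotope: str
) -> FractionComposition:
    """Expected taxon composition of every fraction of one bottle.

    For a labeled-substrate bottle (``isotope == "13C"``) each taxon's band
    center is shifted by ``atom_excess * label_shift``; in the unlabeled
    control all shifts are zero.  Within each density bin, a taxon's mass is
    its base abundance times the Gaussian probability of landing in the bin;
    proportions renormalize mass across taxa (columns of total mass below
    1e-12 are flagged empty and left at zero).
    """
    if isotope not in ("13C", "12C"):
        raise ValidationError(f"isotope must be '13C' or '12C', got {isotope!r}")
    shift = scenario.atom_excess * scenario.label_shift if isotope == "13C" else 0.0
    means = scenario.density_mean + shift
    edges = scenario.fraction_edges
    # P(edge_k < X <= edge_{k+1}) per taxon via the normal CDF
    cdf = norm.cdf(
        edges[np.newaxis, :], loc=means[:, np.newaxis],
        scale=scenario.density_sd[:, np.newaxis],
    )
    bin_mass = np.diff(cdf, axis=1)
    mass = scenario.base_abundance[:, np.newaxis] * bin_mass
    totals = mass.sum(axis=0)
    empty = totals < EMPTY_MASS
    props = np.zeros_like(mass)
    nz = ~empty
    props[:, nz] = mass[:, nz] / totals[np.newaxis, nz]
    return FractionComposition(proportions=props, mass=mass, empty=empty)


def simulate_reads(
    composition: np.ndarray, depth: int, rng: np.random.Generator | int
) -> np.ndarray:
    """One multinomial draw of ``depth`` reads per fraction column.

    ``composition`` is a taxa-by-fractions proportion matrix whose columns
    each sum to 1 within 1e-6.  Deterministic given the same generator state.
    """
    composition = np.asarray(composition, dtype=float)
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if np.any(composition < 0):
        raise ValidationError("proportions must be non-negative")
    sums = composition.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(
            f"column {bad} sums to {sums[bad]}, not normalized"
        )
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cols = []
    for j in range(composition.shape[1]):
        p = composition[:, j] / sums[j]
        cols.append(rng.multinomial(depth, p))
    return np.column_stack(cols).astype(np.int64)


@dataclass
class SimulatedExperiment:
    scenario: SimScenario
    fraction_counts: CountTable  # taxa x (bottle, fraction) samples
    fractions: list[FractionRecord]
    design: list[DesignRecord]
    pools: list  # list[fractionation.PooledSample]
    pooled_counts: CountTable  # taxa x (bottle, light/heavy) samples
    truth: set[str]  # taxa with atom_excess > 0

    @property
    def bottle_ids(self) -> list[str]:
        return [d.bottle_id for d in self.design]


def _bottle_layout(scenario: SimScenario) -> list[tuple[str, str, int]]:
    """(bottle_id, isotope, replicate) triples: labeled replicates first,
    then the single control.  Order fixes the sub-seed assignment."""
    layout = [
        (f"SIP13C-r{r}", "13C", r)
        for r in range(1, scenario.n_label_replicates + 1)
    ]
    layout.append(("SIP12C-r1", "12C", 1))
    return layout


def simulate_experiment(scenario: SimScenario) -> SimulatedExperiment:
    """Run the full forward model for one scenario; see module docstring."""
    scenario.validate()
    mids = scenario.fraction_midpoints
    classes = [fractionation.classify_fraction(m) for m in mids]
    if not any(c is fractionation.FractionClass.HEAVY for c in classes):
        raise UndefinedStatisticError(
            "no fraction midpoint classifies as heavy; RoOR would be undefined"
        )
    if not any(c is fractionation.FractionClass.LIGHT for c in classes):
        raise UndefinedStatisticError(
            "no fraction midpoint classifies as light; RoOR would be undefined"
        )
    layout = _bottle_layout(scenario)
    seeds = np.random.SeedSequence(scenario.seed).spawn(len(layout))
    sample_ids: list[str] = []
    columns: list[np.ndarray] = []
    fractions: list[FractionRecord] = []
    design: list[DesignRecord] = []
    for (bottle, isotope, replicate), seq in zip(layout, seeds):
        comp = simulate_fraction_composition(scenario, isotope)
        rng = np.random.default_rng(seq)
        counts = simulate_reads(
            comp.proportions[:, ~comp.empty], scenario.depth, rng
        )
        nonempty = np.where(~comp.empty)[0]
        for pos, frac_idx in enumerate(nonempty):
            index = int(frac_idx) + 1
            sample_ids.append(fractionation.fraction_sample_id(bottle, index))
            columns.append(counts[:, pos])
            fractions.append(
                FractionRecord(
                    bottle_id=bottle,
                    fraction_index=index,
                    density=float(mids[frac_idx]),
                    dna_concentration=float(comp.fraction_mass[frac_idx]),
                )
            )
        design.append(
            DesignRecord(
                bottle_id=bottle,
                isotope=isotope,
                substrate="CO2-bicarbonate",
                replicate=replicate,
                oxygen="anoxic",
                source_well="SIM",
                weeks=4,
            )
        )
    fraction_counts = CountTable(
        list(scenario.taxa), sample_ids, np.column_stack(columns)
    )
    pools = fractionation.pool_fractions(fraction_counts, fractions)
    pooled = fractionation.pooled_table(pools, scenario.taxa)
    return SimulatedExperiment(
        scenario=scenario,
        fraction_counts=fraction_counts,
        fractions=fractions,
        design=design,
        pools=pools,
        pooled_counts=pooled,
        truth=scenario.labeled_taxa,
    )
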