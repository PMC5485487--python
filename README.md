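# sipcall

Labeling detection for DNA stable-isotope-probing (SIP) gradient
experiments: classify CsCl-gradient fractions as light or heavy by buoyant
density, pool fraction-level 16S read counts per bottle, score heavy-fraction
enrichment with a per-bottle odds ratio and a ratio of odds ratios (RoOR)
against the unlabeled control, and profile/cluster the resulting communities.
A seeded forward simulator generates complete experiments with known labeled
taxa, so every stage is testable without sequencing data.

## Method in brief

For a taxon in one bottle, with pooled heavy/light read counts,

```
OR = (H_arc / H_narc) / (L_arc / L_narc)
```

where `H_arc` is the taxon's reads in the heavy pool, `H_narc` the remaining
heavy reads, and `L_arc`/`L_narc` the light-pool analogues. Only (taxon,
bottle) pairs with ≥ 5 reads in both pools are eligible. For each
labeled-substrate (13C) replicate bottle, `RoOR = OR_13C / OR_12C` against
the paired unlabeled control; `RoOR > 1` calls the taxon labeled in that
replicate. Per-taxon consensus is reported both ways (`labeled_any`,
`labeled_all`). Fractions below 1.715 g/mL are light, at or above
1.72 g/mL heavy; densities in between are excluded by default.

Sample clustering uses 1 − Pearson correlation between percent-abundance
profiles, squared-input Ward agglomeration, and plain bootstrap probabilities
from taxon resampling, exported as Newick.

## CLI

Each stage is a subcommand; `all` chains them on a simulated scenario:

```
sipcall all --out-dir run/ --seed 1 --boot 100
sipcall simulate --out-dir run/ --seed 1 --n-taxa 20 --n-labeled 2
sipcall pool     --counts run/counts.tsv --fractions run/fractions.tsv \
                 --light-max 1.715 --heavy-min 1.72 --out run/pooled.tsv
sipcall label    --pooled run/pooled.tsv --design run/design.tsv \
                 --min-reads 5 --threshold 1.0 --out run/labeling.tsv
sipcall profile  --counts run/pooled.tsv --out run/profile.tsv
sipcall cluster  --profile run/profile.tsv --boot 1000 --seed 42 \
                 --out run/tree.nwk
```

Exit codes: 0 success, 2 validation error, 3 undefined statistic (e.g. a
bottle with no heavy fractions). Reruns with identical configuration are
byte-identical; generated tables carry `#`-comment provenance stamps.

File formats (tab-separated, `#` lines ignored): `counts.tsv` (taxa ×
samples, integer reads; fraction-level sample ids are `<bottle>:<index>`,
pooled ids `<bottle>:light|heavy`), `fractions.tsv` (`bottle_id`,
`fraction_index`, `density`, `dna_concentration`), `design.tsv`
(`bottle_id`, `isotope`, `substrate`, `replicate`, `oxygen`, `source_well`,
`weeks`; every 13C condition group must have exactly one 12C control).

## Package layout

- `sipcall.io_tables` — TSV readers/writers with strict validation
- `sipcall.fractionation` — light/heavy classification and pooling
- `sipcall.sip_stats` — odds ratio, eligibility, RoOR, labeling calls,
  permutation chance-rate utility
- `sipcall.community_profile` — percent relative abundance, clade
  aggregation, shared-taxa queries
- `sipcall.clustering` — correlation distance, Ward linkage, bootstrap
  support, Newick export
- `sipcall.synthetic_data` — Gaussian-band gradient simulator with known
  ground truth
- `sipcall.cli` — subcommands and the end-to-end runner
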