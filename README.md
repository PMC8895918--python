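# clonostat

Similarity and diversity statistics for mouse B-cell receptor (BCR)
heavy-chain repertoires.

Inbred laboratory mice (BALB/c, C57BL/6J) are the workhorse of antibody
discovery and immunization studies, yet untreated individuals already
differ substantially in their BCR repertoires. Quantifying that
*baseline* disparity — per isotype (IgA/IgG/IgM) and per compartment
(blood, spleen) — is what this package is for: it tells a repertoire
study how much between-individual variation to expect before any
treatment signal can be claimed. Its users are immunologists and
bioinformaticians working with AIRR-style clone tables produced by a
clone caller (e.g. MiXCR) from IgH amplicon sequencing.

## What it computes

Given per-sample clone tables (V/D/J calls, CDR3 nucleotide and amino
acid sequences, duplicate counts), `clonostat` provides:

- **Isotype demultiplexing** of raw reads by isotype-specific primer
  matching: a read is assigned to the class whose second-round PCR
  primer has the fewest mismatches over the first 20 nt, below a
  mismatch budget (< 5 for the built-in in-house primer set, < 6 for
  the public IgM variant).
- **Qualified-clone filtering**: CDR3 ≥ 4 aa, no stop symbol, nt/aa
  lengths in frame; one technical replicate kept per sample by the
  larger-value rule.
- **Gene usage** frequency profiles pooled over V, D (including
  D-empty) and J segments, compared between samples by Pearson
  correlation.
- **Clonotype profile similarity** via the Morisita–Horn similarity
  index over CDR3 aa abundance vectors,

      MHSI = 2 Σᵢ pᵢ qᵢ / (Σᵢ pᵢ² + Σᵢ qᵢ²),

  where pᵢ, qᵢ are each sample's clonotype frequencies over the union
  of clonotypes.
- **Evenness** via the normalized Shannon diversity entropy,
  NSDE = −Σᵢ pᵢ ln pᵢ / ln N.
- **Richness and sequencing depth** via Chao1
  (S_obs + f₁²/2f₂, bias-corrected when f₂ = 0), with seeded
  rarefaction (subsampling without replacement in 1% clone increments,
  100 replicates) and Chao1-based extrapolation to 5× the sample size;
  coverage = 100 · S_obs / S_Chao1.
- **Clonal lineage networks**: CDR3 nt clonotypes sharing V gene, J
  gene and CDR3 length are linked at ≥ 95% nucleotide identity;
  connected components with ≥ 2 members are clonal lineages. Reported:
  mutated-clonotype ratio, node degree distribution (degrees pooled at
  8+), maximal degree, and the nearest-neighbor identity distribution
  that motivates the 95% cut-off.
- **Sharing between individuals**: occupancy spectra of clonotypes
  across mice, and cross-individual lineages (pooled over all samples
  of a strain × isotype, min 3 nodes) with per-sample presence
  trace-back, blood/spleen occupancy matrices, and lineage-abundance
  MHSI.
- **A synthetic repertoire generator** that plants all of the above
  structure (skewed abundance, mutation lineages, public clonotypes,
  tissue overlap, primer-tagged reads) with exact ground truth, so the
  whole pipeline is testable without any sequencing data.

## Worked example

```python
from clonostat import (SimConfig, simulate_repertoires, ClonotypeProfile,
                       mhsi, nsde, build_lineages, mutated_ratio,
                       rarefaction_curve, sharing_ratios)

cfg = SimConfig(n_individuals=3, tissues=("blood",), n_clonotypes=2000,
                isotype_props={"IgM": 1.0}, seed=42)
tables, truth = simulate_repertoires(cfg)

profiles = {m: ClonotypeProfile.from_records(df, level="aa")
            for (m, _, _), df in tables.items()}
print({m: round(nsde(p), 4) for m, p in profiles.items()})
print(round(mhsi(profiles["M01"], profiles["M02"]), 4))

rr = rarefaction_curve(profiles["M01"], reps=100, seed=0)
print(f"S_obs={rr.s_obs}  Chao1={rr.s_chao:.1f}  coverage={rr.coverage_pct:.1f}%")

net = build_lineages(tables[("M01", "blood", "IgM")])
print(f"{len(net.lineages)} lineages, mutated ratio {mutated_ratio(net):.1f}%")

by_mouse = {m: df for (m, _, _), df in tables.items()}
print({k: round(v, 2) for k, v in sharing_ratios(by_mouse).ratios.items()})
```

prints

```
{'M01': 0.9432, 'M02': 0.9418, 'M03': 0.9334}
0.0397
S_obs=1941  Chao1=4465.3  coverage=43.5%
133 lineages, mutated ratio 20.0%
{1: 96.32, 2: 0.0, 3: 3.68}
```

Reading: the three simulated IgM repertoires are individually even
(NSDE ≈ 0.94) but overlap little in clonotype composition (MHSI ≈ 0.04
between mice; ~96% of CDR3 aa clonotypes private to one mouse — only
the planted 10% public pool is shared by all three). Sequencing depth
covers ~44% of the Chao1-estimated richness, and exactly the planted
20% of clonotypes sit in somatic-mutation lineages.

The same analyses run from the shell:

```sh
clonostat simulate --out sim/ --seed 3 --n-clonotypes 2000
clonostat compare --inputs sim/M01_blood_IgM.tsv --inputs sim/M02_blood_IgM.tsv \
    --inputs sim/M03_blood_IgM.tsv --out analysis/
```

which writes per-subset diversity summaries, pairwise Pearson/MHSI
matrices, lineage tables, sharing spectra, occupancy matrices and a
`manifest.json` that fully determines the run.

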