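# Methods

This note documents the statistical procedures implemented in
`clonostat`, the choices made where a convention had to be fixed, and
what the synthetic-data generator does and does not emulate.

## Data model

A *clone* is one qualified rearrangement row: V/D/J gene calls, CDR3
nucleotide and amino-acid sequences, and a positive duplicate count,
annotated with sample metadata (mouse, strain, tissue, batch, isotype).
A *clonotype* aggregates clones sharing a CDR3 key — the aa sequence at
the "aa" level, or the (V gene, J gene, CDR3 nt) triple at the "nt"
level. Clone tables travel as pandas DataFrames and are stored as AIRR
rearrangement TSVs (`v_call`, `junction`, `duplicate_count`, ...) with a
configurable column mapping.

Qualification requires CDR3 ≥ 4 aa, no `*`/`_` stop symbol, and
`len(cdr3_nt) == 3 × len(cdr3_aa)`. The frame test is deliberately
local to the CDR3: full V(D)J frame accounting belongs to the upstream
clone caller, which this package consumes rather than replaces.
Dropped rows are tallied per rule, and filtering is idempotent.

## Isotype demultiplexing

Nested isotype-specific PCR places the second-round class primer at a
fixed position of one mate, so classification is positional: count
mismatches between each class primer and the first 20 nt of the read
(Hamming, no indels — the primer position is fixed by the library
design) and assign the class with the fewest mismatches if that count
is strictly below the budget (5 for the in-house three-primer set, 6
for the public IgM-only set, whose primer is located within read 2 and
the overhang before it trimmed). Primers may contain IUPAC degenerate
codes; a position matches when the read base lies in the code's set,
and the compared span is `min(window, len(primer))` (the in-house IgG
primer is 21 nt, so its last base is outside the 20-nt window).

Two conventions are ours: an exact mismatch tie between two classes is
discarded as unassigned (conservative; ties are not addressed by the
protocol the primer sets come from), and reads shorter than the window
are unassigned with a warning. With technical replicates, one dataset
per sample is kept — the one with the larger value of the chosen
criterion (total clones by default, unique clonotypes optionally);
exact ties break by lexicographic sample id for determinism.

## Diversity and similarity statistics

**Gene usage.** Frequencies are computed per segment class (V, D, J)
from clone counts (abundance-weighted; an unweighted per-clonotype mode
is available). Clones whose CDR3 contains no D segment contribute to an
explicit `D-empty` key, so the D block still sums to 1. Pairwise
gene-usage similarity is the Pearson correlation of the concatenated
V+D+J frequency vectors over the union of gene names (missing genes
enter as zero).

**Morisita–Horn similarity (MHSI).** For two clonotype profiles with
within-sample frequencies p and q over the union of clonotypes,
`MHSI = 2 Σ pᵢqᵢ / (Σ pᵢ² + Σ qᵢ²)` ∈ [0, 1]; 1 iff the frequency
vectors are identical, 0 iff supports are disjoint. Abundances default
to summed clone counts per clonotype. The union is iterated in sorted
key order so results are bit-reproducible across processes.

**Evenness (NSDE).** `−Σ pᵢ ln pᵢ / ln N` for N ≥ 2 clonotypes. For
N = 1 the normalizer vanishes; a single-clonotype repertoire has no
evenness, so the value is defined as 0 with a warning.

**Richness.** Chao1 = S_obs + f₁²/(2 f₂) from singleton/doubleton
counts, switching to the bias-corrected S_obs + f₁(f₁−1)/2 when
f₂ = 0; always ≥ S_obs. (Cross-checked in the test suite against
scikit-bio's estimator.) Coverage is 100 · S_obs / S_Chao1.

**Rarefaction/extrapolation.** Interpolation subsamples clones without
replacement at 1% increments with 100 replicates by default. Each
replicate permutes the expanded clone multiset once and reads richness
off prefixes; this is exact subsampling without replacement at every
increment, and because the draws are coupled across increments each
replicate's curve — hence the mean curve — is nondecreasing, which
independent per-increment draws would only satisfy in expectation. A
closed-form hypergeometric mode (`method="analytic"`) gives the exact
expected curve when speed matters. Extrapolation follows the standard
Chao1-based accumulation form
`S(n + m) = S_obs + f̂₀ (1 − (1 − f₁/(n f̂₀ + f₁))^m)` with
f̂₀ = S_Chao1 − S_obs, up to 5× the sample size. SEM is the bootstrap
SEM for interpolated points; for extrapolated points we report the
classic Chao1 variance propagated through the accumulation multiplier
(the two phases are labeled distinctly in the output).

## Clonal lineages

CDR3 nt clonotypes with identical V gene, J gene and CDR3 length are
grouped; percent identity is positional (`100 × matches / length`) and
only defined within a group. Each clonotype's *nearest neighbor* is its
highest-identity companion; the 2D histogram of clonotypes over (CDR3
length, nearest-neighbor identity, 1%-wide bins) is the calibration
plot that separates mutation-derived neighbors (≥ 95%) from the random
background (~55–90%).

The lineage network links same-group pairs at identity ≥ 95%
(inclusive; compared with 1e-9 slack so exact boundary ratios like
19/20 are never lost to floating-point rounding). Lineages are
single-linkage connected components with ≥ 2 members — the network
framing, not cliques. The mutated-clonotype ratio is the percentage of
distinct nt clonotypes belonging to any lineage. Degree statistics
come from the thresholded edge set: the distribution (pooled at 8+) is
over lineage members only, while the maximal degree is over all nodes
(isolated nodes have degree 0 and can only attain the max in an
edgeless sample).

## Sharing and cross-individual lineages

Clonotype sharing between the individuals of a strain × tissue ×
isotype group is presence/absence on clonotype identity, unweighted by
abundance: each distinct clonotype has an occupancy k (number of mice
carrying it) and the k-spectrum is normalized over the union of
clonotypes.

Cross-individual lineages pool all blood and spleen samples of one
strain × isotype, deduplicate clonotypes by (V, J, CDR3 nt), cluster
with the same lineage criteria, and keep components with ≥ 3 nodes
(≥ 5 as a sensitivity variant; both exposed). Each node is traced back
to every sample containing its exact (V, J, CDR3 nt) triple; a lineage
is present in a sample when at least one node traces there. Lineage
abundance in a sample is the summed within-sample node frequency
(clone count over the sample's total clone count); lineage-abundance
profiles of two samples are compared with the MHSI after normalizing
each profile. The occupancy matrix over (number of blood samples,
number of spleen samples) assigns each lineage to exactly one cell and
sums to 100%.

Group comparisons use the two-sided Wilcoxon rank-sum test (unpaired)
or signed-rank test (paired), exact null distributions for n ≤ 25 and
the continuity-corrected normal approximation beyond — group sizes in
this kind of study are small, so the exact branch is the common path.
All-zero paired differences carry no signal and report p = 1 with a
warning.

## Synthetic repertoires

The generator emits per-(mouse, tissue, isotype) clone tables plus a
ground-truth table (public flag and lineage id per row, true isotype
per read). It emulates:

- **skewed clonal abundance** — log-normal counts (σ = 1.2 by default;
  a Zipf option exists). NSDE of the simulated profiles decreases
  monotonically in σ, which the test suite checks over a sweep;
- **gene usage** — one strain-level V/D/J usage profile drawn from a
  Dirichlet (concentration 2.0) and shared by all individuals, so
  between-individual gene-usage Pearson correlation is high while
  clonotype-level overlap stays low, the configuration real baseline
  repertoires show;
- **CDR3s** — random non-stop codons, aa lengths 8–20 with mode 12
  (a triangular approximation of typical IgH CDR3 length spectra);
- **mutation lineages** — 20% of clonotypes by default, geometric size
  distribution (mean 3, minimum 2); each member carries 1..⌊0.05 L⌋
  substitutions from its ancestor, so every member stays ≥ 95%
  identical to the ancestor and single-linkage recovers the planted
  cluster exactly;
- **separability** — background sequences and lineage ancestors are
  rejection-sampled to stay below 80% identity to every earlier member
  of their (V, J, length) group. Since mutants drift ≤ 5%, no mutant
  can reach 95% identity to anything outside its own lineage
  (80 + 5 + 5 < 95 at the boundary), so lineage recovery is exact by
  construction (adjusted Rand index 1.0), not merely likely. Random
  nucleotide sequences have ~25% expected pairwise identity, so the
  rejection step almost never triggers and exists as a guarantee, not
  a workload;
- **publicness and tissue overlap** — a public pool (10% of the
  per-sample clonotype budget) included in each individual with
  configurable probability (1.0 by default, giving a clean
  occupancy-equals-all spectrum; partial inclusion yields the
  conditioned-binomial occupancy the tests verify), and a 30%
  blood/spleen background overlap within each individual;
- **reads** — one read pair per clone row, read 1 carrying the
  isotype's primer (degenerate codes resolved to a matching base) with
  per-base error injection; the ground truth records the realized
  mismatch count and the label a thresholded classifier should
  produce.

Defaults are desk-scale: 2000 clonotypes per subset (10⁴ in the
recovery checks), well below the 10⁵–10⁶ clones of real datasets; a
single `n_clonotypes` knob scales up. What passing tests show is that
the statistics and the clustering are implemented correctly and
recover planted structure exactly under the generator's assumptions.
What they do not show: robustness to clone-caller errors, allele-level
germline variation, junctional P/N-nucleotide structure, selection, or
class-switch dynamics — none of which the generator models.

## Numerical choices and edge cases

- Identity thresholding uses a 1e-9 tolerance; percent identity is
  exact rational arithmetic otherwise.
- MHSI/NSDE/Chao1 raise on empty profiles; rarefaction requires at
  least one clone per increment (≥ 100 clones at the 1% default).
- Degenerate gene-usage vectors (zero variance) raise rather than
  return NaN.
- All random procedures (subsampling, simulation) take explicit seeds
  and are bit-reproducible; derived seeds stay below 2³¹.
- Technical-replicate and tie-break rules are deterministic (documented
  above) so pipeline re-runs are byte-identical.

## Known limitations

- Lineage inference is Hamming-within-equal-length only; indel-bearing
  mutants (Levenshtein-type metrics) are out of scope by design.
- The rarefaction model is individual-based (one draw per sample);
  sample-based multi-draw richness designs are not implemented.
- Chao1 is the only richness estimator; Hill numbers of order q > 0
  are not computed.
- The generator's lineage members co-occur within a sample; lineages
  spanning individuals arise only through tissue overlap, so
  cross-individual lineage occupancy on synthetic data is sparser than
  in real repertoires.
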