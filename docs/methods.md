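# Methods

This note documents the models, estimators and numerical choices behind
`coevonet`, and what the synthetic benchmarks do and do not demonstrate.

## Inverse-Potts contact energies

Aligned family sequences are modelled as equilibrium samples of a
pairwise Potts model over q = 21 states (20 residues, gap as the 21st).
The inference is the classic mean-field inversion:

1. **Filtering.** Sequences with ≥ 30 % gaps are removed (strict "< 30 %
   retained").  For building dated sequence sets, one sequence per
   organism is kept (fewest gaps wins) and the set is greedily pruned —
   dropping the most-gapped sequence, ties towards later input order —
   until every pair's union-gap fraction is below 20 %.  The greedy rule
   is a deterministic reading of the pairwise mutual-gap requirement.
2. **Reweighting.** Each sequence s gets weight 1/|{t : identity(s,t) >
   0.70}| (neighbourhood includes s).  Identity is computed over all
   columns with gap–gap positions counting as matches — the common
   reweighting convention; computed via one-hot matrix products.
   M_eff = Σ w.
3. **Frequencies with pseudocounts.** With weighted counts n_i(σ),
   weighted alignment composition c(σ) and site composition
   c_i(σ) = n_i(σ)/M_eff,

       f1(i,σ) = [n_i(σ) + x·M_eff/21 + y·M_eff·c(σ) + z·M_eff·c_i(σ)]
                 / [M_eff·(1+x+y+z)],

   with x = 0.5 (uniform), y = 0.1 (alignment composition), z = 1.0
   (site composition).  All three masses scale with M_eff, so x, y, z are
   dimensionless.  The two-site pseudocount mass is the product of the
   one-site pseudocount distributions; this factorisation makes the
   f2 → f1 marginalisation exact (a tested invariant).  Site compositions
   use the weighted alignment.  Diagonal blocks are set to
   f2(i,i,σ,ρ) = δ_σρ f1(i,σ).
4. **Mean-field inversion.** The connected-correlation matrix
   C = f2 − f1⊗f1 restricted to the 20 non-gap states is inverted as an
   (N·20)×(N·20) matrix; the off-diagonal blocks of C⁻¹ are the couplings
   ε_ij(σ,ρ), embedded into 21 states with zeros for every gap entry and
   for the i = j blocks.  Inverting in the gap-excluded space realises
   the gap gauge by construction; `apply_gap_gauge` exists separately for
   externally supplied tensors (ε′ = ε − ε(σ,gap) − ε(gap,ρ) +
   ε(gap,gap), with the gap rows/columns then set exactly to zero).
5. **Sign convention.** ε = +C⁻¹ makes pairs that co-occur above
   independence *negative* (attractive), verified against an
   exact-enumeration two-site oracle; lower projected energies mean more
   stable proteins.

No regularisation is applied beyond the pseudocounts; a singular
correlation matrix raises an error advising larger pseudocount masses
rather than being silently ridged.

**Gauge anchoring needs gap statistics.** The zero of energy is the
interaction with an absent residue.  If the inference alignment is
completely gap-free, the gap state has no data support, the 20-state
correlation block is nearly singular, and the gauge zero becomes a
pseudocount artefact with offsets that grow as the pseudocounts shrink
(verified by exact enumeration).  Family alignments therefore must carry
their natural gap content; only the projected (reconstructed-style)
sequences are gap-free.  The synthetic sampler injects 10 % gaps into
inference alignments by default for exactly this reason.

## Contacts and projection

Two residues are in contact when their Cβ atoms (Cα for glycine; Cα also
serves as fallback when a Cβ is missing) are strictly closer than 6.5 Å
and at least `min_separation = 2` apart along the chain (|i−j| = 1
backbone neighbours carry no folding information; the separation is
configurable).  The tensor is zeroed outside native contacts; projecting
it on one sequence gives e(i,j) = ε_ij(σ_i, σ_j), with gapped positions
contributing zero through the gauge.  The energy matrix records its
contact support explicitly, so a genuinely zero-energy contact still
counts in denominators.

## Strongly attractive and frustrated contacts

ε_th is the empirical 5 % quantile (exact order statistic, no
interpolation) of pooled *null* contact energies.  The null is the column
bootstrap: every alignment column independently permuted across sequences
— one-site frequencies preserved bit-exactly, inter-site correlations
destroyed — with the **full** pipeline (reweighting, frequencies,
inversion, filtering, projection) rerun on the bootstrap replicate.
Thresholding uses strict inequalities on both sides: attractive e < ε_th,
frustrated e > 0; zero-energy contacts are neither.  A built-in
sensitivity report reruns the fractions and network statistics over a
grid of thresholds.

Interaction networks take all N residues as nodes and the qualifying
contacts as edges.  "Cluster" means connected component; LCS is the
largest component size over N; orphans are degree-0 nodes.  The
clustering coefficient is the mean local clustering over nodes of degree
≥ 2 (degree < 2 nodes excluded rather than counted as zero); global
transitivity is available as an option.  Random-graph references use
uniform G(n, m) graphs with matching node and edge counts.

## Frustration exponent

For a contiguous segment of length L, the interfacial energy E is the
signed sum of contact energies crossing the segment boundary — signed,
because the cancellation between attractive and repulsive contributions
across the cut is precisely what distinguishes a frustrated system.
E²(L) is averaged over all N−L+1 windows and divided by L²; α is minus
the slope of log E²(L)/L² against log L over the fit range.

**Fit range.** The exponent measures energy compensation only where the
cut area (the number of crossing contacts) grows proportionally to L.
That holds exactly while L stays below the shortest contact separation of
the map; beyond it contacts start falling inside the window and the curve
drops for purely geometric reasons — on compact lattice chains a
uniformly attractive (frustration-free) matrix would otherwise read
α ≈ 0.5.  The default fit range is therefore [1, max(3, s_min)] with
s_min the minimum contact separation (s_min = 3 on the lattice maps);
with it, the ferromagnetic limit measures α ≈ 0.03 and i.i.d. random
energies α ≈ 1, the two calibration anchors.  An explicit fit range and
an automatic mode (extend the upper bound while the log-log R² stays
≥ 0.9) are available, and α is always reported together with the fit
range used.  α and the frustrated fraction f are positively associated
across a mixing family of energy matrices but are distinct statistics —
α also reflects the spatial arrangement of the frustrated contacts.

## Trend statistics

Ages are My before present (extant = 0); regressions use the forward
time coordinate t = −age, so a positive slope means the quantity
increases towards the present.  Significance of the OLS slope comes from
a two-sided permutation test (the value↔age pairing is reshuffled,
preserving both marginals; p = (1 + #{|slope*| ≥ |slope|})/(n_perm + 1),
add-one correction so p > 0; default 10⁵ permutations).  Monotonicity
uses Kendall's tau-b with tie correction (exact enumeration for small
tie-free samples, normal approximation otherwise).  The permutation test
is calibrated: empirical type-I error 0.05 ± 0.02 at nominal 5 % over 500
simulated null datasets (a tested property).  Proteins are treated as
independent points; no phylogenetic correction is applied.

## Synthetic data: what it emulates, and what it does not

`make_planted_model` lays a self-avoiding chain on a cubic lattice
(5 Å spacing: lattice neighbours fall inside the 6.5 Å cutoff, everything
else outside), starting from a boustrophedon fill and randomised with
backbite moves so the chain mixes through the compact volume like a real
globule.  Each site gets a primary residue (single-site field of depth
0.5) and a secondary residue.  Attractive contacts place −2 (evolutive
temperature units) on both phase-consistent pairings (primary–primary and
secondary–secondary), so sequences switch between them by compensatory
double mutations — the covariation signal the inference feeds on.  A
`frustration_mix` fraction of contacts instead places +2 on the same
pairings: whichever phase the surrounding attractive network holds the
sites in, the repulsion is realised, emulating unfavourable interactions
evolution cannot remove without breaking the stabilising structure.

`sample_potts_msa` runs one independent Gibbs chain per output sequence
(50 burn-in sweeps by default) at unit temperature, then injects 10 %
gaps (see gauge anchoring above).  `evolve_on_tree` builds a random
ultrametric topology with evenly spaced merge ages, equilibrates the root
at the selection strength prevailing at the root age, and evolves
sequences by Metropolis-accepted point mutations at Poisson event times;
the inverse selection temperature β(age) is the control knob
(neutral: β = 1; destabilising: β from 2.5 at the root to −0.5 at the
present; stabilising: the mirror).  `write_fixture_structure` emits a
synthetic PDB whose Cβ geometry reproduces the contact map exactly
(CA and CB coincide on the lattice coordinate — a geometric fixture, not
a physical model).

What passing the synthetic benchmarks shows: the inference recovers
planted contacts (precision ≈ 1 at M = 5000), the threshold calibration
is definitionally exact, planted stability trends are recovered with the
correct sign and significance, and the detected frustrated fraction rises
with the planted one in expectation.  What it does not show: performance
under real-family conditions — phylogenetic sequence correlations,
heterogeneous gap patterns, structural divergence across the family,
reconstruction uncertainty in ancestral sequences, and functional
constraints outside the pairwise model are all absent from the generator.
Per-contact localisation of frustration is intrinsically weak under
mean-field inference at these sample sizes: the realised-combination-
weighted mean of an inferred contact block is close to zero, so single
frustrated contacts are detected in aggregate, not individually.

## Defaults

| parameter | default | role |
| --- | --- | --- |
| max_gap | 0.30 | per-sequence gap filter (strict <) |
| identity_threshold | 0.70 | reweighting neighbourhood |
| mutual_gap | 0.20 | pairwise union-gap bound for representatives |
| x, y, z | 0.5, 0.1, 1.0 | pseudocount masses |
| cutoff | 6.5 Å | contact distance (strict <) |
| min_separation | 2 | minimum chain separation of contacts |
| null_quantile | 0.05 | strongly-attractive calibration level |
| n_boot | 100 000 | permutations for the slope test |
| coupling_strength / site_field | 2.0 / 0.5 | planted model energies |
| n_sweeps | 50 | Gibbs burn-in per sampled sequence |

Benchmark problem sizes (N = 30 residues, M = 2000 sequences, five
families for the threshold pool, 100-residue chains for the scaling
anchors, 26-leaf trees) were chosen so the full pipeline exercises every
stage at desk scale while keeping each run in seconds to minutes.

## Known limitations

* Mean-field inversion overestimates strong couplings (≈ 10–20 % at
  |ε| ≈ 0.4 in the two-site oracle) and degrades at highly conserved
  sites, where connected correlations vanish.
* The gap gauge inherits the alignment's gap statistics; families with
  very few gaps have a soft energy zero.
* The frustration exponent's default fit range contains only a few
  segment lengths on short-separation contact maps, so per-protein α
  values are noisy; they are meant to be compared across proteins and
  ages, not interpreted absolutely.
* Homology modelling, ancestral reconstruction and divergence-time
  estimation are out of scope; the pipeline consumes their outputs
  (structures or contact maps, dated sequences) as inputs.
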