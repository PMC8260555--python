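# coevonet

Coevolutionary contact energetics of protein families along evolutionary
time: mean-field inverse-Potts contact energies, calibrated detection of
strongly attractive contacts, residue interaction networks, interfacial-
energy frustration, and trend tests of all of these against protein age.

## The scientific problem

Homologous protein sequences can be treated as equilibrium samples of a
Potts model over the 21 alignment states (20 amino acids + gap): residue
pairs that interact strongly in the native structure mutate in a
correlated way across the family.  Inverting the observed correlations
yields a family-wide interaction tensor ε<sub>ij</sub>(σ, ρ) — the energy,
in units of the evolutive temperature, of hosting residues σ and ρ at
positions i and j.  Projecting the tensor on any one sequence (extant or
ancestrally reconstructed) and keeping only native contacts (Cβ–Cβ < 6.5 Å,
Cα for glycine) gives that protein's contact-energy matrix, from which the
package computes:

* **E<sub>N</sub>** = Σ<sub>i&lt;j</sub> ε<sub>ij</sub> — the native energy;
  lower means more stable.
* **a** — the fraction of *strongly attractive* contacts, those below a
  threshold ε<sub>th</sub> calibrated so that 5 % of null-model contact
  energies (from column-bootstrapped alignments pushed through the full
  inference pipeline) fall below it.
* **f** — the fraction of *frustrated* contacts, ε<sub>ij</sub> > 0 under
  the gap gauge (interactions with the gap state define the zero of
  energy).
* **α** — the Anderson frustration exponent: the mean square interfacial
  energy E²(L) between chain segments of length L and the rest of the
  protein, normalised by L², decays as 1/L<sup>α</sup>; α = 0 for a
  frustration-free (ferromagnetic-like) system, larger α means more
  frustration.
* Interaction-network statistics — largest-cluster size (LCS), orphan
  fraction, clustering coefficient — of the networks whose edges are the
  strongly attractive (or frustrated) contacts.
* Trends of any of these against protein age (My before present): OLS
  slope, a two-sided permutation p-value on the slope, and Kendall's
  tau-b.  Slopes are reported against forward time, so a positive
  E<sub>N</sub> slope means destabilisation towards the present.

Because real analyses of this kind require family alignments, native
structures and dated ancestral reconstructions, the package ships a
synthetic-data module that generates all inputs with known ground truth:
compact lattice-chain contact maps, planted Potts models with attractive
and frustrated couplings, Monte-Carlo equilibrium alignments, and dated
sequence sets evolved along a tree under a controllable selection
schedule.  The whole pipeline runs without any download.

## Worked example

Simulate a family whose selection pressure relaxes towards the present
(a planted destabilising trend), then run the full analysis:

```bash
coevonet simulate --n-residues 30 --n-seq 1000 --n-leaves 13 \
    --schedule destabilising --seed 42 --out demo
cat > demo/config.txt <<EOF
alignment = demo/alignment.fasta
dated_sequences = demo/dated.fasta
dated_metadata = demo/dated_metadata.tsv
contact_map = demo/contact_map.tsv
output_dir = demo/out
family = demo
n_boot = 10000
seed = 0
EOF
coevonet all --config demo/config.txt
```

which prints:

```
INFO coevonet: family=demo M=998 M_eff=998.0 N=30
INFO coevonet: native contacts: 30 (cutoff 6.50 Å)
INFO coevonet: eps_th=-0.7689 from 29940 pooled null energies
eps_th = -0.768917
       quantity  slope_per_My  p_bootstrap  kendall_tau  p_kendall  n
            E_N      0.007252     0.000100     0.609830   0.000085 25
              a     -0.000027     0.000400    -0.653165   0.000156 25
              f      0.000295     0.000100     0.728380   0.000006 25
          alpha      0.000506     0.000100     0.562617   0.000288 25
            lcs      0.000001     0.816718    -0.008139   0.964113 25
orphan_fraction      0.000057     0.000200     0.701365   0.000034 25
     clustering           NaN          NaN          NaN        NaN 25
```

Reading the table: across the 25 dated proteins (13 extant + 12
ancestors), the native energy rises towards the present at
+0.0073 per My (permutation p = 10⁻⁴, Kendall τ = 0.61) — the pipeline
recovers the planted destabilising trend.  The strongly-attractive
threshold calibrated from the column-bootstrap null is ε_th = −0.77, and
the fraction of strongly attractive contacts *a* falls while the
frustrated fraction *f* and the frustration exponent α rise, as expected
when selection for stability weakens.  A NaN row means the quantity was
constant across proteins, so no trend is defined.  Per-protein tables,
age-binned per-site profiles (E_i and f_i) and random-graph null
references are written under `demo/out/`.

The library API mirrors the stages (`read_alignment`, `compute_weights`,
`count_frequencies`, `infer_couplings`, `contact_map_from_structure`,
`project_energies`, `calibrate_threshold`, `build_network`,
`scaling_exponent`, `trend_result`, …); every CLI subcommand is a thin
wrapper over it.

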