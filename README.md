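# tetragam

Tetraploid meiosis analysis for a duplex (AAMM) × nulliplex (AA) cross.

A doubled-diploid parent of interspecific origin produces diploid gametes
whose genotypes can be read directly off the allele doses of its triploid
progeny (the other parent contributes a single alternative allele). From
such dose data `tetragam`:

- calls allele doses from raw two-channel fluorescence signals using
  control-anchored theta angles (`tetragam.calling`);
- validates, QC-filters and de-duplicates dose matrices, and infers
  diploid-gamete genotypes (`tetragam.data`);
- estimates per-chromosome preferential pairing (PP), the tetrasomic rate
  (τ = 1 − PP) from centromeric loci, and double reduction (β ≤ 1/6) from
  telomeric loci by closed-form maximum likelihood, plus parental
  heterozygosity restitution (PHR) summaries (`tetragam.inheritance`);
- tests segregation distortion (allele vs 1:1, homozygote excess, 1:4:1
  genotype fit) (`tetragam.segregation`);
- profiles crossovers via graphical genotypes and genome-composition
  summaries (`tetragam.recomb`);
- builds a simplified tetraploid linkage map: pairwise recombination
  fractions by ML under the random-pairing two-locus model, LOD and
  independence-LOD grouping, isomap/MDS marker ordering, Kosambi distances,
  and Marey/synteny diagnostics (`tetragam.linkage`);
- clusters gametes by Euclidean dose distance with a neighbor-joining tree
  in newick format (`tetragam.diversity`);
- simulates the whole design — locus-wise draws from the single-locus model
  or whole-meiosis simulation with Poisson crossovers, preferential pairing
  and approximate double reduction — including noisy fluorescence signals
  (`tetragam.sim`).

## Model

At a duplex locus, with probability PP meiosis pairs strictly homologous
chromosomes and the gamete is heterozygous (AM); with probability τ = 1 − PP
the three bivalent configurations are equally likely, giving 1 AA : 4 AM :
1 MM. Double reduction occurs within the random-pairing fraction at relative
frequency β (max 1/6) and yields AA or MM equally often:

    p_AM = PP + τ·(2/3)·(1 − β)
    p_AA = p_MM = τ·((1 − β)/6 + β/2)

which gives the closed-form estimators τ̂ = 3·f_hom (centromeric loci,
β = 0) and β̂ = (3·f_hom/τ − 1)/2 (telomeric loci, τ fixed).

## CLI

Run the full pipeline from a JSON config (simulated or file-based input):

```sh
tetragam run --config config.json --out outdir --seed 1 --log-level INFO
```

Minimal simulated config:

```json
{"simulate": true,
 "sim": {"preset": "giant_key", "mode": "chromosome_wise"},
 "lod_threshold": 5.0}
```

File-based input replaces `simulate` with `"dose_matrix": "doses.tsv"` and
`"markers": "markers.tsv"` (or `"signals"`/`"controls"` CSVs for theta-based
dose calling). The output directory receives the QC report, gamete matrix,
PHR/inheritance/distortion tables, crossover and run-length tables, the
pairwise linkage table, genetic map, Marey data, newick tree and a
deterministic `summary.json`.

Generate a simulation bundle (dose + gamete matrices, truth JSON):

```sh
tetragam simulate --config sim.json --out simdir --seed 7
```

`sim.json` is either `{"preset": "giant_key", ...}` or an explicit list of
chromosomes with `pp`, `beta_telomeric`, marker counts and lengths.

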