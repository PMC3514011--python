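# thermoclade

**COI phylogeography and thermal-niche segregation analysis for cryptic
marine invasions.**

Invasive fouling organisms often turn out to be complexes of genetically
deep, morphologically indistinguishable lineages ("cryptic invasions").
Whether those lineages sort into different ranges — and whether sea-surface
temperature (SST) explains the sorting — is a question that combines
mitochondrial barcoding (COI), population genetics and spatial statistics.
`thermoclade` packages that full analysis as a tested, reusable pipeline,
built around the *Watersipora* bryozoan system but applicable to any study
with aligned COI sequences, a site-occurrence table and (optionally) zooid
morphometrics.

## What it computes

| stage | statistic |
| --- | --- |
| `seq_core` | haplotype collapsing (with set-wide masking of ambiguous columns), base composition, alignment windows |
| `distances` | Kimura 2-parameter distances `d = -½ln(1-2P-Q) - ¼ln(1-2Q)` with pairwise deletion; within/between/net clade divergence `d_net = d_between - (d_within,X + d_within,Y)/2` |
| `popgen` | diversity indices (n, K, S, S/n, π ± sd, D); Tajima's `D = (π̂ - S/a₁)/√(e₁S + e₂S(S-1))` with a fixed-S neutral-coalescent null; hierarchical AMOVA (Φ_ST, Φ_SC, Φ_CT) with permutation tests; pairwise Φ_ST |
| `network` | median-joining haplotype networks (ε-relaxed minimum spanning network plus consensus median vectors) with a statistical-parsimony 95 % connection limit |
| `thermal` | colony-count-weighted median SST per clade with percentile-bootstrap CIs; rank-based partial Mantel tests `r = (r_AB - r_AC·r_BC)/√((1-r_AC²)(1-r_BC²))` of clade occurrence vs SST, corrected for spatial distance |
| `morphometrics` | log₁₀ zooid/orifice-area ANCOVA (group and slope-heterogeneity F-tests) and zooid-length vs SST regression |
| `synthetic_data` | coalescent sequence, thermal-niche occurrence and zooid generators used to calibrate every stage |

The package ships a transcription of the *Watersipora* occurrence table
(63 rows: region, site, coordinates, mean annual SST, COI phylogroup,
colony count) as `thermoclade/data/watersipora_table1.csv`.

## Worked example

```python
>>> import thermoclade as tc
>>> table = tc.load_sample_table()          # packaged occurrence table
>>> tc.weighted_median_sst(table, "new_sp").median_sst
11.8
>>> tc.weighted_median_sst(table, "subovoidea").median_sst
26.0
>>> sub = table.restrict(["arcuata", "A"])
>>> res = tc.partial_mantel(
...     tc.clade_indicator_matrix(sub, "arcuata"),
...     tc.sst_distance_matrix(sub),
...     tc.geo_distance_matrix(sub),
...     permutations=10000, seed=1)
>>> round(res.r, 4), res.p < 0.001
(0.0943, True)
```

The two medians say the *W.* n. sp. phylogroup occupies cold sites
(median 11.8 °C of 108 colonies) while *W. subovoidea* occupies tropical
ones (26.0 °C of 23 colonies).  The partial Mantel r of 0.094 (p < 0.001,
10 000 matrix permutations, colony units, ranked) shows that *W. arcuata*
and *W. subtorquata* clade A occupy statistically distinguishable SST
regimes even after removing the effect of spatial proximity.

The same analyses are available from a shell:

```bash
thermoclade thermal --group new_sp --seed 1 --out out/
thermoclade simulate --seed 7 --out sim/       # full synthetic dataset
thermoclade amova --fasta sim/sequences.fasta --populations sim/clades.csv \
    --permutations 5000 --seed 1 --out out/
```

Every subcommand writes tidy CSV plus a `manifest.json` recording inputs,
parameters and the seed, sufficient to re-run the command bit-identically.

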