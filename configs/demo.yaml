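# Bundled demo: 200-kb synthetic genome, three genotypes, two replicates.
# All sim values omitted here fall back to the generator defaults, which
# encode the study conditions (depth 100 reads/bin, NB dispersion 1000,
# planted feature/expression/orientation enrichment effects).
sim: {}
engine: vi
draws: 500
mutation_draws: 1000
n_boot: 2000
reference_genotype: WT
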