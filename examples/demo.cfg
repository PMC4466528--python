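# Demo: two-genome simulated community, full pipeline in ~1 minute.
#   ghrecover run-all --config examples/demo.cfg --seed 3 --outdir out/

[defaults]
# the standard operating point; listed explicitly for visibility
recruit_evalue_max = 1e-2
genetic_code = 11
min_overlap_len = 40
min_overlap_identity = 0.90
min_contig_len = 1000
validation_min_identity = 0.95
rng_seed = 3

[simulate]
n_genomes = 2
genome_len = 6000
genes_per_genome = 1
n_reads_per_sample = 1000
rng_seed = 3
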