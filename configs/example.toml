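# Example end-to-end study configuration.
#
# Run with:  azsearch run --config configs/example.toml
# (This example is scaled down; raise n_individuals / n_replicates for a
# full-size study.)

[data]
# "synthetic" generates the panel below; "vcf" reads the paths instead.
source = "synthetic"
# genotypes = "path/to/genotypes.vcf"     # phased GT fields
# posteriors = "path/to/posteriors.vcf"   # AP1/AP2 FORMAT fields

[simulate]
n_individuals = 300
n_loci = 18
alleles_min = 6
alleles_max = 14
frequency_concentration = 1.0
accuracy = 0.9                 # imputation fidelity in [0, 1]
posterior_concentration = 20.0

[search]
reference_fraction = 0.6
n_replicates = 10
base_seed = 0
schemes = ["true", "called", "expected"]

[hl]
max_exact_pairs = 50000000     # Walsh pairs enumerated exactly up to here
n_subsample = 10000000         # seeded uniform pair sample beyond the cap

[output]
directory = "results/example"

# Provenance metadata is carried through to the resolved config untouched.
# The block below archives the settings of the upstream imputation engine
# whose output (AP fields) this pipeline consumes; the pipeline itself never
# runs imputation.
[provenance.beagle]
version = "5.4"
impute = true
ap = true
gp = true
imp-states = 1600
imp-segment = 6.0
imp-step = 0.1
imp-nsteps = 6.0
cluster = 0.005
ne = 100000
window = 40.0
overlap = 2.0
seed = -99999
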