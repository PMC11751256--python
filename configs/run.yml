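# Full-pipeline run configuration (flags override these values).
# Omit input_dir to simulate a dataset with the given seed instead.

# input_dir: results/synthetic_dataset
out_dir: results
seed: 1
alpha: 0.05
n_perm: 999

mcmc_chains: 4
mcmc_iterations_headwidth: 3000
mcmc_iterations_env: 4000
backend: conjugate          # conjugate | emcee

magnitude: abs              # FA-size transform: abs | square | signed
downweight: true            # rare-species downweighting before ordination
covariables: [month, air_temp]
# env_variables: [herbs, litter]   # override the Layer-1 selection
layers: [layer1, layer2, layer3]
min_cohort_n: 5
simulate_n_per_cell: 2
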