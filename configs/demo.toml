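# Demonstration run: the full study design at reduced analyte counts so the
# whole pipeline (simulate -> preprocess -> diversity -> differential ->
# network) completes in seconds.  Thresholds are the analysis defaults.

seed = 0

[simulate]
planted_demo = true
noise_sd = 2.0

[simulate.n_analytes]
blood_cells = 12
colonic_cells = 12
fecal_microbes = 30
colonic_microbes = 25

[diversity]
n_permutations = 99
use_tree = true

[diversity.rarefy_depths]
fecal_microbes = 17401
colonic_microbes = 5458

[network]
min_prevalence = 24
fdr = 0.05
slope_p = 0.005
dffits = 2.0
skew = 3.0
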