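"""Tune the wavelet-kernel parameters and the neuron count with the GA.

Each candidate is a 20-bit chromosome (4 bits each for w, x, y in 1..16 and
8 bits for the neuron count in 5..260); fitness is the training accuracy of
the center-subset wavelet-kernel ELM the chromosome decodes to.
"""

from wkelm import GAConfig, SimConfig, ga_optimize, simulate_dataset

ds = simulate_dataset(SimConfig(n_samples=150, effect_size=1.2, seed=2))

config = GAConfig(population_size=40, generations=15, seed=0)
result = ga_optimize(ds.features, ds.labels, config, E=1.0)

p = result.best_params
print(f"best parameters: w={p.w}, x={p.x}, y={p.y}, n_hidden={p.n_hidden}")
print(f"best training accuracy (fitness): {result.best_fitness:.4f}")
print(f"model fits performed: {result.evaluations}")
print("generation  best    mean")
for gen, (best, mean) in enumerate(result.history):
    print(f"{gen:>10}  {best:.4f}  {mean:.4f}")
# with elitism the best column never decreases; the mean column shows the
# population catching up as selection concentrates on good kernels
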