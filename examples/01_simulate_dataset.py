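"""Generate a synthetic two-state expression dataset with planted key regulators.

Each of the 50 regulators drives 3-20 target genes (target = regulator
expression + Gaussian noise); the first 5 regulators additionally carry a
mean shift between the two sample groups, making them ground-truth key
regulators for the rest of the pipeline.
"""

from keyreg import SimulationSpec, downsample, simulate_regulators

spec = SimulationSpec(
    n_samples=40,
    n_regulators=50,
    n_bona_fide=5,
    targets_min=3,
    targets_max=20,
    effect_size=2.0,
    seed=1,
)
ds = simulate_regulators(spec)
print(f"genes: {ds.expression.n_genes} "
      f"(= {spec.n_regulators} regulators + their targets)")
print(f"samples per group: {ds.expression.groups.value_counts().to_dict()}")
print(f"planted key regulators: {ds.truth}")

small = downsample(ds, 10, seed=2)
print(f"after down-sampling to 10 samples: "
      f"{small.expression.groups.value_counts().to_dict()}, "
      f"gene set unchanged: {small.expression.n_genes == ds.expression.n_genes}")
# The gene count is the fixed regulator count plus one uniform draw of
# targets per regulator, so it varies seed to seed around its expectation.
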