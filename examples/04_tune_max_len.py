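"""Cross-validated selection of the maximum shapelet length.

The only hyper-parameter worth tuning per dataset is max_len, which
combats overfitting. For each value in {M/4, M/2, 3M/4, M} a reduced-
budget evolution is run and the 3-fold cross-validated log loss of the
ridge logistic regression on the resulting transform is compared.
"""

from shapevo import EvolutionConfig, make_motif_two_class, tune_max_len

# the discriminative motif has length 10 = M/4; longer shapelets only add noise
data = make_motif_two_class(n_per_class=10, length=40, motif_length=10, noise=0.2, seed=3)

chosen = tune_max_len(
    data,
    EvolutionConfig(seed=0, patience=4),
    budget_population=16,
    budget_generations=10,
)
print(f"series length M = {data.min_length}, implanted motif length = 10")
print(f"selected max_len = {chosen}")
# Expected: a value below M (usually 10 or 20) — the cross-validated loss
# favors shapelet lengths near the true motif scale.
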