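"""Fit growth models on a synthetic training pool and cross-validate them.

Generates genomes with planted doubling times, computes their codon-usage
features, fits the whole-sample-background (mmv1) and bias-corrected (mmbc)
Box-Cox models, and compares random k-fold with phylum-blocked
cross-validation (blocking controls for shared codon-preference ancestry).
"""

import warnings

import cubgrowth as cg

warnings.simplefilter("ignore", cg.CubgrowthWarning)

pool = cg.synthesize_pool(n_genomes=60, n_clusters=4, gc_range=(0.3, 0.7), seed=1)
table = cg.training_table_from_pool(pool, seed=2)

feats = cg.features_from_frame(table)
y = table["doubling_time_h"].to_numpy()
for mode in ("mmv1", "mmbc"):
    model = cg.fit_growth_model(feats, y, mode=mode)
    print(
        f"{mode}: lambda={model.lam:+.2f} intercept={model.intercept:.3f} "
        f"coefficients={ {k: round(v, 3) for k, v in model.coefficients.items()} } "
        f"R^2={model.training_metadata['r_squared']:.2f}"
    )

for scheme in ("random-kfold", "blocked-by-phylum"):
    cv = cg.cross_validate(table, scheme=scheme, mode="mmbc", seed=3)
    print(f"{scheme}: mean CV MSE (Box-Cox scale) = {cv['mse'].mean():.3f}")
# Blocked CV is usually harder than random CV: whole preference clusters are
# held out, so the model cannot lean on relatives of the test genomes.
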