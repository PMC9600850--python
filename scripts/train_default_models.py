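"""Regenerate the shipped default model coefficients.

The defaults are fitted on the package's own synthetic genome generator and
are labeled SYNTHETIC in their metadata: they demonstrate the method and back
the test suite, and should be replaced by models trained on a real trait
compilation for scientific use.

Run from the repository root:

    python scripts/train_default_models.py
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

from cubgrowth import (
    CubgrowthWarning,
    features_from_frame,
    fit_growth_model,
    synthesize_pool,
    training_table_from_pool,
)

SEED = 12060  # fixed so the committed coefficients are reproducible
N_GENOMES = 300
N_CLUSTERS = 6
DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "cubgrowth" / "data"


def train_set(with_temperature: bool, seed: int) -> dict:
    pool = synthesize_pool(
        n_genomes=N_GENOMES,
        n_clusters=N_CLUSTERS,
        gc_range=(0.30, 0.70),
        seed=seed,
        with_temperature=with_temperature,
    )
    table = training_table_from_pool(pool, seed=seed + 1)
    feats = features_from_frame(table)
    y = table["doubling_time_h"].to_numpy()
    out = {}
    for mode in ("mmv1", "mmbc"):
        model = fit_growth_model(
            feats, y, mode=mode, with_temperature=with_temperature
        )
        model.training_metadata.update(
            {
                "source": "SYNTHETIC",
                "note": (
                    "fitted on the cubgrowth synthetic genome generator; "
                    "replace with a real training table for scientific use"
                ),
                "generator_seed": seed,
                "n_genomes": N_GENOMES,
                "n_clusters": N_CLUSTERS,
            }
        )
        out[mode] = model
        print(
            f"{mode} (temp={with_temperature}): lambda={model.lam:.3f} "
            f"intercept={model.intercept:.4f} coefs={model.coefficients} "
            f"R2={model.training_metadata['r_squared']:.3f}"
        )
    return out


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CubgrowthWarning)
        for with_temp, name in [
            (False, "models_synthetic.json"),
            (True, "models_synthetic_temp.json"),
        ]:
            models = train_set(with_temp, SEED + (1000 if with_temp else 0))
            doc = {mode: m.to_dict() for mode, m in models.items()}
            (DATA_DIR / name).write_text(json.dumps(doc, indent=2) + "\n")
            print(f"wrote {DATA_DIR / name}")


if __name__ == "__main__":
    main()
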