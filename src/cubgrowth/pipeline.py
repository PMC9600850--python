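"""End-to-end community-level prediction: HE designation, filtering, feature
computation with optional abundance weighting, and model dispatch."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .codonstats import (
    CubgrowthWarning,
    GeneRecord,
    background_from_counts,
    cub_he,
    drop_high_ambiguity_genes,
    filter_genes,
    gc_content,
    icub_mean,
    pooled_counts,
    psi,
    sample_background_genes,
)
from .models import (
    FeatureVector,
    GrowthModel,
    GrowthPrediction,
    predict_mmbc,
    predict_mmv1,
    predict_mmv2,
)

__all__ = ["SampleOptions", "designate_he_genes", "compute_features", "predict_community"]


@dataclass
class SampleOptions:
    """Configuration of one community prediction run.

    Defaults follow the method's standard settings: 100 shuffled null genes
    per sequence, 100 sampled background genes for iCUB̄_All, and an 80-codon
    length filter (40 with ``fragments``).
    """

    mode: str = "mmv2"
    fragments: bool = False
    weighted: bool = False
    temperature: float | None = None
    n_shuffles: int = 100
    background_k: int = 100
    seed: int = 0
    max_skipped_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in ("mmv1", "mmbc", "mmv2"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def min_codons(self) -> int:
        return 40 if self.fragments else 80


def designate_he_genes(
    genes: list[GeneRecord],
    pattern: str = "ribosomal protein",
    id_list: list[str] | None = None,
) -> list[GeneRecord]:
    """Flag highly expressed genes by ID membership or by case-insensitive
    substring match on the description header (default: ribosomal proteins).

    ``id_list`` takes precedence over the pattern.  Returns the same gene
    objects with ``is_highly_expressed`` set; errors if nothing matches.
    """
    if id_list is not None:
        wanted = set(id_list)
        for g in genes:
            g.is_highly_expressed = g.id in wanted
    else:
        needle = pattern.lower()
        for g in genes:
            g.is_highly_expressed = needle in g.description.lower()
    n_he = sum(g.is_highly_expressed for g in genes)
    if n_he == 0:
        raise ValueError(
            "no highly expressed genes designated "
            f"({'id list' if id_list is not None else f'pattern {pattern!r}'})"
        )
    return genes


def compute_features(
    genes: list[GeneRecord], options: SampleOptions
) -> FeatureVector:
    """Compute the full feature vector of a sample.

    CUB̄_HE is the (weighted) median MILC of HE genes against the pooled
    sample-wide background; iCUB̄_All averages per-gene shuffled-null MILC over
    ``background_k`` sampled non-HE genes; iCUB̄_HE does the same over the HE
    genes; Ψ is the HE-gene consistency.  Deterministic given ``options.seed``.
    """
    genes = filter_genes(genes, options.min_codons)
    genes = drop_high_ambiguity_genes(genes, options.max_skipped_fraction)
    he = [g for g in genes if g.is_highly_expressed]
    bg = [g for g in genes if not g.is_highly_expressed]
    if not he:
        raise ValueError("no highly expressed genes remain after filtering")
    if not bg:
        raise ValueError("no background (non-HE) genes remain after filtering")

    rng = np.random.default_rng(options.seed)
    sample_bg = background_from_counts(pooled_counts(genes), source="sample-wide")
    cub = cub_he(
        genes,
        sample_bg,
        aggregate="weighted-median" if options.weighted else "median",
    )
    # background genes for iCUB_All are sampled uniformly; abundance weights
    # enter through the weighted means/medians, not the sample itself
    sampled = sample_background_genes(bg, k=options.background_k, seed=rng)
    icub_all = icub_mean(
        sampled, n_shuffles=options.n_shuffles, seed=rng, weighted=options.weighted
    )
    icub_he = icub_mean(
        he, n_shuffles=options.n_shuffles, seed=rng, weighted=options.weighted
    )
    gc = gc_content(genes, weighted=options.weighted)
    psi_value = psi(he) if len(he) >= 2 else None
    return FeatureVector(
        cub_he=cub,
        icub_all=icub_all,
        icub_he=icub_he,
        gc=gc,
        psi=psi_value,
        ogt=options.temperature,
    )


def predict_community(
    genes: list[GeneRecord],
    models: dict[str, GrowthModel],
    options: SampleOptions | None = None,
) -> GrowthPrediction:
    """Predict the average community-wide maximal growth rate of a sample.

    ``models`` maps mode name -> fitted GrowthModel and must cover the
    requested mode ("mmv2" needs both "mmv1" and "mmbc").  Warnings raised
    anywhere in the pipeline (HE count < 10, clamping, ambiguity drops) are
    embedded in the returned prediction.
    """
    options = options or SampleOptions()
    needed = ("mmv1", "mmbc") if options.mode == "mmv2" else (options.mode,)
    for name in needed:
        if name not in models:
            raise ValueError(f"model set lacks the {name!r} model")
        if models[name].with_temperature != (options.temperature is not None):
            raise ValueError(
                f"model {name!r} temperature flag does not match the options"
            )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", CubgrowthWarning)
        features = compute_features(genes, options)
        if options.mode == "mmv1":
            pred = predict_mmv1(features, models["mmv1"])
        elif options.mode == "mmbc":
            pred = predict_mmbc(features, models["mmbc"])
        else:
            pred = predict_mmv2(features, models["mmv1"], models["mmbc"])
    seen = set(pred.warnings)
    for w in caught:
        if issubclass(w.category, CubgrowthWarning):
            msg = str(w.message)
            if msg not in seen:
                pred.warnings.append(msg)
                seen.add(msg)
    return pred
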