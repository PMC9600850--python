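"""Synthetic genomes, genome mixtures, abundances, temperatures, gene
subsampling, and the convergence benchmark.

The generator emulates the validation design used for community-level growth
predictors: genomes are sets of coding sequences drawn codon-by-codon from
per-family preference vectors, with (i) a genome-wide GC tilt solved to hit a
target GC, (ii) sharpened preferences in the highly expressed (ribosomal
protein) genes whose strength scales inversely with the planted minimum
doubling time, and (iii) preference *rankings* shared within a "phylum"
cluster so that single-cluster pools yield low-Ψ (codon-consistent)
communities and many-cluster pools yield high-Ψ ones.  Mixtures concatenate
the coding sequences of 10 genomes with lognormal relative abundances.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._genetic_code import CODON_STRINGS, GeneticCode, genetic_code
from .codonstats import CubgrowthWarning, GeneRecord
from .models import PSI_SWITCH_THRESHOLD, GrowthModel, predict_mmbc, predict_mmv1, predict_mmv2
from .pipeline import SampleOptions, compute_features

__all__ = [
    "SyntheticGenomeSpec",
    "MixtureSpec",
    "GenomePool",
    "BenchmarkResult",
    "cluster_preferences",
    "jitter_preferences",
    "he_bias_from_doubling_time",
    "synthesize_genome",
    "synthesize_pool",
    "make_mixture",
    "simulate_abundances",
    "simulate_temperatures",
    "simulate_community",
    "subsample_genes",
    "training_table_from_pool",
    "convergence_benchmark",
]

_CODON_BYTES = np.array(CODON_STRINGS, dtype="S3")


# --------------------------------------------------------------------------
# specs


@dataclass
class SyntheticGenomeSpec:
    """Recipe for one synthetic genome."""

    n_genes: int = 80
    gene_length_codons: int = 300
    codon_preference: dict[str, np.ndarray] = field(default_factory=dict)
    he_bias_strength: float = 2.0
    gc_target: float = 0.5
    true_doubling_time: float = 3.0  # hours
    he_fraction: float = 0.125
    genome_id: str = "genome"


@dataclass
class MixtureSpec:
    """A simulated community: which genomes, at which relative abundances."""

    genome_ids: list[str]
    abundances: list[float]
    sample_temperature: float | None = None
    per_genome_ogt: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genome_ids) != len(self.abundances):
            raise ValueError("genome_ids and abundances differ in length")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


@dataclass
class GenomePool:
    """A pool of synthetic genomes with their planted traits."""

    genomes: dict[str, list[GeneRecord]]
    table: pd.DataFrame  # genome_id, phylum, gc_target, doubling_time_h, ...

    def __len__(self) -> int:
        return len(self.genomes)


@dataclass
class BenchmarkResult:
    per_mixture: pd.DataFrame
    summary: dict


# --------------------------------------------------------------------------
# codon preferences


def cluster_preferences(
    rng: np.random.Generator,
    decay: float = 0.25,
    code: GeneticCode | None = None,
) -> dict[str, np.ndarray]:
    """Random per-family preference vectors with a geometric rank profile.

    Each family gets a random codon ranking; codon ranked k receives weight
    ``decay**k`` (normalized), so the preferred codon takes ~75% of a 4-fold
    family at the default decay.
    """
    code = code or genetic_code()
    prefs: dict[str, np.ndarray] = {}
    for aa, idx in zip(code.family_names, code.family_codon_idx):
        r = len(idx)
        ranks = rng.permutation(r)
        w = decay ** ranks.astype(float)
        prefs[aa] = w / w.sum()
    return prefs


def jitter_preferences(
    prefs: dict[str, np.ndarray],
    rng: np.random.Generator,
    sd: float = 0.1,
) -> dict[str, np.ndarray]:
    """Perturb preference vectors multiplicatively (log-normal noise)."""
    out = {}
    for aa, w in prefs.items():
        v = w * np.exp(rng.normal(0.0, sd, size=w.size))
        out[aa] = v / v.sum()
    return out


def he_bias_from_doubling_time(
    doubling_time: float, scale: float = 3.0, exponent: float = 0.5
) -> float:
    """Planted HE-gene sharpening: fast growers (small doubling time) get
    strongly concentrated ribosomal-protein codon preferences."""
    return scale * doubling_time ** (-exponent)


# --------------------------------------------------------------------------
# genome synthesis


def _composite_weights(
    prefs: dict[str, np.ndarray],
    beta: float,
    he_exponent: float,
    code: GeneticCode,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Background and HE codon sampling weights per family.

    Background usage combines the genome's preference vector with a GC tilt
    exp(beta * gc_fraction); HE genes sharpen the genome's *realized*
    distribution, (pref * tilt)**(1+s), mirroring the observation that
    translationally optimal codons are the codons the genome itself prefers,
    composition effects included.
    """
    bg, he = [], []
    for aa, idx in zip(code.family_names, code.family_codon_idx):
        gcfrac = code.codon_gc[idx]
        tilt = np.exp(beta * gcfrac)
        w_bg = prefs[aa] * tilt
        w_he = w_bg ** (1.0 + he_exponent)
        bg.append(w_bg / w_bg.sum())
        he.append(w_he / w_he.sum())
    return bg, he


def _expected_gc(
    prefs: dict[str, np.ndarray],
    beta: float,
    he_exponent: float,
    he_fraction: float,
    fam_probs: np.ndarray,
    code: GeneticCode,
) -> float:
    bg, he = _composite_weights(prefs, beta, he_exponent, code)
    total = 0.0
    for p_fam, w_bg, w_he, idx in zip(
        fam_probs, bg, he, code.family_codon_idx
    ):
        gcfrac = code.codon_gc[idx]
        mix = (1.0 - he_fraction) * w_bg + he_fraction * w_he
        total += p_fam * float(mix @ gcfrac)
    return total


def _solve_gc_tilt(
    prefs: dict[str, np.ndarray],
    gc_target: float,
    he_exponent: float,
    he_fraction: float,
    fam_probs: np.ndarray,
    code: GeneticCode,
) -> float:
    lo, hi = -40.0, 40.0
    g_lo = _expected_gc(prefs, lo, he_exponent, he_fraction, fam_probs, code)
    g_hi = _expected_gc(prefs, hi, he_exponent, he_fraction, fam_probs, code)
    if gc_target < g_lo - 0.045 or gc_target > g_hi + 0.045:
        raise ValueError(
            f"gc_target {gc_target:.3f} infeasible for this code "
            f"(achievable range [{g_lo:.3f}, {g_hi:.3f}])"
        )
    if gc_target <= g_lo:
        return lo
    if gc_target >= g_hi:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_gc(prefs, mid, he_exponent, he_fraction, fam_probs, code) < gc_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_codon_block(
    n_codons: int,
    weights: list[np.ndarray],
    fam_probs: np.ndarray,
    rng: np.random.Generator,
    code: GeneticCode,
) -> np.ndarray:
    """Draw codon indices: family ~ fam_probs, codon ~ family weights."""
    fam = rng.choice(len(fam_probs), size=n_codons, p=fam_probs)
    u = rng.random(n_codons)
    out = np.empty(n_codons, dtype=np.int64)
    for f, (idx, w) in enumerate(zip(code.family_codon_idx, weights)):
        mask = fam == f
        if not mask.any():
            continue
        pick = np.searchsorted(np.cumsum(w), u[mask], side="right")
        pick = np.minimum(pick, len(idx) - 1)
        out[mask] = idx[pick]
    return out


def synthesize_genome(
    spec: SyntheticGenomeSpec, seed: int | np.random.Generator = 0
) -> list[GeneRecord]:
    """Generate one synthetic genome as a list of coding sequences.

    HE genes (``he_fraction`` of genes, flagged, headers containing
    "ribosomal protein") are drawn from sharpened preferences controlled by
    ``he_bias_strength``; at strength 0 they are statistically identical to
    background genes.  Realized GC lands within ±0.05 of ``gc_target``.
    """
    code = genetic_code()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    prefs = spec.codon_preference or cluster_preferences(rng)
    fam_probs = code.degeneracy / code.degeneracy.sum()
    beta = _solve_gc_tilt(
        prefs, spec.gc_target, spec.he_bias_strength, spec.he_fraction,
        fam_probs, code,
    )
    w_bg, w_he = _composite_weights(prefs, beta, spec.he_bias_strength, code)

    n_he = max(1, round(spec.n_genes * spec.he_fraction))
    n_bg = spec.n_genes - n_he
    L = spec.gene_length_codons
    he_codons = _draw_codon_block(n_he * L, w_he, fam_probs, rng, code).reshape(n_he, L)
    bg_codons = _draw_codon_block(n_bg * L, w_bg, fam_probs, rng, code).reshape(n_bg, L)

    genes: list[GeneRecord] = []
    for i in range(n_he):
        gid = f"{spec.genome_id}_rp{i:03d}"
        seq = "ATG" + _CODON_BYTES[he_codons[i]].tobytes().decode("ascii")
        genes.append(
            GeneRecord(
                id=gid,
                sequence=seq,
                is_highly_expressed=True,
                description=f"{gid} 50S ribosomal protein L{i + 1}",
                source_id=spec.genome_id,
            )
        )
    for i in range(n_bg):
        gid = f"{spec.genome_id}_g{i:04d}"
        seq = "ATG" + _CODON_BYTES[bg_codons[i]].tobytes().decode("ascii")
        genes.append(
            GeneRecord(
                id=gid,
                sequence=seq,
                description=f"{gid} hypothetical protein",
                source_id=spec.genome_id,
            )
        )
    return genes


def synthesize_pool(
    n_genomes: int = 30,
    n_clusters: int = 3,
    seed: int = 0,
    n_genes: int = 80,
    gene_length_codons: int = 300,
    gc_range: tuple[float, float] = (0.35, 0.65),
    doubling_time_meanlog: float = float(np.log(3.0)),
    doubling_time_sdlog: float = 1.0,
    doubling_time_range: tuple[float, float] = (0.25, 45.0),
    fixed_doubling_time: float | None = None,
    jitter_sd: float = 0.1,
    decay: float = 0.25,
    cluster_divergence: float = 1.0,
    he_bias_scale: float = 3.0,
    he_fraction: float = 0.125,
    with_temperature: bool = False,
    id_prefix: str = "G",
) -> GenomePool:
    """Generate a pool of synthetic genomes organized into preference clusters.

    Genomes within a cluster share a codon-preference ranking (a synthetic
    "phylum"); doubling times are lognormal (or fixed), GC targets uniform
    over ``gc_range``, and the HE-gene bias is planted inversely proportional
    to the square root of the doubling time.
    """
    rng = np.random.default_rng(seed)
    base_prefs = cluster_preferences(rng, decay=decay)
    v = float(np.clip(cluster_divergence, 0.0, 1.0))
    cluster_prefs = []
    for _ in range(n_clusters):
        own = cluster_preferences(rng, decay=decay)
        # geometric blend between a shared consensus ranking and the
        # cluster's own ranking sets how dissimilar codon preferences are
        # across clusters (and hence the Ψ of cross-cluster mixtures)
        blended = {}
        for aa in own:
            w = base_prefs[aa] ** (1.0 - v) * own[aa] ** v
            blended[aa] = w / w.sum()
        cluster_prefs.append(blended)
    rows = []
    genomes: dict[str, list[GeneRecord]] = {}
    for i in range(n_genomes):
        cluster = i % n_clusters
        if fixed_doubling_time is not None:
            d_base = fixed_doubling_time
        else:
            d_base = float(
                np.clip(
                    rng.lognormal(doubling_time_meanlog, doubling_time_sdlog),
                    *doubling_time_range,
                )
            )
        if with_temperature:
            ogt = float(rng.uniform(5.0, 55.0))
            d = float(
                np.clip(d_base * np.exp(-0.02 * (ogt - 25.0)), 0.05, 200.0)
            )
        else:
            ogt = np.nan
            d = d_base
        gc_target = float(rng.uniform(*gc_range))
        gid = f"{id_prefix}{i:03d}"
        spec = SyntheticGenomeSpec(
            n_genes=n_genes,
            gene_length_codons=gene_length_codons,
            codon_preference=jitter_preferences(cluster_prefs[cluster], rng, jitter_sd),
            he_bias_strength=he_bias_from_doubling_time(d_base, scale=he_bias_scale),
            gc_target=gc_target,
            true_doubling_time=d,
            he_fraction=he_fraction,
            genome_id=gid,
        )
        genomes[gid] = synthesize_genome(spec, rng)
        rows.append(
            {
                "genome_id": gid,
                "phylum": f"cluster{cluster}",
                "gc_target": gc_target,
                "doubling_time_h": d,
                "he_bias_strength": spec.he_bias_strength,
                "ogt_c": ogt,
            }
        )
    return GenomePool(genomes=genomes, table=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# mixtures


def make_mixture(
    genome_pool: dict[str, list[GeneRecord]] | GenomePool,
    n: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[MixtureSpec, list[GeneRecord]]:
    """Sample ``n`` distinct genomes and concatenate their coding sequences.

    Gene records are copied so per-mixture abundance weights do not leak into
    the pool; provenance is retained in each gene's ``source_id``.
    """
    pool = genome_pool.genomes if isinstance(genome_pool, GenomePool) else genome_pool
    if len(pool) < n:
        raise ValueError(f"pool of {len(pool)} genomes is too small for n={n}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ids = sorted(pool)
    chosen = [ids[i] for i in rng.choice(len(ids), size=n, replace=False)]
    genes = [
        dataclasses.replace(g) for gid in chosen for g in pool[gid]
    ]
    spec = MixtureSpec(
        genome_ids=chosen,
        abundances=[1.0 / n] * n,
        seed=int(rng.integers(2**31)),
    )
    return spec, genes


def simulate_abundances(
    n: int,
    meanlog: float = 0.0,
    sdlog: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Lognormal relative abundances normalized to sum to one."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sdlog < 0:
        raise ValueError("sdlog must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    draws = rng.lognormal(meanlog, sdlog, size=n)
    return draws / draws.sum()


def simulate_temperatures(
    n: int, seed: int | np.random.Generator = 0
) -> tuple[float, np.ndarray]:
    """Sample temperature ~ U(0, 60) °C; per-genome OGT adds N(0, 10) offsets."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t = float(rng.uniform(0.0, 60.0))
    ogts = t + rng.normal(0.0, 10.0, size=n)
    return t, ogts


def simulate_community(
    pool: GenomePool,
    n: int = 10,
    seed: int = 0,
    meanlog: float = 0.0,
    sdlog: float = 1.0,
    with_temperature: bool = False,
) -> tuple[MixtureSpec, list[GeneRecord]]:
    """Convenience: mixture + lognormal abundances (+ temperatures) with gene
    weights set to the source genome's relative abundance."""
    rng = np.random.default_rng(seed)
    spec, genes = make_mixture(pool, n=n, seed=rng)
    abundances = simulate_abundances(n, meanlog, sdlog, seed=rng)
    spec.abundances = [float(a) for a in abundances]
    if with_temperature:
        t, ogts = simulate_temperatures(n, seed=rng)
        spec.sample_temperature = t
        spec.per_genome_ogt = [float(o) for o in ogts]
    by_id = dict(zip(spec.genome_ids, abundances))
    for g in genes:
        g.weight = float(by_id[g.source_id])
    spec.seed = seed
    return spec, genes


def subsample_genes(
    genes: list[GeneRecord],
    fraction: float,
    seed: int | np.random.Generator = 0,
) -> tuple[list[GeneRecord], int]:
    """Draw ⌈fraction·N⌉ genes without replacement with inclusion probability
    proportional to abundance weight.  Returns (genes, unique HE genes kept)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        picked = list(genes)
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        m = int(np.ceil(fraction * len(genes)))
        w = np.array([g.weight for g in genes], dtype=float)
        p = w / w.sum() if w.sum() > 0 else np.full(len(genes), 1.0 / len(genes))
        idx = rng.choice(len(genes), size=m, replace=False, p=p)
        picked = [genes[i] for i in idx]
    n_he = len({g.id for g in picked if g.is_highly_expressed})
    return picked, n_he


# --------------------------------------------------------------------------
# training table and benchmark


def _spawn_seed(base: int, *path: int) -> int:
    return int(
        np.random.SeedSequence(entropy=[int(base), *map(int, path)]).generate_state(1)[0]
        % 2**31
    )


def genome_features(
    pool: GenomePool,
    options: SampleOptions | None = None,
    seed: int = 0,
):
    """Per-genome feature vectors (cached inputs for training/benchmarks)."""
    base = options or SampleOptions()
    feats = {}
    for j, gid in enumerate(sorted(pool.genomes)):
        opts = dataclasses.replace(
            base, weighted=False, temperature=None, seed=_spawn_seed(seed, 1, j)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CubgrowthWarning)
            feats[gid] = compute_features(pool.genomes[gid], opts)
    return feats


def training_table_from_pool(
    pool: GenomePool,
    options: SampleOptions | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Training table (species, phylum, doubling_time_h, ogt_c + features)
    computed from a synthetic genome pool."""
    feats = genome_features(pool, options, seed)
    rows = []
    for _, meta in pool.table.iterrows():
        f = feats[meta["genome_id"]]
        rows.append(
            {
                "species": meta["genome_id"],
                "phylum": meta["phylum"],
                "doubling_time_h": meta["doubling_time_h"],
                "ogt_c": meta["ogt_c"],
                "cub_he": f.cub_he,
                "icub_all": f.icub_all,
                "icub_he": f.icub_he,
                "gc": f.gc,
                "psi": f.psi,
            }
        )
    return pd.DataFrame(rows)


def _dispatch(features, models: dict[str, GrowthModel], mode: str):
    if mode == "mmv1":
        return predict_mmv1(features, models["mmv1"])
    if mode == "mmbc":
        return predict_mmbc(features, models["mmbc"])
    return predict_mmv2(features, models["mmv1"], models["mmbc"])


def convergence_benchmark(
    pool: GenomePool,
    mixtures: list[tuple[MixtureSpec, list[GeneRecord]]],
    models: dict[str, GrowthModel],
    model_mode: str = "mmv2",
    aggregate: str = "mean",
    scale: str = "log10-hours",
    options: SampleOptions | None = None,
    seed: int = 0,
    genome_feats: dict | None = None,
) -> BenchmarkResult:
    """How well a predictor converges to itself on mixed communities.

    For each mixture the benchmark value is the abundance-weighted aggregate
    (mean or median) of per-genome predictions under ``model_mode``; the error
    is the squared difference between the community prediction and that
    benchmark on the chosen scale (log10-hours by default).  The summary
    stratifies MSE by the Ψ switch threshold and by pooled-GC bins.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if scale not in ("log10-hours", "hours"):
        raise ValueError(f"unknown scale {scale!r}")
    base = options or SampleOptions()
    feats_by_genome = (
        genome_feats
        if genome_feats is not None
        else genome_features(pool, base, seed=seed)
    )

    rows = []
    n_failed = 0
    for m, (spec, genes) in enumerate(mixtures):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", CubgrowthWarning)
                # per-genome predictions (OGT attached per mixture if simulated)
                d_genomes = []
                for j, gid in enumerate(spec.genome_ids):
                    f = feats_by_genome[gid]
                    if base.temperature is not None or spec.per_genome_ogt:
                        f = dataclasses.replace(
                            f,
                            ogt=(
                                spec.per_genome_ogt[j]
                                if spec.per_genome_ogt
                                else base.temperature
                            ),
                        )
                    d_genomes.append(_dispatch(f, models, model_mode).doubling_time)
                d_genomes = np.array(d_genomes)
                a = np.asarray(spec.abundances, dtype=float)

                opts = dataclasses.replace(
                    base,
                    mode=model_mode,
                    temperature=spec.sample_temperature
                    if spec.sample_temperature is not None
                    else base.temperature,
                    seed=_spawn_seed(seed, 2, m),
                )
                feats = compute_features(genes, opts)
                pred = _dispatch(feats, models, model_mode)

                vals = np.log10(d_genomes) if scale == "log10-hours" else d_genomes
                if aggregate == "mean":
                    bench = float(np.average(vals, weights=a))
                else:
                    from .codonstats import weighted_median

                    bench = weighted_median(vals, a)
                comm = (
                    np.log10(pred.doubling_time)
                    if scale == "log10-hours"
                    else pred.doubling_time
                )
                bench_h = 10**bench if scale == "log10-hours" else bench
                rows.append(
                    {
                        "mixture": m,
                        "psi": feats.psi,
                        "gc": feats.gc,
                        "mode_used": pred.mode_used,
                        "community_doubling_time_h": pred.doubling_time,
                        "benchmark_doubling_time_h": bench_h,
                        "signed_error": comm - bench,
                        "sq_error": (comm - bench) ** 2,
                    }
                )
        except ValueError as exc:
            n_failed += 1
            warnings.warn(
                f"mixture {m} failed prediction and was excluded: {exc}",
                CubgrowthWarning,
                stacklevel=2,
            )
    per_mixture = pd.DataFrame(rows)
    summary: dict = {
        "model_mode": model_mode,
        "aggregate": aggregate,
        "scale": scale,
        "n": int(len(per_mixture)),
        "n_failed": n_failed,
        "mse": float(per_mixture["sq_error"].mean()) if len(per_mixture) else np.nan,
    }
    if len(per_mixture):
        low = per_mixture["psi"] < PSI_SWITCH_THRESHOLD
        summary["mse_psi_low"] = float(per_mixture.loc[low, "sq_error"].mean())
        summary["mse_psi_high"] = float(per_mixture.loc[~low, "sq_error"].mean())
        bins = pd.cut(
            per_mixture["gc"],
            bins=[0.0, 0.45, 0.55, 1.0],
            labels=["gc<0.45", "0.45-0.55", "gc>0.55"],
        )
        summary["mse_by_gc"] = {
            str(k): float(v)
            for k, v in per_mixture.groupby(bins, observed=True)["sq_error"]
            .mean()
            .items()
        }
    return BenchmarkResult(per_mixture=per_mixture, summary=summary)
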