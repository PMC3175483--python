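"""Ground-truth generator of synthetic immunosignature experiments.

The generator emulates the structure the latent-factor models assume: a
serum sample's log10 intensity on peptide p is

    log10(RFU_ip) = baseline_p + Σ_f λ_pf · η_fi + ε_ip

where η_fi is sample i's score on latent "antibody" factor f (normal with
a group-dependent mean shift and unit variance), λ_pf are loadings carried
by a configured subset of peptides (one antibody binds many peptides), and
ε is log-scale noise that also absorbs competitive-binding attenuation.
Values are back-transformed to RFU and clipped to the 16-bit scanner
ceiling; empty spots are uniform draws from the background range.

Defaults mirror a three-group breast-cancer study design: 52 normal / 98
single-tumor / 21 second-tumor samples, 10,375 peptides of which 1,172 are
empty spots, background 150-300 RFU, ceiling 65,500.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arraydata import IntensityMatrix

__all__ = ["FactorConfig", "SyntheticConfig", "GroundTruth", "generate",
           "make_null", "second_tumor_preset", "two_group_config",
           "small_config"]

_AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_GROUP_SIZES = {"normal": 52, "single_tumor": 98, "second_tumor": 21}


@dataclass
class FactorConfig:
    """One latent antibody factor.

    ``mean_shift`` maps group -> mean of the factor score in that group
    (unlisted groups sit at 0); ``score_sd`` maps group -> score standard
    deviation (default 1; an antibody a group never raises should get a
    small value — absent means neither mean nor variance).  The factor
    loads on ``n_loading_peptides`` peptides with |loadings| drawn
    uniformly from ``loading_range`` and the given sign (+1: reactivity
    increased where the shift is positive).
    """

    name: str
    mean_shift: dict[str, float]
    n_loading_peptides: int = 25
    loading_range: tuple[float, float] = (0.25, 0.45)
    sign: int = 1
    score_sd: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_peptides: int = 10375
    n_empty_spots: int = 1172
    factors: list[FactorConfig] = field(default_factory=list)
    baseline_log_mean: float = 2.5          # log10 RFU ~= 320, typical signal
    baseline_log_sd: float = 0.15
    noise_log_sd: float = 0.12
    background_rfu_range: tuple[float, float] = (150.0, 300.0)
    ceiling: float = 65500.0
    seed: int = 0
    allow_overlap: bool = False
    group_noise_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.group_sizes.values()):
            raise ValueError("every group needs at least 1 sample")
        if not 0 <= self.n_empty_spots < self.n_peptides:
            raise ValueError("n_empty_spots must be < n_peptides")
        if self.ceiling <= 0:
            raise ValueError("ceiling must be positive")
        total_loading = sum(f.n_loading_peptides for f in self.factors)
        if total_loading > self.n_peptides - self.n_empty_spots:
            raise ValueError(
                f"factors claim {total_loading} loading peptides but only "
                f"{self.n_peptides - self.n_empty_spots} printed peptides exist"
            )


@dataclass
class GroundTruth:
    """What the generator actually planted, for estimator checking."""

    factor_scores: np.ndarray        # n_samples x n_factors (η)
    loadings: np.ndarray             # n_peptides x n_factors (λ)
    peptide_factor: dict[str, str]   # loading peptide id -> factor name
    group_labels: list[str]
    factor_names: list[str]
    spiked_peptides: dict[str, list[str]]  # factor name -> peptide ids
    baseline: np.ndarray


def _random_sequences(rng: np.random.Generator, n: int, length: int = 17) -> list[str]:
    # random-sequence mimotope plus the common GSC linker
    letters = rng.integers(0, len(_AA), size=(n, length))
    return ["".join(_AA[j] for j in row) + "GSC" for row in letters]


def generate(config: SyntheticConfig) -> tuple[IntensityMatrix, GroundTruth]:
    """Draw one synthetic experiment; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    groups = list(config.group_sizes)
    labels = [g for g in groups for _ in range(config.group_sizes[g])]
    n = len(labels)
    v = config.n_peptides

    # layout: empty spots scattered across the array surface
    empty_idx = rng.choice(v, size=config.n_empty_spots, replace=False)
    empty = np.zeros(v, dtype=bool)
    empty[empty_idx] = True
    printed = np.flatnonzero(~empty)

    peptide_ids = [f"V{i+1}" for i in range(v)]
    sequences = [""] * v
    seqs = _random_sequences(rng, printed.size)
    for i, s in zip(printed, seqs):
        sequences[i] = s
    for i in empty_idx:
        sequences[i] = "empty"

    fnames = [f.name for f in config.factors]
    loadings = np.zeros((v, len(fnames)))
    spiked: dict[str, list[str]] = {}
    pep_factor: dict[str, str] = {}
    pool = printed.copy()
    rng.shuffle(pool)
    pos = 0
    for j, fc in enumerate(config.factors):
        if config.allow_overlap:
            chosen = rng.choice(printed, size=fc.n_loading_peptides, replace=False)
        else:
            chosen = pool[pos:pos + fc.n_loading_peptides]
            pos += fc.n_loading_peptides
        lo, hi = fc.loading_range
        loadings[chosen, j] = fc.sign * rng.uniform(lo, hi, size=chosen.size)
        spiked[fc.name] = [peptide_ids[i] for i in chosen]
        for i in chosen:
            pep_factor[peptide_ids[i]] = fc.name

    shifts = np.array([[fc.mean_shift.get(g, 0.0) for fc in config.factors]
                       for g in labels])
    sds = np.array([[fc.score_sd.get(g, 1.0) for fc in config.factors]
                    for g in labels])
    eta = shifts + sds * rng.standard_normal((n, len(fnames))) if fnames else \
        np.zeros((n, 0))

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=v)
    noise_sd = config.noise_log_sd * np.array(
        [config.group_noise_scale.get(g, 1.0) for g in labels])
    log_int = (baseline[None, :] + eta @ loadings.T
               + noise_sd[:, None] * rng.standard_normal((n, v)))
    rfu = np.clip(10.0 ** log_int, 0.0, config.ceiling)
    lo_bg, hi_bg = config.background_rfu_range
    rfu[:, empty] = rng.uniform(lo_bg, hi_bg, size=(n, config.n_empty_spots))

    x = IntensityMatrix(
        values=rfu,
        sample_ids=[f"S{i+1:03d}" for i in range(n)],
        group_labels=labels,
        peptide_ids=peptide_ids,
        peptide_sequences=sequences,
        empty_spot=empty,
    )
    truth = GroundTruth(
        factor_scores=eta,
        loadings=loadings,
        peptide_factor=pep_factor,
        group_labels=labels,
        factor_names=fnames,
        spiked_peptides=spiked,
        baseline=baseline,
    )
    return x, truth


def make_null(config: SyntheticConfig) -> tuple[IntensityMatrix, GroundTruth]:
    """Same generative process with every group mean shift set to 0: factor
    structure without group information, the null for error-rate suites."""
    null_factors = [replace(f, mean_shift={g: 0.0 for g in f.mean_shift},
                            score_sd={})
                    for f in config.factors]
    return generate(replace(config, factors=null_factors,
                            group_noise_scale={}))


def second_tumor_preset(seed: int = 0) -> SyntheticConfig:
    """Three-group preset with a wider-dynamic-range second-tumor group.

    A tumor antibody shared by both cancer groups, a second-tumor-specific
    antibody with strong loadings, a *suppressed* antibody (negative sign,
    lowering the second-tumor floor), and broader second-tumor noise
    together reproduce the qualitative pooled-range ordering
    second > single > normal.
    """
    return SyntheticConfig(
        factors=[
            FactorConfig("ab_single", {"single_tumor": 1.5, "second_tumor": 1.0},
                         n_loading_peptides=40, loading_range=(0.2, 0.45),
                         score_sd={"normal": 0.3}),
            FactorConfig("ab_second", {"second_tumor": 2.2},
                         n_loading_peptides=40, loading_range=(0.35, 0.6),
                         score_sd={"normal": 0.15, "single_tumor": 0.15}),
            FactorConfig("ab_suppressed", {"second_tumor": 2.0},
                         n_loading_peptides=30, loading_range=(0.5, 0.9),
                         sign=-1,
                         score_sd={"normal": 0.15, "single_tumor": 0.15}),
        ],
        group_noise_scale={"second_tumor": 1.4},
        seed=seed,
    )


def two_group_config(seed: int = 0, separation: float = 2.0,
                     groups: tuple[str, str] = ("normal", "single_tumor"),
                     n_peptides: int = 400, n_empty_spots: int = 40,
                     group_sizes: dict[str, int] | None = None) -> SyntheticConfig:
    """Two-group scenario with one latent antibody per group (disjoint
    peptide sets), the high-separation condition of the classification
    suites: each group's factor score is shifted by *separation* SDs in its
    own group and nearly silent (SD 0.2) in the other."""
    a, b = groups
    if group_sizes is None:
        group_sizes = {a: 52, b: 98}
    return SyntheticConfig(
        group_sizes=group_sizes,
        n_peptides=n_peptides,
        n_empty_spots=n_empty_spots,
        factors=[
            FactorConfig(f"ab_{a}", {a: separation}, n_loading_peptides=25,
                         score_sd={b: 0.2}),
            FactorConfig(f"ab_{b}", {b: separation}, n_loading_peptides=25,
                         score_sd={a: 0.2}),
        ],
        seed=seed,
    )


def small_config(
    group_sizes: dict[str, int] | None = None,
    n_peptides: int = 400,
    n_empty_spots: int = 40,
    factors: list[FactorConfig] | None = None,
    seed: int = 0,
    **kwargs,
) -> SyntheticConfig:
    """Scaled-down config for simulation suites (same structure, smaller
    array) — study-scale group sizes with a few hundred peptides."""
    if group_sizes is None:
        group_sizes = {"normal": 52, "single_tumor": 98}
    if factors is None:
        factors = [FactorConfig("ab1", {"single_tumor": 2.0},
                                n_loading_peptides=25)]
    return SyntheticConfig(group_sizes=group_sizes, n_peptides=n_peptides,
                           n_empty_spots=n_empty_spots, factors=factors,
                           seed=seed, **kwargs)
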