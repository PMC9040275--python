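"""Forward Wright-Fisher simulation of a neutral gene.

The point of the simulation: for unlinked neutral sites at mutation-drift
equilibrium, the expected number of segregating sites observed in a
population sample is proportional to the gene's total mutation rate
(theta = 4*Ne*mu per site, E[S] ~= a_{n-1} * theta summed over sites when
theta << 1).  This proportionality is what licenses reading relative
per-gene CNV mutation rates off per-gene site counts in a population SV
catalog, provided the variants are not under selection.

The gene is a set of independent biallelic sites, each starting monomorphic
ancestral, with symmetric two-way mutation at ``site_mu`` per allele copy
per generation.  Each generation the derived-allele count of each site is
redrawn as Binomial(2N, p') where p' is the post-mutation frequency — the
standard allele-frequency-vector formulation of the Wright-Fisher model,
statistically identical to an individual-based run for unlinked neutral
sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_REFERENCE_N_SITES = (100, 320, 1000)
_REFERENCE_SITE_MU = (1e-10, 1e-9, 1e-8, 1e-7)


@dataclass(frozen=True)
class DriftConfig:
    """Parameters of one neutral-gene simulation.

    Defaults mirror the reference configuration (constant population of
    100,000; one million generations; a 10,000-individual sample, matching
    the scale of the population SV catalog); tests and the desk-scale
    acceptance run use reduced sizes with >= 20*Ne generations of burn-in.
    """

    pop_size: int = 100_000
    generations: int = 1_000_000
    n_sites: int = 100
    site_mu: float = 1e-8
    sample_size: int = 10_000
    reps: int = 300
    seed: int = 0
    selection_coeff: float = 0.0
    dominance_coeff: float = 0.0
    require_polymorphic: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.sample_size < self.pop_size:
            raise ValueError("need pop_size > sample_size > 0")
        if self.site_mu < 0:
            raise ValueError("site_mu must be nonnegative")
        # weak-mutation regime: per-site theta must stay well below 1, as it
        # is for CNV-like rates (<= 1e-7) at the reference population size
        if 4.0 * self.pop_size * self.site_mu > 0.5:
            raise ValueError("4*Ne*site_mu must be << 1 (weak mutation)")
        if self.reps < 1 or self.n_sites < 1:
            raise ValueError("reps and n_sites must be >= 1")
        if self.selection_coeff != 0.0:
            raise NotImplementedError("only the neutral model is implemented")

    @property
    def total_gene_rate(self) -> float:
        return self.n_sites * self.site_mu


@dataclass(frozen=True)
class DriftResult:
    config: DriftConfig
    per_rep_counts: tuple[int, ...]

    @property
    def mean_segregating_sites(self) -> float:
        return float(np.mean(self.per_rep_counts))

    @property
    def total_gene_rate(self) -> float:
        return self.config.total_gene_rate


def simulate_gene(config: DriftConfig) -> DriftResult:
    """Run ``config.reps`` replicate Wright-Fisher histories of one gene.

    Returns per-replicate counts of sites segregating (by default: derived
    allele present in, but not fixed in, the sample) among ``sample_size``
    individuals drawn without replacement from the final generation.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    two_n = 2 * config.pop_size
    counts = np.zeros((config.reps, config.n_sites), dtype=np.int64)
    mu = config.site_mu
    for _ in range(config.generations):
        p = counts / two_n
        # symmetric two-way mutation, then binomial resampling
        p_next = p * (1.0 - mu) + (1.0 - p) * mu
        counts = rng.binomial(two_n, p_next)
    # sample 2*sample_size alleles without replacement from the 2N pool
    sample_alleles = 2 * config.sample_size
    sampled = rng.hypergeometric(counts, two_n - counts, sample_alleles)
    if config.require_polymorphic:
        segregating = (sampled > 0) & (sampled < sample_alleles)
    else:
        segregating = sampled > 0
    per_rep = segregating.sum(axis=1)
    return DriftResult(config=config, per_rep_counts=tuple(int(x) for x in per_rep))


def watterson_expected_segregating(
    n_alleles: int, pop_size: int, total_rate: float
) -> float:
    """Neutral closed-form expectation a_{n-1} * 4*Ne*mu_total (theta << 1)."""
    a = np.sum(1.0 / np.arange(1, n_alleles))
    return float(a * 4 * pop_size * total_rate)


def rate_site_correlation(results: list[DriftResult]) -> float:
    """Pearson correlation between total gene mutation rate and the mean
    segregating-site count across a grid of simulated configurations."""
    if len(results) < 2:
        raise ValueError("need >= 2 grid points")
    rates = np.array([r.total_gene_rate for r in results])
    means = np.array([r.mean_segregating_sites for r in results])
    if np.allclose(rates, rates[0]):
        raise ValueError("degenerate grid: all total rates equal")
    return float(np.corrcoef(rates, means)[0, 1])


def reference_grid(scale: dict | None = None, seed: int = 0) -> list[DriftConfig]:
    """The n_sites x site_mu factorial grid, optionally overridden by
    ``scale`` (a dict of DriftConfig field overrides for desk-scale runs)."""
    scale = scale or {}
    n_sites_values = scale.pop("n_sites_values", _REFERENCE_N_SITES)
    mu_values = scale.pop("site_mu_values", _REFERENCE_SITE_MU)
    grid = []
    for i, n_sites in enumerate(n_sites_values):
        for j, mu in enumerate(mu_values):
            grid.append(
                DriftConfig(
                    n_sites=n_sites,
                    site_mu=mu,
                    seed=seed + 1000 * i + j,
                    **scale,
                )
            )
    return grid
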