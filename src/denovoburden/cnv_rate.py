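"""Per-gene mutation rates of <1 Mb exon-deleting (LOF) CNVs.

Pipeline: pick neutral "training" genes (LOF-tolerant, no LOF-intolerant
gene within 1 Mb, autosomal); count 50 bp - 1 Mb exon-deleting deletion
sites per gene in a population SV catalog; regress the counts on five
genomic covariates (gene length, exon count, transcript length, nearby SD
pairs, telomere distance capped at 25 Mb) over all 2^5 - 1 = 31 covariate
subsets; select by AIC; predict relative rates for every gene; convert to
absolute de novo rates per individual per generation using the Watterson
estimator of the total rate in the training genes and the mean number of
training genes hit per CNV site:

    rate_g = total_abs_rate * genes_per_cnv / sum(relative, training) * relative_g
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genome_io import ConstraintRecord, GeneModel, SDPair, SVSite, overlaps_exon

logger = logging.getLogger("denovoburden")

COVARIATE_NAMES = (
    "gene_length_bp",
    "n_exons",
    "transcript_length_bp",
    "n_sd_pairs",
    "telomere_distance_bp",
)
TELOMERE_CAP_BP = 25_000_000
LOEUF_FIRST_DECILE = 0.278


@dataclass(frozen=True)
class CnvRateModel:
    """One fitted candidate regression model."""

    covariate_subset: tuple[str, ...]
    params: dict[str, float]  # includes "intercept"
    aic: float
    model_index: int
    family: str
    n_trials: int  # binomial total-trials N; unused for poisson
    converged: bool

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(covariates), self.params["intercept"])
        for name in self.covariate_subset:
            eta = eta + self.params[name] * covariates[name].to_numpy(dtype=float)
        return eta


# ---------------------------------------------------------------------------
# training-gene selection and covariates
# ---------------------------------------------------------------------------


def select_training_genes(
    genes: list[GeneModel],
    constraints: dict[str, ConstraintRecord],
    flank_bp: int = 1_000_000,
    loeuf_cutoff: float = LOEUF_FIRST_DECILE,
) -> list[str]:
    """Neutral training genes: autosomal, LOEUF >= cutoff (LOF-tolerant),
    and no LOF-intolerant gene (LOEUF < cutoff) within ``flank_bp`` of the
    gene body."""
    missing = [g.gene_id for g in genes if g.gene_id not in constraints]
    if missing:
        logger.info("select_training_genes: %d genes lack LOEUF, excluded", len(missing))
    intolerant = [
        g
        for g in genes
        if g.gene_id in constraints and constraints[g.gene_id].loeuf < loeuf_cutoff
    ]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in intolerant:
        by_chrom.setdefault(g.chrom, []).append(g)

    selected = []
    for g in genes:
        if g.gene_id not in constraints or not g.is_autosomal:
            continue
        if constraints[g.gene_id].loeuf < loeuf_cutoff:
            continue
        window_start = g.tx_start - flank_bp
        window_end = g.tx_end + flank_bp
        clash = any(
            other.tx_start < window_end and window_start < other.tx_end
            for other in by_chrom.get(g.chrom, [])
        )
        if not clash:
            selected.append(g.gene_id)
    return selected


def count_lof_cnv_sites(
    sites: list[SVSite],
    genes: list[GeneModel],
    min_bp: int = 50,
    max_bp: int = 1_000_000,
) -> pd.Series:
    """Per-gene count of exon-deleting deletion sites with
    ``min_bp <= size <= max_bp``; a site contributes to every gene whose
    exons it overlaps."""
    counts = pd.Series(0, index=[g.gene_id for g in genes], dtype=int)
    qualifying = [s for s in sites if min_bp <= s.size <= max_bp]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for site in qualifying:
        for gene in by_chrom.get(site.chrom, []):
            if overlaps_exon(site, gene):
                counts[gene.gene_id] += 1
    return counts


def _sd_pair_near_gene(pair: SDPair, gene: GeneModel, window_bp: int) -> bool:
    lo, hi = gene.tx_start - window_bp, gene.tx_end + window_bp
    for chrom, start, end in (pair.interval_a, pair.interval_b):
        if chrom == gene.chrom and start < hi and lo < end:
            return True
    return False


def compute_covariates(
    gene: GeneModel,
    sd_pairs: list[SDPair],
    chrom_lengths: dict[str, int],
    sd_window_bp: int = 1_000_000,
    sd_max_separation_bp: int = 1_000_000,
) -> dict[str, float]:
    """The five explanatory variables for one gene.

    Telomere distance is min(tx_start, chrom_len - tx_end) capped at 25 Mb
    (site counts are flat beyond that range).  The SD-pair count includes
    pairs whose members are < 1 Mb apart on the gene's chromosome with at
    least one member overlapping the gene body +/- ``sd_window_bp``.
    """
    if gene.chrom not in chrom_lengths:
        raise KeyError(f"unknown chromosome {gene.chrom!r}")
    chrom_len = chrom_lengths[gene.chrom]
    telomere = min(gene.tx_start, chrom_len - gene.tx_end)
    telomere = min(telomere, TELOMERE_CAP_BP)
    n_sd = sum(
        1
        for p in sd_pairs
        if p.interval_a[0] == p.interval_b[0] == gene.chrom
        and p.separation_bp < sd_max_separation_bp
        and _sd_pair_near_gene(p, gene, sd_window_bp)
    )
    return {
        "gene_id": gene.gene_id,
        "gene_length_bp": float(gene.gene_length_bp),
        "n_exons": float(gene.n_exons),
        "transcript_length_bp": float(gene.transcript_length_bp),
        "n_sd_pairs": float(n_sd),
        "telomere_distance_bp": float(telomere),
    }


def covariate_table(
    genes: list[GeneModel],
    sd_pairs: list[SDPair],
    chrom_lengths: dict[str, int],
    **kwargs,
) -> pd.DataFrame:
    rows = [compute_covariates(g, sd_pairs, chrom_lengths, **kwargs) for g in genes]
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# regression over all covariate subsets
# ---------------------------------------------------------------------------


def fit_cnv_models(
    counts: pd.Series,
    covariates: pd.DataFrame,
    family: str = "binomial",
    covariate_names: tuple[str, ...] = COVARIATE_NAMES,
) -> list[CnvRateModel]:
    """Fit one GLM per nonempty covariate subset (2^k - 1 models).

    ``binomial``: each gene's count is Binomial(N, p_g) with N the total
    qualifying site count over the training genes and a logit link.
    ``poisson``: log-link Poisson on the raw counts.  The two agree for
    small p; the binomial reading matches the response being a share of a
    fixed catalog of sites.
    """
    if len(counts) < 50:
        raise ValueError(f"need >= 50 training genes, got {len(counts)}")
    total = int(counts.sum())
    if total <= 0:
        raise ValueError("no qualifying sites in the training genes")
    if family not in {"binomial", "poisson"}:
        raise ValueError(f"unknown family {family!r}")
    covariates = covariates.loc[counts.index]
    y = counts.to_numpy(dtype=float)

    models: list[CnvRateModel] = []
    index = 0
    for k in range(1, len(covariate_names) + 1):
        for subset in combinations(covariate_names, k):
            index += 1
            X = sm.add_constant(
                covariates[list(subset)].to_numpy(dtype=float), has_constant="add"
            )
            try:
                if family == "binomial":
                    endog = np.column_stack([y, total - y])
                    fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
                else:
                    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
                converged = bool(fit.converged) and np.all(np.isfinite(fit.params))
            except Exception:  # noqa: BLE001 - any IRLS failure marks the model failed
                logger.warning("fit_cnv_models: subset %s failed to fit", subset)
                models.append(
                    CnvRateModel(subset, {}, float("inf"), index, family, total, False)
                )
                continue
            if not converged:
                logger.warning("fit_cnv_models: subset %s did not converge", subset)
            params = {"intercept": float(fit.params[0])}
            params.update({name: float(b) for name, b in zip(subset, fit.params[1:])})
            models.append(
                CnvRateModel(
                    covariate_subset=subset,
                    params=params,
                    aic=float(fit.aic),
                    model_index=index,
                    family=family,
                    n_trials=total,
                    converged=converged,
                )
            )
    return models


def select_best_model(models: list[CnvRateModel]) -> CnvRateModel:
    """Lowest-AIC converged model; AIC ties broken toward fewer covariates."""
    ok = [m for m in models if m.converged and np.isfinite(m.aic)]
    if not ok:
        raise ValueError("no successfully fitted model")
    return min(ok, key=lambda m: (m.aic, len(m.covariate_subset)))


def predict_relative_rates(model: CnvRateModel, covariates: pd.DataFrame) -> pd.Series:
    """Predicted per-gene relative CNV mutation rates (expected site counts
    under the fitted model; any overall scale cancels in absolutization)."""
    missing = covariates[list(model.covariate_subset)].isna().any(axis=1)
    if missing.any():
        logger.info("predict_relative_rates: %d genes missing covariates, excluded", int(missing.sum()))
        covariates = covariates[~missing]
    eta = model.linear_predictor(covariates)
    if model.family == "binomial":
        mu = model.n_trials / (1.0 + np.exp(-eta))
    else:
        mu = np.exp(eta)
    return pd.Series(mu, index=covariates.index, name="relative_rate")


# ---------------------------------------------------------------------------
# absolutization via the Watterson estimator
# ---------------------------------------------------------------------------


def watterson_total_rate(K: int, n_alleles: int, Ne: int) -> float:
    """Total mutation rate per generation from K segregating sites in a
    sample of ``n_alleles`` alleles: theta = K / a_{n-1}, mu = theta / (4*Ne)."""
    if n_alleles < 2:
        raise ValueError("need >= 2 alleles")
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    if K < 0:
        raise ValueError("K must be nonnegative")
    a = float(np.sum(1.0 / np.arange(1, n_alleles)))
    return K / (a * 4.0 * Ne)


def average_population_rates(rates: list[float]) -> float:
    """Unweighted mean of per-population total-rate estimates."""
    if not rates:
        raise ValueError("no population estimates")
    return float(np.mean(rates))


def genes_per_cnv(
    sites: list[SVSite],
    training_gene_ids: list[str],
    genes: list[GeneModel],
    min_bp: int = 50,
    max_bp: int = 1_000_000,
) -> float:
    """Mean number of training genes exon-overlapped per qualifying site,
    over sites hitting at least one training gene (~1.2 in the reference
    catalog)."""
    training = [g for g in genes if g.gene_id in set(training_gene_ids)]
    per_site = []
    for site in sites:
        if not min_bp <= site.size <= max_bp:
            continue
        n = sum(1 for g in training if overlaps_exon(site, g))
        if n > 0:
            per_site.append(n)
    if not per_site:
        raise ValueError("no qualifying sites hit a training gene")
    return float(np.mean(per_site))


def absolutize_rates(
    relative_rates: pd.Series,
    total_abs_rate: float,
    genes_per_cnv_factor: float,
    training_gene_ids: list[str],
) -> pd.Series:
    """Absolute de novo <1 Mb LOF-CNV rate per individual per generation:

        rate_g = total_abs_rate * genes_per_cnv / sum(rel, training) * rel_g

    The training-gene absolute rates then sum to
    ``total_abs_rate * genes_per_cnv`` (0.00155 * 1.2 = 0.00186 in the
    reference catalog).
    """
    training = [g for g in training_gene_ids if g in relative_rates.index]
    rel_total = float(relative_rates.loc[training].sum())
    if rel_total <= 0:
        raise ValueError("training genes' relative rates sum to zero")
    scale = total_abs_rate * genes_per_cnv_factor / rel_total
    out = relative_rates * scale
    out.name = "absolute_rate"
    return out


def oe_ratio(observed: pd.Series, expected: pd.Series) -> pd.Series:
    """Per-gene observed/expected ratio; genes with expected <= 0 omitted."""
    expected = expected.reindex(observed.index)
    bad = ~(expected > 0)
    if bad.any():
        logger.info("oe_ratio: %d genes with expected <= 0 omitted", int(bad.sum()))
    keep = ~bad
    return observed[keep] / expected[keep]
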