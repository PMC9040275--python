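"""Per-gene Poisson burden tests of de novo LOF and damaging-missense
events across merged cohorts, two-step multiple-testing correction, and
candidate-gene classification.

Under the null, the observed DNM count in a gene follows a Poisson
distribution with mean lambda = (per-individual mutation rate) x (number of
trios); sums over cohorts and over SNV/CNV sources remain Poisson with the
summed mean.  Three one-sided tests are run per gene (LOF, d-MIS,
LOF + d-MIS) where MPC annotation exists, else LOF only; the gene-level
minimum Bonferroni-adjusted p is then BH-adjusted exome-wide (q < 0.05).
A flat Bonferroni mode (alpha / (n_genes x 3)) is available.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import DnmRecord, LOF_SNV_CLASSES

logger = logging.getLogger("denovoburden")

DEFAULT_ALPHA = 0.05
DEFAULT_MPC_CUTOFF = 2.0
MAX_DNCNV_BP = 1_000_000  # larger de novo CNV calls are discarded
PLI_PLAUSIBLE = 0.9
LOEUF_PLAUSIBLE = 0.35
MISSENSE_Z_PLAUSIBLE = 2.5


@dataclass(frozen=True)
class GeneTestInput:
    """Observed counts and Poisson means for one gene across all cohorts."""

    gene_id: str
    lam_lof: float
    lam_dmis: float
    obs_lof: int
    obs_dmis: int
    has_mpc: bool = True

    def __post_init__(self) -> None:
        if self.lam_lof < 0 or self.lam_dmis < 0:
            raise ValueError(f"{self.gene_id}: negative Poisson mean")
        if self.obs_lof < 0 or self.obs_dmis < 0:
            raise ValueError(f"{self.gene_id}: negative observed count")


@dataclass(frozen=True)
class EnrichmentResult:
    gene_id: str
    p_lof: float
    p_dmis: float | None
    p_combined: float | None
    n_tests: int
    p_gene: float
    q: float = float("nan")
    significant: bool = False


@dataclass(frozen=True)
class CandidateCall:
    gene_id: str
    status: str  # known | new
    plausible: bool
    rationale: str  # lof_constrained | dmis_constrained | recurrent_dmis | excluded


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------


def expected_count(rate: float, n_trios: int) -> float:
    """Poisson mean: per-individual per-generation rate x number of trios."""
    if rate < 0 or n_trios < 0:
        raise ValueError("rate and n_trios must be nonnegative")
    return rate * n_trios


def combine_expectations(lams: list[float]) -> float:
    """Sum of independent Poisson means (itself a Poisson mean)."""
    if any(lam < 0 for lam in lams):
        raise ValueError("negative Poisson mean")
    return float(sum(lams))


def poisson_upper_p(observed: int, lam: float) -> float:
    """P(X >= observed) for X ~ Poisson(lam); 1 when observed = 0."""
    if observed < 0 or lam < 0:
        raise ValueError("observed and lam must be nonnegative")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))


def expected_false_positives(n_significant: int, fdr: float) -> float:
    """Theoretically expected false positives among the significant genes
    (e.g. 380 x 0.05 = 19)."""
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    return n_significant * fdr


# ---------------------------------------------------------------------------
# assembling test inputs from DNM tables
# ---------------------------------------------------------------------------


def observed_counts(
    dnms: list[DnmRecord],
    mpc_cutoff: float = DEFAULT_MPC_CUTOFF,
) -> pd.DataFrame:
    """Per-gene observed LOF (SNV/indel LOF classes + exon-deleting CNVs)
    and d-MIS (missense with MPC > cutoff) DNM counts."""
    lof: Counter[str] = Counter()
    dmis: Counter[str] = Counter()
    for rec in dnms:
        if rec.consequence in LOF_SNV_CLASSES or rec.consequence == "cnv_lof":
            lof[rec.gene_id] += 1
        elif (
            rec.consequence == "missense"
            and rec.mpc is not None
            and rec.mpc > mpc_cutoff
        ):
            dmis[rec.gene_id] += 1
    genes = sorted(set(lof) | set(dmis))
    return pd.DataFrame(
        {
            "obs_lof": [lof.get(g, 0) for g in genes],
            "obs_dmis": [dmis.get(g, 0) for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )


def assemble_inputs(
    rate_tables: dict[str, pd.DataFrame],
    n_trios: dict[str, int],
    dnms: list[DnmRecord],
    mpc_cutoff: float = DEFAULT_MPC_CUTOFF,
    cnv_trios: dict[str, int] | None = None,
) -> list[GeneTestInput]:
    """Build per-gene test inputs from per-cohort calibrated rate tables.

    ``rate_tables[cohort]`` holds columns ``lof_snv``, ``d_mis`` and
    optionally ``lof_cnv``; SNV means use ``n_trios[cohort]`` and CNV means
    ``cnv_trios[cohort]`` (defaults to the SNV trio count), reflecting that
    de novo CNV data are typically available for a subset of the trios.
    """
    cnv_trios = cnv_trios or {}
    genes: set[str] = set()
    for table in rate_tables.values():
        genes |= set(table.index)
    obs = observed_counts(dnms, mpc_cutoff)
    genes |= set(obs.index)

    lam_lof = pd.Series(0.0, index=sorted(genes))
    lam_dmis = pd.Series(0.0, index=sorted(genes))
    has_mpc = pd.Series(False, index=sorted(genes))
    for cohort, table in rate_tables.items():
        n = n_trios.get(cohort, 0)
        snv = table["lof_snv"].reindex(lam_lof.index).fillna(0.0)
        lam_lof += snv * n
        if "lof_cnv" in table.columns:
            n_cnv = cnv_trios.get(cohort, n)
            lam_lof += table["lof_cnv"].reindex(lam_lof.index).fillna(0.0) * n_cnv
        if "d_mis" in table.columns:
            d = table["d_mis"].reindex(lam_dmis.index)
            has_mpc |= d.notna()
            lam_dmis += d.fillna(0.0) * n

    inputs = []
    for g in lam_lof.index:
        inputs.append(
            GeneTestInput(
                gene_id=g,
                lam_lof=float(lam_lof[g]),
                lam_dmis=float(lam_dmis[g]),
                obs_lof=int(obs["obs_lof"].get(g, 0)),
                obs_dmis=int(obs["obs_dmis"].get(g, 0)),
                has_mpc=bool(has_mpc[g]),
            )
        )
    return inputs


def filter_large_dncnvs(
    dnms: list[DnmRecord],
    sizes_bp: dict[tuple[str, str], int],
    max_bp: int = MAX_DNCNV_BP,
) -> list[DnmRecord]:
    """Drop cnv_lof calls larger than ``max_bp`` (their sizes supplied per
    (sample_id, gene_id)); such calls are usually pathogenic multi-gene
    events that the per-gene model does not cover."""
    kept = []
    dropped = 0
    for rec in dnms:
        if rec.consequence == "cnv_lof":
            size = sizes_bp.get((rec.sample_id, rec.gene_id))
            if size is not None and size > max_bp:
                dropped += 1
                continue
        kept.append(rec)
    if dropped:
        logger.info("filter_large_dncnvs: discarded %d calls > %d bp", dropped, max_bp)
    return kept


# ---------------------------------------------------------------------------
# tests and correction
# ---------------------------------------------------------------------------


def run_gene_tests(inputs: list[GeneTestInput]) -> list[EnrichmentResult]:
    """Three one-sided Poisson tests per gene (LOF, d-MIS, LOF + d-MIS);
    genes without MPC annotation get the LOF test only."""
    results = []
    for gi in inputs:
        p_lof = poisson_upper_p(gi.obs_lof, gi.lam_lof)
        if gi.has_mpc:
            p_dmis = poisson_upper_p(gi.obs_dmis, gi.lam_dmis)
            p_comb = poisson_upper_p(gi.obs_lof + gi.obs_dmis, gi.lam_lof + gi.lam_dmis)
            n_tests = 3
            p_gene = min(min(1.0, n_tests * p) for p in (p_lof, p_dmis, p_comb))
        else:
            p_dmis = p_comb = None
            n_tests = 1
            p_gene = p_lof
        results.append(
            EnrichmentResult(
                gene_id=gi.gene_id,
                p_lof=p_lof,
                p_dmis=p_dmis,
                p_combined=p_comb,
                n_tests=n_tests,
                p_gene=p_gene,
            )
        )
    return results


def two_step_adjust(
    results: list[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
    mode: str = "two_step",
    n_genes_flat: int | None = None,
) -> list[EnrichmentResult]:
    """Exome-wide adjustment of the gene-level p-values.

    ``two_step`` (default): BH step-up over each gene's Bonferroni minimum
    ``p_gene``; significant iff q < alpha.  ``flat``: each individual test
    is compared against alpha / (n_genes x 3) (8.3e-7 for 20,034 genes at
    alpha 0.05); q is still reported for reference.
    """
    if not results:
        return []
    p_gene = np.array([r.p_gene for r in results])
    _, q, _, _ = multipletests(p_gene, method="fdr_bh")
    if mode == "two_step":
        significant = q < alpha
    elif mode == "flat":
        threshold = flat_bonferroni_threshold(
            n_genes_flat if n_genes_flat is not None else len(results), alpha=alpha
        )
        significant = np.array(
            [
                min(p for p in (r.p_lof, r.p_dmis, r.p_combined) if p is not None)
                < threshold
                for r in results
            ]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [
        EnrichmentResult(
            gene_id=r.gene_id,
            p_lof=r.p_lof,
            p_dmis=r.p_dmis,
            p_combined=r.p_combined,
            n_tests=r.n_tests,
            p_gene=r.p_gene,
            q=float(qi),
            significant=bool(si),
        )
        for r, qi, si in zip(results, q, significant)
    ]


def flat_bonferroni_threshold(
    n_genes: int, n_tests_per_gene: int = 3, alpha: float = DEFAULT_ALPHA
) -> float:
    """Per-test significance threshold alpha / (n_genes x tests-per-gene)."""
    if n_genes <= 0 or n_tests_per_gene <= 0:
        raise ValueError("counts must be positive")
    return alpha / (n_genes * n_tests_per_gene)


# ---------------------------------------------------------------------------
# candidate classification
# ---------------------------------------------------------------------------


def _has_recurrent_dmis(
    gene_id: str, dnms: list[DnmRecord], mpc_cutoff: float = DEFAULT_MPC_CUTOFF
) -> bool:
    positions = Counter(
        rec.amino_acid_position
        for rec in dnms
        if rec.gene_id == gene_id
        and rec.consequence == "missense"
        and rec.mpc is not None
        and rec.mpc > mpc_cutoff
        and rec.amino_acid_position is not None
    )
    return any(count >= 2 for count in positions.values())


def classify_candidates(
    results: list[EnrichmentResult],
    known_genes: list[str],
    constraints,
    dnms: list[DnmRecord],
    alpha: float = DEFAULT_ALPHA,
    exclude: list[str] | None = None,
) -> list[CandidateCall]:
    """Split significant genes into known/new and flag plausible new genes.

    A new gene is plausible if it is (1) LOF-enriched and strongly
    LOF-constrained (pLI > 0.9 and LOEUF < 0.35), or (2) d-MIS-enriched
    and either missense-constrained (missense z > 2.5) or carrying >= 2
    d-MIS DNMs at the same amino-acid position.  ``exclude`` holds manually
    curated removals; curation itself is never automated.
    """
    known = set(known_genes)
    excluded = set(exclude or [])
    calls = []
    for r in results:
        if not r.significant or r.gene_id in excluded:
            continue
        if r.gene_id in known:
            calls.append(CandidateCall(r.gene_id, "known", False, "excluded"))
            continue
        c = constraints.get(r.gene_id)
        lof_enriched = min(1.0, r.n_tests * r.p_lof) < alpha or (
            r.p_combined is not None and min(1.0, r.n_tests * r.p_combined) < alpha
        )
        dmis_enriched = r.p_dmis is not None and min(1.0, r.n_tests * r.p_dmis) < alpha
        if (
            lof_enriched
            and c is not None
            and c.pli > PLI_PLAUSIBLE
            and c.loeuf < LOEUF_PLAUSIBLE
        ):
            calls.append(CandidateCall(r.gene_id, "new", True, "lof_constrained"))
        elif dmis_enriched and c is not None and c.missense_z > MISSENSE_Z_PLAUSIBLE:
            calls.append(CandidateCall(r.gene_id, "new", True, "dmis_constrained"))
        elif dmis_enriched and _has_recurrent_dmis(r.gene_id, dnms):
            calls.append(CandidateCall(r.gene_id, "new", True, "recurrent_dmis"))
        else:
            calls.append(CandidateCall(r.gene_id, "new", False, "excluded"))
    return calls


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """EnrichmentResult list as a DataFrame indexed by gene."""
    return pd.DataFrame(
        {
            "p_lof": [r.p_lof for r in results],
            "p_dmis": [r.p_dmis for r in results],
            "p_combined": [r.p_combined for r in results],
            "n_tests": [r.n_tests for r in results],
            "p_gene": [r.p_gene for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
        },
        index=pd.Index([r.gene_id for r in results], name="gene_id"),
    )
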