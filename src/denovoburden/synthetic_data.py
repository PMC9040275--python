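"""Synthetic inputs with known ground truth for every stage of the
framework: a toy genome (genes, exons, SD pairs, constraint table), an SV
site catalog drawn from a known per-gene log-linear rate law, de novo
variant cohorts with spiked-in enriched genes, and predictor tables with
controllable class separation.

Every generator takes an explicit seed and is bitwise reproducible; a
manifest dict recording the generating parameters accompanies each output.
Defaults emulate the structure of the real inputs at desk scale: a few
hundred genes on a handful of ~100 Mb chromosomes, per-gene de novo rates
of order 1e-6 to 1e-4, cohort sizes in the tens of thousands of trios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import ConstraintRecord, DnmRecord, GeneModel, SDPair, SVSite

#: generating slope coefficients of the deletion-site rate law, per raw
#: covariate unit (a 100 kb gene contributes 0.5 to the linear predictor)
DEFAULT_SV_COEFFICIENTS = {"gene_length_bp": 5e-6, "n_exons": 0.05}


@dataclass
class SyntheticGenome:
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    sd_pairs: list[SDPair]
    constraints: dict[str, ConstraintRecord]
    manifest: dict = field(default_factory=dict)


def make_genome(
    seed: int,
    n_chroms: int = 4,
    n_genes: int = 200,
    median_gene_length_bp: float = 30_000,
    gene_length_sigma: float = 0.8,
    median_intergenic_bp: float = 300_000,
    intolerant_frac: float = 0.1,
    sd_pairs_per_chrom: int = 6,
    include_allosome: bool = True,
) -> SyntheticGenome:
    """A toy genome of non-overlapping genes laid down left to right.

    Gene lengths and exon counts are log-normal; exons are placed uniformly
    inside each gene.  A fraction of genes is marked LOF-intolerant
    (LOEUF < 0.278) in clusters of 1-3 adjacent genes, so that the 1 Mb
    flanking rule of training-gene selection actually removes neighbours.
    An X chromosome carries a share of the genes when ``include_allosome``.
    """
    if n_genes < 10:
        raise ValueError("need n_genes >= 10")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    if include_allosome:
        chrom_names.append("chrX")
    per_chrom = np.array_split(np.arange(n_genes), len(chrom_names))

    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    sd_pairs: list[SDPair] = []
    gi = 0
    for chrom, idxs in zip(chrom_names, per_chrom):
        pos = int(rng.integers(50_000, 2_000_000))  # variable telomere offset
        for _ in idxs:
            length = int(
                np.clip(
                    rng.lognormal(np.log(median_gene_length_bp), gene_length_sigma),
                    2_000,
                    2_000_000,
                )
            )
            n_exons = int(np.clip(round(rng.lognormal(np.log(8), 0.6)), 1, 60))
            exons = _place_exons(rng, pos, pos + length, n_exons)
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:04d}",
                    chrom=chrom,
                    strand=rng.choice(["+", "-"]),
                    tx_start=pos,
                    tx_end=pos + length,
                    exons=exons,
                    cds_length_bp=int(sum(e - s for s, e in exons) * 0.8),
                    is_autosomal=chrom != "chrX",
                )
            )
            gi += 1
            pos += length + int(rng.exponential(median_intergenic_bp)) + 1_000
        chrom_lengths[chrom] = pos + int(rng.integers(100_000, 30_000_000))
        for _ in range(sd_pairs_per_chrom):
            a_start = int(rng.integers(0, max(1, chrom_lengths[chrom] - 2_200_000)))
            a_len = int(rng.integers(10_000, 100_000))
            gap = int(rng.integers(1_000, 900_000))
            b_start = a_start + a_len + gap
            sd_pairs.append(
                SDPair(
                    (chrom, a_start, a_start + a_len),
                    (chrom, b_start, b_start + a_len),
                )
            )

    constraints = _make_constraints(rng, genes, intolerant_frac)
    manifest = {
        "seed": seed,
        "n_chroms": n_chroms,
        "n_genes": n_genes,
        "median_gene_length_bp": median_gene_length_bp,
        "intolerant_frac": intolerant_frac,
    }
    return SyntheticGenome(genes, chrom_lengths, sd_pairs, constraints, manifest)


def _place_exons(rng, tx_start: int, tx_end: int, n_exons: int):
    span = tx_end - tx_start
    if n_exons == 1:
        return ((tx_start, tx_end),)
    # split the gene into n_exons blocks, one exon inside each block
    bounds = np.linspace(tx_start, tx_end, n_exons + 1).astype(int)
    exons = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        block = hi - lo
        elen = int(np.clip(rng.lognormal(np.log(150), 0.5), 20, max(21, block - 2)))
        offset = int(rng.integers(0, max(1, block - elen)))
        exons.append((lo + offset, lo + offset + elen))
    exons[0] = (tx_start, exons[0][1])  # anchor first/last exon to tx bounds
    exons[-1] = (exons[-1][0], tx_end)
    return tuple(exons)


def _make_constraints(rng, genes, intolerant_frac):
    n = len(genes)
    intolerant = np.zeros(n, dtype=bool)
    target = int(round(intolerant_frac * n))
    while intolerant.sum() < target:
        start = int(rng.integers(0, n))
        for j in range(start, min(n, start + int(rng.integers(1, 4)))):
            intolerant[j] = True
    constraints = {}
    for g, bad in zip(genes, intolerant):
        if bad:
            loeuf = float(rng.uniform(0.03, 0.27))
            pli = float(rng.uniform(0.9, 1.0))
            mis_z = float(rng.normal(3.0, 0.8))
        else:
            loeuf = float(rng.uniform(0.3, 2.0))
            pli = float(rng.uniform(0.0, 0.5))
            mis_z = float(rng.normal(0.0, 1.0))
        constraints[g.gene_id] = ConstraintRecord(
            gene_id=g.gene_id,
            pli=pli,
            loeuf=loeuf,
            missense_z=mis_z,
            oe_lof=loeuf * 0.8,
            cds_length_bp=g.cds_length_bp,
        )
    return constraints


# ---------------------------------------------------------------------------
# SV catalog from a known rate law
# ---------------------------------------------------------------------------


def make_sv_catalog(
    genome: SyntheticGenome,
    covariates: pd.DataFrame,
    total_sites: int,
    seed: int,
    coefficients: dict[str, float] | None = None,
    population: str = "ALL",
    max_site_bp: int = 20_000,
) -> tuple[list[SVSite], pd.Series]:
    """Deletion sites with per-gene counts Poisson around expectations
    proportional to exp(sum_j beta_j x_gj).

    Each site is placed to overlap one exon of its gene, with sizes in
    [50, ``max_site_bp``] bp (small against intergenic gaps, so sites
    rarely straddle neighbouring genes).  Returns the catalog and the
    per-gene expected counts (the ground truth).
    """
    coefficients = DEFAULT_SV_COEFFICIENTS if coefficients is None else coefficients
    rng = np.random.default_rng(seed)
    eta = np.zeros(len(covariates))
    for name, beta in coefficients.items():
        eta = eta + beta * covariates[name].to_numpy(dtype=float)
    weights = np.exp(eta - eta.max())
    mu = total_sites * weights / weights.sum()
    expected = pd.Series(mu, index=covariates.index, name="expected_sites")
    if total_sites == 0:
        return [], expected

    counts = rng.poisson(mu)
    by_id = {g.gene_id: g for g in genome.genes}
    sites = []
    for gene_id, k in zip(covariates.index, counts):
        gene = by_id[gene_id]
        for _ in range(int(k)):
            ex_start, ex_end = gene.exons[rng.integers(0, len(gene.exons))]
            size = int(rng.integers(50, max_site_bp + 1))
            start = int(rng.integers(max(0, ex_start - size + 1), ex_end))
            sites.append(
                SVSite(
                    chrom=gene.chrom,
                    start=start,
                    end=start + size,
                    sv_type="DEL",
                    population=population,
                    allele_count=int(rng.integers(1, 10)),
                )
            )
    return sites, expected


# ---------------------------------------------------------------------------
# DNM cohorts with spiked genes
# ---------------------------------------------------------------------------


def make_dnm_cohort(
    rate_table: pd.DataFrame,
    n_trios: int,
    seed: int,
    spikes: dict[str, float] | None = None,
    cohort: str = "synthetic",
    recurrent_genes: dict[str, int] | None = None,
) -> list[DnmRecord]:
    """De novo call list with per-gene class counts ~ Poisson(fold x rate x
    n_trios).

    ``rate_table`` columns follow the per-gene rate schema (synonymous,
    missense, d_mis, nonsense, splice, frameshift, lof_cnv); d-MIS records
    get MPC drawn in (2, 5], other missense in [0, 2].  ``recurrent_genes``
    forces that many of a gene's d-MIS calls onto one amino-acid position,
    exercising the recurrence rule of candidate classification.
    """
    spikes = spikes or {}
    recurrent_genes = recurrent_genes or {}
    if any(f < 1 for f in spikes.values()):
        raise ValueError("spike folds must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[DnmRecord] = []
    if n_trios == 0:
        return records
    sample_counter = 0

    def new_sample():
        nonlocal sample_counter
        sample_counter += 1
        return f"{cohort}_s{sample_counter:06d}"

    for gene_id, row in rate_table.iterrows():
        fold = spikes.get(gene_id, 1.0)
        dmis_rate = 0.0 if pd.isna(row.get("d_mis", np.nan)) else float(row["d_mis"])

        def draw(rate):
            return int(rng.poisson(max(rate, 0.0) * fold * n_trios))

        for _ in range(draw(row.get("synonymous", 0.0))):
            records.append(DnmRecord(new_sample(), gene_id, "synonymous", cohort=cohort))
        benign_mis = max(float(row.get("missense", 0.0)) - dmis_rate, 0.0)
        for _ in range(draw(benign_mis)):
            records.append(
                DnmRecord(
                    new_sample(),
                    gene_id,
                    "missense",
                    mpc=float(rng.uniform(0.0, 2.0)),
                    cohort=cohort,
                    amino_acid_position=int(rng.integers(1, 500)),
                )
            )
        n_dmis = draw(dmis_rate)
        forced = min(recurrent_genes.get(gene_id, 0), max(n_dmis, 2))
        n_dmis = max(n_dmis, forced)
        shared_pos = int(rng.integers(1, 500))
        for j in range(n_dmis):
            pos = shared_pos if j < forced else int(rng.integers(1, 500))
            records.append(
                DnmRecord(
                    new_sample(),
                    gene_id,
                    "missense",
                    mpc=float(rng.uniform(2.0, 5.0)),
                    cohort=cohort,
                    amino_acid_position=pos,
                )
            )
        for _ in range(draw(row.get("nonsense", 0.0))):
            records.append(DnmRecord(new_sample(), gene_id, "nonsense", cohort=cohort))
        for _ in range(draw(row.get("frameshift", 0.0))):
            records.append(DnmRecord(new_sample(), gene_id, "frameshift", cohort=cohort))
        for _ in range(draw(row.get("splice", 0.0))):
            cls = "splice_acceptor" if rng.random() < 0.5 else "splice_donor"
            records.append(DnmRecord(new_sample(), gene_id, cls, cohort=cohort))
        for _ in range(draw(row.get("lof_cnv", 0.0))):
            records.append(DnmRecord(new_sample(), gene_id, "cnv_lof", cohort=cohort))
    return records


def make_rate_table(
    gene_ids: list[str],
    seed: int,
    mean_syn: float = 1.0e-5,
    large_gene_ids: list[str] | None = None,
    large_gene_scale: float = 8.0,
) -> pd.DataFrame:
    """Per-gene class rates on a realistic scale: synonymous around 1e-5
    per individual per generation, missense ~2.2x synonymous, d-MIS ~15%
    of missense, nonsense ~0.12x synonymous, CNV-LOF around 1e-6.
    ``large_gene_ids`` get all rates multiplied by ``large_gene_scale``,
    emulating long constrained genes."""
    rng = np.random.default_rng(seed)
    large = set(large_gene_ids or [])
    rows = []
    for g in gene_ids:
        scale = large_gene_scale if g in large else float(rng.lognormal(0.0, 0.6))
        syn = mean_syn * scale
        mis = 2.2 * syn
        dmis = 0.15 * mis
        non = 0.12 * syn
        splice = 0.3 * non
        fs = 1.1 * non
        rows.append(
            {
                "gene_id": g,
                "synonymous": syn,
                "missense": mis,
                "d_mis": dmis,
                "nonsense": non,
                "splice": splice,
                "frameshift": fs,
                "lof_snv": non + splice + fs,
                "lof_cnv": 1.0e-6 * scale,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# predictor tables for the similarity model
# ---------------------------------------------------------------------------


def make_predictor_table(
    n_pos: int,
    n_neg: int,
    separation: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.Series]:
    """Class-conditional predictor table: numeric predictors are Gaussian
    with a mean shift of ``separation`` (signed by the direction the
    predictor moves in real disease genes), binary predictors Bernoulli
    with a class-dependent probability, the module categorical skewed
    toward the enriched modules in positives.  ``separation`` 0 makes the
    classes exchangeable."""
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.array([1] * n_pos + [0] * n_neg)
    sep = separation * labels
    p_flag = 1.0 / (1.0 + np.exp(-(sep - separation / 2.0 if separation else 0.0)))
    df = pd.DataFrame(
        {
            "pli": np.clip(0.5 + 0.15 * (sep - separation / 2) + 0.15 * rng.normal(size=n), 0, 1),
            "loeuf": np.clip(1.0 - 0.2 * sep + 0.25 * rng.normal(size=n), 0.01, None),
            "missense_z": sep + rng.normal(size=n),
            "tsea_brain": rng.binomial(1, p_flag),
            "brain_coord_count": rng.poisson(1 + 2 * sep),
            "go_term_count": rng.poisson(2 + 5 * sep),
            "string_member": rng.binomial(1, p_flag),
            "cds_length": rng.lognormal(np.log(1500), 0.5, size=n).astype(int),
            "module": [
                rng.choice(["M1", "M4", "M7", "M13"])
                if (lab and rng.random() < min(0.2 * separation, 0.8))
                else rng.choice(["M2", "M5", "Others"])
                for lab in labels
            ],
        },
        index=pd.Index([f"P{i:04d}" for i in range(n)], name="gene_id"),
    )
    return df, pd.Series(labels, index=df.index, name="label")
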