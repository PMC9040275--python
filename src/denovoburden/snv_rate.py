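"""Per-gene de novo SNV/indel mutation rates from trinucleotide-context
per-possible-variant rate lists, with sequencing-depth adjustment and
per-cohort calibration.

Class rates per gene are sums of the (depth-adjusted) rates of all possible
variants in the class.  Frameshift indel rates are 1.1 x the nonsense rate
(the observed frameshift:nonsense DNM ratio in large exome data), and the
LOF-SNV rate is nonsense + splice + frameshift.  Cohorts without per-base
depth are instead calibrated by a single multiplier, the observed/expected
ratio of rare synonymous DNMs in that cohort (0.76 and 0.67 for the two
reference meta-cohorts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

logger = logging.getLogger("denovoburden")

RATE_CLASSES = (
    "synonymous",
    "missense",
    "d_mis",
    "nonsense",
    "splice",
    "frameshift",
    "lof_snv",
    "lof_cnv",
)
DEPTH_FULL_COVERAGE = 40.0
DEPTH_SLOPE = 0.025
FRAMESHIFT_TO_NONSENSE = 1.1
DEFAULT_MPC_CUTOFF = 2.0


@dataclass(frozen=True)
class CohortCalibration:
    """Synonymous observed/expected multiplier for one cohort."""

    cohort: str
    syn_observed: int
    syn_expected: float

    @property
    def multiplier(self) -> float:
        if self.syn_expected <= 0:
            raise ValueError("syn_expected must be positive")
        m = self.syn_observed / self.syn_expected
        if m <= 0:
            raise ValueError("calibration multiplier must be positive")
        return m


def depth_adjust(rate: float, depth: float | None) -> float:
    """Scale a per-variant rate by 0.025 x depth when median depth < 40x
    (0.025 x 40 = 1, so the adjustment is continuous); no depth, no change."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if depth is None:
        return rate
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if depth < DEPTH_FULL_COVERAGE:
        return rate * DEPTH_SLOPE * depth
    return rate


def read_possible_variants(stream: Iterable[str]) -> pd.DataFrame:
    """Parse a per-possible-variant TSV: gene, pos, ref, alt, context, rate,
    consequence[, mpc, depth]."""
    df = pd.read_csv(stream, sep="\t", comment="#")
    required = {"gene", "rate", "consequence"}
    if not required <= set(df.columns):
        raise ValueError(f"possible-variant table missing {required - set(df.columns)}")
    if (df["rate"] <= 0).any():
        raise ValueError("per-variant rates must be positive")
    return df


def aggregate_gene_rates(
    possible_variants: pd.DataFrame,
    mpc_cutoff: float = DEFAULT_MPC_CUTOFF,
    frameshift_ratio: float = FRAMESHIFT_TO_NONSENSE,
    apply_depth: bool = True,
) -> pd.DataFrame:
    """Per-gene, per-class rate table from a per-possible-variant list.

    d-MIS (damaging missense) is the sum over missense variants with
    MPC > ``mpc_cutoff``; genes whose missense variants carry no MPC
    annotation get NaN there and are burden-tested once (LOF only).
    Splice acceptor/donor rates are summed into a single ``splice`` class.
    """
    df = possible_variants.copy()
    if apply_depth and "depth" in df.columns:
        df["rate"] = [
            depth_adjust(r, None if pd.isna(d) else float(d))
            for r, d in zip(df["rate"], df["depth"])
        ]
    if "mpc" not in df.columns:
        df["mpc"] = float("nan")

    genes = df["gene"].unique()
    out = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"), columns=list(RATE_CLASSES))

    def class_sum(mask: pd.Series) -> pd.Series:
        return df.loc[mask].groupby("gene")["rate"].sum()

    for cls in ("synonymous", "missense", "nonsense"):
        s = class_sum(df["consequence"] == cls)
        out.loc[s.index, cls] = s
    splice = class_sum(df["consequence"].isin(["splice_acceptor", "splice_donor"]))
    out.loc[splice.index, "splice"] = splice

    dmis = class_sum((df["consequence"] == "missense") & (df["mpc"] > mpc_cutoff))
    out.loc[dmis.index, "d_mis"] = dmis
    # a gene whose missense variants are all unannotated has no d-MIS model
    mis_annotated = df.loc[df["consequence"] == "missense"].groupby("gene")["mpc"].apply(
        lambda s: s.notna().any()
    )
    no_mpc = mis_annotated.index[~mis_annotated]
    out.loc[no_mpc, "d_mis"] = float("nan")
    if len(no_mpc):
        logger.info("aggregate_gene_rates: %d genes lack MPC annotation", len(no_mpc))

    out["frameshift"] = out["nonsense"] * frameshift_ratio
    out["lof_snv"] = out["nonsense"] + out["splice"] + out["frameshift"]
    return out


def calibrate_cohort(rate_table: pd.DataFrame, calibration: CohortCalibration) -> pd.DataFrame:
    """Scale every per-gene per-class SNV/indel rate by the cohort's
    synonymous observed/expected multiplier, so the cohort's expected
    synonymous count matches its observed count by construction.  The
    CNV-LOF column, which comes from the deletion-rate model rather than the
    trinucleotide model, is left untouched."""
    out = rate_table * calibration.multiplier
    if "lof_cnv" in rate_table.columns:
        out["lof_cnv"] = rate_table["lof_cnv"]
    return out
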