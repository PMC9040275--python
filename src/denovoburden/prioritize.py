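"""Candidate-gene prioritization: a feed-forward similarity model over
gene-level predictors, AUC comparison with retraining-based empirical
p-values, and conversion of model scores to true-positive posterior
probabilities via kernel-density likelihood ratios and naive Bayes.

The model scores how similar a gene's predictor profile is to known
disease genes.  Predictors: pLI, LOEUF, missense z, brain-specific
expression (binary), count of known-gene-enriched brain coordinates with
specific expression, co-expression module (categorical, the four
known-gene-enriched modules vs Others), count of known-gene-enriched GO
terms containing the gene, membership of a known-gene-enriched PPI cluster
(binary), and CDS length.  Architecture: two 128-unit ReLU hidden layers
and a sigmoid output trained with Adam on binary cross-entropy, batch size
5, five epochs over the training genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger("denovoburden")

MODULE_LEVELS = ("M1", "M4", "M7", "M13", "Others")
NUMERIC_PREDICTORS = (
    "pli",
    "loeuf",
    "missense_z",
    "brain_coord_count",
    "go_term_count",
    "cds_length",
)
BINARY_PREDICTORS = ("tsea_brain", "string_member")
BRAIN_COORD_IMPUTE = 1  # median of the candidate genes in the reference analysis
DENSITY_FLOOR = 1e-12


@dataclass(frozen=True)
class NNConfig:
    hidden_width: int = 128
    n_hidden: int = 2
    batch: int = 5
    epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch < 1 or self.epochs < 1:
            raise ValueError("batch and epochs must be >= 1")


@dataclass(frozen=True)
class PosteriorResult:
    gene_id: str
    score: float
    likelihood_ratio: float
    prior: float
    posterior: float


# ---------------------------------------------------------------------------
# predictor encoding
# ---------------------------------------------------------------------------


def preprocess_predictors(raw: pd.DataFrame, for_training: bool = True) -> pd.DataFrame:
    """Encode a raw per-gene annotation table into the model's predictors.

    Missing ``brain_coord_count`` is imputed to 1 and missing ``module`` to
    "Others"; modules outside the four enriched ones collapse to "Others".
    With ``for_training`` True, genes missing any of pLI/LOEUF/missense z
    are dropped (logged); at scoring time they raise instead.
    """
    df = raw.copy()
    required = {"pli", "loeuf", "missense_z"}
    if not required <= set(df.columns):
        raise ValueError(f"missing predictor columns {required - set(df.columns)}")
    core_missing = df[list(required)].isna().any(axis=1)
    if core_missing.any():
        if not for_training:
            raise ValueError(
                f"{int(core_missing.sum())} genes missing core constraint predictors"
            )
        logger.info(
            "preprocess_predictors: dropped %d genes missing pLI/LOEUF/missense z",
            int(core_missing.sum()),
        )
        df = df[~core_missing]
    if "brain_coord_count" not in df.columns:
        df["brain_coord_count"] = BRAIN_COORD_IMPUTE
    df["brain_coord_count"] = df["brain_coord_count"].fillna(BRAIN_COORD_IMPUTE)
    if "module" not in df.columns:
        df["module"] = "Others"
    df["module"] = df["module"].fillna("Others")
    df.loc[~df["module"].isin(MODULE_LEVELS), "module"] = "Others"
    for col in ("tsea_brain", "string_member", "go_term_count", "cds_length"):
        if col not in df.columns:
            df[col] = 0
        df[col] = df[col].fillna(0)
    return df


def encode_features(
    df: pd.DataFrame, scaler: StandardScaler | None = None
) -> tuple[np.ndarray, StandardScaler]:
    """Numeric predictors standardized (training statistics), binary kept,
    module one-hot over its five levels.  Returns the matrix and the fitted
    scaler for reuse at scoring time."""
    unknown = set(df["module"]) - set(MODULE_LEVELS)
    if unknown:
        raise ValueError(f"unseen module categories {sorted(unknown)} in column 'module'")
    numeric = df[list(NUMERIC_PREDICTORS)].to_numpy(dtype=float)
    if scaler is None:
        scaler = StandardScaler().fit(numeric)
    numeric = scaler.transform(numeric)
    binary = df[list(BINARY_PREDICTORS)].to_numpy(dtype=float)
    onehot = np.column_stack(
        [(df["module"] == lvl).to_numpy(dtype=float) for lvl in MODULE_LEVELS]
    )
    return np.hstack([numeric, binary, onehot]), scaler


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


@dataclass
class GeneSimilarityModel:
    config: NNConfig
    scaler: StandardScaler = field(default=None, repr=False)
    net: MLPClassifier = field(default=None, repr=False)

    @property
    def loss_curve(self) -> list[float]:
        return list(self.net.loss_curve_)


def train_nn(
    features: pd.DataFrame, labels: pd.Series, config: NNConfig = NNConfig()
) -> GeneSimilarityModel:
    """Train the similarity model.  ``features`` is a preprocessed predictor
    table (see :func:`preprocess_predictors`); ``labels`` is 1 for known
    disease genes, 0 for negatives.  Deterministic given ``config.seed``."""
    y = labels.loc[features.index].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X, scaler = encode_features(features)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite encoded features")
    net = MLPClassifier(
        hidden_layer_sizes=(config.hidden_width,) * config.n_hidden,
        activation="relu",
        solver="adam",
        batch_size=config.batch,
        max_iter=config.epochs,
        shuffle=True,
        random_state=config.seed,
        alpha=0.0,
    )
    with warnings.catch_warnings():
        # five epochs is the intended training budget, not a convergence target
        warnings.simplefilter("ignore")
        net.fit(X, y)
    return GeneSimilarityModel(config=config, scaler=scaler, net=net)


def score_genes(model: GeneSimilarityModel, features: pd.DataFrame) -> pd.Series:
    """Similarity scores in (0, 1); higher = more like the known genes."""
    X, _ = encode_features(features, scaler=model.scaler)
    scores = model.net.predict_proba(X)[:, 1]
    return pd.Series(scores, index=features.index, name="score")


# ---------------------------------------------------------------------------
# AUC comparison
# ---------------------------------------------------------------------------


def auc(scores, labels) -> float:
    """Area under the ROC curve (midrank tie handling; equals the
    normalized Mann-Whitney U statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def retrained_auc_distribution(
    features: pd.DataFrame,
    labels: pd.Series,
    eval_features: pd.DataFrame,
    eval_labels: pd.Series,
    n_retrains: int = 500,
    config: NNConfig = NNConfig(),
) -> np.ndarray:
    """AUCs of ``n_retrains`` models retrained with distinct seeds derived
    from ``config.seed``, evaluated on a held-out set."""
    aucs = np.empty(n_retrains)
    for i in range(n_retrains):
        cfg = NNConfig(
            hidden_width=config.hidden_width,
            n_hidden=config.n_hidden,
            batch=config.batch,
            epochs=config.epochs,
            seed=(config.seed + 7919 * (i + 1)) % (2**31 - 1),
        )
        model = train_nn(features, labels, cfg)
        aucs[i] = auc(score_genes(model, eval_features), eval_labels)
    return aucs


def auc_empirical_p(comparator_auc: float, nn_auc_distribution: np.ndarray) -> float:
    """Empirical p that the network does not beat a comparator: the
    proportion of retrained-model AUCs at or below the comparator's AUC."""
    dist = np.asarray(nn_auc_distribution, dtype=float)
    if dist.size == 0:
        raise ValueError("empty AUC distribution")
    return float(np.mean(dist <= comparator_auc))


# ---------------------------------------------------------------------------
# likelihood ratios and posteriors
# ---------------------------------------------------------------------------


def kde_likelihood_ratio(
    pos_scores,
    neg_scores,
    query_scores,
    bw_method: str | float = "scott",
    floor: float = DENSITY_FLOOR,
) -> np.ndarray:
    """Gaussian-KDE likelihood ratio density_pos(q) / density_neg(q) with
    both densities floored at ``floor`` against division blow-up."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size < 10 or neg.size < 10:
        raise ValueError("need >= 10 scores per class for a stable KDE")
    q = np.atleast_1d(np.asarray(query_scores, dtype=float))
    dens_pos = np.maximum(gaussian_kde(pos, bw_method=bw_method)(q), floor)
    dens_neg = np.maximum(gaussian_kde(neg, bw_method=bw_method)(q), floor)
    return dens_pos / dens_neg


def posterior(prior: float, likelihood_ratio: float) -> float:
    """Naive-Bayes posterior: prior*LR / (prior*LR + 1 - prior).
    LR = 1 returns the prior; monotone increasing in both arguments."""
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")
    if likelihood_ratio <= 0:
        raise ValueError("likelihood ratio must be positive")
    num = prior * likelihood_ratio
    return num / (num + 1.0 - prior)


def posterior_table(
    scores: pd.Series,
    pos_scores,
    neg_scores,
    prior: float,
    bw_method: str | float = "scott",
) -> list[PosteriorResult]:
    """Posterior true-positive probability per candidate gene."""
    lrs = kde_likelihood_ratio(pos_scores, neg_scores, scores.to_numpy(), bw_method)
    return [
        PosteriorResult(
            gene_id=g,
            score=float(s),
            likelihood_ratio=float(lr),
            prior=prior,
            posterior=posterior(prior, float(lr)),
        )
        for g, s, lr in zip(scores.index, scores.to_numpy(), lrs)
    ]


def median_posterior_over_models(
    features: pd.DataFrame,
    labels: pd.Series,
    candidate_features: pd.DataFrame,
    pos_eval: pd.DataFrame,
    neg_eval: pd.DataFrame,
    prior: float,
    n_models: int = 100,
    config: NNConfig = NNConfig(),
) -> pd.Series:
    """Median posterior per candidate over ``n_models`` retrained models,
    each scoring the candidates and the positive/negative evaluation sets
    used for the KDE likelihood ratios."""
    posteriors = np.empty((n_models, len(candidate_features)))
    for i in range(n_models):
        cfg = NNConfig(
            hidden_width=config.hidden_width,
            n_hidden=config.n_hidden,
            batch=config.batch,
            epochs=config.epochs,
            seed=(config.seed + 104729 * (i + 1)) % (2**31 - 1),
        )
        model = train_nn(features, labels, cfg)
        cand = score_genes(model, candidate_features)
        pos = score_genes(model, pos_eval).to_numpy()
        neg = score_genes(model, neg_eval).to_numpy()
        res = posterior_table(cand, pos, neg, prior)
        posteriors[i] = [r.posterior for r in res]
    return pd.Series(
        np.median(posteriors, axis=0), index=candidate_features.index, name="posterior"
    )
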