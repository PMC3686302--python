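"""Gaussian naive Bayes fusion of multi-method threading scores.

Ten threading / fold-recognition programs each assign a real-valued score to
every (target, template) pair. A Gaussian naive Bayes classifier (NBC)
combines these into a single posterior probability that the template is a
functional one: per class (positive / negative) and per scoring method, the
score is modeled as a normal distribution whose mean and standard deviation
are estimated from labeled training data; at prediction time the class
posteriors follow from Bayes' rule with the features treated as independent.

Two model flavors exist per binding aspect: *Location* (does the template
bind its partner in a similar place) and *Features* (is the bound molecule
chemically similar / the binding mode conserved). Accuracy is assessed with
twofold cross-validation grouped by target, with a Pearson chi-squared check
that the two folds are distributionally homogeneous per scoring method.

Missing scores (a template not ranked by some method) are handled by taking
the likelihood product over the present features only; all density work is
done in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .geometry import BindingAspect

__all__ = [
    "THREADING_METHODS",
    "TemplateRecord",
    "GaussianNBCModel",
    "fit_gnbc",
    "posterior_probability",
    "classify",
    "twofold_split",
    "chi_squared_homogeneity",
    "cross_validated_posteriors",
]

#: The registry of threading / fold-recognition methods whose scores are fused.
THREADING_METHODS: tuple[str, ...] = (
    "CSI-BLAST",
    "COMPASS",
    "HHpred",
    "HMMER",
    "pfTools",
    "pGenThreader",
    "SAM-T2K",
    "SP3",
    "SPARKS2",
    "Threader",
)

Flavor = Literal["LOCATION", "FEATURES"]


@dataclass
class TemplateRecord:
    """One candidate template for one target and one binding aspect.

    ``scores`` maps method name -> real score; absent entries mean the method
    did not rank this template. Labels are None when unknown; posteriors are
    filled by prediction or cross-validation.
    """

    target_id: str
    template_id: str
    aspect: BindingAspect
    scores: dict[str, float] = field(default_factory=dict)
    label_location: bool | None = None
    label_features: bool | None = None
    posterior_location: float | None = None
    posterior_features: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.scores) - set(THREADING_METHODS)
        if unknown:
            raise ValueError(f"unknown threading methods: {sorted(unknown)}")
        if not self.scores:
            raise ValueError("a template record needs at least one score")

    def label(self, flavor: Flavor) -> bool | None:
        return self.label_location if flavor == "LOCATION" else self.label_features

    def set_posterior(self, flavor: Flavor, p: float) -> None:
        if flavor == "LOCATION":
            self.posterior_location = p
        else:
            self.posterior_features = p


@dataclass
class GaussianNBCModel:
    """A trained Gaussian NBC for one binding aspect and one flavor.

    ``per_feature`` maps method name -> (mean_pos, sd_pos, mean_neg, sd_neg).
    All stored SDs are floored at ``sd_floor`` to keep densities proper.
    """

    aspect: BindingAspect
    flavor: Flavor
    class_priors: tuple[float, float]  # (positive, negative)
    per_feature: dict[str, tuple[float, float, float, float]]
    sd_floor: float

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.class_priors), 1.0):
            raise ValueError("class priors must sum to 1")
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be positive")


def fit_gnbc(
    records: Sequence[TemplateRecord],
    flavor: Flavor,
    *,
    priors: tuple[float, float] | None = None,
    sd_floor_scale: float = 1e-6,
) -> GaussianNBCModel:
    """Fit a Gaussian NBC from labeled template records.

    Per class and per scoring method, the mean and standard deviation are
    computed over the records where that method's score is present. SDs are
    floored at ``sd_floor_scale`` times the pooled per-feature SD (or at
    ``sd_floor_scale`` itself when the pooled SD is zero). Priors default to
    the class frequencies in the training data; pass ``priors`` to override
    (e.g. with known positives/negatives ratios).

    A method with no scores at all in one class is dropped from the model
    with a warning; a class with fewer than two labeled records is an error.
    """
    labeled = [r for r in records if r.label(flavor) is not None]
    pos = [r for r in labeled if r.label(flavor)]
    neg = [r for r in labeled if not r.label(flavor)]
    for name, cls in (("positive", pos), ("negative", neg)):
        if len(cls) < 2:
            raise ValueError(f"need >= 2 labeled records in the {name} class, got {len(cls)}")

    aspect = labeled[0].aspect
    per_feature: dict[str, tuple[float, float, float, float]] = {}
    floors: list[float] = []
    for method in THREADING_METHODS:
        xs_pos = np.array([r.scores[method] for r in pos if method in r.scores])
        xs_neg = np.array([r.scores[method] for r in neg if method in r.scores])
        pooled = np.concatenate([xs_pos, xs_neg])
        if pooled.size == 0:
            continue
        if xs_pos.size == 0 or xs_neg.size == 0:
            warnings.warn(
                f"method {method!r} absent in one class; dropped from the model",
                stacklevel=2,
            )
            continue
        pooled_sd = float(pooled.std(ddof=0))
        floor = sd_floor_scale * (pooled_sd if pooled_sd > 0 else 1.0)
        floors.append(floor)
        per_feature[method] = (
            float(xs_pos.mean()),
            max(float(xs_pos.std(ddof=0)), floor),
            float(xs_neg.mean()),
            max(float(xs_neg.std(ddof=0)), floor),
        )
    if not per_feature:
        raise ValueError("no usable features: every method is absent in one class")

    if priors is None:
        priors = (len(pos) / len(labeled), len(neg) / len(labeled))
    return GaussianNBCModel(
        aspect=aspect,
        flavor=flavor,
        class_priors=(float(priors[0]), float(priors[1])),
        per_feature=per_feature,
        sd_floor=min(floors),
    )


def posterior_probability(model: GaussianNBCModel, scores: Mapping[str, float]) -> float:
    """Posterior probability of the positive class for one score vector.

    ``P(+|x) = pi_+ prod_f N(x_f; mu_+f, sd_+f) / sum_c pi_c prod_f N(...)``
    with the product over the features present in both the query and the
    model. Evaluated in log space with log-sum-exp normalization.
    """
    # fixed registry order keeps the float summation independent of dict order
    shared = [m for m in THREADING_METHODS if m in model.per_feature and m in scores]
    if not shared:
        raise ValueError("query shares no features with the model")
    log_pos = np.log(model.class_priors[0])
    log_neg = np.log(model.class_priors[1])
    for m in shared:
        mu_p, sd_p, mu_n, sd_n = model.per_feature[m]
        x = scores[m]
        log_pos += _log_normal_pdf(x, mu_p, sd_p)
        log_neg += _log_normal_pdf(x, mu_n, sd_n)
    # sigmoid of the log odds: exact at log_pos == log_neg, stable elsewhere
    return float(np.exp(-np.logaddexp(0.0, log_neg - log_pos)))


def _log_normal_pdf(x: float, mu: float, sd: float) -> float:
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def classify(model: GaussianNBCModel, scores: Mapping[str, float], cutoff: float) -> bool:
    """Binary call at a posterior cutoff (inclusive: posterior == cutoff is positive)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    return posterior_probability(model, scores) >= cutoff


def twofold_split(
    records: Sequence[TemplateRecord], seed: int
) -> tuple[list[TemplateRecord], list[TemplateRecord]]:
    """Random half-split of records grouped by target.

    All templates of one target land in the same fold, so no model is ever
    evaluated on templates of a target it trained on. Fold sizes differ by at
    most one target; the split is deterministic for a given seed.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 records to split")
    targets = sorted({r.target_id for r in records})
    rng = np.random.default_rng(seed)
    rng.shuffle(targets)
    half = set(targets[: (len(targets) + 1) // 2])
    fold_a = [r for r in records if r.target_id in half]
    fold_b = [r for r in records if r.target_id not in half]
    return fold_a, fold_b


def chi_squared_homogeneity(
    values_a: Sequence[float], values_b: Sequence[float], n_bins: int = 10
) -> tuple[float, int, float]:
    """Pearson chi-squared homogeneity test between two real-valued samples.

    Values are pooled and binned at pooled quantiles; the test statistic is
    Pearson's chi-squared on the 2 x n_bins contingency of fold membership
    against bin, with df = (effective bins - 1). Bins whose expected count is
    zero are merged into their neighbor and df adjusted. Returns
    ``(statistic, df, p_value)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    pooled = np.concatenate([a, b])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    obs_a, _ = np.histogram(a, bins=edges)
    obs_b, _ = np.histogram(b, bins=edges)
    # a bin with zero pooled count has zero expected count: merge it away
    keep = (obs_a + obs_b) > 0
    obs_a, obs_b = obs_a[keep], obs_b[keep]
    table = np.vstack([obs_a, obs_b]).astype(float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    df = table.shape[1] - 1
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def cross_validated_posteriors(
    records: Sequence[TemplateRecord],
    flavor: Flavor,
    seed: int,
    *,
    priors: tuple[float, float] | None = None,
) -> list[TemplateRecord]:
    """Fill each record's posterior from a model trained on the opposite fold.

    Twofold cross-validation grouped by target: the records are split in
    half, a model is fit on each half, and every record is scored by the
    model that never saw it. Returns the same records, posteriors filled.
    """
    fold_a, fold_b = twofold_split(records, seed)
    models = []
    for name, fold in (("A", fold_a), ("B", fold_b)):
        labels = {r.label(flavor) for r in fold}
        if len(labels - {None}) < 2:
            raise ValueError(f"fold {name} contains a single class; cannot train")
        models.append(fit_gnbc(fold, flavor, priors=priors))
    model_a, model_b = models
    for rec in fold_a:
        rec.set_posterior(flavor, posterior_probability(model_b, rec.scores))
    for rec in fold_b:
        rec.set_posterior(flavor, posterior_probability(model_a, rec.scores))
    return list(records)
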