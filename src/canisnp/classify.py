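"""Population-assignment classifiers returning membership probabilities.

Two models are provided:

* **Naive Bayes** on the three genotype states per locus.  Class-conditional
  state probabilities are estimated with Laplace smoothing,
  ``(count + alpha) / (n + 3 alpha)``, loci are treated as independent, and
  membership probabilities are the per-class likelihood products normalized
  under equal priors.  Used for membership probability and blind tests.
* **Linear discriminant analysis** on allele-fraction features (0 / 0.5 / 1
  per locus): class means with a pooled within-class covariance, a small
  ridge ``epsilon`` added to the diagonal, equal priors.  One-hot features
  would make the pooled covariance structurally singular, so the allele
  fraction is the LDA feature mapping.

Both models skip MISSING loci at prediction time (for LDA via the marginal
Gaussian over the observed features).  An individual missing at every model
locus is flagged ``unassignable`` with uniform membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .panel import GenotypeMatrix

__all__ = [
    "ClassifierConfig",
    "AssignmentResult",
    "NaiveBayesClassifier",
    "LdaClassifier",
    "fit_classifier",
    "membership_probabilities",
    "assign_individuals",
]

MODELS = ("naive_bayes", "lda")
#: a naive-Bayes posterior below 1 - HYBRID_TOL for the best class is
#: annotated as a possible hybrid (advisory only)
HYBRID_TOL = 1e-7


@dataclass
class ClassifierConfig:
    model: str = "naive_bayes"
    smoothing_alpha: float = 1.0
    ridge_epsilon: float = 1e-6
    locus_subset: Optional[Sequence[str]] = None
    flag_hybrids: bool = True

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.smoothing_alpha < 0:
            raise ValueError("smoothing_alpha must be >= 0")
        if self.ridge_epsilon <= 0:
            raise ValueError("ridge_epsilon must be positive")


@dataclass
class AssignmentResult:
    individual_id: str
    membership: dict[str, float]
    predicted: str
    log_likelihoods: dict[str, float]
    flags: tuple[str, ...] = ()


def _check_training(training: GenotypeMatrix) -> list[str]:
    pops = sorted(training.populations.unique())
    if len(pops) < 2:
        raise ValueError("training data must contain at least two populations")
    for pop, count in training.population_counts().items():
        if count < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 training individuals")
    return pops


class NaiveBayesClassifier:
    """Genotype-state naive Bayes with Laplace smoothing and equal priors."""

    def __init__(self, alpha: float = 1.0, flag_hybrids: bool = True):
        self.alpha = alpha
        self.flag_hybrids = flag_hybrids
        self.classes_: list[str] = []
        self.locus_ids: list[str] = []
        # log_probs_[c] is (loci x 3) log P(state | class), states (2, 1, 0)
        self.log_probs_: dict[str, np.ndarray] = {}

    def fit(self, training: GenotypeMatrix) -> "NaiveBayesClassifier":
        self.classes_ = _check_training(training)
        self.locus_ids = training.locus_ids
        self.log_probs_ = {}
        for pop in self.classes_:
            sub = training.dosage[training.populations == pop].to_numpy()
            probs = np.empty((len(self.locus_ids), 3))
            for j in range(sub.shape[1]):
                col = sub[:, j]
                valid = col[col >= 0]
                counts = np.array(
                    [(valid == 2).sum(), (valid == 1).sum(), (valid == 0).sum()], float
                )
                denom = counts.sum() + 3.0 * self.alpha
                if denom == 0:
                    raise ValueError(f"no training data for {pop} at {self.locus_ids[j]}")
                probs[j] = (counts + self.alpha) / denom
            with np.errstate(divide="ignore"):
                self.log_probs_[pop] = np.log(probs)
        return self

    def log_likelihoods(self, dosages: np.ndarray) -> dict[str, float]:
        """Sum of per-locus log class-conditionals over non-missing loci."""
        out = {}
        state_idx = 2 - dosages  # dosage 2 -> column 0
        observed = dosages >= 0
        for pop in self.classes_:
            lp = self.log_probs_[pop]
            out[pop] = float(lp[np.nonzero(observed)[0], state_idx[observed]].sum())
        return out

    def membership(self, query: GenotypeMatrix) -> list[AssignmentResult]:
        results = []
        d = query.dosage[self.locus_ids].to_numpy()
        for i, ind in enumerate(query.individual_ids):
            row = d[i]
            flags: list[str] = []
            if (row < 0).all():
                ll = {pop: float("-inf") for pop in self.classes_}
                memb = {pop: 1.0 / len(self.classes_) for pop in self.classes_}
                flags.append("unassignable")
            else:
                ll = self.log_likelihoods(row)
                vals = np.array([ll[p] for p in self.classes_])
                if np.all(np.isneginf(vals)):
                    memb = {pop: 1.0 / len(self.classes_) for pop in self.classes_}
                    flags.append("degenerate_likelihood")
                else:
                    logpost = vals - logsumexp(vals)
                    memb = dict(zip(self.classes_, np.exp(logpost)))
            best = max(memb.values())
            predicted = sorted(p for p in self.classes_ if memb[p] == best)[0]
            if self.flag_hybrids and "unassignable" not in flags and best < 1.0 - HYBRID_TOL:
                flags.append("possible_hybrid")
            results.append(
                AssignmentResult(ind, memb, predicted, ll, tuple(flags))
            )
        return results


class LdaClassifier:
    """Two-or-more-class LDA on allele-fraction features, equal priors."""

    def __init__(self, epsilon: float = 1e-6):
        self.epsilon = epsilon
        self.classes_: list[str] = []
        self.locus_ids: list[str] = []
        self.means_: dict[str, np.ndarray] = {}
        self.cov_: np.ndarray | None = None

    def fit(self, training: GenotypeMatrix) -> "LdaClassifier":
        self.classes_ = _check_training(training)
        self.locus_ids = training.locus_ids
        d = training.dosage.to_numpy(float)
        d[d < 0] = np.nan
        X = d / 2.0
        labels = training.populations.to_numpy()
        n_features = X.shape[1]
        scatter = np.zeros((n_features, n_features))
        n_total = 0
        for pop in self.classes_:
            sub = X[labels == pop]
            mu = np.nanmean(sub, axis=0)
            if np.isnan(mu).any():
                raise ValueError(f"population {pop!r} entirely missing at some locus")
            self.means_[pop] = mu
            filled = np.where(np.isnan(sub), mu, sub)  # class-mean imputation
            centred = filled - mu
            scatter += centred.T @ centred
            n_total += len(sub)
        cov = scatter / max(n_total - len(self.classes_), 1)
        self.cov_ = cov + self.epsilon * np.eye(n_features)
        return self

    def _log_gaussian(self, x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
        diff = x - mu
        sign, logdet = np.linalg.slogdet(cov)
        maha = diff @ np.linalg.solve(cov, diff)
        return float(-0.5 * (len(x) * np.log(2 * np.pi) + logdet + maha))

    def membership(self, query: GenotypeMatrix) -> list[AssignmentResult]:
        results = []
        d = query.dosage[self.locus_ids].to_numpy(float)
        d[d < 0] = np.nan
        X = d / 2.0
        for i, ind in enumerate(query.individual_ids):
            x = X[i]
            obs = ~np.isnan(x)
            flags: list[str] = []
            if not obs.any():
                ll = {pop: float("-inf") for pop in self.classes_}
                memb = {pop: 1.0 / len(self.classes_) for pop in self.classes_}
                flags.append("unassignable")
            else:
                cov = self.cov_[np.ix_(obs, obs)]
                ll = {
                    pop: self._log_gaussian(x[obs], self.means_[pop][obs], cov)
                    for pop in self.classes_
                }
                vals = np.array([ll[p] for p in self.classes_])
                logpost = vals - logsumexp(vals)
                memb = dict(zip(self.classes_, np.exp(logpost)))
            best = max(memb.values())
            predicted = sorted(p for p in self.classes_ if memb[p] == best)[0]
            results.append(AssignmentResult(ind, memb, predicted, ll, tuple(flags)))
        return results


def fit_classifier(training: GenotypeMatrix, config: ClassifierConfig):
    """Fit the configured model on training data (restricted to the locus subset)."""
    if config.locus_subset is not None:
        if len(config.locus_subset) == 0:
            raise ValueError("locus subset must be non-empty")
        training = training.subset_loci(config.locus_subset)
    if config.model == "naive_bayes":
        model = NaiveBayesClassifier(alpha=config.smoothing_alpha,
                                     flag_hybrids=config.flag_hybrids)
    else:
        model = LdaClassifier(epsilon=config.ridge_epsilon)
    return model.fit(training)


def membership_probabilities(model, query: GenotypeMatrix) -> list[AssignmentResult]:
    """Membership probabilities of query individuals under a fitted model."""
    missing = set(model.locus_ids) - set(query.locus_ids)
    if missing:
        raise ValueError(f"query lacks model loci: {sorted(missing)}")
    return model.membership(query.subset_loci(model.locus_ids))


def assign_individuals(
    results: Sequence[AssignmentResult],
    true_labels: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, Optional[dict[str, float]]]:
    """Tabulate assignments; per-population accuracy when labels are known.

    Returns a tidy frame (one row per individual) and, if ``true_labels``
    are given, ``{population: accuracy, 'overall': accuracy}``.
    """
    rows = []
    for r in results:
        row = {"individual_id": r.individual_id, "predicted": r.predicted,
               "flags": ";".join(r.flags)}
        for pop, p in r.membership.items():
            row[f"membership_{pop}"] = p
        rows.append(row)
    frame = pd.DataFrame(rows)
    if true_labels is None:
        return frame, None
    frame["true"] = [true_labels[r.individual_id] for r in results]
    acc: dict[str, float] = {}
    for pop in sorted(set(frame["true"])):
        sub = frame[frame["true"] == pop]
        acc[pop] = float((sub["predicted"] == pop).mean())
    acc["overall"] = float((frame["predicted"] == frame["true"]).mean())
    return frame, acc
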