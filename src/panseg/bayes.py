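"""Naive Bayes soft labels for pancreatic subregions.

Each subregion s in {head, body, tail} gets class-conditional univariate
Gaussians over the two anatomy features alpha' (length fraction) and
beta' (volume fraction), fitted on labelled training voxels pooled across
cases.  The per-voxel posterior factorizes naively,

    P(s | x) ∝ N(alpha'; mu_a[s], sigma_a[s]) * p_a(s)
             * N(beta';  mu_b[s], sigma_b[s]) * p_b(s),

with flat priors (0.33 per class, applied once per feature); the three
posteriors are renormalized per voxel to sum to 1, so constant priors
cancel.  Densities are evaluated in log space with log-sum-exp
normalization to stay safe at distribution tails.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io_prep import SUBREGION_NAMES, SUBREGIONS
from .mask_geometry import FeatureMaps

SCHEMA_VERSION = 1

#: lower bound on fitted standard deviations (dimensionless fraction scale);
#: guards against degenerate spikes from tiny subregions.
SIGMA_FLOOR = 1e-3


@dataclass
class ClassGaussians:
    """Fitted (mu, sigma) per feature per subregion, plus class priors."""

    mu_alpha: np.ndarray
    sigma_alpha: np.ndarray
    mu_beta: np.ndarray
    sigma_beta: np.ndarray
    priors: np.ndarray = field(default_factory=lambda: np.full(3, 1.0 / 3.0))
    sigma_floor: float = SIGMA_FLOOR

    def __post_init__(self):
        for name in ("mu_alpha", "sigma_alpha", "mu_beta", "sigma_beta", "priors"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must have shape (3,)")
        if np.any(self.priors < 0) or not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must be nonnegative and sum to 1")
        if np.any(self.sigma_alpha < self.sigma_floor) or np.any(
            self.sigma_beta < self.sigma_floor
        ):
            raise ValueError("sigmas below sigma_floor")

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "classes": [SUBREGION_NAMES[s] for s in SUBREGIONS],
            "mu_alpha": self.mu_alpha.tolist(),
            "sigma_alpha": self.sigma_alpha.tolist(),
            "mu_beta": self.mu_beta.tolist(),
            "sigma_beta": self.sigma_beta.tolist(),
            "priors": self.priors.tolist(),
            "sigma_floor": self.sigma_floor,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ClassGaussians":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unsupported ClassGaussians schema version")
        return cls(
            mu_alpha=payload["mu_alpha"],
            sigma_alpha=payload["sigma_alpha"],
            mu_beta=payload["mu_beta"],
            sigma_beta=payload["sigma_beta"],
            priors=payload["priors"],
            sigma_floor=payload["sigma_floor"],
        )


def fit_gaussians(features, labels, sigma_floor=SIGMA_FLOOR, priors=None) -> ClassGaussians:
    """Fit per-subregion Gaussians on voxels pooled across training cases.

    Parameters
    ----------
    features : FeatureMaps or sequence of FeatureMaps
    labels : label volume or sequence of label volumes (0/1/2/3)

    mu is the pooled sample mean and sigma the pooled unbiased sample
    standard deviation of each feature within each subregion, floored at
    ``sigma_floor``.  Raises if any subregion is absent from all cases.
    """
    if isinstance(features, FeatureMaps):
        features, labels = [features], [labels]
    if len(features) == 0:
        raise ValueError("need at least one training case")
    if len(features) != len(labels):
        raise ValueError("features and labels lists differ in length")
    mu_a, sd_a, mu_b, sd_b = (np.empty(3) for _ in range(4))
    for ci, s in enumerate(SUBREGIONS):
        av = np.concatenate(
            [f.alpha[np.asarray(l) == s] for f, l in zip(features, labels)]
        )
        bv = np.concatenate(
            [f.beta[np.asarray(l) == s] for f, l in zip(features, labels)]
        )
        if av.size == 0:
            raise ValueError(
                f"subregion {SUBREGION_NAMES[s]!r} absent from all training labels"
            )
        if np.any(~np.isfinite(av)) or np.any(~np.isfinite(bv)):
            raise ValueError("labelled voxels with undefined features")
        mu_a[ci], mu_b[ci] = av.mean(), bv.mean()
        sd_a[ci] = av.std(ddof=1) if av.size > 1 else 0.0
        sd_b[ci] = bv.std(ddof=1) if bv.size > 1 else 0.0
    sd_a = np.maximum(sd_a, sigma_floor)
    sd_b = np.maximum(sd_b, sigma_floor)
    if not (mu_a[0] < mu_a[1] < mu_a[2]):
        warnings.warn(
            "fitted alpha means are not in head < body < tail order; "
            "check labels and laterality convention",
            stacklevel=2,
        )
    if priors is None:
        priors = np.full(3, 1.0 / 3.0)
    return ClassGaussians(mu_a, sd_a, mu_b, sd_b, priors=np.asarray(priors, float),
                          sigma_floor=sigma_floor)


def _log_normal(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)


def posterior_map(features: FeatureMaps, params: ClassGaussians, log_space=True):
    """Per-voxel subregion posteriors as a (3, *shape) probability grid.

    Channels are ordered head, body, tail; each pancreas voxel's channel
    sum is 1; all channels are 0 outside the mask.  ``log_space=False``
    evaluates densities directly (useful for cross-checking; both routes
    agree to ~1e-8 where the direct route does not underflow).
    """
    mask = features.mask
    a, b = features.alpha[mask], features.beta[mask]
    probs = np.zeros((3,) + mask.shape)
    with np.errstate(divide="ignore"):
        log_priors = np.log(params.priors)
    if log_space:
        scores = np.stack(
            [
                _log_normal(a, params.mu_alpha[c], params.sigma_alpha[c])
                + _log_normal(b, params.mu_beta[c], params.sigma_beta[c])
                + 2.0 * log_priors[c]  # prior applied once per feature
                for c in range(3)
            ]
        )
        norm = logsumexp(scores, axis=0)
        finite = np.isfinite(norm)
        post = np.full_like(scores, 1.0 / 3.0)
        post[:, finite] = np.exp(scores[:, finite] - norm[finite])
    else:
        scores = np.stack(
            [
                np.exp(_log_normal(a, params.mu_alpha[c], params.sigma_alpha[c]))
                * np.exp(_log_normal(b, params.mu_beta[c], params.sigma_beta[c]))
                * params.priors[c] ** 2
                for c in range(3)
            ]
        )
        tot = scores.sum(axis=0)
        good = tot > 0
        post = np.full_like(scores, 1.0 / 3.0)
        post[:, good] = scores[:, good] / tot[good]
    probs[:, mask] = post
    return probs


def bayes_segment(soft, mask=None):
    """Hard labels from a soft-label map by per-voxel argmax.

    Ties resolve to the lower label index (head < body < tail).  Voxels
    outside the mask stay background (0).
    """
    soft = np.asarray(soft)
    if mask is None:
        mask = soft.sum(axis=0) > 0
    labels = np.zeros(soft.shape[1:], dtype=np.uint8)
    labels[mask] = np.argmax(soft[:, mask], axis=0).astype(np.uint8) + 1
    return labels
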