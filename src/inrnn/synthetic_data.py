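"""Synthetic cardiotocography-like tabular data.

The generator emulates the *shape* of the NSP classification problem —
21 continuous attributes, three classes with strong imbalance — without
any claim of clinical realism. Features are class-conditional Gaussian
clusters: class centers sit at a configurable distance (``separation``,
in units of the within-class spread) along random orthogonal directions,
so ``separation=0`` yields indistinguishable classes and large values
yield a trivially separable problem. The finished matrix is min–max
scaled to [0, 1] columnwise, matching what the preprocessing stage would
produce on real data.

Default class proportions follow the observed per-fold composition of
the cardiotocography benchmark, 342 normal : 52 suspicious : 31
pathologic; exact per-class counts come from largest-remainder rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import (ConfigurationError, LabeledDataset, NSP_CLASSES,
                      apply_minmax, fit_minmax)

__all__ = ["SyntheticConfig", "generate", "generate_separable",
           "DEFAULT_PROPORTIONS"]

#: Class mix of one cross-validation fold of the CTG benchmark (342:52:31).
DEFAULT_PROPORTIONS: tuple[float, ...] = (342 / 425, 52 / 425, 31 / 425)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic generator.

    Attributes
    ----------
    n_instances : int
        Total rows to generate (≥ number of classes).
    n_features : int
        Attribute count; 21 mirrors the CTG feature table.
    class_proportions : tuple of float
        Simplex weights over (N, S, P); must sum to 1.
    separation : float
        Distance between every pair of class centers, measured in units
        of the within-class standard deviation. 0 ⇒ a pure null model.
    noise_sd : float
        Within-class standard deviation of every attribute.
    seed : int
        Drives all randomness.
    """

    n_instances: int
    n_features: int = 21
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    separation: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    class_order: tuple[str, ...] = NSP_CLASSES

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("class proportions must sum to 1")
        if len(self.class_proportions) != len(self.class_order):
            raise ConfigurationError("one proportion per class required")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.n_instances < len(self.class_order):
            raise ConfigurationError("need at least one instance per class")
        if self.separation < 0 or self.noise_sd <= 0:
            raise ConfigurationError("separation >= 0 and noise_sd > 0 required")


def largest_remainder_counts(n: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Apportion n into integer counts matching proportions exactly."""
    shares = np.asarray(proportions, dtype=float) * n
    counts = np.floor(shares).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(shares - counts))   # largest fractional parts first
    counts[order[:remainder]] += 1
    return counts


def _orthogonal_centers(k: int, d: int, distance: float,
                        rng: np.random.Generator) -> np.ndarray:
    """k centers in R^d with all pairwise distances equal to ``distance``."""
    if distance == 0:
        return np.zeros((k, d))
    if d < k:
        raise ConfigurationError("need n_features >= number of classes to "
                                 "place equidistant class centers")
    gaussian = rng.normal(size=(d, k))
    q, _ = np.linalg.qr(gaussian)
    # Orthonormal directions are √2 apart; rescale to the requested distance.
    return (distance / np.sqrt(2.0)) * q[:, :k].T


def generate(config: SyntheticConfig) -> LabeledDataset:
    """Draw a labeled dataset per the config; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    counts = largest_remainder_counts(config.n_instances,
                                      config.class_proportions)
    if np.any(counts == 0):
        raise ConfigurationError("a class received zero instances; increase "
                                 "n_instances or its proportion")
    centers = _orthogonal_centers(len(config.class_order), config.n_features,
                                  config.separation * config.noise_sd, rng)
    labels = np.concatenate([
        np.full(c, name, dtype=object)
        for c, name in zip(counts, config.class_order)])
    features = np.vstack([
        centers[i] + rng.normal(scale=config.noise_sd,
                                size=(counts[i], config.n_features))
        for i in range(len(config.class_order))])
    order = rng.permutation(config.n_instances)
    features, labels = features[order], labels[order]
    features = apply_minmax(features, fit_minmax(features))
    return LabeledDataset(features, labels, config.class_order)


def generate_separable(n: int, seed: int = 0,
                       n_features: int = 21) -> LabeledDataset:
    """Balanced three-class preset with wide separation (6 spread units).

    Clusters are far enough apart that any competent classifier exceeds
    95% accuracy; used by convergence and cross-validation checks.
    """
    if n < 6:
        raise ConfigurationError("need n >= 6 for a balanced 3-class set")
    config = SyntheticConfig(
        n_instances=n, n_features=n_features,
        class_proportions=(1 / 3, 1 / 3, 1 - 2 / 3),
        separation=6.0, noise_sd=1.0, seed=seed)
    return generate(config)
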