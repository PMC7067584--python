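"""Synthetic generators for the simulation studies.

Generators cover every simulated input the toolkit's validation uses:

* uniform (continuous) null feature values;
* Gaussian-mixture modular alternatives parameterised by the separation of
  adjacent mode means in units of the component standard deviation (the
  benchmark alternative is k = 2, n = 40, separation 5 SD);
* grid-module-like specs whose mode means follow a geometric progression
  (adjacent grid-module spacings scale by ~1.4) with SDs proportional to
  the means and optionally declining mode weights;
* recording-location schemes over a dorsoventral extent (default 2500 µm):
  evenly spaced or uniformly sampled.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MixtureSpec",
    "FeatureSample",
    "sample_uniform",
    "sample_modular",
    "make_mixture_spec",
    "make_grid_like_spec",
    "sample_locations",
    "paired_dataset",
]

DEFAULT_EXTENT_UM = 2500.0


@dataclass(frozen=True)
class MixtureSpec:
    """Generative description of a modular (Gaussian mixture) distribution."""

    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        means = np.asarray(self.means, dtype=float)
        sigmas = np.asarray(self.sigmas, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sigmas", sigmas)
        object.__setattr__(self, "weights", weights)
        k = len(means)
        if not (len(sigmas) == len(weights) == k):
            raise ValueError("means, sigmas, weights must have equal length")
        if k == 0:
            raise ValueError("need at least one component")
        if np.any(np.diff(means) <= 0):
            raise ValueError("means must be strictly increasing")
        if np.any(sigmas <= 0):
            raise ValueError("sigmas must be positive")
        if abs(weights.sum() - 1.0) > 1e-12 or np.any(weights < 0):
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def k(self) -> int:
        return len(self.means)

    @property
    def separation_sd(self) -> float:
        """Adjacent-mean distance in component-SD units (homogeneous sigmas).

        NaN when k = 1 or sigmas are heterogeneous / spacings unequal.
        """
        if self.k < 2:
            return float("nan")
        d = np.diff(self.means)
        if np.allclose(self.sigmas, self.sigmas[0]) and np.allclose(d, d[0]):
            return float(d[0] / self.sigmas[0])
        return float("nan")


@dataclass(frozen=True)
class FeatureSample:
    """One animal's observations of one feature."""

    animal_id: str
    feature_name: str
    values: np.ndarray
    locations: np.ndarray | None = None
    labels: np.ndarray | None = None  # true mixture component, synthetic only
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if self.locations is not None:
            locs = np.asarray(self.locations, dtype=float)
            if len(locs) != len(values):
                raise ValueError("locations must match values in length")
            object.__setattr__(self, "locations", locs)
        if self.labels is not None:
            object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))

    @property
    def n(self) -> int:
        return len(self.values)


def sample_uniform(n: int, lo: float, hi: float, rng=None) -> np.ndarray:
    """n i.i.d. uniform(lo, hi) draws."""
    if not lo < hi:
        raise ValueError(f"require lo < hi; got {lo}, {hi}")
    return np.random.default_rng(rng).uniform(lo, hi, size=n)


def make_mixture_spec(
    k: int, separation_sd: float, sigma: float = 1.0, base_mean: float = 0.0, weights=None
) -> MixtureSpec:
    """Homogeneous-sigma mixture with equal adjacent-mean spacing.

    Adjacent means are ``separation_sd * sigma`` apart — the parameterisation
    used throughout the power analysis (e.g. k=2, separation 5 SD).
    """
    means = base_mean + np.arange(k) * separation_sd * sigma
    sigmas = np.full(k, sigma)
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, dtype=float)
    return MixtureSpec(means, sigmas, w)


def sample_modular(
    n: int, spec: MixtureSpec, rng=None, animal_id: str = "sim", feature_name: str = "feature"
) -> FeatureSample:
    """Draw n values from a Gaussian mixture, retaining true labels."""
    gen = np.random.default_rng(rng)
    labels = gen.choice(spec.k, size=n, p=spec.weights)
    values = gen.normal(spec.means[labels], spec.sigmas[labels])
    return FeatureSample(animal_id, feature_name, values, labels=labels)


def make_grid_like_spec(
    k: int,
    base_mean: float = 1.0,
    ratio: float = 1.42,
    cv: float = 0.02,
    weight_profile: str = "declining",
) -> MixtureSpec:
    """Mixture spec echoing grid-module spacing structure.

    Mode means form a geometric progression ``base_mean * ratio**i`` (grid
    spacing scales by ~1.42 between modules); sigmas scale with the means
    (``sigma_i = cv * mean_i``); weights are equal or geometrically
    declining (ventral modules hold fewer sampled cells).  Overlapping
    modes (large cv) are legitimate hard cases, not errors.
    """
    if ratio <= 1.0:
        raise ValueError("ratio must exceed 1")
    if base_mean <= 0:
        raise ValueError("base_mean must be positive")
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    means = base_mean * ratio ** np.arange(k)
    sigmas = np.maximum(cv * means, 1e-12)
    if weight_profile == "equal":
        w = np.full(k, 1.0 / k)
    elif weight_profile == "declining":
        w = (1.0 / ratio) ** np.arange(k)
        w = w / w.sum()
    else:
        raise ValueError("weight_profile must be 'equal' or 'declining'")
    return MixtureSpec(means, sigmas, w)


def sample_locations(n: int, extent: float = DEFAULT_EXTENT_UM, scheme: str = "even", rng=None):
    """Recording locations over [0, extent] µm, evenly spaced or uniform."""
    if extent <= 0:
        raise ValueError("extent must be positive")
    if scheme == "even":
        return np.linspace(0.0, extent, n)
    if scheme == "uniform":
        return np.random.default_rng(rng).uniform(0.0, extent, size=n)
    raise ValueError("scheme must be 'even' or 'uniform'")


def paired_dataset(
    n: int,
    value_source="uniform",
    location_scheme: str = "uniform",
    extent: float = DEFAULT_EXTENT_UM,
    rng=None,
    animal_id: str = "sim",
    feature_name: str = "feature",
) -> FeatureSample:
    """Bundle values and locations for lnDS tests and panel simulations.

    ``value_source`` is 'uniform' (continuous null over (0, 1)) or a
    :class:`MixtureSpec` (modular alternative).
    """
    gen = np.random.default_rng(rng)
    if isinstance(value_source, MixtureSpec):
        fs = sample_modular(n, value_source, rng=gen)
        values, labels = fs.values, fs.labels
        provenance = {
            "source": "mixture",
            "k": value_source.k,
            "separation_sd": value_source.separation_sd,
        }
    elif value_source == "uniform":
        values = gen.random(n)
        labels = None
        provenance = {"source": "uniform"}
    else:
        raise ValueError("value_source must be 'uniform' or a MixtureSpec")
    locations = sample_locations(n, extent, location_scheme, rng=gen)
    provenance.update({"location_scheme": location_scheme, "extent_um": extent})
    return FeatureSample(animal_id, feature_name, values, locations, labels, meta=provenance)
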