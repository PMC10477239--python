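"""Synthetic landscapes, presence maps, and perturbed suitability scores.

The estimation and control stages are exercised on generated data with the
statistical structure the workflow assumes: a patchy categorical land-use
map, species presence sampled with probability proportional to the true
per-class suitability, and Gaussian-perturbed class scores.  Everything is
deterministic under a fixed seed (bit-identical rasters), so generated
scenarios double as reproducible test fixtures and ground truth for
parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import Grid, LandUseMap, PresenceMap

__all__ = ["ScenarioSpec", "make_landscape", "sample_presence", "perturb_scores",
           "default_true_scores", "make_scenario"]


def default_true_scores(n_classes: int) -> dict[int, float]:
    """Linearly ramped suitabilities 0.05 .. 0.9 over the class codes."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    ramp = np.linspace(0.05, 0.9, n_classes)
    return {c: float(s) for c, s in enumerate(ramp)}


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study landscape.

    blob_scale is the correlation length of the underlying Gaussian random
    field in cells; 0 gives spatially independent classes.  presence_rate
    is the occupancy probability of a cell of the *most* suitable class;
    less suitable classes are occupied proportionally less often.
    """

    shape: tuple[int, int] = (200, 200)
    n_classes: int = 8
    blob_scale: float = 5.0
    true_scores: dict[int, float] = field(default_factory=dict)
    presence_rate: float = 0.05
    cellsize: float = 20.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError("degenerate shape")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0 < self.presence_rate < 1:
            raise ValueError("presence_rate must be in (0,1)")
        if not self.true_scores:
            self.true_scores = default_true_scores(self.n_classes)
        if any(s < 0 for s in self.true_scores.values()):
            raise ValueError("true_scores must be non-negative")


def make_landscape(spec: ScenarioSpec) -> LandUseMap:
    """Patchy categorical map from a quantile-sliced Gaussian random field.

    White noise is smoothed with a Gaussian kernel of width ``blob_scale``
    cells and cut at its empirical quantiles into ``n_classes`` codes, so
    class areas are equal by construction and patch geometry is controlled
    by the correlation length alone.
    """
    rng = np.random.default_rng(spec.seed)
    fieldv = rng.standard_normal(spec.shape)
    if spec.blob_scale > 0:
        fieldv = gaussian_filter(fieldv, sigma=spec.blob_scale, mode="reflect")
    # quantile slicing: equal-area classes
    qs = np.quantile(fieldv, np.linspace(0, 1, spec.n_classes + 1)[1:-1])
    codes = np.searchsorted(qs, fieldv, side="right")
    table = {c: f"class_{c}" for c in range(spec.n_classes)}
    return LandUseMap(values=codes.astype(np.int64), cellsize=spec.cellsize,
                      class_table=table)


def sample_presence(
    lu: LandUseMap,
    true_scores: Mapping[int, float],
    presence_rate: float,
    seed: int,
) -> PresenceMap:
    """Bernoulli presence with P(cell) = rate * score[class] / max score."""
    missing = set(lu.codes()) - set(int(c) for c in true_scores)
    if missing:
        raise ValueError(f"no score for classes {sorted(missing)}")
    smax = max(true_scores.values())
    if smax <= 0:
        raise ValueError("all-zero suitability scores")
    prob = np.zeros(lu.shape)
    for c, s in true_scores.items():
        prob[lu.values == int(c)] = presence_rate * s / smax
    rng = np.random.default_rng(seed)
    pres = (rng.random(lu.shape) < prob).astype(float)
    if lu.nodata is not None:
        pres[~lu.mask()] = -9999.0
        return PresenceMap(values=pres, cellsize=lu.cellsize, nodata=-9999.0,
                           xllcorner=lu.xllcorner, yllcorner=lu.yllcorner)
    return PresenceMap(values=pres, cellsize=lu.cellsize,
                       xllcorner=lu.xllcorner, yllcorner=lu.yllcorner)


def perturb_scores(
    scores: Mapping[int, float],
    sd_fraction: float,
    n_samples: int,
    seed: int,
) -> list[dict[int, float]]:
    """Independent Gaussian perturbations of each class score.

    Each sample draws score_c ~ N(mean=scores[c], sd=sd_fraction*scores[c])
    independently per class, truncated at 0 (negative draws are clipped).
    """
    if sd_fraction < 0:
        raise ValueError("sd_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    codes = list(scores)
    means = np.array([scores[c] for c in codes], dtype=float)
    sds = sd_fraction * means
    draws = rng.normal(means, np.maximum(sds, 0.0), size=(n_samples, len(codes)))
    draws = np.clip(draws, 0.0, None)
    return [dict(zip(codes, map(float, row))) for row in draws]


def make_scenario(spec: ScenarioSpec) -> tuple[LandUseMap, PresenceMap]:
    """Landscape plus matching presence map (presence seed = seed + 1)."""
    lu = make_landscape(spec)
    presence = sample_presence(lu, spec.true_scores, spec.presence_rate, spec.seed + 1)
    return lu, presence
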