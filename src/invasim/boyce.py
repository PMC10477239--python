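"""Presence-only validation of a suitability map via the Boyce index.

The suitability range is partitioned into classes (or overlapping moving
windows, in the continuous variant) and, per class i, the predicted
frequency P_i = p_i / sum_j p_j of presences is compared with the expected
frequency E_i = a_i / sum_j a_j under a random placement, where a_i is the
number of cells in class i.  A good map makes the predicted-to-expected
ratio F_i = P_i / E_i increase monotonically with suitability; the Boyce
index is the Spearman rank correlation between F_i and the class rank, in
[-1, 1].  Values near 0 mean the map is no better than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import Grid, PresenceMap

__all__ = ["BoyceCurve", "BoyceResult", "pe_curve", "spearman",
           "classwise_boyce", "continuous_boyce"]


@dataclass
class BoyceCurve:
    """Predicted/expected frequencies per suitability class or window."""

    bin_centers: np.ndarray
    P: np.ndarray  # predicted frequency of presences per bin
    E: np.ndarray  # expected frequency (relative area) per bin
    F: np.ndarray  # P/E ratio, empty-area bins dropped
    n_dropped: int = 0


@dataclass
class BoyceResult:
    index: float
    curve: BoyceCurve
    mode: str  # "classwise" or "continuous"
    window_width: float | None = None

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.index <= 1 + 1e-12:
            raise ValueError("Boyce index must lie in [-1, 1]")


def _validate(hsi: Grid, presence: PresenceMap) -> tuple[np.ndarray, np.ndarray]:
    hsi.require_aligned(presence, "HSI and presence maps")
    valid = hsi.mask() & presence.mask()
    h = hsi.values[valid].astype(float)
    pres = presence.values[valid] == 1
    if not pres.any():
        raise ValueError("no presence cells")
    return h, pres


def pe_curve(hsi: Grid, presence: PresenceMap, bins: np.ndarray | int) -> BoyceCurve:
    """Predicted-to-expected curve over a fixed partition of the HSI range.

    ``bins`` is either the number of equal-width classes or an explicit
    ascending edge array covering the observed range.  Classes are
    half-open [lo, hi) with the final class closed; classes covering no
    cells are dropped (after normalization over all classes).
    """
    h, pres = _validate(hsi, presence)
    if np.isscalar(bins):
        if int(bins) < 2:
            raise ValueError("need at least 2 suitability classes")
        edges = np.linspace(h.min(), h.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
        if edges.size < 3:
            raise ValueError("need at least 2 suitability classes")
        if edges[0] > h.min() or edges[-1] < h.max():
            raise ValueError("bins do not cover the observed HSI range")
    # np.histogram uses half-open bins with the last bin closed
    a, _ = np.histogram(h, bins=edges)
    p, _ = np.histogram(h[pres], bins=edges)
    P = p / p.sum()
    E = a / a.sum()
    keep = a > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(keep, P / np.where(keep, E, 1.0), np.nan)
    return BoyceCurve(bin_centers=centers[keep], P=P[keep], E=E[keep],
                      F=F[keep], n_dropped=int((~keep).sum()))


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises on constant input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def classwise_boyce(hsi: Grid, presence: PresenceMap, bins: np.ndarray | int = 10) -> BoyceResult:
    """Boyce index with fixed suitability classes."""
    curve = pe_curve(hsi, presence, bins)
    if curve.F.size < 2:
        raise ValueError("fewer than 2 retained classes")
    idx = spearman(curve.F, curve.bin_centers)
    return BoyceResult(index=idx, curve=curve, mode="classwise")


def continuous_boyce(
    hsi: Grid,
    presence: PresenceMap,
    window_width: float | str = "auto",
    n_eval: int = 100,
) -> BoyceResult:
    """Continuous Boyce index with a moving suitability window.

    ``n_eval`` overlapping windows of width ``window_width`` (default:
    one tenth of the observed HSI range) slide across [min, max]; each
    window's F ratio is computed from the cells and presences whose HSI
    falls inside it (closed bounds), windows covering no cells are
    dropped, and the index is the Spearman correlation between F and the
    window midpoints.
    """
    if n_eval < 3:
        raise ValueError("n_eval must be >= 3")
    h, pres = _validate(hsi, presence)
    lo, hi = float(h.min()), float(h.max())
    if hi <= lo:
        raise ValueError("HSI map is constant; index undefined")
    width = (hi - lo) / 10.0 if window_width == "auto" else float(window_width)
    if width <= 0:
        raise ValueError("window width must be positive")
    starts = np.linspace(lo, hi - min(width, hi - lo), n_eval)
    hp = h[pres]
    n_tot_p, n_tot_a = hp.size, h.size
    centers, Fs, Ps, Es = [], [], [], []
    n_dropped = 0
    hs = np.sort(h)
    hps = np.sort(hp)
    for s in starts:
        e = s + width
        a = np.searchsorted(hs, e, side="right") - np.searchsorted(hs, s, side="left")
        if a == 0:
            n_dropped += 1
            continue
        p = np.searchsorted(hps, e, side="right") - np.searchsorted(hps, s, side="left")
        P = p / n_tot_p
        E = a / n_tot_a
        centers.append(s + width / 2)
        Ps.append(P)
        Es.append(E)
        Fs.append(P / E)
    if len(Fs) < 3:
        raise ValueError("fewer than 3 retained windows")
    curve = BoyceCurve(bin_centers=np.array(centers), P=np.array(Ps),
                       E=np.array(Es), F=np.array(Fs), n_dropped=n_dropped)
    idx = spearman(curve.F, curve.bin_centers)
    return BoyceResult(index=idx, curve=curve, mode="continuous", window_width=width)
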