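"""Population-scale read-outs.

Summaries of the agent-based simulations: the mean distance of a
(sub)population to a ligand peak over time, classification of cells as
attracted to MeAsp or serine by which side of a threshold their final
x-coordinate lies on, the accumulation ratio d_final / d_initial (smaller =
stronger accumulation), and a least-squares Hill fit of the fraction of
cells attracted to serine as a function of the serine scaling factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fields import MEASP, SERINE

__all__ = [
    "MetricsError",
    "AttractionCounts",
    "HillFit",
    "PopulationSummary",
    "mean_distance_timecourse",
    "attraction_counts",
    "accumulation_ratio",
    "hill_fit",
]


class MetricsError(ValueError):
    """Invalid metric input (empty data, degenerate fit, ...)."""


def _distances(x, y, peak) -> np.ndarray:
    px, py = peak
    return np.hypot(np.asarray(x, dtype=float) - px,
                    np.asarray(y, dtype=float) - py)


def mean_distance_timecourse(trajectories: pd.DataFrame,
                             peak: Tuple[float, float],
                             group: str = "beta") -> pd.DataFrame:
    """Per-recorded-step mean Euclidean distance to ``peak``.

    ``trajectories`` needs columns step, x, y and the grouping column
    (default the subpopulation label ``beta``).  Returns a tidy frame with
    columns [step, <group>, distance].  Empty groups are dropped with a
    warning.
    """
    if trajectories.empty:
        raise MetricsError("trajectories must be non-empty")
    df = trajectories.copy()
    df["distance"] = _distances(df["x"], df["y"], peak)
    out = (df.groupby(["step", group], sort=True)["distance"]
             .mean().reset_index())
    n_expected = df[group].nunique() * df["step"].nunique()
    if len(out) < n_expected:
        warnings.warn("some (step, group) cells are empty and were omitted")
    return out


@dataclass(frozen=True)
class AttractionCounts:
    """Cells attracted to each ligand by the final-x classification rule."""

    meAsp: int       # final x strictly below the threshold
    serine: int      # final x strictly above the threshold
    boundary: int    # final x exactly at the threshold (counted to neither)

    @property
    def total(self) -> int:
        return self.meAsp + self.serine + self.boundary

    @property
    def fraction_serine(self) -> float:
        return self.serine / self.total


def attraction_counts(final_positions: pd.DataFrame,
                      threshold: float = 0.0) -> AttractionCounts:
    """Classify cells by final x-coordinate: MeAsp side (x < threshold) vs
    serine side (x > threshold).

    The default threshold 0 is the midpoint between the MeAsp peak at
    (-1, 0) and the serine peak at (+1, 0) in the competition experiment.
    Cells exactly at the threshold are reported separately.
    """
    x = np.asarray(final_positions["x"], dtype=float)
    return AttractionCounts(
        meAsp=int(np.sum(x < threshold)),
        serine=int(np.sum(x > threshold)),
        boundary=int(np.sum(x == threshold)),
    )


def accumulation_ratio(initial_positions: pd.DataFrame,
                       final_positions: pd.DataFrame,
                       peak: Tuple[float, float]) -> float:
    """Ratio of final to initial mean distance to ``peak``.

    Values below 1 indicate net accumulation toward the peak; ~1 indicates
    no accumulation.  Undefined when the population starts on the peak.
    """
    d0 = float(np.mean(_distances(initial_positions["x"],
                                  initial_positions["y"], peak)))
    d1 = float(np.mean(_distances(final_positions["x"],
                                  final_positions["y"], peak)))
    if d0 <= 0.0:
        raise MetricsError("initial mean distance is zero; ratio undefined")
    return d1 / d0


@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill fit f(u) = u^n / (K^n + u^n)."""

    K: float
    n: float
    residual: float  # root-mean-square residual of the fit

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        return u ** self.n / (self.K ** self.n + u ** self.n)


def hill_fit(upsilons: Sequence[float], fractions: Sequence[float],
             n_starts: int = 25) -> HillFit:
    """Fit a Hill function to fraction-attracted-versus-scaling data.

    The fit is an unweighted least squares of
    f(u) = u^n / (K^n + u^n) against the fractions, parameterised in
    (log K, n) so the dose axis is logarithmic.  A multi-start over a
    log-spaced K grid spanning the data range guards against local minima.
    """
    u = np.asarray(upsilons, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if u.ndim != 1 or len(u) < 4 or len(np.unique(u)) < 4:
        raise MetricsError("need at least 4 distinct upsilon values")
    if np.any(u <= 0):
        raise MetricsError("upsilon values must be positive")
    if np.any((f < 0) | (f > 1)):
        raise MetricsError("fractions must lie in [0, 1]")
    if np.all(f == f[0]):
        raise MetricsError("degenerate data: all fractions identical")

    logu = np.log(u)

    def resid(p):
        logK, n = p
        # f = 1 / (1 + exp(-n (ln u - ln K))): logistic in ln u
        return 1.0 / (1.0 + np.exp(-n * (logu - logK))) - f

    best = None
    for logK0 in np.linspace(logu.min() - 1.0, logu.max() + 1.0, n_starts):
        for n0 in (1.0, 3.0):
            sol = least_squares(resid, x0=[logK0, n0],
                                bounds=([-np.inf, 1e-6], [np.inf, 50.0]))
            if best is None or sol.cost < best.cost:
                best = sol
    K = float(np.exp(best.x[0]))
    n = float(best.x[1])
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    return HillFit(K=K, n=n, residual=rms)


@dataclass
class PopulationSummary:
    """Aggregate read-outs of one simulation.

    ``mean_distance`` is the per-(step, beta) mean-distance-to-peak table
    for each ligand peak; ``final_mean_distance`` its last recorded step;
    ``attraction`` classifies final x-positions (two-ligand runs);
    ``ratios`` holds per-peak accumulation ratios; ``equilibrated`` is a
    diagnostic flag (mean distance changed by < 2% over the final tenth of
    the run), reported but never enforced.
    """

    n_cells: int
    mean_distance: Dict[str, pd.DataFrame]
    final_positions: pd.DataFrame
    final_mean_distance: pd.DataFrame
    ratios: Dict[str, float]
    attraction: Optional[AttractionCounts]
    equilibrated: Dict[str, bool]


def summarize(trajectories: pd.DataFrame,
              peaks: Dict[str, Tuple[float, float]],
              attraction_threshold: Optional[float] = None
              ) -> PopulationSummary:
    """Build a :class:`PopulationSummary` from a trajectory table.

    ``peaks`` maps species name to peak position; ``attraction_threshold``
    switches on the MeAsp/serine final-x classification (used for
    two-ligand runs).
    """
    if trajectories.empty:
        raise MetricsError("trajectories must be non-empty")
    steps = np.sort(trajectories["step"].unique())
    first, last = steps[0], steps[-1]
    initial = trajectories[trajectories["step"] == first]
    final = trajectories[trajectories["step"] == last]

    mean_distance: Dict[str, pd.DataFrame] = {}
    final_mean_rows = []
    ratios: Dict[str, float] = {}
    equilibrated: Dict[str, bool] = {}
    for species, peak in peaks.items():
        tc = mean_distance_timecourse(trajectories, peak)
        mean_distance[species] = tc
        fm = tc[tc["step"] == last].copy()
        fm.insert(0, "species", species)
        final_mean_rows.append(fm)
        ratios[species] = accumulation_ratio(initial, final, peak)
        # equilibrium diagnostic on the population-wide mean distance
        pop = tc.groupby("step")["distance"].mean()
        t90 = steps[int(0.9 * (len(steps) - 1))]
        d90, dend = float(pop.loc[t90]), float(pop.loc[last])
        equilibrated[species] = bool(abs(dend - d90) <= 0.02 * max(dend, 1e-12))

    final_positions = final[["cell", "beta", "x", "y"]].reset_index(drop=True)
    attraction = (attraction_counts(final_positions, attraction_threshold)
                  if attraction_threshold is not None else None)
    final_mean = (pd.concat(final_mean_rows, ignore_index=True)
                  if final_mean_rows else
                  pd.DataFrame(columns=["species", "step", "beta",
                                        "distance"]))
    return PopulationSummary(
        n_cells=final_positions.shape[0],
        mean_distance=mean_distance,
        final_positions=final_positions,
        final_mean_distance=final_mean,
        ratios=ratios,
        attraction=attraction,
        equilibrated=equilibrated,
    )
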