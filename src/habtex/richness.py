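"""Species richness and sample-based rarefaction.

Richness per point is the count of distinct species recorded at that point
over all years and visits.  The species-accumulation (rarefaction) curve
for a habitat resamples the order of survey events (point x visit samples)
and reports, for each number of accumulated samples k, the mean and
standard deviation of the cumulative distinct-species count over random
orderings.  A plateauing curve indicates the community was sampled to near
completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def total_richness(observations: pd.DataFrame, point_id=None) -> int:
    """Distinct species recorded (optionally restricted to one point)."""
    obs = observations
    if point_id is not None:
        obs = obs[obs["point_id"] == point_id]
    return int(obs["species"].nunique())


def richness_by_point(observations: pd.DataFrame,
                      points: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-point distinct species across all years/visits.

    Points with no observations get richness 0 when ``points`` (with an
    ``id`` column) is supplied.
    """
    counts = observations.groupby("point_id")["species"].nunique()
    if points is not None:
        counts = counts.reindex(points["id"], fill_value=0)
        counts.index.name = "point_id"
    return counts.rename("richness").reset_index()


@dataclass
class AccumulationCurve:
    habitat: str
    n_samples: np.ndarray  # 1..S
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"habitat": self.habitat, "k": self.n_samples,
                             "mean_richness": self.mean_richness,
                             "sd": self.sd_richness})


def accumulation_curve(incidence: np.ndarray, n_permutations: int = 1000,
                       seed: int = 0,
                       habitat: str = "") -> AccumulationCurve:
    """Permutation rarefaction of a samples x species incidence matrix.

    For each k in 1..S the cumulative distinct-species count is averaged
    over ``n_permutations`` random orderings of the S samples; the SD over
    orderings is reported alongside (it is exactly 0 at k = S).
    """
    inc = np.asarray(incidence, dtype=bool)
    if inc.ndim != 2 or inc.shape[0] < 1:
        raise ValueError("incidence must be a non-empty 2-D matrix")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    S = inc.shape[0]
    rng = np.random.default_rng(seed)
    curves = np.empty((n_permutations, S), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(S)
        seen = np.logical_or.accumulate(inc[order], axis=0)
        curves[p] = seen.sum(axis=1)
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1) if n_permutations > 1 \
        else np.zeros(S)
    return AccumulationCurve(habitat, np.arange(1, S + 1), mean, sd,
                             n_permutations)


def incidence_matrix(observations: pd.DataFrame) -> np.ndarray:
    """Binary (survey event x species) incidence from long observations.

    A survey event is one (point_id, year, visit) triple.
    """
    key = observations[["point_id", "year", "visit"]].astype(str).agg(
        "|".join, axis=1)
    tab = pd.crosstab(key, observations["species"])
    return (tab.to_numpy() > 0)
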