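"""Mini-culture growth-curve phenotyping.

T50 is the time a culture takes to reach half-maximal optical density;
dT50 = T50(stress) - T50(optimal) measures the stress-induced growth delay.
A deletion strain's deficient score is its mean dT50 divided by the
wild-type mean dT50 over >= 3 replicate pairs; a score of 2 or greater
designates the strain H2O2-sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GrowthCurve:
    strain: str
    condition: str              # "optimal" | "stress"
    replicate: int
    time_min: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_min.shape != self.od.shape:
            raise ValueError("time/OD length mismatch")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("negative OD")
        if self.time_min.size < 5:
            raise ValueError("need >= 5 samples spanning the inflection")


@dataclass
class DeficientScore:
    strain: str
    mutant_deltas: np.ndarray
    wildtype_deltas: np.ndarray
    score: float
    sensitive: bool


def _smooth3(x: np.ndarray) -> np.ndarray:
    """3-point moving average with shrinking edge windows."""
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    lo = np.maximum(np.arange(n) - 1, 0)
    hi = np.minimum(np.arange(n) + 2, n)
    return (c[hi] - c[lo]) / (hi - lo)


def t50(curve: GrowthCurve) -> float:
    """First crossing time of the half-maximal OD on the smoothed curve.

    Half-max is (plateau + baseline)/2 with baseline the smoothed minimum;
    linear interpolation between samples; inf (with a warning) when the
    curve never reaches it.
    """
    od = _smooth3(curve.od)
    baseline = float(od.min())
    half = 0.5 * (float(od.max()) + baseline)
    above = od >= half
    if not above.any():
        warnings.warn(f"curve {curve.strain}/{curve.condition} never reaches half-max")
        return float("inf")
    i = int(np.argmax(above))
    if i == 0:
        return float(curve.time_min[0])
    t0, t1 = curve.time_min[i - 1], curve.time_min[i]
    v0, v1 = od[i - 1], od[i]
    return float(t0 + (half - v0) * (t1 - t0) / (v1 - v0))


def delta_t50(stress_curve: GrowthCurve, optimal_curve: GrowthCurve) -> float:
    """T50(stress) - T50(optimal) for one strain/replicate pair.

    Negative values (faster growth under stress) are passed through.
    """
    if stress_curve.strain != optimal_curve.strain:
        raise ValueError("curves from different strains")
    a, b = t50(stress_curve), t50(optimal_curve)
    if not (np.isfinite(a) and np.isfinite(b)):
        return float("inf")
    return a - b


def deficient_score(
    mutant_deltas: np.ndarray,
    wildtype_deltas: np.ndarray,
    strain: str = "",
    threshold: float = 2.0,
    aggregate: str = "ratio_of_means",
) -> DeficientScore:
    """Normalised growth-delay score: mean mutant dT50 over mean wild-type
    dT50 (or mean of per-replicate ratios with ``aggregate='mean_of_ratios'``).

    Sensitive iff score >= ``threshold`` (inclusive).
    """
    mut = np.asarray(mutant_deltas, dtype=float)
    wt = np.asarray(wildtype_deltas, dtype=float)
    if mut.size < 3 or wt.size < 3:
        raise ValueError("need >= 3 replicate delta-T50 values per strain")
    if aggregate == "ratio_of_means":
        wt_mean = wt.mean()
        if wt_mean <= 0:
            raise ValueError("wild-type mean delta-T50 must be positive")
        score = float(mut.mean() / wt_mean)
    elif aggregate == "mean_of_ratios":
        if np.any(wt <= 0):
            raise ValueError("wild-type delta-T50 values must be positive")
        k = min(mut.size, wt.size)
        score = float(np.mean(mut[:k] / wt[:k]))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return DeficientScore(strain, mut, wt, score, score >= threshold)


def score_strains(
    curves: list[GrowthCurve], wildtype: str = "wt", threshold: float = 2.0
) -> pd.DataFrame:
    """Deficient scores for every strain in a curve set against a wild type.

    Pairs stress/optimal curves by replicate id per strain.
    """
    deltas: dict[str, list[float]] = {}
    by_key = {(c.strain, c.condition, c.replicate): c for c in curves}
    strains = sorted({c.strain for c in curves})
    for strain in strains:
        reps = sorted({c.replicate for c in curves if c.strain == strain})
        vals = []
        for r in reps:
            s = by_key.get((strain, "stress", r))
            o = by_key.get((strain, "optimal", r))
            if s is not None and o is not None:
                vals.append(delta_t50(s, o))
        deltas[strain] = vals
    if wildtype not in deltas:
        raise ValueError(f"wild-type strain {wildtype!r} absent from curve set")
    wt = np.array(deltas[wildtype])
    rows = []
    for strain in strains:
        ds = deficient_score(np.array(deltas[strain]), wt, strain, threshold)
        rows.append(
            {"strain": strain, "mean_delta_t50": float(np.mean(deltas[strain])),
             "deficient_score": ds.score, "sensitive": ds.sensitive}
        )
    return pd.DataFrame(rows).set_index("strain")


def write_growth_csv(curves: list[GrowthCurve], path: str) -> None:
    rows = []
    for i, c in enumerate(curves):
        for t, od in zip(c.time_min, c.od):
            rows.append(
                {"well": i, "strain": c.strain, "condition": c.condition,
                 "replicate": c.replicate, "time_min": t, "od": od}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_growth_csv(path: str) -> list[GrowthCurve]:
    df = pd.read_csv(path)
    out = []
    for (strain, cond, rep), grp in df.groupby(
        ["strain", "condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_min")
        out.append(
            GrowthCurve(str(strain), str(cond), int(rep),
                        grp["time_min"].to_numpy(), grp["od"].to_numpy())
        )
    return out
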