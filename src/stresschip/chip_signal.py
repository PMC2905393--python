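"""Tiling-array normalisation and significantly-enriched-region (SER) calling.

A ChIP-chip track is the per-probe log2 ratio of immunoprecipitated over
whole-cell-extract signal.  An SER — the operational definition of a protein
occupancy — is a run of at least ``min_consecutive`` consecutive probes whose
ratio exceeds a robust threshold (median + 2.5 MAD), validated by an
upper-tail binomial test in a moving 9-probe window at p <= 0.001.  The apex
(position of the maximal smoothed ratio inside the SER) is the binding site;
the smoothed value there is its enrichment level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess


@dataclass
class ProbeTrack:
    """Ordered probe positions with per-probe log2 enrichment ratios."""

    chromosome: str
    positions: np.ndarray  # probe start positions, bp, strictly increasing
    values: np.ndarray     # log2(ChIP/WCE) per probe
    strands: np.ndarray | None = None
    probe_length: int = 50

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions/values length mismatch")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite probe values")

    def __len__(self) -> int:
        return int(self.positions.size)

    def with_values(self, values: np.ndarray) -> "ProbeTrack":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chromosome": self.chromosome, "start": self.positions,
             "log2_ratio": self.values}
        )
        df["strand"] = self.strands if self.strands is not None else "."
        return df[["chromosome", "start", "strand", "log2_ratio"]]


def write_probe_table(tracks: list[ProbeTrack], path: str) -> None:
    pd.concat([t.to_frame() for t in tracks]).to_csv(path, sep="\t", index=False)


def read_probe_table(path: str, probe_length: int = 50) -> list[ProbeTrack]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for chrom, grp in df.groupby("chromosome", sort=True):
        grp = grp.sort_values("start")
        out.append(
            ProbeTrack(str(chrom), grp["start"].to_numpy(),
                       grp["log2_ratio"].to_numpy(),
                       strands=grp["strand"].to_numpy(),
                       probe_length=probe_length)
        )
    return out


@dataclass
class SERParams:
    """Parameters of the SER caller (defaults match the published procedure)."""

    mad_multiplier: float = 2.5
    window_probes: int = 9
    min_consecutive: int = 4
    p_threshold: float = 1e-3
    smoothing_window: int = 5
    smoothing_rounds: int = 3

    def __post_init__(self) -> None:
        if self.window_probes % 2 == 0:
            raise ValueError("window_probes must be odd")
        if self.min_consecutive > self.window_probes:
            raise ValueError("min_consecutive must be <= window_probes")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0,1)")


@dataclass
class Occupancy:
    """A called SER with its apex (= binding site) and enrichment level."""

    chromosome: str
    start_index: int
    end_index: int          # inclusive probe index of last probe in run
    start_bp: int
    end_bp: int
    apex: int               # bp position of maximal smoothed signal
    level: float            # smoothed log2 ratio at the apex
    n_probes: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start_bp <= self.apex <= self.end_bp:
            raise ValueError("apex outside SER bounds")


# -------------------------------------------------------------- normalisation


def lowess_normalize(
    chip_intensity: np.ndarray,
    wce_intensity: np.ndarray,
    frac: float = 0.3,
) -> np.ndarray:
    """Intensity-dependent (dye-bias) correction of a two-channel array.

    Fits a local regression of M = log2(chip/wce) on A = mean log intensity,
    subtracts the fitted trend and median-centres the result so the array
    median is 0 in log scale.
    """
    chip = np.asarray(chip_intensity, dtype=float)
    wce = np.asarray(wce_intensity, dtype=float)
    if chip.shape != wce.shape:
        raise ValueError("channel length mismatch")
    if np.any(chip <= 0) or np.any(wce <= 0):
        raise ValueError("intensities must be positive")
    m = np.log2(chip) - np.log2(wce)
    a = 0.5 * (np.log2(chip) + np.log2(wce))
    if np.ptp(a) == 0:
        trend = np.full_like(m, m.mean())
    else:
        fitted = _sm_lowess(m, a, frac=frac, it=2, return_sorted=False)
        trend = fitted
    out = m - trend
    return out - np.median(out)


def quantile_normalize(value_sets: list[np.ndarray]) -> list[np.ndarray]:
    """Force identical value distributions across arrays.

    Each array's sorted values are replaced by the mean of all arrays'
    sorted values; within-array rank order is preserved.
    """
    arrays = [np.asarray(v, dtype=float) for v in value_sets]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("all tracks must share the same probe set")
    ref = np.mean([np.sort(a) for a in arrays], axis=0)
    out = []
    for a in arrays:
        ranks = np.empty(n, dtype=np.int64)
        ranks[np.argsort(a, kind="stable")] = np.arange(n)
        out.append(ref[ranks])
    return out


def quantile_normalize_tracks(tracks: list[ProbeTrack]) -> list[ProbeTrack]:
    for t in tracks[1:]:
        if len(t) != len(tracks[0]):
            raise ValueError("all tracks must share the same probe set")
    normed = quantile_normalize([t.values for t in tracks])
    return [t.with_values(v) for t, v in zip(tracks, normed)]


# ------------------------------------------------------------------ statistics


def mad_threshold(values: np.ndarray, n: float = 2.5) -> float:
    """Median(R) + n * MAD(R) with the unscaled median absolute deviation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty track")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    return float(med + n * mad)


def window_binom_p(m: int, L: int, Pr: float) -> float:
    """Upper-tail binomial probability P(X >= m) for X ~ Binom(L, Pr)."""
    if not 0 < Pr < 1:
        raise ValueError("Pr must lie in (0,1)")
    if not 0 <= m <= L:
        raise ValueError("m must lie in [0, L]")
    return float(stats.binom.sf(m - 1, L, Pr))


def exceedance_fraction(tracks: list[ProbeTrack] | ProbeTrack, threshold: float) -> float:
    """Genome-wide fraction of probes above the enrichment threshold (Pr)."""
    if isinstance(tracks, ProbeTrack):
        tracks = [tracks]
    above = sum(int(np.sum(t.values > threshold)) for t in tracks)
    total = sum(len(t) for t in tracks)
    return above / total


def smooth(values: np.ndarray, window: int = 5, rounds: int = 3) -> np.ndarray:
    """Repeated centred moving average; the window shrinks at the edges.

    Constants are preserved exactly and max(output) <= max(input).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    v = np.asarray(values, dtype=float)
    half = window // 2
    for _ in range(rounds):
        c = np.concatenate(([0.0], np.cumsum(v)))
        n = v.size
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        v = (c[hi] - c[lo]) / (hi - lo)
    return v


def smooth_track(track: ProbeTrack, params: SERParams) -> ProbeTrack:
    return track.with_values(
        smooth(track.values, params.smoothing_window, params.smoothing_rounds)
    )


# -------------------------------------------------------------------- calling


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def find_apex(
    start_index: int, end_index: int, smoothed: ProbeTrack
) -> tuple[int, float]:
    """Apex = position of the maximal smoothed value in the SER; leftmost tie."""
    seg = smoothed.values[start_index : end_index + 1]
    off = int(np.argmax(seg))  # argmax returns the first (leftmost) maximum
    return int(smoothed.positions[start_index + off]), float(seg[off])


def call_sers(
    track: ProbeTrack,
    params: SERParams = SERParams(),
    threshold: float | None = None,
    exceed_fraction: float | None = None,
    label: str = "",
) -> list[Occupancy]:
    """Call significantly enriched regions on one normalised track.

    A maximal run of >= ``min_consecutive`` consecutive probes above the MAD
    threshold is an SER iff at least one ``window_probes``-probe window
    centred on a probe of the run has binomial upper-tail p <= p_threshold.
    ``threshold`` and ``exceed_fraction`` default to track-derived values but
    should be supplied genome-wide when the track is one chromosome of many.
    """
    L = params.window_probes
    if len(track) < L:
        warnings.warn("track shorter than the test window; no SERs called")
        return []
    if threshold is None:
        threshold = mad_threshold(track.values, params.mad_multiplier)
    above = track.values > threshold
    Pr = exceed_fraction if exceed_fraction is not None else float(above.mean())
    if not 0 < Pr < 1:
        return []
    # precompute exceedance count for the L-window centred on every probe;
    # windows are clipped at chromosome ends (shorter L there)
    half = L // 2
    c = np.concatenate(([0], np.cumsum(above.astype(np.int64))))
    n = len(track)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    m_in_window = c[hi] - c[lo]
    win_len = hi - lo
    # p-value per centre probe (vectorised over the few distinct (m, len) pairs)
    pvals = stats.binom.sf(m_in_window - 1, win_len, Pr)

    smoothed = smooth_track(track, params)
    sers: list[Occupancy] = []
    for s, e in _runs_above(above):
        if e - s + 1 < params.min_consecutive:
            continue
        if np.min(pvals[s : e + 1]) > params.p_threshold:
            continue
        apex, level = find_apex(s, e, smoothed)
        sers.append(
            Occupancy(
                chromosome=track.chromosome,
                start_index=s,
                end_index=e,
                start_bp=int(track.positions[s]),
                end_bp=int(track.positions[e]) + track.probe_length,
                apex=apex,
                level=level,
                n_probes=e - s + 1,
                label=label,
            )
        )
    return sers


def call_sers_genome(
    tracks: list[ProbeTrack], params: SERParams = SERParams(), label: str = ""
) -> list[Occupancy]:
    """Call SERs across chromosomes with one genome-wide threshold and Pr."""
    allv = np.concatenate([t.values for t in tracks])
    thr = mad_threshold(allv, params.mad_multiplier)
    pr = float(np.mean(allv > thr))
    out: list[Occupancy] = []
    for t in tracks:
        out.extend(call_sers(t, params, threshold=thr, exceed_fraction=pr, label=label))
    return out


def estimate_fdr(
    tracks: list[ProbeTrack] | ProbeTrack,
    params: SERParams = SERParams(),
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Empirical FDR of the SER calls by within-chromosome value permutation.

    Permuting probe values preserves the value distribution (hence the
    threshold and Pr) while destroying spatial runs; FDR is the mean null
    SER count over permutations divided by the observed count, clipped to
    [0, 1]; NaN when nothing is observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(tracks, ProbeTrack):
        tracks = [tracks]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    allv = np.concatenate([t.values for t in tracks])
    thr = mad_threshold(allv, params.mad_multiplier)
    pr = float(np.mean(allv > thr))
    observed = sum(
        len(call_sers(t, params, threshold=thr, exceed_fraction=pr)) for t in tracks
    )
    if observed == 0:
        return float("nan")
    null_counts = np.empty(n_perm)
    for i in range(n_perm):
        total = 0
        for t in tracks:
            perm = t.with_values(rng.permutation(t.values))
            total += len(call_sers(perm, params, threshold=thr, exceed_fraction=pr))
        null_counts[i] = total
    return float(np.clip(null_counts.mean() / observed, 0.0, 1.0))
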