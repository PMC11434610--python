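"""Extracellular single-unit classification and firing-rate change calls.

Starts from sorted units (a mean spike waveform plus spike times per
epoch), mirroring post-sorting analysis of multi-channel recordings:

* waveform features: trough-to-peak duration and trough-lobe half-width;
* cell-type call: putative pyramidal cell (PYR) vs interneuron (INT),
  either by the 430 us trough-to-peak threshold or by k-means (k = 2) on
  standardized (trough_to_peak, half_width, mean_rate);
* ISI histograms with refractory-violation counts;
* pre- vs post-stimulation rate change per unit via a two-sided Wilcoxon
  rank-sum test on binned spike counts, called increased / decreased /
  unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ranksums
from sklearn.cluster import KMeans

from .errors import InsufficientDataError, ShapeError

__all__ = [
    "UnitWaveform",
    "UnitFeatures",
    "UnitLabel",
    "RateChange",
    "PYR_TROUGH_TO_PEAK_US",
    "waveform_features",
    "classify_units",
    "isi_histogram",
    "rate_change",
]

#: trough-to-peak boundary (us) separating putative PYR (above) from INT
PYR_TROUGH_TO_PEAK_US = 430.0


@dataclass
class UnitWaveform:
    """Mean extracellular spike waveform of one sorted unit."""

    samples: np.ndarray
    fs: float  # sampling rate, Hz

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 5:
            raise ValueError("waveform too short")


@dataclass(frozen=True)
class UnitFeatures:
    """Classification features of one unit (durations in us, rate in Hz)."""

    trough_to_peak: float
    half_width: float
    mean_rate: float = 0.0

    def __post_init__(self):
        if self.trough_to_peak <= 0 or self.half_width <= 0:
            raise ValueError("waveform durations must be positive")


@dataclass(frozen=True)
class UnitLabel:
    label: str   # "PYR" | "INT"
    method: str  # "threshold" | "kmeans"

    def __post_init__(self):
        if self.label not in ("PYR", "INT"):
            raise ValueError("label must be PYR or INT")


@dataclass(frozen=True)
class RateChange:
    """Pre/post firing-rate comparison of one unit."""

    direction: str  # "increased" | "decreased" | "unchanged"
    p_value: float
    pre_rate: float
    post_rate: float


def waveform_features(w: UnitWaveform, mean_rate: float = 0.0) -> UnitFeatures:
    """Trough-to-peak duration and trough half-width of a biphasic waveform.

    The waveform must contain a negative trough followed by a positive
    peak; the half-width is the width of the trough lobe at half its depth
    (measured from the pre-trough baseline), with subsample interpolation
    at the half-depth crossings.
    """
    v = w.samples
    dt_us = 1e6 / w.fs
    i_trough = int(np.argmin(v))
    if v[i_trough] >= 0:
        raise ShapeError("waveform has no negative trough")
    after = v[i_trough + 1:]
    if after.size == 0:
        raise ShapeError("waveform ends at the trough; no peak follows")
    i_peak = i_trough + 1 + int(np.argmax(after))
    if v[i_peak] <= v[i_trough] or v[i_peak] <= 0:
        raise ShapeError("no positive peak follows the trough")
    trough_to_peak = (i_peak - i_trough) * dt_us

    half_level = 0.5 * v[i_trough]  # half the trough depth (negative value)
    a = i_trough
    while a > 0 and v[a - 1] <= half_level:
        a -= 1
    b = i_trough
    while b + 1 < v.size and v[b + 1] <= half_level:
        b += 1
    t_left = a * dt_us
    if a > 0:
        t_left = (a - 1 + (v[a - 1] - half_level) / (v[a - 1] - v[a])) * dt_us
    t_right = b * dt_us
    if b + 1 < v.size:
        t_right = (b + (v[b] - half_level) / (v[b] - v[b + 1])) * dt_us
    return UnitFeatures(trough_to_peak=float(trough_to_peak),
                        half_width=float(t_right - t_left),
                        mean_rate=float(mean_rate))


def classify_units(features: list[UnitFeatures], method: str = "threshold",
                   seed: int = 0) -> list[UnitLabel]:
    """Label each unit PYR or INT.

    ``threshold``: PYR iff trough_to_peak > 430 us.  ``kmeans``: k = 2 on
    standardized (trough_to_peak, half_width, mean_rate) with 10 restarts;
    the cluster with the larger mean trough-to-peak is PYR (a tie is broken
    by the 430 us rule applied to the cluster means).
    """
    if method == "threshold":
        return [UnitLabel("PYR" if f.trough_to_peak > PYR_TROUGH_TO_PEAK_US
                          else "INT", "threshold") for f in features]
    if method != "kmeans":
        raise ValueError("method must be 'threshold' or 'kmeans'")
    if len(features) < 2:
        raise ValueError("k-means classification needs at least 2 units")
    X = np.array([[f.trough_to_peak, f.half_width, f.mean_rate]
                  for f in features])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Z)
    ttp_means = [X[km.labels_ == c, 0].mean() for c in (0, 1)]
    if ttp_means[0] != ttp_means[1]:
        pyr_cluster = int(np.argmax(ttp_means))
    else:
        pyr_cluster = int(ttp_means[0] > PYR_TROUGH_TO_PEAK_US)
    return [UnitLabel("PYR" if lab == pyr_cluster else "INT", "kmeans")
            for lab in km.labels_]


def isi_histogram(spike_times, bin_width: float = 1.0,
                  refractory: float = 2.0,
                  max_isi: float | None = None):
    """Histogram of inter-spike intervals plus refractory-violation count.

    ``spike_times`` must be sorted (ms).  Returns (counts, bin_edges,
    n_violations) where violations are intervals shorter than
    ``refractory`` ms.
    """
    times = np.asarray(list(spike_times), dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be sorted")
    isis = np.diff(times)
    if max_isi is None:
        max_isi = float(isis.max()) + bin_width if isis.size else bin_width
    edges = np.arange(0.0, max_isi + bin_width, bin_width)
    counts, edges = np.histogram(isis, bins=edges)
    violations = int(np.sum(isis < refractory))
    return counts, edges, violations


def rate_change(pre_spikes, post_spikes, pre_duration_s: float,
                post_duration_s: float, bin_width_s: float = 1.0,
                alpha: float = 0.05) -> RateChange:
    """Call a unit's firing-rate change between two epochs.

    Spike times are in ms relative to their epoch start.  Counts in
    ``bin_width_s`` bins are compared by a two-sided Wilcoxon rank-sum
    test; when p < alpha the direction follows the sign of the difference
    of median bin counts (mean difference breaking an exact median tie),
    otherwise the unit is called unchanged.  Each epoch must provide at
    least 10 full bins.
    """
    pre_bins = _bin_counts(pre_spikes, pre_duration_s, bin_width_s)
    post_bins = _bin_counts(post_spikes, post_duration_s, bin_width_s)
    if pre_bins.size < 10 or post_bins.size < 10:
        raise InsufficientDataError(
            "each epoch needs >= 10 bins at the chosen bin width")
    stat, p = ranksums(post_bins, pre_bins)
    pre_rate = pre_bins.sum() / (pre_bins.size * bin_width_s)
    post_rate = post_bins.sum() / (post_bins.size * bin_width_s)
    if p < alpha:
        diff = np.median(post_bins) - np.median(pre_bins)
        if diff == 0:
            diff = post_bins.mean() - pre_bins.mean()
        direction = "increased" if diff > 0 else "decreased"
    else:
        direction = "unchanged"
    return RateChange(direction=direction, p_value=float(p),
                      pre_rate=float(pre_rate), post_rate=float(post_rate))


def _bin_counts(spikes_ms, duration_s: float, bin_width_s: float) -> np.ndarray:
    times = np.asarray(list(spikes_ms), dtype=float) / 1000.0
    n_bins = int(duration_s / bin_width_s)
    edges = np.arange(n_bins + 1) * bin_width_s
    counts, _ = np.histogram(times, bins=edges)
    return counts
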