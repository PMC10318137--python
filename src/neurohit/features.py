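"""Song-level neurophysiologic statistics.

Immersion is recorded at 1 Hz per participant per song.  The analysis unit is
the song: per-second traces are averaged across the participants who heard the
song without knowing it, and three statistics are derived from the averaged
series ``v_t`` (t = 0..T-1):

* **average immersion** — the mean of ``v_t`` (immersion units);
* **peak immersion** — the fraction of total immersion ``Im = sum_t v_t``
  contributed by seconds whose averaged value strictly exceeds the threshold
  ``M = median(v) + s``, where ``s`` is the sample SD of *all*
  participant-second samples of the song;
* **retreat** — the fraction of ``Im`` contributed by the ``k = max(1,
  floor(0.2 T))`` smallest values of the averaged series (the lowest-quintile
  mass).

Participants who reported being familiar with a song are excluded from that
song before averaging, because self-reported liking is confounded with
familiarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SongSeries",
    "ThresholdStats",
    "song_average_series",
    "compute_threshold",
    "compute_peak_immersion",
    "compute_retreat",
    "filter_unfamiliar",
    "featurize",
    "featurize_cohort",
]


@dataclass(frozen=True)
class SongSeries:
    """Cross-participant average series for one song.

    ``sample_matrix`` has one row per participant, one column per second;
    ``avg_series`` is its column mean.  All traces are truncated to the
    shortest common length before averaging.
    """

    song_id: str
    sample_matrix: np.ndarray  # (n_participants, T)
    avg_series: np.ndarray  # (T,)
    n_participants: int

    @property
    def duration(self) -> int:
        return int(self.avg_series.shape[0])


@dataclass(frozen=True)
class ThresholdStats:
    """Median-plus-SD threshold and total immersion for one song."""

    median_avg: float
    sample_sd: float
    threshold: float  # median_avg + sample_sd
    total_immersion: float  # sum of the averaged series


def song_average_series(traces, song_id: str = "") -> SongSeries:
    """Average per-second traces across participants for one song.

    Parameters
    ----------
    traces : sequence of 1-D arrays
        One immersion trace per participant.  Traces of unequal length are
        truncated to the shortest common length so the cross-participant
        average is defined at every retained second.
    """
    traces = [np.asarray(t, dtype=float) for t in traces]
    if len(traces) == 0:
        raise ValueError("song_average_series requires at least one trace")
    t_min = min(t.shape[0] for t in traces)
    if t_min < 1:
        raise ValueError("traces must have at least one sample")
    matrix = np.vstack([t[:t_min] for t in traces])
    avg = matrix.mean(axis=0)
    return SongSeries(
        song_id=song_id,
        sample_matrix=matrix,
        avg_series=avg,
        n_participants=matrix.shape[0],
    )


def compute_threshold(series: SongSeries) -> ThresholdStats:
    """Median of the averaged series plus the all-sample SD, and total immersion.

    The SD is the sample standard deviation (ddof=1) taken over every
    participant-second sample of the song, not over participant means: this is
    the only reading that uses all participants and the full duration at once.
    A single sample has SD 0 by convention.
    """
    avg = series.avg_series
    if avg.size == 0:
        raise ValueError("empty series")
    samples = series.sample_matrix.ravel()
    sd = float(np.std(samples, ddof=1)) if samples.size > 1 else 0.0
    med = float(np.median(avg))
    return ThresholdStats(
        median_avg=med,
        sample_sd=sd,
        threshold=med + sd,
        total_immersion=float(np.sum(avg)),
    )


def compute_peak_immersion(
    series: SongSeries,
    stats: ThresholdStats | None = None,
    integrand: str = "value",
) -> float:
    """Fraction of total immersion in seconds strictly above the threshold.

    ``integrand="value"`` (default) sums the above-threshold averaged values;
    ``integrand="indicator"`` sums seconds above threshold instead, still
    normalized by total immersion.
    """
    if stats is None:
        stats = compute_threshold(series)
    if stats.total_immersion <= 0:
        raise ValueError("total immersion must be positive (all-zero song?)")
    avg = series.avg_series
    mask = avg > stats.threshold
    if integrand == "value":
        numer = float(np.sum(avg[mask]))
    elif integrand == "indicator":
        numer = float(np.count_nonzero(mask))
    else:
        raise ValueError(f"unknown integrand {integrand!r}")
    return numer / stats.total_immersion


def retreat_quintile_count(duration: int) -> int:
    """Number of seconds in the lowest quintile: max(1, floor(0.2 T))."""
    return max(1, math.floor(0.2 * duration))


def compute_retreat(
    series: SongSeries,
    stats: ThresholdStats | None = None,
    normalized: bool = True,
) -> float:
    """Cumulated mass of the lowest 20% of the averaged series.

    Sorts the averaged series ascending (stable in time order), sums the
    ``k = max(1, floor(0.2 T))`` smallest values and, by default, divides by
    total immersion so the statistic is a unitless fraction.
    """
    if stats is None:
        stats = compute_threshold(series)
    if stats.total_immersion <= 0:
        raise ValueError("total immersion must be positive (all-zero song?)")
    avg = series.avg_series
    k = retreat_quintile_count(avg.shape[0])
    low_sum = float(np.sort(avg, kind="stable")[:k].sum())
    if normalized:
        return low_sum / stats.total_immersion
    return low_sum


# ---------------------------------------------------------------------------
# Familiarity filtering and the end-to-end feature table
# ---------------------------------------------------------------------------


def filter_unfamiliar(
    traces: pd.DataFrame,
    surveys: pd.DataFrame,
    min_participants: int = 2,
) -> pd.DataFrame:
    """Drop participant-song traces whose survey marks the song familiar.

    Every (participant, song) pair in ``traces`` must have a survey row.
    Songs retaining fewer than ``min_participants`` unfamiliar listeners are
    excluded entirely, with a logged warning.
    """
    fam = surveys.set_index(["participant_id", "song_id"])["familiar"]
    pairs = traces[["participant_id", "song_id"]].drop_duplicates()
    idx = pd.MultiIndex.from_frame(pairs)
    missing = idx.difference(fam.index)
    if len(missing) > 0:
        raise ValueError(
            f"traces without a matching survey row: {list(missing[:5])}"
        )
    keep_pairs = idx[fam.reindex(idx).to_numpy() == 0]
    kept = traces.set_index(["participant_id", "song_id"]).loc[keep_pairs].reset_index()
    counts = kept.groupby("song_id")["participant_id"].nunique()
    thin = counts[counts < min_participants].index.tolist()
    dropped_entirely = set(traces["song_id"]) - set(counts.index)
    for song in sorted(set(thin) | dropped_entirely):
        logger.warning(
            "song %s excluded: fewer than %d unfamiliar participants",
            song,
            min_participants,
        )
    if thin:
        kept = kept[~kept["song_id"].isin(thin)]
    return kept


def _series_from_long(song_traces: pd.DataFrame, song_id: str) -> SongSeries:
    per_participant = [
        grp.sort_values("t_sec")["immersion"].to_numpy()
        for _, grp in song_traces.groupby("participant_id", sort=True)
    ]
    return song_average_series(per_participant, song_id=song_id)


def featurize(
    traces: pd.DataFrame,
    surveys: pd.DataFrame,
    songs: pd.DataFrame,
    window: str = "full",
    min_participants: int = 2,
    peak_integrand: str = "value",
    retreat_normalized: bool = True,
) -> pd.DataFrame:
    """Build the song-level feature table from long-format traces.

    Applies familiarity filtering, optionally truncates to the first minute
    (``window="first_minute"``), then computes average immersion, peak
    immersion and retreat per song.  Returns one row per retained song with
    columns ``song_id, label, avg_immersion, peak_immersion, retreat,
    n_participants, window``.
    """
    if window not in ("full", "first_minute"):
        raise ValueError(f"unknown window {window!r}")
    labels = songs.set_index("song_id")["label"]
    kept = filter_unfamiliar(traces, surveys, min_participants=min_participants)
    if window == "first_minute":
        kept = kept[kept["t_sec"] < 60]
    if kept.empty:
        raise ValueError("no traces left after familiarity filtering")
    rows = []
    for song_id, grp in kept.groupby("song_id", sort=True):
        if song_id not in labels.index or pd.isna(labels.loc[song_id]):
            raise ValueError(f"song {song_id} has no label in the songs table")
        series = _series_from_long(grp, str(song_id))
        stats = compute_threshold(series)
        rows.append(
            {
                "song_id": song_id,
                "label": labels.loc[song_id],
                "avg_immersion": float(series.avg_series.mean()),
                "peak_immersion": compute_peak_immersion(
                    series, stats, integrand=peak_integrand
                ),
                "retreat": compute_retreat(
                    series, stats, normalized=retreat_normalized
                ),
                "n_participants": series.n_participants,
                "window": window,
            }
        )
    return pd.DataFrame(rows)


def featurize_cohort(
    cohort,
    window: str = "full",
    min_participants: int = 2,
    peak_integrand: str = "value",
    retreat_normalized: bool = True,
) -> pd.DataFrame:
    """Fast array path of :func:`featurize` for simulated cohorts.

    Operates directly on the cohort's (participants, songs, seconds) value
    array and familiarity matrix; numerically identical to running
    :func:`featurize` on the long-format frames.
    """
    if window not in ("full", "first_minute"):
        raise ValueError(f"unknown window {window!r}")
    values = cohort.values  # (P, S, T)
    familiar = cohort.familiar  # (P, S) in {0, 1}
    T = values.shape[2] if window == "full" else min(60, values.shape[2])
    song_ids = cohort.songs["song_id"].to_numpy()
    labels = cohort.songs.set_index("song_id")["label"]
    rows = []
    for s, song_id in enumerate(song_ids):
        mask = familiar[:, s] == 0
        if int(mask.sum()) < min_participants:
            logger.warning(
                "song %s excluded: fewer than %d unfamiliar participants",
                song_id,
                min_participants,
            )
            continue
        matrix = values[mask, s, :T]
        series = SongSeries(
            song_id=str(song_id),
            sample_matrix=matrix,
            avg_series=matrix.mean(axis=0),
            n_participants=int(mask.sum()),
        )
        stats = compute_threshold(series)
        rows.append(
            {
                "song_id": song_id,
                "label": labels.loc[song_id],
                "avg_immersion": float(series.avg_series.mean()),
                "peak_immersion": compute_peak_immersion(
                    series, stats, integrand=peak_integrand
                ),
                "retreat": compute_retreat(
                    series, stats, normalized=retreat_normalized
                ),
                "n_participants": int(mask.sum()),
                "window": window,
            }
        )
    if not rows:
        raise ValueError("no songs left after familiarity filtering")
    return pd.DataFrame(rows)
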