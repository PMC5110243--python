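"""Mitotic phase durations, spindle-orientation summaries and group tests.

Live imaging with a vital DNA dye yields, per dividing cell, the frame times
at which chromosome condensation, congression, metaphase-plate formation,
anaphase onset, decondensation and restored interphase morphology are first
seen (frame interval about 1.1 min). Successive differences of these event
times are the phase durations; prometaphase and metaphase are also reported
as their sum, and total mitosis is the sum of all phases.

Chromosome-plate orientation tracks (degrees from apical-surface
orthogonality, folded into [0, 90] with 90 = vertical plate) are summarised
by the maximal orientation range between plate formation and anaphase onset
and by the plate angle at a fixed offset (2.2 min) after anaphase onset,
which predicts the cleavage plane.

Group comparisons follow the convention of two-sided Mann-Whitney for two
groups and Kruskal-Wallis with Dunn's pairwise post-hoc test for three or
more, significant at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EVENT_FIELDS = (
    "t_prophase_start",
    "t_congression_start",
    "t_plate_formed",
    "t_anaphase_onset",
    "t_telophase_start",
    "t_interphase_restored",
)

PHASE_NAMES = ("prophase", "prometaphase", "metaphase", "anaphase", "telophase")

ALPHA = 0.05  # significance level used throughout


class TrackError(ValueError):
    """Invalid mitosis or orientation track."""


@dataclass
class MitosisTrack:
    """Ordered mitotic event times (minutes) for one cell, on a frame grid."""

    cell_id: str
    group: str
    t_prophase_start: float
    t_congression_start: float
    t_plate_formed: float
    t_anaphase_onset: float
    t_telophase_start: float
    t_interphase_restored: float
    frame_interval: float = 1.1

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise TrackError("frame interval must be positive")
        times = self.event_times
        if (times < 0).any():
            raise TrackError(f"negative event time in track {self.cell_id}")
        for i in range(len(times) - 1):
            if times[i] > times[i + 1] + 1e-9:
                raise TrackError(
                    f"track {self.cell_id}: {EVENT_FIELDS[i]} after "
                    f"{EVENT_FIELDS[i + 1]}"
                )
        frames = times / self.frame_interval
        if np.abs(frames - np.round(frames)).max() > 1e-6:
            raise TrackError(
                f"track {self.cell_id}: event times not on the frame grid"
            )

    @property
    def event_times(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in EVENT_FIELDS], dtype=float)


@dataclass
class PhaseDurations:
    """Per-phase durations in minutes. ``prometa_meta`` and ``total`` are sums."""

    prophase: float
    prometaphase: float
    metaphase: float
    anaphase: float
    telophase: float

    @property
    def prometa_meta(self) -> float:
        return self.prometaphase + self.metaphase

    @property
    def total(self) -> float:
        return (
            self.prophase
            + self.prometaphase
            + self.metaphase
            + self.anaphase
            + self.telophase
        )

    def as_dict(self) -> dict[str, float]:
        d = {p: getattr(self, p) for p in PHASE_NAMES}
        d["prometa_meta"] = self.prometa_meta
        d["total"] = self.total
        return d


def phase_durations(track: MitosisTrack) -> PhaseDurations:
    """Successive differences of the six event times."""
    t = track.event_times
    d = np.diff(t)
    return PhaseDurations(*d)


@dataclass
class OrientationTrack:
    """Time-resolved chromosome-plate angle for one mitotic cell.

    Angles are in degrees, folded into [0, 90] (90 = perfectly vertical
    plate, i.e. cleavage perpendicular to the apical surface).
    """

    cell_id: str
    times: np.ndarray
    angles: np.ndarray
    t_plate_formed: float
    t_anaphase_onset: float
    group: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape:
            raise TrackError("times and angles differ in length")
        if np.any(np.diff(self.times) < 0):
            raise TrackError("orientation samples not in time order")
        if ((self.angles < 0) | (self.angles > 90)).any():
            raise TrackError("angles outside [0, 90] degrees")
        if self.t_plate_formed > self.t_anaphase_onset:
            raise TrackError("plate formation after anaphase onset")


def orientation_range(track: OrientationTrack) -> float:
    """Maximal angle range between plate formation and anaphase onset."""
    in_window = (track.times >= track.t_plate_formed - 1e-9) & (
        track.times <= track.t_anaphase_onset + 1e-9
    )
    if not in_window.any():
        raise TrackError(
            f"track {track.cell_id}: no samples between plate formation and "
            "anaphase onset"
        )
    a = track.angles[in_window]
    return float(a.max() - a.min())


def cleavage_angle(track: OrientationTrack, offset: float = 2.2) -> float:
    """Plate angle at the sample nearest to anaphase onset + ``offset`` minutes.

    Ties between equally near samples resolve to the earlier one. The track
    must extend at least ``offset`` past anaphase onset.
    """
    target = track.t_anaphase_onset + offset
    if track.times.size == 0 or track.times.max() < target - 1e-9:
        raise TrackError(
            f"track {track.cell_id}: no samples {offset} min past anaphase onset"
        )
    idx = int(np.argmin(np.abs(track.times - target)))  # first = earlier on ties
    return float(track.angles[idx])


# ---------------------------------------------------------------------------
# group statistics


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def _dunn_pairwise(
    groups: dict[str, np.ndarray], adjust: str | None = None
) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled rank means, with tie correction.

    ``adjust``: None (default), 'bonferroni' or 'holm'.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction: sum over tied sets of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    mean_ranks, offset = {}, 0
    for g in labels:
        n_g = len(groups[g])
        mean_ranks[g] = float(ranks[offset : offset + n_g].mean())
        offset += n_g
    rows = []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / len(groups[gi]) + 1.0 / len(groups[gj])))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            p = float(2 * stats.norm.sf(abs(z)))
            rows.append({"group1": gi, "group2": gj, "z": float(z), "p": p})
    table = pd.DataFrame(rows)
    if adjust == "bonferroni":
        table["p_adjusted"] = np.minimum(1.0, table["p"] * len(table))
    elif adjust == "holm":
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_adjusted"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    p_col = "p_adjusted" if adjust else "p"
    table["significant"] = table[p_col] < ALPHA
    return table


@dataclass
class GroupComparison:
    """Report of a nonparametric comparison of phase durations across groups."""

    phase: str
    test_name: str
    statistic: float
    p_value: float
    significant: bool
    group_stats: pd.DataFrame
    pairwise: pd.DataFrame | None = None
    excluded_groups: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        d = {
            "phase": self.phase,
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": bool(self.significant),
            "groups": self.group_stats.to_dict(orient="records"),
            "excluded_groups": self.excluded_groups,
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


def compare_groups(
    durations: Mapping[str, Sequence[float]],
    phase: str = "",
    adjust: str | None = None,
) -> GroupComparison:
    """Compare a phase duration across groups.

    Two groups: two-sided Mann-Whitney U. Three or more: Kruskal-Wallis
    followed by Dunn's pairwise z tests (unadjusted by default; ``adjust``
    can request 'bonferroni' or 'holm'). Groups with fewer than three
    observations are excluded with a warning.
    """
    usable: dict[str, np.ndarray] = {}
    excluded = []
    for label, vals in durations.items():
        arr = np.asarray(list(vals), dtype=float)
        if len(arr) < 3:
            warnings.warn(
                f"group {label!r} has {len(arr)} < 3 observations; excluded",
                stacklevel=2,
            )
            excluded.append(label)
        else:
            usable[label] = arr
    if len(usable) < 2:
        raise ValueError("need at least two groups with >= 3 observations")

    group_stats = pd.DataFrame(
        [
            {
                "group": g,
                "n": len(v),
                "median": float(np.median(v)),
                "mean": float(v.mean()),
                "sem": _sem(v),
            }
            for g, v in usable.items()
        ]
    )

    labels = list(usable)
    if len(labels) == 2:
        stat, p = stats.mannwhitneyu(
            usable[labels[0]], usable[labels[1]], alternative="two-sided"
        )
        return GroupComparison(
            phase=phase,
            test_name="mann-whitney",
            statistic=float(stat),
            p_value=float(p),
            significant=p < ALPHA,
            group_stats=group_stats,
            excluded_groups=excluded,
        )
    stat, p = stats.kruskal(*usable.values())
    pairwise = _dunn_pairwise(usable, adjust=adjust)
    return GroupComparison(
        phase=phase,
        test_name="kruskal-wallis+dunn",
        statistic=float(stat),
        p_value=float(p),
        significant=p < ALPHA,
        group_stats=group_stats,
        pairwise=pairwise,
        excluded_groups=excluded,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def tracks_to_csv(tracks: Sequence[MitosisTrack], path) -> None:
    rows = [
        {
            "cell_id": t.cell_id,
            "group": t.group,
            **{f: getattr(t, f) for f in EVENT_FIELDS},
            "frame_interval": t.frame_interval,
        }
        for t in tracks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def tracks_from_csv(path) -> list[MitosisTrack]:
    df = pd.read_csv(path)
    return [
        MitosisTrack(
            cell_id=str(r["cell_id"]),
            group=str(r["group"]),
            frame_interval=float(r["frame_interval"]),
            **{f: float(r[f]) for f in EVENT_FIELDS},
        )
        for _, r in df.iterrows()
    ]


def orientation_tracks_to_csv(tracks: Sequence[OrientationTrack], path) -> None:
    rows = []
    for t in tracks:
        for time, angle in zip(t.times, t.angles):
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "group": t.group,
                    "time_min": time,
                    "angle_deg": angle,
                    "t_plate_formed": t.t_plate_formed,
                    "t_anaphase_onset": t.t_anaphase_onset,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def orientation_tracks_from_csv(path) -> list[OrientationTrack]:
    df = pd.read_csv(path)
    tracks = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        tracks.append(
            OrientationTrack(
                cell_id=str(cell_id),
                times=sub["time_min"].to_numpy(),
                angles=sub["angle_deg"].to_numpy(),
                t_plate_formed=float(sub["t_plate_formed"].iloc[0]),
                t_anaphase_onset=float(sub["t_anaphase_onset"].iloc[0]),
                group=str(sub["group"].iloc[0]) if "group" in sub else "",
            )
        )
    return tracks
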