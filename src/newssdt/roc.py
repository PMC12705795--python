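"""Rating-scale ROC construction, trapezoidal AUC, and the B"D bias index.

For each participant and phase, the 1..K reliability ratings of true and fake
news items are swept with the criteria "rated >= k" for k = K..2, giving a hit
rate (proportion of true items at or above k) and false-alarm rate (fake items
at or above k) per criterion.  The resulting cumulative operating points,
together with the fixed anchors (0,0) and (1,1), define an empirical ROC
curve.  Discrimination is the trapezoidal area under that curve (0.5 = chance,
1 = perfect); response bias is the mean over criteria of Donaldson's

    B"D = [(1-HR)(1-FAR) - HR*FAR] / [(1-HR)(1-FAR) + HR*FAR]

with +1 extreme conservative, -1 extreme liberal, 0 unbiased.

Conventions (documented in docs/methods.md): the k=1 criterion, whose point
is structurally (1,1) and whose B"D is constantly -1, is excluded from the
B"D average; the 0/0 corners (HR,FAR) = (1,0) and (0,1) are assigned B"D = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ComputationError
from .io_model import RatingsTable


@dataclass(frozen=True)
class OperatingPoint:
    """One ROC operating point: the criterion "rated >= k" and its (FAR, HR)."""

    criterion: int
    far: float
    hr: float


@dataclass(frozen=True)
class ROCCurve:
    """Cumulative operating points for k = scale_max..2, most conservative first.

    The fixed anchors (0,0) and (1,1) are implicit; the k=1 point always
    coincides with the (1,1) anchor and is not stored.
    """

    criteria: np.ndarray  # descending, scale_max..2
    far: np.ndarray
    hr: np.ndarray
    scale_max: int
    n_true: int = 0
    n_fake: int = 0
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for name in ("criteria", "far", "hr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.criteria) == len(self.far) == len(self.hr)):
            raise ComputationError(f"ragged ROC arrays for group {self.label!r}")
        if np.any(np.diff(self.far) < -1e-12) or np.any(np.diff(self.hr) < -1e-12):
            raise ComputationError(
                f"non-monotone cumulative proportions for group {self.label!r}"
            )

    @property
    def points(self) -> list[OperatingPoint]:
        return [
            OperatingPoint(int(k), float(f), float(h))
            for k, f, h in zip(self.criteria, self.far, self.hr)
        ]

    def polyline(self) -> tuple[np.ndarray, np.ndarray]:
        """Anchored (FAR, HR) path from (0,0) to (1,1), deduplicated."""
        f = np.concatenate([[0.0], self.far, [1.0]])
        h = np.concatenate([[0.0], self.hr, [1.0]])
        # cumulative curves stall at repeated points; drop exact duplicates
        keep = np.ones(len(f), dtype=bool)
        keep[1:] = (np.diff(f) > 0) | (np.diff(h) > 0)
        return f[keep], h[keep]


def operating_points(
    true_ratings: np.ndarray,
    fake_ratings: np.ndarray,
    scale_max: int,
    label: str = "",
) -> ROCCurve:
    """Build the ROC curve for one participant-phase group of ratings."""
    t = np.asarray(true_ratings, dtype=int)
    f = np.asarray(fake_ratings, dtype=int)
    if t.size == 0 or f.size == 0:
        raise ComputationError(
            f"group {label!r} needs at least one true and one fake item"
        )
    ks = np.arange(scale_max, 1, -1)  # K..2, most conservative first
    hr = (t[None, :] >= ks[:, None]).mean(axis=1)
    far = (f[None, :] >= ks[:, None]).mean(axis=1)
    return ROCCurve(
        criteria=ks, far=far, hr=hr, scale_max=scale_max,
        n_true=t.size, n_fake=f.size, label=label,
    )


def auc_trapezoid(curve: ROCCurve) -> float:
    """Trapezoidal area under the anchored empirical ROC polyline."""
    f, h = curve.polyline()
    return float(np.trapezoid(h, f))


def bias_bdprime(hr, far):
    """Donaldson's B"D at one operating point; vectorised over arrays.

    The 0/0 corners (HR,FAR) = (1,0) and (0,1), where a perfect or perverse
    separation point carries no bias information, are assigned 0.
    """
    hr = np.asarray(hr, dtype=float)
    far = np.asarray(far, dtype=float)
    num = (1.0 - hr) * (1.0 - far) - hr * far
    den = (1.0 - hr) * (1.0 - far) + hr * far
    out = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    if out.ndim == 0:
        return float(out)
    return out


def mean_bias(curve: ROCCurve) -> float:
    """Unweighted mean of B"D over the k = scale_max..2 criteria."""
    if len(curve.criteria) == 0:
        raise ComputationError(
            f"group {curve.label!r} has no includable criteria for B\"D"
        )
    return float(np.mean(bias_bdprime(curve.hr, curve.far)))


# -- whole-table summaries ----------------------------------------------------


def _rating_matrices(table: RatingsTable):
    """Group ratings into per-(participant, phase) count matrices.

    Returns (group keys DataFrame, true counts, fake counts) where counts have
    shape (n_groups, K) with column r-1 holding the number of items rated r.
    """
    df = table.data
    K = table.scale_max
    grouped = df.groupby(["participant_id", "phase"], sort=True)
    group_idx = grouped.ngroup().to_numpy()
    keys = list(grouped.groups)
    n_groups = len(keys)
    is_true = (df["truth"] == "true_news").to_numpy()
    ratings = df["rating"].to_numpy()
    counts = np.zeros((2, n_groups, K), dtype=np.int64)
    np.add.at(counts, (is_true.astype(int), group_idx, ratings - 1), 1)
    key_df = pd.DataFrame({
        "participant_id": [k[0] for k in keys],
        "phase": [k[1] for k in keys],
    })
    sets = df.drop_duplicates("participant_id").set_index("participant_id")["set"]
    key_df["set"] = key_df["participant_id"].map(sets)
    return key_df, counts[1], counts[0]


def _hr_far(counts: np.ndarray) -> np.ndarray:
    """Cumulative P(rating >= k) for k = K..2; shape (n_groups, K-1)."""
    totals = counts.sum(axis=1, keepdims=True)
    # reversed cumulative sum: column j counts ratings >= K-j
    ge = np.cumsum(counts[:, ::-1], axis=1)
    return ge[:, :-1] / totals


def summarize(table: RatingsTable) -> pd.DataFrame:
    """Per-(participant, phase) AUC and mean B"D.

    Returns a DataFrame with columns ``participant_id, set, phase, auc, bias,
    n_true, n_fake``, one row per participant-phase group, deterministic given
    the table.
    """
    key_df, true_counts, fake_counts = _rating_matrices(table)
    n_true = true_counts.sum(axis=1)
    n_fake = fake_counts.sum(axis=1)
    bad = (n_true == 0) | (n_fake == 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ComputationError(
            f"participant {key_df['participant_id'][i]!r}, phase "
            f"{key_df['phase'][i]!r} lacks true or fake items"
        )
    hr = _hr_far(true_counts)
    far = _hr_far(fake_counts)
    # anchored path (0,0) -> points (k=K..2) -> (1,1); trapezoid along FAR
    pad = np.zeros((len(hr), 1))
    one = np.ones((len(hr), 1))
    hp = np.hstack([pad, hr, one])
    fp = np.hstack([pad, far, one])
    auc = np.sum((fp[:, 1:] - fp[:, :-1]) * (hp[:, 1:] + hp[:, :-1]) / 2.0, axis=1)
    bias = bias_bdprime(hr, far).mean(axis=1)
    out = key_df.copy()
    out["auc"] = auc
    out["bias"] = bias
    out["n_true"] = n_true
    out["n_fake"] = n_fake
    out["phase"] = pd.Categorical(out["phase"], categories=["pre", "post"], ordered=True)
    return out.sort_values(["participant_id", "phase"]).reset_index(drop=True)


def curve_for(table: RatingsTable, participant_id: str, phase: str) -> ROCCurve:
    """The ROC curve of one participant in one phase."""
    df = table.data
    grp = df[(df["participant_id"] == str(participant_id)) & (df["phase"] == phase)]
    if grp.empty:
        raise ComputationError(f"no records for participant {participant_id!r}, phase {phase!r}")
    return operating_points(
        grp.loc[grp["truth"] == "true_news", "rating"].to_numpy(),
        grp.loc[grp["truth"] == "fake_news", "rating"].to_numpy(),
        table.scale_max,
        label=f"{participant_id}/{phase}",
    )


def group_roc(table: RatingsTable) -> pd.DataFrame:
    """Average ROC per phase: mean HR and FAR across participants per criterion.

    Provided for plotting/report export; inference always uses the
    per-participant statistics from :func:`summarize`.
    """
    key_df, true_counts, fake_counts = _rating_matrices(table)
    hr = _hr_far(true_counts)
    far = _hr_far(fake_counts)
    ks = np.arange(table.scale_max, 1, -1)
    rows = []
    for phase in ("pre", "post"):
        mask = (key_df["phase"] == phase).to_numpy()
        if not mask.any():
            continue
        for j, k in enumerate(ks):
            rows.append({
                "phase": phase,
                "criterion": int(k),
                "mean_far": float(far[mask, j].mean()),
                "mean_hr": float(hr[mask, j].mean()),
            })
    return pd.DataFrame(rows, columns=["phase", "criterion", "mean_far", "mean_hr"])


def concordance_auc(true_ratings, fake_ratings) -> float:
    """Pairwise concordance P(true > fake) + 0.5 P(tie) over all item pairs.

    Brute-force Mann-Whitney-style oracle; equals the trapezoidal AUC over all
    rating criteria exactly.
    """
    t = np.asarray(true_ratings, dtype=float)[:, None]
    f = np.asarray(fake_ratings, dtype=float)[None, :]
    return float(((t > f) + 0.5 * (t == f)).mean())
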