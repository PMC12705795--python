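"""Data contract and I/O for long-format truth-rating tables.

A ratings table holds one row per participant x phase x news item with the
participant's 1..K reliability rating, whether the item was true or fake news,
the fake-news technique category, and the counterbalancing set the participant
was assigned to.  :class:`RatingsTable` validates the contract on
construction; :func:`read_ratings_csv` / :func:`write_ratings_csv` round-trip
it through plain CSV; :func:`apply_exclusions` implements the preregistered
participant screening rules (exceptionally fast completion, reported technical
issues, not completing the intervention game).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SchemaError, ValidationError

PHASES = ("pre", "post")
SET_ASSIGNMENTS = ("A", "B")
TRUTH_LABELS = ("true_news", "fake_news")
CATEGORIES = ("Control", "Impersonation", "Conspiracy", "Discrediting")
FAKE_CATEGORIES = CATEGORIES[1:]

REQUIRED_COLUMNS = (
    "participant_id",
    "set",
    "phase",
    "item_id",
    "truth",
    "category",
    "rating",
)

#: Screening rule labels, in the priority order used when several rules fire
#: for the same participant.
EXCLUSION_RULES = ("did_not_complete_game", "reported_technical_issue", "too_fast")
FLAG_RULES = ("did_not_complete_game", "reported_technical_issue")

_CANONICAL = {
    "phase": {p.lower(): p for p in PHASES},
    "set": {s.lower(): s for s in SET_ASSIGNMENTS},
    "truth": {t.lower(): t for t in TRUTH_LABELS},
    "category": {c.lower(): c for c in CATEGORIES},
}


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Map case-insensitive categorical codes onto their canonical spelling."""
    df = df.copy()
    for col, mapping in _CANONICAL.items():
        values = df[col].astype(str).str.strip()
        lowered = values.str.lower()
        bad = ~lowered.isin(mapping)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"column {col!r}: unrecognised value {values.iloc[row]!r} at row {row}"
            )
        df[col] = lowered.map(mapping)
    return df


@dataclass(frozen=True)
class RatingsTable:
    """Validated long-format ratings records plus per-participant metadata.

    Parameters
    ----------
    data
        One row per (participant, phase, item) with the ``REQUIRED_COLUMNS``.
    scale_max
        Top of the rating scale K (ratings are integers in ``1..K``).
    metadata
        Free key -> value mapping.  The key ``"completion_time_seconds"``
        (participant_id -> seconds) feeds the speed exclusion rule.
    """

    data: pd.DataFrame
    scale_max: int = 7
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if self.scale_max < 2:
            raise ValidationError(f"scale_max must be >= 2, got {self.scale_max}")
        df = self.data.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        df["participant_id"] = df["participant_id"].astype(str)
        df["item_id"] = df["item_id"].astype(str)
        df = _canonicalize(df)
        df["rating"] = _parse_ratings(df["rating"], self.scale_max)
        _validate_records(df)
        object.__setattr__(self, "data", df)

    # -- convenience accessors -------------------------------------------------

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.data["participant_id"]))

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()

    def completion_times(self) -> dict[str, float] | None:
        times = self.metadata.get("completion_time_seconds")
        if times is None:
            return None
        return {str(k): float(v) for k, v in times.items()}

    def subset(self, participant_ids: Iterable[str]) -> "RatingsTable":
        keep = set(participant_ids)
        data = self.data[self.data["participant_id"].isin(keep)].reset_index(drop=True)
        metadata = dict(self.metadata)
        times = self.completion_times()
        if times is not None:
            metadata["completion_time_seconds"] = {
                pid: t for pid, t in times.items() if pid in keep
            }
        return RatingsTable(data, self.scale_max, metadata)

    def equals(self, other: "RatingsTable") -> bool:
        """Field-by-field equality of records, scale and completion times."""
        if self.scale_max != other.scale_max:
            return False
        a = self.data.sort_values(["participant_id", "phase", "item_id"]).reset_index(drop=True)
        b = other.data.sort_values(["participant_id", "phase", "item_id"]).reset_index(drop=True)
        if not a.equals(b):
            return False
        return self.completion_times() == other.completion_times()


def _parse_ratings(raw: pd.Series, scale_max: int) -> pd.Series:
    """Strictly parse ratings as integers in 1..K (no float coercion)."""
    values = np.empty(len(raw), dtype=np.int64)
    for i, v in enumerate(raw):
        if isinstance(v, (bool, np.bool_)):
            raise ValidationError(f"rating is not an integer at row {i}: {v!r}")
        if isinstance(v, (int, np.integer)):
            values[i] = int(v)
        elif isinstance(v, (float, np.floating)):
            if float(v) != int(v):
                raise ValidationError(f"rating is not an integer at row {i}: {v!r}")
            values[i] = int(v)
        else:
            s = str(v).strip()
            if not (s.isdigit() or (s.startswith("-") and s[1:].isdigit())):
                raise ValidationError(f"rating is not an integer at row {i}: {v!r}")
            values[i] = int(s)
        if not 1 <= values[i] <= scale_max:
            raise ValidationError(
                f"rating {values[i]} outside 1..{scale_max} at row {i}"
            )
    return pd.Series(values, name="rating")


def _validate_records(df: pd.DataFrame) -> None:
    # truth <-> category correspondence: the true items are the control items
    is_true = df["truth"] == "true_news"
    is_control = df["category"] == "Control"
    bad = is_true != is_control
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            "truth and category disagree at row "
            f"{row}: {df['truth'].iloc[row]!r} / {df['category'].iloc[row]!r} "
            "(true_news <=> Control)"
        )
    # one set assignment per participant
    sets_per_pid = df.groupby("participant_id", sort=False)["set"].nunique()
    bad_pids = sets_per_pid[sets_per_pid > 1]
    if len(bad_pids):
        raise ValidationError(
            f"participant {bad_pids.index[0]!r} has inconsistent set assignment"
        )
    # unique items and >=1 true / >=1 fake within each (participant, phase)
    grouped = df.groupby(["participant_id", "phase"], sort=False)
    dup = grouped["item_id"].nunique() != grouped["item_id"].size()
    if dup.any():
        pid, phase = dup[dup].index[0]
        raise ValidationError(f"duplicate item_id for participant {pid!r}, phase {phase!r}")
    counts = grouped["truth"].value_counts().unstack(fill_value=0)
    for label in TRUTH_LABELS:
        if label not in counts.columns:
            counts[label] = 0
    empty = counts[(counts["true_news"] < 1) | (counts["fake_news"] < 1)]
    if len(empty):
        pid, phase = empty.index[0]
        raise ValidationError(
            f"participant {pid!r}, phase {phase!r} lacks true or fake records"
        )


def read_ratings_csv(path: str | Path, scale_max: int = 7) -> RatingsTable:
    """Read and validate a long-format ratings CSV.

    The file must carry the columns ``participant_id, set, phase, item_id,
    truth, category, rating`` (header required; comma-separated; UTF-8).  An
    optional ``completion_time_seconds`` column, constant within participant,
    is lifted into table metadata for the speed exclusion rule.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"ratings file not found: {path}")
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "item_id": str, "rating": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    metadata: dict[str, Any] = {}
    if "completion_time_seconds" in df.columns:
        times = df.groupby("participant_id")["completion_time_seconds"]
        if (times.nunique() > 1).any():
            pid = times.nunique()[times.nunique() > 1].index[0]
            raise ValidationError(
                f"completion_time_seconds varies within participant {pid!r}"
            )
        metadata["completion_time_seconds"] = {
            str(pid): float(t) for pid, t in times.first().items()
        }
        df = df.drop(columns=["completion_time_seconds"])
    return RatingsTable(df, scale_max=scale_max, metadata=metadata)


def write_ratings_csv(table: RatingsTable, path: str | Path) -> None:
    """Write a ratings table to CSV, re-readable by :func:`read_ratings_csv`."""
    df = table.data.copy()
    times = table.completion_times()
    if times is not None:
        df["completion_time_seconds"] = df["participant_id"].map(times)
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of the preregistered participant screening.

    ``rule_fired`` maps each excluded participant to the first rule (in
    ``EXCLUSION_RULES`` priority order) that removed them; ``values`` carries
    the participant's completion time where the speed rule was evaluable.
    ``threshold_seconds`` is mean - 3*SD of completion time over all
    participants in the screened table (sample SD, n-1 denominator), computed
    before any exclusion.
    """

    rule_fired: dict[str, str]
    values: dict[str, float]
    threshold_seconds: float | None

    @property
    def excluded_ids(self) -> set[str]:
        return set(self.rule_fired)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": pid,
                "rule_fired": rule,
                "value": self.values.get(pid, float("nan")),
                "threshold": self.threshold_seconds
                if self.threshold_seconds is not None
                else float("nan"),
            }
            for pid, rule in sorted(self.rule_fired.items())
        ]
        return pd.DataFrame(
            rows, columns=["participant_id", "rule_fired", "value", "threshold"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_exclusions(
    table: RatingsTable,
    flags: Mapping[str, Iterable[str]] | None = None,
    speed_rule: bool | str = "auto",
) -> tuple[RatingsTable, ExclusionReport]:
    """Apply the preregistered screening rules and return the filtered table.

    Parameters
    ----------
    flags
        Optional participant_id -> iterable of flags drawn from
        ``{"reported_technical_issue", "did_not_complete_game"}``.
    speed_rule
        ``True`` to require the completion-time rule (error if no times are
        available), ``False`` to skip it, ``"auto"`` (default) to apply it
        exactly when completion times are present in the table metadata.

    A participant failing *any* rule is removed entirely.  The speed threshold
    is mean - 3*SD (sample SD) of the completion times of the table passed in;
    a participant is excluded when strictly below the threshold ("more than
    three standard deviations below the mean").
    """
    flags = {str(k): set(v) for k, v in (flags or {}).items()}
    for pid, fl in flags.items():
        unknown = fl - set(FLAG_RULES)
        if unknown:
            raise ConfigurationError(
                f"unknown screening flag(s) {sorted(unknown)} for participant {pid!r}"
            )
    times = table.completion_times()
    if speed_rule is True and times is None:
        raise ConfigurationError(
            "speed rule requested but the table has no completion times"
        )
    use_speed = bool(times) if speed_rule == "auto" else bool(speed_rule)

    threshold: float | None = None
    too_fast: set[str] = set()
    values: dict[str, float] = {}
    if use_speed and times:
        arr = np.array(list(times.values()), dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        threshold = float(arr.mean() - 3.0 * sd)
        too_fast = {pid for pid, t in times.items() if t < threshold}
        values = dict(times)

    rule_fired: dict[str, str] = {}
    for pid in table.participants:
        fired = [r for r in FLAG_RULES if r in flags.get(pid, set())]
        if pid in too_fast:
            fired.append("too_fast")
        if fired:
            rule_fired[pid] = min(fired, key=EXCLUSION_RULES.index)
    report = ExclusionReport(rule_fired=rule_fired, values=values, threshold_seconds=threshold)
    keep = [pid for pid in table.participants if pid not in rule_fired]
    return table.subset(keep), report


def read_flags_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read screening flags from a two-column TSV (participant_id, flag)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("participant_id", "flag"):
        if col not in df.columns:
            raise SchemaError(f"flags file missing column {col!r}")
    out: dict[str, set[str]] = {}
    for pid, flag in zip(df["participant_id"], df["flag"]):
        out.setdefault(str(pid), set()).add(str(flag))
    return out


def config_digest(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    import hashlib
    import json

    def default(o: Any) -> Any:
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    payload = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
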