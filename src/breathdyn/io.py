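"""Readers, writers and the cohort data model.

All interchange is plain CSV (comma, dot decimal, UTF-8, mandatory header).
Recordings are one belt-displacement channel, optionally with a time column;
anxiety scores follow the Beck Anxiety Inventory layout (total and/or 21
items scored 0-3); behavioral logs are one row per N-back trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("rest", "task")

#: canonical metric order for the 16-feature dynamics vector
METRICS = ("mean", "sd", "cv", "acw50", "psd_slope", "lzc", "sampen", "mse")
SERIES = ("rate", "amp")
#: canonical column order: metric-major, rate before amplitude
FEATURE_COLUMNS = tuple(f"{m}_{s}" for m in METRICS for s in SERIES)

META_COLUMNS = ("subject", "condition", "site")


@dataclass
class BreathRecording:
    """Raw sampled belt signal with subject/condition/site metadata."""

    subject_id: str
    condition: str
    site_id: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2:
            raise ValueError("recording needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples after load")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class AnxietyRecord:
    """One subject's Beck Anxiety Inventory outcome (total 0-63, items 0-3)."""

    subject_id: str
    bai_total: int
    bai_items: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.bai_total <= 63:
            raise ValueError(f"BAI total must be in 0..63, got {self.bai_total}")
        if self.bai_items is not None:
            items = tuple(int(v) for v in self.bai_items)
            if len(items) != 21:
                raise ValueError("BAI needs exactly 21 items")
            if any(v not in (0, 1, 2, 3) for v in items):
                raise ValueError("each BAI item must be in {0,1,2,3}")
            if sum(items) != self.bai_total:
                raise ValueError(
                    f"BAI total {self.bai_total} != item sum {sum(items)}"
                )
            self.bai_items = items


@dataclass
class BehaviorTrial:
    """One scored N-back trial."""

    subject_id: str
    load: int
    speed: str
    correct: int
    rt: float

    def __post_init__(self) -> None:
        if self.load not in (1, 2, 3):
            raise ValueError(f"load must be 1, 2 or 3, got {self.load}")
        if self.correct not in (0, 1):
            raise ValueError("correct must be 0 or 1")
        if not (np.isfinite(self.rt) and self.rt > 0):
            raise ValueError(f"rt must be finite and positive, got {self.rt}")


@dataclass
class FeatureTable:
    """Cohort feature table: one row per subject x condition.

    ``transform_state`` tracks the analysis ladder raw -> logged ->
    harmonized; statistical stages check it so that, e.g., site
    harmonization can only run on log-transformed features.
    """

    df: pd.DataFrame
    transform_state: str = "raw"
    untransformed: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS + FEATURE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if self.transform_state not in ("raw", "logged", "harmonized"):
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        dup = self.df.duplicated(subset=["subject", "condition"])
        if dup.any():
            rows = self.df.loc[dup, ["subject", "condition"]].to_records(index=False)
            raise ValueError(f"duplicate subject x condition rows: {list(rows)}")
        # canonical column order
        self.df = self.df.loc[:, list(META_COLUMNS) + list(FEATURE_COLUMNS)].reset_index(
            drop=True
        )

    @property
    def features(self) -> pd.DataFrame:
        return self.df.loc[:, list(FEATURE_COLUMNS)]

    def select(self, condition: str) -> "FeatureTable":
        """Rows for one condition, sorted by subject."""
        sub = self.df[self.df["condition"] == condition].sort_values("subject")
        return FeatureTable(sub.copy(), self.transform_state, self.untransformed)

    def drop_incomplete(self) -> "FeatureTable":
        """Listwise-exclude rows with any missing feature (logged)."""
        keep = self.df[list(FEATURE_COLUMNS)].notna().all(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d incomplete subject-condition rows", n_drop)
        return FeatureTable(self.df[keep].copy(), self.transform_state, self.untransformed)


def read_recording(
    path: str | Path,
    fs: float | None = None,
    *,
    subject_id: str,
    condition: str,
    site_id: str = "site0",
) -> BreathRecording:
    """Load a belt recording from CSV.

    The file holds either a single signal column or (time, signal) columns.
    When a time column is present the sampling rate is inferred from the
    median step and checked for monotonicity; rows with unparseable values
    are dropped and counted.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"empty recording file: {path}")
    if df.shape[1] == 1:
        raw = pd.to_numeric(df.iloc[:, 0], errors="coerce")
        n_dropped = int(raw.isna().sum())
        signal = raw.dropna().to_numpy()
        if fs is None:
            raise ValueError("fs required for single-column recordings")
        t0 = 0.0
    else:
        t = pd.to_numeric(df.iloc[:, 0], errors="coerce")
        x = pd.to_numeric(df.iloc[:, 1], errors="coerce")
        ok = t.notna() & x.notna()
        n_dropped = int((~ok).sum())
        t, x = t[ok].to_numpy(), x[ok].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotonic time column in {path}")
        inferred = 1.0 / float(np.median(np.diff(t)))
        if fs is None:
            fs = inferred
        elif abs(fs - inferred) / fs > 0.01:
            raise ValueError(f"declared fs {fs} Hz disagrees with time column ({inferred:.3g} Hz)")
        signal = x
        t0 = float(t[0])
    if signal.size == 0:
        raise ValueError(f"no numeric signal values in {path}")
    logger.info("%s: %d rows read, %d kept, %d dropped", path.name, df.shape[0],
                signal.size, n_dropped)
    return BreathRecording(
        subject_id=subject_id, condition=condition, site_id=site_id,
        fs=float(fs), samples=signal, t0=t0, n_dropped=n_dropped,
    )


def read_anxiety_table(path: str | Path) -> list[AnxietyRecord]:
    """Load BAI scores: ``subject,bai_total[,item_1..item_21]``.

    When items are present the total is validated against (or derived
    from) their sum.
    """
    df = pd.read_csv(path)
    if "subject" not in df.columns:
        raise ValueError("anxiety table needs a 'subject' column")
    item_cols = [f"item_{i}" for i in range(1, 22)]
    has_items = all(c in df.columns for c in item_cols)
    if not has_items and "bai_total" not in df.columns:
        raise ValueError("anxiety table needs bai_total or item_1..item_21 columns")
    records = []
    for _, row in df.iterrows():
        items = tuple(int(row[c]) for c in item_cols) if has_items else None
        total = int(row["bai_total"]) if "bai_total" in df.columns else sum(items)
        records.append(AnxietyRecord(str(row["subject"]), total, items))
    return records


def read_behavior_table(path: str | Path) -> list[BehaviorTrial]:
    """Load N-back trials: ``subject,load,speed,correct,rt``.

    A missing speed column is tolerated (set to "unknown"); speeds are
    pooled within load downstream anyway.
    """
    df = pd.read_csv(path)
    required = {"subject", "load", "correct", "rt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    if "speed" not in df.columns:
        df = df.assign(speed="unknown")
    return [
        BehaviorTrial(str(r.subject), int(r.load), str(r.speed), int(r.correct), float(r.rt))
        for r in df.itertuples(index=False)
    ]


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as wide CSV in canonical column order.

    Values are written with 17 significant digits so the write/read
    round trip is exact.
    """
    table.df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path, transform_state: str = "raw") -> FeatureTable:
    df = pd.read_csv(path, dtype={"subject": str, "condition": str, "site": str})
    if df.shape[0] == 0 and df.shape[1] == 0:
        raise ValueError(f"empty feature file: {path}")
    return FeatureTable(df, transform_state)


def make_feature_table(rows: Sequence[dict], transform_state: str = "raw") -> FeatureTable:
    """Assemble a FeatureTable from per-row dicts (metadata + 16 features)."""
    return FeatureTable(pd.DataFrame(list(rows)), transform_state)
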