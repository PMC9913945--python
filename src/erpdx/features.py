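"""Parametrized sliding-window feature extraction from ERP intervals.

Each condition's analysis interval is split into (possibly overlapping)
windows of ``window_size_ms`` whose starts advance by ``shift_pct`` % of
the window size.  Per window, the minimum, maximum and mean amplitude
are extracted; per signal the global mean/max/min and the serial numbers
of the windows attaining the global extrema are appended, so a signal
with ``n`` windows yields ``3n + 5`` features.

Features are named ``{condition}_{channel}_{type}_{window}`` with the
window number omitted for global features — e.g. ``plus1_T6_min_1`` is
the minimum of the first window of channel T6 in condition plus1.

The default per-condition window parameters reproduce the best reported
configuration:

=======  ==============  =============
cond     window size ms  window shift %
=======  ==============  =============
plus1    49              50
plus2    5               50
nogo     49              100
go       20              100
ph       5               100
=======  ==============  =============

At 250 Hz these produce 7/45/4/10/15 windows over the five condition
intervals and 986 ERP features in total across the 22 channel-signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from erpdx.erp_data import (
    ConditionRegistry,
    ERPDataset,
    default_registry,
    ms_to_sample,
    slice_interval,
    POSITIVE_GROUP,
)
from erpdx.errors import ConfigError, ValidationError

FEATURE_TYPES = ("min", "max", "mean", "argmaxwin", "argminwin")
GLOBAL_TYPES = ("mean", "max", "min", "argmaxwin", "argminwin")
BEHAVIOR_FEATURES = ("miss_pct", "false_click_pct", "rt_ms", "rt_var")


@dataclass(frozen=True)
class WindowParams:
    """Window size in ms and start-to-start shift as % of window size.

    ``shift_pct`` = 100 tiles the interval without overlap; < 100
    overlaps consecutive windows.
    """

    window_size_ms: float
    shift_pct: float

    def __post_init__(self) -> None:
        if self.window_size_ms <= 0:
            raise ConfigError("window_size_ms must be > 0")
        if not 0 < self.shift_pct <= 100:
            raise ConfigError("shift_pct must be in (0, 100]")


def default_window_params() -> dict[str, WindowParams]:
    """Best reported per-condition window parameters (see module docstring)."""
    return {
        "plus1": WindowParams(49, 50),
        "plus2": WindowParams(5, 50),
        "nogo": WindowParams(49, 100),
        "go": WindowParams(20, 100),
        "ph": WindowParams(5, 100),
    }


def smoke_window_params(registry: ConditionRegistry | None = None) -> dict[str, WindowParams]:
    """Coarse parameters for fast end-to-end runs: non-overlapping
    half-interval windows (one or two windows per condition)."""
    if registry is None:
        registry = default_registry()
    return {
        s.name: WindowParams((s.interval_end_ms - s.interval_start_ms) / 2.0, 100)
        for s in registry
    }


@dataclass(frozen=True)
class FeatureName:
    """Structured form of the `{condition}_{channel}_{type}_{window}` template."""

    condition: str
    channel: str
    feature_type: str
    window: int | None = None  # None for global features

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValidationError(f"unknown feature type {self.feature_type!r}")
        if self.window is not None and self.window < 1:
            raise ValidationError("window numbers start at 1")

    def __str__(self) -> str:
        base = f"{self.condition}_{self.channel}_{self.feature_type}"
        return base if self.window is None else f"{base}_{self.window}"

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        parts = name.split("_")
        if len(parts) == 4:
            cond, ch, ftype, win = parts
            return cls(cond, ch, ftype, int(win))
        if len(parts) == 3:
            cond, ch, ftype = parts
            return cls(cond, ch, ftype, None)
        raise ValidationError(f"cannot parse feature name {name!r}")


def make_windows(n_samples: int, params: WindowParams, fs: float) -> list[tuple[int, int]]:
    """Half-open sample-index windows over a signal of length ``n_samples``.

    ``w = max(1, round(W*fs/1000))`` samples per window,
    ``s = max(1, round(w*shift_pct/100))`` samples between starts;
    windows start at 0, s, 2s, ... while they fit; a trailing remainder
    shorter than ``w`` is dropped.
    """
    if n_samples < 1:
        raise ConfigError("signal must have at least 1 sample")
    w = max(1, ms_to_sample(params.window_size_ms, fs))
    s = max(1, round(w * params.shift_pct / 100.0))
    if w > n_samples:
        raise ConfigError(
            f"window of {w} samples ({params.window_size_ms} ms) exceeds "
            f"signal length {n_samples}"
        )
    return [(start, start + w) for start in range(0, n_samples - w + 1, s)]


def extract_signal_features(signal, params: WindowParams, fs: float
                            ) -> list[tuple[str, int | None, float]]:
    """Windowed + global features of one signal as (type, window, value).

    Order: min_1..min_n, max_1..max_n, mean_1..mean_n, then global mean,
    max, min, and the 1-based serial numbers of the first windows
    attaining the window-level maximum/minimum (which equal the windows
    attaining the global extrema whenever those fall inside a window).
    Total 3n + 5 values.
    """
    x = np.asarray(signal, dtype=float)
    windows = make_windows(x.size, params, fs)
    mins = [float(x[a:b].min()) for a, b in windows]
    maxs = [float(x[a:b].max()) for a, b in windows]
    means = [float(x[a:b].mean()) for a, b in windows]

    out: list[tuple[str, int | None, float]] = []
    out += [("min", j + 1, v) for j, v in enumerate(mins)]
    out += [("max", j + 1, v) for j, v in enumerate(maxs)]
    out += [("mean", j + 1, v) for j, v in enumerate(means)]
    out.append(("mean", None, float(x.mean())))
    out.append(("max", None, float(x.max())))
    out.append(("min", None, float(x.min())))
    out.append(("argmaxwin", None, float(int(np.argmax(maxs)) + 1)))
    out.append(("argminwin", None, float(int(np.argmin(mins)) + 1)))
    return out


class FeatureTable:
    """Named feature matrix: rows = subjects, columns = features.

    Wraps a DataFrame indexed by subject id with a parallel group-label
    series.  The patient class (``schizophrenia``) is the positive class
    everywhere downstream.
    """

    def __init__(self, values: pd.DataFrame, groups: pd.Series):
        if values.columns.duplicated().any():
            raise ValidationError("duplicate feature names")
        if values.isna().any().any():
            raise ValidationError("feature table contains missing values")
        if not values.index.equals(groups.index):
            raise ValidationError("values and groups index mismatch")
        self.values = values
        self.groups = groups

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return (self.groups == POSITIVE_GROUP).to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown features {missing}")
        return FeatureTable(self.values[names].copy(), self.groups.copy())

    def select_rows(self, idx) -> "FeatureTable":
        return FeatureTable(self.values.iloc[idx].copy(), self.groups.iloc[idx].copy())

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.insert(0, "group", self.groups)
        df.insert(0, "subject_id", self.values.index)
        return df.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        df = df.set_index("subject_id")
        groups = df.pop("group")
        return cls(df, groups)


def build_feature_table(dataset: ERPDataset,
                        params: dict[str, WindowParams] | None = None,
                        include_behavior: bool = True) -> FeatureTable:
    """Extract the full feature table for a cohort.

    Signals are processed in registry order, channels in each
    condition's declared order, so the column order is deterministic
    given (registry, params). The four behavioral columns are appended
    when ``include_behavior`` is set.
    """
    if params is None:
        params = default_window_params()
    registry = dataset.registry
    missing = [s.name for s in registry if s.name not in params]
    if missing:
        raise ConfigError(f"window parameters missing for conditions {missing}")

    columns: list[str] | None = None
    rows = []
    for subj in dataset.subjects:
        row: list[float] = []
        names: list[str] = []
        for spec in registry:
            p = params[spec.name]
            for ch in spec.channels:
                wave = subj.erps.get((spec.name, ch))
                if wave is None:
                    raise ValidationError(
                        f"subject {subj.subject_id}: missing ({spec.name}, {ch})")
                try:
                    feats = extract_signal_features(
                        slice_interval(wave, spec), p, wave.sampling_rate_hz)
                except Exception as e:
                    raise type(e)(
                        f"subject {subj.subject_id}, condition {spec.name}, "
                        f"channel {ch}: {e}") from e
                for ftype, win, val in feats:
                    names.append(str(FeatureName(spec.name, ch, ftype, win)))
                    row.append(val)
        if include_behavior:
            if subj.behavior is None:
                raise ValidationError(
                    f"subject {subj.subject_id}: behavior requested but absent")
            names.extend(BEHAVIOR_FEATURES)
            row.extend(subj.behavior.as_tuple())
        if columns is None:
            columns = names
        elif names != columns:
            raise ValidationError(f"inconsistent feature layout for {subj.subject_id}")
        rows.append(row)

    if columns is None:  # empty dataset: synthesize header from registry
        columns = []
        fs = 250.0
        for spec in registry:
            n = len(make_windows(spec.n_interval_samples(fs), params[spec.name], fs))
            for ch in spec.channels:
                for ftype in ("min", "max", "mean"):
                    columns += [str(FeatureName(spec.name, ch, ftype, j + 1)) for j in range(n)]
                columns += [str(FeatureName(spec.name, ch, t)) for t in GLOBAL_TYPES]
        # per-signal ordering above matches the non-empty path
        if include_behavior:
            columns += list(BEHAVIOR_FEATURES)

    index = pd.Index([s.subject_id for s in dataset.subjects], name="subject_id")
    values = pd.DataFrame(rows, index=index, columns=columns, dtype=float)
    groups = pd.Series([s.group for s in dataset.subjects], index=index, name="group")
    return FeatureTable(values, groups)
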