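"""Domain types for averaged ERP data and the fixed condition registry.

The analysis operates on per-subject ERP averages from a visual cued
Go/NoGo paradigm recorded with 19 channels of the 10-20 montage at
250 Hz.  Five named conditions are analysed, each over a fixed channel
subset and a fixed latency interval relative to either the first (cue)
or the second (imperative) stimulus of a trial:

=======  ==================  ===========  ================  ==========
name     channels            interval ms  reference         component
=======  ==================  ===========  ================  ==========
plus1    T5 O1 O2 T6         320-520      first stimulus    P3cue
plus2    P3 Pz P4            900-1080     first stimulus    CNV
nogo     C3 Cz C4 P3 Pz P4   300-500      second stimulus   P300 NoGo
go       C3 Cz C4 P3 Pz P4   250-450      second stimulus   P3b
ph       C3 Cz C4            160-220      second stimulus   P3a
=======  ==================  ===========  ================  ==========

The interchange format is long CSV with columns
``subject_id,group,condition,channel,time_ms,amplitude_uv`` where
``time_ms`` is relative to the condition's reference stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from erpdx.errors import CoverageError, FormatError, ValidationError

#: The 19 electrode labels of the 10-20 montage used throughout.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "C3", "Cz", "C4", "T3", "T4",
    "P3", "Pz", "P4", "T5", "T6", "O1", "O2",
)

GROUPS: tuple[str, str] = ("healthy", "schizophrenia")

#: Positive (patient) class label for classification.
POSITIVE_GROUP = "schizophrenia"

CONDITION_NAMES: tuple[str, ...] = ("plus1", "plus2", "nogo", "go", "ph")

ERP_COLUMNS = ["subject_id", "group", "condition", "channel", "time_ms", "amplitude_uv"]
BEHAVIOR_COLUMNS = ["subject_id", "group", "miss_pct", "false_click_pct", "rt_ms", "rt_var"]


def ms_to_sample(ms: float, fs: float) -> int:
    """Convert milliseconds to a sample index (round half to even)."""
    return round(ms * fs / 1000.0)


@dataclass(frozen=True)
class ConditionSpec:
    """A named ERP condition: channel subset + analysis interval.

    The interval is in milliseconds relative to ``reference``
    (``first_stimulus`` or ``second_stimulus``) and is half-open
    ``[interval_start_ms, interval_end_ms)`` once converted to samples.
    """

    name: str
    channels: tuple[str, ...]
    interval_start_ms: float
    interval_end_ms: float
    reference: str = "first_stimulus"

    def __post_init__(self) -> None:
        if self.interval_start_ms < 0 or self.interval_end_ms < 0:
            raise ValidationError(f"{self.name}: interval bounds must be non-negative")
        if not self.interval_start_ms < self.interval_end_ms:
            raise ValidationError(
                f"{self.name}: interval_start_ms ({self.interval_start_ms}) must be "
                f"< interval_end_ms ({self.interval_end_ms})"
            )
        if not self.channels:
            raise ValidationError(f"{self.name}: channel list is empty")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError(f"{self.name}: duplicate channels in {self.channels}")
        unknown = [c for c in self.channels if c not in CHANNELS_1020]
        if unknown:
            raise ValidationError(f"{self.name}: unknown channels {unknown}")
        if self.reference not in ("first_stimulus", "second_stimulus"):
            raise ValidationError(f"{self.name}: bad reference {self.reference!r}")

    def n_interval_samples(self, fs: float = 250.0) -> int:
        return ms_to_sample(self.interval_end_ms, fs) - ms_to_sample(self.interval_start_ms, fs)


@dataclass(frozen=True)
class ConditionRegistry:
    """Mapping from condition name to its :class:`ConditionSpec`."""

    specs: tuple[ConditionSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate condition names: {names}")

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def __getitem__(self, name: str) -> ConditionSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.specs)


def default_registry() -> ConditionRegistry:
    """The five Go/NoGo analysis conditions with their fixed intervals."""
    return ConditionRegistry((
        ConditionSpec("plus1", ("T5", "O1", "O2", "T6"), 320, 520, "first_stimulus"),
        ConditionSpec("plus2", ("P3", "Pz", "P4"), 900, 1080, "first_stimulus"),
        ConditionSpec("nogo", ("C3", "Cz", "C4", "P3", "Pz", "P4"), 300, 500, "second_stimulus"),
        ConditionSpec("go", ("C3", "Cz", "C4", "P3", "Pz", "P4"), 250, 450, "second_stimulus"),
        ConditionSpec("ph", ("C3", "Cz", "C4"), 160, 220, "second_stimulus"),
    ))


@dataclass
class Waveform:
    """An averaged ERP trace for one (subject, condition, channel).

    ``onset_ms`` is the time of the reference stimulus relative to the
    first sample; it may be negative when the trace starts after the
    stimulus (the usual case here, since only a latency band around each
    component is stored).
    """

    samples: np.ndarray
    sampling_rate_hz: float = 250.0
    onset_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.samples.size == 0:
            raise ValidationError("waveform has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("waveform contains non-finite samples")

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the reference stimulus."""
        step = 1000.0 / self.sampling_rate_hz
        return -self.onset_ms + step * np.arange(self.samples.size)


def slice_interval(w: Waveform, spec: ConditionSpec) -> np.ndarray:
    """Extract the samples of ``spec``'s half-open analysis interval.

    Index arithmetic: the stimulus sample index is
    ``round(onset_ms * fs / 1000)`` from the start of the trace; the
    interval spans ``round(start*fs/1000) <= i < round(end*fs/1000)``
    counted from the stimulus, so the slice length is exactly
    ``round(end*fs/1000) - round(start*fs/1000)``.
    """
    fs = w.sampling_rate_hz
    onset_idx = ms_to_sample(w.onset_ms, fs)
    i0 = onset_idx + ms_to_sample(spec.interval_start_ms, fs)
    i1 = onset_idx + ms_to_sample(spec.interval_end_ms, fs)
    if i0 < 0 or i1 > w.samples.size:
        raise CoverageError(
            f"waveform covers samples [0, {w.samples.size}) but condition "
            f"{spec.name!r} needs [{i0}, {i1}) "
            f"({spec.interval_start_ms}-{spec.interval_end_ms} ms)"
        )
    return w.samples[i0:i1]


@dataclass
class SubjectRecord:
    """All averaged ERPs and the behavioral summary of one subject."""

    subject_id: str
    group: str
    erps: dict[tuple[str, str], Waveform] = field(default_factory=dict)
    behavior: "BehaviorSummary | None" = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"subject {self.subject_id}: group must be one of {GROUPS}, got {self.group!r}"
            )

    def validate_against(self, registry: ConditionRegistry) -> None:
        """Check every registry (condition, channel) waveform exists and covers its interval."""
        for spec in registry:
            for ch in spec.channels:
                w = self.erps.get((spec.name, ch))
                if w is None:
                    raise ValidationError(
                        f"subject {self.subject_id}: missing waveform for "
                        f"({spec.name}, {ch})"
                    )
                try:
                    slice_interval(w, spec)
                except CoverageError as e:
                    raise CoverageError(
                        f"subject {self.subject_id}, condition {spec.name}, "
                        f"channel {ch}: {e}"
                    ) from e


@dataclass
class ERPDataset:
    """A cohort of :class:`SubjectRecord` plus the condition registry."""

    subjects: list[SubjectRecord]
    registry: ConditionRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]

    def n_by_group(self) -> dict[str, int]:
        out = {g: 0 for g in GROUPS}
        for s in self.subjects:
            out[s.group] += 1
        return out

    def validate(self) -> None:
        for s in self.subjects:
            s.validate_against(self.registry)


def load_erp_table(path, registry: ConditionRegistry | None = None) -> ERPDataset:
    """Read a long-format ERP CSV into an :class:`ERPDataset`.

    The file must have a header row with columns
    ``subject_id,group,condition,channel,time_ms,amplitude_uv``;
    ``time_ms`` is relative to the condition's reference stimulus.
    Waveforms are assembled per (subject, condition, channel) with
    ascending ``time_ms``; the sampling rate is inferred from the time
    grid. Subject invariants are validated.
    """
    if registry is None:
        registry = default_registry()
    df = pd.read_csv(path)
    missing = [c for c in ERP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    bad_ch = sorted(set(df["channel"]) - set(CHANNELS_1020))
    if bad_ch:
        raise ValidationError(f"{path}: unknown channels {bad_ch}")
    bad_cond = sorted(set(df["condition"]) - set(registry.names))
    if bad_cond:
        raise ValidationError(f"{path}: unknown conditions {bad_cond}")
    bad_grp = sorted(set(df["group"]) - set(GROUPS))
    if bad_grp:
        raise ValidationError(f"{path}: unknown groups {bad_grp}")

    subjects: list[SubjectRecord] = []
    # groupby(sort=False) keeps first-appearance subject order
    for sid, sdf in df.groupby("subject_id", sort=False):
        group = sdf["group"].iloc[0]
        if (sdf["group"] != group).any():
            raise ValidationError(f"subject {sid}: inconsistent group labels")
        rec = SubjectRecord(subject_id=str(sid), group=group)
        for (cond, ch), wdf in sdf.groupby(["condition", "channel"], sort=False):
            wdf = wdf.sort_values("time_ms")
            t = wdf["time_ms"].to_numpy(dtype=float)
            if t.size < 2:
                raise FormatError(f"subject {sid} ({cond}, {ch}): fewer than 2 samples")
            steps = np.diff(t)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                raise FormatError(f"subject {sid} ({cond}, {ch}): non-uniform time grid")
            fs = 1000.0 / steps[0]
            rec.erps[(cond, ch)] = Waveform(
                samples=wdf["amplitude_uv"].to_numpy(dtype=float),
                sampling_rate_hz=fs,
                onset_ms=-t[0],
            )
        subjects.append(rec)

    ds = ERPDataset(subjects=subjects, registry=registry)
    ds.validate()
    return ds


def write_erp_table(dataset: ERPDataset, path) -> None:
    """Write the long CSV format; amplitudes at 6 decimals, times at 3.

    ``load_erp_table(write_erp_table(d))`` reproduces the dataset exactly
    when amplitudes are already quantized to 6 decimals (as the synthetic
    generator emits them).
    """
    rows: list[tuple] = []
    for s in dataset.subjects:
        for spec in dataset.registry:
            for ch in spec.channels:
                w = s.erps.get((spec.name, ch))
                if w is None:
                    continue
                for t, a in zip(w.times_ms(), w.samples):
                    rows.append((s.subject_id, s.group, spec.name, ch,
                                 f"{t:.3f}", f"{a:.6f}"))
    df = pd.DataFrame(rows, columns=ERP_COLUMNS)
    df.to_csv(path, index=False)


def write_behavior_table(dataset: ERPDataset, path) -> None:
    """Write per-subject behavioral summaries as CSV."""
    rows = []
    for s in dataset.subjects:
        b = s.behavior
        if b is None:
            continue
        rows.append((s.subject_id, s.group,
                     f"{b.miss_pct:.6f}", f"{b.false_click_pct:.6f}",
                     f"{b.rt_ms:.6f}", f"{b.rt_var:.6f}"))
    pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS).to_csv(path, index=False)


def load_behavior_table(path) -> pd.DataFrame:
    """Read a behavior CSV (`subject_id,group,miss_pct,false_click_pct,rt_ms,rt_var`)."""
    df = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def attach_behavior(dataset: ERPDataset, behavior_df: pd.DataFrame) -> None:
    """Attach behavioral summaries from a behavior table to dataset subjects."""
    from erpdx.behavior import BehaviorSummary

    by_id = behavior_df.set_index("subject_id")
    for s in dataset.subjects:
        if s.subject_id in by_id.index:
            row = by_id.loc[s.subject_id]
            s.behavior = BehaviorSummary(
                miss_pct=float(row["miss_pct"]),
                false_click_pct=float(row["false_click_pct"]),
                rt_ms=float(row["rt_ms"]),
                rt_var=float(row["rt_var"]),
            )
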