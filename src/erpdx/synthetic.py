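"""Seeded synthetic cued Go/NoGo cohorts.

The clinical cohort behind this pipeline (132 healthy controls, 68
patients with schizophrenia) is not publicly available, so this module
generates cohorts with the statistical structure the analysis assumes:

- one Gaussian-bump ERP component per analysis condition (P3cue, CNV,
  P300 NoGo, P3b, P3a), centred at the midpoint of the condition's
  latency interval, with a fixed channel topography and a per-subject
  peak amplitude drawn around a group mean — attenuated in the patient
  group, as repeatedly reported for P300-family and CNV waves in
  schizophrenia;
- additive white Gaussian residual noise on the averaged waveforms;
- per-subject behavioral summaries drawn from group normal models whose
  default means/SDs are the published group statistics (misses %, false
  clicks %, mean RT in ms, RT coefficient of variation in %);
- optional trial-level response logs consistent with those summaries.

``effect_scale`` interpolates every patient group parameter toward the
healthy one (1 = full group difference, 0 = a null cohort in which the
two groups are drawn from identical distributions — ERPs *and*
behavior).  All randomness flows from one seed through per-subject
substreams, so cohorts are reproducible and stable under subject-count
changes.

The waveforms are a minimal statistical emulation, not a physiological
model: no 1/f background, no component latency jitter, no channel
covariance beyond the shared per-component amplitude draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from erpdx.behavior import BehaviorSummary, TrialResponse, GO_TRIAL, NOGO_TRIAL, RT_VALID_MS
from erpdx.erp_data import (
    ConditionRegistry,
    ERPDataset,
    SubjectRecord,
    Waveform,
    default_registry,
    ms_to_sample,
)
from erpdx.errors import ConfigError, ValidationError


@dataclass(frozen=True)
class ComponentModel:
    """One ERP component: a Gaussian bump with group-dependent amplitude."""

    condition: str
    latency_ms: float           # bump centre, ms relative to reference stimulus
    width_ms: float             # Gaussian temporal SD
    topography: dict[str, float]  # channel -> weight in [0, 1]
    amp_healthy_uv: float
    amp_patient_uv: float
    polarity: int = 1           # +1 positive wave, -1 negative (CNV)
    subject_sd_frac: float = 0.25  # between-subject amplitude SD / group mean

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ConfigError(f"{self.condition}: width_ms must be > 0")
        if self.polarity not in (1, -1):
            raise ConfigError(f"{self.condition}: polarity must be +1 or -1")
        if not self.topography or max(self.topography.values()) <= 0:
            raise ConfigError(f"{self.condition}: topography needs a positive weight")
        for ch, w in self.topography.items():
            if not 0.0 <= w <= 1.0:
                raise ConfigError(f"{self.condition}: weight {w} for {ch} outside [0,1]")
        if self.amp_patient_uv > self.amp_healthy_uv:
            raise ConfigError(
                f"{self.condition}: patient amplitude exceeds healthy "
                "(components model patient attenuation)"
            )


#: Group behavioral statistics (mean, SD) used as generator defaults.
TABLE1_BEHAVIOR = {
    "healthy": {"miss_pct": (1.6, 2.8), "false_click_pct": (0.7, 1.3),
                "rt_ms": (379.0, 79.0), "rt_var": (8.4, 2.6)},
    "schizophrenia": {"miss_pct": (9.4, 11.4), "false_click_pct": (2.0, 6.7),
                      "rt_ms": (416.0, 92.0), "rt_var": (12.0, 4.8)},
}

RATE_CLIP = (0.0, 100.0)
RT_CLIP = (200.0, 1000.0)


@dataclass(frozen=True)
class BehaviorModel:
    """Per-group normal models for the four behavioral summaries.

    ``params[group][measure] = (mean, sd)``. Sampled rates are clipped to
    [0, 100] % and RTs to [200, 1000] ms.
    """

    params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(m) for g, m in TABLE1_BEHAVIOR.items()}
    )

    def __post_init__(self) -> None:
        for g, measures in self.params.items():
            for m, (mu, sd) in measures.items():
                if sd <= 0:
                    raise ConfigError(f"{g}/{m}: SD must be > 0")

    def scaled(self, effect_scale: float) -> "BehaviorModel":
        """Interpolate patient parameters toward healthy by 1 - effect_scale."""
        h = self.params["healthy"]
        p = self.params["schizophrenia"]
        mixed = {
            m: (h[m][0] + effect_scale * (p[m][0] - h[m][0]),
                h[m][1] + effect_scale * (p[m][1] - h[m][1]))
            for m in p
        }
        return BehaviorModel({"healthy": dict(h), "schizophrenia": mixed})

    def draw(self, group: str, rng: np.random.Generator) -> BehaviorSummary:
        out = {}
        for m, (mu, sd) in self.params[group].items():
            x = rng.normal(mu, sd)
            lo, hi = RT_CLIP if m == "rt_ms" else RATE_CLIP
            if m == "rt_var":
                lo, hi = 0.0, 100.0
            out[m] = float(np.clip(x, lo, hi))
        return BehaviorSummary(**out)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generation settings; defaults mirror the study's group sizes."""

    n_healthy: int = 132
    n_patient: int = 68
    noise_sd_uv: float = 1.5
    effect_scale: float = 1.0
    seed: int = 0
    sampling_rate_hz: float = 250.0
    margin_ms: float = 100.0  # waveform margin around each condition interval

    def __post_init__(self) -> None:
        if self.n_healthy < 2 or self.n_patient < 2:
            raise ConfigError("need at least 2 subjects per group")
        if not 0.0 <= self.effect_scale <= 1.0:
            raise ConfigError("effect_scale must be in [0, 1]")
        if self.noise_sd_uv < 0:
            raise ConfigError("noise_sd_uv must be >= 0")


def default_components(registry: ConditionRegistry | None = None) -> list[ComponentModel]:
    """One component per registry condition, latency at the interval midpoint.

    Peak amplitudes are calibration choices (the study reports none):
    healthy P300-family peaks near 8 µV with patient attenuation of
    roughly a third, against 1.5 µV residual noise on the averages —
    enough group overlap that classification is non-trivial but
    recoverable. CNV (plus2) is a negative expectancy wave.
    """
    if registry is None:
        registry = default_registry()

    amps = {  # condition -> (healthy, patient, polarity)
        "plus1": (8.0, 5.0, 1),    # P3cue, temporo-occipital
        "plus2": (6.0, 3.5, -1),   # CNV, parietal, negative
        "nogo": (8.0, 5.0, 1),     # P300 NoGo, central-parietal
        "go": (8.0, 5.5, 1),       # P3b
        "ph": (7.0, 4.5, 1),       # P3a
    }
    topo = {
        "plus1": {"T5": 0.9, "O1": 1.0, "O2": 1.0, "T6": 0.9},
        "plus2": {"P3": 0.9, "Pz": 1.0, "P4": 0.9},
        "nogo": {"C3": 0.8, "Cz": 1.0, "C4": 0.8, "P3": 0.85, "Pz": 0.95, "P4": 0.85},
        "go": {"C3": 0.8, "Cz": 1.0, "C4": 0.8, "P3": 0.85, "Pz": 0.95, "P4": 0.85},
        "ph": {"C3": 0.9, "Cz": 1.0, "C4": 0.9},
    }
    out = []
    for spec in registry:
        if spec.name not in amps:
            raise ConfigError(f"no default component for condition {spec.name!r}")
        a_h, a_p, pol = amps[spec.name]
        out.append(ComponentModel(
            condition=spec.name,
            latency_ms=(spec.interval_start_ms + spec.interval_end_ms) / 2.0,
            width_ms=(spec.interval_end_ms - spec.interval_start_ms) / 4.0,
            topography=topo[spec.name],
            amp_healthy_uv=a_h,
            amp_patient_uv=a_p,
            polarity=pol,
        ))
    return out


def _scaled_mean(comp: ComponentModel, group: str, effect_scale: float) -> float:
    if group == "healthy":
        return comp.amp_healthy_uv
    return comp.amp_healthy_uv + effect_scale * (comp.amp_patient_uv - comp.amp_healthy_uv)


def simulate_subject(group: str,
                     components: list[ComponentModel],
                     cfg: CohortConfig,
                     rng: np.random.Generator,
                     registry: ConditionRegistry | None = None,
                     subject_id: str = "s0",
                     behavior_model: BehaviorModel | None = None) -> SubjectRecord:
    """Draw one subject: component-amplitude draws, noisy waveforms, behavior.

    Waveform per (condition, channel):
    ``polarity * A_subj * weight(ch) * exp(-(t - latency)^2 / (2 width^2)) + eps(t)``
    with one ``A_subj ~ N(group mean, subject_sd_frac * mean)`` per
    component (truncated at 0, shared across that component's channels)
    and i.i.d. Gaussian residual noise.  The trace covers the condition
    interval plus ``cfg.margin_ms`` on each side.  Amplitudes are
    quantized to 1e-6 µV so that CSV round-trips are exact.
    """
    if group not in ("healthy", "schizophrenia"):
        raise ValidationError(f"unknown group {group!r}")
    if registry is None:
        registry = default_registry()
    if behavior_model is None:
        behavior_model = BehaviorModel()
    fs = cfg.sampling_rate_hz

    rec = SubjectRecord(subject_id=subject_id, group=group)
    for comp in components:
        spec = registry[comp.condition]
        mean = _scaled_mean(comp, group, cfg.effect_scale)
        sd = comp.subject_sd_frac * mean
        a_subj = max(0.0, rng.normal(mean, sd)) if sd > 0 else mean

        margin = ms_to_sample(cfg.margin_ms, fs)
        k0 = ms_to_sample(spec.interval_start_ms, fs) - margin
        k1 = ms_to_sample(spec.interval_end_ms, fs) + margin
        t = np.arange(k0, k1) * (1000.0 / fs)  # ms relative to reference stimulus
        bump = np.exp(-((t - comp.latency_ms) ** 2) / (2.0 * comp.width_ms ** 2))
        for ch in spec.channels:
            w = comp.topography.get(ch, 0.0)
            y = comp.polarity * a_subj * w * bump
            if cfg.noise_sd_uv > 0:
                y = y + rng.normal(0.0, cfg.noise_sd_uv, size=y.size)
            rec.erps[(spec.name, ch)] = Waveform(
                samples=np.round(y, 6),
                sampling_rate_hz=fs,
                onset_ms=-k0 * (1000.0 / fs),
            )

    rec.behavior = behavior_model.scaled(cfg.effect_scale).draw(group, rng)
    return rec


def simulate_cohort(cfg: CohortConfig,
                    components: list[ComponentModel] | None = None,
                    registry: ConditionRegistry | None = None,
                    behavior_model: BehaviorModel | None = None) -> ERPDataset:
    """Generate the full cohort: healthy subjects first, then patients.

    Subject ids encode group and index (``h001`` ..., ``p001`` ...).
    Each subject uses an independent substream keyed by (seed, index),
    so a fixed seed gives bit-identical cohorts and early subjects are
    unchanged when counts grow.
    """
    if registry is None:
        registry = default_registry()
    if components is None:
        components = default_components(registry)

    subjects = []
    plan = [("healthy", "h", i) for i in range(cfg.n_healthy)] + \
           [("schizophrenia", "p", i) for i in range(cfg.n_patient)]
    for j, (group, tag, i) in enumerate(plan):
        rng = np.random.default_rng([cfg.seed, j])
        subjects.append(simulate_subject(
            group, components, cfg, rng,
            registry=registry,
            subject_id=f"{tag}{i + 1:03d}",
            behavior_model=behavior_model,
        ))
    ds = ERPDataset(subjects=subjects, registry=registry)
    ds.validate()
    return ds


def simulate_trials(subject: SubjectRecord,
                    n_go: int,
                    n_nogo: int,
                    rng: np.random.Generator) -> list[TrialResponse]:
    """Emit trial-level responses consistent with the subject's summary.

    Go (A-A) trials are missed with probability ``miss_pct/100``;
    otherwise a press occurs at an RT drawn from
    ``N(rt_ms, rt_var/100 * rt_ms)`` clipped into the 200-1000 ms
    validity window.  NoGo (A-P) trials are falsely pressed with
    probability ``false_click_pct/100``.
    """
    if n_go <= 0 or n_nogo <= 0:
        raise ConfigError("trial counts must be positive")
    b = subject.behavior
    if b is None:
        raise ValidationError(f"subject {subject.subject_id} has no behavior summary")
    rt_sd = b.rt_var / 100.0 * b.rt_ms

    def draw_rt() -> float:
        return float(np.clip(rng.normal(b.rt_ms, rt_sd), *RT_VALID_MS))

    trials = []
    for _ in range(n_go):
        if rng.random() < b.miss_pct / 100.0:
            trials.append(TrialResponse(GO_TRIAL, pressed=False))
        else:
            trials.append(TrialResponse(GO_TRIAL, pressed=True, rt_ms=draw_rt()))
    for _ in range(n_nogo):
        if rng.random() < b.false_click_pct / 100.0:
            trials.append(TrialResponse(NOGO_TRIAL, pressed=True, rt_ms=draw_rt()))
        else:
            trials.append(TrialResponse(NOGO_TRIAL, pressed=False))
    return trials
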