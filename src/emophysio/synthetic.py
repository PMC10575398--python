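"""Synthetic session generator.

Produces cohorts of sessions that follow the experiment protocol (baseline,
then per emotion category: image stimulus, rest, autobiographical recall,
rest) with controllable emotion/rest physiological contrast, so the full
pipeline can be exercised without real recordings.

The ECG beat template is a sum of five Gaussians (P, Q, R, S, T) placed at
cumulative RR times; RR variability mixes slow (~0.1 Hz) and fast (~0.25 Hz)
sinusoidal modulation with white jitter.  SCL is a slow tonic drift plus a
bi-exponential phasic response at each trigger.  Artifacts (NaN gaps,
negative dips, ECG spike bursts) are injected at configurable Poisson rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import CATEGORIES, SegmentAnnotation, SignalRecord, TriggerMark

# Empirical 9-point SAM arousal proportions used as the default label prior.
DEFAULT_SAM_WEIGHTS = np.array([24, 26, 34, 29, 51, 41, 31, 19, 11], dtype=float)

# (center offset s, amplitude mV, sigma s) for the P, Q, R, S, T deflections
_BEAT_TEMPLATE = (
    (-0.20, 0.12, 0.030),
    (-0.035, -0.15, 0.012),
    (0.0, 1.00, 0.015),
    (0.035, -0.25, 0.012),
    (0.28, 0.35, 0.060),
)

SCR_TAU_RISE_S = 0.75
SCR_TAU_DECAY_S = 2.0


@dataclass(frozen=True)
class ProtocolSpec:
    """Session timeline: 1 baseline + n_categories x (stimulus, rest, recall, rest)."""

    n_categories: int = 7
    stimulus_s: float = 30.0
    rest_s: float = 60.0
    recall_s: float = 30.0
    baseline_s: float = 30.0
    ecg_fs: float = 1024.0
    eda_fs: float = 32.0

    def __post_init__(self) -> None:
        for name in ("stimulus_s", "rest_s", "recall_s", "baseline_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    @property
    def n_segments(self) -> int:
        return 1 + 4 * self.n_categories

    @property
    def session_s(self) -> float:
        return self.baseline_s + self.n_categories * (
            self.stimulus_s + self.rest_s + self.recall_s + self.rest_s
        )

    def annotations(
        self, categories: Optional[Sequence[str]] = None, sam: Optional[dict] = None
    ) -> list[SegmentAnnotation]:
        """Protocol-aligned annotations tiling [0, session_s) exactly."""
        if categories is None:
            categories = list(CATEGORIES)[: self.n_categories]
        if len(categories) != self.n_categories:
            raise ValueError("need one category name per protocol category")
        out = [SegmentAnnotation(0.0, self.baseline_s, "baseline")]
        t = self.baseline_s
        for cat in categories:
            cat_sam = None if sam is None else sam.get(cat)
            for stage, dur, method in (
                ("stimulus", self.stimulus_s, "image"),
                ("rest", self.rest_s, "none"),
                ("recall", self.recall_s, "recall"),
                ("rest", self.rest_s, "none"),
            ):
                out.append(
                    SegmentAnnotation(
                        t,
                        t + dur,
                        stage,
                        category=cat if stage != "rest" else "none",
                        method=method if stage != "rest" else "none",
                        sam=cat_sam if stage != "rest" else None,
                    )
                )
                t += dur
        return out


@dataclass(frozen=True)
class ArtifactRates:
    """Events per minute for each artifact family."""

    nan_gap_rate: float = 0.0
    negative_rate: float = 0.0
    ecg_spike_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nan_gap_rate", "negative_rate", "ecg_spike_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 19
    emotion_hr_shift: float = 10.0  # bpm added to HR in emotion stages
    emotion_rmssd_scale: float = 0.6  # RR jitter SD multiplier in emotion stages
    scr_amplitude: float = 1.0  # microsiemens
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    arousal_effect: float = 0.3  # max extra HF modulation depth at SAM = 9
    scl_noise_sd: float = 0.01
    rest_rr_mean_range: tuple[float, float] = (750.0, 950.0)
    rest_rr_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.arousal_effect < 0:
            raise ValueError("arousal_effect must be >= 0")


@dataclass
class SubjectSession:
    subject_id: str
    ecg: Optional[SignalRecord]
    scl: Optional[SignalRecord]
    annotations: list[SegmentAnnotation]
    truth: dict


def _beat_waveform(beat_times: np.ndarray, duration_s: float, fs: float) -> np.ndarray:
    n = int(round(duration_s * fs))
    sig = np.zeros(n)
    half = int(round(0.45 * fs))
    tpl_t = np.arange(-half, half + 1) / fs
    tpl = np.zeros_like(tpl_t)
    for center, amp, sigma in _BEAT_TEMPLATE:
        tpl += amp * np.exp(-0.5 * ((tpl_t - center) / sigma) ** 2)
    for bt in beat_times:
        idx = int(round(bt * fs))
        lo, hi = idx - half, idx + half + 1
        s_lo, s_hi = max(lo, 0), min(hi, n)
        if s_lo >= s_hi:
            continue
        sig[s_lo:s_hi] += tpl[s_lo - lo : s_hi - lo]
    return sig


def _rr_sequence(
    duration_s: float,
    rr_mean: float,
    rr_sd: float,
    lf_hf_mix: float,
    rng: np.random.Generator,
    hf_freq: float = 0.25,
) -> np.ndarray:
    """Beat times with sinusoidal LF/HF RR modulation plus white jitter."""
    n_max = int(math.ceil(duration_s / (rr_mean / 1000.0))) + 16
    # deterministic phases per call keep segments reproducible
    phi_lf, phi_hf = rng.uniform(0, 2 * np.pi, size=2)
    beats = [rng.uniform(0, rr_mean / 1000.0)]
    white_sd = rr_sd * math.sqrt(0.2)
    a_lf = rr_sd * math.sqrt(2 * 0.8 * lf_hf_mix)
    a_hf = rr_sd * math.sqrt(2 * 0.8 * (1.0 - lf_hf_mix))
    for _ in range(n_max):
        t = beats[-1]
        rr = (
            rr_mean
            + a_lf * math.sin(2 * np.pi * 0.1 * t + phi_lf)
            + a_hf * math.sin(2 * np.pi * hf_freq * t + phi_hf)
            + (rng.normal(0.0, white_sd) if white_sd > 0 else 0.0)
        )
        rr = max(rr, 250.0)  # physiological floor
        nxt = t + rr / 1000.0
        if nxt >= duration_s - 0.05:
            break
        beats.append(nxt)
    return np.asarray(beats)


def generate_ecg(
    duration_s: float,
    rr_mean: float,
    rr_sd: float,
    lf_hf_mix: float = 0.5,
    fs: float = 1024.0,
    spike_rate: float = 0.0,
    seed: int = 0,
    hf_freq: float = 0.25,
) -> SignalRecord:
    """Synthetic single-lead ECG with Gaussian PQRST beats at cumulative RR times.

    ``spike_rate`` (events/min) injects short high-amplitude bursts (>= 5x the
    R wave) to exercise raw-signal outlier removal.  Beat times are stored in
    ``meta['beat_times']`` as ground truth.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    if not 200.0 <= rr_mean <= 2000.0:
        raise ValueError(f"rr_mean must be in [200, 2000] ms, got {rr_mean}")
    if rr_sd < 0:
        raise ValueError("rr_sd must be >= 0")
    rng = np.random.default_rng(seed)
    beats = _rr_sequence(duration_s, rr_mean, rr_sd, lf_hf_mix, rng, hf_freq=hf_freq)
    sig = _beat_waveform(beats, duration_s, fs)
    sig += rng.normal(0.0, 0.01, size=sig.size)  # mild sensor noise
    spike_times: list[float] = []
    if spike_rate > 0:
        n_spikes = rng.poisson(spike_rate * duration_s / 60.0)
        for _ in range(n_spikes):
            t = rng.uniform(0.0, duration_s)
            width = rng.uniform(0.05, 0.4)
            amp = rng.uniform(5.0, 12.0)
            idx = np.arange(int(t * fs), min(int((t + width) * fs), sig.size))
            if idx.size:
                sig[idx] += amp
                spike_times.append(t)
    return SignalRecord(
        values=sig,
        fs=fs,
        channel="ecg",
        units="mV",
        meta={"beat_times": beats, "spike_times": np.asarray(spike_times)},
    )


def scr_kernel(t: np.ndarray) -> np.ndarray:
    """Bi-exponential (fast-rise, slow-decay) skin-conductance response shape.

    Normalized to unit peak so the caller's amplitude is the response peak.
    """
    t = np.asarray(t, dtype=float)
    h = np.where(
        t >= 0,
        np.exp(-np.clip(t, 0, None) / SCR_TAU_DECAY_S)
        - np.exp(-np.clip(t, 0, None) / SCR_TAU_RISE_S),
        0.0,
    )
    t_peak = (
        math.log(SCR_TAU_DECAY_S / SCR_TAU_RISE_S)
        / (1.0 / SCR_TAU_RISE_S - 1.0 / SCR_TAU_DECAY_S)
    )
    peak = math.exp(-t_peak / SCR_TAU_DECAY_S) - math.exp(-t_peak / SCR_TAU_RISE_S)
    return h / peak


def generate_scl(
    protocol: ProtocolSpec,
    trigger_times: Sequence[float],
    scr_amplitude: float = 1.0,
    artifact_rates: ArtifactRates = ArtifactRates(),
    seed: int = 0,
    noise_sd: float = 0.01,
    duration_s: Optional[float] = None,
) -> SignalRecord:
    """Tonic drift (2-20 uS) + phasic SCR at each trigger + optional artifacts."""
    duration = protocol.session_s if duration_s is None else duration_s
    trigger_times = np.asarray(sorted(trigger_times), dtype=float)
    if trigger_times.size and (
        trigger_times[0] < 0 or trigger_times[-1] >= duration
    ):
        raise ValueError("trigger outside session span")
    fs = protocol.eda_fs
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    base = rng.uniform(3.0, 18.0)
    drift = 0.5 * np.sin(2 * np.pi * t / rng.uniform(200.0, 400.0) + rng.uniform(0, 2 * np.pi))
    tonic = base + drift + 0.3 * np.sin(2 * np.pi * t / rng.uniform(500.0, 900.0))
    phasic = np.zeros(n)
    for tt in trigger_times:
        phasic += scr_amplitude * scr_kernel(t - tt)
    sig = tonic + phasic
    if noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, size=n)
    # artifacts
    nan_mask = np.zeros(n, dtype=bool)
    n_gaps = rng.poisson(artifact_rates.nan_gap_rate * duration / 60.0)
    for _ in range(n_gaps):
        start = rng.uniform(1.0, duration - 4.0)
        width = rng.uniform(0.5, 3.0)
        i0, i1 = int(start * fs), min(int((start + width) * fs), n)
        nan_mask[i0:i1] = True
    n_neg = rng.poisson(artifact_rates.negative_rate * duration / 60.0)
    for _ in range(n_neg):
        start = rng.uniform(0.0, duration - 1.0)
        width = rng.uniform(0.1, 0.5)
        i0, i1 = int(start * fs), min(int((start + width) * fs), n)
        sig[i0:i1] -= base + 5.0
    sig[nan_mask] = np.nan
    return SignalRecord(
        values=sig,
        fs=fs,
        channel="scl",
        units="uS",
        meta={"trigger_times": trigger_times, "tonic_base": base},
    )


def _sam_draw(rng: np.random.Generator, weights: np.ndarray) -> int:
    p = weights / weights.sum()
    return int(rng.choice(np.arange(1, 10), p=p))


def generate_cohort(
    cohort: CohortConfig,
    protocol: ProtocolSpec = ProtocolSpec(),
    signals: bool = True,
    sam_weights: Optional[np.ndarray] = None,
) -> list[SubjectSession]:
    """Generate ``cohort.n_subjects`` protocol-structured sessions.

    Emotion/recall stages carry an HR elevated by ``emotion_hr_shift`` bpm and
    RR jitter scaled by ``emotion_rmssd_scale`` relative to the subject's rest
    values.  SAM arousal labels are drawn per category from ``sam_weights``
    (default: empirical 9-point proportions) and stored as ground truth.  With
    ``signals=False`` only annotations and truth are produced (fast path for
    dataset bookkeeping).
    """
    weights = DEFAULT_SAM_WEIGHTS if sam_weights is None else np.asarray(sam_weights, float)
    root = np.random.SeedSequence(cohort.seed)
    sessions: list[SubjectSession] = []
    categories = list(CATEGORIES)[: protocol.n_categories]
    if protocol.n_categories > len(CATEGORIES):
        categories = [f"cat{i}" for i in range(protocol.n_categories)]
    for subj, child in enumerate(root.spawn(cohort.n_subjects)):
        rng = np.random.default_rng(child)
        sam = {cat: _sam_draw(rng, weights) for cat in categories}
        annotations = protocol.annotations(categories, sam=sam)
        trigger_times = np.array([a.start_s for a in annotations])
        rr_rest = rng.uniform(*cohort.rest_rr_mean_range)
        hr_rest = 60000.0 / rr_rest
        rr_emotion = 60000.0 / (hr_rest + cohort.emotion_hr_shift)
        truth: dict = {
            "trigger_times": trigger_times,
            "sam": dict(sam),
            "rr_rest_ms": rr_rest,
            "rr_emotion_ms": rr_emotion,
            "stage_rr_mean": {},
        }
        ecg = scl = None
        if signals:
            seg_sigs = []
            seg_rng = np.random.default_rng(child.spawn(1)[0])
            for k, ann in enumerate(annotations):
                emo = ann.is_emotion
                rr_mean = rr_emotion if emo else rr_rest
                rr_sd = cohort.rest_rr_sd * (cohort.emotion_rmssd_scale if emo else 1.0)
                depth = 0.0
                if emo and ann.sam is not None:
                    depth = cohort.arousal_effect * (ann.sam - 1) / 8.0
                rec = generate_ecg(
                    ann.duration_s,
                    rr_mean,
                    rr_sd,
                    lf_hf_mix=max(0.5 - depth, 0.05),
                    fs=protocol.ecg_fs,
                    spike_rate=cohort.artifact_rates.ecg_spike_rate,
                    seed=int(seg_rng.integers(0, 2**31)),
                )
                seg_sigs.append(rec.values)
                beats = rec.meta["beat_times"]
                if beats.size >= 2:
                    truth["stage_rr_mean"][k] = float(np.mean(np.diff(beats)) * 1000.0)
            ecg = SignalRecord(
                values=np.concatenate(seg_sigs),
                fs=protocol.ecg_fs,
                channel="ecg",
                units="mV",
                meta={"subject": subj},
            )
            scl = generate_scl(
                protocol,
                trigger_times,
                scr_amplitude=cohort.scr_amplitude,
                artifact_rates=cohort.artifact_rates,
                seed=int(np.random.default_rng(child.spawn(2)[1]).integers(0, 2**31)),
                noise_sd=cohort.scl_noise_sd,
            )
        sessions.append(
            SubjectSession(
                subject_id=f"S{subj:02d}",
                ecg=ecg,
                scl=scl,
                annotations=annotations,
                truth=truth,
            )
        )
    return sessions


def truth_triggers(session: SubjectSession) -> list[TriggerMark]:
    return [TriggerMark(float(t), "ground_truth") for t in session.truth["trigger_times"]]
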