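"""Synthetic MEP cohorts: waveforms, rater panels and EDSS trajectories.

Everything downstream of data acquisition — feature extraction, consensus
labelling, agreement statistics, screening, clinical association — is
testable against this module because the ground truth is retained.

The generative story:

* Every trace carries a latent morphological-abnormality score ``z`` in
  [0, 1].  Morphology is treated as continuous; raters dichotomise it.
* ``z = 0`` produces a clean biphasic response (one positive and one
  negative lobe); increasing ``z`` adds oscillatory components (Gabor
  atoms) that are more numerous, faster and more temporally dispersed —
  the polyphasia/dispersion picture of abnormal MEP morphology.
* A simulated rater has a personal threshold ``tau`` and labels a trace
  abnormal when ``z + noise > tau``: raters agree on the concept and
  differ in the cut-point.
* Foot (AH) traces carry a higher abnormality offset than hand (APB)
  traces, and the patient-level abnormality drives both the baseline
  EDSS and the probability of 2-year disability progression, with the
  foot association the stronger one.

All randomness flows from one root seed through ``numpy`` SeedSequence
spawning, so identical seeds reproduce identical cohorts byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import MepTrace

__all__ = [
    "WaveformConfig",
    "RaterSpec",
    "SyntheticCohort",
    "default_rater_panel",
    "generate_trace",
    "simulate_rater_labels",
    "generate_cohort",
]


@dataclass(frozen=True)
class WaveformConfig:
    """Acquisition-like parameters of the waveform generator.

    Defaults mimic the clinical recording protocol: 100 ms of signal at
    19.2 kHz (1920 samples), hand responses starting around 18-28 ms
    after the stimulus and foot responses around 35-50 ms, and
    peak amplitudes of a few hundred uV up to about a millivolt.
    """

    n_samples: int = 1920
    sampling_rate: float = 19.2  # kHz
    baseline_noise_sd: float = 4.0  # uV
    stimulus_artifact_window: float = 5.0  # ms
    onset_latency_range_hand: tuple[float, float] = (18.0, 28.0)  # ms
    onset_latency_range_foot: tuple[float, float] = (35.0, 50.0)  # ms
    base_amplitude_range: tuple[float, float] = (300.0, 1200.0)  # uV
    k_max: int = 6  # extra components at z = 1
    dispersion_noise_frac: float = 0.25  # desynchronised-activity amplitude at z = 1, x base amplitude

    def __post_init__(self) -> None:
        if self.n_samples < 64:
            raise ValueError(f"n_samples must be >= 64, got {self.n_samples}")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be >= 0")
        for name in ("onset_latency_range_hand", "onset_latency_range_foot", "base_amplitude_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must have lower <= upper, got ({lo}, {hi})")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    def onset_range(self, limb_class: str) -> tuple[float, float]:
        if limb_class == "hand":
            return self.onset_latency_range_hand
        if limb_class == "foot":
            return self.onset_latency_range_foot
        raise ValueError(f"limb_class must be 'hand' or 'foot', got {limb_class!r}")


@dataclass(frozen=True)
class RaterSpec:
    """One simulated annotator.

    ``threshold`` is the point on the latent abnormality scale above
    which the rater calls a trace abnormal; ``decision_noise_sd`` blurs
    that decision trace by trace; ``bad_data_prob`` is the chance of
    flagging a trace as unusable; ``repeat_noise_sd`` is the decision
    noise on a second, independent labelling pass of the same trace.
    """

    rater_id: str
    threshold: float = 0.5
    decision_noise_sd: float = 0.05
    bad_data_prob: float = 0.0
    repeat_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if not 0.0 <= self.bad_data_prob <= 1.0:
            raise ValueError(f"bad_data_prob must be in [0, 1], got {self.bad_data_prob}")
        if self.decision_noise_sd < 0 or self.repeat_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def default_rater_panel(
    thresholds: Sequence[float] = (0.40, 0.45, 0.50, 0.55, 0.60),
    decision_noise_sd: float = 0.05,
    bad_data_prob: float = 0.0055,
    repeat_noise_sd: float = 0.05,
) -> list[RaterSpec]:
    """Five raters with spread thresholds centred on 0.5.

    The spread reproduces the study condition that annotators share the
    concept of morphology but differ in their cut-point; together with
    the ~1% artifact traces, the per-rater bad-data probability makes
    roughly 3.5% of traces carry at least one bad flag across the panel.
    """
    return [
        RaterSpec(f"N{i + 1}", t, decision_noise_sd, bad_data_prob, repeat_noise_sd)
        for i, t in enumerate(thresholds)
    ]


def _check_z(z: float) -> float:
    z = float(z)
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"latent abnormality z must be in [0, 1], got {z}")
    return z


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_trace(
    z: float,
    limb_class: str,
    config: WaveformConfig = WaveformConfig(),
    rng_seed=0,
    *,
    trace_id: str = "trace",
    patient_id: str = "p0",
    visit_id: str = "v0",
    side: str = "L",
    excitation_pct: float = 60.0,
) -> tuple[MepTrace, dict]:
    """One synthetic MEP trace plus its ground-truth annotations.

    The response is zero before the drawn onset latency.  At the onset a
    main biphasic deflection (one full sine period over 7-11 ms) begins;
    ``K - 1`` additional Gabor atoms follow, where
    ``K = 1 + round(z * k_max)``.  Their temporal spread (4 + 36 z ms),
    frequency band (80 Hz up to 200 + 600 z Hz) and count all grow
    linearly with ``z``, and a noise-like desynchronised-activity term
    (amplitude ``dispersion_noise_frac * z`` of the base amplitude,
    enveloped over the dispersed window) models the jagged fluctuation
    of temporally dispersed motor-unit potentials — so polyphasia,
    dispersion and hence ApEn increase monotonically with the latent
    score.  Gaussian baseline noise is added throughout.

    Returns ``(trace, truth)`` where ``truth`` records z, onset (ms),
    amplitude (uV) and component count.
    """
    z = _check_z(z)
    rng = _rng(rng_seed)
    onset_lo, onset_hi = config.onset_range(limb_class)
    fs = config.sampling_rate  # samples per ms
    t = np.arange(config.n_samples) / fs  # ms

    onset = rng.uniform(onset_lo, onset_hi)
    amplitude = rng.uniform(*config.base_amplitude_range)
    period = rng.uniform(7.0, 11.0)  # ms, duration of the main biphasic deflection
    k_extra = int(np.floor(z * config.k_max + 0.5))

    y = np.zeros_like(t)
    in_main = (t >= onset) & (t <= onset + period)
    y[in_main] = amplitude * np.sin(2.0 * np.pi * (t[in_main] - onset) / period)

    dispersion = 4.0 + 36.0 * z  # ms over which extra components scatter
    f_hi = 200.0 + 600.0 * z  # Hz
    for _ in range(k_extra):
        t_c = onset + 2.0 + rng.uniform(0.0, dispersion)
        f_k = rng.uniform(80.0, f_hi)
        sigma_k = rng.uniform(0.8, 2.0)
        a_k = amplitude * rng.uniform(0.3, 0.9)
        phi_k = rng.uniform(0.0, 2.0 * np.pi)
        y += a_k * np.exp(-0.5 * ((t - t_c) / sigma_k) ** 2) * np.sin(
            2.0 * np.pi * f_k * (t - t_c) / 1000.0 + phi_k
        )

    if z > 0 and config.dispersion_noise_frac > 0:
        # desynchronised motor-unit activity: noise-like fluctuation under
        # a Gaussian envelope spanning the dispersed response window
        env = np.exp(-0.5 * ((t - (onset + 2.0 + dispersion / 2.0)) / (dispersion / 2.0)) ** 2)
        env[t < onset] = 0.0
        y += config.dispersion_noise_frac * z * amplitude * env * rng.standard_normal(t.size)

    y[t < onset] = 0.0
    if config.baseline_noise_sd > 0:
        y = y + rng.normal(0.0, config.baseline_noise_sd, size=y.shape)

    trace = MepTrace(
        trace_id=trace_id,
        patient_id=patient_id,
        visit_id=visit_id,
        limb="APB" if limb_class == "hand" else "AH",
        side=side,
        excitation_pct=excitation_pct,
        sampling_rate=config.sampling_rate,
        samples=y,
    )
    truth = {
        "z": z,
        "onset_ms": float(onset),
        "amplitude_uv": float(amplitude),
        "n_components": 1 + k_extra,
        "limb_class": limb_class,
    }
    return trace, truth


def _artifact_trace(kind: str, config: WaveformConfig, rng: np.random.Generator) -> np.ndarray:
    """Unusable recordings: a dead channel or a clipped stimulus artifact."""
    n = config.n_samples
    if kind == "flat":
        return rng.normal(0.0, 0.5, size=n)
    # clipped: a huge low-frequency swing saturating the amplifier
    t = np.arange(n) / config.sampling_rate
    swing = 5000.0 * np.sin(2.0 * np.pi * t / rng.uniform(40.0, 80.0))
    clip = 2000.0
    return np.clip(swing, -clip, clip) + rng.normal(0.0, 2.0, size=n)


def simulate_rater_labels(
    z_values,
    raters: Sequence[RaterSpec],
    rng_seed=0,
    *,
    trace_ids: Optional[Sequence[str]] = None,
    repeat_indices: Sequence[int] = (),
) -> pd.DataFrame:
    """Label table (trace_id, rater_id, session, label) for a rater panel.

    Rater ``j`` labels a trace abnormal iff ``z + eps > tau_j`` with
    ``eps ~ N(0, decision_noise_sd)`` drawn independently per trace, or
    emits ``bad`` with probability ``bad_data_prob``.  Traces listed in
    ``repeat_indices`` are labelled a second time with fresh noise of SD
    ``repeat_noise_sd`` (session ``repeat``), mirroring the repeat
    labelling pass used to measure intra-rater reliability.
    """
    z = np.asarray(list(z_values), dtype=float)
    if z.size and (z.min() < 0 or z.max() > 1):
        raise ValueError("all z values must lie in [0, 1]")
    if len(raters) == 0:
        raise ValueError("at least one rater is required")
    if trace_ids is None:
        trace_ids = [f"t{i:05d}" for i in range(z.size)]
    trace_ids = list(trace_ids)
    rng = _rng(rng_seed)
    rows: list[tuple[str, str, str, str]] = []
    for rater in raters:
        for session, noise_sd, indices in (
            ("primary", rater.decision_noise_sd, range(z.size)),
            ("repeat", rater.repeat_noise_sd, repeat_indices),
        ):
            for i in indices:
                if rng.uniform() < rater.bad_data_prob:
                    label = "bad"
                else:
                    eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    label = "abnormal" if z[i] + eps > rater.threshold else "normal"
                rows.append((trace_ids[i], rater.rater_id, session, label))
    return pd.DataFrame(rows, columns=["trace_id", "rater_id", "session", "label"])


@dataclass
class CohortConfig:
    """Population-level knobs of the synthetic cohort.

    The latent patient abnormality is Beta-distributed and skewed low so
    that, against a rater panel centred on 0.5, roughly three quarters
    of traces are labelled normal — the class imbalance of the rated
    clinical sample.  Foot traces sit ``limb_offset`` above and hand
    traces the same amount below the patient level, reflecting the
    longer peripheral conduction path of the foot muscle; on top of
    that, a per-patient foot-specific component (``foot_specific_sd``)
    models independently varying leg-tract involvement, which is what
    makes the foot traces the better disability predictor.
    """

    beta_a: float = 1.3
    beta_b: float = 2.6
    limb_offset: float = 0.06
    foot_specific_sd: float = 0.15
    trace_noise_sd: float = 0.12
    artifact_prob: float = 0.01
    repeat_visits: int = 25
    progression_fraction: float = 0.2
    edss_noise_sd: float = 0.7
    visits_per_patient: int = 1


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth.

    ``traces`` holds the retained (max peak-to-peak) trace per limb/side;
    ``truth`` one row per trace (z, onset, amplitude, components,
    artifact flag); ``labels`` the simulated rater panel's label table;
    ``visits`` visit dates; ``edss`` dated EDSS records (baseline and
    ~2-year follow-up); ``patients`` patient-level ground truth including
    the progression flag.
    """

    traces: list[MepTrace]
    truth: pd.DataFrame
    labels: pd.DataFrame
    visits: pd.DataFrame
    edss: pd.DataFrame
    patients: pd.DataFrame
    raters: list[RaterSpec] = field(default_factory=list)

    def trace_by_id(self, trace_id: str) -> MepTrace:
        for tr in self.traces:
            if tr.trace_id == trace_id:
                return tr
        raise KeyError(trace_id)


def _round_half(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x) * 2.0) / 2.0


def generate_cohort(
    n_patients: int,
    raters: Optional[Sequence[RaterSpec]] = None,
    config: WaveformConfig = WaveformConfig(),
    rng_seed=0,
    cohort: CohortConfig = CohortConfig(),
) -> SyntheticCohort:
    """Patients, visits, traces, rater labels and EDSS with ground truth.

    Each visit contributes four traces (hand/foot x left/right).  The
    patient-level abnormality drives the per-trace z, the baseline EDSS
    (through the mean foot z, more weakly through the hands) and the
    probability of meeting the 2-year progression rule; the configured
    ``progression_fraction`` of patients progresses on average.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if raters is None:
        raters = default_rater_panel()
    root = np.random.SeedSequence(
        rng_seed.entropy if isinstance(rng_seed, np.random.SeedSequence) else rng_seed
    )
    ss_struct, ss_waves, ss_labels, ss_edss = root.spawn(4)
    rng = np.random.default_rng(ss_struct)
    wave_rng = np.random.default_rng(ss_waves)
    edss_rng = np.random.default_rng(ss_edss)

    b = rng.beta(cohort.beta_a, cohort.beta_b, size=n_patients)
    foot_extra = rng.normal(0.0, cohort.foot_specific_sd, size=n_patients)

    traces: list[MepTrace] = []
    truth_rows = []
    visit_rows = []
    z_list: list[float] = []
    trace_ids: list[str] = []
    epoch = date(2018, 1, 1)

    for p in range(n_patients):
        patient_id = f"P{p:04d}"
        date0 = epoch + timedelta(days=int(rng.integers(0, 730)))
        for v in range(cohort.visits_per_patient):
            visit_id = f"{patient_id}_V{v}"
            visit_date = date0 + timedelta(days=365 * v)
            visit_rows.append((visit_id, patient_id, visit_date.isoformat()))
            for limb_class, limb in (("hand", "APB"), ("foot", "AH")):
                for side in ("L", "R"):
                    offset = (
                        cohort.limb_offset + foot_extra[p]
                        if limb_class == "foot"
                        else -cohort.limb_offset
                    )
                    z = float(np.clip(b[p] + offset + rng.normal(0.0, cohort.trace_noise_sd), 0.0, 1.0))
                    trace_id = f"{visit_id}_{limb}_{side}"
                    is_artifact = rng.uniform() < cohort.artifact_prob
                    tr, tru = generate_trace(
                        z,
                        limb_class,
                        config,
                        wave_rng,
                        trace_id=trace_id,
                        patient_id=patient_id,
                        visit_id=visit_id,
                        side=side,
                    )
                    if is_artifact:
                        kind = "flat" if rng.uniform() < 0.5 else "clipped"
                        tr = replace(tr, samples=_artifact_trace(kind, config, wave_rng))
                        tru["artifact"] = kind
                    else:
                        tru["artifact"] = ""
                    traces.append(tr)
                    truth_rows.append(
                        {
                            "trace_id": trace_id,
                            "patient_id": patient_id,
                            "visit_id": visit_id,
                            "limb": limb,
                            "side": side,
                            **tru,
                        }
                    )
                    z_list.append(z)
                    trace_ids.append(trace_id)

    truth = pd.DataFrame(truth_rows)
    visits = pd.DataFrame(visit_rows, columns=["visit_id", "patient_id", "date"])

    # Rater labels: artifact traces are flagged bad by everyone (a dead
    # channel is unmistakable); ordinary traces get thresholded labels.
    repeat_visit_ids = list(visits["visit_id"].iloc[: min(cohort.repeat_visits, len(visits))])
    repeat_idx = [i for i, row in enumerate(truth_rows) if row["visit_id"] in set(repeat_visit_ids)]
    labels = simulate_rater_labels(
        z_list,
        raters,
        np.random.default_rng(ss_labels),
        trace_ids=trace_ids,
        repeat_indices=repeat_idx,
    )
    artifact_ids = set(truth.loc[truth["artifact"] != "", "trace_id"])
    if artifact_ids:
        labels.loc[labels["trace_id"].isin(artifact_ids), "label"] = "bad"

    # EDSS: baseline driven mostly by foot abnormality, follow-up at ~2
    # years meeting the progression rule for the configured fraction.
    foot_z = truth[truth["limb"] == "AH"].groupby("patient_id")["z"].mean()
    edss_rows = []
    patient_rows = []
    mfz_all = foot_z.reindex([f"P{p:04d}" for p in range(n_patients)]).to_numpy()
    weights = (0.15 + 0.85 * mfz_all) ** 2  # risk rises steeply with foot abnormality
    p_prog = np.clip(weights / weights.mean() * cohort.progression_fraction, 0.0, 0.95)
    for p in range(n_patients):
        patient_id = f"P{p:04d}"
        date0 = date.fromisoformat(visits.loc[visits["patient_id"] == patient_id, "date"].iloc[0])
        mfz = float(foot_z[patient_id])
        edss0 = float(np.clip(_round_half(7.5 * mfz + edss_rng.normal(0.0, cohort.edss_noise_sd)), 0.0, 7.5))
        progressed = bool(edss_rng.uniform() < p_prog[p])
        required = 1.0 if edss0 <= 5.5 else 0.5
        if progressed:
            delta = required + 0.5 * edss_rng.integers(0, 2)
        else:
            delta = 0.5 * edss_rng.integers(-1, 2)  # -0.5, 0 or +0.5
            if delta >= required:
                delta = required - 0.5
        edss1 = float(np.clip(edss0 + delta, 0.0, 10.0))
        if progressed and edss1 - edss0 < required:  # clipped at the top of the scale
            edss0 = max(0.0, edss1 - required)
        t0_off = int(edss_rng.integers(-60, 61))
        t1_off = int(edss_rng.integers(580, 1020))
        edss_rows.append((patient_id, (date0 + timedelta(days=t0_off)).isoformat(), edss0))
        edss_rows.append((patient_id, (date0 + timedelta(days=t1_off)).isoformat(), edss1))
        patient_rows.append(
            {
                "patient_id": patient_id,
                "latent_abnormality": float(b[p]),
                "mean_foot_z": mfz,
                "edss_t0": edss0,
                "edss_t1": edss1,
                "progressed": progressed,
            }
        )

    edss = pd.DataFrame(edss_rows, columns=["patient_id", "date", "edss"])
    patients = pd.DataFrame(patient_rows)
    return SyntheticCohort(traces, truth, labels, visits, edss, patients, list(raters))
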