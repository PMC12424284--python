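"""Ground-truthed synthetic inputs for every pipeline stage.

Three layers:

* signal-level oracles (`gen_ar1_series`, `gen_powerlaw_series`,
  `gen_coupled_blocks`) with closed-form or construction-level ground
  truth for the estimators;
* a belt-waveform generator (`gen_breathing_signal`) that plants
  per-breath rates and amplitudes and renders them as a smooth
  quasi-periodic displacement trace plus white noise;
* a cohort generator (`gen_cohort`) that emulates a two-site rest/task
  study: per-subject AR(1)-modulated rate and amplitude series with
  planted rest-to-task shifts (faster, shallower, more variable, more
  entropic breathing under task), anxiety items coupled to a per-subject
  entropy latent, and N-back behavior coupled negatively to a per-subject
  variability latent.

Every generator is a deterministic function of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AnxietyRecord, BehaviorTrial, BreathRecording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary series generators (estimator oracles)

def gen_ar1_series(phi: float, n: int, seed: int | None = None) -> np.ndarray:
    """Stationary AR(1): x_t = phi*x_{t-1} + eps_t with unit-SD innovations."""
    if not abs(phi) < 1:
        raise ValueError("|phi| must be < 1")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0] / np.sqrt(1 - phi ** 2)  # marginal stationary draw
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def gen_powerlaw_series(beta: float, n: int, seed: int | None = None) -> np.ndarray:
    """Spectral synthesis of 1/f^beta noise, normalized to unit variance.

    Fourier amplitudes are proportional to f^(-beta/2) with uniform random
    phases; beta=0 is white noise.
    """
    if not 0 <= beta <= 3:
        raise ValueError("beta must be in [0, 3]")
    if n < 64:
        raise ValueError("need n >= 64")
    rng = np.random.default_rng(seed)
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-beta / 2.0)
    phase = rng.uniform(0, 2 * np.pi, size=f.size)
    spec = amp * np.exp(1j * phase)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    return x / x.std()


def gen_coupled_blocks(
    n: int,
    p: int,
    q: int,
    saliences: list[tuple[np.ndarray, np.ndarray]],
    strengths: list[float],
    noise_sd: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two blocks sharing latent factors with known saliences.

    X = sum_k strength_k * z_k * a_k' + noise, Y likewise with b_k; the
    z_k are iid standard normal latent scores. Salience vectors must be
    unit-norm and mutually orthogonal within each block.
    """
    rng = np.random.default_rng(seed)
    A = np.stack([a for a, _ in saliences])  # K x p
    B = np.stack([b for _, b in saliences])  # K x q
    for M, dim in ((A, p), (B, q)):
        if M.shape[1] != dim:
            raise ValueError("salience vector length mismatch")
        G = M @ M.T
        if not np.allclose(G, np.eye(M.shape[0]), atol=1e-8):
            raise ValueError("salience vectors must be unit-norm and orthogonal")
    Z = rng.standard_normal((n, len(saliences)))
    S = np.diag(strengths)
    X = Z @ S @ A + noise_sd * rng.standard_normal((n, p))
    Y = Z @ S @ B + noise_sd * rng.standard_normal((n, q))
    truth = {"latent_scores": Z, "x_saliences": A.T, "y_saliences": B.T,
             "strengths": np.asarray(strengths, float)}
    return X, Y, truth


# ---------------------------------------------------------------------------
# waveform construction

def waveform_from_breaths(
    rates: np.ndarray,
    amplitudes: np.ndarray,
    fs: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    trough_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Render planted per-breath rates/amplitudes as a belt-like trace.

    Breath i spans 60/rates[i] seconds peak-to-peak; troughs sit at a
    fixed fraction of each interval at displacement 0, peaks at the
    planted amplitude. Segments between consecutive extrema are raised-
    cosine arcs (zero slope at every extremum), so extrema locations are
    exact up to sample quantization. Returns (samples, peak_times).
    """
    rates = np.asarray(rates, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if rates.size != amplitudes.size:
        raise ValueError("rates and amplitudes must have equal length")
    if np.any(rates <= 0) or np.any(amplitudes <= 0):
        raise ValueError("rates and amplitudes must be positive")
    durations = 60.0 / rates
    # peak i at cumulative time; leading/trailing half-cycles close the trace
    peak_times = durations[0] / 2 + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    knot_t = [0.0]
    knot_v = [0.0]
    for i, tp in enumerate(peak_times):
        knot_t.append(tp)
        knot_v.append(amplitudes[i])
        if i < peak_times.size - 1:
            knot_t.append(tp + trough_frac * durations[i])
        else:
            knot_t.append(tp + durations[i] / 2)
        knot_v.append(0.0)
    kt = np.asarray(knot_t)
    kv = np.asarray(knot_v)
    n = int(np.ceil(kt[-1] * fs)) + 1
    t = np.arange(n) / fs
    seg = np.clip(np.searchsorted(kt, t, side="right") - 1, 0, kt.size - 2)
    phase = (t - kt[seg]) / (kt[seg + 1] - kt[seg])
    x = kv[seg] + (kv[seg + 1] - kv[seg]) * 0.5 * (1 - np.cos(np.pi * np.clip(phase, 0, 1)))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        x = x + noise_sd * rng.standard_normal(x.size)
    return x, peak_times


# ---------------------------------------------------------------------------
# cohort specification

@dataclass
class ConditionParams:
    """Generative parameters of one recording condition.

    Both the per-breath rate (bpm) and log-amplitude series follow
    base + sinusoidal slow modulation + AR(1) + white jitter. Resting
    breathing is rendered as a slowly modulated quasi-periodic rhythm
    (sine-dominated, little jitter: long timescales, low entropy at
    every coarse-graining scale); task breathing as a high-variance
    near-white AR(1) (short timescales, high entropy and complexity).
    """

    base_rate: float              # breaths/min
    amp_mean: float               # median breath amplitude, a.u.
    duration: float               # seconds
    # rate series structure (bpm units)
    rate_mod_amp: float = 0.0     # sine modulation amplitude
    rate_mod_period: float = 15.0  # modulation period, breaths
    rate_white_sd: float = 0.0    # white jitter SD
    rate_phi: float = 0.0         # AR(1) coefficient
    rate_ar_sd: float = 0.0       # marginal SD of the AR(1) component
    # log-amplitude series structure (log a.u.)
    amp_mod: float = 0.0
    amp_mod_period: float = 15.0
    amp_white_sd: float = 0.0
    amp_phi: float = 0.0
    amp_ar_sd: float = 0.0
    noise_sd: float = 0.05        # white waveform noise, a.u.
    fs: float = 10.0

    def __post_init__(self) -> None:
        sds = (self.rate_white_sd, self.rate_ar_sd, self.amp_white_sd,
               self.amp_ar_sd, self.noise_sd)
        if min(sds) < 0:
            raise ValueError("SDs must be >= 0")
        for phi in (self.rate_phi, self.amp_phi):
            if not 0 <= phi < 1:
                raise ValueError("AR(1) coefficients must be in [0, 1)")
        if self.duration < 120:
            raise ValueError("duration must be >= 120 s")


@dataclass
class SiteParams:
    label: str
    amp_gain: float = 1.0     # multiplicative belt-gain offset
    rate_offset: float = 0.0  # additive bpm offset


#: rest-to-task shifts planted by the default cohort, as the expected sign
#: of the paired-t statistic on diff = rest - task (negative: task higher)
PLANTED_SIGNS = {
    "mean_rate": -1, "mean_amp": +1,
    "sd_rate": -1, "cv_amp": -1,
    "acw50_rate": +1, "acw50_amp": +1,
    "psd_slope_rate": +1,
    "lzc_rate": -1, "lzc_amp": -1,
    "mse_rate": -1, "mse_amp": -1,
    "sampen_rate": -1,
}


def default_rest_params() -> ConditionParams:
    """Rest: 14 bpm quasi-periodic rhythm, slow (~15-breath) rate and
    amplitude modulation with mild white jitter, 5-minute recording."""
    return ConditionParams(
        base_rate=14.0, amp_mean=1.0, duration=300.0,
        rate_mod_amp=1.4, rate_mod_period=15.0, rate_white_sd=0.30,
        amp_mod=0.18, amp_mod_period=15.0, amp_white_sd=0.08,
    )


def default_task_params() -> ConditionParams:
    """Task: 17 bpm, shallower (0.7 a.u.) and more variable breathing as
    a near-white AR(1), 30-minute recording."""
    return ConditionParams(
        base_rate=17.0, amp_mean=0.70, duration=1800.0,
        rate_phi=0.20, rate_ar_sd=2.0,
        amp_phi=0.30, amp_ar_sd=0.25,
    )


@dataclass
class SyntheticCohortSpec:
    """Study design emulation: sample sizes, condition shifts, couplings."""

    n_subjects: int = 51
    sites: list[SiteParams] = field(default_factory=lambda: [
        SiteParams("siteA", amp_gain=1.0, rate_offset=0.0),
        SiteParams("siteB", amp_gain=1.6, rate_offset=0.8),
    ])
    rest: ConditionParams = field(default_factory=default_rest_params)
    task: ConditionParams = field(default_factory=default_task_params)
    include_task: bool = True
    # between-subject heterogeneity
    subj_rate_sd: float = 1.0        # SD of per-subject base-rate offset, bpm
    subj_amp_log_sd: float = 0.15    # SD of per-subject log amplitude gain
    entropy_white_slope: float = 0.35   # rest white-jitter log-multiplier per unit latent
    variability_log_slope: float = 0.35  # task rate-SD log-multiplier per unit latent
    # outcome couplings
    bai_entropy_rho: float = 0.6     # corr of BAI latent with entropy latent
    eff_variability_beta: float = 0.5  # logit-accuracy drop per unit variability latent
    eff_rt_beta: float = 0.15        # log-RT increase per unit variability latent
    trials_per_cell: int = 80        # per subject x load x speed
    seed: int = 0


@dataclass
class RecordingTruth:
    peak_times: np.ndarray
    rates: np.ndarray
    amplitudes: np.ndarray
    rate_phi: float
    amp_phi: float
    n_clipped: int


@dataclass
class GroundTruth:
    """Planted values every downstream stage is validated against."""

    recordings: dict[tuple[str, str], RecordingTruth]
    expected_signs: dict[str, int]
    entropy_latent: np.ndarray       # per subject, drives rest entropy & BAI
    variability_latent: np.ndarray   # per subject, drives task SD/CV & efficiency
    subjects: list[str]


@dataclass
class CohortBundle:
    recordings: list[BreathRecording]
    anxiety: list[AnxietyRecord]
    behavior: list[BehaviorTrial]
    truth: GroundTruth


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with marginal SD sd."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1 - phi ** 2)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    eps = rng.normal(0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def _structured_series(
    n: int,
    mod_amp: float,
    mod_period: float,
    white_sd: float,
    phi: float,
    ar_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean series: sine modulation + AR(1) + white jitter."""
    x = np.zeros(n)
    if mod_amp > 0:
        period = max(4.0, mod_period + rng.normal(0, 0.15 * mod_period))
        phase = rng.uniform(0, 2 * np.pi)
        x += mod_amp * np.sin(2 * np.pi * np.arange(n) / period + phase)
    if ar_sd > 0:
        x += _ar1(n, phi, ar_sd, rng)
    if white_sd > 0:
        x += white_sd * rng.standard_normal(n)
    return x


def gen_breathing_signal(
    params: ConditionParams,
    *,
    subject_id: str,
    condition: str,
    site: SiteParams | None = None,
    seed: int | None = None,
    rate_offset: float = 0.0,
    amp_gain: float = 1.0,
    white_scale: float = 1.0,
    ar_sd_scale: float = 1.0,
) -> tuple[BreathRecording, RecordingTruth]:
    """One recording with planted per-breath rate/amplitude series.

    Per-subject modifiers express cohort heterogeneity: ``rate_offset``
    and ``amp_gain`` shift central tendency, ``white_scale`` multiplies
    the white-jitter SDs (entropy/complexity lever) and ``ar_sd_scale``
    the rate AR(1) SD (variability lever). Rates straying outside
    (4, 60) bpm are clipped and counted.
    """
    site = site or SiteParams("site0")
    rng = np.random.default_rng(seed)
    base = params.base_rate + rate_offset + site.rate_offset
    rate_spread = params.rate_mod_amp + 4 * (params.rate_ar_sd + params.rate_white_sd)
    n_max = int(np.ceil(params.duration / 60.0 * (base + rate_spread + 10))) + 4
    rates = base + _structured_series(
        n_max, params.rate_mod_amp, params.rate_mod_period,
        params.rate_white_sd * white_scale, params.rate_phi,
        params.rate_ar_sd * ar_sd_scale, rng,
    )
    n_clipped = int(np.sum((rates < 4) | (rates > 60)))
    if n_clipped:
        logger.info("%s/%s: clipped %d planted rates", subject_id, condition, n_clipped)
    rates = np.clip(rates, 4.0, 60.0)
    amps = params.amp_mean * amp_gain * site.amp_gain * np.exp(
        _structured_series(
            n_max, params.amp_mod, params.amp_mod_period,
            params.amp_white_sd * white_scale, params.amp_phi,
            params.amp_ar_sd, rng,
        )
    )
    # keep breaths fitting inside the recording
    cum = np.cumsum(60.0 / rates)
    n_breaths = int(np.searchsorted(cum, params.duration, side="right"))
    rates, amps = rates[:n_breaths], amps[:n_breaths]
    x, peak_times = waveform_from_breaths(
        rates, amps, params.fs, noise_sd=params.noise_sd, rng=rng
    )
    # pad or trim to the nominal duration
    n_target = int(round(params.duration * params.fs))
    if x.size < n_target:
        x = np.concatenate([x, np.zeros(n_target - x.size)])
    else:
        x = x[:n_target]
    rec = BreathRecording(
        subject_id=subject_id, condition=condition, site_id=site.label,
        fs=params.fs, samples=x,
    )
    truth = RecordingTruth(
        peak_times=peak_times, rates=rates, amplitudes=amps,
        rate_phi=params.rate_phi, amp_phi=params.amp_phi, n_clipped=n_clipped,
    )
    return rec, truth


def _bai_items(z: float, rng: np.random.Generator) -> tuple[int, ...]:
    """21 items 0-3 as discretized monotone transforms of a latent."""
    lam = 0.8
    raw = lam * z + rng.standard_normal(21)
    return tuple(int(np.clip(np.digitize(v, [0.5, 1.5, 2.5]), 0, 3)) for v in raw)


def gen_cohort(spec: SyntheticCohortSpec) -> CohortBundle:
    """Full study bundle: recordings, anxiety table, behavior, ground truth.

    Rest-to-task shifts follow the planted directions in
    ``PLANTED_SIGNS``; the Beck-anxiety block is coupled to the entropy
    latent (which lowers the rest-state AR coefficients, raising entropy
    and complexity), and N-back efficiency is coupled negatively to the
    variability latent (which scales the task rate innovations, raising
    SD and CV).
    """
    master = np.random.SeedSequence(spec.seed)
    subj_seeds = master.spawn(spec.n_subjects)
    rng0 = np.random.default_rng(master.spawn(1)[0])
    subjects = [f"s{i:03d}" for i in range(spec.n_subjects)]
    e_lat = rng0.standard_normal(spec.n_subjects)   # entropy latent
    v_lat = rng0.standard_normal(spec.n_subjects)   # variability latent
    rate_off = rng0.normal(0, spec.subj_rate_sd, spec.n_subjects)
    amp_gain = np.exp(rng0.normal(0, spec.subj_amp_log_sd, spec.n_subjects))

    recordings: list[BreathRecording] = []
    anxiety: list[AnxietyRecord] = []
    behavior: list[BehaviorTrial] = []
    rec_truth: dict[tuple[str, str], RecordingTruth] = {}

    acc_logit_base = {1: 2.6, 2: 2.1, 3: 1.5}
    rt_base = {1: 0.45, 2: 0.55, 3: 0.65}

    for i, subj in enumerate(subjects):
        ss = subj_seeds[i].spawn(4)
        site = spec.sites[i % len(spec.sites)]
        # entropy latent raises the rest white jitter -> more irregular
        w_scale = float(np.exp(spec.entropy_white_slope * e_lat[i]))
        rec, tr = gen_breathing_signal(
            spec.rest, subject_id=subj, condition="rest", site=site,
            seed=ss[0], rate_offset=rate_off[i], amp_gain=amp_gain[i],
            white_scale=w_scale,
        )
        recordings.append(rec)
        rec_truth[(subj, "rest")] = tr
        if spec.include_task:
            # variability latent scales the task rate fluctuations
            sd_scale = float(np.exp(spec.variability_log_slope * v_lat[i]))
            rec, tr = gen_breathing_signal(
                spec.task, subject_id=subj, condition="task", site=site,
                seed=ss[1], rate_offset=rate_off[i], amp_gain=amp_gain[i],
                ar_sd_scale=sd_scale,
            )
            recordings.append(rec)
            rec_truth[(subj, "task")] = tr

        rng_b = np.random.default_rng(ss[2])
        z = spec.bai_entropy_rho * e_lat[i] + np.sqrt(1 - spec.bai_entropy_rho ** 2) * rng_b.standard_normal()
        items = _bai_items(z, rng_b)
        anxiety.append(AnxietyRecord(subj, sum(items), items))

        if spec.include_task:
            rng_t = np.random.default_rng(ss[3])
            for load in (1, 2, 3):
                acc = 1 / (1 + np.exp(-(acc_logit_base[load]
                                        - spec.eff_variability_beta * v_lat[i]
                                        + rng_t.normal(0, 0.25))))
                acc = float(np.clip(acc, 0.55, 0.99))
                mrt = rt_base[load] * float(np.exp(spec.eff_rt_beta * v_lat[i]
                                                   + rng_t.normal(0, 0.08)))
                for speed in ("slow", "fast"):
                    correct = rng_t.random(spec.trials_per_cell) < acc
                    rts = mrt * np.exp(rng_t.normal(0, 0.25, spec.trials_per_cell))
                    rts = np.clip(rts, 0.15, 3.0)
                    for c, rt in zip(correct, rts):
                        behavior.append(BehaviorTrial(subj, load, speed, int(c), float(rt)))

    truth = GroundTruth(
        recordings=rec_truth,
        expected_signs=dict(PLANTED_SIGNS),
        entropy_latent=e_lat,
        variability_latent=v_lat,
        subjects=subjects,
    )
    return CohortBundle(recordings=recordings, anxiety=anxiety,
                        behavior=behavior, truth=truth)
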