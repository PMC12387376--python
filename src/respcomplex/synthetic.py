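"""Synthetic wearable respiration and accelerometer cohort generator.

The study's raw recordings (chest/abdomen respiratory inductive plethysmography
plus a 3-axis accelerometer, all sampled at 25 Hz) are not publicly deposited,
so this module generates recordings with the statistical structure the
downstream analysis assumes:

* quasi-periodic breaths with a piecewise half-cosine shape whose rise time
  (inspiration, TI) and decay time (expiration, TE) are controlled by a
  target expiratory fraction TE/(TI+TE);
* breath-to-breath interval jitter;
* a slow raised-cosine amplitude envelope emulating the waxing-and-waning
  tidal volume of periodic breathing (the pulmonary-congestion phenotype's
  signature), plus per-breath amplitude noise;
* sinusoidal baseline drift and additive white noise;
* Poisson-placed movement-artifact bursts that distort the respiration
  channels and produce a synchronized accelerometer excursion.

Every recording carries per-breath ground-truth annotations so downstream
stages (movement exclusion, breath segmentation, feature recovery) can be
tested quantitatively.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeProfile",
    "RawRecording",
    "ClinicalCovariates",
    "NONPC_PROFILE",
    "PC_PROFILE",
    "DEFAULT_EFFECTS",
    "simulate_recording",
    "simulate_cohort",
    "covariates_frame",
]

DEFAULT_FS = 25.0
DEFAULT_START = datetime(2021, 6, 15, 23, 15, 0)

#: Ground-truth annotation columns, one row per fully simulated breath.
GROUND_TRUTH_COLUMNS = [
    "t_valley_start",
    "t_peak",
    "t_valley_end",
    "TI",
    "TE",
    "BBI",
    "RA",
    "TE_ratio",
]


@dataclass(frozen=True)
class PhenotypeProfile:
    """Generative parameters for one subject's night of breathing.

    Parameters
    ----------
    mean_bbi : float
        Mean breath-to-breath interval in seconds (3 s = 20 breaths/min).
    bbi_jitter_sd : float
        SD of the Gaussian per-breath interval perturbation (seconds),
        clipped at +/-40% of ``mean_bbi`` so breaths stay valid.
    te_fraction : float
        Target expiratory fraction TE/(TI+TE), in (0, 1).
    base_amplitude : float
        Breath amplitude in arbitrary units before modulation.
    envelope_depth : float
        Depth in [0, 1] of the raised-cosine periodic-breathing amplitude
        envelope; 0 disables the modulation.
    envelope_period : float
        Period of the amplitude envelope in seconds (~60 s is typical of
        periodic breathing).
    envelope_phase_jitter : float
        SD (radians/breath) of a random walk added to the envelope phase,
        making the waxing-waning quasi-periodic rather than metronomic.
    amplitude_noise_sd : float
        SD of iid per-breath amplitude noise (arbitrary units).
    amplitude_drift_sd : float
        Stationary SD of a slow mean-reverting (AR(1)) multiplicative
        amplitude drift shared by all phenotypes — the gradual tidal-volume
        variation every night shows (posture, sleep stage).  Without it a
        breath-amplitude series is white-noise dominated and its normalised
        entropy saturates, which no real respiration series does.
    amplitude_drift_phi : float
        AR(1) coefficient of the drift (per breath); 0.995 gives a
        ~200-breath (~10 min) correlation time.
    drift_amplitude, drift_period : float
        Slow sinusoidal baseline drift (arbitrary units / seconds).
    noise_sd : float
        SD of additive white sample noise on the summed respiration signal.
    artifact_rate : float
        Expected movement-artifact bursts per hour (Poisson placement).
    artifact_duration_mean : float
        Mean burst duration in seconds (exponential draw, clipped to
        [0.5, 30] s).
    """

    mean_bbi: float = 3.0
    bbi_jitter_sd: float = 0.5
    te_fraction: float = 0.564
    base_amplitude: float = 1.0
    envelope_depth: float = 0.15
    envelope_period: float = 60.0
    envelope_phase_jitter: float = 0.45
    amplitude_noise_sd: float = 0.03
    amplitude_drift_sd: float = 0.25
    amplitude_drift_phi: float = 0.995
    drift_amplitude: float = 0.3
    drift_period: float = 300.0
    noise_sd: float = 0.1
    artifact_rate: float = 20.0
    artifact_duration_mean: float = 10.0

    def validate(self) -> None:
        if not self.mean_bbi > 0:
            raise ValueError(f"mean_bbi must be > 0, got {self.mean_bbi}")
        if not 0.0 < self.te_fraction < 1.0:
            raise ValueError(
                f"te_fraction must lie in (0, 1), got {self.te_fraction}"
            )
        if not 0.0 <= self.envelope_depth <= 1.0:
            raise ValueError(
                f"envelope_depth must lie in [0, 1], got {self.envelope_depth}"
            )
        if self.base_amplitude <= 0:
            raise ValueError(
                f"base_amplitude must be > 0, got {self.base_amplitude}"
            )
        if not 0.0 <= self.amplitude_drift_phi < 1.0:
            raise ValueError(
                "amplitude_drift_phi must lie in [0, 1), got "
                f"{self.amplitude_drift_phi}"
            )
        for name in (
            "bbi_jitter_sd",
            "amplitude_noise_sd",
            "amplitude_drift_sd",
            "envelope_phase_jitter",
            "drift_amplitude",
            "noise_sd",
            "artifact_rate",
            "artifact_duration_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.envelope_period <= 0:
            raise ValueError(
                f"envelope_period must be > 0, got {self.envelope_period}"
            )
        if self.drift_period <= 0:
            raise ValueError(f"drift_period must be > 0, got {self.drift_period}")

    def replace(self, **kwargs) -> "PhenotypeProfile":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RawRecording:
    """Multichannel 25 Hz wearable recording anchored to a wall clock.

    ``chest``/``abdomen`` are the two respiration channels (arbitrary units),
    ``accel`` is an (n, 3) array in g-units.  ``ground_truth`` holds one row
    per simulated breath (columns :data:`GROUND_TRUTH_COLUMNS`, times in
    seconds from recording start); ``artifacts`` lists the injected movement
    bursts as ``[start, end)`` second pairs.  Both are ``None``/empty for
    recordings read from files that lack annotations.
    """

    start_clock: datetime
    fs: float
    chest: np.ndarray
    abdomen: np.ndarray
    accel: np.ndarray
    ground_truth: pd.DataFrame | None = None
    artifacts: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        n = len(self.chest)
        if len(self.abdomen) != n or len(self.accel) != n:
            raise ValueError(
                "chest, abdomen and accel must have equal length "
                f"(got {n}, {len(self.abdomen)}, {len(self.accel)})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.chest)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def end_clock(self) -> datetime:
        return self.start_clock + timedelta(seconds=self.duration_s)

    def total_respiration(self) -> np.ndarray:
        """Timestamp-aligned sum of the chest and abdomen channels."""
        return self.chest + self.abdomen


@dataclass(frozen=True)
class ClinicalCovariates:
    """Per-subject clinical covariate record (study-admission style)."""

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    dbp: float  # diastolic blood pressure, mm Hg
    sbp: float  # systolic blood pressure, mm Hg
    nyha: str  # "II" | "III" | "IV"
    log_ntprobnp: float  # log10(NT-proBNP pg/mL)
    pc_label: int  # 1 = pulmonary congestion

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.nyha not in ("II", "III", "IV"):
            raise ValueError(f"nyha must be II/III/IV, got {self.nyha!r}")
        if not self.dbp < self.sbp:
            raise ValueError(f"dbp must be < sbp (got {self.dbp} >= {self.sbp})")
        if self.pc_label not in (0, 1):
            raise ValueError(f"pc_label must be 0 or 1, got {self.pc_label}")


def _breath_schedule(
    profile: PhenotypeProfile, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Valley times covering [0, duration] plus one overhanging breath."""
    n_max = int(np.ceil(duration / (0.6 * profile.mean_bbi))) + 2
    jitter = rng.normal(0.0, profile.bbi_jitter_sd, size=n_max)
    # truncate at +/-40% of the mean interval so every breath stays valid
    bbis = np.clip(
        profile.mean_bbi + jitter, 0.6 * profile.mean_bbi, 1.4 * profile.mean_bbi
    )
    valleys = np.concatenate([[0.0], np.cumsum(bbis)])
    last = int(np.searchsorted(valleys, duration, side="left"))
    return valleys[: min(last + 1, len(valleys))]


def simulate_recording(
    profile: PhenotypeProfile,
    duration: float,
    seed: int,
    *,
    fs: float = DEFAULT_FS,
    start_clock: datetime = DEFAULT_START,
) -> RawRecording:
    """Simulate one multichannel recording of ``duration`` seconds.

    Breath *i* rises from valley to peak over TI = (1-te_fraction)*BBI_i and
    decays back over TE = te_fraction*BBI_i, both as half-cosines, so the
    expiratory fraction of every simulated breath equals ``te_fraction``
    exactly.  Identical ``(profile, duration, seed)`` give a bit-identical
    recording.
    """
    profile.validate()
    if duration < 60:
        raise ValueError(f"duration must be >= 60 s, got {duration}")

    rng = np.random.default_rng(seed)
    valleys = _breath_schedule(profile, duration, rng)
    bbis = np.diff(valleys)
    n_breaths = len(bbis)

    phase = 2.0 * np.pi * valleys[:-1] / profile.envelope_period
    if profile.envelope_phase_jitter > 0:
        phase = phase + np.cumsum(
            rng.normal(0.0, profile.envelope_phase_jitter, size=n_breaths)
        )
    env = 1.0 - profile.envelope_depth * (1.0 + np.cos(phase)) / 2.0
    # slow mean-reverting multiplicative amplitude drift (stationary AR(1))
    phi = profile.amplitude_drift_phi
    step_sd = profile.amplitude_drift_sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    steps = rng.normal(0.0, step_sd, size=n_breaths)
    drift = np.empty(n_breaths)
    d = rng.normal(0.0, profile.amplitude_drift_sd)
    for i in range(n_breaths):
        d = phi * d + steps[i]
        drift[i] = d
    amp = profile.base_amplitude * env * np.clip(1.0 + drift, 0.2, None)
    amp = amp + rng.normal(0.0, profile.amplitude_noise_sd, size=n_breaths)
    amp = np.maximum(amp, 0.05 * profile.base_amplitude)

    ti = (1.0 - profile.te_fraction) * bbis
    peaks = valleys[:-1] + ti

    n = int(round(duration * fs))
    tt = np.arange(n) / fs
    idx = np.clip(np.searchsorted(valleys, tt, side="right") - 1, 0, n_breaths - 1)
    tau = tt - valleys[idx]
    rising = tau < ti[idx]
    phase_up = np.pi * tau / np.maximum(ti[idx], 1e-12)
    phase_dn = np.pi * (tau - ti[idx]) / np.maximum(bbis[idx] - ti[idx], 1e-12)
    resp = np.where(
        rising,
        amp[idx] * (1.0 - np.cos(phase_up)) / 2.0,
        amp[idx] * (1.0 + np.cos(phase_dn)) / 2.0,
    )

    if profile.drift_amplitude > 0:
        resp = resp + profile.drift_amplitude * np.sin(
            2.0 * np.pi * tt / profile.drift_period
        )

    # accelerometer: gravity on z plus small sensor noise
    accel = rng.normal(0.0, 0.01, size=(n, 3))
    accel[:, 2] += 1.0

    # Poisson-placed movement bursts: large low-frequency respiration
    # transient + synchronized accelerometer excursion
    artifacts: list[tuple[float, float]] = []
    expected = profile.artifact_rate * duration / 3600.0
    n_art = int(rng.poisson(expected)) if expected > 0 else 0
    for _ in range(n_art):
        dur_a = float(
            np.clip(rng.exponential(profile.artifact_duration_mean), 0.5, 30.0)
        )
        start_a = float(rng.uniform(0.0, max(duration - dur_a, 0.0)))
        i0 = int(start_a * fs)
        i1 = min(int((start_a + dur_a) * fs), n)
        if i1 <= i0:
            continue
        tau_a = (np.arange(i1 - i0)) / fs
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        resp[i0:i1] += (
            sign * 5.0 * profile.base_amplitude * np.sin(np.pi * tau_a / dur_a)
        )
        axis = int(rng.integers(0, 3))
        accel[i0:i1, axis] += 0.3 * np.sin(2.0 * np.pi * 3.0 * tau_a)
        accel[i0:i1, :] += rng.normal(0.0, 0.1, size=(i1 - i0, 3))
        artifacts.append((start_a, start_a + dur_a))
    artifacts.sort()

    # 60/40 chest/abdomen split with independent channel noise whose sum has
    # SD = noise_sd
    ch_noise = rng.normal(0.0, profile.noise_sd / np.sqrt(2.0), size=n)
    ab_noise = rng.normal(0.0, profile.noise_sd / np.sqrt(2.0), size=n)
    chest = 0.6 * resp + ch_noise
    abdomen = 0.4 * resp + ab_noise

    complete = valleys[1:] <= duration + 1e-9
    gt = pd.DataFrame(
        {
            "t_valley_start": valleys[:-1][complete],
            "t_peak": peaks[complete],
            "t_valley_end": valleys[1:][complete],
            "TI": ti[complete],
            "TE": (bbis - ti)[complete],
            "BBI": bbis[complete],
            "RA": amp[complete],
            "TE_ratio": np.full(int(complete.sum()), profile.te_fraction),
        }
    )

    return RawRecording(
        start_clock=start_clock,
        fs=fs,
        chest=chest,
        abdomen=abdomen,
        accel=accel,
        ground_truth=gt,
        artifacts=artifacts,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Baseline (non-congested) phenotype.
NONPC_PROFILE = PhenotypeProfile()

#: Group differences (PC minus non-PC) applied on top of the baseline.
#: Signal effects follow the congestion phenotype's qualitative signature
#: (longer expiratory fraction, deeper periodic-breathing envelope, noisier
#: breath amplitudes); covariate effects follow the admission-cohort
#: contrasts (older, lower DBP, higher log NT-proBNP, more NYHA IV).
DEFAULT_EFFECTS: dict[str, float] = {
    "te_fraction": 0.027,
    "envelope_depth": 0.35,
    "amplitude_noise_sd": 0.12,
    "age": 5.8,
    "dbp": -11.3,
    "log_ntprobnp": 0.35,
    "p_nyha_iv": 0.29,
    "p_male": 0.08,
}

#: Convenience profile with all default PC effects applied.
PC_PROFILE = NONPC_PROFILE.replace(
    te_fraction=NONPC_PROFILE.te_fraction + DEFAULT_EFFECTS["te_fraction"],
    envelope_depth=NONPC_PROFILE.envelope_depth + DEFAULT_EFFECTS["envelope_depth"],
    amplitude_noise_sd=NONPC_PROFILE.amplitude_noise_sd
    + DEFAULT_EFFECTS["amplitude_noise_sd"],
)

# between-subject SDs of the varied profile fields
_SUBJECT_SD = {
    "mean_bbi": 0.45,
    "te_fraction": 0.03,
    "envelope_depth": 0.10,
    "amplitude_noise_sd": 0.02,
}

# covariate baselines (non-PC group means / SDs)
_COV_BASE = {
    "age": (56.4, 14.8),
    "dbp": (82.9, 13.0),
    "log_ntprobnp": (3.52, 0.40),
    "pulse_pressure": (42.0, 12.0),  # SBP - DBP
    "p_male": 0.56,
    "p_nyha": (0.17, 0.55, 0.28),  # II, III, IV
}


def _draw_profile(
    group_effects: dict[str, float], rng: np.random.Generator
) -> PhenotypeProfile:
    base = NONPC_PROFILE
    mean_bbi = float(
        np.clip(rng.normal(base.mean_bbi, _SUBJECT_SD["mean_bbi"]), 2.0, 5.0)
    )
    te = float(
        np.clip(
            rng.normal(
                base.te_fraction + group_effects.get("te_fraction", 0.0),
                _SUBJECT_SD["te_fraction"],
            ),
            0.35,
            0.80,
        )
    )
    depth = float(
        np.clip(
            rng.normal(
                base.envelope_depth + group_effects.get("envelope_depth", 0.0),
                _SUBJECT_SD["envelope_depth"],
            ),
            0.0,
            1.0,
        )
    )
    amp_noise = float(
        np.clip(
            rng.normal(
                base.amplitude_noise_sd
                + group_effects.get("amplitude_noise_sd", 0.0),
                _SUBJECT_SD["amplitude_noise_sd"],
            ),
            0.005,
            0.5,
        )
    )
    return base.replace(
        mean_bbi=mean_bbi,
        te_fraction=te,
        envelope_depth=depth,
        amplitude_noise_sd=amp_noise,
    )


def _draw_covariates(
    subject_id: str,
    pc_label: int,
    group_effects: dict[str, float],
    rng: np.random.Generator,
) -> ClinicalCovariates:
    age = float(
        np.clip(
            rng.normal(
                _COV_BASE["age"][0] + group_effects.get("age", 0.0),
                _COV_BASE["age"][1],
            ),
            18,
            95,
        )
    )
    male = rng.uniform() < np.clip(
        _COV_BASE["p_male"] + group_effects.get("p_male", 0.0), 0.0, 1.0
    )
    dbp = float(
        np.clip(
            rng.normal(
                _COV_BASE["dbp"][0] + group_effects.get("dbp", 0.0),
                _COV_BASE["dbp"][1],
            ),
            40,
            130,
        )
    )
    gap = float(
        np.clip(
            rng.normal(
                _COV_BASE["pulse_pressure"][0], _COV_BASE["pulse_pressure"][1]
            ),
            5,
            100,
        )
    )
    lognt = float(
        rng.normal(
            _COV_BASE["log_ntprobnp"][0] + group_effects.get("log_ntprobnp", 0.0),
            _COV_BASE["log_ntprobnp"][1],
        )
    )
    p2, p3, p4 = _COV_BASE["p_nyha"]
    p4g = float(np.clip(p4 + group_effects.get("p_nyha_iv", 0.0), 0.0, 0.95))
    rest = (1.0 - p4g) / (p2 + p3)
    nyha = str(rng.choice(["II", "III", "IV"], p=[p2 * rest, p3 * rest, p4g]))
    return ClinicalCovariates(
        subject_id=subject_id,
        age=age,
        sex="male" if male else "female",
        dbp=dbp,
        sbp=dbp + gap,
        nyha=nyha,
        log_ntprobnp=lognt,
        pc_label=pc_label,
    )


def simulate_cohort(
    n_pc: int,
    n_nonpc: int,
    effect_config: dict[str, float] | None = None,
    seed: int = 0,
    *,
    duration_s: float = 3600.0,
    fs: float = DEFAULT_FS,
    start_clock: datetime = DEFAULT_START,
) -> list[tuple[RawRecording, ClinicalCovariates]]:
    """Simulate a labelled cohort of recordings plus clinical covariates.

    ``effect_config`` maps effect names (see :data:`DEFAULT_EFFECTS`) to the
    PC-minus-non-PC group difference; unknown keys are rejected.  Setting all
    effects to zero makes the two groups draw from identical distributions.
    """
    if n_pc < 1 or n_nonpc < 1:
        raise ValueError(
            f"n_pc and n_nonpc must be >= 1 (got n_pc={n_pc}, n_nonpc={n_nonpc})"
        )
    effects = dict(DEFAULT_EFFECTS if effect_config is None else effect_config)
    unknown = set(effects) - set(DEFAULT_EFFECTS)
    if unknown:
        raise ValueError(f"unknown effect_config keys: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    cohort: list[tuple[RawRecording, ClinicalCovariates]] = []
    labels = [1] * n_pc + [0] * n_nonpc
    for i, label in enumerate(labels):
        group_effects = effects if label == 1 else {}
        profile = _draw_profile(group_effects, rng)
        cov = _draw_covariates(f"S{i:03d}", label, group_effects, rng)
        rec_seed = int(rng.integers(0, 2**31 - 1))
        rec = simulate_recording(
            profile, duration_s, rec_seed, fs=fs, start_clock=start_clock
        )
        cohort.append((rec, cov))
    return cohort


def covariates_frame(
    cohort: list[tuple[RawRecording, ClinicalCovariates]]
    | list[ClinicalCovariates],
) -> pd.DataFrame:
    """Tabulate covariates, adding ``male`` and ``nyha_iv`` indicator columns."""
    covs = [c[1] if isinstance(c, tuple) else c for c in cohort]
    df = pd.DataFrame([dataclasses.asdict(c) for c in covs]).set_index("subject_id")
    df["male"] = (df["sex"] == "male").astype(int)
    df["nyha_iv"] = (df["nyha"] == "IV").astype(int)
    return df
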