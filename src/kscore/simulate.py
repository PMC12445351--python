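"""Seeded synthetic sit-to-stand generator with ground truth.

Emulates multi-repetition sit-to-stand trials of the 11-landmark skeleton:
rest plateaus on a 17-inch (0.432 m) chair, a forward-lean phase, a
minimum-jerk rise with the trunk extending back to vertical, a standing
plateau and an eccentric descent, repeated with timed-cue spacing. Motion is
sagittal-dominant with a small mediolateral sway so every one of the 33
channels carries signal; measurement noise is additive white Gaussian on all
channels. Segment lengths derive from stature by fixed anthropometric ratios.

Impairment is a severity dial acting through three mechanisms with the effect
directions seen in low-back-pain cohorts (greater trunk flexion, slower
rises): extra peak flexion, a slowdown factor that also adds a mid-rise
hesitation to the hip trajectory (so slow movers deviate in *shape*, not just
clock time), and left-right asymmetry (foot placement offset plus lateral
sway). Cohort generation mixes these axes randomly per patient, mimicking the
clinical heterogeneity that defeats single isolated metrics.

Ground truth stored per trial: the rise onset/offset times of the noise-free
signal under the same event definition the detector uses, the commanded phase
boundaries, peak flexion, peak clean center-of-mass velocities, and the exact
segment lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .io import ManifestEntry, SubjectMeta, TrialRecording, write_manifest, write_trial
from .landmarks import CANONICAL
from .preprocess import SegmentationParams, detect_transitions

_SEAT_HEIGHT_M = 0.4318  # standard 17-inch chair

#: Stature fractions of the generator skeleton (fixed constants).
_RATIOS = {
    "trunk": 0.300,
    "thigh": 0.245,
    "shank": 0.246,
    "shoulder_width": 0.259,
    "pelvis_width": 0.191,
    "ankle_height": 0.048,
}


@dataclass(frozen=True)
class AnthroProfile:
    """Skeleton dimensions, all in meters, derived from stature."""

    height: float
    trunk: float
    thigh: float
    shank: float
    shoulder_width: float
    pelvis_width: float
    ankle_height: float
    seat_height: float = _SEAT_HEIGHT_M

    @classmethod
    def from_height(cls, height: float, seat_height: float = _SEAT_HEIGHT_M) -> "AnthroProfile":
        if not height > 0:
            raise ParameterError("height must be positive")
        return cls(
            height=height,
            seat_height=seat_height,
            **{k: v * height for k, v in _RATIOS.items()},
        )

    @property
    def leg_length(self) -> float:
        return self.thigh + self.shank


@dataclass(frozen=True)
class ImpairmentParams:
    """Impairment axes; severity 0 leaves every effect at its identity value."""

    severity: float = 0.0
    flexion_excess_deg: float = 0.0
    slowdown: float = 1.0
    asymmetry: float = 0.0
    jitter_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.severity:
            raise ParameterError("severity must be >= 0")
        if self.slowdown < 1.0:
            raise ParameterError("slowdown must be >= 1")
        if self.jitter_scale <= 0:
            raise ParameterError("jitter_scale must be positive")

    @classmethod
    def from_severity(
        cls, severity: float, mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    ) -> "ImpairmentParams":
        """Deterministic severity -> effect mapping.

        ``mix`` weights the (flexion, slowdown, asymmetry) axes and sums to 1;
        the default splits the severity budget evenly.
        """
        w = np.asarray(mix, dtype=float)
        if w.min() < 0 or abs(w.sum() - 1) > 1e-9:
            raise ParameterError("mix must be a 3-part convex combination")
        # Slowness has an always-on share: impaired movers are consistently
        # slower, while how much extra flexion or asymmetry they show varies
        # from patient to patient.
        return cls(
            severity=severity,
            flexion_excess_deg=severity * (6.0 + 30.0 * w[0]),
            slowdown=1.0 + severity * (0.35 + 0.9 * w[1]),
            asymmetry=min(1.0, severity * (0.15 + 1.0 * w[2])),
            jitter_scale=1.0 + severity,
        )


@dataclass
class SyntheticTrial:
    """A generated recording plus everything a test needs to check it."""

    recording: TrialRecording  # noisy
    clean_positions: np.ndarray  # noise-free T x 33
    events: list[tuple[float, float]]  # (onset, offset) times, noise-free signal
    commanded_phases: list[dict[str, float]]  # rise_start/rise_end/... per rep
    commanded_peak_flexion_deg: list[float]
    commanded_peak_sup_vel: float  # m/s, clean COM, max over trial
    commanded_peak_ant_vel: float
    anthro: AnthroProfile
    impairment: ImpairmentParams
    seed: int

    @property
    def true_durations(self) -> list[float]:
        return [b - a for a, b in self.events]


def _minjerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _two_link_ik(hip: np.ndarray, ankle: np.ndarray, thigh: float, shank: float) -> np.ndarray:
    """Knee positions (T x 3) with exact segment lengths, knee anterior.

    Solved in the plane spanned by the hip-ankle axis and the anterior axis.
    """
    d_vec = ankle - hip
    d = np.linalg.norm(d_vec, axis=1)
    reach = thigh + shank
    if np.any(d >= reach * 0.9999):
        raise ParameterError("hip-ankle distance exceeds leg length")
    along = d_vec / d[:, None]
    anterior = np.array([0.0, 0.0, 1.0])
    perp = anterior - (along @ anterior)[:, None] * along
    norm = np.linalg.norm(perp, axis=1)
    if np.any(norm < 1e-9):
        raise ParameterError("degenerate leg geometry")
    perp /= norm[:, None]
    cos_g = (thigh**2 + d**2 - shank**2) / (2 * thigh * d)
    cos_g = np.clip(cos_g, -1.0, 1.0)
    sin_g = np.sqrt(1.0 - cos_g**2)
    return hip + thigh * (cos_g[:, None] * along + sin_g[:, None] * perp)


def generate_subject(
    anthro: AnthroProfile,
    impair: ImpairmentParams,
    n_reps: int = 5,
    noise_sd: float = 0.003,
    seed: int = 0,
    subject_id: str = "synthetic",
    base_flexion_deg: float = 42.0,
    base_rise_s: float = 1.05,
    base_lean_s: float = 0.45,
    fs: float = 30.0,
) -> SyntheticTrial:
    """Generate one multi-repetition trial; deterministic under (seed, params)."""
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    jit = 0.03 * impair.jitter_scale

    # --- phase schedule -----------------------------------------------------
    slow = impair.slowdown
    phases: list[dict] = []  # per repetition
    t_cursor = 0.0
    for _ in range(n_reps):
        rest = 1.2 * (1 + rng.normal(0, 0.06))
        lean = base_lean_s * slow * (1 + rng.normal(0, jit))
        rise = base_rise_s * slow * (1 + rng.normal(0, jit))
        stand = 0.9 * (1 + rng.normal(0, 0.05))
        descend = 1.25 * slow * (1 + rng.normal(0, jit))
        peak_flex = (base_flexion_deg + impair.flexion_excess_deg) * (1 + rng.normal(0, jit))
        rep = {
            "rest_start": t_cursor,
            "lean_start": t_cursor + rest,
            "rise_start": t_cursor + rest + lean,
            "rise_end": t_cursor + rest + lean + rise,
            "stand_end": t_cursor + rest + lean + rise + stand,
            "descend_end": t_cursor + rest + lean + rise + stand + descend,
            "peak_flexion_deg": peak_flex,
        }
        phases.append(rep)
        t_cursor = rep["descend_end"]
    total = t_cursor + 1.0
    n_frames = int(np.floor(total * fs)) + 1
    t = np.arange(n_frames) / fs

    # --- scalar time courses ------------------------------------------------
    y_seat = anthro.seat_height
    y_stand = anthro.ankle_height + 0.97 * anthro.leg_length
    z_seat, z_stand = -0.16, -0.02
    hesitation = 0.15 * (slow - 1.0)

    theta = np.zeros(n_frames)  # trunk flexion, radians
    y_hip = np.full(n_frames, y_seat)
    z_hip = np.full(n_frames, z_seat)
    for rep in phases:
        pk = np.radians(rep["peak_flexion_deg"])
        rise_dur = rep["rise_end"] - rep["rise_start"]
        # flexion ramp runs from lean start to 25 % into the rise, the decline
        # from there to the end of the rise: the neck-height minimum falls
        # inside the rise where both profiles move at mid-range rates.
        flex_peak_t = rep["rise_start"] + 0.25 * rise_dur
        m = (t >= rep["lean_start"]) & (t < flex_peak_t)
        tau = (t[m] - rep["lean_start"]) / (flex_peak_t - rep["lean_start"])
        theta[m] = pk * _minjerk(tau)
        m = (t >= flex_peak_t) & (t < rep["rise_end"])
        tau = (t[m] - flex_peak_t) / (rep["rise_end"] - flex_peak_t)
        theta[m] = pk * (1.0 - _minjerk(tau))
        # eccentric descent with half the concentric flexion
        m = (t >= rep["stand_end"]) & (t < rep["descend_end"])
        tau = (t[m] - rep["stand_end"]) / (rep["descend_end"] - rep["stand_end"])
        theta[m] = 0.55 * pk * np.sin(np.pi * tau) ** 2

        m = (t >= rep["rise_start"]) & (t < rep["rise_end"])
        tau = (t[m] - rep["rise_start"]) / rise_dur
        s = _minjerk(tau) - hesitation * np.sin(np.pi * tau) ** 4
        y_hip[m] = y_seat + (y_stand - y_seat) * s
        z_hip[m] = z_seat + (z_stand - z_seat) * _minjerk(tau)
        m = (t >= rep["rise_end"]) & (t < rep["stand_end"])
        y_hip[m], z_hip[m] = y_stand, z_stand
        m = (t >= rep["stand_end"]) & (t < rep["descend_end"])
        tau = (t[m] - rep["stand_end"]) / (rep["descend_end"] - rep["stand_end"])
        y_hip[m] = y_stand + (y_seat - y_stand) * _minjerk(tau)
        z_hip[m] = z_stand + (z_seat - z_stand) * _minjerk(tau)

    # Mediolateral motion: a small lateral weight shift locked to each rise
    # (systematic, so healthy lateral waveforms look alike after
    # standardization) plus a faint idiosyncratic sine so every lateral
    # channel carries genuine variance. The shift's side is random per
    # subject; a whole-channel sign flip does not change PC scores.
    side = -1.0 if rng.random() < 0.5 else 1.0
    rise_bump = np.zeros(n_frames)
    for rep in phases:
        m = (t >= rep["rise_start"]) & (t < rep["rise_end"])
        tau = (t[m] - rep["rise_start"]) / (rep["rise_end"] - rep["rise_start"])
        rise_bump[m] = np.sin(np.pi * tau) ** 2
    drift = np.sin(2 * np.pi * t / rng.uniform(5.0, 9.0) + rng.uniform(0, 2 * np.pi))
    # Asymmetry amplifies the subject's own shift direction (never cancels it,
    # which would collapse the lateral variance at intermediate severities).
    x_amp = side * (0.007 * (1 + 0.3 * rng.uniform(-1, 1)) + impair.asymmetry * 0.04)
    x_hip = x_amp * rise_bump + 0.0015 * drift
    lat_tilt = side * (0.010 + impair.asymmetry * 0.06) * rise_bump + 0.003 * drift

    # --- forward kinematics -------------------------------------------------
    hip_center = np.column_stack([x_hip, y_hip, z_hip])
    spine_base = hip_center + np.array([0.0, 0.04, 0.0])
    trunk_dir = np.column_stack([lat_tilt, np.cos(theta), np.sin(theta)])
    trunk_dir /= np.linalg.norm(trunk_dir, axis=1)[:, None]
    neck = spine_base + anthro.trunk * trunk_dir
    spine_mid = spine_base + 0.5 * anthro.trunk * trunk_dir
    shoulder_c = spine_base + 0.95 * anthro.trunk * trunk_dir
    half_sw = 0.5 * anthro.shoulder_width
    half_pw = 0.5 * anthro.pelvis_width
    lateral = np.array([1.0, 0.0, 0.0])
    shoulder_l = shoulder_c + half_sw * lateral
    shoulder_r = shoulder_c - half_sw * lateral
    hip_l = hip_center + half_pw * lateral
    hip_r = hip_center - half_pw * lateral
    ankle_y = anthro.ankle_height
    foot_offset = impair.asymmetry * 0.10
    ankle_l = np.tile([1.1 * half_pw, ankle_y, foot_offset], (n_frames, 1))
    ankle_r = np.tile([-1.1 * half_pw, ankle_y, 0.0], (n_frames, 1))
    knee_l = _two_link_ik(hip_l, ankle_l, anthro.thigh, anthro.shank)
    knee_r = _two_link_ik(hip_r, ankle_r, anthro.thigh, anthro.shank)

    by_name = {
        "neck": neck,
        "shoulder_l": shoulder_l,
        "shoulder_r": shoulder_r,
        "spine_mid": spine_mid,
        "spine_base": spine_base,
        "hip_l": hip_l,
        "hip_r": hip_r,
        "knee_l": knee_l,
        "knee_r": knee_r,
        "ankle_l": ankle_l,
        "ankle_r": ankle_r,
    }
    clean = np.concatenate([by_name[n] for n in CANONICAL.names], axis=1)
    noisy = clean + rng.normal(0, noise_sd, clean.shape) if noise_sd > 0 else clean.copy()

    # --- ground truth -------------------------------------------------------
    neck_y = clean[:, CANONICAL.channel_index("neck", "y")]
    idx_events = detect_transitions(neck_y, t, SegmentationParams())
    events = [(float(t[a]), float(t[b])) for a, b in idx_events]
    trunk_names = ("neck", "shoulder_l", "shoulder_r", "spine_mid", "spine_base")
    com = np.mean([by_name[n] for n in trunk_names], axis=0)
    vel = np.gradient(com, t, axis=0)

    recording = TrialRecording(
        subject_id=subject_id,
        timestamps=t,
        positions=noisy,
        landmark_set=CANONICAL,
        sampling_rate=fs,
    )
    return SyntheticTrial(
        recording=recording,
        clean_positions=clean,
        events=events,
        commanded_phases=phases,
        commanded_peak_flexion_deg=[r["peak_flexion_deg"] for r in phases],
        commanded_peak_sup_vel=float(np.max(vel[:, 1])),
        commanded_peak_ant_vel=float(np.max(np.abs(vel[:, 2]))),
        anthro=anthro,
        impairment=impair,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    entries: list[ManifestEntry]
    trials: dict[str, SyntheticTrial]
    manifest_path: Path | None = None
    seed: int = 0


def _sample_subject(rng: np.random.Generator, sid: str, group: str) -> SubjectMeta:
    sex = "F" if rng.random() < 0.5 else "M"
    height = rng.normal(1.63 if sex == "F" else 1.77, 0.06)
    height = float(np.clip(height, 1.50, 1.95))
    return SubjectMeta(
        subject_id=sid,
        group=group,
        sex=sex,
        age=float(np.clip(rng.normal(56, 12), 25, 85)),
        height=height,
        bmi=float(np.clip(rng.normal(26.5, 5.0), 17, 35)),
    )


def generate_cohort(
    n_controls: int,
    n_patients: int,
    severity: float,
    seed: int,
    out_dir: str | Path | None = None,
    n_reps: int = 5,
    noise_sd: float = 0.003,
    heterogeneous: bool = True,
) -> Cohort:
    """Generate a control + patient cohort, optionally writing CSVs + manifest.

    Controls get severity 0 with sampled anthropometry and timing; patients
    get ``severity`` scaled by a per-subject factor in [0.75, 1.25] and, when
    ``heterogeneous``, a random Dirichlet mix over the impairment axes so
    different patients deviate through different mechanisms.
    """
    if n_controls < 1 or n_patients < 1:
        raise ParameterError("cohort sizes must be >= 1")
    rng = np.random.default_rng(seed)
    entries: list[ManifestEntry] = []
    trials: dict[str, SyntheticTrial] = {}

    def make(sid: str, group: str, sev: float) -> None:
        meta = _sample_subject(rng, sid, group)
        anthro = AnthroProfile.from_height(meta.height)
        # Draw the impairment mix unconditionally so two cohorts generated with
        # the same seed but different severities share identical subjects
        # (matched severity arms differ only through the severity dial).
        mix = tuple(rng.dirichlet([1.2, 1.2, 1.2])) if heterogeneous else (1 / 3, 1 / 3, 1 / 3)
        subject_sev = sev * float(rng.uniform(0.75, 1.25))
        impair = ImpairmentParams.from_severity(subject_sev, mix=mix) if sev > 0 else ImpairmentParams()
        trial = generate_subject(
            anthro,
            impair,
            n_reps=n_reps,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
            subject_id=sid,
            base_flexion_deg=float(np.clip(rng.normal(42.0, 4.0), 30.0, 54.0)),
            base_rise_s=float(np.clip(rng.normal(1.05, 0.08), 0.8, 1.35)),
            base_lean_s=float(np.clip(rng.normal(0.45, 0.04), 0.32, 0.60)),
        )
        trials[sid] = trial
        entries.append(ManifestEntry(meta=meta, trial_path=Path(f"{sid}.csv")))

    for i in range(n_controls):
        make(f"ctrl_{i:03d}", "CTRL", 0.0)
    for i in range(n_patients):
        make(f"pat_{i:03d}", "PATIENT", severity)

    manifest_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, trial in trials.items():
            write_trial(trial.recording, out_dir / f"{sid}.csv")
        manifest_path = out_dir / "manifest.csv"
        # manifest rows keep bare filenames; read_manifest resolves them
        # against the manifest's own directory
        write_manifest(entries, manifest_path)
        entries = [
            ManifestEntry(meta=e.meta, trial_path=out_dir / e.trial_path) for e in entries
        ]
    return Cohort(entries=entries, trials=trials, manifest_path=manifest_path, seed=seed)
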