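"""Synthetic mCTSIB accelerometer cohort generator.

The study protocol records 23 subjects standing quietly for 30 s under each
of the four conditions of the modified Clinical Test of Sensory Interaction
and Balance (mCTSIB): firm surface / eyes open, firm / eyes closed, foam /
eyes open, foam / eyes closed.  A tri-axial accelerometer worn at the lower
back samples at 60 Hz with +/-2 g full scale (16,384 LSB/g).  The real
recordings are not public, so this module emulates their statistical
structure: quasi-static, band-limited sway whose ML/AP RMS amplitude grows
as sensory inputs are removed (condition 1 smallest, condition 4 largest;
the AP effect larger than the ML effect; the ML effect driven by the
eyes-closed conditions).

The sway path model is Gaussian white noise shaped by a second-order
Butterworth lowpass at the condition's sway bandwidth (default 1 Hz, well
below the 4 Hz analysis cutoff), anchored so the first sample is exactly
zero (the downstream inclination-offset removal is then a no-op on clean
data) and rescaled so the sample RMS equals the condition target exactly.
Paths are mapped to tri-axial accelerations by inverting the pendulum
projection under the quasi-static assumption R = 1 g, then quantized with
additive Gaussian sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DomainError, InvalidArgumentError
from .sway import COM_HEIGHT_FRACTION, RawAccelRecording

#: time constant (s) of the exponential start anchor; bandwidth ~0.08 Hz
_ANCHOR_TAU_S = 2.0


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics needed by the pendulum projection."""

    subject_id: str
    height: float          # cm
    com_height_L: float    # cm, COM-to-ground distance

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise InvalidArgumentError("height must be positive")
        if not 0 < self.com_height_L < self.height:
            raise InvalidArgumentError("com_height_L must lie in (0, height)")


@dataclass(frozen=True)
class ConditionSpec:
    """RMS targets (cm) and sway bandwidth (Hz) for one mCTSIB condition."""

    condition_id: int
    ml_rms_target: float
    ap_rms_target: float
    sway_bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.ml_rms_target < 0 or self.ap_rms_target < 0:
            raise InvalidArgumentError("RMS targets must be >= 0")
        if self.sway_bandwidth <= 0:
            raise InvalidArgumentError("sway_bandwidth must be positive")


#: default condition effect sizes: sway grows from condition 1 to 4, the AP
#: effect is larger than the ML effect, and ML barely changes while the eyes
#: are open (conditions 1 and 3).
DEFAULT_CONDITIONS: tuple[ConditionSpec, ...] = (
    ConditionSpec(1, ml_rms_target=0.30, ap_rms_target=0.40),
    ConditionSpec(2, ml_rms_target=0.45, ap_rms_target=0.70),
    ConditionSpec(3, ml_rms_target=0.32, ap_rms_target=0.90),
    ConditionSpec(4, ml_rms_target=0.60, ap_rms_target=1.40),
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level acquisition and sensor parameters."""

    n_subjects: int = 23
    fs: float = 60.0                 # Hz
    duration: float = 30.0           # s per condition
    sensitivity: float = 16384.0     # LSB/g at +/-2 g full scale
    full_scale: float = 2.0          # g
    noise_sd: float = 0.0005         # g, MEMS accelerometer with onboard lowpass enabled
    jitter_sigma: float = 0.40       # lognormal sigma of per-subject RMS factor
    bandwidth_jitter_sigma: float = 0.7  # lognormal sigma of per-subject sway bandwidth
    mean_height: float = 173.6       # cm, cohort mean
    sd_height: float = 6.8           # cm, cohort SD
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise InvalidArgumentError("fs and duration must be positive")
        if self.sensitivity <= 0:
            raise InvalidArgumentError("sensitivity must be positive")
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be >= 1")


def _child_seed(master_seed: int, *counters: int) -> np.random.SeedSequence:
    """Documented counter scheme: every random stream is keyed by
    (master_seed, counter...) through a SeedSequence, so any subject /
    condition / channel subset regenerates identically on its own."""
    return np.random.SeedSequence([int(master_seed), *map(int, counters)])


def _band_limited_noise(
    n: int, fs: float, bandwidth: float, rng: np.random.Generator
) -> np.ndarray:
    white = rng.standard_normal(n)
    b, a = signal.butter(2, bandwidth / (fs / 2.0), btype="low")
    zi = signal.lfilter_zi(b, a) * 0.0  # quiet start from rest
    shaped, _ = signal.lfilter(b, a, white, zi=zi)
    return shaped


def _anchored_path(raw: np.ndarray, fs: float, target_rms: float) -> np.ndarray:
    """Demean, re-anchor the first sample to exactly zero with a smooth
    (~0.08 Hz) exponential correction, and rescale to the exact target RMS."""
    n = raw.size
    d = raw - raw.mean()
    t = np.arange(n) / fs
    d = d - d[0] * np.exp(-t / _ANCHOR_TAU_S)
    scale = target_rms / np.sqrt(np.mean(d**2))
    return d * scale


def generate_sway_path(
    spec: ConditionSpec, duration: float, fs: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Planar COM ground-displacement path (d_x ML, d_y AP) in cm.

    Band-limited (<= spec.sway_bandwidth) stochastic paths whose sample RMS
    equals the targets exactly and whose first sample is zero; deterministic
    given the seed (ML drawn before AP from one stream).
    """
    if fs <= 0 or duration <= 0:
        raise InvalidArgumentError("fs and duration must be positive")
    n = int(round(duration * fs))
    if n < 2:
        raise InvalidArgumentError("duration*fs must cover at least 2 samples")
    rng = np.random.default_rng(seed)
    paths = []
    for target in (spec.ml_rms_target, spec.ap_rms_target):
        raw = _band_limited_noise(n, fs, spec.sway_bandwidth, rng)
        if target == 0:
            paths.append(np.zeros(n))
        else:
            paths.append(_anchored_path(raw, fs, target))
    return paths[0], paths[1]


def sway_to_accel(
    d_x: np.ndarray, d_y: np.ndarray, L: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert the pendulum projection under the quasi-static assumption R = 1 g.

    a_x = -(d_x/L), a_y = -(d_y/L), a_z = +sqrt(1 - a_x^2 - a_y^2); feeding
    the result through :func:`swaysom.sway.project_sway` recovers d_x, d_y
    exactly (before noise/quantization).
    """
    d_x = np.asarray(d_x, dtype=float)
    d_y = np.asarray(d_y, dtype=float)
    if L <= 0:
        raise InvalidArgumentError("L must be positive")
    if np.any(np.abs(d_x) >= L) or np.any(np.abs(d_y) >= L):
        raise DomainError("|displacement| must stay below L (pendulum geometry)")
    a_x = -d_x / L
    a_y = -d_y / L
    s = a_x**2 + a_y**2
    if np.any(s > 1.0):
        raise DomainError("cos^2(alpha) + cos^2(beta) exceeds 1")
    a_z = np.sqrt(1.0 - s)
    return a_x, a_y, a_z


def quantize_to_lsb(
    accel_g: np.ndarray,
    sensitivity: float = 16384.0,
    full_scale: float = 2.0,
    noise_sd: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Additive Gaussian sensor noise, scale to LSB, round, clip to range."""
    if sensitivity <= 0:
        raise InvalidArgumentError("sensitivity must be positive")
    if full_scale <= 0:
        raise InvalidArgumentError("full_scale must be positive")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    accel_g = np.asarray(accel_g, dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        accel_g = accel_g + rng.normal(0.0, noise_sd, size=accel_g.shape)
    lo = -full_scale * sensitivity
    hi = full_scale * sensitivity - 1
    lsb = np.clip(np.rint(accel_g * sensitivity), lo, hi)
    return lsb.astype(np.int64)


def default_profiles(config: CohortConfig) -> list[SubjectProfile]:
    """Subject heights drawn from the cohort's normal distribution; the
    COM-to-ground distance defaults to 0.53 x height."""
    rng = np.random.default_rng(_child_seed(config.rng_seed, 0))
    heights = rng.normal(config.mean_height, config.sd_height, config.n_subjects)
    heights = np.clip(heights, 140.0, 210.0)
    return [
        SubjectProfile(
            subject_id=f"{i + 1:02d}",
            height=float(h),
            com_height_L=float(COM_HEIGHT_FRACTION * h),
        )
        for i, h in enumerate(heights)
    ]


def generate_recording(
    profile: SubjectProfile,
    spec: ConditionSpec,
    config: CohortConfig,
    seed,
    noise_seed=None,
) -> RawAccelRecording:
    """One synthetic recording; condition semantics live only in the spec
    values, so identical specs and seeds yield identical samples regardless
    of the condition id."""
    d_x, d_y = generate_sway_path(spec, config.duration, config.fs, seed)
    a = np.column_stack(sway_to_accel(d_x, d_y, profile.com_height_L))
    lsb = quantize_to_lsb(
        a,
        sensitivity=config.sensitivity,
        full_scale=config.full_scale,
        noise_sd=config.noise_sd,
        seed=noise_seed if noise_seed is not None else seed,
    )
    return RawAccelRecording(
        subject_id=profile.subject_id,
        condition_id=spec.condition_id,
        fs=config.fs,
        samples=lsb,
    )


def generate_cohort(
    config: CohortConfig | None = None,
    condition_specs: tuple[ConditionSpec, ...] = DEFAULT_CONDITIONS,
    profiles: list[SubjectProfile] | None = None,
) -> tuple[list[RawAccelRecording], list[SubjectProfile]]:
    """n_subjects x 4 recordings with per-subject lognormal RMS jitter.

    Each subject carries one lognormal(sigma=jitter_sigma) multiplicative
    RMS factor per direction plus one lognormal(sigma=bandwidth_jitter_sigma)
    sway-bandwidth factor, all shared across conditions: subject-level sway
    magnitude and tempo traits.  The amplitude trait creates between-subject
    RMS spread while preserving the within-subject condition ordering; the
    tempo trait varies the velocity-to-position ratio across subjects, which
    reproduces the feature-correlation structure the screening stage assumes
    (velocity and acceleration collinear, position only weakly related to
    either).  The jittered bandwidth is capped at 2.5 Hz so the sway stays
    inside the 4 Hz analysis passband.
    """
    config = config or CohortConfig()
    if len(condition_specs) != 4:
        raise InvalidArgumentError("exactly 4 condition specs are required")
    if profiles is None:
        profiles = default_profiles(config)
    if len(profiles) != config.n_subjects:
        raise InvalidArgumentError("profiles length must equal n_subjects")

    recordings: list[RawAccelRecording] = []
    for s_idx, profile in enumerate(profiles):
        jit_rng = np.random.default_rng(_child_seed(config.rng_seed, 1, s_idx))
        ml_factor, ap_factor = np.exp(
            jit_rng.normal(0.0, config.jitter_sigma, size=2)
        )
        bw_factor = float(
            np.exp(jit_rng.normal(0.0, config.bandwidth_jitter_sigma))
        )
        for c_idx, spec in enumerate(condition_specs):
            jittered = replace(
                spec,
                ml_rms_target=spec.ml_rms_target * ml_factor,
                ap_rms_target=spec.ap_rms_target * ap_factor,
                sway_bandwidth=min(spec.sway_bandwidth * bw_factor, 2.5),
            )
            recordings.append(
                generate_recording(
                    profile,
                    jittered,
                    config,
                    seed=_child_seed(config.rng_seed, 2, s_idx, c_idx, 0),
                    noise_seed=_child_seed(config.rng_seed, 2, s_idx, c_idx, 1),
                )
            )
    return recordings, profiles


def write_cohort(
    recordings: list[RawAccelRecording],
    profiles: list[SubjectProfile],
    outdir: str | Path,
) -> Path:
    """Write one `S<id>_C<condition>.csv` per recording (header t,x,y,z) and
    a `manifest.csv` tying subjects, anthropometrics and files together.
    Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {p.subject_id: p for p in profiles}
    rows = []
    for rec in recordings:
        fname = f"S{rec.subject_id}_C{rec.condition_id}.csv"
        t = np.arange(rec.n_samples) / rec.fs
        df = pd.DataFrame(
            {
                "t": t,
                "x": rec.samples[:, 0],
                "y": rec.samples[:, 1],
                "z": rec.samples[:, 2],
            }
        )
        df.to_csv(outdir / fname, index=False, float_format="%.6f")
        profile = by_id[rec.subject_id]
        rows.append(
            {
                "subject_id": rec.subject_id,
                "height_cm": round(profile.height, 4),
                "L_cm": round(profile.com_height_L, 4),
                "condition": rec.condition_id,
                "file": fname,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(
    manifest_path: str | Path, fs: float = 60.0
) -> tuple[list[RawAccelRecording], list[SubjectProfile]]:
    """Load recordings and profiles back from a manifest written by
    :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, dtype={"subject_id": str})
    base = manifest_path.parent
    recordings = []
    profiles: dict[str, SubjectProfile] = {}
    for row in table.itertuples(index=False):
        df = pd.read_csv(base / row.file)
        recordings.append(
            RawAccelRecording(
                subject_id=str(row.subject_id),
                condition_id=int(row.condition),
                fs=fs,
                samples=df[["x", "y", "z"]].to_numpy(dtype=np.int64),
            )
        )
        profiles.setdefault(
            str(row.subject_id),
            SubjectProfile(
                subject_id=str(row.subject_id),
                height=float(row.height_cm),
                com_height_L=float(row.L_cm),
            ),
        )
    return recordings, list(profiles.values())
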