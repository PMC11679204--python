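"""EEG trial containers, preprocessing, and synthetic motor-imagery generation.

The synthetic generator emulates the statistical structure that cross-subject
motor-imagery classification relies on: 22-channel, 250 Hz, 7 s trials in which
each of the four imagery classes (left hand, right hand, feet, tongue)
attenuates band power (event-related desynchronization, ERD) in a
class-specific frequency band over a class-specific subset of sensorimotor
channels, on top of 1/f-shaped background noise.  A per-subject orthonormal
channel mixing creates the inter-subject distribution shift that transfer
learning is meant to bridge, and a smaller per-session rotation models
session-to-session drift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

__all__ = [
    "MontageInfo",
    "TrialSet",
    "SyntheticProfile",
    "Cohort",
    "default_profile",
    "load_gdf_session",
    "extract_window",
    "drop_channels",
    "generate_subject",
    "make_cohort",
    "save_cohort",
    "load_cohort",
]

# 10-20 labels of the 22-electrode montage used by the BCI IV 2a recordings,
# in the printed 1-based channel order.
MONTAGE_2A_NAMES = (
    "Fz",
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2",
    "POz",
)

CLASS_NAMES = {1: "left hand", 2: "right hand", 3: "feet", 4: "tongue"}


@dataclass(frozen=True)
class MontageInfo:
    """Electrode montage: 1-based channel ids, 10-20 labels, sampling rate."""

    channel_ids: Tuple[int, ...]
    channel_names: Tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_ids) != len(self.channel_names):
            raise ValueError("channel_ids and channel_names differ in length")
        if list(self.channel_ids) != sorted(set(self.channel_ids)):
            raise ValueError("channel ids must be unique and ascending")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @classmethod
    def standard_2a(cls, fs: float = 250.0) -> "MontageInfo":
        """The 22-channel montage compatible with the 2a recordings."""
        return cls(tuple(range(1, 23)), MONTAGE_2A_NAMES, fs)

    def subset(self, ids: Sequence[int]) -> "MontageInfo":
        keep = sorted(ids)
        missing = [i for i in keep if i not in self.channel_ids]
        if missing:
            raise ValueError(f"channels {missing} not in montage")
        names = tuple(self.channel_names[self.channel_ids.index(i)] for i in keep)
        return MontageInfo(tuple(keep), names, self.fs)


@dataclass
class TrialSet:
    """A cube of EEG trials (trials x channels x samples) with labels 1..4.

    ``data`` is stored as float32 microvolts.  ``window`` is the time span
    the samples cover, in seconds relative to trial onset.
    """

    data: np.ndarray
    labels: np.ndarray
    montage: MontageInfo
    subject_id: int = 0
    session_id: int = 0
    window: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length does not match trial count")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if self.labels.size and not np.isin(self.labels, [1, 2, 3, 4]).all():
            raise ValueError("labels must be in {1,2,3,4}")
        start, end = self.window
        expected = int(round((end - start) * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.window} at fs={self.fs} implies "
                f"{expected} samples, data has {self.data.shape[2]}"
            )

    @property
    def fs(self) -> float:
        return self.montage.fs

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset_trials(self, index: np.ndarray) -> "TrialSet":
        return TrialSet(
            self.data[index], self.labels[index], self.montage,
            self.subject_id, self.session_id, self.window,
        )

    @staticmethod
    def concatenate(sets: Sequence["TrialSet"]) -> "TrialSet":
        if not sets:
            raise ValueError("no trial sets to concatenate")
        first = sets[0]
        for s in sets[1:]:
            if s.n_channels != first.n_channels or s.n_samples != first.n_samples:
                raise ValueError("trial sets have incompatible shapes")
        return TrialSet(
            np.concatenate([s.data for s in sets]),
            np.concatenate([s.labels for s in sets]),
            first.montage, first.subject_id, first.session_id, first.window,
        )


@dataclass(frozen=True)
class SyntheticProfile:
    """Parameters of the synthetic motor-imagery EEG family.

    ``class_channel_map`` gives the informative channels (1-based montage ids)
    per class; ``band_specs`` maps each class to (center Hz, bandwidth Hz,
    ERD depth in [0,1]).  ``snr_db`` is the band-limited rhythm power over the
    broadband background power on an informative channel.  ``mixing_strength``
    scales a per-subject random orthonormal channel rotation;
    ``drift_per_session`` scales an additional rotation applied to session 2.
    ``band_jitter_hz`` is the standard deviation of the per-subject shift of
    the mu peak (individual peak frequencies differ across subjects; higher
    bands shift proportionally).  ``depth_jitter`` scales per-subject,
    per-class variation of the ERD depth: subjects express imagery classes
    with different strengths.
    """

    class_channel_map: Dict[int, Tuple[int, ...]]
    band_specs: Dict[int, Tuple[float, float, float]]
    snr_db: float = 5.0
    subject_seed: int = 0
    mixing_strength: float = 0.3
    drift_per_session: float = 0.1
    band_jitter_hz: float = 0.75
    depth_jitter: float = 0.0

    def __post_init__(self) -> None:
        for c in (1, 2, 3, 4):
            if c not in self.class_channel_map or not self.class_channel_map[c]:
                raise ValueError(f"class {c} has no informative channels")
            if c not in self.band_specs:
                raise ValueError(f"class {c} has no band definition")
            _, _, depth = self.band_specs[c]
            if not 0.0 <= depth <= 1.0:
                raise ValueError("ERD depth must lie in [0,1]")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if not 0.0 <= self.mixing_strength:
            raise ValueError("mixing_strength must be non-negative")


def default_profile(
    erd_depth: float = 0.5,
    snr_db: float = 5.0,
    mixing_strength: float = 0.3,
    drift_per_session: float = 0.1,
    depth_jitter: float = 0.3,
    subject_seed: int = 0,
) -> SyntheticProfile:
    """Sensorimotor ERD profile over the 22-channel montage.

    Hand imagery desynchronizes the contralateral mu rhythm (~11 Hz) over
    the hand knob (C3/C4 neighbourhoods); foot imagery acts on midline
    electrodes in the beta band; tongue imagery on bilateral central
    electrodes in upper beta.
    """
    return SyntheticProfile(
        class_channel_map={
            1: (6, 11, 12, 13, 17, 18),   # left hand -> right hemisphere
            2: (2, 7, 8, 9, 14, 15),      # right hand -> left hemisphere
            3: (4, 10, 16, 20),           # feet -> midline
            4: (3, 5, 9, 11),             # tongue -> bilateral central
        },
        band_specs={
            1: (11.0, 4.0, erd_depth),
            2: (11.0, 4.0, erd_depth),
            3: (22.0, 6.0, erd_depth),
            4: (26.0, 6.0, erd_depth),
        },
        snr_db=snr_db,
        subject_seed=subject_seed,
        mixing_strength=mixing_strength,
        drift_per_session=drift_per_session,
        depth_jitter=depth_jitter,
    )


@dataclass
class Cohort:
    """Subjects with per-session trial sets, playing source or target role."""

    subjects: List[Tuple[int, List[TrialSet]]]
    role: str = "source"

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("subject ids must be unique")
        if self.role not in ("source", "target"):
            raise ValueError("role must be 'source' or 'target'")

    @property
    def subject_ids(self) -> List[int]:
        return [sid for sid, _ in self.subjects]

    def sessions(self, subject_id: int) -> List[TrialSet]:
        for sid, sess in self.subjects:
            if sid == subject_id:
                return sess
        raise KeyError(f"subject {subject_id} not in cohort")

    def combined(self, subject_id: int) -> TrialSet:
        """All sessions of a subject concatenated in session order."""
        return TrialSet.concatenate(self.sessions(subject_id))


# ---------------------------------------------------------------------------
# preprocessing


def extract_window(trials: TrialSet, start_s: float, dur_s: float) -> TrialSet:
    """Cut a fixed window (seconds relative to the current window start)."""
    fs = trials.fs
    i0 = int(round(start_s * fs))
    n = int(round(dur_s * fs))
    if i0 < 0 or n <= 0 or i0 + n > trials.n_samples:
        raise ValueError(
            f"window [{start_s}, {start_s + dur_s}) s outside trial "
            f"of {trials.n_samples / fs} s"
        )
    w0 = trials.window[0] + start_s
    return TrialSet(
        trials.data[:, :, i0:i0 + n], trials.labels, trials.montage,
        trials.subject_id, trials.session_id, (w0, w0 + n / fs),
    )


def drop_channels(trials: TrialSet, mask) -> TrialSet:
    """Retain only the channels selected by ``mask`` (ascending printed index).

    ``mask`` may be a ChannelMask, a boolean vector over the montage, or a
    sequence of 1-based channel ids.
    """
    keep_ids = _mask_to_ids(mask, trials.montage)
    if not keep_ids:
        raise ValueError("channel mask selects no channels")
    rows = [trials.montage.channel_ids.index(i) for i in keep_ids]
    return TrialSet(
        trials.data[:, rows, :], trials.labels, trials.montage.subset(keep_ids),
        trials.subject_id, trials.session_id, trials.window,
    )


def _mask_to_ids(mask, montage: MontageInfo) -> List[int]:
    bits = getattr(mask, "bits", None)
    if bits is not None:
        mask = np.asarray(bits)
    mask = np.asarray(mask)
    if mask.dtype == bool or set(np.unique(mask)) <= {0, 1}:
        if mask.shape[0] == montage.n_channels and (
            mask.dtype == bool or mask.max(initial=0) <= 1
        ):
            return [cid for cid, b in zip(montage.channel_ids, mask) if b]
    return sorted(int(i) for i in mask)


# ---------------------------------------------------------------------------
# synthetic generation


def _pink_noise(rng: np.random.Generator, shape: Tuple[int, ...], fs: float) -> np.ndarray:
    """1/f-power background noise along the last axis, unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True) + 1e-12
    return x


def _narrowband(rng: np.random.Generator, shape: Tuple[int, ...], fs: float,
                center: float, bw: float) -> np.ndarray:
    """Gaussian-envelope band-limited noise (an ongoing rhythm), unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    win = np.exp(-0.5 * ((freqs - center) / (bw / 2.0)) ** 2)
    x = np.fft.irfft(spec * win, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True) + 1e-12
    return x


def _erd_envelope(n: int, fs: float, trial_s: float, depth: float) -> np.ndarray:
    """Amplitude envelope: unity at baseline/rest, sqrt(1-depth) during imagery.

    The trial mirrors the recording scheme: baseline 0-2 s, imagery 2-6 s
    (clipped to the trial length), rest afterwards, with 0.2 s cosine ramps.
    """
    t = np.arange(n) / fs
    on, off = 2.0, min(6.0, trial_s)
    ramp = 0.2
    a = np.ones(n)
    lo = np.sqrt(max(0.0, 1.0 - depth))
    rise = (t >= on) & (t < on + ramp)
    fall = (t >= off - ramp) & (t < off)
    a[(t >= on + ramp) & (t < off - ramp)] = lo
    a[rise] = 1.0 + (lo - 1.0) * 0.5 * (1 - np.cos(np.pi * (t[rise] - on) / ramp))
    a[fall] = lo + (1.0 - lo) * 0.5 * (1 - np.cos(np.pi * (t[fall] - (off - ramp)) / ramp))
    return a


def _rotation(strength: float, n: int, seed: int) -> np.ndarray:
    """Orthonormal mixing: identity at strength 0, random rotation otherwise."""
    if strength == 0.0:
        return np.eye(n)
    rng = np.random.Generator(np.random.PCG64(seed))
    a = rng.standard_normal((n, n))
    skew = (a - a.T) / (2.0 * np.sqrt(n))
    return expm(strength * skew)


def generate_subject(
    profile: SyntheticProfile,
    n_trials: int,
    fs: float = 250.0,
    trial_s: float = 7.0,
    seed: int = 0,
    session_id: int = 1,
    subject_id: int = 0,
    montage: MontageInfo | None = None,
) -> TrialSet:
    """Simulate one recording session for one subject.

    Classes are balanced up to remainder.  Every class rhythm is present on
    its channels in every trial; only the rhythm of the trial's own class is
    attenuated during the imagery interval (ERD).  Deterministic per
    (profile, seed).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    montage = montage or MontageInfo.standard_2a(fs)
    if montage.fs != fs:
        montage = MontageInfo(montage.channel_ids, montage.channel_names, fs)
    C = montage.n_channels
    n = int(round(trial_s * fs))
    rng = np.random.Generator(np.random.PCG64([seed, profile.subject_seed, session_id]))

    labels = np.tile(np.arange(1, 5), n_trials // 4 + 1)[:n_trials]
    rng.shuffle(labels)

    noise_uv = 10.0  # background RMS in microvolts
    amp = noise_uv * 10.0 ** (profile.snr_db / 20.0)

    data = noise_uv * _pink_noise(rng, (n_trials, C, n), fs)
    ch_rows = {
        c: [montage.channel_ids.index(i) for i in profile.class_channel_map[c]
            if i in montage.channel_ids]
        for c in (1, 2, 3, 4)
    }
    # per-subject traits: individual peak frequency (one proportional band
    # shift) and per-class ERD expression strength
    sub_rng = np.random.Generator(np.random.PCG64([profile.subject_seed, 0xF0]))
    delta = float(np.clip(sub_rng.normal(0.0, profile.band_jitter_hz or 1e-9),
                          -2 * profile.band_jitter_hz,
                          2 * profile.band_jitter_hz)) if profile.band_jitter_hz > 0 else 0.0
    depth_factor = {c: 1.0 for c in (1, 2, 3, 4)}
    if profile.depth_jitter > 0:
        for c in (1, 2, 3, 4):
            depth_factor[c] = float(np.clip(
                sub_rng.normal(1.0, profile.depth_jitter), 0.4, 1.6))
    for c in (1, 2, 3, 4):
        rows = ch_rows[c]
        if not rows:
            continue
        center, bw, depth = profile.band_specs[c]
        center = center * (1.0 + delta / 11.0)
        depth = float(np.clip(depth * depth_factor[c], 0.0, 0.95))
        rhythm = amp * _narrowband(rng, (n_trials, len(rows), n), fs, center, bw)
        env = _erd_envelope(n, fs, trial_s, depth)
        mod = np.where((labels == c)[:, None, None], env[None, None, :], 1.0)
        data[:, rows, :] += rhythm * mod

    mix = _rotation(profile.mixing_strength, C, profile.subject_seed)
    if session_id > 1:
        drift = _rotation(
            profile.drift_per_session, C, profile.subject_seed * 7919 + session_id
        )
        mix = drift @ mix
    data = np.einsum("ij,njt->nit", mix, data)

    return TrialSet(
        data.astype(np.float32), labels, montage,
        subject_id=subject_id, session_id=session_id, window=(0.0, trial_s),
    )


def make_cohort(
    n_source: int,
    n_target: int,
    profile_family: SyntheticProfile | Callable[[int], SyntheticProfile] | None = None,
    seed: int = 0,
    n_trials: int = 288,
    n_sessions: int = 2,
    fs: float = 250.0,
    trial_s: float = 7.0,
) -> Tuple[Cohort, Cohort]:
    """Simulate source and target cohorts with inter-subject shift.

    Subject ids run 1..n_source for sources and n_source+1.. for targets,
    mirroring the benchmark's grouping (sources 1-6, targets 7-9 for (6, 3)).
    Each subject records ``n_sessions`` sessions of ``n_trials`` trials.
    """
    if n_source < 1 or n_target < 1:
        raise ValueError("need at least one source and one target subject")
    base = profile_family if profile_family is not None else default_profile()

    def profile_for(subject: int) -> SyntheticProfile:
        if callable(base):
            prof = base(subject)
        else:
            prof = base
        return replace(prof, subject_seed=seed * 100003 + subject)

    def build(ids: List[int], role: str) -> Cohort:
        subjects = []
        for sid in ids:
            prof = profile_for(sid)
            sess = [
                generate_subject(
                    prof, n_trials, fs=fs, trial_s=trial_s,
                    seed=seed, session_id=k, subject_id=sid,
                )
                for k in range(1, n_sessions + 1)
            ]
            subjects.append((sid, sess))
        return Cohort(subjects, role=role)

    source = build(list(range(1, n_source + 1)), "source")
    target = build(list(range(n_source + 1, n_source + n_target + 1)), "target")
    return source, target


# ---------------------------------------------------------------------------
# GDF input (optional real-data path)

# cue annotation codes of the 2a recordings
_GDF_CLASS_CODES = {"769": 1, "770": 2, "771": 3, "772": 4}


def load_gdf_session(path, montage: MontageInfo | None = None,
                     trial_s: float = 7.0) -> TrialSet:
    """Read a 4-class motor-imagery GDF recording into full trials.

    Trials are aligned to cue onset minus 2 s (so the cube covers the full
    7 s scheme: 2 s baseline, imagery from cue) and labelled 1..4 from the
    cue annotation codes.  EOG channels, if present, are dropped.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading GDF files requires the 'mne' package") from exc

    try:
        raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"unreadable GDF file {path}: {exc}") from exc

    eeg_picks = [i for i, name in enumerate(raw.ch_names) if "EOG" not in name.upper()]
    fs = float(raw.info["sfreq"])
    montage = montage or MontageInfo.standard_2a(fs)
    if len(eeg_picks) != montage.n_channels:
        raise ValueError(
            f"expected {montage.n_channels} EEG channels, found {len(eeg_picks)}"
        )

    onsets, labels = [], []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc in _GDF_CLASS_CODES:
            onsets.append(onset)
            labels.append(_GDF_CLASS_CODES[desc])
    if not labels:
        raise ValueError(f"no trials: {path} has no cue annotations")

    sig = raw.get_data(picks=eeg_picks) * 1e6  # volts -> microvolts
    n = int(round(trial_s * fs))
    cubes, keep = [], []
    for onset, lab in zip(onsets, labels):
        i0 = int(round((onset - 2.0) * fs))
        if i0 < 0 or i0 + n > sig.shape[1]:
            continue
        cubes.append(sig[:, i0:i0 + n])
        keep.append(lab)
    if not cubes:
        raise ValueError(f"no trials: all cue windows fall outside {path}")
    return TrialSet(
        np.stack(cubes), np.asarray(keep), montage, window=(0.0, trial_s)
    )


# ---------------------------------------------------------------------------
# persistence


def save_cohort(path, cohorts: Dict[str, Cohort]) -> None:
    """Write cohorts to an HDF5 container (role -> subject -> session)."""
    import h5py

    with h5py.File(path, "w") as f:
        for role, cohort in cohorts.items():
            g = f.create_group(role)
            for sid, sessions in cohort.subjects:
                sg = g.create_group(f"subject{sid}")
                for ts in sessions:
                    dg = sg.create_group(f"session{ts.session_id}")
                    dg.create_dataset("data", data=ts.data, compression="gzip")
                    dg.create_dataset("labels", data=ts.labels)
                    dg.attrs["fs"] = ts.fs
                    dg.attrs["subject"] = sid
                    dg.attrs["session"] = ts.session_id
                    dg.attrs["window"] = list(ts.window)
                    dg.attrs["channel_ids"] = list(ts.montage.channel_ids)
                    dg.attrs["channel_names"] = list(ts.montage.channel_names)


def load_cohort(path) -> Dict[str, Cohort]:
    import h5py

    out: Dict[str, Cohort] = {}
    with h5py.File(path, "r") as f:
        for role in f:
            subjects = []
            for sname in sorted(f[role], key=lambda s: int(s.replace("subject", ""))):
                sid = int(sname.replace("subject", ""))
                sessions = []
                for dname in sorted(f[role][sname]):
                    dg = f[role][sname][dname]
                    montage = MontageInfo(
                        tuple(int(i) for i in dg.attrs["channel_ids"]),
                        tuple(str(n) for n in dg.attrs["channel_names"]),
                        float(dg.attrs["fs"]),
                    )
                    sessions.append(TrialSet(
                        dg["data"][()], dg["labels"][()], montage,
                        subject_id=sid, session_id=int(dg.attrs["session"]),
                        window=tuple(dg.attrs["window"]),
                    ))
                subjects.append((sid, sessions))
            out[role] = Cohort(subjects, role=role)
    return out
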