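"""Ground-truthed synthetic multi-state LFP studies.

Each disease state (naive, mild, moderate) is realized as a stable
5-channel VAR process.  Channel dynamics place AR(2) resonances at the
network's two characteristic frequencies (15 and 35 Hz by default), so
every channel shows the two-peak spectrum typical of this montage.
Directed couplings are damped-cosine FIR kernels on the off-diagonal
coefficients, tuned to a center frequency so that the induced spectral
GC concentrates in the corresponding band; their magnitude is scaled
per state by configurable multipliers, which is how between-state
connectivity changes are planted.

The default coupling set mirrors the headline disease pattern: the
descending cortico-subthalamic drive (L-PMC to L-STN, low band)
weakens at disease onset, the ascending drive (L-STN to L-PMC, high
band) strengthens, and the right-cortical M1-to-PMC drive (high band)
strengthens across both transitions.

On top of the VAR signal the generator layers 1/f^alpha background
noise, a line component at 60 Hz with its 2nd/3rd harmonics, and —
with small probability per recording — a whole-recording amplitude
inflation emulating movement-artifact trials.  Everything is driven by
one seed, so (spec, seed) reproduces a study bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .granger import VARModel, STABILITY_MARGIN
from .preprocess import Recording, MONTAGE, STATES

__all__ = [
    "CouplingSpec",
    "NuisanceSpec",
    "StudySpec",
    "GroundTruth",
    "StudyDataset",
    "place_oscillator_poles",
    "build_state_var",
    "simulate_recording",
    "generate_study",
    "default_couplings",
    "default_study_spec",
]

TRANSITIONS = (("naive", "mild"), ("naive", "moderate"), ("mild", "moderate"))


def transition_name(a: str, b: str) -> str:
    return f"{a}->{b}"


@dataclass(frozen=True)
class CouplingSpec:
    """A planted directed coupling between two montage channels.

    strength is the peak magnitude response of the coupling kernel; the
    per-state multiplier scales it, so sign(multiplier difference) is
    the ground-truth direction of the between-state GC change.
    """

    source: str
    target: str
    center_freq: float
    strength: float
    state_multipliers: dict[str, float]

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("coupling source and target must differ")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if any(m < 0 for m in self.state_multipliers.values()):
            raise ValueError("state multipliers must be >= 0")


@dataclass(frozen=True)
class NuisanceSpec:
    """Additive nuisance components layered on the clean VAR signal.

    pink_amp and line_amp are relative to each channel's clean signal
    standard deviation.  artifact_trial_prob is the per-recording
    probability of whole-recording amplitude inflation by
    artifact_gain.
    """

    pink_exponent: float = 1.0
    pink_amp: float = 0.4
    line_freq: float = 60.0
    line_amp: float = 0.3
    artifact_trial_prob: float = 0.05
    artifact_gain: float = 8.0

    def __post_init__(self) -> None:
        if self.pink_exponent < 0:
            raise ValueError("pink_exponent must be >= 0")
        if not 0.0 <= self.artifact_trial_prob <= 1.0:
            raise ValueError("artifact_trial_prob must be in [0, 1]")


@dataclass
class StudySpec:
    """Design of a synthetic multi-state, multi-session study."""

    channels: tuple[str, ...] = MONTAGE
    fs: float = 400.0
    states: tuple[str, ...] = STATES
    sessions_per_state: tuple[int, ...] = (15, 16, 5)
    session_duration: float = 300.0
    couplings: tuple[CouplingSpec, ...] = ()
    oscillator_freqs: tuple[float, ...] = (15.0, 35.0)
    pole_radius: float = 0.94
    coupling_lags: int = 6
    noise: NuisanceSpec = field(default_factory=NuisanceSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if isinstance(self.sessions_per_state, int):
            self.sessions_per_state = tuple(
                [self.sessions_per_state] * len(self.states))
        if len(self.sessions_per_state) != len(self.states):
            raise ValueError("need one session count per state")
        nyq = self.fs / 2.0
        for f in self.oscillator_freqs:
            if not 0 < f < nyq:
                raise ValueError(f"oscillator at {f} Hz out of (0, Nyquist)")
        for c in self.couplings:
            if not 0 < c.center_freq < nyq:
                raise ValueError("coupling center frequency out of band")
            if c.source not in self.channels or c.target not in self.channels:
                raise ValueError("coupling references unknown channel")
        if self.fs <= 2 * max([self.noise.line_freq, *self.oscillator_freqs]):
            raise ValueError("fs must exceed twice the highest planted tone")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream scoring.

    expected_signs maps (source, target, band, transition) -> {-1, 0, +1}
    for the bands the couplings live in; models holds the per-state
    generating VAR; rescales records any uniform coupling shrinkage
    applied to restore stability.
    """

    models: dict[str, VARModel]
    expected_signs: dict[tuple[str, str, str, str], int]
    rescales: dict[str, float]
    artifact_sessions: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        signs = {"|".join(k): v for k, v in self.expected_signs.items()}
        return json.dumps({
            "expected_signs": signs,
            "rescales": self.rescales,
            "artifact_sessions": self.artifact_sessions,
        })


@dataclass
class StudyDataset:
    spec: StudySpec
    recordings: list[Recording]


def place_oscillator_poles(center_freq: float, pole_radius: float,
                           fs: float) -> tuple[float, float]:
    """AR(2) coefficients (a1, a2) putting a complex pole pair at
    ``pole_radius * exp(+-i 2 pi f0 / fs)``: a1 = 2 r cos(2 pi f0/fs),
    a2 = -r^2.  The AR(2) spectrum then peaks near f0."""
    if not 0 <= pole_radius < 1:
        raise ValueError("pole_radius must lie in [0, 1) for stability")
    if not 0 < center_freq < fs / 2:
        raise ValueError("center_freq must lie in (0, fs/2)")
    if pole_radius == 0:
        return 0.0, 0.0
    a1 = 2.0 * pole_radius * np.cos(2.0 * np.pi * center_freq / fs)
    a2 = -pole_radius**2
    return float(a1), float(a2)


def _coupling_kernel(center_freq: float, n_lags: int, fs: float,
                     decay: float = 0.9,
                     suppress_freqs: tuple[float, ...] = ()) -> np.ndarray:
    """Band-selective FIR coupling kernel, unit peak magnitude response.

    A damped cosine at the center frequency (resonant around it) is
    convolved with a unit-circle zero pair at each frequency in
    ``suppress_freqs`` (the other channel resonances), so that the
    coupling transfers the source's oscillation at the center frequency
    but not its other spectral peaks.  Normalizing to unit peak gain
    makes ``strength`` the peak cross-transfer gain.
    """
    k = np.arange(1, n_lags + 1)
    c = decay**k * np.cos(2.0 * np.pi * center_freq * k / fs)
    for f_z in suppress_freqs:
        zero = np.array([1.0, -2.0 * np.cos(2.0 * np.pi * f_z / fs), 1.0])
        c = np.convolve(c, zero)
    w, h = scipy.signal.freqz(np.concatenate([[0.0], c]), worN=1024, fs=fs)
    return c / np.max(np.abs(h))


def band_of_frequency(f: float) -> str | None:
    """Which analysis band a planted center frequency falls in."""
    if 5.0 <= f <= 20.0:
        return "peakA"
    if 25.0 <= f <= 45.0:
        return "peakB"
    return None


def build_state_var(spec: StudySpec, state: str,
                    max_rescale_iter: int = 40) -> tuple[VARModel, float]:
    """Construct the stable generating VAR for one state.

    Diagonal blocks hold the channel oscillators (one AR(2) resonance
    per oscillator frequency, convolved); off-diagonal entries hold the
    coupling kernels scaled by strength x state multiplier.  If the
    assembled model is unstable, all couplings are shrunk uniformly
    (factor 0.9 per iteration) until the companion spectral radius drops
    below 0.98; the final shrink factor is returned.
    """
    if state not in spec.states:
        raise ValueError(f"unknown state {state!r}")
    n = len(spec.channels)
    # per-channel AR polynomial: product of the oscillator AR(2) factors
    poly = np.array([1.0])
    for f0 in spec.oscillator_freqs:
        a1, a2 = place_oscillator_poles(f0, spec.pole_radius, spec.fs)
        poly = np.convolve(poly, [1.0, -a1, -a2])
    p_diag = len(poly) - 1
    # coupling kernels gain 2 lags per suppressed resonance (see below)
    kern_len = spec.coupling_lags + 2 * max(0, len(spec.oscillator_freqs) - 1)
    p = max(p_diag, kern_len)
    idx = {ch: i for i, ch in enumerate(spec.channels)}

    diag = np.zeros((p, n, n))
    for j in range(p_diag):
        diag[j][np.diag_indices(n)] = -poly[j + 1]

    # suppress the source's other resonances so the coupling stays in band
    cross = np.zeros((p, n, n))
    for c in spec.couplings:
        mult = c.state_multipliers.get(state, 1.0)
        amp = c.strength * mult
        if amp == 0:
            continue
        others = tuple(f for f in spec.oscillator_freqs
                       if abs(f - c.center_freq) > 5.0)
        kern = _coupling_kernel(c.center_freq, spec.coupling_lags, spec.fs,
                                suppress_freqs=others)
        cross[:len(kern), idx[c.target], idx[c.source]] += amp * kern

    scale = 1.0
    for _ in range(max_rescale_iter):
        model = VARModel(diag + scale * cross, np.eye(n), fs=spec.fs)
        if model.spectral_radius() < 0.98:
            return model, scale
        scale *= 0.9
    raise RuntimeError(
        f"could not stabilize the state VAR for {state!r} after "
        f"{max_rescale_iter} coupling rescales"
    )


def _simulate_var_loop(coeffs: np.ndarray, innov: np.ndarray) -> np.ndarray:
    p, n, _ = coeffs.shape
    T = innov.shape[0]
    # flattened lag weights: x_t = A_flat @ [x_{t-1}; ...; x_{t-p}] + e_t
    A_flat = np.concatenate(list(coeffs), axis=1)
    x = np.zeros((T, n))
    buf = np.zeros(n * p)
    for t in range(T):
        xt = A_flat @ buf + innov[t]
        x[t] = xt
        buf = np.concatenate((xt, buf[:-n]))
    return x


def _simulate_var_core(coeffs: np.ndarray, innov: np.ndarray) -> np.ndarray:
    # scalar-loop formulation, written for jit compilation
    p, n, _ = coeffs.shape
    T = innov.shape[0]
    x = np.zeros((T, n))
    for t in range(T):
        for a in range(n):
            x[t, a] = innov[t, a]
        jmax = p if t >= p else t
        for j in range(1, jmax + 1):
            for a in range(n):
                s = 0.0
                for b in range(n):
                    s += coeffs[j - 1, a, b] * x[t - j, b]
                x[t, a] += s
    return x


try:  # optional jit of the hot simulation loop
    import numba

    _simulate_var_jit = numba.njit(cache=False)(_simulate_var_core)
except Exception:  # pragma: no cover - numba genuinely absent
    _simulate_var_jit = None


def _simulate_var(model: VARModel, T: int, rng: np.random.Generator) -> np.ndarray:
    p, n = model.order, model.n_channels
    chol = np.linalg.cholesky(model.sigma)
    innov = rng.standard_normal((T, n)) @ chol.T
    offdiag = model.coeffs.copy()
    for j in range(p):
        np.fill_diagonal(offdiag[j], 0.0)
    if not np.any(offdiag):
        # uncoupled channels: filter each one independently (fast path)
        x = np.empty((T, n))
        for c in range(n):
            a = np.concatenate([[1.0], -model.coeffs[:, c, c]])
            x[:, c] = scipy.signal.lfilter([1.0], a, innov[:, c])
        return x
    if _simulate_var_jit is not None:
        return _simulate_var_jit(model.coeffs, innov)
    return _simulate_var_loop(model.coeffs, innov)


def _pink_noise(rng: np.random.Generator, T: int, n: int,
                exponent: float) -> np.ndarray:
    """1/f^alpha noise by spectral shaping of white noise, unit variance
    per channel."""
    white = rng.standard_normal((T, n))
    spec = np.fft.rfft(white, axis=0)
    f = np.fft.rfftfreq(T)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * gain[:, None], n=T, axis=0)
    sd = shaped.std(axis=0)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate_recording(model: VARModel, duration: float, fs: float,
                       nuisance: NuisanceSpec | None = None,
                       seed: int | np.random.SeedSequence = 0) -> Recording:
    """Simulate one recording from a stable VAR, with burn-in discarded
    and nuisance components added.

    The returned Recording carries an ``artifact`` attribute marking
    whether whole-recording amplitude inflation was applied.  Identical
    (model, seed) pairs reproduce identical samples.
    """
    if nuisance is None:
        nuisance = NuisanceSpec()
    if not model.is_stable(STABILITY_MARGIN):
        raise ValueError("refusing to simulate from an unstable VAR")
    T = int(np.floor(duration * fs))
    if T < 10 * model.order:
        raise ValueError("duration too short: need >= 10 x model order samples")
    burn = max(1000, 10 * model.order)
    rng = np.random.default_rng(seed)
    x = _simulate_var(model, T + burn, rng)[burn:]
    sd = x.std(axis=0)

    if nuisance.pink_amp > 0:
        x = x + nuisance.pink_amp * sd * _pink_noise(
            rng, T, model.n_channels, nuisance.pink_exponent)
    if nuisance.line_amp > 0:
        t = np.arange(T) / fs
        for c in range(model.n_channels):
            line = np.zeros(T)
            for harm, rel in ((1, 1.0), (2, 0.3), (3, 0.15)):
                f_h = harm * nuisance.line_freq
                if f_h >= fs / 2:
                    continue
                phase = rng.uniform(0, 2 * np.pi)
                line += rel * np.sin(2 * np.pi * f_h * t + phase)
            x[:, c] = x[:, c] + nuisance.line_amp * sd[c] * line

    artifact = bool(rng.uniform() < nuisance.artifact_trial_prob)
    if artifact:
        x = x * nuisance.artifact_gain

    rec = Recording(data=x, fs=fs, channels=MONTAGE[:model.n_channels]
                    if model.n_channels <= len(MONTAGE)
                    else tuple(f"ch{i}" for i in range(model.n_channels)))
    rec.artifact = artifact
    return rec


def generate_study(spec: StudySpec) -> tuple[StudyDataset, GroundTruth]:
    """Generate one recording per (state, session) plus ground truth."""
    models: dict[str, VARModel] = {}
    rescales: dict[str, float] = {}
    for state in spec.states:
        models[state], rescales[state] = build_state_var(spec, state)

    signs: dict[tuple[str, str, str, str], int] = {}
    for c in spec.couplings:
        band = band_of_frequency(c.center_freq)
        if band is None:
            continue
        for a, b in TRANSITIONS:
            if a not in spec.states or b not in spec.states:
                continue
            d = (c.state_multipliers.get(b, 1.0)
                 - c.state_multipliers.get(a, 1.0))
            signs[(c.source, c.target, band, transition_name(a, b))] = (
                int(np.sign(d)))

    truth = GroundTruth(models=models, expected_signs=signs,
                        rescales=rescales)
    recordings: list[Recording] = []
    root = np.random.SeedSequence(spec.seed)
    state_seeds = root.spawn(len(spec.states))
    for s_idx, state in enumerate(spec.states):
        session_seeds = state_seeds[s_idx].spawn(spec.sessions_per_state[s_idx])
        for k in range(spec.sessions_per_state[s_idx]):
            rec = simulate_recording(models[state], spec.session_duration,
                                     spec.fs, spec.noise, session_seeds[k])
            rec.state = state
            rec.session_id = f"{state}-s{k:02d}"
            rec.channels = tuple(spec.channels)
            if rec.artifact:
                truth.artifact_sessions.append(rec.session_id)
            recordings.append(rec)
    return StudyDataset(spec=spec, recordings=recordings), truth


def default_couplings() -> tuple[CouplingSpec, ...]:
    """The planted disease pattern: descending low-band drive weakens at
    onset, ascending high-band drive strengthens, right-cortical
    M1-to-PMC drive strengthens across both transitions."""
    return (
        CouplingSpec("L-PMC", "L-STN", 15.0, 0.35,
                     {"naive": 1.0, "mild": 0.35, "moderate": 0.35}),
        CouplingSpec("L-STN", "L-PMC", 35.0, 0.35,
                     {"naive": 0.35, "mild": 1.0, "moderate": 1.0}),
        CouplingSpec("R-M1", "R-PMC", 35.0, 0.35,
                     {"naive": 0.35, "mild": 1.0, "moderate": 1.6}),
    )


def default_study_spec(**overrides) -> StudySpec:
    """The default synthetic study: 5-channel montage at 400 Hz, session
    counts mirroring the experimental design (15/16/5), 300 s sessions,
    oscillators at 15 and 35 Hz, and the default planted couplings."""
    kw = dict(couplings=default_couplings())
    kw.update(overrides)
    return StudySpec(**kw)
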