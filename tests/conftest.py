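import numpy as np
import pytest

from lfpgc import granger, preprocess, synthgen


def make_recording(data, fs=400.0, channels=None, state="naive",
                   session_id="sess"):
    n = data.shape[1]
    if channels is None:
        channels = preprocess.MONTAGE[:n] if n <= 5 else tuple(
            f"ch{i}" for i in range(n))
    return preprocess.Recording(data=data, fs=fs, channels=channels,
                                state=state, session_id=session_id)


def tone_recording(freq, fs=400.0, duration=10.0, n_channels=2, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq * t)
    return make_recording(np.tile(sig[:, None], (1, n_channels)), fs=fs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


def _geweke_minimum_phase(model):
    """Hypothesis of the Geweke integral identity: after the
    normalization transform, the target's own transfer function must be
    minimum-phase in each direction.  Equivalently the polynomial
    A_ss(z) - (Sigma_ts / Sigma_tt) A_ts(z) has no roots inside the
    closed unit disk.  Rare strongly-fed-back models violate this, and
    for them the spectral average genuinely falls below the time-domain
    GC."""
    for tgt, src in ((0, 1), (1, 0)):
        rho = model.sigma[tgt, src] / model.sigma[tgt, tgt]
        a_ss = np.array([1.0] + [-model.coeffs[j][src, src]
                                 for j in range(model.order)])
        a_ts = np.array([0.0] + [-model.coeffs[j][tgt, src]
                                 for j in range(model.order)])
        phi = a_ss - rho * a_ts
        roots = np.roots(phi[::-1])
        if np.any(np.abs(roots) <= 1.0):
            return False
    return True


@pytest.fixture(scope="session")
def random_stable_var2():
    """A deterministic collection of 20 random stable bivariate VAR(2)
    models with correlated innovations, sampled within the hypotheses
    of the Geweke spectral-integral identity (minimum-phase normalized
    transfer)."""
    gen = np.random.default_rng(7)
    models = []
    while len(models) < 20:
        A = gen.normal(scale=0.4, size=(2, 2, 2))
        c = gen.uniform(-0.6, 0.6)
        sigma = np.array([[1.0, c], [c, 1.0]])
        m = granger.VARModel(A, sigma, fs=1.0)
        if (m.is_stable() and m.spectral_radius() < 0.95
                and _geweke_minimum_phase(m)):
            models.append(m)
    return models


@pytest.fixture(scope="session")
def coupled_segment():
    """One 60 s conditioned, normalized segment from the default mild-state
    generating model (planted couplings present), reused across tests."""
    spec = synthgen.default_study_spec()
    model, _ = synthgen.build_state_var(spec, "mild")
    rec = synthgen.simulate_recording(model, 60.0, spec.fs, spec.noise,
                                      seed=11)
    rec.state, rec.session_id = "mild", "fix"
    rec = preprocess.notch(preprocess.bandpass(rec), (60.0, 120.0))
    seg = preprocess.split_segments(rec, 60.0)[0]
    return preprocess.normalize(seg)
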