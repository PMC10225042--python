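"""Seeded synthetic generator for the three airway-protective maneuvers.

No public recordings of the study maneuvers exist, so this module synthesizes
labeled waveforms carrying the qualitative acoustic structure reported for
each class, to exercise the full pipeline end to end:

* **voluntary cough** — burst-like onset (broadband noise with a sub-800 Hz
  oscillation), decaying turbulent frication, and a non-mandatory voiced coda
  (probability 0.5) that lifts the amplitude contour again near the offset;
  the amplitude contour is therefore high-low(-high), i.e. convex.
* **throat clearing** — weak onset followed by one sustained low-frequency
  (100-300 Hz) amplitude-modulated oscillatory fragment that rises then falls,
  giving a concave amplitude contour, low kurtosis and low sample entropy.
* **induced reflexive cough** — a very brief (5-15 ms) strong onset pulse and
  elevated, bursty frication extending well above 800 Hz, giving high
  kurtosis and a strongly convex amplitude contour.

A channel model emulates the skin-contact (neck-mounted) microphone, which
attenuates high-frequency components relative to the free-standing
microphone; it is a plain low-pass filter.

These waveforms are acoustic caricatures, not vocal-tract simulations: they
reproduce the contour shapes, band-energy balances and histogram statistics
that the analysis measures, nothing physiological.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sfft
from scipy import signal as ssig

from .signal_io import (
    MANEUVER_CLASSES,
    Waveform,
    make_cohort_table,
)

DEFAULT_RATE = 44100.0


@dataclass(frozen=True)
class ManeuverSpec:
    """Parametric recipe for one synthetic maneuver token.

    Gains are linear amplitude factors relative to each other; the pipeline's
    energy normalization removes the overall scale anyway.  ``seed`` fixes
    the PCG64 stream, so equal specs generate bit-identical waveforms.
    """

    maneuver: str
    duration_s: float
    onset_len_s: float
    onset_gain: float
    fric_lo_hz: float
    fric_hi_hz: float
    fric_gain: float
    fric_decay: float          # amplitude decay rate of the frication, 1/s
    fric_am_depth: float       # bursty amplitude modulation of the frication
    lfo_f0_hz: float           # low-frequency oscillation during onset/body
    lfo_gain: float
    lfo_am_depth: float
    body_rise_fall: bool       # hann (rise-then-fall) body envelope
    coda_prob: float
    coda_f0_hz: float
    coda_len_s: float
    coda_gain: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maneuver not in MANEUVER_CLASSES:
            raise ValueError(f"unknown maneuver class {self.maneuver!r}")
        if self.duration_s <= self.onset_len_s + self.coda_len_s:
            raise ValueError("duration must exceed onset length + coda length")
        for name in ("onset_gain", "fric_gain", "lfo_gain", "coda_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.coda_prob <= 1.0:
            raise ValueError("coda_prob must lie in [0, 1]")


#: Class defaults.  Durations follow the typical maneuver lengths the three
#: classes exhibit (voluntary cough ~0.39 s, throat clearing ~0.46 s,
#: reflexive cough ~0.31 s); spectral extents follow the qualitative class
#: descriptions in the module docstring.
CLASS_DEFAULTS: dict[str, ManeuverSpec] = {
    "voluntary_cough": ManeuverSpec(
        maneuver="voluntary_cough", duration_s=0.39,
        onset_len_s=0.07, onset_gain=1.0,
        fric_lo_hz=400.0, fric_hi_hz=3000.0, fric_gain=0.28, fric_decay=6.0,
        fric_am_depth=0.0,
        lfo_f0_hz=250.0, lfo_gain=0.7, lfo_am_depth=0.0,
        body_rise_fall=False,
        coda_prob=0.5, coda_f0_hz=150.0, coda_len_s=0.12, coda_gain=0.4,
    ),
    "throat_clearing": ManeuverSpec(
        maneuver="throat_clearing", duration_s=0.46,
        onset_len_s=0.03, onset_gain=0.25,
        fric_lo_hz=400.0, fric_hi_hz=2500.0, fric_gain=0.12, fric_decay=0.0,
        fric_am_depth=0.0,
        lfo_f0_hz=180.0, lfo_gain=1.0, lfo_am_depth=0.4,
        body_rise_fall=True,
        coda_prob=0.0, coda_f0_hz=150.0, coda_len_s=0.0, coda_gain=0.0,
    ),
    "reflexive_cough": ManeuverSpec(
        maneuver="reflexive_cough", duration_s=0.31,
        onset_len_s=0.010, onset_gain=5.0,
        fric_lo_hz=800.0, fric_hi_hz=8000.0, fric_gain=0.45, fric_decay=4.0,
        fric_am_depth=1.0,
        lfo_f0_hz=0.0, lfo_gain=0.0, lfo_am_depth=0.0,
        body_rise_fall=False,
        coda_prob=0.3, coda_f0_hz=160.0, coda_len_s=0.08, coda_gain=0.3,
    ),
}


@dataclass(frozen=True)
class ChannelModel:
    """Microphone channel: identity, or tissue-attenuated (skin contact)."""

    kind: str = "free_standing"
    cutoff_hz: float = 1500.0
    order: int = 8

    def __post_init__(self) -> None:
        if self.kind not in ("free_standing", "skin_contact"):
            raise ValueError(f"unknown channel kind {self.kind!r}")


def default_spec(maneuver: str, **overrides) -> ManeuverSpec:
    """Class default spec, optionally with field overrides."""
    return replace(CLASS_DEFAULTS[maneuver], **overrides)


def _band_noise(n: int, rate: float, lo: float, hi: float, rng) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi) Hz via the DCT."""
    white = rng.standard_normal(n)
    coeffs = sfft.dct(white, type=2, norm="ortho")
    freqs = np.arange(n) * rate / (2.0 * n)
    hi = min(hi, rate / 2.0)
    coeffs[(freqs < lo) | (freqs >= hi)] = 0.0
    x = sfft.idct(coeffs, type=2, norm="ortho")
    rms = np.sqrt(np.mean(np.square(x)))
    return x / rms if rms > 0 else x


def _attack_decay(n: int, rate: float, attack_s: float, decay: float) -> np.ndarray:
    """Envelope: linear attack over ``attack_s`` then exp(-decay * t)."""
    t = np.arange(n) / rate
    n_att = max(1, int(round(attack_s * rate)))
    env = np.exp(-decay * np.maximum(t - attack_s, 0.0))
    env[:n_att] *= np.linspace(0.0, 1.0, n_att, endpoint=False) + 1.0 / n_att
    return env


def generate(spec: ManeuverSpec, rate: float = DEFAULT_RATE):
    """Synthesize one maneuver token.

    Returns ``(Waveform, annotation)`` where the annotation maps fragment
    names (``onset``, ``frication``, ``coda``) to half-open sample ranges
    that partition ``[0, N)``; ``coda`` is ``None`` when absent.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * rate))
    n_on = int(round(spec.onset_len_s * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)

    # --- onset: short broadband burst with sharp attack
    if n_on > 0 and spec.onset_gain > 0:
        burst = _band_noise(n_on, rate, 400.0, 8000.0, rng)
        burst *= _attack_decay(n_on, rate, 0.002, 3.0 / max(spec.onset_len_s, 1e-3))
        x[:n_on] += spec.onset_gain * burst

    # --- low-frequency oscillation: during the onset for a cough burst,
    #     over the whole body (rise-fall AM envelope) for a throat clearing
    if spec.lfo_gain > 0 and spec.lfo_f0_hz > 0:
        f0 = spec.lfo_f0_hz * np.exp(rng.normal(0.0, 0.05))
        osc = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        if spec.lfo_am_depth > 0:
            am_f = rng.uniform(18.0, 30.0)
            osc *= 1.0 + spec.lfo_am_depth * np.sin(2 * np.pi * am_f * t)
        if spec.body_rise_fall:
            env = np.square(np.sin(np.pi * t / spec.duration_s))  # hann-shaped
        else:
            env = np.zeros(n)
            env[:n_on] = _attack_decay(n_on, rate, 0.004,
                                       2.0 / max(spec.onset_len_s, 1e-3))
        x += spec.lfo_gain * osc * env

    # --- frication: band-limited turbulence after the onset
    n_fric = n - n_on
    if n_fric > 8 and spec.fric_gain > 0:
        fric = _band_noise(n_fric, rate, spec.fric_lo_hz, spec.fric_hi_hz, rng)
        if spec.fric_am_depth > 0:
            # bursty modulation by rectified slow noise -> heavy-tailed frames
            slow = _band_noise(n_fric, rate, 0.0, 60.0, rng)
            fric *= 1.0 + spec.fric_am_depth * np.abs(slow)
        env = np.exp(-spec.fric_decay * (t[:n_fric]))
        x[n_on:] += spec.fric_gain * fric * env

    # --- non-mandatory voiced coda: quasi-periodic low-frequency fragment
    n_coda = int(round(spec.coda_len_s * rate))
    has_coda = n_coda > 0 and rng.random() < spec.coda_prob
    if has_coda:
        tc = t[:n_coda]
        f0 = spec.coda_f0_hz * np.exp(rng.normal(0.0, 0.05))
        voiced = np.sin(2 * np.pi * f0 * tc + rng.uniform(0, 2 * np.pi))
        voiced += 0.3 * np.sin(2 * np.pi * 2 * f0 * tc)
        voiced *= np.square(np.sin(np.pi * tc / spec.coda_len_s))
        x[n - n_coda:] += spec.coda_gain * voiced

    annotation = {
        "onset": (0, n_on),
        "frication": (n_on, n - n_coda if has_coda else n),
        "coda": (n - n_coda, n) if has_coda else None,
    }
    return Waveform(samples=x, rate=rate), annotation


def apply_channel(w: Waveform, ch: ChannelModel) -> Waveform:
    """Apply the microphone channel model.

    ``free_standing`` is the identity.  ``skin_contact`` low-pass filters at
    ``cutoff_hz`` (zero-phase Butterworth, >= 40 dB in the stop band),
    emulating the attenuation of high-frequency components propagating
    through neck tissue.  Re-normalization is left to the pipeline.
    """
    if ch.kind == "free_standing":
        return w
    if not ch.cutoff_hz < w.rate / 2.0:
        raise ValueError("skin-contact cutoff must be below Nyquist")
    sos = ssig.butter(ch.order, ch.cutoff_hz, btype="low", fs=w.rate, output="sos")
    return Waveform(samples=ssig.sosfiltfilt(sos, w.samples), rate=w.rate)


def generate_cohort(
    n_subjects: int,
    tokens_per_class: int,
    classes=MANEUVER_CLASSES,
    channel: ChannelModel | None = None,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
):
    """Generate a labeled synthetic cohort.

    Per-subject random effects (lognormal multipliers, sigma = 0.15, on gain
    and duration) are drawn once per subject and applied to every token of
    that subject; tokens add a smaller (sigma = 0.05) jitter.  Reflexive
    tokens alternate the two induction-method labels within each subject, so
    an urge-vs-suppressed contrast is a true null by construction.

    Returns ``(waveforms, cohort)``: a dict mapping file id to
    ``(Waveform, annotation)`` and a validated cohort metadata table.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if channel is None:
        channel = ChannelModel()
    root = np.random.SeedSequence(seed)
    subj_seqs = root.spawn(n_subjects)
    waveforms: dict[str, tuple[Waveform, dict]] = {}
    rows = []
    mic = channel.kind
    for s, seq in enumerate(subj_seqs):
        subj_rng = np.random.default_rng(seq)
        gain_mult = float(np.exp(subj_rng.normal(0.0, 0.15)))
        dur_mult = float(np.exp(subj_rng.normal(0.0, 0.15)))
        for cls in classes:
            base = CLASS_DEFAULTS[cls]
            for tok in range(tokens_per_class):
                tok_dur = dur_mult * float(np.exp(subj_rng.normal(0.0, 0.05)))
                tok_gain = gain_mult * float(np.exp(subj_rng.normal(0.0, 0.05)))
                tok_seed = int(subj_rng.integers(0, 2**31 - 1))
                spec = replace(
                    base,
                    duration_s=base.duration_s * tok_dur,
                    onset_gain=base.onset_gain * tok_gain,
                    lfo_gain=base.lfo_gain * tok_gain,
                    fric_gain=base.fric_gain * tok_gain,
                    coda_gain=base.coda_gain * tok_gain,
                    seed=tok_seed,
                )
                w, ann = generate(spec, rate=rate)
                w = apply_channel(w, channel)
                if cls == "reflexive_cough":
                    induction = "urge_to_cough" if tok % 2 == 0 else "suppressed"
                else:
                    induction = "none"
                file_id = f"s{s:03d}_{cls}_t{tok}.wav"
                waveforms[file_id] = (w, ann)
                rows.append({
                    "file_id": file_id, "subject": f"s{s:03d}", "maneuver": cls,
                    "microphone": mic, "induction": induction, "token": tok,
                })
    return waveforms, make_cohort_table(rows)
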