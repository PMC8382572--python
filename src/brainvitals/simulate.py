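"""Synthetic stimulus sequences, ERP recordings, and whole cohorts.

The generator emulates a rapid auditory brain-function assessment: an oddball
tone stream (frequent standards, rare deviants) interleaved—in time, after the
tones—with spoken word-pair stimuli whose targets are semantically congruent
or incongruent with their primes. Deviant tones evoke an N100 (negative,
~100 ms) and a P300 (positive, ~300 ms); incongruent word targets evoke an
N400 (negative, ~400 ms) relative to congruent targets. Each component is a
Gaussian-windowed deflection with per-channel topography weights, added to
1/f-shaped background noise; blinks appear on the EOG channel at a Poisson
rate and propagate onto the scalp channels with fixed coefficients.

Cohort simulation has two modes: ``"table"`` draws the six participant-level
measures directly from configured distributions (cheap, for testing the
statistics stages at scale) and ``"recordings"`` renders full EEG sessions
whose ground-truth component parameters are those same draws.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .measures import LONG_COLUMNS, UNITS
from .pipeline import QC_EXCLUDED_QUALITY, QC_INCLUDED, QC_N400_MISSING_LANGUAGE, PipelineConfig
from .recording import DEFAULT_CHANNELS, RawRecording, StimulusSequence

# ---------------------------------------------------------------------------
# Stimulus sequences

#: (prime, congruent target, incongruent target) word triples.
DEFAULT_LEXICON: tuple[tuple[str, str, str], ...] = (
    ("bread", "butter", "window"), ("cat", "dog", "spoon"), ("salt", "pepper", "cloud"),
    ("day", "night", "pencil"), ("king", "queen", "garlic"), ("table", "chair", "ocean"),
    ("hot", "cold", "letter"), ("black", "white", "hammer"), ("sun", "moon", "carpet"),
    ("shoe", "sock", "melon"), ("rain", "snow", "button"), ("door", "key", "pillow"),
    ("cup", "saucer", "gravel"), ("knife", "fork", "candle"), ("hand", "glove", "turnip"),
    ("fish", "chips", "ladder"), ("left", "right", "yogurt"), ("up", "down", "jacket"),
    ("pen", "paper", "anchor"), ("lock", "key", "walnut"), ("milk", "cookie", "engine"),
    ("doctor", "nurse", "planet"), ("thunder", "lightning", "ribbon"), ("needle", "thread", "valley"),
    ("apple", "orange", "brick"), ("shirt", "pants", "puddle"), ("river", "bank", "mitten"),
    ("bee", "honey", "tunnel"), ("horse", "saddle", "napkin"), ("bird", "nest", "kettle"),
    ("tooth", "brush", "meadow"), ("coffee", "tea", "shovel"), ("winter", "summer", "basket"),
    ("chalk", "board", "lemon"), ("lion", "tiger", "faucet"), ("star", "sky", "wallet"),
    ("boat", "sail", "pretzel"), ("book", "page", "lantern"), ("soap", "water", "magnet"),
    ("car", "road", "sweater"), ("frog", "pond", "trumpet"), ("clock", "time", "radish"),
    ("queen", "crown", "sandal"), ("spider", "web", "helmet"), ("nail", "hammer", "celery"),
    ("candle", "flame", "zipper"), ("grass", "green", "bottle"), ("piano", "music", "pocket"),
    ("shoes", "laces", "pickle"), ("egg", "bacon", "marble"), ("moon", "stars", "diesel"),
    ("pillow", "blanket", "cactus"), ("soup", "spoon", "gutter"), ("tree", "leaf", "stapler"),
    ("fire", "smoke", "noodle"), ("beach", "sand", "copper"), ("snow", "ice", "pepper"),
    ("glove", "mitten", "turbine"), ("chain", "link", "butter"), ("storm", "wind", "saddle"),
    ("ship", "ocean", "crumpet"), ("wolf", "howl", "teapot"), ("rose", "thorn", "gearbox"),
    ("desk", "lamp", "seaweed"), ("rope", "knot", "mustard"), ("glass", "mirror", "pigeon"),
    ("cheese", "mouse", "anvil"), ("plate", "dish", "falcon"), ("clown", "circus", "gravy"),
    ("wheel", "tire", "parsley"), ("broom", "dust", "lagoon"), ("crown", "jewel", "pencil"),
    ("nurse", "doctor", "magnet"), ("comb", "hair", "walrus"), ("drum", "beat", "lettuce"),
    ("ear", "sound", "pebble"), ("eye", "sight", "timber"), ("nose", "smell", "bucket"),
    ("mouth", "tongue", "girder"), ("foot", "toe", "sapphire"), ("arm", "elbow", "nutmeg"),
    ("bank", "money", "feather"), ("judge", "court", "syrup"), ("priest", "church", "gravel"),
    ("pilot", "plane", "radish"), ("farmer", "tractor", "violin"), ("sailor", "anchor", "muffin"),
    ("baker", "oven", "tunnel"), ("teacher", "school", "pebbles"), ("singer", "song", "hinge"),
    ("cow", "milk", "ledger"), ("hen", "egg", "plaster"), ("sheep", "wool", "marker"),
    ("pig", "mud", "lantern"), ("duck", "pond", "cabinet"), ("owl", "night", "sprocket"),
    ("snake", "hiss", "duvet"), ("shark", "teeth", "crayon"), ("whale", "blubber", "stencil"),
    ("ant", "hill", "goggles"), ("worm", "soil", "tambourine"), ("moth", "flame", "spanner"),
    ("leaf", "branch", "kayak"), ("root", "earth", "whistle"), ("seed", "plant", "goblet"),
    ("vine", "grape", "mattress"), ("bark", "trunk", "pelican"), ("fern", "forest", "caliper"),
    ("tide", "shore", "biscuit"), ("wave", "surf", "trombone"), ("cliff", "edge", "porridge"),
    ("cave", "dark", "spatula"), ("dune", "desert", "flannel"), ("creek", "stream", "padlock"),
    ("flour", "dough", "antenna"), ("sugar", "sweet", "gasket"), ("honey", "bee", "plywood"),
    ("jam", "toast", "scooter"), ("wine", "grape", "chisel"), ("beer", "foam", "corduroy"),
    ("fork", "knife", "pylon"), ("bowl", "cereal", "sawdust"), ("pan", "stove", "mollusk"),
    ("jar", "lid", "trellis"), ("mug", "coffee", "fender"), ("tray", "serve", "gazebo"),
)


def _non_adjacent_positions(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random choice of ``k`` positions from ``range(n)`` with no two adjacent."""
    if k > (n + 1) // 2:
        raise ValueError(f"cannot place {k} non-adjacent deviants among {n} stimuli")
    if k == 0:
        return np.empty(0, dtype=int)
    # bijection: k-subsets of range(n-k+1) <-> non-adjacent k-subsets of range(n)
    base = np.sort(rng.choice(n - k + 1, size=k, replace=False))
    return base + np.arange(k)


def generate_tone_sequence(n_stimuli: int, deviant_fraction: float = 0.2,
                           isi: float = 0.6, seed: int | None = None, *,
                           no_adjacent_deviants: bool = True,
                           start: float = 0.0) -> StimulusSequence:
    """Oddball tone stream: ``round(deviant_fraction * n_stimuli)`` deviants.

    Deviant placement is pseudorandomized; by default no two deviants are
    adjacent, so the oddball expectation is never broken by a deviant run.
    Deterministic for a fixed seed.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    if not 0.0 <= deviant_fraction <= 1.0:
        raise ValueError("deviant_fraction must lie in [0, 1]")
    if isi <= 0:
        raise ValueError("isi must be positive")
    rng = np.random.default_rng(seed)
    k = int(round(deviant_fraction * n_stimuli))
    if no_adjacent_deviants:
        pos = _non_adjacent_positions(n_stimuli, k, rng)
    else:
        pos = rng.choice(n_stimuli, size=k, replace=False)
    deviant = np.zeros(n_stimuli, dtype=bool)
    deviant[pos] = True
    onsets = start + isi * np.arange(n_stimuli)
    kinds = ["deviant_tone" if d else "standard_tone" for d in deviant]
    conditions = ["deviant" if d else "standard" for d in deviant]
    return StimulusSequence(onsets, kinds, conditions)


def generate_word_pair_sequence(n_pairs: int, congruent_fraction: float = 0.5,
                                seed: int | None = None,
                                lexicon: tuple[tuple[str, str, str], ...] | None = None, *,
                                soa: float = 1.0, pair_interval: float = 2.5,
                                start: float = 0.0) -> StimulusSequence:
    """Prime–target word pairs, ``round(congruent_fraction * n_pairs)`` congruent.

    Pairs are drawn from the lexicon without replacement and shuffled, so a
    fresh seed yields a different arrangement (retest emulation). The prime
    fires at the pair onset (condition ``none``) and the target ``soa``
    seconds later.
    """
    if not 0.0 <= congruent_fraction <= 1.0:
        raise ValueError("congruent_fraction must lie in [0, 1]")
    lex = tuple(lexicon) if lexicon is not None else DEFAULT_LEXICON
    if len(lex) < n_pairs:
        raise ValueError(f"lexicon has {len(lex)} entries; {n_pairs} pairs requested")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(lex), size=n_pairs, replace=False)
    k = int(round(congruent_fraction * n_pairs))
    congruent = np.zeros(n_pairs, dtype=bool)
    congruent[rng.choice(n_pairs, size=k, replace=False)] = True

    onsets, kinds, conditions = [], [], []
    for i in range(n_pairs):
        t = start + i * pair_interval
        onsets.extend([t, t + soa])
        kinds.extend(["word_prime", "word_target"])
        conditions.extend(["none", "congruent" if congruent[i] else "incongruent"])
    seq = StimulusSequence(np.array(onsets), kinds, conditions)
    seq.pairs = [lex[j] for j in chosen]  # type: ignore[attr-defined]
    return seq


# ---------------------------------------------------------------------------
# Participants and forward model

DEFAULT_WIDTHS_MS: dict[str, float] = {"n100": 30.0, "p300": 80.0, "n400": 100.0}

#: Per-component scalp topography (the default measurement electrode carries 1.0).
DEFAULT_CHANNEL_WEIGHTS: dict[str, dict[str, float]] = {
    "n100": {"Fz": 0.9, "Cz": 1.0, "Pz": 0.7},
    "p300": {"Fz": 0.6, "Cz": 0.9, "Pz": 1.0},
    "n400": {"Fz": 0.8, "Cz": 1.0, "Pz": 0.9},
}


@dataclass
class ComponentTruth:
    """Ground-truth ERP component: peak magnitude (uV), latency (ms), FWHM width (ms)."""

    amplitude: float
    latency: float
    width: float


def default_components() -> dict[str, ComponentTruth]:
    return {
        "n100": ComponentTruth(9.5, 110.0, DEFAULT_WIDTHS_MS["n100"]),
        "p300": ComponentTruth(10.0, 280.0, DEFAULT_WIDTHS_MS["p300"]),
        "n400": ComponentTruth(5.5, 440.0, DEFAULT_WIDTHS_MS["n400"]),
    }


@dataclass
class ParticipantProfile:
    """One simulated participant and their ground-truth ERP components."""

    id: str
    group: str = "A"
    age: float = 16.0
    sex: str = "male"
    english_fluent: bool = True
    true_components: dict[str, ComponentTruth] = field(default_factory=default_components)
    #: session -> component -> amplitude multiplier (e.g. N400 habituation at session 2)
    session_effects: dict[int, dict[str, float]] = field(
        default_factory=lambda: {2: {"n400": 0.815}}
    )

    def components_for_session(self, session: int) -> dict[str, ComponentTruth]:
        comps = {k: replace(v) for k, v in self.true_components.items()}
        for comp, factor in self.session_effects.get(session, {}).items():
            if not 0.0 < factor <= 1.0:
                raise ValueError("habituation factor must lie in (0, 1]")
            comps[comp].amplitude *= factor
        return comps


@dataclass
class NoiseConfig:
    """Background and artifact model for synthesized recordings."""

    background_sd_uv: float = 8.0    # total background SD per scalp channel
    pink_fraction: float = 0.6       # share of background variance with 1/f shape
    blink_rate_hz: float = 0.1       # Poisson blink rate (~6 per minute)
    blink_amplitude_uv: float = 150.0
    blink_propagation: dict[str, float] = field(
        default_factory=lambda: {"Fz": 0.35, "Cz": 0.2, "Pz": 0.1}
    )

    def __post_init__(self) -> None:
        if self.background_sd_uv < 0 or self.blink_rate_hz < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 <= self.pink_fraction <= 1.0:
            raise ValueError("pink_fraction must lie in [0, 1]")


def _gaussian_deflection(n: int, rate: float, center_idx: int, width_ms: float,
                         amplitude: float) -> np.ndarray:
    """Gaussian-windowed deflection (length n), peak ``amplitude`` at ``center_idx``."""
    sigma = (width_ms / 2.3548) * rate / 1000.0  # FWHM -> sigma, in samples
    idx = np.arange(n)
    return amplitude * np.exp(-0.5 * ((idx - center_idx) / sigma) ** 2)


@functools.lru_cache(maxsize=4096)
def _measurement_matrix(latencies_ms: tuple[float, ...], widths_ms: tuple[float, ...],
                        rate: float, band: tuple[float, float], order: int,
                        baseline_ms: tuple[float, float]) -> np.ndarray:
    """Linear map from template amplitudes to measured (band-passed,
    baseline-corrected) values at the target latencies.

    Entry (i, j) is the value read at latency i after pushing a unit template
    at latency j through the analysis band-pass and subtracting the pre-
    stimulus baseline mean. The diagonal is the filter's peak gain on that
    template; off-diagonals capture cross-talk between same-event components
    (the high-pass transient of one deflection under the peak of another).
    """
    from scipy import signal as _signal

    m = len(latencies_ms)
    margin = int(3.0 * rate)  # seconds of context so the filter transient settles
    onset = margin
    n = margin * 2 + int(1.5 * rate)
    sos = _signal.butter(order, band, btype="bandpass", fs=rate, output="sos")
    t_idx = [onset + int(round(lat * rate / 1000.0)) for lat in latencies_ms]
    b_lo = onset + int(round(baseline_ms[0] * rate / 1000.0))
    b_hi = onset + int(round(baseline_ms[1] * rate / 1000.0))
    G = np.empty((m, m))
    for j in range(m):
        tpl = _gaussian_deflection(n, rate, t_idx[j], widths_ms[j], 1.0)
        y = _signal.sosfiltfilt(sos, tpl)
        y = y - y[b_lo : b_hi + 1].mean()
        G[:, j] = y[t_idx]
    return G


def _calibrate_amplitudes(comps: dict[str, "ComponentTruth"], rate: float,
                          band: tuple[float, float], order: int,
                          baseline_ms: tuple[float, float]) -> dict[str, float]:
    """Signed template amplitudes that reproduce the ground truth downstream.

    Ground-truth amplitudes are defined at the pipeline's analysis point —
    after the 0.5-20 Hz zero-phase band-pass and baseline correction — so the
    injected templates are pre-scaled (jointly, for the N100/P300 pair that
    share a stimulus) such that the noiseless measured peaks equal the truth.
    """
    out: dict[str, float] = {}
    tone = [c for c in ("n100", "p300") if c in comps]
    if tone:
        lats = tuple(comps[c].latency for c in tone)
        widths = tuple(comps[c].width for c in tone)
        G = _measurement_matrix(lats, widths, rate, tuple(band), order, tuple(baseline_ms))
        targets = np.array([POLARITY_SIGN[c] * comps[c].amplitude for c in tone])
        amps = np.linalg.solve(G, targets)
        out.update(dict(zip(tone, amps)))
    if "n400" in comps:
        c = comps["n400"]
        G = _measurement_matrix((c.latency,), (c.width,), rate, tuple(band), order,
                                tuple(baseline_ms))
        out["n400"] = -c.amplitude / float(G[0, 0])
    return out


POLARITY_SIGN = {"n100": -1.0, "p300": +1.0, "n400": -1.0}


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def _blink_waveform(rate: float, amplitude: float) -> np.ndarray:
    """Biphasic ~400 ms blink transient peaking at ``amplitude`` uV."""
    t = np.arange(0.0, 0.4, 1.0 / rate)
    w = np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2) - 0.35 * np.exp(-0.5 * ((t - 0.28) / 0.07) ** 2)
    return amplitude * w / np.max(np.abs(w))


def synthesize_recording(profile: ParticipantProfile, tones: StimulusSequence,
                         words: StimulusSequence | None = None,
                         noise: NoiseConfig | None = None, seed: int | None = None, *,
                         session: int = 1, sample_rate: float = 500.0,
                         channel_weights: dict[str, dict[str, float]] | None = None,
                         windows: dict[str, tuple[float, float]] | None = None,
                         analysis_band: tuple[float, float] | None = (0.5, 20.0),
                         filter_order: int = 4,
                         baseline_ms: tuple[float, float] = (-100.0, 0.0),
                         tail_s: float = 1.2) -> RawRecording:
    """Render a full multichannel recording for one participant-session.

    Each deviant tone contributes the participant's N100 (negative) and P300
    (positive) templates; each incongruent word target contributes the N400
    (negative) template; congruent targets contribute nothing, so the
    incongruent-minus-congruent difference wave carries the N400. Template
    centers are snapped to the sample grid, which makes latency recovery exact
    for a noiseless recording. Deterministic for a fixed seed.
    """
    noise = noise or NoiseConfig()
    weights = channel_weights or DEFAULT_CHANNEL_WEIGHTS
    windows = windows or PipelineConfig().windows_ms
    comps = profile.components_for_session(session)
    for name, c in comps.items():
        lo, hi = windows[name]
        if not lo < c.latency < hi:
            raise ValueError(
                f"{name} true latency {c.latency} ms outside detection window {windows[name]}")
        if c.amplitude < 0:
            raise ValueError("component amplitudes are magnitudes and must be >= 0")

    markers = tones if words is None else StimulusSequence.concatenate(tones, words)
    duration = float(markers.onsets[-1]) + tail_s if len(markers) else tail_s
    n = int(round(duration * sample_rate)) + 1
    channels = list(DEFAULT_CHANNELS)
    data = np.zeros((len(channels), n))
    rng = np.random.default_rng(seed)

    if analysis_band is not None:
        # truth amplitudes are defined at the analysis point (band-passed,
        # baseline-corrected), so templates are jointly pre-scaled
        signed_amps = _calibrate_amplitudes(comps, sample_rate, analysis_band,
                                            filter_order, baseline_ms)
    else:
        signed_amps = {c: POLARITY_SIGN[c] * comps[c].amplitude for c in comps}

    def add_component(onset_s: float, comp: str) -> None:
        c = comps[comp]
        center = int(round(onset_s * sample_rate)) + int(round(c.latency * sample_rate / 1000.0))
        tpl = _gaussian_deflection(n, sample_rate, center, c.width, signed_amps[comp])
        for ch, w in weights[comp].items():
            data[channels.index(ch)] += w * tpl

    for onset, cond in zip(markers.onsets, markers.conditions):
        if cond == "deviant":
            add_component(onset, "n100")
            add_component(onset, "p300")
        elif cond == "incongruent":
            add_component(onset, "n400")

    if noise.background_sd_uv > 0:
        for ci in range(len(channels)):
            pink = _pink_noise(n, rng) * math.sqrt(noise.pink_fraction)
            white = rng.standard_normal(n) * math.sqrt(1.0 - noise.pink_fraction)
            data[ci] += noise.background_sd_uv * (pink + white)

    if noise.blink_rate_hz > 0 and noise.blink_amplitude_uv > 0:
        n_blinks = rng.poisson(noise.blink_rate_hz * duration)
        wave = _blink_waveform(sample_rate, noise.blink_amplitude_uv)
        eog_idx = channels.index("EOG")
        for _ in range(n_blinks):
            t0 = int(rng.uniform(0, max(n - len(wave), 1)))
            seg = slice(t0, t0 + len(wave))
            jitter = rng.uniform(0.8, 1.2)
            data[eog_idx, seg] += jitter * wave[: data.shape[1] - t0]
            for ch, coef in noise.blink_propagation.items():
                data[channels.index(ch), seg] += coef * jitter * wave[: data.shape[1] - t0]

    return RawRecording(sample_rate, channels, data, markers)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class MeasureSpec:
    """Population distribution of one measure within a group."""

    mean: float
    sd: float
    retest_rho: float = 0.0   # between-session correlation (2-session groups)
    age_slope: float = 0.0    # units per year, centered at the group mean age

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("measure SD must be positive")
        if abs(self.retest_rho) > 1:
            raise ValueError("|retest_rho| must be <= 1")


@dataclass
class GroupSpec:
    """One cohort arm: sample size, demographics, measure distributions, QC counts."""

    name: str
    n: int
    sessions: int = 1
    age_mean: float = 40.0
    age_sd: float = 15.0
    age_min: float | None = None
    age_max: float | None = None
    sex: str = "mixed"              # "male", "female" or "mixed"
    measures: dict[str, MeasureSpec] = field(default_factory=dict)
    habituation: dict[str, float] = field(default_factory=dict)  # session-2 multipliers
    n_exclude_quality: int = 0      # session-1 quality exclusions to emulate
    n_nonfluent: int = 0            # participants without N400 (language screen)
    n_nonfluent_included: int | None = None  # of those, how many pass quality QC
    n_retest: int | None = None     # participants with a second session
    n_retest_nonfluent: int | None = None
    n_missing_n100: int = 0         # participants with unmeasurable N100


@dataclass
class CohortConfig:
    """Whole-study simulation: group arms plus waveform-mode rendering knobs."""

    groups: list[GroupSpec]
    mode: str = "table"             # "table" or "recordings"
    n_tones: int = 300
    deviant_fraction: float = 0.2
    tone_isi: float = 0.6
    n_word_pairs: int = 70
    congruent_fraction: float = 0.5
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    sample_rate: float = 500.0
    latency_grid_ms: float = 2.0    # latencies snapped to the 500 Hz sample grid


def _draw_ages(g: GroupSpec, rng: np.random.Generator) -> np.ndarray:
    if g.age_min is not None and g.age_max is not None:
        a = (g.age_min - g.age_mean) / g.age_sd
        b = (g.age_max - g.age_mean) / g.age_sd
        return stats.truncnorm.rvs(a, b, loc=g.age_mean, scale=g.age_sd,
                                   size=g.n, random_state=rng)
    return rng.normal(g.age_mean, g.age_sd, size=g.n)


def _assign_flags(g: GroupSpec, rng: np.random.Generator) -> tuple[set[int], set[int], set[int], set[int]]:
    """Deterministically assign QC / fluency / retest / missing-N100 index sets."""
    order = list(rng.permutation(g.n))
    excluded = set(order[: g.n_exclude_quality])
    included = [i for i in order if i not in excluded]

    n_nf_inc = g.n_nonfluent_included
    if n_nf_inc is None:
        n_nf_inc = min(g.n_nonfluent, len(included))
    n_nf_exc = g.n_nonfluent - n_nf_inc
    if n_nf_exc > len(excluded) or n_nf_inc > len(included):
        raise ValueError("non-fluent counts incompatible with quality-exclusion count")
    nonfluent = set(list(excluded)[:n_nf_exc]) | set(included[:n_nf_inc])

    n_retest = g.n_retest if g.n_retest is not None else (g.n if g.sessions > 1 else 0)
    # retest pairs come from quality-included participants, so complete-pair
    # counts equal the configured retest counts
    pool = [i for i in order if i not in excluded]
    if n_retest > len(pool):
        raise ValueError("retest count exceeds quality-included participants")
    if g.n_retest_nonfluent is None:
        retested = set(pool[-n_retest:]) if n_retest else set()
    else:
        nf = [i for i in pool if i in nonfluent]
        fl = [i for i in pool if i not in nonfluent]
        if g.n_retest_nonfluent > len(nf) or n_retest - g.n_retest_nonfluent > len(fl):
            raise ValueError("retest composition incompatible with fluency counts")
        retested = set(nf[: g.n_retest_nonfluent]) | set(fl[: n_retest - g.n_retest_nonfluent])
    fluent_pool = [i for i in order if i not in nonfluent]
    missing_n100 = set(fluent_pool[-g.n_missing_n100:]) if g.n_missing_n100 else set()
    return excluded, nonfluent, retested, missing_n100


def _snap_latency(value: float, grid_ms: float) -> float:
    return grid_ms * round(value / grid_ms)


def simulate_cohort(config: CohortConfig, seed: int | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a whole study cohort; return ``(measurements, truth)`` tables.

    Both tables are long format (``participant_id, group, age, sex, session,
    measure, value, unit``); the truth table additionally carries ``qc`` and
    retains every drawn value, while the measurements table reflects what an
    observer would actually obtain: quality-excluded session-1 participants,
    non-fluent participants' N400 rows and non-retested session-2 rows are
    absent. In ``"recordings"`` mode use :func:`simulate_cohort_recordings`.
    """
    rng = np.random.default_rng(seed)
    meas_rows: list[dict] = []
    truth_rows: list[dict] = []
    for g in config.groups:
        ages = _draw_ages(g, rng)
        excluded, nonfluent, retested, missing_n100 = _assign_flags(g, rng)
        sexes = _draw_sexes(g, rng)
        for i in range(g.n):
            pid = f"{g.name}{i + 1:03d}"
            qc1 = QC_EXCLUDED_QUALITY if i in excluded else (
                QC_N400_MISSING_LANGUAGE if i in nonfluent else QC_INCLUDED)
            sessions = [1] + ([2] if (g.sessions > 1 and i in retested) else [])
            values = _draw_measures(g, ages[i], rng, config.latency_grid_ms)
            for m in g.measures:
                for s in sessions:
                    v = values[m][s - 1]
                    row = dict(participant_id=pid, group=g.name, age=ages[i],
                               sex=sexes[i], session=s, measure=m, value=v, unit=UNITS[m])
                    truth_rows.append({**row, "qc": qc1 if s == 1 else QC_INCLUDED,
                                       "fluent": i not in nonfluent})
                    if s == 1 and i in excluded:
                        continue
                    if m.startswith("n400") and i in nonfluent:
                        continue
                    if m.startswith("n100") and i in missing_n100:
                        continue
                    meas_rows.append(row)
    measurements = pd.DataFrame(meas_rows, columns=list(LONG_COLUMNS))
    truth = pd.DataFrame(truth_rows, columns=list(LONG_COLUMNS) + ["qc", "fluent"])
    return measurements, truth


def _draw_sexes(g: GroupSpec, rng: np.random.Generator) -> list[str]:
    if g.sex in ("male", "female"):
        return [g.sex] * g.n
    return ["male" if rng.random() < 0.5 else "female" for _ in range(g.n)]


def _draw_measures(g: GroupSpec, age: float, rng: np.random.Generator,
                   grid_ms: float) -> dict[str, tuple[float, ...]]:
    """Per-measure (session1, session2) true values for one participant.

    ``MeasureSpec.sd`` is the total population SD; the residual spread is
    reduced so that the age-slope component does not inflate it.
    """
    out: dict[str, tuple[float, ...]] = {}
    for m, spec in g.measures.items():
        loc = spec.mean + spec.age_slope * (age - g.age_mean)
        var_age = (spec.age_slope * g.age_sd) ** 2
        if var_age >= spec.sd ** 2:
            raise ValueError(f"age slope for {m} implies more variance than the total SD")
        resid_sd = math.sqrt(spec.sd ** 2 - var_age)
        if g.sessions > 1:
            rho = spec.retest_rho
            cov = resid_sd ** 2 * np.array([[1.0, rho], [rho, 1.0]])
            v1, v2 = rng.multivariate_normal([loc, loc], cov)
            v2 *= g.habituation.get(m, 1.0)
            vals = [v1, v2]
        else:
            vals = [rng.normal(loc, resid_sd)]
        cleaned = []
        for v in vals:
            if m.endswith("latency"):
                v = _snap_latency(v, grid_ms)
            else:
                v = max(v, 0.05)  # amplitudes are magnitudes
            cleaned.append(v)
        out[m] = tuple(cleaned)
    return out


def simulate_cohort_recordings(config: CohortConfig, seed: int | None = None,
                               windows: dict[str, tuple[float, float]] | None = None,
                               ) -> tuple[list[tuple[ParticipantProfile, int, RawRecording]], pd.DataFrame]:
    """Render full EEG sessions for every participant drawn by the cohort config.

    Ground-truth component amplitudes/latencies are the table-mode draws,
    clipped into the detection windows (with a 6 ms interior margin) and
    snapped to the sample grid; the returned truth table records the values
    actually rendered.
    """
    windows = windows or PipelineConfig().windows_ms
    rng = np.random.default_rng(seed)
    _, truth = simulate_cohort(config, seed=seed)
    sessions_out = []
    truth_rows = []
    wide = truth.pivot_table(index=["participant_id", "group", "age", "sex", "session", "fluent"],
                             values="value", columns="measure", aggfunc="first").reset_index()
    for _, row in wide.iterrows():
        comps: dict[str, ComponentTruth] = {}
        for comp in ("n100", "p300", "n400"):
            lo, hi = windows[comp]
            lat = float(np.clip(row[f"{comp}_latency"], lo + 6.0, hi - 6.0))
            lat = _snap_latency(lat, 1000.0 / config.sample_rate * 1)
            amp = float(max(row[f"{comp}_amplitude"], 0.2))
            comps[comp] = ComponentTruth(amp, lat, DEFAULT_WIDTHS_MS[comp])
        profile = ParticipantProfile(
            id=str(row["participant_id"]), group=str(row["group"]), age=float(row["age"]),
            sex=str(row["sex"]), english_fluent=bool(row["fluent"]),
            true_components=comps, session_effects={})
        sub_seed = int(rng.integers(0, 2**31 - 1))
        tones = generate_tone_sequence(config.n_tones, config.deviant_fraction,
                                       config.tone_isi, seed=sub_seed)
        words_start = float(tones.onsets[-1]) + 2.0
        words = generate_word_pair_sequence(config.n_word_pairs, config.congruent_fraction,
                                            seed=sub_seed + 1, start=words_start)
        rec = synthesize_recording(profile, tones, words, config.noise, seed=sub_seed + 2,
                                   sample_rate=config.sample_rate, windows=windows)
        session = int(row["session"])
        sessions_out.append((profile, session, rec))
        for comp in ("n100", "p300", "n400"):
            for kind in ("amplitude", "latency"):
                truth_rows.append(dict(
                    participant_id=row["participant_id"], group=row["group"], age=row["age"],
                    sex=row["sex"], session=session, measure=f"{comp}_{kind}",
                    value=getattr(comps[comp], kind), unit=UNITS[f"{comp}_{kind}"]))
    return sessions_out, pd.DataFrame(truth_rows, columns=list(LONG_COLUMNS))


# ---------------------------------------------------------------------------
# Reference-study presets

#: Elite-athlete arm: adolescent males, two sessions two days apart.
def group_a_spec() -> GroupSpec:
    return GroupSpec(
        name="A", n=58, sessions=2, age_mean=16.24, age_sd=0.76, sex="male",
        measures={
            "n100_amplitude": MeasureSpec(9.48, 3.52, retest_rho=0.58, age_slope=+0.02),
            "n100_latency": MeasureSpec(109.46, 15.44, retest_rho=0.69, age_slope=+0.01),
            "p300_amplitude": MeasureSpec(9.53, 4.32, retest_rho=0.57, age_slope=-0.05),
            "p300_latency": MeasureSpec(279.04, 38.78, retest_rho=0.63, age_slope=+0.20),
            "n400_amplitude": MeasureSpec(6.26, 2.40, retest_rho=0.50, age_slope=-0.046),
            "n400_latency": MeasureSpec(438.26, 58.95, retest_rho=0.70, age_slope=+0.28),
        },
        habituation={"n400_amplitude": 0.815},
        n_exclude_quality=6, n_nonfluent=15, n_nonfluent_included=14,
        n_retest=46, n_retest_nonfluent=13,
    )


#: General reference arm: mixed sexes, ages 8-83, one session.
def group_b_spec() -> GroupSpec:
    return GroupSpec(
        name="B", n=135, sessions=1, age_mean=40.62, age_sd=16.88,
        age_min=8.0, age_max=83.0, sex="mixed",
        measures={
            "n100_amplitude": MeasureSpec(9.98, 4.28, age_slope=+0.02),
            "n100_latency": MeasureSpec(102.96, 11.09, age_slope=+0.01),
            "p300_amplitude": MeasureSpec(10.14, 4.38, age_slope=-0.05),
            "p300_latency": MeasureSpec(281.57, 51.36, age_slope=+0.20),
            "n400_amplitude": MeasureSpec(4.99, 2.28, age_slope=-0.046),
            "n400_latency": MeasureSpec(456.24, 69.18, age_slope=+0.28),
        },
        n_missing_n100=1,
    )


def reference_cohort_config(mode: str = "table") -> CohortConfig:
    """The default two-arm study the simulator emulates."""
    return CohortConfig(groups=[group_a_spec(), group_b_spec()], mode=mode)
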