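"""Generative model of operant conditioned-suppression test sessions.

The assay: a rat lever-presses for food under continuous low-level
broad-band noise (BBN).  One-minute *probe* periods are substituted into
the background at random; two of the ten probes in a daily 60-min session
are always speaker-off (silence), during which lever pressing is punished
with foot shock.  A rat with tinnitus cannot experience speaker-off as
silence, so probe tones resembling its tinnitus percept are treated like
speaker-off and pressing is suppressed.

This module simulates such sessions from a latent tinnitus-severity
parameter ``tau`` per animal: a perceived-similarity kernel maps each probe
stimulus to a similarity ``S`` with the animal's danger percept, and
per-minute press counts are Poisson with rate ``lambda_bg * (1 - c_off*S)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TONE",
    "BBN",
    "SPEAKER_OFF",
    "BACKGROUND",
    "PROBE",
    "Stimulus",
    "Period",
    "Protocol",
    "ProtocolError",
    "AnimalState",
    "SessionLog",
    "CohortAnimal",
    "SimilarityParams",
    "default_catalog",
    "build_protocol",
    "perceived_similarity",
    "expected_rate",
    "simulate_session",
    "simulate_cohort",
    "make_controlled_session",
]

# stimulus kinds
TONE = "tone"
BBN = "bbn"
SPEAKER_OFF = "speaker_off"

# period kinds
BACKGROUND = "background"
PROBE = "probe"

MINUTE_SEC = 60.0


@dataclass(frozen=True)
class Stimulus:
    """A 1-min test stimulus: a pure tone, broad-band noise, or silence."""

    kind: str
    freq_khz: float | None = None
    level_db: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (TONE, BBN, SPEAKER_OFF):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == TONE:
            if self.freq_khz is None or self.freq_khz <= 0:
                raise ValueError("tone stimulus requires a positive freq_khz")
        if self.kind == SPEAKER_OFF:
            if self.level_db is not None or self.freq_khz is not None:
                raise ValueError("speaker_off carries no frequency or level")
        elif self.level_db is None:
            raise ValueError(f"{self.kind} stimulus requires a level_db")

    @property
    def label(self) -> str:
        if self.kind == SPEAKER_OFF:
            return "OFF"
        if self.kind == BBN:
            return f"BBN@{self.level_db:g}dB"
        return f"{self.freq_khz:g}kHz@{self.level_db:g}dB"


@dataclass(frozen=True)
class Period:
    """Half-open interval [start_sec, end_sec) of one schedule period."""

    start_sec: float
    end_sec: float
    kind: str  # BACKGROUND or PROBE
    stimulus: Stimulus | None = None  # None for background (ambient BBN on)

    def __post_init__(self) -> None:
        if self.end_sec <= self.start_sec:
            raise ValueError("period must have positive duration")
        if self.kind not in (BACKGROUND, PROBE):
            raise ValueError(f"unknown period kind {self.kind!r}")
        if self.kind == PROBE and self.stimulus is None:
            raise ValueError("probe period requires a stimulus")


DEFAULT_LEVELS_DB = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)


def default_catalog(
    kind: str = TONE, freq_khz: float = 20.0, levels_db: Sequence[float] = DEFAULT_LEVELS_DB
) -> tuple[Stimulus, ...]:
    """Probe catalog of one stimulus kind across presentation levels.

    The diagnostic catalog is 20 kHz tones at 30-90 dB SPL; a BBN catalog
    (the non-diagnostic control stimulus) uses ``kind=BBN``.
    """
    if kind == TONE:
        return tuple(Stimulus(TONE, freq_khz, lv) for lv in levels_db)
    if kind == BBN:
        return tuple(Stimulus(BBN, None, lv) for lv in levels_db)
    raise ValueError("catalog kind must be 'tone' or 'bbn'")


class ProtocolError(ValueError):
    """Raised for infeasible or inconsistent session protocols."""


@dataclass(frozen=True)
class Protocol:
    """Parameters of one daily test session.

    Defaults follow the assay design: 60 one-minute epochs, 10 randomly
    inserted non-contiguous probe minutes, 2 of which are always
    speaker-off, the remaining 8 drawn from the probe catalog
    (levels 30-90 dB SPL), over a 60 dB SPL BBN background.
    """

    session_minutes: int = 60
    n_probes: int = 10
    n_speaker_off: int = 2
    probe_catalog: tuple[Stimulus, ...] = field(default_factory=default_catalog)
    background_level_db: float = 60.0

    def __post_init__(self) -> None:
        if not (0 <= self.n_speaker_off <= self.n_probes <= self.session_minutes):
            raise ProtocolError(
                "require n_speaker_off <= n_probes <= session_minutes "
                f"(got {self.n_speaker_off}, {self.n_probes}, {self.session_minutes})"
            )
        if self.n_probes > self.n_speaker_off and not self.probe_catalog:
            raise ProtocolError("non-speaker-off probes requested but catalog is empty")
        for stim in self.probe_catalog:
            if stim.kind == SPEAKER_OFF:
                raise ProtocolError("speaker_off is scheduled separately, not via the catalog")
            if not (30.0 <= stim.level_db <= 90.0):
                raise ProtocolError(f"catalog level {stim.level_db} dB outside [30, 90] dB SPL")
        # probes occupy interior minutes (1 .. m-2) and must be pairwise
        # non-adjacent: k non-adjacent slots fit among n iff k <= (n+1)//2
        n_slots = self.session_minutes - 2
        if self.n_probes > max(0, (n_slots + 1) // 2):
            raise ProtocolError(
                f"cannot place {self.n_probes} non-contiguous probe minutes in "
                f"{self.session_minutes} session minutes"
            )

    @property
    def session_seconds(self) -> float:
        return self.session_minutes * MINUTE_SEC


def _sample_nonadjacent(rng: np.random.Generator, n_slots: int, k: int) -> np.ndarray:
    """Uniformly sample k pairwise non-adjacent indices from range(n_slots).

    Standard bijection: sorted choices z from range(n_slots - k + 1) map to
    x_i = z_i + i, which are strictly increasing with gaps >= 2.
    """
    if k == 0:
        return np.empty(0, dtype=int)
    z = np.sort(rng.choice(n_slots - k + 1, size=k, replace=False))
    return z + np.arange(k)


def build_protocol(protocol: Protocol | None = None, seed=0) -> tuple[Period, ...]:
    """Realise a session schedule from a protocol.

    Probe minutes are whole 1-min slots chosen uniformly at random among
    interior, pairwise non-adjacent minutes; ``n_speaker_off`` of them are
    speaker-off and the rest draw stimuli from the catalog in an
    as-balanced-as-possible shuffled rotation (so every catalog entry is
    presented before any repeats).
    """
    protocol = protocol or Protocol()
    rng = np.random.default_rng(seed)
    m = protocol.session_minutes
    probe_minutes = 1 + _sample_nonadjacent(rng, m - 2, protocol.n_probes)

    n_stim = protocol.n_probes - protocol.n_speaker_off
    off_idx = rng.choice(protocol.n_probes, size=protocol.n_speaker_off, replace=False)
    stimuli: list[Stimulus] = []
    if n_stim > 0:
        # each catalog pass is shuffled independently, so every entry is
        # presented once before any entry repeats (balanced rotation)
        catalog = protocol.probe_catalog
        reps = -(-n_stim // len(catalog))  # ceil
        for _ in range(reps):
            order = rng.permutation(len(catalog))
            stimuli.extend(catalog[i] for i in order)
        stimuli = stimuli[:n_stim]

    assignment: dict[int, Stimulus] = {}
    j = 0
    for i, minute in enumerate(probe_minutes):
        if i in off_idx:
            assignment[int(minute)] = Stimulus(SPEAKER_OFF)
        else:
            assignment[int(minute)] = stimuli[j]
            j += 1

    periods = []
    for minute in range(m):
        t0, t1 = minute * MINUTE_SEC, (minute + 1) * MINUTE_SEC
        if minute in assignment:
            periods.append(Period(t0, t1, PROBE, assignment[minute]))
        else:
            periods.append(Period(t0, t1, BACKGROUND, None))
    return tuple(periods)


@dataclass(frozen=True)
class AnimalState:
    """Latent state of one simulated animal.

    ``tau`` is the tinnitus severity in [0, 1] (0 = no tinnitus); it is a
    simulation-only latent and is never visible to the scoring pipeline.
    ``lambda_bg`` is the mean press rate (presses/min) under background
    noise, and ``c_off`` the trained suppression depth: the fraction of the
    baseline rate withheld when the percept fully matches the conditioned
    danger percept.
    """

    animal_id: str
    exposed: bool
    tau: float
    tinnitus_pitch_khz: float = 20.0
    lambda_bg: float = 15.0
    c_off: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must lie in [0, 1]")
        if not self.exposed and self.tau != 0.0:
            raise ValueError("unexposed animals have tau = 0 under the default cohort model")
        if self.lambda_bg <= 0:
            raise ValueError("lambda_bg must be positive")
        if not (0.0 <= self.c_off <= 1.0):
            raise ValueError("c_off must lie in [0, 1]")


@dataclass(frozen=True)
class SimilarityParams:
    """Tunable parameters of the perceived-similarity kernel.

    silence_level50 / silence_slope_db: midpoint and slope (dB) of the
    decreasing logistic mapping presentation level to similarity with
    silence.  pitch_sigma_oct: width (octaves) of the Gaussian kernel in
    log2-frequency around the tinnitus pitch.  The admission window scales
    tinnitus-likeness down gently with level (faint tones resemble a faint
    phantom percept more than loud ones) and is floored so separation
    persists at high levels.  Similarities below ``similarity_floor`` are
    clamped to zero.
    """

    silence_level50: float = 45.0
    silence_slope_db: float = 6.0
    pitch_sigma_oct: float = 0.5
    admission_ref_db: float = 30.0
    admission_decay_per_db: float = 0.01
    admission_floor: float = 0.35
    similarity_floor: float = 0.05


DEFAULT_SIMILARITY = SimilarityParams()


def _silence_similarity(level_db: float, p: SimilarityParams) -> float:
    return 1.0 / (1.0 + math.exp((level_db - p.silence_level50) / p.silence_slope_db))


def perceived_similarity(
    stimulus: Stimulus, animal: AnimalState, params: SimilarityParams = DEFAULT_SIMILARITY
) -> float:
    """Similarity S in [0, 1] of a probe stimulus to the danger percept.

    S = (1 - tau) * S_sil(level) + tau * S_tin(freq, level); speaker-off is
    the danger percept itself (silence for tau=0, the tinnitus for tau=1),
    so S(speaker_off) = 1 always.  For broad-band noise S_tin is taken
    equal to S_sil (a tonal phantom percept blends with faint noise exactly
    as silence does), which makes BBN discrimination tau-independent.
    """
    if stimulus.kind == SPEAKER_OFF:
        return 1.0
    s_sil = _silence_similarity(stimulus.level_db, params)
    if stimulus.kind == BBN:
        s = s_sil
    else:
        d_oct = math.log2(stimulus.freq_khz / animal.tinnitus_pitch_khz)
        gauss = math.exp(-(d_oct**2) / (2.0 * params.pitch_sigma_oct**2))
        admission = min(
            1.0,
            max(
                params.admission_floor,
                1.0 - params.admission_decay_per_db * (stimulus.level_db - params.admission_ref_db),
            ),
        )
        s = (1.0 - animal.tau) * s_sil + animal.tau * gauss * admission
    if s < params.similarity_floor:
        return 0.0
    return min(s, 1.0)


def expected_rate(
    animal: AnimalState, period: Period, params: SimilarityParams = DEFAULT_SIMILARITY
) -> float:
    """Expected presses/min for one period: lambda_bg * (1 - c_off * S)."""
    if period.kind == BACKGROUND:
        s = 0.0
    else:
        s = perceived_similarity(period.stimulus, animal, params)
    return animal.lambda_bg * (1.0 - animal.c_off * s)


@dataclass(frozen=True)
class SessionLog:
    """Timestamped lever presses plus the period schedule of one session."""

    animal_id: str
    press_times: np.ndarray  # seconds from session start, ascending
    schedule: tuple[Period, ...]
    seed: int | None = None
    session_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.press_times, dtype=float)
        object.__setattr__(self, "press_times", t)
        end = self.schedule[-1].end_sec
        if t.size and (t.min() < 0 or t.max() >= end):
            raise ValueError("press times must lie within [0, session end)")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("press times must be ascending")

    @property
    def n_minutes(self) -> int:
        return len(self.schedule)

    @property
    def total_presses(self) -> int:
        return int(self.press_times.size)


def simulate_session(
    animal: AnimalState,
    protocol: Protocol | tuple[Period, ...] | None = None,
    seed=0,
    params: SimilarityParams = DEFAULT_SIMILARITY,
    session_index: int = 0,
) -> SessionLog:
    """Simulate one session: per-minute Poisson counts, uniform press times.

    If ``protocol`` is a Protocol (or None), the schedule itself is drawn
    from the same seed stream, so identical (inputs, seed) give
    byte-identical logs.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    sched_ss, press_ss = ss.spawn(2)
    if protocol is None or isinstance(protocol, Protocol):
        schedule = build_protocol(protocol, seed=np.random.default_rng(sched_ss))
    else:
        schedule = tuple(protocol)
    rng = np.random.default_rng(press_ss)
    times = []
    for period in schedule:
        lam = expected_rate(animal, period, params) * (period.end_sec - period.start_sec) / MINUTE_SEC
        n = rng.poisson(lam)
        if n:
            times.append(np.sort(rng.uniform(period.start_sec, period.end_sec, size=n)))
    press = np.concatenate(times) if times else np.empty(0)
    return SessionLog(
        animal_id=animal.animal_id,
        press_times=press,
        schedule=schedule,
        seed=int(ss.entropy) if isinstance(ss.entropy, int) and ss.entropy < 2**63 else None,
        session_index=session_index,
    )


@dataclass(frozen=True)
class CohortAnimal:
    state: AnimalState
    sessions: tuple[SessionLog, ...]


TauDistribution = Callable[[np.random.Generator], float]


def _resolve_tau_distribution(spec) -> TauDistribution:
    if spec is None:
        return lambda rng: float(rng.uniform())
    if callable(spec) and not hasattr(spec, "rvs"):
        return spec
    if hasattr(spec, "rvs"):  # scipy frozen distribution
        return lambda rng: float(spec.rvs(random_state=rng))
    if isinstance(spec, (int, float)):
        value = float(spec)
        if not (0.0 <= value <= 1.0):
            raise ValueError("degenerate tau must lie in [0, 1]")
        return lambda rng: value
    if isinstance(spec, (tuple, list)):
        name, *args = spec
        if name == "uniform":
            lo, hi = args or (0.0, 1.0)
            return lambda rng: float(rng.uniform(lo, hi))
        if name == "beta":
            a, b = args
            return lambda rng: float(rng.beta(a, b))
        if name == "constant":
            (value,) = args
            return _resolve_tau_distribution(float(value))
    raise ValueError(f"unrecognised tau distribution spec {spec!r}")


def simulate_cohort(
    n_exposed: int,
    n_unexposed: int,
    tau_distribution=None,
    n_sessions: int = 10,
    seed=0,
    protocol: Protocol | None = None,
    lambda_bg_median: float = 15.0,
    lambda_bg_sigma: float = 0.8,
    c_off: float = 0.9,
    tinnitus_pitch_khz: float = 20.0,
    params: SimilarityParams = DEFAULT_SIMILARITY,
) -> list[CohortAnimal]:
    """Simulate a cohort of exposed and unexposed animals.

    Unexposed animals have tau = 0; exposed animals draw tau from
    ``tau_distribution`` (default uniform on [0, 1]).  Baseline press rates
    are drawn per animal from a log-normal with median
    ``lambda_bg_median``/min so that session QC filters have non-trivial
    action.  Each session gets a fresh sub-seed spawned from ``seed``.
    """
    if n_exposed < 0 or n_unexposed < 0 or (n_exposed + n_unexposed) == 0:
        raise ValueError("cohort sizes must be non-negative and not both zero")
    if n_sessions < 0:
        raise ValueError("n_sessions must be non-negative")
    draw_tau = _resolve_tau_distribution(tau_distribution)
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    animal_seeds = ss.spawn(n_exposed + n_unexposed)
    protocol = protocol or Protocol()

    cohort: list[CohortAnimal] = []
    specs = [(f"E{i + 1:02d}", True) for i in range(n_exposed)] + [
        (f"U{i + 1:02d}", False) for i in range(n_unexposed)
    ]
    for (animal_id, exposed), animal_ss in zip(specs, animal_seeds):
        state_ss, sessions_ss = animal_ss.spawn(2)
        rng = np.random.default_rng(state_ss)
        tau = float(draw_tau(rng)) if exposed else 0.0
        if not (0.0 <= tau <= 1.0):
            raise ValueError("tau distribution produced a value outside [0, 1]")
        lam = float(lambda_bg_median * math.exp(rng.normal(0.0, lambda_bg_sigma)))
        state = AnimalState(
            animal_id=animal_id,
            exposed=exposed,
            tau=tau,
            tinnitus_pitch_khz=tinnitus_pitch_khz,
            lambda_bg=lam,
            c_off=c_off,
        )
        sessions = tuple(
            simulate_session(state, protocol, seed=sess_ss, params=params, session_index=k)
            for k, sess_ss in enumerate(sessions_ss.spawn(n_sessions))
        )
        cohort.append(CohortAnimal(state=state, sessions=sessions))
    return cohort


def make_controlled_session(
    mean_background_r: Fraction | float,
    total_presses: int | None = None,
    animal_id: str = "ctrl",
    session_minutes: int = 60,
) -> SessionLog:
    """Deterministic session with an exact mean background suppression ratio.

    QC boundary scans need sessions whose total press count and mean
    background R are controlled exactly.  Probe minutes tile the odd
    minutes, so every even background minute immediately follows a probe
    and is excluded from the background average; only two engineered
    background minutes near the session end are QC-eligible, each carrying
    R = B/(A+B) built from the exact fraction requested.  The mean of two
    identical floats is that float, so the reported mean equals the request
    bit-for-bit.  Remaining presses are parked on minute 0 (whose R has no
    preceding segment and is always excluded).
    """
    if session_minutes != 60:
        raise ValueError("the controlled layout is defined for 60-minute sessions")
    r = Fraction(mean_background_r).limit_denominator(10**6)
    if not (0 <= r <= 1):
        raise ValueError("mean background R must lie in [0, 1]")
    b = r.numerator
    a = r.denominator - r.numerator
    if a == 0:  # r == 1 needs a zero-count preceding minute: use A=0, B=1
        a, b = 0, 1
    if b == 0:
        a, b = 1, 0

    counts = np.zeros(session_minutes, dtype=int)
    probe_minutes = set(range(1, 52, 2)) | {54, 57}
    counts[52], counts[53] = a, b  # minute 53 eligible: R = b/(a+b)
    counts[55], counts[56] = a, b  # minute 56 eligible: R = b/(a+b)
    base = int(counts.sum())
    if total_presses is None:
        total_presses = max(base, 400)
    slack = total_presses - base
    if slack < 0:
        raise ValueError(f"total_presses must be at least {base} for R = {r}")
    counts[0] += slack

    stim = Stimulus(TONE, 20.0, 70.0)
    periods = []
    times = []
    for minute in range(session_minutes):
        t0, t1 = minute * MINUTE_SEC, (minute + 1) * MINUTE_SEC
        kind = PROBE if minute in probe_minutes else BACKGROUND
        periods.append(Period(t0, t1, kind, stim if kind == PROBE else None))
        c = int(counts[minute])
        if c:
            times.append(t0 + (np.arange(c) + 0.5) * (MINUTE_SEC / c))
    press = np.concatenate(times) if times else np.empty(0)
    return SessionLog(animal_id=animal_id, press_times=press, schedule=tuple(periods))
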