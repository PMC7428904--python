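"""Synthetic paired-device RR recordings for testing and simulation.

The generator emulates 5-minute seated resting recordings: each subject's
tachogram is a mean RR plus three in-band sinusoids (VLF, LF, HF — the HF
tone standing in for respiratory sinus arrhythmia at the subject's
spontaneous breathing rate) plus beat-to-beat white noise:

    RR_i = rr0 + sum_b a_b sin(2 pi f_b t_i + phi_b) + eps_i

with t_i the cumulative beat time.  The reference ("ECG") recording is the
clean series; the test ("chest-strap") twin is derived from it by jittering
beat times, dropping beats (adjacent intervals merge) and inserting
spurious beats (an interval splits), which is how transmission glitches
present in real chest-strap data.

Because the modulation is sinusoidal, each component's contribution to the
tachogram power is a_b^2 / 2 in closed form — the ground truth used in the
spectral-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .metrics import DEFAULT_BANDS
from .rr import Recording, RRSeries, from_beat_times

__all__ = [
    "SubjectModel",
    "DeviceModel",
    "PopulationSpec",
    "generate_rr",
    "band_power_truth",
    "degrade",
    "generate_cohort",
]

_BANDS = ("vlf", "lf", "hf")


@dataclass
class SubjectModel:
    """Parameters of one subject's tachogram.

    Amplitudes ``a_*`` and the white-noise SD ``sigma_wn`` are in ms;
    frequencies in Hz and constrained to their spectral bands.  ``rr0`` must
    dominate the oscillations so intervals stay positive.
    """

    rr0: float = 850.0
    a_vlf: float = 18.0
    a_lf: float = 22.0
    a_hf: float = 28.0
    f_vlf: float = 0.02
    f_lf: float = 0.1
    f_hf: float = 0.25
    phi_vlf: float = 0.0
    phi_lf: float = 0.0
    phi_hf: float = 0.0
    sigma_wn: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rr0 <= 0:
            raise ValueError("rr0 must be positive")
        for b in _BANDS:
            a = getattr(self, f"a_{b}")
            f = getattr(self, f"f_{b}")
            lo, hi = DEFAULT_BANDS[b]
            if a < 0:
                raise ValueError(f"a_{b} must be >= 0")
            if not (lo <= f < hi) or (b == "vlf" and f <= 0):
                raise ValueError(f"f_{b}={f} outside band [{lo}, {hi})")
        if self.sigma_wn < 0:
            raise ValueError("sigma_wn must be >= 0")
        amp = self.a_vlf + self.a_lf + self.a_hf
        if amp + 6.0 * self.sigma_wn >= self.rr0:
            raise ValueError("oscillation amplitudes risk non-positive intervals")


@dataclass
class DeviceModel:
    """Degradation applied to the test-device recording."""

    jitter_sd: float = 3.0  # ms of per-beat timing noise
    miss_rate: float = 0.005  # probability a beat is dropped
    extra_rate: float = 0.005  # probability a spurious beat splits an interval
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for name in ("miss_rate", "extra_rate"):
            r = getattr(self, name)
            if not (0 <= r <= 0.05):
                raise ValueError(f"{name} must be in [0, 0.05]")

    @property
    def is_identity(self) -> bool:
        return self.jitter_sd == 0 and self.miss_rate == 0 and self.extra_rate == 0


def generate_rr(model: SubjectModel, duration: float = 300.0) -> RRSeries:
    """Generate beats iteratively until the cumulative time exceeds duration.

    Deterministic for a fixed ``model.seed``.  The final interval crosses
    ``duration`` so the recording always spans the requested length.
    """
    if duration < 60:
        raise ValueError("duration must be >= 60 s")
    rng = np.random.default_rng(model.seed)
    omegas = [2 * math.pi * getattr(model, f"f_{b}") for b in _BANDS]
    amps = [getattr(model, f"a_{b}") for b in _BANDS]
    phis = [getattr(model, f"phi_{b}") for b in _BANDS]
    intervals: list[float] = []
    t = 0.0
    while t < duration:
        # the tachogram assigns interval i to its terminating beat, so the
        # modulation is evaluated there (one fixed-point refinement suffices)
        t_end = t + model.rr0 / 1000.0
        for _ in range(2):
            rr = model.rr0
            for a, w, p in zip(amps, omegas, phis):
                rr += a * math.sin(w * t_end + p)
            t_end = t + rr / 1000.0
        if model.sigma_wn > 0:
            rr += rng.normal(0.0, model.sigma_wn)
        rr = max(rr, 1.0)
        intervals.append(rr)
        t += rr / 1000.0
    return RRSeries(np.asarray(intervals))


def band_power_truth(model: SubjectModel) -> dict[str, float]:
    """Analytic tachogram power (ms^2) of each sinusoidal component: a^2/2."""
    return {b: getattr(model, f"a_{b}") ** 2 / 2.0 for b in _BANDS}


def degrade(rr: RRSeries, dev: DeviceModel) -> RRSeries:
    """Apply device noise to beat times and rebuild the interval series.

    Beat times are perturbed by N(0, jitter_sd^2); internal beats are
    dropped with ``miss_rate`` (merging adjacent intervals) and spurious
    beats inserted with ``extra_rate`` (splitting an interval at a uniform
    point).  Deterministic per ``dev.seed``.
    """
    if dev.is_identity:
        return rr.copy()
    rng = np.random.default_rng(dev.seed)
    times = np.concatenate(([0.0], rr.beat_times))
    if dev.jitter_sd > 0:
        times = times + rng.normal(0.0, dev.jitter_sd / 1000.0, times.size)
    if dev.miss_rate > 0 and times.size > 2:
        internal = rng.random(times.size - 2) < dev.miss_rate
        keep = np.ones(times.size, dtype=bool)
        keep[1:-1] = ~internal
        times = times[keep]
    if dev.extra_rate > 0 and times.size >= 2:
        lo, hi = times[:-1], times[1:]
        split = rng.random(lo.size) < dev.extra_rate
        extras = lo[split] + rng.random(int(split.sum())) * (hi[split] - lo[split])
        times = np.concatenate([times, extras])
    times = np.unique(np.sort(times))
    if times.size < 2:
        raise ValueError("device degradation left fewer than 2 beats")
    return from_beat_times(times)


@dataclass
class PopulationSpec:
    """Distributions from which a cohort's subject models are drawn.

    Defaults describe young healthy adults seated at rest breathing
    spontaneously: log-normal oscillation amplitudes (between-subject
    spread of autonomic modulation), uniform in-band frequencies with the
    HF tone at the subject's breathing rate (0.18-0.35 Hz, i.e. 11-21
    breaths/min), and moderate beat-to-beat noise.
    """

    rr0_mean: float = 850.0
    rr0_sd: float = 70.0
    amp_medians: dict = field(
        default_factory=lambda: {"vlf": 18.0, "lf": 22.0, "hf": 28.0}
    )
    amp_sigmas: dict = field(
        default_factory=lambda: {"vlf": 0.4, "lf": 0.4, "hf": 0.5}
    )
    freq_ranges: dict = field(
        default_factory=lambda: {
            "vlf": (0.005, 0.035),
            "lf": (0.06, 0.13),
            "hf": (0.18, 0.35),
        }
    )
    sigma_wn_range: tuple = (8.0, 18.0)
    amp_cap: float = 70.0  # ms; keeps rr0 dominant over the oscillations

    def draw(self, rng: np.random.Generator, seed: int) -> SubjectModel:
        kw: dict = {"seed": seed}
        kw["rr0"] = float(np.clip(rng.normal(self.rr0_mean, self.rr0_sd), 600, 1100))
        for b in _BANDS:
            a = rng.lognormal(math.log(self.amp_medians[b]), self.amp_sigmas[b])
            kw[f"a_{b}"] = float(min(a, self.amp_cap))
            lo, hi = self.freq_ranges[b]
            kw[f"f_{b}"] = float(rng.uniform(lo, hi))
            kw[f"phi_{b}"] = float(rng.uniform(0, 2 * math.pi))
        kw["sigma_wn"] = float(rng.uniform(*self.sigma_wn_range))
        return SubjectModel(**kw)


def generate_cohort(
    n_subjects: int = 60,
    population: PopulationSpec | None = None,
    device: DeviceModel | None = None,
    master_seed: int = 0,
    duration: float = 300.0,
) -> list[tuple[Recording, Recording]]:
    """Paired (reference, test) recordings for a cohort.

    Per-subject seeds are derived as ``master_seed + i`` (device noise uses
    an offset stream), so any subject's pair is reproducible independently
    of cohort size.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    population = population or PopulationSpec()
    device = device or DeviceModel()
    pairs: list[tuple[Recording, Recording]] = []
    for i in range(n_subjects):
        subj_seed = int((master_seed + i) % 2**31)
        rng = np.random.default_rng(subj_seed)
        model = population.draw(rng, seed=subj_seed)
        rr_ref = generate_rr(model, duration)
        dev_i = DeviceModel(
            jitter_sd=device.jitter_sd,
            miss_rate=device.miss_rate,
            extra_rate=device.extra_rate,
            seed=int((master_seed + 1_000_000 + i) % 2**31),
        )
        rr_test = degrade(rr_ref, dev_i)
        sid = f"S{i:03d}"
        meta = {"model": model, "truth_ms2": band_power_truth(model)}
        pairs.append(
            (
                Recording(sid, "reference", rr_ref, dict(meta)),
                Recording(sid, "test", rr_test, dict(meta)),
            )
        )
    return pairs
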