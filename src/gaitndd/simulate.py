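"""Synthetic vGRF generator for the four gait phenotypes (HC, ALS, HD, PD).

The generator produces a per-foot train of stance-phase force profiles.
Each stance is an M-shaped double bump (loading peak, mid-stance valley,
push-off peak); the two feet alternate with a half-cycle phase offset, so
the compound-foot (CF) sum shows, per combined gait cycle, two deep minima
at the step transitions and one shallower single-support minimum.

Phenotypes differ in cadence and its variability, not in an arbitrary
label: healthy controls walk with a stable step rate in the 1.6-2.1 Hz
band; ALS gait is slower (~1.3 Hz steps) with raised inter-peak minima
(incomplete unloading) and larger step-to-step variability; Huntington's
gait is modeled as a bounded random walk of cadence across 1-2.5 Hz
(fluctuating walking velocity); Parkinsonian gait keeps a near-normal
cadence but adds left/right amplitude asymmetry and a ~5 Hz tremor
modulation.

Force units are arbitrary, scaled to the 0-3.5 range of the force-sensing
insole the target database was recorded with; no Newton calibration is
claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import GROUPS, GaitRecord

#: Stance occupies this fraction of one foot's full gait cycle.  Slightly
#: more than half: successive stances overlap only briefly (double
#: support), so the compound force dips toward zero at every step
#: transition, as in the target database's sensor traces.
STANCE_FRACTION = 0.55
#: Loading-response and push-off peak heights and mid-stance valley depth,
#: as fractions of the body-weight scale amplitude.
PEAK1, PEAK2, VALLEY = 1.0, 1.05, 0.8


@dataclass(frozen=True)
class GaitPhenotypeConfig:
    """Parameters of one simulated gait phenotype.

    Attributes
    ----------
    step_rate_hz : float
        Mean step rate (steps per second, both feet counted).  The CF
        spectrum's fundamental sits here.
    step_rate_cv : float
        Coefficient of variation of the inter-step interval (independent
        per-step jitter).
    minimum_floor : float
        Fraction of the per-foot peak force retained during swing
        (incomplete unloading); 0 for healthy gait.
    asymmetry : float
        LF/RF amplitude ratio; 1 means symmetric.
    tremor_hz : float | None
        Tremor modulation frequency, or None.
    tremor_amp : float
        Tremor modulation depth as a fraction of the stance profile.
    rate_walk_sigma : float
        Per-step standard deviation of a bounded random walk of the mean
        cadence (Hz per step); drives the Huntington phenotype.
    rate_walk_bounds : tuple
        Reflecting bounds of the cadence random walk, Hz.
    amplitude : float
        Per-foot peak force, arbitrary units.
    amplitude_ceiling : float
        Sensor ceiling; output is clipped to [0, ceiling].
    seed : int
        Seed of the per-record random stream.
    """

    group: str
    step_rate_hz: float
    step_rate_cv: float
    minimum_floor: float = 0.0
    asymmetry: float = 1.0
    tremor_hz: float | None = None
    tremor_amp: float = 0.0
    rate_walk_sigma: float = 0.0
    rate_walk_bounds: tuple[float, float] = (1.0, 2.5)
    amplitude: float = 1.5
    amplitude_ceiling: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.step_rate_hz > 0:
            raise ValueError("step_rate_hz must be > 0")
        if not 0 <= self.minimum_floor < 1:
            raise ValueError("minimum_floor must be in [0, 1)")
        if not 0 <= self.tremor_amp < 1:
            raise ValueError("tremor_amp must be in [0, 1)")
        if not self.amplitude_ceiling > 0:
            raise ValueError("amplitude_ceiling must be > 0")


_DEFAULTS: dict[str, GaitPhenotypeConfig] = {
    # Stable cadence in the healthy 1.6-2.1 Hz band, full unloading.
    "HC": GaitPhenotypeConfig("HC", step_rate_hz=1.85, step_rate_cv=0.02),
    # Slow gait, high step-time variability, minima far from zero.
    "ALS": GaitPhenotypeConfig(
        "ALS", step_rate_hz=1.3, step_rate_cv=0.12, minimum_floor=0.35
    ),
    # Fluctuating walking velocity: cadence random-walks across 1-2.5 Hz.
    "HD": GaitPhenotypeConfig(
        "HD", step_rate_hz=1.7, step_rate_cv=0.06, rate_walk_sigma=0.08,
        minimum_floor=0.15,
    ),
    # Near-normal cadence, unequal force distribution, ~5 Hz tremor.
    "PD": GaitPhenotypeConfig(
        "PD", step_rate_hz=1.8, step_rate_cv=0.04, asymmetry=0.75,
        tremor_hz=5.0, tremor_amp=0.15,
    ),
}


def default_phenotype(group: str) -> GaitPhenotypeConfig:
    """The default phenotype configuration for one of HC, ALS, HD, PD."""
    try:
        return _DEFAULTS[group]
    except KeyError:
        raise ValueError(
            f"unknown group {group!r}; expected one of {GROUPS}"
        ) from None


#: Control points of the M-shaped stance profile on normalized stance time:
#: rise from 0 to the loading-response peak, dip to the mid-stance valley,
#: rise to the push-off peak, fall back to 0.
_STANCE_KNOTS_U = (0.0, 0.25, 0.5, 0.75, 1.0)


def _stance_profile(u: np.ndarray) -> np.ndarray:
    """M-shaped stance force profile on normalized stance time u in [0, 1].

    Piecewise raised-cosine interpolation through the knot values
    (0, PEAK1, VALLEY, PEAK2, 0); smooth, with zero slope at every knot.
    """
    knots_v = (0.0, PEAK1, VALLEY, PEAK2, 0.0)
    u = np.clip(u, 0.0, 1.0)
    prof = np.zeros_like(u)
    for (u0, u1), (v0, v1) in zip(
        zip(_STANCE_KNOTS_U[:-1], _STANCE_KNOTS_U[1:]),
        zip(knots_v[:-1], knots_v[1:]),
    ):
        seg = (u >= u0) & (u <= u1)
        frac = (u[seg] - u0) / (u1 - u0)
        prof[seg] = v0 + (v1 - v0) * 0.5 * (1 - np.cos(np.pi * frac))
    return prof


def _step_times(
    config: GaitPhenotypeConfig, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Onset times of successive steps (feet alternating) covering duration."""
    times = [0.0]
    rate = config.step_rate_hz
    lo, hi = config.rate_walk_bounds
    while times[-1] < duration_s:
        if config.rate_walk_sigma > 0:
            rate = rate + rng.normal(0.0, config.rate_walk_sigma)
            # reflect into bounds
            if rate < lo:
                rate = lo + (lo - rate)
            if rate > hi:
                rate = hi - (rate - hi)
            rate = float(np.clip(rate, lo, hi))
        interval = (1.0 / rate) * max(
            0.2, 1.0 + config.step_rate_cv * rng.standard_normal()
        )
        times.append(times[-1] + interval)
    return np.asarray(times)


def generate_record(
    config: GaitPhenotypeConfig,
    duration_s: float = 300.0,
    fs: float = 300.0,
    subject_id: str = "sim",
) -> GaitRecord:
    """Synthesize one two-channel vGRF record from a phenotype config.

    Bit-identical output for identical (config, duration_s, fs).
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    steps = _step_times(config, duration_s, rng)
    forces = {0: np.zeros(n), 1: np.zeros(n)}  # 0 = LF, 1 = RF
    for i, onset in enumerate(steps):
        foot = i % 2
        # stance lasts STANCE_FRACTION of this foot's full cycle (two steps)
        if i + 2 < steps.size:
            cycle = steps[i + 2] - onset
        elif i + 1 < steps.size:
            cycle = 2 * (steps[i + 1] - onset)
        else:
            cycle = 2.0 / config.step_rate_hz
        stance = STANCE_FRACTION * cycle
        i0 = int(np.ceil(onset * fs))
        i1 = min(int(np.floor((onset + stance) * fs)) + 1, n)
        if i0 >= n or i1 <= i0:
            continue
        u = (t[i0:i1] - onset) / stance
        forces[foot][i0:i1] += _stance_profile(u)
    lf = forces[0] * config.amplitude * config.asymmetry
    rf = forces[1] * config.amplitude
    if config.tremor_hz is not None and config.tremor_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        mod = 1.0 + config.tremor_amp * np.sin(2 * np.pi * config.tremor_hz * t + phase)
        lf = lf * mod
        rf = rf * mod
    # incomplete unloading: the foot never drops below a floor force
    floor_lf = config.minimum_floor * config.amplitude * config.asymmetry
    floor_rf = config.minimum_floor * config.amplitude
    lf = np.maximum(lf, floor_lf)
    rf = np.maximum(rf, floor_rf)
    lf = np.clip(lf, 0.0, config.amplitude_ceiling)
    rf = np.clip(rf, 0.0, config.amplitude_ceiling)
    return GaitRecord(subject_id=subject_id, group=config.group, fs=fs, lf=lf, rf=rf)


#: Cohort sizes of the public database: 16 HC, 13 ALS, 20 HD, 15 PD.
DEFAULT_COHORT = {"HC": 16, "ALS": 13, "HD": 20, "PD": 15}


def generate_cohort(
    n_per_group: dict[str, int] | None = None,
    duration_s: float = 300.0,
    fs: float = 300.0,
    seed: int = 0,
    overrides: dict[str, GaitPhenotypeConfig] | None = None,
) -> list[GaitRecord]:
    """Generate a cohort of records with deterministic per-subject seeds.

    Per-subject seeds are drawn from a SeedSequence spawned from ``seed``,
    so cohorts are reproducible and subjects mutually independent.
    """
    n_per_group = DEFAULT_COHORT if n_per_group is None else n_per_group
    overrides = overrides or {}
    ss = np.random.SeedSequence(seed)
    records = []
    for group in GROUPS:
        count = int(n_per_group.get(group, 0))
        for j in range(count):
            child = ss.spawn(1)[0]
            sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            base = overrides.get(group, default_phenotype(group))
            cfg = replace(base, seed=sub_seed)
            records.append(
                generate_record(
                    cfg, duration_s=duration_s, fs=fs, subject_id=f"{group.lower()}{j + 1:02d}"
                )
            )
    return records
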