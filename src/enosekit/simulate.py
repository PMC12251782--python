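"""Synthetic electronic-nose array recordings.

The module emulates a 23-channel gas-sensor array (9 electrochemical, 5
metal-oxide, 6 photoionization, 1 NDIR channel plus pressure and
temperature/humidity reference channels) exposed to mixtures of the eight
regulated malodor gases.  Two sampling protocols are provided:

* **intermittent** — clean / gas / clean cycles recorded as 600 points per
  cycle (pre-clean 300 s, gas 180 s, post-clean 120 s at 1 Hz), and
* **continuous** — a long initial clean-air stretch followed by random
  concentration steps with random hold times, without purging.

Sensor dynamics are modelled as asymmetric first-order relaxation toward a
power-law steady state, with optional short-term drift: a random-walk
baseline plus a carry-over term that lets an incompletely recovered channel
contaminate the next exposure (the mechanism behind unequal responses to
identical pulses after short cleans).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GAS_NAMES",
    "GasSpec",
    "SensorSpec",
    "ExposureProfile",
    "ArrayRecording",
    "default_gases",
    "default_array",
    "gen_intermittent",
    "gen_continuous",
    "simulate_response",
]

#: The eight regulated malodor gases, in canonical column order.
GAS_NAMES = (
    "hydrogen_sulfide",
    "methyl_sulfide",
    "dimethyl_disulfide",
    "methyl_mercaptan",
    "carbon_disulfide",
    "styrene",
    "ammonia",
    "trimethylamine",
)

# reference conditions at which sensitivities are specified
T_REF_C = 25.0
RH_REF_PCT = 57.0
P_REF_KPA = 101.3

TEMP_BOUNDS_C = (15.0, 36.0)
RH_BOUNDS_PCT = (30.0, 84.0)


@dataclass(frozen=True)
class GasSpec:
    """A target gas and its concentration range in ppm."""

    name: str
    conc_min: float = 0.0
    conc_max: float = 14.0

    def __post_init__(self):
        if self.conc_min < 0:
            raise ValueError(f"{self.name}: conc_min must be >= 0")
        if self.conc_max <= self.conc_min:
            raise ValueError(f"{self.name}: conc_max must exceed conc_min")


def default_gases() -> list[GasSpec]:
    """The eight regulated gases: six at 0-14 ppm, the two amines at 0-20 ppm."""
    return [
        GasSpec(name, 0.0, 20.0 if name in ("ammonia", "trimethylamine") else 14.0)
        for name in GAS_NAMES
    ]


@dataclass
class SensorSpec:
    """One array channel: static sensitivity, dynamics, noise and drift."""

    id: str
    principle: str  # EC | MOS | PID | NDIR | RC
    sensitivity: np.ndarray  # AD counts per ppm at reference conditions, len 8
    exponent: np.ndarray  # power-law response shape per gas, len 8
    tau_resp: float  # response time constant, s
    tau_rec: float  # recovery time constant, s
    baseline: float  # clean-air AD level
    noise_sd: float  # measurement noise, AD counts
    drift_walk_sd: float  # random-walk baseline step sd, AD counts
    carryover: float  # fraction of previous excess carried into the next segment
    carry_tau: float = 600.0  # decay time of the carry-over term, s
    env_coeff: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )  # AD per (degC, %RH, kPa) away from reference

    def __post_init__(self):
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.exponent = np.asarray(self.exponent, dtype=float)
        self.env_coeff = np.asarray(self.env_coeff, dtype=float)
        if self.sensitivity.shape != (len(GAS_NAMES),):
            raise ValueError(f"{self.id}: sensitivity must have length 8")
        if self.exponent.shape != (len(GAS_NAMES),):
            raise ValueError(f"{self.id}: exponent must have length 8")
        if self.tau_resp <= 0 or self.tau_rec <= 0:
            raise ValueError(f"{self.id}: time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError(f"{self.id}: noise_sd must be >= 0")
        if not (0.0 <= self.carryover < 1.0):
            raise ValueError(f"{self.id}: carryover must lie in [0, 1)")

    @property
    def is_environment(self) -> bool:
        return self.principle == "RC"


# index shorthand for the default sensitivity table
_G = {name: i for i, name in enumerate(GAS_NAMES)}


def _sens(**ppm_gains: float) -> np.ndarray:
    v = np.zeros(len(GAS_NAMES))
    for name, gain in ppm_gains.items():
        v[_G[name]] = gain
    return v


def _default_specs() -> list[SensorSpec]:
    ec = dict(tau_resp=25.0, tau_rec=45.0, baseline=400.0, noise_sd=2.0,
              drift_walk_sd=0.4, carryover=0.15,
              env_coeff=np.array([0.8, 0.2, 0.0]))
    mos = dict(tau_resp=35.0, tau_rec=90.0, baseline=800.0, noise_sd=3.0,
               drift_walk_sd=0.8, carryover=0.30,
               env_coeff=np.array([-3.0, -1.2, 0.0]))
    pid = dict(tau_resp=8.0, tau_rec=15.0, baseline=300.0, noise_sd=2.0,
               drift_walk_sd=0.5, carryover=0.10,
               env_coeff=np.array([0.5, -0.4, 0.0]))
    ones = np.ones(8)
    sub = np.full(8, 0.6)  # MOS channels respond sublinearly

    def mk(sid, principle, sens, kin, exp=ones):
        return SensorSpec(id=sid, principle=principle, sensitivity=sens,
                          exponent=exp, **kin)

    specs = [
        # electrochemical: the nominal target of each cell carries the top gain
        mk("S1", "EC", _sens(ammonia=35, trimethylamine=6), ec),
        mk("S2", "EC", _sens(hydrogen_sulfide=40, methyl_mercaptan=8,
                             dimethyl_disulfide=4), ec),
        mk("S3", "EC", _sens(methyl_mercaptan=45, hydrogen_sulfide=10,
                             methyl_sulfide=6), ec),
        mk("S4", "EC", _sens(methyl_sulfide=42, dimethyl_disulfide=8,
                             methyl_mercaptan=6), ec),
        mk("S5", "EC", _sens(carbon_disulfide=40, hydrogen_sulfide=3), ec),
        mk("S6", "EC", _sens(dimethyl_disulfide=44, methyl_sulfide=8,
                             methyl_mercaptan=5), ec),
        mk("S7", "EC", _sens(carbon_disulfide=30, dimethyl_disulfide=4), ec),
        mk("S8", "EC", _sens(styrene=38, methyl_sulfide=2), ec),
        mk("S9", "EC", _sens(hydrogen_sulfide=6, methyl_mercaptan=4,
                             carbon_disulfide=3), ec),
        # metal-oxide: broadly sensitive, sublinear
        mk("S10", "MOS", _sens(hydrogen_sulfide=18, methyl_sulfide=14,
                               dimethyl_disulfide=12, methyl_mercaptan=16,
                               carbon_disulfide=8, styrene=12, ammonia=6,
                               trimethylamine=10), mos, sub),
        mk("S11", "MOS", _sens(hydrogen_sulfide=14, methyl_sulfide=16,
                               dimethyl_disulfide=14, methyl_mercaptan=12,
                               carbon_disulfide=6, styrene=16, ammonia=8,
                               trimethylamine=12), mos, sub),
        mk("S12", "MOS", _sens(trimethylamine=30, ammonia=18,
                               methyl_mercaptan=10, hydrogen_sulfide=8,
                               methyl_sulfide=8, dimethyl_disulfide=8,
                               styrene=10, carbon_disulfide=4), mos, sub),
        mk("S13", "MOS", _sens(trimethylamine=22, methyl_mercaptan=14,
                               hydrogen_sulfide=12, ammonia=10,
                               dimethyl_disulfide=10, methyl_sulfide=8,
                               styrene=6, carbon_disulfide=4), mos, sub),
        mk("S14", "MOS", _sens(styrene=16, methyl_sulfide=12,
                               dimethyl_disulfide=10, carbon_disulfide=10,
                               methyl_mercaptan=8, hydrogen_sulfide=8,
                               ammonia=4, trimethylamine=8), mos, sub),
        # photoionization: strong for organics, weak for H2S/NH3
        mk("S15", "PID", _sens(styrene=30, dimethyl_disulfide=28,
                               methyl_sulfide=25, methyl_mercaptan=22,
                               trimethylamine=20, carbon_disulfide=8,
                               hydrogen_sulfide=4, ammonia=2), pid),
        mk("S16", "PID", _sens(trimethylamine=35, styrene=26,
                               dimethyl_disulfide=24, methyl_sulfide=22,
                               methyl_mercaptan=20, carbon_disulfide=7,
                               hydrogen_sulfide=4, ammonia=2), pid),
        mk("S17", "PID", _sens(styrene=24, methyl_sulfide=20,
                               dimethyl_disulfide=22, methyl_mercaptan=18,
                               trimethylamine=16, carbon_disulfide=6,
                               hydrogen_sulfide=3, ammonia=1), pid),
        mk("S18", "PID", _sens(styrene=18, methyl_sulfide=15,
                               dimethyl_disulfide=16, methyl_mercaptan=13,
                               trimethylamine=12, carbon_disulfide=5,
                               hydrogen_sulfide=2, ammonia=1), pid),
        mk("S19", "PID", _sens(styrene=28, methyl_sulfide=23,
                               dimethyl_disulfide=25, methyl_mercaptan=20,
                               trimethylamine=18, carbon_disulfide=7,
                               hydrogen_sulfide=3, ammonia=1), pid),
        mk("S20", "PID", _sens(styrene=10, methyl_sulfide=8,
                               dimethyl_disulfide=9, methyl_mercaptan=7,
                               trimethylamine=6, carbon_disulfide=3,
                               hydrogen_sulfide=1, ammonia=1), pid),
        # NDIR: near-inert to the target set
        SensorSpec(id="S21", principle="NDIR",
                   sensitivity=_sens(carbon_disulfide=2, styrene=1),
                   exponent=ones, tau_resp=15.0, tau_rec=20.0, baseline=1200.0,
                   noise_sd=2.0, drift_walk_sd=0.2, carryover=0.0,
                   env_coeff=np.array([0.3, 0.0, -1.0])),
        # reference channels: pressure (S22) and temperature/humidity (S23)
        SensorSpec(id="S22", principle="RC", sensitivity=np.zeros(8),
                   exponent=ones, tau_resp=1.0, tau_rec=1.0, baseline=2000.0,
                   noise_sd=1.0, drift_walk_sd=0.0, carryover=0.0,
                   env_coeff=np.array([0.0, 0.0, 50.0])),
        SensorSpec(id="S23", principle="RC", sensitivity=np.zeros(8),
                   exponent=ones, tau_resp=1.0, tau_rec=1.0, baseline=1000.0,
                   noise_sd=1.0, drift_walk_sd=0.0, carryover=0.0,
                   env_coeff=np.array([10.0, 5.0, 0.0])),
    ]
    return specs


def default_array(config: dict | None = None) -> list[SensorSpec]:
    """Return the 23 default channel specs, optionally overriding fields.

    ``config`` maps a channel id (or the wildcard ``"*"``) to a dict of
    SensorSpec field overrides, e.g. ``{"*": {"noise_sd": 0.0}}``.
    """
    specs = _default_specs()
    if not config:
        return specs
    known = {s.id for s in specs}
    for sid in config:
        if sid != "*" and sid not in known:
            raise KeyError(f"unknown channel id {sid!r}")
    out = []
    for s in specs:
        overrides = dict(config.get("*", {}))
        overrides.update(config.get(s.id, {}))
        out.append(replace(s, **overrides) if overrides else s)
    return out


@dataclass
class ExposureProfile:
    """Ground-truth exposure: concentrations plus chamber environment at 1 Hz."""

    time: np.ndarray  # seconds, strictly increasing at 1 s
    conc: np.ndarray  # (T, 8) ppm
    temp: np.ndarray  # degC
    rh: np.ndarray  # %RH
    press: np.ndarray  # kPa
    segments: list[tuple[int, int, str]]  # (start, end, "clean"|"gas"), end exclusive

    def __post_init__(self):
        T = len(self.time)
        if self.conc.shape != (T, len(GAS_NAMES)):
            raise ValueError("conc must be (T, 8)")
        if (self.conc < 0).any():
            raise ValueError("concentrations must be nonnegative")

    def __len__(self) -> int:
        return len(self.time)


def _env_series(T: int, rng: np.random.Generator,
                temp_bounds=TEMP_BOUNDS_C, rh_bounds=RH_BOUNDS_PCT,
                press_mean=P_REF_KPA) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slowly varying chamber temperature/humidity/pressure within bounds."""
    t = np.arange(T)

    def slow(lo, hi, period, walk_sd):
        mid, amp = 0.5 * (lo + hi), 0.35 * (hi - lo)
        phase = rng.uniform(0, 2 * np.pi)
        base = mid + amp * np.sin(2 * np.pi * t / period + phase)
        walk = np.cumsum(rng.normal(0.0, walk_sd, T))
        return np.clip(base + walk, lo, hi)

    temp = slow(*temp_bounds, period=86400.0, walk_sd=2e-3)
    rh = slow(*rh_bounds, period=86400.0, walk_sd=6e-3)
    press = np.clip(press_mean + np.cumsum(rng.normal(0, 2e-4, T)),
                    press_mean - 1.0, press_mean + 1.0)
    return temp, rh, press


def _draw_conc(rng: np.random.Generator, gas_specs: list[GasSpec],
               active: np.ndarray) -> np.ndarray:
    c = np.zeros(len(gas_specs))
    for j in active:
        g = gas_specs[j]
        c[j] = rng.uniform(g.conc_min, g.conc_max)
    return c


def gen_intermittent(n_cycles: int, gases: list[str] | None = None,
                     seed: int | None = None,
                     protocol: tuple[int, int, int] = (300, 180, 120),
                     mixture: bool = False, max_components: int = 3,
                     gas_specs: list[GasSpec] | None = None) -> ExposureProfile:
    """Clean/gas/clean cycles, 600 recorded points per cycle at 1 Hz.

    Each cycle draws either a single gas (default) or a small mixture, with
    concentrations uniform within each gas's range.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    pre, gas_dur, post = protocol
    if pre + gas_dur + post != 600:
        raise ValueError(
            f"protocol {protocol} does not tile the 600-point cycle window")
    gas_specs = gas_specs or default_gases()
    names = [g.name for g in gas_specs]
    pool = np.arange(len(names)) if gases is None else np.array(
        [names.index(g) for g in gases])
    rng = np.random.default_rng(seed)

    T = 600 * n_cycles
    conc = np.zeros((T, len(gas_specs)))
    segments: list[tuple[int, int, str]] = []
    for k in range(n_cycles):
        t0 = 600 * k
        if mixture:
            n_active = rng.integers(1, min(max_components, len(pool)) + 1)
            active = rng.choice(pool, size=n_active, replace=False)
        else:
            active = np.array([rng.choice(pool)])
        c = _draw_conc(rng, gas_specs, active)
        conc[t0 + pre : t0 + pre + gas_dur] = c
        segments += [(t0, t0 + pre, "clean"),
                     (t0 + pre, t0 + pre + gas_dur, "gas"),
                     (t0 + pre + gas_dur, t0 + 600, "clean")]
    temp, rh, press = _env_series(T, rng)
    return ExposureProfile(np.arange(T, dtype=float), conc, temp, rh, press,
                           segments)


def gen_continuous(n_conditions: int, seed: int | None = None,
                   hold_range: tuple[int, int] = (60, 300),
                   initial_clean: int = 1200, mixture: bool = True,
                   max_components: int = 3, p_clean: float = 0.2,
                   all_zero: bool = False,
                   gas_specs: list[GasSpec] | None = None) -> ExposureProfile:
    """Non-intermittent protocol: initial clean air, then random step conditions.

    Hold times are uniform over ``hold_range`` seconds; with probability
    ``p_clean`` a condition is a ventilation (all-zero) step.  ``all_zero``
    forces a clean-air-only profile of the same length statistics.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    gas_specs = gas_specs or default_gases()
    rng = np.random.default_rng(seed)

    holds = rng.integers(hold_range[0], hold_range[1] + 1, size=n_conditions)
    T = int(initial_clean + holds.sum())
    conc = np.zeros((T, len(gas_specs)))
    segments: list[tuple[int, int, str]] = [(0, initial_clean, "clean")]
    t0 = initial_clean
    pool = np.arange(len(gas_specs))
    for hold in holds:
        t1 = t0 + int(hold)
        if all_zero or rng.uniform() < p_clean:
            segments.append((t0, t1, "clean"))
        else:
            n_active = rng.integers(1, max_components + 1) if mixture else 1
            active = rng.choice(pool, size=n_active, replace=False)
            conc[t0:t1] = _draw_conc(rng, gas_specs, active)
            segments.append((t0, t1, "gas"))
        t0 = t1
    temp, rh, press = _env_series(T, rng)
    return ExposureProfile(np.arange(T, dtype=float), conc, temp, rh, press,
                           segments)


@dataclass
class ArrayRecording:
    """A simulated (or loaded) multichannel recording with ground truth."""

    time: np.ndarray  # seconds at 1 Hz
    channels: np.ndarray  # (T, C) AD counts
    channel_ids: list[str]
    truth: np.ndarray  # (T, 8) ppm
    temp: np.ndarray
    rh: np.ndarray
    press: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        T = len(self.time)
        if self.channels.shape[0] != T or self.truth.shape != (T, len(GAS_NAMES)):
            raise ValueError("inconsistent recording dimensions")
        if np.isnan(self.channels).any() or np.isnan(self.truth).any():
            raise ValueError("recording contains missing values")
        dt = np.diff(self.time)
        if len(dt) and not np.allclose(dt, 1.0):
            raise ValueError("time must advance in strict 1 s steps")

    def __len__(self) -> int:
        return len(self.time)

    def copy_with(self, channels: np.ndarray) -> "ArrayRecording":
        return ArrayRecording(self.time.copy(), channels, list(self.channel_ids),
                              self.truth.copy(), self.temp.copy(),
                              self.rh.copy(), self.press.copy(),
                              dict(self.provenance))

    # ----------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time}
        for i, cid in enumerate(self.channel_ids):
            data[f"ch_{cid}"] = self.channels[:, i]
        data["temp_C"] = self.temp
        data["rh_pct"] = self.rh
        data["press_kPa"] = self.press
        for j, g in enumerate(GAS_NAMES):
            data[f"c_{g}"] = self.truth[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ArrayRecording":
        df = pd.read_csv(path)
        ch_cols = [c for c in df.columns if c.startswith("ch_")]
        return cls(
            time=df["time_s"].to_numpy(dtype=float),
            channels=df[ch_cols].to_numpy(dtype=float),
            channel_ids=[c[3:] for c in ch_cols],
            truth=df[[f"c_{g}" for g in GAS_NAMES]].to_numpy(dtype=float),
            temp=df["temp_C"].to_numpy(dtype=float),
            rh=df["rh_pct"].to_numpy(dtype=float),
            press=df["press_kPa"].to_numpy(dtype=float),
        )


def _steady_state(spec: SensorSpec, profile: ExposureProfile) -> np.ndarray:
    """Target AD level per time step: baseline + power-law gas term + environment."""
    conc = profile.conc
    gas = np.zeros(len(profile))
    for j in range(conc.shape[1]):
        if spec.sensitivity[j] != 0.0:
            gas += spec.sensitivity[j] * conc[:, j] ** spec.exponent[j]
    env = (spec.env_coeff[0] * (profile.temp - T_REF_C)
           + spec.env_coeff[1] * (profile.rh - RH_REF_PCT)
           + spec.env_coeff[2] * (profile.press - P_REF_KPA))
    return spec.baseline + gas + env


def simulate_response(profile: ExposureProfile, sensors: list[SensorSpec],
                      seed: int | None = None, drift_on: bool = True
                      ) -> ArrayRecording:
    """Integrate the sensor dynamics over an exposure profile.

    Per channel the internal state relaxes toward the steady-state target with
    the response time constant on the way up and the (slower) recovery
    constant on the way down, using the exact one-step exponential update of
    the first-order ODE at the 1 s sampling interval.  With ``drift_on`` a
    random-walk baseline and a decaying carry-over term (injected whenever a
    gas segment ends) are added before noise and integer AD quantization.
    """
    for s in sensors:
        if not np.all(np.isfinite([s.tau_resp, s.tau_rec, s.baseline])):
            raise ValueError(f"{s.id}: non-finite dynamics parameters")
    T = len(profile)
    rng = np.random.default_rng(seed)
    out = np.zeros((T, len(sensors)))
    gas_ends = sorted(end for start, end, mode in profile.segments
                      if mode == "gas" and end < T)
    a_resp = {s.id: 1.0 - np.exp(-1.0 / s.tau_resp) for s in sensors}
    a_rec = {s.id: 1.0 - np.exp(-1.0 / s.tau_rec) for s in sensors}
    for i, spec in enumerate(sensors):
        target = _steady_state(spec, profile)
        state = np.empty(T)
        state[0] = target[0]
        up, down = a_resp[spec.id], a_rec[spec.id]
        s = target[0]
        # relax toward the previous instant's target: a step at t0 first
        # moves the response at t0 + 1, so t0 + tau sees 1 - e^-1 of the step
        for t in range(1, T):
            alpha = up if target[t - 1] > s else down
            s += alpha * (target[t - 1] - s)
            state[t] = s
        signal = state
        if drift_on:
            walk = np.cumsum(rng.normal(0.0, spec.drift_walk_sd, T))
            hyst = np.zeros(T)
            if spec.carryover > 0.0 and gas_ends:
                decay = np.exp(-1.0 / spec.carry_tau)
                ends = set(gas_ends)
                h = 0.0
                for t in range(T):
                    h *= decay
                    if t in ends:
                        # excess of the state over the gas-free level when
                        # the exposure ends feeds the next segment
                        h += spec.carryover * max(
                            state[t] - env_only_level(spec, profile, t), 0.0)
                    hyst[t] = h
            signal = signal + walk + hyst
        noise = rng.normal(0.0, spec.noise_sd, T) if spec.noise_sd > 0 else 0.0
        out[:, i] = np.maximum(np.round(signal + noise), 0.0)
    provenance = {"seed": seed, "drift_on": drift_on,
                  "n_sensors": len(sensors)}
    return ArrayRecording(profile.time.copy(), out, [s.id for s in sensors],
                          profile.conc.copy(), profile.temp.copy(),
                          profile.rh.copy(), profile.press.copy(), provenance)


def env_only_level(spec: SensorSpec, profile: ExposureProfile, t: int) -> float:
    """The channel's gas-free AD level at time t (baseline + environment)."""
    return float(
        spec.baseline
        + spec.env_coeff[0] * (profile.temp[t] - T_REF_C)
        + spec.env_coeff[1] * (profile.rh[t] - RH_REF_PCT)
        + spec.env_coeff[2] * (profile.press[t] - P_REF_KPA)
    )
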