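"""Synthetic anesthesia-case simulator.

Generates per-patient 1-Hz records of cumulative propofol/remifentanil dose
and BIS through three anesthesia phases (induction bolus, maintenance
plateau, recovery after the propofol stop), with covariate-driven
inter-patient distribution shift and configurable recording defects
(measurement noise, missing stretches, non-monotone cumulative-dose
glitches, a depressed starting BIS, a delayed first BIS sample).

Drug disposition follows a standard three-compartment mammillary model with
an effect-site compartment:

    dA1/dt = u(t) - (k10 + k12 + k13) A1 + k21 A2 + k31 A3
    dA2/dt = k12 A1 - k21 A2
    dA3/dt = k13 A1 - k31 A3
    dCe/dt = ke0 (A1/V1 - Ce)

with plasma concentration Cp = A1/V1.  The system is linear with
piecewise-constant input, so each 1-s step is advanced by the exact
zero-order-hold discretization (matrix exponential of the augmented
system); mass balance then holds to machine precision and the
one-compartment limit reproduces its closed form exactly.

Effect is a sigmoid-Emax response on the combined potency-scaled effect-site
concentration U = Ce_prop/EC50_prop + Ce_remi/EC50_remi:

    BIS = E0 - Emax * U^gamma / (1 + U^gamma)

The default population constants are arbitrary fixture values in plausible
propofol/remifentanil ranges, not clinical parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PKParams",
    "PDParams",
    "PatientProfile",
    "InfusionProtocol",
    "CaseRecord",
    "NoiseConfig",
    "DEFAULT_SHIFT_CONFIG",
    "sample_patient",
    "simulate_pk",
    "simulate_drug_pk",
    "default_protocol",
    "simulate_bis",
    "simulate_case",
    "corrupt",
    "generate_cohort",
]

MISSING = np.nan


@dataclass(frozen=True)
class PKParams:
    """Compartment volumes (L) and rate constants (1/min) for one drug."""

    V1: float
    V2: float
    V3: float
    k10: float
    k12: float
    k21: float
    k13: float
    k31: float
    ke0: float

    def validate(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"PK parameter {name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class PDParams:
    """Sigmoid-Emax response surface parameters."""

    E0: float  # awake BIS
    Emax: float  # maximal BIS depression
    EC50_prop: float  # µg/mL
    EC50_remi: float  # ng/mL
    gamma: float

    def validate(self) -> None:
        if not (0 < self.Emax <= self.E0 <= 100):
            raise ValueError(f"require 0 < Emax <= E0 <= 100, got Emax={self.Emax}, E0={self.E0}")
        if self.gamma <= 0 or self.EC50_prop <= 0 or self.EC50_remi <= 0:
            raise ValueError("gamma and EC50s must be > 0")


@dataclass(frozen=True)
class PatientProfile:
    age: float  # years
    sex: str  # {male, female}
    height: float  # cm
    weight: float  # kg
    pk_prop: PKParams
    pk_remi: PKParams
    pd: PDParams

    def validate(self) -> None:
        self.pk_prop.validate()
        self.pk_remi.validate()
        self.pd.validate()
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex}")

    @property
    def covariates(self) -> np.ndarray:
        return np.array([self.age, 1.0 if self.sex == "male" else 0.0, self.height, self.weight])


@dataclass(frozen=True)
class InfusionProtocol:
    """Piecewise-constant rate schedules; rates are (start_s, rate) steps."""

    duration: int  # s
    propofol_steps: tuple  # ((t_s, mg/s), ...)
    remifentanil_steps: tuple  # ((t_s, µg/s), ...)
    stop_time: int  # s, propofol stop -> recovery onset

    def rate_series(self, which: str) -> np.ndarray:
        steps = self.propofol_steps if which == "prop" else self.remifentanil_steps
        rates = np.zeros(self.duration)
        for t0, r in steps:
            if r < 0:
                raise ValueError("infusion rates must be >= 0")
            rates[int(t0):] = r
        if which == "prop":
            rates[self.stop_time:] = 0.0
        if self.duration < self.stop_time:
            raise ValueError("duration must cover stop_time")
        return rates


@dataclass
class CaseRecord:
    """One patient's raw 1-Hz record; the unit of all I/O."""

    case_id: str
    t: np.ndarray  # s, strictly increasing 1-s grid
    prop_cum: np.ndarray  # mg, may contain NaN missing marks
    remi_cum: np.ndarray  # µg, may contain NaN missing marks
    bis: np.ndarray  # [0, 100], may contain NaN missing marks
    age: float
    sex: str
    height: float
    weight: float
    infusion_start: int  # s
    infusion_stop: int  # s

    def validate(self) -> None:
        if not np.all(np.diff(self.t) == 1):
            raise ValueError("timestamps must be a strictly increasing 1-s grid")
        present = self.bis[~np.isnan(self.bis)]
        if present.size and (present.min() < 0 or present.max() > 100):
            raise ValueError("present BIS values must lie in [0, 100]")
        if not (self.infusion_start <= self.infusion_stop <= self.t[-1]):
            raise ValueError("require infusion_start <= infusion_stop <= last timestamp")

    @property
    def covariates(self) -> np.ndarray:
        return np.array([self.age, 1.0 if self.sex == "male" else 0.0, self.height, self.weight])

    def copy(self) -> "CaseRecord":
        return CaseRecord(
            self.case_id, self.t.copy(), self.prop_cum.copy(), self.remi_cum.copy(),
            self.bis.copy(), self.age, self.sex, self.height, self.weight,
            self.infusion_start, self.infusion_stop,
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Recording defects to plant in a clean simulated case."""

    bis_sd: float = 0.0  # BIS units of Gaussian measurement noise
    missing_gap_lengths: tuple = ()  # seconds, one interior BIS gap per entry
    glitch_count: int = 0  # non-monotone cumulative-dose corruptions
    start_bis_override: float | None = None  # BIS value forced at infusion start
    first_bis_delay: int | None = None  # s: drop BIS before infusion_start+delay

    def validate(self) -> None:
        if self.bis_sd < 0:
            raise ValueError("bis_sd must be >= 0")
        if any(g < 1 for g in self.missing_gap_lengths):
            raise ValueError("gap lengths must be >= 1 s")
        if self.glitch_count < 0:
            raise ValueError("glitch_count must be >= 0")


# population fixture constants (arbitrary, in plausible ranges)
_BASE_PK_PROP = PKParams(V1=4.3, V2=18.9, V3=238.0, k10=0.35, k12=0.112,
                         k21=0.055, k13=0.042, k31=0.0033, ke0=0.456)
_BASE_PK_REMI = PKParams(V1=5.1, V2=9.8, V3=5.4, k10=0.60, k12=0.38,
                         k21=0.19, k13=0.02, k31=0.014, ke0=0.595)
_BASE_PD = PDParams(E0=93.0, Emax=72.0, EC50_prop=3.0, EC50_remi=12.0, gamma=2.2)
_REF_AGE = 50.0

#: Default covariate->parameter trends (per year of age, centred at 50 y).
#: These trends are the distribution-shift knob of the cohort generator.
DEFAULT_SHIFT_CONFIG: dict = {
    "ec50_prop_per_year": -0.015,
    "ec50_remi_per_year": -0.06,
    "ke0_prop_per_year": -0.003,
    "iiv_sd": 0.12,  # lognormal inter-individual variability (unit mean)
}


def sample_patient(rng_seed: int, shift_config: dict | None = None) -> PatientProfile:
    """Draw one patient; age trends follow ``shift_config`` exactly in expectation.

    Identical seeds give identical profiles.  Lognormal variability is
    mean-one so declared covariate trends are recoverable by regression.
    """
    cfg = dict(DEFAULT_SHIFT_CONFIG)
    if shift_config:
        unknown = set(shift_config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown shift_config keys: {sorted(unknown)}")
        cfg.update(shift_config)
    rng = np.random.default_rng(np.random.SeedSequence((int(rng_seed), 0xA5)))

    age = rng.uniform(20.0, 80.0)
    sex = "male" if rng.random() < 0.5 else "female"
    height = rng.normal(175.0 if sex == "male" else 162.0, 7.0)
    weight = rng.normal(78.0 if sex == "male" else 64.0, 10.0)
    weight = float(np.clip(weight, 40.0, 120.0))
    height = float(np.clip(height, 140.0, 200.0))

    sd = cfg["iiv_sd"]

    def lognorm():
        # unit-mean lognormal: exp(N(-sd^2/2, sd^2))
        return float(np.exp(rng.normal(-0.5 * sd * sd, sd)))

    da = age - _REF_AGE
    ec50_prop = (_BASE_PD.EC50_prop + cfg["ec50_prop_per_year"] * da) * lognorm()
    ec50_remi = (_BASE_PD.EC50_remi + cfg["ec50_remi_per_year"] * da) * lognorm()
    ke0_prop = (_BASE_PK_PROP.ke0 + cfg["ke0_prop_per_year"] * da) * lognorm()
    if min(ec50_prop, ec50_remi, ke0_prop) <= 0 or (
        _BASE_PD.EC50_prop + cfg["ec50_prop_per_year"] * 30 <= 0
        or _BASE_PD.EC50_remi + cfg["ec50_remi_per_year"] * 30 <= 0
        or _BASE_PK_PROP.ke0 + cfg["ke0_prop_per_year"] * 30 <= 0
    ):
        raise ValueError(
            "shift_config slopes drive EC50/ke0 non-positive over the sampled age range"
        )

    k10_prop = _BASE_PK_PROP.k10 * lognorm()
    k10_remi = _BASE_PK_REMI.k10 * lognorm()
    e0 = float(np.clip(rng.normal(_BASE_PD.E0, 1.5), 86.0, 98.0))

    profile = PatientProfile(
        age=float(age), sex=sex, height=height, weight=weight,
        pk_prop=replace(_BASE_PK_PROP, k10=k10_prop, ke0=ke0_prop),
        pk_remi=replace(_BASE_PK_REMI, k10=k10_remi),
        pd=replace(_BASE_PD, E0=e0, Emax=e0 - 21.0,
                   EC50_prop=ec50_prop, EC50_remi=ec50_remi),
    )
    profile.validate()
    return profile


def _zoh_step(pk: PKParams, dt_s: float):
    """Exact 1-step transition (Phi, psi) of the augmented linear system.

    State x = (A1, A2, A3, Ce, E) with E the eliminated mass; input is the
    infusion rate held constant over the step.  x_{t+dt} = Phi @ x + psi * rate.
    """
    m = np.zeros((5, 5))
    m[0, 0] = -(pk.k10 + pk.k12 + pk.k13)
    m[0, 1], m[0, 2] = pk.k21, pk.k31
    m[1, 0], m[1, 1] = pk.k12, -pk.k21
    m[2, 0], m[2, 2] = pk.k13, -pk.k31
    m[3, 0], m[3, 3] = pk.ke0 / pk.V1, -pk.ke0
    m[4, 0] = pk.k10
    m = m / 60.0  # rate constants are per minute; we step in seconds
    aug = np.zeros((6, 6))
    aug[:5, :5] = m * dt_s
    aug[0, 5] = dt_s
    e = expm(aug)
    return e[:5, :5], e[:5, 5]


def simulate_drug_pk(profile_pk: PKParams, rates: np.ndarray, dt: float = 1.0):
    """Integrate one drug's disposition under a 1-Hz piecewise-constant rate.

    Returns dict with plasma concentration ``cp``, effect-site ``ce``,
    compartment masses and eliminated mass, all sampled at step ends.
    Raises if the state goes negative or non-finite (unstable step).
    """
    if dt > 1.0:
        raise ValueError(f"dt={dt} s too coarse; require dt <= 1 s")
    profile_pk.validate()
    n = len(rates)
    phi, psi = _zoh_step(profile_pk, dt)
    x = np.zeros(5)
    out = np.empty((n, 5))
    for i in range(n):
        x = phi @ x + psi * rates[i]
        out[i] = x
    if not np.all(np.isfinite(out)) or out.min() < -1e-9:
        raise FloatingPointError(f"PK integration unstable at dt={dt} s")
    out = np.clip(out, 0.0, None)
    return {
        "cp": out[:, 0] / profile_pk.V1,
        "ce": out[:, 3],
        "masses": out[:, :3],
        "eliminated": out[:, 4],
        "infused": np.cumsum(rates) * dt,
    }


def simulate_pk(profile: PatientProfile, protocol: InfusionProtocol, dt: float = 1.0):
    """Both drugs' plasma and effect-site concentration series for a case."""
    return {
        "prop": simulate_drug_pk(profile.pk_prop, protocol.rate_series("prop"), dt),
        "remi": simulate_drug_pk(profile.pk_remi, protocol.rate_series("remi"), dt),
    }


def simulate_bis(ce_prop: np.ndarray, ce_remi: np.ndarray, profile: PatientProfile) -> np.ndarray:
    """Sigmoid-Emax response on the potency-normalized combined concentration."""
    if len(ce_prop) != len(ce_remi):
        raise ValueError("concentration series must have equal length")
    if np.min(ce_prop) < 0 or np.min(ce_remi) < 0:
        raise ValueError("concentrations must be nonnegative")
    pd_ = profile.pd
    u = ce_prop / pd_.EC50_prop + ce_remi / pd_.EC50_remi
    ug = u**pd_.gamma
    return pd_.E0 - pd_.Emax * ug / (1.0 + ug)


def default_protocol(profile: PatientProfile, rng: np.random.Generator,
                     duration: int = 2400, infusion_start: int = 1250) -> InfusionProtocol:
    """Three-phase schedule: induction bolus, maintenance plateau, recovery.

    Bolus ~2 mg/kg propofol over 30 s; maintenance rate jittered per case;
    propofol stops a few minutes before the record ends so the recovery
    rise is observed, remifentanil slightly earlier.  The long awake
    baseline before the infusion gives every prediction window (which
    needs 120 ten-second bins of history) a fully recorded history, so
    predictions span induction, maintenance and recovery alike.
    """
    w = profile.weight
    bolus_rate = 2.0 * w / 30.0  # mg/s for 30 s
    maint_prop = w * rng.uniform(0.09, 0.13) / 60.0  # mg/s
    maint_remi = w * rng.uniform(0.10, 0.20) / 60.0  # µg/s
    stop = int(duration) - int(rng.integers(240, 320))
    return InfusionProtocol(
        duration=duration,
        propofol_steps=((infusion_start, bolus_rate), (infusion_start + 30, maint_prop)),
        remifentanil_steps=((infusion_start, maint_remi), (stop - 60, 0.0)),
        stop_time=stop,
    )


def simulate_case(case_id: str, profile: PatientProfile, protocol: InfusionProtocol) -> CaseRecord:
    """Noise-free case: cumulative doses and clean BIS on the 1-s grid."""
    prop_rates = protocol.rate_series("prop")
    remi_rates = protocol.rate_series("remi")
    pk_p = simulate_drug_pk(profile.pk_prop, prop_rates)
    pk_r = simulate_drug_pk(profile.pk_remi, remi_rates)
    bis = simulate_bis(pk_p["ce"], pk_r["ce"], profile)
    rec = CaseRecord(
        case_id=case_id,
        t=np.arange(protocol.duration, dtype=float),
        prop_cum=pk_p["infused"],
        remi_cum=pk_r["infused"],
        bis=np.clip(bis, 0.0, 100.0),
        age=profile.age, sex=profile.sex, height=profile.height, weight=profile.weight,
        infusion_start=int(np.argmax((prop_rates > 0) | (remi_rates > 0))),
        infusion_stop=protocol.stop_time,
    )
    rec.validate()
    return rec


def corrupt(case: CaseRecord, noise: NoiseConfig, rng_seed: int):
    """Plant the configured recording defects; returns (case, defect metadata).

    The metadata records planted gap/glitch positions and which eligibility
    rule (if any) the corrupted case is constructed to violate, so
    preprocessing tests can be exact rather than statistical.
    """
    noise.validate()
    rng = np.random.default_rng(np.random.SeedSequence((int(rng_seed), 0xC0)))
    out = case.copy()
    n = len(out.t)
    meta: dict = {"gaps": [], "glitches": [], "violation": None}

    if noise.bis_sd > 0:
        out.bis = np.clip(out.bis + rng.normal(0.0, noise.bis_sd, n), 0.0, 100.0)

    if noise.start_bis_override is not None:
        # depress the pre/peri-induction BIS so the start-of-infusion value
        # is the override (smoothly blended over the first minute after start)
        i0 = out.infusion_start
        delta = out.bis[i0] - noise.start_bis_override
        fade = np.zeros(n)
        fade[: i0 + 1] = 1.0
        ramp = np.linspace(1.0, 0.0, min(60, n - i0))
        fade[i0: i0 + len(ramp)] = ramp
        out.bis = np.clip(out.bis - delta * fade, 0.0, 100.0)
        if noise.start_bis_override < 80:
            meta["violation"] = "start_bis"

    if noise.first_bis_delay is not None:
        cut = out.infusion_start + int(noise.first_bis_delay)
        if cut >= n:
            raise ValueError("first_bis_delay falls outside the record")
        out.bis[:cut] = MISSING
        meta["violation"] = meta["violation"] or "dose_before_bis"

    for gap in noise.missing_gap_lengths:
        gap = int(gap)
        lo_min = out.infusion_start + 60
        if gap > n - lo_min - 60:
            raise ValueError(f"requested gap of {gap} s longer than the record allows")
        lo = int(rng.integers(lo_min, n - gap - 60))
        out.bis[lo: lo + gap] = MISSING
        meta["gaps"].append((lo, gap))
        if gap > 300:
            meta["violation"] = meta["violation"] or "long_gap"

    for _ in range(noise.glitch_count):
        # pick an index where the cumulative channel is strictly increasing
        incr = np.where(np.diff(case.prop_cum) > 1e-9)[0]
        incr = incr[(incr > 1) & (incr < n - 2)]
        i = int(rng.choice(incr)) + 1
        drop = (case.prop_cum[i] - case.prop_cum[i - 1]) + rng.uniform(0.5, 2.0)
        out.prop_cum[i] = max(case.prop_cum[i] - drop, 0.0)
        meta["glitches"].append(i)

    return out, meta


def generate_cohort(n: int, rng_seed: int, shift_config: dict | None = None,
                    noise_menu: dict | None = None, duration: int = 2400):
    """Generate ``n`` cases plus ground-truth defect metadata.

    ``noise_menu`` maps case index -> NoiseConfig; unlisted cases get the
    default benign noise (BIS sd 1.5, one short interior gap, one dose
    glitch) which every preprocessing rule must repair but none discard.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    noise_menu = noise_menu or {}
    cases, metas = [], []
    for i in range(n):
        seed_i = int(np.random.SeedSequence((int(rng_seed), i)).generate_state(1)[0] % (2**31))
        profile = sample_patient(seed_i, shift_config)
        rng = np.random.default_rng(np.random.SeedSequence((seed_i, 0xB0)))
        protocol = default_protocol(profile, rng, duration=duration)
        clean = simulate_case(f"case{i:04d}", profile, protocol)
        noise = noise_menu.get(i, NoiseConfig(bis_sd=1.5, missing_gap_lengths=(20,), glitch_count=1))
        corrupted, meta = corrupt(clean, noise, seed_i)
        meta["case_id"] = clean.case_id
        cases.append(corrupted)
        metas.append(meta)
    return cases, metas
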