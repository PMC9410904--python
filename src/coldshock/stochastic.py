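"""Exact stochastic simulation of transcription-translation model variants.

Five model variants share translation (RNA -> RNA + P at rate k2), RNA decay
(RNA -> 0 at lambda1) and protein decay/dilution (P -> 0 at lambda2), and
differ only in transcription:

* ``ONE_STEP``      — Pro -> Pro + RNA at k1 (one rate-limiting step).
* ``TWO_STEP``      — Pro -> Pro* at k1a, Pro* -> Pro + RNA at k1b
                      (two sequential rate-limiting initiation sub-steps).
* ``ON_OFF``        — telegraph promoter: ON -> OFF at k_minus, OFF -> ON at
                      k_plus, ON -> ON + RNA at k1.
* ``TWO_STEP_ON_OFF`` — two-step initiation whose first sub-step is subject
                      to ON-OFF locking.
* ``DUAL_ON_OFF``   — two-step initiation with each sub-step independently
                      subject to ON-OFF locking (shared k_plus/k_minus).

Dynamics follow the Stochastic Simulation Algorithm (Gillespie's direct
method), implemented in a numba-compiled kernel.  Stationary statistics are
taken from states sampled at fixed intervals after a burn-in, pooled across
independent runs; runs are seeded as base_seed + run_index so that scaled-down
ensembles stay reproducible.  Monte-Carlo standard errors are delete-one
jackknife estimates across runs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


__all__ = [
    "ModelVariant",
    "RateSet",
    "SimulationConfig",
    "MomentSummary",
    "SimulationResult",
    "RelativeCV2",
    "ConfigurationError",
    "InconsistencyError",
    "simulate",
    "steady_state_moments",
    "match_mean",
    "relative_cv2",
    "stationary_mean_protein",
]


class ConfigurationError(ValueError):
    """Invalid rate/variant/config combination."""


class InconsistencyError(RuntimeError):
    """A precondition re-check failed (e.g. means no longer matched)."""


class ModelVariant(enum.Enum):
    ONE_STEP = "one_step"
    TWO_STEP = "two_step"
    ON_OFF = "on_off"
    TWO_STEP_ON_OFF = "two_step_on_off"
    DUAL_ON_OFF = "dual_on_off"

    @classmethod
    def parse(cls, value) -> "ModelVariant":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


_VARIANT_CODE = {
    ModelVariant.ONE_STEP: 0,
    ModelVariant.TWO_STEP: 1,
    ModelVariant.ON_OFF: 2,
    ModelVariant.TWO_STEP_ON_OFF: 3,
    ModelVariant.DUAL_ON_OFF: 4,
}

# rates that must be strictly positive for each variant (decay rates are
# always required so that total propensity can never stall with species left)
_REQUIRED = {
    ModelVariant.ONE_STEP: ("k1", "k2", "lambda1", "lambda2"),
    ModelVariant.TWO_STEP: ("k1a", "k1b", "k2", "lambda1", "lambda2"),
    ModelVariant.ON_OFF: ("k1", "k_plus", "k2", "lambda1", "lambda2"),
    ModelVariant.TWO_STEP_ON_OFF: ("k1a", "k1b", "k_plus", "k2", "lambda1", "lambda2"),
    ModelVariant.DUAL_ON_OFF: ("k1a", "k1b", "k_plus", "k2", "lambda1", "lambda2"),
}


@dataclass(frozen=True)
class RateSet:
    """Kinetic parameters (all 1/s) of a transcription-translation variant.

    k1: transcription rate from an active promoter; k1a/k1b: sequential
    initiation sub-step rates (two-step variants); k2: translation rate per
    RNA; lambda1/lambda2: RNA and protein decay rates; k_plus/k_minus:
    OFF->ON unlocking and ON->OFF locking rates.
    """

    k1: float = 0.0
    k1a: float = 0.0
    k1b: float = 0.0
    k2: float = 0.0
    lambda1: float = 0.0
    lambda2: float = 0.0
    k_plus: float = 0.0
    k_minus: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"rate {name} must be >= 0")

    def validate_for(self, variant: ModelVariant) -> None:
        for name in _REQUIRED[variant]:
            if getattr(self, name) <= 0:
                # k1=0 is allowed for the production rate: it yields the
                # trivial all-zero ensemble, a documented degenerate case.
                if name in ("k1", "k1a", "k1b", "k2"):
                    continue
                raise ConfigurationError(
                    f"variant {variant.value} requires rate {name} > 0"
                )
        if self.lambda1 + self.lambda2 <= 0:
            raise ConfigurationError("decay rates lambda1 + lambda2 must be > 0")

    @property
    def timescale_separation_ok(self) -> bool:
        """Assumption check: RNA turns over much faster than protein (lambda1 >> lambda2)."""
        return self.lambda1 > self.lambda2


# Documented default parameter set: biologically plausible for E. coli in
# balanced growth (RNA half-life ~2 min, protein dilution-limited ~40 min,
# mean RNA ~2, mean protein ~333, Omega ~10.4).
DEFAULT_RATES = RateSet(k1=0.01, k2=0.05, lambda1=0.005, lambda2=0.0003)


@dataclass(frozen=True)
class SimulationConfig:
    """Ensemble definition for stationary statistics.

    Defaults mirror the study conditions (1e6 s horizon, 100 runs, promoter
    initially ON); tests and the acceptance script use the scaled-down
    ensembles stated in the methods note.
    """

    horizon: float = 1e6
    n_runs: int = 100
    burn_in_fraction: float = 0.1
    sample_interval: float = 1e3
    seed: int = 0
    promoter_initially_on: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in_fraction < 1):
            raise ConfigurationError("burn_in_fraction must be in [0, 1)")
        if self.sample_interval <= 0:
            raise ConfigurationError("sample_interval must be > 0")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be > 0")


@dataclass
class MomentSummary:
    """Sample moments of a pooled protein-number ensemble."""

    M: float
    variance: float
    cv2: float
    skewness: float
    omega: float
    sem_cv2: float
    sem_omega: float = float("nan")
    sem_mean: float = float("nan")
    n_samples: int = 0
    flag_undefined: bool = False


@dataclass
class SimulationResult:
    """Pooled post-burn-in samples plus per-run summaries."""

    variant: ModelVariant
    rates: RateSet
    config: SimulationConfig
    promoter: np.ndarray  # active-promoter indicator per sample
    rna: np.ndarray
    protein: np.ndarray
    run_index: np.ndarray  # run of origin per pooled sample
    samples_per_run: int

    def per_run_protein(self) -> np.ndarray:
        return self.protein.reshape(self.config.n_runs, self.samples_per_run)


@njit(cache=False)
def _ssa_run(variant, k1, k1a, k1b, k2, lam1, lam2, kp, km,
             t_end, t_burn, dt, seed, init_on,
             out_pro, out_rna, out_prot):  # pragma: no cover - numba kernel
    np.random.seed(seed)
    t = 0.0
    on1 = 1 if init_on else 0
    on2 = 1
    stage = 0  # 0: awaiting first initiation sub-step, 1: awaiting second
    rna = 0
    prot = 0
    n_out = out_rna.shape[0]
    idx = 0
    next_sample = t_burn
    while idx < n_out:
        a_tx = 0.0
        a_step2 = 0.0
        a_lock = 0.0
        a_unlock = 0.0
        a_lock2 = 0.0
        a_unlock2 = 0.0
        if variant == 0:
            a_tx = k1
        elif variant == 1:
            if stage == 0:
                a_tx = k1a
            else:
                a_step2 = k1b
        elif variant == 2:
            if on1 == 1:
                a_tx = k1
                a_lock = km
            else:
                a_unlock = kp
        elif variant == 3:
            if stage == 0:
                if on1 == 1:
                    a_tx = k1a
                    a_lock = km
                else:
                    a_unlock = kp
            else:
                a_step2 = k1b
        else:
            if stage == 0:
                if on1 == 1:
                    a_tx = k1a
                    a_lock = km
                else:
                    a_unlock = kp
            else:
                if on2 == 1:
                    a_step2 = k1b
                    a_lock2 = km
                else:
                    a_unlock2 = kp
        a_tl = k2 * rna
        a_rd = lam1 * rna
        a_pd = lam2 * prot
        a_tot = (a_tx + a_step2 + a_lock + a_unlock + a_lock2 + a_unlock2
                 + a_tl + a_rd + a_pd)
        if a_tot <= 0.0:
            # absorbing state (possible only when production rates are zero
            # and all species have decayed): remaining samples are constant
            while idx < n_out:
                out_pro[idx] = on1
                out_rna[idx] = rna
                out_prot[idx] = prot
                idx += 1
            break
        tau = np.random.exponential(1.0 / a_tot)
        t_new = t + tau
        while idx < n_out and next_sample < t_new:
            out_pro[idx] = on1
            out_rna[idx] = rna
            out_prot[idx] = prot
            idx += 1
            next_sample += dt
        if idx >= n_out:
            break
        t = t_new
        r = np.random.random() * a_tot
        if r < a_tx:
            if variant == 0 or variant == 2:
                rna += 1
            else:
                stage = 1
        elif r < a_tx + a_step2:
            rna += 1
            stage = 0
        elif r < a_tx + a_step2 + a_lock:
            on1 = 0
        elif r < a_tx + a_step2 + a_lock + a_unlock:
            on1 = 1
        elif r < a_tx + a_step2 + a_lock + a_unlock + a_lock2:
            on2 = 0
        elif r < a_tx + a_step2 + a_lock + a_unlock + a_lock2 + a_unlock2:
            on2 = 1
        elif r < a_tx + a_step2 + a_lock + a_unlock + a_lock2 + a_unlock2 + a_tl:
            prot += 1
        elif r < (a_tx + a_step2 + a_lock + a_unlock + a_lock2 + a_unlock2
                  + a_tl + a_rd):
            rna -= 1
        else:
            prot -= 1


def simulate(variant, rates: RateSet, config: SimulationConfig) -> SimulationResult:
    """Run the exact SSA for one model variant.

    Returns all post-burn-in states sampled every ``config.sample_interval``
    seconds, pooled across ``config.n_runs`` independent runs.  Bit-identical
    for identical (variant, rates, config).
    """
    variant = ModelVariant.parse(variant)
    rates.validate_for(variant)
    t_burn = config.horizon * config.burn_in_fraction
    n_per_run = int(math.floor((config.horizon - t_burn) / config.sample_interval)) + 1
    if n_per_run < 1:
        raise ConfigurationError("sample_interval too large for post-burn-in window")
    code = _VARIANT_CODE[variant]
    n_runs = config.n_runs
    pro = np.empty(n_runs * n_per_run, dtype=np.int64)
    rna = np.empty(n_runs * n_per_run, dtype=np.int64)
    prot = np.empty(n_runs * n_per_run, dtype=np.int64)
    run_idx = np.repeat(np.arange(n_runs), n_per_run)
    for i in range(n_runs):
        seed_i = (config.seed + i) % (2**31 - 1)
        sl = slice(i * n_per_run, (i + 1) * n_per_run)
        _ssa_run(code, rates.k1, rates.k1a, rates.k1b, rates.k2,
                 rates.lambda1, rates.lambda2, rates.k_plus, rates.k_minus,
                 config.horizon, t_burn, config.sample_interval,
                 seed_i, config.promoter_initially_on,
                 pro[sl], rna[sl], prot[sl])
    return SimulationResult(variant=variant, rates=rates, config=config,
                            promoter=pro, rna=rna, protein=prot,
                            run_index=run_idx, samples_per_run=n_per_run)


def _moments_from_sums(n, s1, s2, s3):
    m = s1 / n
    var = (s2 - n * m * m) / (n - 1)
    m3 = (s3 - 3 * m * s2 + 2 * n * m**3) / n
    return m, var, m3


def steady_state_moments(samples) -> MomentSummary:
    """Moment summary of a pooled protein-number ensemble.

    ``samples`` is either a :class:`SimulationResult` (jackknife SEMs across
    runs) or a 1-D array (jackknife across 20 contiguous blocks).  With mean
    zero, CV^2 is undefined and the summary is flagged.
    """
    if isinstance(samples, SimulationResult):
        x = samples.protein.astype(float)
        groups = samples.run_index
        n_groups = samples.config.n_runs
    else:
        x = np.asarray(samples, dtype=float).ravel()
        n_groups = min(20, max(2, x.size // 2))
        groups = np.arange(x.size) * n_groups // x.size
    if x.size < 2:
        raise ValueError("need at least 2 pooled samples")

    n = x.size
    s1, s2, s3 = x.sum(), (x**2).sum(), (x**3).sum()
    M, var, m3 = _moments_from_sums(n, s1, s2, s3)
    if M <= 0 or var < 0:
        return MomentSummary(M=M, variance=max(var, 0.0), cv2=float("nan"),
                             skewness=float("nan"), omega=float("nan"),
                             sem_cv2=float("nan"), n_samples=n,
                             flag_undefined=True)
    cv2 = var / M**2
    skew = m3 / var**1.5 if var > 0 else 0.0
    omega = M * cv2

    # delete-one-group jackknife for SEMs of mean, cv2, omega
    cv2_j, om_j, m_j = [], [], []
    for g in range(n_groups):
        mask = groups != g
        ng = mask.sum()
        if ng < 2:
            continue
        xg = x[mask]
        mg = xg.mean()
        vg = xg.var(ddof=1)
        if mg > 0:
            cv2_j.append(vg / mg**2)
            om_j.append(vg / mg)
            m_j.append(mg)
    if len(cv2_j) >= 2:
        k = len(cv2_j)
        fac = (k - 1) / k

        def jse(vals):
            v = np.asarray(vals)
            return math.sqrt(fac * ((v - v.mean()) ** 2).sum())

        sem_cv2, sem_omega, sem_mean = jse(cv2_j), jse(om_j), jse(m_j)
    else:
        sem_cv2 = sem_omega = sem_mean = float("nan")
    return MomentSummary(M=M, variance=var, cv2=cv2, skewness=skew,
                         omega=omega, sem_cv2=sem_cv2, sem_omega=sem_omega,
                         sem_mean=sem_mean, n_samples=n)


def _effective_initiation_rate(variant: ModelVariant, r: RateSet) -> float:
    """Stationary RNA production rate of the promoter cycle."""
    if variant is ModelVariant.ONE_STEP:
        return r.k1
    if variant is ModelVariant.ON_OFF:
        duty = r.k_plus / (r.k_plus + r.k_minus)
        return r.k1 * duty
    if variant is ModelVariant.TWO_STEP:
        return 1.0 / (1.0 / r.k1a + 1.0 / r.k1b)
    duty = r.k_plus / (r.k_plus + r.k_minus)
    if variant is ModelVariant.TWO_STEP_ON_OFF:
        # locking interrupts only the wait for the first sub-step
        return 1.0 / (1.0 / (r.k1a * duty) + 1.0 / r.k1b)
    # DUAL_ON_OFF: both sub-step waits are stretched by 1/duty
    return 1.0 / ((1.0 / r.k1a + 1.0 / r.k1b) / duty)


def stationary_mean_protein(variant, rates: RateSet) -> float:
    """Analytic stationary mean protein number, k_eff * k2 / (lambda1 * lambda2)."""
    variant = ModelVariant.parse(variant)
    rates.validate_for(variant)
    if rates.lambda1 <= 0 or rates.lambda2 <= 0:
        raise ConfigurationError("decay rates must be positive for a stationary mean")
    return _effective_initiation_rate(variant, rates) * rates.k2 / (
        rates.lambda1 * rates.lambda2)


def match_mean(variant, reference: RateSet, fixed: Optional[dict] = None) -> RateSet:
    """Rates giving ``variant`` the same stationary mean protein as the
    one-step ``reference`` model.

    ``fixed`` supplies the variant-specific parameters (k_plus/k_minus for
    ON-OFF variants; optionally one of k1a/k1b for two-step variants) and must
    leave exactly one free production parameter, which is solved analytically:

    * ON_OFF: k1 = k1_ref / duty with duty = k_plus / (k_plus + k_minus);
    * TWO_STEP: harmonic-mean condition (1/k1a + 1/k1b)^-1 = k1_ref, with an
      even split k1a = k1b = 2 k1_ref when neither sub-step rate is fixed;
    * TWO_STEP_ON_OFF / DUAL_ON_OFF: the same cycle-time balance with the
      locked waits stretched by 1/duty.
    """
    variant = ModelVariant.parse(variant)
    fixed = dict(fixed or {})
    reference.validate_for(ModelVariant.ONE_STEP)
    if reference.k1 <= 0:
        raise ConfigurationError("reference k1 must be > 0 for mean matching")
    base = replace(reference, k1a=0.0, k1b=0.0, k_plus=0.0, k_minus=0.0)

    if variant is ModelVariant.ONE_STEP:
        if fixed:
            raise ConfigurationError("ONE_STEP takes no fixed parameters")
        return reference

    if variant is ModelVariant.ON_OFF:
        try:
            kp, km = fixed.pop("k_plus"), fixed.pop("k_minus")
        except KeyError as e:
            raise ConfigurationError("ON_OFF requires fixed k_plus and k_minus") from e
        if fixed:
            raise ConfigurationError(f"over-determined fixed set: {sorted(fixed)}")
        if kp <= 0:
            raise ConfigurationError("k_plus must be > 0")
        duty = kp / (kp + km)
        return replace(base, k1=reference.k1 / duty, k_plus=kp, k_minus=km)

    if variant is ModelVariant.TWO_STEP:
        k1a, k1b = fixed.pop("k1a", None), fixed.pop("k1b", None)
        if fixed:
            raise ConfigurationError(f"unexpected fixed parameters: {sorted(fixed)}")
        if k1a is not None and k1b is not None:
            raise ConfigurationError("over-determined: both k1a and k1b fixed")
        if k1a is None and k1b is None:
            k1a = k1b = 2.0 * reference.k1
        elif k1a is not None:
            if k1a <= reference.k1:
                raise ConfigurationError("fixed k1a must exceed reference k1")
            k1b = 1.0 / (1.0 / reference.k1 - 1.0 / k1a)
        else:
            if k1b <= reference.k1:
                raise ConfigurationError("fixed k1b must exceed reference k1")
            k1a = 1.0 / (1.0 / reference.k1 - 1.0 / k1b)
        return replace(base, k1=0.0, k1a=k1a, k1b=k1b)

    # composite variants
    try:
        kp, km = fixed.pop("k_plus"), fixed.pop("k_minus")
    except KeyError as e:
        raise ConfigurationError(f"{variant.value} requires fixed k_plus and k_minus") from e
    k1a, k1b = fixed.pop("k1a", None), fixed.pop("k1b", None)
    if fixed:
        raise ConfigurationError(f"unexpected fixed parameters: {sorted(fixed)}")
    if k1a is not None and k1b is not None:
        raise ConfigurationError("over-determined: both k1a and k1b fixed")
    if kp <= 0:
        raise ConfigurationError("k_plus must be > 0")
    duty = kp / (kp + km)
    target = 1.0 / reference.k1  # required total mean cycle time
    if variant is ModelVariant.TWO_STEP_ON_OFF:
        # cycle time = 1/(k1a*duty) + 1/k1b; default: even split in time
        if k1a is None and k1b is None:
            k1a = 2.0 / (target * duty)
            k1b = 2.0 / target
        elif k1a is not None:
            rem = target - 1.0 / (k1a * duty)
            if rem <= 0:
                raise ConfigurationError("fixed k1a leaves no time for the second step")
            k1b = 1.0 / rem
        else:
            rem = target - 1.0 / k1b
            if rem <= 0:
                raise ConfigurationError("fixed k1b leaves no time for the first step")
            k1a = 1.0 / (rem * duty)
    else:  # DUAL_ON_OFF: cycle time = (1/k1a + 1/k1b)/duty
        if k1a is None and k1b is None:
            k1a = k1b = 2.0 / (target * duty)
        elif k1a is not None:
            rem = target * duty - 1.0 / k1a
            if rem <= 0:
                raise ConfigurationError("fixed k1a leaves no time for the second step")
            k1b = 1.0 / rem
        else:
            rem = target * duty - 1.0 / k1b
            if rem <= 0:
                raise ConfigurationError("fixed k1b leaves no time for the first step")
            k1a = 1.0 / rem
    return replace(base, k1=0.0, k1a=k1a, k1b=k1b, k_plus=kp, k_minus=km)


@dataclass
class RelativeCV2:
    """Protein CV^2 of a variant relative to the mean-matched one-step model."""

    ratio: float
    sem_ratio: float
    variant_moments: MomentSummary
    reference_moments: MomentSummary


def relative_cv2(variant, matched: RateSet, reference: RateSet,
                 config: SimulationConfig) -> RelativeCV2:
    """Simulate variant and reference and return the protein CV^2 ratio.

    Re-checks the mean-matching precondition: if the simulated means differ by
    more than 3 combined SEM, an :class:`InconsistencyError` is raised.  The
    ratio's SEM combines the two jackknife SEMs in quadrature.
    """
    variant = ModelVariant.parse(variant)
    ref_cfg = replace(config, seed=(config.seed + 1_000_003) % (2**31 - 1))
    mom_v = steady_state_moments(simulate(variant, matched, config))
    mom_r = steady_state_moments(simulate(ModelVariant.ONE_STEP, reference, ref_cfg))
    if mom_v.flag_undefined or mom_r.flag_undefined:
        raise InconsistencyError("undefined moments in relative CV^2 comparison")
    sem = math.hypot(mom_v.sem_mean, mom_r.sem_mean)
    if abs(mom_v.M - mom_r.M) > 3 * sem:
        raise InconsistencyError(
            f"means not matched: {mom_v.M:.3f} vs {mom_r.M:.3f} (3 SEM = {3*sem:.3f})")
    ratio = mom_v.cv2 / mom_r.cv2
    sem_ratio = ratio * math.hypot(mom_v.sem_cv2 / mom_v.cv2,
                                   mom_r.sem_cv2 / mom_r.cv2)
    return RelativeCV2(ratio=ratio, sem_ratio=sem_ratio,
                       variant_moments=mom_v, reference_moments=mom_r)
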