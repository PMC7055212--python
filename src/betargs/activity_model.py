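"""Radionuclide decay bookkeeping and SUV-to-activity conversion.

Links the imaging measurement (a dimensionless SUV from a diagnostic
PET tracer) to the specific activity a therapeutic beta emitter would
exhibit in the same tissue at surgery time, under a stated injection
protocol: activity per unit mass, physical decay between injection and
surgery, and the inverse of the SUV normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LN2 = float(np.log(2.0))

# 90Y: pure beta-minus emitter; daughter 90Zr (Z = 40). The 2.28 MeV endpoint
# is the physical value; it is often quoted rounded to 2.2 MeV.
Y90 = None  # assigned below once IsotopeSpec exists


@dataclass(frozen=True)
class IsotopeSpec:
    """A pure beta-minus emitter.

    half_life : hours
    beta_endpoint : MeV, maximum kinetic energy of the emitted electron
    daughter_atomic_number : Z of the daughter nucleus (Coulomb correction)
    """

    name: str
    half_life: float
    beta_endpoint: float
    daughter_atomic_number: int

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half-life must be positive")
        if self.beta_endpoint <= 0:
            raise ValueError("beta endpoint must be positive")


Y90 = IsotopeSpec(name="Y-90", half_life=64.0, beta_endpoint=2.280,
                  daughter_atomic_number=40)


@dataclass(frozen=True)
class InjectionPlan:
    """Injection protocol for the therapeutic radiopharmaceutical.

    activity_per_mass : MBq/kg administered at injection
    patient_mass : kg
    delay_to_surgery : hours between injection and the intraoperative probe
    isotope : the administered emitter
    biodistribution_factor : multiplicative factor relating the diagnostic
        SUV to the therapeutic tracer's SUV at surgery time (default 1,
        i.e. identical biodistribution); exposed for sensitivity analysis.
    decay_correct : if True (default) the administered activity is decayed
        physically over ``delay_to_surgery`` before rate prediction.
    """

    activity_per_mass: float = 1.5
    patient_mass: float = 70.0
    delay_to_surgery: float = 24.0
    isotope: IsotopeSpec = Y90
    biodistribution_factor: float = 1.0
    decay_correct: bool = True

    def __post_init__(self) -> None:
        if self.activity_per_mass <= 0:
            raise ValueError("activity per mass must be positive")
        if self.patient_mass <= 0:
            raise ValueError("patient mass must be positive")
        if self.delay_to_surgery < 0:
            raise ValueError("delay to surgery must be non-negative")

    @property
    def total_activity(self) -> float:
        """MBq administered: activity_per_mass x patient_mass."""
        return self.activity_per_mass * self.patient_mass


def total_administered_activity(plan: InjectionPlan) -> float:
    """Total administered activity in MBq (e.g. 1.5 MBq/kg x 70 kg = 105)."""
    return plan.total_activity


def decayed_activity(a0: float, elapsed: float, isotope: IsotopeSpec) -> float:
    """Activity after ``elapsed`` hours of physical decay: a0 * 2^(-t/T_half)."""
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    return a0 * 2.0 ** (-elapsed / isotope.half_life)


def mean_lifetime(isotope: IsotopeSpec) -> float:
    """Mean lifetime tau = T_half / ln 2, hours (64 h half-life -> ~92 h)."""
    return isotope.half_life / LN2


def tissue_specific_activity(suv: float, available_activity: float,
                             patient_mass: float) -> float:
    """Tissue specific activity (kBq/mL) implied by an SUV.

    Inverts the SUV normalization at surgery time: concentration =
    SUV * A / W with mass in grams and unit tissue density, so
    SUV 1 at 105 MBq / 70 kg gives 1.5 kBq/mL.
    """
    if suv < 0:
        raise ValueError("SUV must be non-negative")
    if patient_mass <= 0:
        raise ValueError("patient mass must be positive")
    activity_kbq = available_activity * 1000.0
    mass_g = patient_mass * 1000.0
    return suv * activity_kbq / mass_g


def activity_at_surgery(plan: InjectionPlan) -> float:
    """Administered activity (MBq) remaining at surgery time.

    Applies physical decay over the injection-to-surgery delay unless the
    plan disables decay correction.
    """
    a0 = plan.total_activity
    if not plan.decay_correct:
        return a0
    return decayed_activity(a0, plan.delay_to_surgery, plan.isotope)
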