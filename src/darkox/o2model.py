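"""Forward models and inversion for dissolved O2 in groundwater:
Rayleigh respiration, pool mixing, air contamination, in-situ ("dark")
oxygen addition, and a per-sample scenario classifier.

The diagnostic plane is O2/Ar ratio (argon is biologically inert and mixes
conservatively, so O2/Ar isolates biological O2 gain/loss from physical gas
effects) against d18O of the dissolved O2 pool:

* respiration moves a sample down-left-to-up: O2/Ar decreases while the
  residual O2 becomes enriched in 18O (d18O rises);
* air contamination pulls a sample back toward the air-equilibrated point
  (O2/Ar = 1 in normalized units, d18O = +23.9 per mil);
* addition of in-situ produced O2 with very low d18O (~ -20 per mil,
  inherited from the 18O-depleted groundwater it is made from) *raises*
  O2/Ar while *lowering* d18O.

No combination of respiration and air contamination can enter the quadrant
{O2/Ar above air-equilibrated, d18O below +23.9}; observations there demand
an O2 source other than the atmosphere — e.g. microbial dismutation of
chlorite, nitric oxide, or peroxide.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .conventions import rayleigh_residual_delta

#: d18O of O2 in air-equilibrated water, per mil vs V-SMOW.
AIR_EQ_D18O = 23.9
#: Instrument precision of d18O-O2 measurements, per mil.
SIGMA_D18O_DEFAULT = 0.1
#: Instrument precision of the (normalized) O2/Ar ratio.
SIGMA_O2AR_DEFAULT = 0.05


@dataclass(frozen=True)
class EndMember:
    """A point in the (O2/Ar, d18O) plane with a label."""

    o2_ar: float
    d18o: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.o2_ar < 0:
            raise ValueError("O2/Ar ratio must be >= 0")


#: Air-equilibrated water at the reference O2/Ar normalization of 1.
AIR_EQUILIBRATED = EndMember(o2_ar=1.0, d18o=AIR_EQ_D18O, label="air-equilibrated water")


@dataclass(frozen=True)
class GasIsotopeObservation:
    """One replicate vial's O2/Ar ratio and d18O-O2 with measurement sigmas."""

    sample_id: str
    replicate: int
    o2_ar: float
    d18o_o2: float
    sigma_d18o: float = SIGMA_D18O_DEFAULT
    sigma_o2ar: float = SIGMA_O2AR_DEFAULT

    def __post_init__(self) -> None:
        if self.o2_ar < 0:
            raise ValueError("O2/Ar ratio must be >= 0")
        if self.sigma_d18o <= 0 or self.sigma_o2ar <= 0:
            raise ValueError("measurement sigmas must be > 0")


@dataclass(frozen=True)
class ScenarioParams:
    """Unknowns of the isotope model.

    epsilon_resp
        Respiration enrichment factor, per mil; positive means the residual
        O2 pool is enriched as O2 is consumed (consumed O2 is light). Both
        sign conventions circulate in the literature — this package fixes
        epsilon_resp > 0 == residual enrichment.
    delta_source
        d18O of in-situ produced O2, per mil vs V-SMOW (default -20,
        inherited from the isotopically light groundwater).
    f_resp
        Fraction of the initial O2 remaining after respiration, (0, 1].
    x_prod
        Produced O2 as a fraction of the air-equilibrated O2 amount, >= 0.
    x_air
        Air-contamination mixing fraction in [0, 1].
    """

    epsilon_resp: float = 18.0
    delta_source: float = -20.0
    f_resp: float = 1.0
    x_prod: float = 0.0
    x_air: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.f_resp <= 1.0):
            raise ValueError("f_resp must be in (0, 1]")
        if self.x_prod < 0:
            raise ValueError("x_prod must be >= 0")
        if not (0.0 <= self.x_air <= 1.0):
            raise ValueError("x_air must be in [0, 1]")


class ScenarioLabel(str, enum.Enum):
    AIR_EQUILIBRATED = "air_equilibrated"
    RESPIRATION_CONSISTENT = "respiration_consistent"
    CONTAMINATION_CONSISTENT = "contamination_consistent"
    REQUIRES_LIGHT_SOURCE = "requires_light_source"


@dataclass(frozen=True)
class ScenarioVerdict:
    label: ScenarioLabel
    fitted: ScenarioParams
    residual: float
    mean_o2_ar: float
    mean_d18o: float
    se_o2_ar: float
    se_d18o: float
    dark_fraction: float = 0.0


# ---------------------------------------------------------------------------
# Forward processes
# ---------------------------------------------------------------------------


def rayleigh_respiration(em0: EndMember, f_resp: float, epsilon_resp: float) -> EndMember:
    """Respire the pool down to fraction ``f_resp`` of its O2.

    Argon is conservative, so O2/Ar scales by ``f_resp``; the residual d18O
    follows the Rayleigh form and strictly increases as f decreases when
    epsilon_resp > 0.
    """
    if not (0.0 < f_resp <= 1.0):
        raise ValueError("f_resp must be in (0, 1]; f_resp=0 is singular")
    if em0.o2_ar <= 0:
        raise ValueError("initial O2/Ar must be > 0")
    return EndMember(
        o2_ar=em0.o2_ar * f_resp,
        d18o=float(rayleigh_residual_delta(em0.d18o, f_resp, epsilon_resp)),
        label=f"{em0.label} respired to f={f_resp:g}".strip(),
    )


def _delta_to_atom_fraction(delta: float, r_std: float = 2.0052e-3) -> float:
    r = r_std * (1.0 + delta / 1000.0)
    return r / (1.0 + r)


def _atom_fraction_to_delta(x18: float, r_std: float = 2.0052e-3) -> float:
    r = x18 / (1.0 - x18)
    return (r / r_std - 1.0) * 1000.0


def mix_o2_pools(base: EndMember, added: EndMember, x: float, exact: bool = False) -> EndMember:
    """Add O2 amounting to fraction ``x`` of the base pool's O2.

    Argon is identical and conservative across pools, so the mixed O2/Ar is
    ``base.o2_ar * (1 + x)``. The mixed delta is the O2-amount-weighted mean
    ``(d_base + x * d_added) / (1 + x)`` (delta-linear convention). With
    ``exact=True`` the mixture is computed in 18O atom-fraction space; the
    two agree to well under 0.01 per mil for |delta| <= 50.
    """
    if x < 0:
        raise ValueError("added fraction x must be >= 0")
    o2_ar = base.o2_ar * (1.0 + x)
    if x == 0:
        return replace(base, o2_ar=o2_ar)
    if exact:
        xb = _delta_to_atom_fraction(base.d18o)
        xa = _delta_to_atom_fraction(added.d18o)
        d18o = _atom_fraction_to_delta((xb + x * xa) / (1.0 + x))
    else:
        d18o = (base.d18o + x * added.d18o) / (1.0 + x)
    return EndMember(o2_ar=o2_ar, d18o=d18o, label=f"mix({base.label}+{added.label})")


def air_contamination(obs: EndMember, em_air_eq: EndMember = AIR_EQUILIBRATED,
                      x_air: float = 0.0) -> EndMember:
    """Replace a water fraction ``x_air`` of the sample with air-equilibrated water.

    Same amount-weighted delta arithmetic as :func:`mix_o2_pools`, but
    parameterised so that ``x_air=1`` returns exactly the air-equilibrated
    endmember and any 0 < x_air < 1 moves the observation strictly toward it.
    """
    if not (0.0 <= x_air <= 1.0):
        raise ValueError("x_air must be in [0, 1]")
    o2_ar = (1.0 - x_air) * obs.o2_ar + x_air * em_air_eq.o2_ar
    w_obs = (1.0 - x_air) * obs.o2_ar
    w_air = x_air * em_air_eq.o2_ar
    if w_obs + w_air == 0:
        raise ValueError("both pools contain no O2; mixed delta undefined")
    d18o = (w_obs * obs.d18o + w_air * em_air_eq.d18o) / (w_obs + w_air)
    return EndMember(o2_ar=o2_ar, d18o=d18o, label="air-contaminated")


def forward_dark_o2(params: ScenarioParams,
                    em_air_eq: EndMember = AIR_EQUILIBRATED) -> EndMember:
    """Full forward model: respiration, then dark-O2 addition, then air contamination.

    Composition order is a stated convention of the model; commuting
    respiration and production changes predictions by less than measurement
    sigma over the parameter ranges of interest.
    """
    em = rayleigh_respiration(em_air_eq, params.f_resp, params.epsilon_resp)
    if params.x_prod > 0:
        # x_prod is a fraction of the *air-equilibrated* O2 amount; relative
        # to the respired pool that is x_prod / f_resp.
        source = EndMember(o2_ar=0.0, d18o=params.delta_source, label="dark O2")
        em = mix_o2_pools(em, source, params.x_prod / params.f_resp)
    if params.x_air > 0:
        em = air_contamination(em, em_air_eq, params.x_air)
    return em


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InversionResult:
    f_resp: float
    x_prod: float
    dark_fraction: float
    feasible: bool
    message: str = ""


def invert_dark_o2(
    obs: GasIsotopeObservation | EndMember,
    em_air_eq: EndMember = AIR_EQUILIBRATED,
    epsilon_resp: float = 18.0,
    delta_source: float = -20.0,
) -> InversionResult:
    """Solve the two-observable system for (f_resp, x_prod), x_air = 0.

    With s = O2/Ar(obs) / O2/Ar(air-eq) = f_resp + x_prod fixed by the
    conservative-argon budget, the delta balance

        s * d_obs = f * delta_rayleigh(f) + (s - f) * delta_source

    is monotone in f (the residual pool is always heavier than the produced
    O2), so the root is bracketed and unique on (0, min(1, s)]. Infeasible
    observations (no f in range) are flagged rather than raised.

    Returns the dark-O2 fraction of the *current* pool, x_prod / s.
    """
    if em_air_eq.o2_ar <= 0:
        raise ValueError("air-equilibrated endmember must have O2/Ar > 0")
    o2_ar = obs.o2_ar
    d_obs = obs.d18o_o2 if isinstance(obs, GasIsotopeObservation) else obs.d18o
    s = o2_ar / em_air_eq.o2_ar
    if s <= 0:
        return InversionResult(math.nan, math.nan, math.nan, False, "no O2 in observation")

    d_eq = em_air_eq.d18o

    def residual(f: float) -> float:
        d_resp = float(rayleigh_residual_delta(d_eq, f, epsilon_resp))
        return f * (d_resp - delta_source) - s * (d_obs - delta_source)

    f_hi = min(1.0, s)
    lo, hi = 1e-9, f_hi
    r_lo, r_hi = residual(lo), residual(hi)
    if abs(r_hi) < 1e-12:
        f = f_hi
    elif r_lo * r_hi > 0:
        return InversionResult(
            math.nan, math.nan, math.nan, False,
            "no (f_resp, x_prod) with f in (0,1], x_prod >= 0 explains the observation "
            f"under epsilon_resp={epsilon_resp:g}, delta_source={delta_source:g}",
        )
    else:
        f = brentq(residual, lo, hi, xtol=1e-14, rtol=1e-15)
    x_prod = s - f
    if x_prod < 0:  # numerical guard; |x_prod| is at root tolerance here
        x_prod = 0.0
        f = s
    return InversionResult(f_resp=f, x_prod=x_prod, dark_fraction=x_prod / s, feasible=True)


# ---------------------------------------------------------------------------
# Scenario classification
# ---------------------------------------------------------------------------


def _replicate_means(replicates: Sequence[GasIsotopeObservation]):
    if len(replicates) == 0:
        raise ValueError("at least one replicate observation is required")
    r = np.array([o.o2_ar for o in replicates], dtype=float)
    d = np.array([o.d18o_o2 for o in replicates], dtype=float)
    sig_r = np.array([o.sigma_o2ar for o in replicates], dtype=float)
    sig_d = np.array([o.sigma_d18o for o in replicates], dtype=float)
    n = len(replicates)
    # Instrument sigma of the mean; replicate scatter widens it when larger.
    se_r = max(float(np.mean(sig_r)) / math.sqrt(n),
               float(np.std(r, ddof=1) / math.sqrt(n)) if n > 1 else 0.0)
    se_d = max(float(np.mean(sig_d)) / math.sqrt(n),
               float(np.std(d, ddof=1) / math.sqrt(n)) if n > 1 else 0.0)
    return float(np.mean(r)), float(np.mean(d)), se_r, se_d


def classify_scenario(
    replicates: Sequence[GasIsotopeObservation],
    em_air_eq: EndMember = AIR_EQUILIBRATED,
    epsilon_range: tuple[float, float] = (0.0, 25.0),
    delta_source: float = -20.0,
    sigma_multiplier: float = 3.0,
) -> ScenarioVerdict:
    """Classify a sample's replicate cloud against nested null scenarios.

    Tested in order, each at ``sigma_multiplier`` times the propagated
    replicate-mean sigma:

    1. *air_equilibrated* — within tolerance of the air-equilibrated point.
    2. *respiration_consistent* — on a Rayleigh curve for some
       epsilon in ``epsilon_range`` (O2/Ar at or below air-equilibrated,
       d18O at or above +23.9).
    3. *contamination_consistent* — reachable by respiration followed by
       air contamination (grid sweep over f, x_air, epsilon).
    4. *requires_light_source* — nothing above fits; only in-situ O2
       production (x_prod > 0) can explain the point. The verdict carries
       the inverted (f_resp, x_prod) under the default epsilon and
       delta_source.
    """
    mean_r, mean_d, se_r, se_d = _replicate_means(replicates)
    tol_r = sigma_multiplier * se_r
    tol_d = sigma_multiplier * se_d
    r_eq, d_eq = em_air_eq.o2_ar, em_air_eq.d18o

    def residual_of(point: EndMember) -> float:
        return math.hypot((point.o2_ar - mean_r) / max(se_r, 1e-12),
                          (point.d18o - mean_d) / max(se_d, 1e-12))

    # 1. null: air-equilibrated
    if abs(mean_r - r_eq) <= tol_r and abs(mean_d - d_eq) <= tol_d:
        params = ScenarioParams(delta_source=delta_source)
        return ScenarioVerdict(ScenarioLabel.AIR_EQUILIBRATED, params,
                               residual_of(em_air_eq), mean_r, mean_d, se_r, se_d)

    eps_grid = np.linspace(epsilon_range[0], epsilon_range[1], 126)

    # 2. respiration only: f is pinned by the O2/Ar ratio
    f_obs = mean_r / r_eq
    if f_obs <= 1.0 + tol_r / r_eq:
        f = min(max(f_obs, 1e-6), 1.0)
        d_pred = np.asarray(rayleigh_residual_delta(d_eq, f, eps_grid))
        k = int(np.argmin(np.abs(d_pred - mean_d)))
        if abs(d_pred[k] - mean_d) <= tol_d and abs(f * r_eq - mean_r) <= tol_r:
            params = ScenarioParams(epsilon_resp=float(eps_grid[k]),
                                    delta_source=delta_source, f_resp=f)
            point = rayleigh_respiration(em_air_eq, f, float(eps_grid[k]))
            return ScenarioVerdict(ScenarioLabel.RESPIRATION_CONSISTENT, params,
                                   residual_of(point), mean_r, mean_d, se_r, se_d)

    # 3. respiration + air contamination (vectorized grid sweep)
    f_grid = np.linspace(1e-3, 1.0, 120)
    x_grid = np.linspace(0.0, 1.0, 101)
    eps_c = np.linspace(epsilon_range[0], epsilon_range[1], 26)
    F, X, E = np.meshgrid(f_grid, x_grid, eps_c, indexing="ij")
    d_resp = (1000.0 + d_eq) * F ** (-E / 1000.0) - 1000.0
    r_mix = (1.0 - X) * r_eq * F + X * r_eq
    w_obs = (1.0 - X) * r_eq * F
    w_air = X * r_eq
    d_mix = (w_obs * d_resp + w_air * d_eq) / (w_obs + w_air)
    chi = ((r_mix - mean_r) / max(se_r, 1e-12)) ** 2 + ((d_mix - mean_d) / max(se_d, 1e-12)) ** 2
    idx = np.unravel_index(int(np.argmin(chi)), chi.shape)
    if (abs(r_mix[idx] - mean_r) <= tol_r) and (abs(d_mix[idx] - mean_d) <= tol_d):
        params = ScenarioParams(epsilon_resp=float(E[idx]), delta_source=delta_source,
                                f_resp=float(F[idx]), x_air=float(X[idx]))
        return ScenarioVerdict(ScenarioLabel.CONTAMINATION_CONSISTENT, params,
                               float(math.sqrt(chi[idx])), mean_r, mean_d, se_r, se_d)

    # 4. requires in-situ O2 production
    mean_obs = GasIsotopeObservation(
        sample_id=replicates[0].sample_id, replicate=-1,
        o2_ar=mean_r, d18o_o2=mean_d,
    )
    inv = invert_dark_o2(mean_obs, em_air_eq, epsilon_resp=18.0, delta_source=delta_source)
    if inv.feasible:
        params = ScenarioParams(epsilon_resp=18.0, delta_source=delta_source,
                                f_resp=min(max(inv.f_resp, 1e-9), 1.0), x_prod=inv.x_prod)
        point = forward_dark_o2(params, em_air_eq)
        return ScenarioVerdict(ScenarioLabel.REQUIRES_LIGHT_SOURCE, params,
                               residual_of(point), mean_r, mean_d, se_r, se_d,
                               dark_fraction=inv.dark_fraction)
    # Not even production fits exactly under the default epsilon: best-effort
    # least-squares over (f, x_prod) keeps the verdict informative.
    f_grid = np.linspace(1e-3, 1.0, 200)
    s = np.maximum(mean_r / r_eq, 1e-9)
    x = np.maximum(s - f_grid, 0.0)
    d_resp = np.asarray(rayleigh_residual_delta(d_eq, f_grid, 18.0))
    d_pred = (f_grid * d_resp + x * delta_source) / (f_grid + x)
    r_pred = r_eq * (f_grid + x)
    chi = ((r_pred - mean_r) / max(se_r, 1e-12)) ** 2 + ((d_pred - mean_d) / max(se_d, 1e-12)) ** 2
    k = int(np.argmin(chi))
    params = ScenarioParams(epsilon_resp=18.0, delta_source=delta_source,
                            f_resp=float(f_grid[k]), x_prod=float(x[k]))
    s_k = float(f_grid[k] + x[k])
    return ScenarioVerdict(ScenarioLabel.REQUIRES_LIGHT_SOURCE, params,
                           float(math.sqrt(chi[k])), mean_r, mean_d, se_r, se_d,
                           dark_fraction=float(x[k]) / s_k if s_k > 0 else 0.0)
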