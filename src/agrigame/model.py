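"""Core game model: parameters, payoff matrix, expected utilities.

Three populations interact over pollution control in one district: local
governments either actively guide green production (strategy ``g``) or not
(``ḡ``); new agricultural operators produce green (``e``) or non-green
(``ē``); traditional farmers cooperate — green production on their own land
or supervision/denunciation of operators — (``h``) or stay passive (``h̄``).
Operators farm a share ``alpha`` of the district's (unit) land, traditional
farmers the remaining ``1 - alpha``.

The payoff matrix assigns each of the eight pure-strategy profiles a triple
of payoffs (government, operator, farmer).  The replicator dynamics depend
only on the three utility *differences*

    G = u_g - u_ḡ,   E = u_e - u_ē,   H = u_h - u_h̄,

which are multilinear in the population shares (x, y, z) and independent of
the eight "level" parameters (regular incomes, the superior-government
punishment, the special fund, and the damage complements) that enter both
strategies of a player equally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, NamedTuple

import pandas as pd

from .errors import InsufficientParameterizationError, ParameterError

__all__ = [
    "GameParameters",
    "StrategyProfile",
    "PayoffMatrix",
    "MixedState",
    "UtilityDifferences",
    "ExpectedUtilities",
    "ValidationReport",
    "all_profiles",
    "payoff",
    "payoff_matrix",
    "expected_utilities",
    "utility_differences",
    "validate",
    "require_valid",
    "PARAMETER_NAMES",
    "LEVEL_PARAMETERS",
]

#: Required economic parameters, in canonical order (config keys use the same names).
PARAMETER_NAMES: tuple[str, ...] = (
    "Sg", "Se", "Sh", "Pg", "Dh", "Cg", "Pe", "We", "Le", "Ce",
    "kebe", "dSe", "dSh", "Ch", "khbh", "Wh", "dWh", "dSg", "alpha",
)

#: Parameters that cancel out of the utility differences G, E, H: they shift
#: both strategies of a player by the same amount and cannot affect the dynamics.
LEVEL_PARAMETERS: tuple[str, ...] = (
    "Sg", "Se", "Sh", "Pg", "Dh", "Cg", "comp_kebe", "comp_khbh",
)


@dataclass(frozen=True)
class GameParameters:
    """The economic parameter vector of the trilateral game.

    All quantities are in dimensionless currency units on a unit land area
    and unit group size.

    Attributes
    ----------
    Sg : regular income of local governments (taxes and fees).
    Se : regular per-unit-land income of new agricultural operators.
    Sh : regular per-unit-land income of traditional farmers.
    Pg : punishment on local governments from the superior government when
        the local environment deteriorates.
    Dh : land-transfer income of traditional farmers (per unit transferred land).
    Cg : local-government special fund for pollution control; must satisfy
        ``Cg < Sg``.
    Pe : fine imposed by an active government on non-green operators.
    We : government incentive paid to green operators.
    Le : operators' loss from termination of the land-operation contract when
        denounced by cooperating farmers.
    Ce : operators' extra cost of green production.
    kebe : operators' own share of future pollution damage (the lumped
        product ke*be).
    dSe : operators' extra income from selling green produce.
    dSh : farmers' extra income from selling green produce.
    Ch : farmers' extra cost of green production.
    khbh : farmers' own share of future pollution damage (kh*bh).
    Wh : government environmental-protection incentive paid to cooperating
        farmers.
    dWh : extra government reward to farmers for denouncing non-green
        operators.
    dSg : reward from the superior government to an active local government
        when both producer groups are green.
    alpha : share of district land operated by new agricultural operators,
        strictly between 0 and 1.
    comp_kebe : optional; the complementary damage (1-ke)*be borne by farmers
        who transferred land.  Needed only for payoff-level computations.
    comp_khbh : optional; the complementary damage (1-kh)*bh borne by local
        governments.  Needed only for payoff-level computations.
    """

    Sg: float
    Se: float
    Sh: float
    Pg: float
    Dh: float
    Cg: float
    Pe: float
    We: float
    Le: float
    Ce: float
    kebe: float
    dSe: float
    dSh: float
    Ch: float
    khbh: float
    Wh: float
    dWh: float
    dSg: float
    alpha: float
    comp_kebe: float | None = None
    comp_khbh: float | None = None

    @classmethod
    def from_dict(cls, mapping: dict) -> "GameParameters":
        """Build from a flat name -> value mapping (unknown keys rejected).

        Accepts either the lumped damages ``kebe``/``khbh`` directly, or the
        separate rates and damages ``ke, be, kh, bh``, from which both the
        lumped products and their complements are populated.
        """
        data = dict(mapping)
        if "ke" in data or "be" in data:
            try:
                ke, be = float(data.pop("ke")), float(data.pop("be"))
            except KeyError as exc:
                raise ParameterError(f"ke and be must be supplied together (missing {exc})")
            data.setdefault("kebe", ke * be)
            data.setdefault("comp_kebe", (1.0 - ke) * be)
        if "kh" in data or "bh" in data:
            try:
                kh, bh = float(data.pop("kh")), float(data.pop("bh"))
            except KeyError as exc:
                raise ParameterError(f"kh and bh must be supplied together (missing {exc})")
            data.setdefault("khbh", kh * bh)
            data.setdefault("comp_khbh", (1.0 - kh) * bh)
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {', '.join(unknown)}")
        missing = [name for name in PARAMETER_NAMES if name not in data]
        if missing:
            raise ParameterError(f"missing parameter(s): {', '.join(missing)}")
        return cls(**{k: (None if v is None else float(v)) for k, v in data.items()})

    def to_dict(self, include_complements: bool = True) -> dict:
        out = {name: getattr(self, name) for name in PARAMETER_NAMES}
        if include_complements:
            for name in ("comp_kebe", "comp_khbh"):
                value = getattr(self, name)
                if value is not None:
                    out[name] = value
        return out

    def replace(self, **changes) -> "GameParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class StrategyProfile:
    """One of the 8 pure-strategy profiles.

    ``gov``/``op``/``farmer`` are True for the active strategy (g, e, h) and
    False for its alternative (ḡ, ē, h̄).
    """

    gov: bool
    op: bool
    farmer: bool

    @property
    def label(self) -> str:
        return "({},{},{})".format(
            "g" if self.gov else "ḡ",
            "e" if self.op else "ē",
            "h" if self.farmer else "h̄",
        )


def all_profiles() -> Iterator[StrategyProfile]:
    """The 8 pure-strategy profiles, government-major order."""
    for gov, op, farmer in itertools.product((True, False), repeat=3):
        yield StrategyProfile(gov, op, farmer)


@dataclass(frozen=True)
class MixedState:
    """Population shares of the active strategies at one time point."""

    x: float  # share of local governments playing g
    y: float  # share of operators playing e
    z: float  # share of farmers playing h
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"state coordinate {name}={v} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


class UtilityDifferences(NamedTuple):
    G: float  # u_g - u_ḡ
    E: float  # u_e - u_ē
    H: float  # u_h - u_h̄


class ExpectedUtilities(NamedTuple):
    u_g: float
    u_gbar: float
    u_e: float
    u_ebar: float
    u_h: float
    u_hbar: float


def _require(params: GameParameters, name: str, context: str) -> float:
    value = getattr(params, name)
    if value is None:
        raise InsufficientParameterizationError(name, context)
    return value


def payoff(params: GameParameters, profile: StrategyProfile) -> tuple[float, float, float]:
    """Payoff triple (government, operator, farmer) of a pure-strategy profile.

    Profiles in which farmers are passive charge the government the
    complementary damage (1-kh)*bh; profiles with non-green operators charge
    transferring farmers (1-ke)*be.  Those cells require the optional
    complement fields and raise :class:`InsufficientParameterizationError`
    when they are absent.
    """
    p = params
    a = p.alpha
    ctx = f"payoff of profile {profile.label}"

    # --- government -------------------------------------------------------
    if profile.gov:
        if profile.op and profile.farmer:
            pi_g = p.Sg + p.dSg - p.Cg - p.We * a - (1 - a) * p.Wh
        elif profile.op and not profile.farmer:
            pi_g = p.Sg - p.Pg - p.We * a - p.Cg - _require(p, "comp_khbh", ctx) * (1 - a)
        elif not profile.op and profile.farmer:
            pi_g = p.Sg - p.Pg + p.Pe * a - p.Wh * (1 - a) - p.dWh * a - p.Cg
        else:
            pi_g = p.Sg - p.Pg + p.Pe * a - p.Cg - _require(p, "comp_khbh", ctx) * (1 - a)
    else:
        if profile.op and profile.farmer:
            pi_g = p.Sg - p.Cg
        elif not profile.op and profile.farmer:
            pi_g = p.Sg - p.Pg - p.Cg
        else:  # farmer passive: environment deteriorates either way
            pi_g = p.Sg - p.Pg - p.Cg - _require(p, "comp_khbh", ctx) * (1 - a)

    # --- operator ---------------------------------------------------------
    if profile.op:
        base = p.Se + p.dSe - p.Dh - p.Ce
        pi_e = (base + p.We) * a if profile.gov else base * a
    else:
        base = p.Se - p.Dh - p.kebe
        if profile.gov:
            # an active government always fines; denouncing farmers add the
            # contract-termination loss Le on top
            pi_e = (base - p.Le - p.Pe) * a if profile.farmer else (base - p.Pe) * a
        else:
            pi_e = (base - p.Le) * a if profile.farmer else base * a

    # --- farmer -----------------------------------------------------------
    transfer = p.Dh if profile.op else p.Dh - _require(p, "comp_kebe", ctx)
    if profile.farmer:
        own = (p.Sh + p.dSh - p.Ch + p.Wh) if profile.gov else (p.Sh + p.dSh - p.Ch)
        denounce = p.dWh if (profile.gov and not profile.op) else 0.0
        pi_h = (transfer + denounce) * a + own * (1 - a)
    else:
        pi_h = transfer * a + (p.Sh - p.khbh) * (1 - a)

    return (pi_g, pi_e, pi_h)


@dataclass(frozen=True)
class PayoffMatrix:
    """Payoffs of the three players for each of the 8 pure-strategy profiles."""

    entries: dict[StrategyProfile, tuple[float, float, float]] = field(repr=False)

    def __getitem__(self, profile: StrategyProfile) -> tuple[float, float, float]:
        return self.entries[profile]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per profile, three payoff columns."""
        rows = [
            {
                "profile": prof.label,
                "gov": prof.gov,
                "op": prof.op,
                "farmer": prof.farmer,
                "pi_gov": pi[0],
                "pi_op": pi[1],
                "pi_farmer": pi[2],
            }
            for prof, pi in self.entries.items()
        ]
        return pd.DataFrame(rows)


def payoff_matrix(params: GameParameters) -> PayoffMatrix:
    return PayoffMatrix({prof: payoff(params, prof) for prof in all_profiles()})


def expected_utilities(params: GameParameters, state: MixedState) -> ExpectedUtilities:
    """Expected utility of each of the six strategies at a mixed state.

    The utility of a strategy is its payoff averaged over the other two
    populations' strategy mixtures.  Requires the damage complements, since
    individual payoff cells do.  By construction the differences equal the
    closed forms returned by :func:`utility_differences`.
    """
    x, y, z = state.x, state.y, state.z

    def mix(fixed: str, active: bool) -> float:
        total = 0.0
        for prof in all_profiles():
            if getattr(prof, fixed) is not active:
                continue
            w = 1.0
            if fixed != "gov":
                w *= x if prof.gov else (1 - x)
            if fixed != "op":
                w *= y if prof.op else (1 - y)
            if fixed != "farmer":
                w *= z if prof.farmer else (1 - z)
            idx = {"gov": 0, "op": 1, "farmer": 2}[fixed]
            total += w * payoff(params, prof)[idx]
        return total

    return ExpectedUtilities(
        u_g=mix("gov", True), u_gbar=mix("gov", False),
        u_e=mix("op", True), u_ebar=mix("op", False),
        u_h=mix("farmer", True), u_hbar=mix("farmer", False),
    )


def _geh(params: GameParameters, x: float, y: float, z: float) -> tuple[float, float, float]:
    """Closed-form utility differences (G, E, H); hot path of the ODE right-hand side."""
    a = params.alpha
    G = (
        y * z * params.dSg
        - y * a * params.We
        - z * (1 - a) * params.Wh
        + (y - 1) * a * z * params.dWh
        + (1 - y) * a * params.Pe
    )
    E = a * (
        x * (params.We + params.Pe)
        + z * params.Le
        + params.dSe
        - params.Ce
        + params.kebe
    )
    H = (
        x * (1 - y) * params.dWh * a
        + (params.dSh - params.Ch + params.khbh) * (1 - a)
        + x * params.Wh * (1 - a)
    )
    return G, E, H


def utility_differences(params: GameParameters, state: MixedState) -> UtilityDifferences:
    """The bracketed drivers (G, E, H) of the replicator system.

    These need no damage complements: level parameters cancel from every
    strategy comparison.
    """
    return UtilityDifferences(*_geh(params, state.x, state.y, state.z))


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of parameter validation: hard violations and soft warnings."""

    hard_violations: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def is_valid(self) -> bool:
        return not self.hard_violations


def validate(params: GameParameters) -> ValidationReport:
    """Check model constraints.

    Hard violations: a negative parameter, ``alpha`` outside the open
    interval (0, 1), or ``Cg >= Sg``.  Warnings: the incentive-budget
    constraint ``Cg + dSg >= We*alpha + Wh*(1-alpha)`` failing, and — when
    the damage complements allow every cell to be evaluated — any negative
    payoff entry.
    """
    hard: list[str] = []
    warn: list[str] = []

    for name in PARAMETER_NAMES:
        v = getattr(params, name)
        if v < 0:
            hard.append(f"parameter {name}={v} is negative")
    for name in ("comp_kebe", "comp_khbh"):
        v = getattr(params, name)
        if v is not None and v < 0:
            hard.append(f"parameter {name}={v} is negative")
    if not 0.0 < params.alpha < 1.0:
        hard.append(f"alpha out of (0,1): alpha={params.alpha}")
    if params.Cg >= params.Sg:
        hard.append(f"Cg < Sg fails: Cg={params.Cg}, Sg={params.Sg}")

    budget = params.Cg + params.dSg
    outlay = params.We * params.alpha + params.Wh * (1 - params.alpha)
    if budget < outlay:
        warn.append(
            f"incentive budget Cg+dSg={budget} below outlay We*alpha+Wh*(1-alpha)={outlay}"
        )
    if params.comp_kebe is not None and params.comp_khbh is not None and not hard:
        for prof in all_profiles():
            for who, pi in zip(("gov", "op", "farmer"), payoff(params, prof)):
                if pi < 0:
                    warn.append(f"negative payoff {pi:.6g} for {who} in profile {prof.label}")
    return ValidationReport(tuple(hard), tuple(warn))


def require_valid(params: GameParameters) -> GameParameters:
    """Raise :class:`ParameterError` on any hard validation violation."""
    report = validate(params)
    if not report.is_valid:
        raise ParameterError("; ".join(report.hard_violations))
    return params
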