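"""Rest-point enumeration and local stability analysis.

Candidate rest points of the replicator system fall into three classes:

* the 8 cube corners (always rest points, labelled E1-E8);
* up to 5 edge/face candidates with one coordinate pinned at 0 or 1 and the
  remaining utility differences zeroed (E9-E13);
* up to 2 fully interior candidates where G = E = H = 0 simultaneously
  (E14, E15), the roots of a quadratic obtained by eliminating y and z.

Stability is judged from the Jacobian: all eigenvalue real parts negative
means asymptotically stable (an evolutionarily stable outcome), any positive
real part means unstable, and eigenvalues within ``eig_tol`` of the
imaginary axis make the point non-hyperbolic, where linearisation is silent.

For each corner that can be stable there is a closed-form set of strict
parameter inequalities (conditions 1-6); conditions 7 and 8 are their
numerically evaluated analogues for the two interior candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import root

from .dynamics import VERTEX_LABELS, vector_field
from .errors import ContractViolationError
from .model import GameParameters, _geh

__all__ = [
    "EquilibriumPoint",
    "StabilityAssessment",
    "AuxiliaryConstants",
    "aux_constants",
    "vertex_equilibria",
    "edge_equilibria",
    "interior_equilibria",
    "all_equilibria",
    "jacobian",
    "vertex_eigenvalues",
    "classify",
    "check_conditions",
    "condition_values",
    "stability_report",
    "CONDITION_OF_POINT",
]

logger = logging.getLogger(__name__)

_ADMISSIBLE_MARGIN = 1e-9
_DENOM_EPS = 1e-12

#: Candidate point -> stability-condition number (1-8).
CONDITION_OF_POINT: dict[str, int] = {
    "E2": 1, "E3": 2, "E4": 3, "E6": 4, "E7": 5, "E8": 6, "E14": 7, "E15": 8,
}


@dataclass(frozen=True)
class EquilibriumPoint:
    coords: tuple[float, float, float]
    kind: str  # "vertex" | "edge" | "interior"
    label: str | None = None
    admissible: bool = True
    note: str = ""


@dataclass(frozen=True)
class StabilityAssessment:
    eigenvalues: tuple[complex, complex, complex]
    classification: str  # "asymptotically_stable" | "unstable" | "non_hyperbolic"
    matched_condition: int | None


@dataclass(frozen=True)
class AuxiliaryConstants:
    """Shorthands of the interior-equilibrium algebra.

    A = We + Pe, B = Ce - kebe - dSe, C = dSg + alpha*dWh,
    D = dSh - Ch + khbh, E = (alpha - 1)*Wh - alpha*dWh,
    F = the square root of the quadratic discriminant (None when the
    radicand is negative and no real interior solution exists).
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float | None


def _quadratic_coefficients(p: GameParameters) -> tuple[float, float, float]:
    """Coefficients (a2, a1, a0) of the interior-equilibrium quadratic in x.

    Eliminating z = (B - x A)/Le from E = 0 and y = (D(1-alpha) - x E)/(x alpha dWh)
    from H = 0 and substituting into G = 0 gives
        a2 x^2 + a1 x + a0 = 0,
    a2 = E A dSg, a1 = -(1-a) C A D - B C E + A E a Le + B E a dWh + a^2 dWh Le Pe,
    a0 = D (1-a) (B C - A a Le).
    """
    a = p.alpha
    aux = aux_constants(p)
    A, B, C, D, E = aux.A, aux.B, aux.C, aux.D, aux.E
    a2 = E * A * p.dSg
    a1 = (
        -(1 - a) * C * A * D
        - B * C * E
        + A * E * a * p.Le
        + B * E * a * p.dWh
        + a**2 * p.dWh * p.Le * p.Pe
    )
    a0 = D * (1 - a) * (B * C - A * a * p.Le)
    return a2, a1, a0


def aux_constants(params: GameParameters) -> AuxiliaryConstants:
    p = params
    a = p.alpha
    A = p.We + p.Pe
    B = p.Ce - p.kebe - p.dSe
    C = p.dSg + a * p.dWh
    D = p.dSh - p.Ch + p.khbh
    E = (a - 1) * p.Wh - a * p.dWh
    a2 = E * A * p.dSg
    a1 = (
        -(1 - a) * C * A * D - B * C * E + A * E * a * p.Le
        + B * E * a * p.dWh + a**2 * p.dWh * p.Le * p.Pe
    )
    a0 = D * (1 - a) * (B * C - A * a * p.Le)
    radicand = a1 * a1 - 4 * a2 * a0
    F = math.sqrt(radicand) if radicand >= 0 else None
    return AuxiliaryConstants(A=A, B=B, C=C, D=D, E=E, F=F)


def _free_in_open_unit(*values: float) -> bool:
    return all(_ADMISSIBLE_MARGIN < v < 1 - _ADMISSIBLE_MARGIN for v in values)


def vertex_equilibria() -> list[EquilibriumPoint]:
    """The 8 corners of the unit cube; rest points for every parameter set."""
    return [
        EquilibriumPoint(coords=coords, kind="vertex", label=label)
        for label, coords in VERTEX_LABELS.items()
    ]


def edge_equilibria(params: GameParameters) -> list[EquilibriumPoint]:
    """Candidate rest points with exactly one coordinate pinned at 0 or 1 (E9-E13).

    Each candidate zeroes the two utility differences whose logistic factors
    are free.  Candidates whose defining denominators vanish are skipped with
    a logged note; candidates outside the open unit square of their free
    coordinates are returned flagged inadmissible, not dropped.
    """
    p = params
    a = p.alpha
    aux = aux_constants(p)
    A, B, D = aux.A, aux.B, aux.D
    out: list[EquilibriumPoint] = []

    def add(label: str, coords: tuple[float, float, float], free: tuple[float, ...]) -> None:
        out.append(
            EquilibriumPoint(
                coords=coords, kind="edge", label=label,
                admissible=_free_in_open_unit(*free),
            )
        )

    # E9: x = 1; E(1, ., z) = 0 and H(1, y, .) = 0
    if abs(p.Le) > _DENOM_EPS and abs(a * p.dWh) > _DENOM_EPS:
        y9 = (a * p.dWh + D * (1 - a) + p.Wh * (1 - a)) / (a * p.dWh)
        z9 = (B - A) / p.Le
        add("E9", (1.0, y9, z9), (y9, z9))
    else:
        logger.info("E9 skipped: zero denominator (Le or alpha*dWh)")

    # E10: y = 0; G(., 0, z) = 0 and H(x, 0, .) = 0
    den_x = p.Wh * (a - 1) - p.dWh * a
    den_z = (1 - a) * p.Wh + a * p.dWh
    if abs(den_x) > _DENOM_EPS and abs(den_z) > _DENOM_EPS:
        x10 = D * (1 - a) / den_x
        z10 = a * p.Pe / den_z
        add("E10", (x10, 0.0, z10), (x10, z10))
    else:
        logger.info("E10 skipped: zero denominator")

    # E11: z = 0; E(x, ., 0) = 0 and G(., y, 0) = 0
    if abs(A) > _DENOM_EPS:
        add("E11", (B / A, p.Pe / A, 0.0), (B / A, p.Pe / A))
    else:
        logger.info("E11 skipped: We + Pe = 0")

    # E12: y = 1; H(x, 1, .) = 0 and G(., 1, z) = 0
    den_z = p.dSg - (1 - a) * p.Wh
    if abs(p.Wh) > _DENOM_EPS and abs(den_z) > _DENOM_EPS:
        x12 = -D / p.Wh
        z12 = a * p.We / den_z
        add("E12", (x12, 1.0, z12), (x12, z12))
    else:
        logger.info("E12 skipped: zero denominator (Wh or dSg-(1-alpha)*Wh)")

    # E13: z = 1; E(x, ., 1) = 0 and G(., y, 1) = 0
    den_y = a * A - a * p.dWh - p.dSg
    if abs(A) > _DENOM_EPS and abs(den_y) > _DENOM_EPS:
        x13 = (B - p.Le) / A
        y13 = (-a * p.dWh + (a - 1) * p.Wh + a * p.Pe) / den_y
        add("E13", (x13, y13, 1.0), (x13, y13))
    else:
        logger.info("E13 skipped: zero denominator")

    return out


def interior_equilibria(
    params: GameParameters, cross_check: bool = True
) -> list[EquilibriumPoint]:
    """The up-to-two interior candidates E14 and E15 where G = E = H = 0.

    Solves the closed-form quadratic in x (see :func:`_quadratic_coefficients`)
    and recovers y and z by back-substitution.  Each root is cross-validated
    against a multivariate root-finder on (G, E, H); on disagreement beyond
    1e-6 the numeric root replaces the closed form and a discrepancy warning
    is logged.  Returns the empty list when the discriminant is negative or a
    defining denominator vanishes.
    """
    p = params
    a = p.alpha
    if abs(p.Le) < _DENOM_EPS or abs(a * p.dWh) < _DENOM_EPS:
        logger.info("interior candidates skipped: zero denominator (Le or alpha*dWh)")
        return []
    aux = aux_constants(p)
    if aux.F is None:
        logger.info("interior candidates skipped: negative discriminant, no real solution")
        return []
    a2, a1, _ = _quadratic_coefficients(p)

    roots_x: list[float]
    if abs(a2) < _DENOM_EPS:
        if abs(a1) < _DENOM_EPS:
            logger.info("interior candidates skipped: degenerate (a2 = a1 = 0)")
            return []
        _, _, a0 = _quadratic_coefficients(p)
        roots_x = [-a0 / a1]
    else:
        roots_x = [(-a1 - aux.F) / (2 * a2), (-a1 + aux.F) / (2 * a2)]

    out: list[EquilibriumPoint] = []
    for label, x in zip(("E14", "E15"), roots_x):
        if abs(x) < _DENOM_EPS:
            logger.info("%s skipped: x = 0 makes the back-substitution singular", label)
            continue
        z = (aux.B - x * aux.A) / p.Le
        y = (aux.D * (1 - a) - x * aux.E) / (x * a * p.dWh)
        coords = (x, y, z)
        note = ""
        if cross_check:
            sol = root(lambda v: _geh(p, *v), x0=np.array(coords), tol=1e-12)
            if sol.success and np.max(np.abs(sol.x - np.array(coords))) > 1e-6:
                logger.warning(
                    "%s closed form %s disagrees with numeric root %s; using numeric",
                    label, coords, tuple(sol.x),
                )
                coords = (float(sol.x[0]), float(sol.x[1]), float(sol.x[2]))
                note = "formula-discrepancy: numeric root substituted"
        out.append(
            EquilibriumPoint(
                coords=coords, kind="interior", label=label,
                admissible=_free_in_open_unit(*coords), note=note,
            )
        )
    return out


def all_equilibria(params: GameParameters) -> list[EquilibriumPoint]:
    return vertex_equilibria() + edge_equilibria(params) + interior_equilibria(params)


def jacobian(params: GameParameters, state) -> np.ndarray:
    """Analytic 3x3 Jacobian of the replicator vector field at a state."""
    p = params
    a = p.alpha
    if hasattr(state, "as_tuple"):
        x, y, z = state.as_tuple()
    else:
        x, y, z = state
    A = p.We + p.Pe
    B = p.Ce - p.kebe - p.dSe
    D = p.dSh - p.Ch + p.khbh
    G, E, H = _geh(p, x, y, z)
    return np.array(
        [
            [
                (1 - 2 * x) * G,
                x * (1 - x) * (z * p.dSg - a * A + a * z * p.dWh),
                x * (1 - x) * (y * p.dSg - (1 - a) * p.Wh + (y - 1) * a * p.dWh),
            ],
            [
                y * (1 - y) * a * A,
                (1 - 2 * y) * a * (x * A + z * p.Le - B),
                y * (1 - y) * a * p.Le,
            ],
            [
                z * (1 - z) * ((1 - y) * p.dWh * a + p.Wh * (1 - a)),
                z * (1 - z) * (-x * p.dWh * a),
                (1 - 2 * z) * (x * (1 - y) * p.dWh * a + D * (1 - a) + x * p.Wh * (1 - a)),
            ],
        ]
    )


def vertex_eigenvalues(params: GameParameters, label: str) -> tuple[float, float, float]:
    """Closed-form Jacobian eigenvalues at a cube corner.

    At a corner the Jacobian is diagonal with entries
    ((1-2x) G, (1-2y) E, (1-2z) H) evaluated there.
    """
    if label not in VERTEX_LABELS:
        raise ContractViolationError(f"unknown vertex label {label!r}")
    p = params
    a = p.alpha
    D = p.dSh - p.Ch + p.khbh
    table = {
        "E1": (a * p.Pe, a * (-p.Ce + p.kebe + p.dSe), D * (1 - a)),
        "E2": (
            -(1 - a) * p.Wh - a * p.dWh + a * p.Pe,
            a * (p.Le - p.Ce + p.kebe + p.dSe),
            -D * (1 - a),
        ),
        "E3": (-a * p.We, a * (p.Ce - p.dSe - p.kebe), D * (1 - a)),
        "E4": (
            -a * p.Pe,
            a * (p.We + p.Pe - p.Ce + p.kebe + p.dSe),
            p.dWh * a + D * (1 - a) + p.Wh * (1 - a),
        ),
        "E5": (
            a * p.We,
            -a * (p.We + p.Pe - p.Ce + p.kebe + p.dSe),
            D * (1 - a) + p.Wh * (1 - a),
        ),
        "E6": (
            (1 - a) * p.Wh + a * p.dWh - a * p.Pe,
            a * (p.We + p.Pe + p.Le - p.Ce + p.kebe + p.dSe),
            -(p.dWh * a + D * (1 - a) + p.Wh * (1 - a)),
        ),
        "E7": (
            p.dSg - a * p.We - (1 - a) * p.Wh,
            -a * (p.Le - p.Ce + p.kebe + p.dSe),
            -D * (1 - a),
        ),
        "E8": (
            -p.dSg + a * p.We + (1 - a) * p.Wh,
            -a * (p.We + p.Pe + p.Le - p.Ce + p.kebe + p.dSe),
            -D * (1 - a) - p.Wh * (1 - a),
        ),
    }
    return table[label]


def classify(
    params: GameParameters, point: EquilibriumPoint, eig_tol: float = 1e-9
) -> StabilityAssessment:
    """Eigenvalue-based stability verdict at a rest point.

    Asymptotically stable: all real parts < -eig_tol.  Unstable: some real
    part > +eig_tol.  Otherwise non-hyperbolic.  Raises
    :class:`ContractViolationError` when called on a non-rest-point.
    """
    residual = float(np.linalg.norm(vector_field(params, point.coords)))
    if residual > 1e-8:
        raise ContractViolationError(
            f"classify() requires a rest point; vector-field norm is {residual:.3e} "
            f"at {point.coords}"
        )
    eig = np.linalg.eigvals(jacobian(params, point.coords))
    real = eig.real
    if np.all(real < -eig_tol):
        classification = "asymptotically_stable"
    elif np.any(real > eig_tol):
        classification = "unstable"
    else:
        classification = "non_hyperbolic"
    matched = None
    if classification == "asymptotically_stable" and point.label in CONDITION_OF_POINT:
        matched = CONDITION_OF_POINT[point.label]
    eig_sorted = sorted(eig, key=lambda v: (v.real, v.imag))
    return StabilityAssessment(
        eigenvalues=(complex(eig_sorted[0]), complex(eig_sorted[1]), complex(eig_sorted[2])),
        classification=classification,
        matched_condition=matched,
    )


def condition_values(params: GameParameters, condition: int) -> tuple[float, float, float]:
    """The three left-hand sides of a corner stability condition (1-6).

    The condition holds iff every value is strictly negative.  Values are the
    printed inequality forms; some drop overall positive factors of alpha or
    (1-alpha), which cannot change the sign.
    """
    p = params
    a = p.alpha
    D = p.dSh - p.Ch + p.khbh
    table = {
        1: (
            -(1 - a) * p.Wh - a * p.dWh + a * p.Pe,
            p.Le - p.Ce + p.kebe + p.dSe,
            -D,
        ),
        2: (-a * p.We, p.Ce - p.dSe - p.kebe, D),
        3: (
            -a * p.Pe,
            p.We + p.Pe - p.Ce + p.kebe + p.dSe,
            p.dWh * a + D * (1 - a) + p.Wh * (1 - a),
        ),
        4: (
            (1 - a) * p.Wh + a * p.dWh - a * p.Pe,
            p.We + p.Pe + p.Le - p.Ce + p.kebe + p.dSe,
            -(p.dWh * a + D * (1 - a) + p.Wh * (1 - a)),
        ),
        5: (
            p.dSg - a * p.We - (1 - a) * p.Wh,
            -(p.Le - p.Ce + p.kebe + p.dSe),
            -D,
        ),
        6: (
            -p.dSg + a * p.We + (1 - a) * p.Wh,
            -a * (p.We + p.Pe + p.Le - p.Ce + p.kebe + p.dSe),
            -D * (1 - a) - p.Wh * (1 - a),
        ),
    }
    if condition not in table:
        raise ContractViolationError(f"condition must be 1..6, got {condition}")
    return table[condition]


def check_conditions(params: GameParameters, eig_tol: float = 1e-9) -> set[int]:
    """Numbers (1-8) of all stability conditions the parameter set satisfies.

    1-6 are the strict closed-form inequalities for corners E2, E3, E4, E6,
    E7, E8; equality counts as not satisfied (degenerate boundary).  7 and 8
    hold when the corresponding interior candidate is admissible with all
    Jacobian eigenvalue real parts below -eig_tol.
    """
    satisfied: set[int] = set()
    for cond in range(1, 7):
        values = condition_values(params, cond)
        if all(v < 0 for v in values):
            satisfied.add(cond)
        elif any(v == 0 for v in values) and all(v <= 0 for v in values):
            logger.info("condition %d degenerate: an inequality holds with equality", cond)
    for point in interior_equilibria(params):
        if not point.admissible:
            continue
        eig = np.linalg.eigvals(jacobian(params, point.coords))
        if np.all(eig.real < -eig_tol):
            satisfied.add(CONDITION_OF_POINT[point.label])
    return satisfied


def stability_report(params: GameParameters) -> pd.DataFrame:
    """Full candidate table: coordinates, eigenvalues, verdict, condition.

    One row per candidate rest point (corners always; edge/interior when
    their formulas are defined).  Inadmissible candidates are retained with
    classification "inadmissible".
    """
    satisfied = check_conditions(params)
    rows = []
    for pt in all_equilibria(params):
        entry = {
            "label": pt.label,
            "kind": pt.kind,
            "x": pt.coords[0],
            "y": pt.coords[1],
            "z": pt.coords[2],
            "admissible": pt.admissible,
        }
        if pt.admissible:
            assessment = classify(params, pt)
            for i, ev in enumerate(assessment.eigenvalues, start=1):
                entry[f"lambda{i}_re"] = ev.real
                entry[f"lambda{i}_im"] = ev.imag
            entry["classification"] = assessment.classification
            cond = CONDITION_OF_POINT.get(pt.label)
            entry["condition"] = cond if cond in satisfied else None
        else:
            entry["classification"] = "inadmissible"
            entry["condition"] = None
        rows.append(entry)
    return pd.DataFrame(rows)
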