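"""Exact mass-action equilibrium solvers for the hub/Kap/partner schemes.

Given total component concentrations and a :class:`~heatfit.thermo.ThermoScheme`,
these solvers return the equilibrium concentration of every free and
complexed species.  The free hub concentration [A] always has a closed-form
(quadratic) solution once the free ligand concentrations [B] and [C] are
known, because every species is at most second order in A.  [B] (and [C]
in the ternary case) are then found by bracketed scalar root finding on the
corresponding mass-balance residual: the residual is strictly negative at 0
and non-negative at the total concentration, so a bracket always exists and
convergence is unconditional.

All solves are deterministic and handle the degenerate limits (zero totals,
zero constants) analytically rather than by epsilon-regularization, so the
scheme-reduction identities hold exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from scipy.optimize import brentq

from .errors import InvalidParameterError, OracleFailureError, SolverFailureError
from .thermo import SchemeId, ThermoScheme

# Minimum relative tolerance scipy's brentq accepts (4 * machine eps).
_BRENTQ_RTOL = 8.881784197001252e-16

_BINARY_SCHEMES = (
    SchemeId.MONOMER_DIMER,
    SchemeId.SINGLE_SITE,
    SchemeId.TWO_MODE,
    SchemeId.MULTI_EQ,
)
_TERNARY_SCHEMES = (SchemeId.TERNARY, SchemeId.TERNARY_MONOMERIC)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (molar) of every species.

    ``A2starB`` is the 2:1 complex of two hub *monomers* bridged by one
    Kap (written A2*B); it differs from ``A2B`` (a preformed hub dimer
    bound to one Kap) in the oligomeric state of A.  Species not defined
    by the active scheme are exactly zero.
    """

    free_A: float = 0.0
    free_B: float = 0.0
    free_C: float = 0.0
    A2: float = 0.0
    AB: float = 0.0
    A2B: float = 0.0
    A2B2: float = 0.0
    A2starB: float = 0.0
    AC: float = 0.0
    A2C: float = 0.0
    A2C2: float = 0.0
    ABC: float = 0.0
    A2BC: float = 0.0
    A2BC2: float = 0.0
    A2B2C: float = 0.0
    A2B2C2: float = 0.0
    A2starBC: float = 0.0
    A2starBC2: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def totals(self) -> tuple[float, float, float]:
        """Reconstructed total concentrations (A, B, C) from the species."""
        s = self
        tot_a = (
            s.free_A
            + s.AB
            + s.AC
            + s.ABC
            + 2.0
            * (
                s.A2
                + s.A2B
                + s.A2B2
                + s.A2starB
                + s.A2C
                + s.A2C2
                + s.A2BC
                + s.A2BC2
                + s.A2B2C
                + s.A2B2C2
                + s.A2starBC
                + s.A2starBC2
            )
        )
        tot_b = (
            s.free_B
            + s.AB
            + s.A2B
            + s.A2starB
            + s.ABC
            + s.A2BC
            + s.A2BC2
            + s.A2starBC
            + s.A2starBC2
            + 2.0 * (s.A2B2 + s.A2B2C + s.A2B2C2)
        )
        tot_c = (
            s.free_C
            + s.AC
            + s.A2C
            + s.ABC
            + s.A2BC
            + s.A2B2C
            + s.A2starBC
            + 2.0 * (s.A2C2 + s.A2BC2 + s.A2B2C2 + s.A2starBC2)
        )
        return tot_a, tot_b, tot_c


def bond_group_concentrations(state: SpeciesState) -> dict[str, float]:
    """Molar concentration of formed "bonds" per reaction step, keyed by
    the enthalpy parameter that pays for them.

    Each complex is decomposed (Hess-style) into its formation steps: e.g.
    A2BC contains one hub-dimer contact (dH_sc), one dimer-Kap step (dH1)
    and one partner bond on the Kap-loaded dimer site (dH6).  Species with
    two partner molecules count their per-site bond twice.  The injection
    heat model multiplies the change of each group by its enthalpy, which
    is exactly the oligomer-shift (lambda) bookkeeping of the titration
    equations.
    """
    s = state
    return {
        "dH_sc": s.A2
        + s.A2C
        + s.A2C2
        + s.A2B
        + s.A2BC
        + s.A2BC2
        + s.A2B2
        + s.A2B2C
        + s.A2B2C2,
        "dH1": s.A2B + s.A2BC + s.A2BC2,
        "dH2": s.A2B2 + s.A2B2C + s.A2B2C2,
        "dH3": s.AB + s.ABC,
        "dH4": s.A2starB + s.A2starBC + s.A2starBC2,
        "dH5": s.AC + s.A2C + 2.0 * s.A2C2,
        "dH6": s.A2BC + 2.0 * s.A2BC2 + s.A2B2C + 2.0 * s.A2B2C2,
        "dH7": s.ABC + s.A2starBC + 2.0 * s.A2starBC2,
    }


def solve_monomer_dimer(total_A: float, K_sc: float) -> float:
    """Free monomer concentration for the pure 2A <-> A2 equilibrium.

    Closed form from the mass balance [A]_tot = [A] + 2*K_sc*[A]^2, written
    in a cancellation-free form; K_sc = 0 returns the trivial limit.
    """
    if total_A < 0 or K_sc < 0:
        raise InvalidParameterError("total_A and K_sc must be non-negative")
    if K_sc == 0.0 or total_A == 0.0:
        return total_A
    # [A] = (-1 + sqrt(1 + 8 K [A]_tot)) / (4K)  ==  2[A]_tot / (1 + sqrt(1 + 8 K [A]_tot))
    return 2.0 * total_A / (1.0 + math.sqrt(1.0 + 8.0 * K_sc * total_A))


def _free_A(total_A: float, B: float, C: float, sch: ThermoScheme) -> float:
    """Closed-form free [A] given free [B], [C] and the total of A.

    The A mass balance is quadratic in [A]:  p*[A]^2 + q*[A] - [A]_tot = 0
    with p, q depending on [B] and [C]; solved as 2*t/(q + sqrt(q^2+4pt))
    to avoid subtractive cancellation and to cover p = 0 smoothly.
    """
    c5 = 1.0 + sch.K5 * C
    c6 = 1.0 + sch.K6 * C
    c7 = 1.0 + sch.K7 * C
    p = (
        2.0 * sch.K_sc * c5 * c5
        + 2.0 * sch.K_sc * (sch.K1 * B + sch.K2 * B * B) * c6 * c6
        + 2.0 * sch.K4 * B * c7 * c7
    )
    q = 1.0 + sch.K5 * C + sch.K3 * B * c7
    if total_A == 0.0:
        return 0.0
    return 2.0 * total_A / (q + math.sqrt(q * q + 4.0 * p * total_A))


def _species_from_free(A: float, B: float, C: float, sch: ThermoScheme) -> SpeciesState:
    """All species concentrations as monomials in the free concentrations."""
    A2 = sch.K_sc * A * A
    AA = A * A
    return SpeciesState(
        free_A=A,
        free_B=B,
        free_C=C,
        A2=A2,
        AB=sch.K3 * A * B,
        A2B=sch.K1 * A2 * B,
        A2B2=sch.K2 * A2 * B * B,
        A2starB=sch.K4 * AA * B,
        AC=sch.K5 * A * C,
        A2C=2.0 * sch.K5 * A2 * C,
        A2C2=sch.K5 * sch.K5 * A2 * C * C,
        ABC=sch.K7 * sch.K3 * A * B * C,
        A2BC=2.0 * sch.K6 * sch.K1 * A2 * B * C,
        A2BC2=sch.K6 * sch.K6 * sch.K1 * A2 * B * C * C,
        A2B2C=2.0 * sch.K6 * sch.K2 * A2 * B * B * C,
        A2B2C2=sch.K6 * sch.K6 * sch.K2 * A2 * B * B * C * C,
        A2starBC=2.0 * sch.K7 * sch.K4 * AA * B * C,
        A2starBC2=sch.K7 * sch.K7 * sch.K4 * AA * B * C * C,
    )


def _solve_free_B(total_A: float, total_B: float, C: float, sch: ThermoScheme) -> float:
    """Free [B] at fixed free [C] by bracketed root finding on the B balance."""
    if total_B == 0.0:
        return 0.0

    def resid(B: float) -> float:
        A = _free_A(total_A, B, C, sch)
        st = _species_from_free(A, B, C, sch)
        return st.totals()[1] - total_B

    hi = resid(total_B)
    if hi <= 0.0:
        # No B is consumed by complexes (all B-coupling constants zero).
        return total_B
    try:
        return brentq(
            resid,
            0.0,
            total_B,
            xtol=1e-300,  # roots can sit many decades below the total
            rtol=_BRENTQ_RTOL,
            maxiter=2000,
        )
    except Exception as exc:  # pragma: no cover - bracket is guaranteed
        raise SolverFailureError(
            f"free-B root solve failed: totals=({total_A}, {total_B}), C={C}: {exc}"
        ) from exc


def solve_binary(total_A: float, total_B: float, scheme: ThermoScheme) -> SpeciesState:
    """Equilibrium species for the two-component (hub + Kap) system.

    Accepts any non-ternary scheme; TWO_MODE and MULTI_EQ are the intended
    cases, MONOMER_DIMER and SINGLE_SITE are their natural reductions.
    """
    if scheme.scheme_id not in _BINARY_SCHEMES:
        raise InvalidParameterError(
            f"solve_binary expects a two-component scheme, got {scheme.scheme_id.value}"
        )
    return _solve_general(total_A, total_B, 0.0, scheme)


def solve_ternary(
    total_A: float, total_B: float, total_C: float, scheme: ThermoScheme
) -> SpeciesState:
    """Equilibrium species for the three-component (hub + Kap + partner) system."""
    if scheme.scheme_id not in _TERNARY_SCHEMES:
        raise InvalidParameterError(
            f"solve_ternary expects a ternary scheme, got {scheme.scheme_id.value}"
        )
    return _solve_general(total_A, total_B, total_C, scheme)


def solve_species(
    total_A: float, total_B: float, total_C: float, scheme: ThermoScheme
) -> SpeciesState:
    """Scheme-dispatching equilibrium solve used by the forward model."""
    if scheme.scheme_id in _TERNARY_SCHEMES:
        return solve_ternary(total_A, total_B, total_C, scheme)
    if total_C != 0.0:
        raise InvalidParameterError(
            f"scheme {scheme.scheme_id.value} does not involve component C"
        )
    return solve_binary(total_A, total_B, scheme)


def _solve_general(
    total_A: float, total_B: float, total_C: float, sch: ThermoScheme
) -> SpeciesState:
    if min(total_A, total_B, total_C) < 0:
        raise InvalidParameterError("total concentrations must be non-negative")

    if total_C == 0.0:
        B = _solve_free_B(total_A, total_B, 0.0, sch)
        A = _free_A(total_A, B, 0.0, sch)
        return _species_from_free(A, B, 0.0, sch)

    def resid_c(C: float) -> float:
        B = _solve_free_B(total_A, total_B, C, sch)
        A = _free_A(total_A, B, C, sch)
        st = _species_from_free(A, B, C, sch)
        return st.totals()[2] - total_C

    hi = resid_c(total_C)
    if hi <= 0.0:
        C = total_C
    else:
        try:
            C = brentq(
                resid_c,
                0.0,
                total_C,
                xtol=1e-300,
                rtol=_BRENTQ_RTOL,
                maxiter=2000,
            )
        except Exception as exc:  # pragma: no cover - bracket is guaranteed
            raise SolverFailureError(
                "free-C root solve failed: totals="
                f"({total_A}, {total_B}, {total_C}): {exc}"
            ) from exc
    B = _solve_free_B(total_A, total_B, C, sch)
    A = _free_A(total_A, B, C, sch)
    return _species_from_free(A, B, C, sch)


# ---------------------------------------------------------------------------
# Independent verification oracle
# ---------------------------------------------------------------------------

#: Species table for the oracle: name -> (A-stoich, B-stoich, C-stoich,
#: coefficient builder).  Written independently of the production formulas.
def _oracle_species_table(sch: ThermoScheme) -> dict[str, tuple[int, int, int, float]]:
    Ksc, K1, K2, K3, K4, K5, K6, K7 = (
        sch.K_sc,
        sch.K1,
        sch.K2,
        sch.K3,
        sch.K4,
        sch.K5,
        sch.K6,
        sch.K7,
    )
    return {
        "A2": (2, 0, 0, Ksc),
        "AB": (1, 1, 0, K3),
        "A2B": (2, 1, 0, K1 * Ksc),
        "A2B2": (2, 2, 0, K2 * Ksc),
        "A2starB": (2, 1, 0, K4),
        "AC": (1, 0, 1, K5),
        "A2C": (2, 0, 1, 2.0 * K5 * Ksc),
        "A2C2": (2, 0, 2, K5 * K5 * Ksc),
        "ABC": (1, 1, 1, K7 * K3),
        "A2BC": (2, 1, 1, 2.0 * K6 * K1 * Ksc),
        "A2BC2": (2, 1, 2, K6 * K6 * K1 * Ksc),
        "A2B2C": (2, 2, 1, 2.0 * K6 * K2 * Ksc),
        "A2B2C2": (2, 2, 2, K6 * K6 * K2 * Ksc),
        "A2starBC": (2, 1, 1, 2.0 * K7 * K4),
        "A2starBC2": (2, 1, 2, K7 * K7 * K4),
    }


def oracle_solve(
    totals: tuple[float, float, float],
    scheme: ThermoScheme,
    rel_tol: float = 1e-13,
    max_iter: int = 200_000,
) -> SpeciesState:
    """Solve the same mass balances by damped multiplicative fixed point.

    Intended as an independent cross-check for small test systems: it shares
    no code path with the production solver (no quadratic closed form, no
    bracketed root finding).  Each iteration rescales every free
    concentration by (total/reconstructed_total)**damp, a contraction for
    mass-action binding polynomials.  Progressively smaller damping factors
    are tried before giving up.
    """
    tot = tuple(float(t) for t in totals)
    if min(tot) < 0:
        raise InvalidParameterError("totals must be non-negative")
    table = _oracle_species_table(scheme)

    def reconstruct(free: list[float]) -> tuple[list[float], dict[str, float]]:
        conc = {
            name: coeff * free[0] ** a * free[1] ** b * free[2] ** c
            for name, (a, b, c, coeff) in table.items()
        }
        recon = list(free)
        for name, (a, b, c, _) in table.items():
            recon[0] += a * conc[name]
            recon[1] += b * conc[name]
            recon[2] += c * conc[name]
        return recon, conc

    for damp in (0.5, 0.25, 0.1):
        free = [t if t > 0 else 0.0 for t in tot]
        for _ in range(max_iter):
            recon, _ = reconstruct(free)
            err = 0.0
            for j in range(3):
                if tot[j] > 0:
                    err = max(err, abs(recon[j] - tot[j]) / tot[j])
            if err < rel_tol:
                _, conc = reconstruct(free)
                return SpeciesState(
                    free_A=free[0], free_B=free[1], free_C=free[2], **conc
                )
            for j in range(3):
                if tot[j] > 0:
                    free[j] *= (tot[j] / recon[j]) ** damp
    raise OracleFailureError(
        f"oracle fixed point did not converge for totals={tot}, "
        f"scheme={scheme.scheme_id.value}"
    )
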