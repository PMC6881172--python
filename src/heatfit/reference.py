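"""Published thermodynamic constants for the yeast Nup53 hub system.

These are the literature values for the interactions of the Nup53 core
fragment (hub, A) with Kap121 (B), Nic96 (C) and Nup157 (D) at 288 K, as
obtained from global calorimetric analysis.  They parameterize the default
synthetic titration designs and serve as generating truths in recovery
tests.  K is in M^-1 (M^-2 for the termolecular steps), enthalpies and the
derived dG / TdS are in kcal/mol.
"""

from __future__ import annotations

from .thermo import KCAL, SchemeId, ThermoScheme

#: Row key -> (interaction, K, K_sd, unit, dH, dH_sd, dG, TdS), kcal/mol.
TABLE: dict[str, dict] = {
    "1": dict(interaction="2A <-> A2", K=1.0e4, K_sd=0.1e4, unit="M^-1",
              dH=6.5, dH_sd=0.2, dG=-5.3, TdS=11.8),
    "2a": dict(interaction="A + B <-> AB", K=4.2e6, K_sd=0.7e6, unit="M^-1",
               dH=-2.7, dH_sd=0.1, dG=-8.7, TdS=6.0),
    "2b": dict(interaction="2A + B <-> A2*B", K=1.9e11, K_sd=0.5e11, unit="M^-2",
               dH=4.2, dH_sd=0.7, dG=-14.9, TdS=19.1),
    "2c": dict(interaction="A2 + B <-> A2B", K=5.6e7, K_sd=0.8e7, unit="M^-1",
               dH=16.3, dH_sd=1.4, dG=-10.2, TdS=26.5),
    "2d": dict(interaction="A2 + 2B <-> A2B2", K=3.9e14, K_sd=1.0e14, unit="M^-2",
               dH=-1.3, dH_sd=0.4, dG=-19.2, TdS=17.9),
    "3": dict(interaction="A + D <-> AD", K=1.1e6, K_sd=0.3e6, unit="M^-1",
              dH=-10.1, dH_sd=0.5, dG=-8.0, TdS=-2.1),
    "4": dict(interaction="A + C <-> AC", K=9.9e5, K_sd=0.9e5, unit="M^-1",
              dH=-4.4, dH_sd=0.1, dG=-7.9, TdS=3.5),
    "5a": dict(interaction="(AB)app + C <-> (AB)appC", K=1.3e5, K_sd=0.4e5,
               unit="M^-1", dH=-5.2, dH_sd=0.6, dG=-6.7, TdS=1.5),
    "5a'": dict(interaction="(AB')app + C <-> (AB')appC", K=1.0e5, K_sd=0.1e5,
                unit="M^-1", dH=-5.1, dH_sd=0.4, dG=-6.6, TdS=1.5),
    "5b": dict(interaction="AB + C <-> ABC", K=2.0e5, K_sd=0.9e5, unit="M^-1",
               dH=-6.7, dH_sd=1.7, dG=-7.0, TdS=0.3),
    "5c": dict(interaction="A2Bi + C <-> A2BiC", K=1.2e5, K_sd=0.2e5,
               unit="M^-1", dH=-2.5, dH_sd=0.3, dG=-6.7, TdS=4.2),
}


def _kd(row: str, key: str) -> float:
    return TABLE[row][key]


def monomer_dimer_scheme() -> ThermoScheme:
    """Hub homodimerization only (dissociation-by-dilution experiments)."""
    return ThermoScheme(
        scheme_id=SchemeId.MONOMER_DIMER,
        K_sc=_kd("1", "K"),
        dH_sc=_kd("1", "dH") * KCAL,
    )


def single_site_scheme(row: str = "3") -> ThermoScheme:
    """Classic 1:1 scheme at one of the published single-site rows."""
    return ThermoScheme(
        scheme_id=SchemeId.SINGLE_SITE,
        K3=_kd(row, "K"),
        dH3=_kd(row, "dH") * KCAL,
    )


def two_mode_scheme() -> ThermoScheme:
    """1:1 plus bivalent 2:1 binding of the Kap to the monomeric hub
    C-terminal IDRs (the RRM-less construct)."""
    return ThermoScheme(
        scheme_id=SchemeId.TWO_MODE,
        K3=_kd("2a", "K"),
        dH3=_kd("2a", "dH") * KCAL,
        K4=_kd("2b", "K"),
        dH4=_kd("2b", "dH") * KCAL,
    )


def multi_eq_scheme() -> ThermoScheme:
    """Full hub-Kap scheme: dimerization, monomer modes, dimer modes."""
    return ThermoScheme(
        scheme_id=SchemeId.MULTI_EQ,
        K_sc=_kd("1", "K"),
        dH_sc=_kd("1", "dH") * KCAL,
        K1=_kd("2c", "K"),
        dH1=_kd("2c", "dH") * KCAL,
        K2=_kd("2d", "K"),
        dH2=_kd("2d", "dH") * KCAL,
        K3=_kd("2a", "K"),
        dH3=_kd("2a", "dH") * KCAL,
        K4=_kd("2b", "K"),
        dH4=_kd("2b", "dH") * KCAL,
    )


def ternary_scheme() -> ThermoScheme:
    """Full allosteric ternary scheme (hub + Kap + partner)."""
    base = multi_eq_scheme()
    return ThermoScheme(
        scheme_id=SchemeId.TERNARY,
        K_sc=base.K_sc,
        dH_sc=base.dH_sc,
        K1=base.K1,
        dH1=base.dH1,
        K2=base.K2,
        dH2=base.dH2,
        K3=base.K3,
        dH3=base.dH3,
        K4=base.K4,
        dH4=base.dH4,
        K5=_kd("4", "K"),
        dH5=_kd("4", "dH") * KCAL,
        K6=_kd("5c", "K"),
        dH6=_kd("5c", "dH") * KCAL,
        K7=_kd("5b", "K"),
        dH7=_kd("5b", "dH") * KCAL,
    )
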