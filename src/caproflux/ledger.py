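"""Cofactor-ledger bioenergetics of anaerobic chain elongation.

The model converts a fermentation product spectrum into an exact tally of
ATP (substrate-level and chemiosmotic), NADH, reduced ferredoxin (Fd2-),
translocated protons, and vented H2, under the following bookkeeping:

* substrate oxidation (per mole)
    glucose  -> 2 acetyl-CoA + 2 NADH + 2 Fd2- + 2 ATP (PTS glycolysis + Pfor;
                the PEP spent on uptake replaces the hexokinase ATP)
    lactate  -> 1 acetyl-CoA + 2 NADH net (the confurcating Ldh/EtfAB step
                consumes 1 Fd2- which Pfor restores, so net Fd2- is 0)
    pyruvate -> 1 acetyl-CoA + 1 Fd2-
* each reverse beta-oxidation elongation cycle (thiolase condensation, Hbd,
  Crt, bifurcating Bcd/EtfAB) consumes 3 NADH and regenerates 1 Fd2-;
  caproate costs two cycles from acetyl-CoA, butyrate one
* every mole of net Fd2- is oxidized by the membrane Rnf complex, yielding
  1 NADH and translocating ``rnf_protons_per_2e`` protons (default 2)
* the NADH surplus left after elongation is vented as H2 at 1:1
* the V-type ATPase makes one ATP per ``atpase_protons_per_atp`` protons
  (default 4); net acetate production earns 1 ATP via Ack-Pta, acetate
  consumption enters elongation via CoA transferase at zero ATP cost

All arithmetic is in exact rationals, so ledger closure (NADH produced =
NADH consumed, Fd2- balance = 0, C2-unit conservation) is checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Dict, Optional

from .thermo import Reaction

__all__ = [
    "LedgerConfig",
    "FermentationSpectrum",
    "CofactorLedger",
    "ElongationDemand",
    "FeasibilityResult",
    "RedoxInfeasibleError",
    "SpectrumError",
    "SUBSTRATES",
    "spectrum_from_equation",
    "oxidize_substrate",
    "elongation_demand",
    "run_ledger",
    "free_energy_per_atp",
    "redox_feasibility",
    "reducing_equivalent_pairs",
]


class SpectrumError(ValueError):
    """The product spectrum violates C2-unit (acetyl-CoA) conservation."""


class RedoxInfeasibleError(ValueError):
    """Elongation demands more NADH than the spectrum can supply."""

    def __init__(self, deficit: Fraction):
        self.deficit = deficit
        super().__init__(
            f"redox-infeasible spectrum: NADH deficit of {deficit} mol per basis"
        )


@dataclass(frozen=True)
class LedgerConfig:
    """Chemiosmotic stoichiometry of the membrane machinery.

    ``rnf_protons_per_2e`` is a calibration: 2 is the unique small integer
    that, together with 4 H+/ATP, reproduces both measured ATP yields.
    ``hydrogenase_donor`` selects which carrier's surplus leaves as H2;
    only net bookkeeping is observable, so this is configuration, not fact.
    """

    rnf_protons_per_2e: Fraction = Fraction(2)
    atpase_protons_per_atp: Fraction = Fraction(4)
    hydrogenase_donor: str = "nadh"  # "nadh" | "ferredoxin"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rnf_protons_per_2e", Fraction(self.rnf_protons_per_2e))
        object.__setattr__(
            self, "atpase_protons_per_atp", Fraction(self.atpase_protons_per_atp)
        )
        if self.rnf_protons_per_2e <= 0 or self.atpase_protons_per_atp <= 0:
            raise ValueError("proton stoichiometries must be positive")
        if self.hydrogenase_donor not in ("nadh", "ferredoxin"):
            raise ValueError("hydrogenase_donor must be 'nadh' or 'ferredoxin'")


@dataclass(frozen=True)
class _Oxidation:
    acetyl_coa: Fraction
    nadh: Fraction
    fd_red: Fraction
    atp_slp: Fraction


SUBSTRATES: Dict[str, _Oxidation] = {
    "glucose": _Oxidation(Fraction(2), Fraction(2), Fraction(2), Fraction(2)),
    "lactate": _Oxidation(Fraction(1), Fraction(2), Fraction(0), Fraction(0)),
    "pyruvate": _Oxidation(Fraction(1), Fraction(0), Fraction(1), Fraction(0)),
}


@dataclass
class FermentationSpectrum:
    """Moles of substrate and products on a stated basis.

    ``acetate_consumed`` is negative when acetate is a net product.
    """

    substrate: str
    substrate_moles: Fraction
    acetate_consumed: Fraction = Fraction(0)
    caproate: Fraction = Fraction(0)
    butyrate: Fraction = Fraction(0)
    basis: str = "per mole substrate"

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate {self.substrate!r}")
        for f in ("substrate_moles", "acetate_consumed", "caproate", "butyrate"):
            setattr(self, f, Fraction(getattr(self, f)))
        if self.substrate_moles < 0:
            raise ValueError("substrate moles must be nonnegative")
        if self.caproate < 0 or self.butyrate < 0:
            raise ValueError("product moles must be nonnegative")

    def c2_residual(self) -> Fraction:
        """Acetyl-CoA units in products minus units supplied; 0 when conserved."""
        ox = SUBSTRATES[self.substrate]
        supply = ox.acetyl_coa * self.substrate_moles + self.acetate_consumed
        demand = 3 * self.caproate + 2 * self.butyrate
        return demand - supply

    def scaled(self, k: Fraction, basis: Optional[str] = None) -> "FermentationSpectrum":
        k = Fraction(k)
        return FermentationSpectrum(
            self.substrate,
            self.substrate_moles * k,
            self.acetate_consumed * k,
            self.caproate * k,
            self.butyrate * k,
            basis or self.basis,
        )


@dataclass(frozen=True)
class ElongationDemand:
    steps: Fraction
    nadh_required: Fraction
    fd_generated: Fraction


@dataclass(frozen=True)
class CofactorLedger:
    atp_slp: Fraction
    nadh_produced: Fraction
    nadh_consumed: Fraction
    fd_reduced: Fraction  # mol Fd2- routed through Rnf
    protons_translocated: Fraction
    atp_chemiosmotic: Fraction
    h2: Fraction
    atp_total: Fraction
    config: LedgerConfig = field(default_factory=LedgerConfig)

    def as_dict(self) -> Dict[str, float]:
        return {
            "atp_slp": float(self.atp_slp),
            "nadh_produced": float(self.nadh_produced),
            "nadh_consumed": float(self.nadh_consumed),
            "fd_through_rnf": float(self.fd_reduced),
            "protons_translocated": float(self.protons_translocated),
            "atp_chemiosmotic": float(self.atp_chemiosmotic),
            "h2": float(self.h2),
            "atp_total": float(self.atp_total),
        }


@dataclass(frozen=True)
class FeasibilityResult:
    feasible: bool
    nadh_deficit: Fraction
    fallback_spectrum: Optional[FermentationSpectrum] = None


def spectrum_from_equation(rxn: Reaction, per: str = "substrate") -> FermentationSpectrum:
    """Read a balanced fermentation equation into a product spectrum.

    ``per`` selects the normalization basis: ``"substrate"`` (per mole of
    the reducing substrate), ``"glucose_equivalent"`` (per mole glucose or
    per two moles lactate/pyruvate — one mole of glucose is equivalent to
    two moles of lactate), or ``"as_printed"`` (no rescaling).
    """
    subs = [s for s in SUBSTRATES if rxn.stoich.get(s, Fraction(0)) < 0]
    if len(subs) != 1:
        raise ValueError(f"expected exactly one reducing substrate, found {subs}")
    substrate = subs[0]
    moles = -rxn.stoich[substrate]
    spec = FermentationSpectrum(
        substrate=substrate,
        substrate_moles=moles,
        acetate_consumed=-rxn.stoich.get("acetate", Fraction(0)),
        caproate=max(rxn.stoich.get("caproate", Fraction(0)), Fraction(0)),
        butyrate=max(rxn.stoich.get("butyrate", Fraction(0)), Fraction(0)),
        basis="as printed",
    )
    if per == "as_printed":
        return spec
    if per == "substrate":
        return spec.scaled(1 / moles, basis=f"per mole {substrate}")
    if per == "glucose_equivalent":
        k = Fraction(1) if substrate == "glucose" else Fraction(2)
        return spec.scaled(k / moles, basis="per glucose-equivalent")
    raise ValueError(f"unknown basis {per!r}")


def oxidize_substrate(substrate: str, moles: Fraction = Fraction(1)) -> Dict[str, Fraction]:
    """Acetyl-CoA, NADH, Fd2- and SLP-ATP from oxidizing ``moles`` of substrate."""
    try:
        ox = SUBSTRATES[substrate]
    except KeyError:
        raise ValueError(f"unknown substrate {substrate!r}") from None
    moles = Fraction(moles)
    return {
        "acetyl_coa": ox.acetyl_coa * moles,
        "nadh": ox.nadh * moles,
        "fd_reduced": ox.fd_red * moles,
        "atp_slp": ox.atp_slp * moles,
    }


def reducing_equivalent_pairs(substrate: str, moles: Fraction = Fraction(1)) -> Fraction:
    """(NADH + Fd2-) 2-electron pairs released per ``moles`` of substrate.

    glucose:lactate:pyruvate = 4:2:1 — pyruvate supplies one quarter of the
    reducing power of glucose and one half of that of lactate.
    """
    ox = oxidize_substrate(substrate, moles)
    return ox["nadh"] + ox["fd_reduced"]


def elongation_demand(spectrum: FermentationSpectrum) -> ElongationDemand:
    """Reverse beta-oxidation cycles and their redox demand for a spectrum."""
    steps = 2 * spectrum.caproate + spectrum.butyrate
    if steps < 0:
        raise SpectrumError("malformed spectrum: negative elongation steps")
    return ElongationDemand(steps, 3 * steps, steps)


def run_ledger(
    spectrum: FermentationSpectrum, config: Optional[LedgerConfig] = None
) -> CofactorLedger:
    """Close the cofactor ledger for a feasible spectrum.

    Raises :class:`RedoxInfeasibleError` (carrying the deficit) when
    elongation demands more NADH than oxidation plus Rnf can supply, and
    :class:`SpectrumError` when C2 units do not balance.
    """
    config = config or LedgerConfig()
    ox = oxidize_substrate(spectrum.substrate, spectrum.substrate_moles)
    elong = elongation_demand(spectrum)

    acetate_produced = max(-spectrum.acetate_consumed, Fraction(0))
    supply = ox["acetyl_coa"] + max(spectrum.acetate_consumed, Fraction(0))
    demand = 3 * spectrum.caproate + 2 * spectrum.butyrate + acetate_produced
    if supply != demand:
        raise SpectrumError(
            f"acetyl-CoA units do not balance: supplied {supply}, consumed {demand}"
        )

    fd_total = ox["fd_reduced"] + elong.fd_generated
    if config.hydrogenase_donor == "nadh":
        fd_through_rnf = fd_total
        nadh_produced = ox["nadh"] + fd_through_rnf
        surplus = nadh_produced - elong.nadh_required
        if surplus < 0:
            raise RedoxInfeasibleError(-surplus)
        h2 = surplus
        nadh_consumed = elong.nadh_required + h2
    else:  # surplus vented from ferredoxin before Rnf
        need = elong.nadh_required - ox["nadh"]
        if need > fd_total:
            raise RedoxInfeasibleError(need - fd_total)
        fd_through_rnf = max(need, Fraction(0))
        nadh_surplus = max(-need, Fraction(0))
        h2 = (fd_total - fd_through_rnf) + nadh_surplus
        nadh_produced = ox["nadh"] + fd_through_rnf
        nadh_consumed = elong.nadh_required + nadh_surplus

    protons = config.rnf_protons_per_2e * fd_through_rnf
    atp_slp = ox["atp_slp"] + acetate_produced  # Ack-Pta earns 1 ATP per acetate
    atp_chemi = protons / config.atpase_protons_per_atp
    return CofactorLedger(
        atp_slp=atp_slp,
        nadh_produced=nadh_produced,
        nadh_consumed=nadh_consumed,
        fd_reduced=fd_through_rnf,
        protons_translocated=protons,
        atp_chemiosmotic=atp_chemi,
        h2=h2,
        atp_total=atp_slp + atp_chemi,
        config=config,
    )


def redox_feasibility(
    spectrum: FermentationSpectrum, config: Optional[LedgerConfig] = None
) -> FeasibilityResult:
    """NADH deficit of a spectrum, with the maximal achievable fallback.

    The deficit is demand minus everything obtainable (oxidation NADH plus
    Rnf conversion of all Fd2-, including the Fd2- elongation itself
    regenerates).  When infeasible, the fallback scales elongation down to
    the redox-limited maximum and routes the leftover acetyl-CoA to acetate
    (earning 1 SLP-ATP each via Ack-Pta).
    """
    config = config or LedgerConfig()
    ox = oxidize_substrate(spectrum.substrate, spectrum.substrate_moles)
    elong = elongation_demand(spectrum)
    obtainable = ox["nadh"] + ox["fd_reduced"] + elong.fd_generated
    deficit = max(Fraction(0), elong.nadh_required - obtainable)
    if deficit == 0:
        return FeasibilityResult(True, Fraction(0))
    # 3*s <= nadh_ox + fd_ox + s  =>  s_max = (nadh_ox + fd_ox) / 2
    s_max = (ox["nadh"] + ox["fd_reduced"]) / 2
    scale = s_max / elong.steps
    cap = spectrum.caproate * scale
    but = spectrum.butyrate * scale
    supply = ox["acetyl_coa"] + max(spectrum.acetate_consumed, Fraction(0))
    leftover = supply - 3 * cap - 2 * but
    fallback = FermentationSpectrum(
        substrate=spectrum.substrate,
        substrate_moles=spectrum.substrate_moles,
        acetate_consumed=spectrum.acetate_consumed - leftover,
        caproate=cap,
        butyrate=but,
        basis=spectrum.basis + " (redox-limited)",
    )
    return FeasibilityResult(False, deficit, fallback)


def free_energy_per_atp(drg_per_basis: float, atp_per_basis: Fraction) -> float:
    """|dG| per mole of ATP; both inputs must share the same basis."""
    if atp_per_basis <= 0:
        raise ValueError("zero ATP yield: free energy per ATP is undefined")
    return abs(float(drg_per_basis)) / float(atp_per_basis)
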