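#!/usr/bin/env python
"""Thermodynamics and cofactor-ledger bioenergetics of the two fermentations:
transformed Gibbs energies, ATP yields, free energy per ATP, and the
reducing-equivalent comparison across substrates."""

import json
from pathlib import Path

from caproflux import thermo
from caproflux.ledger import (
    free_energy_per_atp,
    reducing_equivalent_pairs,
    run_ledger,
    spectrum_from_equation,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main():
    registry = thermo.CompoundRegistry.default()
    rxn1, rxn2 = thermo.eq1(registry), thermo.eq2(registry)

    dg1 = thermo.delta_r_g_prime(rxn1, "glucose", registry)
    dg2 = thermo.delta_r_g_prime(rxn2, "lactate", registry)
    print(f"dG'0 per mol glucose: {dg1.drg_prime:.1f} +/- {dg1.uncertainty:.1f} kJ/mol")
    print(f"dG'0 per mol lactate: {dg2.drg_prime:.1f} +/- {dg2.uncertainty:.1f} kJ/mol")

    led_g = run_ledger(spectrum_from_equation(rxn1))
    led_l2 = run_ledger(spectrum_from_equation(rxn2, per="glucose_equivalent"))
    print(f"ATP per mol glucose: {float(led_g.atp_total):.2f} "
          f"(SLP {float(led_g.atp_slp)}, chemiosmotic {float(led_g.atp_chemiosmotic)})")
    print(f"ATP per 2 mol lactate: {float(led_l2.atp_total):.2f}")
    print(f"lactate/glucose ATP ratio per glucose-equivalent: "
          f"{float(led_l2.atp_total / led_g.atp_total):.2f}")

    per_glc = free_energy_per_atp(dg1.drg_prime, led_g.atp_total)
    per_lac = free_energy_per_atp(dg2.drg_prime, led_l2.atp_total / 2)  # per mol lactate
    print(f"free energy per ATP: glucose route {per_glc:.1f} kJ/mol, "
          f"lactate route {per_lac:.1f} kJ/mol")

    pairs = {s: float(reducing_equivalent_pairs(s)) for s in ("glucose", "lactate", "pyruvate")}
    print(f"reducing-equivalent pairs per mole: {pairs}")

    report = {
        "drg_prime_glucose": round(dg1.drg_prime, 2),
        "drg_prime_lactate": round(dg2.drg_prime, 2),
        "atp_per_glucose": float(led_g.atp_total),
        "atp_per_two_lactate": round(float(led_l2.atp_total), 3),
        "ledger_glucose": led_g.as_dict(),
        "ledger_two_lactate": led_l2.as_dict(),
        "kj_per_atp_glucose_route": round(per_glc, 1),
        "kj_per_atp_lactate_route": round(per_lac, 1),
        "reducing_equivalent_pairs": pairs,
    }
    (OUT / "bioenergetics.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {OUT / 'bioenergetics.json'}")


if __name__ == "__main__":
    main()
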