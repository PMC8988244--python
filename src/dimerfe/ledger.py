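"""Assembly of the binding free energy from its sixteen staged contributions.

A :class:`FreeEnergyLedger` holds one variant's sixteen named terms: the
eleven bound-state restraint-imposition costs (loop, barrel and interface
conformational restraints per chain; three orientational angles; two axial
angles), the combined separation + axial term, the analytic free-state
orientational term, and the three free-state conformational release terms
(counted once per monomer, hence doubled).  The total is

    ΔG_bind = −Σ(11 bound terms) + ΔG_dist+a + ΔG_o^free
              + 2ΔG_I,c^free + 2ΔG_B,c^free + 2ΔG_L,c^free,

equivalently ΔG_bind = −kT·ln(K_eq/c°).  Errors combine in quadrature
treating terms as independent, with the doubled terms' errors doubled.

The module also produces the standard dissections: per-region nets
(2ΔG_free − ΔG_boundA − ΔG_boundB), the orientational net, exclusion
pathways (ΔG_bind without loop / loop+barrel / loop+barrel+interface /
barrel terms), ΔΔG between variants, and the heterodimer relation
ΔG_het = 2ΔG_WT-mut − ΔG_WT-WT − ΔG_mut-mut.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .pmf import FreeEnergyEstimate

__all__ = [
    "BOUND_TERMS",
    "ANGULAR_BOUND_TERMS",
    "FREE_CONF_TERMS",
    "TERM_NAMES",
    "FreeEnergyLedger",
    "assemble",
    "group_contributions",
    "ddg",
    "heterodimer_prediction",
    "propagate",
    "round_half_away",
    "load_ledger",
    "save_ledger",
    "reference_ledger",
    "reference_dg_bind",
    "variant_names",
    "angular_restraint_parameters",
    "conformational_restraint_parameters",
    "histidine_reference_charges",
]

#: The eleven bound-state terms, in the order the restraints are imposed.
BOUND_TERMS = (
    "dG_LA_c_bound", "dG_LB_c_bound",
    "dG_BA_c_bound", "dG_BB_c_bound",
    "dG_IA_c_bound", "dG_IB_c_bound",
    "dG_Theta_o_bound", "dG_Phi_o_bound", "dG_Psi_o_bound",
    "dG_theta_a_bound", "dG_phi_a_bound",
)

#: Bound-state angular terms (orientational Euler angles plus axial angles).
ANGULAR_BOUND_TERMS = (
    "dG_Theta_o_bound", "dG_Phi_o_bound", "dG_Psi_o_bound",
    "dG_theta_a_bound", "dG_phi_a_bound",
)

#: Free-state conformational terms; each enters the total with coefficient 2.
FREE_CONF_TERMS = ("dG_I_c_free", "dG_B_c_free", "dG_L_c_free")

TERM_NAMES = BOUND_TERMS + ("dG_dist_a_restr", "dG_o_free") + FREE_CONF_TERMS

_REGIONS = {
    "loop": ("dG_LA_c_bound", "dG_LB_c_bound", "dG_L_c_free"),
    "barrel": ("dG_BA_c_bound", "dG_BB_c_bound", "dG_B_c_free"),
    "interface": ("dG_IA_c_bound", "dG_IB_c_bound", "dG_I_c_free"),
}


class MissingTermError(KeyError):
    """A required ledger term is absent."""


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (report convention for tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class FreeEnergyLedger:
    """The sixteen named free-energy terms of one variant."""

    variant: str
    terms: dict[str, FreeEnergyEstimate]

    def __post_init__(self) -> None:
        missing = [name for name in TERM_NAMES if name not in self.terms]
        if missing:
            raise MissingTermError(f"ledger {self.variant!r} is missing terms: {missing}")

    def __getitem__(self, name: str) -> FreeEnergyEstimate:
        try:
            return self.terms[name]
        except KeyError as exc:
            raise MissingTermError(name) from exc

    @classmethod
    def from_values(
        cls, variant: str, values: Mapping[str, float | Sequence[float]]
    ) -> "FreeEnergyLedger":
        terms = {}
        for name, val in values.items():
            if isinstance(val, (int, float)):
                terms[name] = FreeEnergyEstimate(float(val))
            else:
                v, e = val
                terms[name] = FreeEnergyEstimate(float(v), stat_error=float(e))
        return cls(variant, terms)


def propagate(errors: Sequence[float], coefficients: Sequence[float] | None = None) -> float:
    """Quadrature error of a linear combination of independent terms."""
    if coefficients is None:
        coefficients = [1.0] * len(errors)
    if any(e < 0 for e in errors):
        raise ValueError("errors must be non-negative")
    return math.sqrt(sum((c * e) ** 2 for c, e in zip(coefficients, errors)))


def _combine(ledger: FreeEnergyLedger, coeffs: Mapping[str, float]) -> FreeEnergyEstimate:
    value = sum(c * ledger[name].value for name, c in coeffs.items())
    err = propagate(
        [ledger[name].error for name in coeffs], list(coeffs.values())
    )
    return FreeEnergyEstimate(value, stat_error=err)


def _assembly_coefficients(exclude_regions: Sequence[str] = ()) -> dict[str, float]:
    coeffs: dict[str, float] = {name: -1.0 for name in BOUND_TERMS}
    coeffs["dG_dist_a_restr"] = 1.0
    coeffs["dG_o_free"] = 1.0
    for name in FREE_CONF_TERMS:
        coeffs[name] = 2.0
    for region in exclude_regions:
        a, b, free = _REGIONS[region]
        for name in (a, b, free):
            del coeffs[name]
    return coeffs


def assemble(ledger: FreeEnergyLedger,
             exclude_regions: Sequence[str] = ()) -> FreeEnergyEstimate:
    """ΔG_bind from the sixteen terms, optionally deleting whole regions.

    ``exclude_regions`` may list any of "loop", "barrel", "interface"; the
    corresponding bound terms and the doubled free term are removed from the
    sum, giving the dissected totals (e.g. ΔG_bind without the loop terms).
    """
    return _combine(ledger, _assembly_coefficients(exclude_regions))


def group_contributions(ledger: FreeEnergyLedger) -> dict[str, FreeEnergyEstimate]:
    """Named dissections of the assembled total.

    Region nets are the net free-energy change of that conformational freedom
    upon monomerization, 2ΔG_free − ΔG_boundA − ΔG_boundB; the orientational
    net subtracts all five bound angular terms from the analytic free-state
    orientational term.  Exclusion pathways re-assemble the total with whole
    regions deleted.
    """
    out: dict[str, FreeEnergyEstimate] = {}
    for region, (a, b, free) in _REGIONS.items():
        out[f"{region}_net"] = _combine(ledger, {free: 2.0, a: -1.0, b: -1.0})
    orient = {"dG_o_free": 1.0}
    orient.update({name: -1.0 for name in ANGULAR_BOUND_TERMS})
    out["orientational_net"] = _combine(ledger, orient)
    conf = {}
    for region, (a, b, free) in _REGIONS.items():
        conf.update({free: 2.0, a: -1.0, b: -1.0})
    out["conformational_net"] = _combine(ledger, conf)
    out["sum_free_conformational"] = _combine(
        ledger, {name: 2.0 for name in FREE_CONF_TERMS}
    )
    out["sum_bound_conformational"] = _combine(
        ledger,
        {name: 1.0 for region in _REGIONS.values() for name in region[:2]},
    )
    out["dG_bind"] = assemble(ledger)
    out["dG_bind_noL"] = assemble(ledger, exclude_regions=("loop",))
    out["dG_bind_noLB"] = assemble(ledger, exclude_regions=("loop", "barrel"))
    out["dG_bind_noLBI"] = assemble(
        ledger, exclude_regions=("loop", "barrel", "interface")
    )
    out["dG_bind_noB"] = assemble(ledger, exclude_regions=("barrel",))
    return out


def ddg(variant: FreeEnergyLedger, reference: FreeEnergyLedger) -> FreeEnergyEstimate:
    """ΔΔG_bind = ΔG_bind(variant) − ΔG_bind(reference), errors in quadrature."""
    a = assemble(variant)
    b = assemble(reference)
    return FreeEnergyEstimate(a.value - b.value, stat_error=propagate([a.error, b.error]))


def heterodimer_prediction(
    dg_het: float, dg_wt_homodimer: float, dg_mut_homodimer: float
) -> float:
    """Heterodimer binding free energy from the homodimer values (kcal/mol).

    Inverts ΔG_het = 2ΔG_WT-mut − ΔG_WT-WT − ΔG_mut-mut for ΔG_WT-mut, where
    ΔG_het is the (experimentally measured) imbalance of the heterodimer
    against the two homodimers.
    """
    return 0.5 * (dg_het + dg_wt_homodimer + dg_mut_homodimer)


# ---------------------------------------------------------------------------
# I/O and packaged reference data
# ---------------------------------------------------------------------------

def save_ledger(ledger: FreeEnergyLedger, path) -> None:
    """Write a ledger as TSV (columns: term, value, error) or JSON by suffix."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "variant": ledger.variant,
            "terms": {n: [ledger[n].value, ledger[n].error] for n in TERM_NAMES},
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        df = pd.DataFrame(
            {
                "term": list(TERM_NAMES),
                "value": [ledger[n].value for n in TERM_NAMES],
                "error": [ledger[n].error for n in TERM_NAMES],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def load_ledger(path, variant: str | None = None) -> FreeEnergyLedger:
    """Read a ledger from TSV (term/value/error columns) or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return FreeEnergyLedger.from_values(
            variant or payload.get("variant", path.stem), payload["terms"]
        )
    df = pd.read_csv(path, sep="\t")
    values = {
        str(row["term"]): (float(row["value"]), float(row.get("error", 0.0)))
        for _, row in df.iterrows()
    }
    return FreeEnergyLedger.from_values(variant or path.stem, values)


def _load_data(name: str) -> dict:
    with resources.files("dimerfe.data").joinpath(name).open() as fh:
        return json.load(fh)


def variant_names() -> list[str]:
    """The five SOD1 variants with packaged reference ledgers."""
    data = _load_data("sod1_free_energy_ledgers.json")
    return [k for k in data if not k.startswith("_")]


def reference_ledger(variant: str) -> FreeEnergyLedger:
    """Packaged reference ledger (sixteen terms with errors) for a variant."""
    data = _load_data("sod1_free_energy_ledgers.json")
    if variant not in data:
        raise KeyError(f"unknown variant {variant!r}; known: {variant_names()}")
    return FreeEnergyLedger.from_values(variant, data[variant]["terms"])


def reference_dg_bind(variant: str) -> FreeEnergyEstimate:
    """The study's own assembled ΔG_bind for a variant, as printed."""
    data = _load_data("sod1_free_energy_ledgers.json")
    value, error = data[variant]["dG_bind"]
    return FreeEnergyEstimate(value, stat_error=error)


def angular_restraint_parameters(variant: str) -> dict:
    """Orientational/axial restraint centers (rad), k, and r* for a variant."""
    data = _load_data("sod1_restraints.json")["angular"]
    if variant not in data:
        raise KeyError(f"unknown variant {variant!r}; known: {list(data)}")
    return data[variant]


def conformational_restraint_parameters() -> dict:
    """The six conformational RMSD restraints (centers, k, selections)."""
    return _load_data("sod1_restraints.json")["conformational"]


def histidine_reference_charges() -> dict:
    """Reference partial charges of the reparametrized histidine types."""
    return {
        k: v for k, v in _load_data("sod1_histidine_charges.json").items()
        if not k.startswith("_")
    }
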