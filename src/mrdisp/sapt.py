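"""SAPT(MC) / CAS+DISP assembly: corrections, totals and error metrics.

The interaction energy is decomposed into first-order electrostatics and
exchange, second-order induction, exchange-induction, dispersion and
exchange-dispersion, plus a delta correction for higher-order induction:

* delta_HF for ground states: the part of the supermolecular Hartree-Fock
  interaction energy not captured by the listed mean-field SAPT terms;
* delta_CAS for excited states: delta_HF scaled by the excited-to-ground
  ratio of the second-order induction energies;
* exchange terms in a large basis estimated by scaling the small-basis value
  with the ratio of the corresponding polarization components (the
  convergence of second-order polarization and exchange components with the
  basis is assumed identical);
* CAS+DISP: supermolecular CASSCF interaction energy plus
  E_disp^(2) + E_exch-disp^(2).

All energies in this module are in kcal/mol.  The printed component tables
of the reference data set ship as CSV fixtures and are reproduced by the
pure arithmetic here; one row (AcOH-pentane CAS+DISP, ground state) is
inconsistent with its own printed components by 0.06 kcal/mol and is
tracked as a known discrepancy rather than silently adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["SAPTComponents", "MetricsReport", "delta_hf", "delta_cas",
           "scale_exchange", "total_sapt", "cas_plus_disp", "error_metrics",
           "es_gs_differences", "load_table", "reconstruct_table1_totals",
           "KNOWN_DISCREPANCIES", "ROUNDING_BOUND"]

STATES = ("GS", "ES")
#: half of one unit in the last printed place, accumulated over <= 7 addends
#: that were each rounded to two decimals
ROUNDING_BOUND = 0.015

#: printed totals that are NOT reproducible from their printed parts within
#: the rounding bound: (table, complex, state) -> printed-minus-recomputed
KNOWN_DISCREPANCIES = {("table2", "AcOH-Pentane", "GS"): -0.06}


@dataclass
class SAPTComponents:
    """One complex / one electronic state worth of interaction-energy terms."""

    e_elst: float
    e_exch: float
    e_ind: float
    e_exch_ind: float
    e_disp: float
    e_exch_disp: float
    delta: float
    state: str = "GS"
    basis: str = "aVTZ"
    complex_id: str = ""

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        for name in ("e_elst", "e_exch", "e_ind", "e_exch_ind", "e_disp",
                     "e_exch_disp", "delta"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"component {name} missing or non-finite")


@dataclass
class MetricsReport:
    errors: np.ndarray       # signed, value - reference
    mae: float
    mape: float
    reference: str = ""


def delta_hf(e_int_hf: float, hf: SAPTComponents) -> float:
    """Higher-order induction estimate from the supermolecular HF energy.

    delta_HF = E_int^HF - (E_elst^(1) + E_exch^(1) + E_ind^(2) +
    E_exch-ind^(2)), all terms from mean-field (Hartree-Fock) monomers.
    """
    return e_int_hf - (hf.e_elst + hf.e_exch + hf.e_ind + hf.e_exch_ind)


def delta_cas(d_hf: float, e_ind_gs: float, e_ind_es: float) -> float:
    """Excited-state delta correction by induction-ratio scaling.

    delta_CAS = delta_HF * E_ind^(2)(ES) / E_ind^(2)(GS): the change of
    higher-than-second-order induction upon excitation is assumed
    proportional to the shift in the second-order induction itself.
    """
    if e_ind_gs == 0:
        raise ValueError("ground-state induction is zero: ratio undefined")
    return d_hf * (e_ind_es / e_ind_gs)


def scale_exchange(e_exch_small: float, e_pol_small: float,
                   e_pol_large: float) -> float:
    """Estimate an exchange component in a larger basis.

    The exchange term is scaled by the ratio of its polarization partner
    (induction for exchange-induction, dispersion for exchange-dispersion)
    between the two bases.
    """
    if e_pol_small == 0:
        raise ValueError("small-basis polarization component is zero")
    return e_exch_small * (e_pol_large / e_pol_small)


def total_sapt(c: SAPTComponents) -> float:
    """Sum of all seven interaction-energy components."""
    return (c.e_elst + c.e_exch + c.e_ind + c.e_exch_ind + c.e_disp
            + c.e_exch_disp + c.delta)


def cas_plus_disp(e_casscf: float, e_disp: float, e_exch_disp: float) -> float:
    """Supermolecular CASSCF interaction energy plus DISP = E_disp + E_exch-disp."""
    return e_casscf + e_disp + e_exch_disp


def error_metrics(values, refs, reference: str = "") -> MetricsReport:
    """Signed errors, MAE and MA%E of ``values`` against ``refs``."""
    v = np.asarray(values, dtype=float)
    r = np.asarray(refs, dtype=float)
    if v.shape != r.shape or v.size == 0:
        raise ValueError("values and references must have equal nonzero length")
    if np.any(r == 0.0):
        raise ValueError("zero reference value: MA%E undefined")
    err = v - r
    return MetricsReport(err, float(np.mean(np.abs(err))),
                         float(np.mean(100.0 * np.abs(err) / np.abs(r))),
                         reference)


def es_gs_differences(gs: SAPTComponents, es: SAPTComponents) -> dict:
    """Per-component excitation-induced shifts Delta E_x = E_x(ES) - E_x(GS)."""
    if gs.complex_id != es.complex_id:
        raise ValueError("GS/ES records belong to different complexes")
    out = {}
    for name in ("e_elst", "e_exch", "e_ind", "e_exch_ind", "e_disp",
                 "e_exch_disp", "delta"):
        out[name] = getattr(es, name) - getattr(gs, name)
    out["total"] = total_sapt(es) - total_sapt(gs)
    return out


# ---------------------------------------------------------------------------
# Printed-table fixtures
# ---------------------------------------------------------------------------

def load_table(which: str) -> pd.DataFrame:
    """Load one of the shipped component tables ("table1" .. "table3")."""
    if which not in ("table1", "table2", "table3"):
        raise ValueError("unknown table")
    path = resources.files("mrdisp") / "data" / f"{which}.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def table1_components(df: pd.DataFrame | None = None) -> list[SAPTComponents]:
    df = load_table("table1") if df is None else df
    return [SAPTComponents(r.e_elst, r.e_exch, r.e_ind, r.e_exch_ind,
                           r.e_disp, r.e_exch_disp, r.delta, r.state,
                           "aVTZ", r.complex)
            for r in df.itertuples()]


def reconstruct_table1_totals() -> pd.DataFrame:
    """Recompute every printed total from its printed components.

    Returns a frame with the recomputed sum, the printed total and their
    difference; all rows are expected inside the two-decimal rounding bound.
    """
    df = load_table("table1")
    comps = table1_components(df)
    rec = [total_sapt(c) for c in comps]
    out = df[["complex", "state", "sapt"]].copy()
    out["recomputed"] = np.round(rec, 10)
    out["difference"] = out["recomputed"] - out["sapt"]
    return out
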