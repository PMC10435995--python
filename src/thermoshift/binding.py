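"""Biophysical binding models.

One-site isothermal titration calorimetry (ITC) in the reverse-titration
geometry (protein titrated from the syringe into a ligand-containing cell),
with displacement-style dilution bookkeeping; nonlinear least-squares
fitting of Kd, binding enthalpy, stoichiometry and a per-injection heat
offset; and competitive-inhibition enzyme kinetics with IC50 extraction.

Units follow calorimetry practice: volumes in microlitres, concentrations
in micromolar (Kd in nanomolar at the interface, since the affinities of
interest are nanomolar), enthalpies in kJ/mol, heats in microjoules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "InjectionSchedule",
    "Isotherm",
    "BindingFit",
    "EnzymeAssay",
    "itc_titration",
    "itc_expected_heats",
    "fit_itc",
    "inhibited_rate",
    "ic50_from_rates",
    "wiseman_c",
]


@dataclass(frozen=True)
class InjectionSchedule:
    """Reverse-titration injection schedule.

    The cell holds the small-molecule ligand; the syringe holds the protein
    titrant. Defaults mirror a low-volume calorimeter run: 169 ul effective
    cell volume (the overfill beyond it only guarantees a full cell), 1 uM
    ligand in the cell, 4.3 uM protein in a 50 ul syringe delivered as one
    0.96 ul conditioning injection followed by 24 x 2 ul, 300 s apart,
    at 37 C.
    """

    cell_volume_ul: float = 169.0
    cell_ligand_um: float = 1.0
    syringe_protein_um: float = 4.3
    injection_volumes_ul: tuple[float, ...] = (0.96,) + (2.0,) * 24
    syringe_volume_ul: float = 50.0
    temperature_c: float = 37.0
    spacing_s: float = 300.0

    def __post_init__(self) -> None:
        vols = np.asarray(self.injection_volumes_ul, dtype=float)
        if self.cell_volume_ul <= 0:
            raise ValueError("cell volume must be positive")
        if self.cell_ligand_um <= 0 or self.syringe_protein_um <= 0:
            raise ValueError("non-physical concentrations (must be > 0)")
        if vols.size == 0 or np.any(vols <= 0):
            raise ValueError("injection volumes must be positive")
        if np.any(vols > self.cell_volume_ul):
            raise ValueError("an injection cannot exceed the cell volume")
        if vols.sum() > self.syringe_volume_ul + 1e-9:
            raise ValueError(
                f"cumulative injected volume {vols.sum():.2f} ul exceeds the "
                f"{self.syringe_volume_ul} ul syringe"
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)


@dataclass
class Isotherm:
    """Per-injection integrated heats for one titration."""

    schedule: InjectionSchedule
    heats_uj: np.ndarray

    def __post_init__(self) -> None:
        self.heats_uj = np.asarray(self.heats_uj, dtype=float)
        if self.heats_uj.shape != (self.schedule.n_injections,):
            raise ValueError(
                f"expected one heat per injection "
                f"({self.schedule.n_injections}), got {self.heats_uj.shape}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection": np.arange(1, self.schedule.n_injections + 1),
                "volume_ul": list(self.schedule.injection_volumes_ul),
                "heat_uj": self.heats_uj,
            }
        )


@dataclass
class BindingFit:
    """One-site fit result: Kd, enthalpy, stoichiometry and diagnostics."""

    kd_nm: float
    dh_kj_mol: float
    n_stoich: float
    heat_offset_uj: float
    ok: bool = True
    message: str = ""
    rss: float = np.nan
    n_obs: int = 0
    cov: np.ndarray | None = field(default=None, repr=False)
    kd_se_nm: float = np.nan
    c_value: float = np.nan


def _bound_complex(p_tot_um: np.ndarray, l_tot_um: np.ndarray, kd_um: float) -> np.ndarray:
    """Equilibrium complex concentration from the one-site quadratic.

    [PL] = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / 2, the physical
    root of Kd = (P - PL)(L - PL)/PL.
    """
    b = p_tot_um + l_tot_um + kd_um
    disc = b * b - 4.0 * p_tot_um * l_tot_um
    return 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))


def itc_titration(
    kd_nm: float,
    dh_kj_mol: float,
    schedule: InjectionSchedule,
    n_stoich: float = 1.0,
    displacement: bool = True,
) -> pd.DataFrame:
    """Simulate the full titration state injection by injection.

    Dilution follows the displacement convention: each injection expels a
    matching volume of cell liquid at its pre-injection composition, so
    cell-species totals are scaled by (1 - v/V) while the titrant gains
    syringe material. ``n_stoich`` scales the protein's effective binding
    sites. The per-injection heat is the enthalpy times the change in
    complex amount inside the cell, net of complex carried out by the
    expelled volume.

    Returns a DataFrame with columns ``injection``, ``volume_ul``,
    ``protein_um``, ``ligand_um``, ``complex_um``, ``heat_uj``.
    """
    if kd_nm <= 0:
        raise ValueError("Kd must be positive")
    kd_um = kd_nm * 1e-3
    V = schedule.cell_volume_ul
    L = schedule.cell_ligand_um
    P = 0.0
    pl_prev = _bound_complex(np.float64(n_stoich * P), np.float64(L), kd_um)
    rows = []
    for i, v in enumerate(schedule.injection_volumes_ul, start=1):
        if displacement:
            d = 1.0 - v / V
            L *= d
            P = P * d + schedule.syringe_protein_um * v / V
        else:
            d = V / (V + v)
            L *= d
            P = P * d + schedule.syringe_protein_um * v / (V + v)
        pl = float(_bound_complex(np.float64(n_stoich * P), np.float64(L), kd_um))
        # uJ = (kJ/mol) * (ul * uM = 1e-12 mol) * 1e9 uJ/kJ
        heat = dh_kj_mol * V * (pl - pl_prev * d) * 1e-3
        rows.append(
            {
                "injection": i,
                "volume_ul": v,
                "protein_um": P,
                "ligand_um": L,
                "complex_um": pl,
                "heat_uj": heat,
            }
        )
        pl_prev = pl
    return pd.DataFrame(rows)


def itc_expected_heats(
    kd_nm: float,
    dh_kj_mol: float,
    schedule: InjectionSchedule,
    n_stoich: float = 1.0,
    displacement: bool = True,
) -> np.ndarray:
    """Noise-free per-injection heats (uJ) for the one-site model."""
    return itc_titration(
        kd_nm, dh_kj_mol, schedule, n_stoich=n_stoich, displacement=displacement
    )["heat_uj"].to_numpy()


def wiseman_c(kd_nm: float, schedule: InjectionSchedule) -> float:
    """Wiseman c-value: cell-species concentration over Kd.

    Governs how much curvature (hence Kd information) the isotherm carries;
    c well below 1 gives a featureless, low-information titration.
    """
    return schedule.cell_ligand_um / (kd_nm * 1e-3)


def fit_itc(
    isotherm: Isotherm,
    init: BindingFit | None = None,
    fix_n: float | None = None,
    first_injection_weight: float = 0.1,
    displacement: bool = True,
) -> BindingFit:
    """Least-squares one-site fit of an isotherm.

    Fits (Kd, dH, n, per-injection offset) by multi-start nonlinear least
    squares on log10(Kd); the first (conditioning) injection is
    down-weighted by default. ``fix_n`` pins the stoichiometry (e.g. 1.0).
    Never raises on non-convergence: a flagged fit is returned instead.
    Fits in a low-information regime (c-value < 1) are flagged with a wide
    Kd standard error.
    """
    sched = isotherm.schedule
    heats = isotherm.heats_uj
    if sched.n_injections < 8:
        raise ValueError("need at least 8 injections to fit four parameters")
    if not np.all(np.isfinite(heats)):
        raise ValueError("heats must be finite")

    w = np.ones_like(heats)
    w[0] = first_injection_weight
    sw = np.sqrt(w)

    # Enthalpy scale guess: if all ligand ended bound, total heat ~ dh*V*L0.
    dh0 = float(np.sum(heats) / (sched.cell_volume_ul * sched.cell_ligand_um * 1e-3))
    if dh0 == 0:
        dh0 = -1.0

    def model(theta: np.ndarray) -> np.ndarray:
        log_kd, dh, n, offset = theta
        n_eff = fix_n if fix_n is not None else n
        return (
            itc_expected_heats(
                10.0**log_kd, dh, sched, n_stoich=n_eff, displacement=displacement
            )
            + offset
        )

    def resid(theta: np.ndarray) -> np.ndarray:
        return sw * (model(theta) - heats)

    lb = [-3.0, -1e4, 0.05, -np.inf]
    ub = [6.0, 1e4, 20.0, np.inf]
    best = None
    for log_kd0 in (-1.0, 0.0, 1.0, 2.0, 3.0):
        theta0 = np.array([log_kd0, dh0, 1.0, 0.0])
        try:
            sol = least_squares(resid, theta0, bounds=(lb, ub), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return BindingFit(
            np.nan, np.nan, np.nan, np.nan, ok=False,
            message="no start converged", n_obs=len(heats),
        )

    log_kd, dh, n, offset = best.x
    kd_nm = float(10.0**log_kd)
    n_eff = float(fix_n) if fix_n is not None else float(n)
    rss = float(2.0 * best.cost)
    dof = max(len(heats) - (3 if fix_n is not None else 4), 1)
    s2 = rss / dof
    J = best.jac
    cov = None
    kd_se = np.nan
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        # delta method: kd = 10^log_kd
        kd_se = float(np.sqrt(cov[0, 0]) * np.log(10.0) * kd_nm)
    except np.linalg.LinAlgError:
        pass

    c = wiseman_c(kd_nm, sched)
    ok = True
    message = ""
    if c < 1.0 or not np.isfinite(kd_se) or kd_se > 0.5 * kd_nm:
        ok = False
        message = (
            f"low-information fit (c-value {c:.3g}, Kd SE {kd_se:.3g} nM): "
            "Kd poorly constrained, interpret the wide interval with care"
        )
    return BindingFit(
        kd_nm=kd_nm,
        dh_kj_mol=float(dh),
        n_stoich=n_eff,
        heat_offset_uj=float(offset),
        ok=ok,
        message=message,
        rss=rss,
        n_obs=len(heats),
        cov=cov,
        kd_se_nm=kd_se,
        c_value=float(c),
    )


@dataclass(frozen=True)
class EnzymeAssay:
    """Steady-state assay of a reductase following NADPH turnover at 340 nm.

    Concentrations: substrate (dihydrofolate) and cofactor in uM, inhibitor
    and its Ki in nM; rate units are delta-A340 per minute.
    """

    substrate_um: float = 50.0
    cofactor_um: float = 60.0
    km_um: float = 5.0
    ki_nm: float = 10.0
    vmax: float = 1.0

    def __post_init__(self) -> None:
        if self.substrate_um < 0 or self.cofactor_um < 0:
            raise ValueError("concentrations must be non-negative")
        if self.km_um <= 0 or self.ki_nm <= 0 or self.vmax <= 0:
            raise ValueError("Km, Ki and Vmax must be positive")


def inhibited_rate(assay: EnzymeAssay, inhibitor_nm: float | np.ndarray) -> np.ndarray:
    """Competitive-inhibition rate: v = Vmax*S / (Km*(1 + I/Ki) + S)."""
    I = np.asarray(inhibitor_nm, dtype=float)
    if np.any(I < 0):
        raise ValueError("inhibitor concentrations must be non-negative")
    S, Km, Ki = assay.substrate_um, assay.km_um, assay.ki_nm
    return assay.vmax * S / (Km * (1.0 + I / Ki) + S)


@dataclass
class Ic50Result:
    ic50_nm: float
    hill: float
    top: float
    ok: bool = True
    message: str = ""


def ic50_from_rates(inhibitor_nm: np.ndarray, rates: np.ndarray) -> Ic50Result:
    """IC50 from a rate-vs-inhibitor series via a log-logistic fit.

    Fits v = top / (1 + (I/ic50)^h) and reports the concentration at half
    the uninhibited rate. A series without a transition (rates essentially
    flat, or not crossing 50% inside the tested range) is returned flagged
    rather than extrapolated silently.
    """
    I = np.asarray(inhibitor_nm, dtype=float)
    v = np.asarray(rates, dtype=float)
    if I.size < 4:
        raise ValueError("need at least 4 inhibitor concentrations")
    if I.size != v.size:
        raise ValueError("inhibitor and rate vectors differ in length")
    span = v.max() - v.min()
    if span <= 1e-12 * max(abs(v.max()), 1.0):
        return Ic50Result(np.nan, np.nan, float(v.mean()), ok=False,
                          message="rates are constant: no transition to fit")

    top0 = float(v.max())
    pos = I[I > 0]
    ic0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0

    def resid(theta):
        log_ic50, h, top = theta
        with np.errstate(divide="ignore"):
            ratio = np.where(I > 0, I / 10.0**log_ic50, 0.0)
        return top / (1.0 + ratio**h) - v

    sol = least_squares(
        resid,
        np.array([np.log10(ic0), 1.0, top0]),
        bounds=([-6, 0.05, 0], [9, 20, np.inf]),
    )
    log_ic50, h, top = sol.x
    ic50 = float(10.0**log_ic50)
    ok = True
    message = ""
    if not (I[I > 0].min() <= ic50 <= I.max()):
        ok = False
        message = f"IC50 {ic50:.3g} nM lies outside the tested range (extrapolated)"
    if v.min() > 0.6 * top or v.max() < 0.4 * top:
        ok = False
        message = "rates do not bracket the 50% transition in the tested range"
    return Ic50Result(ic50, float(h), float(top), ok=ok, message=message)
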