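"""Synthetic data with known ground truth for every pipeline stage.

Generates TPP intensity cubes (TMT10-style: a 10-temperature ladder, two
conditions, replicated plexes, a minority of proteins with drug-induced
melt shifts, multiplicative log-normal channel noise, optional per-plex
batch offsets), single-temperature CETSA dose series, one-site ITC
isotherms, 5PL dose-viability tables, and annotated gene universes for
overrepresentation analysis. All generators are fully determined by their
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import InjectionSchedule, Isotherm, itc_expected_heats
from .doseresp import five_pl
from .tpp import IntensityCube

__all__ = [
    "LADDER",
    "LADDER_AS_PRINTED",
    "MeltModel",
    "SimConfig",
    "gen_tpp",
    "gen_cetsa",
    "gen_itc",
    "gen_doseresponse",
    "gen_ora_universe",
]

#: Default 10-point temperature ladder (degrees C). The protocol this
#: emulates lists 68.6 between 55.5 and 62, which breaks monotonicity and
#: is almost certainly a transposition of 58.6; the default uses the
#: monotone ladder, the literal one is available as LADDER_AS_PRINTED.
LADDER: tuple[float, ...] = (37.0, 40.4, 44.0, 46.9, 49.8, 52.9, 55.5, 58.6, 62.0, 66.3)
LADDER_AS_PRINTED: tuple[float, ...] = (
    37.0, 40.4, 44.0, 46.9, 49.8, 52.9, 55.5, 68.6, 62.0, 66.3,
)


@dataclass(frozen=True)
class MeltModel:
    """Per-protein melting model.

    Soluble fraction f(T) = plateau + (1 - plateau) / (1 + exp(slope*(T - tm))),
    a monotone-decreasing sigmoid with midpoint ``tm`` (degrees C), steepness
    ``slope`` (1/degrees C) and a non-melting residual ``plateau``. Under
    drug treatment the midpoint moves to ``tm + delta_tm`` (positive =
    stabilised, negative = destabilised).
    """

    tm: float
    slope: float
    plateau: float = 0.0
    delta_tm: float = 0.0
    base_abundance: float = 1e6

    def __post_init__(self) -> None:
        if not (0.0 <= self.plateau < 1.0):
            raise ValueError("plateau must lie in [0, 1)")
        if self.slope <= 0:
            raise ValueError("slope must be positive (melting steepens with T)")
        if self.base_abundance <= 0:
            raise ValueError("base abundance must be positive")

    def fraction(self, temperature_c, treated: bool = False) -> np.ndarray:
        """Soluble fraction at the given temperature(s)."""
        t_mid = self.tm + (self.delta_tm if treated else 0.0)
        T = np.asarray(temperature_c, dtype=float)
        return self.plateau + (1.0 - self.plateau) / (
            1.0 + np.exp(self.slope * (T - t_mid))
        )


@dataclass(frozen=True)
class SimConfig:
    """TPP simulation conditions.

    Defaults emulate one TMT10 thermal-profiling experiment: a 10-point
    ladder, treatment and vehicle arms, two replicate plexes, 5% of
    proteins stabilised (+4 C) and 2% destabilised (-4 C), 5% multiplicative
    channel noise, and no batch offsets unless given (``batch_effects`` maps
    a replicate label to a log2 offset applied to both arms of that plex).
    """

    n_proteins: int = 2000
    ladder: tuple[float, ...] = LADDER
    conditions: tuple[str, str] = ("treatment", "vehicle")
    n_replicates: int = 2
    frac_stabilized: float = 0.05
    frac_destabilized: float = 0.02
    delta_tm_stabilized: float = 4.0
    delta_tm_destabilized: float = -4.0
    noise_cv: float = 0.05
    batch_effects: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")
        if len(self.ladder) < 3:
            raise ValueError("ladder needs at least 3 temperatures")
        if len(set(self.ladder)) != len(self.ladder):
            raise ValueError("ladder temperatures must be distinct")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if min(self.frac_stabilized, self.frac_destabilized) < 0:
            raise ValueError("shifted fractions must be non-negative")
        if self.frac_stabilized + self.frac_destabilized > 1:
            raise ValueError("shifted fractions must sum to at most 1")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions (treatment, vehicle)")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the stated CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def gen_tpp(config: SimConfig) -> tuple[IntensityCube, pd.DataFrame]:
    """Simulate a TPP experiment with known per-protein ground truth.

    Intensity(p, channel) = base_abundance(p) * f_condition(T_channel)
    * noise * 2^batch_offset, where the treated curve uses tm + delta_tm
    for shifted proteins. Returns the raw cube and a truth table with the
    melt parameters and class label (stabilized / destabilized / null) of
    every protein.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]

    tm = rng.uniform(46.0, 56.0, n)
    slope = rng.uniform(0.25, 0.6, n)
    plateau = rng.uniform(0.0, 0.25, n)
    base = np.exp(rng.normal(np.log(1e6), 1.0, n))

    n_stab = int(round(config.frac_stabilized * n))
    n_dest = int(round(config.frac_destabilized * n))
    order = rng.permutation(n)
    labels = np.array(["null"] * n, dtype=object)
    delta = np.zeros(n)
    labels[order[:n_stab]] = "stabilized"
    delta[order[:n_stab]] = config.delta_tm_stabilized
    labels[order[n_stab:n_stab + n_dest]] = "destabilized"
    delta[order[n_stab:n_stab + n_dest]] = config.delta_tm_destabilized

    treatment, vehicle = config.conditions
    batch_effects = config.batch_effects or {}
    ladder = np.asarray(config.ladder, dtype=float)

    chan_rows = []
    data = {}
    for rep_i in range(1, config.n_replicates + 1):
        rep = f"r{rep_i}"
        offset = 2.0 ** batch_effects.get(rep, 0.0)
        for cond in (treatment, vehicle):
            treated = cond == treatment
            t_mid = tm + (delta if treated else 0.0)
            for temp in ladder:
                chan = f"{cond}_{rep}_T{temp:g}"
                frac = plateau + (1.0 - plateau) / (
                    1.0 + np.exp(slope * (temp - t_mid))
                )
                noise = _lognormal_factors(rng, config.noise_cv, n)
                data[chan] = base * frac * noise * offset
                chan_rows.append(
                    {
                        "channel": chan,
                        "temperature_c": temp,
                        "condition": cond,
                        "replicate": rep,
                        "batch": rep,
                    }
                )

    intensities = pd.DataFrame(data, index=proteins)
    channels = pd.DataFrame(chan_rows).set_index("channel")
    cube = IntensityCube(intensities, channels)
    truth = pd.DataFrame(
        {
            "protein": proteins,
            "tm": tm,
            "slope": slope,
            "plateau": plateau,
            "delta_tm": delta,
            "base_abundance": base,
            "class": labels,
        }
    ).set_index("protein")
    return cube, truth


def gen_cetsa(
    doses_nm,
    ec50_stab_nm: float = 10.0,
    max_effect: float = 3.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    drug: str = "drugA",
    context: str = "lineA",
    baseline_ratio: float = 1.0,
    loading_intensity: float = 1000.0,
) -> pd.DataFrame:
    """Simulate a fixed-temperature CETSA dose series.

    The target/loading band ratio follows a saturating one-site curve in
    dose: baseline at dose 0, rising towards baseline*max_effect with
    half-maximal stabilisation at ``ec50_stab_nm``. Returns a raw band
    table (drug, context, dose_nm, target, loading).
    """
    doses = np.asarray(doses_nm, dtype=float)
    if doses.size == 0:
        raise ValueError("empty dose list")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if ec50_stab_nm <= 0:
        raise ValueError("ec50 must be positive")
    rng = np.random.default_rng(seed)
    ratio = baseline_ratio * (1.0 + (max_effect - 1.0) * doses / (doses + ec50_stab_nm))
    loading = loading_intensity * _lognormal_factors(rng, noise_cv, doses.size)
    target = loading_intensity * ratio * _lognormal_factors(rng, noise_cv, doses.size)
    return pd.DataFrame(
        {
            "drug": drug,
            "context": context,
            "dose_nm": doses,
            "target": target,
            "loading": loading,
        }
    )


def gen_itc(
    kd_nm: float,
    dh_kj_mol: float = -40.0,
    schedule: InjectionSchedule | None = None,
    n_stoich: float = 1.0,
    noise_sd_uj: float | None = None,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> Isotherm:
    """Simulate a reverse-titration isotherm.

    Heats are the exact one-site model heats plus i.i.d. Gaussian noise.
    ``noise_sd_uj`` defaults to ``noise_frac`` (2%) of the largest expected
    injection heat, the scale of integration noise in a well-behaved run.
    """
    schedule = schedule or InjectionSchedule()
    rng = np.random.default_rng(seed)
    expected = itc_expected_heats(kd_nm, dh_kj_mol, schedule, n_stoich=n_stoich)
    if noise_sd_uj is None:
        scale = float(np.max(np.abs(expected)))
        noise_sd_uj = noise_frac * (scale if scale > 0 else 1.0)
    heats = expected + rng.normal(0.0, noise_sd_uj, expected.size)
    return Isotherm(schedule, heats)


def gen_doseresponse(
    ic50_nm: float,
    doses_nm=None,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    asym: float = 1.0,
    noise_cv: float = 0.05,
    n_replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a dose-viability titration around a 5PL curve.

    The curve is parameterised by its *relative* IC50 (midpoint between
    asymptotes); the underlying 5PL midpoint c_mid is derived from it.
    Default doses are 9 half-log steps spanning two decades either side of
    the IC50. Noise is multiplicative log-normal with the stated CV.
    """
    if ic50_nm <= 0:
        raise ValueError("IC50 must be positive")
    if top <= bottom:
        raise ValueError("top asymptote must exceed bottom")
    if doses_nm is None:
        doses_nm = ic50_nm * 10.0 ** np.arange(-2.0, 2.5, 0.5)
    doses = np.asarray(doses_nm, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    c_mid = ic50_nm / (2.0 ** (1.0 / asym) - 1.0) ** (1.0 / hill)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        mean = five_pl(doses, bottom, top, hill, c_mid, asym)
        resp = mean * _lognormal_factors(rng, noise_cv, doses.size)
        for d, r in zip(doses, resp):
            rows.append({"dose_nm": d, "response": r, "replicate": rep})
    return pd.DataFrame(rows)


def gen_ora_universe(
    n_universe: int = 1000,
    term_sizes: dict[str, int] | None = None,
    enriched_odds: dict[str, float] | None = None,
    hitlist_size: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], dict[str, float]]:
    """Simulate an annotated gene universe and a hit list.

    Each term annotates a random subset of the stated size. Hits are drawn
    without replacement with per-gene inclusion odds multiplied by
    ``enriched_odds[term]`` for every enriched term the gene belongs to
    (weighted reservoir sampling), so enriched terms are overrepresented
    among the hits. Returns (annotation table, hit list, truth odds).
    """
    if term_sizes is None:
        term_sizes = {"termA": 50, "termB": 100, "termC": 200}
    enriched_odds = enriched_odds or {}
    if hitlist_size > n_universe:
        raise ValueError("hit list cannot exceed the universe")
    for term, size in term_sizes.items():
        if size > n_universe:
            raise ValueError(f"term {term} larger than the universe")
    unknown = set(enriched_odds) - set(term_sizes)
    if unknown:
        raise ValueError(f"enriched terms not in term_sizes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_universe)])
    rows = []
    weights = np.ones(n_universe)
    for term, size in term_sizes.items():
        members = rng.choice(n_universe, size=size, replace=False)
        for m in members:
            rows.append({"gene": genes[m], "term": term})
        odds = enriched_odds.get(term, 1.0)
        if odds != 1.0:
            weights[members] *= odds
    annotation = pd.DataFrame(rows)
    # Efraimidis-Spirakis weighted sampling without replacement
    keys = rng.random(n_universe) ** (1.0 / weights)
    hits = list(genes[np.argsort(keys)[::-1][:hitlist_size]])
    return annotation, hits, dict(enriched_odds)
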