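"""Thermal proteome profiling (TPP) scoring pipeline.

A TPP experiment heats aliquots of drug- and vehicle-treated cells across a
temperature ladder and quantifies the remaining soluble protein per
temperature (one TMT channel each). Ligand binding shifts a target's
melting behaviour, which this pipeline detects as a *stability score*:

* abundance score  — mean log2 treatment/vehicle fold change at the two
  lowest (non-denaturing) temperatures; captures expression-level change;
* stability score  — sum over all ladder temperatures of the
  abundance-corrected log2 fold changes; positive = drug-stabilised,
  negative = destabilised.

Scores are computed per replicate, tested across replicates with a
moderated one-sample statistic (empirical-Bayes variance shrinkage across
proteins), FDR-adjusted, Z-transformed across the experiment, and
classified into hits and candidates. Melting curves per protein/condition
are fitted with a logistic-in-temperature model to report Tm and
drug-induced Tm shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from ._stats import moderated_onesample, zscore
from .scoring import bh_fdr

__all__ = [
    "IntensityCube",
    "MeltCurveFit",
    "read_cube",
    "normalize",
    "remove_batch",
    "log2fc",
    "abundance_score",
    "stability_score",
    "test_scores",
    "call_hits",
    "score_cube",
    "fit_melting",
    "melt_shift",
    "compare_profiles",
]

CHANNEL_COLS = ("temperature_c", "condition", "replicate", "batch")

#: Aliases recognised as the vehicle/control condition when not specified.
_VEHICLE_ALIASES = {"vehicle", "dmso", "control", "ctrl", "untreated"}


@dataclass
class IntensityCube:
    """Protein x TMT-channel intensities with channel metadata.

    ``intensities`` is proteins x channels; ``channels`` is indexed by
    channel id with columns temperature_c, condition, replicate, batch.
    Every (condition, replicate) pair must cover each ladder temperature
    exactly once (one TMT10 plex per pair).
    """

    intensities: pd.DataFrame
    channels: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        missing = set(CHANNEL_COLS) - set(self.channels.columns)
        if missing:
            raise ValueError(f"channel map missing columns: {sorted(missing)}")
        if not self.intensities.index.is_unique:
            dups = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate protein IDs: {list(dups[:5])}")
        if set(self.intensities.columns) != set(self.channels.index):
            raise ValueError("intensity columns and channel map disagree")
        # align column order to the channel map
        self.intensities = self.intensities[self.channels.index]
        if not self.log_scale and (self.intensities.to_numpy() < 0).any():
            raise ValueError("raw intensities must be non-negative")
        ladder = set(self.ladder)
        for (cond, rep), grp in self.channels.groupby(["condition", "replicate"]):
            temps = list(grp["temperature_c"])
            if len(temps) != len(set(temps)) or set(temps) != ladder:
                raise ValueError(
                    f"({cond}, {rep}) does not cover the ladder exactly once"
                )

    @property
    def ladder(self) -> np.ndarray:
        """Sorted unique ladder temperatures (degrees C)."""
        return np.sort(self.channels["temperature_c"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.channels["condition"].unique())

    def copy_with(self, intensities: pd.DataFrame, log_scale: bool) -> "IntensityCube":
        return IntensityCube(intensities, self.channels.copy(), log_scale=log_scale)

    def write(self, intensities_tsv, channels_tsv) -> None:
        self.intensities.rename_axis("protein").to_csv(intensities_tsv, sep="\t")
        self.channels.rename_axis("channel").to_csv(channels_tsv, sep="\t")


def read_cube(
    intensities_tsv,
    channels_tsv,
    min_unique_peptides: int = 2,
    peptide_column: str = "unique_peptides",
) -> IntensityCube:
    """Load an intensity matrix and channel map from TSV.

    The intensity table's first column is the protein ID; an optional
    ``unique_peptides`` column applies the low-evidence filter (rows with
    fewer than ``min_unique_peptides`` are dropped). Duplicate protein rows
    are dropped, keeping the first.
    """
    inten = pd.read_csv(intensities_tsv, sep="\t", index_col=0)
    chans = pd.read_csv(channels_tsv, sep="\t", index_col=0)
    if peptide_column in inten.columns:
        inten = inten[inten[peptide_column] >= min_unique_peptides]
        inten = inten.drop(columns=[peptide_column])
    inten = inten[~inten.index.duplicated(keep="first")]
    return IntensityCube(inten, chans)


def _glog2(x: np.ndarray, c: float) -> np.ndarray:
    """Generalised log2: log2((x + sqrt(x^2 + c^2)) / 2); plain log2 at c=0."""
    if c == 0:
        return np.log2(x)
    return np.log2(0.5 * (x + np.sqrt(x * x + c * c)))


def normalize(cube: IntensityCube, glog_c: float = 0.0) -> IntensityCube:
    """Per-temperature channel calibration followed by a glog2 transform.

    Each temperature is normalised independently (signal drops sharply at
    higher temperatures, so cross-temperature pooling would distort the
    calibration): every channel is rescaled through the origin so its
    median matches the cross-channel median target at that temperature,
    then glog2-transformed (plain log2 for ``glog_c=0``, the default, which
    keeps downstream fold changes exact). The transform is strictly
    increasing per channel, so within-channel protein ranks are preserved.
    """
    if cube.log_scale:
        raise ValueError("cube is already on the log scale")
    out = cube.intensities.astype(float).copy()
    for temp, grp in cube.channels.groupby("temperature_c"):
        cols = list(grp.index)
        if len(cols) < 2:
            raise ValueError(
                f"temperature {temp} has a single channel; cannot calibrate"
            )
        block = out[cols]
        med = block.median(axis=0)
        if (med <= 0).any():
            raise ValueError(f"non-positive channel median at {temp} C")
        target = float(med.median())
        out[cols] = block * (target / med)
    arr = out.to_numpy()
    if glog_c == 0 and (arr <= 0).any():
        raise ValueError("zero intensities present; use glog_c > 0")
    out = pd.DataFrame(_glog2(arr, glog_c), index=out.index, columns=out.columns)
    return cube.copy_with(out, log_scale=True)


def remove_batch(cube: IntensityCube) -> IntensityCube:
    """Remove additive batch offsets on the log2 scale.

    Per temperature, fits intensity ~ condition + batch by least squares
    across channels (batch coded as mean-centred indicators) and subtracts
    the fitted batch component, preserving condition means in balanced
    designs. Requires the batch structure to be identifiable: batches
    confounded with condition raise an error.
    """
    if not cube.log_scale:
        raise ValueError("remove_batch expects a normalized (log-scale) cube")
    batches = cube.channels["batch"]
    if batches.nunique() <= 1:
        return cube.copy_with(cube.intensities.copy(), log_scale=True)

    out = cube.intensities.copy()
    for temp, grp in cube.channels.groupby("temperature_c"):
        cols = list(grp.index)
        cond = pd.get_dummies(grp["condition"]).to_numpy(dtype=float)
        bat = pd.get_dummies(grp["batch"], drop_first=True).to_numpy(dtype=float)
        bat_centered = bat - bat.mean(axis=0, keepdims=True)
        X = np.hstack([cond, bat_centered])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"batch is confounded with condition at {temp} C; "
                "batch offsets are unidentifiable"
            )
        Y = out[cols].to_numpy().T  # channels x proteins
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        batch_part = bat_centered @ beta[cond.shape[1]:, :]
        out[cols] = (Y - batch_part).T
    return cube.copy_with(out, log_scale=True)


def _resolve_conditions(
    cube: IntensityCube, treatment: str | None, vehicle: str | None
) -> tuple[str, str]:
    conds = cube.conditions
    if treatment is not None and vehicle is not None:
        if not {treatment, vehicle} <= set(conds):
            raise ValueError(f"conditions {treatment!r}/{vehicle!r} not in cube {conds}")
        return treatment, vehicle
    if len(conds) != 2:
        raise ValueError(
            f"cannot infer treatment/vehicle from conditions {conds}; pass them"
        )
    veh = [c for c in conds if str(c).lower() in _VEHICLE_ALIASES]
    if len(veh) != 1:
        raise ValueError(
            f"cannot identify the vehicle among {conds}; pass treatment/vehicle"
        )
    vehicle = veh[0]
    treatment = next(c for c in conds if c != vehicle)
    return treatment, vehicle


def log2fc(
    cube: IntensityCube,
    treatment: str | None = None,
    vehicle: str | None = None,
) -> pd.DataFrame:
    """Per-protein log2 fold changes, treatment over vehicle.

    Replicate labels pair the treated channel to its vehicle channel at
    each temperature. Returns proteins x MultiIndex(temperature_c,
    replicate); positive values mean more soluble protein under treatment
    (stabilisation at denaturing temperatures).
    """
    if not cube.log_scale:
        raise ValueError("log2fc expects a normalized (log-scale) cube")
    treatment, vehicle = _resolve_conditions(cube, treatment, vehicle)
    ch = cube.channels
    reps_t = set(ch.loc[ch["condition"] == treatment, "replicate"])
    reps_v = set(ch.loc[ch["condition"] == vehicle, "replicate"])
    unpaired = reps_t ^ reps_v
    if unpaired:
        raise ValueError(f"unpaired replicate labels: {sorted(map(str, unpaired))}")

    pieces = {}
    for rep in sorted(reps_t, key=str):
        for temp in cube.ladder:
            sel_t = ch[(ch["condition"] == treatment) & (ch["replicate"] == rep)
                       & (ch["temperature_c"] == temp)].index[0]
            sel_v = ch[(ch["condition"] == vehicle) & (ch["replicate"] == rep)
                       & (ch["temperature_c"] == temp)].index[0]
            pieces[(temp, rep)] = cube.intensities[sel_t] - cube.intensities[sel_v]
    fc = pd.DataFrame(pieces)
    fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["temperature_c", "replicate"])
    return fc


def abundance_score(fc: pd.DataFrame) -> pd.DataFrame:
    """Mean log2 fold change at the two lowest ladder temperatures.

    Returns proteins x replicates. Captures drug-induced expression change
    uncontaminated by melting, since the two lowest temperatures do not
    denature.
    """
    temps = np.sort(fc.columns.get_level_values("temperature_c").unique())
    if temps.size < 2:
        raise ValueError("need at least 2 ladder temperatures")
    low = temps[:2]
    sub = fc.loc[:, fc.columns.get_level_values("temperature_c").isin(low)]
    return sub.T.groupby(level="replicate").mean().T


def stability_score(fc: pd.DataFrame, abundance: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sum over all ladder temperatures of abundance-corrected fold changes.

    Per protein and replicate: sum_T (fc_T - abundance). The algebraic
    identity ``sum_T fc_T = stability + n_temps * abundance`` holds exactly.
    """
    if abundance is None:
        abundance = abundance_score(fc)
    if not fc.index.equals(abundance.index):
        raise ValueError("fold-change and abundance tables cover different proteins")
    n_temps = fc.columns.get_level_values("temperature_c").nunique()
    total = fc.T.groupby(level="replicate").sum().T
    if not set(total.columns) == set(abundance.columns):
        raise ValueError("replicate labels of fc and abundance disagree")
    return total - n_temps * abundance[total.columns]


def test_scores(
    stability: pd.DataFrame,
    abundance: pd.DataFrame | None = None,
    fdr_method: str = "bh",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated significance testing of per-replicate scores.

    Tests each protein's replicate stability scores against zero with a
    moderated one-sample statistic (variances shrunk across proteins),
    two-sided p, FDR column (Benjamini-Hochberg by default, or an
    empirical half-normal-null estimate with ``fdr_method="empirical"``),
    and an experiment-wide Z-transform of the mean stability score.
    """
    if stability.shape[1] < 2:
        raise ValueError(
            "significance testing needs >= 2 replicates; "
            "re-run the experiment with replication"
        )
    res = moderated_onesample(stability.to_numpy(), prior_df=prior_df)
    table = pd.DataFrame(index=stability.index)
    table.index.name = "protein"
    table["stability_score"] = res["mean"]
    table["stat"] = res["stat"]
    table["p"] = res["p"]
    if fdr_method == "bh":
        table["fdr"] = bh_fdr(table["p"].to_numpy())
    elif fdr_method == "empirical":
        table["fdr"] = _empirical_fdr(table["stat"].to_numpy())
    else:
        raise ValueError("fdr_method must be 'bh' or 'empirical'")
    means = table["stability_score"].to_numpy()
    # degenerate (e.g. noise-free null) tables are all-zero: z is 0 there
    table["z"] = zscore(means) if means.std() > 0 else np.zeros_like(means)
    if abundance is not None:
        ab = moderated_onesample(abundance.loc[stability.index].to_numpy(),
                                 prior_df=prior_df)
        table.insert(0, "abundance_score", ab["mean"])
        table["abundance_stat"] = ab["stat"]
        table["abundance_p"] = ab["p"]
        table["abundance_fdr"] = bh_fdr(ab["p"])
    return table


def _empirical_fdr(stat: np.ndarray) -> np.ndarray:
    """Tail-area FDR against an empirical half-normal null.

    The null scale is estimated robustly from the central mass of the
    statistic distribution (median absolute statistic over the normal
    quartile), then BH is applied to the empirical-null p-values.
    """
    scale = np.median(np.abs(stat)) / stats.norm.ppf(0.75)
    if scale == 0:
        return np.ones_like(stat, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(stat) / scale)
    return bh_fdr(p)


def call_hits(
    table: pd.DataFrame, fdr_hit: float = 0.01, fdr_candidate: float = 0.05
) -> pd.DataFrame:
    """Classify proteins by FDR: hit, candidate, or not_significant.

    The stability score's sign carries the direction (stabilised vs
    destabilised); the class depends on the FDR alone.
    """
    if not (0 < fdr_hit <= fdr_candidate <= 1):
        raise ValueError("require 0 < fdr_hit <= fdr_candidate <= 1")
    out = table.copy()
    fdr = out["fdr"]
    out["class"] = np.where(
        fdr <= fdr_hit, "hit", np.where(fdr <= fdr_candidate, "candidate", "not_significant")
    )
    return out


def score_cube(
    cube: IntensityCube,
    treatment: str | None = None,
    vehicle: str | None = None,
    fdr_hit: float = 0.01,
    fdr_candidate: float = 0.05,
    fdr_method: str = "bh",
    glog_c: float = 0.0,
) -> pd.DataFrame:
    """Full pipeline from raw cube to classified stability table."""
    norm = normalize(cube, glog_c=glog_c)
    norm = remove_batch(norm)
    fc = log2fc(norm, treatment=treatment, vehicle=vehicle)
    ab = abundance_score(fc)
    st = stability_score(fc, ab)
    table = test_scores(st, abundance=ab, fdr_method=fdr_method)
    return call_hits(table, fdr_hit=fdr_hit, fdr_candidate=fdr_candidate)


@dataclass
class MeltCurveFit:
    """Logistic melting-curve fit for one protein in one condition."""

    tm: float
    slope: float
    plateau: float
    r2: float
    fractions: pd.Series = field(repr=False)
    ok: bool = True
    message: str = ""


def _melt_curve(T: np.ndarray, tm: float, slope: float, plateau: float) -> np.ndarray:
    return plateau + (1.0 - plateau) / (1.0 + np.exp(slope * (T - tm)))


def fit_melting(
    cube: IntensityCube, protein: str, condition: str
) -> MeltCurveFit:
    """Fit the logistic melt model to one protein's soluble-fraction profile.

    The per-temperature soluble fraction is the replicate-averaged (linear)
    intensity scaled to the lowest ladder temperature = 1. Non-convergent
    or non-sigmoidal profiles return a flagged fit with diagnostics rather
    than raising. Tm shifts are obtained as tm(treatment) - tm(vehicle)
    via :func:`melt_shift`.
    """
    if protein not in cube.intensities.index:
        raise ValueError(f"protein {protein!r} not in cube")
    if condition not in cube.conditions:
        raise ValueError(f"condition {condition!r} not in cube")
    ladder = cube.ladder
    if ladder.size < 4:
        raise ValueError("need at least 4 ladder temperatures to fit a melt curve")

    ch = cube.channels
    vals = {}
    for temp in ladder:
        cols = ch[(ch["condition"] == condition) & (ch["temperature_c"] == temp)].index
        v = cube.intensities.loc[protein, cols].to_numpy(dtype=float)
        vals[temp] = np.mean(2.0**v) if cube.log_scale else np.mean(v)
    frac = pd.Series(vals).sort_index()
    if frac.iloc[0] <= 0:
        raise ValueError("non-positive intensity at the lowest temperature")
    frac = frac / frac.iloc[0]
    T = frac.index.to_numpy(dtype=float)
    y = frac.to_numpy()

    def resid(theta):
        return _melt_curve(T, *theta) - y

    lb = [T.min() - 10.0, 1e-3, 0.0]
    ub = [T.max() + 10.0, 5.0, 1.0 - 1e-9]
    best = None
    for tm0 in np.quantile(T, (0.25, 0.5, 0.75)):
        for s0 in (0.1, 0.3, 1.0):
            try:
                sol = least_squares(resid, np.clip([tm0, s0, 0.05], lb, ub),
                                    bounds=(lb, ub))
            except Exception:  # pragma: no cover
                continue
            if best is None or sol.cost < best.cost:
                best = sol

    tss = float(np.sum((y - y.mean()) ** 2))
    if best is None:
        return MeltCurveFit(np.nan, np.nan, np.nan, np.nan, frac, ok=False,
                            message="no start converged")
    tm, slope, plateau = best.x
    rss = float(2.0 * best.cost)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    ok = True
    message = ""
    amplitude = y.max() - y.min()
    if amplitude < 0.2 or (1.0 - plateau) < 0.2:
        ok = False
        message = f"non-sigmoidal profile (amplitude {amplitude:.3f}); Tm unreliable"
    elif tss > 0 and r2 < 0.8:
        ok = False
        message = f"poor fit (R^2 = {r2:.3f})"
    return MeltCurveFit(float(tm), float(slope), float(plateau), r2, frac,
                        ok=ok, message=message)


def melt_shift(
    cube: IntensityCube,
    protein: str,
    treatment: str | None = None,
    vehicle: str | None = None,
) -> tuple[float, MeltCurveFit, MeltCurveFit]:
    """Drug-induced Tm shift: tm(treatment) - tm(vehicle) for one protein."""
    treatment, vehicle = _resolve_conditions(cube, treatment, vehicle)
    fit_t = fit_melting(cube, protein, treatment)
    fit_v = fit_melting(cube, protein, vehicle)
    return fit_t.tm - fit_v.tm, fit_t, fit_v


def compare_profiles(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    suffixes: tuple[str, str] = ("_a", "_b"),
) -> pd.DataFrame:
    """Join two stability tables on shared proteins for cross-experiment comparison.

    Z-scores are recomputed within each experiment *before* joining, so the
    joined columns are comparable even if the experiments differ in overall
    effect scale (e.g. different cell lines or compounds).
    """
    shared = table_a.index.intersection(table_b.index)
    if shared.empty:
        raise ValueError("no shared proteins between the two tables")
    a = table_a.copy()
    b = table_b.copy()
    a["z"] = zscore(a["stability_score"].to_numpy())
    b["z"] = zscore(b["stability_score"].to_numpy())
    return a.loc[shared].join(b.loc[shared], lsuffix=suffixes[0], rsuffix=suffixes[1])
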