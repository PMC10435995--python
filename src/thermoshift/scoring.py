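"""Self-contained scoring utilities.

Binomial overrepresentation analysis (ORA) with Benjamini-Hochberg FDR,
Tversky similarity over maximum-common-substructure atom counts, and the
two HADDOCK score linear combinations (rigid-body and refinement stages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OraResult",
    "binomial_ora",
    "ora_table",
    "bh_fdr",
    "tversky",
    "haddock_score",
    "HADDOCK_WEIGHTS",
]


@dataclass(frozen=True)
class OraResult:
    """Overrepresentation result for a single annotation term."""

    k: int  # hits annotated to the term
    n: int  # total hits
    K: int  # universe genes annotated to the term
    N: int  # universe size
    fold_enrichment: float
    p: float


def binomial_ora(
    k: int, n: int, K: int, N: int, underrepresentation: bool = False
) -> OraResult:
    """One-sided binomial overrepresentation test for one term.

    The hit list of size ``n`` is treated as ``n`` draws at the universe
    annotation rate ``K/N``; ``p`` is the upper-tail probability of observing
    at least ``k`` annotated hits (lower tail if ``underrepresentation``).
    Fold enrichment is the observed rate over the universe rate.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"require 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if not (n <= N and K <= N):
        raise ValueError(f"hit list and term must fit the universe (n={n}, K={K}, N={N})")
    if K == 0:
        raise ValueError("term annotates no universe genes (K=0): fold enrichment undefined")
    rate = K / N
    fold = (k / n) / rate
    alternative = "less" if underrepresentation else "greater"
    p = stats.binomtest(k, n, rate, alternative=alternative).pvalue
    return OraResult(k=k, n=n, K=K, N=N, fold_enrichment=fold, p=float(p))


def ora_table(
    annotation: pd.DataFrame,
    hits: list[str] | set[str],
    universe: list[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Run binomial ORA for every term in a gene->term annotation table.

    Parameters
    ----------
    annotation : DataFrame with columns ``gene`` and ``term``.
    hits : identifiers of the hit list (must be within the universe).
    universe : background gene set; defaults to all annotated genes.

    Returns a DataFrame with per-term counts, fold enrichment, binomial p
    and BH-adjusted FDR, sorted by p.
    """
    if not {"gene", "term"} <= set(annotation.columns):
        raise ValueError("annotation table needs 'gene' and 'term' columns")
    if universe is None:
        universe = set(annotation["gene"])
    else:
        universe = set(universe)
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hit list contains genes outside the universe")
    N, n = len(universe), len(hits)
    rows = []
    ann = annotation[annotation["gene"].isin(universe)]
    for term, members in ann.groupby("term")["gene"]:
        members = set(members)
        res = binomial_ora(len(members & hits), n, len(members), N)
        rows.append(
            {
                "term": term,
                "k": res.k,
                "n": n,
                "K": res.K,
                "N": N,
                "fold_enrichment": res.fold_enrichment,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tversky(
    mcs_atoms: float,
    only_target: float,
    only_template: float,
    alpha: float = 0.8,
    beta: float = 0.2,
) -> float:
    """Tversky similarity over maximum-common-substructure counts.

    ``s = mcs / (mcs + alpha*only_target + beta*only_template)``. The default
    weights bias the comparison towards the target compound (alpha=0.8)
    versus the template (beta=0.2). Whether the counts are atoms or
    atoms+bonds is the caller's convention; only consistency matters.
    """
    if min(mcs_atoms, only_target, only_template) < 0:
        raise ValueError("counts must be non-negative")
    if alpha < 0 or beta < 0 or alpha + beta == 0:
        raise ValueError("weights must be non-negative and not both zero")
    denom = mcs_atoms + alpha * only_target + beta * only_template
    if denom == 0:
        raise ValueError("all counts zero: similarity undefined")
    return mcs_atoms / denom


#: Linear weights (e_vdw, e_elec, e_desolv, e_air, bsa) per docking stage.
HADDOCK_WEIGHTS: dict[str, dict[str, float]] = {
    "rigid_body": {"e_vdw": 0.0, "e_elec": 1.0, "e_desolv": 1.0, "e_air": 0.01, "bsa": -0.01},
    "refinement": {"e_vdw": 1.0, "e_elec": 1.0, "e_desolv": 1.0, "e_air": 0.1, "bsa": -0.01},
}


def haddock_score(
    stage: str,
    e_vdw: float,
    e_elec: float,
    e_desolv: float,
    e_air: float,
    bsa: float,
) -> float:
    """HADDOCK score: stage-specific linear combination of energy terms.

    ``stage`` is ``"rigid_body"`` or ``"refinement"``. Terms are van der
    Waals, electrostatic and desolvation energies, the ambiguous-restraint
    energy, and the buried surface area (penalised).
    """
    try:
        w = HADDOCK_WEIGHTS[stage]
    except KeyError:
        raise ValueError(
            f"unknown stage {stage!r}; expected one of {sorted(HADDOCK_WEIGHTS)}"
        ) from None
    terms = {"e_vdw": e_vdw, "e_elec": e_elec, "e_desolv": e_desolv, "e_air": e_air, "bsa": bsa}
    for name, value in terms.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite energy term {name}={value}")
    return sum(w[name] * value for name, value in terms.items())
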