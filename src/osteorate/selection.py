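"""Likelihood-ratio-test plumbing for codon-model selection scans.

This module never fits codon models itself.  It consumes tables of
log-likelihoods produced upstream (codeml branch-site and clade-model-C /
M2a_ref fits, each run from three initial omega values) and provides:

* the LRT statistic 2*(lnL_alt - lnL_null), clamped at zero, with an
  upper-tail chi-square P value (df=1 for both tests here; the branch-site
  test may alternatively be referred to the 50:50 mixture of a point mass at
  zero and chi-square_1);
* a multi-start stability filter: a gene's model fit is trusted only when
  the three starts agree in log-likelihood to a tolerance;
* classification into positively selected (PSG, branch-site P < alpha) and
  divergently selected (DSG, CmC vs M2a_ref P < alpha and stable) genes,
  with a foreground-specific label requiring foreground omega2 > 1 and
  background omega1 < 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "LrtResult",
    "lrt",
    "stability_filter",
    "classify_selection",
    "STABILITY_TOL",
    "REQUIRED_STARTS",
]

#: log-likelihood units within which three starts count as "unchangeable"
STABILITY_TOL = 1e-2
#: the three initial omega values each model is run from
REQUIRED_STARTS = (0.5, 1.0, 1.5)
#: slack allowed before a null lnL exceeding the alternative triggers a warning
LNL_TOL = 1e-3


@dataclass
class LrtResult:
    gene_id: str
    statistic: float
    df: int
    p: float
    stable: bool = True
    classification: str = "none"


def lrt(lnl_alt: float, lnl_null: float, df: int = 1, mixture: bool = False):
    """LRT statistic and P value for nested model log-likelihoods.

    ``statistic = max(0, 2*(lnl_alt - lnl_null))``; ``p`` is the chi-square
    upper tail with ``df`` degrees of freedom.  ``mixture=True`` uses the
    50:50 mix of a point mass at 0 and chi-square_1 (appropriate when the
    null pins a parameter at the boundary), halving the tail probability for
    positive statistics.  A null likelihood exceeding the alternative by more
    than a small tolerance indicates an upstream optimization failure and is
    reported as a warning; the statistic is clamped to 0 either way.
    """
    if df < 1:
        raise InvalidInputError("df must be >= 1")
    delta = 2.0 * (lnl_alt - lnl_null)
    if delta < -2.0 * LNL_TOL:
        warnings.warn(
            f"null log-likelihood exceeds alternative by {-delta / 2:.4g}; "
            "upstream optimization likely failed — statistic clamped to 0",
            stacklevel=2,
        )
    statistic = max(0.0, delta)
    if mixture:
        if df != 1:
            raise InvalidInputError("mixture reference is defined for df=1")
        p = 0.5 * stats.chi2.sf(statistic, 1) if statistic > 0 else 1.0
    else:
        p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return statistic, float(p)


def stability_filter(
    records: pd.DataFrame, tol: float = STABILITY_TOL
) -> pd.DataFrame:
    """Per gene x model multi-start agreement check.

    ``records`` columns: gene, model, start_omega, loglik (plus optional
    omega1, omega2 carried through from the best start).  A gene x model is
    stable iff all three required starts are present and
    ``max(loglik) - min(loglik) <= tol``; the best-likelihood start's row is
    carried forward.  Returns one row per gene x model with columns gene,
    model, loglik, stable, reason and any omega columns.
    """
    need = {"gene", "model", "start_omega", "loglik"}
    if not need <= set(records.columns):
        raise InvalidInputError(f"records must have columns {sorted(need)}")
    extra = [c for c in records.columns if c not in need]
    out = []
    for (gene, model), grp in records.groupby(["gene", "model"], sort=False):
        starts = set(np.round(grp["start_omega"].astype(float), 6))
        row = grp.loc[grp["loglik"].idxmax()]
        rec = {"gene": gene, "model": model, "loglik": float(row["loglik"])}
        for c in extra:
            rec[c] = row[c]
        missing = set(REQUIRED_STARTS) - starts
        if missing:
            rec["stable"] = False
            rec["reason"] = f"missing starts: {sorted(missing)}"
        else:
            spread = float(grp["loglik"].max() - grp["loglik"].min())
            rec["stable"] = spread <= tol
            rec["reason"] = "" if rec["stable"] else f"loglik spread {spread:.4g} > {tol}"
        out.append(rec)
    return pd.DataFrame(out)


def classify_selection(
    fits: pd.DataFrame,
    alpha: float = 0.05,
    branch_site_mixture: bool = False,
    stability_tol: float = STABILITY_TOL,
) -> pd.DataFrame:
    """Classify genes as PSG / DSG from multi-start model-fit records.

    ``fits`` columns: gene, model in {branch_site_alt, branch_site_null,
    cmc, m2a_ref}, start_omega, loglik, and for the alternative models
    omega1 (background) and omega2 (foreground) where available.

    Per gene:

    * PSG when the branch-site LRT (alt vs null, df=1) has P < alpha;
    * DSG when the CmC vs M2a_ref LRT (df=1) has P < alpha and the CmC fit
      is start-stable;
    * ``divergent_foreground`` additionally requires the CmC foreground
      omega2 > 1 and background omega1 < 1 — the pattern of clade-specific
      divergent selection.

    Classification is invariant to record order; genes with missing model
    pairs are returned unclassified with a reason.
    """
    best = stability_filter(fits, tol=stability_tol)
    rows = []
    for gene, grp in best.groupby("gene", sort=False):
        by_model = {r["model"]: r for _, r in grp.iterrows()}
        rec = dict(
            gene=gene,
            psg=False, psg_p=np.nan, psg_stat=np.nan,
            dsg=False, dsg_p=np.nan, dsg_stat=np.nan,
            omega1=np.nan, omega2=np.nan,
            divergent_foreground=False, stable=True, reason="",
        )
        bs_ok = {"branch_site_alt", "branch_site_null"} <= by_model.keys()
        cm_ok = {"cmc", "m2a_ref"} <= by_model.keys()
        if not bs_ok and not cm_ok:
            rec["reason"] = "no complete model pair"
        if bs_ok:
            alt, nul = by_model["branch_site_alt"], by_model["branch_site_null"]
            stat, p = lrt(alt["loglik"], nul["loglik"], df=1, mixture=branch_site_mixture)
            stable = bool(alt["stable"] and nul["stable"])
            rec.update(psg_stat=stat, psg_p=p, psg=bool(p < alpha))
            rec["stable"] = rec["stable"] and stable
        if cm_ok:
            alt, nul = by_model["cmc"], by_model["m2a_ref"]
            stat, p = lrt(alt["loglik"], nul["loglik"], df=1)
            stable = bool(alt["stable"] and nul["stable"])
            o1 = float(alt.get("omega1", np.nan))
            o2 = float(alt.get("omega2", np.nan))
            rec.update(dsg_stat=stat, dsg_p=p, omega1=o1, omega2=o2,
                       dsg=bool(p < alpha and stable))
            rec["divergent_foreground"] = bool(rec["dsg"] and o2 > 1.0 and o1 < 1.0)
            rec["stable"] = rec["stable"] and stable
        if rec["psg"] and rec["dsg"]:
            rec["classification"] = "PSG+DSG"
        elif rec["psg"]:
            rec["classification"] = "PSG"
        elif rec["dsg"]:
            rec["classification"] = "DSG"
        else:
            rec["classification"] = "none"
        rows.append(rec)
    return pd.DataFrame(rows)
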