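"""RNA stability vs protein abundance: regression, concordance, pathway ANOVA.

Under the expectation that a transcript's steady-state protein output
tracks its mRNA stability, the module (i) regresses transformed protein
abundance on transformed stability index (ordinary least squares, default
log2-log2) with an extra-sum-of-squares F test of the slope against the
intercept-only model, (ii) extracts the concordant set of genes whose RNA
stability and protein abundance change in the same direction past
thresholds, and (iii) compares pathway-level pooled protein abundance
across groups by one-way ANOVA with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stability import CLASS_DESTABILIZED, CLASS_STABILIZED
from .synthesis import bh_adjust

__all__ = [
    "RegressionFit",
    "fit_stability_protein_regression",
    "concordant_set",
    "aggregate_pathway_compare",
]


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    F: float
    p: float
    n: int
    slope_se: float = float("nan")


_TRANSFORMS = {
    "log2": np.log2,
    "log10": np.log10,
    "identity": lambda v: v,
}


def fit_stability_protein_regression(
    stability_indices,
    protein_abundances,
    transform: str = "log2",
) -> RegressionFit:
    """OLS of transformed protein abundance on transformed stability index.

    F = (SS_null - SS_res) / (SS_res / (n - 2)) with SS_null the
    intercept-only residual sum of squares — the extra-sum-of-squares test
    of the slope; p is the F(1, n-2) upper tail.  ``transform`` applies to
    both variables ('log2' default, 'log10', 'identity').
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    f = _TRANSFORMS[transform]
    with np.errstate(divide="ignore", invalid="ignore"):
        x = f(np.asarray(stability_indices, dtype=float))
        y = f(np.asarray(protein_abundances, dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 paired observations after NA removal")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in predictor")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_null = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_null if ss_null > 0 else 1.0
    if ss_res == 0:
        F = np.inf if ss_null > ss_res else 0.0
        p = 0.0 if F > 0 else 1.0
        se = 0.0
    else:
        F = (ss_null - ss_res) / (ss_res / (n - 2))
        p = float(stats.f.sf(F, 1, n - 2))
        se = float(np.sqrt((ss_res / (n - 2)) / sxx))
    return RegressionFit(
        slope=float(slope), intercept=intercept, r_squared=float(r2),
        F=float(F), p=p, n=int(n), slope_se=se,
    )


def concordant_set(
    stability: pd.DataFrame,
    protein_changes: pd.Series,
    protein_min_change: float = 0.10,
) -> pd.DataFrame:
    """Genes whose RNA stability and protein abundance move together.

    ``protein_changes`` holds the relative change vs control
    ((case - control) / control) per gene.  A protein is called up/down
    when |change| >= protein_min_change (default 10%), unchanged otherwise.
    A gene is concordant when (destabilized and down) or (stabilized and
    up).  Genes absent from either table are skipped; the skip count is in
    ``DataFrame.attrs['n_missing']``.
    """
    if protein_min_change < 0:
        raise ValueError("protein_min_change must be >= 0")
    shared = stability.index.intersection(protein_changes.index)
    n_missing = len(stability.index) - len(shared)
    rows = []
    for g in shared:
        change = protein_changes[g]
        if not np.isfinite(change):
            n_missing += 1
            continue
        if change >= protein_min_change:
            direction = "up"
        elif change <= -protein_min_change:
            direction = "down"
        else:
            direction = "unchanged"
        cls = stability.loc[g, "class"]
        concordant = (cls == CLASS_DESTABILIZED and direction == "down") or (
            cls == CLASS_STABILIZED and direction == "up"
        )
        rows.append(
            {
                "gene_id": g,
                "stability_class": cls,
                "protein_change": float(change),
                "protein_direction": direction,
                "concordant": concordant,
            }
        )
    res = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "stability_class", "protein_change",
            "protein_direction", "concordant",
        ],
    )
    res.attrs["n_missing"] = n_missing
    return res


def concordance_summary(records: pd.DataFrame) -> dict:
    """Concordant-set size and its share of RNA and protein changes."""
    if records.empty:
        return {"n_concordant": 0, "frac_of_rna_changes": np.nan,
                "frac_of_protein_changes": np.nan}
    n_conc = int(records["concordant"].sum())
    rna_changed = records["stability_class"].isin(
        [CLASS_STABILIZED, CLASS_DESTABILIZED]
    ).sum()
    prot_changed = (records["protein_direction"] != "unchanged").sum()
    return {
        "n_concordant": n_conc,
        "frac_of_rna_changes": n_conc / rna_changed if rna_changed else np.nan,
        "frac_of_protein_changes": n_conc / prot_changed if prot_changed else np.nan,
    }


def aggregate_pathway_compare(
    protein_table: pd.DataFrame,
    pathways: dict[str, list[str]],
    groups: list[str],
    control: str,
) -> pd.DataFrame:
    """Pathway-level group comparison of pooled protein abundance.

    Each protein is normalized to its control-group mean (= 1); per sample
    (group, replicate) the normalized abundances of the pathway's proteins
    are averaged, and the per-sample values are compared across groups by
    one-way ANOVA, BH-adjusted over the pathways tested in the same call.

    Degenerate inputs: all values identical -> F = 0, p = 1; zero
    within-group variance with unequal means -> p = 0 with
    ``degenerate_variance`` flagged.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sub = protein_table[protein_table["group"].isin(groups)].copy()
    ctrl_mean = (
        protein_table[protein_table["group"] == control]
        .groupby("gene_id")["abundance"]
        .mean()
    )
    sub["norm"] = sub["abundance"] / sub["gene_id"].map(ctrl_mean)
    sub = sub[np.isfinite(sub["norm"])]

    rows = []
    for name, genes in pathways.items():
        path = sub[sub["gene_id"].isin(set(genes))]
        pooled = path.groupby(["group", "replicate"])["norm"].mean()
        samples = [pooled[g].to_numpy() for g in groups if g in pooled.index]
        if len(samples) < 2 or any(len(s) < 2 for s in samples):
            continue
        grand = np.concatenate(samples)
        means = {g: float(pooled[g].mean()) for g in groups if g in pooled.index}
        degenerate = False
        if np.ptp(grand) == 0:
            F, p = 0.0, 1.0
        else:
            within = sum(float(np.sum((s - s.mean()) ** 2)) for s in samples)
            if within == 0:
                F, p, degenerate = np.inf, 0.0, True
            else:
                res = stats.f_oneway(*samples)
                F, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "pathway_name": name,
                **{f"mean_{g}": means.get(g, np.nan) for g in groups},
                "F": F,
                "p": p,
                "degenerate_variance": degenerate,
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["q"] = bh_adjust(np.clip(res["p"].to_numpy(), np.nextafter(0, 1), 1.0))
    return res
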