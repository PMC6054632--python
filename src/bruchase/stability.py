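"""Per-transcript RNA stability indices and differential-stability calls.

The stability index of a transcript is the ratio of its labeled-RNA
abundance after the chase to its abundance at pulse end (RPKM at 6 h over
RPKM at 0.5 h).  Indices are computed per replicate from paired pulse/chase
libraries, summarized per condition by the median across replicates, and
compared between case and control as a ratio R.  A gene is called
stabilized when R >= fold_change_min (inclusive), destabilized when
R <= 1/fold_change_min, unchanged otherwise, and not_evaluable when any
required index is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_STABILIZED",
    "CLASS_DESTABILIZED",
    "CLASS_UNCHANGED",
    "CLASS_NOT_EVALUABLE",
    "StabilityConfig",
    "permutation_stability_fdr",
    "replicate_stability_index",
    "condition_stability",
    "differential_stability",
    "stability_analysis",
]

CLASS_STABILIZED = "stabilized"
CLASS_DESTABILIZED = "destabilized"
CLASS_UNCHANGED = "unchanged"
CLASS_NOT_EVALUABLE = "not_evaluable"


@dataclass
class StabilityConfig:
    fold_change_min: float = 1.5
    # guard against ratio blow-ups from near-zero pulse signal
    pulse_min_rpkm: float = 0.5
    t_chase: float = 6.0  # hours; only used for the model-derived half-life

    def validate(self) -> None:
        if self.fold_change_min <= 1:
            raise ValueError("fold_change_min must be > 1")
        if self.pulse_min_rpkm < 0:
            raise ValueError("pulse_min_rpkm must be >= 0")


def replicate_stability_index(
    expression: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    pulse_min_rpkm: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate stability index S = RPKM_chase / RPKM_pulse.

    Pulse and chase libraries are paired by (subject_id, replicate).  The
    index is NaN (not evaluable) wherever the pulse RPKM falls below
    ``pulse_min_rpkm``.

    Returns
    -------
    (S, pairs)
        ``S``: genes x pairs frame of indices; ``pairs``: one row per pair
        with columns pair_id, subject_id, replicate, group.
    """
    pulse = sample_sheet[sample_sheet["assay"] == "pulse"]
    chase = sample_sheet[sample_sheet["assay"] == "chase"]
    pulse_map = {
        (r.subject_id, r.replicate): r.library_id for r in pulse.itertuples()
    }
    orphans = [
        r.library_id
        for r in chase.itertuples()
        if (r.subject_id, r.replicate) not in pulse_map
    ]
    if orphans:
        raise ValueError(f"chase library(ies) without a pulse partner: {orphans}")

    cols = {}
    rows = []
    for r in chase.itertuples():
        pulse_lib = pulse_map[(r.subject_id, r.replicate)]
        p = expression[pulse_lib].to_numpy(dtype=float)
        c = expression[r.library_id].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(p >= max(pulse_min_rpkm, np.finfo(float).tiny), c / p, np.nan)
        pair_id = f"{r.subject_id}_rep{r.replicate}"
        cols[pair_id] = s
        rows.append(
            {
                "pair_id": pair_id,
                "subject_id": r.subject_id,
                "replicate": r.replicate,
                "group": r.group,
            }
        )
    S = pd.DataFrame(cols, index=expression.index)
    pairs = pd.DataFrame(rows)
    return S, pairs


def condition_stability(
    S: pd.DataFrame, pairs: pd.DataFrame, group: str
) -> pd.Series:
    """Condition-level index: median of evaluable replicate indices.

    For an even number of evaluable replicates this is the arithmetic mean
    of the two central values; genes with no evaluable replicate are NaN.
    """
    pair_ids = pairs.loc[pairs["group"] == group, "pair_id"]
    if pair_ids.empty:
        raise ValueError(f"no replicate pairs for group {group!r}")
    return S[list(pair_ids)].median(axis=1, skipna=True)


def differential_stability(
    s_case: pd.Series, s_control: pd.Series, fold_change_min: float = 1.5
) -> pd.DataFrame:
    """Case/control stability ratio and class per gene.

    R = S_case / S_control; stabilized iff R >= fold_change_min (the
    boundary is inclusive), destabilized iff R <= 1/fold_change_min,
    unchanged in between.  Genes with an undefined or zero-denominator
    index are not_evaluable.
    """
    if fold_change_min <= 1:
        raise ValueError("fold_change_min must be > 1")
    s_control = s_control.reindex(s_case.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s_control > 0, s_case / s_control, np.nan)
    ratio = pd.Series(ratio, index=s_case.index)
    cls = pd.Series(CLASS_UNCHANGED, index=s_case.index, dtype=object)
    cls[ratio >= fold_change_min] = CLASS_STABILIZED
    cls[ratio <= 1.0 / fold_change_min] = CLASS_DESTABILIZED
    cls[~np.isfinite(ratio)] = CLASS_NOT_EVALUABLE
    return pd.DataFrame({"ratio": ratio, "class": cls})


def permutation_stability_fdr(
    S: pd.DataFrame,
    pairs: pd.DataFrame,
    case: str,
    control: str,
    n_perm: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Optional extension: empirical FDR for differential-stability ratios.

    The fold-change rule carries no error model; this attaches one by
    shuffling group labels across subject/replicate pairs (group sizes
    preserved), recomputing the case/control ratio per permutation, and
    scoring p = (1 + #{|log R_perm| >= |log R_obs|}) / (1 + n_perm) per
    gene, BH-adjusted.  Off by default in the pipeline; results carry an
    ``extension`` flag in their column names to keep them distinct from
    the primary fold-change classification.
    """
    from .synthesis import bh_adjust

    rng = np.random.default_rng(seed)
    sub = pairs[pairs["group"].isin([case, control])].reset_index(drop=True)
    n_case = int((sub["group"] == case).sum())
    if n_case == 0 or n_case == len(sub):
        raise ValueError("both groups need at least one replicate pair")
    cols = list(sub["pair_id"])
    mat = S[cols]

    def ratio(case_cols, ctrl_cols):
        with np.errstate(divide="ignore", invalid="ignore"):
            return mat[case_cols].median(axis=1) / mat[ctrl_cols].median(axis=1)

    obs = ratio(
        list(sub.loc[sub["group"] == case, "pair_id"]),
        list(sub.loc[sub["group"] == control, "pair_id"]),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_stat = np.abs(np.log(obs))
    exceed = np.zeros(len(mat), dtype=float)
    valid = np.isfinite(obs_stat).to_numpy()
    for _ in range(n_perm):
        perm = rng.permutation(len(sub))
        case_cols = [cols[i] for i in perm[:n_case]]
        ctrl_cols = [cols[i] for i in perm[n_case:]]
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.abs(np.log(ratio(case_cols, ctrl_cols)))
        exceed += (stat.to_numpy() >= obs_stat.to_numpy() - 1e-12) & valid
    p = np.where(valid, (1.0 + exceed) / (1.0 + n_perm), np.nan)
    out = pd.DataFrame({"perm_p_extension": p}, index=mat.index)
    out["perm_q_extension"] = np.nan
    out.loc[valid, "perm_q_extension"] = bh_adjust(p[valid])
    return out


def stability_analysis(
    expression: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    case: str,
    control: str,
    config: StabilityConfig | None = None,
) -> pd.DataFrame:
    """Full stability workflow for one case/control contrast.

    Returns a gene_id-indexed frame with s_case, s_control, ratio, class
    and a model-derived half-life column per condition
    (t_half = -t_chase * ln(2) / ln(S), valid under first-order decay and
    exact up to library normalization).
    """
    config = config or StabilityConfig()
    config.validate()
    groups = set(sample_sheet["group"])
    for g in (case, control):
        if g not in groups:
            raise ValueError(f"group {g!r} not present in sample sheet")
    S, pairs = replicate_stability_index(
        expression, sample_sheet, config.pulse_min_rpkm
    )
    s_case = condition_stability(S, pairs, case)
    s_control = condition_stability(S, pairs, control)
    diff = differential_stability(s_case, s_control, config.fold_change_min)

    def model_half_life(s: pd.Series) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            hl = np.where(
                (s > 0) & (s < 1), -config.t_chase * np.log(2.0) / np.log(s), np.nan
            )
        return pd.Series(hl, index=s.index)

    out = pd.DataFrame(
        {
            "s_case": s_case,
            "s_control": s_control,
            "ratio": diff["ratio"],
            "class": diff["class"],
            "half_life_case_h": model_half_life(s_case),
            "half_life_control_h": model_half_life(s_control),
        }
    )
    out.index.name = "gene_id"
    return out


def class_counts(stability: pd.DataFrame) -> dict[str, int]:
    """Counts per stability class; values partition the gene universe."""
    counts = stability["class"].value_counts().to_dict()
    return {
        c: int(counts.get(c, 0))
        for c in (
            CLASS_STABILIZED,
            CLASS_DESTABILIZED,
            CLASS_UNCHANGED,
            CLASS_NOT_EVALUABLE,
        )
    }
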