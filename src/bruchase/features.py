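"""Transcript-feature association and 3'UTR motif enrichment.

Links stability to structural features of transcripts (length, 3'UTR
length, intron count) via Spearman correlation with a permutation p-value,
and tests whether RNA-binding-protein recognition motifs (IUPAC consensus,
RNA or DNA alphabet) are enriched in the 3'UTRs of stability-altered
transcripts relative to a background list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthesis import bh_adjust

__all__ = [
    "feature_association",
    "scan_motif",
    "motif_enrichment",
]

# IUPAC nucleotide codes over the DNA alphabet (U is normalized to T)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def feature_association(
    stability_values,
    feature_values,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Spearman association between stability and one transcript feature.

    Uses average ranks for ties; the permutation p-value is
    (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm) over random
    permutations of the feature vector.  Returns NaN statistics when either
    vector is constant after NA removal.
    """
    x = np.asarray(stability_values, dtype=float)
    y = np.asarray(feature_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 paired observations after NA removal")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return {"rho": np.nan, "p_perm": np.nan, "n": int(x.size)}
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    # Spearman rho is Pearson on ranks; precompute standardized ranks so
    # each permutation is a single dot product
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(zy)
        if abs(float(zx @ perm) / x.size) >= abs(rho) - 1e-12:
            hits += 1
    return {"rho": rho, "p_perm": (1 + hits) / (1 + n_perm), "n": int(x.size)}


def _encode(seq: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    try:
        return np.fromiter((_CODE[c] for c in s), dtype=np.int8, count=len(s))
    except KeyError as e:
        raise ValueError(f"invalid nucleotide symbol {e.args[0]!r}") from None


def _pattern_table(pattern: str) -> np.ndarray:
    """m x 5 boolean table; column 4 (N in sequence) never matches."""
    if not pattern:
        raise ValueError("empty motif pattern")
    pat = pattern.upper().replace("U", "T")
    table = np.zeros((len(pat), 5), dtype=bool)
    for i, c in enumerate(pat):
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {c!r} in motif")
        for b in IUPAC[c]:
            table[i, _CODE[b]] = True
    return table


def scan_motif(sequence: str, iupac_pattern: str) -> int:
    """Count matching start positions of an IUPAC motif; overlaps allowed.

    T and U are equivalent; an N in the sequence matches nothing.
    """
    table = _pattern_table(iupac_pattern)
    m = table.shape[0]
    codes = _encode(sequence)
    if codes.size < m:
        return 0
    ok = table[0, codes[: codes.size - m + 1]]
    for j in range(1, m):
        ok = ok & table[j, codes[j : codes.size - m + 1 + j]]
    return int(ok.sum())


def motif_enrichment(
    altered_genes,
    background_genes,
    utr3_seqs: dict[str, str],
    motifs: dict[str, str],
    min_seq_fraction: float = 0.8,
) -> pd.DataFrame:
    """Per-motif 3'UTR enrichment in altered vs background transcripts.

    Densities are hits per kb of pooled 3'UTR sequence per list (total-kb
    pooling avoids short-UTR instability); the primary test is a two-sided
    Fisher exact test on motif presence (gene has >= 1 hit) in altered vs
    background, BH-adjusted across motifs.  A per-gene Mann-Whitney U on
    densities is reported as a secondary statistic.
    """
    altered = [g for g in altered_genes if g in utr3_seqs]
    background = [g for g in background_genes if g in utr3_seqs]
    if not list(background_genes):
        raise ValueError("empty background list")
    for name, genes, avail in (
        ("altered", list(altered_genes), altered),
        ("background", list(background_genes), background),
    ):
        if genes and len(avail) / len(genes) < min_seq_fraction:
            raise ValueError(
                f"3'UTR sequences available for only {len(avail)}/{len(genes)} "
                f"{name} genes (need fraction >= {min_seq_fraction})"
            )

    kb_alt = sum(len(utr3_seqs[g]) for g in altered) / 1000.0
    kb_bg = sum(len(utr3_seqs[g]) for g in background) / 1000.0

    rows = []
    for motif_name, pattern in motifs.items():
        hits_alt = {g: scan_motif(utr3_seqs[g], pattern) for g in altered}
        hits_bg = {g: scan_motif(utr3_seqs[g], pattern) for g in background}
        present_alt = sum(1 for v in hits_alt.values() if v > 0)
        present_bg = sum(1 for v in hits_bg.values() if v > 0)
        table = [
            [present_alt, len(altered) - present_alt],
            [present_bg, len(background) - present_bg],
        ]
        odds, fisher_p = stats.fisher_exact(table, alternative="two-sided")
        dens_alt = [1000.0 * v / len(utr3_seqs[g]) for g, v in hits_alt.items()]
        dens_bg = [1000.0 * v / len(utr3_seqs[g]) for g, v in hits_bg.items()]
        if altered and background and (np.ptp(dens_alt + dens_bg) > 0):
            mw = stats.mannwhitneyu(dens_alt, dens_bg, alternative="two-sided")
            mw_p = float(mw.pvalue)
        else:
            mw_p = 1.0
        rows.append(
            {
                "motif_name": motif_name,
                "pattern": pattern,
                "density_altered": sum(hits_alt.values()) / kb_alt if kb_alt else 0.0,
                "density_background": sum(hits_bg.values()) / kb_bg if kb_bg else 0.0,
                "presence_odds_ratio": float(odds),
                "fisher_p": float(fisher_p),
                "mannwhitney_p": mw_p,
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["q"] = bh_adjust(
            np.clip(res["fisher_p"].to_numpy(), np.nextafter(0, 1), 1.0)
        )
    return res
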