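"""End-to-end orchestration: simulate/load -> quantify -> stability &
synthesis -> enrichment, features, concordance, with a machine-readable run
summary and a content manifest.

A run is driven by one YAML config (see :data:`DEFAULT_CONFIG` for the
shape and defaults).  All outputs are deterministic given (config, seed):
derived stage seeds come from the run seed, no timestamps enter any
artifact, and the manifest records a sha256 per output file.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .concordance import (
    aggregate_pathway_compare,
    concordance_summary,
    concordant_set,
    fit_stability_protein_regression,
)
from .enrichment import ora_analysis
from .features import feature_association, motif_enrichment
from .quantify import FilterConfig, apply_filters, compute_rpkm
from .simulate import (
    GroupSpec,
    SimulationConfig,
    simulate_experiment,
    simulate_protein_table,
    simulate_utr3_sequences,
)
from .stability import StabilityConfig, class_counts, stability_analysis
from .synthesis import synthesis_analysis

__all__ = ["DEFAULT_CONFIG", "DEFAULT_MOTIFS", "load_run_config", "run_pipeline"]

# Consensus recognition motifs for stress-granule-associated RBPs, written
# as IUPAC strings (RNA alphabet accepted; stored here as DNA).
DEFAULT_MOTIFS: dict[str, str] = {
    "TDP43_UG": "TGTGTG",
    "TIA1_Urich": "TTTTT",
    "FUS_GGUG": "GGTG",
    "HuR_ARE": "ATTTA",
    "PUM2": "TGTAHATA",
    "KHSRP_AU": "ATTTATTTA",
    "SRSF1_ESE": "GAAGAA",
    "QKI_QRE": "ACTAAY",
    "HNRNPC_U5": "TTTTC",
    "MBNL_YGCY": "YGCY",
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "bruchase_out",
    "case": "case",
    "control": "control",
    "filters": {
        "min_mean_rpkm": 0.5,
        "min_length_bp": 300,
        "synthesis_fdr_max": 0.1,
        "fold_change_min": 1.5,
    },
    "stability": {"fold_change_min": 1.5, "pulse_min_rpkm": 0.5},
    "enrichment_fdr": 0.05,
    "protein_min_change": 0.10,
    "feature_permutations": 500,
    "simulate": {
        "n_genes": 2000,
        "depth_pulse": 5_000_000,
        "depth_chase": 5_000_000,
        "t_pulse": 0.5,
        "t_chase": 6.0,
        "dispersion": 0.05,
        "half_life_log_median": 4.0,
        "half_life_log_sd": 0.7,
        "gene_sets": {
            "ribosome": 80,
            "oxphos": 60,
            "rna_transport": 50,
            "proteasome": 50,
            "glycolysis": 40,
        },
        "groups": [
            {"name": "control", "n_replicates": 4},
            {
                "name": "case",
                "n_replicates": 4,
                "k_multipliers": {"ribosome": 2.0, "oxphos": 2.0},
            },
        ],
        "planted_motif": {
            "motif": "TGTGTG",
            "density_per_kb": 0.5,
            "boost_fold": 3.0,
        },
        "protein": {
            "coupling_slope": 0.8,
            "noise_sd": 0.2,
            "n_replicates": 3,
            "decoupled_sets": ["ribosome"],
            "set_group_scale": {"oxphos": {"case": 0.7}},
        },
    },
    "motifs": dict(DEFAULT_MOTIFS),
}


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_run_config(path=None, overrides: dict | None = None) -> dict:
    """Merge DEFAULT_CONFIG <- YAML file <- explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        cfg = _deep_update(cfg, io.read_yaml(path) or {})
    if overrides:
        cfg = _deep_update(cfg, overrides)
    return cfg


def _sim_config_from_dict(sim: dict, seed: int) -> SimulationConfig:
    groups = [
        GroupSpec(
            name=g["name"],
            n_replicates=int(g.get("n_replicates", 4)),
            k_multipliers={k: float(v) for k, v in (g.get("k_multipliers") or {}).items()},
            alpha_multipliers={
                k: float(v) for k, v in (g.get("alpha_multipliers") or {}).items()
            },
        )
        for g in sim["groups"]
    ]
    return SimulationConfig(
        n_genes=int(sim["n_genes"]),
        groups=groups,
        t_pulse=float(sim["t_pulse"]),
        t_chase=float(sim["t_chase"]),
        depth_pulse=float(sim["depth_pulse"]),
        depth_chase=float(sim["depth_chase"]),
        half_life_log_median=float(sim["half_life_log_median"]),
        half_life_log_sd=float(sim["half_life_log_sd"]),
        dispersion=float(sim["dispersion"]),
        gene_sets={k: int(v) for k, v in sim["gene_sets"].items()},
        seed=seed,
    )


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(cfg: dict, output_dir=None) -> dict:
    """Execute every stage of the analysis; returns the run summary dict.

    Inputs come either from ``cfg['inputs']`` (paths to counts, samples,
    gene models, GMT, 3'UTR FASTA, motif table, protein table) or from the
    ``cfg['simulate']`` block.  Stage outputs, ``summary.json``,
    ``manifest.json`` and ``run.log`` land in the output directory.
    """
    cfg = _deep_update(DEFAULT_CONFIG, cfg)
    out = io.ensure_dir(output_dir or cfg["output_dir"])
    seed = int(cfg["seed"])
    case, control = cfg["case"], cfg["control"]
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    log(f"bruchase {__version__} run, seed={seed}, case={case}, control={control}")

    # ---- stage: inputs (simulate or load) ---------------------------------
    gene_sets: dict[str, list[str]]
    protein = None
    if "inputs" in cfg and cfg["inputs"]:
        paths = cfg["inputs"]
        counts = io.read_counts(paths["counts"])
        samples = io.read_sample_sheet(paths["samples"])
        gene_models = io.read_gene_models(paths["gene_models"])
        gene_sets = io.read_gmt(paths["gene_sets"]) if "gene_sets" in paths else {}
        utr3 = io.read_fasta(paths["utr3_fasta"]) if "utr3_fasta" in paths else {}
        if "motifs" in paths:
            mt = io.read_motif_table(paths["motifs"])
            motifs = dict(zip(mt["motif_name"], mt["pattern"]))
        else:
            motifs = dict(cfg["motifs"])
        if "protein" in paths:
            protein = io.read_protein_table(paths["protein"])
        truth = None
        log(f"loaded {counts.shape[0]} genes x {counts.shape[1]} libraries")
    else:
        sim = cfg["simulate"]
        sim_cfg = _sim_config_from_dict(sim, seed)
        ds = simulate_experiment(sim_cfg)
        counts, samples = ds.counts, ds.sample_sheet
        gene_models, gene_sets, truth = ds.gene_models, ds.gene_sets, ds.truth
        motifs = dict(cfg["motifs"])
        utr3 = ds.utr3_seqs
        prot_cfg = sim.get("protein")
        if prot_cfg:
            protein, _ = simulate_protein_table(
                truth,
                coupling_slope=float(prot_cfg["coupling_slope"]),
                noise_sd=float(prot_cfg["noise_sd"]),
                seed=seed + 1_000_003,
                n_replicates=int(prot_cfg["n_replicates"]),
                decoupled_sets=tuple(prot_cfg.get("decoupled_sets") or ()),
                gene_sets=gene_sets,
                set_group_scale=prot_cfg.get("set_group_scale"),
            )
        log(f"simulated {counts.shape[0]} genes x {counts.shape[1]} libraries")

    groups = set(samples["group"])
    for g in (case, control):
        if g not in groups:
            raise ValueError(f"configured group {g!r} not present in sample sheet")

    # planted motif enrichment happens after stability below when simulating;
    # regenerate UTRs with the spike once destabilized genes are known
    io.write_counts(counts, out / "counts.tsv")
    io.write_sample_sheet(samples, out / "samples.csv")
    io.write_gene_models(gene_models, out / "gene_models.tsv")
    if gene_sets:
        io.write_gmt(gene_sets, out / "gene_sets.gmt")
    if truth is not None:
        io.write_table(truth, out / "truth.tsv")
    io.write_yaml(cfg, out / "config.yaml")

    # ---- stage: quantify ---------------------------------------------------
    filt = FilterConfig(**cfg["filters"])
    expression = compute_rpkm(counts, gene_models)
    io.write_table(expression.reset_index(), out / "expression.tsv")
    pulse_libs = list(
        samples.loc[
            (samples["assay"] == "pulse") & samples["group"].isin([case, control]),
            "library_id",
        ]
    )
    kept = apply_filters(expression, gene_models, filt, pulse_libs)
    log(f"filters retained {len(kept)}/{expression.shape[0]} genes")

    # ---- stage: stability --------------------------------------------------
    stab_cfg = StabilityConfig(
        fold_change_min=float(cfg["stability"]["fold_change_min"]),
        pulse_min_rpkm=float(cfg["stability"]["pulse_min_rpkm"]),
        t_chase=float(cfg.get("simulate", {}).get("t_chase", 6.0)),
    )
    stability = stability_analysis(
        expression.loc[kept], samples, case, control, stab_cfg
    )
    io.write_table(stability.reset_index(), out / "stability.tsv")
    counts_by_class = class_counts(stability)
    n_changed = counts_by_class["stabilized"] + counts_by_class["destabilized"]
    log(
        f"stability: {n_changed} genes altered >= {stab_cfg.fold_change_min}-fold "
        f"({counts_by_class['destabilized']} destabilized, "
        f"{counts_by_class['stabilized']} stabilized)"
    )

    # simulate-mode: spike the first configured motif into destabilized UTRs
    if truth is not None and cfg["simulate"].get("planted_motif"):
        pm = cfg["simulate"]["planted_motif"]
        destab = set(stability.index[stability["class"] == "destabilized"])
        utr3 = simulate_utr3_sequences(
            gene_models["utr3_len_bp"],
            np.random.default_rng(seed + 2_000_003),
            motif=pm["motif"],
            density_per_kb=float(pm["density_per_kb"]),
            boosted_genes=destab,
            boost_fold=float(pm["boost_fold"]),
        )
    if utr3:
        io.write_fasta(utr3, out / "utr3.fasta")

    # ---- stage: synthesis --------------------------------------------------
    synthesis = synthesis_analysis(
        counts,
        samples,
        case,
        control,
        keep_genes=kept,
        fdr_max=filt.synthesis_fdr_max,
        fold_change_min=filt.fold_change_min,
    )
    io.write_table(synthesis.reset_index(), out / "synthesis.tsv")
    volcano = pd.DataFrame(
        {
            "gene_id": synthesis.index,
            "log2fc": synthesis["log2fc"],
            "neg_log10_q": -np.log10(synthesis["q"]),
        }
    )
    io.write_table(volcano, out / "synthesis_volcano.tsv")
    log(f"synthesis: {int(synthesis['passes'].sum())} genes pass FDR+FC selection")

    # ---- stage: enrichment -------------------------------------------------
    universe = stability.index[stability["class"] != "not_evaluable"]
    enr = {}
    if gene_sets:
        for direction in ("destabilized", "stabilized"):
            genes = stability.index[stability["class"] == direction]
            res = ora_analysis(genes, gene_sets, universe, float(cfg["enrichment_fdr"]))
            io.write_table(res, out / f"enrichment_{direction}.tsv")
            enr[direction] = res

    # ---- stage: features & motifs -----------------------------------------
    feats = []
    s_ctrl = stability["s_control"]
    for feat in ("length_bp", "utr3_len_bp", "intron_count"):
        assoc = feature_association(
            s_ctrl.to_numpy(),
            gene_models.loc[stability.index, feat].to_numpy(dtype=float),
            n_perm=int(cfg["feature_permutations"]),
            seed=seed + 3_000_017,
        )
        feats.append({"feature_name": feat, **assoc})
    features_df = pd.DataFrame(feats)
    io.write_table(features_df, out / "features.tsv")

    motif_res = None
    if utr3 and motifs:
        altered = [
            g
            for g in stability.index[
                stability["class"].isin(["stabilized", "destabilized"])
            ]
            if g in utr3
        ]
        background = [
            g for g in stability.index[stability["class"] == "unchanged"] if g in utr3
        ]
        if altered and background:
            motif_res = motif_enrichment(altered, background, utr3, motifs)
            io.write_table(motif_res, out / "motif_enrichment.tsv")

    # ---- stage: concordance ------------------------------------------------
    concord = None
    regression = {}
    pathway_cmp = None
    if protein is not None:
        prot_case = (
            protein[protein["group"] == case].groupby("gene_id")["abundance"].mean()
        )
        prot_ctrl = (
            protein[protein["group"] == control].groupby("gene_id")["abundance"].mean()
        )
        shared = stability.index.intersection(prot_case.index)
        evaluable = stability.loc[shared, "s_case"].notna()
        shared = shared[np.asarray(evaluable)]
        fit = fit_stability_protein_regression(
            stability.loc[shared, "s_case"].to_numpy(),
            prot_case[shared].to_numpy(),
        )
        regression["all"] = vars(fit)
        for set_name, members in gene_sets.items():
            idx = shared.intersection(pd.Index(members))
            if len(idx) >= 3:
                try:
                    fit = fit_stability_protein_regression(
                        stability.loc[idx, "s_case"].to_numpy(),
                        prot_case[idx].to_numpy(),
                    )
                    regression[set_name] = vars(fit)
                except ValueError:
                    pass
        with open(out / "regression.json", "w") as fh:
            json.dump(regression, fh, indent=2, sort_keys=True)

        rel_change = (prot_case - prot_ctrl) / prot_ctrl
        concord = concordant_set(
            stability, rel_change, float(cfg["protein_min_change"])
        )
        io.write_table(concord, out / "concordance.tsv")
        io.write_protein_table(protein, out / "protein.tsv")

        if gene_sets:
            pathway_cmp = aggregate_pathway_compare(
                protein, gene_sets, [control, case], control
            )
            io.write_table(pathway_cmp, out / "pathway_protein_anova.tsv")
        log(f"concordance: {concordance_summary(concord)['n_concordant']} genes")

    # ---- summary & manifest ------------------------------------------------
    summary = {
        "tool_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "case": case,
        "control": control,
        "n_genes_input": int(counts.shape[0]),
        "n_libraries": int(counts.shape[1]),
        "n_genes_filtered": int(len(kept)),
        "stability_class_counts": counts_by_class,
        "fraction_destabilized": (
            counts_by_class["destabilized"] / n_changed if n_changed else None
        ),
        "n_synthesis_pass": int(synthesis["passes"].sum()),
        "top_enriched_destabilized": (
            enr["destabilized"].head(3)[["set_name", "q"]].to_dict("records")
            if "destabilized" in enr and len(enr["destabilized"])
            else []
        ),
        "regression": regression,
        "concordance": concordance_summary(concord) if concord is not None else None,
        "feature_associations": features_df.to_dict("records"),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    manifest = {}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or not path.is_file():
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
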