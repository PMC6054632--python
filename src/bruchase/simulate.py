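"""Synthetic pulse-chase sequencing data with known kinetic ground truth.

The generator emulates a bromouridine metabolic-labeling experiment: nascent
RNA is labeled during a short pulse (default 0.5 h), then chased with excess
uridine (default 6 h) so that the surviving labeled RNA reflects decay.  Each
gene *i* follows first-order kinetics with constant synthesis rate ``alpha_i``
(copies/h) and decay rate ``k_i`` (1/h), so the labeled mass at pulse end is

    m_pulse = (alpha/k) * (1 - exp(-k * t_pulse))

and after the chase

    m_chase = m_pulse * exp(-k * t_chase).

Sequencing reads are drawn per library with expected count proportional to
labeled mass x transcript length (fragment-level sampling, so RPKM recovers
copy number), scaled to a target depth, with negative-binomial replicate
noise (variance mu + phi*mu^2).  Group-level effects are multiplicative on
``k`` and/or ``alpha`` per gene set, which plants pathway-structured
destabilization for end-to-end testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KineticGene",
    "GroupSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "expected_label_mass",
    "simulate_genes",
    "simulate_experiment",
    "simulate_utr3_sequences",
    "simulate_protein_table",
]

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class KineticGene:
    """Ground-truth generative parameters for one gene."""

    gene_id: str
    length_bp: int
    utr3_len_bp: int
    intron_count: int
    alpha: float  # synthesis rate, transcript copies per hour
    k: float  # first-order decay rate, 1/h
    dispersion: float = 0.05  # NB dispersion phi, variance = mu + phi*mu^2
    set_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.k <= 0:
            raise ValueError(f"{self.gene_id}: alpha and k must be > 0")
        if self.length_bp < 1:
            raise ValueError(f"{self.gene_id}: length_bp must be >= 1")
        if not 0 <= self.utr3_len_bp <= self.length_bp:
            raise ValueError(f"{self.gene_id}: 3'UTR longer than transcript")
        if self.intron_count < 0:
            raise ValueError(f"{self.gene_id}: negative intron_count")
        if self.dispersion < 0:
            raise ValueError(f"{self.gene_id}: negative dispersion")

    def half_life(self) -> float:
        return float(np.log(2.0) / self.k)


@dataclass
class GroupSpec:
    """One experimental group (e.g. control, C9ALS) and its planted effects.

    ``k_multipliers`` / ``alpha_multipliers`` map gene-set name -> strictly
    positive multiplier applied to every member gene's decay or synthesis
    rate in this group.  A destabilizing effect is a k multiplier > 1.
    """

    name: str
    n_replicates: int = 4
    k_multipliers: dict[str, float] = field(default_factory=dict)
    alpha_multipliers: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"group {self.name}: n_replicates must be >= 1")
        for d in (self.k_multipliers, self.alpha_multipliers):
            for s, m in d.items():
                if m <= 0:
                    raise ValueError(
                        f"group {self.name}: multiplier for set {s} must be > 0"
                    )


@dataclass
class SimulationConfig:
    """Parameters of one simulated pulse-chase experiment.

    Defaults mirror the labeling protocol (0.5 h pulse, 6 h chase) and a
    fibroblast-like design: two groups of four replicate subjects.  Decay
    rates are lognormal with median half-life 4 h (log-sd 0.7); replicate
    noise uses NB dispersion 0.05.
    """

    n_genes: int = 2000
    groups: list[GroupSpec] = field(
        default_factory=lambda: [GroupSpec("control"), GroupSpec("case")]
    )
    t_pulse: float = 0.5  # hours of BrU labeling
    t_chase: float = 6.0  # hours of uridine chase
    depth_pulse: float = 5e6  # expected reads per pulse library
    depth_chase: float = 5e6  # expected reads per chase library
    half_life_log_median: float = 4.0  # hours, median of lognormal half-life
    half_life_log_sd: float = 0.7  # sd of log half-life
    dispersion: float = 0.05  # NB dispersion phi (0 -> Poisson)
    gene_sets: dict[str, int] = field(
        default_factory=lambda: {
            "ribosome": 80,
            "oxphos": 60,
            "rna_transport": 50,
            "proteasome": 50,
            "glycolysis": 40,
        }
    )
    seed: int | None = None

    def validate(self) -> None:
        if self.t_pulse <= 0 or self.t_chase <= 0:
            raise ValueError("t_pulse and t_chase must be strictly positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.depth_pulse <= 0 or self.depth_chase <= 0:
            raise ValueError("library depths must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not self.groups:
            raise ValueError("at least one group required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        for g in self.groups:
            g.validate()
            for d in (g.k_multipliers, g.alpha_multipliers):
                for s in d:
                    if s not in self.gene_sets:
                        raise ValueError(
                            f"group {g.name} references unknown gene set {s!r}"
                        )
        if sum(self.gene_sets.values()) > self.n_genes:
            raise ValueError("gene sets larger than the gene universe")


@dataclass
class SyntheticDataset:
    """Everything one simulated experiment produces, with ground truth."""

    counts: pd.DataFrame  # genes x libraries, integer reads
    sample_sheet: pd.DataFrame  # library_id, subject_id, group, assay, replicate
    gene_models: pd.DataFrame  # gene_id-indexed lengths / UTRs / introns
    truth: pd.DataFrame  # per (gene, group): alpha, k, expected stability
    gene_sets: dict[str, list[str]]
    utr3_seqs: dict[str, str]
    protein: pd.DataFrame | None
    config: SimulationConfig

    def validate(self) -> None:
        libs = set(self.counts.columns)
        sheet_libs = list(self.sample_sheet["library_id"])
        if len(sheet_libs) != len(set(sheet_libs)):
            raise ValueError("duplicate library in sample sheet")
        if libs != set(sheet_libs):
            raise ValueError("count matrix and sample sheet disagree on libraries")
        genes = set(self.counts.index)
        if set(self.truth["gene_id"]) != genes:
            raise ValueError("truth table does not cover every gene")


def expected_label_mass(alpha, k, t_pulse, t_chase):
    """Expected labeled-RNA mass per gene at pulse end and chase end.

    Closed form of dL/dt = alpha - k*L during the pulse (L(0)=0) followed by
    dL/dt = -k*L during the chase.  Accepts scalars or broadcastable arrays.
    The k -> 0 limit is handled through expm1 so mass_pulse -> alpha*t_pulse
    without cancellation.

    Returns
    -------
    (mass_pulse, mass_chase) with mass_chase / mass_pulse = exp(-k*t_chase).
    """
    alpha = np.asarray(alpha, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be > 0")
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    if not np.all(np.isfinite(alpha)) or not np.all(np.isfinite(k)):
        raise ValueError("alpha and k must be finite")
    if t_pulse <= 0:
        raise ValueError("t_pulse must be > 0")
    if t_chase < 0:
        raise ValueError("t_chase must be >= 0")
    x = k * t_pulse
    # (1 - e^{-x})/x, with the x=0 limit equal to 1
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(x > 0, -np.expm1(-x) / np.where(x > 0, x, 1.0), 1.0)
    mass_pulse = alpha * t_pulse * frac
    mass_chase = mass_pulse * np.exp(-k * t_chase)
    if mass_pulse.ndim == 0:
        return float(mass_pulse), float(mass_chase)
    return mass_pulse, mass_chase


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, variance mu + phi*mu^2) counts; phi == 0 falls back to Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        size = 1.0 / phi[~pois]
        p = size / (size + mu[~pois])
        out[~pois] = rng.negative_binomial(size, p)
    return out


def simulate_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene kinetic parameters and structural features.

    Returns a frame indexed by gene_id with columns length_bp, utr3_len_bp,
    intron_count, alpha, k, dispersion, set_labels (tuple of set names).
    """
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    length = np.maximum(
        200, np.rint(rng.lognormal(np.log(1500.0), 0.6, n)).astype(int)
    )
    utr3 = np.rint(rng.lognormal(np.log(300.0), 0.5, n)).astype(int)
    utr3 = np.clip(utr3, 20, length)
    introns = rng.poisson(1.0 + length / 2000.0)
    half_life = rng.lognormal(np.log(config.half_life_log_median), config.half_life_log_sd, n)
    k = np.log(2.0) / half_life
    alpha = rng.lognormal(np.log(50.0), 1.0, n)

    labels: list[tuple[str, ...]] = [() for _ in range(n)]
    order = rng.permutation(n)
    pos = 0
    for set_name, size in config.gene_sets.items():
        for idx in order[pos : pos + size]:
            labels[idx] = labels[idx] + (set_name,)
        pos += size

    return pd.DataFrame(
        {
            "length_bp": length,
            "utr3_len_bp": utr3,
            "intron_count": introns,
            "alpha": alpha,
            "k": k,
            "dispersion": config.dispersion,
            "set_labels": labels,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _group_rates(
    genes: pd.DataFrame, group: GroupSpec, gene_sets: dict[str, list[str]]
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a group's multiplicative effects to per-gene alpha and k."""
    alpha = genes["alpha"].to_numpy(copy=True)
    k = genes["k"].to_numpy(copy=True)
    pos = {g: i for i, g in enumerate(genes.index)}
    for set_name, mult in group.k_multipliers.items():
        for g in gene_sets[set_name]:
            k[pos[g]] *= mult
    for set_name, mult in group.alpha_multipliers.items():
        for g in gene_sets[set_name]:
            alpha[pos[g]] *= mult
    return alpha, k


def simulate_experiment(
    config: SimulationConfig,
    seed: int | None = None,
    genes: pd.DataFrame | None = None,
) -> SyntheticDataset:
    """Simulate a full paired pulse/chase experiment.

    For library *j* in group *g*, the expected count of gene *i* is

        depth_j * m_ig * L_i / sum_h(m_hg * L_h)

    where ``m`` is the labeled mass at the library's timepoint (pulse or
    chase) under the group's effect-modified rates; realized counts are NB.
    Identical (config, seed) pairs reproduce identical datasets bit-for-bit.

    The truth table records, per (gene, group), the effective rates and the
    expected stability index

        exp(-k_ig * t_chase) * T_pulse_g / T_chase_g

    with T the total mass-times-length of the group's composition, i.e. the
    value the RPKM-ratio estimator converges to at infinite depth.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (argument or config.seed)")
    # gene-level parameters (the ground truth) follow the config's own seed
    # so that re-sampling noise with a different experiment seed leaves the
    # truth table identical; both streams are kept independent
    gene_seed = config.seed if config.seed is not None else seed
    gene_rng = np.random.default_rng([int(gene_seed), 17])
    rng = np.random.default_rng([int(seed), 29])
    if genes is None:
        genes = simulate_genes(config, gene_rng)
    else:
        required = {"length_bp", "utr3_len_bp", "intron_count", "alpha", "k",
                    "dispersion", "set_labels"}
        missing = required - set(genes.columns)
        if missing:
            raise ValueError(f"gene table missing column(s) {sorted(missing)}")
        if len(genes) != config.n_genes:
            raise ValueError("gene table size disagrees with config.n_genes")
    gene_ids = genes.index
    L = genes["length_bp"].to_numpy(dtype=float)
    phi = genes["dispersion"].to_numpy(dtype=float)

    gene_sets: dict[str, list[str]] = {s: [] for s in config.gene_sets}
    for g, labs in genes["set_labels"].items():
        for s in labs:
            gene_sets.setdefault(s, []).append(g)

    counts: dict[str, np.ndarray] = {}
    sheet_rows = []
    truth_rows = []
    for group in config.groups:
        alpha_g, k_g = _group_rates(genes, group, gene_sets)
        m_pulse, m_chase = expected_label_mass(
            alpha_g, k_g, config.t_pulse, config.t_chase
        )
        t_pulse_tot = float(np.sum(m_pulse * L))
        t_chase_tot = float(np.sum(m_chase * L))
        if t_pulse_tot <= 0 or t_chase_tot <= 0:
            raise ValueError(f"group {group.name}: zero total labeled mass")
        mu_pulse = config.depth_pulse * m_pulse * L / t_pulse_tot
        mu_chase = config.depth_chase * m_chase * L / t_chase_tot
        expected_s = np.exp(-k_g * config.t_chase) * t_pulse_tot / t_chase_tot
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "group": group.name,
                    "alpha": alpha_g,
                    "k": k_g,
                    "expected_stability": expected_s,
                }
            )
        )
        for rep in range(1, group.n_replicates + 1):
            subject = f"{group.name}_s{rep}"
            for assay, mu in (("pulse", mu_pulse), ("chase", mu_chase)):
                lib = f"{group.name}_r{rep}_{assay}"
                counts[lib] = _nb_sample(rng, mu, phi)
                sheet_rows.append(
                    {
                        "library_id": lib,
                        "subject_id": subject,
                        "group": group.name,
                        "assay": assay,
                        "replicate": rep,
                    }
                )

    count_df = pd.DataFrame(counts, index=gene_ids)
    sample_sheet = pd.DataFrame(sheet_rows)
    truth = pd.concat(truth_rows, ignore_index=True)
    gene_models = genes[["length_bp", "utr3_len_bp", "intron_count"]].copy()
    gene_models["strand"] = "+"

    utr3 = simulate_utr3_sequences(gene_models["utr3_len_bp"], rng)
    ds = SyntheticDataset(
        counts=count_df,
        sample_sheet=sample_sheet,
        gene_models=gene_models,
        truth=truth,
        gene_sets=gene_sets,
        utr3_seqs=utr3,
        protein=None,
        config=config,
    )
    ds.validate()
    return ds


def simulate_utr3_sequences(
    utr_lengths: pd.Series,
    rng: np.random.Generator,
    motif: str | None = None,
    density_per_kb: float = 0.5,
    boosted_genes: set[str] | frozenset[str] = frozenset(),
    boost_fold: float = 3.0,
) -> dict[str, str]:
    """Random 3'UTR sequences, optionally seeded with a planted motif.

    When ``motif`` is given, each gene receives Poisson(density_per_kb * kb)
    non-overlapping insertions of the motif at random positions; genes in
    ``boosted_genes`` receive ``boost_fold`` times that density.  The motif
    is written in the DNA alphabet (U -> T).
    """
    seqs: dict[str, str] = {}
    planted = motif.upper().replace("U", "T") if motif else None
    for gene_id, n in utr_lengths.items():
        n = int(n)
        seq = rng.choice(_NT, size=n)
        if planted and n >= len(planted):
            dens = density_per_kb * (boost_fold if gene_id in boosted_genes else 1.0)
            n_ins = rng.poisson(dens * n / 1000.0)
            for _ in range(n_ins):
                start = int(rng.integers(0, n - len(planted) + 1))
                seq[start : start + len(planted)] = list(planted)
        seqs[str(gene_id)] = "".join(seq)
    return seqs


def simulate_protein_table(
    truth: pd.DataFrame,
    coupling_slope: float = 0.8,
    noise_sd: float = 0.2,
    seed: int | None = None,
    n_replicates: int = 3,
    intercept_log2: float = 10.0,
    decoupled_sets: tuple[str, ...] = (),
    gene_sets: dict[str, list[str]] | None = None,
    set_group_scale: dict[str, dict[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein abundances coupled to the expected RNA stability index.

    log2 abundance = intercept + slope * log2(expected stability) + noise,
    per gene, group, and replicate.  Genes in ``decoupled_sets`` get slope 0
    (a "ribosome-like" buffered class whose protein level ignores RNA
    stability); ``set_group_scale`` multiplies abundances of a set's genes in
    a named group (planting an aggregate pathway-level shift).

    Returns (protein_table, slopes): a long table with columns gene_id,
    group, replicate, abundance, and a per-gene frame of the ground-truth
    slope actually used.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if (decoupled_sets or set_group_scale) and gene_sets is None:
        raise ValueError("gene_sets required when sets are referenced")
    rng = np.random.default_rng(seed)

    decoupled: set[str] = set()
    for s in decoupled_sets:
        decoupled.update(gene_sets[s])

    scale: dict[tuple[str, str], float] = {}
    if set_group_scale:
        for s, per_group in set_group_scale.items():
            for grp, mult in per_group.items():
                for g in gene_sets[s]:
                    scale[(g, grp)] = scale.get((g, grp), 1.0) * mult

    rows = []
    slope_rows = {}
    for _, rec in truth.iterrows():
        g, grp = rec["gene_id"], rec["group"]
        slope = 0.0 if g in decoupled else coupling_slope
        slope_rows[g] = slope
        base = intercept_log2 + slope * np.log2(rec["expected_stability"])
        mult = scale.get((g, grp), 1.0)
        for rep in range(1, n_replicates + 1):
            log2_ab = base + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "gene_id": g,
                    "group": grp,
                    "replicate": rep,
                    "abundance": mult * float(2.0**log2_ab),
                }
            )
    table = pd.DataFrame(rows)
    slopes = pd.DataFrame(
        {"gene_id": list(slope_rows), "true_slope": list(slope_rows.values())}
    )
    return table, slopes
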