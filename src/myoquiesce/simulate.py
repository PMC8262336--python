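"""Synthetic myometrial cohorts: NB counts, qPCR Ct values and clinical metadata.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline runs without any external download:

* negative-binomial gene x sample counts with a library-size log-normal,
  a batch log-fold effect, and a dispersion-mean trend alpha(mu) = a0/mu + a1;
* a planted quiescent (Q) vs nonquiescent (NQ) contrast affecting a
  configurable fraction of genes at |log2 FC| >= a floor, with the two
  calcium-transporter anchor genes always planted (ATP2B4 down in NQ,
  ATP2A2 up in NQ) and the qPCR reference genes (B2M, RPL30) always null;
* duplicate-well qPCR Ct values generated as Ct = c0 - log2(normalized
  expression) + noise, so the comparative 2^-dCt statistic recovers the
  planted per-sample expression ratio;
* clinical covariates drawn from phenotype-conditional distributions, with a
  configurable clinical/molecular mismatch rate (probability that a record's
  clinical presentation contradicts its molecular phenotype).

Randomness uses numpy's PCG64 generator; a fixed seed yields byte-identical
cohorts. The RNG algorithm name is recorded in the cohort's config echo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import (
    ANCHOR_DENOMINATOR,
    ANCHOR_NUMERATOR,
    REFERENCE_GENES,
    CountMatrix,
    GeneSetCollection,
)

RNG_ALGORITHM = "numpy.random.Generator(PCG64)"

PHENOTYPE_Q = "Q"
PHENOTYPE_NQ = "NQ"


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with cohort-scale defaults.

    Group sizes default to the reference design: 5 term-labor (molecularly NQ)
    + 5 term-not-in-labor (Q) + 21 preterm samples of which 4 are NQ and 17 Q.
    21% of genes carry a planted contrast of at least |log2 1.5|.
    """

    n_genes: int = 20000
    n_tl: int = 5
    n_tnl: int = 5
    n_ptb_nq: int = 4
    n_ptb_q: int = 17
    de_fraction: float = 0.21
    min_planted_lfc: float = math.log2(1.5)
    lfc_scale: float = 0.6  # exponential tail of |lfc| above the floor
    atp2b4_lfc: float = -1.5  # NQ vs Q
    atp2a2_lfc: float = 0.9
    atp2b4_base_mean: float = 1500.0  # quiescent-state anchor expression
    atp2a2_base_mean: float = 500.0  # baseline ratio 3.0 in Q samples
    dispersion_a0: float = 5.0
    dispersion_a1: float = 0.05
    log2_mean_loc: float = 8.0  # baseline log2 mean expression
    log2_mean_scale: float = 2.0
    min_base_mean: float = 10.0  # detection floor: only "detected" genes are simulated
    libsize_log_sd: float = 0.3  # natural-log sd of library size factors
    n_batches: int = 2
    batch_lfc_sd: float = 0.1  # per-gene log2 batch shift sd (non-reference batches)
    ct_intercept: float = 32.0  # Ct of one normalized count unit
    ct_noise_sd: float = 0.15  # per-well Ct replicate noise (cycles)
    n_wells: int = 2
    # clinical emission probabilities, conditional on the clinical state
    p_contraction2_laboring: float = 0.95
    p_contraction1_quiet: float = 0.1
    p_ruptured_laboring: float = 0.5
    p_ruptured_quiet: float = 0.1
    p_triplei_laboring: float = 0.4
    p_triplei_quiet: float = 0.1
    dilation_rate_laboring: float = 3.0  # Poisson mean above 1 cm
    dilation_p_quiet: float = 0.2
    mismatch_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.de_fraction, self.p_contraction2_laboring, self.p_contraction1_quiet,
            self.p_ruptured_laboring, self.p_ruptured_quiet, self.p_triplei_laboring,
            self.p_triplei_quiet, self.dilation_p_quiet, self.mismatch_rate,
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        sizes = (self.n_tl, self.n_tnl, self.n_ptb_nq, self.n_ptb_q)
        if any(n < 0 for n in sizes):
            raise ValueError("group sizes must be >= 0")
        if sum(sizes) == 0:
            raise ValueError("at least one group size must be positive")
        if self.n_genes < len(REFERENCE_GENES) + 2:
            raise ValueError("n_genes too small to hold anchors and reference genes")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["rng_algorithm"] = RNG_ALGORITHM
        return out


@dataclass
class SyntheticCohort:
    """A simulated cohort bundle with its ground truth."""

    counts: CountMatrix
    samples: pd.DataFrame  # metadata + latent truth columns
    ct: pd.DataFrame
    gene_truth: pd.DataFrame  # gene, base_mean, true_lfc, is_de, dispersion
    config: SimulationConfig


def _gene_names(n_genes: int) -> list[str]:
    width = max(5, len(str(n_genes)))
    names = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    special = [ANCHOR_NUMERATOR, ANCHOR_DENOMINATOR, *REFERENCE_GENES]
    names[: len(special)] = special
    return names


def _sample_design(config: SimulationConfig) -> pd.DataFrame:
    arms, phenos = [], []
    arms += ["TL"] * config.n_tl + ["TNL"] * config.n_tnl
    phenos += [PHENOTYPE_NQ] * config.n_tl + [PHENOTYPE_Q] * config.n_tnl
    arms += ["PTB"] * (config.n_ptb_nq + config.n_ptb_q)
    phenos += [PHENOTYPE_NQ] * config.n_ptb_nq + [PHENOTYPE_Q] * config.n_ptb_q
    n = len(arms)
    ids = [f"MY{i:02d}" for i in range(1, n + 1)]
    # term samples share the first batch (single-batch reference design);
    # preterm samples cycle through all batches
    batches = []
    ptb_counter = 0
    for arm in arms:
        if arm == "PTB" and config.n_batches > 1:
            batches.append(f"B{ptb_counter % config.n_batches + 1}")
            ptb_counter += 1
        else:
            batches.append("B1")
    return pd.DataFrame({
        "sample_id": ids, "arm": arms, "true_phenotype": phenos, "batch": batches,
    })


def simulate_counts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the count matrix; returns (counts, sample truth, gene truth).

    Counts are NB with mean s_j * q_i * 2^(lfc_i * z_j) * 2^(batch shift) and
    gene-wise dispersion alpha(q_i) = a0/q_i + a1, where z_j is the latent
    NQ indicator. Exactly round(de_fraction * n_genes) genes carry
    |lfc| >= min_planted_lfc (the anchors are counted among them when the
    fraction allows; at de_fraction = 0 the anchors alone remain planted).
    Reference genes are never differentially expressed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    design = _sample_design(config)
    n = len(design)
    g = config.n_genes
    genes = _gene_names(g)

    base_mean = np.maximum(
        2.0 ** rng.normal(config.log2_mean_loc, config.log2_mean_scale, size=g),
        config.min_base_mean,
    )
    # anchors sit at fixed baseline expression so the ratio scale is stable;
    # reference genes are robustly detected housekeeping transcripts
    base_mean[0] = config.atp2b4_base_mean
    base_mean[1] = config.atp2a2_base_mean
    base_mean[2:4] = np.maximum(base_mean[2:4], 500.0)

    lfc = np.zeros(g)
    n_de = int(round(config.de_fraction * g))
    special = 4  # anchors + references occupy the first four slots
    if n_de > 0:
        n_extra = max(n_de - 2, 0)  # anchors count toward the planted total
        eligible = np.arange(special, g)
        chosen = rng.choice(eligible, size=min(n_extra, len(eligible)), replace=False)
        magnitudes = config.min_planted_lfc + rng.exponential(config.lfc_scale, size=len(chosen))
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        lfc[chosen] = signs * magnitudes
    # anchors are exempt from the lottery and always planted
    lfc[0] = config.atp2b4_lfc
    lfc[1] = config.atp2a2_lfc

    dispersion = config.dispersion_a0 / base_mean + config.dispersion_a1

    size_factor = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n))
    batch_levels = sorted(design["batch"].unique())
    batch_shift = {batch_levels[0]: np.zeros(g)}
    for b in batch_levels[1:]:
        batch_shift[b] = rng.normal(0.0, config.batch_lfc_sd, size=g)

    z = (design["true_phenotype"] == PHENOTYPE_NQ).to_numpy().astype(float)
    log2_mu = (
        np.log2(base_mean)[:, None]
        + lfc[:, None] * z[None, :]
        + np.stack([batch_shift[b] for b in design["batch"]], axis=1)
    )
    mu = (2.0 ** log2_mu) * size_factor[None, :]

    n_nb = 1.0 / dispersion
    p_nb = n_nb[:, None] / (n_nb[:, None] + mu)
    counts = rng.negative_binomial(n_nb[:, None], p_nb)

    cm = CountMatrix(genes, list(design["sample_id"]), counts, batch=list(design["batch"]))

    # planted within-sample anchor ratio (library size cancels; the zero-mean
    # batch shift is excluded: the planted ratio is the phenotype contrast)
    true_ratio = 2.0 ** (
        (np.log2(base_mean[0]) + lfc[0] * z) - (np.log2(base_mean[1]) + lfc[1] * z)
    )
    sample_truth = design.assign(true_size_factor=size_factor, true_ratio=true_ratio)

    gene_truth = pd.DataFrame({
        "gene": genes,
        "base_mean": base_mean,
        "true_lfc": lfc,
        "is_de": lfc != 0.0,
        "dispersion": dispersion,
    })
    return cm, sample_truth, gene_truth


def simulate_ct(
    true_log2_expr: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a duplicate-well Ct table from true log2 normalized expression.

    ``true_log2_expr`` is an assay x sample DataFrame of log2 normalized
    expression (library size removed). Each well's Ct is
    ``c0 - log2_expr + Normal(0, ct_noise_sd)``, so at zero noise the
    comparative 2^-dCt statistic equals the planted per-sample ratio exactly
    and doubling a gene's expression lowers its Ct by one cycle.
    """
    required = {ANCHOR_NUMERATOR, ANCHOR_DENOMINATOR}
    missing = required - set(true_log2_expr.index)
    if missing:
        raise ValueError(f"anchor gene(s) missing from expression table: {sorted(missing)}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for assay in true_log2_expr.index:
        for sample in true_log2_expr.columns:
            base_ct = config.ct_intercept - float(true_log2_expr.loc[assay, sample])
            for well in range(1, config.n_wells + 1):
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd > 0 else 0.0
                rows.append({
                    "sample_id": sample, "assay": assay, "well": well,
                    "ct": base_ct + noise,
                })
    return pd.DataFrame(rows)


def simulate_clinical(
    sample_truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw clinical covariates conditional on the latent molecular phenotype.

    Each sample's *clinical* laboring state equals its molecular phenotype
    flipped with probability ``mismatch_rate``; raw clinical fields are then
    emitted conditional on that clinical state. At mismatch_rate = 1 every
    clinically laboring record is molecularly quiescent and vice versa.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = sample_truth.copy()
    n = len(out)
    molecular_nq = (out["true_phenotype"] == PHENOTYPE_NQ).to_numpy()
    flip = rng.random(n) < config.mismatch_rate
    laboring = molecular_nq ^ flip

    term = out["arm"].isin(["TL", "TNL"]).to_numpy()
    ga = np.where(
        term,
        np.clip(rng.normal(39.5, 1.0, size=n), 37.3, 43.0),
        np.clip(rng.normal(29.0, 2.5, size=n), 16.5, 33.8),
    ).round(1)

    contractions = np.where(
        laboring,
        np.where(rng.random(n) < config.p_contraction2_laboring,
                 "regular_with_cervical_change", "irregular_or_receded"),
        np.where(rng.random(n) < config.p_contraction1_quiet,
                 "irregular_or_receded", "absent"),
    )
    dilation = np.where(
        laboring,
        np.minimum(10, 1 + rng.poisson(config.dilation_rate_laboring, size=n)),
        (rng.random(n) < config.dilation_p_quiet).astype(int),
    )
    ruptured = np.where(
        laboring,
        rng.random(n) < config.p_ruptured_laboring,
        rng.random(n) < config.p_ruptured_quiet,
    )
    membranes = np.where(ruptured, "ruptured", "intact")
    # Triple I was only assessed in preterm deliveries; term records are unknown
    triplei_drawn = np.where(
        laboring,
        rng.random(n) < config.p_triplei_laboring,
        rng.random(n) < config.p_triplei_quiet,
    )
    triple_i = np.where(term, "unknown",
                        np.where(triplei_drawn, "suspected_or_confirmed", "absent"))

    spontaneous = np.where(term, out["arm"] == "TL", laboring | ruptured)
    provider = ~spontaneous

    out["group"] = np.where(term, out["arm"], "PTB")
    out["ga_weeks"] = ga
    out["contractions_raw"] = contractions
    out["dilation_cm"] = dilation.astype(int)
    out["membranes"] = membranes
    out["triple_i"] = triple_i
    out["spontaneous_onset"] = spontaneous.astype(bool)
    out["provider_initiated"] = provider.astype(bool)
    out["clinical_laboring"] = laboring.astype(bool)
    # reference (term) samples carry their phenotype label; preterm are unlabeled
    out["phenotype_label"] = np.where(term, out["true_phenotype"], "")
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort (counts + clinical metadata + qPCR Ct table)."""
    rng = np.random.default_rng(config.seed)
    counts, sample_truth, gene_truth = simulate_counts(config, rng)
    samples = simulate_clinical(sample_truth, config, rng)

    # true log2 normalized expression of the four assay genes
    assays = [ANCHOR_NUMERATOR, ANCHOR_DENOMINATOR, *REFERENCE_GENES]
    z = (samples["true_phenotype"] == PHENOTYPE_NQ).to_numpy().astype(float)
    rows = {}
    base = gene_truth.set_index("gene")
    batch_cols = samples["batch"].tolist()
    for assay in assays:
        # same per-sample true mean used by simulate_counts, minus the
        # library-size factor (normalized scale); the small zero-mean batch
        # shift is omitted so 2^-dCt targets the phenotype contrast
        rows[assay] = (
            np.log2(base.loc[assay, "base_mean"])
            + base.loc[assay, "true_lfc"] * z
        )
    expr = pd.DataFrame(rows, index=samples["sample_id"]).T
    ct = simulate_ct(expr, config, rng)
    return SyntheticCohort(counts=counts, samples=samples, ct=ct,
                           gene_truth=gene_truth, config=config)


def make_gene_sets(
    gene_truth: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    n_random: int = 20,
    set_size: int = 50,
    planted_size: int = 50,
) -> GeneSetCollection:
    """Build gene sets for enrichment testing from a simulated cohort's truth.

    Emits one coordinately-up set, one coordinately-down set (sampled from the
    planted contrast) and ``n_random`` random sets drawn from the whole gene
    universe.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    genes = gene_truth["gene"].to_numpy()
    lfc = gene_truth["true_lfc"].to_numpy()
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    up = genes[lfc > 0]
    down = genes[lfc < 0]
    if len(up) >= 2:
        k = min(planted_size, len(up))
        sets["PLANTED_UP"] = frozenset(rng.choice(up, size=k, replace=False))
        descriptions["PLANTED_UP"] = "genes planted up in NQ"
    if len(down) >= 2:
        k = min(planted_size, len(down))
        sets["PLANTED_DOWN"] = frozenset(rng.choice(down, size=k, replace=False))
        descriptions["PLANTED_DOWN"] = "genes planted down in NQ"
    for i in range(1, n_random + 1):
        name = f"RANDOM_{i:03d}"
        sets[name] = frozenset(rng.choice(genes, size=min(set_size, len(genes)), replace=False))
        descriptions[name] = "random gene set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
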