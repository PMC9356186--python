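"""Seeded synthetic data with the structure the pipeline assumes.

Three generators stand in for the experimental inputs:

* ``simulate_treatment_experiment`` — NB counts for CD4+ T cells under
  primary stimulation (PS) or restimulation (RS), untreated or treated with
  the CDK9 inhibitor NVP-2, plus a resting (unstimulated) baseline arm.
  NVP-2 applies a uniform log2 shift to every pol II gene plus an extra
  repression proportional to each gene's activation strength (stronger under
  RS), while pol I/III control transcripts are untouched — exactly the
  regime in which control-anchored (not total-count) normalization recovers
  the truth.
* ``simulate_cohort`` — log-scale (microarray-like) patient expression where
  signature genes are shifted upward in disease and further in anti-TNF
  non-responders; insensitive control genes carry no group shift. Clinical
  severity indices are weakly coupled to the per-sample shift.
* ``simulate_chip`` — TSS annotations, promoter-proximal peak intervals, and
  TSS-window read counts for resting/stimulated/input channels, where the
  stimulation-induced occupancy gain couples (negatively) to NVP-2
  repression.

All three are deterministic functions of (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_CONTROL_TRANSCRIPTS, CountMatrix

TREATMENT_ARMS = ("untreated-PS", "NVP2-PS", "untreated-RS", "NVP2-RS")
UNSTIMULATED_ARM = "unstimulated"


class ConfigurationError(ValueError):
    pass


@dataclass
class TreatmentSimConfig:
    """Study conditions for the treated/untreated RNA-seq simulation.

    Defaults mirror the experimental design: three donors per arm, NB
    dispersion 0.05, ~20% of genes induced by stimulation (log2FC 1-6), a
    global -1 log2 shift of pol II transcription under NVP-2, and an
    activation-coupled extra repression that is stronger during
    restimulation (coupling_rs < coupling_ps < 0).
    """

    seed: int = 1
    n_genes: int = 2000
    n_control: int = 31  # pol I/III stand-ins, named after the real anchors
    samples_per_arm: int = 3
    arms: tuple[str, ...] = TREATMENT_ARMS
    include_unstimulated: bool = True
    baseline_log_mean_range: tuple[float, float] = (3.0, 9.0)  # log2 mean counts
    dispersion: float | tuple[float, float] = 0.05
    frac_activated: float = 0.2
    activation_lfc_range: tuple[float, float] = (1.0, 6.0)
    coupling_ps: float = -0.3
    coupling_rs: float = -0.5
    global_repression_lfc: float = -1.0
    size_factor_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_control < 0 or self.samples_per_arm <= 0:
            raise ConfigurationError("dimensions must be positive")
        if self.samples_per_arm < 2:
            raise ConfigurationError("samples_per_arm must be >= 2")
        if not 0 <= self.frac_activated <= 1:
            raise ConfigurationError("frac_activated must be in [0, 1]")


@dataclass
class TreatmentTruth:
    genes: pd.DataFrame  # is_control, baseline, activation_lfc, treatment_lfc_ps/rs
    size_factors: pd.Series


def _control_ids(n: int) -> list[str]:
    ids = list(DEFAULT_CONTROL_TRANSCRIPTS[:n])
    ids += [f"CTRL{i:03d}" for i in range(len(ids), n)]
    return ids


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, alpha) with Var = mu + alpha mu^2 via gamma-Poisson mixing."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    lam = mean.copy()
    pos = alpha > 0
    if pos.any():
        lam[pos] = rng.gamma(1.0 / alpha[pos], alpha[pos] * mean[pos])
    return rng.poisson(lam)


def simulate_treatment_experiment(
    config: TreatmentSimConfig,
) -> tuple[CountMatrix, pd.DataFrame, TreatmentTruth]:
    """Generate counts, a sample design, and the generating truth."""
    rng = np.random.default_rng(config.seed)
    n_g, n_c = config.n_genes, config.n_control
    gene_ids = [f"G{i:05d}" for i in range(n_g)] + _control_ids(n_c)
    is_control = np.array([False] * n_g + [True] * n_c)

    lo, hi = config.baseline_log_mean_range
    baseline = rng.uniform(lo, hi, size=n_g + n_c)
    if isinstance(config.dispersion, tuple):
        alpha = rng.uniform(*config.dispersion, size=n_g + n_c)
    else:
        alpha = np.full(n_g + n_c, float(config.dispersion))

    activation = np.zeros(n_g + n_c)
    n_act = int(round(config.frac_activated * n_g))
    act_idx = rng.choice(n_g, size=n_act, replace=False)
    activation[act_idx] = rng.uniform(*config.activation_lfc_range, size=n_act)

    t_ps = np.where(is_control, 0.0, config.global_repression_lfc + config.coupling_ps * activation)
    t_rs = np.where(is_control, 0.0, config.global_repression_lfc + config.coupling_rs * activation)

    arms = list(config.arms)
    if config.include_unstimulated:
        arms = [UNSTIMULATED_ARM] + arms
    samples, arm_of = [], []
    for arm in arms:
        for r in range(config.samples_per_arm):
            samples.append(f"{arm}_r{r + 1}")
            arm_of.append(arm)
    s_true = rng.uniform(*config.size_factor_range, size=len(samples))

    counts = np.zeros((n_g + n_c, len(samples)), dtype=np.int64)
    for j, arm in enumerate(arm_of):
        stim = 0.0 if arm == UNSTIMULATED_ARM else 1.0
        if arm == "NVP2-PS":
            treat = t_ps
        elif arm == "NVP2-RS":
            treat = t_rs
        else:
            treat = 0.0
        mu = s_true[j] * 2.0 ** (baseline + stim * activation + treat)
        counts[:, j] = _nb_counts(rng, mu, alpha)

    lengths = pd.Series(rng.integers(300, 10_000, size=n_g + n_c), index=gene_ids)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=samples),
        control_flags=pd.Series(is_control, index=gene_ids),
        gene_lengths=lengths,
    )
    design = pd.DataFrame(
        {
            "arm": arm_of,
            "stimulation": [a.split("-")[-1] if "-" in a else "none" for a in arm_of],
            "treatment": ["NVP2" if a.startswith("NVP2") else
                          ("none" if a == UNSTIMULATED_ARM else "untreated")
                          for a in arm_of],
        },
        index=pd.Index(samples, name="sample"),
    )
    truth = TreatmentTruth(
        genes=pd.DataFrame(
            {
                "is_control": is_control,
                "baseline_log2_mean": baseline,
                "activation_lfc": activation,
                "treatment_lfc_ps": t_ps,
                "treatment_lfc_rs": t_rs,
                "dispersion": alpha,
            },
            index=pd.Index(gene_ids, name="gene"),
        ),
        size_factors=pd.Series(s_true, index=samples, name="true_size_factor"),
    )
    return cm, design, truth


@dataclass
class CohortSimConfig:
    """Study conditions for the patient-cohort simulation.

    Shifts are standardized (multiples of noise_sd). Non-responders receive
    disease_shift + nonresponse_shift on signature genes; insensitive
    control genes receive no group shift at all. Clinical severity indices
    couple weakly (default rho ~ 0.3) to the per-sample shift.
    """

    seed: int = 1
    n_genes: int = 20_000  # transcriptome-scale background, as on expression arrays
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 20, "responder": 50, "non-responder": 50}
    )
    signature_ids: tuple[str, ...] | None = None  # default: 250 random genes
    insensitive_ids: tuple[str, ...] | None = None  # default: 110 random genes
    disease_shift: float = 1.0
    nonresponse_shift: float = 1.0
    noise_sd: float = 1.0
    clinical_coupling: float = 0.3
    sample_shift_sd: float = 0.25  # within-group heterogeneity, x noise_sd
    diagnosis: str = "UC"

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if any(v <= 0 for v in self.n_per_group.values()):
            raise ConfigurationError("every cohort group must be non-empty")


@dataclass
class CohortTruth:
    sample_shift: pd.Series
    genes: pd.DataFrame  # is_signature, is_insensitive


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate a log-scale cohort expression matrix, design, and truth."""
    rng = np.random.default_rng(config.seed)
    gene_ids = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene")

    if config.signature_ids is None:
        pick = rng.choice(config.n_genes, size=min(250 + 110, config.n_genes), replace=False)
        sig_ids = gene_ids[pick[:250]]
        ins_ids = gene_ids[pick[250:]]
    else:
        sig_ids = pd.Index(config.signature_ids)
        ins_ids = pd.Index(config.insensitive_ids or ())
        unknown = sig_ids.difference(gene_ids).union(ins_ids.difference(gene_ids))
        if len(unknown):
            raise ConfigurationError(f"signature ids outside gene universe: {list(unknown)[:5]}")
    is_sig = gene_ids.isin(sig_ids)
    is_ins = gene_ids.isin(ins_ids)

    groups, samples = [], []
    for grp, n in config.n_per_group.items():
        for r in range(n):
            samples.append(f"{grp}_s{r + 1}")
            groups.append(grp)
    group_shift = {
        "HC": 0.0,
        "responder": config.disease_shift * config.noise_sd,
        "non-responder": (config.disease_shift + config.nonresponse_shift) * config.noise_sd,
    }
    jitter = rng.normal(0.0, config.sample_shift_sd * config.noise_sd, size=len(samples))
    shift = np.array([group_shift.get(g, 0.0) for g in groups]) + jitter

    baseline = rng.normal(7.0, 1.5, size=config.n_genes)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(samples)))
    expr = baseline[:, None] + np.outer(is_sig.astype(float), shift) + noise
    expr = pd.DataFrame(expr, index=gene_ids, columns=samples)

    # clinical indices: rho-coupled to the standardized per-sample shift
    z = (shift - shift.mean()) / (shift.std() if shift.std() > 0 else 1.0)
    rho = config.clinical_coupling
    def clin(scale: float, center: float) -> np.ndarray:
        eps = rng.normal(size=len(samples))
        latent = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps
        return center + scale * latent

    design = pd.DataFrame(
        {
            "group": groups,
            "diagnosis": ["HC" if g == "HC" else config.diagnosis for g in groups],
            "response": [g if g in ("responder", "non-responder") else pd.NA for g in groups],
            "remission": ["remission" if g == "responder"
                          else ("active" if g == "non-responder" else pd.NA)
                          for g in groups],
            "mayo": clin(3.0, 6.0),
            "pucai": clin(20.0, 45.0),
            "fcal": np.exp(clin(0.8, 6.0)),
            "timepoint": "pre",
        },
        index=pd.Index(samples, name="sample"),
    )
    truth = CohortTruth(
        sample_shift=pd.Series(shift, index=samples, name="shift"),
        genes=pd.DataFrame({"is_signature": is_sig, "is_insensitive": is_ins}, index=gene_ids),
    )
    return expr, design, truth


@dataclass
class ChipSimConfig:
    """Study conditions for the TSS-occupancy simulation."""

    seed: int = 1
    n_genes: int = 2000
    tss_window_bp: int = 2000
    frac_bound: float = 0.5
    occupancy_gain_range: tuple[float, float] = (0.0, 4.0)  # RPKM gain on stimulation
    base_rpkm_range: tuple[float, float] = (1.0, 10.0)
    input_rate: float = 0.2  # background RPKM in every channel
    coupling_to_repression: float = -0.4
    repression_noise_sd: float = 0.5
    bind_coupling: float = 1.0  # log-odds of binding per SD of occupancy gain
    total_reads: int = 20_000_000

    def __post_init__(self) -> None:
        if self.tss_window_bp <= 0:
            raise ConfigurationError("tss_window_bp must be > 0")
        if not 0 <= self.frac_bound <= 1:
            raise ConfigurationError("frac_bound must be in [0, 1]")


def simulate_chip(
    config: ChipSimConfig,
    repression_lfc: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, "OccupancyCounts", pd.DataFrame]:
    """Generate peaks, a TSS annotation, window read counts, and truth.

    By default the truth table carries an implied NVP-2 ``log2fc``
    (coupling x gain + noise) so occupancy-repression integration can be
    exercised without the RNA-seq generator. When *repression_lfc* supplies
    a per-gene log2 fold change (e.g. the RNA-seq generator's truth), the
    occupancy gain is instead generated to track that repression — strongly
    repressed genes gain the most occupancy on stimulation — and binding
    probability rises with the gain, mimicking activation-coupled P-TEFb
    recruitment.
    """
    from .chipseq import OccupancyCounts

    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n)], name="gene")
    chroms = [f"chr{(i % 5) + 1}" for i in range(n)]
    tss_pos = [50_000 + 100_000 * (i // 5) for i in range(n)]
    tss = pd.DataFrame(
        {"gene": gene_ids, "chrom": chroms, "tss_position": tss_pos,
         "strand": ["+" if i % 2 == 0 else "-" for i in range(n)]}
    )

    lo, hi = config.occupancy_gain_range
    if repression_lfc is not None:
        lfc = repression_lfc.reindex(gene_ids).fillna(0.0).to_numpy(dtype=float)
        z = -(lfc - lfc.mean())
        z = z / (z.std() if z.std() > 0 else 1.0)
        mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
        gain = np.clip(mid + amp * (0.7 * z + 0.3 * rng.normal(size=n)), lo, hi)
        zg = (gain - gain.mean()) / (gain.std() if gain.std() > 0 else 1.0)
        logit = np.log(config.frac_bound / (1 - config.frac_bound)) if 0 < config.frac_bound < 1 else None
        if logit is None:
            bound = np.full(n, config.frac_bound >= 1)
        else:
            p_bound = 1.0 / (1.0 + np.exp(-(logit + config.bind_coupling * zg)))
            bound = rng.random(n) < p_bound
    else:
        gain = rng.uniform(lo, hi, size=n)
        bound = rng.random(n) < config.frac_bound
    rows = []
    for i in np.flatnonzero(bound):
        center = tss_pos[i] + int(rng.integers(-1500, 1501))
        width = int(rng.integers(200, 801))
        start = max(0, center - width // 2)
        rows.append((chroms[i], start, start + width, f"peak_{i}", 0, "."))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    base = rng.uniform(*config.base_rpkm_range, size=n)
    kb = config.tss_window_bp / 1000.0
    per_rpkm = kb * config.total_reads / 1e6  # reads per unit RPKM
    counts = pd.DataFrame(
        {
            "resting": rng.poisson((base + config.input_rate) * per_rpkm),
            "stimulated": rng.poisson((base + gain + config.input_rate) * per_rpkm),
            "input": rng.poisson(np.full(n, config.input_rate * per_rpkm)),
        },
        index=gene_ids,
    )
    occ = OccupancyCounts(
        counts=counts,
        totals={c: config.total_reads for c in counts.columns},
        window_bp=config.tss_window_bp,
    )
    if repression_lfc is not None:
        implied_lfc = repression_lfc.reindex(gene_ids).fillna(0.0).to_numpy(dtype=float)
    else:
        implied_lfc = config.coupling_to_repression * gain + rng.normal(
            0.0, config.repression_noise_sd, size=n
        )
    truth = pd.DataFrame(
        {
            "bound": bound,
            "base_rpkm": base,
            "occupancy_gain": gain,
            "log2fc": implied_lfc,
        },
        index=gene_ids,
    )
    return peaks, tss, occ, truth
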