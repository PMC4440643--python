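"""Synthetic cohort generator with the statistical structure the pipeline assumes.

Emulates, at desk scale, a methylation-array cancer cohort: a random genome
whose annotated CpG sites are true CG dinucleotides, PWMs (high-information
planted motifs plus uninformative decoys) whose sampled occurrences are
written into the +/-50 bp windows of designated CpGs, beta-values in [0,1]
with two-group differential effects, right-censored survival times whose
hazard is log-linear in methylation, and an Erdos-Renyi TF-TF interaction
graph. A :class:`GroundTruth` records every planted site, the causal CpGs
and any planted cluster structure, so recovery can be measured exactly.

Survival model: sample j's event time is exponential with hazard
``baseline_hazard * exp(gamma * mean beta over causal CpGs)``; censoring is
an independent exponential whose rate is tuned (by bisection on the exact
censoring probability) to hit the target censored fraction. Causal CpGs
share a per-sample latent methylation propensity so that each one is
marginally informative about the hazard — the premise a univariate screen
needs. Differential CpGs shift their mean beta between the two groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import dataio
from .dataio import PWM
from .regions import FLANK, REGION_LENGTH

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the study conditions used throughout."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_samples: int = 300
    group_fractions: dict = field(default_factory=lambda: {"ER+": 0.77, "ER-": 0.23})
    group_column: str = "ER"
    n_cpgs: int = 10_000
    n_motifs_decoy: int = 40
    n_motifs_planted: int = 2
    motif_width_range: tuple = (8, 12)
    plant_rate_foreground: float = 0.6
    plant_rate_background: float = 0.05
    n_causal_survival_cpgs: int = 300
    log_hazard_coefficient: float = 3.0     # gamma, log hazard per unit beta
    baseline_hazard: float = 1.0 / 1500.0   # events per day
    censoring_rate: float = 0.3
    diffmeth_effect: float = 0.15           # delta beta between groups
    n_diffmeth_cpgs: int = 500
    n_tf_nodes: int = 30
    edge_probability: float = 0.15
    # beta-value noise model
    beta_concentration: float = 30.0
    causal_latent_concentration: float = 30.0
    # optional planted cluster structure for the k-means analyses
    n_beta_clusters: int = 0
    cluster_mean_range: tuple = (0.1, 0.9)

    def __post_init__(self) -> None:
        for name in ("plant_rate_foreground", "plant_rate_background",
                     "censoring_rate", "edge_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if abs(sum(self.group_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")
        if any(f < 0 or f > 1 for f in self.group_fractions.values()):
            raise ValueError("group fractions must lie in [0,1]")
        if self.motif_width_range[0] < 4:
            raise ValueError("motif widths must be >= 4")
        if self.chrom_length <= REGION_LENGTH:
            raise ValueError(f"chrom_length must exceed {REGION_LENGTH}")


@dataclass
class GroundTruth:
    planted_motif_ids: set
    causal_cpg_ids: set
    planted_site_coordinates: list   # (chrom, start0, strand, motif_id)
    planted_site_sequences: list = field(default_factory=list)  # plus-strand as written
    diffmeth_cpg_ids: set = field(default_factory=set)
    true_cluster_of_cpg: dict | None = None


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome_and_cpgs(config: SimulationConfig):
    """Random genome plus an annotation of ``n_cpgs`` true CG dinucleotides.

    Annotated 1-based positions p satisfy genome[p] = 'C', genome[p+1] = 'G',
    and every CpG's 102-bp window fits inside its chromosome.
    """
    rng = _rng(config, 1)
    genome: dict[str, str] = {}
    candidates = []  # (chrom, 1-based C position)
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        codes = rng.integers(0, 4, size=config.chrom_length, dtype=np.int8)
        genome[chrom] = _BASE_BYTES[codes].tobytes().decode("ascii")
        cg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))  # 0-based C index
        pos = cg + 1  # 1-based
        feasible = pos[(pos - FLANK - 1 >= 1) & (pos + FLANK + 1 <= config.chrom_length)]
        candidates.extend((chrom, int(p)) for p in feasible)
    if len(candidates) < config.n_cpgs:
        raise ValueError(
            f"requested {config.n_cpgs} CpGs but only {len(candidates)} CG dinucleotides "
            f"are available (shortfall {config.n_cpgs - len(candidates)})"
        )
    chosen = rng.choice(len(candidates), size=config.n_cpgs, replace=False)
    chosen_sites = sorted(candidates[i] for i in chosen)
    strands = rng.choice(["+", "-"], size=config.n_cpgs)
    annotation = pd.DataFrame(
        {
            "cpg_id": [f"cg{i:08d}" for i in range(1, config.n_cpgs + 1)],
            "chrom": [c for c, _ in chosen_sites],
            "position": [p for _, p in chosen_sites],
            "strand": strands,
        }
    )
    return genome, annotation


def _sample_planted_pwm(rng, width: int, dominant: float = 0.9) -> np.ndarray:
    consensus = rng.integers(0, 4, size=width)
    probs = np.full((width, 4), (1.0 - dominant) / 3.0)
    probs[np.arange(width), consensus] = dominant
    return probs


def _sample_decoy_pwm(rng, width: int) -> np.ndarray:
    probs = rng.dirichlet(np.full(4, 0.8), size=width)
    return dataio.regularize_probs(probs)


def simulate_pwms_and_plant(genome: dict, annotation: pd.DataFrame, config: SimulationConfig):
    """Decoy + planted PWM sets; planted occurrences overwritten into the genome.

    Each causal CpG receives, with probability ``plant_rate_foreground``, a
    sequence sampled from a uniformly chosen planted PWM at a uniform offset
    inside its 102-bp window, on a uniform strand (reverse-complemented when
    minus); non-causal CpGs receive plants at ``plant_rate_background``.
    """
    rng = _rng(config, 2)
    wmin, wmax = config.motif_width_range
    if wmax > REGION_LENGTH:
        raise ValueError(f"motif width {wmax} exceeds region length {REGION_LENGTH}")

    pwms: list[PWM] = []
    planted_ids = []
    for i in range(config.n_motifs_planted):
        width = int(rng.integers(max(7, wmin), wmax + 1))
        mid = f"PM{i + 1:03d}"
        pwms.append(PWM(mid, f"TFP{i + 1:02d}", _sample_planted_pwm(rng, width)))
        planted_ids.append(mid)
    for i in range(config.n_motifs_decoy):
        width = int(rng.integers(wmin, wmax + 1))
        # decoy motifs share TFs in pairs so TF-level aggregation is exercised
        pwms.append(PWM(f"DM{i + 1:03d}", f"TFD{i // 2 + 1:02d}", _sample_decoy_pwm(rng, width)))

    n_causal = min(config.n_causal_survival_cpgs, len(annotation))
    causal_idx = rng.choice(len(annotation), size=n_causal, replace=False)
    causal_ids = set(annotation["cpg_id"].iloc[causal_idx])

    mutable = {chrom: bytearray(seq, "ascii") for chrom, seq in genome.items()}
    planted_by_id = {p.motif_id: p for p in pwms if p.motif_id in set(planted_ids)}
    sites = []
    inserted_seqs = []
    for rec in annotation.itertuples(index=False):
        rate = (
            config.plant_rate_foreground
            if rec.cpg_id in causal_ids
            else config.plant_rate_background
        )
        if rng.random() >= rate:
            continue
        motif_id = planted_ids[int(rng.integers(len(planted_ids)))]
        pwm = planted_by_id[motif_id]
        seq = "".join("ACGT"[b] for b in
                      [int(rng.choice(4, p=row)) for row in pwm.probs])
        strand = "+" if rng.random() < 0.5 else "-"
        region_start = rec.position - FLANK - 1
        offset = int(rng.integers(0, REGION_LENGTH - pwm.width + 1))
        start = region_start + offset
        inserted = seq if strand == "+" else reverse_complement(seq)
        mutable[rec.chrom][start : start + pwm.width] = inserted.encode("ascii")
        sites.append((rec.chrom, start, strand, motif_id))
        inserted_seqs.append(inserted)

    planted_genome = {chrom: bytes(buf).decode("ascii") for chrom, buf in mutable.items()}
    truth = GroundTruth(set(planted_ids), causal_ids, sites, inserted_seqs)
    return pwms, planted_genome, truth


def _censoring_rate_for(lam_c: float, hazards: np.ndarray) -> float:
    # P(censored) for independent exponentials = E[lam_c / (lam_c + hazard)]
    return float(np.mean(lam_c / (lam_c + hazards)))


def _solve_censoring_rate(target: float, hazards: np.ndarray) -> float:
    lo, hi = 1e-12, 1.0
    while _censoring_rate_for(hi, hazards) < target:
        hi *= 10.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if _censoring_rate_for(mid, hazards) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_phenotypes(annotation: pd.DataFrame, truth: GroundTruth, config: SimulationConfig):
    """Beta matrix and clinical table consistent with the ground truth.

    Also fills ``truth.diffmeth_cpg_ids`` (and ``truth.true_cluster_of_cpg``
    when ``n_beta_clusters`` > 0).
    """
    rng = _rng(config, 3)
    n = config.n_samples
    sample_ids = [f"S{j + 1:04d}" for j in range(n)]
    labels = list(config.group_fractions)
    counts = [int(round(f * n)) for f in config.group_fractions.values()]
    counts[-1] = n - sum(counts[:-1])
    group = np.repeat(labels, counts)
    rng.shuffle(group)

    cpg_ids = annotation["cpg_id"].to_numpy()
    causal_mask = np.isin(cpg_ids, list(truth.causal_cpg_ids))
    non_causal = np.flatnonzero(~causal_mask)
    n_dm = min(config.n_diffmeth_cpgs, len(non_causal))
    dm_idx = rng.choice(non_causal, size=n_dm, replace=False)
    dm_mask = np.zeros(len(cpg_ids), dtype=bool)
    dm_mask[dm_idx] = True
    truth.diffmeth_cpg_ids = set(cpg_ids[dm_mask])

    u = rng.beta(2.0, 2.0, size=n)  # latent per-sample methylation propensity
    base_mean = rng.uniform(0.15, 0.85, size=len(cpg_ids))

    cluster_of = None
    if config.n_beta_clusters > 0:
        lo, hi = config.cluster_mean_range
        cluster_means = np.linspace(lo, hi, config.n_beta_clusters)
        cluster_of = rng.integers(1, config.n_beta_clusters + 1, size=len(cpg_ids))
        base_mean = cluster_means[cluster_of - 1]
        truth.true_cluster_of_cpg = dict(zip(cpg_ids, (int(c) for c in cluster_of)))

    kappa = config.beta_concentration
    kappa_c = config.causal_latent_concentration
    is_g1 = group == labels[0]
    # half the differential CpGs are hypermethylated in group 1, half hypo-
    dm_sign = rng.choice([-1.0, 1.0], size=len(cpg_ids))
    shift = np.where(dm_mask, dm_sign * config.diffmeth_effect / 2.0, 0.0)

    mean_matrix = np.clip(
        base_mean[:, None] + np.where(is_g1[None, :], shift[:, None], -shift[:, None]),
        0.02, 0.98,
    )
    mean_matrix[causal_mask, :] = np.clip(u[None, :], 0.02, 0.98)
    conc = np.where(causal_mask, kappa_c, kappa)[:, None]
    beta_values = rng.beta(conc * mean_matrix, conc * (1.0 - mean_matrix))
    beta = pd.DataFrame(beta_values, index=cpg_ids, columns=sample_ids)

    causal_beta = beta_values[causal_mask, :]
    mean_causal = causal_beta.mean(axis=0) if causal_mask.any() else np.zeros(n)
    hazards = config.baseline_hazard * np.exp(config.log_hazard_coefficient * mean_causal)
    event_time = rng.exponential(1.0 / hazards)
    if config.censoring_rate in (0.0, 1.0):
        warnings.warn(
            f"censoring_rate={config.censoring_rate} is degenerate for the survival screens",
            stacklevel=2,
        )
    if config.censoring_rate <= 0.0:
        censor_time = np.full(n, np.inf)
    else:
        lam_c = _solve_censoring_rate(config.censoring_rate, hazards)
        censor_time = rng.exponential(1.0 / lam_c, size=n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "survival_time": np.maximum(observed, 1e-6),
            "event": event,
            config.group_column: group,
        }
    )
    return beta, clinical


def simulate_tf_edges(config: SimulationConfig, tf_names=None) -> pd.DataFrame:
    """Erdos-Renyi undirected simple edge list over the TF name universe.

    ``tf_names`` (e.g. the simulated motif TFs) are always among the graph's
    nodes, padded with filler TFs up to ``n_tf_nodes``.
    """
    if config.n_tf_nodes < 2:
        raise ValueError("n_tf_nodes must be >= 2")
    names = list(dict.fromkeys(tf_names or []))
    for i in range(1, config.n_tf_nodes + 1):
        if len(names) >= config.n_tf_nodes:
            break
        filler = f"TFX{i:02d}"
        if filler not in names:
            names.append(filler)
    seed = int(np.random.default_rng([config.seed, 4]).integers(2**31))
    g = nx.gnp_random_graph(len(names), config.edge_probability, seed=seed)
    rows = sorted(tuple(sorted((names[u], names[v]))) for u, v in g.edges())
    return pd.DataFrame(rows, columns=["tf1", "tf2"])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict
    annotation: pd.DataFrame
    pwms: list
    truth: GroundTruth
    beta: pd.DataFrame
    clinical: pd.DataFrame
    tf_edges: pd.DataFrame


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage; fully determined by ``config.seed``."""
    genome, annotation = simulate_genome_and_cpgs(config)
    pwms, genome, truth = simulate_pwms_and_plant(genome, annotation, config)
    beta, clinical = simulate_phenotypes(annotation, truth, config)
    edges = simulate_tf_edges(config, tf_names=[p.tf_name for p in pwms])
    return SimulatedDataset(config, genome, annotation, pwms, truth, beta, clinical, edges)


def write_simulation(ds: SimulatedDataset, out_dir) -> None:
    """Emit the on-disk formats the pipeline reads, plus the ground truth."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    dataio.write_genome_fasta(ds.genome, os.path.join(out_dir, "genome.fa"))
    dataio.write_tsv(ds.beta.rename_axis("cpg_id"), os.path.join(out_dir, "beta.tsv"), index=True)
    dataio.write_tsv(ds.annotation, os.path.join(out_dir, "annotation.tsv"))
    dataio.write_tsv(ds.clinical, os.path.join(out_dir, "clinical.tsv"))
    dataio.write_meme_minimal(ds.pwms, os.path.join(out_dir, "motifs.meme"))
    dataio.write_tsv(ds.tf_edges, os.path.join(out_dir, "tf_edges.tsv"))
    sites = pd.DataFrame(
        ds.truth.planted_site_coordinates, columns=["chrom", "start", "strand", "motif_id"]
    )
    dataio.write_tsv(sites, os.path.join(out_dir, "ground_truth_sites.tsv"))
    dataio.write_tsv(
        pd.DataFrame({"cpg_id": sorted(ds.truth.causal_cpg_ids)}),
        os.path.join(out_dir, "ground_truth_causal_cpgs.tsv"),
    )
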