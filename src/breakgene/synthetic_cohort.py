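"""Synthetic array-CGH cohort generator with known planted truth.

Emulates the structure of a segmented, state-called copy-number cohort: an
evenly spaced probe grid (~17 kb default spacing), log-normal gene lengths,
per-sample breakpoint burdens that vary over orders of magnitude (negative
binomial), optionally planted recurrent breakpoint genes, an 8-gene
mutation panel, a modular gene-interaction network, and subtype-dependent
exponential survival.  Breakpoints are simulated as inter-probe boundary
events and converted to segments with alternating neutral / non-neutral
call states, so every planted boundary is recoverable by the breakpoint
extraction rule and the ground truth is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles_io import (BinaryEventMatrix, ClinicalTable, GeneModel, ProbeMap,
                          Segment, SegmentedProfile, write_clinical, write_genes,
                          write_matrix, write_network, write_probes, write_segments)

__all__ = ["SimulationConfig", "SubtypeSpec", "GroundTruth", "SyntheticCohort",
           "simulate_cohort", "scenario"]

# CRC-like mutation panel with literature-scale per-gene mutation frequencies
DEFAULT_MUTATION_PANEL = {
    "APC": 0.50, "TP53": 0.55, "KRAS": 0.40, "PIK3CA": 0.15,
    "FBXW7": 0.10, "SMAD4": 0.10, "BRAF": 0.08, "NRAS": 0.04,
}


@dataclass
class SubtypeSpec:
    """Planted subtype structure: drivers, survival and MSI enrichment.

    ``driver_genes[j]`` lists the breakpoint genes driving subtype j
    (0-based); each is broken with probability ``theta_in`` in its own
    subtype and ``theta_out`` elsewhere.  Survival is exponential with
    per-subtype ``hazards`` (per day) under independent exponential
    censoring; MSI status is enriched in ``msi_subtype``.
    """

    k: int = 4
    n_drivers_per_subtype: int = 15
    theta_in: float = 0.4
    theta_out: float = 0.05
    hazards: tuple = (0.0010, 0.0010, 0.0025, 0.0010)
    censor_rate: float = 0.0004
    msi_subtype: int = 2
    msi_rate_in: float = 0.30
    msi_rate_out: float = 0.01
    mutation_enriched: dict = field(default_factory=lambda: {"BRAF": (0.33, 0.05)})


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults are desk-scale (hundreds of samples, thousands of probes); the
    emulated study magnitudes (352 samples, 168 823 probes) are available
    via :func:`scenario` ``"full-scale"`` but not required anywhere.
    """

    seed: int = 0
    n_samples: int = 100
    n_chromosomes: int = 4
    probes_per_chromosome: int = 5000
    probe_spacing_bp: int = 17000
    n_genes: int = 2000
    gene_length_log_mean: float = np.log(30_000.0)
    gene_length_log_sigma: float = 1.0
    background_bp_mean: float = 40.0
    background_bp_dispersion: float = 1.0
    planted_genes: dict = field(default_factory=dict)   # gene_id -> theta
    mutation_panel: dict = field(default_factory=lambda: dict(DEFAULT_MUTATION_PANEL))
    n_network_genes: int = 1000
    network_within_p: float = 0.08
    network_between_p: float = 0.003
    subtypes: SubtypeSpec | None = None
    baseline_hazard: float = 0.0012
    baseline_censor_rate: float = 0.0004

    def __post_init__(self):
        for g, th in self.planted_genes.items():
            if not 0 <= th <= 1:
                raise ValueError(f"planted theta for {g} outside [0, 1]: {th}")
        for g, f in self.mutation_panel.items():
            if not 0 <= f <= 1:
                raise ValueError(f"mutation frequency for {g} outside [0, 1]")
        if min(self.n_samples, self.n_chromosomes, self.probes_per_chromosome,
               self.n_genes) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact downstream checks."""

    breakpoints: set            # (sample_id, chromosome, left_probe, right_probe)
    planted_recurrent: list     # gene ids planted as recurrent
    subtype_labels: pd.Series | None
    driver_genes: dict          # subtype (0-based) -> list of gene ids
    hazards: tuple | None


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort plus its planted truth."""

    config: SimulationConfig
    probe_map: ProbeMap
    genes: list[GeneModel]
    profiles: list[SegmentedProfile]
    mutation_matrix: BinaryEventMatrix
    network_edges: pd.DataFrame
    clinical: ClinicalTable
    truth: GroundTruth

    @property
    def samples(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def write(self, out_dir) -> None:
        """Emit all cohort files (TSV/BED) into a directory."""
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_probes(self.probe_map, out / "probes.tsv")
        write_genes(self.genes, out / "genes.bed")
        write_segments(self.profiles, out / "segments.tsv")
        write_matrix(self.mutation_matrix, out / "mutations.tsv")
        write_network(self.network_edges, out / "network.tsv")
        write_clinical(self.clinical, out / "clinical.tsv")
        truth = pd.DataFrame(sorted(self.truth.breakpoints),
                             columns=["sample", "chromosome", "left_probe", "right_probe"])
        truth.to_csv(out / "truth_breakpoints.tsv", sep="\t", index=False)


def _make_probe_map(cfg: SimulationConfig) -> ProbeMap:
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        for i in range(cfg.probes_per_chromosome):
            rows.append((f"P{c}_{i}", str(c), (i + 1) * cfg.probe_spacing_bp))
    return ProbeMap(pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"]))


def _make_genes(cfg: SimulationConfig, rng: np.random.Generator,
                special_ids: list[str]) -> list[GeneModel]:
    """Random gene spans; genes named in ``special_ids`` (planted recurrent
    genes, mutation-panel genes) are forced long enough to contain probes."""
    chrom_len = (cfg.probes_per_chromosome + 1) * cfg.probe_spacing_bp
    genes = []
    ids = [f"G{j:05d}" for j in range(cfg.n_genes)] + list(special_ids)
    special = set(special_ids)
    for gid in ids:
        length = int(rng.lognormal(cfg.gene_length_log_mean, cfg.gene_length_log_sigma))
        length = max(length, 500)
        if gid in special:
            length = max(length, 3 * cfg.probe_spacing_bp)
        length = min(length, chrom_len - 2)
        chrom = str(rng.integers(1, cfg.n_chromosomes + 1))
        start = int(rng.integers(1, chrom_len - length))
        genes.append(GeneModel(gid, chrom, start, start + length - 1,
                               "+" if rng.random() < 0.5 else "-"))
    return genes


def _boundaries_overlapping(gene: GeneModel, probe_map: ProbeMap) -> np.ndarray:
    """Inter-probe boundary indices b whose interval (pos[b], pos[b+1]]
    overlaps the gene span."""
    pos = probe_map.positions(gene.chromosome)
    b = np.arange(len(pos) - 1)
    return b[(pos[b] + 1 <= gene.end) & (pos[b + 1] >= gene.start)]


def _segments_from_boundaries(boundaries: np.ndarray, n_probes: int,
                              rng: np.random.Generator) -> list[Segment]:
    """Convert a sorted boundary set into segments with alternating
    neutral / non-neutral calls so that no boundary is neutral–neutral."""
    edges = np.concatenate([[0], boundaries + 1, [n_probes]])
    segs = []
    for j in range(len(edges) - 1):
        start, end = int(edges[j]), int(edges[j + 1]) - 1
        if j % 2 == 0:
            call = 0
            log2 = float(rng.normal(0.0, 0.02))
        else:
            call = int(rng.choice([-2, -1, 1, 2]))
            log2 = float(0.3 * call + rng.normal(0.0, 0.03))
        segs.append(Segment(start, end, round(log2, 4), call))
    return segs


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one full synthetic cohort from the configured generative model.

    Background breakpoints are placed uniformly over inter-probe boundaries
    with a negative-binomial per-sample count; each planted gene is
    additionally broken (at a boundary overlapping its span) with its
    per-sample hit probability — subtype drivers use the in/out-of-subtype
    probabilities.  Identical seeds give identical cohorts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    probe_map = _make_probe_map(cfg)

    special = list(cfg.planted_genes) + [g for g in cfg.mutation_panel
                                         if g not in cfg.planted_genes]
    sub = cfg.subtypes
    driver_genes: dict[int, list[str]] = {}
    if sub is not None:
        for j in range(sub.k):
            driver_genes[j] = [f"DRV{j}_{d:02d}" for d in range(sub.n_drivers_per_subtype)]
            special += driver_genes[j]
    genes = _make_genes(cfg, rng, special)
    gene_by_id = {g.gene_id: g for g in genes}
    for gid in cfg.planted_genes:
        gene = gene_by_id[gid]
        if len(_boundaries_overlapping(gene, probe_map)) == 0:
            raise ValueError(f"planted gene {gid} has no breakpoint site in span")

    samples = [f"S{j:04d}" for j in range(cfg.n_samples)]
    if sub is not None:
        labels = pd.Series(np.repeat(np.arange(sub.k), -(-cfg.n_samples // sub.k))[:cfg.n_samples],
                           index=samples, name="subtype")
    else:
        labels = None

    chroms = probe_map.chromosomes
    n_bound = {c: probe_map.n_probes(c) - 1 for c in chroms}
    total_bound = sum(n_bound.values())
    chrom_weights = np.array([n_bound[c] for c in chroms], dtype=float) / total_bound

    # per-gene candidate boundary sites, computed once
    planted_sites = {gid: _boundaries_overlapping(gene_by_id[gid], probe_map)
                     for gid in cfg.planted_genes}
    driver_sites = {}
    for j, gl in driver_genes.items():
        for gid in gl:
            driver_sites[gid] = _boundaries_overlapping(gene_by_id[gid], probe_map)

    nb_n = cfg.background_bp_dispersion
    nb_p = nb_n / (nb_n + cfg.background_bp_mean)

    profiles, truth_bp = [], set()
    for s_i, sample in enumerate(samples):
        per_chrom: dict[str, set[int]] = {c: set() for c in chroms}
        n_bg = int(rng.negative_binomial(nb_n, nb_p))
        for _ in range(n_bg):
            c = chroms[rng.choice(len(chroms), p=chrom_weights)]
            per_chrom[c].add(int(rng.integers(0, n_bound[c])))
        for gid, theta in cfg.planted_genes.items():
            if rng.random() < theta:
                gene = gene_by_id[gid]
                site = int(rng.choice(planted_sites[gid]))
                per_chrom[gene.chromosome].add(site)
        if sub is not None:
            lab = int(labels.iloc[s_i])
            for j, gl in driver_genes.items():
                theta = sub.theta_in if j == lab else sub.theta_out
                for gid in gl:
                    if rng.random() < theta and len(driver_sites[gid]):
                        gene = gene_by_id[gid]
                        site = int(rng.choice(driver_sites[gid]))
                        per_chrom[gene.chromosome].add(site)
        segments = {}
        for c in chroms:
            bounds = np.array(sorted(per_chrom[c]), dtype=np.int64)
            segments[c] = _segments_from_boundaries(bounds, probe_map.n_probes(c), rng)
            for b in bounds:
                truth_bp.add((sample, c, int(b), int(b) + 1))
        profiles.append(SegmentedProfile(sample, segments))

    # mutation panel
    mut = pd.DataFrame(0, index=pd.Index(sorted(cfg.mutation_panel), name="gene"),
                       columns=samples, dtype=np.int8)
    for gid in sorted(cfg.mutation_panel):
        freq = cfg.mutation_panel[gid]
        if sub is not None and gid in sub.mutation_enriched:
            f_in, f_out = sub.mutation_enriched[gid]
            probs = np.where(labels.to_numpy() == sub.msi_subtype, f_in, f_out)
        else:
            probs = np.full(cfg.n_samples, freq)
        mut.loc[gid] = (rng.random(cfg.n_samples) < probs).astype(np.int8)
    mutation_matrix = BinaryEventMatrix(mut)

    # modular network over a subset of genes (drivers + panel genes included)
    net_genes = list(dict.fromkeys(
        [g for gl in driver_genes.values() for g in gl]
        + sorted(cfg.mutation_panel)
        + list(cfg.planted_genes)))
    fill = [g.gene_id for g in genes if g.gene_id not in set(net_genes)]
    net_genes += fill[:max(0, cfg.n_network_genes - len(net_genes))]
    n_modules = sub.k if sub is not None else 4
    module_of = {}
    for j, gl in driver_genes.items():
        for gid in gl:
            module_of[gid] = j
    rest = [g for g in net_genes if g not in module_of]
    for i, gid in enumerate(rest):
        module_of[gid] = i % n_modules
    edges = []
    ng = len(net_genes)
    mods = np.array([module_of[g] for g in net_genes])
    upper = np.triu_indices(ng, k=1)
    same = mods[upper[0]] == mods[upper[1]]
    p_edge = np.where(same, cfg.network_within_p, cfg.network_between_p)
    draw = rng.random(len(p_edge)) < p_edge
    for i, j in zip(upper[0][draw], upper[1][draw]):
        edges.append((net_genes[i], net_genes[j], 1.0))
    network_edges = pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"])

    # clinical table: exponential survival + independent exponential censoring
    if sub is not None:
        haz = np.array(sub.hazards)[labels.to_numpy()]
        censor_rate = sub.censor_rate
        msi_p = np.where(labels.to_numpy() == sub.msi_subtype,
                         sub.msi_rate_in, sub.msi_rate_out)
    else:
        haz = np.full(cfg.n_samples, cfg.baseline_hazard)
        censor_rate = cfg.baseline_censor_rate
        msi_p = np.full(cfg.n_samples, 0.05)
    t_event = rng.exponential(1.0 / haz)
    t_cens = rng.exponential(1.0 / censor_rate, size=cfg.n_samples)
    os_days = np.minimum(t_event, t_cens).round().astype(int)
    event = (t_event <= t_cens).astype(int)
    msi = (rng.random(cfg.n_samples) < msi_p).astype(int)
    clinical = ClinicalTable(pd.DataFrame({
        "sample": samples, "os_days": os_days, "event": event, "msi_status": msi,
    }))

    truth = GroundTruth(
        breakpoints=truth_bp,
        planted_recurrent=list(cfg.planted_genes),
        subtype_labels=labels,
        driver_genes=driver_genes,
        hazards=sub.hazards if sub is not None else None,
    )
    return SyntheticCohort(cfg, probe_map, genes, profiles, mutation_matrix,
                           network_edges, clinical, truth)


def scenario(name: str, seed: int = 0) -> SimulationConfig:
    """Preset study conditions.

    - ``"null"``: no planted signal; FDR / p-value calibration runs.
    - ``"planted"``: 20 recurrent breakpoint genes at per-sample hit
      probability 0.08 on a 100-sample, 2 000-gene, 20 000-probe cohort —
      the power / FDR benchmark.
    - ``"subtypes"``: 200 samples in 4 survival-separated groups whose
      driver events align with network modules — the stratification
      benchmark.
    - ``"full-scale"``: the emulated study's magnitudes (352 samples,
      ~168k probes); documentation only, not used by tests.
    """
    if name == "null":
        return SimulationConfig(seed=seed)
    if name == "planted":
        planted = {f"REC{j:02d}": 0.08 for j in range(20)}
        return SimulationConfig(seed=seed, planted_genes=planted)
    if name == "subtypes":
        return SimulationConfig(seed=seed, n_samples=200, subtypes=SubtypeSpec())
    if name == "full-scale":
        return SimulationConfig(seed=seed, n_samples=352, n_chromosomes=23,
                                probes_per_chromosome=7340, n_genes=20000)
    raise ValueError(f"unknown scenario {name!r}")
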