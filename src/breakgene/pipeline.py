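"""End-to-end convenience wrappers chaining the analysis stages.

These functions glue the module-level operations into the three stages a
cohort analysis runs: breakpoint extraction and gene mapping, recurrence
testing, and network-based stratification with clinical association.  Each
returns plain dictionaries of the intermediate objects so callers can
inspect or re-run any stage.
"""

from __future__ import annotations

import pandas as pd

from . import breakpoints as bp
from . import recurrence as rec
from . import stratification as strat
from .profiles_io import BinaryEventMatrix, GeneModel, ProbeMap, SegmentedProfile

__all__ = ["breakpoint_stage", "recurrence_stage", "stratification_stage"]


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by a union of closed intervals."""
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def breakpoint_stage(
    profiles: list[SegmentedProfile],
    probe_map: ProbeMap,
    genes: list[GeneModel],
    pool: bool = True,
    mode: str = "interval",
) -> dict:
    """Extract breakpoints, map them to genes, and pool shared-probe genes."""
    all_bp = []
    counts = {}
    for prof in profiles:
        b = bp.derive_breakpoints(prof, probe_map)
        counts[prof.sample_id] = len(b)
        all_bp.extend(b)
    samples = [p.sample_id for p in profiles]
    gene_index = bp.build_gene_probe_index(genes, probe_map)
    gene_matrix, probe_sets = bp.map_breakpoints_to_genes(
        all_bp, genes, probe_map, samples=samples, mode=mode)
    out = {
        "breakpoints": all_bp,
        "breakpoint_counts": pd.Series(counts, name="B_s"),
        "gene_matrix": gene_matrix,
        "probe_sets": probe_sets,
        "gene_index": gene_index,
        "samples": samples,
    }
    if pool:
        pooled, registry = bp.pool_shared_probe_genes(
            gene_matrix, probe_sets, gene_chromosome=gene_index.chromosome)
        out["pooled_matrix"] = pooled
        out["pool_registry"] = registry
        # pooled entity covariates: union of member probe sets, union span
        span_of = {g.gene_id: (g.start, g.end) for g in genes}
        n_probes, span, probes = {}, {}, {}
        for pool_name, members in registry.pools.items():
            ordered = sorted(members)
            union_probes = set()
            for m in ordered:
                union_probes.update(gene_index.probes[m].tolist())
            probes[pool_name] = pd.array(sorted(union_probes)).to_numpy()
            n_probes[pool_name] = len(union_probes)
            span[pool_name] = _union_length([span_of[m] for m in ordered])
        out["pooled_index"] = bp.GeneProbeIndex(
            probes=probes,
            n_probes=pd.Series(n_probes, name="n_probes"),
            span_length=pd.Series(span, name="span_length"),
            chromosome=gene_index.chromosome,
        )
    return out


def recurrence_stage(
    stage: dict,
    alpha: float = rec.ALPHA_DEFAULT,
    genes: str = "all",
    use_pooled: bool = True,
) -> dict:
    """Fit the baseline model and run the gene-level recurrence test."""
    if use_pooled and "pooled_matrix" in stage:
        matrix = stage["pooled_matrix"]
        index = stage["pooled_index"]
    else:
        matrix = stage["gene_matrix"]
        index = stage["gene_index"]
    model = rec.fit_breakpoint_probability_model(
        matrix, index, stage["breakpoint_counts"])
    table = rec.recurrence_table(matrix, model, gene_index=index,
                                 alpha=alpha, genes=genes)
    return {"model": model, "table": table, "matrix": matrix, "index": index}


def select_prevalent_recurrent(
    stage: dict,
    recurrence_result: dict,
    min_prevalence: float = 0.03,
) -> BinaryEventMatrix:
    """Restrict the gene breakpoint matrix to prevalent recurrent genes.

    Stratification consumes only genes whose (pooled) recurrence test is
    significant and whose prevalence exceeds ``min_prevalence`` (the study
    convention: recurrent breakpoint genes broken in > 3% of samples),
    expanded back to individual member genes of significant pools.
    """
    table = recurrence_result["table"]
    keep_entities = table.index[(table["significant"])
                                & (table["prevalence"] > min_prevalence)]
    registry = stage.get("pool_registry")
    genes: set[str] = set()
    for name in keep_entities:
        if registry is not None and name in registry.pools:
            genes |= registry.pools[name]
        else:
            genes.add(name)
    rows = [g for g in stage["gene_matrix"].rows if g in genes]
    return BinaryEventMatrix(stage["gene_matrix"].data.loc[rows].copy())


def stratification_stage(
    breakpoint_matrix: BinaryEventMatrix,
    mutation_matrix: BinaryEventMatrix,
    network_edges: pd.DataFrame,
    config: strat.NBSConfig,
) -> dict:
    """Merge events, propagate over the network, consensus-cluster, score genes."""
    merged, zero_event = strat.merge_events(breakpoint_matrix, mutation_matrix)
    if zero_event:
        keep = [s for s in merged.samples if s not in set(zero_event)]
        merged = BinaryEventMatrix(merged.data[keep])
    network = strat.GeneNetwork.from_edges(network_edges)
    smoothed = strat.propagate(merged, network, alpha=config.alpha,
                               tol=config.prop_tol)
    run, assignment = strat.consensus_cluster(smoothed, network, config)
    scores = strat.extract_gene_scores(run)
    association = strat.subtype_gene_association(scores, assignment)
    return {
        "merged": merged,
        "dropped_samples": zero_event,
        "smoothed": smoothed,
        "run": run,
        "assignment": assignment,
        "scores": scores,
        "association": association,
    }
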