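"""End-to-end orchestration of the clustering workflow.

The stages run in the order: optional redundancy pre-filter, sliding-window
fragmentation, (reactivity-guided) folding, graph encoding, kernel feature
extraction, iterative MinHash candidate detection with UPGMA pruning /
progressive alignment / consensus annotation / centroid extension, and
finally the hard or soft partition report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .folding import (
    FoldParams,
    PseudoEnergyParams,
    SecondaryStructure,
    fold,
    reactivity_to_pseudo_scores,
)
from .graphs import encode
from .kernel import KernelParams, SparseFeatureVector, nspdk_features
from .minhash import ClusterCandidate, ClusterParams, RoundState, run_round
from .preprocess import SeqRecord, Window, filter_low_information, filter_redundant, split_windows
from .refine import (
    Cluster,
    Partition,
    consensus_and_metrics,
    extend_cluster,
    pair_score,
    progressive_align,
    prune_cluster,
    report_partition,
    score_to_distance,
    self_score,
    upgma,
)

import numpy as np

logger = logging.getLogger("rnastructclust")

#: window-length / shift presets: whole-transcript clustering vs motif finding
FLAVORS = {
    "global": {"window_len": 250, "shift": 0.7},
    "local": {"window_len": 100, "shift": 0.7},
}


@dataclass
class PipelineParams:
    flavor: str = "global"
    window_len: Optional[int] = None  # None: take the flavor preset
    shift: Optional[float] = None
    prefilter_identity: Optional[float] = None  # e.g. 0.9 to collapse redundancy
    include_path_graph: bool = True
    use_reactivities: bool = True
    min_nonzero_fraction: float = 0.01  # low-information reactivity filter
    fold_params: FoldParams = field(default_factory=FoldParams)
    pseudo_params: PseudoEnergyParams = field(default_factory=PseudoEnergyParams)
    kernel_params: KernelParams = field(default_factory=KernelParams)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    max_rounds: int = 2
    # centroid-similarity prescreen for extension: recall-only; homologs and
    # background overlap on this statistic, so acceptance is decided by the
    # alignment gate below, and this floor only bounds the scan cost
    extension_threshold: float = 0.4
    # a recruit must align to the cluster at >= this fraction of the
    # self-alignment score (the analog of a homology-search hit threshold);
    # without it, repeated centroid rescans drift toward the data mean
    extension_score_gate: float = 0.5
    extension_max_iter: int = 3
    min_sci: float = 0.01  # conserved-candidate flag threshold (SCI filter)
    partition_mode: str = "hard"

    def resolved_window(self) -> tuple[int, float]:
        preset = FLAVORS[self.flavor]
        return (
            self.window_len if self.window_len is not None else preset["window_len"],
            self.shift if self.shift is not None else preset["shift"],
        )


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    partition: Partition
    windows: dict[str, Window]
    structures: dict[str, SecondaryStructure]
    vectors: dict[str, SparseFeatureVector]
    unclustered: set[str]
    rounds_run: int
    redundancy_map: dict[str, str] = field(default_factory=dict)
    candidate_log: list = field(default_factory=list)

    def sequence_partition(self) -> Partition:
        """Collapse window-level assignments to parent-sequence level.

        A sequence inherits the cluster of its best-assigned window (lowest
        cluster id on ties).  Sequences with no clustered window stay
        unclustered; redundancy-filtered members inherit their
        representative's assignment.
        """
        seq_assign: dict[str, set[int]] = {}
        for wid, cids in self.partition.assignments.items():
            parent = self.windows[wid].parent_id
            seq_assign.setdefault(parent, set()).update(cids)
        if self.partition.mode == "hard":
            seq_assign = {p: {min(c)} for p, c in seq_assign.items()}
        for member, rep in self.redundancy_map.items():
            if rep in seq_assign:
                seq_assign[member] = set(seq_assign[rep])
        parents = {w.parent_id for w in self.windows.values()} | set(self.redundancy_map)
        return Partition(
            mode=self.partition.mode,
            assignments=seq_assign,
            unclustered=parents - set(seq_assign),
        )


def prepare_windows(records: list[SeqRecord], params: PipelineParams) -> dict[str, Window]:
    window_len, shift = params.resolved_window()
    windows: dict[str, Window] = {}
    for rec in records:
        for w in split_windows(rec, window_len, shift):
            windows[w.window_id] = w
    return windows


def fold_windows(
    windows: dict[str, Window],
    params: PipelineParams,
    precomputed: Optional[dict[str, SecondaryStructure]] = None,
) -> dict[str, SecondaryStructure]:
    """One structure per window: precomputed dot-bracket if supplied, else the
    internal DP, reactivity-guided where a usable profile is attached."""
    structures: dict[str, SecondaryStructure] = {}
    for wid, w in windows.items():
        if precomputed and wid in precomputed:
            structures[wid] = precomputed[wid]
            continue
        pseudo = None
        if params.use_reactivities and w.reactivities is not None:
            if filter_low_information(w.reactivities, params.min_nonzero_fraction):
                pseudo = reactivity_to_pseudo_scores(w.reactivities, params.pseudo_params)
        structures[wid] = fold(w.sequence, params.fold_params, pseudo)
    return structures


def featurize(
    windows: dict[str, Window],
    structures: dict[str, SecondaryStructure],
    params: PipelineParams,
) -> dict[str, SparseFeatureVector]:
    return {
        wid: nspdk_features(
            encode(w, structures[wid], params.include_path_graph), params.kernel_params
        )
        for wid, w in windows.items()
    }


def make_refiner(
    windows: dict[str, Window],
    structures: dict[str, SecondaryStructure],
    vectors: dict[str, SparseFeatureVector],
    params: PipelineParams,
    counter: list[int],
):
    """Build the candidate-refinement callback used by each clustering round."""

    def refiner(cand: ClusterCandidate, remaining: set[str]) -> Optional[Cluster]:
        member_data = {
            m: (windows[m].sequence, structures[m]) for m in cand.member_ids
        }
        ids = sorted(member_data)
        scores = {
            frozenset((a, b)): pair_score(member_data[a], member_data[b])
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        }
        selfs = {m: self_score(member_data[m]) for m in ids}
        n = len(ids)
        D = np.zeros((n, n))
        for i, a in enumerate(ids):
            for j in range(i + 1, n):
                b = ids[j]
                D[i, j] = D[j, i] = score_to_distance(
                    scores[frozenset((a, b))], selfs[a], selfs[b]
                )
        tree = upgma(ids, D)
        kept = prune_cluster(tree, scores, params.cluster_params.min_cluster_size)
        if not kept:
            return None
        kept_data = {m: member_data[m] for m in kept}
        alignment = progressive_align(kept_data, tree)
        consensus, sci, covarying = consensus_and_metrics(
            alignment, {m: structures[m] for m in kept}, params.fold_params
        )
        # rebuild-and-rescan: recruiting sharpens the centroid, which can lift
        # further true members over the threshold, so iterate; every recruit
        # must also pass the alignment-score gate against cluster exemplars
        members = list(kept)
        centroid, sims = None, {}
        for _ in range(params.extension_max_iter):
            pool = [m for m in remaining if m not in members]
            added, centroid, sims = extend_cluster(
                members, vectors, pool, params.extension_threshold
            )
            exemplars = sorted(members, key=lambda m: -sims.get(m, 0.0))[:5]
            accepted = []
            for m in sorted(added, key=lambda m: (-sims[m], m)):
                if len(members) + len(accepted) >= params.cluster_params.max_cluster_size:
                    break
                scores_m = [
                    pair_score((windows[m].sequence, structures[m]),
                               (windows[e].sequence, structures[e]))
                    / max(self_score((windows[m].sequence, structures[m])),
                          self_score((windows[e].sequence, structures[e])))
                    for e in exemplars
                ]
                if sum(scores_m) / len(scores_m) >= params.extension_score_gate:
                    accepted.append(m)
                else:
                    sims.pop(m, None)
            if not accepted:
                break
            members = members + accepted
        counter[0] += 1
        metrics = {
            "sci": sci,
            "covarying_pairs": covarying,
            "mean_pairwise_identity": alignment.mean_pairwise_identity(),
            "conserved_candidate": sci >= params.min_sci,
        }
        return Cluster(
            cluster_id=counter[0],
            members=members,
            sources={m: ("initial" if m in kept else "extended") for m in members},
            alignment=alignment,
            consensus_structure=consensus,
            metrics=metrics,
            centroid=centroid,
            member_similarities=sims,
        )

    return refiner


def cluster_sequences(
    records: list[SeqRecord],
    params: PipelineParams = PipelineParams(),
    precomputed_structures: Optional[dict[str, SecondaryStructure]] = None,
) -> ClusterResult:
    """Run the full clustering workflow over a set of sequences."""
    redundancy_map: dict[str, str] = {}
    if params.prefilter_identity is not None:
        records, redundancy_map = filter_redundant(records, params.prefilter_identity)
        logger.info(
            "redundancy pre-filter kept %d representatives (%d mapped members)",
            len(records), len(redundancy_map),
        )
    windows = prepare_windows(records, params)
    structures = fold_windows(windows, params, precomputed_structures)
    vectors = featurize(windows, structures, params)
    counter = [0]
    refiner = make_refiner(windows, structures, vectors, params, counter)
    state = RoundState(round_index=1, unclustered_ids=set(windows))
    rounds = 0
    for _ in range(params.max_rounds):
        if not state.unclustered_ids:
            break
        before = len(state.accepted_clusters)
        state = run_round(state, vectors, params.cluster_params, refiner)
        rounds += 1
        if len(state.accepted_clusters) == before:
            break  # no candidate survived refinement: iteration has converged
    clusters: list[Cluster] = list(state.accepted_clusters)
    partition = report_partition(clusters, params.partition_mode)
    partition.unclustered = set(state.unclustered_ids)
    return ClusterResult(
        clusters=clusters,
        partition=partition,
        windows=windows,
        structures=structures,
        vectors=vectors,
        unclustered=set(state.unclustered_ids),
        rounds_run=rounds,
        redundancy_map=redundancy_map,
        candidate_log=list(state.candidate_log),
    )


def write_reports(result: ClusterResult, outdir) -> None:
    """Write the cluster TSV, per-cluster alignments + consensus, metrics
    JSON, and the partition TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\twindow_id\tparent_id\tstart\tend\tsource\n")
        for cl in result.clusters:
            for m in cl.members:
                w = result.windows[m]
                fh.write(
                    f"{cl.cluster_id}\t{m}\t{w.parent_id}\t{w.start}\t{w.end}\t"
                    f"{cl.sources[m]}\n"
                )
    metrics = {}
    for cl in result.clusters:
        metrics[str(cl.cluster_id)] = {
            **{k: v for k, v in cl.metrics.items()},
            "n_members": len(cl.members),
        }
        if cl.alignment is not None:
            with open(outdir / f"cluster_{cl.cluster_id}.aln.fa", "w") as fh:
                for rid in cl.alignment.ids:
                    fh.write(f">{rid}\n{cl.alignment.rows[rid]}\n")
                fh.write(f">consensus_structure\n{cl.consensus_structure.dotbracket}\n")
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    if result.candidate_log:
        with open(outdir / "candidates.tsv", "w") as fh:
            fh.write("round\tcandidate_id\tcenter_id\tmember_id\test_similarity\n")
            for rnd, rank, center, member, sim in result.candidate_log:
                fh.write(f"{rnd}\t{rnd}.{rank}\t{center}\t{member}\t{sim:.4f}\n")
    if result.redundancy_map:
        with open(outdir / "redundancy.tsv", "w") as fh:
            fh.write("member_id\trepresentative_id\n")
            for m, rep in sorted(result.redundancy_map.items()):
                fh.write(f"{m}\t{rep}\n")
    seq_part = result.sequence_partition()  # sequence-level: the core output
    with open(outdir / "partition.tsv", "w") as fh:
        fh.write("element\tcluster_ids\n")
        for eid in sorted(seq_part.assignments):
            cids = ",".join(str(c) for c in sorted(seq_part.assignments[eid]))
            fh.write(f"{eid}\t{cids}\n")
        for eid in sorted(seq_part.unclustered):
            fh.write(f"{eid}\t-\n")
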