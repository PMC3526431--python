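"""Pipeline orchestration: the iterative tile-assemble-cluster loop.

Two entry modes:

* **R** (random start): reads are partitioned randomly and evenly into N
  tiles, each tile is assembled with the auto-k scheme, and the merged
  (optionally elongated) contig set becomes the first intermediate
  reference.
* **I** (improve): an existing assembly is taken as the intermediate
  reference directly and the loop starts at contig clustering.

Each iteration then: clusters the intermediate reference's contigs into C
groups, re-clusters all input reads against those groups (mate rescue,
multi-cluster membership), re-assembles every read tile, merges, and
optionally elongates the merged set.  The merged-set elongation is skipped
permanently after the first iteration in which it fails to improve, since
it mainly pays off while contigs are still short.  The loop runs for a
fixed user-chosen iteration budget.

Determinism: every random choice derives from the config seed, the
iteration index and the tile index, so a run is a pure function of (reads,
config) — including across checkpoint/resume and serial vs. parallel
execution (tile tasks share no state and results are gathered in tile
order).
"""

from __future__ import annotations

import logging
import pickle
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .contig_clustering import cluster_contigs
from .metrics import EvalReport, evaluate
from .read_clustering import cluster_reads
from .seq_io import ContigSet, Read, pair_up, write_fasta
from .tile_assembly import (
    AssemblyScore,
    ConfigurationError,
    KmerHistory,
    ReadTile,
    assemble_tile,
    elongate_merged_detailed,
    merge_contig_sets,
    partition_reads_random,
    score_assembly,
    select_kmers,
)

log = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


class ResumeError(RuntimeError):
    pass


@dataclass(frozen=True)
class TigerConfig:
    """All pipeline knobs.  ``n_clusters`` defaults to ``n_tiles``."""

    mode: str = "R"
    n_tiles: int = 8
    n_clusters: int | None = None
    iterations: int = 3
    k_min: int = 21
    k_max: int = 61
    n_candidates: int = 3
    seed: int = 0
    word_w: int = 32
    word_step: int = 4
    edge_min: int = 1
    max_postings: int | None = 50
    vertex_scale: int = 1000
    balance_eps: float = 0.3
    seed_length: int = 20
    max_mismatch: int = 2
    multiplicity_cap: bool = True
    min_contig: int = 200
    coverage_cutoff: int = 2
    threads: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("R", "I"):
            raise ConfigurationError("mode must be 'R' or 'I'")
        if self.n_tiles < 1 or self.iterations < 1:
            raise ConfigurationError("n_tiles and iterations must be >= 1")
        if (self.n_clusters is not None and self.n_clusters < 1):
            raise ConfigurationError("n_clusters must be >= 1")
        if self.k_min % 2 == 0 or self.k_max % 2 == 0 or self.k_min > self.k_max:
            raise ConfigurationError("k range must be odd with k_min <= k_max")
        if self.n_candidates < 1 or self.threads < 1:
            raise ConfigurationError("n_candidates and threads must be >= 1")

    @property
    def clusters(self) -> int:
        return self.n_clusters if self.n_clusters is not None else self.n_tiles


@dataclass
class ElongationTraceEntry:
    iteration: int
    attempted: bool
    improved: bool


@dataclass
class IterationState:
    """Mutable loop state, checkpointable between iterations."""

    config: TigerConfig
    iteration: int  # last completed iteration (0 = initial assembly round)
    merged: ContigSet
    histories: dict[int, KmerHistory]
    merged_assembly_enabled: bool
    reports: list[tuple[int, EvalReport]] = field(default_factory=list)
    elongation_trace: list[ElongationTraceEntry] = field(default_factory=list)


@dataclass
class TigerResult:
    contigs: ContigSet
    state: IterationState

    @property
    def reports(self) -> list[tuple[int, EvalReport]]:
        return self.state.reports


def _sub_seed(seed: int, iteration: int, tile: int) -> int:
    return (seed * 1000003 + iteration * 10007 + tile * 101 + 17) % (2**31 - 1)


def _assemble_tile_task(args) -> tuple[int, ContigSet, list[tuple[int, AssemblyScore, float]]]:
    """Assemble one tile trying several k values; pure function of its
    arguments, safe for process pools."""
    tile_index, reads, ks, min_contig, coverage_cutoff, iteration = args
    records: list[tuple[int, AssemblyScore, float]] = []
    best_contigs = ContigSet(label=f"i{iteration}t{tile_index}")
    best_key: tuple[float, int] | None = None
    for k in ks:
        contigs, used = assemble_tile(
            reads,
            k,
            min_contig=min_contig,
            coverage_cutoff=coverage_cutoff,
            label=f"i{iteration}t{tile_index}k{k}",
        )
        score, comp = score_assembly(contigs, used, len(reads))
        records.append((k, score, comp))
        key = (-comp, k)  # higher composite wins; ties prefer smaller k
        if best_key is None or key < best_key:
            best_key = key
            best_contigs = contigs
    return tile_index, best_contigs, records


def _run_assembly_round(
    tiles: Sequence[ReadTile],
    pairs: Mapping[str, tuple[Read, Read]],
    histories: dict[int, KmerHistory],
    config: TigerConfig,
    iteration: int,
) -> list[ContigSet]:
    tasks = []
    for tile in tiles:
        hist = histories.setdefault(tile.index, KmerHistory())
        ks = select_kmers(
            hist,
            (config.k_min, config.k_max),
            config.n_candidates,
            seed=_sub_seed(config.seed, iteration, tile.index),
        )
        tasks.append(
            (
                tile.index,
                tile.reads(pairs),
                ks,
                config.min_contig,
                config.coverage_cutoff,
                iteration,
            )
        )
    if config.threads > 1:
        with ProcessPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(_assemble_tile_task, tasks))
    else:
        results = [_assemble_tile_task(t) for t in tasks]
    results.sort(key=lambda r: r[0])  # gather in tile order regardless of scheduling
    contig_sets: list[ContigSet] = []
    for tile_index, contigs, records in results:
        for k, score, comp in records:
            histories[tile_index].record(k, score, comp)
        contig_sets.append(contigs)
    return contig_sets


def should_skip_merged(state: IterationState) -> bool:
    """The merged-set elongation is skipped once it has ever failed to
    improve; before that it stays enabled."""
    return not state.merged_assembly_enabled


def _maybe_elongate(state: IterationState, merged: ContigSet, iteration: int) -> ContigSet:
    if should_skip_merged(state) or len(merged) == 0:
        state.elongation_trace.append(
            ElongationTraceEntry(iteration=iteration, attempted=False, improved=False)
        )
        return merged
    res = elongate_merged_detailed(merged, min_contig=state.config.min_contig)
    state.elongation_trace.append(
        ElongationTraceEntry(iteration=iteration, attempted=True, improved=res.improved)
    )
    if not res.improved:
        state.merged_assembly_enabled = False
    return res.contigs


def _evaluate(state: IterationState, iteration: int, reference: ContigSet | None) -> None:
    if reference is None:
        return
    report = evaluate(state.merged, reference, min_contig=state.config.min_contig)
    state.reports.append((iteration, report))
    log.info("iteration %d: %s", iteration, report.pretty())


def run_tiger(
    config: TigerConfig,
    reads: Sequence[Read],
    initial_contigs: ContigSet | None = None,
    reference: ContigSet | None = None,
    checkpoint_dir: str | Path | None = None,
    resume_state: IterationState | None = None,
    out_dir: str | Path | None = None,
) -> TigerResult:
    """Run the full iterative assembly.

    Mode R requires no ``initial_contigs``; mode I requires them.  When
    ``reference`` is given, an evaluation report is recorded after the
    initial assembly round (mode R: iteration 0; mode I: the input contigs)
    and after every loop iteration.  ``checkpoint_dir`` stores one
    checkpoint per completed iteration; ``resume_state`` continues a prior
    run identically to an uninterrupted one.
    """
    if config.mode == "I" and initial_contigs is None:
        raise ConfigurationError("mode I requires initial_contigs")
    if config.mode == "R" and initial_contigs is not None:
        raise ConfigurationError("mode R forbids initial_contigs")

    pairs = pair_up(reads)

    if resume_state is not None:
        state = resume_state
        start_iteration = state.iteration + 1
    else:
        if config.mode == "R":
            tiles = partition_reads_random(reads, config.n_tiles, config.seed)
            log.info(
                "mode R: %d pairs in %d tiles (sizes %s...)",
                len(pairs),
                len(tiles),
                [len(t.members) for t in tiles[:8]],
            )
            histories: dict[int, KmerHistory] = {}
            state = IterationState(
                config=config,
                iteration=0,
                merged=ContigSet(label="empty"),
                histories=histories,
                merged_assembly_enabled=True,
            )
            contig_sets = _run_assembly_round(tiles, pairs, histories, config, 0)
            merged = merge_contig_sets(contig_sets, label="iter0", iteration=0)
            state.merged = _maybe_elongate(state, merged, 0)
        else:
            state = IterationState(
                config=config,
                iteration=0,
                merged=initial_contigs,
                histories={},
                merged_assembly_enabled=True,
            )
        _evaluate(state, 0, reference)
        if checkpoint_dir is not None:
            save_checkpoint(state, Path(checkpoint_dir) / "iter0.ckpt")
        start_iteration = 1

    for it in range(start_iteration, config.iterations + 1):
        if len(state.merged) == 0:
            log.warning("iteration %d: empty intermediate reference; re-tiling randomly", it)
            tiles = partition_reads_random(
                reads, config.n_tiles, _sub_seed(config.seed, it, 0)
            )
        else:
            clusters = cluster_contigs(
                state.merged,
                min(config.clusters, len(state.merged)),
                w=config.word_w,
                step=config.word_step,
                edge_min=config.edge_min,
                max_postings=config.max_postings,
                vertex_scale=config.vertex_scale,
                balance_eps=config.balance_eps,
                seed=_sub_seed(config.seed, it, 0),
            )
            crt = cluster_reads(
                reads,
                clusters,
                state.merged,
                seed_length=config.seed_length,
                max_mismatch=config.max_mismatch,
                multiplicity_cap=config.multiplicity_cap,
            )
            tiles = list(crt.tiles)
            # Recycle unplaced pairs into dedicated rescue tiles (bounded at
            # the average tile size): genome regions absent from the
            # intermediate reference keep their reads concentrated, so they
            # can nucleate new contigs at full coverage instead of being
            # diluted across all tiles.
            unplaced = sorted(crt.unplaced)
            if unplaced:
                import numpy as np

                rng = np.random.default_rng(_sub_seed(config.seed, it, 9999))
                order = [unplaced[i] for i in rng.permutation(len(unplaced))]
                target = max(1, len(pairs) // config.clusters)
                n_rescue = -(-len(order) // target)  # ceil
                base, extra = divmod(len(order), n_rescue)
                pos = 0
                for r in range(n_rescue):
                    size = base + (1 if r < extra else 0)
                    tiles.append(
                        ReadTile(
                            index=len(crt.tiles) + r,
                            members=order[pos : pos + size],
                        )
                    )
                    pos += size
            log.info(
                "iteration %d: tiles %s, %d unplaced pairs recycled",
                it,
                [len(t.members) for t in tiles],
                len(crt.unplaced),
            )
        contig_sets = _run_assembly_round(tiles, pairs, state.histories, config, it)
        merged = merge_contig_sets(contig_sets, label=f"iter{it}", iteration=it)
        if len(merged) == 0:
            log.warning("iteration %d produced no contigs; keeping previous reference", it)
            merged = state.merged
            state.elongation_trace.append(
                ElongationTraceEntry(iteration=it, attempted=False, improved=False)
            )
        else:
            merged = _maybe_elongate(state, merged, it)
        state.merged = merged
        state.iteration = it
        _evaluate(state, it, reference)
        if checkpoint_dir is not None:
            save_checkpoint(state, Path(checkpoint_dir) / f"iter{it}.ckpt")
        if out_dir is not None:
            write_fasta(state.merged, Path(out_dir) / f"contigs_iter{it}.fasta")

    if out_dir is not None:
        write_fasta(state.merged, Path(out_dir) / "contigs_final.fasta")
    return TigerResult(contigs=state.merged, state=state)


def save_checkpoint(state: IterationState, path: str | Path) -> None:
    payload = {"version": CHECKPOINT_VERSION, "state": state}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path: str | Path) -> IterationState:
    p = Path(path)
    if not p.exists():
        raise ResumeError(f"checkpoint {p} does not exist")
    with open(p, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != CHECKPOINT_VERSION:
        raise ResumeError(
            f"checkpoint version {payload.get('version')} != {CHECKPOINT_VERSION}"
        )
    return payload["state"]


def resume_tiger(
    checkpoint_path: str | Path,
    reads: Sequence[Read],
    iterations: int | None = None,
    reference: ContigSet | None = None,
    checkpoint_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> TigerResult:
    """Continue a checkpointed run; the continuation is identical to the
    uninterrupted run because all per-iteration seeds derive from the config."""
    state = load_checkpoint(checkpoint_path)
    config = state.config
    if iterations is not None:
        config = replace(config, iterations=iterations)
        state.config = config
    return run_tiger(
        config,
        reads,
        initial_contigs=None,
        reference=reference,
        checkpoint_dir=checkpoint_dir,
        resume_state=state,
        out_dir=out_dir,
    )
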