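"""Simulator of barcoded clonal evolution under drug selection.

The stated world mirrors a lentiviral barcoding experiment: founder cells
are transduced at low MOI (Poisson integrations; unbarcoded cells are
removed by antibiotic selection), expanded to >100x coverage per treatment
group, split multinomially into one vehicle control and several treated
replicates, and treated for 40 days.  During treatment, sensitive cells die
daily; a small drug-tolerant persister compartment survives and divides
slowly, converting to stable resistance at a small per-division probability
(late-emerging resistance); a rare fraction of founder clones is resistant
before treatment (preexisting resistance) and grows exponentially with a
clone-specific fitness.  Final pools are read out by multinomial sequencing
sampling with optional per-base substitution errors, either as a count
table or as FASTQ reads embedding each barcode in the full cassette motif
behind a 0-8 nt stagger.

Every stochastic step draws from a single seeded generator, so identical
config + seed give byte-identical outputs.  Ground truth (clone origins,
per-day trajectories, acquisition days) is retained so that enrichment
calling and origin inference can be scored against the planted answer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon_io import (
    NO_REFERENCE_MATCH,
    BarcodeCountTable,
    ReadRecord,
    write_fastq,
)
from .cassette_design import PROTOSPACER_LEN, CassetteSpec

ORIGIN_PRE = "preexisting"
ORIGIN_ACQ = "acquired"
ORIGIN_NEVER = "never_resistant"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated experiment (defaults are the stated
    world, a ~150x scale-down of the original 3e6-founder screen)."""

    n_founders: int = 20_000          # cells exposed to virus
    library_size: int = 200_000       # distinct barcodes in the library
    library_skew: float = 1.0         # lognormal sigma of barcode weights
    moi: float = 0.3                  # Poisson mean integrations per cell
    expansion_coverage: int = 120     # target cells/clone per treatment group
    expansion_death_prob: float = 0.05
    rho_pre: float = 7e-4             # preexisting-resistant clone fraction
    persister_fraction: float = 0.01
    persister_division_rate: float = 0.2   # turnover divisions per persister per day
    mu_acq: float = 2e-4              # per-division acquisition probability
    kill_prob_sensitive: float = 0.35      # per-day death under drug
    resistant_fitness_mean: float = 1.3    # per-day growth factor
    resistant_fitness_sd: float = 0.15
    days: int = 40
    n_replicates: int = 5
    depth: int = 100_000              # reads per sample
    seq_error: float = 1e-3           # per-base substitution rate
    stagger_max: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_pre", "persister_fraction", "mu_acq",
                     "kill_prob_sensitive", "expansion_death_prob",
                     "seq_error"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.days < 1 or self.depth < 1:
            raise ValueError("days and depth must be >= 1")
        if self.moi <= 0:
            raise ValueError("moi must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return ["control"] + [f"R{i + 1}" for i in range(self.n_replicates)]


@dataclass
class FounderPool:
    """Barcoded founder clones (one clone per transduced cell)."""

    clone_barcodes: list[tuple[int, ...]]   # library indices per clone
    barcode_keys: dict[int, str]            # library index -> 40-nt key
    preexisting: np.ndarray                 # bool per clone
    cells: np.ndarray                       # int per clone
    multi_barcode_fraction: float
    dropout: np.ndarray | None = None       # bool per clone after expansion

    @property
    def n_clones(self) -> int:
        return len(self.clone_barcodes)


def _random_keys(rng: np.random.Generator, n: int) -> list[str]:
    """n distinct random 40-nt barcode keys (order is draw order, so the
    result is fully determined by the generator state)."""
    seen: set[str] = set()
    keys: list[str] = []
    while len(keys) < n:
        block = rng.integers(0, 4, size=(n - len(keys), 2 * PROTOSPACER_LEN))
        for row in block:
            key = "".join("ACGT"[b] for b in row)
            if key not in seen:
                seen.add(key)
                keys.append(key)
    return keys


def barcode_founders(config: SimConfig, rng: np.random.Generator) -> FounderPool:
    """Transduce founders: Poisson(moi) integrations per cell, skewed
    barcode sampling weights, zero-integration cells discarded (antibiotic
    selection); multi-barcode cells are kept and tracked."""
    if config.library_size < config.n_founders:
        warnings.warn(
            "library_size < n_founders: heavy barcode collisions expected"
        )
    n_int = rng.poisson(config.moi, size=config.n_founders)
    n_int = n_int[n_int > 0]
    total = int(n_int.sum())
    weights = rng.lognormal(0.0, config.library_skew, size=config.library_size)
    weights /= weights.sum()
    draws = rng.choice(config.library_size, size=total, p=weights)
    clone_barcodes: list[tuple[int, ...]] = []
    pos = 0
    for k in n_int:
        clone_barcodes.append(tuple(sorted(set(draws[pos : pos + k]))))
        pos += k
    used = sorted({b for bc in clone_barcodes for b in bc})
    key_list = _random_keys(rng, len(used))
    barcode_keys = dict(zip(used, key_list))
    preexisting = rng.random(len(clone_barcodes)) < config.rho_pre
    multi = sum(len(bc) > 1 for bc in clone_barcodes)
    return FounderPool(
        clone_barcodes=clone_barcodes,
        barcode_keys=barcode_keys,
        preexisting=preexisting,
        cells=np.ones(len(clone_barcodes), dtype=np.int64),
        multi_barcode_fraction=multi / len(clone_barcodes),
    )


def expand(
    pool: FounderPool, config: SimConfig, rng: np.random.Generator
) -> FounderPool:
    """Galton-Watson expansion (doubling with a small death probability)
    until mean cells per surviving clone covers every treatment group."""
    if pool.n_clones == 0:
        raise ValueError("empty founder pool")
    target = config.expansion_coverage * (config.n_replicates + 1)
    cells = pool.cells.copy()
    guard = 0
    while cells.sum() < target * pool.n_clones and guard < 200:
        survivors = rng.binomial(cells, 1.0 - config.expansion_death_prob)
        cells = 2 * survivors
        guard += 1
        if cells.sum() == 0:
            break
    pool.cells = cells
    pool.dropout = cells == 0
    return pool


@dataclass
class TreatmentResult:
    """Per-replicate daily trajectories and final compartment counts."""

    sample_ids: list[str]
    trajectories: np.ndarray       # (n_samples, days+1, n_clones) total cells
    final_resistant: np.ndarray    # (n_replicates, n_clones)
    acquired_day: np.ndarray       # (n_replicates, n_clones), -1 = never
    fitness: np.ndarray            # per clone per-day growth factor
    audit: pd.DataFrame            # per (replicate, day): births and deaths
    extinct_replicates: list[str] = field(default_factory=list)

    @property
    def final_counts(self) -> np.ndarray:
        """(n_clones, n_samples) cell counts at the end of treatment."""
        return self.trajectories[:, -1, :].T


def treat(
    pool: FounderPool, config: SimConfig, rng: np.random.Generator
) -> TreatmentResult:
    """Split the expanded pool into control + replicates and run the daily
    kill / persist / acquire / grow dynamics for ``config.days`` days."""
    n_groups = config.n_replicates + 1
    n_clones = pool.n_clones
    splits = rng.multinomial(pool.cells, [1.0 / n_groups] * n_groups)
    fitness = np.exp(
        rng.normal(
            np.log(config.resistant_fitness_mean),
            config.resistant_fitness_sd / config.resistant_fitness_mean,
            size=n_clones,
        )
    )
    traj = np.zeros((n_groups, config.days + 1, n_clones), dtype=np.int64)
    final_resistant = np.zeros((config.n_replicates, n_clones), dtype=np.int64)
    acquired_day = np.full((config.n_replicates, n_clones), -1, dtype=np.int64)
    audit_rows = []
    extinct: list[str] = []
    sample_ids = config.sample_ids

    # vehicle control: no drug kill; baseline distribution held static
    traj[0, :, :] = splits[:, 0]

    for rep in range(config.n_replicates):
        start = splits[:, rep + 1]
        resistant = np.where(pool.preexisting, start, 0).astype(np.int64)
        sensitive = start - resistant
        persister = rng.binomial(sensitive, config.persister_fraction)
        sensitive = sensitive - persister
        traj[rep + 1, 0, :] = sensitive + persister + resistant
        for day in range(1, config.days + 1):
            prev_total = sensitive + persister + resistant
            surv = rng.binomial(sensitive, 1.0 - config.kill_prob_sensitive)
            deaths = int((sensitive - surv).sum())
            sensitive = surv
            # persisters are a maintained slow-cycling pool: divisions are
            # turnover (daughter replaces mother), so the compartment does
            # not expand; a dividing persister converts with prob mu_acq
            divisions = rng.binomial(persister, config.persister_division_rate)
            converts = rng.binomial(divisions, config.mu_acq)
            persister = persister - converts
            newly = (converts > 0) & (acquired_day[rep] < 0)
            acquired_day[rep, newly] = day
            resistant = resistant + converts
            grown = rng.poisson(resistant * fitness)
            births = int((grown - resistant).clip(min=0).sum())
            deaths += int((resistant - grown).clip(min=0).sum())
            resistant = grown
            total = sensitive + persister + resistant
            traj[rep + 1, day, :] = total
            audit_rows.append(
                {
                    "sample": sample_ids[rep + 1],
                    "day": day,
                    "births": births,
                    "deaths": deaths,
                    "total_prev": int(prev_total.sum()),
                    "total": int(total.sum()),
                }
            )
        final_resistant[rep] = resistant
        if traj[rep + 1, -1, :].sum() == 0:
            extinct.append(sample_ids[rep + 1])
    return TreatmentResult(
        sample_ids=sample_ids,
        trajectories=traj,
        final_resistant=final_resistant,
        acquired_day=acquired_day,
        fitness=fitness,
        audit=pd.DataFrame(audit_rows),
        extinct_replicates=extinct,
    )


@dataclass
class SimOutput:
    """Sequencing readout plus the planted ground truth."""

    table: BarcodeCountTable
    truth: pd.DataFrame
    pool: FounderPool
    result: TreatmentResult
    config: SimConfig
    fastq_paths: dict[str, Path] | None = None


def _barcode_cell_counts(
    pool: FounderPool, clone_counts: np.ndarray
) -> dict[int, int]:
    """Aggregate clone cell counts to barcode cell counts (a multi-barcode
    cell contributes its count to every barcode it carries)."""
    out: dict[int, int] = {}
    for clone, bcs in enumerate(pool.clone_barcodes):
        c = int(clone_counts[clone])
        if c:
            for b in bcs:
                out[b] = out.get(b, 0) + c
    return out


def _mutate_reads(
    seqs: list[str], seq_error: float, rng: np.random.Generator
) -> list[str]:
    if seq_error <= 0:
        return seqs
    out = []
    for s in seqs:
        arr = np.frombuffer(s.encode(), dtype="S1").copy()
        hits = np.nonzero(rng.random(len(arr)) < seq_error)[0]
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(0, len(choices))]
        out.append(arr.tobytes().decode())
    return out


def sequence(
    pool: FounderPool,
    result: TreatmentResult,
    config: SimConfig,
    rng: np.random.Generator,
    as_fastq: bool = False,
    out_dir: str | Path | None = None,
    spec: CassetteSpec | None = None,
) -> SimOutput:
    """Multinomial read sampling of the final pools.

    Count mode applies sequencing errors as per-read survival thinning
    (an errored read no longer matches the reference exactly); FASTQ mode
    writes reads embedding each barcode in the full cassette motif behind a
    random 0-``stagger_max`` nt prefix, with per-base substitution errors.
    """
    spec = spec or CassetteSpec()
    final = result.final_counts  # (n_clones, n_samples)
    if final.sum() == 0:
        raise ValueError("all pools are empty: nothing to sequence")
    counts_per_sample: dict[str, dict[str, int]] = {}
    unassigned: dict[str, dict[str, int]] = {}
    fastq_paths: dict[str, Path] | None = {} if as_fastq else None
    all_keys: set[str] = set()
    for si, sample in enumerate(result.sample_ids):
        bc_cells = _barcode_cell_counts(pool, final[:, si])
        if not bc_cells:
            counts_per_sample[sample] = {}
            unassigned[sample] = {NO_REFERENCE_MATCH: 0}
            continue
        bcs = list(bc_cells)
        cells = np.array([bc_cells[b] for b in bcs], dtype=float)
        reads = rng.multinomial(config.depth, cells / cells.sum())
        sample_counts: dict[str, int] = {}
        lost = 0
        if as_fastq:
            records = []
            ridx = 0
            seqs: list[str] = []
            names: list[str] = []
            for b, r in zip(bcs, reads):
                if r == 0:
                    continue
                key = pool.barcode_keys[b]
                cassette = (
                    spec.five_flank + key[:PROTOSPACER_LEN] + spec.linker
                    + key[PROTOSPACER_LEN:] + spec.three_flank
                )
                for _ in range(int(r)):
                    stag = int(rng.integers(0, config.stagger_max + 1))
                    prefix = "".join(
                        "ACGT"[x] for x in rng.integers(0, 4, size=stag)
                    )
                    seqs.append(prefix + cassette)
                    names.append(f"{sample}:{ridx}")
                    ridx += 1
            seqs = _mutate_reads(seqs, config.seq_error, rng)
            records = [ReadRecord(n, s) for n, s in zip(names, seqs)]
            out_dir = Path(out_dir or ".")
            out_dir.mkdir(parents=True, exist_ok=True)
            path = out_dir / f"{sample}.fastq"
            write_fastq(records, path)
            fastq_paths[sample] = path
            # the count table in FASTQ mode reflects error-free assignment
            # intent; re-counting from the FASTQ gives the observed table
            for b, r in zip(bcs, reads):
                if r:
                    sample_counts[pool.barcode_keys[b]] = int(r)
        else:
            p_survive = (1.0 - config.seq_error) ** spec.motif_length
            for b, r in zip(bcs, reads):
                if r == 0:
                    continue
                kept = int(rng.binomial(r, p_survive)) if config.seq_error else int(r)
                lost += int(r) - kept
                if kept:
                    sample_counts[pool.barcode_keys[b]] = kept
        counts_per_sample[sample] = sample_counts
        unassigned[sample] = {NO_REFERENCE_MATCH: lost}
        all_keys.update(sample_counts)

    keys = sorted(all_keys)
    mat = pd.DataFrame(
        {
            s: [counts_per_sample[s].get(k, 0) for k in keys]
            for s in result.sample_ids
        },
        index=pd.Index(keys, name="barcode_key"),
        dtype=np.int64,
    )
    table = BarcodeCountTable(counts=mat, unassigned=unassigned)
    truth = _truth_table(pool, result, config)
    return SimOutput(
        table=table,
        truth=truth,
        pool=pool,
        result=result,
        config=config,
        fastq_paths=fastq_paths,
    )


def _truth_table(
    pool: FounderPool, result: TreatmentResult, config: SimConfig
) -> pd.DataFrame:
    """One row per (clone, barcode): origin, per-replicate resistance and
    acquisition day, final cell counts per sample."""
    rows = []
    final = result.final_counts
    for clone, bcs in enumerate(pool.clone_barcodes):
        if pool.preexisting[clone]:
            origin = ORIGIN_PRE
        elif (result.acquired_day[:, clone] >= 0).any():
            origin = ORIGIN_ACQ
        else:
            origin = ORIGIN_NEVER
        for b in bcs:
            row: dict[str, object] = {
                "clone_id": clone,
                "barcode_key": pool.barcode_keys[b],
                "origin": origin,
                "n_barcodes_in_clone": len(bcs),
            }
            for si, sample in enumerate(result.sample_ids):
                row[f"cells_{sample}"] = int(final[clone, si])
            for rep in range(config.n_replicates):
                rid = result.sample_ids[rep + 1]
                row[f"resistant_{rid}"] = bool(result.final_resistant[rep, clone] > 0)
                row[f"acquired_day_{rid}"] = int(result.acquired_day[rep, clone])
            rows.append(row)
    return pd.DataFrame(rows)


def simulate(
    config: SimConfig,
    as_fastq: bool = False,
    out_dir: str | Path | None = None,
) -> SimOutput:
    """Full pipeline: transduce, expand, treat, sequence."""
    rng = np.random.default_rng(config.seed)
    pool = barcode_founders(config, rng)
    expand(pool, config, rng)
    result = treat(pool, config, rng)
    return sequence(pool, result, config, rng, as_fastq=as_fastq, out_dir=out_dir)


@dataclass
class PipelineEvaluation:
    precision: float
    recall: float
    n_true: int
    n_called: int
    confusion: pd.DataFrame


def evaluate_pipeline(
    sim_output: SimOutput,
    enrichment,  # clonal_stats.EnrichmentSummary
    share_floor: float = 0.01,
) -> PipelineEvaluation:
    """Score enrichment calls against the planted resistant clones.

    Precision/recall are computed per replicate over barcodes whose final
    cell share in that replicate exceeds ``share_floor`` and then pooled
    (micro-averaged).  The confusion matrix cross-tabulates planted origin
    {preexisting, acquired} with the recurrence-based call
    {all-replicates enriched, single-replicate enriched, intermediate}.
    """
    truth = sim_output.truth
    reps = [s for s in sim_output.result.sample_ids if s != "control"]
    tp = fp = fn = 0
    for rep in reps:
        cells = truth.groupby("barcode_key")[f"cells_{rep}"].sum()
        total = cells.sum()
        if total == 0:
            continue
        shares = cells / total
        resistant = truth.groupby("barcode_key")[f"resistant_{rep}"].any()
        big = set(shares[shares > share_floor].index)
        true_set = {b for b in big if resistant.get(b, False)}
        called = enrichment.enriched_sets.get(rep, set()) & big
        tp += len(called & true_set)
        fp += len(called - true_set)
        fn += len(true_set - called)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0

    n_rep = len(reps)
    origin_by_key = truth.groupby("barcode_key")["origin"].agg(
        lambda s: ORIGIN_PRE if (s == ORIGIN_PRE).any()
        else (ORIGIN_ACQ if (s == ORIGIN_ACQ).any() else ORIGIN_NEVER)
    )
    confusion = pd.DataFrame(
        0,
        index=[ORIGIN_PRE, ORIGIN_ACQ, ORIGIN_NEVER],
        columns=["all_replicates", "single_replicate", "intermediate"],
    )
    for b in enrichment.union:
        m = enrichment.replicate_count(b)
        col = (
            "all_replicates" if m == n_rep
            else "single_replicate" if m == 1
            else "intermediate"
        )
        confusion.loc[origin_by_key.get(b, ORIGIN_NEVER), col] += 1
    return PipelineEvaluation(
        precision=precision,
        recall=recall,
        n_true=tp + fn,
        n_called=tp + fp,
        confusion=confusion,
    )
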