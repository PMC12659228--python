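"""Paired-end read generation from mutated genomes under learned models.

Reads start inside BED regions of the mutated genome: a region is chosen
with probability proportional to its RDM total and the start position
within the region proportional to the RDM per-position counts (both
uniform once the RDM has been disabled).  Bases are copied from the
haplotype sequence, substitution errors are injected per PBEM position
when enabled, and qualities are drawn from the per-cycle QM histograms.

The number of reads realising a coverage target ``C`` over a genome of
interest of ``G`` bases (the summed BED region lengths) at read length
``L`` is ``N = ceil(G*C/L)``, counted in single reads; paired mode
rounds up to an even count.

Mixing distributes that total over clones and haplotypes: reads per
(clone, haplotype) are proportional to clone_prop x hap_prop with
largest-remainder correction so the grand total is exact; heterozygous
variants (haplotype 0 only) then surface at a VAF of
clone_prop x hap0_prop, homozygous ones at clone_prop.  Every read name
follows ``{clone}|{hap}|{serial}/{mate}`` so reads remain traceable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .read_models import ModelBundle
from .genome_editor import reverse_complement

__all__ = [
    "GenerateError",
    "ReadRequest",
    "SimRead",
    "GenerationResult",
    "MixPlan",
    "compute_n_reads",
    "sample_starts",
    "generate_reads",
    "allocate_mix",
    "mix",
    "merge_reads",
    "write_fastq",
]


class GenerateError(ValueError):
    pass


@dataclass(frozen=True)
class ReadRequest:
    read_length: int
    n_reads: int
    paired: bool = True
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    clone: str = "clone0"
    hap: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise GenerateError("read_length must be >= 1")
        if self.n_reads < 0:
            raise GenerateError("n_reads must be >= 0")
        if self.paired and self.n_reads % 2:
            raise GenerateError("paired mode needs an even n_reads")
        if self.fragment_mean < self.read_length:
            raise GenerateError("fragment mean must be >= read length")


@dataclass
class SimRead:
    name: str
    seq: str
    qual: str
    mate: int  # 1 or 2 (1 when unpaired)
    chrom: str
    start: int  # j-coordinate of the leftmost base of this read
    reverse: bool = False  # True when seq is the reverse complement


@dataclass
class GenerationResult:
    reads: list[SimRead]
    region_start_counts: np.ndarray  # reads initiated per region
    position_start_counts: list[np.ndarray]  # per region, per position


def compute_n_reads(G: int, C: float, L: int, paired: bool = False) -> int:
    """ceil(G*C/L) single reads; paired mode rounds up to even."""
    if G <= 0 or C <= 0 or L <= 0:
        raise GenerateError("G, C and L must all be positive")
    n = math.ceil(G * C / L)
    if paired and n % 2:
        n += 1
    return n


def sample_starts(
    bundle: ModelBundle, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (region index, absolute start) pairs from the RDM."""
    totals = np.array(bundle.rdm.totals, dtype=float)
    if totals.sum() <= 0:
        raise GenerateError("RDM is empty: no region has any read starts")
    region_idx = rng.choice(len(totals), size=n, p=totals / totals.sum())
    starts = np.empty(n, dtype=np.int64)
    for ridx in np.unique(region_idx):
        mask = region_idx == ridx
        vec = bundle.rdm.vectors[ridx].astype(float)
        if vec.sum() <= 0:
            raise GenerateError(f"RDM region {ridx} has an all-zero start vector")
        offsets = rng.choice(len(vec), size=int(mask.sum()), p=vec / vec.sum())
        starts[mask] = bundle.regions[ridx][1] + offsets
    return region_idx, starts


def _quality_sampler(
    bundle: ModelBundle, L: int, rng: np.random.Generator
) -> Callable[[], np.ndarray]:
    """Per-cycle quality draws from the QM; a constant Q30 fallback is
    used for cycles beyond the learned read length."""
    tables: list[tuple[np.ndarray, np.ndarray]] = []
    for cycle in range(L):
        if cycle < bundle.qm.read_length and bundle.qm.histograms[cycle]:
            hist = bundle.qm.histograms[cycle]
            values = np.array(sorted(hist), dtype=np.int64)
            weights = np.array([hist[v] for v in sorted(hist)], dtype=float)
            tables.append((values, np.cumsum(weights / weights.sum())))
        else:
            tables.append((np.array([30]), np.array([1.0])))

    def draw() -> np.ndarray:
        u = rng.random(L)
        return np.array(
            [tables[c][0][np.searchsorted(tables[c][1], u[c])] for c in range(L)],
            dtype=np.int64,
        )

    return draw


_BASES = "ACGT"


def _error_table(bundle: ModelBundle) -> dict[tuple[str, int], tuple[int, tuple[int, ...]]]:
    table: dict[tuple[str, int], tuple[int, tuple[int, ...]]] = {}
    for ridx, entries in enumerate(bundle.pbem.entries):
        chrom = bundle.regions[ridx][0]
        for pos, depth, a, c, g, t in entries:
            table[(chrom, pos)] = (depth, (a, c, g, t))
    return table


def _phred_string(quals: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def generate_reads(
    genome: Mapping[str, str],
    bundle: ModelBundle,
    req: ReadRequest,
) -> GenerationResult:
    """Generate reads (pairs when requested) from one haplotype genome.

    The bundle must be in mutated (j) coordinates — or still in p space
    for an unedited genome.  With the PBEM disabled every read is an
    exact substring of the genome or its reverse complement.
    """
    if bundle.space not in ("p", "j"):
        raise GenerateError(f"unknown coordinate space {bundle.space!r}")
    L = req.read_length
    rng = np.random.default_rng(req.seed)
    for chrom, start, end in bundle.regions:
        if chrom not in genome:
            raise GenerateError(f"region chromosome {chrom!r} missing from genome")
        if len(genome[chrom]) < L:
            raise GenerateError(
                f"chromosome {chrom!r} shorter than the read length ({L})"
            )
    n_units = req.n_reads // 2 if req.paired else req.n_reads
    region_counts = np.zeros(len(bundle.regions), dtype=np.int64)
    position_counts = [np.zeros(e - s, dtype=np.int64) for _, s, e in bundle.regions]
    reads: list[SimRead] = []
    if n_units == 0:
        return GenerationResult(reads, region_counts, position_counts)

    region_idx, starts = sample_starts(bundle, n_units, rng)
    qdraw = _quality_sampler(bundle, L, rng)
    errors = _error_table(bundle) if bundle.pbem_enabled else {}

    def build_seq(chrom: str, start: int) -> str:
        raw = genome[chrom][start : start + L]
        if not errors:
            return raw
        bases = list(raw)
        for off in range(L):
            hit = errors.get((chrom, start + off))
            if hit is None:
                continue
            depth, counts = hit
            ref_i = _BASE_TO_IDX.get(bases[off].upper())
            nonref = [counts[b] for b in range(4) if b != ref_i] if ref_i is not None \
                else list(counts)
            total_err = sum(nonref)
            if depth <= 0 or total_err <= 0:
                continue
            if rng.random() < total_err / depth:
                pick = rng.choice(len(nonref), p=np.array(nonref) / total_err)
                alts = [b for b in range(4) if b != ref_i] if ref_i is not None \
                    else list(range(4))
                bases[off] = _BASES[alts[int(pick)]]
        return "".join(bases)

    for serial in range(n_units):
        ridx = int(region_idx[serial])
        start = int(starts[serial])
        chrom = bundle.regions[ridx][0]
        chrom_len = len(genome[chrom])
        start = min(start, chrom_len - L)
        region_counts[ridx] += 1
        r_start, r_end = bundle.regions[ridx][1], bundle.regions[ridx][2]
        if r_start <= start < r_end:
            position_counts[ridx][start - r_start] += 1
        name = f"{req.clone}|{req.hap}|{serial}"
        if not req.paired:
            seq = build_seq(chrom, start)
            reads.append(
                SimRead(f"{name}/1", seq, _phred_string(qdraw()), 1, chrom, start)
            )
            continue
        frag = int(round(rng.normal(req.fragment_mean, req.fragment_sd)))
        frag = max(L, min(frag, chrom_len - start))
        mate_start = start + frag - L
        fwd = build_seq(chrom, start)
        rev = reverse_complement(build_seq(chrom, mate_start))
        if rng.random() < 0.5:
            r1 = SimRead(f"{name}/1", fwd, _phred_string(qdraw()), 1, chrom, start)
            r2 = SimRead(f"{name}/2", rev, _phred_string(qdraw()), 2, chrom, mate_start, True)
        else:
            r1 = SimRead(f"{name}/1", rev, _phred_string(qdraw()), 1, chrom, mate_start, True)
            r2 = SimRead(f"{name}/2", fwd, _phred_string(qdraw()), 2, chrom, start)
        reads.extend([r1, r2])
    return GenerationResult(reads, region_counts, position_counts)


_BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# Mixing clones and haplotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixPlan:
    """Coverage target plus clone and haplotype read proportions."""

    coverage: float
    genome_size: int  # G: summed BED region lengths, bp
    read_length: int
    hap_props: tuple[float, float] = (0.5, 0.5)
    clone_props: Mapping[str, float] = field(default_factory=lambda: {"clone0": 1.0})
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise GenerateError("coverage must be positive")
        if abs(sum(self.hap_props) - 1.0) > 1e-6:
            raise GenerateError("haplotype proportions must sum to 1")
        if abs(sum(self.clone_props.values()) - 1.0) > 1e-6:
            raise GenerateError("clone proportions must sum to 1")


def allocate_mix(plan: MixPlan) -> dict[tuple[str, int], int]:
    """Reads per (clone, haplotype), largest-remainder corrected so the
    counts sum exactly to compute_n_reads(G, C, L)."""
    from .variant_designer import largest_remainder

    total = compute_n_reads(
        plan.genome_size, plan.coverage, plan.read_length, paired=plan.paired
    )
    units = total // 2 if plan.paired else total
    combos = [
        (clone, hap)
        for clone in plan.clone_props
        for hap in (0, 1)
    ]
    weights = [plan.clone_props[c] * plan.hap_props[h] for c, h in combos]
    unit_counts = largest_remainder(units, weights)
    factor = 2 if plan.paired else 1
    return {combo: n * factor for combo, n in zip(combos, unit_counts)}


def merge_reads(
    read_sets: Sequence[list[SimRead]], seed: int = 0
) -> list[SimRead]:
    """Merge read sets and shuffle, keeping mate pairs adjacent."""
    units: list[list[SimRead]] = []
    for reads in read_sets:
        i = 0
        while i < len(reads):
            if (
                i + 1 < len(reads)
                and reads[i].mate == 1
                and reads[i + 1].mate == 2
                and reads[i].name[:-2] == reads[i + 1].name[:-2]
            ):
                units.append([reads[i], reads[i + 1]])
                i += 2
            else:
                units.append([reads[i]])
                i += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    return [read for k in order for read in units[k]]


def mix(
    genomes: Mapping[tuple[str, int], Mapping[str, str]],
    bundles: Mapping[tuple[str, int], ModelBundle],
    plan: MixPlan,
    fragment_mean: float = 300.0,
    fragment_sd: float = 50.0,
) -> list[SimRead]:
    """Generate and merge reads for every (clone, haplotype) so the final
    sample realises the plan's coverage, VAF and clonality targets."""
    allocation = allocate_mix(plan)
    read_sets: list[list[SimRead]] = []
    for k, ((clone, hap), n) in enumerate(sorted(allocation.items())):
        if n == 0:
            continue
        if (clone, hap) not in genomes:
            raise GenerateError(f"no genome supplied for clone {clone!r} hap {hap}")
        req = ReadRequest(
            read_length=plan.read_length,
            n_reads=n,
            paired=plan.paired,
            fragment_mean=fragment_mean,
            fragment_sd=fragment_sd,
            clone=clone,
            hap=hap,
            seed=plan.seed + 1000 + k,
        )
        read_sets.append(generate_reads(genomes[(clone, hap)], bundles[(clone, hap)], req).reads)
    return merge_reads(read_sets, seed=plan.seed)


def write_fastq(
    reads: Sequence[SimRead],
    path1: str | Path,
    path2: str | Path | None = None,
) -> None:
    """Write FASTQ (Phred+33); with ``path2``, mates are split by file."""
    def emit(fh, read: SimRead) -> None:
        fh.write(f"@{read.name}\n{read.seq}\n+\n{read.qual}\n")

    if path2 is None:
        with open(path1, "w") as fh:
            for read in reads:
                emit(fh, read)
        return
    with open(path1, "w") as fh1, open(path2, "w") as fh2:
        for read in reads:
            emit(fh1 if read.mate == 1 else fh2, read)
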