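"""Synthetic inputs with known generating parameters.

These generators stand in for the real-world inputs of a simulation
run — a reference genome, aligned sequencing reads, and a mutation
catalogue export — while exposing the exact parameters used to build
them, so the learners and preset builders can be tested for parameter
recovery.  Every generator is a pure function of its arguments
(seed included).

The BAMs written here are genuinely aligned, coordinate-sorted and
indexed records (all-match CIGARs), so model learning exercises the
real I/O path rather than a shortcut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_editor import write_fasta
from .preset_builder import CATALOGUE_COLUMNS, VTYPES
from .var_model import GenomeIndex

__all__ = [
    "make_genome",
    "ReadsTruth",
    "make_aligned_reads",
    "CatalogueTruth",
    "make_catalogue",
]

_BASES = np.array(list("ACGT"))


def make_genome(
    lengths: Mapping[str, int],
    gc: float = 0.41,
    seed: int = 0,
    fasta_path: str | Path | None = None,
) -> tuple[dict[str, str], GenomeIndex]:
    """Random genome with the requested chromosome lengths and GC content."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {
        name: "".join(rng.choice(_BASES, size=n, p=p)) for name, n in lengths.items()
    }
    index = GenomeIndex(names=tuple(lengths), lengths=dict(lengths))
    if fasta_path is not None:
        write_fasta(seqs, fasta_path)
    return seqs, index


@dataclass
class ReadsTruth:
    """Generating parameters of a fixture BAM, for recovery tests."""

    coverage: float
    read_length: int
    error_rate: float
    quality_means: list[float]
    n_reads: int


def make_aligned_reads(
    genome: Mapping[str, str],
    bam_path: str | Path,
    coverage: float = 30.0,
    read_length: int = 100,
    error_rate: float = 0.0,
    quality_means: Sequence[float] | float = 35.0,
    quality_sd: float = 2.0,
    seed: int = 0,
    fixed_start: tuple[str, int] | None = None,
    alt_sites: Mapping[tuple[str, int], tuple[str, float]] | None = None,
    reference_fasta: str | Path | None = None,
) -> ReadsTruth:
    """Write a sorted, indexed fixture BAM with known technical truth.

    Reads are placed uniformly (or all at ``fixed_start``), substitution
    errors injected i.i.d. at ``error_rate`` per base, and qualities
    drawn per machine cycle around ``quality_means`` (scalar = flat
    profile).  ``alt_sites`` plants a non-reference allele at a site in
    the given fraction of covering reads, to exercise known-variant
    exclusion.  Half the reads are flagged reverse-strand (sequence
    stays reference-oriented; stored qualities are flipped accordingly).
    """
    import pysam

    rng = np.random.default_rng(seed)
    L = read_length
    chroms = list(genome)
    for c in chroms:
        if len(genome[c]) < L:
            raise ValueError(f"chromosome {c} shorter than the read length")
    total_len = sum(len(genome[c]) for c in chroms)
    n_reads = math.ceil(total_len * coverage / L)
    means = (
        [float(quality_means)] * L
        if np.isscalar(quality_means)
        else [float(q) for q in quality_means]
    )
    if len(means) != L:
        raise ValueError("quality_means must have one entry per cycle")

    placements: list[tuple[str, int]] = []
    if fixed_start is not None:
        placements = [fixed_start] * n_reads
    else:
        weights = np.array([len(genome[c]) for c in chroms], dtype=float)
        chrom_idx = rng.choice(len(chroms), size=n_reads, p=weights / weights.sum())
        for ci in chrom_idx:
            c = chroms[int(ci)]
            placements.append((c, int(rng.integers(0, len(genome[c]) - L + 1))))
    placements.sort(key=lambda pc: (chroms.index(pc[0]), pc[1]))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    alt_sites = alt_sites or {}
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for i, (chrom, start) in enumerate(placements):
            seq = list(genome[chrom][start : start + L].upper())
            # planted alleles first, then uniform sequencing errors on top
            for off in range(L):
                site = (chrom, start + off)
                if site in alt_sites:
                    alt, frac = alt_sites[site]
                    if rng.random() < frac:
                        seq[off] = alt
            if error_rate > 0:
                err_mask = rng.random(L) < error_rate
                for off in np.nonzero(err_mask)[0]:
                    current = seq[int(off)]
                    others = [b for b in "ACGT" if b != current]
                    seq[int(off)] = others[int(rng.integers(3))]
            quals_machine = np.clip(
                np.round(rng.normal(means, quality_sd)), 2, 41
            ).astype(np.int64)
            is_reverse = bool(i % 2)
            a = pysam.AlignedSegment()
            a.query_name = f"fix{i}"
            a.query_sequence = "".join(seq)
            a.flag = 16 if is_reverse else 0
            a.reference_id = chroms.index(chrom)
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{L}M"
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(
                    chr(int(q) + 33)
                    for q in (quals_machine[::-1] if is_reverse else quals_machine)
                )
            )
            bam.write(a)
    pysam.index(str(bam_path))
    if reference_fasta is not None:
        write_fasta(dict(genome), reference_fasta)
    return ReadsTruth(
        coverage=coverage,
        read_length=L,
        error_rate=error_rate,
        quality_means=means,
        n_reads=n_reads,
    )


@dataclass
class CatalogueTruth:
    """Generating parameters of a synthetic mutation catalogue."""

    type_props: dict[str, float]
    zyg_props: dict[str, float] | None
    mean_variants_per_sample: float
    mean_lengths: dict[str, float]
    n_samples: int
    n_records: int


def _hgvs_for(vtype: str, pos1: int, del_len: int, ins_len: int,
              rng: np.random.Generator) -> str:
    if vtype == "SNP":
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return f"g.{pos1}{ref}>{alt}"
    if vtype == "INS":
        return f"g.{pos1}_{pos1 + 1}ins{ins_len}"
    if vtype == "DEL":
        if del_len == 1:
            return f"g.{pos1}del"
        return f"g.{pos1}_{pos1 + del_len - 1}del"
    if vtype == "DUP":
        if ins_len == 1:
            return f"g.{pos1}dup"
        return f"g.{pos1}_{pos1 + ins_len - 1}dup"
    # DELINS
    if del_len == 1:
        return f"g.{pos1}delins{ins_len}"
    return f"g.{pos1}_{pos1 + del_len - 1}delins{ins_len}"


def make_catalogue(
    n_samples: int = 50,
    cancer_type: str = "breast",
    type_props: Mapping[str, float] | None = None,
    zyg_props: Mapping[str, float] | None = None,
    mean_variants: float = 80.0,
    mean_length: float | Mapping[str, float] = 4.0,
    chrom_lengths: Mapping[str, int] | None = None,
    seed: int = 0,
    tsv_path: str | Path | None = None,
) -> tuple[pd.DataFrame, CatalogueTruth]:
    """Synthetic COSMIC/TCGA-style catalogue with known structure.

    Per sample the variant count is Poisson(``mean_variants``), types
    multinomial over ``type_props``, positions uniform per chromosome
    (chromosome chosen proportionally to length), and event lengths
    1 + Poisson(``mean_length`` - 1).  ``zyg_props=None`` emulates a
    zygosity-free (TCGA-like) export: every record reads ``unknown``.
    """
    rng = np.random.default_rng(seed)
    type_props = dict(type_props or {
        "SNP": 0.5, "INS": 0.1, "DEL": 0.2, "DUP": 0.1, "DELINS": 0.1
    })
    if abs(sum(type_props.values()) - 1.0) > 1e-9:
        raise ValueError("type proportions must sum to 1")
    if zyg_props is not None and abs(sum(zyg_props.values()) - 1.0) > 1e-9:
        raise ValueError("zygosity proportions must sum to 1")
    chrom_lengths = dict(chrom_lengths or {"chr1": 2_000_000, "chr2": 1_000_000})
    mean_lengths = (
        {t: float(mean_length) for t in VTYPES if t != "SNP"}
        if np.isscalar(mean_length)
        else {t: float(mean_length[t]) for t in mean_length}  # type: ignore[index]
    )
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    tnames = list(type_props)
    tprobs = np.array([type_props[t] for t in tnames])

    def draw_len(vtype: str) -> int:
        return 1 + int(rng.poisson(max(mean_lengths.get(vtype, 1.0) - 1.0, 0.0)))

    rows = []
    for s in range(n_samples):
        sample_id = f"S{s:04d}"
        n = max(1, int(rng.poisson(mean_variants)))
        vtypes = [tnames[int(i)] for i in rng.choice(len(tnames), size=n, p=tprobs)]
        for vtype in vtypes:
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            pos = int(rng.integers(1, chrom_lengths[chrom] - 100))
            if vtype == "SNP":
                del_len, ins_len = 1, 1
            elif vtype == "INS":
                del_len, ins_len = 0, draw_len("INS")
            elif vtype == "DEL":
                del_len, ins_len = draw_len("DEL"), 0
            elif vtype == "DUP":
                del_len, ins_len = 0, draw_len("DUP")
            else:
                del_len, ins_len = draw_len("DELINS"), draw_len("DELINS")
            if zyg_props is None:
                zyg = "unknown"
            else:
                zyg = ["het", "hom"][
                    int(rng.random() >= zyg_props.get("het", 0.0))
                ]
            rows.append(
                {
                    "sample_id": sample_id,
                    "cancer_type": cancer_type,
                    "vtype": vtype,
                    "chrom": chrom,
                    "pos": pos,
                    "zygosity": zyg,
                    "hgvs": _hgvs_for(vtype, pos, del_len, ins_len, rng),
                }
            )
    df = pd.DataFrame(rows, columns=CATALOGUE_COLUMNS)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    truth = CatalogueTruth(
        type_props=dict(type_props),
        zyg_props=dict(zyg_props) if zyg_props is not None else None,
        mean_variants_per_sample=mean_variants,
        mean_lengths=mean_lengths,
        n_samples=n_samples,
        n_records=len(df),
    )
    return df, truth
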