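"""Empirical read models learned from real aligned reads.

Three models are learned over user-supplied BED regions of a reference:

* **RDM** (read-depth model): per region, the total number of reads
  whose alignment starts inside the region, plus a per-position vector
  of start counts.  The total always equals the sum of the vector.
* **QM** (quality model): per read-cycle histograms of base-call
  quality scores (cycles are machine order, so reverse-strand reads are
  flipped before counting).
* **PBEM** (position-based error model): per region, six-number vectors
  ``(position, depth, #A, #C, #G, #T)`` summarising the pileup at each
  covered position.  Positions listed in a known-variants VCF are
  excluded (matched by contig+position, allele-agnostic) so real
  polymorphism is not mistaken for sequencing error.

Models are learned in template (``p``) coordinates and must be
converted to mutated-genome (``j``) coordinates through a PositionMap
before reads can be generated from an edited haplotype: counts are
moved, never changed; entries at deleted positions are dropped;
positions created by insertions get zero counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome_editor import DELETED, PositionMap

__all__ = [
    "ModelError",
    "Region",
    "RDM",
    "QM",
    "PBEM",
    "ModelBundle",
    "learn_models",
    "convert_bundle",
    "disable_rdm",
    "disable_pbem",
    "read_bed",
    "write_bed",
]


class ModelError(ValueError):
    pass


Region = tuple[str, int, int]  # chrom, start, end (0-based half-open)


def read_bed(path: str | Path) -> list[Region]:
    regions: list[Region] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


@dataclass
class RDM:
    """Per-region read-start weights: (total, per-position counts)."""

    totals: list[int]
    vectors: list[np.ndarray]

    def check(self) -> None:
        for i, (t, v) in enumerate(zip(self.totals, self.vectors)):
            if t != int(v.sum()):
                raise ModelError(f"RDM region {i}: total {t} != vector sum {int(v.sum())}")

    def copy(self) -> "RDM":
        return RDM(list(self.totals), [v.copy() for v in self.vectors])


@dataclass
class QM:
    """Per-cycle quality histograms: cycle -> {phred score: count}."""

    histograms: list[dict[int, int]]

    @property
    def read_length(self) -> int:
        return len(self.histograms)

    def copy(self) -> "QM":
        return QM([dict(h) for h in self.histograms])


@dataclass
class PBEM:
    """Per-region pileup vectors: lists of (pos, depth, nA, nC, nG, nT)."""

    entries: list[list[tuple[int, int, int, int, int, int]]]

    def copy(self) -> "PBEM":
        return PBEM([list(e) for e in self.entries])


@dataclass
class ModelBundle:
    rdm: RDM
    qm: QM
    pbem: PBEM
    regions: list[Region]
    space: str = "p"  # "p" (template) or "j" (mutated)
    rdm_enabled: bool = True
    pbem_enabled: bool = True

    def copy(self) -> "ModelBundle":
        return ModelBundle(
            rdm=self.rdm.copy(), qm=self.qm.copy(), pbem=self.pbem.copy(),
            regions=list(self.regions), space=self.space,
            rdm_enabled=self.rdm_enabled, pbem_enabled=self.pbem_enabled,
        )

    @classmethod
    def uniform(cls, regions: Sequence[Region], space: str = "j") -> "ModelBundle":
        """A model-free bundle: flat coverage, no errors, default
        qualities — the 'RDM and PBEM disabled' configuration."""
        return cls(
            rdm=RDM(
                totals=[e - s for _, s, e in regions],
                vectors=[np.ones(e - s, dtype=np.int64) for _, s, e in regions],
            ),
            qm=QM(histograms=[]),
            pbem=PBEM(entries=[[] for _ in regions]),
            regions=list(regions),
            space=space,
            rdm_enabled=False,
            pbem_enabled=False,
        )

    # --- persistence: one human-readable JSON + text hybrid ------------
    def save(self, path: str | Path) -> None:
        payload = {
            "format": "somasim-models",
            "version": 1,
            "space": self.space,
            "rdm_enabled": self.rdm_enabled,
            "pbem_enabled": self.pbem_enabled,
            "regions": [[c, s, e] for c, s, e in self.regions],
            "rdm": [
                {"total": t, "counts": v.tolist()}
                for t, v in zip(self.rdm.totals, self.rdm.vectors)
            ],
            "qm": [
                {str(q): c for q, c in hist.items()} for hist in self.qm.histograms
            ],
            "pbem": [[list(v) for v in entry] for entry in self.pbem.entries],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "somasim-models":
            raise ModelError(f"{path}: not a somasim model bundle")
        return cls(
            rdm=RDM(
                totals=[r["total"] for r in payload["rdm"]],
                vectors=[np.array(r["counts"], dtype=np.int64) for r in payload["rdm"]],
            ),
            qm=QM([{int(q): c for q, c in h.items()} for h in payload["qm"]]),
            pbem=PBEM(
                [[tuple(v) for v in entry] for entry in payload["pbem"]]
            ),
            regions=[(c, s, e) for c, s, e in payload["regions"]],
            space=payload["space"],
            rdm_enabled=payload["rdm_enabled"],
            pbem_enabled=payload["pbem_enabled"],
        )


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _vcf_positions(path: str | Path) -> set[tuple[str, int]]:
    """Contig + 0-based position of every record in a (plain-text) VCF."""
    out: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split("\t")
            out.add((fields[0], int(fields[1]) - 1))
    return out


def learn_models(
    bam_paths: Sequence[str | Path],
    reference_fasta: str | Path,
    bed_path: str | Path,
    known_vcf: str | Path | None = None,
) -> ModelBundle:
    """Synthesise RDM, QM and PBEM from aligned reads over BED regions.

    The BAMs must be aligned to ``reference_fasta``; a contig present in
    the BED but absent from a BAM header is a hard error.  The returned
    bundle is in template (p) coordinates.
    """
    import pysam

    regions = read_bed(bed_path)
    if not regions:
        raise ModelError(f"{bed_path}: empty BED")
    known = _vcf_positions(known_vcf) if known_vcf else set()

    totals = [0] * len(regions)
    vectors = [np.zeros(e - s, dtype=np.int64) for _, s, e in regions]
    qual_hists: list[dict[int, int]] = []
    depth = [np.zeros(e - s, dtype=np.int64) for _, s, e in regions]
    base_counts = [np.zeros((e - s, 4), dtype=np.int64) for _, s, e in regions]

    for bam_path in bam_paths:
        with pysam.AlignmentFile(str(bam_path), "rb") as bam:
            contigs = set(bam.references)
            for ridx, (chrom, start, end) in enumerate(regions):
                if chrom not in contigs:
                    raise ModelError(
                        f"BED contig {chrom!r} absent from {bam_path} "
                        "(BAM/reference mismatch?)"
                    )
                for read in bam.fetch(chrom, start, end):
                    if read.is_unmapped or read.is_secondary or read.is_supplementary:
                        continue
                    if start <= read.reference_start < end:
                        totals[ridx] += 1
                        vectors[ridx][read.reference_start - start] += 1
                        quals = read.query_qualities
                        if quals is not None:
                            cycle_quals = (
                                list(quals)[::-1] if read.is_reverse else list(quals)
                            )
                            while len(qual_hists) < len(cycle_quals):
                                qual_hists.append({})
                            for cycle, q in enumerate(cycle_quals):
                                qual_hists[cycle][q] = qual_hists[cycle].get(q, 0) + 1
                    seq = read.query_sequence
                    if seq is None:
                        continue
                    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                        if start <= rpos < end and (chrom, rpos) not in known:
                            depth[ridx][rpos - start] += 1
                            b = seq[qpos].upper()
                            if b in _BASE_IDX:
                                base_counts[ridx][rpos - start, _BASE_IDX[b]] += 1

    pbem_entries = []
    for ridx, (chrom, start, end) in enumerate(regions):
        entry = []
        covered = np.nonzero(depth[ridx] > 0)[0]
        for off in covered:
            a, c, g, t = (int(x) for x in base_counts[ridx][off])
            entry.append((start + int(off), int(depth[ridx][off]), a, c, g, t))
        pbem_entries.append(entry)

    bundle = ModelBundle(
        rdm=RDM(totals=totals, vectors=vectors),
        qm=QM(histograms=qual_hists),
        pbem=PBEM(entries=pbem_entries),
        regions=regions,
        space="p",
    )
    bundle.rdm.check()
    return bundle


def convert_bundle(bundle: ModelBundle, pmap: PositionMap) -> ModelBundle:
    """Lift a template-space bundle into mutated-genome (j) coordinates.

    Per region: the converted interval spans the first to the last
    surviving template position (a boundary that maps to DELETED shrinks
    inward; a fully deleted region is an error).  RDM counts move to
    their j positions; j positions created by insertions get zeros; the
    region total is recomputed as the sum of the converted vector.
    PBEM vectors have their position replaced by j[p], dropping deleted
    positions.  The QM is coordinate-free and passes through.
    """
    if bundle.space != "p":
        raise ModelError("bundle is already in mutated (j) coordinates")
    new_regions: list[Region] = []
    new_totals: list[int] = []
    new_vectors: list[np.ndarray] = []
    new_pbem: list[list[tuple[int, int, int, int, int, int]]] = []
    for ridx, (chrom, start, end) in enumerate(bundle.regions):
        j = pmap[chrom]
        if end > len(j):
            raise ModelError(
                f"region {chrom}:{start}-{end} outside the position map ({len(j)} bp)"
            )
        window = j[start:end]
        alive = np.nonzero(window != DELETED)[0]
        if alive.size == 0:
            raise ModelError(f"region {chrom}:{start}-{end} is entirely deleted")
        new_start = int(window[alive[0]])
        new_end = int(window[alive[-1]]) + 1
        vec = np.zeros(new_end - new_start, dtype=np.int64)
        old_vec = bundle.rdm.vectors[ridx]
        for off in alive:
            vec[int(window[off]) - new_start] = old_vec[off]
        new_regions.append((chrom, new_start, new_end))
        new_vectors.append(vec)
        new_totals.append(int(vec.sum()))
        entry = []
        for pos, d, a, c, g, t in bundle.pbem.entries[ridx]:
            jp = int(j[pos])
            if jp != DELETED:
                entry.append((jp, d, a, c, g, t))
        new_pbem.append(entry)
    out = ModelBundle(
        rdm=RDM(totals=new_totals, vectors=new_vectors),
        qm=bundle.qm.copy(),
        pbem=PBEM(entries=new_pbem),
        regions=new_regions,
        space="j",
        rdm_enabled=bundle.rdm_enabled,
        pbem_enabled=bundle.pbem_enabled,
    )
    out.rdm.check()
    return out


def disable_rdm(bundle: ModelBundle) -> ModelBundle:
    """Flatten coverage: every position of every region becomes equally
    likely to start a read (region weight proportional to its length)."""
    out = bundle.copy()
    out.rdm_enabled = False
    out.rdm = RDM(
        totals=[e - s for _, s, e in out.regions],
        vectors=[np.ones(e - s, dtype=np.int64) for _, s, e in out.regions],
    )
    return out


def disable_pbem(bundle: ModelBundle) -> ModelBundle:
    """Turn off sequencing-error injection; generated reads become exact
    substrings of their source genome."""
    out = bundle.copy()
    out.pbem_enabled = False
    return out
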