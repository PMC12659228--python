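"""Sequential genome editing through an explicit position map.

Variants are applied in VAR-file order to a mutable copy of the template
genome.  A per-chromosome integer vector ``j`` maps every template
coordinate ``t`` (the vector ``p`` = 0..N-1) to its current coordinate
in the mutated sequence, or to the ``DELETED`` sentinel once a deletion
has consumed it.  The two update rules:

* insertion of ``L_ins`` bases anchored at template position ``t``
  splices the new sequence immediately left of ``j[t]`` and increases
  ``j[t:]`` by ``L_ins``;
* deletion of span ``L_del`` at ``t`` removes the ``L_del`` mutated
  bases starting at ``j[t]``, marks ``j[t : t+L_del]`` as DELETED and
  decreases every later (non-deleted) entry by ``L_del``.

Because insertion content may be extracted from the genome *currently
undergoing mutation*, later variants can pick up the alleles introduced
by earlier ones, which is what makes overlapping/complex events
expressible.

Heterozygous variants target haplotype 0 only; homozygous variants are
written as two VAR lines sharing a MID with HAP 0 and HAP 1, so the two
haplotype genomes are edited independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .var_model import (
    GenomeIndex,
    InsertionSpec,
    VariantSpec,
    parse_var,
    validate_variants,
)

__all__ = [
    "DELETED",
    "EditError",
    "PositionMap",
    "HaplotypeGenome",
    "GroundTruthRecord",
    "init_map",
    "apply_deletion",
    "apply_insertion",
    "resolve_ins_seq",
    "apply_variant",
    "edit_sample",
    "reverse_complement",
]

DELETED = -1

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


class EditError(ValueError):
    """Raised when an edit has no defined semantics (e.g. deleting a
    template position that an earlier deletion already consumed)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


class PositionMap:
    """chrom -> int vector ``j`` over template coordinates (-1 = deleted)."""

    MAGIC = "somasim-posmap"
    VERSION = 1

    def __init__(self, maps: dict[str, np.ndarray]):
        self.maps = maps

    @classmethod
    def identity(cls, index: GenomeIndex) -> "PositionMap":
        return cls({name: np.arange(index.lengths[name], dtype=np.int64) for name in index.names})

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.maps[chrom]

    def n_surviving(self, chrom: str) -> int:
        return int(np.count_nonzero(self.maps[chrom] != DELETED))

    def copy(self) -> "PositionMap":
        return PositionMap({c: j.copy() for c, j in self.maps.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionMap):
            return NotImplemented
        return self.maps.keys() == other.maps.keys() and all(
            np.array_equal(self.maps[c], other.maps[c]) for c in self.maps
        )

    # --- serialization: versioned plain-text archive -------------------
    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#{self.MAGIC} v{self.VERSION}\n")
            for chrom, j in self.maps.items():
                fh.write(f">{chrom}\t{len(j)}\n")
                fh.write(" ".join(str(int(x)) for x in j) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PositionMap":
        maps: dict[str, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith(f"#{cls.MAGIC}"):
                raise EditError(f"{path}: not a position-map file")
            chrom = None
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    chrom, n = line[1:].split("\t")
                    maps[chrom] = np.empty(int(n), dtype=np.int64)
                elif chrom is not None and line:
                    maps[chrom][:] = np.array(line.split(), dtype=np.int64)
        return cls(maps)


@dataclass
class HaplotypeGenome:
    """Mutable per-chromosome sequences paired with their PositionMap."""

    seqs: dict[str, bytearray]
    pmap: PositionMap
    template: dict[str, bytes] = field(repr=False, default_factory=dict)

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "HaplotypeGenome":
        byte_seqs = {c: bytearray(s.upper().encode()) for c, s in seqs.items()}
        index = GenomeIndex(names=tuple(seqs.keys()), lengths={c: len(s) for c, s in seqs.items()})
        return cls(
            seqs=byte_seqs,
            pmap=PositionMap.identity(index),
            template={c: bytes(b) for c, b in byte_seqs.items()},
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "HaplotypeGenome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        fa.close()
        return cls.from_sequences(seqs)

    def sequence(self, chrom: str) -> str:
        return self.seqs[chrom].decode()

    def template_sequence(self, chrom: str) -> str:
        return self.template[chrom].decode()


def init_map(index: GenomeIndex) -> PositionMap:
    """Fresh identity map: before any edit, j[t] = t everywhere."""
    return PositionMap.identity(index)


def apply_deletion(g: HaplotypeGenome, chrom: str, t: int, del_span: int) -> None:
    """Delete ``del_span`` mutated bases starting at j[t] (inclusive)."""
    j = g.pmap[chrom]
    n = len(j)
    if t < 0 or t >= n:
        raise EditError(f"deletion start {t} outside chromosome {chrom} (length {n})")
    if t + del_span > n:
        raise EditError(
            f"deletion [{t},{t + del_span}) runs past chromosome {chrom} end ({n})"
        )
    block = j[t : t + del_span]
    if np.any(block == DELETED):
        raise EditError(
            f"deletion [{t},{t + del_span}) on {chrom} overlaps an already-deleted position"
        )
    jt = int(j[t])
    del g.seqs[chrom][jt : jt + del_span]
    j[t : t + del_span] = DELETED
    tail = j[t + del_span :]
    tail[tail != DELETED] -= del_span


def _insertion_anchor(g: HaplotypeGenome, chrom: str, t: int) -> tuple[int | None, int]:
    """First surviving template position >= t and its mutated coordinate.

    Returns (t', j[t']); when nothing survives to the right the anchor is
    (None, len(sequence)) and the insertion appends at the chromosome end.
    """
    j = g.pmap[chrom]
    tail = j[t:]
    alive = np.nonzero(tail != DELETED)[0]
    if alive.size == 0:
        return None, len(g.seqs[chrom])
    tp = t + int(alive[0])
    return tp, int(j[tp])


def apply_insertion(g: HaplotypeGenome, chrom: str, t: int, seq: str) -> None:
    """Splice ``seq`` immediately left of the base at j[t]."""
    if not seq or set(seq.upper()) - set("ACGT"):
        raise EditError(f"insertion sequence must be non-empty over A/C/G/T, got {seq!r}")
    j = g.pmap[chrom]
    if t < 0 or t >= len(j):
        raise EditError(f"insertion position {t} outside chromosome {chrom}")
    if j[t] == DELETED:
        raise EditError(f"insertion anchored on deleted template position {t} of {chrom}")
    jt = int(j[t])
    g.seqs[chrom][jt:jt] = seq.upper().encode()
    tail = j[t:]
    tail[tail != DELETED] += len(seq)


def _append_insertion(g: HaplotypeGenome, chrom: str, seq: str) -> None:
    g.seqs[chrom].extend(seq.upper().encode())


def resolve_ins_seq(
    spec: InsertionSpec,
    g: HaplotypeGenome,
    externals: Mapping[str, Mapping[str, str]] | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Materialize an InsertionSpec into a concrete nucleotide string.

    ``self_extract`` reads the *current* mutated sequence under the
    template interval, so earlier variants inside the window are carried
    into the insertion.  ``external`` slices a separate genome in its own
    coordinates.  ``random`` draws i.i.d. uniform bases from ``rng``.
    """
    if spec.mode == "manual":
        return spec.literal  # type: ignore[return-value]
    if spec.mode == "random":
        if rng is None:
            raise EditError("random insertion content requires a seeded generator")
        return "".join(rng.choice(list("ACGT"), size=spec.length))
    if spec.mode == "self_extract":
        j = g.pmap[spec.source_chrom]
        window = j[spec.start : spec.end]
        if len(window) != spec.end - spec.start:
            raise EditError(
                f"extraction interval [{spec.start},{spec.end}) outside {spec.source_chrom}"
            )
        # Only the window endpoints must survive: the contiguous mutated
        # slice between them carries whatever earlier variants put there
        # (e.g. the replacement base of a SNP inside the window).
        if window[0] == DELETED or window[-1] == DELETED:
            raise EditError(
                f"extraction interval [{spec.start},{spec.end}) on "
                f"{spec.source_chrom} has a deleted boundary position"
            )
        seq = g.seqs[spec.source_chrom][int(window[0]) : int(window[-1]) + 1].decode()
    elif spec.mode == "external":
        if externals is None or spec.external_path not in externals:
            raise EditError(f"external genome {spec.external_path!r} not provided")
        source = externals[spec.external_path]
        if spec.source_chrom not in source:
            raise EditError(
                f"chromosome {spec.source_chrom!r} missing from {spec.external_path!r}"
            )
        seq = source[spec.source_chrom][spec.start : spec.end]
        if len(seq) != spec.end - spec.start:
            raise EditError(
                f"external interval [{spec.start},{spec.end}) outside {spec.source_chrom}"
            )
    else:
        raise EditError(f"cannot resolve insertion mode {spec.mode!r}")
    if spec.orientation == "reverse":
        seq = reverse_complement(seq)
    return seq * spec.copies


@dataclass(frozen=True)
class GroundTruthRecord:
    """Realized outcome of one VAR line, in template (p) coordinates."""

    vid: str
    mid: str
    hap: int
    chrom: str
    pos: int
    ref: str  # template bases consumed ('' for a pure insertion)
    alt: str  # bases inserted ('' for a pure deletion)
    ref_equal_snp: bool = False


def apply_variant(
    g: HaplotypeGenome,
    v: VariantSpec,
    externals: Mapping[str, Mapping[str, str]] | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruthRecord:
    """Apply one VAR line: DEL first, then INS at the same locus.

    A combined event is executed as a deletion followed by an insertion;
    after the deletion has consumed j[t] the insertion anchors at the
    first surviving template position >= t (appending at the chromosome
    end when nothing survives), which keeps a delins contiguous.

    A 1-bp delins whose inserted base equals the template base is a SNP
    that variant callers cannot see; it is flagged so the ground truth
    can be filtered.
    """
    ref = ""
    alt = ""
    if v.has_del:
        ref = g.template[v.chrom][v.pos : v.pos + v.del_span].decode()
        apply_deletion(g, v.chrom, v.pos, v.del_span)
    if v.has_ins:
        alt = resolve_ins_seq(v.ins_seq, g, externals=externals, rng=rng)
        if v.has_del:
            anchor_t, _ = _insertion_anchor(g, v.chrom, v.pos)
            if anchor_t is None:
                _append_insertion(g, v.chrom, alt)
            else:
                apply_insertion(g, v.chrom, anchor_t, alt)
        else:
            apply_insertion(g, v.chrom, v.pos, alt)
    flag = v.has_del and v.has_ins and v.del_span == 1 and len(alt) == 1 and ref == alt
    return GroundTruthRecord(
        vid=v.vid, mid=v.mid, hap=v.hap, chrom=v.chrom, pos=v.pos,
        ref=ref, alt=alt, ref_equal_snp=flag,
    )


# ---------------------------------------------------------------------------
# Whole-sample editing
# ---------------------------------------------------------------------------

@dataclass
class EditResult:
    haplotypes: dict[int, HaplotypeGenome]
    records: list[GroundTruthRecord]
    truth: list[dict]  # one per MID, VCF-level
    index: GenomeIndex


def _mid_truth(records: list[GroundTruthRecord]) -> list[dict]:
    """Collapse per-line records into one ground-truth entry per MID.

    Homozygosity = the MID occurs on both haplotypes.  The haplotype-0
    record supplies REF/ALT (both copies carry the same design).
    """
    by_mid: dict[str, list[GroundTruthRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.mid not in by_mid:
            order.append(rec.mid)
        by_mid.setdefault(rec.mid, []).append(rec)
    truth = []
    for mid in order:
        group = by_mid[mid]
        haps = {r.hap for r in group}
        rep = next((r for r in group if r.hap == 0), group[0])
        truth.append(
            {
                "mid": mid,
                "vid": rep.vid,
                "chrom": rep.chrom,
                "pos": rep.pos,
                "ref": rep.ref,
                "alt": rep.alt,
                "zygosity": "hom" if haps == {0, 1} else "het",
                "ref_equal_snp": any(r.ref_equal_snp for r in group),
            }
        )
    return truth


def _vcf_fields(entry: dict, template: Mapping[str, bytes]) -> tuple[int, str, str]:
    """Normalize an entry to 1-based VCF POS/REF/ALT with anchor bases."""
    chrom, pos, ref, alt = entry["chrom"], entry["pos"], entry["ref"], entry["alt"]
    seq = template[chrom]
    if ref and alt:  # delins / SNP: direct substitution
        return pos + 1, ref, alt
    if ref and not alt:  # pure deletion: left-anchor, right-anchor at pos 0
        if pos > 0:
            anchor = chr(seq[pos - 1])
            return pos, anchor + ref, anchor
        anchor = chr(seq[pos + len(ref)]) if pos + len(ref) < len(seq) else "N"
        return 1, ref + anchor, anchor
    # pure insertion (left of pos)
    if pos > 0:
        anchor = chr(seq[pos - 1])
        return pos, anchor, anchor + alt
    anchor = chr(seq[0])
    return 1, anchor, alt + anchor


def write_truth_vcf(
    truth: list[dict], template: Mapping[str, bytes], index: GenomeIndex, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=somasim\n")
        for name in index.names:
            fh.write(f"##contig=<ID={name},length={index.lengths[name]}>\n")
        fh.write('##INFO=<ID=VID,Number=1,Type=String,Description="Variant id">\n')
        fh.write('##INFO=<ID=MID,Number=1,Type=String,Description="Shared event id">\n')
        fh.write(
            '##INFO=<ID=REF_EQUAL,Number=0,Type=Flag,'
            'Description="Simulated substitution equals the template base">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for entry in truth:
            pos1, ref, alt = _vcf_fields(entry, template)
            info = f"VID={entry['vid']};MID={entry['mid']}"
            if entry["ref_equal_snp"]:
                info += ";REF_EQUAL"
            gt = "1/1" if entry["zygosity"] == "hom" else "0/1"
            fh.write(
                f"{entry['chrom']}\t{pos1}\t{entry['mid']}\t{ref}\t{alt}\t.\tPASS\t"
                f"{info}\tGT\t{gt}\n"
            )


def write_truth_bed(
    truth: list[dict], index: GenomeIndex, flank: int, path: str | Path
) -> list[tuple[str, int, int]]:
    """BED of regions centered on variant positions, [pos-flank, pos+flank)
    in template coordinates, clipped to the chromosome."""
    regions = []
    with open(path, "w") as fh:
        for entry in truth:
            n = index.lengths[entry["chrom"]]
            start = max(0, entry["pos"] - flank)
            end = min(n, entry["pos"] + flank)
            if end > start:
                regions.append((entry["chrom"], start, end))
                fh.write(f"{entry['chrom']}\t{start}\t{end}\t{entry['mid']}\n")
    return regions


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def edit_sample(
    var_path: str | Path,
    template_fasta: str | Path,
    out_dir: str | Path,
    flank: int = 200,
    seed: int = 0,
    externals: Mapping[str, Mapping[str, str]] | None = None,
) -> EditResult:
    """Run the whole editing block for one sample/clone.

    Parses and validates the VAR file, edits both haplotype copies of
    the template independently, and writes: ``hap0.fa``/``hap1.fa``,
    ``map_hap0.txt``/``map_hap1.txt``, ``truth.vcf`` and ``regions.bed``
    (both in template coordinates) into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = GenomeIndex.from_fasta(template_fasta)
    variants = parse_var(var_path)
    findings = validate_variants(variants, index)
    if findings:
        first = findings[0]
        raise EditError(
            f"VAR file failed validation ({len(findings)} finding(s)); "
            f"first: {first.vid}: {first.message}"
        )
    rng = np.random.default_rng(seed)
    base = HaplotypeGenome.from_fasta(template_fasta)
    haps = {
        0: HaplotypeGenome.from_sequences({c: base.template_sequence(c) for c in base.seqs}),
        1: HaplotypeGenome.from_sequences({c: base.template_sequence(c) for c in base.seqs}),
    }
    records: list[GroundTruthRecord] = []
    for v in variants:
        try:
            records.append(apply_variant(haps[v.hap], v, externals=externals, rng=rng))
        except EditError as exc:
            raise EditError(f"variant {v.vid}: {exc}") from exc
    truth = _mid_truth(records)
    for h, g in haps.items():
        write_fasta({c: g.sequence(c) for c in index.names}, out / f"hap{h}.fa")
        g.pmap.save(out / f"map_hap{h}.txt")
    write_truth_vcf(truth, haps[0].template, index, out / "truth.vcf")
    write_truth_bed(truth, index, flank, out / "regions.bed")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return EditResult(haplotypes=haps, records=records, truth=truth, index=index)
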