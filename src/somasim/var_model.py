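"""The VAR variant-description format.

A VAR file lists one variant per line, nine tab-separated fields:

    VID  MID  HAP  CHR  POS  DEL  DEL_SPAN  INS  INS_SEQ

``VID`` uniquely identifies the line; ``MID`` is shared across the two
haplotype copies of a homozygous variant and across the members of a
complex event.  ``HAP`` selects the haplotype (0 or 1) that receives the
edit.  ``POS`` is a 0-based coordinate on the *template* genome; the
editor translates it to the progressively mutated genome through the
position map.  A line may delete (``DEL``/``DEL_SPAN``), insert
(``INS``/``INS_SEQ``) or do both (a delins; SNPs are encoded as a 1-bp
delins).

The ``INS_SEQ`` field is a small sub-language:

* a literal nucleotide string, e.g. ``ACTG``;
* ``random N`` — N i.i.d. uniform bases drawn at edit time;
* ``self:CHR:START-END:xK:forward|reverse`` — extract the current
  (already mutated) sequence under template interval [START, END),
  repeat it K times, optionally reverse-complemented;
* ``ext:PATH:CHR:START-END:xK:forward|reverse`` — same, but sliced from
  an external FASTA in its own coordinates;
* ``none`` when ``INS`` is False.

Lines beginning with ``#`` are comments.  Booleans serialize as
``True``/``False``.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "NUCLEOTIDES",
    "VarFormatError",
    "InsertionSpec",
    "VariantSpec",
    "GenomeIndex",
    "ValidationFinding",
    "parse_var",
    "parse_var_lines",
    "write_var",
    "format_var_line",
    "validate_variants",
]

NUCLEOTIDES = frozenset("ACGT")

_VAR_HEADER = "#VID\tMID\tHAP\tCHR\tPOS\tDEL\tDEL_SPAN\tINS\tINS_SEQ"

_MANUAL_RE = re.compile(r"^[ACGT]+$")
_RANDOM_RE = re.compile(r"^random\s+(\d+)$")
_SELF_RE = re.compile(r"^self:([^:]+):(\d+)-(\d+):x(\d+):(forward|reverse)$")
_EXT_RE = re.compile(r"^ext:(.+):([^:]+):(\d+)-(\d+):x(\d+):(forward|reverse)$")


class VarFormatError(ValueError):
    """Raised on a malformed or inconsistent VAR file."""


@dataclass(frozen=True)
class InsertionSpec:
    """Content specification for the INS half of a variant.

    Exactly the fields of the active ``mode`` are meaningful; the rest
    stay at their inactive defaults.
    """

    mode: str = "none"  # none | manual | random | self_extract | external
    literal: str | None = None
    length: int | None = None
    source_chrom: str | None = None
    start: int | None = None
    end: int | None = None
    copies: int = 1
    orientation: str = "forward"
    external_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"none", "manual", "random", "self_extract", "external"}:
            raise VarFormatError(f"unknown insertion mode {self.mode!r}")
        if self.mode == "manual":
            if not self.literal or not _MANUAL_RE.match(self.literal):
                raise VarFormatError(
                    f"manual insertion needs a non-empty A/C/G/T string, got {self.literal!r}"
                )
        if self.mode == "random" and (self.length is None or self.length < 1):
            raise VarFormatError("random insertion needs length >= 1")
        if self.mode in ("self_extract", "external"):
            if self.start is None or self.end is None or self.start >= self.end:
                raise VarFormatError("extraction interval must satisfy start < end")
            if self.copies < 1:
                raise VarFormatError("copies must be >= 1")
            if self.orientation not in ("forward", "reverse"):
                raise VarFormatError(f"bad orientation {self.orientation!r}")
        if self.mode == "external" and not self.external_path:
            raise VarFormatError("external insertion needs a file path")

    # --- serialization -------------------------------------------------
    def to_token(self) -> str:
        if self.mode == "none":
            return "none"
        if self.mode == "manual":
            return self.literal  # type: ignore[return-value]
        if self.mode == "random":
            return f"random {self.length}"
        if self.mode == "self_extract":
            return (
                f"self:{self.source_chrom}:{self.start}-{self.end}"
                f":x{self.copies}:{self.orientation}"
            )
        return (
            f"ext:{self.external_path}:{self.source_chrom}:{self.start}-{self.end}"
            f":x{self.copies}:{self.orientation}"
        )

    @classmethod
    def from_token(cls, token: str) -> "InsertionSpec":
        token = token.strip()
        if token == "none":
            return cls()
        if _MANUAL_RE.match(token):
            return cls(mode="manual", literal=token)
        m = _RANDOM_RE.match(token)
        if m:
            return cls(mode="random", length=int(m.group(1)))
        m = _SELF_RE.match(token)
        if m:
            return cls(
                mode="self_extract",
                source_chrom=m.group(1),
                start=int(m.group(2)),
                end=int(m.group(3)),
                copies=int(m.group(4)),
                orientation=m.group(5),
            )
        m = _EXT_RE.match(token)
        if m:
            return cls(
                mode="external",
                external_path=m.group(1),
                source_chrom=m.group(2),
                start=int(m.group(3)),
                end=int(m.group(4)),
                copies=int(m.group(5)),
                orientation=m.group(6),
            )
        raise VarFormatError(f"cannot parse INS_SEQ token {token!r}")


@dataclass(frozen=True)
class VariantSpec:
    """One VAR line: an edit on one haplotype at one template locus."""

    vid: str
    mid: str
    hap: int
    chrom: str
    pos: int
    has_del: bool
    del_span: int
    has_ins: bool
    ins_seq: InsertionSpec = field(default_factory=InsertionSpec)

    def __post_init__(self) -> None:
        if self.hap not in (0, 1):
            raise VarFormatError(f"{self.vid}: HAP must be 0 or 1, got {self.hap}")
        if self.pos < 0:
            raise VarFormatError(f"{self.vid}: POS must be >= 0")
        if not (self.has_del or self.has_ins):
            raise VarFormatError(f"{self.vid}: a variant must delete or insert")
        if self.has_del and self.del_span < 1:
            raise VarFormatError(f"{self.vid}: DEL_SPAN must be >= 1 when DEL is set")
        if not self.has_del and self.del_span != 0:
            raise VarFormatError(f"{self.vid}: DEL_SPAN must be 0 when DEL is unset")
        if self.has_ins and self.ins_seq.mode == "none":
            raise VarFormatError(f"{self.vid}: INS set but INS_SEQ is 'none'")
        if not self.has_ins and self.ins_seq.mode != "none":
            raise VarFormatError(f"{self.vid}: INS unset but INS_SEQ given")


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths of a FASTA template."""

    names: tuple[str, ...]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise VarFormatError("duplicate chromosome names in index")
        for name in self.names:
            if self.lengths[name] < 1:
                raise VarFormatError(f"chromosome {name} has length < 1")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        names = tuple(fa.keys())
        lengths = {name: len(fa[name]) for name in names}
        fa.close()
        return cls(names=names, lengths=lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True)
class ValidationFinding:
    vid: str
    code: str
    message: str


def _parse_bool(token: str, where: str) -> bool:
    if token == "True":
        return True
    if token == "False":
        return False
    raise VarFormatError(f"{where}: expected True/False, got {token!r}")


def parse_var_lines(
    lines: Iterable[str], index: GenomeIndex | None = None
) -> list[VariantSpec]:
    """Parse VAR text into VariantSpecs, preserving line order.

    Order matters downstream: the editor applies variants sequentially.
    With an ``index``, unknown chromosomes and out-of-range positions are
    hard errors; without one those checks are deferred to
    :func:`validate_variants`.
    """
    variants: list[VariantSpec] = []
    seen_vids: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise VarFormatError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        vid, mid, hap_s, chrom, pos_s, del_s, span_s, ins_s, seq_s = fields
        where = f"line {lineno} ({vid})"
        try:
            hap = int(hap_s)
            pos = int(pos_s)
            span = int(span_s)
        except ValueError as exc:
            raise VarFormatError(f"{where}: non-integer numeric field: {exc}") from exc
        if vid in seen_vids:
            raise VarFormatError(f"{where}: duplicate VID {vid!r}")
        seen_vids.add(vid)
        spec = VariantSpec(
            vid=vid,
            mid=mid,
            hap=hap,
            chrom=chrom,
            pos=pos,
            has_del=_parse_bool(del_s, where),
            del_span=span,
            has_ins=_parse_bool(ins_s, where),
            ins_seq=InsertionSpec.from_token(seq_s),
        )
        if index is not None:
            if chrom not in index:
                raise VarFormatError(f"{where}: unknown chromosome {chrom!r}")
            if pos >= index.lengths[chrom]:
                raise VarFormatError(
                    f"{where}: POS {pos} >= chromosome length {index.lengths[chrom]}"
                )
        variants.append(spec)
    return variants


def parse_var(path: str | Path, index: GenomeIndex | None = None) -> list[VariantSpec]:
    """Parse a VAR file (see module docstring for the format)."""
    with open(path) as fh:
        return parse_var_lines(fh, index=index)


def format_var_line(v: VariantSpec) -> str:
    return "\t".join(
        [
            v.vid,
            v.mid,
            str(v.hap),
            v.chrom,
            str(v.pos),
            str(v.has_del),
            str(v.del_span),
            str(v.has_ins),
            v.ins_seq.to_token(),
        ]
    )


def write_var(variants: Iterable[VariantSpec], path: str | Path) -> None:
    """Write a VAR file parseable by :func:`parse_var` (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write(_VAR_HEADER + "\n")
        for v in variants:
            fh.write(format_var_line(v) + "\n")


def validate_variants(
    variants: Iterable[VariantSpec], index: GenomeIndex
) -> list[ValidationFinding]:
    """Check every variant against chromosome bounds; never raises.

    Returns one finding per violation; an empty list means the file is
    acceptable.  Unknown chromosome names get near-miss suggestions,
    guarding against 'chr1' vs '1' style mismatches.
    """
    findings: list[ValidationFinding] = []
    for v in variants:
        if v.chrom not in index:
            hint = difflib.get_close_matches(v.chrom, index.names, n=1)
            msg = f"unknown chromosome {v.chrom!r}"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            findings.append(ValidationFinding(v.vid, "unknown_chrom", msg))
            continue
        n = index.lengths[v.chrom]
        if v.pos >= n:
            findings.append(
                ValidationFinding(
                    v.vid, "pos_out_of_bounds", f"POS {v.pos} >= chromosome length {n}"
                )
            )
        elif v.has_del and v.pos + v.del_span > n:
            findings.append(
                ValidationFinding(
                    v.vid,
                    "del_out_of_bounds",
                    f"POS {v.pos} + DEL_SPAN {v.del_span} exceeds chromosome length {n}",
                )
            )
        ins = v.ins_seq
        if ins.mode == "self_extract":
            if ins.source_chrom not in index:
                findings.append(
                    ValidationFinding(
                        v.vid,
                        "extract_unknown_chrom",
                        f"extraction chromosome {ins.source_chrom!r} unknown",
                    )
                )
            elif ins.end > index.lengths[ins.source_chrom]:
                findings.append(
                    ValidationFinding(
                        v.vid,
                        "extract_out_of_bounds",
                        f"extraction interval [{ins.start},{ins.end}) exceeds "
                        f"chromosome length {index.lengths[ins.source_chrom]}",
                    )
                )
    return findings
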