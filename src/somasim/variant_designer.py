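"""Designing VAR files from presets, optionally along a clonal tree.

The designer turns the statistics mined by :mod:`somasim.preset_builder`
into concrete VAR lines: it draws a total variant count, splits it over
the five variant types and the two zygosities by largest-remainder
rounding of the preset proportions, samples per-type lengths, and walks
chromosomes with sampled inter-variant distances to place each event.
Heterozygous variants become one VAR line on haplotype 0; homozygous
variants become two lines sharing a MID on haplotypes 0 and 1.

A clonal tree (one ``parent child distance`` edge per line) expands a
root VAR file into one file per clone: each child inherits its parent's
variants verbatim and acquires ``distance`` new ones of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .preset_builder import FAMILIES, Preset, VTYPES
from .var_model import GenomeIndex, InsertionSpec, VariantSpec

__all__ = [
    "DesignError",
    "DesignConfig",
    "CloneTree",
    "sample_total",
    "allocate_types",
    "allocate_zygosity",
    "sample_lengths",
    "sample_positions",
    "generate_var",
    "parse_clone_tree",
    "expand_clones",
    "largest_remainder",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class DesignConfig:
    """Knobs of the guided/automatic VAR design procedure.

    The automatic-mode defaults mirror the guided procedure: totals,
    lengths and positions are drawn from the empirical distributions,
    while type and zygosity counts follow the proportions of one
    randomly selected sample (``perspective='one_sample'``).  Presets
    mined from a zygosity-free catalogue require an explicit
    ``het_fraction``.
    """

    cancer_type: str
    db_tag: str = ""
    total_variants: int | None = None
    het_fraction: float | None = None
    perspective: str = "one_sample"  # or "all_sample"
    total_source: str = "empirical"  # "empirical" or a family name
    length_source: str = "empirical"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_variants is not None and self.total_variants < 0:
            raise DesignError("total_variants must be >= 0")
        if self.het_fraction is not None and not (0.0 <= self.het_fraction <= 1.0):
            raise DesignError("het_fraction must lie in [0, 1]")
        if self.perspective not in ("one_sample", "all_sample"):
            raise DesignError(f"unknown perspective {self.perspective!r}")


def largest_remainder(total: int, proportions: Sequence[float]) -> list[int]:
    """Integer counts summing to ``total``, each within 1 of total*p."""
    raw = np.asarray(proportions, dtype=float) * total
    base = np.floor(raw).astype(int)
    deficit = total - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for idx in order[:deficit]:
        base[idx] += 1
    return base.tolist()


def _draw_distribution(
    preset: Preset, key: str, n: int, rng: np.random.Generator, source: str
) -> np.ndarray:
    fd = preset.distributions.get(key)
    if fd is None or fd.empirical.total == 0:
        raise DesignError(f"preset has no usable {key!r} distribution")
    if source == "empirical":
        return fd.empirical.sample(n, rng)
    fit = next((f for f in fd.fits if f.family == source and f.fit_ok), None)
    if fit is None:
        raise DesignError(f"no successful {source!r} fit for {key!r}")
    return FAMILIES[source].rvs(fit.params, n, rng)


def sample_total(
    preset: Preset, config: DesignConfig, rng: np.random.Generator
) -> int:
    """Total number of variants: user override, or one draw from the
    (empirical or fitted) total-variants distribution."""
    if config.total_variants is not None:
        return config.total_variants
    draw = _draw_distribution(preset, "total_variants", 1, rng, config.total_source)
    return max(1, int(round(float(draw[0]))))


def allocate_types(total: int, type_props: Mapping[str, float]) -> dict[str, int]:
    props = [type_props.get(t, 0.0) for t in VTYPES]
    s = sum(props)
    if abs(s - 1.0) > 1e-6:
        raise DesignError(f"type proportions must sum to 1, got {s}")
    counts = largest_remainder(total, props)
    return dict(zip(VTYPES, counts))


def allocate_zygosity(total: int, het_fraction: float) -> tuple[int, int]:
    n_het, n_hom = largest_remainder(total, [het_fraction, 1.0 - het_fraction])
    return n_het, n_hom


def sample_lengths(
    preset: Preset,
    vtype: str,
    n: int,
    rng: np.random.Generator,
    source: str = "empirical",
) -> list[int] | list[tuple[int, int]]:
    """Draw ``n`` event lengths for one variant type.

    DELINS events draw their deleted (DELins) and inserted (delINS)
    components independently and return (del_len, ins_len) pairs.  SNPs
    have length 0 by construction and never reach this function.
    """
    if vtype == "SNP":
        raise DesignError("SNP lengths are the constant 0; nothing to sample")
    if vtype not in VTYPES:
        raise DesignError(f"unknown variant type {vtype!r}")
    if n == 0:
        return []
    if vtype == "DELINS":
        dels = _draw_distribution(preset, "length_DELins", n, rng, source)
        inss = _draw_distribution(preset, "length_delINS", n, rng, source)
        return [
            (max(1, int(round(float(d)))), max(1, int(round(float(i)))))
            for d, i in zip(dels, inss)
        ]
    draw = _draw_distribution(preset, f"length_{vtype}", n, rng, source)
    return [max(1, int(round(float(v)))) for v in draw]


def sample_positions(
    preset: Preset,
    vtype: str,
    n: int,
    index: GenomeIndex,
    rng: np.random.Generator,
    start0: int | None = None,
    max_attempts_factor: int = 200,
) -> list[tuple[str, int]]:
    """Place ``n`` variants by a distance-driven walk along chromosomes.

    A chromosome is chosen with probability proportional to its length;
    the walk starts one sampled inter-variant distance from 0 (or at
    ``start0`` when forced) and then advances by sampled distances.
    Whenever the walk runs off the chromosome end, a new chromosome is
    drawn and the walk restarts.
    """
    if n == 0:
        return []
    fd = preset.distributions.get(f"distance_{vtype}")
    if fd is None or fd.empirical.total == 0:
        raise DesignError(f"preset has no usable distance distribution for {vtype}")
    dist = fd.empirical
    lengths = np.array([index.lengths[c] for c in index.names], dtype=float)
    placed: list[tuple[str, int]] = []
    attempts = 0
    budget = max_attempts_factor * n + 1000
    chrom = index.names[int(rng.choice(len(index.names), p=lengths / lengths.sum()))]
    pos = start0 if start0 is not None else int(dist.sample(1, rng)[0])
    while len(placed) < n:
        attempts += 1
        if attempts > budget:
            raise DesignError(
                f"could not place {n} {vtype} positions (genome too small for the "
                "sampled distances)"
            )
        if 0 <= pos < index.lengths[chrom]:
            placed.append((chrom, pos))
            pos += int(dist.sample(1, rng)[0])
        else:
            chrom = index.names[
                int(rng.choice(len(index.names), p=lengths / lengths.sum()))
            ]
            pos = int(dist.sample(1, rng)[0])
    return placed


# ---------------------------------------------------------------------------
# VAR generation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _snp_alt(
    rng: np.random.Generator,
    template: Mapping[str, str] | None,
    chrom: str,
    pos: int,
) -> str:
    """Alt base for a SNP: one of the 3 non-reference bases when the
    template sequence is available at design time, else uniform over 4
    (ref-equal draws are flagged downstream by the editor)."""
    if template is not None and chrom in template:
        ref = template[chrom][pos].upper()
        choices = [b for b in "ACGT" if b != ref]
        if len(choices) == 3:
            return str(rng.choice(choices))
    return str(rng.choice(_BASES))


@dataclass
class _Designed:
    mid: str
    vtype: str
    zygosity: str
    chrom: str
    pos: int
    del_span: int
    ins: InsertionSpec | None


def _footprint(vtype: str, pos: int, del_span: int, ins: InsertionSpec | None) -> int:
    if vtype == "DUP" and ins is not None:
        return ins.end - ins.start
    return max(1, del_span)


def _design_block(
    preset: Preset,
    config: DesignConfig,
    index: GenomeIndex,
    rng: np.random.Generator,
    total: int,
    id_prefix: str,
    used: dict[str, list[tuple[int, int]]],
    template: Mapping[str, str] | None,
) -> list[_Designed]:
    """Design ``total`` MID-level variants, avoiding used footprints."""
    if total == 0:
        return []
    if config.perspective == "one_sample" and preset.per_sample:
        record = preset.per_sample[int(rng.integers(len(preset.per_sample)))]
        type_props = record["type_props"]
        zyg_props = record["zyg_props"]
    else:
        type_props = preset.type_props_all
        zyg_props = preset.zyg_props_all
    if config.het_fraction is not None:
        het_fraction = config.het_fraction
    elif zyg_props is not None:
        het_fraction = zyg_props["het"]
    else:
        raise DesignError(
            "preset carries no zygosity information; het_fraction must be given"
        )
    type_counts = allocate_types(total, type_props)
    n_het, n_hom = allocate_zygosity(total, het_fraction)
    zygosities = ["het"] * n_het + ["hom"] * n_hom
    zygosities = [zygosities[i] for i in rng.permutation(total)]

    designed: list[_Designed] = []
    serial = 0
    for vtype in VTYPES:
        count = type_counts[vtype]
        if count == 0:
            continue
        lengths: list = (
            [0] * count if vtype == "SNP"
            else sample_lengths(preset, vtype, count, rng, config.length_source)
        )
        positions = sample_positions(preset, vtype, count, index, rng)
        for length, (chrom, pos) in zip(lengths, positions):
            if vtype == "SNP":
                del_span, ins_len = 1, 1
            elif vtype == "INS":
                del_span, ins_len = 0, length
            elif vtype == "DEL":
                del_span, ins_len = length, 0
            elif vtype == "DUP":
                del_span, ins_len = 0, length
            else:  # DELINS
                del_span, ins_len = length
            span = max(1, del_span) if vtype != "DUP" else ins_len
            chrom, pos = _resolve_collision(
                preset, vtype, chrom, pos, span, index, used, rng
            )
            ins: InsertionSpec | None = None
            if vtype == "SNP":
                ins = InsertionSpec(
                    mode="manual", literal=_snp_alt(rng, template, chrom, pos)
                )
            elif vtype in ("INS", "DELINS"):
                ins = InsertionSpec(mode="manual", literal=_random_seq(rng, ins_len))
            elif vtype == "DUP":
                ins = InsertionSpec(
                    mode="self_extract", source_chrom=chrom,
                    start=pos, end=pos + ins_len, copies=1, orientation="forward",
                )
            designed.append(
                _Designed(
                    mid=f"{id_prefix}M{serial:05d}",
                    vtype=vtype,
                    zygosity=zygosities[len(designed)],
                    chrom=chrom,
                    pos=pos,
                    del_span=del_span,
                    ins=ins,
                )
            )
            serial += 1
    # shuffle MID-level so variant types are interleaved in edit order
    designed = [designed[i] for i in rng.permutation(len(designed))]
    return designed


def _resolve_collision(
    preset: Preset,
    vtype: str,
    chrom: str,
    pos: int,
    span: int,
    index: GenomeIndex,
    used: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> tuple[str, int]:
    """Re-draw a position whose footprint collides or leaves the
    chromosome, up to ``max_redraws`` times."""
    for _ in range(max_redraws + 1):
        if pos + span <= index.lengths[chrom] and not any(
            s < pos + span and pos < e for s, e in used.get(chrom, [])
        ):
            used.setdefault(chrom, []).append((pos, pos + span))
            return chrom, pos
        chrom, pos = sample_positions(preset, vtype, 1, index, rng)[0]
    raise DesignError(
        f"could not place a {vtype} footprint of {span} bp after "
        f"{max_redraws} re-draws (genome saturated?)"
    )


def _to_var_lines(designed: Iterable[_Designed]) -> list[VariantSpec]:
    lines: list[VariantSpec] = []
    for d in designed:
        haps = (0,) if d.zygosity == "het" else (0, 1)
        for hap in haps:
            lines.append(
                VariantSpec(
                    vid=f"{d.mid}_h{hap}",
                    mid=d.mid,
                    hap=hap,
                    chrom=d.chrom,
                    pos=d.pos,
                    has_del=d.del_span > 0,
                    del_span=d.del_span,
                    has_ins=d.ins is not None,
                    ins_seq=d.ins if d.ins is not None else InsertionSpec(),
                )
            )
    return lines


def generate_var(
    preset: Preset,
    config: DesignConfig,
    index: GenomeIndex,
    template: Mapping[str, str] | None = None,
) -> list[VariantSpec]:
    """Design a complete VAR line list for one sample.

    Fully deterministic for a fixed config seed.  Random SNP/insertion
    content is materialized into manual literals at design time so that
    the two haplotype lines of a homozygous variant carry identical
    content.
    """
    rng = np.random.default_rng(config.seed)
    total = sample_total(preset, config, rng)
    used: dict[str, list[tuple[int, int]]] = {}
    designed = _design_block(preset, config, index, rng, total, "", used, template)
    return _to_var_lines(designed)


# ---------------------------------------------------------------------------
# Clonal trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneTree:
    """Edge list (parent, child, distance); the root is the unique
    parent that never appears as a child.  ``distance`` is the number of
    variants the child acquires on top of its parent's."""

    edges: tuple[tuple[str, str, int], ...]
    root: str = field(init=False)

    def __post_init__(self) -> None:
        parents = {e[0] for e in self.edges}
        children = [e[1] for e in self.edges]
        if len(set(children)) != len(children):
            raise DesignError("clone tree has a repeated child name")
        roots = parents - set(children)
        if len(roots) != 1:
            raise DesignError(
                f"clone tree must have exactly one root, found {sorted(roots)}"
            )
        object.__setattr__(self, "root", next(iter(roots)))
        # reachability check = acyclicity for a child-unique edge list
        reached = {self.root}
        frontier = [self.root]
        while frontier:
            node = frontier.pop()
            for p, c, _ in self.edges:
                if p == node and c not in reached:
                    reached.add(c)
                    frontier.append(c)
        if reached != parents | set(children):
            raise DesignError("clone tree contains a cycle or a disconnected part")

    def bfs_edges(self) -> list[tuple[str, str, int]]:
        ordered: list[tuple[str, str, int]] = []
        frontier = [self.root]
        while frontier:
            node = frontier.pop(0)
            for p, c, d in self.edges:
                if p == node:
                    ordered.append((p, c, d))
                    frontier.append(c)
        return ordered

    def clones(self) -> list[str]:
        return [self.root] + [c for _, c, _ in self.bfs_edges()]


def parse_clone_tree(text: str) -> CloneTree:
    """Parse a tree file: one ``parent child distance`` triple per line."""
    edges: list[tuple[str, str, int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise DesignError(f"tree line {lineno}: expected 3 fields, got {len(fields)}")
        parent, child, dist_s = fields
        try:
            dist = int(dist_s)
        except ValueError as exc:
            raise DesignError(f"tree line {lineno}: non-integer distance {dist_s!r}") from exc
        if dist < 0:
            raise DesignError(f"tree line {lineno}: negative distance")
        edges.append((parent, child, dist))
    if not edges:
        raise DesignError("empty clone tree")
    return CloneTree(edges=tuple(edges))


def expand_clones(
    root_var: list[VariantSpec],
    tree: CloneTree,
    preset: Preset,
    config: DesignConfig,
    index: GenomeIndex,
    template: Mapping[str, str] | None = None,
) -> dict[str, list[VariantSpec]]:
    """Per-clone VAR lists: child = parent's lines + ``distance`` new
    MID-level variants unique to the child (VIDs carry the clone name).

    Variant sets are therefore monotone along every root-to-leaf path.
    """
    rng = np.random.default_rng(config.seed)
    used: dict[str, list[tuple[int, int]]] = {}
    for v in root_var:  # reserve the root's footprints
        span = v.del_span if v.has_del else (
            v.ins_seq.end - v.ins_seq.start
            if v.ins_seq.mode == "self_extract" else 1
        )
        used.setdefault(v.chrom, []).append((v.pos, v.pos + max(1, span)))
    clones: dict[str, list[VariantSpec]] = {tree.root: list(root_var)}
    for parent, child, dist in tree.bfs_edges():
        new = _design_block(
            preset, config, index, rng, dist, f"{child}_", used, template
        )
        clones[child] = clones[parent] + _to_var_lines(new)
    return clones
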