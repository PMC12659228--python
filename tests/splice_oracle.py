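"""Independent splice-replay oracle for sequential genome editing.

The oracle represents the mutated chromosome as a flat token list, each
token tagged with the template position it originated from (``None``
for inserted bases), and replays edits by naive list splicing.  It
never consults a position map, so agreement with the editor checks the
map-based implementation against first principles.

A ``mask`` mirrors which template positions the map rules would mark
deleted, which the random-script generator uses to emit only
well-defined edit scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SpliceOracle:
    def __init__(self, seq: str):
        self.n = len(seq)
        self.tokens: list[tuple[int | None, str]] = list(enumerate(seq))
        self.mask = [False] * self.n  # template positions marked deleted

    # -- helpers --------------------------------------------------------
    def _idx(self, t: int) -> int:
        for i, (tag, _) in enumerate(self.tokens):
            if tag == t:
                return i
        raise AssertionError(f"template position {t} not present in oracle")

    def sequence(self) -> str:
        return "".join(b for _, b in self.tokens)

    def index_of_tag(self, t: int) -> int | None:
        """Physical index of template position t, None if masked."""
        if self.mask[t]:
            return None
        return self._idx(t)

    # -- edits ----------------------------------------------------------
    def delete(self, t: int, span: int) -> None:
        assert not any(self.mask[t : t + span]) and t + span <= self.n
        i = self._idx(t)
        del self.tokens[i : i + span]
        for k in range(t, t + span):
            self.mask[k] = True

    def insert(self, t: int, seq: str) -> None:
        assert not self.mask[t]
        i = self._idx(t)
        self.tokens[i:i] = [(None, b) for b in seq]

    def insert_after_block(self, t: int, seq: str) -> None:
        """Anchor at the first unmasked template position >= t; append at
        the chromosome end when nothing survives."""
        for tp in range(t, self.n):
            if not self.mask[tp]:
                self.insert(tp, seq)
                return
        self.tokens.extend((None, b) for b in seq)

    def delins(self, t: int, span: int, seq: str) -> None:
        self.delete(t, span)
        self.insert_after_block(t, seq)

    def extract(self, start: int, end: int, copies: int, orientation: str) -> str:
        """Contiguous physical slice between the endpoint tokens."""
        assert not self.mask[start] and not self.mask[end - 1]
        i0 = self._idx(start)
        i1 = self._idx(end - 1)
        seq = "".join(b for _, b in self.tokens[i0 : i1 + 1])
        if orientation == "reverse":
            seq = _revcomp(seq)
        return seq * copies


@dataclass(frozen=True)
class Op:
    kind: str  # "del" | "ins" | "delins" | "dup"
    t: int
    span: int = 0
    seq: str = ""
    # dup (self-extract insertion) fields
    start: int = 0
    end: int = 0
    copies: int = 1
    orientation: str = "forward"


def random_script(
    rng: np.random.Generator, n: int, n_ops: int, max_span: int = 6, max_ins: int = 8
) -> list[Op]:
    """A random, always-well-defined edit script for an n-bp chromosome.

    Validity is tracked with the same masking rule the editor enforces,
    so scripts never delete already-deleted positions or anchor
    extractions on masked endpoints.
    """
    bases = "ACGT"
    mask = [False] * n
    ops: list[Op] = []
    while len(ops) < n_ops:
        kind = rng.choice(["del", "ins", "delins", "dup"], p=[0.3, 0.3, 0.3, 0.1])
        for _ in range(30):  # rejection-sample a valid locus
            t = int(rng.integers(0, n))
            if mask[t]:
                continue
            if kind == "ins":
                seq = "".join(rng.choice(list(bases), size=int(rng.integers(1, max_ins + 1))))
                ops.append(Op("ins", t, seq=seq))
                break
            if kind in ("del", "delins"):
                span = int(rng.integers(1, max_span + 1))
                if t + span > n or any(mask[t : t + span]):
                    continue
                if kind == "del":
                    ops.append(Op("del", t, span=span))
                else:
                    seq = "".join(
                        rng.choice(list(bases), size=int(rng.integers(1, max_ins + 1)))
                    )
                    ops.append(Op("delins", t, span=span, seq=seq))
                for k in range(t, t + span):
                    mask[k] = True
                break
            # dup: self-extract insertion anchored at t
            w = int(rng.integers(1, max_span + 1))
            start = int(rng.integers(0, max(1, n - w)))
            end = start + w
            if end > n or mask[start] or mask[end - 1]:
                continue
            ops.append(
                Op(
                    "dup", t, start=start, end=end,
                    copies=int(rng.integers(1, 3)),
                    orientation=str(rng.choice(["forward", "reverse"])),
                )
            )
            break
        else:
            continue
    return ops


def replay(oracle: SpliceOracle, op: Op) -> None:
    if op.kind == "del":
        oracle.delete(op.t, op.span)
    elif op.kind == "ins":
        oracle.insert(op.t, op.seq)
    elif op.kind == "delins":
        oracle.delins(op.t, op.span, op.seq)
    elif op.kind == "dup":
        seq = oracle.extract(op.start, op.end, op.copies, op.orientation)
        oracle.insert(op.t, seq)
    else:
        raise AssertionError(op.kind)
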