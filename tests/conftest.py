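from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from somasim.fixtures import make_catalogue, make_genome
from somasim.preset_builder import build_preset
from somasim.var_model import InsertionSpec, VariantSpec

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """Small two-chromosome genome written to FASTA once per session."""
    path = tmp_path_factory.mktemp("genome") / "toy.fa"
    seqs, index = make_genome({"chr1": 60_000, "chr2": 30_000}, seed=11, fasta_path=path)
    return {"seqs": seqs, "index": index, "fasta": path}


@pytest.fixture(scope="session")
def breast_preset():
    """Preset mined from a synthetic catalogue with known proportions."""
    df, truth = make_catalogue(
        n_samples=40,
        zyg_props={"het": 0.9, "hom": 0.1},
        mean_variants=80.0,
        chrom_lengths={"chr1": 60_000, "chr2": 30_000},
        seed=202,
    )
    return build_preset(df, "breast", "synthetic"), truth


def apply_op(g, op, chrom="chr1", rng=None):
    """Apply a splice-oracle Op through the editor's public API."""
    from somasim.genome_editor import apply_variant

    if op.kind == "del":
        v = VariantSpec("x", "x", 0, chrom, op.t, True, op.span, False)
    elif op.kind == "ins":
        v = VariantSpec(
            "x", "x", 0, chrom, op.t, False, 0, True,
            InsertionSpec(mode="manual", literal=op.seq),
        )
    elif op.kind == "delins":
        v = VariantSpec(
            "x", "x", 0, chrom, op.t, True, op.span, True,
            InsertionSpec(mode="manual", literal=op.seq),
        )
    elif op.kind == "dup":
        v = VariantSpec(
            "x", "x", 0, chrom, op.t, False, 0, True,
            InsertionSpec(
                mode="self_extract", source_chrom=chrom,
                start=op.start, end=op.end,
                copies=op.copies, orientation=op.orientation,
            ),
        )
    else:
        raise AssertionError(op.kind)
    return apply_variant(g, v, rng=rng or np.random.default_rng(0))
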