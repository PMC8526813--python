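"""Shared fixtures: small expression matrices, a demographics table built
from printed cohort counts, and synthetic cohorts at test scale."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stromascope import (BULK_LOG2, BulkSimConfig, ExpressionMatrix,
                         GeneSignature, generate_bulk)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples, log2 scale."""
    df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                      index=["g1", "g2", "g3"], columns=["s1", "s2"])
    return ExpressionMatrix(df, BULK_LOG2)


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    df = pd.DataFrame(rng.normal(7, 1, size=(20, 12)),
                      index=[f"g{i}" for i in range(20)],
                      columns=[f"s{j}" for j in range(12)])
    return ExpressionMatrix(df, BULK_LOG2)


def demographics_annotation() -> pd.DataFrame:
    """Discovery-cohort annotation reconstructed from its printed counts:
    763 tumours (144 group 3, 326 group 4, 223 SHH, 70 WNT); metastasis
    annotated for 573 of them (43/109, 101/255, 26/160 and 6/49 positive
    per subgroup respectively)."""
    spec = {  # subgroup -> (total, n_met, n_annotated)
        "Group3": (144, 43, 109),
        "Group4": (326, 101, 255),
        "SHH": (223, 26, 160),
        "WNT": (70, 6, 49),
    }
    rows = []
    for sg, (total, met, annotated) in spec.items():
        flags = ([True] * met + [False] * (annotated - met)
                 + [None] * (total - annotated))
        for f in flags:
            rows.append({"subgroup": sg, "metastasis": f})
    ann = pd.DataFrame(rows)
    ann.index = pd.Index([f"S{i:04d}" for i in range(len(ann))],
                         name="sample_id")
    return ann


@pytest.fixture
def demographics() -> pd.DataFrame:
    return demographics_annotation()


@pytest.fixture(scope="session")
def small_bulk():
    """A reduced synthetic bulk cohort for fast module tests."""
    cfg = BulkSimConfig(seed=11, n_genes=400, n_samples=120,
                        n_signature_genes=25, n_driver_genes=12,
                        n_rl_decoys=60)
    return generate_bulk(cfg)


@pytest.fixture
def stromal_sig(small_bulk) -> GeneSignature:
    return small_bulk.stromal_signature
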