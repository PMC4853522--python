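"""Shared fixtures: a small spiked dataset and reference locus-id lists."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import traitsam as ts

# Curated rice RAP locus ids of ion-homeostasis and transport genes
# (Na+/H+ exchangers, K+ transporters, anion transporters, channels and
# membrane-intrinsic proteins); used to exercise identifier parsing on
# real-world inputs.
ION_TRANSPORT_LOCI = [
    "Os01g0557500", "Os01g0645200", "Os05g0382200", "Os06g0152200",
    "Os06g0701600", "Os08g0503700", "Os09g0286400", "Os09g0299400",
    "Os09g0484900", "Os10g0436900", "Os11g0648000", "Os12g0170300",
    "Os12g0641100", "Os01g0210700", "Os01g0369300", "Os01g0648000",
    "Os01g0696100", "Os01g0932500", "Os02g0519100", "Os02g0612700",
    "Os03g0337500", "Os03g0575200", "Os03g0656500", "Os04g0401700",
    "Os04g0682800", "Os06g0625900", "Os06g0671000", "Os07g0102100",
    "Os07g0669700", "Os01g0678500", "Os01g0908500", "Os02g0138900",
    "Os02g0720700", "Os04g0605500", "Os04g0653200", "Os05g0594200",
    "Os03g0150800", "Os03g0161200", "Os03g0195800", "Os03g0838400",
    "Os04g0185600", "Os05g0477800", "Os08g0155400", "Os08g0406400",
    "Os09g0240500", "Os10g0444600", "Os01g0588200", "Os01g0704100",
    "Os01g0975900", "Os02g0117500", "Os02g0255000", "Os02g0823100",
    "Os03g0129100", "Os03g0758300", "Os04g0643600", "Os05g0231700",
    "Os06g0527400", "Os08g0555000", "Os09g0541000", "Os12g0639800",
]

#: the documented RAP -> MSU conversion example
RAP_MSU_EXAMPLE = ("Os06g0699400", "LOC_Os06g48590")


def make_matrix(values, probe_ids=None, genotypes=None, condition="stressed",
                scale="log2"):
    """Build a minimal ExpressionMatrix around a raw value array."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    probe_ids = probe_ids or [f"Os01g{i:07d}" for i in range(1, m + 1)]
    genotypes = genotypes or [f"G{j}" for j in range(n)]
    samples = pd.DataFrame({
        "genotype": genotypes,
        "condition": condition,
        "replicate": 1,
    }, index=pd.Index([f"S{j}" for j in range(n)], name="sample_id"))
    return ts.ExpressionMatrix(values, probe_ids, samples, scale=scale)


@pytest.fixture(scope="session")
def spiked_dataset():
    """One small spiked simulation shared across tests (read-only)."""
    cfg = ts.SimulationConfig(n_probes=400, seed=11,
                              spiked_traits=("shoot_Na",), spike_fraction=0.03)
    matrix, traits, truth = ts.generate_dataset(cfg)
    return cfg, matrix, traits, truth


@pytest.fixture(scope="session")
def normalized_stressed(spiked_dataset):
    """The spiked dataset, preprocessed and restricted to stressed samples."""
    _, matrix, traits, _ = spiked_dataset
    norm = ts.log2_transform(ts.quantile_normalize(matrix))
    return ts.subset_condition(norm, "stressed"), traits
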