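"""Shared fixtures: small planted datasets and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synsig.datatypes import ExpressionDataset, SimulationConfig
from synsig.simulate import simulate_disease, simulate_drug


def make_dataset(values: np.ndarray, n_a: int, n_b: int,
                 labels=("case", "control"), prefix="s") -> ExpressionDataset:
    """Wrap a raw genes x samples array into a validated dataset."""
    n_genes = values.shape[0]
    genes = pd.Index([f"g{i:03d}" for i in range(n_genes)], name="gene_id")
    samples = [f"{prefix}{i}" for i in range(n_a + n_b)]
    groups = pd.Series([labels[0]] * n_a + [labels[1]] * n_b,
                       index=pd.Index(samples, name="sample_id"))
    return ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=samples), groups=groups
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Independent Benjamini-Hochberg step-up, written from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top  # 1-based rank of this p value
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


@pytest.fixture
def planted_config() -> SimulationConfig:
    """Small planted-signature condition used across unit tests."""
    return SimulationConfig(
        n_genes=400, n_case=25, n_control=25,
        frac_up=0.05, frac_down=0.05,
        effect_size=2.0, noise_sd=0.5,
        n_treated=25, n_drug_control=25, seed=42,
    )


@pytest.fixture
def planted_disease(planted_config):
    return simulate_disease(planted_config)


@pytest.fixture
def reverse_drug(planted_config, planted_disease):
    _, truth = planted_disease
    return simulate_drug(planted_config, truth, drug_id="rev", seed=43)
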