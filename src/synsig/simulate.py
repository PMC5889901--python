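"""Synthetic expression data with planted, fully known ground truth.

The generator emulates the pipeline's two input kinds on log2 scale:

* a disease dataset -- per-gene baselines drawn uniformly from a stated
  range, i.i.d. Gaussian noise everywhere, and a planted fraction of
  up/down genes whose case samples are shifted by ``effect_size``;
* drug datasets whose planted effects *reverse*, *mimic*, or ignore
  (*null*) the disease signature, or reverse a random fraction of it
  (*partial*).

Mimic mode is generated as the exact mirror image of the same-seed
reverse dataset about the gene baselines.  Because the noise is
zero-mean Gaussian this is distributionally identical to drawing fresh
noise, and it makes the reverse/mimic score symmetry exact rather than
approximate: every per-gene t statistic, and hence every z-score and
the final indicator score, is negated bit-for-bit.

Identical seeds give bit-identical output (numpy PCG64 generator).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from synsig.datatypes import ExpressionDataset, GroundTruth, SimulationConfig

__all__ = ["simulate_disease", "simulate_drug"]


def _gene_ids(n: int) -> pd.Index:
    width = len(str(n))
    return pd.Index([f"g{i:0{width}d}" for i in range(1, n + 1)], name="gene_id")


def simulate_disease(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a case/control disease dataset and its ground truth.

    Planted up genes are shifted by ``+effect_size`` in case samples,
    down genes by ``-effect_size``; every entry carries Gaussian noise
    of sd ``noise_sd`` on top of a per-gene baseline drawn once from
    ``baseline_range``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_up = round(config.frac_up * config.n_genes)
    n_down = round(config.frac_down * config.n_genes)
    planted = rng.choice(config.n_genes, size=n_up + n_down, replace=False)

    direction = pd.Series("null", index=genes, dtype=object)
    direction.iloc[planted[:n_up]] = "up"
    direction.iloc[planted[n_up:]] = "down"

    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)
    n_samples = config.n_case + config.n_control
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))

    shift = np.zeros(config.n_genes)
    shift[direction.to_numpy() == "up"] = config.effect_size
    shift[direction.to_numpy() == "down"] = -config.effect_size

    values = baseline[:, None] + noise
    values[:, : config.n_case] += shift[:, None]

    samples = [f"case{i:03d}" for i in range(1, config.n_case + 1)] + [
        f"ctrl{i:03d}" for i in range(1, config.n_control + 1)
    ]
    groups = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control,
        index=pd.Index(samples, name="sample_id"),
    )
    data = ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=samples), groups=groups
    )
    return data, GroundTruth(disease_direction=direction)


def simulate_drug(
    config: SimulationConfig,
    truth: GroundTruth,
    drug_id: str = "drug",
    target_genes: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate one drug-treated dataset against a disease ground truth.

    Modes (``config.drug_mode``):

    * ``reverse`` -- treated samples shift planted disease up genes down
      and down genes up by ``drug_effect_size``;
    * ``mimic``   -- same-direction shifts, realised as the exact mirror
      of the reverse dataset about the baselines (see module docstring);
    * ``null``    -- no shift anywhere;
    * ``partial`` -- reverses a random fraction ``drug_partial_fraction``
      of the planted genes.

    ``target_genes`` restricts the drug's action to a subset of the
    planted signature (e.g. disjoint halves for two drugs).  ``seed``
    defaults to ``config.seed``; pass distinct seeds for distinct drugs.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    direction = truth.disease_direction
    genes = direction.index
    n_genes = len(genes)

    targetable = direction[direction != "null"].index
    if target_genes is not None:
        target_genes = pd.Index(target_genes)
        unknown = target_genes.difference(genes)
        if len(unknown) > 0:
            raise ValueError(f"unknown target genes: {list(unknown[:5])}")
        targetable = targetable.intersection(target_genes)

    if config.drug_mode == "partial":
        n_hit = round(config.drug_partial_fraction * len(targetable))
        hit = pd.Index(
            rng.choice(targetable.to_numpy(), size=n_hit, replace=False)
        )
    elif config.drug_mode == "null":
        hit = pd.Index([], dtype=object)
    else:
        hit = targetable

    # reverse-direction shift vector; mimic mirrors the whole dataset
    shift = np.zeros(n_genes)
    is_hit = genes.isin(hit)
    shift[is_hit & (direction == "up").to_numpy()] = -config.drug_effect_size
    shift[is_hit & (direction == "down").to_numpy()] = config.drug_effect_size

    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=n_genes)
    n_samples = config.n_treated + config.n_drug_control
    noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))

    deviations = noise.copy()
    deviations[:, : config.n_treated] += shift[:, None]
    mirror = -1.0 if config.drug_mode == "mimic" else 1.0
    values = baseline[:, None] + mirror * deviations

    samples = [f"{drug_id}_trt{i:03d}" for i in range(1, config.n_treated + 1)] + [
        f"{drug_id}_ctl{i:03d}" for i in range(1, config.n_drug_control + 1)
    ]
    groups = pd.Series(
        ["treated"] * config.n_treated + ["control"] * config.n_drug_control,
        index=pd.Index(samples, name="sample_id"),
    )
    data = ExpressionDataset(
        values=pd.DataFrame(values, index=genes, columns=samples), groups=groups
    )

    drug_dir = pd.Series("null", index=genes, dtype=object)
    sign = mirror * shift
    drug_dir[sign > 0] = "up"
    drug_dir[sign < 0] = "down"
    out_truth = GroundTruth(
        disease_direction=direction,
        drug_direction={**truth.drug_direction, drug_id: drug_dir},
    )
    return data, out_truth
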