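"""End-to-end driver: disease DEGs -> drug z -> pair combination ->
matching/scoring -> single-vs-combination ranking."""

from __future__ import annotations

import logging
from typing import Sequence

from synsig.combine import combine_pair, enumerate_pairs
from synsig.datatypes import (
    DiseaseSignature,
    DrugZProfile,
    ExpressionDataset,
    PipelineConfig,
    RankingResult,
    ScoreRecord,
)
from synsig.diffexpr import disease_degs, drug_zscores
from synsig.scoring import rank_triplet, score_all

log = logging.getLogger("synsig")

__all__ = ["run_pipeline"]


def run_pipeline(
    disease_data: dict[str, ExpressionDataset],
    drug_data: dict[str, ExpressionDataset],
    config: PipelineConfig | None = None,
) -> tuple[list[ScoreRecord], list[RankingResult]]:
    """Run the full scoring flow for every disease and every drug/pair.

    Parameters
    ----------
    disease_data
        Mapping disease id -> case/control dataset.
    drug_data
        Mapping drug id -> treated/control dataset (>= 2 drugs).
    config
        Thresholds; defaults to microarray mode (alpha 0.01, fold
        change 2, |z| > 1.96).

    Returns score records for all singles and pairs, plus one ranking
    verdict per pair per disease.
    """
    config = config or PipelineConfig()
    if len(drug_data) < 2:
        raise ValueError("need at least 2 drug datasets to form combinations")
    alpha = config.effective_alpha

    signatures: list[DiseaseSignature] = []
    for disease_id in sorted(disease_data):
        try:
            sig = disease_degs(
                disease_data[disease_id],
                alpha_bh=alpha,
                min_fold_change=config.min_fold_change,
                disease_id=disease_id,
                equal_var=config.equal_var,
            )
        except ValueError as exc:
            raise RuntimeError(f"[disease-degs] {disease_id}: {exc}") from exc
        log.info("disease %s: %d DEGs (alpha=%g, fc>=%g)",
                 disease_id, sig.N, alpha, config.min_fold_change)
        signatures.append(sig)

    singles: list[DrugZProfile] = []
    for drug_id in sorted(drug_data):
        try:
            prof = drug_zscores(
                drug_data[drug_id],
                treatment_id=drug_id,
                equal_var=config.equal_var,
                z_threshold=config.z_threshold,
                eps=config.clamp_eps,
            )
        except ValueError as exc:
            raise RuntimeError(f"[drug-z] {drug_id}: {exc}") from exc
        n_deg = int((prof.regulation != "none").sum())
        log.info("drug %s: %d regulated genes (|z|>%g)",
                 drug_id, n_deg, config.z_threshold)
        singles.append(prof)

    by_id = {p.treatment_id: p for p in singles}
    combos = []
    for a, b in enumerate_pairs(sorted(by_id)):
        try:
            combos.append(
                combine_pair(
                    by_id[a], by_id[b],
                    z_threshold=config.z_threshold, eps=config.clamp_eps,
                )
            )
        except ValueError as exc:
            raise RuntimeError(f"[combine] {a}+{b}: {exc}") from exc
    log.info("combined %d drug pairs", len(combos))

    records = score_all(list(singles) + list(combos), signatures)
    by_key = {(r.disease_id, r.treatment_id): r for r in records}
    for r in records:
        if r.flag:
            log.warning("score %s / %s flagged: %s",
                        r.treatment_id, r.disease_id, r.flag)
        else:
            log.info("score %s / %s: k=%d N=%d score=%.4f",
                     r.treatment_id, r.disease_id, r.k, r.N, r.score)

    rankings: list[RankingResult] = []
    for sig in signatures:
        for a, b in enumerate_pairs(sorted(by_id)):
            rankings.append(
                rank_triplet(
                    by_key[(sig.disease_id, a)],
                    by_key[(sig.disease_id, b)],
                    by_key[(sig.disease_id, f"{a}+{b}")],
                )
            )
    return records, rankings
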