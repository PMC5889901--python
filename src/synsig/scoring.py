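"""Signature matching, the indicator score, and treatment ranking.

A treatment profile is matched against a disease signature gene by
gene: every signature gene with a non-null drug regulation enters the
match table with coefficient I = +1 when the drug opposes the disease
direction (reversal) and I = -1 when it mirrors it.  The indicator
score is the signed mean evidence per matched gene scaled by signature
coverage,

    mean_signed = sum(I * |z|) / k
    p_k         = Phi(mean_signed)
    score       = mean_signed * k / N  (= Phi^-1(p_k) * k / N)

where k is the matched-gene count and N the disease DEG count.  The
direct form avoids the Phi -> Phi^-1 round trip, which saturates in
floating point once mean_signed exceeds about 8, but is algebraically
identical.  Positive scores predict therapeutic benefit.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from synsig.datatypes import (
    ComboZProfile,
    DiseaseSignature,
    DrugZProfile,
    MatchTable,
    RankingResult,
    ScoreRecord,
)

Profile = Union[DrugZProfile, ComboZProfile]

__all__ = ["match_genes", "score_treatment", "score_all", "rank_triplet"]

_MATCH_COLUMNS = ["gene", "disease_direction", "drug_regulation", "I", "magnitude"]


def match_genes(profile: Profile, signature: DiseaseSignature) -> MatchTable:
    """Match a treatment profile against a disease signature.

    Rows are exactly the signature genes whose profile regulation is up
    or down; I = +1 for opposite directions, -1 for identical ones.
    k = 0 (empty table) is a legal outcome handled downstream.
    """
    genes = signature.calls.index.intersection(profile.z.index)
    reg = profile.regulation.loc[genes]
    matched = genes[reg != "none"]
    disease_dir = signature.calls.loc[matched]
    drug_reg = profile.regulation.loc[matched]
    coeff = np.where(disease_dir.to_numpy() == drug_reg.to_numpy(), -1, 1)
    rows = pd.DataFrame(
        {
            "gene": matched,
            "disease_direction": disease_dir.to_numpy(),
            "drug_regulation": drug_reg.to_numpy(),
            "I": coeff,
            "magnitude": np.abs(profile.z.loc[matched].to_numpy()),
        },
        columns=_MATCH_COLUMNS,
    )
    return MatchTable(
        treatment_id=profile.treatment_id,
        disease_id=signature.disease_id,
        rows=rows,
    )


def score_treatment(match: MatchTable, N: int) -> ScoreRecord:
    """Indicator score of one treatment from its match table.

    A k = 0 match or N = 0 signature produces a flagged record with NaN
    score, excluded from ranking, so that "no evidence" is never
    conflated with "net-zero evidence".
    """
    k = match.k
    if N <= 0:
        return ScoreRecord(
            match.treatment_id, match.disease_id, k, N,
            float("nan"), float("nan"), float("nan"), flag="empty_signature",
        )
    if k == 0:
        return ScoreRecord(
            match.treatment_id, match.disease_id, 0, N,
            float("nan"), float("nan"), float("nan"), flag="no_matched_genes",
        )
    signed = match.rows["I"].to_numpy() * match.rows["magnitude"].to_numpy()
    mean_signed = float(signed.sum() / k)
    p_k = float(stats.norm.cdf(mean_signed))
    score = mean_signed * k / N
    return ScoreRecord(
        treatment_id=match.treatment_id,
        disease_id=match.disease_id,
        k=k,
        N=N,
        mean_signed=mean_signed,
        p_k=p_k,
        score=score,
    )


def score_all(
    profiles: Sequence[Profile], signatures: Sequence[DiseaseSignature]
) -> list[ScoreRecord]:
    """One ScoreRecord per (treatment, disease), deterministically ordered
    by (disease id, treatment id) regardless of input order."""
    if not profiles or not signatures:
        raise ValueError("profiles and signatures must both be nonempty")
    records = []
    for sig in sorted(signatures, key=lambda s: s.disease_id):
        for prof in sorted(profiles, key=lambda p: p.treatment_id):
            records.append(score_treatment(match_genes(prof, sig), sig.N))
    return records


def _effective(record: ScoreRecord) -> float:
    # flagged records carry no evidence; treat as non-positive for ranking
    return record.score if record.rankable else float("-inf")


def rank_triplet(
    score_a: ScoreRecord, score_b: ScoreRecord, score_ab: ScoreRecord
) -> RankingResult:
    """Compare a drug pair's combination score with its two singles.

    The best treatment is the score maximum, required to be strictly
    positive; the combination wins only if strictly greater than both
    singles (ties go to the single drugs, and a tie between the two
    singles goes to drug A).
    """
    if not (score_a.disease_id == score_b.disease_id == score_ab.disease_id):
        raise ValueError(
            f"mismatched disease ids: {score_a.disease_id!r}, "
            f"{score_b.disease_id!r}, {score_ab.disease_id!r}"
        )
    pair = (score_a.treatment_id, score_b.treatment_id)
    expected = "+".join(sorted(pair))
    if score_ab.treatment_id != expected:
        raise ValueError(
            f"combination id {score_ab.treatment_id!r} does not match pair {pair}"
        )
    a, b, ab = _effective(score_a), _effective(score_b), _effective(score_ab)
    if max(a, b, ab) <= 0 or all(np.isneginf([a, b, ab])):
        verdict = "none_effective"
    elif ab > a and ab > b:
        verdict = "combination_more_effective"
    elif a >= b:
        verdict = "single_A_best"
    else:
        verdict = "single_B_best"
    return RankingResult(
        disease_id=score_a.disease_id,
        pair=pair,
        score_a=score_a.score,
        score_b=score_b.score,
        score_ab=score_ab.score,
        verdict=verdict,
    )
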