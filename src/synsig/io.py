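"""TSV readers and writers for every pipeline artifact.

Formats
-------
Expression matrix
    TSV, first column ``gene_id``, header row of sample ids, log2 values.
Group annotation
    Two-column TSV ``sample_id<TAB>group`` with groups ``case``/``control``
    (disease) or ``treated``/``control`` (drug).
Signature
    TSV ``gene_id, direction, t, p, p_adj, log2fc``.
z-profile
    TSV ``gene_id, t, z, regulation`` (``t`` empty for combinations).
Score / ranking tables and the optional network edge list are written
by :func:`write_scores`, :func:`write_rankings`, :func:`write_edge_list`.

All outputs are re-readable by the matching reader; a schema comment
line (``# synsig <kind> v1``) is stamped at the top of each file.
"""

from __future__ import annotations

import os
from typing import Sequence, Union

import numpy as np
import pandas as pd

from synsig.datatypes import (
    ComboZProfile,
    DiseaseSignature,
    DrugZProfile,
    ExpressionDataset,
    RankingResult,
    ScoreRecord,
    ValidationError,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_signature",
    "write_signature",
    "read_zprofile",
    "write_zprofile",
    "write_scores",
    "write_rankings",
    "write_edge_list",
    "read_drug_manifest",
]

_VALID_GROUPS = {"case", "control", "treated"}


def _stamp(path: str, kind: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# synsig {kind} v1\n")


def read_expression(path: str, annotation_path: str) -> ExpressionDataset:
    """Load and validate an expression matrix plus its group annotation.

    Hard errors (duplicate gene ids, unknown group labels, missing
    values, sample mismatches) name the offending line or identifier.
    """
    matrix = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    matrix.index = matrix.index.astype(str)
    if matrix.index.duplicated().any():
        dupe = matrix.index[matrix.index.duplicated()][0]
        line = int(np.where(matrix.index == dupe)[0][-1]) + 2  # header is line 1
        raise ValidationError(
            f"{path}: duplicate gene id {dupe!r} (around line {line})"
        )
    if matrix.isna().any().any():
        gene = matrix.index[matrix.isna().any(axis=1)][0]
        raise ValidationError(f"{path}: missing value in gene {gene!r}")

    annot = pd.read_csv(
        annotation_path,
        sep="\t",
        header=None,
        names=["sample_id", "group"],
        comment="#",
        dtype=str,
    )
    # tolerate an optional header row
    if annot.iloc[0, 0] in ("sample_id", "sample"):
        annot = annot.iloc[1:]
    bad = annot.loc[~annot["group"].isin(_VALID_GROUPS)]
    if len(bad) > 0:
        row = bad.iloc[0]
        raise ValidationError(
            f"{annotation_path}: unknown group {row['group']!r} for sample "
            f"{row['sample_id']!r} (line {bad.index[0] + 1})"
        )
    groups = annot.set_index("sample_id")["group"]
    return ExpressionDataset(values=matrix, groups=groups)


def write_expression(
    data: ExpressionDataset, path: str, annotation_path: str
) -> None:
    data.values.to_csv(path, sep="\t", index_label="gene_id")
    data.groups.to_csv(annotation_path, sep="\t", header=False)


def write_signature(signature: DiseaseSignature, path: str) -> None:
    _stamp(path, "signature")
    stats = signature.stats
    if stats is None:
        stats = pd.DataFrame(index=signature.calls.index)
    out = stats.loc[signature.calls.index].copy()
    out.insert(0, "direction", signature.calls)
    with open(path, "a") as fh:
        fh.write(
            f"# disease={signature.disease_id} N={signature.N} "
            f"alpha_bh={signature.alpha_bh} min_fold_change={signature.min_fold_change}\n"
        )
        out.to_csv(fh, sep="\t", index_label="gene_id")


def read_signature(path: str, disease_id: str | None = None) -> DiseaseSignature:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    key, val = tok.split("=", 1)
                    meta[key] = val
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    table.index = table.index.astype(str)
    return DiseaseSignature(
        disease_id=disease_id or meta.get("disease", "disease"),
        calls=table["direction"],
        alpha_bh=float(meta.get("alpha_bh", "nan")),
        min_fold_change=float(meta.get("min_fold_change", "nan")),
        stats=table.drop(columns=["direction"]),
    )


def write_zprofile(profile: Union[DrugZProfile, ComboZProfile], path: str) -> None:
    _stamp(path, "zprofile")
    out = pd.DataFrame(index=profile.z.index)
    if isinstance(profile, ComboZProfile):
        out["p_s"] = profile.p_s
    else:
        out["t"] = profile.t
    out["z"] = profile.z
    out["regulation"] = profile.regulation
    with open(path, "a") as fh:
        fh.write(f"# treatment={profile.treatment_id}\n")
        out.to_csv(fh, sep="\t", index_label="gene_id")


def read_zprofile(path: str) -> DrugZProfile:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    key, val = tok.split("=", 1)
                    meta[key] = val
    table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    table.index = table.index.astype(str)
    return DrugZProfile(
        treatment_id=meta.get("treatment", os.path.basename(path)),
        z=table["z"],
        regulation=table["regulation"],
        t=table["t"] if "t" in table.columns else None,
    )


def scores_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "treatment_id": r.treatment_id,
                "disease_id": r.disease_id,
                "k": r.k,
                "N": r.N,
                "p_k": r.p_k,
                "score": r.score,
                "flag": r.flag,
            }
            for r in records
        ]
    )


def write_scores(records: Sequence[ScoreRecord], path: str) -> None:
    _stamp(path, "scores")
    with open(path, "a") as fh:
        scores_frame(records).to_csv(fh, sep="\t", index=False)


def rankings_frame(results: Sequence[RankingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "disease_id": r.disease_id,
                "drug_a": r.pair[0],
                "drug_b": r.pair[1],
                "score_a": r.score_a,
                "score_b": r.score_b,
                "score_ab": r.score_ab,
                "verdict": r.verdict,
            }
            for r in results
        ]
    )


def write_rankings(results: Sequence[RankingResult], path: str) -> None:
    _stamp(path, "rankings")
    with open(path, "a") as fh:
        rankings_frame(results).to_csv(fh, sep="\t", index=False)


def write_edge_list(records: Sequence[ScoreRecord], path: str) -> None:
    """Treatment--disease edges weighted by score, for network drawing;
    only rankable records with positive score are exported."""
    _stamp(path, "edges")
    rows = [
        {"treatment_id": r.treatment_id, "disease_id": r.disease_id, "score": r.score}
        for r in records
        if r.rankable and r.score > 0
    ]
    with open(path, "a") as fh:
        pd.DataFrame(rows, columns=["treatment_id", "disease_id", "score"]).to_csv(
            fh, sep="\t", index=False
        )


def read_drug_manifest(path: str) -> pd.DataFrame:
    """Manifest mapping drug id -> matrix path, annotation path.

    Three tab-separated columns: ``drug_id, matrix, annotation``; paths
    are resolved relative to the manifest's own directory.
    """
    manifest = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["drug_id", "matrix", "annotation"],
        comment="#",
        dtype=str,
    )
    if manifest.iloc[0, 0] == "drug_id":
        manifest = manifest.iloc[1:].reset_index(drop=True)
    if manifest["drug_id"].duplicated().any():
        dupe = manifest["drug_id"][manifest["drug_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate drug id {dupe!r}")
    base = os.path.dirname(os.path.abspath(path))
    for col in ("matrix", "annotation"):
        manifest[col] = [
            p if os.path.isabs(p) else os.path.join(base, p) for p in manifest[col]
        ]
    return manifest
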