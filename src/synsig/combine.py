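"""Pairwise drug combination: Fisher-type z-score combination.

For each gene the two drugs' z-scores are combined through their
upper-tail probabilities,

    x   = -2 * [ln(1 - Phi(z_a)) + ln(1 - Phi(z_b))]
    p_s = P(chi2_4 < x)            (lower-tail chi-square CDF, 4 df)
    z'  = Phi^-1(p_s)

so two strongly upregulating drugs push z' toward +inf and two strongly
downregulating drugs toward -inf.  The combined profile is symmetric in
the two drugs and regulation is called by the same +/-1.96 rule as for
single drugs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from synsig.datatypes import (
    CLAMP_EPS,
    Z_THRESHOLD,
    ComboZProfile,
    DrugZProfile,
)

__all__ = ["enumerate_pairs", "combine_pair", "combine_zscores"]


def enumerate_pairs(treatments: list[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered pairs of treatment ids, lexicographically
    ordered within and across pairs for deterministic output."""
    ids = list(treatments)
    if len(ids) != len(set(ids)):
        seen, dupes = set(), []
        for x in ids:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise ValueError(f"duplicate treatment ids: {dupes}")
    if len(ids) < 2:
        raise ValueError("need at least 2 treatments to form pairs")
    return list(itertools.combinations(sorted(ids), 2))


def combine_zscores(
    z_a: np.ndarray, z_b: np.ndarray, eps: float = CLAMP_EPS
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised combination of two z arrays; returns ``(p_s, z')``.

    Upper-tail probabilities and p_s are clamped to [eps, 1 - eps]
    before the logs and the normal quantile, keeping z' finite.
    """
    ua = np.clip(stats.norm.sf(np.asarray(z_a, dtype=float)), eps, 1.0 - eps)
    ub = np.clip(stats.norm.sf(np.asarray(z_b, dtype=float)), eps, 1.0 - eps)
    x = -2.0 * (np.log(ua) + np.log(ub))
    p_s = np.clip(stats.chi2.cdf(x, df=4), eps, 1.0 - eps)
    return p_s, stats.norm.ppf(p_s)


def combine_pair(
    profile_a: DrugZProfile,
    profile_b: DrugZProfile,
    z_threshold: float = Z_THRESHOLD,
    eps: float = CLAMP_EPS,
) -> ComboZProfile:
    """Combined z'-profile of an unordered drug pair.

    The gene universe is the intersection of the two profiles; an empty
    intersection is an error.
    """
    genes = profile_a.z.index.intersection(profile_b.z.index)
    if len(genes) == 0:
        raise ValueError(
            f"profiles {profile_a.treatment_id!r} and "
            f"{profile_b.treatment_id!r} share no genes"
        )
    pair = tuple(sorted([profile_a.treatment_id, profile_b.treatment_id]))
    p_s, z_comb = combine_zscores(
        profile_a.z.loc[genes].to_numpy(), profile_b.z.loc[genes].to_numpy(), eps=eps
    )
    z_series = pd.Series(z_comb, index=genes, name="z_combined")
    reg = pd.Series("none", index=genes, dtype=object)
    reg[z_series > z_threshold] = "up"
    reg[z_series < -z_threshold] = "down"
    return ComboZProfile(pair=pair, p_s=pd.Series(p_s, index=genes), z=z_series, regulation=reg)
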