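"""Cross-kinase score harmonization, GoF/LoF classification, positional
enrichment with FDR control, conservation rules, and SASA stratification.

Abundance scores are zero-centered on synonymous variants and rescaled so the
per-kinase nonsense (stop-gain) means land on a common reference, then
averaged across substrate backgrounds. Decoupled activity scores are rescaled
piecewise (positives by the mean positive score, negatives by the magnitude of
the mean negative score, zeros untouched) with a between-kinase offset that
aligns the mean of high-confidence positives (> 0.20). Variants are classed
GoF/LoF/neutral, positions tested for over-representation of either class with
a one-sided Fisher's exact test and Benjamini-Hochberg correction (FDR <=
0.10), and cross-kinase conserved positions called by a 2-of-3 rule with a
20th-percentile rescue for the remaining kinase. Residues are stratified by
solvent-accessible surface area into ordinal exposure bins.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


# --------------------------------------------------------------------------
# normalization / harmonization
# --------------------------------------------------------------------------


def normalize_abundance(
    scores: pd.DataFrame, reference: float | None = None, center_first: bool = True
) -> pd.DataFrame:
    """Normalize abundance scores for cross-kinase comparison.

    Per kinase: subtract the synonymous-class mean (zero-centering neutral
    changes), then multiply by reference / centered-nonsense-mean so stop-gain
    baselines align on a common reference (default: the cross-kinase mean of
    centered nonsense means). Finally average each variant across its substrate
    backgrounds. Input needs columns kinase, substrate, position, wt_aa,
    mut_aa, variant_class, score.
    """
    df = scores.copy()
    stats = {}
    for kin, grp in df.groupby("kinase"):
        syn = grp.loc[grp["variant_class"] == "synonymous", "score"]
        non = grp.loc[grp["variant_class"] == "nonsense", "score"]
        if syn.empty or non.empty:
            raise ValueError(f"kinase {kin}: need >=1 synonymous and >=1 nonsense variant")
        syn_mean = syn.mean()
        non_mean = non.mean() - (syn_mean if center_first else 0.0)
        if non_mean == 0:
            raise ValueError(f"kinase {kin}: centered nonsense mean is zero; scale undefined")
        stats[kin] = (syn_mean, non_mean)
    ref = reference if reference is not None else float(np.mean([v[1] for v in stats.values()]))
    for kin, (syn_mean, non_mean) in stats.items():
        sel = df["kinase"] == kin
        if center_first:
            df.loc[sel, "score"] = (df.loc[sel, "score"] - syn_mean) * (ref / non_mean)
        else:
            df.loc[sel, "score"] = df.loc[sel, "score"] * (ref / non_mean) - syn_mean
    grouped = (
        df[df["variant_class"].isin(["missense", "nonsense", "synonymous"])]
        .groupby(["kinase", "position", "wt_aa", "mut_aa", "variant_class"], as_index=False)["score"]
        .mean()
    )
    grouped.attrs["reference"] = ref
    return grouped


def harmonize_activity(scores: pd.DataFrame, positive_floor: float = 0.20) -> pd.DataFrame:
    """Two-step harmonization of decoupled activity scores across kinases.

    Step 1 (per kinase): positive scores divided by the mean of all positive
    scores, negative scores by |mean of all negative scores|; zeros unchanged.
    Step 2: an additive per-kinase offset aligns the mean rescaled score of
    variants whose pre-offset rescaled score exceeds ``positive_floor`` to the
    cross-kinase mean of those means. Needs columns kinase, score.
    """
    df = scores.copy()
    for kin, grp in df.groupby("kinase"):
        pos = grp.loc[grp["score"] > 0, "score"]
        neg = grp.loc[grp["score"] < 0, "score"]
        if pos.empty or neg.empty:
            raise ValueError(f"kinase {kin}: need >=1 positive and >=1 negative score")
        sel = df["kinase"] == kin
        rescaled = df.loc[sel, "score"].copy()
        rescaled[rescaled > 0] = rescaled[rescaled > 0] / pos.mean()
        rescaled[rescaled < 0] = rescaled[rescaled < 0] / abs(neg.mean())
        df.loc[sel, "score"] = rescaled
    hi_means = {}
    for kin, grp in df.groupby("kinase"):
        hi = grp.loc[grp["score"] > positive_floor, "score"]
        if hi.empty:
            warnings.warn(f"kinase {kin}: no scores > {positive_floor}; offset skipped")
        else:
            hi_means[kin] = hi.mean()
    if hi_means:
        ref = float(np.mean(list(hi_means.values())))
        for kin, m in hi_means.items():
            df.loc[df["kinase"] == kin, "score"] += ref - m
    return df


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------


def classify_variants(
    scores: pd.DataFrame,
    phenotype: str,
    gof_threshold: float = 0.24,
    lof_threshold: float = -0.21,
    lof_negative_fraction: float = 0.45,
) -> pd.DataFrame:
    """GoF/LoF/neutral labels (strict inequalities, exhaustive and exclusive).

    Abundance: GoF if score > per-kinase mean of all positive scores; LoF if
    score < ``lof_negative_fraction`` times the per-kinase mean of all negative
    scores. Activity: fixed thresholds (GoF > 0.24, LoF < -0.21).
    """
    df = scores.copy()
    df["label"] = "neutral"
    df["phenotype"] = phenotype
    if phenotype == "activity":
        df.loc[df["score"] > gof_threshold, "label"] = "GoF"
        df.loc[df["score"] < lof_threshold, "label"] = "LoF"
    elif phenotype == "abundance":
        for kin, grp in df.groupby("kinase"):
            pos_mean = grp.loc[grp["score"] > 0, "score"].mean()
            neg_mean = grp.loc[grp["score"] < 0, "score"].mean()
            sel = df["kinase"] == kin
            if np.isfinite(pos_mean):
                df.loc[sel & (df["score"] > pos_mean), "label"] = "GoF"
            if np.isfinite(neg_mean):
                df.loc[sel & (df["score"] < lof_negative_fraction * neg_mean), "label"] = "LoF"
    else:
        raise ValueError("phenotype must be 'abundance' or 'activity'")
    return df


# --------------------------------------------------------------------------
# positional enrichment
# --------------------------------------------------------------------------


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail (over-representation) p of the 2x2 table [[a, b], [c, d]].

    a = direction hits at the position, b = other variants at the position,
    c = direction hits elsewhere, d = the rest; p = P(X >= a) for
    X ~ Hypergeometric(N, K=a+c, n=a+b).
    """
    N = a + b + c + d
    return float(hypergeom.sf(a - 1, N, a + c, a + b))


def position_enrichment(
    labels: pd.DataFrame, direction: str, fdr: float = 0.10, positions: list[int] | None = None
) -> pd.DataFrame:
    """Per-position one-sided Fisher test of GoF/LoF over-representation.

    Tests each position against all other positions, per kinase;
    Benjamini-Hochberg correction is applied across positions within each
    kinase, and positions with q <= ``fdr`` are flagged enriched.
    """
    if direction not in ("GoF", "LoF"):
        raise ValueError("direction must be 'GoF' or 'LoF'")
    rows = []
    for kin, grp in labels.groupby("kinase"):
        pos_list = positions or sorted(grp["position"].unique())
        if len(pos_list) < 2:
            raise ValueError("need >=2 positions for enrichment testing")
        is_dir = grp["label"] == direction
        total_dir = int(is_dir.sum())
        total = len(grp)
        pvals = []
        counts = []
        for pos in pos_list:
            at_pos = grp["position"] == pos
            a = int((at_pos & is_dir).sum())
            b = int(at_pos.sum()) - a
            c = total_dir - a
            d = total - a - b - c
            pvals.append(fisher_one_sided(a, b, c, d) if a > 0 else 1.0)
            counts.append((a, b, c, d))
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for pos, p, q, (a, b, c, d) in zip(pos_list, pvals, qvals, counts):
            rows.append(
                {
                    "kinase": kin, "position": pos, "direction": direction,
                    "a": a, "b": b, "c": c, "d": d,
                    "p": p, "q": float(q), "enriched": bool(q <= fdr),
                }
            )
    return pd.DataFrame(rows)


def _nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile (deterministic): the ceil(pct*n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty distribution")
    rank = max(1, int(np.ceil(pct / 100.0 * len(v))))
    return float(v[rank - 1])


def conserved_positions(
    enrichment: pd.DataFrame,
    scores: pd.DataFrame,
    direction: str,
    min_kinases: int = 2,
    rescue_pct: float = 20.0,
    rescue_min_variants: int = 2,
) -> pd.DataFrame:
    """Cross-kinase conservation of enriched positions with a percentile rescue.

    A position is conserved when enriched in at least ``min_kinases`` kinases.
    A kinase that missed the FDR threshold at a conserved position is rescued
    when it has >= ``rescue_min_variants`` variants there in the bottom (LoF)
    or top (GoF) ``rescue_pct`` percentile of its full score distribution.
    """
    kinases = sorted(enrichment["kinase"].unique())
    if len(kinases) < 2:
        raise ValueError("need >=2 kinases for conservation analysis")
    enr = enrichment[enrichment["direction"] == direction]
    by_pos = enr.groupby("position")["enriched"].sum()
    rows = []
    for pos, n_enr in by_pos.items():
        conserved = bool(n_enr >= min_kinases)
        rescued = []
        if conserved:
            missing = enr.loc[(enr["position"] == pos) & ~enr["enriched"], "kinase"]
            for kin in missing:
                kin_scores = scores.loc[scores["kinase"] == kin, "score"].to_numpy()
                at_pos = scores.loc[
                    (scores["kinase"] == kin) & (scores["position"] == pos), "score"
                ].to_numpy()
                if direction == "LoF":
                    cut = _nearest_rank_percentile(kin_scores, rescue_pct)
                    n_extreme = int((at_pos <= cut).sum())
                else:
                    cut = _nearest_rank_percentile(kin_scores, 100.0 - rescue_pct)
                    n_extreme = int((at_pos >= cut).sum())
                if n_extreme >= rescue_min_variants:
                    rescued.append(kin)
        rows.append(
            {
                "position": pos, "direction": direction, "n_enriched": int(n_enr),
                "conserved": conserved, "rescued_kinases": ";".join(rescued),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# SASA stratification
# --------------------------------------------------------------------------

#: (lower bound inclusive?, bin test) is encoded directly below; boundary 50
#: is assigned to the moderately-exposed bin (label 0).
SASA_LABELS = {
    -1: "strongly_exposed",  # SASA > 150
    0: "moderately_exposed",  # 50 <= SASA <= 150 (50 by assignment)
    1: "buried",  # 10 <= SASA < 50
    2: "strongly_buried",  # 2.5 <= SASA < 10
    3: "core_hydrophobic",  # SASA < 2.5
}


def sasa_label(sasa: float) -> int:
    """Ordinal exposure label from per-residue SASA in square Angstroms."""
    if sasa < 0:
        raise ValueError("SASA must be non-negative")
    if sasa > 150:
        return -1
    if sasa >= 50:
        return 0
    if sasa >= 10:
        return 1
    if sasa >= 2.5:
        return 2
    return 3


def stratify_sasa(sasa: pd.DataFrame) -> pd.DataFrame:
    """Attach ordinal exposure labels to a per-residue SASA table (column sasa_A2)."""
    out = sasa.copy()
    out["label"] = out["sasa_A2"].map(sasa_label)
    out["stratum"] = out["label"].map(SASA_LABELS)
    return out
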