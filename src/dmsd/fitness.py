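"""Selection-count fitness scoring: counting, filtering, log2FC, collapse.

Short-read barcode counts from pre/post-methotrexate selection replicates are
turned into per-variant score matrices: barcodes are counted by exact match
against the lookup table, filtered (pre-selection coverage strictly >20 reads,
library-tag consistency, at most two amino-acid changes), converted to
depth-normalised per-barcode log2 fold changes with a pseudocount, cleaned of
within-variant outliers (|z| > 2), and collapsed to variant-level scores by
averaging across barcodes and replicates. This replaces the external
MAGeCK/Rosace calls of the original workflow with defined operations.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .design import BARCODE_ANCHOR, StudyDesign


class EmptyFilterResult(RuntimeError):
    """All barcodes were removed by filtering."""


# --------------------------------------------------------------------------
# counting
# --------------------------------------------------------------------------


def extract_barcode(read: str, barcode_length: int = 16) -> str | None:
    """Barcode = the ``barcode_length`` nt immediately 5' of the constant anchor."""
    i = read.find(BARCODE_ANCHOR)
    if i < barcode_length:
        return None
    return read[i - barcode_length : i]


def count_barcodes(
    reads_by_sample: dict, lookup: pd.DataFrame, barcode_length: int = 16
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count lookup-table barcodes in merged short reads, per sample.

    Reads lacking the anchor, or whose barcode has no exact lookup match, are
    not assigned; they are tallied in the returned diagnostics table.
    """
    known = set(lookup["barcode"])
    counts: dict[str, dict[str, int]] = {}
    diag_rows = []
    for sample, reads in reads_by_sample.items():
        col: dict[str, int] = {}
        no_anchor = unmatched = 0
        for read in reads:
            seq = str(read.seq) if hasattr(read, "seq") else str(read)
            bc = extract_barcode(seq, barcode_length)
            if bc is None:
                no_anchor += 1
            elif bc in known:
                col[bc] = col.get(bc, 0) + 1
            else:
                unmatched += 1
        counts[sample] = col
        diag_rows.append({"sample": sample, "no_anchor": no_anchor, "unmatched_barcode": unmatched})
    matrix = pd.DataFrame(counts).fillna(0).astype(np.int64)
    matrix.index.name = "barcode"
    return matrix, pd.DataFrame(diag_rows)


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------


def _pre_columns(counts: pd.DataFrame) -> list[str]:
    cols = [c for c in counts.columns if str(c).startswith("pre")]
    if not cols:
        raise ValueError("count matrix has no pre-selection columns (named 'pre*')")
    return cols


def filter_barcodes(
    counts: pd.DataFrame,
    lookup: pd.DataFrame,
    design: StudyDesign | None = None,
    min_pre: int = 20,
    max_aa_changes: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the barcode-level QC filters; returns (filtered counts, filter log).

    Rules, in order: barcode must map to the lookup table; its embedded tag
    must match the mapped kinase's library tag (when a design is given); every
    pre-selection replicate must exceed ``min_pre`` reads (strict); the mapped
    variant must have at most ``max_aa_changes`` amino-acid changes.
    """
    lk = lookup.set_index("barcode")
    log = []
    idx = counts.index

    mapped = idx.isin(lk.index)
    log.append({"rule": "unmapped_barcode", "n_removed": int((~mapped).sum())})
    counts = counts.loc[mapped]

    if design is not None and len(counts):
        kin = lk.loc[counts.index, "kinase"]
        tags = kin.map(lambda k: design.tag_of(k) if k in design.kinases else None)
        ok = np.array([b[: len(t)] == t if t else False for b, t in zip(counts.index, tags)])
    else:
        ok = np.ones(len(counts), dtype=bool)
    log.append({"rule": "tag_mismatch", "n_removed": int((~ok).sum())})
    counts = counts.loc[ok]

    pre_cols = _pre_columns(counts)
    covered = (counts[pre_cols] > min_pre).all(axis=1)
    log.append({"rule": "low_pre_coverage", "n_removed": int((~covered).sum())})
    counts = counts.loc[covered]

    if len(counts):
        n_aa = lk.loc[counts.index, "n_aa_changes"]
        few = n_aa <= max_aa_changes
    else:
        few = pd.Series(dtype=bool)
    log.append({"rule": "too_many_aa_changes", "n_removed": int((~few).sum())})
    counts = counts.loc[few[few].index] if len(counts) else counts

    if counts.empty:
        raise EmptyFilterResult("no barcodes survive filtering")
    return counts, pd.DataFrame(log)


# --------------------------------------------------------------------------
# fold changes and outlier removal
# --------------------------------------------------------------------------


def compute_log2fc(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Depth-normalised per-barcode log2 fold change per replicate.

    log2fc_r = log2((post_r + pc) / D_post_r) - log2((pre_r + pc) / D_pre_r),
    with D the column depth (sum of counts). The pseudocount keeps zero
    post-selection counts finite.
    """
    pre_cols = sorted(_pre_columns(counts))
    post_cols = sorted(c for c in counts.columns if str(c).startswith("post"))
    if len(pre_cols) != len(post_cols):
        raise ValueError("pre/post replicate columns do not pair up")
    out = {}
    for pre, post in zip(pre_cols, post_cols):
        rep = str(post).split("_", 1)[-1]
        d_pre, d_post = counts[pre].sum(), counts[post].sum()
        out[f"lfc_{rep}"] = np.log2((counts[post] + pseudocount) / d_post) - np.log2(
            (counts[pre] + pseudocount) / d_pre
        )
    return pd.DataFrame(out, index=counts.index)


def remove_outlier_barcodes(
    fcs: pd.DataFrame, variants: pd.Series, z_max: float = 2.0
) -> tuple[pd.DataFrame, pd.Index]:
    """Drop barcodes whose log2FC is an outlier within its variant group.

    z-scores (population s.d.) are computed within each variant group per
    replicate; a barcode with |z| > ``z_max`` (strict) in any replicate is
    excluded. Groups of size <= 2 or with zero variance are exempt.
    """
    keys = variants.reindex(fcs.index)
    outlier = pd.Series(False, index=fcs.index)
    for col in fcs.columns:
        grouped = fcs[col].groupby(keys)
        mean = grouped.transform("mean")
        sd = grouped.transform(lambda v: v.std(ddof=0))
        size = grouped.transform("size")
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (fcs[col] - mean) / sd
        outlier |= (size > 2) & (sd > 0) & (z.abs() > z_max)
    removed = fcs.index[outlier]
    return fcs.loc[~outlier], removed


# --------------------------------------------------------------------------
# collapse to variants
# --------------------------------------------------------------------------

_AA_VARIANT_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


def variants_from_lookup(lookup: pd.DataFrame) -> pd.DataFrame:
    """Barcode-level variant annotations from a lookup table.

    Parses single amino-acid variant strings (``V195E``); barcodes with no
    amino-acid change are wild-type or synonymous. Returns a DataFrame indexed
    by barcode with kinase, position, wt_aa, mut_aa, variant_class.
    """
    rows = []
    for _, r in lookup.iterrows():
        aa = [v for v in str(r.get("aa_variants", "") or "").split(";") if v]
        nt = [v for v in str(r.get("nt_variants", "") or "").split(";") if v]
        changes = []
        syn = False
        for v in aa:
            m = _AA_VARIANT_RE.match(v)
            if not m:
                continue
            if m.group(1) == m.group(3):
                syn = True
            else:
                changes.append((m.group(1), int(m.group(2)), m.group(3)))
        if len(changes) == 1:
            wt, pos, mut = changes[0][0], changes[0][1], changes[0][2]
            vclass = "nonsense" if mut == "*" else "missense"
        elif changes:
            wt, pos, mut = "", 0, ""
            vclass = "multi"
        else:
            wt, pos, mut = "", 0, ""
            vclass = "synonymous" if (syn or nt) else "wildtype"
        rows.append(
            {
                "barcode": r["barcode"], "kinase": r["kinase"], "position": pos,
                "wt_aa": wt, "mut_aa": mut, "variant_class": vclass,
            }
        )
    return pd.DataFrame(rows).set_index("barcode")


def variant_key(meta: pd.DataFrame) -> pd.Series:
    """Grouping key: missense/nonsense by (kinase, position, mutation);
    wild-type and synonymous barcodes pool into per-kinase neutral classes."""
    def _key(r):
        if r.variant_class in ("wildtype", "synonymous"):
            return f"{r.kinase}|{r.variant_class}"
        return f"{r.kinase}|{r.wt_aa}{r.position}{r.mut_aa}"
    return meta.apply(_key, axis=1)


def collapse_to_variants(
    fcs: pd.DataFrame,
    meta: pd.DataFrame,
    assay: str = "phospho",
    substrate: str | None = None,
) -> pd.DataFrame:
    """Collapse cleaned per-barcode log2FCs to variant-level scores.

    Score = mean over barcodes and replicates; se = s.d./sqrt(n values).
    Missense and nonsense variants keep their (position, mutation) identity;
    wild-type and synonymous barcodes are pooled per kinase.
    """
    if fcs.empty:
        raise ValueError("no fold changes to collapse")
    meta = meta.reindex(fcs.index)
    rows = []
    for key, sub in fcs.groupby(variant_key(meta)):
        vals = sub.to_numpy().ravel()
        vals = vals[np.isfinite(vals)]
        first = meta.loc[sub.index[0]]
        rows.append(
            {
                "kinase": first.kinase,
                "substrate": substrate or "",
                "assay": assay,
                "position": int(first.position) if first.variant_class in ("missense", "nonsense") else 0,
                "wt_aa": first.wt_aa,
                "mut_aa": first.mut_aa,
                "variant_class": first.variant_class,
                "score": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                "n_barcodes": len(sub),
            }
        )
    return pd.DataFrame(rows)


def score_pipeline(
    counts: pd.DataFrame,
    lookup: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    design: StudyDesign | None = None,
    assay: str = "phospho",
    substrate: str | None = None,
    min_pre: int = 20,
    max_aa_changes: int = 2,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Filter -> log2FC -> outlier removal -> variant collapse, end to end."""
    if meta is None:
        meta = variants_from_lookup(lookup)
    filtered, _log = filter_barcodes(counts, lookup, design, min_pre, max_aa_changes)
    fcs = compute_log2fc(filtered, pseudocount)
    cleaned, _removed = remove_outlier_barcodes(fcs, variant_key(meta.reindex(fcs.index)))
    return collapse_to_variants(cleaned, meta, assay=assay, substrate=substrate)
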