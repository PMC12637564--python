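"""Barcode -> variant lookup construction from noisy long reads.

Reads are QC-filtered for the exact vector context, the constant cassette
anchor, and the 3' overhang; the barcode and kinase ORF are extracted by
anchor matching, reads are grouped by barcode, and a per-position Bayesian
consensus is called. With a uniform prior over {A, C, G, T} and a symmetric
substitution likelihood (0.9 for the read base matching the true base, 0.1/3
for each mismatch by default), the posterior at position i is

    P(b_i = b | D_i)  ∝  P(b_i = b) * prod_reads P(read base | b_i = b)

The consensus takes the argmax base per position (ties broken A < C < G < T);
the joint posterior of the whole consensus, assuming position-wise
independence, is the product of per-position maximum posteriors, and
barcode-variant pairs with joint posterior below 0.99 are filtered out.
All posterior arithmetic is done in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .design import (
    AA_BY_CODON_INDEX,
    BARCODE_ANCHOR,
    BASES,
    OVERHANG_3P,
    VECTOR_CONTEXT,
    StudyDesign,
    translate_orf,
)


@dataclass
class LikelihoodConfig:
    """Read-error likelihood, base prior, and lookup retention threshold."""

    p_match: float = 0.9
    p_mismatch: float = 0.1 / 3
    prior: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    joint_threshold: float = 0.99
    anchor_tolerance: int = 0  # Hamming tolerance for anchor matching

    def __post_init__(self) -> None:
        if abs(sum(self.prior) - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1")
        if not (0 < self.p_match <= 1 and 0 < self.p_mismatch < 1):
            raise ValueError("likelihood values must lie in (0, 1]")


@dataclass
class LongReadRecord:
    read_id: str
    sequence: str
    qc_flags: set[str] = field(default_factory=set)


@dataclass
class ReadGroup:
    barcode: str
    orf_observations: list[str]


@dataclass
class ConsensusCall:
    barcode: str
    kinase: str
    consensus_orf: str
    position_posteriors: np.ndarray  # (L, 4) over A, C, G, T
    joint_posterior: float
    n_reads: int
    nt_variants: list[str] = field(default_factory=list)
    aa_variants: list[str] = field(default_factory=list)
    n_aa_changes: int = 0


# --------------------------------------------------------------------------
# QC and extraction
# --------------------------------------------------------------------------


def _find_anchor(seq: str, anchor: str, tolerance: int, start: int = 0) -> int:
    """Index of the first occurrence of ``anchor`` (exact, or within a Hamming
    tolerance when configured); -1 if absent."""
    if tolerance <= 0:
        return seq.find(anchor, start)
    n, m = len(seq), len(anchor)
    for i in range(start, n - m + 1):
        mism = 0
        for a, b in zip(seq[i : i + m], anchor):
            if a != b:
                mism += 1
                if mism > tolerance:
                    break
        else:
            return i
    return -1


def qc_and_extract(
    read: LongReadRecord | str,
    design: StudyDesign,
    kinase: str | None = None,
    config: LikelihoodConfig | None = None,
) -> tuple[str, str] | LongReadRecord:
    """Extract (barcode, ORF) from a long read, or return the read with flags.

    QC rules: both the 5' vector context and the 3' overhang anchor must be
    present (``missing_anchor``), the constant cassette anchor must separate
    barcode from ORF (``missing_cassette``), the embedded two-base tag must
    match the library's kinase when one is given (``bad_tag``), and the ORF
    must have the design length (``bad_orf_length``).
    """
    config = config or LikelihoodConfig()
    if isinstance(read, str):
        read = LongReadRecord(read_id="", sequence=read)
    seq = read.sequence.upper()
    tol = config.anchor_tolerance
    i5 = _find_anchor(seq, VECTOR_CONTEXT, tol)
    i3 = _find_anchor(seq, OVERHANG_3P, tol)
    if i5 < 0 or i3 < 0:
        read.qc_flags.add("missing_anchor")
        return read
    ic = _find_anchor(seq, BARCODE_ANCHOR, tol, start=i5)
    if ic < 0 or ic >= i3:
        read.qc_flags.add("missing_cassette")
        return read
    barcode = seq[i5 + len(VECTOR_CONTEXT) : ic]
    orf = seq[ic + len(BARCODE_ANCHOR) : i3]
    if len(barcode) != design.barcode_length:
        read.qc_flags.add("missing_cassette")
        return read
    tag = barcode[:2]
    if kinase is not None:
        if tag != design.tag_of(kinase):
            read.qc_flags.add("bad_tag")
            return read
    elif design.kinase_for_tag(tag) is None:
        read.qc_flags.add("bad_tag")
        return read
    if len(orf) != design.orf_length:
        read.qc_flags.add("bad_orf_length")
        return read
    return barcode, orf


# --------------------------------------------------------------------------
# Bayesian consensus
# --------------------------------------------------------------------------


def pileup_log_posteriors(counts: np.ndarray, config: LikelihoodConfig) -> np.ndarray:
    """Log posteriors over {A,C,G,T} from base counts (..., 4).

    ``counts[..., b]`` is the number of reads observing base b; the posterior
    for hypothesis "true base is h" accumulates log p_match for agreeing reads
    and log p_mismatch otherwise, plus the log prior, normalised per position.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=-1, keepdims=True)
    loglik = counts * np.log(config.p_match) + (total - counts) * np.log(config.p_mismatch)
    logpost = loglik + np.log(np.asarray(config.prior))
    return logpost - logsumexp(logpost, axis=-1, keepdims=True)


def position_posterior(observed_bases: list[str], config: LikelihoodConfig | None = None) -> np.ndarray:
    """Posterior 4-vector over {A,C,G,T} at one position; empty input -> prior.

    ``N`` observations are skipped (they carry no likelihood).
    """
    config = config or LikelihoodConfig()
    counts = np.zeros(4)
    for b in observed_bases:
        b = b.upper()
        if b == "N":
            continue
        counts[BASES.index(b)] += 1
    return np.exp(pileup_log_posteriors(counts, config))


def consensus_from_counts(
    counts: np.ndarray, config: LikelihoodConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised consensus over pileup counts of shape (..., L, 4).

    Returns (consensus base indices, per-position max posterior, joint log
    posterior summed over L). Argmax ties break lexicographically A<C<G<T.
    """
    logpost = pileup_log_posteriors(counts, config)
    cons = np.argmax(logpost, axis=-1).astype(np.uint8)  # first max = lexicographic
    max_logpost = np.take_along_axis(logpost, cons[..., None].astype(np.intp), axis=-1)[..., 0]
    joint_log = max_logpost.sum(axis=-1)
    return cons, np.exp(max_logpost), joint_log


def consensus_for_group(
    group: ReadGroup,
    config: LikelihoodConfig | None = None,
    design: StudyDesign | None = None,
    kinase: str | None = None,
) -> ConsensusCall:
    """Call the per-position Bayesian consensus for one barcode's read group."""
    config = config or LikelihoodConfig()
    if not group.orf_observations:
        raise ValueError("read group has no observations")
    L = len(group.orf_observations[0])
    if any(len(o) != L for o in group.orf_observations):
        raise ValueError("all observations in a group must have equal length")
    counts = np.zeros((L, 4))
    for obs in group.orf_observations:
        for i, b in enumerate(obs.upper()):
            if b != "N":
                counts[i, BASES.index(b)] += 1
    cons_idx, max_post, joint_log = consensus_from_counts(counts, config)
    posteriors = np.exp(pileup_log_posteriors(counts, config))
    consensus = "".join(BASES[i] for i in cons_idx)
    call = ConsensusCall(
        barcode=group.barcode,
        kinase=kinase or "",
        consensus_orf=consensus,
        position_posteriors=posteriors,
        joint_posterior=float(np.exp(joint_log)),
        n_reads=len(group.orf_observations),
    )
    if design is not None and kinase is not None:
        wt = design.kinases[kinase].codon_seq
        if len(consensus) == len(wt):
            nt, aa, n_aa = call_codon_variants(consensus, wt)
            call.nt_variants, call.aa_variants, call.n_aa_changes = nt, aa, n_aa
    return call


def call_codon_variants(consensus_orf: str, wildtype_orf: str) -> tuple[list[str], list[str], int]:
    """Codon-wise nucleotide- and amino-acid-level variant calls vs wild type.

    Returns (nt variants like ``G584A``, aa variants like ``V195E`` with
    synonymous calls rendered as ``L23L``, number of aa changes).
    """
    if len(consensus_orf) != len(wildtype_orf):
        raise ValueError("bad_orf_length: consensus and wild type differ in length")
    if len(consensus_orf) % 3:
        raise ValueError("bad_orf_length: ORF length not divisible by 3")
    wt_aa = translate_orf(wildtype_orf)
    if "*" in wt_aa[:-1]:
        raise ValueError("wild-type ORF contains an internal stop")
    nt_variants = [
        f"{w}{i + 1}{c}" for i, (w, c) in enumerate(zip(wildtype_orf, consensus_orf)) if w != c
    ]
    aa_variants: list[str] = []
    n_aa = 0
    cons_aa = translate_orf(consensus_orf)
    for pos in range(len(wt_aa)):
        if consensus_orf[3 * pos : 3 * pos + 3] != wildtype_orf[3 * pos : 3 * pos + 3]:
            w, m = wt_aa[pos], cons_aa[pos]
            aa_variants.append(f"{w}{pos + 1}{m}")
            if w != m:
                n_aa += 1
    return nt_variants, aa_variants, n_aa


# --------------------------------------------------------------------------
# lookup table assembly
# --------------------------------------------------------------------------


def build_lookup_table(calls: list[ConsensusCall], config: LikelihoodConfig | None = None) -> pd.DataFrame:
    """Retain calls with joint posterior >= threshold; one row per barcode.

    Duplicate barcodes with conflicting consensus keep the higher-confidence
    call; conflicts are recorded in ``.attrs['conflicts']``.
    """
    config = config or LikelihoodConfig()
    best: dict[str, ConsensusCall] = {}
    conflicts: list[str] = []
    for call in calls:
        if call.joint_posterior < config.joint_threshold:
            continue
        prev = best.get(call.barcode)
        if prev is None:
            best[call.barcode] = call
        elif prev.consensus_orf != call.consensus_orf:
            conflicts.append(call.barcode)
            if call.joint_posterior > prev.joint_posterior:
                best[call.barcode] = call
        elif call.joint_posterior > prev.joint_posterior:
            best[call.barcode] = call
    rows = [
        {
            "barcode": c.barcode,
            "kinase": c.kinase,
            "nt_variants": ";".join(c.nt_variants),
            "aa_variants": ";".join(c.aa_variants),
            "n_reads": c.n_reads,
            "joint_posterior": c.joint_posterior,
            "n_aa_changes": c.n_aa_changes,
        }
        for c in best.values()
    ]
    out = pd.DataFrame(
        rows,
        columns=[
            "barcode", "kinase", "nt_variants", "aa_variants",
            "n_reads", "joint_posterior", "n_aa_changes",
        ],
    )
    out.attrs["conflicts"] = conflicts
    return out


def build_lookup_from_reads(
    reads, design: StudyDesign, config: LikelihoodConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: QC, group by barcode, consensus, variant calls, filter.

    ``reads`` is an iterable of Bio SeqRecords, (id, sequence) pairs, or plain
    strings. Returns (lookup table, QC summary with per-flag rejection counts).
    """
    config = config or LikelihoodConfig()
    groups: dict[str, list[str]] = {}
    flag_counts: dict[str, int] = {}
    n_pass = 0
    for rec in reads:
        if hasattr(rec, "seq"):
            rid, seq = rec.id, str(rec.seq)
        elif isinstance(rec, tuple):
            rid, seq = rec
        else:
            rid, seq = "", rec
        res = qc_and_extract(LongReadRecord(rid, seq), design, config=config)
        if isinstance(res, LongReadRecord):
            for f in res.qc_flags:
                flag_counts[f] = flag_counts.get(f, 0) + 1
            continue
        barcode, orf = res
        groups.setdefault(barcode, []).append(orf)
        n_pass += 1
    calls = []
    for barcode, orfs in groups.items():
        kinase = design.kinase_for_tag(barcode[:2])
        calls.append(
            consensus_for_group(ReadGroup(barcode, orfs), config, design=design, kinase=kinase)
        )
    qc = pd.DataFrame(
        [{"flag": k, "n_reads": v} for k, v in sorted(flag_counts.items())]
        + [{"flag": "pass", "n_reads": n_pass}]
    )
    return build_lookup_table(calls, config), qc


def build_lookup_from_pileup(
    library,
    reads_per_barcode: int = 10,
    read_error: float = 0.01,
    config: LikelihoodConfig | None = None,
    seed: int = 0,
    chunk_size: int = 16384,
) -> pd.DataFrame:
    """Scale path: consensus-call a whole synthetic library from read pileups.

    Per (barcode, position) the number of erroneous reads is Binomial(R,
    read_error), split multinomially over the three wrong bases -- the exact
    count distribution induced by i.i.d. per-read substitutions. Error-free
    positions all share one known pileup (R observations of the template
    base), so their posterior is computed once through the shared consensus
    math; only positions that drew errors get an individual 4-hypothesis
    evaluation. Reads are grouped by their true barcode (the post-QC pileup;
    the FASTQ path exercises anchor/tag QC). Adds a
    ``consensus_matches_truth`` column comparing the consensus to the true
    template nucleotide-exactly, and a ``retained`` column for the
    joint-posterior filter.
    """
    config = config or LikelihoodConfig()
    design = library.design
    rng = np.random.default_rng(seed)
    R = reads_per_barcode
    L = design.orf_length
    n = len(library)
    # posterior of an error-free position (base identity is symmetric)
    clean_counts = np.zeros(4)
    clean_counts[0] = R
    clean_max_logpost = float(pileup_log_posteriors(clean_counts, config)[0])
    weights3 = np.array([16, 4, 1])
    frames = []
    for start in range(0, n, chunk_size):
        rows = np.arange(start, min(start + chunk_size, n))
        B = len(rows)
        templates = library.template_indices(rows)
        if read_error > 0:
            n_err = rng.binomial(R, read_error, size=(B, L))
        else:
            n_err = np.zeros((B, L), dtype=np.int64)
        dirty = n_err > 0
        joint_log = (L - dirty.sum(axis=1)) * clean_max_logpost
        consensus = templates.copy()
        if dirty.any():
            b_idx, l_idx = np.nonzero(dirty)
            n_d = n_err[b_idx, l_idx]
            split = rng.multinomial(n_d, [1 / 3] * 3)
            t = templates[b_idx, l_idx].astype(np.intp)
            counts = np.zeros((len(b_idx), 4))
            ar = np.arange(len(b_idx))
            counts[ar, t] = R - n_d
            for j in range(3):
                counts[ar, (t + 1 + j) % 4] += split[:, j]
            logpost = pileup_log_posteriors(counts, config)
            cons_d = np.argmax(logpost, axis=1)
            max_lp = logpost[ar, cons_d]
            np.add.at(joint_log, b_idx, max_lp)
            consensus[b_idx, l_idx] = cons_d.astype(np.uint8)
        matches = (consensus == templates).all(axis=1)
        keep = joint_log >= np.log(config.joint_threshold)
        sub = library.table.iloc[rows]
        # positions overturned by errors are vanishingly rare; only those
        # barcodes need a fresh codon-level call, the rest inherit the
        # library's known change count
        n_aa_changes = sub["n_aa_changes"].to_numpy().copy()
        changed = np.flatnonzero(~matches)
        if len(changed):
            codon_idx = consensus[changed].reshape(len(changed), -1, 3).astype(np.intp) @ weights3
            aa = AA_BY_CODON_INDEX[codon_idx]
            kin_changed = sub["kinase"].to_numpy()[changed]
            for name, spec in design.kinases.items():
                sel = kin_changed == name
                if not sel.any():
                    continue
                wt_aa = np.array(list(translate_orf(spec.codon_seq)), dtype="U1")
                n_aa_changes[changed[sel]] = (aa[sel] != wt_aa[None, :]).sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "barcode": sub["barcode"].to_numpy(),
                    "kinase": sub["kinase"].to_numpy(),
                    "n_reads": R,
                    "joint_posterior": np.exp(joint_log),
                    "n_aa_changes": n_aa_changes,
                    "consensus_matches_truth": matches,
                    "retained": keep,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_lookup(lookup: pd.DataFrame, path: str) -> None:
    lookup.to_csv(path, sep="\t", index=False)


def read_lookup(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
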