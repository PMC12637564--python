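"""Synthetic phospho-PCA / abundance-PCA studies with known ground truth.

Every downstream stage of the pipeline (barcode-variant lookup, fitness
scoring, growth-rate extraction, Bayesian decomposition, enrichment, and
allosteric-graph analysis) can be exercised on data generated here, with the
latent truth retained for comparison.

The generative model for selection follows deterministic exponential
amplification over ``g`` generations: a barcode with latent score ``x`` changes
its expected frequency by ``2**(g*x)`` relative to neutral, after which counts
are drawn multinomially at the requested sequencing depth. Latent phospho
scores are the linear sum ``alpha + c + s`` of abundance, activity, and
substrate-specificity effects; abundance-PCA selections respond to ``alpha``
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .design import (
    AA_ALPHABET,
    AA_INDEX,
    BARCODE_ANCHOR,
    BASES,
    NNK_CODONS,
    OVERHANG_3P,
    VECTOR_CONTEXT,
    StudyDesign,
    decode_seq,
    encode_seq,
    translate_codon,
)


class BarcodeCollisionError(RuntimeError):
    """Raised when distinct barcodes cannot be drawn within the retry budget."""


# --------------------------------------------------------------------------
# truth parameters
# --------------------------------------------------------------------------


@dataclass
class TruthParameters:
    """Latent per-variant effects and nuisance parameters of a simulated study.

    ``alpha`` (abundance) and ``c`` (activity) are indexed per kinase as
    ``(position, mutation)`` arrays over the 21-letter amino-acid alphabet
    (20 residues + stop); ``s`` (specificity) additionally varies by substrate.
    Wild-type identity cells are pinned to zero so synonymous variants anchor
    neutrality; stop-gains carry a strong negative abundance shift so nonsense
    variants anchor the nonfunctional baseline.
    """

    alpha: dict[str, np.ndarray]
    c: dict[str, np.ndarray]
    s: dict[tuple[str, str], np.ndarray]
    sigma_p: float = 0.1
    sigma_a: float = 0.1
    sparsity_s: float = 0.05
    generations: float = 5.0
    read_error: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_p <= 0 or self.sigma_a <= 0:
            raise ValueError("observation noise s.d. must be positive")
        if not 0.0 <= self.sparsity_s <= 1.0:
            raise ValueError("sparsity_s must lie in [0, 1]")
        if not 0.0 <= self.read_error < 0.25:
            raise ValueError("read_error must lie in [0, 0.25)")

    @classmethod
    def generate(
        cls,
        design: StudyDesign,
        seed: int = 0,
        alpha_sd: float = 0.5,
        c_sd: float = 0.5,
        s_magnitude: float = 0.3,
        sparsity_s: float = 0.05,
        nonsense_shift: float = 1.5,
        sigma_p: float = 0.1,
        sigma_a: float = 0.1,
        generations: float = 5.0,
        read_error: float = 0.01,
    ) -> "TruthParameters":
        """Draw latent effects: alpha, c ~ N(0, sd^2); s sparse at +/-magnitude."""
        rng = np.random.default_rng(seed)
        P = design.n_positions
        L = len(AA_ALPHABET)
        stop = AA_INDEX["*"]
        alpha: dict[str, np.ndarray] = {}
        c: dict[str, np.ndarray] = {}
        s: dict[tuple[str, str], np.ndarray] = {}
        for name, spec in design.kinases.items():
            a_k = rng.normal(0.0, alpha_sd, size=(P, L))
            c_k = rng.normal(0.0, c_sd, size=(P, L))
            # stop-gains: strongly destabilised, no residual catalytic effect
            a_k[:, stop] -= nonsense_shift
            c_k[:, stop] = 0.0
            wt_idx = np.array([AA_INDEX[a] for a in spec.aa_seq])
            a_k[np.arange(P), wt_idx] = 0.0
            c_k[np.arange(P), wt_idx] = 0.0
            alpha[name] = a_k
            c[name] = c_k
            for sub in design.substrates:
                nonzero = rng.random(size=(P, L)) < sparsity_s
                signs = rng.choice([-1.0, 1.0], size=(P, L))
                s_k = np.where(nonzero, signs * s_magnitude, 0.0)
                s_k[:, stop] = 0.0
                s_k[np.arange(P), wt_idx] = 0.0
                s[(name, sub)] = s_k
        return cls(
            alpha=alpha,
            c=c,
            s=s,
            sigma_p=sigma_p,
            sigma_a=sigma_a,
            sparsity_s=sparsity_s,
            generations=generations,
            read_error=read_error,
            seed=seed,
        )

    def score(
        self, kinase: str, position: int, mut_aa: str, assay: str, substrate: str | None
    ) -> float:
        """Latent selection score of one variant (0 for wild type, position 0)."""
        if position == 0:
            return 0.0
        k, l = position - 1, AA_INDEX[mut_aa]
        a = self.alpha[kinase][k, l]
        if assay == "abundance":
            return float(a)
        return float(a + self.c[kinase][k, l] + self.s[(kinase, substrate)][k, l])


# --------------------------------------------------------------------------
# barcoded library
# --------------------------------------------------------------------------


@dataclass
class Library:
    """A barcoded NNK saturation library over one or more kinase domains.

    ``table`` has one row per barcode: barcode, kinase, position (0 for the
    wild-type entry), mut_codon ('' for wild type), wt_aa, mut_aa,
    variant_class, n_aa_changes.
    """

    design: StudyDesign
    table: pd.DataFrame
    _templates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, spec in self.design.kinases.items():
            self._templates[name] = encode_seq(spec.codon_seq)
        # vectorised per-row mutation data for fast template construction
        n = len(self.table)
        pos = self.table["position"].to_numpy()
        self._positions = pos.astype(np.int64)
        self._mut_codon_idx = np.zeros((n, 3), dtype=np.uint8)
        mutated = pos > 0
        if mutated.any():
            joined = "".join(self.table["mut_codon"].to_numpy()[mutated])
            self._mut_codon_idx[mutated] = encode_seq(joined).reshape(-1, 3)
        self._kinase_codes = self.table["kinase"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def orf_of(self, row: int | pd.Series) -> str:
        """Reconstruct the full ORF (765 nt by default) for one barcode row."""
        if isinstance(row, (int, np.integer)):
            row = self.table.iloc[int(row)]
        seq = self.design.kinases[row.kinase].codon_seq
        pos = int(row.position)
        if pos == 0:
            return seq
        i = 3 * (pos - 1)
        return seq[:i] + row.mut_codon + seq[i + 3 :]

    def template_indices(self, rows: np.ndarray) -> np.ndarray:
        """Encoded (B, L) template ORFs for the given integer row positions."""
        rows = np.asarray(rows)
        kin = self._kinase_codes[rows]
        pos = self._positions[rows]
        L = self.design.orf_length
        out = np.empty((len(rows), L), dtype=np.uint8)
        for name in self.design.kinases:
            sel = kin == name
            out[sel] = self._templates[name]
        mutated = np.flatnonzero(pos > 0)
        if len(mutated):
            starts = 3 * (pos[mutated] - 1)
            codon_idx = self._mut_codon_idx[rows[mutated]]
            for j in range(3):
                out[mutated, starts + j] = codon_idx[:, j]
        return out

    def truth_lookup(self) -> pd.DataFrame:
        """The true barcode -> variant map (ground truth for lookup recovery)."""
        cols = ["barcode", "kinase", "position", "wt_aa", "mut_aa", "variant_class", "n_aa_changes"]
        return self.table[cols].copy()


def _draw_barcodes(
    rng: np.random.Generator, n: int, tag: str, length: int, taken: set[str], max_retries: int = 100
) -> list[str]:
    suffix_len = length - len(tag)
    out: list[str] = []
    need = n
    for _ in range(max_retries):
        draws = rng.integers(0, 4, size=(need, suffix_len))
        base_arr = np.array(list(BASES))
        cands = ["".join(row) for row in base_arr[draws]]
        for c in cands:
            bc = tag + c
            if bc not in taken:
                taken.add(bc)
                out.append(bc)
        need = n - len(out)
        if need == 0:
            return out
    raise BarcodeCollisionError(
        f"could not draw {n} distinct barcodes with tag {tag!r} after 100 retries "
        f"({len(out)} drawn); increase barcode length or reduce library size"
    )


def generate_library(
    design: StudyDesign, n_barcodes_per_variant: int = 15, seed: int = 0
) -> Library:
    """Enumerate the NNK-reachable single-codon variant universe and barcode it.

    Each kinase gets one entry per NNK codon differing from the wild-type codon
    at each position, plus a wild-type entry; every variant receives
    ``n_barcodes_per_variant`` distinct random barcodes whose first bases equal
    the kinase tag.
    """
    if n_barcodes_per_variant < 1:
        raise ValueError("n_barcodes_per_variant must be >= 1")
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    records: dict[str, list] = {
        "barcode": [], "kinase": [], "position": [], "mut_codon": [],
        "wt_aa": [], "mut_aa": [], "variant_class": [], "n_aa_changes": [],
    }
    for name, spec in design.kinases.items():
        variants: list[tuple[int, str]] = [(0, "")]
        for pos in range(1, spec.n_positions + 1):
            wt_codon = spec.wt_codon(pos)
            variants.extend((pos, cd) for cd in NNK_CODONS if cd != wt_codon)
        barcodes = _draw_barcodes(
            rng, len(variants) * n_barcodes_per_variant, spec.tag, design.barcode_length, taken
        )
        aa_seq = spec.aa_seq
        for vi, (pos, codon) in enumerate(variants):
            if pos == 0:
                wt_aa = mut_aa = ""
                vclass, n_aa = "wildtype", 0
            else:
                wt_aa = aa_seq[pos - 1]
                mut_aa = translate_codon(codon)
                if mut_aa == wt_aa:
                    vclass, n_aa = "synonymous", 0
                elif mut_aa == "*":
                    vclass, n_aa = "nonsense", 1
                else:
                    vclass, n_aa = "missense", 1
            for b in range(n_barcodes_per_variant):
                records["barcode"].append(barcodes[vi * n_barcodes_per_variant + b])
                records["kinase"].append(name)
                records["position"].append(pos)
                records["mut_codon"].append(codon)
                records["wt_aa"].append(wt_aa)
                records["mut_aa"].append(mut_aa)
                records["variant_class"].append(vclass)
                records["n_aa_changes"].append(n_aa)
    table = pd.DataFrame(records)
    return Library(design=design, table=table)


# --------------------------------------------------------------------------
# long reads
# --------------------------------------------------------------------------


def _mutate_string(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    idx = encode_seq(seq).copy()
    mask = rng.random(len(idx)) < rate
    n = int(mask.sum())
    if n:
        idx[mask] = (idx[mask] + rng.integers(1, 4, size=n)) % 4
    return decode_seq(idx)


def generate_long_reads(
    library: Library,
    reads_per_barcode: int = 10,
    read_error: float = 0.0,
    seed: int = 0,
    anchor_dropout: float = 0.0,
) -> list[SeqRecord]:
    """Simulate long reads over the full cassette.

    Each read is vector context + barcode + constant anchor + ORF + 3'
    overhang, with i.i.d. per-base substitutions at ``read_error`` applied to
    the whole read. A fraction ``anchor_dropout`` of reads lose one anchor
    (alternating 5'/3') so downstream QC has something to reject.
    """
    if reads_per_barcode < 1:
        raise ValueError("reads_per_barcode must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[SeqRecord] = []
    for i, row in library.table.iterrows():
        orf = library.orf_of(row)
        template = VECTOR_CONTEXT + row.barcode + BARCODE_ANCHOR + orf + OVERHANG_3P
        for r in range(reads_per_barcode):
            seq = _mutate_string(rng, template, read_error)
            if anchor_dropout > 0 and rng.random() < anchor_dropout:
                if rng.random() < 0.5:
                    seq = seq[len(VECTOR_CONTEXT):]
                else:
                    seq = seq[: -len(OVERHANG_3P)]
            rec = SeqRecord(Seq(seq), id=f"{row.barcode}/{r}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
    return records


def write_fastq(records: list[SeqRecord], path: str) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def generate_read_pileup(
    library: Library,
    reads_per_barcode: int = 10,
    read_error: float = 0.01,
    seed: int = 0,
    chunk_size: int = 4096,
):
    """Yield per-barcode ORF base-count pileups in chunks.

    For each (barcode, position) the number of erroneous reads is
    Binomial(reads, read_error) split multinomially over the three wrong bases
    -- exactly the count distribution induced by i.i.d. per-base substitutions,
    computed without materialising individual reads. Reads are grouped by their
    true barcode (the post-QC pileup); the FASTQ path exercises anchor/tag QC.

    Yields ``(row_indices, counts)`` with counts of shape (chunk, L, 4).
    """
    rng = np.random.default_rng(seed)
    n = len(library)
    L = library.design.orf_length
    R = reads_per_barcode
    for start in range(0, n, chunk_size):
        rows = np.arange(start, min(start + chunk_size, n))
        templates = library.template_indices(rows)  # (B, L) uint8
        B = len(rows)
        counts = np.zeros((B, L, 4), dtype=np.uint16)
        if read_error > 0:
            n_err = rng.binomial(R, read_error, size=(B, L))
        else:
            n_err = np.zeros((B, L), dtype=np.int64)
        np.put_along_axis(
            counts, templates[:, :, None].astype(np.intp), (R - n_err)[:, :, None].astype(np.uint16), axis=2
        )
        if read_error > 0 and n_err.any():
            split = rng.multinomial(n_err.ravel(), [1 / 3] * 3).reshape(B, L, 3)
            for j in range(3):
                wrong = ((templates.astype(np.intp) + 1 + j) % 4)
                cur = np.take_along_axis(counts, wrong[:, :, None], axis=2)
                np.put_along_axis(
                    counts, wrong[:, :, None], cur + split[:, :, j : j + 1].astype(np.uint16), axis=2
                )
        yield rows, counts


# --------------------------------------------------------------------------
# selection counts
# --------------------------------------------------------------------------


def generate_selection_counts(
    library: Library,
    truth: TruthParameters,
    depth: int = 10**6,
    replicates: int = 2,
    assay: str = "phospho",
    substrate: str | None = None,
    sample: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate pre/post-selection barcode count tables.

    Pre-selection counts are multinomial at equal expected abundance; the
    post-selection expected frequency of a barcode is proportional to its
    realised pre-selection frequency times ``2**(g * (score + eps))`` with
    eps ~ N(0, sigma) per barcode and replicate. With ``sample=False`` the
    expected (real-valued) counts are returned and eps is zero -- the
    infinite-depth, noise-free limit.

    Returns a wide DataFrame indexed by barcode with columns ``pre_r`` /
    ``post_r`` and metadata in ``.attrs``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if assay not in ("phospho", "abundance"):
        raise ValueError("assay must be 'phospho' or 'abundance'")
    if assay == "phospho" and substrate is None:
        raise ValueError("phospho assay requires a substrate")
    rng = np.random.default_rng(seed)
    tab = library.table
    n = len(tab)
    g = truth.generations
    sigma = truth.sigma_p if assay == "phospho" else truth.sigma_a
    scores = np.array(
        [
            truth.score(k, p, m if p else "A", assay, substrate) if p else 0.0
            for k, p, m in zip(tab["kinase"], tab["position"], tab["mut_aa"])
        ]
    )
    data: dict[str, np.ndarray] = {}
    for r in range(1, replicates + 1):
        if sample:
            pre = rng.multinomial(depth, np.full(n, 1.0 / n)).astype(float)
        else:
            pre = np.full(n, depth / n)
        eps = rng.normal(0.0, sigma, size=n) if sample else np.zeros(n)
        w = (pre / pre.sum()) * np.exp2(g * (scores + eps))
        freq = w / w.sum()
        post = rng.multinomial(depth, freq).astype(float) if sample else depth * freq
        data[f"pre_{r}"] = pre
        data[f"post_{r}"] = post
    out = pd.DataFrame(data, index=pd.Index(tab["barcode"], name="barcode"))
    if sample:
        out = out.astype(np.int64)
    out.attrs.update(
        {"assay": assay, "substrate": substrate, "generations": g, "depth": depth, "seed": seed}
    )
    return out


# --------------------------------------------------------------------------
# growth curves
# --------------------------------------------------------------------------


@dataclass
class GrowthCurve:
    """One plate-reader OD600 trajectory (15-min sampling over 60 h default)."""

    time_min: np.ndarray
    od: np.ndarray
    kinase: str | None = None
    substrate: str | None = None
    replicate: int | None = None

    def __len__(self) -> int:
        return len(self.time_min)


def logistic_od(t_hours: np.ndarray, rate: float, od0: float, capacity: float) -> np.ndarray:
    """Closed-form logistic OD trajectory with growth rate ``rate`` per hour."""
    if rate == 0:
        return np.full_like(np.asarray(t_hours, dtype=float), od0)
    e = np.exp(rate * np.asarray(t_hours, dtype=float))
    return capacity * od0 * e / (capacity + od0 * (e - 1.0))


def generate_growth_curves(
    rate: float,
    noise_sd: float = 0.0,
    duration_h: float = 60.0,
    dt_min: float = 15.0,
    od0: float = 0.005,
    carrying_capacity: float = 1.5,
    seed: int = 0,
    **labels,
) -> GrowthCurve:
    """Logistic growth trajectory with additive Gaussian noise (241 points default)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    time_min = np.arange(0.0, duration_h * 60.0 + dt_min / 2, dt_min)
    od = logistic_od(time_min / 60.0, rate, od0, carrying_capacity)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return GrowthCurve(time_min=time_min, od=od, **labels)


# --------------------------------------------------------------------------
# contact tables
# --------------------------------------------------------------------------


def generate_contact_tables(
    n_residues: int,
    planted_pathway: list[int],
    effect: float,
    replicates: int = 2,
    seed: int = 0,
    background_density: float = 0.05,
    jitter_sd: float = 0.01,
    conserved_edges: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Contact-frequency tables for wt and mutant with a planted differential path.

    Consecutive pairs of ``planted_pathway`` are shifted by ``+effect`` /
    ``-effect`` (alternating) in the mutant relative to a shared wt baseline of
    0.45; background contacts are drawn at ``background_density`` with matched
    means in both conditions, and replicate-level Gaussian jitter is added.
    """
    if len(planted_pathway) < 2:
        raise ValueError("planted pathway must contain at least 2 nodes")
    if any(not (1 <= r <= n_residues) for r in planted_pathway):
        raise ValueError("planted nodes must lie within 1..n_residues")
    rng = np.random.default_rng(seed)
    path_edges = [tuple(sorted(p)) for p in zip(planted_pathway[:-1], planted_pathway[1:])]
    special = set(path_edges) | {tuple(sorted(e)) for e in (conserved_edges or [])}
    base: dict[tuple[int, int], tuple[float, float]] = {}  # edge -> (wt, mut) means
    for k, e in enumerate(path_edges):
        sign = 1.0 if k % 2 == 0 else -1.0
        wt = 0.45
        base[e] = (wt, float(np.clip(wt + sign * effect, 0.0, 1.0)))
    for e in conserved_edges or []:
        base[tuple(sorted(e))] = (0.9, 0.9)
    for i in range(1, n_residues + 1):
        for j in range(i + 1, n_residues + 1):
            if (i, j) in special:
                continue
            if rng.random() < background_density:
                f = rng.uniform(0.02, 0.6)
                base[(i, j)] = (f, f)
    rows = []
    for (i, j), (wt, mut) in sorted(base.items()):
        for cond, mean in (("wt", wt), ("mutant", mut)):
            for rep in range(1, replicates + 1):
                f = float(np.clip(mean + rng.normal(0.0, jitter_sd), 0.0, 1.0))
                rows.append((i, j, cond, rep, f))
    return pd.DataFrame(rows, columns=["res_i", "res_j", "condition", "replicate", "frequency"])


# --------------------------------------------------------------------------
# score tensors (direct input to the decomposition model)
# --------------------------------------------------------------------------


def generate_score_tensor(design: StudyDesign, truth: TruthParameters, seed: int = 0):
    """Noisy phospho/abundance score tensors drawn around the latent truth.

    Observations: abundance[i,j,k,l] ~ N(alpha, sigma_a^2) per substrate
    background, phospho[i,j,k,l] ~ N(alpha + c + s, sigma_p^2). Wild-type
    identity and stop cells are masked (missense mutations only).
    """
    from .decomposition import ScoreTensor

    rng = np.random.default_rng(seed)
    kinases = list(design.kinases)
    substrates = list(design.substrates)
    P, L = design.n_positions, len(AA_ALPHABET)
    I, J = len(kinases), len(substrates)
    phospho = np.zeros((I, J, P, L))
    abundance = np.zeros((I, J, P, L))
    mask = np.zeros((I, J, P, L), dtype=bool)
    stop = AA_INDEX["*"]
    for i, kin in enumerate(kinases):
        wt_idx = np.array([AA_INDEX[a] for a in design.kinases[kin].aa_seq])
        valid = np.ones((P, L), dtype=bool)
        valid[:, stop] = False
        valid[np.arange(P), wt_idx] = False
        for j, sub in enumerate(substrates):
            mu_p = truth.alpha[kin] + truth.c[kin] + truth.s[(kin, sub)]
            phospho[i, j] = mu_p + rng.normal(0.0, truth.sigma_p, size=(P, L))
            abundance[i, j] = truth.alpha[kin] + rng.normal(0.0, truth.sigma_a, size=(P, L))
            mask[i, j] = valid
    return ScoreTensor(
        phospho=phospho,
        abundance=abundance,
        mask_phospho=mask,
        mask_abundance=mask.copy(),
        kinases=kinases,
        substrates=substrates,
        positions=list(range(1, P + 1)),
        mutations=list(AA_ALPHABET),
        se_phospho=np.full((I, J, P, L), truth.sigma_p),
        se_abundance=np.full((I, J, P, L), truth.sigma_a),
    )
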