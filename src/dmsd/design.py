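"""Study designs and variant identifiers for kinase-domain deep mutational scans.

A study couples a set of Src-family kinase domains (254 residues by default,
encoded by a 765-nt ORF including the stop codon) to a set of tethered peptide
substrates. Each kinase library carries a distinct two-base tag embedded at the
start of its 16-bp barcodes, and domain positions map to full-length protein
numbering through a per-kinase offset (Fyn +269, Lck +260, c-Src +244).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: the 32 NNK codons (N = any base, K = G/T) used for saturation mutagenesis
NNK_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in "GT")

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino-acid alphabet used for mutation indexing (20 residues + stop)
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY*"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: amino acids reachable by NNK codons (all 20 plus the TAG stop)
NNK_AMINO_ACIDS = frozenset(CODON_TO_AA[c] for c in NNK_CODONS)

# codon index (4*4*4 base-4 encoding) -> amino-acid letter, for vectorised calls
AA_BY_CODON_INDEX = np.array(
    [CODON_TO_AA[a + b + c] for a in BASES for b in BASES for c in BASES],
    dtype="U1",
)


def translate_codon(codon: str) -> str:
    """Translate a single DNA codon; stops become ``*``."""
    return CODON_TO_AA[codon.upper()]


def translate_orf(orf: str) -> str:
    """Codon-wise translation of an ORF (length divisible by 3)."""
    if len(orf) % 3:
        raise ValueError(f"ORF length {len(orf)} not divisible by 3")
    return "".join(CODON_TO_AA[orf[i : i + 3]] for i in range(0, len(orf), 3))


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 indices (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    out = lut[arr]
    if (out == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return out


def decode_seq(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


@dataclass(frozen=True)
class VariantID:
    """Single amino-acid (or codon-level) variant of one kinase domain.

    ``position`` is the 1-based domain position; synonymous variants have
    ``mut_aa == wt_aa`` and stop-gains have ``mut_aa == '*'``.
    """

    kinase: str
    position: int
    wt_aa: str
    mut_aa: str

    @property
    def is_nonsense(self) -> bool:
        return self.mut_aa == "*"

    @property
    def is_synonymous(self) -> bool:
        return self.mut_aa == self.wt_aa

    @property
    def variant_class(self) -> str:
        if self.is_synonymous:
            return "synonymous"
        if self.is_nonsense:
            return "nonsense"
        return "missense"

    def full_position(self, offset: int) -> int:
        """Map the domain position to full-length protein numbering."""
        return self.position + offset

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass
class KinaseSpec:
    """One kinase library: wild-type coding sequence, barcode tag, offset."""

    name: str
    codon_seq: str  # full ORF including the stop codon
    tag: str
    offset: int

    def __post_init__(self) -> None:
        self.codon_seq = self.codon_seq.upper()
        if len(self.codon_seq) % 3:
            raise ValueError(f"{self.name}: ORF length not divisible by 3")
        aa = translate_orf(self.codon_seq)
        if aa[-1] != "*":
            raise ValueError(f"{self.name}: ORF must end in a stop codon")
        if "*" in aa[:-1]:
            raise ValueError(f"{self.name}: internal stop codon in wild type")

    @property
    def n_positions(self) -> int:
        return len(self.codon_seq) // 3 - 1

    @property
    def aa_seq(self) -> str:
        return translate_orf(self.codon_seq)[:-1]

    def wt_codon(self, position: int) -> str:
        """Wild-type codon at a 1-based domain position."""
        return self.codon_seq[3 * (position - 1) : 3 * position]


@dataclass
class StudyDesign:
    """The kinase x substrate panel of one phospho-PCA / abundance-PCA study."""

    kinases: dict[str, KinaseSpec]
    substrates: list[str] = field(default_factory=list)
    barcode_length: int = 16

    def __post_init__(self) -> None:
        lengths = {k.n_positions for k in self.kinases.values()}
        if len(lengths) > 1:
            raise ValueError("kinase domains must share a common length")
        tags = [k.tag for k in self.kinases.values()]
        if len(set(tags)) != len(tags):
            raise ValueError("kinase tags must be pairwise distinct")
        tag_len = max((len(t) for t in tags), default=0)
        if self.barcode_length < tag_len + 4:
            raise ValueError("barcode_length must be at least tag length + 4")

    @property
    def n_positions(self) -> int:
        return next(iter(self.kinases.values())).n_positions

    @property
    def orf_length(self) -> int:
        return 3 * self.n_positions + 3

    def tag_of(self, kinase: str) -> str:
        return self.kinases[kinase].tag

    def kinase_for_tag(self, tag: str) -> str | None:
        for name, spec in self.kinases.items():
            if spec.tag == tag:
                return name
        return None


# Cassette landmarks shared by read simulation and read parsing. The barcode
# sits immediately 5' of the constant anchor separating it from the kinase ORF;
# the vector context precedes the barcode and a 3' overhang motif closes the
# cassette. Short-read barcode extraction takes the 16 nt 5' of BARCODE_ANCHOR.
VECTOR_CONTEXT = "TCGACGGATCCA"
BARCODE_ANCHOR = "GCCTAGGCAGCTATGACCATGATTACGCCAAGCG"
OVERHANG_3P = "AAGCTTGGCACT"

DEFAULT_KINASES = ("Fyn", "Lck", "Src")
DEFAULT_TAGS = ("AG", "CT", "TA")
DEFAULT_OFFSETS = (269, 260, 244)
DEFAULT_SUBSTRATES = ("Fyn-sub", "Lck-sub", "Src-sub")

_SENSE_CODONS = tuple(c for c, a in CODON_TO_AA.items() if a != "*")


def random_design(
    n_kinases: int = 3,
    n_positions: int = 254,
    seed: int = 0,
    names: tuple[str, ...] = DEFAULT_KINASES,
    tags: tuple[str, ...] = DEFAULT_TAGS,
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
    substrates: tuple[str, ...] = DEFAULT_SUBSTRATES,
    barcode_length: int = 16,
) -> StudyDesign:
    """Build a reproducible synthetic study design.

    Wild-type coding sequences are drawn uniformly over sense codons (so the
    wild type never contains an internal stop) and terminated with TAA. The
    default panel mirrors the three-kinase, three-substrate layout with tags
    AG/CT/TA and offsets 269/260/244.
    """
    rng = np.random.default_rng(seed)
    kinases: dict[str, KinaseSpec] = {}
    for idx in range(n_kinases):
        codons = rng.choice(len(_SENSE_CODONS), size=n_positions)
        seq = "".join(_SENSE_CODONS[i] for i in codons) + "TAA"
        kinases[names[idx]] = KinaseSpec(
            name=names[idx], codon_seq=seq, tag=tags[idx], offset=offsets[idx]
        )
    return StudyDesign(
        kinases=kinases,
        substrates=list(substrates[: max(n_kinases, 1)]),
        barcode_length=barcode_length,
    )
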