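"""Fusion proteins, predicted mRNAs in a vector context, Kozak classification.

The screen evaluates each candidate SP in the fixed context of an expression
vector: the transcript is 5'UTR + SP CDS + propeptide CDS + 3'UTR + poly-A
signal region + poly-A tail, transcribed to RNA.  The 5'UTR is the
transcript-level UTR (the bases immediately upstream of AUG), so the start
codon position is always ``len(utr5)`` and Kozak context is fully determined
by the UTR tail plus the SP's first two codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

# CMV promoter + 5'UTR region of the pVax_BMP2 expression vector (5'->3').
# Only the transcript-level tail of this region appears in the mRNA; the
# default 5'UTR below is its final 150 nt, placing the start codon at
# transcript positions 151-153 (1-based).
PVAX_PROMOTER_UTR5 = (
    "GTGATGCGGTTTTGGCAGTACATCAATGGGCGTGGATAGCGGTTTGACTCACGGGGATTTCCAAGTCTCC"
    "ACCCCATTGACGTCAATGGGAGTTTGTTTTGGCACCAAAATCAACGGGACTTTCCAAAATGTCGTAACAA"
    "CTCCGCCCCATTGACGCAAATGGGCGGTAGGCGTGTACGGTGGGAGGTCTATATAAGCAGAGCTCTCTGG"
    "CTAACTAGAGAACCCACTGCTTACTGGCTTATCGAAATTAATACGACTCACTATAGGGAGACCCAAGCTG"
    "GCTAGCGTTTAAACTTAAGCTTGGTACCGAGCTCGGATCCACTAGTCCAGTGTGGTGGAATTCGGCTTGC"
    "CACC"
)

DEFAULT_UTR5_LENGTH = 150
DEFAULT_UTR5 = PVAX_PROMOTER_UTR5[-DEFAULT_UTR5_LENGTH:]

PURINES = {"A", "G"}

_SEGMENT_ORDER = ("utr5", "sp_cds", "propeptide_cds", "utr3", "polya_region", "polya_tail")


class ConstructError(ValueError):
    pass


@dataclass
class VectorContext:
    """Vector-side pieces of the predicted transcript (DNA alphabet).

    ``utr5`` ends at the base immediately before the start codon;
    ``polya_region`` is the poly-A signal region (e.g. BGH, truncated ~20 nt
    downstream of the AATAAA site); ``polya_tail_length`` A residues are
    appended literally so the tail is folded with the rest of the molecule.
    """

    utr5: str
    propeptide_cds: str
    utr3: str = ""
    polya_region: str = ""
    polya_tail_length: int = 150

    def __post_init__(self) -> None:
        self.utr5 = self.utr5.strip().upper()
        self.propeptide_cds = self.propeptide_cds.strip().upper()
        self.utr3 = self.utr3.strip().upper()
        self.polya_region = self.polya_region.strip().upper()
        if not self.utr5:
            raise ConstructError("utr5 must be non-empty")
        if len(self.propeptide_cds) % 3:
            raise ConstructError(
                f"propeptide_cds length {len(self.propeptide_cds)} not divisible by 3"
            )
        if self.polya_tail_length < 0:
            raise ConstructError("polya_tail_length must be >= 0")

    @classmethod
    def from_config(cls, path: str | Path) -> "VectorContext":
        """Load from a YAML/JSON mapping with fields named as above."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConstructError(f"{path}: vector config must be a mapping")
        unknown = set(data) - {
            "utr5", "propeptide_cds", "utr3", "polya_region", "polya_tail_length",
        }
        if unknown:
            raise ConstructError(f"{path}: unknown vector fields {sorted(unknown)}")
        return cls(**data)

    def to_config(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "utr5": self.utr5,
                    "propeptide_cds": self.propeptide_cds,
                    "utr3": self.utr3,
                    "polya_region": self.polya_region,
                    "polya_tail_length": self.polya_tail_length,
                },
                fh,
                sort_keys=False,
            )


@dataclass
class PredictedMRNA:
    """Assembled transcript (RNA alphabet) with annotated segment intervals.

    ``segments`` maps segment name to a 0-based half-open interval; the
    intervals tile the sequence in order without gaps.  ``start_index`` is
    the position of the A of AUG and always equals ``len(utr5)``.
    """

    name: str
    sequence: str
    start_index: int
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def start_codon_1based(self) -> tuple[int, int]:
        """1-based inclusive start-codon span, e.g. (151, 153)."""
        return (self.start_index + 1, self.start_index + 3)


def transcribe(dna: str) -> str:
    """DNA -> RNA (T to U); accepts sequences already in RNA alphabet."""
    return dna.upper().replace("T", "U")


def build_fusion_protein(sp_aa: str, propeptide_aa: str) -> str:
    """Concatenate an SP onto the propeptide, forming the fusion preprotein."""
    if not sp_aa or not propeptide_aa:
        raise ConstructError("sp_aa and propeptide_aa must be non-empty")
    if not sp_aa.startswith("M"):
        raise ConstructError(f"signal peptide must start with M, got {sp_aa[:5]!r}...")
    return sp_aa + propeptide_aa


def assemble_mrna(
    vector: VectorContext, sp_nt: str, name: str = "candidate"
) -> PredictedMRNA:
    """Assemble the predicted transcript for one SP CDS.

    Segment order is 5'UTR, SP CDS, propeptide CDS, 3'UTR, poly-A region,
    poly-A tail; everything is transcribed T->U.
    """
    sp_nt = sp_nt.strip().upper()
    if not sp_nt:
        raise ConstructError("sp_nt must be non-empty")
    parts = {
        "utr5": transcribe(vector.utr5),
        "sp_cds": transcribe(sp_nt),
        "propeptide_cds": transcribe(vector.propeptide_cds),
        "utr3": transcribe(vector.utr3),
        "polya_region": transcribe(vector.polya_region),
        "polya_tail": "A" * vector.polya_tail_length,
    }
    segments: dict[str, tuple[int, int]] = {}
    pos = 0
    chunks = []
    for seg in _SEGMENT_ORDER:
        chunk = parts[seg]
        segments[seg] = (pos, pos + len(chunk))
        pos += len(chunk)
        chunks.append(chunk)
    return PredictedMRNA(
        name=name,
        sequence="".join(chunks),
        start_index=len(vector.utr5),
        segments=segments,
    )


def classify_kozak(
    vector: VectorContext,
    sp_nt: str,
    require_minus3_purine: bool = True,
    require_plus4_g: bool = True,
) -> str:
    """Classify start-codon context as ``"strong"`` or ``"weak"``.

    Strong context requires a purine at position -3 (third-from-last base of
    the 5'UTR) and G at +4 (first base of the SP's second codon); either
    sub-condition can be switched off.
    """
    sp_nt = sp_nt.strip().upper()
    if not sp_nt.startswith("ATG") or len(sp_nt) < 6:
        raise ConstructError("sp_nt must start with ATG and be at least 6 nt")
    if len(vector.utr5) < 3:
        raise ConstructError("utr5 shorter than 3 nt: -3 position undefined")
    minus3 = vector.utr5[-3]
    plus4 = sp_nt[3]
    strong = True
    if require_minus3_purine and minus3 not in PURINES:
        strong = False
    if require_plus4_g and plus4 != "G":
        strong = False
    return "strong" if strong else "weak"


def write_mrna_fasta(mrnas: list[PredictedMRNA], path: str | Path) -> None:
    """Write assembled transcripts as FASTA; segment spans (1-based inclusive)
    go in the description line."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in mrnas:
            segs = " ".join(
                f"{name}={a + 1}-{b}" for name, (a, b) in m.segments.items() if b > a
            )
            fh.write(f">{m.name} start_codon={m.start_codon_1based[0]}-"
                     f"{m.start_codon_1based[1]} {segs}\n")
            for i in range(0, len(m.sequence), 70):
                fh.write(m.sequence[i : i + 70] + "\n")
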