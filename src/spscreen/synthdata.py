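"""Deterministic synthetic fixtures with known ground truth.

Two kinds of fixture live here.  ``gen_table_fixture`` packages the eight
benchmark candidates whose sequences and metrics are published (the five
top-ranked screen hits SP1-SP5, the native hBMP2 SP, its TISIGNER
codon-optimised variant, and the hIL2 SP); these drive regression tests and
the worked examples.  ``gen_record_set`` fabricates arbitrarily large
candidate sets with controlled defect rates (frame errors, missing start
codons, mistranslations, duplicate CDSs, weak Kozak contexts) and mock
predictor scores, together with a ground-truth object stating exactly what
every pipeline stage should do with them — so the whole filter funnel is
testable without any database download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .constructs import DEFAULT_UTR5, VectorContext
from .records import SPRecord, translate_cds
from .rnastruct import SecondaryStructure, fold_nussinov, structure_from_pairs
from .scoring import STAGE_LABELS

# ---------------------------------------------------------------------------
# Published benchmark candidates (Tables of the screen's top hits + controls)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateFixture:
    """One benchmark candidate: record plus its published metrics.

    ``opening_energy`` values are the printed integer opening energies;
    each is consistent with printed MFE / printed SP score (the published
    table typesets the numeric columns without separators, so the opening
    energies were recovered by checking MFE / SP-score division against
    every row).
    """

    name: str
    record: SPRecord
    sec_spi: float
    mfe: float
    opening_energy: float
    sp_score: float
    z_score: float


_TABLE_ROWS = [
    # name, species, protein, uniprot, source_db, source_acc, nt, aa,
    # sec_spi, mfe, opening, sp_score, z_score
    (
        "SP1", "Vireo altiloquus", "BMP 15", "A0A7K5LQ98", "EBI ENA", "NWT20625.1",
        "ATGGCTATGCCCTACTCTTTTGCCAGCCTCCTCCTCCTCCTCCTTGTTGTGCCCCTTTCCCAGGCT",
        "MAMPYSFASLLLLLLVVPLSQA",
        0.9997, -438.2, -47.0, 9.32, 10.5,
    ),
    (
        "SP2", "Parambassis ranga", "GDF 10-like", "A0A6P7IG99",
        "NCBI Nucleotide", "XM_028407950.1",
        "ATGGAATCACTTTTCAGATCCTCAGCTATGCTCAGCCGGCTTTTTTTCATCCTGTGTATATTGGTGATCCTGGAGTCCAGCTGGGCT",
        "MESLFRSSAMLSRLFFILCILVILESSWA",
        0.9997, -448.6, -70.0, 6.41, 6.6,
    ),
    (
        "SP3", "Muntiacus muntjak", "Artemin related", "A0A5N3WKB5",
        "EBI ENA", "KAB0362191.1",
        "ATGGAGCCTGGACGTGGAGGCCCTTCTGTGCTGCCCCTCCGGGCCGGGCCTAGGAGGCAGCAGCCTGCCCTGTGG"
        "CACACCCTGGCCGCTCTGGCCCTGCTGAGCAGCGTCGCCGAGGGT",
        "MEPGRGGPSVLPLRAGPRRQQPALWHTLAALALLSSVAEG",
        0.5494, -488.7, -82.0, 5.96, 6.0,
    ),
    (
        "SP4", "Phyllostomus discolor", "Artemin", "A0A7E6DRJ2",
        "EBI ENA", "KAF6107540.1",
        "ATGGAGCCTGGACGTGGAGGCCCTTCTGTGCTGCCCCGCTGGCCCCTGCCTAGGCGGCAGCCTGCCCTGTGG"
        "CCAACCCTGGCTACTCTGGTTCTGCTGAGCAGTGTCGCTGAGGCC",
        "MEPGRGGPSVLPRWPLPRRQPALWPTLATLVLLSSVAEA",
        0.7878, -480.1, -82.0, 5.85, 5.9,
    ),
    (
        "SP5", "Molossus molossus", "Artemin", "A0A7J8F7B8",
        "EBI ENA", "KAF6443102.1",
        "ATGGAGCCTGGATGTGGAGGCCCTCCTGTGCTGCTCCGCTGGACCCCACCTACGCGGCAGCCTGCCCTGTGG"
        "CCAACCCTGGCCACTCTGGTCCTGCTGAGCAGTGTCGCTGAGGCC",
        "MEPGCGGPPVLLRWTPPTRQPALWPTLATLVLLSSVAEA",
        0.6976, -477.9, -82.0, 5.83, 5.8,
    ),
    (
        "hBMP2", "Homo sapiens", "BMP2", "P12643",
        "NCBI nucleotide", "NM_001200.4",
        "ATGGTGGCCGGGACCCGCTGTCTTCTAGCGTTGCTGCTTCCCCAGGTCCTCCTGGGCGGCGCGGCTGGC",
        "MVAGTRCLLALLLPQVLLGGAAG",
        0.9988, -462.3, -205.0, 2.26, 1.0,
    ),
    (
        "hBMP2-TIS", "Homo sapiens", "BMP2 (TISIGNER codon-optimised SP)", "hBMP2-TIS",
        "", "",
        "ATGGTTGCCGGTACGCGCTGTCTACTAGCATTGCTGCTTCCCCAGGTCCTCCTGGGCGGCGCGGCTGGC",
        "MVAGTRCLLALLLPQVLLGGAAG",
        0.9988, -459.8, -219.0, 2.10, 0.8,
    ),
    (
        "hIL2", "Homo sapiens", "IL2", "P60568",
        "NCBI nucleotide", "NM_000586.4",
        "ATGTACAGGATGCAACTCCTGTCTTGCATTGCACTAAGTCTTGCACTTGTCACAAACAGT",
        "MYRMQLLSCIALSLALVTNS",
        0.9994, -435.3, -417.0, 1.04, -0.6,
    ),
]


def gen_table_fixture() -> list[CandidateFixture]:
    """The eight published benchmark candidates, byte-stable."""
    out = []
    for (name, species, protein, acc, db, db_acc, nt, aa,
         sec, mfe, opening, sp, z) in _TABLE_ROWS:
        out.append(
            CandidateFixture(
                name=name,
                record=SPRecord(
                    uniprot_accession=acc,
                    species=species,
                    protein_name=protein,
                    aa_sequence=aa,
                    nt_sequence=nt,
                    source_db=db,
                    source_accession=db_acc,
                ),
                sec_spi=sec,
                mfe=mfe,
                opening_energy=opening,
                sp_score=sp,
                z_score=z,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Synthetic vector context
# ---------------------------------------------------------------------------

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_G_CODONS = tuple(c for c in _NON_STOP_CODONS if c[0] == "G")
_NON_G_CODONS = tuple(c for c in _NON_STOP_CODONS if c[0] != "G")


def synthetic_vector(
    seed: int = 20240523,
    propeptide_codons: int = 373,
    utr3_length: int = 120,
    polya_tail_length: int = 150,
) -> VectorContext:
    """A synthetic stand-in for the expression-vector context.

    The 5'UTR is the real transcript-level UTR tail of the pVax vector (its
    sequence is published); the propeptide CDS, 3'UTR and poly-A signal
    region are *synthetic* seeded stand-ins of realistic length (the real
    hBMP2 propeptide and vector 3' sequences are not shipped).  At the
    defaults the assembled transcripts are ~1.7 kb, matching the intended
    construct scale; pass smaller ``propeptide_codons``/``utr3_length`` for
    fast demonstrations.
    """
    rng = np.random.default_rng(seed)
    propeptide = "".join(
        _NON_STOP_CODONS[i]
        for i in rng.integers(0, len(_NON_STOP_CODONS), size=propeptide_codons)
    )
    utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=utr3_length))
    polya_region = (
        "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
        + "AATAAA"
        + "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))
    )
    return VectorContext(
        utr5=DEFAULT_UTR5,
        propeptide_cds=propeptide,
        utr3=utr3,
        polya_region=polya_region,
        polya_tail_length=polya_tail_length,
    )


# ---------------------------------------------------------------------------
# Random RNA / structures (folding-oracle inputs)
# ---------------------------------------------------------------------------

def gen_random_rna(length: int, gc_fraction: float, seed: int) -> str:
    """Random RNA with the requested expected GC content; deterministic."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gc = rng.random(length) < gc_fraction
    strand = rng.random(length) < 0.5
    return "".join(
        ("G" if s else "C") if g else ("A" if s else "U")
        for g, s in zip(gc, strand)
    )


def gen_random_structure(
    length: int, seed: int, gc_fraction: float = 0.5, pair_keep: float = 0.7
) -> SecondaryStructure:
    """A random valid nested structure over a random sequence.

    Folds a random sequence by pair maximisation, then deletes each pair
    independently with probability ``1 - pair_keep``; deletion preserves
    nesting and can only enlarge loops, so the result is always a valid
    structure, with a good mix of stacks, bulges, internal loops and
    multiloops for property tests.
    """
    rng = np.random.default_rng(seed)
    seq = gen_random_rna(length, gc_fraction, seed + 1)
    full = fold_nussinov(seq)
    kept = [p for p in full.pairs if rng.random() < pair_keep]
    return structure_from_pairs(seq, kept)


# ---------------------------------------------------------------------------
# Synthetic record sets with ground truth
# ---------------------------------------------------------------------------

@dataclass
class ScoreModel:
    """Mock predictor-score model: a two-component mixture straddling the
    0.5 exclusion threshold, plus deliberately injected exact-0.5 scores
    (which pass, since exclusion is strictly-below)."""

    fraction_low_sec_spi: float = 0.31
    fraction_low_extracellular: float = 0.0
    pass_range: tuple[float, float] = (0.55, 1.0)
    fail_range: tuple[float, float] = (0.0, 0.45)
    n_exact_threshold: int = 1


@dataclass
class SynthSpec:
    """Generator parameters.

    Defect fractions are fractions of ``n_records`` and are disjoint per
    record; defaults approximate the stage attrition of a real screen
    (small QC losses, heavy duplication, roughly a third failing secretion
    prediction, none failing localisation, and a substantial weak-Kozak
    fraction).  ``sp_length_range`` is in codons and spans the observed SP
    length range.
    """

    n_records: int = 100
    fraction_invalid_frame: float = 0.02
    fraction_no_start: float = 0.02
    fraction_mistranslated: float = 0.03
    fraction_duplicate: float = 0.30
    fraction_weak_kozak: float = 0.20
    sp_length_range: tuple[int, int] = (20, 45)
    seed: int = 0
    score_model: ScoreModel = field(default_factory=ScoreModel)

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_invalid_frame
            + self.fraction_no_start
            + self.fraction_mistranslated
            + self.fraction_duplicate
            + self.fraction_weak_kozak
            + self.score_model.fraction_low_sec_spi
            + self.score_model.fraction_low_extracellular
        )
        if fracs > 1.0 + 1e-9:
            raise ValueError(f"defect + score-model fractions sum to {fracs:.3f} > 1")
        if self.sp_length_range[0] < 2:
            raise ValueError("sp_length_range minimum must be >= 2 codons")
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")


@dataclass
class GroundTruth:
    """What every stage of the pipeline should do with a generated set."""

    category: dict[str, str]  # accession -> defect category ("clean" if none)
    qc_pass: dict[str, bool]
    duplicate_of: dict[str, str]  # accession -> source accession
    kozak: dict[str, str]
    sec_spi_pass: dict[str, bool]
    extracellular_pass: dict[str, bool]
    final_pass: dict[str, bool]
    expected_funnel: list[tuple[str, int]]


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def gen_record_set(
    spec: SynthSpec,
) -> tuple[list[SPRecord], dict[str, tuple[float, float]], GroundTruth]:
    """Generate records + mock predictor scores + ground truth.

    Deterministic for a given spec; each defect category is realised on
    ``round(fraction * n)`` records (within one record of the request) and
    categories are disjoint, so expected funnel counts follow exactly.
    Duplicate records always appear after the clean record they copy, so
    first-occurrence dedup removes precisely the duplicates.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    counts = {
        "invalid_frame": round(spec.fraction_invalid_frame * n),
        "no_start": round(spec.fraction_no_start * n),
        "mistranslated": round(spec.fraction_mistranslated * n),
        "duplicate": round(spec.fraction_duplicate * n),
        "weak_kozak": round(spec.fraction_weak_kozak * n),
        "low_sec_spi": round(spec.score_model.fraction_low_sec_spi * n),
        "low_extracellular": round(spec.score_model.fraction_low_extracellular * n),
    }
    if sum(counts.values()) > n:
        raise ValueError("rounded defect counts exceed n_records")

    cats = ["clean"] * n
    pos = 0
    for cat, cnt in counts.items():
        for _ in range(cnt):
            cats[pos] = cat
            pos += 1
    perm = rng.permutation(n)
    cats = [cats[i] for i in perm]

    if counts["duplicate"]:
        if "clean" not in cats:
            raise ValueError("duplicates requested but no clean records to copy")
        # a duplicate must follow the clean record it copies: swap any
        # duplicate that precedes every clean record with a later clean one
        seen_clean = False
        for i in range(n):
            if cats[i] == "clean":
                seen_clean = True
            elif cats[i] == "duplicate" and not seen_clean:
                later = next(j for j in range(i + 1, n) if cats[j] == "clean")
                cats[i], cats[later] = cats[later], cats[i]
                seen_clean = True

    records: list[SPRecord] = []
    scores: dict[str, tuple[float, float]] = {}
    truth = GroundTruth({}, {}, {}, {}, {}, {}, {}, [])
    clean_accessions: list[tuple[int, str]] = []  # (position, accession)
    lo, hi = spec.sp_length_range

    def draw_cds(weak_kozak: bool) -> str:
        n_codons = int(rng.integers(lo, hi + 1))
        second_pool = _NON_G_CODONS if weak_kozak else _G_CODONS
        second = second_pool[int(rng.integers(0, len(second_pool)))]
        rest = "".join(
            _NON_STOP_CODONS[i]
            for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 2)
        )
        return "ATG" + second + rest

    for i, cat in enumerate(cats):
        acc = f"SYN{i:05d}"
        if cat == "duplicate":
            earlier = [a for p, a in clean_accessions if p < i]
            src = earlier[int(rng.integers(0, len(earlier)))]
            src_rec = next(r for r in records if r.uniprot_accession == src)
            nt, aa = src_rec.nt_sequence, src_rec.aa_sequence
            truth.duplicate_of[acc] = src
        else:
            nt = draw_cds(weak_kozak=(cat == "weak_kozak"))
            aa = translate_cds(nt)
            if cat == "invalid_frame":
                nt = nt + "AC"[: int(rng.integers(1, 3))]
            elif cat == "no_start":
                nt = "CTG" + nt[3:]
            elif cat == "mistranslated":
                k = int(rng.integers(1, len(aa)))
                repl = _AA20[int(rng.integers(0, 20))]
                if repl == aa[k]:
                    repl = _AA20[(_AA20.index(repl) + 1) % 20]
                aa = aa[:k] + repl + aa[k + 1:]
        rec = SPRecord(
            uniprot_accession=acc,
            species="Synthetica exempli",
            protein_name="synthetic TGF-beta-like SP",
            aa_sequence=aa,
            nt_sequence=nt,
            source_db="synthetic",
            source_accession=acc,
        )
        records.append(rec)
        if cat == "clean":
            clean_accessions.append((i, acc))

        pr, fr = spec.score_model.pass_range, spec.score_model.fail_range
        sec = (
            float(rng.uniform(*fr)) if cat == "low_sec_spi" else float(rng.uniform(*pr))
        )
        extr = (
            float(rng.uniform(*fr))
            if cat == "low_extracellular"
            else float(rng.uniform(*pr))
        )
        scores[acc] = (sec, extr)

        qc = cat not in ("invalid_frame", "no_start", "mistranslated")
        truth.category[acc] = cat
        truth.qc_pass[acc] = qc
        truth.kozak[acc] = "weak" if cat == "weak_kozak" else "strong"
        truth.sec_spi_pass[acc] = cat != "low_sec_spi"
        truth.extracellular_pass[acc] = cat != "low_extracellular"
        truth.final_pass[acc] = cat == "clean"

    # inject exact-threshold Sec/SPI scores on clean records (they pass)
    for k in range(min(spec.score_model.n_exact_threshold, len(clean_accessions))):
        acc = clean_accessions[k][1]
        scores[acc] = (0.5, scores[acc][1])

    n_qc = n - counts["invalid_frame"] - counts["no_start"] - counts["mistranslated"]
    n_unique = n_qc - counts["duplicate"]
    n_sp = n_unique - counts["low_sec_spi"]
    n_dl = n_sp - counts["low_extracellular"]
    n_kz = n_dl - counts["weak_kozak"]
    truth.expected_funnel = list(
        zip(STAGE_LABELS, [n, n_qc, n_unique, n_sp, n_dl, n_kz])
    )
    return records, scores, truth


# ---------------------------------------------------------------------------
# On-disk emission (round-trips through the CLI)
# ---------------------------------------------------------------------------

def write_synthetic_inputs(
    outdir: str | Path,
    spec: SynthSpec,
    vector: Optional[VectorContext] = None,
) -> dict[str, Path]:
    """Emit a generated set in the formats the pipeline consumes.

    Writes ``records.tsv``, the paired FASTA (``records.aa.fasta`` /
    ``records.nt.fasta``), mock ``signalp.tsv`` (SignalP 6 tabular layout),
    ``deeploc.csv`` (DeepLoc 2 layout), ``vector.yaml`` and
    ``ground_truth.json``.  Returns the path of each artefact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, scores, truth = gen_record_set(spec)
    vector = vector or synthetic_vector(seed=spec.seed + 1)

    paths = {name: outdir / fname for name, fname in [
        ("records_tsv", "records.tsv"),
        ("aa_fasta", "records.aa.fasta"),
        ("nt_fasta", "records.nt.fasta"),
        ("signalp", "signalp.tsv"),
        ("deeploc", "deeploc.csv"),
        ("vector", "vector.yaml"),
        ("ground_truth", "ground_truth.json"),
    ]}

    with open(paths["records_tsv"], "w", encoding="utf-8") as fh:
        fh.write(
            "uniprot_accession\tspecies\tprotein_name\taa_sequence\t"
            "nt_sequence\tsource_db\tsource_accession\n"
        )
        for r in records:
            fh.write(
                f"{r.uniprot_accession}\t{r.species}\t{r.protein_name}\t"
                f"{r.aa_sequence}\t{r.nt_sequence or ''}\t{r.source_db}\t"
                f"{r.source_accession}\n"
            )
    with open(paths["aa_fasta"], "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                f">{r.uniprot_accession} species={r.species.replace(' ', '_')} "
                f"protein={r.protein_name.replace(' ', '_')} source_db={r.source_db}\n"
                f"{r.aa_sequence}\n"
            )
    with open(paths["nt_fasta"], "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.uniprot_accession}\n{r.nt_sequence or ''}\n")
    with open(paths["signalp"], "w", encoding="utf-8") as fh:
        fh.write("# SignalP-6.0\tOrganism: Eukarya\tTimestamp: synthetic\n")
        fh.write("# ID\tPrediction\tOTHER\tSP(Sec/SPI)\tCS Position\n")
        for r in records:
            sec = scores[r.uniprot_accession][0]
            pred = "SP" if sec >= 0.5 else "OTHER"
            fh.write(f"{r.uniprot_accession}\t{pred}\t{1 - sec:.4f}\t{sec:.4f}\t\n")
    with open(paths["deeploc"], "w", encoding="utf-8") as fh:
        fh.write("Protein_ID,Localizations,Signals,Cytoplasm,Nucleus,Extracellular\n")
        for r in records:
            extr = scores[r.uniprot_accession][1]
            loc = "Extracellular" if extr >= 0.5 else "Cytoplasm"
            fh.write(
                f"{r.uniprot_accession},{loc},SP,{(1 - extr) / 2:.4f},"
                f"{(1 - extr) / 2:.4f},{extr:.4f}\n"
            )
    vector.to_config(paths["vector"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "seed": spec.seed,
                "category": truth.category,
                "expected_funnel": [
                    {"stage": s, "surviving": c} for s, c in truth.expected_funnel
                ],
            },
            fh,
            indent=2,
        )
    return paths
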