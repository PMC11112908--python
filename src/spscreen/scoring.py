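"""Filter cascade, windowed opening energy, SP score, Z-scores, ranking, funnel.

The screen's ranking metric is ``SP score = MFE / opening energy``: MFE is
the free energy of the whole predicted transcript's structure (global
stability), and the opening energy is the summed free energy of the
structural elements occluding a +/-15 nt window around the start codon (the
cost of melting structure over the ribosomal attachment site).  Both are
negative, so higher SP scores combine a stable molecule with an accessible
start site.  Candidates are Z-scored against the scored population and
ranked descending.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .constructs import PredictedMRNA, VectorContext, assemble_mrna, classify_kozak
from .records import SPRecord, dedup_records, validate_record
from .rnastruct import (
    EnergyParams,
    Loop,
    SecondaryStructure,
    annotate_energies,
    decompose_loops,
    default_params,
    fold_mfe,
    total_energy,
)

log = logging.getLogger("spscreen")


@dataclass
class Thresholds:
    """Filter-cascade thresholds.

    ``sec_spi_min``/``extracellular_min`` are *exclusion* thresholds: a
    candidate is dropped when its score is strictly below the threshold, so
    an exact 0.5 passes at the default 0.5.  ``window_flank`` is the number
    of nucleotides either side of the start codon used for opening energy.
    """

    sec_spi_min: float = 0.5
    extracellular_min: float = 0.5
    require_strong_kozak: bool = True
    window_flank: int = 15

    def __post_init__(self) -> None:
        if not (0.0 <= self.sec_spi_min <= 1.0 and 0.0 <= self.extracellular_min <= 1.0):
            raise ValueError("predictor thresholds must lie in [0, 1]")
        if self.window_flank < 0:
            raise ValueError("window_flank must be >= 0")


@dataclass
class CandidateScore:
    """Per-candidate metrics accumulated along the pipeline."""

    accession: str
    species: str = ""
    protein_name: str = ""
    sec_spi: Optional[float] = None
    extracellular: Optional[float] = None
    kozak: Optional[str] = None
    mfe: Optional[float] = None
    opening_energy: Optional[float] = None
    sp_score: Optional[float] = None
    z_score: Optional[float] = None
    rank: Optional[int] = None


@dataclass
class FilterFunnel:
    """Ordered (stage label, surviving count) pairs; counts never increase."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, label: str, surviving: int) -> None:
        if self.stages and surviving > self.stages[-1][1]:
            raise ValueError(
                f"funnel stage {label!r} increases count "
                f"({self.stages[-1][1]} -> {surviving})"
            )
        self.stages.append((label, surviving))

    def counts(self) -> list[int]:
        return [n for _, n in self.stages]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = [{"stage": s, "surviving": n} for s, n in self.stages]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


# ---------------------------------------------------------------------------
# Window / opening energy
# ---------------------------------------------------------------------------

def start_window(
    mrna: PredictedMRNA, flank: int = 15, anchor: str = "codon"
) -> tuple[int, int]:
    """Half-open window around the start codon, clipped to the sequence.

    ``anchor="codon"`` spans ``[start - flank, start + 3 + flank)`` (33 nt at
    the default flank); ``anchor="a"`` centres on the A of AUG alone
    (31 nt at the default flank).
    """
    if anchor == "codon":
        lo, hi = mrna.start_index - flank, mrna.start_index + 3 + flank
    elif anchor == "a":
        lo, hi = mrna.start_index - flank, mrna.start_index + 1 + flank
    else:
        raise ValueError(f"unknown window anchor {anchor!r}")
    return max(0, lo), min(len(mrna.sequence), hi)


def opening_energy(
    mrna: PredictedMRNA,
    loops: Sequence[Loop],
    flank: int = 15,
    anchor: str = "codon",
) -> float:
    """Summed energy of loops with a paired endpoint inside the start window.

    A loop is counted when at least one endpoint of its closing pair or of
    any branch pair lies inside the window; unpaired membership alone does
    not trigger inclusion (opening energy is the cost of melting the *pairs*
    occluding the window).  Loops must carry energies
    (:func:`spscreen.rnastruct.annotate_energies`).  Returns 0.0 when the
    window is structure-free.
    """
    lo, hi = start_window(mrna, flank, anchor)
    total = 0.0
    for lp in loops:
        if lp.kind == "exterior":
            continue
        if any(lo <= p < hi for p in lp.paired_endpoints()):
            if lp.energy is None:
                raise ValueError("loops must be energy-annotated before windowing")
            total += lp.energy
    return total


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def sp_score(mfe: float, opening: float) -> Optional[float]:
    """``MFE / opening energy``; ``None`` (with a warning) when the start
    window is fully accessible (opening == 0), marking the candidate
    unscorable rather than raising."""
    if opening == 0:
        log.warning("opening energy is 0 (fully accessible start): unscorable")
        return None
    return mfe / opening


def summary_stats(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and *population* standard deviation (divisor n)."""
    if len(values) == 0:
        raise ValueError("summary_stats needs at least one value")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


def z_scores(scores: Sequence[float]) -> list[float]:
    """Population Z-scores of ``scores`` against their own mean/SD."""
    if len(scores) < 2:
        raise ValueError("z_scores needs at least two values")
    mean, sd = summary_stats(scores)
    if sd == 0:
        raise ValueError("z_scores undefined: zero standard deviation")
    return [(x - mean) / sd for x in scores]


# ---------------------------------------------------------------------------
# Predictor-output readers
# ---------------------------------------------------------------------------

def read_signalp(path: str | Path) -> dict[str, float]:
    """Read SignalP 6 tabular output into ``{accession: Sec/SPI score}``.

    Header lines start with ``#``; the last header line names the columns
    and one of them contains ``Sec/SPI``.
    """
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = [c.strip() for c in line.lstrip("# ").split("\t")]
            else:
                rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: no '#' header line found")
    try:
        col = next(i for i, name in enumerate(header) if "Sec/SPI" in name)
    except StopIteration:
        raise ValueError(f"{path}: no Sec/SPI column in header {header}")
    return {row[0].strip(): float(row[col]) for row in rows if len(row) > col}


def read_deeploc(path: str | Path) -> dict[str, float]:
    """Read DeepLoc 2 CSV into ``{accession: extracellular probability}``."""
    df = pd.read_csv(path)
    if "Protein_ID" not in df.columns or "Extracellular" not in df.columns:
        raise ValueError(
            f"{path}: expected Protein_ID and Extracellular columns, got {list(df.columns)}"
        )
    return dict(zip(df["Protein_ID"].astype(str), df["Extracellular"].astype(float)))


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

STAGE_LABELS = (
    "has_signal_peptide",
    "qc_valid",
    "unique_nt",
    "signalp_pass",
    "deeploc_pass",
    "kozak_strong",
)


def apply_filters(
    records: Sequence[SPRecord],
    predictor_scores: Mapping[str, tuple[float, float]],
    kozak: Mapping[str, str] | VectorContext,
    thresholds: Thresholds | None = None,
) -> tuple[list[SPRecord], FilterFunnel]:
    """Run the filter cascade and record the funnel.

    Stages, in order: annotated with an SP (non-empty protein sequence) ->
    QC valid -> unique CDS -> SignalP pass -> DeepLoc pass -> strong Kozak.
    ``predictor_scores`` maps accession to ``(sec_spi, extracellular)``; a
    missing entry excludes the record at the relevant stage with a logged
    reason.  ``kozak`` is either a precomputed accession->class mapping or a
    :class:`VectorContext` to classify against.  Exclusions are data, never
    exceptions.
    """
    thresholds = thresholds or Thresholds()
    funnel = FilterFunnel()

    current = [r for r in records if r.aa_sequence]
    funnel.add(STAGE_LABELS[0], len(current))

    current = [r for r in current if validate_record(r).overall_pass]
    funnel.add(STAGE_LABELS[1], len(current))

    current, _removed = dedup_records(current)
    funnel.add(STAGE_LABELS[2], len(current))

    kept = []
    for r in current:
        entry = predictor_scores.get(r.uniprot_accession)
        if entry is None:
            log.info("%s: no SignalP score, excluded", r.uniprot_accession)
            continue
        if entry[0] < thresholds.sec_spi_min:
            continue
        kept.append(r)
    current = kept
    funnel.add(STAGE_LABELS[3], len(current))

    kept = []
    for r in current:
        entry = predictor_scores.get(r.uniprot_accession)
        if entry is None or entry[1] is None:
            log.info("%s: no DeepLoc score, excluded", r.uniprot_accession)
            continue
        if entry[1] < thresholds.extracellular_min:
            continue
        kept.append(r)
    current = kept
    funnel.add(STAGE_LABELS[4], len(current))

    if thresholds.require_strong_kozak:
        kept = []
        for r in current:
            if isinstance(kozak, VectorContext):
                cls = classify_kozak(kozak, r.nt_sequence)
            else:
                cls = kozak.get(r.uniprot_accession)
                if cls is None:
                    log.info("%s: no Kozak class, excluded", r.uniprot_accession)
                    continue
            if cls == "strong":
                kept.append(r)
        current = kept
    funnel.add(STAGE_LABELS[5], len(current))

    return current, funnel


# ---------------------------------------------------------------------------
# Ranking and reports
# ---------------------------------------------------------------------------

def attach_z_scores(candidates: Sequence[CandidateScore]) -> None:
    """Z-score the scorable candidates in place against their own population."""
    scorable = [c for c in candidates if c.sp_score is not None]
    if len(scorable) < 2:
        return
    zs = z_scores([c.sp_score for c in scorable])
    for c, z in zip(scorable, zs):
        c.z_score = z


def rank_candidates(
    candidates: Sequence[CandidateScore], top_k: int | None = None
) -> list[CandidateScore]:
    """Rank scorable candidates by descending SP score.

    Ties break on less-negative opening energy, then accession.  Candidates
    with ``sp_score is None`` (unscorable) are excluded with a warning.
    Ranks 1..k are written onto the returned candidates.
    """
    scorable = [c for c in candidates if c.sp_score is not None]
    dropped = len(candidates) - len(scorable)
    if dropped:
        log.warning("%d unscorable candidate(s) excluded from ranking", dropped)
    ordered = sorted(
        scorable,
        key=lambda c: (
            -c.sp_score,
            -(c.opening_energy if c.opening_energy is not None else -math.inf),
            c.accession,
        ),
    )
    if top_k is not None:
        if top_k > len(ordered):
            log.warning("top_k=%d exceeds %d candidates; returning all", top_k, len(ordered))
        ordered = ordered[:top_k]
    for pos, c in enumerate(ordered, start=1):
        c.rank = pos
    return ordered


def run_screen(
    records: Sequence[SPRecord],
    predictor_scores: Mapping[str, tuple[float, float]],
    vector: VectorContext,
    thresholds: Thresholds | None = None,
    params: EnergyParams | None = None,
    structures: Mapping[str, tuple[SecondaryStructure, Optional[float]]] | None = None,
    top_k: int | None = None,
) -> tuple[list[CandidateScore], FilterFunnel]:
    """End-to-end screen: filters, assembly, folding/evaluation, ranking.

    For each filter survivor the predicted transcript is assembled, its
    structure obtained either from ``structures`` (external-backend output
    keyed by accession; a reported energy is used as the MFE, otherwise the
    packaged evaluator recomputes it) or from the built-in MFE folder, its
    loops energy-annotated, and the windowed opening energy, SP score and
    Z-score computed.  Returns the ranked candidates and the funnel.

    The built-in folder is cubic-time: for full-length (~1.7 kb)
    transcripts supply external structures and keep built-in folding for
    short constructs.
    """
    thresholds = thresholds or Thresholds()
    params = params or default_params()
    survivors, funnel = apply_filters(records, predictor_scores, vector, thresholds)
    candidates: list[CandidateScore] = []
    for rec in survivors:
        acc = rec.uniprot_accession
        mrna = assemble_mrna(vector, rec.nt_sequence, name=acc)
        if structures is not None and acc in structures:
            structure, reported = structures[acc]
            if len(structure) != len(mrna.sequence):
                raise ValueError(
                    f"{acc}: external structure length {len(structure)} != "
                    f"assembled transcript length {len(mrna.sequence)}"
                )
            mfe = reported if reported is not None else total_energy(structure, params)
        else:
            structure, mfe = fold_mfe(mrna.sequence, params)
        loops = annotate_energies(decompose_loops(structure), structure.sequence, params)
        opening = opening_energy(mrna, loops, flank=thresholds.window_flank)
        entry = predictor_scores.get(acc)
        candidates.append(
            CandidateScore(
                accession=acc,
                species=rec.species,
                protein_name=rec.protein_name,
                sec_spi=entry[0] if entry else None,
                extracellular=entry[1] if entry else None,
                kozak=classify_kozak(vector, rec.nt_sequence),
                mfe=mfe,
                opening_energy=opening,
                sp_score=sp_score(mfe, opening),
            )
        )
    attach_z_scores(candidates)
    ranked = rank_candidates(candidates, top_k)
    return ranked, funnel


def scores_to_frame(
    candidates: Iterable[CandidateScore],
    records: Mapping[str, SPRecord] | None = None,
) -> pd.DataFrame:
    """Tabulate candidates (Table-1-like layout).

    Report rounding: energies to 1 dp, SP score to 2 dp, Z to 1 dp; full
    precision stays on the :class:`CandidateScore` objects.
    """
    rows = []
    for c in candidates:
        rec = records.get(c.accession) if records else None
        rows.append(
            {
                "accession": c.accession,
                "species": c.species or (rec.species if rec else ""),
                "protein_name": c.protein_name or (rec.protein_name if rec else ""),
                "nt_sequence": rec.nt_sequence if rec else "",
                "aa_sequence": rec.aa_sequence if rec else "",
                "sec_spi": c.sec_spi,
                "kozak": c.kozak,
                "mfe": None if c.mfe is None else round(c.mfe, 1),
                "opening_energy": (
                    None if c.opening_energy is None else round(c.opening_energy, 1)
                ),
                "sp_score": None if c.sp_score is None else round(c.sp_score, 2),
                "z_score": None if c.z_score is None else round(c.z_score, 1),
                "rank": c.rank,
            }
        )
    return pd.DataFrame(rows)


def write_ranked_tsv(
    candidates: Iterable[CandidateScore],
    path: str | Path,
    records: Mapping[str, SPRecord] | None = None,
) -> None:
    scores_to_frame(candidates, records).to_csv(path, sep="\t", index=False)
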