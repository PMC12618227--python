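"""Sequence-overlap scoring between tumor and matched saliva/stool panels.

Each patient contributes labelled bacterial sequence sets reconstructed from
tumor, saliva and stool shotgun data. Overlap between compartments of the
same patient is scored by local alignment: identity above 95% records a
species-level overlap, above 98% the sequences count as the same genome, and
segments that match the same species in *other* patients at least as well are
disqualified as non-specific. The fraction of the tumor sequence covered by
the aligned segment is reported as percent length matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

SPECIES_OVERLAP_IDENTITY = 95.0  # strict: identity must exceed this
SAME_GENOME_IDENTITY = 98.0


@dataclass
class SeqRecordEntry:
    seq_id: str
    species: str
    sequence: str


@dataclass
class SequencePanel:
    """Per-patient, per-compartment set of labelled bacterial sequences."""

    patient_id: str
    compartment: str  # tumor | saliva | stool
    records: list[SeqRecordEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.records:
            if not r.sequence:
                raise ValueError(f"{r.seq_id}: empty sequence")
            if set(r.sequence.upper()) - set("ACGTN"):
                raise ValueError(f"{r.seq_id}: non-ACGTN characters")

    @property
    def species(self) -> set[str]:
        return {r.species for r in self.records}


@dataclass
class OverlapResult:
    patient_id: str
    species: str
    compartment: str
    tumor_seq_id: str
    distal_seq_id: str
    tumor_seq_length: int
    matched_length: int
    identity: float  # percent
    verdict: str  # same_genome | species_overlap | none | disqualified_crosspatient

    @property
    def percent_length_matching(self) -> float:
        return 100.0 * self.matched_length / self.tumor_seq_length


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def align_pair(a: str, b: str) -> tuple[float, tuple[int, int]]:
    """Best local alignment of ``b`` against ``a`` on either strand.

    Returns (identity in percent over the aligned columns, the aligned
    interval on ``a`` as a half-open span). A match on the reverse complement
    of ``b`` counts equally.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner()
    best = None
    for query in (b, reverse_complement(b)):
        alns = aligner.align(a, query)
        if len(alns) == 0:
            continue
        aln = alns[0]
        if best is None or aln.score > best.score:
            best = aln
    if best is None or best.score <= 0:
        return 0.0, (0, 0)
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    span = (int(best.aligned[0][0][0]), int(best.aligned[0][-1][1]))
    return identity, span


def match_species(
    tumor: SequencePanel, distal: SequencePanel
) -> list[OverlapResult]:
    """Score every tumor sequence against the matched distal panel.

    Sequences are compared within a species label ("unassigned" compares
    against everything); for each tumor sequence the best-identity distal hit
    is kept. Identity above 95% yields a species overlap; above 98% the pair
    counts as the same genome. Thresholds are strict.
    """
    if tumor.patient_id != distal.patient_id:
        raise ValueError("panels must share a patient id")
    results: list[OverlapResult] = []
    for trec in tumor.records:
        best: OverlapResult | None = None
        for drec in distal.records:
            if (
                trec.species != drec.species
                and trec.species != "unassigned"
                and drec.species != "unassigned"
            ):
                continue
            identity, span = align_pair(trec.sequence, drec.sequence)
            res = OverlapResult(
                patient_id=tumor.patient_id,
                species=trec.species,
                compartment=distal.compartment,
                tumor_seq_id=trec.seq_id,
                distal_seq_id=drec.seq_id,
                tumor_seq_length=len(trec.sequence),
                matched_length=span[1] - span[0],
                identity=identity,
                verdict=_verdict(identity),
            )
            if best is None or res.identity > best.identity:
                best = res
        if best is not None:
            results.append(best)
    return results


def _verdict(identity: float) -> str:
    if identity > SAME_GENOME_IDENTITY:
        return "same_genome"
    if identity > SPECIES_OVERLAP_IDENTITY:
        return "species_overlap"
    return "none"


def crosspatient_exclusion(
    results: list[OverlapResult],
    tumor_panels: dict[str, SequencePanel],
) -> list[OverlapResult]:
    """Disqualify overlaps matched at least as well by another patient's sequences.

    For each qualifying same-patient overlap, the tumor segment is compared to
    sequences of the same species in every other patient's tumor panel; when
    any such sequence matches at an identity >= the same-patient identity (and
    above the 95% floor) the overlap verdict becomes
    ``disqualified_crosspatient``.
    """
    if len(tumor_panels) < 2:
        return results
    tumor_seq = {
        pid: {r.seq_id: r for r in panel.records} for pid, panel in tumor_panels.items()
    }
    out: list[OverlapResult] = []
    for res in results:
        if res.verdict not in ("species_overlap", "same_genome"):
            out.append(res)
            continue
        segment = tumor_seq[res.patient_id][res.tumor_seq_id].sequence
        disqualified = False
        for pid, panel in tumor_panels.items():
            if pid == res.patient_id:
                continue
            for rec in panel.records:
                if rec.species != res.species:
                    continue
                identity, _ = align_pair(segment, rec.sequence)
                if identity > SPECIES_OVERLAP_IDENTITY and identity >= res.identity:
                    disqualified = True
                    break
            if disqualified:
                break
        if disqualified:
            res = OverlapResult(**{**res.__dict__, "verdict": "disqualified_crosspatient"})
        out.append(res)
    return out


def summarize_overlap(
    results: list[OverlapResult], tumor_panels: dict[str, SequencePanel]
) -> dict:
    """Per-patient and cohort summaries of qualifying overlaps."""
    per_patient: dict[str, dict] = {}
    for pid, panel in tumor_panels.items():
        pres = [
            r for r in results
            if r.patient_id == pid and r.verdict in ("species_overlap", "same_genome")
        ]
        species_overlapping = sorted({r.species for r in pres})
        n_total = len(panel.species)
        per_patient[pid] = {
            "n_species_total": n_total,
            "n_species_overlapping": len(species_overlapping),
            "taxa_overlap_percent": 100.0 * len(species_overlapping) / n_total if n_total else 0.0,
            "mean_percent_length_matching": float(
                np.mean([r.percent_length_matching for r in pres])
            )
            if pres
            else 0.0,
        }
    lengths = [
        v["mean_percent_length_matching"] for v in per_patient.values()
        if v["n_species_overlapping"] > 0
    ]
    taxa = [v["taxa_overlap_percent"] for v in per_patient.values()]
    return {
        "per_patient": per_patient,
        "cohort": {
            "mean_percent_length_matching": float(np.mean(lengths)) if lengths else 0.0,
            "length_matching_range": [float(np.min(lengths)), float(np.max(lengths))]
            if lengths
            else [0.0, 0.0],
            "mean_taxa_overlap_percent": float(np.mean(taxa)) if taxa else 0.0,
        },
    }


# ---------------------------------------------------------------------------
# FASTA I/O: headers follow the "patient|compartment|species|seq_id" convention
# ---------------------------------------------------------------------------

def read_panels(path) -> dict[tuple[str, str], SequencePanel]:
    """Read FASTA into panels keyed by (patient_id, compartment)."""
    panels: dict[tuple[str, str], SequencePanel] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")  # species labels may contain spaces
        if len(parts) < 4:
            raise ValueError(
                f"header {rec.description!r} not in patient|compartment|species|seq_id form"
            )
        patient, compartment, species, seq_id = parts[0], parts[1], parts[2], parts[3]
        key = (patient, compartment)
        if key not in panels:
            panels[key] = SequencePanel(patient, compartment, [])
        panels[key].records.append(SeqRecordEntry(seq_id, species, str(rec.seq).upper()))
    return panels


def write_panels(panels: dict[tuple[str, str], SequencePanel], path) -> None:
    with open(path, "w") as fh:
        for (patient, compartment), panel in panels.items():
            for r in panel.records:
                fh.write(f">{patient}|{compartment}|{r.species}|{r.seq_id}\n{r.sequence}\n")
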