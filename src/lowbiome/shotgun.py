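"""Genome selection and contaminant filtering for shotgun read-hit tables.

Input is a table of read-to-genome alignments (one row per hit), the shape of
post-alignment output against a comprehensive bacterial reference: read id,
genome accession, genus, species, percent identity, alignment length, bit
score, and flags marking metagenome-assembled (MAG) or assembly-anomalous
genomes. The workflow:

* drop low-informativity reads — those whose top-scoring hits span more than
  one genus or at least two distinct species;
* greedy minimum set cover over the remaining reads, excluding flagged
  genomes up front, to pick the minimal genome set explaining all reads;
* three contaminant filters on the cover: control-taxon removal, removal of
  assigned hits shorter than the (recomputed) median alignment length, and
  removal of species whose pooled depth of coverage across samples exceeds 2x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Relative tolerance within which two bit scores count as tied at the top.
TOP_SCORE_RTOL = 1e-6

REQUIRED_COLUMNS = [
    "read_id", "accession", "genus", "species",
    "pident", "length", "bitscore",
]


def validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Check the hit-table schema and fill optional flag columns."""
    missing = [c for c in REQUIRED_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    if ((hits["pident"] < 0) | (hits["pident"] > 100)).any():
        raise ValueError("pident must lie in [0, 100]")
    if (hits["length"] < 1).any():
        raise ValueError("alignment_length must be >= 1")
    hits = hits.copy()
    for flag in ("is_mag", "assembly_anomaly"):
        if flag not in hits.columns:
            hits[flag] = False
    return hits


def filter_low_informativity(hits: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove reads whose top-scoring hits are taxonomically ambiguous.

    For each read, the top set is every hit whose bit score is within
    ``TOP_SCORE_RTOL`` (relative) of the read's maximum. The read is removed
    when that set spans more than one genus or two or more distinct species;
    otherwise *all* of its hits (top and non-top) are retained for the cover.
    Returns the surviving hit rows and the removed read ids.
    """
    hits = validate_hits(hits)
    removed: list[str] = []
    for read_id, grp in hits.groupby("read_id", sort=False):
        top = grp["bitscore"].max()
        top_set = grp[grp["bitscore"] >= top * (1 - TOP_SCORE_RTOL)]
        if top_set["genus"].nunique() > 1 or top_set["species"].nunique() >= 2:
            removed.append(read_id)
    kept = hits[~hits["read_id"].isin(removed)].reset_index(drop=True)
    return kept, sorted(removed)


@dataclass
class CoverSolution:
    """A greedy set-cover solution over reads and genomes.

    ``selected`` preserves the greedy pick order; ``assignment`` maps each
    covered read to the genome selected at the step that first covered it.
    """

    selected: list[str] = field(default_factory=list)
    assignment: dict[str, str] = field(default_factory=dict)
    dropped_reads: list[str] = field(default_factory=list)
    genome_taxa: dict[str, tuple[str, str]] = field(default_factory=dict)  # accession -> (genus, species)

    @property
    def reads_per_genome(self) -> dict[str, int]:
        out: dict[str, int] = {g: 0 for g in self.selected}
        for g in self.assignment.values():
            out[g] = out.get(g, 0) + 1
        return out

    def species_of(self, accession: str) -> str:
        return self.genome_taxa.get(accession, ("", ""))[1]

    def copy(self) -> "CoverSolution":
        return CoverSolution(
            list(self.selected), dict(self.assignment),
            list(self.dropped_reads), dict(self.genome_taxa),
        )


def min_set_cover(hits: pd.DataFrame) -> CoverSolution:
    """Greedy minimum set cover of reads by genomes.

    Genomes flagged as MAG-derived or assembly-anomalous are excluded before
    covering. At each step the genome covering the most uncovered reads wins;
    ties break by higher summed bit score over the uncovered reads it covers,
    then lexicographically smaller accession. Reads with no eligible genome
    are dropped and reported.
    """
    hits = validate_hits(hits)
    flagged = hits.groupby("accession")[["is_mag", "assembly_anomaly"]].any()
    bad_genomes = set(flagged.index[flagged.any(axis=1)])
    eligible = hits[~hits["accession"].isin(bad_genomes)]

    genome_reads: dict[str, set[str]] = {}
    genome_scores: dict[str, dict[str, float]] = {}
    for acc, grp in eligible.groupby("accession"):
        genome_reads[acc] = set(grp["read_id"])
        genome_scores[acc] = dict(zip(grp["read_id"], grp["bitscore"]))

    all_reads = set(hits["read_id"])
    coverable = set().union(*genome_reads.values()) if genome_reads else set()
    solution = CoverSolution(dropped_reads=sorted(all_reads - coverable))
    taxa = hits.groupby("accession")[["genus", "species"]].first()
    solution.genome_taxa = {a: (r["genus"], r["species"]) for a, r in taxa.iterrows()}

    uncovered = set(coverable)
    while uncovered:
        best_key = None
        best_acc = None
        for acc in sorted(genome_reads):
            new = genome_reads[acc] & uncovered
            if not new:
                continue
            score = sum(genome_scores[acc][r] for r in new)
            key = (len(new), score)
            # accession ascending is implied by the sorted iteration order
            if best_key is None or key > best_key:
                best_key = key
                best_acc = acc
        newly = genome_reads[best_acc] & uncovered
        solution.selected.append(best_acc)
        for r in newly:
            solution.assignment[r] = best_acc
        uncovered -= newly
    return solution


def filter_control_taxa(
    solution: CoverSolution, control_taxa: set[str]
) -> tuple[CoverSolution, list[str]]:
    """Drop selected genomes whose species (or genus) appears in negative controls."""
    out = solution.copy()
    removed = [
        acc for acc in out.selected
        if out.genome_taxa.get(acc, ("", ""))[1] in control_taxa
        or out.genome_taxa.get(acc, ("", ""))[0] in control_taxa
    ]
    out.selected = [a for a in out.selected if a not in removed]
    out.assignment = {r: g for r, g in out.assignment.items() if g not in removed}
    return out, removed


def filter_short_hits(
    solution: CoverSolution, hits: pd.DataFrame, median_override: float | None = None
) -> tuple[CoverSolution, float]:
    """Drop assigned hits shorter than the median assigned alignment length.

    The median is recomputed from the solution's own assigned hits each run
    (it is a data statistic, not a constant); ``median_override`` pins it when
    reproducing a previously derived value. Hits strictly below the median are
    removed; genomes left with no reads are dropped. Returns the filtered
    solution and the median used.
    """
    hits = validate_hits(hits)
    out = solution.copy()
    lengths: dict[str, float] = {}
    for (read_id, acc), grp in hits.groupby(["read_id", "accession"]):
        if out.assignment.get(read_id) == acc:
            lengths[read_id] = float(grp["length"].max())
    if not lengths:
        return out, float("nan")
    median = float(np.median(list(lengths.values()))) if median_override is None else float(median_override)
    short = {r for r, ln in lengths.items() if ln < median}
    out.assignment = {r: g for r, g in out.assignment.items() if r not in short}
    surviving = set(out.assignment.values())
    out.selected = [g for g in out.selected if g in surviving]
    return out, median


def filter_high_coverage(
    solutions: dict[str, CoverSolution],
    hits_by_sample: dict[str, pd.DataFrame],
    genome_lengths: dict[str, float],
    max_depth: float = 2.0,
) -> tuple[dict[str, CoverSolution], list[str]]:
    """Remove species whose pooled depth of coverage across samples exceeds ``max_depth``.

    Depth per species = sum over all samples of assigned alignment lengths,
    divided by the unique covered sequence length: the union of covered
    genome intervals when ``sstart``/``send`` columns are present, otherwise
    the genome length. Removal is strict (depth exactly ``max_depth`` is kept)
    and applies to every sample's solution.
    """
    assigned_bp: dict[str, float] = {}
    intervals: dict[str, list[tuple[float, float]]] = {}
    denom_by_species: dict[str, float] = {}
    for sample, sol in solutions.items():
        hits = validate_hits(hits_by_sample[sample])
        has_coords = {"sstart", "send"}.issubset(hits.columns)
        for _, row in hits.iterrows():
            if sol.assignment.get(row["read_id"]) != row["accession"]:
                continue
            sp = row["species"]
            assigned_bp[sp] = assigned_bp.get(sp, 0.0) + float(row["length"])
            if has_coords and np.isfinite(row["sstart"]) and np.isfinite(row["send"]):
                lo, hi = sorted((float(row["sstart"]), float(row["send"])))
                intervals.setdefault(sp, []).append((lo, hi))
            else:
                acc = row["accession"]
                if acc in genome_lengths:
                    denom_by_species[sp] = max(
                        denom_by_species.get(sp, 0.0), float(genome_lengths[acc])
                    )

    removed: list[str] = []
    for sp, bp in assigned_bp.items():
        if sp in intervals:
            denom = _union_length(intervals[sp])
        elif sp in denom_by_species:
            denom = denom_by_species[sp]
        else:
            import warnings

            warnings.warn(f"species {sp}: no genome length available; skipped")
            continue
        if denom > 0 and bp / denom > max_depth:
            removed.append(sp)

    out: dict[str, CoverSolution] = {}
    for sample, sol in solutions.items():
        new = sol.copy()
        doomed_accs = {a for a in new.selected if new.species_of(a) in removed}
        new.selected = [a for a in new.selected if a not in doomed_accs]
        new.assignment = {r: g for r, g in new.assignment.items() if g not in doomed_accs}
        out[sample] = new
    return out, sorted(removed)


def _union_length(spans: list[tuple[float, float]]) -> float:
    """Total length of the union of closed 1-D intervals."""
    merged: list[list[float]] = []
    for lo, hi in sorted(spans):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return float(sum(hi - lo for lo, hi in merged))


def pool_samples(hits_by_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-sample hit tables into one bulk table (read ids made unique)."""
    frames = []
    for sample, hits in hits_by_sample.items():
        h = hits.copy()
        h["read_id"] = [f"{sample}:{r}" for r in h["read_id"]]
        h["sample_id"] = sample
        frames.append(h)
    return pd.concat(frames, ignore_index=True)


def run_shotgun_filtration(
    hits: pd.DataFrame,
    control_taxa: set[str] | None = None,
    genome_lengths: dict[str, float] | None = None,
    median_override: float | None = None,
) -> tuple[CoverSolution, dict]:
    """Full bulk-sample workflow: informativity filter, cover, Steps 2-4."""
    informative, low_info = filter_low_informativity(hits)
    solution = min_set_cover(informative)
    report: dict = {
        "low_informativity_reads": low_info,
        "dropped_reads": solution.dropped_reads,
        "basal_genomes": list(solution.selected),
    }
    solution, removed_ctrl = filter_control_taxa(solution, control_taxa or set())
    report["control_taxa_genomes_removed"] = removed_ctrl
    solution, median = filter_short_hits(solution, informative, median_override)
    report["median_alignment_length"] = median
    pooled = {"bulk": solution}
    pooled, removed_cov = filter_high_coverage(
        pooled, {"bulk": informative}, genome_lengths or {}
    )
    report["high_coverage_species_removed"] = removed_cov
    return pooled["bulk"], report
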