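"""Seeded synthetic-data generators for every pipeline input type.

Each generator is a pure function of its config (including the seed): rerun
with the same config, it emits bit-identical tables. Every generator also
emits a ground-truth sidecar sufficient to score downstream recovery —
contaminant labels for the amplicon table, planted positive cells for the
transcript cloud, source genomes for the read-hit table.

What the generators emulate (and what they do not) is documented in
``docs/methods.md``: the statistical structure the analysis exploits is
present (contaminants shared across controls at high pooled abundance,
genuine taxa sparse and specimen-restricted, bacterial transcripts planted at
cell centroids, reads drawn from a known genome subset, log-normal ROI
counts over a negative-probe floor), while sequence evolution, cell
morphology and imaging physics are deliberately simplified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon import AsvTable
from .dsp import RoiMatrix
from .errors import ConfigError, PackingError
from .spatial import FovGeometry


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


# ---------------------------------------------------------------------------
# Amplicon (16S ASV table)
# ---------------------------------------------------------------------------

@dataclass
class AmpliconSimConfig:
    """Study conditions for the synthetic ASV table.

    Contaminant ASVs are shared across controls and specimens at high pooled
    proportion and prevalence; genuine ASVs are sparse, specimen-restricted
    and absent from controls; batch-artifact ASVs appear in specimens of a
    single batch only. ``contaminant_mean_proportion`` must exceed
    ``genuine_mean_proportion`` — the separation the Step-1/2 thresholds
    exploit.
    """

    n_tumor_samples: int = 40
    n_control_samples: int = 12
    n_batches: int = 2
    plate_shape: tuple[int, int] = (8, 12)
    n_contaminant_asvs: int = 30
    n_genuine_asvs: int = 20
    n_batch_artifact_asvs: int = 4
    contaminant_mean_proportion: float = 0.02
    genuine_mean_proportion: float = 0.001
    library_size: int = 50_000
    seed: int = 0
    #: fraction of tumor specimens carrying each genuine ASV
    genuine_prevalence: float = 0.1
    #: control-only low-level noise ASVs giving the control curves their tail
    n_noise_asvs: int = 40

    def __post_init__(self) -> None:
        _require(self.n_tumor_samples >= 1, "n_tumor_samples", "must be >= 1")
        _require(self.n_control_samples >= 1, "n_control_samples", "must be >= 1")
        _require(self.n_batches >= 1, "n_batches", "must be >= 1")
        _require(self.library_size >= 1, "library_size", "must be >= 1")
        for f in ("n_contaminant_asvs", "n_genuine_asvs", "n_batch_artifact_asvs", "n_noise_asvs"):
            _require(getattr(self, f) >= 0, f, "must be >= 0")
        for f in ("contaminant_mean_proportion", "genuine_mean_proportion", "genuine_prevalence"):
            _require(0.0 < getattr(self, f) < 1.0, f, "must lie in (0, 1)")
        _require(
            self.contaminant_mean_proportion > self.genuine_mean_proportion,
            "contaminant_mean_proportion",
            "must exceed genuine_mean_proportion",
        )
        rows, cols = self.plate_shape
        per_batch = -(-(self.n_tumor_samples + self.n_control_samples) // self.n_batches)
        _require(rows * cols >= per_batch, "plate_shape", "plate too small for samples per batch")


def simulate_asv_table(cfg: AmpliconSimConfig) -> tuple[AsvTable, pd.DataFrame]:
    """Generate an ASV table plus the ground-truth class sidecar.

    Returns ``(table, truth)`` where ``truth`` has one row per ASV with its
    ``truth_class`` in {contaminant, genuine, batch_artifact} and a
    ``in_specimens`` flag marking ASVs that actually carry specimen counts
    (control-only contaminants cannot be scored for removal).
    """
    rng = np.random.default_rng(cfg.seed)

    cont = [f"CONT_{i:03d}" for i in range(cfg.n_contaminant_asvs)]
    gen = [f"GEN_{i:03d}" for i in range(cfg.n_genuine_asvs)]
    bart = [f"BART_{i:03d}" for i in range(cfg.n_batch_artifact_asvs)]
    noise = [f"NOISE_{i:03d}" for i in range(cfg.n_noise_asvs)]
    asvs = cont + gen + bart + noise

    genus = {}
    for i, a in enumerate(cont):
        genus[a] = f"ContGenus_{i // 3}"  # ~3 ASVs per contaminant genus
    for i, a in enumerate(gen):
        genus[a] = f"GenuineGenus_{i}"
    for i, a in enumerate(bart):
        genus[a] = f"BatchGenus_{i}"
    for i, a in enumerate(noise):
        genus[a] = f"NoiseGenus_{i}"

    samples = [f"T{i:03d}" for i in range(cfg.n_tumor_samples)] + [
        f"C{i:03d}" for i in range(cfg.n_control_samples)
    ]
    is_control = [False] * cfg.n_tumor_samples + [True] * cfg.n_control_samples
    batches = [i % cfg.n_batches for i in range(len(samples))]

    # plate wells row-major per batch, controls interleaved with specimens
    rows_, cols_ = cfg.plate_shape
    meta = pd.DataFrame(
        {"batch": batches, "is_control": is_control, "cohort": "synthetic"},
        index=pd.Index(samples, name="sample_id"),
    )
    meta["well_row"] = 0
    meta["well_col"] = 0
    for b in range(cfg.n_batches):
        ids = meta.index[meta["batch"] == b]
        ctrls = [s for s in ids if meta.loc[s, "is_control"]]
        specs = [s for s in ids if not meta.loc[s, "is_control"]]
        interleaved: list[str] = []
        ci = si = 0
        stride = max(len(specs) // (len(ctrls) + 1), 1) if ctrls else len(specs)
        while si < len(specs) or ci < len(ctrls):
            take = specs[si : si + stride]
            interleaved.extend(take)
            si += len(take)
            if ci < len(ctrls):
                interleaved.append(ctrls[ci])
                ci += 1
        for pos, s in enumerate(interleaved):
            meta.loc[s, "well_row"] = pos // cols_
            meta.loc[s, "well_col"] = pos % cols_

    # genuine carriers stratified across batches so a genuine taxon is never
    # batch-exclusive by sampling accident (it has no batch association)
    tumor_by_batch: dict[int, list[int]] = {}
    for i in range(cfg.n_tumor_samples):
        tumor_by_batch.setdefault(batches[i], []).append(i)
    n_carriers = max(2, int(round(cfg.genuine_prevalence * cfg.n_tumor_samples)))
    genuine_carriers: dict[str, set[int]] = {}
    for a in gen:
        chosen: list[int] = []
        batch_order = list(tumor_by_batch)
        rng.shuffle(batch_order)
        bi = 0
        pools = {b: rng.permutation(tumor_by_batch[b]).tolist() for b in batch_order}
        while len(chosen) < n_carriers and any(pools.values()):
            b = batch_order[bi % len(batch_order)]
            if pools[b]:
                chosen.append(pools[b].pop())
            bi += 1
        genuine_carriers[a] = set(chosen)
    bart_batch = {a: int(rng.integers(cfg.n_batches)) for a in bart}

    # weights are absolute proportions of the sequencing library; the
    # remainder models reads outside the ASV table (host, unassigned)
    counts = np.zeros((len(samples), len(asvs)), dtype=np.int64)
    col = {a: j for j, a in enumerate(asvs)}
    for i, s in enumerate(samples):
        weights = np.zeros(len(asvs))
        for a in cont:
            weights[col[a]] = rng.gamma(5.0, cfg.contaminant_mean_proportion / 5.0)
        if is_control[i]:
            if noise:
                for a in rng.choice(noise, size=min(3, len(noise)), replace=False):
                    weights[col[a]] = rng.gamma(5.0, cfg.genuine_mean_proportion / 10.0 / 5.0)
        else:
            t_idx = i  # tumor samples come first
            for a in gen:
                if t_idx in genuine_carriers[a]:
                    weights[col[a]] = rng.gamma(5.0, cfg.genuine_mean_proportion / 5.0)
            for a in bart:
                if batches[i] == bart_batch[a] and rng.random() < 0.3:
                    weights[col[a]] = rng.gamma(5.0, cfg.genuine_mean_proportion / 5.0)
        total = weights.sum()
        if total > 1.0:
            weights /= total
            total = 1.0
        draw = rng.multinomial(cfg.library_size, np.append(weights, 1.0 - total))
        counts[i] = draw[:-1]

    table = AsvTable(
        counts=pd.DataFrame(counts, index=meta.index, columns=asvs),
        sample_meta=meta,
        taxonomy=pd.DataFrame(
            {"genus": [genus[a] for a in asvs]}, index=pd.Index(asvs, name="asv_id")
        ),
        library_totals=pd.Series(float(cfg.library_size), index=meta.index),
    )
    truth_class = (
        ["contaminant"] * len(cont)
        + ["genuine"] * len(gen)
        + ["batch_artifact"] * len(bart)
        + ["contaminant"] * len(noise)
    )
    spec_counts = table.counts.loc[table.specimen_ids]
    truth = pd.DataFrame(
        {
            "truth_class": truth_class,
            "genus": [genus[a] for a in asvs],
            "in_specimens": (spec_counts.sum(axis=0) > 0).values,
        },
        index=pd.Index(asvs, name="asv_id"),
    )
    return table, truth


def score_filtration(
    truth: pd.DataFrame, before: AsvTable, after: AsvTable
) -> dict[str, float]:
    """Contaminant-removal sensitivity and genuine-taxon retention vs the sidecar.

    A planted contaminant (or batch artifact) counts as removed when it
    retains no specimen counts after filtration; only ASVs that carried
    specimen counts before filtration are scored.
    """
    spec = before.specimen_ids
    present = truth.index[(before.counts.loc[spec].sum(axis=0) > 0)]
    after_spec = after.counts.loc[spec]
    gone = after_spec.sum(axis=0) == 0
    contaminants = [
        a for a in present if truth.loc[a, "truth_class"] in ("contaminant", "batch_artifact")
    ]
    genuine = [a for a in present if truth.loc[a, "truth_class"] == "genuine"]
    sensitivity = float(np.mean([gone[a] for a in contaminants])) if contaminants else float("nan")
    retention = float(np.mean([~gone[a] for a in genuine])) if genuine else float("nan")
    return {"contaminant_removal_sensitivity": sensitivity, "genuine_retention": retention}


# ---------------------------------------------------------------------------
# Spatial transcript cloud
# ---------------------------------------------------------------------------

@dataclass
class SpatialSimConfig:
    """Study conditions for the synthetic spatial transcript cloud.

    Cells are non-overlapping disks inside each FOV; host transcripts and
    negative probes scatter uniformly within cells; planted positive cells
    receive bacterial transcripts concentrated near the centroid (so the
    central-50% criterion holds by construction); extracellular bacterial
    transcripts scatter uniformly outside every cell.
    """

    n_fovs: int = 4
    fov_pixels: int = 4256
    pixel_size_um: float = 0.12
    cells_per_fov: int = 80
    cell_radius_um: float = 8.0
    host_transcripts_per_cell: float = 100.0
    n_planted_positive_cells: int = 30
    bacterial_counts_in_positive: float = 30.0
    extracellular_bacterial_rate: float = 2e-4  # transcripts / µm²
    negprobe_rate: float = 0.01  # fraction of the host transcript rate
    z_depth_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_fovs >= 1, "n_fovs", "must be >= 1")
        _require(self.fov_pixels >= 1, "fov_pixels", "must be >= 1")
        _require(self.pixel_size_um > 0, "pixel_size_um", "must be > 0")
        _require(self.cells_per_fov >= 1, "cells_per_fov", "must be >= 1")
        _require(self.cell_radius_um > 0, "cell_radius_um", "must be > 0")
        _require(
            self.n_planted_positive_cells <= self.n_fovs * self.cells_per_fov,
            "n_planted_positive_cells",
            "cannot exceed the total number of cells",
        )
        for f in ("host_transcripts_per_cell", "extracellular_bacterial_rate", "negprobe_rate"):
            _require(getattr(self, f) >= 0, f, "must be >= 0")

    @property
    def geometry(self) -> FovGeometry:
        return FovGeometry(self.fov_pixels, self.pixel_size_um)


CELL_TYPES = ["tumor", "astrocyte", "neuron", "myeloid", "lymphoid"]


def simulate_transcript_cloud(
    cfg: SpatialSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (transcripts, cells, truth) tables.

    Transcript rows: target, probe_class, x_um, y_um, z_um, fov, cell_id
    (NaN for extracellular). Cell rows: cell_id, fov, centroid, area,
    cell_type, is_tumor, total_counts. Truth rows: cell_id, planted flag and
    the planted bacterial count.
    """
    rng = np.random.default_rng(cfg.seed)
    edge = cfg.geometry.edge_um
    r = cfg.cell_radius_um

    cell_rows = []
    transcript_rows = []
    all_centers: dict[int, np.ndarray] = {}
    cell_ids: list[str] = []
    for fov in range(cfg.n_fovs):
        centers = _pack_disks(rng, cfg.cells_per_fov, r, edge)
        all_centers[fov] = centers
        for i, (cx, cy) in enumerate(centers):
            cid = f"f{fov}_c{i:03d}"
            cell_ids.append(cid)
            ctype = CELL_TYPES[rng.integers(len(CELL_TYPES))] if rng.random() > 0.5 else "tumor"
            cell_rows.append(
                {
                    "cell_id": cid,
                    "fov": fov,
                    "x_um": cx,
                    "y_um": cy,
                    "area_um2": np.pi * r * r,
                    "cell_type": ctype,
                    "is_tumor": ctype == "tumor",
                }
            )

    planted = rng.choice(len(cell_ids), size=cfg.n_planted_positive_cells, replace=False)
    planted_ids = {cell_ids[i] for i in planted}
    planted_counts: dict[str, int] = {}

    for row in cell_rows:
        cid, fov = row["cell_id"], row["fov"]
        cx, cy = row["x_um"], row["y_um"]
        n_host = rng.poisson(cfg.host_transcripts_per_cell)
        n_neg = rng.poisson(cfg.negprobe_rate * cfg.host_transcripts_per_cell)
        for _ in range(max(n_host, 4)):  # every cell passes the >=4-transcript floor
            x, y = _uniform_in_disk(rng, cx, cy, r)
            transcript_rows.append(
                ("HOST_GENE", "host", x, y, rng.uniform(0, cfg.z_depth_um), fov, cid)
            )
        for _ in range(n_neg):
            x, y = _uniform_in_disk(rng, cx, cy, r)
            cls = "negprobe_host" if rng.random() < 0.5 else "negprobe_bact"
            transcript_rows.append(
                ("NegPrb", cls, x, y, rng.uniform(0, cfg.z_depth_um), fov, cid)
            )
        if cid in planted_ids:
            n_bact = max(1, rng.poisson(cfg.bacterial_counts_in_positive))
            planted_counts[cid] = n_bact
            for _ in range(n_bact):
                # tight cluster at the centroid keeps the median inside the IQR
                x = cx + rng.normal(0, r / 8)
                y = cy + rng.normal(0, r / 8)
                z = cfg.z_depth_um / 2 + rng.normal(0, cfg.z_depth_um / 16)
                transcript_rows.append(("BACT_16S", "bacterial", x, y, z, fov, cid))

    # extracellular bacterial transcripts, uniform outside every cell
    for fov in range(cfg.n_fovs):
        cell_area = cfg.cells_per_fov * np.pi * r * r
        extra_area = edge * edge - cell_area
        n_extra = rng.poisson(cfg.extracellular_bacterial_rate * extra_area)
        centers = all_centers[fov]
        placed = 0
        attempts = 0
        while placed < n_extra and attempts < 100 * max(n_extra, 1):
            attempts += 1
            x, y = rng.uniform(0, edge, size=2)
            if centers.size and np.min(np.hypot(centers[:, 0] - x, centers[:, 1] - y)) <= r:
                continue
            transcript_rows.append(
                ("BACT_16S", "bacterial", x, y, rng.uniform(0, cfg.z_depth_um), fov, None)
            )
            placed += 1

    transcripts = pd.DataFrame(
        transcript_rows,
        columns=["target", "probe_class", "x_um", "y_um", "z_um", "fov", "cell_id"],
    )
    cells = pd.DataFrame(cell_rows)
    totals = transcripts[transcripts["cell_id"].notna()].groupby("cell_id").size()
    cells["total_counts"] = totals.reindex(cells["cell_id"], fill_value=0).values
    truth = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "planted_positive": cells["cell_id"].isin(planted_ids).values,
            "n_bacterial_planted": [planted_counts.get(c, 0) for c in cells["cell_id"]],
        }
    )
    return transcripts, cells, truth


def _pack_disks(rng: np.random.Generator, n: int, r: float, edge: float) -> np.ndarray:
    """Place n non-overlapping disk centers by rejection sampling."""
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * n
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"could not place {n} cells of radius {r} µm in a {edge:.0f} µm FOV"
            )
        x = rng.uniform(r, edge - r)
        y = rng.uniform(r, edge - r)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= (2 * r) ** 2 for cx, cy in centers):
            centers.append((x, y))
    return np.asarray(centers)


def _uniform_in_disk(rng: np.random.Generator, cx: float, cy: float, r: float) -> tuple[float, float]:
    rho = r * np.sqrt(rng.random())
    theta = rng.uniform(0, 2 * np.pi)
    return cx + rho * np.cos(theta), cy + rho * np.sin(theta)


# ---------------------------------------------------------------------------
# Shotgun read-hit table
# ---------------------------------------------------------------------------

@dataclass
class ShotgunSimConfig:
    """Study conditions for the synthetic read–genome hit table.

    Genomes carry distinct genus/species labels (two species per genus so
    congeneric ambiguity exists). Reads are sampled with substitutions from a
    known subset of clean genomes; contaminant genomes are flagged as
    MAG-derived or assembly-anomalous. A fraction of reads is engineered to
    tie across two genera (low-informativity truth label).
    """

    n_genomes: int = 10
    genome_length: int = 5_000
    n_reads: int = 60
    read_length_range: tuple[int, int] = (120, 300)
    substitution_rate: float = 0.02
    n_contaminant_genomes: int = 2
    ambiguous_read_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genomes >= 1, "n_genomes", "must be >= 1")
        _require(self.genome_length >= 1, "genome_length", "must be >= 1")
        _require(self.n_reads >= 1, "n_reads", "must be >= 1")
        lo, hi = self.read_length_range
        _require(1 <= lo <= hi, "read_length_range", "must be a valid interval")
        _require(hi <= self.genome_length, "read_length_range", "read lengths must not exceed genome_length")
        _require(0.0 <= self.substitution_rate <= 0.2, "substitution_rate", "must lie in [0, 0.2]")
        _require(
            0 <= self.n_contaminant_genomes < self.n_genomes,
            "n_contaminant_genomes",
            "must leave at least one clean genome",
        )
        _require(0.0 <= self.ambiguous_read_fraction <= 1.0, "ambiguous_read_fraction", "must lie in [0, 1]")


BASES = np.array(list("ACGT"))


def simulate_read_hits(
    cfg: ShotgunSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Generate (hits, truth, genomes).

    ``hits`` is a read–genome alignment table (read_id, accession, genus,
    species, pident, length, bitscore, sstart, send, is_mag,
    assembly_anomaly); ``truth`` records each read's source genome and its
    low-informativity label; ``genomes`` maps accession to sequence.
    """
    rng = np.random.default_rng(cfg.seed)
    accs = [f"ACC_{i:03d}" for i in range(cfg.n_genomes)]
    genus = {a: f"Genus_{i // 2}" for i, a in enumerate(accs)}
    species = {a: f"Genus_{i // 2} species_{i}" for i, a in enumerate(accs)}
    genomes = {
        a: "".join(rng.choice(BASES, size=cfg.genome_length)) for a in accs
    }
    contaminants = set(accs[cfg.n_genomes - cfg.n_contaminant_genomes :]) if cfg.n_contaminant_genomes else set()
    # flags are genome properties; alternate the two flag kinds deterministically
    flag_mag = {a: (a in contaminants and i % 2 == 0) for i, a in enumerate(accs)}
    flag_anom = {a: (a in contaminants and i % 2 == 1) for i, a in enumerate(accs)}
    clean = [a for a in accs if a not in contaminants]
    sources = clean[: max(1, len(clean) // 2 + 1)]

    hit_rows = []
    truth_rows = []
    for i in range(cfg.n_reads):
        rid = f"read_{i:04d}"
        src = sources[rng.integers(len(sources))]
        length = int(rng.integers(cfg.read_length_range[0], cfg.read_length_range[1] + 1))
        start = int(rng.integers(0, cfg.genome_length - length + 1))
        n_sub = rng.binomial(length, cfg.substitution_rate)
        matches = length - n_sub
        pident = 100.0 * matches / length
        bitscore = 2.0 * matches - 3.0 * n_sub
        ambiguous = rng.random() < cfg.ambiguous_read_fraction and cfg.n_genomes > 2

        def add_hit(acc, pid, score, s=start, ln=length):
            hit_rows.append(
                {
                    "read_id": rid,
                    "accession": acc,
                    "genus": genus[acc],
                    "species": species[acc],
                    "pident": pid,
                    "length": ln,
                    "bitscore": score,
                    "sstart": s,
                    "send": s + ln,
                    "is_mag": flag_mag[acc],
                    "assembly_anomaly": flag_anom[acc],
                }
            )

        add_hit(src, pident, bitscore)
        if ambiguous:
            # an equal-score hit to a genome of a different genus
            others = [a for a in accs if genus[a] != genus[src]]
            add_hit(others[rng.integers(len(others))], pident, bitscore)
        elif cfg.n_genomes > 1 and rng.random() < 0.3:
            # a clearly secondary hit (lower score) somewhere else
            others = [a for a in accs if a != src]
            other = others[rng.integers(len(others))]
            add_hit(other, max(90.0, pident - 4.0), bitscore * 0.7)
        truth_rows.append(
            {"read_id": rid, "source_accession": src, "low_informativity": bool(ambiguous)}
        )

    hits = pd.DataFrame(hit_rows)
    truth = pd.DataFrame(truth_rows)
    return hits, truth, genomes


# ---------------------------------------------------------------------------
# DSP ROI matrix
# ---------------------------------------------------------------------------

def simulate_dsp_matrix(
    n_rois: int = 24,
    n_targets: int = 100,
    n_negprobes: int = 8,
    n_16s_probes: int = 4,
    n_igg: int = 3,
    seed: int = 0,
) -> RoiMatrix:
    """Log-normal counts per ROI with a negative-probe floor and a 16S probe set.

    Analyte targets draw from a log-normal centered well above the
    negative-probe location; half the ROIs carry an elevated 16S level so the
    quartile annotation has structure; QC columns are populated to pass the
    default gates.
    """
    for name, v in (("n_rois", n_rois), ("n_targets", n_targets), ("n_negprobes", n_negprobes)):
        _require(v >= 1, name, "must be >= 1")
    rng = np.random.default_rng(seed)
    rois = [f"ROI_{i:03d}" for i in range(n_rois)]

    size = np.exp(rng.normal(0.0, 0.25, size=n_rois))  # ROI depth factors
    base = np.exp(rng.normal(np.log(100.0), 0.8, size=n_targets))
    analyte = rng.poisson(np.outer(base, size))
    neg = rng.poisson(np.outer(np.full(n_negprobes, 5.0), size))
    high_roi = rng.permutation(n_rois) < n_rois // 2
    s16_level = np.where(high_roi, 60.0, 6.0)
    s16 = rng.poisson(np.outer(np.full(n_16s_probes, 1.0), s16_level * size))
    igg = rng.poisson(np.outer(np.full(n_igg, 10.0), size))

    counts = np.vstack([analyte, neg, s16, igg])
    index = (
        [f"GENE_{i:04d}" for i in range(n_targets)]
        + [f"NegPrb_{i:02d}" for i in range(n_negprobes)]
        + [f"BACT16S_{i}" for i in range(n_16s_probes)]
        + [f"IgG_{i}" for i in range(n_igg)]
    )
    probe_class = pd.Series(
        ["analyte"] * n_targets
        + ["negprobe"] * n_negprobes
        + ["bact16s"] * n_16s_probes
        + ["igg"] * n_igg,
        index=index,
    )
    cdf = pd.DataFrame(counts, index=index, columns=rois)
    qc = pd.DataFrame(
        {
            "aligned_frac": rng.uniform(0.85, 0.99, size=n_rois),
            "saturation": rng.uniform(0.55, 0.95, size=n_rois),
            "total_reads": cdf.sum(axis=0).values,
        },
        index=rois,
    )
    return RoiMatrix(cdf, probe_class, qc)
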