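"""Plain-text readers and writers for every pipeline table.

Conventions follow the field's flat-file habits: ASV counts as a TSV with
ASVs as rows and samples as columns, sample metadata and taxonomy as TSVs
keyed on their ids, spatial tables as CSVs, hit tables as TSVs, and FASTA for
sequences. Round-trips are lossless for the dtypes the pipeline uses.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .amplicon import AsvTable
from .dsp import RoiMatrix


def write_asv_table(table: AsvTable, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.counts.T.to_csv(outdir / "counts.tsv", sep="\t", index_label="asv_id")
    table.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t", index_label="sample_id")
    table.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index_label="asv_id")


def read_asv_table(indir) -> AsvTable:
    indir = Path(indir)
    counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col="asv_id").T
    counts.index.name = "sample_id"
    counts.columns.name = None
    meta = pd.read_csv(indir / "sample_meta.tsv", sep="\t", index_col="sample_id")
    tax = pd.read_csv(indir / "taxonomy.tsv", sep="\t", index_col="asv_id")
    return AsvTable(counts, meta, tax)


def write_transcripts(transcripts: pd.DataFrame, path) -> None:
    transcripts.to_csv(path, index=False)


def read_transcripts(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"cell_id": "object"})


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"cell_id": "object"})


def write_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_hits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_roi_matrix(m: RoiMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = m.counts.copy()
    counts.insert(0, "probe_class", m.probe_class.values)
    counts.to_csv(outdir / "dsp_counts.tsv", sep="\t", index_label="target")
    m.roi_qc.to_csv(outdir / "roi_qc.tsv", sep="\t", index_label="roi_id")


def read_roi_matrix(indir) -> RoiMatrix:
    indir = Path(indir)
    raw = pd.read_csv(indir / "dsp_counts.tsv", sep="\t", index_col="target")
    raw.index.name = None
    probe_class = raw.pop("probe_class")
    qc = pd.read_csv(indir / "roi_qc.tsv", sep="\t", index_col="roi_id")
    return RoiMatrix(raw, probe_class, qc)


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
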