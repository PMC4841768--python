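"""Readers and writers for the plain-text formats the pipeline consumes.

Tabular formats are TSV throughout.  Genomic formats follow the usual
conventions: BED is 0-based half-open; BED6 tag records place the tag at
``start`` for + strand reads and ``end - 1`` for - strand reads; bedGraph
tracks are written in fixed bin-size steps.  FASTA goes through Biopython,
JASPAR motif files through Bio.motifs, and mzML through pyteomics behind
the same reader contract as the TSV scan table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

from .chip_signal import PWM, SignalTrack, TagSet
from .expression import ExpressionMatrix
from .interactome import IntensityTable
from .ptm_quant import MS1Run, ModifiedPeptide, Scan

__all__ = [
    "read_ms1_tsv",
    "write_ms1_tsv",
    "read_mzml",
    "read_isoform_table",
    "write_isoform_table",
    "write_stoichiometry",
    "read_lfq_table",
    "read_sample_metadata",
    "read_peptide_table",
    "read_chrom_sizes",
    "read_bed_tags",
    "write_bed_tags",
    "read_bed_peaks",
    "write_bed_peaks",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_jaspar_pwm",
    "read_expression_matrix",
    "write_expression_matrix",
]


# -- mass spectrometry ------------------------------------------------------

def read_ms1_tsv(path: str | Path) -> MS1Run:
    """MS1 scan table with columns ``scan_rt, mz, intensity`` (one centroid per row)."""
    df = pd.read_csv(path, sep="\t")
    scans = [
        Scan(float(rt), grp["mz"].to_numpy(), grp["intensity"].to_numpy())
        for rt, grp in df.groupby("scan_rt", sort=True)
    ]
    return MS1Run(scans)


def write_ms1_tsv(run: MS1Run, path: str | Path) -> None:
    rows = [
        {"scan_rt": s.rt, "mz": mz, "intensity": it}
        for s in run.scans
        for mz, it in zip(s.mz, s.intensity)
    ]
    pd.DataFrame(rows, columns=["scan_rt", "mz", "intensity"]).to_csv(path, sep="\t", index=False)


def read_mzml(path: str | Path) -> MS1Run:
    """MS1 survey scans from an mzML run file (MS level 1 spectra only).

    A compact reader for centroided mzML: binary arrays may be 32- or
    64-bit floats, optionally zlib-compressed; retention times in seconds
    are converted to minutes.
    """
    import base64
    import xml.etree.ElementTree as ET
    import zlib

    ns = {"mz": "http://psi.hupo.org/ms/mzml"}

    def decode(bda):
        cvs = {cv.get("accession"): cv for cv in bda.findall("mz:cvParam", ns)}
        raw = base64.b64decode(bda.findtext("mz:binary", "", ns))
        if "MS:1000574" in cvs:  # zlib compression
            raw = zlib.decompress(raw)
        dtype = np.float32 if "MS:1000521" in cvs else np.float64
        return np.frombuffer(raw, dtype=dtype).astype(float), cvs

    scans = []
    tree = ET.parse(str(path))
    for spectrum in tree.iter(f"{{{ns['mz']}}}spectrum"):
        cvs = {cv.get("accession"): cv for cv in spectrum.findall("mz:cvParam", ns)}
        level = cvs.get("MS:1000511")
        if level is not None and level.get("value") != "1":
            continue
        scan_elem = spectrum.find("mz:scanList/mz:scan", ns)
        rt = 0.0
        for cv in scan_elem.findall("mz:cvParam", ns):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    rt /= 60.0
        mz_arr = inten_arr = None
        for bda in spectrum.findall("mz:binaryDataArrayList/mz:binaryDataArray", ns):
            values, bda_cvs = decode(bda)
            if "MS:1000514" in bda_cvs:
                mz_arr = values
            elif "MS:1000515" in bda_cvs:
                inten_arr = values
        if mz_arr is None or inten_arr is None:
            raise ValueError(f"spectrum {spectrum.get('id')!r} lacks m/z or intensity array")
        scans.append(Scan(rt, mz_arr, inten_arr))
    scans.sort(key=lambda s: s.rt)
    return MS1Run(scans)


def _parse_mods(spec: str) -> tuple[tuple[int, str], ...]:
    if not spec or spec in (".", "-"):
        return ()
    return tuple(
        (int(part.split(":")[0]), part.split(":")[1]) for part in spec.split(";")
    )


def read_isoform_table(path: str | Path) -> tuple[list[ModifiedPeptide], dict[str, tuple[float, float]]]:
    """Isoform definition TSV: label, sequence, mods, charges, rt_start, rt_end.

    ``mods`` is ``site:kind`` pairs joined by ``;`` (0-based sites), ``.``
    for none; ``charges`` is ``;``-separated.  Returns the peptide list (one
    per label x charge) and the retention-time window per label.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    peptides = []
    windows = {}
    for row in df.itertuples(index=False):
        mods = _parse_mods(row.mods)
        for z in str(row.charges).split(";"):
            peptides.append(ModifiedPeptide(row.sequence, mods, charge=int(z), label=row.label))
        windows[row.label] = (float(row.rt_start), float(row.rt_end))
    return peptides, windows


def write_isoform_table(
    peptides: list[ModifiedPeptide],
    windows: Mapping[str, tuple[float, float]],
    path: str | Path,
) -> None:
    rows = {}
    for p in peptides:
        entry = rows.setdefault(
            p.label,
            {
                "label": p.label,
                "sequence": p.sequence,
                "mods": ";".join(f"{i}:{k}" for i, k in p.modifications) or ".",
                "charges": [],
                "rt_start": windows[p.label][0],
                "rt_end": windows[p.label][1],
            },
        )
        entry["charges"].append(str(p.charge))
    out = pd.DataFrame(
        [{**r, "charges": ";".join(r["charges"])} for r in rows.values()],
        columns=["label", "sequence", "mods", "charges", "rt_start", "rt_end"],
    )
    out.to_csv(path, sep="\t", index=False)


def write_stoichiometry(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# -- AP-MS tables -----------------------------------------------------------

def read_lfq_table(path: str | Path, metadata_path: str | Path) -> IntensityTable:
    """Protein LFQ TSV (``protein`` column + one column per sample) plus metadata."""
    intens = pd.read_csv(path, sep="\t", index_col="protein")
    meta = read_sample_metadata(metadata_path)
    return IntensityTable(intens, meta)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with columns ``sample, tag, replicate``."""
    return pd.read_csv(path, sep="\t", index_col="sample")


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Peptide TSV: protein, peptide, start, homologous + sample columns."""
    df = pd.read_csv(path, sep="\t")
    df["homologous"] = df["homologous"].astype(bool)
    return df


# -- genomics ---------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_bed_tags(path: str | Path, chrom_sizes: dict[str, int]) -> TagSet:
    """Aligned tags from BED6; tag position is the 5' end per strand."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    pos = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    tags = pd.DataFrame({"chrom": df["chrom"], "pos": pos, "strand": df["strand"]})
    return TagSet(tags, chrom_sizes)


def write_bed_tags(tags: TagSet, path: str | Path, read_length: int = 1) -> None:
    df = tags.tags
    start = np.where(df["strand"] == "+", df["pos"], df["pos"] - read_length + 1)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": np.clip(start, 0, None),
            "end": np.clip(start, 0, None) + read_length,
            "name": ".",
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed_peaks(path: str | Path) -> pd.DataFrame:
    """Peak intervals from BED3+ (extra columns beyond the first six ignored)."""
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, : min(df.shape[1], 6)]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    out = df[["chrom", "start", "end"]].copy()
    if "score" in df.columns:
        out["score"] = pd.to_numeric(df["score"], errors="coerce")
    return out


def write_bed_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    out = peaks[["chrom", "start", "end"]].copy()
    if "score" in peaks.columns:
        out["name"] = "."
        out["score"] = peaks["score"]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: SignalTrack, path: str | Path, skip_zero: bool = False) -> None:
    """SignalTrack as bedGraph in fixed bin-size steps."""
    with open(path, "w") as fh:
        for chrom in track.chrom_sizes:
            values = track.data[chrom]
            size = track.chrom_sizes[chrom]
            for i, v in enumerate(values):
                if skip_zero and v == 0:
                    continue
                start = i * track.bin_size
                end = min(start + track.bin_size, size)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_jaspar_pwm(path: str | Path, background: np.ndarray | None = None) -> PWM:
    """A PWM from a JASPAR-format text file (counts converted to log2-odds)."""
    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([list(motif.counts[b]) for b in "ACGT"], dtype=float)
    return PWM.from_counts(counts, background=background)


# -- expression -------------------------------------------------------------

def read_expression_matrix(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Expression TSV (``gene`` column + sample columns) plus sample metadata
    TSV with columns ``sample, condition, pair``."""
    values = pd.read_csv(path, sep="\t", index_col="gene")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    return ExpressionMatrix(values, meta)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t")
    matrix.metadata.to_csv(metadata_path, sep="\t")
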