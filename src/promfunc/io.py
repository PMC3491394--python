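"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Bio.SeqIO; peaks and sites are BED-like tab tables;
conservation tracks are bedGraph; luminosity tables, consensus libraries
and evaluation reports are TSV via pandas.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif_core import PWM, ScoredSite, build_pwm


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {name: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- PWM text

def read_pwm_jaspar(path_or_text, name: str | None = None, pseudocount: float = 0.0) -> PWM:
    """Read a JASPAR-format PWM (4 labeled rows A/C/G/T) via Bio.motifs."""
    if isinstance(path_or_text, (str, Path)) and Path(str(path_or_text)).exists():
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = str(path_or_text)
    m = motifs.read(_io.StringIO(text), "jaspar")
    counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
    return build_pwm(counts, pseudocount=pseudocount, name=name or m.name or "pwm")


def read_pwm_matrix(path, name: str | None = None, pseudocount: float = 0.0) -> PWM:
    """Read a TRANSFAC-like plain matrix: W whitespace-separated rows x 4 columns (A C G T)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ">", "P0", "XX", "//")):
                continue
            fields = line.split()
            # tolerate a leading position index column
            if len(fields) == 5:
                fields = fields[1:]
            rows.append([float(x) for x in fields[:4]])
    return build_pwm(np.array(rows), pseudocount=pseudocount, name=name or Path(path).stem)


def write_pwm_frequencies(pwm: PWM, path) -> None:
    """Export position frequencies as TSV (pos, A, C, G, T) for logo tools."""
    df = pd.DataFrame(pwm.frequencies, columns=list("ACGT"))
    df.insert(0, "pos", np.arange(1, pwm.width + 1))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- BED

def write_sites_bed(sites: list[ScoredSite], path) -> None:
    """Emit sites as BED6: score column = bits x 100, rounded."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.tf}\t{int(round(s.score * 100))}\t{s.strand}\n"
            )


def read_sites_bed(path) -> list[ScoredSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.split()[:6]
            sites.append(
                ScoredSite(chrom, int(start), int(end), strand, float(score) / 100.0, name)
            )
    return sites


def write_peaks_bed(peaks, path) -> None:
    """Peaks as BED+: chrom start end name score strand summit_offset peak_fdr."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t0\t.\t{p.summit}\t{p.peak_fdr!r}\n"
            )


def read_peaks_bed(path):
    """Read peaks; accepts summit offset in column 7, or narrowPeak-style column 10."""
    from .site_prediction import PeakRegion

    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if len(f) >= 10:  # narrowPeak: qvalue col 9 (-log10), summit col 10
                summit = int(f[9])
                fdr = 10 ** (-float(f[8])) if float(f[8]) >= 0 else 1.0
            else:
                summit = int(f[6])
                fdr = float(f[7])
            peaks.append(PeakRegion(chrom, start, end, summit, fdr))
    return peaks


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(tracks: dict[str, np.ndarray], path) -> None:
    """Per-base conservation tracks as bedGraph (one line per base run)."""
    with open(path, "w") as fh:
        for chrom, values in tracks.items():
            values = np.asarray(values, dtype=float)
            # run-length encode consecutive equal values
            start = 0
            for i in range(1, len(values) + 1):
                if i == len(values) or values[i] != values[start]:
                    fh.write(f"{chrom}\t{start}\t{i}\t{values[start]:.6g}\n")
                    start = i


def read_bedgraph(path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    tracks = {c: np.zeros(n) for c, n in lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            tracks[chrom][int(start) : int(end)] = float(value)
    return tracks


# ---------------------------------------------------------------- TSV tables

def read_luminosity_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_luminosity_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_consensus_library(path) -> list[tuple[str, str]]:
    """2-column TSV (tf, IUPAC pattern)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tf", "pattern"], comment="#")
    return list(df.itertuples(index=False, name=None))


def write_consensus_library(entries: list[tuple[str, str]], path) -> None:
    pd.DataFrame(entries, columns=["tf", "pattern"]).to_csv(
        path, sep="\t", index=False, header=False
    )
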