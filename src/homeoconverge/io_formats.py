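"""Standard-format I/O and internal table conventions.

All internal coordinates are 0-based half-open; conversions happen only at
format boundaries (GFF3 is 1-based inclusive on disk, BED is already 0-based
half-open).  Output tables are TSV with one header line and a deterministic
row order so that reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

log = logging.getLogger("homeoconverge")

GENOME_LABELS = ("Ar", "Co", "An", "Cn")
MARKS = ("H3K4me3", "H3K4me1", "H3K27me3", "H3K9me2", "ACR")
#: marks included in Class I/II/III summary tables (H3K9me2 is processed but
#: excluded from class proportions by default)
CLASS_MARKS = ("H3K4me3", "H3K4me1", "H3K27me3", "ACR")
#: homoeologous pair axes: diploid-vs-tetraploid and within-ploidy
PAIRS = ("Ar-An", "Co-Cn", "Ar-Co", "An-Cn")

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GenomeAssembly:
    """One (sub)genome: label in {Ar, Co, An, Cn} plus its chromosomes."""

    label: str
    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class GeneModel:
    """A gene with its transcription start site.

    ``span`` is the 0-based half-open genomic interval of the gene feature;
    ``tss`` is the span start on '+' and span end - 1 on '-'.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: tuple[int, int]


@dataclass
class Peak:
    """A typed epigenomic interval (histone mark or ACR)."""

    chrom: str
    start: int
    end: int
    mark: str
    score: float = 0.0

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def read_fasta(path: str | Path, label: str | None = None) -> GenomeAssembly:
    """Read a genome FASTA into an assembly, case-normalised to uppercase.

    Raises :class:`FormatError` on an empty file, duplicate record names or
    non-ACGTN characters.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-ACGTN characters {sorted(bad)}")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeAssembly(label=label or path.stem, sequences=sequences)


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_gff3(path: str | Path, assembly: GenomeAssembly) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open;
    the TSS is the span start on the '+' strand and span end - 1 on '-'.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.id
        if gene_id in seen:
            raise FormatError(f"{path}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        if feat.seqid not in assembly.sequences:
            raise FormatError(
                f"{path}: gene {gene_id!r} on unknown chromosome {feat.seqid!r}")
        if feat.strand not in ("+", "-"):
            raise FormatError(f"{path}: gene {gene_id!r} has unknown strand {feat.strand!r}")
        start0 = feat.start - 1
        end0 = feat.end
        clen = len(assembly.sequences[feat.seqid])
        if start0 < 0 or end0 > clen or start0 >= end0:
            raise FormatError(
                f"{path}: gene {gene_id!r} span [{start0},{end0}) outside "
                f"chromosome {feat.seqid!r} of length {clen}")
        tss = start0 if feat.strand == "+" else end0 - 1
        genes.append(GeneModel(gene_id=gene_id, chrom=feat.seqid,
                               strand=feat.strand, tss=tss, span=(start0, end0)))
    return genes


def write_gff3(path: str | Path, genes: Iterable[GeneModel], source: str = "homeoconverge") -> None:
    """Write gene features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join([
                g.chrom, source, "gene", str(g.span[0] + 1), str(g.span[1]),
                ".", g.strand, ".", f"ID={g.gene_id}",
            ]) + "\n")


def read_bed_peaks(path: str | Path, mark: str) -> list[Peak]:
    """Read peaks from a BED3+ file (0-based half-open, preserved bit-exact).

    Column 5, when present, becomes the peak score (else 0).
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            score = 0.0
            if len(parts) >= 5 and parts[4] not in (".", ""):
                score = float(parts[4])
            if score < 0:
                raise FormatError(f"{path}:{lineno}: negative peak score {score}")
            peaks.append(Peak(chrom=chrom, start=start, end=end, mark=mark, score=score))
    return peaks


def write_bed_peaks(path: str | Path, peaks: Iterable[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.mark}\t{p.score:g}\t.\n")


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    """Read a gene-level TPM table (columns ``gene_id`` and ``tpm``)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "tpm" not in df.columns:
        raise FormatError(f"{path}: expected columns 'gene_id' and 'tpm'")
    if (df["tpm"] < 0).any():
        raise FormatError(f"{path}: negative TPM values")
    return dict(zip(df["gene_id"].astype(str), df["tpm"].astype(float)))


def write_expression_tsv(path: str | Path, tpm: Mapping[str, float]) -> None:
    df = pd.DataFrame({"gene_id": list(tpm), "tpm": [tpm[g] for g in tpm]})
    df.to_csv(path, sep="\t", index=False)


def write_results(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write result tables as TSV files with deterministic row order.

    Rows are sorted by all of ``tetrad_id``/``pair``/``mark`` columns that are
    present (then by the remaining columns as a stable tiebreak).  Returns a
    map from table name to the written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        df = df.copy()
        sort_cols = [c for c in ("tetrad_id", "pair", "mark", "layer", "gene_id",
                                 "motif_id", "vtype", "position") if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
        dest = outdir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", index=False)
        written[name] = dest
    return written


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def setup_logging(seed: int | None = None, config: Mapping | None = None) -> None:
    """Log to stderr; echo the run seed and configuration once."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    if seed is not None:
        log.info("run seed: %d", seed)
    if config is not None:
        log.info("config: %s", dict(config))
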