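"""Readers, writers and core domain containers.

All genomic coordinates are 0-based half-open (BED convention) internally;
GTF input is converted on read.  Matrices are held dense: the intended data
scales (tens of thousands of features by a few thousand cells) fit
comfortably in memory, and dense arrays keep the SOM training loop simple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "GenomicInterval",
    "GeneAnnotation",
    "PWM",
    "TraitLabels",
    "read_matrix",
    "write_matrix",
    "filter_features",
    "read_bed",
    "read_tss",
    "read_meme_motifs",
    "write_meme_motifs",
]

ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Non-negative signal matrix of features (genes or peaks) by cells."""

    feature_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # (n_features, n_cells), float64
    feature_kind: str = "gene"  # "gene" or "region"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.feature_kind not in ("gene", "region"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if len(self.feature_ids) != len(set(self.feature_ids)):
            raise ValueError("duplicate feature id")
        if len(self.cell_ids) != len(set(self.cell_ids)):
            raise ValueError("duplicate cell id")
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        if len(self.feature_ids) < 2 or len(self.cell_ids) < 2:
            raise ValueError("need at least 2 features and 2 cells")
        if not np.all(np.isfinite(self.values)):
            bad = np.where(~np.isfinite(self.values).all(axis=1))[0][0]
            raise ValueError(f"non-finite value in feature {self.feature_ids[bad]!r}")
        if np.any(self.values < 0):
            bad = np.where((self.values < 0).any(axis=1))[0][0]
            raise ValueError(f"negative value in feature {self.feature_ids[bad]!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def log1p(self) -> "FeatureMatrix":
        """Return a copy with log1p-transformed values."""
        return FeatureMatrix(
            list(self.feature_ids), list(self.cell_ids),
            np.log1p(self.values), self.feature_kind,
        )

    def normalize_cells(self) -> "FeatureMatrix":
        """Scale each cell's column to the mean library size (total-count scaling)."""
        totals = self.values.sum(axis=0)
        target = totals[totals > 0].mean() if np.any(totals > 0) else 1.0
        scale = np.where(totals > 0, target / np.where(totals > 0, totals, 1.0), 1.0)
        return FeatureMatrix(
            list(self.feature_ids), list(self.cell_ids),
            self.values * scale[None, :], self.feature_kind,
        )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int  # 0-based position of the transcription start site
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")


@dataclass
class PWM:
    """Position probability matrix over (A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray  # (L, 4) probabilities

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError(f"PWM {self.motif_id}: matrix must be (L>=1, 4)")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"PWM {self.motif_id}: row does not sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in np.argmax(self.matrix, axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1].copy())


@dataclass
class TraitLabels:
    """Categorical per-cell labels (e.g. timepoint)."""

    cell_ids: list[str]
    trait: list[str]

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.trait):
            raise ValueError("cell_ids and trait must have equal length")
        if len(self.cell_ids) != len(set(self.cell_ids)):
            raise ValueError("duplicate cell id in trait labels")

    @property
    def levels(self) -> list[str]:
        return sorted(set(self.trait))

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.trait))

    def indicator(self, level: str, cell_ids: list[str]) -> np.ndarray:
        """Binary indicator for `level`, ordered to match `cell_ids`."""
        lookup = self.as_dict()
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise ValueError(f"cells missing from trait labels: {missing[:3]}")
        return np.array([1.0 if lookup[c] == level else 0.0 for c in cell_ids])


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def read_matrix(path: str, feature_kind: str = "gene") -> FeatureMatrix:
    """Read a feature-by-cell matrix from TSV (header row of cell ids) or a
    three-column triplet file (feature, cell, value; missing pairs are 0).

    The format is sniffed from the first line: a line with a numeric third
    field and non-numeric second field, or exactly 3 fields where the header
    heuristic fails, is treated as a triplet file; otherwise TSV with header.
    """
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    fields = first.rstrip("\n").split("\t")
    is_triplet = len(fields) == 3 and _is_number(fields[2]) and not _is_number(fields[1])
    if is_triplet:
        return _read_triplet(path, feature_kind)
    return _read_tsv(path, feature_kind)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _read_tsv(path: str, feature_kind: str) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):  # pandas would mangle duplicates
        raise ValueError(f"{path}: duplicate cell id in header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    cells = [str(c) for c in df.columns]
    feats = [str(f) for f in df.index]
    if len(set(feats)) != len(feats):
        raise ValueError(f"{path}: duplicate feature id")
    values = df.to_numpy(dtype=np.float64)
    for i, f in enumerate(feats):
        row = values[i]
        if np.any(~np.isfinite(row)):
            raise ValueError(f"{path}: non-finite value in row {f!r}")
        if np.any(row < 0):
            raise ValueError(f"{path}: negative value in row {f!r}")
    return FeatureMatrix(feats, cells, values, feature_kind)


def _read_triplet(path: str, feature_kind: str) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["feature", "cell", "value"],
                     dtype={"feature": str, "cell": str})
    if df["value"].isna().any() or not np.all(np.isfinite(df["value"])):
        bad = df.loc[~np.isfinite(df["value"].fillna(np.nan)), "feature"].iloc[0]
        raise ValueError(f"{path}: non-finite value in row {bad!r}")
    if (df["value"] < 0).any():
        bad = df.loc[df["value"] < 0, "feature"].iloc[0]
        raise ValueError(f"{path}: negative value in row {bad!r}")
    dup = df.duplicated(subset=["feature", "cell"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValueError(f"{path}: duplicate entry for ({bad['feature']}, {bad['cell']})")
    feats = list(dict.fromkeys(df["feature"]))
    cells = list(dict.fromkeys(df["cell"]))
    fidx = {f: i for i, f in enumerate(feats)}
    cidx = {c: i for i, c in enumerate(cells)}
    values = np.zeros((len(feats), len(cells)))
    values[df["feature"].map(fidx), df["cell"].map(cidx)] = df["value"]
    return FeatureMatrix(feats, cells, values, feature_kind)


def write_matrix(m: FeatureMatrix, path: str) -> None:
    """Write a FeatureMatrix as TSV with a cell-id header row."""
    df = pd.DataFrame(m.values, index=m.feature_ids, columns=m.cell_ids)
    df.index.name = "feature"
    df.to_csv(path, sep="\t")


def filter_features(m: FeatureMatrix, min_value: float,
                    min_cell_fraction: float) -> FeatureMatrix:
    """Retain features strictly exceeding ``min_value`` in at least
    ``ceil(min_cell_fraction * n_cells)`` cells (e.g. ">1 FPKM in 5% of cells").
    """
    if not 0.0 <= min_cell_fraction <= 1.0:
        raise ValueError("min_cell_fraction must be in [0, 1]")
    need = math.ceil(min_cell_fraction * m.n_cells)
    keep = (m.values > min_value).sum(axis=1) >= need
    if not keep.any():
        raise ValueError("filter removed every feature")
    return FeatureMatrix(
        [f for f, k in zip(m.feature_ids, keep) if k],
        list(m.cell_ids),
        m.values[keep],
        m.feature_kind,
    )


# ---------------------------------------------------------------------------
# genomic annotation I/O
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals; a 4th column supplies the id, otherwise
    ids default to ``chrom:start-end``."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) >= 4 and cols[3] not in (".", "") \
                else f"{chrom}:{start}-{end}"
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            out.append(GenomicInterval(chrom, start, end, name))
    return out


def read_tss(path: str) -> list[GeneAnnotation]:
    """Read gene TSS annotation from GTF or a 4-column TSV
    (gene_id, chrom, tss, strand).

    GTF coordinates are 1-based closed; the TSS is the feature start on "+"
    and the feature end on "-", converted to 0-based.  With multiple
    transcript lines per gene the 5'-most TSS is kept.  Exact duplicate
    TSV rows are deduplicated; conflicting duplicates are an error.
    """
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                probe = line
                break
        else:
            raise ValueError(f"{path}: no records")
    if len(probe.rstrip("\n").split("\t")) >= 9:
        return _read_gtf(path)
    return _read_tss_tsv(path)


def _read_gtf(path: str) -> list[GeneAnnotation]:
    # 5'-most TSS per gene across gene/transcript lines
    best: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{ln}: malformed GTF line")
            chrom, _, feature, start, end, _, strand, _, attrs = cols[:9]
            if feature not in ("gene", "transcript", "mRNA"):
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: unknown strand {strand!r}")
            gene_id = _gtf_attr(attrs, "gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{ln}: missing gene_id attribute")
            # GTF is 1-based closed: 0-based TSS is start-1 on +, end-1 on -
            tss = int(start) - 1 if strand == "+" else int(end) - 1
            cur = best.get(gene_id)
            if cur is None:
                best[gene_id] = GeneAnnotation(gene_id, chrom, tss, strand)
            else:
                more_5prime = tss < cur.tss if strand == "+" else tss > cur.tss
                if more_5prime:
                    best[gene_id] = GeneAnnotation(gene_id, chrom, tss, strand)
    return list(best.values())


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key):
            return part[len(key):].strip().strip('"')
    return None


def _read_tss_tsv(path: str) -> list[GeneAnnotation]:
    seen: dict[str, GeneAnnotation] = {}
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns (gene, chrom, tss, strand)")
            gene_id, chrom, tss, strand = cols[0], cols[1], int(cols[2]), cols[3]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: unknown strand {strand!r}")
            rec = GeneAnnotation(gene_id, chrom, tss, strand)
            if gene_id in seen:
                if seen[gene_id] != rec:
                    raise ValueError(f"{path}:{ln}: conflicting records for {gene_id}")
                continue
            seen[gene_id] = rec
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_motifs(path: str) -> list[PWM]:
    """Parse MEME minimal format. Probability rows off from 1 by <=1e-3 are
    renormalized; larger deviations are an error."""
    motifs: list[PWM] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif_{len(motifs)}"
            # advance to the letter-probability header
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise ValueError(f"{path}: MOTIF {motif_id} has no letter-probability matrix")
                i += 1
            if i >= len(lines):
                raise ValueError(f"{path}: MOTIF {motif_id} has no letter-probability matrix")
            i += 1
            rows = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = s.split()
                if len(vals) != 4:
                    raise ValueError(f"{path}: motif {motif_id}: expected 4 columns, got {len(vals)}")
                row = np.array([float(v) for v in vals])
                total = row.sum()
                if abs(total - 1.0) > 1e-3:
                    raise ValueError(
                        f"{path}: motif {motif_id}: probability row sums to {total:.4f}"
                    )
                rows.append(row / total)
                i += 1
            if not rows:
                raise ValueError(f"{path}: motif {motif_id}: empty matrix")
            motifs.append(PWM(motif_id, np.array(rows)))
        else:
            i += 1
    return motifs


def write_meme_motifs(pwms: list[PWM], path: str,
                      background: np.ndarray | None = None) -> None:
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
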