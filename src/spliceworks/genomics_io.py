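"""Genome FASTA / GFF-GTF annotation access and one-hot sequence encoding.

Coordinate conventions
----------------------
Annotation files use 1-based inclusive intervals (GFF/GTF standard); all
internal interval arithmetic in this package is 0-based half-open; BED
output is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "GenomeSequence",
    "Genome",
    "GeneModel",
    "Transcript",
    "parse_annotation",
    "select_canonical",
    "extract_gene_sequence",
    "one_hot_encode",
    "one_hot_decode",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes (and anything else unexpected) normalize to N;
# lowercase is uppercased; RNA U maps to T.
_NORMALIZE = {c: c for c in "ACGTN"}
_NORMALIZE.update({c.lower(): c for c in "ACGTN"})
_NORMALIZE.update({"U": "T", "u": "T"})

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# Byte-level lookup tables used by the vectorized encoders.
_NORM_TABLE = np.full(256, ord("N"), dtype=np.uint8)
for _src, _dst in _NORMALIZE.items():
    _NORM_TABLE[ord(_src)] = ord(_dst)

_ONEHOT_TABLE = np.zeros((256, 4), dtype=np.float32)
for _b, _i in _BASE_INDEX.items():
    _ONEHOT_TABLE[ord(_b), _i] = 1.0
    _ONEHOT_TABLE[ord(_b.lower()), _i] = 1.0
_ONEHOT_TABLE[ord("U"), 3] = 1.0
_ONEHOT_TABLE[ord("u"), 3] = 1.0


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T, and map every non-ACGT symbol to N."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _NORM_TABLE[arr].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """A single named sequence with normalized half-open slicing.

    Every residue returned is in {A, C, G, T, N}.
    """

    def __init__(self, name: str, sequence: str):
        self.name = name
        self._seq = normalize_sequence(sequence)

    @property
    def length(self) -> int:
        return len(self._seq)

    def __len__(self) -> int:
        return len(self._seq)

    def residues(self, start: int, end: int) -> str:
        """Return bases in the 0-based half-open interval [start, end)."""
        if not (0 <= start <= end <= len(self._seq)):
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for sequence "
                f"{self.name!r} of length {len(self._seq)}"
            )
        return self._seq[start:end]

    def __str__(self) -> str:
        return self._seq


class Genome:
    """Collection of GenomeSequence records keyed by name.

    Loads a (multi-)FASTA eagerly via pyfaidx.  Genomes in this package are
    gene-scale or toy-genome-scale, so in-memory residency is fine; pyfaidx
    still provides indexed parsing of arbitrary FASTA layouts.
    """

    def __init__(self, sequences: dict[str, GenomeSequence]):
        self._sequences = dict(sequences)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), sequence_always_upper=True, rebuild=True)
        seqs = {name: GenomeSequence(name, str(fa[name][:])) for name in fa.keys()}
        fa.close()
        return cls(seqs)

    def __getitem__(self, name: str) -> GenomeSequence:
        return self._sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sequences

    def keys(self):
        return self._sequences.keys()

    def values(self):
        return self._sequences.values()

    def items(self):
        return self._sequences.items()


@dataclass
class Transcript:
    """An exon chain.  Exons are 1-based inclusive genomic intervals,
    non-overlapping, sorted by genomic coordinate."""

    transcript_id: str
    exons: list[tuple[int, int]]
    strand: str

    def __post_init__(self):
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = -1
        for a, b in self.exons:
            if a > b:
                raise ValueError(f"exon ({a}, {b}) has start > end")
            if a <= prev_end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id!r}"
                )
            prev_end = b

    @property
    def spliced_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    """A gene locus with its transcripts on a named sequence."""

    gene_id: str
    seq_name: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    biotype: str = ""
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id!r}: start > end")
        for tx in self.transcripts:
            if tx.exons and not (self.start <= tx.start and tx.end <= self.end):
                raise ValueError(
                    f"transcript {tx.transcript_id!r} extends outside gene "
                    f"{self.gene_id!r}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_GENE_FEATURES = {"gene"}
_TRANSCRIPT_FEATURES = {"mRNA", "transcript"}
_PROTEIN_CODING = {"protein_coding", "protein-coding", "mRNA"}


def _validate_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{path}: unparseable annotation line {lineno}: "
                    f"expected 9 tab-separated columns"
                )


def _detect_dialect(path: Path) -> str:
    """'gff3' if attributes use key=value, 'gtf' if key \"value\";."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            attrs = line.rstrip("\n").split("\t")[-1]
            if "=" in attrs.split(";")[0]:
                return "gff3"
            return "gtf"
    return "gff3"


def _feature_biotype(feat) -> str:
    """Biotype resolution order: gene_biotype, then biotype, then the
    feature type itself."""
    for key in ("gene_biotype", "biotype"):
        if key in feat.attributes:
            return feat.attributes[key][0]
    return feat.featuretype


def parse_annotation(
    gff_path: str | Path,
    biotype_filter: str = "protein-coding",
) -> list[GeneModel]:
    """Read a GFF3 or GTF file into GeneModel objects.

    Parameters
    ----------
    biotype_filter : {"protein-coding", "all"}
        "protein-coding" keeps genes whose resolved biotype is
        protein_coding; "all" keeps everything.

    Genes without any exon-bearing transcript are skipped with a warning.
    """
    import gffutils

    if biotype_filter not in ("protein-coding", "all"):
        raise ValueError("biotype_filter must be 'protein-coding' or 'all'")
    path = Path(gff_path)
    _validate_lines(path)
    dialect = _detect_dialect(path)

    kwargs: dict = dict(
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    if dialect == "gtf":
        kwargs.update(
            disable_infer_genes=False,
            disable_infer_transcripts=False,
        )
    db = gffutils.create_db(str(path), **kwargs)

    genes: list[GeneModel] = []
    for feat in db.all_features():
        if feat.featuretype not in _GENE_FEATURES:
            continue
        biotype = _feature_biotype(feat)
        if biotype_filter == "protein-coding" and biotype not in _PROTEIN_CODING:
            continue
        gene_id = feat.id
        transcripts: list[Transcript] = []
        for child in db.children(feat, level=1):
            if child.featuretype not in _TRANSCRIPT_FEATURES:
                continue
            exons = [
                (ex.start, ex.end)
                for ex in db.children(child, featuretype="exon")
            ]
            if not exons:
                continue
            transcripts.append(
                Transcript(
                    transcript_id=child.id,
                    exons=exons,
                    strand=child.strand,
                )
            )
        if not transcripts:
            # GTF-style: exons may hang directly off the gene record.
            exons = [
                (ex.start, ex.end)
                for ex in db.children(feat, featuretype="exon", level=1)
            ]
            if exons:
                transcripts.append(
                    Transcript(
                        transcript_id=gene_id + ".t1",
                        exons=exons,
                        strand=feat.strand,
                    )
                )
        if not transcripts:
            warnings.warn(
                f"gene {gene_id!r} has no exon-bearing transcript; skipped",
                stacklevel=2,
            )
            continue
        genes.append(
            GeneModel(
                gene_id=gene_id,
                seq_name=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                biotype=biotype,
                transcripts=transcripts,
            )
        )
    return genes


def select_canonical(gene: GeneModel) -> Transcript:
    """The transcript with maximal spliced (exonic) length.

    Ties are broken by lexicographically smallest transcript ID so the
    choice is deterministic.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id!r} has no transcripts")
    return min(
        gene.transcripts, key=lambda tx: (-tx.spliced_length, tx.transcript_id)
    )


def extract_gene_sequence(genome: GenomeSequence, gene: GeneModel) -> str:
    """Sense-strand sequence of the gene locus.

    Forward slice for '+' genes, reverse complement for '-'; always of
    length gene.end - gene.start + 1.
    """
    if gene.start < 1 or gene.end > genome.length:
        raise ValueError(
            f"gene {gene.gene_id!r} interval [{gene.start}, {gene.end}] is "
            f"out of bounds for {genome.name!r} (length {genome.length})"
        )
    forward = genome.residues(gene.start - 1, gene.end)
    if gene.strand == "-":
        return reverse_complement(forward)
    return forward


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an (L, 4) matrix, channels A,C,G,T.

    A=[1,0,0,0], C=[0,1,0,0], G=[0,0,1,0], T/U=[0,0,0,1]; N and any other
    symbol encode as the all-zero row.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ONEHOT_TABLE[arr].copy()


def one_hot_decode(matrix: np.ndarray) -> str:
    """Invert one_hot_encode: zero rows become N."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValueError("expected an (L, 4) matrix")
    bases = np.array(list("ACGT"))
    idx = matrix.argmax(axis=1)
    out = bases[idx]
    out[matrix.sum(axis=1) == 0] = "N"
    return "".join(out)
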