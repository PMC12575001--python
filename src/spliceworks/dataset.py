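"""Training/test dataset construction: chromosome splitting, pseudogene and
paralog removal, splice-site labeling, fixed-window segmentation, and HDF5
serialization.

Splice-label convention (used consistently by labeling, evaluation, BED
output and ISM site selection): the donor label sits on the LAST EXONIC
base upstream of the intron, the acceptor label on the FIRST EXONIC base
downstream of it, both on the sense strand.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .genomics_io import GeneModel, Transcript, one_hot_encode

__all__ = [
    "DONOR_ON_LAST_EXONIC_BASE",
    "CANONICAL_INTRON_DINUCLEOTIDES",
    "SplitSpec",
    "LabeledGene",
    "EncodedDataset",
    "split_chromosomes",
    "filter_pseudogenes",
    "remove_paralogs",
    "label_splice_sites",
    "segment",
    "write_dataset",
    "read_dataset",
]

# Single switch for the label-position convention documented above.
DONOR_ON_LAST_EXONIC_BASE = True

CANONICAL_INTRON_DINUCLEOTIDES = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}

_PSEUDOGENE_BIOTYPES = {
    "pseudogene",
    "transcribed_pseudogene",
    "processed_pseudogene",
}

#: Label classes; Y channel order is (none, acceptor, donor).
LABEL_NONE, LABEL_ACCEPTOR, LABEL_DONOR = 0, 1, 2

_HUMAN_TRAIN = {str(c) for c in (2, 4, 6, 8, *range(10, 23))} | {"X", "Y"}
_HUMAN_TEST = {"1", "3", "5", "7", "9"}


@dataclass
class SplitSpec:
    method: str = "random"  # {"human", "random"}
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("human", "random"):
            raise ValueError("split method must be 'human' or 'random'")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


def split_chromosomes(
    chromosomes: list[tuple[str, int]], spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Partition chromosome names into (train, test).

    "human": fixed SpliceAI-style split (train 2,4,6,8,10..22,X,Y; test
    1,3,5,7,9), accepting both "1" and "chr1" naming.  "random": shuffle by
    seed, then accumulate chromosomes into the training set until the
    cumulative length reaches train_fraction of the total; the remainder is
    the test set.
    """
    names = [n for n, _ in chromosomes]
    if len(set(names)) != len(names):
        raise ValueError("chromosome names must be unique")
    if any(l <= 0 for _, l in chromosomes):
        raise ValueError("chromosome lengths must be positive")

    if spec.method == "human":
        train, test, unmatched = [], [], []
        for name, _ in chromosomes:
            key = name[3:] if name.lower().startswith("chr") else name
            if key in _HUMAN_TRAIN:
                train.append(name)
            elif key in _HUMAN_TEST:
                test.append(name)
            else:
                unmatched.append(name)
        if unmatched:
            raise ValueError(
                "human split method cannot place chromosome names: "
                + ", ".join(unmatched)
            )
        return train, test

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(chromosomes))
    total = sum(l for _, l in chromosomes)
    target = spec.train_fraction * total
    train, test = [], []
    cum = 0
    for idx in order:
        name, length = chromosomes[idx]
        if cum < target:
            train.append(name)
            cum += length
        else:
            test.append(name)
    if not test:
        warnings.warn(
            "random split produced an empty test set; all chromosomes "
            "were needed to reach the training fraction",
            stacklevel=2,
        )
    return train, test


def filter_pseudogenes(genes: list[GeneModel]) -> list[GeneModel]:
    """Drop genes annotated as pseudogenes (by feature type or biotype)."""
    return [g for g in genes if g.biotype not in _PSEUDOGENE_BIOTYPES]


@dataclass
class LabeledGene:
    """A gene's sense-strand sequence with per-position splice labels."""

    gene_id: str
    sequence: str
    labels: np.ndarray  # int8, 0=none 1=acceptor 2=donor
    donor_positions: np.ndarray
    acceptor_positions: np.ndarray

    def __post_init__(self):
        if len(self.labels) != len(self.sequence):
            raise ValueError("labels and sequence lengths differ")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _local_exons(
    transcript: Transcript, gene_start: int, gene_length: int
) -> list[tuple[int, int]]:
    """Exons as 0-based half-open intervals on the sense strand."""
    out = []
    if transcript.strand == "-":
        gene_end = gene_start + gene_length - 1
        for a, b in transcript.exons:
            out.append((gene_end - b, gene_end - a + 1))
        out.sort()
    else:
        for a, b in transcript.exons:
            out.append((a - gene_start, b - gene_start + 1))
    return out


def label_splice_sites(
    transcript: Transcript,
    gene_sequence: str,
    canonical_only: bool = False,
    gene_id: str | None = None,
    gene_start: int | None = None,
) -> LabeledGene:
    """Label donor/acceptor positions implied by a transcript's introns.

    Each intron contributes one donor and one acceptor label; with
    canonical_only, introns whose terminal dinucleotides are not GT-AG,
    GC-AG or AT-AC contribute nothing.
    """
    L = len(gene_sequence)
    if gene_start is None:
        gene_start = transcript.start
    exons = _local_exons(transcript, gene_start, L)
    for a, b in exons:
        if not (0 <= a < b <= L):
            raise ValueError(
                f"exon interval [{a}, {b}) outside the gene sequence "
                f"(length {L})"
            )

    labels = np.zeros(L, dtype=np.int8)
    donors, acceptors = [], []
    for (_, e_prev), (s_next, _) in zip(exons[:-1], exons[1:]):
        intron = gene_sequence[e_prev:s_next]
        if canonical_only:
            pair = (intron[:2], intron[-2:])
            if pair not in CANONICAL_INTRON_DINUCLEOTIDES:
                continue
        donor_pos = e_prev - 1 if DONOR_ON_LAST_EXONIC_BASE else e_prev
        acceptor_pos = s_next if DONOR_ON_LAST_EXONIC_BASE else s_next - 1
        labels[donor_pos] = LABEL_DONOR
        labels[acceptor_pos] = LABEL_ACCEPTOR
        donors.append(donor_pos)
        acceptors.append(acceptor_pos)
    return LabeledGene(
        gene_id=gene_id or transcript.transcript_id,
        sequence=gene_sequence,
        labels=labels,
        donor_positions=np.asarray(donors, dtype=np.int64),
        acceptor_positions=np.asarray(acceptors, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# paralog removal
# ---------------------------------------------------------------------------

def _minimap2_hits(
    test_genes: list[LabeledGene], train_genes: list[LabeledGene]
) -> list[tuple[str, str, float, float]]:
    """Align test (query) against train (target) with a high-divergence
    preset; identity = matches / alignment length, coverage = aligned query
    length / query length."""
    exe = shutil.which("minimap2")
    if exe is None:
        raise RuntimeError(
            "minimap2 executable not found; rerun remove_paralogs with "
            "backend='kmer' to use the built-in k-mer containment fallback"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        target = tmp / "train.fa"
        query = tmp / "test.fa"
        for path, genes in ((target, train_genes), (query, test_genes)):
            with open(path, "w") as fh:
                for g in genes:
                    fh.write(f">{g.gene_id}\n{g.sequence}\n")
        proc = subprocess.run(
            [exe, "-c", "-x", "asm20", "--secondary=yes", str(target),
             str(query)],
            capture_output=True,
            text=True,
            check=True,
        )
    hits = []
    for line in proc.stdout.splitlines():
        f = line.split("\t")
        qname, qlen, qstart, qend = f[0], int(f[1]), int(f[2]), int(f[3])
        tname, nmatch, alen = f[5], int(f[9]), int(f[10])
        if alen == 0:
            continue
        identity = nmatch / alen
        coverage = (qend - qstart) / qlen
        hits.append((qname, tname, identity, coverage))
    return hits


def _kmer_hits(
    test_genes: list[LabeledGene],
    train_genes: list[LabeledGene],
    k: int = 15,
) -> list[tuple[str, str, float, float]]:
    """Fallback: k-mer containment of each test gene in each train gene.

    The containment fraction is reported as both identity and coverage, so
    the caller's dual-threshold rule applies unchanged.
    """
    def kmers(seq: str) -> set:
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    train_sets = [(g.gene_id, kmers(g.sequence)) for g in train_genes]
    hits = []
    for tg in test_genes:
        tk = kmers(tg.sequence)
        if not tk:
            continue
        for train_id, sk in train_sets:
            c = len(tk & sk) / len(tk)
            if c > 0:
                hits.append((tg.gene_id, train_id, c, c))
    return hits


def remove_paralogs(
    test_genes: list[LabeledGene],
    train_genes: list[LabeledGene],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
    backend: str = "auto",
) -> tuple[list[LabeledGene], pd.DataFrame]:
    """Drop test genes alignable to any training gene with identity AND
    coverage both strictly above the thresholds.

    Only the test set is filtered; the training set is never touched.
    Returns (kept test genes, removal report with columns test_id,
    train_id, identity, coverage).
    """
    if any(not g.sequence for g in test_genes + train_genes):
        raise ValueError("gene sequences must be non-empty")
    if backend == "auto":
        backend = "minimap2" if shutil.which("minimap2") else "kmer"
    if backend == "minimap2":
        hits = _minimap2_hits(test_genes, train_genes)
    elif backend == "kmer":
        hits = _kmer_hits(test_genes, train_genes)
    else:
        raise ValueError("backend must be 'auto', 'minimap2' or 'kmer'")

    removed: dict[str, tuple[str, float, float]] = {}
    for qname, tname, identity, coverage in hits:
        if identity > min_identity and coverage > min_coverage:
            prev = removed.get(qname)
            if prev is None or identity * coverage > prev[1] * prev[2]:
                removed[qname] = (tname, identity, coverage)
    report = pd.DataFrame(
        [
            {"test_id": q, "train_id": t, "identity": i, "coverage": c}
            for q, (t, i, c) in sorted(removed.items())
        ],
        columns=["test_id", "train_id", "identity", "coverage"],
    )
    kept = [g for g in test_genes if g.gene_id not in removed]
    return kept, report


# ---------------------------------------------------------------------------
# segmentation and HDF5 container
# ---------------------------------------------------------------------------

def segment(
    gene: LabeledGene, core: int = 5000, flank: int = 5000
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a gene into ceil(L/core) overlapping windows.

    Segment i holds the core interval [i*core, (i+1)*core) plus `flank`
    context on each side; positions beyond the gene are N-padding (all-zero
    rows) in X and the all-zero padding label in Y.  Shapes:
    X (segments, core + 2*flank, 4), Y (segments, core, 3).
    """
    if core <= 0 or flank <= 0:
        raise ValueError("core and flank must be positive")
    L = gene.length
    if L == 0:
        raise ValueError(f"gene {gene.gene_id!r} has an empty sequence")
    n_seg = ceil(L / core)
    onehot = one_hot_encode(gene.sequence)
    X = np.zeros((n_seg, core + 2 * flank, 4), dtype=np.float32)
    Y = np.zeros((n_seg, core, 3), dtype=np.float32)
    eye = np.eye(3, dtype=np.float32)
    for i in range(n_seg):
        w_start = i * core - flank
        w_end = (i + 1) * core + flank
        src_start, src_end = max(w_start, 0), min(w_end, L)
        X[i, src_start - w_start : src_end - w_start, :] = onehot[
            src_start:src_end
        ]
        c_start, c_end = i * core, min((i + 1) * core, L)
        Y[i, : c_end - c_start, :] = eye[gene.labels[c_start:c_end]]
    return X, Y


@dataclass
class EncodedDataset:
    """Paired one-hot feature windows and label windows, kept per gene."""

    gene_ids: list[str] = field(default_factory=list)
    X: list[np.ndarray] = field(default_factory=list)  # (segs_g, core+2f, 4)
    Y: list[np.ndarray] = field(default_factory=list)  # (segs_g, core, 3)

    @classmethod
    def from_genes(
        cls, genes: list[LabeledGene], core: int = 5000, flank: int = 5000
    ) -> "EncodedDataset":
        ds = cls()
        for g in genes:
            x, y = segment(g, core, flank)
            ds.gene_ids.append(g.gene_id)
            ds.X.append(x)
            ds.Y.append(y)
        return ds

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def n_segments(self) -> int:
        return sum(x.shape[0] for x in self.X)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All segments of all genes as two stacked matrices."""
        if not self.X:
            raise ValueError("dataset is empty")
        return np.concatenate(self.X), np.concatenate(self.Y)


def write_dataset(
    ds: EncodedDataset, path: str | Path, batch_size: int = 100
) -> None:
    """Serialize to HDF5, concatenating genes in batches of `batch_size`
    (one stacked X/Y matrix pair per batch group)."""
    if batch_size < 1:
        raise ValueError("batch_size must be positive")
    n_batches = ceil(len(ds) / batch_size)
    with h5py.File(path, "w") as f:
        f.attrs["n_batches"] = n_batches
        f.attrs["batch_size"] = batch_size
        for b in range(n_batches):
            sl = slice(b * batch_size, (b + 1) * batch_size)
            grp = f.create_group(f"batch{b}")
            grp.create_dataset("X", data=np.concatenate(ds.X[sl]))
            grp.create_dataset("Y", data=np.concatenate(ds.Y[sl]))
            grp.create_dataset(
                "gene_ids",
                data=np.array(ds.gene_ids[sl], dtype=h5py.string_dtype()),
            )
            grp.create_dataset(
                "segments",
                data=np.array([x.shape[0] for x in ds.X[sl]], dtype=np.int64),
            )


def read_dataset(path: str | Path) -> EncodedDataset:
    ds = EncodedDataset()
    with h5py.File(path, "r") as f:
        n_batches = int(f.attrs["n_batches"])
        for b in range(n_batches):
            grp = f[f"batch{b}"]
            for key in ("X", "Y", "gene_ids", "segments"):
                if key not in grp:
                    raise ValueError(
                        f"corrupt dataset file {path}: missing "
                        f"'batch{b}/{key}'"
                    )
            X = grp["X"][()]
            Y = grp["Y"][()]
            ids = [s.decode() for s in grp["gene_ids"][()]]
            counts = grp["segments"][()]
            offset = 0
            for gid, n in zip(ids, counts):
                ds.gene_ids.append(gid)
                ds.X.append(X[offset : offset + n])
                ds.Y.append(Y[offset : offset + n])
                offset += int(n)
    return ds
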