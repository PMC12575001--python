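"""Seeded generator of toy genomes with planted multi-exon genes.

Emits matched FASTA + GFF3 + a truth table (and VCF variants on demand) so
the dataset builder, models, and variant scorer can all be exercised and
verified against known ground truth without downloading any real genome.

The planted gene model: multi-exon protein-coding genes on both strands
with canonical GT-AG introns (plus configurable fractions of GC-AG, AT-AC,
and non-canonical CT-AC introns), a donor consensus of the
[C/A]AG | GT[A/G]AGT form, and acceptor sites preceded by a polypyrimidine
tract and a YAG trinucleotide.  "Strength" parameters give the per-position
probability that a consensus base is used instead of a random draw.
Near-consensus decoy sites with a broken boundary dinucleotide are planted
inside introns; a recorded single-base fix converts a decoy into a
full-consensus site (a cryptic gain).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomics_io import reverse_complement

__all__ = [
    "SyntheticSpec",
    "GeneTruth",
    "DecoyTruth",
    "TruthTable",
    "generate_genome",
    "plant_variant",
    "write_vcf",
]

_CANONICAL_CLASSES = ("GT-AG", "GC-AG", "AT-AC")
_NONCANONICAL_CLASS = "CT-AC"

# Consensus around the exon|intron junction: last 3 exonic bases then the
# first 6 intronic bases.  Tuples list allowed consensus bases.
_DONOR_EXONIC = (("C", "A"), ("A",), ("G",))
_DONOR_INTRONIC_TAIL = (("A", "G"), ("A",), ("G",), ("T",))  # after the dinucleotide
_ACCEPTOR_Y = ("C", "T")


@dataclass
class SyntheticSpec:
    """Parameters of a toy genome.  Same seed => byte-identical outputs."""

    n_chromosomes: int = 10
    chromosome_length: int = 200_000
    genes_per_chromosome: int = 8
    exon_count_range: tuple[int, int] = (3, 6)
    exon_length_range: tuple[int, int] = (100, 250)
    intron_length_range: tuple[int, int] = (250, 900)
    donor_strength: float = 0.995
    acceptor_strength: float = 0.995
    pyrimidine_tract_length: int = 14
    gc_ag_fraction: float = 0.03
    at_ac_fraction: float = 0.02
    noncanonical_fraction: float = 0.03
    background_gc: float = 0.42
    decoys_per_gene: int = 1
    end_margin: int = 2_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("chromosome counts and lengths must be positive")
        if self.genes_per_chromosome < 0:
            raise ValueError("genes_per_chromosome must be >= 0")
        if min(self.exon_length_range) < 10 or min(self.intron_length_range) < 40:
            raise ValueError("exon/intron lengths too short for planted motifs")
        frac = self.gc_ag_fraction + self.at_ac_fraction + self.noncanonical_fraction
        if frac > 1:
            raise ValueError("intron class fractions sum to more than 1")
        if not (0 <= self.background_gc <= 1):
            raise ValueError("background_gc must be in [0, 1]")


@dataclass
class DecoyTruth:
    """A planted near-consensus site, one base away from functional."""

    gene_id: str
    chrom: str
    site_class: str  # "donor" or "acceptor"
    local_pos: int  # would-be label position, 0-based on the gene sense strand
    fix_local_pos: int  # sense-strand position of the broken base
    fix_ref: str  # sense-strand base currently there
    fix_alt: str  # sense-strand base restoring consensus


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive genomic
    end: int
    exons: list[tuple[int, int]]  # 1-based inclusive genomic, sorted
    donor_local: list[int]  # 0-based on the sense-strand gene sequence
    acceptor_local: list[int]
    intron_classes: list[str]  # aligned with sense-strand intron order

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def local_to_genomic(self, local: int) -> int:
        """Map a 0-based sense-strand offset to a 0-based genomic position."""
        if self.strand == "+":
            return self.start - 1 + local
        return self.end - 1 - local


@dataclass
class TruthTable:
    genes: list[GeneTruth] = field(default_factory=list)
    decoys: list[DecoyTruth] = field(default_factory=list)

    def donor_count(self, canonical_only: bool = False) -> int:
        return sum(
            sum(1 for c in g.intron_classes if not canonical_only or c in _CANONICAL_CLASSES)
            for g in self.genes
        )

    def acceptor_count(self, canonical_only: bool = False) -> int:
        return self.donor_count(canonical_only)

    def gene(self, gene_id: str) -> GeneTruth:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(
                ["gene_id", "chrom", "strand", "start", "end", "exons",
                 "donor_local", "acceptor_local", "intron_classes"]
            )
            for g in self.genes:
                w.writerow(
                    [
                        g.gene_id, g.chrom, g.strand, g.start, g.end,
                        ";".join(f"{a}-{b}" for a, b in g.exons),
                        ";".join(map(str, g.donor_local)),
                        ";".join(map(str, g.acceptor_local)),
                        ";".join(g.intron_classes),
                    ]
                )


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _consensus_base(rng: np.random.Generator, allowed, strength: float) -> str:
    if rng.random() < strength:
        return allowed[rng.integers(len(allowed))]
    return "ACGT"[rng.integers(4)]


def _sample_intron_class(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    r = rng.random()
    if r < spec.noncanonical_fraction:
        return _NONCANONICAL_CLASS
    r -= spec.noncanonical_fraction
    if r < spec.gc_ag_fraction:
        return "GC-AG"
    r -= spec.gc_ag_fraction
    if r < spec.at_ac_fraction:
        return "AT-AC"
    return "GT-AG"


def _build_gene_sequence(
    rng: np.random.Generator, spec: SyntheticSpec
) -> tuple[str, list[tuple[int, int]], list[str], list[dict]]:
    """Build one sense-strand gene.

    Returns (sequence, local exon intervals 0-based half-open, intron
    classes, decoy dicts in local sense coordinates).
    """
    lo, hi = spec.exon_count_range
    n_exons = int(rng.integers(lo, hi + 1))
    exon_lens = rng.integers(
        spec.exon_length_range[0], spec.exon_length_range[1] + 1, size=n_exons
    )
    intron_lens = rng.integers(
        spec.intron_length_range[0], spec.intron_length_range[1] + 1,
        size=max(n_exons - 1, 0),
    )

    parts: list[np.ndarray] = []
    exons_local: list[tuple[int, int]] = []
    classes: list[str] = []
    decoy_slots: list[dict] = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exon = _random_bases(rng, int(el), spec.background_gc)
        if i > 0:
            # acceptor side of this exon was shaped in the preceding intron
            pass
        exons_local.append((pos, pos + int(el)))
        parts.append(exon)
        pos += int(el)
        if i < n_exons - 1:
            il = int(intron_lens[i])
            intron = _random_bases(rng, il, spec.background_gc)
            cls = _sample_intron_class(rng, spec)
            d5, a3 = cls.split("-")
            # donor consensus: overwrite last 3 exonic bases ...
            for k, allowed in enumerate(_DONOR_EXONIC):
                exon[-3 + k] = _consensus_base(rng, allowed, spec.donor_strength)
            # ... and first 6 intronic bases (class dinucleotide is exact)
            intron[0], intron[1] = d5[0], d5[1]
            for k, allowed in enumerate(_DONOR_INTRONIC_TAIL):
                intron[2 + k] = _consensus_base(rng, allowed, spec.donor_strength)
            # acceptor: polypyrimidine tract, then Y A G at the intron end
            tract = spec.pyrimidine_tract_length
            for k in range(-3 - tract, -3):
                if rng.random() < spec.acceptor_strength:
                    intron[k] = _ACCEPTOR_Y[rng.integers(2)]
            intron[-3] = _consensus_base(rng, _ACCEPTOR_Y, spec.acceptor_strength)
            intron[-2], intron[-1] = a3[0], a3[1]
            classes.append(cls)
            # decoy slot: the intron interior available for planting
            decoy_slots.append(
                {"intron_start": pos, "intron_len": il, "tract": tract}
            )
            parts.append(intron)
            pos += il

    seq = np.concatenate(parts) if parts else np.array([], dtype="<U1")

    decoys: list[dict] = []
    n_decoys = spec.decoys_per_gene
    usable = [s for s in decoy_slots if s["intron_len"] >= 120]
    for _ in range(n_decoys):
        if not usable:
            break
        slot = usable[rng.integers(len(usable))]
        site_class = "donor" if rng.random() < 0.5 else "acceptor"
        il, istart = slot["intron_len"], slot["intron_start"]
        # keep clear of the real boundary motifs on both sides
        lo_off, hi_off = 30, il - 30 - slot["tract"] - 10
        if hi_off <= lo_off:
            continue
        off = int(rng.integers(lo_off, hi_off))
        if site_class == "donor":
            # plant "CAG GTAAGT" with GT broken to GG; fixing base: the T
            motif = list("CAGGGAAGT")
            start = istart + off
            seq[start : start + len(motif)] = motif
            decoys.append(
                {
                    "site_class": "donor",
                    # would-be donor label: last exonic-like base = the G of CAG
                    "local_pos": start + 2,
                    "fix_local_pos": start + 4,
                    "fix_ref": "G",
                    "fix_alt": "T",
                }
            )
        else:
            # plant tract + "TAA" with terminal AG broken to AA; fix A->G
            tract = "".join(
                _ACCEPTOR_Y[rng.integers(2)] for _ in range(12)
            )
            motif = list(tract + "TAA" + "G")  # trailing G = first "exonic" base
            start = istart + off
            seq[start : start + len(motif)] = motif
            fix_pos = start + len(tract) + 2  # the broken A (should be G)
            decoys.append(
                {
                    "site_class": "acceptor",
                    "local_pos": start + len(motif) - 1,
                    "fix_local_pos": fix_pos,
                    "fix_ref": "A",
                    "fix_alt": "G",
                }
            )
    return "".join(seq), exons_local, classes, decoys


def generate_genome(
    spec: SyntheticSpec, output_dir: str | Path | None = None
) -> tuple[dict[str, str], TruthTable]:
    """Generate the toy genome.

    Returns (chromosome name -> forward-strand sequence, truth table).
    When output_dir is given, writes genome.fa, annotation.gff3 and
    truth.tsv there.
    """
    spec.validate()
    rng_root = np.random.SeedSequence(spec.seed)
    chrom_seeds = rng_root.spawn(spec.n_chromosomes)

    chroms: dict[str, str] = {}
    truth = TruthTable()
    gene_counter = 0
    for ci in range(spec.n_chromosomes):
        rng = np.random.Generator(np.random.Philox(chrom_seeds[ci]))
        chrom_name = f"chr{ci + 1}"
        backbone = _random_bases(rng, spec.chromosome_length, spec.background_gc)

        genes_here: list[tuple[str, int, str, list, list, list]] = []
        cursor = spec.end_margin
        placed = 0
        attempts = 0
        while placed < spec.genes_per_chromosome:
            attempts += 1
            if attempts > spec.genes_per_chromosome * 4:
                raise ValueError(
                    "could not place all genes without overlap; use longer "
                    "chromosomes or fewer genes"
                )
            seq, exons_local, classes, decoys = _build_gene_sequence(rng, spec)
            gap = int(rng.integers(500, 2000))
            start0 = cursor + gap  # 0-based genomic start
            if start0 + len(seq) > spec.chromosome_length - spec.end_margin:
                raise ValueError(
                    "could not place all genes without overlap; use longer "
                    "chromosomes or fewer genes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gene_counter += 1
            gene_id = f"gene{gene_counter:04d}"
            genomic_seq = seq if strand == "+" else reverse_complement(seq)
            backbone[start0 : start0 + len(seq)] = list(genomic_seq)
            genes_here.append(
                (gene_id, start0, strand, exons_local, classes, decoys)
            )
            cursor = start0 + len(seq)
            placed += 1

            L = len(seq)
            start1, end1 = start0 + 1, start0 + L  # 1-based inclusive
            if strand == "+":
                exons_genomic = [
                    (start1 + a, start1 + b - 1) for a, b in exons_local
                ]
            else:
                exons_genomic = sorted(
                    (end1 - (b - 1), end1 - a) for a, b in exons_local
                )
            donors, acceptors = [], []
            for (a0, b0), (a1, _b1) in zip(exons_local[:-1], exons_local[1:]):
                donors.append(b0 - 1)  # last exonic base before the intron
                acceptors.append(a1)  # first exonic base after the intron
            truth.genes.append(
                GeneTruth(
                    gene_id=gene_id,
                    chrom=chrom_name,
                    strand=strand,
                    start=start1,
                    end=end1,
                    exons=exons_genomic,
                    donor_local=donors,
                    acceptor_local=acceptors,
                    intron_classes=list(classes),
                )
            )
            for d in decoys:
                truth.decoys.append(
                    DecoyTruth(
                        gene_id=gene_id,
                        chrom=chrom_name,
                        site_class=d["site_class"],
                        local_pos=d["local_pos"],
                        fix_local_pos=d["fix_local_pos"],
                        fix_ref=d["fix_ref"],
                        fix_alt=d["fix_alt"],
                    )
                )
        chroms[chrom_name] = "".join(backbone)

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(chroms, out / "genome.fa")
        write_gff(truth, out / "annotation.gff3")
        truth.write_tsv(out / "truth.tsv")
    return chroms, truth


def write_fasta(chroms: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in truth.genes:
            attrs = f"ID={g.gene_id};gene_biotype=protein_coding"
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsynthetic\tmRNA\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for k, (a, b) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tsynthetic\texon\t{a}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.exon{k};Parent={tid}\n"
                )


def _forward_base(chroms: dict[str, str], chrom: str, pos0: int) -> str:
    return chroms[chrom][pos0]


def plant_variant(
    chroms: dict[str, str],
    truth: TruthTable,
    kind: str,
    seed: int = 0,
) -> tuple[tuple[str, int, str, str], str]:
    """Construct a single-nucleotide variant with a known splicing effect.

    kind : {"donor_loss", "acceptor_loss", "cryptic_gain"}

    Returns ((chrom, pos 1-based, ref, alt), expected dominant channel),
    the variant expressed on the forward genome strand.
    """
    rng = np.random.default_rng(seed)
    comp = str.maketrans("ACGT", "TGCA")

    if kind in ("donor_loss", "acceptor_loss"):
        candidates = [
            (g, i)
            for g in truth.genes
            for i, cls in enumerate(g.intron_classes)
            if cls == "GT-AG"
        ]
        if not candidates:
            raise ValueError("no eligible canonical intron found")
        g, i = candidates[rng.integers(len(candidates))]
        if kind == "donor_loss":
            # mutate the T of the sense-strand GT dinucleotide
            local = g.donor_local[i] + 2
            sense_ref, sense_alt = "T", "A"
            channel = "DS_DL"
        else:
            # mutate the G of the sense-strand terminal AG
            local = g.acceptor_local[i] - 1
            sense_ref, sense_alt = "G", "T"
            channel = "DS_AL"
        pos0 = g.local_to_genomic(local)
        if g.strand == "+":
            ref, alt = sense_ref, sense_alt
        else:
            ref, alt = sense_ref.translate(comp), sense_alt.translate(comp)
        actual = _forward_base(chroms, g.chrom, pos0)
        if actual != ref:
            raise RuntimeError(
                f"truth/genome mismatch at {g.chrom}:{pos0 + 1} "
                f"(expected {ref}, found {actual})"
            )
        return (g.chrom, pos0 + 1, ref, alt), channel

    if kind == "cryptic_gain":
        if not truth.decoys:
            raise ValueError("no planted decoy sites available")
        d = truth.decoys[rng.integers(len(truth.decoys))]
        g = truth.gene(d.gene_id)
        pos0 = g.local_to_genomic(d.fix_local_pos)
        if g.strand == "+":
            ref, alt = d.fix_ref, d.fix_alt
        else:
            ref, alt = d.fix_ref.translate(comp), d.fix_alt.translate(comp)
        actual = _forward_base(chroms, g.chrom, pos0)
        if actual != ref:
            raise RuntimeError(
                f"decoy truth/genome mismatch at {g.chrom}:{pos0 + 1}"
            )
        channel = "DS_DG" if d.site_class == "donor" else "DS_AG"
        return (g.chrom, pos0 + 1, ref, alt), channel

    raise ValueError(f"unknown variant kind {kind!r}")


def write_vcf(
    variants: list[tuple[str, int, str, str]],
    chroms: dict[str, str],
    path: str | Path,
) -> None:
    """Write minimal VCF 4.2 with contig headers for the toy genome."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in chroms.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for k, (chrom, pos, ref, alt) in enumerate(variants, start=1):
            fh.write(f"{chrom}\t{pos}\tvar{k}\t{ref}\t{alt}\t.\t.\t.\n")
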