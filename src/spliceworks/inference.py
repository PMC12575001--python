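"""Windowed ensemble prediction and variant delta scoring.

Prediction slides windows of core 5000 nt plus flank/2 context per side
across the input; the model crop removes exactly the context, so the
concatenated cores tile the sequence and every base receives a score.
Ensembles (any number of models sharing a flank) are averaged per
position.

Variant delta scores follow the four-channel convention: within a window
of +-distance around the variant, DS(acceptor gain) = max(a_alt - a_ref),
DS(acceptor loss) = max(a_ref - a_alt), DS(donor gain) = max(d_alt -
d_ref), DS(donor loss) = max(d_ref - d_alt), each clamped at 0, with the
delta position DP the offset of the maximum relative to the variant
(negative = upstream on the gene's sense strand).

Indel alignment: alternate-allele scores are mapped back onto reference
coordinates -- inserted positions are skipped, and reference positions
inside a deletion take the score at the deletion junction (the last
retained alternate base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np

from .genomics_io import (
    GeneModel,
    GenomeSequence,
    one_hot_encode,
    reverse_complement,
)
from .model import SpliceModel

__all__ = [
    "Window",
    "WindowPlan",
    "PredictionTrack",
    "DeltaScores",
    "plan_windows",
    "predict_track",
    "call_sites",
    "score_variant",
    "variant_eligibility",
    "annotate_vcf",
    "VCF_INFO_KEY",
]

CORE = 5000
VCF_INFO_KEY = "SpliceDelta"
_ACCEPTOR, _DONOR = 1, 2


@dataclass
class Window:
    start: int  # nominal window start (may be negative -> left padding)
    end: int  # nominal window end (may exceed the sequence -> right pad)
    left_pad: int
    right_pad: int
    core_start: int
    core_end: int


@dataclass
class WindowPlan:
    seq_id: str
    seq_len: int
    flank: int
    windows: list[Window] = field(default_factory=list)
    chunks: list[tuple[int, int]] = field(default_factory=list)


def plan_windows(
    seq_len: int,
    flank: int,
    seq_id: str = "seq",
    split_threshold: int = 1_500_000,
) -> WindowPlan:
    """Tile a sequence with prediction windows of length CORE + flank.

    Cores tile [0, seq_len) exactly once; the first window is left-padded
    flank/2 Ns and the last is right-padded to full window length.
    Sequences longer than split_threshold are additionally divided into
    chunks overlapping by flank/2 for memory management (chunking never
    changes scores because window context always comes from the real
    sequence where it exists).
    """
    if seq_len <= 0:
        raise ValueError("sequence length must be positive")
    half = flank // 2
    plan = WindowPlan(seq_id=seq_id, seq_len=seq_len, flank=flank)
    n_win = ceil(seq_len / CORE)
    for i in range(n_win):
        core_start = i * CORE
        core_end = min(core_start + CORE, seq_len)
        start = core_start - half
        end = core_start + CORE + half
        plan.windows.append(
            Window(
                start=start,
                end=end,
                left_pad=max(0, -start),
                right_pad=max(0, end - seq_len),
                core_start=core_start,
                core_end=core_end,
            )
        )
    if seq_len > split_threshold:
        step = split_threshold - flank
        pos = 0
        while pos < seq_len:
            plan.chunks.append((pos, min(pos + split_threshold, seq_len)))
            pos += step
    else:
        plan.chunks.append((0, seq_len))
    return plan


@dataclass
class PredictionTrack:
    seq_id: str
    none: np.ndarray
    acceptor: np.ndarray
    donor: np.ndarray

    def __len__(self) -> int:
        return len(self.acceptor)


def _check_ensemble(models: list[SpliceModel]) -> int:
    if not models:
        raise ValueError("at least one model is required")
    flanks = {m.config.flank for m in models}
    if len(flanks) != 1:
        raise ValueError(
            f"ensemble models must share one flanking size, got {sorted(flanks)}"
        )
    return flanks.pop()


def _window_matrix(onehot: np.ndarray, plan: WindowPlan) -> np.ndarray:
    """(n_windows, CORE + flank, 4) one-hot with zero-padding outside."""
    width = CORE + plan.flank
    X = np.zeros((len(plan.windows), width, 4), dtype=np.float32)
    L = plan.seq_len
    for i, w in enumerate(plan.windows):
        src_start, src_end = max(w.start, 0), min(w.end, L)
        X[i, src_start - w.start : src_end - w.start, :] = onehot[
            src_start:src_end
        ]
    return X


def predict_ensemble(
    models: list[SpliceModel], X: np.ndarray, batch_size: int = 16
) -> np.ndarray:
    """Mean class probabilities across the ensemble."""
    _check_ensemble(models)
    acc = None
    for m in models:
        p = m.predict_proba(X, batch_size=batch_size)
        acc = p if acc is None else acc + p
    return acc / len(models)


def predict_track(
    models: list[SpliceModel] | SpliceModel,
    seq: str,
    seq_id: str = "seq",
    split_threshold: int = 1_500_000,
    batch_size: int = 16,
) -> PredictionTrack:
    """Score every base of a sequence with the (ensemble-averaged) model."""
    if isinstance(models, SpliceModel):
        models = [models]
    flank = _check_ensemble(models)
    if not seq:
        raise ValueError("cannot predict on an empty sequence")
    plan = plan_windows(len(seq), flank, seq_id, split_threshold)
    onehot = one_hot_encode(seq)
    X = _window_matrix(onehot, plan)
    probs = predict_ensemble(models, X, batch_size)  # (n_win, CORE, 3)
    track = np.empty((len(seq), 3), dtype=np.float32)
    for i, w in enumerate(plan.windows):
        n = w.core_end - w.core_start
        track[w.core_start : w.core_end] = probs[i, :n]
    return PredictionTrack(
        seq_id=seq_id,
        none=track[:, 0].copy(),
        acceptor=track[:, _ACCEPTOR].copy(),
        donor=track[:, _DONOR].copy(),
    )


def call_sites(
    track: PredictionTrack,
    threshold: float = 0.5,
    chrom: str | None = None,
    offset: int = 0,
    strand: str = "+",
    gene_end: int | None = None,
) -> tuple[list[tuple], list[tuple]]:
    """BED records (0-based half-open) for positions scoring above the
    threshold: (donor records, acceptor records), score = probability.

    For a minus-strand gene, pass the gene's 0-based end (exclusive) as
    gene_end together with offset = gene start, and track positions are
    mapped back to genomic coordinates.
    """
    chrom = chrom or track.seq_id
    donor_recs, acceptor_recs = [], []
    for arr, name, recs in (
        (track.donor, "donor", donor_recs),
        (track.acceptor, "acceptor", acceptor_recs),
    ):
        for p in np.flatnonzero(arr > threshold):
            p = int(p)
            if strand == "-":
                if gene_end is None:
                    raise ValueError("minus-strand mapping requires gene_end")
                g = gene_end - 1 - p
            else:
                g = offset + p
            recs.append((chrom, g, g + 1, name, float(arr[p]), strand))
    donor_recs.sort(key=lambda r: r[1])
    acceptor_recs.sort(key=lambda r: r[1])
    return donor_recs, acceptor_recs


def write_bed(records: list[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:.4f}\t{strand}\n")


@dataclass
class DeltaScores:
    ds_ag: float
    ds_al: float
    ds_dg: float
    ds_dl: float
    dp_ag: int
    dp_al: int
    dp_dg: int
    dp_dl: int

    def as_dict(self) -> dict:
        return {
            "DS_AG": self.ds_ag, "DS_AL": self.ds_al,
            "DS_DG": self.ds_dg, "DS_DL": self.ds_dl,
            "DP_AG": self.dp_ag, "DP_AL": self.dp_al,
            "DP_DG": self.dp_dg, "DP_DL": self.dp_dl,
        }

    def info_string(self) -> str:
        return (
            f"{self.ds_ag:.4f}|{self.ds_al:.4f}|{self.ds_dg:.4f}|"
            f"{self.ds_dl:.4f}|{self.dp_ag}|{self.dp_al}|{self.dp_dg}|"
            f"{self.dp_dl}"
        )

    def dominant_channel(self) -> str:
        scores = {
            "DS_AG": self.ds_ag, "DS_AL": self.ds_al,
            "DS_DG": self.ds_dg, "DS_DL": self.ds_dl,
        }
        return max(scores, key=scores.get)


def _max_and_pos(diff: np.ndarray, offsets: np.ndarray) -> tuple[float, int]:
    """Clamped maximum and its offset; ties -> smallest |offset| then
    upstream (negative)."""
    best = float(diff.max())
    if best <= 0:
        return 0.0, 0
    cand = offsets[diff == best]
    cand = sorted(cand, key=lambda o: (abs(o), o))
    return best, int(cand[0])


def align_alt_to_ref(
    alt_scores: np.ndarray, anchor: int, ref_len: int, alt_len: int,
    offsets: np.ndarray,
) -> np.ndarray:
    """Select alternate-allele scores at reference-relative offsets.

    anchor is the index of the variant's first base in the alternate score
    array.  Inserted positions are skipped; deleted reference positions
    read the score at the deletion junction.
    """
    out = np.empty(len(offsets), dtype=alt_scores.dtype)
    shared = min(ref_len, alt_len)
    for j, rel in enumerate(offsets):
        if rel < 0:
            idx = anchor + rel
        elif rel < shared:
            idx = anchor + rel
        elif rel < ref_len:  # deleted reference base
            idx = anchor + alt_len - 1
        else:  # past the variant
            idx = anchor + rel - ref_len + alt_len
        out[j] = alt_scores[idx]
    return out


def score_variant(
    models: list[SpliceModel] | SpliceModel,
    genome: GenomeSequence,
    variant: tuple[str, int, str, str],
    gene: GeneModel,
    distance: int = 50,
    batch_size: int = 4,
) -> DeltaScores:
    """Delta scores for a variant (chrom, 1-based pos, ref, alt) inside an
    annotated gene.

    Flanking context is taken from the real genome sequence (N-padding is
    used only when the window would run off the chromosome).  For genes on
    the minus strand the model runs on the sense strand and delta positions
    are reported in sense orientation.
    """
    if isinstance(models, SpliceModel):
        models = [models]
    flank = _check_ensemble(models)
    chrom, pos1, ref, alt = variant
    pos0 = pos1 - 1
    ref, alt = ref.upper(), alt.upper()
    actual = genome.residues(pos0, min(pos0 + len(ref), genome.length))
    if actual != ref:
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos1}: VCF says {ref!r}, "
            f"genome has {actual!r}"
        )

    half = flank // 2
    pad = distance + half

    def grab(start: int, end: int) -> str:
        s, e = max(start, 0), min(end, genome.length)
        return "N" * (s - start) + genome.residues(s, e) + "N" * (end - e)

    ref_fwd = grab(pos0 - pad, pos0 + len(ref) + pad)
    alt_fwd = grab(pos0 - pad, pos0) + alt + grab(
        pos0 + len(ref), pos0 + len(ref) + pad
    )
    if gene.strand == "-":
        ref_seq, alt_seq = reverse_complement(ref_fwd), reverse_complement(alt_fwd)
    else:
        ref_seq, alt_seq = ref_fwd, alt_fwd

    def scores(seq: str) -> np.ndarray:
        x = one_hot_encode(seq)[None, :, :]
        return predict_ensemble(models, x, batch_size)[0]  # (len-flank, 3)

    p_ref = scores(ref_seq)
    p_alt = scores(alt_seq)
    # scored index of the variant's first sense base is `distance` for both
    # strands (the windows are symmetric around the allele).
    anchor = distance
    offsets = np.arange(-distance, distance + 1)
    a_ref = p_ref[anchor + offsets, _ACCEPTOR]
    d_ref = p_ref[anchor + offsets, _DONOR]
    a_alt = align_alt_to_ref(
        p_alt[:, _ACCEPTOR], anchor, len(ref), len(alt), offsets
    )
    d_alt = align_alt_to_ref(
        p_alt[:, _DONOR], anchor, len(ref), len(alt), offsets
    )

    ds_ag, dp_ag = _max_and_pos(a_alt - a_ref, offsets)
    ds_al, dp_al = _max_and_pos(a_ref - a_alt, offsets)
    ds_dg, dp_dg = _max_and_pos(d_alt - d_ref, offsets)
    ds_dl, dp_dl = _max_and_pos(d_ref - d_alt, offsets)
    return DeltaScores(ds_ag, ds_al, ds_dg, ds_dl, dp_ag, dp_al, dp_dg, dp_dl)


def variant_eligibility(
    variant: tuple[str, int, str, str],
    genes: list[GeneModel],
    chrom_len: int,
    flank: int,
    distance: int = 50,
) -> tuple[GeneModel | None, str | None]:
    """(containing gene, None) if scorable, else (None, reason code).

    Reasons: "outside_gene", "near_chromosome_end", "long_deletion".
    """
    chrom, pos1, ref, alt = variant
    pos0 = pos1 - 1
    hit = None
    for g in genes:
        if g.seq_name == chrom and g.start <= pos1 <= g.end:
            hit = g
            break
    if hit is None:
        return None, "outside_gene"
    if pos0 < flank or pos0 + len(ref) > chrom_len - flank:
        return None, "near_chromosome_end"
    if len(ref) - len(alt) > 2 * distance:
        return None, "long_deletion"
    return hit, None


def annotate_vcf(
    vcf_in: str | Path,
    genome,
    genes: list[GeneModel],
    models: list[SpliceModel] | SpliceModel,
    vcf_out: str | Path,
    distance: int = 50,
) -> dict[str, int]:
    """Annotate eligible VCF records with the eight delta values.

    Input records are all preserved; eligible ones gain the
    ``SpliceDelta`` INFO field DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|
    DP_DL and the header gains its definition.  Returns counts of
    annotated / skipped records by reason.
    """
    from cyvcf2 import VCF, Writer

    if isinstance(models, SpliceModel):
        models = [models]
    flank = _check_ensemble(models)
    vcf = VCF(str(vcf_in))
    vcf.add_info_to_header(
        {
            "ID": VCF_INFO_KEY,
            "Number": ".",
            "Type": "String",
            "Description": (
                "Splice delta scores and positions: "
                "DS_AG|DS_AL|DS_DG|DS_DL|DP_AG|DP_AL|DP_DG|DP_DL"
            ),
        }
    )
    writer = Writer(str(vcf_out), vcf)
    counts: dict[str, int] = {"annotated": 0}
    contig_lens = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
    for i, rec in enumerate(vcf, start=1):
        try:
            alts = rec.ALT or []
            infos = []
            for alt in alts:
                var = (rec.CHROM, rec.POS, rec.REF, alt)
                chrom_len = contig_lens.get(
                    rec.CHROM, genome[rec.CHROM].length
                )
                gene, reason = variant_eligibility(
                    var, genes, chrom_len, flank, distance
                )
                if gene is None:
                    counts[reason] = counts.get(reason, 0) + 1
                    continue
                ds = score_variant(
                    models, genome[rec.CHROM], var, gene, distance
                )
                infos.append(ds.info_string())
            if infos:
                rec.INFO[VCF_INFO_KEY] = ",".join(infos)
                counts["annotated"] += 1
            writer.write_record(rec)
        except ValueError as exc:
            writer.close()
            vcf.close()
            raise ValueError(f"VCF record {i}: {exc}") from exc
    writer.close()
    vcf.close()
    return counts
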