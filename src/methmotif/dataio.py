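"""Input parsing, validation and result serialization.

All tabular inputs and outputs are TSV (tab-separated, header row, UTF-8,
'.' decimal), matching the TCGA Level-3 style the pipeline emulates.
Genomic regions are exchanged as BED6 (0-based half-open); motif models as
MEME minimal, JASPAR PFM, or TRANSFAC-style count matrices; networks as
GraphML.
"""

from __future__ import annotations

import io
import math
import os
import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: pseudocount added to every cell of a count matrix before normalization
COUNT_PSEUDOCOUNT = 0.1
#: floor applied to probability matrices (then renormalized) so log-odds stay finite
PROB_FLOOR = 1e-4


@dataclass
class PWM:
    """A transcription-factor binding model: per-position base probabilities.

    ``probs`` has shape (width, 4) over (A, C, G, T); every row sums to 1 and
    every entry is strictly positive (regularized at load time).
    """

    motif_id: str
    tf_name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"PWM {self.motif_id}: probabilities must be width x 4")
        if self.probs.shape[0] < 1:
            raise ValueError(f"PWM {self.motif_id}: zero-width motif")
        if np.any(self.probs <= 0):
            raise ValueError(f"PWM {self.motif_id}: non-positive probability")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


def regularize_counts(counts: np.ndarray, pseudocount: float = COUNT_PSEUDOCOUNT) -> np.ndarray:
    """Count matrix (width x 4) -> probability matrix with pseudocount."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative count in motif matrix")
    if np.any(counts.sum(axis=1) == 0) and pseudocount == 0:
        raise ValueError("uninformative position: row of zeros")
    c = counts + pseudocount
    return c / c.sum(axis=1, keepdims=True)


def regularize_probs(probs: np.ndarray, floor: float = PROB_FLOOR) -> np.ndarray:
    """Probability matrix -> floored at ``floor`` and renormalized."""
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < 0):
        raise ValueError("negative probability in motif matrix")
    if np.any(probs.sum(axis=1) == 0):
        raise ValueError("uninformative position: row of zeros")
    p = np.maximum(probs, floor)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# methylation dataset


def _check_unique(ids, what: str) -> None:
    dup = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate {what}: {sorted(set(dup))[:5]}")


def validate_beta(beta: pd.DataFrame) -> pd.DataFrame:
    """Validate a CpG x sample beta-value matrix (NaN allowed, values in [0,1])."""
    _check_unique(beta.index, "CpG ids")
    _check_unique(beta.columns, "sample ids")
    values = beta.to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 1))
    if len(bad):
        r, c = bad[0]
        raise ValueError(
            f"beta value out of [0,1] at CpG {beta.index[r]!r}, sample "
            f"{beta.columns[c]!r}: {values[r, c]}"
        )
    return beta.astype(float)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    required = ["cpg_id", "chrom", "position", "strand"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    _check_unique(ann["cpg_id"], "CpG ids")
    if (ann["position"] < 1).any():
        raise ValueError("annotation positions must be 1-based (>= 1)")
    bad = set(ann["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"invalid strand values: {bad}")
    return ann.reset_index(drop=True)


def validate_clinical(clin: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "survival_time", "event"]
    missing = [c for c in required if c not in clin.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    _check_unique(clin["sample_id"], "sample ids")
    if (clin["survival_time"] <= 0).any():
        raise ValueError("survival_time must be > 0")
    if not clin["event"].isin([0, 1]).all():
        raise ValueError("event must be binary 0/1")
    return clin.reset_index(drop=True)


def load_methylation_dataset(beta_path, annotation_path, clinical_path):
    """Load and cross-validate the beta matrix, CpG annotation and clinical table.

    Samples present in the beta matrix but absent from the clinical table are
    retained and reported with a warning; downstream screens work on the id
    intersection.
    """
    beta = pd.read_csv(beta_path, sep="\t", index_col=0)
    beta = validate_beta(beta)
    ann = validate_annotation(pd.read_csv(annotation_path, sep="\t"))
    clin = validate_clinical(pd.read_csv(clinical_path, sep="\t"))
    unmatched = sorted(set(beta.columns) - set(clin["sample_id"]))
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} beta-matrix sample(s) absent from clinical table: "
            f"{unmatched[:5]}",
            stacklevel=2,
        )
    return beta, ann, clin


# ---------------------------------------------------------------------------
# motifs


def _meme_alt_names(text: str) -> dict:
    """MOTIF lines may carry an alternate (TF) name the parser drops."""
    out = {}
    for line in text.splitlines():
        m = re.match(r"MOTIF\s+(\S+)(?:\s+(\S+))?", line)
        if m and m.group(2):
            out[m.group(1)] = m.group(2)
    return out


def read_pwms(path, format: str, tf_names: dict | None = None) -> list[PWM]:
    """Parse motif models into regularized :class:`PWM` objects.

    ``format`` is one of ``meme`` (MEME minimal, probability matrices),
    ``jaspar_pfm`` (JASPAR count matrices) or ``transfac_counts``.
    ``tf_names`` optionally maps motif_id -> TF name, overriding the record.
    """
    tf_names = tf_names or {}
    with open(path) as fh:
        text = fh.read()
    pwms: list[PWM] = []
    if format == "meme":
        records = bio_motifs.parse(io.StringIO(text), "minimal")
        alt = _meme_alt_names(text)
        for m in records:
            probs = np.column_stack([m.pwm[b] for b in BASES])
            mid = m.name
            pwms.append(PWM(mid, tf_names.get(mid, alt.get(mid, mid)), regularize_probs(probs)))
    elif format == "jaspar_pfm":
        records = bio_motifs.parse(io.StringIO(text), "jaspar")
        for m in records:
            counts = np.column_stack([m.counts[b] for b in BASES])
            mid = m.matrix_id or m.name
            pwms.append(PWM(mid, tf_names.get(mid, m.name or mid), regularize_counts(counts)))
    elif format == "transfac_counts":
        records = bio_motifs.parse(io.StringIO(text), "TRANSFAC", strict=False)
        for m in records:
            counts = np.column_stack([m.counts[b] for b in BASES])
            mid = m.get("AC") or m.get("ID")
            name = m.get("NA") or m.get("ID") or mid
            pwms.append(PWM(mid, tf_names.get(mid, name), regularize_counts(counts)))
    else:
        raise ValueError(f"unknown motif format: {format!r}")
    if not pwms:
        raise ValueError(f"no motifs parsed from {path}")
    _check_unique([p.motif_id for p in pwms], "motif ids")
    return pwms


def write_meme_minimal(pwms: list[PWM], path, background=None) -> None:
    """Write PWMs in MEME minimal format (probability matrices)."""
    bg = background if background is not None else [0.25] * 4
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {q:.5f}" for b, q in zip(BASES, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id} {p.tf_name}\n")
            # large nsites: parsers that reconstruct integer counts keep full precision
            fh.write(
                f"letter-probability matrix: alphabet= ACGT w= {p.width} nsites= 1000000 E= 0\n"
            )
            for row in p.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# genome


def read_genome_fasta(path) -> dict:
    """FASTA -> {chrom: uppercase sequence}; non-ACGTN characters become N."""
    genome: dict[str, str] = {}
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate chromosome name: {rec.id}")
        seq = str(rec.seq).upper()
        cleaned = re.sub(r"[^ACGTN]", "N", seq)
        n_replaced += sum(1 for a, b in zip(seq, cleaned) if a != b)
        genome[rec.id] = cleaned
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    if n_replaced:
        warnings.warn(f"replaced {n_replaced} non-ACGTN character(s) with N", stacklevel=2)
    return genome


def write_genome_fasta(genome: dict, path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# result artifacts


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.12g")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """CpG regions -> BED6 (chrom, start, end, name=cpg_id, score=-log10 p capped at 999, strand)."""
    score = np.minimum(-np.log10(np.maximum(regions["p_value"].to_numpy(float), 1e-999)), 999.0)
    bed = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"].astype(int),
            "end": regions["end"].astype(int),
            "name": regions["cpg_id"],
            "score": np.round(score, 6),
            "strand": regions["strand"],
        }
    )
    if (bed["start"] < 0).any() or (bed["start"] >= bed["end"]).any():
        raise ValueError("invalid BED interval (need 0 <= start < end)")
    return bed


def write_bed(regions: pd.DataFrame, path) -> None:
    regions_to_bed(regions).to_csv(path, sep="\t", index=False, header=False)


def read_bed_regions(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "cpg_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
            "p_value": 10.0 ** (-bed["score"]),
        }
    )


def write_graphml(graph: nx.Graph, path) -> None:
    # drop None attributes (GraphML cannot encode them)
    g = graph.copy()
    for _, data in g.nodes(data=True):
        for k in [k for k, v in data.items() if v is None]:
            del data[k]
    nx.write_graphml(g, path)


def write_outputs(results: dict, out_dir) -> dict:
    """Serialize a result bundle; returns {key: written path}.

    DataFrames become TSV, region tables additionally BED, networkx graphs
    GraphML. Writing is idempotent (same inputs -> byte-identical files).
    """
    os.makedirs(out_dir, exist_ok=True)
    written = {}
    for key, obj in results.items():
        if isinstance(obj, nx.Graph):
            path = os.path.join(out_dir, f"{key}.graphml")
            write_graphml(obj, path)
        elif isinstance(obj, pd.DataFrame):
            path = os.path.join(out_dir, f"{key}.tsv")
            write_tsv(obj, path, index=bool(obj.index.name))
            if {"chrom", "start", "end", "strand", "p_value"} <= set(obj.columns):
                write_bed(obj, os.path.join(out_dir, f"{key}.bed"))
        elif isinstance(obj, dict):
            import json

            path = os.path.join(out_dir, f"{key}.json")
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        else:
            raise TypeError(f"cannot serialize result {key!r} of type {type(obj)}")
        written[key] = path
    return written
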