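"""Reading and writing the plain-text formats used by the pipelines.

FASTA/FASTQ go through Biopython; bedGraph, lane-profile, titration and
summary tables are tab-separated files handled with pandas. Stranded tracks
are stored as one bedGraph per strand (0-based half-open intervals).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from strandfold.core import (
    InitiationZone,
    LaneProfile,
    PlasmidReference,
    ReadPair,
    ReferenceSet,
    StrandedBinTrack,
    TitrationCurve,
)
from strandfold.scarseq import MetaProfile

_PHRED_CONST = "I"  # constant Q40 for simulated reads


# --- FASTA references ------------------------------------------------------


def write_references(refs: ReferenceSet, fasta_path: str | Path, roles_path: str | Path) -> None:
    """Write references as FASTA plus a (name, role, circular) roles table."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.name, description=f"role={r.role} circular={int(r.circular)}")
        for r in refs
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [{"name": r.name, "role": r.role, "circular": int(r.circular)} for r in refs]
    ).to_csv(roles_path, sep="\t", index=False)


def read_references(fasta_path: str | Path, roles_path: str | Path) -> ReferenceSet:
    roles = pd.read_csv(roles_path, sep="\t").set_index("name")
    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = roles.loc[rec.id]
        refs.append(
            PlasmidReference(
                name=rec.id,
                sequence=str(rec.seq).upper(),
                circular=bool(int(row["circular"])),
                role=str(row["role"]),
            )
        )
    return ReferenceSet(tuple(refs))


# --- FASTQ read pairs ------------------------------------------------------


def write_fastq_pairs(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    """Write mates to two FASTQ files (4-line records, constant quality)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.r1}\n+\n{_PHRED_CONST * len(p.r1)}\n")
            f2.write(f"@{p.name}/2\n{p.r2}\n+\n{_PHRED_CONST * len(p.r2)}\n")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    pairs = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(r1_path), "fastq"), SeqIO.parse(str(r2_path), "fastq"), strict=True
    ):
        name = rec1.id.removesuffix("/1")
        pairs.append(ReadPair(name=name, r1=str(rec1.seq), r2=str(rec2.seq)))
    return pairs


# --- stranded bedGraph tracks ---------------------------------------------


def write_stranded_bedgraph(
    track: StrandedBinTrack, fwd_path: str | Path, rev_path: str | Path
) -> None:
    """One bedGraph per strand; bin i covers [i*w, (i+1)*w)."""
    w = track.bin_width
    for path, values in ((fwd_path, track.F), (rev_path, track.R)):
        pd.DataFrame(
            {
                "chrom": track.reference,
                "start": np.arange(values.size) * w,
                "end": (np.arange(values.size) + 1) * w,
                "value": values,
            }
        ).to_csv(path, sep="\t", header=False, index=False)


def read_stranded_bedgraph(
    fwd_path: str | Path, rev_path: str | Path, units: str = "counts"
) -> StrandedBinTrack:
    cols = ["chrom", "start", "end", "value"]
    fwd = pd.read_csv(fwd_path, sep="\t", names=cols)
    rev = pd.read_csv(rev_path, sep="\t", names=cols)
    if len(fwd) != len(rev):
        raise ValueError("forward and reverse bedGraphs differ in bin count")
    chroms = fwd["chrom"].unique()
    if chroms.size != 1:
        raise ValueError("expected a single reference per track")
    widths = (fwd["end"] - fwd["start"]).unique()
    if widths.size != 1:
        raise ValueError("expected a fixed bin width")
    return StrandedBinTrack(
        reference=str(chroms[0]),
        bin_width=int(widths[0]),
        F=fwd["value"].to_numpy(),
        R=rev["value"].to_numpy(),
        units=units,
    )


# --- initiation zones (BED) -----------------------------------------------


def read_izs_bed(path: str | Path, bin_width: int) -> list[InitiationZone]:
    """BED of initiation zones: chrom, start, end, name, score, strand.

    The zone center (midpoint) is converted to a bin index; '-' strand maps
    to orientation -1.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    izs = []
    for _, row in bed.iterrows():
        center = (int(row["start"]) + int(row["end"])) // 2
        izs.append(
            InitiationZone(
                reference=str(row["chrom"]),
                center_bin=center // bin_width,
                strand_orientation=-1 if row["strand"] == "-" else 1,
            )
        )
    return izs


def write_metaprofile(profile: MetaProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"offset_bp": profile.offsets_bp, "mean_partition": profile.mean, "n": profile.n}
    ).to_csv(path, sep="\t", index=False)


# --- lane profiles and titrations -----------------------------------------


def write_lane_profile(profile: LaneProfile, path: str | Path) -> None:
    pd.DataFrame({"position": profile.position, "intensity": profile.intensity}).to_csv(
        path, sep="\t", index=False
    )


def read_lane_profile(path: str | Path, lane_length: float | None = None) -> LaneProfile:
    df = pd.read_csv(path, sep="\t")
    pos = df["position"].to_numpy(dtype=float)
    return LaneProfile(
        position=pos,
        intensity=df["intensity"].to_numpy(dtype=float),
        lane_length=lane_length if lane_length is not None else float(pos[-1]),
    )


def write_titration(curve: TitrationCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"concentration": curve.concentration, "response": curve.response}
    ).to_csv(path, sep="\t", index=False)


def read_titration(path: str | Path, response_kind: str = "percent_bound") -> TitrationCurve:
    df = pd.read_csv(path, sep="\t")
    return TitrationCurve(
        concentration=df["concentration"].to_numpy(dtype=float),
        response=df["response"].to_numpy(dtype=float),
        response_kind=response_kind,
    )
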