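"""Annotation-free ORF discovery from peptide evidence.

A six-frame stop-to-stop translation of the genome provides the search
space; identified peptides are matched back to it (and to the annotated
proteome), sequences sharing peptides are clustered into protein groups,
and groups without any annotated member become candidate novel ORFs that
are then checked against strand-specific RNA-seq coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .tracks import CoverageTrack

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class SixFrameORF:
    """A stop-free translation stretch in one of the six reading frames.

    ``start``/``end`` are 0-based half-open forward-strand genome
    coordinates of the coding stretch (the bounding stop codons are
    excluded), so ``end - start == 3 * len(aa)``.
    """

    identifier: str
    frame: int
    start: int
    end: int
    strand: str
    aa: str


@dataclass
class ProteinGroup:
    """Connected component of the sequence-peptide bipartite graph."""

    group_id: int
    members: tuple[str, ...]
    peptides: tuple[str, ...]
    has_annotated_member: bool


def six_frame_translate(
    sequence: str, replicon: str = "genome", min_aa: int = 7
) -> list[SixFrameORF]:
    """Translate all six frames and emit every stop-free stretch >= min_aa.

    Identifiers are ``<replicon>:<frame>:<1-based aa start in the frame
    translation>``; reverse-frame coordinates are mapped back to the
    forward strand.
    """
    sequence = sequence.upper()
    n = len(sequence)
    orfs: list[SixFrameORF] = []
    rc = str(Seq(sequence).reverse_complement())
    for frame in FRAMES:
        offset = abs(frame) - 1
        template = sequence if frame > 0 else rc
        usable = (n - offset) - (n - offset) % 3
        if usable <= 0:
            continue
        aa_all = str(Seq(template[offset:offset + usable]).translate())
        pos = 0
        for stretch in aa_all.split("*"):
            if len(stretch) >= min_aa:
                i, j = pos, pos + len(stretch)  # aa coords within frame
                nt_lo, nt_hi = offset + 3 * i, offset + 3 * j
                if frame > 0:
                    start, end, strand = nt_lo, nt_hi, "+"
                else:
                    start, end, strand = n - nt_hi, n - nt_lo, "-"
                orfs.append(SixFrameORF(
                    identifier=f"{replicon}:{frame:+d}:{i + 1}",
                    frame=frame, start=start, end=end, strand=strand,
                    aa=stretch,
                ))
            pos += len(stretch) + 1  # skip the stop
    return orfs


def digest_lysC(
    protein: str, max_missed: int = 2, min_len: int = 6
) -> list[str]:
    """In-silico Lys-C digest: cleave after every K (K-P bonds included).

    Emits each peptide spanning at most ``max_missed`` internal lysines,
    enumerated once per position, filtered to length >= ``min_len``.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    pieces: list[str] = []
    last = 0
    for i, aa in enumerate(protein):
        if aa == "K":
            pieces.append(protein[last:i + 1])
            last = i + 1
    if last < len(protein):
        pieces.append(protein[last:])
    peptides: list[str] = []
    for i in range(len(pieces)):
        for j in range(i, min(i + max_missed + 1, len(pieces))):
            pep = "".join(pieces[i:j + 1])
            if len(pep) >= min_len:
                peptides.append(pep)
    return peptides


def match_peptides(
    peptides: Iterable[str], database: Mapping[str, str]
) -> pd.DataFrame:
    """Locate evidence peptides in a sequence database.

    A match is an exact substring whose termini are Lys-C consistent
    (preceded by K or the sequence start; ending in K or at the sequence
    end), which is equivalent to membership in the sequence's digest
    lattice.  Returns a table with one row per (peptide, sequence) pair.
    """
    pepset = {p for p in peptides if p}
    if not pepset:
        return pd.DataFrame(columns=["peptide", "seq_id"])
    max_internal_k = max(p[:-1].count("K") for p in pepset)
    min_len = min(len(p) for p in pepset)
    rows: list[tuple[str, str]] = []
    for seq_id, seq in database.items():
        hits = set()
        for pep in digest_lysC(seq, max_missed=max_internal_k, min_len=min_len):
            if pep in pepset:
                hits.add(pep)
        rows.extend((pep, seq_id) for pep in sorted(hits))
    return pd.DataFrame(rows, columns=["peptide", "seq_id"])


def group_proteins(
    matches: pd.DataFrame,
    annotated_ids: set[str],
    min_novel_peptides: int = 2,
) -> tuple[list[ProteinGroup], pd.DataFrame]:
    """Cluster matched sequences into protein groups and call novel ORFs.

    Groups are connected components of the bipartite sequence-peptide
    graph.  A group lacking any annotated member and supported by at
    least ``min_novel_peptides`` unique peptides yields a novel-ORF
    call; the member with most peptide support represents the group.
    """
    graph = nx.Graph()
    for pep, seq_id in matches.itertuples(index=False):
        graph.add_edge(("pep", pep), ("seq", seq_id))
    groups: list[ProteinGroup] = []
    calls: list[dict] = []
    for gid, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    ):
        members = tuple(sorted(n[1] for n in comp if n[0] == "seq"))
        peps = tuple(sorted(n[1] for n in comp if n[0] == "pep"))
        has_annot = any(m in annotated_ids for m in members)
        groups.append(ProteinGroup(gid, members, peps, has_annot))
        if not has_annot and len(peps) >= min_novel_peptides:
            support = matches[matches["seq_id"].isin(members)]
            rep = (support.groupby("seq_id")["peptide"].nunique()
                   .sort_values(ascending=False).index[0])
            calls.append({"group_id": gid, "orf_id": rep,
                          "n_peptides": len(peps)})
    call_df = pd.DataFrame(calls, columns=["group_id", "orf_id", "n_peptides"])
    return groups, call_df


def validate_with_coverage(
    orf,
    track: CoverageTrack,
    min_mean: float = 10.0,
    min_frac: float = 0.8,
) -> dict:
    """RNA-seq support for a candidate ORF.

    Supported iff mean per-nucleotide coverage over the ORF span (on the
    ORF's strand) >= ``min_mean`` and the fraction of covered positions
    >= ``min_frac``.
    """
    if orf.start < 0 or orf.end > len(track) or orf.start >= orf.end:
        raise ValueError(
            f"ORF span [{orf.start}, {orf.end}) outside track bounds"
        )
    window = track.strand(orf.strand)[orf.start:orf.end]
    mean_cov = float(window.mean())
    frac = float((window > 0).mean())
    status = "supported" if (mean_cov >= min_mean and frac >= min_frac) else "insufficient"
    return {"status": status, "mean_coverage": mean_cov, "covered_fraction": frac}


def call_novel_orfs(
    evidence: pd.DataFrame,
    annotated: Mapping[str, str],
    orf_db: Sequence[SixFrameORF],
    track: CoverageTrack | None = None,
    min_novel_peptides: int = 2,
    min_mean: float = 10.0,
    min_frac: float = 0.8,
) -> pd.DataFrame:
    """End-to-end novel-ORF discovery from a peptide evidence table.

    Returns one row per novel call with peptide counts, coordinates and
    (when a coverage track is given) the RNA-seq validation status.
    """
    by_id = {o.identifier: o for o in orf_db}
    database = dict(annotated)
    database.update({o.identifier: o.aa for o in orf_db})
    matches = match_peptides(evidence["peptide"].unique(), database)
    _, calls = group_proteins(matches, set(annotated), min_novel_peptides)
    records = []
    for row in calls.itertuples(index=False):
        orf = by_id.get(row.orf_id)
        rec = {"orf_id": row.orf_id, "n_peptides": row.n_peptides,
               "start": orf.start if orf else pd.NA,
               "end": orf.end if orf else pd.NA,
               "strand": orf.strand if orf else pd.NA}
        if track is not None and orf is not None:
            rec.update({f"rnaseq_{k}" if k == "status" else k: v
                        for k, v in validate_with_coverage(
                            orf, track, min_mean, min_frac).items()})
        records.append(rec)
    cols = ["orf_id", "n_peptides", "start", "end", "strand"]
    if track is not None:
        cols += ["rnaseq_status", "mean_coverage", "covered_fraction"]
    return pd.DataFrame(records, columns=cols)


def write_orf_fasta(orfs: Sequence[SixFrameORF], path: str | Path) -> None:
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(f">{orf.identifier} {orf.start}-{orf.end}({orf.strand})\n")
            for i in range(0, len(orf.aa), 70):
                fh.write(orf.aa[i:i + 70] + "\n")
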