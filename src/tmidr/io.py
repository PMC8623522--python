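"""File formats: FASTA, topology, label/accessibility TSV, predictions.

All user-facing coordinates are 1-based closed; internal coordinates are
0-based half-open. FASTA goes through Biopython; the tabular formats are
plain TSV handled with pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import AccessibilityTrack
from .protein import AnnotatedProtein
from .topology import TopologyTrack, parse_topology


def read_fasta(path) -> dict:
    """id -> sequence (uppercased)."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="")
               for pid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_topology_file(path, sequences: dict, fmt: str = "string") -> dict:
    """id -> TopologyTrack.

    ``fmt='string'``: two-column TSV ``id<TAB>labels`` with one per-residue
    I/O/M/L string per protein. ``fmt='regions'``: TSV
    ``id  start  end  label`` with 1-based closed regions (gaps side-inferred).
    """
    tracks = {}
    if fmt == "string":
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                pid, labels = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: expected 'id<TAB>labels'") from exc
            tracks[pid] = parse_topology(labels.strip(),
                                         length=len(sequences[pid]))
    elif fmt == "regions":
        df = pd.read_csv(path, sep="\t",
                         names=["id", "start", "end", "label"], comment="#")
        for pid, grp in df.groupby("id", sort=False):
            regions = [(int(r.start), int(r.end), str(r.label))
                       for r in grp.itertuples()]
            tracks[pid] = parse_topology(regions, length=len(sequences[pid]))
    else:
        raise ValueError(f"unknown topology format {fmt!r}")
    return tracks


def write_topology_file(path, tracks: dict) -> None:
    with open(path, "w") as fh:
        for pid, track in tracks.items():
            fh.write(f"{pid}\t{track.labels}\n")


def read_label_file(path) -> dict:
    """Labelled-residue TSV ``protein_id  position  residue  label`` (1-based)
    -> id -> label string (D/O/U)."""
    df = pd.read_csv(path, sep="\t",
                     names=["id", "position", "residue", "label"], comment="#")
    out = {}
    for pid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("position")
        n = int(grp["position"].max())
        labels = ["U"] * n
        for r in grp.itertuples():
            labels[int(r.position) - 1] = str(r.label)
        out[pid] = "".join(labels)
    return out


def write_label_file(path, proteins: list) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            for i, (aa, lab) in enumerate(zip(p.sequence, p.labels), 1):
                fh.write(f"{p.id}\t{i}\t{aa}\t{lab}\n")


def read_rsa_file(path) -> dict:
    """Accessibility TSV ``protein_id  position  residue  rsa`` (1-based)."""
    df = pd.read_csv(path, sep="\t",
                     names=["id", "position", "residue", "rsa"], comment="#")
    out = {}
    for pid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("position")
        vals = np.zeros(int(grp["position"].max()))
        for r in grp.itertuples():
            vals[int(r.position) - 1] = float(r.rsa)
        out[pid] = AccessibilityTrack(vals, source="external")
    return out


def write_rsa_file(path, proteins: list, rsas: dict) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            rsa = rsas[p.id].rsa
            for i, aa in enumerate(p.sequence, 1):
                fh.write(f"{p.id}\t{i}\t{aa}\t{rsa[i - 1]:.4f}\n")


# ---------------------------------------------------------------------------
# corpus round trip


def write_corpus(directory, corpus) -> None:
    """Persist a labelled corpus in the interchange formats."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    proteins = corpus.proteins
    write_fasta(directory / "sequences.fasta",
                {p.id: p.sequence for p in proteins})
    write_topology_file(directory / "topology.tsv",
                        {p.id: p.topology for p in proteins})
    write_label_file(directory / "labels.tsv", proteins)
    write_rsa_file(directory / "accessibility.tsv", proteins, corpus.rsas)


def read_corpus(directory):
    """Load a corpus written by :func:`write_corpus`."""
    from .features import pseudo_profile
    from .synthetic import SyntheticCorpus

    directory = Path(directory)
    sequences = read_fasta(directory / "sequences.fasta")
    tracks = read_topology_file(directory / "topology.tsv", sequences)
    labels = read_label_file(directory / "labels.tsv")
    rsas = read_rsa_file(directory / "accessibility.tsv")
    proteins = []
    for pid, seq in sequences.items():
        proteins.append(AnnotatedProtein(
            id=pid, sequence=seq, topology=tracks[pid],
            labels=labels.get(pid), rsa=rsas[pid].rsa if pid in rsas else None,
        ))
    profiles = {p.id: pseudo_profile(p.sequence) for p in proteins}
    return SyntheticCorpus(proteins, profiles, rsas)


# ---------------------------------------------------------------------------
# fragments and predictions


def write_fragments(directory, fragments: list, split=None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(directory / "fragments.fasta",
                {f"frag{i:06d}": f.sequence for i, f in enumerate(fragments)})
    rows = []
    for i, f in enumerate(fragments):
        rows.append({
            "fragment_id": f"frag{i:06d}", "parent_id": f.parent_id,
            "start": f.start + 1, "end": f.end, "kind": f.kind,
            "split": split.assignment[i] if split is not None else "",
        })
    pd.DataFrame(rows).to_csv(directory / "fragments.tsv", sep="\t",
                              index=False)


_PRED_COLUMNS = ["position", "residue", "topology", "category", "raw",
                 "smoothed", "display", "call_specific", "call_sensitive"]


def write_predictions(path, protein: AnnotatedProtein, categories,
                      raw, specific, sensitive) -> None:
    """Per-protein prediction TSV exposing every intermediate track.

    ``smoothed``/``display`` columns carry the sensitive-mode track (the
    specific-mode call has its own column; both calls are derived from their
    own smoothed tracks at the shared cutoff).
    """
    rows = []
    for i in range(len(protein)):
        rows.append({
            "position": i + 1,
            "residue": protein.sequence[i],
            "topology": protein.topology.labels[i],
            "category": int(categories[i]),
            "raw": round(float(raw[i]), 6),
            "smoothed": round(float(sensitive.smoothed[i]), 6),
            "display": round(float(sensitive.display[i]), 6),
            "call_specific": int(specific.calls[i]),
            "call_sensitive": int(sensitive.calls[i]),
        })
    pd.DataFrame(rows, columns=_PRED_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"prediction file lacks columns: {sorted(missing)}")
    return df


def read_regions_file(path) -> list:
    """Region TSV ``protein_id  start  end`` (1-based closed) ->
    [(id, start0, end0-half-open)]."""
    df = pd.read_csv(path, sep="\t", names=["id", "start", "end"], comment="#")
    return [(str(r.id), int(r.start) - 1, int(r.end)) for r in df.itertuples()]
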