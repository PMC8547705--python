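"""Readers and writers for the external formats the pipeline touches.

FASTA via biopython, networks via networkx GraphML, tabular data via pandas.
Every stage logs counts in/out so the dataset bookkeeping is reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import RawHitRecord, RunConfig, SequenceRecord, check_unique_ids

log = logging.getLogger("gh19net")

_METADATA_COLUMNS = ("id", "is_seed", "activity_label", "taxonomy", "truth_group")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "yes", "t")


def read_fasta(path: str | Path, metadata: str | Path | None = None) -> list[SequenceRecord]:
    """Read sequences from FASTA, optionally merging a metadata sidecar TSV.

    The header token before the first whitespace becomes the record id. The
    sidecar TSV is keyed by id and may carry is_seed, activity_label,
    taxonomy and truth_group columns; unknown columns are ignored.
    """
    path = Path(path)
    meta: dict[str, dict] = {}
    if metadata is not None:
        df = pd.read_csv(metadata, sep="\t", dtype=str).fillna("")
        if "id" not in df.columns:
            raise ValueError(f"metadata file {metadata} lacks an 'id' column")
        for _, row in df.iterrows():
            entry: dict = {}
            if "is_seed" in df.columns and row["is_seed"] != "":
                entry["is_seed"] = _parse_bool(row["is_seed"])
            for col in ("activity_label", "taxonomy", "truth_group"):
                if col in df.columns and row[col] != "":
                    entry[col] = row[col]
            meta[row["id"]] = entry

    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        extra = meta.get(entry.id, {})
        records.append(
            SequenceRecord(
                id=entry.id,
                residues=str(entry.seq),
                description=entry.description[len(entry.id):].strip(),
                **extra,
            )
        )
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    check_unique_ids(records)
    log.info("read %d sequences from %s", len(records), path)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def write_metadata(records: list[SequenceRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "is_seed": str(r.is_seed).lower(),
            "activity_label": r.activity_label or "",
            "taxonomy": r.taxonomy or "",
            "truth_group": r.truth_group or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def filter_fragments(
    records: list[SequenceRecord], min_len: int = 120
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition records into full-length sequences and fragments.

    Sequences shorter than ``min_len`` residues are treated as fragments;
    the default of 120 matches the usual catalytic-domain lower bound.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    kept = [r for r in records if len(r) >= min_len]
    removed = [r for r in records if len(r) < min_len]
    for r in removed:
        log.info("fragment removed: %s (length %d < %d)", r.id, len(r), min_len)
    log.info("fragment filter: %d kept, %d removed (min_len=%d)",
             len(kept), len(removed), min_len)
    return kept, removed


def write_graphml(network, node_attributes: dict[str, dict] | None, path: str | Path) -> None:
    """Export a sequence network to GraphML with typed node/edge attributes.

    Edge weights are identity percentages; node attributes (taxonomy,
    subfamily, group, ...) come from ``node_attributes`` keyed by node id.
    """
    g = nx.Graph()
    g.graph.update({k: v for k, v in network.graph.items()})
    for node in network.nodes:
        attrs = dict(network.nodes[node])
        if node_attributes and node in node_attributes:
            attrs.update({k: v for k, v in node_attributes[node].items() if v is not None})
        g.add_node(node, **attrs)
    for u, v, data in network.edges(data=True):
        g.add_edge(u, v, **data)
    nx.write_graphml(g, str(path))
    log.info("wrote GraphML: %d nodes, %d edges -> %s",
             g.number_of_nodes(), g.number_of_edges(), path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


_DOMTBL_COLUMNS = 22  # minimum fields of the per-domain tabular dialect


def read_hit_table(path: str | Path, dialect: str = "domtbl") -> list[RawHitRecord]:
    """Read per-domain hits from a tabular scan output.

    ``dialect='domtbl'`` parses the whitespace-separated per-domain table
    emitted by standard profile-search suites (target name in column 1,
    query/profile name in column 4, i-Evalue in column 13, score/bias in
    columns 14-15, envelope coordinates in columns 20-21).
    ``dialect='tsv'`` parses the package's own TSV written by
    :func:`write_hit_table`.
    """
    path = Path(path)
    hits: list[RawHitRecord] = []
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        for i, row in df.iterrows():
            try:
                hits.append(
                    RawHitRecord(
                        seq_id=str(row["seq_id"]),
                        profile_id=str(row["profile_id"]),
                        score=float(row["score"]),
                        bias=float(row["bias"]),
                        evalue=float(row["evalue"]),
                        start=int(row["start"]),
                        end=int(row["end"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: malformed row {i + 2}: {exc}") from exc
    elif dialect == "domtbl":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < _DOMTBL_COLUMNS:
                    raise ValueError(
                        f"{path}: malformed row at line {lineno}: "
                        f"expected >= {_DOMTBL_COLUMNS} fields, got {len(fields)}"
                    )
                try:
                    hits.append(
                        RawHitRecord(
                            seq_id=fields[0],
                            profile_id=fields[3],
                            evalue=float(fields[12]),
                            score=float(fields[13]),
                            bias=float(fields[14]),
                            start=int(fields[19]),
                            end=int(fields[20]),
                        )
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    else:
        raise ValueError(f"unknown hit-table dialect {dialect!r}")
    log.info("read %d domain hits from %s (%s)", len(hits), path, dialect)
    return hits


def write_hit_table(hits: list[RawHitRecord], path: str | Path) -> None:
    rows = [
        {
            "seq_id": h.seq_id,
            "profile_id": h.profile_id,
            "score": h.score,
            "bias": h.bias,
            "evalue": h.evalue,
            "start": h.start,
            "end": h.end,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=["seq_id", "profile_id", "score", "bias",
                                "evalue", "start", "end"]).to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(vars(config), fh, sort_keys=False)
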