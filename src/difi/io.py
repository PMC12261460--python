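"""Readers and writers for the on-disk formats, plus run manifests.

Conventions:

* residue positions are 1-based in every on-disk table (UniProt style) and
  0-based in memory; conversion happens here and only here;
* parsers reject malformed input instead of coercing it, naming file, line
  and field in the error;
* every CLI run writes exactly one JSON manifest with the resolved config,
  seed, input checksums and output paths.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .knowledge_maps import KnowledgeMap, Provenance

LABEL_COLUMN = "label"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into (accession, sequence) pairs.

    Sequences are upper-cased; wrapped lines are joined by the parser.
    Empty files and duplicate accessions are rejected.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate accession {rec.id!r}", path=path)
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError("no FASTA records found", path=path)
    return records


def write_fasta(records, path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path, label_column: str = LABEL_COLUMN):
    """Read a samples x genes table with a label column.

    TSV or CSV by extension; the first column is the sample id index. NA
    values and non-numeric expression cells are rejected.
    Returns ``(expr, labels)`` with ``expr`` a numeric DataFrame.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if label_column not in frame.columns:
        raise FormatError("missing label column", path=path, field=label_column)
    labels = frame[label_column].copy()
    expr = frame.drop(columns=[label_column])
    if expr.isna().any().any():
        gene = expr.columns[expr.isna().any()][0]
        row = expr.index[expr[gene].isna()][0]
        raise FormatError("NA expression value", path=path,
                          line=str(row), field=str(gene))
    try:
        expr = expr.astype(float)
    except (TypeError, ValueError):
        bad = [c for c in expr.columns
               if not pd.api.types.is_numeric_dtype(pd.to_numeric(expr[c], errors="coerce"))
               or pd.to_numeric(expr[c], errors="coerce").isna().any()]
        raise FormatError("non-numeric expression value", path=path,
                          field=str(bad[0]) if bad else "?") from None
    return expr, labels


def write_expression_matrix(expr: pd.DataFrame, labels, path,
                            label_column: str = LABEL_COLUMN) -> None:
    out = expr.copy()
    out[label_column] = np.asarray(labels)
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# knowledge maps


def write_knowledge_map(km: KnowledgeMap, path) -> None:
    """TSV with columns feature_id, score, mask (one header line).

    Integer feature ids (residue positions) are written 1-based; the
    provenance rides along in a leading comment line.
    """
    with open(path, "w") as fh:
        fh.write(f"# provenance={km.provenance.value}\n")
        fh.write("feature_id\tscore\tmask\n")
        for fid, score, mask in zip(km.feature_ids, km.scores, km.mask):
            disk_id = fid + 1 if isinstance(fid, (int, np.integer)) else fid
            fh.write(f"{disk_id}\t{float(score)!r}\t{int(mask)}\n")


def read_knowledge_map(path) -> KnowledgeMap:
    path = Path(path)
    provenance = Provenance.USER
    feature_ids, scores, mask = [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for n, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if line.startswith("# provenance="):
            provenance = Provenance(line.split("=", 1)[1])
        elif line.startswith("#") or not line.strip():
            continue
        else:
            body.append((n, line))
    if not body or body[0][1].split("\t") != ["feature_id", "score", "mask"]:
        raise FormatError("expected header 'feature_id\\tscore\\tmask'", path=path, line=1)
    for n, line in body[1:]:
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError("expected 3 tab-separated fields", path=path, line=n)
        fid_raw, score_raw, mask_raw = parts
        try:
            score = float(score_raw)
        except ValueError:
            raise FormatError("non-numeric score", path=path, line=n, field="score") from None
        if mask_raw not in ("0", "1"):
            raise FormatError("mask must be 0 or 1", path=path, line=n, field="mask")
        fid = int(fid_raw) - 1 if fid_raw.lstrip("-").isdigit() else fid_raw
        if isinstance(fid, int) and fid < 0:
            raise FormatError("positions on disk are 1-based", path=path, line=n,
                              field="feature_id")
        feature_ids.append(fid)
        scores.append(score)
        mask.append(int(mask_raw))
    return KnowledgeMap(tuple(feature_ids), np.array(scores), np.array(mask, dtype=float),
                        provenance)


# ---------------------------------------------------------------------------
# catalytic-site tables


def read_site_table(path, lengths: dict | None = None) -> dict[str, tuple[int, ...]]:
    """Accession -> 0-based positions, from a TSV of 1-based position lists.

    Format: ``accession<TAB>p1,p2,...`` with 1-based positions. When
    ``lengths`` is given, positions beyond an accession's length are
    rejected with the accession and offending position in the message.
    """
    path = Path(path)
    table: dict[str, tuple[int, ...]] = {}
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError("expected 'accession<TAB>positions'", path=path, line=n)
            acc, pos_raw = parts
            if acc in table:
                raise FormatError(f"duplicate accession {acc!r}", path=path, line=n)
            positions = []
            for token in pos_raw.split(","):
                token = token.strip()
                if not token.isdigit() or int(token) < 1:
                    raise FormatError(f"bad 1-based position {token!r} for {acc}",
                                      path=path, line=n, field="positions")
                pos = int(token)
                if lengths is not None and pos > lengths.get(acc, pos):
                    raise FormatError(
                        f"position {pos} out of range for {acc} "
                        f"(length {lengths[acc]})", path=path, line=n, field="positions",
                    )
                positions.append(pos - 1)
            table[acc] = tuple(positions)
    if not table:
        raise FormatError("no site entries found", path=path)
    return table


def write_site_table(sites: dict, path) -> None:
    """Inverse of :func:`read_site_table` (writes 1-based positions)."""
    with open(path, "w") as fh:
        for acc in sites:
            fh.write(f"{acc}\t{','.join(str(p + 1) for p in sites[acc])}\n")


# ---------------------------------------------------------------------------
# feature-map export


def write_feature_map(fm, path, feature_ids=None) -> None:
    ids = feature_ids if feature_ids is not None else (
        fm.feature_ids if fm.feature_ids is not None else range(len(fm.weights))
    )
    with open(path, "w") as fh:
        fh.write("feature_id\tweight\n")
        for fid, w in zip(ids, fm.weights):
            disk_id = fid + 1 if isinstance(fid, (int, np.integer)) else fid
            fh.write(f"{disk_id}\t{float(w)!r}\n")


# ---------------------------------------------------------------------------
# manifests


def sha256_of(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def new_manifest(command: str, config: dict, seed: int | None, inputs=()) -> RunManifest:
    return RunManifest(
        command=command, config=config, seed=seed,
        inputs={str(p): sha256_of(p) for p in inputs},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
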