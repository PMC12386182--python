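"""Readers and writers for the delimited-text artifacts.

Input formats
-------------
* **Counts + metadata CSV** (wide layout): first column ``gene_id``,
  remaining columns one per sample.  The first seven data rows form a
  metadata block keyed by reserved row names ``#experiment_id``,
  ``#condition_id``, ``#tissue``, ``#intensity_ppfd``, ``#duration_min``,
  ``#age_days``, ``#is_control``; all following rows are integer counts.
  A two-file layout (plain count matrix + per-sample metadata table) is
  accepted as well.
* **GO mapping** (TAIR GO-slim style TSV): gene id in the first column
  and a ``GO:NNNNNNN`` accession somewhere in the row.
* **Gene annotation TSV**: columns ``gene_id``, ``description``,
  ``tf_family`` (blank for non-TFs).

Outputs are tab-delimited UTF-8 with a header row; floats are written
with six significant digits.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from lightmeta.datamodel import (
    CountStudy,
    GeneAnnotation,
    SampleRecord,
    SchemaError,
    ValidationError,
)

log = logging.getLogger("lightmeta")

_META_ROWS = (
    "#experiment_id",
    "#condition_id",
    "#tissue",
    "#intensity_ppfd",
    "#duration_min",
    "#age_days",
    "#is_control",
)

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}

_GO_RE = re.compile(r"GO:\d{7}")


def _parse_bool(value: str, context: str) -> bool:
    try:
        return _BOOL[str(value).strip().lower()]
    except KeyError:
        raise ValidationError(f"{context}: cannot interpret {value!r} as boolean") from None


def read_count_study(
    path: str | Path,
    metadata_path: str | Path | None = None,
    delimiter: str = ",",
) -> CountStudy:
    """Load a count study from disk.

    With only ``path``, the wide single-file layout (metadata block +
    counts) is expected.  With ``metadata_path``, ``path`` is a plain
    gene x sample count matrix and metadata comes from the second file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise SchemaError(f"{path}: expected a gene-id column plus >=1 sample column")
    gene_col = raw.columns[0]
    sample_ids = [str(c) for c in raw.columns[1:]]
    raw = raw.set_index(gene_col)

    if metadata_path is None:
        missing = [m for m in _META_ROWS if m not in raw.index]
        if missing:
            raise SchemaError(
                f"{path}: missing metadata row(s) {missing}; "
                "supply a separate metadata file for the two-file layout"
            )
        meta = raw.loc[list(_META_ROWS)]
        counts_raw = raw.drop(index=list(_META_ROWS))
        meta_table = meta.T  # sample x field
        meta_table.columns = [c.lstrip("#") for c in meta_table.columns]
    else:
        counts_raw = raw
        meta_table = pd.read_csv(
            Path(metadata_path), sep=delimiter, dtype=str, keep_default_na=False
        )
        if "sample_id" not in meta_table.columns:
            raise SchemaError(f"{metadata_path}: missing 'sample_id' column")
        meta_table = meta_table.set_index("sample_id")
        absent = [s for s in sample_ids if s not in meta_table.index]
        if absent:
            raise SchemaError(f"{metadata_path}: no metadata for sample(s) {absent}")
        meta_table = meta_table.loc[sample_ids]

    required = [m.lstrip("#") for m in _META_ROWS]
    missing_cols = [c for c in required if c not in meta_table.columns]
    if missing_cols:
        raise SchemaError(f"metadata missing field(s) {missing_cols}")

    samples = []
    for sid in sample_ids:
        row = meta_table.loc[sid]
        samples.append(
            SampleRecord(
                sample_id=sid,
                experiment_id=str(row["experiment_id"]),
                condition_id=str(row["condition_id"]),
                tissue=str(row["tissue"]).strip().lower(),
                intensity_ppfd=float(row["intensity_ppfd"]),
                duration_min=float(row["duration_min"]),
                age_days=float(row["age_days"]),
                is_control=_parse_bool(row["is_control"], f"sample {sid!r}"),
            )
        )

    genes = [str(g) for g in counts_raw.index]
    mat = np.empty((len(genes), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        col = counts_raw[sid].to_numpy()
        for i, v in enumerate(col):
            try:
                f = float(v)
            except ValueError:
                raise ValidationError(
                    f"non-numeric count {v!r} at gene {genes[i]!r}, sample {sid!r}"
                ) from None
            if not np.isfinite(f) or f != int(f):
                raise ValidationError(
                    f"non-integer count {v!r} at gene {genes[i]!r}, sample {sid!r}"
                )
            if f < 0:
                raise ValidationError(
                    f"negative count {v!r} at gene {genes[i]!r}, sample {sid!r}"
                )
            mat[i, j] = int(f)
    return CountStudy(genes=genes, samples=samples, counts=mat)


def write_count_study(study: CountStudy, path: str | Path, delimiter: str = ",") -> None:
    """Write a study in the wide single-file layout read_count_study accepts."""
    path = Path(path)
    meta = {
        "#experiment_id": [s.experiment_id for s in study.samples],
        "#condition_id": [s.condition_id for s in study.samples],
        "#tissue": [s.tissue for s in study.samples],
        "#intensity_ppfd": [_fmt(s.intensity_ppfd) for s in study.samples],
        "#duration_min": [_fmt(s.duration_min) for s in study.samples],
        "#age_days": [_fmt(s.age_days) for s in study.samples],
        "#is_control": [str(s.is_control).lower() for s in study.samples],
    }
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["gene_id"] + study.sample_ids)
        for key in _META_ROWS:
            w.writerow([key] + meta[key])
        for i, g in enumerate(study.genes):
            w.writerow([g] + [int(v) for v in study.counts[i]])


def read_gene_annotation(
    go_path: str | Path, gene_path: str | Path
) -> dict[str, GeneAnnotation]:
    """Merge a flat GO mapping with a gene description/TF-family table.

    Genes present in the annotation table but absent from the GO file
    get an empty term set.  Malformed GO rows are skipped with a logged
    running count.
    """
    gene_path = Path(gene_path)
    go_path = Path(go_path)
    table = pd.read_csv(gene_path, sep="\t", dtype=str, keep_default_na=False,
                        comment="#")
    for col in ("gene_id", "description", "tf_family"):
        if col not in table.columns:
            raise SchemaError(f"{gene_path}: missing column {col!r}")

    go_terms: dict[str, set[str]] = {}
    skipped = 0
    with go_path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):  # comment lines
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                skipped += 1
                continue
            gene = fields[0].strip()
            m = _GO_RE.search(line)
            if not gene or m is None:
                skipped += 1
                continue
            go_terms.setdefault(gene, set()).add(m.group(0))
    if skipped:
        log.warning("read_gene_annotation: skipped %d malformed GO row(s)", skipped)

    out: dict[str, GeneAnnotation] = {}
    for _, row in table.iterrows():
        gid = row["gene_id"].strip()
        fam = row["tf_family"].strip() or None
        out[gid] = GeneAnnotation(
            gene_id=gid,
            description=row["description"],
            tf_family=fam,
            go_terms=frozenset(go_terms.get(gid, set())),
        )
    # genes only in the GO file still get an entry so they can serve in universes
    for gid, terms in go_terms.items():
        if gid not in out:
            out[gid] = GeneAnnotation(gene_id=gid, go_terms=frozenset(terms))
    return out


def _fmt(v: object, sig: int = 6) -> str:
    if isinstance(v, (float, np.floating)):
        if np.isnan(v):
            return "nan"
        return f"{v:.{sig}g}"
    return str(v)


def write_table(
    records,
    path: str | Path,
    header_comment: str | None = None,
    sig_digits: int = 6,
) -> None:
    """Write tabular records as tab-delimited UTF-8 with a header row.

    ``records`` may be a DataFrame, a list of dataclasses/dicts, or an
    empty list with no inferable schema (header-only file in that case
    only when a DataFrame carries columns).
    """
    if records is None:
        raise ValueError("records must not be None")
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        rows = list(records)
        if rows and not isinstance(rows[0], Mapping):
            rows = [vars(r) for r in rows]
        frame = pd.DataFrame(rows)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(list(frame.columns))
        for row in frame.itertuples(index=False):
            w.writerow([_fmt(v, sig_digits) for v in row])


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
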