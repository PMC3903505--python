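"""Readers and writers for the package's tabular text formats.

All tables are UTF-8, tab-separated, with a ``#``-prefixed header block
carrying the schema version (and, for count/fraction tables, per-sample
metadata lines). The formats are deliberately diff-able and spreadsheet-safe;
a minimal BIOM-like JSON dialect is supported for count tables as well.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .containers import CountTable
from .gradient import FractionRecord, FractionSet

__all__ = [
    "write_count_table",
    "read_count_table",
    "write_fraction_table",
    "read_fraction_table",
    "write_results",
    "gc_content_from_fasta",
]

COUNT_SCHEMA = "pyrosip count_table v1"
FRACTION_SCHEMA = "pyrosip fraction_table v1"
RESULTS_SCHEMA = "pyrosip results v1"
BIOM_FORMAT = "pyrosip biom-like 1.0"


def _sample_meta_line(sid: str, row: pd.Series) -> str:
    frac = row.get("fraction")
    frac = "" if pd.isna(frac) else str(int(frac))
    bin_ = row.get("bin")
    bin_ = "" if pd.isna(bin_) else str(bin_)
    return (
        f"# sample\t{sid}\tcondition={row['condition']}\t"
        f"fraction={frac}\tbin={bin_}\treplicate={row['replicate']}"
    )


def write_count_table(ct: CountTable, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# {COUNT_SCHEMA}"]
    for sid in ct.counts.columns:
        lines.append(_sample_meta_line(sid, ct.samples.loc[sid]))
    lineage_cols = list(ct.lineages.columns) if ct.lineages is not None else []
    header = ["taxon_id"] + [f"lineage:{c}" for c in lineage_cols] + list(ct.counts.columns)
    lines.append("\t".join(header))
    for taxon in ct.counts.index:
        row = [str(taxon)]
        for c in lineage_cols:
            row.append(str(ct.lineages.loc[taxon, c]) if taxon in ct.lineages.index else "")
        row += [str(int(v)) for v in ct.counts.loc[taxon]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_sample_line(parts: list[str], lineno: int) -> tuple[str, dict]:
    if len(parts) < 3:
        raise ValueError(f"line {lineno}: malformed sample metadata line")
    sid = parts[1]
    meta: dict = {}
    for kv in parts[2:]:
        if "=" not in kv:
            raise ValueError(f"line {lineno}: malformed key=value field {kv!r}")
        k, v = kv.split("=", 1)
        meta[k] = v
    frac = meta.get("fraction", "")
    return sid, {
        "condition": meta.get("condition", ""),
        "fraction": int(frac) if frac else pd.NA,
        "bin": meta.get("bin") or pd.NA,
        "replicate": meta.get("replicate", ""),
    }


def read_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Read a count table in the TSV dialect (default) or BIOM-like JSON.

    Duplicate taxon ids and non-integral counts are rejected with the
    offending taxon / line number named.
    """
    path = Path(path)
    if dialect == "biom-json":
        return _read_biom_json(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    sample_meta: dict[str, dict] = {}
    header: list[str] | None = None
    taxa: list[str] = []
    lineage_rows: list[list[str]] = []
    count_rows: list[list[int]] = []
    lineage_cols: list[str] = []
    n_cols = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line.split("\t")
                if parts[0].strip() == "# sample" or parts[0] == "# sample":
                    sid, meta = _parse_sample_line(parts, lineno)
                    sample_meta[sid] = meta
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[0] != "taxon_id":
                    raise ValueError(f"line {lineno}: expected 'taxon_id' header, got {header[0]!r}")
                lineage_cols = [c.split(":", 1)[1] for c in header if c.startswith("lineage:")]
                n_cols = len(header)
                continue
            if len(parts) != n_cols:
                raise ValueError(
                    f"line {lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            taxon = parts[0]
            if taxon in taxa:
                raise ValueError(f"line {lineno}: duplicate taxon id {taxon!r}")
            taxa.append(taxon)
            nl = len(lineage_cols)
            lineage_rows.append(parts[1:1 + nl])
            vals = []
            for col_name, v in zip(header[1 + nl:], parts[1 + nl:]):
                try:
                    fv = float(v)
                except ValueError:
                    raise ValueError(f"line {lineno}: non-numeric count {v!r}") from None
                if fv != int(fv):
                    raise ValueError(
                        f"line {lineno}: non-integral count {v!r} in sample {col_name!r}"
                    )
                vals.append(int(fv))
            count_rows.append(vals)
    if header is None:
        raise ValueError(f"{path}: no table header found")
    sample_ids = header[1 + len(lineage_cols):]
    counts = pd.DataFrame(count_rows, index=taxa, columns=sample_ids)
    samples = pd.DataFrame.from_dict(
        {sid: sample_meta.get(sid, {"condition": "", "fraction": pd.NA,
                                    "bin": pd.NA, "replicate": ""})
         for sid in sample_ids},
        orient="index",
    )
    lineages = (
        pd.DataFrame(lineage_rows, index=taxa, columns=lineage_cols)
        if lineage_cols else None
    )
    return CountTable(counts=counts, samples=samples, lineages=lineages)


def write_count_table_biom(ct: CountTable, path: str | Path) -> Path:
    """Write the BIOM-like JSON dialect (dense matrix, documented key set)."""
    path = Path(path)
    rows = []
    for taxon in ct.counts.index:
        md = {}
        if ct.lineages is not None and taxon in ct.lineages.index:
            md["lineage"] = {k: str(v) for k, v in ct.lineages.loc[taxon].items()}
        rows.append({"id": str(taxon), "metadata": md})
    cols = []
    for sid in ct.counts.columns:
        m = ct.samples.loc[sid]
        frac = m.get("fraction")
        cols.append({
            "id": sid,
            "metadata": {
                "condition": str(m["condition"]),
                "fraction": None if pd.isna(frac) else int(frac),
                "bin": None if pd.isna(m.get("bin")) else str(m.get("bin")),
                "replicate": str(m["replicate"]),
            },
        })
    doc = {
        "format": BIOM_FORMAT,
        "type": "OTU table",
        "matrix_type": "dense",
        "shape": list(ct.counts.shape),
        "rows": rows,
        "columns": cols,
        "data": ct.counts.to_numpy().astype(int).tolist(),
    }
    path.write_text(json.dumps(doc))
    return path


def _read_biom_json(path: Path) -> CountTable:
    doc = json.loads(path.read_text())
    if doc.get("format") != BIOM_FORMAT:
        raise ValueError(f"unexpected BIOM format tag {doc.get('format')!r}")
    taxa = [r["id"] for r in doc["rows"]]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxon ids: {dupes}")
    sample_ids = [c["id"] for c in doc["columns"]]
    counts = pd.DataFrame(doc["data"], index=taxa, columns=sample_ids)
    samples = pd.DataFrame.from_dict(
        {
            c["id"]: {
                "condition": c["metadata"].get("condition", ""),
                "fraction": c["metadata"].get("fraction") if c["metadata"].get("fraction") is not None else pd.NA,
                "bin": c["metadata"].get("bin") or pd.NA,
                "replicate": c["metadata"].get("replicate", ""),
            }
            for c in doc["columns"]
        },
        orient="index",
    )
    lineage_maps = {
        r["id"]: r.get("metadata", {}).get("lineage") for r in doc["rows"]
    }
    lineages = None
    if any(lineage_maps.values()):
        lineages = pd.DataFrame.from_dict(
            {k: (v or {}) for k, v in lineage_maps.items()}, orient="index"
        ).fillna("")
    return CountTable(counts=counts, samples=samples, lineages=lineages)


# ---------------------------------------------------------------------------
# fraction tables

_FRACTION_COLUMNS = ("index", "volume_ul", "density_g_ml", "dna_ng")


def write_fraction_table(fs: FractionSet, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"# {FRACTION_SCHEMA}",
        f"# sample\t{fs.sample}\tcondition={fs.condition}",
        "\t".join(_FRACTION_COLUMNS),
    ]
    for f in fs.fractions:
        lines.append(f"{f.index}\t{f.volume_ul:g}\t{f.density:.6f}\t{f.dna_ng:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_fraction_table(path: str | Path) -> FractionSet:
    path = Path(path)
    sample, condition = "", "control"
    header: list[str] | None = None
    records: list[FractionRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line.split("\t")
                if parts[0] == "# sample" and len(parts) >= 2:
                    sample = parts[1]
                    for kv in parts[2:]:
                        if kv.startswith("condition="):
                            condition = kv.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                missing = [c for c in _FRACTION_COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"missing column(s) {missing} in {path}")
                continue
            if len(parts) != len(header):
                raise ValueError(f"line {lineno}: expected {len(header)} fields")
            row = dict(zip(header, parts))
            try:
                records.append(
                    FractionRecord(
                        index=int(row["index"]),
                        volume_ul=float(row["volume_ul"]),
                        density=float(row["density_g_ml"]),
                        dna_ng=float(row["dna_ng"]),
                    )
                )
            except ValueError as e:
                raise ValueError(f"line {lineno}: {e}") from None
    if header is None:
        raise ValueError(f"{path}: no table header found")
    return FractionSet(records, sample=sample, condition=condition)


# ---------------------------------------------------------------------------
# results


def write_results(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write named result frames as schema-stamped TSVs into ``out_dir``.

    Column order is as given by each frame; the index is written as the first
    column. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in results.items():
        p = out_dir / f"{name}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(f"# {RESULTS_SCHEMA}\t{name}\n")
            frame.to_csv(fh, sep="\t")
        written.append(p)
    return written


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


# ---------------------------------------------------------------------------
# sequences


def gc_content_from_fasta(path: str | Path) -> dict[str, float]:
    """GC content per FASTA record: (G+C)/(A+C+G+T), ambiguity codes excluded."""
    out: dict[str, float] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        gc = s.count("G") + s.count("C")
        denom = gc + s.count("A") + s.count("T")
        if denom == 0:
            raise ValueError(f"record {rec.id!r} has no unambiguous bases")
        out[rec.id] = gc / denom
    return out
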