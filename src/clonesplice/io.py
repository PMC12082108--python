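"""Readers and writers for the package's on-disk formats.

Text formats carry a two-line comment header with the schema tag and the
generating seed; floating-point values are serialized at 6 decimals for
reproducible diffs.  Formats:

* VAF series CSV: variant, time_months, vaf, droplets, censored
* colony genotype TSV and binary mutation-matrix TSV
* junction counts: MatrixMarket ``.mtx`` + ``.rows.tsv`` (row id, genotype)
  + ``.junctions.bed`` BED-like sidecar (chrom, start, end, id, 0, strand, kind)
* GTF-lite transcript annotation (exon/CDS features, 1-based inclusive on
  disk, converted to 0-based half-open in memory)
* Newick clone trees and JSON reports
"""

from __future__ import annotations

import json
import re

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .dynamics import VafTimeSeries
from .errors import InputError
from .phylo import AgeInterval, BinaryMutationMatrix, CloneTree
from .splice import GenomeAnnotation, JunctionCountTable, Transcript

SCHEMA_VERSION = 1

__all__ = [
    "write_vaf_csv", "read_vaf_csv",
    "write_colony_table", "read_colony_table",
    "write_mutation_matrix", "read_mutation_matrix",
    "write_junction_counts", "read_junction_counts",
    "write_gtf", "read_gtf",
    "write_newick", "read_newick",
    "write_json_report", "read_json_report",
    "write_age_intervals",
]


def _header(kind: str, seed) -> str:
    return f"# clonesplice.{kind}.v{SCHEMA_VERSION}\n# seed={seed}\n"


def _read_table(path, sep, required, kind):
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:
        raise InputError(f"{path}: cannot parse {kind} table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    return df


def _fmt(x) -> str:
    return f"{float(x):.6f}"


# -- VAF series -------------------------------------------------------------

def write_vaf_csv(series, path, seed="NA") -> None:
    with open(path, "w") as fh:
        fh.write(_header("vaf", seed))
        fh.write("variant,time_months,vaf,droplets,censored\n")
        for s in series:
            for t, v, d, c in zip(s.times, s.vaf, s.droplets, s.censored):
                fh.write(f"{s.variant_id},{_fmt(t)},{_fmt(v)},{int(d)},{int(c)}\n")


def read_vaf_csv(path):
    df = _read_table(path, ",", ["variant", "time_months", "vaf", "droplets"], "VAF")
    if "censored" not in df.columns:
        df["censored"] = 0
    offset = _data_line_offset(path)
    for i, row in df.iterrows():
        try:
            float(row["time_months"]), float(row["vaf"]), int(row["droplets"])
        except (TypeError, ValueError) as exc:
            raise InputError(f"{path}: malformed row at line {offset + i + 1}") from exc
        if not 0.0 <= float(row["vaf"]) <= 1.0:
            raise InputError(f"{path}: VAF outside [0, 1] at line {offset + i + 1}")
    out = []
    for variant, sub in df.groupby("variant", sort=False):
        sub = sub.sort_values("time_months")
        out.append(VafTimeSeries(
            variant_id=str(variant),
            times=sub["time_months"].to_numpy(dtype=float),
            vaf=sub["vaf"].to_numpy(dtype=float),
            droplets=sub["droplets"].to_numpy(dtype=int),
            censored=sub["censored"].to_numpy(dtype=bool),
        ))
    return out


def _data_line_offset(path) -> int:
    """Line number (1-based) of the column header row."""
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                return n
    return 0


# -- colony tables and mutation matrices ------------------------------------

def write_colony_table(meta: pd.DataFrame, path, seed="NA") -> None:
    with open(path, "w") as fh:
        fh.write(_header("colonies", seed))
        meta.to_csv(fh, sep="\t")


def read_colony_table(path) -> pd.DataFrame:
    df = _read_table(path, "\t", ["colony", "compartment", "age_years"], "colony")
    return df.set_index("colony")


def write_mutation_matrix(matrix: BinaryMutationMatrix, path, seed="NA") -> None:
    df = matrix.matrix.copy()
    df.insert(0, "age_years", matrix.age_years if matrix.age_years is not None else np.nan)
    df.insert(0, "compartment",
              matrix.compartment if matrix.compartment is not None else "NA")
    with open(path, "w") as fh:
        fh.write(_header("mutation_matrix", seed))
        df.to_csv(fh, sep="\t", float_format="%.0f")


def read_mutation_matrix(path) -> BinaryMutationMatrix:
    df = _read_table(path, "\t", ["colony", "compartment", "age_years"], "mutation matrix")
    df = df.set_index("colony")
    compartment = df.pop("compartment")
    age = df.pop("age_years").astype(float)
    mat = df.astype(float)
    return BinaryMutationMatrix(matrix=mat, compartment=compartment, age_years=age)


# -- junction counts --------------------------------------------------------

def write_junction_counts(table: JunctionCountTable, prefix, seed="NA") -> None:
    prefix = str(prefix)
    m = sparse.csr_matrix(table.counts.to_numpy())
    spio.mmwrite(f"{prefix}.mtx", m,
                 comment=f"clonesplice.junctions.v{SCHEMA_VERSION} seed={seed}")
    with open(f"{prefix}.rows.tsv", "w") as fh:
        fh.write(_header("junction_rows", seed))
        fh.write("row_id\tgenotype\n")
        for rid in table.counts.index:
            fh.write(f"{rid}\t{table.genotypes[rid]}\n")
    with open(f"{prefix}.junctions.bed", "w") as fh:
        fh.write(_header("junction_sidecar", seed))
        for jid, row in table.junctions.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                     f"{jid}\t0\t{row['strand']}\t{row.get('kind', 'junction')}\n")


def read_junction_counts(prefix) -> JunctionCountTable:
    prefix = str(prefix)
    m = spio.mmread(f"{prefix}.mtx").toarray().astype(int)
    rows = _read_table(f"{prefix}.rows.tsv", "\t", ["row_id", "genotype"], "row")
    bed = pd.read_csv(
        f"{prefix}.junctions.bed", sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "junction_id", "score", "strand", "kind"],
    )
    if bed["junction_id"].duplicated().any():
        raise InputError(f"{prefix}.junctions.bed: duplicate junction ids")
    junc = bed.set_index("junction_id")[["chrom", "start", "end", "strand", "kind"]]
    if m.shape != (len(rows), len(junc)):
        raise InputError(
            f"{prefix}: matrix shape {m.shape} does not match "
            f"{len(rows)} rows x {len(junc)} junctions")
    counts = pd.DataFrame(m, index=pd.Index(rows["row_id"], name="cell"),
                          columns=junc.index)
    genotypes = pd.Series(rows["genotype"].to_numpy(), index=counts.index, name="genotype")
    return JunctionCountTable(counts=counts, junctions=junc, genotypes=genotypes)


# -- GTF-lite ---------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(annotation: GenomeAnnotation, path, seed="NA") -> None:
    """0-based half-open in memory -> 1-based inclusive GTF on disk."""
    with open(path, "w") as fh:
        fh.write(_header("gtf", seed))
        for t in annotation.transcripts.values():
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for feature, ivals in (("exon", t.exons), ("CDS", t.cds)):
                for s, e in sorted(ivals):
                    fh.write(f"{t.chrom}\tclonesplice\t{feature}\t{s + 1}\t{e}\t.\t"
                             f"{t.strand}\t.\t{attrs}\n")


def read_gtf(path) -> GenomeAnnotation:
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise InputError(f"{path}: malformed GTF row at line {n}")
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start) - 1, int(end)  # to 0-based half-open
            except ValueError as exc:
                raise InputError(f"{path}: non-integer coordinates at line {n}") from exc
            fields = dict(_GTF_ATTR.findall(attrs))
            if "transcript_id" not in fields or "gene_id" not in fields:
                raise InputError(f"{path}: missing gene_id/transcript_id at line {n}")
            rec = exons.setdefault(fields["transcript_id"], {
                "gene_id": fields["gene_id"], "chrom": chrom, "strand": strand,
                "exon": [], "CDS": [],
            })
            rec[feature].append((start, end))
    return GenomeAnnotation([
        Transcript(tid, rec["gene_id"], rec["chrom"], rec["strand"],
                   tuple(sorted(rec["exon"])), tuple(sorted(rec["CDS"])))
        for tid, rec in exons.items()
    ])


# -- trees, intervals, reports ----------------------------------------------

def write_newick(tree: CloneTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path) -> CloneTree:
    with open(path) as fh:
        return CloneTree.from_newick(fh.read())


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), 6)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def write_json_report(payload: dict, path, seed="NA") -> None:
    body = {"schema": f"clonesplice.report.v{SCHEMA_VERSION}", "seed": seed}
    body.update(_round_floats(payload))
    with open(path, "w") as fh:
        json.dump(body, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_age_intervals(intervals, path, seed="NA") -> None:
    write_json_report({
        "age_intervals": [
            {
                "mutation_id": iv.mutation_id,
                "lower_bound_years": iv.lower_bound_years,
                "point_estimate_years": iv.point_estimate_years,
                "upper_bound_years": iv.upper_bound_years,
                "confidence": iv.confidence,
            } for iv in intervals
        ]
    }, path, seed=seed)
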